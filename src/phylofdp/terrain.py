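"""Quadrat topography and ordered habitat classification.

A stem-mapped plot is divided into a lattice of square quadrats. From a
grid of surveyed corner-post elevations we derive, per quadrat, the three
topographic variables the habitat scheme uses:

* elevation — mean of the quadrat's four corner posts (m);
* slope — mean angular slope of the four planes through each triple of
  corner posts (degrees), the stem-plot convention;
* convexity — quadrat elevation minus the mean elevation of its rook
  neighbours (m); positive on ridges, negative in gullies.

Quadrats are then classified into five ordered habitat types by comparing
slope and elevation to their plot-wide medians, with the sign of convexity
splitting the high-elevation steep quadrats:

======  =============  ==============  ===========
label   slope          elevation       convexity
======  =============  ==============  ===========
V       < median       < median        any
LS      >= median      < median        any
HG      >= median      >= median       < 0
HS      >= median      >= median       >= 0
RT      < median       >= median       >= 0
======  =============  ==============  ===========

The combination slope < median, elevation >= median, convexity < 0 is not
covered by the published rules; by default it is assigned to HG, with
which it shares high elevation and concave form (configurable).

The habitat order V < LS < HG < RT < HS (ranks 1..5) reflects habitat
similarity and is what ordered-variable analyses downstream consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HABITAT_ORDER",
    "HABITAT_RANK",
    "TopographyGrid",
    "HabitatMap",
    "quadrat_topography",
    "classify_habitats",
    "aggregate_scale",
    "habitat_summary",
]

#: habitat labels in their similarity order (rank 1..5)
HABITAT_ORDER: tuple[str, ...] = ("V", "LS", "HG", "RT", "HS")
HABITAT_RANK: dict[str, int] = {h: i + 1 for i, h in enumerate(HABITAT_ORDER)}


@dataclass
class TopographyGrid:
    """Per-quadrat topography on a regular lattice.

    Arrays are indexed ``[row, col]`` with row 0 at y=0; ``quadrat_m`` is
    the quadrat side length in metres.
    """

    elevation: np.ndarray  # m
    slope: np.ndarray  # degrees
    convexity: np.ndarray  # m
    quadrat_m: float

    def __post_init__(self) -> None:
        for name in ("elevation", "slope", "convexity"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.elevation.shape:
                raise ValueError("topography field shapes differ")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if self.elevation.size == 0:
            raise ValueError("empty topography grid")

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.elevation.shape)
        return pd.DataFrame(
            {
                "col": cols.ravel(),
                "row": rows.ravel(),
                "elevation_m": self.elevation.ravel(),
                "slope_deg": self.slope.ravel(),
                "convexity_m": self.convexity.ravel(),
            }
        )


@dataclass
class HabitatMap:
    """Ordered habitat label per quadrat, plus the medians that defined it."""

    labels: np.ndarray  # dtype '<U2', shape (n_rows, n_cols)
    quadrat_m: float
    median_slope: float = float("nan")
    median_elevation: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U2")
        bad = set(self.labels.ravel()) - set(HABITAT_ORDER)
        if bad:
            raise ValueError(f"unknown habitat labels: {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.labels.shape[1]

    def ranks(self) -> np.ndarray:
        """Ordinal habitat score per quadrat (V=1 ... HS=5)."""
        out = np.zeros(self.labels.shape, dtype=int)
        for lab, r in HABITAT_RANK.items():
            out[self.labels == lab] = r
        return out

    def counts(self) -> dict[str, int]:
        return {h: int((self.labels == h).sum()) for h in HABITAT_ORDER}

    def areas_ha(self) -> dict[str, float]:
        per = (self.quadrat_m**2) / 1e4
        return {h: n * per for h, n in self.counts().items()}

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.labels.shape)
        return pd.DataFrame(
            {"col": cols.ravel(), "row": rows.ravel(), "habitat": self.labels.ravel()}
        )


def _lower_median(x: np.ndarray) -> float:
    """Median as the lower of the two central order statistics for even n.

    Deterministic and independent of input order, so classification never
    depends on how quadrats happen to be enumerated.
    """
    x = np.sort(np.asarray(x).ravel())
    return float(x[(len(x) - 1) // 2])


def quadrat_topography(corner_elevations: np.ndarray, quadrat_m: float) -> TopographyGrid:
    """Derive per-quadrat topography from a corner-post elevation grid.

    ``corner_elevations`` has shape (n_rows+1, n_cols+1): one elevation per
    lattice corner. See the module docstring for the three derived fields.
    """
    z = np.asarray(corner_elevations, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("corner grid must be at least 2x2")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite corner elevations")
    if quadrat_m <= 0:
        raise ValueError("quadrat size must be positive")
    d = float(quadrat_m)
    # corners per quadrat: z00 lower-left, z10 +x, z01 +y, z11 opposite
    z00 = z[:-1, :-1]
    z01 = z[1:, :-1]
    z10 = z[:-1, 1:]
    z11 = z[1:, 1:]
    elevation = (z00 + z01 + z10 + z11) / 4.0

    def plane_slope(za, zb, zc):
        # plane through 3 corners with zb at +x and zc at +y of za
        gx = (zb - za) / d
        gy = (zc - za) / d
        return np.degrees(np.arctan(np.hypot(gx, gy)))

    slope = (
        plane_slope(z00, z10, z01)
        + plane_slope(z10, z00, z11)  # omit z01: base at z10, +x back to z00
        + plane_slope(z01, z11, z00)
        + plane_slope(z11, z01, z10)
    ) / 4.0

    # convexity: elevation minus the mean of rook-neighbour elevations;
    # edge quadrats simply use the neighbours that exist.
    nbr_sum = np.zeros_like(elevation)
    nbr_cnt = np.zeros_like(elevation)
    nbr_sum[1:, :] += elevation[:-1, :]
    nbr_cnt[1:, :] += 1
    nbr_sum[:-1, :] += elevation[1:, :]
    nbr_cnt[:-1, :] += 1
    nbr_sum[:, 1:] += elevation[:, :-1]
    nbr_cnt[:, 1:] += 1
    nbr_sum[:, :-1] += elevation[:, 1:]
    nbr_cnt[:, :-1] += 1
    if elevation.size == 1:
        convexity = np.zeros_like(elevation)
    else:
        convexity = elevation - nbr_sum / nbr_cnt
    return TopographyGrid(elevation=elevation, slope=slope, convexity=convexity, quadrat_m=d)


def classify_habitats(topography: TopographyGrid, gap_label: str = "HG") -> HabitatMap:
    """Assign every quadrat one of the five ordered habitat labels.

    Medians are plot-wide lower medians. Convexity zero goes with the
    positive class (HS/RT), which guarantees total coverage. ``gap_label``
    receives the rule-free combination described in the module docstring.
    """
    if gap_label not in HABITAT_ORDER:
        raise ValueError(f"gap_label must be one of {HABITAT_ORDER}")
    med_slope = _lower_median(topography.slope)
    med_elev = _lower_median(topography.elevation)
    lo_slope = topography.slope < med_slope
    lo_elev = topography.elevation < med_elev
    concave = topography.convexity < 0

    labels = np.empty(topography.elevation.shape, dtype="<U2")
    labels[lo_slope & lo_elev] = "V"
    labels[~lo_slope & lo_elev] = "LS"
    labels[~lo_slope & ~lo_elev & concave] = "HG"
    labels[~lo_slope & ~lo_elev & ~concave] = "HS"
    labels[lo_slope & ~lo_elev & ~concave] = "RT"
    labels[lo_slope & ~lo_elev & concave] = gap_label
    return HabitatMap(
        labels=labels,
        quadrat_m=topography.quadrat_m,
        median_slope=med_slope,
        median_elevation=med_elev,
    )


@dataclass
class AggregationResult:
    """A community matrix re-binned to a coarser lattice.

    ``truncated_cells`` lists the base-scale (row, col) quadrats that fall
    in partial strips the coarse lattice cannot cover and were dropped.
    """

    matrix: pd.DataFrame  # coarse cells x species
    cell_coords: pd.DataFrame  # coarse (row, col) per matrix row
    factor: int
    truncated_cells: list[tuple[int, int]] = field(default_factory=list)


def aggregate_scale(community, factor: int) -> AggregationResult:
    """Re-bin a quadrat x species community matrix by an integer factor.

    ``factor`` 2 turns a 20 m lattice into 40 m cells, 5 into 100 m cells.
    Plot sides not divisible by the coarse cell leave a partial strip of
    base quadrats, which is truncated and reported.
    """
    from .community import CommunityMatrix

    if factor not in (2, 5):
        raise ValueError("supported aggregation factors are 2 and 5")
    if not isinstance(community, CommunityMatrix):
        raise TypeError("aggregate_scale expects a CommunityMatrix")
    n_rows_c = community.n_rows // factor
    n_cols_c = community.n_cols // factor
    if n_rows_c == 0 or n_cols_c == 0:
        raise ValueError("plot smaller than one coarse cell")
    truncated = [
        (r, c)
        for r in range(community.n_rows)
        for c in range(community.n_cols)
        if r >= n_rows_c * factor or c >= n_cols_c * factor
    ]
    counts = community.counts  # (n_rows, n_cols, n_species)
    kept = counts[: n_rows_c * factor, : n_cols_c * factor, :]
    coarse = kept.reshape(n_rows_c, factor, n_cols_c, factor, -1).sum(axis=(1, 3))
    rows, cols = np.indices((n_rows_c, n_cols_c))
    matrix = pd.DataFrame(
        coarse.reshape(n_rows_c * n_cols_c, -1), columns=community.species
    )
    cell_coords = pd.DataFrame({"row": rows.ravel(), "col": cols.ravel()})
    return AggregationResult(
        matrix=matrix, cell_coords=cell_coords, factor=factor, truncated_cells=truncated
    )


def habitat_summary(habitat_map: HabitatMap, community) -> pd.DataFrame:
    """Plot summary per habitat: area, quadrats, richness, stems, density.

    Density is always the computed quotient stems / area (no rounding of
    intermediate values), with area in hectares.
    """
    per_ha = (habitat_map.quadrat_m**2) / 1e4
    flat = habitat_map.labels.ravel()
    rows = []
    for h in HABITAT_ORDER:
        mask = flat == h
        n_quad = int(mask.sum())
        area = n_quad * per_ha
        sub = community.matrix.values[mask, :]
        stems = int(sub.sum())
        richness = int((sub.sum(axis=0) > 0).sum())
        rows.append(
            {
                "habitat": h,
                "n_quadrats": n_quad,
                "area_ha": area,
                "n_species": richness,
                "n_stems": stems,
                "density_per_ha": stems / area if area > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
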