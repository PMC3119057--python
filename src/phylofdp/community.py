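"""Stem maps and the quadrat x species community matrix built from them."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StemMap", "CommunityMatrix", "build_community_matrix"]


@dataclass
class StemMap:
    """Individual mapped stems: x/y in metres, one species label each."""

    stems: pd.DataFrame  # columns: stem_id, x_m, y_m, species
    plot_x_m: float
    plot_y_m: float

    def __post_init__(self) -> None:
        required = {"stem_id", "x_m", "y_m", "species"}
        missing = required - set(self.stems.columns)
        if missing:
            raise ValueError(f"stem table lacks columns: {sorted(missing)}")

    @property
    def n_stems(self) -> int:
        return len(self.stems)

    def species_abundances(self) -> pd.Series:
        return self.stems["species"].value_counts().sort_index()

    def to_tsv(self, path) -> None:
        self.stems.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, plot_x_m: float, plot_y_m: float) -> "StemMap":
        return cls(pd.read_csv(path, sep="\t"), plot_x_m=plot_x_m, plot_y_m=plot_y_m)


class CommunityMatrix:
    """Quadrat x species abundance counts on a regular lattice.

    Quadrats are enumerated row-major (row 0 first), matching the flat
    ordering used by :class:`~phylofdp.terrain.HabitatMap` views.
    """

    def __init__(self, counts: np.ndarray, species: list[str], quadrat_m: float):
        counts = np.asarray(counts)
        if counts.ndim != 3 or counts.shape[2] != len(species):
            raise ValueError("counts must be (n_rows, n_cols, n_species)")
        if (counts < 0).any():
            raise ValueError("negative abundance")
        self.counts = counts.astype(np.int64)
        self.species = list(species)
        self.quadrat_m = float(quadrat_m)

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]

    @property
    def n_quadrats(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def matrix(self) -> pd.DataFrame:
        """Flat quadrat x species DataFrame (row-major quadrat order)."""
        return pd.DataFrame(
            self.counts.reshape(self.n_quadrats, -1), columns=self.species
        )

    def presence(self) -> np.ndarray:
        return (self.counts.reshape(self.n_quadrats, -1) > 0).astype(np.int8)

    def total_stems(self) -> int:
        return int(self.counts.sum())

    def richness(self) -> np.ndarray:
        """Species count per quadrat, flat row-major order."""
        return (self.counts.reshape(self.n_quadrats, -1) > 0).sum(axis=1)


def build_community_matrix(stem_map: StemMap, quadrat_m: float = 20.0) -> CommunityMatrix:
    """Bin stems into quadrats: stem (x, y) -> quadrat (floor(x/q), floor(y/q)).

    Raises if any stem lies outside [0, plot_x) x [0, plot_y).
    """
    x = stem_map.stems["x_m"].to_numpy(dtype=float)
    y = stem_map.stems["y_m"].to_numpy(dtype=float)
    if ((x < 0) | (x >= stem_map.plot_x_m) | (y < 0) | (y >= stem_map.plot_y_m)).any():
        bad = stem_map.stems[
            (x < 0) | (x >= stem_map.plot_x_m) | (y < 0) | (y >= stem_map.plot_y_m)
        ]
        raise ValueError(f"{len(bad)} stems outside the plot, first: "
                         f"{bad.iloc[0].to_dict()}")
    n_cols = int(round(stem_map.plot_x_m / quadrat_m))
    n_rows = int(round(stem_map.plot_y_m / quadrat_m))
    col = np.floor(x / quadrat_m).astype(int)
    row = np.floor(y / quadrat_m).astype(int)
    species = sorted(stem_map.stems["species"].unique())
    sp_index = {s: i for i, s in enumerate(species)}
    sp = stem_map.stems["species"].map(sp_index).to_numpy()
    counts = np.zeros((n_rows, n_cols, len(species)), dtype=np.int64)
    np.add.at(counts, (row, col, sp), 1)
    return CommunityMatrix(counts, species, quadrat_m)
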