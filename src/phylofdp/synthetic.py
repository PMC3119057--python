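"""Synthetic stem-mapped forest plots with tunable habitat structure.

Real forest-dynamics-plot censuses are rarely redistributable, so every
downstream stage of this package is exercised against plots generated
here. The generator emulates the statistical features the analyses
assume, at the scale of a 400 m x 500 m, 20-ha subtropical plot:

* smooth terrain (low-pass-filtered Gaussian noise) from which slope and
  convexity, and hence the five ordered habitat types, are derived;
* an ultrametric pure-birth phylogeny over the species pool;
* a habitat-preference trait evolved on that tree with tunable
  phylogenetic signal (a weighted mix of a Brownian realization and
  independent noise, mapped onto the ordered habitat scale 1..5);
* a log-series species-abundance distribution (strong dominance, many
  rare species) totalling the configured stem count;
* spatially aggregated stem placement via a Thomas cluster process, with
  habitat filtering applied as an acceptance kernel
  ``exp(-filtering_strength * |preference - quadrat habitat rank|)``.

Setting ``filtering_strength = 0`` and ``signal_strength = 0`` gives the
neutral limit: stems ignore habitat and the trait ignores the tree, so
association tests, signal tests and SES metrics should all be calibrated
at their nominal levels.

One global seed deterministically spawns independent substreams per
stage (terrain, tree, trait, abundances, placement), so re-running any
stage with the same config reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats
import yaml

from .community import StemMap
from .phylogeny import Phylogeny, brownian_trait, yule_tree
from .terrain import HabitatMap, TopographyGrid, quadrat_topography

__all__ = [
    "SimulationConfig",
    "generate_topography",
    "generate_phylogeny",
    "evolve_habitat_preference",
    "generate_stem_map",
    "taxonomy_from_tree",
    "generate_forest",
    "ForestDataset",
]

# substream indices for the per-stage random generators
_STAGES = {"terrain": 0, "phylogeny": 1, "preference": 2, "abundance": 3, "stems": 4}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic plot.

    Defaults describe a 20-ha plot matching the census scale the package
    emulates: 500 x 400 m, 20 m quadrats, 183 species, 71,336 stems,
    moderate habitat filtering acting on a strongly heritable habitat
    preference.
    """

    plot_x_m: float = 500.0
    plot_y_m: float = 400.0
    quadrat_m: float = 20.0
    n_species: int = 183
    n_stems: int = 71336
    terrain_smoothness: float = 3.0  # correlation length, quadrats
    terrain_relief_m: float = 30.0  # sd of the elevation field, m
    signal_strength: float = 0.8  # 0 = no phylogenetic signal, 1 = pure Brownian
    filtering_strength: float = 2.0  # 0 = neutral placement
    cluster_rate: float = 8.0  # Thomas parents per species
    cluster_sd: float = 25.0  # Gaussian offspring spread, m
    abundance_shape: float = 0.9997  # log-series parameter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plot_x_m <= 0 or self.plot_y_m <= 0 or self.quadrat_m <= 0:
            raise ValueError("plot and quadrat dimensions must be positive")
        for side, name in ((self.plot_x_m, "plot_x_m"), (self.plot_y_m, "plot_y_m")):
            if abs(side / self.quadrat_m - round(side / self.quadrat_m)) > 1e-9:
                raise ValueError(f"{name} must be divisible by quadrat_m")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_stems < self.n_species:
            raise ValueError("need at least one stem per species")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.filtering_strength < 0:
            raise ValueError("filtering_strength must be non-negative")
        if self.terrain_smoothness <= 0 or self.terrain_relief_m < 0:
            raise ValueError("terrain_smoothness > 0 and terrain_relief_m >= 0 required")
        if not 0.0 < self.abundance_shape < 1.0:
            raise ValueError("abundance_shape is a log-series parameter in (0, 1)")
        if self.cluster_rate <= 0 or self.cluster_sd <= 0:
            raise ValueError("cluster parameters must be positive")

    @property
    def n_cols(self) -> int:
        return int(round(self.plot_x_m / self.quadrat_m))

    @property
    def n_rows(self) -> int:
        return int(round(self.plot_y_m / self.quadrat_m))

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible generator for a named stage."""
        key = _STAGES[stage]
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )


def generate_topography(config: SimulationConfig) -> TopographyGrid:
    """Smooth synthetic terrain on the plot's corner-post lattice.

    White noise on the (n_rows+1) x (n_cols+1) corner grid is low-pass
    filtered with a Gaussian kernel of width ``terrain_smoothness``
    (in quadrats), standardized, and scaled to ``terrain_relief_m``
    around a 326.3 m base elevation. ``terrain_relief_m = 0`` yields the
    flat-terrain limit (zero slope and convexity everywhere).
    """
    rng = config.rng("terrain")
    shape = (config.n_rows + 1, config.n_cols + 1)
    noise = rng.standard_normal(shape)
    smooth = scipy.ndimage.gaussian_filter(noise, sigma=config.terrain_smoothness,
                                           mode="reflect")
    sd = smooth.std()
    if config.terrain_relief_m == 0 or sd == 0:
        corners = np.full(shape, 326.3)
    else:
        corners = 326.3 + (smooth - smooth.mean()) / sd * config.terrain_relief_m
    return quadrat_topography(corners, config.quadrat_m)


def generate_phylogeny(n_species: int, seed: int) -> Phylogeny:
    """Ultrametric pure-birth tree, root depth 1, tips ``sp001...``."""
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGES["phylogeny"],))
    )
    return yule_tree(n_species, rng)


def evolve_habitat_preference(
    phylogeny: Phylogeny, signal_strength: float, seed: int
) -> dict[str, float]:
    """Habitat-preference trait with tunable phylogenetic signal.

    The latent trait is ``s * z(BM) + sqrt(1 - s^2) * z(noise)`` where BM
    is one Brownian realization on the tree, the noise is i.i.d. across
    tips and ``z`` standardizes; at ``s = 1`` the trait is pure Brownian,
    at ``s = 0`` it is phylogeny-free. The latent values are mapped
    affinely (min -> 1, max -> 5) onto the ordered habitat score scale;
    an affine map keeps Blomberg's K of the preference exactly equal to
    that of the latent trait, so the Brownian limit stays K ~ 1.
    """
    if not 0.0 <= signal_strength <= 1.0:
        raise ValueError("signal_strength must be in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STAGES["preference"],))
    )
    bm = brownian_trait(phylogeny, rng)
    taxa = phylogeny.taxa
    x = np.array([bm[t] for t in taxa])
    noise = rng.standard_normal(len(taxa))

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    s = signal_strength
    latent = s * z(x) + np.sqrt(1.0 - s * s) * z(noise)
    span = np.ptp(latent)
    if span == 0:  # degenerate draw: put everyone mid-scale
        return dict.fromkeys(taxa, 3.0)
    scores = 1.0 + 4.0 * (latent - latent.min()) / span
    return dict(zip(taxa, scores))


def _logseries_abundances(
    n_species: int, n_stems: int, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Abundances summing exactly to ``n_stems``, one stem guaranteed each.

    Log-series draws set the relative weights; stems beyond the guaranteed
    one per species are allocated multinomially.
    """
    weights = scipy.stats.logser.rvs(shape, size=n_species, random_state=rng).astype(float)
    p = weights / weights.sum()
    extra = rng.multinomial(n_stems - n_species, p)
    return extra + 1


def generate_stem_map(
    habitat_map: HabitatMap,
    preferences: dict[str, float],
    config: SimulationConfig,
    max_rounds: int = 1000,
) -> StemMap:
    """Place every stem by a Thomas cluster process with habitat filtering.

    Per species: Poisson(cluster_rate) parent points (at least one) fall
    uniformly in the plot; each stem is a Gaussian offset from a random
    parent, wrapped toroidally so it stays in bounds. A proposed location
    in a quadrat of habitat rank ``h`` is accepted with probability
    ``exp(-filtering_strength * |preference - h|)``. A species whose
    stems are still unplaced after ``max_rounds`` proposal rounds raises.
    """
    species = sorted(preferences)
    if len(species) != config.n_species:
        raise ValueError("preferences must cover exactly the configured species")
    ab_rng = config.rng("abundance")
    abundances = _logseries_abundances(
        config.n_species, config.n_stems, config.abundance_shape, ab_rng
    )
    rng = config.rng("stems")
    ranks = habitat_map.ranks()  # (n_rows, n_cols)
    q = config.quadrat_m
    fs = config.filtering_strength
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    labels: list[str] = []
    for sp, a in zip(species, abundances):
        n_par = max(1, rng.poisson(config.cluster_rate))
        par = rng.uniform(0, [config.plot_x_m, config.plot_y_m], size=(n_par, 2))
        pref = preferences[sp]
        need = int(a)
        got_x: list[np.ndarray] = []
        got_y: list[np.ndarray] = []
        for _ in range(max_rounds):
            if need == 0:
                break
            pick = rng.integers(n_par, size=need)
            prop = par[pick] + rng.normal(0.0, config.cluster_sd, size=(need, 2))
            prop[:, 0] %= config.plot_x_m
            prop[:, 1] %= config.plot_y_m
            col = np.minimum((prop[:, 0] / q).astype(int), habitat_map.n_cols - 1)
            row = np.minimum((prop[:, 1] / q).astype(int), habitat_map.n_rows - 1)
            p_acc = np.exp(-fs * np.abs(pref - ranks[row, col]))
            keep = rng.random(need) < p_acc
            got_x.append(prop[keep, 0])
            got_y.append(prop[keep, 1])
            need -= int(keep.sum())
        if need > 0:
            raise RuntimeError(
                f"could not place all stems of species {sp!r} within "
                f"{max_rounds} proposal rounds (preference {pref:.2f}, "
                f"filtering_strength {fs})"
            )
        xs.append(np.concatenate(got_x) if got_x else np.empty(0))
        ys.append(np.concatenate(got_y) if got_y else np.empty(0))
        labels.extend([sp] * int(a))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    stems = pd.DataFrame(
        {
            "stem_id": np.arange(1, len(x) + 1),
            "x_m": x,
            "y_m": y,
            "species": labels,
        }
    )
    return StemMap(stems=stems, plot_x_m=config.plot_x_m, plot_y_m=config.plot_y_m)


def taxonomy_from_tree(
    phylogeny: Phylogeny, family_depth: float = 0.6, genus_depth: float = 0.85
) -> pd.DataFrame:
    """Derive a nested species/genus/family table from clade structure.

    Genera are the maximal clades whose stem crosses ``genus_depth``
    (fraction of root-to-tip depth), families likewise at
    ``family_depth``; the taxonomy is therefore perfectly congruent with
    the tree, as a backbone-tree comparison baseline requires.
    """
    if not 0 < family_depth < genus_depth < 1:
        raise ValueError("need 0 < family_depth < genus_depth < 1")
    total = float(np.mean(phylogeny.tip_depths()))
    rows: list[dict[str, str]] = []
    fam_i = 0

    def node_tips(node) -> list[str]:
        return sorted(l.taxon.label for l in node.leaf_iter())

    def depth(node) -> float:
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d / total

    def crossing_clades(root, cut: float):
        """Maximal nodes whose subtending edge crosses the cut depth."""
        found = []
        stack = [root]
        while stack:
            n = stack.pop()
            d_child = depth(n)
            d_parent = depth(n.parent_node) if n.parent_node is not None else 0.0
            if d_child >= cut > d_parent or n.is_leaf():
                found.append(n)
            else:
                stack.extend(n.child_nodes())
        return found

    root = phylogeny.tree.seed_node
    for fam_node in crossing_clades(root, family_depth):
        fam_i += 1
        fam = f"fam{fam_i:03d}"
        gen_i = 0
        for gen_node in crossing_clades(fam_node, genus_depth):
            gen_i += 1
            gen = f"{fam}_gen{gen_i:02d}"
            for sp in node_tips(gen_node):
                rows.append({"species": sp, "genus": gen, "family": fam})
    df = pd.DataFrame(rows).sort_values("species").reset_index(drop=True)
    if len(df) != phylogeny.n_tips:
        raise RuntimeError("taxonomy derivation lost or duplicated tips")
    return df


@dataclass
class ForestDataset:
    """Everything one synthetic census comprises."""

    config: SimulationConfig
    topography: TopographyGrid
    habitat_map: HabitatMap
    phylogeny: Phylogeny
    preferences: dict[str, float]
    stem_map: StemMap
    taxonomy: pd.DataFrame

    def write(self, outdir) -> None:
        """Write stems.tsv, topography.tsv, habitatmap.tsv, tree.nwk,
        taxonomy.tsv and a config echo into ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.stem_map.to_tsv(out / "stems.tsv")
        self.topography.to_frame().to_csv(out / "topography.tsv", sep="\t", index=False)
        self.habitat_map.to_frame().to_csv(out / "habitatmap.tsv", sep="\t", index=False)
        (out / "tree.nwk").write_text(self.phylogeny.to_newick() + "\n")
        self.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self.config), fh)


def generate_forest(config: SimulationConfig) -> ForestDataset:
    """Run every generation stage in order for one config."""
    from .terrain import classify_habitats

    topo = generate_topography(config)
    habitat_map = classify_habitats(topo)
    phylogeny = generate_phylogeny(config.n_species, config.seed)
    preferences = evolve_habitat_preference(
        phylogeny, config.signal_strength, config.seed
    )
    stem_map = generate_stem_map(habitat_map, preferences, config)
    taxonomy = taxonomy_from_tree(phylogeny)
    return ForestDataset(
        config=config,
        topography=topo,
        habitat_map=habitat_map,
        phylogeny=phylogeny,
        preferences=preferences,
        stem_map=stem_map,
        taxonomy=taxonomy,
    )
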