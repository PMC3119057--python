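"""End-to-end orchestration of the community-assembly analysis.

One config drives the full chain: (optionally) simulate a plot →
classify habitats → torus-translation association tests → phylogenetic
signal of median habitat → NRI/NTI under the swap null (per spatial
scale, for both the primary tree and the taxonomy-backbone tree) →
SAR-GLS habitat means → paired tree comparison and richness ANOVA →
assembly-process labels per habitat. All randomized stages draw from
substreams of one seed, so a rerun with the same config reproduces
every table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import results_frame, summarize_associations, torus_test
from .community import CommunityMatrix, StemMap, build_community_matrix
from .phylogeny import Phylogeny, taxonomy_tree, ultrametricize
from .signal import SignalResult, k_permutation_test, median_habitat_score
from .spatial import paired_phylogeny_comparison, richness_anova, rook_weights, sar_gls
from .structure import ses_frame, ses_structure, habitat_pool_ses
from .synthetic import ForestDataset, SimulationConfig, generate_forest
from .terrain import HABITAT_ORDER, aggregate_scale, habitat_summary

logger = logging.getLogger("phylofdp")

__all__ = ["AnalysisConfig", "PipelineResult", "run_pipeline", "interpret_framework"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of one full analysis run.

    Either ``simulate`` holds a :class:`SimulationConfig`, or the four
    input paths point at an existing dataset (stems.tsv, topography or
    habitat map, tree.nwk, taxonomy.tsv).
    """

    simulate: SimulationConfig | None = None
    stems_tsv: str | None = None
    tree_nwk: str | None = None
    taxonomy_tsv: str | None = None
    habitatmap_tsv: str | None = None
    plot_x_m: float = 500.0
    plot_y_m: float = 400.0
    quadrat_m: float = 20.0
    alpha: float = 0.05
    min_stems: int = 20
    n_null: int = 999
    n_perm: int = 999
    scales: tuple[int, ...] = (20, 40, 100)
    swap_burnin: int = 500_000
    swap_thin: int = 50_000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_null < 1 or self.n_perm < 1:
            raise ValueError("n_null and n_perm must be at least 1")
        if self.simulate is None and (self.stems_tsv is None or self.tree_nwk is None):
            raise ValueError("either a simulate block or input paths are required")
        base = self.quadrat_m
        for s in self.scales:
            if s % int(base) != 0 or (s // int(base)) not in (1, 2, 5):
                raise ValueError(f"unsupported scale {s} for base {base}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # where results land must not change what they are
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: AnalysisConfig
    dataset: ForestDataset | None
    habitat_table: pd.DataFrame
    associations: pd.DataFrame
    association_summary: pd.DataFrame
    signal: SignalResult
    ses: dict[tuple[str, int], pd.DataFrame]  # (tree source, scale m) -> table
    habitat_pool: dict[str, pd.DataFrame]
    sar: dict[tuple[str, str], object]  # (source, metric) -> SARFit
    comparisons: pd.DataFrame
    anova: dict
    labels: dict[str, str]
    manifest: dict


def interpret_framework(
    signal_result: SignalResult,
    habitat_mean_tests: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Assembly-process label per habitat from the signal x dispersion grid.

    A habitat whose mean SES is significantly positive is clustered,
    significantly negative overdispersed, otherwise random. Crossed with
    the signal test (two-tailed permutation p <= alpha; K above the null
    median = signal, below = 'anti-signal'):

    * signal + clustered → Habitat Filtering; signal + overdispersed →
      Limiting Similarity;
    * anti-signal + clustered → Limiting Similarity; anti-signal +
      overdispersed → Habitat Filtering;
    * random assemblage → Neutrality regardless of signal;
    * non-random assemblage without a significant signal test →
      Indeterminate (the grid's premise is unmet).
    """
    required = {"habitat", "mean", "p"}
    if not required <= set(habitat_mean_tests.columns):
        raise ValueError(f"habitat_mean_tests needs columns {sorted(required)}")
    has_signal = signal_result.p_two_tailed <= alpha
    above = signal_result.k_above_null_median
    labels = {}
    for _, row in habitat_mean_tests.iterrows():
        if row["p"] > alpha:
            structure = "random"
        elif row["mean"] > 0:
            structure = "clustered"
        else:
            structure = "overdispersed"
        if structure == "random":
            lab = "Neutrality"
        elif not has_signal:
            lab = "Indeterminate"
        elif (structure == "clustered") == above:
            lab = "Habitat Filtering"
        else:
            lab = "Limiting Similarity"
        labels[row["habitat"]] = lab
    return labels


def _load_dataset(config: AnalysisConfig):
    from .terrain import HabitatMap

    stem_map = StemMap.from_tsv(
        config.stems_tsv, plot_x_m=config.plot_x_m, plot_y_m=config.plot_y_m
    )
    tree = ultrametricize(Phylogeny.from_newick(config.tree_nwk))
    hm_df = pd.read_csv(config.habitatmap_tsv, sep="\t")
    n_rows = hm_df["row"].max() + 1
    n_cols = hm_df["col"].max() + 1
    labels = np.empty((n_rows, n_cols), dtype="<U2")
    labels[hm_df["row"], hm_df["col"]] = hm_df["habitat"]
    habitat_map = HabitatMap(labels=labels, quadrat_m=config.quadrat_m)
    taxonomy = (
        pd.read_csv(config.taxonomy_tsv, sep="\t") if config.taxonomy_tsv else None
    )
    return stem_map, habitat_map, tree, taxonomy


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Execute every stage and (if ``outdir`` is set) write all tables."""
    t0 = time.time()
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str, fn):
        t = time.time()
        try:
            out = fn()
        except Exception:
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = {"status": "failed"}
            raise
        manifest["stages"][name] = {"status": "ok", "seconds": round(time.time() - t, 2)}
        logger.info("stage %s done in %.1fs", name, time.time() - t)
        return out

    # --- data ------------------------------------------------------------
    dataset = None
    if config.simulate is not None:
        dataset = stage("simulate", lambda: generate_forest(config.simulate))
        stem_map = dataset.stem_map
        habitat_map = dataset.habitat_map
        tree = dataset.phylogeny
        taxonomy = dataset.taxonomy
    else:
        stem_map, habitat_map, tree, taxonomy = stage(
            "load", lambda: _load_dataset(config)
        )

    community = stage(
        "community", lambda: build_community_matrix(stem_map, config.quadrat_m)
    )
    manifest["stages"]["community"]["n_stems"] = community.total_stems()
    habitat_table = habitat_summary(habitat_map, community)
    manifest["stages"]["community"]["stems_reconciled"] = bool(
        habitat_table["n_stems"].sum() == community.total_stems() == stem_map.n_stems
    )

    # --- associations ----------------------------------------------------
    assoc = stage(
        "associations",
        lambda: torus_test(
            community, habitat_map, min_stems=config.min_stems, alpha=config.alpha
        ),
    )
    assoc_table = results_frame(assoc)
    assoc_summary = summarize_associations(assoc)

    # --- signal ----------------------------------------------------------
    trait = median_habitat_score(community, habitat_map)
    shared = [s for s in tree.taxa if s in trait]
    tree_for_signal = tree
    if len(shared) < tree.n_tips:
        keep = set(shared)
        pruned = Phylogeny.from_newick(tree.to_newick())
        pruned.tree.retain_taxa_with_labels(list(keep))
        tree_for_signal = Phylogeny(pruned.tree)
    sig = stage(
        "signal",
        lambda: k_permutation_test(
            tree_for_signal,
            {s: trait[s] for s in shared},
            n_perm=config.n_perm,
            seed=np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(101,))
            ),
        ),
    )

    # --- community structure ---------------------------------------------
    sources: dict[str, Phylogeny] = {"molecular": tree}
    if taxonomy is not None:
        sources["taxonomy"] = taxonomy_tree(taxonomy)
    ses_tables: dict[tuple[str, int], pd.DataFrame] = {}
    pool_tables: dict[str, pd.DataFrame] = {}
    flat_ranks = habitat_map.labels.ravel()
    for si, (source, phylo) in enumerate(sources.items()):
        for scale in config.scales:
            factor = scale // int(config.quadrat_m)
            if factor == 1:
                matrix = community
                ids = [f"q{i}" for i in range(community.n_quadrats)]
            else:
                agg = aggregate_scale(community, factor)
                matrix = agg.matrix
                ids = [f"c{factor}_{i}" for i in range(len(agg.matrix))]
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(200 + 10 * si + factor,))
            )
            res = stage(
                f"ses_{source}_{scale}m",
                lambda m=matrix, p=phylo, r=rng, i=ids: ses_structure(
                    m,
                    p,
                    n_null=config.n_null,
                    seed=r,
                    n_burnin=config.swap_burnin,
                    n_thin=config.swap_thin,
                    assemblage_ids=i,
                ),
            )
            ses_tables[(source, scale)] = ses_frame(res)
        # habitat-level species pools
        pres = community.presence()
        lists = {
            h: [
                community.species[j]
                for j in np.flatnonzero(pres[flat_ranks == h].sum(axis=0) > 0)
            ]
            for h in HABITAT_ORDER
        }
        pool_tables[source] = ses_frame(
            stage(
                f"habitat_pool_{source}",
                lambda l=lists, p=phylo, si=si: habitat_pool_ses(
                    l,
                    community.species,
                    p,
                    n_null=config.n_null,
                    seed=np.random.default_rng(
                        np.random.SeedSequence(config.seed, spawn_key=(300 + si,))
                    ),
                ),
            )
        )

    # --- spatial inference at the base scale -------------------------------
    base = int(config.quadrat_m)
    rows, cols = np.indices(habitat_map.labels.shape)
    sar_fits: dict[tuple[str, str], object] = {}
    for source in sources:
        ses_t = ses_tables[(source, base)]
        ok = ~ses_t["degenerate"].to_numpy()
        coords = np.column_stack([rows.ravel()[ok], cols.ravel()[ok]])
        W = rook_weights(coords)
        indicators = pd.DataFrame(
            {h: (flat_ranks[ok] == h).astype(float) for h in HABITAT_ORDER}
        )
        for metric in ("nri", "nti"):
            sar_fits[(source, metric)] = stage(
                f"sar_{source}_{metric}",
                lambda v=ses_t.loc[ok, metric].to_numpy(), X=indicators, w=W: sar_gls(
                    v, X, w
                ),
            )

    # --- comparisons -------------------------------------------------------
    comparisons = pd.DataFrame()
    if "taxonomy" in sources:
        comp_rows = []
        for metric in ("nri", "nti"):
            a = ses_tables[("molecular", base)][metric].to_numpy()
            b = ses_tables[("taxonomy", base)][metric].to_numpy()
            comp = paired_phylogeny_comparison(a, b, flat_ranks)
            comp.insert(0, "metric", metric)
            comp_rows.append(comp)
        comparisons = pd.concat(comp_rows, ignore_index=True)

    # --- richness ANOVA: clustered vs overdispersed quadrats ----------------
    ses_base = ses_tables[("molecular", base)]
    richness = ses_base["richness"].to_numpy(dtype=float)
    nri = ses_base["nri"].to_numpy()
    groups = np.where(nri > 0, "clustered", "overdispersed")
    ok = np.isfinite(nri) & (nri != 0)
    anova = stage(
        "richness_anova", lambda: richness_anova(richness[ok], groups[ok])
    )

    # --- framework labels ---------------------------------------------------
    labels = interpret_framework(
        sig, sar_fits[("molecular", "nri")].coefficients, alpha=config.alpha
    )

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    result = PipelineResult(
        config=config,
        dataset=dataset,
        habitat_table=habitat_table,
        associations=assoc_table,
        association_summary=assoc_summary,
        signal=sig,
        ses=ses_tables,
        habitat_pool=pool_tables,
        sar=sar_fits,
        comparisons=comparisons,
        anova=anova,
        labels=labels,
        manifest=manifest,
    )
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    meta = f"# config_hash={result.config.config_hash()} seed={result.config.seed}\n"

    def write(df: pd.DataFrame, name: str) -> None:
        with open(outdir / name, "w") as fh:
            fh.write(meta)
            df.to_csv(fh, sep="\t", index=False)

    if result.dataset is not None:
        result.dataset.write(outdir / "dataset")
    write(result.habitat_table, "habitat_summary.tsv")
    write(result.associations, "associations.tsv")
    write(result.association_summary, "association_summary.tsv")
    sig_df = pd.DataFrame(
        [
            {
                "K": result.signal.k,
                "n_perm": result.signal.n_permutations,
                "p_two_tailed": result.signal.p_two_tailed,
                "k_above_null_median": result.signal.k_above_null_median,
            }
        ]
    )
    write(sig_df, "signal.tsv")
    for (source, scale), df in result.ses.items():
        write(df, f"ses_{source}_{scale}m.tsv")
    for source, df in result.habitat_pool.items():
        write(df, f"habitat_pool_{source}.tsv")
    sar_rows = []
    for (source, metric), fit in result.sar.items():
        coef = fit.coefficients.copy()
        coef.insert(0, "metric", metric)
        coef.insert(0, "source", source)
        coef["lambda"] = fit.lam
        sar_rows.append(coef)
    write(pd.concat(sar_rows, ignore_index=True), "habitat_means.tsv")
    if len(result.comparisons):
        write(result.comparisons, "phylogeny_comparison.tsv")
    write(
        pd.DataFrame(
            [{"habitat": h, "label": l} for h, l in result.labels.items()]
        ),
        "framework_labels.tsv",
    )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=False)
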