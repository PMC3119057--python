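"""Torus-translation tests of species–habitat association.

The classic randomization for stem-mapped plots: because both species
distributions and habitats are spatially autocorrelated, per-quadrat
chi-square tests are anticonservative. Instead the habitat map is slid
around a torus (and optionally rotated/mirrored) relative to the fixed
stem map; each translated map yields one null value of the association
statistic (the species' stem count in the habitat), preserving the
internal spatial structure of both layers.

The null set comprises all ``n_cols * n_rows`` toroidal translations of
each of four map variants — the original, its 180-degree rotation, its
mirror image, and the mirrored rotation — with the untranslated original
included, so p-values are never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .terrain import HABITAT_ORDER, HabitatMap

__all__ = [
    "AssociationResult",
    "torus_null_maps",
    "torus_test",
    "summarize_associations",
]


@dataclass
class AssociationResult:
    """One species x habitat test."""

    species: str
    habitat: str
    observed: int  # stems of the species in the habitat under the true map
    n_null: int  # null maps used (observed map included)
    p_positive: float  # P(null >= observed)
    p_negative: float  # P(null <= observed)
    verdict: str  # '+', '-' or 'ns'


def _variants(labels: np.ndarray, use_rotations: bool) -> list[np.ndarray]:
    if not use_rotations:
        return [labels]
    return [
        labels,
        labels[::-1, ::-1],  # 180-degree rotation
        labels[:, ::-1],  # mirror
        labels[::-1, :],  # mirrored rotation
    ]


def torus_null_maps(
    habitat_map: HabitatMap, use_rotations: bool = True
) -> list[np.ndarray]:
    """All toroidal translations of the map (and its rotations/mirrors).

    Returns ``(4 if use_rotations else 1) * n_rows * n_cols`` label
    arrays; the first is the untranslated original. Every null map has
    exactly the same per-habitat quadrat counts as the original.
    """
    out = []
    for var in _variants(habitat_map.labels, use_rotations):
        for dr in range(habitat_map.n_rows):
            for dc in range(habitat_map.n_cols):
                out.append(np.roll(var, shift=(dr, dc), axis=(0, 1)))
    return out


def _habitat_count_stack(null_maps: list[np.ndarray]) -> np.ndarray:
    """Stack of one-hot habitat indicators: (n_maps, 5, n_quadrats)."""
    flat = np.stack([m.ravel() for m in null_maps])  # (n_maps, Q) of labels
    return np.stack([(flat == h) for h in HABITAT_ORDER], axis=1).astype(np.float64)


def torus_test(
    community: CommunityMatrix,
    habitat_map: HabitatMap,
    min_stems: int = 20,
    alpha: float = 0.05,
    use_rotations: bool = True,
) -> list[AssociationResult]:
    """Two-tailed torus-translation test for every sufficiently common species.

    Species with strictly more than ``min_stems`` stems are eligible. For
    each eligible species and each habitat, the observed stem count in
    that habitat is compared with its value under every null map:
    ``p_positive = #(null >= observed) / n_maps`` and symmetrically for
    ``p_negative``. The verdict is '+' if ``p_positive <= alpha/2``, '-'
    if ``p_negative <= alpha/2``, else 'ns'.
    """
    if community.n_rows != habitat_map.n_rows or community.n_cols != habitat_map.n_cols:
        raise ValueError("community matrix and habitat map lattices differ")
    abund = community.matrix.sum(axis=0)
    eligible = [s for s in community.species if abund[s] > min_stems]
    if not eligible:
        warnings.warn("no species exceeds the abundance threshold; empty result")
        return []
    sp_idx = [community.species.index(s) for s in eligible]
    A = community.matrix.values[:, sp_idx].astype(np.float64)  # (Q, S_eligible)
    null_maps = torus_null_maps(habitat_map, use_rotations=use_rotations)
    H = _habitat_count_stack(null_maps)  # (n_maps, 5, Q)
    n_maps = H.shape[0]
    # stats[m, h, s] = stems of species s in habitat h under null map m
    stats = H @ A  # (n_maps, 5, S)
    obs = stats[0]  # first null map is the untranslated original
    p_pos = (stats >= obs[None, :, :] - 1e-9).sum(axis=0) / n_maps
    p_neg = (stats <= obs[None, :, :] + 1e-9).sum(axis=0) / n_maps
    results = []
    for j, sp in enumerate(eligible):
        for i, hab in enumerate(HABITAT_ORDER):
            pp = float(p_pos[i, j])
            pn = float(p_neg[i, j])
            if pp <= alpha / 2:
                verdict = "+"
            elif pn <= alpha / 2:
                verdict = "-"
            else:
                verdict = "ns"
            results.append(
                AssociationResult(
                    species=sp,
                    habitat=hab,
                    observed=int(round(obs[i, j])),
                    n_null=n_maps,
                    p_positive=pp,
                    p_negative=pn,
                    verdict=verdict,
                )
            )
    return results


def summarize_associations(results: list[AssociationResult]) -> pd.DataFrame:
    """Per-habitat counts of significant positive/negative associations.

    Returns one row per habitat plus a ``Total`` row; the attached
    ``attrs['n_species_any']`` counts species with at least one verdict,
    ``attrs['fraction_significant']`` the share of significant tests.
    """
    df = pd.DataFrame(
        {
            "habitat": [r.habitat for r in results],
            "species": [r.species for r in results],
            "verdict": [r.verdict for r in results],
        }
    )
    rows = []
    for hab in HABITAT_ORDER:
        sub = df[df["habitat"] == hab] if len(df) else df
        rows.append(
            {
                "habitat": hab,
                "n_positive": int((sub["verdict"] == "+").sum()) if len(df) else 0,
                "n_negative": int((sub["verdict"] == "-").sum()) if len(df) else 0,
            }
        )
    total = {
        "habitat": "Total",
        "n_positive": sum(r["n_positive"] for r in rows),
        "n_negative": sum(r["n_negative"] for r in rows),
    }
    out = pd.DataFrame(rows + [total])
    n_sig = total["n_positive"] + total["n_negative"]
    out.attrs["n_tests"] = len(results)
    out.attrs["n_significant"] = n_sig
    out.attrs["fraction_significant"] = n_sig / len(results) if results else 0.0
    if len(df):
        sig_species = df.loc[df["verdict"] != "ns", "species"].nunique()
    else:
        sig_species = 0
    out.attrs["n_species_any"] = int(sig_species)
    return out


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flat table of per-test results, one row per species x habitat."""
    return pd.DataFrame(
        {
            "species": [r.species for r in results],
            "habitat": [r.habitat for r in results],
            "observed": [r.observed for r in results],
            "p_pos": [r.p_positive for r in results],
            "p_neg": [r.p_negative for r in results],
            "verdict": [r.verdict for r in results],
        }
    )
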