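"""Published census summaries of the Dinghushan (DHS) 20-ha plot.

The raw census, topography and trait data of the DHS forest dynamics
plot are not publicly deposited, so the package cannot recompute the
plot's headline statistics from stems. What the published summaries do
support is a set of exact accounting identities — habitat areas versus
quadrat counts, stem totals, density quotients, test-count arithmetic —
which this module stores and re-derives. They double as the reference
frame the synthetic generator is scaled to (plot dimensions, species
and stem totals, habitat quadrat counts).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "DHS_HABITAT_SUMMARY",
    "DHS_ASSOCIATION_COUNTS",
    "DHS_HEADLINE",
    "QUADRAT_AREA_HA",
    "accounting_identities",
]

#: area of one 20 m x 20 m quadrat in hectares
QUADRAT_AREA_HA = 0.04

#: per-habitat census summary of the DHS plot (2005 census):
#: area, quadrat count, species and stem totals.
DHS_HABITAT_SUMMARY = pd.DataFrame(
    {
        "habitat": ["V", "HG", "LS", "HS", "RT"],
        "area_ha": [6.92, 3.08, 4.60, 2.92, 2.48],
        "n_quadrats": [173, 77, 115, 73, 62],
        "n_species": [149, 133, 135, 135, 105],
        "n_stems": [19501, 11052, 17215, 14174, 9394],
    }
)

#: published torus-translation outcomes for the 99 common species
#: (and the 19 most abundant), significant at the two-tailed 5% level.
DHS_ASSOCIATION_COUNTS = pd.DataFrame(
    {
        "habitat": ["V", "HG", "LS", "HS", "RT"],
        "positive_99": [0, 4, 1, 22, 11],
        "negative_99": [0, 1, 0, 1, 12],
        "positive_19": [0, 1, 1, 2, 4],
        "negative_19": [0, 0, 0, 0, 4],
    }
)

#: plot-level headline statistics of the published analysis
DHS_HEADLINE = {
    "n_species": 183,
    "n_stems": 71336,
    "n_quadrats": 500,
    "n_common_species": 99,  # > 20 stems
    "n_abundant_species": 19,  # >= 1000 stems
    "blomberg_k": 0.80,
    "blomberg_p": 0.019,
    "richness_anova_F": 26.414,
    "median_slope_deg": 33.0,
    "median_elevation_m": 326.3,
}


def accounting_identities() -> dict[str, float]:
    """Recompute the arithmetic the published summaries must satisfy.

    Every value here is derived at call time from the stored per-habitat
    rows — quadrat counts from areas, totals as sums, densities as
    stems/area quotients, test counts as species x habitat products.
    """
    t = DHS_HABITAT_SUMMARY
    a = DHS_ASSOCIATION_COUNTS
    quadrats_from_area = (t["area_ha"] / QUADRAT_AREA_HA).round().astype(int)
    densities = t["n_stems"] / t["area_ha"]
    n_tests = DHS_HEADLINE["n_common_species"] * len(t)
    n_significant = int(a["positive_99"].sum() + a["negative_99"].sum())
    return {
        "total_area_ha": float(t["area_ha"].sum()),
        "total_quadrats": int(t["n_quadrats"].sum()),
        "quadrats_match_areas": bool(
            (quadrats_from_area == t["n_quadrats"]).all()
        ),
        "valley_quadrats_from_area": int(quadrats_from_area.iloc[0]),
        "total_stems": int(t["n_stems"].sum()),
        "density_high_gully_per_ha": float(densities.iloc[1]),
        "density_high_slope_per_ha": float(densities.iloc[3]),
        "n_association_tests": int(n_tests),
        "n_significant_associations": n_significant,
        "fraction_significant_pct": 100.0 * n_significant / n_tests,
    }
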