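"""Community phylogenetic structure: MPD/MNTD and NRI/NTI under an
independent-swap null.

For an assemblage (the species present in one quadrat), MPD is the mean
cophenetic distance over all unordered species pairs and MMPD (elsewhere
called MNTD) the mean distance of each species to its nearest co-occurring
relative. Observed values are standardized against 999 randomized
communities from the independent-swap null, which shuffles the binary
quadrat x species matrix by 2x2 checkerboard swaps and therefore
preserves both species occurrence frequencies and quadrat richness
exactly::

    NRI = -(MPD_obs  - mean(MPD_null))  / sd(MPD_null)
    NTI = -(MMPD_obs - mean(MMPD_null)) / sd(MMPD_null)

Positive values indicate phylogenetic clustering (co-occurring species
more related than expected), negative values overdispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylogeny import Phylogeny

__all__ = [
    "SESResult",
    "mpd",
    "mmpd",
    "independent_swap",
    "swap_samples",
    "ses_structure",
    "habitat_pool_ses",
]


@dataclass
class SESResult:
    assemblage: str
    richness: int
    mpd_obs: float
    mmpd_obs: float
    rnd_mpd_mean: float
    rnd_mpd_sd: float
    rnd_mmpd_mean: float
    rnd_mmpd_sd: float
    nri: float
    nti: float
    degenerate: bool  # null sd was zero (SES forced to 0)


def mpd(members: np.ndarray, distances: np.ndarray) -> float:
    """Mean pairwise cophenetic distance of an assemblage.

    ``members`` holds indices into ``distances``; richness must be >= 2.
    """
    idx = np.asarray(members)
    k = len(idx)
    if k < 2:
        raise ValueError("MPD needs at least 2 species")
    sub = distances[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def mmpd(members: np.ndarray, distances: np.ndarray) -> float:
    """Mean distance of each member to its nearest co-occurring relative."""
    idx = np.asarray(members)
    k = len(idx)
    if k < 2:
        raise ValueError("MMPD needs at least 2 species")
    sub = distances[np.ix_(idx, idx)].astype(float)
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _has_checkerboard(P: np.ndarray) -> bool:
    """Whether any 2x2 checkerboard submatrix exists in binary matrix P."""
    P = P.astype(np.int64)
    A = P @ (1 - P).T  # A[i,j] = #cols where row i has 1 and row j has 0
    np.fill_diagonal(A, 0)
    return bool(((A > 0) & (A.T > 0)).any())


def independent_swap(
    presence: np.ndarray,
    n_burnin: int = 500_000,
    n_thin: int = 50_000,
    seed: int | np.random.Generator = 0,
    n_samples: int = 1,
) -> list[np.ndarray]:
    """Independent-swap randomizations of a binary presence matrix.

    Runs a Markov chain of trial 2x2 checkerboard swaps, discarding
    ``n_burnin`` attempted swaps, then emitting one matrix copy every
    ``n_thin`` attempts. Row and column sums are preserved exactly on
    every sample. A matrix containing no checkerboard cannot move and is
    returned unchanged with a warning.
    """
    P = np.asarray(presence)
    if not np.isin(P, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    P = P.astype(np.int8).copy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if not _has_checkerboard(P):
        warnings.warn("matrix has no 2x2 checkerboard; returning it unchanged")
        return [P.copy() for _ in range(n_samples)]
    _run_swaps(P, rng, n_burnin)
    out = []
    for _ in range(n_samples):
        _run_swaps(P, rng, n_thin)
        out.append(P.copy())
    return out


try:  # the jitted kernel makes long, well-mixed chains affordable
    import numba

    @numba.njit(cache=False)
    def _apply_swaps(P, rows, cols):  # pragma: no cover - exercised via wrapper
        for k in range(rows.shape[0]):
            r1, r2 = rows[k, 0], rows[k, 1]
            c1, c2 = cols[k, 0], cols[k, 1]
            a = P[r1, c1]
            b = P[r1, c2]
            if a != b and P[r2, c1] == b and P[r2, c2] == a:
                P[r1, c1] = b
                P[r1, c2] = a
                P[r2, c1] = a
                P[r2, c2] = b

except ImportError:  # pure-python fallback, identical semantics

    def _apply_swaps(P, rows, cols):
        for k in range(rows.shape[0]):
            r1, r2 = rows[k, 0], rows[k, 1]
            c1, c2 = cols[k, 0], cols[k, 1]
            a = P[r1, c1]
            b = P[r1, c2]
            if a != b and P[r2, c1] == b and P[r2, c2] == a:
                P[r1, c1] = b
                P[r1, c2] = a
                P[r2, c1] = a
                P[r2, c2] = b


def _run_swaps(P: np.ndarray, rng: np.random.Generator, n_attempts: int) -> None:
    n, m = P.shape
    chunk = 1_000_000
    done = 0
    while done < n_attempts:
        size = min(chunk, n_attempts - done)
        rows = rng.integers(0, n, size=(size, 2))
        cols = rng.integers(0, m, size=(size, 2))
        _apply_swaps(P, rows, cols)
        done += size


def swap_samples(
    presence: np.ndarray,
    n_samples: int,
    n_burnin: int = 500_000,
    n_thin: int = 50_000,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Convenience wrapper: ``n_samples`` swap-null matrices."""
    return independent_swap(
        presence, n_burnin=n_burnin, n_thin=n_thin, seed=seed, n_samples=n_samples
    )


def _metrics_all_rows(P: np.ndarray, D: np.ndarray):
    """MPD and MMPD for every row of a binary matrix (nan where richness<2)."""
    Pf = P.astype(np.float64)
    k = Pf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_sums = np.einsum("ij,jk,ik->i", Pf, D, Pf)
        mpd_vals = np.where(k >= 2, pair_sums / (k * (k - 1)), np.nan)
    Dinf = D.astype(float).copy()
    np.fill_diagonal(Dinf, np.inf)
    mmpd_vals = np.full(P.shape[0], np.nan)
    for i in np.flatnonzero(k >= 2):
        idx = np.flatnonzero(P[i])
        sub = Dinf[np.ix_(idx, idx)]
        mmpd_vals[i] = sub.min(axis=1).mean()
    return mpd_vals, mmpd_vals


def ses_structure(
    community,
    phylogeny: Phylogeny,
    n_null: int = 999,
    seed: int | np.random.Generator = 0,
    n_burnin: int = 500_000,
    n_thin: int = 50_000,
    assemblage_ids: list[str] | None = None,
) -> list[SESResult]:
    """NRI and NTI per assemblage under the independent-swap null.

    ``community`` is a :class:`~phylofdp.community.CommunityMatrix` or a
    quadrat x species DataFrame of abundances. Species absent from the
    phylogeny are dropped (logged); assemblages with richness < 2 after
    the intersection are flagged degenerate and get NaN metrics.
    """
    matrix = community.matrix if hasattr(community, "matrix") else pd.DataFrame(community)
    species = list(matrix.columns)
    shared = [s for s in species if s in set(phylogeny.taxa)]
    if not shared:
        raise ValueError("no species shared between community matrix and tree")
    if len(shared) < len(species):
        warnings.warn(
            f"{len(species) - len(shared)} species absent from the tree were dropped"
        )
    D_full = phylogeny.cophenetic_matrix()
    tip_idx = {t: i for i, t in enumerate(phylogeny.taxa)}
    D = D_full[np.ix_([tip_idx[s] for s in shared], [tip_idx[s] for s in shared])]
    P_obs = (matrix[shared].to_numpy() > 0).astype(np.int8)
    n_assemb = P_obs.shape[0]
    if assemblage_ids is None:
        assemblage_ids = [f"q{i}" for i in range(n_assemb)]

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mpd_obs, mmpd_obs = _metrics_all_rows(P_obs, D)

    null_mpd = np.empty((n_null, n_assemb))
    null_mmpd = np.empty((n_null, n_assemb))
    has_cb = _has_checkerboard(P_obs)
    if not has_cb:
        warnings.warn("matrix has no 2x2 checkerboard; null is degenerate")
    P = P_obs.copy()
    row_sums = P_obs.sum(axis=1)
    col_sums = P_obs.sum(axis=0)
    if has_cb:
        _run_swaps(P, rng, n_burnin)
    for r in range(n_null):
        if has_cb:
            _run_swaps(P, rng, n_thin)
        assert (P.sum(axis=1) == row_sums).all() and (P.sum(axis=0) == col_sums).all()
        null_mpd[r], null_mmpd[r] = _metrics_all_rows(P, D)

    results = []
    for i in range(n_assemb):
        rich = int(row_sums[i])
        if rich < 2:
            results.append(
                SESResult(
                    assemblage=assemblage_ids[i],
                    richness=rich,
                    mpd_obs=float("nan"),
                    mmpd_obs=float("nan"),
                    rnd_mpd_mean=float("nan"),
                    rnd_mpd_sd=float("nan"),
                    rnd_mmpd_mean=float("nan"),
                    rnd_mmpd_sd=float("nan"),
                    nri=float("nan"),
                    nti=float("nan"),
                    degenerate=True,
                )
            )
            continue
        mu_mpd = float(np.mean(null_mpd[:, i]))
        sd_mpd = float(np.std(null_mpd[:, i], ddof=1))
        mu_mmpd = float(np.mean(null_mmpd[:, i]))
        sd_mmpd = float(np.std(null_mmpd[:, i], ddof=1))
        # a null spread at rounding-noise level is a degenerate null
        tol_mpd = 1e-10 * max(1.0, abs(mu_mpd))
        tol_mmpd = 1e-10 * max(1.0, abs(mu_mmpd))
        degenerate = sd_mpd <= tol_mpd or sd_mmpd <= tol_mmpd
        nri = -(mpd_obs[i] - mu_mpd) / sd_mpd if sd_mpd > tol_mpd else 0.0
        nti = -(mmpd_obs[i] - mu_mmpd) / sd_mmpd if sd_mmpd > tol_mmpd else 0.0
        results.append(
            SESResult(
                assemblage=assemblage_ids[i],
                richness=rich,
                mpd_obs=float(mpd_obs[i]),
                mmpd_obs=float(mmpd_obs[i]),
                rnd_mpd_mean=mu_mpd,
                rnd_mpd_sd=sd_mpd,
                rnd_mmpd_mean=mu_mmpd,
                rnd_mmpd_sd=sd_mmpd,
                nri=float(nri),
                nti=float(nti),
                degenerate=degenerate,
            )
        )
    return results


def habitat_pool_ses(
    habitat_lists: dict[str, list[str]],
    pool: list[str],
    phylogeny: Phylogeny,
    n_null: int = 999,
    seed: int | np.random.Generator = 0,
    **swap_kwargs,
) -> list[SESResult]:
    """SES for whole-habitat species lists against the plot species pool.

    Builds the 5 x S presence matrix (habitats as assemblages, the plot
    list as the pool) and runs the same swap-null machinery.
    """
    pool = list(pool)
    for hab, members in habitat_lists.items():
        extra = set(members) - set(pool)
        if extra:
            raise ValueError(f"habitat {hab!r} lists species outside the pool: "
                             f"{sorted(extra)[:5]}")
    labels = list(habitat_lists)
    P = pd.DataFrame(
        [[int(s in set(habitat_lists[h])) for s in pool] for h in labels],
        columns=pool,
    )
    return ses_structure(
        P, phylogeny, n_null=n_null, seed=seed, assemblage_ids=labels, **swap_kwargs
    )


def ses_frame(results: list[SESResult]) -> pd.DataFrame:
    """Flat table of SES results, one row per assemblage."""
    return pd.DataFrame([r.__dict__ for r in results])
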