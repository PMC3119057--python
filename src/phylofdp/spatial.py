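"""Spatially autoregressive estimation of habitat means, plus the
secondary significance tests.

Per-quadrat NRI/NTI values are spatially autocorrelated, so habitat
means are estimated with a simultaneous-autoregressive (SAR) error
model on the quadrat lattice::

    y = X beta + e,    e = lambda W e + u,    u ~ N(0, sigma^2 I)

where X holds habitat indicator columns (no global intercept, so each
coefficient is that habitat's mean), W is the row-standardized
first-order (rook) neighbour matrix, and lambda is the spatial
dependence parameter, estimated by profile maximum likelihood over its
admissible eigenvalue-bounded interval. At lambda = 0 the fit reduces
exactly to OLS, i.e. ordinary per-habitat means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "SARFit",
    "rook_weights",
    "sar_gls",
    "paired_phylogeny_comparison",
    "richness_anova",
]


def rook_weights(coords: np.ndarray, scheme: str = "rook") -> np.ndarray:
    """Row-standardized lattice-neighbour weight matrix.

    ``coords`` is an (n, 2) integer array of (row, col) lattice positions
    of the included quadrats. Rook neighbours share an edge; ``scheme =
    'queen'`` also joins diagonals. Quadrats without any included
    neighbour get an all-zero row (with a warning).
    """
    coords = np.asarray(coords, dtype=int)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2) of (row, col)")
    n = len(coords)
    index = {tuple(rc): i for i, rc in enumerate(map(tuple, coords))}
    if len(index) != n:
        raise ValueError("duplicate lattice coordinates")
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif scheme == "queen":
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        raise ValueError("scheme must be 'rook' or 'queen'")
    W = np.zeros((n, n))
    for i, (r, c) in enumerate(coords):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                W[i, j] = 1.0
    row_sums = W.sum(axis=1)
    isolated = row_sums == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} quadrats have no neighbours; "
                      "their weight rows are zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(row_sums[:, None] > 0, W / row_sums[:, None], 0.0)
    return W


@dataclass
class SARFit:
    lam: float  # spatial dependence
    lam_se: float
    coefficients: pd.DataFrame  # habitat, mean, se, t, p
    sigma2: float
    loglik: float
    loglik_lambda0: float
    n: int


def _profile_loglik(lam: float, y, X, W, eigvals) -> tuple[float, np.ndarray, float]:
    n = len(y)
    S = np.eye(n) - lam * W
    ys = S @ y
    Xs = S @ X
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    sigma2 = float(resid @ resid) / n
    logdet = float(np.log(np.abs(1.0 - lam * eigvals)).sum())
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
    return ll, beta, sigma2


def sar_gls(
    values: np.ndarray,
    habitat_indicators: pd.DataFrame,
    W: np.ndarray,
    lam: float | None = None,
) -> SARFit:
    """Fit the SAR-error model and test each habitat mean against zero.

    ``habitat_indicators`` is an n x k 0/1 DataFrame, one column per
    habitat, no intercept. Pass ``lam`` to fix the dependence parameter
    (``lam = 0`` reproduces OLS exactly); otherwise it is estimated by
    profile maximum likelihood on its admissible interval.
    """
    y = np.asarray(values, dtype=float)
    X = pd.DataFrame(habitat_indicators)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n, k = Xv.shape
    if len(y) != n or W.shape != (n, n):
        raise ValueError("values, design and W dimensions disagree")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    empty = [names[j] for j in range(k) if Xv[:, j].sum() == 0]
    if empty:
        raise ValueError(f"habitat(s) with no quadrats in the design: {empty}")

    eigvals = np.linalg.eigvals(W).real  # W similar to symmetric: real spectrum
    w_min, w_max = float(eigvals.min()), float(eigvals.max())
    eps = 1e-6
    lo = 1.0 / w_min + eps if w_min < 0 else -np.inf
    hi = 1.0 / w_max - eps if w_max > 0 else np.inf
    lo = max(lo, -0.999999) if not np.isfinite(lo) else lo
    hi = min(hi, 0.999999) if not np.isfinite(hi) else hi

    if lam is not None:
        lam_hat = float(lam)
        lam_se = float("nan")
    elif np.allclose(W, 0):
        lam_hat = 0.0
        lam_se = float("nan")
    else:
        res = scipy.optimize.minimize_scalar(
            lambda l: -_profile_loglik(l, y, Xv, W, eigvals)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
        # asymptotic se from the curvature of the profile likelihood
        h = max(1e-5, 1e-4 * (hi - lo))
        h = min(h, (hi - lam_hat) / 2, (lam_hat - lo) / 2) or 1e-6
        ll_m = _profile_loglik(lam_hat - h, y, Xv, W, eigvals)[0]
        ll_0 = _profile_loglik(lam_hat, y, Xv, W, eigvals)[0]
        ll_p = _profile_loglik(lam_hat + h, y, Xv, W, eigvals)[0]
        d2 = (ll_p - 2 * ll_0 + ll_m) / (h * h)
        lam_se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else float("nan")

    ll, beta, sigma2 = _profile_loglik(lam_hat, y, Xv, W, eigvals)
    ll0 = _profile_loglik(0.0, y, Xv, W, eigvals)[0]
    S = np.eye(n) - lam_hat * W
    Xs = S @ Xv
    XtX = Xs.T @ Xs
    cov = sigma2 * n / (n - k) * np.linalg.inv(XtX)  # df-adjusted sigma^2
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - k)
    coef = pd.DataFrame(
        {"habitat": names, "mean": beta, "se": se, "t": t, "p": p}
    )
    return SARFit(
        lam=lam_hat,
        lam_se=lam_se,
        coefficients=coef,
        sigma2=float(sigma2),
        loglik=float(ll),
        loglik_lambda0=float(ll0),
        n=n,
    )


def paired_phylogeny_comparison(
    ses_a: np.ndarray,
    ses_b: np.ndarray,
    groups: np.ndarray,
) -> pd.DataFrame:
    """Paired t-tests of two per-quadrat SES series, by group.

    ``ses_a`` and ``ses_b`` are aligned per-quadrat values (e.g. NRI from
    a molecular tree vs. from a taxonomy-backbone tree); ``groups`` the
    habitat label per quadrat. Pairs with a NaN in either series are
    dropped. Returns one row per group plus an ``all`` row with the mean
    difference (a - b), its standard error, t, df and two-tailed p.
    """
    a = np.asarray(ses_a, dtype=float)
    b = np.asarray(ses_b, dtype=float)
    g = np.asarray(groups)
    if not (len(a) == len(b) == len(g)):
        raise ValueError("inputs must be aligned per quadrat")
    rows = []
    for label, mask in [("all", np.ones(len(a), bool))] + [
        (lab, g == lab) for lab in pd.unique(g)
    ]:
        ok = mask & np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            raise ValueError(f"fewer than 2 complete pairs in group {label!r}")
        d = a[ok] - b[ok]
        nn = len(d)
        se = d.std(ddof=1) / np.sqrt(nn)
        t, p = scipy.stats.ttest_rel(a[ok], b[ok])
        rows.append(
            {
                "group": label,
                "n": nn,
                "mean_diff": float(d.mean()),
                "se_diff": float(se),
                "t": float(t),
                "df": nn - 1,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def richness_anova(richness: np.ndarray, groups: np.ndarray) -> dict:
    """One-way ANOVA of quadrat richness between groups.

    Returns F, degrees of freedom, p, and per-group mean +- SE. Groups
    must number at least two, each with at least two quadrats; a
    zero-within-variance configuration is flagged.
    """
    r = np.asarray(richness, dtype=float)
    g = np.asarray(groups)
    ok = np.isfinite(r)
    r, g = r[ok], g[ok]
    labels = list(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    parts = [r[g == lab] for lab in labels]
    if any(len(p) < 2 for p in parts):
        raise ValueError("every group needs at least two quadrats")
    F, p = scipy.stats.f_oneway(*parts)
    group_stats = pd.DataFrame(
        {
            "group": labels,
            "n": [len(x) for x in parts],
            "mean": [float(x.mean()) for x in parts],
            "se": [float(x.std(ddof=1) / np.sqrt(len(x))) for x in parts],
        }
    )
    degenerate = all(x.std(ddof=1) == 0 for x in parts)
    return {
        "F": float(F),
        "df_between": len(labels) - 1,
        "df_within": len(r) - len(labels),
        "p": float(p),
        "groups": group_stats,
        "degenerate_within": degenerate,
    }
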