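"""Independent brute-force oracles shared by the unit and acceptance suites.

Everything here is deliberately written from first principles (plain
loops, hand algebra) and never calls the package code paths it checks.
"""

import itertools

import numpy as np


def dense_blomberg_k(V: np.ndarray, x: np.ndarray) -> float:
    """The K formula evaluated directly with dense matrix algebra."""
    n = len(x)
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    a = (one @ Vi @ x) / (one @ Vi @ one)
    mse0 = (x - a) @ (x - a) / (n - 1)
    mse = (x - a) @ Vi @ (x - a) / (n - 1)
    expected = (np.trace(V) - n / (one @ Vi @ one)) / (n - 1)
    return (mse0 / mse) / expected


def torus_strip_pvalues(habitat_row, stems, habitat):
    """Exhaustive torus-translation p-values on a 1-row strip.

    Enumerates the four map variants (original, 180-degree rotation,
    mirror, mirrored rotation — on one row the middle two coincide with
    column flips) times every cyclic shift, by list slicing.
    """
    variants = [list(habitat_row), habitat_row[::-1], habitat_row[::-1], list(habitat_row)]
    null = []
    n = len(habitat_row)
    for var in variants:
        for shift in range(n):
            shifted = var[-shift:] + var[:-shift] if shift else list(var)
            null.append(sum(s for s, h in zip(stems, shifted) if h == habitat))
    obs = null[0]
    return (
        sum(v >= obs for v in null) / len(null),
        sum(v <= obs for v in null) / len(null),
    )


def exact_fixed_margin_nri(D: np.ndarray, P: np.ndarray):
    """Exact per-row NRI by enumerating every binary matrix with P's margins.

    Recursion over rows with column-capacity pruning; suitable for toy
    matrices only (a handful of rows and columns).
    """
    n_rows, n_cols = P.shape
    row_sums = P.sum(axis=1)
    col_sums = P.sum(axis=0)

    def row_mpd(cols):
        idx = list(cols)
        k = len(idx)
        sub = D[np.ix_(idx, idx)]
        return sub.sum() / (k * (k - 1))

    per_row_values = [[] for _ in range(n_rows)]
    choices = [list(itertools.combinations(range(n_cols), r)) for r in row_sums]

    def recurse(r, caps, picked):
        if r == n_rows:
            if all(c == 0 for c in caps):
                for i, cols in enumerate(picked):
                    per_row_values[i].append(row_mpd(cols))
            return
        for cols in choices[r]:
            if all(caps[c] > 0 for c in cols):
                caps2 = list(caps)
                for c in cols:
                    caps2[c] -= 1
                recurse(r + 1, caps2, picked + [cols])

    recurse(0, list(col_sums), [])
    obs = [row_mpd(np.flatnonzero(P[i])) for i in range(n_rows)]
    return np.array(
        [
            -(obs[i] - np.mean(per_row_values[i]))
            / np.std(per_row_values[i], ddof=1)
            for i in range(n_rows)
        ]
    )
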