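"""Brute-force reference implementations used only by the test suite."""

import itertools
import math

import numpy as np


def exhaustive_null_wd(xbar_df, n_df, omega_floor=True):
    """Background-hypothesis null, fully enumerated per prey.

    For each prey, every assignment of its observed non-zero (xbar, n)
    entries (with replacement) onto all k bait slots is enumerated; for each
    assignment omega is the sample-CV of the row (floored at 1) and each
    slot contributes sqrt(x * omega**n).  Returns ``[(prey, array of
    per-assignment k-tuples flattened)]``.
    """
    k = xbar_df.shape[0]
    pooled = []
    for prey in xbar_df.columns:
        xcol = xbar_df[prey].to_numpy()
        ncol = n_df[prey].to_numpy()
        entries = [(x, n) for x, n in zip(xcol, ncol) if x > 0]
        if not entries:
            continue
        values = []
        for combo in itertools.product(range(len(entries)), repeat=k):
            xs = np.array([entries[i][0] for i in combo], dtype=float)
            ns = np.array([entries[i][1] for i in combo], dtype=float)
            mean = xs.mean()
            sd = xs.std(ddof=1) if k > 1 else 0.0
            omega = sd / mean if mean > 0 else 1.0
            if omega_floor:
                omega = max(omega, 1.0)
            values.extend(math.sqrt(x * omega**n) for x, n in zip(xs, ns))
        pooled.append((prey, np.asarray(values)))
    return pooled


def exhaustive_null_quantile(xbar_df, n_df, q, omega_floor=True):
    """Quantile of the enumerated null mixture (equal weight per prey)."""
    per_prey = exhaustive_null_wd(xbar_df, n_df, omega_floor)
    grid = np.unique(np.concatenate([v for _, v in per_prey]))
    cdf = np.mean([np.searchsorted(np.sort(v), grid, side="right") / len(v)
                   for _, v in per_prey], axis=0)
    return float(grid[np.searchsorted(cdf, q, side="left")])


def sample_from_exhaustive_null(xbar_df, n_df, n_rounds, rng, omega_floor=True):
    """Draw a pool from the enumerated null by uniform assignment choice.

    Mirrors the sampling scheme (each round, each prey contributes k
    values) but routes through the explicit enumeration.
    """
    per_prey = exhaustive_null_wd(xbar_df, n_df, omega_floor)
    k = xbar_df.shape[0]
    out = []
    for _, values in per_prey:
        n_assignments = len(values) // k
        picks = rng.integers(0, n_assignments, size=n_rounds)
        for p in picks:
            out.append(values[p * k:(p + 1) * k])
    return np.concatenate(out)


def brute_force_nsaf(counts, lengths):
    """NSAF of one run from plain dicts, computed with scalar arithmetic."""
    saf = {p: c / lengths[p] for p, c in counts.items() if c > 0}
    total = sum(saf.values())
    return {p: v / total for p, v in saf.items()}


def average_linkage_three(d):
    """Average-linkage merge sequence for exactly 3 items.

    ``d`` is a 3x3 symmetric distance matrix.  Returns
    [(pair, height), (all, height)] using frozensets of original indices.
    """
    pairs = [(0, 1), (0, 2), (1, 2)]
    i, j = min(pairs, key=lambda p: d[p[0], p[1]])
    first_height = d[i, j]
    rest = ({0, 1, 2} - {i, j}).pop()
    second_height = (d[i, rest] + d[j, rest]) / 2.0
    return [(frozenset((i, j)), first_height), (frozenset((0, 1, 2)), second_height)]
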