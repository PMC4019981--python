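"""CompPASS-style WD scoring with a permutation-derived normalization.

The WD score of a candidate interaction combines three ingredients: prey
abundance (mean NSAF ``xbar`` across the bait's replicates), prey frequency
across the ``k`` baits of the screen (``f``, with a reproducibility weight
``omega``), and replicate reproducibility (``n``, the number of the bait's
replicates detecting the prey):

    WD_{i,j} = sqrt( xbar_{i,j} * ((k / f_j) * omega_j) ** n_{i,j} )

Raw WD scores are normalized to the empirical ``sim_quantile`` (default
95%) quantile of WD scores computed on a simulated stats matrix;
interactions with WD^N >= 1 pass.  The simulated matrix embodies the
background hypothesis — every prey is a nonspecific binder: each prey's
observed non-zero (xbar, n) entries are resampled with replacement to fill
all ``k`` bait columns, so ``f = k`` by construction while abundances and
replicate reproducibility keep their observed distributions; ``omega`` is
recomputed on each simulated row.  Specific interactions (rare across
baits, hence large ``k/f``) then stand out against this null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datamodel import Dataset
from .errors import DataError


@dataclass
class StatsTable:
    """Bait x prey summary statistics feeding the WD score.

    ``xbar`` and ``n`` are baits-as-rows DataFrames sharing index/columns;
    ``f`` counts baits detecting each prey and ``omega`` is its
    reproducibility weight (coefficient of variation of the non-zero xbar
    values, floored at 1; 1 for preys seen with a single bait).  A bait's
    own protein is excluded from its row.
    """

    xbar: pd.DataFrame
    n: pd.DataFrame
    k: int
    f: pd.Series
    omega: pd.Series

    @property
    def baits(self) -> list[str]:
        return list(self.xbar.index)

    @property
    def preys(self) -> list[str]:
        return list(self.xbar.columns)


def _omega_from_arrays(
    x: np.ndarray, detected: np.ndarray, floor: bool
) -> np.ndarray:
    """Per-column CV of x over detected entries; 1 where fewer than 2."""
    cnt = detected.sum(axis=0)
    total = np.where(detected, x, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, total / np.maximum(cnt, 1), 0.0)
        ss = np.where(detected, x * x, 0.0).sum(axis=0)
        var = np.where(cnt > 1, (ss - cnt * mean**2) / np.maximum(cnt - 1, 1), 0.0)
        sd = np.sqrt(np.clip(var, 0.0, None))
        cv = np.where((cnt > 1) & (mean > 0), sd / np.where(mean > 0, mean, 1.0), 1.0)
    omega = np.where(cnt > 1, cv, 1.0)
    if floor:
        omega = np.maximum(omega, 1.0)
    return omega


def build_stats_table(
    bait_nsaf: pd.DataFrame, dataset: Dataset, *, omega_floor: bool = True
) -> StatsTable:
    """Aggregate the per-run NSAF matrix into the bait x prey stats table.

    ``xbar`` is the mean NSAF across each bait's replicates with zeros
    included; ``n`` counts replicates detecting the prey.  Control runs are
    never part of this table (they feed the enrichment filter instead).
    """
    run_to_bait = {r.run_id: r.bait_id for r in dataset.runs}
    missing = [rid for rid in bait_nsaf.index if rid not in run_to_bait]
    if missing:
        raise DataError(f"NSAF rows not found among sample runs: {missing}")
    if not run_to_bait:
        raise DataError("stats table requires bait runs (controls only given)")
    baits = bait_nsaf.index.map(run_to_bait)
    xbar = bait_nsaf.groupby(baits).mean()
    n = (bait_nsaf > 0).groupby(baits).sum().astype(int)
    # a bait is trivially "detected" with itself; drop the self entry
    for bait in xbar.index:
        if bait in xbar.columns:
            xbar.loc[bait, bait] = 0.0
            n.loc[bait, bait] = 0
    k = int(xbar.shape[0])
    detected = n.to_numpy() > 0
    f = pd.Series(detected.sum(axis=0), index=xbar.columns)
    omega = pd.Series(
        _omega_from_arrays(xbar.to_numpy(), detected, omega_floor),
        index=xbar.columns,
    )
    return StatsTable(xbar=xbar, n=n, k=k, f=f, omega=omega)


def _wd_array(
    x: np.ndarray, n: np.ndarray, k: int, f: np.ndarray, omega: np.ndarray
) -> np.ndarray:
    """WD over a baits x preys array; 0 where xbar is 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.where(f > 0, (k / np.maximum(f, 1)) * omega, 0.0)
        wd = np.sqrt(x * np.power(base[np.newaxis, :], n))
    return np.where(x > 0, wd, 0.0)


def wd_matrix(table: StatsTable) -> pd.DataFrame:
    """WD scores for every entry of the stats table."""
    vals = _wd_array(
        table.xbar.to_numpy(),
        table.n.to_numpy(),
        table.k,
        table.f.to_numpy(),
        table.omega.to_numpy(),
    )
    return pd.DataFrame(vals, index=table.xbar.index, columns=table.xbar.columns)


def wd_score(table: StatsTable, bait: str, prey: str) -> float:
    """WD score of a single (bait, prey) entry."""
    xbar = float(table.xbar.loc[bait, prey])
    if xbar == 0.0:
        return 0.0
    f = int(table.f[prey])
    if f == 0:
        raise DataError(
            f"inconsistent stats table: xbar > 0 but f = 0 for prey {prey!r}"
        )
    nn = int(table.n.loc[bait, prey])
    return math.sqrt(xbar * ((table.k / f) * float(table.omega[prey])) ** nn)


def permuted_wd_scores(
    table: StatsTable,
    n_permutations: int,
    rng: np.random.Generator,
    *,
    omega_floor: bool = True,
) -> np.ndarray:
    """Pooled WD scores from rounds of the background-hypothesis simulation.

    Each round builds a simulated stats matrix in which every prey is
    rendered nonspecific: its observed non-zero (xbar, n) entries are
    resampled with replacement to fill all ``k`` bait columns (``f = k``),
    ``omega`` is recomputed per simulated row, and WD is computed on every
    simulated entry.  Entries are pooled across preys and rounds.
    """
    k = table.k
    pooled: list[np.ndarray] = []
    any_entries = False
    for prey in table.preys:
        xcol = table.xbar[prey].to_numpy()
        ncol = table.n[prey].to_numpy()
        mask = xcol > 0
        m = int(mask.sum())
        if m == 0:
            continue
        any_entries = True
        vals = xcol[mask]
        ns = ncol[mask]
        idx = rng.integers(0, m, size=(n_permutations, k))
        xs = vals[idx]  # rounds x baits, all non-zero
        nn = ns[idx]
        mean = xs.mean(axis=1, keepdims=True)
        sd = xs.std(axis=1, ddof=1, keepdims=True) if k > 1 else np.zeros_like(mean)
        omega = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 1.0)
        if omega_floor or k == 1:
            omega = np.maximum(omega, 1.0)
        # f = k, so the frequency factor reduces to omega alone
        pooled.append(np.sqrt(xs * np.power(omega, nn)).ravel())
    if not any_entries:
        raise DataError("stats table has no non-zero entries")
    return np.concatenate(pooled)


def simulate_threshold(table: StatsTable, config: PipelineConfig | None = None) -> float:
    """WD-score value below which ``sim_quantile`` of the simulated data falls.

    Deterministic given ``config.rng_seed``; raw WD scores divided by this
    value give WD^N.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng([config.rng_seed, 3])
    pooled = permuted_wd_scores(
        table, config.n_permutations, rng, omega_floor=config.omega_floor
    )
    return float(np.quantile(pooled, config.sim_quantile))


def wdn_filter(
    table: StatsTable, threshold: float, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Normalize WD by the simulated threshold and apply the pass rule.

    Returns one row per non-zero (bait, prey) entry with columns ``bait,
    prey, n, f, omega, wd, wdn, passed_wdn``; the pass rule is inclusive
    ``wdn >= wdn_min``.
    """
    config = config or PipelineConfig()
    if not threshold > 0:
        raise DataError(f"threshold must be positive, got {threshold}")
    wd = wd_matrix(table)
    rows = []
    for bait in table.baits:
        xrow = table.xbar.loc[bait]
        for prey in xrow.index[xrow.to_numpy() > 0]:
            w = float(wd.loc[bait, prey])
            wdn = w / threshold
            rows.append(
                {
                    "bait": bait,
                    "prey": prey,
                    "n": int(table.n.loc[bait, prey]),
                    "f": int(table.f[prey]),
                    "omega": float(table.omega[prey]),
                    "wd": w,
                    "wdn": wdn,
                    "passed_wdn": wdn >= config.wdn_min,
                }
            )
    return pd.DataFrame(
        rows, columns=["bait", "prey", "n", "f", "omega", "wd", "wdn", "passed_wdn"]
    )


__all__ = [
    "StatsTable",
    "build_stats_table",
    "permuted_wd_scores",
    "simulate_threshold",
    "wd_matrix",
    "wd_score",
    "wdn_filter",
]
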