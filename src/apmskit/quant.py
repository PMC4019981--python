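"""Label-free TOP3 quantification and condition comparisons.

A protein's abundance in a run is estimated as the mean of its three most
intense precursor ions (TOP3) and normalized to the bait's TOP3 in the same
run, giving bait-relative abundances that are comparable across runs and
conditions.  Condition contrasts report a log2 fold change of mean relative
abundance with a per-prey two-sample t-test on log-transformed replicate
values; significance stars follow the two-level convention
(* P < 0.05, ** P < 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .datamodel import Dataset, PurificationRun
from .errors import DataError

logger = logging.getLogger(__name__)


def top3(intensities: list[float] | np.ndarray, top_n: int = 3) -> tuple[float, bool]:
    """Mean of the ``top_n`` largest intensities.

    Returns ``(value, low_evidence)``; with fewer than ``top_n`` values the
    mean of all available is used and flagged low-evidence.  An empty
    sequence is an error (abundance undefined).
    """
    vals = np.asarray(intensities, dtype=float)
    if vals.size == 0:
        raise DataError("TOP3 abundance undefined for an empty intensity list")
    if np.any(vals <= 0):
        raise DataError("intensities must be positive")
    low_evidence = vals.size < top_n
    top = np.sort(vals)[::-1][:top_n]
    return float(top.mean()), low_evidence


def bait_normalize(
    run: PurificationRun, top_n: int = 3
) -> tuple[dict[str, float], set[str]]:
    """Bait-relative TOP3 abundances for one run.

    Returns ``(relative abundances, low-evidence protein ids)``.  A missing
    or zero bait TOP3 excludes the run (error).
    """
    if run.bait_id not in run.intensities or not run.intensities[run.bait_id]:
        raise DataError(
            f"run {run.run_id!r}: bait {run.bait_id!r} has no intensities; run excluded"
        )
    bait_val, _ = top3(run.intensities[run.bait_id], top_n)
    rel: dict[str, float] = {}
    flagged: set[str] = set()
    for pid, vals in run.intensities.items():
        if not vals:
            continue
        value, low = top3(vals, top_n)
        rel[pid] = value / bait_val
        if low:
            flagged.add(pid)
    return rel, flagged


def relative_abundance_table(
    dataset: Dataset, bait: str, condition: str, top_n: int = 3
) -> tuple[pd.DataFrame, set[str]]:
    """Replicates x proteins table of bait-relative TOP3 abundances.

    Rows are the bait's runs in ``condition``; absent proteins get 0.
    """
    runs = dataset.runs_for_bait(bait, condition)
    if not runs:
        raise DataError(f"no runs for bait {bait!r} in condition {condition!r}")
    per_run: dict[str, dict[str, float]] = {}
    flagged: set[str] = set()
    for run in runs:
        rel, low = bait_normalize(run, top_n)
        per_run[run.run_id] = rel
        flagged |= low
    table = pd.DataFrame(per_run).T.fillna(0.0)
    return table, flagged


@dataclass
class QuantComparison:
    """Per-prey differential interaction results between two conditions."""

    table: pd.DataFrame  # prey, mean_rel_a, mean_rel_b, log2fc, p_value, stars, degenerate
    epsilon: float


def _stars(p: float, alpha_levels: tuple[float, float]) -> str:
    one_star, two_star = alpha_levels
    if p < two_star:
        return "**"
    if p < one_star:
        return "*"
    return "ns"


def compare_conditions(
    rel_a: dict[str, list[float]],
    rel_b: dict[str, list[float]],
    config: PipelineConfig | None = None,
) -> QuantComparison:
    """Log2 fold changes and t-tests between two replicate sets.

    ``rel_a`` / ``rel_b`` map prey to bait-relative abundances across
    replicates.  A shared pseudo-value epsilon (half the smallest non-zero
    relative abundance in the whole comparison) stabilizes ratios and the
    log transform; the t-test runs on ``log(value + epsilon)`` (Student by
    default, Welch when ``equal_var=False``).  Preys with fewer than two
    replicates in either condition are skipped with a warning; groups with
    identical constant values give p = 1 with a degenerate flag.
    """
    config = config or PipelineConfig()
    preys = sorted(set(rel_a) | set(rel_b))
    all_values = [v for d in (rel_a, rel_b) for vals in d.values() for v in vals if v > 0]
    eps = min(all_values) / 2.0 if all_values else 1e-12
    rows = []
    for prey in preys:
        a = np.asarray(rel_a.get(prey, []), dtype=float)
        b = np.asarray(rel_b.get(prey, []), dtype=float)
        if a.size < 2 or b.size < 2:
            logger.warning("prey %s has <2 replicates in a condition; skipped", prey)
            continue
        mean_a, mean_b = float(a.mean()), float(b.mean())
        log2fc = math.log2((mean_b + eps) / (mean_a + eps))
        la, lb = np.log(a + eps), np.log(b + eps)
        degenerate = la.std() == 0.0 and lb.std() == 0.0
        if degenerate and np.isclose(la.mean(), lb.mean()):
            p = 1.0
        else:
            p = float(
                stats.ttest_ind(lb, la, equal_var=config.equal_var).pvalue
            )
            if math.isnan(p):
                p, degenerate = 1.0, True
        rows.append(
            {
                "prey": prey,
                "mean_rel_a": mean_a,
                "mean_rel_b": mean_b,
                "log2fc": log2fc,
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["prey", "mean_rel_a", "mean_rel_b", "log2fc", "p_value", "degenerate"],
    )
    pvals = table["p_value"]
    if config.bh_correction and len(table):
        pvals = pd.Series(_benjamini_hochberg(pvals.to_numpy()), index=table.index)
        table["p_adjusted"] = pvals
    table["stars"] = [_stars(p, config.alpha_levels) for p in pvals]
    return QuantComparison(table=table, epsilon=eps)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def compare_bait_conditions(
    dataset: Dataset,
    bait: str,
    condition_a: str,
    condition_b: str,
    config: PipelineConfig | None = None,
) -> QuantComparison:
    """TOP3-based condition contrast for one bait, straight from a dataset."""
    config = config or PipelineConfig()
    tab_a, _ = relative_abundance_table(dataset, bait, condition_a, config.top_n_intensities)
    tab_b, _ = relative_abundance_table(dataset, bait, condition_b, config.top_n_intensities)
    preys = sorted((set(tab_a.columns) | set(tab_b.columns)) - {bait})
    rel_a = {p: list(tab_a[p]) if p in tab_a.columns else [0.0] * len(tab_a) for p in preys}
    rel_b = {p: list(tab_b[p]) if p in tab_b.columns else [0.0] * len(tab_b) for p in preys}
    return compare_conditions(rel_a, rel_b, config)


def time_course(
    rel_by_time: list[tuple[str, dict[str, list[float]]]],
) -> pd.DataFrame:
    """Mean and standard deviation of relative abundance per prey and time.

    ``rel_by_time`` is an ordered sequence of ``(time label, prey ->
    replicate values)``.  Returns a long DataFrame with columns ``prey,
    time, mean, sd`` preserving the given time order; times missing for a
    prey are absent from the output (logged) and a single replicate yields
    ``sd = NaN``.
    """
    if len(rel_by_time) < 2:
        raise DataError("time course requires at least two time points")
    preys = sorted({p for _, d in rel_by_time for p in d})
    rows = []
    for prey in preys:
        for label, d in rel_by_time:
            vals = np.asarray(d.get(prey, []), dtype=float)
            if vals.size == 0:
                logger.info("prey %s missing at time %s", prey, label)
                continue
            sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
            rows.append({"prey": prey, "time": label, "mean": float(vals.mean()), "sd": sd})
    return pd.DataFrame(rows, columns=["prey", "time", "mean", "sd"])


__all__ = [
    "QuantComparison",
    "bait_normalize",
    "compare_bait_conditions",
    "compare_conditions",
    "relative_abundance_table",
    "time_course",
    "top3",
]
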