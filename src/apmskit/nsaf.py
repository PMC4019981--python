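"""NSAF abundance matrices, the mock-control profile and the enrichment filter.

NSAF (normalized spectral abundance factor) of protein *j* in run *r* is

    NSAF_{r,j} = (SpC_{r,j} / L_j) / sum_k (SpC_{r,k} / L_k)

i.e. length-normalized spectral counts rescaled to sum to one per run.  The
contaminant background is summarized by averaging each protein's top-n NSAF
values over all mock-control runs (zero-padded to n), and a candidate
bait-prey pair passes the control filter when its mean bait-level NSAF
exceeds ``enrichment_min`` times the control value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datamodel import Dataset, PurificationRun
from .errors import ConfigError, DataError

#: Control floor when no control run detected anything (degenerate case).
EMPTY_CONTROL_FLOOR = 1e-9


def compute_nsaf(dataset: Dataset, *, controls: bool = False) -> pd.DataFrame:
    """NSAF matrix (runs x proteins) for the sample or the control runs.

    Every protein of the dataset appears as a column; undetected proteins
    get NSAF 0, so each row sums to 1 over the proteins detected in that
    run.  A run with no counts at all is an error naming the run.
    """
    runs = dataset.control_runs if controls else dataset.runs
    if not runs:
        raise DataError("no runs to normalize" + (" (controls)" if controls else ""))
    proteins = list(dataset.proteins)
    lengths = np.array([dataset.proteins[p].length for p in proteins], dtype=float)
    col_index = {p: i for i, p in enumerate(proteins)}
    values = np.zeros((len(runs), len(proteins)))
    for i, run in enumerate(runs):
        if not run.counts or all(c == 0 for c in run.counts.values()):
            raise DataError(f"run {run.run_id!r} has no nonzero spectral counts")
        for pid, c in run.counts.items():
            values[i, col_index[pid]] = c
    saf = values / lengths
    values = saf / saf.sum(axis=1, keepdims=True)
    return pd.DataFrame(values, index=[r.run_id for r in runs], columns=proteins)


def redistribute_shared_counts(
    dataset: Dataset, shared_map: dict[str, list[str]] | None = None
) -> Dataset:
    """Distribute shared peptide-group counts onto member proteins.

    ``shared_map`` maps a group id (a pseudo-protein id carrying the group's
    counts in a run) to its member proteins.  Within each run the group's
    counts are split proportionally to each member's unique-count evidence;
    members with no unique counts anywhere in the run split equally.  With
    no map, the dataset is returned unchanged (inputs are assumed
    protein-level, already adjusted).
    """
    if not shared_map:
        return dataset
    for group, members in shared_map.items():
        for pid in members:
            if pid not in dataset.proteins:
                raise DataError(
                    f"shared group {group!r} references unknown protein {pid!r}"
                )
    new_runs: list[PurificationRun] = []
    for run in list(dataset.runs) + list(dataset.control_runs):
        counts = dict(run.counts)
        for group, members in shared_map.items():
            gcount = counts.pop(group, 0)
            if gcount == 0:
                continue
            unique = np.array([counts.get(p, 0) for p in members], dtype=float)
            weights = unique / unique.sum() if unique.sum() > 0 else np.full(
                len(members), 1.0 / len(members)
            )
            for pid, w in zip(members, weights):
                counts[pid] = counts.get(pid, 0) + gcount * w
        new_runs.append(
            PurificationRun(
                run_id=run.run_id,
                bait_id=run.bait_id,
                replicate_index=run.replicate_index,
                condition=run.condition,
                counts=counts,
                intensities=dict(run.intensities),
            )
        )
    n_sample = len(dataset.runs)
    return Dataset(
        proteins=dict(dataset.proteins),
        runs=new_runs[:n_sample],
        control_runs=new_runs[n_sample:],
    )


@dataclass
class ControlProfile:
    """Per-protein contaminant abundance estimated from mock controls.

    ``values[j]`` is the mean of protein *j*'s ``top_n`` highest NSAF values
    across all control runs, zero-padded to ``top_n`` when seen in fewer
    runs.  ``floor`` stands in for proteins never seen in any control and is
    the detection limit of the control set: the profile value a protein
    would receive if detected exactly once at the smallest NSAF observed in
    any control run (that value divided by ``top_n``) — the infimum of
    attainable profile values, keeping enrichment ratios finite without
    penalizing preys that the controls simply never saw.
    """

    values: pd.Series
    floor: float
    top_n: int

    def control_value(self, protein_id: str) -> float:
        v = float(self.values.get(protein_id, 0.0))
        return v if v > 0 else self.floor


def build_control_profile(control_nsaf: pd.DataFrame, control_top_n: int = 10) -> ControlProfile:
    """Average each protein's top-n control NSAF values (zero padded)."""
    if control_top_n < 1:
        raise ConfigError("control_top_n must be >= 1")
    if control_nsaf.shape[0] < 1:
        raise DataError("control profile requires at least one control run")
    arr = control_nsaf.to_numpy()
    n = min(control_top_n, arr.shape[0])
    # top-n of the zero-padded column = sum of the n largest (values >= 0)
    top = np.sort(arr, axis=0)[::-1][:n, :]
    values = pd.Series(top.sum(axis=0) / control_top_n, index=control_nsaf.columns)
    nonzero = arr[arr > 0]
    floor = (
        float(nonzero.min()) / control_top_n if nonzero.size else EMPTY_CONTROL_FLOOR
    )
    return ControlProfile(values=values, floor=floor, top_n=control_top_n)


def enrichment_filter(
    bait_nsaf: pd.DataFrame,
    dataset: Dataset,
    profile: ControlProfile,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Control-enrichment test for every detected bait-prey candidate.

    Returns a DataFrame with one row per (bait, prey) pair whose bait-level
    NSAF summary ``xbar`` is non-zero (the bait's own protein excluded):
    columns ``bait, prey, xbar, control_value, enrichment,
    passed_enrichment``.  ``xbar`` averages NSAF over the bait's replicates
    with zeros included (or takes the per-replicate maximum when
    ``enrichment_stat='max'``); the pass rule is strict
    ``enrichment > enrichment_min``.
    """
    config = config or PipelineConfig()
    run_to_bait = {r.run_id: r.bait_id for r in dataset.runs}
    missing = [rid for rid in bait_nsaf.index if rid not in run_to_bait]
    if missing:
        raise DataError(f"NSAF rows not found among sample runs: {missing}")
    baits = bait_nsaf.index.map(run_to_bait)
    grouped = bait_nsaf.groupby(baits)
    summary = grouped.mean() if config.enrichment_stat == "mean" else grouped.max()

    rows = []
    for bait in summary.index:
        xbars = summary.loc[bait]
        for prey in xbars.index[xbars.to_numpy() > 0]:
            if prey == bait:
                continue
            xbar = float(xbars[prey])
            cval = profile.control_value(prey)
            ratio = xbar / cval
            rows.append(
                {
                    "bait": bait,
                    "prey": prey,
                    "xbar": xbar,
                    "control_value": cval,
                    "enrichment": ratio,
                    "passed_enrichment": ratio > config.enrichment_min,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["bait", "prey", "xbar", "control_value", "enrichment", "passed_enrichment"],
    )


__all__ = [
    "ControlProfile",
    "build_control_profile",
    "compute_nsaf",
    "enrichment_filter",
    "redistribute_shared_counts",
]
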