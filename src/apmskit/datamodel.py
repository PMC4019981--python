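"""Core data model for AP-MS interaction proteomics.

An affinity-purification experiment tags one *bait* protein, purifies it
together with its binding partners (*preys*) and identifies the co-purified
proteins by mass spectrometry.  Evidence per run is a spectral count (number
of MS/MS spectra matched to a protein) and a list of precursor-ion
intensities per protein.  Mock purifications of an inert tag (GFP / RFP-NLS)
capture the nonspecific contaminant background and are stored as *control
runs*, identified by the reserved bait token ``CONTROL:<name>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ValidationError

#: Reserved bait-id prefix marking mock-control purifications.
CONTROL_PREFIX = "CONTROL:"


def is_control_bait(bait_id: str) -> bool:
    return bait_id.startswith(CONTROL_PREFIX)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-independent representation of an undirected protein pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein known to the dataset.

    ``length`` is the sequence length in amino acids and is the
    normalization denominator of NSAF.
    """

    protein_id: str
    length: int
    is_bait: bool = False

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if int(self.length) < 1:
            raise ValidationError(
                f"protein {self.protein_id!r}: length must be >= 1, got {self.length}"
            )


@dataclass
class PurificationRun:
    """One affinity-purification replicate.

    ``counts`` maps protein id to a non-negative spectral count; proteins
    with zero counts may simply be absent.  ``intensities`` maps protein id
    to the positive precursor-ion intensities observed for that protein in
    this run (used by TOP3 quantification).
    """

    run_id: str
    bait_id: str
    replicate_index: int
    condition: str
    counts: dict[str, int] = field(default_factory=dict)
    intensities: dict[str, list[float]] = field(default_factory=dict)

    @property
    def is_control(self) -> bool:
        return is_control_bait(self.bait_id)

    def validate(self) -> None:
        if self.replicate_index < 1:
            raise ValidationError(
                f"run {self.run_id!r}: replicate_index must be >= 1"
            )
        for pid, c in self.counts.items():
            if c < 0:
                raise ValidationError(
                    f"run {self.run_id!r}, protein {pid!r}: negative spectral count {c}"
                )
        for pid, vals in self.intensities.items():
            for v in vals:
                if not v > 0:
                    raise ValidationError(
                        f"run {self.run_id!r}, protein {pid!r}: non-positive intensity {v}"
                    )
        if not self.is_control and self.counts and self.bait_id not in self.counts:
            raise ValidationError(
                f"run {self.run_id!r}: bait {self.bait_id!r} absent from its own counts"
            )


@dataclass
class Dataset:
    """Proteins, bait purification runs and mock-control runs.

    ``proteins`` indexes every protein referenced by any run; ``runs`` holds
    bait purifications and ``control_runs`` the mock purifications (their
    ``bait_id`` carries the ``CONTROL:`` token).
    """

    proteins: dict[str, ProteinRecord]
    runs: list[PurificationRun]
    control_runs: list[PurificationRun] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        run_ids: set[str] = set()
        for run in list(self.runs) + list(self.control_runs):
            run.validate()
            if run.run_id in run_ids:
                raise ValidationError(f"duplicate run_id {run.run_id!r}")
            run_ids.add(run.run_id)
            for pid in run.counts:
                if pid not in self.proteins:
                    raise ValidationError(
                        f"run {run.run_id!r}: protein {pid!r} has no ProteinRecord"
                    )
            for pid in run.intensities:
                if pid not in self.proteins:
                    raise ValidationError(
                        f"run {run.run_id!r}: protein {pid!r} has no ProteinRecord"
                    )
        for run in self.runs:
            if run.is_control:
                raise ValidationError(
                    f"run {run.run_id!r}: control-tagged bait in sample runs"
                )
        for run in self.control_runs:
            if not run.is_control:
                raise ValidationError(
                    f"run {run.run_id!r}: control run lacks {CONTROL_PREFIX!r} bait token"
                )

    @property
    def baits(self) -> list[str]:
        """Bait ids in first-appearance order."""
        seen: dict[str, None] = {}
        for run in self.runs:
            seen.setdefault(run.bait_id, None)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for run in self.runs:
            seen.setdefault(run.condition, None)
        return list(seen)

    def runs_for_bait(
        self, bait_id: str, condition: str | None = None
    ) -> list[PurificationRun]:
        return [
            r
            for r in self.runs
            if r.bait_id == bait_id
            and (condition is None or r.condition == condition)
        ]

    def subset_condition(self, condition: str) -> "Dataset":
        """Dataset restricted to one condition (controls carried along)."""
        return Dataset(
            proteins=self.proteins,
            runs=[r for r in self.runs if r.condition == condition],
            control_runs=list(self.control_runs),
        )

    def length_of(self, protein_id: str) -> int:
        return self.proteins[protein_id].length


@dataclass
class Edge:
    """A bait-prey interaction with score annotations.

    ``attrs`` carries WD^N, the control-enrichment ratio, the rescued flag,
    the module label and the abundance relative to the bait, plus any other
    per-edge annotation.  For bait-bait pairs observed from both directions
    the reverse direction's scores are merged under ``<key>_rev``.
    """

    bait: str
    prey: str
    attrs: dict = field(default_factory=dict)

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.bait, self.prey)


class InteractionNetwork:
    """Set of scored bait-prey edges with canonical (unordered) identity."""

    def __init__(self, edges: Iterable[Edge] = ()):
        self._edges: dict[tuple[str, str], Edge] = {}
        for e in edges:
            self.add_edge(e)

    def add_edge(self, edge: Edge) -> None:
        if edge.bait == edge.prey:
            raise ValidationError(f"self-edge on {edge.bait!r} not allowed")
        key = edge.pair
        existing = self._edges.get(key)
        if existing is None:
            self._edges[key] = edge
        else:
            # same pair seen from the reciprocal purification: keep one
            # canonical edge, retain the other direction's scores
            for k, v in edge.attrs.items():
                if k not in existing.attrs:
                    existing.attrs[k] = v
                elif existing.attrs[k] != v:
                    existing.attrs.setdefault(f"{k}_rev", v)

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[Edge]:
        return iter(self._edges.values())

    def __contains__(self, pair: Sequence[str]) -> bool:
        a, b = pair
        return canonical_pair(a, b) in self._edges

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._edges)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self._edges.values():
            out.add(e.bait)
            out.add(e.prey)
        return out

    def get(self, a: str, b: str) -> Edge | None:
        return self._edges.get(canonical_pair(a, b))


__all__ = [
    "CONTROL_PREFIX",
    "Dataset",
    "Edge",
    "InteractionNetwork",
    "ProteinRecord",
    "PurificationRun",
    "canonical_pair",
    "is_control_bait",
]
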