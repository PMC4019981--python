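"""Synthetic AP-MS data with planted ground truth.

The generator emulates the statistical structure of a bait-prey interaction
screen: a set of baits partitioned into interaction modules, true preys
attached to one to three baits of a single module at bait-relative
abundances drawn log-uniformly, and a frequency-structured contaminant
background (Zipf-like rank-abundance) shared between bait runs and mock
controls.  Spectral counts are Poisson with expectation proportional to
``abundance x length`` (so NSAF is the natural abundance estimator) and
precursor-ion intensities are lognormal with median proportional to
abundance.  Condition effects multiply specific bait-prey abundances so
that downstream quantification has a known answer.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Dataset, ProteinRecord, PurificationRun
from .errors import ConfigError, DataError

BASELINE_CONDITION = "untreated"
#: Median precursor intensity of a protein at bait-level abundance.
BASE_INTENSITY = 1.0e6
#: Lognormal jitter (sigma, natural log) on the contaminant rank-abundance law.
CONTAMINANT_JITTER_SIGMA = 0.2


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic screen.

    Defaults describe a compact screen: 12 baits in 3 modules, 300 true
    preys, 150 Zipf-distributed contaminants, duplicate purifications, 20
    mock controls and an expected sequencing depth of 10^4 spectra per run.
    """

    n_baits: int = 12
    n_true_preys: int = 300
    n_contaminants: int = 150
    n_modules: int = 3
    replicates_per_bait: int = 2
    n_control_runs: int = 20
    sequencing_depth: int = 10_000
    contaminant_zipf_exponent: float = 1.0
    count_noise: str = "poisson"
    intensity_cv: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_baits", "n_true_preys", "n_contaminants", "n_modules",
                     "n_control_runs", "sequencing_depth"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.replicates_per_bait < 2:
            raise ConfigError("replicates_per_bait must be >= 2")
        if self.n_modules > self.n_baits:
            raise ConfigError("n_modules cannot exceed n_baits")
        if self.count_noise != "poisson":
            raise ConfigError("count_noise must be 'poisson'")
        if self.intensity_cv < 0:
            raise ConfigError("intensity_cv must be non-negative")
        if self.contaminant_zipf_exponent <= 0:
            raise ConfigError("contaminant_zipf_exponent must be positive")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(
                f"unknown generator config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**mapping)


@dataclass(frozen=True)
class TrueEdge:
    bait_id: str
    prey_id: str
    relative_abundance: float
    module_label: int


@dataclass
class SyntheticTruth:
    """Planted interactome the scoring stages must recover.

    ``condition_effects`` maps ``(condition, bait, prey)`` to a
    multiplicative abundance factor (0 removes the prey from that
    condition's runs); edges without an entry keep factor 1.
    """

    true_edges: list[TrueEdge]
    contaminant_profile: dict[str, float]
    condition_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    bait_modules: dict[str, int] = field(default_factory=dict)
    protein_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def baits(self) -> list[str]:
        return list(self.bait_modules)

    @property
    def true_pairs(self) -> set[tuple[str, str]]:
        return {(e.bait_id, e.prey_id) for e in self.true_edges}

    @property
    def prey_modules(self) -> dict[str, int]:
        """Module label per true prey (preys belong to exactly one module)."""
        out: dict[str, int] = {}
        for e in self.true_edges:
            out[e.prey_id] = e.module_label
        return out

    def edges_of_bait(self, bait_id: str) -> list[TrueEdge]:
        return [e for e in self.true_edges if e.bait_id == bait_id]


def _draw_length(rng: np.random.Generator) -> int:
    # typical human protein lengths, uniform over 100-1000 aa
    return int(rng.integers(100, 1001))


def generate_truth(config: GeneratorConfig) -> SyntheticTruth:
    """Plant a modular interactome and a contaminant background.

    Baits are partitioned as evenly as possible into ``n_modules`` modules;
    each true prey joins one module (round-robin, so every module gets
    preys) and attaches to 1-3 of its module's baits with per-edge relative
    abundance drawn log-uniformly from [0.01, 1].  Contaminant abundances
    follow ``rank^-s`` with mild lognormal jitter.  Deterministic given
    ``config.rng_seed``.
    """
    rng = np.random.default_rng([config.rng_seed, 0])
    baits = [f"BAIT{i + 1:02d}" for i in range(config.n_baits)]
    module_of_bait: dict[str, int] = {}
    module_baits: dict[int, list[str]] = {}
    for m, chunk in enumerate(np.array_split(np.array(baits), config.n_modules), start=1):
        for b in chunk:
            module_of_bait[str(b)] = m
        module_baits[m] = [str(b) for b in chunk]

    lengths: dict[str, int] = {b: _draw_length(rng) for b in baits}

    edges: list[TrueEdge] = []
    for idx in range(config.n_true_preys):
        prey = f"PREY{idx + 1:04d}"
        lengths[prey] = _draw_length(rng)
        module = (idx % config.n_modules) + 1
        pool = module_baits[module]
        deg = int(rng.integers(1, min(3, len(pool)) + 1))
        chosen = rng.choice(pool, size=deg, replace=False)
        for b in sorted(str(x) for x in chosen):
            abundance = float(10.0 ** rng.uniform(-2.0, 0.0))
            edges.append(TrueEdge(b, prey, abundance, module))

    profile: dict[str, float] = {}
    for r in range(1, config.n_contaminants + 1):
        cid = f"CONT{r:04d}"
        lengths[cid] = _draw_length(rng)
        jitter = math.exp(rng.normal(0.0, CONTAMINANT_JITTER_SIGMA))
        profile[cid] = float(r ** (-config.contaminant_zipf_exponent) * jitter)

    return SyntheticTruth(
        true_edges=edges,
        contaminant_profile=profile,
        bait_modules=module_of_bait,
        protein_lengths=lengths,
    )


def _run_abundances(
    truth: SyntheticTruth, bait: str, condition: str
) -> dict[str, float]:
    """Expected abundance (relative to the bait) of every species in a run."""
    a: dict[str, float] = {bait: 1.0}
    for edge in truth.edges_of_bait(bait):
        factor = truth.condition_effects.get((condition, bait, edge.prey_id), 1.0)
        value = edge.relative_abundance * factor
        if value > 0:
            a[edge.prey_id] = value
    for cid, value in truth.contaminant_profile.items():
        if value > 0:
            a[cid] = value
    return a


def _draw_counts(
    rng: np.random.Generator,
    abundances: dict[str, float],
    lengths: dict[str, int],
    depth: int,
    anchor: str,
) -> dict[str, int]:
    pids = list(abundances)
    a = np.array([abundances[p] for p in pids], dtype=float)
    L = np.array([lengths[p] for p in pids], dtype=float)
    lam = depth * a * L / float(np.sum(a * L))
    draws = rng.poisson(lam)
    counts = {p: int(c) for p, c in zip(pids, draws) if c > 0}
    # the anchor species (bait, or top contaminant in controls) is always
    # identified in its own purification
    if anchor not in counts:
        counts[anchor] = 1
    return counts


def _draw_intensities(
    rng: np.random.Generator,
    counts: dict[str, int],
    abundances: dict[str, float],
    lengths: dict[str, int],
    cv: float,
) -> dict[str, list[float]]:
    sigma = math.sqrt(math.log1p(cv * cv))
    out: dict[str, list[float]] = {}
    for pid in counts:
        m = max(3, int(round(lengths[pid] / 50.0)))
        median = BASE_INTENSITY * abundances[pid]
        if sigma == 0.0:
            vals = np.full(m, median)
        else:
            vals = median * np.exp(rng.normal(0.0, sigma, size=m))
        out[pid] = [float(v) for v in vals]
    return out


def simulate_runs(truth: SyntheticTruth, config: GeneratorConfig) -> Dataset:
    """Draw bait purification replicates from the planted truth.

    One set of ``replicates_per_bait`` runs per bait for the baseline
    condition, plus one per condition named in ``truth.condition_effects``.
    Expected count of species *j* is ``depth * a_j * L_j / sum_k a_k L_k``;
    realized counts are Poisson.  Deterministic given ``config.rng_seed``.
    """
    missing = [b for b in truth.bait_modules if b not in truth.protein_lengths]
    if missing:
        raise DataError(f"truth references baits without lengths: {missing}")
    rng = np.random.default_rng([config.rng_seed, 1])

    proteins: dict[str, ProteinRecord] = {}
    bait_ids = set(truth.bait_modules)
    for pid, length in truth.protein_lengths.items():
        proteins[pid] = ProteinRecord(pid, length, is_bait=pid in bait_ids)

    conditions = [BASELINE_CONDITION] + sorted(
        {cond for (cond, _, _) in truth.condition_effects if cond != BASELINE_CONDITION}
    )
    runs: list[PurificationRun] = []
    for bait in truth.bait_modules:
        for condition in conditions:
            abundances = _run_abundances(truth, bait, condition)
            for rep in range(1, config.replicates_per_bait + 1):
                counts = _draw_counts(
                    rng, abundances, truth.protein_lengths,
                    config.sequencing_depth, anchor=bait,
                )
                intens = _draw_intensities(
                    rng, counts, abundances, truth.protein_lengths,
                    config.intensity_cv,
                )
                runs.append(
                    PurificationRun(
                        run_id=f"{bait}_{condition}_r{rep}",
                        bait_id=bait,
                        replicate_index=rep,
                        condition=condition,
                        counts=counts,
                        intensities=intens,
                    )
                )
    return Dataset(proteins=proteins, runs=runs)


def simulate_controls(
    truth: SyntheticTruth, config: GeneratorConfig
) -> list[PurificationRun]:
    """Draw mock-control runs containing only the contaminant background.

    Mirrors a GFP/RFP-NLS mock purification set: roughly five of six runs
    carry the GFP tag, the remainder RFP-NLS.  No true prey ever appears.
    """
    rng = np.random.default_rng([config.rng_seed, 2])
    n_gfp = max(1, int(math.ceil(config.n_control_runs * 5 / 6)))
    top_contaminant = max(
        truth.contaminant_profile, key=lambda c: truth.contaminant_profile[c]
    )
    runs: list[PurificationRun] = []
    for i in range(1, config.n_control_runs + 1):
        tag = "GFP" if i <= n_gfp else "RFP-NLS"
        abundances = {
            c: v for c, v in truth.contaminant_profile.items() if v > 0
        }
        counts = _draw_counts(
            rng, abundances, truth.protein_lengths,
            config.sequencing_depth, anchor=top_contaminant,
        )
        intens = _draw_intensities(
            rng, counts, abundances, truth.protein_lengths, config.intensity_cv
        )
        runs.append(
            PurificationRun(
                run_id=f"CTRL_{tag}_r{i}",
                bait_id=f"CONTROL:{tag}",
                replicate_index=i,
                condition=BASELINE_CONDITION,
                counts=counts,
                intensities=intens,
            )
        )
    return runs


def simulate_dataset(
    config: GeneratorConfig, truth: SyntheticTruth | None = None
) -> tuple[Dataset, SyntheticTruth]:
    """Generate truth, bait runs and controls as one validated dataset."""
    if truth is None:
        truth = generate_truth(config)
    sample = simulate_runs(truth, config)
    controls = simulate_controls(truth, config)
    dataset = Dataset(
        proteins=sample.proteins, runs=sample.runs, control_runs=controls
    )
    return dataset, truth


__all__ = [
    "BASELINE_CONDITION",
    "GeneratorConfig",
    "SyntheticTruth",
    "TrueEdge",
    "generate_truth",
    "simulate_controls",
    "simulate_dataset",
    "simulate_runs",
]
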