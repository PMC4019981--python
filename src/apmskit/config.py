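"""Pipeline configuration.

All thresholds of the HCIP filtering cascade live here with the defaults
used throughout: control enrichment > 10, WD^N >= 1 against the 95% quantile
of the permutation null, top-10 control averaging, two-level significance
stars at P < 0.05 and P < 0.01.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Thresholds and switches for scoring, clustering and quantification.

    Parameters
    ----------
    enrichment_min
        Candidates must exceed this NSAF enrichment ratio over the mock
        controls (strict ``>``).
    wdn_min
        Normalized WD-score pass threshold (inclusive ``>=``).
    control_top_n
        Per protein, the control abundance is the mean of its top-n NSAF
        values across all control runs, zero-padded to n.
    sim_quantile
        Quantile of the permuted-matrix WD distribution used to normalize
        raw WD scores.
    n_permutations
        Permutation rounds pooled into the null distribution.
    top_n_intensities
        Number of most-intense precursor ions averaged by TOP3.
    n_major_clusters
        Cut level of the average-linkage tree for major modules.
    n_sub_clusters
        Deeper cut exposing sub-modules.
    alpha_levels
        (one-star, two-star) p-value thresholds.
    enrichment_stat
        "mean" (default) averages NSAF over a bait's replicates, zeros
        included; "max" uses the per-replicate maximum.
    omega_floor
        Floor the reproducibility weight omega at 1 (default) or leave the
        raw coefficient of variation.
    rescue_mode
        "similarity" (default) rescues a sub-threshold prey when its profile
        has uncentered-Pearson similarity above ``rescue_min_similarity``
        with an HCIP of the same bait; "distance" applies the literal
        distance-greater-than-zero reading.
    equal_var
        Student (True, default) vs Welch t-test in condition comparisons.
    bh_correction
        Apply Benjamini-Hochberg across preys in a comparison (off by
        default; stars are per-prey).
    """

    enrichment_min: float = 10.0
    wdn_min: float = 1.0
    control_top_n: int = 10
    sim_quantile: float = 0.95
    n_permutations: int = 100
    top_n_intensities: int = 3
    n_major_clusters: int = 3
    n_sub_clusters: int = 6
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    rng_seed: int = 0
    enrichment_stat: str = "mean"
    omega_floor: bool = True
    rescue_mode: str = "similarity"
    rescue_min_similarity: float = 0.0
    equal_var: bool = True
    bh_correction: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("enrichment_min", "wdn_min"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        for name in ("control_top_n", "n_permutations", "top_n_intensities",
                     "n_major_clusters", "n_sub_clusters"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if not 0.0 < self.sim_quantile < 1.0:
            raise ConfigError("sim_quantile must lie in the open unit interval")
        a1, a2 = self.alpha_levels
        if not (0 < a2 < a1 < 1):
            raise ConfigError(
                "alpha_levels must satisfy 0 < two-star < one-star < 1"
            )
        if self.enrichment_stat not in ("mean", "max"):
            raise ConfigError("enrichment_stat must be 'mean' or 'max'")
        if self.rescue_mode not in ("similarity", "distance"):
            raise ConfigError("rescue_mode must be 'similarity' or 'distance'")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        """Build from a parsed config section, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(
                f"unknown pipeline config key(s): {', '.join(sorted(unknown))}"
            )
        kwargs = dict(mapping)
        if "alpha_levels" in kwargs:
            kwargs["alpha_levels"] = tuple(kwargs["alpha_levels"])
        return cls(**kwargs)


__all__ = ["PipelineConfig"]
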