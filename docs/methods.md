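# Methods

This note documents the statistical model behind `apmskit`, the defaults it
ships with, and the design decisions taken where the underlying methodology
leaves room for interpretation.

## Problem setting

Affinity purification–mass spectrometry (AP-MS) screens tag a *bait*
protein, purify it under mild conditions and identify co-purifying
proteins (*preys*) by MS/MS. The raw evidence per purification run is a
spectral count (SpC, the number of MS/MS spectra matched to a protein) and
a list of precursor-ion intensities per protein. The analytical problem is
that most identified proteins are nonspecific background — resin binders,
ribosomes, chaperones — so a scoring cascade must separate high-confidence
interacting proteins (HCIPs) from contaminants using (i) mock purifications
of an inert tag and (ii) the frequency structure of preys across many baits.

## Abundance: NSAF

Protein abundance within a run is summarized by the normalized spectral
abundance factor

    NSAF_{r,j} = (SpC_{r,j} / L_j) / Σ_k (SpC_{r,k} / L_k)

where `L_j` is protein length in amino acids. Rows sum to one over detected
proteins, making runs of different depth comparable; dividing by `L` removes
the bias that longer proteins yield more peptides.

## Control filter

The contaminant background is estimated from mock-control runs (GFP /
RFP-NLS purifications, bait token `CONTROL:<tag>`). For every protein the
control profile value is the mean of its `control_top_n` (default 10)
highest NSAF values across all control runs, zero-padded to `top_n` when it
was seen less often. The zero padding follows the top-10-of-74 averaging
rule literally and penalizes frequent contaminants more than rare ones.

A candidate (bait *i*, prey *j*) passes when

    E_{ij} = x̄_{ij} / max(profile_j, floor)  >  enrichment_min   (default 10, strict)

with `x̄_{ij}` the mean NSAF over bait *i*'s replicates, zeros included
(irreproducible preys score lower by construction; a `max`-over-replicates
variant is available via `enrichment_stat`).

**Floor.** For preys never seen in any control, the denominator is the
detection limit of the control set: the profile value a protein would get
if detected exactly once at the smallest non-zero NSAF observed in any
control run, i.e. `min_nonzero_control_NSAF / top_n`. This is the infimum of
attainable profile values, so it is data-driven and scale-free. An earlier
candidate rule — the smallest non-zero *profile* value — ratioed
control-absent preys against the weakest real contaminant and, on the
synthetic benchmark below, capped the filter's recall near 0.35; absence
from dozens of controls is stronger evidence than one weak detection, and
the detection-limit floor encodes exactly that.

## Specificity: WD and WD^N

The WD score combines abundance, cross-bait frequency and replicate
reproducibility:

    WD_{ij} = sqrt( x̄_{ij} · ((k / f_j) · ω_j)^{n_{ij}} )

- `k` — number of baits in the screen (controls excluded),
- `f_j` — number of baits detecting prey *j* (the bait's own protein is
  excluded from its own row),
- `ω_j` — reproducibility weight: sample coefficient of variation (ddof 1)
  of the non-zero `x̄` values of prey *j*, floored at 1 (`omega_floor`
  exposes the unfloored variant); `ω_j = 1` when `f_j ≤ 1`,
- `n_{ij}` — number of bait *i*'s replicates detecting prey *j*.

Raw WD scores are normalized by the empirical 95% quantile
(`sim_quantile`) of WD scores computed on a simulated stats matrix, and
interactions with `WD^N = WD / threshold ≥ 1` pass (inclusive).

**The simulated matrix.** The null hypothesis behind the threshold is that
a prey is a ubiquitous nonspecific binder. Each simulation round therefore
resamples every prey's observed non-zero `(x̄, n)` entries with replacement
onto all `k` bait columns: `f = k` by construction, `ω` is recomputed on
each simulated row, and WD is evaluated for every simulated entry. Pooling
entries across preys and `n_permutations` rounds (default 100, seeded)
gives the null distribution; its `sim_quantile` quantile is the single
global threshold. This design keeps each prey's abundance and
reproducibility marginals but deletes bait specificity, which is precisely
what the frequency term `(k/f)^n` is meant to reward. Note that a
permutation which only moves a prey's entries *between* bait columns while
preserving `f`, `ω` and the `(x̄, n)` pairs leaves every WD value
numerically unchanged and cannot produce a usable null; the resampling
scheme above is the package's resolution of that degeneracy.

Useful invariances: multiplying all `x̄` by `c > 0` scales WD and the
threshold by `√c`, so WD^N is invariant under global count rescaling.

## Profiles, distances, modules

HCIP profiles are abundances relative to the purifying bait: per run,
`NSAF_prey / NSAF_bait`, averaged over the bait's replicates (zeros
included). Profile similarity is the uncentered Pearson correlation

    r_u(x, y) = Σ x_i y_i / sqrt(Σ x_i² · Σ y_i²)

and the clustering distance is `d = 1 − r_u ∈ [0, 1]` for non-negative
profiles. Modules come from average-linkage agglomerative clustering of the
gene distance matrix (GDM), cut at `n_major_clusters` (default 3; a deeper
`n_sub_clusters = 6` cut exposes sub-modules). Inputs are sorted
lexicographically before linkage and cluster labels renumbered by each
cluster's first member, so ties resolve deterministically. Baits that never
occur as preys are attached to the module whose member preys are most
abundant in their purification.

## Rescue of sub-threshold interactions

To recover genuine interactors that narrowly miss the WD^N cut, a
candidate that **passes the control filter** but fails WD^N is rescued when
its profile has uncentered-Pearson similarity strictly greater than
`rescue_min_similarity` (default 0) with at least one HCIP of the same
bait. Restricting eligibility to control-passing candidates matters:
contaminant profiles are non-zero in every bait and correlate positively
with almost any HCIP, so an unrestricted rule would readmit most of the
background the filters just removed. The literal distance-greater-than-zero
reading is available via `rescue_mode="distance"`. Rescue only ever adds
edges; the final network is the union of strictly passing and rescued
pairs, with reciprocal bait–bait detections collapsed onto one canonical
edge.

## TOP3 quantification

Protein abundance per run is the mean of the `top_n_intensities` (default
3) most intense precursor ions, normalized to the bait's value in the same
run, which cancels global per-run intensity scale. With fewer than three
ions the mean of the available ones is used and flagged low-evidence —
dropping such preys would silently lose sparse interactors.

Condition contrasts use a shared pseudo-value ε (half the smallest non-zero
relative abundance in the comparison) and report
`log2((mean_B + ε)/(mean_A + ε))` with a two-sided two-sample t-test on
`log(value + ε)` replicates. Student's test is the default (with n = 3 per
group, Welch degrees of freedom are unstable; `equal_var=False` switches).
Stars follow the two-level convention (`*` P < 0.05, `**` P < 0.01) per
prey, without multiple-testing correction; a Benjamini–Hochberg option
exists behind `bh_correction`.

## Synthetic data generator

The generator is the test bed for the whole cascade and defines the
benchmark conditions: **12 baits in 3 modules, 300 true preys, 150
contaminants, 2 replicates per bait, 20 mock controls, expected depth 10⁴
spectra per run**. Structure:

- baits split evenly into modules; each true prey joins one module
  (round-robin) and attaches to 1–3 of its module's baits with per-edge
  relative abundance drawn log-uniformly from [0.01, 1] (bait abundance is
  fixed at 1, so truth is parameterized the same way the clustering and
  quantification read the data);
- contaminants follow a Zipf rank-abundance law `rank^(−s)` (default
  exponent 1, the canonical choice for rank-frequency laws) with mild
  lognormal jitter (σ = 0.2) so the rank curve is not perfectly smooth; the
  top contaminant sits at bait-level abundance, reflecting how resin
  binders dominate mock purifications; contaminant expectations are
  identical in bait runs and controls, which is exactly the assumption the
  control filter makes;
- expected counts are `depth · a_j L_j / Σ_k a_k L_k` with Poisson noise
  (the simplest model consistent with spectral counting; overdispersion is
  an extension point, not a default), lengths uniform on 100–1000 aa; the
  anchor species of a run (its bait; the top contaminant in controls) is
  floored at one count, since a purification that fails to identify its own
  bait would be discarded upstream;
- precursor intensities: `max(3, round(L/50))` values per detected protein,
  lognormal with median `10⁶ · a_j` and coefficient of variation
  `intensity_cv` (default 0.1, typical for label-free precursor areas), so
  TOP3 and NSAF remain distinct estimators sharing only the true abundance;
- condition effects multiply specific (condition, bait, prey) abundances;
  a factor of 0 removes the prey from that condition's runs.

Everything is deterministic given `rng_seed` (separate substreams for
truth, bait runs and controls).

**What the generator does not emulate:** shared-peptide ambiguity,
peptide-level properties (missed cleavages, retention time), inter-batch
drift, bait expression differences, overdispersed counts, and correlated
contaminant structure (e.g. whole ribosomes co-varying). Passing the
synthetic-recovery suite therefore demonstrates that the cascade's logic
recovers a planted signal under honest count noise — not that these
thresholds are optimal for any particular real screen.

On this benchmark (seeds 1–5) the cascade reaches precision 1.0 and recall
0.79–0.86 against the planted truth, the 3-module structure is recovered at
adjusted Rand index 1.0, and a planted 4× condition effect is recovered
within ±0.3 log2 units with significance calls in ≥4/5 seeds — these are
the quantities the acceptance test suite recomputes.

## Numerical choices and degenerate inputs

- NSAF requires each run to have at least one non-zero count (error naming
  the run); a bait undetected in its own run is an error.
- Control profile with no detections at all falls back to a floor of 1e-9.
- All-zero profiles are dropped from the GDM with a warning; a GDM needs at
  least two profiles.
- Constant-and-equal replicate groups in a t-test report p = 1 with a
  degenerate flag; preys with fewer than two replicates are skipped.
- `fcluster` cuts with `maxclust`; when distinct profiles are fewer than
  the requested cluster count the partition is still valid and
  deterministic.
- Shared-peptide redistribution (optional, off by default — inputs are
  assumed protein-level) splits group counts proportionally to unique
  evidence within the run, equally when no member has unique counts.

## Known limitations

- The WD functional form is one member of the CompPASS family; all of its
  components (`k`, `f`, `ω`, `n`) are exposed so the expression is easy to
  swap.
- The permutation count (default 100) trades null resolution against run
  time; the pooled null has `~candidates × rounds` entries, so the default
  is ample for a 95% quantile on screens of a few thousand candidates.
- Recall against public PPI references depends entirely on the reference's
  coverage; the recall operation reports a fraction of a chosen stratum,
  not a truth-level error rate.
- The pipeline scores one condition at a time (the baseline by default);
  cross-condition scoring is left to the quantification module.
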