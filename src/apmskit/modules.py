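"""Bait-relative abundance profiles, uncentered-Pearson clustering, rescue
of sub-threshold interactions and final network assembly.

Interactor profiles are abundances relative to the purifying bait (prey
NSAF / bait NSAF, averaged over replicates).  Profile similarity is the
uncentered Pearson correlation

    r_u(x, y) = sum_i x_i y_i / sqrt(sum_i x_i^2 * sum_i y_i^2)

(a cosine similarity, no mean-centering) and the clustering distance is
``d = 1 - r_u``.  Modules come from average-linkage agglomerative
clustering of the gene distance matrix (GDM); the GDM additionally rescues
sub-threshold interactions whose profiles co-vary with an established
high-confidence interactor of the same bait.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import PipelineConfig
from .datamodel import Dataset, Edge, InteractionNetwork, canonical_pair
from .errors import DataError

logger = logging.getLogger(__name__)


def relative_abundance(bait_nsaf: pd.DataFrame, dataset: Dataset) -> pd.DataFrame:
    """Protein x bait matrix of abundances relative to each bait.

    Per run, every protein's NSAF is divided by the bait's own NSAF in that
    run; ratios are averaged across the bait's replicates with zeros for
    undetected proteins.  A bait undetected in its own run is an error
    naming the run.
    """
    run_to_bait = {r.run_id: r.bait_id for r in dataset.runs}
    ratio_rows = np.empty(bait_nsaf.shape)
    for i, rid in enumerate(bait_nsaf.index):
        bait = run_to_bait.get(rid)
        if bait is None:
            raise DataError(f"NSAF row {rid!r} is not a sample run")
        bait_val = float(bait_nsaf.loc[rid, bait]) if bait in bait_nsaf.columns else 0.0
        if bait_val <= 0:
            raise DataError(f"bait {bait!r} undetected in its own run {rid!r}")
        ratio_rows[i] = bait_nsaf.loc[rid].to_numpy() / bait_val
    ratios = pd.DataFrame(ratio_rows, index=bait_nsaf.index, columns=bait_nsaf.columns)
    baits = ratios.index.map(run_to_bait)
    per_bait = ratios.groupby(baits).mean()  # baits x proteins
    return per_bait.T  # proteins x baits


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Uncentered Pearson correlation (cosine) of two profiles."""
    nx = float(np.sqrt(np.sum(np.square(x))))
    ny = float(np.sqrt(np.sum(np.square(y))))
    if nx == 0.0 or ny == 0.0:
        raise DataError("uncentered correlation undefined for an all-zero profile")
    return float(np.dot(x, y) / (nx * ny))


@dataclass
class GeneDistanceMatrix:
    """Symmetric uncentered-Pearson distance matrix ``d = 1 - r_u``.

    For non-negative profiles d lies in [0, 1] with d(x, x) = 0.
    """

    values: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.values.index

    def distance(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])

    def similarity(self, a: str, b: str) -> float:
        return 1.0 - self.distance(a, b)


def gene_distance_matrix(profiles: pd.DataFrame) -> GeneDistanceMatrix:
    """GDM over profile rows; all-zero profiles are dropped with a warning."""
    norms = np.sqrt(np.square(profiles.to_numpy()).sum(axis=1))
    zero = norms == 0
    if zero.any():
        dropped = list(profiles.index[zero])
        logger.warning("dropping %d all-zero profile(s): %s", len(dropped), dropped[:10])
        profiles = profiles.loc[~zero]
        norms = norms[~zero]
    if profiles.shape[0] < 2:
        raise DataError("gene distance matrix requires at least 2 non-zero profiles")
    unit = profiles.to_numpy() / norms[:, np.newaxis]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return GeneDistanceMatrix(
        values=pd.DataFrame(d, index=profiles.index, columns=profiles.index)
    )


@dataclass
class ModuleAssignment:
    """Cluster labels (1..n, ordered by first lexicographic member) plus the
    average-linkage merge tree."""

    labels: dict[str, int]
    linkage_matrix: np.ndarray
    ids: list[str]

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list[str]:
        return [p for p, m in self.labels.items() if m == label]


def hierarchical_modules(gdm: GeneDistanceMatrix, n_major_clusters: int = 3) -> ModuleAssignment:
    """Average-linkage clustering of the GDM cut into major modules.

    Inputs are ordered lexicographically before linkage so that tie-breaks
    are deterministic; cluster labels are renumbered by the lexicographic
    rank of each cluster's first member.
    """
    ids = sorted(gdm.ids)
    if n_major_clusters > len(ids):
        raise DataError(
            f"n_major_clusters={n_major_clusters} exceeds {len(ids)} profiles"
        )
    d = gdm.values.loc[ids, ids].to_numpy()
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method="average")
    raw = fcluster(z, t=n_major_clusters, criterion="maxclust")
    # renumber deterministically: module 1 contains the lexicographically
    # smallest member among all clusters, and so on
    order: dict[int, int] = {}
    for pid, lab in zip(ids, raw):
        if lab not in order:
            order[lab] = len(order) + 1
    labels = {pid: order[lab] for pid, lab in zip(ids, raw)}
    return ModuleAssignment(labels=labels, linkage_matrix=z, ids=ids)


def assign_bait_modules(
    rel: pd.DataFrame, assignment: ModuleAssignment
) -> dict[str, int]:
    """Attach each bait to the module whose preys are most abundant in it.

    ``rel`` is the protein x bait relative-abundance matrix; a bait already
    clustered as a prey keeps its own label.
    """
    out: dict[str, int] = {}
    module_ids = sorted(set(assignment.labels.values()))
    for bait in rel.columns:
        if bait in assignment.labels:
            out[bait] = assignment.labels[bait]
            continue
        best, best_val = module_ids[0], -np.inf
        for m in module_ids:
            members = [p for p in assignment.members(m) if p in rel.index]
            if not members:
                continue
            val = float(rel.loc[members, bait].mean())
            if val > best_val:
                best, best_val = m, val
        out[bait] = best
    return out


def rescue_subthreshold(
    candidates: pd.DataFrame,
    gdm: GeneDistanceMatrix,
    config: PipelineConfig | None = None,
) -> set[tuple[str, str]]:
    """Profile-supported rescue of candidates that missed the WD^N cut.

    ``candidates`` needs columns ``bait, prey, is_hcip``; when a
    ``passed_enrichment`` column is present only candidates that cleared
    the control filter are eligible (contaminant-level preys are never
    rescued).  A sub-threshold pair (i, j) is rescued when prey j's profile
    has uncentered-Pearson similarity above ``rescue_min_similarity``
    (strict, default 0) with at least one high-confidence interactor of
    bait i.  With ``rescue_mode='distance'`` the literal reading is applied
    instead (rescued when the GDM distance to an HCIP of the bait exceeds
    zero).  Preys absent from the GDM are never rescued (logged).
    """
    config = config or PipelineConfig()
    required = {"bait", "prey", "is_hcip"}
    if not required.issubset(candidates.columns):
        raise DataError(f"candidates table needs columns {sorted(required)}")
    has_enrichment = "passed_enrichment" in candidates.columns
    hcips_of_bait: dict[str, list[str]] = {}
    for row in candidates.itertuples(index=False):
        if row.is_hcip:
            hcips_of_bait.setdefault(row.bait, []).append(row.prey)
    rescued: set[tuple[str, str]] = set()
    for row in candidates.itertuples(index=False):
        if row.is_hcip:
            continue
        if has_enrichment and not row.passed_enrichment:
            continue
        if row.prey not in gdm:
            logger.info("prey %s absent from GDM; not rescued", row.prey)
            continue
        for partner in hcips_of_bait.get(row.bait, ()):
            if partner == row.prey or partner not in gdm:
                continue
            if config.rescue_mode == "similarity":
                hit = gdm.similarity(row.prey, partner) > config.rescue_min_similarity
            else:
                hit = gdm.distance(row.prey, partner) > 0.0
            if hit:
                rescued.add((row.bait, row.prey))
                break
    return rescued


def assemble_network(
    scores: pd.DataFrame,
    rescued: set[tuple[str, str]] | None = None,
    modules: dict[str, int] | None = None,
    rel: pd.DataFrame | None = None,
) -> InteractionNetwork:
    """Union of strictly passing and rescued pairs as an annotated network.

    ``scores`` needs columns ``bait, prey, is_hcip`` and optionally
    ``wdn, enrichment``.  Reciprocal bait-bait detections collapse onto one
    canonical edge (the second direction's differing scores are kept under
    ``*_rev`` attributes).  An empty result is allowed with a warning.
    """
    rescued = rescued or set()
    modules = modules or {}
    net = InteractionNetwork()
    for row in scores.itertuples(index=False):
        pair = (row.bait, row.prey)
        is_rescued = pair in rescued
        if not (row.is_hcip or is_rescued):
            continue
        attrs = {"rescued": is_rescued}
        for key in ("wdn", "enrichment"):
            if hasattr(row, key):
                attrs[key] = float(getattr(row, key))
        if row.prey in modules:
            attrs["module"] = modules[row.prey]
        if rel is not None and row.prey in rel.index and row.bait in rel.columns:
            attrs["rel_abundance"] = float(rel.loc[row.prey, row.bait])
        net.add_edge(Edge(row.bait, row.prey, attrs))
    if len(net) == 0:
        logger.warning("assembled network is empty")
    return net


def recall_vs_reference(
    network: InteractionNetwork,
    reference: dict[tuple[str, str], int],
    min_publications: int = 1,
) -> float:
    """Fraction of the reference stratum recovered by the network.

    The stratum is the set of reference pairs with at least
    ``min_publications`` supporting publications; an empty stratum is an
    error.
    """
    stratum = {
        canonical_pair(*pair)
        for pair, npub in reference.items()
        if npub >= min_publications
    }
    if not stratum:
        raise DataError(
            f"no reference interactions with n_publications >= {min_publications}"
        )
    found = network.pairs
    return len(stratum & found) / len(stratum)


def enumerate_family_dimers(network: InteractionNetwork, family: set[str]) -> int:
    """Count distinct unordered within-family pairs connected in the network.

    Used to enumerate pairwise sub-complexes among a protein family (e.g.
    the SARAH-domain proteins MST1/2, SAV1 and the RASSF family, where
    binding selectivity restricts which homotypic dimers can form).
    """
    count = 0
    for a, b in itertools.combinations(sorted(family), 2):
        if (a, b) in network:
            count += 1
    return count


__all__ = [
    "GeneDistanceMatrix",
    "ModuleAssignment",
    "assemble_network",
    "assign_bait_modules",
    "enumerate_family_dimers",
    "gene_distance_matrix",
    "hierarchical_modules",
    "recall_vs_reference",
    "relative_abundance",
    "rescue_subthreshold",
    "uncentered_correlation",
]
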