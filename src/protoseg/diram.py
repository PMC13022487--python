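"""DIRAM: density-based clustering on complete subdatasets.

The matrix is first sliced into complete subdatasets by missing-mask
similarity (see :mod:`protoseg.missingness`).  Each subdataset is embedded
to two dimensions with UMAP, clusters are detected on the embedding with
DBSCAN, clusters outside a size window are relabeled noise, and clusters
found in different subdatasets that contain largely the same participants
are merged.

Because a 2-D manifold embedding is a stochastic optimisation, each
subdataset can additionally be embedded under several audit seeds; the
distribution of pairwise adjusted Rand indices between the per-seed
cluster outcomes is reported so an unstable (local-minimum) projection is
visible.  The audit is a report, not an automated rejection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.metrics import adjusted_rand_score

from .containers import NOISE, ClusterAssignment, ProteinMatrix
from .missingness import MissingnessGrouping, extract_subdataset, group_by_missingness

logger = logging.getLogger(__name__)

DEFAULT_EPS = 0.1
DEFAULT_MIN_SAMPLES = 10
#: factor applied to the median min_samples-th neighbour distance when
#: eps="auto" (k-distance heuristic)
AUTO_EPS_FACTOR = 2.0
DEFAULT_MIN_CLUSTER_SIZE = 100
DEFAULT_MAX_CLUSTER_SIZE = 20_000
DEFAULT_MERGE_MARGIN = 0.4


@dataclass
class EmbeddingResult:
    subdataset_id: str
    seed: int
    participant_ids: list[str]
    coords: np.ndarray  # (n, 2)


@dataclass
class StabilityReport:
    """Pairwise ARI of density-cluster outcomes across audit seeds."""

    subdataset_id: str
    seeds: list[int]
    pairwise_ari: list[float]

    @property
    def median_ari(self) -> float:
        return float(np.median(self.pairwise_ari)) if self.pairwise_ari else 1.0


def _umap_embed(x: np.ndarray, seed: int) -> np.ndarray:
    # library defaults except the random seed; UMAP warns that a fixed
    # random_state disables parallelism, which is exactly what we want
    import umap  # deferred: slow import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, random_state=seed)
        return np.asarray(reducer.fit_transform(x), dtype=float)


def embed_2d(
    sub: ProteinMatrix,
    seed: int = 1,
    n_seeds_audit: int = 0,
    audit_eps: float | str = DEFAULT_EPS,
    audit_min_samples: int = DEFAULT_MIN_SAMPLES,
) -> tuple[EmbeddingResult, StabilityReport | None]:
    """2-D UMAP embedding of a complete subdataset, deterministic per seed.

    With ``n_seeds_audit`` > 1 the subdataset is additionally embedded under
    audit seeds ``seed, seed+1, ...``; each audit embedding is
    density-clustered (DBSCAN with the audit parameters) and all pairwise
    adjusted Rand indices between the outcomes are reported.  A warning is
    logged when the median pairwise ARI is below 0.5.
    """
    if not sub.is_complete():
        raise ValueError("subdataset contains missing values")
    n_neighbors = 15  # umap default
    if sub.n_participants < n_neighbors:
        raise ValueError(
            f"{sub.n_participants} participants < embedding neighborhood {n_neighbors}"
        )
    sub_id = getattr(sub, "subdataset_id", "sub")
    coords = _umap_embed(sub.values, seed)
    result = EmbeddingResult(sub_id, seed, list(sub.participant_ids), coords)

    report = None
    if n_seeds_audit > 1:
        seeds = [seed + k for k in range(n_seeds_audit)]
        outcomes = []
        for s in seeds:
            c = coords if s == seed else _umap_embed(sub.values, s)
            e = auto_eps(c, audit_min_samples) if audit_eps == "auto" else audit_eps
            labels = DBSCAN(eps=e, min_samples=audit_min_samples).fit_predict(c)
            outcomes.append(labels)
        aris = [
            float(adjusted_rand_score(outcomes[i], outcomes[j]))
            for i in range(len(seeds))
            for j in range(i + 1, len(seeds))
        ]
        report = StabilityReport(sub_id, seeds, aris)
        if report.median_ari < 0.5:
            logger.warning(
                "unstable embedding for %s: median pairwise ARI %.2f over %d seeds",
                sub_id,
                report.median_ari,
                n_seeds_audit,
            )
    return result, report


def auto_eps(coords: np.ndarray, min_samples: int = DEFAULT_MIN_SAMPLES) -> float:
    """Density-adaptive DBSCAN radius: twice the median distance to the
    ``min_samples``-th nearest neighbour (k-distance heuristic).

    A fixed radius only suits one point density; the embedding's density
    scales with cohort size, so smaller cohorts need a proportionally
    larger radius for the same connectivity.
    """
    from sklearn.neighbors import NearestNeighbors

    k = min(min_samples, len(coords) - 1)
    d, _ = NearestNeighbors(n_neighbors=k + 1).fit(coords).kneighbors(coords)
    return float(AUTO_EPS_FACTOR * np.median(d[:, -1]))


def density_cluster(
    embedding: EmbeddingResult,
    eps: float | str = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    max_cluster_size: int = DEFAULT_MAX_CLUSTER_SIZE,
) -> ClusterAssignment:
    """DBSCAN on the 2-D embedding with a cluster-size window.

    ``eps`` may be the string ``"auto"`` to use the k-distance heuristic
    (:func:`auto_eps`).  Clusters smaller than ``min_cluster_size`` or
    larger than ``max_cluster_size`` are relabeled noise.  Cluster labels
    are ``"<subdataset_id>:<k>"``.
    """
    if eps == "auto":
        eps = auto_eps(embedding.coords, min_samples)
    if not isinstance(eps, (int, float)) or eps <= 0:
        raise ValueError("eps must be positive or 'auto'")
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(embedding.coords)
    labels: dict[str, str] = {}
    sizes = {k: int((raw == k).sum()) for k in set(raw) if k != -1}
    for pid, k in zip(embedding.participant_ids, raw):
        if k == -1 or not (min_cluster_size <= sizes[k] <= max_cluster_size):
            labels[pid] = NOISE
        else:
            labels[pid] = f"{embedding.subdataset_id}:{k}"
    provenance = {
        f"{embedding.subdataset_id}:{k}": {
            "subdataset": embedding.subdataset_id,
            "seed": embedding.seed,
            "eps": eps,
            "min_samples": min_samples,
        }
        for k, size in sizes.items()
        if min_cluster_size <= size <= max_cluster_size
    }
    return ClusterAssignment(method="DIRAM", labels=labels, provenance=provenance)


# ---------------------------------------------------------------------------
# merging clusters found in different subdatasets


def _merge_score(
    c1: set[str], c2: set[str], universe1: set[str], universe2: set[str], denominator: str
) -> float | None:
    """Excess of observed over independence-expected overlap, normalised.

    Restricted to the shared participant universe; ``None`` when the shared
    universe is empty or either restricted cluster is."""
    shared = universe1 & universe2
    n = len(shared)
    if n == 0:
        return None
    a = c1 & shared
    b = c2 & shared
    if not a or not b:
        return None
    expected = len(a) * len(b) / n
    observed = len(a & b)
    if denominator == "min":
        denom = min(len(a), len(b))
    elif denominator == "union":
        denom = len(a | b)
    elif denominator == "geometric":
        denom = float(np.sqrt(len(a) * len(b)))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return (observed - expected) / denom


def merge_clusters(
    assignments: list[ClusterAssignment],
    overlap_margin: float = DEFAULT_MERGE_MARGIN,
    denominator: str = "min",
) -> ClusterAssignment:
    """Merge clusters from different subdatasets that contain largely the
    same participants.

    For clusters C1, C2 from different assignments, over the shared
    participant universe of size N, the expected overlap under independence
    is E = |C1|*|C2|/N; the pair is merged when
    ``(observed - E) / min(|C1|, |C2|) > overlap_margin`` (denominator
    configurable: ``min`` | ``union`` | ``geometric``).  Merging is
    transitive.  A participant claimed by several merged clusters is
    assigned to the one backed by the most source clusters (ties broken by
    label order).
    """
    clusters: list[tuple[int, str, set[str]]] = []  # (assignment idx, label, members)
    universes = [set(a.labels.keys()) for a in assignments]
    for ai, a in enumerate(assignments):
        for cid in a.cluster_ids:
            clusters.append((ai, cid, set(a.members(cid))))

    m = len(clusters)
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            ai, _, ci = clusters[i]
            aj, _, cj = clusters[j]
            if ai == aj:
                continue
            score = _merge_score(ci, cj, universes[ai], universes[aj], denominator)
            if score is None:
                logger.warning(
                    "empty shared universe or empty restricted cluster for "
                    "%s / %s; pair skipped",
                    clusters[i][1],
                    clusters[j][1],
                )
                continue
            if score > overlap_margin:
                parent[find(i)] = find(j)

    components: dict[int, list[int]] = {}
    for i in range(m):
        components.setdefault(find(i), []).append(i)

    labels: dict[str, str] = {}
    claim_count: dict[str, int] = {}
    provenance: dict[str, dict] = {}
    for k, comp in enumerate(sorted(components.values(), key=lambda c: min(clusters[i][1] for i in c))):
        label = f"A{k + 1}"
        sources = [clusters[i][1] for i in comp]
        provenance[label] = {
            "sources": sorted(sources),
            "subdatasets": sorted({assignments[clusters[i][0]].provenance.get(clusters[i][1], {}).get("subdataset", "?") for i in comp}),
        }
        votes: dict[str, int] = {}
        for i in comp:
            for pid in clusters[i][2]:
                votes[pid] = votes.get(pid, 0) + 1
        for pid, v in votes.items():
            if pid not in labels or v > claim_count[pid]:
                labels[pid] = label
                claim_count[pid] = v

    # participants seen by any subdataset but claimed by no cluster: noise
    for u in universes:
        for pid in u:
            labels.setdefault(pid, NOISE)
    return ClusterAssignment(method="DIRAM", labels=labels, provenance=provenance)


@dataclass
class DiramResult:
    assignment: ClusterAssignment
    grouping: MissingnessGrouping
    stability: list[StabilityReport] = field(default_factory=list)


def run_diram(
    matrix: ProteinMatrix,
    similarity_threshold: float = 0.5,
    eps: float | str = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    max_cluster_size: int = DEFAULT_MAX_CLUSTER_SIZE,
    merge_margin: float = DEFAULT_MERGE_MARGIN,
    seed: int = 1,
    n_seeds_audit: int = 0,
) -> DiramResult:
    """Full DIRAM pass: missingness grouping -> per-subdataset embedding and
    density clustering -> cross-subdataset merge.

    Degenerate missingness groups (too few retained participants to admit a
    cluster) are skipped with a log message.
    """
    grouping = group_by_missingness(
        matrix, similarity_threshold, min_group_participants=min_cluster_size
    )
    assignments: list[ClusterAssignment] = []
    stability: list[StabilityReport] = []
    for group in grouping.groups:
        if group.degenerate:
            logger.info("skipping degenerate missingness group %s", group.group_id)
            continue
        sub = extract_subdataset(matrix, group)
        sub.subdataset_id = group.group_id  # type: ignore[attr-defined]
        emb, rep = embed_2d(sub, seed=seed, n_seeds_audit=n_seeds_audit,
                            audit_eps=eps, audit_min_samples=min_samples)
        if rep is not None:
            stability.append(rep)
        assignments.append(
            density_cluster(emb, eps, min_samples, min_cluster_size, max_cluster_size)
        )
    if not assignments:
        raise ValueError("no usable missingness group")
    merged = merge_clusters(assignments, merge_margin)
    # participants never retained in any subdataset are noise
    for pid in matrix.participant_ids:
        merged.labels.setdefault(pid, NOISE)
    return DiramResult(assignment=merged, grouping=grouping, stability=stability)
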