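"""DIRCOD: iterated community detection with raw-data protein selection.

Missing values are first imputed by nearest-neighbour averaging.  Leiden
community detection then runs on a k-nearest-neighbour participant graph;
each detected community is contrasted against the rest of the population on
the *raw* (non-imputed) matrix with a two-sample Kolmogorov-Smirnov test per
protein, Bonferroni-corrected, and the proteins with significantly
different distributions in at least one community feed the next community
detection round.  The validation on raw data bounds the bias imputation
could introduce.  The iteration is not assumed to converge; after a fixed
number of rounds participants with similar patterns of community
assignment across rounds are grouped into final clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .containers import NOISE, ClusterAssignment, ProteinMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_NEIGHBORS = 15
DEFAULT_ITERATIONS = 20
DEFAULT_ALPHA = 0.05
DEFAULT_PATTERN_THRESHOLD = 0.9
DEFAULT_MIN_CLUSTER_SIZE = 100
#: a (community, protein) selection test needs this many observed values
#: on each side to be meaningful
MIN_OBSERVED_PER_TEST = 20


@dataclass
class CommunityHistory:
    """State of one DIRCOD iteration: the proteins the community detection
    ran on and the resulting participant -> community labels."""

    iteration: int
    selected_proteins: list[str]
    community_of: dict[str, int]


def impute_knn(
    matrix: ProteinMatrix, n_neighbors: int = DEFAULT_N_NEIGHBORS
) -> ProteinMatrix:
    """Nearest-neighbour imputation of missing entries.

    Each missing cell is replaced by the mean of that protein over the
    ``n_neighbors`` nearest participants that observed it.  Distances are
    Euclidean over all proteins, with missing cells mean-filled for the
    distance computation only.  Observed entries are unchanged; the output
    mask is all-True.

    Raises
    ------
    ValueError
        If some protein is observed in fewer than ``n_neighbors``
        participants (naming it).
    """
    if matrix.is_complete():
        return ProteinMatrix(
            matrix.participant_ids,
            matrix.protein_ids,
            matrix.values.copy(),
            np.ones_like(matrix.mask),
        )
    obs_per_protein = matrix.mask.sum(axis=0)
    bad = np.flatnonzero(obs_per_protein < n_neighbors)
    if bad.size:
        raise ValueError(
            f"protein {matrix.protein_ids[bad[0]]!r} observed in only "
            f"{obs_per_protein[bad[0]]} participants (< {n_neighbors})"
        )

    filled = matrix.values.copy()
    col_means = np.nanmean(matrix.values, axis=0)
    miss_r, miss_c = np.nonzero(~matrix.mask)
    filled[miss_r, miss_c] = col_means[miss_c]

    n_query = min(
        matrix.n_participants, 4 * n_neighbors + 1
    )  # headroom: neighbours missing the target protein are skipped
    nn = NearestNeighbors(n_neighbors=n_query).fit(filled)
    _, idx = nn.kneighbors(filled)

    out = filled.copy()
    for i in np.unique(miss_r):
        cols = miss_c[miss_r == i]
        neigh = idx[i][idx[i] != i]
        for j in cols:
            donors = neigh[matrix.mask[neigh, j]][:n_neighbors]
            if donors.size == 0:  # fall back to the column mean
                out[i, j] = col_means[j]
            else:
                out[i, j] = matrix.values[donors, j].mean()
    return ProteinMatrix(
        matrix.participant_ids,
        matrix.protein_ids,
        out,
        np.ones_like(matrix.mask),
    )


def detect_communities(
    matrix: ProteinMatrix,
    selected: list[str] | None = None,
    resolution: float = 1.0,
    seed: int = 0,
    k: int = 15,
) -> dict[str, int]:
    """Leiden communities on a k-nearest-neighbour participant graph.

    The graph connects each participant to its ``k`` nearest neighbours
    (Euclidean distance on the selected-protein submatrix, which must be
    complete) and is partitioned by Leiden modularity (RB configuration,
    resolution 1.0 by default).  Deterministic for a fixed seed.
    """
    if selected is not None and len(selected) == 0:
        raise ValueError("selected protein subset is empty")
    sub = matrix.subset(proteins=selected) if selected is not None else matrix
    if not sub.is_complete():
        raise ValueError("matrix must be complete on the selected proteins")
    n = sub.n_participants
    if n < k + 1:
        logger.warning("only %d participants for k=%d graph; single community", n, k)
        return {p: 0 for p in sub.participant_ids}
    nn = NearestNeighbors(n_neighbors=k + 1).fit(sub.values)
    _, idx = nn.kneighbors(sub.values)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i][1:]}
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return {p: int(m) for p, m in zip(sub.participant_ids, part.membership)}


def select_differential_proteins(
    raw: ProteinMatrix,
    communities: dict[str, int],
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Proteins whose raw-value distribution differs inside at least one
    community versus the rest of the population.

    Per (community, protein) pair a two-sample Kolmogorov-Smirnov test on
    observed (non-missing) values inside vs outside the community;
    Bonferroni correction over all pairs actually tested.  Pairs with
    fewer than :data:`MIN_OBSERVED_PER_TEST` observed values on either
    side are skipped.
    """
    comm_labels = sorted(set(communities.values()))
    pvals: list[tuple[float, int]] = []  # (raw p, protein index)
    in_comm = {
        c: np.asarray([communities.get(p) == c for p in raw.participant_ids])
        for c in comm_labels
    }
    for j in range(raw.n_proteins):
        col = raw.values[:, j]
        obs = raw.mask[:, j]
        for c in comm_labels:
            inside = col[obs & in_comm[c]]
            outside = col[obs & ~in_comm[c]]
            if inside.size < MIN_OBSERVED_PER_TEST or outside.size < MIN_OBSERVED_PER_TEST:
                logger.debug(
                    "skipping KS test for protein %s, community %s: too few values",
                    raw.protein_ids[j],
                    c,
                )
                continue
            # exact null distribution where it is cheap and matters most;
            # the asymptotic one is accurate at the larger sizes
            method = "exact" if min(inside.size, outside.size) <= 250 else "asymp"
            p = stats.ks_2samp(inside, outside, method=method).pvalue
            pvals.append((float(p), j))
    if not pvals:
        return []
    m = len(pvals)
    selected = sorted({j for p, j in pvals if p * m <= alpha})
    return [raw.protein_ids[j] for j in selected]


def iterate_dircod(
    matrix: ProteinMatrix,
    raw: ProteinMatrix,
    T: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    resolution: float = 1.0,
    k: int = 15,
) -> list[CommunityHistory]:
    """Alternate community detection (on the imputed matrix restricted to
    the current protein subset) and differential-protein selection (on the
    raw matrix), recording every iteration.

    Iteration 1 uses all proteins; iteration t+1 uses exactly the proteins
    selected at iteration t.  If selection ever empties the subset the
    iteration stops early and returns the history so far.  No convergence
    is assumed.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if matrix.participant_ids != raw.participant_ids or matrix.protein_ids != raw.protein_ids:
        raise ValueError("imputed and raw matrices must share ids")
    history: list[CommunityHistory] = []
    selected = list(matrix.protein_ids)
    for t in range(1, T + 1):
        comm = detect_communities(
            matrix, selected, resolution=resolution, seed=seed + t, k=k
        )
        history.append(CommunityHistory(t, list(selected), comm))
        if t == T:
            break
        new_selected = select_differential_proteins(raw, comm, alpha=alpha)
        if not new_selected:
            logger.warning(
                "protein selection empty after iteration %d; stopping early", t
            )
            break
        selected = new_selected
    return history


def assign_by_pattern(
    history: list[CommunityHistory],
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    pattern_threshold: float = DEFAULT_PATTERN_THRESHOLD,
) -> ClusterAssignment:
    """Group participants with similar patterns of community assignment.

    The co-assignment similarity of two participants is the fraction of
    iterations in which they share a community.  Participants are linked
    when similarity >= ``pattern_threshold`` (1.0 = identical patterns) and
    final clusters are the connected components of that graph; components
    smaller than ``min_cluster_size`` become noise.  Community labels are
    never matched across iterations — only co-membership matters.
    """
    if not history:
        raise ValueError("empty history")
    participants = list(history[0].community_of.keys())
    n = len(participants)
    T = len(history)
    lab = np.empty((T, n), dtype=int)
    for t, h in enumerate(history):
        lab[t] = [h.community_of[p] for p in participants]
    co = np.zeros((n, n), dtype=np.int32)
    for t in range(T):
        co += lab[t][:, None] == lab[t][None, :]
    sim = co / T

    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix(sim >= pattern_threshold)
    n_comp, comp = connected_components(adj, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    # stable labels: order components by size (desc), then first member
    order = sorted(
        (k for k in range(n_comp) if sizes[k] >= min_cluster_size),
        key=lambda k: (-sizes[k], int(np.argmax(comp == k))),
    )
    relabel = {k: f"B{i + 1}" for i, k in enumerate(order)}
    labels = {
        p: relabel.get(comp[i], NOISE) for i, p in enumerate(participants)
    }
    provenance = {
        lbl: {"iterations": T, "pattern_threshold": pattern_threshold, "size": int(sizes[k])}
        for k, lbl in relabel.items()
    }
    return ClusterAssignment(method="DIRCOD", labels=labels, provenance=provenance)


@dataclass
class DircodResult:
    assignment: ClusterAssignment
    history: list[CommunityHistory]


def run_dircod(
    matrix: ProteinMatrix,
    T: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    pattern_threshold: float = DEFAULT_PATTERN_THRESHOLD,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    resolution: float = 1.0,
) -> DircodResult:
    """Full DIRCOD pass: impute -> iterate detection/selection -> pattern
    assignment.  The raw matrix is kept for every selection step."""
    imputed = impute_knn(matrix, n_neighbors=n_neighbors)
    history = iterate_dircod(
        imputed, matrix, T=T, seed=seed, alpha=alpha, k=n_neighbors
    )
    assignment = assign_by_pattern(
        history, min_cluster_size=min_cluster_size, pattern_threshold=pattern_threshold
    )
    return DircodResult(assignment=assignment, history=history)
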