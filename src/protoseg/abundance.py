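"""Quartile-based high/low abundance calls per (cluster, protein).

A protein is called *high* in a cluster when the cluster's 25th percentile
(its bottom quartile boundary) strictly exceeds the 75th percentile of the
rest of the population — i.e. the top three quartiles inside the cluster
all lie above the comparison population's top quartile.  *Low* is the
mirror image.  This deliberately conservative rule trades sensitivity for
robustness: no distributional assumption, no p-value, and near-boundary
ties yield no call.

Percentiles use linear interpolation between closest ranks; the convention
is fixed because verdicts near the boundary depend on it.  Missing values
are excluded, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .containers import ProteinMatrix

Verdict = Literal["high", "low", "none"]

DEFAULT_MIN_OBSERVED = 20


@dataclass
class AbundanceCall:
    cluster_id: str
    protein_id: str
    verdict: Verdict
    q1_in: float
    q3_in: float
    q1_out: float
    q3_out: float
    n_in: int
    n_out: int
    insufficient_data: bool = False


def call_abundance(
    matrix: ProteinMatrix,
    cluster: Sequence[str],
    protein: str,
    min_observed: int = DEFAULT_MIN_OBSERVED,
    cluster_id: str = "cluster",
) -> AbundanceCall:
    """Quartile verdict for one protein in one cluster vs everyone else.

    ``high`` iff q1(inside) > q3(outside); ``low`` iff q3(inside) <
    q1(outside); strict inequalities; otherwise ``none``.  When either side
    has fewer than ``min_observed`` observed values the verdict is ``none``
    with ``insufficient_data`` set.
    """
    cluster_set = set(cluster)
    if not cluster_set:
        raise ValueError("empty cluster")
    outside = [p for p in matrix.participant_ids if p not in cluster_set]
    if not outside:
        raise ValueError("cluster must be a strict subset of participants")
    inside_vals = matrix.observed_values(protein, list(cluster))
    outside_vals = matrix.observed_values(protein, outside)

    if inside_vals.size < min_observed or outside_vals.size < min_observed:
        nan = float("nan")
        return AbundanceCall(
            cluster_id, protein, "none", nan, nan, nan, nan,
            int(inside_vals.size), int(outside_vals.size), insufficient_data=True,
        )

    q1_in, q3_in = np.percentile(inside_vals, [25, 75], method="linear")
    q1_out, q3_out = np.percentile(outside_vals, [25, 75], method="linear")
    if q1_in > q3_out:
        verdict: Verdict = "high"
    elif q3_in < q1_out:
        verdict = "low"
    else:
        verdict = "none"
    return AbundanceCall(
        cluster_id, protein, verdict,
        float(q1_in), float(q3_in), float(q1_out), float(q3_out),
        int(inside_vals.size), int(outside_vals.size),
    )


def call_abundance_all(
    matrix: ProteinMatrix,
    clusters: Mapping[str, Sequence[str]],
    min_observed: int = DEFAULT_MIN_OBSERVED,
) -> list[AbundanceCall]:
    """All (cluster, protein) abundance calls, long format."""
    return [
        call_abundance(matrix, members, prot, min_observed, cluster_id=cid)
        for cid, members in clusters.items()
        for prot in matrix.protein_ids
    ]


def common_signature(
    calls: Iterable[AbundanceCall],
    clusters: Sequence[str],
    direction: Literal["high", "low"],
    tolerance: int = 0,
) -> list[str]:
    """Proteins carrying the stated verdict in all the given clusters, or in
    all but at most ``tolerance`` of them.

    ``tolerance=1`` supports the differential-correlation analysis, which
    admits proteins present in all considered clusters or all but one.
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    wanted = set(clusters)
    hits: dict[str, set[str]] = {}
    for call in calls:
        if call.cluster_id in wanted and call.verdict == direction:
            hits.setdefault(call.protein_id, set()).add(call.cluster_id)
    need = len(wanted) - tolerance
    return sorted(p for p, cs in hits.items() if len(cs) >= need)
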