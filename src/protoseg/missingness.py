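"""Grouping proteins by similarity of their missing-value patterns.

Large multiplex panels miss values in blocks: proteins measured on the same
plate or delivery batch tend to be missing for the same participants.  The
density-clustering path exploits this by grouping proteins whose missing
masks are identical or similar, then dropping the few participants with any
missing value inside each group, yielding complete ("no loss of
information") subdatasets.

Similarity between two proteins is the Jaccard index of their sets of
missing participants; grouping is single-linkage at a threshold (exact for
the identical-mask case, transitive for chains of similar masks).  Proteins
with no missing value at all form one shared fully-observed group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ProteinMatrix

FULLY_OBSERVED_GROUP = "G_complete"

#: admissible clusters need at least this many participants, so smaller
#: subdatasets cannot contribute and are flagged degenerate
DEFAULT_MIN_GROUP_PARTICIPANTS = 100


@dataclass
class MissingnessGroup:
    group_id: str
    protein_ids: list[str]
    retained_participants: list[str]
    degenerate: bool = False


@dataclass
class MissingnessGrouping:
    """Partition of proteins by missing-mask similarity.

    ``groups`` partition the proteins having at least one observed value;
    ``discarded_proteins`` lists all-missing proteins, which are never
    grouped.
    """

    groups: list[MissingnessGroup]
    discarded_proteins: list[str] = field(default_factory=list)

    def group_of(self, protein_id: str) -> MissingnessGroup:
        for g in self.groups:
            if protein_id in g.protein_ids:
                return g
        raise KeyError(protein_id)


def _jaccard_linkage(missing_sets: list[set[int]], threshold: float) -> list[list[int]]:
    """Single-linkage components of proteins with Jaccard(missing sets)
    >= threshold (union-find over the pairwise similarity graph)."""
    m = len(missing_sets)
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            a, b = missing_sets[i], missing_sets[j]
            inter = len(a & b)
            if inter == 0:
                continue
            jac = inter / (len(a) + len(b) - inter)
            if jac >= threshold:
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(m):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def group_by_missingness(
    matrix: ProteinMatrix,
    similarity_threshold: float = 0.5,
    min_group_participants: int = DEFAULT_MIN_GROUP_PARTICIPANTS,
) -> MissingnessGrouping:
    """Partition proteins by Jaccard similarity of their missing masks.

    Proteins with no missing entries form the single group
    :data:`FULLY_OBSERVED_GROUP`; all-missing proteins go to the discard
    list.  Within each group, participants with any missing value on the
    group's proteins are dropped; groups retaining fewer than
    ``min_group_participants`` participants are flagged ``degenerate``.
    """
    if matrix.n_participants == 0 or matrix.n_proteins == 0:
        raise ValueError("empty matrix")
    if not 0 <= similarity_threshold <= 1:
        raise ValueError("similarity_threshold must be in [0, 1]")

    missing = ~matrix.mask
    n_missing = missing.sum(axis=0)
    complete_cols = np.flatnonzero(n_missing == 0)
    all_missing_cols = np.flatnonzero(n_missing == matrix.n_participants)
    partial_cols = np.flatnonzero(
        (n_missing > 0) & (n_missing < matrix.n_participants)
    )

    groups: list[MissingnessGroup] = []

    def build(group_id: str, cols: np.ndarray) -> MissingnessGroup:
        any_missing = missing[:, cols].any(axis=1)
        retained = [
            matrix.participant_ids[i] for i in np.flatnonzero(~any_missing)
        ]
        return MissingnessGroup(
            group_id=group_id,
            protein_ids=[matrix.protein_ids[j] for j in cols],
            retained_participants=retained,
            degenerate=len(retained) < min_group_participants,
        )

    if complete_cols.size:
        groups.append(build(FULLY_OBSERVED_GROUP, complete_cols))

    missing_sets = [set(np.flatnonzero(missing[:, j]).tolist()) for j in partial_cols]
    for gi, comp in enumerate(_jaccard_linkage(missing_sets, similarity_threshold)):
        groups.append(build(f"G{gi:03d}", partial_cols[np.asarray(comp)]))

    return MissingnessGrouping(
        groups=groups,
        discarded_proteins=[matrix.protein_ids[j] for j in all_missing_cols],
    )


def extract_subdataset(matrix: ProteinMatrix, group: MissingnessGroup) -> ProteinMatrix:
    """Dense, complete submatrix (group's retained participants x proteins);
    participant and protein order follow the source matrix."""
    if not group.retained_participants:
        raise ValueError(f"group {group.group_id} retains no participants")
    sub = matrix.subset(group.retained_participants, group.protein_ids)
    if not sub.is_complete():  # pragma: no cover - guards grouping bugs
        raise AssertionError(f"subdataset for {group.group_id} is not complete")
    return sub
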