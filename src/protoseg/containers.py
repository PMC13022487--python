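"""Core in-memory containers shared by every analysis stage.

A :class:`ProteinMatrix` is a participants x proteins matrix of continuous
abundances (NPX-like, i.e. roughly log-scale normal) with an explicit
boolean observation mask; entries where the mask is ``False`` are missing
and must be ignored by every consumer.  A :class:`PhenotypeTable` carries
per-participant age, sex and the set of 3-character ICD-10 diagnosis codes.
A :class:`ClusterAssignment` maps participants to cluster labels, with the
special label :data:`NOISE` for participants no cluster claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: label used for participants not assigned to any cluster
NOISE = "noise"


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ProteinMatrix:
    """Participants x proteins abundances with an explicit missingness mask.

    Parameters
    ----------
    participant_ids, protein_ids
        Ordered, duplicate-free identifier sequences.
    values
        ``(n_participants, n_proteins)`` float array.  Cells where ``mask``
        is ``False`` are missing; their stored value is irrelevant (NaN by
        convention) and never read by any analysis.
    mask
        Boolean array of the same shape, ``True`` = observed.
    """

    participant_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.participant_ids = list(self.participant_ids)
        self.protein_ids = list(self.protein_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (len(self.participant_ids), len(self.protein_ids))
        if self.values.shape != shape:
            raise ValueError(
                f"values shape {self.values.shape} != ids shape {shape}"
            )
        if self.mask.shape != shape:
            raise ValueError(f"mask shape {self.mask.shape} != ids shape {shape}")
        _check_unique(self.participant_ids, "participant")
        _check_unique(self.protein_ids, "protein")
        # normalise: masked cells hold NaN so accidental reads are loud
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan

    # -- basic geometry -------------------------------------------------
    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.n_participants, self.n_proteins

    def is_complete(self) -> bool:
        """True when every cell is observed."""
        return bool(self.mask.all())

    # -- indexing helpers ----------------------------------------------
    def participant_indexer(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.participant_ids)}
        try:
            return np.asarray([lookup[p] for p in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown participant {exc.args[0]!r}") from None

    def protein_indexer(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.protein_ids)}
        try:
            return np.asarray([lookup[p] for p in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown protein {exc.args[0]!r}") from None

    def subset(
        self,
        participants: Sequence[str] | None = None,
        proteins: Sequence[str] | None = None,
    ) -> "ProteinMatrix":
        """Submatrix restricted to the given identifiers, order preserved
        as given (or original order when ``None``)."""
        p_ids = list(participants) if participants is not None else self.participant_ids
        q_ids = list(proteins) if proteins is not None else self.protein_ids
        ri = self.participant_indexer(p_ids)
        ci = self.protein_indexer(q_ids)
        return ProteinMatrix(
            p_ids, q_ids, self.values[np.ix_(ri, ci)], self.mask[np.ix_(ri, ci)]
        )

    def observed_values(self, protein: str, participants: Sequence[str] | None = None) -> np.ndarray:
        """The observed (non-missing) values of one protein, optionally
        restricted to a participant subset."""
        ci = self.protein_indexer([protein])[0]
        col = self.values[:, ci]
        m = self.mask[:, ci]
        if participants is not None:
            ri = self.participant_indexer(participants)
            col, m = col[ri], m[ri]
        return col[m]

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view with NaN in missing cells."""
        return pd.DataFrame(
            self.values, index=self.participant_ids, columns=self.protein_ids
        )


@dataclass
class PhenotypeTable:
    """Per-participant age, sex and 3-character ICD-10 code sets.

    ``sex`` is a binary category stored as strings (e.g. ``"F"``/``"M"``);
    ``icd10_codes`` maps participant -> frozenset of normalized codes.
    The participant universe may differ from a ProteinMatrix's; joins are
    by intersection.
    """

    participant_ids: list[str]
    age: np.ndarray
    sex: np.ndarray
    icd10_codes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.participant_ids = list(self.participant_ids)
        _check_unique(self.participant_ids, "participant")
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=object)
        n = len(self.participant_ids)
        if self.age.shape != (n,) or self.sex.shape != (n,):
            raise ValueError("age/sex length must match participant_ids")
        if np.any(self.age < 0):
            raise ValueError("age must be nonnegative")
        self.icd10_codes = {
            p: frozenset(self.icd10_codes.get(p, frozenset()))
            for p in self.participant_ids
        }

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def has_code(self, code: str) -> np.ndarray:
        """Boolean vector (aligned to participant_ids): carries ``code``."""
        return np.asarray(
            [code in self.icd10_codes[p] for p in self.participant_ids], dtype=bool
        )

    def age_of(self, participants: Sequence[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.participant_ids)}
        return self.age[[lookup[p] for p in participants]]

    def sex_of(self, participants: Sequence[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.participant_ids)}
        return self.sex[[lookup[p] for p in participants]]


@dataclass
class ClusterAssignment:
    """Participant -> cluster label map with provenance.

    ``method`` names the producing pipeline (``"DIRAM"``, ``"DIRCOD"``, or
    anything else for ad-hoc assignments).  ``provenance`` records, per
    cluster label, where the cluster came from (source subdatasets,
    iteration trail, parameters) as free-form mappings.
    """

    method: str
    labels: dict[str, str]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = dict(self.labels)

    @property
    def cluster_ids(self) -> list[str]:
        """Sorted non-noise cluster labels."""
        return sorted({l for l in self.labels.values() if l != NOISE})

    def members(self, cluster_id: str) -> list[str]:
        return [p for p, l in self.labels.items() if l == cluster_id]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for l in self.labels.values():
            if l != NOISE:
                out[l] = out.get(l, 0) + 1
        return out

    def label_vector(self, participants: Sequence[str]) -> np.ndarray:
        """Labels aligned to ``participants`` (noise for absentees)."""
        return np.asarray(
            [self.labels.get(p, NOISE) for p in participants], dtype=object
        )

    def merged_members(self, cluster_ids: Iterable[str]) -> list[str]:
        """Union of several clusters' member lists (pooled cluster)."""
        wanted = set(cluster_ids)
        return [p for p, l in self.labels.items() if l in wanted]
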