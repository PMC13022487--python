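"""Delimited-text readers/writers and ICD-10 normalization.

Matrix files are wide delimited text (TSV by default): first row is the
protein header, first column the participant ID, empty cells or a
configurable sentinel (``"NA"`` by default) denote missing values.  All
outputs written by this package carry provenance header lines starting
with ``'#'``; readers skip such lines.
"""

from __future__ import annotations

import csv
import io as _io
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ClusterAssignment, PhenotypeTable, ProteinMatrix

#: cell contents treated as missing on read (case-sensitive), besides ""
DEFAULT_MISSING_SENTINELS = ("", "NA", "NaN", "nan")

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}$")


def normalize_icd10(raw_code: str) -> str:
    """Normalize an ICD-10 code to its 3-character category.

    Strips whitespace and any dot-suffix (``"K90.0" -> "K90"``), uppercases,
    and truncates to the leading letter plus two digits.  Idempotent.

    Raises
    ------
    ValueError
        If the cleaned code is shorter than 3 characters or does not match
        the letter-digit-digit pattern.
    """
    if not raw_code or not raw_code.strip():
        raise ValueError("empty ICD-10 code")
    code = raw_code.strip().upper().split(".")[0]
    code = code[:3]
    if len(code) < 3:
        raise ValueError(f"ICD-10 code too short after cleaning: {raw_code!r}")
    if not _ICD10_RE.match(code):
        raise ValueError(f"malformed ICD-10 code: {raw_code!r}")
    return code


def apply_icd10_grouping(code: str, grouping: Mapping[str, str] | None) -> str:
    """Map a normalized 3-character code through an optional user-supplied
    super-category grouping; codes absent from the mapping pass through."""
    if grouping is None:
        return code
    return grouping.get(code, code)


def read_icd10_grouping(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Two-column file (code, group) -> dict; '#' lines skipped."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if not row or row[0].startswith("#"):
                continue
            out[normalize_icd10(row[0])] = row[1].strip()
    return out


# ---------------------------------------------------------------------------
# protein matrices


def read_protein_matrix(
    path: str | Path,
    delimiter: str = "\t",
    missing_sentinels: Sequence[str] = DEFAULT_MISSING_SENTINELS,
) -> ProteinMatrix:
    """Read a wide participants x proteins abundance table.

    First row: protein header (first cell is the participant-ID column
    name, ignored).  Empty cells or any listed sentinel become missing.
    Row and column order are preserved from the file.

    Raises
    ------
    ValueError
        On duplicate participant or protein identifiers (naming the
        duplicate) and on non-numeric non-missing cells (naming row and
        column).
    """
    sentinels = set(missing_sentinels) | {""}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delimiter) if r and not r[0].startswith("#")]
    if not rows:
        raise ValueError(f"empty matrix file: {path}")
    header = [h.strip() for h in rows[0][1:]]
    seen: set[str] = set()
    for h in header:
        if h in seen:
            raise ValueError(f"duplicate protein header: {h!r}")
        seen.add(h)
    participant_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(header)), dtype=float)
    mask = np.ones_like(values, dtype=bool)
    seen_p: set[str] = set()
    for i, row in enumerate(rows[1:]):
        pid = row[0].strip()
        if pid in seen_p:
            raise ValueError(f"duplicate participant identifier: {pid!r}")
        seen_p.add(pid)
        participant_ids.append(pid)
        cells = row[1:]
        if len(cells) != len(header):
            raise ValueError(f"row {pid!r} has {len(cells)} cells, expected {len(header)}")
        for j, cell in enumerate(cells):
            c = cell.strip()
            if c in sentinels:
                values[i, j] = np.nan
                mask[i, j] = False
            else:
                try:
                    values[i, j] = float(c)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell at participant {pid!r}, protein {header[j]!r}: {cell!r}"
                    ) from None
    return ProteinMatrix(participant_ids, header, values, mask)


def write_protein_matrix(
    matrix: ProteinMatrix,
    path: str | Path,
    delimiter: str = "\t",
    missing_repr: str = "",
    header_comment: str | None = None,
) -> None:
    """Write a matrix as wide delimited text; missing cells as ``missing_repr``."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["participant_id", *matrix.protein_ids])
        for i, pid in enumerate(matrix.participant_ids):
            row = [pid]
            for j in range(matrix.n_proteins):
                row.append(repr(float(matrix.values[i, j])) if matrix.mask[i, j] else missing_repr)
            w.writerow(row)


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(
    path: str | Path,
    delimiter: str = "\t",
    icd10_grouping: Mapping[str, str] | None = None,
) -> PhenotypeTable:
    """Read a phenotype table: columns participant_id, age, sex, icd10.

    ``icd10`` is a semicolon-separated list of raw codes; each is
    normalized to 3 characters and optionally mapped through a grouping.
    """
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str).fillna("")
    required = {"participant_id", "age", "sex", "icd10"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {sorted(missing)}")
    codes: dict[str, frozenset[str]] = {}
    for pid, raw in zip(df["participant_id"], df["icd10"]):
        cs = frozenset(
            apply_icd10_grouping(normalize_icd10(c), icd10_grouping)
            for c in raw.split(";")
            if c.strip()
        )
        codes[pid] = cs
    return PhenotypeTable(
        list(df["participant_id"]),
        df["age"].astype(float).to_numpy(),
        df["sex"].to_numpy(dtype=object),
        codes,
    )


def write_phenotypes(table: PhenotypeTable, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["participant_id", "age", "sex", "icd10"])
        for i, pid in enumerate(table.participant_ids):
            w.writerow(
                [pid, repr(float(table.age[i])), table.sex[i], ";".join(sorted(table.icd10_codes[pid]))]
            )


# ---------------------------------------------------------------------------
# cluster assignments


def write_assignments(
    assignment: ClusterAssignment, path: str | Path, delimiter: str = "\t"
) -> None:
    """Two-column (participant_id, cluster_label) file, sorted by
    participant ID, with a '#' provenance header recording the method."""
    if not assignment.labels:
        raise ValueError("empty assignment")
    with open(path, "w", newline="") as fh:
        fh.write(f"# protoseg cluster assignment; method={assignment.method}\n")
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["participant_id", "cluster_label"])
        for pid in sorted(assignment.labels):
            w.writerow([pid, assignment.labels[pid]])


def read_assignments(path: str | Path, delimiter: str = "\t") -> ClusterAssignment:
    method = "unknown"
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if not row:
                continue
            if row[0].startswith("#"):
                m = re.search(r"method=(\S+)", row[0])
                if m:
                    method = m.group(1)
                continue
            if row[0] == "participant_id":
                continue
            labels[row[0]] = row[1]
    if not labels:
        raise ValueError(f"no assignments in {path}")
    return ClusterAssignment(method=method, labels=labels)
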