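"""Cluster recreation: percentile slicing of the whole population on a
protein signature, with odds-ratio curves and leave-one-out contributions.

The participants of the disease-associated clusters are pooled into a
single reference cluster.  For each protein in the signature and each
percentile on a grid, the threshold is that percentile of the protein's
observed values *inside the pooled cluster*; the whole population is then
filtered (value >= threshold for high-direction proteins, <= for low) and
the odds ratio of the disease in the selected vs unselected population is
reported.  Omitting one protein at a time quantifies its contribution: the
selection can only grow, and the change in the odds-ratio curve reflects
how much that protein's threshold was doing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._stats import OddsRatio, odds_ratio
from .containers import PhenotypeTable, ProteinMatrix

logger = logging.getLogger(__name__)

Direction = Literal["high", "low"]
#: a (protein, direction) pair
SignatureItem = tuple[str, Direction]

DEFAULT_PERCENTILE_GRID = tuple(range(5, 100, 5))


@dataclass
class PercentilePoint:
    percentile: float
    selected_n: int
    cases_in: int
    cases_out: int
    odds: OddsRatio


@dataclass
class RecreationCurve:
    disease_code: str
    signature: list[SignatureItem]
    points: list[PercentilePoint]
    #: protein omitted to produce this curve, None for the full signature
    omitted: str | None = None

    @property
    def percentiles(self) -> list[float]:
        return [pt.percentile for pt in self.points]

    def odds_ratios(self) -> list[float]:
        return [pt.odds.value for pt in self.points]


def signature_thresholds(
    matrix: ProteinMatrix,
    pooled_cluster: Sequence[str],
    signature: Sequence[SignatureItem],
    percentile: float,
) -> dict[str, float]:
    """Per-protein cutoffs: the given percentile of each signature protein's
    observed values inside the pooled cluster (linear interpolation).

    Selection semantics downstream: ``high`` keeps value >= threshold,
    ``low`` keeps value <= threshold.
    """
    if not pooled_cluster:
        raise ValueError("empty pooled cluster")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    out: dict[str, float] = {}
    for protein, _ in signature:
        vals = matrix.observed_values(protein, list(pooled_cluster))
        if vals.size == 0:
            raise ValueError(f"protein {protein!r} unobserved in pooled cluster")
        out[protein] = float(np.percentile(vals, percentile, method="linear"))
    return out


def select_population(
    matrix: ProteinMatrix,
    signature: Sequence[SignatureItem],
    thresholds: dict[str, float],
    conjunctive: bool = True,
) -> np.ndarray:
    """Boolean selection vector over ``matrix.participant_ids``.

    Conjunctive (default): a participant is selected when every signature
    protein is observed and passes its threshold.  Disjunctive: when at
    least one observed protein passes.  Participants missing a needed
    protein value cannot satisfy that protein's filter.
    """
    n = matrix.n_participants
    if conjunctive:
        keep = np.ones(n, dtype=bool)
    else:
        keep = np.zeros(n, dtype=bool)
    for protein, direction in signature:
        j = matrix.protein_indexer([protein])[0]
        col, obs = matrix.values[:, j], matrix.mask[:, j]
        with np.errstate(invalid="ignore"):
            passes = (
                (col >= thresholds[protein])
                if direction == "high"
                else (col <= thresholds[protein])
            )
        passes &= obs
        keep = (keep & passes) if conjunctive else (keep | passes)
    return keep


def recreate(
    matrix: ProteinMatrix,
    phenotypes: PhenotypeTable,
    pooled_cluster: Sequence[str],
    signature: Sequence[SignatureItem],
    disease_code: str,
    percentile_grid: Sequence[float] = DEFAULT_PERCENTILE_GRID,
    conjunctive: bool = True,
    drop_missing: bool = False,
) -> RecreationCurve:
    """Odds-ratio curve of the disease in the percentile-sliced population.

    At each percentile the thresholds are defined on the pooled cluster and
    applied to the whole population.  Participants missing a signature
    value count as unselected (default) or are dropped from the 2x2 table
    entirely (``drop_missing=True``).  The odds ratio carries a Woolf 95%
    CI with Haldane-Anscombe correction for zero cells; a percentile with
    no selected participant yields an undefined (flagged) odds ratio.
    """
    common = [p for p in matrix.participant_ids if p in set(phenotypes.participant_ids)]
    sick_all = dict(zip(phenotypes.participant_ids, phenotypes.has_code(disease_code)))
    sick = np.asarray([sick_all[p] for p in common], dtype=bool)
    keep_idx = matrix.participant_indexer(common)

    fully_observed = np.ones(len(common), dtype=bool)
    for protein, _ in signature:
        j = matrix.protein_indexer([protein])[0]
        fully_observed &= matrix.mask[keep_idx, j]

    points: list[PercentilePoint] = []
    for pct in percentile_grid:
        thr = signature_thresholds(matrix, pooled_cluster, signature, pct)
        selected = select_population(matrix, signature, thr, conjunctive)[keep_idx]
        if drop_missing:
            in_table = fully_observed
        else:
            in_table = np.ones(len(common), dtype=bool)
        sel, sick_t = selected[in_table], sick[in_table]
        a = int((sel & sick_t).sum())
        b = int((sel & ~sick_t).sum())
        c = int((~sel & sick_t).sum())
        d = int((~sel & ~sick_t).sum())
        orr = odds_ratio(a, b, c, d)
        if not orr.defined:
            logger.warning(
                "odds ratio undefined at percentile %s for %s (empty margin)",
                pct,
                disease_code,
            )
        points.append(PercentilePoint(float(pct), a + b, a, c, orr))
    return RecreationCurve(disease_code, list(signature), points)


def leave_one_out(
    matrix: ProteinMatrix,
    phenotypes: PhenotypeTable,
    pooled_cluster: Sequence[str],
    signature: Sequence[SignatureItem],
    disease_code: str,
    percentile_grid: Sequence[float] = DEFAULT_PERCENTILE_GRID,
    conjunctive: bool = True,
) -> dict[str, RecreationCurve]:
    """Rerun the recreation once per omitted signature protein.

    Dropping a protein removes one conjunctive constraint, so every
    selection set is a superset of the full-signature selection; the
    difference between the curves is the omitted protein's contribution.
    """
    if len(signature) < 2:
        raise ValueError("leave-one-out needs a signature of length >= 2")
    out: dict[str, RecreationCurve] = {}
    for omit, _ in signature:
        reduced = [s for s in signature if s[0] != omit]
        curve = recreate(
            matrix, phenotypes, pooled_cluster, reduced, disease_code,
            percentile_grid, conjunctive,
        )
        curve.omitted = omit
        out[omit] = curve
    return out


def delta_or(
    full: RecreationCurve, loo: dict[str, RecreationCurve]
) -> dict[str, list[float]]:
    """Per-protein (omitted-curve OR minus full-signature OR) at each
    percentile; NaN where either is undefined."""
    base = np.asarray(full.odds_ratios(), dtype=float)
    return {
        prot: list(np.asarray(curve.odds_ratios(), dtype=float) - base)
        for prot, curve in loo.items()
    }
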