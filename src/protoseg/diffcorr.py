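"""Differential coregulation analysis.

For a disease-associated group of participants and a screened protein
subset, two Pearson correlation matrices are computed on non-imputed,
pairwise-complete observations: A inside the group, B over all other
participants.  The object of interest is delta = A - B: positive entries
mark protein pairs more tightly coregulated inside the group, negative
entries a loss of coregulation.  A Bonferroni critical correlation for the
relevant sample size says which |r| would be individually significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ProteinMatrix

logger = logging.getLogger(__name__)

DEFAULT_R_KEEP = 0.8
DEFAULT_MIN_PAIRS = 30


@dataclass
class DiffCorrResult:
    proteins: list[str]
    matrix_in: np.ndarray  # A
    matrix_out: np.ndarray  # B
    delta: np.ndarray  # A - B, NaN where masked
    n_in: np.ndarray  # per-pair observed counts inside
    n_out: np.ndarray
    critical_r_in: float
    critical_r_out: float
    masked_pairs: list[tuple[str, str]]


def _pairwise_corr(
    sub: ProteinMatrix, method: str = "pearson"
) -> tuple[np.ndarray, np.ndarray]:
    """(correlation matrix, per-pair observation counts) on
    pairwise-complete observed values."""
    df = sub.to_frame()
    corr = df.corr(method=method, min_periods=2).to_numpy()
    obs = sub.mask.astype(int)
    counts = obs.T @ obs
    return corr, counts


def prefilter_proteins(
    matrix: ProteinMatrix,
    candidates: Sequence[str],
    population: Sequence[str],
    r_keep: float = DEFAULT_R_KEEP,
    method: str = "pearson",
) -> list[str]:
    """Keep candidates correlated (|r| >= ``r_keep``) with at least one
    other candidate on the stated population; discard the rest.

    This screens a common-signature protein list down to the coregulated
    core before the differential-correlation step.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate proteins")
    sub = matrix.subset(list(population), candidates)
    corr, _ = _pairwise_corr(sub, method)
    np.fill_diagonal(corr, np.nan)
    with np.errstate(invalid="ignore"):
        keep = np.nanmax(np.abs(corr), axis=1) >= r_keep
    return [p for p, k in zip(candidates, keep) if k]


def differential_correlation(
    matrix: ProteinMatrix,
    group: Sequence[str],
    proteins: Sequence[str],
    min_pairs: int = DEFAULT_MIN_PAIRS,
    alpha: float = 0.05,
    method: str = "pearson",
) -> DiffCorrResult:
    """delta = corr(inside group) - corr(rest), per protein pair.

    Pearson (default) on pairwise-complete observed values.  Pairs with
    fewer than ``min_pairs`` observations on either side — including pairs
    involving a protein that is constant on one side — are masked (NaN in
    delta) and reported.  Critical correlations are Bonferroni thresholds
    at the median per-pair sample size of each side.
    """
    proteins = list(proteins)
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    group = list(group)
    group_set = set(group)
    rest = [p for p in matrix.participant_ids if p not in group_set]
    if not group or not rest:
        raise ValueError("group must be a nonempty strict subset of participants")

    sub_in = matrix.subset(group, proteins)
    sub_out = matrix.subset(rest, proteins)
    A, n_in = _pairwise_corr(sub_in, method)
    B, n_out = _pairwise_corr(sub_out, method)

    k = len(proteins)
    masked: list[tuple[str, str]] = []
    for i in range(k):
        for j in range(i + 1, k):
            bad = (
                n_in[i, j] < min_pairs
                or n_out[i, j] < min_pairs
                or not np.isfinite(A[i, j])
                or not np.isfinite(B[i, j])
            )
            if bad:
                masked.append((proteins[i], proteins[j]))
                A[i, j] = A[j, i] = np.nan
                B[i, j] = B[j, i] = np.nan
    if masked:
        logger.info("masked %d under-observed or degenerate pairs", len(masked))
    np.fill_diagonal(A, 1.0)
    np.fill_diagonal(B, 1.0)
    delta = A - B

    m_tests = k * (k - 1) // 2
    iu = np.triu_indices(k, 1)

    def _crit(counts: np.ndarray) -> float:
        med = int(np.median(counts[iu]))
        if med < 4:
            return float("nan")
        return critical_correlation(med, alpha, m_tests)

    return DiffCorrResult(
        proteins=proteins,
        matrix_in=A,
        matrix_out=B,
        delta=delta,
        n_in=n_in,
        n_out=n_out,
        critical_r_in=_crit(n_in),
        critical_r_out=_crit(n_out),
        masked_pairs=masked,
    )


def critical_correlation(n: int, alpha: float = 0.05, m_tests: int = 1) -> float:
    """Smallest |r| significant at family-wise level ``alpha`` after
    Bonferroni correction over ``m_tests`` pairs, for sample size ``n``.

    Inverts the t-transform t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of
    freedom: r* = t*/sqrt(t*^2 + n - 2) with t* the two-sided
    alpha/m_tests critical value.  Strictly decreasing in n, strictly
    increasing in m_tests.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    a = alpha / m_tests
    if not 0 < a < 1:
        raise ValueError(f"alpha/m_tests = {a} outside (0, 1)")
    t = stats.t.ppf(1 - a / 2, df=n - 2)
    return float(t / np.sqrt(t * t + n - 2))
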