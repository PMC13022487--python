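"""Principal-axis prevalence gradients.

A disease signature's protein concentrations are collapsed to a single
coordinate: the first principal axis of the signature submatrix, fitted on
the participants of the disease-associated clusters.  The same transform is
then applied to a target population (typically everyone), participants are
binned into equal-size groups by their axis coordinate, and per-bin disease
prevalence is related to bin position by ordinary least squares —
optionally excluding the extreme bins, whose prevalences are noisiest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .containers import PhenotypeTable, ProteinMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 20


@dataclass
class AxisTransform:
    proteins: list[str]
    loadings: np.ndarray
    center: np.ndarray
    scale: np.ndarray  # all-ones when standardization is off
    fitted_on: list[str]

    def apply(self, matrix: ProteinMatrix, participants: Sequence[str]) -> tuple[list[str], np.ndarray]:
        """Axis coordinates for the participants with all signature proteins
        observed (others are excluded and logged)."""
        sub = matrix.subset(list(participants), self.proteins)
        complete = sub.mask.all(axis=1)
        dropped = int((~complete).sum())
        if dropped:
            logger.info("axis transform: %d participants missing signature values excluded", dropped)
        kept = [p for p, ok in zip(sub.participant_ids, complete) if ok]
        x = (sub.values[complete] - self.center) / self.scale
        return kept, x @ self.loadings


@dataclass
class AxisBinning:
    transform: AxisTransform
    #: participants of each bin, ordered by increasing axis coordinate
    bins: list[list[str]]
    bin_prevalence: np.ndarray
    bin_cases: np.ndarray
    bin_midpoints: np.ndarray  # mean axis coordinate per bin
    slope: float
    intercept: float
    slope_stderr: float
    #: reference lines: prevalence in the fitting clusters / in the population
    prevalence_fitting: float
    prevalence_population: float

    @property
    def bin_sizes(self) -> np.ndarray:
        return np.asarray([len(b) for b in self.bins])

    @property
    def overall_prevalence(self) -> float:
        return float(self.bin_cases.sum() / self.bin_sizes.sum())


def fit_axis(
    matrix: ProteinMatrix,
    pooled_cluster: Sequence[str],
    proteins: Sequence[str],
    standardize: bool = True,
) -> AxisTransform:
    """First principal axis of the signature submatrix on the pooled cluster.

    Columns are centered (and by default standardized — the proteins are on
    different scales) on the fitting population; the axis is the leading
    eigenvector of that population's covariance.  The sign is fixed so the
    first signature protein's loading is nonnegative.  Rows with any missing
    signature value are excluded from the fit (and logged).
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("empty protein signature")
    sub = matrix.subset(list(pooled_cluster), proteins)
    complete = sub.mask.all(axis=1)
    kept = [p for p, ok in zip(sub.participant_ids, complete) if ok]
    if len(kept) < len(proteins) + 1:
        logger.warning(
            "only %d complete fitting participants for %d proteins",
            len(kept), len(proteins),
        )
    if not kept:
        raise ValueError("no fitting participant with complete signature")
    x = sub.values[complete]
    center = x.mean(axis=0)
    if standardize:
        scale = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.ones(len(proteins))
    else:
        scale = np.ones(len(proteins))
    if np.any(scale == 0) or np.any(~np.isfinite(scale)):
        j = int(np.flatnonzero((scale == 0) | ~np.isfinite(scale))[0])
        raise ValueError(f"zero-variance protein in fitting population: {proteins[j]!r}")
    xs = (x - center) / scale
    if len(proteins) == 1:
        loadings = np.ones(1)
    else:
        cov = np.cov(xs, rowvar=False)
        w, v = np.linalg.eigh(cov)
        loadings = v[:, -1]
    if loadings[0] < 0:
        loadings = -loadings
    return AxisTransform(proteins, loadings, center, scale, kept)


def bin_prevalence(
    transform: AxisTransform,
    matrix: ProteinMatrix,
    population: Sequence[str],
    phenotypes: PhenotypeTable,
    disease_code: str,
    n_bins: int = DEFAULT_N_BINS,
    exclude_extremes: bool = True,
) -> AxisBinning:
    """Equal-size binning of a population by axis coordinate, with per-bin
    disease prevalence and an OLS prevalence-vs-position fit.

    Bin sizes differ by at most one; ties in the coordinate are broken by
    participant ID so the binning is deterministic.  The regression is
    prevalence on bin mean coordinate, excluding the first and last bins
    when ``exclude_extremes`` (their prevalences are the noisiest).  The
    weighted mean of bin prevalences (weights = sizes) equals the overall
    prevalence of the binned population exactly.
    """
    population = [p for p in population if p in set(phenotypes.participant_ids)]
    kept, coords = transform.apply(matrix, population)
    if n_bins > len(kept):
        raise ValueError(f"n_bins={n_bins} exceeds population size {len(kept)}")
    if exclude_extremes and n_bins < 3:
        raise ValueError("need n_bins >= 3 when excluding extreme bins")

    order = sorted(range(len(kept)), key=lambda i: (coords[i], kept[i]))
    chunks = np.array_split(np.asarray(order), n_bins)
    bins = [[kept[i] for i in chunk] for chunk in chunks]

    sick = dict(zip(phenotypes.participant_ids, phenotypes.has_code(disease_code)))
    bin_cases = np.asarray([sum(sick[p] for p in b) for b in bins], dtype=float)
    sizes = np.asarray([len(b) for b in bins], dtype=float)
    prev = bin_cases / sizes
    mid = np.asarray([coords[chunk].mean() for chunk in chunks])

    fit_slice = slice(1, -1) if exclude_extremes else slice(None)
    xf, yf = mid[fit_slice], prev[fit_slice]
    A = np.vstack([xf, np.ones_like(xf)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, yf, rcond=None)
    dof = len(xf) - 2
    if dof > 0 and res.size:
        s2 = float(res[0]) / dof
        sxx = float(((xf - xf.mean()) ** 2).sum())
        stderr = float(np.sqrt(s2 / sxx)) if sxx > 0 else float("nan")
    else:
        stderr = float("nan")

    fit_ids = [p for p in transform.fitted_on if p in sick]
    prev_fit = float(np.mean([sick[p] for p in fit_ids])) if fit_ids else float("nan")
    prev_pop = float(np.mean([sick[p] for p in kept]))
    return AxisBinning(
        transform=transform,
        bins=bins,
        bin_prevalence=prev,
        bin_cases=bin_cases,
        bin_midpoints=mid,
        slope=float(slope),
        intercept=float(intercept),
        slope_stderr=stderr,
        prevalence_fitting=prev_fit,
        prevalence_population=prev_pop,
    )
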