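"""Per-cluster descriptive characterization.

Disease enrichment: one Fisher exact test per (cluster, ICD-10 code) 2x2
table, Bonferroni-corrected over all pairs tested in the call, odds ratios
with Woolf confidence intervals (Haldane-Anscombe adjusted when a cell is
zero; the p-value always uses the raw counts).  Optional sex
stratification repeats the analysis within each sex.

Demographics: per cluster, a Mann-Whitney U test of age (cluster vs
everyone else), a chi-square test of sex composition, and the minority-sex
fraction; Bonferroni within each test family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._stats import OddsRatio, odds_ratio
from .containers import ClusterAssignment, PhenotypeTable

logger = logging.getLogger(__name__)

MIN_CLUSTER_FOR_DEMOGRAPHICS = 10


@dataclass
class EnrichmentResult:
    cluster_id: str
    disease_code: str
    sex: str | None  # stratum, None = both sexes
    a: int  # in-cluster cases
    b: int  # in-cluster non-cases
    c: int  # out-cluster cases
    d: int  # out-cluster non-cases
    odds: OddsRatio
    p_raw: float
    p_bonferroni: float
    flagged: bool = False  # zero-cell or absent code


def disease_enrichment(
    clusters: ClusterAssignment,
    phenotypes: PhenotypeTable,
    codes: Sequence[str],
    stratify_sex: bool = False,
) -> list[EnrichmentResult]:
    """Fisher exact enrichment of each ICD-10 code in each cluster.

    The comparison population is every phenotyped participant with a
    cluster assignment record (noise included) outside the cluster.
    Bonferroni correction spans all (cluster, code[, sex]) pairs tested in
    this call — one family per analysis.
    """
    universe = [p for p in phenotypes.participant_ids if p in clusters.labels]
    if not universe:
        raise ValueError("no overlap between phenotypes and cluster assignment")
    sick = {code: dict(zip(phenotypes.participant_ids, phenotypes.has_code(code))) for code in codes}
    sex_of = dict(zip(phenotypes.participant_ids, phenotypes.sex))
    strata: list[str | None] = (
        sorted({str(s) for s in sex_of.values()}) if stratify_sex else [None]
    )

    results: list[EnrichmentResult] = []
    for stratum in strata:
        pop = [p for p in universe if stratum is None or sex_of[p] == stratum]
        for cid in clusters.cluster_ids:
            in_cluster = {p for p in clusters.members(cid)} & set(pop)
            for code in codes:
                a = sum(sick[code][p] for p in in_cluster)
                b = len(in_cluster) - a
                c = sum(sick[code][p] for p in pop if p not in in_cluster)
                d = len(pop) - len(in_cluster) - c
                p_raw = float(stats.fisher_exact([[a, b], [c, d]]).pvalue)
                orr = odds_ratio(a, b, c, d)
                flagged = (a + c == 0) or orr.corrected or not orr.defined
                if a + c == 0:
                    logger.warning("code %s absent from phenotypes (stratum %s)", code, stratum)
                results.append(
                    EnrichmentResult(cid, code, stratum, a, b, c, d, orr, p_raw, p_raw, flagged)
                )
    m = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p_raw * m)
    return results


@dataclass
class DemographicResult:
    cluster_id: str
    n: int
    age_median_in: float
    age_median_out: float
    age_p_raw: float
    age_p_bonferroni: float
    sex_counts: dict[str, int]
    minority_sex_fraction: float
    sex_p_raw: float
    sex_p_bonferroni: float


def demographic_contrast(
    clusters: ClusterAssignment, phenotypes: PhenotypeTable
) -> list[DemographicResult]:
    """Age and sex contrasts of each cluster against all other participants.

    Age: two-sample Mann-Whitney U.  Sex: chi-square on the 2 x 2 (or
    2 x k) sex-by-membership table.  Bonferroni over clusters within each
    family.  Clusters smaller than 10 are skipped with a warning.  The
    minority-sex fraction flags strongly sex-skewed clusters (e.g. one sex
    under 40%).
    """
    universe = [p for p in phenotypes.participant_ids if p in clusters.labels]
    age = dict(zip(phenotypes.participant_ids, phenotypes.age))
    sex = dict(zip(phenotypes.participant_ids, (str(s) for s in phenotypes.sex)))
    sex_levels = sorted(set(sex[p] for p in universe))

    results: list[DemographicResult] = []
    for cid in clusters.cluster_ids:
        members = [p for p in clusters.members(cid) if p in age]
        if len(members) < MIN_CLUSTER_FOR_DEMOGRAPHICS:
            logger.warning("cluster %s too small for demographics (%d)", cid, len(members))
            continue
        others = [p for p in universe if clusters.labels.get(p) != cid]
        age_in = np.asarray([age[p] for p in members])
        age_out = np.asarray([age[p] for p in others])
        age_p = float(stats.mannwhitneyu(age_in, age_out, alternative="two-sided").pvalue)

        counts_in = {s: sum(sex[p] == s for p in members) for s in sex_levels}
        counts_out = {s: sum(sex[p] == s for p in others) for s in sex_levels}
        table = np.asarray(
            [[counts_in[s] for s in sex_levels], [counts_out[s] for s in sex_levels]]
        )
        nonzero_cols = table.sum(axis=0) > 0
        if nonzero_cols.sum() < 2:
            sex_p = 1.0
        else:
            sex_p = float(stats.chi2_contingency(table[:, nonzero_cols]).pvalue)
        total_in = sum(counts_in.values())
        minority = min(counts_in.values()) / total_in if total_in else float("nan")
        results.append(
            DemographicResult(
                cluster_id=cid,
                n=len(members),
                age_median_in=float(np.median(age_in)),
                age_median_out=float(np.median(age_out)),
                age_p_raw=age_p,
                age_p_bonferroni=age_p,
                sex_counts=counts_in,
                minority_sex_fraction=float(minority),
                sex_p_raw=sex_p,
                sex_p_bonferroni=sex_p,
            )
        )
    m = len(results)
    for r in results:
        r.age_p_bonferroni = min(1.0, r.age_p_raw * m)
        r.sex_p_bonferroni = min(1.0, r.sex_p_raw * m)
    return results
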