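"""Synthetic plasma-proteome cohorts with planted structure.

The generator emulates the statistical features the segmentation framework
relies on, so every downstream stage is testable without access-restricted
cohort data:

* baseline abundances are i.i.d. standard normal (NPX values are roughly
  log-scale normal);
* latent participant clusters are realized as additive mean shifts on a
  per-cluster protein subset;
* block-structured missingness: groups of proteins share one missing mask
  over a common random participant subset (panels measured together fail
  together), plus an optional batch-style dropout masking a contiguous
  trailing protein subset for a participant fraction;
* binary disease labels whose odds depend on cluster membership;
* optional within-cluster coregulation of a protein subset via a shared
  latent factor ``x_i = sqrt(rho) * z + sqrt(1 - rho) * e_i``, which gives
  exact pairwise target correlation ``rho``.

The same seed always yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import PhenotypeTable, ProteinMatrix


@dataclass
class DiseaseSpec:
    """One synthetic disease: ICD-10-style code, baseline prevalence and a
    per-cluster odds multiplier (length = n_clusters; 1.0 = no effect)."""

    code: str
    baseline_prevalence: float
    odds_multiplier: Sequence[float]


@dataclass
class CoregulationSpec:
    """Plant pairwise correlation ``rho`` among the cohort's last
    ``n_proteins`` proteins, inside cluster ``cluster`` only."""

    cluster: int
    n_proteins: int
    rho: float


@dataclass
class SyntheticConfig:
    n_participants: int = 3000
    n_proteins: int = 120
    n_clusters: int = 4
    cluster_proportions: Sequence[float] | None = None  # default: uniform
    shift_proteins_per_cluster: int = 30
    shift_magnitude: float = 3.0
    #: list of (protein-subset size, participant fraction masked)
    missing_block_spec: Sequence[tuple[int, float]] = field(default_factory=list)
    #: optional (participant fraction, protein-subset size)
    batch_dropout: tuple[float, int] | None = None
    #: additional fully random missingness, fraction of all cells
    random_missing_fraction: float = 0.0
    disease_spec: Sequence[DiseaseSpec] = field(default_factory=list)
    coregulation_spec: CoregulationSpec | None = None
    #: log-odds of disease per year of (centered) age, applied to every disease
    age_log_odds: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_proportions is None:
            self.cluster_proportions = [1.0 / self.n_clusters] * self.n_clusters
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.n_clusters:
            raise ValueError("cluster_proportions length != n_clusters")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        if self.shift_magnitude < 0:
            raise ValueError("shift_magnitude must be >= 0")
        if self.shift_proteins_per_cluster * self.n_clusters > self.n_proteins:
            raise ValueError("shift protein subsets exceed n_proteins")
        for size, frac in self.missing_block_spec:
            if size > self.n_proteins or not 0 <= frac <= 1:
                raise ValueError("infeasible missing block spec")
        if sum(s for s, _ in self.missing_block_spec) > self.n_proteins:
            raise ValueError("missing blocks exceed n_proteins")
        if self.batch_dropout is not None:
            frac, size = self.batch_dropout
            if size > self.n_proteins or not 0 <= frac <= 1:
                raise ValueError("infeasible batch_dropout")
        for d in self.disease_spec:
            if not 0 <= d.baseline_prevalence <= 1:
                raise ValueError(f"prevalence out of [0,1] for {d.code}")
            if len(d.odds_multiplier) != self.n_clusters:
                raise ValueError(f"odds_multiplier length != n_clusters for {d.code}")
        if self.coregulation_spec is not None:
            cs = self.coregulation_spec
            if not 0 <= cs.rho < 1:
                raise ValueError("coregulation rho must be in [0, 1)")
            if cs.n_proteins > self.n_proteins:
                raise ValueError("coregulation subset exceeds n_proteins")
            if cs.n_proteins < 2:
                raise ValueError("coregulation subset needs >= 2 proteins")
            if not 0 <= cs.cluster < self.n_clusters:
                raise ValueError("coregulation cluster index out of range")


def shift_proteins(config: SyntheticConfig, cluster: int) -> list[str]:
    """Protein IDs shifted in ``cluster`` (deterministic contiguous blocks)."""
    k = config.shift_proteins_per_cluster
    return [f"P{j:04d}" for j in range(cluster * k, (cluster + 1) * k)]


def coregulation_proteins(config: SyntheticConfig) -> list[str]:
    """Protein IDs of the coregulated subset: the last ``n_proteins`` ones."""
    if config.coregulation_spec is None:
        raise ValueError("config has no coregulation_spec")
    k = config.coregulation_spec.n_proteins
    return [f"P{j:04d}" for j in range(config.n_proteins - k, config.n_proteins)]


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ProteinMatrix, PhenotypeTable, dict[str, int]]:
    """Draw one cohort; returns (matrix, phenotypes, participant -> true cluster).

    Cluster ``c`` shifts proteins ``[c*k, (c+1)*k)`` by ``shift_magnitude``.
    Missing blocks mask randomly chosen disjoint protein subsets for a shared
    random participant subset each; batch dropout masks the trailing protein
    subset for a random participant fraction.  Ages are uniform on 40-70
    years, sex balanced, both independent of cluster.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_participants, config.n_proteins
    participant_ids = [f"S{i:06d}" for i in range(n)]
    protein_ids = [f"P{j:04d}" for j in range(p)]

    clusters = rng.choice(
        config.n_clusters, size=n, p=np.asarray(config.cluster_proportions)
    )
    values = rng.standard_normal((n, p))

    k = config.shift_proteins_per_cluster
    for c in range(config.n_clusters):
        rows = clusters == c
        values[np.ix_(rows, np.arange(c * k, (c + 1) * k))] += config.shift_magnitude

    if config.coregulation_spec is not None:
        cs = config.coregulation_spec
        cols = np.arange(p - cs.n_proteins, p)
        rows = np.flatnonzero(clusters == cs.cluster)
        z = rng.standard_normal(rows.size)
        e = rng.standard_normal((rows.size, cols.size))
        values[np.ix_(rows, cols)] = (
            np.sqrt(cs.rho) * z[:, None] + np.sqrt(1.0 - cs.rho) * e
        )

    mask = np.ones((n, p), dtype=bool)
    free = list(range(p))  # proteins not yet claimed by a missing block
    for size, frac in config.missing_block_spec:
        cols = rng.choice(free, size=size, replace=False)
        free = [j for j in free if j not in set(cols.tolist())]
        rows = rng.random(n) < frac
        mask[np.ix_(rows, cols)] = False
    if config.batch_dropout is not None:
        frac, size = config.batch_dropout
        rows = rng.random(n) < frac
        mask[np.ix_(rows, np.arange(p - size, p))] = False
    if config.random_missing_fraction > 0:
        mask &= rng.random((n, p)) >= config.random_missing_fraction

    age = rng.uniform(40.0, 70.0, size=n)
    sex = np.where(rng.random(n) < 0.5, "F", "M").astype(object)

    codes: dict[str, set[str]] = {pid: set() for pid in participant_ids}
    age_c = age - age.mean()
    for d in config.disease_spec:
        if d.baseline_prevalence in (0.0, 1.0):
            sick = np.full(n, d.baseline_prevalence == 1.0)
        else:
            base_logit = np.log(d.baseline_prevalence / (1 - d.baseline_prevalence))
            mult = np.asarray([d.odds_multiplier[c] for c in clusters], dtype=float)
            logit = base_logit + np.log(mult) + config.age_log_odds * age_c
            sick = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
        for i in np.flatnonzero(sick):
            codes[participant_ids[i]].add(d.code)

    matrix = ProteinMatrix(participant_ids, protein_ids, values, mask)
    phenotypes = PhenotypeTable(
        participant_ids, age, sex, {k_: frozenset(v) for k_, v in codes.items()}
    )
    true_labels = {pid: int(c) for pid, c in zip(participant_ids, clusters)}
    return matrix, phenotypes, true_labels


def planted_correlation_check(
    matrix: ProteinMatrix,
    spec: CoregulationSpec,
    labels: dict[str, int],
) -> float:
    """Mean pairwise sample correlation of the coregulated protein subset
    within the named cluster (test support for the differential-correlation
    analyses).

    Raises
    ------
    ValueError
        If the cluster is absent from ``labels`` or the subset has < 2
        proteins (pairwise correlation undefined).
    """
    if spec.n_proteins < 2:
        raise ValueError("correlation undefined for a single-protein subset")
    members = [p for p in matrix.participant_ids if labels.get(p) == spec.cluster]
    if not members:
        raise ValueError(f"cluster {spec.cluster} absent from labels")
    cols = matrix.protein_ids[-spec.n_proteins :]
    sub = matrix.subset(participants=members, proteins=cols)
    corr = np.corrcoef(sub.values, rowvar=False)
    iu = np.triu_indices(spec.n_proteins, k=1)
    return float(np.mean(corr[iu]))
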