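"""Synthetic RNA-seq counts with planted clusters and co-expression modules.

Counts are drawn from a negative binomial (gamma–Poisson) with gene-level
means modulated by

* a per-gene base abundance (log-normal across genes),
* planted per-stratum log2 mean shifts ("clusters" — groups of genes
  sharing one expression pattern across genotype x condition strata), and
* shared latent factors ("modules" — one standard-normal factor per
  module per sample, entering multiplicatively on the log scale), which
  induce within-module correlation at a requested level.

The factor loading for a target correlation rho is
``lambda = sigma * sqrt(rho / (1 - rho))`` where sigma approximates the
per-gene log2 sampling noise, ``sigma^2 = (1/mu + phi) / ln(2)^2``.
A module's hub gene gets a modestly inflated loading so its correlations
with every member exceed the member–member level.  Modules may be
restricted to a subset of strata; elsewhere their genes are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..dge import CONDITIONS, CountMatrix

_LN2 = np.log(2.0)


@dataclass
class ClusterPlan:
    """A planted expression cluster: ``size`` genes sharing one pattern.

    ``shifts`` maps (genotype, condition) strata to log2 mean shifts;
    unlisted strata shift by 0.
    """

    size: int
    shifts: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class ModulePlan:
    """A planted co-expression module driven by one latent factor.

    ``correlation`` is the target pairwise correlation between member
    log-expression profiles; ``hub`` plants one designated hub gene;
    ``strata`` restricts the factor to those (genotype, condition)
    strata (None = active everywhere).
    """

    size: int
    correlation: float
    hub: bool = False
    strata: list[tuple[str, str]] | None = None
    shifts: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("module correlation must lie in (-1, 1)")
        if self.size < 2:
            raise ValueError("a module needs at least 2 genes")


@dataclass
class ExprSimSpec:
    """Study design and planted structure for one simulated count matrix.

    The default design mirrors a four-cultivar (two resistant, two
    susceptible) x two-condition (infested / uninfested) experiment with
    three biological replicates per stratum.
    """

    n_genes: int = 1000
    strata: list[tuple[str, str, int]] = field(
        default_factory=lambda: [
            (g, c, 3)
            for g in ("H1706", "H9775", "H9492", "H9553")
            for c in CONDITIONS
        ]
    )
    cluster_plan: list[ClusterPlan] = field(default_factory=list)
    module_plan: list[ModulePlan] = field(default_factory=list)
    library_size: float = 5e5
    dispersion: float = 0.05
    base_log2_sd: float = 1.0
    background_pattern_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if any(reps < 2 for _, _, reps in self.strata):
            raise ValueError("every stratum needs >= 2 replicates")
        planted = sum(c.size for c in self.cluster_plan) + sum(
            m.size for m in self.module_plan
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted cluster+module sizes ({planted}) exceed n_genes"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class ExprTruth:
    """Generative ground truth accompanying a simulated count matrix.

    cluster_labels: per-gene integer, 1..k for planted clusters, 0 for
    background genes.  module_members / hub_genes are keyed by module
    index (1-based, in plan order).
    """

    cluster_labels: pd.Series
    module_members: dict[int, list[str]]
    hub_genes: dict[int, str]


def simulate_counts(spec: ExprSimSpec) -> tuple[CountMatrix, ExprTruth]:
    """Draw one count matrix; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]

    sample_rows = []
    for genotype, condition, reps in spec.strata:
        for r in range(1, reps + 1):
            sample_rows.append(
                {
                    "sample": f"{genotype}_{condition}_r{r}",
                    "genotype": genotype,
                    "condition": condition,
                    "replicate": r,
                }
            )
    samples = pd.DataFrame(sample_rows).set_index("sample")
    n_samples = len(samples)
    stratum_of = list(zip(samples["genotype"], samples["condition"]))

    # per-gene base abundance (relative, log-normal across genes)
    base = rng.lognormal(mean=0.0, sigma=spec.base_log2_sd * _LN2, size=spec.n_genes)
    base *= spec.library_size / base.sum()

    # planted cluster shifts
    log2_shift = np.zeros((spec.n_genes, n_samples))
    cluster_labels = np.zeros(spec.n_genes, dtype=int)
    cursor = 0
    for ci, plan in enumerate(spec.cluster_plan, start=1):
        idx = np.arange(cursor, cursor + plan.size)
        cursor += plan.size
        cluster_labels[idx] = ci
        for j, stratum in enumerate(stratum_of):
            shift = plan.shifts.get(stratum, 0.0)
            if shift:
                log2_shift[idx, j] += shift

    # per-gene noise scale for loading calibration (uses pre-factor means)
    mu0 = base[:, None] * 2.0**log2_shift
    sigma_log2 = np.sqrt((1.0 / np.maximum(mu0.mean(axis=1), 1e-9) + spec.dispersion)) / _LN2

    module_members: dict[int, list[str]] = {}
    hub_genes: dict[int, str] = {}
    for mi, plan in enumerate(spec.module_plan, start=1):
        idx = np.arange(cursor, cursor + plan.size)
        cursor += plan.size
        module_members[mi] = [genes[i] for i in idx]
        for j, stratum in enumerate(stratum_of):
            shift = plan.shifts.get(stratum, 0.0)
            if shift:
                log2_shift[idx, j] += shift
        rho = abs(plan.correlation)
        if rho > 0:
            factor = rng.normal(size=n_samples)
            active = np.array(
                [
                    plan.strata is None or stratum_of[j] in plan.strata
                    for j in range(n_samples)
                ]
            )
            # first-order correction for the fixed-depth compensation: the
            # module's own swing is renormalized away in proportion to its
            # share of the library, which would dilute the realized loading
            weight = base[idx].sum() / base.sum()
            lam = sigma_log2[idx] * np.sqrt(rho / (1.0 - rho)) / max(1.0 - weight, 0.5)
            if plan.hub:
                # the hub tracks the latent factor almost exactly, so it
                # correlates with every member at ~sqrt(rho) while members
                # inter-correlate at rho — a star-topped module
                lam = lam.copy()
                lam[0] *= 5.0
            sign = np.sign(plan.correlation)
            log2_shift[idx, :] += np.where(
                active[None, :], sign * lam[:, None] * factor[None, :], 0.0
            )
        if plan.hub:
            hub_genes[mi] = genes[idx[0]]

    # background genes: optional idiosyncratic per-gene stratum patterns, so
    # unplanted genes scatter in profile space instead of forming one flat group
    if spec.background_pattern_sd > 0 and cursor < spec.n_genes:
        bg = np.arange(cursor, spec.n_genes)  # genes in no cluster and no module
        uniq = sorted(set(stratum_of))
        pattern = rng.normal(0.0, spec.background_pattern_sd, size=(len(bg), len(uniq)))
        col_of = np.array([uniq.index(s) for s in stratum_of])
        log2_shift[bg, :] += pattern[:, col_of]

    mu = base[:, None] * 2.0 ** log2_shift
    # fixed sequencing depth: expected per-sample totals equal library_size,
    # so planted swings change composition, not depth (avoids spurious
    # normalization-induced correlation between unrelated genes)
    mu *= spec.library_size / mu.sum(axis=0, keepdims=True)
    # gamma-Poisson mixture == negative binomial with dispersion phi
    shape = 1.0 / spec.dispersion
    gamma = rng.gamma(shape=shape, scale=1.0 / shape, size=mu.shape)
    counts = rng.poisson(mu * gamma)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples.index),
        samples=samples,
    )
    truth = ExprTruth(
        cluster_labels=pd.Series(cluster_labels, index=genes),
        module_members=module_members,
        hub_genes=hub_genes,
    )
    return cm, truth
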