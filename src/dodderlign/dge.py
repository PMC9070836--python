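"""Differential gene expression for the host-response count data.

Counts are normalized to counts-per-million (CPM) and modelled per gene
as a linear model on log2(CPM + 0.5) with condition (infested /
uninfested), genotype, and their interaction.  Two selection routes are
provided:

``interaction_dge``
    Tests a specific interaction contrast — whether the infestation
    response of one genotype differs from another's — and selects genes
    at adjusted p < 0.1 and |log2 fold change| > 1, where the fold
    change is the difference-of-differences of stratum means on the
    log2 scale.

``twofactor_anova_dge``
    Omnibus two-way ANOVA F-test per gene (any condition, genotype or
    interaction effect) selected at FDR < 0.1.

Benjamini–Hochberg is the multiple-testing procedure throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("uninfested", "infested")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample metadata.

    ``samples`` must carry columns ``genotype``, ``condition`` (values in
    {"infested", "uninfested"}) and ``replicate``; ``dpa`` (days post
    attachment) is optional and used by the time-course route.
    """

    counts: pd.DataFrame  # genes x samples
    samples: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples lack metadata: {sorted(missing)}")
        for col in ("genotype", "condition", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def strata(self) -> pd.Series:
        """(genotype, condition) label per sample, aligned to count columns."""
        meta = self.samples.loc[self.counts.columns]
        return pd.Series(
            list(zip(meta["genotype"], meta["condition"])), index=self.counts.columns
        )


@dataclass
class DGEThresholds:
    """Selection cutoffs. fc_min applies to the time-course variant only."""

    fdr_max: float = 0.1
    log2fc_min: float = 1.0
    fc_min: float = 1.5

    def __post_init__(self) -> None:
        if min(self.fdr_max, self.log2fc_min, self.fc_min) <= 0:
            raise ValueError("all thresholds must be positive")


def cpm_normalize(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: every sample column rescaled to sum to 1e6."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return df * (1e6 / totals)


def log2_cpm(counts: CountMatrix | pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    return np.log2(cpm_normalize(counts) + pseudocount)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def _check_replication(cm: CountMatrix) -> pd.Series:
    strata = cm.strata()
    sizes = strata.value_counts()
    thin = sizes[sizes < 2]
    if len(thin):
        raise ValueError(f"strata with <2 replicates: {list(thin.index)}")
    return strata


def _design_matrix(strata: pd.Series) -> tuple[np.ndarray, list[str], dict]:
    """Reference-cell coded condition + genotype + interaction design."""
    genotypes = sorted({g for g, _ in strata})
    ref_geno = genotypes[0]
    cols = ["intercept", "infested"]
    cols += [f"geno:{g}" for g in genotypes[1:]]
    cols += [f"ix:{g}" for g in genotypes[1:]]
    X = np.zeros((len(strata), len(cols)))
    X[:, 0] = 1.0
    for i, (g, cond) in enumerate(strata):
        inf = 1.0 if cond == "infested" else 0.0
        X[i, 1] = inf
        if g != ref_geno:
            X[i, cols.index(f"geno:{g}")] = 1.0
            X[i, cols.index(f"ix:{g}")] = inf
    return X, cols, {"genotypes": genotypes, "ref": ref_geno}


def _ols_contrast(Y: np.ndarray, X: np.ndarray, c: np.ndarray):
    """Vectorized per-row OLS t-test of the contrast c'beta.

    Y: genes x samples; returns (estimate, t, p, df_resid) arrays.
    """
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = Y @ X @ XtX_inv.T  # genes x p
    resid = Y - beta @ X.T
    df = n - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=1) / df
    est = beta @ c
    se = np.sqrt(sigma2 * float(c @ XtX_inv @ c))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    return est, t, pval, df


def interaction_dge(
    cm: CountMatrix,
    thresholds: DGEThresholds | None = None,
    contrast: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Interaction-contrast DGE on log2(CPM + 0.5).

    ``contrast=(a, b)`` tests whether genotype *a*'s infestation response
    differs from genotype *b*'s (the difference-of-differences of the
    four stratum means).  Defaults to (last, first) genotype in sorted
    order.  Returns a per-gene frame with columns log2fc, p, fdr, passes.
    """
    thresholds = thresholds or DGEThresholds()
    strata = _check_replication(cm)
    X, cols, info = _design_matrix(strata)
    genotypes = info["genotypes"]
    if contrast is None:
        contrast = (genotypes[-1], genotypes[0])
    a, b = contrast
    for g in (a, b):
        if g not in genotypes:
            raise ValueError(f"unknown genotype in contrast: {g!r}")
    if a == b:
        raise ValueError("contrast genotypes must differ")
    c = np.zeros(len(cols))
    if a != info["ref"]:
        c[cols.index(f"ix:{a}")] = 1.0
    if b != info["ref"]:
        c[cols.index(f"ix:{b}")] = -1.0

    Y = log2_cpm(cm).values
    est, _, pval, _ = _ols_contrast(Y, X, c)
    fdr = bh_adjust(pval)
    out = pd.DataFrame(
        {
            "log2fc": est,
            "p": pval,
            "fdr": fdr,
            "passes": (fdr < thresholds.fdr_max)
            & (np.abs(est) > thresholds.log2fc_min),
        },
        index=cm.gene_ids,
    )
    return out


def twofactor_anova_dge(
    cm: CountMatrix, thresholds: DGEThresholds | None = None
) -> pd.DataFrame:
    """Per-gene omnibus two-way ANOVA (condition x genotype, with interaction).

    The F statistic compares the full cell-means model against the
    intercept-only model, so it detects any main or interaction effect.
    Selection at fdr < fdr_max (no fold-change condition on this route).
    """
    thresholds = thresholds or DGEThresholds()
    strata = _check_replication(cm)
    Y = log2_cpm(cm).values
    # cell-means parameterization: one indicator column per stratum
    levels = sorted(set(strata))
    X = np.zeros((len(strata), len(levels)))
    for i, s in enumerate(strata):
        X[i, levels.index(s)] = 1.0
    n = len(strata)
    k = np.linalg.matrix_rank(X)
    beta = Y @ X @ np.linalg.pinv(X.T @ X).T
    fitted = beta @ X.T
    rss = ((Y - fitted) ** 2).sum(axis=1)
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((tss - rss) / df1) / np.where(rss > 0, rss / df2, np.nan)
    F = np.where(np.isnan(F), 0.0, F)  # constant genes: no evidence
    pval = stats.f.sf(F, df1, df2)
    fdr = bh_adjust(pval)
    return pd.DataFrame(
        {"F": F, "p": pval, "fdr": fdr, "passes": fdr < thresholds.fdr_max},
        index=cm.gene_ids,
    )


def deg_overlap(deg_sets: dict[str, set]) -> dict[frozenset, int]:
    """Counts for every exclusive intersection region of the labelled sets.

    Keys are frozensets of labels; the value counts genes belonging to
    exactly those sets.  The regions partition the union.
    """
    labels = list(deg_sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(deg_sets[l] for l in combo))
            outside = set.union(
                set(), *(deg_sets[l] for l in labels if l not in combo)
            )
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def heatmap_order(expr: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Dendrogram leaf orders (rows, columns) under Euclidean distance and
    complete linkage."""
    mat = expr.values if isinstance(expr, pd.DataFrame) else np.asarray(expr)
    if not np.all(np.isfinite(mat)):
        raise ValueError("expression matrix must be finite")

    def order(m: np.ndarray) -> np.ndarray:
        if m.shape[0] < 2:
            return np.arange(m.shape[0])
        return leaves_list(linkage(m, method="complete", metric="euclidean"))

    return order(mat), order(mat.T)
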