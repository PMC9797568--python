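"""Gene–phenotype association by discretized Bayesian evidence comparison.

Continuous per-sample observations (gene expression, physiological
phenotype) are binned into k classes with Sturges' rule,
k = ceil(1 + log2 n). Each candidate gene -> phenotype link is then scored
by the difference in Dirichlet–multinomial log marginal likelihood of the
phenotype classes when conditioned on the gene classes versus
unconditioned (a BDeu-style prior splitting an equivalent sample size
uniformly over cells). A positive score means conditioning improves the
evidence despite the extra parameters; the link's sign comes from the
Pearson correlation of the undiscretized values. This scores each edge
independently — no network structure search is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import pearsonr

from .errors import ParameterError


def sturges_k(n_samples: int) -> int:
    """Sturges' bin count ceil(1 + log2 n)."""
    if n_samples < 1:
        raise ParameterError("need at least one sample")
    return math.ceil(1 + math.log2(n_samples))


def discretize(values, k: int) -> np.ndarray:
    """Equal-width binning over [min, max] into labels 0..k-1.

    The maximum maps to the top bin; a constant vector maps to all zeros.
    Labels are invariant under translation and positive scaling.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ParameterError("need at least one value")
    if k < 1:
        raise ParameterError("k must be >= 1")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.size, dtype=int)
    labels = np.floor((values - lo) / (hi - lo) * k).astype(int)
    return np.minimum(labels, k - 1)


def _dirmult_log_evidence(counts: np.ndarray, alpha_total: float) -> float:
    """Log marginal likelihood of multinomial counts under a symmetric
    Dirichlet prior with total pseudo-count *alpha_total*."""
    counts = np.asarray(counts, dtype=float)
    a = alpha_total / counts.size
    return float(
        gammaln(alpha_total)
        - gammaln(alpha_total + counts.sum())
        + np.sum(gammaln(counts + a) - gammaln(a))
    )


def bayes_score(
    gene_classes: np.ndarray, pheno_classes: np.ndarray, k: int, ess: float = 1.0
) -> float:
    """Evidence gain of modelling phenotype classes given gene classes.

    score = log P(pheno | gene) - log P(pheno), each a Dirichlet–
    multinomial marginal with equivalent sample size *ess* split
    uniformly over cells (ess/k for the marginal, ess/(k*k) per
    conditional cell, BDeu style). Larger conditional tables pay a prior
    cost, so independent data tends to score below 0.
    """
    if ess <= 0:
        raise ParameterError("equivalent sample size must be positive")
    marginal = _dirmult_log_evidence(np.bincount(pheno_classes, minlength=k), ess)
    conditional = 0.0
    for g in range(k):
        sel = pheno_classes[gene_classes == g]
        conditional += _dirmult_log_evidence(np.bincount(sel, minlength=k), ess / k)
    return conditional - marginal


@dataclass
class AssociationRecord:
    gene: str
    phenotype: str
    bayes_score: float
    passes: bool
    sign: str | None  # '+' or '-' only when passes

    def __post_init__(self) -> None:
        if not self.passes and self.sign is not None:
            raise ParameterError("sign defined only for passing associations")


def associate(
    gene: str,
    expression,
    phenotype_name: str,
    phenotype,
    k: int | None = None,
    ess: float = 1.0,
    threshold: float = 0.0,
) -> AssociationRecord:
    """Score one gene -> phenotype link.

    *expression* and *phenotype* are equal-length per-sample vectors
    (n >= 4). k defaults to Sturges' rule on n. The link passes iff the
    evidence gain exceeds *threshold*; its sign is the sign of the
    Pearson correlation on the raw values. A zero-variance phenotype or
    gene yields a non-passing record.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if x.size != y.size:
        raise ParameterError("expression and phenotype lengths differ")
    if x.size < 4:
        raise ParameterError("need at least 4 samples")
    if k is None:
        k = sturges_k(x.size)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return AssociationRecord(gene, phenotype_name, float("-inf"), False, None)
    score = bayes_score(discretize(x, k), discretize(y, k), k, ess)
    passes = score > threshold
    sign = None
    if passes:
        r = pearsonr(x, y).statistic
        sign = "+" if r >= 0 else "-"
    return AssociationRecord(gene, phenotype_name, score, passes, sign)


def associate_all(expression_df, phenotype_df, ess: float = 1.0, threshold: float = 0.0):
    """Score every (gene, phenotype) pair.

    *expression_df*: genes x samples DataFrame; *phenotype_df*: samples x
    phenotypes DataFrame with matching sample labels. Returns a list of
    :class:`AssociationRecord`.
    """
    common = [s for s in expression_df.columns if s in phenotype_df.index]
    if len(common) < 4:
        raise ParameterError("fewer than 4 shared samples between tables")
    k = sturges_k(len(common))
    records = []
    for pheno in phenotype_df.columns:
        y = phenotype_df.loc[common, pheno].to_numpy(dtype=float)
        for gene in expression_df.index:
            x = expression_df.loc[gene, common].to_numpy(dtype=float)
            records.append(associate(gene, x, pheno, y, k=k, ess=ess, threshold=threshold))
    return records
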