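"""Blood transcriptomic signature construction and classifier validation.

Starting from a gene × sample count matrix with a technical-replicate map, the
pipeline is:

1. collapse technical replicates by summation (one column per subject),
2. normalise by median-of-ratios size factors,
3. per-gene negative-binomial Wald test of the two-group contrast
   (Phen1 vs non-Phen1) with trend-shrunk method-of-moments dispersions,
4. Benjamini–Hochberg FDR adjustment,
5. build the ranked signature: drop genes whose median raw count is not
   greater than ``min_median`` reads, sort by log2 fold change, take the top
   ``k`` up- and down-regulated genes,
6. validate the separation: PCA on log2-normalised expression restricted to a
   gene subset, leave-one-out logistic classification on the first two PCA
   coordinates, and a label-permutation null for the LOOCV accuracy.

The negative-binomial model for gene g in subject j is
``K_gj ~ NB(mu_gj, alpha_g)`` with ``mu_gj = s_j * q_g * 2^(beta_g * x_j)``
where ``s_j`` is the size factor, ``x_j`` the group indicator and ``beta_g``
the log2 fold change. With only a group factor the MLE separates by group, so
each group mean is found by a one-dimensional Newton solve of the NB score
equation; the Wald statistic for ``beta_g`` is referred to a t distribution
with ``n_subjects - 2`` degrees of freedom, a small-sample choice that keeps
the type-I error near nominal at the study's 10 + 10 design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "RankedSignature",
    "ClassifierReport",
    "collapse_replicates",
    "size_factors",
    "estimate_dispersions",
    "differential_expression",
    "bh_adjust",
    "log_normalized",
    "ranked_signature",
    "pca_classify",
    "loocv_logistic",
    "permutation_null",
]

_MIN_DISP = 1e-8
_MAX_DISP = 10.0


@dataclass
class CountMatrix:
    """Gene × sample integer counts with a technical-replicate map.

    ``replicate_map`` sends each sample (column) to its subject;
    ``subject_group`` sends each subject to its phenotype group.
    """

    counts: pd.DataFrame
    replicate_map: pd.Series
    subject_group: pd.Series

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        missing = [s for s in self.counts.columns if s not in self.replicate_map.index]
        if missing:
            raise ValueError(f"samples missing from replicate_map: {missing}")
        subs = set(self.replicate_map.loc[list(self.counts.columns)])
        unmapped = subs - set(self.subject_group.index)
        if unmapped:
            raise ValueError(f"subjects missing from subject_group: {sorted(unmapped)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class RankedSignature:
    """Ordered gene list (rank 1 = greatest up-regulation) with query sets."""

    genes: list
    up_set: list
    down_set: list
    k: int = 250
    median_filter_threshold: float = 10.0
    log2fc: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if set(self.up_set) & set(self.down_set):
            raise ValueError("up_set and down_set overlap")


@dataclass
class ClassifierReport:
    """LOOCV accuracy with its label-permutation null.

    ``permutation_p`` is the conservative add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)``; because LOOCV
    accuracy is discrete, heavy ties make it strictly valid but
    super-uniform under the null. ``permutation_p_randomized`` breaks ties
    uniformly at random, which restores exact uniformity under label
    exchangeability and is the quantity to use for calibration diagnostics.
    """

    loocv_accuracy: float
    null_scores: np.ndarray
    permutation_p: float
    n_permutations: int
    permutation_p_randomized: float = float("nan")


# ---------------------------------------------------------------------------
# counts processing


def collapse_replicates(cm: CountMatrix) -> CountMatrix:
    """Sum technical replicates so each subject contributes one column.

    Total counts are conserved: the collapsed column of a subject is exactly
    the sum of its replicate columns.
    """
    subjects = self_subjects = pd.unique(cm.replicate_map.loc[list(cm.samples)])
    groups = cm.counts.T.groupby(cm.replicate_map.loc[list(cm.samples)], sort=False)
    collapsed = groups.sum().T.loc[:, self_subjects]
    empty = [s for s in cm.subject_group.index if s not in set(subjects)]
    if empty:
        raise ValueError(f"subjects with zero samples: {empty}")
    return CountMatrix(
        counts=collapsed,
        replicate_map=pd.Series(collapsed.columns, index=collapsed.columns),
        subject_group=cm.subject_group.loc[collapsed.columns],
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each gene expressed in every subject, the ratio of its count to its
    across-subject geometric mean is formed; a subject's factor is the median
    ratio over those genes.
    """
    c = counts.to_numpy(dtype=float)
    all_pos = (c > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has nonzero counts in every subject")
    logc = np.log(c[all_pos])
    log_gmean = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_gmean, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB MLE of the group mean with known dispersion and offsets.

    Solves sum_j (y_gj - s_j m_g) / (1 + alpha_g s_j m_g) = 0 for m_g by
    Newton iteration on log m; vectorised over genes.
    """
    n = y.shape[1]
    m = np.maximum((y / s).mean(axis=1), 1e-8)
    eta = np.log(m)
    for _ in range(50):
        mu = s * np.exp(eta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        # negative expected derivative of the score wrt eta
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(eta)


def estimate_dispersions(
    counts: pd.DataFrame, sf: pd.Series, groups: pd.Series, shrink: float = 0.5
) -> pd.Series:
    """Per-gene NB dispersions: method-of-moments shrunk toward a mean trend.

    The raw estimate uses pooled within-group variances of normalised counts;
    a 1/mean trend ``a0 + a1/mu`` is fitted by trimmed non-negative least
    squares, and gene-wise estimates are shrunk toward the trend in log space
    with weight ``shrink``.
    """
    c = counts.to_numpy(dtype=float)
    s = sf.to_numpy()
    xn = c / s
    labels = groups.loc[counts.columns].to_numpy()
    z = float(np.mean(1.0 / s))
    num = np.zeros(c.shape[0])
    dof = 0
    mu_parts = []
    for g in np.unique(labels):
        block = xn[:, labels == g]
        if block.shape[1] >= 2:
            num += block.var(axis=1, ddof=1) * (block.shape[1] - 1)
            dof += block.shape[1] - 1
        mu_parts.append(block.mean(axis=1))
    mu = np.mean(mu_parts, axis=0)
    pooled_var = num / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (pooled_var - z * mu) / mu**2
    mom = np.where(np.isfinite(mom), mom, _MIN_DISP)
    mom = np.clip(mom, _MIN_DISP, _MAX_DISP)

    ok = (mu > 1.0) & (mom > _MIN_DISP * 2)
    if ok.sum() >= 10:
        a = _fit_trend(mu[ok], mom[ok])
    else:  # too few informative genes to fit a trend
        a = np.array([np.median(mom[mu > 0]) if (mu > 0).any() else 0.1, 0.0])
    trend = np.clip(a[0] + a[1] / np.maximum(mu, 1e-8), _MIN_DISP, _MAX_DISP)
    log_alpha = (1.0 - shrink) * np.log(mom) + shrink * np.log(trend)
    alpha = np.clip(np.exp(log_alpha), _MIN_DISP, _MAX_DISP)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _fit_trend(mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    a, _ = optimize.nnls(X, disp)
    for _ in range(2):  # trim gross outliers and refit
        fit = np.maximum(X @ a, 1e-8)
        ratio = disp / fit
        keep = (ratio < 10) & (ratio > 0.01)
        if keep.sum() < 10 or keep.all():
            break
        a, _ = optimize.nnls(X[keep], disp[keep])
    return a


def differential_expression(
    cm: CountMatrix,
    reference: str | None = None,
    dispersion_shrink: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB Wald differential expression on collapsed counts.

    Returns a DataFrame indexed by gene with columns ``baseMean`` (mean of
    normalised counts), ``log2FoldChange`` (test group over reference),
    ``pvalue`` and ``padj`` (Benjamini–Hochberg). Genes with zero counts
    everywhere are reported as NaN and excluded from testing and from the
    FDR adjustment.
    """
    cm = collapse_replicates(cm)
    labels = cm.subject_group.loc[cm.counts.columns]
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    if reference is None:
        reference = sorted(uniq)[0]
    test = [g for g in uniq if g != reference][0]
    for g in (reference, test):
        if int((labels == g).sum()) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    sf = size_factors(cm.counts)
    alpha = estimate_dispersions(cm.counts, sf, labels, shrink=dispersion_shrink)

    c = cm.counts.to_numpy(dtype=float)
    s = sf.to_numpy()
    a = alpha.to_numpy()
    mask_ref = (labels == reference).to_numpy()
    mask_tst = (labels == test).to_numpy()

    nonzero = c.sum(axis=1) > 0
    base_mean = (c / s).mean(axis=1)

    m_ref = np.full(c.shape[0], np.nan)
    m_tst = np.full(c.shape[0], np.nan)
    m_ref[nonzero] = _nb_group_mean(c[nonzero][:, mask_ref], s[mask_ref], a[nonzero])
    m_tst[nonzero] = _nb_group_mean(c[nonzero][:, mask_tst], s[mask_tst], a[nonzero])

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(m_tst) - np.log2(m_ref)
        mu_r = s[mask_ref] * m_ref[:, None]
        mu_t = s[mask_tst] * m_tst[:, None]
        info_r = (mu_r / (1 + a[:, None] * mu_r)).sum(axis=1)
        info_t = (mu_t / (1 + a[:, None] * mu_t)).sum(axis=1)
        se_ln = np.sqrt(1.0 / np.maximum(info_r, 1e-12) + 1.0 / np.maximum(info_t, 1e-12))
        wald = (np.log(m_tst) - np.log(m_ref)) / se_ln
    df = c.shape[1] - 2
    pval = np.full(c.shape[0], np.nan)
    ok = nonzero & np.isfinite(wald)
    pval[ok] = 2.0 * stats.t.sf(np.abs(wald[ok]), df=df)

    padj = np.full(c.shape[0], np.nan)
    padj[ok] = bh_adjust(pval[ok])
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": np.where(nonzero, lfc, np.nan),
            "pvalue": pval,
            "padj": padj,
        },
        index=cm.counts.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log_normalized(cm: CountMatrix) -> pd.DataFrame:
    """log2(normalised count + 1) matrix, subjects × genes."""
    cm = collapse_replicates(cm)
    sf = size_factors(cm.counts)
    return np.log2(cm.counts.div(sf, axis=1) + 1.0).T


# ---------------------------------------------------------------------------
# ranked signature


def ranked_signature(
    sig: pd.DataFrame,
    counts: pd.DataFrame,
    k: int = 250,
    min_median: float = 10.0,
    use_normalized: bool = False,
    sf: pd.Series | None = None,
) -> RankedSignature:
    """Top-k up/down ranked signature after a median-expression filter.

    Genes whose median count across subjects is not strictly greater than
    ``min_median`` reads are dropped (raw counts by default; set
    ``use_normalized`` to filter on normalised counts). Remaining genes are
    sorted by log2 fold change, descending; ties are broken by smaller
    p-value, then gene identifier.
    """
    mat = counts
    if use_normalized:
        if sf is None:
            sf = size_factors(counts)
        mat = counts.div(sf, axis=1)
    med = mat.median(axis=1)
    eligible = sig.loc[sig.index.intersection(med.index[med > min_median])]
    eligible = eligible.dropna(subset=["log2FoldChange"])
    if len(eligible) < 2 * k:
        raise ValueError(
            f"only {len(eligible)} genes pass the median>{min_median} filter; "
            f"need at least {2 * k}"
        )
    order = eligible.assign(_id=eligible.index.astype(str)).sort_values(
        by=["log2FoldChange", "pvalue", "_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    genes = list(order.index)
    return RankedSignature(
        genes=genes,
        up_set=genes[:k],
        down_set=genes[-k:],
        k=k,
        median_filter_threshold=min_median,
        log2fc=order["log2FoldChange"],
    )


# ---------------------------------------------------------------------------
# PCA + LOOCV classification


def pca_classify(expr: pd.DataFrame, gene_subset) -> pd.DataFrame:
    """First two PCA coordinates of subjects on a gene subset.

    ``expr`` is a subjects × genes log-normalised matrix. Columns are centred
    (no unit scaling, matching the convention of ``prcomp`` defaults).
    """
    gene_subset = list(gene_subset)
    if len(gene_subset) < 2:
        raise ValueError("gene_subset must contain at least 2 genes")
    X = expr.loc[:, gene_subset].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    Xc = X - X.mean(axis=0)
    u, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    if X.shape[0] == 2:
        warnings.warn("only 2 subjects: PC2 is degenerate", stacklevel=2)
    coords = u[:, :2] * sv[:2]
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(coords.shape[0])])
    return pd.DataFrame(coords, index=expr.index, columns=["PC1", "PC2"])


def _logistic_predict_loo(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Held-out class predictions for every leave-one-out fold.

    Newton/IRLS on all n folds at once: fold f trains on every sample except
    f. A fixed tiny ridge keeps the Hessian invertible under quasi-separation.
    """
    n = X.shape[0]
    Z = np.column_stack([np.ones(n), X])  # n × p
    p = Z.shape[1]
    W = 1.0 - np.eye(n)  # fold × sample inclusion mask
    beta = np.zeros((n, p))
    eye = np.eye(p) * ridge
    for _ in range(30):
        eta = np.clip(beta @ Z.T, -30, 30)  # fold × sample
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = (W * (y[None, :] - mu)) @ Z - ridge * beta
        wt = W * mu * (1.0 - mu)
        H = np.einsum("fs,sp,sq->fpq", wt, Z, Z) + eye[None, :, :]
        try:
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.einsum("fpq,fq->fp", np.linalg.pinv(H), grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta_out = np.einsum("fp,fp->f", beta, Z)  # fold f scores its own held-out sample
    return (eta_out > 0).astype(int)


def loocv_logistic(coords: pd.DataFrame, labels) -> float:
    """Leave-one-out accuracy of a logistic classifier on 2-D coordinates.

    Each subject is classified (threshold 0.5) by a model fitted on all other
    subjects; the returned accuracy is the fraction classified correctly.
    """
    X = np.asarray(coords, dtype=float)
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 subjects for LOOCV")
    y = (y_raw == classes[1]).astype(int)
    pred = _logistic_predict_loo(X, y.astype(float))
    return float(np.mean(pred == y))


def permutation_null(
    coords: pd.DataFrame,
    labels,
    n_iter: int = 1000,
    seed: int | None = None,
) -> ClassifierReport:
    """Permutation test of the LOOCV accuracy under shuffled phenotypes.

    ``permutation_p`` uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_iter)`` so it can never be zero.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X = np.asarray(coords, dtype=float)
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = (y_raw == classes[1]).astype(float)
    observed = float(np.mean(_logistic_predict_loo(X, y) == y))
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        yp = rng.permutation(y)
        null[i] = np.mean(_logistic_predict_loo(X, yp) == yp)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_iter)
    n_greater = int(np.sum(null > observed))
    n_ties = int(np.sum(null == observed))
    p_rand = (n_greater + rng.uniform() * (1 + n_ties)) / (1.0 + n_iter)
    return ClassifierReport(
        loocv_accuracy=observed,
        null_scores=null,
        permutation_p=float(p),
        n_permutations=n_iter,
        permutation_p_randomized=float(p_rand),
    )
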