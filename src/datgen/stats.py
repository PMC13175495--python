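"""Similarity, diagnostic and agreement statistics for generated-vs-real
delayed-image evaluation.

Covers: PSNR / per-slice 2D SSIM / RMSE; Pearson correlation of regional
binding ratios; rank-based ROC-AUC with a paired permutation test for
comparing the AUC of real-derived and generated-derived markers; confusion
-matrix diagnostics with Wilson 95% CIs; exact McNemar; Fleiss' and Cohen's
kappa with large-sample standard errors and the z-test comparing two kappas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage.metrics import structural_similarity
from statsmodels.stats.proportion import proportion_confint


# ----------------------------------------------------------------------------
# Image similarity
# ----------------------------------------------------------------------------

@dataclass
class SimilarityReport:
    ssim: float
    psnr: float          # dB; math.inf when MSE == 0
    rmse: float
    psnr_infinite: bool
    per_slice_ssim: list[float] = field(default_factory=list)


def similarity_metrics(real: np.ndarray, gen: np.ndarray,
                       data_range: float) -> SimilarityReport:
    """PSNR, per-slice 2D SSIM (averaged over slices) and RMSE.

    PSNR uses Max = the maximum voxel intensity of the real (reference)
    volume: PSNR = 10 log10(Max^2 / MSE).  SSIM follows the standard Wang et
    al. form with an 11x11 Gaussian window (sigma 1.5), K1 = 0.01, K2 = 0.03,
    computed per axial slice and averaged.
    """
    if real.shape != gen.shape:
        raise ValueError(f"shape mismatch {real.shape} vs {gen.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    r = np.asarray(real, dtype=np.float64)
    g = np.asarray(gen, dtype=np.float64)
    mse = float(np.mean((r - g) ** 2))
    rmse = math.sqrt(mse)
    if mse == 0.0:
        return SimilarityReport(ssim=1.0, psnr=math.inf, rmse=0.0,
                                psnr_infinite=True,
                                per_slice_ssim=[1.0] * real.shape[0])
    peak = float(r.max())
    # a reference with no positive signal has no defined peak ratio
    psnr = 10.0 * math.log10(peak ** 2 / mse) if peak > 0 else math.nan
    # the 11x11 window shrinks (to the largest odd fit) on very small slices
    win = min(11, min(real.shape[1:]) // 2 * 2 - 1)
    win = max(win, 1)
    per_slice = [
        float(structural_similarity(
            r[z], g[z], data_range=data_range, gaussian_weights=True,
            sigma=1.5, win_size=win, use_sample_covariance=False,
            K1=0.01, K2=0.03))
        for z in range(real.shape[0])
    ]
    return SimilarityReport(ssim=float(np.mean(per_slice)), psnr=psnr,
                            rmse=rmse, psnr_infinite=False,
                            per_slice_ssim=per_slice)


# ----------------------------------------------------------------------------
# Correlation and ROC
# ----------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Product-moment correlation; requires n >= 3 and non-zero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    return float(sps.pearsonr(x, y).statistic)


@dataclass
class RocResult:
    auc: float
    p_permutation: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def roc_auc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC: the fraction of (positive, negative) pairs
    in which the positive scores higher, ties counting one half.

    Callers whose marker decreases with disease (e.g. striatal SNBR for DP)
    pass negated scores so that an informative marker yields AUC >= 0.5.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


@dataclass
class AucComparison:
    roc_a: RocResult
    roc_b: RocResult
    delta: float
    p_value: float
    n_permutations: int
    seed: int


def auc_permutation_test(scores_a, scores_b, labels, n_permutations: int = 10000,
                         seed: int = 0) -> AucComparison:
    """Paired permutation test for a difference in AUC.

    ``scores_a`` and ``scores_b`` are the same marker measured on the same
    subjects from two sources (real- and generated-derived).  The null
    distribution of |AUC_a - AUC_b| is built by independently swapping the
    two sources within each subject with probability one half;
    p = (1 + #{delta* >= delta}) / (B + 1).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if not (a.shape == b.shape == labels.shape) or a.ndim != 1:
        raise ValueError("scores_a, scores_b, labels must be 1-D of equal length")
    auc_a = roc_auc(a, labels)
    auc_b = roc_auc(b, labels)
    delta = abs(auc_a - auc_b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        swap = rng.random(a.size) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        if abs(roc_auc(pa, labels) - roc_auc(pb, labels)) >= delta - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return AucComparison(
        roc_a=RocResult(auc_a, p, n_permutations, seed),
        roc_b=RocResult(auc_b, p, n_permutations, seed),
        delta=delta, p_value=p, n_permutations=n_permutations, seed=seed)


# ----------------------------------------------------------------------------
# Diagnostic metrics from confusion counts
# ----------------------------------------------------------------------------

@dataclass
class ProportionCI:
    point: float            # proportion in [0, 1]; nan when undefined
    lower: float
    upper: float
    defined: bool = True


@dataclass
class DiagnosticTable:
    tn: int
    fp: int
    fn: int
    tp: int
    accuracy: ProportionCI
    sensitivity: ProportionCI
    specificity: ProportionCI


def _wilson(count: int, nobs: int) -> ProportionCI:
    if nobs == 0:
        return ProportionCI(float("nan"), float("nan"), float("nan"), False)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return ProportionCI(count / nobs, float(lo), float(hi))


def diagnostic_metrics(tn: int, fp: int, fn: int, tp: int) -> DiagnosticTable:
    """Accuracy, sensitivity and specificity with Wilson score 95% CIs.

    A metric whose denominator is zero is flagged undefined rather than
    raising, matching how such cells are reported in practice.
    """
    for name, v in (("tn", tn), ("fp", fp), ("fn", fn), ("tp", tp)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    return DiagnosticTable(
        tn=tn, fp=fp, fn=fn, tp=tp,
        accuracy=_wilson(tp + tn, tp + tn + fp + fn),
        sensitivity=_wilson(tp, tp + fn),
        specificity=_wilson(tn, tn + fp))


def mcnemar_exact(b: int, c: int) -> float:
    """Exact binomial two-sided McNemar p on the discordant pairs.

    b and c are the two discordant counts; under H0 each discordant pair
    falls either way with probability one half.  Returns 1.0 when b + c = 0.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(sps.binomtest(min(b, c), n, 0.5).pvalue)


# ----------------------------------------------------------------------------
# Agreement statistics
# ----------------------------------------------------------------------------

@dataclass
class AgreementResult:
    kappa: float
    se: float
    n_subjects: int


def fleiss_kappa(ratings: np.ndarray) -> AgreementResult:
    """Fleiss' kappa from a subjects x categories count table.

    Every subject must be rated by the same number of raters.  The standard
    error is the large-sample H0 formula of Fleiss (1971), suitable for the
    z-comparison of two kappas.
    """
    table = np.asarray(ratings, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("ratings must be a 2-D table with >= 2 subjects")
    counts = table.sum(axis=1)
    n = counts[0]
    if not np.all(counts == n):
        raise ValueError("every subject must have the same number of raters")
    if n < 2:
        raise ValueError("need at least 2 raters")
    big_n = table.shape[0]
    p_j = table.sum(axis=0) / (big_n * n)
    p_i = ((table ** 2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_e = float((p_j ** 2).sum())
    if p_e >= 1.0:  # all ratings in one category: agreement is trivially 1
        return AgreementResult(1.0, 0.0, big_n)
    kappa = (p_bar - p_e) / (1.0 - p_e)
    q_j = 1.0 - p_j
    spq = float((p_j * q_j).sum())
    se = (math.sqrt(2.0 / (big_n * n * (n - 1)))
          * math.sqrt(abs(spq ** 2 - float((p_j * q_j * (q_j - p_j)).sum())))
          / spq)
    return AgreementResult(float(kappa), float(se), big_n)


def cohen_kappa(r1, r2) -> AgreementResult:
    """Cohen's kappa between two raters (or one rater on two image sources).

    SE is the common large-sample approximation
    sqrt(po (1 - po) / (N (1 - pe)^2)).
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rating vectors must be 1-D of equal length")
    n = r1.size
    if n < 2:
        raise ValueError("need at least 2 rated subjects")
    cats = np.unique(np.concatenate([r1, r2]))
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((cats.size, cats.size))
    for a, b in zip(r1, r2):
        table[idx[a], idx[b]] += 1
    po = float(np.trace(table)) / n
    pe = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / n ** 2
    if pe >= 1.0:
        return AgreementResult(1.0, 0.0, n)
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(max(po * (1.0 - po), 0.0) / (n * (1.0 - pe) ** 2))
    return AgreementResult(float(kappa), float(se), n)


def kappa_ztest(k1: float, se1: float, k2: float, se2: float) -> tuple[float, float]:
    """z and two-sided p for the difference of two independent kappas."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (k1 - k2) / math.sqrt(se1 ** 2 + se2 ** 2)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return float(z), p
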