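"""Statistical calling for DamID count data.

A self-contained negative-binomial Wald test stands in for DESeq2:
median-of-ratios size factors, method-of-moments dispersions shrunk
toward a fitted mean-dispersion trend, and a per-bin two-group GLM with
a Wald test on the fold change, Benjamini-Hochberg corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .damid_quant import NormalizedRatioTrack

_MIN_DISP = 1e-8
_MAX_DISP = 10.0


@dataclass
class DifferentialAssociationParams:
    fdr: float = 0.05
    #: |delta log2| threshold; 0.58 corresponds to a 1.5-fold change.
    min_abs_delta_log2: float = 0.58

    def __post_init__(self):
        if self.fdr <= 0 or self.min_abs_delta_log2 <= 0:
            raise ValueError("fdr and min_abs_delta_log2 must be positive")


@dataclass
class EnrichmentTable:
    """Per-bin (or per-gene) fusion-vs-control test results."""

    base_mean: np.ndarray
    log2_fold: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    enriched: np.ndarray  # q < fdr AND fusion above control
    fdr: float
    method: str = "nb_wald"

    def __len__(self) -> int:
        return len(self.p_value)

    @property
    def n_enriched(self) -> int:
        return int(self.enriched.sum())


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Standard BH step-up q-values.

    q_(i) = min_{j >= i} p_(j) * n / j over the sorted p-values; the
    result is monotone non-decreasing in p and never below p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors from a (bins x samples) count matrix.

    Uses only rows with all-positive counts; falls back to library-size
    scaling when no such row exists.
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if positive.sum() >= 1:
        logs = np.log(counts[positive])
        log_geo = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - log_geo, axis=0))
    else:
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    return sf


def _dispersion_estimates(norm: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Method-of-moments per-row dispersions, shrunk toward a trend.

    MoM: alpha = (pooled within-group variance - mean) / mean^2 on
    normalized counts.  A trend alpha(mu) = a0 + a1/mu is fitted by least
    squares; the working dispersion is the maximum of the per-row
    estimate blended with the trend and the trend itself, which errs on
    the conservative side for small replicate numbers.
    """
    mu = norm.mean(axis=1)
    ss = np.zeros(norm.shape[0])
    df = 0
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        if sub.shape[1] >= 2:
            ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
            df += sub.shape[1] - 1
    if df == 0:  # single replicate per side: Poisson fallback upstream
        return np.zeros(norm.shape[0])
    var = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var - mu) / np.square(mu)
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
    alpha_mom = np.clip(alpha_mom, _MIN_DISP, _MAX_DISP)

    ok = mu > 0
    if ok.sum() >= 10:
        X = np.stack([np.ones(ok.sum()), 1.0 / mu[ok]], axis=1)
        coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
    else:
        a0, a1 = float(np.median(alpha_mom)), 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-12), a0)
    trend = np.clip(trend, _MIN_DISP, _MAX_DISP)

    blended = np.exp(0.5 * (np.log(alpha_mom) + np.log(trend)))
    return np.clip(np.maximum(blended, trend), _MIN_DISP, _MAX_DISP)


def _nb_glm_wald(
    counts: np.ndarray,
    sf: np.ndarray,
    cond: np.ndarray,
    alpha: np.ndarray,
    n_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row IRLS for a two-group NB GLM with log link.

    Returns (beta1, se1): the group contrast on the natural-log scale and
    its Wald standard error.  Size factors enter as offsets.
    """
    n_rows, n_samp = counts.shape
    x = cond.astype(float)
    q = counts / sf
    mu_c = q[:, cond == 0].mean(axis=1)
    mu_f = q[:, cond == 1].mean(axis=1)
    b0 = np.log(np.maximum(mu_c, 1e-8))
    b1 = np.log(np.maximum(mu_f, 1e-8)) - b0
    a = alpha[:, None]
    for _ in range(n_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :]
        mu = sf[None, :] * np.exp(np.clip(eta, -50, 50))
        mu = np.maximum(mu, 1e-10)
        w = mu / (1.0 + a * mu)
        z = eta + (counts - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = sw * swx - swx * swx  # x^2 = x for an indicator
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        nb0 = (swx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        nb0 = np.clip(nb0, -50, 50)
        nb1 = np.clip(nb1, -50, 50)
        if np.max(np.abs(nb0 - b0)) < tol and np.max(np.abs(nb1 - b1)) < tol:
            b0, b1 = nb0, nb1
            break
        b0, b1 = nb0, nb1
    eta = b0[:, None] + b1[:, None] * x[None, :]
    mu = np.maximum(sf[None, :] * np.exp(np.clip(eta, -50, 50)), 1e-10)
    w = mu / (1.0 + a * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    det = np.maximum(sw * swx - swx * swx, 1e-300)
    se1 = np.sqrt(np.maximum(sw / det, 0.0))
    return b1, se1


def nb_enrichment_test(
    fusion_reps: Sequence[np.ndarray],
    control_reps: Sequence[np.ndarray],
    fdr: float = 0.05,
) -> EnrichmentTable:
    """Per-bin negative-binomial Wald test of fusion vs control counts.

    The two-sided p-value is BH-corrected over all bins; the enrichment
    flag additionally requires the fold estimate to favor the fusion.
    With a single replicate per side a Poisson model is used and flagged
    in ``method``.
    """
    fusion = np.stack([np.asarray(r, dtype=float) for r in fusion_reps], axis=1)
    control = np.stack([np.asarray(r, dtype=float) for r in control_reps], axis=1)
    if fusion.shape[0] != control.shape[0]:
        raise ValueError("fusion and control replicate vectors differ in length")
    counts = np.concatenate([control, fusion], axis=1)
    cond = np.concatenate(
        [np.zeros(control.shape[1], dtype=int), np.ones(fusion.shape[1], dtype=int)]
    )
    sf = median_of_ratios_size_factors(counts)
    norm = counts / sf
    base_mean = norm.mean(axis=1)

    poisson_mode = fusion.shape[1] < 2 and control.shape[1] < 2
    if poisson_mode:
        alpha = np.zeros(counts.shape[0])
        method = "poisson_wald"
    else:
        alpha = _dispersion_estimates(norm, cond)
        method = "nb_wald"

    nonzero = counts.sum(axis=1) > 0
    beta1 = np.zeros(counts.shape[0])
    se1 = np.full(counts.shape[0], np.inf)
    if nonzero.any():
        b1, s1 = _nb_glm_wald(
            counts[nonzero], sf, cond, alpha[nonzero]
        )
        beta1[nonzero] = b1
        se1[nonzero] = s1

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se1 > 0, beta1 / se1, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(nonzero, p, 1.0)  # all-zero rows: p = 1 by convention
    q = benjamini_hochberg(p)
    log2_fold = beta1 / np.log(2.0)
    enriched = (q < fdr) & (log2_fold > 0) & nonzero
    return EnrichmentTable(base_mean, log2_fold, p, q, enriched, fdr, method)


@dataclass
class AccessibilityResult:
    """Differential accessibility between two Dam-only sample groups."""

    table_1_over_2: EnrichmentTable
    table_2_over_1: EnrichmentTable
    n_bins_up_in_1: int
    n_bins_up_in_2: int
    percent_genome_1: float
    percent_genome_2: float


def percent_of_genome(
    n_bins: int, bin_size: int, genome_length: int, ndigits: int | None = None
) -> float:
    """Exact percent of the genome covered by *n_bins* bins."""
    pct = 100.0 * (n_bins * bin_size) / genome_length
    return pct if ndigits is None else round(pct, ndigits)


def differential_accessibility(
    tissue1_reps: Sequence[np.ndarray],
    tissue2_reps: Sequence[np.ndarray],
    bin_size: int,
    genome_length: int,
    fdr: float = 0.05,
) -> AccessibilityResult:
    """Bins more accessible in either Dam-only tissue, with genome percents."""
    t12 = nb_enrichment_test(tissue1_reps, tissue2_reps, fdr=fdr)
    t21 = nb_enrichment_test(tissue2_reps, tissue1_reps, fdr=fdr)
    n1, n2 = t12.n_enriched, t21.n_enriched
    return AccessibilityResult(
        t12,
        t21,
        n1,
        n2,
        percent_of_genome(n1, bin_size, genome_length),
        percent_of_genome(n2, bin_size, genome_length),
    )


@dataclass
class DifferentialAssociationResult:
    a_preferential: np.ndarray  # bin indices
    b_preferential: np.ndarray
    delta: np.ndarray  # trackA - trackB per bin
    arm_summary: dict = field(default_factory=dict)


def differential_association(
    enrich_a: EnrichmentTable,
    enrich_b: EnrichmentTable,
    track_a: NormalizedRatioTrack,
    track_b: NormalizedRatioTrack,
    params: DifferentialAssociationParams | None = None,
    bin_labels: Sequence[str] | None = None,
) -> DifferentialAssociationResult:
    """Bins preferentially bound by protein A or B.

    A-preferential bins are enriched for A (vs its control) with
    track(A) - track(B) strictly above the delta threshold; symmetric
    for B, so the two sets are disjoint.  If arm/center bin labels are
    supplied, each set gets a binomial test of its arm fraction against
    the genome-wide autosomal arm fraction.
    """
    params = params or DifferentialAssociationParams()
    if len(track_a.values) != len(track_b.values) or len(enrich_a) != len(
        track_a.values
    ):
        raise ValueError("inputs are on different bin grids")
    delta = track_a.values - track_b.values
    a_pref = np.flatnonzero(enrich_a.enriched & (delta > params.min_abs_delta_log2))
    b_pref = np.flatnonzero(enrich_b.enriched & (-delta > params.min_abs_delta_log2))

    arm_summary: dict = {}
    if bin_labels is not None:
        labels = np.asarray(bin_labels)
        autosomal = labels != "not_applicable"
        n_arm_total = int((labels == "arm").sum())
        n_auto = int(autosomal.sum())
        p_arm = n_arm_total / n_auto if n_auto else np.nan
        for name, idx in (("a_preferential", a_pref), ("b_preferential", b_pref)):
            sel = labels[idx]
            n_sel_auto = int((sel != "not_applicable").sum())
            n_sel_arm = int((sel == "arm").sum())
            entry = {
                "n_bins": len(idx),
                "n_autosomal": n_sel_auto,
                "n_arm": n_sel_arm,
                "arm_fraction": n_sel_arm / n_sel_auto if n_sel_auto else np.nan,
                "null_arm_fraction": p_arm,
            }
            if n_sel_auto > 0 and np.isfinite(p_arm):
                entry["binom_p"] = stats.binomtest(
                    n_sel_arm, n_sel_auto, p_arm, alternative="two-sided"
                ).pvalue
            arm_summary[name] = entry
    return DifferentialAssociationResult(a_pref, b_pref, delta, arm_summary)


@dataclass
class GroupComparison:
    groups: list[str]
    medians: dict[str, float]
    quartiles: dict[str, tuple[float, float]]
    n: dict[str, int]
    pairs: list[tuple[str, str]]
    p_values: np.ndarray
    q_values: np.ndarray


def _rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 50) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with continuity and tie correction.
    """
    if (
        len(x) <= exact_max_n
        and len(y) <= exact_max_n
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    ):
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def arm_center_compare(
    values: np.ndarray,
    labels: Sequence[str],
) -> GroupComparison:
    """Per-group distribution summaries and BH-corrected pairwise
    Wilcoxon rank-sum tests over arm/center (or finer) labels.

    Bins labelled ``not_applicable`` are dropped; groups with fewer than
    2 bins yield missing (NaN) p-values for their pairs.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = labels != "not_applicable"
    values, labels = values[keep], labels[keep]
    groups = sorted(set(labels.tolist()))
    by_group = {g: values[labels == g] for g in groups}
    medians = {g: float(np.median(v)) if len(v) else np.nan for g, v in by_group.items()}
    quartiles = {
        g: (
            (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
            if len(v)
            else (np.nan, np.nan)
        )
        for g, v in by_group.items()
    }
    ns = {g: int(len(v)) for g, v in by_group.items()}
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    pvals = []
    for a, b in pairs:
        if ns[a] < 2 or ns[b] < 2:
            pvals.append(np.nan)
        else:
            pvals.append(_rank_sum_p(by_group[a], by_group[b]))
    pvals = np.asarray(pvals)
    defined = ~np.isnan(pvals)
    qvals = np.full_like(pvals, np.nan)
    if defined.any():
        qvals[defined] = benjamini_hochberg(pvals[defined])
    return GroupComparison(groups, medians, quartiles, ns, pairs, pvals, qvals)
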