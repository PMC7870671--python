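"""Reliability statistics for scan-subsampling of the VI score.

Implements the study's battery against the 9-scan reference standard
(the mean VI over all analysable scans of a volume):

* :func:`icc_absolute_agreement` — two-way random-effects, absolute-
  agreement, single-measure ICC (McGraw & Wong ICC(A,1) / Shrout–Fleiss
  ICC(2,1)) from ANOVA mean squares, with the F-based 95% CI;
* :func:`deviation_from_reference` — median and IQR of absolute per-eye
  differences, plus Bland–Altman 95% limits of agreement
  (mean ± 1.96 × SD of the signed differences);
* :func:`bland_altman_regression` — OLS of signed difference on pairwise
  mean (proportional-bias check), excluding eyes whose pairwise mean
  exceeds the sensitivity range (default > 0.1);
* :func:`paired_wilcoxon_holm` — paired Wilcoxon signed-rank tests over
  a family of scheme comparisons with Holm step-down adjustment;
* :func:`split_roc` — discrimination of eyes above vs below the median
  (or a quartile) of the reference score, AUC with DeLong 95% CI;
* :func:`run_reliability_analysis` — the full report.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateTestWarning,
    InsufficientDataError,
    UndefinedAUCError,
    ValidationError,
)
from .selection import SCHEME_NAMES, scheme_mean_vi, select_scans

__all__ = [
    "ICCResult",
    "AgreementResult",
    "BlandAltmanRegression",
    "PairwiseTestResult",
    "ROCResult",
    "AnalysisConfig",
    "ReliabilityReport",
    "icc_absolute_agreement",
    "deviation_from_reference",
    "bland_altman_regression",
    "paired_wilcoxon_holm",
    "split_roc",
    "scheme_score_table",
    "run_reliability_analysis",
]


# --------------------------------------------------------------------------
# ICC


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    n_subjects: int
    n_raters: int
    n_dropped: int = 0


def _anova_mean_squares(x: np.ndarray):
    """Two-way ANOVA mean squares of an n × k matrix (rows, cols, error)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_absolute_agreement(
    score_matrix, model: str = "absolute_agreement", alpha: float = 0.05
) -> ICCResult:
    """Single-measure ICC of an eyes × scans score matrix.

    Default is the two-way random-effects absolute-agreement form
    ICC(2,1): scans are treated as a random sample of "raters" and
    systematic per-scan offsets count against agreement. The
    ``"consistency"`` variant (ICC(3,1)) is available. Rows containing
    missing values are dropped and counted in ``n_dropped``. The 95% CI
    follows the published F-based formulas with Satterthwaite degrees of
    freedom.
    """
    x = np.asarray(score_matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("score_matrix must be 2D (eyes × scans)")
    complete = ~np.isnan(x).any(axis=1)
    n_dropped = int((~complete).sum())
    x = x[complete]
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(f"need >= 2 complete rows and >= 2 columns, got {n} × {k}")

    msr, msc, mse = _anova_mean_squares(x)

    if model == "consistency":
        denom = msr + (k - 1) * mse
        icc = 0.0 if denom == 0 else (msr - mse) / denom
        if mse == 0:
            lo = hi = icc
        else:
            f = msr / mse
            fl = f / sps.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
            fu = f * sps.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif model == "absolute_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = 0.0 if denom == 0 else (msr - mse) / denom
        if mse == 0 and msc == 0:
            lo = hi = icc
        else:
            a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
            b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
            if not np.isfinite(a):
                lo = hi = icc
            else:
                v_num = (a * msc + b * mse) ** 2
                v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                v = v_num / v_den
                f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
                f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
                hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    else:
        raise ValidationError("model must be 'absolute_agreement' or 'consistency'")

    lo, hi = float(min(lo, hi)), float(max(lo, hi))
    lo = min(lo, float(icc))
    hi = max(hi, float(icc))
    return ICCResult(
        icc=float(icc),
        ci_low=lo,
        ci_high=hi,
        model=model,
        n_subjects=n,
        n_raters=k,
        n_dropped=n_dropped,
    )


# --------------------------------------------------------------------------
# Agreement with the reference standard


@dataclass(frozen=True)
class AgreementResult:
    scheme: str
    median_abs_diff: float
    iqr: float
    loa_low: float
    loa_high: float
    mean_diff: float
    n: int


def deviation_from_reference(scheme_scores, reference_scores, scheme: str = "") -> AgreementResult:
    """Per-eye deviation of a scheme's mean VI from the reference.

    Median and IQR summarise the absolute differences; the 95% limits of
    agreement come from the signed differences as mean ± 1.96 × SD
    (sample SD, ddof = 1).
    """
    s = np.asarray(scheme_scores, dtype=float)
    r = np.asarray(reference_scores, dtype=float)
    if s.shape != r.shape or s.ndim != 1:
        raise ValidationError("scheme and reference scores must be aligned 1D arrays")
    d = s - r
    abs_d = np.abs(d)
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    q75, q25 = np.percentile(abs_d, [75, 25])
    return AgreementResult(
        scheme=scheme,
        median_abs_diff=float(np.median(abs_d)),
        iqr=float(q75 - q25),
        loa_low=mean_d - 1.96 * sd,
        loa_high=mean_d + 1.96 * sd,
        mean_diff=mean_d,
        n=int(d.size),
    )


@dataclass(frozen=True)
class BlandAltmanRegression:
    scheme: str
    slope: float
    intercept: float
    p_value: float
    n_excluded: int
    n_used: int
    exclusion_threshold: float


def bland_altman_regression(
    scheme_scores, reference_scores, exclusion_threshold: float = 0.1, scheme: str = ""
) -> BlandAltmanRegression:
    """Proportional-bias check: OLS of signed difference on pairwise mean.

    Eyes whose pairwise mean exceeds ``exclusion_threshold`` (outside the
    score's sensitivity range, default 0.1) are excluded before fitting.
    """
    s = np.asarray(scheme_scores, dtype=float)
    r = np.asarray(reference_scores, dtype=float)
    if s.shape != r.shape or s.ndim != 1:
        raise ValidationError("scheme and reference scores must be aligned 1D arrays")
    means = (s + r) / 2.0
    diffs = s - r
    keep = means <= exclusion_threshold
    n_excluded = int((~keep).sum())
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} eyes remain after excluding means > {exclusion_threshold}"
        )
    x, y = means[keep], diffs[keep]
    if np.ptp(x) == 0:
        raise InsufficientDataError("pairwise means are constant; slope undefined")
    fit = sps.linregress(x, y)
    return BlandAltmanRegression(
        scheme=scheme,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n_excluded=n_excluded,
        n_used=int(keep.sum()),
        exclusion_threshold=exclusion_threshold,
    )


# --------------------------------------------------------------------------
# Paired tests with Holm adjustment


@dataclass(frozen=True)
class PairwiseTestResult:
    scheme_a: str
    scheme_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    degenerate: bool = False


def paired_wilcoxon_holm(
    abs_diff_table: pd.DataFrame,
    comparisons,
    paired: bool = True,
) -> list[PairwiseTestResult]:
    """Wilcoxon tests over a family of scheme comparisons, Holm-adjusted.

    ``abs_diff_table`` holds one row per eye and one column per scheme
    (typically the absolute deviations from the reference standard).
    ``paired=True`` (default) uses the signed-rank test on per-eye
    differences; ``paired=False`` the unpaired rank-sum test. A
    comparison whose per-eye differences are all zero is degenerate:
    p = 1 with a :class:`DegenerateTestWarning`.
    """
    comparisons = list(comparisons)
    if not comparisons:
        raise ValidationError("comparison family is empty")
    stats_, p_raw, degen = [], [], []
    for a, b in comparisons:
        xa = abs_diff_table[a].to_numpy(dtype=float)
        xb = abs_diff_table[b].to_numpy(dtype=float)
        if paired and np.all(xa == xb):
            warnings.warn(f"all differences zero for {a} vs {b}; p = 1", DegenerateTestWarning)
            stats_.append(0.0)
            p_raw.append(1.0)
            degen.append(True)
            continue
        if paired:
            res = sps.wilcoxon(xa, xb)
        else:
            res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        stats_.append(float(res.statistic))
        p_raw.append(float(res.pvalue))
        degen.append(False)
    _, p_adj, _, _ = multipletests(p_raw, method="holm")
    return [
        PairwiseTestResult(a, b, s, pr, float(pa), dg)
        for (a, b), s, pr, pa, dg in zip(comparisons, stats_, p_raw, p_adj, degen)
    ]


# --------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class ROCResult:
    scheme: str
    auc: float
    ci_low: float
    ci_high: float
    state_variable: str
    n_positive: int
    n_negative: int


_SPLIT_Q = {"median": 0.5, "upper_quartile": 0.75, "lower_quartile": 0.25}


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float, alpha: float = 0.05):
    """DeLong variance of the AUC via mid-rank structural components."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = sps.rankdata(allv)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(1 - alpha / 2)
    return float(np.clip(auc - z * se, 0.0, 1.0)), float(np.clip(auc + z * se, 0.0, 1.0))


def split_roc(scheme_scores, reference_scores, split: str = "median", scheme: str = "") -> ROCResult:
    """AUC for detecting eyes at or above a split of the reference score.

    The state variable is ``reference >= split point`` (ties go to the
    positive class); the predictor is the scheme score. The AUC is the
    tie-corrected normalized Mann–Whitney U; the 95% CI uses DeLong.
    """
    s = np.asarray(scheme_scores, dtype=float)
    r = np.asarray(reference_scores, dtype=float)
    if s.shape != r.shape or s.ndim != 1:
        raise ValidationError("scheme and reference scores must be aligned 1D arrays")
    if np.unique(r).size < 2:
        raise ValidationError("reference scores need >= 2 distinct values")
    if split not in _SPLIT_Q:
        raise ValidationError(f"split must be one of {sorted(_SPLIT_Q)}")
    point = float(np.quantile(r, _SPLIT_Q[split]))
    labels = r >= point
    if labels.all() or not labels.any():
        raise UndefinedAUCError(f"split {split!r} leaves one class empty")
    auc = float(roc_auc_score(labels, s))
    lo, hi = _delong_ci(s[labels], s[~labels], auc)
    return ROCResult(
        scheme=scheme,
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        state_variable=split,
        n_positive=int(labels.sum()),
        n_negative=int((~labels).sum()),
    )


# --------------------------------------------------------------------------
# Full report


@dataclass(frozen=True)
class AnalysisConfig:
    """Options of the full reliability analysis."""

    schemes: tuple = ("1c", "3c", "5c", "7c", "3w")
    icc_model: str = "absolute_agreement"
    splits: tuple = ("median", "upper_quartile", "lower_quartile")
    #: Holm family: the two comparisons highlighted in the study plus the
    #: remaining adjacent central-scheme pairs
    comparisons: tuple = (("1c", "3c"), ("3c", "5c"), ("5c", "7c"), ("3w", "5c"), ("7c", "3w"))
    exclusion_threshold: float = 0.1
    paired: bool = True


@dataclass
class ReliabilityReport:
    """Machine-readable twin of the study's result tables."""

    n_eyes: int
    median_reference_vi: float
    iqr_reference_vi: float
    icc: ICCResult
    agreement: dict
    regression: dict
    wilcoxon: list
    roc: dict
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_eyes": self.n_eyes,
            "median_reference_vi": self.median_reference_vi,
            "iqr_reference_vi": self.iqr_reference_vi,
            "icc": asdict(self.icc),
            "agreement": {k: asdict(v) for k, v in self.agreement.items()},
            "regression": {k: (asdict(v) if v is not None else None) for k, v in self.regression.items()},
            "wilcoxon": [asdict(w) for w in self.wilcoxon],
            "roc": {split: [asdict(r) for r in results] for split, results in self.roc.items()},
            "flags": list(self.flags),
        }

    def table1(self) -> pd.DataFrame:
        """Deviation-from-reference table (one row per scheme)."""
        rows = [
            {
                "scheme": a.scheme,
                "median_diff": a.median_abs_diff,
                "iqr": a.iqr,
                "loa_low": a.loa_low,
                "loa_high": a.loa_high,
            }
            for a in self.agreement.values()
            if a.scheme != "9s"
        ]
        return pd.DataFrame(rows)

    def table2(self, split: str = "median") -> pd.DataFrame:
        """AUC table for one state variable (one row per scheme)."""
        rows = [
            {"scheme": r.scheme, "auc": r.auc, "ci_low": r.ci_low, "ci_high": r.ci_high}
            for r in self.roc[split]
        ]
        return pd.DataFrame(rows)


def scheme_score_table(vi_wide: pd.DataFrame, schemes=SCHEME_NAMES) -> pd.DataFrame:
    """Per-eye scheme means from an eyes × 9 per-scan VI table.

    ``vi_wide`` has one row per eye and the 9 analysable scan positions
    as columns (0..8, any column labels in positional order). Missing
    per-scan values are skipped inside each scheme mean.
    """
    if vi_wide.shape[1] != 9:
        raise ValidationError(f"expected 9 scan columns, got {vi_wide.shape[1]}")
    out = {}
    for name in schemes:
        scheme = select_scans(name)
        out[name] = [
            scheme_mean_vi(row, scheme, eye_id=str(idx)).mean_vi
            for idx, row in zip(vi_wide.index, vi_wide.to_numpy())
        ]
    return pd.DataFrame(out, index=vi_wide.index)


def run_reliability_analysis(vi_wide: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()) -> ReliabilityReport:
    """The full battery on an eyes × 9 per-scan VI table.

    The reference standard is the 9s mean. The report always includes the
    9s conservation row (identically zero deviation by construction);
    components that cannot be computed (e.g. regression after full
    exclusion) are flagged rather than fatal.
    """
    vi_wide = pd.DataFrame(vi_wide)
    flags: list[str] = []
    all_schemes = tuple(dict.fromkeys(tuple(config.schemes) + ("9s",)))
    table = scheme_score_table(vi_wide, schemes=all_schemes)
    reference = table["9s"].to_numpy()

    icc = icc_absolute_agreement(vi_wide.to_numpy(), model=config.icc_model)

    agreement, regression = {}, {}
    for name in all_schemes:
        s = table[name].to_numpy()
        agreement[name] = deviation_from_reference(s, reference, scheme=name)
        if name == "9s":
            continue
        try:
            regression[name] = bland_altman_regression(
                s, reference, exclusion_threshold=config.exclusion_threshold, scheme=name
            )
        except InsufficientDataError as exc:
            regression[name] = None
            flags.append(f"regression[{name}]: {exc}")

    if np.max(np.abs(table["9s"].to_numpy() - reference)) != 0:
        flags.append("9s conservation violated")  # pragma: no cover - wired-in check

    abs_diff = pd.DataFrame(
        {name: np.abs(table[name].to_numpy() - reference) for name in config.schemes},
        index=table.index,
    )
    if float(abs_diff.to_numpy().max()) == 0.0:
        flags.append("degenerate cohort: all schemes identical to reference")
    wilcoxon = paired_wilcoxon_holm(abs_diff, config.comparisons, paired=config.paired)

    roc: dict[str, list[ROCResult]] = {}
    for split in config.splits:
        try:
            roc[split] = [
                split_roc(table[name].to_numpy(), reference, split=split, scheme=name)
                for name in config.schemes
            ]
        except (UndefinedAUCError, ValidationError) as exc:
            roc[split] = []
            flags.append(f"roc[{split}]: {exc}")

    q75, q25 = np.percentile(reference, [75, 25])
    return ReliabilityReport(
        n_eyes=int(vi_wide.shape[0]),
        median_reference_vi=float(np.median(reference)),
        iqr_reference_vi=float(q75 - q25),
        icc=icc,
        agreement=agreement,
        regression=regression,
        wilcoxon=wilcoxon,
        roc=roc,
        flags=flags,
    )
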