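"""Method-comparison statistics for CDL measurement studies.

Covers the comparison stage of a multi-method CDL study: per-method
summary rows (CDL, coverage and predicted insertion angle), one-way ANOVA
across methods, Dunnett many-to-one contrasts against the reference
method, Pearson correlations with a dependent-correlation comparison
(Hotelling-Williams), and two-rater ICC(2,1) inter-rater reliability with
poor/fair/good/excellent banding.

The Dunnett adjusted p-values and simultaneous confidence intervals are
computed from the one-factor representation of the equicorrelated
multivariate t distribution by deterministic numerical integration
(Gauss-Hermite in the shared normal factor, adaptive quadrature in the
pooled-sd chi factor), so results are reproducible to ~1e-8 rather than
Monte-Carlo noisy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats as sps
from scipy.integrate import quad
from scipy.optimize import brentq

from .estimators import ElectrodeSpec, predict_cc

__all__ = [
    "StatsError",
    "SummaryRow",
    "AnovaResult",
    "DunnettResult",
    "CorrelationResult",
    "ReliabilityResult",
    "summarize",
    "anova_oneway",
    "dunnett_vs_control",
    "dunnett_critical_value",
    "pearson",
    "compare_dependent_correlations",
    "icc_agreement",
    "icc_category",
    "build_report",
    "report_to_markdown",
]


class StatsError(ValueError):
    pass


#: reliability bands: lower edge (inclusive) -> label, checked top-down
DEFAULT_ICC_BANDS = ((0.75, "excellent"), (0.60, "good"),
                     (0.40, "fair"), (float("-inf"), "poor"))


@dataclass(frozen=True)
class SummaryRow:
    method: str
    n: int
    mean_cdl_mm: float
    sd_cdl_mm: float
    mean_cc_percent: float
    sd_cc_percent: float
    mean_ia_deg: float
    sd_ia_deg: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class DunnettResult:
    """One many-to-one contrast; mean_difference = control - group.

    Positive differences mean the group underestimates the reference.
    """

    label: str
    mean_difference_mm: float
    ci95_mm: tuple
    p_adjusted: float
    statistic: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    model_label: str
    category: str


# --------------------------------------------------------------------------
# summaries


def summarize(table: pd.DataFrame,
              electrode: ElectrodeSpec = ElectrodeSpec(),
              theta_full_deg: float = 900.0) -> list[SummaryRow]:
    """Per-method mean/SD of CDL, coverage and predicted insertion angle.

    Coverage and IA are computed per specimen (mean of ratios, not ratio
    of means) so that mean_ia = (theta_full/100) * mean_cc holds exactly.
    Expects one row per (specimen, method): filter to a single rater
    first. SDs use the n-1 denominator.
    """
    rows = []
    for method, grp in table.groupby("method", sort=False):
        if grp["specimen_id"].duplicated().any():
            raise StatsError(
                f"method {method!r} has several rows per specimen; "
                "filter to one rater before summarising")
        if len(grp) < 2:
            raise StatsError(f"method {method!r} needs >= 2 specimens")
        cdl = grp["cdl_mm"].to_numpy(dtype=float)
        cc = np.array([predict_cc(v, electrode, theta_full_deg).cc_percent
                       for v in cdl])
        ia = cc * theta_full_deg / 100.0
        rows.append(SummaryRow(
            method=method, n=len(cdl),
            mean_cdl_mm=float(cdl.mean()), sd_cdl_mm=float(cdl.std(ddof=1)),
            mean_cc_percent=float(cc.mean()), sd_cc_percent=float(cc.std(ddof=1)),
            mean_ia_deg=float(ia.mean()), sd_ia_deg=float(ia.std(ddof=1)),
        ))
    return rows


# --------------------------------------------------------------------------
# ANOVA + Dunnett


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict:
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(clean) < 2:
        raise StatsError("need at least 2 groups")
    for k, v in clean.items():
        if len(v) < 2:
            raise StatsError(f"group {k!r} needs at least 2 values")
        if not np.all(np.isfinite(v)):
            raise StatsError(f"group {k!r} has non-finite values")
    return clean


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA across the method groups."""
    clean = _check_groups(groups)
    values = list(clean.values())
    k = len(values)
    N = sum(len(v) for v in values)
    grand = np.concatenate(values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    ss_between = sum(len(v) * (v.mean() - grand.mean()) ** 2 for v in values)
    df_b, df_w = k - 1, N - k
    if ss_within <= 1e-300 * max(ss_between, 1.0):
        if ss_between <= 1e-300:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=float("inf"), df_between=df_b, df_within=df_w,
                           p=0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


_GH_NODES, _GH_WEIGHTS = hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def _dunnett_family_prob(q: float, df: int, lambdas: np.ndarray) -> float:
    """P(max_i |T_i| <= q) for many-to-one t statistics.

    T_i share the control mean and pooled sd: T_i = (Z_i' + lam_i Z0)/U
    with corr(T_i, T_j) = lam_i lam_j, U = chi_df/sqrt(df). Integrates
    the shared factor Z0 by 80-node Gauss-Hermite and U by adaptive
    quadrature against the chi density.
    """
    if q <= 0:
        return 0.0
    lam = np.asarray(lambdas, dtype=float)
    sig = np.sqrt(1.0 - lam ** 2)
    z = _GH_NODES[:, None]  # (nodes, 1)

    chi = sps.chi(df, scale=1.0 / np.sqrt(df))

    def inner(u: float) -> float:
        upper = (q * u + lam * z) / sig
        lower = (-q * u + lam * z) / sig
        probs = sps.norm.cdf(upper) - sps.norm.cdf(lower)
        return float(np.sum(_GH_WEIGHTS * np.prod(probs, axis=1)))

    val, _ = quad(lambda u: chi.pdf(u) * inner(u), 0.0, chi.ppf(1 - 1e-12),
                  epsabs=1e-10, epsrel=1e-10, limit=200)
    return min(val, 1.0)


def dunnett_critical_value(df: int, lambdas: np.ndarray,
                           alpha: float = 0.05) -> float:
    """Two-sided equicoordinate critical point q with family prob 1-alpha."""
    return brentq(lambda q: _dunnett_family_prob(q, df, lambdas) - (1 - alpha),
                  0.1, 20.0, xtol=1e-10)


def dunnett_vs_control(groups: Mapping[str, Sequence[float]],
                       control_label: str,
                       alpha: float = 0.05) -> list[DunnettResult]:
    """Dunnett many-to-one comparisons against the control group.

    Returns, per non-control group, the mean difference (control - group),
    the simultaneous two-sided (1-alpha) confidence interval and the
    multiplicity-adjusted p-value. Balanced and unbalanced designs use the
    same one-factor integral (the correlation structure of many-to-one
    contrasts is exactly lam_i lam_j in both cases).
    """
    clean = _check_groups(groups)
    if control_label not in clean:
        raise StatsError(f"control group {control_label!r} missing")
    control = clean[control_label]
    others = {k: v for k, v in clean.items() if k != control_label}
    if not others:
        raise StatsError("need at least one non-control group")
    N = sum(len(v) for v in clean.values())
    k = len(clean)
    df = N - k
    s2 = sum(((v - v.mean()) ** 2).sum() for v in clean.values()) / df
    n0 = len(control)
    lambdas = np.array([np.sqrt(len(v) / (len(v) + n0))
                        for v in others.values()])
    qcrit = dunnett_critical_value(df, lambdas, alpha)
    results = []
    for i, (label, v) in enumerate(others.items()):
        se = np.sqrt(s2 * (1.0 / len(v) + 1.0 / n0))
        diff = control.mean() - v.mean()
        tstat = diff / se
        p_adj = 1.0 - _dunnett_family_prob(abs(tstat), df, lambdas)
        half = qcrit * se
        results.append(DunnettResult(
            label=label,
            mean_difference_mm=float(diff),
            ci95_mm=(float(diff - half), float(diff + half)),
            p_adjusted=float(min(max(p_adj, 0.0), 1.0)),
            statistic=float(tstat),
        ))
    return results


# --------------------------------------------------------------------------
# correlations


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=len(x))


def compare_dependent_correlations(r_jk: float, r_jh: float, r_kh: float,
                                   n: int) -> tuple[float, float]:
    """Hotelling-Williams test for two dependent correlations.

    Compares corr(j,k) and corr(j,h) sharing variable j (here: the
    reference CDL correlated with two competing methods k and h), given
    corr(k,h) and the common sample size. Returns (t, two-sided p) with
    n - 3 degrees of freedom.
    """
    for r in (r_jk, r_jh, r_kh):
        if not -1.0 < r < 1.0:
            raise StatsError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise StatsError("need n >= 4")
    det = (1.0 - r_jk ** 2 - r_jh ** 2 - r_kh ** 2
           + 2.0 * r_jk * r_jh * r_kh)
    rbar = 0.5 * (r_jk + r_jh)
    denom = (2.0 * det * (n - 1) / (n - 3)
             + rbar ** 2 * (1.0 - r_kh) ** 3)
    if denom <= 0:
        raise StatsError("degenerate correlation configuration")
    t = (r_jk - r_jh) * np.sqrt((n - 1) * (1.0 + r_kh) / denom)
    p = 2.0 * float(sps.t.sf(abs(t), n - 3))
    return float(t), min(p, 1.0)


# --------------------------------------------------------------------------
# reliability


def icc_agreement(ratings: np.ndarray,
                  bands=DEFAULT_ICC_BANDS) -> ReliabilityResult:
    """Two-way random-effects absolute-agreement single-rater ICC(2,1).

    ``ratings`` is (n_specimens, n_raters), complete. Computed from the
    two-way ANOVA mean squares:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise StatsError("ratings must be (specimens, >=2 raters)")
    n, k = X.shape
    if n < 5:
        raise StatsError("need at least 5 specimens")
    if not np.all(np.isfinite(X)):
        raise StatsError("ratings must be complete and finite")
    grand = X.mean()
    if np.allclose(X, grand):
        raise StatsError("zero total variance: ICC undefined")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((X - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ReliabilityResult(icc=float(icc),
                             model_label="ICC(2,1) absolute agreement",
                             category=icc_category(float(icc), bands))


def icc_category(icc: float, bands=DEFAULT_ICC_BANDS) -> str:
    """Reliability label: < .40 poor, .40-.59 fair, .60-.74 good, >= .75 excellent."""
    if icc > 1.0:
        raise StatsError("ICC cannot exceed 1")
    for edge, label in bands:
        if icc >= edge:
            return label
    return bands[-1][1]


# --------------------------------------------------------------------------
# report


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def build_report(summary: list[SummaryRow] | None = None,
                 anova: AnovaResult | None = None,
                 dunnett: list[DunnettResult] | None = None,
                 correlations: Mapping[str, CorrelationResult] | None = None,
                 dependent_correlation_tests: Mapping[str, tuple] | None = None,
                 reliability: Mapping[str, ReliabilityResult] | None = None,
                 notes: Mapping[str, str] | None = None) -> dict:
    """Assemble the pipeline outputs into one JSON-serialisable report."""
    missing = [name for name, obj in
               (("summary", summary), ("anova", anova), ("dunnett", dunnett))
               if obj is None]
    if missing:
        raise StatsError(f"missing report stages: {', '.join(missing)}")
    for row in summary:
        ratio = row.mean_ia_deg / row.mean_cc_percent
        if abs(row.mean_ia_deg - 9.0 * row.mean_cc_percent) > 1e-6 * ratio:
            raise StatsError("summary violates IA = 9 x CC linearity")
    report = {
        "assumptions": {
            "icc_model": "ICC(2,1) two-way random, absolute agreement, "
                         "single measurement",
            "dependent_correlation_test": "Hotelling-Williams (t, df = n-3)",
        },
        "summary": [vars(r) for r in summary],
        "anova": vars(anova),
        "dunnett": [
            {**vars(d), "p_formatted": _fmt_p(d.p_adjusted)} for d in dunnett
        ],
        "correlations": {k: vars(v) for k, v in (correlations or {}).items()},
        "dependent_correlation_tests": {
            k: {"statistic": t, "p": p, "p_formatted": _fmt_p(p)}
            for k, (t, p) in (dependent_correlation_tests or {}).items()},
        "reliability": {k: vars(v) for k, v in (reliability or {}).items()},
        "notes": dict(notes or {}),
    }
    return report


def report_to_markdown(report: dict) -> str:
    """Render the report dict as a Markdown document."""
    lines = ["# CDL method-comparison report", ""]
    lines.append("_Assumptions: {icc}; dependent-correlation test: {dep}._".format(
        icc=report["assumptions"]["icc_model"],
        dep=report["assumptions"]["dependent_correlation_test"]))
    lines += ["", "## Per-method summary (CDL mm / CC % / IA deg)", ""]
    lines.append("| method | n | mean CDL | SD CDL | mean CC | SD CC "
                 "| mean IA | SD IA |")
    lines.append("|---|---|---|---|---|---|---|---|")
    for r in report["summary"]:
        lines.append(
            "| {method} | {n} | {mean_cdl_mm:.1f} | {sd_cdl_mm:.1f} "
            "| {mean_cc_percent:.1f} | {sd_cc_percent:.1f} "
            "| {mean_ia_deg:.1f} | {sd_ia_deg:.1f} |".format(**r))
    a = report["anova"]
    lines += ["", "## One-way ANOVA", "",
              "F ({df_between}, {df_within}) = {F:.2f}, p = {p}".format(
                  df_between=a["df_between"], df_within=a["df_within"],
                  F=a["F"], p=_fmt_p(a["p"]))]
    lines += ["", "## Dunnett contrasts vs. reference", "",
              "| method | mean difference (mm) | 95% CI (mm) | adj. p |",
              "|---|---|---|---|"]
    for d in report["dunnett"]:
        lo, hi = d["ci95_mm"]
        lines.append(f"| {d['label']} | {d['mean_difference_mm']:.1f} "
                     f"| {lo:.1f} to {hi:.1f} | {d['p_formatted']} |")
    if report["correlations"]:
        lines += ["", "## Pearson correlations vs. reference", "",
                  "| method | r | p | n |", "|---|---|---|---|"]
        for k, c in report["correlations"].items():
            lines.append(f"| {k} | {c['r']:.2f} | {_fmt_p(c['p'])} | {c['n']} |")
    if report["reliability"]:
        lines += ["", "## Inter-rater reliability", "",
                  "| method | ICC | category |", "|---|---|---|"]
        for k, v in report["reliability"].items():
            lines.append(f"| {k} | {v['icc']:.2f} | {v['category']} |")
    if report["notes"]:
        lines += ["", "## Notes", ""]
        for k, v in report["notes"].items():
            lines.append(f"- **{k}**: {v}")
    return "\n".join(lines) + "\n"
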