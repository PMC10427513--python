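"""Paired baseline/follow-up cohort statistics.

For each metric the cohort summary reports baseline and follow-up
mean +/- SD, per-subject absolute and percent change (summarised as the
mean +/- SD of the per-subject values, not the ratio of means), a paired
t-test, and a repeated-measures Cohen's d with a bootstrap 95% CI.

Effect-size variants for a paired design:

    d_z  = mean(diff) / SD(diff)
    d_rm = d_z * sqrt(2 * (1 - r))        (r = pre/post correlation)
    d_av = mean(diff) / ((SD_pre + SD_post) / 2)

d_rm is the default: it standardises the change against the pooled
between-subject spread rather than the change spread, so it is comparable
with between-group d values.

Confidence intervals default to inverting the noncentral-t distribution of
the paired t statistic in its noncentrality parameter, which is exact for
d_z under normality; for d_rm and d_av the d_z interval is rescaled by the
variant's (data-dependent) standardiser ratio, the usual approximation for
repeated-measures d. A seeded percentile bootstrap over subjects (default
10,000 resamples) is available as ``ci_method="percentile"``; note that at
the small sample sizes typical of paired imaging cohorts the percentile
interval of a standardised effect size undercovers noticeably.

This is an exploratory, descriptive summary: no multiple-testing
adjustment is applied, and each metric uses its complete pairs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticError, UndefinedPercentChangeError

SESSIONS = ("baseline", "followup")
ALPHA = 0.05
DEFAULT_N_BOOT = 10_000

#: Magnitude thresholds on |d|: > 0.2 small, > 0.5 medium, > 0.8 large.
MAGNITUDE_THRESHOLDS = (("large", 0.8), ("medium", 0.5), ("small", 0.2))


def classify_magnitude(d: float) -> str:
    for name, threshold in MAGNITUDE_THRESHOLDS:
        if abs(d) > threshold:
            return name
    return "negligible"


class PairedCohortTable:
    """Long-format per-subject, per-metric values for two sessions.

    Wraps a DataFrame with columns ``subject``, ``session`` (one of
    ``baseline``/``followup``), ``metric``, ``value``. Statistical
    comparisons use complete pairs only; subjects missing either session
    for a metric are dropped listwise for that metric.
    """

    REQUIRED_COLUMNS = ("subject", "session", "metric", "value")

    def __init__(self, data: pd.DataFrame):
        missing = set(self.REQUIRED_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        bad = set(data["session"].unique()) - set(SESSIONS)
        if bad:
            raise ValueError(f"unknown session labels {sorted(bad)}; expected {SESSIONS}")
        dup = data.duplicated(subset=["subject", "session", "metric"])
        if dup.any():
            raise ValueError("duplicate (subject, session, metric) rows in cohort table")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedCohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def metrics(self) -> list[str]:
        """Metric names in first-appearance order."""
        return list(dict.fromkeys(self.data["metric"]))

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.data["subject"]))

    def pairs(self, metric: str) -> pd.DataFrame:
        """Complete pairs for one metric: columns subject, baseline, followup."""
        sub = self.data[self.data["metric"] == metric]
        wide = sub.pivot(index="subject", columns="session", values="value")
        for session in SESSIONS:
            if session not in wide.columns:
                wide[session] = np.nan
        wide = wide[list(SESSIONS)].dropna()
        return wide.reset_index()

    def unpaired_subjects(self, metric: str) -> list[str]:
        sub = self.data[self.data["metric"] == metric]
        counts = sub.groupby("subject")["session"].nunique()
        return sorted(counts[counts < 2].index.tolist())


def paired_change_table(cohort: PairedCohortTable) -> pd.DataFrame:
    """Per-subject absolute and percent change for every metric.

    absolute = followup - baseline; percent = 100 * absolute / baseline.
    A zero baseline value makes percent change undefined and raises
    :class:`UndefinedPercentChangeError` naming the subject and metric.
    """
    frames = []
    for metric in cohort.metrics():
        wide = cohort.pairs(metric)
        zero = wide[wide["baseline"] == 0]
        if not zero.empty:
            subject = zero["subject"].iloc[0]
            raise UndefinedPercentChangeError(
                f"baseline value is 0 for subject {subject!r}, metric {metric!r}; "
                "percent change undefined"
            )
        frame = wide.assign(
            metric=metric,
            absolute_change=wide["followup"] - wide["baseline"],
            percent_change=100.0 * (wide["followup"] - wide["baseline"]) / wide["baseline"],
        )
        frames.append(frame[["subject", "metric", "baseline", "followup", "absolute_change", "percent_change"]])
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    p: float
    df: int
    n: int
    mean_diff: float
    sd_diff: float


def paired_t_test(pre: np.ndarray, post: np.ndarray) -> PairedTTestResult:
    """Two-sided paired t-test on matched samples.

    t = mean(diff) / (SD(diff)/sqrt(n)) with df = n - 1. Zero-variance
    differences make the statistic undefined and raise
    :class:`DegenerateStatisticError`.
    """
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if pre.shape != post.shape:
        raise ValueError(f"paired samples differ in length: {pre.shape} vs {post.shape}")
    n = pre.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    diff = post - pre
    sd = float(np.std(diff, ddof=1))
    if sd == 0:
        raise DegenerateStatisticError("all paired differences are identical; t undefined")
    result = stats.ttest_rel(post, pre)
    return PairedTTestResult(
        t=float(result.statistic),
        p=float(result.pvalue),
        df=n - 1,
        n=n,
        mean_diff=float(np.mean(diff)),
        sd_diff=sd,
    )


@dataclass(frozen=True)
class EffectSizeResult:
    estimate: float
    ci_low: float
    ci_high: float
    variant: str
    magnitude_class: str
    n: int
    ci_method: str
    n_boot: int | None = None


def _effect_size(pre: np.ndarray, post: np.ndarray, variant: str, axis: int | None = None):
    """Vectorised effect size; pre/post may be (n,) or (B, n) resamples."""
    diff = post - pre
    mean = diff.mean(axis=axis)
    sd_diff = diff.std(ddof=1, axis=axis)
    if variant == "d_z":
        return mean / sd_diff
    s1 = pre.std(ddof=1, axis=axis)
    s2 = post.std(ddof=1, axis=axis)
    if variant == "d_av":
        return mean / ((s1 + s2) / 2.0)
    if variant == "d_rm":
        # corr along the resample axis
        if axis is None:
            r = np.corrcoef(pre, post)[0, 1]
        else:
            pc = pre - pre.mean(axis=axis, keepdims=True)
            qc = post - post.mean(axis=axis, keepdims=True)
            denom = np.sqrt((pc**2).sum(axis=axis) * (qc**2).sum(axis=axis))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (pc * qc).sum(axis=axis) / denom
        with np.errstate(invalid="ignore", divide="ignore"):
            return mean / sd_diff * np.sqrt(2.0 * (1.0 - r))
    raise ValueError(f"unknown effect-size variant {variant!r}; expected d_z, d_rm or d_av")


def _nct_cdf(t: float, df: int, ncp: float) -> float:
    val = stats.nct.cdf(t, df, ncp)
    if np.isnan(val):  # far tails: cdf -> 0 for ncp >> t, -> 1 for ncp << t
        return 0.0 if ncp > t else 1.0
    return float(val)


def _nct_ci_dz(dz: float, n: int, ci_level: float) -> tuple[float, float]:
    """Exact CI for the population d_z by noncentrality inversion.

    sqrt(n)*d_z follows a noncentral t with df = n-1 and noncentrality
    sqrt(n)*delta; the interval is the set of delta not rejected at level
    1 - ci_level.
    """
    from scipy.optimize import brentq

    t = dz * np.sqrt(n)
    df = n - 1
    alpha = 1.0 - ci_level
    span = 10.0 + 2.0 * abs(t)
    lo = brentq(lambda ncp: _nct_cdf(t, df, ncp) - (1.0 - alpha / 2.0), t - span, t + span)
    hi = brentq(lambda ncp: _nct_cdf(t, df, ncp) - alpha / 2.0, t - span, t + span)
    return lo / np.sqrt(n), hi / np.sqrt(n)


def cohens_d_repeated(
    pre: np.ndarray,
    post: np.ndarray,
    variant: str = "d_rm",
    ci_method: str = "nct",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> EffectSizeResult:
    """Repeated-measures Cohen's d with a 95% (by default) CI.

    ``ci_method="nct"`` inverts the noncentral-t distribution of the
    paired t statistic (exact for d_z under normality; rescaled by the
    variant's standardiser ratio for d_rm/d_av). ``ci_method="percentile"``
    resamples subjects with replacement ``n_boot`` times and takes the
    percentile interval; resamples where the statistic is undefined (zero
    spread after resampling) are discarded.
    """
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if pre.shape != post.shape:
        raise ValueError(f"paired samples differ in length: {pre.shape} vs {post.shape}")
    n = pre.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    diff = post - pre
    sd_diff = float(np.std(diff, ddof=1))
    if sd_diff == 0:
        raise DegenerateStatisticError("zero variance of paired differences; d undefined")
    if variant in ("d_rm", "d_av"):
        s1, s2 = float(np.std(pre, ddof=1)), float(np.std(post, ddof=1))
        if s1 == 0 or s2 == 0:
            raise DegenerateStatisticError(f"zero arm SD; {variant} undefined")
        if variant == "d_rm":
            r = float(np.corrcoef(pre, post)[0, 1])
            if abs(r) >= 1.0:
                raise DegenerateStatisticError("|pre/post correlation| = 1; d_rm undefined")
    estimate = float(_effect_size(pre, post, variant))

    if ci_method == "nct":
        dz = float(np.mean(diff)) / sd_diff
        # ratio of SD(diff) to the variant's standardiser: d_variant = scale * d_z
        if variant == "d_z":
            scale = 1.0
        elif variant == "d_rm":
            scale = float(np.sqrt(2.0 * (1.0 - r)))
        else:  # d_av
            scale = sd_diff / ((s1 + s2) / 2.0)
        lo, hi = _nct_ci_dz(dz, n, ci_level)
        ci_low, ci_high = sorted((lo * scale, hi * scale))
        boot_used = None
    elif ci_method == "percentile":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        with np.errstate(invalid="ignore", divide="ignore"):
            boot = np.asarray(_effect_size(pre[idx], post[idx], variant, axis=1))
        boot = boot[np.isfinite(boot)]
        if boot.size == 0:
            raise DegenerateStatisticError("all bootstrap resamples degenerate; CI undefined")
        q = (1.0 - ci_level) / 2.0
        ci_low, ci_high = np.quantile(boot, [q, 1.0 - q])
        boot_used = n_boot
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}; expected 'nct' or 'percentile'")
    return EffectSizeResult(
        estimate=estimate,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        variant=variant,
        magnitude_class=classify_magnitude(estimate),
        n=n,
        ci_method=ci_method,
        n_boot=boot_used,
    )


def summarize_comparisons(
    cohort: PairedCohortTable,
    variant: str = "d_rm",
    ci_method: str = "nct",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """One comparison row per metric, in input order.

    Columns: sample size, baseline/follow-up mean and SD, absolute and
    percent change mean and SD, paired t, two-sided p, significance flag
    at alpha = 0.05, effect size with 95% CI and magnitude class, and a
    status column. Degenerate metrics (e.g. identical sessions) are
    annotated in ``status`` rather than aborting the summary; no
    multiple-comparison adjustment is applied.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for metric in cohort.metrics():
        wide = cohort.pairs(metric)
        n = len(wide)
        row: dict = {"metric": metric, "n": n, "status": "ok"}
        if n < 2:
            row.update(status="insufficient-pairs")
            rows.append(row)
            continue
        pre = wide["baseline"].to_numpy(dtype=np.float64)
        post = wide["followup"].to_numpy(dtype=np.float64)
        diff = post - pre
        row.update(
            baseline_mean=pre.mean(),
            baseline_sd=pre.std(ddof=1),
            followup_mean=post.mean(),
            followup_sd=post.std(ddof=1),
            change_mean=diff.mean(),
            change_sd=diff.std(ddof=1),
        )
        if np.all(pre != 0):
            pct = 100.0 * diff / pre
            row.update(pct_change_mean=pct.mean(), pct_change_sd=pct.std(ddof=1))
        else:
            row.update(pct_change_mean=np.nan, pct_change_sd=np.nan, status="zero-baseline")
        try:
            ttest = paired_t_test(pre, post)
            row.update(t=ttest.t, p=ttest.p, significant=ttest.p < ALPHA)
        except DegenerateStatisticError as exc:
            row.update(t=np.nan, p=np.nan, significant=False, status=f"degenerate: {exc}")
        try:
            es = cohens_d_repeated(
                pre, post, variant=variant, ci_method=ci_method, n_boot=n_boot, seed=rng
            )
            row.update(
                effect_size=es.estimate,
                effect_ci_low=es.ci_low,
                effect_ci_high=es.ci_high,
                effect_variant=es.variant,
                magnitude=es.magnitude_class,
            )
        except DegenerateStatisticError as exc:
            row.update(
                effect_size=np.nan,
                effect_ci_low=np.nan,
                effect_ci_high=np.nan,
                effect_variant=variant,
                magnitude="undefined",
            )
            if row["status"] == "ok":
                row["status"] = f"degenerate: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
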