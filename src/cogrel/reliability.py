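"""Classical test-retest statistics.

Two-session reliability of a per-subject measure is quantified by:

* ICC(A,1) — two-way, single-measure, absolute-agreement intraclass
  correlation (session is a fixed effect, subject random); penalises
  systematic session shifts.
* ICC(1) — one-way random-effects, single-measure, absolute agreement.
* Pearson's r with a Fisher-z confidence interval (consistency only).

Practice effects are tested with paired t-tests (Cohen's d_z) and, for
factorial measure-by-session designs, repeated-measures ANOVA with
partial eta squared. Estimates are banded poor / fair / good / excellent
at 0.40 / 0.60 / 0.75.

The study's power analysis is reproduced by
:func:`required_n_correlation`: the smallest n at which a one-tailed test
of H0: rho = 0 reaches the target power, using the noncentral-t
formulation with noncentrality rho * sqrt(n) / sqrt(1 - rho^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasures",
    "icc_a1",
    "icc_1",
    "pearson_ci",
    "practice_effects",
    "rm_anova",
    "required_n_correlation",
    "correlation_power",
    "band",
    "reliability_report",
]

_BANDS = ((0.40, "poor"), (0.60, "fair"), (0.75, "good"), (np.inf, "excellent"))


def band(estimate: float) -> str:
    """Qualitative reliability band at thresholds 0.40 / 0.60 / 0.75."""
    if not np.isfinite(estimate):
        return "undefined"
    for upper, label in _BANDS:
        if estimate < upper:
            return label
    return "excellent"


@dataclass
class PairedMeasures:
    """Per-subject values of one measure at session 1 and session 2."""

    session1: np.ndarray
    session2: np.ndarray
    name: str = ""

    def __post_init__(self):
        s1 = np.asarray(self.session1, dtype=float)
        s2 = np.asarray(self.session2, dtype=float)
        if s1.shape != s2.shape or s1.ndim != 1:
            raise ValueError("sessions must be equal-length 1-D arrays")
        keep = np.isfinite(s1) & np.isfinite(s2)  # listwise deletion
        self.session1, self.session2 = s1[keep], s2[keep]
        if len(self.session1) < 3:
            raise ValueError("need at least 3 complete pairs")

    @property
    def n(self):
        return len(self.session1)

    def _long(self):
        n = self.n
        return pd.DataFrame({
            "subject": np.tile(np.arange(n), 2),
            "session": np.repeat([1, 2], n),
            "y": np.concatenate([self.session1, self.session2]),
        })


@dataclass
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    band: str


def _icc_from_pingouin(pairs: PairedMeasures, icc_type: str) -> IccResult:
    import pingouin as pg

    y = np.concatenate([pairs.session1, pairs.session2])
    if np.ptp(y) == 0:  # zero total variance: undefined
        return IccResult(np.nan, np.nan, np.nan, "undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        tab = pg.intraclass_corr(pairs._long(), targets="subject",
                                 raters="session", ratings="y")
    row = tab[tab.Type == icc_type].iloc[0]
    est = float(row.ICC)
    lo, hi = row.CI95
    return IccResult(est, float(lo), float(hi), band(est))


def icc_a1(pairs: PairedMeasures) -> IccResult:
    """Two-way single-measure absolute-agreement ICC with F-based 95% CI."""
    return _icc_from_pingouin(pairs, "ICC(A,1)")


def icc_1(pairs: PairedMeasures) -> IccResult:
    """One-way random-effects single-measure ICC with F-based 95% CI."""
    return _icc_from_pingouin(pairs, "ICC(1,1)")


@dataclass
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p: float


def pearson_ci(pairs: PairedMeasures, alpha=0.05) -> PearsonResult:
    """Pearson correlation with a Fisher-z confidence interval."""
    if pairs.n < 4:
        raise ValueError("Pearson CI requires at least 4 pairs")
    if np.std(pairs.session1) == 0 or np.std(pairs.session2) == 0:
        return PearsonResult(np.nan, np.nan, np.nan, np.nan)
    res = stats.pearsonr(pairs.session1, pairs.session2)
    ci = res.confidence_interval(1 - alpha)
    return PearsonResult(float(res.statistic), float(ci.low), float(ci.high),
                         float(res.pvalue))


@dataclass
class PracticeEffect:
    t: float
    df: int
    p: float
    d_z: float
    mean_diff: float


def practice_effects(pairs: PairedMeasures) -> PracticeEffect:
    """Paired t-test of session 2 vs session 1 with Cohen's d_z."""
    diff = pairs.session2 - pairs.session1
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return PracticeEffect(0.0, pairs.n - 1, 1.0, 0.0, 0.0)
        return PracticeEffect(np.inf, pairs.n - 1, 0.0, np.nan, float(diff.mean()))
    t, p = stats.ttest_rel(pairs.session2, pairs.session1)
    return PracticeEffect(float(t), pairs.n - 1, float(p),
                          float(diff.mean() / sd), float(diff.mean()))


def rm_anova(long: pd.DataFrame, dv: str, within, subject: str) -> pd.DataFrame:
    """Repeated-measures ANOVA (one or two within factors).

    Returns pingouin's table with F, p and partial eta squared (np2).
    Sphericity corrections are not applied: exact for 2-level factors and
    reported uncorrected for 3-level factors.
    """
    import pingouin as pg

    tab = pg.rm_anova(data=long, dv=dv, within=within, subject=subject,
                      detailed=True, correction=False)
    if "np2" not in tab.columns:
        # partial eta^2 = SS_effect / (SS_effect + SS_error); pingouin's
        # two-way table carries SS_error implicitly via MS_error = MS / F
        ss_err = (tab["MS"] / tab["F"]) * tab["ddof2"]
        tab = tab.assign(np2=tab["SS"] / (tab["SS"] + ss_err))
    return tab


# ---------------------------------------------------------------------------
# Power analysis for detecting a correlation
# ---------------------------------------------------------------------------


def correlation_power(n: int, rho: float, alpha=0.05, tails=1) -> float:
    """Power of the t-test of H0: rho=0 at true correlation ``rho``.

    Noncentral-t formulation: the test statistic has df = n - 2 and
    noncentrality delta = rho * sqrt(n) / sqrt(1 - rho^2).
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    if n < 4:
        return 0.0
    df = n - 2
    delta = rho * np.sqrt(n) / np.sqrt(1.0 - rho**2)
    crit = stats.t.ppf(1.0 - alpha / tails, df)
    return float(1.0 - stats.nct.cdf(crit, df, delta))


def required_n_correlation(rho=0.4, alpha=0.05, power=0.90, tails=1,
                           n_max=100000) -> int:
    """Smallest n whose correlation-test power reaches the target."""
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    for n in range(4, n_max + 1):
        if correlation_power(n, rho, alpha, tails) >= power:
            return n
    raise ValueError(f"power {power} not attainable below n = {n_max}")


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def reliability_report(measures: dict) -> pd.DataFrame:
    """Table-style reliability report for a dict of PairedMeasures.

    One row per measure: ICC(A,1), ICC(1), Pearson r (each with 95% CI),
    practice-effect t / p / d_z, and the qualitative band of ICC(A,1).
    """
    rows = []
    for name, pairs in measures.items():
        a1 = icc_a1(pairs)
        i1 = icc_1(pairs)
        pr = pearson_ci(pairs)
        pe = practice_effects(pairs)
        rows.append({
            "measure": name, "n": pairs.n,
            "icc_a1": a1.estimate, "icc_a1_lo": a1.ci_low, "icc_a1_hi": a1.ci_high,
            "icc_1": i1.estimate, "icc_1_lo": i1.ci_low, "icc_1_hi": i1.ci_high,
            "pearson_r": pr.r, "pearson_lo": pr.ci_low, "pearson_hi": pr.ci_high,
            "practice_t": pe.t, "practice_p": pe.p, "practice_dz": pe.d_z,
            "band": a1.band,
        })
    return pd.DataFrame(rows)
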