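"""Hypothesis tests and the EOD-frequency mixed model.

Covers the trial-level inference around the threshold estimate:

* one-sample Wilcoxon signed-rank test of baseline side preference against
  50 % occupancy;
* Friedman rank-sum test across analysis intervals per movement metric,
  followed by paired Wilcoxon tests of each interval against baseline with
  Holm step-down correction over the interval family;
* a zero-intercept random-slope mixed model for the percent change of median
  EOD frequency (fixed effects: experimental time and the interaction of
  inverted DO with the fraction of time spent in hypoxia);
* a two-way repeated-measures ANOVA for the repeatability trials (DO as
  between-subject factor, experimental day within-subject).

Note: the paired per-fish comparisons are signed-rank tests — the paired
design admits no two-sample rank-sum — and "inverted DO" defaults to
(100 − DO)/100 so the interaction grows as DO falls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from ._lmm import MixedModelFit, fit_mixed
from .errors import DegenerateTestError, InsufficientDataError

MIN_INFORMATIVE_PAIRS = 5


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, raw and (optionally) adjusted p."""

    name: str
    statistic: float
    p: float
    n: int
    p_adjusted: float | None = None
    family: str | None = None


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------

def one_sample_wilcoxon(values: Sequence[float], mu: float = 50.0,
                        name: str = "wilcoxon_one_sample") -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu``.

    Uses the exact signed-rank null for n ≤ 25 without ties in the absolute
    differences, otherwise the normal approximation with continuity
    correction.  Zero differences are dropped; all-zero input raises
    :class:`DegenerateTestError`.
    """
    d = np.asarray(values, float) - mu
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateTestError("all values equal the null location")
    absd = np.abs(d)
    exact = d.size <= 25 and np.unique(absd).size == absd.size
    res = sst.wilcoxon(d, alternative="two-sided",
                       method="exact" if exact else "approx",
                       correction=not exact)
    return TestResult(name, float(res.statistic), float(res.pvalue), int(d.size))


def pairwise_wilcoxon_holm(baseline: Sequence[float],
                           interval_values: Mapping[str, Sequence[float]],
                           metric: str = "metric") -> list[TestResult]:
    """Paired signed-rank test of each interval against baseline, Holm-corrected.

    Values are paired by fish (same order in ``baseline`` and every entry of
    ``interval_values``).  The Holm family is the full set of post-baseline
    intervals for this one metric.  Intervals with fewer than
    ``MIN_INFORMATIVE_PAIRS`` non-zero differences get p = NaN with a
    warning and are excluded from the correction.
    """
    base = np.asarray(baseline, float)
    raw: list[tuple[str, float, float, int]] = []
    for iv, vals in interval_values.items():
        v = np.asarray(vals, float)
        if v.shape != base.shape:
            raise InsufficientDataError(f"interval {iv}: unpaired values")
        d = v - base
        informative = int(np.sum(d != 0))
        if informative < MIN_INFORMATIVE_PAIRS:
            warnings.warn(f"{metric}/{iv}: only {informative} informative pairs; "
                          "p reported as NA", stacklevel=2)
            raw.append((iv, np.nan, np.nan, informative))
            continue
        res = sst.wilcoxon(d[d != 0], alternative="two-sided")
        raw.append((iv, float(res.statistic), float(res.pvalue), informative))

    ps = np.array([p for _, _, p, _ in raw])
    ok = np.isfinite(ps)
    adjusted = np.full(len(ps), np.nan)
    if ok.any():
        adjusted[ok] = multipletests(ps[ok], method="holm")[1]
    return [TestResult(iv, stat, p, n, p_adjusted=float(adj) if np.isfinite(adj) else None,
                       family=metric)
            for (iv, stat, p, n), adj in zip(raw, adjusted)]


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjustment of a family of raw p-values."""
    return multipletests(np.asarray(p_values, float), method="holm")[1]


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

def friedman_test(matrix: np.ndarray | pd.DataFrame,
                  name: str = "friedman") -> TestResult:
    """Friedman rank-sum test over a complete fish × interval matrix.

    Rows are subjects (fish), columns repeated conditions (intervals); ties
    within a row get average ranks and the statistic uses the general
    tie-corrected form.  A matrix of identical columns returns statistic 0,
    p = 1.  The reference distribution is chi-square with k − 1 df.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InsufficientDataError("need a complete matrix with >= 2 rows and columns")
    if not np.all(np.isfinite(m)):
        raise InsufficientDataError("missing cells in Friedman matrix")
    n, k = m.shape
    ranks = np.apply_along_axis(sst.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    den = np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:
        return TestResult(name, 0.0, 1.0, n)  # fully tied (identical columns)
    stat = num / den
    return TestResult(name, float(stat), float(sst.chi2.sf(stat, k - 1)), n)


# ---------------------------------------------------------------------------
# EOD frequency mixed model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EODModelSpec:
    """Specification of the EOD percent-change mixed model.

    Response: per-interval percent change of the median EOD frequency
    (baseline excluded — its change is 0 by construction).  Fixed effects:
    experimental time (interval index) and the interaction of inverted DO
    with the fraction of the interval spent in hypoxia.  Random effect: a
    per-fish random slope on time.  No intercept (the response is anchored
    at 0 at baseline).
    """

    inverted_do: str = "one_minus"   # "one_minus": (100-DO)/100; "reciprocal": 1/DO
    time_col: str = "time"
    do_col: str = "do"
    residence_col: str = "residence_frac"
    response_col: str = "pct_change"
    fish_col: str = "fish_id"

    def inverted(self, do: np.ndarray) -> np.ndarray:
        do = np.asarray(do, float)
        if self.inverted_do == "one_minus":
            return (100.0 - do) / 100.0
        if self.inverted_do == "reciprocal":
            return 1.0 / np.maximum(do, 1e-9)
        raise ValueError(f"unknown inverted_do rule {self.inverted_do!r}")


def _eod_design(rows: pd.DataFrame, spec: EODModelSpec,
                terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = {}
    if "time" in terms:
        cols["time"] = rows[spec.time_col].to_numpy(float)
    if "interaction" in terms:
        cols["inverted_do:residence"] = (spec.inverted(rows[spec.do_col].to_numpy())
                                         * rows[spec.residence_col].to_numpy(float))
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InsufficientDataError(
            f"rank-deficient design: collinear terms among {list(cols)}")
    return X, list(cols)


def fit_eod_lmm(rows: pd.DataFrame, spec: EODModelSpec | None = None,
                terms: tuple[str, ...] = ("time", "interaction"),
                compute_df: bool = True) -> MixedModelFit:
    """Zero-intercept random-slope LMM for EOD percent change.

    ``rows``: one row per fish per post-baseline interval with columns named
    by ``spec``.  Returns the fitted model with Satterthwaite t-tests; the
    signs of the time effect and the interaction are the quantities of
    interest (a negative time effect with a negligible interaction indicates
    cooling, not hypoxia, moves the frequency).
    """
    spec = spec or EODModelSpec()
    X, names = _eod_design(rows, spec, terms)
    Z = rows[spec.time_col].to_numpy(float)[:, None]   # random slope on time
    return fit_mixed(X, rows[spec.response_col].to_numpy(float), Z,
                     rows[spec.fish_col].to_numpy(), names, compute_df=compute_df)


def compare_eod_models(rows: pd.DataFrame,
                       spec: EODModelSpec | None = None) -> pd.DataFrame:
    """AIC comparison of the candidate fixed-effect sets.

    Candidates: {time}, {time, interaction}, {interaction}; smaller AIC is
    the better fit.  Returns a DataFrame sorted by AIC.
    """
    spec = spec or EODModelSpec()
    out = []
    for terms in (("time",), ("time", "interaction"), ("interaction",)):
        fit = fit_eod_lmm(rows, spec, terms=terms, compute_df=False)
        out.append({"terms": "+".join(terms), "aic": fit.aic, "llf": fit.llf})
    return pd.DataFrame(out).sort_values("aic").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Repeatability ANOVA
# ---------------------------------------------------------------------------

def rm_anova_repeatability(rows: pd.DataFrame,
                           dv: str = "residence") -> TestResult:
    """Two-way repeated-measures ANOVA for the repeatability trials.

    ``rows`` needs columns fish_id, do, day, and the response ``dv``, with
    exactly one observation per (fish, DO level, day) and two days.  DO is
    treated as the between-subject factor with subject = (fish, DO-level)
    cell, experimental day as the within-subject factor; the reported F and
    p are for the day effect.
    """
    for c in ("fish_id", "do", "day"):
        if c not in rows.columns:
            raise InsufficientDataError(f"missing column {c}")
    df = rows.copy()
    days = sorted(df["day"].unique())
    if len(days) != 2:
        raise InsufficientDataError("need exactly two experimental days")
    counts = df.groupby(["fish_id", "do", "day"]).size()
    if (counts != 1).any() or counts.groupby(level=[0, 1]).size().nunique() != 1:
        raise InsufficientDataError("unbalanced design: need one row per fish/DO/day")

    wide = df.pivot_table(index=["fish_id", "do"], columns="day", values=dv)
    diffs = wide[days[1]] - wide[days[0]]
    if np.allclose(diffs, 0):
        # no within-subject change at all: day effect exactly null
        return TestResult("rm_anova_day", 0.0, 1.0, len(wide))

    df["subject"] = df["fish_id"].astype(str) + "@" + df["do"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.mixed_anova(data=df, dv=dv, within="day",
                               subject="subject", between="do")
    row = table[table["Source"] == "day"].iloc[0]
    pcol = "p_unc" if "p_unc" in table.columns else "p-unc"
    return TestResult("rm_anova_day", float(row["F"]), float(row[pcol]),
                      int(len(wide)))
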