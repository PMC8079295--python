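"""Broken-stick mixed-model estimation of the hypoxia avoidance threshold.

The dataset is residence time in the hypoxic compartment (% of interval
time) per fish per established air-saturation level, with the normoxic
baseline coded at DO = 100.  Two linear mixed models with per-fish random
intercepts — residence ~ DO, fish as random effect — are fitted to the
high-DO ("pre-threshold") and low-DO ("post-threshold") subsets; the split
between consecutive DO levels is chosen by exhaustively minimizing the sum
of the two conditional residual sums of squares (the mixed-model analogue of
the classical two-segment Pcrit procedure).  The avoidance threshold is the
DO at which the two fixed-effect regression lines intersect.

Estimation is by maximum likelihood so RSS is comparable across splits; a
plain-OLS mode (the classical two-segment procedure without random effects)
is available via ``mode="ols"``, and per-fish random slopes can be added
with ``random_slope=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lmm import MixedModelFit, MixedTerm, fit_mixed, nakagawa_r2
from .errors import InsufficientDataError, ShuttleboxError


class NoIntersectionError(ShuttleboxError):
    """The two segment lines are parallel; no threshold exists."""


REQUIRED_COLUMNS = ("fish_id", "do", "residence")


def validate_residence_dataset(data: pd.DataFrame) -> pd.DataFrame:
    """Check the residence-vs-DO dataset invariants and return a clean copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise InsufficientDataError(f"residence dataset missing columns {missing}")
    df = data[list(REQUIRED_COLUMNS)].copy()
    if ((df["residence"] < 0) | (df["residence"] > 100)).any():
        raise InsufficientDataError("residence values must lie in [0, 100] %")
    if df["fish_id"].nunique() < 2:
        raise InsufficientDataError("need at least 2 fish")
    if df["do"].nunique() < 4:
        raise InsufficientDataError("need at least 4 distinct DO levels")
    return df


@dataclass
class LMMFit:
    """Random-intercept model of residence on DO for one segment.

    ``intercept``/``slope`` are the fixed effects (β0, β1) with Satterthwaite
    t-tests; ``rss`` is the sum of squared conditional residuals; R² values
    follow the Nakagawa variance decomposition.
    """

    fit: MixedModelFit

    @property
    def intercept(self) -> MixedTerm:
        return self.fit.terms[0]

    @property
    def slope(self) -> MixedTerm:
        return self.fit.terms[1]

    @property
    def rss(self) -> float:
        return self.fit.rss

    @property
    def r2_marginal(self) -> float:
        return self.fit.r2_marginal

    @property
    def r2_conditional(self) -> float:
        return self.fit.r2_conditional

    @property
    def ols_fallback(self) -> bool:
        return self.fit.ols_fallback


def fit_random_intercept_lmm(rows: pd.DataFrame, compute_df: bool = True,
                             random_slope: bool = False,
                             ols: bool = False) -> LMMFit:
    """Fit residence ~ DO with a per-fish random intercept by ML.

    ``rows`` needs columns fish_id, do, residence with ≥ 2 fish and ≥ 2
    distinct DO values.  ``random_slope=True`` adds a per-fish random slope
    (unstructured covariance); ``ols=True`` drops the random effects
    entirely.  A singular random-effect fit falls back to OLS with a flag.
    """
    if rows["do"].nunique() < 2:
        raise InsufficientDataError("need >= 2 distinct DO values in a segment")
    if rows["fish_id"].nunique() < 2 and not ols:
        raise InsufficientDataError("need >= 2 fish for a mixed model")
    x = rows["do"].to_numpy(float)
    X = np.column_stack([np.ones_like(x), x])
    Z = X if random_slope else np.ones((len(x), 1))
    fit = fit_mixed(X, rows["residence"].to_numpy(float), Z,
                    rows["fish_id"].to_numpy(), ["intercept", "do"],
                    compute_df=compute_df, ols=ols)
    return LMMFit(fit)


def intersect_lines(b0_pre: float, b1_pre: float,
                    b0_post: float, b1_post: float) -> float:
    """DO value where the two fixed-effect lines intersect.

    Solves b0_pre + b1_pre·x = b0_post + b1_post·x; raises
    :class:`NoIntersectionError` for (numerically) parallel lines.
    """
    dslope = b1_post - b1_pre
    scale = max(abs(b1_pre), abs(b1_post), 1.0)
    if abs(dslope) <= 1e-12 * scale:
        raise NoIntersectionError("segment lines are parallel; no intersection")
    return (b0_pre - b0_post) / dslope


@dataclass
class BrokenStickFit:
    """Result of the two-segment mixed-model split search."""

    split_do: float                 # midpoint between the two DO levels at the split
    pre: LMMFit                     # levels above the split (high DO)
    post: LMMFit                    # levels at/below the split (low DO)
    threshold: float                # DO where the fixed-effect lines intersect
    total_rss: float
    candidates: list[tuple[float, float]]  # (split_do, total rss) for every candidate

    @property
    def pre_levels(self) -> str:
        return f"do > {self.split_do:g}"


def candidate_splits(levels: np.ndarray, min_levels: int = 2) -> list[float]:
    """Midpoints between consecutive distinct DO levels leaving at least
    ``min_levels`` distinct levels in each segment."""
    lv = np.unique(np.asarray(levels, float))
    out = []
    for k in range(min_levels - 1, len(lv) - min_levels):
        out.append(float((lv[k] + lv[k + 1]) / 2.0))
    return out


def broken_stick_search(data: pd.DataFrame, mode: str = "lmm",
                        random_slope: bool = False, min_levels: int = 2,
                        compute_df: bool = True) -> BrokenStickFit:
    """Exhaustive two-segment split search minimizing total conditional RSS.

    Every admissible split (midpoint between consecutive sorted distinct DO
    levels, each segment keeping ≥ ``min_levels`` distinct levels) is
    evaluated by fitting the pre (high-DO) and post (low-DO) models; the
    split with the smallest combined RSS wins, ties resolved toward the
    higher-DO split.  The threshold is the intersection of the two
    fixed-effect lines of the winning split.
    """
    if mode not in ("lmm", "ols"):
        raise ValueError("mode must be 'lmm' or 'ols'")
    df = validate_residence_dataset(data)
    splits = candidate_splits(df["do"].to_numpy(), min_levels)
    if not splits:
        raise InsufficientDataError(
            f"need >= {2 * min_levels} distinct DO levels for a split search")

    ols = mode == "ols"
    results = []
    for s in splits:
        post_rows = df[df["do"] <= s]
        pre_rows = df[df["do"] > s]
        pre = fit_random_intercept_lmm(pre_rows, compute_df=False,
                                       random_slope=random_slope, ols=ols)
        post = fit_random_intercept_lmm(post_rows, compute_df=False,
                                        random_slope=random_slope, ols=ols)
        results.append((s, pre.rss + post.rss))

    best_rss = min(r for _, r in results)
    # ties (to numerical tolerance) resolved toward the higher-DO split
    best_split = max(s for s, r in results
                     if r <= best_rss * (1 + 1e-9) + 1e-9)

    pre = fit_random_intercept_lmm(df[df["do"] > best_split], compute_df=compute_df,
                                   random_slope=random_slope, ols=ols)
    post = fit_random_intercept_lmm(df[df["do"] <= best_split], compute_df=compute_df,
                                    random_slope=random_slope, ols=ols)
    threshold = intersect_lines(pre.intercept.estimate, pre.slope.estimate,
                                post.intercept.estimate, post.slope.estimate)
    return BrokenStickFit(split_do=best_split, pre=pre, post=post,
                          threshold=float(threshold),
                          total_rss=pre.rss + post.rss, candidates=results)
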