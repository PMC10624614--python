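"""Cohort statistics: log transforms, normality gate, index-outcome
regressions, insult-group ANOVA, and threshold-based two-group tests.

Effect sizes reported as variance-explained analogues throughout: squared
Pearson r for regressions, eta-squared for ANOVA, and t^2/(t^2+df) for
two-group tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import AnalysisConfig, OutcomeRecord, outcomes_to_frame
from .errors import ComputeError, DataError

log = logging.getLogger(__name__)

OUTCOME_COLUMNS = ("bgt_log_lac_naa", "wm_log_lac_naa", "tunel_log10")

#: Minimum n for the omnibus normality test (skewness+kurtosis z-scores
#: are unstable below this).
NORMALITY_MIN_N = 8


@dataclass(frozen=True)
class RegressionResult:
    index_name: str
    outcome_name: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_two_tailed: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise DataError("regression needs n >= 3")


@dataclass(frozen=True)
class GroupTestResult:
    index_name: str
    grouping: str  # insult-group | LacNAA-threshold
    statistic: float
    p: float
    effect_size_r2: float
    welch_used: bool = False

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.effect_size_r2 <= 1 + 1e-12):
            raise ComputeError("effect size outside [0, 1]")


def log10_outcomes(outcomes: list[OutcomeRecord]) -> pd.DataFrame:
    """Per-subject outcome frame with Lac/NAA ratios on the log10 scale.

    TUNEL is passed through (already log10). Raises on nonpositive ratios.
    """
    frame = outcomes_to_frame(outcomes)
    for col in ("bgt_lac_naa", "wm_lac_naa"):
        vals = frame[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise DataError(f"log10_outcomes: nonpositive {col} value")
    frame["bgt_log_lac_naa"] = np.log10(frame["bgt_lac_naa"])
    frame["wm_log_lac_naa"] = np.log10(frame["wm_lac_naa"])
    return frame


def normality_test(sample: np.ndarray, alpha: float = 0.05
                   ) -> tuple[float, float, bool]:
    """Omnibus K^2 test combining skewness and kurtosis z-scores.

    Returns ``(statistic, p, is_normal_at_alpha)``.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < NORMALITY_MIN_N:
        raise DataError(f"normality test requires n >= {NORMALITY_MIN_N}, "
                        f"got {sample.size}")
    stat, p = sps.normaltest(sample)
    return float(stat), float(p), bool(p >= alpha)


def linear_regression(x: np.ndarray, y: np.ndarray, *, index_name: str = "x",
                      outcome_name: str = "y") -> RegressionResult:
    """Ordinary least squares with two-tailed slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("regression needs matched x, y with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("regression inputs must be finite")
    if np.ptp(x) == 0:
        raise DataError("zero variance in x")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue ** 2) if np.ptp(y) > 0 else 0.0
    p = float(res.pvalue) if np.ptp(y) > 0 else 1.0
    return RegressionResult(index_name, outcome_name, int(x.size),
                            float(res.slope), float(res.intercept), r2, p)


def one_way_anova(groups: list[np.ndarray], *, index_name: str = "x"
                  ) -> GroupTestResult:
    """F test across >= 2 groups with eta-squared effect size."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise DataError("ANOVA needs >= 2 groups of n >= 2")
    grand = np.concatenate(groups)
    ss_total = float(((grand - grand.mean()) ** 2).sum())
    ss_between = float(sum(g.size * (g.mean() - grand.mean()) ** 2 for g in groups))
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    if ss_total > 0 and ss_total - ss_between > 1e-300:
        f_stat, p = sps.f_oneway(*groups)
    else:  # zero within-group variance: F degenerate
        f_stat, p = np.inf, 0.0
    return GroupTestResult(index_name, "insult-group", float(f_stat), float(p),
                           float(eta2))


def two_group_test(a: np.ndarray, b: np.ndarray, *, force_welch: str = "auto",
                   alpha: float = 0.05, index_name: str = "x",
                   grouping: str = "LacNAA-threshold") -> GroupTestResult:
    """Two-tailed t test; Welch's correction per a Levene pre-test in auto mode.

    Effect size is t^2 / (t^2 + df).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("two-group test needs n >= 2 per group")
    if force_welch not in ("auto", "always", "never"):
        raise DataError(f"unknown force_welch mode {force_welch!r}")
    if force_welch == "always":
        welch = True
    elif force_welch == "never":
        welch = False
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            welch = False
        else:
            _, p_lev = sps.levene(a, b, center="median")
            welch = bool(p_lev < alpha)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    df = float(res.df)
    if np.isnan(t):  # both groups constant and equal
        t, p, r2 = 0.0, 1.0, 0.0
    else:
        p = float(res.pvalue)
        r2 = t * t / (t * t + df)
    return GroupTestResult(index_name, grouping, t, p, float(r2), welch)


def classify_outcome(bgt_lac_naa: float, threshold: float = 0.39) -> str:
    """'poor' iff the BGT Lac/NAA ratio is at or above the threshold."""
    if bgt_lac_naa < 0:
        raise DataError("Lac/NAA ratio must be >= 0")
    return "poor" if bgt_lac_naa >= threshold else "good"


# ---------------------------------------------------------------------------
# Full cohort report
# ---------------------------------------------------------------------------

@dataclass
class CohortStatsReport:
    """Serializable bundle of all per-(index, outcome) statistics."""

    indices: pd.DataFrame                      # per-subject wide index table
    regressions: list[RegressionResult] = field(default_factory=list)
    group_tests: list[GroupTestResult] = field(default_factory=list)
    normality: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        reg = pd.DataFrame([r.__dict__ for r in self.regressions])
        if not reg.empty:
            reg["p_bh"] = benjamini_hochberg(reg["p_two_tailed"].to_numpy())
        grp = pd.DataFrame([g.__dict__ for g in self.group_tests])
        if not grp.empty:
            grp["p_bh"] = benjamini_hochberg(grp["p"].to_numpy())
        return {"indices": self.indices, "regressions": reg,
                "group_tests": grp, "normality": self.normality}

    def to_dict(self) -> dict:
        return {name: frame.to_dict(orient="records")
                for name, frame in self.to_frames().items()}

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True,
                                   default=float) + "\n")
        return path


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p values (emitted for transparency; not used for gating)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


def run_outcome_analysis(index_table: pd.DataFrame, outcomes: list[OutcomeRecord],
                         cfg: AnalysisConfig) -> CohortStatsReport:
    """Cross every index column with every outcome regression and both group
    analyses.

    ``index_table`` is the wide frame from ``indices.index_wide_frame``
    (columns ``<pair>_<kind>`` plus subject_id and group). The normality
    check per variable is logged and recorded, not used to switch methods
    (the log10 transform is the designated remedy and is always applied
    to the Lac/NAA ratios).
    """
    out_frame = log10_outcomes(outcomes)
    merged = index_table.merge(out_frame, on="subject_id", how="inner",
                               suffixes=("", "_outcome"))
    if len(merged) < 3:
        raise DataError(f"only {len(merged)} subjects join between index and "
                        "outcome tables; need >= 3")
    if "group" not in merged.columns and "group_outcome" in merged.columns:
        merged["group"] = merged["group_outcome"]

    index_cols = [c for c in index_table.columns
                  if c.endswith("_semblance") or c.endswith("_coherence")]
    if not index_cols:
        raise DataError("index table has no index columns")

    norm_rows = []
    for col in list(index_cols) + list(OUTCOME_COLUMNS):
        vals = merged[col].dropna().to_numpy(dtype=float)
        if vals.size >= NORMALITY_MIN_N and np.ptp(vals) > 0:
            stat, p, ok = normality_test(vals, cfg.alpha)
            norm_rows.append({"variable": col, "k2": stat, "p": p, "normal": ok})
            if not ok:
                log.info("normality: %s non-normal (p=%.3g)", col, p)
        else:
            norm_rows.append({"variable": col, "k2": np.nan, "p": np.nan,
                              "normal": None})

    regressions: list[RegressionResult] = []
    for col in index_cols:
        for out_col in OUTCOME_COLUMNS:
            sub = merged[[col, out_col]].dropna()
            if len(sub) < 3:
                continue
            regressions.append(linear_regression(
                sub[col].to_numpy(), sub[out_col].to_numpy(),
                index_name=col, outcome_name=out_col))

    group_tests: list[GroupTestResult] = []
    merged["outcome_class"] = [classify_outcome(v, cfg.lacnaa_threshold)
                               for v in merged["bgt_lac_naa"]]
    for col in index_cols:
        vals = merged[[col, "group", "outcome_class"]].dropna(subset=[col])
        by_group = [vals.loc[vals["group"] == g, col].to_numpy()
                    for g in ("control", "moderate", "severe")]
        by_group = [g for g in by_group if g.size >= 2]
        if len(by_group) >= 2:
            group_tests.append(one_way_anova(by_group, index_name=col))
        good = vals.loc[vals["outcome_class"] == "good", col].to_numpy()
        poor = vals.loc[vals["outcome_class"] == "poor", col].to_numpy()
        if good.size >= 2 and poor.size >= 2:
            group_tests.append(two_group_test(good, poor, alpha=cfg.alpha,
                                              index_name=col))

    return CohortStatsReport(indices=index_table, regressions=regressions,
                             group_tests=group_tests,
                             normality=pd.DataFrame(norm_rows))
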