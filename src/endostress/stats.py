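"""Between-group statistics: U-test, chi-square, Fisher, t-test, and the
comparison table.

The primary comparison is a one-sided Mann-Whitney U test per
(channel, anchor) cell, stratified as all / female / male, with the
direction declared a priori per feature (music arm lower for the stress
markers) — never inferred from the data. Contingency comparisons of the
cohort characteristics use plain Pearson chi-square (no continuity
correction) or Fisher's exact test; interval covariates use Student's or
Welch's t. Significance is flagged at one-sided p <= 0.05 and no
multiple-testing adjustment is applied by default (a Holm option exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

ALPHA = 0.05
EXACT_MAX_N = 12  # exact U distribution up to this combined sample size (no ties)

STRATA = ("all", "female", "male")

#: A-priori one-sided directions: the music arm is hypothesised to show
#: lower distress markers (fEMG, sympathetic arousal, heart rate) and
#: higher peripheral temperature (vasodilation under relaxation).
DEFAULT_DIRECTIONS = {
    "femg_corrugator": "less",
    "femg_zygomaticus": "less",
    "scl": "less",
    "bpm": "less",
    "tmp": "greater",
}


@dataclass
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    p_one_sided: float = float("nan")
    n_per_group: tuple = ()

    def __post_init__(self) -> None:
        for p in (self.p_two_sided, self.p_one_sided):
            if not np.isnan(p) and not 0 <= p <= 1 + 1e-12:
                raise ValueError(f"p-value {p} outside [0, 1]")


@dataclass
class ComparisonPlan:
    """What to compare and in which pre-declared direction."""

    directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    alpha: float = ALPHA
    strata: tuple = STRATA
    holm: bool = False  # optional family-wise correction across cells


def mann_whitney_u(a, b, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test; ``alternative`` refers to sample ``a``.

    Uses the exact U distribution when the combined sample size is at most
    12 and there are no ties; otherwise the normal approximation with tie
    and continuity corrections. The reported statistic is U for sample
    ``a`` (midranks for ties, so U_a + U_b = n_a * n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one observation")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and (a.size + b.size) <= EXACT_MAX_N
    method = "exact" if exact else "asymptotic"
    res_dir = sst.mannwhitneyu(a, b, alternative=alternative, method=method,
                               use_continuity=True)
    res_two = sst.mannwhitneyu(a, b, alternative="two-sided", method=method,
                               use_continuity=True)
    p_one = float(res_dir.pvalue) if alternative != "two-sided" else float("nan")
    return TestResult(statistic=float(res_dir.statistic),
                      p_two_sided=float(res_two.pvalue),
                      p_one_sided=p_one,
                      method=f"mann-whitney-u ({method})",
                      n_per_group=(a.size, b.size))


def pearson_chi_square(table) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined for a zero row or column margin")
    chi2, p, _, _ = sst.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(chi2), p_two_sided=float(p),
                      method="pearson-chi-square",
                      n_per_group=(int(t[0].sum()), int(t[1].sum())))


def fisher_exact(table) -> TestResult:
    """Fisher's exact test (two-sided, sum of no-more-probable tables)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        # degenerate margin: only one table is possible
        return TestResult(statistic=float("nan"), p_two_sided=1.0,
                          method="fisher-exact (degenerate margin)",
                          n_per_group=(int(t[0].sum()), int(t[1].sum())))
    odds, p = sst.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_two_sided=float(p),
                      method="fisher-exact",
                      n_per_group=(int(t[0].sum()), int(t[1].sum())))


def two_sample_t(a, b, variant: str = "pooled") -> TestResult:
    """Student's (pooled) or Welch's two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two observations")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("t-test undefined when both groups have zero variance")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = sst.ttest_ind(a, b, equal_var=(variant == "pooled"))
    res_less = sst.ttest_ind(a, b, equal_var=(variant == "pooled"), alternative="less")
    return TestResult(statistic=float(res.statistic),
                      p_two_sided=float(res.pvalue),
                      p_one_sided=float(res_less.pvalue),
                      method=f"t-test ({variant})",
                      n_per_group=(a.size, b.size))


# ---------------------------------------------------------------------------
# Comparison table


def compare_groups(features: pd.DataFrame,
                   plan: ComparisonPlan | None = None) -> pd.DataFrame:
    """Build the comparison table: one row per (channel, anchor, stratum).

    Columns: per-group N, mean, SD; the one-sided U-test p in the plan's
    declared direction; and a significance flag at the plan's alpha. Cells
    whose stratum leaves a group empty are reported as not computable
    (NaN p) and the run continues. The function is pure: identical inputs
    give identical output.
    """
    plan = plan or ComparisonPlan()
    usable = features.dropna(subset=["value"])
    rows = []
    channels = sorted(usable["channel"].unique(),
                      key=lambda c: list(plan.directions).index(c)
                      if c in plan.directions else 99)
    anchors_present = [a for a in ("start", "cecum", "end")
                       if a in set(usable["anchor"])]
    for channel in channels:
        direction = plan.directions.get(channel, "less")
        for anchor in anchors_present:
            cell = usable[(usable["channel"] == channel) & (usable["anchor"] == anchor)]
            for stratum in plan.strata:
                sub = cell if stratum == "all" else cell[cell["sex"] == stratum]
                ctrl = sub.loc[sub["group"] == "control", "value"].to_numpy()
                music = sub.loc[sub["group"] == "music", "value"].to_numpy()
                row = {"channel": channel, "anchor": anchor, "stratum": stratum,
                       "direction": f"music_{direction}",
                       "n_control": ctrl.size, "n_music": music.size,
                       "mean_control": float(np.mean(ctrl)) if ctrl.size else float("nan"),
                       "sd_control": float(np.std(ctrl, ddof=1)) if ctrl.size > 1 else float("nan"),
                       "mean_music": float(np.mean(music)) if music.size else float("nan"),
                       "sd_music": float(np.std(music, ddof=1)) if music.size > 1 else float("nan")}
                if ctrl.size and music.size:
                    # direction is declared for the music arm; the test's
                    # first sample is the music group
                    res = mann_whitney_u(music, ctrl, alternative=direction)
                    row["u_statistic"] = res.statistic
                    row["p_one_sided"] = res.p_one_sided
                else:
                    row["u_statistic"] = float("nan")
                    row["p_one_sided"] = float("nan")
                rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        if plan.holm:
            table["p_adjusted"] = _holm(table["p_one_sided"].to_numpy())
            table["significant"] = table["p_adjusted"] <= plan.alpha
        else:
            table["significant"] = table["p_one_sided"] <= plan.alpha
    return table


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (NaNs passed through)."""
    adjusted = np.full_like(p, np.nan, dtype=float)
    valid = np.flatnonzero(~np.isnan(p))
    m = valid.size
    order = valid[np.argsort(p[valid])]
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def render_comparison_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the comparison table."""
    lines = []
    for (channel, anchor), block in table.groupby(["channel", "anchor"], sort=False):
        lines.append(f"{channel} @ {anchor}")
        lines.append(f"  {'stratum':<8} {'N c/m':>9} {'mean c':>8} {'SD c':>7} "
                     f"{'mean m':>8} {'SD m':>7} {'p (one-side)':>13}")
        for _, r in block.iterrows():
            star = "*" if r.get("significant", False) else ""
            p = f"{r['p_one_sided']:.3f}{star}" if np.isfinite(r["p_one_sided"]) else "n/a"
            lines.append(
                f"  {r['stratum']:<8} {r['n_control']:>4}/{r['n_music']:<4} "
                f"{r['mean_control']:>8.2f} {r['sd_control']:>7.2f} "
                f"{r['mean_music']:>8.2f} {r['sd_music']:>7.2f} {p:>13}")
        lines.append("")
    return "\n".join(lines)
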