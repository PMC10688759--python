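"""The study's nonparametric statistical procedure.

Within each group, every variable is screened across the seven timepoints
(H0–H6) with a Friedman repeated-measures rank test; only when the Friedman
test is significant (p < 0.05) are the post-hoc Wilcoxon signed-rank tests
of each hour against baseline reported (the "gate").  Between-group
comparisons at each hour use the Mann–Whitney test.  All tests are
two-sided and no multiple-testing correction is applied — a faithful
reproduction of the original procedure, not a statistical endorsement.

Summaries are "median(Q1;Q3)" with quartiles by linear interpolation
(type-7), so formatted strings are bit-reproducible.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import InsufficientDataError, ValidationError

log = logging.getLogger(__name__)

HOURS = ("H0", "H1", "H2", "H3", "H4", "H5", "H6")
ALPHA = 0.05
WITHIN_MARK = "*"
BETWEEN_MARK = "▲"  # ▲

#: Upper bound on (k!)^n for the exact Friedman permutation path.
_FRIEDMAN_EXACT_LIMIT = 20000


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def friedman(matrix, method: str = "auto") -> tuple[float, float]:
    """Friedman test on a subjects × timepoints matrix.

    Returns ``(chi-square statistic, p)``.  ``method`` is ``"chisq"`` for
    the k−1 df chi-square approximation with tie correction (the study-scale
    path), ``"exact"`` for full enumeration of the within-subject
    permutation distribution (feasible only for tiny n and k, and only
    without ties), or ``"auto"`` to enumerate when (k!)^n is small.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 3:
        raise ValidationError("Friedman needs >= 2 subjects and >= 3 timepoints")
    n, k = x.shape
    stat = _friedman_statistic(x)
    if np.ptp(x, axis=1).max() == 0:  # every row constant
        return 0.0, 1.0
    has_ties = any(np.unique(row).size < k for row in x)
    if method == "auto":
        method = ("exact" if math.factorial(k) ** n <= _FRIEDMAN_EXACT_LIMIT
                  and not has_ties else "chisq")
    if method == "exact":
        if has_ties:
            raise ValidationError("exact Friedman enumeration requires no ties")
        return stat, _friedman_exact_p(x, stat)
    p = float(sp_stats.chi2.sf(stat, k - 1))
    return stat, p


def _friedman_statistic(x: np.ndarray) -> float:
    """Chi-square statistic on within-subject average ranks, tie-corrected."""
    n, k = x.shape
    ranks = np.apply_along_axis(sp_stats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    stat = (12.0 / (n * k * (k + 1))) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction (identical to the classical c = 1 - Σ(t³ − t)/(n k (k² − 1)))
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0
    return float(stat / c)


def _friedman_exact_p(x: np.ndarray, observed: float) -> float:
    """P(statistic >= observed) over all (k!)^n within-row orderings."""
    n, k = x.shape
    perms = list(itertools.permutations(range(1, k + 1)))
    count = total = 0
    for assignment in itertools.product(perms, repeat=n):
        ranks = np.asarray(assignment, dtype=float)
        col_sums = ranks.sum(axis=0)
        stat = (12.0 / (n * k * (k + 1))) * np.sum(col_sums**2) \
            - 3.0 * n * (k + 1)
        total += 1
        if stat >= observed - 1e-9:
            count += 1
    return count / total


def wilcoxon_signed_rank(baseline, followup, method: str = "auto") -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped (Wilcoxon's convention).  The exact
    distribution is used for n <= 25 untied differences, otherwise the
    normal approximation with tie and continuity correction.
    """
    a = np.asarray(baseline, dtype=float)
    b = np.asarray(followup, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    if d.size < 5:
        raise InsufficientDataError(
            f"Wilcoxon needs >= 5 non-zero differences, got {d.size}"
        )
    if method == "auto":
        method = "exact" if d.size <= 25 else "approx"
    res = sp_stats.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided",
        correction=(method != "exact"),
        method="exact" if method == "exact" else "approx",
    )
    return float(res.pvalue)


def mann_whitney(group_a, group_b, method: str = "auto") -> float:
    """Two-sided Mann–Whitney p for two independent samples.

    Exact for small samples without ties (min n <= 8), otherwise the normal
    approximation with tie and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) \
            else "asymptotic"
    res = sp_stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Summaries and the report
# ---------------------------------------------------------------------------

def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation (type-7)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return (float("nan"),) * 3
    return (float(np.median(v)),
            float(np.percentile(v, 25)),
            float(np.percentile(v, 75)))


def format_median_iqr(values, fmt: str = "%.3g") -> str:
    med, q1, q3 = median_iqr(values)
    return f"{fmt % med}({fmt % q1};{fmt % q3})"


def repeated_measures_matrix(df: pd.DataFrame, variable: str, group: str,
                             hours=HOURS) -> tuple[np.ndarray, list]:
    """Subjects × timepoints matrix of one variable for one group.

    Subjects with any missing cell are excluded (and logged), since the
    Friedman test requires a complete block design.
    """
    sub = df[df["group"] == group]
    wide = sub.pivot_table(index="subject", columns="timepoint",
                           values=variable, aggfunc="first")
    wide = wide.reindex(columns=list(hours))
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        log.warning("%s/%s: excluding %d subject(s) with missing cells: %s",
                    variable, group, len(dropped), dropped)
    return complete.to_numpy(), list(complete.index)


@dataclass
class StatReport:
    """Per-variable Friedman p, gated Wilcoxon and Mann–Whitney p-values,
    and median(Q1;Q3) summaries, mirroring the study's table layout."""

    summary: pd.DataFrame     # variable, group, timepoint, median, q1, q3, label
    friedman: pd.DataFrame    # variable, group, statistic, p
    wilcoxon: pd.DataFrame    # variable, group, timepoint, p, significant
    mannwhitney: pd.DataFrame  # variable, timepoint, p, significant
    alpha: float = ALPHA
    variables: list = field(default_factory=list)

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.friedman.to_csv(out / "friedman.csv", index=False)
        self.wilcoxon.to_csv(out / "wilcoxon.csv", index=False)
        self.mannwhitney.to_csv(out / "mannwhitney.csv", index=False)

    def format_table(self) -> str:
        """Plain-text table: one block per variable, a row per group with
        median(Q1;Q3) per hour, '*' for within-group significance vs H0
        (Friedman-gated Wilcoxon) and '▲' for between-group significance."""
        lines = []
        header = "\t".join(["variable", "group"] + list(HOURS) + ["friedman_p"])
        lines.append(header)
        wilc = self.wilcoxon.set_index(["variable", "group", "timepoint"])
        mw = self.mannwhitney.set_index(["variable", "timepoint"])
        fr = self.friedman.set_index(["variable", "group"])
        summ = self.summary.set_index(["variable", "group", "timepoint"])
        for var in self.variables:
            for group in sorted(self.summary["group"].unique()):
                cells = []
                for hour in HOURS:
                    try:
                        label = summ.loc[(var, group, hour), "label"]
                    except KeyError:
                        label = "NA"
                    mark = ""
                    key = (var, group, hour)
                    if key in wilc.index and wilc.loc[key, "significant"]:
                        mark += WITHIN_MARK
                    cells.append(f"{label}{mark}")
                try:
                    fp = f"{fr.loc[(var, group), 'p']:.3g}"
                except KeyError:
                    fp = "NA"
                lines.append("\t".join([var, group] + cells + [fp]))
            marks = []
            for hour in HOURS:
                key = (var, hour)
                sig = key in mw.index and bool(mw.loc[key, "significant"])
                marks.append(BETWEEN_MARK if sig else "")
            lines.append("\t".join([var, "LPS vs control"] + marks + [""]))
        return "\n".join(lines)


def summarize(df: pd.DataFrame, variables=None, hours=HOURS,
              group_a: str = "LPS", group_b: str = "Control",
              alpha: float = ALPHA, baseline: str = "H0") -> StatReport:
    """Run the full statistical procedure on a long-format cohort table.

    ``df`` needs columns ``subject``, ``group``, ``timepoint`` plus one
    column per variable.  Variables absent from the table are omitted with
    a warning.
    """
    key_cols = {"subject", "group", "timepoint"}
    missing = key_cols - set(df.columns)
    if missing:
        raise ValidationError(f"cohort table lacks key column(s) {sorted(missing)}")
    groups = sorted(df["group"].unique())
    if variables is None:
        variables = [c for c in df.columns if c not in key_cols]
    kept = []
    for var in variables:
        if var not in df.columns or df[var].dropna().empty:
            log.warning("variable %r missing or empty; omitted", var)
            continue
        kept.append(var)

    summary_rows, friedman_rows, wilcoxon_rows, mw_rows = [], [], [], []
    for var in kept:
        for group in groups:
            mat, _ = repeated_measures_matrix(df, var, group, hours)
            if mat.shape[0] >= 2:
                stat, p = friedman(mat)
                friedman_rows.append(
                    {"variable": var, "group": group, "statistic": stat, "p": p}
                )
                if p < alpha:  # the gate: post-hoc only when Friedman rejects
                    base_idx = list(hours).index(baseline)
                    for j, hour in enumerate(hours):
                        if hour == baseline:
                            continue
                        try:
                            wp = wilcoxon_signed_rank(mat[:, base_idx], mat[:, j])
                        except InsufficientDataError:
                            wp = float("nan")
                        wilcoxon_rows.append(
                            {"variable": var, "group": group, "timepoint": hour,
                             "p": wp, "significant": bool(wp < alpha)}
                        )
            for hour in hours:
                vals = df[(df["group"] == group) & (df["timepoint"] == hour)][var]
                med, q1, q3 = median_iqr(vals)
                summary_rows.append(
                    {"variable": var, "group": group, "timepoint": hour,
                     "median": med, "q1": q1, "q3": q3,
                     "label": format_median_iqr(vals)}
                )
        if group_a in groups and group_b in groups:
            for hour in hours:
                va = df[(df["group"] == group_a) & (df["timepoint"] == hour)][var]
                vb = df[(df["group"] == group_b) & (df["timepoint"] == hour)][var]
                va, vb = va.dropna(), vb.dropna()
                if va.empty or vb.empty:
                    continue
                p = mann_whitney(va, vb)
                mw_rows.append({"variable": var, "timepoint": hour, "p": p,
                                "significant": bool(p < alpha)})

    return StatReport(
        summary=pd.DataFrame(summary_rows),
        friedman=pd.DataFrame(friedman_rows),
        wilcoxon=pd.DataFrame(
            wilcoxon_rows,
            columns=["variable", "group", "timepoint", "p", "significant"],
        ),
        mannwhitney=pd.DataFrame(
            mw_rows, columns=["variable", "timepoint", "p", "significant"],
        ),
        alpha=alpha,
        variables=kept,
    )


__all__ = ["HOURS", "ALPHA", "friedman", "wilcoxon_signed_rank",
           "mann_whitney", "median_iqr", "format_median_iqr",
           "repeated_measures_matrix", "StatReport", "summarize"]
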