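"""Group-comparison statistics for per-larva metrics.

The reporting layer follows common practice in zebrafish cardiac
physiology: a Shapiro-Wilk normality gate routes each comparison to a
parametric branch (unpaired Student's t-test; one-way ANOVA with Tukey
or Dunnett post-tests) or a nonparametric branch (Mann-Whitney;
Kruskal-Wallis with Dunn post-test); nominal outcomes use the chi-square
test; correlations use ordinary least squares with R^2.  Significance
is coded at 0.05/0.01/0.001/0.0001 with the star family (*) for
parametric results and the x family for nonparametric ones.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "GroupTable",
    "significance_code",
    "normality_gate",
    "compare_two",
    "compare_many",
    "chi_square_counts",
    "linreg_r2",
]

_THRESHOLDS = (0.0001, 0.001, 0.01, 0.05)
_CODES = {"parametric": ("****", "***", "**", "*"), "nonparametric": ("xxxx", "xxx", "xx", "x")}


@dataclass
class TestResult:
    """Outcome of one statistical comparison."""

    test_name: str
    statistic: float
    p_value: float
    branch: str
    posthoc: list[tuple[tuple[str, str], float]] = field(default_factory=list)

    @property
    def significance_code(self) -> str:
        return significance_code(self.p_value, self.branch)


def significance_code(p: float, branch: str = "parametric") -> str:
    """Map a p-value to its star (parametric) or x (nonparametric) code."""
    if not (0 <= p <= 1):
        raise ValueError("p-value must lie in [0, 1]")
    codes = _CODES[branch]
    for threshold, code in zip(_THRESHOLDS, codes):
        if p < threshold:
            return code
    return "ns"


def _check_groups(groups, min_n: int = 3):
    cleaned = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if len(arr) < min_n:
            raise ValueError(f"every group needs n >= {min_n}, got {len(arr)}")
        cleaned.append(arr)
    return cleaned


def normality_gate(*groups, alpha: float = 0.05) -> str:
    """Route to 'parametric' iff every group passes Shapiro-Wilk at alpha."""
    cleaned = _check_groups(groups)
    for arr in cleaned:
        if np.ptp(arr) == 0:
            raise ValueError(
                "degenerate group (zero variance): normality test undefined"
            )
        if stats.shapiro(arr).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def compare_two(a, b, branch: str | None = None, equal_var: bool = True) -> TestResult:
    """Two-group comparison: Student's t-test or Mann-Whitney, two-sided.

    ``branch=None`` applies the normality gate.  ``equal_var=False``
    switches the parametric branch to Welch's t-test.  Degenerate
    (zero-variance in both groups) parametric input falls back to the
    nonparametric branch with a warning.
    """
    a, b = _check_groups([a, b])
    if branch is None:
        branch = normality_gate(a, b)
    if branch == "parametric":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                # identical constants: no evidence of any difference
                return TestResult("Student t", 0.0, 1.0, branch)
            warnings.warn(
                "zero variance in both groups: falling back to Mann-Whitney",
                stacklevel=2,
            )
            branch = "nonparametric"
        else:
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            name = "Student t" if equal_var else "Welch t"
            return TestResult(name, float(res.statistic), float(res.pvalue), branch)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        "Mann-Whitney U", float(res.statistic), float(res.pvalue), "nonparametric"
    )


def _dunn_posthoc(groups: dict[str, np.ndarray], pairs) -> list:
    """Dunn's rank-based multiple comparisons with Bonferroni adjustment."""
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(groups[k]) for k in labels])
    mean_ranks = {
        k: ranks[offsets[i] : offsets[i + 1]].mean() for i, k in enumerate(labels)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    m = len(pairs)
    for ka, kb in pairs:
        se = np.sqrt(var_base * (1.0 / len(groups[ka]) + 1.0 / len(groups[kb])))
        z = abs(mean_ranks[ka] - mean_ranks[kb]) / se
        p = min(1.0, 2.0 * stats.norm.sf(z) * m)
        out.append(((ka, kb), float(p)))
    return out


def compare_many(
    groups: dict[str, "np.ndarray | list"],
    branch: str | None = None,
    mode: str = "all_pairs",
    control: str | None = None,
) -> TestResult:
    """Multi-group comparison with adjusted post-test p-values.

    Parametric: one-way ANOVA with Tukey HSD (``mode='all_pairs'``) or
    Dunnett's test against ``control`` (``mode='vs_control'``).
    Nonparametric: Kruskal-Wallis with Dunn's post-test (Bonferroni-
    adjusted), either all pairs or versus the control group only.
    """
    if len(groups) < 3:
        raise ValueError("compare_many needs at least 3 groups")
    if mode not in ("all_pairs", "vs_control"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "vs_control":
        if control is None or control not in groups:
            raise ValueError("vs_control mode requires a control group label")
    labels = list(groups)
    arrays = dict(zip(labels, _check_groups([groups[k] for k in labels])))
    if branch is None:
        branch = normality_gate(*arrays.values())

    if mode == "all_pairs":
        pairs = list(itertools.combinations(labels, 2))
    else:
        pairs = [(control, k) for k in labels if k != control]

    if branch == "parametric":
        omnibus = stats.f_oneway(*arrays.values())
        if mode == "all_pairs":
            hsd = stats.tukey_hsd(*[arrays[k] for k in labels])
            posthoc = [
                ((labels[i], labels[j]), float(hsd.pvalue[i, j]))
                for i, j in itertools.combinations(range(len(labels)), 2)
            ]
            name = "one-way ANOVA + Tukey"
        else:
            others = [k for k in labels if k != control]
            dn = stats.dunnett(
                *[arrays[k] for k in others], control=arrays[control]
            )
            posthoc = [
                ((control, k), float(p)) for k, p in zip(others, dn.pvalue)
            ]
            name = "one-way ANOVA + Dunnett"
        return TestResult(
            name, float(omnibus.statistic), float(omnibus.pvalue), branch, posthoc
        )

    omnibus = stats.kruskal(*arrays.values())
    posthoc = _dunn_posthoc(arrays, pairs)
    return TestResult(
        "Kruskal-Wallis + Dunn",
        float(omnibus.statistic),
        float(omnibus.pvalue),
        "nonparametric",
        posthoc,
    )


def chi_square_counts(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction by default; enable Yates with
    ``correction=True``.  Degrees of freedom are (r-1)(c-1).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a contingency table of at least 2 x 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the contingency table")
    res = stats.chi2_contingency(table, correction=correction)
    return TestResult(
        "chi-square", float(res.statistic), float(res.pvalue), "parametric"
    )


def linreg_r2(x, y):
    """Ordinary least squares fit: returns (slope, intercept, r2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched x, y with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


class GroupTable:
    """Tidy per-larva metric table: (group, larva_id, metric, value) rows."""

    COLUMNS = ("group", "larva_id", "metric", "value")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"GroupTable missing columns: {sorted(missing)}")
        key = df[["group", "larva_id", "metric"]]
        if key.duplicated().any():
            raise ValueError("duplicated (group, larva_id, metric) key")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "GroupTable":
        return cls(pd.read_csv(path))

    def groups_for(self, metric: str) -> dict[str, np.ndarray]:
        sub = self.df[self.df["metric"] == metric]
        out = {
            g: grp["value"].to_numpy(dtype=float)
            for g, grp in sub.groupby("group", sort=False)
        }
        if not out:
            raise KeyError(f"metric {metric!r} not present")
        return out

    def compare(self, metric: str, mode: str = "all_pairs",
                control: str | None = None) -> TestResult:
        """Gate-and-compare one metric across all groups in the table."""
        groups = self.groups_for(metric)
        groups = {k: v[np.isfinite(v)] for k, v in groups.items()}
        if len(groups) == 2:
            (a, b) = groups.values()
            return compare_two(a, b)
        return compare_many(groups, mode=mode, control=control)
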