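"""Normality-driven statistical workflow for cell-level measurements.

Mirrors a common practice in cellular neurophysiology: summarise as
mean ± SEM; test normality per group (D'Agostino–Pearson when the sample is
large enough, Shapiro–Wilk otherwise); pick the two-sample test from the
normality and variance-equality outcomes; confirm significant cell-level
results with a nested, animal-aware analysis (mixed model with animal random
intercept, or an animal-level permutation test when the mixed fit fails).

All tests are two-tailed at α = 0.05 by default, and every comparison logs
the branch of the selection logic that fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CannotEstimateError, EmptyInputError, InsufficientDataError, ValidationError

#: Minimum per-group n for the D'Agostino–Pearson normality test; smaller
#: samples fall back to Shapiro–Wilk.
DAGOSTINO_MIN_N = 8


@dataclass
class SummaryStats:
    mean: float
    sem: float | None
    n: int

    def __str__(self) -> str:
        if self.sem is None:
            return f"{self.mean:g} (n=1)"
        return f"{self.mean:.4g} ± {self.sem:.3g} (n={self.n})"


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    alpha: float = 0.05
    tails: int = 2
    details: dict = field(default_factory=dict)
    decision_trace: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def summarize(values) -> SummaryStats:
    """Mean ± SEM with SEM = sample SD (n−1 denominator) / √n."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise EmptyInputError("cannot summarise an empty sample")
    if x.size == 1:
        return SummaryStats(mean=float(x[0]), sem=None, n=1)
    return SummaryStats(mean=float(x.mean()), sem=float(x.std(ddof=1) / np.sqrt(x.size)), n=int(x.size))


def format_proportion(k: int, n: int, decimals: int = 1) -> float:
    """Percentage k/n rounded to ``decimals`` (half away from zero)."""
    if n <= 0 or not 0 <= k <= n:
        raise ValidationError("need 0 <= k <= n, n > 0")
    pct = 100.0 * k / n
    scale = 10.0**decimals
    return float(np.floor(pct * scale + 0.5) / scale)


def _normality_p(x: np.ndarray) -> tuple[float, str]:
    if np.ptp(x) == 0:
        return 0.0, "constant"  # a point mass is maximally non-normal
    if x.size >= DAGOSTINO_MIN_N:
        return float(stats.normaltest(x).pvalue), "dagostino_pearson"
    return float(stats.shapiro(x).pvalue), "shapiro_wilk"


def _has_ties(*groups: np.ndarray) -> bool:
    pooled = np.concatenate(groups)
    return np.unique(pooled).size < pooled.size


def mann_whitney(a: np.ndarray, b: np.ndarray):
    """Two-sided Mann–Whitney U; exact null distribution for small tie-free
    samples (n ≤ 8 per group), asymptotic otherwise."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    exact = a.size <= 8 and b.size <= 8 and not _has_ties(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact else "auto")
    return res, exact


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray):
    """Two-sided Wilcoxon matched-pairs signed-rank; exact for small
    tie-free, zero-free difference sets."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    d = a - b
    exact = a.size <= 25 and not _has_ties(d) and np.all(d != 0)
    res = stats.wilcoxon(a, b, alternative="two-sided", mode="exact" if exact else "approx")
    return res, exact


def choose_and_compare(
    group_a,
    group_b,
    paired: bool = False,
    alpha: float = 0.05,
    welch: str = "auto",
) -> TestResult:
    """Two-group comparison with normality-driven test selection.

    Unpaired: t-test when both groups pass normality (Welch's correction when
    an F-ratio test rejects equal variances, or always when ``welch`` is
    ``"always"``), Mann–Whitney otherwise.  Paired: paired t vs Wilcoxon
    matched-pairs signed-rank.  Two-tailed throughout.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs n >= 3")
    if paired and a.size != b.size:
        raise ValidationError("paired comparison needs equal-length groups")
    trace: list[str] = []
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return TestResult("degenerate_equal", 0.0, 1.0, (a.size, b.size), alpha, decision_trace=["both groups constant and equal"])
    pa, name_a = _normality_p(a)
    pb, name_b = _normality_p(b)
    normal = pa >= alpha and pb >= alpha
    trace.append(f"normality: A {name_a} p={pa:.3g}, B {name_b} p={pb:.3g} -> {'normal' if normal else 'non-normal'}")
    if paired:
        if normal:
            res = stats.ttest_rel(a, b)
            name = "paired_t"
        else:
            res, _ = wilcoxon_signed_rank(a, b)
            name = "wilcoxon_signed_rank"
        trace.append(f"paired -> {name}")
    elif normal:
        sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
        if welch == "always":
            use_welch, trace_msg = True, "welch forced by config"
        else:
            f = max(sa2, sb2) / max(min(sa2, sb2), 1e-300)
            dfn = (a.size if sa2 >= sb2 else b.size) - 1
            dfd = (b.size if sa2 >= sb2 else a.size) - 1
            p_var = 2.0 * min(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
            use_welch = p_var < alpha
            trace_msg = f"F-ratio variance test p={p_var:.3g} -> {'unequal' if use_welch else 'equal'} variances"
        trace.append(trace_msg)
        res = stats.ttest_ind(a, b, equal_var=not use_welch)
        name = "welch_t" if use_welch else "student_t"
    else:
        res, exact = mann_whitney(a, b)
        name = "mann_whitney_u"
        trace.append(f"non-normal unpaired -> Mann-Whitney ({'exact' if exact else 'asymptotic'})")
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(a.size, b.size),
        alpha=alpha,
        details={"normality_p": (pa, pb)},
        decision_trace=trace,
    )


def repeated_measures_check(data) -> TestResult:
    """One-way repeated-measures ANOVA on an (n_subjects, k_timepoints) table.

    Complete cases only; missing values raise.  Classic within-subject
    decomposition: F = MS_time / MS_error with (k−1), (k−1)(n−1) df.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("need an (n_subjects, >=2 timepoints) array")
    if np.any(~np.isfinite(x)):
        raise ValidationError("incomplete cases are not allowed (no imputation)")
    n, k = x.shape
    grand = x.mean()
    ss_time = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_time - ss_subj
    df_time, df_err = k - 1, (k - 1) * (n - 1)
    if ss_time <= 1e-300:
        return TestResult("rm_anova", 0.0, 1.0, (n,), details={"df": (df_time, df_err)})
    ms_time = ss_time / df_time
    ms_err = ss_err / df_err
    f = np.inf if ms_err <= 0 else ms_time / ms_err
    p = 0.0 if not np.isfinite(f) else float(stats.f.sf(f, df_time, df_err))
    return TestResult(
        "rm_anova",
        float(f),
        p,
        (n,),
        details={"df": (df_time, df_err), "ss": {"time": ss_time, "subject": ss_subj, "error": ss_err}},
    )


def _records_frame(records, measurement: str, group_col: str, animal_col: str) -> pd.DataFrame:
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    for col in (measurement, group_col, animal_col):
        if col not in df.columns:
            raise ValidationError(f"records lack column {col!r}")
    return df.dropna(subset=[measurement])


def _animal_permutation_p(df: pd.DataFrame, measurement: str, group_col: str, animal_col: str, n_perm: int, seed: int) -> tuple[float, float]:
    """Permute group labels at the animal level; stat = cell-level mean diff."""
    animals = df.groupby(animal_col)[group_col].first()
    groups = animals.unique()
    obs = df.groupby(group_col)[measurement].mean()
    stat_obs = float(obs.loc[groups[0]] - obs.loc[groups[1]])
    rng = np.random.default_rng(seed)
    labels = animals.values.copy()
    vals = df[measurement].to_numpy()
    animal_of_cell = df[animal_col].to_numpy()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        lab_map = dict(zip(animals.index, perm))
        cell_lab = np.array([lab_map[a] for a in animal_of_cell])
        m0 = vals[cell_lab == groups[0]].mean()
        m1 = vals[cell_lab == groups[1]].mean()
        if abs(m0 - m1) >= abs(stat_obs) - 1e-12:
            count += 1
    return stat_obs, (count + 1) / (n_perm + 1)


def nested_compare(
    records,
    measurement: str,
    group_col: str = "subtype",
    animal_col: str = "animal_id",
    alpha: float = 0.05,
    method: str = "auto",
    n_perm: int = 10000,
    seed: int = 0,
) -> TestResult:
    """Animal-aware two-group comparison of a cell-level measurement.

    Primary route: linear mixed model (REML) of the measurement on group with
    an animal random intercept; the fixed-effect p-value uses a t reference
    with ``n_animals − 2`` degrees of freedom, which keeps the test honest
    with the few animals typical of slice studies.  Fallback (or
    ``method="permutation"``): a seeded permutation test that shuffles group
    labels at the animal level.
    """
    df = _records_frame(records, measurement, group_col, animal_col)
    groups = df[group_col].unique()
    if len(groups) != 2:
        raise ValidationError("nested comparison needs exactly two groups")
    per_group_animals = df.groupby(group_col)[animal_col].nunique()
    if per_group_animals.min() < 2:
        raise CannotEstimateError(
            "need >= 2 animals per group to separate animal and group effects"
        )
    mixed_groups = df.groupby(animal_col)[group_col].nunique()
    if mixed_groups.max() > 1:
        raise ValidationError("each animal must belong to a single group")
    n_per = tuple(int(v) for v in df.groupby(group_col)[measurement].count())
    if np.ptp(df[measurement].to_numpy()) == 0:
        return TestResult("nested_degenerate", 0.0, 1.0, n_per, alpha, decision_trace=["measurement constant everywhere"])
    n_animals = int(df[animal_col].nunique())

    if method in ("auto", "mixed"):
        try:
            import warnings

            import statsmodels.formula.api as smf

            work = df.rename(columns={measurement: "_y", group_col: "_g", animal_col: "_a"})
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm("_y ~ C(_g)", data=work, groups=work["_a"]).fit(reml=True)
            coef_name = [c for c in fit.params.index if c.startswith("C(_g)")][0]
            est = float(fit.params[coef_name])
            se = float(fit.bse[coef_name])
            if not (np.isfinite(est) and np.isfinite(se) and se > 0):
                raise ValueError("singular mixed fit")
            tval = est / se
            p = float(2.0 * stats.t.sf(abs(tval), df=max(n_animals - 2, 1)))
            return TestResult(
                "nested_mixed_model",
                tval,
                p,
                n_per,
                alpha,
                details={
                    "effect": est,
                    "se": se,
                    "df": n_animals - 2,
                    "animal_var": float(fit.cov_re.iloc[0, 0]),
                    "residual_var": float(fit.scale),
                },
                decision_trace=["mixed model (REML), t with n_animals-2 df"],
            )
        except Exception as exc:  # singular / non-converged -> permutation
            if method == "mixed":
                raise CannotEstimateError(f"mixed model failed: {exc}") from exc
    stat, p = _animal_permutation_p(df, measurement, group_col, animal_col, n_perm, seed)
    return TestResult(
        "nested_permutation",
        stat,
        p,
        n_per,
        alpha,
        details={"n_perm": n_perm},
        decision_trace=["animal-level permutation test"],
    )


def mean_sem_sentence(name: str, values, unit: str = "") -> str:
    """Results-style sentence fragment: 'name: mean ± SEM unit; n=…'."""
    s = summarize(values)
    unit_s = f" {unit}" if unit else ""
    if s.sem is None:
        return f"{name}: {s.mean:.4g}{unit_s}; n=1"
    return f"{name}: {s.mean:.4g} ± {s.sem:.3g}{unit_s}; n={s.n}"
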