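"""Group-comparison statistics for per-animal time-course summaries.

The designs here are animals x hours matrices with one between-subject
factor (group: e.g. control vs chronic morphine) and one within-subject
factor (time).  Provided: the pooled-variance unpaired t-test, the
classical split-plot (mixed-design) two-way ANOVA, and a label-permutation
alternative that keeps each animal's time course intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "DesignMatrix",
    "TTestResult",
    "AnovaResult",
    "PermutationResult",
    "unpaired_t_test",
    "mixed_anova",
    "permutation_group_test",
]


@dataclass
class DesignMatrix:
    """Animals x time-points response matrix with group labels.

    Every animal must have a value at every time point (complete
    within-subject grid); group sizes may differ but each group needs at
    least two animals for inference.
    """

    values: np.ndarray
    groups: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D animals x times matrix")
        if self.groups.shape != (self.values.shape[0],):
            raise ValueError("one group label per animal is required")
        if np.isnan(self.values).any():
            raise ValueError(
                "missing cells: every animal needs a value at every time point"
            )
        if self.times is None:
            self.times = np.arange(self.values.shape[1])
        self.times = np.asarray(self.times)
        if self.times.shape != (self.values.shape[1],):
            raise ValueError("one time label per column is required")
        _, counts = np.unique(self.groups, return_counts=True)
        if (counts < 2).any():
            raise ValueError("each group needs at least two animals")

    @classmethod
    def from_tidy(
        cls,
        df: pd.DataFrame,
        value: str,
        subject: str,
        group: str,
        time: str,
    ) -> "DesignMatrix":
        """Build from a tidy frame with one row per (subject, time)."""
        wide = df.pivot(index=subject, columns=time, values=value)
        grp = df.drop_duplicates(subject).set_index(subject)[group]
        grp = grp.loc[wide.index]
        return cls(
            values=wide.to_numpy(),
            groups=grp.to_numpy(),
            times=wide.columns.to_numpy(),
        )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def unpaired_t_test(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test between independent groups.

    Pooled-variance (Student) by default with df = n1 + n2 - 2; Welch's
    unequal-variance form as an option.  ``alternative`` is 'two-sided',
    'less', or 'greater' (one-sided modes test the mean of x against y).
    Two identical constant samples give t = 0, p = 1; constant samples
    with different means have no valid scale and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, float(x.size + y.size - 2), 1.0)
        raise ValueError(
            "degenerate samples: zero variance with unequal means"
        )
    res = _sstats.ttest_ind(x, y, equal_var=not welch, alternative=alternative)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


@dataclass(frozen=True)
class AnovaResult:
    """Split-plot ANOVA table: group, time, and group x time effects."""

    F_group: float
    F_time: float
    F_interaction: float
    df_group: tuple[int, int]
    df_time: tuple[float, float]
    df_interaction: tuple[float, float]
    p_group: float
    p_time: float
    p_interaction: float
    ss: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "F": [self.F_group, self.F_time, self.F_interaction],
                "df1": [
                    self.df_group[0],
                    self.df_time[0],
                    self.df_interaction[0],
                ],
                "df2": [
                    self.df_group[1],
                    self.df_time[1],
                    self.df_interaction[1],
                ],
                "p": [self.p_group, self.p_time, self.p_interaction],
            },
            index=["group", "time", "group x time"],
        )


def _gg_epsilon(d: DesignMatrix) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    t = d.n_times
    pooled = np.zeros((t, t))
    dof = 0
    for g in np.unique(d.groups):
        sub = d.values[d.groups == g]
        pooled += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
        dof += sub.shape[0] - 1
    s = pooled / dof
    mean_diag = np.trace(s) / t
    num = (t * mean_diag - s.mean()) ** 2
    den = (t - 1) * (
        (s**2).sum() - 2 * t * (s.mean(axis=1) ** 2).sum() + t**2 * s.mean() ** 2
    )
    eps = num / den if den > 0 else 1.0
    return float(min(max(eps, 1.0 / (t - 1)), 1.0))


def mixed_anova(d: DesignMatrix, correction: str | None = None) -> AnovaResult:
    """Classical split-plot two-way ANOVA.

    Between-subject factor: group, tested against subjects-within-group;
    within-subject factor: time, and the group x time interaction, tested
    against the subject x time residual.  The sums of squares decompose
    the total exactly even with unequal group sizes, as long as the time
    grid is complete.

    Parameters
    ----------
    correction
        None (default) or ``"gg"`` for Greenhouse-Geisser-adjusted
        degrees of freedom on the within-subject p-values.
    """
    y = d.values
    n, t = y.shape
    group_labels = np.unique(d.groups)
    g = group_labels.size
    if g < 2:
        raise ValueError("need at least two groups")
    if t < 2:
        raise ValueError("need at least two time points")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)

    ss_group = 0.0
    ss_subj = 0.0
    ss_int = 0.0
    for lbl in group_labels:
        mask = d.groups == lbl
        ng = mask.sum()
        gm = y[mask].mean()
        ss_group += ng * t * (gm - grand) ** 2
        ss_subj += t * ((subj_means[mask] - gm) ** 2).sum()
        cell = y[mask].mean(axis=0)  # per-time means within group
        ss_int += ng * ((cell - gm - time_means + grand) ** 2).sum()
    ss_time = n * ((time_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj - ss_time - ss_int

    df_group = (g - 1, n - g)
    df_time = (t - 1, (n - g) * (t - 1))
    df_int = ((g - 1) * (t - 1), (n - g) * (t - 1))

    ms_group = ss_group / df_group[0]
    ms_subj = ss_subj / df_group[1]
    ms_time = ss_time / df_time[0]
    ms_int = ss_int / df_int[0]
    ms_err = ss_err / df_time[1]

    def _f(ms_num: float, ms_den: float) -> float:
        if ms_den == 0.0:
            return 0.0 if ms_num == 0.0 else math.inf
        return ms_num / ms_den

    f_group = _f(ms_group, ms_subj)
    f_time = _f(ms_time, ms_err)
    f_int = _f(ms_int, ms_err)

    eps = _gg_epsilon(d) if correction == "gg" else 1.0
    p_group = float(_sstats.f.sf(f_group, *df_group))
    p_time = float(_sstats.f.sf(f_time, eps * df_time[0], eps * df_time[1]))
    p_int = float(_sstats.f.sf(f_int, eps * df_int[0], eps * df_int[1]))

    return AnovaResult(
        F_group=float(f_group),
        F_time=float(f_time),
        F_interaction=float(f_int),
        df_group=df_group,
        df_time=(eps * df_time[0], eps * df_time[1]),
        df_interaction=(eps * df_int[0], eps * df_int[1]),
        p_group=p_group,
        p_time=p_time,
        p_interaction=p_int,
        ss={
            "group": float(ss_group),
            "subjects_within_group": float(ss_subj),
            "time": float(ss_time),
            "interaction": float(ss_int),
            "error": float(ss_err),
            "total": float(ss_total),
        },
    )


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    observed: float
    n_perm: int
    exhaustive: bool
    per_time_p: np.ndarray | None = None


def _statistic(values: np.ndarray, groups: np.ndarray, kind: str):
    labels = np.unique(groups)
    if kind == "group_F":
        return mixed_anova(DesignMatrix(values, groups)).F_group, None
    if labels.size != 2:
        raise ValueError(f"statistic {kind!r} requires exactly two groups")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if kind == "mean_diff":
        return abs(a.mean() - b.mean()), None
    if kind == "max_t":
        tvals = np.abs(
            _sstats.ttest_ind(a, b, axis=0, equal_var=True).statistic
        )
        return float(tvals.max()), tvals
    raise ValueError(f"unknown statistic {kind!r}")


def permutation_group_test(
    d: DesignMatrix,
    statistic: str = "group_F",
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test of the between-group effect.

    Group labels are permuted across animals while each animal's time
    course stays intact, so the test is exact under exchangeability of
    whole animals.  Statistics: ``group_F`` (split-plot group F),
    ``mean_diff`` (absolute difference of group means, two groups), or
    ``max_t`` (maximum absolute per-time-point t; also yields max-T
    family-wise-adjusted per-time p-values).

    With two groups, when the number of distinct relabelings does not
    exceed ``n_perm`` the null distribution is enumerated exhaustively
    and the p-value is the exact proportion of relabelings with a
    statistic at least as large as the observed one; otherwise ``n_perm``
    random permutations are drawn and p = (1 + #{perm >= obs}) /
    (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    obs, obs_per_time = _statistic(d.values, d.groups, statistic)

    labels = np.unique(d.groups)
    n = d.n_subjects
    exhaustive = False
    perms: list[np.ndarray] = []
    if labels.size == 2:
        n1 = int((d.groups == labels[0]).sum())
        n_distinct = math.comb(n, n1)
        if n_distinct <= n_perm:
            exhaustive = True
            for idx in combinations(range(n), n1):
                lab = np.full(n, labels[1], dtype=d.groups.dtype)
                lab[list(idx)] = labels[0]
                perms.append(lab)
    if not exhaustive:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(d.groups) for _ in range(n_perm)]

    stats = np.empty(len(perms))
    per_time_null = [] if obs_per_time is not None else None
    for i, lab in enumerate(perms):
        s, pt = _statistic(d.values, lab, statistic)
        stats[i] = s
        if per_time_null is not None:
            per_time_null.append(s)  # max-T: null of the maximum

    tol = 1e-12 * max(1.0, abs(obs))
    n_ge = int(np.count_nonzero(stats >= obs - tol))
    if exhaustive:
        p = n_ge / len(perms)
    else:
        p = (1 + n_ge) / (1 + len(perms))

    per_time_p = None
    if obs_per_time is not None:
        null_max = np.asarray(per_time_null)
        counts = (null_max[:, None] >= obs_per_time[None, :] - tol).sum(axis=0)
        if exhaustive:
            per_time_p = counts / len(perms)
        else:
            per_time_p = (1 + counts) / (1 + len(perms))

    return PermutationResult(
        p_value=float(p),
        observed=float(obs),
        n_perm=len(perms),
        exhaustive=exhaustive,
        per_time_p=per_time_p,
    )
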