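"""Group-level statistics on binned peri-event traces.

The analysis design treats the 20 post-stimulus group-mean bins as the
repeated-measures unit: each bin contributes one value per timepoint
(baseline, injection, day 2, day 6, day 28), collapsed across the subjects
of a group.  That choice — bins, not animals, as rows — is statistically
unusual but is the design the degrees of freedom of the reference analyses
require (e.g. a within-group error df of 4x19 = 76 before sphericity
correction, and a 2x20-row between design with df 1, 38), and it is stated
explicitly here for that reason.

Provided tests:

* one-way repeated-measures ANOVA with Greenhouse-Geisser (GG) correction and
  Dunnett's comparisons against baseline;
* Friedman test with Dunn's rank comparisons (non-normal groups);
* mixed (split-plot) two-way ANOVA — treatment between, timepoint within —
  with Sidak-adjusted per-timepoint contrasts;
* paired t on per-subject peak points;
* Fisher's exact test on 2x2 threat-response tables.

The RM and mixed ANOVA fits are delegated to pingouin; Dunnett adjusted
p-values integrate the equicorrelated (rho = 1/2) multivariate t
distribution with a seeded quasi-Monte-Carlo rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .perievent import BinnedTrace
from .session_io import ValidationError

__all__ = [
    "DegenerateStatisticError",
    "PosthocComparison",
    "AnovaResult",
    "FriedmanResult",
    "MixedAnovaResult",
    "collapse_group",
    "bin_by_timepoint_matrix",
    "rm_anova_gg",
    "friedman_dunn",
    "mixed_two_way_anova",
    "paired_t",
    "fisher_exact_2x2",
    "gg_epsilon",
]


class DegenerateStatisticError(ValueError):
    """The requested statistic is undefined on this input (e.g. 0/0 variance)."""


@dataclass(frozen=True)
class PosthocComparison:
    comparison: str
    estimate: float
    statistic: float
    p_uncorrected: float
    p_adjusted: float


@dataclass
class AnovaResult:
    F: float
    df1: float
    df2: float
    epsilon: float
    p: float
    p_uncorrected: float
    posthoc: list[PosthocComparison] = field(default_factory=list)


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    posthoc: list[PosthocComparison] = field(default_factory=list)


@dataclass
class MixedAnovaResult:
    between: AnovaResult
    within: AnovaResult
    interaction: AnovaResult
    posthoc: list[PosthocComparison] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------


def collapse_group(traces: list[BinnedTrace]) -> np.ndarray:
    """Per-bin mean across the subjects of one group/timepoint (post bins only)."""
    if not traces:
        raise ValidationError("empty group")
    for t in traces:
        if not t.normalized:
            raise ValidationError("collapse_group expects normalized traces")
    post = np.stack([t.post for t in traces])
    return post.mean(axis=0)


def bin_by_timepoint_matrix(groups: dict[str, list[BinnedTrace]],
                            timepoints: list[str] | None = None) -> pd.DataFrame:
    """20 post bins x timepoints matrix of group means.

    ``groups`` maps timepoint name to that timepoint's normalized traces.
    """
    timepoints = timepoints or list(groups)
    cols = {tp: collapse_group(groups[tp]) for tp in timepoints}
    lengths = {v.size for v in cols.values()}
    if len(lengths) != 1:
        raise ValidationError("timepoints disagree on post-bin count")
    df = pd.DataFrame(cols)
    df.index.name = "bin"
    return df


def _check_complete(matrix: pd.DataFrame) -> None:
    if matrix.isna().any().any():
        raise ValidationError("matrix has missing cells; RM designs must be complete")


def _long(matrix: pd.DataFrame) -> pd.DataFrame:
    long = matrix.reset_index(names="row").melt(
        id_vars="row", var_name="condition", value_name="value"
    )
    return long


# ---------------------------------------------------------------------------
# Greenhouse-Geisser epsilon
# ---------------------------------------------------------------------------


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction from a k x k condition covariance.

    With S the double-centered covariance, eps = trace(S)^2 / ((k-1) sum S^2),
    clamped to the admissible interval [1/(k-1), 1].
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValidationError("covariance must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValidationError("need at least 2 conditions")
    C = np.eye(k) - np.ones((k, k)) / k
    Sc = C @ S @ C
    denom = (k - 1) * np.sum(Sc ** 2)
    if denom == 0:
        return 1.0
    eps = np.trace(Sc) ** 2 / denom
    return float(min(1.0, max(1.0 / (k - 1), eps)))


# ---------------------------------------------------------------------------
# Dunnett adjustment (equicorrelated multivariate t, rho = 1/2)
# ---------------------------------------------------------------------------


def _dunnett_adjusted_p(t_obs: float, df: float, m: int, seed: int = 0) -> float:
    """Two-sided family-wise p for one of m comparisons against a common control.

    P(max_j |T_j| >= |t|) where T is m-variate t with df degrees of freedom
    and pairwise correlation 1/2 (equal group sizes sharing the control).
    Evaluated by seeded quasi-Monte-Carlo integration of the rectangle
    probability; for m = 1 this is the ordinary two-sided t-tail.
    """
    t_abs = abs(float(t_obs))
    if m == 1:
        return float(2 * stats.t.sf(t_abs, df))
    shape = np.eye(m) * 0.5 + 0.5
    mvt = stats.multivariate_t(loc=np.zeros(m), shape=shape, df=df)
    inside = mvt.cdf(
        np.full(m, t_abs),
        lower_limit=np.full(m, -t_abs),
        random_state=np.random.default_rng(seed),
    )
    return float(min(1.0, max(0.0, 1.0 - inside)))


# ---------------------------------------------------------------------------
# Repeated-measures one-way ANOVA + Dunnett
# ---------------------------------------------------------------------------


def rm_anova_gg(matrix: pd.DataFrame, baseline: str = "baseline",
                dunnett_seed: int = 0) -> AnovaResult:
    """One-way RM-ANOVA over the matrix columns with GG-corrected dfs.

    Rows are the repeated-measures units; ``baseline`` names the reference
    column for Dunnett's comparisons.  Reported dfs are eps*(k-1) and
    eps*(k-1)*(n-1); the reported p uses them.
    """
    _check_complete(matrix)
    k = matrix.shape[1]
    n = matrix.shape[0]
    if k < 2:
        raise ValidationError("need at least 2 timepoints")
    if n < 3:
        raise ValidationError("need at least 3 repeated-measures rows")
    if baseline not in matrix.columns:
        raise ValidationError(f"baseline column {baseline!r} not in matrix")

    # degenerate designs (zero residual variance) break the F ratio; resolve
    # them by the sums of squares directly
    y = matrix.to_numpy()
    grand = y.mean()
    ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_row = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_err_direct = np.sum((y - grand) ** 2) - ss_cond - ss_row
    scale = max(np.sum((y - grand) ** 2), 1.0)
    if ss_err_direct <= 1e-12 * scale:
        degenerate_F = 0.0 if ss_cond <= 1e-12 * scale else np.inf
        p_val = 1.0 if degenerate_F == 0.0 else 0.0
        posthoc = [
            PosthocComparison(
                comparison=f"{c} vs {baseline}",
                estimate=float(matrix[c].mean() - matrix[baseline].mean()),
                statistic=0.0 if p_val == 1.0 else np.inf,
                p_uncorrected=p_val, p_adjusted=p_val,
            )
            for c in matrix.columns if c != baseline
        ]
        return AnovaResult(F=degenerate_F, df1=float(k - 1),
                           df2=float((k - 1) * (n - 1)), epsilon=1.0,
                           p=p_val, p_uncorrected=p_val, posthoc=posthoc)

    aov = pg.rm_anova(
        data=_long(matrix), dv="value", within="condition", subject="row",
        correction=True, detailed=True,
    )
    F = float(aov.loc[0, "F"])
    eps = float(aov.loc[0, "eps"])
    ss_err = float(aov.loc[1, "SS"])
    df_err = float(aov.loc[1, "DF"])
    mse = ss_err / df_err
    if not np.isfinite(F):
        # 0/0: no condition effect and no residual variance
        F = 0.0
    if not np.isfinite(eps):
        eps = 1.0
    df1, df2 = eps * (k - 1), eps * (k - 1) * (n - 1)
    p_unc = float(stats.f.sf(F, k - 1, (k - 1) * (n - 1)))
    p = float(stats.f.sf(F, df1, df2))

    means = matrix.mean(axis=0)
    others = [c for c in matrix.columns if c != baseline]
    posthoc = []
    if mse > 0:
        se = np.sqrt(2.0 * mse / n)
        for c in others:
            t = float((means[c] - means[baseline]) / se)
            p_c = float(2 * stats.t.sf(abs(t), df_err))
            p_adj = _dunnett_adjusted_p(t, df_err, len(others), seed=dunnett_seed)
            posthoc.append(PosthocComparison(
                comparison=f"{c} vs {baseline}",
                estimate=float(means[c] - means[baseline]),
                statistic=t,
                p_uncorrected=p_c,
                p_adjusted=max(p_adj, p_c),
            ))
    else:
        for c in others:
            posthoc.append(PosthocComparison(
                comparison=f"{c} vs {baseline}", estimate=0.0,
                statistic=0.0, p_uncorrected=1.0, p_adjusted=1.0,
            ))
    return AnovaResult(F=F, df1=df1, df2=df2, epsilon=eps, p=p,
                       p_uncorrected=p_unc, posthoc=posthoc)


# ---------------------------------------------------------------------------
# Friedman + Dunn
# ---------------------------------------------------------------------------


def friedman_dunn(matrix: pd.DataFrame, baseline: str = "baseline",
                  family: str = "vs_baseline") -> FriedmanResult:
    """Friedman rank test over columns with Dunn's multiple comparisons.

    ``family`` selects the comparison family: ``"vs_baseline"`` (default,
    mirroring Dunnett) or ``"all_pairs"``.  Dunn z statistics are adjusted
    by Bonferroni scaling over the family.
    """
    _check_complete(matrix)
    if family not in {"vs_baseline", "all_pairs"}:
        raise ValueError(f"unknown comparison family {family!r}")
    k = matrix.shape[1]
    n = matrix.shape[0]
    if k < 3:
        # scipy's Friedman needs >= 3 conditions; 2-condition designs reduce
        # to a sign/Wilcoxon situation outside this operation's contract.
        raise ValidationError("Friedman test needs at least 3 timepoints")
    if baseline not in matrix.columns:
        raise ValidationError(f"baseline column {baseline!r} not in matrix")
    values = [matrix[c].to_numpy() for c in matrix.columns]
    if np.ptp(np.stack(values), axis=0).max() == 0:
        # every row constant across conditions: no rank information
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*values)

    ranks = np.apply_along_axis(stats.rankdata, 1, matrix.to_numpy())
    mean_ranks = pd.Series(ranks.mean(axis=0), index=matrix.columns)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    if family == "vs_baseline":
        pairs = [(c, baseline) for c in matrix.columns if c != baseline]
    else:
        cols = list(matrix.columns)
        pairs = [(cols[j], cols[i]) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    posthoc = []
    for a, b in pairs:
        z = float((mean_ranks[a] - mean_ranks[b]) / se)
        p_unc = float(2 * stats.norm.sf(abs(z)))
        posthoc.append(PosthocComparison(
            comparison=f"{a} vs {b}",
            estimate=float(mean_ranks[a] - mean_ranks[b]),
            statistic=z,
            p_uncorrected=p_unc,
            p_adjusted=float(min(1.0, m * p_unc)),
        ))
    return FriedmanResult(chi2=float(chi2), df=k - 1, p=float(p), posthoc=posthoc)


# ---------------------------------------------------------------------------
# Mixed (split-plot) two-way ANOVA + Sidak
# ---------------------------------------------------------------------------


def mixed_two_way_anova(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                        labels: tuple[str, str] = ("vehicle", "psilocin"),
                        alpha: float = 0.05) -> MixedAnovaResult:
    """Treatment (between) x timepoint (within) split-plot ANOVA.

    Each matrix holds one group's rows (bins) x timepoints; rows of the two
    groups are independent units.  The within factor's p is GG-corrected;
    the between and interaction terms are reported on uncorrected dfs.
    Sidak contrasts compare the groups at each timepoint with a pooled
    two-sample t; adjusted p = 1 - (1 - p)^m over the m timepoints.
    """
    _check_complete(matrix_a)
    _check_complete(matrix_b)
    if list(matrix_a.columns) != list(matrix_b.columns):
        raise ValidationError("groups must share the same timepoint columns")
    if matrix_a.shape != matrix_b.shape:
        raise ValidationError(
            f"mismatched shapes {matrix_a.shape} vs {matrix_b.shape}"
        )
    k = matrix_a.shape[1]
    rows = []
    for g_label, mat in zip(labels, (matrix_a, matrix_b)):
        for i, row in mat.iterrows():
            for c in mat.columns:
                rows.append((f"{g_label}:{i}", g_label, c, row[c]))
    long = pd.DataFrame(rows, columns=["subj", "group", "condition", "value"])
    aov = pg.mixed_anova(
        data=long, dv="value", within="condition", between="group",
        subject="subj", correction=True,
    ).set_index("Source")

    def term(name: str, corrected: bool) -> AnovaResult:
        r = aov.loc[name]
        F = float(r["F"])
        df1, df2 = float(r["DF1"]), float(r["DF2"])
        p_unc = float(r["p_unc"])
        eps = float(r["eps"]) if corrected and np.isfinite(r.get("eps", np.nan)) else 1.0
        if corrected and eps < 1.0:
            p = float(stats.f.sf(F, eps * df1, eps * df2))
            return AnovaResult(F=F, df1=eps * df1, df2=eps * df2, epsilon=eps,
                               p=p, p_uncorrected=p_unc)
        return AnovaResult(F=F, df1=df1, df2=df2, epsilon=eps, p=p_unc,
                           p_uncorrected=p_unc)

    between = term("group", corrected=False)
    within = term("condition", corrected=True)
    interaction = term("Interaction", corrected=False)

    n_a, n_b = matrix_a.shape[0], matrix_b.shape[0]
    posthoc = []
    for c in matrix_a.columns:
        a, b = matrix_a[c].to_numpy(), matrix_b[c].to_numpy()
        diff = a.mean() - b.mean()
        sp2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
        if sp2 == 0:
            t, p_unc = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
        else:
            t = diff / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
            p_unc = float(2 * stats.t.sf(abs(t), n_a + n_b - 2))
        p_adj = float(1.0 - (1.0 - p_unc) ** k)
        posthoc.append(PosthocComparison(
            comparison=f"{labels[0]} vs {labels[1]} @ {c}",
            estimate=float(diff), statistic=float(t),
            p_uncorrected=p_unc, p_adjusted=max(p_adj, p_unc),
        ))
    return MixedAnovaResult(between=between, within=within,
                            interaction=interaction, posthoc=posthoc)


# ---------------------------------------------------------------------------
# Paired t and Fisher exact
# ---------------------------------------------------------------------------


def paired_t(peaks_a, peaks_b) -> tuple[float, int, float]:
    """Paired t test on per-subject summary values (same subjects, two sessions)."""
    a = np.asarray(peaks_a, dtype=float)
    b = np.asarray(peaks_b, dtype=float)
    if a.size != b.size:
        raise ValidationError("paired samples must have equal length")
    if a.size < 2:
        raise ValidationError("paired t needs n >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        if d[0] == 0:
            return 0.0, a.size - 1, 1.0
        raise DegenerateStatisticError(
            "constant nonzero difference: paired t undefined (zero variance)"
        )
    t, p = stats.ttest_rel(a, b)
    return float(t), a.size - 1, float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities of tables (at fixed margins) no more
    probable than the observed one; degenerate margins give p = 1.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab_f = np.asarray(table, dtype=float)
        if np.any(tab_f < 0) or np.any(tab_f != np.round(tab_f)):
            raise ValidationError("table entries must be nonnegative integers")
        tab = tab_f.astype(int)
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    return float(p)
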