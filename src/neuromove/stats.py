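"""Statistical layer: mixed ANOVA with partial eta-squared, BH-corrected
post-hocs, Spearman (partial) rank correlations and normality checks.

The mixed ANOVA handles one between-subject factor (group) and any
number of two-level within-subject factors on balanced, complete data
(subjects with incomplete cells are dropped listwise).  The classical
univariate decomposition is computed by recursive mean-centring
(a Moebius inversion over factor subsets): each effect is the cell-mean
array minus all lower-order effects, its sum of squares the sum of the
squared effect broadcast over the full data array.  Between-subject
effects are tested against the subject-within-group mean square; every
within effect is tested against its own subject-interaction mean square.
With two-level within factors sphericity is not an issue, so no
correction is applied (a guard raises for factors with more levels).

Partial eta squared is SS_effect / (SS_effect + SS_error-term); the
conventional small/medium/large landmarks 0.02 / 0.13 / 0.26 are used
for labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "AnovaResult",
    "CorrelationResult",
    "mixed_anova",
    "posthoc_pairwise",
    "bh_adjust",
    "spearman_partial",
    "effect_size_label",
    "shapiro_check",
]


@dataclass
class AnovaResult:
    """Mixed-ANOVA effects table plus per-cell normality checks."""

    table: pd.DataFrame  # effect, df_num, df_den, F, p, eta2p
    normality: dict[str, float] = field(default_factory=dict)  # cell -> Shapiro p
    dv: str = ""

    def effect(self, name: str) -> pd.Series:
        m = self.table[self.table["effect"] == name]
        if m.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.table['effect'])}")
        return m.iloc[0]


@dataclass
class CorrelationResult:
    """Spearman (partial) rank correlation with the r_s^2 reporting filter."""

    x: str
    y: str
    covariates: tuple[str, ...]
    rho: float
    r_s2: float
    p: float
    n: int
    reported: bool  # r_s^2 > 0.25
    defined: bool = True


def _subsets(items: tuple) -> list[tuple]:
    return list(chain.from_iterable(combinations(items, r) for r in range(len(items) + 1)))


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    between: str = "group",
    within: tuple[str, ...] | list[str] = ("hand",),
    subject: str = "subject",
) -> AnovaResult:
    """Balanced mixed ANOVA for one between and >=1 within factors.

    Subjects missing any within cell are dropped listwise; fewer than two
    complete subjects per group is an error.
    """
    within = tuple(within)
    if dv not in table.columns:
        raise ValueError(f"dv {dv!r} not in table")
    for f in (between, subject, *within):
        if f not in table.columns:
            raise ValueError(f"factor {f!r} not in table")
    df = table.dropna(subset=[dv]).copy()

    levels = {w: sorted(df[w].dropna().unique()) for w in within}
    for w, lv in levels.items():
        if len(lv) > 2:
            raise NotImplementedError(
                f"within factor {w!r} has {len(lv)} levels; sphericity handling "
                "for >2 levels is not supported"
            )
        if len(lv) < 2:
            raise ValueError(f"within factor {w!r} has fewer than 2 levels")
    n_cells = int(np.prod([len(lv) for lv in levels.values()]))

    # one row per subject x cell; listwise-complete subjects only
    pivot = df.pivot_table(
        index=subject, columns=list(within), values=dv, aggfunc="mean", observed=True
    )
    complete = pivot.dropna()
    if complete.shape[1] != n_cells:
        raise ValueError("within-factor cells are not fully crossed")
    groups = df.drop_duplicates(subject).set_index(subject)[between]
    g_of = groups.loc[complete.index]
    group_levels = sorted(g_of.unique())
    counts = g_of.value_counts()
    if (counts < 2).any() or len(group_levels) < 2:
        raise ValueError("need at least 2 complete subjects in each group")

    # data array (N, l1, ..., lk) ordered by group then subject id
    idx_sorted = complete.index[np.lexsort((complete.index, g_of[complete.index].map(group_levels.index)))]
    shape = [len(levels[w]) for w in within]
    Y = complete.loc[idx_sorted].to_numpy().reshape([len(idx_sorted)] + shape)
    g = g_of[idx_sorted].map(group_levels.index).to_numpy()
    N, n_groups = len(idx_sorted), len(group_levels)

    def group_mean_rows(A: np.ndarray) -> np.ndarray:
        """Replace each subject row by its group mean (over subject axis)."""
        out = np.empty_like(A)
        for gi in range(n_groups):
            out[g == gi] = A[g == gi].mean(axis=0, keepdims=True)
        return out

    within_axes = {w: i + 1 for i, w in enumerate(within)}
    grand = Y.mean()

    effects: dict[tuple, np.ndarray] = {(0, ()): np.broadcast_to(grand, Y.shape)}

    def term_mean(b: int, S: tuple[str, ...]) -> np.ndarray:
        """Mean of Y keeping (group if b) and the within factors in S."""
        axes = tuple(within_axes[w] for w in within if w not in S)
        M = Y.mean(axis=axes, keepdims=True) if axes else Y.copy()
        M = np.broadcast_to(M, Y.shape).copy()
        M = group_mean_rows(M) if b else np.broadcast_to(M.mean(axis=0, keepdims=True), Y.shape)
        return M

    # fixed effects: all (b, S) != (0, ())
    for S in _subsets(within):
        for b in (0, 1):
            if b == 0 and not S:
                continue
            M = term_mean(b, S)
            eff = M.copy()
            for S2 in _subsets(S):
                for b2 in range(b + 1):
                    if (b2, S2) != (b, S) and (b2, S2) in effects:
                        eff = eff - effects[(b2, S2)]
            effects[(b, S)] = eff

    # subject terms: ("s", S) for all subsets S (S = () is the between error)
    subj_effects: dict[tuple, np.ndarray] = {}
    for S in _subsets(within):
        axes = tuple(within_axes[w] for w in within if w not in S)
        M = Y.mean(axis=axes, keepdims=True) if axes else Y.copy()
        M = np.broadcast_to(M, Y.shape).copy()
        eff = M.copy()
        for S2 in _subsets(S):
            for b2 in (0, 1):
                if (b2, S2) in effects:
                    eff = eff - effects[(b2, S2)]
            if S2 != S and ("s", S2) in subj_effects:
                eff = eff - subj_effects[("s", S2)]
        subj_effects[("s", S)] = eff

    def ss(arr: np.ndarray) -> float:
        return float(np.sum(arr * arr))

    def df_within(S: tuple[str, ...]) -> int:
        return int(np.prod([len(levels[w]) - 1 for w in S])) if S else 1

    rows = []
    normality: dict[str, float] = {}
    for S in _subsets(within):
        for b in (0, 1):
            if b == 0 and not S:
                continue
            name = ":".join(([between] if b else []) + list(S))
            ss_eff = ss(effects[(b, S)])
            ss_err = ss(subj_effects[("s", S)])
            df_num = (n_groups - 1) ** b * df_within(S)
            df_den = (N - n_groups) * df_within(S)
            ms_eff = ss_eff / df_num
            ms_err = ss_err / df_den
            if ms_err <= 1e-300:
                F, p = (0.0, 1.0) if ms_eff <= 1e-300 else (np.inf, 0.0)
            else:
                F = ms_eff / ms_err
                p = float(sp_stats.f.sf(F, df_num, df_den))
            denom = ss_eff + ss_err
            eta2p = ss_eff / denom if denom > 0 else 0.0
            rows.append({
                "effect": name, "df_num": df_num, "df_den": df_den,
                "ss_effect": ss_eff, "ss_error": ss_err,
                "F": F, "p": p, "eta2p": eta2p,
                "label": effect_size_label(min(eta2p, 1.0)),
            })

    # per-cell Shapiro-Wilk on the raw values (assumption check)
    cells = df.groupby([between, *within], observed=True)[dv]
    for key, vals in cells:
        key_s = "/".join(map(str, key if isinstance(key, tuple) else (key,)))
        v = vals.to_numpy(dtype=float)
        if 3 <= len(v) <= 5000 and np.ptp(v) > 0:
            normality[key_s] = float(sp_stats.shapiro(v).pvalue)
        else:
            normality[key_s] = np.nan
    return AnovaResult(table=pd.DataFrame(rows), normality=normality, dv=dv)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def posthoc_pairwise(
    table: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str = "subject",
    paired: bool | None = None,
) -> pd.DataFrame:
    """Pairwise t-tests between the levels of ``factor`` with BH correction.

    ``paired`` defaults to True when every subject appears at more than
    one level (a within factor).  Values are averaged per subject and
    level first.
    """
    agg = table.groupby([subject, factor], observed=True)[dv].mean().reset_index()
    levels = sorted(agg[factor].unique())
    if paired is None:
        per_subj = agg.groupby(subject, observed=True)[factor].nunique()
        paired = bool((per_subj > 1).any())
    rows = []
    for a, b in combinations(levels, 2):
        xa = agg[agg[factor] == a].set_index(subject)[dv]
        xb = agg[agg[factor] == b].set_index(subject)[dv]
        if paired:
            common = xa.index.intersection(xb.index)
            va, vb = xa.loc[common].to_numpy(), xb.loc[common].to_numpy()
            if np.allclose(va, vb):
                t, p, dof = 0.0, 1.0, len(common) - 1
            else:
                res = sp_stats.ttest_rel(va, vb)
                t, p, dof = float(res.statistic), float(res.pvalue), len(common) - 1
        else:
            va, vb = xa.to_numpy(), xb.to_numpy()
            res = sp_stats.ttest_ind(va, vb)
            t, p, dof = float(res.statistic), float(res.pvalue), len(va) + len(vb) - 2
        if np.isnan(t):
            t, p = 0.0, 1.0
        rows.append({"A": a, "B": b, "paired": paired, "n": len(va), "t": t,
                     "df": dof, "p_unc": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p_unc"].to_numpy())
    else:
        out["p_adj"] = []
    return out


def spearman_partial(
    x,
    y,
    covariates=None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple[str, ...] = (),
    report_threshold: float = 0.25,
) -> CorrelationResult:
    """Spearman rank correlation, optionally partialling out covariates.

    Ranks use average ranking for ties.  With covariates, the ranks of x
    and y are residualized on the ranks of the covariates (plus an
    intercept) and the residuals are Pearson-correlated; the p-value uses
    the t approximation with n - 2 - k degrees of freedom.  The
    ``reported`` flag marks at-least-moderate associations
    (r_s^2 > 0.25).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = None
    if covariates is not None:
        cov = np.column_stack([np.asarray(c, dtype=float) for c in np.atleast_2d(covariates)]) \
            if not isinstance(covariates, (list, tuple)) else np.column_stack(
                [np.asarray(c, dtype=float) for c in covariates])
    mask = np.isfinite(x) & np.isfinite(y)
    if cov is not None:
        mask &= np.all(np.isfinite(cov), axis=1)
        cov = cov[mask]
    x, y = x[mask], y[mask]
    n = len(x)
    k = 0 if cov is None else cov.shape[1]
    if n < 4:
        raise ValueError("need at least 4 complete cases")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(x_name, y_name, tuple(covariate_names),
                                 np.nan, np.nan, np.nan, n, False, defined=False)
    rx = sp_stats.rankdata(x)
    ry = sp_stats.rankdata(y)
    if k:
        rc = np.column_stack([sp_stats.rankdata(cov[:, j]) for j in range(k)])
        X = np.column_stack([np.ones(n), rc])
        rx = rx - X @ np.linalg.lstsq(X, rx, rcond=None)[0]
        ry = ry - X @ np.linalg.lstsq(X, ry, rcond=None)[0]
    num = np.sum((rx - rx.mean()) * (ry - ry.mean()))
    den = np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
    if den == 0:
        return CorrelationResult(x_name, y_name, tuple(covariate_names),
                                 np.nan, np.nan, np.nan, n, False, defined=False)
    rho = float(np.clip(num / den, -1.0, 1.0))
    dof = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(dof / (1.0 - rho * rho))
        p = float(2.0 * sp_stats.t.sf(abs(t), dof))
    r2 = rho * rho
    return CorrelationResult(
        x_name, y_name, tuple(covariate_names), rho, r2, p, n,
        reported=bool(r2 > report_threshold),
    )


def effect_size_label(eta2p: float) -> str:
    """Conventional partial-eta-squared landmarks, lower-inclusive."""
    if not (0.0 <= eta2p <= 1.0):
        raise ValueError("eta2p must lie in [0, 1]")
    if eta2p < 0.02:
        return "negligible"
    if eta2p < 0.13:
        return "small"
    if eta2p < 0.26:
        return "medium"
    return "large"


def shapiro_check(values, alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro-Wilk p-value and a non-normality flag at ``alpha``."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if not (3 <= len(v) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant samples")
    p = float(sp_stats.shapiro(v).pvalue)
    return p, p < alpha
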