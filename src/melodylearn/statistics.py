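"""Statistical layer: group tests, normality check, rank-based longitudinal
models with Type III tests and least-squares contrasts, and two-group power.

The longitudinal model follows the rank-based strategy for repeated-measures
designs that do not meet normality: the response is replaced by mid-ranks
computed over all observations, then a mixed model with a participant random
intercept is evaluated.  Type III F tests use containment-style denominator
degrees of freedom — between-subject effects are tested in the
subject-means stratum, within-subject effects against the residual after
absorbing subject intercepts — which for a random-intercept design
reproduces the classical mixed-model ANOVA exactly and is deterministic.
An iterative REML route (statsmodels MixedLM) is available as
``engine="reml"`` for sensitivity analysis.  All tests are two-sided at
alpha = 0.05 and no multiplicity correction is applied.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ModelResult",
    "two_sample_t",
    "wilcoxon_rank_sum",
    "ks_normality",
    "rank_mixed_model",
    "block_slopes",
    "sample_size_two_groups",
    "table1_summary",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    estimate: float | None = None
    method: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class EffectTest:
    name: str
    F: float
    df_num: int
    df_den: int
    p_value: float


@dataclass(frozen=True)
class Contrast:
    label: str
    t: float
    df: int
    p_value: float
    estimate: float
    estimate_backtransformed: float | None = None


@dataclass(frozen=True)
class ModelResult:
    effects: tuple[EffectTest, ...]
    contrasts: tuple[Contrast, ...] = ()
    slopes: dict = field(default_factory=dict)
    interaction_removed: bool = False
    interaction_test: EffectTest | None = None
    engine: str = "anova"


# ---------------------------------------------------------------------------
# Simple two-group tests
# ---------------------------------------------------------------------------

def two_sample_t(x, y, pooled: bool = True) -> TestResult:
    """Independent two-sample t-test (pooled-variance Student t by default,
    df = n1 + n2 - 2), two-sided."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    if pooled and np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and x.mean() != y.mean():
        raise FloatingPointError("zero pooled variance with unequal means: t is infinite")
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        estimate=float(x.mean() - y.mean()),
        method="Student t (pooled)" if pooled else "Welch t",
    )


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Wilcoxon rank-sum test.  W is the mid-rank sum of the first sample.

    Exact two-sided p for combined n <= 20 without ties; otherwise a normal
    approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each sample needs at least one observation")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks
    W = float(ranks[: len(x)].sum())
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return TestResult(W, None, 1.0, method="Wilcoxon rank sum (degenerate)")
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        statistic=W,
        df=None,
        p_value=float(res.pvalue),
        estimate=float(np.median(x) - np.median(y)),
        method=f"Wilcoxon rank sum ({method})",
    )


def ks_normality(x) -> TestResult:
    """Kolmogorov-Smirnov normality check against a normal with estimated
    mean/SD (Lilliefors-corrected p).  Flags ``rank_based_recommended`` when
    p < 0.05."""
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(x, float)
    if len(x) < 4:
        raise ValueError("normality check needs at least four observations")
    if np.all(x == x[0]):
        raise ValueError("degenerate (constant) sample: distribution has no spread")
    d, p = lilliefors(x, dist="norm")
    flags = ("rank_based_recommended",) if p < 0.05 else ()
    return TestResult(float(d), float(len(x)), float(p), method="Lilliefors KS", flags=flags)


# ---------------------------------------------------------------------------
# Rank-based longitudinal mixed model
# ---------------------------------------------------------------------------

def _sum_code(values: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k-1 columns, last level coded -1."""
    k = len(levels)
    cols = np.zeros((len(values), k - 1))
    arr = values.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = (arr == lev).astype(float)
    cols[arr == levels[-1], :] = -1.0
    return cols


def _ols_sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and model rank via least squares."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _f_drop(X_full, y, drop_cols, df_check: str, n_strata_obs: int):
    """Type III F for a term: compare full model with the term's columns dropped."""
    sse_f, rank_f = _ols_sse(X_full, y)
    keep = [c for c in range(X_full.shape[1]) if c not in drop_cols]
    sse_r, rank_r = _ols_sse(X_full[:, keep], y)
    df_num = int(rank_f - rank_r)
    df_den = int(n_strata_obs - rank_f)
    if df_num < 1 or df_den < 1:
        raise ValueError(f"rank-deficient design for term {df_check!r} (empty cell?)")
    F = ((sse_r - sse_f) / df_num) / (sse_f / df_den)
    p = float(sps.f.sf(F, df_num, df_den))
    return EffectTest(df_check, float(F), df_num, df_den, p)


def _backtransform(mean_rank: float, ranks: np.ndarray, values: np.ndarray) -> float:
    """Map a rank-scale LS-mean back to the response scale by interpolating
    the empirical rank -> value relation."""
    order = np.argsort(ranks)
    return float(np.interp(mean_rank, ranks[order], values[order]))


def rank_mixed_model(
    data: pd.DataFrame,
    response: str,
    subject: str,
    between: str,
    within: str | None = None,
    covariate: str | None = None,
    interaction: bool = True,
    reduce_if_ns: bool = True,
    alpha: float = 0.05,
    engine: str = "anova",
    rank_transform: bool = True,
) -> ModelResult:
    """Rank-based mixed model with Type III tests and LS-mean contrasts.

    Fixed effects: ``between`` (group), ``within`` (session or block),
    optionally their interaction and a between-subject ``covariate``; random
    intercept of ``subject``.  The response is replaced by mid-ranks over all
    observations (disable with ``rank_transform=False`` for a parametric
    fit of the same design).  If the interaction is not significant at
    ``alpha`` the model is refitted with main effects only, mirroring the
    model-reduction workflow.  Pairwise within-level contrasts are reported
    on the rank scale with back-transformed estimates alongside.
    """
    df = data.copy()
    for col in filter(None, [response, subject, between, within, covariate]):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not in data")
    y_raw = df[response].to_numpy(float)
    y = sps.rankdata(y_raw) if rank_transform else y_raw.copy()
    df["_y"] = y

    groups_lv = sorted(df[between].unique().tolist())
    if len(groups_lv) < 2:
        raise ValueError(f"between factor {between!r} needs >= 2 levels")
    subjects = df[subject].unique().tolist()
    n_subj = len(subjects)

    if within is not None:
        within_lv = list(pd.unique(df[within]))
        if len(within_lv) < 2:
            raise ValueError(f"within factor {within!r} needs >= 2 levels")
        cell_counts = df.groupby([between, within], observed=True).size()
        for g, w in itertools.product(groups_lv, within_lv):
            if (g, w) not in cell_counts.index:
                raise ValueError(f"empty design cell: ({between}={g}, {within}={w})")
    else:
        within_lv = []

    if engine == "reml":
        return _reml_model(
            df, subject, between, within, covariate, interaction, reduce_if_ns, alpha,
            groups_lv, within_lv, y_raw,
        )
    if engine != "anova":
        raise ValueError(f"unknown engine {engine!r}")

    # ---- between-subject stratum: subject means of the (ranked) response
    agg = {"_y": "mean", between: "first"}
    if covariate:
        agg[covariate] = "first"
    subj_df = df.groupby(subject).agg(agg)
    yb = subj_df["_y"].to_numpy()
    Xb_cols: list[np.ndarray] = [np.ones((n_subj, 1))]
    gb = _sum_code(subj_df[between], groups_lv)
    Xb_cols.append(gb)
    terms_b = {between: list(range(1, 1 + gb.shape[1]))}
    if covariate:
        cov = subj_df[covariate].to_numpy(float)
        col0 = sum(c.shape[1] for c in Xb_cols)
        Xb_cols.append((cov - cov.mean()).reshape(-1, 1))
        terms_b[covariate] = [col0]
    Xb = np.hstack(Xb_cols)

    effects: list[EffectTest] = []
    interaction_test: EffectTest | None = None
    interaction_removed = False

    for name, cols in terms_b.items():
        effects.append(_f_drop(Xb, yb, cols, name, n_subj))

    contrasts: list[Contrast] = []
    if within is not None:
        # ---- within-subject stratum: subject intercepts absorbed
        n = len(df)
        subj_dummies = pd.get_dummies(df[subject]).to_numpy(float)
        wcols = _sum_code(df[within], within_lv)
        gcols_full = _sum_code(df[between], groups_lv)
        inter_cols = np.hstack(
            [gcols_full[:, [i]] * wcols for i in range(gcols_full.shape[1])]
        )

        def build(with_inter: bool):
            blocks = [subj_dummies, wcols] + ([inter_cols] if with_inter else [])
            X = np.hstack(blocks)
            idx_w = list(range(subj_dummies.shape[1], subj_dummies.shape[1] + wcols.shape[1]))
            idx_i = (
                list(range(X.shape[1] - inter_cols.shape[1], X.shape[1]))
                if with_inter
                else []
            )
            return X, idx_w, idx_i

        if interaction:
            Xw, idx_w, idx_i = build(True)
            interaction_test = _f_drop(Xw, y, idx_i, f"{between}:{within}", n)
            if reduce_if_ns and interaction_test.p_value > alpha:
                interaction_removed = True
                Xw, idx_w, idx_i = build(False)
            else:
                effects.append(interaction_test)
        else:
            Xw, idx_w, idx_i = build(False)
        effects.insert(1, _f_drop(Xw, y, idx_w, within, n))

        # ---- LS-mean pairwise contrasts of within levels on the rank scale
        beta, _, rank_x, _ = np.linalg.lstsq(Xw, y, rcond=None)
        resid = y - Xw @ beta
        df_den = int(len(df) - rank_x)
        sigma2 = float(resid @ resid) / df_den
        xtx_inv = np.linalg.pinv(Xw.T @ Xw)
        k = len(within_lv)

        def level_vec(i: int) -> np.ndarray:
            v = np.zeros(Xw.shape[1])
            if i < k - 1:
                v[idx_w[i]] = 1.0
            else:
                v[idx_w] = -1.0
            return v

        for i, j in itertools.combinations(range(k), 2):
            c = level_vec(i) - level_vec(j)
            est = float(c @ beta)
            se = math.sqrt(sigma2 * float(c @ xtx_inv @ c))
            tstat = est / se
            p = float(2 * sps.t.sf(abs(tstat), df_den))
            # back-transform the two LS-means separately, then difference
            grand = float(np.mean(y))
            bt = _backtransform(grand + float(level_vec(i) @ beta), y, y_raw) - _backtransform(
                grand + float(level_vec(j) @ beta), y, y_raw
            )
            contrasts.append(
                Contrast(
                    label=f"{within_lv[i]} - {within_lv[j]}",
                    t=float(tstat),
                    df=df_den,
                    p_value=p,
                    estimate=est,
                    estimate_backtransformed=bt,
                )
            )

    return ModelResult(
        effects=tuple(effects),
        contrasts=tuple(contrasts),
        interaction_removed=interaction_removed,
        interaction_test=interaction_test,
        engine="anova",
    )


def _reml_model(
    df, subject, between, within, covariate, interaction, reduce_if_ns, alpha,
    groups_lv, within_lv, y_raw,
):
    """REML route: statsmodels MixedLM on the ranked response, Wald Type III
    F tests with the same containment denominator df as the ANOVA route."""
    import statsmodels.api as sm

    n = len(df)
    n_subj = df[subject].nunique()

    def fit(with_inter: bool):
        blocks = [np.ones((n, 1))]
        terms: dict[str, list[int]] = {}
        g = _sum_code(df[between], groups_lv)
        terms[between] = list(range(1, 1 + g.shape[1]))
        blocks.append(g)
        pos = 1 + g.shape[1]
        if within is not None:
            w = _sum_code(df[within], within_lv)
            terms[within] = list(range(pos, pos + w.shape[1]))
            blocks.append(w)
            pos += w.shape[1]
            if with_inter:
                ic = np.hstack([g[:, [i]] * w for i in range(g.shape[1])])
                terms[f"{between}:{within}"] = list(range(pos, pos + ic.shape[1]))
                blocks.append(ic)
                pos += ic.shape[1]
        if covariate:
            cov = df[covariate].to_numpy(float)
            terms[covariate] = [pos]
            blocks.append((cov - cov.mean()).reshape(-1, 1))
            pos += 1
        X = np.hstack(blocks)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(df["_y"].to_numpy(), X, groups=df[subject]).fit(reml=True)
        return res, terms, X

    def containment_den(name: str, terms) -> int:
        between_terms = {between, covariate} - {None}
        n_within_p = sum(len(c) for t, c in terms.items() if t not in between_terms and t != "Intercept")
        n_between_p = sum(len(c) for t, c in terms.items() if t in between_terms)
        if name in between_terms:
            return n_subj - 1 - n_between_p
        return n - n_subj - n_within_p

    res, terms, X = fit(interaction and within is not None)
    interaction_test = None
    interaction_removed = False
    inter_name = f"{between}:{within}" if within is not None else None
    effects = []

    def wald(name, res, terms):
        cols = terms[name]
        beta = res.fe_params[cols]
        V = np.asarray(res.cov_params())[np.ix_(cols, cols)]
        q = len(cols)
        F = float(beta @ np.linalg.solve(V, beta)) / q
        dden = containment_den(name, terms)
        return EffectTest(name, F, q, dden, float(sps.f.sf(F, q, dden)))

    if inter_name and inter_name in terms:
        interaction_test = wald(inter_name, res, terms)
        if reduce_if_ns and interaction_test.p_value > alpha:
            interaction_removed = True
            res, terms, X = fit(False)
        else:
            effects.append(interaction_test)
    for name in terms:
        if name != inter_name or not interaction_removed:
            if name == inter_name:
                continue  # already appended
            effects.append(wald(name, res, terms))
    return ModelResult(
        effects=tuple(effects),
        interaction_removed=interaction_removed,
        interaction_test=interaction_test,
        engine="reml",
    )


def block_slopes(
    data: pd.DataFrame,
    response: str,
    subject: str,
    group: str,
    block: str,
) -> dict:
    """Per-group linear trend of the raw response over numeric block,
    in percentage points per block, with subject intercepts absorbed
    (the least-squares trend within the mixed-model framework)."""
    out: dict[str, float] = {}
    blocks = pd.to_numeric(data[block])
    if blocks.nunique() < 3:
        raise ValueError("trend estimation needs at least three blocks")
    for g, sub in data.groupby(group, observed=True):
        y = sub[response].to_numpy(float)
        b = pd.to_numeric(sub[block]).to_numpy(float)
        dummies = pd.get_dummies(sub[subject]).to_numpy(float)
        X = np.hstack([dummies, b.reshape(-1, 1)])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        out[str(g)] = float(beta[-1])
    levels = sorted(out)
    if len(levels) == 2:
        out["difference"] = out[levels[0]] - out[levels[1]]
    return out


def sample_size_two_groups(
    mean_diff: float,
    sd: float,
    power: float = 0.80,
    alpha: float = 0.05,
    n_max: int = 10_000_000,
) -> int:
    """Smallest n per group giving the requested power for a two-sided
    pooled two-sample t-test, via the noncentral t distribution."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if mean_diff == 0:
        raise OverflowError("zero effect size: required n is infinite")
    d = abs(mean_diff) / sd

    def attained(n: int) -> float:
        dfree = 2 * n - 2
        ncp = d * math.sqrt(n / 2)
        crit = sps.t.ppf(1 - alpha / 2, dfree)
        return float(sps.nct.sf(crit, dfree, ncp) + sps.nct.cdf(-crit, dfree, ncp))

    lo, hi = 2, 4
    while attained(hi) < power:
        hi *= 2
        if hi > n_max:
            raise OverflowError("required n exceeds n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if attained(mid) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def table1_summary(records: pd.DataFrame, field_name: str, group: str) -> tuple[float, float]:
    """Group mean and sample SD of one numeric participant-table column."""
    if field_name not in records.columns:
        raise ValueError(f"unknown field {field_name!r}")
    sub = records.loc[records["group"] == group, field_name].astype(float)
    if len(sub) == 0:
        raise ValueError(f"no rows for group {group!r}")
    mean = float(sub.mean())
    sd = float(sub.std(ddof=1)) if len(sub) > 1 else float("nan")
    if len(sub) == 1:
        warnings.warn("single-row group: SD undefined", stacklevel=2)
    return mean, sd
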