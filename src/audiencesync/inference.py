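"""Affect statistics and hierarchical regressions on synchrony contributions.

The individual-level synchrony contributions (effect sizes) produced by the
audience stage become dependent variables in linear mixed models with a
random intercept per concert, since concerts differ in venue, program order
and staging.  Predictors are survey covariates; by default they are centered
within concert so the fixed effects capture within-concert variation, except
personality traits, which have no plausible between-concert variance and
enter uncentered.

Model fitting is delegated to :mod:`statsmodels` (``MixedLM``, REML).
Reported p-values for fixed effects use the large-sample normal
approximation; the explained variance of the whole model is the squared
correlation between fitted (fixed + predicted random effects) and observed
values, and the random-intercept share is its variance over the total.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "FixedEffect",
    "MixedModelResult",
    "PrePostResult",
    "PieceContrastResult",
    "affect_change_effect_size",
    "prepost_ttest",
    "affect_change_table",
    "center_within_group",
    "fit_random_intercept_model",
    "fit_two_pass",
    "piece_contrast_analysis",
]


class InferenceError(ValueError):
    """Raised for degenerate or misspecified inference inputs."""


# ---------------------------------------------------------------------------
# pre/post affect
# ---------------------------------------------------------------------------

@dataclass
class PrePostResult:
    """Paired pre/post comparison for one scale (optionally one concert)."""

    scale: str
    concert_id: str
    mean_pre: float
    mean_post: float
    t_statistic: float
    p_value: float
    effect_size: float
    n: int
    degenerate: bool = False


def affect_change_effect_size(pre, post):
    """Group-level change effect size (mean pre - mean post) / SD(pre).

    Positive values indicate a decline from pre to post.  Also returns the
    per-participant change scores ``(pre_i - post_i) / SD(pre)`` used as
    predictors downstream.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    ok = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[ok], post[ok]
    if len(pre) < 2:
        raise InferenceError("need >= 2 complete pre/post pairs")
    sd_pre = np.std(pre, ddof=1)
    if sd_pre == 0:
        raise InferenceError("SD of pre scores is zero; effect size undefined")
    es = (pre.mean() - post.mean()) / sd_pre
    change_scores = (pre - post) / sd_pre
    return float(es), change_scores


def prepost_ttest(pre, post, scale: str = "", concert_id: str = "") -> PrePostResult:
    """Two-sided paired t-test of pre vs post scores."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    ok = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[ok], post[ok]
    if len(pre) < 3:
        raise InferenceError("paired t-test needs >= 3 complete pairs")
    diffs = pre - post
    degenerate = False
    if np.std(diffs, ddof=1) == 0:
        degenerate = True
        if np.allclose(diffs, 0):
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn("zero variance of differences with nonzero shift")
            t_stat, p = np.inf * np.sign(diffs.mean()), 0.0
    else:
        t_stat, p = stats.ttest_rel(pre, post)
    sd_pre = np.std(pre, ddof=1)
    es = (pre.mean() - post.mean()) / sd_pre if sd_pre > 0 else np.nan
    return PrePostResult(
        scale=scale, concert_id=concert_id,
        mean_pre=float(pre.mean()), mean_post=float(post.mean()),
        t_statistic=float(t_stat), p_value=float(p),
        effect_size=float(es), n=len(pre), degenerate=degenerate,
    )


def affect_change_table(
    survey: pd.DataFrame, scales: Sequence[str] = ("PA", "NA", "VA")
) -> pd.DataFrame:
    """Pre/post means and paired tests per concert plus a pooled row."""
    rows = []
    for scale in scales:
        pre_col, post_col = f"{scale}_pre", f"{scale}_post"
        for concert_id, g in survey.groupby("concert_id"):
            res = prepost_ttest(g[pre_col], g[post_col], scale, str(concert_id))
            rows.append(res)
        rows.append(prepost_ttest(survey[pre_col], survey[post_col], scale, "All"))
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def center_within_group(values, group_labels) -> np.ndarray:
    """Subtract each group's mean, isolating within-group variation."""
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(group_labels))
    if len(s) != len(g):
        raise InferenceError("values and group labels differ in length")
    counts = s.groupby(g.values).count()
    if (counts == 0).any() or len(s) == 0:
        raise InferenceError("every group needs at least one non-missing value")
    return (s - s.groupby(g.values).transform("mean")).to_numpy()


@dataclass
class FixedEffect:
    name: str
    estimate: float
    t: float
    p: float


@dataclass
class MixedModelResult:
    """Random-intercept model summary for one synchrony outcome."""

    outcome: str
    fixed_effects: list
    random_intercept_variance_pct: float
    n_observations: int
    r2_pct: float
    converged: bool = True
    centered: bool = True

    def effect(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(fe) for fe in self.fixed_effects])
        df.insert(0, "outcome", self.outcome)
        df["random_intercept_variance_pct"] = self.random_intercept_variance_pct
        df["n"] = self.n_observations
        df["r2_pct"] = self.r2_pct
        return df


def _check_collinearity(X: pd.DataFrame) -> None:
    """Raise, naming offending columns, if the design is rank-deficient."""
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank >= arr.shape[1]:
        return
    bad = [c for c in X.columns if c != "const" and X[c].std() == 0]
    if not bad:
        # greedy: a column is offending if dropping it restores full rank
        for c in X.columns:
            if c == "const":
                continue
            sub = X.drop(columns=[c]).to_numpy()
            if np.linalg.matrix_rank(sub) == sub.shape[1]:
                bad.append(c)
    raise InferenceError(f"collinear or constant predictors: {bad}")


def fit_random_intercept_model(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    group: str,
    center: bool = True,
) -> MixedModelResult:
    """Linear mixed model: outcome ~ predictors + (1 | group), REML.

    ``center=True`` centers every predictor within group first (used for
    affect, experience and piece predictors; personality traits stay
    uncentered).  With a single group level the model reduces to ordinary
    least squares with a zero-variance random intercept.
    """
    cols = [outcome, *predictors, group]
    d = data[cols].dropna().copy()
    if len(d) <= len(predictors) + 1:
        raise InferenceError("too few observations for the requested model")
    if center:
        for p_name in predictors:
            d[p_name] = center_within_group(d[p_name].to_numpy(), d[group].to_numpy())
    X = sm.add_constant(d[list(predictors)], has_constant="add")
    _check_collinearity(X)
    y = d[outcome].to_numpy()
    n_levels = d[group].nunique()

    if n_levels < 2:
        ols = sm.OLS(y, X).fit()
        fitted, params = ols.fittedvalues, ols.params
        tvals, pvals = ols.tvalues, ols.pvalues
        var_pct, converged = 0.0, True
    else:
        model = sm.MixedLM(y, X, groups=d[group].to_numpy())
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            warnings.simplefilter("ignore", category=UserWarning)
            try:
                res = model.fit(reml=True)
            except (np.linalg.LinAlgError, ValueError):
                res = None
        if res is None or not np.all(np.isfinite(res.fe_params)):
            warnings.warn("singular mixed-model fit; falling back to OLS "
                          "with a zero-variance random intercept")
            ols = sm.OLS(y, X).fit()
            fitted, params = ols.fittedvalues, ols.params
            tvals, pvals = ols.tvalues, ols.pvalues
            var_pct, converged = 0.0, False
        else:
            params = res.fe_params
            tvals = res.tvalues[: len(params)]
            pvals = res.pvalues[: len(params)]
            fitted = np.asarray(res.fittedvalues)
            var_re = float(np.squeeze(res.cov_re.to_numpy())) if hasattr(res.cov_re, "to_numpy") else float(np.squeeze(res.cov_re))
            var_pct = 100.0 * var_re / (var_re + res.scale) if (var_re + res.scale) > 0 else 0.0

    if np.std(fitted) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) * 100.0
    else:
        r2 = 0.0
    params, tvals, pvals = (np.asarray(v, dtype=float) for v in (params, tvals, pvals))
    effects = [
        FixedEffect(
            name=("Intercept" if name == "const" else str(name)),
            estimate=float(params[i]),
            t=float(tvals[i]),
            p=float(pvals[i]),
        )
        for i, name in enumerate(X.columns)
    ]
    return MixedModelResult(
        outcome=outcome,
        fixed_effects=effects,
        random_intercept_variance_pct=float(var_pct),
        n_observations=len(d),
        r2_pct=r2,
        converged=converged,
        centered=center,
    )


def fit_two_pass(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    group: str,
    center: bool = True,
    alpha: float = 0.05,
) -> MixedModelResult:
    """Two-pass selection: fit all predictors, refit keeping the significant.

    Mirrors the practice of reducing a large correlated predictor block to
    its significant members to limit multicollinearity.  If no predictor
    survives the first pass the full model is returned.
    """
    first = fit_random_intercept_model(data, outcome, predictors, group, center)
    keep = [fe.name for fe in first.fixed_effects if fe.name != "Intercept" and fe.p < alpha]
    if not keep or set(keep) == set(predictors):
        return first
    return fit_random_intercept_model(data, outcome, keep, group, center)


# ---------------------------------------------------------------------------
# piece contrasts
# ---------------------------------------------------------------------------

@dataclass
class PieceContrastResult:
    """Piece-level mixed model with Holm-corrected pairwise contrasts."""

    outcome: str
    piece_means: dict
    contrasts: pd.DataFrame
    rank_string: str
    random_intercept_variance_pct: float
    n_observations: int


def piece_contrast_analysis(
    data: pd.DataFrame,
    value: str,
    piece: str,
    group: str,
    alpha: float = 0.05,
) -> PieceContrastResult:
    """Categorical piece effect with all pairwise Holm-corrected contrasts.

    Fits ``value ~ C(piece) + (1 | group)`` and tests every piece pair.  The
    rank string orders pieces by marginal mean and joins adjacent pieces with
    '>' when their contrast is significant after Holm correction, '=' when
    not; it is empty when no contrast is significant.
    """
    d = data[[value, piece, group]].dropna().copy()
    pieces = sorted(d[piece].unique())
    if len(pieces) < 2:
        raise InferenceError("piece contrasts need >= 2 pieces")
    dummies = pd.get_dummies(d[piece], prefix="piece", dtype=float)
    X = sm.add_constant(dummies.iloc[:, 1:], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        res = sm.MixedLM(d[value].to_numpy(), X, groups=d[group].to_numpy()).fit(reml=True)
    fe = np.asarray(res.fe_params, dtype=float)
    coef = {pieces[0]: 0.0}
    for k, p_label in enumerate(pieces[1:], start=1):
        coef[p_label] = float(fe[k])
    intercept = float(fe[0])
    piece_means = {p_label: intercept + coef[p_label] for p_label in pieces}

    rows = []
    k_fe = len(res.fe_params)
    for a, b in itertools.combinations(pieces, 2):
        L = np.zeros((1, k_fe))
        for p_label, sign in ((a, 1.0), (b, -1.0)):
            if p_label != pieces[0]:
                L[0, 1 + pieces[1:].index(p_label)] = sign
        tt = res.t_test(L)
        rows.append({
            "piece_a": a, "piece_b": b,
            "estimate": float(np.squeeze(tt.effect)),
            "t": float(np.squeeze(tt.tvalue)),
            "p_raw": float(np.squeeze(tt.pvalue)),
        })
    contrasts = pd.DataFrame(rows)
    contrasts["p_holm"] = multipletests(contrasts["p_raw"], method="holm")[1]

    ordered = sorted(pieces, key=lambda p_label: piece_means[p_label], reverse=True)
    sig = {
        frozenset((r.piece_a, r.piece_b)): r.p_holm < alpha
        for r in contrasts.itertuples()
    }
    if any(sig.values()):
        parts = [ordered[0]]
        for prev, nxt in zip(ordered, ordered[1:]):
            parts.append(">" if sig[frozenset((prev, nxt))] else "=")
            parts.append(nxt)
        rank_string = " ".join(parts)
    else:
        rank_string = ""
    var_re = float(np.squeeze(np.asarray(res.cov_re)))
    var_pct = 100.0 * var_re / (var_re + res.scale) if (var_re + res.scale) > 0 else 0.0
    return PieceContrastResult(
        outcome=value,
        piece_means=piece_means,
        contrasts=contrasts,
        rank_string=rank_string,
        random_intercept_variance_pct=float(var_pct),
        n_observations=len(d),
    )
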