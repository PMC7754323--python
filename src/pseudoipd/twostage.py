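"""Two-stage pseudo-IPD analysis and standard aggregate-data comparators.

Stage one fits an ordinary ANCOVA separately in each study,

    y_Fij = b0_i + b1_i x_ij + b2_i y_Bij (+ b3_i (y_Bij - ybar_Bi) x_ij) + e_ij,

yielding per-study treatment (and interaction) effects with model-based
standard errors; stage two pools them with a fixed-effect or random-effects
meta-analysis.  The high-level wrappers default to REML pooling with t(k-1)
intervals, mirroring the likelihood-based mixed-model pooling of the
one-stage approach; DerSimonian-Laird is available everywhere as the
classical method-of-moments alternative.

The module also provides the classical aggregate-data comparators that need
no IPD at all: the change-score meta-analysis, final-value and baseline
mean-difference meta-analyses, and random-effects meta-regression of study
effects on a study-level covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .aggregate import MetaAggregate
from .generate import PseudoIPD

__all__ = [
    "StudyEffect",
    "PooledResult",
    "fit_study_ancova",
    "pool",
    "TwoStageAncova",
    "change_score_ma",
    "final_values_ma",
    "baseline_ma",
    "meta_regression",
]

EffectKind = Literal["treatment", "interaction", "change_diff", "final_diff", "baseline_diff"]


@dataclass(frozen=True)
class StudyEffect:
    study_id: str
    estimate: float
    se: float
    df: int
    kind: EffectKind

    def __post_init__(self):
        if not np.isfinite(self.estimate):
            raise ValueError(f"study {self.study_id!r}: non-finite estimate")
        if not self.se > 0:
            raise ValueError(f"study {self.study_id!r}: se must be > 0")


@dataclass(frozen=True)
class PooledResult:
    estimate: float
    se: float
    ci: tuple[float, float]
    tau_sq: float
    method: str
    k: int
    q_stat: float | None = None

    def summary(self) -> str:
        return (
            f"pooled estimate {self.estimate:.4f} (SE {self.se:.4f}), "
            f"95%-type CI ({self.ci[0]:.4f}, {self.ci[1]:.4f}), "
            f"tau^2 = {self.tau_sq:.4f}, k = {self.k}, method = {self.method}"
        )


def fit_study_ancova(
    ipd_one_study: pd.DataFrame, interaction: bool = False
) -> list[StudyEffect]:
    """OLS ANCOVA of one study; returns the treatment effect (and, when
    requested, the within-study interaction on the study-mean-centred
    baseline, so coefficients are comparable with the one-stage models)."""
    df = ipd_one_study
    sids = df["study"].unique()
    if len(sids) != 1:
        raise ValueError("fit_study_ancova expects a single study's records")
    sid = str(sids[0])
    if df["treat"].nunique() != 2:
        raise ValueError(f"study {sid!r}: needs both a treated and a control arm")
    need = 5 if interaction else 4
    if len(df) < need:
        raise ValueError(f"study {sid!r}: too few subjects for ANCOVA")
    bc = df["y_base"] - df["y_base"].mean()
    cols = {"treat": df["treat"].to_numpy(float), "y_base": df["y_base"].to_numpy(float)}
    if interaction:
        cols["treat:baseline_c"] = (bc * df["treat"]).to_numpy(float)
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"study {sid!r}: rank-deficient ANCOVA design")
    res = sm.OLS(df["y_final"].to_numpy(float), X).fit()
    out = [
        StudyEffect(sid, float(res.params["treat"]), float(res.bse["treat"]),
                    int(res.df_resid), "treatment")
    ]
    if interaction:
        out.append(
            StudyEffect(sid, float(res.params["treat:baseline_c"]),
                        float(res.bse["treat:baseline_c"]), int(res.df_resid), "interaction")
        )
    return out


def pool(
    effects: Sequence[StudyEffect],
    method: Literal["DL", "REML_meta", "fixed"] = "DL",
    ci: Literal["normal", "t"] = "normal",
    level: float = 0.95,
) -> PooledResult:
    """Pool per-study effects.

    DL: method-of-moments tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    with fixed-effect weights w = 1/se^2, then inverse-variance pooling with
    w* = 1/(se^2 + tau^2).  REML_meta iterates the restricted likelihood on
    the (estimate, se) pairs.  k = 1 degenerates to the single effect.
    """
    k = len(effects)
    if k == 0:
        raise ValueError("no effects to pool")
    y = np.array([e.estimate for e in effects])
    v = np.array([e.se**2 for e in effects])
    if k == 1:
        e = effects[0]
        z = stats.norm.ppf(0.5 + level / 2)
        return PooledResult(e.estimate, e.se, (e.estimate - z * e.se, e.estimate + z * e.se),
                            0.0, "fixed", 1)
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    if method == "fixed":
        tau_sq = 0.0
    elif method == "DL":
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau_sq = max(0.0, (Q - (k - 1)) / denom)
    elif method == "REML_meta":
        tau_sq = _reml_tau_sq(y, v)
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    ws = 1.0 / (v + tau_sq)
    est = float(np.sum(ws * y) / np.sum(ws))
    se = float(np.sqrt(1.0 / np.sum(ws)))
    crit = (stats.t.ppf(0.5 + level / 2, k - 1) if ci == "t"
            else stats.norm.ppf(0.5 + level / 2))
    return PooledResult(est, se, (est - crit * se, est + crit * se),
                        float(tau_sq), method, k, q_stat=Q)


def _reml_tau_sq(y: np.ndarray, v: np.ndarray, tol: float = 1e-10, maxiter: int = 200) -> float:
    """Iterative REML estimate of the between-study variance."""
    tau = max(np.var(y, ddof=1) - np.mean(v), 0.0)
    for _ in range(maxiter):
        w = 1.0 / (v + tau)
        mu = np.sum(w * y) / np.sum(w)
        num = np.sum(w**2 * ((y - mu) ** 2 - v)) + np.sum(w**2) / np.sum(w)
        new = max(float(num / np.sum(w**2)), 0.0)
        if abs(new - tau) < tol * (1.0 + tau):
            tau = new
            break
        tau = new
    return float(tau)


class TwoStageAncova:
    """Two-stage pseudo-IPD meta-analysis model.

    Parameters
    ----------
    ipd : PseudoIPD or DataFrame
        Subject-level records (pseudo or true).
    interaction : bool
        Also estimate the per-study treatment-by-baseline interaction.
    """

    def __init__(self, ipd: PseudoIPD | pd.DataFrame, interaction: bool = False):
        df = ipd.data if isinstance(ipd, PseudoIPD) else ipd
        if "treat" not in df.columns:
            df = df.assign(treat=(df["arm"] == "treated").astype(int))
        self.data = df
        self.interaction = interaction

    def study_effects(self) -> list[StudyEffect]:
        out: list[StudyEffect] = []
        for sid in self.data["study"].unique():
            out.extend(
                fit_study_ancova(self.data[self.data["study"] == sid], self.interaction)
            )
        return out

    def fit(self, method: Literal["DL", "REML_meta", "fixed"] = "REML_meta",
            ci: Literal["normal", "t"] = "t") -> "TwoStageResults":
        effects = self.study_effects()
        treatment = pool([e for e in effects if e.kind == "treatment"], method, ci)
        inter = None
        if self.interaction:
            inter = pool([e for e in effects if e.kind == "interaction"], method, ci)
        return TwoStageResults(effects, treatment, inter)


@dataclass(frozen=True)
class TwoStageResults:
    study_effects: list[StudyEffect]
    treatment: PooledResult
    interaction: PooledResult | None = None

    def summary(self) -> str:
        lines = ["Two-stage ANCOVA meta-analysis", "  treatment: " + self.treatment.summary()]
        if self.interaction is not None:
            lines.append("  interaction: " + self.interaction.summary())
        return "\n".join(lines)


def forest_data(effects: Sequence[StudyEffect], pooled: PooledResult,
                level: float = 0.95) -> pd.DataFrame:
    """Forest-plot table: per-study rows with normal CIs and random-effects
    weights (percent), plus the pooled row.  Plotting is left to the user."""
    z = stats.norm.ppf(0.5 + level / 2)
    w = np.array([1.0 / (e.se**2 + pooled.tau_sq) for e in effects])
    w = 100.0 * w / w.sum()
    rows = [
        {"study": e.study_id, "estimate": e.estimate,
         "ci_low": e.estimate - z * e.se, "ci_high": e.estimate + z * e.se,
         "weight_pct": wi}
        for e, wi in zip(effects, w)
    ]
    rows.append({"study": f"pooled ({pooled.method})", "estimate": pooled.estimate,
                 "ci_low": pooled.ci[0], "ci_high": pooled.ci[1],
                 "weight_pct": 100.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregate-data comparators


def _ad_effects(data: MetaAggregate, kind: EffectKind) -> list[StudyEffect]:
    data = data.completed() if kind == "change_diff" else data
    out = []
    for sid, t, c in data.studies:
        if kind == "change_diff":
            est = t.mean_change - c.mean_change
            var = t.sd_change**2 / t.n + c.sd_change**2 / c.n
        elif kind == "final_diff":
            est = t.mean_final - c.mean_final
            var = t.sd_final**2 / t.n + c.sd_final**2 / c.n
        elif kind == "baseline_diff":
            est = t.mean_baseline - c.mean_baseline
            var = t.sd_baseline**2 / t.n + c.sd_baseline**2 / c.n
        else:
            raise ValueError(kind)
        out.append(StudyEffect(sid, float(est), float(np.sqrt(var)), t.n + c.n - 2, kind))
    return out


def change_score_ma(data: MetaAggregate, method="REML_meta", ci="t") -> PooledResult:
    """Meta-analysis of the between-group difference in mean change scores.

    Per-arm change-score SDs are derived from the reported SDs and
    correlation when not given directly; the result is exactly invariant
    under treated-arm baseline shifts (the shift cancels in the change).
    """
    effects = _ad_effects(data, "change_diff")
    return pool(effects, method, ci) if len(effects) > 1 else pool(effects, "fixed")


def final_values_ma(data: MetaAggregate, method="REML_meta", ci="t") -> PooledResult:
    """Meta-analysis of the difference in mean final values (ignores baseline)."""
    effects = _ad_effects(data, "final_diff")
    return pool(effects, method, ci) if len(effects) > 1 else pool(effects, "fixed")


def baseline_ma(data: MetaAggregate, method="REML_meta", ci="t") -> PooledResult:
    """Meta-analysis of the baseline mean difference (imbalance diagnostic)."""
    effects = _ad_effects(data, "baseline_diff")
    return pool(effects, method, ci) if len(effects) > 1 else pool(effects, "fixed")


@dataclass(frozen=True)
class MetaRegressionResult:
    slope: float
    se: float
    ci: tuple[float, float]
    intercept: float
    tau_sq: float
    k: int


def meta_regression(
    effects: Sequence[StudyEffect],
    covariate: Sequence[float],
    method: Literal["MoM", "REML_meta"] = "MoM",
    level: float = 0.95,
) -> MetaRegressionResult:
    """Random-effects meta-regression of study effects on a study covariate.

    Weighted least squares with an additive between-study variance estimated
    by method-of-moments (DL-type, default) or REML.  The slope is the
    across-trial analogue of the within-trial interaction and is vulnerable
    to ecological bias; see the one-stage interaction model for the
    protected estimand.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("meta-regression needs at least 3 studies")
    x = np.asarray(covariate, float)
    if len(x) != k:
        raise ValueError("covariate length must match the number of effects")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    y = np.array([e.estimate for e in effects])
    v = np.array([e.se**2 for e in effects])
    X = np.column_stack([np.ones(k), x])

    def wls(tau_sq):
        w = 1.0 / (v + tau_sq)
        XtW = X.T * w
        cov = np.linalg.inv(XtW @ X)
        beta = cov @ (XtW @ y)
        resid = y - X @ beta
        return beta, cov, resid, w

    beta, cov, resid, w = wls(0.0)
    Q = float(np.sum(w * resid**2))
    if method == "MoM":
        # DL-type moment estimator with fixed-effect residual Q
        W = np.diag(w)
        P = W - W @ X @ np.linalg.inv(X.T @ W @ X) @ X.T @ W
        tau_sq = max(0.0, (Q - (k - 2)) / float(np.trace(P)))
    elif method == "REML_meta":
        tau_sq = _metareg_reml_tau(y, v, X)
    else:
        raise ValueError(f"unknown method {method!r}")
    beta, cov, resid, w = wls(tau_sq)
    se = float(np.sqrt(cov[1, 1]))
    z = stats.norm.ppf(0.5 + level / 2)
    return MetaRegressionResult(
        slope=float(beta[1]), se=se, ci=(beta[1] - z * se, beta[1] + z * se),
        intercept=float(beta[0]), tau_sq=float(tau_sq), k=k,
    )


def _metareg_reml_tau(y, v, X, tol=1e-10, maxiter=200):
    k, p = X.shape
    tau = max(np.var(y, ddof=1) - np.mean(v), 0.0)
    for _ in range(maxiter):
        w = 1.0 / (v + tau)
        XtW = X.T * w
        cov = np.linalg.inv(XtW @ X)
        beta = cov @ (XtW @ y)
        resid = y - X @ beta
        h = np.einsum("ij,jk,ik->i", X, cov, X) * w  # leverage under current weights
        num = np.sum(w**2 * (resid**2 - v)) + np.sum(w * h)
        new = max(float(num / np.sum(w**2)), 0.0)
        if abs(new - tau) < tol * (1.0 + tau):
            tau = new
            break
        tau = new
    return float(tau)
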