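"""One-stage ANCOVA linear mixed models for baseline/follow-up IPD.

The follow-up outcome ``y_final`` of subject j in study i is regressed on
treatment and the study-mean-centred baseline::

    stratified study:  y_Fij = b0_i + (b1 + u1_i) x_ij + b2_i (y_Bij - ybar_Bi) + e_ij
    random study:      y_Fij = (b0 + u0_i) + (b1 + u1_i) x_ij
                               + (b2 + u2_i)(y_Bij - ybar_Bi) + e_ij

optionally extended with a treatment-by-baseline interaction split into a
within-trial term (b3 + u3_i)(y_Bij - ybar_Bi) x_ij and an across-trial term
b4 * ybar_Bi * x_ij; the separation protects the within-trial coefficient
from ecological bias.  Residual variances may be free per study-arm cell,
per study, per arm, or pooled.  Estimation is REML.

The restricted likelihood depends on the data only through per-(study, arm)
counts and first/second moments of (y_base, y_final); the engine works on
those sufficient statistics, so fitting cost is independent of the number of
subjects and pseudo IPD with matching moments reproduce the true-IPD fit to
numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .generate import PseudoIPD

__all__ = ["ModelSpec", "AncovaLMM", "AncovaResults", "fit_one_stage", "build_design"]

LOG2PI = float(np.log(2.0 * np.pi))

ResidualStructure = Literal["by_study_arm", "by_study", "by_arm", "pooled"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one ANCOVA linear mixed model.

    Parameters
    ----------
    level : {"stratified_study", "random_study"}
        Stratified: fixed per-study intercepts and baseline slopes.
        Random: study intercept and baseline slope treated as random effects.
    interaction : bool
        Include the treatment-by-baseline interaction terms.
    residual_structure : {"by_study_arm", "by_study", "by_arm", "pooled"}
        Grouping of the free residual variances.
    random_effects_cov : {"unstructured", "independent"} or None
        Covariance of the study-level random effects.  None picks the
        conventional default: unstructured for the stratified interaction
        model's (treatment, interaction) pair, independent otherwise.
    treatment_random : bool
        Give the treatment effect a between-study random component (tau1^2).
    include_across_trial : bool
        Keep the across-trial interaction column ybar_Bi * x_ij when
        ``interaction``; omitting it collapses within- and across-trial
        effect modification into one coefficient subject to ecological bias.
    center_treatment_random : bool or None
        Centre the 0/1 treatment indicator at 0.5 inside random-effect
        design columns only.  None → True for random-study models.
    df_method : {"between_within", "satterthwaite"}
    ci_level : float
    """

    level: Literal["stratified_study", "random_study"] = "stratified_study"
    interaction: bool = False
    residual_structure: ResidualStructure = "by_study"
    random_effects_cov: Literal["unstructured", "independent"] | None = None
    treatment_random: bool = True
    include_across_trial: bool = True
    center_treatment_random: bool | None = None
    df_method: Literal["between_within", "satterthwaite"] = "between_within"
    ci_level: float = 0.95
    reml_constant: Literal["overparameterized", "rank"] = "overparameterized"

    def __post_init__(self):
        if self.level not in ("stratified_study", "random_study"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.residual_structure not in ("by_study_arm", "by_study", "by_arm", "pooled"):
            raise ValueError(f"unknown residual structure {self.residual_structure!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.reml_constant not in ("overparameterized", "rank"):
            raise ValueError(f"unknown reml_constant {self.reml_constant!r}")

    @property
    def re_cov(self) -> str:
        if self.random_effects_cov is not None:
            return self.random_effects_cov
        if self.level == "stratified_study" and self.interaction:
            return "unstructured"  # (u1, u3) block
        return "independent"

    @property
    def center_re(self) -> bool:
        if self.center_treatment_random is not None:
            return self.center_treatment_random
        return self.level == "random_study"


# ---------------------------------------------------------------------------
# design construction on sufficient statistics


@dataclass
class _Cell:
    arm: int                    # 0 control, 1 treated
    n: int
    M: np.ndarray               # 3x3 cross-product of t = (1, y_base, y_final)
    res_idx: int = 0            # residual-variance parameter index
    S: np.ndarray | None = None  # C' M C for the block's local columns


@dataclass
class _StudyBlock:
    study_id: str
    center: float               # observed study mean baseline ybar_Bi
    cells: list[_Cell]
    fixed_idx: np.ndarray       # global indices of the local fixed columns
    kf: int = 0
    q: int = 0

    @property
    def n(self) -> int:
        return sum(c.n for c in self.cells)


@dataclass
class _Design:
    blocks: list[_StudyBlock]
    fixed_names: list[str]
    re_names: list[str]
    res_names: list[str]
    spec: ModelSpec
    n_obs: int

    @property
    def p(self) -> int:
        return len(self.fixed_names)

    @property
    def p_constant(self) -> int:
        """Fixed-design size entering the (n - p) log 2pi likelihood constant.

        "rank" uses the rank of the full-rank design (the nlme/lme4
        convention).  "overparameterized" uses the column count of the
        factor-expanded design in which a categorical effect contributes one
        column per level (the convention of mixed-model software using
        overparameterized classification coding, e.g. SAS PROC MIXED) —
        here: intercept + study levels + 2 treatment levels (+ 2 columns for
        each treatment-interacted term).  The choice shifts the restricted
        log-likelihood by a data-independent constant only.
        """
        if self.spec.reml_constant == "rank":
            return self.p
        N = len(self.blocks)
        if self.spec.level == "stratified_study":
            cols = 1 + N + 2 + N
        else:
            cols = 1 + 1 + 2
        if self.spec.interaction:
            cols += 2
            if self.spec.include_across_trial:
                cols += 2
        return cols

    @property
    def q(self) -> int:
        return len(self.re_names)

    @property
    def n_res(self) -> int:
        return len(self.res_names)


def _cell_stats(df: pd.DataFrame) -> dict[str, dict[int, tuple[int, np.ndarray]]]:
    out: dict[str, dict[int, tuple[int, np.ndarray]]] = {}
    for (sid, x), g in df.groupby(["study", "treat"], sort=False):
        t = np.column_stack([np.ones(len(g)), g["y_base"].to_numpy(), g["y_final"].to_numpy()])
        out.setdefault(str(sid), {})[int(x)] = (len(g), t.T @ t)
    return out


def build_design(ipd: PseudoIPD | pd.DataFrame, spec: ModelSpec) -> _Design:
    """Compile IPD and a ModelSpec into per-study sufficient-statistic blocks.

    Raises on single-arm studies and on studies with (numerically) constant
    baseline, where the baseline slope is unidentifiable.
    """
    df = ipd.data if isinstance(ipd, PseudoIPD) else ipd
    stats_ = _cell_stats(df)
    study_ids = list(stats_)
    N = len(study_ids)
    stratified = spec.level == "stratified_study"

    if not stratified and N < 2:
        raise ValueError("random-study models need at least 2 studies")

    # global fixed-effect layout
    fixed_names: list[str] = []
    if stratified:
        fixed_names += [f"intercept[{s}]" for s in study_ids]
        fixed_names += [f"baseline_c[{s}]" for s in study_ids]
    else:
        fixed_names += ["intercept", "baseline_c"]
    fixed_names.append("treat")
    if spec.interaction:
        fixed_names.append("treat:baseline_c")
        if spec.include_across_trial:
            fixed_names.append("treat:baseline_mean")
    col = {name: i for i, name in enumerate(fixed_names)}

    # random-effect layout (shared covariance across studies)
    re_names: list[str] = []
    if not stratified:
        re_names += ["intercept", "baseline_c"]
    if spec.treatment_random:
        re_names.append("treat")
    if spec.interaction and (spec.treatment_random or not stratified):
        re_names.append("treat:baseline_c")
    if spec.re_cov == "unstructured" and len(re_names) < 2 and re_names:
        raise ValueError("unstructured random-effects covariance needs >= 2 random effects")

    # residual-variance layout
    rs = spec.residual_structure
    if rs == "by_study_arm":
        res_names = [f"{s}/{a}" for s in study_ids for a in ("control", "treated")]
    elif rs == "by_study":
        res_names = list(study_ids)
    elif rs == "by_arm":
        res_names = ["control", "treated"]
    else:
        res_names = ["pooled"]
    res_col = {name: i for i, name in enumerate(res_names)}

    kappa = 0.5 if spec.center_re else 0.0
    blocks: list[_StudyBlock] = []
    n_obs = 0
    for si, sid in enumerate(study_ids):
        arms = stats_[sid]
        if set(arms) != {0, 1}:
            raise ValueError(f"study {sid!r} must have both a treated and a control arm")
        n_i = sum(v[0] for v in arms.values())
        sum_b = sum(v[1][0, 1] for v in arms.values())
        ssq_b = sum(v[1][1, 1] for v in arms.values())
        m = sum_b / n_i
        if ssq_b - n_i * m * m <= 1e-10 * max(1.0, ssq_b):
            raise ValueError(f"study {sid!r}: baseline is constant; slope unidentifiable")
        n_obs += n_i

        if stratified:
            loc_names = [f"intercept[{sid}]", f"baseline_c[{sid}]", "treat"]
        else:
            loc_names = ["intercept", "baseline_c", "treat"]
        if spec.interaction:
            loc_names.append("treat:baseline_c")
            if spec.include_across_trial:
                loc_names.append("treat:baseline_mean")
        fixed_idx = np.array([col[nm] for nm in loc_names])

        cells = []
        for x in (0, 1):
            n_c, M = arms[x]
            # each design column restricted to a cell is c0 + c1 * y_base,
            # coded as a coefficient vector against t = (1, y_base, y_final)
            coefs = []
            for nm in loc_names:
                coefs.append(_fixed_coef(nm, x, m))
            for nm in re_names:
                coefs.append(_re_coef(nm, x, m, kappa))
            coefs.append(np.array([0.0, 0.0, 1.0]))  # the response
            C = np.column_stack(coefs)
            if rs == "by_study_arm":
                ridx = res_col[f"{sid}/{'treated' if x else 'control'}"]
            elif rs == "by_study":
                ridx = res_col[sid]
            elif rs == "by_arm":
                ridx = res_col["treated" if x else "control"]
            else:
                ridx = 0
            cells.append(_Cell(arm=x, n=n_c, M=M, res_idx=ridx, S=C.T @ M @ C))
        blocks.append(
            _StudyBlock(
                study_id=sid,
                center=m,
                cells=cells,
                fixed_idx=fixed_idx,
                kf=len(loc_names),
                q=len(re_names),
            )
        )
    return _Design(
        blocks=blocks,
        fixed_names=fixed_names,
        re_names=re_names,
        res_names=res_names,
        spec=spec,
        n_obs=n_obs,
    )


def _fixed_coef(name: str, x: int, m: float) -> np.ndarray:
    if name.startswith("intercept"):
        return np.array([1.0, 0.0, 0.0])
    if name.startswith("baseline_c"):
        return np.array([-m, 1.0, 0.0])
    if name == "treat":
        return np.array([float(x), 0.0, 0.0])
    if name == "treat:baseline_c":
        return np.array([-m * x, float(x), 0.0])
    if name == "treat:baseline_mean":
        return np.array([m * x, 0.0, 0.0])
    raise KeyError(name)


def _re_coef(name: str, x: int, m: float, kappa: float) -> np.ndarray:
    xc = x - kappa
    if name == "intercept":
        return np.array([1.0, 0.0, 0.0])
    if name == "baseline_c":
        return np.array([-m, 1.0, 0.0])
    if name == "treat":
        return np.array([xc, 0.0, 0.0])
    if name == "treat:baseline_c":
        return np.array([-m * xc, xc, 0.0])
    raise KeyError(name)


# ---------------------------------------------------------------------------
# REML objective on the compiled design


def _n_g_params(q: int, cov: str) -> int:
    return q * (q + 1) // 2 if cov == "unstructured" else q


def _g_chol(theta_g: np.ndarray, q: int, cov: str) -> np.ndarray:
    """Lower-triangular factor L with G = L L' from the unconstrained params."""
    L = np.zeros((q, q), dtype=theta_g.dtype if np.iscomplexobj(theta_g) else float)
    if cov == "unstructured":
        k = 0
        for j in range(q):
            L[j, j] = np.exp(theta_g[k])
            k += 1
        for j in range(q):
            for i in range(j + 1, q):
                L[i, j] = theta_g[k]
                k += 1
    else:
        L[np.diag_indices(q)] = np.exp(theta_g)
    return L


def _logdet(A: np.ndarray):
    """Holomorphic log-determinant: exact for real matrices, and carries the
    first-order imaginary part for complex-step differentiation."""
    sign, logabs = np.linalg.slogdet(A)
    if np.iscomplexobj(A):
        return logabs + 1j * np.angle(sign), True
    return logabs, sign > 0


def _profile(theta: np.ndarray, design: _Design):
    """Return (-2 restricted logL, P, qvec, s) at variance parameters theta.

    All operations are holomorphic in theta, so evaluating at theta + i*h*e_k
    yields the exact directional derivative in the imaginary part
    (complex-step differentiation).
    """
    theta = np.asarray(theta)
    complex_in = np.iscomplexobj(theta)
    dtype = complex if complex_in else float
    n_res, q = design.n_res, design.q
    w = np.exp(-2.0 * theta[:n_res])
    L = _g_chol(theta[n_res:], q, design.spec.re_cov) if q else None

    p = design.p
    P = np.zeros((p, p), dtype=dtype)
    qvec = np.zeros(p, dtype=dtype)
    s = 0.0
    logdetV = 0.0
    for b in design.blocks:
        k = b.kf + q + 1
        A = np.zeros((k, k), dtype=dtype)
        for c in b.cells:
            A += w[c.res_idx] * c.S
            logdetV += c.n * 2.0 * theta[c.res_idx]
        F = slice(0, b.kf)
        yi = b.kf + q
        if q:
            Z = slice(b.kf, b.kf + q)
            ZZ = A[Z, Z]
            K = np.eye(q, dtype=dtype) + L.T @ ZZ @ L
            ld, ok = _logdet(K)
            if not ok:
                return np.inf, P, qvec, s
            logdetV += ld
            # rows: [F | y] against Z
            B = np.vstack([A[F, Z], A[yi, Z][None, :]]) @ L      # (kf+1, q)
            corr = B @ np.linalg.solve(K, B.T)                   # (kf+1, kf+1)
            XVX = A[F, F] - corr[:-1, :-1]
            XVy = A[F, yi] - corr[:-1, -1]
            yVy = A[yi, yi] - corr[-1, -1]
        else:
            XVX = A[F, F]
            XVy = A[F, yi]
            yVy = A[yi, yi]
        idx = b.fixed_idx
        P[np.ix_(idx, idx)] += XVX
        qvec[idx] += XVy
        s += yVy

    logdetP, ok = _logdet(P)
    if not ok:
        return np.inf, P, qvec, s
    beta = np.linalg.solve(P, qvec)
    rss = s - qvec @ beta
    if not complex_in and rss <= 0:
        return np.inf, P, qvec, s
    m2 = logdetV + logdetP + rss + (design.n_obs - design.p_constant) * LOG2PI
    return m2, P, qvec, s


def _objective(theta: np.ndarray, design: _Design) -> float:
    return _profile(theta, design)[0]


def _start_values(design: _Design) -> np.ndarray:
    """Residuals start at the within-cell ANCOVA residual variance; random
    effects at a modest fraction of the residual scale."""
    n_res = design.n_res
    acc_var = np.zeros(n_res)
    acc_n = np.zeros(n_res)
    for b in design.blocks:
        for c in b.cells:
            n, M = c.n, c.M
            mB, mF = M[0, 1] / n, M[0, 2] / n
            vB = max(M[1, 1] / n - mB * mB, 1e-12)
            vF = max(M[2, 2] / n - mF * mF, 1e-12)
            cBF = M[1, 2] / n - mB * mF
            r2 = min(cBF * cBF / (vB * vF), 0.99)
            acc_var[c.res_idx] += n * vF * (1.0 - r2)
            acc_n[c.res_idx] += n
    sig2 = acc_var / np.maximum(acc_n, 1.0)
    theta = list(0.5 * np.log(np.maximum(sig2, 1e-8)))
    sd0 = float(np.sqrt(np.mean(sig2)))

    q = design.q
    if q:
        scales = []
        for nm in design.re_names:
            if nm in ("intercept", "treat"):
                scales.append(0.3 * sd0)
            else:  # baseline-slope-like effects, per baseline unit
                sdB = np.sqrt(
                    np.mean([
                        max(c.M[1, 1] / c.n - (c.M[0, 1] / c.n) ** 2, 1e-12)
                        for b in design.blocks for c in b.cells
                    ])
                )
                scales.append(0.3 * sd0 / max(sdB, 1e-6))
        if design.spec.re_cov == "unstructured":
            theta += list(np.log(scales)) + [0.0] * (q * (q - 1) // 2)
        else:
            theta += list(np.log(scales))
    return np.array(theta)


_LOG_BOUND = 20.0


def _fit_variance_params(design: _Design, theta0=None):
    theta0 = _start_values(design) if theta0 is None else np.asarray(theta0, float)
    d = len(theta0)
    # residual and diagonal G parameters are log-SDs; unstructured off-diagonal
    # Cholesky entries are unconstrained
    n_log = design.n_res + design.q
    bounds = [(-_LOG_BOUND, _LOG_BOUND)] * n_log + [(-1e3, 1e3)] * (d - n_log)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    res = optimize.minimize(
        _objective,
        theta0,
        args=(design,),
        method="L-BFGS-B",
        jac=lambda th, d_: _num_grad(th, d_),
        bounds=bounds,
        options={"maxiter": 500, "maxfun": 5000, "ftol": 1e-15, "gtol": 1e-9},
    )
    theta = np.clip(res.x, lo, hi)
    f = _objective(theta, design)

    # Damped-Newton (Levenberg) polish with numerical derivatives.  The REML
    # surface can be extremely flat along weakly identified variance
    # directions; damping keeps steps productive there, and the convergence
    # decision uses the Newton decrement so flat directions do not mask an
    # unconverged informative one.
    converged = False
    iterations = int(res.nit)
    lam = 1e-8
    gnorm = float(np.linalg.norm(_num_grad(theta, design)))
    for _ in range(200):
        g = _num_grad(theta, design)
        gnorm = float(np.linalg.norm(g))
        H = _num_hess(theta, design)
        moved = False
        step_inf = np.inf
        for _ in range(30):
            try:
                delta = np.linalg.solve(H + lam * np.eye(d), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = np.clip(theta + delta, lo, hi)
            step_inf = float(np.max(np.abs(cand - theta)))
            fc = _objective(cand, design)
            if fc < f:
                theta, f = cand, fc
                lam = max(lam / 10.0, 1e-10)
                moved = True
                break
            # near the optimum the objective is flat to float resolution;
            # accept steps that still shrink the (exact) gradient
            if fc < f + 1e-9 * max(1.0, abs(f)):
                gc = float(np.linalg.norm(_num_grad(cand, design)))
                if gc < 0.7 * gnorm:
                    theta, f, gnorm = cand, min(f, fc), gc
                    lam = max(lam / 10.0, 1e-10)
                    moved = True
                    break
            lam *= 10.0
            if lam > 1e13:
                break
        iterations += 1
        # a tiny step only signals convergence when it was an (almost)
        # undamped Newton step; heavily damped tiny steps can occur far from
        # the optimum along flat valleys
        if moved and step_inf < 1e-8 and lam <= 1e-4:
            converged = True
            break
        if not moved:
            # no damping level helps: numerical optimum reached; declare
            # convergence if the remaining exact gradient is tiny relative
            # to the curvature scale
            converged = step_inf < 1e-6 or float(np.max(np.abs(g))) < 1e-5
            break
    return theta, f, converged, iterations


_CS_H = 1e-20


def _num_grad(theta: np.ndarray, design: _Design) -> np.ndarray:
    """Exact gradient of the -2 REML objective by complex-step differentiation."""
    theta = np.asarray(theta, float)
    g = np.empty(len(theta))
    for i in range(len(theta)):
        e = np.zeros(len(theta), dtype=complex)
        e[i] = 1j * _CS_H
        g[i] = _profile(theta + e, design)[0].imag / _CS_H
    return g


def _num_hess(theta: np.ndarray, design: _Design, h: float = 1e-5) -> np.ndarray:
    """Hessian by central differences of the exact complex-step gradient."""
    d = len(theta)
    H = np.empty((d, d))
    for i in range(d):
        e = np.zeros(d); e[i] = h
        H[:, i] = (_num_grad(theta + e, design) - _num_grad(theta - e, design)) / (2 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# model / results objects


class AncovaLMM:
    """One-stage ANCOVA linear mixed model on (pseudo or true) IPD.

    Parameters
    ----------
    ipd : PseudoIPD or DataFrame
        Subject-level records with columns ``study, treat, y_base, y_final``
        (an ``arm`` label column is accepted in place of ``treat``).
    spec : ModelSpec, optional
        Full model description; keyword arguments override its fields.
    """

    def __init__(self, ipd: PseudoIPD | pd.DataFrame, spec: ModelSpec | None = None, **kwargs):
        if spec is None:
            spec = ModelSpec(**kwargs)
        elif kwargs:
            spec = ModelSpec(**{**spec.__dict__, **kwargs})
        df = ipd.data if isinstance(ipd, PseudoIPD) else ipd.copy()
        if "treat" not in df.columns:
            if "arm" not in df.columns:
                raise ValueError("IPD needs a 'treat' (0/1) or 'arm' column")
            df = df.assign(treat=(df["arm"] == "treated").astype(int))
        self.spec = spec
        self.data = df
        self.design = build_design(df, spec)

    @classmethod
    def from_aggregate(cls, aggregate, seed: int = 0, spec: ModelSpec | None = None, **kwargs):
        """Generate pseudo IPD from aggregate data and build the model."""
        from .generate import generate_dataset

        return cls(generate_dataset(aggregate.completed(), seed=seed), spec, **kwargs)

    def fit(self, start_params=None) -> "AncovaResults":
        design = self.design
        theta, m2, converged, iterations = _fit_variance_params(design, start_params)
        if not converged:
            warnings.warn("REML estimation did not converge to tolerance", RuntimeWarning)
        _, P, qvec, _ = _profile(theta, design)
        Pinv = np.linalg.inv(P)
        beta = Pinv @ qvec
        return AncovaResults(
            model=self,
            theta=np.asarray(theta),
            params=pd.Series(beta, index=design.fixed_names),
            cov_params=pd.DataFrame(Pinv, index=design.fixed_names, columns=design.fixed_names),
            minus2_reml=float(m2),
            converged=bool(converged),
            iterations=int(iterations),
        )


@dataclass
class AncovaResults:
    """REML fit of an :class:`AncovaLMM`.

    Attributes
    ----------
    params, bse : Series of fixed-effect estimates and model-based SEs.
    vc_re : DataFrame, estimated covariance matrix of the random effects.
    residual_variances : Series of residual variances per cell class.
    minus2_reml : -2 x restricted log-likelihood (all constants included).
    aic : minus2_reml + 2 x (number of variance-covariance parameters).
    """

    model: AncovaLMM
    theta: np.ndarray
    params: pd.Series
    cov_params: pd.DataFrame
    minus2_reml: float
    converged: bool
    iterations: int
    _satt_cache: dict = field(default_factory=dict, repr=False)

    # -- variance components -------------------------------------------------
    @property
    def residual_variances(self) -> pd.Series:
        d = self.model.design
        return pd.Series(np.exp(2.0 * self.theta[: d.n_res]), index=d.res_names, name="sigma2")

    @property
    def vc_re(self) -> pd.DataFrame:
        d = self.model.design
        q = d.q
        if q == 0:
            return pd.DataFrame(index=[], columns=[])
        L = _g_chol(self.theta[d.n_res:], q, d.spec.re_cov)
        G = L @ L.T
        return pd.DataFrame(G, index=d.re_names, columns=d.re_names)

    @property
    def tau1_sq(self) -> float:
        """Between-study variance of the treatment effect."""
        G = self.vc_re
        if "treat" not in G.index:
            return 0.0
        return float(G.loc["treat", "treat"])

    @property
    def tau3_sq(self) -> float:
        G = self.vc_re
        if "treat:baseline_c" not in G.index:
            return 0.0
        return float(G.loc["treat:baseline_c", "treat:baseline_c"])

    @property
    def boundary_flags(self) -> pd.Series:
        G = self.vc_re
        diag = pd.Series(np.diag(G.to_numpy()), index=G.index) if len(G) else pd.Series(dtype=float)
        return diag < 1e-10

    @property
    def n_cov_params(self) -> int:
        return len(self.theta)

    @property
    def aic(self) -> float:
        return self.minus2_reml + 2.0 * self.n_cov_params

    # -- fixed-effect summaries ----------------------------------------------
    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index)

    @property
    def beta1(self) -> float:
        return float(self.params["treat"])

    @property
    def beta3(self) -> float:
        return float(self.params["treat:baseline_c"])

    @property
    def beta4(self) -> float:
        return float(self.params["treat:baseline_mean"])

    @property
    def n_studies(self) -> int:
        return len(self.model.design.blocks)

    def df_for(self, effect: str, method: str | None = None) -> float:
        """Degrees of freedom for one fixed effect.

        Between-within: effects carrying a study-level random component
        (the treatment effect, and the within-trial interaction when its
        random effect is present) get the between-study df N - 1; all other
        effects get the residual df N_obs - p.  Satterthwaite uses the
        REML information matrix of the variance parameters.
        """
        if effect not in self.params.index:
            raise KeyError(f"effect {effect!r} not in the model")
        method = method or self.model.spec.df_method
        d = self.model.design
        if method == "between_within":
            re_backed = {"treat": "treat", "treat:baseline_c": "treat:baseline_c"}
            if effect in re_backed and re_backed[effect] in d.re_names:
                return float(self.n_studies - 1)
            return float(d.n_obs - d.p)
        if method == "satterthwaite":
            return self._satterthwaite_df(effect)
        raise ValueError(f"unknown df method {method!r}")

    def _satterthwaite_df(self, effect: str) -> float:
        if effect in self._satt_cache:
            return self._satt_cache[effect]
        d = self.model.design
        j = list(self.params.index).index(effect)
        theta = self.theta

        # exact gradient of Var(effect) in the variance parameters, again by
        # complex step
        g = np.empty(len(theta))
        for i in range(len(theta)):
            e = np.zeros(len(theta), dtype=complex)
            e[i] = 1j * _CS_H
            _, P, _, _ = _profile(theta + e, d)
            g[i] = np.linalg.inv(P)[j, j].imag / _CS_H
        H = _num_hess(theta, d)

        def var_of_effect(th):
            _, P, _, _ = _profile(th, d)
            return float(np.linalg.inv(P)[j, j])
        # asymptotic covariance of theta-hat is 2 * H^{-1} (H is the Hessian
        # of -2 logL); guard against a singular Hessian at the boundary
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = 2.0 * np.linalg.pinv(H)
        denom = float(g @ cov @ g)
        v = var_of_effect(theta)
        df = np.inf if denom <= 0 else 2.0 * v * v / denom
        self._satt_cache[effect] = df
        return df

    def conf_int(self, effect: str = "treat", method: str | None = None,
                 level: float | None = None) -> tuple[float, float, float]:
        """(lower, upper, df) t-interval for one fixed effect."""
        level = level if level is not None else self.model.spec.ci_level
        df = self.df_for(effect, method)
        tcrit = stats.t.ppf(0.5 + level / 2.0, df) if np.isfinite(df) else stats.norm.ppf(0.5 + level / 2.0)
        est = float(self.params[effect])
        se = float(self.bse[effect])
        return est - tcrit * se, est + tcrit * se, float(df)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "ANCOVA linear mixed model (REML)",
            f"  level: {spec.level}   interaction: {spec.interaction}   "
            f"residuals: {spec.residual_structure}",
            f"  studies: {self.n_studies}   observations: {self.model.design.n_obs}",
            f"  -2 REML logL: {self.minus2_reml:.1f}   AIC: {self.aic:.1f}   "
            f"cov params: {self.n_cov_params}   converged: {self.converged}",
            "",
            f"{'effect':<24}{'estimate':>12}{'SE':>10}{'df':>8}{'CI low':>12}{'CI high':>12}",
        ]
        show = [n for n in self.params.index
                if n in ("treat", "treat:baseline_c", "treat:baseline_mean")]
        for nm in show:
            lo, hi, df = self.conf_int(nm)
            lines.append(
                f"{nm:<24}{self.params[nm]:>12.4f}{self.bse[nm]:>10.4f}"
                f"{df:>8.1f}{lo:>12.4f}{hi:>12.4f}"
            )
        lines.append("")
        G = self.vc_re
        if len(G):
            for nm in G.index:
                lines.append(f"  tau^2[{nm}] = {G.loc[nm, nm]:.4f}")
        rv = self.residual_variances
        lines.append(f"  residual variances ({spec.residual_structure}): "
                     + ", ".join(f"{v:.2f}" for v in rv.head(8))
                     + (" ..." if len(rv) > 8 else ""))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "tau1_sq": self.tau1_sq,
            "residual_variances": self.residual_variances.to_dict(),
            "minus2_reml": self.minus2_reml,
            "aic": self.aic,
            "n_cov_params": self.n_cov_params,
            "converged": self.converged,
            "iterations": self.iterations,
        }
        ci = {}
        for nm in ("treat", "treat:baseline_c", "treat:baseline_mean"):
            if nm in self.params.index:
                lo, hi, df = self.conf_int(nm)
                ci[nm] = {"low": lo, "high": hi, "df": df}
        out["conf_int"] = ci
        if self.model.spec.interaction:
            out["tau3_sq"] = self.tau3_sq
        return out


def fit_one_stage(ipd, spec: ModelSpec | None = None, **kwargs) -> AncovaResults:
    """Convenience wrapper: build and fit an :class:`AncovaLMM`."""
    return AncovaLMM(ipd, spec, **kwargs).fit()
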