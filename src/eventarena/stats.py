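"""Inference stage: repeated-measures learning-curve tests and the
linear mixed-effects (LME) models of one-shot learning.

The headline analysis asks whether room-by-room prior-knowledge
precision (OPA performance) predicts one-shot learning of a new goal
location (NPA block-2 path efficiency), holding naive-search luck in
NPA block 1 constant.  Participants and rooms ("item effects") enter
as crossed random intercepts; random slopes allowed by the data are
included maximally and pruned — interaction slopes first — when the
model cannot be fit.

The mixed-model engine estimates variance-components models by
restricted maximum likelihood (REML) on the profiled deviance, using
the Woodbury identity so that each likelihood evaluation costs
O(q^3) in the number of random-effect columns rather than O(n^3).
Random slopes are independent of intercepts (zero-correlation
parameterization).  Fixed-effect t-tests use Satterthwaite
approximate degrees of freedom, computed from the gradient of the
coefficient variance with respect to the variance parameters and the
inverse curvature of the REML log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats as spstats

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "ModelResult",
    "AnovaResult",
    "rm_anova",
    "condition_block_anova",
    "fit_lme",
    "prune_random_effects",
    "schema_benefit_model",
    "activity_models",
]


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: float
    df2: float
    epsilon: float
    df1_corrected: float
    df2_corrected: float
    p_uncorrected: float
    p_corrected: float


def rm_anova(table) -> AnovaResult:
    """One-way within-subject ANOVA on a participants x conditions table.

    The F statistic tests the condition effect against the subject x
    condition interaction.  Sphericity is corrected with the
    Greenhouse-Geisser epsilon computed from the double-centered
    condition covariance matrix; corrected degrees of freedom are the
    uncorrected ones scaled by epsilon.
    """
    a = np.asarray(table, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D participants x conditions table")
    n, k = a.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 conditions and >= 3 participants")
    if np.any(~np.isfinite(a)):
        raise ValueError("missing cells are not allowed (no imputation)")
    grand = a.mean()
    cond_means = a.mean(axis=0)
    subj_means = a.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((a - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    # Greenhouse-Geisser epsilon from the double-centered covariance
    S = np.cov(a, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    row = S.mean(axis=1, keepdims=True)
    col = S.mean(axis=0, keepdims=True)
    Sc = S - row - col + S.mean()
    eps = float(np.trace(Sc) ** 2 / ((k - 1) * np.sum(Sc * Sc)))
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    df1c, df2c = eps * df1, eps * df2
    return AnovaResult(
        F=float(F), df1=float(df1), df2=float(df2), epsilon=eps,
        df1_corrected=df1c, df2_corrected=df2c,
        p_uncorrected=float(spstats.f.sf(F, df1, df2)),
        p_corrected=float(spstats.f.sf(F, df1c, df2c)))


def condition_block_anova(opa_table, npa_table) -> dict:
    """Condition (OPA vs NPA) x block within-subject comparison.

    Both tables are participants x blocks over the *same* blocks (for
    the learning-rate comparison: blocks 2 and 3 of each phase).  With
    a two-level condition factor, the condition main effect reduces to
    a one-way test on per-participant condition means, and the
    condition x block interaction to a one-way repeated-measures ANOVA
    on the per-block OPA-NPA differences.
    """
    o = np.asarray(opa_table, dtype=float)
    p = np.asarray(npa_table, dtype=float)
    if o.shape != p.shape:
        raise ValueError("condition tables must share shape")
    cond_means = np.column_stack([o.mean(axis=1), p.mean(axis=1)])
    return {
        "condition": rm_anova(cond_means),
        "interaction": rm_anova(o - p),
    }


# ---------------------------------------------------------------------------
# Mixed-model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomTerm:
    """One random-effect variance component.

    ``slope=None`` denotes a random intercept for ``group``; otherwise
    a random slope of the named predictor (``"a:b"`` for an interaction
    slope).  ``is_interaction`` marks terms pruned first.
    """

    group: str
    slope: str | None = None
    is_interaction: bool = False

    @property
    def label(self) -> str:
        return (f"(1|{self.group})" if self.slope is None
                else f"(0+{self.slope}|{self.group})")


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one LME fit.

    Participant and room intercepts are always present; random slopes
    are the maximal set allowed and may be pruned.
    """

    response: str
    fixed: tuple = ()
    random_intercepts: tuple = ("participant", "room")
    random_slopes: tuple = ()
    reml: bool = True
    df_method: str = "satterthwaite"

    def __post_init__(self) -> None:
        if not self.random_intercepts:
            raise ValueError("at least one random intercept grouping factor "
                             "is required")

    @property
    def formula(self) -> str:
        rhs = " + ".join(["1", *self.fixed])
        re_parts = [RandomTerm(g).label for g in self.random_intercepts]
        re_parts += [t.label for t in self.random_slopes]
        return f"{self.response} ~ {rhs} + " + " + ".join(re_parts)


@dataclass
class ModelResult:
    """Fixed-effect table, variance components, and fit diagnostics."""

    coef: pd.DataFrame          # index term; estimate, se, t, df, p
    varcomp: dict               # term label -> variance (incl. "residual")
    converged: bool
    singular_terms: tuple = ()
    pruning_trace: tuple = ()   # labels of removed slope terms, in order
    spec: ModelSpec | None = None
    loglik: float = float("nan")
    n_obs: int = 0

    def term(self, name: str) -> pd.Series:
        return self.coef.loc[name]

    def report(self) -> str:
        lines = []
        if self.spec is not None:
            lines.append(f"model: {self.spec.formula}")
        lines.append(f"REML fit on {self.n_obs} observations; "
                     f"converged={self.converged}")
        if self.pruning_trace:
            lines.append("pruned random slopes: "
                         + " -> ".join(self.pruning_trace))
        if self.singular_terms:
            lines.append("singular variance components: "
                         + ", ".join(self.singular_terms))
        lines.append("")
        lines.append(self.coef.to_string(float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        lines.append("variance components:")
        for k, v in self.varcomp.items():
            lines.append(f"  {k}: {v:.5g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# REML variance-components engine
# ---------------------------------------------------------------------------

class _VCEngine:
    """Profiled-REML estimation of y = X b + sum_k Z_k u_k + e with
    u_k ~ N(0, sigma_k^2 I), e ~ N(0, sigma_e^2 I)."""

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 Z_list: list[np.ndarray], term_labels: list[str]):
        self.y = y
        self.X = X
        self.term_labels = term_labels
        self.n, self.p = X.shape
        self.k = len(Z_list)
        self.col_term = np.concatenate(
            [np.full(Z.shape[1], i) for i, Z in enumerate(Z_list)])
        U = np.hstack(Z_list)
        self.q = U.shape[1]
        self.U = U
        self.UtU = U.T @ U
        self.UtX = U.T @ X
        self.Uty = U.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    # -- core linear algebra at fixed variance ratios ------------------

    def _solve(self, gamma: np.ndarray) -> dict:
        """Profiled quantities at gamma_k = sigma_k^2 / sigma_e^2."""
        if not np.all(np.isfinite(gamma)):
            raise np.linalg.LinAlgError("non-finite variance ratios")
        g_col = gamma[self.col_term]
        s = np.sqrt(g_col)
        M = np.eye(self.q) + (s[:, None] * self.UtU) * s[None, :]
        L = np.linalg.cholesky(M)
        logdetW = 2.0 * float(np.sum(np.log(np.diag(L))))

        def wsolve(B_Ut):  # returns M^{-1} (s * B) for B = U'A blocks
            return np.linalg.solve(L.T, np.linalg.solve(L, s[:, None] * B_Ut))

        SUtX = wsolve(self.UtX)
        SUty = wsolve(self.Uty[:, None])[:, 0]
        XtWiX = self.XtX - (s[:, None] * self.UtX).T @ SUtX
        XtWiy = self.Xty - (s * self.Uty) @ SUtX
        yWiy = self.yty - float((s * self.Uty) @ SUty)
        beta = np.linalg.solve(XtWiX, XtWiy)
        rWir = max(yWiy - float(beta @ XtWiy), 1e-12)
        sigma2 = rWir / (self.n - self.p)
        sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'W^-1X not positive definite")
        return {"logdetW": logdetW, "XtWiX": XtWiX, "beta": beta,
                "sigma2": sigma2, "logdetXtWiX": logdetXtWiX, "rWir": rWir}

    def profiled_reml(self, gamma: np.ndarray) -> float:
        """REML log-likelihood profiled over beta and sigma_e^2."""
        sol = self._solve(gamma)
        npp = self.n - self.p
        return -0.5 * (sol["logdetW"] + npp * np.log(sol["sigma2"])
                       + sol["logdetXtWiX"] + npp * (1.0 + np.log(2.0 * np.pi)))

    def profiled_reml_grad(self, gamma: np.ndarray) -> tuple[float, np.ndarray]:
        """Profiled REML log-likelihood and its analytic gradient in gamma.

        With W = I + sum_k gamma_k Z_k Z_k', A = X'W^-1X and
        R = r'W^-1 r, the derivative of -2 logLik wrt gamma_k is
        tr(W^-1 Z_k Z_k') - tr(A^-1 G_k'G_k) - (n-p) e_k'e_k / R,
        where G_k = Z_k'W^-1 X and e_k = Z_k'W^-1 r; all pieces come
        from the cached cross-products via the Woodbury identity.
        """
        if not np.all(np.isfinite(gamma)):
            raise np.linalg.LinAlgError("non-finite variance ratios")
        g_col = gamma[self.col_term]
        s = np.sqrt(g_col)
        M = np.eye(self.q) + (s[:, None] * self.UtU) * s[None, :]
        L = np.linalg.cholesky(M)
        logdetW = 2.0 * float(np.sum(np.log(np.diag(L))))

        def msolve(B):
            return np.linalg.solve(L.T, np.linalg.solve(L, B))

        # U'W^-1 U, U'W^-1 X, U'W^-1 y  via Woodbury
        SUtU = msolve(s[:, None] * self.UtU)        # M^-1 S U'U
        UtWiU = self.UtU - (self.UtU * s[None, :]) @ SUtU
        UtWiX = self.UtX - (self.UtU * s[None, :]) @ msolve(s[:, None] * self.UtX)
        UtWiy = self.Uty - (self.UtU * s[None, :]) @ msolve(s * self.Uty)
        XtWiX = self.XtX - (self.UtX * s[:, None]).T @ msolve(s[:, None] * self.UtX)
        XtWiy = self.Xty - (self.UtX * s[:, None]).T @ msolve(s * self.Uty)
        yWiy = self.yty - float((self.Uty * s) @ msolve(s * self.Uty))

        beta = np.linalg.solve(XtWiX, XtWiy)
        R = max(yWiy - float(beta @ XtWiy), 1e-12)
        npp = self.n - self.p
        sign, logdetA = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'W^-1X not positive definite")
        ll = -0.5 * (logdetW + npp * np.log(R / npp) + logdetA
                     + npp * (1.0 + np.log(2.0 * np.pi)))

        Ainv_G = np.linalg.solve(XtWiX, UtWiX.T)   # p x q
        e = UtWiy - UtWiX @ beta                   # q
        grad = np.empty(self.k)
        for k_idx in range(self.k):
            cols = self.col_term == k_idx
            # tr(W^-1 Z_k Z_k') = tr(Z_k' W^-1 Z_k)
            tr_w = float(np.sum(np.diag(UtWiU)[cols]))
            tr_a = float(np.sum(UtWiX[cols] * Ainv_G[:, cols].T))
            quad = float(e[cols] @ e[cols])
            d_m2ll = tr_w - tr_a - npp * quad / R
            grad[k_idx] = -0.5 * d_m2ll
        return ll, grad

    def reml_at_variances(self, theta: np.ndarray) -> float:
        """REML log-likelihood at explicit variances
        theta = (sigma_1^2 ... sigma_k^2, sigma_e^2)."""
        s2e = theta[-1]
        gamma = np.maximum(theta[:-1], 0.0) / s2e
        sol = self._solve(gamma)
        npp = self.n - self.p
        logdetV = self.n * np.log(s2e) + sol["logdetW"]
        logdetXtViX = sol["logdetXtWiX"] - self.p * np.log(s2e)
        quad = sol["rWir"] / s2e
        return -0.5 * (logdetV + logdetXtViX + quad
                       + npp * np.log(2.0 * np.pi))

    def fit(self) -> dict:
        LOG_LO, LOG_HI = -30.0, 20.0

        def nll_grad(log_g):
            g = np.exp(np.clip(log_g, LOG_LO, LOG_HI))
            try:
                ll, grad = self.profiled_reml_grad(g)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros_like(g)
            if not (np.isfinite(ll) and np.all(np.isfinite(grad))):
                return 1e12, np.zeros_like(g)
            return -ll, -grad * g  # chain rule to log scale

        best = None
        for x0 in (np.full(self.k, np.log(0.3)),
                   np.full(self.k, np.log(0.02))):
            res = optimize.minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                                    bounds=[(LOG_LO, LOG_HI)] * self.k,
                                    options={"maxiter": 400, "ftol": 1e-12,
                                             "gtol": 1e-7})
            if best is None or res.fun < best.fun:
                best = res
            if best.success and best.fun < 1e11:
                break
        if not best.success or best.fun >= 1e11:
            # derivative-free fallback for awkward likelihood surfaces
            nm = optimize.minimize(lambda lg: nll_grad(lg)[0], best.x,
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-7, "fatol": 1e-10,
                                            "maxiter": 4000})
            if nm.fun <= best.fun + 1e-9:
                best = nm
        gamma = np.exp(np.clip(best.x, LOG_LO, LOG_HI))
        # components driven to the lower bound are zero variances
        gamma[gamma <= np.exp(LOG_LO) * 1.01] = 0.0
        success = bool(best.success and best.fun < 1e11)
        # a gradient that is tiny (or pushing into the boundary) means the
        # optimizer stopped at a genuine (possibly boundary) optimum even if
        # the line search reported failure
        if not success and best.fun < 1e11:
            _, gr = nll_grad(np.log(np.maximum(gamma, np.exp(LOG_LO))))
            at_bound = gamma == 0.0
            success = bool(np.all(np.abs(gr[~at_bound]) < 1e-3)
                           and np.all(gr[at_bound] > -1e-3))
        sol = self._solve(gamma)
        sigma2 = sol["sigma2"]
        cov_beta = sigma2 * np.linalg.inv(sol["XtWiX"])
        return {"gamma": gamma, "beta": sol["beta"], "sigma2": sigma2,
                "cov_beta": cov_beta, "converged": success,
                "loglik": self.profiled_reml(gamma)}

    # -- Satterthwaite df ----------------------------------------------

    def satterthwaite_df(self, gamma: np.ndarray, sigma2: float) -> np.ndarray:
        """Approximate df for each fixed effect.

        f_j(theta) = Var(beta_j) as a function of the variance vector;
        df_j = 2 f_j^2 / (grad_j' A grad_j), A the inverse negative
        Hessian of the REML log-likelihood.  Variance components at the
        zero boundary are held fixed (excluded from theta).
        """
        theta = np.concatenate([gamma * sigma2, [sigma2]])
        free = np.concatenate([gamma * sigma2 > 1e-8 * sigma2, [True]])
        free_idx = np.where(free)[0]

        def cjj(th_free: np.ndarray) -> np.ndarray:
            th = theta.copy()
            th[free_idx] = th_free
            s2e = th[-1]
            g = np.maximum(th[:-1], 0.0) / s2e
            sol = self._solve(g)
            return s2e * np.diag(np.linalg.inv(sol["XtWiX"]))

        def ll(th_free: np.ndarray) -> float:
            th = theta.copy()
            th[free_idx] = th_free
            try:
                return self.reml_at_variances(th)
            except np.linalg.LinAlgError:
                return -1e12

        t0 = theta[free_idx]
        # steps scaled to the residual variance: small components need an
        # absolute floor or roundoff swamps the curvature
        h = np.maximum(1e-4 * np.abs(t0), 1e-5 * sigma2)
        m = len(t0)
        fallback = np.full(self.p, float(self.n - self.p))

        # gradient of each coefficient variance wrt free variance params
        grads = np.zeros((m, self.p))
        try:
            for i in range(m):
                tp = t0.copy(); tp[i] += h[i]
                tm = t0.copy(); tm[i] = max(tm[i] - h[i], 1e-12)
                grads[i] = (cjj(tp) - cjj(tm)) / (tp[i] - tm[i])
        except np.linalg.LinAlgError:
            return fallback

        # negative Hessian of the REML log-likelihood (central differences)
        H = np.zeros((m, m))
        f0 = ll(t0)
        for i in range(m):
            tp = t0.copy(); tp[i] += h[i]
            tm = t0.copy(); tm[i] = max(tm[i] - h[i], 1e-12)
            a, b = tp[i] - t0[i], t0[i] - tm[i]
            H[i, i] = 2.0 * (b * ll(tp) - (a + b) * f0 + a * ll(tm)) \
                / (a * b * (a + b))
            for j in range(i + 1, m):
                tpp = t0.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = t0.copy(); tpm[i] += h[i]; tpm[j] = max(tpm[j] - h[j], 1e-12)
                tmp = t0.copy(); tmp[i] = max(tmp[i] - h[i], 1e-12); tmp[j] += h[j]
                tmm = t0.copy()
                tmm[i] = max(tmm[i] - h[i], 1e-12)
                tmm[j] = max(tmm[j] - h[j], 1e-12)
                num = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm))
                den = (tpp[i] - tmm[i]) * (tpp[j] - tmm[j])
                H[i, j] = H[j, i] = num / den
        df = fallback
        try:
            A = np.linalg.inv(-H)
            var0 = cjj(t0)
        except np.linalg.LinAlgError:
            return df
        for j in range(self.p):
            denom = float(grads[:, j] @ A @ grads[:, j])
            if denom > 0 and np.isfinite(denom):
                cand = 2.0 * var0[j] ** 2 / denom
                if np.isfinite(cand) and cand > 0:
                    df[j] = float(min(cand, self.n - self.p))
        return df


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def _design_column(data: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a predictor name, supporting 'a:b' product interactions."""
    if name in data.columns:
        return data[name].to_numpy(dtype=float)
    if ":" in name:
        parts = name.split(":")
        col = np.ones(len(data))
        for part in parts:
            if part not in data.columns:
                raise KeyError(f"predictor column {part!r} not found")
            col = col * data[part].to_numpy(dtype=float)
        return col
    raise KeyError(f"predictor column {name!r} not found")


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def fit_lme(data: pd.DataFrame, spec: ModelSpec, *,
            compute_df: bool = True) -> ModelResult:
    """Fit one variance-components LME by REML.

    Fixed effects get Satterthwaite approximate t-tests; the variance
    components (crossed random intercepts plus any independent random
    slopes) are reported on the response scale.  Non-convergence and
    singular (zero-boundary) components are flagged on the result, not
    raised — pruning is the caller's job.
    """
    y = data[spec.response].to_numpy(dtype=float)
    names = ["(Intercept)", *spec.fixed]
    X = np.column_stack([np.ones(len(data))]
                        + [_design_column(data, f) for f in spec.fixed])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")

    Z_list, labels = [], []
    for g in spec.random_intercepts:
        codes, levels = pd.factorize(data[g])
        if len(levels) < 2:
            raise ValueError(f"grouping factor {g!r} has a single level")
        Z_list.append(_indicator(codes, len(levels)))
        labels.append(RandomTerm(g).label)
    for term in spec.random_slopes:
        codes, levels = pd.factorize(data[term.group])
        if len(levels) < 2:
            raise ValueError(f"grouping factor {term.group!r} has a single level")
        Z = _indicator(codes, len(levels))
        Z = Z * _design_column(data, term.slope)[:, None]
        Z_list.append(Z)
        labels.append(term.label)

    engine = _VCEngine(y, X, Z_list, labels)
    try:
        fit = engine.fit()
    except np.linalg.LinAlgError:
        empty = pd.DataFrame(index=names,
                             columns=["estimate", "se", "t", "df", "p"],
                             dtype=float)
        return ModelResult(coef=empty, varcomp={}, converged=False,
                           spec=spec, n_obs=len(data))

    gamma, sigma2 = fit["gamma"], fit["sigma2"]
    se = np.sqrt(np.diag(fit["cov_beta"]))
    if spec.df_method == "satterthwaite" and compute_df:
        df = engine.satterthwaite_df(gamma, sigma2)
    else:
        df = np.full(len(names), float(len(data) - len(names)))
    t = fit["beta"] / se
    p = 2.0 * spstats.t.sf(np.abs(t), df)
    coef = pd.DataFrame({"estimate": fit["beta"], "se": se, "t": t,
                         "df": df, "p": p}, index=names)
    varcomp = {lab: float(g * sigma2) for lab, g in zip(labels, gamma)}
    varcomp["residual"] = float(sigma2)
    singular = tuple(lab for lab, g in zip(labels, gamma) if g < 1e-8)
    return ModelResult(coef=coef, varcomp=varcomp,
                       converged=bool(fit["converged"]),
                       singular_terms=singular, spec=spec,
                       loglik=float(fit["loglik"]), n_obs=len(data))


def prune_random_effects(data: pd.DataFrame, spec: ModelSpec
                         ) -> tuple[ModelSpec, ModelResult]:
    """Fit the maximal model, pruning random slopes until it fits.

    A model "cannot be fit" when the optimizer fails or a random-slope
    variance collapses to the zero boundary (singular fit).  One slope
    is removed per round: interaction slopes first, then main-effect
    slopes in reverse order of entry.  Random intercepts are never
    removed; if even the intercepts-only model fails, an error is
    raised.  The removal sequence is recorded on the result.
    """
    current = spec
    trace: list[str] = []
    while True:
        result = fit_lme(data, current, compute_df=False)
        slope_labels = {t.label for t in current.random_slopes}
        bad_slopes = [lab for lab in result.singular_terms
                      if lab in slope_labels]
        ok = result.converged and not bad_slopes
        if ok:
            result = fit_lme(data, current)  # final fit with Satterthwaite df
            result.pruning_trace = tuple(trace)
            return current, result
        if not current.random_slopes:
            raise RuntimeError("intercepts-only model failed to converge")
        slopes = list(current.random_slopes)
        interactions = [t for t in slopes if t.is_interaction]
        drop = interactions[-1] if interactions else slopes[-1]
        slopes.remove(drop)
        trace.append(drop.label)
        current = replace(current, random_slopes=tuple(slopes))


# ---------------------------------------------------------------------------
# Paradigm-level models
# ---------------------------------------------------------------------------

def _maximal_slopes(predictors) -> tuple:
    return tuple(RandomTerm("participant", p, is_interaction=":" in p)
                 for p in predictors)


def assemble_model_table(knowledge: pd.DataFrame, block1: pd.DataFrame,
                         npa2: pd.DataFrame) -> pd.DataFrame:
    """Merge room-level knowledge, the block-1 luck decomposition, and
    NPA block-2 PE into one (participant, room) modeling table."""
    b1 = block1.rename(columns={"pe": "pe_block1"})
    resp = npa2.rename(columns={"pe": "npa2_pe"})[
        ["participant", "room", "npa2_pe"]]
    out = knowledge.merge(b1, on=[c for c in ("participant", "room")
                                  if c in b1.columns], how="inner")
    out = out.merge(resp, on=["participant", "room"], how="inner")
    return out


def schema_benefit_model(table: pd.DataFrame, which_prior: str = "recent",
                         *, prune: bool = True) -> ModelResult:
    """The headline test: does prior-knowledge precision predict
    one-shot NPA learning, holding naive-search luck constant?

    ``table`` is the output of :func:`assemble_model_table` (columns
    ``npa2_pe``, ``opa_recent``, ``opa_average``, ``lucky``,
    ``residual_pe``).  Fits ``npa2_pe ~ prior + lucky + residual_pe``
    with crossed participant/room intercepts and maximal participant
    slopes, pruned as needed; the coefficient of interest is the prior
    term.
    """
    if which_prior not in ("recent", "average"):
        raise ValueError("which_prior must be 'recent' or 'average'")
    prior = f"opa_{which_prior}"
    fixed = (prior, "lucky", "residual_pe")
    spec = ModelSpec(response="npa2_pe", fixed=fixed,
                     random_slopes=_maximal_slopes(fixed))
    if prune:
        _, result = prune_random_effects(table, spec)
    else:
        result = fit_lme(table, replace(spec, random_slopes=()))
    return result


def activity_models(table: pd.DataFrame, activity: pd.DataFrame,
                    *, omnibus: bool = False, which_prior: str = "recent",
                    reverse: bool = False, prune: bool = True) -> dict:
    """Per-ROI models linking trial-level activity and one-shot learning.

    Forward models fit ``npa2_pe ~ activity + lucky + residual_pe``
    (plus the OPA prior term when ``omnibus``); the reversed model fits
    ``activity ~ prior + residual_pe + prior:residual_pe``, testing
    whether prior knowledge and its interaction with naive-search
    efficiency predict activity.  ROIs with missing trials are skipped
    with a warning.  Returns ``{roi_label: ModelResult}``.
    """
    prior = f"opa_{which_prior}"
    out: dict[str, ModelResult] = {}
    for roi, grp in activity.groupby("roi_label"):
        merged = table.merge(grp[["participant", "room", "value"]],
                             on=["participant", "room"], how="inner")
        if len(merged) < len(table):
            warnings.warn(f"ROI {roi!r}: missing trials; skipped",
                          stacklevel=2)
            continue
        if reverse:
            fixed = (prior, "residual_pe", f"{prior}:residual_pe")
            spec = ModelSpec(response="value", fixed=fixed,
                             random_slopes=_maximal_slopes(fixed))
        else:
            fixed = ("value", "lucky", "residual_pe")
            if omnibus:
                fixed = (prior, *fixed)
            spec = ModelSpec(response="npa2_pe", fixed=fixed,
                             random_slopes=_maximal_slopes(fixed))
        if prune:
            _, result = prune_random_effects(merged, spec)
        else:
            result = fit_lme(merged, replace(spec, random_slopes=()))
        out[roi] = result
    return out
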