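"""Restricted maximum likelihood estimation of family variance components.

The phenotype vector ``y`` (covariate-residualized and standardized child
scores) is modelled as multivariate normal with covariance

``V(theta) = V_o * A_c + V_parent * A_p + V_cross * (A_cp + A_cp') + V_e * I``

where ``A_c`` is the relatedness matrix among children, ``A_p`` among the
corresponding parents, and ``A_cp`` the child-by-parent cross matrix; the
offspring-only model keeps just ``V_o * A_c + V_e * I``.  Because a child's
cross relatedness with its own parent is ~0.5, the symmetrized cross
structure contributes ``2 * 0.5 * V_cross = V_cross`` to the phenotypic
variance, so total genetic variance is ``G = V_o + V_parent + V_cross`` and
all components are directly proportions of the (unit) phenotypic variance.

Estimation is average-information (AI) REML with step halving and an EM
fallback; variance components are floored at zero (the covariance component
is unconstrained in sign).  Standard errors come from the inverse AI matrix
at the optimum, and nested models are compared with a likelihood-ratio
chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lapack
from scipy.stats import chi2

from .grm import GRM, GRMSet

__all__ = [
    "NotPositiveDefiniteError",
    "ModelSpec",
    "VarianceComponentsResult",
    "restricted_loglik",
    "reml_fit",
    "lrt",
    "combined_G",
    "fit_offspring_model",
    "fit_parent_model",
]


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """The proposed covariance matrix V(theta) is not positive definite."""


_PARAM_NAMES = {
    "offspring": ("V_o", "V_e"),
    "maternal": ("V_o", "V_m", "V_om", "V_e"),
    "paternal": ("V_o", "V_f", "V_of", "V_e"),
    "null": ("V_e",),
}


@dataclass(frozen=True)
class ModelSpec:
    """Variance-structure matrices of one REML model.

    ``structures`` are aligned symmetric n x n matrices, one per variance
    parameter, with the identity (residual) last by convention.  ``nonneg``
    flags parameters constrained to be nonnegative (variances yes,
    cross-covariance no).
    """

    kind: str
    param_names: tuple[str, ...]
    structures: tuple[np.ndarray, ...]
    nonneg: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = self.structures[0].shape[0]
        for S in self.structures:
            if S.shape != (n, n):
                raise ValueError("structure matrices must be square and aligned")
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError("structure matrices must be symmetric")
        if not (len(self.param_names) == len(self.structures) == len(self.nonneg)):
            raise ValueError("param_names, structures, nonneg must align")

    @property
    def n(self) -> int:
        return self.structures[0].shape[0]

    @property
    def n_params(self) -> int:
        return len(self.structures)

    @classmethod
    def offspring(cls, grm: GRM | np.ndarray) -> "ModelSpec":
        A = grm.values if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
        return cls("offspring", _PARAM_NAMES["offspring"],
                   (A, np.eye(len(A))), (True, True))

    @classmethod
    def parent(cls, grm_set: GRMSet, kind: str = "maternal") -> "ModelSpec":
        if kind not in ("maternal", "paternal"):
            raise ValueError("kind must be 'maternal' or 'paternal'")
        if grm_set.parental is None or grm_set.cross is None:
            raise ValueError("parent model needs parental and cross matrices")
        A_c = grm_set.offspring.values
        A_p = grm_set.parental.values
        S_cross = grm_set.cross.values + grm_set.cross.values.T
        return cls(kind, _PARAM_NAMES[kind],
                   (A_c, A_p, S_cross, np.eye(len(A_c))),
                   (True, True, False, True))

    @classmethod
    def residual_only(cls, n: int) -> "ModelSpec":
        return cls("null", _PARAM_NAMES["null"], (np.eye(n),), (True,))


@dataclass
class VarianceComponentsResult:
    """One fitted model: variance fractions, SEs, combined G, fit diagnostics.

    ``theta`` holds the parameters in ``param_names`` order; named accessors
    (``v_o``, ``v_parent``, ``v_cross``, ``v_e``) return NaN where a model
    has no such term.  ``g = v_o + v_parent + v_cross`` with a delta-method
    standard error; ``lrt_p`` compares the model against its reduced
    counterpart (offspring-only for the parent models).
    """

    kind: str
    param_names: tuple[str, ...]
    theta: np.ndarray
    se: np.ndarray | None
    param_cov: np.ndarray | None
    loglik: float
    n: int
    iterations: int
    converged: bool
    boundary: np.ndarray
    g: float = np.nan
    g_se: float | None = None
    lrt_stat: float | None = None
    lrt_p: float | None = None

    @classmethod
    def from_estimates(
        cls,
        kind: str,
        v_o: float,
        v_parent: float | None = None,
        v_cross: float | None = None,
        v_e: float = np.nan,
        n: int = 0,
    ) -> "VarianceComponentsResult":
        """Build a result container from externally reported point estimates
        (e.g. a published table row) so operations like :func:`combined_G`
        can be applied to them."""
        names = _PARAM_NAMES[kind]
        if kind == "offspring":
            theta = np.array([v_o, v_e], dtype=float)
        else:
            theta = np.array([v_o, v_parent, v_cross, v_e], dtype=float)
        return cls(kind, names, theta, None, None, np.nan, n, 0, True,
                   np.zeros(len(theta), dtype=bool))

    def _get(self, name_options: tuple[str, ...]) -> float:
        for nm in name_options:
            if nm in self.param_names:
                return float(self.theta[self.param_names.index(nm)])
        return np.nan

    def _get_se(self, name_options: tuple[str, ...]) -> float:
        if self.se is None:
            return np.nan
        for nm in name_options:
            if nm in self.param_names:
                return float(self.se[self.param_names.index(nm)])
        return np.nan

    @property
    def v_o(self) -> float:
        return self._get(("V_o",))

    @property
    def v_parent(self) -> float:
        return self._get(("V_m", "V_f"))

    @property
    def v_cross(self) -> float:
        return self._get(("V_om", "V_of"))

    @property
    def v_e(self) -> float:
        return self._get(("V_e",))

    def to_row(self, phenotype: str = "") -> dict:
        """Table-shaped summary row (components, SEs, G, logL, p, N)."""
        return {
            "model": self.kind,
            "phenotype": phenotype,
            "V_o": self.v_o,
            "V_o_se": self._get_se(("V_o",)),
            "V_parent": self.v_parent,
            "V_parent_se": self._get_se(("V_m", "V_f")),
            "V_cross": self.v_cross,
            "V_cross_se": self._get_se(("V_om", "V_of")),
            "G": self.g,
            "G_se": np.nan if self.g_se is None else self.g_se,
            "logL": self.loglik,
            "p": np.nan if self.lrt_p is None else self.lrt_p,
            "N": self.n,
        }


# ---------------------------------------------------------------------------
# REML internals


@dataclass
class _State:
    theta: np.ndarray
    loglik: float
    Py: np.ndarray
    Vinv: np.ndarray
    ViX: np.ndarray
    XtViX_inv: np.ndarray


def _compute_state(y: np.ndarray, X: np.ndarray, structures, theta) -> _State:
    n = len(y)
    V = np.zeros((n, n))
    for t, S in zip(theta, structures):
        if t != 0.0:
            V += t * S
    L, info = lapack.dpotrf(V, lower=1, overwrite_a=1)
    if info != 0:
        raise NotPositiveDefiniteError(f"V not positive definite (dpotrf info={info})")
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    rhs = np.column_stack([X, y])
    sol, info = lapack.dpotrs(L, rhs, lower=1)
    if info != 0:  # pragma: no cover - dpotrs only fails on bad input
        raise np.linalg.LinAlgError("dpotrs failed")
    ViX, Viy = sol[:, :-1], sol[:, -1]
    XtViX = X.T @ ViX
    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise NotPositiveDefiniteError("X' V^-1 X not positive definite")
    XtViX_inv = np.linalg.inv(XtViX)
    beta = XtViX_inv @ (X.T @ Viy)
    Py = Viy - ViX @ beta
    ypPy = float(y @ Py)
    loglik = -0.5 * (logdet_V + logdet_X + ypPy)
    # explicit V^-1 for the trace terms (dpotri gives the lower triangle)
    Vinv_tri, info = lapack.dpotri(L, lower=1, overwrite_c=1)
    if info != 0:  # pragma: no cover
        raise np.linalg.LinAlgError("dpotri failed")
    Vinv = np.tril(Vinv_tri) + np.tril(Vinv_tri, -1).T
    return _State(np.asarray(theta, dtype=float), loglik, Py, Vinv, ViX, XtViX_inv)


def _derivatives(state: _State, structures) -> tuple[np.ndarray, np.ndarray]:
    """REML gradient and average-information matrix at ``state``."""
    K = len(structures)
    Py, Vinv, ViX, XtViX_inv = state.Py, state.Vinv, state.ViX, state.XtViX_inv
    q = [S @ Py for S in structures]
    grad = np.empty(K)
    for k, S in enumerate(structures):
        tr_ViS = float(np.sum(Vinv * S))
        W = ViX.T @ (S @ ViX)
        tr_PS = tr_ViS - float(np.sum(XtViX_inv * W))
        grad[k] = -0.5 * (tr_PS - float(Py @ q[k]))
    Pq = []
    for qk in q:
        Viq = Vinv @ qk
        Pq.append(Viq - ViX @ (XtViX_inv @ (ViX.T @ qk)))
    AI = np.empty((K, K))
    for k in range(K):
        for l in range(k, K):
            AI[k, l] = AI[l, k] = 0.5 * float(q[k] @ Pq[l])
    return grad, AI


def restricted_loglik(y: np.ndarray, spec: ModelSpec, params) -> float:
    """REML log-likelihood ``-1/2 [log|V| + log|X'V^-1 X| + y'Py]`` with X
    the intercept (other fixed effects are residualized out upstream).

    Raises :class:`NotPositiveDefiniteError` when V(params) is not positive
    definite (distinct from any optimizer convergence failure).
    """
    y = np.asarray(y, dtype=float)
    X = np.ones((len(y), 1))
    state = _compute_state(y, X, spec.structures, np.asarray(params, dtype=float))
    return state.loglik


def reml_fit(
    y: np.ndarray,
    spec: ModelSpec,
    max_iter: int = 100,
    tol: float = 1e-8,
    start: np.ndarray | None = None,
) -> VarianceComponentsResult:
    """Average-information REML fit of ``spec`` to ``y``.

    Iterates AI (Newton-type) updates with Levenberg-style damping: when
    the undamped AI step does not improve the restricted likelihood (the
    AI matrix is only an approximation of the curvature and can badly
    overshoot along curved ridges), the AI matrix diagonal is inflated and
    the step recomputed, bending the direction toward the gradient; an EM
    step is the fallback of last resort.  Nonnegative parameters are
    floored at zero when a step crosses it (the cross-covariance term is
    unconstrained); the residual component keeps a small positive floor so
    V stays invertible.  Convergence is declared when the Newton decrement
    over the free parameters -- the predicted log-likelihood gain of the
    next undamped step -- falls below ``tol`` relative to ``|logL|``;
    hitting ``max_iter`` flags the result as non-converged but still
    returns the last iterate.  Standard errors are the square roots of the
    diagonal of the inverse AI matrix at the optimum (absent, flagged by
    ``se=None``, if the AI matrix is singular).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    K = spec.n_params
    if n < K + 10:
        raise ValueError(f"n={n} too small for {K} variance parameters")
    X = np.ones((n, 1))
    nonneg = np.asarray(spec.nonneg)
    vary = float(y.var())
    floor_e = 1e-8 * max(vary, 1e-12)

    if start is None:
        theta = np.full(K, vary / K)
    else:
        theta = np.asarray(start, dtype=float).copy()
    state = _compute_state(y, X, spec.structures, theta)

    def _clip(t: np.ndarray) -> np.ndarray:
        t = t.copy()
        t[nonneg & (t < 0)] = 0.0
        t[-1] = max(t[-1], floor_e)  # residual (identity) term keeps V invertible
        return t

    def _solve_step(grad, AI, free, lam):
        M = AI[np.ix_(free, free)].copy()
        if lam > 0:
            M[np.diag_indices_from(M)] += lam * np.abs(np.diag(M)).clip(min=1e-12)
        delta = np.zeros(K)
        try:
            d = np.linalg.solve(M, grad[free])
        except np.linalg.LinAlgError:
            d = np.linalg.pinv(M) @ grad[free]
        delta[free] = d
        return delta if np.isfinite(delta).all() else np.zeros(K)

    converged = False
    iterations = 0
    lam = 0.0
    for iterations in range(1, max_iter + 1):
        grad, AI = _derivatives(state, spec.structures)
        # freeze nonnegative parameters pinned at zero whose gradient points outward
        free = ~(nonneg & (state.theta <= floor_e) & (grad < 0))
        if not free.any():
            converged = True
            break
        # Newton decrement: predicted gain of the undamped step
        newton = _solve_step(grad, AI, free, 0.0)
        decrement = 0.5 * float(grad @ newton)
        if 0 <= decrement < tol * max(1.0, abs(state.loglik)):
            converged = True
            break

        new_state = None
        trial_lam = lam
        for _ in range(16):
            cand = _clip(state.theta + _solve_step(grad, AI, free, trial_lam))
            try:
                trial = _compute_state(y, X, spec.structures, cand)
                if trial.loglik > state.loglik - 1e-12:
                    new_state = trial
                    lam = trial_lam / 10.0 if trial_lam > 1e-8 else 0.0
                    break
            except NotPositiveDefiniteError:
                pass
            trial_lam = 1e-4 if trial_lam == 0 else trial_lam * 10.0
        if new_state is None:
            # EM fallback: guaranteed-ascent but slow update
            yPSPy = np.array([float(state.Py @ (S @ state.Py)) for S in spec.structures])
            tr_PS = yPSPy - 2.0 * grad
            cand = _clip(state.theta + state.theta**2 * (yPSPy - tr_PS) / n)
            try:
                new_state = _compute_state(y, X, spec.structures, cand)
            except NotPositiveDefiniteError:
                break  # give up; flagged non-converged below
            lam = max(lam, 1e-4)
        state = new_state

    grad, AI = _derivatives(state, spec.structures)
    se: np.ndarray | None
    cov: np.ndarray | None
    try:
        cov = np.linalg.inv(AI)
        diag = np.diag(cov)
        if np.any(diag < 0) or not np.isfinite(cov).all():
            raise np.linalg.LinAlgError
        se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        se, cov = None, None

    boundary = nonneg & (state.theta <= floor_e)
    result = VarianceComponentsResult(
        kind=spec.kind,
        param_names=spec.param_names,
        theta=state.theta,
        se=se,
        param_cov=cov,
        loglik=state.loglik,
        n=n,
        iterations=iterations,
        converged=converged,
        boundary=boundary,
    )
    result.g, result.g_se = combined_G(result)
    return result


def lrt(
    full: VarianceComponentsResult,
    reduced: VarianceComponentsResult,
    df: int | None = None,
) -> tuple[float, float]:
    """Likelihood-ratio test of nested REML models.

    ``statistic = 2 (logL_full - logL_reduced)`` floored at 0; the p-value
    is the chi-square upper tail with ``df`` degrees of freedom (default:
    the parameter-count difference).  A full-model likelihood below the
    reduced one beyond numerical tolerance indicates an optimizer fault and
    raises.
    """
    if df is None:
        df = len(full.param_names) - len(reduced.param_names)
    if df < 1:
        raise ValueError("reduced model must have fewer parameters")
    stat = 2.0 * (full.loglik - reduced.loglik)
    tol = 1e-6 * max(1.0, abs(reduced.loglik))
    if stat < -tol:
        raise RuntimeError(
            f"full-model logL {full.loglik:.6f} below reduced {reduced.loglik:.6f}; "
            "REML optimizer fault"
        )
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, df))


def combined_G(result: VarianceComponentsResult) -> tuple[float, float | None]:
    """Combined direct + indirect genetic variance ``G`` and its SE.

    ``G`` is the sum of all genetic components (every parameter except the
    residual); the SE comes from the delta method: the square root of the
    sum of all entries of the genetic block of the parameter covariance.
    Returns ``(g, None)`` when no parameter covariance is available.
    """
    gen_idx = [i for i, nm in enumerate(result.param_names) if nm != "V_e"]
    g = float(np.sum(result.theta[gen_idx]))
    if result.param_cov is None:
        return g, None
    block = result.param_cov[np.ix_(gen_idx, gen_idx)]
    var_g = float(np.sum(block))
    return g, float(np.sqrt(max(var_g, 0.0)))


def fit_offspring_model(
    y: np.ndarray,
    grm: GRM | np.ndarray,
    **fit_kwargs,
) -> VarianceComponentsResult:
    """Offspring-only GREML (SNP heritability): ``V_o A + V_e I`` with an
    LRT against the residual-only model (df = 1)."""
    spec = ModelSpec.offspring(grm)
    full = reml_fit(y, spec, **fit_kwargs)
    reduced = reml_fit(y, ModelSpec.residual_only(spec.n), **fit_kwargs)
    full.lrt_stat, full.lrt_p = lrt(full, reduced, df=1)
    return full


def fit_parent_model(
    y: np.ndarray,
    grm_set: GRMSet,
    parent_kind: str = "maternal",
    **fit_kwargs,
) -> VarianceComponentsResult:
    """Extended parent-offspring GREML: direct, nurture, and covariance
    components, with an LRT against the offspring-only model (df = 2)."""
    spec = ModelSpec.parent(grm_set, parent_kind)
    full = reml_fit(y, spec, **fit_kwargs)
    reduced = reml_fit(y, ModelSpec.offspring(grm_set.offspring), **fit_kwargs)
    full.lrt_stat, full.lrt_p = lrt(full, reduced, df=2)
    return full
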