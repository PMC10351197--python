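"""Linear mixed model with three variance components, fit by REML.

The null model for each metabolite is

    y = X beta + u_g + u_h + u_c + e,
    u_g ~ N(0, sg2 * 2K),  u_h ~ N(0, sh2 * Zh Zh'),
    u_c ~ N(0, sc2 * Zc Zc'),  e ~ N(0, se2 * I),

with K the pairwise kinship matrix and Zh / Zc household and
census-block indicator matrices.  Variance components are estimated by
average-information REML with EM fallback steps; they are then held
fixed, and every association test in the package is a generalized
least-squares Wald test under the fitted covariance
V = sg2*2K + sh2*ZhZh' + sc2*ZcZc' + se2*I.

Solving with V exploits its block structure: samples that share no
kinship, household or block are independent, so V is block diagonal
over the connected components of the combined relatedness graph.  Each
component is factored densely; with a fully dense kinship matrix this
degrades gracefully to a single dense factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .cohort import CohortStructure

__all__ = ["AncestryLMM", "NullModelFit", "GLSTestResult"]

VC_NAMES = ("kinship", "household", "block", "residual")


# ---------------------------------------------------------------------------
# blocked covariance machinery
# ---------------------------------------------------------------------------


class _BlockedKernels:
    """Kernels of V grouped by connected component of the relatedness graph.

    Components of equal size are stacked into (m, s, s) arrays so all
    factorizations and solves are batched LAPACK calls.
    """

    def __init__(self, kernels: list, n: int):
        self.n = n
        pattern = None
        for K in kernels:
            Ks = K if sp.issparse(K) else sp.csr_matrix(K)
            pattern = abs(Ks) if pattern is None else pattern + abs(Ks)
        _, labels = sp.csgraph.connected_components(pattern, directed=False)
        comps: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            comps.setdefault(lab, []).append(i)
        by_size: dict[int, list[np.ndarray]] = {}
        for members in comps.values():
            by_size.setdefault(len(members), []).append(np.asarray(members))
        dense = [K.toarray() if sp.issparse(K) else np.asarray(K, float)
                 for K in kernels]
        self.classes = []
        for s, groups in sorted(by_size.items()):
            idx = np.vstack(groups)  # (m, s)
            blocks = [
                np.stack([D[np.ix_(c, c)] for c in groups]) for D in dense
            ]  # per kernel: (m, s, s)
            self.classes.append((idx, blocks))
        self.n_kernels = len(kernels)

    def factor(self, sigmas: np.ndarray) -> "_CovFactor":
        return _CovFactor(self, np.asarray(sigmas, float))


class _CovFactor:
    def __init__(self, kernels: _BlockedKernels, sigmas: np.ndarray):
        self.kernels = kernels
        self.sigmas = sigmas
        self._vinv = []
        logdet = 0.0
        for idx, blocks in kernels.classes:
            V = sum(s * B for s, B in zip(sigmas, blocks))
            L = np.linalg.cholesky(V)  # raises on non-PD
            logdet += 2.0 * np.sum(np.log(np.einsum("mii->mi", L)))
            self._vinv.append(np.linalg.inv(V))
        self.logdet = float(logdet)

    def solve(self, M: np.ndarray) -> np.ndarray:
        """V^{-1} M for M of shape (n,) or (n, k)."""
        vec = M.ndim == 1
        M2 = M[:, None] if vec else M
        out = np.empty_like(M2, dtype=float)
        for (idx, _), Vi in zip(self.kernels.classes, self._vinv):
            out[idx] = Vi @ M2[idx]
        return out[:, 0] if vec else out

    def kernel_dot(self, i: int, M: np.ndarray) -> np.ndarray:
        """G_i M for kernel i."""
        vec = M.ndim == 1
        M2 = M[:, None] if vec else M
        out = np.empty_like(M2, dtype=float)
        for idx, blocks in self.kernels.classes:
            out[idx] = blocks[i] @ M2[idx]
        return out[:, 0] if vec else out

    def trace_vinv_kernel(self, i: int) -> float:
        return float(
            sum(np.sum(Vi * blocks[i])
                for (_, blocks), Vi in zip(self.kernels.classes, self._vinv))
        )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class GLSTestResult:
    """Wald test of a block of covariates under the fitted covariance."""

    statistic: float
    df: int
    pvalue: float
    params: np.ndarray  # NaN where a column was dropped
    bse: np.ndarray
    names: list
    dropped: list = field(default_factory=list)
    untestable: bool = False

    @property
    def reduced_df(self) -> bool:
        return len(self.dropped) > 0


@dataclass
class NullModelFit:
    """REML fit of the null model; the covariance contract for all tests.

    Carries the variance-component estimates, the GLS fixed-effect
    estimates under the fitted V, and the solver used by
    :meth:`gls_test` / :meth:`solve_v` for every downstream association
    test (variance components stay fixed at their null-model values).
    """

    model: "AncestryLMM"
    vc: dict
    fe_params: pd.Series
    fe_bse: pd.Series
    cov_fe: np.ndarray
    loglike: float
    converged: bool
    n_iter: int
    _fact: _CovFactor = field(repr=False, default=None)
    _ViX: np.ndarray = field(repr=False, default=None)
    _XtViX_inv: np.ndarray = field(repr=False, default=None)
    _Viy: np.ndarray = field(repr=False, default=None)

    def solve_v(self, M: np.ndarray) -> np.ndarray:
        """Return V^{-1} M under the fitted covariance."""
        return self._fact.solve(M)

    def gls_test(
        self, W: np.ndarray, names=None, extra: np.ndarray | None = None,
        _rtol: float = 1e-8,
    ) -> GLSTestResult:
        """Wald chi-square test of covariate block W, adjusting for X (+extra).

        W columns collinear with the adjustment covariates (or with each
        other) are dropped and df reduced; df = 0 flags the test
        untestable.  ``extra`` adds fixed covariates beyond the null
        design (used by conditional analyses); variance components are
        never re-estimated.
        """
        W = np.atleast_2d(np.asarray(W, dtype=float))
        if W.shape[0] != self.model.n:
            W = W.T
        k = W.shape[1]
        if names is None:
            names = [f"w{j}" for j in range(k)]

        y = self.model.endog
        if extra is None:
            ViX, XtViX_inv = self._ViX, self._XtViX_inv
            X = self.model.exog
        else:
            extra = np.atleast_2d(np.asarray(extra, dtype=float))
            if extra.shape[0] != self.model.n:
                extra = extra.T
            X = np.hstack([self.model.exog, extra])
            ViX = self._fact.solve(X)
            # pinv tolerates extra columns collinear with the null design
            XtViX_inv = np.linalg.pinv(X.T @ ViX, hermitian=True)

        ViW = self._fact.solve(W)
        A = X.T @ ViW
        S = W.T @ ViW - A.T @ XtViX_inv @ A
        u = W.T @ self._Viy - A.T @ XtViX_inv @ (X.T @ self._Viy)
        scale = np.diag(W.T @ ViW).copy()

        kept: list[int] = []
        dropped: list[int] = []
        for j in range(k):
            if scale[j] <= 0:
                dropped.append(j)
                continue
            trial = kept + [j]
            Ssub = S[np.ix_(trial, trial)]
            try:
                L = np.linalg.cholesky(Ssub)
                if L[-1, -1] ** 2 <= _rtol * scale[j]:
                    raise np.linalg.LinAlgError
                kept = trial
            except np.linalg.LinAlgError:
                dropped.append(j)

        params = np.full(k, np.nan)
        bse = np.full(k, np.nan)
        if not kept:
            return GLSTestResult(
                statistic=np.nan, df=0, pvalue=np.nan, params=params, bse=bse,
                names=list(names), dropped=dropped, untestable=True,
            )
        Skk = S[np.ix_(kept, kept)]
        uk = u[kept]
        c = cho_factor(Skk)
        gamma = cho_solve(c, uk)
        cov = cho_solve(c, np.eye(len(kept)))
        stat = float(max(uk @ gamma, 0.0))
        df = len(kept)
        params[kept] = gamma
        bse[kept] = np.sqrt(np.diag(cov))
        return GLSTestResult(
            statistic=stat, df=df, pvalue=float(stats.chi2.sf(stat, df)),
            params=params, bse=bse, names=list(names), dropped=dropped,
        )

    def summary(self) -> str:
        lines = ["Null mixed model (REML)", "=" * 46]
        lines.append(f"n = {self.model.n}   converged = {self.converged} "
                     f"({self.n_iter} iterations)")
        lines.append(f"REML log-likelihood = {self.loglike:.4f}")
        lines.append("")
        lines.append("Variance components:")
        for name in VC_NAMES:
            lines.append(f"  {name:<10s} {self.vc[name]:>12.6f}")
        lines.append("")
        fe = pd.DataFrame({"coef": self.fe_params, "se": self.fe_bse})
        fe["z"] = fe["coef"] / fe["se"]
        lines.append("Fixed effects:")
        lines.append(fe.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class AncestryLMM:
    """Three-variance-component linear mixed model for one phenotype.

    Parameters
    ----------
    endog : array (n,)
        Complete (post-prep) phenotype vector.
    exog : array (n, p) or DataFrame
        Fixed-effect design, full column rank, including the intercept.
    structure : CohortStructure
        Kinship + household/block labels defining the random effects.
    kin_scale : float
        Multiplier turning kinship coefficients into the genetic
        relationship kernel (2.0 under the standard convention).
    """

    def __init__(self, endog, exog, structure: CohortStructure,
                 kin_scale: float = 2.0, exog_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        n = len(y)
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotype contains missing/non-finite values; "
                             "run phenotype preparation first")
        if X.shape[0] != n or structure.n_samples != n:
            raise ValueError("dimension mismatch between y, X and structure")
        self.exog_names = exog_names or [f"x{j}" for j in range(X.shape[1])]
        # rank check, naming the collinear columns
        _, R, piv = _qr_pivot(X)
        diag = np.abs(np.diag(R))
        bad = piv[diag <= 1e-10 * max(diag[0], 1.0)]
        if len(bad):
            raise ValueError(
                "design matrix rank deficient; collinear columns: "
                + ", ".join(self.exog_names[j] for j in bad)
            )
        self.endog = y
        self.exog = X
        self.structure = structure
        self.n = n
        Zh = structure.cluster_indicator(structure.household)
        Zc = structure.cluster_indicator(structure.block)
        self._kernels = _BlockedKernels(
            [kin_scale * structure.kinship, Zh @ Zh.T, Zc @ Zc.T,
             sp.eye(n, format="csr")],
            n,
        )

    # -- REML ----------------------------------------------------------

    def _state(self, sigmas: np.ndarray) -> dict:
        fact = self._kernels.factor(sigmas)
        X, y = self.exog, self.endog
        ViX = fact.solve(X)
        XtViX = X.T @ ViX
        cX = cho_factor(XtViX)
        Viy = fact.solve(y)
        XtViy = X.T @ Viy
        Py = Viy - ViX @ cho_solve(cX, XtViy)
        ytPy = float(y @ Py)
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        ll = -0.5 * (fact.logdet + logdet_xvx + ytPy)
        # score and average-information matrix
        nk = self._kernels.n_kernels
        T = np.column_stack([fact.kernel_dot(i, Py) for i in range(nk)])
        ViT = fact.solve(T)
        PT = ViT - ViX @ cho_solve(cX, X.T @ ViT)
        AI = 0.5 * (T.T @ PT)
        score = np.empty(nk)
        B = cho_solve(cX, np.eye(X.shape[1]))
        for i in range(nk):
            GiViX = fact.kernel_dot(i, ViX)
            trPGi = fact.trace_vinv_kernel(i) - float(np.sum(B * (ViX.T @ GiViX)))
            score[i] = -0.5 * (trPGi - float(Py @ T[:, i]))
        return {
            "fact": fact, "ll": ll, "score": score, "AI": AI,
            "ViX": ViX, "cX": cX, "Viy": Viy, "Py": Py, "B": B,
        }

    def fit(self, start=None, maxiter: int = 100, tol: float = 1e-6,
            verbose: bool = False) -> NullModelFit:
        """Estimate variance components by AI-REML and return the fit.

        Negative proposals are projected to the boundary; a component
        pushed negative twice is fixed at zero.  Iterations that would
        decrease the REML objective fall back to step halving and then
        to an EM update, so accepted steps are non-decreasing.
        """
        n, p = self.n, self.exog.shape[1]
        nk = self._kernels.n_kernels
        resid = self.endog - self.exog @ np.linalg.lstsq(
            self.exog, self.endog, rcond=None)[0]
        vary = max(float(resid.var()), 1e-12)
        sigmas = np.asarray(start, float) if start is not None \
            else np.full(nk, vary / nk)
        floor = 1e-10 * vary
        sigmas = np.maximum(sigmas, floor)
        fixed_zero = np.zeros(nk, bool)
        neg_hits = np.zeros(nk, int)

        state = self._state(sigmas)
        converged = False
        n_iter = 0
        for it in range(1, maxiter + 1):
            n_iter = it
            # a component at the zero boundary with a negative gradient is
            # fixed there (keeps the AI system well conditioned)
            at_floor = (sigmas <= 10 * floor) & (state["score"] < 0)
            at_floor[-1] = False
            fixed_zero |= at_floor
            free = ~fixed_zero
            score, AI = state["score"][free], state["AI"][np.ix_(free, free)]
            try:
                delta = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                delta = None
            accepted = None
            if delta is not None:
                step = 1.0
                for _ in range(12):
                    cand = sigmas.copy()
                    cand[free] = sigmas[free] + step * delta
                    neg = cand < 0
                    cand[neg] = floor
                    cand[fixed_zero] = 0.0
                    cand[-1] = max(cand[-1], floor)  # residual keeps V positive
                    try:
                        cand_state = self._state(cand)
                    except np.linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if cand_state["ll"] >= state["ll"] - 1e-10:
                        neg_hits[neg & free] += 1
                        accepted = (cand, cand_state)
                        break
                    step *= 0.5
            if accepted is None:
                # EM fallback: guaranteed ascent direction
                cand = sigmas.copy()
                cand[free] = sigmas[free] + (2.0 * sigmas[free] ** 2 / n) \
                    * state["score"][free]
                cand = np.maximum(cand, 0.0)
                cand[fixed_zero] = 0.0
                cand[-1] = max(cand[-1], floor)
                cand_state = self._state(cand)
                accepted = (cand, cand_state)
            new_sigmas, new_state = accepted
            fixed_zero |= neg_hits >= 2
            new_sigmas[fixed_zero] = 0.0
            if verbose:
                print(f"iter {it}: ll={new_state['ll']:.8f} sigmas={new_sigmas}")
            if abs(new_state["ll"] - state["ll"]) < tol:
                sigmas, state = new_sigmas, new_state
                converged = True
                break
            sigmas, state = new_sigmas, new_state

        sigmas = np.where(sigmas <= 10 * floor, 0.0, sigmas)
        state = self._state(sigmas)
        return self._make_results(sigmas, state, converged, n_iter)

    def fit_fixed(self, sigmas) -> NullModelFit:
        """Build the fit at externally supplied variance components.

        No estimation is performed; used when true components are known
        (simulation studies) or to reuse components across phenotypes.
        """
        sigmas = np.asarray(sigmas, dtype=float)
        if sigmas.min() < 0:
            raise ValueError("variance components must be >= 0")
        state = self._state(sigmas)
        return self._make_results(sigmas, state, converged=True, n_iter=0)

    def _make_results(self, sigmas, state, converged, n_iter) -> NullModelFit:
        # GLS fixed effects under the (final) covariance
        fe = cho_solve(state["cX"], self.exog.T @ state["Viy"])
        cov_fe = state["B"]
        vc = {name: float(s) for name, s in zip(VC_NAMES, sigmas)}
        return NullModelFit(
            model=self,
            vc=vc,
            fe_params=pd.Series(fe, index=self.exog_names),
            fe_bse=pd.Series(np.sqrt(np.diag(cov_fe)), index=self.exog_names),
            cov_fe=cov_fe,
            loglike=float(state["ll"]),
            converged=converged,
            n_iter=n_iter,
            _fact=state["fact"],
            _ViX=state["ViX"],
            _XtViX_inv=state["B"],
            _Viy=state["Viy"],
        )


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv
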