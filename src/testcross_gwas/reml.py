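"""Dense REML engine for Gaussian mixed models.

Fits models of the form

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma2_k K_k),  e ~ N(0, sigma2_e I)

by average-information (AI) REML with EM fallback steps, for a handful of
random terms whose covariance is either the identity on the factor levels or
a supplied dense matrix (e.g. a genomic relationship matrix).  Everything is
dense: the panels this engine serves have at most a few hundred individuals
and a few thousand observations, where explicit n x n algebra is both simple
and fast.

Variance components are constrained to be non-negative; an update that
leaves the parameter space is pinned at zero (boundary REML) and the pinned
component is released again only if its score turns positive.  Accepted
iterations never decrease the REML log-likelihood (AI steps are halved until
they improve it, then an EM step is tried, which is monotone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

log = logging.getLogger(__name__)

_RESIDUAL = "residual"


@dataclass
class RandomTerm:
    """One random effect: incidence matrix ``Z`` (n x q) and optional dense
    covariance ``K`` (q x q, PSD); ``K=None`` means the identity."""

    name: str
    Z: np.ndarray
    K: np.ndarray | None = None

    def cov_contribution(self) -> np.ndarray:
        """Return V_k = Z K Z' (n x n)."""
        Z = np.asarray(self.Z, dtype=float)
        if self.K is None:
            return Z @ Z.T
        K = np.asarray(self.K, dtype=float)
        if K.shape != (Z.shape[1], Z.shape[1]):
            raise ValueError(f"random term {self.name!r}: K shape {K.shape} "
                             f"does not match Z columns {Z.shape[1]}")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError(f"random term {self.name!r}: K is not symmetric")
        return Z @ K @ Z.T


@dataclass
class ModelSpec:
    """Response, fixed design and random terms of one mixed model.

    ``fixed_names`` labels the columns of ``X``; ``term_levels`` optionally
    maps a fixed factor name to ``(levels, column_indices, ref_level)`` so
    that per-level adjusted means can be reconstructed after the fit.
    """

    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    random_terms: list[RandomTerm] = field(default_factory=list)
    term_levels: dict = field(default_factory=dict)


@dataclass
class MixedModelFit:
    beta: np.ndarray
    fixed_names: list[str]
    vc: dict[str, float]
    C_inv: np.ndarray            # (X' V^-1 X)^-1 on the retained fixed columns
    reml_loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    dropped_fixed: list[str] = field(default_factory=list)
    term_levels: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"REML fit: n={self.n_obs}, loglik={self.reml_loglik:.4f}, "
                 f"converged={self.converged} ({self.n_iter} iter)"]
        lines.append("variance components:")
        for k, v in self.vc.items():
            lines.append(f"  {k:24s} {v:.6g}")
        lines.append("fixed effects:")
        for name, b in zip(self.fixed_names, self.beta):
            lines.append(f"  {name:24s} {b:.6g}")
        if self.dropped_fixed:
            lines.append(f"dropped (aliased): {', '.join(self.dropped_fixed)}")
        return "\n".join(lines)


def drop_aliased_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove linearly dependent columns of X by pivoted QR rank detection."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        return X, list(names), []
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    kept_names = [names[i] for i in keep]
    dropped = [names[i] for i in sorted(piv[rank:])]
    if dropped:
        log.info("dropped aliased fixed columns: %s", ", ".join(map(str, dropped)))
    return X[:, keep], kept_names, dropped


def _reml_loglik(y, X, V):
    """REML log-likelihood (constant dropped) and reusable pieces."""
    n, p = X.shape
    cho = linalg.cho_factor(V, lower=True)
    Vinv_y = linalg.cho_solve(cho, y)
    Vinv_X = linalg.cho_solve(cho, X)
    XtVinvX = X.T @ Vinv_X
    cho_x = linalg.cho_factor(XtVinvX, lower=True)
    C_inv = linalg.cho_solve(cho_x, np.eye(p))
    beta = C_inv @ (X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    logdet_V = 2.0 * np.sum(np.log(np.diag(cho[0])))
    logdet_X = 2.0 * np.sum(np.log(np.diag(cho_x[0])))
    ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    return ll, cho, Py, beta, C_inv, Vinv_X


def fit_reml(spec: ModelSpec, tol: float = 1e-8, max_iter: int = 200) -> MixedModelFit:
    """Estimate variance components by AI-REML, then beta by GLS.

    Convergence requires both a relative log-likelihood change < ``tol`` and
    a maximum relative parameter change < 1e-6.  Non-convergence returns the
    best iterate with ``converged=False`` and a warning.
    """
    y = np.asarray(spec.y, dtype=float).ravel()
    n = y.size
    X, kept_names, dropped = drop_aliased_columns(np.asarray(spec.X, dtype=float), spec.fixed_names)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"need more observations ({n}) than fixed-effect columns ({p})")

    # response scaling keeps tolerances meaningful across trait units
    scale = float(np.std(y))
    if scale == 0.0:
        scale = 1.0
    ys = y / scale

    Vks = [t.cov_contribution() for t in spec.random_terms]
    names = [t.name for t in spec.random_terms] + [_RESIDUAL]
    m = len(Vks) + 1  # + residual
    eye = np.eye(n)

    # start: OLS residual variance split evenly over all components
    bhat, *_ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ bhat
    s2_tot = float(resid @ resid) / max(n - p, 1)
    sig = np.full(m, max(s2_tot, 1e-8) / m)
    floor = 1e-10

    def build_V(s):
        V = s[-1] * eye
        for sk, Vk in zip(s[:-1], Vks):
            V = V + sk * Vk
        return V

    def loglik_of(s):
        try:
            return _reml_loglik(ys, X, build_V(s))
        except np.linalg.LinAlgError:
            return None

    state = loglik_of(sig)
    if state is None:
        raise np.linalg.LinAlgError("initial covariance matrix is singular")
    ll = state[0]
    converged = False
    it = 0
    pinned = np.zeros(m, dtype=bool)

    for it in range(1, max_iter + 1):
        _, cho, Py, _, _, _ = state
        # P @ M products via the identity P M = V^-1 M - V^-1 X (X'V^-1X)^-1 X' V^-1 M
        Vinv = linalg.cho_solve(cho, eye)
        VinvX = linalg.cho_solve(cho, X)
        C_inv_x = np.linalg.inv(X.T @ VinvX)
        P = Vinv - VinvX @ C_inv_x @ VinvX.T

        all_Vk = Vks + [eye]
        score = np.empty(m)
        PVkPy = []
        for k, Vk in enumerate(all_Vk):
            VkPy = Vk @ Py
            PVkPy.append(P @ VkPy)
            trPVk = float(np.sum(P * Vk))  # tr(P Vk), Vk symmetric
            score[k] = -0.5 * (trPVk - float(Py @ VkPy))

        # release pinned components whose score points back inside
        pinned &= ~(score > 0)
        free = ~pinned

        q_eff = np.array([t.Z.shape[1] for t in spec.random_terms] + [n], dtype=float)
        # EM direction: sigma^2 + (sigma^4/q) [y'P Vk P y - tr(P Vk)] = sigma^2 + 2 sigma^4 score / q
        em_target = np.where(free, np.maximum(sig + 2.0 * sig**2 * score / q_eff, 0.0), sig)

        def clamp(s):
            s = np.maximum(s, 0.0)
            s[-1] = max(s[-1], floor)
            return s

        def try_step(target):
            """Halve toward ``sig`` until the log-likelihood does not drop
            (a tiny numerical slack keeps flat steps acceptable)."""
            step = target
            for _ in range(25):
                trial = clamp(step)
                st = loglik_of(trial)
                if st is not None and st[0] >= ll - 1e-9 * max(1.0, abs(ll)):
                    return trial, st
                step = sig + 0.5 * (step - sig)
            return None, None

        # average-information matrix on free components
        idx = np.where(free)[0]
        AI = np.empty((idx.size, idx.size))
        for a, ka in enumerate(idx):
            for b, kb in enumerate(idx):
                AI[a, b] = 0.5 * float((all_Vk[ka] @ Py) @ PVkPy[kb])

        proposal, prop_state = None, None
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(idx.size), score[idx])
            target = sig.copy()
            target[idx] = sig[idx] + delta
            proposal, prop_state = try_step(target)
        except np.linalg.LinAlgError:
            pass
        if proposal is None:
            proposal, prop_state = try_step(em_target)
        if proposal is None:
            # no step improves the likelihood: at a (boundary) optimum when
            # the remaining EM displacement is negligible
            em_rel = np.max(np.abs(clamp(em_target.copy()) - sig)
                            / np.maximum(np.abs(sig), 1e-12))
            if em_rel < 1e-4 or np.max(np.abs(score[free])) < 1e-6 * n:
                converged = True
            else:
                log.warning("REML: no admissible update at iteration %d", it)
            break

        new_sig = proposal
        pinned |= new_sig[:m] <= 0
        pinned[-1] = False  # residual stays free (floored, never pinned)
        rel_par = np.max(np.abs(new_sig - sig) / np.maximum(np.abs(sig), 1e-12))
        rel_ll = abs(prop_state[0] - ll) / max(abs(ll), 1.0)
        sig, state, ll = new_sig, prop_state, prop_state[0]
        if rel_ll < tol and rel_par < 1e-6:
            converged = True
            break

    if not converged:
        log.warning("REML did not converge in %d iterations (rel ll change %.3g)", it, tol)

    ll, cho, Py, beta_s, C_inv_s, _ = state
    vc = {name: float(s * scale**2) for name, s in zip(names, sig)}
    beta = beta_s * scale
    C_inv = C_inv_s * scale**2
    return MixedModelFit(
        beta=beta,
        fixed_names=kept_names,
        vc=vc,
        C_inv=C_inv,
        reml_loglik=float(ll),
        converged=converged,
        n_iter=it,
        n_obs=n,
        dropped_fixed=dropped,
        term_levels=dict(spec.term_levels),
    )


def reml_loglik_at(spec: ModelSpec, components: dict[str, float]) -> float:
    """REML log-likelihood at fixed variance components (for grid checks).

    The response is internally standardised exactly as in :func:`fit_reml`,
    so values are directly comparable with ``MixedModelFit.reml_loglik`` when
    the supplied components are on the original trait scale.
    """
    y = np.asarray(spec.y, dtype=float).ravel()
    X, _, _ = drop_aliased_columns(np.asarray(spec.X, dtype=float), spec.fixed_names)
    scale = float(np.std(y)) or 1.0
    ys = y / scale
    V = max(components[_RESIDUAL] / scale**2, 1e-12) * np.eye(y.size)
    for t in spec.random_terms:
        V = V + (components[t.name] / scale**2) * t.cov_contribution()
    return float(_reml_loglik(ys, X, V)[0])


def blues_and_contrast_variance(fit: MixedModelFit, factor: str):
    """Per-level adjusted means of a fixed factor and the mean pairwise
    contrast variance v_bar_Delta.

    The factor must have been coded with a reference level absorbed into the
    intercept; level estimates fold the intercept back in so they sit on the
    trait scale (other fixed terms held at their reference/zero).  The mean
    contrast variance averages var(est_i - est_j) = C_ii + C_jj - 2 C_ij
    over all level pairs, taken from the precision matrix of the fit.
    """
    if factor not in fit.term_levels:
        raise ValueError(
            f"{factor!r} was not fitted as a fixed factor in this model; "
            "fit the dual model with the factor fixed to obtain contrasts"
        )
    levels, cols, ref = fit.term_levels[factor]
    try:
        i0 = fit.fixed_names.index("Intercept")
    except ValueError as exc:
        raise ValueError("model has no intercept; adjusted means undefined") from exc
    mu = fit.beta[i0]

    # column index in the *retained* design for each non-reference level
    col_idx = {}
    for lev, name in cols.items():
        if name in fit.fixed_names:
            col_idx[lev] = fit.fixed_names.index(name)
    estimates = {}
    for lev in levels:
        estimates[lev] = mu if lev == ref else mu + fit.beta[col_idx[lev]]

    k = len(levels)
    C = np.zeros((k, k))
    order = list(levels)
    for a, la in enumerate(order):
        for b, lb in enumerate(order):
            ia = col_idx.get(la)
            ib = col_idx.get(lb)
            if ia is not None and ib is not None:
                C[a, b] = fit.C_inv[ia, ib]
    # reference level row/col are zero: var(beta_ref)=0 by construction
    pair_vars = []
    for a in range(k):
        for b in range(a + 1, k):
            pair_vars.append(C[a, a] + C[b, b] - 2.0 * C[a, b])
    v_bar = float(np.mean(pair_vars)) if pair_vars else float("nan")
    return pd.Series(estimates, name="estimate"), v_bar


def dummy_design(frame, factors: list[str], covariates: list[str] | None = None):
    """Intercept + treatment-coded factor dummies + covariate columns.

    Returns ``(X, names, term_levels)`` where ``term_levels[f]`` is
    ``(levels, {level: column_name}, reference_level)`` — the bookkeeping
    :func:`blues_and_contrast_variance` needs.  The reference is the first
    level in sorted order.
    """
    n = len(frame)
    blocks = [np.ones((n, 1))]
    names = ["Intercept"]
    term_levels = {}
    for f in factors:
        vals = pd.Categorical(frame[f].astype(str))
        levels = list(vals.categories)
        ref = levels[0]
        cols = {}
        for lev in levels[1:]:
            name = f"{f}[{lev}]"
            blocks.append((vals == lev).astype(float).reshape(-1, 1))
            names.append(name)
            cols[lev] = name
        term_levels[f] = (levels, cols, ref)
    for c in covariates or []:
        blocks.append(np.asarray(frame[c], dtype=float).reshape(-1, 1))
        names.append(c)
    return np.hstack(blocks), names, term_levels


def incidence(frame, factor: str, levels=None) -> tuple[np.ndarray, list]:
    """0/1 incidence matrix of a factor (n x q) and its level order."""
    vals = frame[factor].astype(str)
    if levels is None:
        levels = sorted(vals.unique())
    lut = {lev: j for j, lev in enumerate(levels)}
    Z = np.zeros((len(frame), len(levels)))
    for i, v in enumerate(vals):
        Z[i, lut[v]] = 1.0
    return Z, list(levels)
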