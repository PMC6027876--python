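"""Restricted maximum likelihood for all-random variance-component models.

Model: y = 1·mu + sum_i Z_i u_i + e, with u_i ~ N(0, sigma2_i I) for each
random factor (genotype, location, G×L, replicate, block, ...) and
e ~ N(0, sigma2_e I). The solver works on Henderson's mixed-model equations

    C [beta; u] = W'y,    C = W'W + diag(0, lambda_i I),  lambda_i = s2e/s2i,

and maximises the restricted likelihood by average-information (AI) updates
with EM fallback steps whenever an AI proposal leaves the parameter space or
decreases the likelihood. Variance components are kept nonnegative by
projection onto a small positive floor. Convergence is declared when the
restricted log-likelihood changes by less than ``tol`` (default 1e-8), with
an iteration cap of 200.

Every factor here enters through a 0/1 incidence matrix, so each diagonal
block of W'W is diagonal; the implementation nevertheless stays fully dense
(p up to a few thousand), which is fast enough for the trial sizes this
package targets.

Identities used (X = intercept, p_X = 1, q = total random levels):
  ln|V| + ln|X'V^-1 X| = (n - p_X - q) ln s2e + sum_i q_i ln s2i + ln|C|
  Py = (y - W sol)/s2e,  y'Py = (y'y - sol'W'y)/s2e
  tr(P Z_i Z_i') = (q_i - lambda_i tr(C^ii)) / s2i
These are exercised against a direct dense-V implementation in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import ModelError

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class RandomTerm:
    """One random factor: name, integer level codes per observation, level labels."""

    name: str
    codes: np.ndarray
    levels: np.ndarray

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @classmethod
    def from_labels(cls, name: str, labels) -> "RandomTerm":
        codes, levels = _factorize(labels)
        return cls(name, codes, levels)


def _factorize(labels):
    import pandas as pd

    codes, levels = pd.factorize(pd.Series(labels).astype(str), sort=True)
    return codes.astype(int), np.asarray(levels)


@dataclass
class REMLResult:
    sigma2: dict[str, float]          # per term plus "residual"
    mu: float
    u: dict[str, np.ndarray]          # BLUPs per term, in level order
    terms: list[RandomTerm]
    loglik: float
    n_iter: int
    converged: bool
    n_obs: int
    history: list[float] = field(default_factory=list)


def _build_design(n: int, terms: list[RandomTerm]) -> tuple[np.ndarray, list[slice]]:
    q_total = sum(t.n_levels for t in terms)
    W = np.zeros((n, 1 + q_total))
    W[:, 0] = 1.0
    blocks, offset = [], 1
    for t in terms:
        W[np.arange(n), offset + t.codes] = 1.0
        blocks.append(slice(offset, offset + t.n_levels))
        offset += t.n_levels
    return W, blocks


def reml_loglik_direct(y: np.ndarray, terms: list[RandomTerm], sigma2: dict[str, float]) -> float:
    """Restricted log-likelihood evaluated the slow, textbook way (dense V).

    Independent of the MME machinery; O(n^3), intended for small problems
    and for validating the solver in tests.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    V = sigma2["residual"] * np.eye(n)
    for t in terms:
        Z = np.zeros((n, t.n_levels))
        Z[np.arange(n), t.codes] = 1.0
        V += sigma2[t.name] * (Z @ Z.T)
    X = np.ones((n, 1))
    Vinv = linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ linalg.inv(XtVinvX) @ X.T @ Vinv
    _, logdetV = np.linalg.slogdet(V)
    _, logdetX = np.linalg.slogdet(XtVinvX)
    return float(-0.5 * ((n - 1) * LOG2PI + logdetV + logdetX + y @ P @ y))


def reml_fit(
    y,
    terms: list[RandomTerm],
    tol: float = 1e-8,
    max_iter: int = 200,
    em_warmup: int = 3,
) -> REMLResult:
    """Fit the all-random model by AI-REML with EM warm-up and fallback."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ModelError("need at least 3 observations")
    if np.isnan(y).any():
        raise ModelError("response contains missing values; drop them first")
    vary = float(np.var(y))
    if vary <= 0:
        raise ModelError("response is constant; variance components undefined")
    floor = 1e-8 * vary

    W, blocks = _build_design(n, terms)
    M = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    m = len(terms)
    q = np.array([t.n_levels for t in terms])
    q_total = int(q.sum())

    # theta = (sigma2 per term..., sigma2_e)
    theta = np.full(m + 1, vary / (m + 1))

    def mme(theta):
        lam = theta[m] / theta[:m]
        C = M.copy()
        for i, blk in enumerate(blocks):
            idx = np.arange(blk.start, blk.stop)
            C[idx, idx] += lam[i]
        cho = linalg.cho_factor(C, lower=True)
        sol = linalg.cho_solve(cho, Wty)
        ss = yty - float(sol @ Wty)  # = s2e * y'Py
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        ll = -0.5 * (
            (n - 1) * LOG2PI
            + (n - 1 - q_total) * np.log(theta[m])
            + float(q @ np.log(theta[:m]))
            + logdetC
            + ss / theta[m]
        )
        return cho, sol, ss, ll, lam

    def block_traces(cho):
        # tr(C^ii) per random term, via the full inverse (p is modest)
        Cinv = linalg.cho_solve(cho, np.eye(M.shape[0]))
        return np.array([np.trace(Cinv[blk, blk]) for blk in blocks])

    def em_step(theta, cho, sol, ss):
        tr = block_traces(cho)
        new = theta.copy()
        for i, blk in enumerate(blocks):
            ui = sol[blk]
            new[i] = (float(ui @ ui) + theta[m] * tr[i]) / q[i]
        new[m] = ss / (n - 1)
        return np.maximum(new, floor)

    def ai_step(theta, cho, sol, ss, lam):
        tr = block_traces(cho)
        s2e = theta[m]
        uu = np.array([float(sol[blk] @ sol[blk]) for blk in blocks])
        trPZZ = (q - lam * tr) / theta[:m]
        score = -0.5 * (trPZZ - uu / theta[:m] ** 2)
        ehat = y - W @ sol
        ee = float(ehat @ ehat)
        trP = (n - 1 - float(theta[:m] @ trPZZ)) / s2e
        score_e = -0.5 * (trP - ee / s2e**2)
        # average-information matrix from working vectors f_i = dV/dtheta_i @ Py
        F = np.empty((n, m + 1))
        for i, blk in enumerate(blocks):
            t = terms[i]
            F[:, i] = sol[blk][t.codes] / theta[i]
        F[:, m] = ehat / s2e
        PF = (F - W @ linalg.cho_solve(cho, W.T @ F)) / s2e
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)
        full_score = np.append(score, score_e)
        # active-set Newton: components pinned at the floor with a negative
        # gradient stay fixed, so boundary components cannot stall the rest
        free = (theta > 10 * floor) | (full_score > 0)
        free[m] = True  # residual variance is never pinned
        proposal = theta.copy()
        proposal[~free] = floor
        try:
            delta = linalg.solve(
                AI[np.ix_(free, free)], full_score[free], assume_a="pos"
            )
        except linalg.LinAlgError:
            return None
        new_free = theta[free] + delta
        # per-component safeguard: a component driven negative moves a
        # decade toward the boundary instead of shrinking the whole step
        new_free = np.where(new_free > floor, new_free, np.maximum(theta[free] * 0.1, floor))
        proposal[free] = new_free
        return proposal

    cho, sol, ss, ll, lam = mme(theta)
    history = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if it <= em_warmup:
            proposal = em_step(theta, cho, sol, ss)
        else:
            proposal = ai_step(theta, cho, sol, ss, lam)
            if proposal is None:
                proposal = em_step(theta, cho, sol, ss)
        new = mme(proposal)
        if not np.isfinite(new[3]) or (it > em_warmup and new[3] < ll - 1e-6):
            proposal = em_step(theta, cho, sol, ss)
            new = mme(proposal)
        theta = proposal
        cho, sol, ss, ll_new, lam = new
        history.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    sigma2 = {t.name: float(theta[i]) for i, t in enumerate(terms)}
    sigma2["residual"] = float(theta[m])
    u = {t.name: sol[blk].copy() for t, blk in zip(terms, blocks)}
    return REMLResult(
        sigma2=sigma2,
        mu=float(sol[0]),
        u=u,
        terms=terms,
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        n_obs=n,
        history=history,
    )
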