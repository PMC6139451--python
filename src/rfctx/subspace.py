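"""Multifilter LN model estimation: spike-triggered statistics, STC and
iSTAC subspaces, and low-rank quadratic-nonlinear (MNE) models.

These estimators assume the relevant stimulus subspace is low-dimensional.
STC/iSTAC additionally assume a whitened Gaussian stimulus; binary bar
stimuli violate that assumption, and the estimators are applied as-is, with
the consequent underperformance left to the evaluation stage to reveal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "SpikeTriggeredStats",
    "FilterBank",
    "QNModel",
    "spike_triggered_stats",
    "stc_filters",
    "null_filters",
    "istac_objective",
    "istac_gradient",
    "istac_fit",
    "mne_fit",
    "mne_scores",
    "lowrank_scores",
    "lowrank_select",
    "refine_filters",
]

LOG2 = np.log(2.0)


@dataclass
class SpikeTriggeredStats:
    """Count-weighted spike-triggered mean (STA) and covariance (STC)."""

    sta: np.ndarray
    stc: np.ndarray
    n_spikes: float
    stimulus_variance: np.ndarray

    @property
    def mean_variance(self) -> float:
        return float(np.mean(self.stimulus_variance))


@dataclass
class FilterBank:
    """Subspace filters as columns of ``filters`` (orthonormal for stc/istac)."""

    filters: np.ndarray
    eigenvalues: np.ndarray | None = None
    kind: str = "stc"
    marginal_info: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.filters.shape[1]

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Project a design onto the filters; (n, m), or (n,) when m = 1."""
        Z = np.asarray(X) @ self.filters
        return Z[:, 0] if self.m == 1 else Z


@dataclass
class LowRankFilter:
    w: np.ndarray          # unit-norm filter
    lam: float             # eigenvalue (J source) or linear coefficient (v source)
    source: str            # "v" or "J"


@dataclass
class QNModel:
    """Quadratic-nonlinear model z = c + x'v + x'Jx with logistic output, and
    optionally a low-rank selection of its filters."""

    c: float
    v: np.ndarray
    J: np.ndarray
    selected: list = field(default_factory=list)

    def copy(self) -> "QNModel":
        return QNModel(self.c, self.v.copy(), self.J.copy(),
                       [LowRankFilter(f.w.copy(), f.lam, f.source)
                        for f in self.selected])


def spike_triggered_stats(X: np.ndarray, counts: np.ndarray) -> SpikeTriggeredStats:
    """STA/STC with each sample weighted by its spike count."""
    X = np.asarray(X, float)
    y = np.asarray(counts, float)
    n_spk = y.sum()
    if n_spk <= 0:
        raise ValueError("cannot form spike-triggered statistics with zero spikes")
    mu = X.T @ y / n_spk
    Xc = X - mu
    stc = (Xc.T * y) @ Xc / n_spk
    stc = 0.5 * (stc + stc.T)
    return SpikeTriggeredStats(sta=mu, stc=stc, n_spikes=float(n_spk),
                               stimulus_variance=X.var(axis=0))


def _eig_sorted(stats: SpikeTriggeredStats):
    evals, evecs = np.linalg.eigh(stats.stc)
    return evals, evecs


def stc_filters(stats: SpikeTriggeredStats, n: int) -> FilterBank:
    """Eigenvectors of the STC matrix ranked by |eigenvalue - stimulus
    variance| (largest deviation first), so both variance-expanded (excitatory)
    and variance-shrunk (suppressive) directions surface."""
    evals, evecs = _eig_sorted(stats)
    if n > len(evals):
        raise ValueError("more filters requested than dimensions available")
    order = np.argsort(-np.abs(evals - stats.mean_variance))[:n]
    return FilterBank(filters=evecs[:, order], eigenvalues=evals[order], kind="stc")


def null_filters(stats: SpikeTriggeredStats, n: int) -> FilterBank:
    """The n eigenvectors with eigenvalues closest to the stimulus variance:
    directions carrying (approximately) no stimulus-response information, used
    to calibrate the finite-sample information bias."""
    evals, evecs = _eig_sorted(stats)
    if n > len(evals):
        raise ValueError("more null filters requested than dimensions available")
    order = np.argsort(np.abs(evals - stats.mean_variance))[:n]
    return FilterBank(filters=evecs[:, order], eigenvalues=evals[order], kind="stc")


# --------------------------------------------------------------------------
# iSTAC: Gaussian information of a subspace

def istac_objective(B: np.ndarray, stats: SpikeTriggeredStats) -> float:
    """Gaussian single-spike information (bits) carried by the subspace B
    under a whitened stimulus:

        I = [Tr(B'(L + mu mu')B) - log|B'LB| - m] / (2 ln 2)

    i.e. the KL divergence between N(B'mu, B'LB) and N(0, I)."""
    B = np.atleast_2d(np.asarray(B, float))
    if B.ndim == 2 and B.shape[0] == 1:
        B = B.T
    m = B.shape[1]
    M = stats.stc + np.outer(stats.sta, stats.sta)
    BLB = B.T @ stats.stc @ B
    sign, logdet = np.linalg.slogdet(BLB)
    if sign <= 0:
        raise np.linalg.LinAlgError("B'LB is singular or not positive definite")
    return (np.trace(B.T @ M @ B) - logdet - m) / (2.0 * LOG2)


def istac_gradient(B: np.ndarray, stats: SpikeTriggeredStats) -> np.ndarray:
    """dI/dB = [(L + mu mu')B - LB(B'LB)^-1] / ln 2."""
    B = np.asarray(B, float)
    M = stats.stc + np.outer(stats.sta, stats.sta)
    BLB = B.T @ stats.stc @ B
    return (M @ B - stats.stc @ B @ np.linalg.inv(BLB)) / LOG2


def _orth_append(B_prev: np.ndarray | None, col: np.ndarray) -> np.ndarray:
    if B_prev is None or B_prev.shape[1] == 0:
        v = col / np.linalg.norm(col)
        return v[:, None]
    v = col - B_prev @ (B_prev.T @ col)
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValueError("candidate column lies in the existing subspace")
    return np.hstack([B_prev, (v / nv)[:, None]])


def istac_fit(stats: SpikeTriggeredStats, m: int, max_steps: int = 500,
              tol: float = 1e-6) -> FilterBank:
    """Greedy sequential subspace search maximizing the Gaussian information.

    Each new column is initialized from the best of the STA direction and the
    leading STC eigenvectors, then the whole basis is polished by projected
    gradient ascent with QR re-orthonormalization.
    """
    d = stats.stc.shape[0]
    if m > d:
        raise ValueError("m exceeds the stimulus dimension")
    evals, evecs = _eig_sorted(stats)
    dev_order = np.argsort(-np.abs(evals - stats.mean_variance))
    candidates = []
    if np.linalg.norm(stats.sta) > 1e-12:
        candidates.append(stats.sta)
    candidates += [evecs[:, i] for i in dev_order[: min(2 * m + 2, d)]]

    B = None
    infos = []
    for _ in range(m):
        best, best_val = None, -np.inf
        for cand in candidates:
            try:
                Bc = _orth_append(B, cand)
                val = istac_objective(Bc, stats)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if val > best_val:
                best, best_val = Bc, val
        if best is None:
            raise RuntimeError("no admissible candidate direction found")
        B = best
        # projected gradient ascent on the full current basis
        val = best_val
        step = 0.1
        converged = False
        for _ in range(max_steps):
            G = istac_gradient(B, stats)
            Bn, _ = np.linalg.qr(B + step * G / max(np.linalg.norm(G), 1e-30))
            try:
                vn = istac_objective(Bn, stats)
            except np.linalg.LinAlgError:
                vn = -np.inf
            if vn > val + tol:
                B, val = Bn, vn
            elif step > 1e-6:
                step *= 0.5
            else:
                converged = True
                break
        if not converged:
            warnings.warn("iSTAC ascent hit the step cap; best iterate kept")
        infos.append(val)
    marg = np.diff([0.0] + infos)
    return FilterBank(filters=B, eigenvalues=None, kind="istac",
                      marginal_info=marg)


# --------------------------------------------------------------------------
# MNE / low-rank QN models

def mne_scores(model: QNModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    return model.c + X @ model.v + np.einsum("ij,ij->i", X @ model.J, X)


def _mne_loss_grad(theta, X, y, ytilde, beta, C, d):
    c = theta[0]
    v = theta[1 : 1 + d]
    J = theta[1 + d :].reshape(d, d)
    XJ = X @ J
    z = c + X @ v + np.einsum("ij,ij->i", XJ, X)
    mzg = ytilde * z
    loss = C * float(np.sum(beta * np.logaddexp(0.0, -mzg)))
    loss += 0.5 * float(v @ v) + 0.5 * float(np.sum(J * J))
    sig = 1.0 / (1.0 + np.exp(-np.clip(mzg, -500, 500)))
    s = C * beta * (sig - 1.0) * ytilde
    g_c = float(np.sum(s))
    g_v = X.T @ s + v
    g_J = (X.T * s) @ X + J
    return loss, np.concatenate([[g_c], g_v, g_J.ravel()])


def mne_fit(X: np.ndarray, counts: np.ndarray, C: float = 1.0,
            max_iter: int = 500) -> QNModel:
    """Maximum-noise-entropy quadratic model: weighted regularized logistic
    regression on z = c + x'v + x'Jx.  Quadratic terms are evaluated on the
    fly (never as an n x d^2 feature matrix) and J is kept symmetric."""
    X = np.asarray(X, float)
    y = np.asarray(counts, float)
    n, d = X.shape
    ytilde = np.where(y == 0, -1.0, 1.0)
    beta = np.maximum(y, 1.0)
    theta0 = np.zeros(1 + d + d * d)
    res = optimize.minimize(
        _mne_loss_grad, theta0, args=(X, y, ytilde, beta, C, d),
        jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    c = float(res.x[0])
    v = res.x[1 : 1 + d]
    J = res.x[1 + d :].reshape(d, d)
    J = 0.5 * (J + J.T)
    return QNModel(c=c, v=v, J=J)


def lowrank_scores(model: QNModel, X: np.ndarray) -> np.ndarray:
    """Diagonalized low-rank score: z = x'w_v + sum_m lam_m (x'w_m)^2."""
    X = np.asarray(X, float)
    z = np.zeros(X.shape[0])
    for f in model.selected:
        p = X @ f.w
        z += f.lam * p if f.source == "v" else f.lam * p**2
    return z


def lowrank_select(model: QNModel, n_filters: int, X: np.ndarray,
                   counts: np.ndarray, bins: int = 15) -> QNModel:
    """Pick ``n_filters`` low-rank filters from a fitted QN model.

    The n-1 eigenvectors of J with the largest |eigenvalue| are taken first
    and projected out of v; the final filter is either the v-residual or the
    next eigenvector, whichever scores higher single-spike information.
    """
    from .info import score_distribution, single_spike_info

    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    out = model.copy()
    evals, evecs = np.linalg.eigh(model.J)
    order = np.argsort(-np.abs(evals))
    selected = [LowRankFilter(evecs[:, i].copy(), float(evals[i]), "J")
                for i in order[: n_filters - 1]]
    v_res = model.v.copy()
    for f in selected:
        v_res -= (v_res @ f.w) * f.w
    v_norm = float(np.linalg.norm(v_res))

    def info_of(sel):
        cand = model.copy()
        cand.selected = sel
        z = lowrank_scores(cand, X)
        if np.ptp(z) == 0:
            return 0.0
        return single_spike_info(score_distribution(z, counts, bins))

    options = []
    if v_norm > 1e-12:
        options.append(selected + [LowRankFilter(v_res / v_norm, v_norm, "v")])
    if n_filters - 1 < len(evals):
        i = order[n_filters - 1]
        options.append(selected + [LowRankFilter(evecs[:, i].copy(),
                                                 float(evals[i]), "J")])
    if not options:
        raise ValueError("no candidate for the final filter")
    out.selected = max(options, key=info_of)
    return out


def _lowrank_theta(model: QNModel):
    parts, meta = [], []
    for f in model.selected:
        w = f.lam * f.w if f.source == "v" else f.w
        parts.append(w)
        meta.append((f.source, f.lam))
    return np.concatenate(parts), meta


def _lowrank_unpack(theta, meta, d):
    sel = []
    for i, (source, lam) in enumerate(meta):
        w = theta[i * d : (i + 1) * d]
        if source == "v":
            nv = float(np.linalg.norm(w))
            sel.append(LowRankFilter(w / max(nv, 1e-30), nv, "v"))
        else:
            sel.append(LowRankFilter(w.copy(), lam, "J"))
    return sel


def _lowrank_loss_grad(theta, meta, X, y, ytilde, beta, C, c0, d):
    n = X.shape[0]
    z = np.full(n, c0)
    projs = []
    for i, (source, lam) in enumerate(meta):
        w = theta[i * d : (i + 1) * d]
        p = X @ w
        projs.append(p)
        z += p if source == "v" else lam * p**2
    mzg = ytilde * z
    loss = C * float(np.sum(beta * np.logaddexp(0.0, -mzg)))
    loss += 0.5 * float(theta @ theta)
    sig = 1.0 / (1.0 + np.exp(-np.clip(mzg, -500, 500)))
    s = C * beta * (sig - 1.0) * ytilde
    grads = []
    for i, (source, lam) in enumerate(meta):
        if source == "v":
            g = X.T @ s
        else:
            g = X.T @ (s * 2.0 * lam * projs[i])
        grads.append(g + theta[i * d : (i + 1) * d])
    return loss, np.concatenate(grads)


def refine_filters(model: QNModel, X: np.ndarray, counts: np.ndarray,
                   C_grid, X_val: np.ndarray, counts_val: np.ndarray,
                   max_steps: int = 200, bins: int = 15) -> QNModel:
    """Gradient-descent refinement of the low-rank filters on the weighted
    logistic loss of the diagonalized score, with the regularization strength
    and the stopping point both chosen by validation-set information."""
    from .info import score_distribution, single_spike_info

    if not model.selected:
        raise ValueError("refine_filters requires a low-rank selection")
    y = np.asarray(counts, float)
    ytilde = np.where(y == 0, -1.0, 1.0)
    beta = np.maximum(y, 1.0)
    d = X.shape[1]
    if np.isscalar(C_grid):
        C_grid = [float(C_grid)]

    def val_info(sel):
        cand = model.copy()
        cand.selected = sel
        z = lowrank_scores(cand, X_val)
        if np.ptp(z) == 0:
            return 0.0
        return single_spike_info(score_distribution(z, counts_val, bins))

    theta0, meta = _lowrank_theta(model)
    best_sel = [LowRankFilter(f.w.copy(), f.lam, f.source) for f in model.selected]
    best_val = val_info(best_sel)
    for C in C_grid:
        theta = theta0.copy()
        loss, grad = _lowrank_loss_grad(theta, meta, X, y, ytilde, beta, C,
                                        model.c, d)
        step = 0.1 / max(np.linalg.norm(grad), 1e-30) * max(np.linalg.norm(theta), 1.0)
        diverged = 0
        for _ in range(max_steps):
            cand = theta - step * grad
            cl, cg = _lowrank_loss_grad(cand, meta, X, y, ytilde, beta, C,
                                        model.c, d)
            if not np.isfinite(cl) or cl > loss:
                step *= 0.5
                diverged += 1
                if diverged > 30:
                    break
                continue
            theta, loss, grad = cand, cl, cg
            sel = _lowrank_unpack(theta, meta, d)
            vi = val_info(sel)
            if vi > best_val:
                best_val, best_sel = vi, sel
            if np.linalg.norm(step * grad) < 1e-10:
                break
    out = model.copy()
    out.selected = best_sel
    return out
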