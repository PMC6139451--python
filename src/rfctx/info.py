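"""Single-spike information of similarity scores and direct
information-maximization (MID) refinement.

The single-spike information is the KL divergence, in bits, between the
distribution of scores at spike times and the marginal score distribution:

    I = sum_z P(z|spike) log2[ P(z|spike) / P(z) ]

with both distributions estimated by histograms (1-D or 2-D).  Every sample
contributes once to P(z); sample i contributes y_i times to P(z|spike).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScoreDistribution",
    "MIDConfig",
    "score_distribution",
    "single_spike_info",
    "info_gradient",
    "mid_ascent",
]


@dataclass
class ScoreDistribution:
    bin_edges: list
    p_z: np.ndarray
    p_z_spike: np.ndarray
    p_spike: float

    @property
    def ndim(self) -> int:
        return self.p_z.ndim


@dataclass
class MIDConfig:
    bins_per_dim: int = 15
    step_size: float = 0.05
    max_steps: int = 200
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bins_per_dim < 2 or self.max_steps < 1:
            raise ValueError("need bins_per_dim >= 2 and max_steps >= 1")


def _as_2d(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, float)
    if z.ndim == 1:
        z = z[:, None]
    if z.ndim != 2 or z.shape[1] > 2:
        raise ValueError("histogram-based information supports 1-D or 2-D scores")
    return z


def _edges(z2: np.ndarray, bins: int) -> list:
    edges = []
    for d in range(z2.shape[1]):
        lo, hi = float(z2[:, d].min()), float(z2[:, d].max())
        if hi <= lo:  # degenerate (constant) score: one occupied bin
            lo, hi = lo - 0.5, hi + 0.5
        edges.append(np.linspace(lo, hi, bins + 1))
    return edges


def score_distribution(z: np.ndarray, counts: np.ndarray, bins: int,
                       edges: list | None = None) -> ScoreDistribution:
    """Histogram estimates of P(z) and the count-weighted P(z|spike) on shared
    edges spanning the observed score range."""
    z2 = _as_2d(z)
    counts = np.asarray(counts, float)
    if counts.sum() <= 0:
        raise ValueError("need at least one spike to estimate P(z|spike)")
    if edges is None:
        edges = _edges(z2, bins)
    h_all, _ = np.histogramdd(z2, bins=edges)
    h_spk, _ = np.histogramdd(z2, bins=edges, weights=counts)
    p_z = h_all / h_all.sum()
    p_spk = h_spk / h_spk.sum()
    out_shape = p_z.shape if z2.shape[1] > 1 else (p_z.shape[0],)
    return ScoreDistribution(
        bin_edges=edges,
        p_z=p_z.reshape(out_shape),
        p_z_spike=p_spk.reshape(out_shape),
        p_spike=float(counts.mean()),
    )


def single_spike_info(dist: ScoreDistribution) -> float:
    """Sum over occupied bins of p(z|spike) log2[p(z|spike)/p(z)]; bins with
    p(z|spike)=0 contribute nothing."""
    ps = dist.p_z_spike
    pz = dist.p_z
    mask = ps > 0
    assert np.all(pz[mask] > 0), "spike mass in a bin with zero total mass"
    return float(np.sum(ps[mask] * np.log2(ps[mask] / pz[mask])))


# --------------------------------------------------------------------------
# Information gradient (histogram MID)

def _bin_index(vals: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.digitize(vals, edges) - 1
    return np.clip(idx, 0, len(edges) - 2)


def _ratio_derivative(ratio: np.ndarray, centers: list, axis: int,
                      occupied: np.ndarray) -> np.ndarray:
    """Finite-difference derivative of P(z|spike)/P(z) across bins along one
    axis; unoccupied bins are treated as missing (one-sided differences at
    their boundaries, zero where isolated)."""
    r = np.where(occupied, ratio, np.nan)
    d = np.gradient(r, centers[axis], axis=axis)
    return np.nan_to_num(d)


def info_gradient(z: np.ndarray, grad_rows: list, counts: np.ndarray,
                  dist: ScoreDistribution) -> list:
    """Gradient of the single-spike information w.r.t. model parameters.

    ``grad_rows[m]`` holds per-sample rows of dz_m/dtheta_m (the score's
    parameter gradient along dimension m); the returned list matches it.
    Implements the bin-wise estimator

        dI/dtheta = sum_b P(b) [<dz|b,spike> - <dz|b>] d/dz_m(ratio_b) / ln 2

    with the ratio derivative taken by finite differences across bins.
    """
    z2 = _as_2d(z)
    counts = np.asarray(counts, float)
    ndim = z2.shape[1]
    if len(grad_rows) != ndim:
        raise ValueError("need one gradient-row matrix per score dimension")
    edges = dist.bin_edges
    centers = [0.5 * (e[1:] + e[:-1]) for e in edges]
    pz = np.atleast_1d(dist.p_z)
    ps = np.atleast_1d(dist.p_z_spike)
    occ = pz > 0
    ratio = np.where(occ, ps / np.where(occ, pz, 1.0), 0.0)

    idx = [_bin_index(z2[:, d], edges[d]) for d in range(ndim)]
    flat = np.ravel_multi_index(idx, pz.shape)
    nbins = pz.size
    out = []
    for m in range(ndim):
        G = np.asarray(grad_rows[m], float)
        P = G.shape[1]
        sum_all = np.zeros((nbins, P))
        sum_spk = np.zeros((nbins, P))
        np.add.at(sum_all, flat, G)
        np.add.at(sum_spk, flat, G * counts[:, None])
        n_all = np.bincount(flat, minlength=nbins).astype(float)
        n_spk = np.bincount(flat, weights=counts, minlength=nbins)
        mean_all = sum_all / np.maximum(n_all, 1.0)[:, None]
        mean_spk = sum_spk / np.maximum(n_spk, 1e-300)[:, None]
        dr = _ratio_derivative(ratio, centers, m, occ).ravel()
        w = pz.ravel() * dr / np.log(2.0)
        w[n_spk == 0] *= 0.0  # no conditional spike mean available
        out.append((w[:, None] * (mean_spk - mean_all)).sum(axis=0))
    return out


# --------------------------------------------------------------------------
# Gradient-ascent refinement (MID) for filter banks and context models

def _model_scores_grads(model, design, need_grads=True):
    """(z, grad_rows, get/set parameter vector) for the two supported kinds."""
    from . import context as ctx
    from .subspace import FilterBank

    if isinstance(model, FilterBank):
        X = design.X if hasattr(design, "X") else np.asarray(design)
        z = X @ model.filters
        if z.shape[1] == 1:
            z = z[:, 0]
        grads = [X] * model.filters.shape[1] if need_grads else None
        return z, grads

    if isinstance(model, ctx.ContextModelParams):
        z = ctx.similarity_scores(model, design)
        if not need_grads:
            return z, None
        A = ctx.rf_design_rows(model, design)
        blocks = [A]
        for l in range(len(model.cfs)):
            blocks.append(ctx.cf_design_rows(model, design, l))
        return z, [np.hstack(blocks)]
    raise TypeError(f"unsupported model type {type(model).__name__}")


def _get_theta(model):
    from . import context as ctx
    from .subspace import FilterBank

    if isinstance(model, FilterBank):
        return model.filters.ravel().copy()
    parts = [model.rf_flat.copy()]
    for cf in model.cfs:
        parts.append(cf.weights.ravel().copy())
    return np.concatenate(parts)


def _set_theta(model, theta):
    from . import context as ctx
    from .subspace import FilterBank

    if isinstance(model, FilterBank):
        model.filters = theta.reshape(model.filters.shape)
        return
    n_rf = model.rf.size
    model.rf = theta[:n_rf].reshape(model.rf.shape)
    off = n_rf
    for cf in model.cfs:
        w = theta[off : off + cf.spec.size].reshape(cf.weights.shape)
        w[cf.spec.origin] = 0.0  # origin stays structurally zero
        cf.weights = w
        off += cf.spec.size


def _ascent_gradient(model, design, counts, bins):
    from .subspace import FilterBank

    z, grads = _model_scores_grads(model, design)
    dist = score_distribution(z, counts, bins)
    gl = info_gradient(z, grads, counts, dist)
    if isinstance(model, FilterBank):
        # match the (d, m) filters array flattened row-major
        return np.column_stack(gl).ravel()
    return gl[0]


def _train_info(model, design, counts, bins):
    z, _ = _model_scores_grads(model, design, need_grads=False)
    return single_spike_info(score_distribution(z, counts, bins))


def _copy_model(model):
    from .subspace import FilterBank

    if isinstance(model, FilterBank):
        return FilterBank(model.filters.copy(), model.eigenvalues, model.kind)
    return model.copy()


def mid_ascent(model, design_train, counts_train, design_val, counts_val,
               cfg: MIDConfig):
    """Maximize single-spike information by gradient ascent, returning the
    iterate with the highest validation-set information (early stopping); the
    result is never worse than the initialization on that measure."""
    model = _copy_model(model)
    bins = cfg.bins_per_dim
    best = _copy_model(model)
    best_val = _train_info(model, design_val, counts_val, bins)
    cur_train = _train_info(model, design_train, counts_train, bins)
    for _ in range(cfg.max_steps):
        g = _ascent_gradient(model, design_train, counts_train, bins)
        gn = float(np.linalg.norm(g))
        if not np.isfinite(gn):
            raise RuntimeError("non-finite information gradient")
        if gn == 0:
            break
        theta = _get_theta(model)
        step = cfg.step_size * max(np.linalg.norm(theta), 1.0) / gn
        accepted = False
        for _ in range(12):
            cand = _copy_model(model)
            _set_theta(cand, theta + step * g)
            ti = _train_info(cand, design_train, counts_train, bins)
            if ti >= cur_train:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        model, cur_train = cand, ti
        vi = _train_info(model, design_val, counts_val, bins)
        if vi > best_val:
            best_val, best = vi, _copy_model(model)
    return best
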