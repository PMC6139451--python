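"""Context models: a receptive field whose elements are multiplicatively
gated by local stimulus context.

A context model scores each stimulus window as

    z_i = w0 + sum_l sum_{j in ctx_l} w_j^rf x_ij (1 + sum_k w_k^{cf_l} x~_ijk)

where ``x~_ij`` is the local context patch around stimulus element ``x_ij``
and each context field (CF) ``l`` serves a disjoint set of RF indices.  The
joint problem is nonconvex, but holding either field fixed leaves a convex
generalized-linear subproblem in the other; the fitter alternates between the
two until the loss stabilizes.  Linear, logistic and Poisson subproblem
families correspond to identity, logistic and exponential output
nonlinearities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .stimulus import (
    ContextWindowSpec,
    LaggedDesign,
    context_modulation_map,
)

__all__ = [
    "ContextField",
    "ContextModelParams",
    "SolverConfig",
    "FitResult",
    "similarity_scores",
    "linear_constant",
    "rf_design_rows",
    "cf_design_rows",
    "solve_linear_subproblem",
    "solve_glm_subproblem",
    "make_regularizer",
    "alternating_fit",
    "flip_and_restart",
    "fit_double_cf_intensity",
    "default_params",
    "data_loss",
]


@dataclass
class ContextField:
    """One context field: a (height x width) weight window plus the set of RF
    indices it serves.  The weight at the window origin is structurally zero.
    ``rf_assignment`` is a boolean mask over flattened RF indices (None means
    "all")."""

    weights: np.ndarray
    spec: ContextWindowSpec
    rf_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float).reshape(
            self.spec.height, self.spec.width
        )
        self.weights[self.spec.origin] = 0.0

    def mask_for(self, n_rf: int) -> np.ndarray:
        if self.rf_assignment is None:
            return np.ones(n_rf, bool)
        m = np.asarray(self.rf_assignment, bool)
        if m.shape != (n_rf,):
            raise ValueError("rf_assignment mask does not match RF size")
        return m


@dataclass
class ContextModelParams:
    """Bias, vectorized RF (stored as an (n_rows, n_lags) grid) and a list of
    context fields whose assignments partition the RF indices."""

    w0: float
    rf: np.ndarray
    cfs: list[ContextField] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, float)
        if self.rf.ndim != 2:
            raise ValueError("rf must be an (n_rows, n_lags) grid")
        n_rf = self.rf.size
        covered = np.zeros(n_rf, int)
        for cf in self.cfs:
            covered += cf.mask_for(n_rf)
        if self.cfs and np.any(covered > 1):
            raise ValueError("context-field assignments overlap")

    @property
    def rf_flat(self) -> np.ndarray:
        return self.rf.ravel()

    def copy(self) -> "ContextModelParams":
        return ContextModelParams(
            self.w0,
            self.rf.copy(),
            [ContextField(cf.weights.copy(), cf.spec,
                          None if cf.rf_assignment is None else cf.rf_assignment.copy())
             for cf in self.cfs],
        )


@dataclass
class SolverConfig:
    """Settings for the alternating fitter.

    ``C`` scales the data term of the subproblem losses (larger C = weaker
    regularization); ``conv_rel`` is the relative loss-decrease threshold that
    defines convergence of the outer loop (1e-4 = 0.01%).
    """

    family: str = "poisson"
    C: float = 0.1
    reg_kind: str = "l2"
    tol: float = 1e-3
    conv_rel: float = 1e-4
    cv_folds: int = 5
    cv_grid: tuple = tuple(np.logspace(-3, 2, 11))
    max_outer: int = 100
    seed: int = 0
    final_cv: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0 or self.conv_rel <= 0:
            raise ValueError("C and conv_rel must be positive")
        if self.family not in ("linear", "logistic", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class FitResult:
    params: ContextModelParams
    loss_trace: list
    chosen_C: dict
    flipped: bool = False
    converged: bool = True


# --------------------------------------------------------------------------
# Similarity scores and subproblem design matrices

def _modulation_maps(params: ContextModelParams, design: LaggedDesign):
    """Per-CF maps (1 + context cross-correlation) over the full stimulus."""
    ens = design.ensemble
    maps = []
    for cf in params.cfs:
        ctx = context_modulation_map(ens.frames, cf.weights, cf.spec, ens.n_planes)
        maps.append(1.0 + ctx)
    return maps


def rf_design_rows(params: ContextModelParams, design: LaggedDesign) -> np.ndarray:
    """Rows are the gradients dz_i/dw_rf: the stimulus window with each element
    scaled by (1 + context score) of its assigned CF.  With all CFs zero this
    is the raw lagged design."""
    from .stimulus import _lagged_matrix

    n_rf = params.rf.size
    if design.X.shape[1] != n_rf:
        raise ValueError("design width does not match RF size")
    if not params.cfs:
        return design.X.copy()
    A = np.array(design.X, float, copy=True)
    ens = design.ensemble
    sel = design.sample_indices
    for cf, mod in zip(params.cfs, _modulation_maps(params, design)):
        mask = cf.mask_for(n_rf)
        M = ens.frames * mod
        rows = _lagged_matrix(M, design.n_lags)
        if sel is not None:
            rows = rows[sel]
        A[:, mask] = rows[:, mask]
    return A


def cf_design_rows(params: ContextModelParams, design: LaggedDesign, l: int) -> np.ndarray:
    """Rows are the gradients dz_i/dw_cf_l, one column per CF window cell:

        dz_i/dw_k = sum_{j in ctx_l} w_j^rf x~_ijk x_ij

    computed as a valid 2-D correlation of shifted stimulus products with the
    RF (restricted to the CF's assigned indices).  The origin column equals
    sum_j w_j x_ij^2 mathematically but its weight is structurally zero; the
    solver drops it."""
    cf = params.cfs[l]
    n_rf = params.rf.size
    mask = cf.mask_for(n_rf)
    if not mask.any():
        raise ValueError("context field has an empty rf_assignment")
    ens = design.ensemble
    nb, nf = ens.frames.shape
    rows = nb // ens.n_planes
    L = design.n_lags
    r0, c0 = cf.spec.origin
    wmask = (params.rf_flat * mask).reshape(nb, L)
    n_samples = design.n_samples
    A = np.zeros((n_samples, cf.spec.size))
    for pl in range(ens.n_planes):
        S = ens.frames[pl * rows : (pl + 1) * rows].astype(float)
        W = wmask[pl * rows : (pl + 1) * rows]
        if not W.any():
            continue
        pad = np.pad(S, ((cf.spec.height, cf.spec.height),
                         (cf.spec.width, cf.spec.width)))
        for p in range(cf.spec.height):
            for q in range(cf.spec.width):
                rs = cf.spec.height + p - r0
                cs = cf.spec.width + q - c0
                T = S * pad[rs : rs + rows, cs : cs + nf]
                # valid correlation over time of T with the masked RF
                col = signal.fftconvolve(T, W[::-1, ::-1], mode="valid")[0]
                if design.sample_indices is not None:
                    col = col[design.sample_indices]
                A[:, p * cf.spec.width + q] += col
    A[:, cf.spec.origin_flat] = 0.0  # structural zero; never solved for
    return A


def similarity_scores(params: ContextModelParams, design: LaggedDesign) -> np.ndarray:
    """z_i = w0 + w_rf . (context-modulated window i)."""
    A = rf_design_rows(params, design)
    return params.w0 + A @ params.rf_flat


def linear_constant(params: ContextModelParams, design: LaggedDesign) -> np.ndarray:
    """The CF-subproblem constant k_i = w0 + w_rf . x_i (raw design)."""
    return params.w0 + design.X @ params.rf_flat


# --------------------------------------------------------------------------
# Regularizers and convex subproblem solvers

def make_regularizer(kind: str, field_shape: tuple[int, int]) -> np.ndarray:
    """Tikhonov matrix over a 2-D field grid (flattened row-major).

    ``l2`` gives the identity; ``laplacian`` the 2-D discrete Laplace operator
    with one-sided (Neumann) stencils on the boundary, which favours smooth
    fields and annihilates constants.
    """
    h, w = field_shape
    n = h * w
    if kind == "l2":
        return np.eye(n)
    if kind != "laplacian":
        raise ValueError(f"unknown regularizer kind {kind!r}")

    def second_diff(m: int) -> np.ndarray:
        if m == 1:
            return np.zeros((1, 1))
        D = 2.0 * np.eye(m)
        D[0, 0] = D[-1, -1] = 1.0
        idx = np.arange(m - 1)
        D[idx, idx + 1] = -1.0
        D[idx + 1, idx] = -1.0
        return D

    return np.kron(second_diff(h), np.eye(w)) + np.kron(np.eye(h), second_diff(w))


def solve_linear_subproblem(A, y, k, C, Gamma) -> np.ndarray:
    """Closed-form ridge solution w = (A'A + Gamma'Gamma/(2C))^-1 A'(y - k)."""
    A = np.asarray(A, float)
    r = np.asarray(y, float)
    if k is not None:
        r = r - np.asarray(k, float)
    H = A.T @ A
    if Gamma is not None:
        H = H + (Gamma.T @ Gamma) / (2.0 * C)
    b = A.T @ r
    try:
        return np.linalg.solve(H, b)
    except np.linalg.LinAlgError:
        warnings.warn("singular normal equations; falling back to pseudoinverse")
        return np.linalg.pinv(H) @ b


def _glm_terms(family: str, z, y, ytilde, beta):
    """(loss, dL/dz, d2L/dz2) of the per-sample data term."""
    if family == "logistic":
        m = ytilde * z
        loss = float(np.sum(beta * np.logaddexp(0.0, -m)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(m, -500, 500)))
        g = beta * (sig - 1.0) * ytilde
        h = beta * sig * (1.0 - sig)
        return loss, g, h
    if family == "poisson":
        ez = np.exp(np.clip(z, -500, 500))
        loss = float(np.sum(ez - y * z))
        return loss, ez - y, ez
    raise ValueError(f"unknown GLM family {family!r}")


def solve_glm_subproblem(A, y, k, C, Gamma, family, tol: float = 1e-3,
                         w_init=None, max_iter: int = 100) -> np.ndarray:
    """Damped-Newton minimizer of the logistic / Poisson subproblem loss

        L = C sum_i beta_i * l(z_i) + 0.5 ||Gamma w||^2,   z = k + A w

    with the signed targets y~ in {-1,+1} (y~=-1 iff y=0) and weights
    beta = max(y, 1) in the logistic case.  The per-sample offset ``k`` is what
    rules out off-the-shelf GLM solvers.
    """
    A = np.asarray(A, float)
    y = np.asarray(y, float)
    k = np.zeros(len(y)) if k is None else np.asarray(k, float)
    n, d = A.shape
    G = np.zeros((d, d)) if Gamma is None else Gamma.T @ Gamma
    ytilde = np.where(y == 0, -1.0, 1.0)
    beta = np.maximum(y, 1.0)
    w = np.zeros(d) if w_init is None else np.asarray(w_init, float).copy()

    def full_loss(wv):
        z = k + A @ wv
        data, _, _ = _glm_terms(family, z, y, ytilde, beta)
        return C * data + 0.5 * float(wv @ (G @ wv))

    loss = full_loss(w)
    for _ in range(max_iter):
        z = k + A @ w
        _, g1, h1 = _glm_terms(family, z, y, ytilde, beta)
        grad = C * (A.T @ g1) + G @ w
        H = C * (A.T * h1) @ A + G
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(d), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        # backtracking: halve until the loss is finite and non-increasing
        t, ok = 1.0, False
        for _ in range(40):
            cand = w + t * step
            cl = full_loss(cand)
            if np.isfinite(cl) and cl <= loss + 1e-12 * max(1.0, abs(loss)):
                ok = True
                break
            t *= 0.5
        if not ok:
            raise RuntimeError("GLM subproblem failed to make progress")
        w, new_loss = cand, cl
        rel = (loss - new_loss) / max(1.0, abs(loss))
        gnorm = float(np.linalg.norm(grad))
        loss = new_loss
        if rel < 1e-10 or gnorm * t < tol:
            break
    return w


def data_loss(family: str, z, y) -> float:
    """Unregularized data term of the chosen subproblem family."""
    y = np.asarray(y, float)
    if family == "linear":
        return float(np.sum((y - z) ** 2))
    ytilde = np.where(y == 0, -1.0, 1.0)
    beta = np.maximum(y, 1.0)
    loss, _, _ = _glm_terms(family, z, y, ytilde, beta)
    return loss


def _solve_subproblem(A, y, k, C, Gamma, family, tol, w_init=None):
    if family == "linear":
        return solve_linear_subproblem(A, y, k, C, Gamma)
    return solve_glm_subproblem(A, y, k, C, Gamma, family, tol, w_init=w_init)


# --------------------------------------------------------------------------
# Alternating optimization

def _pad_bias(A: np.ndarray, Gamma: np.ndarray):
    """Append a ones column for the bias; the bias row of Gamma is zero."""
    A1 = np.hstack([A, np.ones((A.shape[0], 1))])
    d = Gamma.shape[0]
    G1 = np.zeros((d + 1, d + 1))
    G1[:d, :d] = Gamma
    return A1, G1


def _drop_origin(A: np.ndarray, Gamma: np.ndarray, origin: int):
    keep = np.arange(A.shape[1]) != origin
    return A[:, keep], Gamma[np.ix_(keep, keep)], keep


def _objective(params, design, counts, cfg, Gam_rf, Gam_cfs, C) -> float:
    z = similarity_scores(params, design)
    val = C * data_loss(cfg.family, z, counts)
    val += 0.5 * float(np.sum((Gam_rf @ params.rf_flat) ** 2))
    for cf, G in zip(params.cfs, Gam_cfs):
        val += 0.5 * float(np.sum((G @ cf.weights.ravel()) ** 2))
    return val


def _cv_choose_C(A, y, k, Gamma, family, cfg, rng) -> float:
    """Pick C from the grid by k-fold CV on the held-out subproblem data loss.

    Folds are contiguous blocks (samples are temporally dependent).  Ties go
    to the smallest (most regularizing) C.
    """
    n = A.shape[0]
    bounds = np.linspace(0, n, cfg.cv_folds + 1).astype(int)
    scores = np.zeros(len(cfg.cv_grid))
    GtG = Gamma.T @ Gamma if Gamma is not None else None
    for f in range(cfg.cv_folds):
        te = np.zeros(n, bool)
        te[bounds[f] : bounds[f + 1]] = True
        tr = ~te
        if family == "linear":
            # share the Gram matrix across the C grid
            H0 = A[tr].T @ A[tr]
            b = A[tr].T @ (y[tr] - k[tr])
            for ci, C in enumerate(cfg.cv_grid):
                w = np.linalg.solve(H0 + GtG / (2.0 * C), b)
                z = k[te] + A[te] @ w
                scores[ci] += data_loss(family, z, y[te])
            continue
        for ci, C in enumerate(cfg.cv_grid):
            w = _solve_subproblem(A[tr], y[tr], k[tr], C, Gamma, family, cfg.tol)
            z = k[te] + A[te] @ w
            scores[ci] += data_loss(family, z, y[te])
    if not np.any(np.isfinite(scores)):
        raise RuntimeError("cross-validation produced no finite scores")
    best = np.flatnonzero(scores <= np.nanmin(scores) + 1e-12)[0]
    return float(cfg.cv_grid[best])


def alternating_fit(design: LaggedDesign, counts: np.ndarray,
                    init: ContextModelParams, cfg: SolverConfig) -> FitResult:
    """Alternate RF- and CF-subproblem solves until the relative loss decrease
    drops below ``cfg.conv_rel``, then run one extra iteration with C chosen
    per step by contiguous k-fold cross-validation on the training data.
    """
    params = init.copy()
    counts = np.asarray(counts, float)
    rng = np.random.default_rng(cfg.seed)
    n_rf = params.rf.size

    Gam_rf = make_regularizer(cfg.reg_kind, params.rf.shape)
    Gam_cfs = [make_regularizer(cfg.reg_kind, (cf.spec.height, cf.spec.width))
               for cf in params.cfs]

    # Break the all-zero-CF stationary point with tiny seeded jitter.
    for cf in params.cfs:
        if not cf.weights.any():
            cf.weights += 1e-3 * rng.standard_normal(cf.weights.shape)
            cf.weights[cf.spec.origin] = 0.0

    def rf_step(C):
        A = rf_design_rows(params, design)
        A1, G1 = _pad_bias(A, Gam_rf)
        w_init = np.append(params.rf_flat, params.w0)
        w = _solve_subproblem(A1, counts, None, C, G1, cfg.family, cfg.tol, w_init)
        params.rf = w[:-1].reshape(params.rf.shape)
        params.w0 = float(w[-1])

    def cf_step(l, C):
        cf = params.cfs[l]
        A = cf_design_rows(params, design, l)
        k = linear_constant(params, design)
        for lo in range(len(params.cfs)):
            if lo != l:
                k = k + cf_design_rows(params, design, lo) @ params.cfs[lo].weights.ravel()
        Ad, Gd, keep = _drop_origin(A, Gam_cfs[l], cf.spec.origin_flat)
        w_init = cf.weights.ravel()[keep]
        w = _solve_subproblem(Ad, counts, k, C, Gd, cfg.family, cfg.tol, w_init)
        full = np.zeros(cf.spec.size)
        full[keep] = w
        cf.weights = full.reshape(cf.spec.height, cf.spec.width)

    trace = []
    converged = False
    for it in range(cfg.max_outer):
        rf_step(cfg.C)
        for l in range(len(params.cfs)):
            cf_step(l, cfg.C)
        loss = _objective(params, design, counts, cfg, Gam_rf, Gam_cfs, cfg.C)
        if trace:
            prev = trace[-1]
            if loss > prev + 1e-6 * max(1.0, abs(prev)):
                raise RuntimeError(
                    f"outer loss increased from {prev:.6g} to {loss:.6g} at "
                    f"iteration {it}; subproblem solves are inconsistent"
                )
            if (prev - loss) <= cfg.conv_rel * abs(prev):
                trace.append(loss)
                converged = True
                break
        trace.append(loss)
    if not converged:
        warnings.warn("alternating fit hit the outer-iteration cap")

    chosen: dict = {}
    if cfg.final_cv and params.cfs:
        A = rf_design_rows(params, design)
        A1, G1 = _pad_bias(A, Gam_rf)
        C_rf = _cv_choose_C(A1, counts, np.zeros(len(counts)), G1, cfg.family, cfg, rng)
        chosen["rf"] = C_rf
        rf_step(C_rf)
        for l in range(len(params.cfs)):
            cf = params.cfs[l]
            A = cf_design_rows(params, design, l)
            k = linear_constant(params, design)
            for lo in range(len(params.cfs)):
                if lo != l:
                    k = k + cf_design_rows(params, design, lo) @ params.cfs[lo].weights.ravel()
            Ad, Gd, _ = _drop_origin(A, Gam_cfs[l], cf.spec.origin_flat)
            C_cf = _cv_choose_C(Ad, counts, k, Gd, cfg.family, cfg, rng)
            chosen[f"cf{l}"] = C_cf
            cf_step(l, C_cf)
        trace.append(_objective(params, design, counts, cfg, Gam_rf, Gam_cfs, cfg.C))

    return FitResult(params=params, loss_trace=trace, chosen_C=chosen,
                     converged=converged)


def flip_and_restart(result: FitResult, design: LaggedDesign, counts,
                     cfg: SolverConfig) -> FitResult:
    """Sign convention: if the RF's most negative entry dominates its most
    positive one, negate RF and CFs and rerun the alternating fit (the RF/CF
    product makes joint sign flips near-equivalent solutions)."""
    rf = result.params.rf
    if abs(rf.min()) <= rf.max():
        return result
    init = result.params.copy()
    init.rf = -init.rf
    for cf in init.cfs:
        cf.weights = -cf.weights
    out = alternating_fit(design, counts, init, cfg)
    out.flipped = True
    return out


def default_params(design: LaggedDesign, n_cfs: int = 1,
                   window: ContextWindowSpec | None = None) -> ContextModelParams:
    """Zero-initialized parameters with ``n_cfs`` context fields.

    With one CF the assignment covers every RF index.  With two CFs on an
    intensity-concatenated design, the first CF serves the bright half and the
    second the dark half of the RF rows.
    """
    window = window or ContextWindowSpec()
    nb, L = design.n_bars, design.n_lags
    rf = np.zeros((nb, L))
    cfs = []
    if n_cfs == 1:
        cfs = [ContextField(np.zeros((window.height, window.width)), window)]
    elif n_cfs == 2:
        half = nb // 2
        grid = np.zeros((nb, L), bool)
        bright = grid.copy()
        bright[:half] = True
        dark = ~bright
        cfs = [
            ContextField(np.zeros((window.height, window.width)), window, bright.ravel()),
            ContextField(np.zeros((window.height, window.width)), window, dark.ravel()),
        ]
    elif n_cfs != 0:
        raise ValueError("supported CF counts: 0, 1, 2")
    return ContextModelParams(w0=0.0, rf=rf, cfs=cfs)


def fit_double_cf_intensity(design_concat: LaggedDesign, counts,
                            cfg: SolverConfig,
                            window: ContextWindowSpec | None = None) -> FitResult:
    """Two-stage fit on the space-time-intensity (bright+dark) design: first a
    single CF shared by all RF indices, then two CFs (bright half, dark half)
    initialized from the shared solution."""
    if design_concat.ensemble.n_planes != 2:
        raise ValueError("design must use the concatenated bright+dark basis")
    window = window or ContextWindowSpec()
    stage1 = alternating_fit(design_concat, counts,
                             default_params(design_concat, 1, window), cfg)
    init2 = default_params(design_concat, 2, window)
    init2.w0 = stage1.params.w0
    init2.rf = stage1.params.rf.copy()
    for cf in init2.cfs:
        cf.weights = stage1.params.cfs[0].weights.copy()
    stage2 = alternating_fit(design_concat, counts, init2, cfg)
    stage2.chosen_C["stage1"] = stage1.chosen_C
    return stage2
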