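"""Model evaluation: histogram nonlinearities, bias-corrected single-spike
information, correlation scores, and the five-fold protocol.

Naive histogram information estimates carry a positive finite-sample bias
that grows with histogram resolution and dimensionality.  Two corrections
are provided: (1) the null-feature method, which measures the apparent
information of stimulus projections that carry none (STC eigenvectors with
eigenvalues at the stimulus variance) as a function of the number of
occupied bins, and subtracts the interpolated bias; (2) quadratic
extrapolation (QE) of subsampled naive estimates to infinite data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .info import ScoreDistribution, score_distribution, single_spike_info

__all__ = [
    "NonlinearityHistogram",
    "InfoEstimate",
    "EvalReport",
    "estimate_nonlinearity",
    "predict_rate",
    "bias_corrected_info_null",
    "bias_corrected_info_qe",
    "correlation_score",
    "crossval_protocol",
    "normalized_scores",
    "fold_indices",
]

DEFAULT_RESOLUTIONS = tuple(range(25, 36))


@dataclass
class NonlinearityHistogram:
    """Binned Bayes-rule nonlinearity f(z) = P(spike) P(z|spike) / P(z)."""

    bin_edges: list
    f: np.ndarray
    p_spike: float
    bins_per_dim: int = 20


@dataclass
class InfoEstimate:
    """Naive, bias and corrected information per histogram resolution; the
    headline ``value`` is the mean corrected estimate across resolutions."""

    resolutions: np.ndarray
    naive: np.ndarray
    bias: np.ndarray
    corrected: np.ndarray
    value: float
    method: str = "null"


@dataclass
class EvalReport:
    model: str
    folds: pd.DataFrame          # columns: fold, I_train, I_test, r_train, r_test
    mean: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = ["I_train", "I_test", "r_train", "r_test"]
        for c in cols:
            v = self.folds[c].to_numpy(float)
            v = v[np.isfinite(v)]
            self.mean[c] = float(v.mean()) if v.size else np.nan
            self.se[c] = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan


def estimate_nonlinearity(z_train, counts_train, bins: int = 20) -> NonlinearityHistogram:
    """Per-bin spike probability via Bayes' rule with P(spike) equal to the
    mean per-frame rate.  Bins never visited in training inherit the global
    mean rate."""
    counts_train = np.asarray(counts_train, float)
    if counts_train.sum() <= 0:
        raise ValueError("cannot estimate a nonlinearity with zero spikes")
    dist = score_distribution(z_train, counts_train, bins)
    occ = dist.p_z > 0
    f = np.full(dist.p_z.shape, dist.p_spike)
    f[occ] = dist.p_spike * dist.p_z_spike[occ] / dist.p_z[occ]
    return NonlinearityHistogram(bin_edges=dist.bin_edges, f=f,
                                 p_spike=dist.p_spike, bins_per_dim=bins)


def predict_rate(z, nl: NonlinearityHistogram) -> np.ndarray:
    """Look up f(z) for test scores; out-of-range scores clamp to edge bins."""
    z2 = np.asarray(z, float)
    if z2.ndim == 1:
        z2 = z2[:, None]
    if z2.shape[1] != len(nl.bin_edges):
        raise ValueError("score dimensionality does not match the nonlinearity")
    idx = []
    for d, e in enumerate(nl.bin_edges):
        i = np.digitize(z2[:, d], e) - 1
        idx.append(np.clip(i, 0, len(e) - 2))
    return nl.f[tuple(idx)]


# --------------------------------------------------------------------------
# Bias-corrected information

def _effective_bins(dist: ScoreDistribution) -> float:
    return 0.5 * (np.count_nonzero(dist.p_z) + np.count_nonzero(dist.p_z_spike))


def _bias_curve(null_scores, counts, sample_resolutions) -> tuple[np.ndarray, np.ndarray]:
    """Sample (effective bins -> apparent information) from null projections."""
    pts = []
    for ns in null_scores:
        for r in sample_resolutions:
            d = score_distribution(ns, counts, int(r))
            pts.append((_effective_bins(d), single_spike_info(d)))
    pts.sort()
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    # average duplicated abscissae so np.interp sees a function
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.bincount(inv, weights=ys) / np.bincount(inv)
    return ux, uy


def bias_corrected_info_null(z, counts, null_scores: list,
                             resolutions=DEFAULT_RESOLUTIONS,
                             bias_resolutions=None) -> InfoEstimate:
    """Null-feature bias correction.

    For each evaluation resolution: compute the naive information of ``z``,
    read the expected bias off the null-feature curve at the observed number
    of occupied bins, and subtract.  The final value is the mean corrected
    estimate over the (default 25-35 bins/dim) resolutions.
    """
    if len(null_scores) < 3:
        warnings.warn("fewer than 3 null features; the bias estimate is noisy")
    if bias_resolutions is None:
        bias_resolutions = np.unique(
            np.concatenate([np.linspace(5, 50, 10).astype(int),
                            np.asarray(resolutions, int)])
        )
    bx, by = _bias_curve(null_scores, counts, bias_resolutions)
    res = np.asarray(list(resolutions), int)
    naive = np.zeros(len(res))
    bias = np.zeros(len(res))
    for i, r in enumerate(res):
        d = score_distribution(z, counts, int(r))
        naive[i] = single_spike_info(d)
        bias[i] = float(np.interp(_effective_bins(d), bx, by))
    corrected = naive - bias
    return InfoEstimate(res, naive, bias, corrected, float(corrected.mean()),
                        method="null")


def bias_corrected_info_qe(z, counts, fractions=(1.0, 0.9, 0.8, 0.7, 0.6, 0.5),
                           n_repeats: int = 10, seed: int = 0,
                           resolutions=DEFAULT_RESOLUTIONS) -> InfoEstimate:
    """Quadratic-extrapolation correction: fit naive I against 1/N over random
    subsamples and keep the 1/N -> 0 intercept, per resolution."""
    fractions = sorted(set(float(f) for f in fractions))
    if len(fractions) < 3:
        raise ValueError("need at least 3 distinct fractions for a quadratic fit")
    z2 = np.asarray(z, float)
    counts = np.asarray(counts, float)
    n = len(counts)
    rng = np.random.default_rng(seed)
    res = np.asarray(list(resolutions), int)
    naive = np.zeros(len(res))
    corrected = np.zeros(len(res))
    for i, r in enumerate(res):
        inv_n, ivals = [], []
        for frac in fractions:
            m = max(int(round(frac * n)), 10)
            reps = 1 if frac >= 1.0 else n_repeats
            acc = []
            for _ in range(reps):
                idx = (np.arange(n) if frac >= 1.0
                       else rng.choice(n, size=m, replace=False))
                if counts[idx].sum() <= 0:
                    continue
                d = score_distribution(z2[idx], counts[idx], int(r))
                acc.append(single_spike_info(d))
            if acc:
                inv_n.append(1.0 / m)
                ivals.append(float(np.mean(acc)))
        coef = np.polyfit(inv_n, ivals, 2)
        naive[i] = ivals[inv_n.index(min(inv_n))]
        corrected[i] = coef[-1]
    bias = naive - corrected
    return InfoEstimate(res, naive, bias, corrected, float(corrected.mean()),
                        method="qe")


def correlation_score(predicted, observed) -> float:
    """Pearson correlation between predicted and observed counts; NaN when
    either side is constant."""
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if len(p) != len(o):
        raise ValueError("length mismatch")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        return float("nan")
    return float(sps.pearsonr(p, o)[0])


# --------------------------------------------------------------------------
# Five-fold protocol

def fold_indices(n_samples: int, n_folds: int = 5,
                 train_fraction: float = 0.8):
    """Contiguous temporal folds.  For each held-out test block, the remaining
    samples are split (in temporal order) into training and validation.

    For 1,000 usable samples with 5 folds: 200 test, 640 train, 160 validation.
    """
    bounds = np.linspace(0, n_samples, n_folds + 1).astype(int)
    for f in range(n_folds):
        test = np.arange(bounds[f], bounds[f + 1])
        rest = np.concatenate([np.arange(0, bounds[f]),
                               np.arange(bounds[f + 1], n_samples)])
        n_train = int(round(train_fraction * len(rest)))
        yield test, rest[:n_train], rest[n_train:]


def crossval_protocol(design, counts, model_spec, seed: int = 0,
                      n_folds: int = 5, nl_bins: int = 20,
                      resolutions=DEFAULT_RESOLUTIONS,
                      n_null: int = 10) -> EvalReport:
    """Run the five-fold training/validation/testing protocol for one model.

    ``model_spec`` must provide ``fit(X_or_design, counts, idx_train, idx_val)``
    returning a fitted object with ``scores(idx)`` (similarity scores for a
    sample subset) and a ``name``.  Information is bias-corrected with null
    features drawn from the training fold's STC analysis.
    """
    from .subspace import null_filters, spike_triggered_stats

    counts = np.asarray(counts)
    n = design.n_samples if hasattr(design, "n_samples") else len(counts)
    rows = []
    for fold, (test, train, val) in enumerate(fold_indices(n, n_folds)):
        try:
            fitted = model_spec.fit(design, counts, train, val)
            z_train = fitted.scores(train)
            z_test = fitted.scores(test)
            ndim = 1 if np.ndim(z_train) == 1 else np.shape(z_train)[1]
            X = design.X if hasattr(design, "X") else np.asarray(design)
            st = spike_triggered_stats(X[train], counts[train])
            nulls = null_filters(st, n_null if ndim == 1 else 2 * n_null)
            def null_scores(idx):
                P = X[idx] @ nulls.filters
                if ndim == 1:
                    return [P[:, i] for i in range(P.shape[1])]
                return [P[:, 2 * i : 2 * i + 2] for i in range(P.shape[1] // 2)]
            I_tr = bias_corrected_info_null(z_train, counts[train],
                                            null_scores(train), resolutions).value
            I_te = bias_corrected_info_null(z_test, counts[test],
                                            null_scores(test), resolutions).value
            nl = estimate_nonlinearity(z_train, counts[train], nl_bins)
            r_tr = correlation_score(predict_rate(z_train, nl), counts[train])
            r_te = correlation_score(predict_rate(z_test, nl), counts[test])
            rows.append((fold, I_tr, I_te, r_tr, r_te))
        except Exception as exc:  # noqa: BLE001 - a fold may fail; report the rest
            warnings.warn(f"fold {fold} failed: {exc}")
            rows.append((fold, np.nan, np.nan, np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["fold", "I_train", "I_test",
                                     "r_train", "r_test"])
    return EvalReport(model=getattr(model_spec, "name", "model"), folds=df)


def normalized_scores(reports: dict) -> pd.DataFrame:
    """Divide each model's mean test information and correlation by the best
    value across models (the winning model scores exactly 1)."""
    if len(reports) < 2:
        raise ValueError("normalization needs at least two models")
    names = list(reports)
    I = np.array([reports[m].mean["I_test"] for m in names])
    r = np.array([reports[m].mean["r_test"] for m in names])
    Imax, rmax = np.nanmax(I), np.nanmax(r)
    if not (Imax > 0):
        warnings.warn("nonpositive best information; normalization undefined")
    return pd.DataFrame({
        "model": names,
        "I_test": I, "r_test": r,
        "I_norm": I / Imax if Imax > 0 else np.full_like(I, np.nan),
        "r_norm": r / rmax if rmax > 0 else np.full_like(r, np.nan),
    }).set_index("model")
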