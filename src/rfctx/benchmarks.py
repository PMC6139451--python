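"""Reference simulation benchmarks: context model vs two-filter LN model on
the feedforward complex-cell networks.

These are the package's headline experiments.  Each benchmark simulates a
network, splits the resulting stimulus-response data into training (64%),
validation (16%) and held-out testing (20%) blocks, fits

* a single-CF context model by the alternating algorithm (linear subproblem
  family, l2 regularization, final cross-validated C), and
* a two-filter LN model (spike-triggered initialization from the STA and the
  leading STC deviation eigenvector, refined by gradient ascent on
  single-spike information with validation-based early stopping),

and reports the bias-corrected single-spike information of each model's
similarity scores on the held-out block (null-feature correction, mean over
25-35 bins per dimension).
"""

from __future__ import annotations

import numpy as np

from .context import (
    SolverConfig,
    alternating_fit,
    default_params,
    flip_and_restart,
    similarity_scores,
)
from .evaluation import bias_corrected_info_null
from .info import MIDConfig, mid_ascent
from .simulate import (
    DepressingSynapse,
    LIFParams,
    NetworkConfig,
    simulate_complex_network,
)
from .stimulus import StimulusEnsemble, apply_basis, build_lagged_design, subset_design
from .subspace import FilterBank, null_filters, spike_triggered_stats, stc_filters

__all__ = [
    "depressing_network_config",
    "simplified_network_config",
    "spike_triggered_two_filter_init",
    "fit_context_scores",
    "fit_two_filter_scores",
    "network_benchmark",
]

N_LAGS = 16


def depressing_network_config(n_frames: int = 50_000, seed: int = 0) -> NetworkConfig:
    """Nine input cells, depressing synapses (u=0.9, tau_rec=200 ms): the
    declared simulator defaults."""
    return NetworkConfig(n_inputs=9, depression=True, n_frames=n_frames,
                         seed=seed)


def simplified_network_config(n_frames: int = 50_000, seed: int = 0) -> NetworkConfig:
    """Two input cells (bank positions 4 and 6), no synaptic depression.

    The relay synapses do not deplete, so each input spike reaches the output
    at full weight; the drive gain is set so the output stays in a sparse,
    reliably stimulus-locked regime.
    """
    return NetworkConfig(n_inputs=2, positions=[4, 6], depression=False,
                         n_frames=n_frames, seed=seed, lif=LIFParams(gain=0.7),
                         synapse=DepressingSynapse(weight=1.5))


def _splits(n: int):
    tr = np.arange(0, int(0.64 * n))
    va = np.arange(int(0.64 * n), int(0.80 * n))
    te = np.arange(int(0.80 * n), n)
    return tr, va, te


def spike_triggered_two_filter_init(X: np.ndarray, counts: np.ndarray
                                    ) -> FilterBank:
    """Two-filter starting point from spike-triggered statistics: the
    (centered) STA plus the leading STC deviation eigenvector orthogonalized
    against it."""
    st = spike_triggered_stats(X, counts)
    sta = st.sta - X.mean(axis=0)
    b1 = sta / np.linalg.norm(sta)
    cand = stc_filters(st, 3)
    for i in range(cand.m):
        v = cand.filters[:, i] - (cand.filters[:, i] @ b1) * b1
        if np.linalg.norm(v) > 0.3:
            break
    b2 = v / np.linalg.norm(v)
    return FilterBank(np.column_stack([b1, b2]), kind="stc")


def fit_context_scores(design, counts, tr, te, seed: int = 0):
    """Alternating-fit single-CF context model; held-out similarity scores."""
    cfg = SolverConfig(family="linear", seed=seed)
    dtr = subset_design(design, tr)
    res = alternating_fit(dtr, counts[tr], default_params(dtr, 1), cfg)
    res = flip_and_restart(res, dtr, counts[tr], cfg)
    return similarity_scores(res.params, subset_design(design, te)), res


def fit_two_filter_scores(design, counts, tr, va, te, seed: int = 0,
                          mid_steps: int = 200):
    """STA/STC-initialized two-filter LN model with MID refinement; held-out
    two-dimensional similarity scores."""
    bank = spike_triggered_two_filter_init(design.X[tr], counts[tr])
    bank = mid_ascent(bank, design.X[tr], counts[tr], design.X[va],
                      counts[va], MIDConfig(max_steps=mid_steps, seed=seed))
    return design.X[te] @ bank.filters, bank


def network_benchmark(cfg: NetworkConfig, seed: int = 0, n_null: int = 10
                      ) -> dict:
    """Run one network end to end; bias-corrected held-out information of the
    context model and of the two-filter LN model, in bits per spike."""
    ens = simulate_complex_network(cfg)
    enc = StimulusEnsemble(apply_basis(ens.frames, "bright"), ens.counts,
                           ens.frame_rate)
    design = build_lagged_design(enc, N_LAGS)
    counts = design.counts
    tr, va, te = _splits(design.n_samples)

    z_ctx, ctx_fit = fit_context_scores(design, counts, tr, te, seed)
    z_ln, bank = fit_two_filter_scores(design, counts, tr, va, te, seed)

    st = spike_triggered_stats(design.X[tr], counts[tr])
    nulls = null_filters(st, 2 * n_null)
    P = design.X[te] @ nulls.filters
    null_1d = [P[:, i] for i in range(n_null)]
    null_2d = [P[:, 2 * i : 2 * i + 2] for i in range(n_null)]

    I_ctx = bias_corrected_info_null(z_ctx, counts[te], null_1d).value
    I_ln = bias_corrected_info_null(z_ln, counts[te], null_2d).value
    return {
        "context_info": float(I_ctx),
        "ln2_info": float(I_ln),
        "n_frames": int(ens.n_frames),
        "n_test": int(len(te)),
        "mean_count": float(counts.mean()),
        "context_fit": ctx_fit,
        "ln_bank": bank,
    }
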