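"""Synthetic stimulus-response generators.

The centerpiece is a small feedforward network realizing the hierarchical
description of a cortical complex cell: nine leaky integrate-and-fire (LIF)
input cells with identical but spatially shifted linear receptive fields,
driving one LIF output cell through excitatory depressing synapses
(release fraction u = 0.9, resource recovery tau_rec = 200 ms).  A simplified
variant uses two input cells (bank positions 4 and 6) and no depression, so
that the output is genuinely confined to a two-dimensional stimulus subspace.

Generic LN-Poisson and context-model-Poisson generators are also provided for
parameter-recovery testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .stimulus import StimulusEnsemble

__all__ = [
    "LIFParams",
    "DepressingSynapse",
    "NetworkConfig",
    "make_bar_stimulus",
    "depressing_update",
    "rf_template",
    "input_rf_bank",
    "simulate_complex_network",
    "generate_ln_poisson",
    "generate_context_poisson",
    "cf_tail_energy",
]

try:  # optional compiled inner loop; the numpy path gives identical results
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap


@dataclass
class LIFParams:
    """Leaky integrate-and-fire constants (potentials in threshold units)."""

    tau_m: float = 20.0      # membrane time constant, ms
    v_rest: float = 0.0
    v_reset: float = 0.0
    v_thresh: float = 1.0
    t_ref: float = 2.0       # refractory period, ms
    dt: float = 1.0          # integration step, ms
    gain: float = 1.0        # input drive -> current scaling

    def __post_init__(self) -> None:
        if self.v_thresh <= self.v_reset:
            raise ValueError("threshold must exceed the reset potential")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class DepressingSynapse:
    """Tsodyks-Markram style depressing synapse.

    Between spikes the resource recovers as dR/dt = (1 - R)/tau_rec; a
    presynaptic spike releases ``weight * u * R`` and depletes R <- R(1 - u).
    """

    u: float = 0.9
    tau_rec: float = 200.0   # ms
    weight: float = 1.0
    R: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.u <= 1.0):
            raise ValueError("u must lie in (0, 1]")
        if not (0.0 <= self.R <= 1.0):
            raise ValueError("R must lie in [0, 1]")


def depressing_update(syn: DepressingSynapse, dt: float,
                      presynaptic_spike: bool) -> tuple[DepressingSynapse, float]:
    """Advance the synapse by ``dt`` ms and release on a spike.

    Recovery uses the exact exponential solution of dR/dt = (1 - R)/tau_rec,
    so periodic drive settles on the closed-form steady state
    R* = (1 - e^(-dt_isi/tau)) / (1 - (1 - u) e^(-dt_isi/tau)).
    """
    R = 1.0 - (1.0 - syn.R) * np.exp(-dt / syn.tau_rec)
    amplitude = 0.0
    if presynaptic_spike:
        amplitude = syn.weight * syn.u * R
        R = R * (1.0 - syn.u)
    return replace(syn, R=R), amplitude


def make_bar_stimulus(n_bars: int = 16, n_frames: int = 50_000,
                      frame_rate: float = 60.0, seed: int = 0) -> StimulusEnsemble:
    """I.i.d. equiprobable binary bars per frame, coded raw as -1/+1."""
    if n_bars < 1 or n_frames < 1:
        raise ValueError("need at least one bar and one frame")
    rng = np.random.default_rng(seed)
    frames = rng.integers(0, 2, size=(n_bars, n_frames)).astype(np.int8) * 2 - 1
    return StimulusEnsemble(frames=frames, frame_rate=frame_rate)


# --------------------------------------------------------------------------
# Input receptive-field bank

def rf_template(n_space: int = 3, n_time: int = 10) -> np.ndarray:
    """Gabor-like space-time template shared by all input cells:
    center-surround along bars, biphasic in time (columns oldest -> newest)."""
    sp = np.full(n_space, -0.5)
    sp[n_space // 2] = 1.0
    t = np.linspace(1.0, 0.0, n_time)  # 1 = oldest, 0 = most recent
    # damped oscillation peaking just before the present, negative rebound earlier
    tp = np.exp(-((t - 0.15) ** 2) / 0.02) - 0.55 * np.exp(-((t - 0.45) ** 2) / 0.03)
    return np.outer(sp, tp)


def input_rf_bank(n_bars: int, n_inputs: int, template: np.ndarray | None = None,
                  positions: list | None = None) -> tuple[np.ndarray, list]:
    """Stack of identical templates shifted by one bar per input.

    Returns (bank, positions) with ``bank[i]`` an (n_bars, n_time) field.
    ``positions`` are 1-based bank indices; default places n_inputs
    consecutive shifts centered on the bar array.
    """
    template = rf_template() if template is None else np.asarray(template, float)
    ht = template.shape[0]
    if positions is None:
        positions = list(range(1, n_inputs + 1))
    # one-bar shifts, centered: position p (1-based, relative to a bank of
    # n_inputs slots) puts the template at row start_row + (p - min(positions))
    start_row = (n_bars - ((max(positions) - min(positions)) + ht)) // 2
    bank = np.zeros((len(positions), n_bars, template.shape[1]))
    used = []
    for i, p in enumerate(positions):
        r = start_row + (p - min(positions))
        if r < 0 or r + ht > n_bars:
            raise ValueError("RF bank does not fit inside the bar array")
        bank[i, r : r + ht] = template
        used.append(p)
    return bank, used


@dataclass
class NetworkConfig:
    """Configuration of the feedforward complex-cell network."""

    n_inputs: int = 9
    positions: list | None = None      # 1-based bank positions (default 1..n)
    depression: bool = True
    n_frames: int = 50_000
    n_bars: int = 16
    frame_rate: float = 60.0
    seed: int = 0
    lif: LIFParams = field(default_factory=lambda: LIFParams(gain=2.2))
    synapse: DepressingSynapse = field(default_factory=lambda:
                                       DepressingSynapse(u=0.9, tau_rec=200.0,
                                                         weight=0.7))
    template: np.ndarray | None = None


@_njit(cache=True)
def _lif_network_loop(drives, frame_of_step, n_steps, tau_m, v_rest, v_reset,
                      v_thresh, ref_steps, dt, gain, weights, u, tau_rec,
                      depress, out_counts, in_counts):  # pragma: no cover
    n_in = drives.shape[0]
    v_in = np.full(n_in, v_rest)
    ref_in = np.zeros(n_in, np.int64)
    R = np.ones(n_in)
    rec = np.exp(-dt / tau_rec)
    v_out = v_rest
    ref_out = 0
    leak = dt / tau_m
    for s in range(n_steps):
        f = frame_of_step[s]
        kick = 0.0
        for i in range(n_in):
            R[i] = 1.0 - (1.0 - R[i]) * rec
            if ref_in[i] > 0:
                ref_in[i] -= 1
                continue
            v_in[i] += leak * (-(v_in[i] - v_rest) + gain * drives[i, f])
            if v_in[i] >= v_thresh:
                v_in[i] = v_reset
                ref_in[i] = ref_steps
                in_counts[i] += 1
                if depress:
                    kick += weights[i] * u * R[i]
                    R[i] = R[i] * (1.0 - u)
                else:
                    kick += weights[i]
        if ref_out > 0:
            ref_out -= 1
            v_out += kick
            continue
        v_out += leak * (-(v_out - v_rest)) + kick
        if v_out >= v_thresh:
            v_out = v_reset
            ref_out = ref_steps
            out_counts[f] += 1
    return out_counts


def _drives(frames: np.ndarray, bank: np.ndarray) -> np.ndarray:
    """Per-frame linear drive of each input cell (causal, zero history pad)."""
    n_in = bank.shape[0]
    n_time = bank.shape[2]
    padded = np.pad(frames.astype(float), ((0, 0), (n_time - 1, 0)))
    out = np.zeros((n_in, frames.shape[1]))
    for i in range(n_in):
        # full-height valid 2-D correlation = per-frame dot product with the RF
        out[i] = signal.fftconvolve(padded, bank[i, ::-1, ::-1],
                                    mode="valid")[0]
    return out


def simulate_complex_network(cfg: NetworkConfig,
                             stimulus: StimulusEnsemble | None = None,
                             return_diagnostics: bool = False):
    """Run the network and return the stimulus with per-frame output counts.

    With ``return_diagnostics`` also returns a dict holding the input cells'
    firing rates and the output rate (spikes/s), useful when calibrating the
    drive gain and synaptic weight.
    """
    if stimulus is None:
        stimulus = make_bar_stimulus(cfg.n_bars, cfg.n_frames, cfg.frame_rate,
                                     cfg.seed)
    frames = stimulus.frames
    bank, _ = input_rf_bank(stimulus.n_bars, cfg.n_inputs, cfg.template,
                            cfg.positions)
    drives = _drives(frames, bank)

    lif = cfg.lif
    n_frames = stimulus.n_frames
    total_ms = n_frames * 1000.0 / stimulus.frame_rate
    n_steps = int(np.floor(total_ms / lif.dt))
    step_t = np.arange(n_steps) * lif.dt
    frame_of_step = np.minimum((step_t * stimulus.frame_rate / 1000.0).astype(np.int64),
                               n_frames - 1)
    ref_steps = int(round(lif.t_ref / lif.dt))
    weights = np.full(cfg.n_inputs, cfg.synapse.weight, float)
    counts = np.zeros(n_frames, np.int64)
    in_counts = np.zeros(cfg.n_inputs, np.int64)
    _lif_network_loop(
        np.ascontiguousarray(drives), frame_of_step, n_steps,
        lif.tau_m, lif.v_rest, lif.v_reset, lif.v_thresh, ref_steps, lif.dt,
        lif.gain, weights, cfg.synapse.u, cfg.synapse.tau_rec,
        cfg.depression, counts, in_counts,
    )
    if counts.sum() == 0:
        warnings.warn(
            "silent network: no output spikes "
            f"(input rates {in_counts * 1000.0 / total_ms} Hz, "
            f"gain={lif.gain}, weight={cfg.synapse.weight})"
        )
    out = stimulus.with_counts(counts)
    if return_diagnostics:
        diag = {"input_rates_hz": in_counts * 1000.0 / total_ms,
                "output_rate_hz": counts.sum() * 1000.0 / total_ms}
        return out, diag
    return out


# --------------------------------------------------------------------------
# Generic Poisson generators for parameter recovery

def _poisson_counts(rate: np.ndarray, rng) -> np.ndarray:
    if np.any(rate > 1e3):
        warnings.warn("rate overflow; clipping at 1000 spikes/frame")
        rate = np.clip(rate, 0.0, 1e3)
    return rng.poisson(np.clip(rate, 0.0, None))


def generate_ln_poisson(rf: np.ndarray, nonlinearity, ensemble: StimulusEnsemble,
                        seed: int = 0) -> StimulusEnsemble:
    """Poisson counts from a single-filter LN model; ``rf`` is an
    (n_bars, n_lags) grid, ``nonlinearity`` maps score to rate per frame."""
    from .stimulus import build_lagged_design

    rf = np.asarray(rf, float)
    design = build_lagged_design(ensemble, rf.shape[1])
    z = design.X @ rf.ravel()
    rng = np.random.default_rng(seed)
    counts = np.zeros(ensemble.n_frames, np.int64)
    counts[rf.shape[1] - 1 :] = _poisson_counts(nonlinearity(z), rng)
    return ensemble.with_counts(counts)


def generate_context_poisson(params, nonlinearity, ensemble: StimulusEnsemble,
                             seed: int = 0) -> StimulusEnsemble:
    """Poisson counts from a context model (rate = nonlinearity(z))."""
    from .context import similarity_scores
    from .stimulus import build_lagged_design

    n_lags = params.rf.shape[1]
    design = build_lagged_design(ensemble, n_lags)
    z = similarity_scores(params, design)
    rng = np.random.default_rng(seed)
    counts = np.zeros(ensemble.n_frames, np.int64)
    counts[n_lags - 1 :] = _poisson_counts(nonlinearity(z), rng)
    return ensemble.with_counts(counts)


def cf_tail_energy(cf_weights: np.ndarray) -> float:
    """Opposite-sign trailing-tail statistic of a fitted context field.

    Synaptic depression shows up in CFs as a long region of sign opposite to
    the excitatory subfield, trailing it in time (i.e. at the earliest lags of
    the window, which persist beyond the input template's own biphasic
    rebound).  The statistic locates the largest-magnitude cell in the recent
    (right) half of the window and returns the mean of
    ``-sign(peak) * weight`` over the earliest quarter of the lag columns in
    the same row, normalized by the peak magnitude: clearly positive values
    indicate a depression-like tail, values near zero its absence.
    """
    w = np.asarray(cf_weights, float)
    # the input-template subfield sits in the rightmost part of the window
    lead = w.shape[1] - max(w.shape[1] // 3, 1)
    r, c = np.unravel_index(np.argmax(np.abs(w[:, lead:])), w[:, lead:].shape)
    c += lead
    peak = w[r, c]
    if peak == 0.0:
        return 0.0
    n_tail = max(w.shape[1] // 4, 1)
    tail = w[r, :n_tail]
    return float(np.mean(-np.sign(peak) * tail) / abs(peak))
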