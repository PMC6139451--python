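"""Orchestration: named model specifications, the simulate -> fit ->
refine -> evaluate -> compare pipeline, and parameter accounting.

Model names follow the naming convention used throughout this package:
``LinReg``/``LogReg``/``PoiReg`` are traditional single-filter GLMs;
``*Ctx`` adds one context field; ``*Ctx2Int`` uses the bright+dark
space-time-intensity basis with two context fields; ``STC2``/``iSTAC2`` are
two-filter spike-triggered subspace models; ``MNE2``/``MNE4`` low-rank
quadratic models; ``MID2_<init>`` and ``MID_<ctx>`` are information-maximized
refinements of the named initializer.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import context as ctx
from . import subspace as sub
from .evaluation import EvalReport, crossval_protocol, normalized_scores
from .info import MIDConfig, mid_ascent
from .simulate import simulate_complex_network
from .stimulus import (
    ContextWindowSpec,
    StimulusEnsemble,
    apply_basis,
    build_lagged_design,
    load_ensemble_hdf5,
    subset_design,
)

__all__ = [
    "RunConfig",
    "model_spec",
    "parameter_count",
    "run_comparison",
]


# --------------------------------------------------------------------------
# Fitted-model adapters: each exposes .scores(sample_indices)

class _FittedGLM:
    def __init__(self, design, w, w0):
        self.design, self.w, self.w0 = design, w, w0

    def scores(self, idx):
        return self.w0 + self.design.X[idx] @ self.w


class _FittedContext:
    def __init__(self, design, params):
        self.design, self.params = design, params

    def scores(self, idx):
        return ctx.similarity_scores(self.params, subset_design(self.design, idx))


class _FittedBank:
    def __init__(self, design, bank, center=None, scale=None):
        self.design, self.bank = design, bank
        self.center, self.scale = center, scale

    def scores(self, idx):
        X = self.design.X[idx]
        if self.center is not None:
            X = (X - self.center) / self.scale
        return self.bank.scores(X)


class _FittedLowRank:
    def __init__(self, design, model):
        self.design, self.model = design, model

    def scores(self, idx):
        return sub.lowrank_scores(self.model, self.design.X[idx])


# --------------------------------------------------------------------------
# Model specifications

@dataclass
class GLMSpec:
    name: str
    family: str
    C: float = 0.1
    reg_kind: str = "l2"

    def fit(self, design, counts, train, val):
        X = design.X[train]
        y = np.asarray(counts, float)[train]
        Gam = np.eye(X.shape[1] + 1)
        Gam[-1, -1] = 0.0  # bias unpenalized
        A1 = np.hstack([X, np.ones((X.shape[0], 1))])
        w = ctx._solve_subproblem(A1, y, None, self.C, Gam, self.family, 1e-3)
        return _FittedGLM(design, w[:-1], float(w[-1]))

    def n_parameters(self, design):
        return design.X.shape[1]


@dataclass
class ContextSpec:
    name: str
    family: str
    n_cfs: int = 1
    reg_kind: str = "l2"
    window: ContextWindowSpec = field(default_factory=ContextWindowSpec)
    seed: int = 0
    final_cv: bool = True

    def fit(self, design, counts, train, val):
        cfg = ctx.SolverConfig(family=self.family, reg_kind=self.reg_kind,
                               seed=self.seed, final_cv=self.final_cv)
        dtr = subset_design(design, train)
        ytr = np.asarray(counts)[train]
        if self.n_cfs == 2:
            res = ctx.fit_double_cf_intensity(dtr, ytr, cfg, self.window)
        else:
            init = ctx.default_params(dtr, self.n_cfs, self.window)
            res = ctx.alternating_fit(dtr, ytr, init, cfg)
        res = ctx.flip_and_restart(res, dtr, ytr, cfg)
        return _FittedContext(design, res.params)

    def n_parameters(self, design):
        w = self.window
        return design.X.shape[1] + self.n_cfs * (w.size - 1)


@dataclass
class STCSpec:
    name: str
    n_filters: int = 2

    def fit(self, design, counts, train, val):
        st = sub.spike_triggered_stats(design.X[train],
                                       np.asarray(counts)[train])
        return _FittedBank(design, sub.stc_filters(st, self.n_filters))

    def n_parameters(self, design):
        return self.n_filters * design.X.shape[1]


@dataclass
class ISTACSpec:
    name: str
    n_filters: int = 2

    def fit(self, design, counts, train, val):
        X = design.X[train]
        center = X.mean(axis=0)
        scale = np.maximum(X.std(axis=0), 1e-12)
        Xw = (X - center) / scale
        st = sub.spike_triggered_stats(Xw, np.asarray(counts)[train])
        bank = sub.istac_fit(st, self.n_filters)
        return _FittedBank(design, bank, center, scale)

    def n_parameters(self, design):
        return self.n_filters * design.X.shape[1]


@dataclass
class MNESpec:
    name: str
    n_filters: int = 2
    C: float = 1.0
    refine: bool = True

    def fit(self, design, counts, train, val):
        y = np.asarray(counts)
        model = sub.mne_fit(design.X[train], y[train], self.C)
        model = sub.lowrank_select(model, self.n_filters, design.X[train],
                                   y[train])
        if self.refine and len(val):
            model = sub.refine_filters(model, design.X[train], y[train],
                                       [0.1, 1.0, 10.0], design.X[val], y[val])
        return _FittedLowRank(design, model)

    def n_parameters(self, design):
        return self.n_filters * design.X.shape[1]


@dataclass
class MIDSpec:
    """Information-maximization refinement of a named initializer."""

    name: str
    init_spec: object
    mid: MIDConfig = field(default_factory=MIDConfig)

    def fit(self, design, counts, train, val):
        fitted = self.init_spec.fit(design, counts, train, val)
        y = np.asarray(counts)
        dtr, dva = subset_design(design, train), subset_design(design, val)
        if isinstance(fitted, _FittedContext):
            model = mid_ascent(fitted.params, dtr, y[train], dva, y[val], self.mid)
            return _FittedContext(design, model)
        if isinstance(fitted, _FittedBank):
            model = mid_ascent(fitted.bank, dtr.X, y[train], dva.X, y[val],
                               self.mid)
            return _FittedBank(design, model, fitted.center, fitted.scale)
        raise TypeError("MID refinement supports filter banks and context models")

    def n_parameters(self, design):
        return self.init_spec.n_parameters(design)


_FAMILIES = {"Lin": "linear", "Log": "logistic", "Poi": "poisson"}


def model_spec(name: str, seed: int = 0):
    """Resolve a model name from the comparison roster into a specification."""
    if name.startswith("MID"):
        head, _, init = name.partition("_")
        if not init:
            raise ValueError(f"MID model {name!r} needs an initializer suffix")
        base = model_spec(init, seed)
        return MIDSpec(name=name, init_spec=base)
    for pref, family in _FAMILIES.items():
        if name == f"{pref}Reg":
            return GLMSpec(name=name, family=family)
        if name == f"{pref}RegCtx":
            return ContextSpec(name=name, family=family, n_cfs=1, seed=seed)
        if name == f"{pref}RegCtx2Int":
            return ContextSpec(name=name, family=family, n_cfs=2, seed=seed)
    if name.startswith("STC"):
        return STCSpec(name=name, n_filters=int(name[3:] or 2))
    if name.startswith("iSTAC"):
        return ISTACSpec(name=name, n_filters=int(name[5:] or 2))
    if name.startswith("MNE"):
        return MNESpec(name=name, n_filters=int(name[3:] or 2))
    raise ValueError(f"unknown model name {name!r}")


def parameter_count(spec, design) -> int:
    """Field/filter parameter count (bias terms excluded), for
    equal-complexity comparisons: a single-CF context model on a 16x16 window
    with a 9x9 CF counts 256 + 80 parameters, close to the 512 of a two-filter
    LN model only when the CF window is enlarged; the intensity double-CF
    model's 512 + 2*80 matches a four-filter LN model's 1024 in the same
    loose sense."""
    return int(spec.n_parameters(design))


# --------------------------------------------------------------------------
# Run configuration and comparison driver

@dataclass
class RunConfig:
    models: list
    data: str | None = None          # HDF5 path; None -> simulate
    network: str = "nine-depressing"
    n_frames: int = 50_000
    n_lags: int = 16
    basis: str = "bright"
    folds: int = 5
    seed: int = 0
    out_dir: str = "runs"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _load_or_simulate(cfg: RunConfig) -> StimulusEnsemble:
    from .benchmarks import depressing_network_config, simplified_network_config

    if cfg.data:
        return load_ensemble_hdf5(cfg.data)
    if cfg.network == "nine-depressing":
        net = depressing_network_config(cfg.n_frames, cfg.seed)
    elif cfg.network == "two-plain":
        net = simplified_network_config(cfg.n_frames, cfg.seed)
    else:
        raise ValueError(f"unknown network {cfg.network!r}")
    return simulate_complex_network(net)


def _prepared_design(ensemble: StimulusEnsemble, cfg: RunConfig):
    frames = apply_basis(ensemble.frames, cfg.basis)
    n_planes = 2 if cfg.basis in ("bright+dark", "concat") else 1
    enc = StimulusEnsemble(frames, ensemble.counts, ensemble.frame_rate,
                           n_planes=n_planes)
    return build_lagged_design(enc, cfg.n_lags)


def run_comparison(cfg: RunConfig) -> dict:
    """Five-fold evaluation of every model in the roster on shared folds.

    Returns a dict with per-model reports, the normalized score table, the
    winner, and a manifest of any failures; files are also written under
    ``cfg.out_dir`` (CSV per model, JSON summary).
    """
    if len(set(cfg.models)) != len(cfg.models):
        raise ValueError("model names must be unique")
    t0 = time.time()
    ensemble = _load_or_simulate(cfg)
    design = _prepared_design(ensemble, cfg)
    counts = design.counts
    reports: dict[str, EvalReport] = {}
    failures: dict[str, str] = {}
    log = []
    for name in cfg.models:
        t = time.time()
        try:
            spec = model_spec(name, seed=cfg.seed)
            reports[name] = crossval_protocol(design, counts, spec,
                                              seed=cfg.seed, n_folds=cfg.folds)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"model {name} failed: {exc}")
            failures[name] = str(exc)
        log.append({"stage": name, "seconds": round(time.time() - t, 2)})

    out = {"reports": reports, "failures": failures, "log": log}
    if len(reports) >= 2:
        table = normalized_scores(reports)
        out["normalized"] = table
        out["winner"] = str(table["I_test"].idxmax())
    cfg_hash = hashlib.sha256(
        json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    out["config_hash"] = cfg_hash

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, rep in reports.items():
        rep.folds.assign(model=name).to_csv(out_dir / f"{name}.csv", index=False)
    summary = {
        "config_hash": cfg_hash,
        "seconds": round(time.time() - t0, 2),
        "winner": out.get("winner"),
        "failures": failures,
        "mean_I_test": {m: reports[m].mean["I_test"] for m in reports},
        "mean_r_test": {m: reports[m].mean["r_test"] for m in reports},
        "log": log,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return out
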