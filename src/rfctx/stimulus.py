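"""Bar-stimulus containers, lagged designs, and local context windows.

The experimental geometry this package targets is a one-dimensional array of
binary bars refreshed at a fixed frame rate (e.g. 16 bars at 60 Hz).  A frame
matrix holds one column per frame; the model input for frame *t* is the
space-time window covering the most recent ``n_lags`` frames, flattened into a
row of the lagged design matrix.

Flattening convention (used everywhere in this package): windows are flattened
bar-major, i.e. index ``j = bar * n_lags + lag`` with ``lag = 0`` the oldest
frame and ``lag = n_lags - 1`` the most recent (rightmost) frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusEnsemble",
    "LaggedDesign",
    "ContextWindowSpec",
    "build_lagged_design",
    "subset_design",
    "extract_context_vector",
    "context_modulation_map",
    "apply_basis",
    "load_ensemble_hdf5",
    "save_ensemble_hdf5",
    "load_ensemble_csv",
]


@dataclass
class StimulusEnsemble:
    """A bar stimulus (bars x frames) with per-frame spike counts.

    ``frames`` entries are either raw ``{-1, +1}`` bar intensities or ``{0, 1}``
    after a dark/bright basis has been applied.  ``n_planes`` is 2 when the
    concatenated bright+dark (space-time-intensity) basis doubles the bar
    dimension; local context windows never cross plane boundaries.
    """

    frames: np.ndarray
    counts: np.ndarray | None = None
    frame_rate: float = 60.0
    n_planes: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_bars, n_frames) matrix")
        vals = np.unique(self.frames)
        if not (set(vals) <= {-1, 0, 1}):
            raise ValueError("frames entries must come from {-1,+1} or {0,1}")
        if self.counts is None:
            self.counts = np.zeros(self.frames.shape[1], dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.frames.shape[1],):
            raise ValueError("counts length must equal n_frames")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.frames.shape[0] % self.n_planes:
            raise ValueError("n_bars must be divisible by n_planes")

    @property
    def n_bars(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    def with_counts(self, counts: np.ndarray) -> "StimulusEnsemble":
        return StimulusEnsemble(self.frames, counts, self.frame_rate, self.n_planes)


@dataclass
class LaggedDesign:
    """Lagged design matrix: one flattened bars x lags window per usable frame.

    Row ``i`` is the window ending at frame ``i + n_lags - 1``; the paired spike
    count is the count of that last frame.  Frames with incomplete history are
    dropped, so ``n_samples = n_frames - n_lags + 1``.  A reference to the
    source ensemble is kept because context windows may reach outside a
    sample's own bars x lags window.
    """

    X: np.ndarray
    n_bars: int
    n_lags: int
    counts: np.ndarray
    ensemble: StimulusEnsemble
    lag_convention: str = "bar-major, most recent frame in the last lag column"
    sample_indices: np.ndarray | None = None  # subset view into the full design

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def window(self, i: int) -> np.ndarray:
        """Sample ``i`` reshaped back to its (n_bars, n_lags) window."""
        return self.X[i].reshape(self.n_bars, self.n_lags)


@dataclass
class ContextWindowSpec:
    """Geometry of the local context window attached to each stimulus element.

    ``origin`` is the (row, col) position inside the window that is aligned
    with the stimulus element itself; the context-field coefficient there is
    structurally fixed to zero so the field carries interaction terms only.
    Cells falling outside the stimulus take ``pad_value``.
    """

    height: int = 9
    width: int = 9
    origin: tuple[int, int] | None = None
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.origin is None:
            # Centered spatially; temporally three elements in from the right
            # edge so that the two frames following the origin can still
            # modulate the response.
            self.origin = (self.height // 2, max(self.width - 3, 0))
        r, c = self.origin
        if not (0 <= r < self.height and 0 <= c < self.width):
            raise ValueError("origin must lie inside the window")

    @property
    def size(self) -> int:
        return self.height * self.width

    @property
    def origin_flat(self) -> int:
        r, c = self.origin
        return r * self.width + c


def build_lagged_design(ensemble: StimulusEnsemble, n_lags: int) -> LaggedDesign:
    """Slide a bars x ``n_lags`` window over the frame matrix.

    Raises a dimension error when ``n_lags`` exceeds the number of frames.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if n_lags > ensemble.n_frames:
        raise ValueError(
            f"n_lags={n_lags} exceeds the {ensemble.n_frames} available frames"
        )
    X = _lagged_matrix(ensemble.frames, n_lags)
    counts = np.asarray(ensemble.counts)[n_lags - 1 :]
    return LaggedDesign(X=X, n_bars=ensemble.n_bars, n_lags=n_lags,
                        counts=counts, ensemble=ensemble)


def subset_design(design: LaggedDesign, idx) -> LaggedDesign:
    """Restrict a full design to a subset of samples (e.g. a training fold).

    The frame matrix is kept whole so that context windows, which may reach
    outside a sample's own bars x lags window, stay well defined; operations
    that derive per-sample rows from the frames honour ``sample_indices``.
    """
    if design.sample_indices is not None:
        raise ValueError("can only subset the full design")
    idx = np.asarray(idx, int)
    return LaggedDesign(X=design.X[idx], n_bars=design.n_bars,
                        n_lags=design.n_lags, counts=design.counts[idx],
                        ensemble=design.ensemble, sample_indices=idx)


def _lagged_matrix(frames: np.ndarray, n_lags: int) -> np.ndarray:
    """(n_frames - n_lags + 1, n_bars*n_lags) lagged matrix, bar-major order."""
    win = np.lib.stride_tricks.sliding_window_view(frames, n_lags, axis=1)
    # win: (n_bars, n_samples, n_lags) -> (n_samples, n_bars, n_lags)
    win = win.transpose(1, 0, 2)
    return win.reshape(win.shape[0], -1).astype(np.float64)


def extract_context_vector(
    ensemble: StimulusEnsemble,
    sample_index: int,
    bar: int,
    lag: int,
    window: ContextWindowSpec,
    n_lags: int,
) -> np.ndarray:
    """Context patch around one element of one sample's window.

    The returned (height, width) patch is positioned so that the window origin
    coincides with stimulus element ``(bar, frame)`` where
    ``frame = sample_index + lag``.  The origin cell's value is reported but
    its context-field coefficient is fixed to zero, so it never contributes to
    a context dot product.  Context windows are confined to the plane of the
    addressed bar (relevant for the intensity-concatenated basis).
    """
    if not (0 <= sample_index <= ensemble.n_frames - n_lags):
        raise IndexError("sample_index out of range")
    if not (0 <= bar < ensemble.n_bars and 0 <= lag < n_lags):
        raise IndexError("element index outside the sample window")
    frame = sample_index + lag
    rows_per_plane = ensemble.n_bars // ensemble.n_planes
    plane = bar // rows_per_plane
    lo = plane * rows_per_plane
    r0, c0 = window.origin
    patch = np.full((window.height, window.width), window.pad_value, float)
    for p in range(window.height):
        b = bar - r0 + p
        if not (lo <= b < lo + rows_per_plane):
            continue
        for q in range(window.width):
            f = frame - c0 + q
            if 0 <= f < ensemble.n_frames:
                patch[p, q] = ensemble.frames[b, f]
    return patch


def context_modulation_map(
    frames: np.ndarray,
    cf_weights: np.ndarray,
    window: ContextWindowSpec,
    n_planes: int = 1,
) -> np.ndarray:
    """Cross-correlate the stimulus with a context field.

    Returns ``Ctx`` with ``Ctx[b, f] = sum_{p,q} w[p,q] * S[b - r0 + p, f - c0 + q]``
    (zero padding outside the stimulus, correlation confined to each plane).
    This is the map whose entries are the context dot products ``x~_ij . w_cf``
    for every stimulus element.
    """
    cf = np.asarray(cf_weights, float).reshape(window.height, window.width)
    r0, c0 = window.origin
    nb, nf = frames.shape
    rows = nb // n_planes
    out = np.zeros((nb, nf))
    for pl in range(n_planes):
        S = frames[pl * rows : (pl + 1) * rows]
        pad = np.pad(S.astype(float), ((window.height, window.height),
                                       (window.width, window.width)))
        acc = np.zeros((rows, nf))
        for p in range(window.height):
            for q in range(window.width):
                w = cf[p, q]
                if w == 0.0:
                    continue
                rs = window.height + p - r0
                cs = window.width + q - c0
                acc += w * pad[rs : rs + rows, cs : cs + nf]
        out[pl * rows : (pl + 1) * rows] = acc
    return out


def apply_basis(frames_raw: np.ndarray, basis: str) -> np.ndarray:
    """Map a raw {-1,+1} frame matrix through an intensity basis.

    ``bright`` codes a bright bar (+1) as 1 and a dark bar as 0; ``dark``
    reverses this; ``bright+dark`` stacks the dark encoding under the bright
    one, doubling the bar dimension into a space-time-intensity input; ``raw``
    passes through.
    """
    frames_raw = np.asarray(frames_raw)
    if not set(np.unique(frames_raw)) <= {-1, 1}:
        raise ValueError("raw frames must contain only -1 and +1")
    bright = (frames_raw > 0).astype(np.int8)
    if basis == "bright":
        return bright
    if basis == "dark":
        return 1 - bright
    if basis in ("bright+dark", "concat"):
        return np.vstack([bright, 1 - bright])
    if basis == "raw":
        return frames_raw.astype(np.int8)
    raise ValueError(f"unknown basis {basis!r}")


# --------------------------------------------------------------------------
# File formats: HDF5 container (/frames, /counts, frame_rate_hz) and a CSV
# alternative with one frame per column (last row = counts).

def save_ensemble_hdf5(path, ensemble: StimulusEnsemble) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=ensemble.frames.astype(np.int8))
        h5.create_dataset("counts", data=ensemble.counts.astype(np.int32))
        h5.attrs["frame_rate_hz"] = ensemble.frame_rate
        h5.attrs["n_planes"] = ensemble.n_planes


def load_ensemble_hdf5(path) -> StimulusEnsemble:
    import h5py

    with h5py.File(path, "r") as h5:
        return StimulusEnsemble(
            frames=h5["frames"][...],
            counts=h5["counts"][...],
            frame_rate=float(h5.attrs.get("frame_rate_hz", 60.0)),
            n_planes=int(h5.attrs.get("n_planes", 1)),
        )


def load_ensemble_csv(path, frame_rate: float = 60.0) -> StimulusEnsemble:
    """CSV with one frame per column; the final row holds the spike counts."""
    arr = np.loadtxt(path, delimiter=",")
    return StimulusEnsemble(frames=arr[:-1].astype(np.int8),
                            counts=arr[-1].astype(np.int64),
                            frame_rate=frame_rate)
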