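"""Band-limited phase extraction and phase-locking-value (PLV) connectivity.

The PLV between two channels is the magnitude of the time-averaged unit
phasor of their instantaneous phase difference,

    PLV(i, j) = (1/M) | sum_t exp(i * (phi_i(t) - phi_j(t))) |,

with phases taken from the analytic (Hilbert) signal of the band-passed
data.  PLV is 1 for perfectly phase-locked channels, ~1/sqrt(M) for
independent phases, invariant to amplitude scaling and to common phase
offsets, symmetric, and bounded in [0, 1].

Band-passing uses a zero-phase 4th-order Butterworth (forward-backward,
``sosfiltfilt``).  Because both the filter and the Hilbert transform smear
the epoch edges, a configurable number of edge samples (default 125, i.e.
0.5 s at 250 Hz) is trimmed from each end before averaging the phasor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from sklearn.base import BaseEstimator, TransformerMixin

from .data import TrialSet

__all__ = [
    "BandSpec",
    "BANDS",
    "get_band",
    "bandpass_filter",
    "instantaneous_phase",
    "plv_from_phases",
    "plv_matrix",
    "plv_dataset",
    "PLVTensor",
    "PLVTransform",
    "class_mean_plv",
]

EDGE_TRIM_DEFAULT = 125  # samples trimmed per epoch edge before phasor averaging
FILTER_ORDER = 4


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with inclusive edges in Hz."""

    name: str
    low: float
    high: float

    def validate(self, fs: float) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})")
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name!r}: high edge {self.high} Hz >= Nyquist {fs / 2} Hz"
            )


#: The packaged analysis bands.  "mi" (8-30 Hz) spans the sensorimotor mu+beta
#: range classically modulated by motor imagery; "all" is the broadband input.
BANDS: dict[str, BandSpec] = {
    b.name: b
    for b in (
        BandSpec("all", 1.0, 51.0),
        BandSpec("delta", 1.0, 4.0),
        BandSpec("theta", 4.0, 8.0),
        BandSpec("alpha", 8.0, 12.0),
        BandSpec("mu", 8.0, 13.0),
        BandSpec("beta", 12.0, 30.0),
        BandSpec("mi", 8.0, 30.0),
        BandSpec("gamma", 30.0, 51.0),
    )
}


def get_band(band: str | BandSpec) -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; available: {', '.join(BANDS)}") from None


def _bandpass_array(X: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    band.validate(fs)
    sos = butter(FILTER_ORDER, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(X, dtype=np.float64), axis=-1)


def bandpass_filter(trials: TrialSet, band: str | BandSpec) -> TrialSet:
    """Zero-phase band-pass of every channel of every trial."""
    band = get_band(band)
    out = _bandpass_array(trials.signals, band, trials.fs)
    return trials.with_signals(out, note={"op": "bandpass", "band": band.name,
                                          "low": band.low, "high": band.high,
                                          "order": FILTER_ORDER, "zero_phase": True})


def instantaneous_phase(signal: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Instantaneous phase (radians, wrapped to (-pi, pi]) of the analytic signal.

    Works on the last axis of any array.  The input should already be
    band-limited; an all-zero channel has no defined phase and raises.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.shape[-1] < 4:
        raise ValueError("signal too short for phase extraction (need >= 4 samples)")
    flat = x.reshape(-1, x.shape[-1])
    if np.any(np.all(flat == 0, axis=-1)):
        raise ValueError("phase undefined for an all-zero channel")
    return np.angle(hilbert(x, axis=-1))


def plv_from_phases(phases: np.ndarray) -> np.ndarray:
    """Pairwise PLV matrix from per-channel instantaneous phases.

    ``phases`` is (channels, samples); returns (channels, channels), symmetric
    with unit diagonal.  This is the core phasor average; callers handle
    filtering and edge trimming.
    """
    phases = np.asarray(phases, dtype=np.float64)
    if phases.ndim != 2 or phases.shape[0] < 2:
        raise ValueError("phases must be (channels >= 2, samples)")
    z = np.exp(1j * phases)
    M = phases.shape[1]
    plv = np.abs(z @ z.conj().T) / M
    np.fill_diagonal(plv, 1.0)
    return np.clip(plv, 0.0, 1.0)


def plv_matrix(trial: np.ndarray, fs: float, edge_trim: int = EDGE_TRIM_DEFAULT) -> np.ndarray:
    """PLV matrix of one band-passed trial (channels x samples).

    ``edge_trim`` samples are discarded from each end of the epoch before
    averaging to suppress filter/Hilbert edge artifacts; pass 0 for exact
    arithmetic on synthetic phases.
    """
    trial = np.asarray(trial, dtype=np.float64)
    if trial.ndim != 2 or trial.shape[0] < 2:
        raise ValueError("trial must be (channels >= 2, samples)")
    if 2 * edge_trim >= trial.shape[1] - 4:
        raise ValueError(f"edge_trim {edge_trim} leaves too few samples of {trial.shape[1]}")
    phases = instantaneous_phase(trial, fs)
    if edge_trim:
        phases = phases[:, edge_trim:-edge_trim]
    return plv_from_phases(phases)


@dataclass
class PLVTensor:
    """Per-trial PLV connectivity matrices for one band."""

    values: np.ndarray  # (trials, channels, channels) in [0, 1]
    band: BandSpec
    channel_names: tuple[str, ...]
    labels: np.ndarray
    class_names: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def plv_dataset(trials: TrialSet, band: str | BandSpec,
                edge_trim: int = EDGE_TRIM_DEFAULT) -> PLVTensor:
    """Band-pass a TrialSet and compute one PLV matrix per trial."""
    band = get_band(band)
    filtered = _bandpass_array(trials.signals, band, trials.fs)
    n = filtered.shape[0]
    values = np.empty((n, trials.n_channels, trials.n_channels))
    phases = instantaneous_phase(filtered, trials.fs)
    if edge_trim:
        phases = phases[..., edge_trim:-edge_trim]
    for t in range(n):
        values[t] = plv_from_phases(phases[t])
    return PLVTensor(
        values=values,
        band=band,
        channel_names=trials.channel_names,
        labels=trials.labels.copy(),
        class_names=trials.class_names,
        provenance={**trials.provenance, "plv_band": band.name, "edge_trim": edge_trim},
    )


def class_mean_plv(tensor: PLVTensor) -> dict[str, np.ndarray]:
    """Per-class mean PLV matrices (connectivity heat-map tables)."""
    names = tensor.class_names or tuple(str(c) for c in np.unique(tensor.labels))
    return {
        names[c]: tensor.values[tensor.labels == c].mean(axis=0)
        for c in np.unique(tensor.labels)
    }


class PLVTransform(BaseEstimator, TransformerMixin):
    """Transformer mapping raw trials (n, C, S) to PLV matrices (n, C, C).

    Composes with sklearn pipelines in front of :class:`~migraph.estimators.PLVCNNClassifier`.
    """

    def __init__(self, band: str = "mi", fs: float = 250.0, edge_trim: int = EDGE_TRIM_DEFAULT):
        self.band = band
        self.fs = fs
        self.edge_trim = edge_trim

    def fit(self, X, y=None):
        self.band_ = get_band(self.band)
        self.band_.validate(self.fs)
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "band_")
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError(f"expected (n_trials, channels, samples), got {X.shape}")
        filtered = _bandpass_array(X, self.band_, self.fs)
        phases = instantaneous_phase(filtered, self.fs)
        if self.edge_trim:
            phases = phases[..., self.edge_trim:-self.edge_trim]
        return np.stack([plv_from_phases(p) for p in phases])
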