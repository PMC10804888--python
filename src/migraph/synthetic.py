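"""Synthetic multichannel EEG with planted, class-dependent structure.

The generator emulates the geometry of a motor-imagery benchmark session
(22 channels, 250 Hz, 4-s epochs, 4 classes, 9 pseudo-subjects) while
planting two kinds of recoverable class structure:

* **Phase coupling** — chosen channel pairs share one narrowband
  oscillator whose instantaneous frequency wanders slowly around a band
  centre (AR(1) drift, bounded), with independent band-limited Gaussian
  phase jitter added per channel.  If the pair's phase-difference standard
  deviation is sigma, the expected phase-locking value is the closed form
  ``exp(-sigma^2 / 2)`` (mean of a unit phasor with Gaussian angle); the
  jitter is split as sigma/sqrt(2) per channel so this holds exactly.
  The jitter is smoothed to a ~2 Hz bandwidth before use (and rescaled to
  the target marginal std) so it survives the analysis band-pass; its
  marginal law, and hence the expectation, is unchanged.

* **Regional sources with power modulation** — a :class:`RegionalSource`
  is one narrowband oscillator projected with zero lag onto a set of
  channels with fixed weights, the way volume conduction spreads a
  cortical source coherently over nearby electrodes.  Per-class
  multiplicative factors on a source's power mimic event-related
  desynchronisation of the sensorimotor rhythm; because the projection is
  coherent, neighbourhood averaging (the structural embedding) raises
  rather than destroys its signal-to-noise ratio.

Channels that are neither coupled nor source members carry independent
oscillators whose per-trial centre
frequency is drawn uniformly within ``osc_center +/- osc_spread``, so their
pairwise phase differences drift through several cycles per epoch and the
background PLV stays low.  All channels receive 1/f-plus-white background
noise; ``snr_db`` is the broadband oscillator-to-noise power ratio (the
noise share falling inside any one analysis band is much smaller).

Not emulated: volume conduction / leadfield mixing, ocular or muscular
artifacts, non-stationarity across a session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .data import TrialSet
from .montage import build_layout

__all__ = ["Coupling", "RegionalSource", "SynthSpec", "generate_dataset", "planted_oracle",
           "preset_spec", "PRESETS"]


@dataclass(frozen=True)
class Coupling:
    """A planted phase-coupled channel pair."""

    ch_i: str
    ch_j: str
    freq: float = 10.0   # oscillator band centre, Hz
    sigma: float = 0.3   # std of the pair's phase difference, radians

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class RegionalSource:
    """One oscillator projected coherently (zero lag) onto several channels."""

    name: str
    channels: tuple[str, ...]
    weights: tuple[float, ...]
    freq: float = 10.0

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.weights):
            raise ValueError("channels and weights must have equal length")


@dataclass(frozen=True)
class SynthSpec:
    """Full description of one synthetic dataset.

    Defaults reproduce the benchmark geometry: 4 classes x 648 trials =
    2592 trials of 22 x 1000 samples at 250 Hz across 9 pseudo-subjects.

    ``amplitude`` maps, per class, a *source name* (for regional sources)
    or a *channel name* (for independent-oscillator channels) to a power
    factor.  A channel may not be both a coupling member and a source
    member.
    """

    class_count: int = 4
    trials_per_class: int = 648
    fs: float = 250.0
    duration_s: float = 4.0
    montage: str = "bci2a-22"
    coupling: tuple[tuple[Coupling, ...], ...] = ()   # per class
    sources: tuple[RegionalSource, ...] = ()          # shared across classes
    amplitude: tuple[dict, ...] = ()                  # per class: source/channel -> power factor
    snr_db: float = 0.0          # broadband oscillator-to-noise ratio
    pink_fraction: float = 0.5   # share of noise power that is 1/f
    n_subjects: int = 9
    osc_center: float = 10.0     # uncoupled-channel rhythm centre, Hz
    osc_spread: float = 1.5      # per-trial uniform centre jitter, Hz
    drift_std: float = 0.5       # AR(1) instantaneous-frequency drift std, Hz
    drift_rho: float = 0.995
    drift_max: float = 1.5       # drift clip, Hz
    jitter_smooth: float = 23.0  # Gaussian smoothing of phase jitter, samples (~2 Hz bandwidth)
    base_amp: float = 1.0
    seed: int = 0
    class_names: tuple[str, ...] = ("left_hand", "right_hand", "feet", "tongue")

    def __post_init__(self) -> None:
        m = self.fs * self.duration_s
        if abs(m - round(m)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer sample count")
        if self.coupling and len(self.coupling) != self.class_count:
            raise ValueError("coupling must list one (possibly empty) tuple per class")
        if self.amplitude and len(self.amplitude) != self.class_count:
            raise ValueError("amplitude must list one (possibly empty) mapping per class")
        if len(self.class_names) != self.class_count:
            raise ValueError("class_names length must equal class_count")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def class_coupling(self, c: int) -> tuple[Coupling, ...]:
        return self.coupling[c] if self.coupling else ()

    def class_amplitude(self, c: int) -> dict:
        return self.amplitude[c] if self.amplitude else {}


def _validate_channels(spec: SynthSpec, channels: tuple[str, ...]) -> None:
    known = set(channels)
    source_members = set()
    source_names = set()
    for src in spec.sources:
        source_names.add(src.name)
        for ch in src.channels:
            if ch not in known:
                raise ValueError(f"source channel {ch!r} not in montage {spec.montage!r}")
            source_members.add(ch)
    for c in range(spec.class_count):
        for cp in spec.class_coupling(c):
            for ch in (cp.ch_i, cp.ch_j):
                if ch not in known:
                    raise ValueError(f"coupling channel {ch!r} not in montage {spec.montage!r}")
                if ch in source_members:
                    raise ValueError(
                        f"channel {ch!r} is both a coupling member and a regional-source member"
                    )
        for name in spec.class_amplitude(c):
            if name not in known and name not in source_names:
                raise ValueError(
                    f"amplitude key {name!r} is neither a montage channel nor a source name"
                )


def _osc_phase(rng: np.random.Generator, m: int, fs: float, f0: float, spec: SynthSpec,
               center_jitter: bool) -> np.ndarray:
    """Phase track of one oscillator: band centre + bounded AR(1) drift."""
    if center_jitter:
        f0 = f0 + rng.uniform(-spec.osc_spread, spec.osc_spread)
    innov_std = spec.drift_std * np.sqrt(1.0 - spec.drift_rho**2)
    drift = lfilter([1.0], [1.0, -spec.drift_rho], innov_std * rng.standard_normal(m))
    drift += spec.drift_std * rng.standard_normal() * spec.drift_rho  # warm start
    np.clip(drift, -spec.drift_max, spec.drift_max, out=drift)
    theta0 = rng.uniform(0, 2 * np.pi)
    return theta0 + 2 * np.pi * np.cumsum(f0 + drift) / fs


def _band_limited_jitter(rng: np.random.Generator, m: int, std: float, smooth: float) -> np.ndarray:
    """Slow Gaussian phase jitter with exact (sample) marginal std."""
    if std == 0:
        return np.zeros(m)
    eps = gaussian_filter1d(rng.standard_normal(m), smooth, mode="reflect")
    s = eps.std()
    return eps * (std / s) if s > 0 else eps


def _background_noise(rng: np.random.Generator, n_ch: int, m: int, spec: SynthSpec) -> np.ndarray:
    """Pink + white mixture, unit-variance shape, scaled by the SNR target."""
    white = rng.standard_normal((n_ch, m))
    spectrum = np.fft.rfft(rng.standard_normal((n_ch, m)), axis=-1)
    freqs = np.fft.rfftfreq(m, d=1.0 / spec.fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[0] = 0.0
    pink = np.fft.irfft(spectrum * shaping, n=m, axis=-1)
    pink /= pink.std(axis=-1, keepdims=True)
    mix = np.sqrt(spec.pink_fraction) * pink + np.sqrt(1 - spec.pink_fraction) * white
    osc_power = 0.5 * spec.base_amp**2
    noise_power = osc_power * 10.0 ** (-spec.snr_db / 10.0)
    return mix * np.sqrt(noise_power)


def generate_dataset(spec: SynthSpec) -> TrialSet:
    """Generate the labelled TrialSet a spec describes.

    Deterministic in ``spec.seed``: the same spec yields a bit-identical
    dataset.  Trials interleave classes and assign subjects round-robin
    over ``n_subjects`` pseudo-subjects (each with a small fixed gain).
    """
    layout = build_layout(spec.montage)
    _validate_channels(spec, layout.channels)
    n_ch = layout.n_channels
    m = spec.n_samples
    n_trials = spec.class_count * spec.trials_per_class
    rng = np.random.default_rng(spec.seed)

    labels = np.tile(np.arange(spec.class_count), spec.trials_per_class)
    subject_ids = np.arange(n_trials) % spec.n_subjects
    subject_gain = np.exp(0.1 * rng.standard_normal(spec.n_subjects))

    signals = np.empty((n_trials, n_ch, m), dtype=np.float32)
    ch_index = {ch: k for k, ch in enumerate(layout.channels)}

    for t in range(n_trials):
        c = labels[t]
        amp_map = spec.class_amplitude(c)
        gains = np.full(n_ch, spec.base_amp) * subject_gain[subject_ids[t]]
        for name, factor in amp_map.items():
            if name in ch_index:
                gains[ch_index[name]] *= np.sqrt(factor)

        trial = np.zeros((n_ch, m))
        done = np.zeros(n_ch, dtype=bool)
        for src in spec.sources:
            theta = _osc_phase(rng, m, spec.fs, src.freq, spec, center_jitter=False)
            wave = np.sqrt(amp_map.get(src.name, 1.0)) * np.cos(theta)
            for ch, w in zip(src.channels, src.weights):
                k = ch_index[ch]
                trial[k] += gains[k] * w * wave
                done[k] = True
        for cp in spec.class_coupling(c):
            theta = _osc_phase(rng, m, spec.fs, cp.freq, spec, center_jitter=False)
            per_ch = cp.sigma / np.sqrt(2.0)
            for ch in (cp.ch_i, cp.ch_j):
                k = ch_index[ch]
                eps = _band_limited_jitter(rng, m, per_ch, spec.jitter_smooth)
                trial[k] = gains[k] * np.cos(theta + eps)
                done[k] = True
        for k in np.flatnonzero(~done):
            theta = _osc_phase(rng, m, spec.fs, spec.osc_center, spec, center_jitter=True)
            trial[k] = gains[k] * np.cos(theta)
        trial += _background_noise(rng, n_ch, m, spec)
        signals[t] = trial.astype(np.float32)

    return TrialSet(
        signals=signals,
        labels=labels,
        fs=spec.fs,
        channel_names=layout.channels,
        subject_ids=subject_ids,
        class_names=spec.class_names,
        provenance={"generator": "migraph.synthetic", "seed": spec.seed,
                    "snr_db": spec.snr_db, "trials_per_class": spec.trials_per_class,
                    "montage": spec.montage},
    )


def planted_oracle(spec: SynthSpec) -> dict:
    """Analytic expectations for the planted structure.

    Returns ``{"plv": {class_name: (C, C) matrix}, "power": {class_name:
    (C,) vector}}``.  Coupled entries carry ``exp(-sigma^2/2)``; the
    uncoupled baseline is the uniform-phase expectation
    ``sqrt(pi)/2 / sqrt(M)`` for M i.i.d. samples (an optimistic floor —
    band-limited signals have fewer effective samples); diagonal is 1.
    """
    layout = build_layout(spec.montage)
    _validate_channels(spec, layout.channels)
    n_ch = layout.n_channels
    ch_index = {ch: k for k, ch in enumerate(layout.channels)}
    baseline = np.sqrt(np.pi) / 2.0 / np.sqrt(spec.n_samples)
    membership: dict[str, int] = {}
    for src in spec.sources:
        for ch in src.channels:
            membership[ch] = membership.get(ch, 0) + 1
    plv, power = {}, {}
    for c in range(spec.class_count):
        amp_map = spec.class_amplitude(c)
        mat = np.full((n_ch, n_ch), baseline)
        np.fill_diagonal(mat, 1.0)
        # zero-lag co-members of a single shared source are perfectly locked;
        # channels shared between sources mix phases and are left at baseline
        for src in spec.sources:
            pure = [ch for ch in src.channels if membership[ch] == 1]
            for a in pure:
                for b in pure:
                    if a != b:
                        mat[ch_index[a], ch_index[b]] = 1.0
        for cp in spec.class_coupling(c):
            i, j = ch_index[cp.ch_i], ch_index[cp.ch_j]
            mat[i, j] = mat[j, i] = np.exp(-cp.sigma**2 / 2.0)
        vec = np.ones(n_ch)
        contrib = np.zeros(n_ch)
        for src in spec.sources:
            factor = amp_map.get(src.name, 1.0)
            for ch, w in zip(src.channels, src.weights):
                contrib[ch_index[ch]] += w**2 * factor
        for ch, cnt in membership.items():
            vec[ch_index[ch]] = contrib[ch_index[ch]]
        for name, factor in amp_map.items():
            if name in ch_index and name not in membership:
                vec[ch_index[name]] = factor
        cls = spec.class_names[c]
        plv[cls] = mat
        power[cls] = vec
    return {"plv": plv, "power": power}


def _plv_separable_coupling(sigma: float, freq: float) -> tuple[tuple[Coupling, ...], ...]:
    pairs = (
        (("C3", "C4"), ("FC3", "FC4")),
        (("Fz", "Pz"), ("FCz", "CPz")),
        (("C5", "C6"), ("CP3", "CP4")),
        (("C1", "C2"), ("P1", "P2")),
    )
    return tuple(
        tuple(Coupling(a, b, freq=freq, sigma=sigma) for a, b in cls_pairs)
        for cls_pairs in pairs
    )


def _sensorimotor_sources(montage: str, freq: float) -> tuple[RegionalSource, ...]:
    """One coherent source per sensorimotor site (C3, C4, Cz): the centre
    electrode at weight 1, its grid neighbours at 1/sqrt(2) (power falls by
    half per grid step, a crude volume-conduction taper)."""
    from .montage import build_adjacency

    graph = build_adjacency(build_layout(montage))
    sources = []
    for centre in ("C3", "C4", "Cz"):
        members = (centre, *sorted(graph.neighbors(centre)))
        weights = (1.0,) + (1.0 / np.sqrt(2.0),) * (len(members) - 1)
        sources.append(RegionalSource(name=centre, channels=members, weights=weights, freq=freq))
    return tuple(sources)


def _erd_amplitude() -> tuple[dict, ...]:
    # +/-50% sensorimotor source-power modulation, one topography per class
    return (
        {"C3": 0.5, "C4": 1.5},
        {"C3": 1.5, "C4": 0.5},
        {"Cz": 0.5},
        {},
    )


def _parietal_coupling(sigma: float, freq: float) -> tuple[tuple[Coupling, ...], ...]:
    # pairs kept clear of the sensorimotor source regions
    pairs = ((("Fz", "Pz"),), (("P1", "P2"),), (("Fz", "POz"),), (("Pz", "P2"),))
    return tuple(
        tuple(Coupling(a, b, freq=freq, sigma=sigma) for a, b in cls_pairs)
        for cls_pairs in pairs
    )


PRESETS = ("plv-separable", "erd-separable", "both")


def preset_spec(name: str, *, trials_per_class: int = 200, sigma: float = 0.3,
                freq: float = 10.0, seed: int = 0, **overrides) -> SynthSpec:
    """Shipped class designs.

    ``"plv-separable"``: classes differ only in which channel pairs are
    phase-coupled (two disjoint pairs per class, default sigma 0.3 in the
    mu rhythm).  ``"erd-separable"``: classes differ only in sensorimotor
    power topography — coherent regional sources at C3/C4/Cz with +/-50%
    per-class power modulation.  ``"both"``: the power topography plus one
    distinct phase-coupled parietal/frontal pair per class.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    kwargs: dict = dict(trials_per_class=trials_per_class, seed=seed)
    montage = overrides.get("montage", "bci2a-22")
    if name == "plv-separable":
        kwargs["coupling"] = _plv_separable_coupling(sigma, freq)
    if name in ("erd-separable", "both"):
        kwargs["sources"] = _sensorimotor_sources(montage, freq)
        kwargs["amplitude"] = _erd_amplitude()
    if name == "both":
        kwargs["coupling"] = _parietal_coupling(sigma, freq)
    kwargs.update(overrides)
    return SynthSpec(**kwargs)
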