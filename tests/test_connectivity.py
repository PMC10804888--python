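"""Band-pass filtering, analytic-signal phase and PLV properties."""

import numpy as np
import pytest
from scipy.signal import periodogram

from migraph import (
    BANDS,
    TrialSet,
    bandpass_filter,
    get_band,
    instantaneous_phase,
    plv_dataset,
    plv_from_phases,
    plv_matrix,
)
from migraph.connectivity import class_mean_plv
from migraph.synthetic import generate_dataset, preset_spec

FS = 250.0


def tone(freq, n=1000, fs=FS, phase=0.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


def band_power(x, fs, lo, hi):
    f, p = periodogram(x, fs=fs)
    return p[(f >= lo) & (f <= hi)].sum()


def make_trials(signals, fs=FS):
    n, c, _ = signals.shape
    return TrialSet(signals=signals, labels=np.zeros(n, dtype=int), fs=fs,
                    channel_names=[f"ch{i}" for i in range(c)],
                    subject_ids=np.zeros(n, dtype=int), class_names=("only",))


class TestBandpass:
    def test_passband_and_stopband_power(self):
        x = tone(10.0)[None, None, :]
        y = bandpass_filter(make_trials(x), "alpha").signals[0, 0]
        assert band_power(y, FS, 8, 12) >= 0.9 * band_power(x[0, 0], FS, 8, 12)
        z = bandpass_filter(make_trials(tone(40.0)[None, None, :]), "alpha").signals[0, 0]
        assert band_power(z, FS, 0, 125) <= 0.01 * band_power(tone(40.0), FS, 0, 125)

    def test_idempotent_within_passband(self):
        x = tone(10.0)[None, None, :]
        once = bandpass_filter(make_trials(x), "alpha")
        twice = bandpass_filter(once, "alpha")
        mid = slice(200, 800)
        ratio = twice.signals[0, 0, mid].std() / once.signals[0, 0, mid].std()
        assert abs(ratio - 1.0) < 0.05

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(make_trials(tone(10.0)[None, None, :], fs=80.0), "gamma")

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError, match="available"):
            get_band("ultraslow")

    def test_packaged_band_edges(self):
        assert (BANDS["mu"].low, BANDS["mu"].high) == (8.0, 13.0)
        assert (BANDS["mi"].low, BANDS["mi"].high) == (8.0, 30.0)
        assert len(BANDS) == 8


class TestInstantaneousPhase:
    def test_pure_tone_phase_velocity(self):
        ph = np.unwrap(instantaneous_phase(tone(10.0)))
        inc = np.diff(ph[100:-100]).mean()
        assert inc == pytest.approx(2 * np.pi * 10.0 / FS, rel=0.01)

    def test_quadrature_pair_offset(self):
        t = np.arange(1000) / FS
        pc = instantaneous_phase(np.cos(2 * np.pi * 10 * t))
        ps = instantaneous_phase(np.sin(2 * np.pi * 10 * t))
        diff = np.angle(np.exp(1j * (pc - ps)))[100:-100]
        assert np.allclose(diff, np.pi / 2, atol=0.05)

    def test_amplitude_invariance(self):
        x = tone(10.0)
        assert np.allclose(instantaneous_phase(x), instantaneous_phase(5.0 * x), atol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            instantaneous_phase(np.zeros(100))
        with pytest.raises(ValueError, match="short"):
            instantaneous_phase(np.ones(3))


class TestPhasorAverage:
    def test_identical_phases_give_unity(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert plv_from_phases(np.stack([ph, ph]))[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_gives_unity(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert plv_from_phases(np.stack([ph, ph + 1.1]))[0, 1] >= 0.99

    def test_uniform_phase_null_level(self, rng):
        # E[PLV] for M i.i.d. uniform phase differences is sqrt(pi)/2/sqrt(M) ~= 0.028
        vals = [plv_from_phases(rng.uniform(-np.pi, np.pi, (2, 1000)))[0, 1]
                for _ in range(200)]
        assert np.mean(vals) < 0.05

    @pytest.mark.parametrize("sigma", [0.2, 1.0])
    def test_gaussian_jitter_closed_form(self, rng, sigma):
        # E[exp(i*eps)] = exp(-sigma^2/2) for eps ~ N(0, sigma^2)
        vals = []
        for _ in range(200):
            p1 = rng.uniform(-np.pi, np.pi, 1000)
            vals.append(plv_from_phases(np.stack([p1, p1 + rng.normal(0, sigma, 1000)]))[0, 1])
        assert abs(np.mean(vals) - np.exp(-sigma**2 / 2)) <= 0.05

    def test_monotone_degradation_with_jitter(self, rng):
        means = []
        for sigma in (0.2, 0.6, 1.0, 1.5):
            vals = []
            for _ in range(100):
                p1 = rng.uniform(-np.pi, np.pi, 1000)
                vals.append(plv_from_phases(np.stack([p1, p1 + rng.normal(0, sigma, 1000)]))[0, 1])
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestPLVMatrix:
    def test_exact_copy_is_perfectly_locked(self):
        x = tone(10.0, phase=0.3)
        plv = plv_matrix(np.stack([x, x.copy()]), FS)
        assert plv[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_fixed_delay_in_narrow_band(self):
        x = tone(10.0)
        y = tone(10.0, phase=1.0)
        assert plv_matrix(np.stack([x, y]), FS)[0, 1] >= 0.99

    def test_symmetry_bounds_diagonal(self, rng):
        trial = rng.standard_normal((5, 800))
        plv = plv_matrix(trial, FS)
        assert np.allclose(plv, plv.T)
        assert np.all((plv >= 0) & (plv <= 1))
        assert np.allclose(np.diag(plv), 1.0)

    def test_amplitude_and_common_offset_invariance(self, rng):
        x = rng.standard_normal((3, 900))
        base = plv_matrix(x, FS)
        scaled = plv_matrix(x * np.array([1.0, 7.0, 0.2])[:, None], FS)
        assert np.allclose(base, scaled, atol=1e-9)

    def test_constant_channel_rejected(self):
        trial = np.stack([tone(10.0), np.zeros(1000)])
        with pytest.raises(ValueError, match="all-zero"):
            plv_matrix(trial, FS)

    def test_edge_trim_bounds(self):
        with pytest.raises(ValueError, match="edge_trim"):
            plv_matrix(np.random.default_rng(0).standard_normal((2, 100)), FS, edge_trim=50)


@pytest.fixture(scope="module")
def small_preset():
    spec = preset_spec("plv-separable", trials_per_class=50, seed=77)
    trials = generate_dataset(spec)
    return spec, trials, plv_dataset(trials, "mu")


class TestPLVDataset:
    def test_shape_and_labels_carried(self, small_preset):
        spec, trials, tensor = small_preset
        assert tensor.values.shape == (trials.n_trials, 22, 22)
        assert np.array_equal(tensor.labels, trials.labels)
        assert tensor.band.name == "mu"

    def test_class_means_are_per_class(self, small_preset):
        _, trials, tensor = small_preset
        means = class_mean_plv(tensor)
        assert set(means) == set(trials.class_names)
        for mat in means.values():
            assert mat.shape == (22, 22)
            assert np.allclose(mat, mat.T)

    def test_planted_contrast_exceeds_background(self, small_preset):
        spec, trials, tensor = small_preset
        names = trials.channel_names
        coupled, uncoupled = [], []
        pair_set = {frozenset((cp.ch_i, cp.ch_j)) for cps in spec.coupling for cp in cps}
        for c, cps in enumerate(spec.coupling):
            mean = tensor.values[tensor.labels == c].mean(axis=0)
            for cp in cps:
                coupled.append(mean[names.index(cp.ch_i), names.index(cp.ch_j)])
            # the same entries in classes where the pair is NOT planted
            for other_c in range(spec.class_count):
                if other_c == c:
                    continue
                other = tensor.values[tensor.labels == other_c].mean(axis=0)
                for cp in cps:
                    uncoupled.append(other[names.index(cp.ch_i), names.index(cp.ch_j)])
        assert np.mean(coupled) - np.mean(uncoupled) > 0.3
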