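"""Generator determinism, class construction, and spectral fingerprints."""

import numpy as np
import pytest

from ieegssl.evaluation import _binary_auroc
from ieegssl.synthetic import (
    GeneratorError, GeneratorParams, generate_dataset, generate_recording,
    generate_segment,
)


class TestGenerateSegment:
    def test_fixed_seed_is_byte_identical(self, params):
        a = generate_segment(3, params, seed=1)
        b = generate_segment(3, params, seed=1)
        assert a.samples.tobytes() == b.samples.tobytes()

    def test_segment_length_and_finiteness(self, params):
        for label in range(4):
            seg = generate_segment(label, params, seed=11)
            assert seg.samples.shape == (params.n_samples,)
            assert np.isfinite(seg.samples).all()
            assert seg.label == label

    def test_mains_segment_peaks_at_line_frequency(self):
        # full-length FFT argmax oracle
        for mains in (50.0, 60.0):
            p = GeneratorParams(mains_hz=mains)
            seg = generate_segment(0, p, seed=7)
            mag = np.abs(np.fft.rfft(seg.samples))
            freqs = np.fft.rfftfreq(seg.samples.size, d=1.0 / p.sampling_rate_hz)
            assert abs(freqs[np.argmax(mag)] - mains) <= freqs[1]

    def test_pathological_amplitude_exceeds_background(self, params):
        # class 2 shares its background with class 3 at the same seed
        patho = generate_segment(2, params, seed=3)
        physio = generate_segment(3, params, seed=3)
        assert np.max(np.abs(patho.samples)) >= params.ied_amp_factor / 2 * physio.samples.std()

    def test_unknown_label_rejected(self, params):
        with pytest.raises(GeneratorError, match="unknown label"):
            generate_segment(7, params, seed=0)

    def test_hfo_skipped_below_nyquist_but_ieds_remain(self):
        p = GeneratorParams(sampling_rate_hz=256.0)  # Nyquist 128 < hfo high 200
        assert not p.hfo_enabled
        patho = generate_segment(2, p, seed=3)
        physio = generate_segment(3, p, seed=3)
        assert np.max(np.abs(patho.samples)) >= p.ied_amp_factor / 2 * physio.samples.std()

    def test_invalid_params_rejected(self):
        with pytest.raises(GeneratorError):
            GeneratorParams(sampling_rate_hz=100.0, segment_seconds=3.001)
        with pytest.raises(GeneratorError):
            GeneratorParams(mains_hz=45.0)


class TestGenerateDataset:
    def test_counts_are_exact(self, params):
        segs = generate_dataset({0: 5, 1: 5, 2: 5, 3: 5}, params, seed=0)
        assert len(segs) == 20
        labels = [s.label for s in segs]
        assert all(labels.count(c) == 5 for c in range(4))

    def test_zero_count_class_absent(self, params):
        segs = generate_dataset({2: 0, 3: 10}, params, seed=0)
        assert len(segs) == 10
        assert all(s.label == 3 for s in segs)

    def test_deterministic_ids_and_samples(self, params):
        a = generate_dataset({0: 3, 2: 3}, params, seed=9)
        b = generate_dataset({0: 3, 2: 3}, params, seed=9)
        assert [s.segment_id for s in a] == [s.segment_id for s in b]
        assert all(x.samples.tobytes() == y.samples.tobytes() for x, y in zip(a, b))

    def test_distinct_master_seeds_give_distinct_ids(self, params):
        a = generate_dataset({3: 3}, params, seed=1)
        b = generate_dataset({3: 3}, params, seed=2)
        assert not set(s.segment_id for s in a) & set(s.segment_id for s in b)

    def test_negative_count_rejected(self, params):
        with pytest.raises(GeneratorError, match="negative"):
            generate_dataset({3: -1}, params, seed=0)

    def test_patient_round_robin(self, params):
        segs = generate_dataset({3: 16}, params, seed=0, n_patients=4)
        assert len({s.patient_id for s in segs}) == 4


class TestGenerateRecording:
    def test_zero_prevalence_all_physiological(self, params):
        segs = generate_recording(30, 0.0, params, seed=0)
        assert len(segs) == 10
        assert all(s.label == 0 for s in segs)

    def test_floor_arithmetic(self, params):
        assert len(generate_recording(1800, 0.1, params, seed=0)) == 600
        assert len(generate_recording(31.5, 0.1, params, seed=0)) == 10

    def test_prevalence_within_binomial_bound(self, params):
        segs = generate_recording(1800, 0.1, params, seed=5)
        frac = np.mean([s.label for s in segs])
        assert abs(frac - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / 600)

    def test_bad_prevalence_rejected(self, params):
        with pytest.raises(GeneratorError, match="prevalence"):
            generate_recording(30, 1.5, params, seed=0)


def _band_power_ratio(seg, lo, hi, fs, notch_mains=None):
    freqs = np.fft.rfftfreq(seg.samples.size, d=1.0 / fs)
    power = np.abs(np.fft.rfft(seg.samples)) ** 2
    mask = (freqs >= lo) & (freqs < hi)
    if notch_mains is not None:
        # line noise is narrowband; exclude the mains fundamental + harmonics so the
        # broadband-activity fingerprint is not contaminated by the mains peaks
        for k in (1, 2, 3):
            mask &= np.abs(freqs - k * notch_mains) > 2.0
    return power[mask].sum() / power.sum()


def test_spectral_fingerprints_separate_classes(params):
    """Band-power ratios discriminate mains / muscle / physiological pairwise.

    This is the separability floor the downstream pipeline relies on.
    """
    segs = generate_dataset({c: 100 for c in (0, 1, 3)}, params, seed=77)
    fs = params.sampling_rate_hz
    bands = {0: (params.mains_hz - 2, params.mains_hz + 2, None),
             1: (params.emg_band_low_hz, fs / 2, params.mains_hz),
             3: (*params.osc_band_hz, None)}
    for target, (lo, hi, notch) in bands.items():
        scores = np.array([_band_power_ratio(s, lo, hi, fs, notch) for s in segs])
        labels = np.array([s.label for s in segs])
        for other in bands:
            if other == target:
                continue
            mask = np.isin(labels, (target, other))
            auc = _binary_auroc(scores[mask], labels[mask] == target)
            assert auc > 0.9, f"class {target} vs {other} via band ({lo},{hi}): AUROC {auc:.3f}"
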