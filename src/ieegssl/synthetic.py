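"""Seeded generator of iEEG-like segments in four annotation classes.

Emulates the segment taxonomy used in clinical iEEG review: physiological
background activity, pathological activity carrying interictal epileptiform
discharges (IEDs) and high-frequency oscillation (HFO) bursts, muscle
artifacts, and power-line noise.  Class codes follow the review convention:

    0 — power-line noise, 1 — artifact, 2 — pathological, 3 — physiological.

Waveform models are deliberately simple parametric stand-ins with the right
time-frequency signatures (pink-noise background, raised-cosine sharp waves,
Gabor HFO atoms, burst-gated high-passed noise, mains sinusoid + harmonics);
they are calibration knobs for pipeline testing, not biophysical estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "UNLABELED",
    "CLASS_NAMES",
    "BINARY_CLASS_NAMES",
    "GeneratorParams",
    "SegmentRecord",
    "generate_segment",
    "generate_dataset",
    "generate_recording",
]

#: Sentinel label for segments whose gold standard has been withheld/discarded.
UNLABELED = -1

CLASS_NAMES = {
    0: "power line noise",
    1: "artifact",
    2: "pathological",
    3: "physiological",
}

#: Re-coding used in the pseudo-prospective (long recording) mode.
BINARY_CLASS_NAMES = {0: "physiological", 1: "IED"}

_BACKGROUND_STD_UV = 10.0  # pink-noise background scale, µV


class GeneratorError(ValueError):
    """Raised for invalid generator parameters or labels."""


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic segment generator.

    ``sampling_rate_hz`` defaults to a desk-scale 512 Hz; set 5000 to mimic
    clinical acquisition (3-s segments of 15,000 samples).
    """

    sampling_rate_hz: float = 512.0
    segment_seconds: float = 3.0
    background_exponent: float = 1.0
    osc_band_hz: tuple[float, float] = (8.0, 12.0)
    ied_width_ms: tuple[float, float] = (30.0, 70.0)
    ied_amp_factor: float = 6.0
    hfo_band_hz: tuple[float, float] = (80.0, 200.0)
    emg_band_low_hz: float = 30.0
    mains_hz: float = 50.0
    snr_db: float = 20.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.segment_seconds <= 0:
            raise GeneratorError("sampling rate and segment duration must be positive")
        n = self.sampling_rate_hz * self.segment_seconds
        if abs(n - round(n)) > 1e-9:
            raise GeneratorError(
                f"sampling_rate_hz * segment_seconds = {n} is not a whole number of samples"
            )
        nyq = self.sampling_rate_hz / 2.0
        if not (0 < self.osc_band_hz[0] < self.osc_band_hz[1] < nyq):
            raise GeneratorError("osc_band_hz must lie strictly below Nyquist")
        if self.mains_hz not in (50.0, 60.0, 50, 60):
            raise GeneratorError("mains_hz must be 50 or 60")
        if self.mains_hz >= nyq:
            raise GeneratorError("mains_hz must lie below Nyquist")
        if not np.isfinite([self.ied_amp_factor, self.snr_db]).all():
            raise GeneratorError("amplitudes must be finite")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.segment_seconds))

    @property
    def hfo_enabled(self) -> bool:
        """HFO insertion is silently skipped when the band tops out above Nyquist."""
        return self.hfo_band_hz[1] < self.sampling_rate_hz / 2.0


@dataclass
class SegmentRecord:
    """One 3-s single-channel iEEG window (samples in µV)."""

    segment_id: str
    samples: np.ndarray
    sampling_rate_hz: float
    label: int = UNLABELED
    patient_id: str = "synthetic"
    institution: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise GeneratorError("samples must be a 1-D vector")
        if not np.isfinite(self.samples).all():
            raise GeneratorError("samples must be finite")
        valid = set(CLASS_NAMES) | {UNLABELED}
        if int(self.label) not in valid:
            raise GeneratorError(f"label {self.label!r} not in {sorted(valid)}")
        self.label = int(self.label)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^alpha noise via spectral shaping, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _background(rng: np.random.Generator, params: GeneratorParams) -> np.ndarray:
    """Physiological background: pink noise + band-limited oscillation."""
    n = params.n_samples
    bg = _BACKGROUND_STD_UV * _pink_noise(rng, n, params.background_exponent)
    lo, hi = params.osc_band_hz
    f0 = rng.uniform(lo, hi)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / params.sampling_rate_hz
    # amplitude-modulated so the rhythm waxes and wanes like real background
    env = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.1, 0.5) * t + rng.uniform(0, 2 * np.pi))
    osc = 1.5 * _BACKGROUND_STD_UV * env * np.sin(2 * np.pi * f0 * t + phase)
    return bg + osc


def _ied_waveform(width_samples: int) -> np.ndarray:
    """Biphasic raised-cosine sharp wave: sharp positive lobe, slower negative lobe."""
    w1 = max(width_samples, 2)
    w2 = 2 * w1
    lobe1 = 0.5 * (1 - np.cos(2 * np.pi * np.arange(w1) / w1))
    lobe2 = -0.5 * 0.5 * (1 - np.cos(2 * np.pi * np.arange(w2) / w2))
    return np.concatenate([lobe1, lobe2])


def _add_ieds(sig: np.ndarray, rng: np.random.Generator, params: GeneratorParams,
              bg_std: float) -> None:
    n = sig.size
    fs = params.sampling_rate_hz
    for _ in range(rng.integers(1, 6)):
        width_ms = rng.uniform(*params.ied_width_ms)
        wave = _ied_waveform(int(round(width_ms * 1e-3 * fs)))
        amp = params.ied_amp_factor * bg_std * rng.choice([-1.0, 1.0])
        onset = rng.integers(0, max(n - wave.size, 1))
        sig[onset:onset + wave.size] += amp * wave[: n - onset]


def _add_hfos(sig: np.ndarray, rng: np.random.Generator, params: GeneratorParams,
              bg_std: float) -> None:
    n = sig.size
    fs = params.sampling_rate_hz
    for _ in range(rng.integers(1, 4)):
        f0 = rng.uniform(*params.hfo_band_hz)
        n_cycles = rng.uniform(6, 12)
        dur = int(round(n_cycles / f0 * fs))
        if dur < 4 or dur >= n:
            continue
        t = np.arange(dur) / fs
        gauss = np.exp(-0.5 * ((t - t[-1] / 2) / (t[-1] / 4)) ** 2)
        atom = gauss * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        onset = rng.integers(0, n - dur)
        sig[onset:onset + dur] += 2.0 * bg_std * atom


def _muscle_artifact(rng: np.random.Generator, params: GeneratorParams) -> np.ndarray:
    """Pink background + 2-4 amplitude-modulated bursts of high-passed white noise."""
    n = params.n_samples
    fs = params.sampling_rate_hz
    sig = _BACKGROUND_STD_UV * _pink_noise(rng, n, params.background_exponent)
    burst_std = _BACKGROUND_STD_UV * 10 ** (params.snr_db / 20.0)
    sos = signal.butter(4, params.emg_band_low_hz, btype="highpass", fs=fs, output="sos")
    for _ in range(rng.integers(2, 5)):
        dur = int(rng.uniform(0.3, 1.0) * fs)
        dur = min(dur, n - 1)
        noise = signal.sosfiltfilt(sos, rng.standard_normal(dur))
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * burst_std
        env = np.hanning(dur)
        onset = rng.integers(0, n - dur)
        sig[onset:onset + dur] += env * noise
    return sig


def _mains_noise(rng: np.random.Generator, params: GeneratorParams) -> np.ndarray:
    """Mains sinusoid + 2nd/3rd harmonics at -10/-20 dB + low-level pink noise."""
    n = params.n_samples
    fs = params.sampling_rate_hz
    t = np.arange(n) / fs
    amp = 50.0  # µV, typical contaminated-channel line amplitude
    sig = amp * np.sin(2 * np.pi * params.mains_hz * t + rng.uniform(0, 2 * np.pi))
    nyq = fs / 2.0
    for k, db in ((2, -10.0), (3, -20.0)):
        if k * params.mains_hz < nyq:
            sig += amp * 10 ** (db / 20.0) * np.sin(
                2 * np.pi * k * params.mains_hz * t + rng.uniform(0, 2 * np.pi)
            )
    pink_std = (amp / np.sqrt(2)) * 10 ** (-params.snr_db / 20.0)
    sig += pink_std * _pink_noise(rng, n, params.background_exponent)
    return sig


def generate_segment(label: int, params: GeneratorParams | None = None,
                     seed: int = 0) -> SegmentRecord:
    """Generate one labeled segment; deterministic in ``(label, params, seed)``.

    Classes 2 and 3 share the same background realization for a given seed
    (class 2 = class-3 background + IED/HFO graphoelements), so pathological
    transients can be compared against their own background statistics.
    """
    params = params or GeneratorParams()
    if label not in CLASS_NAMES:
        raise GeneratorError(f"unknown label code {label!r}; expected one of {sorted(CLASS_NAMES)}")
    rng_bg = np.random.default_rng([int(seed), 0])
    rng_extra = np.random.default_rng([int(seed), 1])
    if label == 3:
        sig = _background(rng_bg, params)
    elif label == 2:
        sig = _background(rng_bg, params)
        _add_ieds(sig, rng_extra, params, sig.std())
        if params.hfo_enabled:
            _add_hfos(sig, rng_extra, params, sig.std())
    elif label == 1:
        sig = _muscle_artifact(rng_bg, params)
    else:
        sig = _mains_noise(rng_bg, params)
    return SegmentRecord(
        segment_id=f"seg-{label}-{seed}",
        samples=sig,
        sampling_rate_hz=params.sampling_rate_hz,
        label=label,
    )


def _child_seed(master_seed: int, index: int) -> int:
    """Stable per-segment seed derived from (master seed, index)."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % (2**31))


def generate_dataset(counts: dict[int, int], params: GeneratorParams | None = None,
                     seed: int = 0, n_patients: int = 8) -> list[SegmentRecord]:
    """Generate ``sum(counts.values())`` segments with the requested class counts.

    Segments get synthetic patient ids round-robin so patient-stratified fold
    plans can be exercised.  Fully reproducible: per-segment seeds are derived
    from ``(seed, running index)``.
    """
    params = params or GeneratorParams()
    for label, count in counts.items():
        if label not in CLASS_NAMES:
            raise GeneratorError(f"unknown label code {label!r}")
        if count < 0:
            raise GeneratorError(f"negative count {count} for class {label}")
    records: list[SegmentRecord] = []
    index = 0
    for label in sorted(counts):
        for _ in range(counts[label]):
            rec = generate_segment(label, params, seed=_child_seed(seed, index))
            rec.segment_id = f"seg{int(seed)}-{index:06d}"
            rec.patient_id = f"pat{index % n_patients:02d}"
            rec.institution = "siteA" if (index % n_patients) < n_patients // 2 else "siteB"
            records.append(rec)
            index += 1
    return records


def generate_recording(duration_s: float, ied_prevalence: float,
                       params: GeneratorParams | None = None,
                       seed: int = 0) -> list[SegmentRecord]:
    """Long pseudo-prospective recording cut into consecutive segments.

    Each segment is pathological (with IEDs) with probability
    ``ied_prevalence``, else physiological.  Labels are re-coded for this mode:
    0 = physiological, 1 = IED.
    """
    params = params or GeneratorParams()
    if not 0.0 <= ied_prevalence <= 1.0:
        raise GeneratorError(f"ied_prevalence {ied_prevalence} outside [0, 1]")
    if duration_s < params.segment_seconds:
        raise GeneratorError("duration_s shorter than one segment")
    n_segments = int(duration_s // params.segment_seconds)
    rng = np.random.default_rng([int(seed), 2])
    records = []
    for i in range(n_segments):
        is_ied = bool(rng.random() < ied_prevalence)
        rec = generate_segment(2 if is_ied else 3, params, seed=_child_seed(seed, i))
        rec.segment_id = f"rec{int(seed)}-{i:06d}"
        rec.label = 1 if is_ied else 0
        rec.patient_id = "prospective00"
        records.append(rec)
    return records
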