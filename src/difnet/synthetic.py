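"""Synthetic resting-state EEG cohorts with known class structure.

The generative model is the simplest one that exposes the statistical
structure the downstream pipeline is meant to detect: each channel is a sum
of a 1/f^alpha Gaussian background, one narrowband Gaussian process per
classical frequency band, and white measurement noise.  Band rhythms are
band-limited noise rather than fixed sinusoids deliberately: a sinusoid's
phase is stable across a subject's overlapping epochs, which would let a
classifier identify subjects (and hence labels, under trial-level
cross-validation) without using any class effect.  A diagnosis effect is
injected as a multiplicative shift of the band amplitudes of MDD subjects,
and that shift is itself scaled by the subject's (normalized) age and years
of education, so band power, differential entropy and demographic modulation
are all controlled and recoverable by construction.

Units are microvolts throughout; amplitudes are typical of scalp EEG
(prominent occipital-style alpha, weaker fast activity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectProfile",
    "SyntheticCohortConfig",
    "RawRecording",
    "generate_subject",
    "generate_cohort",
    "DEFAULT_CHANNELS",
    "BAND_CENTER_HZ",
]

#: 10-20 montage subset used by default (frontal-polar through temporal).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
)

#: Frequency ranges (Hz) of the classical EEG bands the generator emulates.
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}

# kept for callers that need a nominal per-band frequency (e.g. plots)
BAND_CENTER_HZ: dict[str, float] = {
    name: 0.5 * (lo + hi) for name, (lo, hi) in EEG_BANDS.items()
}


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    label: str               # "MDD" or "HC"
    age: int                 # years
    sex: int                 # 0 / 1 code
    education_years: int

    def __post_init__(self):
        if self.label not in ("MDD", "HC"):
            raise ValueError(f"label must be MDD or HC, got {self.label!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sex not in (0, 1):
            raise ValueError("sex code must be 0 or 1")
        if self.education_years < 0:
            raise ValueError("education_years must be non-negative")


def _default_band_amplitudes() -> dict[str, float]:
    return {"delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 5.0, "gamma": 2.0}


def _default_class_effect() -> dict[str, float]:
    # Relative MDD amplitude shift per band: strongest in beta, then alpha,
    # weakest in delta — matching the band ranking the classifier is meant
    # to recover.
    return {"delta": 0.05, "theta": 0.12, "alpha": 0.30, "beta": 0.40, "gamma": 0.18}


def _default_demo_modulation() -> dict[str, float]:
    return {"age": 0.5, "education": 0.5}


@dataclass
class SyntheticCohortConfig:
    """Generative parameters for one cohort.

    ``class_effect`` holds per-band relative amplitude shifts applied to MDD
    subjects; ``demo_modulation`` scales that shift linearly in the subject's
    min-max-normalized age and education, so with positive coefficients the
    MDD-vs-HC band-power gap grows with age and education.
    """

    n_mdd: int = 29
    n_hc: int = 24
    sampling_rate: float = 250.0
    duration: float = 300.0          # seconds per subject
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    spectral_exponent: float = 1.0   # 1/f^alpha background slope
    background_rms: float = 10.0     # µV RMS of the 1/f background
    band_amplitudes: dict[str, float] = field(default_factory=_default_band_amplitudes)
    class_effect: dict[str, float] = field(default_factory=_default_class_effect)
    demo_modulation: dict[str, float] = field(default_factory=_default_demo_modulation)
    noise_sd: float = 2.0            # µV white measurement noise
    age_range: tuple[int, int] = (18, 65)
    education_range: tuple[int, int] = (6, 22)
    # Optional class-conditional demographic ranges; None falls back to the
    # shared ranges above.  Used to build cohorts where demographics alone
    # carry class signal.
    mdd_age_range: tuple[int, int] | None = None
    hc_age_range: tuple[int, int] | None = None
    mdd_education_range: tuple[int, int] | None = None
    hc_education_range: tuple[int, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_mdd < 1 or self.n_hc < 1:
            raise ValueError("n_mdd and n_hc must each be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration * self.sampling_rate < 1:
            raise ValueError("duration must cover at least one sample")
        for name in self.band_amplitudes:
            if name not in BAND_CENTER_HZ:
                raise ValueError(f"unknown band name {name!r}")
        for name in self.class_effect:
            if name not in BAND_CENTER_HZ:
                raise ValueError(f"unknown band name {name!r}")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be non-negative")


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts, channels x samples."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    sampling_rate: float
    profile: SubjectProfile
    history: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, n_samples) matching channel_names")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains NaN/Inf")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def _normalize01(x: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return 0.0
    return float(np.clip((x - lo) / (hi - lo), 0.0, 1.0))


def effect_scale(profile: SubjectProfile, config: SyntheticCohortConfig) -> float:
    """Demographic multiplier on the MDD class effect (1 for HC subjects)."""
    if profile.label != "MDD":
        return 0.0
    a = _normalize01(profile.age, *config.age_range)
    e = _normalize01(profile.education_years, *config.education_range)
    mod = config.demo_modulation
    return 1.0 + mod.get("age", 0.0) * a + mod.get("education", 0.0) * e


def _one_over_f(rng: np.random.Generator, n_channels: int, n_samples: int,
                alpha: float, rms: float) -> np.ndarray:
    if rms == 0.0 or n_samples < 2:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    shaped = np.fft.irfft(spec * shaping[None, :], n=n_samples, axis=1)
    cur = shaped.std(axis=1, keepdims=True)
    cur[cur == 0] = 1.0
    return shaped / cur * rms


def generate_subject(profile: SubjectProfile, config: SyntheticCohortConfig,
                     seed: int) -> RawRecording:
    """Simulate one subject's multichannel recording; bit-reproducible in ``seed``."""
    config.validate()
    rng = np.random.default_rng(seed)
    n_ch = len(config.channel_names)
    n = int(round(config.duration * config.sampling_rate))
    if n < 1:
        raise ValueError("duration shorter than one sample")

    data = _one_over_f(rng, n_ch, n, config.spectral_exponent, config.background_rms)
    scale = effect_scale(profile, config)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sampling_rate)
    for band, amp in config.band_amplitudes.items():
        amp_eff = amp * (1.0 + config.class_effect.get(band, 0.0) * scale)
        if amp_eff == 0.0:
            continue
        lo, hi = EEG_BANDS[band]
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            continue
        # narrowband Gaussian rhythm: FFT-masked white noise, scaled to the
        # RMS of a sinusoid of amplitude amp_eff (amp_eff / sqrt(2))
        spec = np.fft.rfft(rng.standard_normal((n_ch, n)), axis=1)
        spec[:, ~mask] = 0.0
        rhythm = np.fft.irfft(spec, n=n, axis=1)
        rms = rhythm.std(axis=1, keepdims=True)
        rms[rms == 0] = 1.0
        data += rhythm / rms * (amp_eff / np.sqrt(2.0))
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=(n_ch, n))
    return RawRecording(data=data, channel_names=tuple(config.channel_names),
                        sampling_rate=config.sampling_rate, profile=profile)


def _draw_profiles(config: SyntheticCohortConfig,
                   rng: np.random.Generator) -> list[SubjectProfile]:
    profiles = []
    specs = [("MDD", config.n_mdd, config.mdd_age_range, config.mdd_education_range),
             ("HC", config.n_hc, config.hc_age_range, config.hc_education_range)]
    idx = 0
    for label, count, age_range, edu_range in specs:
        age_lo, age_hi = age_range or config.age_range
        edu_lo, edu_hi = edu_range or config.education_range
        for _ in range(count):
            idx += 1
            profiles.append(SubjectProfile(
                subject_id=f"sub-{idx:03d}",
                label=label,
                age=int(rng.integers(age_lo, age_hi + 1)),
                sex=int(rng.integers(0, 2)),
                education_years=int(rng.integers(edu_lo, edu_hi + 1)),
            ))
    return profiles


def generate_cohort(config: SyntheticCohortConfig
                    ) -> tuple[list[RawRecording], pd.DataFrame]:
    """Simulate a full cohort; returns recordings plus a demographics table."""
    config.validate()
    if config.n_mdd + config.n_hc < 2:
        raise ValueError("cohort needs at least two subjects")
    seq = np.random.SeedSequence(config.seed)
    profile_seed, *subject_seeds = seq.spawn(1 + config.n_mdd + config.n_hc)
    profiles = _draw_profiles(config, np.random.default_rng(profile_seed))
    recordings = [
        generate_subject(p, config, seed=int(s.generate_state(1)[0] % (2**31)))
        for p, s in zip(profiles, subject_seeds)
    ]
    demographics = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "label": [p.label for p in profiles],
            "age": [p.age for p in profiles],
            "sex": [p.sex for p in profiles],
            "education_years": [p.education_years for p in profiles],
        }
    )
    return recordings, demographics


def demographics_only_config(n_mdd: int, n_hc: int, seed: int = 0,
                             duration: float = 20.0) -> SyntheticCohortConfig:
    """Cohort in which the EEG carries no class signal but demographics do.

    Every recording is pure white measurement noise — identically
    distributed across subjects and epochs, so there is no class effect and
    no subject-specific spectral fingerprint for a classifier to exploit
    under trial-level cross-validation.  The two diagnostic groups are drawn
    from disjoint age and education ranges, so only the demographic pathway
    can separate them.
    """
    return SyntheticCohortConfig(
        n_mdd=n_mdd, n_hc=n_hc, duration=duration, seed=seed,
        class_effect={b: 0.0 for b in BAND_CENTER_HZ},
        band_amplitudes={b: 0.0 for b in BAND_CENTER_HZ},
        background_rms=0.0, noise_sd=10.0,
        mdd_age_range=(45, 65), hc_age_range=(18, 35),
        mdd_education_range=(6, 11), hc_education_range=(16, 22),
    )


def beta_only_config(n_mdd: int, n_hc: int, seed: int = 0,
                     duration: float = 20.0,
                     effect: float = 0.4) -> SyntheticCohortConfig:
    """Cohort whose diagnosis effect is confined to the beta band."""
    ce = {b: 0.0 for b in BAND_CENTER_HZ}
    ce["beta"] = effect
    return SyntheticCohortConfig(n_mdd=n_mdd, n_hc=n_hc, duration=duration,
                                 seed=seed, class_effect=ce)
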