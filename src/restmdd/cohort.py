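"""Synthetic clinical-protocol EEG cohorts.

Real resting-state recordings from depressed patients are rarely shareable,
so every downstream stage of this package is exercised on simulated cohorts
that carry the statistical structure the analysis assumes: per-band scalp
power profiles with a 1/f background, an eyes-closed alpha boost, a
configurable multiplicative group effect for the MDD class, the clinical
recording protocol (alternating eyes-open/eyes-closed rest, photic
stimulation at five flash frequencies, hyperventilation) encoded as
annotations, and the usual artifact classes (blinks, mains hum, drift).

The signals are sums of band-limited Gaussian noise — no dipole or forward
modelling — which is sufficient for testing spectral and complexity features
but does not emulate evoked responses or true cortical dynamics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .recording import CHANNELS_1020, Annotation, EEGRecording

GROUP_MDD = "MDD"
GROUP_HEALTHY = "HEALTHY"

EYES_OPEN = "EYES_OPEN"
EYES_CLOSED = "EYES_CLOSED"
PHOTIC = "PHOTIC"
HYPERVENTILATION = "HYPERVENTILATION"

#: Flash frequencies of the photic-stimulation block, in protocol order (Hz).
PHOTIC_FREQUENCIES = (4.0, 8.0, 16.0, 24.0, 30.0)

#: Nominal EEG band edges in Hz; gamma is capped by the 40 Hz analysis filter.
BAND_RANGES = {
    "delta": (0.1, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}
BAND_NAMES = tuple(BAND_RANGES)

_MIN_RESTING_PERIOD = 10.0  # seconds; shorter periods starve the wavelet depth

# Cohort demography used when sampling subject metadata: per group, the
# fraction of female subjects and the age mean/SD per sex (years).
_DEMOGRAPHY = {
    GROUP_HEALTHY: {"p_female": 32 / 70, "F": (35.88, 9.96), "M": (36.16, 11.35)},
    GROUP_MDD: {"p_female": 37 / 70, "F": (36.86, 10.22), "M": (45.24, 12.10)},
}


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str
    age: int
    sex: str
    seed: int

    def __post_init__(self) -> None:
        if self.group not in (GROUP_MDD, GROUP_HEALTHY):
            raise ValueError(f"group must be MDD or HEALTHY, got {self.group!r}")
        if self.age <= 0:
            raise ValueError("age must be a positive integer")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass(frozen=True)
class ProtocolPhase:
    label: str
    duration: float
    flash_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if self.label == PHOTIC and self.flash_frequency is None:
            raise ValueError("PHOTIC phases need a flash_frequency")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered recording phases: rest, photic stimulation, hyperventilation."""

    phases: tuple[ProtocolPhase, ...]

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    @property
    def resting_phases(self) -> list[ProtocolPhase]:
        return [p for p in self.phases if p.label in (EYES_OPEN, EYES_CLOSED)]


@dataclass
class SpectralProfile:
    """Target per-band scalp power and the group/condition modulations.

    ``band_weights`` are band variances in μV². ``group_effect`` multiplies
    the MDD group's band variances (identity = no group difference, i.e. a
    null cohort). ``ec_alpha_gain`` multiplies alpha variance during
    eyes-closed periods, emulating the posterior alpha rhythm. Between-subject
    heterogeneity is lognormal: a per-subject factor shared across channels
    (``subject_sigma``, log-scale SD) and an independent per-channel factor
    (``channel_sigma``). ``spatial_rho`` is the fraction of each band's
    variance carried by a few latent band-limited sources
    (``sources_per_band``) projected to the scalp through signed random
    per-subject topographies, emulating volume conduction: real scalp
    channels are strongly correlated and in-band activity is approximately
    low-rank, which is what lets ICA isolate artifact components. The
    remainder is channel-independent noise; per-channel band variances equal
    the configured weights regardless of ``spatial_rho``.
    """

    band_weights: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 20.0, "theta": 10.0, "alpha": 25.0, "beta": 8.0, "gamma": 4.0
        }
    )
    one_over_f_exponent: float = 1.0
    background_weight: float = 10.0
    ec_alpha_gain: float = 1.5
    group_effect: dict[str, float] = field(
        default_factory=lambda: {"alpha": 1.3, "gamma": 0.8}
    )
    subject_sigma: float = 0.12
    channel_sigma: float = 0.08
    spatial_rho: float = 0.85
    sources_per_band: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.spatial_rho <= 1):
            raise ValueError("spatial_rho must be within [0, 1]")
        if self.sources_per_band < 1:
            raise ValueError("sources_per_band must be >= 1")
        unknown = set(self.band_weights) - set(BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown bands in band_weights: {sorted(unknown)}")
        if any(w < 0 for w in self.band_weights.values()):
            raise ValueError("band weights must be non-negative")
        if self.ec_alpha_gain < 1:
            raise ValueError("ec_alpha_gain must be >= 1")
        if unknown := set(self.group_effect) - set(BAND_NAMES):
            raise ValueError(f"unknown bands in group_effect: {sorted(unknown)}")

    def full_group_effect(self) -> dict[str, float]:
        return {b: self.group_effect.get(b, 1.0) for b in BAND_NAMES}


@dataclass
class ArtifactSpec:
    """Amplitudes/rates of the injected artifact classes; zero disables one."""

    blink_rate: float = 6.0  # events per minute
    blink_amplitude: float = 120.0  # μV at Fp1/Fp2
    line_noise_amplitude: float = 5.0  # μV of 50 Hz mains hum
    drift_amplitude: float = 20.0  # μV of sub-0.1 Hz wander

    def __post_init__(self) -> None:
        for name in ("blink_rate", "blink_amplitude",
                     "line_noise_amplitude", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def is_null(self) -> bool:
        return (
            self.blink_rate * self.blink_amplitude == 0
            and self.line_noise_amplitude == 0
            and self.drift_amplitude == 0
        )

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(0.0, 0.0, 0.0, 0.0)


def make_default_protocol(
    total_resting_seconds: float = 100.0,
    photic_seconds: float = 10.0,
    hyperventilation_seconds: float = 30.0,
) -> ProtocolSpec:
    """Build the clinical protocol: 5 alternating EO/EC rests, then photic
    flashes at 4/8/16/24/30 Hz, then hyperventilation.

    The resting section is divided into five equal periods starting with
    eyes open. ``total_resting_seconds`` must allow at least 10 s per period.
    """
    if total_resting_seconds < 5 * _MIN_RESTING_PERIOD:
        raise ValueError(
            f"total_resting_seconds={total_resting_seconds} cannot fit five "
            f"resting periods of at least {_MIN_RESTING_PERIOD:.0f} s each "
            f"(need >= {5 * _MIN_RESTING_PERIOD:.0f} s)"
        )
    period = total_resting_seconds / 5.0
    phases = [
        ProtocolPhase(EYES_OPEN if i % 2 == 0 else EYES_CLOSED, period)
        for i in range(5)
    ]
    phases += [ProtocolPhase(PHOTIC, photic_seconds, flash_frequency=f)
               for f in PHOTIC_FREQUENCIES]
    phases.append(ProtocolPhase(HYPERVENTILATION, hyperventilation_seconds))
    return ProtocolSpec(tuple(phases))


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float, rows: int | None = None) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz.

    With ``rows`` set, returns that many independent rows filtered in one
    vectorized pass.
    """
    shape = n if rows is None else (rows, n)
    x = rng.standard_normal(shape)
    nyq = fs / 2.0
    lo = max(lo, 0.01)
    hi = min(hi, nyq * 0.99)
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", output="sos", fs=fs)
    y = scipy.signal.sosfiltfilt(sos, x, axis=-1)
    sd = y.std(axis=-1, keepdims=rows is not None)
    return np.divide(y, sd, out=y, where=sd > 0)


def _random_topographies(rng: np.random.Generator, n_ch: int, k: int,
                         target_var: np.ndarray) -> np.ndarray:
    """Signed random scalp projections for ``k`` latent sources.

    Dipolar cortical sources project to the scalp with both polarities, so
    topography entries are zero-mean Gaussian (signed) — this keeps the
    shared variance largely intact under average referencing. Columns are
    scaled per channel so the sources jointly contribute exactly
    ``target_var[c]`` at channel ``c``.
    """
    topo = rng.standard_normal((n_ch, k))
    norm = np.sqrt(np.sum(topo**2, axis=1))
    norm[norm < 1e-12] = 1.0
    return topo * (np.sqrt(target_var) / norm)[:, None]


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, rows: int | None = None) -> np.ndarray:
    """Unit-variance 1/f^exponent background noise via spectral shaping."""
    shape = n if rows is None else (rows, n)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    y = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = y.std(axis=-1, keepdims=rows is not None)
    return np.divide(y, sd, out=y, where=sd > 0)


def protocol_annotations(protocol: ProtocolSpec) -> list[Annotation]:
    anns = []
    t = 0.0
    for phase in protocol.phases:
        label = phase.label
        if phase.label == PHOTIC:
            label = f"{PHOTIC}_{phase.flash_frequency:g}HZ"
        anns.append(Annotation(onset=t, duration=phase.duration, label=label))
        t += phase.duration
    return anns


def synth_recording(
    profile: SubjectProfile,
    spectral: SpectralProfile | None = None,
    protocol: ProtocolSpec | None = None,
    artifacts: ArtifactSpec | None = None,
    fs: float = 200.0,
    channel_names: list[str] | None = None,
) -> EEGRecording:
    """Simulate one subject's recording under the clinical protocol.

    Each channel is a sum over the five bands of band-limited Gaussian noise
    with variance equal to the subject-, channel- and group-adjusted band
    weight, plus a 1/f background. Eyes-closed periods multiply the alpha
    variance by ``ec_alpha_gain``. Identical ``profile.seed`` gives
    bit-identical output. Artifacts, if requested, are injected last.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    spectral = spectral if spectral is not None else SpectralProfile()
    protocol = protocol if protocol is not None else make_default_protocol()
    channel_names = list(channel_names) if channel_names is not None else list(CHANNELS_1020)

    rng = np.random.default_rng(profile.seed)
    n_ch = len(channel_names)
    n = int(round(protocol.total_duration * fs))

    group_mult = (spectral.full_group_effect() if profile.group == GROUP_MDD
                  else {b: 1.0 for b in BAND_NAMES})
    # Between-subject heterogeneity: shared-across-channels and per-channel
    # lognormal factors on each band's variance.
    subj_factor = {b: float(np.exp(rng.normal(0.0, spectral.subject_sigma)))
                   for b in BAND_NAMES}
    chan_factor = {b: np.exp(rng.normal(0.0, spectral.channel_sigma, size=n_ch))
                   for b in BAND_NAMES}

    # Eyes-closed amplitude envelope for the alpha band.
    ec_env = np.ones(n)
    t0 = 0.0
    for phase in protocol.phases:
        i0, i1 = int(round(t0 * fs)), int(round((t0 + phase.duration) * fs))
        if phase.label == EYES_CLOSED:
            ec_env[i0:i1] = np.sqrt(spectral.ec_alpha_gain)
        t0 += phase.duration

    data = np.zeros((n_ch, n))
    for band, (lo, hi) in BAND_RANGES.items():
        base = spectral.band_weights.get(band, 0.0) * group_mult[band] * subj_factor[band]
        if base == 0.0:
            continue
        rho = spectral.spatial_rho
        var_c = base * chan_factor[band]  # per-channel target variance
        band_sig = np.zeros((n_ch, n))
        if rho > 0:
            # Low-rank volume-conducted part: a few latent sources with
            # signed random topographies, scaled so the shared part
            # contributes exactly rho * var_c at every channel.
            k = spectral.sources_per_band
            topo = _random_topographies(rng, n_ch, k, rho * var_c)
            band_sig += topo @ _band_noise(rng, n, fs, lo, hi, rows=k)
        if rho < 1:
            own = _band_noise(rng, n, fs, lo, hi, rows=n_ch)
            band_sig += np.sqrt((1.0 - rho) * var_c)[:, None] * own
        if band == "alpha":
            band_sig = band_sig * ec_env[None, :]
        data += band_sig
    if spectral.background_weight > 0:
        # The 1/f background is treated like the bands: mostly
        # volume-conducted (low-rank shared part) plus independent sensor
        # noise, with per-channel variance equal to background_weight.
        rho = spectral.spatial_rho
        if rho > 0:
            k = spectral.sources_per_band
            topo = _random_topographies(
                rng, n_ch, k,
                np.full(n_ch, float(spectral.background_weight)))
            data += (topo * np.sqrt(rho)) @ _pink_noise(
                rng, n, fs, spectral.one_over_f_exponent, rows=k)
        if rho < 1:
            data += (np.sqrt((1.0 - rho) * spectral.background_weight)
                     * _pink_noise(rng, n, fs, spectral.one_over_f_exponent,
                                   rows=n_ch))

    rec = EEGRecording(
        data=data, fs=fs, channel_names=channel_names,
        annotations=protocol_annotations(protocol),
        subject_id=profile.subject_id, group=profile.group,
        age=profile.age, sex=profile.sex,
    )
    if artifacts is not None and not artifacts.is_null():
        rec = inject_artifacts(rec, artifacts, seed=profile.seed + 1)
    return rec


def draw_subject_profiles(
    n_mdd: int, n_healthy: int, seed: int
) -> list[SubjectProfile]:
    """Sample subject metadata matching the cohort's age/sex distribution.

    Ages are normal per group and sex (truncated at 18); the female fraction
    per group follows the cohort demography table.
    """
    if n_mdd < 1 or n_healthy < 1:
        raise ValueError(
            f"both groups need at least one subject (got n_mdd={n_mdd}, "
            f"n_healthy={n_healthy})"
        )
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_mdd + n_healthy)]
    profiles: list[SubjectProfile] = []
    idx = 0
    for group, count in ((GROUP_MDD, n_mdd), (GROUP_HEALTHY, n_healthy)):
        demo = _DEMOGRAPHY[group]
        for i in range(count):
            sex = "F" if rng.random() < demo["p_female"] else "M"
            mean, sd = demo[sex]
            age = 0
            while age < 18:
                age = int(round(rng.normal(mean, sd)))
            profiles.append(SubjectProfile(
                subject_id=f"{'mdd' if group == GROUP_MDD else 'hc'}_{i + 1:03d}",
                group=group, age=age, sex=sex, seed=child_seeds[idx],
            ))
            idx += 1
    return profiles


def synth_cohort(
    n_mdd: int = 70,
    n_healthy: int = 70,
    spectral: SpectralProfile | None = None,
    artifacts: ArtifactSpec | None = None,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    fs: float = 200.0,
) -> list[EEGRecording]:
    """Simulate a full cohort; MDD recordings carry the group effect."""
    profiles = draw_subject_profiles(n_mdd, n_healthy, seed)
    return [
        synth_recording(p, spectral=spectral, protocol=protocol,
                        artifacts=artifacts, fs=fs)
        for p in profiles
    ]


def inject_artifacts(
    rec: EEGRecording, artifacts: ArtifactSpec, seed: int
) -> EEGRecording:
    """Add blinks (frontal transients), 50 Hz mains hum, and slow drift.

    Every injected blink is annotated (``ARTIFACT_BLINK``) so tests can
    compare detected against injected events. An all-zero spec returns an
    identical copy.
    """
    out = rec.copy()
    if artifacts.is_null():
        return out
    rng = np.random.default_rng(seed)
    fs, n, n_ch = rec.fs, rec.n_samples, rec.n_channels

    if artifacts.line_noise_amplitude > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        hum = np.sin(2 * np.pi * 50.0 * t + phase)
        gains = rng.uniform(0.5, 1.5, size=n_ch)  # channel-dependent coupling
        out.data += artifacts.line_noise_amplitude * gains[:, None] * hum[None, :]

    if artifacts.drift_amplitude > 0:
        walk = np.cumsum(rng.standard_normal((n_ch, n)), axis=-1)
        sos = scipy.signal.butter(2, 0.05, btype="lowpass", output="sos", fs=fs)
        slow = scipy.signal.sosfiltfilt(sos, walk, axis=-1)
        sd = slow.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        out.data += artifacts.drift_amplitude * slow / sd

    if artifacts.blink_rate > 0 and artifacts.blink_amplitude > 0:
        blink_dur = 0.3  # seconds
        n_blinks = rng.poisson(artifacts.blink_rate * rec.duration / 60.0)
        width = int(round(blink_dur * fs))
        shape = np.hanning(width)
        topo = np.zeros(n_ch)
        for name, w in (("Fp1", 1.0), ("Fp2", 1.0), ("F7", 0.35), ("F3", 0.3),
                        ("Fz", 0.25), ("F4", 0.3), ("F8", 0.35)):
            if name in rec.channel_names:
                topo[rec.channel_names.index(name)] = w
        onsets = np.sort(rng.uniform(0.5, rec.duration - 0.5 - blink_dur,
                                     size=n_blinks))
        for onset in onsets:
            i0 = int(round(onset * fs))
            out.data[:, i0:i0 + width] += (
                artifacts.blink_amplitude * topo[:, None] * shape[None, :width]
            )
            out.annotations.append(
                Annotation(onset=float(onset), duration=blink_dur,
                           label="ARTIFACT_BLINK"))
    return out
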