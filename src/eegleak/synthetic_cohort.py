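"""Synthetic multi-subject EEG cohorts with controllable subject fingerprints.

The generator produces resting-state-like multi-channel signals built from
four canonical band oscillations (delta, theta, alpha, beta) on top of a
1/f-shaped noise floor.  Two knobs control the statistical structure that
matters for leakage audits:

``fingerprint_strength``
    Standard deviation of subject-level deviations in band power (log scale)
    and band peak frequency.  At 0, all subjects are statistically
    exchangeable; at large values, segments from one subject are far more
    similar to each other than to segments from other subjects.

``disease_effect``
    A group-level shift in theta-band power (slowing-like signal): the two
    diagnostic groups receive base theta power ``p0 +/- disease_effect / 2``.
    This is the *real* signal a classifier ought to learn.

Subject-level amplitude jitter is mean-power-normalised
(``exp(sigma*Z - sigma**2)`` multiplies amplitude, so the expected power
multiplier is exactly 1); the group-mean band-power difference therefore
estimates ``disease_effect`` without bias at any fingerprint strength.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BANDS",
    "DISEASE_BAND",
    "CohortConfig",
    "SubjectProfile",
    "Recording",
    "generate_cohort",
    "inject_events",
    "balance_nonevent",
    "LabeledPools",
    "write_npz",
    "read_npz",
    "write_edf",
    "read_edf",
]

# Canonical rhythm bands: name -> (centre frequency Hz, base band power).
# Powers are in squared signal units (arbitrary, microvolt-scale).
BANDS = {
    "delta": (2.0, 1.0),
    "theta": (6.0, 0.5),
    "alpha": (10.0, 1.0),
    "beta": (20.0, 0.2),
}
#: Band that carries the group-level disease signal (slowing-like theta shift).
DISEASE_BAND = "theta"

#: Integration ranges (Hz) used when estimating band power from a periodogram.
BAND_RANGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


class InvalidConfigError(ValueError):
    """Raised for physically meaningless cohort parameters."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic two-group resting EEG cohort."""

    n_subjects_per_group: int = 20
    n_channels: int = 19
    fs: float = 250.0
    duration: float = 300.0
    fingerprint_strength: float = 0.5
    disease_effect: float = 0.0
    noise_level: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_channels < 1:
            raise InvalidConfigError("subject and channel counts must be >= 1")
        if self.fs <= 0:
            raise InvalidConfigError(f"fs must be positive, got {self.fs}")
        if self.duration <= 0:
            raise InvalidConfigError(
                f"duration must be positive, got {self.duration}"
            )
        for name in ("fingerprint_strength", "disease_effect", "noise_level"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject idiosyncrasies, drawn once and fixed across all segments.

    ``band_powers`` has shape (n_bands, n_channels) and already includes the
    group-level disease shift; ``peak_frequencies`` is one frequency per band
    (subject-global, as e.g. the individual alpha peak is); ``mixing`` is the
    per-subject channel-mixing matrix applied to the noise floor (a spatial
    fingerprint, identity at fingerprint_strength 0).
    """

    subject_id: str
    group_label: int
    band_powers: np.ndarray
    peak_frequencies: np.ndarray
    phases: np.ndarray  # (n_bands, n_channels) oscillator phases
    mixing: np.ndarray  # (n_channels, n_channels)


@dataclass
class Recording:
    """One subject's multi-channel EEG time-series."""

    subject_id: str
    group_label: int
    signal: np.ndarray  # (n_channels, n_samples)
    fs: float
    event_intervals: list[tuple[float, float]] = field(default_factory=list)
    profile: SubjectProfile | None = None

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_profile(
    rng: np.random.Generator,
    subject_id: str,
    group_label: int,
    config: CohortConfig,
) -> SubjectProfile:
    sigma = config.fingerprint_strength
    n_bands = len(BANDS)
    nc = config.n_channels

    base_power = np.empty(n_bands)
    centre = np.empty(n_bands)
    for b, (name, (f0, p0)) in enumerate(BANDS.items()):
        centre[b] = f0
        if name == DISEASE_BAND:
            shift = config.disease_effect / 2.0
            p0 = p0 + shift if group_label == 1 else p0 - shift
            p0 = max(p0, 0.0)
        base_power[b] = p0

    # Amplitude jitter exp(sigma*Z - sigma^2): expected *power* multiplier 1.
    z = rng.standard_normal((n_bands, nc))
    amp_jitter = np.exp(sigma * z - sigma**2)
    band_powers = base_power[:, None] * amp_jitter**2

    peak = centre + rng.normal(0.0, 0.5 * sigma, size=n_bands)
    peak = np.clip(peak, 0.5, None)

    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_bands, nc))

    mixing = np.eye(nc)
    if sigma > 0:
        g = rng.standard_normal((nc, nc)) / np.sqrt(nc)
        mixing = mixing + 0.1 * sigma * g
        # keep the noise variance scale: unit-norm rows
        mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)

    return SubjectProfile(
        subject_id=subject_id,
        group_label=group_label,
        band_powers=band_powers,
        peak_frequencies=peak,
        phases=phases,
        mixing=mixing,
    )


_NOISE_F_LO = 0.5  # Hz: no noise power below this
_NOISE_F_KNEE = 1.0  # Hz: 1/f shaping above; tapered ramp in between


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float
) -> np.ndarray:
    """Per-channel pink (1/f-PSD) noise with unit expected variance.

    The spectrum is band-limited below ~0.5 Hz: unbounded low-frequency
    power would give every recording a persistent realized slow-wave
    profile shared by all of its segments — an accidental subject
    fingerprint that must vanish at fingerprint_strength 0.  For the same
    reason the output is normalised by the *expected* variance of the
    shaping filter, not the realised one (a realised-std normalisation
    couples all segments of a recording through a common scale factor).
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    hi = freqs >= _NOISE_F_KNEE
    shape[hi] = freqs[hi] ** -0.5
    ramp = (freqs >= _NOISE_F_LO) & (~hi)
    if ramp.any():
        knee_gain = _NOISE_F_KNEE**-0.5
        shape[ramp] = knee_gain * (freqs[ramp] - _NOISE_F_LO) / (
            _NOISE_F_KNEE - _NOISE_F_LO
        )
    spec *= shape
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    # expected variance of irfft(rfft(white) * shape), via Parseval
    weight = np.full_like(shape, 2.0)
    weight[0] = 1.0
    if n_samples % 2 == 0:
        weight[-1] = 1.0
    expected_var = (weight * shape**2).sum() / n_samples
    if expected_var <= 0:
        return np.zeros_like(out)
    return out / np.sqrt(expected_var)


def _render_signal(
    profile: SubjectProfile,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    sig = np.zeros((config.n_channels, n))
    for b in range(len(BANDS)):
        amp = np.sqrt(2.0 * profile.band_powers[b])  # power A^2/2 -> A
        omega_t = 2.0 * np.pi * profile.peak_frequencies[b] * t
        # sin(wt + phi) = cos(phi) sin(wt) + sin(phi) cos(wt): evaluate the
        # oscillator once per band, fan out per channel via outer products
        sin_wt, cos_wt = np.sin(omega_t), np.cos(omega_t)
        phi = profile.phases[b]
        sig += np.outer(amp * np.cos(phi), sin_wt)
        sig += np.outer(amp * np.sin(phi), cos_wt)
    if config.noise_level > 0:
        noise = _one_over_f_noise(rng, config.n_channels, n, config.fs)
        sig += config.noise_level * (profile.mixing @ noise)
    return sig


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """Generate a balanced two-group cohort, deterministically from the seed.

    Subject profiles are drawn from dedicated child streams before any
    time-series noise, so cohort membership (who the subjects *are*) is
    stable under changes of ``duration``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    n_total = 2 * config.n_subjects_per_group
    children = root.spawn(n_total)

    recordings: list[Recording] = []
    for i, child in enumerate(children):
        group = i % 2  # alternate groups: balanced by construction
        profile_ss, noise_ss = child.spawn(2)
        profile = _draw_profile(
            np.random.default_rng(profile_ss), f"sub-{i:03d}", group, config
        )
        signal = _render_signal(profile, config, np.random.default_rng(noise_ss))
        recordings.append(
            Recording(
                subject_id=profile.subject_id,
                group_label=group,
                signal=signal,
                fs=config.fs,
                profile=profile,
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# transient events (seizure-like bursts)
# ---------------------------------------------------------------------------

class EventPackingError(ValueError):
    pass


_EVENT_FREQ = 3.0  # Hz, ictal-like slow oscillatory burst
_PLACEMENT_ATTEMPTS = 10_000


def inject_events(
    recording: Recording,
    n_events: int,
    event_duration: float,
    event_strength: float,
    seed: int,
) -> Recording:
    """Return a copy of the recording with high-amplitude ~3 Hz bursts added.

    Burst amplitude per channel is ``event_strength`` scaled by the subject's
    delta-band amplitude jitter, so event morphology is subject-specific
    whenever the cohort has fingerprints.  Intervals are placed by rejection
    sampling and never overlap.
    """
    if n_events == 0:
        return recording
    total_needed = n_events * event_duration
    if total_needed > recording.duration:
        raise EventPackingError(
            f"requested {total_needed:.1f} s of events but only "
            f"{recording.duration:.1f} s of recording is available"
        )
    rng = np.random.default_rng(seed)
    placed: list[tuple[float, float]] = list(recording.event_intervals)
    for _ in range(n_events):
        for attempt in range(_PLACEMENT_ATTEMPTS):
            start = rng.uniform(0.0, recording.duration - event_duration)
            end = start + event_duration
            if all(end <= s or start >= e for s, e in placed):
                placed.append((start, end))
                break
        else:
            raise EventPackingError(
                f"could not place {n_events} x {event_duration:.1f} s events "
                f"in {recording.duration:.1f} s without overlap"
            )
    new_intervals = sorted(placed[len(recording.event_intervals):])

    signal = recording.signal.copy()
    nc = recording.n_channels
    if recording.profile is not None:
        base = np.sqrt(2.0 * recording.profile.band_powers[0])
        mod = base / max(base.mean(), 1e-12)  # subject-specific spatial shape
    else:
        mod = np.ones(nc)
    for start, end in new_intervals:
        i0 = int(round(start * recording.fs))
        i1 = int(round(end * recording.fs))
        t = np.arange(i1 - i0) / recording.fs
        envelope = np.hanning(i1 - i0)
        phase = rng.uniform(0, 2 * np.pi, size=nc)
        burst = (
            event_strength
            * mod[:, None]
            * envelope[None, :]
            * np.sin(2 * np.pi * _EVENT_FREQ * t[None, :] + phase[:, None])
        )
        signal[:, i0:i1] += burst

    return replace_recording(
        recording,
        signal=signal,
        event_intervals=sorted(recording.event_intervals + new_intervals),
    )


def replace_recording(recording: Recording, **changes) -> Recording:
    return replace(recording, **changes)


# ---------------------------------------------------------------------------
# event / non-event balancing
# ---------------------------------------------------------------------------

@dataclass
class LabeledPools:
    """Equal-duration event and non-event signal pools from one recording.

    Each pool is a list of ``(start_s, end_s, signal_chunk)`` with chunks of
    shape (n_channels, samples); total sample counts of the two pools are
    equal to the nearest sample.
    """

    event: list[tuple[float, float, np.ndarray]]
    nonevent: list[tuple[float, float, np.ndarray]]
    fs: float

    def total_samples(self, pool: str) -> int:
        return sum(c.shape[1] for _, _, c in getattr(self, pool))


def balance_nonevent(recording: Recording) -> LabeledPools:
    """Cut equal-duration event and non-event pools from one recording.

    Mimics the balanced construction used in within-subject event detection:
    the non-event pool is taken from the *beginning* of the recording
    (skipping event spans) and truncated to the total event duration.
    """
    fs = recording.fs
    events = sorted(recording.event_intervals)
    if not events:
        warnings.warn("recording has no events; returning empty pools")
        return LabeledPools(event=[], nonevent=[], fs=fs)

    event_pool = []
    total_event_samples = 0
    for start, end in events:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        event_pool.append((start, end, recording.signal[:, i0:i1]))
        total_event_samples += i1 - i0

    # complement of event spans, scanned from the start of the recording
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for start, end in events:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        if i0 > cursor:
            gaps.append((cursor, i0))
        cursor = max(cursor, i1)
    if cursor < recording.n_samples:
        gaps.append((cursor, recording.n_samples))

    available = sum(i1 - i0 for i0, i1 in gaps)
    if available < total_event_samples:
        raise ValueError(
            f"recording holds {total_event_samples / fs:.1f} s of events but "
            f"only {available / fs:.1f} s of non-event time"
        )

    nonevent_pool = []
    remaining = total_event_samples
    for i0, i1 in gaps:
        if remaining <= 0:
            break
        take = min(i1 - i0, remaining)
        nonevent_pool.append(
            (i0 / fs, (i0 + take) / fs, recording.signal[:, i0:i0 + take])
        )
        remaining -= take
    return LabeledPools(event=event_pool, nonevent=nonevent_pool, fs=fs)


# ---------------------------------------------------------------------------
# interchange: npz container with JSON sidecar, and minimal EDF
# ---------------------------------------------------------------------------

def write_npz(recordings: list[Recording], directory) -> None:
    """Write a cohort as compressed arrays plus a JSON sidecar per recording.

    Event intervals are stored as half-open ``[start, end)`` seconds.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        np.savez_compressed(directory / f"{rec.subject_id}.npz", signal=rec.signal)
        meta = {
            "subject_id": rec.subject_id,
            "group": int(rec.group_label),
            "fs": rec.fs,
            "events": [[float(s), float(e)] for s, e in rec.event_intervals],
        }
        (directory / f"{rec.subject_id}.json").write_text(
            json.dumps(meta, indent=1)
        )


def read_npz(directory) -> list[Recording]:
    from pathlib import Path

    directory = Path(directory)
    recordings = []
    for meta_path in sorted(directory.glob("*.json")):
        meta = json.loads(meta_path.read_text())
        with np.load(meta_path.with_suffix(".npz")) as payload:
            signal = payload["signal"]
        recordings.append(
            Recording(
                subject_id=meta["subject_id"],
                group_label=meta["group"],
                signal=signal,
                fs=meta["fs"],
                event_intervals=[tuple(ev) for ev in meta["events"]],
            )
        )
    return recordings


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Write a recording as EDF (16-bit samples, 1-second data records).

    A minimal but standards-conformant writer for interchange with EEG
    tooling; the trailing partial second of the signal is dropped because EDF
    data records have fixed duration.
    """
    fs = recording.fs
    spr = int(round(fs))  # samples per 1 s record, per channel
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = recording.n_samples // spr
    nc = recording.n_channels
    sig = recording.signal[:, : n_records * spr]

    phys_min = float(sig.min())
    phys_max = float(sig.max())
    if phys_max <= phys_min:
        phys_max = phys_min + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((sig - phys_min) * scale + dig_min).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(recording.subject_id, 80),
            _edf_field("synthetic EEG", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 + 256 * nc, 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),  # record duration, seconds
            _edf_field(nc, 4),
        ]
    )
    labels = [f"EEG {i:02d}" for i in range(nc)]
    header += b"".join(_edf_field(lbl, 16) for lbl in labels)
    header += b"".join(_edf_field("", 80) for _ in range(nc))  # transducer
    header += b"".join(_edf_field("uV", 8) for _ in range(nc))
    header += b"".join(_edf_field(f"{phys_min:.3f}"[:8], 8) for _ in range(nc))
    header += b"".join(_edf_field(f"{phys_max:.3f}"[:8], 8) for _ in range(nc))
    header += b"".join(_edf_field(dig_min, 8) for _ in range(nc))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(nc))
    header += b"".join(_edf_field("", 80) for _ in range(nc))  # prefiltering
    header += b"".join(_edf_field(spr, 8) for _ in range(nc))
    header += b"".join(_edf_field("", 32) for _ in range(nc))  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path, subject_id: str | None = None, group_label: int = 0) -> Recording:
    """Read an EDF file into a Recording (via MNE's EDF reader)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        subject_id=subject_id or str(path),
        group_label=group_label,
        signal=raw.get_data(),
        fs=float(raw.info["sfreq"]),
    )
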