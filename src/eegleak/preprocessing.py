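"""Recording -> model-input pipelines.

Two pipelines mirror common translational-EEG practice:

* **raw-segment pipeline** — zero-phase low-pass, then non-overlapping
  fixed-length segments stacked as (samples, channels) matrices;
* **spectrogram-image pipeline** — balanced event/non-event pools, short-time
  Fourier transform with a Hann taper, log power rendered through the viridis
  colormap as square RGB images.

Both produce a :class:`SegmentSet` holding the design matrix ``X``, the label
vector ``y`` and the subject-provenance vector ``s`` used by the two
cross-validation schemes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic_cohort import LabeledPools, Recording, balance_nonevent

__all__ = [
    "SegmentSet",
    "SpectrogramChunk",
    "lowpass_filter",
    "segment_timeseries",
    "segment_cohort",
    "label_event_segments",
    "stft_spectrogram",
    "render_rgb_image",
]


@dataclass
class SegmentSet:
    """n segments with labels and subject provenance.

    ``X`` is (n, samples, channels) for the raw pipeline or
    (n, height, width, 3) for the image pipeline.  ``y`` are binary labels,
    ``s`` subject tokens — one per segment, aligned with the first axis.
    """

    X: np.ndarray
    y: np.ndarray
    s: np.ndarray
    fs: float
    segment_s: float

    def __post_init__(self):
        n = self.X.shape[0]
        if len(self.y) != n or len(self.s) != n:
            raise ValueError(
                f"misaligned SegmentSet: X has {n} segments, "
                f"y has {len(self.y)}, s has {len(self.s)}"
            )

    @property
    def n_segments(self) -> int:
        return self.X.shape[0]

    def subjects(self) -> np.ndarray:
        return np.unique(self.s)

    @staticmethod
    def concatenate(parts: list["SegmentSet"]) -> "SegmentSet":
        parts = [p for p in parts if p.n_segments > 0]
        if not parts:
            raise ValueError("nothing to concatenate")
        ref = parts[0]
        return SegmentSet(
            X=np.concatenate([p.X for p in parts], axis=0),
            y=np.concatenate([p.y for p in parts]),
            s=np.concatenate([p.s for p in parts]),
            fs=ref.fs,
            segment_s=ref.segment_s,
        )


@dataclass
class SpectrogramChunk:
    """Short-time power matrix for one segment of one channel."""

    power: np.ndarray  # (freq_bins, time_windows)
    freqs: np.ndarray
    window: int
    hop: int
    duration: float


# ---------------------------------------------------------------------------
# raw-segment pipeline
# ---------------------------------------------------------------------------

def lowpass_filter(recording: Recording, cutoff: float) -> Recording:
    """Zero-phase 4th-order Butterworth low-pass, applied per channel."""
    nyquist = recording.fs / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"low-pass cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz"
        )
    sos = sps.butter(4, cutoff, btype="low", fs=recording.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1)
    return Recording(
        subject_id=recording.subject_id,
        group_label=recording.group_label,
        signal=filtered,
        fs=recording.fs,
        event_intervals=list(recording.event_intervals),
        profile=recording.profile,
    )


def segment_timeseries(recording: Recording, segment_s: float) -> SegmentSet:
    """Cut non-overlapping consecutive segments; trailing remainder dropped.

    Each segment is (samples, channels); the recording's group label and
    subject token are replicated across its segments.
    """
    m = int(round(segment_s * recording.fs))
    n_seg = recording.n_samples // m
    if n_seg == 0:
        warnings.warn(
            f"recording {recording.subject_id} shorter than one "
            f"{segment_s} s segment; empty SegmentSet"
        )
        X = np.empty((0, m, recording.n_channels))
    else:
        trimmed = recording.signal[:, : n_seg * m]  # (ch, n_seg*m)
        X = trimmed.reshape(recording.n_channels, n_seg, m).transpose(1, 2, 0)
    return SegmentSet(
        X=X,
        y=np.full(X.shape[0], recording.group_label, dtype=int),
        s=np.full(X.shape[0], recording.subject_id, dtype=object),
        fs=recording.fs,
        segment_s=segment_s,
    )


def segment_cohort(
    recordings: list[Recording],
    segment_s: float,
    lowpass_hz: float | None = None,
) -> SegmentSet:
    """Raw-segment pipeline over a whole cohort."""
    parts = []
    for rec in recordings:
        if lowpass_hz is not None:
            rec = lowpass_filter(rec, lowpass_hz)
        parts.append(segment_timeseries(rec, segment_s))
    return SegmentSet.concatenate(parts)


# ---------------------------------------------------------------------------
# event/non-event pipeline
# ---------------------------------------------------------------------------

def label_event_segments(
    recording: Recording,
    segment_s: float,
    pools: LabeledPools | None = None,
) -> SegmentSet:
    """Segment balanced event/non-event pools; y=1 within events.

    Pools are cut independently, so no segment straddles an event boundary.
    With equal-duration pools the class counts differ by at most one segment.
    """
    if pools is None:
        pools = balance_nonevent(recording)
    m = int(round(segment_s * recording.fs))
    xs, ys = [], []
    for label, pool in ((1, pools.event), (0, pools.nonevent)):
        for _, _, chunk in pool:
            n_seg = chunk.shape[1] // m
            if n_seg == 0:
                continue
            trimmed = chunk[:, : n_seg * m]
            xs.append(trimmed.reshape(chunk.shape[0], n_seg, m).transpose(1, 2, 0))
            ys.append(np.full(n_seg, label, dtype=int))
    if xs:
        X = np.concatenate(xs, axis=0)
        y = np.concatenate(ys)
    else:
        X = np.empty((0, m, recording.n_channels))
        y = np.empty(0, dtype=int)
    return SegmentSet(
        X=X,
        y=y,
        s=np.full(X.shape[0], recording.subject_id, dtype=object),
        fs=recording.fs,
        segment_s=segment_s,
    )


# ---------------------------------------------------------------------------
# spectrogram-image pipeline
# ---------------------------------------------------------------------------

def stft_spectrogram(
    segment: np.ndarray, fs: float, window: int = 256, hop: int = 128
) -> SpectrogramChunk:
    """Magnitude-squared STFT with a Hann taper.

    Time-window count is ``floor((len(segment) - window) / hop) + 1``; no
    zero-padding at the edges, so only fully supported windows appear.
    """
    segment = np.asarray(segment)
    if segment.ndim != 1:
        raise ValueError("stft_spectrogram expects a single-channel segment")
    if window > segment.size:
        raise ValueError(
            f"window of {window} samples exceeds segment of {segment.size}"
        )
    if not 0 < hop <= window:
        raise ValueError(f"hop must be in (0, window], got {hop}")
    freqs, _, sxx = sps.spectrogram(
        segment,
        fs=fs,
        window="hann",
        nperseg=window,
        noverlap=window - hop,
        detrend=False,
        scaling="spectrum",
        mode="magnitude",
    )
    return SpectrogramChunk(
        power=sxx**2,
        freqs=freqs,
        window=window,
        hop=hop,
        duration=segment.size / fs,
    )


def render_rgb_image(
    chunk: SpectrogramChunk, out_size: int = 224
) -> np.ndarray:
    """Render log power through the viridis colormap as an RGB image in [0,1].

    Power is log-scaled, min-max normalised per image (so images are
    invariant to positive rescaling of the input), mapped through viridis
    and bilinearly resized to ``out_size x out_size x 3``.
    """
    from matplotlib import colormaps
    from skimage.transform import resize

    if chunk.power.size == 0:
        raise ValueError("cannot render an empty spectrogram chunk")
    log_power = np.log10(chunk.power + 1e-12)
    lo, hi = log_power.min(), log_power.max()
    if hi - lo < 1e-12:
        warnings.warn("constant spectrogram chunk; rendering colormap midpoint")
        scaled = np.full_like(log_power, 0.5)
    else:
        scaled = (log_power - lo) / (hi - lo)
    # low frequencies at the bottom of the image, as spectrograms are drawn
    rgba = colormaps["viridis"](scaled[::-1, :])
    rgb = rgba[..., :3]
    return resize(
        rgb, (out_size, out_size, 3), order=1, mode="edge", anti_aliasing=False
    )
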