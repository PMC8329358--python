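"""Continuous EEG → condition-labelled, artifact-screened 2-s segments.

The canonical chain, applied in this fixed order, is::

    bandpass 0.01–70 Hz → downsample ×2 → ocular regression → re-reference
    to Cz → bandpass 0.1–30 Hz → segment (2 s from stimulus onset) →
    baseline (first 200 ms) → amplitude rejection (±80 µV, strict)

Filters are 4th-order Butterworth applied forward–backward (zero phase).
Ocular correction is a Gratton-style single-coefficient regression of each
EEG channel on the vertical EOG channel, estimated over blink windows found
by a median-absolute-deviation threshold on the EOG.  Rejection flags a
whole segment when any sample on any analysis channel is strictly beyond
±80 µV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from efaa.io_formats import Marker, Recording

#: channels that never count as EEG analysis channels
NON_EEG = ("VEOG", "HEOG", "EOG")

#: condition tuple order used throughout: (emotion, relevance, response)
EMOTIONS = ("threat", "neutral")
RELEVANCES = ("relevant", "irrelevant")
RESPONSES = ("go", "nogo")


@dataclass
class Segment:
    condition: tuple[str, str, str]  # (emotion, relevance, response)
    data: np.ndarray                 # channels × samples, µV
    rejected: bool = False
    rejection_reason: str = "none"


@dataclass
class SegmentSet:
    channels: list[str]
    sfreq: float
    segments: list[Segment]
    n_skipped: int = 0
    provenance: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return sum(not s.rejected for s in self.segments)

    @property
    def n_rejected(self) -> int:
        return sum(s.rejected for s in self.segments)

    def kept(self) -> list[Segment]:
        return [s for s in self.segments if not s.rejected]

    def analysis_channels(self) -> list[str]:
        return [c for c in self.channels if c.upper() not in NON_EEG]


def decode_condition(description: str) -> tuple[str, str, str]:
    """Decode a marker description ``emotion-relevance-response`` into the
    condition tuple; raises on anything malformed."""
    parts = tuple(description.split("-"))
    if (
        len(parts) != 3
        or parts[0] not in EMOTIONS
        or parts[1] not in RELEVANCES
        or parts[2] not in RESPONSES
    ):
        raise ValueError(f"cannot decode condition from marker {description!r}")
    return parts


def encode_condition(emotion: str, relevance: str, response: str) -> str:
    return f"{emotion}-{relevance}-{response}"


# ---------------------------------------------------------------------------
# continuous-domain steps
# ---------------------------------------------------------------------------

def bandpass_filter(rec: Recording, low_hz: float, high_hz: float,
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass; markers pass through unchanged."""
    nyq = rec.sfreq / 2.0
    if not 0 <= low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=rec.sfreq, output="sos")
    out = rec.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def downsample(rec: Recording, factor: int) -> Recording:
    """Decimate by an integer factor with anti-alias filtering.

    Marker sample indices are rescaled by floor division; the output length
    is ``ceil(n / factor)``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return rec.copy()
    data = signal.decimate(rec.data, factor, axis=1, ftype="iir", zero_phase=True)
    markers = [
        Marker(m.kind, m.description, m.onset_sample // factor)
        for m in rec.markers
    ]
    return Recording(channels=list(rec.channels), sfreq=rec.sfreq / factor,
                     data=data, markers=markers)


def rereference(rec: Recording, ref_channel: str = "Cz") -> Recording:
    """Subtract the reference channel from every channel.

    The reference itself becomes identically zero and is retained, so the
    operation is idempotent.
    """
    out = rec.copy()
    ref = out.get(ref_channel).copy()
    out.data -= ref[None, :]
    return out


def correct_ocular(rec: Recording, eog_channel: str = "VEOG",
                   mad_mult: float = 3.0) -> Recording:
    """Regress the vertical EOG out of every EEG channel.

    The propagation coefficient per channel is the least-squares slope of
    the channel on the EOG, estimated over blink windows (samples where
    |EOG − median| exceeds ``mad_mult`` × MAD).  With a zero-variance EOG
    the input is returned unchanged.
    """
    out = rec.copy()
    eog = out.get(eog_channel)
    if np.ptp(eog) == 0:
        out.provenance = getattr(out, "provenance", [])
        return out
    med = np.median(eog)
    mad = np.median(np.abs(eog - med))
    if mad == 0:
        # nearly-flat EOG with isolated blinks: fall back to std threshold
        active = np.abs(eog - med) > 3.0 * np.std(eog)
    else:
        active = np.abs(eog - med) > mad_mult * 1.4826 * mad
    if not active.any():
        return out
    e = eog[active] - eog[active].mean()
    denom = float(e @ e)
    if denom == 0:
        return out
    eog_idx = out.channel_index(eog_channel)
    for i in range(out.data.shape[0]):
        if i == eog_idx:
            continue
        x = out.data[i, active]
        b = float(e @ (x - x.mean())) / denom
        out.data[i] -= b * eog
    return out


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def segment(rec: Recording, duration_s: float = 2.0) -> SegmentSet:
    """Cut one epoch per stimulus marker, ``[onset, onset + duration)``.

    Trials whose epoch would run past the end of the recording are skipped
    and counted.
    """
    n_samp = int(round(duration_s * rec.sfreq))
    segments: list[Segment] = []
    skipped = 0
    for m in rec.markers:
        if m.kind != "Stimulus":
            continue
        cond = decode_condition(m.description)
        stop = m.onset_sample + n_samp
        if stop > rec.n_times:
            skipped += 1
            continue
        segments.append(Segment(condition=cond,
                                data=rec.data[:, m.onset_sample:stop].copy()))
    return SegmentSet(channels=list(rec.channels), sfreq=rec.sfreq,
                      segments=segments, n_skipped=skipped)


def baseline_correct(segs: SegmentSet, baseline_s: float = 0.2) -> SegmentSet:
    """Subtract, per channel and segment, the mean of the first
    ``baseline_s`` seconds (the pre-cue interval)."""
    n_base = int(round(baseline_s * segs.sfreq))
    if n_base < 1:
        raise ValueError("baseline window shorter than one sample")
    for s in segs.segments:
        if s.data.shape[1] < n_base:
            raise ValueError("segment shorter than the baseline window")
        s.data -= s.data[:, :n_base].mean(axis=1, keepdims=True)
    segs.provenance.append(f"baseline {baseline_s * 1e3:.0f} ms")
    return segs


def reject_artifacts(segs: SegmentSet, limit_uv: float = 80.0,
                     channels: list[str] | None = None) -> SegmentSet:
    """Flag segments with any sample strictly beyond ±``limit_uv`` on any
    analysis channel.  Exactly ±limit is kept (strict inequality)."""
    if channels is None:
        channels = segs.analysis_channels()
    idx = [segs.channels.index(c) for c in channels]
    for s in segs.segments:
        if s.rejected:
            continue
        block = s.data[idx]
        if (block > limit_uv).any() or (block < -limit_uv).any():
            s.rejected = True
            s.rejection_reason = "amplitude"
    segs.provenance.append(f"amplitude rejection ±{limit_uv:g} µV")
    return segs


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

#: the fixed processing order, recorded into provenance and asserted in tests
PIPELINE_ORDER = (
    "bandpass 0.01-70",
    "downsample 2",
    "ocular regression",
    "rereference Cz",
    "bandpass 0.1-30",
    "segment 2 s",
    "baseline 200 ms",
    "reject ±80 µV",
)


def run_preprocessing(
    rec: Recording,
    *,
    wide_band: tuple[float, float] = (0.01, 70.0),
    narrow_band: tuple[float, float] = (0.1, 30.0),
    filter_order: int = 4,
    downsample_factor: int = 2,
    ref_channel: str = "Cz",
    eog_channel: str = "VEOG",
    ocular_correction: bool = True,
    reject_limit_uv: float = 80.0,
    segment_s: float = 2.0,
    baseline_s: float = 0.2,
) -> SegmentSet:
    """Run the full canonical chain and return the screened segments."""
    rec = bandpass_filter(rec, *wide_band, order=filter_order)
    rec = downsample(rec, downsample_factor)
    if ocular_correction:
        rec = correct_ocular(rec, eog_channel)
    rec = rereference(rec, ref_channel)
    rec = bandpass_filter(rec, *narrow_band, order=filter_order)
    segs = segment(rec, duration_s=segment_s)
    segs.provenance = list(PIPELINE_ORDER[:6])
    segs = baseline_correct(segs, baseline_s=baseline_s)
    segs = reject_artifacts(segs, limit_uv=reject_limit_uv)
    return segs
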