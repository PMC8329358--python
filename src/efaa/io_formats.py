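"""Readers and writers for the EEG container and tabular sidecars.

The EEG container is the BrainVision triplet (``.vhdr`` INI-style header,
``.vmrk`` marker file, ``.eeg`` binary data).  Only the multiplexed
IEEE_FLOAT_32 dialect is written; reading additionally accepts INT_16 with
per-channel resolution.  Internally everything is 0-based, half-open sample
indexing; the vendor format's 1-based marker positions are converted at the
boundary.

Subject scores travel as a plain CSV (RFC-4180, UTF-8, "." decimal) with a
fixed header; missing clinical fields (PTA, time post-injury — absent for
controls) are empty fields.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("Control", "NonSymp", "Symp")

SCORES_COLUMNS = [
    "subject_id",
    "group",
    "rpq",
    "rpq_emotional",
    "bdi",
    "brief_gec",
    "brief_ec",
    "age",
    "pta_hours",
    "months_post_injury",
]

#: scores columns that must be null exactly for controls
_MTBI_ONLY = ("pta_hours", "months_post_injury")


@dataclass
class Marker:
    """One event marker: a type, a condition-encoding description and a
    0-based onset sample index."""

    kind: str
    description: str
    onset_sample: int


@dataclass
class Recording:
    """Continuous multi-channel EEG in µV.

    ``data`` is channels × time; ``channels`` gives the ordered labels.
    """

    channels: list[str]
    sfreq: float
    data: np.ndarray
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be (n_channels={len(self.channels)}, n_times); "
                f"got shape {self.data.shape}"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.data.shape[1]
        last = -1
        for m in self.markers:
            if not 0 <= m.onset_sample < n:
                raise ValueError(
                    f"marker at sample {m.onset_sample} outside recording "
                    f"of {n} samples"
                )
            if m.onset_sample < last:
                raise ValueError("marker onsets must be nondecreasing")
            last = m.onset_sample

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy(self) -> "Recording":
        return Recording(
            channels=list(self.channels),
            sfreq=self.sfreq,
            data=self.data.copy(),
            markers=[Marker(m.kind, m.description, m.onset_sample) for m in self.markers],
        )


# ---------------------------------------------------------------------------
# BrainVision triplet
# ---------------------------------------------------------------------------

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by efaa

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={nchan}
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Ch<n>=<name>,<reference>,<resolution in µV>,<unit>
{channel_lines}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
; Mk<n>=<type>,<description>,<position>,<points>,<channel>
{marker_lines}
"""


def write_brainvision(rec: Recording, basename: str | Path) -> tuple[Path, Path, Path]:
    """Write ``rec`` as ``basename``.vhdr/.vmrk/.eeg.

    Data are multiplexed little-endian float32 at resolution 1.0 µV; marker
    positions are converted to the vendor's 1-based convention.
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    channel_lines = "\n".join(
        f"Ch{i + 1}={name},,1.0,µV" for i, name in enumerate(rec.channels)
    )
    sampling_interval_us = 1e6 / rec.sfreq
    vhdr.write_text(
        _VHDR_TEMPLATE.format(
            stem=stem,
            nchan=len(rec.channels),
            sampling_interval=f"{sampling_interval_us:g}",
            channel_lines=channel_lines,
        ),
        encoding="utf-8",
    )

    # vendor convention: first marker is the New Segment marker
    lines = [f"Mk1=New Segment,,1,1,0"]
    for i, m in enumerate(rec.markers, start=2):
        if "," in m.description or "," in m.kind:
            raise ValueError("marker fields may not contain commas")
        lines.append(f"Mk{i}={m.kind},{m.description},{m.onset_sample + 1},1,0")
    vmrk.write_text(_VMRK_TEMPLATE.format(stem=stem, marker_lines="\n".join(lines)),
                    encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr, vmrk, eeg


def _parse_ini(path: Path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(strict=False, interpolation=None)
    cp.optionxform = str  # keys are case sensitive (Ch1 vs ch1)
    text = path.read_text(encoding="utf-8")
    # drop the signature line before the first [Section]
    idx = text.find("[")
    if idx < 0:
        raise ValueError(f"{path} is not an INI-style BrainVision file")
    cp.read_string(text[idx:])
    return cp


def read_brainvision(vhdr_path: str | Path) -> Recording:
    """Read a BrainVision triplet back into a :class:`Recording`."""
    vhdr_path = Path(vhdr_path)
    if not vhdr_path.exists():
        raise FileNotFoundError(vhdr_path)
    cp = _parse_ini(vhdr_path)

    common = cp["Common Infos"]
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED data orientation is supported")
    binary_format = cp["Binary Infos"]["BinaryFormat"].upper()
    if binary_format not in ("IEEE_FLOAT_32", "INT_16"):
        raise ValueError(f"unsupported BinaryFormat {binary_format!r}")

    nchan = int(common["NumberOfChannels"])
    sfreq = 1e6 / float(common["SamplingInterval"])

    channels: list[str] = []
    resolutions: list[float] = []
    for i in range(1, nchan + 1):
        entry = cp["Channel Infos"][f"Ch{i}"]
        parts = entry.split(",")
        channels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1.0"
        resolutions.append(float(res))

    eeg_path = vhdr_path.parent / common["DataFile"]
    vmrk_path = vhdr_path.parent / common.get("MarkerFile", vhdr_path.stem + ".vmrk")
    if not eeg_path.exists():
        raise FileNotFoundError(f"missing data file {eeg_path}")
    if not vmrk_path.exists():
        raise FileNotFoundError(f"missing marker file {vmrk_path}")

    dtype = "<f4" if binary_format == "IEEE_FLOAT_32" else "<i2"
    raw = np.fromfile(eeg_path, dtype=dtype)
    if raw.size % nchan:
        raise ValueError(
            f"data file length {raw.size} not divisible by {nchan} channels"
        )
    data = raw.reshape(-1, nchan).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]

    markers: list[Marker] = []
    mcp = _parse_ini(vmrk_path)
    for key in mcp["Marker Infos"]:
        if not key.startswith("Mk"):
            continue
        parts = mcp["Marker Infos"][key].split(",")
        kind, desc, pos = parts[0], parts[1], int(parts[2])
        if kind == "New Segment":
            continue
        markers.append(Marker(kind, desc, pos - 1))
    markers.sort(key=lambda m: m.onset_sample)

    return Recording(channels=channels, sfreq=sfreq, data=data, markers=markers)


# ---------------------------------------------------------------------------
# Scores table
# ---------------------------------------------------------------------------

def validate_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a scores table against its invariants; returns the frame."""
    missing = [c for c in SCORES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scores table missing columns {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject id(s): {sorted(set(dup))}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    ctrl = df["group"] == "Control"
    for col in _MTBI_ONLY:
        if df.loc[ctrl, col].notna().any():
            offenders = df.loc[ctrl & df[col].notna(), "subject_id"].tolist()
            raise ValueError(f"Control subjects must have null {col}: {offenders}")
        if df.loc[~ctrl, col].isna().any():
            offenders = df.loc[~ctrl & df[col].isna(), "subject_id"].tolist()
            raise ValueError(f"MTBI subjects must have {col}: {offenders}")
    return df


def write_scores(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_scores(df)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=SCORES_COLUMNS)
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_scores(df)
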