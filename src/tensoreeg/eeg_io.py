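"""EEG recording I/O, 10-20 montage selection and segment extraction.

Recordings are channels x samples matrices in microvolts.  Two on-disk
formats are supported: EDF (16-bit European Data Format; read through
:mod:`mne`, written by a minimal in-package writer) and delimited text
(one column per channel, JSON metadata on a leading ``#`` line).

A packaged table maps the 128-channel HydroCel geodesic net onto the 19
classical 10-20 electrodes (Fp1 ... O2); the map is overridable because
vendor nets differ and no single equivalence is universal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical ordering of the 19 electrodes of the classical 10-20 montage
CANONICAL_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)


@dataclass
class EEGRecording:
    """A multichannel EEG segment with sampling rate and participant metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per row of ``data``.
    participant_id : str
        Identifier used to align with the participant table.
    age_code : int
        Integer age label of the recording session (1 = infancy, then the
        age in years: 3, 5, 7).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    participant_id: str = ""
    age_code: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class MontageMap:
    """Injective map from 10-20 target labels to source channel labels."""

    mapping: dict[str, str]
    targets: tuple[str, ...] = CANONICAL_1020

    def __post_init__(self) -> None:
        if len(self.targets) != 19:
            raise ValueError("a 10-20 montage map must list exactly 19 targets")
        missing = [t for t in self.targets if t not in self.mapping]
        if missing:
            raise ValueError(f"montage map lacks targets: {missing}")
        sources = [self.mapping[t] for t in self.targets]
        if len(set(sources)) != len(sources):
            raise ValueError("montage map is not injective (duplicate sources)")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MontageMap":
        df = pd.read_csv(path)
        mapping = dict(zip(df["target"].astype(str), df["source"].astype(str)))
        return cls(mapping=mapping, targets=tuple(df["target"].astype(str)))

    @classmethod
    def default_hydrocel128(cls) -> "MontageMap":
        """Packaged HydroCel-128 -> 10-20 equivalence table."""
        with resources.as_file(
            resources.files("tensoreeg.data") / "hydrocel128_to_1020.csv"
        ) as p:
            return cls.from_csv(p)


def select_1020_channels(rec: EEGRecording, montage: MontageMap | None = None) -> EEGRecording:
    """Project a recording onto the 19 classical 10-20 channels.

    A pure row selection: output rows equal the mapped input rows exactly,
    ordered canonically (Fp1 ... O2).  Raises ``KeyError`` naming the 10-20
    label whose source channel is absent.
    """
    montage = montage or MontageMap.default_hydrocel128()
    index = {lab: i for i, lab in enumerate(rec.channel_labels)}
    rows = []
    for target in montage.targets:
        source = montage.mapping[target]
        if source not in index:
            raise KeyError(
                f"source channel {source!r} for 10-20 electrode {target!r} "
                "not present in recording"
            )
        rows.append(index[source])
    return replace(
        rec,
        data=rec.data[rows].copy(),
        channel_labels=list(montage.targets),
    )


def select_segment(rec: EEGRecording, start_s: float = 0.0, duration_s: float = 30.0) -> EEGRecording:
    """Extract a fixed-length analysis window, half-open in samples.

    The default 30 s window is the segment length used for resting-state
    nonlinear analysis throughout the pipeline.
    """
    start = int(round(start_s * rec.fs))
    n = int(round(duration_s * rec.fs))
    if start < 0 or n <= 0:
        raise ValueError("start and duration must be non-negative / positive")
    if start + n > rec.n_samples:
        raise ValueError(
            f"window [{start_s}, {start_s + duration_s}) s exceeds recording "
            f"length {rec.duration:.3f} s"
        )
    return replace(rec, data=rec.data[:, start : start + n].copy())


# ---------------------------------------------------------------------------
# delimited-text format


def _write_txt(rec: EEGRecording, path: Path) -> None:
    meta = {
        "fs": rec.fs,
        "participant_id": rec.participant_id,
        "age_code": rec.age_code,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.10g", delimiter=",")


def _read_txt(path: Path) -> EEGRecording:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing '# {{json}}' metadata line with fs")
        meta = json.loads(first.lstrip("# ").strip())
        if "fs" not in meta:
            raise ValueError(f"{path}: metadata line lacks 'fs'")
        df = pd.read_csv(fh)
    labels = [str(c) for c in df.columns]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(
            f"{path}: non-numeric value at data row {r}, column {labels[c]!r}"
        )
    return EEGRecording(
        data=values.T,
        fs=float(meta["fs"]),
        channel_labels=labels,
        participant_id=str(meta.get("participant_id", "")),
        age_code=int(meta.get("age_code", 0)),
    )


# ---------------------------------------------------------------------------
# EDF format

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: one data record per second, 16-bit samples.

    Physical range is the per-channel data range (symmetric, padded), so the
    quantization step is range / 2**16.  Samples per record must be integral,
    i.e. fs must be a whole number of Hz.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    ns = rec.n_channels
    n_samples = rec.n_samples
    n_records = int(np.ceil(n_samples / fs))
    padded = np.zeros((ns, n_records * fs))
    padded[:, :n_samples] = rec.data

    # symmetric physical range per channel, padded 1% to keep extremes in-range
    absmax = np.maximum(np.abs(padded).max(axis=1), 1e-6) * 1.01
    pmin, pmax = -absmax, absmax
    gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * gain[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(rec.participant_id or "X", 80))
        fh.write(_edf_field(f"age_code={rec.age_code}", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(256 * (ns + 1)), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field("1", 8))  # record duration, seconds
        fh.write(_edf_field(str(ns), 4))
        for lab in rec.channel_labels:
            fh.write(_edf_field(lab, 16))
        fh.write(_edf_field("", 80) * ns)  # transducer
        fh.write(_edf_field("uV", 8) * ns)
        for v in pmin:
            fh.write(_edf_field(f"{v:.6g}"[:8], 8))
        for v in pmax:
            fh.write(_edf_field(f"{v:.6g}"[:8], 8))
        fh.write(_edf_field(str(_EDF_DIG_MIN), 8) * ns)
        fh.write(_edf_field(str(_EDF_DIG_MAX), 8) * ns)
        fh.write(_edf_field("", 80) * ns)  # prefiltering
        fh.write(_edf_field(str(fs), 8) * ns)
        fh.write(_edf_field("", 32) * ns)
        for rec_i in range(n_records):
            block = digital[:, rec_i * fs : (rec_i + 1) * fs]
            fh.write(block.tobytes())


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for EEG channels
    participant_id = ""
    info_subj = raw.info.get("subject_info") or {}
    for key in ("his_id", "last_name"):
        if info_subj.get(key):
            participant_id = str(info_subj[key])
            break
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        participant_id=participant_id,
    )


# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in {".csv", ".txt", ".tsv"}:
        return "txt"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EDF or delimited-text recording.

    Raises a descriptive error for unknown formats, missing sampling rate
    or non-numeric samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "txt":
        return _read_txt(path)
    raise ValueError(f"unknown recording format {fmt!r} (expected 'edf' or 'txt')")


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as EDF or delimited text (see :func:`read_recording`)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "txt":
        _write_txt(rec, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r} (expected 'edf' or 'txt')")
    return path


def write_participant_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the participant table (id, group, age_code, sex, birthweight...)."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_participant_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
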