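"""Segment and dataset IO plus the channel-to-lobe lookup table.

EEG segments are channels x samples matrices.  The on-disk CSV dialect is
rows = channels, columns = samples, with an optional first header row of
channel names.  A dataset manifest is a two-column delimited file pairing a
segment path with its class label.  Channel indices are 1-based in every
public contract.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EegSegment",
    "DatasetManifest",
    "LobeLUT",
    "load_segment",
    "save_segment",
    "load_manifest",
    "save_manifest",
    "default_lobe_lut",
]

#: Default montage of the 14-channel Emotiv Epoc X cap, in recording order.
EMOTIV14_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

LOBE_SYMBOLS = ("F", "T", "P", "O")


@dataclass
class EegSegment:
    """One multi-channel EEG window.

    Parameters
    ----------
    data : ndarray, shape (C, N)
        Channel-by-sample amplitude matrix (units are never used by any
        downstream algorithm; only per-timepoint orderings matter).
    channel_names : sequence of str
        One name per channel, in row order.
    segment_id : str
        Identifier carried through feature extraction.
    """

    data: np.ndarray
    channel_names: Sequence[str]
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"segment data must be 2-D, got shape {self.data.shape}")
        c, n = self.data.shape
        if c < 2:
            raise ValueError(f"need at least 2 channels, got {c}")
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value at channel row {bad[0] + 1}, sample column {bad[1] + 1}"
            )
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class DatasetManifest:
    """Ordered pairing of segment paths with class labels."""

    entries: list[tuple[Path, str]]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [(Path(p), str(lab)) for p, lab in self.entries]
        if not self.class_names:
            seen: list[str] = []
            for _, lab in self.entries:
                if lab not in seen:
                    seen.append(lab)
            self.class_names = seen

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.entries]


@dataclass(frozen=True)
class LobeLUT:
    """Total map from 1-based channel index to a lobe symbol in {F, T, P, O}."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("LUT must cover at least 2 channels")
        bad = set(self.symbols) - set(LOBE_SYMBOLS)
        if bad:
            raise ValueError(f"symbols outside the F/T/P/O alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __getitem__(self, channel: int) -> str:
        if not 1 <= channel <= len(self.symbols):
            raise IndexError(
                f"channel {channel} outside 1..{len(self.symbols)} (channels are 1-based)"
            )
        return self.symbols[channel - 1]


def default_lobe_lut() -> LobeLUT:
    """Lobe lookup for the 14-channel Emotiv montage.

    AF3/F7/F3/FC5 and FC6/F4/F8/AF4 are frontal, T7/T8 temporal, P7/P8
    parietal, O1/O2 occipital, giving the symbol list
    F F F F T P O O P T F F F F in channel order.
    """
    return LobeLUT(("F", "F", "F", "F", "T", "P", "O", "O", "P", "T", "F", "F", "F", "F"))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _load_csv_segment(path: Path) -> EegSegment:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header: list[str] | None = None
    if not all(_is_number(tok) for tok in rows[0]):
        header = [tok.strip() for tok in rows[0]]
        rows = rows[1:]
    data = np.empty((len(rows), len(rows[0]) if rows else 0), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != data.shape[1]:
            raise ValueError(f"{path}: row {i + 1} has {len(row)} cells, expected {data.shape[1]}")
        for j, tok in enumerate(row):
            try:
                v = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at channel row {i + 1}, sample column {j + 1}: {tok!r}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-finite value at channel row {i + 1}, sample column {j + 1}"
                )
            data[i, j] = v
    names = header if header is not None else [f"ch{i + 1}" for i in range(data.shape[0])]
    return EegSegment(data=data, channel_names=names, segment_id=path.stem)


def _load_edf_segment(path: Path, channels: Sequence[str] | None) -> EegSegment:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env without mne
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(list(channels))
    return EegSegment(
        data=raw.get_data(),
        channel_names=list(raw.ch_names),
        segment_id=path.stem,
    )


def load_segment(path, fmt: str | None = None, channels: Sequence[str] | None = None) -> EegSegment:
    """Read one EEG segment from CSV or EDF.

    Parameters
    ----------
    path : path-like
        Segment file.  Format is inferred from the suffix unless ``fmt``
        is given ("csv" or "edf").
    channels : sequence of str, optional
        For EDF only: select these channels by name, in the given order.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file, non-numeric or non-finite cells, or a matrix smaller
        than 2 channels x 2 samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "csv":
        return _load_csv_segment(path)
    if fmt == "edf":
        return _load_edf_segment(path, channels)
    raise ValueError(f"unknown segment format {fmt!r}")


def save_segment(segment: EegSegment, path) -> Path:
    """Write a segment as CSV (header row of channel names, rows = channels)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(segment.channel_names)
        for row in segment.data:
            writer.writerow([repr(float(v)) for v in row])
    return path


def load_manifest(path, delimiter: str | None = None) -> DatasetManifest:
    """Read a two-column (path, label) manifest; paths resolve relative to it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    delim = delimiter
    if delim is None:
        delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    entries: list[tuple[Path, str]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter=delim)):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {i + 1} needs two columns (path, label)")
            seg = Path(row[0].strip())
            if not seg.is_absolute():
                seg = path.parent / seg
            if not seg.exists():
                raise FileNotFoundError(f"{path}: line {i + 1}: segment file {seg} not found")
            entries.append((seg, row[1].strip()))
    if not entries:
        raise ValueError(f"{path}: empty manifest")
    return DatasetManifest(entries=entries)


def save_manifest(manifest: DatasetManifest, path, delimiter: str = ",") -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for seg, lab in manifest.entries:
            writer.writerow([str(seg), lab])
    return path
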