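"""ChannelPat transition-histogram features.

The rank sequence is scanned with overlapping length-2 blocks; each
ordered pair of channel indices (a, b) is encoded to a single base-C
digit pair, code = C*(a-1) + (b-1), and the histogram over all C^2 codes
is the feature vector.  Pairs span the whole flat sequence, including
across time-point boundaries, so a segment of N samples contributes
exactly C*N - 1 counts.  Feature bins are 1-based (bin = code + 1): bin b
represents the transition from channel floor((b-1)/C)+1 to channel
((b-1) mod C)+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DatasetManifest, EegSegment, load_segment
from .transform import RankSequence, channel_transform

__all__ = [
    "FeatureVector",
    "FeatureMatrix",
    "pair_code",
    "extract_features",
    "build_feature_matrix",
    "feature_names",
]


def pair_code(a: int, b: int, n_channels: int) -> int:
    """Base-C code of the ordered channel pair (a, b): C*(a-1) + (b-1).

    Channel indices are 1-based; the code is 0-based in 0..C^2-1 and the
    corresponding feature bin is ``code + 1``.
    """
    c = int(n_channels)
    if c < 2:
        raise ValueError("need at least 2 channels")
    if not (1 <= a <= c and 1 <= b <= c):
        raise ValueError(f"channel pair ({a}, {b}) outside 1..{c}")
    return c * (a - 1) + (b - 1)


def feature_names(n_channels: int) -> list[str]:
    """Bin labels 'p<a>_<b>' in bin order (bin 1 = pair (1,1))."""
    c = int(n_channels)
    return [f"p{a}_{b}" for a in range(1, c + 1) for b in range(1, c + 1)]


@dataclass
class FeatureVector:
    """C^2-bin histogram of ordered channel transitions for one segment."""

    counts: np.ndarray
    n_channels: int
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = int(self.n_channels)
        if self.counts.shape != (c * c,):
            raise ValueError(
                f"expected {c * c} bins for C={c}, got shape {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative bin count")

    def as_table(self) -> np.ndarray:
        """Counts reshaped to a (from-channel, to-channel) C x C table."""
        c = self.n_channels
        return self.counts.reshape(c, c)


@dataclass
class FeatureMatrix:
    """Stacked feature vectors with per-row class labels."""

    X: np.ndarray
    labels: list[str]
    n_channels: int
    segment_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("row count differs from label count")
        if self.X.shape[1] != self.n_channels**2:
            raise ValueError(
                f"{self.X.shape[1]} columns does not match C^2={self.n_channels ** 2}"
            )
        if not self.segment_ids:
            self.segment_ids = [f"seg{i}" for i in range(self.X.shape[0])]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def class_names(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=feature_names(self.n_channels))
        df.insert(0, "label", self.labels)
        df.index = pd.Index(self.segment_ids, name="segment_id")
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        labels = df["label"].astype(str).tolist()
        X = df.drop(columns=["label"]).to_numpy()
        c = int(round(X.shape[1] ** 0.5))
        ids = [str(i) for i in df.index]
        return cls(X=X, labels=labels, n_channels=c, segment_ids=ids)


def extract_features(ranks, n_channels: int | None = None) -> FeatureVector:
    """Histogram the overlapping channel-index pairs of a rank sequence.

    ``ranks`` is a :class:`RankSequence` or any 1-D sequence of channel
    indices in 1..C (then ``n_channels`` is required).  The histogram
    sums to ``len(ranks) - 1`` by construction.
    """
    if isinstance(ranks, RankSequence):
        v, c = ranks.values, ranks.n_channels
    else:
        if n_channels is None:
            raise ValueError("n_channels required for a plain index sequence")
        v, c = np.asarray(ranks, dtype=np.int64), int(n_channels)
        if v.ndim != 1:
            raise ValueError("rank sequence must be 1-D")
        if v.size and (v.min() < 1 or v.max() > c):
            raise ValueError(f"rank values must lie in 1..{c}")
    if v.size < 2:
        raise ValueError("rank sequence must have at least 2 values")
    codes = c * (v[:-1] - 1) + (v[1:] - 1)
    counts = np.bincount(codes, minlength=c * c)
    return FeatureVector(counts=counts, n_channels=c)


def build_feature_matrix(
    manifest: DatasetManifest | None = None,
    *,
    segments: Sequence[EegSegment] | None = None,
    labels: Sequence[str] | None = None,
) -> FeatureMatrix:
    """One ChannelPat feature row per segment, manifest order preserved.

    Pass either a manifest (segments are loaded from disk) or in-memory
    ``segments`` with matching ``labels``.  All segments must share the
    same channel count.
    """
    if manifest is not None:
        segs = [load_segment(p) for p, _ in manifest.entries]
        labs = manifest.labels
    else:
        if segments is None or labels is None:
            raise ValueError("need a manifest, or both segments and labels")
        segs = list(segments)
        labs = [str(x) for x in labels]
    if not segs:
        raise ValueError("no segments to featurize")
    if len(segs) != len(labs):
        raise ValueError("segment count differs from label count")
    c = segs[0].n_channels
    rows = []
    ids = []
    for seg in segs:
        if seg.n_channels != c:
            raise ValueError(
                f"segment {seg.segment_id!r} has {seg.n_channels} channels, expected {c}"
            )
        rows.append(extract_features(channel_transform(seg)).counts)
        ids.append(seg.segment_id)
    return FeatureMatrix(X=np.vstack(rows), labels=labs, n_channels=c, segment_ids=ids)
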