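"""Lobish: a four-letter symbolic reading of selected transition features.

Each selected ChannelPat feature encodes an ordered channel pair; mapping
both channels through a channel-to-lobe lookup table yields two symbols
from the alphabet F (frontal), T (temporal), P (parietal), O (occipital).
Concatenating the symbol pairs over the selected features, in selection
order, gives a "sentence" whose symbol histogram, 4x4 transition table,
row-stochastic transition matrix and Shannon entropies summarize which
lobes — and which lobe-to-lobe interactions — carry the discriminative
channel-ordering structure.

Feature id decoding is the exact inverse of the ChannelPat pair code:
for a 1-based bin id, from-channel a = floor((id-1)/C) + 1 and
to-channel b = ((id-1) mod C) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import LOBE_SYMBOLS, LobeLUT, default_lobe_lut

__all__ = [
    "LobishSentence",
    "LobeStats",
    "TRANSITION_GLOSS",
    "feature_to_symbols",
    "generate_sentence",
    "lobe_histogram",
    "transition_counts",
    "transition_matrix",
    "shannon_entropy",
    "lobe_stats",
]

#: Short functional reading of each two-symbol word (annotation only; no
#: computation depends on these strings).  F = cognition/planning,
#: T = audition/memory, P = somatosensory/spatial integration, O = vision.
TRANSITION_GLOSS: dict[str, str] = {
    "FF": "sustained cognitive engagement",
    "TT": "sustained auditory/memory processing",
    "PP": "sustained sensory-spatial integration",
    "OO": "sustained visual processing",
    "FT": "cognition handing off to audition/memory",
    "FP": "cognition handing off to sensory integration",
    "FO": "cognition handing off to visual analysis",
    "TP": "audition/memory feeding sensory integration",
    "TO": "audition/memory feeding visual interpretation",
    "PO": "sensory-spatial input feeding visual processing",
    "TF": "audition/memory feeding cognition",
    "PF": "sensory input feeding cognition",
    "OF": "visual input feeding cognition",
    "PT": "sensory input feeding audition/memory",
    "OT": "visual input feeding audition/memory",
    "OP": "visual input feeding sensory-spatial awareness",
}


@dataclass
class LobishSentence:
    """Symbol string over {F, T, P, O} with per-feature provenance."""

    symbols: str
    provenance: list = field(default_factory=lambda: ["external"])

    def __post_init__(self) -> None:
        bad = set(self.symbols) - set(LOBE_SYMBOLS)
        if bad:
            raise ValueError(f"symbols outside the F/T/P/O alphabet: {sorted(bad)}")
        if self.provenance != ["external"] and len(self.symbols) != 2 * len(self.provenance):
            raise ValueError("sentence length must be twice the number of source features")

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols


def feature_to_symbols(feature_id: int, lut: LobeLUT | None = None) -> tuple[str, str]:
    """Decode a 1-based feature bin id to its (from-lobe, to-lobe) symbols."""
    if lut is None:
        lut = default_lobe_lut()
    c = len(lut)
    if not 1 <= feature_id <= c * c:
        raise ValueError(f"feature id {feature_id} outside 1..{c * c}")
    a = (feature_id - 1) // c + 1
    b = (feature_id - 1) % c + 1
    return lut[a], lut[b]


def generate_sentence(feature_ids: Sequence[int], lut: LobeLUT | None = None) -> LobishSentence:
    """Two symbols per selected feature, concatenated in selection order."""
    if lut is None:
        lut = default_lobe_lut()
    ids = [int(i) for i in feature_ids]
    if not ids:
        import warnings

        warnings.warn("empty feature id list: empty sentence", stacklevel=2)
        return LobishSentence(symbols="", provenance=[])
    parts = [feature_to_symbols(i, lut) for i in ids]
    return LobishSentence(symbols="".join(a + b for a, b in parts), provenance=ids)


def _symbols_of(sentence) -> str:
    return sentence.symbols if isinstance(sentence, LobishSentence) else str(sentence)


def lobe_histogram(sentence) -> dict[str, int]:
    """Exact multiplicity of each symbol F, T, P, O."""
    s = _symbols_of(sentence)
    if not s:
        raise ValueError("empty sentence")
    bad = set(s) - set(LOBE_SYMBOLS)
    if bad:
        raise ValueError(f"symbols outside the F/T/P/O alphabet: {sorted(bad)}")
    return {sym: s.count(sym) for sym in LOBE_SYMBOLS}


def transition_counts(sentence) -> pd.DataFrame:
    """4x4 table of overlapping consecutive symbol pairs (from-row, to-column).

    Counts sum to ``len(sentence) - 1``; pairs span the whole sentence,
    including positions that straddle feature boundaries.
    """
    s = _symbols_of(sentence)
    if len(s) < 2:
        raise ValueError("need at least 2 symbols for transitions")
    bad = set(s) - set(LOBE_SYMBOLS)
    if bad:
        raise ValueError(f"symbols outside the F/T/P/O alphabet: {sorted(bad)}")
    pos = {sym: i for i, sym in enumerate(LOBE_SYMBOLS)}
    counts = np.zeros((4, 4), dtype=np.int64)
    for a, b in zip(s[:-1], s[1:]):
        counts[pos[a], pos[b]] += 1
    return pd.DataFrame(counts, index=list(LOBE_SYMBOLS), columns=list(LOBE_SYMBOLS))


def transition_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a transition-count table; all-zero rows stay all-zero."""
    arr = np.asarray(counts, dtype=float)
    if arr.shape[0] != arr.shape[1] or (arr < 0).any():
        raise ValueError("counts must be a square nonnegative table")
    rowsum = arr.sum(axis=1, keepdims=True)
    out = np.divide(arr, rowsum, out=np.zeros_like(arr), where=rowsum > 0)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return pd.DataFrame(out, index=list(LOBE_SYMBOLS), columns=list(LOBE_SYMBOLS))


def shannon_entropy(counts) -> float:
    """Shannon entropy in bits of a nonnegative count distribution.

    Zero cells contribute nothing (0 * log 0 = 0).  A symbol histogram
    is bounded by log2(4) = 2 bits, a 16-cell transition table by
    log2(16) = 4 bits.
    """
    if isinstance(counts, dict):
        arr = np.asarray(list(counts.values()), dtype=float)
    else:
        arr = np.asarray(counts, dtype=float).ravel()
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero distribution has no entropy")
    p = arr[arr > 0] / total
    return float(-(p * np.log2(p)).sum())


@dataclass
class LobeStats:
    """Bundle of sentence-level summaries."""

    symbol_counts: dict[str, int]
    transition_counts: pd.DataFrame
    transition_matrix: pd.DataFrame
    symbol_entropy_bits: float
    transition_entropy_bits: float


def lobe_stats(sentence) -> LobeStats:
    """Histogram, transition table + matrix, and both entropies of a sentence."""
    sc = lobe_histogram(sentence)
    tc = transition_counts(sentence)
    return LobeStats(
        symbol_counts=sc,
        transition_counts=tc,
        transition_matrix=transition_matrix(tc),
        symbol_entropy_bits=shannon_entropy(sc),
        transition_entropy_bits=shannon_entropy(tc),
    )
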