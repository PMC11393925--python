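"""High-level model object orchestrating the full pipeline.

``ChannelPatModel`` holds labelled segments; ``fit()`` runs the five
stages in order — rank transform, ChannelPat histograms, INCA
selection, tkNN classification, Lobish interpretation — and returns a
``ChannelPatResults`` with the selection, the prediction ensemble, the
confusion matrix and metrics, the Lobish sentence and its statistics,
and a ``summary()`` table.

One global seed fans out to the named per-stage seeds (INCA loss folds,
tkNN folds) so every stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix, build_feature_matrix
from .inca import SelectionResult, inca_select
from .io import DatasetManifest, EegSegment, LobeLUT, default_lobe_lut, load_manifest
from .lobish import LobeStats, LobishSentence, generate_sentence, lobe_stats
from .metrics import ConfusionMatrix, classification_metrics, format_metrics_table
from .synthetic import SynthParams, generate_dataset
from .tknn import PredictionEnsemble, TknnResult, run_tknn

__all__ = ["ChannelPatModel", "ChannelPatResults"]


@dataclass
class ChannelPatResults:
    """Artifacts of one fitted pipeline."""

    feature_matrix: FeatureMatrix
    selection: SelectionResult
    ensemble: PredictionEnsemble
    tknn_result: TknnResult
    confusion: ConfusionMatrix
    metrics: dict
    sentence: LobishSentence
    stats: LobeStats
    seed: int

    @property
    def accuracy(self) -> float:
        """Headline tkNN accuracy (greedy winner over the 118 outcomes).

        Selected on the same labels it is scored on; read as the
        protocol's internal cross-validated figure, not an unbiased
        estimate on unseen subjects.
        """
        return self.tknn_result.final_accuracy

    def summary(self) -> str:
        sel = self.selection
        res = self.tknn_result
        src = (
            f"classifier #{res.source_index + 1} ({res.config.k}-NN, {res.config.distance}, "
            f"{res.config.weight})"
            if res.source == "classifier"
            else f"voted outcome (top-{res.source_index} majority)"
        )
        lines = [
            "ChannelPat pipeline results",
            "===========================",
            f"Segments:            {self.feature_matrix.X.shape[0]}"
            f"  (classes: {', '.join(self.feature_matrix.class_names)})",
            f"Features extracted:  {self.feature_matrix.n_features}"
            f"  (C={self.feature_matrix.n_channels})",
            f"Features selected:   {sel.chosen_size}"
            f"  (loss-kNN CV accuracy {sel.chosen_accuracy:.4f}, "
            f"{len(sel.per_size_accuracy)} sizes evaluated)",
            f"tkNN outcomes:       {self.ensemble.n_outcomes}"
            f"  (60 classifier-wise + {self.ensemble.voted_preds.shape[0]} voted)",
            f"Final accuracy:      {res.final_accuracy:.4f}  from {src}",
            f"Seed:                {self.seed}",
            "",
            format_metrics_table(self.confusion, self.metrics),
        ]
        if self.stats is not None:
            lines += [
                "",
                f"Lobish sentence ({len(self.sentence)} symbols):",
                self.sentence.symbols,
                "Symbol counts:       "
                + ", ".join(f"{k}:{v}" for k, v in self.stats.symbol_counts.items()),
                f"Symbol entropy:      {self.stats.symbol_entropy_bits:.4f} bits (max 2)",
                f"Transition entropy:  {self.stats.transition_entropy_bits:.4f} bits (max 4)",
            ]
        return "\n".join(lines)


class ChannelPatModel:
    """Channel-rank EEG classification and interpretation pipeline.

    Parameters
    ----------
    segments, labels : labelled EEG segments (all sharing one channel count)
    lobe_lut : LobeLUT, optional
        Channel-to-lobe map; defaults to the 14-channel Emotiv layout
        when the data has 14 channels, otherwise must be provided for
        the Lobish stage.
    """

    def __init__(
        self,
        segments: list[EegSegment],
        labels: list[str],
        lobe_lut: LobeLUT | None = None,
    ) -> None:
        if len(segments) != len(labels):
            raise ValueError("segment count differs from label count")
        if not segments:
            raise ValueError("no segments")
        self.segments = list(segments)
        self.labels = [str(x) for x in labels]
        c = segments[0].n_channels
        if lobe_lut is None and c == 14:
            lobe_lut = default_lobe_lut()
        if lobe_lut is not None and len(lobe_lut) != c:
            raise ValueError(f"LUT covers {len(lobe_lut)} channels, data has {c}")
        self.lobe_lut = lobe_lut

    @classmethod
    def from_manifest(cls, path, lobe_lut: LobeLUT | None = None) -> "ChannelPatModel":
        manifest = load_manifest(path)
        from .io import load_segment

        segments = [load_segment(p) for p, _ in manifest.entries]
        return cls(segments, manifest.labels, lobe_lut=lobe_lut)

    @classmethod
    def from_synthetic(cls, params: SynthParams | None = None, **kwargs) -> "ChannelPatModel":
        params = params or SynthParams(**kwargs)
        segments, labels = generate_dataset(params)
        return cls(segments, labels)

    def fit(
        self,
        *,
        size_range: tuple[int, int] | None = None,
        seed: int = 0,
        n_folds: int = 10,
    ) -> ChannelPatResults:
        """Run extract -> select -> classify -> interpret.

        ``size_range`` defaults to (10, C^2), the full published range
        for the 14-channel montage.
        """
        fm = build_feature_matrix(segments=self.segments, labels=self.labels)
        if size_range is None:
            size_range = (min(10, fm.n_features), fm.n_features)
        # named per-stage seeds derived from the global seed
        inca_seed = int(seed)
        tknn_seed = int(seed) + 1
        selection = inca_select(
            fm, size_range=size_range, seed=inca_seed, n_folds=n_folds
        )
        cols = selection.chosen_indices - 1  # 1-based ids -> columns
        ensemble, result = run_tknn(
            fm.X[:, cols], np.asarray(fm.labels), seed=tknn_seed, n_folds=n_folds
        )
        cm = ConfusionMatrix.from_labels(
            fm.labels, result.final_labels, class_names=fm.class_names
        )
        metrics = classification_metrics(cm)
        if self.lobe_lut is not None:
            sentence = generate_sentence(selection.chosen_indices, self.lobe_lut)
            stats = lobe_stats(sentence)
        else:
            sentence = LobishSentence(symbols="", provenance=[])
            stats = None
        return ChannelPatResults(
            feature_matrix=fm,
            selection=selection,
            ensemble=ensemble,
            tknn_result=result,
            confusion=cm,
            metrics=metrics,
            sentence=sentence,
            stats=stats,
            seed=int(seed),
        )
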