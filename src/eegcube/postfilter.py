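"""Sliding-window mode filtering of predicted label streams.

A classifier emitting one emotion label per second produces occasional
isolated mispredictions; since an emotional state persists over seconds
within a film clip, replacing each label by the most frequent label in a
surrounding window corrects them.  The default filter is *centered and
non-cascading*: every output position is the mode of the ORIGINAL labels in
the window of length ``window_s`` centered at it, truncated at trial
boundaries (clips are independent, so windows never cross them).  On a tied
mode the original label is kept by default (a tie carries no evidence to
overturn the classifier); a ``lowest-class`` tie policy and a cascading
left-to-right variant (each window reads already-rewritten labels) are
available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelSequence", "mode_filter", "window_sweep"]


@dataclass
class LabelSequence:
    """Integer class labels at 1-s resolution with trial boundaries.

    ``boundaries`` is a list of half-open (start, end) index pairs
    partitioning the sequence; by default the whole sequence is one trial.
    """

    labels: np.ndarray
    n_classes: int
    boundaries: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1D sequence")
        n = self.labels.size
        if n and ((self.labels < 0).any() or (self.labels >= self.n_classes).any()):
            raise ValueError(f"labels must lie in [0, {self.n_classes})")
        if not self.boundaries:
            self.boundaries = [(0, n)] if n else []
        spans = sorted(self.boundaries)
        covered = 0
        for start, end in spans:
            if start != covered or end <= start:
                raise ValueError(
                    f"boundaries {self.boundaries} do not partition [0, {n})"
                )
            covered = end
        if spans and covered != n:
            raise ValueError(
                f"boundaries do not partition the sequence: cover [0, {covered}) "
                f"of {n} labels"
            )

    def __len__(self) -> int:
        return self.labels.size


def _filter_trial(labels: np.ndarray, window: int, tie_policy: str,
                  n_classes: int, cascade: bool) -> np.ndarray:
    n = labels.size
    half = window // 2
    source = labels.copy() if cascade else labels
    out = np.empty_like(labels)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        counts = np.bincount(source[lo:hi], minlength=n_classes)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if winners.size == 1:
            out[i] = winners[0]
        elif tie_policy == "keep-original":
            out[i] = labels[i] if labels[i] in winners else winners[0]
        else:  # lowest-class
            out[i] = winners[0]
        if cascade:
            source[i] = out[i]
    return out


def mode_filter(
    seq: LabelSequence,
    window_s: int,
    tie_policy: str = "keep-original",
    cascade: bool = False,
) -> LabelSequence:
    """Mode-filter a label stream with a centered window of ``window_s``.

    Windows truncate at trial edges (a window larger than a trial reduces
    to the whole trial); the output has the same length, boundaries and
    class count as the input.
    """
    if window_s < 1:
        raise ValueError("window must be >= 1")
    if tie_policy not in ("keep-original", "lowest-class"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    if len(seq) == 0:
        return LabelSequence(seq.labels.copy(), seq.n_classes, [])
    out = seq.labels.copy()
    for start, end in seq.boundaries:
        out[start:end] = _filter_trial(
            seq.labels[start:end], window_s, tie_policy, seq.n_classes, cascade
        )
    return LabelSequence(out, seq.n_classes, list(seq.boundaries))


def window_sweep(
    seq: LabelSequence,
    truth: LabelSequence,
    windows: list[int],
    tie_policy: str = "keep-original",
) -> list[tuple[int | None, float]]:
    """Accuracy of the filtered stream against the truth per window size.

    Returns ``[(None, unfiltered accuracy), (w, accuracy), ...]`` in the
    order given, the unfiltered baseline first.
    """
    if len(seq) != len(truth):
        raise ValueError(
            f"prediction stream has {len(seq)} labels, truth has {len(truth)}"
        )
    rows: list[tuple[int | None, float]] = [
        (None, float((seq.labels == truth.labels).mean()))
    ]
    for w in windows:
        filtered = mode_filter(seq, w, tie_policy=tie_policy)
        rows.append((w, float((filtered.labels == truth.labels).mean())))
    return rows
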