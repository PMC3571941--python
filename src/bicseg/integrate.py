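"""Multi-source consensus: merge thresholded profiles on a union grid.

Several measurements of the same individual (different platforms, labs or
preprocessing pipelines) may disagree probe by probe, and each alone may be
too sparse to resolve a short aberration.  Each source is binarized with its
own threshold — no cross-source standardization — and the resulting
indicator sequences are interleaved by genomic coordinate into one merged
sequence over the union of probe locations.  Segmenting the merged sequence
yields a consensus call at higher effective resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from bicseg.binarize import (
    CopyNumberProfile,
    Direction,
    binarize_gain,
    binarize_loss,
)
from bicseg.core import BinarySequence, SegmentationResult, segment

__all__ = [
    "SourceProfile",
    "MergedSequence",
    "ConsensusSegmentation",
    "threshold_sources",
    "merge_sources",
    "consensus_segment",
]


@dataclass(frozen=True)
class SourceProfile:
    """One source's profile with its own gain/loss thresholds."""

    source_id: str
    profile: CopyNumberProfile
    tau_plus: Optional[float] = None
    tau_minus: Optional[float] = None


@dataclass(frozen=True)
class MergedSequence:
    """Union-coordinate interleaving of several thresholded sources.

    ``provenance`` records, per merged element, the originating source id
    and the probe's 1-based index within that source.  Coincident
    coordinates from different sources remain distinct adjacent elements,
    ordered by source position in the input list.
    """

    positions: np.ndarray
    bits: np.ndarray
    source_ids: np.ndarray
    source_index: np.ndarray  # 1-based probe index within the source

    def __post_init__(self) -> None:
        n = self.bits.size
        if not (
            self.positions.size == self.source_ids.size == self.source_index.size == n
        ):
            raise ValueError("merged arrays must share one length")

    def __len__(self) -> int:
        return int(self.bits.size)

    def as_binary_sequence(self) -> BinarySequence:
        # Coincident coordinates break strict monotonicity, so the merged
        # order itself is authoritative; positions are carried separately.
        return BinarySequence(bits=self.bits)


@dataclass(frozen=True)
class ConsensusSegmentation:
    """Segmentation of a merged sequence with genomic-coordinate intervals.

    ``intervals[i]`` is the (start, end) base-pair span of the first and
    last merged probes in ``result.segments[i]``.
    """

    result: SegmentationResult
    intervals: tuple[tuple[int, int], ...]


def threshold_sources(
    sources: Sequence[SourceProfile], direction: Direction
) -> list[BinarySequence]:
    """Binarize each source with its own threshold for ``direction``.

    Sources are never standardized against one another; per-source
    thresholds absorb platform-specific attenuation.
    """
    out = []
    for src in sources:
        if direction == "gain":
            if src.tau_plus is None:
                raise ValueError(f"source {src.source_id!r} has no tau_plus")
            seq = binarize_gain(src.profile, src.tau_plus)
        elif direction == "loss":
            if src.tau_minus is None:
                raise ValueError(f"source {src.source_id!r} has no tau_minus")
            seq = binarize_loss(src.profile, src.tau_minus)
        else:
            raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
        if seq.positions is None:
            raise ValueError(
                f"source {src.source_id!r} spans multiple chromosomes; "
                "merge sources one chromosome at a time"
            )
        out.append(seq)
    return out


def merge_sources(
    thresholded: Sequence[BinarySequence],
    source_ids: Optional[Sequence[str]] = None,
) -> MergedSequence:
    """Interleave thresholded sequences by ascending genomic coordinate.

    Every source probe contributes exactly one merged element, so the total
    1-count is conserved.  Ties at coincident coordinates are stable by
    source order in the input list.
    """
    if not thresholded:
        raise ValueError("need at least one sequence to merge")
    if source_ids is None:
        source_ids = [f"source{j + 1}" for j in range(len(thresholded))]
    if len(source_ids) != len(thresholded):
        raise ValueError("source_ids must match the number of sequences")
    pos_parts, bit_parts, id_parts, idx_parts = [], [], [], []
    for sid, seq in zip(source_ids, thresholded):
        if seq.positions is None:
            raise ValueError(f"sequence from {sid!r} carries no genomic positions")
        pos_parts.append(seq.positions)
        bit_parts.append(seq.bits)
        id_parts.append(np.full(len(seq), sid, dtype=object))
        idx_parts.append(np.arange(1, len(seq) + 1))
    pos = np.concatenate(pos_parts)
    order = np.argsort(pos, kind="stable")
    return MergedSequence(
        positions=pos[order],
        bits=np.concatenate(bit_parts)[order],
        source_ids=np.concatenate(id_parts)[order],
        source_index=np.concatenate(idx_parts)[order],
    )


def consensus_segment(merged: MergedSequence) -> ConsensusSegmentation:
    """Segment a merged sequence and report genomic intervals per segment.

    Interval bounds are the positions of the first and last probes in each
    segment; the gap between adjacent segments is not apportioned.
    """
    result = segment(merged.as_binary_sequence())
    intervals = tuple(
        (int(merged.positions[s.start - 1]), int(merged.positions[s.end - 1]))
        for s in result.segments
    )
    return ConsensusSegmentation(result=result, intervals=intervals)
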