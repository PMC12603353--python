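"""Weighted voting: aggregate segment probabilities to one contig call.

Each segment votes with weight equal to its length in bases, so a short
tail segment counts proportionally less than a full window.  The contig
probability is the weight-normalized mean of segment virulence
probabilities; the hard label is virulent iff that probability reaches the
decision threshold (ties resolve to virulent).  Neutral flagged segments
(too short to tokenize, p = 0.5) are excluded whenever any informative
segment exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .model import EncoderClassifier, SegmentPrediction
from .segmentation import Segment, contiguous_segments, DEFAULT_SEGMENT_LEN, DEFAULT_MIN_TAIL
from .sequence_io import ContigRecord, TEMPERATE, VIRULENT, reverse_complement

DEFAULT_THRESHOLD = 0.5


@dataclass
class ContigPrediction:
    contig_id: str
    p_virulent: float
    label: str
    n_segments: int
    total_bases_classified: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_virulent <= 1.0):
            raise ValueError("p_virulent must lie in [0, 1]")
        if self.n_segments < 1:
            raise ValueError("a contig prediction needs at least one segment")


def vote(predictions: Sequence[SegmentPrediction],
         threshold: float = DEFAULT_THRESHOLD) -> ContigPrediction:
    """Length-weighted vote over segment predictions of one contig.

    p(contig) = sum_i w_i p_i / sum_i w_i with w_i = len(segment_i).
    Bounded by [min p_i, max p_i], permutation-invariant, and monotone in
    every p_i.
    """
    if not predictions:
        raise ValueError("no segment predictions to vote on")
    contig_ids = {p.segment.contig_id for p in predictions if p.segment is not None}
    if len(contig_ids) > 1:
        raise ValueError(f"mixed contig ids in one vote: {sorted(contig_ids)}")
    informative = [p for p in predictions if not p.flagged]
    used = informative if informative else list(predictions)
    weights = [float(len(p.segment)) if p.segment is not None else 1.0 for p in used]
    # fsum: the vote is exactly permutation-invariant in float arithmetic
    p_contig = math.fsum(w * p.p_virulent for w, p in zip(weights, used)) / math.fsum(weights)
    p_contig = min(1.0, max(0.0, p_contig))
    contig_id = next(iter(contig_ids)) if contig_ids else ""
    n_bases = sum(len(p.segment) for p in used if p.segment is not None)
    return ContigPrediction(
        contig_id=contig_id,
        p_virulent=p_contig,
        label=VIRULENT if p_contig >= threshold else TEMPERATE,
        n_segments=len(used),
        total_bases_classified=n_bases,
    )


def predict_contig(
    model: EncoderClassifier,
    record: ContigRecord,
    segment_len: int = DEFAULT_SEGMENT_LEN,
    min_tail: int = DEFAULT_MIN_TAIL,
    both_strands: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
    batch_size: int = 64,
) -> ContigPrediction:
    """Contiguous segmentation -> segment prediction -> weighted vote.

    With ``both_strands`` the reverse complement of the contig is tiled the
    same way and its segments join the same vote.  Because the union of the
    two tilings is identical for a contig and its reverse complement, the
    call is exactly invariant to input orientation.  Deterministic for a
    fixed model.
    """
    L = len(record.seq)
    segments = contiguous_segments(record, segment_len=segment_len, min_tail=min_tail)
    if both_strands:
        rc_record = ContigRecord(record.id, reverse_complement(record.seq),
                                 record.label, record.source)
        for s in contiguous_segments(rc_record, segment_len=segment_len,
                                     min_tail=min_tail):
            # report coordinates in the forward frame, strand "-"
            segments.append(
                Segment(record.id, L - s.end, L - s.start, "-", s.seq, record.label)
            )
    preds = model.predict_segments(segments, batch_size=batch_size)
    return vote(preds, threshold=threshold)


def contig_label_predictor(model: EncoderClassifier, **kwargs):
    """A ContigRecord -> label callable for the benchmark harness."""

    def _predict(record: ContigRecord) -> str:
        return predict_contig(model, record, **kwargs).label

    return _predict
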