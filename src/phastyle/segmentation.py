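"""Segmentation of contigs into classifier-sized pieces.

Three regimes:

* random training segmentation at a fixed expected per-base coverage
  (default 10x, 512 bp segments),
* contiguous non-overlapping tiling for inference,
* fixed-length fragment simulation for the benchmark protocol
  (default lengths 500, 2000 and 10000 bp, class-balanced).

Coordinates are 0-based half-open throughout.  A segment on strand "-"
carries the reverse complement of the parent slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .sequence_io import ContigRecord, reverse_complement

DEFAULT_SEGMENT_LEN = 512
DEFAULT_COVERAGE = 10.0
DEFAULT_FRAGMENT_LENGTHS = (500, 2000, 10000)
DEFAULT_MIN_TAIL = 50


@dataclass
class Segment:
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # "+" or "-"
    seq: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad segment coordinates [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.seq) != self.end - self.start:
            raise ValueError("segment seq length disagrees with coordinates")

    def __len__(self) -> int:
        return self.end - self.start


def _slice(record: ContigRecord, start: int, end: int, strand: str) -> Segment:
    seq = record.seq[start:end]
    if strand == "-":
        seq = reverse_complement(seq)
    return Segment(record.id, start, end, strand, seq, record.label)


def n_training_segments(genome_len: int, segment_len: int, coverage: float) -> int:
    """Number of random segments drawn: ceil(coverage * L / segment_len)."""
    return math.ceil(coverage * genome_len / segment_len)


def sample_training_segments(
    record: ContigRecord,
    segment_len: int = DEFAULT_SEGMENT_LEN,
    coverage: float = DEFAULT_COVERAGE,
    rng: Optional[np.random.Generator] = None,
    both_strands: bool = True,
) -> list[Segment]:
    """Randomly sample segments at a fixed expected per-base coverage.

    Start positions are uniform on [0, L - segment_len] with replacement;
    the number of draws is ceil(coverage * L / segment_len) so that expected
    per-base coverage equals ``coverage``.  Contigs shorter than
    ``segment_len`` are emitted whole, ceil(coverage) times.  With
    ``both_strands`` every drawn segment is also emitted as its reverse
    complement (strand augmentation).
    """
    if segment_len < 1:
        raise ValueError("segment_len must be >= 1")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    L = len(record.seq)
    segments: list[Segment] = []
    if L < segment_len:
        starts = np.zeros(math.ceil(coverage), dtype=int)
        seg_len = L
    else:
        n = n_training_segments(L, segment_len, coverage)
        starts = rng.integers(0, L - segment_len + 1, size=n)
        seg_len = segment_len
    for s in starts:
        s = int(s)
        segments.append(_slice(record, s, s + seg_len, "+"))
        if both_strands:
            segments.append(_slice(record, s, s + seg_len, "-"))
    return segments


def contiguous_segments(
    record: ContigRecord,
    segment_len: int = DEFAULT_SEGMENT_LEN,
    min_tail: int = DEFAULT_MIN_TAIL,
) -> list[Segment]:
    """Tile a contig into non-overlapping windows for inference.

    Windows are [0, l), [l, 2l), ... in genomic order; the final partial
    window is kept iff it is at least ``min_tail`` bases long.  A contig
    shorter than ``segment_len`` yields one whole-contig segment.
    """
    if segment_len < 1:
        raise ValueError("segment_len must be >= 1")
    L = len(record.seq)
    if L <= segment_len:
        return [_slice(record, 0, L, "+")]
    segments = []
    for start in range(0, L - segment_len + 1, segment_len):
        segments.append(_slice(record, start, start + segment_len, "+"))
    tail_start = segments[-1].end
    if L - tail_start >= min_tail:
        segments.append(_slice(record, tail_start, L, "+"))
    return segments


def simulate_fragments(
    records: Sequence[ContigRecord],
    lengths: Sequence[int] = DEFAULT_FRAGMENT_LENGTHS,
    n_per_class_per_length: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> dict[int, list[ContigRecord]]:
    """Simulate fixed-length assembly fragments from labeled contigs.

    For every requested length L an equal number of virulent- and
    temperate-derived fragments is drawn: each fragment is a uniform random
    slice of exactly L bases from a randomly chosen source contig of that
    class with length >= L.  Fragments inherit the source label and record
    the source contig id in ``source`` for leakage accounting.
    """
    rng = np.random.default_rng() if rng is None else rng
    by_class: dict[str, list[ContigRecord]] = {"virulent": [], "temperate": []}
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} is unlabeled")
        by_class[rec.label].append(rec)
    for label, recs in by_class.items():
        if not recs:
            raise ValueError(f"no records of class {label!r}")
    out: dict[int, list[ContigRecord]] = {}
    for L in lengths:
        frags: list[ContigRecord] = []
        for label in ("virulent", "temperate"):
            eligible = [r for r in by_class[label] if len(r.seq) >= L]
            if not eligible:
                raise ValueError(f"no {label} record of length >= {L}")
            picks = rng.integers(0, len(eligible), size=n_per_class_per_length)
            for j, pick in enumerate(picks):
                src = eligible[int(pick)]
                start = int(rng.integers(0, len(src.seq) - L + 1))
                frags.append(
                    ContigRecord(
                        id=f"frag_{L}_{label}_{j}",
                        seq=src.seq[start : start + L],
                        label=label,
                        source=src.id,
                    )
                )
        out[L] = frags
    return out
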