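"""FASTA input/output and basic nucleotide-sequence utilities.

Everything downstream (segmentation, tokenization, sketching) works on a
closed alphabet {A, C, G, T, N}.  Reading normalizes to that alphabet:
lowercase is uppercased and any other IUPAC/ambiguity character becomes N
(counted and reported via logging).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

VIRULENT = "virulent"
TEMPERATE = "temperate"
LIFESTYLES = (VIRULENT, TEMPERATE)

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# any byte not in the closed alphabet is rewritten to N on read
_NORMALIZE = {c: c for c in "ACGTN"}
_NORMALIZE.update({c.lower(): c for c in "ACGTN"})


@dataclass
class ContigRecord:
    """An identified nucleotide sequence with optional lifestyle label.

    ``seq`` is uppercase over {A,C,G,T,N} and non-empty; ``label`` is one of
    ``"virulent"`` / ``"temperate"`` or None; ``source`` is free-text
    provenance (e.g. the originating genome of a simulated fragment).
    """

    id: str
    seq: str
    label: Optional[str] = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        if self.label is not None and self.label not in LIFESTYLES:
            raise ValueError(f"contig {self.id!r}: unknown label {self.label!r}")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase ``raw`` and map non-ACGTN characters to N.

    Returns the normalized sequence and the number of characters rewritten.
    """
    out = []
    n_ambiguous = 0
    for c in raw:
        norm = _NORMALIZE.get(c)
        if norm is None:
            norm = "N"
            n_ambiguous += 1
        out.append(norm)
    return "".join(out), n_ambiguous


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[ContigRecord]:
    """Read a (optionally gzip-compressed) FASTA file into ContigRecords.

    Raises on missing files, empty files and duplicate record ids.  Counts
    of ambiguity characters collapsed to N are logged as a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ContigRecord] = []
    seen: set[str] = set()
    n_ambiguous = 0
    with _open_maybe_gzip(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            if entry.id in seen:
                raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
            seen.add(entry.id)
            seq, n_amb = normalize_sequence(str(entry.seq))
            n_ambiguous += n_amb
            records.append(ContigRecord(id=entry.id, seq=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if n_ambiguous:
        logger.warning(
            "%s: %d ambiguous characters mapped to N", path, n_ambiguous
        )
    return records


def write_fasta(records: Iterable[ContigRecord], path, width: int = 70) -> None:
    """Write records as FASTA (gzip if the path ends in .gz), 70-col lines."""
    path = Path(path)
    with _open_maybe_gzip(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV ``contig_id<TAB>label`` into a dict."""
    path = Path(path)
    labels: dict[str, str] = {}
    with _open_maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            cid, label = parts
            if label not in LIFESTYLES:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            if cid in labels:
                raise ValueError(f"{path}:{lineno}: duplicate contig id {cid!r}")
            labels[cid] = label
    return labels


def write_labels(records: Iterable[ContigRecord], path) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            if rec.label is not None:
                handle.write(f"{rec.id}\t{rec.label}\n")


def attach_labels(records: list[ContigRecord], labels: dict[str, str]) -> list[ContigRecord]:
    """Return records with labels attached; missing ids stay unlabeled."""
    return [
        ContigRecord(rec.id, rec.seq, labels.get(rec.id, rec.label), rec.source)
        for rec in records
    ]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"characters outside A/C/G/T/N: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Distinct canonical (strand-minimum) k-mers of ``seq``.

    Each length-k window without N contributes min(window, rc(window)) in
    lexicographic order; windows containing N are skipped.  A sequence
    shorter than k yields the empty set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        rc = reverse_complement(window)
        out.add(window if window <= rc else rc)
    return out
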