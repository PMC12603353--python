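"""Train-test leakage control: MinHash sketches, ANI estimates, holdout filtering.

Relatedness between training and test genomes is estimated two ways:

* a bottom-k MinHash sketch (default: the 300 smallest 64-bit MurmurHash3
  values, seed 3, over canonical 21-mers) giving a Jaccard estimate and a
  Mash-style ANI estimate, and
* ingestion of FastANI all-against-all output, which additionally carries
  the aligned-length fraction.

``build_holdout`` applies the removal rule: in strict mode, a training
record showing >= 80% ANI to any test record (over >= 80% of its length,
when an aligned fraction is available from FastANI) is removed; standard
mode leaves the training set untouched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._murmur3 import hash64_rows
from .sequence_io import ContigRecord

DEFAULT_SKETCH_K = 21
DEFAULT_SKETCH_SIZE = 300
DEFAULT_SKETCH_SEED = 3
DEFAULT_ANI_THRESHOLD = 0.80
DEFAULT_FRAC_THRESHOLD = 0.80

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MinHashSignature:
    """Bottom-k sketch: the ``size`` smallest distinct hash values of a
    sequence's canonical k-mer set (fewer if the sequence is k-mer-poor)."""

    contig_id: str
    k: int
    size: int
    seed: int
    mins: tuple[int, ...]  # strictly increasing 64-bit values

    def __post_init__(self) -> None:
        if len(self.mins) > self.size:
            raise ValueError("sketch larger than its nominal size")
        if any(b <= a for a, b in zip(self.mins, self.mins[1:])):
            raise ValueError("sketch mins must be strictly increasing")

    def compatible(self, other: "MinHashSignature") -> bool:
        return (self.k, self.size, self.seed) == (other.k, other.size, other.seed)


def _canonical_kmer_hashes(seq: str, k: int, seed: int) -> np.ndarray:
    """Distinct 64-bit hashes of the canonical k-mers of ``seq`` (vectorized).

    Canonical means the lexicographic minimum of a window and its reverse
    complement; windows containing N are skipped.  Equals hashing the output
    of ``sequence_io.canonical_kmers`` (property-checked in the tests).
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31] for 2-bit packing")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.uint64)
    is_n = (codes == 255).astype(np.int32)
    csum = np.concatenate([[0], np.cumsum(is_n)])
    valid = (csum[k:] - csum[:-k]) == 0
    if not valid.any():
        return np.empty(0, dtype=np.uint64)
    codes64 = np.where(codes == 255, 0, codes).astype(np.uint64)
    fwd = np.zeros(n_win, dtype=np.uint64)
    rc = np.zeros(n_win, dtype=np.uint64)
    for j in range(k):
        base = codes64[j : j + n_win]
        fwd |= base << np.uint64(2 * (k - 1 - j))
        rc |= (np.uint64(3) - base) << np.uint64(2 * j)
    canon = np.minimum(fwd, rc)[valid]
    canon = np.unique(canon)
    # unpack the 2-bit canonical k-mers back to ASCII rows and hash them
    rows = np.empty((len(canon), k), dtype=np.uint8)
    for j in range(k):
        rows[:, j] = _ASCII[((canon >> np.uint64(2 * (k - 1 - j))) & np.uint64(3)).astype(np.intp)]
    return np.unique(hash64_rows(rows, seed=seed))


def sketch(
    record: ContigRecord,
    k: int = DEFAULT_SKETCH_K,
    size: int = DEFAULT_SKETCH_SIZE,
    seed: int = DEFAULT_SKETCH_SEED,
) -> MinHashSignature:
    """Bottom-``size`` MinHash signature of a contig's canonical k-mers."""
    hashes = _canonical_kmer_hashes(record.seq, k, seed)
    if len(hashes) > size:
        mins = np.sort(np.partition(hashes, size)[:size])
    else:
        mins = np.sort(hashes)
    return MinHashSignature(
        contig_id=record.id, k=k, size=size, seed=seed,
        mins=tuple(int(x) for x in mins),
    )


def jaccard_estimate(a: MinHashSignature, b: MinHashSignature) -> float:
    """Bottom-k merge estimator of the Jaccard index of two k-mer sets."""
    if not a.compatible(b):
        raise ValueError("signatures have different (k, size, seed) parameters")
    if not a.mins or not b.mins:
        return 0.0
    set_a, set_b = set(a.mins), set(b.mins)
    if len(a.mins) < a.size or len(b.mins) < b.size:
        # tiny sketches hold the full hash sets; use the smaller set size
        denom = min(len(a.mins), len(b.mins))
        return len(set_a & set_b) / denom
    union = np.union1d(np.array(a.mins, dtype=np.uint64), np.array(b.mins, dtype=np.uint64))
    merged = union[: a.size]
    shared = sum(1 for h in merged.tolist() if h in set_a and h in set_b)
    return shared / len(merged)


def ani_from_jaccard(j: float, k: int = DEFAULT_SKETCH_K) -> float:
    """Mash-style ANI estimate: 1 + (1/k) * ln(2j / (1 + j)), clipped to [0, 1].

    j = 0 has no defined estimate and is reported as 0.
    """
    if not (0.0 <= j <= 1.0):
        raise ValueError("jaccard must lie in [0, 1]")
    if j == 0.0:
        return 0.0
    ani = 1.0 + math.log(2.0 * j / (1.0 + j)) / k
    return min(1.0, max(0.0, ani))


@dataclass(frozen=True)
class PairSimilarity:
    id_a: str
    id_b: str
    jaccard_est: Optional[float]
    ani_est: float
    aligned_frac: Optional[float] = None
    source: str = "sketch"  # or "fastani"
    ani_defined: bool = True


def sketch_similarity(a: MinHashSignature, b: MinHashSignature) -> PairSimilarity:
    j = jaccard_estimate(a, b)
    return PairSimilarity(
        id_a=a.contig_id, id_b=b.contig_id,
        jaccard_est=j, ani_est=ani_from_jaccard(j, a.k),
        aligned_frac=None, source="sketch", ani_defined=j > 0.0,
    )


def parse_fastani(path) -> list[PairSimilarity]:
    """Parse FastANI default 5-column output (query, ref, ANI%, matched, total)."""
    path = Path(path)
    pairs: list[PairSimilarity] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(parts)}"
                )
            query, ref, ani_pct, matched, total = parts
            try:
                ani = float(ani_pct) / 100.0
                matched_i, total_i = int(matched), int(total)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if total_i <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive fragment total")
            pairs.append(
                PairSimilarity(
                    id_a=query, id_b=ref, jaccard_est=None, ani_est=ani,
                    aligned_frac=matched_i / total_i, source="fastani",
                )
            )
    return pairs


@dataclass
class Removal:
    train_id: str
    test_id: str
    ani_est: float
    aligned_frac: Optional[float]
    source: str


@dataclass
class HoldoutReport:
    mode: str
    ani_threshold: float
    frac_threshold: float
    similarity_source: str
    removals: list[Removal] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def removed_ids(self) -> set[str]:
        return {r.train_id for r in self.removals}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("train_id\ttest_id\tani_est\taligned_frac\tsource\n")
            for r in self.removals:
                frac = "" if r.aligned_frac is None else f"{r.aligned_frac:.4f}"
                fh.write(f"{r.train_id}\t{r.test_id}\t{r.ani_est:.4f}\t{frac}\t{r.source}\n")


def _sketch_removals(
    train: Sequence[ContigRecord],
    test: Sequence[ContigRecord],
    ani_threshold: float,
    sketch_k: int,
    sketch_size: int,
    sketch_seed: int,
) -> list[Removal]:
    test_sigs = [sketch(r, sketch_k, sketch_size, sketch_seed) for r in test]
    removals = []
    for rec in train:
        sig = sketch(rec, sketch_k, sketch_size, sketch_seed)
        for tsig in test_sigs:
            sim = sketch_similarity(sig, tsig)
            if sim.ani_defined and sim.ani_est >= ani_threshold:
                removals.append(
                    Removal(rec.id, tsig.contig_id, sim.ani_est, None, "sketch")
                )
                break
    return removals


def _fastani_removals(
    train_ids: set[str],
    test_ids: set[str],
    pairs: Sequence[PairSimilarity],
    ani_threshold: float,
    frac_threshold: float,
) -> list[Removal]:
    removals = []
    flagged: set[str] = set()
    for p in pairs:
        # the record on the training side is the FastANI query, whose
        # fragment fraction measures the 80%-of-length clause
        if p.id_a in train_ids and p.id_b in test_ids and p.id_a not in flagged:
            frac_ok = p.aligned_frac is None or p.aligned_frac >= frac_threshold
            if p.ani_est >= ani_threshold and frac_ok:
                flagged.add(p.id_a)
                removals.append(Removal(p.id_a, p.id_b, p.ani_est, p.aligned_frac, "fastani"))
    return removals


def build_holdout(
    train: Sequence[ContigRecord],
    test: Sequence[ContigRecord],
    mode: str = "strict",
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
    frac_threshold: float = DEFAULT_FRAC_THRESHOLD,
    fastani_pairs: Optional[Sequence[PairSimilarity]] = None,
    sketch_k: int = DEFAULT_SKETCH_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    sketch_seed: int = DEFAULT_SKETCH_SEED,
) -> tuple[list[ContigRecord], HoldoutReport]:
    """Construct a strict- or standard-holdout training set.

    Standard mode returns the training set unchanged.  Strict mode removes
    every training record related to any test record: ANI >= ani_threshold,
    and additionally aligned fraction >= frac_threshold when similarities
    come from a FastANI table.  Sketch-based filtering applies the ANI
    criterion alone (an aligned fraction cannot be derived from a Jaccard
    sketch); the report records this.
    """
    if mode not in ("strict", "standard"):
        raise ValueError(f"unknown holdout mode {mode!r}")
    if not train or not test:
        raise ValueError("train and test sets must both be non-empty")
    source = "fastani" if fastani_pairs is not None else "sketch"
    report = HoldoutReport(
        mode=mode, ani_threshold=ani_threshold, frac_threshold=frac_threshold,
        similarity_source=source,
    )
    if mode == "standard":
        return list(train), report
    if fastani_pairs is not None:
        report.removals = _fastani_removals(
            {r.id for r in train}, {r.id for r in test},
            fastani_pairs, ani_threshold, frac_threshold,
        )
    else:
        report.notes.append(
            "sketch similarity source: aligned-fraction clause not applicable"
        )
        report.removals = _sketch_removals(
            train, test, ani_threshold, sketch_k, sketch_size, sketch_seed
        )
    removed = report.removed_ids
    return [r for r in train if r.id not in removed], report


def verify_holdout(
    train: Sequence[ContigRecord],
    test: Sequence[ContigRecord],
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
    sketch_k: int = DEFAULT_SKETCH_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    sketch_seed: int = DEFAULT_SKETCH_SEED,
) -> list[tuple[str, str, float]]:
    """Return surviving train-test pairs still meeting the ANI criterion."""
    train_sigs = [sketch(r, sketch_k, sketch_size, sketch_seed) for r in train]
    test_sigs = [sketch(r, sketch_k, sketch_size, sketch_seed) for r in test]
    violations = []
    for sig in train_sigs:
        for tsig in test_sigs:
            sim = sketch_similarity(sig, tsig)
            if sim.ani_defined and sim.ani_est >= ani_threshold:
                violations.append((sig.contig_id, tsig.contig_id, sim.ani_est))
    return violations


def save_signatures(signatures: Sequence[MinHashSignature], path) -> None:
    """Serialize signatures as JSON lines."""
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write(json.dumps({
                "contig_id": sig.contig_id, "k": sig.k, "size": sig.size,
                "seed": sig.seed, "mins": list(sig.mins),
            }) + "\n")


def load_signatures(path) -> list[MinHashSignature]:
    sigs = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                sigs.append(MinHashSignature(
                    contig_id=d["contig_id"], k=d["k"], size=d["size"],
                    seed=d["seed"], mins=tuple(d["mins"]),
                ))
    return sigs
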