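"""Synthetic labeled phage genomes for desk-scale testing of the pipeline.

Real virulent and temperate phages differ in gene repertoire (integrase and
excisionase cassettes in temperate genomes versus lysis and nucleotide-
metabolism genes in virulent ones).  The generator emulates that signal
abstractly: lifestyle is encoded by planted, mutation-noised 30-bp motif
cassettes drawn from two class-specific motif sets that share no canonical
21-mer, inserted into a random background of tunable GC content.  Signal
density is tuned so that 500-bp fragments are genuinely hard (most contain
no cassette) while 10-kb fragments almost surely contain several — the
qualitative difficulty gradient of fragmented real assemblies.

Divergence-controlled "families" of point-mutant genomes exercise the
leakage filter: a descendant at per-site divergence d has true ANI = 1 - d
against its ancestor by construction (no indels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sequence_io import ContigRecord, TEMPERATE, VIRULENT, canonical_kmers

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Fixed default signature motifs (30-mers).  The two sets share no
# canonical 21-mer (asserted by GeneratorConfig.validate).
DEFAULT_VIRULENT_MOTIFS = (
    "ACTACGAACCTAACCACCAATCTTCGACGC",
    "GGAGAGCTAGAAGGCCGGCCTCGTAACCAA",
    "GTTCTCTTCCTTCGGCGAGTATCGCAGGTA",
    "TGTACGCCAACCTCATCCGACGAGATTTCG",
)
DEFAULT_TEMPERATE_MOTIFS = (
    "AGGAAGTCATCTATGTTTTGTTCTATTTGG",
    "TCGGCGGTAGAAAGCCGTATTGAACGGAAA",
    "GTAATATGACGGTACCGTGTCGTACCACCA",
    "AAGCCAGAGGAATTTACATATTTTCGACAA",
)


@dataclass(frozen=True)
class GeneratorConfig:
    genome_len_range: tuple[int, int] = (20_000, 100_000)
    gc_content: float = 0.5
    motif_set_virulent: tuple[str, ...] = DEFAULT_VIRULENT_MOTIFS
    motif_set_temperate: tuple[str, ...] = DEFAULT_TEMPERATE_MOTIFS
    cassettes_per_genome: int = 100
    motif_mutation_rate: float = 0.02
    background_order: int = 0  # 0 = iid, 1 = first-order Markov
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.genome_len_range
        if not (0 < lo <= hi):
            raise ValueError("bad genome length range")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie in (0, 1)")
        if not (0.0 <= self.motif_mutation_rate <= 0.3):
            raise ValueError("motif_mutation_rate must lie in [0, 0.3]")
        if self.background_order not in (0, 1):
            raise ValueError("background_order must be 0 or 1")
        if self.cassettes_per_genome < 0:
            raise ValueError("cassettes_per_genome must be >= 0")
        kv = set().union(*(canonical_kmers(m, 21) for m in self.motif_set_virulent))
        kt = set().union(*(canonical_kmers(m, 21) for m in self.motif_set_temperate))
        if kv & kt:
            raise ValueError("class motif sets share canonical 21-mers")

    def motifs(self, lifestyle: str) -> tuple[str, ...]:
        if lifestyle == VIRULENT:
            return self.motif_set_virulent
        if lifestyle == TEMPERATE:
            return self.motif_set_temperate
        raise ValueError(f"unknown lifestyle {lifestyle!r}")


def _background(length: int, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    gc = cfg.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if cfg.background_order == 0:
        return rng.choice(4, size=length, p=probs)
    # first-order Markov: with probability rho repeat the previous base,
    # otherwise draw iid at the stationary composition
    rho = 0.1
    draws = rng.choice(4, size=length, p=probs)
    repeat = rng.random(length) < rho
    out = draws.copy()
    for i in range(1, length):
        if repeat[i]:
            out[i] = out[i - 1]
    return out


def _mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point-mutate 2-bit base codes: each site changes to a different base
    with probability ``rate``."""
    if rate <= 0:
        return codes
    hit = rng.random(len(codes)) < rate
    if not hit.any():
        return codes
    out = codes.copy()
    # shift by 1..3 mod 4 guarantees a different base
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _seq_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside A/C/G/T")
    return codes


def generate_genome(
    lifestyle: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    genome_id: Optional[str] = None,
) -> ContigRecord:
    """One labeled genome: Markov background + planted, noised motif cassettes.

    Cassette positions are uniform random and non-overlapping; each cassette
    is an independently point-mutated copy of a motif drawn from the class's
    motif set.
    """
    cfg.validate()
    motifs = cfg.motifs(lifestyle)
    lo, hi = cfg.genome_len_range
    length = int(rng.integers(lo, hi + 1))
    motif_len = len(motifs[0])
    if cfg.cassettes_per_genome * motif_len > length // 2:
        raise ValueError("genome too short to host the requested cassettes")
    codes = _background(length, cfg, rng)
    # rejection-sample non-overlapping insertion positions
    taken: list[tuple[int, int]] = []
    placed = 0
    attempts = 0
    while placed < cfg.cassettes_per_genome:
        attempts += 1
        if attempts > 1000 * max(1, cfg.cassettes_per_genome):
            raise RuntimeError("could not place cassettes without overlap")
        start = int(rng.integers(0, length - motif_len + 1))
        if any(start < e and s < start + motif_len for s, e in taken):
            continue
        taken.append((start, start + motif_len))
        motif = motifs[int(rng.integers(0, len(motifs)))]
        cassette = _mutate_codes(_seq_to_codes(motif), cfg.motif_mutation_rate, rng)
        codes[start : start + motif_len] = cassette
        placed += 1
    gid = genome_id or f"{lifestyle}_{rng.integers(0, 10**9)}"
    return ContigRecord(id=gid, seq=_codes_to_seq(codes), label=lifestyle, source="synthetic")


@dataclass
class DatasetSplits:
    train: list[ContigRecord]
    val: list[ContigRecord]
    test: list[ContigRecord]

    def all_records(self) -> list[ContigRecord]:
        return self.train + self.val + self.test


def generate_dataset(
    n_per_class: int,
    cfg: GeneratorConfig = GeneratorConfig(),
    rng: Optional[np.random.Generator] = None,
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
) -> DatasetSplits:
    """Class-balanced labeled genomes in disjoint train/val/test splits.

    Each class contributes n_per_class genomes, split per class at the given
    fractions (train gets the remainder), so splits stay class-balanced.
    Fully reproducible from the generator state.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    splits = DatasetSplits([], [], [])
    for lifestyle in (VIRULENT, TEMPERATE):
        genomes = [
            generate_genome(lifestyle, cfg, rng, genome_id=f"{lifestyle}_{i}")
            for i in range(n_per_class)
        ]
        n_val = int(round(split_fractions[1] * n_per_class))
        n_test = int(round(split_fractions[2] * n_per_class))
        if n_per_class >= 3:
            # keep every requested split non-empty at small n
            n_val = max(n_val, 1 if split_fractions[1] > 0 else 0)
            n_test = max(n_test, 1 if split_fractions[2] > 0 else 0)
        n_train = n_per_class - n_val - n_test
        if n_train < 1:
            raise ValueError("split fractions leave no training genomes")
        splits.train.extend(genomes[:n_train])
        splits.val.extend(genomes[n_train : n_train + n_val])
        splits.test.extend(genomes[n_train + n_val :])
    return splits


def generate_family(
    ancestor: ContigRecord,
    divergence: float,
    n: int,
    rng: np.random.Generator,
) -> list[ContigRecord]:
    """n independent point-mutant descendants of ``ancestor``.

    Substitutions only (no indels), each site mutated with probability
    ``divergence``, so true ANI against the ancestor is 1 - divergence in
    expectation and analytically known for filter tests.
    """
    if not (0.0 <= divergence <= 0.3):
        raise ValueError("divergence must lie in [0, 0.3]")
    codes = _seq_to_codes(ancestor.seq)
    out = []
    for i in range(n):
        child = _mutate_codes(codes, divergence, rng)
        out.append(
            ContigRecord(
                id=f"{ancestor.id}_d{divergence:g}_{i}",
                seq=_codes_to_seq(child),
                label=ancestor.label,
                source=f"family:{ancestor.id}",
            )
        )
    return out
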