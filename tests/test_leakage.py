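"""MinHash sketching, Jaccard/ANI estimation and holdout filtering."""

import math

import numpy as np
import pytest

from phastyle._murmur3 import hash64, hash64_rows, murmur3_x64_128
from phastyle.leakage import (MinHashSignature, ani_from_jaccard, build_holdout,
                              jaccard_estimate, load_signatures, parse_fastani,
                              save_signatures, sketch, sketch_similarity,
                              verify_holdout)
from phastyle.sequence_io import ContigRecord, canonical_kmers, reverse_complement
from phastyle.synthetic import generate_family


def _random_contig(n, rng, cid="c"):
    return ContigRecord(cid, "".join(rng.choice(list("ACGT"), size=n)))


class TestMurmur3:
    def test_smhasher_verification_value(self):
        # standard self-test of the x64-128 variant: hash the concatenated
        # digests of 256 incremental keys; low 32 bits must be 0x6384BA69
        buf = b""
        for i in range(256):
            h1, h2 = murmur3_x64_128(bytes(range(i)), 256 - i)
            buf += h1.to_bytes(8, "little") + h2.to_bytes(8, "little")
        assert murmur3_x64_128(buf, 0)[0] & 0xFFFFFFFF == 0x6384BA69

    def test_vectorized_matches_scalar(self, rng):
        rows = rng.integers(65, 91, size=(200, 21)).astype(np.uint8)
        vec = hash64_rows(rows, seed=3)
        ref = np.array([hash64(bytes(r), 3) for r in rows], dtype=np.uint64)
        assert (vec == ref).all()

    def test_seed_changes_hash(self):
        assert hash64(b"ACGTACGTACGTACGTACGTA", 3) != hash64(b"ACGTACGTACGTACGTACGTA", 4)


class TestSketch:
    def test_deterministic(self, rng):
        rec = _random_contig(5000, rng)
        assert sketch(rec).mins == sketch(rec).mins

    def test_full_size_signature(self, rng):
        # >= 300 distinct canonical 21-mers -> exactly 300 elements
        rec = _random_contig(2000, rng)
        sig = sketch(rec)
        assert len(sig.mins) == 300
        assert all(b > a for a, b in zip(sig.mins, sig.mins[1:]))

    def test_strand_invariance(self, rng):
        rec = _random_contig(3000, rng)
        rc = ContigRecord("rc", reverse_complement(rec.seq))
        assert sketch(rec).mins == sketch(rc).mins

    def test_matches_bruteforce_hash_of_canonical_kmers(self, rng):
        # the vectorized packing path equals hashing canonical_kmers() output
        rec = _random_contig(400, rng)
        expected = sorted(
            hash64(km.encode(), 3) for km in canonical_kmers(rec.seq, 21)
        )[:300]
        assert list(sketch(rec).mins) == expected

    def test_short_sequence_gives_short_sketch(self):
        sig = sketch(ContigRecord("s", "ACGTACGTACGTACGTACGTACG"))  # 23 bp -> 3 windows
        assert 0 < len(sig.mins) <= 3

    def test_n_windows_skipped(self):
        sig = sketch(ContigRecord("s", "A" * 10 + "N" + "A" * 10))  # no N-free window
        assert len(sig.mins) == 0

    def test_jsonl_roundtrip(self, rng, tmp_path):
        sigs = [sketch(_random_contig(1000, rng, f"c{i}")) for i in range(3)]
        save_signatures(sigs, tmp_path / "sigs.jsonl")
        assert load_signatures(tmp_path / "sigs.jsonl") == sigs


class TestJaccard:
    def test_self_similarity(self, rng):
        sig = sketch(_random_contig(5000, rng))
        assert jaccard_estimate(sig, sig) == 1.0

    def test_disjoint_sequences(self, rng):
        a = sketch(ContigRecord("a", "A" * 100))
        b = sketch(ContigRecord("b", "C" * 100))
        assert jaccard_estimate(a, b) == 0.0

    def test_parameter_mismatch_rejected(self, rng):
        rec = _random_contig(1000, rng)
        with pytest.raises(ValueError):
            jaccard_estimate(sketch(rec, seed=3), sketch(rec, seed=4))

    def test_estimate_tracks_exact_jaccard(self, rng):
        # two 10 kb sequences sharing an engineered common core
        core = "".join(rng.choice(list("ACGT"), size=5000))
        a = ContigRecord("a", core + "".join(rng.choice(list("ACGT"), size=5000)))
        b = ContigRecord("b", "".join(rng.choice(list("ACGT"), size=5000)) + core)
        exact = len(canonical_kmers(a.seq, 21) & canonical_kmers(b.seq, 21)) / len(
            canonical_kmers(a.seq, 21) | canonical_kmers(b.seq, 21)
        )
        est = jaccard_estimate(sketch(a), sketch(b))
        assert abs(est - exact) < 0.1


class TestAniFromJaccard:
    def test_identity(self):
        assert ani_from_jaccard(1.0, 21) == 1.0

    def test_zero_jaccard_flagged_as_undefined(self, rng):
        a = sketch(ContigRecord("a", "A" * 100))
        b = sketch(ContigRecord("b", "C" * 100))
        sim = sketch_similarity(a, b)
        assert sim.ani_est == 0.0 and not sim.ani_defined

    def test_monotone_in_jaccard(self):
        grid = np.linspace(0.01, 1.0, 25)
        anis = [ani_from_jaccard(j, 21) for j in grid]
        assert all(x < y for x, y in zip(anis, anis[1:]) if y < 1.0)

    def test_mutation_simulation_oracle(self, rng):
        # 5% per-site divergence -> ANI estimate within 0.02 of 0.95
        anc = _random_contig(20_000, rng, "anc")
        (child,) = generate_family(anc, 0.05, 1, rng)
        sim = sketch_similarity(sketch(anc), sketch(child))
        assert abs(sim.ani_est - 0.95) < 0.02

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            ani_from_jaccard(1.5, 21)


class TestParseFastani:
    def test_row_arithmetic(self, tmp_path):
        p = tmp_path / "ani.tsv"
        p.write_text("a\tb\t97.5\t80\t100\n")
        (pair,) = parse_fastani(p)
        assert pair.ani_est == pytest.approx(0.975)
        assert pair.aligned_frac == pytest.approx(0.80)
        assert pair.source == "fastani"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "ani.tsv"
        p.write_text("")
        assert parse_fastani(p) == []

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "ani.tsv"
        p.write_text("a\tb\t97.5\t80\t100\na\tb\t97.5\t80\n")
        with pytest.raises(ValueError, match=":2:"):
            parse_fastani(p)


class TestBuildHoldout:
    def test_identical_record_removed_in_strict(self, rng):
        shared = _random_contig(5000, rng, "shared")
        train = [shared, _random_contig(5000, rng, "other")]
        test = [ContigRecord("test_copy", shared.seq)]
        filtered, report = build_holdout(train, test, "strict")
        assert [r.id for r in filtered] == ["other"]
        assert report.removals[0].ani_est == 1.0

    def test_standard_mode_removes_nothing(self, rng):
        shared = _random_contig(5000, rng, "shared")
        filtered, report = build_holdout(
            [shared], [ContigRecord("t", shared.seq)], "standard"
        )
        assert len(filtered) == 1 and not report.removals

    def test_divergence_controlled_families(self, rng):
        # 5% divergence family split across train/test: cross-set relatives
        # removed; 30% divergence family retained (ANI ~ 0.70 < 0.80)
        anc_a = _random_contig(15_000, rng, "ancA")
        anc_b = _random_contig(15_000, rng, "ancB")
        close = generate_family(anc_a, 0.05, 4, rng)
        far = generate_family(anc_b, 0.30, 4, rng)
        train = close[:2] + far[:2]
        test = close[2:] + far[2:]
        filtered, report = build_holdout(train, test, "strict")
        assert {r.id for r in filtered} == {r.id for r in far[:2]}
        assert report.removed_ids == {r.id for r in close[:2]}
        assert verify_holdout(filtered, test) == []

    def test_fastani_two_part_rule(self, rng, tmp_path):
        train = [_random_contig(1000, rng, "tr1"), _random_contig(1000, rng, "tr2")]
        test = [_random_contig(1000, rng, "te1")]
        p = tmp_path / "ani.tsv"
        # tr1: high ANI, high fraction -> removed; tr2: high ANI, low fraction -> kept
        p.write_text("tr1\tte1\t95.0\t90\t100\ntr2\tte1\t95.0\t10\t100\n")
        filtered, report = build_holdout(train, test, "strict",
                                         fastani_pairs=parse_fastani(p))
        assert [r.id for r in filtered] == ["tr2"]
        assert report.similarity_source == "fastani"

    def test_threshold_is_inclusive(self, rng, tmp_path):
        train = [_random_contig(1000, rng, "tr1")]
        test = [_random_contig(1000, rng, "te1")]
        p = tmp_path / "ani.tsv"
        p.write_text("tr1\tte1\t80.0\t80\t100\n")  # exactly at both thresholds
        filtered, _ = build_holdout(train, test, "strict", fastani_pairs=parse_fastani(p))
        assert filtered == []
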