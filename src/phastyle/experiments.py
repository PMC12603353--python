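"""Desk-scale end-to-end experiment: generate, train, benchmark.

This wires the whole pipeline together at a size a single CPU handles in
minutes: synthetic labeled genomes are split into train/val/test, training
segments are drawn at 10x expected coverage (then subsampled to a
class-balanced fine-tuning budget), the compact encoder is trained from
scratch, and contig-level weighted-voting calls are benchmarked on
simulated 500/2000/10000 bp fragments from the held-out test genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import benchmark
from .model import (EncoderClassifier, TrainConfig, TrainResult, tiny_config, train)
from .segmentation import Segment, sample_training_segments, simulate_fragments
from .sequence_io import ContigRecord
from .synthetic import DatasetSplits, GeneratorConfig, generate_dataset
from .tokenization import LCATokenizer
from .voting import contig_label_predictor


@dataclass
class ExperimentConfig:
    """Study conditions for the desk-scale run.

    ``n_per_class`` genomes per lifestyle at the generator defaults;
    training segments drawn at ``coverage`` (10x) and 512 bp, subsampled to
    ``max_train_segments`` for the CPU training budget.  The tokenizer is
    the 6-mer LCA variant at shift 3 (171 tokens per 512 bp segment); the
    model is the tiny preset (2 layers, 4 heads, width 64).  The learning
    rate is raised above the fine-tuning default because this model trains
    from random initialization rather than from pretrained weights.
    """

    n_per_class: int = 50
    segment_len: int = 512
    coverage: float = 10.0
    max_train_segments: int = 4000
    max_val_segments: int = 600
    dropout: float = 0.1
    tokenizer_shift: int = 3
    max_len: int = 176
    epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    fragment_lengths: tuple[int, ...] = (500, 2000, 10000)
    n_fragments_per_class: int = 30


@dataclass
class ExperimentResult:
    splits: DatasetSplits
    model: EncoderClassifier
    train_result: TrainResult
    table: pd.DataFrame  # one MetricRow per fragment length
    n_train_segments: int

    def balanced_accuracy(self, length: int) -> float:
        row = self.table[self.table.fragment_length == length]
        return float(row.balanced_accuracy.iloc[0])


def _subsample_balanced(segments: list[Segment], budget: int,
                        rng: np.random.Generator) -> list[Segment]:
    """Class-balanced random subsample without replacement."""
    if len(segments) <= budget:
        return segments
    by_class: dict[str, list[int]] = {}
    for i, s in enumerate(segments):
        by_class.setdefault(s.label, []).append(i)
    per_class = budget // len(by_class)
    keep: list[int] = []
    for idxs in by_class.values():
        chosen = rng.choice(len(idxs), size=min(per_class, len(idxs)), replace=False)
        keep.extend(idxs[c] for c in chosen)
    keep.sort()
    return [segments[i] for i in keep]


def _training_pool(records: Sequence[ContigRecord], cfg: ExperimentConfig,
                   rng: np.random.Generator) -> list[Segment]:
    pool: list[Segment] = []
    for rec in records:
        pool.extend(
            sample_training_segments(
                rec, segment_len=cfg.segment_len, coverage=cfg.coverage,
                rng=rng, both_strands=True,
            )
        )
    return pool


def run_experiment(
    seed: int,
    cfg: ExperimentConfig = ExperimentConfig(),
    gen_cfg: Optional[GeneratorConfig] = None,
    holdout_mode: str = "standard",
) -> ExperimentResult:
    """Run the full desk-scale study from one integer seed."""
    rng = np.random.default_rng(seed)
    gen_cfg = gen_cfg if gen_cfg is not None else GeneratorConfig(seed=seed)
    splits = generate_dataset(cfg.n_per_class, gen_cfg, rng)

    train_pool = _training_pool(splits.train, cfg, rng)
    train_segments = _subsample_balanced(train_pool, cfg.max_train_segments, rng)
    del train_pool
    val_pool = _training_pool(splits.val, cfg, rng)
    val_segments = _subsample_balanced(val_pool, cfg.max_val_segments, rng)
    del val_pool

    tokenizer = LCATokenizer(k=6, shift=cfg.tokenizer_shift, max_len=cfg.max_len)
    model = EncoderClassifier(
        tiny_config(vocab_size=len(tokenizer.vocab), max_len=cfg.max_len,
                    dropout=cfg.dropout),
        tokenizer, seed=seed + 1,
    )
    tcfg = TrainConfig(
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        epochs=cfg.epochs, seed=seed + 2,
    )
    result = train(model, train_segments, val_segments, tcfg)

    fragments = simulate_fragments(
        splits.test, lengths=cfg.fragment_lengths,
        n_per_class_per_length=cfg.n_fragments_per_class, rng=rng,
    )
    predictor = contig_label_predictor(model, segment_len=cfg.segment_len)
    table = benchmark(predictor, fragments, holdout_mode=holdout_mode,
                      model_name="tiny-encoder")
    return ExperimentResult(
        splits=splits, model=model, train_result=result, table=table,
        n_train_segments=len(train_segments),
    )
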