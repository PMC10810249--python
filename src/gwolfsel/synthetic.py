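"""Ground-truthed synthetic expression data.

The generator emulates processed two-class microarray data on the log2
scale: a Gaussian baseline around 7, a small planted set of informative
genes whose class means differ by ~2-3 log2 units (random sign, so both
up- and down-regulated genes occur), class imbalance near 4:1
(cancer:normal), and optional per-batch additive/multiplicative effects for
exercising the merge/adjustment stage.  It makes no attempt to model
probe-level artifacts or gene-gene correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gwolfsel.io_prep import ExpressionMatrix


@dataclass
class BatchSpec:
    n_batches: int = 2
    shift_sd: float = 1.0      # per-gene additive batch offset, log2 units
    scale_sd: float = 0.0      # per-gene multiplicative noise-scale spread


@dataclass
class SyntheticSpec:
    n_samples: int = 160
    n_genes: int = 500
    n_informative: int = 30
    effect_size: float = 2.5   # mean |log2 FC| of informative genes
    noise_sd: float = 0.5
    baseline: float = 7.0      # log2-scale grand mean
    imbalance: float = 0.8     # positive (cancer) fraction
    batch: BatchSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if not 0 < self.imbalance < 1:
            raise ValueError("imbalance must lie in (0,1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, list[str]]:
    """Generate one labeled dataset and the list of planted informative genes.

    Labels are assigned deterministically to the imbalance fraction
    (rounded), then shuffled; values are baseline + class * signed effect
    (informative genes only) + N(0, noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.imbalance * spec.n_samples))
    n_pos = min(max(n_pos, 1), spec.n_samples - 1)
    labels = np.zeros(spec.n_samples, dtype=np.int8)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    genes = _gene_ids(spec.n_genes)
    informative_idx = rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)

    values = rng.normal(spec.baseline, spec.noise_sd, (spec.n_genes, spec.n_samples))
    shift = np.zeros(spec.n_genes)
    shift[informative_idx] = signs * spec.effect_size
    values += np.outer(shift, labels.astype(float))

    sample_ids = [f"S{i:04d}" for i in range(1, spec.n_samples + 1)]
    m = ExpressionMatrix(values, genes, sample_ids, labels=labels)
    truth = sorted(genes[i] for i in informative_idx)
    return m, truth


def generate_batched_pair(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Two cohorts with identical biology but distinct batch effects.

    Both halves share the planted genes and signs; the second cohort gets a
    per-gene additive offset N(0, shift_sd) and its noise scale multiplied
    by |N(1, scale_sd)| per gene.  Sample ids are disjoint so the pair can
    be merged directly.
    """
    if spec.batch is None or spec.batch.n_batches != 2:
        raise ValueError("generate_batched_pair needs a batch block with n_batches=2")
    rng = np.random.default_rng(spec.seed)
    half = spec.n_samples // 2
    genes = _gene_ids(spec.n_genes)
    informative_idx = rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
    shift = np.zeros(spec.n_genes)
    shift[informative_idx] = signs * spec.effect_size

    offsets = rng.normal(0.0, spec.batch.shift_sd, spec.n_genes)
    scales = np.abs(rng.normal(1.0, spec.batch.scale_sd, spec.n_genes))

    mats = []
    for b, n_b in enumerate((half, spec.n_samples - half)):
        n_pos = int(round(spec.imbalance * n_b))
        n_pos = min(max(n_pos, 1), n_b - 1)
        labels = np.zeros(n_b, dtype=np.int8)
        labels[:n_pos] = 1
        rng.shuffle(labels)
        sd = spec.noise_sd * (scales[:, None] if b == 1 else 1.0)
        noise = rng.normal(0.0, 1.0, (spec.n_genes, n_b)) * sd
        values = spec.baseline + noise + np.outer(shift, labels.astype(float))
        if b == 1:
            values = values + offsets[:, None]
        sample_ids = [f"B{b + 1}S{i:04d}" for i in range(1, n_b + 1)]
        mats.append(
            ExpressionMatrix(
                values,
                genes,
                sample_ids,
                labels=labels,
                batch=np.full(n_b, f"batch{b + 1}"),
            )
        )
    truth = sorted(genes[i] for i in informative_idx)
    return mats[0], mats[1], truth
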