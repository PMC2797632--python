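"""Community-level growth-rate prediction from metagenomic gene sets.

All computations run in the gene-averaged index mode (each gene against its
own nucleotide background), which remains meaningful for mixtures of
species with different preferred codons.  Uncertainty of the community
average comes from bootstrap resampling of genes: background genes and
highly expressed genes are resampled with replacement independently within
each joint replicate, to their original cardinalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .codon_bias import (
    BiasIndexSet,
    PerGeneStats,
    aggregate_gene_stats,
    per_gene_stats,
)
from .predictor import GROWTH_CLASSES, PredictorModel, classify
from .seq_io import GeneRecord, GeneSetPartition

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAPS = 1000


@dataclass
class MetagenomeSample:
    """A named community gene set: background ORFs plus the HEG subset."""

    name: str
    genes: list[GeneRecord]
    heg: list[GeneRecord]
    ogt_assumed: float | None = None

    def __post_init__(self) -> None:
        if not self.heg:
            raise ValueError(f"sample {self.name!r}: HEG set must be nonempty")
        if not self.genes:
            raise ValueError(f"sample {self.name!r}: gene set must be nonempty")


@dataclass
class BootstrapResult:
    """Replicate community predictions and their dispersion."""

    B: int
    replicate_d: np.ndarray
    mean_d: float
    sd_d: float
    seed: int
    point_d: float

    def __post_init__(self) -> None:
        self.replicate_d = np.asarray(self.replicate_d, dtype=float)
        if len(self.replicate_d) != self.B:
            raise ValueError("replicate_d length must equal B")


def _sample_stats(
    sample: MetagenomeSample, table_id: int = 11
) -> tuple[PerGeneStats, PerGeneStats]:
    return per_gene_stats(sample.genes, table_id), per_gene_stats(sample.heg, table_id)


def _predict_from_stats(
    stats_all: PerGeneStats,
    stats_heg: PerGeneStats,
    model: PredictorModel,
    ogt: float | None,
) -> float:
    idx = aggregate_gene_stats(stats_all, stats_heg)
    f = model.compose_f(idx.delta_enc, idx.s)
    return float(model.predict_d(f=f, ogt=ogt if model.slope_ogt is not None else None))


def predict_metagenome(
    sample: MetagenomeSample, model: PredictorModel, table_id: int = 11
) -> float:
    """Point prediction of the community-average minimal generation time (h)."""
    stats_all, stats_heg = _sample_stats(sample, table_id)
    return _predict_from_stats(stats_all, stats_heg, model, sample.ogt_assumed)


def community_indices(
    sample: MetagenomeSample, table_id: int = 11
) -> BiasIndexSet:
    """Gene-averaged ΔENC′_a / S_a for a community sample."""
    stats_all, stats_heg = _sample_stats(sample, table_id)
    return aggregate_gene_stats(stats_all, stats_heg)


def bootstrap_community(
    sample: MetagenomeSample,
    model: PredictorModel,
    B: int = DEFAULT_BOOTSTRAPS,
    seed: int = 0,
    table_id: int = 11,
) -> BootstrapResult:
    """Bootstrap the community prediction.

    Each replicate resamples background genes and HEG genes with
    replacement, independently, to their original cardinalities, and
    recomputes the full prediction.  Deterministic under a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    stats_all, stats_heg = _sample_stats(sample, table_id)
    point = _predict_from_stats(stats_all, stats_heg, model, sample.ogt_assumed)
    rng = np.random.default_rng(seed)
    n_all, n_heg = len(stats_all), len(stats_heg)
    reps = np.empty(B)
    for b in range(B):
        ia = rng.integers(0, n_all, n_all)
        ih = rng.integers(0, n_heg, n_heg)
        reps[b] = _predict_from_stats(
            stats_all.take(ia), stats_heg.take(ih), model, sample.ogt_assumed
        )
    return BootstrapResult(
        B=B, replicate_d=reps, mean_d=float(reps.mean()),
        sd_d=float(reps.std(ddof=1)) if B > 1 else 0.0,
        seed=seed, point_d=point,
    )


@dataclass
class ComparisonResult:
    """Bootstrap comparison of two community averages.

    ``p_value`` is the proportion of paired replicates whose difference
    contradicts the sign of the observed mean difference; when no replicate
    contradicts it the p-value is censored at 1/B and reported as
    ``p < 1/B``.
    """

    p_value: float
    censored: bool
    n_contradictions: int
    B: int

    def __str__(self) -> str:
        return f"p<{1.0 / self.B:g}" if self.censored else f"p={self.p_value:g}"


def compare_communities(a: BootstrapResult, b: BootstrapResult) -> ComparisonResult:
    """Paired bootstrap p-value for the difference of two community means."""
    if a.B != b.B:
        raise ValueError(f"mismatched replicate counts: {a.B} != {b.B}")
    diffs = a.replicate_d - b.replicate_d
    expected_sign = np.sign(a.mean_d - b.mean_d)
    if expected_sign == 0:
        return ComparisonResult(p_value=1.0, censored=False, n_contradictions=a.B, B=a.B)
    contradictions = int(np.sum(np.sign(diffs) == -expected_sign))
    if contradictions == 0:
        return ComparisonResult(
            p_value=1.0 / a.B, censored=True, n_contradictions=0, B=a.B
        )
    return ComparisonResult(
        p_value=contradictions / a.B, censored=False,
        n_contradictions=contradictions, B=a.B,
    )


def subsample_accuracy_experiment(
    partition: GeneSetPartition,
    sizes: Sequence[int],
    iterations: int = 100,
    vary: str = "background",
    seed: int = 0,
    model: PredictorModel | None = None,
    table_id: int = 11,
) -> pd.DataFrame:
    """Dispersion of the composite F_a under subsampling of one gene set.

    For each size and iteration, a random subset (without replacement)
    replaces the varied set (``"background"`` or ``"heg"``) while the other
    set stays complete; the gene-averaged indices and F_a are recomputed.
    Returns a tidy table with columns ``size``, ``iteration``, ``f_a``.
    """
    if vary not in ("background", "heg"):
        raise ValueError("vary must be 'background' or 'heg'")
    if model is None or model.composite is None:
        raise ValueError("a model with a fitted composite is required to report F_a")
    stats_all = per_gene_stats(partition.background, table_id)
    stats_heg = per_gene_stats(partition.heg, table_id)
    pool = stats_all if vary == "background" else stats_heg
    for size in sizes:
        if size > len(pool):
            raise ValueError(f"subsample size {size} exceeds pool of {len(pool)} genes")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for it in range(iterations):
            idx = rng.choice(len(pool), size=size, replace=False)
            sub = pool.take(idx)
            sa = sub if vary == "background" else stats_all
            sh = stats_heg if vary == "background" else sub
            ix = aggregate_gene_stats(sa, sh)
            rows.append(
                {"size": size, "iteration": it,
                 "f_a": float(model.compose_f(ix.delta_enc, ix.s))}
            )
    return pd.DataFrame(rows)


def minimal_gene_classification(
    genomes: Sequence[tuple[GeneSetPartition, float]],
    model: PredictorModel,
    n_heg: int = 5,
    n_bg: int = 5,
    experiments: int = 1000,
    seed: int = 0,
    table_id: int = 11,
) -> tuple[float, float, float]:
    """Growth-class accuracy from tiny gene samples.

    Per experiment and genome, ``n_heg`` HEG and ``n_bg`` background genes
    are drawn at random (without replacement), the generation time is
    predicted and classified, and compared against the class of the known
    observed time.  Genomes with too few genes are skipped with a warning.
    Returns the percentages of exact, exact-or-adjacent, and gross
    misclassifications over all experiment × genome draws.
    """
    rng = np.random.default_rng(seed)
    prepared = []
    for partition, d_obs in genomes:
        if len(partition.heg) < n_heg or len(partition.background) < n_bg:
            logger.warning(
                "genome with %d HEG / %d background genes skipped (need %d/%d)",
                len(partition.heg), len(partition.background), n_heg, n_bg,
            )
            continue
        prepared.append(
            (
                per_gene_stats(partition.background, table_id),
                per_gene_stats(partition.heg, table_id),
                GROWTH_CLASSES.index(classify(d_obs)),
            )
        )
    if not prepared:
        raise ValueError("no genome with enough genes")
    slow = GROWTH_CLASSES.index("slow")
    fastish = {GROWTH_CLASSES.index("very_fast"), GROWTH_CLASSES.index("fast")}
    exact = approx = wrong = total = 0
    for _ in range(experiments):
        for stats_all, stats_heg, obs in prepared:
            ia = rng.choice(len(stats_all), size=n_bg, replace=False)
            ih = rng.choice(len(stats_heg), size=n_heg, replace=False)
            d_hat = _predict_from_stats(
                stats_all.take(ia), stats_heg.take(ih), model, None
            )
            pred = GROWTH_CLASSES.index(classify(d_hat))
            total += 1
            exact += pred == obs
            approx += abs(pred - obs) <= 1
            wrong += (obs == slow and pred in fastish) or (
                obs in fastish and pred == slow
            )
    return (100.0 * exact / total, 100.0 * approx / total, 100.0 * wrong / total)


def community_report(
    samples: Sequence[MetagenomeSample],
    model: PredictorModel,
    B: int = DEFAULT_BOOTSTRAPS,
    seed: int = 0,
    table_id: int = 11,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample report plus a pairwise comparison p-value matrix.

    Replicates are paired across samples by iteration index under a shared
    master seed, so per-iteration differences are meaningful.
    """
    results: list[BootstrapResult] = []
    rows = []
    for i, sample in enumerate(samples):
        idx = community_indices(sample, table_id)
        res = bootstrap_community(sample, model, B=B, seed=seed, table_id=table_id)
        results.append(res)
        rows.append(
            {
                "sample": sample.name,
                "n_genes": len(sample.genes),
                "n_heg": len(sample.heg),
                "delta_enc_a": idx.delta_enc,
                "s_a": idx.s,
                "F": float(model.compose_f(idx.delta_enc, idx.s)),
                "d_point": res.point_d,
                "d_mean": res.mean_d,
                "d_sd": res.sd_d,
                "B": B,
                "seed": seed,
            }
        )
    names = [s.name for s in samples]
    pmat = pd.DataFrame(np.ones((len(samples), len(samples))), index=names, columns=names)
    for i in range(len(samples)):
        for j in range(len(samples)):
            if i != j:
                cmp_ = compare_communities(results[i], results[j])
                pmat.iloc[i, j] = cmp_.p_value
    return pd.DataFrame(rows), pmat
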