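"""Codon-usage-bias indices: ENC′, ΔENC′, optimal-codon P frequencies and S.

The background-corrected effective number of codons ENC′ measures how far
synonymous codon usage deviates from the expectation under the sequence's
own nucleotide composition: 20 means one codon per amino acid (maximal
bias), 61 means usage indistinguishable from the mutational background.

ΔENC′ is the relative reduction of ENC′ in highly expressed genes (HEG,
here ribosomal proteins) versus the control gene set — an empirical
estimator of translational selection.  S is a weighted log-odds of the
translationally optimal codon (the Watson-Crick-matched codon of the
two-codon amino acids Phe, Ile, Tyr, Asn) in HEG versus all genes.

Two computation modes exist.  ``concatenated`` pools each gene set into one
count table (appropriate for single genomes).  ``gene-averaged`` computes
ENC′ and P per gene — each gene against its *own* nucleotide background —
and aggregates the means; this is the mode that stays meaningful on
metagenomic mixtures of species with different preferred codons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetic_code import (
    BASES,
    DEFAULT_TABLE,
    degeneracy_class_sizes,
    n_single_codon_amino_acids,
    sense_codons,
    stop_codons,
    synonymous_families,
)
from .seq_io import GeneRecord, GeneSetPartition, NoHegError

logger = logging.getLogger(__name__)

ENC_FLOOR = 20.0
ENC_CAP = 61.0

#: Optimal/suboptimal codon pairs (C1, C2) for the S index, DNA alphabet.
#: C1 is the codon Watson-Crick matched to the (single) tRNA anticodon.
S_PAIRS: dict[str, tuple[str, str]] = {
    "Phe": ("TTC", "TTT"),
    "Ile": ("ATC", "ATT"),
    "Tyr": ("TAC", "TAT"),
    "Asn": ("AAC", "AAT"),
}
S_AMINO_ACIDS = tuple(S_PAIRS)


class UndefinedIndexError(ValueError):
    """Raised when a codon-bias index cannot be computed from the data."""


@dataclass
class CodonCounts:
    """Sense-codon counts plus the background nucleotide composition.

    ``background`` is the (A, C, G, T) frequency vector of the coding
    sequence the counts came from; it drives the expected codon frequencies
    in ENC′.
    """

    counts: dict[str, int]
    background: np.ndarray
    n_codons: int

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,):
            raise ValueError("background must be a length-4 (A,C,G,T) vector")
        if np.any(self.background < 0) or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must be >= 0 and sum to 1")
        if sum(self.counts.values()) != self.n_codons:
            raise ValueError("counts must sum to n_codons")

    def count(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def _count_one(seq: str, stops: frozenset[str]) -> tuple[dict[str, int], np.ndarray, int]:
    counts: dict[str, int] = {}
    n = 0
    nt = dict.fromkeys(BASES, 0)
    for base in seq:
        if base in nt:
            nt[base] += 1
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon or codon in stops:
            continue
        counts[codon] = counts.get(codon, 0) + 1
        n += 1
    total_nt = sum(nt.values())
    bg = (
        np.array([nt[b] / total_nt for b in BASES])
        if total_nt
        else np.full(4, 0.25)
    )
    return counts, bg, n


def count_codons(
    genes: Sequence[GeneRecord],
    concatenate: bool = True,
    table_id: int = DEFAULT_TABLE,
) -> CodonCounts | list[CodonCounts]:
    """Count sense codons for a gene set.

    Stop codons and codons containing ``N`` are skipped.  With
    ``concatenate=True`` a single pooled count is returned whose background
    is the average coding nucleotide frequency of the pooled sequence; with
    ``concatenate=False`` one :class:`CodonCounts` per gene is returned,
    each with the gene's own background.  Genes with zero countable codons
    are excluded with a warning.
    """
    if not genes:
        raise ValueError("empty gene list")
    stops = frozenset(stop_codons(table_id))
    per_gene: list[CodonCounts] = []
    for g in genes:
        if len(g.seq) % 3:
            raise ValueError(f"gene {g.id!r}: length {len(g.seq)} is not a multiple of 3")
        counts, bg, n = _count_one(g.seq, stops)
        if n == 0:
            logger.warning("gene %r has no countable codons; excluded", g.id)
            continue
        per_gene.append(CodonCounts(counts=counts, background=bg, n_codons=n))
    if not per_gene:
        raise ValueError("no gene with countable codons")
    if not concatenate:
        return per_gene
    pooled_seq = "".join(g.seq for g in genes)
    counts, bg, n = _count_one(pooled_seq, stops)
    return CodonCounts(counts=counts, background=bg, n_codons=n)


def _family_homozygosity(
    obs: Sequence[int], expected: Sequence[float]
) -> float | None:
    """Novembre's composition-corrected homozygosity F̂′ for one family.

    ``None`` when the family carries fewer than two codons (inestimable).
    """
    n = int(sum(obs))
    k = len(obs)
    if n < 2:
        return None
    chi2 = 0.0
    for o, e in zip(obs, expected):
        p = o / n
        if e > 0:
            chi2 += (p - e) ** 2 / e
        elif o:
            return 1e12  # observed codon with zero expectation: infinite deviation
    chi2 *= n
    f = (chi2 + n - k) / (k * (n - 1))
    return max(f, 1e-12)


def enc_prime(
    counts: CodonCounts,
    table_id: int = DEFAULT_TABLE,
    sixfold: str = "own_class",
) -> float:
    """Background-corrected effective number of codons (ENC′).

    Per synonymous family, expected codon frequencies are derived from the
    background nucleotide composition (position-independent product,
    renormalised within the family); a chi-square deviation of observed from
    expected codon frequencies gives the corrected homozygosity.  Family
    values are averaged within degeneracy classes and combined by Wright's
    formula (for table 11 with whole sixfold families:
    ``ENC′ = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6``).  The result is capped to
    ``[20, 61]``.

    An entirely unobserved degeneracy class is imputed Wright-style — the
    threefold class from ``(F̄2 + F̄4)/2``, any other single missing class
    from the mean of the observed class means; with two or more classes
    missing the index is undefined and :class:`UndefinedIndexError` is
    raised.
    """
    if counts.n_codons <= 0:
        raise UndefinedIndexError("no counted codons")
    bg = dict(zip(BASES, counts.background))
    class_values: dict[int, list[float]] = {}
    for _, codons in synonymous_families(table_id, sixfold):
        k = len(codons)
        obs = [counts.count(c) for c in codons]
        weights = [bg[c[0]] * bg[c[1]] * bg[c[2]] for c in codons]
        total_w = sum(weights)
        if total_w <= 0:
            continue
        f = _family_homozygosity(obs, [w / total_w for w in weights])
        if f is not None:
            class_values.setdefault(k, []).append(f)

    sizes = degeneracy_class_sizes(table_id, sixfold)
    means = {k: float(np.mean(v)) for k, v in class_values.items()}
    missing = [k for k in sizes if k not in means]
    if len(means) == 0 or len(missing) >= 2:
        raise UndefinedIndexError(
            f"ENC' undefined: degeneracy classes {missing} unobserved"
        )
    for k in missing:
        if k == 3 and 2 in means and 4 in means:
            means[k] = (means[2] + means[4]) / 2.0
        else:
            means[k] = float(np.mean(list(means.values())))

    enc = n_single_codon_amino_acids(table_id) + sum(
        sizes[k] / means[k] for k in sizes
    )
    return float(min(max(enc, ENC_FLOOR), ENC_CAP))


def delta_enc_prime(enc_all: float, enc_heg: float) -> float:
    """Relative ENC′ reduction in HEG: ``(ENC′_all − ENC′_heg) / ENC′_all``."""
    for name, v in (("enc_all", enc_all), ("enc_heg", enc_heg)):
        if not (ENC_FLOOR <= v <= ENC_CAP):
            raise ValueError(f"{name}={v} outside [{ENC_FLOOR}, {ENC_CAP}]")
    return (enc_all - enc_heg) / enc_all


def p_optimal(counts: CodonCounts) -> dict[str, float | None]:
    """Optimal-codon frequency ``P = C1/(C1+C2)`` for Phe, Ile, Tyr, Asn.

    Amino acids with zero ``C1+C2`` counts are flagged absent (``None``).
    """
    out: dict[str, float | None] = {}
    for aa, (c1, c2) in S_PAIRS.items():
        n1, n2 = counts.count(c1), counts.count(c2)
        out[aa] = n1 / (n1 + n2) if n1 + n2 else None
    return out


def s_index(
    p_heg: Mapping[str, float | None],
    p_all: Mapping[str, float | None],
    weights: Mapping[str, float],
) -> tuple[dict[str, float], float]:
    """Selection-strength index S from optimal-codon frequencies.

    Per amino acid, ``S_i = ln[(P_heg/(1−P_heg)) / (P_all/(1−P_all))]`` —
    the log odds ratio of optimal-codon use in HEG versus all genes.  S is
    the mean of the ``S_i`` weighted by ``weights`` (conventionally the
    ``C1+C2`` codon counts observed in the HEG set).  Amino acids that are
    absent, have degenerate frequencies (0 or 1), or zero weight are dropped
    with a warning; with none left the index is undefined.
    """
    components: dict[str, float] = {}
    used_weights: dict[str, float] = {}
    for aa in S_AMINO_ACIDS:
        ph, pa = p_heg.get(aa), p_all.get(aa)
        w = float(weights.get(aa, 0.0))
        if ph is None or pa is None or w <= 0:
            logger.warning("S: amino acid %s absent or unweighted; dropped", aa)
            continue
        if not (0.0 < ph < 1.0) or not (0.0 < pa < 1.0):
            logger.warning(
                "S: degenerate optimal-codon frequency for %s "
                "(P_heg=%s, P_all=%s); dropped — consider pseudocounts", aa, ph, pa
            )
            continue
        components[aa] = float(
            np.log((ph / (1 - ph)) / (pa / (1 - pa)))
        )
        used_weights[aa] = w
    if not components:
        raise UndefinedIndexError("S undefined: no usable amino acid")
    total_w = sum(used_weights.values())
    s = sum(components[aa] * used_weights[aa] for aa in components) / total_w
    return components, float(s)


@dataclass
class BiasIndexSet:
    """ENC′ / ΔENC′ / P / S values for one HEG-vs-background comparison."""

    mode: str  # "concatenated" or "gene-averaged"
    n_all: int
    n_heg: int
    enc_all: float
    enc_heg: float
    delta_enc: float
    p_all: dict[str, float | None]
    p_heg: dict[str, float | None]
    s_components: dict[str, float]
    s: float

    def to_row(self) -> dict[str, object]:
        """Flatten into one report row (tab-separated output layout)."""
        row: dict[str, object] = {
            "n_genes_all": self.n_all,
            "n_genes_heg": self.n_heg,
            "enc_all": self.enc_all,
            "enc_heg": self.enc_heg,
            "delta_enc": self.delta_enc,
        }
        for aa in S_AMINO_ACIDS:
            row[f"P_{aa}_all"] = self.p_all.get(aa)
            row[f"P_{aa}_heg"] = self.p_heg.get(aa)
        for aa in S_AMINO_ACIDS:
            row[f"S_{aa}"] = self.s_components.get(aa)
        row["S"] = self.s
        row["mode"] = self.mode
        return row


# ---------------------------------------------------------------------------
# per-gene statistics (the gene-averaged / metagenomic mode)


@dataclass
class PerGeneStats:
    """Cached per-gene index ingredients, for fast resampling.

    ``enc`` holds NaN for genes whose per-gene ENC′ is undefined; ``c1`` /
    ``c2`` are ``(n_genes, 4)`` count arrays over the S amino acids in
    :data:`S_AMINO_ACIDS` order.
    """

    ids: list[str]
    enc: np.ndarray
    c1: np.ndarray
    c2: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def take(self, idx: np.ndarray) -> "PerGeneStats":
        return PerGeneStats(
            ids=[self.ids[i] for i in idx],
            enc=self.enc[idx],
            c1=self.c1[idx],
            c2=self.c2[idx],
        )


def per_gene_stats(
    genes: Sequence[GeneRecord], table_id: int = DEFAULT_TABLE,
    sixfold: str = "own_class",
) -> PerGeneStats:
    """Compute per-gene ENC′ (own background) and C1/C2 counts."""
    if not genes:
        raise ValueError("empty gene list")
    counts_list = count_codons(genes, concatenate=False, table_id=table_id)
    n = len(counts_list)
    enc = np.full(n, np.nan)
    c1 = np.zeros((n, 4), dtype=np.int64)
    c2 = np.zeros((n, 4), dtype=np.int64)
    ids: list[str] = []
    for i, cc in enumerate(counts_list):
        try:
            enc[i] = enc_prime(cc, table_id=table_id, sixfold=sixfold)
        except UndefinedIndexError:
            pass  # dropped from the mean
        for j, aa in enumerate(S_AMINO_ACIDS):
            a, b = S_PAIRS[aa]
            c1[i, j] = cc.count(a)
            c2[i, j] = cc.count(b)
    ids = [g.id for g in genes][:n]
    return PerGeneStats(ids=ids, enc=enc, c1=c1, c2=c2)


def _mean_p(stats: PerGeneStats, pseudocount: float) -> np.ndarray:
    """Mean per-gene optimal-codon frequency, NaN where no gene is usable.

    The pseudocount is added to both C1 and C2 of a gene only when either
    count is zero, keeping per-gene log odds finite without touching
    well-populated genes.
    """
    c1 = stats.c1.astype(float)
    c2 = stats.c2.astype(float)
    tot = c1 + c2
    usable = tot > 0
    needs = usable & ((c1 == 0) | (c2 == 0))
    p = np.where(
        needs, (c1 + pseudocount) / (tot + 2 * pseudocount),
        np.divide(c1, tot, out=np.zeros_like(c1), where=usable),
    )
    p = np.where(usable, p, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(p, axis=0)


def aggregate_gene_stats(
    stats_all: PerGeneStats,
    stats_heg: PerGeneStats,
    pseudocount: float = 0.5,
) -> BiasIndexSet:
    """Gene-averaged ΔENC′_a and S_a from cached per-gene statistics.

    The mean per-gene ENC′ of each set feeds the ΔENC′ formula; the mean
    per-gene P values feed the S log-odds formula, weighted by the total
    ``C1+C2`` counts of the HEG set.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        enc_all = float(np.nanmean(stats_all.enc))
        enc_heg = float(np.nanmean(stats_heg.enc))
    if np.isnan(enc_all) or np.isnan(enc_heg):
        raise UndefinedIndexError("no gene with a computable ENC' in one of the sets")
    delta = (enc_all - enc_heg) / enc_all

    p_all_arr = _mean_p(stats_all, pseudocount)
    p_heg_arr = _mean_p(stats_heg, pseudocount)
    p_all = {
        aa: (None if np.isnan(p_all_arr[j]) else float(p_all_arr[j]))
        for j, aa in enumerate(S_AMINO_ACIDS)
    }
    p_heg = {
        aa: (None if np.isnan(p_heg_arr[j]) else float(p_heg_arr[j]))
        for j, aa in enumerate(S_AMINO_ACIDS)
    }
    weights = {
        aa: float((stats_heg.c1[:, j] + stats_heg.c2[:, j]).sum())
        for j, aa in enumerate(S_AMINO_ACIDS)
    }
    s_comp, s = s_index(p_heg, p_all, weights)
    return BiasIndexSet(
        mode="gene-averaged",
        n_all=len(stats_all),
        n_heg=len(stats_heg),
        enc_all=enc_all,
        enc_heg=enc_heg,
        delta_enc=delta,
        p_all=p_all,
        p_heg=p_heg,
        s_components=s_comp,
        s=s,
    )


def gene_level_indices(
    partition: GeneSetPartition,
    table_id: int = DEFAULT_TABLE,
    pseudocount: float = 0.5,
    sixfold: str = "own_class",
) -> BiasIndexSet:
    """Gene-averaged indices (ΔENC′_a, S_a) for a partition.

    The control ("all genes") side is the partition's background set; the
    HEG side its HEG set.
    """
    if not partition.heg:
        raise NoHegError("partition has no HEG genes")
    if not partition.background:
        raise ValueError("partition has no background genes")
    stats_all = per_gene_stats(partition.background, table_id, sixfold)
    stats_heg = per_gene_stats(partition.heg, table_id, sixfold)
    return aggregate_gene_stats(stats_all, stats_heg, pseudocount)


def concatenated_indices(
    partition: GeneSetPartition,
    table_id: int = DEFAULT_TABLE,
    sixfold: str = "own_class",
) -> BiasIndexSet:
    """Concatenated-mode indices (whole-genome convention, no pseudocounts)."""
    if not partition.heg:
        raise NoHegError("partition has no HEG genes")
    if not partition.background:
        raise ValueError("partition has no background genes")
    cc_all = count_codons(partition.background, concatenate=True, table_id=table_id)
    cc_heg = count_codons(partition.heg, concatenate=True, table_id=table_id)
    enc_all = enc_prime(cc_all, table_id, sixfold)
    enc_heg = enc_prime(cc_heg, table_id, sixfold)
    p_all = p_optimal(cc_all)
    p_heg = p_optimal(cc_heg)
    weights = {
        aa: cc_heg.count(c1) + cc_heg.count(c2) for aa, (c1, c2) in S_PAIRS.items()
    }
    s_comp, s = s_index(p_heg, p_all, weights)
    return BiasIndexSet(
        mode="concatenated",
        n_all=len(partition.background),
        n_heg=len(partition.heg),
        enc_all=enc_all,
        enc_heg=enc_heg,
        delta_enc=delta_enc_prime(enc_all, enc_heg),
        p_all=p_all,
        p_heg=p_heg,
        s_components=s_comp,
        s=s,
    )


def bias_indices(
    partition: GeneSetPartition,
    mode: str = "concatenated",
    table_id: int = DEFAULT_TABLE,
    **kwargs,
) -> BiasIndexSet:
    """Dispatch to :func:`concatenated_indices` or :func:`gene_level_indices`."""
    if mode == "concatenated":
        return concatenated_indices(partition, table_id, **kwargs)
    if mode == "gene-averaged":
        return gene_level_indices(partition, table_id, **kwargs)
    raise ValueError(f"unknown mode: {mode!r}")
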