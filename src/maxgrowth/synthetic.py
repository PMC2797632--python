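"""Synthetic genomes and training tables with controlled codon-usage selection.

The generator emulates the mutation-selection structure behind
translation-associated codon bias: background genes draw synonymous codons
from a G+C-driven mutational background, while a designated highly
expressed subset reweights translationally optimal codons by
``exp(s_strength)``.  Selection acts only on synonymous choice — amino-acid
content is drawn from the same background marginal in both sets — so any
ENC′/S contrast between the sets is a pure codon-bias signal.

Training tables link known "true" generation times to the composite F
through a chosen regression, enabling exact and noisy parameter-recovery
tests of the predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_bias import S_PAIRS
from .genetic_code import BASES, DEFAULT_TABLE, sense_codons, table as _table
from .predictor import fit_composite, inverse_box_cox
from .seq_io import GeneRecord, GeneSetPartition, write_fasta


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome.

    Defaults sketch a small but realistic prokaryotic genome: 500 coding
    genes of ~900 nt mean length, 50 of them highly expressed (the typical
    ribosomal-protein complement), balanced G+C, and moderate selection
    (``s_strength = 1``, roughly one unit of log-odds preference for
    optimal codons in HEG).
    """

    n_genes: int = 500
    n_heg: int = 50
    gene_len: int = 900
    gc: float = 0.5
    s_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if self.n_heg > self.n_genes:
            raise ValueError("n_heg cannot exceed n_genes")
        if self.n_heg < 1 or self.n_genes < 2:
            raise ValueError("need at least 1 HEG and 2 genes")
        if self.s_strength < 0:
            raise ValueError("s_strength must be >= 0")


MIN_GENE_LEN = 450  # nt, start and stop codons included


def _background_codon_probs(gc: float, table_id: int) -> tuple[list[str], np.ndarray]:
    codons = list(sense_codons(table_id))
    nt_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    w = np.array([nt_p[c[0]] * nt_p[c[1]] * nt_p[c[2]] for c in codons])
    return codons, w / w.sum()


def optimal_codons(gc: float, table_id: int = DEFAULT_TABLE) -> frozenset[str]:
    """The optimal-codon set used for synthesis.

    The C1 codons of the four S amino acids, plus the most background-
    consistent codon of every other synonymous family (ties broken
    lexicographically) — this way selection leaves a footprint in both the
    S pairs and the ENC′ families.
    """
    codons, probs = _background_codon_probs(gc, table_id)
    prob = dict(zip(codons, probs))
    fwd = _table(table_id).forward_table
    by_aa: dict[str, list[str]] = {}
    for c in codons:
        by_aa.setdefault(fwd[c], []).append(c)
    c1_by_aa = {}
    for aa3, (c1, _) in S_PAIRS.items():
        c1_by_aa[fwd[c1]] = c1
    out = set(c1_by_aa.values())
    for aa, fam in by_aa.items():
        if len(fam) < 2 or aa in c1_by_aa:
            continue
        out.add(max(sorted(fam), key=lambda c: prob[c]))
    return frozenset(out)


def _heg_codon_probs(
    codons: list[str], bg: np.ndarray, optimal: frozenset[str],
    s_strength: float, table_id: int,
) -> np.ndarray:
    """Selection-reweighted codon distribution preserving the amino-acid marginal."""
    fwd = _table(table_id).forward_table
    aa_of = np.array([fwd[c] for c in codons])
    boost = np.array([np.exp(s_strength) if c in optimal else 1.0 for c in codons])
    w = bg * boost
    out = np.empty_like(w)
    for aa in set(aa_of):
        mask = aa_of == aa
        aa_mass = bg[mask].sum()
        out[mask] = aa_mass * w[mask] / w[mask].sum()
    return out / out.sum()


def generate_genome(spec: SyntheticSpec, table_id: int = DEFAULT_TABLE) -> GeneSetPartition:
    """Generate a synthetic genome partitioned into HEG and background genes.

    Gene lengths are drawn around ``spec.gene_len`` (sd 20%), rounded to
    codons and floored at 450 nt; every gene is ``ATG`` + sense-codon body +
    ``TAA``.  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    codons, bg = _background_codon_probs(spec.gc, table_id)
    opt = optimal_codons(spec.gc, table_id)
    heg_p = _heg_codon_probs(codons, bg, opt, spec.s_strength, table_id)
    codon_arr = np.array(codons)

    def make_gene(gid: str, probs: np.ndarray, is_heg: bool) -> GeneRecord:
        total_len = int(round(rng.normal(spec.gene_len, 0.2 * spec.gene_len)))
        n_body = max((MIN_GENE_LEN - 6) // 3, total_len // 3 - 2)
        body = "".join(codon_arr[rng.choice(len(codon_arr), n_body, p=probs)])
        return GeneRecord(
            id=gid, seq="ATG" + body + "TAA",
            source=f"synthetic-{spec.seed}", is_heg=is_heg,
        )

    heg = [make_gene(f"heg{i:04d}", heg_p, True) for i in range(spec.n_heg)]
    background = [
        make_gene(f"bg{i:04d}", bg, False)
        for i in range(spec.n_genes - spec.n_heg)
    ]
    return GeneSetPartition(heg=heg, background=background, selection_method="synthetic")


def generate_training_table(
    n_species: int,
    model_truth: tuple[float, float, float] = (0.8741, -0.6496, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    index_location: tuple[float, float] = (0.12, 0.6),
    index_scale: tuple[float, float] = (0.08, 0.5),
    pc_share: float = 0.9,
) -> pd.DataFrame:
    """Synthetic species table of (ΔENC′, S, d, OGT) with known regression truth.

    A latent composite is embedded in the two index columns so that
    refitting the composite on the emitted table reproduces it exactly;
    generation times then follow ``d = Φ⁻¹_λ(intercept + slope·F + ε)`` with
    Gaussian Φ-scale noise ``ε``.  With ``noise_sd = 0`` a refit (at the
    true λ) recovers the coefficients to machine precision.

    ``pc_share`` sets how much of each standardised index column is carried
    by the shared component versus index-specific variation.  The OGT
    column is drawn in the mesophilic band and carries no signal.
    """
    if n_species < 10:
        raise ValueError("n_species must be >= 10")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (0.5 < pc_share < 1.0):
        raise ValueError("pc_share must be in (0.5, 1)")
    intercept, slope, lam = model_truth
    rng = np.random.default_rng(seed)

    def _standardise(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std(ddof=1)

    latent = _standardise(rng.normal(size=n_species))
    ortho = rng.normal(size=n_species)
    ortho -= (ortho @ latent) / (latent @ latent) * latent
    ortho = _standardise(ortho)
    a, b = pc_share, np.sqrt(1.0 - pc_share**2)
    z1 = a * latent + b * ortho
    z2 = a * latent - b * ortho
    delta_enc = index_location[0] + index_scale[0] * z1
    s = index_location[1] + index_scale[1] * z2

    df = pd.DataFrame({"delta_enc": delta_enc, "s": s})
    f = fit_composite(df).transform(delta_enc, s)
    phi = intercept + slope * f + rng.normal(0.0, noise_sd, size=n_species)
    df["d"] = inverse_box_cox(phi, lam)
    df["ogt"] = np.clip(rng.normal(37.0, 5.0, size=n_species), 16.0, 45.0)
    return df


def write_dataset(
    partition: GeneSetPartition, outdir: str | Path, truth: dict | None = None
) -> None:
    """Write a synthetic dataset as FASTA pair (all genes, HEG) + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(partition.all_genes, outdir / "all_genes.fna")
    write_fasta(partition.heg, outdir / "heg.fna")
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
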