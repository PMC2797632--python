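"""Genetic-code bookkeeping shared by the codon-usage modules.

Thin layer over Biopython's codon tables.  The default is NCBI translation
table 11 (bacteria, archaea and plant plastids), which fits the prokaryotic
scope of the package; every public function takes ``table_id`` so other codes
can be used.

A *synonymous family* is the set of sense codons encoding one amino acid.
Two conventions for the sixfold-degenerate amino acids (Leu, Ser, Arg) are
supported:

``"own_class"`` (default)
    each sixfold family is kept whole and contributes to a degeneracy-6
    class, as in Wright's effective-number-of-codons formula.
``"split"``
    each sixfold family is split into a twofold and a fourfold sub-family
    sharing their first two nucleotides.
"""

from __future__ import annotations

from collections import defaultdict
from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

BASES = "ACGT"
DEFAULT_TABLE = 11
#: start codons used when trimming ORFs; table 11 formally allows more
#: (ATT, ATC, ATA, CTG) but these three cover virtually all annotated genes.
DEFAULT_STARTS = ("ATG", "GTG", "TTG")


@lru_cache(maxsize=None)
def table(table_id: int = DEFAULT_TABLE) -> CodonTable.CodonTable:
    """Return the unambiguous-DNA codon table for ``table_id``."""
    return CodonTable.unambiguous_dna_by_id[table_id]


@lru_cache(maxsize=None)
def sense_codons(table_id: int = DEFAULT_TABLE) -> tuple[str, ...]:
    """All sense codons of the code, sorted (61 for table 11)."""
    return tuple(sorted(table(table_id).forward_table))


@lru_cache(maxsize=None)
def stop_codons(table_id: int = DEFAULT_TABLE) -> tuple[str, ...]:
    return tuple(table(table_id).stop_codons)


@lru_cache(maxsize=None)
def synonymous_families(
    table_id: int = DEFAULT_TABLE, sixfold: str = "own_class"
) -> tuple[tuple[str, tuple[str, ...]], ...]:
    """Synonymous families with degeneracy >= 2 as ``(name, codons)`` pairs.

    Single-codon amino acids (Met, Trp in table 11) are excluded; they carry
    no synonymous choice and enter codon-bias statistics only as constants.
    """
    if sixfold not in ("own_class", "split"):
        raise ValueError(f"unknown sixfold convention: {sixfold!r}")
    by_aa: dict[str, list[str]] = defaultdict(list)
    for codon, aa in table(table_id).forward_table.items():
        by_aa[aa].append(codon)
    fams: list[tuple[str, tuple[str, ...]]] = []
    for aa in sorted(by_aa):
        codons = tuple(sorted(by_aa[aa]))
        if len(codons) < 2:
            continue
        if sixfold == "split" and len(codons) >= 6:
            sub: dict[str, list[str]] = defaultdict(list)
            for c in codons:
                sub[c[:2]].append(c)
            for prefix in sorted(sub):
                fams.append((f"{aa}-{prefix}", tuple(sorted(sub[prefix]))))
        else:
            fams.append((aa, codons))
    return tuple(fams)


@lru_cache(maxsize=None)
def n_single_codon_amino_acids(table_id: int = DEFAULT_TABLE) -> int:
    """Number of amino acids encoded by exactly one codon (2 in table 11)."""
    by_aa: dict[str, int] = defaultdict(int)
    for aa in table(table_id).forward_table.values():
        by_aa[aa] += 1
    return sum(1 for n in by_aa.values() if n == 1)


@lru_cache(maxsize=None)
def degeneracy_class_sizes(
    table_id: int = DEFAULT_TABLE, sixfold: str = "own_class"
) -> dict[int, int]:
    """Number of synonymous families per degeneracy class.

    Table 11, ``own_class``: ``{2: 9, 3: 1, 4: 5, 6: 3}``.
    """
    sizes: dict[int, int] = defaultdict(int)
    for _, codons in synonymous_families(table_id, sixfold):
        sizes[len(codons)] += 1
    return dict(sizes)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str, table_id: int = DEFAULT_TABLE) -> str:
    """Translate an in-frame nucleotide sequence (stops rendered as ``*``)."""
    return str(Seq(seq).translate(table=table_id))
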