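"""Sequence input and gene-set assembly.

Reads nucleotide FASTA files, extracts candidate protein-coding ORFs from
contigs (getorf-style stop-to-stop regions trimmed to their first start
codon), and partitions gene sets into highly expressed genes (HEG; here,
ribosomal-protein-like genes) and a background/control set.  The HEG /
background split is what every downstream codon-bias index is built on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .genetic_code import (
    DEFAULT_STARTS,
    DEFAULT_TABLE,
    reverse_complement,
    stop_codons,
    translate,
)

logger = logging.getLogger(__name__)

_VALID_NT = frozenset("ACGTN")

#: Minimum ORF length in nucleotides (start and stop codons included).
DEFAULT_MIN_ORF_LEN = 450

#: Packaged protein reference for similarity-based HEG detection.  This file
#: is a synthetic stand-in (see its header); replace with a real
#: ribosomal-protein database for production use.
SYNTHETIC_RIBOSOMAL_REFERENCE = "ribosomal_proteins.synthetic.faa"


class NoHegError(ValueError):
    """Raised when HEG selection yields zero highly expressed genes."""


@dataclass
class GeneRecord:
    """One in-frame coding sequence.

    Attributes
    ----------
    id : str
        Text identifier, unique within a gene set.
    seq : str
        Nucleotide sequence over ``A, C, G, T, N``; upper-cased on
        construction.  ORF-finder output is a multiple of 3, begins with a
        start codon and ends with a stop codon.
    source : str
        Identifier of the genome or contig of origin.
    is_heg : bool
        Whether the gene belongs to the highly-expressed set.
    frame_start : int
        0-based offset of the gene on the forward strand of its source.
    strand : str
        ``"+"`` or ``"-"``.
    """

    id: str
    seq: str
    source: str = ""
    is_heg: bool = False
    frame_start: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - _VALID_NT
        if bad:
            raise ValueError(
                f"gene {self.id!r}: non-ACGTN symbol(s) {sorted(bad)} in sequence"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.seq)

    def codons(self) -> list[str]:
        """Complete codons of the sequence (a trailing partial codon is ignored)."""
        return [self.seq[i : i + 3] for i in range(0, len(self.seq) - 2, 3)]


@dataclass
class GeneSetPartition:
    """Disjoint split of a gene collection into HEG and background sets."""

    heg: list[GeneRecord]
    background: list[GeneRecord]
    selection_method: str = "id-list"

    def __post_init__(self) -> None:
        heg_ids = {g.id for g in self.heg}
        bg_ids = {g.id for g in self.background}
        common = heg_ids & bg_ids
        if common:
            raise ValueError(f"HEG and background overlap by id: {sorted(common)[:5]}")

    @property
    def all_genes(self) -> list[GeneRecord]:
        return list(self.background) + list(self.heg)


def read_fasta(path: str | Path) -> list[GeneRecord]:
    """Read a nucleotide FASTA file into :class:`GeneRecord` objects.

    Order is preserved, sequences are upper-cased, duplicate identifiers are
    kept (with a logged warning).  An empty or record-less file raises
    ``ValueError``.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            logger.warning("duplicate FASTA id %r in %s", rec.id, path)
        seen.add(rec.id)
        records.append(GeneRecord(id=rec.id, seq=str(rec.seq), source=path.stem))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _read_proteins(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA as ``(id, sequence)`` pairs."""
    pairs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise ValueError(f"no FASTA records found in {path}")
    return pairs


def extract_orfs(
    contig: str,
    min_len: int = DEFAULT_MIN_ORF_LEN,
    table_id: int = DEFAULT_TABLE,
    starts: Sequence[str] = DEFAULT_STARTS,
    trim_to_start: bool = True,
    source: str = "contig",
) -> list[GeneRecord]:
    """Extract candidate ORFs from a contig on both strands.

    Scans all six reading frames for maximal regions bounded on the right by
    a stop codon (regions opening at the contig edge are kept; regions with
    no closing stop are not).  With ``trim_to_start`` (default) each region
    is trimmed to its first start codon and regions without one are
    discarded, so every emitted gene begins with a start codon and ends with
    a stop codon; with ``trim_to_start=False`` the raw stop-to-stop region is
    emitted.  Coordinates are recorded 0-based on the forward strand
    (``frame_start`` is the lowest forward-strand position of the ORF).

    A contig shorter than ``min_len`` simply yields an empty list.
    """
    if min_len < 3 or min_len % 3:
        raise ValueError("min_len must be a multiple of 3 and >= 3")
    contig = contig.upper()
    bad = set(contig) - _VALID_NT
    if bad:
        raise ValueError(f"non-ACGTN symbol(s) {sorted(bad)} in contig")
    stops = set(stop_codons(table_id))
    starts = tuple(s.upper() for s in starts)
    length = len(contig)
    out: list[GeneRecord] = []
    counter = 0

    for strand, seq in (("+", contig), ("-", reverse_complement(contig))):
        for frame in range(3):
            region_start = frame
            for i in range(frame, len(seq) - 2, 3):
                if seq[i : i + 3] in stops:
                    region_end = i + 3  # stop codon included
                    orf_start = region_start
                    if trim_to_start:
                        orf_start = next(
                            (
                                j
                                for j in range(region_start, region_end - 3, 3)
                                if seq[j : j + 3] in starts
                            ),
                            -1,
                        )
                    if orf_start >= 0 and region_end - orf_start >= min_len:
                        fwd_start = (
                            orf_start if strand == "+" else length - region_end
                        )
                        counter += 1
                        out.append(
                            GeneRecord(
                                id=f"{source}|orf{counter:04d}",
                                seq=seq[orf_start:region_end],
                                source=source,
                                frame_start=fwd_start,
                                strand=strand,
                            )
                        )
                    region_start = i + 3
    return out


def extract_orfs_from_contigs(
    contigs: Iterable[GeneRecord],
    min_len: int = DEFAULT_MIN_ORF_LEN,
    table_id: int = DEFAULT_TABLE,
    **kwargs,
) -> list[GeneRecord]:
    """Run :func:`extract_orfs` over a collection of contig records."""
    genes: list[GeneRecord] = []
    for contig in contigs:
        genes.extend(
            extract_orfs(
                contig.seq, min_len=min_len, table_id=table_id,
                source=contig.id, **kwargs,
            )
        )
    return genes


# Gapped BLOSUM62 Karlin-Altschul parameters, used to convert a local
# alignment score into a BLAST-style expectation value.
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def packaged_ribosomal_reference() -> Path:
    """Path of the packaged (synthetic stand-in) ribosomal-protein FASTA."""
    return Path(
        str(resources.files("maxgrowth").joinpath("data", SYNTHETIC_RIBOSOMAL_REFERENCE))
    )


def select_heg(
    genes: Sequence[GeneRecord],
    method: str,
    reference: str | Path | None = None,
    ids: Iterable[str] | None = None,
    annotation: pd.DataFrame | None = None,
    keyword: str = "ribosomal protein",
    evalue_threshold: float = 1e-5,
    table_id: int = DEFAULT_TABLE,
) -> GeneSetPartition:
    """Partition ``genes`` into highly-expressed and background sets.

    Parameters
    ----------
    method : {"id-list", "annotation-keyword", "similarity"}
        ``id-list``
            flag genes whose id appears in ``ids``; all listed ids must
            exist among ``genes``.
        ``annotation-keyword``
            flag genes whose ``product`` column in ``annotation`` (a table
            with at least columns ``id`` and ``product``) contains
            ``keyword`` (case-insensitive).
        ``similarity``
            translate each gene and align it (local, BLOSUM62) against the
            protein ``reference`` FASTA; the gene is flagged when its best
            hit has Karlin-Altschul expectation below ``evalue_threshold``.
            Without an explicit reference the packaged stand-in is used.

    Raises
    ------
    NoHegError
        If no gene is selected (downstream indices are then undefined).
    """
    genes = list(genes)
    if method == "id-list":
        if ids is None:
            raise ValueError("method 'id-list' requires ids")
        wanted = set(ids)
        missing = wanted - {g.id for g in genes}
        if missing:
            raise ValueError(f"ids not found among genes: {sorted(missing)[:5]}")
        flags = [g.id in wanted for g in genes]
    elif method == "annotation-keyword":
        if annotation is None:
            raise ValueError("method 'annotation-keyword' requires an annotation table")
        kw = keyword.lower()
        matched = {
            str(row["id"])
            for _, row in annotation.iterrows()
            if kw in str(row.get("product", "")).lower()
        }
        flags = [g.id in matched for g in genes]
    elif method == "similarity":
        ref_path = Path(reference) if reference else packaged_ribosomal_reference()
        refs = _read_proteins(ref_path)
        db_len = sum(len(s) for _, s in refs)
        aligner = _make_aligner()
        flags = []
        for g in genes:
            prot = translate(g.seq, table_id).rstrip("*")
            if "*" in prot or not prot:
                flags.append(False)
                continue
            # PairwiseAligner rejects symbols outside the matrix alphabet (X
            # from N-containing codons); mask them conservatively.
            prot = prot.replace("X", "A")
            best = max(aligner.score(prot, rseq) for _, rseq in refs)
            evalue = _KA_K * len(prot) * db_len * math.exp(-_KA_LAMBDA * best)
            flags.append(evalue < evalue_threshold)
    else:
        raise ValueError(f"unknown selection method: {method!r}")

    heg = [replace(g, is_heg=True) for g, f in zip(genes, flags) if f]
    background = [replace(g, is_heg=False) for g, f in zip(genes, flags) if not f]
    if not heg:
        raise NoHegError(
            f"no highly expressed genes selected by method {method!r}; "
            "codon-bias indices are undefined without a HEG set"
        )
    return GeneSetPartition(heg=heg, background=background, selection_method=method)


def write_fasta(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene records as a plain FASTA file."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), 70):
                fh.write(g.seq[i : i + 70] + "\n")
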