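"""Non-codon growth-associated genome traits.

Fast-growing prokaryotes amplify their stable-RNA genes (rRNA operons,
tRNAs — in particular the nearly ubiquitous tRNAs whose anticodons match
generally preferred codons) and position translation/transcription genes
near the replication origin to exploit replication-associated gene dosage.
This module extracts those traits from feature annotations: gene
multiplicities and mean relative distances to the origin of replication on
a circular chromosome (0 = origin, 1 = the position opposite the origin).

Origins of replication are inputs (e.g. from DoriC); no origin prediction
is attempted, and archaea — whose multiple origins are hard to assess —
should be flagged so distance traits are skipped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default gap (nt) within which consecutive 16S anchors merge into one operon.
DEFAULT_OPERON_GAP = 3000

#: Gene categories whose origin-relative positions are reported.
POSITION_CATEGORIES = ("rRNA", "tRNA", "ubi-tRNA", "ribosomal-protein", "RNA-polymerase")

SYNTHETIC_UBI_LIST = "ubi_trna_anticodons.synthetic.tsv"


@dataclass
class TraitTable:
    """Trait values for one genome."""

    genome_id: str
    rrna_operons: int
    trna_total: int
    trna_ubi: int
    trna_nonubi: int
    rel_dist: dict[str, float]
    ori_position: int | None = None

    def __post_init__(self) -> None:
        if self.trna_ubi + self.trna_nonubi != self.trna_total:
            raise ValueError("ubi + non-ubi tRNA counts must equal the total")
        for cat, v in self.rel_dist.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"relative distance for {cat} outside [0, 1]")
        if self.ori_position is None and self.rel_dist:
            raise ValueError("relative distances require an origin position")

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "genome": self.genome_id,
            "rrna_operons": self.rrna_operons,
            "trna_total": self.trna_total,
            "trna_ubi": self.trna_ubi,
            "trna_nonubi": self.trna_nonubi,
            "ori_position": self.ori_position,
        }
        for cat in POSITION_CATEGORIES:
            row[f"rel_dist_{cat}"] = self.rel_dist.get(cat)
        return row


def relative_ori_distance(gene_pos: int, ori_pos: int, chrom_len: int) -> float:
    """Smallest circular distance to the origin over half the replicon.

    0 corresponds to the origin of replication, 0.5 to half the replicon
    arm, and 1 to the position diametrically opposite the origin (typically
    the terminus).
    """
    if chrom_len <= 0:
        raise ValueError("chrom_len must be > 0")
    for name, pos in (("gene_pos", gene_pos), ("ori_pos", ori_pos)):
        if not (0 <= pos < chrom_len):
            raise ValueError(f"{name}={pos} outside [0, {chrom_len})")
    raw = abs(gene_pos - ori_pos)
    circ = min(raw, chrom_len - raw)
    return circ / (chrom_len / 2.0)


def load_ubi_anticodons(path: str | Path | None = None) -> frozenset[str]:
    """Load the nearly-ubiquitous tRNA anticodon list (DNA alphabet).

    Without an explicit path, loads the packaged list — a synthetic
    stand-in (see the file header) to be replaced by the published
    ubi-tRNA anticodon set for production use.
    """
    if path is None:
        path = resources.files("maxgrowth").joinpath("data", SYNTHETIC_UBI_LIST)
    out = set()
    for line in Path(str(path)).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        anticodon = line.split("\t")[0].upper().replace("U", "T")
        out.add(anticodon)
    return frozenset(out)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the lightweight tab-separated annotation table.

    Expected columns: ``id``, ``start``, ``end``, ``strand``, ``product``
    (optionally ``type`` and ``anticodon``).  Coordinates are 0-based
    half-open.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"id", "start", "end", "strand", "product"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    return df


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 feature file into the lightweight annotation layout."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            continue
        attrs = dict(_GFF_ATTR.findall(parts[8]))
        rows.append(
            {
                "id": attrs.get("ID", attrs.get("locus_tag", f"{parts[0]}:{parts[3]}")),
                "start": int(parts[3]) - 1,  # GFF is 1-based inclusive
                "end": int(parts[4]),
                "strand": parts[6],
                "type": parts[2],
                "product": attrs.get("product", ""),
                "anticodon": attrs.get("anticodon", ""),
            }
        )
    if not rows:
        raise ValueError(f"no features parsed from {path}")
    return pd.DataFrame(rows)


def _is_type(row: pd.Series, key: str) -> bool:
    return key.lower() in str(row.get("type", "")).lower()


def _category_mask(df: pd.DataFrame, category: str, ubi: frozenset[str]) -> pd.Series:
    product = df.get("product", pd.Series("", index=df.index)).astype(str)
    ftype = df.get("type", pd.Series("", index=df.index)).astype(str)
    anticodon = (
        df.get("anticodon", pd.Series("", index=df.index))
        .astype(str).str.upper().str.replace("U", "T")
    )
    if category == "rRNA":
        return ftype.str.contains("rRNA", case=False) & product.str.contains(
            "16S", case=False
        )
    if category == "tRNA":
        return ftype.str.contains("tRNA", case=False)
    if category == "ubi-tRNA":
        return ftype.str.contains("tRNA", case=False) & anticodon.isin(ubi)
    if category == "ribosomal-protein":
        return product.str.contains("ribosomal protein", case=False)
    if category == "RNA-polymerase":
        return product.str.contains("RNA polymerase", case=False)
    raise ValueError(f"unknown category {category!r}")


def count_rrna_operons(
    annotation: pd.DataFrame, operon_gap: int = DEFAULT_OPERON_GAP
) -> int:
    """Count rRNA operons as clusters of 16S anchors merged within a gap.

    Order-independent: features are sorted by start before clustering.
    """
    mask = _category_mask(annotation, "rRNA", frozenset())
    rows = annotation.loc[mask].sort_values("start")
    count = 0
    prev_end = None
    for _, row in rows.iterrows():
        if prev_end is None or row["start"] - prev_end > operon_gap:
            count += 1
        prev_end = max(prev_end, row["end"]) if prev_end is not None else row["end"]
    return count


def count_stable_rna(
    annotation: pd.DataFrame,
    ubi_anticodons: frozenset[str] | None = None,
    operon_gap: int = DEFAULT_OPERON_GAP,
) -> dict[str, int]:
    """Stable-RNA gene multiplicities: rRNA operons and tRNA counts.

    tRNAs whose anticodon belongs to the ubi list are counted as ubi-tRNAs;
    the remainder as non-ubi.  Annotations without any rRNA/tRNA feature
    yield zero counts with a warning.
    """
    ubi = ubi_anticodons if ubi_anticodons is not None else load_ubi_anticodons()
    trna_mask = _category_mask(annotation, "tRNA", ubi)
    ubi_mask = _category_mask(annotation, "ubi-tRNA", ubi)
    counts = {
        "rrna_operons": count_rrna_operons(annotation, operon_gap),
        "trna_total": int(trna_mask.sum()),
        "trna_ubi": int(ubi_mask.sum()),
    }
    counts["trna_nonubi"] = counts["trna_total"] - counts["trna_ubi"]
    if counts["rrna_operons"] == 0 and counts["trna_total"] == 0:
        logger.warning("annotation contains no rRNA or tRNA features")
    return counts


def trait_table(
    genome_id: str,
    annotation: pd.DataFrame,
    ori_position: int | None = None,
    chrom_len: int | None = None,
    ubi_anticodons: frozenset[str] | None = None,
    archaeon: bool = False,
    operon_gap: int = DEFAULT_OPERON_GAP,
) -> TraitTable:
    """Full trait extraction for one genome.

    Mean origin-relative distances (gene midpoints) are reported per
    category when an origin and replicon length are supplied and the genome
    is not flagged as an archaeon.
    """
    ubi = ubi_anticodons if ubi_anticodons is not None else load_ubi_anticodons()
    counts = count_stable_rna(annotation, ubi, operon_gap)
    rel: dict[str, float] = {}
    if ori_position is not None and chrom_len is not None and not archaeon:
        mid = ((annotation["start"] + annotation["end"]) // 2) % chrom_len
        for cat in POSITION_CATEGORIES:
            mask = _category_mask(annotation, cat, ubi)
            if mask.any():
                rel[cat] = float(
                    np.mean(
                        [
                            relative_ori_distance(int(m), ori_position, chrom_len)
                            for m in mid[mask]
                        ]
                    )
                )
    return TraitTable(
        genome_id=genome_id,
        rrna_operons=counts["rrna_operons"],
        trna_total=counts["trna_total"],
        trna_ubi=counts["trna_ubi"],
        trna_nonubi=counts["trna_nonubi"],
        rel_dist=rel,
        ori_position=ori_position,
    )
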