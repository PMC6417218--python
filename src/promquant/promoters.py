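"""Operon-aware extraction of intergenic promoter regions.

A promoter is taken, operationally, as the whole intergenic region between a
gene and the nearest preceding open reading frame on either strand. For a
gene inside an operon the shared promoter sits upstream of the operon lead,
so every member resolves to the lead gene's region. Coordinates are 1-based
inclusive (GFF3 convention) throughout; minus-strand sequences are returned
reverse-complemented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (DegenerateRegionError, InvalidArgumentError,
                     NotFoundError)

__all__ = [
    "Annotation",
    "OperonTable",
    "PromoterRegion",
    "resolve_anchor",
    "extract_promoter",
    "fetch_sequence",
    "read_gff3",
    "write_gff3",
    "read_genome_fasta",
    "write_genome_fasta",
]

_GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score",
                "strand", "phase", "attributes"]


class Annotation:
    """Gene coordinates: gene_id, contig, strand, 1-based inclusive start/end."""

    def __init__(self, genes: pd.DataFrame):
        required = {"gene_id", "contig", "strand", "start", "end"}
        if not required.issubset(genes.columns):
            raise InvalidArgumentError(f"annotation needs columns {sorted(required)}")
        if genes["gene_id"].duplicated().any():
            raise InvalidArgumentError("duplicate gene_ids in annotation")
        if (genes["start"] > genes["end"]).any():
            raise InvalidArgumentError("start must be <= end")
        if not genes["strand"].isin(["+", "-"]).all():
            raise InvalidArgumentError("strand must be '+' or '-'")
        self.genes = genes.reset_index(drop=True).copy()
        self._by_id = self.genes.set_index("gene_id")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id.index

    def gene(self, gene_id: str) -> pd.Series:
        try:
            return self._by_id.loc[gene_id]
        except KeyError:
            raise NotFoundError(f"gene {gene_id!r} not in annotation") from None

    def on_contig(self, contig: str) -> pd.DataFrame:
        return self.genes[self.genes["contig"] == contig]


class OperonTable:
    """Operon membership: members in transcription order, one strand each."""

    def __init__(self, table: pd.DataFrame):
        required = {"operon_id", "gene_id", "position_in_operon", "strand"}
        if not required.issubset(table.columns):
            raise InvalidArgumentError(f"operon table needs columns {sorted(required)}")
        if table["gene_id"].duplicated().any():
            raise InvalidArgumentError("a gene may belong to at most one operon")
        self.table = table.reset_index(drop=True).copy()
        self._operon_of = dict(zip(self.table["gene_id"], self.table["operon_id"]))

    def __len__(self) -> int:
        return self.table["operon_id"].nunique()

    def operon_of(self, gene_id: str) -> str | None:
        return self._operon_of.get(gene_id)

    def lead_gene(self, operon_id: str) -> str:
        members = self.table[self.table["operon_id"] == operon_id]
        if members.empty:
            raise NotFoundError(f"operon {operon_id!r} not found")
        return members.sort_values("position_in_operon").iloc[0]["gene_id"]

    def members(self, operon_id: str) -> list[str]:
        sub = self.table[self.table["operon_id"] == operon_id]
        return list(sub.sort_values("position_in_operon")["gene_id"])

    @classmethod
    def empty(cls) -> "OperonTable":
        return cls(pd.DataFrame(columns=["operon_id", "gene_id",
                                         "position_in_operon", "strand"]))


@dataclass(frozen=True)
class PromoterRegion:
    """Strand-aware intergenic interval upstream of an anchor gene."""

    anchor_gene_id: str
    contig: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    truncated: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InvalidArgumentError("end must be >= start")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise InvalidArgumentError("sequence length must equal region length")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def resolve_anchor(gene_id: str, operons: OperonTable,
                   annotation: Annotation | None = None) -> str:
    """Map a gene to its promoter-bearing anchor.

    Operon members resolve to the operon's first gene in transcription order
    (which carries the shared promoter); other genes anchor themselves.
    """
    if annotation is not None and gene_id not in annotation:
        raise NotFoundError(f"gene {gene_id!r} not in annotation")
    oid = operons.operon_of(gene_id)
    if oid is None:
        return gene_id
    return operons.lead_gene(oid)


def extract_promoter(anchor: str, annotation: Annotation,
                     contig_lengths: dict[str, int] | None = None
                     ) -> PromoterRegion:
    """Extract the intergenic region upstream of the anchor gene.

    On the + strand the region runs from one base past the nearest ORF
    ending before the anchor's start, up to the base before the anchor; on
    the - strand, from the base after the anchor's end up to the base before
    the nearest ORF starting after it. "Nearest" considers genes on either
    strand. An anchor at the contig edge yields a region truncated at the
    contig boundary (flagged); when ``contig_lengths`` is absent the
    downstream bound for an edge anchor on the - strand falls back to the
    last annotated position. A zero-length gap raises
    :class:`DegenerateRegionError`.
    """
    g = annotation.gene(anchor)
    contig_genes = annotation.on_contig(g["contig"])
    others = contig_genes[contig_genes["gene_id"] != anchor]

    truncated = False
    if g["strand"] == "+":
        preceding = others[others["end"] < g["start"]]
        if preceding.empty:
            lo, truncated = 1, True
            neighbour = "contig start"
        else:
            prev = preceding.loc[preceding["end"].idxmax()]
            lo = int(prev["end"]) + 1
            neighbour = prev["gene_id"]
        hi = int(g["start"]) - 1
    else:
        following = others[others["start"] > g["end"]]
        lo = int(g["end"]) + 1
        if following.empty:
            truncated = True
            neighbour = "contig end"
            if contig_lengths and g["contig"] in contig_lengths:
                hi = int(contig_lengths[g["contig"]])
            else:
                hi = max(int(contig_genes["end"].max()), lo)
        else:
            nxt = following.loc[following["start"].idxmin()]
            hi = int(nxt["start"]) - 1
            neighbour = nxt["gene_id"]
    if hi < lo:
        raise DegenerateRegionError(
            f"no intergenic gap between {anchor} and {neighbour} "
            f"on {g['contig']}")
    return PromoterRegion(anchor_gene_id=anchor, contig=g["contig"],
                          strand=g["strand"], start=lo, end=hi,
                          truncated=truncated)


def fetch_sequence(region: PromoterRegion,
                   genome: dict[str, str]) -> PromoterRegion:
    """Attach the genomic sequence to a region (reverse-complemented on -)."""
    if region.contig not in genome:
        raise NotFoundError(f"contig {region.contig!r} not in genome")
    contig_seq = genome[region.contig]
    if region.end > len(contig_seq):
        raise InvalidArgumentError(
            f"region {region.start}-{region.end} exceeds contig length "
            f"{len(contig_seq)}")
    raw = contig_seq[region.start - 1:region.end].upper()
    if set(raw) - set("ACGTN"):
        raise InvalidArgumentError("contig contains non-nucleotide characters")
    seq = str(Seq(raw).reverse_complement()) if region.strand == "-" else raw
    return replace(region, sequence=seq)


# --- file I/O -------------------------------------------------------------

def write_gff3(annotation: Annotation, path: str | Path) -> None:
    rows = annotation.genes
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in rows.iterrows():
            attrs = f"ID={r['gene_id']}"
            fh.write("\t".join([
                str(r["contig"]), "promquant", "gene", str(r["start"]),
                str(r["end"]), ".", r["strand"], ".", attrs]) + "\n")


def read_gff3(path: str | Path) -> Annotation:
    """Read `gene` features from a GFF3 file (needs an ID= attribute)."""
    frame = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=_GFF_COLUMNS, dtype={"seqid": str})
    frame = frame[frame["type"] == "gene"].copy()
    ids = frame["attributes"].str.extract(r"ID=([^;]+)")[0]
    if ids.isna().any():
        raise InvalidArgumentError("gene feature without ID= attribute")
    return Annotation(pd.DataFrame({
        "gene_id": ids.to_numpy(),
        "contig": frame["seqid"].to_numpy(),
        "strand": frame["strand"].to_numpy(),
        "start": frame["start"].astype(int).to_numpy(),
        "end": frame["end"].astype(int).to_numpy(),
    }))


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_promoters_fasta(regions: list[PromoterRegion],
                          path: str | Path) -> None:
    records = []
    for r in regions:
        if r.sequence is None:
            raise InvalidArgumentError(
                f"region {r.anchor_gene_id} has no sequence attached")
        records.append(SeqRecord(
            Seq(r.sequence), id=r.anchor_gene_id,
            description=f"{r.contig}:{r.start}-{r.end}({r.strand})"))
    SeqIO.write(records, str(path), "fasta")


def regions_to_frame(regions: list[PromoterRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"anchor_gene_id": r.anchor_gene_id, "contig": r.contig,
          "strand": r.strand, "start": r.start, "end": r.end,
          "length": r.length, "truncated": r.truncated}
         for r in regions],
        columns=["anchor_gene_id", "contig", "strand", "start", "end",
                 "length", "truncated"])
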