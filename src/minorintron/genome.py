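"""Annotation parsing, longest-isoform transcriptomes and intron extraction.

Coordinates are 1-based inclusive at the GFF3/GTF boundary and 0-based half-open
internally; every coordinate the package reports is 1-based inclusive.  Introns are
gaps between consecutive CDS segments of each gene's longest coding isoform (or
between exon segments for transcripts without CDS); minus-strand sequence is
reverse-complemented so termini and motifs are always reported on the sense strand.
Introns shorter than ``min_length`` (default 30 nt) are discarded.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio import SeqIO

from .errors import InsufficientDataError, ParameterError
from .synthetic import revcomp

log = logging.getLogger(__name__)

INTRON_TSV_COLUMNS = [
    "species", "gene_id", "transcript_id", "intron_id", "contig", "start", "end",
    "strand", "length", "phase", "relative_position", "terminus_5", "terminus_3",
    "defining_feature", "cds_offset", "has_n",
]


@dataclass
class TranscriptModel:
    """One gene's selected isoform: ordered coding segments on the genome."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    cds_segments: list[tuple[int, int]]   # 0-based half-open, genomic order
    defining_feature: str = "CDS"         # 'CDS' or 'exon'

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def segments_in_transcription_order(self) -> list[tuple[int, int]]:
        segs = sorted(self.cds_segments)
        return segs if self.strand == "+" else segs[::-1]


@dataclass
class IntronRecord:
    """One intron with sense-strand sequence features and transcript context."""

    species: str
    gene_id: str
    transcript_id: str
    intron_id: str
    contig: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    strand: str
    length: int
    phase: int | None          # None for exon-defined (UTR) introns
    relative_position: float
    terminus_5: str
    terminus_3: str
    defining_feature: str
    cds_offset: int            # cumulative preceding coding length (nt)
    sequence: str = ""
    has_n: bool = False

    @property
    def termini(self) -> str:
        return f"{self.terminus_5}-{self.terminus_3}"


def read_genome(path) -> dict[str, str]:
    """Load a FASTA into an in-memory {contig: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _feature_db(annotation_path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(annotation_path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )


def build_transcriptome(annotation, genome: dict[str, str] | None = None) -> dict[str, TranscriptModel]:
    """One TranscriptModel per gene: the isoform maximising coding length.

    Ties are broken by lexicographically smaller transcript_id.  Transcripts without
    CDS fall back to exon segments (``defining_feature='exon'``); CDS features whose
    parent mRNA is missing are attached to the gene permissively (logged).  A CDS
    segment outside its contig voids the gene (record-level error, logged).
    """
    db = annotation if isinstance(annotation, gffutils.FeatureDB) else _feature_db(annotation)
    models: dict[str, TranscriptModel] = {}

    for gene in db.features_of_type(("gene",)):
        candidates: list[tuple[int, str, TranscriptModel]] = []
        transcripts = list(db.children(gene, level=1, featuretype=("mRNA", "transcript")))
        if not transcripts:
            # permissive: CDS (or exon) directly under the gene
            segs = [(c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")]
            if segs:
                log.info("gene %s has CDS without an mRNA parent; parsed permissively", gene.id)
                candidates.append((sum(e - s for s, e in segs), gene.id, TranscriptModel(
                    gene.id, gene.id, gene.seqid, gene.strand, sorted(segs))))
        for tx in transcripts:
            cds = [(c.start - 1, c.end) for c in db.children(tx, featuretype="CDS")]
            if cds:
                model = TranscriptModel(gene.id, tx.id, gene.seqid, gene.strand,
                                        sorted(cds), "CDS")
            else:
                exons = [(c.start - 1, c.end) for c in db.children(tx, featuretype="exon")]
                if not exons:
                    continue
                model = TranscriptModel(gene.id, tx.id, gene.seqid, gene.strand,
                                        sorted(exons), "exon")
            candidates.append((model.coding_length if model.defining_feature == "CDS" else 0,
                               tx.id, model))
        if not candidates:
            continue
        # longest coding length; ties -> lexicographically smaller transcript_id
        candidates.sort(key=lambda c: (-c[0], c[1]))
        chosen = candidates[0][2]
        if genome is not None:
            contig_len = len(genome.get(chosen.contig, ""))
            if chosen.contig not in genome or any(e > contig_len or s < 0
                                                  for s, e in chosen.cds_segments):
                log.warning("gene %s: segment outside contig bounds; gene skipped", gene.id)
                continue
        models[gene.id] = chosen
    return models


def extract_introns(
    transcripts: dict[str, TranscriptModel],
    genome: dict[str, str],
    min_length: int = 30,
    species: str = "sp",
) -> list[IntronRecord]:
    """Extract introns (with phase, relative position, termini and sequence).

    Phase = cumulative preceding coding length mod 3; relative position = cumulative
    preceding coding length / total coding length.  Exon-defined transcripts yield
    introns with phase None (excluded from comparative analyses downstream).
    """
    if min_length < 0:
        raise ParameterError("min_length must be >= 0")
    records: list[IntronRecord] = []
    for gene_id in sorted(transcripts):
        tx = transcripts[gene_id]
        contig_seq = genome[tx.contig]
        segs = tx.segments_in_transcription_order()
        total = sum(e - s for s, e in segs)
        cum = 0
        n_out = 0
        for i in range(len(segs) - 1):
            s0, e0 = segs[i]
            cum += e0 - s0
            s1, e1 = segs[i + 1]
            lo, hi = (e0, s1) if tx.strand == "+" else (e1, s0)
            if hi - lo <= 0:
                log.warning("gene %s: zero-length gap between segments (malformed annotation)",
                            gene_id)
                continue
            if hi - lo < min_length:
                continue
            seq = contig_seq[lo:hi]
            if tx.strand == "-":
                seq = revcomp(seq)
            n_out += 1
            t5, t3 = seq[:2], seq[-2:]
            records.append(IntronRecord(
                species=species,
                gene_id=gene_id,
                transcript_id=tx.transcript_id,
                intron_id=f"{tx.transcript_id}.i{n_out}",
                contig=tx.contig,
                start=lo + 1,
                end=hi,
                strand=tx.strand,
                length=hi - lo,
                phase=(cum % 3) if tx.defining_feature == "CDS" else None,
                relative_position=cum / total if total else 0.0,
                terminus_5=t5,
                terminus_3=t3,
                defining_feature=tx.defining_feature,
                cds_offset=cum,
                sequence=seq,
                has_n="N" in t5 + t3,
            ))
    return records


def introns_to_frame(records: list[IntronRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in INTRON_TSV_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=INTRON_TSV_COLUMNS)


def write_intron_tsv(records: list[IntronRecord], path) -> None:
    introns_to_frame(records).to_csv(path, sep="\t", index=False)


def write_intron_bed(records: list[IntronRecord], path) -> None:
    """BED12-style export (one block per intron, 0-based half-open)."""
    with open(path, "w") as fh:
        for r in records:
            size = r.end - r.start + 1
            fh.write("\t".join(map(str, [
                r.contig, r.start - 1, r.end, r.intron_id, 0, r.strand,
                r.start - 1, r.end, "0,0,0", 1, size, 0,
            ])) + "\n")


@dataclass
class StrandSanityReport:
    termini_counts: Counter
    ct_ac_fraction: float
    warning: bool


def strand_sanity_report(records: list[IntronRecord], max_ct_ac: float = 0.01) -> StrandSanityReport:
    """Tally termini and flag a suspicious fraction of CT-AC boundaries.

    CT-AC is the exact reverse complement of GT-AG, so an appreciable fraction
    (> 1% by default) suggests genes annotated on the wrong strand.
    """
    if not records:
        raise InsufficientDataError("strand sanity report requires at least one intron")
    tally = Counter(r.termini for r in records)
    frac = tally.get("CT-AC", 0) / len(records)
    return StrandSanityReport(tally, frac, frac > max_ct_ac)


def genic_intron_density(
    transcripts: dict[str, TranscriptModel],
    records: list[IntronRecord],
) -> pd.DataFrame:
    """Per-gene introns per kbp coding sequence, plus coding length.

    density = n_introns * 1000 / coding_length; genes with zero coding length
    (exon-defined models) are excluded.
    """
    per_gene = Counter(r.gene_id for r in records if r.defining_feature == "CDS")
    rows = []
    for gene_id in sorted(transcripts):
        tx = transcripts[gene_id]
        if tx.defining_feature != "CDS" or tx.coding_length == 0:
            continue
        n = per_gene.get(gene_id, 0)
        rows.append({
            "gene_id": gene_id,
            "n_introns": n,
            "coding_length": tx.coding_length,
            "genic_intron_density": n * 1000.0 / tx.coding_length,
        })
    return pd.DataFrame(rows, columns=["gene_id", "n_introns", "coding_length",
                                       "genic_intron_density"])
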