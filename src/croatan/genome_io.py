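"""Sequence and gene-model input, and enumeration of candidate Cas9 targets.

Coordinates are 0-based half-open everywhere. A target's ``cut_coord`` is the
boundary index of the blunt SpCas9 cut, 3 bp 5' of the NGG PAM (between
protospacer bases 17 and 18), so the inter-DSB distance of a guide pair is
simply ``abs(cut_a - cut_b)`` in bp.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, ValidationError

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

#: protospacer occupies context30[4:24]; PAM is context30[24:27]
CONTEXT_LEN = 30
PROTO_OFFSET = 4
PAM_OFFSET = 24
#: cut boundary inside the 30-nt context window
CONTEXT_CUT_INDEX = 21


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    strand: str

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for a, b in zip(self.exons, self.exons[1:]):
            if b[0] < a[1]:
                raise ValidationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValidationError(
                    f"CDS interval [{cs},{ce}) outside exons in {self.transcript_id}"
                )


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand if self.transcripts else "+"

    @property
    def span(self) -> tuple[int, int]:
        starts = [e[0] for t in self.transcripts for e in t.exons]
        ends = [e[1] for t in self.transcripts for e in t.exons]
        return min(starts), max(ends)


@dataclass
class TargetSite:
    site_id: str
    chromosome: str
    strand: str
    protospacer: str
    pam: str
    cut_coord: int
    context30: str
    overlapping_transcripts: list[str] = field(default_factory=list)
    cds_aa_index: Optional[int] = None
    gene_id: Optional[str] = None

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise ValidationError(f"{self.site_id}: protospacer must be 20 nt")
        if len(self.context30) != CONTEXT_LEN:
            raise ValidationError(f"{self.site_id}: context must be 30 nt")
        if self.context30[PROTO_OFFSET:PAM_OFFSET] != self.protospacer:
            raise ValidationError(
                f"{self.site_id}: context does not embed protospacer at offset 4"
            )

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic half-open interval occupied by the protospacer."""
        if self.strand == "+":
            return self.cut_coord - 17, self.cut_coord + 3
        return self.cut_coord - 3, self.cut_coord + 17


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-line) FASTA into ``{id: uppercase sequence}``.

    The id is the first whitespace token of the header. Non-IUPAC residues
    raise :class:`FormatError` naming the offending line.
    """
    records: dict[str, str] = {}
    with open(path) as fh:
        seqio = SeqIO.parse(fh, "fasta")
        for rec in seqio:
            records[rec.id] = str(rec.seq).upper()
    # validate residues with line provenance
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(">"):
                if line.startswith(">") and len(line) == 1:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                continue
            bad = set(line.upper()) - IUPAC_DNA
            if bad:
                raise FormatError(
                    f"line {lineno}: non-IUPAC residue(s) {sorted(bad)}"
                )
    return records


def _gene_models_from_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        gm = GeneModel(gene_id=g.id, chromosome=g.seqid)
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = [(e.start - 1, e.end) for e in db.children(t, featuretype="exon")]
            cds = [(c.start - 1, c.end) for c in db.children(t, featuretype="CDS")]
            gm.transcripts.append(
                Transcript(transcript_id=t.id, exons=exons, cds=cds, strand=t.strand)
            )
        genes.append(gm)
    return genes


_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def _gene_models_from_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#")
    genes: list[GeneModel] = []
    for _, row in df.iterrows():
        start = int(row.start)
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        offs = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != int(row.blockCount) or len(offs) != int(row.blockCount):
            raise FormatError(f"BED12 record {row['name']}: block count mismatch")
        exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
        thick = (int(row.thickStart), int(row.thickEnd))
        cds = [
            (max(es, thick[0]), min(ee, thick[1]))
            for es, ee in exons
            if max(es, thick[0]) < min(ee, thick[1])
        ]
        tx = Transcript(
            transcript_id=str(row["name"]), exons=exons, cds=cds, strand=str(row.strand)
        )
        genes.append(
            GeneModel(gene_id=str(row["name"]), chromosome=str(row.chrom),
                      transcripts=[tx])
        )
    return genes


def read_gene_models(path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (1-based closed) or BED12 (0-based half-open)."""
    if dialect == "gff3":
        return _gene_models_from_gff3(path)
    if dialect == "bed12":
        return _gene_models_from_bed12(path)
    raise ValidationError(f"unknown gene-model dialect: {dialect!r}")


def _pam_regex(pam_pattern: str) -> re.Pattern:
    parts = []
    for ch in pam_pattern.upper():
        if ch == "N":
            parts.append("[ACGT]")
        elif ch in "ACGT":
            parts.append(ch)
        else:
            raise ValidationError(
                f"PAM pattern {pam_pattern!r}: only ACGT and N are supported"
            )
    return re.compile("".join(parts))


def _cds_aa_index(gene_models: Iterable[GeneModel], chrom: str, cut: int,
                  strand_of_tx: str = None) -> tuple[list[str], Optional[int]]:
    """Transcripts overlapping the cut, and the aa index of the codon at the cut."""
    overlapping: list[str] = []
    aa_index: Optional[int] = None
    for gm in gene_models:
        if gm.chromosome != chrom:
            continue
        for tx in gm.transcripts:
            in_exon = any(es <= cut - 1 and cut <= ee for es, ee in tx.exons)
            if not in_exon:
                continue
            overlapping.append(tx.transcript_id)
            # base whose codon "contains" the cut: the first base 3' of the cut
            # along the transcript orientation
            base = cut if tx.strand == "+" else cut - 1
            offset = 0
            found = None
            cds_iter = tx.cds if tx.strand == "+" else list(reversed(tx.cds))
            for cs, ce in cds_iter:
                if cs <= base < ce:
                    local = (base - cs) if tx.strand == "+" else (ce - 1 - base)
                    found = offset + local
                    break
                offset += ce - cs
            if found is not None and aa_index is None:
                aa_index = found // 3
    return overlapping, aa_index


def enumerate_targets(
    sequence: str,
    gene_models: Iterable[GeneModel] = (),
    pam_pattern: str = "NGG",
    chromosome: str = "chr",
    id_prefix: str = "site",
) -> list[TargetSite]:
    """Enumerate NGG Cas9 target sites on both strands of ``sequence``.

    Sites whose 30-nt context window does not fit inside the sequence, or
    whose window contains an ambiguous base, are skipped.
    """
    seq = sequence.upper()
    pam_re = _pam_regex(pam_pattern)
    gene_models = list(gene_models)
    sites: list[TargetSite] = []
    L = len(seq)

    def scan(s: str, strand: str):
        for m in re.finditer("(?=GG)", s):
            p = m.start() - 1  # PAM begins one base before the GG
            if p < PROTO_OFFSET + 20 or p + 6 > len(s):
                continue
            pam = s[p:p + 3]
            if not pam_re.fullmatch(pam):
                continue
            ctx = s[p - 24:p + 6]
            if set(ctx) - set("ACGT"):
                continue
            cut_local = p - 3
            if strand == "+":
                cut = cut_local
            else:
                cut = L - cut_local
            ov, aa = _cds_aa_index(gene_models, chromosome, cut)
            sites.append(TargetSite(
                site_id=f"{id_prefix}_{strand}{cut}",
                chromosome=chromosome,
                strand=strand,
                protospacer=s[p - 20:p],
                pam=pam,
                cut_coord=cut,
                context30=ctx,
                overlapping_transcripts=ov,
                cds_aa_index=aa,
            ))

    scan(seq, "+")
    scan(revcomp(seq), "-")
    sites.sort(key=lambda t: (t.cut_coord, t.strand))
    return sites


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    rows = [{
        "site_id": s.site_id, "chrom": s.chromosome, "strand": s.strand,
        "cut_coord": s.cut_coord, "protospacer": s.protospacer, "pam": s.pam,
        "context30": s.context30,
        "transcripts": ",".join(s.overlapping_transcripts),
        "cds_aa_index": "" if s.cds_aa_index is None else s.cds_aa_index,
    } for s in sites]
    return pd.DataFrame(rows, columns=[
        "site_id", "chrom", "strand", "cut_coord", "protospacer", "pam",
        "context30", "transcripts", "cds_aa_index",
    ])
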