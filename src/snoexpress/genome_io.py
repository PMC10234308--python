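"""Genome and annotation I/O plus genomic-context features for snoRNAs.

Internal coordinates are 0-based half-open throughout; the GTF boundary
converts from/to the 1-based inclusive convention. Sequences handed to the
rest of the package are RNA (T -> U), 5'->3' in the orientation of the
snoRNA itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

INTERGENIC = "intergenic"

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned as DNA)."""
    return seq.translate(_COMPLEMENT)[::-1].replace("u", "t").replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class SnoRecord:
    """One annotated snoRNA: coordinates, class, strand-corrected RNA sequence."""

    id: str
    interval: GenomicInterval
    sno_type: str  # "CD" or "HACA"
    sequence: str

    def __post_init__(self) -> None:
        if self.sno_type not in ("CD", "HACA"):
            raise ValueError(f"unknown snoRNA type {self.sno_type!r}")
        if len(self.sequence) != self.interval.length:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"interval length {self.interval.length}"
            )
        if set(self.sequence) - set("ACGUTN"):
            raise ValueError(f"{self.id}: non-nucleotide characters in sequence")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class Gene:
    id: str
    interval: GenomicInterval
    biotype: str


@dataclass(frozen=True)
class Transcript:
    id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]  # sorted by genomic start

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.interval.chrom, a.end, b.start, self.interval.strand)
                )
        return tuple(out)

    def introns_5p_to_3p(self) -> tuple[GenomicInterval, ...]:
        """Introns ordered from the transcript 5' end."""
        ivs = self.introns
        return ivs if self.interval.strand == "+" else tuple(reversed(ivs))


@dataclass
class Annotation:
    genes: dict[str, Gene]
    transcripts: dict[str, Transcript]

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def genes_with_biotype(self, biotype: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.biotype == biotype]


@dataclass(frozen=True)
class HostAssignment:
    sno_id: str
    host_id: str | None
    host_biotype: str  # protein_coding | noncoding | intergenic

    @property
    def is_intergenic(self) -> bool:
        return self.host_id is None


@dataclass
class IntronContext:
    """Position of an intronic snoRNA within its host intron.

    Distances are on the coding strand of the host: `dist_upstream_exon` is
    the gap between the host-5' exon boundary and the snoRNA 5' end.
    """

    total_introns: int
    intron_length: int
    rank_5p: int
    rank_3p: int
    relative_rank_3p: float
    dist_upstream_exon: int
    dist_downstream_exon: int
    dist_branchpoint: int | None = None
    # genomic interval of the hosting intron (convenience for branchpoint lookup)
    intron_interval: GenomicInterval | None = None

    def validate(self, sno_length: int) -> None:
        assert 1 <= self.rank_5p <= self.total_introns
        assert 1 <= self.rank_3p <= self.total_introns
        assert self.rank_5p + self.rank_3p == self.total_introns + 1
        assert 0 < self.relative_rank_3p <= 1
        assert self.dist_upstream_exon >= 0 and self.dist_downstream_exon >= 0
        assert (
            self.dist_upstream_exon + sno_length + self.dist_downstream_exon
            == self.intron_length
        )


class AnnotationError(ValueError):
    pass


def _prescan_gtf(path: Path) -> None:
    """Cheap syntactic validation so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise AnnotationError(
                    f"{path}: malformed GTF line {lineno}: start > end"
                )


def read_annotation(gtf_path: str | Path) -> Annotation:
    """Read an Ensembl-dialect GTF into genes, transcripts, and exons.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Every exon must lie within its transcript, every transcript within its
    gene; violations raise :class:`AnnotationError`.
    """
    gtf_path = Path(gtf_path)
    if not gtf_path.exists():
        raise FileNotFoundError(gtf_path)
    _prescan_gtf(gtf_path)

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, tuple[str, GenomicInterval]] = {}

    for feat in db.all_features():
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "gene":
            gid = feat.attributes["gene_id"][0]
            biotype = feat.attributes.get("gene_biotype", ["unknown"])[0]
            genes[gid] = Gene(gid, iv, biotype)
        elif feat.featuretype == "transcript":
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
            tx_meta[tid] = (gid, iv)
        elif feat.featuretype == "exon":
            tid = feat.attributes["transcript_id"][0]
            exons_by_tx.setdefault(tid, []).append(iv)

    for tid, (gid, iv) in tx_meta.items():
        exons = tuple(sorted(exons_by_tx.get(tid, []), key=lambda e: e.start))
        for e in exons:
            if e.start < iv.start or e.end > iv.end:
                raise AnnotationError(
                    f"exon {e.chrom}:{e.start}-{e.end} outside transcript {tid}"
                )
        transcripts[tid] = Transcript(tid, gid, iv, exons)
    for tid, exons in exons_by_tx.items():
        if tid not in tx_meta:
            raise AnnotationError(f"exon references unknown transcript {tid}")

    return Annotation(genes, transcripts)


def read_snorna_records(
    annotation: Annotation,
    fasta: str | Path | Fasta,
    type_map: Mapping[str, str],
    biotype: str = "snoRNA",
) -> list[SnoRecord]:
    """Extract snoRNA genes and their strand-corrected RNA sequences.

    `type_map` maps gene id -> {"CD", "HACA"}; genes missing from it are
    skipped with a warning.
    """
    genome = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    records = []
    for gene in annotation.genes_with_biotype(biotype):
        if gene.id not in type_map:
            logger.warning("snoRNA %s has no type annotation; skipped", gene.id)
            continue
        iv = gene.interval
        seq = str(genome[iv.chrom][iv.start : iv.end]).upper()
        if iv.strand == "-":
            seq = reverse_complement(seq)
        records.append(SnoRecord(gene.id, iv, type_map[gene.id], to_rna(seq)))
    return sorted(records, key=lambda r: r.id)


def assign_host(
    sno: SnoRecord, genes: Iterable[Gene], exclude: frozenset[str] | None = None
) -> HostAssignment:
    """Assign the host gene: a same-strand gene overlapping the snoRNA.

    Several candidates are resolved to the smallest gene fully containing
    the snoRNA, falling back to the smallest overlapping one; ties break by
    gene id. No candidate means the snoRNA is intergenic.
    """
    exclude = exclude or frozenset()
    cands = [
        g
        for g in genes
        if g.id != sno.id
        and g.id not in exclude
        and g.interval.overlaps(sno.interval, same_strand=True)
    ]
    if not cands:
        return HostAssignment(sno.id, None, INTERGENIC)
    containing = [g for g in cands if g.interval.contains(sno.interval)]
    pool = containing or cands
    if len(cands) > 1:
        logger.warning(
            "snoRNA %s overlaps %d candidate hosts; choosing smallest", sno.id, len(cands)
        )
    host = min(pool, key=lambda g: (g.interval.length, g.id))
    biotype = "protein_coding" if host.biotype == "protein_coding" else "noncoding"
    return HostAssignment(sno.id, host.id, biotype)


def derive_intron_context(
    sno: SnoRecord, host_transcripts: Sequence[Transcript]
) -> IntronContext | None:
    """Intron rank/length and exon distances for an intronic snoRNA.

    Among host transcripts with an intron fully containing the snoRNA, the
    smallest containing intron wins (tie-break by transcript id). Returns
    None when the snoRNA overlaps an exon of every transcript or sits in no
    intron (context MISSING).
    """
    best: tuple[int, str, Transcript, int] | None = None  # (intron_len, tid, tx, rank0)
    for tx in sorted(host_transcripts, key=lambda t: t.id):
        for rank0, intron in enumerate(tx.introns_5p_to_3p()):
            if intron.contains(sno.interval):
                key = (intron.length, tx.id, tx, rank0)
                if best is None or key[:2] < best[:2]:
                    best = key
    if best is None:
        exonic = any(
            ex.overlaps(sno.interval, same_strand=True)
            for tx in host_transcripts
            for ex in tx.exons
        )
        logger.warning(
            "snoRNA %s is %s in host transcripts; intron context missing",
            sno.id,
            "exonic" if exonic else "not intron-contained",
        )
        return None

    intron_len, _tid, tx, rank0 = best
    introns = tx.introns_5p_to_3p()
    total = len(introns)
    intron = introns[rank0]
    rank_5p = rank0 + 1
    rank_3p = total - rank0
    if sno.interval.strand == "+":
        dist_up = sno.interval.start - intron.start
        dist_down = intron.end - sno.interval.end
    else:
        dist_up = intron.end - sno.interval.end
        dist_down = sno.interval.start - intron.start
    ctx = IntronContext(
        total_introns=total,
        intron_length=intron.length,
        rank_5p=rank_5p,
        rank_3p=rank_3p,
        relative_rank_3p=rank_3p / total,
        dist_upstream_exon=dist_up,
        dist_downstream_exon=dist_down,
        intron_interval=intron,
    )
    ctx.validate(sno.length)
    return ctx


def read_branchpoints(path: str | Path) -> pd.DataFrame:
    """Read a branchpoint TSV (chrom, pos 1-based, strand, intron_id,
    probability, source) into a frame with 0-based `pos`."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "pos", "strand", "intron_id", "probability", "source"],
        header=0,
    )
    df["pos"] = df["pos"].astype(int) - 1
    return df


def distance_to_branchpoint(
    sno: SnoRecord, branchpoints: pd.DataFrame | Sequence[tuple[int, float]]
) -> int | None:
    """Distance (non-negative magnitude) from the snoRNA 3' end to the
    highest-probability branchpoint of its intron.

    Probability ties break toward the nearer branchpoint. Empty set ->
    None (MISSING).
    """
    if isinstance(branchpoints, pd.DataFrame):
        entries = list(zip(branchpoints["pos"], branchpoints["probability"]))
    else:
        entries = list(branchpoints)
    if not entries:
        return None
    three_prime = (
        sno.interval.end - 1 if sno.interval.strand == "+" else sno.interval.start
    )
    best = min(entries, key=lambda e: (-e[1], abs(e[0] - three_prime)))
    return abs(best[0] - three_prime)


def extract_flanks(
    sno: SnoRecord,
    fasta: Fasta | str | Path,
    up_len: int = 15,
    down_len: int = 15,
) -> tuple[str, str]:
    """Genomic flanks of the snoRNA, 5'->3' in snoRNA orientation (RNA).

    On the minus strand the mirrored windows are reverse-complemented and
    swapped so that "upstream" is genic-upstream of the snoRNA 5' end.
    Flanks running off the chromosome edge are truncated with a warning.
    """
    genome = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    iv = sno.interval
    chrom_len = len(genome[iv.chrom])

    if iv.strand == "+":
        up_start, up_end = iv.start - up_len, iv.start
        down_start, down_end = iv.end, iv.end + down_len
    else:
        up_start, up_end = iv.end, iv.end + up_len
        down_start, down_end = iv.start - down_len, iv.start

    def _slice(s: int, e: int) -> str:
        cs, ce = max(0, s), min(chrom_len, e)
        if (cs, ce) != (s, e):
            logger.warning(
                "snoRNA %s flank truncated at chromosome edge (%d nt lost)",
                sno.id,
                (cs - s) + (e - ce),
            )
        return str(genome[iv.chrom][cs:ce]).upper() if cs < ce else ""

    up = _slice(up_start, up_end)
    down = _slice(down_start, down_end)
    if iv.strand == "-":
        up, down = reverse_complement(up), reverse_complement(down)
    return to_rna(up), to_rna(down)
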