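"""Genomic back-mapping, annotation overlap, and BED track export.

All internal coordinates are 0-based half-open on the forward genomic
strand.  GTF input (1-based, inclusive) is converted on read; BED output
stays 0-based half-open.

The central theorem of this module is round-trip fidelity: every genomic
locus reported for a peptide must retranslate (reverse-complemented for
minus-strand loci) to exactly the peptide's residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from intervaltree import IntervalTree

from .dbgen import NucleotideSequence, TranslatedEntry, reverse_complement, translate_frame
from .digest import Peptide


@dataclass(frozen=True, order=True)
class GenomicLocus:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    frame: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


# ------------------------------------------------------------- annotation


@dataclass
class _Transcript:
    chrom: str
    strand: str
    biotype: str
    exons: list  # [(start, end)] 0-based half-open, genomic order
    cds: list  # [(start, end)] genomic order; empty for non-coding


class AnnotationSet:
    """Exon/CDS/UTR intervals indexed for overlap and coordinate queries."""

    def __init__(self, records: list[tuple]):
        """records: (chrom, start, end, strand, feature, transcript_id, biotype),
        coordinates 0-based half-open."""
        self.transcripts: dict[str, _Transcript] = {}
        for chrom, start, end, strand, feature, tx_id, biotype in records:
            tx = self.transcripts.setdefault(tx_id, _Transcript(chrom, strand, biotype, [], []))
            if feature == "exon":
                tx.exons.append((start, end))
            elif feature == "CDS":
                tx.cds.append((start, end))
            # UTR features are implied by exon minus CDS; accepted but not stored
        for tx in self.transcripts.values():
            tx.exons.sort()
            tx.cds.sort()
        self._exon_tree: dict[str, IntervalTree] = {}
        self._span_tree: dict[str, IntervalTree] = {}
        for tx_id, tx in self.transcripts.items():
            if not tx.exons:
                continue
            et = self._exon_tree.setdefault(tx.chrom, IntervalTree())
            for s, e in tx.exons:
                et.addi(s, e, tx_id)
            span_s = min(s for s, _ in tx.exons)
            span_e = max(e for _, e in tx.exons)
            self._span_tree.setdefault(tx.chrom, IntervalTree()).addi(span_s, span_e, tx_id)

    # -- membership -----------------------------------------------------

    def has_transcript(self, tx_id: str) -> bool:
        return tx_id in self.transcripts

    def biotype(self, tx_id: str) -> str:
        return self.transcripts[tx_id].biotype

    def exons(self, tx_id: str) -> list:
        return list(self.transcripts[tx_id].exons)

    # -- coordinate mapping ---------------------------------------------

    def genomic_to_tx(self, tx_id: str, g: int) -> int:
        """Transcript coordinate of genomic position g (must lie in an exon)."""
        tx = self.transcripts[tx_id]
        if tx.strand == "+":
            off = 0
            for s, e in tx.exons:
                if s <= g < e:
                    return off + (g - s)
                off += e - s
        else:
            off = 0
            for s, e in reversed(tx.exons):
                if s <= g < e:
                    return off + (e - 1 - g)
                off += e - s
        raise ValueError(f"position {g} not exonic in {tx_id}")

    def transcript_cds_tx_interval(self, tx_id: str) -> tuple[int, int] | None:
        """CDS interval in transcript coordinates (half-open), or None."""
        tx = self.transcripts[tx_id]
        if not tx.cds:
            return None
        g5 = tx.cds[0][0] if tx.strand == "+" else tx.cds[-1][1] - 1
        g3 = tx.cds[-1][1] - 1 if tx.strand == "+" else tx.cds[0][0]
        t5 = self.genomic_to_tx(tx_id, g5)
        t3 = self.genomic_to_tx(tx_id, g3)
        return (t5, t3 + 1)

    # -- overlap queries -------------------------------------------------

    def overlaps_exon(self, locus: GenomicLocus) -> bool:
        tree = self._exon_tree.get(locus.chrom)
        return bool(tree and tree.overlap(locus.start, locus.end))

    def within_gene_span(self, locus: GenomicLocus) -> bool:
        tree = self._span_tree.get(locus.chrom)
        return bool(tree and tree.overlap(locus.start, locus.end))


def classify_locus(locus: GenomicLocus, ann: AnnotationSet) -> str:
    """'exonic' on >=1 bp exon overlap; else 'intronic' inside any gene span
    (either strand); else 'intergenic'."""
    if ann.overlaps_exon(locus):
        return "exonic"
    if ann.within_gene_span(locus):
        return "intronic"
    return "intergenic"


# ------------------------------------------------------------ GTF reading


def _gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path) -> list[tuple]:
    """GTF -> annotation records (0-based half-open).

    Keeps exon/CDS/UTR features; transcript_id and biotype pulled from the
    attribute column (gene_biotype or transcript_biotype, either spelling).
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, feature, start, end, _, strand, _, attr_text = f[:9]
            if feature not in ("exon", "CDS", "UTR", "five_prime_utr", "three_prime_utr"):
                continue
            attrs = _gtf_attributes(attr_text)
            biotype = (
                attrs.get("transcript_biotype")
                or attrs.get("transcript_type")
                or attrs.get("gene_biotype")
                or attrs.get("gene_type")
                or "protein_coding"
            )
            feat = "UTR" if feature.endswith("utr") else feature
            records.append(
                (chrom, int(start) - 1, int(end), strand, feat,
                 attrs.get("transcript_id", ""), biotype)
            )
    return records


def write_gtf(records: list[tuple], path, source: str = "pgmap") -> None:
    """Annotation records (0-based half-open) -> GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for chrom, start, end, strand, feature, tx_id, biotype in records:
            attrs = (
                f'gene_id "{tx_id}_g"; transcript_id "{tx_id}"; '
                f'transcript_biotype "{biotype}";'
            )
            fh.write(
                f"{chrom}\t{source}\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


# --------------------------------------------------------- peptide mapping


def map_peptide_to_loci(
    p: Peptide, entry: TranslatedEntry, chrom_lengths: dict[str, int]
) -> list[GenomicLocus]:
    """Project a genome-database peptide back onto chromosome coordinates.

    With a = entry.aa_offset + pep_offset codons from the frame start:
    plus strand  -> [frame + 3a, frame + 3a + 3L);
    minus strand -> the same arithmetic on the reverse complement, i.e.
    end = chrom_len - (frame + 3a), start = end - 3L.
    """
    if entry.source_kind != "genome":
        raise ValueError("only genome-database entries map directly to loci")
    clen = chrom_lengths[entry.source_id]
    a = entry.aa_offset + p.pep_offset
    span = 3 * len(p.residues)
    if entry.strand == "+":
        start = entry.frame + 3 * a
        end = start + span
    else:
        end = clen - (entry.frame + 3 * a)
        start = end - span
    if start < 0 or end > clen:
        raise AssertionError("mapped locus exceeds chromosome bounds")
    return [GenomicLocus(entry.source_id, start, end, entry.strand, entry.frame)]


def map_psm_loci(
    psm, entries_by_id: dict[str, TranslatedEntry], chrom_lengths: dict[str, int]
) -> list[GenomicLocus]:
    """All genomic loci of one PSM's peptide (one per genome-entry parent)."""
    loci = []
    for entry_id, pep_offset in psm.parents:
        entry = entries_by_id[entry_id]
        if entry.source_kind != "genome":
            continue
        pep = Peptide(psm.residues, psm.mono_mass, 0, entry_id, pep_offset)
        loci.extend(map_peptide_to_loci(pep, entry, chrom_lengths))
    return sorted(set(loci))


def retranslate_locus(locus: GenomicLocus, genome: dict[str, str]) -> str:
    """Amino-acid sequence encoded at a locus (strand-aware); the round-trip
    check for every mapped peptide."""
    seg = genome[locus.chrom][locus.start : locus.end]
    if locus.strand == "-":
        seg = reverse_complement(seg)
    return translate_frame(NucleotideSequence("_", seg), "+", 0)


def unique_filter(
    loci_by_peptide: dict[str, list[GenomicLocus]],
) -> tuple[dict[str, GenomicLocus], dict[str, list[GenomicLocus]]]:
    """Partition peptides into unique (exactly one genomic site) and
    multi-mapping."""
    unique, multi = {}, {}
    for pep, loci in loci_by_peptide.items():
        distinct = sorted(set(loci))
        if len(distinct) == 1:
            unique[pep] = distinct[0]
        else:
            multi[pep] = distinct
    return unique, multi


# -------------------------------------------------------- evidence tracks


def _track_trees(intervals: list[tuple]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, *_ in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def evidence_overlap(
    loci: list[GenomicLocus], tracks: dict[str, list[tuple]]
) -> dict:
    """Overlap tallies of loci against named evidence tracks.

    Returns per-track counts (loci overlapping >=1 interval of that track),
    the union-of-intersections count (loci with >=1 overlapping track) and
    the central-intersection count (loci overlapped by every track).
    """
    if not tracks:
        raise ValueError("at least one evidence track required")
    trees = {name: _track_trees(ivs) for name, ivs in tracks.items()}
    per_track = {name: 0 for name in tracks}
    union = central = 0
    for locus in loci:
        hits = 0
        for name, by_chrom in trees.items():
            tree = by_chrom.get(locus.chrom)
            if tree and tree.overlap(locus.start, locus.end):
                per_track[name] += 1
                hits += 1
        union += hits >= 1
        central += hits == len(tracks)
    return {"per_track": per_track, "union": union, "central": central}


# --------------------------------------------------------------- BED I/O


def bed_score(evalue: float) -> int:
    """Track display score: taller bar = more significant identification."""
    if evalue <= 0:
        return 1000
    return max(0, min(1000, round(-100.0 * math.log10(evalue))))


def write_bed(records: list[tuple], path) -> None:
    """records: (locus, peptide, rank, database, evalue) -> BED6 file."""
    rows = []
    for locus, peptide, rank, database, evalue in records:
        rows.append(
            (locus.chrom, locus.start, locus.end,
             f"{peptide}|{rank}|{database}", bed_score(evalue), locus.strand)
        )
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_bed(path) -> list[tuple]:
    """BED -> list of (chrom, start, end, name, score, strand); BED3 files
    get name='', score=0, strand='+'. """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else ""
            score = int(f[4]) if len(f) > 4 else 0
            strand = f[5] if len(f) > 5 else "+"
            out.append((chrom, start, end, name, score, strand))
    return out


def validate_bed6(path) -> None:
    """Strict structural check of a BED6 file; raises on any violation."""
    prev = None
    with open(path) as fh:
        for i, line in enumerate(fh):
            f = line.rstrip("\n").split("\t")
            if len(f) != 6:
                raise ValueError(f"line {i}: expected 6 tab-separated fields")
            chrom, start, end, name, score, strand = f
            if not chrom or " " in chrom:
                raise ValueError(f"line {i}: bad chrom {chrom!r}")
            s, e = int(start), int(end)
            if not (0 <= s < e):
                raise ValueError(f"line {i}: bad interval")
            if not (0 <= int(score) <= 1000):
                raise ValueError(f"line {i}: score out of range")
            if strand not in "+-":
                raise ValueError(f"line {i}: bad strand")
            key = (chrom, s, e, name)
            if prev is not None and key < prev:
                raise ValueError(f"line {i}: records not sorted")
            prev = key
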