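"""Genomic back-mapping, annotation classification, BED/GTF round trips."""

import numpy as np
import pytest

from pgmap.dbgen import NucleotideSequence, TranslatedEntry, build_genome_db, reverse_complement
from pgmap.digest import Peptide, peptide_monoisotopic_mass, tryptic_digest
from pgmap.genomics import (
    AnnotationSet,
    GenomicLocus,
    bed_score,
    classify_locus,
    evidence_overlap,
    map_peptide_to_loci,
    read_bed,
    read_gtf,
    retranslate_locus,
    unique_filter,
    validate_bed6,
    write_bed,
    write_gtf,
)


def _pep(seq, parent="e", off=0):
    return Peptide(seq, peptide_monoisotopic_mass(seq), 0, parent, off)


def _entry(strand, frame, aa_offset, source="chr1", kind="genome"):
    return TranslatedEntry("e", "MK", source, strand, frame, aa_offset, kind)


def test_plus_strand_mapping_arithmetic():
    locus, = map_peptide_to_loci(_pep("MK"), _entry("+", 0, 0), {"chr1": 12})
    assert (locus.start, locus.end, locus.strand) == (0, 6, "+")


def test_minus_strand_mapping_arithmetic():
    locus, = map_peptide_to_loci(_pep("MK"), _entry("-", 0, 0), {"chr1": 12})
    assert (locus.start, locus.end, locus.strand) == (6, 12, "-")


def test_mapping_rejects_non_genome_entries():
    with pytest.raises(ValueError):
        map_peptide_to_loci(_pep("MK"), _entry("+", 0, 0, kind="protein"), {"chr1": 12})


def test_round_trip_every_locus(rng):
    """Every peptide from a six-frame digest retranslates from its locus."""
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
    genome = {"chrR": seq}
    entries = build_genome_db([NucleotideSequence("chrR", seq)])
    checked = 0
    for e in entries:
        for p in tryptic_digest(e, max_missed=1, min_len=6, max_len=30):
            locus, = map_peptide_to_loci(p, e, {"chrR": len(seq)})
            assert retranslate_locus(locus, genome) == p.residues
            checked += 1
    assert checked > 50


def test_minus_strand_metamorphic(rng):
    """Minus-strand entries of S equal plus-strand entries of revcomp(S) with
    mirrored genomic coordinates."""
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 900)])
    L = len(seq)
    fwd = build_genome_db([NucleotideSequence("c", seq)])
    rev = build_genome_db([NucleotideSequence("c", reverse_complement(seq))])

    def loci(entries, strand):
        out = set()
        for e in entries:
            if e.strand != strand:
                continue
            for p in tryptic_digest(e, 0, 6, 30):
                locus, = map_peptide_to_loci(p, e, {"c": L})
                out.add((p.residues, locus.start, locus.end))
        return out

    minus_on_fwd = loci(fwd, "-")
    plus_on_rev = {(pep, L - e, L - s) for pep, s, e in loci(rev, "+")}
    assert minus_on_fwd == plus_on_rev


def test_unique_filter_partition():
    l1 = GenomicLocus("c", 0, 6, "+")
    l2 = GenomicLocus("c", 30, 36, "+")
    unique, multi = unique_filter({"AAAK": [l1], "CCCK": [l1, l2], "DDDK": [l1, l1]})
    assert set(unique) == {"AAAK", "DDDK"}  # duplicate sites collapse
    assert set(multi) == {"CCCK"}
    assert len(unique) + len(multi) == 3


THREE_EXON_GTF = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\ttest\tCDS\t151\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\ttest\tCDS\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\ttest\tCDS\t501\t550\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
"""


def test_gtf_three_exon_fixture(tmp_path):
    p = tmp_path / "ann.gtf"
    p.write_text(THREE_EXON_GTF)
    records = read_gtf(p)
    ann = AnnotationSet(records)
    # 1-based inclusive GTF -> 0-based half-open internal
    assert ann.exons("t1") == [(100, 200), (300, 400), (500, 600)]
    # CDS in transcript coordinates: 50 nt into exon 1, through exon 2,
    # 50 nt into exon 3 -> [50, 250) of the 300 nt transcript
    assert ann.transcript_cds_tx_interval("t1") == (50, 250)
    # genomic <-> transcript coordinate checks across the splice junction
    assert ann.genomic_to_tx("t1", 100) == 0
    assert ann.genomic_to_tx("t1", 300) == 100
    assert ann.genomic_to_tx("t1", 599) == 299
    # write back out and re-read: identical records
    out = tmp_path / "roundtrip.gtf"
    write_gtf(records, out)
    assert read_gtf(out) == records


def test_classify_locus_three_ways(tmp_path):
    p = tmp_path / "ann.gtf"
    p.write_text(THREE_EXON_GTF)
    ann = AnnotationSet(read_gtf(p))
    assert classify_locus(GenomicLocus("chr1", 110, 140, "+"), ann) == "exonic"
    assert classify_locus(GenomicLocus("chr1", 195, 205, "+"), ann) == "exonic"  # boundary
    assert classify_locus(GenomicLocus("chr1", 210, 240, "-"), ann) == "intronic"
    assert classify_locus(GenomicLocus("chr1", 900, 930, "+"), ann) == "intergenic"
    assert classify_locus(GenomicLocus("chr9", 10, 40, "+"), ann) == "intergenic"


def test_minus_strand_cds_tx_interval():
    records = [
        ("chr2", 100, 160, "-", "exon", "tm", "protein_coding"),
        ("chr2", 200, 260, "-", "exon", "tm", "protein_coding"),
        ("chr2", 130, 160, "-", "CDS", "tm", "protein_coding"),
        ("chr2", 200, 260, "-", "CDS", "tm", "protein_coding"),
    ]
    ann = AnnotationSet(records)
    # transcript runs 260->200 then 160->100; CDS covers first 60 then 30 more
    assert ann.transcript_cds_tx_interval("tm") == (0, 90)
    assert ann.genomic_to_tx("tm", 259) == 0
    assert ann.genomic_to_tx("tm", 159) == 60


def test_evidence_overlap_counts(rng):
    locus = GenomicLocus("c", 100, 130, "+")
    tracks = {
        "a": [("c", 90, 110)],
        "b": [("c", 120, 125)],
        "t": [("c", 500, 600)],
    }
    res = evidence_overlap([locus], tracks)
    assert res["per_track"] == {"a": 1, "b": 1, "t": 0}
    assert res["union"] == 1 and res["central"] == 0
    with pytest.raises(ValueError):
        evidence_overlap([locus], {})
    # quadratic oracle on random fixtures
    for _ in range(10):
        loci = [
            GenomicLocus("c", int(s), int(s) + int(rng.integers(5, 40)), "+")
            for s in rng.integers(0, 2000, 30)
        ]
        tracks = {
            name: [("c", int(s), int(s) + int(rng.integers(5, 60)))
                   for s in rng.integers(0, 2000, 15)]
            for name in ("t1", "t2", "t3")
        }
        res = evidence_overlap(loci, tracks)
        for name, ivs in tracks.items():
            brute = sum(
                1 for l in loci if any(l.start < e and s < l.end for _, s, e in ivs)
            )
            assert res["per_track"][name] == brute
        hits = [
            sum(any(l.start < e and s < l.end for _, s, e in ivs) for ivs in tracks.values())
            for l in loci
        ]
        assert res["union"] == sum(1 for h in hits if h >= 1)
        assert res["central"] == sum(1 for h in hits if h == len(tracks))


def test_bed_score_formula():
    assert bed_score(1e-4) == 400
    assert bed_score(1.0) == 0
    assert bed_score(10.0) == 0  # clamped at zero
    assert bed_score(1e-30) == 1000  # capped


def test_bed_write_validate_read(tmp_path):
    records = [
        (GenomicLocus("chr2", 50, 80, "-"), "CCCK", 1, "genome", 1e-3),
        (GenomicLocus("chr1", 10, 40, "+"), "AAAK", 1, "genome", 1e-4),
        (GenomicLocus("chr1", 10, 40, "+"), "AAAK", 2, "genome", 1e-2),
    ]
    path = tmp_path / "out.bed"
    write_bed(records, path)
    validate_bed6(path)
    rows = read_bed(path)
    assert rows[0] == ("chr1", 10, 40, "AAAK|1|genome", 400, "+")
    assert rows[1] == ("chr1", 10, 40, "AAAK|2|genome", 200, "+")
    assert rows[2] == ("chr2", 50, 80, "CCCK|1|genome", 300, "-")
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t40\t10\tx\t0\t+\n")
    with pytest.raises(ValueError):
        validate_bed6(bad)
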