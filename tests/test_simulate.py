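"""Synthetic-world generator: determinism, cross-consistency, noise model."""

import numpy as np
import pytest

from pgmap import pipeline, search, simulate
from pgmap.dbgen import reverse_complement
from pgmap.digest import peptide_monoisotopic_mass
from pgmap.scoring import fragment_mz_array
from pgmap.simulate import SimConfig, simulate_world, spectrum_from_peptide
from pgmap.spectra import neutral_mass


SMALL = dict(genome_length=100_000, n_genes=6)


def test_same_seed_reproduces_world_exactly():
    w1 = simulate_world(SimConfig(**SMALL, seed=7))
    w2 = simulate_world(SimConfig(**SMALL, seed=7))
    assert w1.genome == w2.genome
    assert w1.annotation_records == w2.annotation_records
    assert w1.truth_peptides.equals(w2.truth_peptides)
    assert all(
        np.array_equal(a.mz, b.mz) and a.precursor_mz == b.precursor_mz
        for a, b in zip(w1.spectra, w2.spectra)
    )
    w3 = simulate_world(SimConfig(**SMALL, seed=8))
    assert w1.genome != w3.genome


def test_genome_too_small_rejected():
    with pytest.raises(ValueError, match="genome too small"):
        simulate_world(SimConfig(genome_length=10_000, n_genes=20))


def test_transcripts_match_exon_extraction():
    """Spliced transcript equals exon concatenation pulled from the genome
    via the GTF, by an independent extractor."""
    w = simulate_world(SimConfig(**SMALL, seed=3))
    ann = w.annotation
    chrom_seq = w.genome[w.cfg.chrom_name]
    for t in w.transcripts:
        tx = ann.transcripts[t.id]
        pieces = [chrom_seq[s:e] for s, e in tx.exons]
        if tx.strand == "+":
            extracted = "".join(pieces)
        else:
            extracted = "".join(reverse_complement(p) for p in reversed(pieces))
        assert extracted == t.residues


def test_proteins_match_cds_translation():
    w = simulate_world(SimConfig(**SMALL, seed=3))
    ann = w.annotation
    proteins = dict(w.proteins)
    for t in w.transcripts:
        cds = ann.transcript_cds_tx_interval(t.id)
        if cds is None:
            continue
        from pgmap.dbgen import NucleotideSequence, translate_frame

        cds_nt = t.residues[cds[0] : cds[1]]
        prot = translate_frame(NucleotideSequence("x", cds_nt), "+", 0)
        assert prot == proteins[t.id.replace("_t", "_p")]


def test_truth_loci_retranslate_to_peptides():
    w = simulate_world(SimConfig(**SMALL, seed=3))
    chrom = w.genome[w.cfg.chrom_name]
    for row in w.truth_peptides.itertuples(index=False):
        seg = chrom[row.start : row.end]
        if row.strand == "-":
            seg = reverse_complement(seg)
        from pgmap.dbgen import NucleotideSequence, translate_frame

        assert translate_frame(NucleotideSequence("x", seg), "+", 0) == row.peptide


def test_truth_classes_match_annotation():
    w = simulate_world(SimConfig(**SMALL, seed=3))
    from pgmap.genomics import GenomicLocus, classify_locus

    ann = w.annotation
    for row in w.truth_peptides.itertuples(index=False):
        locus = GenomicLocus(row.chrom, row.start, row.end, row.strand)
        assert classify_locus(locus, ann) == row.genomic_class


def test_noise_free_spectrum_equals_theory():
    cfg = SimConfig(peak_dropout=0.0, mz_jitter_sd=0.0, precursor_jitter_sd=0.0,
                    n_noise_peaks=0)
    rng = np.random.default_rng(0)
    pep = "ACDEFGHIK"
    s = spectrum_from_peptide(pep, cfg, rng, "s")
    assert np.allclose(np.sort(s.mz), np.sort(fragment_mz_array(pep)), atol=1e-9)
    assert neutral_mass(s) == pytest.approx(peptide_monoisotopic_mass(pep), abs=1e-6)


def test_full_dropout_leaves_only_noise():
    cfg = SimConfig(peak_dropout=1.0, n_noise_peaks=5)
    rng = np.random.default_rng(0)
    s = spectrum_from_peptide("ACDEFGHIK", cfg, rng, "s")
    assert s.n_peaks == 5


def test_dropout_rate_binomial():
    cfg = SimConfig(peak_dropout=0.3, mz_jitter_sd=0.0, n_noise_peaks=0)
    rng = np.random.default_rng(42)
    pep = "ACDEFGHIKLMNQSTV"
    n_frag = len(fragment_mz_array(pep))
    kept = [spectrum_from_peptide(pep, cfg, rng, f"s{i}").n_peaks for i in range(500)]
    p_keep = np.mean(kept) / n_frag
    sigma = np.sqrt(0.3 * 0.7 / (500 * n_frag))
    assert abs(p_keep - 0.7) < 3 * sigma


def test_noise_free_world_end_to_end_rank1():
    """With no noise, every planted spectrum's rank-1 match is its peptide."""
    cfg = SimConfig(**SMALL, seed=9, peak_dropout=0.0, mz_jitter_sd=0.0,
                    precursor_jitter_sd=0.0, n_noise_peaks=0, frac_noise_spectra=0.0,
                    spectra_per_peptide=1)
    w = simulate_world(cfg)
    db = pipeline.build_database("genome", search.SearchConfig(), genome=w.genome_seqs)
    r = pipeline.run_search(w.spectra, db, search.SearchConfig())
    truth = dict(zip(w.truth_spectra.spectrum_id, w.truth_spectra.peptide))
    rank1 = {p.spectrum_id: p.residues for p in r.target_psms if p.rank == 1}
    assert rank1 and all(rank1[sid] == truth[sid] for sid in rank1)
    assert set(rank1) == set(truth)


def test_non_exonic_peptides_absent_from_protein_search(three_results, small_world):
    """Planted intergenic/intronic peptides surface only in the genome search."""
    tp = small_world.truth_peptides
    non_exonic = set(tp[tp.genomic_class != "exonic"].peptide)
    assert non_exonic
    genome_peps = {p.residues for p in three_results["genome"].identified}
    protein_peps = {p.residues for p in three_results["protein"].identified}
    assert non_exonic & genome_peps  # recovered by the genome search
    assert not (non_exonic & protein_peps)


def test_world_files_written(tmp_path):
    w = simulate_world(SimConfig(**SMALL, seed=2))
    paths = simulate.write_world(w, tmp_path)
    for p in paths.values():
        assert p.exists() and p.stat().st_size > 0
    from pgmap.dbgen import read_nt_fasta
    from pgmap.genomics import read_gtf
    from pgmap.spectra import read_mgf

    assert len(read_nt_fasta(paths["genome"])[0].residues) == w.cfg.genome_length
    assert len(read_mgf(paths["spectra"])) == len(w.spectra)
    assert read_gtf(paths["annotation"]) == sorted(w.annotation_records)
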