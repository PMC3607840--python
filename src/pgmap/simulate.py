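"""Synthetic proteogenomic test world with full ground truth.

The generator plants protein-coding and non-coding genes (with exon/intron
structure) on both strands of a random background genome, derives the
cross-consistent transcript and protein sets (transcript = spliced exon
concatenation, protein = translated CDS), plants additional tryptic ORFs in
intergenic and intronic space to exercise the non-exonic discovery
scenario, and emits noisy CID-style b/y-ion spectra for a sample of planted
peptides together with hard-null noise spectra whose precursor masses are
drawn from the planted mass distribution.

Every random draw comes from a named substream of one seed, in a fixed
order (background, gene content, planted ORFs, spectra), so adding a new
output never perturbs existing ones and the same seed reproduces the world
byte-for-byte.

Planted peptides are chosen so their coding context (one flanking codon on
each side) sits inside a single exon, which makes each of them discoverable
by the six-frame genome search; ground truth records where each peptide
lives, its genomic class (exonic / intronic / intergenic) and which
databases should contain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .dbgen import NucleotideSequence, TranslatedEntry, reverse_complement
from .digest import peptide_monoisotopic_mass, tryptic_digest
from .genomics import AnnotationSet, write_gtf
from .scoring import fragment_mz_array
from .spectra import Spectrum, mz_from_neutral, write_mgf

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_STOPS = sorted(_TABLE.stop_codons)
AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic world."""

    genome_length: int = 1_000_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 5)
    frac_noncoding: float = 0.2
    peptides_per_gene: int = 4
    spectra_per_peptide: int = 2
    peak_dropout: float = 0.2
    mz_jitter_sd: float = 0.1  # Th, fragment peaks
    precursor_jitter_sd: float = 0.003  # Da, neutral precursor mass
    n_noise_peaks: int = 5
    frac_noise_spectra: float = 0.1
    frac_intergenic: float = 0.15  # planted peptides placed in intergenic ORFs
    frac_intronic: float = 0.05  # planted peptides placed inside introns
    seed: int = 0
    chrom_name: str = "chrS1"

    def __post_init__(self):
        for name in ("frac_noncoding", "peak_dropout", "frac_noise_spectra",
                     "frac_intergenic", "frac_intronic"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class SimWorld:
    cfg: SimConfig
    genome: dict[str, str]
    transcripts: list[NucleotideSequence]
    proteins: list[tuple[str, str]]
    annotation_records: list[tuple]
    spectra: list[Spectrum]
    truth_peptides: pd.DataFrame
    truth_spectra: pd.DataFrame

    @property
    def genome_seqs(self) -> list[NucleotideSequence]:
        return [NucleotideSequence(c, s) for c, s in self.genome.items()]

    @property
    def annotation(self) -> AnnotationSet:
        return AnnotationSet(self.annotation_records)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


# ----------------------------------------------------------- gene pieces


def _random_nt(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _encode_protein(rng, protein: str) -> str:
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(0, len(_AA_TO_CODONS[aa]))] for aa in protein
    )


def _random_protein(rng, length: int) -> str:
    return "M" + "".join(np.array(list(AA20))[rng.integers(0, 20, length - 1)])


def _tryptic_orf_peptide(rng, min_len: int = 8, max_len: int = 20) -> str:
    """A peptide that tryptic digestion will excise from an R+pep+stop ORF:
    interior free of K/R, not starting with P, ending in K or R."""
    length = int(rng.integers(min_len, max_len + 1))
    interior = "ACDEFGHILMNQSTVWY"  # no K/R/P to keep cleavage unambiguous
    pep = "".join(np.array(list(interior))[rng.integers(0, len(interior), length - 1)])
    return pep + ("K" if rng.integers(0, 2) else "R")


def _orf_dna(rng, peptide: str) -> str:
    """R codon + peptide codons + stop: digesting the frame yields peptide."""
    return (
        _AA_TO_CODONS["R"][rng.integers(0, 6)]
        + _encode_protein(rng, peptide)
        + _STOPS[rng.integers(0, 3)]
    )


@dataclass
class _Gene:
    gene_id: str
    strand: str
    biotype: str
    transcript: str  # sense-strand mRNA
    exon_tx: list  # [(t0, t1)] transcript-space exon intervals
    cds_tx: tuple | None  # (start, end) transcript-space, stop excluded
    protein: str | None
    g_start: int = 0  # absolute genomic start of the gene block
    exon_g: list = field(default_factory=list)  # genomic exon intervals, genomic order


def _split_exons(rng, tx_len: int, n_exons: int, forbidden: tuple | None = None) -> list:
    """Transcript-space exon intervals; cuts avoid the forbidden zone."""
    allowed = [
        i for i in range(30, tx_len - 30)
        if forbidden is None or not (forbidden[0] <= i < forbidden[1])
    ]
    n_cuts = min(n_exons - 1, len(allowed))
    cuts = sorted(rng.choice(allowed, size=n_cuts, replace=False)) if n_cuts else []
    bounds = [0] + [int(c) for c in cuts] + [tx_len]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _gene_layout(rng, gene: _Gene) -> str:
    """Assemble the genomic block of a gene; fills gene.exon_g with
    block-relative genomic exon intervals (genomic left-to-right order)."""
    pieces = [gene.transcript[t0:t1] for t0, t1 in gene.exon_tx]
    introns = [_random_nt(rng, int(rng.integers(60, 301))) for _ in range(len(pieces) - 1)]
    if gene.strand == "-":
        pieces = [reverse_complement(p) for p in reversed(pieces)]
    block = []
    pos = 0
    exon_g = []
    for i, p in enumerate(pieces):
        exon_g.append((pos, pos + len(p)))
        block.append(p)
        pos += len(p)
        if i < len(introns):
            block.append(introns[i])
            pos += len(introns[i])
    gene.exon_g = exon_g
    return "".join(block)


def _tx_to_genomic(gene: _Gene, t0: int, t1: int) -> list[tuple[int, int]]:
    """Project a transcript-space interval through the exon structure."""
    exon_tx = gene.exon_tx
    n = len(exon_tx)
    out = []
    for k, (e0, e1) in enumerate(exon_tx):
        lo, hi = max(t0, e0), min(t1, e1)
        if lo >= hi:
            continue
        if gene.strand == "+":
            gs, ge = gene.exon_g[k]
            out.append((gene.g_start + gs + (lo - e0), gene.g_start + gs + (hi - e0)))
        else:
            gs, ge = gene.exon_g[n - 1 - k]  # tx exon k is genomic exon n-1-k
            out.append((gene.g_start + ge - (hi - e0), gene.g_start + ge - (lo - e0)))
    return sorted(out)


# ----------------------------------------------------------- spectra


def spectrum_from_peptide(
    residues: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    spectrum_id: str,
    charge: int | None = None,
) -> Spectrum:
    """Noisy CID-style spectrum: jittered b/y peaks with dropout + noise."""
    if len(residues) < 6:
        raise ValueError("peptide too short to simulate")
    mass = peptide_monoisotopic_mass(residues)
    if charge is None:
        charge = 2 if mass < 2400 else 3
    frag = np.sort(fragment_mz_array(residues))
    keep = rng.random(frag.size) >= cfg.peak_dropout
    mz = frag[keep] + rng.normal(0.0, cfg.mz_jitter_sd, int(keep.sum()))
    inten = rng.uniform(30.0, 100.0, mz.size)
    if cfg.n_noise_peaks:
        noise_mz = rng.uniform(100.0, mass, cfg.n_noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, rng.uniform(1.0, 30.0, cfg.n_noise_peaks)])
    if mz.size == 0:  # fully dropped, no noise requested: keep spectrum valid
        mz = np.array([mz_from_neutral(mass, charge)])
        inten = np.array([1.0])
    precursor = mz_from_neutral(mass + rng.normal(0.0, cfg.precursor_jitter_sd), charge)
    return Spectrum(spectrum_id, precursor, charge, mz, inten)


def _noise_spectrum(masses: np.ndarray, lengths: np.ndarray, cfg: SimConfig,
                    rng: np.random.Generator, spectrum_id: str) -> Spectrum:
    """Hard null: precursor near a planted mass, peaks uniform at random."""
    i = int(rng.integers(0, masses.size))
    mass = float(masses[i] + rng.normal(0.0, cfg.precursor_jitter_sd))
    charge = 2 if mass < 2400 else 3
    n_pk = max(1, round(2 * (int(lengths[i]) - 1) * (1 - cfg.peak_dropout)) + cfg.n_noise_peaks)
    mz = rng.uniform(100.0, mass, n_pk)
    inten = rng.uniform(1.0, 100.0, n_pk)
    return Spectrum(spectrum_id, mz_from_neutral(mass, charge), charge, mz, inten)


# ----------------------------------------------------------- world build


def simulate_world(cfg: SimConfig) -> SimWorld:
    ss = np.random.SeedSequence(cfg.seed)
    # fixed substream order: background, gene content, planted ORFs, spectra
    rng_bg, rng_gene, rng_orf, rng_spec = (np.random.default_rng(c) for c in ss.spawn(4))

    chrom = cfg.chrom_name
    genome = np.frombuffer(_random_nt(rng_bg, cfg.genome_length).encode(), dtype=np.uint8).copy()

    # ---- gene content -------------------------------------------------
    genes: list[_Gene] = []
    n_noncoding = round(cfg.n_genes * cfg.frac_noncoding)
    nc_orfs: list[tuple[str, str, tuple]] = []  # (gene_id, peptide, tx interval)
    for i in range(cfg.n_genes):
        strand = "+" if rng_gene.integers(0, 2) else "-"
        coding = i >= n_noncoding
        if coding:
            prot = _random_protein(rng_gene, int(rng_gene.integers(150, 301)))
            cds = _encode_protein(rng_gene, prot) + _STOPS[rng_gene.integers(0, 3)]
            u5 = _random_nt(rng_gene, int(rng_gene.integers(30, 91)))
            u3 = _random_nt(rng_gene, int(rng_gene.integers(50, 151)))
            tx = u5 + cds + u3
            cds_tx = (len(u5), len(u5) + 3 * len(prot))
            forbidden = None
            gene = _Gene(f"gene{i}", strand, "protein_coding", tx,
                         [], cds_tx, prot)
        else:
            tx = _random_nt(rng_gene, int(rng_gene.integers(400, 1001)))
            pep = _tryptic_orf_peptide(rng_gene)
            orf = _orf_dna(rng_gene, pep)
            pos = int(rng_gene.integers(40, len(tx) - len(orf) - 40))
            tx = tx[:pos] + orf + tx[pos + len(orf):]
            forbidden = (pos - 3, pos + len(orf) + 3)
            gene = _Gene(f"gene{i}", strand, "lincRNA", tx, [], None, None)
            nc_orfs.append((gene.gene_id, pep, (pos + 3, pos + 3 + 3 * len(pep))))
        n_ex = int(rng_gene.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        gene.exon_tx = _split_exons(rng_gene, len(gene.transcript), n_ex, forbidden)
        genes.append(gene)

    # ---- placement ----------------------------------------------------
    blocks = [_gene_layout(rng_gene, g) for g in genes]
    min_gap = 400
    needed = sum(len(b) for b in blocks) + (len(blocks) + 1) * min_gap + 20_000
    if needed > cfg.genome_length:
        raise ValueError(
            f"genome too small for {cfg.n_genes} genes: need >= {needed} bases"
        )
    cursor = 0
    for g, block in zip(genes, blocks):
        cursor += int(rng_gene.integers(min_gap, 2 * min_gap))
        g.g_start = cursor
        genome[cursor : cursor + len(block)] = np.frombuffer(block.encode(), dtype=np.uint8)
        cursor += len(block)
    tail_start = cursor + min_gap

    # ---- truth bookkeeping --------------------------------------------
    rows = []  # truth peptide rows
    seen: set[str] = set()

    def add_row(pep, origin, kind, start, end, strand, gclass, tx_id, in_prot, in_tx):
        if pep in seen:
            return False
        seen.add(pep)
        rows.append(dict(peptide=pep, origin=origin, kind=kind, chrom=chrom,
                         start=start, end=end, strand=strand, genomic_class=gclass,
                         transcript_id=tx_id, in_protein_db=in_prot,
                         in_transcript_db=in_tx,
                         mono_mass=peptide_monoisotopic_mass(pep)))
        return True

    # coding-gene peptides: tryptic, coding context inside a single exon
    for g in genes:
        if g.protein is None:
            continue
        entry = TranslatedEntry(g.gene_id, g.protein, g.gene_id, ".", -1, 0, "protein")
        cands = []
        for p in tryptic_digest(entry, max_missed=0, min_len=7, max_len=25):
            if p.pep_offset == 0:
                continue  # N-terminal peptide lacks a K/R context upstream
            t0 = g.cds_tx[0] + 3 * p.pep_offset
            t1 = t0 + 3 * len(p.residues)
            if any(e0 <= t0 - 3 and t1 + 3 <= e1 for e0, e1 in g.exon_tx):
                cands.append((p.residues, t0, t1))
        if not cands:
            continue
        pick = rng_orf.choice(len(cands), size=min(cfg.peptides_per_gene, len(cands)),
                              replace=False)
        for j in sorted(int(x) for x in pick):
            pep, t0, t1 = cands[j]
            (gs, ge), = _tx_to_genomic(g, t0, t1)
            add_row(pep, g.gene_id, "coding_exonic", gs, ge, g.strand, "exonic",
                    f"{g.gene_id}_t", True, True)

    # non-coding transcript ORF peptides (exonic in the genome)
    for gene_id, pep, (t0, t1) in nc_orfs:
        g = next(x for x in genes if x.gene_id == gene_id)
        spans = _tx_to_genomic(g, t0, t1)
        if len(spans) == 1:  # ORF embedded in one exon by construction
            (gs, ge), = spans
            add_row(pep, gene_id, "noncoding_exonic", gs, ge, g.strand, "exonic",
                    f"{gene_id}_t", False, True)

    # intergenic and intronic ORFs
    n_exonic_planted = len(rows)
    n_igr = max(1, round(cfg.frac_intergenic * n_exonic_planted)) if cfg.frac_intergenic else 0
    n_intr = max(1, round(cfg.frac_intronic * n_exonic_planted)) if cfg.frac_intronic else 0

    cursor = tail_start
    for k in range(n_igr):
        pep = _tryptic_orf_peptide(rng_orf)
        dna = _orf_dna(rng_orf, pep)
        strand = "+" if rng_orf.integers(0, 2) else "-"
        cursor += int(rng_orf.integers(200, 1000))
        if cursor + len(dna) > cfg.genome_length - 100:
            break
        planted = dna if strand == "+" else reverse_complement(dna)
        genome[cursor : cursor + len(dna)] = np.frombuffer(planted.encode(), dtype=np.uint8)
        add_row(pep, f"igr{k}", "intergenic_orf", cursor + 3, cursor + 3 + 3 * len(pep),
                strand, "intergenic", "", False, False)
        cursor += len(dna)

    introns = []  # (abs_start, abs_end) of intron intervals
    for g in genes:
        for (s0, e0), (s1, e1) in zip(g.exon_g, g.exon_g[1:]):
            introns.append((g.g_start + e0, g.g_start + s1))
    planted_intr = 0
    for k, (i0, i1) in enumerate(sorted(introns, key=lambda iv: iv[0] - iv[1])):
        if planted_intr >= n_intr:
            break
        pep = _tryptic_orf_peptide(rng_orf)
        dna = _orf_dna(rng_orf, pep)
        if i1 - i0 < len(dna) + 12:
            continue
        strand = "+" if rng_orf.integers(0, 2) else "-"
        pos = i0 + 6
        planted = dna if strand == "+" else reverse_complement(dna)
        genome[pos : pos + len(dna)] = np.frombuffer(planted.encode(), dtype=np.uint8)
        if add_row(pep, f"intron{k}", "intronic_orf", pos + 3, pos + 3 + 3 * len(pep),
                   strand, "intronic", "", False, False):
            planted_intr += 1

    truth_peptides = pd.DataFrame(rows)

    # ---- annotation ---------------------------------------------------
    ann_records = []
    for g in genes:
        tx_id = f"{g.gene_id}_t"
        for t0, t1 in g.exon_tx:
            for gs, ge in _tx_to_genomic(g, t0, t1):
                ann_records.append((chrom, gs, ge, g.strand, "exon", tx_id, g.biotype))
        if g.cds_tx:
            for gs, ge in _tx_to_genomic(g, *g.cds_tx):
                ann_records.append((chrom, gs, ge, g.strand, "CDS", tx_id, g.biotype))
            tx_len = len(g.transcript)
            for u0, u1 in ((0, g.cds_tx[0]), (g.cds_tx[1] + 3, tx_len)):
                if u1 > u0:
                    for gs, ge in _tx_to_genomic(g, u0, u1):
                        ann_records.append((chrom, gs, ge, g.strand, "UTR", tx_id, g.biotype))
    ann_records.sort()

    # ---- spectra -------------------------------------------------------
    spectra = []
    truth_rows = []
    masses = truth_peptides["mono_mass"].to_numpy()
    lengths = truth_peptides["peptide"].str.len().to_numpy()
    for i, pep in enumerate(truth_peptides["peptide"]):
        for j in range(cfg.spectra_per_peptide):
            sid = f"sim|pep{i}|{j}"
            spectra.append(spectrum_from_peptide(pep, cfg, rng_spec, sid))
            truth_rows.append(dict(spectrum_id=sid, peptide=pep, is_noise=False))
    n_signal = len(spectra)
    f = cfg.frac_noise_spectra
    n_noise = round(n_signal * f / (1 - f)) if f < 1 else 0
    for k in range(n_noise):
        sid = f"sim|noise{k}"
        spectra.append(_noise_spectrum(masses, lengths, cfg, rng_spec, sid))
        truth_rows.append(dict(spectrum_id=sid, peptide="", is_noise=True))

    genome_str = genome.tobytes().decode("ascii")
    transcripts = [NucleotideSequence(f"{g.gene_id}_t", g.transcript) for g in genes]
    proteins = [(f"{g.gene_id}_p", g.protein) for g in genes if g.protein]
    return SimWorld(
        cfg=cfg,
        genome={chrom: genome_str},
        transcripts=transcripts,
        proteins=proteins,
        annotation_records=ann_records,
        spectra=spectra,
        truth_peptides=truth_peptides,
        truth_spectra=pd.DataFrame(truth_rows),
    )


# --------------------------------------------- transcript-class fixture


def simulate_transcript_classes(
    n_frameshift: int, n_noncoding: int, n_utr: int, seed: int = 0
) -> tuple[dict, list[tuple]]:
    """Planted transcript-only peptides with known labels.

    Returns (peptides, annotation_records) where ``peptides`` maps each
    planted peptide to its transcript placements [(tx_id, frame, nt_start,
    nt_end)] as consumed by reconcile.classify_transcript_only, planted so
    the true label mix is exactly the requested one.  Single-exon
    transcripts on a toy chromosome keep the coordinate arithmetic
    transparent.
    """
    rng = np.random.default_rng(seed)
    peptides: dict[str, list] = {}
    records = []
    labels = (["frameshift"] * n_frameshift + ["noncoding_transcript"] * n_noncoding
              + ["utr_or_boundary"] * n_utr)
    g_cursor = 1000
    for i, label in enumerate(labels):
        tx_id = f"tx{i}"
        pep = _tryptic_orf_peptide(rng)
        while pep in peptides:
            pep = _tryptic_orf_peptide(rng)
        L = 3 * len(pep)
        tx_len = 600
        cds = (90, 390)  # frame 0 CDS on a coding transcript
        biotype = "lincRNA" if label == "noncoding_transcript" else "protein_coding"
        if label == "frameshift":
            frame = int(rng.integers(1, 3))
            nt_start = frame + 3 * int(rng.integers(40, 60))
        elif label == "noncoding_transcript":
            frame = 0
            nt_start = 3 * int(rng.integers(10, 100))
        else:  # in-frame but reaching the 5' UTR
            frame = cds[0] % 3
            nt_start = cds[0] - 3 * int(rng.integers(4, 10))
        placements = [(tx_id, frame, nt_start, nt_start + L)]
        peptides[pep] = placements
        records.append(("chrT", g_cursor, g_cursor + tx_len, "+", "exon", tx_id, biotype))
        if biotype == "protein_coding":
            records.append(("chrT", g_cursor + cds[0], g_cursor + cds[1], "+", "CDS",
                            tx_id, biotype))
        g_cursor += tx_len + 200
    return peptides, records


# ------------------------------------------------------- database inflation


def inflate_entries(entries: list[TranslatedEntry], factor: int, seed: int) -> list:
    """Pad a database with shuffled copies of its entries to ``factor`` times
    the original size, for database-size sensitivity experiments."""
    rng = np.random.default_rng(seed)
    out = list(entries)
    for rep in range(factor - 1):
        for e in entries:
            arr = np.array(list(e.residues))
            rng.shuffle(arr)
            out.append(
                TranslatedEntry(f"pad{rep}_{e.entry_id}", "".join(arr), e.source_id,
                                e.strand, e.frame, e.aa_offset, e.source_kind)
            )
    return out


# ------------------------------------------------------------- file output


def write_world(world: SimWorld, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "transcripts": outdir / "transcripts.fasta",
        "proteins": outdir / "proteins.fasta",
        "annotation": outdir / "annotation.gtf",
        "spectra": outdir / "spectra.mgf",
        "truth_peptides": outdir / "truth_peptides.tsv",
        "truth_spectra": outdir / "truth_spectra.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom, seq in world.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["transcripts"], "w") as fh:
        for t in world.transcripts:
            fh.write(f">{t.id}\n{t.residues}\n")
    with open(paths["proteins"], "w") as fh:
        for pid, seq in world.proteins:
            fh.write(f">{pid}\n{seq}\n")
    write_gtf(world.annotation_records, paths["annotation"])
    write_mgf(world.spectra, paths["spectra"])
    world.truth_peptides.to_csv(paths["truth_peptides"], sep="\t", index=False)
    world.truth_spectra.to_csv(paths["truth_spectra"], sep="\t", index=False)
    return paths
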