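"""End-to-end orchestration: build databases, search, filter, reconcile.

Thin glue over the per-stage modules so the CLI, the test suite and batch
scripts run the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import dbgen, digest, genomics, reconcile, search
from .dbgen import NucleotideSequence, TranslatedEntry
from .digest import MassIndex
from .search import FdrResult, PSM, SearchConfig
from .spectra import Spectrum


@dataclass
class Database:
    """Target + decoy mass indexes for one database kind."""

    kind: str  # genome | transcript | protein
    entries: list[TranslatedEntry]
    target_index: MassIndex
    decoy_index: MassIndex
    entries_by_id: dict[str, TranslatedEntry]


def build_database(kind: str, cfg: SearchConfig, *, genome=None, transcripts=None,
                   proteins=None, entries=None) -> Database:
    """Translate/digest one input set into searchable target+decoy indexes."""
    if entries is None:
        if kind == "genome":
            entries = dbgen.build_genome_db(genome)
        elif kind == "transcript":
            entries = dbgen.build_transcript_db(transcripts)
        elif kind == "protein":
            entries = dbgen.build_protein_db(proteins)
        else:
            raise ValueError(f"unknown database kind {kind!r}")
    decoys = dbgen.make_decoy(entries)
    kw = dict(max_missed=cfg.max_missed, min_len=cfg.min_len, max_len=cfg.max_len)
    target_index = MassIndex(digest.digest_database(entries, **kw))
    decoy_index = MassIndex(digest.digest_database(decoys, **kw))
    return Database(kind, entries, target_index, decoy_index,
                    {e.entry_id: e for e in entries})


@dataclass
class SearchResult:
    database: Database
    target_psms: list[PSM]
    decoy_psms: list[PSM]
    fdr: FdrResult
    identified: list[PSM]  # FDR-filtered target PSMs (all retained ranks)


def run_search(spectra: list[Spectrum], db: Database, cfg: SearchConfig) -> SearchResult:
    target = search.search_database(spectra, db.target_index, cfg, db.kind, False)
    decoy = search.search_database(spectra, db.decoy_index, cfg, db.kind, True)
    fdr = search.estimate_fdr_threshold(target, decoy, cfg.fdr)
    identified = search.filter_psms(target, fdr, cfg.max_rank)
    return SearchResult(db, target, decoy, fdr, identified)


def run_three_searches(
    spectra: list[Spectrum],
    genome: list[NucleotideSequence],
    transcripts: list[NucleotideSequence],
    proteins: list[tuple[str, str]],
    cfg: SearchConfig,
) -> dict[str, SearchResult]:
    out = {}
    for kind, kw in (("protein", {"proteins": proteins}),
                     ("transcript", {"transcripts": transcripts}),
                     ("genome", {"genome": genome})):
        db = build_database(kind, cfg, **kw)
        out[kind] = run_search(spectra, db, cfg)
    return out


def reconcile_results(results: dict[str, SearchResult]):
    psm_sets = {kind: r.identified for kind, r in results.items()}
    return reconcile.best_match_across(psm_sets)


def genome_loci_by_peptide(result: SearchResult, chrom_lengths: dict[str, int],
                           rank: int = 1) -> dict[str, list]:
    """Distinct genomic loci per identified peptide in a genome search."""
    loci: dict[str, list] = {}
    for p in result.identified:
        if p.rank > rank:
            continue
        loci.setdefault(p.residues, []).extend(
            genomics.map_psm_loci(p, result.database.entries_by_id, chrom_lengths)
        )
    return {pep: sorted(set(ls)) for pep, ls in loci.items()}


def bed_records(results: dict[str, SearchResult], chrom_lengths: dict[str, int]):
    """(locus, peptide, rank, database, evalue) rows for genomics.write_bed."""
    rows = []
    for kind, r in results.items():
        if kind != "genome":
            continue
        for p in r.identified:
            for locus in genomics.map_psm_loci(p, r.database.entries_by_id, chrom_lengths):
                rows.append((locus, p.residues, p.rank, kind, p.evalue))
    return rows
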