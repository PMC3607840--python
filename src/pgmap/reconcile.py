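"""Cross-database reconciliation: one best peptide per spectrum.

The three searches (protein, transcript, genome) are FDR-filtered
independently; a spectrum may then carry different rank-1 peptides in
different databases.  Reconciliation keeps, for each spectrum, only the
highest-scoring rank-1 peptide across databases: agreeing attributions are
all retained, conflicting lower-scoring ones are removed and tallied per
losing database.  Score ties go to the smaller, better-calibrated
database (protein > transcript > genome).
"""

from __future__ import annotations

from dataclasses import dataclass

from .search import PSM

#: tie-break priority: smaller database wins a score tie
DB_PRIORITY = {"protein": 0, "transcript": 1, "genome": 2}


@dataclass(frozen=True)
class ReconciledPSM:
    spectrum_id: str
    residues: str
    score: float
    evalue: float
    winning_database: str
    displaced_databases: tuple
    parents: tuple


def _priority(db: str) -> tuple:
    return (DB_PRIORITY.get(db, len(DB_PRIORITY)), db)


def best_match_across(
    psm_sets: dict[str, list[PSM]],
) -> tuple[list[ReconciledPSM], dict[str, int], dict[str, list[PSM]]]:
    """Resolve conflicting rank-1 identifications across databases.

    Returns (reconciled PSMs, per-database removal tally, per-database
    retained PSM lists).  A spectrum whose rank-1 peptides agree everywhere
    keeps all its attributions; a conflicted spectrum keeps only the
    highest-scoring database's PSMs, and each losing database's hit counts
    one removal.  Ranks 2-3 follow their database's rank-1 fate.
    """
    rank1: dict[str, dict[str, PSM]] = {}
    for db, psms in psm_sets.items():
        for p in psms:
            if p.rank == 1:
                rank1.setdefault(p.spectrum_id, {})[db] = p
    removals = {db: 0 for db in psm_sets}
    losing: dict[str, set] = {db: set() for db in psm_sets}  # spectrum ids removed
    reconciled = []
    for sid in sorted(rank1):
        by_db = rank1[sid]
        seqs = {p.residues for p in by_db.values()}
        win_db = min(by_db, key=lambda db: (-by_db[db].score, _priority(db)))
        win = by_db[win_db]
        if len(seqs) == 1:
            displaced = ()
        else:
            displaced = tuple(
                sorted(db for db in by_db if by_db[db].residues != win.residues)
            )
            for db in displaced:
                removals[db] += 1
                losing[db].add(sid)
        reconciled.append(
            ReconciledPSM(
                spectrum_id=sid,
                residues=win.residues,
                score=win.score,
                evalue=win.evalue,
                winning_database=win_db,
                displaced_databases=displaced,
                parents=win.parents,
            )
        )
    retained = {
        db: [p for p in psms if p.spectrum_id not in losing[db]]
        for db, psms in psm_sets.items()
    }
    return reconciled, removals, retained


def peptide_venn(psm_sets: dict[str, list[PSM]]) -> dict[str, set]:
    """Partition distinct rank-1 peptide sequences into the 7 Venn regions.

    Region keys are '&'-joined sorted database names, e.g. ``genome``,
    ``protein&transcript``, ``genome&protein&transcript``.
    """
    sets = {
        db: {p.residues for p in psms if p.rank == 1} for db, psms in psm_sets.items()
    }
    universe = set().union(*sets.values()) if sets else set()
    regions: dict[str, set] = {}
    for pep in universe:
        members = tuple(sorted(db for db, s in sets.items() if pep in s))
        regions.setdefault("&".join(members), set()).add(pep)
    return regions


def venn_counts(psm_sets: dict[str, list[PSM]]) -> dict[str, int]:
    return {k: len(v) for k, v in peptide_venn(psm_sets).items()}


# ------------------------------------------------ transcript-only triage

NONCODING_BIOTYPES = {"lincRNA", "noncoding", "non_coding", "antisense", "processed_transcript"}

#: classification precedence, most specific first
TRANSCRIPT_LABELS = ("frameshift", "noncoding_transcript", "utr_or_boundary", "unclassified")


def _classify_one(nt_start: int, nt_end: int, frame: int, biotype: str | None,
                  cds_tx: tuple[int, int] | None) -> str:
    if biotype is None:
        return "unclassified"
    if biotype in NONCODING_BIOTYPES or cds_tx is None:
        # no CDS on the parent transcript: translation of a non-coding RNA
        return "noncoding_transcript"
    cds_start, cds_end = cds_tx
    if frame != cds_start % 3:
        return "frameshift"
    if nt_start < cds_start or nt_end > cds_end:
        return "utr_or_boundary"
    return "unclassified"  # in-frame, fully inside the CDS


def classify_transcript_only(
    peptides: dict[str, list[tuple]],
    annotation,
) -> dict[str, str]:
    """Explain why a peptide was found only by the transcript search.

    ``peptides`` maps peptide sequence -> list of (transcript_id, frame,
    nt_start, nt_end) placements in transcript coordinates.  ``annotation``
    must expose ``biotype(tx_id)`` and ``transcript_cds_tx_interval(tx_id)``
    (genomics.AnnotationSet does).  Labels, in precedence order: a peptide
    translated in a different frame than the annotated CDS is a
    ``frameshift`` product; one on a transcript without coding annotation
    comes from a ``noncoding_transcript``; an in-frame peptide reaching
    outside the CDS is ``utr_or_boundary``.  Transcripts absent from the
    annotation yield ``unclassified``.
    """
    out = {}
    for pep, placements in peptides.items():
        labels = []
        for tx_id, frame, nt_start, nt_end in placements:
            if not annotation.has_transcript(tx_id):
                labels.append("unclassified")
                continue
            labels.append(
                _classify_one(
                    nt_start,
                    nt_end,
                    frame,
                    annotation.biotype(tx_id),
                    annotation.transcript_cds_tx_interval(tx_id),
                )
            )
        out[pep] = min(labels, key=TRANSCRIPT_LABELS.index) if labels else "unclassified"
    return out
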