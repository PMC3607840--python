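"""Per-database search driver: candidate retrieval, scoring, ranking, FDR.

For each spectrum, candidates are pulled from the mass index within the
precursor tolerance around the neutral precursor mass (0.02 Da by default),
scored, and the top-ranked peptide-spectrum matches retained.  Identical
sequences reaching a spectrum from different parent entries collapse to a
single PSM carrying every parent reference, so locus multiplicity survives.

Target and decoy databases are searched separately with identical
configuration; the E-value threshold for a requested FDR is the largest
threshold at which decoy passes / target passes stays at or below the
requested rate (computed on rank-1 PSMs; lower ranks inherit the
threshold).  Thresholds are estimated per database, because databases of
very different size produce very different score null distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digest import MassIndex, Peptide
from .scoring import SCORERS, fit_evalue
from .spectra import Spectrum, neutral_mass

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    precursor_tol: float = 0.02  # Da, on neutral monoisotopic mass
    fragment_tol: float = 0.5  # Da
    max_missed: int = 1
    max_rank: int = 3
    fdr: float = 0.01
    min_len: int = 6
    max_len: int = 50
    charge_cap: int = 1
    scorer: str = "binomial"
    # E-value null model: widen the candidate window (calibration only)
    # until enough scores are available for a stable tail fit.
    min_candidates: int = 20
    calib_target: int = 128  # widen until this many calibration scores
    calib_tol: float = 1.0  # Da, initial widened half-window
    calib_cap: int = 256  # even subsample cap on calibration candidates

    def __post_init__(self):
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0,1)")
        for name in ("precursor_tol", "fragment_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match within a database search."""

    spectrum_id: str
    residues: str
    mono_mass: float
    score: float
    evalue: float
    rank: int
    database: str
    is_decoy: bool
    parents: tuple  # ((entry_id, pep_offset), ...) every co-located parent


@dataclass(frozen=True)
class FdrResult:
    evalue_threshold: float
    n_target_pass: int
    n_decoy_pass: int
    achieved_fdr: float
    requested_fdr: float


def _collapse_by_sequence(cands: list[Peptide]) -> dict[str, tuple]:
    """sequence -> ((entry,offset), ...) with deterministic parent order."""
    by_seq: dict[str, list] = {}
    for p in cands:
        by_seq.setdefault(p.residues, []).append((p.parent_entry, p.pep_offset))
    return {seq: tuple(sorted(parents)) for seq, parents in by_seq.items()}


def _calibration_sequences(index: MassIndex, m: float, cfg: SearchConfig,
                           have: dict[str, tuple]) -> list[str]:
    """Extra unique sequences from a widened mass window, for the null fit.

    The window doubles until it holds ``calib_target`` distinct sequences
    or spans the whole index, then the sequences are even-subsampled to
    ``calib_cap``; everything is deterministic for fixed inputs.
    """
    tol = cfg.calib_tol
    seqs: list[str] = []
    while True:
        wide = index.query_mass(m, tol)
        seqs = sorted({p.residues for p in wide} - set(have))
        if len(seqs) >= cfg.calib_target or len(wide) >= len(index):
            break
        tol *= 2.0
    if len(seqs) > cfg.calib_cap:
        step = len(seqs) / cfg.calib_cap
        seqs = [seqs[int(i * step)] for i in range(cfg.calib_cap)]
    return seqs


def search_database(
    spectra: list[Spectrum],
    index: MassIndex,
    cfg: SearchConfig,
    database: str,
    is_decoy: bool = False,
) -> list[PSM]:
    """Score every spectrum against its mass-window candidates.

    Returns the top ``cfg.max_rank`` PSMs per spectrum with ranks assigned
    by descending score (ties broken lexicographically on sequence).
    Spectra with no candidate in the window produce no PSM and are counted
    in the run log.
    """
    scorer = SCORERS[cfg.scorer]
    psms: list[PSM] = []
    n_empty = 0
    for s in spectra:
        m = neutral_mass(s)
        cands = index.query_mass(m, cfg.precursor_tol)
        if not cands:
            n_empty += 1
            continue
        by_seq = _collapse_by_sequence(cands)
        mass_of = {p.residues: p.mono_mass for p in cands}
        scored = {
            seq: scorer(s, seq, cfg.fragment_tol, cfg.charge_cap) for seq in by_seq
        }
        calib_scores = list(scored.values())
        if len(calib_scores) < cfg.calib_target:
            for seq in _calibration_sequences(index, m, cfg, by_seq):
                calib_scores.append(scorer(s, seq, cfg.fragment_tol, cfg.charge_cap))
        ranked = sorted(by_seq, key=lambda seq: (-scored[seq], seq))
        for rank, seq in enumerate(ranked[: cfg.max_rank], start=1):
            psms.append(
                PSM(
                    spectrum_id=s.spectrum_id,
                    residues=seq,
                    mono_mass=mass_of[seq],
                    score=scored[seq],
                    evalue=fit_evalue(calib_scores, scored[seq], cfg.min_candidates),
                    rank=rank,
                    database=database,
                    is_decoy=is_decoy,
                    parents=by_seq[seq],
                )
            )
    if n_empty:
        log.info("%s search: %d/%d spectra had no candidate in the precursor window",
                 database, n_empty, len(spectra))
    return collapse_charge_trials(psms)


def collapse_charge_trials(psms: list[PSM]) -> list[PSM]:
    """Keep the better-scoring trial charge for spectra searched at several.

    Trial-charge spectra carry ids like ``title/z2``; for each base title
    only the charge whose rank-1 score is highest is retained (ties: lower
    charge wins), and its ids are rewritten to the base title.
    """
    trials: dict[str, list[PSM]] = {}
    out = []
    for p in psms:
        base, sep, z = p.spectrum_id.rpartition("/z")
        if sep and z.isdigit():
            trials.setdefault(base, []).append(p)
        else:
            out.append(p)
    for base, group in sorted(trials.items()):
        best_of = {}
        for p in group:
            z = int(p.spectrum_id.rpartition("/z")[2])
            if p.rank == 1:
                cur = best_of.get("best")
                if cur is None or (-p.score, z) < (-cur[0].score, cur[1]):
                    best_of["best"] = (p, z)
        if "best" not in best_of:
            continue
        win_z = best_of["best"][1]
        for p in group:
            if int(p.spectrum_id.rpartition("/z")[2]) == win_z:
                out.append(
                    PSM(base, p.residues, p.mono_mass, p.score, p.evalue,
                        p.rank, p.database, p.is_decoy, p.parents)
                )
    return out


def estimate_fdr_threshold(
    target_psms: list[PSM], decoy_psms: list[PSM], fdr: float
) -> FdrResult:
    """Largest E-value threshold with decoy/target pass ratio <= fdr.

    Computed on rank-1 PSMs only.  E-value ties at the threshold are
    resolved conservatively: a decoy tied at the threshold counts against
    it, so the threshold tightens.
    """
    t_ev = np.sort([p.evalue for p in target_psms if p.rank == 1])
    d_ev = np.sort([p.evalue for p in decoy_psms if p.rank == 1])
    if t_ev.size == 0:
        raise ValueError("no target rank-1 PSMs; cannot estimate an FDR threshold")
    if d_ev.size == 0:
        thr = float(t_ev[-1])
        return FdrResult(thr, int(t_ev.size), 0, 0.0, fdr)
    best = None
    for t in np.unique(t_ev):
        n_t = int(np.searchsorted(t_ev, t, side="right"))
        n_d = int(np.searchsorted(d_ev, t, side="right"))
        rate = n_d / n_t
        if rate <= fdr:
            best = (float(t), n_t, n_d, rate)
    if best is None:
        return FdrResult(0.0, 0, 0, 0.0, fdr)
    return FdrResult(best[0], best[1], best[2], best[3], fdr)


def filter_psms(psms: list[PSM], result: FdrResult, max_rank: int = 3) -> list[PSM]:
    """PSMs identified at the estimated threshold (lower ranks inherit it)."""
    return [p for p in psms if p.rank <= max_rank and p.evalue <= result.evalue_threshold]


def run_report(psms_by_db: dict[str, list[PSM]]) -> pd.DataFrame:
    """Distinct spectrum / peptide / parent counts per database."""
    rows = []
    for db, psms in psms_by_db.items():
        rank1 = [p for p in psms if p.rank == 1]
        rows.append(
            {
                "database": db,
                "n_spectra": len({p.spectrum_id for p in rank1}),
                "n_peptides": len({p.residues for p in rank1}),
                "n_parents": len({e for p in rank1 for e, _ in p.parents}),
            }
        )
    return pd.DataFrame(rows)


def psm_table(psms: list[PSM]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "peptide": [p.residues for p in psms],
            "mono_mass": [p.mono_mass for p in psms],
            "score": [p.score for p in psms],
            "evalue": [p.evalue for p in psms],
            "rank": [p.rank for p in psms],
            "database": [p.database for p in psms],
            "is_decoy": [p.is_decoy for p in psms],
            "parents": [";".join(f"{e}@{o}" for e, o in p.parents) for p in psms],
        }
    )
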