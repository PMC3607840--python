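"""Best-match-per-spectrum reconciliation and peptide set comparisons."""

import numpy as np

from pgmap.reconcile import (
    best_match_across,
    classify_transcript_only,
    peptide_venn,
    venn_counts,
)
from pgmap.genomics import AnnotationSet
from pgmap.search import PSM
from pgmap.simulate import simulate_transcript_classes


def _psm(sid, pep, score, db, rank=1):
    return PSM(sid, pep, 800.0, score, 10.0 ** -score, rank, db, False, (("e", 0),))


def test_agreeing_spectrum_kept_everywhere():
    sets = {
        "protein": [_psm("s1", "AAAK", 10, "protein")],
        "transcript": [_psm("s1", "AAAK", 9, "transcript")],
        "genome": [_psm("s1", "AAAK", 8, "genome")],
    }
    rec, removals, retained = best_match_across(sets)
    assert len(rec) == 1 and rec[0].displaced_databases == ()
    assert removals == {"protein": 0, "transcript": 0, "genome": 0}
    assert all(len(v) == 1 for v in retained.values())


def test_conflict_removes_lower_scoring_database():
    sets = {
        "protein": [_psm("s1", "AAAK", 10, "protein")],
        "genome": [_psm("s1", "CCCK", 12, "genome")],
    }
    rec, removals, retained = best_match_across(sets)
    assert rec[0].winning_database == "genome"
    assert rec[0].residues == "CCCK"
    assert removals == {"protein": 1, "genome": 0}
    assert retained["protein"] == [] and len(retained["genome"]) == 1


def test_score_tie_prefers_smaller_database():
    sets = {
        "protein": [_psm("s1", "AAAK", 10, "protein")],
        "genome": [_psm("s1", "CCCK", 10, "genome")],
    }
    rec, _, _ = best_match_across(sets)
    assert rec[0].winning_database == "protein"


def test_reconciliation_set_arithmetic_oracle(rng):
    """Totals agree with brute-force set arithmetic on random fixtures."""
    dbs = ["protein", "transcript", "genome"]
    peps = ["AAAK", "CCCK", "DDDK", "EEEK"]
    for trial in range(20):
        sets = {db: [] for db in dbs}
        spectra = [f"s{i}" for i in range(15)]
        truth = {}
        for sid in spectra:
            for db in dbs:
                if rng.random() < 0.7:
                    pep = peps[rng.integers(0, len(peps))]
                    score = float(np.round(rng.uniform(1, 20), 3))
                    sets[db].append(_psm(sid, pep, score, db))
                    truth.setdefault(sid, []).append((db, pep, score))
        rec, removals, retained = best_match_across(sets)
        conflicted = {
            sid for sid, hits in truth.items() if len({p for _, p, _ in hits}) > 1
        }
        # total removals equals the number of losing (spectrum, database) hits
        expect_removed = sum(
            sum(1 for db, p, s in hits if p != max(hits, key=lambda h: h[2])[1])
            for sid, hits in truth.items()
            if sid in conflicted
        )
        assert sum(removals.values()) == expect_removed
        for db in dbs:
            pre = {p.spectrum_id for p in sets[db]}
            post = {p.spectrum_id for p in retained[db]}
            assert len(post) == len(pre) - removals[db]
        # every spectrum appears once with the maximal score across databases
        assert len(rec) == len(truth)
        for r in rec:
            assert r.score == max(s for _, _, s in truth[r.spectrum_id])


def test_venn_regions():
    sets = {
        "protein": [_psm("s1", "AAAK", 5, "protein"), _psm("s2", "BBBK", 5, "protein")],
        "transcript": [_psm("s3", "AAAK", 5, "transcript")],
        "genome": [_psm("s4", "GGGK", 5, "genome")],
    }
    counts = venn_counts(sets)
    assert counts == {"protein": 1, "protein&transcript": 1, "genome": 1}
    regions = peptide_venn(sets)
    assert regions["genome"] == {"GGGK"}
    total = sum(counts.values())
    union = {p.residues for psms in sets.values() for p in psms}
    assert total == len(union)


def test_venn_matches_set_oracle(rng):
    peps = [f"PEP{i}K" for i in range(8)]
    for _ in range(10):
        sets = {}
        raw = {}
        for db in ("protein", "transcript", "genome"):
            chosen = {p for p in peps if rng.random() < 0.5}
            raw[db] = chosen
            sets[db] = [_psm(f"{db}{i}", p, 5, db) for i, p in enumerate(sorted(chosen))]
        counts = venn_counts(sets)
        for pep in set().union(*raw.values()):
            key = "&".join(sorted(db for db in raw if pep in raw[db]))
            assert pep in peptide_venn(sets)[key]
        assert sum(counts.values()) == len(set().union(*raw.values()))


# ---------------------------------------------- transcript-only classes


def _toy_annotation():
    # single-exon coding transcript: exon [0,600), CDS genomic [1090,1390)
    records = [
        ("chrT", 1000, 1600, "+", "exon", "txc", "protein_coding"),
        ("chrT", 1090, 1390, "+", "CDS", "txc", "protein_coding"),
        ("chrT", 2000, 2600, "+", "exon", "txn", "lincRNA"),
    ]
    return AnnotationSet(records)


def test_classify_rules():
    ann = _toy_annotation()
    # CDS starts at transcript position 90 -> frame 0
    out = classify_transcript_only(
        {
            "FRAMEK": [("txc", 1, 121, 151)],  # translated frame 1 != CDS frame 0
            "NONCOK": [("txn", 0, 30, 60)],
            "UTRPEK": [("txc", 0, 60, 120)],  # in-frame, reaches 5' UTR
            "LOSTPK": [("missing", 0, 0, 30)],
        },
        ann,
    )
    assert out == {
        "FRAMEK": "frameshift",
        "NONCOK": "noncoding_transcript",
        "UTRPEK": "utr_or_boundary",
        "LOSTPK": "unclassified",
    }


def test_planted_class_mix_recovered_exactly():
    """Generator-planted 5/20/75% label mix comes back exactly."""
    n_fs, n_nc, n_utr = 4, 16, 60
    peptides, records = simulate_transcript_classes(n_fs, n_nc, n_utr, seed=5)
    ann = AnnotationSet(records)
    labels = classify_transcript_only(peptides, ann)
    counts = {}
    for lab in labels.values():
        counts[lab] = counts.get(lab, 0) + 1
    assert counts == {
        "frameshift": n_fs,
        "noncoding_transcript": n_nc,
        "utr_or_boundary": n_utr,
    }


def test_combined_spectra_not_fewer_than_single_db(three_results):
    psm_sets = {k: r.identified for k, r in three_results.items()}
    rec, _, _ = best_match_across(psm_sets)
    combined = {r.spectrum_id for r in rec}
    for k, res in three_results.items():
        assert len(combined) >= len({p.spectrum_id for p in res.identified})
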