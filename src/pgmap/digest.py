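"""In-silico tryptic digestion and the mass-ordered candidate index.

Trypsin cleaves after K or R; by default a cleavage is suppressed when the
following residue is proline (standard specificity, configurable).  Products
with up to ``max_missed`` internal uncut K/R sites and length within
[min_len, max_len] become search candidates.  Monoisotopic masses come from
the pyteomics residue table plus one water.

Duplicate peptide sequences from distinct parent entries are deliberately
kept apart so that genomic locus multiplicity stays recoverable; sequence
level deduplication happens only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics import mass as _pmass

from .dbgen import TranslatedEntry

WATER = _pmass.calculate_mass(formula="H2O")  # 18.0105646837 Da
PROTON = _pmass.nist_mass["H+"][0][0]  # 1.00727646677 Da

# monoisotopic residue masses, 20 standard amino acids
RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

_MASS_ARR = np.zeros(128)
for _aa, _m in RESIDUE_MASS.items():
    _MASS_ARR[ord(_aa)] = _m


@dataclass(frozen=True)
class Peptide:
    """A digestion product tied to its parent entry by residue offset."""

    residues: str
    mono_mass: float
    missed_cleavages: int
    parent_entry: str
    pep_offset: int

    def __len__(self) -> int:
        return len(self.residues)


def peptide_monoisotopic_mass(residues: str) -> float:
    """Neutral monoisotopic mass: sum of residue masses + one water."""
    if not residues:
        raise ValueError("empty peptide")
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    masses = _MASS_ARR[arr]
    if (masses == 0).any():
        bad = sorted(set(residues) - set(RESIDUE_MASS))
        raise ValueError(f"unknown residues {bad!r}")
    return float(masses.sum() + WATER)


def cleavage_sites(residues: str, proline_rule: bool = True) -> list[int]:
    """Positions i such that trypsin cuts between residues i-1 and i."""
    sites = []
    for i in range(1, len(residues)):
        if residues[i - 1] in "KR" and not (proline_rule and residues[i] == "P"):
            sites.append(i)
    return sites


def tryptic_digest(
    entry: TranslatedEntry,
    max_missed: int = 1,
    min_len: int = 6,
    max_len: int = 50,
    proline_rule: bool = True,
) -> list[Peptide]:
    """All tryptic products of one entry with 0..max_missed internal sites.

    Peptides containing 'X' never arise here because entries are stop/X-split
    upstream; the length filter is applied after enumeration.
    """
    res = entry.residues
    bounds = [0] + cleavage_sites(res, proline_rule) + [len(res)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(bounds))):
            start, end = bounds[i], bounds[j]
            if not (min_len <= end - start <= max_len):
                continue
            pep = res[start:end]
            peptides.append(
                Peptide(
                    residues=pep,
                    mono_mass=peptide_monoisotopic_mass(pep),
                    missed_cleavages=j - i - 1,
                    parent_entry=entry.entry_id,
                    pep_offset=start,
                )
            )
    return peptides


def digest_database(
    entries: list[TranslatedEntry],
    max_missed: int = 1,
    min_len: int = 6,
    max_len: int = 50,
    proline_rule: bool = True,
) -> list[Peptide]:
    out = []
    for e in entries:
        out.extend(tryptic_digest(e, max_missed, min_len, max_len, proline_rule))
    return out


class MassIndex:
    """Mass-sorted peptide candidate index with O(log n) range query.

    Duplicate sequences from distinct parents are all retained.
    """

    def __init__(self, peptides: list[Peptide]):
        order = np.argsort([p.mono_mass for p in peptides], kind="stable")
        self.peptides = [peptides[i] for i in order]
        self.masses = np.array([p.mono_mass for p in self.peptides])

    def __len__(self) -> int:
        return len(self.peptides)

    def query_range(self, lo: float, hi: float) -> list[Peptide]:
        """All peptides with lo <= mass <= hi."""
        i = int(np.searchsorted(self.masses, lo, side="left"))
        j = int(np.searchsorted(self.masses, hi, side="right"))
        return self.peptides[i:j]

    def query_mass(self, m: float, tol: float) -> list[Peptide]:
        return self.query_range(m - tol, m + tol)


def dump_digest_tsv(peptides: list[Peptide], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tmono_mass\tmissed_cleavages\tparent_entry\tpep_offset\n")
        for p in peptides:
            fh.write(
                f"{p.residues}\t{p.mono_mass:.6f}\t{p.missed_cleavages}\t"
                f"{p.parent_entry}\t{p.pep_offset}\n"
            )
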