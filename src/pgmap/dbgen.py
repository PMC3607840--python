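"""Target and decoy protein-space database construction.

A genome is translated in all six reading frames (three codon offsets on
each strand), a transcript set in the three forward frames, and a protein
FASTA is taken as-is.  Each stop codon ends one searchable entry and the
next entry begins after it, so a frame translation is split into maximal
stop-free fragments.  Every entry carries full provenance (source sequence,
strand, frame, offset in the frame translation) so that an identified
peptide can later be projected back onto genomic coordinates.

Decoy databases are built by reversing each target entry, which preserves
entry count, length distribution and amino-acid composition.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

VALID_NT = set("ACGTN")
# 20 standard residues; 'X' marks an untranslatable (N-containing) codon.
AA20 = set("ACDEFGHIKLMNPQRSTVWY")

_BASE_ORD = np.full(256, 4, dtype=np.int8)  # everything unknown -> N slot
for _i, _b in enumerate("ACGT"):
    _BASE_ORD[ord(_b)] = _i


def _codon_lookup() -> np.ndarray:
    """64-entry codon -> amino-acid byte table (standard genetic code)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    lut = np.zeros(64, dtype=np.uint8)
    bases = "ACGT"
    for i, a in enumerate(bases):
        for j, b in enumerate(bases):
            for k, c in enumerate(bases):
                codon = a + b + c
                aa = "*" if codon in table.stop_codons else table.forward_table[codon]
                lut[16 * i + 4 * j + k] = ord(aa)
    return lut


_CODON_LUT = _codon_lookup()

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence over the A/C/G/T/N alphabet."""

    id: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues) - VALID_NT
        if bad:
            raise ValueError(f"{self.id}: invalid nucleotide symbols {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TranslatedEntry:
    """One stop-free protein-space entry with coordinate provenance.

    ``aa_offset`` is the index of the entry's first residue within the full
    translation of its frame (codons counted from the frame start), the
    quantity needed to project peptides back onto the source sequence.
    """

    entry_id: str
    residues: str
    source_id: str
    strand: str  # '+', '-', or '.' for protein input
    frame: int  # 0-2; -1 for protein input
    aa_offset: int
    source_kind: str  # genome | transcript | protein
    is_decoy: bool = False


def reverse_complement(residues: str) -> str:
    return residues.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


def normalize_nt(residues: str) -> str:
    """Uppercase, map U->T; common FASTA dialect tolerance."""
    return residues.upper().replace("U", "T")


def translate_frame(seq: NucleotideSequence, strand: str, frame: int) -> str:
    """Translate one reading frame to amino acids, '*' for stops, 'X' for N codons.

    On the minus strand the frame offset is counted from the start of the
    reverse complement (this convention is the contract the genomic
    back-mapping relies on).
    """
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    if frame not in (0, 1, 2):
        raise ValueError(f"invalid frame {frame!r}")
    residues = seq.residues if strand == "+" else reverse_complement(seq.residues)
    codes = _BASE_ORD[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    n_codons = (len(codes) - frame) // 3
    if n_codons <= 0:
        return ""
    tri = codes[frame : frame + 3 * n_codons].reshape(n_codons, 3)
    has_n = (tri == 4).any(axis=1)
    idx = tri[:, 0].astype(np.int32) * 16 + tri[:, 1] * 4 + tri[:, 2]
    idx[has_n] = 0  # any valid slot; overwritten below
    aa = _CODON_LUT[idx]
    aa[has_n] = ord("X")
    return aa.tobytes().decode("ascii")


_FRAGMENT_RE = re.compile(r"[^*X]+")


def stop_split(translation: str) -> list[tuple[int, str]]:
    """Split a frame translation on '*' and 'X' into (aa_offset, fragment) pairs."""
    return [(m.start(), m.group()) for m in _FRAGMENT_RE.finditer(translation)]


def _frame_entries(seq: NucleotideSequence, strand: str, frame: int, kind: str) -> list[TranslatedEntry]:
    entries = []
    for off, frag in stop_split(translate_frame(seq, strand, frame)):
        entry_id = f"{seq.id}|{strand}{frame}|{off}"
        entries.append(
            TranslatedEntry(
                entry_id=entry_id,
                residues=frag,
                source_id=seq.id,
                strand=strand,
                frame=frame,
                aa_offset=off,
                source_kind=kind,
            )
        )
    return entries


def build_genome_db(seqs: list[NucleotideSequence]) -> list[TranslatedEntry]:
    """Six-frame translation, stop-split, of every input chromosome."""
    if not seqs:
        raise ValueError("empty genome input")
    entries = []
    for seq in seqs:
        for strand in "+-":
            for frame in range(3):
                entries.extend(_frame_entries(seq, strand, frame, "genome"))
    return entries


def build_transcript_db(seqs: list[NucleotideSequence]) -> list[TranslatedEntry]:
    """Three forward-frame translation of sense-strand mRNAs, stop-split."""
    entries = []
    for seq in seqs:
        for frame in range(3):
            entries.extend(_frame_entries(seq, "+", frame, "transcript"))
    return entries


def build_protein_db(records: list[tuple[str, str]]) -> list[TranslatedEntry]:
    """One entry per protein record; terminal '*' stripped, bad records rejected.

    Records with non-amino-acid characters in mid-sequence are dropped with
    a logged warning rather than aborting the whole database.
    """
    entries = []
    for rec_id, residues in records:
        residues = residues.upper().rstrip("*")
        bad = set(residues) - AA20
        if bad:
            log.warning("protein record %s rejected: invalid residues %r", rec_id, sorted(bad))
            continue
        if not residues:
            log.warning("protein record %s rejected: empty after cleanup", rec_id)
            continue
        entries.append(
            TranslatedEntry(
                entry_id=rec_id,
                residues=residues,
                source_id=rec_id,
                strand=".",
                frame=-1,
                aa_offset=0,
                source_kind="protein",
            )
        )
    return entries


DECOY_PREFIX = "rev_"


def make_decoy(db: list[TranslatedEntry]) -> list[TranslatedEntry]:
    """Reverse every target entry; same counts, lengths and composition."""
    return [
        TranslatedEntry(
            entry_id=DECOY_PREFIX + e.entry_id,
            residues=e.residues[::-1],
            source_id=e.source_id,
            strand=e.strand,
            frame=e.frame,
            aa_offset=e.aa_offset,
            source_kind=e.source_kind,
            is_decoy=True,
        )
        for e in db
    ]


# ---------------------------------------------------------------- FASTA I/O


def read_nt_fasta(path) -> list[NucleotideSequence]:
    return [
        NucleotideSequence(rec.id, normalize_nt(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_protein_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_entry_fasta(entries: list[TranslatedEntry], path) -> None:
    """Dump a database as FASTA with provenance encoded in headers."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(
                f">{e.entry_id}|{e.source_id}|{e.strand}|{e.frame}|{e.aa_offset}|"
                f"{int(e.is_decoy)}|{e.source_kind}\n{e.residues}\n"
            )


def read_entry_fasta(path) -> list[TranslatedEntry]:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        # entry_id itself may contain '|' separators; rebuild from the tail
        source_kind = parts[-1]
        is_decoy = bool(int(parts[-2]))
        aa_offset = int(parts[-3])
        frame = int(parts[-4])
        strand = parts[-5]
        source_id = parts[-6]
        entry_id = "|".join(parts[:-6])
        entries.append(
            TranslatedEntry(entry_id, str(rec.seq), source_id, strand, frame,
                            aa_offset, source_kind, is_decoy)
        )
    return entries
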