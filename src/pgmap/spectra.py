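"""MS/MS spectrum containers and readers for MGF and dta files.

The dta dialect: first line holds the singly-protonated precursor mass
(M+H)+ and the charge state; every following line is one fragment
m/z / intensity pair.  MGF is the multi-spectrum exchange format; blocks
are handed to the pyteomics MGF parser one at a time so that a single
malformed block is skipped with a warning instead of aborting the file.

The precursor tolerance downstream is applied on the neutral monoisotopic
mass in Da, so ``neutral_mass`` is the quantity searches key on.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pyteomics import mgf as _mgf

from .digest import PROTON

log = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor m/z + charge + mz-sorted peak list."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"{self.spectrum_id}: charge must be >= 1")
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError(f"{self.spectrum_id}: empty peak list")
        if (self.mz <= 0).any():
            raise ValueError(f"{self.spectrum_id}: non-positive m/z")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def neutral_mass(s: Spectrum) -> float:
    """Neutral monoisotopic precursor mass: mz*z - z*proton."""
    return s.precursor_mz * s.charge - s.charge * PROTON


def mz_from_neutral(m: float, z: int) -> float:
    return (m + z * PROTON) / z


# ------------------------------------------------------------------- MGF


def _parse_mgf_block(block: str, default_charges: tuple[int, ...], idx: int) -> list[Spectrum]:
    with io.StringIO(block) as fh:
        entries = list(_mgf.read(fh, use_index=False))
    out = []
    for entry in entries:
        params = entry["params"]
        title = str(params.get("title", f"spectrum_{idx}"))
        pepmass = params["pepmass"][0]
        if pepmass is None:
            raise ValueError("missing PEPMASS")
        charges = params.get("charge")
        zs = [int(c) for c in charges] if charges else list(default_charges)
        mz = entry["m/z array"]
        inten = entry["intensity array"]
        for z in zs:
            sid = title if len(zs) == 1 else f"{title}/z{z}"
            out.append(Spectrum(sid, float(pepmass), z, mz, inten))
    return out


def read_mgf(path, default_charges: tuple[int, ...] = (2, 3)) -> list[Spectrum]:
    """Read an MGF file; malformed blocks are skipped with a logged warning.

    Spectra with no CHARGE line are expanded over ``default_charges`` (one
    Spectrum per trial charge) so downstream search can keep the better
    match.
    """
    text = Path(path).read_text()
    spectra: list[Spectrum] = []
    idx = 0
    pos = 0
    while True:
        start = text.find("BEGIN IONS", pos)
        if start < 0:
            break
        end = text.find("END IONS", start)
        if end < 0:
            log.warning("MGF block %d unterminated; skipped", idx)
            break
        block = text[start : end + len("END IONS")] + "\n"
        pos = end + len("END IONS")
        try:
            spectra.extend(_parse_mgf_block(block, default_charges, idx))
        except Exception as exc:  # malformed block: skip, keep the rest
            log.warning("MGF block %d skipped: %s", idx, exc)
        idx += 1
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            for mz, it in zip(s.mz, s.intensity):
                fh.write(f"{mz:.5f} {it:.2f}\n")
            fh.write("END IONS\n")


# ------------------------------------------------------------------- dta


def read_dta(path) -> Spectrum:
    """Read one spectrum from a dta file.

    First line: (M+H)+ mass and charge.  The precursor m/z is reconstructed
    as (MH + (z-1)*proton)/z.
    """
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: dta needs a header line and at least one peak")
    mh, z = float(lines[0][0]), int(float(lines[0][1]))
    peaks = np.array([[float(a), float(b)] for a, b in lines[1:]])
    if (peaks[:, 1] < 0).any():
        raise ValueError(f"{path}: negative intensity")
    precursor_mz = (mh + (z - 1) * PROTON) / z
    return Spectrum(Path(path).stem, precursor_mz, z, peaks[:, 0], peaks[:, 1])


def write_dta(s: Spectrum, path) -> None:
    mh = neutral_mass(s) + PROTON
    with open(path, "w") as fh:
        fh.write(f"{mh:.6f} {s.charge}\n")
        for mz, it in zip(s.mz, s.intensity):
            fh.write(f"{mz:.5f} {it:.2f}\n")


def read_dta_dir(directory) -> list[Spectrum]:
    """Ingest a directory of single-spectrum dta files (sorted by name)."""
    return [read_dta(p) for p in sorted(Path(directory).glob("*.dta"))]
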