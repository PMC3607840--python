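"""Fragment-match scoring and E-value calibration.

The scorer counts how many theoretical b/y fragment m/z values of a
candidate peptide are matched by observed peaks within the fragment
tolerance (each observed peak consumable once, greedy nearest-first), and
reports -log10 of the binomial survival probability of seeing at least
that many matches by chance, with the per-fragment random match
probability estimated from peak density.  The scorer sits behind a small
registry so a different peptide-spectrum scoring function can be dropped
in without touching the search driver.

E-values follow the survival-curve tail-fit approach: the log10 survival
count of all candidate scores for one spectrum is fit with a least-squares
line over its central region and extrapolated to the top score, giving the
expected number of random candidates scoring at least that well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .digest import PROTON, WATER, _MASS_ARR
from .spectra import Spectrum

LN10 = np.log(10.0)


def _residue_masses(residues: str) -> np.ndarray:
    arr = _MASS_ARR[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        raise ValueError(f"unknown residue in {residues!r}")
    return arr


def theoretical_fragments(residues: str, charge_cap: int = 1) -> list[tuple[str, int, float]]:
    """Singly-charged (by default) b- and y-ion m/z values.

    b_i is the N-terminal fragment of i residues (prefix mass + proton);
    y_i the C-terminal fragment of i residues (suffix mass + water +
    proton).  For charge c the m/z is (neutral + c*proton)/c.
    """
    if len(residues) < 2:
        raise ValueError("peptide must have length >= 2")
    masses = _residue_masses(residues)
    prefix = np.cumsum(masses)[:-1]  # b1 .. b(n-1)
    suffix = np.cumsum(masses[::-1])[:-1]  # y1 .. y(n-1)
    out = []
    for z in range(1, charge_cap + 1):
        for i, m in enumerate(prefix, start=1):
            out.append((f"b{'+'*z}" if z > 1 else "b", i, (m + z * PROTON) / z))
        for i, m in enumerate(suffix, start=1):
            out.append((f"y{'+'*z}" if z > 1 else "y", i, (m + WATER + z * PROTON) / z))
    return out


def fragment_mz_array(residues: str, charge_cap: int = 1) -> np.ndarray:
    """Fragment m/z values only, unsorted, for the fast scoring path."""
    masses = _residue_masses(residues)
    prefix = np.cumsum(masses)[:-1]
    suffix = np.cumsum(masses[::-1])[:-1]
    parts = []
    for z in range(1, charge_cap + 1):
        parts.append((prefix + z * PROTON) / z)
        parts.append((suffix + WATER + z * PROTON) / z)
    return np.concatenate(parts)


def count_matched_fragments(spectrum: Spectrum, frag_mz: np.ndarray, frag_tol: float) -> int:
    """Fragments matched by >=1 peak, each peak consumable once.

    Ambiguities (one peak near several fragments) are resolved greedily by
    smallest |delta| first; ties break on fragment then peak index, which is
    deterministic because peaks are mz-sorted on load.
    """
    peaks = spectrum.mz
    lo = np.searchsorted(peaks, frag_mz - frag_tol, side="left")
    hi = np.searchsorted(peaks, frag_mz + frag_tol, side="right")
    pairs = []
    for fi in range(frag_mz.size):
        for pj in range(lo[fi], hi[fi]):
            pairs.append((abs(peaks[pj] - frag_mz[fi]), fi, pj))
    pairs.sort()
    frag_used = np.zeros(frag_mz.size, dtype=bool)
    peak_used = np.zeros(peaks.size, dtype=bool)
    k = 0
    for _, fi, pj in pairs:
        if not frag_used[fi] and not peak_used[pj]:
            frag_used[fi] = True
            peak_used[pj] = True
            k += 1
    return k


def random_match_probability(spectrum: Spectrum, frag_tol: float) -> float:
    """Per-fragment probability of a random peak match, from peak density."""
    span = float(spectrum.mz[-1] - spectrum.mz[0])
    if span <= 0:
        return 0.99
    return min(0.99, 2.0 * frag_tol * spectrum.n_peaks / span)


def match_score(spectrum: Spectrum, residues: str, frag_tol: float = 0.5,
                charge_cap: int = 1) -> float:
    """-log10 binomial survival probability of the observed fragment matches."""
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    if spectrum.n_peaks == 0:
        return 0.0
    frag_mz = fragment_mz_array(residues, charge_cap)
    n = frag_mz.size
    k = count_matched_fragments(spectrum, frag_mz, frag_tol)
    if k == 0:
        return 0.0
    q = random_match_probability(spectrum, frag_tol)
    # survival P(X >= k) for X ~ Binomial(n, q); logsf for numerical range
    log_sf = stats.binom.logsf(k - 1, n, q)
    return float(-log_sf / LN10)


#: pluggable scorer registry; the search driver looks its scorer up here.
SCORERS = {"binomial": match_score}


# ----------------------------------------------------------------- E-values


def empirical_evalue(candidate_scores, top_score: float) -> float:
    """Rank-based fallback: count of candidates scoring at or above top."""
    scores = np.asarray(candidate_scores, dtype=float)
    return float(max(1, int((scores >= top_score).sum())))


def fit_evalue(candidate_scores, top_score: float, min_candidates: int = 20) -> float:
    """Survival-curve tail fit E-value for one spectrum's top score.

    Survival counts N(>=s) over all candidate scores are fit with a
    least-squares line in (s, log10 N) over the tail region running from
    the median score down to the 5th-highest, with the survival function
    evaluated on an even score grid (so the fit tracks the decay per unit
    score rather than the local density of tied scores), and the line is
    extrapolated to the top score:  E = 10^(a*top + b).  Spectra with too
    few candidates, or degenerate score distributions, fall back to the
    empirical at-or-above count.
    """
    scores = np.sort(np.asarray(candidate_scores, dtype=float))
    n = scores.size
    if n < max(min_candidates, 10):  # the tail fit needs >=10 points
        return empirical_evalue(scores, top_score)
    s_lo = scores[n - n // 2]  # survival ~ n/2
    s_hi = scores[-5]  # survival ~ 5: below this, counts are too noisy
    if s_hi <= s_lo:
        return empirical_evalue(scores, top_score)
    grid = np.linspace(s_lo, s_hi, 12)
    survival = n - np.searchsorted(scores, grid, side="left")  # N(>= s)
    mask = survival >= 1
    if mask.sum() < 2:
        return empirical_evalue(scores, top_score)
    a, b = np.polyfit(grid[mask], np.log10(survival[mask]), 1)
    if a >= 0:  # survival must decay with score; refuse a rising fit
        return empirical_evalue(scores, top_score)
    return float(max(10.0 ** (a * top_score + b), 1e-300))
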