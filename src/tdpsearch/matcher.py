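"""Comparison of experimental spectra with theoretical fragment sets.

Matching is one-to-one (each experimental peak explains at most one
theoretical fragment; closest ppm wins).  Matched fragments are rewarded
through a step-mapped intensity, and *consecutive* matches along an ion
series earn a flat bonus from the third consecutive hit onward — runs of
adjacent matched fragments are the hallmark of a correct identification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fragmenter import TheoreticalFragment
from .peak_io import SpectrumRecord

log = logging.getLogger(__name__)

INTENSITY_STEP_THRESHOLD = 9.2e-5  # on max-normalized intensities
CONSECUTIVE_BONUS = 1.5
CONSECUTIVE_RUN = 3


@dataclass(frozen=True)
class MatchResult:
    matches: tuple[tuple[int, TheoreticalFragment, float], ...]  # (peak idx, fragment, ppm error)
    runs: tuple[int, ...]       # lengths of consecutive matched-fragment runs
    score_insilico: float
    n_matched: int
    frag_experimental: int      # total experimental peaks


def normalize_intensities(
    spectrum: SpectrumRecord,
    intensity_map: str = "step",
    threshold: float = INTENSITY_STEP_THRESHOLD,
    steepness: float = 1e5,
) -> np.ndarray:
    """Max-normalize intensities to [0, 1], then map them for scoring.

    ``step`` (default): 0.001 below the threshold, 1 at or above it.
    ``sigmoid``: logistic curve with midpoint at the threshold.
    """
    intens = spectrum.intensities
    top = intens.max() if len(intens) else 0.0
    if top <= 0:
        log.warning("%s: all-zero intensities", spectrum.spectrum_id)
        return np.full(len(intens), 0.001)
    norm = intens / top
    if intensity_map == "step":
        return np.where(norm < threshold, 0.001, 1.0)
    if intensity_map == "sigmoid":
        return 1.0 / (1.0 + np.exp(-steepness * (norm - threshold)))
    raise ValueError(f"unknown intensity map {intensity_map!r}")


def match(
    spectrum: SpectrumRecord,
    fragments: list[TheoreticalFragment],
    tolerance_ppm: float = 15.0,
    consecutive_bonus: str = "from_third",
    intensity_map: str = "step",
) -> MatchResult:
    """Match an experimental spectrum against theoretical fragments.

    Every matched fragment contributes its peak's mapped intensity, upgraded
    to a flat 1.5 from the third consecutive match in an ion series onward
    (``consecutive_bonus="retroactive"`` upgrades the whole run once it
    reaches three).  The in-silico score is the contribution sum divided by
    the number of experimental peaks.
    """
    if consecutive_bonus not in ("from_third", "retroactive"):
        raise ValueError(f"unknown consecutive bonus mode {consecutive_bonus!r}")
    n_peaks = len(spectrum)
    if not fragments or n_peaks == 0:
        return MatchResult((), (), 0.0, 0, n_peaks)
    peak_masses = spectrum.masses
    norm = normalize_intensities(spectrum, intensity_map)
    frag_masses = np.array([f.mass for f in fragments])
    # series-order rank, for run bookkeeping and deterministic tie-breaks
    series_rank = np.empty(len(fragments), dtype=int)
    order = sorted(range(len(fragments)), key=lambda k: fragments[k].series_key)
    series_rank[order] = np.arange(len(fragments))

    # candidate (peak, fragment) pairs within ppm tolerance
    tol = frag_masses * tolerance_ppm * 1e-6
    lo = np.searchsorted(peak_masses, frag_masses - tol, side="left")
    hi = np.searchsorted(peak_masses, frag_masses + tol, side="right")
    cand = [
        (abs(peak_masses[p] - frag_masses[f]) / frag_masses[f] * 1e6, series_rank[f], p, f)
        for f in range(len(fragments))
        for p in range(lo[f], hi[f])
    ]
    cand.sort()
    peak_used = np.zeros(n_peaks, dtype=bool)
    frag_used = np.zeros(len(fragments), dtype=bool)
    assigned: dict[int, int] = {}  # fragment idx -> peak idx
    for _, _, p, f in cand:
        if peak_used[p] or frag_used[f]:
            continue
        peak_used[p] = True
        frag_used[f] = True
        assigned[f] = p

    # walk fragments in series order, tracking consecutive matched runs
    contributions = 0.0
    runs: list[int] = []
    matches: list[tuple[int, TheoreticalFragment, float]] = []
    run = 0
    prev_group = None
    pending: list[int] = []  # peak indices of the current run (retroactive mode)

    def flush() -> None:
        nonlocal contributions
        if run:
            runs.append(run)
        if consecutive_bonus == "retroactive" and run >= CONSECUTIVE_RUN:
            contributions += CONSECUTIVE_BONUS * len(pending) - sum(norm[p] for p in pending)

    for f in order:
        frag = fragments[f]
        group = (frag.series, frag.loss)
        if group != prev_group:
            flush()
            run = 0
            pending = []
            prev_group = group
        if f in assigned:
            p = assigned[f]
            run += 1
            pending.append(p)
            ppm = (peak_masses[p] - frag.mass) / frag.mass * 1e6
            matches.append((p, frag, float(ppm)))
            if consecutive_bonus == "from_third" and run >= CONSECUTIVE_RUN:
                contributions += CONSECUTIVE_BONUS
            else:
                contributions += float(norm[p])
        else:
            flush()
            run = 0
            pending = []
    flush()

    matches.sort(key=lambda m: m[0])
    return MatchResult(
        matches=tuple(matches),
        runs=tuple(runs),
        score_insilico=contributions / n_peaks,
        n_matched=len(assigned),
        frag_experimental=n_peaks,
    )


def count_matched_peaks(
    peak_masses: np.ndarray,
    frag_masses: np.ndarray,
    tolerance_ppm: float,
) -> int:
    """Fast count of experimental peaks lying within ppm tolerance of any
    theoretical fragment (no one-to-one constraint).  Used for the
    database-wide match counts behind spectral probabilities."""
    if len(frag_masses) == 0 or len(peak_masses) == 0:
        return 0
    frag_masses = np.sort(frag_masses)
    idx = np.searchsorted(frag_masses, peak_masses)
    best = np.full(len(peak_masses), np.inf)
    for side in (np.clip(idx - 1, 0, len(frag_masses) - 1), np.clip(idx, 0, len(frag_masses) - 1)):
        delta = np.abs(peak_masses - frag_masses[side]) / frag_masses[side] * 1e6
        best = np.minimum(best, delta)
    return int(np.sum(best <= tolerance_ppm))
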