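"""Precursor intact-mass tuning from complementary fragment-pair sums.

A complementary N-/C-terminal fragment pair sums to the precursor mass plus a
small, ion-chemistry-dependent constant: with neutral fragment masses,
b_i + y_(L-i) equals the neutral proteoform mass exactly, c + z-dot sums to
M + 1.007825, and a + x to M - 2.015650.  The tuner therefore collects all
peak-pair sums near (reported precursor + offset), slides a proton-mass-wide
window over them, keeps the most populated window, and reports the
intensity-weighted mean of the sums inside it (minus the offset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem import HYDROGEN, PROTON
from .peak_io import SpectrumRecord

log = logging.getLogger(__name__)

#: pair-sum offset (sum of complementary neutral fragments minus precursor) per mode
PAIR_OFFSETS = {
    "CID": 0.0, "HCD": 0.0, "IRMPD": 0.0, "SID": 0.0, "BIRD": 0.0,
    "ECD": HYDROGEN, "ETD": HYDROGEN,
    "EDD": -2 * HYDROGEN,
    "UVPD": 0.0,
}


@dataclass(frozen=True)
class FragmentPairSum:
    sum_mass: float        # peaks[i].mass + peaks[j].mass, Da
    mean_intensity: float  # (intensity_i + intensity_j) / 2
    i: int
    j: int


@dataclass(frozen=True)
class TunerConfig:
    tolerance: float = 2.2        # Da window around reported precursor for selecting sums
    window_width: float = PROTON  # sliding-window width, Da
    step: float = 0.1             # window shift increment, Da

    def __post_init__(self) -> None:
        if self.tolerance <= 0 or self.window_width <= 0 or self.step <= 0:
            raise ValueError("tolerance, window_width and step must all be positive")


@dataclass(frozen=True)
class TunerResult:
    mass: float
    tuned: bool
    window_start: float | None = None
    n_pairs: int = 0


def pair_sums(
    spectrum: SpectrumRecord,
    cfg: TunerConfig,
    pair_offset: float | None = None,
) -> list[FragmentPairSum]:
    """All unordered peak pairs whose mass sum lies within ``cfg.tolerance`` of
    the reported precursor plus the mode's complementarity offset, sorted
    ascending by sum."""
    if pair_offset is None:
        pair_offset = PAIR_OFFSETS.get(spectrum.fragmentation_mode, 0.0)
    n = len(spectrum)
    if n < 2:
        log.warning("%s: fewer than 2 peaks, no pair sums", spectrum.spectrum_id)
        return []
    masses = spectrum.masses
    intens = spectrum.intensities
    target = spectrum.precursor_mass + pair_offset
    ii, jj = np.triu_indices(n, k=1)
    sums = masses[ii] + masses[jj]
    keep = np.abs(sums - target) <= cfg.tolerance
    ii, jj, sums = ii[keep], jj[keep], sums[keep]
    means = (intens[ii] + intens[jj]) / 2.0
    order = np.argsort(sums, kind="stable")
    return [
        FragmentPairSum(float(sums[k]), float(means[k]), int(ii[k]), int(jj[k]))
        for k in order
    ]


def tune_mass(
    spectrum: SpectrumRecord,
    cfg: TunerConfig | None = None,
    pair_offset: float | None = None,
) -> TunerResult:
    """Tune the precursor mass by the sliding-window vote over pair sums.

    Windows of ``cfg.window_width`` start at the smallest pair sum and advance
    by ``cfg.step`` until the largest; the window holding the most sums wins
    (ties: larger total pair intensity, then lower window start).  The tuned
    mass is the intensity-weighted mean of sums inside the winning window,
    minus the complementarity offset.  With no pair sums at all the reported
    precursor is returned unchanged.
    """
    if cfg is None:
        cfg = TunerConfig()
    if pair_offset is None:
        pair_offset = PAIR_OFFSETS.get(spectrum.fragmentation_mode, 0.0)
    pairs = pair_sums(spectrum, cfg, pair_offset)
    if not pairs:
        return TunerResult(spectrum.precursor_mass, tuned=False)
    sums = np.array([p.sum_mass for p in pairs])
    weights = np.array([p.mean_intensity for p in pairs])
    lo, hi = sums[0], sums[-1]
    n_windows = max(1, int(np.floor((hi - lo) / cfg.step)) + 1)
    starts = lo + cfg.step * np.arange(n_windows)
    # counts per window over the sorted sums
    left = np.searchsorted(sums, starts, side="left")
    right = np.searchsorted(sums, starts + cfg.window_width, side="right")
    counts = right - left
    cum_w = np.concatenate([[0.0], np.cumsum(weights)])
    win_weight = cum_w[right] - cum_w[left]
    # argmax with tie-breaks: count desc, total intensity desc, start asc
    best = max(range(n_windows), key=lambda k: (counts[k], win_weight[k], -starts[k]))
    sel = slice(left[best], right[best])
    w = weights[sel]
    if w.sum() <= 0:
        tuned = float(sums[sel].mean())
    else:
        tuned = float(np.average(sums[sel], weights=w))
    return TunerResult(
        mass=tuned - pair_offset,
        tuned=True,
        window_start=float(starts[best]),
        n_pairs=int(counts[best]),
    )
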