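"""Composite scoring, target-decoy FDR and spectral-probability E-values.

The final score is a weighted sum of the three component scores divided by a
fixed 3 (so unit weights give a plain average).  FDR follows the paired
target/decoy convention: each spectrum contributes its best target and best
decoy match, and at a score threshold the counts are
TO (target only), DO (decoy only), TB (both, target better) and DB (both,
decoy better or equal), giving FDR = (2·DB + DO)/(TO + TB + DB).
E-values derive from a database-frequency spectral probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .fragmenter import Proteoform
from .protein_db import ProteinEntry

log = logging.getLogger(__name__)

EVALUE_FACTOR = 0.693


@dataclass(frozen=True)
class PrSM:
    """One proteoform-spectrum match with component and final scores."""

    spectrum_id: str
    proteoform: Proteoform
    score_mass: float
    score_pst: float
    score_insilico: float
    score_final: float
    n_matched: int
    e_value: float | None = None
    q_value: float | None = None

    @property
    def accession(self) -> str:
        return self.proteoform.base.accession

    @property
    def is_decoy(self) -> bool:
        return self.proteoform.base.is_decoy


@dataclass(frozen=True)
class FdrCounts:
    TO: int
    TB: int
    DO: int
    DB: int

    def __post_init__(self) -> None:
        if min(self.TO, self.TB, self.DO, self.DB) < 0:
            raise ValueError("FDR counts must be non-negative")


def final_score(
    score_mass: float,
    score_pst: float,
    score_insilico: float,
    w1: float = 1.0,
    w2: float = 1.0,
    w3: float = 1.0,
) -> float:
    """(W1·mass + W2·PST + W3·in-silico) / 3 — the divisor is a fixed 3
    regardless of the weights."""
    if min(w1, w2, w3) < 0:
        raise ValueError("weights must be non-negative")
    return (w1 * score_mass + w2 * score_pst + w3 * score_insilico) / 3.0


def sequence_log_probabilities(db: list[ProteinEntry]) -> np.ndarray:
    """Per-entry log probability under the database residue-frequency model,
    renormalized so the database sums to one (raw products underflow at
    protein length, hence log space)."""
    from collections import Counter

    counts: Counter[str] = Counter()
    for entry in db:
        counts.update(entry.sequence)
    total = sum(counts.values())
    log_freq = {r: np.log(c / total) for r, c in counts.items()}
    log_probs = np.array([sum(log_freq[r] for r in e.sequence) for e in db])
    return log_probs - logsumexp(log_probs)


def spectral_probability(
    db: list[ProteinEntry],
    t: int,
    match_counts: dict[str, int],
) -> float:
    """Probability mass of database sequences achieving at least ``t``
    spectral matches, under the residue-frequency sequence model."""
    if t < 0:
        raise ValueError("match-count threshold t must be >= 0")
    log_probs = sequence_log_probabilities(db)
    qualify = np.array([match_counts.get(e.accession, 0) >= t for e in db])
    if not qualify.any():
        return 0.0
    return float(np.exp(logsumexp(log_probs[qualify])))


def e_value(spectral_prob: float) -> float:
    if not 0.0 <= spectral_prob <= 1.0:
        raise ValueError("spectral probability must lie in [0, 1]")
    return EVALUE_FACTOR * spectral_prob


def fdr(counts: FdrCounts) -> float | None:
    """(2·DB + DO) / (TO + TB + DB); None when the denominator is zero."""
    denom = counts.TO + counts.TB + counts.DB
    if denom == 0:
        return None
    return (2 * counts.DB + counts.DO) / denom


def fdr_counts_at(
    target_scores: np.ndarray,
    decoy_scores: np.ndarray,
    threshold: float,
) -> FdrCounts:
    """Paired per-spectrum counts at a score threshold.  ``target_scores`` and
    ``decoy_scores`` are aligned per spectrum (−inf where that search reported
    nothing)."""
    t_in = target_scores >= threshold
    d_in = decoy_scores >= threshold
    both = t_in & d_in
    return FdrCounts(
        TO=int(np.sum(t_in & ~d_in)),
        DO=int(np.sum(d_in & ~t_in)),
        TB=int(np.sum(both & (target_scores > decoy_scores))),
        DB=int(np.sum(both & (decoy_scores >= target_scores))),
    )


def assign_q_values(prsms: list[PrSM]) -> list[PrSM]:
    """Attach q-values (running minimum of FDR from the lowest score upward)
    to a list holding, per spectrum, the best target and/or best decoy match.

    Returns a new list sorted by final score descending.  Without any decoys
    q-values stay absent.
    """
    ranked = sorted(prsms, key=lambda p: -p.score_final)
    if not any(p.is_decoy for p in ranked):
        log.warning("no decoy matches present; q-values not assigned")
        return ranked
    by_spectrum: dict[str, dict[bool, float]] = {}
    for p in ranked:
        slot = by_spectrum.setdefault(p.spectrum_id, {})
        slot[p.is_decoy] = max(slot.get(p.is_decoy, -np.inf), p.score_final)
    spectra = sorted(by_spectrum)
    t_scores = np.array([by_spectrum[s].get(False, -np.inf) for s in spectra])
    d_scores = np.array([by_spectrum[s].get(True, -np.inf) for s in spectra])

    fdrs = []
    for p in ranked:
        value = fdr(fdr_counts_at(t_scores, d_scores, p.score_final))
        fdrs.append(np.nan if value is None else value)
    # running min from the bottom of the ranked list; clamp to [0, 1]
    out: list[PrSM] = []
    running = np.inf
    for p, f in zip(reversed(ranked), reversed(fdrs)):
        if not np.isnan(f):
            running = min(running, f)
        q = None if np.isinf(running) else float(min(1.0, running))
        out.append(replace(p, q_value=q))
    out.reverse()
    return out
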