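"""Intact-mass filtering and scoring of candidate proteins.

A candidate survives if |experimental − theoretical| falls inside the
user-defined Da tolerance.  The survivor's mass score decays from 1 (perfect
agreement) toward 0 at the tolerance edge.  Two functional forms are
available: the default ``bounded`` form clamp(2^(1/diff) − 1, 0, 1), which
stays in [0, 1] so it can be averaged with the other component scores, and a
``paper_raw`` form 2^(1/diff), which is unbounded below 1 Da.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .chem import ResidueMassTable, residue_table
from .protein_db import ProteinEntry, theoretical_mass

MASS_SCORE_FORMS = ("bounded", "paper_raw")


@dataclass(frozen=True)
class MassScore:
    mass_diff: float  # |experimental − theoretical|, Da
    score: float


def _pow2_inv(diff: float) -> float:
    # 2 ** (1/diff) without overflow for tiny diff
    exponent = 1.0 / diff
    if exponent > 1023:
        return math.inf
    return 2.0 ** exponent


def score_mass(
    experimental: float,
    theoretical: float,
    thr: float,
    form: str = "bounded",
) -> MassScore:
    """Score agreement between experimental and theoretical intact mass."""
    if thr <= 0:
        raise ValueError("mass tolerance must be positive")
    if form not in MASS_SCORE_FORMS:
        raise ValueError(f"unknown mass score form {form!r}")
    diff = abs(experimental - theoretical)
    if diff == 0:
        return MassScore(0.0, 1.0)
    if diff > thr:
        return MassScore(diff, 0.0)
    raw = _pow2_inv(diff)
    if form == "paper_raw":
        return MassScore(diff, raw)
    return MassScore(diff, min(1.0, max(0.0, raw - 1.0)))


def filter_by_mass(
    db: list[ProteinEntry],
    experimental: float,
    thr: float,
    table: ResidueMassTable | None = None,
    form: str = "bounded",
) -> list[tuple[ProteinEntry, MassScore]]:
    """Shortlist database entries whose intact mass lies within ``thr`` Da of
    the experimental mass, in input order, each with its mass score."""
    if table is None:
        table = residue_table()
    survivors = []
    for entry in db:
        ms = score_mass(experimental, theoretical_mass(entry.sequence, table), thr, form)
        if ms.mass_diff <= thr:
            survivors.append((entry, ms))
    return survivors
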