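"""Protein database: FASTA loading, theoretical proteoform mass, decoy construction.

Decoys follow the shuffle-and-mutate recipe: each target sequence is uniformly
permuted and then a small number of positions (3 by default) are substituted
with a uniformly random *different* residue.  Three such decoys per target
stabilize the downstream FDR estimate.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .chem import AMINO_ACIDS, ResidueError, ResidueMassTable, residue_table
from .errors import EmptyDatabaseError

log = logging.getLogger(__name__)

_NONSTANDARD_MAP = {"B": "N", "Z": "Q", "U": "C", "O": "K"}


@dataclass(frozen=True)
class ProteinEntry:
    """One database entry; decoys carry ``is_decoy`` and point back to their target."""

    accession: str
    description: str
    sequence: str
    is_decoy: bool = False
    decoy_of: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ResidueError(f"{self.accession}: non-standard residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def load_fasta(path: str | os.PathLike, nonstandard: str = "skip_protein") -> list[ProteinEntry]:
    """Load a FASTA protein database.

    ``nonstandard`` controls records with residues outside the 20-letter
    alphabet: ``"skip_protein"`` drops the whole record, ``"map"`` rewrites
    B->N, Z->Q, U->C, O->K and drops X/* positions.  Counts are logged.
    """
    from pyteomics import fasta

    if nonstandard not in ("skip_protein", "map"):
        raise ValueError(f"unknown nonstandard policy {nonstandard!r}")
    entries: list[ProteinEntry] = []
    n_skipped = n_mapped = 0
    for header, seq in fasta.read(str(path)):
        accession = header.split()[0]
        description = header[len(accession):].strip()
        seq = seq.upper().rstrip("*")
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            if nonstandard == "skip_protein":
                n_skipped += 1
                log.info("skipping %s: non-standard residues %s", accession, sorted(bad))
                continue
            seq = "".join(_NONSTANDARD_MAP.get(ch, ch) for ch in seq)
            seq = "".join(ch for ch in seq if ch in AMINO_ACIDS)
            n_mapped += 1
            if not seq:
                n_skipped += 1
                continue
        entries.append(ProteinEntry(accession, description, seq))
    if n_skipped or n_mapped:
        log.info("FASTA sanitization: %d records skipped, %d mapped", n_skipped, n_mapped)
    if not entries:
        raise EmptyDatabaseError(f"no usable protein records in {path}")
    return entries


def theoretical_mass(
    sequence: str,
    table: ResidueMassTable | None = None,
    mass_mode: str = "monoisotopic",
) -> float:
    """Neutral mass of an intact chain: residue sum plus one water (H at the
    N-terminus, OH at the C-terminus)."""
    if table is None:
        table = residue_table(mass_mode)
    if not sequence:
        raise ValueError("empty sequence")
    total = table.water_mass
    for pos, res in enumerate(sequence, start=1):
        try:
            total += table.masses[res]
        except KeyError:
            raise ResidueError(f"unknown residue {res!r} at position {pos}") from None
    return total


def make_decoys(
    db: list[ProteinEntry],
    n_decoys_per_target: int = 3,
    n_mutations: int = 3,
    seed: int = 0,
) -> list[ProteinEntry]:
    """Shuffled-and-mutated decoys: ``n_decoys_per_target`` per entry, each a
    uniform permutation of the target followed by ``n_mutations`` substitutions
    at distinct positions (never substituting a residue with itself)."""
    if not db:
        raise EmptyDatabaseError("cannot build decoys for an empty database")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    decoys: list[ProteinEntry] = []
    for entry in db:
        seq = np.frombuffer(entry.sequence.encode(), dtype="S1")
        for k in range(1, n_decoys_per_target + 1):
            shuffled = rng.permutation(seq).copy()
            n_mut = min(n_mutations, len(seq))
            if n_mut < n_mutations:
                log.info("%s: capping mutations at sequence length %d", entry.accession, len(seq))
            positions = rng.choice(len(seq), size=n_mut, replace=False)
            for pos in positions:
                choices = alphabet[alphabet != shuffled[pos]]
                shuffled[pos] = rng.choice(choices)
            decoys.append(
                ProteinEntry(
                    accession=f"DECOY_{k}_{entry.accession}",
                    description=f"decoy {k} of {entry.accession}",
                    sequence=shuffled.tobytes().decode(),
                    is_decoy=True,
                    decoy_of=entry.accession,
                )
            )
    return decoys
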