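import numpy as np
import pytest

from tdpsearch import (
    ProteinEntry,
    Proteoform,
    enumerate_truncations,
    fragment,
    mode_to_series,
    theoretical_mass,
)
from tdpsearch.chem import DEFAULT_LOSSES, WATER_MONO
from tdpsearch.errors import ConfigurationError, ProteoformError
from tdpsearch.ptm_search import ModificationSite, load_ptm_table

from conftest import random_protein

PTMS = {p.name: p for p in load_ptm_table()}


def test_fragment_counts_closed_form(rng):
    entry = random_protein(rng, 30)
    L = len(entry.sequence)
    prof = Proteoform(base=entry)
    assert len(fragment(prof, "CID")) == 2 * (L - 1)
    assert len(fragment(prof, "UVPD")) == 6 * (L - 1)
    assert len(fragment(prof, "CID", losses=DEFAULT_LOSSES)) == 2 * (L - 1) * 3


def test_mode_series_mapping():
    assert [s.series for s in mode_to_series("CID")] == ["b", "y"]
    assert [s.series for s in mode_to_series("ETD")] == ["c", "z"]
    assert [s.series for s in mode_to_series("EDD")] == ["a", "x"]
    assert [s.series for s in mode_to_series("UVPD")] == ["a", "b", "c", "x", "y", "z"]
    override = mode_to_series("CID", overrides={"CID": ["b", "y", "a"]})
    assert [s.series for s in override] == ["b", "y", "a"]
    with pytest.raises(ConfigurationError):
        mode_to_series("LASER")


def test_gg_b_and_y_masses(table):
    entry = ProteinEntry("P", "", "GG")
    frags = {(f.series, f.index): f.mass for f in fragment(Proteoform(base=entry), "CID")}
    g = table.masses["G"]
    assert frags[("b", 1)] == pytest.approx(g)              # neutral b = residue sum
    assert frags[("y", 1)] == pytest.approx(g + WATER_MONO)  # neutral y = residues + water
    # complementary pair reconstructs the whole chain mass
    assert frags[("b", 1)] + frags[("y", 1)] == pytest.approx(theoretical_mass("GG"))


def test_complementarity_invariant(rng, table):
    """N-fragment residue sum + C-fragment residue sum equals the proteoform
    residue total at every cleavage site, for all six series."""
    offsets = {s.series: s.mass_offset for m in ("UVPD",) for s in mode_to_series(m)}
    for _ in range(50):
        entry = random_protein(rng, int(rng.integers(5, 60)))
        prof = Proteoform(base=entry)
        total = theoretical_mass(entry.sequence, table) - WATER_MONO
        frags = fragment(prof, "UVPD")
        by_key = {(f.series, f.index): f.mass for f in frags}
        L = len(entry.sequence)
        for n_series, c_series in (("a", "x"), ("b", "y"), ("c", "z")):
            for i in range(1, L):
                n_sum = by_key[(n_series, i)] - offsets[n_series]
                c_sum = by_key[(c_series, L - i)] - offsets[c_series]
                assert n_sum + c_sum == pytest.approx(total, abs=1e-9)


def test_modification_shifts_prefix_and_suffix():
    entry = ProteinEntry("P", "", "PEPTIDE")
    phospho = PTMS["Phospho"]
    prof = Proteoform(base=entry, modifications=(ModificationSite(3, phospho, 1.0),))
    plain = {(f.series, f.index): f.mass for f in fragment(Proteoform(base=entry), "CID")}
    mod = {(f.series, f.index): f.mass for f in fragment(prof, "CID")}
    delta = phospho.delta_mass
    for i in (1, 2):
        assert mod[("b", i)] == pytest.approx(plain[("b", i)])
    for i in (3, 4, 5, 6):
        assert mod[("b", i)] == pytest.approx(plain[("b", i)] + delta)
    for j in (1, 2, 3, 4):  # y1..y4 cover residues 4..7, untouched
        assert mod[("y", j)] == pytest.approx(plain[("y", j)])
    for j in (5, 6):
        assert mod[("y", j)] == pytest.approx(plain[("y", j)] + delta)


def test_unexplained_shift_moves_fragments_containing_position():
    entry = ProteinEntry("P", "", "PEPTIDE")
    shift = 100.0
    prof = Proteoform(base=entry, unexplained_shift=shift, shift_position=4)
    plain = {(f.series, f.index): f.mass for f in fragment(Proteoform(base=entry), "CID")}
    mod = {(f.series, f.index): f.mass for f in fragment(prof, "CID")}
    for i in range(1, 7):
        expected = plain[("b", i)] + (shift if i >= 4 else 0.0)
        assert mod[("b", i)] == pytest.approx(expected)
    for j in range(1, 7):  # y_j covers positions 8-j..7
        expected = plain[("y", j)] + (shift if 8 - j <= 4 else 0.0)
        assert mod[("y", j)] == pytest.approx(expected)


def test_neutral_loss_copies():
    entry = ProteinEntry("P", "", "PEP")
    frags = fragment(Proteoform(base=entry), "CID", losses=[("H2O", -18.010565)])
    base = [f for f in frags if f.loss is None]
    lost = [f for f in frags if f.loss == "H2O"]
    assert len(base) == len(lost) == 4
    for b in base:
        partner = next(l for l in lost if (l.series, l.index) == (b.series, b.index))
        assert partner.mass == pytest.approx(b.mass - 18.010565)


def test_paper_offsets_switch(table):
    entry = ProteinEntry("P", "", "GG")
    frags = {(f.series, f.index): f.mass
             for f in fragment(Proteoform(base=entry), "CID", paper_offsets=True)}
    g = table.masses["G"]
    assert frags[("b", 1)] == pytest.approx(g + 17.002740)  # hydroxyl on N-terminal ion
    assert frags[("y", 1)] == pytest.approx(g + 1.007276)   # proton on C-terminal ion


def test_truncation_sequence_and_validation():
    entry = ProteinEntry("P", "", "PEPTIDE")
    assert Proteoform(base=entry, truncation=("N", 2)).sequence == "PTIDE"
    assert Proteoform(base=entry, truncation=("C", 3)).sequence == "PEPT"
    with pytest.raises(ProteoformError):
        Proteoform(base=entry, truncation=("N", 7))
    with pytest.raises(ProteoformError):
        Proteoform(base=entry, truncation=("X", 1))


def test_enumerate_truncations_examples(table):
    entry = ProteinEntry("P", "", "PEPTIDEG")
    M = theoretical_mass(entry.sequence, table)
    intact_only = enumerate_truncations(entry, M, thr=0.01, table=table)
    assert len(intact_only) == 1 and intact_only[0].truncation is None

    # drop the C-terminal glycine
    target = theoretical_mass("PEPTIDE", table)
    res = enumerate_truncations(entry, target, thr=0.01, table=table)
    assert len(res) == 1
    assert res[0].truncation == ("C", 1)
    assert res[0].sequence == "PEPTIDE"

    assert enumerate_truncations(entry, M + 500.0, thr=0.01, table=table) == []


def test_enumerate_truncations_matches_brute_force(rng, table):
    for _ in range(10):
        entry = random_protein(rng, int(rng.integers(10, 120)))
        L = len(entry.sequence)
        exp = theoretical_mass(entry.sequence, table) - float(rng.uniform(0, 3000))
        thr = 50.0
        got = {
            (p.truncation or ("-", 0)): p.mass(table)
            for p in enumerate_truncations(entry, exp, thr, table)
        }
        expected = {}
        if abs(theoretical_mass(entry.sequence, table) - exp) <= thr:
            expected[("-", 0)] = theoretical_mass(entry.sequence, table)
        for k in range(1, L):
            for side, seq in (("N", entry.sequence[k:]), ("C", entry.sequence[:-k])):
                m = theoretical_mass(seq, table)
                if abs(m - exp) <= thr:
                    expected[(side, k)] = m
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=1e-9)


def test_proteoform_mass_includes_mods_and_shift(table):
    entry = ProteinEntry("P", "", "PEPTIDE")
    phospho = PTMS["Phospho"]
    prof = Proteoform(
        base=entry,
        modifications=(ModificationSite(3, phospho, 1.0),),
        unexplained_shift=5.0,
        shift_position=2,
    )
    assert prof.mass(table) == pytest.approx(
        theoretical_mass("PEPTIDE", table) + phospho.delta_mass + 5.0
    )
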