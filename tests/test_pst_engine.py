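import math

import numpy as np
import pytest

from tdpsearch import (
    ProteinEntry,
    build_ladders,
    extract_hops,
    extract_tags,
    make_record,
    score_pst,
    score_protein_psts,
)
from tdpsearch.pst_engine import Hop, PST, count_overlapping

from conftest import ladder_record, random_protein


def brute_force_hops(masses, tolerance, table, collapse=True):
    out = []
    residues = {r: m for r, m in table.masses.items() if not (collapse and r == "I")}
    for i in range(len(masses)):
        for j in range(i + 1, len(masses)):
            d = masses[j] - masses[i]
            for res, rm in residues.items():
                if abs(d - rm) <= tolerance:
                    out.append((i, j, res))
    return sorted(out)


def test_single_alanine_hop():
    rec = make_record("s", 1000.0, [200.000, 271.037], [1.0, 1.0])
    hops = extract_hops(rec, 0.01)
    assert len(hops) == 1
    assert hops[0].residue == "A"
    assert hops[0].error == pytest.approx(-0.00011, abs=1e-5)


def test_no_hop_when_no_residue_matches():
    rec = make_record("s", 1000.0, [200.0, 300.0], [1.0, 1.0])
    assert extract_hops(rec, 0.01) == []


def test_leu_ile_collapsed_by_default(table):
    rec = make_record("s", 1000.0, [200.0, 200.0 + table.masses["L"]], [1.0, 1.0])
    hops = extract_hops(rec, 0.001)
    assert [h.residue for h in hops] == ["L"]
    both = extract_hops(rec, 0.001, collapse_leu_ile=False)
    assert sorted(h.residue for h in both) == ["I", "L"]


def test_hops_match_brute_force(rng, table):
    for _ in range(10):
        n = int(rng.integers(5, 60))
        masses = np.sort(rng.uniform(100, 2000, n))
        rec = make_record("s", 3000.0, masses, np.ones(n))
        got = sorted((h.start_peak, h.end_peak, h.residue) for h in extract_hops(rec, 0.02))
        assert got == brute_force_hops(rec.masses, 0.02, table)


def test_ladder_chaining_and_length_filter(table):
    # W+A does not sum to any residue mass, so no shortcut hops appear
    rec = ladder_record("WA", base_mass=200.0)
    hops = extract_hops(rec, 0.001)
    ladders = build_ladders(hops, 1, 10)
    assert [l.residues for l in ladders] == ["WA"]
    assert build_ladders(hops, 3, 10) == []  # too short after filtering

    single = build_ladders(hops[:1], 2, 10)
    assert single == []  # single hop below min length


def test_only_maximal_chains_emitted():
    rec = ladder_record("WAW", base_mass=150.0)
    hops = extract_hops(rec, 0.001)
    ladders = build_ladders(hops, 1, 10)
    # the full chain is maximal; its sub-chains ("W", "A", "WA", "AW") are not emitted
    assert [l.residues for l in ladders] == ["WAW"]


def test_shortcut_hops_create_alternative_ladders():
    # A+G equals Q's residue mass to 1e-5, so the two-hop path and the
    # one-hop shortcut are both maximal ladders over the same peaks
    rec = ladder_record("AG", base_mass=200.0)
    ladders = build_ladders(extract_hops(rec, 0.001), 1, 10)
    assert sorted(l.residues for l in ladders) == ["AG", "Q"]


def test_sequence_recovered_from_full_ladder(table):
    rec = ladder_record("SAMPLER", base_mass=300.0)
    tags = extract_tags(rec, hop_tolerance=0.005, min_len=2, max_len=10,
                        rmse_tolerance=None)
    assert any(t.residues == "SAMPLER" for t in tags)


def test_score_pst_worked_example():
    """All hop errors zero and all supporting peaks at max intensity, N = 4:
    error score 1, cumulative intensity 1, length score 16, frequency 16."""
    rec = ladder_record("AGAS", base_mass=200.0)
    tags = [t for t in extract_tags(rec, 0.001, 2, 10) if t.residues == "AGAS"]
    assert tags
    t = tags[0]
    assert t.rmse == pytest.approx(0.0, abs=1e-6)
    assert t.error_score == pytest.approx(1.0, abs=1e-4)
    assert t.intensity == pytest.approx(1.0)
    assert t.len_score == 16.0
    assert t.freq_score == pytest.approx(16.0, abs=1e-3)


def test_error_score_vanishes_for_large_rmse():
    hops = (Hop(0, 1, 71.087, "A", 71.03711, 0.05),)
    rec = make_record("s", 1000.0, [200.0, 271.087], [1.0, 1.0])
    t = score_pst(PST(hops=hops, residues="A"), rec)
    assert t.error_score == pytest.approx(math.exp(-2 * 0.05))
    big = score_pst(PST(hops=(Hop(0, 1, 81.0, "A", 71.03711, 10.0),), residues="A"), rec)
    assert big.error_score < 1e-8


def test_length_score_quadratic(table):
    rec1 = ladder_record("A", base_mass=200.0)
    rec3 = ladder_record("AGA", base_mass=200.0)
    t1 = extract_tags(rec1, 0.001, 1, 10)[0]
    t3 = [t for t in extract_tags(rec3, 0.001, 1, 10) if len(t.residues) == 3][0]
    assert t3.len_score / t1.len_score == pytest.approx(9.0)  # N=1 vs N=3 -> 1:9


def test_rmse_uses_n_outside_radical():
    errors = [0.004, -0.003, 0.002]
    hops = tuple(
        Hop(i, i + 1, 71.03711 + e, "A", 71.03711, e) for i, e in enumerate(errors)
    )
    masses = np.cumsum([200.0] + [71.03711 + e for e in errors])
    rec = make_record("s", 2000.0, masses, np.ones(4))
    t = score_pst(PST(hops=hops, residues="AAA"), rec)
    expected = math.sqrt(sum(e**2 for e in errors)) / 3  # N divides outside sqrt
    assert t.rmse == pytest.approx(expected, abs=1e-12)


def test_score_invariant_to_intensity_scaling(table):
    masses = [200.0, 271.03711, 328.05857]
    rec_a = make_record("s", 1000.0, masses, [2.0, 4.0, 8.0])
    rec_b = make_record("s", 1000.0, masses, [20.0, 40.0, 80.0])
    ta = extract_tags(rec_a, 0.001, 1, 10)
    tb = extract_tags(rec_b, 0.001, 1, 10)
    for a, b in zip(ta, tb):
        assert a.freq_score == pytest.approx(b.freq_score)
        assert a.error_score == pytest.approx(b.error_score)


def test_count_overlapping():
    assert count_overlapping("AAAA", "AA") == 3
    assert count_overlapping("GGAGG", "AG") == 1
    assert count_overlapping("GGAGG", "GA") == 1


def test_occurrence_counts_both_directions():
    protein = ProteinEntry("P", "", "GGAGG")
    tag = PST(hops=(), residues="AG", error_score=1.0, freq_score=16.0)
    # forward "AG" once, reversed "GA" once -> occurrence 2 -> 2 * (1 + 16)
    assert score_protein_psts(protein, [tag]) == pytest.approx(34.0)


def test_palindromic_tag_counted_once():
    protein = ProteinEntry("P", "", "GAGAG")
    tag = PST(hops=(), residues="GAG", error_score=1.0, freq_score=9.0)
    assert score_protein_psts(protein, [tag]) == pytest.approx(2 * (1 + 9))  # two overlapping GAG


def test_score_protein_psts_arithmetic_and_additivity():
    protein = ProteinEntry("P", "", "SAMPLERS")
    t1 = PST(hops=(), residues="AMP", error_score=1.0, freq_score=16.0)
    t2 = PST(hops=(), residues="LER", error_score=0.5, freq_score=9.0)
    t_absent = PST(hops=(), residues="WWW", error_score=1.0, freq_score=9.0)
    assert score_protein_psts(protein, []) == 0.0
    assert score_protein_psts(protein, [t_absent]) == 0.0
    total = score_protein_psts(protein, [t1, t2])
    assert total == pytest.approx(
        score_protein_psts(protein, [t1]) + score_protein_psts(protein, [t2])
    )
    assert score_protein_psts(protein, [t1]) == pytest.approx(17.0)


def test_tag_recovery_degrades_with_noise(rng, table):
    """Adding uniform noise peaks never increases (and eventually hurts)
    recovery of the true tag in extracted ladders."""
    recoveries = []
    for k_noise in (0, 10, 40):
        hits = 0
        for trial in range(20):
            entry = random_protein(rng, 10, accession=f"T{trial}")
            seq = entry.sequence.replace("I", "L")
            rec = ladder_record(seq, base_mass=250.0)
            masses = list(rec.masses)
            if k_noise:
                lo, hi = min(masses), max(masses)
                noise = []
                while len(noise) < k_noise:
                    m = rng.uniform(lo, hi)
                    if np.min(np.abs(np.array(masses) - m)) > 0.2:
                        noise.append(m)
                masses = masses + noise
            rec2 = make_record("s", rec.precursor_mass, masses, np.ones(len(masses)))
            tags = extract_tags(rec2, 0.005, 2, 15, rmse_tolerance=None, max_tags=None)
            if any(seq in t.residues or seq in t.residues[::-1] for t in tags):
                hits += 1
        recoveries.append(hits)
    assert recoveries[0] == 20
    assert recoveries[0] >= recoveries[1] >= recoveries[2]
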