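import base64
import struct
import zlib

import numpy as np
import pytest

from tdpsearch import (
    Peak,
    Proteoform,
    ProteinEntry,
    make_record,
    read_batch,
    read_spectra,
    write_results,
)
from tdpsearch.errors import ConfigurationError, FormatError
from tdpsearch.stats_scoring import PrSM

from conftest import write_minimal_mzml


def test_peak_invariants():
    with pytest.raises(ValueError):
        Peak(-1.0, 5.0)
    with pytest.raises(ValueError):
        Peak(100.0, -1.0)
    assert Peak(100.0, 0.0).intensity == 0.0  # zero intensity retained


def test_make_record_sorts_and_merges_duplicates():
    rec = make_record("s", 1000.0, [300.0, 100.0, 100.0 + 5e-7], [1.0, 2.0, 3.0])
    assert [p.mass for p in rec.peaks] == [100.0, 300.0]
    assert rec.peaks[0].intensity == 5.0  # duplicate masses merged, intensities summed


def test_mgf_single_block(tmp_path):
    p = tmp_path / "one.mgf"
    p.write_text(
        "BEGIN IONS\nTITLE=sp1\nPEPMASS=11236.15\n"
        "100.0 5.0\n200.0 7.0\n300.5 1.0\nEND IONS\n"
    )
    recs = read_spectra(p)
    assert len(recs) == 1
    assert recs[0].precursor_mass == 11236.15
    assert len(recs[0].peaks) == 3


def test_flat_text_requires_precursor(tmp_path):
    p = tmp_path / "peaks.txt"
    p.write_text("# comment\n100.0 5.0\n200.0,7.0\n")
    with pytest.raises(ConfigurationError):
        read_spectra(p)
    recs = read_spectra(p, precursor_mass=1000.0)
    assert len(recs) == 1
    assert [pk.mass for pk in recs[0].peaks] == [100.0, 200.0]


def test_flat_text_bad_line_names_location(tmp_path):
    p = tmp_path / "peaks.txt"
    p.write_text("100.0 5.0\nnot numbers here\n")
    with pytest.raises(FormatError, match="peaks.txt:2"):
        read_spectra(p, precursor_mass=1000.0)


def test_mzml_two_spectra_roundtrip(tmp_path):
    p = tmp_path / "two.mzml"
    write_minimal_mzml(
        p,
        [(3, 5000.0, [100.0, 200.0], [1.0, 2.0]), (7, 6000.0, [150.0, 151.0], [3.0, 4.0])],
    )
    recs = read_spectra(p)
    assert [r.scan_number for r in recs] == [3, 7]
    assert recs[1].precursor_mass == 6000.0
    np.testing.assert_allclose(recs[0].masses, [100.0, 200.0])


def test_mzxml_reader(tmp_path):
    masses, intens = [100.0, 250.0], [5.0, 6.0]
    interleaved = [v for pair in zip(masses, intens) for v in pair]
    payload = base64.b64encode(
        zlib.compress(struct.pack(f">{len(interleaved)}d", *interleaved))
    ).decode()
    p = tmp_path / "one.mzxml"
    p.write_text(
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">'
        '<msRun><scan num="9" msLevel="2"><precursorMz>4321.5</precursorMz>'
        f'<peaks precision="64" byteOrder="network" compressionType="zlib">{payload}</peaks>'
        "</scan></msRun></mzXML>"
    )
    recs = read_spectra(p)
    assert recs[0].scan_number == 9
    assert recs[0].precursor_mass == 4321.5
    np.testing.assert_allclose(recs[0].masses, masses)
    np.testing.assert_allclose(recs[0].intensities, intens)


def test_mgf_and_flat_text_agree(tmp_path):
    masses, intens, prec = [100.25, 205.5, 333.125], [4.0, 5.5, 0.5], 2500.0
    mgf_p = tmp_path / "a.mgf"
    mgf_p.write_text(
        "BEGIN IONS\nTITLE=x\nPEPMASS=2500.0\n"
        + "".join(f"{m} {i}\n" for m, i in zip(masses, intens))
        + "END IONS\n"
    )
    flat_p = tmp_path / "a.txt"
    flat_p.write_text("".join(f"{m} {i}\n" for m, i in zip(masses, intens)))
    a = read_spectra(mgf_p)[0]
    b = read_spectra(flat_p, precursor_mass=prec)[0]
    assert a.peaks == b.peaks
    assert a.precursor_mass == b.precursor_mass


def test_flat_text_roundtrip_six_decimals(tmp_path, rng):
    masses = np.sort(rng.uniform(100, 5000, size=50))
    intens = rng.uniform(0, 100, size=50)
    p = tmp_path / "rt.txt"
    p.write_text("".join(f"{m:.6f} {i:.6f}\n" for m, i in zip(masses, intens)))
    rec = read_spectra(p, precursor_mass=9000.0)[0]
    np.testing.assert_allclose(rec.masses, np.round(masses, 6), atol=1e-9)
    np.testing.assert_allclose(rec.intensities, np.round(intens, 6), atol=1e-9)


def test_batch_ordering_and_empty(tmp_path, caplog):
    for name in ["b.txt", "a.txt", "c.txt"]:
        (tmp_path / name).write_text("100.0 1.0\n")
    recs = read_batch(tmp_path, "flat_text", precursor_mass=500.0)
    assert [r.spectrum_id for r in recs] == ["a.txt", "b.txt", "c.txt"]
    empty = tmp_path / "empty"
    empty.mkdir()
    assert read_batch(empty, "flat_text") == []


def _dummy_prsm(score, accession="P1", spectrum_id="s1", decoy=False):
    entry = ProteinEntry(accession, "", "SAMPLEK", is_decoy=decoy,
                         decoy_of="P0" if decoy else None)
    return PrSM(
        spectrum_id=spectrum_id,
        proteoform=Proteoform(base=entry),
        score_mass=0.5,
        score_pst=12.25,
        score_insilico=0.333333,
        score_final=score,
        n_matched=7,
        e_value=1.23456e-8,
        q_value=0.01,
    )


def test_write_results_empty_and_roundtrip(tmp_path):
    out = tmp_path / "results.tsv"
    write_results([], out)
    assert out.read_text().count("\n") == 1  # header only

    write_results([_dummy_prsm(3.5)], out)
    lines = out.read_text().splitlines()
    assert len(lines) == 2
    row = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
    assert row["accession"] == "P1"
    assert float(row["score_final"]) == pytest.approx(3.5)
    assert float(row["e_value"]) == pytest.approx(1.23456e-8, rel=1e-5)


def test_write_results_sorted_by_score(tmp_path, rng):
    prsms = [_dummy_prsm(float(s), spectrum_id=f"s{i}") for i, s in enumerate(rng.uniform(0, 10, 100))]
    out = tmp_path / "results.tsv"
    write_results(prsms, out)
    scores = [float(l.split("\t")[9]) for l in out.read_text().splitlines()[1:]]
    assert scores == sorted(scores, reverse=True)
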