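import base64
import struct
import zlib

import numpy as np
import pytest

from tdpsearch import ProteinEntry, Proteoform, make_record
from tdpsearch.chem import residue_table


@pytest.fixture
def table():
    return residue_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ladder_record(sequence, base_mass=200.0, precursor=None, intensities=None,
                  spectrum_id="ladder", table=None, mode="CID"):
    """Spectrum whose peaks are cumulative residue sums from a base mass, so
    consecutive peaks differ by exactly one residue (a clean tag ladder)."""
    if table is None:
        table = residue_table()
    masses = [base_mass]
    for r in sequence:
        masses.append(masses[-1] + table.masses[r])
    if intensities is None:
        intensities = np.ones(len(masses))
    if precursor is None:
        precursor = masses[-1] + 500.0
    return make_record(spectrum_id, precursor, masses, intensities,
                       fragmentation_mode=mode)


def random_protein(rng, length, accession="P1"):
    from tdpsearch.chem import AMINO_ACIDS
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinEntry(accession, "random", seq)


def _encode_array(values):
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(zlib.compress(raw)).decode()


def write_minimal_mzml(path, spectra):
    """Write a minimal-but-valid mzML file (64-bit, zlib) for reader tests.

    ``spectra`` is a list of (scan_number, precursor_mass, masses, intensities).
    """
    chunks = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="1"><cv id="MS" fullName="PSI-MS" URI="http://psi.hupo.org"/></cvList>',
        '<run id="run1">',
        f'<spectrumList count="{len(spectra)}">',
    ]
    for i, (scan, prec, masses, intens) in enumerate(spectra):
        mz_b64 = _encode_array(masses)
        int_b64 = _encode_array(intens)
        chunks.append(f'''<spectrum index="{i}" id="scan={scan}" defaultArrayLength="{len(masses)}">
<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
<precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>
<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{prec}"/>
</selectedIon></selectedIonList></precursor></precursorList>
<binaryDataArrayList count="2">
<binaryDataArray encodedLength="{len(mz_b64)}">
<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
<binary>{mz_b64}</binary></binaryDataArray>
<binaryDataArray encodedLength="{len(int_b64)}">
<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
<binary>{int_b64}</binary></binaryDataArray>
</binaryDataArrayList></spectrum>''')
    chunks += ["</spectrumList>", "</run>", "</mzML>"]
    path.write_text("\n".join(chunks))
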