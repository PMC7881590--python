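"""Shared fixtures: small synthetic matrices and minimal spectrum files.

All fixtures are generated programmatically; the mzML/mzXML writers emit
minimal synthetic files (base64-encoded arrays) sufficient for the readers.
"""

from __future__ import annotations

import base64
import struct

import numpy as np
import pytest

from chickn import KernelConfig, generate_matrix, two_cluster_spec


@pytest.fixture
def small_matrix():
    """60-column two-cluster synthetic matrix with labels."""
    return generate_matrix(two_cluster_spec(seed=42))


@pytest.fixture
def kernel_cfg():
    return KernelConfig(p=2, gamma=0.05)


def _b64_doubles(values) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode()


def write_mzml(path, scans):
    """Write a minimal synthetic mzML file.

    ``scans`` is a list of (ms_level, rt_seconds, mz_array, intensity_array).
    """
    spectra = []
    for i, (level, rt, mz, inten) in enumerate(scans):
        spectra.append(f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time"
                     value="{rt}" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{_b64_doubles(mz)}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{_b64_doubles(inten)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="synthetic">
    <spectrumList count="{len(scans)}">{"".join(spectra)}
    </spectrumList>
  </run>
</mzML>
"""
    with open(path, "w") as f:
        f.write(doc)


def write_mzxml(path, scans):
    """Write a minimal synthetic mzXML file (same scans signature)."""
    body = []
    for i, (level, rt, mz, inten) in enumerate(scans):
        pairs = np.empty(2 * len(mz))
        pairs[0::2] = mz
        pairs[1::2] = inten
        raw = struct.pack(f">{len(pairs)}d", *pairs)  # network byte order
        b64 = base64.b64encode(raw).decode()
        body.append(f"""
    <scan num="{i + 1}" msLevel="{level}" retentionTime="PT{rt}S" peaksCount="{len(mz)}">
      <peaks compressionType="none" compressedLen="0" precision="64"
             byteOrder="network" contentType="m/z-int">{b64}</peaks>
    </scan>""")
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">
  <msRun scanCount="{len(scans)}">{"".join(body)}
  </msRun>
</mzXML>
"""
    with open(path, "w") as f:
        f.write(doc)
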