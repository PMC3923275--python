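"""Centroided MS1 spectrum container and mzML round-trip.

Reading is a compact lxml-based mzML 1.1 parser covering the subset the
pipeline consumes: centroided MS1 scans with 32/64-bit float peak arrays,
uncompressed or zlib-compressed, retention times normalized to seconds; MS2
scans are skipped.  Writing emits a minimal but valid mzML 1.1 document
(64-bit little-endian arrays, uncompressed, centroid MS1) sufficient for
interchange with standard readers — the simulator uses it so every pipeline
stage can be exercised from files on disk.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
from xml.sax.saxutils import escape

import numpy as np
from lxml import etree

__all__ = ["Spectrum", "read_ms1", "write_mzml", "NoMS1Error"]


@dataclass(frozen=True)
class Spectrum:
    """One centroided MS1 scan: retention time (s) and peak arrays."""

    scan_id: str
    rt_s: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])


class NoMS1Error(ValueError):
    """The mzML file contains no MS1 scans."""


# cvParam accessions the reader dispatches on
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"


def _cv_params(element) -> dict[str, dict]:
    out = {}
    for cv in element.iter("{*}cvParam"):
        out[cv.get("accession")] = dict(cv.attrib)
    return out


def _decode_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one binaryDataArray element → (array kind, values)."""
    params = _cv_params(bda)
    binary = bda.find("{*}binary")
    raw = base64.b64decode((binary.text or "").encode("ascii"))
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = "mz" if _ACC_MZ_ARRAY in params else (
        "intensity" if _ACC_INT_ARRAY in params else None
    )
    return kind, values


def read_ms1(path: str | Path) -> list[Spectrum]:
    """Read all centroided MS1 spectra from an mzML file, RT in seconds.

    Raises :class:`NoMS1Error` when the file holds no MS1 scans and
    ``lxml.etree.XMLSyntaxError`` (with the byte position) on malformed or
    truncated documents.
    """
    spectra: list[Spectrum] = []
    # iterparse keeps memory flat for many-scan files
    for _, elem in etree.iterparse(str(path), events=("end",), tag="{*}spectrum"):
        params = _cv_params(elem)
        level = int(params.get(_ACC_MS_LEVEL, {}).get("value", 1))
        if level == 1:
            rt_s = 0.0
            scan = elem.find("{*}scanList/{*}scan")
            if scan is not None:
                sp = _cv_params(scan)
                if _ACC_SCAN_START in sp:
                    attrs = sp[_ACC_SCAN_START]
                    rt_s = float(attrs["value"])
                    if attrs.get("unitName", "second").startswith("minute"):
                        rt_s *= 60.0
            arrays: dict[str, np.ndarray] = {}
            for bda in elem.iter("{*}binaryDataArray"):
                kind, values = _decode_array(bda)
                if kind:
                    arrays[kind] = values
            spectra.append(
                Spectrum(
                    scan_id=elem.get("id", f"scan={len(spectra) + 1}"),
                    rt_s=rt_s,
                    mz=arrays.get("mz", np.empty(0)),
                    intensity=arrays.get("intensity", np.empty(0)),
                )
            )
        elem.clear(keep_tail=True)
    if not spectra:
        raise NoMS1Error(f"no MS1 scans found in {path}")
    return spectra


def _b64_doubles(values: Sequence[float]) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


_SPECTRUM_TEMPLATE = """\
   <spectrum index="{index}" id="{sid}" defaultArrayLength="{n}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    <scanList count="1">
     <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
     <scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
     </scan>
    </scanList>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{mz_len}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
      <binary>{mz_b64}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{int_len}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
      <binary>{int_b64}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
"""


def write_mzml(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write centroid MS1 spectra as an uncompressed mzML 1.1 document."""
    spectra = list(spectra)
    chunks = []
    for i, spec in enumerate(spectra):
        mz_b64 = _b64_doubles(spec.mz.tolist())
        int_b64 = _b64_doubles(spec.intensity.tolist())
        chunks.append(
            _SPECTRUM_TEMPLATE.format(
                index=i,
                sid=escape(spec.scan_id, {'"': "&quot;"}),
                n=spec.mz.size,
                rt=repr(float(spec.rt_s)),
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        ' <cvList count="2">\n'
        '  <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
        '  <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>\n'
        " </cvList>\n"
        ' <fileDescription><fileContent>\n'
        '  <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
        '  <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
        " </fileContent></fileDescription>\n"
        ' <softwareList count="1"><software id="o18quant" version="0.1.0"/></softwareList>\n'
        ' <instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"/></instrumentConfigurationList>\n'
        ' <dataProcessingList count="1"><dataProcessing id="simulation">'
        '<processingMethod order="1" softwareRef="o18quant"/></dataProcessing></dataProcessingList>\n'
        ' <run id="run1" defaultInstrumentConfigurationRef="IC1">\n'
        f'  <spectrumList count="{len(spectra)}" defaultDataProcessingRef="simulation">\n'
        + "".join(chunks)
        + "  </spectrumList>\n </run>\n</mzML>\n"
    )
    Path(path).write_text(doc, encoding="utf-8")
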