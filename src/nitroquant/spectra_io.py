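"""Centroided LC-MS/MS run model with mzML reading and writing.

Both directions are implemented over lxml: reading iterates ``<spectrum>``
elements and decodes base64 binary arrays (uncompressed or zlib, 32- or
64-bit floats); writing emits minimal, standards-conformant indexed mzML
1.1.0 (64-bit float arrays, no compression) that round-trips bit-exactly.
Retention times are minutes everywhere.  Scan identity is the native mzML
id string.
"""

from __future__ import annotations

import base64
import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import quoteattr

import numpy as np
from lxml import etree

__all__ = [
    "PrecursorInfo",
    "Spectrum",
    "Run",
    "read_mzml",
    "write_mzml",
    "ms2_iter",
    "centroid_profile",
]


@dataclass(frozen=True)
class PrecursorInfo:
    """Precursor selection metadata of an MS2 scan."""

    selected_mz: float
    charge: int | None = None
    isolation_center: float | None = None
    isolation_width: float | None = None

    def __post_init__(self) -> None:
        if self.isolation_width is not None and self.isolation_width <= 0:
            raise ValueError("isolation width must be positive")


@dataclass
class Spectrum:
    """One centroided scan: parallel m/z (ascending) and intensity arrays."""

    id: str
    ms_level: int
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor: PrecursorInfo | None = None
    resolution: float | None = None
    is_profile: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"spectrum {self.id}: m/z must be strictly ascending")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError(f"spectrum {self.id}: intensities must be finite and >= 0")
        if self.ms_level not in (1, 2):
            raise ValueError(f"spectrum {self.id}: ms_level must be 1 or 2")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """An ordered LC-MS/MS run (spectra by retention time)."""

    spectra: list[Spectrum] = field(default_factory=list)
    source: str | None = None
    metadata: str = ""

    def __post_init__(self) -> None:
        rts = [s.rt_min for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be in non-decreasing retention-time order")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


def ms2_iter(run: Run):
    """Yield only the MS2 spectra of *run* in retention-time order."""
    for spec in run.spectra:
        if spec.ms_level == 2:
            yield spec


def centroid_profile(spectrum: Spectrum) -> Spectrum:
    """Centroid a profile spectrum by apex picking.

    Local intensity maxima become sticks; the m/z of each is refined with a
    three-point parabolic fit through the apex and its neighbours.
    """
    mz, inten = spectrum.mz, spectrum.intensity
    if mz.size < 3:
        return Spectrum(
            spectrum.id, spectrum.ms_level, spectrum.rt_min, mz, inten,
            spectrum.precursor, spectrum.resolution, is_profile=False,
        )
    apex = np.where((inten[1:-1] > inten[:-2]) & (inten[1:-1] >= inten[2:]))[0] + 1
    out_mz, out_i = [], []
    for i in apex:
        y0, y1, y2 = inten[i - 1], inten[i], inten[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            step = 0.5 * (mz[i + 1] - mz[i - 1])
            out_mz.append(mz[i] + delta * step)
        else:
            out_mz.append(mz[i])
        out_i.append(y1)
    order = np.argsort(out_mz)
    return Spectrum(
        spectrum.id, spectrum.ms_level, spectrum.rt_min,
        np.asarray(out_mz)[order], np.asarray(out_i)[order],
        spectrum.precursor, spectrum.resolution, is_profile=False,
    )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _local(tag) -> str:
    tag = str(tag)
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, str]:
    """name -> value for the cvParams that are direct children of *elem*."""
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("name", "")] = child.get("value", "")
    return out


def _find_child(elem, name):
    for child in elem:
        if _local(child.tag) == name:
            return child
    return None


def _iter_named(elem, name):
    return (c for c in elem.iter() if _local(c.tag) == name)


def _decode_binary_array(bda, scan_context: str) -> tuple[str | None, np.ndarray]:
    params = _cv_params(bda)
    binary = _find_child(bda, "binary")
    raw = base64.b64decode(binary.text or "") if binary is not None else b""
    compressions = {"no compression", "zlib compression"}
    declared = [
        n for n in params
        if "compression" in n.lower()
    ]
    for name in declared:
        if name not in compressions:
            raise ValueError(f"{scan_context}: unsupported compression {name!r}")
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    if "32-bit float" in params:
        values = np.frombuffer(raw, dtype="<f4").astype(np.float64)
    else:  # 64-bit float is the default in practice
        values = np.frombuffer(raw, dtype="<f8").copy()
    kind = None
    if "m/z array" in params:
        kind = "mz"
    elif "intensity array" in params:
        kind = "intensity"
    return kind, values


def _parse_spectrum(elem) -> Spectrum:
    sid = elem.get("id", "")
    params = _cv_params(elem)
    ms_level = int(params.get("ms level", 1) or 1)
    is_profile = "profile spectrum" in params

    rt = 0.0
    resolution = None
    scan_list = _find_child(elem, "scanList")
    if scan_list is not None:
        scan = _find_child(scan_list, "scan")
        if scan is not None:
            for child in scan:
                name = _local(child.tag)
                if name == "cvParam" and child.get("name") == "scan start time":
                    rt = float(child.get("value", "0"))
                    if child.get("unitName", "minute") in ("second", "seconds"):
                        rt /= 60.0
                elif name == "userParam" and child.get("name") == "nominal resolution":
                    resolution = float(child.get("value"))

    precursor = None
    plist = _find_child(elem, "precursorList")
    if plist is not None:
        prec = _find_child(plist, "precursor")
        if prec is not None:
            center = lower = upper = None
            iso = _find_child(prec, "isolationWindow")
            if iso is not None:
                p = _cv_params(iso)
                center = p.get("isolation window target m/z")
                lower = p.get("isolation window lower offset")
                upper = p.get("isolation window upper offset")
            selected_mz, charge = None, None
            for sel in _iter_named(prec, "selectedIon"):
                p = _cv_params(sel)
                if "selected ion m/z" in p:
                    selected_mz = float(p["selected ion m/z"])
                if p.get("charge state"):
                    charge = int(float(p["charge state"]))
                break
            width = None
            if lower is not None and upper is not None:
                width = float(lower) + float(upper)
            if selected_mz is None:
                selected_mz = float(center) if center is not None else 0.0
            precursor = PrecursorInfo(
                selected_mz=selected_mz,
                charge=charge,
                isolation_center=float(center) if center is not None else None,
                isolation_width=width,
            )

    mz = np.array([])
    intensity = np.array([])
    for bda in _iter_named(elem, "binaryDataArray"):
        kind, values = _decode_binary_array(bda, f"spectrum {sid}")
        if kind == "mz":
            mz = values
        elif kind == "intensity":
            intensity = values
    return Spectrum(
        id=sid,
        ms_level=ms_level,
        rt_min=rt,
        mz=mz,
        intensity=intensity,
        precursor=precursor,
        resolution=resolution,
        is_profile=is_profile,
    )


def read_mzml(path: str | Path) -> Run:
    """Read an mzML file into a :class:`Run`.

    Profile spectra are flagged (``is_profile``), not centroided implicitly;
    missing precursor charge is preserved as ``None``; retention times are
    normalised to minutes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    metadata = ""
    try:
        for _event, elem in etree.iterparse(str(path), events=("end",)):
            name = _local(elem.tag)
            if name == "spectrum":
                spectra.append(_parse_spectrum(elem))
                elem.clear()
            elif name == "instrumentConfiguration":
                for up in elem:
                    if (
                        _local(up.tag) == "userParam"
                        and up.get("name") == "instrument description"
                    ):
                        metadata = up.get("value", "")
    except etree.XMLSyntaxError as exc:
        context = spectra[-1].id if spectra else "start of file"
        raise ValueError(
            f"malformed mzML in {path} (last good spectrum: {context}): {exc}"
        ) from exc
    return Run(spectra=spectra, source=str(path), metadata=metadata)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _b64(array: np.ndarray) -> str:
    return base64.b64encode(np.asarray(array, dtype="<f8").tobytes()).decode("ascii")


def _cv(accession: str, name: str, value: str | None = None, unit: tuple | None = None) -> str:
    parts = [f'<cvParam cvRef="MS" accession={quoteattr(accession)} name={quoteattr(name)}']
    parts.append(f" value={quoteattr(value if value is not None else '')}")
    if unit:
        uref, uacc, uname = unit
        parts.append(
            f" unitCvRef={quoteattr(uref)} unitAccession={quoteattr(uacc)}"
            f" unitName={quoteattr(uname)}"
        )
    parts.append("/>")
    return "".join(parts)


def _binary_array(array: np.ndarray, kind_cv: str) -> str:
    data = _b64(array)
    return (
        f'<binaryDataArray encodedLength="{len(data)}">'
        + _cv("MS:1000523", "64-bit float")
        + _cv("MS:1000576", "no compression")
        + kind_cv
        + f"<binary>{data}</binary></binaryDataArray>"
    )


def _spectrum_xml(spec: Spectrum, index: int) -> str:
    parts = [
        f'<spectrum index="{index}" id={quoteattr(spec.id)} '
        f'defaultArrayLength="{len(spec)}">'
    ]
    parts.append(_cv("MS:1000511", "ms level", str(spec.ms_level)))
    if spec.ms_level == 1:
        parts.append(_cv("MS:1000579", "MS1 spectrum"))
    else:
        parts.append(_cv("MS:1000580", "MSn spectrum"))
    if spec.is_profile:
        parts.append(_cv("MS:1000128", "profile spectrum"))
    else:
        parts.append(_cv("MS:1000127", "centroid spectrum"))
    parts.append('<scanList count="1">')
    parts.append(_cv("MS:1000795", "no combination"))
    parts.append("<scan>")
    parts.append(
        _cv(
            "MS:1000016",
            "scan start time",
            repr(spec.rt_min),
            ("UO", "UO:0000031", "minute"),
        )
    )
    if spec.resolution is not None:
        parts.append(
            f'<userParam name="nominal resolution" value={quoteattr(repr(spec.resolution))}'
            f' type="xsd:float"/>'
        )
    parts.append("</scan></scanList>")
    if spec.precursor is not None:
        p = spec.precursor
        parts.append('<precursorList count="1"><precursor>')
        if p.isolation_center is not None:
            half = (p.isolation_width or 0.0) / 2.0
            parts.append("<isolationWindow>")
            parts.append(
                _cv("MS:1000827", "isolation window target m/z", repr(p.isolation_center),
                    ("MS", "MS:1000040", "m/z"))
            )
            parts.append(
                _cv("MS:1000828", "isolation window lower offset", repr(half),
                    ("MS", "MS:1000040", "m/z"))
            )
            parts.append(
                _cv("MS:1000829", "isolation window upper offset", repr(half),
                    ("MS", "MS:1000040", "m/z"))
            )
            parts.append("</isolationWindow>")
        parts.append('<selectedIonList count="1"><selectedIon>')
        parts.append(
            _cv("MS:1000744", "selected ion m/z", repr(p.selected_mz),
                ("MS", "MS:1000040", "m/z"))
        )
        if p.charge is not None:
            parts.append(_cv("MS:1000041", "charge state", str(p.charge)))
        parts.append("</selectedIon></selectedIonList>")
        parts.append("<activation>" + _cv("MS:1000422", "beam-type collision-induced dissociation") + "</activation>")
        parts.append("</precursor></precursorList>")
    parts.append('<binaryDataArrayList count="2">')
    parts.append(
        _binary_array(spec.mz, _cv("MS:1000514", "m/z array", unit=("MS", "MS:1000040", "m/z")))
    )
    parts.append(
        _binary_array(
            spec.intensity,
            _cv("MS:1000515", "intensity array",
                unit=("MS", "MS:1000131", "number of detector counts")),
        )
    )
    parts.append("</binaryDataArrayList></spectrum>")
    return "".join(parts)


def write_mzml(run: Run, path: str | Path) -> None:
    """Write *run* as indexed mzML 1.1.0.

    Arrays are encoded as uncompressed 64-bit floats, so a write/read
    round-trip preserves peak arrays bit-identically.
    """
    path = Path(path)
    header = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        f'<indexedmzML xmlns="{_MZML_NS}">\n'
        f'<mzML xmlns="{_MZML_NS}" id="nitroquant_run" version="1.1.0">\n'
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>\n"
        "<fileDescription><fileContent>"
        + _cv("MS:1000579", "MS1 spectrum")
        + _cv("MS:1000580", "MSn spectrum")
        + "</fileContent></fileDescription>\n"
        '<softwareList count="1"><software id="nitroquant" version="0.1.0">'
        + _cv("MS:1000799", "custom unreleased software tool", "nitroquant")
        + "</software></softwareList>\n"
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1">'
        + _cv("MS:1000031", "instrument model")
        + (
            f'<userParam name="instrument description" value={quoteattr(run.metadata)}/>'
            if run.metadata
            else ""
        )
        + "</instrumentConfiguration></instrumentConfigurationList>\n"
        '<dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="1" softwareRef="nitroquant">'
        + _cv("MS:1000544", "Conversion to mzML")
        + "</processingMethod></dataProcessing></dataProcessingList>\n"
        '<run id="run1" defaultInstrumentConfigurationRef="IC1">\n'
        f'<spectrumList count="{len(run)}" defaultDataProcessingRef="DP1">\n'
    )
    chunks: list[bytes] = [header.encode("utf-8")]
    offsets: list[tuple[str, int]] = []
    pos = len(chunks[0])
    for i, spec in enumerate(run.spectra):
        xml = _spectrum_xml(spec, i).encode("utf-8") + b"\n"
        offsets.append((spec.id, pos))
        chunks.append(xml)
        pos += len(xml)
    footer = "</spectrumList>\n</run>\n</mzML>\n".encode("utf-8")
    chunks.append(footer)
    pos += len(footer)

    index_lines = ['<indexList count="1">\n<index name="spectrum">\n']
    for sid, off in offsets:
        index_lines.append(f"<offset idRef={quoteattr(sid)}>{off}</offset>\n")
    index_lines.append("</index>\n</indexList>\n")
    index_lines.append(f"<indexListOffset>{pos}</indexListOffset>\n")
    body = b"".join(chunks) + "".join(index_lines).encode("utf-8")
    sha1 = hashlib.sha1(body + b"<fileChecksum>").hexdigest()
    body += f"<fileChecksum>{sha1}</fileChecksum>\n</indexedmzML>\n".encode("utf-8")
    path.write_bytes(body)
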