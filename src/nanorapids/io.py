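"""File I/O: mzML/mzXML/JSON scan reading, minimal mzML/mzXML writing,
MGF and quantification-table export, plate/trace CSVs, GraphML, YAML
config.

Reading of the standard MS formats goes through pyteomics.  Writing
mzML/mzXML is only needed to materialize synthetic runs as standard
files, so the writers here emit a minimal, uncompressed, schema-valid
subset (64-bit arrays, no indexing) that pyteomics — and any compliant
reader — can open.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from xml.sax.saxutils import escape, quoteattr

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf
from pyteomics import mzxml as _mzxml

from .alignment import DelayModel
from .features import DetectionParams, Feature
from .mapping import BioactiveAssignment
from .plate import ROW_LETTERS, BioactivityTrace, PlateLayout, PlateRead
from .spectra import FragmentSpectrum, Scan

__all__ = [
    "read_msrun",
    "write_mzml",
    "write_mzxml",
    "write_scans_json",
    "write_fbmn_bundle",
    "read_mgf",
    "read_plate_csv",
    "write_plate_csv",
    "read_trace_csv",
    "write_trace_csv",
    "write_graphml",
    "write_edge_list",
    "write_assignments_csv",
    "write_delay_report",
    "read_delay_report",
    "PipelineConfig",
]


class MSFileError(RuntimeError):
    """Raised when an MS run file cannot be parsed."""


# ---------------------------------------------------------------------------
# scan reading


def _rt_minutes(value) -> float:
    """Normalize a pyteomics retention time (unitfloat) to minutes."""
    unit = getattr(value, "unit_info", None)
    v = float(value)
    if unit in ("second", "seconds", "s"):
        return v / 60.0
    return v  # pyteomics mzXML reader and our mzML writer use minutes


# mzML is parsed with a self-contained ElementTree reader covering the
# centroid-LC-MS/MS subset this pipeline consumes (64/32-bit arrays,
# zlib or no compression); the installed pyteomics mzML backend needs an
# extra CV package that is not part of this stack.

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(bda) -> np.ndarray:
    dtype = np.float64
    compressed = False
    kind = None
    payload = ""
    for el in bda.iter():
        tag = el.tag.replace(_MZML_NS, "")
        if tag == "cvParam":
            acc = el.get("accession", "")
            if acc == "MS:1000521":
                dtype = np.float32
            elif acc == "MS:1000523":
                dtype = np.float64
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif tag == "binary":
            payload = el.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _iter_mzml_spectra(path: Path):
    import xml.etree.ElementTree as ET

    for _, el in ET.iterparse(str(path)):
        if el.tag == f"{_MZML_NS}spectrum":
            yield el
            el.clear()


def _scan_from_mzml(spectrum, idx: int) -> Scan:
    ms_level = 1
    centroided = False
    rt = 0.0
    prec_mz = prec_z = prec_int = None
    arrays: dict[str, np.ndarray] = {}
    for el in spectrum.iter(f"{_MZML_NS}cvParam"):
        acc = el.get("accession", "")
        if acc == "MS:1000511":
            ms_level = int(el.get("value"))
        elif acc == "MS:1000127":
            centroided = True
        elif acc == "MS:1000016":
            rt = float(el.get("value"))
            if el.get("unitName", "minute").startswith("second"):
                rt /= 60.0
        elif acc == "MS:1000744":
            prec_mz = float(el.get("value"))
        elif acc == "MS:1000041":
            prec_z = int(el.get("value"))
        elif acc == "MS:1000042":
            prec_int = float(el.get("value"))
    for bda in spectrum.iter(f"{_MZML_NS}binaryDataArray"):
        kind, arr = _decode_binary_array(bda)
        if kind:
            arrays[kind] = arr
    mz = arrays.get("mz", np.empty(0))
    inten = arrays.get("intensity", np.empty(0))
    n = int(spectrum.get("defaultArrayLength", mz.size))
    if mz.size != n or inten.size != n:
        raise MSFileError(
            f"array length mismatch in spectrum {idx}: "
            f"expected {n}, got {mz.size}/{inten.size}"
        )
    order = np.argsort(mz, kind="stable")
    return Scan(
        ms_level, rt, mz[order], inten[order],
        centroided=centroided, scan_id=idx,
        precursor_mz=prec_mz, precursor_charge=prec_z,
        precursor_intensity=prec_int,
    )


def _scan_from_mzxml(entry: dict, idx: int) -> Scan:
    ms_level = int(entry.get("msLevel", 1))
    rt = _rt_minutes(entry.get("retentionTime", 0.0))
    prec_mz = prec_z = prec_int = None
    if ms_level == 2 and entry.get("precursorMz"):
        p = entry["precursorMz"][0]
        prec_mz = float(p["precursorMz"])
        prec_z = int(p.get("precursorCharge", 1))
        if "precursorIntensity" in p:
            prec_int = float(p["precursorIntensity"])
    mz = np.asarray(entry["m/z array"], dtype=float)
    inten = np.asarray(entry["intensity array"], dtype=float)
    order = np.argsort(mz, kind="stable")
    return Scan(
        ms_level, rt, mz[order], inten[order],
        centroided=entry.get("centroided", True) in (True, "1", 1),
        scan_id=idx, precursor_mz=prec_mz, precursor_charge=prec_z,
        precursor_intensity=prec_int,
    )


def _scan_from_json(entry: dict, idx: int) -> Scan:
    return Scan(
        int(entry["ms_level"]), float(entry["rt"]),
        np.asarray(entry["mz"], dtype=float),
        np.asarray(entry["intensity"], dtype=float),
        centroided=bool(entry.get("centroided", True)),
        scan_id=entry.get("scan_id", idx),
        precursor_mz=entry.get("precursor_mz"),
        precursor_charge=entry.get("precursor_charge"),
        precursor_intensity=entry.get("precursor_intensity"),
    )


def read_msrun(path: str | Path) -> list[Scan]:
    """Read an LC-MS/MS run (mzML, mzXML or internal scan JSON).

    Scans are returned RT-ordered with ms_level and precursor metadata
    preserved.  A malformed file raises :class:`MSFileError` rather
    than returning a silent partial result.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    scans: list[Scan] = []
    try:
        if suffix == ".json":
            data = json.loads(path.read_text())
            scans = [_scan_from_json(e, i) for i, e in enumerate(data["scans"])]
        elif suffix == ".mzml":
            scans = [
                _scan_from_mzml(e, i)
                for i, e in enumerate(_iter_mzml_spectra(path))
            ]
        elif suffix == ".mzxml":
            with _mzxml.MzXML(str(path)) as reader:
                scans = [_scan_from_mzxml(e, i) for i, e in enumerate(reader)]
        else:
            raise MSFileError(f"unsupported MS run format: {path.name}")
    except MSFileError:
        raise
    except Exception as exc:  # malformed XML/JSON/base64
        raise MSFileError(f"failed to parse {path.name}: {exc}") from exc
    scans.sort(key=lambda s: (s.rt, s.scan_id))
    return scans


# ---------------------------------------------------------------------------
# scan writing (synthetic runs -> standard formats)


def _b64(doubles: np.ndarray, big_endian: bool = False) -> str:
    fmt = ">" if big_endian else "<"
    raw = struct.pack(f"{fmt}{doubles.size}d", *doubles.astype(float))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(scans: list[Scan], path: str | Path) -> Path:
    """Write scans as minimal uncompressed mzML 1.1 (64-bit arrays)."""
    path = Path(path)
    out = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '  <cvList count="2">',
        '    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '    <cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        '  </cvList>',
        '  <run id="run">',
        f'    <spectrumList count="{len(scans)}">',
    ]
    for i, s in enumerate(scans):
        mz_b = _b64(s.mz)
        int_b = _b64(s.intensity)
        out.append(
            f'      <spectrum index="{i}" id="scan={s.scan_id or i + 1}" '
            f'defaultArrayLength="{s.mz.size}">'
        )
        out.append(
            f'        <cvParam cvRef="MS" accession="MS:1000511" '
            f'name="ms level" value="{s.ms_level}"/>'
        )
        if s.centroided:
            out.append(
                '        <cvParam cvRef="MS" accession="MS:1000127" '
                'name="centroid spectrum" value=""/>'
            )
        out.append('        <scanList count="1"><scan>')
        out.append(
            f'          <cvParam cvRef="MS" accession="MS:1000016" '
            f'name="scan start time" value="{s.rt:.6f}" '
            f'unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
        )
        out.append('        </scan></scanList>')
        if s.ms_level == 2 and s.precursor_mz is not None:
            out.append('        <precursorList count="1"><precursor>')
            out.append('          <selectedIonList count="1"><selectedIon>')
            out.append(
                f'            <cvParam cvRef="MS" accession="MS:1000744" '
                f'name="selected ion m/z" value="{s.precursor_mz:.6f}"/>'
            )
            out.append(
                f'            <cvParam cvRef="MS" accession="MS:1000041" '
                f'name="charge state" value="{s.precursor_charge or 1}"/>'
            )
            if s.precursor_intensity is not None:
                out.append(
                    f'            <cvParam cvRef="MS" accession="MS:1000042" '
                    f'name="peak intensity" value="{s.precursor_intensity:.4f}"/>'
                )
            out.append('          </selectedIon></selectedIonList>')
            out.append('        </precursor></precursorList>')
        out.append('        <binaryDataArrayList count="2">')
        for accession, name, data in (
            ("MS:1000514", "m/z array", mz_b),
            ("MS:1000515", "intensity array", int_b),
        ):
            out.append(
                f'          <binaryDataArray encodedLength="{len(data)}">'
            )
            out.append(
                '            <cvParam cvRef="MS" accession="MS:1000523" '
                'name="64-bit float" value=""/>'
            )
            out.append(
                '            <cvParam cvRef="MS" accession="MS:1000576" '
                'name="no compression" value=""/>'
            )
            out.append(
                f'            <cvParam cvRef="MS" accession="{accession}" '
                f'name="{name}" value=""/>'
            )
            out.append(f'            <binary>{data}</binary>')
            out.append('          </binaryDataArray>')
        out.append('        </binaryDataArrayList>')
        out.append('      </spectrum>')
    out += ['    </spectrumList>', '  </run>', '</mzML>', '']
    path.write_text("\n".join(out))
    return path


def write_mzxml(scans: list[Scan], path: str | Path) -> Path:
    """Write scans as minimal mzXML 3.2 (network-order 64-bit pairs)."""
    path = Path(path)
    out = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f'  <msRun scanCount="{len(scans)}">',
    ]
    for i, s in enumerate(scans):
        interleaved = np.empty(2 * s.mz.size)
        interleaved[0::2] = s.mz
        interleaved[1::2] = s.intensity
        data = _b64(interleaved, big_endian=True)
        out.append(
            f'    <scan num="{i + 1}" msLevel="{s.ms_level}" '
            f'retentionTime="PT{s.rt * 60.0:.6f}S" '
            f'peaksCount="{s.mz.size}" centroided="{1 if s.centroided else 0}">'
        )
        if s.ms_level == 2 and s.precursor_mz is not None:
            attrs = f'precursorCharge="{s.precursor_charge or 1}"'
            if s.precursor_intensity is not None:
                attrs += f' precursorIntensity="{s.precursor_intensity:.4f}"'
            out.append(
                f'      <precursorMz {attrs}>{s.precursor_mz:.6f}</precursorMz>'
            )
        out.append(
            '      <peaks compressionType="none" compressedLen="0" '
            'precision="64" byteOrder="network" '
            f'contentType="m/z-int">{data}</peaks>'
        )
        out.append('    </scan>')
    out += ['  </msRun>', '</mzXML>', '']
    path.write_text("\n".join(out))
    return path


def write_scans_json(scans: list[Scan], path: str | Path) -> Path:
    """Write scans in the pipeline's internal JSON format."""
    path = Path(path)
    payload = {"scans": []}
    for s in scans:
        e = {
            "ms_level": s.ms_level,
            "rt": round(s.rt, 6),
            "mz": s.mz.tolist(),
            "intensity": s.intensity.tolist(),
            "centroided": s.centroided,
            "scan_id": s.scan_id,
        }
        if s.precursor_mz is not None:
            e["precursor_mz"] = round(s.precursor_mz, 6)
            e["precursor_charge"] = s.precursor_charge
            e["precursor_intensity"] = (
                round(s.precursor_intensity, 4)
                if s.precursor_intensity is not None else None
            )
        payload["scans"].append(e)
    path.write_text(json.dumps(payload))
    return path


# ---------------------------------------------------------------------------
# FBMN bundle (quantification table + MGF) and MGF round-trip


def write_fbmn_bundle(
    features: list[Feature], outdir: str | Path, sample: str = "sample"
) -> tuple[Path, Path]:
    """Export the feature quantification table (CSV) and MS2 MGF.

    Row ids in the CSV match MGF ``FEATURE_ID`` one-to-one; RT is
    minutes in the CSV and seconds (``RTINSECONDS``) in the MGF, per
    the FBMN convention.  Features without MS2 must have been filtered
    upstream; they are rejected here to keep the two files in lockstep.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = [f.id for f in features]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate feature ids in export")
    rows = []
    for f in features:
        if f.ms2 is None:
            raise ValueError(f"feature {f.id} has no MS2; filter rows first")
        rows.append(
            {
                "row ID": f.id,
                "row m/z": round(f.mz, 4),
                "row retention time": round(f.rt_apex, 4),
                f"{sample} Peak area": round(f.area, 4),
            }
        )
    csv_path = outdir / "feature_quantification.csv"
    cols = ["row ID", "row m/z", "row retention time", f"{sample} Peak area"]
    pd.DataFrame(rows, columns=cols).to_csv(csv_path, index=False)
    mgf_path = outdir / "ms2_spectra.mgf"
    entries = []
    for f in features:
        entries.append(
            {
                "m/z array": f.ms2.mz,
                "intensity array": f.ms2.intensity,
                "params": {
                    "FEATURE_ID": f.id,
                    "PEPMASS": f.ms2.precursor_mz,
                    "RTINSECONDS": round(f.rt_apex * 60.0, 3),
                    "SCANS": f.id,
                    "CHARGE": f"{f.ms2.charge}+",
                },
            }
        )
    _mgf.write(entries, str(mgf_path), file_mode="w")
    return csv_path, mgf_path


def read_fbmn_bundle(
    csv_path: str | Path, mgf_path: str | Path
) -> list[Feature]:
    """Rebuild a feature table from an exported quantification CSV + MGF.

    Peak height is not part of the quantification-table convention, so
    the read-back features carry area as height; that preserves the
    (descending-abundance) orderings the downstream steps rely on.
    """
    df = pd.read_csv(csv_path)
    area_col = next(c for c in df.columns if c.endswith("Peak area"))
    spectra = {s.feature_id: s for s in read_mgf(mgf_path)}
    feats = []
    for _, row in df.iterrows():
        fid = int(row["row ID"])
        rt = float(row["row retention time"])
        area = float(row[area_col])
        feats.append(
            Feature(
                id=fid, mz=float(row["row m/z"]), rt_apex=rt,
                rt_start=rt, rt_end=rt, height=area, area=area,
                ms2=spectra.get(fid),
            )
        )
    return feats


def read_mgf(path: str | Path) -> list[FragmentSpectrum]:
    """Read an MGF file into fragment spectra (FBMN dialect keys)."""
    out = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pep = params.get("pepmass", (0.0,))
            prec = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            charge = params.get("charge")
            z = int(charge[0]) if charge else 1
            fid = params.get("feature_id", params.get("scans"))
            rt = params.get("rtinseconds")
            out.append(
                FragmentSpectrum(
                    precursor_mz=prec,
                    peaks=np.column_stack(
                        [entry["m/z array"], entry["intensity array"]]
                    ),
                    charge=z,
                    feature_id=int(fid) if fid is not None else None,
                    rt=float(rt) / 60.0 if rt is not None else None,
                    name=params.get("name") or params.get("title"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# plate / trace CSVs


def write_plate_csv(read: PlateRead, path: str | Path) -> Path:
    """Plate CSV: header row of column indices, header column of row
    letters, blanks for unmeasured wells."""
    path = Path(path)
    rows, cols = read.grid.shape
    lines = ["," + ",".join(str(c) for c in range(1, cols + 1))]
    for r in range(rows):
        vals = [
            "" if not np.isfinite(v) else f"{v:.4f}" for v in read.grid[r]
        ]
        lines.append(ROW_LETTERS[r] + "," + ",".join(vals))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_plate_csv(path: str | Path) -> PlateRead:
    df = pd.read_csv(path, index_col=0)
    return PlateRead(df.to_numpy(dtype=float))


def write_trace_csv(trace: BioactivityTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"time_min": np.round(trace.times, 4),
         "response": np.round(trace.response, 6)}
    )
    df.to_csv(path, index=False)
    return path


def read_trace_csv(path: str | Path) -> BioactivityTrace:
    df = pd.read_csv(path)
    return BioactivityTrace(df["time_min"].to_numpy(),
                            df["response"].to_numpy())


# ---------------------------------------------------------------------------
# network / assignment / delay artifacts


def write_graphml(g: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(g, str(path))
    return path


def write_edge_list(g: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "node_a": u, "node_b": v,
            "cosine": d["cosine"],
            "matched_peaks": d["matched_peaks"],
            "mass_shift": d["mass_shift"],
        }
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(
        rows, columns=["node_a", "node_b", "cosine", "matched_peaks",
                       "mass_shift"]
    ).to_csv(path, sep="\t", index=False)
    return path


def write_assignments_csv(
    assignments: list[BioactiveAssignment], path: str | Path
) -> Path:
    path = Path(path)
    rows = []
    for asg in assignments:
        labels_by_feat: dict[int, list[str]] = {}
        for rel in asg.relations:
            labels_by_feat.setdefault(rel.to_feature, []).append(rel.label)
        if not asg.features:
            rows.append(
                {"peak_id": asg.peak.peak_id,
                 "peak_start": round(asg.peak.start_time, 4),
                 "peak_end": round(asg.peak.end_time, 4),
                 "feature_id": "", "mz": "", "rt": "", "height": "",
                 "relation_labels": ""}
            )
        for f in asg.features:
            rows.append(
                {
                    "peak_id": asg.peak.peak_id,
                    "peak_start": round(asg.peak.start_time, 4),
                    "peak_end": round(asg.peak.end_time, 4),
                    "feature_id": f.id,
                    "mz": round(f.mz, 4),
                    "rt": round(f.rt_apex, 4),
                    "height": round(f.height, 1),
                    "relation_labels": ";".join(
                        sorted(set(labels_by_feat.get(f.id, [])))
                    ),
                }
            )
    pd.DataFrame(
        rows, columns=["peak_id", "peak_start", "peak_end", "feature_id",
                       "mz", "rt", "height", "relation_labels"]
    ).to_csv(path, index=False)
    return path


def write_delay_report(model: DelayModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "delay_min": round(model.delay, 4),
                "ms_apex_min": round(model.ms_apex, 4),
                "bio_apex_min": round(model.bio_apex, 4),
                "calibrant": model.calibrant_name,
            },
            indent=2,
        )
        + "\n"
    )
    return path


def read_delay_report(path: str | Path) -> DelayModel:
    d = json.loads(Path(path).read_text())
    return DelayModel(
        delay=d["delay_min"], calibrant_name=d.get("calibrant", ""),
        ms_apex=d.get("ms_apex_min", float("nan")),
        bio_apex=d.get("bio_apex_min", float("nan")),
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips losslessly through YAML.

    Defaults are the published screening parameters.  Unknown keys in a
    config file are rejected with a message naming the offender.
    """

    detection: DetectionParams = field(default_factory=DetectionParams)
    layout: PlateLayout = field(default_factory=PlateLayout)
    bio_threshold: float = 0.8
    bio_min_width: int = 2
    delay: float | None = None
    delay_sanity_limit: float = 5.0
    cosine_threshold: float = 0.7
    min_matched: int = 4
    fragment_tol: float = 0.9
    precursor_tol: float = 0.02
    top_k: int | None = None
    library_score_min: float = 0.7
    library_matched_min: int = 3
    rt_tolerance: float = 0.1
    relation_mz_tol: float = 0.005
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict = {}
        for name, sub_cls in (("detection", DetectionParams),
                              ("layout", PlateLayout)):
            if name in data:
                sub = dict(data.pop(name) or {})
                valid = {f.name for f in fields(sub_cls)}
                unknown = set(sub) - valid
                if unknown:
                    raise ValueError(
                        f"unknown {name} config keys: {sorted(unknown)}"
                    )
                if "iso_charges" in sub:
                    sub["iso_charges"] = tuple(sub["iso_charges"])
                kwargs[name] = sub_cls(**sub)
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detection"]["iso_charges"] = list(d["detection"]["iso_charges"])
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
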