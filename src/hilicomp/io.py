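"""File I/O: mzML and CSV scan series, ROI/retention/descriptor tables.

mzML support covers the minimal centroid profile this pipeline needs:
MS1 spectra with 64-bit uncompressed base64 m/z and intensity arrays,
scan start times in minutes, and a polarity cvParam.  Profile spectra
are rejected on read — ROI extraction presumes centroided peaks.

The CSV scan-list dialect is three columns, ``rt_min, mz, intensity``,
one row per centroid, grouped by strictly increasing retention time.
"""

from __future__ import annotations

import base64
import json
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .descriptors import DescriptorTable
from .retention import MetaboliteTarget, RetentionMatrix
from .roi import ROIMatrix, ROIParams, Scan, ScanSeries

__all__ = [
    "write_mzml", "read_mzml",
    "write_scan_csv", "read_scan_csv",
    "write_roi_matrix", "read_roi_matrix",
    "write_retention_matrix", "read_retention_matrix",
    "write_descriptor_table", "read_descriptor_table",
    "read_targets_csv", "write_targets_csv",
]

_MZML_NS = "http://psi.hupo.org/ms/mzml"
_CV = {
    "ms_level": "MS:1000511",
    "centroid": "MS:1000127",
    "profile": "MS:1000128",
    "positive": "MS:1000130",
    "negative": "MS:1000129",
    "scan_start": "MS:1000016",
    "f64": "MS:1000523",
    "no_compression": "MS:1000576",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
}


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def write_mzml(series: ScanSeries, path: str | Path) -> None:
    """Write a centroid mzML file (64-bit float, no compression)."""
    E = lambda tag, parent, **attrs: etree.SubElement(parent, f"{{{_MZML_NS}}}{tag}", **attrs)

    def cv(parent, accession, name, value="", **extra):
        etree.SubElement(parent, f"{{{_MZML_NS}}}cvParam", cvRef="MS",
                         accession=accession, name=name, value=value, **extra)

    root = etree.Element(f"{{{_MZML_NS}}}mzML", nsmap={None: _MZML_NS}, version="1.1.0")
    run = E("run", root, id=series.run_id or "run1")
    slist = E("spectrumList", run, count=str(len(series.scans)))
    pol_acc = _CV[series.polarity]
    pol_name = f"{series.polarity} scan"
    for i, scan in enumerate(series.scans):
        sp = E("spectrum", slist, index=str(i), id=f"scan={i + 1}",
               defaultArrayLength=str(scan.mz.size))
        cv(sp, _CV["ms_level"], "ms level", "1")
        cv(sp, _CV["centroid"], "centroid spectrum")
        cv(sp, pol_acc, pol_name)
        sl = E("scanList", sp, count="1")
        sc = E("scan", sl)
        cv(sc, _CV["scan_start"], "scan start time", repr(float(scan.rt)),
           unitCvRef="UO", unitAccession="UO:0000031", unitName="minute")
        bal = E("binaryDataArrayList", sp, count="2")
        for acc, name, arr in ((_CV["mz_array"], "m/z array", scan.mz),
                               (_CV["intensity_array"], "intensity array", scan.intensity)):
            enc = _b64(arr)
            bda = E("binaryDataArray", bal, encodedLength=str(len(enc)))
            cv(bda, _CV["f64"], "64-bit float")
            cv(bda, _CV["no_compression"], "no compression")
            cv(bda, acc, name)
            E("binary", bda).text = enc
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="utf-8", pretty_print=True)


def read_mzml(path: str | Path, run_id: str = "") -> ScanSeries:
    """Read centroid MS1 spectra from an mzML file.

    Profile spectra are rejected: ROI extraction requires centroid data.
    Only 64-bit uncompressed binary arrays are supported.
    """
    tree = etree.parse(str(path))
    ns = {"m": _MZML_NS}
    scans: list[tuple[float, np.ndarray, np.ndarray]] = []
    polarity = "positive"
    for sp in tree.iterfind(".//m:spectrum", ns):
        accs = {e.get("accession") for e in sp.iterfind(".//m:cvParam", ns)}
        if _CV["profile"] in accs:
            raise ValueError("profile spectra are not supported; centroid the data first")
        if _CV["negative"] in accs:
            polarity = "negative"
        rt_el = sp.find(f".//m:cvParam[@accession='{_CV['scan_start']}']", ns)
        if rt_el is None:
            raise ValueError("spectrum without scan start time")
        rt = float(rt_el.get("value"))
        if rt_el.get("unitName") == "second":
            rt /= 60.0
        arrays = {}
        for bda in sp.iterfind(".//m:binaryDataArray", ns):
            baccs = {e.get("accession") for e in bda.iterfind("m:cvParam", ns)}
            if _CV["f64"] not in baccs or _CV["no_compression"] not in baccs:
                raise ValueError("only 64-bit uncompressed arrays are supported")
            raw = bda.findtext("m:binary", namespaces=ns) or ""
            data = np.frombuffer(base64.b64decode(raw), dtype="<f8")
            if _CV["mz_array"] in baccs:
                arrays["mz"] = data
            elif _CV["intensity_array"] in baccs:
                arrays["intensity"] = data
        scans.append((rt, arrays.get("mz", np.empty(0)),
                      arrays.get("intensity", np.empty(0))))
    scans.sort(key=lambda s: s[0])
    return ScanSeries([Scan(rt, mz, it) for rt, mz, it in scans],
                      polarity=polarity, run_id=run_id)


def write_scan_csv(series: ScanSeries, path: str | Path) -> None:
    rows = [(s.rt, mz, it) for s in series.scans for mz, it in zip(s.mz, s.intensity)]
    pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"]).to_csv(path, index=False)


def read_scan_csv(path: str | Path, polarity: str = "positive",
                  run_id: str = "") -> ScanSeries:
    df = pd.read_csv(path)
    need = {"rt_min", "mz", "intensity"}
    if not need <= set(df.columns):
        raise ValueError(f"scan CSV needs columns {sorted(need)}")
    scans = [Scan(float(rt), g["mz"].to_numpy(), g["intensity"].to_numpy())
             for rt, g in df.groupby("rt_min", sort=True)]
    return ScanSeries(scans, polarity=polarity, run_id=run_id)


def write_roi_matrix(matrix: ROIMatrix, csv_path: str | Path,
                     json_path: str | Path | None = None) -> None:
    """ROI matrix CSV (first column rt_min, columns headed by mean m/z to
    4 decimals) plus a JSON provenance sidecar."""
    df = pd.DataFrame(matrix.intensities,
                      columns=[f"{mz:.4f}" for mz in matrix.roi_mz])
    df.insert(0, "rt_min", matrix.rt_axis)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        prov = {"run_id": matrix.run_id, "polarity": matrix.polarity,
                "snr_fraction": matrix.params.snr_fraction,
                "mz_tolerance": matrix.params.mz_tolerance,
                "min_consecutive": matrix.params.min_consecutive,
                "roi_mz": [float(v) for v in matrix.roi_mz]}
        Path(json_path).write_text(json.dumps(prov, indent=1))


def read_roi_matrix(csv_path: str | Path,
                    json_path: str | Path | None = None) -> ROIMatrix:
    df = pd.read_csv(csv_path)
    rt = df.pop("rt_min").to_numpy(dtype=float)
    params, run_id, polarity, roi_mz = ROIParams(), "", "positive", None
    if json_path is not None:
        prov = json.loads(Path(json_path).read_text())
        params = ROIParams(prov["snr_fraction"], prov["mz_tolerance"],
                           prov["min_consecutive"])
        run_id, polarity = prov["run_id"], prov["polarity"]
        roi_mz = np.array(prov["roi_mz"], dtype=float)
    if roi_mz is None:
        roi_mz = np.array([float(c) for c in df.columns])
    return ROIMatrix(rt, roi_mz, df.to_numpy(dtype=float), params, run_id, polarity)


_DESIGN_COLS = ["phase", "pH", "ionic_strength", "replicate"]


def write_retention_matrix(D: RetentionMatrix, path: str | Path) -> None:
    """Matrix D as CSV: run_id index, design metadata columns first, then
    one column per metabolite (empty cell = masked)."""
    out = pd.concat([D.design, D.values.where(~D.mask)], axis=1)
    out.to_csv(path, index=True)


def read_retention_matrix(path: str | Path) -> RetentionMatrix:
    df = pd.read_csv(path, index_col=0)
    meta = [c for c in df.columns if c in _DESIGN_COLS or c == "replicate"]
    design = df[meta]
    values = df.drop(columns=meta).astype(float)
    return RetentionMatrix(design, values, values.isna())


def write_descriptor_table(table: DescriptorTable, path: str | Path) -> None:
    table.values.to_csv(path, index=True, index_label="compound")


def read_descriptor_table(path: str | Path) -> DescriptorTable:
    return DescriptorTable(pd.read_csv(path, index_col="compound"))


def write_targets_csv(targets: list[MetaboliteTarget], path: str | Path) -> None:
    pd.DataFrame([{"name": t.name, "family": t.family, "expected_mz": t.expected_mz,
                   "polarity": t.preferred_polarity} for t in targets]
                 ).to_csv(path, index=False)


def read_targets_csv(path: str | Path) -> list[MetaboliteTarget]:
    df = pd.read_csv(path)
    return [MetaboliteTarget(r["name"], r["family"], float(r["expected_mz"]),
                             r.get("polarity", "either"))
            for _, r in df.iterrows()]
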