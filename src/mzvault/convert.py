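"""mzML and CSV interchange.

mzML import streams MS1 spectra one at a time (memory bounded by a single
scan), emits one point per (m/z, intensity) array pair with the spectrum's
scan start time as RT, and drops points whose intensity falls below the
noise floor (default 1, applied only on mzML import). Scan times tagged in
minutes are converted to seconds. Profile and centroid data are not
distinguished; every surviving array pair becomes a point.

The mzML reader is a streaming lxml ``iterparse`` walker over ``spectrum``
elements, handling 32/64-bit float binary arrays with or without zlib
compression. It reads the MS1 subset of mzML this store ingests; it is not
a general-purpose mzML object model.

The CSV interchange schema is the 5-column
``[m/z, RT, intensity, XIC ID, isotope distribution ID]`` — comma
separator, '.' decimal point, floats at round-trip precision, an optional
header row detected by a non-numeric first field, and blank trace/envelope
fields read as the unassigned sentinel 0. CSV import applies no intensity
floor, so a CSV export re-imports losslessly.
"""

from __future__ import annotations

import base64
import csv
import os
import struct
import zlib
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, TextIO, Tuple

from lxml import etree

from .model import MsPoint, QueryWindow

__all__ = [
    "DEFAULT_INTENSITY_FLOOR",
    "CSV_HEADER",
    "import_mzml",
    "import_csv",
    "export_csv",
    "write_csv",
]

#: mzML import noise floor: points with intensity below this are excluded.
DEFAULT_INTENSITY_FLOOR = 1.0

CSV_HEADER = ["mz", "rt", "intensity", "xic_id", "envelope_id"]


# PSI-MS controlled-vocabulary accessions used by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


def _localname(el) -> str:
    return etree.QName(el).localname


def _cv_params(el) -> dict:
    """accession -> (value, unit name) over all cvParam descendants of el."""
    out = {}
    for cv in el.iter():
        if isinstance(cv.tag, str) and _localname(cv) == "cvParam":
            out[cv.get("accession")] = (cv.get("value"), cv.get("unitName"))
    return out


def _decode_binary_array(array_el, index: int) -> Tuple[str, List[float]]:
    kind = None
    fmt = "d"
    compressed = False
    text = ""
    for child in array_el:
        if not isinstance(child.tag, str):
            continue
        name = _localname(child)
        if name == "cvParam":
            acc = child.get("accession")
            if acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INTENSITY_ARRAY:
                kind = "intensity"
            elif acc == _ACC_F32:
                fmt = "f"
            elif acc == _ACC_F64:
                fmt = "d"
            elif acc == _ACC_ZLIB:
                compressed = True
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    width = struct.calcsize(fmt)
    if len(raw) % width:
        raise ValueError(f"spectrum {index}: binary array length not a multiple of {width}")
    values = list(struct.unpack("<%d%s" % (len(raw) // width, fmt), raw))
    return kind, values


def _scan_time_seconds(spectrum_el, index: int) -> float:
    for el in spectrum_el.iter():
        if not isinstance(el.tag, str) or _localname(el) != "cvParam":
            continue
        if el.get("accession") == _ACC_SCAN_START:
            value = float(el.get("value"))
            unit = el.get("unitName") or "minute"
            # mzML's customary scan-time unit is minutes
            return value * 60.0 if unit.startswith("minute") else value
    raise ValueError(f"spectrum {index}: missing scan start time")


def import_mzml(
    path: os.PathLike,
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
) -> Iterator[MsPoint]:
    """Stream an mzML file as MS1 points, grouped by spectrum in file order.

    Provisional ids number the emitted points 0, 1, ...; they are remapped
    to record indices when a store is built.
    """
    next_id = 0
    index = -1
    try:
        context = etree.iterparse(os.fspath(path), events=("end",), recover=False)
        for _, el in context:
            if not isinstance(el.tag, str) or _localname(el) != "spectrum":
                continue
            index += 1
            params = _cv_params(el)
            level = params.get(_ACC_MS_LEVEL)
            if level is not None and int(level[0]) != 1:
                el.clear()
                continue
            rt = _scan_time_seconds(el, index)
            mzs: List[float] = []
            intensities: List[float] = []
            for sub in el.iter():
                if isinstance(sub.tag, str) and _localname(sub) == "binaryDataArray":
                    kind, values = _decode_binary_array(sub, index)
                    if kind == "mz":
                        mzs = values
                    elif kind == "intensity":
                        intensities = values
            if len(mzs) != len(intensities):
                raise ValueError(
                    f"spectrum {index}: m/z and intensity arrays differ in length"
                )
            for mz, inten in zip(mzs, intensities):
                if inten < intensity_floor:
                    continue
                yield MsPoint(id=next_id, mz=mz, rt=rt, intensity=inten)
                next_id += 1
            el.clear()  # bound memory to one spectrum
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed mzML near spectrum {index + 1}: {exc}") from None


def _parse_float(field: str, name: str, line: int) -> float:
    try:
        return float(field)
    except ValueError:
        raise ValueError(f"line {line}: non-numeric {name} field {field!r}") from None


def _parse_id(field: str, name: str, line: int) -> int:
    field = field.strip()
    if field == "":
        return 0
    try:
        value = int(float(field))
    except ValueError:
        raise ValueError(f"line {line}: non-numeric {name} field {field!r}") from None
    if value < 0:
        raise ValueError(f"line {line}: negative {name} {value}")
    return value


def import_csv(path: os.PathLike) -> Iterator[MsPoint]:
    """Stream a 5-column CSV as points, one per row, segmentation included."""
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh)
        next_id = 0
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1:
                try:
                    float(row[0])
                except ValueError:
                    continue  # header row
            if len(row) != 5:
                raise ValueError(
                    f"line {lineno}: expected 5 columns, got {len(row)}"
                )
            yield MsPoint(
                id=next_id,
                mz=_parse_float(row[0], "m/z", lineno),
                rt=_parse_float(row[1], "RT", lineno),
                intensity=_parse_float(row[2], "intensity", lineno),
                trace_id=_parse_id(row[3], "XIC ID", lineno),
                envelope_id=_parse_id(row[4], "envelope ID", lineno),
            )
            next_id += 1


def write_csv(points: Sequence[MsPoint], out: TextIO) -> int:
    """Write points as CSV rows (with header); returns the row count."""
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for p in points:
        writer.writerow(
            [repr(p.mz), repr(p.rt), repr(p.intensity), p.trace_id, p.envelope_id]
        )
    return len(points)


def export_csv(store, window: Optional[QueryWindow], path: os.PathLike) -> int:
    """Export every in-window point (no summarization) with its current
    segmentation. ``window=None`` exports the full extent."""
    if window is None:
        window = QueryWindow.covering(store.bounds)
    else:
        window = window.with_budget(None)
    points = store.query(window)
    with open(path, "w", newline="") as fh:
        return write_csv(points, fh)
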