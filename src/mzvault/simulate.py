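"""Deterministic synthetic LC-MS data and query workloads.

The cloud generator emulates the shape of centroided MS1 data: molecules
appear as isotopic envelopes, each a small set of extracted-ion
chromatograms (traces) spaced 1.003/charge apart in m/z with
geometrically decaying peak heights, eluting as a Gaussian over retention
time and sampled once per scan. Points below the intensity floor are not
emitted. Uniform noise points carry trace id 0. Every non-noise point
carries its ground-truth trace and envelope id, so segmentation round
trips can be checked exactly. Identical seeds give identical clouds.

What this does not emulate: profile-mode peak shapes in m/z, detector
saturation, charge-state coelution artifacts, or the intensity
distributions of any particular instrument.

The path generator reproduces an interactive navigation workload: a
window is repeatedly mutated by a random jump drawn from six moves —
zoom-in, zoom-out, pan up/down in RT, pan up/down in m/z — so consecutive
windows overlap, the access pattern a point cache is designed for.
"""

from __future__ import annotations

import base64
import math
import os
import struct
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .model import DataBounds, MsPoint, QueryWindow

__all__ = [
    "CloudSpec",
    "PathSpec",
    "gen_cloud",
    "gen_query_paths",
    "write_mzml",
    "cloud_to_spectra",
]


@dataclass(frozen=True)
class CloudSpec:
    """Parameters of one synthetic LC-MS run.

    Defaults sketch a small peptide-like run: 40 envelopes of charge 1-3
    with 3-5 isotope peaks each over a 600 s gradient sampled every
    second, plus sparse uniform noise, intensity floor 1.
    """

    seed: int = 0
    n_envelopes: int = 40
    charges: Tuple[int, ...] = (1, 2, 3)
    min_isotopes: int = 3
    max_isotopes: int = 5
    rt_range: Tuple[float, float] = (0.0, 600.0)
    scan_interval: float = 1.0
    mz_range: Tuple[float, float] = (400.0, 1200.0)
    elution_sigma: Tuple[float, float] = (5.0, 20.0)
    apex_intensity: Tuple[float, float] = (50.0, 5000.0)
    isotope_decay: float = 0.7
    isotope_spacing: float = 1.003
    mz_jitter: float = 0.002
    noise_density: float = 0.05  # expected noise points per scan per Th
    noise_intensity: Tuple[float, float] = (1.0, 20.0)
    intensity_floor: float = 1.0


@dataclass(frozen=True)
class PathSpec:
    """Parameters of one adjacent-query navigation workload."""

    seed: int = 0
    queries_per_path: int = 100
    bounds: DataBounds = field(
        default_factory=lambda: DataBounds(400.0, 1200.0, 0.0, 600.0)
    )
    initial_fraction: float = 0.25  # initial window edge, as share of extent
    zoom_in: Tuple[float, float] = (0.5, 0.8)
    zoom_out: Tuple[float, float] = (1.25, 2.0)
    pan_fraction: Tuple[float, float] = (0.25, 0.75)
    budget: int = 1000


def gen_cloud(spec: CloudSpec) -> List[MsPoint]:
    """Generate a seeded synthetic point cloud with ground-truth ids."""
    lo_rt, hi_rt = spec.rt_range
    lo_mz, hi_mz = spec.mz_range
    if not (lo_rt < hi_rt) or not (lo_mz < hi_mz):
        raise ValueError("rt_range and mz_range must be non-degenerate")
    rng = np.random.default_rng(spec.seed)
    scans = np.arange(lo_rt, hi_rt, spec.scan_interval)
    points: List[MsPoint] = []
    next_trace = 1
    for env in range(1, spec.n_envelopes + 1):
        charge = int(rng.choice(spec.charges))
        n_iso = int(rng.integers(spec.min_isotopes, spec.max_isotopes + 1))
        base_mz = float(rng.uniform(lo_mz, hi_mz - n_iso * spec.isotope_spacing))
        mu = float(rng.uniform(lo_rt, hi_rt))
        sigma = float(rng.uniform(*spec.elution_sigma))
        apex = float(rng.uniform(*spec.apex_intensity))
        for k in range(n_iso):
            trace = next_trace
            next_trace += 1
            trace_mz = base_mz + k * spec.isotope_spacing / charge
            peak = apex * spec.isotope_decay**k
            heights = peak * np.exp(-0.5 * ((scans - mu) / sigma) ** 2)
            live = heights >= spec.intensity_floor
            jit = rng.uniform(-spec.mz_jitter, spec.mz_jitter, size=int(live.sum()))
            for rt, h, j in zip(scans[live], heights[live], jit):
                points.append(
                    MsPoint(
                        id=len(points),
                        mz=trace_mz + float(j),
                        rt=float(rt),
                        intensity=float(h),
                        trace_id=trace,
                        envelope_id=env,
                    )
                )
    n_noise = rng.poisson(spec.noise_density * len(scans) * (hi_mz - lo_mz))
    for _ in range(n_noise):
        points.append(
            MsPoint(
                id=len(points),
                mz=float(rng.uniform(lo_mz, hi_mz)),
                rt=float(rng.choice(scans)),
                intensity=float(rng.uniform(*spec.noise_intensity)),
                trace_id=0,
                envelope_id=0,
            )
        )
    return points


_MOVES = ("zoom_in", "zoom_out", "pan_rt_up", "pan_rt_down", "pan_mz_up", "pan_mz_down")


def _clamp_window(
    mz_lo: float, mz_hi: float, rt_lo: float, rt_hi: float, b: DataBounds, n: int
) -> QueryWindow:
    mz_w = min(mz_hi - mz_lo, b.max_mz - b.min_mz)
    rt_w = min(rt_hi - rt_lo, b.max_rt - b.min_rt)
    mz_lo = min(max(mz_lo, b.min_mz), b.max_mz - mz_w)
    rt_lo = min(max(rt_lo, b.min_rt), b.max_rt - rt_w)
    return QueryWindow(mz_lo, mz_lo + mz_w, rt_lo, rt_lo + rt_w, n)


def gen_query_paths(spec: PathSpec, n_paths: int) -> List[List[QueryWindow]]:
    """Seeded navigation paths: ``n_paths`` sequences of adjacent windows."""
    if spec.queries_per_path < 1:
        raise ValueError("queries_per_path must be >= 1")
    rng = np.random.default_rng(spec.seed)
    b = spec.bounds
    ext_mz = b.max_mz - b.min_mz
    ext_rt = b.max_rt - b.min_rt
    paths: List[List[QueryWindow]] = []
    for _ in range(n_paths):
        mz_w = ext_mz * spec.initial_fraction
        rt_w = ext_rt * spec.initial_fraction
        mz_lo = float(rng.uniform(b.min_mz, b.max_mz - mz_w))
        rt_lo = float(rng.uniform(b.min_rt, b.max_rt - rt_w))
        win = QueryWindow(mz_lo, mz_lo + mz_w, rt_lo, rt_lo + rt_w, spec.budget)
        path = [win]
        while len(path) < spec.queries_per_path:
            move = _MOVES[int(rng.integers(len(_MOVES)))]
            mz_w = win.mz_hi - win.mz_lo
            rt_w = win.rt_hi - win.rt_lo
            cx = (win.mz_lo + win.mz_hi) / 2
            cy = (win.rt_lo + win.rt_hi) / 2
            if move in ("zoom_in", "zoom_out"):
                f = float(rng.uniform(*(spec.zoom_in if move == "zoom_in" else spec.zoom_out)))
                mz_w *= f
                rt_w *= f
                win = _clamp_window(
                    cx - mz_w / 2, cx + mz_w / 2, cy - rt_w / 2, cy + rt_w / 2,
                    b, spec.budget,
                )
            else:
                f = float(rng.uniform(*spec.pan_fraction))
                dmz = mz_w * f if move == "pan_mz_up" else -mz_w * f if move == "pan_mz_down" else 0.0
                drt = rt_w * f if move == "pan_rt_up" else -rt_w * f if move == "pan_rt_down" else 0.0
                win = _clamp_window(
                    win.mz_lo + dmz, win.mz_hi + dmz,
                    win.rt_lo + drt, win.rt_hi + drt,
                    b, spec.budget,
                )
            path.append(win)
        paths.append(path)
    return paths


# -- minimal mzML writing for import tests --------------------------------

def cloud_to_spectra(
    points: Sequence[MsPoint],
) -> List[Tuple[float, List[Tuple[float, float]]]]:
    """Group points into (RT-seconds, [(mz, intensity), ...]) scans."""
    by_rt: Dict[float, List[Tuple[float, float]]] = {}
    for p in points:
        by_rt.setdefault(p.rt, []).append((p.mz, p.intensity))
    return [(rt, sorted(by_rt[rt])) for rt in sorted(by_rt)]


def _b64_doubles(values: Sequence[float]) -> str:
    return base64.b64encode(
        struct.pack("<%dd" % len(values), *values)
    ).decode("ascii")


_SPECTRUM_TMPL = """\
   <spectrum index="{index}" id="scan={index}" defaultArrayLength="{n}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
    <scanList count="1">
     <scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_value}" unitCvRef="UO" unitAccession="{unit_acc}" unitName="{unit_name}"/>
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

_MZML_TMPL = """\
<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <cvList count="2">
  <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
 </cvList>
 <run id="synthetic_run">
  <spectrumList count="{count}" defaultDataProcessingRef="dp">
{spectra}  </spectrumList>
 </run>
</mzML>
"""


def write_mzml(
    path: os.PathLike,
    spectra: Sequence[Tuple[float, Sequence[Tuple[float, float]]]],
    ms_levels: Sequence[int] = (),
    time_unit: str = "second",
) -> None:
    """Write a minimal single-run mzML file (synthetic; uncompressed f64).

    ``spectra`` is a list of (RT in seconds, [(mz, intensity), ...]);
    ``ms_levels`` optionally overrides the per-spectrum MS level
    (default: all MS1). Scan start times are tagged in ``time_unit``
    ("second" keeps the values bit-exact; "minute" exercises the
    importer's unit conversion).
    """
    if time_unit not in ("second", "minute"):
        raise ValueError("time_unit must be 'second' or 'minute'")
    unit_acc = "UO:0000010" if time_unit == "second" else "UO:0000031"
    chunks = []
    for index, (rt, pairs) in enumerate(spectra):
        level = ms_levels[index] if index < len(ms_levels) else 1
        mzs = [mz for mz, _ in pairs]
        ints = [i for _, i in pairs]
        mz_b64 = _b64_doubles(mzs)
        int_b64 = _b64_doubles(ints)
        chunks.append(
            _SPECTRUM_TMPL.format(
                index=index, n=len(pairs), ms_level=level,
                rt_value=repr(rt if time_unit == "second" else rt / 60.0),
                unit_acc=unit_acc, unit_name=time_unit,
                mz_len=len(mz_b64), mz_b64=mz_b64,
                int_len=len(int_b64), int_b64=int_b64,
            )
        )
    with open(path, "w") as fh:
        fh.write(_MZML_TMPL.format(count=len(spectra), spectra="".join(chunks)))
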