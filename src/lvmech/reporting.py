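"""Result extraction and report writing.

Hemodynamic summary (volumes, pressures, transvalvular gradients, stroke
work) from a steady-state cycle; global / regional / AHA-17-segment myofiber
stress and strain statistics at end-diastole and peak systole; CSV + VTK
report bundle with a reproducibility manifest.

End-diastole is the instant of mitral-valve closure (maximal LV volume);
peak systole is the instant of maximal LV pressure.  Statistics are
element-volume weighted (removing mesh-density bias); element-count-weighted
values are also derivable from the per-segment table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .circulation import MMHG, CycleSolution
from .fem import FemProblem, fiber_stress_strain_field
from .geometry import write_vtk

__all__ = [
    "HemodynamicSummary", "SegmentStressReport",
    "hemodynamic_summary", "segment_statistics", "stress_strain_report",
    "write_reports", "REGIONS",
]

REGIONS = {"basal": range(1, 7), "mid": range(7, 13), "apical": range(13, 18)}


@dataclass
class HemodynamicSummary:
    """Cycle-level physiology: volumes mL, pressures mmHg, EF as a fraction."""

    edv: float
    esv: float
    ef: float
    lv_sys: float
    lv_dia: float
    ao_sys: float
    ao_dia: float
    grad_mean: float
    grad_peak: float
    stroke_work: float

    def as_dict(self) -> dict:
        return asdict(self)


def hemodynamic_summary(cycle: CycleSolution) -> HemodynamicSummary:
    """Summarize one steady-state cycle.

    EDV/ESV are the LV cavity volume extrema; the ejection window is where
    aortic valve flow is positive; the transvalvular gradient is LV minus
    arterial pressure over that window (time-mean and peak).  LV diastolic
    pressure is taken at the end-diastolic (maximal volume) instant.
    Raises ``RuntimeError`` when the aortic valve never opens.
    """
    v = cycle.series("v_lv")
    p_lv = cycle.series("p_lv")
    p_art = cycle.series("p_art")
    q_av = cycle.series("q_av")
    eject = q_av > 0.0
    if not np.any(eject):
        raise RuntimeError("aortic valve never opens: non-physical calibration")
    edv = float(v.max())
    esv = float(v.min())
    i_ed = int(np.argmax(v))
    grad = (p_lv - p_art)[eject] / MMHG
    dv = np.diff(v, append=v[:1])
    stroke_work = float(-(p_lv / MMHG * dv).sum())
    return HemodynamicSummary(
        edv=edv, esv=esv, ef=(edv - esv) / edv,
        lv_sys=float(p_lv.max() / MMHG),
        lv_dia=float(p_lv[i_ed] / MMHG),
        ao_sys=float(p_art.max() / MMHG),
        ao_dia=float(p_art.min() / MMHG),
        grad_mean=float(grad.mean()),
        grad_peak=float(grad.max()),
        stroke_work=stroke_work,
    )


# --------------------------------------------------------------------------
# segment statistics
# --------------------------------------------------------------------------

@dataclass
class SegmentStressReport:
    """Volume-weighted myofiber stress/strain statistics.

    ``per_segment`` has one row per AHA segment (1..17); ``per_region`` one
    row per basal/mid/apical region; ``global_stats`` one row.  Columns:
    stress_ed/ps and strain_ed/ps mean and sd (kPa / dimensionless), element
    count and wall volume (mm^3).
    """

    per_segment: pd.DataFrame
    per_region: pd.DataFrame
    global_stats: pd.DataFrame
    ed_time: float
    ps_time: float


def _wstats(x: np.ndarray, w: np.ndarray):
    m = float(np.average(x, weights=w))
    sd = float(np.sqrt(np.average((x - m) ** 2, weights=w)))
    return m, sd


def segment_statistics(labels: np.ndarray, volumes: np.ndarray,
                       stress_ed: np.ndarray, strain_ed: np.ndarray,
                       stress_ps: np.ndarray, strain_ps: np.ndarray,
                       ed_time: float = 0.0,
                       ps_time: float = 0.0) -> SegmentStressReport:
    """Aggregate per-element fields into segment/region/global statistics."""
    if labels is None:
        raise ValueError("mesh has no AHA segment labels")
    fields = {"stress_ed": stress_ed, "strain_ed": strain_ed,
              "stress_ps": stress_ps, "strain_ps": strain_ps}

    def rows(groups):
        out = []
        for name, mask in groups:
            rec = {"group": name, "n_elements": int(mask.sum()),
                   "volume_mm3": float(volumes[mask].sum())}
            for fname, arr in fields.items():
                m, sd = _wstats(arr[mask], volumes[mask])
                rec[f"{fname}_mean"] = m
                rec[f"{fname}_sd"] = sd
            out.append(rec)
        return pd.DataFrame(out)

    seg_groups = [(s, labels == s) for s in range(1, 18)]
    missing = [s for s, m in seg_groups if not m.any()]
    if missing:
        raise ValueError(f"segments without elements: {missing}")
    reg_groups = [(name, np.isin(labels, list(segs)))
                  for name, segs in REGIONS.items()]
    glob = [("global", np.ones_like(labels, dtype=bool))]
    return SegmentStressReport(per_segment=rows(seg_groups),
                               per_region=rows(reg_groups),
                               global_stats=rows(glob),
                               ed_time=ed_time, ps_time=ps_time)


def _nearest_fem_index(cycle: CycleSolution, t_target: float) -> int:
    if cycle.fem_times is None or cycle.fem_solutions is None:
        raise ValueError("cycle carries no FEM wall states")
    return int(np.argmin(np.abs(cycle.fem_times - t_target)))


def stress_strain_report(problem: FemProblem, cycle: CycleSolution,
                         ed_time: Optional[float] = None,
                         ps_time: Optional[float] = None) -> SegmentStressReport:
    """Myofiber stress/strain statistics at end-diastole and peak systole.

    The instants default to maximal LV volume (mitral closure) and maximal LV
    pressure, mapped to the nearest stored wall state.
    """
    if ed_time is None:
        ed_time = float(cycle.time[np.argmax(cycle.series("v_lv"))])
    if ps_time is None:
        ps_time = float(cycle.time[np.argmax(cycle.series("p_lv"))])
    mesh = problem.mesh
    i_ed = _nearest_fem_index(cycle, ed_time)
    i_ps = _nearest_fem_index(cycle, ps_time)
    s_ed, e_ed, vols = fiber_stress_strain_field(problem, cycle.fem_solutions[i_ed])
    s_ps, e_ps, _ = fiber_stress_strain_field(problem, cycle.fem_solutions[i_ps])
    return segment_statistics(mesh.segment_label, vols, s_ed, e_ed, s_ps, e_ps,
                              ed_time=float(cycle.fem_times[i_ed]),
                              ps_time=float(cycle.fem_times[i_ps]))


# --------------------------------------------------------------------------
# report bundle
# --------------------------------------------------------------------------

def write_reports(summary: HemodynamicSummary,
                  segment_report: SegmentStressReport,
                  targets, outdir,
                  problem: Optional[FemProblem] = None,
                  cycle: Optional[CycleSolution] = None,
                  config_dict: Optional[dict] = None,
                  seed: Optional[int] = None) -> dict:
    """Write the CSV/VTK report bundle; returns the file map.

    Contents: measured-vs-simulated comparison table, per-segment statistics,
    cycle time series, ED/PS wall states with stress/strain fields (legacy
    VTK), and a JSON manifest with the config hash and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    rows = []
    tdict = targets.as_dict() if hasattr(targets, "as_dict") else dict(targets)
    sdict = summary.as_dict()
    display = {"ef": 100.0}
    for key, measured in tdict.items():
        if key not in sdict:
            continue
        sim = sdict[key]
        scale = display.get(key, 1.0)
        rows.append({"parameter": key,
                     "measured": measured * scale,
                     "simulated": sim * scale,
                     "relative_deviation": abs(sim - measured) / abs(measured)})
    comparison = pd.DataFrame(rows)
    files["comparison"] = outdir / "comparison_table.csv"
    comparison.to_csv(files["comparison"], index=False)

    files["segments"] = outdir / "segment_stress.csv"
    segment_report.per_segment.to_csv(files["segments"], index=False)
    files["regions"] = outdir / "region_stress.csv"
    segment_report.per_region.to_csv(files["regions"], index=False)
    files["global"] = outdir / "global_stress.csv"
    segment_report.global_stats.to_csv(files["global"], index=False)

    files["summary"] = outdir / "hemodynamic_summary.csv"
    pd.DataFrame([sdict]).to_csv(files["summary"], index=False)

    if cycle is not None:
        ts = pd.DataFrame({"t": cycle.time})
        for k, arr in cycle.fields.items():
            col = arr / MMHG if k.startswith("p_") else arr
            ts[k if not k.startswith("p_") else k + "_mmHg"] = col
        files["timeseries"] = outdir / "cycle_timeseries.csv"
        ts.to_csv(files["timeseries"], index=False)

    if problem is not None and cycle is not None \
            and cycle.fem_solutions is not None:
        for tag, t_target in (("ed", segment_report.ed_time),
                              ("ps", segment_report.ps_time)):
            i = _nearest_fem_index(cycle, t_target)
            sol = cycle.fem_solutions[i]
            stress, strain, _ = fiber_stress_strain_field(problem, sol)
            files[f"vtk_{tag}"] = outdir / f"{tag}.vtk"
            write_vtk(problem.mesh, files[f"vtk_{tag}"],
                      point_data={"displacement": sol.displacement},
                      cell_data={"fiber_stress_kPa": stress,
                                 "fiber_strain": strain})

    manifest = {
        "seed": seed,
        "config_sha256": (hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest() if config_dict is not None else None),
        "config": config_dict,
        "versions": _versions(),
    }
    files["manifest"] = outdir / "manifest.json"
    with open(files["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return files


def _versions() -> dict:
    import numpy, scipy, pandas
    from . import __version__
    return {"lvmech": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__}
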