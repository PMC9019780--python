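# lvmech — LV biomechanics of low-flow, low-gradient aortic stenosis

`lvmech` is a desk-scale computational-physiology pipeline for studying the
left ventricle (LV) in **low-flow, low-gradient (LFLG) aortic stenosis** —
the AS phenotype in which a failing ventricle cannot generate the usual high
transvalvular gradient (mean < 40 mmHg despite a small valve area). The
package builds a synthetic patient-like LV, couples it to a closed-loop
circulation with a stenotic aortic valve, calibrates the coupled model to
measured hemodynamics, and reports global and AHA 17-segment myofiber stress
and strain at end-diastole and peak systole. It is aimed at cardiovascular
biomechanics researchers who want a transparent, fully scriptable
re-implementation of this modeling workflow without a commercial FEM
platform.

## Model

* **Geometry** — a truncated-ellipsoid LV wall (dilated, near-spherical:
  eccentric remodeling; EDV preset 180 mL, wall 12→9 mm) meshed with
  quadratic tetrahedra, with rule-based myofiber architecture: helix angle
  linear across the wall from −60° (endocardium) to +60° (epicardium),
  unloaded sarcomere length 1.78→1.91 µm.
* **Passive myocardium** — Holzapfel–Ogden anisotropic hyperelasticity on
  the isochoric invariants,
  `Ψ = a/2b·e^{b(Ī₁−3)} + Σᵢ aᵢ/2bᵢ·(e^{bᵢ(Ī₄ᵢ−1)²}−1) + …`, with
  a = 3.354 kPa, b = 7.08, a_f = 2.501 kPa (remaining moduli null; vanishing
  exponents handled by their exact quadratic limit), plus a volumetric
  penalty `Ψ_vol = (1/D)((J²−1)/2 − ln J)`, D = 2/K.
* **Active contraction** — time-varying elastance fiber tension
  `σ_af = (T_max/2)·Ca₀²/(Ca₀²+ECa₅₀²(l))·(1−cos ω(t,l))` with
  length-dependent calcium sensitivity and a sarcomere-length-dependent
  relaxation time (T_max = 135.7 kPa, Ca₀ = 4.35 µmol/l, B = 4.750 µm⁻¹,
  l₀ = 1.58 µm, m = 1.0489 s/µm, b = −1.429 s).
* **FEM** — total-Lagrangian quasi-statics, 10-node tetrahedra, follower
  endocardial pressure, Newton with LU reuse; a cavity-volume-constrained
  (bordered) solve mode drives the circulation coupling.
* **Circulation** — five-compartment closed loop (LV, left atrium, right
  ventricle, arterial and pulmonary chambers); valves are diodes with
  resistances; aortic stenosis = raised aortic valve resistance. Blood
  volume is conserved to round-off by construction.
* **Calibration** — derivative-free tuning of
  {R_av, R_art, C_art, atrial elastance, T_max scale, passive a scale, total
  blood volume} so that the steady-state beat reproduces the measured
  targets (EF 25%, LV 128/12, aorta 116/45, gradients 15/25 mmHg), gated at
  10% on the key parameter set.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
from lvmech import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(), seed=1, outdir="results")
s = result.summary
print(f"EF {100*s.ef:.1f}%  LV {s.lv_sys:.0f}/{s.lv_dia:.0f} mmHg  "
      f"Ao {s.ao_sys:.0f}/{s.ao_dia:.0f} mmHg  "
      f"gradients {s.grad_mean:.1f}/{s.grad_peak:.1f} mmHg")
g = result.segment_report.global_stats.iloc[0]
print(f"fiber stress ED/PS {g.stress_ed_mean:.2f}/{g.stress_ps_mean:.1f} kPa, "
      f"strain ED/PS {g.strain_ed_mean:+.3f}/{g.strain_ps_mean:+.3f}")
```

prints (seed 1, about ten minutes on one CPU):

```
EF 25.0%  LV 130/9 mmHg  Ao 120/45 mmHg  gradients 14.3/26.3 mmHg
fiber stress ED/PS 4.21/69.3 kPa, strain ED/PS +0.061/-0.045
```

Reading: the calibrated beat reproduces the measured LFLG physiology — a
~25% ejection fraction at near-normal systolic pressure with a low (≪ 40
mmHg) mean transvalvular gradient. Myofiber strain is positive at
end-diastole (+0.07-scale filling stretch from the unloaded reference) and
negative at peak systole (shortening). Mean myofiber Cauchy stress is a few
kPa at end-diastole and several tens of kPa at peak systole; the systolic
magnitude is pinned by static equilibrium (≈3.5–4 × p·V_cavity/V_wall at the
calibrated pressure — see the equilibrium note in `docs/methods.md`), with
the regional ordering mid-wall > basal > apical.

The same run from a shell, plus the other tools:

```bash
lvmech run --seed 1 --out results        # full pipeline + report bundle
lvmech generate-geometry --out lv.vtk    # mesh with fibers and AHA labels
lvmech material-point --table twitch     # active-tension time course (CSV)
lvmech calibrate --out calibrated        # tuning only; writes reusable YAML
lvmech report --from results             # deviations from a finished run
```

`results/` contains the measured-vs-simulated comparison table, per-segment
and regional stress/strain CSVs, the cycle time series, ED/PS wall states as
legacy VTK, and a manifest (config hash, seed, versions).

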