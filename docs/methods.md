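# Methods

`lvmech` models the left ventricle (LV) of a patient with low-flow,
low-gradient (LFLG) aortic stenosis as a quasi-static anisotropic
hyperelastic body coupled to a closed-loop lumped circulation, calibrated so
that the simulated beat reproduces clinically measured hemodynamics. This
note records the model, its assumptions, the numerical choices, and what the
synthetic test bed does and does not establish.

## Geometry

The patient geometry (in the clinical workflow, a CT segmentation) is
replaced by a synthetic truncated ellipsoid of revolution. The endocardium
is the ellipsoid `x²/rs² + y²/rs² + z²/rl² = 1` cut by a flat basal plane at
`z = +truncation_height`; the epicardium is an outward normal offset whose
thickness tapers linearly from base to apex. Defaults (all in the config):

| parameter | default | rationale |
|---|---|---|
| long/short endocardial radius | 46 / 36.8 mm | near-spherical (ratio 0.8), the eccentric remodeling phenotype |
| end-diastolic cavity volume preset | 180 mL | dilated LV; the short radius is rescaled analytically to hit it |
| wall thickness base→apex | 12 → 9 mm | hypertensive pressure-overload remodeling; wall volume ≈ 160 mL (LV mass ≈ 170 g) |
| truncation height | 12 mm | basal cut above the equator |
| mesh edge length | 12 mm | ≈ 940 quadratic tetrahedra; see mesh convergence below |

The wall is meshed by a structured (meridian × azimuth × transmural) grid
split into tetrahedra with the Kuhn (translation-invariant, conforming)
pattern, apex closed by prisms sharing the pole edge, and every node —
corners and edge midpoints alike — evaluated from the analytic mapping, so
quadratic elements follow the curved surfaces exactly to interpolation
order. Surfaces carry endocardium/epicardium/base tags; the basal
endocardial ring closes the cavity with a flat cap for volume evaluation.
The mesh generator is deterministic; the cavity volume of the generated mesh
matches the analytic truncated-ellipsoid value to ~0.1% and the target EDV
within 2% (enforced).

The transmural coordinate (0 endocardium → 1 epicardium) is the normalized
distance to the two tagged surfaces. AHA-17 labels split the long axis into
an apical cap (bottom 15% of the axis) plus three equal thirds, with 6/6/4
azimuthal sectors on fixed azimuth boundaries; the segment-1 azimuth is an
arbitrary fixed reference, since the synthetic LV has no anatomical
landmarks.

## Fiber architecture

Per-element orthonormal triads (fiber f0, sheet s0, normal n0): the fiber
lies in the local circumferential–longitudinal plane at a helix angle
varying linearly with wall depth from −60° (endocardium) to +60°
(epicardium); the sheet direction is purely transmural (zero sheet angle —
with the sheet and fiber–sheet moduli null in the passive parameter set this
choice cannot affect stress). The local basis is built from the long axis
and the gradient of the transmural field; apex-pole elements with a
degenerate circumferential direction copy the nearest well-defined triad.
The unloaded sarcomere length rises linearly across the wall from 1.78 µm
(endocardium) to 1.91 µm (epicardium).

## Passive material

Holzapfel–Ogden strain energy on the isochoric invariants
(Ī₁, Ī₄f, Ī₄s, Ī₈fs):

Ψ_dev = a/(2b)·e^{b(Ī₁−3)} + Σ_{i=f,s} a_i/(2b_i)·(e^{b_i(Ī₄ᵢ−1)²}−1)
        + a_fs/(2b_fs)·(e^{b_fs Ī₈²}−1)

with the patient parameter set a = 3.354 kPa, b = 7.08, a_f = 2.501 kPa and
all remaining moduli null. A vanishing exponent is handled by its exact
quadratic limit, (a_f/2)(Ī₄f−1)². Fiber/sheet terms engage only in tension
(I₄ > 1); the switch is C¹-smoothed over |I₄−1| < 10⁻⁴ (fiber strains of a
few 10⁻⁵) because the hard switch puts every reference-state quadrature
point exactly on a tangent discontinuity, which destroys Newton convergence
near the unloaded state. Near-incompressibility uses
Ψ_vol = (1/D)·((J²−1)/2 − ln J) with D = 2/K and bulk modulus K = 1000 kPa
by default (J stays within ±3% in converged states); the raw D can be set
directly.

## Active contraction

Time-varying elastance fiber tension

σ_af(t, E_ff) = (T_max/2) · Ca₀²/(Ca₀² + ECa₅₀²(l)) · (1 − cos ω(t, l)),

with length-dependent calcium sensitivity
ECa₅₀ = Ca₀max/√(e^{B(l−l₀)} − 1), sarcomere length l = l_r·√(2E_ff+1),
rise phase ω = πt/t₀ for t < t₀, relaxation ω = π(t−t₀+t_r)/t_r until
t₀ + t_r with t_r = m·l + b, zero afterwards. Constants: T_max = 135.7 kPa,
Ca₀ = Ca₀max = 4.35 µmol/l, m = 1.0489 s/µm, b = −1.429 s, B = 4.750 µm⁻¹,
l₀ = 1.58 µm. Time-to-peak t₀ = 0.25 s and period 0.8 s (75 bpm) are
physiologic defaults exposed in the config. Sarcomere lengths at or below
l₀ are clamped (l₀ + 0.01 µm) so activation tends continuously to zero
instead of raising a domain error. Activation is spatially simultaneous;
the active Cauchy stress acts along the deformed fiber direction only (a
transverse active fraction, present in some model variants, is not applied).
Total stress is the additive passive + active split.

## Finite elements

Total-Lagrangian displacement formulation, 10-node tetrahedra with 4-point
quadrature, endocardial pressure as a follower load (with its exact
unsymmetric load stiffness), displacement-only near-incompressibility via
the volumetric penalty (locking controlled by the quadratic element order
and verified against the thick-sphere oracle). The imaged-diastole geometry
is the unloaded, stress-free reference — no inverse unloading step — which
biases end-diastolic stress/strain low and is the convention the reported
diastolic values use.

Basal constraint: all basal-plane nodes fixed axially, plus distributed
*azimuthal* springs (10 mN/mm per node) on the basal ring. The springs
remove the in-plane translation/rotation modes exactly where two point pins
would leave a near-mechanism: on a ~3 kPa-modulus wall, pins give a
stiffness ratio of ~10⁻⁸·‖K‖ for the rim-rotation mode and Newton directions
along it explode. Tangential springs exert no force in axisymmetric states,
so the sphere benchmark is unaffected, and they stay orders of magnitude
softer than the wall for any non-rigid deformation.

The material tangent is assembled from central finite differences of the
analytic second Piola–Kirchhoff stress (6 Voigt directions, step 10⁻⁶),
keeping the constitutive code single-sourced; the assembled tangent matches
a finite-difference residual to ~10⁻⁹ (tested). Newton iteration reuses the
sparse LU factorization across iterations and warm-started steps, refreshing
it when the residual contraction per iteration exceeds 0.3 and the
factorization is at least two iterations old; load steps bisect
automatically on divergence (down to 1/256 of the step). Convergence:
relative residual < 10⁻⁶ against the load scale.

Two solve modes: pressure-driven (`solve_static`) and cavity-volume-
constrained (`solve_volume_constrained`), the latter a bordered Newton
system in which the cavity pressure is the unknown conjugate to the volume
constraint (two back-solves of the same factorization per iteration; the
volume gradient is the analytic divergence-theorem expression, test-verified
against finite differences). The volume-constrained mode drives both the
response-surface tabulation and the circulation coupling, because it stays
well-posed through the stiff isovolumic phases where V(p) is nearly
vertical.

Cavity volume is the divergence-theorem surface integral over the deformed
endocardium closed by the basal-plane cap (exact translation invariance and
cubic scaling are tested).

## Circulation

Five-compartment closed loop: LV (FEM chamber, its tabulated response
surface, or an elastance surrogate), arterial chamber (compliance C_art),
right ventricle (elastance waveform), pulmonary chamber (compliance), left
atrium (elastance waveform). Aortic and mitral valves are ideal diodes in
series with resistances; the systemic branch carries a check valve
protecting the RV inflow, the pulmonic valve is a diode, and a small
pulmonary-venous resistance closes the loop into the atrium. Aortic stenosis
is imposed purely by raising the aortic valve resistance (a config knob; a
"classic AS" preset with a ≥40 mmHg gradient is available for qualitative
comparison). Volumes are the state; pressures derive from the
elastance/compliance laws, so total blood volume is conserved to round-off
by construction. Explicit stepping at dt = 1 ms.

The source publication's circuit constants are retained verbatim as
documentation (`PRINTED_SOURCE_CONSTANTS`); as typeset their magnitudes are
mutually inconsistent (the arterial resistance prints ~10¹⁰ × the aortic
valve resistance), so working values are physiologic starting points on the
package's kPa·s/mL system and the calibration owns the final numbers.

FEM coupling exchanges every 10 ms: the circuit is integrated with the LV
pressure interpolated linearly across the exchange interval, the FEM chamber
is solved at the resulting volume, and the end-of-interval pressure is
fixed-point iterated until consecutive trials agree within a 0.5%
volume-equivalent tolerance. Warm starts use a secant predictor
(extrapolation of the last two converged wall states). Steady state: peak
and trough of every chamber pressure change < 5% between consecutive cycles.

## Calibration

Targets are the measured patient values: EF 25%, LV 128/12 mmHg, aorta
116/45 mmHg, mean/peak transvalvular gradient 15/25 mmHg. Tuned scale
factors: aortic valve resistance, arterial resistance, arterial compliance,
atrial elastance amplitude, contractility (T_max) scale, passive matrix (a)
scale, total blood volume — each bounded within ×/÷100 of its start.
Nelder–Mead in log-scale space, deterministic for a fixed seed.

Convergence is gated on the key subset {EF, LV systolic, aortic systolic,
aortic diastolic, peak gradient} at 10%: the source model's own published
simulation misses LV diastolic pressure (12→6 mmHg) and the mean gradient
(15→17 mmHg) by more than 10%, so those two are reported in every bundle but
do not gate. The search objective is the key-set maximum deviation plus 0.2
× the all-target maximum, which keeps the non-gating targets pulling on the
solution without letting their unreachable floor flatten the objective.

Each candidate evaluation runs the closed loop to steady state against an
LV pressure–volume–time response surface tabulated beforehand by the
package's own FEM solver (volume-constrained solves on a 6 × 10 grid of
cavity volume × cycle time, chained with secant-predicted warm starts).
The surface splits into its fully-relaxed (passive) component and active
excess, to which the matrix and contractility scales apply multiplicatively
— exact at fixed deformation, approximate through the equilibrium shift.
The calibrated parameters are then verified by the fully coupled
FEM↔circulation run; if the coupled summary drifts beyond 80% of tolerance,
one correction pass retargets the surface calibration by the
surface-vs-coupled offset and re-runs the loop (the "iterative tuning"
step). The final reported numbers always come from the coupled run.

Identifiability: the hemodynamic targets pin the contractility scale well —
at the calibrated operating point the peak-systolic fiber tension is fixed
by equilibrium (see below) — while LV diastolic pressure and total blood
volume trade off along a preload direction; the reported EDV is therefore a
model outcome, not a target.

## Reported quantities and an equilibrium bound worth knowing

End-diastole is the instant of maximal LV volume (mitral closure); peak
systole the instant of maximal LV pressure, both mapped to the nearest
stored wall state. Myofiber stress is f̂·σf̂ (deformed unit fiber, total
Cauchy stress); myofiber strain is the Green–Lagrange fiber component
relative to the unloaded reference (hence positive diastolic, negative
systolic values). Statistics are element-volume weighted; per-segment,
per-region (basal 1–6, mid 7–12, apical 13–17) and global tables all
recompute from the same element fields, and the global mean equals the
volume-weighted composition of the segment means identically.

A static bound constrains what any equilibrium model can report: integrating
equilibrium over the wall of a cavity-pressurized body gives
∫_wall σ dV = p·V_cav·I (plus basal-reaction terms), and with active
contraction balanced by transverse compression the volume-averaged fiber
stress at peak systole evaluates to ≈3.5–4 × p·V_cav/V_wall. At ~128 mmHg
and this geometry that is 60–70 kPa — the model's reported value. Global
mean fiber stresses of a few kPa at such pressures would require a wall an
order of magnitude more massive than any LV; the package therefore reports
the equilibrium-consistent magnitudes, and comparisons against smaller
published magnitudes should rely on the orderings (systolic ≫ diastolic,
mid-wall above apical), which the model reproduces, rather than the scale.

## Synthetic test bed: what it shows and what it does not

The generator emulates the study conditions (dilated near-spherical LV,
EDV preset 180 mL, LFLG hemodynamics) but not: real CT-derived wall
irregularity, papillary muscles and trabeculation, atrial/outflow geometry
(reduced to boundary conditions and lumped chambers), regional material or
activation heterogeneity, or residual stress/inverse unloading. Passing
tests therefore demonstrate correctness of the mechanics, coupling,
calibration machinery and reporting on a controlled geometry — not
patient-specific accuracy. Agreement with the published per-segment values
is expected only at the level of orderings and gross magnitudes.

## Problem sizes and tolerances (defaults)

Mesh ≈ 940 quadratic tetrahedra (≈ 4,900 dofs; the refinement test doubles
the element count and bounds the change in the global stress statistics by
5%);
response surface 6 volumes × 10 times; calibration budget 200 evaluations;
2 coupled confirmation cycles at 10 ms exchange / 1 ms circulation steps.
Newton relative residual 10⁻⁶; volume constraint 10⁻⁸ relative; cavity
volume vs analytic geometry < 1%; blood volume drift < 10⁻⁶ relative over
10 cycles.

## Known limitations

- No inverse unloading: diastolic stresses/strains are measured from the
  imaged-diastole reference and are biased accordingly.
- The response-surface emulator interpolates the twitch in time; fast
  isovolumic transients are resolved only at the exchange step in the
  coupled run (peak-gradient estimates carry a few-percent discretization
  sensitivity).
- The basal springs are a regularization, not anatomy; stresses in the one
  element ring at the base inherit the constraint choice.
- Explicit circulation stepping requires the (physiologic) parameter ranges
  the calibration bounds enforce; extreme compliances would need a smaller
  dt.
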