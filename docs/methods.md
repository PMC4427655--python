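# Methods

`cardiosim` is a desk-scale, reduced-order model of human left-ventricular
function with ischemic mitral regurgitation (IMR) and its correction by an
undersized annuloplasty ring carrying a sub-valvular element.  This note
documents the models, their assumptions, the parameters that matter, and the
limits of what the simulations can show.  Units are fixed package-wide:
kPa, mL, mm, s.

## Passive myocardium

The passive response is an orthotropic exponential (Holzapfel–Ogden-type)
strain-energy density in the local fiber/sheet/normal frame:

Ψ = a/(2b)·(e^{b(I₁−3)} − 1) − a·ln J
  + Σ_{i∈{ff,ss}} aᵢ/(2bᵢ)·(e^{bᵢ⟨I₄ᵢ−1⟩²} − 1)
  + a_fs/(2b_fs)·(e^{b_fs I₈fs²} − 1) + (k/2)(ln J)²

with full (non-isochoric) invariants, tension-only fiber/sheet switches
⟨x⟩ = max(x, 0), and near-incompressibility enforced by k ≫ a.  The
−a·ln J term is the standard compensation that makes the reference
configuration exactly stress-free when full invariants are used; it vanishes
identically on isochoric deformations, so it does not affect shear or
uniaxial isochoric responses.  The default parameter set is the transversely
isotropic normal-human one: k = 1000 kPa, a = 0.33 kPa, b = 7.08,
a_ff = 0.25 kPa, b_ff = 5.34, a_ss = b_ss = a_fs = b_fs = 0.

Virtual simple-shear rigs produce true-stress/true-strain curves for the six
modes FS, FN, SF, SN, NF, NS.  Mode "XY" applies F = I + γ(e_Y ⊗ e_X), so
material lines along X are rotated and stretched (I₄X = 1 + γ²).  Under
this convention FN and FS are the fiber-stiff modes, and fitting (a, b,
a_ff, b_ff) to FN+FS curves is well-posed — the alternative convention
(stretching the *second* axis) leaves the fiber term invisible in FN/FS and
makes such a fit singular, which is why we fixed the convention this way.

## Leaflet, chordae and active laws

Mitral leaflet directions (circumferential, radial) and chordae groups
(basal, marginal) each follow a decoupled two-parameter exponential law
σ(ε) = A(e^{Bε} − 1) on true strain; chordae are tension-only.  Defaults
(leaflet: circumferential A = 20 kPa, B = 25; radial A = 15 kPa, B = 15;
chordae: basal A = 40 kPa, B = 45; marginal A = 25 kPa, B = 60) are chosen
so that at 10% strain the circumferential direction is stiffer than the
radial and the marginal chordae stiffer than the basal, the qualitative
ordering of porcine leaflet and chordae measurements, with chordae reaching
MPa-scale stresses at a few percent strain.

Active contraction is a prescribed squared-sine fiber-tension pulse
T = T_max·sin²(π(t − t_act)/t_dur)·max(0, 1 + β(λ − 1)) with default
duration 0.55 s in a 1 s cycle and length-dependence slope β = 4 — a
replacement for electromechanical activation, which is out of scope.

## Material fitting

Fitting minimizes the sum of squared differences between measured and
predicted stresses at the measured strains (bounded trust-region least
squares, `scipy.optimize.least_squares`, ftol 1e-10, max 10 000
evaluations; deterministic, no restarts).  The synthetic-curve generator is
the package's stand-in for experimental data: exponential-law evaluations
plus seeded Gaussian noise.  Noiseless recovery is exact to optimizer
precision for both law families; under 5% noise the exponent B of the 1-D
law is recovered within 10% in at least 18 of 20 seeds at n = 50 points.
What passing these tests shows is that the optimization pipeline is
well-posed on data of the assumed functional form; real tissue curves
deviate from a two-parameter exponential and their fits inherit model error
the synthetic fixtures cannot expose.

## Reduced-order ventricle and circulation

The ventricle is lumped into one representative fiber: stretch
λ(V) = ((V + V_wall/3)/(V_ref + V_wall/3))^{1/3}, total fiber Cauchy stress
σ_f = σ_pass(λ) + (1 − φ)·T_act, and cavity pressure through the thick-wall
logarithmic relation P = (σ_f/3)·ln(1 + V_wall/V).  σ_pass is the fiber
stress under isochoric uniaxial stretch with the hydrostatic pressure
eliminated by zero transverse stress.  An infarct of wall-volume fraction φ
generates no active stress; a volume floor of 0.25 mL guards the (invalid)
V → 0 limit of the thick-wall relation.

The circulation is a two-state lumped model: LV volume and arterial
pressure, diode mitral/aortic valves, a single Windkessel
(C_art = 8 mL/kPa, R_per = 0.32 kPa·s/mL), constant venous pressure
P_ven = 0.55 kPa, and a square-root orifice mitral leak
Q = k·A_gap(t)·√(P_lv − P_ven) with k = 0.85 mL/s per mm² per √kPa
(Bernoulli orifice with discharge coefficient 0.62 for blood).  Explicit
Euler with per-substep stability control (substep ∝ 1/(dP/dV·ΣG)) keeps the
stiff filling/ejection phases stable at dt = 1 ms.  Cycles repeat until the
volume trace and arterial pressure are periodic (max |ΔV| < 0.1 mL and
|ΔP_art| < 0.02 kPa between cycles), normally 3–6 beats.

Geometry readout: the cavity is an equivalent prolate spheroid with
long/short-axis ratio `aspect`, so L = 2·aspect^{2/3}·(3V/4π)^{1/3};
shortening over a cycle is L(EDV) − min L.

**Preload and the shortening target.**  With this closure, shortening at a
fixed ejection fraction is proportional to aspect^{2/3}·EDV^{1/3}.  Meeting
the healthy targets (EF 55%, shortening 12.1 mm) with a physically
admissible aspect ≥ 1 requires EDV ≲ 73 mL, so the default preload
(P_ven = 0.55 kPa, unloaded volume 20 mL) is set for EDV ≈ 71 mL — within
echocardiographic normal ranges, though below the textbook 120 mL.  The
healthy calibration is a triangular two-parameter root find: T_max is
bracketed and solved for the EF target (aspect does not feed back into the
dynamics), then aspect follows in closed form from the converged volumes.
Calibrated defaults land at T_max ≈ 21.9 kPa, aspect ≈ 1.012.

Infarct sizing bisects φ on [0, 0.6] (EF is monotone non-increasing in φ,
asserted against a grid scan) until EF matches the post-infarct target
within 0.25 EF points.

## Mitral apparatus

The valve is 12 independent radial strips (two per scallop pair A1-P1 …
A3-P3).  Each strip is a 2-D quasi-static problem in its cutting plane:
two elastic leaflet cables (8 anterior / 6 posterior segments, radial
exponential law, small compression and discrete-bending regularization)
hinged at the annulus, loaded by uniform transvalvular pressure normal to
their segments (consistent nodal loads, no phantom closing edge), tethered
by tension-only chordae (posterior: one basal at 55% arc, one marginal at
the free edge; anterior: one marginal), with C¹-smoothed unilateral penalty
contact between the leaflets (repulsive shell at one-thickness clearance)
and against the rigid sub-valvular element.  Equilibrium is found by damped
Newton iteration on the nodal force residual (finite-difference Jacobian,
backtracking on the residual norm), with dynamic-relaxation transport and a
pressure-ramped cold start as fallbacks; solutions are warm-started across
the 20 sampled instants of the loaded systolic window (transvalvular
pressure above 10% of its peak — the mitral valve carries load through
isovolumic contraction, not only ejection).

Chordae rest lengths derive from a nominal closed configuration (leaflets
routed straight to the coaptation point with the leftover length as a
vertical coaptation tail): posterior chordae are taut exactly at nominal
closure, anterior marginal chordae are 8% longer.  The extra anterior slack
reflects the anterior leaflet's greater excursion — in systole it leans on
the coapted posterior leaflet rather than hanging on its chordae — and is
what allows posterior tethering to uncouple the free edges; with equal
tautness both edges are tied to the same papillary tip and a regurgitant
gap can never form in this discretization.

Annulus kinematics: D(t) = D_ref·(V(t)/V_ref)^{1/3}, with the excursion
clamped to [0.75, 1.15]·D_ref (the fibrous annulus does not follow extreme
cavity excursions, and the clamp keeps leaking coupled cycles out of
degenerate geometry).  An infarct additionally dilates the annulus of the
posterior-sector strips by a factor 1 + 0.5·φ — regional annular dilation
is, together with papillary tethering, the defining lesion of ischemic
mitral regurgitation — and displaces their papillary tips apically and
laterally in a 2:1 ratio by φ·pap_disp_scale.  Healthy papillary tips also
shorten apically with the load waveform (3.5 mm at peak), representing
systolic papillary contraction; infarcted sector tips lose this excursion
entirely because the infarct includes the posterior papillary muscle.  The
loss of papillary systolic tensioning is what allows the post-infarct
average chordae force to fall below healthy even while tethering and
dilation act to raise it.

Per strip, the reported coaptation length is the posterior arc in contact,
the gap width is the minimum free-edge separation beyond the contact
clearance when no contact exists, and A_gap = Σ gap·strip-width feeds the
circulation's leak.  Valve and circulation are coupled by damped
fixed-point iteration on the A_gap(t) trace (under-relaxation 0.5, at most
6 passes, converged when max |ΔA| < 1 mm²; a marginally competent valve
otherwise alternates between open and closed states).

`pap_disp_scale` is calibrated on the coupled system so the infarcted
model's peak average posterior chordae force, normalized by the healthy
peak, matches its 78% target (grid bracket plus bisection; lands at
≈ 11.9 mm with φ ≈ 0.178, giving a regurgitant orifice of order 10² mm² in
early systole and ≈ 5 mL/beat regurgitation).

## Annuloplasty device

The ring pins every strip's annulus points (sutures: no separation) at a
frozen diameter of 0.92·D_ref.  The sub-valvular element is a rigid
cylinder (radius 4 mm) 11 mm below and 6 mm anterior of the posterior
annulus, covering the posterior-sector strips.  Chordae wrap around it as
taut strings (exact tangent-arc-tangent geometry; path-length gradients via
the taut-string property), and leaflet nodes see it as a unilateral contact
surface.  The prototype's true dimensions are unpublished; these defaults
were sized so the modeled element does what the device is designed to do —
engage the posterior chordae and contact the inferior free edge of the
posterior leaflet.  The survey that produced them showed two regimes: an
element placed too deep or too central *props up* the leaflet and unloads
the chordae, while a shallow posterior element lengthens the chordae paths
and raises their tension above healthy while restoring coaptation.  The
treated arm is evaluated with every infarct-arm parameter frozen; its
normalized chordae force is a prediction of the model, not a fitted value.

## Numerical choices

- Penalty stiffness 1000 kPa/mm with a 0.05 mm smoothing band: converged
  penetrations stay below the 0.05 mm contact tolerance (a softer 100
  kPa/mm violates it by 3×).
- Newton residual tolerance 1e-8 relative to the pressure-load force scale;
  maximum 80 iterations; per-node step cap 5 mm.
- Initial guesses are nudged off the exact rest-length/contact-clearance
  kinks (0.5% stretch, 0.15 mm tail separation), where finite-difference
  Jacobians are ill-defined, and projected out of the sub-valvular element.
- Exponential-law exponents are capped at e^500 to keep diverged relaxation
  iterates finite and recoverable.
- All solvers are deterministic; the only RNG in the package is the seeded
  synthetic-curve generator.

## Problem sizes

Default runs use 1000 time steps per cardiac cycle, at most 50 cycles to
the limit cycle, 12 strips × 20 sampled instants per valve solve, at most
6 coupling passes, and the calibration loops described above.  The full
three-arm study completes in roughly four minutes on one CPU.

## Known limitations

- The ventricle has no regional mechanics: an infarct changes global
  active stress, papillary anchoring and sector annulus size, but there is
  no dyskinetic wall motion or remodeling over time.
- The circulation is open-loop (constant venous pressure), so chronic
  volume loading by regurgitation is not captured; forward output at the
  limit cycle is filling-limited and per-beat effects of a leak must be
  read from single-beat comparisons.
- Strips do not exchange membrane forces; circumferential leaflet coupling
  and true 3-D coaptation-line geometry are absent, which is why regional
  annular dilation (rather than emergent 3-D kinematics) must carry part of
  the IMR mechanism.
- The regurgitant orifice is a free-edge-separation proxy, not a vena
  contracta; absolute regurgitant volumes are indicative only.
- Quasi-static valve solutions ignore leaflet inertia and fluid forces;
  closure dynamics at very low transvalvular pressure are not resolved.
- Device stresses cannot be extracted (the device is rigid), and chordal
  rupture, fatigue and durability are out of scope.
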