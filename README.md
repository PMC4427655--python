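# cardiosim

Reduced-order simulation of human left-ventricular function, ischemic
mitral regurgitation (IMR), and its correction by an undersized
annuloplasty ring with a sub-valvular element.

IMR is a leak of the mitral valve caused not by diseased leaflets but by
ventricular remodeling after infarction: the posterior papillary muscle
stops contracting and is displaced apically and laterally, the posterior
annulus dilates, the leaflets are tethered away from each other, and
coaptation is lost.  Devices that undersize the annulus — and, in the
prototype modeled here, additionally engage the posterior chordae and
leaflet from below — aim to restore coaptation.  `cardiosim` is built for
engineers and modelers who want this entire causal chain (myocardial
constitutive behavior → ventricular pressure–volume function → infarct →
valve tethering and leak → device) in a package that runs in minutes on a
laptop, not in a finite-element cluster job.

## What is inside

- **materials** — passive myocardium as an orthotropic exponential
  (Holzapfel–Ogden-type) energy,
  Ψ = a/(2b)(e^{b(I₁−3)}−1) − a ln J + a_ff/(2b_ff)(e^{b_ff⟨I₄f−1⟩²}−1)
  + … + (k/2)(ln J)², with the transversely isotropic normal-human set
  (k=1000, a=0.33, b=7.08, a_ff=0.25, b_ff=5.34 in kPa) as default; virtual
  simple-shear rigs; 1-D exponential laws σ = A(e^{Bε}−1) for leaflets and
  (tension-only) chordae; a prescribed squared-sine active-tension pulse.
- **calibration** — bounded least-squares fitting of any of these laws to
  true-stress/true-strain curves, plus a seeded synthetic-curve generator
  emulating leaflet (circumferential/radial) and chordae (basal/marginal)
  test data.
- **ventricle** — a one-fiber thick-wall left ventricle,
  P = (σ_f/3)·ln(1 + V_wall/V_cav), with infarcts as zero-active-stress
  wall fractions, automatic infarct sizing to a target ejection fraction,
  and the two-parameter healthy-baseline calibration.
- **circulation** — a two-state lumped circulation (diode valves, single
  Windkessel, square-root orifice mitral leak) integrated to a limit cycle.
- **valve** — a strip-discretized quasi-static mitral apparatus: elastic
  leaflet cables, tension-only chordae, smoothed penalty contact,
  volume-driven annular kinematics, papillary displacement, and the rigid
  annuloplasty ring with its chordae-wrapping sub-valvular element.
- **study / cli** — the deterministic three-arm pipeline
  (healthy → infarcted → treated) with YAML configuration.

See `docs/methods.md` for the model equations, defaults, and limitations.

## Worked example

```python
from cardiosim.config import StudyConfig
from cardiosim.study import run_study

result = run_study(StudyConfig(), out_dir="out")
print(result.summary())
```

prints (about four minutes on one CPU):

```
Three-arm study summary
  healthy  : EF= 55.0%  EDV=  71.0  ESV=  31.9  short=12.10 mm  normF= 100.0%  A_gap_max=   0.0 mm^2
  infarcted: EF= 52.5%  EDV=  71.2  ESV=  33.9  short=11.38 mm  normF=  77.6%  A_gap_max= 137.1 mm^2
  treated  : EF= 44.8%  EDV=  71.7  ESV=  39.6  short= 9.33 mm  normF= 114.6%  A_gap_max=   0.0 mm^2
```

Reading it: the healthy baseline calibrates to a 55% ejection fraction with
12.1 mm long-axis shortening and a competent valve (no regurgitant gap
area, chordae force trace normalized to its own peak).  Sizing the infarct
lowers the no-leak ejection fraction to 45% (the 52.5% shown for the
infarcted arm is the *total* EF of the leak-coupled cycle — part of that
ejection goes backward through the 137 mm² regurgitant orifice, about
5 mL/beat).  The infarcted papillary muscle stops contracting and is
displaced, and the calibrated displacement reproduces a peak average
posterior chordae force of 77.6% of healthy.  Attaching the device with all
parameters frozen closes the gap entirely and the chordae, now wrapped over
the sub-valvular element, carry 114.6% of the healthy peak force.

The same pipeline is scriptable from the shell:

```bash
cardiosim study --config study.yaml --out results/
cardiosim simulate --config study.yaml --out sim/
cardiosim infarct-size --config study.yaml --out infarct.json
cardiosim valve --config study.yaml --device on --out valve/
cardiosim fit --law exp1d --curves curves.csv --free A,B \
    --bounds "A=1e-6,100;B=0.1,100" --out fit.json
```

An empty YAML file (`{}`) is a valid configuration; every parameter has a
documented default and unknown keys are rejected with a full error list.

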