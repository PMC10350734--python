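# graftflow

Pulsatile hemodynamics of femoral endografts: a scripted, desk-scale
re-creation of the patient-specific CFD workflow used to investigate
stent-graft thrombosis in the superficial femoral artery (SFA).

After endovascular recanalization of an occluded SFA with a covered stent
graft, some grafts thrombose repeatedly despite normal anatomy on CT and
duplex ultrasound. The suspected culprit is hemodynamic: zones of slow,
recirculating flow downstream of the femoral bifurcation — often seeded
by an *edge stenosis* at the graft's proximal end and left unwashed when
the flow waveform has lost its reverse phase — where low wall shear
stress means long residence times for coagulation factors on a
thrombogenic graft surface. The quantitative marker is the
**time-averaged wall shear stress**

$$\mathrm{TAWSS}(s) = \frac{1}{T}\int_0^T |\tau_w(s,t)|\,dt ,$$

with 0.4 Pa (proatherogenic activation), 0.15 Pa and 0.05 Pa (levels seen
around thrombosing grafts) as the thresholds of interest.

`graftflow` implements every stage of that analysis as a tested Python
library:

* duplex-like triphasic/monophasic velocity waveform synthesis and CSV I/O;
* centerline-velocity → volumetric-flow conversion via the closed-form
  Womersley relation, per frequency harmonic
  ($\alpha = R\sqrt{\omega/\nu}$), plus Womersley inlet profiles;
* 3-element Windkessel (RCR) outlets — response, impedance
  $Z(\omega) = R_p + R_d/(1+i\omega R_d C)$, and two-stage tuning to
  measured branch flows;
* a parametric 2D CFA→SFA/DFA bifurcation geometry with cosine-bump
  stenoses/widenings, endograft annotation, **virtual angioplasty**, and
  an unstructured triangle mesher;
* a pulsatile incompressible Navier–Stokes solver (stabilized P1–P1 FEM,
  Crank–Nicolson/Adams–Bashforth, implicit RCR coupling, backflow
  stabilization) run to cycle periodicity;
* consistent-flux wall shear recovery, TAWSS maps, low-shear threshold
  reports, and pre/post-intervention deltas.

Patient images and waveforms are not distributable, so the pipeline ships
two synthetic analogue cases — a patent "control" and a thrombosis-prone
"occlusion" configuration — that reproduce the qualitative clinical
regimes (see `docs/methods.md` for what they do and do not represent).

## Worked example

```python
import numpy as np
from graftflow import (FluidProperties, synth_duplex_waveform,
                       flow_from_centerline, womersley_number)

fluid = FluidProperties()                      # blood: 1060 kg/m^3, 3.5 mPa s
wave = synth_duplex_waveform(psv=0.9, reverse_fraction=0.3, T=1.0, seed=1)
alpha = womersley_number(3e-3, 2*np.pi, fluid.nu)
flow = flow_from_centerline(wave, R=3e-3, fluid=fluid)
print(f"alpha={alpha:.2f}, mean flow {flow.mean()*6e7:.0f} mL/min")
```

prints

```
alpha=4.14, mean flow 88 mL/min
```

— a typical resting femoral Womersley number and mean flow. The full
pipeline (`examples/05_full_pipeline.py`) runs both analogue cases and the
virtual angioplasty; it prints, per case, the proximal-SFA wall fraction
below each TAWSS threshold and the segment minimum:

```
wall fraction below TAWSS thresholds in the proximal SFA:
  control   : <0.4 Pa 0.0%, <0.15 Pa 0.0%, <0.05 Pa 0.0%; minimum 0.815 Pa
  occlusion : <0.4 Pa 81.7%, <0.15 Pa 40.4%, <0.05 Pa 1.8%; minimum 0.045 Pa
virtual angioplasty of the edge stenosis: proximal-SFA minimum TAWSS
0.045 -> 0.089 Pa (crossed upward: ['0.05'])
```

The patent control stays above 0.4 Pa everywhere; the occlusion-prone
case develops a deep-stasis pocket at the graft's proximal edge, and
inflating the edge stenosis roughly doubles the minimum TAWSS there —
the package's analogue of CFD-based treatment decision support.

A thin CLI wraps the same pipeline: `graftflow run config.yaml`,
`graftflow intervene config.yaml --vessel SFA --s-from 0.004 --s-to 0.014`,
`graftflow synth-waveform --out wave.csv`, `graftflow report results/`.

Other examples: `examples/01_synthesize_waveforms.py` (waveform
morphologies), `02_centerline_to_flow.py` (Womersley conversion),
`03_windkessel_tuning.py` (RCR parameter recovery),
`04_channel_oracle.py` (solver verification against the channel closed
form).

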