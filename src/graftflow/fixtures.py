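"""Bundled analogue cases.

Patient geometries and duplex recordings behind the clinical findings this
package models are not public, so the pipeline ships two synthetic analogue
cases that reproduce the *regimes* reported clinically, not any patient's
numbers:

* ``control_config`` — a patent reconstruction: lesion-free bifurcation and
  triphasic (normal) femoral waveforms at all three sites.
* ``occlusion_config`` — a thrombosis-prone reconstruction: an endograft in
  the proximal SFA whose proximal edge lies near the bifurcation, a tight
  (65%) edge stenosis immediately upstream of the graft edge, a widened
  graft-entry segment distal to it (the stasis pouch), and severely
  dampened monophasic inflow/SFA waveforms (no reverse-phase washout).

Waveform peak velocities and the flow split are chosen as typical resting
femoral values for each condition: a patent limb (CFA PSV ~0.9 m/s,
triphasic) versus combined inflow disease and a failing graft (monophasic
CFA ~0.4 m/s, severely damped mid-graft SFA ~0.2 m/s, collateral-dominant
DFA).  The solver settings form the "coarse profile" used by the test
suite and examples: 0.5 mm base mesh resolution (halved inside lesions and
their downstream jet region) and cycle periodicity to 4%.  See
docs/methods.md for what these analogues do and do not represent.
"""

from __future__ import annotations

import copy

from .pipeline import RunConfig

__all__ = [
    "control_config",
    "occlusion_config",
    "ANGIOPLASTY_VESSEL",
    "ANGIOPLASTY_INTERVAL",
]

_GEOMETRY = {
    "vessels": [
        {"name": "CFA", "radius": 4.0e-3, "length": 0.020, "angle_deg": 0.0},
        {"name": "SFA", "radius": 3.0e-3, "length": 0.028, "angle_deg": 12.0},
        {"name": "DFA", "radius": 2.5e-3, "length": 0.016, "angle_deg": -40.0},
    ],
    "wall_segments": {
        "CFA": ["CFA", 0.0, 0.020],
        "proximal SFA": ["SFA", 0.003, 0.020],
        "distal SFA": ["SFA", 0.020, 0.028],
        "DFA": ["DFA", 0.0, 0.016],
    },
}

# endograft proximal edge ~1 cm from the bifurcation (< 3 cm, as in the
# clinical series) with a tight edge stenosis immediately upstream and the
# patch-angioplasty widening of the SFA origin just proximal of it
_ENDOGRAFT = {"vessel": "SFA", "s_start": 0.012, "s_end": 0.028}
_EDGE_STENOSIS = {
    "vessel": "SFA",
    "center_s": 0.009,
    "length": 0.006,
    "kind": "stenosis",
    "severity": 0.65,
}
# widened graft-entry segment distal to the edge stenosis: the jet entering
# it bypasses a large slow recirculation pouch (the analogue of the
# contrast-devoid proximal graft region seen clinically)
_GRAFT_ENTRY_WIDENING = {
    "vessel": "SFA",
    "center_s": 0.017,
    "length": 0.008,
    "kind": "widening",
    "severity": 0.5,
}

# virtual angioplasty interval covering the edge stenosis (m)
ANGIOPLASTY_VESSEL = "SFA"
ANGIOPLASTY_INTERVAL = (0.004, 0.014)

# coarse profile: separated pulsatile flow on these meshes keeps a ~2-3%
# cycle-to-cycle flow variability, so the periodicity tolerance sits above it
_SOLVER_COARSE = {
    "resolution": 5.0e-4,
    "dt": 1.0e-3,
    "cycles_max": 8,
    "periodicity_tol": 0.04,
    "backflow_beta": 0.2,
    "cfl_target": 0.45,
    "n_store": 200,
}

_CONTROL = {
    "geometry": _GEOMETRY,
    "waveforms": {
        "T": 1.0,
        "n_samples": 200,
        "CFA": {"psv": 0.90, "reverse_fraction": 0.30, "phase": "triphasic"},
        "SFA": {"psv": 0.70, "reverse_fraction": 0.30, "phase": "triphasic"},
        "DFA": {"psv": 0.80, "reverse_fraction": 0.25, "phase": "triphasic"},
    },
    "fluid": {"rho": 1060.0, "mu": 3.5e-3},
    "windkessel": {"mode": "tune", "mean_pressure_mmhg": 100.0, "tolerance": 0.05},
    "solver": _SOLVER_COARSE,
    "thresholds": [0.4, 0.15, 0.05],
}

_OCCLUSION = {
    **copy.deepcopy(_CONTROL),
    "geometry": {
        **copy.deepcopy(_GEOMETRY),
        "lesions": [_EDGE_STENOSIS, _GRAFT_ENTRY_WIDENING],
        "endograft": _ENDOGRAFT,
    },
    "waveforms": {
        "T": 1.0,
        "n_samples": 200,
        "CFA": {"psv": 0.38, "phase": "monophasic"},
        "SFA": {"psv": 0.20, "phase": "monophasic"},
        "DFA": {"psv": 0.85, "reverse_fraction": 0.25, "phase": "triphasic"},
    },
}


def control_config(seed: int = 1, **overrides) -> RunConfig:
    """Patent-reconstruction analogue (no lesion, triphasic waveforms)."""
    cfg = copy.deepcopy(_CONTROL)
    cfg["seed"] = seed
    _apply(cfg, overrides)
    return RunConfig.from_dict(cfg)


def occlusion_config(seed: int = 1, **overrides) -> RunConfig:
    """Thrombosis-prone analogue (edge stenosis + monophasic inflow)."""
    cfg = copy.deepcopy(_OCCLUSION)
    cfg["seed"] = seed
    _apply(cfg, overrides)
    return RunConfig.from_dict(cfg)


def _apply(cfg: dict, overrides: dict) -> None:
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
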