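"""Named parameter regimes and structured-text (YAML) parameter I/O.

The preset names map onto the simulated activity regimes:

``background``
    The resting neocortical column: noise-driven, stationary, no
    narrowband rhythm above the theta range and no epileptiform transients.
``fcd_spikewave``
    The epileptic column regime of a type-2 focal cortical dysplasia:
    glutamatergic gains and the fast (PV-mediated) somatic inhibition are
    raised while the slow (SST-mediated) dendritic inhibition is lowered,
    strongly increasing the excitation-to-dendritic-inhibition ratio.  The
    factors were calibrated once so the column emits recurrent
    spike-wave complexes at 2-3 events/s, then frozen.
``alpha_boost`` / ``beta_boost`` / ``delta_boost``
    Rhythm add-ons for resting-state realism: stronger SST dendritic
    inhibition (with raised drive) yields an ~10 Hz alpha peak; much
    stronger PV somatic inhibition (with the slow loop trimmed so the fast
    loop dominates) yields an ~21 Hz beta peak; slowing every PSP's
    kinetics (halving the rate constants 1/tau) yields a delta-band rhythm.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .nmm_core import (
    CorticalColumnParams,
    SigmoidParams,
    Synapse,
    SynapseKernel,
    ThalamusParams,
)

__all__ = [
    "PresetDelta",
    "PRESETS",
    "apply_preset",
    "cortical_params",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]

_GLUT = ("PYR->PYR2", "PYR2->PYR", "PYR->PV", "PYR->SST")
_SST_DENDRITIC = ("SST->PYR:apical", "SST->PYR:basal")


@dataclass(frozen=True)
class PresetDelta:
    """Multiplicative deviation from the background column parameters."""

    w_scale: Mapping[str, float] = field(default_factory=dict)
    tau_scale: Mapping[str, float] = field(default_factory=dict)
    noise_mean: float | None = None
    noise_sd: float | None = None

    def apply(self, params: CorticalColumnParams) -> CorticalColumnParams:
        return params.scaled(
            w_scale=self.w_scale,
            tau_scale=self.tau_scale,
            noise_mean=self.noise_mean,
            noise_sd=self.noise_sd,
        )


PRESETS: dict[str, PresetDelta] = {
    "background": PresetDelta(),
    "fcd_spikewave": PresetDelta(
        w_scale={
            **{name: 1.65 for name in _GLUT},
            **{name: 0.9 for name in _SST_DENDRITIC},
            "PV->PYR": 1.5,
        }
    ),
    "alpha_boost": PresetDelta(
        w_scale={name: 1.2 for name in _SST_DENDRITIC},
        noise_mean=250.0,
    ),
    "beta_boost": PresetDelta(
        w_scale={"PV->PYR": 5.0, "SST->PV": 0.2, **{name: 0.5 for name in _SST_DENDRITIC}},
        noise_mean=300.0,
    ),
    "delta_boost": PresetDelta(tau_scale={"*": 2.0}),
}


def apply_preset(params: CorticalColumnParams, name: str) -> CorticalColumnParams:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return PRESETS[name].apply(params)


def cortical_params(preset: str = "background") -> CorticalColumnParams:
    """Column parameters for a named preset, starting from the defaults."""
    return apply_preset(CorticalColumnParams(), preset)


def params_to_dict(params) -> dict:
    """Serialize column/thalamus parameters to plain nested dicts."""
    return {
        "kind": "thalamus" if isinstance(params, ThalamusParams) else "cortical",
        "sigmoid": {name: asdict(sp) for name, sp in params.sigmoid.items()},
        "synapses": {
            s.name: {
                "pre": s.pre,
                "post": s.post,
                "W": s.kernel.W,
                "tau_w": s.kernel.tau_w,
                "sign": s.kernel.sign,
                "coupling": s.coupling,
            }
            for s in params.synapses
        },
        "noise_mean": params.noise_mean,
        "noise_sd": params.noise_sd,
    }


def params_from_dict(d: Mapping):
    cls = ThalamusParams if d.get("kind") == "thalamus" else CorticalColumnParams
    synapses = tuple(
        Synapse(
            name=name,
            pre=spec["pre"],
            post=spec["post"],
            kernel=SynapseKernel(W=spec["W"], tau_w=spec["tau_w"], sign=spec["sign"]),
            coupling=spec["coupling"],
        )
        for name, spec in d["synapses"].items()
    )
    sig = {name: SigmoidParams(**sp) for name, sp in d["sigmoid"].items()}
    return cls(
        sigmoid=sig,
        synapses=synapses,
        noise_mean=d["noise_mean"],
        noise_sd=d["noise_sd"],
    )


def save_params(params, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))


def load_params(path: str | Path):
    return params_from_dict(yaml.safe_load(Path(path).read_text()))
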