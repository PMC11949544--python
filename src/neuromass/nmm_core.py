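"""Single-region neural mass dynamics.

A neural mass describes one cortical (or thalamic) region by the mean firing
rate and mean postsynaptic potentials of its neuronal subpopulations.  The
neocortical column modeled here has six subpopulations -- two glutamatergic
pyramidal pools (``PYR`` and its collateral-excitation partner ``PYR2``) and
four GABAergic interneuron classes (``PV`` fast somatic, ``SST`` slow
dendritic, ``VIP`` disinhibitory, ``NGFC`` slow volume inhibition).  The
thalamic mass has a thalamocortical relay pool ``TC`` and two reticular
GABAergic pools ``RN1`` (slow) and ``RN2`` (fast).

Units are millivolts, seconds and spikes/s throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SigmoidParams",
    "SynapseKernel",
    "SynapseState",
    "Synapse",
    "CorticalColumnParams",
    "ThalamusParams",
    "ColumnTrace",
    "NumericalBlowupError",
    "CORTICAL_SUBPOPS",
    "THALAMIC_SUBPOPS",
    "sigmoid",
    "synapse_step",
    "synapse_steady_state",
    "column_motif",
    "simulate_column",
    "simulate_thalamus",
]

CORTICAL_SUBPOPS = ("PYR", "PYR2", "PV", "SST", "VIP", "NGFC")
THALAMIC_SUBPOPS = ("TC", "RN1", "RN2")

#: glutamatergic PSP kinetics shared by all long-range afferents (mV, s)
LONG_RANGE_KERNEL = ("excitatory", 3.25, 0.010)


class NumericalBlowupError(RuntimeError):
    """State became non-finite during integration.

    Attributes ``step`` (integration step index) and ``region`` (region name,
    or ``None`` for single-mass simulations) identify where it happened.
    """

    def __init__(self, step: int, region: str | None = None):
        self.step = step
        self.region = region
        where = f" in region '{region}'" if region else ""
        super().__init__(f"non-finite state at integration step {step}{where}")


@dataclass(frozen=True)
class SigmoidParams:
    """Wave-to-pulse transfer function parameters.

    ``2*e0`` is the maximum firing rate (spikes/s), ``r`` the stiffness
    (1/mV) and ``v0`` the potential at half-maximum (mV).
    """

    e0: float = 2.5
    r: float = 0.56
    v0: float = 6.0

    def __post_init__(self) -> None:
        if not (self.e0 > 0 and self.r > 0):
            raise ValueError("sigmoid requires e0 > 0 and r > 0")


def sigmoid(v, p: SigmoidParams):
    """Mean firing rate S(v) = 2*e0 / (1 + exp(r*(v0 - v))).

    Strictly increasing, bounded in (0, 2*e0), with S(v0) = e0 exactly.
    Accepts scalars or arrays of membrane potential in mV.
    """
    return 2.0 * p.e0 / (1.0 + np.exp(p.r * (p.v0 - np.asarray(v, dtype=float))))


@dataclass(frozen=True)
class SynapseKernel:
    """Alpha-function PSP kernel: gain ``W`` (mV), time constant ``tau_w`` (s).

    ``sign`` is +1 for excitatory (EPSP) and -1 for inhibitory (IPSP)
    synapses and determines how the PSP enters the target's membrane sum.
    """

    W: float
    tau_w: float
    sign: int

    def __post_init__(self) -> None:
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 (excitatory) or -1 (inhibitory)")

    def impulse_response(self, t):
        """Closed-form response to a unit Dirac impulse:
        h(t) = (W/tau_w) * t * exp(-t/tau_w), peaking at t = tau_w with W/e."""
        t = np.asarray(t, dtype=float)
        return (self.W / self.tau_w) * t * np.exp(-t / self.tau_w) * (t >= 0)


@dataclass
class SynapseState:
    """PSP state pair: ``y`` (mV) and its derivative ``y_dot`` (mV/s)."""

    y: float = 0.0
    y_dot: float = 0.0


def synapse_step(s: SynapseState, input_rate: float, k: SynapseKernel, dt: float) -> SynapseState:
    """Advance the second-order PSP ODE one step (Heun / explicit trapezoid).

    The ODE is ``y'' = (W/tau)*u - (2/tau)*y' - y/tau**2`` with the input
    rate ``u`` (spikes/s) held constant over the step.  Requires
    ``dt <= tau_w / 10`` so the kernel is resolved.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if dt > k.tau_w / 10.0 + 1e-15:
        raise ValueError(f"dt={dt} too coarse for tau_w={k.tau_w} (need dt <= tau_w/10)")
    if not math.isfinite(input_rate):
        raise ValueError("non-finite synaptic input")
    tau = k.tau_w
    drive = k.W / tau * input_rate

    def acc(y, yd):
        return drive - (2.0 / tau) * yd - y / tau**2

    a1 = acc(s.y, s.y_dot)
    y_p = s.y + dt * s.y_dot
    yd_p = s.y_dot + dt * a1
    a2 = acc(y_p, yd_p)
    return SynapseState(
        y=s.y + 0.5 * dt * (s.y_dot + yd_p),
        y_dot=s.y_dot + 0.5 * dt * (a1 + a2),
    )


def synapse_steady_state(input_rate: float, k: SynapseKernel) -> float:
    """Equilibrium PSP for a constant input rate: y = W * tau_w * u."""
    return k.W * k.tau_w * input_rate


@dataclass(frozen=True)
class Synapse:
    """One directed connection inside a mass.

    ``pre`` is the source subpopulation (``None`` for the external noise
    drive), ``post`` the target.  ``coupling`` is the dimensionless synaptic
    contact coefficient multiplying the presynaptic rate; must be >= 0.
    """

    name: str
    pre: str | None
    post: str
    kernel: SynapseKernel
    coupling: float

    def __post_init__(self) -> None:
        if self.coupling < 0:
            raise ValueError(f"negative coupling on {self.name}")


def column_motif(include_ngfc_excitation: bool = False) -> list[tuple[str | None, str, str]]:
    """Canonical intra-column connection list as (pre, post, kind) triples.

    Kinds: ``glutamatergic``, ``gaba_fast`` (somatic), ``gaba_slow``
    (dendritic; the SST->PYR projection appears twice, once with slow apical
    and once with faster basal kinetics), ``gaba_very_slow`` (volume
    inhibition) and ``external`` (noise drive onto PYR).  The optional weak
    PYR->NGFC excitation is off by default and not part of the canonical
    motif.
    """
    motif: list[tuple[str | None, str, str]] = [
        ("PYR", "PYR2", "glutamatergic"),
        ("PYR2", "PYR", "glutamatergic"),
        ("PYR", "PV", "glutamatergic"),
        ("PYR", "SST", "glutamatergic"),
        ("PV", "PYR", "gaba_fast"),
        ("SST", "PYR", "gaba_slow_apical"),
        ("SST", "PYR", "gaba_slow_basal"),
        ("SST", "PV", "gaba_slow"),
        ("VIP", "SST", "gaba"),
        ("NGFC", "PYR", "gaba_very_slow"),
        (None, "PYR", "external"),
    ]
    if include_ngfc_excitation:
        motif.append(("PYR", "NGFC", "glutamatergic"))
    return motif


def _default_cortical_synapses() -> tuple[Synapse, ...]:
    """Default intra-column synapses.

    Gains/kinetics follow the classical neural-mass literature: EPSP
    3.25 mV / 10 ms; fast somatic IPSP with gain-x-tau matched to the
    classical fast loop at tau = 5 ms; slow dendritic IPSPs 10 mV at 30 ms
    (apical) and 15 ms (basal); NGFC volume inhibition slowest at 60 ms.
    Contact coefficients are fractions of the base connectivity constant
    C = 135.
    """
    epsp = SynapseKernel(W=3.25, tau_w=0.010, sign=+1)
    gaba_fast = SynapseKernel(W=4.0, tau_w=0.005, sign=-1)
    gaba_apical = SynapseKernel(W=10.0, tau_w=0.030, sign=-1)
    gaba_basal = SynapseKernel(W=10.0, tau_w=0.015, sign=-1)
    gaba_slow = SynapseKernel(W=22.0, tau_w=0.020, sign=-1)
    gaba_vip = SynapseKernel(W=10.0, tau_w=0.010, sign=-1)
    gaba_ngfc = SynapseKernel(W=8.0, tau_w=0.060, sign=-1)
    C = 135.0
    return (
        Synapse("PYR->PYR2", "PYR", "PYR2", epsp, C),
        Synapse("PYR2->PYR", "PYR2", "PYR", epsp, 0.8 * C),
        Synapse("PYR->PV", "PYR", "PV", epsp, 0.3 * C),
        Synapse("PYR->SST", "PYR", "SST", epsp, 0.25 * C),
        Synapse("PV->PYR", "PV", "PYR", gaba_fast, 0.8 * C),
        Synapse("SST->PYR:apical", "SST", "PYR", gaba_apical, 0.25 * C),
        Synapse("SST->PYR:basal", "SST", "PYR", gaba_basal, 0.25 * C),
        Synapse("SST->PV", "SST", "PV", gaba_slow, 0.1 * C),
        Synapse("VIP->SST", "VIP", "SST", gaba_vip, 0.1 * C),
        Synapse("NGFC->PYR", "NGFC", "PYR", gaba_ngfc, 0.1 * C),
        Synapse("PYR->NGFC", "PYR", "NGFC", epsp, 0.1 * C),
        Synapse("noise->PYR", None, "PYR", epsp, 1.0),
    )


def _default_thalamic_synapses() -> tuple[Synapse, ...]:
    epsp = SynapseKernel(W=3.25, tau_w=0.010, sign=+1)
    gaba_slow = SynapseKernel(W=10.0, tau_w=0.030, sign=-1)
    gaba_fast = SynapseKernel(W=4.0, tau_w=0.005, sign=-1)
    return (
        Synapse("TC->RN1", "TC", "RN1", epsp, 35.0),
        Synapse("TC->RN2", "TC", "RN2", epsp, 35.0),
        Synapse("RN1->TC", "RN1", "TC", gaba_slow, 30.0),
        Synapse("RN2->TC", "RN2", "TC", gaba_fast, 30.0),
        Synapse("noise->TC", None, "TC", epsp, 1.0),
    )


def _check_motif(synapses: Sequence[Synapse], allowed: Iterable[tuple[str | None, str]]) -> None:
    allowed = set(allowed)
    for s in synapses:
        if (s.pre, s.post) not in allowed:
            raise ValueError(f"synapse {s.name} not part of the declared motif")


@dataclass(frozen=True)
class CorticalColumnParams:
    """Full parameter set of one neocortical mass."""

    sigmoid: Mapping[str, SigmoidParams] = field(
        default_factory=lambda: {name: SigmoidParams() for name in CORTICAL_SUBPOPS}
    )
    synapses: tuple[Synapse, ...] = field(default_factory=_default_cortical_synapses)
    noise_mean: float = 90.0  # spikes/s, white drive onto PYR
    noise_sd: float = 30.0

    #: per-target-class weight on long-range glutamatergic afferents
    long_range_weights: Mapping[str, float] = field(
        default_factory=lambda: {"PYR": 1.0, "PV": 1.0, "SST": 1.0, "VIP": 1.0, "NGFC": 1.0}
    )

    subpops = CORTICAL_SUBPOPS
    output_subpop = "PYR"
    #: subpopulations reached by long-range glutamatergic afferents
    long_range_targets = ("PYR", "PV", "SST", "VIP", "NGFC")

    def __post_init__(self) -> None:
        allowed = {(pre, post) for pre, post, _ in column_motif(include_ngfc_excitation=True)}
        _check_motif(self.synapses, allowed)

    def scaled(
        self,
        w_scale: Mapping[str, float] | None = None,
        tau_scale: Mapping[str, float] | None = None,
        noise_mean: float | None = None,
        noise_sd: float | None = None,
    ) -> "CorticalColumnParams":
        """Return a copy with per-synapse gain/time-constant factors applied.

        Keys of ``w_scale``/``tau_scale`` are synapse names; the special key
        ``"*"`` applies to every synapse.
        """
        return _apply_scaling(self, w_scale, tau_scale, noise_mean, noise_sd)

    def synapse(self, name: str) -> Synapse:
        for s in self.synapses:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class ThalamusParams:
    """Parameter set of the lumped thalamic mass (TC relay + RN1/RN2)."""

    sigmoid: Mapping[str, SigmoidParams] = field(
        default_factory=lambda: {name: SigmoidParams() for name in THALAMIC_SUBPOPS}
    )
    synapses: tuple[Synapse, ...] = field(default_factory=_default_thalamic_synapses)
    noise_mean: float = 30.0
    noise_sd: float = 10.0
    #: cortical afferents excite TC directly and the reticular pools more
    #: weakly, so increased cortical drive raises the TC equilibrium
    long_range_weights: Mapping[str, float] = field(
        default_factory=lambda: {"TC": 1.0, "RN1": 0.2, "RN2": 0.2}
    )

    subpops = THALAMIC_SUBPOPS
    output_subpop = "TC"
    long_range_targets = ("TC", "RN1", "RN2")

    def __post_init__(self) -> None:
        allowed = {
            ("TC", "RN1"), ("TC", "RN2"), ("RN1", "TC"), ("RN2", "TC"), (None, "TC"),
        }
        _check_motif(self.synapses, allowed)
        for s in self.synapses:
            if s.pre == "TC" and s.kernel.sign != 1:
                raise ValueError("TC output must be excitatory")
            if s.pre in ("RN1", "RN2") and s.kernel.sign != -1:
                raise ValueError("RN output onto TC must be inhibitory")

    def scaled(self, w_scale=None, tau_scale=None, noise_mean=None, noise_sd=None):
        return _apply_scaling(self, w_scale, tau_scale, noise_mean, noise_sd)


def _apply_scaling(params, w_scale, tau_scale, noise_mean, noise_sd):
    w_scale = dict(w_scale or {})
    tau_scale = dict(tau_scale or {})
    new_synapses = []
    for s in params.synapses:
        fw = w_scale.get(s.name, w_scale.get("*", 1.0))
        ft = tau_scale.get(s.name, tau_scale.get("*", 1.0))
        if fw != 1.0 or ft != 1.0:
            k = SynapseKernel(W=s.kernel.W * fw, tau_w=s.kernel.tau_w * ft, sign=s.kernel.sign)
            s = replace(s, kernel=k)
        new_synapses.append(s)
    known = {s.name for s in params.synapses} | {"*"}
    unknown = (set(w_scale) | set(tau_scale)) - known
    if unknown:
        raise KeyError(f"unknown synapse name(s) in scaling: {sorted(unknown)}")
    return replace(
        params,
        synapses=tuple(new_synapses),
        noise_mean=params.noise_mean if noise_mean is None else noise_mean,
        noise_sd=params.noise_sd if noise_sd is None else noise_sd,
    )


@dataclass
class ColumnTrace:
    """Simulation output of a single mass.

    ``potentials`` maps each subpopulation to its membrane potential trace
    (mV); ``dipole_drive`` is the layer-V summed synaptic variable (the
    membrane potential of PYR) that feeds the current dipole.
    """

    dt: float
    potentials: dict[str, np.ndarray]
    dipole_drive: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.dipole_drive.size) * self.dt


def simulate_column(
    params: CorticalColumnParams,
    duration: float,
    dt: float = 1.0 / 2048.0,
    seed: int | np.random.SeedSequence = 0,
    external_inputs: Mapping[str, np.ndarray] | None = None,
) -> ColumnTrace:
    """Integrate one isolated cortical column.

    ``external_inputs`` optionally maps subpopulation names to firing-rate
    traces (spikes/s, one value per step) delivered through a glutamatergic
    long-range kernel.  Identical seed and parameters give identical output.
    """
    from ._engine import simulate_single_mass

    return simulate_single_mass(params, duration, dt, seed, external_inputs)


def simulate_thalamus(
    params: ThalamusParams,
    cortical_drive: np.ndarray | None,
    duration: float,
    dt: float = 1.0 / 2048.0,
    seed: int | np.random.SeedSequence = 0,
) -> ColumnTrace:
    """Integrate the isolated thalamic mass under a given cortical rate drive.

    ``cortical_drive`` (spikes/s per step) is delivered to TC, RN1 and RN2
    through the long-range glutamatergic kernel; ``None`` means no drive.
    """
    from ._engine import simulate_single_mass

    ext = None
    if cortical_drive is not None:
        ext = {pop: cortical_drive for pop in params.long_range_targets}
    return simulate_single_mass(params, duration, dt, seed, ext)
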