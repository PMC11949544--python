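"""Scalp projection: current dipoles, leadfields, montages.

Each cortical region's layer-V summed synaptic variable y_k(t) drives an
axial current I_k(t) = eta * y_k(t) (eta = 1e-3 S).  Far from the source the
extracellular potential follows the current dipole approximation

    phi(r) = 1/(4*sigma*pi) * sum_k I_k * ||d_k|| * cos(theta_k) / R_k**2

with ``d_k`` the distance vector traveled by the axial current, ``theta_k``
the angle between the dipole axis and the source-to-electrode vector,
``sigma`` the extracellular conductivity and ``R_k`` the source-electrode
distance.  A leadfield matrix collects these geometric factors per region
and electrode; a single calibrated output gain maps model units to uV.

Coordinates are millimeters in a right-handed RAS frame (x right, y
anterior, z superior) shared by centroids and electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DipoleSource",
    "ForwardParams",
    "Leadfield",
    "Montage",
    "EEGRecording",
    "standard_1020_positions",
    "ELECTRODES_32",
    "longitudinal_montage",
    "dipole_potential",
    "analytic_leadfield",
    "aggregate_leadfield",
    "project_to_scalp",
    "virtual_resection",
]

#: calibrated global scale from (leadfield x mV dipole drive) to uV, chosen
#: once so background scalp EEG sits at a realistic tens-of-uV amplitude
DEFAULT_OUTPUT_GAIN_UV = 5.0e4


@dataclass(frozen=True)
class ForwardParams:
    """Extracellular conductivity (S/m) and the model-to-uV output gain."""

    sigma: float = 0.33
    output_gain_uv: float = DEFAULT_OUTPUT_GAIN_UV

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("conductivity must be positive")


@dataclass(frozen=True)
class DipoleSource:
    """One regional current dipole.

    ``trace`` is the layer-V synaptic drive y_k(t) (mV); ``position`` (mm)
    and unit ``orientation`` give the pose; ``d_mm`` is the length of the
    axial current path and ``eta`` (S) converts PSP to postsynaptic current.
    ``strength`` scales the dipole (surface-area bookkeeping of fragmented
    regions).
    """

    trace: np.ndarray
    position: tuple[float, float, float]
    orientation: tuple[float, float, float]
    d_mm: float = 3.0
    eta: float = 1.0e-3
    strength: float = 1.0

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if not self.d_mm > 0:
            raise ValueError("axial path length must be positive")


def _gain_factor(position, orientation, electrode_mm, sigma, d_mm, eta, strength):
    src = np.asarray(position, dtype=float) * 1e-3
    ele = np.asarray(electrode_mm, dtype=float) * 1e-3
    n = np.asarray(orientation, dtype=float)
    n = n / np.linalg.norm(n)
    rvec = ele - src
    R = np.linalg.norm(rvec)
    if R <= 0:
        raise ValueError("electrode coincides with the source")
    cos_theta = float(np.dot(n, rvec) / R)
    return strength * eta * (d_mm * 1e-3) * cos_theta / (4.0 * np.pi * sigma * R**2)


def dipole_potential(
    sources: Sequence[DipoleSource],
    electrode_position: Sequence[float],
    fp: ForwardParams | None = None,
) -> np.ndarray:
    """Extracellular potential trace at one electrode (model units).

    Linear in every source trace and decaying as 1/R^2; a source placed at
    the electrode is rejected.
    """
    fp = fp or ForwardParams()
    total = None
    for s in sources:
        g = _gain_factor(
            s.position, s.orientation, electrode_position, fp.sigma, s.d_mm, s.eta, s.strength
        )
        contrib = g * np.asarray(s.trace, dtype=float)
        total = contrib if total is None else total + contrib
    if total is None:
        raise ValueError("no sources given")
    return total


# ---------------------------------------------------------------------------
# electrode geometry

ELECTRODES_32 = (
    "Fp1", "Fp2", "AFz",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "POz", "PO4",
    "O1", "Oz", "O2",
)


def _sph(incl_deg: float, az_deg: float) -> np.ndarray:
    inc = np.deg2rad(incl_deg)
    az = np.deg2rad(az_deg)
    return np.array(
        [np.sin(inc) * np.cos(az), np.sin(inc) * np.sin(az), np.cos(inc)]
    )


def standard_1020_positions(radius_mm: float = 95.0) -> dict[str, np.ndarray]:
    """Approximate 10-20/10-10 positions of the 32-channel set on a sphere.

    Primary 10-20 sites sit on the canonical vertex/temporal rings;
    intermediate 10-10 sites are normalized midpoints of their neighbours.
    """
    u: dict[str, np.ndarray] = {
        "Cz": _sph(0, 0),
        "Fz": _sph(45, 90), "Pz": _sph(45, 270), "C3": _sph(45, 180), "C4": _sph(45, 0),
        "Fp1": _sph(90, 108), "Fp2": _sph(90, 72),
        "F7": _sph(90, 144), "F8": _sph(90, 36),
        "T7": _sph(90, 180), "T8": _sph(90, 0),
        "P7": _sph(90, 216), "P8": _sph(90, 324),
        "O1": _sph(90, 252), "O2": _sph(90, 288), "Oz": _sph(90, 270),
    }

    def mid(a, b):
        v = u[a] + u[b]
        return v / np.linalg.norm(v)

    u["F3"] = mid("Fz", "F7")
    u["F4"] = mid("Fz", "F8")
    u["P3"] = mid("Pz", "P7")
    u["P4"] = mid("Pz", "P8")
    u["FC5"] = mid("F7", "C3")
    u["FC1"] = mid("F3", "Cz")
    u["FC2"] = mid("F4", "Cz")
    u["FC6"] = mid("F8", "C4")
    u["CP5"] = mid("T7", "P3")
    u["CP1"] = mid("C3", "Pz")
    u["CP2"] = mid("C4", "Pz")
    u["CP6"] = mid("T8", "P4")
    u["PO3"] = mid("P3", "O1")
    u["POz"] = mid("Pz", "Oz")
    u["PO4"] = mid("P4", "O2")
    fpz = (u["Fp1"] + u["Fp2"]) / np.linalg.norm(u["Fp1"] + u["Fp2"])
    u["AFz"] = (u["Fz"] + fpz) / np.linalg.norm(u["Fz"] + fpz)
    return {name: radius_mm * u[name] for name in ELECTRODES_32}


# ---------------------------------------------------------------------------
# montages

_LONGITUDINAL_CHAINS = (
    ("Fp1", "F7", "T7", "P7", "O1"),
    ("Fp1", "F3", "C3", "P3", "O1"),
    ("Fz", "Cz", "Pz"),
    ("Fp2", "F4", "C4", "P4", "O2"),
    ("Fp2", "F8", "T8", "P8", "O2"),
)


@dataclass(frozen=True)
class Montage:
    """Bipolar derivations grouped in anterior-to-posterior chains."""

    chains: tuple[tuple[str, ...], ...]

    @property
    def derivations(self) -> list[tuple[str, str]]:
        out = []
        for chain in self.chains:
            out.extend(zip(chain[:-1], chain[1:]))
        return out

    @property
    def derivation_names(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.derivations]

    @property
    def electrodes(self) -> list[str]:
        seen: list[str] = []
        for chain in self.chains:
            for e in chain:
                if e not in seen:
                    seen.append(e)
        return seen

    def chain_derivation_names(self) -> list[list[str]]:
        return [
            [f"{a}-{b}" for a, b in zip(chain[:-1], chain[1:])] for chain in self.chains
        ]

    def save(self, path: str | Path) -> None:
        lines = []
        for chain in self.chain_derivation_names():
            lines.extend(chain)
            lines.append("")
        Path(path).write_text("\n".join(lines).rstrip() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Montage":
        chains: list[tuple[str, ...]] = []
        current: list[str] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                if current:
                    chains.append(tuple(current))
                    current = []
                continue
            a, b = line.split("-")
            if not current:
                current = [a, b]
            elif current[-1] == a:
                current.append(b)
            else:
                chains.append(tuple(current))
                current = [a, b]
        if current:
            chains.append(tuple(current))
        return cls(chains=tuple(chains))


def longitudinal_montage() -> Montage:
    """The standard bipolar longitudinal ('double banana') montage."""
    return Montage(chains=_LONGITUDINAL_CHAINS)


# ---------------------------------------------------------------------------
# leadfield

@dataclass(frozen=True)
class Leadfield:
    """Region-to-electrode gain matrix (regions x electrodes)."""

    region_names: tuple[str, ...]
    electrode_names: tuple[str, ...]
    matrix: np.ndarray
    provenance: str = "loaded"  # loaded | analytic | aggregated

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.region_names), len(self.electrode_names)):
            raise ValueError("leadfield shape mismatch")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite leadfield entries")
        object.__setattr__(self, "matrix", m)

    def save(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=self.region_names, columns=self.electrode_names
        ).to_csv(path, sep="\t")

    @classmethod
    def load(cls, path: str | Path) -> "Leadfield":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            region_names=tuple(df.index),
            electrode_names=tuple(df.columns),
            matrix=df.to_numpy(dtype=float),
            provenance="loaded",
        )


def analytic_leadfield(
    region_names: Sequence[str],
    positions_mm: np.ndarray,
    orientations: np.ndarray,
    electrode_positions: Mapping[str, np.ndarray],
    fp: ForwardParams | None = None,
    strengths: Sequence[float] | None = None,
    d_mm: float = 3.0,
    eta: float = 1.0e-3,
) -> Leadfield:
    """Single-shell analytic leadfield built directly from the dipole formula."""
    fp = fp or ForwardParams()
    strengths = strengths if strengths is not None else np.ones(len(region_names))
    electrode_names = tuple(electrode_positions)
    G = np.empty((len(region_names), len(electrode_names)))
    for i in range(len(region_names)):
        for j, ename in enumerate(electrode_names):
            G[i, j] = _gain_factor(
                positions_mm[i],
                orientations[i],
                electrode_positions[ename],
                fp.sigma,
                d_mm,
                eta,
                strengths[i],
            )
    return Leadfield(
        region_names=tuple(region_names),
        electrode_names=electrode_names,
        matrix=G,
        provenance="analytic",
    )


def aggregate_leadfield(
    dipole_leadfield: np.ndarray,
    dipole_to_region: Sequence[str | None],
    region_names: Sequence[str],
    electrode_names: Sequence[str],
) -> Leadfield:
    """Aggregate a dipole-level leadfield (dipoles x electrodes) by region.

    Each region's row is the sum of the rows of its dipoles; dipoles mapped
    to ``None`` (e.g. excluded insular dipoles) are dropped.  Referencing a
    region absent from ``region_names`` is an error.
    """
    A = np.asarray(dipole_leadfield, dtype=float)
    if A.shape[0] != len(dipole_to_region):
        raise ValueError("one region assignment per dipole required")
    if A.shape[1] != len(electrode_names):
        raise ValueError("electrode count mismatch")
    index = {name: i for i, name in enumerate(region_names)}
    G = np.zeros((len(region_names), len(electrode_names)))
    for row, region in zip(A, dipole_to_region):
        if region is None:
            continue
        if region not in index:
            raise KeyError(f"dipole mapped to unknown region {region!r}")
        G[index[region]] += row
    return Leadfield(
        region_names=tuple(region_names),
        electrode_names=tuple(electrode_names),
        matrix=G,
        provenance="aggregated",
    )


def virtual_resection(leadfield: Leadfield, region_names: Sequence[str]) -> Leadfield:
    """In-silico surgery: zero the named regions' leadfield rows.

    Dimensions are preserved so regional traces stay aligned with the rows.
    """
    m = leadfield.matrix.copy()
    for name in region_names:
        if name not in leadfield.region_names:
            raise KeyError(f"unknown region {name!r}")
        m[leadfield.region_names.index(name)] = 0.0
    return replace(leadfield, matrix=m)


# ---------------------------------------------------------------------------
# EEG container and projection

@dataclass
class EEGRecording:
    """Channels x samples in uV with sampling rate and montage kind."""

    channel_names: list[str]
    data: np.ndarray
    fs: float
    kind: str = "referential"  # or "bipolar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


def project_to_scalp(
    regional_traces: np.ndarray,
    leadfield: Leadfield,
    fs: float,
    montage: Montage | None = None,
    fp: ForwardParams | None = None,
) -> EEGRecording:
    """Project regional dipole drives (regions x samples, mV) to the scalp.

    Referential potentials are ``gain * G.T @ traces`` per sample; when a
    montage is given, each bipolar derivation is anode minus cathode.
    """
    fp = fp or ForwardParams()
    X = np.asarray(regional_traces, dtype=float)
    if X.shape[0] != len(leadfield.region_names):
        raise ValueError("trace count must equal leadfield rows")
    ref = fp.output_gain_uv * (leadfield.matrix.T @ X)
    if montage is None:
        return EEGRecording(list(leadfield.electrode_names), ref, fs, kind="referential")
    missing = set(montage.electrodes) - set(leadfield.electrode_names)
    if missing:
        raise KeyError(f"montage references missing electrodes: {sorted(missing)}")
    idx = {name: i for i, name in enumerate(leadfield.electrode_names)}
    rows = [ref[idx[a]] - ref[idx[b]] for a, b in montage.derivations]
    return EEGRecording(montage.derivation_names, np.array(rows), fs, kind="bipolar")
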