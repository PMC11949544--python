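"""Whole-brain coupling of regional neural masses.

Regions of a cortical atlas (plus one lumped thalamic mass) are coupled by
long-range glutamatergic projections: each region's pyramidal output rate,
lagged by an axonal conduction delay (centroid distance / velocity) and
scaled by the structural connectivity weight and a global coupling gain, is
summed into the afferent-target subpopulations of the destination mass
(PYR, PV, SST, VIP and NGFC for cortex; TC, RN1 and RN2 for the thalamus).

Also provides the structural surgery primitives: fragmentation of an atlas
region into children that inherit the parent's connectivity, and annulment
of all connections of a resected region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nmm_core import CorticalColumnParams, ThalamusParams
from .presets import cortical_params

__all__ = [
    "Region",
    "Atlas",
    "ConnectivityMatrix",
    "build_delay_matrix",
    "NetworkModel",
    "build_network",
    "fragment_region",
    "annul_region_connections",
    "simulate_network",
    "RegionalTraces",
    "region_seed",
    "DEFAULT_VELOCITY",
    "DEFAULT_GLOBAL_COUPLING",
]

#: mean axonal conduction velocity (m/s)
DEFAULT_VELOCITY = 7.5
#: scalar gain on the max-normalized connectivity matrix (calibrated once so
#: coupling shapes regional dynamics -- epileptic discharges spread visibly
#: to connected regions -- without breaking through the scalp spike
#: detector once the source region is resected)
DEFAULT_GLOBAL_COUPLING = 6.0

THALAMUS_NAME = "thalamus"


@dataclass(frozen=True)
class Region:
    """One atlas record: name, hemisphere, centroid (mm), optional parent.

    ``area`` is the region's surface bookkeeping weight (1.0 for a full
    region; fragmentation children carry their surface fraction) and scales
    the region's dipole strength in the forward model.
    """

    name: str
    hemisphere: str  # "lh", "rh" or "sub"
    centroid: tuple[float, float, float]
    parent: str | None = None
    area: float = 1.0

    @property
    def is_cortical(self) -> bool:
        return self.hemisphere in ("lh", "rh")


@dataclass(frozen=True)
class Atlas:
    """Ordered collection of regions; names are unique."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("atlas region names must be unique")
        for r in self.regions:
            if r.parent is not None and r.parent in names:
                raise ValueError(f"child {r.name} coexists with its parent {r.parent}")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def cortical_names(self) -> list[str]:
        return [r.name for r in self.regions if r.is_cortical]

    @property
    def centroids(self) -> np.ndarray:
        return np.array([r.centroid for r in self.regions], dtype=float)

    def __len__(self) -> int:
        return len(self.regions)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown region {name!r}") from None

    def get(self, name: str) -> Region:
        return self.regions[self.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "hemisphere": [r.hemisphere for r in self.regions],
                "x": [r.centroid[0] for r in self.regions],
                "y": [r.centroid[1] for r in self.regions],
                "z": [r.centroid[2] for r in self.regions],
                "parent": [r.parent or "" for r in self.regions],
                "area": [r.area for r in self.regions],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "Atlas":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        regions = tuple(
            Region(
                name=row["name"],
                hemisphere=row["hemisphere"],
                centroid=(float(row["x"]), float(row["y"]), float(row["z"])),
                parent=row["parent"] or None,
                area=float(row.get("area", 1.0)),
            )
            for _, row in df.iterrows()
        )
        return cls(regions)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Square non-negative structural weight matrix over atlas regions."""

    names: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.names), len(self.names)):
            raise ValueError("weight matrix shape does not match region names")
        if np.any(w < 0):
            raise ValueError("connectivity weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("connectivity diagonal must be zero")
        object.__setattr__(self, "weights", w)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown region {name!r}") from None

    def save(self, path: str | Path) -> None:
        pd.DataFrame(self.weights, index=self.names, columns=self.names).to_csv(path, sep="\t")

    @classmethod
    def load(cls, path: str | Path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(names=tuple(df.columns), weights=df.to_numpy(dtype=float))


def build_delay_matrix(atlas: Atlas, velocity: float = DEFAULT_VELOCITY) -> np.ndarray:
    """Conduction delays (s): pairwise centroid distance / velocity.

    Centroids are in mm; the returned matrix is symmetric with a zero
    diagonal.
    """
    if not velocity > 0:
        raise ValueError("velocity must be positive")
    c = atlas.centroids
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite centroid coordinates")
    diff = c[:, None, :] - c[None, :, :]
    dist_m = np.sqrt((diff**2).sum(-1)) * 1e-3
    return dist_m / velocity


@dataclass(frozen=True)
class NetworkModel:
    """Regional masses + connectivity + delays + thalamocortical wiring."""

    atlas: Atlas
    connectivity: ConnectivityMatrix
    delays: np.ndarray  # seconds
    params: Mapping[str, CorticalColumnParams | ThalamusParams]
    velocity: float = DEFAULT_VELOCITY
    global_coupling: float = DEFAULT_GLOBAL_COUPLING

    def __post_init__(self) -> None:
        if tuple(self.connectivity.names) != tuple(self.atlas.names):
            raise ValueError("connectivity regions do not match atlas")
        if set(self.params) != set(self.atlas.names):
            raise ValueError("need exactly one parameter set per region")

    @property
    def n_masses(self) -> int:
        return len(self.atlas)


def build_network(
    atlas: Atlas,
    connectivity: ConnectivityMatrix,
    params: CorticalColumnParams | None = None,
    thalamus_params: ThalamusParams | None = None,
    velocity: float = DEFAULT_VELOCITY,
    global_coupling: float = DEFAULT_GLOBAL_COUPLING,
) -> NetworkModel:
    """Assemble a NetworkModel with one mass per atlas region.

    Cortical regions receive ``params`` (background preset by default); a
    region named ``thalamus`` receives the thalamic mass.
    """
    params = params or cortical_params("background")
    thalamus_params = thalamus_params or ThalamusParams()
    per_region: dict[str, CorticalColumnParams | ThalamusParams] = {}
    for r in atlas.regions:
        per_region[r.name] = thalamus_params if r.name == THALAMUS_NAME else params
    return NetworkModel(
        atlas=atlas,
        connectivity=connectivity,
        delays=build_delay_matrix(atlas, velocity),
        params=per_region,
        velocity=velocity,
        global_coupling=global_coupling,
    )


def fragment_region(
    atlas: Atlas,
    connectivity: ConnectivityMatrix,
    region_name: str,
    parts: Sequence[float],
    extent_mm: float = 20.0,
) -> tuple[Atlas, ConnectivityMatrix]:
    """Split a region into children that keep the parent's connectivity.

    ``parts`` are positive surface fractions summing to 1.  Each child's
    connectivity row/column is a copy of the parent's (not a split), child
    centroids are spread along the parent's anteroposterior tangent axis at
    fraction-weighted positions, and each child's ``area`` is the parent's
    area times its fraction (scaling its dipole strength downstream).
    """
    parts = np.asarray(parts, dtype=float)
    if np.any(parts <= 0) or abs(parts.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    idx = atlas.index(region_name)
    parent = atlas.regions[idx]

    # principal axis: anterior (+y) direction projected on the local tangent
    # plane of the centroid's radial direction; falls back to +y at the pole
    radial = np.asarray(parent.centroid, dtype=float)
    nrm = np.linalg.norm(radial)
    axis = np.array([0.0, 1.0, 0.0])
    if nrm > 0:
        radial = radial / nrm
        axis = axis - np.dot(axis, radial) * radial
        if np.linalg.norm(axis) < 1e-9:
            axis = np.array([0.0, 1.0, 0.0])
        else:
            axis = axis / np.linalg.norm(axis)

    cum = np.concatenate([[0.0], np.cumsum(parts)])
    mids = 0.5 * (cum[:-1] + cum[1:])
    children = []
    if len(parts) == 1:
        offsets = [0.0]
    else:
        offsets = (mids - 0.5) * extent_mm
    for i, (frac, off) in enumerate(zip(parts, offsets)):
        centroid = tuple(np.asarray(parent.centroid) + off * axis)
        children.append(
            Region(
                name=f"{parent.name}#{i}",
                hemisphere=parent.hemisphere,
                centroid=centroid,
                parent=parent.name,
                area=parent.area * float(frac),
            )
        )

    new_regions = list(atlas.regions[:idx]) + children + list(atlas.regions[idx + 1 :])
    new_atlas = Atlas(tuple(new_regions))

    w = connectivity.weights
    k = connectivity.index(region_name)
    new_w = np.zeros((w.shape[0] - 1 + len(children),) * 2)
    new_names = [r.name for r in new_regions]
    old_names = list(connectivity.names)
    for a, na in enumerate(new_names):
        oa = old_names.index(na) if na in old_names else k
        for b, nb in enumerate(new_names):
            if a == b:
                continue
            ob = old_names.index(nb) if nb in old_names else k
            if oa == k and ob == k:
                new_w[a, b] = 0.0  # siblings: parent self-weight (diagonal) is zero
            else:
                new_w[a, b] = w[oa, ob]
    return new_atlas, ConnectivityMatrix(names=tuple(new_names), weights=new_w)


def annul_region_connections(
    connectivity: ConnectivityMatrix, region_name: str
) -> ConnectivityMatrix:
    """Zero all weights to and from a (resected) region; all else untouched."""
    k = connectivity.index(region_name)
    w = connectivity.weights.copy()
    w[k, :] = 0.0
    w[:, k] = 0.0
    return ConnectivityMatrix(names=connectivity.names, weights=w)


def region_seed(seed: int, region_index: int) -> np.random.SeedSequence:
    """Noise-stream seed of one region; the documented per-region derivation.

    An isolated column simulated with this seed consumes the same noise
    stream as the corresponding region inside ``simulate_network(seed=...)``.
    """
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(region_index),))


@dataclass
class RegionalTraces:
    """Per-region dipole-drive traces (mV) on the integration grid."""

    names: list[str]
    data: np.ndarray  # (n_regions, n_steps)
    dt: float

    def trace(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]


def simulate_network(
    model: NetworkModel,
    duration: float,
    dt: float = 1.0 / 2048.0,
    seed: int = 0,
    ez_regions: Sequence[str] = (),
    ez_params: CorticalColumnParams | None = None,
) -> RegionalTraces:
    """Integrate the delayed network; returns per-region dipole drives.

    ``ez_regions`` are simulated with the epileptic (``fcd_spikewave``)
    parameters, or with ``ez_params`` when given; all other cortical
    regions keep their configured parameters.  Deterministic for a fixed
    seed: region ``i`` draws its noise from ``region_seed(seed, i)``.
    """
    from ._engine import compile_masses, run_network

    names = model.atlas.names
    for name in ez_regions:
        if name not in names:
            raise KeyError(f"EZ region {name!r} not in atlas")
    ez_params = ez_params or cortical_params("fcd_spikewave")
    mass_params = []
    for name in names:
        if name in ez_regions:
            mass_params.append(ez_params)
        else:
            mass_params.append(model.params[name])

    w = model.connectivity.weights
    wmax = w.max()
    conn = w / wmax if wmax > 0 else w
    delay_steps = np.rint(model.delays / dt).astype(int)
    compiled = compile_masses(mass_params, region_names=names)
    seeds = [region_seed(seed, i) for i in range(len(names))]
    out, _ = run_network(
        compiled,
        duration,
        dt,
        seeds=seeds,
        connectivity=conn,
        delay_steps=delay_steps,
        global_coupling=model.global_coupling,
    )
    return RegionalTraces(names=list(names), data=out, dt=dt)
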