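"""Synthetic geometry, connectivity, reference EEGs and scenario replay.

Everything needed to exercise the full pipeline without clinical data:

* a synthetic head: 66 cortical regions (Desikan-Killiany labels, insula
  excluded) on a spherical cortical shell plus a central thalamus, 32
  standard 10-20 electrodes on an outer shell, and an analytic leadfield
  built from the current-dipole formula with radially oriented sources;
* distance-decaying random structural connectivity standing in for a
  group-averaged diffusion-imaging connectome;
* reference scalp EEGs with spike-wave templates injected at controlled
  rate, amplitude and polarity per derivation (with a controllable
  phase-inversion electrode), returned together with their ground truth;
* the epileptogenic-zone workflow: place the epileptic mass in every
  candidate region, score each simulated scalp EEG against the reference,
  refine by fragmenting the winning region, and verify that an in-silico
  resection abolishes the scalp spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .brain_network import (
    Atlas,
    ConnectivityMatrix,
    Region,
    build_network,
    fragment_region,
    simulate_network,
)
from .forward_model import (
    EEGRecording,
    Leadfield,
    Montage,
    analytic_leadfield,
    longitudinal_montage,
    project_to_scalp,
    standard_1020_positions,
    virtual_resection,
)
from .ies_metrics import (
    DetectorParams,
    IESFeatureSet,
    SpikeEvent,
    detect_ies,
    eeg_ies_score,
    extract_ies_features,
)
from .presets import PRESETS, PresetDelta, cortical_params

__all__ = [
    "DK_CORTICAL_LABELS",
    "ScenarioSpec",
    "SpikeTrainSpec",
    "make_synthetic_head",
    "make_synthetic_connectivity",
    "spike_wave_template",
    "make_reference_eeg",
    "rhythm_presets",
    "replay_fcd_scenario",
    "ScenarioResult",
]

# Desikan-Killiany cortical parcels per hemisphere, insula excluded (33),
# hand-ordered from anterior to posterior for the synthetic layout
DK_CORTICAL_LABELS = (
    "frontalpole",
    "rostralmiddlefrontal",
    "medialorbitofrontal",
    "lateralorbitofrontal",
    "parsorbitalis",
    "rostralanteriorcingulate",
    "superiorfrontal",
    "parstriangularis",
    "temporalpole",
    "parsopercularis",
    "caudalmiddlefrontal",
    "caudalanteriorcingulate",
    "entorhinal",
    "precentral",
    "paracentral",
    "superiortemporal",
    "middletemporal",
    "inferiortemporal",
    "transversetemporal",
    "postcentral",
    "parahippocampal",
    "posteriorcingulate",
    "supramarginal",
    "fusiform",
    "superiorparietal",
    "isthmuscingulate",
    "bankssts",
    "inferiorparietal",
    "precuneus",
    "lingual",
    "lateraloccipital",
    "pericalcarine",
    "cuneus",
)

_CORTICAL_SHELL_MM = 70.0
_ELECTRODE_SHELL_MM = 95.0


@dataclass(frozen=True)
class SpikeTrainSpec:
    """Injected spike-wave train on one derivation of a reference EEG."""

    rate: float  # events/s
    amplitude: float  # spike peak, uV
    polarity: str  # PP | PN | NP | NN
    wave_fraction: float = 0.5  # wave peak relative to spike peak


@dataclass(frozen=True)
class ScenarioSpec:
    """Fully serializable description of one in-silico experiment."""

    n_regions: int = 66
    geometry_seed: int = 0
    conn_decay_mm: float = 40.0
    conn_density: float = 0.3
    conn_seed: int = 0
    ez_region: str = "lh.rostralmiddlefrontal"
    ez_fractions: tuple[float, ...] = ()  # empty: whole-region EZ
    ez_child: int = 0
    preset: str = "fcd_spikewave"
    rhythm_regions: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    duration: float = 16.0
    burn_in: float = 2.0
    fs: float = 512.0
    seed: int = 0
    #: fraction of a background region's area that is synchronously active;
    #: scalp amplitude scales with synchronous area, and epileptic
    #: discharges recruit their whole region while background does not
    background_synchrony: float = 0.3

    def to_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "geometry_seed": self.geometry_seed,
            "conn_decay_mm": self.conn_decay_mm,
            "conn_density": self.conn_density,
            "conn_seed": self.conn_seed,
            "ez_region": self.ez_region,
            "ez_fractions": list(self.ez_fractions),
            "ez_child": self.ez_child,
            "preset": self.preset,
            "rhythm_regions": {k: list(v) for k, v in self.rhythm_regions.items()},
            "duration": self.duration,
            "burn_in": self.burn_in,
            "fs": self.fs,
            "seed": self.seed,
            "background_synchrony": self.background_synchrony,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioSpec":
        d = dict(d)
        d["ez_fractions"] = tuple(d.get("ez_fractions", ()))
        d["rhythm_regions"] = {k: tuple(v) for k, v in d.get("rhythm_regions", {}).items()}
        return cls(**d)


def _hemisphere_points(n: int, seed: int) -> np.ndarray:
    """Quasi-uniform points on the left upper-lateral spherical shell,
    ordered anterior to posterior; a small seeded jitter decorrelates
    geometries across seeds without destroying the layout."""
    k = np.arange(n)
    # golden-angle spiral restricted to inclinations [25 deg, 115 deg] and
    # azimuths (95 deg, 265 deg) (x < 0: left hemisphere, mostly above ear)
    incl = np.deg2rad(25.0 + 90.0 * (k + 0.5) / n)
    az = np.deg2rad(95.0 + (170.0 * ((k * 0.61803398875) % 1.0)))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 901]))
    incl = incl + rng.normal(0, 0.01, n)
    az = az + rng.normal(0, 0.01, n)
    pts = np.column_stack(
        [np.sin(incl) * np.cos(az), np.sin(incl) * np.sin(az), np.cos(incl)]
    )
    order = np.argsort(-pts[:, 1])  # anterior (large y) first
    return pts[order]


def make_synthetic_head(
    spec: ScenarioSpec | None = None,
) -> tuple[Atlas, dict[str, np.ndarray], Leadfield]:
    """Synthetic atlas + electrode positions + analytic leadfield.

    Cortical centroids lie on a 70 mm shell (33 anteroposterior-ordered
    Desikan-Killiany labels per hemisphere), the thalamus at the center,
    and the 32 electrodes on a 95 mm shell.  Dipoles are radial; the
    leadfield covers cortical regions only (the lumped thalamus is a
    closed-field deep source and does not project).  Deterministic per
    geometry seed.
    """
    spec = spec or ScenarioSpec()
    if spec.n_regions < 2:
        raise ValueError("need at least 2 cortical regions")
    per_hemi = (spec.n_regions + 1) // 2
    labels = [
        DK_CORTICAL_LABELS[i % len(DK_CORTICAL_LABELS)]
        + ("" if i < len(DK_CORTICAL_LABELS) else f"_{i // len(DK_CORTICAL_LABELS)}")
        for i in range(per_hemi)
    ]
    unit = _hemisphere_points(per_hemi, spec.geometry_seed)
    regions: list[Region] = []
    for hemi, sign in (("lh", 1.0), ("rh", -1.0)):
        for label, u in zip(labels, unit):
            centroid = _CORTICAL_SHELL_MM * np.array([sign * u[0], u[1], u[2]])
            regions.append(
                Region(
                    name=f"{hemi}.{label}",
                    hemisphere=hemi,
                    centroid=tuple(centroid),
                )
            )
    regions = regions[: spec.n_regions]
    regions.append(Region(name="thalamus", hemisphere="sub", centroid=(0.0, -10.0, 10.0)))
    atlas = Atlas(tuple(regions))

    electrodes = standard_1020_positions(_ELECTRODE_SHELL_MM)
    leadfield = _leadfield_for_atlas(atlas, electrodes)
    return atlas, electrodes, leadfield


def _leadfield_for_atlas(atlas: Atlas, electrodes: Mapping[str, np.ndarray]) -> Leadfield:
    cortical = [r for r in atlas.regions if r.is_cortical]
    positions = np.array([r.centroid for r in cortical])
    norms = np.linalg.norm(positions, axis=1, keepdims=True)
    orientations = positions / np.where(norms > 0, norms, 1.0)
    return analytic_leadfield(
        region_names=[r.name for r in cortical],
        positions_mm=positions,
        orientations=orientations,
        electrode_positions=dict(electrodes),
        strengths=[r.area for r in cortical],
    )


def make_synthetic_connectivity(
    atlas: Atlas,
    decay_mm: float = 40.0,
    density: float = 0.3,
    seed: int = 0,
) -> ConnectivityMatrix:
    """Random symmetric connectome with distance-dependent weight decay.

    Cortico-cortical weights are exp(-distance/decay) times a lognormal
    factor, thresholded so that ``density`` of the off-diagonal pairs
    survive, then max-normalized.  Thalamocortical connections are always
    kept (the thalamus projects to and receives from every cortical
    region).
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    n = len(atlas)
    c = atlas.centroids
    dist = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    noise = rng.lognormal(mean=0.0, sigma=0.5, size=(n, n))
    w = np.exp(-dist / decay_mm) * noise
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)

    thal = [i for i, r in enumerate(atlas.regions) if not r.is_cortical]
    cortical = [i for i, r in enumerate(atlas.regions) if r.is_cortical]
    iu = np.triu_indices(n, k=1)
    mask = np.zeros((n, n), dtype=bool)
    cort_pairs = [
        (i, j) for i, j in zip(*iu) if i in set(cortical) and j in set(cortical)
    ]
    if cort_pairs and density > 0:
        vals = np.array([w[i, j] for i, j in cort_pairs])
        keep = max(1, int(round(density * len(cort_pairs))))
        thr = np.sort(vals)[::-1][keep - 1]
        for i, j in cort_pairs:
            if w[i, j] >= thr:
                mask[i, j] = mask[j, i] = True
    if density > 0:
        # the thalamus projects to and receives from all cortical regions
        for t in thal:
            for i in cortical:
                mask[t, i] = mask[i, t] = True
    w = np.where(mask, w, 0.0)
    if w.max() > 0:
        w = w / w.max()
    return ConnectivityMatrix(names=tuple(atlas.names), weights=w)


def spike_wave_template(
    fs: float,
    polarity: str = "NP",
    spike_amp: float = 100.0,
    wave_amp: float = 50.0,
) -> np.ndarray:
    """Spike-wave complex: difference-of-Gaussians spike (70 ms) followed
    by a half-sine slow wave (300 ms).

    Deliberately independent of the neural-mass dynamics so that detector
    validation against injected events is not circular.  Signs of the two
    components follow the polarity class (first letter spike, second wave).
    """
    if polarity not in ("PP", "PN", "NP", "NN"):
        raise ValueError(f"invalid polarity {polarity!r}")
    n = int(round(0.45 * fs))
    t = np.arange(n) / fs
    t0 = 0.06
    s1, s2 = 0.012, 0.030
    spike = np.exp(-0.5 * ((t - t0) / s1) ** 2) - 0.6 * np.exp(-0.5 * ((t - t0) / s2) ** 2)
    spike = spike / spike.max()
    wave = np.zeros(n)
    w0, w1 = 0.13, 0.43
    m = (t >= w0) & (t < w1)
    wave[m] = np.sin(np.pi * (t[m] - w0) / (w1 - w0))
    s_sign = +1.0 if polarity[0] == "P" else -1.0
    w_sign = +1.0 if polarity[1] == "P" else -1.0
    return s_sign * spike_amp * spike + w_sign * wave_amp * wave


def make_reference_eeg(
    trains: Mapping[str, SpikeTrainSpec] | None = None,
    montage: Montage | None = None,
    duration: float = 40.0,
    fs: float = 512.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[EEGRecording, list[SpikeEvent]]:
    """Reference bipolar scalp EEG with implanted spike-wave discharges.

    ``trains`` maps derivation names (e.g. ``"Fp1-F3"``) to their injected
    spike trains; unlisted derivations carry background noise only.  The
    default configuration mimics a left parasagittal frontal irritative
    field with a phase inversion on F3 (PN above / NP below).  Returns the
    recording plus the ground-truth event list (times, amplitudes,
    polarities as injected).
    """
    montage = montage or longitudinal_montage()
    if trains is None:
        trains = {
            "Fp1-F3": SpikeTrainSpec(rate=2.5, amplitude=90.0, polarity="PN"),
            "F3-C3": SpikeTrainSpec(rate=2.5, amplitude=110.0, polarity="NP"),
            "C3-P3": SpikeTrainSpec(rate=2.5, amplitude=45.0, polarity="NP"),
            "Fp1-F7": SpikeTrainSpec(rate=2.0, amplitude=35.0, polarity="PN"),
        }
    names = montage.derivation_names
    unknown = set(trains) - set(names)
    if unknown:
        raise KeyError(f"unknown derivations in train spec: {sorted(unknown)}")
    n = int(round(duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 55]))
    # pink-ish background: white noise low-passed at 25 Hz
    from scipy import signal as sps

    sos = sps.butter(2, 25.0, btype="lowpass", fs=fs, output="sos")
    data = np.empty((len(names), n))
    for i in range(len(names)):
        white = rng.standard_normal(n)
        bg = sps.sosfiltfilt(sos, white)
        data[i] = noise_sd * bg / bg.std()

    truth: list[SpikeEvent] = []
    margin = 0.3  # keep whole complexes away from the window edges
    for name, spec in trains.items():
        i = names.index(name)
        tpl = spike_wave_template(fs, spec.polarity, spec.amplitude,
                                  spec.wave_fraction * spec.amplitude)
        n_events = int(np.floor(duration * spec.rate))
        span = duration - 2 * margin - tpl.size / fs
        spacing = span / max(n_events - 1, 1)
        for k in range(n_events):
            start = margin + k * spacing + 0.3 * spacing * (rng.random() - 0.5)
            j = min(max(0, int(round(start * fs))), n - tpl.size)
            data[i, j : j + tpl.size] += tpl
            peak = j + int(np.argmax(np.abs(tpl)))
            truth.append(
                SpikeEvent(
                    derivation=name,
                    peak_time=peak / fs,
                    amp_max=float(tpl.max()),
                    amp_min=float(tpl.min()),
                    polarity=spec.polarity,
                )
            )
    return EEGRecording(list(names), data, fs, kind="bipolar"), truth


def rhythm_presets() -> dict[str, tuple[PresetDelta, tuple[str, ...]]]:
    """Named rhythm add-ons with their default target regions.

    Alpha strengthens SST dendritic inhibition in occipital visual areas,
    beta strengthens somatic inhibition in the middle frontal cortex, and
    delta slows the PSP kinetics in the left frontal pole.
    """
    return {
        "alpha_boost": (
            PRESETS["alpha_boost"],
            (
                "lh.lateraloccipital", "rh.lateraloccipital",
                "lh.inferiortemporal", "rh.inferiortemporal",
                "lh.lingual", "rh.lingual",
            ),
        ),
        "beta_boost": (
            PRESETS["beta_boost"],
            (
                "lh.rostralmiddlefrontal", "rh.rostralmiddlefrontal",
                "lh.caudalmiddlefrontal", "rh.caudalmiddlefrontal",
            ),
        ),
        "delta_boost": (PRESETS["delta_boost"], ("lh.frontalpole",)),
    }


@dataclass
class ScenarioResult:
    """Bundle produced by the epileptogenic-zone replay workflow."""

    spec: ScenarioSpec
    reference_eeg: EEGRecording
    reference_features: IESFeatureSet
    placement_scores: dict[str, float]
    best_region: str
    fragment_scores: dict[str, float]
    best_fragment: str | None
    full_region_score: float
    post_resection_event_count: int
    pre_resection_event_count: int


def _simulate_scalp(
    atlas: Atlas,
    conn: ConnectivityMatrix,
    leadfield: Leadfield,
    ez: Sequence[str],
    spec: ScenarioSpec,
    montage: Montage,
    rhythm: Mapping[str, tuple[PresetDelta, tuple[str, ...]]] | None = None,
) -> tuple[EEGRecording, "object"]:
    model = build_network(atlas, conn)
    if rhythm:
        per_region = dict(model.params)
        for _, (delta, targets) in rhythm.items():
            for name in targets:
                if name in per_region and name != "thalamus":
                    per_region[name] = delta.apply(per_region[name])
        model = replace(model, params=per_region)
    traces = simulate_network(
        model,
        duration=spec.duration,
        seed=spec.seed,
        ez_regions=list(ez),
        ez_params=cortical_params(spec.preset),
    )
    return _project(traces, atlas, leadfield, spec, montage, ez), traces


def _project(
    traces,
    atlas: Atlas,
    leadfield: Leadfield,
    spec: ScenarioSpec,
    montage: Montage,
    ez: Sequence[str] = (),
):
    step = int(round(1.0 / (spec.fs * traces.dt)))
    skip = int(round(spec.burn_in / traces.dt))
    rows = []
    for name in leadfield.region_names:
        sync = 1.0 if name in ez else spec.background_synchrony
        rows.append(sync * traces.trace(name)[skip::step])
    return project_to_scalp(np.array(rows), leadfield, fs=spec.fs, montage=montage)


def replay_fcd_scenario(
    spec: ScenarioSpec | None = None,
    candidates: Sequence[str] | None = None,
    detector: DetectorParams | None = None,
) -> ScenarioResult:
    """Full in-silico localization experiment on synthetic data.

    1. Build the synthetic head and connectome; simulate the reference
       scalp EEG with the epileptic mass in the specified region (or in
       one fragment of it when ``ez_fractions`` is set).
    2. Place the epileptic mass consecutively in every candidate cortical
       region, score each simulated EEG against the reference with the
       seven-criterion EEG-IES index, and rank (descending score; ties by
       region order).
    3. If fractions are specified, fragment the winning region and rescore
       each child EZ against the reference.
    4. Resect the true EZ (zero its leadfield rows) and count the scalp
       spikes that remain.
    """
    spec = spec or ScenarioSpec()
    montage = longitudinal_montage()
    atlas, _, leadfield = make_synthetic_head(spec)
    conn = make_synthetic_connectivity(
        atlas, spec.conn_decay_mm, spec.conn_density, spec.conn_seed
    )
    window = spec.duration - spec.burn_in

    # reference (possibly from a sub-fraction of the EZ region)
    if spec.ez_fractions:
        ref_atlas, ref_conn = fragment_region(
            atlas, conn, spec.ez_region, spec.ez_fractions
        )
        ref_leadfield = _leadfield_for_atlas(ref_atlas, standard_1020_positions(_ELECTRODE_SHELL_MM))
        true_ez = [f"{spec.ez_region}#{spec.ez_child}"]
        ref_eeg, ref_traces = _simulate_scalp(
            ref_atlas, ref_conn, ref_leadfield, true_ez, spec, montage
        )
        res_leadfield = ref_leadfield
        res_atlas = ref_atlas
    else:
        true_ez = [spec.ez_region]
        ref_eeg, ref_traces = _simulate_scalp(atlas, conn, leadfield, true_ez, spec, montage)
        res_leadfield = leadfield
        res_atlas = atlas
    ref_features = extract_ies_features(ref_eeg, montage, window, detector)

    # stage 1: whole-region placement search
    if candidates is None:
        candidates = atlas.cortical_names
    placement_scores: dict[str, float] = {}
    for name in candidates:
        eeg, _ = _simulate_scalp(atlas, conn, leadfield, [name], spec, montage)
        feats = extract_ies_features(eeg, montage, window, detector)
        placement_scores[name] = eeg_ies_score(ref_features, feats).percentage
    order = list(candidates)
    best_region = max(order, key=lambda n: (placement_scores[n], -order.index(n)))
    full_region_score = placement_scores[best_region]

    # stage 2: fragmentation refinement of the winning region
    fragment_scores: dict[str, float] = {}
    best_fragment = None
    if spec.ez_fractions:
        frag_atlas, frag_conn = fragment_region(
            atlas, conn, best_region, spec.ez_fractions
        )
        frag_leadfield = _leadfield_for_atlas(
            frag_atlas, standard_1020_positions(_ELECTRODE_SHELL_MM)
        )
        children = [r.name for r in frag_atlas.regions if r.parent == best_region]
        for child in children:
            eeg, _ = _simulate_scalp(
                frag_atlas, frag_conn, frag_leadfield, [child], spec, montage
            )
            feats = extract_ies_features(eeg, montage, window, detector)
            fragment_scores[child] = eeg_ies_score(ref_features, feats).percentage
        best_fragment = max(
            children, key=lambda n: (fragment_scores[n], -children.index(n))
        )

    # stage 3: in-silico surgery on the true EZ
    pre_events = detect_ies(ref_eeg, montage, window, detector)
    resected = virtual_resection(res_leadfield, true_ez)
    post_eeg = _project(ref_traces, res_atlas, resected, spec, montage, true_ez)
    post_events = detect_ies(post_eeg, montage, window, detector)

    return ScenarioResult(
        spec=spec,
        reference_eeg=ref_eeg,
        reference_features=ref_features,
        placement_scores=placement_scores,
        best_region=best_region,
        fragment_scores=fragment_scores,
        best_fragment=best_fragment,
        full_region_score=full_region_score,
        post_resection_event_count=len(post_events),
        pre_resection_event_count=len(pre_events),
    )
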