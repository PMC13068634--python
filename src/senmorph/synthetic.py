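"""Seeded synthetic populations, images and time-lapses with ground truth.

The generator emulates the cell populations the morphometric pipeline was
designed for: a compact control population; two enlarged senescent
morphotypes — the extension-rich, irregular E-state (star-like outlines with
prominent spiky extensions) and the flattened, regular F-state (large smooth
ellipses that progressively enlarge over time); and a small proliferative
subpopulation.  Per-state fluorescence models cover FUCCI cell-cycle reporter
intensities, GFP-LC3 autophagosome puncta (Poisson counts, E >> F),
senescence/survival markers (p16 higher in E than F, Bcl-2 lower in F) and
CFSE dye dilution (halved per division; enlarged states do not divide).
Time-lapses follow a per-frame condensed-state Markov chain in which E->F
transitions dominate and F->E reversions are rare.

Every draw flows from one scenario seed split into named substreams (shapes,
fluorescence, transitions, placement), so the same seed reproduces identical
tables and adding a channel does not perturb the geometry.  Ground-truth
columns (state, area, puncta counts, phase, divisions, transition log, spot
coordinates) are emitted alongside, sufficient to score every downstream stage.

Effect sizes are defaults encoding ordinal relationships (E more autophagic
than F, p16 twice as high in E, CFSE 8x retained in non-dividing cells), not
measured magnitudes; all are exposed on :class:`SyntheticScenario`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage import draw as skdraw

from .errors import ConfigError
from .morphometry import (
    Compartment,
    FluorescenceProfile,
    MorphoRecord,
    ShapeObject,
    compute_descriptors,
    compute_irregularity,
    records_to_frame,
)

__all__ = [
    "ShapeModel",
    "FluorescenceModel",
    "GrowthModel",
    "SyntheticScenario",
    "SyntheticPopulation",
    "SyntheticTimelapse",
    "RenderedImages",
    "generate_control_population",
    "generate_condition",
    "generate_timelapse",
    "generate_growth_series",
    "render_images",
    "CONDITION_PRESETS",
]

STATES = ("N", "E", "F", "small")
CHANNEL_NAMES = ("fucci_red", "fucci_green", "lc3", "p16", "bcl2", "promoter", "cfse")

BACKGROUND_LEVEL = 10.0
BACKGROUND_SD = 2.0
SPOT_AMPLITUDE = 200.0
SPOT_SIGMA = 1.5
SPOT_NOMINAL_PX = 13  # supra-threshold footprint of one rendered punctum


@dataclass
class ShapeModel:
    """Lognormal area model plus outline-irregularity parameters for one state."""

    area_mean: float                 # px^2, arithmetic mean of the lognormal
    area_sigma_log: float = 0.15     # lognormal shape parameter
    aspect_range: tuple[float, float] = (1.05, 1.35)
    boundary_noise: float = 0.02     # radial Fourier perturbation amplitude
    n_spikes_range: tuple[int, int] = (0, 0)      # E-state extensions
    spike_length_range: tuple[float, float] = (1.0, 3.0)  # in body radii
    spike_width: float = 0.22        # angular half-width (rad)

    def draw_area(self, rng: np.random.Generator) -> float:
        mu = math.log(self.area_mean) - self.area_sigma_log**2 / 2
        return float(rng.lognormal(mu, self.area_sigma_log))


@dataclass
class FluorescenceModel:
    """Per-state fluorescence parameterization."""

    fucci_probs: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.55, "S": 0.15, "G2M": 0.30}
    )
    puncta_mean: float = 1.0         # Poisson mean of GFP-LC3 puncta
    p16_mfi: float = 100.0
    bcl2_mfi: float = 250.0
    promoter_mfi: float = 150.0
    cfse_divisions: int = 3          # dye halves per division
    cfse_initial_sum: float = 2.0e5  # integrated CFSE at zero divisions
    fucci_on_mfi: float = 500.0


def _default_shape_models() -> dict[str, ShapeModel]:
    return {
        "N": ShapeModel(area_mean=2000.0),
        "small": ShapeModel(area_mean=900.0),
        # E-state: spiky extensions 1-3 body radii long -> high irregularity
        "E": ShapeModel(area_mean=5000.0, area_sigma_log=0.20,
                        aspect_range=(1.05, 1.3), boundary_noise=0.03,
                        n_spikes_range=(3, 6)),
        # F-state: large, smooth, near-round -> low irregularity
        "F": ShapeModel(area_mean=7000.0, area_sigma_log=0.20,
                        aspect_range=(1.0, 1.2), boundary_noise=0.015),
    }


def _default_fluorescence_models() -> dict[str, FluorescenceModel]:
    return {
        "N": FluorescenceModel(),
        "small": FluorescenceModel(
            fucci_probs={"G1": 0.40, "S": 0.20, "G2M": 0.40},
            puncta_mean=1.0, cfse_divisions=3,
        ),
        "E": FluorescenceModel(
            fucci_probs={"G1": 0.85, "S": 0.05, "G2M": 0.10},
            puncta_mean=8.0, p16_mfi=400.0, bcl2_mfi=300.0,
            promoter_mfi=400.0, cfse_divisions=0,
        ),
        "F": FluorescenceModel(
            fucci_probs={"G1": 0.90, "S": 0.02, "G2M": 0.08},
            puncta_mean=1.0, p16_mfi=200.0, bcl2_mfi=150.0,
            promoter_mfi=100.0, cfse_divisions=0,
        ),
    }


@dataclass
class GrowthModel:
    """Passage-wise growth factors for cumulative-population-doubling scenarios.

    The default emulates a treatment-arrest course: exponential growth, a
    proliferative plateau under drug, then regrowth of escapers.
    """

    seeded: float = 1.0e4
    passage_days: float = 3.0
    growth_factors: tuple[float, ...] = (2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.6, 2.0)
    noise_sd_log: float = 0.02


@dataclass
class SyntheticScenario:
    """Full generative parameterization of one synthetic experiment."""

    seed: int = 0
    n_per_condition: int = 500
    compartment: str = "cell"
    state_mixture: dict[str, float] = field(
        default_factory=lambda: {"N": 0.45, "E": 0.35, "F": 0.15, "small": 0.05}
    )
    shape_models: dict[str, ShapeModel] = field(default_factory=_default_shape_models)
    fluorescence_models: dict[str, FluorescenceModel] = field(
        default_factory=_default_fluorescence_models
    )
    # condensed-state per-frame Markov matrix; E->F dominates, F->E is rare
    transition_matrix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "N": {"N": 0.90, "E": 0.08, "F": 0.02},
            "E": {"N": 0.00, "E": 0.60, "F": 0.40},
            "F": {"N": 0.00, "E": 0.05, "F": 0.95},
        }
    )
    n_tracks: int = 100
    frames: int = 10
    frame_interval: float = 0.5       # days (12 h)
    f_drift_per_frame: float = 0.05   # progressive F-state area enlargement
    track_autocorr: float = 0.7       # AR(1) coefficient of within-track area noise
    intensity_noise_frac: float = 0.10
    growth_model: GrowthModel = field(default_factory=GrowthModel)
    nucleus_area_scale: float = 0.25  # nuclear areas relative to cell areas

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.state_mixture.values()) - 1.0) > 1e-9:
            raise ConfigError("state_mixture must sum to 1")
        if any(v < 0 for v in self.state_mixture.values()):
            raise ConfigError("state_mixture proportions must be >= 0")
        for src, row in self.transition_matrix.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ConfigError(f"transition row {src!r} must sum to 1")
            if any(v < 0 for v in row.values()):
                raise ConfigError(f"transition row {src!r} has a negative rate")
        if self.n_per_condition < 1 or self.frames < 2 or self.n_tracks < 1:
            raise ConfigError("n_per_condition >= 1, frames >= 2, n_tracks >= 1 required")

    def substream(self, name: str) -> np.random.Generator:
        """Named child stream so adding one consumer never perturbs another."""
        order = ("shapes", "fluorescence", "transitions", "placement", "growth")
        if name not in order:
            raise ConfigError(f"unknown substream {name!r}")
        child = np.random.SeedSequence(self.seed, spawn_key=(order.index(name),))
        return np.random.default_rng(child)

    def to_yaml(self, path=None) -> str:
        payload = asdict(self)
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SyntheticScenario":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        for key in ("shape_models",):
            if key in payload:
                payload[key] = {
                    k: ShapeModel(**{**v, **{f: tuple(v[f]) for f in
                                             ("aspect_range", "n_spikes_range", "spike_length_range")
                                             if f in v}})
                    for k, v in payload[key].items()
                }
        if "fluorescence_models" in payload:
            payload["fluorescence_models"] = {
                k: FluorescenceModel(**v) for k, v in payload["fluorescence_models"].items()
            }
        if "growth_model" in payload:
            gm = payload["growth_model"]
            if "growth_factors" in gm:
                gm["growth_factors"] = tuple(gm["growth_factors"])
            payload["growth_model"] = GrowthModel(**gm)
        return cls(**payload)


# Condition presets emulating the treatment time-course: the extension-rich
# E-state dominates early, the flattened F-state accumulates, and a small
# proliferative subpopulation emerges at intermediate times.
CONDITION_PRESETS: dict[str, dict[str, float]] = {
    "control": {"N": 1.0, "E": 0.0, "F": 0.0, "small": 0.0},
    "day5": {"N": 0.45, "E": 0.35, "F": 0.15, "small": 0.05},
    "day12": {"N": 0.35, "E": 0.15, "F": 0.35, "small": 0.15},
    "day19": {"N": 0.30, "E": 0.05, "F": 0.55, "small": 0.10},
}


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    return (theta + math.pi) % (2 * math.pi) - math.pi


def _state_polygon(
    rng: np.random.Generator,
    model: ShapeModel,
    target_area: float,
    n_vertices: int = 180,
) -> np.ndarray:
    """Draw one star-shaped (radial) outline and rescale to the target area.

    Base outline is an ellipse with the drawn aspect ratio, perturbed by a
    smooth low-order Fourier radial noise; E-state outlines additionally carry
    triangular spiky extensions at random angles.  Radial construction
    guarantees a simple polygon; a final isotropic rescale pins the enclosed
    area to ``target_area`` exactly, so the stored ground-truth area is exact.
    """
    theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    aspect = rng.uniform(*model.aspect_range)
    a, b = math.sqrt(aspect), 1.0 / math.sqrt(aspect)
    # ellipse radius in polar form
    r = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    for k in range(2, 6):  # smooth boundary roughness
        amp = rng.normal(0.0, model.boundary_noise / k)
        phase = rng.uniform(0, 2 * math.pi)
        r *= 1.0 + amp * np.cos(k * theta + phase)
    n_spikes_lo, n_spikes_hi = model.n_spikes_range
    if n_spikes_hi > 0:
        n_spikes = int(rng.integers(n_spikes_lo, n_spikes_hi + 1))
        # extensions spread around the body (jittered even spacing) so the
        # centroid stays near the body center, as in extension-rich cells
        centers = (
            np.arange(n_spikes) * 2 * math.pi / n_spikes
            + rng.uniform(0, 2 * math.pi)
            + rng.normal(0, 0.25, size=n_spikes)
        )
        lengths = rng.uniform(*model.spike_length_range, size=n_spikes)
        bump_total = np.zeros_like(theta)
        for c, length in zip(centers, lengths):
            bump = np.clip(1.0 - np.abs(_wrap_angle(theta - c)) / model.spike_width, 0, None)
            bump_total += length * bump
        # extensions measured in body radii; overlapping spikes merge, capped
        # so the longest extension never exceeds the configured maximum
        r = r * (1.0 + np.minimum(bump_total, model.spike_length_range[1]))
    rot = rng.uniform(0, 2 * math.pi)
    xy = np.column_stack([r * np.cos(theta + rot), r * np.sin(theta + rot)])
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return xy * math.sqrt(target_area / area)


@dataclass
class SyntheticPopulation:
    """One generated condition: shapes, measured records and ground truth."""

    condition: str
    compartment: Compartment
    shapes: list[ShapeObject]
    records: list[MorphoRecord]
    ground_truth: pd.DataFrame   # object_id, state, true area, puncta, phase, divisions
    spots: pd.DataFrame          # per-punctum offsets relative to the object centroid
    scenario: SyntheticScenario

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def _draw_fluorescence(
    rng: np.random.Generator,
    fmodel: FluorescenceModel,
    area: float,
    noise_frac: float,
) -> tuple[FluorescenceProfile, dict]:
    phases = list(fmodel.fucci_probs)
    probs = np.array([fmodel.fucci_probs[p] for p in phases], dtype=float)
    phase = str(rng.choice(phases, p=probs / probs.sum()))
    noisy = lambda v: float(v * rng.lognormal(0.0, noise_frac)) if v > BACKGROUND_LEVEL else float(v)
    red = fmodel.fucci_on_mfi if phase in ("G1", "S") else BACKGROUND_LEVEL
    green = fmodel.fucci_on_mfi if phase in ("S", "G2M") else BACKGROUND_LEVEL
    puncta = int(rng.poisson(fmodel.puncta_mean))
    cfse_sum = fmodel.cfse_initial_sum / 2**fmodel.cfse_divisions * rng.lognormal(0.0, noise_frac)
    mfi = {
        "fucci_red": noisy(red),
        "fucci_green": noisy(green),
        "lc3": BACKGROUND_LEVEL + puncta * SPOT_NOMINAL_PX * SPOT_AMPLITUDE / area,
        "p16": noisy(fmodel.p16_mfi),
        "bcl2": noisy(fmodel.bcl2_mfi),
        "promoter": noisy(fmodel.promoter_mfi),
        "cfse": cfse_sum / area,
    }
    profile = FluorescenceProfile(
        mfi=mfi,
        density_sum={k: v * area for k, v in mfi.items()},
        puncta_count=puncta,
        puncta_total_area=float(puncta * SPOT_NOMINAL_PX),
    )
    truth = {"phase": phase, "puncta_count": puncta,
             "divisions": fmodel.cfse_divisions, "cfse_sum": cfse_sum}
    return profile, truth


def generate_condition(
    scenario: SyntheticScenario,
    condition: str = "day5",
    mixture: Optional[dict[str, float]] = None,
    timepoint: float = 0.0,
    compartment: Optional[str] = None,
) -> SyntheticPopulation:
    """Generate one mixed-state population with ground-truth state labels.

    ``condition`` selects a preset mixture (control/day5/day12/day19) unless an
    explicit ``mixture`` is given.  Per-object state, exact area, FUCCI phase,
    puncta count and CFSE divisions are stored in ``ground_truth``.
    """
    scenario.validate()
    if mixture is None:
        mixture = CONDITION_PRESETS.get(condition, scenario.state_mixture)
    total = sum(mixture.values())
    if total <= 0 or any(v < 0 for v in mixture.values()):
        raise ConfigError("invalid mixture")
    comp = Compartment(compartment or scenario.compartment)
    area_scale = scenario.nucleus_area_scale if comp is Compartment.NUCLEUS else 1.0
    shape_rng = scenario.substream("shapes")
    fluo_rng = scenario.substream("fluorescence")
    states = list(mixture)
    probs = np.array([mixture[s] for s in states], dtype=float) / total
    n = scenario.n_per_condition
    # exact proportional allocation (largest remainder), shuffled: the
    # generated composition equals the requested mixture, so downstream
    # recovery error measures the pipeline, not multinomial sampling noise
    quota = n * probs
    counts = np.floor(quota).astype(int)
    frac_order = np.argsort(-(quota - counts))
    counts[frac_order[: n - counts.sum()]] += 1
    drawn = np.repeat(states, counts)
    shape_rng.shuffle(drawn)
    shapes, records, truth_rows, spot_rows = [], [], [], []
    for i, state in enumerate(drawn):
        smodel = scenario.shape_models[state]
        fmodel = scenario.fluorescence_models[state]
        area = smodel.draw_area(shape_rng) * area_scale
        poly = _state_polygon(shape_rng, smodel, area)
        oid = f"{condition}_{i:05d}"
        shape = ShapeObject(object_id=oid, compartment=comp, polygon=poly)
        desc = compute_descriptors(shape)
        profile, ftruth = _draw_fluorescence(fluo_rng, fmodel, area, scenario.intensity_noise_frac)
        records.append(MorphoRecord(
            object_id=oid, compartment=comp, descriptors=desc,
            irregularity=compute_irregularity(desc), condition=condition,
            timepoint=timepoint, fluorescence=profile, ground_truth_state=state,
        ))
        shapes.append(shape)
        truth_rows.append({"object_id": oid, "state": state, "true_area": area, **ftruth})
        for _ in range(ftruth["puncta_count"]):
            spot_rows.append({"object_id": oid})
    return SyntheticPopulation(
        condition=condition, compartment=comp, shapes=shapes, records=records,
        ground_truth=pd.DataFrame(truth_rows),
        spots=pd.DataFrame(spot_rows, columns=["object_id"]),
        scenario=scenario,
    )


def generate_control_population(
    n: int = 1000,
    seed: int = 42,
    compartment: str = "nucleus",
    scenario: Optional[SyntheticScenario] = None,
) -> SyntheticPopulation:
    """Compact, mildly elliptical control population (unimodal area and
    irregularity), used to calibrate the normal ellipse.  Deterministic per seed."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    if scenario is None:
        scenario = SyntheticScenario(seed=seed, n_per_condition=n, compartment=compartment)
    else:
        scenario.validate()
    return generate_condition(scenario, condition="control", compartment=compartment)


@dataclass
class SyntheticTimelapse:
    """Tracked per-frame records plus the ground-truth transition log."""

    records: pd.DataFrame
    transition_log: pd.DataFrame   # track_id, frame, timepoint, from_state, to_state
    state_log: pd.DataFrame        # track_id, frame, state
    scenario: SyntheticScenario


def generate_timelapse(scenario: SyntheticScenario) -> SyntheticTimelapse:
    """Simulate tracked cells through the condensed-state Markov chain.

    Each track starts in a state drawn from the (N/E/F-renormalised) mixture
    and evolves per frame by ``transition_matrix``.  Per-frame areas follow the
    current state's lognormal model with a per-track random scale and AR(1)
    within-track noise; time spent in the F-state compounds a multiplicative
    area drift, emulating progressive enlargement.  The exact transition events
    are logged as ground truth.
    """
    scenario.validate()
    trans_rng = scenario.substream("transitions")
    shape_rng = scenario.substream("shapes")
    comp = Compartment(scenario.compartment)
    chain_states = list(scenario.transition_matrix)
    start_probs = np.array(
        [scenario.state_mixture.get(s, 0.0) for s in chain_states], dtype=float
    )
    if start_probs.sum() <= 0:
        raise ConfigError("state_mixture assigns no mass to chain states")
    start_probs /= start_probs.sum()
    rows, trans_rows, state_rows = [], [], []
    rho = scenario.track_autocorr
    for t in range(scenario.n_tracks):
        track_id = f"track_{t:04d}"
        state = str(trans_rng.choice(chain_states, p=start_probs))
        track_scale = float(shape_rng.lognormal(0.0, 0.05))
        eps = float(shape_rng.normal())
        frames_in_f = 0
        for f in range(scenario.frames):
            smodel = scenario.shape_models[state]
            eps = rho * eps + math.sqrt(1 - rho**2) * float(shape_rng.normal())
            drift = (1.0 + scenario.f_drift_per_frame) ** frames_in_f
            area = smodel.area_mean * track_scale * drift * math.exp(
                smodel.area_sigma_log * eps - smodel.area_sigma_log**2 / 2
            )
            poly = _state_polygon(shape_rng, smodel, area)
            oid = f"{track_id}_f{f:02d}"
            desc = compute_descriptors(
                ShapeObject(object_id=oid, compartment=comp, polygon=poly)
            )
            rows.append(MorphoRecord(
                object_id=oid, compartment=comp, descriptors=desc,
                irregularity=compute_irregularity(desc), condition="timelapse",
                timepoint=f * scenario.frame_interval, track_id=track_id,
                ground_truth_state=state,
            ))
            state_rows.append({"track_id": track_id, "frame": f, "state": state})
            if f < scenario.frames - 1:
                row = scenario.transition_matrix[state]
                nxt = str(trans_rng.choice(chain_states,
                                           p=np.array([row[s] for s in chain_states])))
                if nxt != state:
                    trans_rows.append({
                        "track_id": track_id, "frame": f + 1,
                        "timepoint": (f + 1) * scenario.frame_interval,
                        "from_state": state, "to_state": nxt,
                    })
                if state == "F":
                    frames_in_f += 1
                state = nxt
    return SyntheticTimelapse(
        records=records_to_frame(rows),
        transition_log=pd.DataFrame(
            trans_rows, columns=["track_id", "frame", "timepoint", "from_state", "to_state"]
        ),
        state_log=pd.DataFrame(state_rows),
        scenario=scenario,
    )


def generate_growth_series(
    scenario: SyntheticScenario,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Passage timepoints and counts under the scenario's growth model.

    Returns ``(timepoints, counts, seeded)`` for :func:`senmorph.population.cumulative_pd`:
    at each passage the culture is reseeded at ``seeded`` cells and counted
    after multiplying by the phase's growth factor (with lognormal noise).
    """
    gm = scenario.growth_model
    rng = scenario.substream("growth")
    n_pass = len(gm.growth_factors)
    timepoints = np.arange(n_pass + 1, dtype=float) * gm.passage_days
    counts = np.empty(n_pass + 1)
    counts[0] = gm.seeded
    for i, factor in enumerate(gm.growth_factors):
        counts[i + 1] = gm.seeded * factor * rng.lognormal(0.0, gm.noise_sd_log)
    return timepoints, counts, gm.seeded


@dataclass
class RenderedImages:
    """Rasterized label mask and fluorescence channels for one population."""

    mask: np.ndarray                      # uint16 label image
    channels: dict[str, np.ndarray]       # float32, same shape as mask
    label_map: dict[int, str]             # label -> object_id
    spots: pd.DataFrame                   # object_id, x, y of rendered puncta
    offsets: pd.DataFrame                 # object_id, label, dx, dy placement


def _place_spots(
    rng: np.random.Generator,
    binary: np.ndarray,
    n_spots: int,
    min_edge_dist: float = 4.0,
    min_separation: float = 8.0,
    max_tries: int = 200,
) -> list[tuple[int, int]]:
    """Sample punctum centers inside a region, away from the edge and each other."""
    if n_spots == 0:
        return []
    dist = ndimage.distance_transform_edt(binary)
    rows, cols = np.nonzero(dist >= min_edge_dist)
    if len(rows) == 0:
        rows, cols = np.nonzero(binary)
    placed: list[tuple[int, int]] = []
    for _ in range(n_spots):
        for _ in range(max_tries):
            j = int(rng.integers(len(rows)))
            cand = (int(rows[j]), int(cols[j]))
            if all(math.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_separation for p in placed):
                placed.append(cand)
                break
        else:  # crowded cell: accept a closer spot rather than dropping it
            j = int(rng.integers(len(rows)))
            placed.append((int(rows[j]), int(cols[j])))
    return placed


def render_images(
    population: SyntheticPopulation,
    channels: Sequence[str] = CHANNEL_NAMES,
    margin: int = 12,
) -> RenderedImages:
    """Rasterize a population onto a grid canvas with no overlaps.

    Each object is placed in its own grid tile (sized to the largest bounding
    box plus ``margin``), so labels never touch each other or the border.
    Fluorescence channels are filled with the object's generated mean intensity
    plus pixel noise; the LC3 channel carries Gaussian puncta at logged
    coordinates on a diffuse background.
    """
    shapes = population.shapes
    rng = population.scenario.substream("placement")
    noise_frac = population.scenario.intensity_noise_frac
    if not shapes:
        side = 64
        blank = np.full((side, side), BACKGROUND_LEVEL, dtype=np.float32)
        blank += rng.normal(0, BACKGROUND_SD, blank.shape).astype(np.float32)
        return RenderedImages(
            mask=np.zeros((side, side), dtype=np.uint16),
            channels={c: np.clip(blank, 0, None) for c in channels},
            label_map={},
            spots=pd.DataFrame(columns=["object_id", "x", "y"]),
            offsets=pd.DataFrame(columns=["object_id", "label", "dx", "dy"]),
        )
    extents = []
    for s in shapes:
        p = s.polygon
        extents.append(max(p[:, 0].max() - p[:, 0].min(), p[:, 1].max() - p[:, 1].min()))
    tile = int(math.ceil(max(extents))) + 2 * margin
    ncol = int(math.ceil(math.sqrt(len(shapes))))
    nrow = int(math.ceil(len(shapes) / ncol))
    H, W = nrow * tile, ncol * tile
    mask = np.zeros((H, W), dtype=np.uint16)
    truth = population.ground_truth.set_index("object_id")
    rec_by_id = {r.object_id: r for r in population.records}
    label_map, offsets, spot_rows = {}, [], []
    spot_pixels: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    fills: dict[str, list] = {c: [] for c in channels if c != "lc3"}
    for idx, shape in enumerate(shapes):
        rtile, ctile = divmod(idx, ncol)
        cx = ctile * tile + tile / 2
        cy = rtile * tile + tile / 2
        poly = shape.polygon.copy()
        poly[:, 0] += cx - (poly[:, 0].max() + poly[:, 0].min()) / 2
        poly[:, 1] += cy - (poly[:, 1].max() + poly[:, 1].min()) / 2
        if poly[:, 0].min() < 1 or poly[:, 1].min() < 1 or poly[:, 0].max() > W - 2 or poly[:, 1].max() > H - 2:
            raise ConfigError(f"object {shape.object_id!r} overflows its tile")
        rr, cc = skdraw.polygon(poly[:, 1], poly[:, 0], shape=mask.shape)
        label = idx + 1
        mask[rr, cc] = label
        label_map[label] = shape.object_id
        offsets.append({"object_id": shape.object_id, "label": label,
                        "dx": float(cx), "dy": float(cy)})
        record = rec_by_id[shape.object_id]
        mfi = record.fluorescence.mfi if record.fluorescence else {}
        for c in fills:
            fills[c].append((rr, cc, float(mfi.get(c, BACKGROUND_LEVEL))))
        if "lc3" in channels:
            n_spots = int(truth.loc[shape.object_id, "puncta_count"]) if shape.object_id in truth.index else 0
            binary = np.zeros(mask.shape, dtype=bool)
            binary[rr, cc] = True
            win = binary[rtile * tile:(rtile + 1) * tile, ctile * tile:(ctile + 1) * tile]
            for r0, c0 in _place_spots(rng, win, n_spots):
                gr = rtile * tile + r0
                gc = ctile * tile + c0
                spot_rows.append({"object_id": shape.object_id, "x": gc, "y": gr})
    images: dict[str, np.ndarray] = {}
    for c in channels:
        img = np.full((H, W), BACKGROUND_LEVEL, dtype=np.float64)
        if c == "lc3":
            half = int(math.ceil(4 * SPOT_SIGMA))
            for row in spot_rows:
                gr, gc = row["y"], row["x"]
                r0, r1 = max(gr - half, 0), min(gr + half + 1, H)
                c0, c1 = max(gc - half, 0), min(gc + half + 1, W)
                yy, xx = np.mgrid[r0:r1, c0:c1]
                img[r0:r1, c0:c1] += SPOT_AMPLITUDE * np.exp(
                    -((yy - gr) ** 2 + (xx - gc) ** 2) / (2 * SPOT_SIGMA**2)
                )
        else:
            for rr, cc, level in fills[c]:
                base = max(level, BACKGROUND_LEVEL)
                img[rr, cc] = base * (1.0 + noise_frac * rng.normal(size=len(rr)) * 0.1)
        img += rng.normal(0, BACKGROUND_SD, img.shape)
        images[c] = np.clip(img, 0, None).astype(np.float32)
    return RenderedImages(
        mask=mask,
        channels=images,
        label_map=label_map,
        spots=pd.DataFrame(spot_rows, columns=["object_id", "x", "y"]),
        offsets=pd.DataFrame(offsets),
    )
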