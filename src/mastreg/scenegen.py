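"""Synthetic two/three-channel skin-movie generator with full ground truth.

Emulates the appearance and dynamics of intravital confocal movies of
mouse ear skin so that every analysis stage can be verified against a
known answer:

* sessile, elongated dermal mast cells (tdTomato red) with
  tdT-negative nuclear holes, placed as a hard-core point process at
  ~360 cells/mm²;
* motile, round Tregs (eGFP green) at ~1/20 the mast-cell density,
  rising ~15-fold in the anaphylaxis (PCA) arm, performing an isotropic
  random walk with scheduled contact episodes on mast-cell boundaries;
* "yellow" autofluorescent hair follicles rendered in both the red and
  blue channels, never in green;
* an optional epidermal Langerhans-cell layer at a distinct z with
  periodically sprouting dendrite tips, to exercise the temporal
  color coding;
* a slow mast-cell depletion/repopulation time course after conditional
  ablation.

The generator is deterministic given a seed, and seeds a fixed number of
cells, N = round(density × area), so density-recovery tests carry no
seeding variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .stackio import (
    DEFAULT_FRAME_INTERVAL_MIN,
    TREG_FRAME_INTERVAL_MIN,
    ImageStack,
    StackMeta,
)

__all__ = [
    "MCShape",
    "NoiseConfig",
    "ContactModel",
    "control_contact_model",
    "pca_contact_model",
    "ScenarioConfig",
    "MCCell",
    "TregTrack",
    "Follicle",
    "LCCell",
    "SeededContact",
    "GroundTruth",
    "sample_cell_positions",
    "mc_repopulation_density",
    "simulate_treg_tracks",
    "render_stack",
    "simulate_scene",
    "contact_scenario",
    "velocity_scenario",
    "homeostasis_scenario",
]


@dataclass(frozen=True)
class MCShape:
    """Mast-cell ellipse geometry (full axes, µm)."""

    major_axis_um: float = 20.0
    minor_axis_um: float = 8.0
    nuclear_hole: bool = True
    #: nuclear ellipse axes as a fraction of the cell axes
    hole_fraction: float = 0.35


@dataclass(frozen=True)
class NoiseConfig:
    """Additive background, Gaussian read noise sd, and shot-noise flag.

    Intensities are on a scale where a cell body renders at 1.0.
    """

    background: float = 0.05
    gaussian_sd: float = 0.02
    photon_noise: bool = False
    #: photons per unit intensity when shot noise is enabled
    photons_per_unit: float = 100.0

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(background=0.0, gaussian_sd=0.0, photon_noise=False)


@dataclass(frozen=True)
class ContactModel:
    """Distribution of seeded contact-episode durations (minutes).

    Either an exponential with mean ``mean_min`` or a mixture of uniform
    components ``(weight, (low, high))`` with weights summing to 1.
    """

    kind: str = "exponential"
    mean_min: float = 3.0
    components: tuple[tuple[float, tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "mixture"):
            raise ValueError(f"unknown contact model kind {self.kind!r}")
        if self.kind == "mixture":
            total = sum(w for w, _ in self.components)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"mixture weights must sum to 1, got {total}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "exponential":
            return float(rng.exponential(self.mean_min))
        u = rng.random()
        acc = 0.0
        for w, (lo, hi) in self.components:
            acc += w
            if u <= acc:
                return float(rng.uniform(lo, hi))
        lo, hi = self.components[-1][1]
        return float(rng.uniform(lo, hi))


def control_contact_model() -> ContactModel:
    """Occasional brief encounters: exponential, mean 3 min."""
    return ContactModel(kind="exponential", mean_min=3.0)


def pca_contact_model() -> ContactModel:
    """Post-degranulation episodes: mostly 10–50 min, a fraction >50 min."""
    return ContactModel(
        kind="mixture",
        components=((0.6, (10.0, 50.0)), (0.25, (50.0, 80.0)), (0.15, (0.0, 10.0))),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one simulated imaging session."""

    field_size_mm: tuple[float, float] = (0.45, 0.45)
    mc_density_per_mm2: float = 360.0
    treg_baseline_per_mm2: float = 18.0
    pca: bool = False
    pca_treg_fold: float = 15.0
    treg_speed_um_min: float = 5.0
    n_frames: int = 1
    meta: StackMeta = field(default_factory=StackMeta)
    mc_shape: MCShape = field(default_factory=MCShape)
    follicle_density_per_mm2: float = 4.0
    follicle_diameter_um: float = 40.0
    contact_model: ContactModel | None = field(default_factory=control_contact_model)
    episodes_per_treg: int = 1
    repopulation_day: float | None = None
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    include_lc_layer: bool = False
    lc_density_per_mm2: float = 50.0
    #: hard-core separation of mast-cell centroids; just above the cell major
    #: axis so neighboring cells never merge into one thresholded component
    min_separation_um: float = 22.0
    #: outside scheduled episodes, Treg steps landing closer than this to a
    #: mast-cell boundary are resampled, so scheduled episodes are the only
    #: contacts and the ground truth stays unambiguous; comfortably beyond
    #: the Treg blob's above-floor intensity footprint
    mc_avoidance_um: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.field_size_mm) <= 0:
            raise ValueError("field dimensions must be strictly positive")
        for name in ("mc_density_per_mm2", "treg_baseline_per_mm2", "follicle_density_per_mm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pca_treg_fold < 1:
            raise ValueError("pca_treg_fold must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pca and self.contact_model is not None and self.contact_model.kind == "exponential":
            # the PCA arm defaults to the shifted duration mixture
            object.__setattr__(self, "contact_model", pca_contact_model())

    @property
    def area_mm2(self) -> float:
        return self.field_size_mm[0] * self.field_size_mm[1]

    @property
    def field_size_um(self) -> tuple[float, float]:
        return (self.field_size_mm[0] * 1000.0, self.field_size_mm[1] * 1000.0)

    @property
    def treg_density_per_mm2(self) -> float:
        return self.treg_baseline_per_mm2 * (self.pca_treg_fold if self.pca else 1.0)

    @property
    def effective_mc_density_per_mm2(self) -> float:
        if self.repopulation_day is None:
            return self.mc_density_per_mm2
        return mc_repopulation_density(self.repopulation_day, self.mc_density_per_mm2)

    def with_meta_field(self) -> "ScenarioConfig":
        """Return a copy whose meta field_size_px matches the field in mm."""
        px = self.meta.pixel_size_um
        h = int(round(self.field_size_um[0] / px))
        w = int(round(self.field_size_um[1] / px))
        return replace(self, meta=self.meta.replace(field_size_px=(h, w)))


@dataclass(frozen=True)
class MCCell:
    id: int
    y_um: float
    x_um: float
    orientation_rad: float
    major_axis_um: float
    minor_axis_um: float

    def boundary_point(self, tau: float) -> tuple[float, float]:
        """Boundary point at parametric angle ``tau`` (ellipse frame)."""
        a = self.major_axis_um / 2.0
        b = self.minor_axis_um / 2.0
        ex, ey = a * math.cos(tau), b * math.sin(tau)
        c, s = math.cos(self.orientation_rad), math.sin(self.orientation_rad)
        return (self.y_um + ex * s + ey * c, self.x_um + ex * c - ey * s)

    def boundary_normal(self, tau: float) -> tuple[float, float]:
        """Outward unit normal at parametric angle ``tau``, as (dy, dx)."""
        a = self.major_axis_um / 2.0
        b = self.minor_axis_um / 2.0
        nx, ny = math.cos(tau) / a, math.sin(tau) / b
        norm = math.hypot(nx, ny)
        nx, ny = nx / norm, ny / norm
        c, s = math.cos(self.orientation_rad), math.sin(self.orientation_rad)
        return (nx * s + ny * c, nx * c - ny * s)

    def boundary_samples(self, n: int = 48) -> np.ndarray:
        """(n, 2) array of (y, x) boundary points, for fast distance queries."""
        taus = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        a = self.major_axis_um / 2.0
        b = self.minor_axis_um / 2.0
        ex, ey = a * np.cos(taus), b * np.sin(taus)
        c, s = math.cos(self.orientation_rad), math.sin(self.orientation_rad)
        return np.column_stack([self.y_um + ex * s + ey * c, self.x_um + ex * c - ey * s])

    def signed_boundary_distance(self, y_um: float, x_um: float) -> float:
        """Approximate signed distance to the ellipse boundary (negative inside).

        Radial approximation: exact on circles, adequate for the mild
        4:1.6 axis ratios used here.
        """
        a = self.major_axis_um / 2.0
        b = self.minor_axis_um / 2.0
        dy, dx = y_um - self.y_um, x_um - self.x_um
        c, s = math.cos(self.orientation_rad), math.sin(self.orientation_rad)
        u = dx * c + dy * s   # along major axis
        v = -dx * s + dy * c  # along minor axis
        r = math.hypot(u, v)
        if r == 0:
            return -b
        r_boundary = 1.0 / math.sqrt((u / r / a) ** 2 + (v / r / b) ** 2)
        return r - r_boundary


@dataclass
class TregTrack:
    id: int
    positions_um: np.ndarray  # (n_frames, 2) as (y, x)


@dataclass(frozen=True)
class Follicle:
    y_um: float
    x_um: float
    diameter_um: float


@dataclass
class LCCell:
    id: int
    y_um: float
    x_um: float
    #: (n_frames, 4, 2) dendrite tip positions (y, x) µm
    tip_positions_um: np.ndarray


@dataclass(frozen=True)
class SeededContact:
    mc_id: int
    treg_id: int
    start_frame: int
    end_frame: int


@dataclass
class GroundTruth:
    """Generator-emitted cells, tracks, and contact intervals."""

    mc_cells: list[MCCell]
    treg_tracks: list[TregTrack]
    follicles: list[Follicle]
    contacts: list[SeededContact]
    lc_cells: list[LCCell] = field(default_factory=list)
    densities_seeded: dict[str, float] = field(default_factory=dict)


def sample_cell_positions(
    density_per_mm2: float,
    field_size_mm: tuple[float, float],
    min_separation_um: float,
    rng: np.random.Generator,
    margin_um: float = 0.0,
    forbidden_centers: np.ndarray | None = None,
    forbidden_radius_um: float = 0.0,
) -> np.ndarray:
    """Hard-core uniform placement of exactly N = round(density × area) points.

    Returns an (N, 2) array of (y, x) centroids in µm.  ``margin_um``
    keeps points away from the field border (so rendered cell bodies stay
    in frame); ``forbidden_centers`` (with ``forbidden_radius_um``)
    excludes zones already occupied by other structures.  Raises when the
    requested packing is infeasible after a bounded number of rejection
    rounds.
    """
    if density_per_mm2 < 0:
        raise ValueError("density must be >= 0")
    if min_separation_um < 0:
        raise ValueError("min_separation must be >= 0")
    h_um, w_um = field_size_mm[0] * 1000.0, field_size_mm[1] * 1000.0
    n = int(round(density_per_mm2 * field_size_mm[0] * field_size_mm[1]))
    if n == 0:
        return np.empty((0, 2))
    min_sq = min_separation_um**2
    forb = None
    if forbidden_centers is not None and len(forbidden_centers):
        forb = np.asarray(forbidden_centers, dtype=float)
    forb_sq = forbidden_radius_um**2
    for _round in range(5):
        arr = np.empty((n, 2))
        failed = False
        for i in range(n):
            for _try in range(1000):
                y = rng.uniform(margin_um, h_um - margin_um)
                x = rng.uniform(margin_um, w_um - margin_um)
                if forb is not None:
                    d2f = (forb[:, 0] - y) ** 2 + (forb[:, 1] - x) ** 2
                    if d2f.min() < forb_sq:
                        continue
                if i == 0:
                    break
                d2 = (arr[:i, 0] - y) ** 2 + (arr[:i, 1] - x) ** 2
                if d2.min() >= min_sq:
                    break
            else:
                failed = True
                break
            arr[i] = (y, x)
        if not failed:
            return arr
    raise RuntimeError(
        f"infeasible packing: {n} points with {min_separation_um} µm separation "
        f"in a {field_size_mm[0]}×{field_size_mm[1]} mm field"
    )


#: Repopulation anchor days and densities after diphtheria-toxin ablation:
#: profound depletion by day 6, first repopulating cells around day 11,
#: slow recovery to ~150 cells/mm² at 3 months, flat thereafter.
_REPOPULATION_DAYS = (0.0, 6.0, 11.0, 90.0)
_REPOPULATION_DENSITIES = (None, 5.0, 30.0, 150.0)  # None = baseline


def mc_repopulation_density(day: float, baseline_per_mm2: float) -> float:
    """Mast-cell density (cells/mm²) at ``day`` days after conditional ablation.

    Piecewise-linear through (0, baseline), (6, 5), (11, 30), (90, 150),
    constant beyond day 90.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    ys = (baseline_per_mm2,) + _REPOPULATION_DENSITIES[1:]
    return float(np.interp(day, _REPOPULATION_DAYS, ys))


#: radial clearance (µm) of a contacting Treg centroid outside the mast-cell
#: boundary; the upper end is the ground-truth adjacency tolerance
EPISODE_OFFSET_RANGE_UM = (0.5, 1.5)


def _nearest_mc(mc_cells: list[MCCell], y: float, x: float) -> MCCell:
    return min(mc_cells, key=lambda m: (m.y_um - y) ** 2 + (m.x_um - x) ** 2)


def _schedule_episodes(
    config: ScenarioConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Non-overlapping (start, end) frame spans for one Treg's episodes."""
    dt = config.meta.frame_interval_min
    spans: list[tuple[int, int]] = []
    for _ in range(config.episodes_per_treg):
        duration_min = config.contact_model.sample(rng)
        n = max(1, int(round(duration_min / dt)))
        n = min(n, config.n_frames)
        for _try in range(50):
            start = int(rng.integers(0, config.n_frames - n + 1))
            end = start + n - 1
            # keep a 2-frame buffer so episodes are unambiguously separate
            if all(start > e + 2 or end < s - 2 for s, e in spans):
                spans.append((start, end))
                break
    return sorted(spans)


def simulate_treg_tracks(
    config: ScenarioConfig,
    mc_cells: list[MCCell],
    rng: np.random.Generator,
) -> tuple[list[TregTrack], list[SeededContact]]:
    """Simulate Treg random walks with scheduled mast-cell contact episodes.

    Between episodes each Treg takes fixed-length isotropic steps of
    ``treg_speed_um_min × frame_interval_min`` µm, reflected at the field
    borders and resampled away from mast-cell boundaries (avoidance
    buffer).  During an episode the Treg wobbles along the assigned
    mast cell's boundary, its centroid within 2 µm of the boundary, at
    the nominal speed but with the per-frame angular excursion capped so
    a wobbling cell crawls around its mast cell rather than jumping
    across it.  Each mast cell hosts at most one Treg at a time, so
    every seeded episode is an unambiguous, isolated ground-truth event.
    """
    if config.n_frames < 2 and config.episodes_per_treg > 0 and config.contact_model is not None:
        raise ValueError("contact simulation needs n_frames >= 2")
    n_tregs = int(round(config.treg_density_per_mm2 * config.area_mm2))
    want_contacts = config.contact_model is not None and config.episodes_per_treg > 0
    if want_contacts and n_tregs > 0 and not mc_cells:
        raise ValueError("contact model demands contacts but no mast cells are present")

    h_um, w_um = config.field_size_um
    dt = config.meta.frame_interval_min
    step = config.treg_speed_um_min * dt
    avoid = config.mc_avoidance_um
    margin = 5.0

    # sampled boundaries give near-exact clearance queries (the radial
    # approximation can overestimate clearance by several µm on elongated
    # cells, which would let "avoided" walk positions graze real contacts)
    boundary_pts = (
        np.vstack([m.boundary_samples() for m in mc_cells]) if mc_cells else np.empty((0, 2))
    )
    avoid_sq = avoid * avoid

    def too_close(y: float, x: float) -> bool:
        if not len(boundary_pts):
            return False
        d2 = (boundary_pts[:, 0] - y) ** 2 + (boundary_pts[:, 1] - x) ** 2
        return bool(d2.min() < avoid_sq)

    def free_position() -> tuple[float, float]:
        for _ in range(200):
            y = rng.uniform(margin, h_um - margin)
            x = rng.uniform(margin, w_um - margin)
            if not too_close(y, x):
                return y, x
        return y, x

    tracks: list[TregTrack] = []
    contacts: list[SeededContact] = []
    #: mc id -> frame spans already hosting a Treg (one guest at a time)
    occupancy: dict[int, list[tuple[int, int]]] = {}

    def pick_free_mc(y: float, x: float, span: tuple[int, int]) -> MCCell:
        # a few frames of buffer between successive guests of one mast cell
        # keep distinct seeded episodes temporally well separated
        s, e = span
        ordered = sorted(mc_cells, key=lambda m: (m.y_um - y) ** 2 + (m.x_um - x) ** 2)
        for mc in ordered:
            if all(e + 4 < s2 or s > e2 + 4 for s2, e2 in occupancy.get(mc.id, [])):
                return mc
        return ordered[0]

    for tid in range(n_tregs):
        spans = _schedule_episodes(config, rng) if want_contacts and mc_cells else []
        in_span = {}
        for si, (s, e) in enumerate(spans):
            for f in range(s, e + 1):
                in_span[f] = si
        span_mc: dict[int, MCCell] = {}
        span_tau: dict[int, float] = {}

        pos = np.empty((config.n_frames, 2))
        y, x = free_position()
        for f in range(config.n_frames):
            si = in_span.get(f)
            if si is not None:
                mc = span_mc.get(si)
                if mc is None:
                    mc = pick_free_mc(y, x, spans[si])
                    span_mc[si] = mc
                    occupancy.setdefault(mc.id, []).append(spans[si])
                    span_tau[si] = rng.uniform(0, 2 * math.pi)
                else:
                    # crawl along the boundary; cap the angular excursion so
                    # wobbling stays local to one side of the cell
                    r_eff = (mc.major_axis_um + mc.minor_axis_um) / 4.0
                    dtau = min(step / max(r_eff, 1.0), 0.6)
                    span_tau[si] += rng.choice((-1.0, 1.0)) * dtau
                by, bx = mc.boundary_point(span_tau[si])
                ny, nx = mc.boundary_normal(span_tau[si])
                # small offset along the outward normal keeps the centroid
                # within 2 µm of the boundary but clearly outside it
                # (touching, not straddling)
                off = rng.uniform(*EPISODE_OFFSET_RANGE_UM)
                y = by + off * ny
                x = bx + off * nx
            elif f > 0:
                for _try in range(20):
                    phi = rng.uniform(0, 2 * math.pi)
                    ny = y + step * math.sin(phi)
                    nx = x + step * math.cos(phi)
                    # reflect at the field borders
                    ny = abs(ny)
                    ny = 2 * h_um - ny if ny > h_um else ny
                    nx = abs(nx)
                    nx = 2 * w_um - nx if nx > w_um else nx
                    if not too_close(ny, nx):
                        break
                y, x = ny, nx
            y = min(max(y, 0.0), h_um)
            x = min(max(x, 0.0), w_um)
            pos[f] = (y, x)
        tracks.append(TregTrack(id=tid, positions_um=pos))
        for si, (s, e) in enumerate(spans):
            contacts.append(
                SeededContact(mc_id=span_mc[si].id, treg_id=tid, start_frame=s, end_frame=e)
            )
    return tracks, contacts


def _add_gaussian_blob(plane: np.ndarray, y_px: float, x_px: float, sigma_px: float,
                       amplitude: float = 1.0) -> None:
    """Add a Gaussian spot to ``plane`` in place (3.5 sd support)."""
    h, w = plane.shape
    r = int(math.ceil(3.5 * sigma_px))
    y0, y1 = int(math.floor(y_px)) - r, int(math.floor(y_px)) + r + 1
    x0, x1 = int(math.floor(x_px)) - r, int(math.floor(x_px)) + r + 1
    ys = np.arange(max(y0, 0), min(y1, h))
    xs = np.arange(max(x0, 0), min(x1, w))
    if ys.size == 0 or xs.size == 0:
        return
    gy = np.exp(-((ys - y_px) ** 2) / (2 * sigma_px**2))
    gx = np.exp(-((xs - x_px) ** 2) / (2 * sigma_px**2))
    patch = amplitude * np.outer(gy, gx)
    region = plane[ys[0]: ys[-1] + 1, xs[0]: xs[-1] + 1]
    np.maximum(region, patch, out=region)


TREG_BLOB_SIGMA_UM = 3.0
FOLLICLE_AMPLITUDE = 0.8
LC_SOMA_RADIUS_UM = 5.0
LC_DENDRITE_BASE_UM = 8.0
LC_DENDRITE_AMPLITUDE_UM = 5.0
LC_DENDRITE_PERIOD_MIN = 10.0
PSF_SIGMA_PX = 1.0


def _simulate_lc_cells(config: ScenarioConfig, rng: np.random.Generator) -> list[LCCell]:
    positions = sample_cell_positions(
        config.lc_density_per_mm2, config.field_size_mm, config.min_separation_um, rng,
        margin_um=LC_DENDRITE_BASE_UM + LC_DENDRITE_AMPLITUDE_UM,
    )
    dt = config.meta.frame_interval_min
    cells = []
    for i, (y, x) in enumerate(positions):
        angles = rng.uniform(0, 2 * math.pi) + np.arange(4) * (math.pi / 2)
        phase = rng.uniform(0, 2 * math.pi)
        tips = np.empty((config.n_frames, 4, 2))
        for f in range(config.n_frames):
            r = LC_DENDRITE_BASE_UM + LC_DENDRITE_AMPLITUDE_UM * math.sin(
                2 * math.pi * f * dt / LC_DENDRITE_PERIOD_MIN + phase
            )
            tips[f, :, 0] = y + r * np.sin(angles)
            tips[f, :, 1] = x + r * np.cos(angles)
        cells.append(LCCell(id=i, y_um=y, x_um=x, tip_positions_um=tips))
    return cells


def render_stack(
    truth: GroundTruth, config: ScenarioConfig, rng: np.random.Generator
) -> ImageStack:
    """Render a ground-truth scene into a calibrated image stack.

    Red channel: mast-cell ellipses (intensity 1.0, nuclear hole at 0)
    plus follicle disks; green: Treg Gaussian blobs (sd 3 µm) plus
    optional Langerhans somata/dendrite tips; blue: follicle disks.  Each
    population occupies its own z-slab (Langerhans cells at a distinct z)
    so maximum Z-projection merges them.  All planes are blurred with a
    Gaussian point-spread function (sd 1 px), then background and noise
    are applied.
    """
    config = config.with_meta_field()
    meta = config.meta
    px = meta.pixel_size_um
    h, w = meta.field_size_px
    h_um, w_um = config.field_size_um
    for mc in truth.mc_cells:
        if not (0 <= mc.y_um <= h_um and 0 <= mc.x_um <= w_um):
            raise ValueError("ground truth mast cell outside the configured field")
    for tr in truth.treg_tracks:
        if tr.positions_um.shape[0] != config.n_frames:
            raise ValueError("ground truth track length differs from n_frames")

    roles = meta.channel_roles
    n_z = 3 if config.include_lc_layer else 2
    z_mc, z_treg, z_lc = 0, min(1, n_z - 1), n_z - 1

    # static planes: mast cells + follicles (red), follicles (blue)
    red_static = np.zeros((h, w))
    for mc in truth.mc_cells:
        # orientation is measured from +x counterclockwise; skimage's
        # rotation convention requires the minor axis first and the sign
        # flipped to describe the same ellipse
        rr, cc = draw_ellipse(
            mc.y_um / px, mc.x_um / px,
            mc.minor_axis_um / 2 / px, mc.major_axis_um / 2 / px,
            shape=(h, w), rotation=-mc.orientation_rad,
        )
        red_static[rr, cc] = 1.0
        if config.mc_shape.nuclear_hole:
            frac = config.mc_shape.hole_fraction
            rr, cc = draw_ellipse(
                mc.y_um / px, mc.x_um / px,
                frac * mc.minor_axis_um / 2 / px, frac * mc.major_axis_um / 2 / px,
                shape=(h, w), rotation=-mc.orientation_rad,
            )
            red_static[rr, cc] = 0.0
    follicle_static = np.zeros((h, w))
    for fol in truth.follicles:
        rr, cc = draw_disk((fol.y_um / px, fol.x_um / px), fol.diameter_um / 2 / px, shape=(h, w))
        follicle_static[rr, cc] = FOLLICLE_AMPLITUDE
    red_static = ndimage.gaussian_filter(np.maximum(red_static, follicle_static), PSF_SIGMA_PX)
    blue_static = ndimage.gaussian_filter(follicle_static, PSF_SIGMA_PX)

    data = np.zeros((config.n_frames, n_z, len(roles), h, w), dtype=np.float64)
    treg_sigma_px = TREG_BLOB_SIGMA_UM / px
    for t in range(config.n_frames):
        for ci, role in enumerate(roles):
            if role == "red_tdt":
                data[t, z_mc, ci] = red_static
            elif role == "blue_auto":
                data[t, z_mc, ci] = blue_static
            elif role == "green_egfp":
                green = np.zeros((h, w))
                for tr in truth.treg_tracks:
                    y, x = tr.positions_um[t]
                    _add_gaussian_blob(green, y / px, x / px, treg_sigma_px)
                data[t, z_treg, ci] = ndimage.gaussian_filter(green, PSF_SIGMA_PX)
                if config.include_lc_layer and truth.lc_cells:
                    lc = np.zeros((h, w))
                    for cell in truth.lc_cells:
                        rr, cc = draw_disk(
                            (cell.y_um / px, cell.x_um / px), LC_SOMA_RADIUS_UM / px, shape=(h, w)
                        )
                        lc[rr, cc] = 1.0
                        for ty, tx in cell.tip_positions_um[t]:
                            _add_gaussian_blob(lc, ty / px, tx / px, 1.5 / px, amplitude=0.8)
                    data[t, z_lc, ci] = ndimage.gaussian_filter(lc, PSF_SIGMA_PX)

    noise = config.noise
    if noise.photon_noise:
        scale = noise.photons_per_unit
        data = rng.poisson((data + noise.background) * scale) / scale
    else:
        data = data + noise.background
    if noise.gaussian_sd > 0:
        data = data + rng.normal(0.0, noise.gaussian_sd, size=data.shape)
    np.clip(data, 0.0, None, out=data)
    return ImageStack(meta=meta, data=data.astype(np.float32))


def simulate_scene(config: ScenarioConfig) -> tuple[ImageStack, GroundTruth]:
    """Sample a full scene (cells, tracks, contacts) and render its stack."""
    config = config.with_meta_field()
    rng = np.random.default_rng(config.rng_seed)
    shape = config.mc_shape
    # follicles first: they occupy space the dermal cells cannot
    follicle_positions = sample_cell_positions(
        config.follicle_density_per_mm2, config.field_size_mm,
        config.follicle_diameter_um + config.min_separation_um, rng,
        margin_um=config.follicle_diameter_um / 2,
    )
    follicles = [
        Follicle(y_um=y, x_um=x, diameter_um=config.follicle_diameter_um)
        for y, x in follicle_positions
    ]
    mc_density = config.effective_mc_density_per_mm2
    mc_positions = sample_cell_positions(
        mc_density, config.field_size_mm, config.min_separation_um, rng,
        margin_um=shape.major_axis_um / 2,
        forbidden_centers=follicle_positions,
        forbidden_radius_um=config.follicle_diameter_um / 2
        + shape.major_axis_um / 2 + 2.0,
    )
    mc_cells = [
        MCCell(
            id=i, y_um=y, x_um=x,
            orientation_rad=float(rng.uniform(0, math.pi)),
            major_axis_um=shape.major_axis_um, minor_axis_um=shape.minor_axis_um,
        )
        for i, (y, x) in enumerate(mc_positions)
    ]
    if config.n_frames >= 2:
        treg_tracks, contacts = simulate_treg_tracks(config, mc_cells, rng)
    else:
        n_tregs = int(round(config.treg_density_per_mm2 * config.area_mm2))
        h_um, w_um = config.field_size_um
        treg_tracks = [
            TregTrack(id=i, positions_um=np.array([[rng.uniform(5, h_um - 5),
                                                    rng.uniform(5, w_um - 5)]]))
            for i in range(n_tregs)
        ]
        contacts = []
    lc_cells = _simulate_lc_cells(config, rng) if config.include_lc_layer else []
    truth = GroundTruth(
        mc_cells=mc_cells,
        treg_tracks=treg_tracks,
        follicles=follicles,
        contacts=contacts,
        lc_cells=lc_cells,
        densities_seeded={
            "red_tdt": len(mc_cells) / config.area_mm2,
            "green_egfp": len(treg_tracks) / config.area_mm2,
            "follicles": len(follicles) / config.area_mm2,
        },
    )
    stack = render_stack(truth, config, rng)
    return stack, truth


# ---------------------------------------------------------------------------
# canonical study scenarios


def homeostasis_scenario(
    seed: int = 0,
    field_size_mm: tuple[float, float] = (0.45, 0.45),
    noise: NoiseConfig | None = None,
    repopulation_day: float | None = None,
) -> ScenarioConfig:
    """A single-time-point enumeration field: sessile mast cells, few Tregs.

    Mirrors the static mosaic acquisitions used for cell counting —
    a ~450 µm × 450 µm field at the steady-state mast-cell density.
    """
    return ScenarioConfig(
        field_size_mm=field_size_mm,
        n_frames=1,
        rng_seed=seed,
        noise=noise if noise is not None else NoiseConfig(),
        repopulation_day=repopulation_day,
        contact_model=None,
        episodes_per_treg=0,
    )


def contact_scenario(
    pca: bool,
    seed: int = 0,
    field_size_mm: tuple[float, float] = (0.42, 0.42),
    n_frames: int = 30,
    noise: NoiseConfig | None = None,
) -> ScenarioConfig:
    """A contact-monitoring video: 4 min duty cycle, two-hour span.

    Thirty frames at the 4-minute contact duty cycle cover 120 min, long
    enough for the >50 min contact class to occur and complete.
    """
    return ScenarioConfig(
        field_size_mm=field_size_mm,
        n_frames=n_frames,
        rng_seed=seed,
        pca=pca,
        noise=noise if noise is not None else NoiseConfig(),
    )


def velocity_scenario(
    pca: bool,
    seed: int = 0,
    field_size_mm: tuple[float, float] = (0.6, 0.6),
    n_frames: int = 20,
    noise: NoiseConfig | None = None,
) -> ScenarioConfig:
    """A fast Treg-motility video: 40 s duty cycle, green channel only.

    Mirrors the reduced-size, rapid-duty-cycle acquisitions used for
    velocity quantification.  Contact episodes are disabled so measured
    speeds reflect the free random walk; both arms use the same field
    geometry so border effects cancel in between-arm comparisons.
    """
    meta = StackMeta(
        frame_interval_min=TREG_FRAME_INTERVAL_MIN,
        channel_roles=("green_egfp",),
    )
    return ScenarioConfig(
        field_size_mm=field_size_mm,
        n_frames=n_frames,
        rng_seed=seed,
        pca=pca,
        meta=meta,
        contact_model=None,
        episodes_per_treg=0,
        noise=noise if noise is not None else NoiseConfig.off(),
    )
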