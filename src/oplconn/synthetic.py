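"""Synthetic outer-plexiform-layer (OPL) generator.

Produces a fully labelled synthetic outer-retina dataset with the
statistical structure the downstream analysis assumes: a jittered cone
pedicle mosaic with ~5% S-cones, a dense rod spherule field over half
the dataset, per-type bipolar cell (BC) mosaics with configured
dendritic hull areas and coverage factors, wiring rules per BC type
(invaginating ON contacts, basal OFF contacts, CBC9→S-cone selectivity,
sparse atypical CBCX contacts, rod→RBC and rod→OFF-CBC contacts,
cone→RBC contacts), spurious peripheral contacts, starburst amacrine
cell (SAC/ChAT) band surfaces in the IPL, and CBC5 axonal depth
profiles in three planted subtypes.

Every random draw flows from the single config seed through fixed,
stage-indexed generator streams, so a fixed config yields byte-identical
output.  Ground-truth labels (synaptic vs. non-synaptic contact sets,
cone spectral types, CBC5 subtypes, the wiring diagram) are kept in a
separate :class:`GroundTruth` record and are not attached to the
analysis-facing objects unless explicitly requested.

Default parameters emulate the source reconstruction: a 114 × 80 µm
field holding ~163 cone pedicles, a 4.8% S-cone fraction, per-type BC
counts / dendritic hull areas / coverage factors of the published
type table, ~35 rods converging onto each rod bipolar cell, and 75% of
RBCs receiving cone input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .geometry import (
    ConePedicle,
    ContactPoint,
    ContactSet,
    RodSpherule,
    Skeleton,
    group_contact_sets,
)


class GenerationError(RuntimeError):
    """Raised when a configuration cannot be realised (e.g. exclusion
    radius incompatible with the requested density)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

ON = "ON"
OFF = "OFF"
RBC = "RBC"


@dataclass
class BCTypeParams:
    """Per-type mosaic and wiring parameters.

    count: cells of this type in the field.
    hull_area: mean projected dendritic (OPL) convex-hull area, µm².
    hull_area_sd: per-cell SD of the hull area, µm².
    coverage: target hull coverage factor (sum of hull areas / union).
    polarity: 'ON', 'OFF' or 'RBC' — selects the synaptic contact style.
    contact_fraction: probability that an in-field cone is synaptically
        contacted (ignored for CBC9/RBC special rules).
    style: 'standard' | 'tip_mixed' (CBCX) | 'scone_selective' (CBC9).
    ipl_hull_area: mean axonal hull area in the IPL, µm² (used for the
        CBC5 clustering overlap term and RBC axonal clouds).
    """

    count: int
    hull_area: float
    hull_area_sd: float
    coverage: float
    polarity: str = ON
    contact_fraction: float = 0.7
    style: str = "standard"
    ipl_hull_area: float = 200.0


def default_bc_type_params() -> dict[str, BCTypeParams]:
    """BC-type table used by default (counts, OPL hull areas, coverage
    factors and IPL hull areas follow the published type table; contact
    fractions follow the reported contacted-fraction regime per type)."""
    p = BCTypeParams
    return {
        "CBC1": p(26, 175, 26, 1.17, OFF, 0.70, ipl_hull_area=376),
        "CBC2": p(34, 204, 31, 1.18, OFF, 0.70, ipl_hull_area=353),
        "CBC3A": p(22, 273, 41, 1.17, OFF, 0.70, ipl_hull_area=308),
        "CBC3B": p(32, 292, 44, 1.41, OFF, 0.72, ipl_hull_area=224),
        "CBC4": p(30, 302, 45, 1.32, OFF, 0.70, ipl_hull_area=274),
        "CBC5T": p(22, 256, 38, 1.13, ON, 0.45, ipl_hull_area=402),
        "CBC5O": p(22, 380, 57, 1.35, ON, 0.45, ipl_hull_area=359),
        "CBC5I": p(25, 459, 69, 1.55, ON, 0.70, ipl_hull_area=276),
        "CBCX": p(7, 433, 65, 1.02, ON, 0.20, style="tip_mixed", ipl_hull_area=899),
        "CBC6": p(45, 125, 19, 1.14, ON, 0.70, ipl_hull_area=165),
        "CBC7": p(29, 254, 38, 1.22, ON, 0.70, ipl_hull_area=274),
        "CBC8": p(61, 249, 37, 1.14, ON, 0.45, ipl_hull_area=699),
        "CBC9": p(62, 223, 33, 1.84, ON, 1.0, style="scone_selective", ipl_hull_area=1605),
        "RBC": p(141, 128, 19, 2.17, RBC, 0.0, ipl_hull_area=65),
    }


@dataclass
class ContactNoiseParams:
    """Class-conditional geometry of generated contacts.

    Eccentricities are drawn uniformly as a fraction of the terminal
    radius; heights uniformly as a fraction of the terminal height;
    per-point areas are log-normal (µm², parameterised by the median).
    Peripheral (non-synaptic) contacts overlap the synaptic ranges
    slightly, mimicking the imperfect separability of real contacts.
    """

    invag_ecc: tuple[float, float] = (0.05, 0.50)
    invag_height: tuple[float, float] = (0.15, 0.60)
    invag_area_median: float = 0.20
    invag_area_sigma: float = 0.5
    invag_points: tuple[int, int] = (1, 4)

    basal_ecc: tuple[float, float] = (0.05, 0.55)
    basal_height: tuple[float, float] = (0.0, 0.18)
    basal_area_median: float = 0.10
    basal_area_sigma: float = 0.5
    basal_points: tuple[int, int] = (1, 3)

    tip_ecc: tuple[float, float] = (0.10, 0.60)
    tip_height: tuple[float, float] = (0.0, 0.25)
    tip_area_median: float = 0.05
    tip_area_sigma: float = 0.5

    periph_ecc: tuple[float, float] = (0.55, 1.40)
    periph_height: tuple[float, float] = (0.10, 1.10)
    periph_area_median: float = 0.04
    periph_area_sigma: float = 0.6
    periph_points: tuple[int, int] = (1, 3)

    # probability that an in-reach but unwired (BC, cone) pair gets a
    # spurious peripheral contact set
    spurious_rate: float = 0.35
    # spurious peripheral touches of OFF-CBC dendrites on nearby rods
    rod_spurious_rate: float = 0.06


@dataclass
class Cbc5Params:
    """Planted CBC5 subtype structure and SAC band geometry."""

    subtype_depths: tuple[float, float, float] = (0.35, 0.55, 0.75)
    profile_sd: float = 0.06
    n_axon_points: int = 150
    sac_z_on: float = -52.0
    sac_z_off: float = -42.0
    sac_warp_amplitude: float = 1.5
    sac_warp_wavelength: tuple[float, float] = (70.0, 55.0)
    sac_n_points: int = 4000
    sac_depth_noise: float = 0.3


@dataclass
class OplSimConfig:
    """Configuration of one synthetic OPL realisation.

    Densities are per 1000 µm²; the defaults reproduce a 114 × 80 µm
    field with ~163 cone pedicles (density 17.9), a 4.8%-expected S-cone
    fraction and ~1730 rod spherules over the left half of the field.
    """

    field_size: tuple[float, float] = (114.0, 80.0)
    cone_density: float = 17.9
    s_cone_prob: float = 0.05
    cone_exclusion: float = 5.0
    pedicle_radius: float = 3.0
    pedicle_radius_sd: float = 0.25
    pedicle_height: float = 2.0
    pedicle_height_sd: float = 0.15

    rod_density: float = 380.0
    rod_region_frac: float = 0.5     # x-fraction of the field holding rods
    rod_radius: float = 1.2
    rod_exclusion: float = 1.0
    # rod → number-of-RBC-partners distribution (index = partner count)
    rod_rbc_partners: tuple[float, float, float] = (0.02, 0.54, 0.44)
    rbc_cone_fraction: float = 0.75  # fraction of RBCs with cone contacts
    rbc_cone_mean_extra: float = 0.8  # 1 + Poisson(this) cones per such RBC

    bc_type_params: dict[str, BCTypeParams] = field(
        default_factory=default_bc_type_params
    )
    contact_noise: ContactNoiseParams = field(default_factory=ContactNoiseParams)
    cbc5: Cbc5Params = field(default_factory=Cbc5Params)

    cbcx_invag_prob: float = 3.0 / 19.0   # invaginating share of CBCX contacts
    cbc9_m_cone_rate: float = 0.04        # single stray CBC9→M-cone contacts
    off_rod_targets: dict[str, float] = field(
        default_factory=lambda: {
            "CBC1": 0.3, "CBC2": 0.5, "CBC3A": 5.0, "CBC3B": 10.0, "CBC4": 5.0
        }
    )

    seed: int = 0

    def validate(self):
        if not (0.0 <= self.s_cone_prob <= 1.0):
            raise ValueError("s_cone_prob must lie in [0, 1]")
        for name, val in [
            ("cone_density", self.cone_density),
            ("rod_density", self.rod_density),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(sum(self.rod_rbc_partners) - 1.0) > 1e-9:
            raise ValueError("rod_rbc_partners must sum to 1")
        return self


def _stage_rng(config: OplSimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


# ---------------------------------------------------------------------------
# mosaics
# ---------------------------------------------------------------------------

def _jittered_hex_lattice(
    rng: np.random.Generator,
    width: float,
    height: float,
    density_per_um2: float,
    exclusion: float,
    jitter_frac: float = 0.18,
    max_retries: int = 200,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Jittered hexagonal lattice with a hard pairwise exclusion radius.

    Raises GenerationError if the exclusion cannot be satisfied after
    bounded per-point retries (density too high for the exclusion).
    """
    if density_per_um2 <= 0:
        return np.empty((0, 2))
    spacing = math.sqrt(2.0 / (math.sqrt(3.0) * density_per_um2))
    if exclusion >= spacing:
        raise GenerationError(
            f"exclusion radius {exclusion:.2f} µm incompatible with lattice "
            f"spacing {spacing:.2f} µm at the requested density"
        )
    row_h = spacing * math.sqrt(3.0) / 2.0
    n_failed = 0
    pts: list[np.ndarray] = []
    tree_pts: list[np.ndarray] = []
    ny = int(math.ceil(height / row_h)) + 1
    nx = int(math.ceil(width / spacing)) + 1
    sigma = jitter_frac * spacing
    for iy in range(ny):
        y0 = (iy + 0.5) * row_h
        xoff = 0.5 * spacing if iy % 2 else 0.0
        for ix in range(nx):
            x0 = (ix + 0.5) * spacing + xoff
            if x0 > width or y0 > height:
                continue
            ok = False
            for attempt in range(max_retries):
                if attempt < max_retries // 2:
                    cand = np.array([x0, y0]) + rng.normal(0.0, sigma, 2)
                else:
                    # widen the search over the whole lattice cell when
                    # gaussian jitter cannot escape a crowded neighbour
                    cand = np.array([x0, y0]) + rng.uniform(
                        [-0.5 * spacing, -0.5 * row_h], [0.5 * spacing, 0.5 * row_h]
                    )
                if not (0 <= cand[0] <= width and 0 <= cand[1] <= height):
                    continue
                if tree_pts:
                    d = np.linalg.norm(np.array(tree_pts) - cand, axis=1)
                    if np.min(d) < exclusion:
                        continue
                ok = True
                break
            if not ok:
                # an isolated unplaceable point (e.g. a clipped border
                # cell) is skipped; widespread failure means the density
                # is incompatible with the exclusion radius
                n_failed += 1
                continue
            pts.append(cand)
            tree_pts.append(cand)
    if pts and n_failed > 0.1 * (len(pts) + n_failed):
        raise GenerationError(
            f"could not satisfy the exclusion radius for {n_failed} of "
            f"{len(pts) + n_failed} mosaic points"
        )
    out = np.array(pts) + np.asarray(origin)
    return out


def generate_cone_mosaic(config: OplSimConfig, rng=None) -> list[ConePedicle]:
    """Jittered hexagonal cone pedicle mosaic clipped to the field.

    Each pedicle is labelled S with probability ``s_cone_prob``; the
    optical axis is the global +z axis and the basal plane sits near
    z = 0.  Pedicles whose full planar extent falls inside the field are
    flagged complete.
    """
    config.validate()
    rng = rng if rng is not None else _stage_rng(config, 1)
    w, h = config.field_size
    xy = _jittered_hex_lattice(
        rng, w, h, config.cone_density / 1000.0, config.cone_exclusion
    )
    cones = []
    for i, (x, y) in enumerate(xy):
        radius = max(1.0, rng.normal(config.pedicle_radius, config.pedicle_radius_sd))
        height = max(0.5, rng.normal(config.pedicle_height, config.pedicle_height_sd))
        basal_z = rng.normal(0.0, 0.3)
        spectral = "S" if rng.random() < config.s_cone_prob else "M"
        complete = (
            radius <= x <= w - radius and radius <= y <= h - radius
        )
        cones.append(
            ConePedicle(
                terminal_id=f"cone_{i:04d}",
                center=np.array([x, y, basal_z + height / 2.0]),
                basal_z=basal_z,
                height=height,
                axis=np.array([0.0, 0.0, 1.0]),
                radius=radius,
                spectral_type=spectral,
                complete=bool(complete),
            )
        )
    return cones


def generate_rod_field(config: OplSimConfig, rng=None) -> list[RodSpherule]:
    """Dense rod spherule field over the configured sub-rectangle
    (left ``rod_region_frac`` of the field), mirroring a half-field
    reconstruction."""
    config.validate()
    rng = rng if rng is not None else _stage_rng(config, 2)
    w, h = config.field_size
    rw = w * config.rod_region_frac
    if rw <= 0 or config.rod_density <= 0:
        return []
    xy = _jittered_hex_lattice(
        rng, rw, h, config.rod_density / 1000.0, config.rod_exclusion,
        jitter_frac=0.15,
    )
    rods = []
    for i, (x, y) in enumerate(xy):
        z = rng.normal(1.8, 0.3) + config.rod_radius
        rods.append(
            RodSpherule(
                terminal_id=f"rod_{i:05d}",
                center=np.array([x, y, z]),
                radius=config.rod_radius,
            )
        )
    return rods


def rod_region_bounds(config: OplSimConfig) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) of the rod-bearing sub-rectangle."""
    w, h = config.field_size
    return 0.0, w * config.rod_region_frac, 0.0, h


# ---------------------------------------------------------------------------
# dendritic trees
# ---------------------------------------------------------------------------

class _Arbor:
    """Mutable skeleton under construction (soma, trunk, dendrites and,
    during wiring, terminal contact twigs)."""

    def __init__(self, cell_id: str, cell_type: str):
        self.cell_id = cell_id
        self.cell_type = cell_type
        self.xyz: list[np.ndarray] = []
        self.parent: list[int] = []
        self.radius: list[float] = []
        # nodes below this index belong to the grown arbor proper; twigs
        # added during wiring anchor only here so twig tips stay leaves
        self.backbone_n: int | None = None

    def freeze_backbone(self):
        if self.backbone_n is None:
            self.backbone_n = self.n

    def add(self, pos, parent: int, radius: float = 0.3) -> int:
        self.xyz.append(np.asarray(pos, dtype=float))
        self.parent.append(parent)
        self.radius.append(radius)
        return len(self.xyz) - 1

    @property
    def n(self) -> int:
        return len(self.xyz)

    def positions(self) -> np.ndarray:
        return np.array(self.xyz)

    def to_skeleton(self) -> Skeleton:
        ids = np.arange(1, self.n + 1)
        parents = np.array([p + 1 if p >= 0 else -1 for p in self.parent])
        return Skeleton(
            ids, parents, np.array(self.xyz), np.array(self.radius),
            cell_id=self.cell_id, cell_type=self.cell_type,
        )


def _grow_arbor(
    rng: np.random.Generator,
    cell_id: str,
    cell_type: str,
    soma_xy: np.ndarray,
    target_hull_area: float,
    soma_z: float = -8.0,
    dendrite_z: float = -1.2,
) -> _Arbor:
    """Grow a random planar dendritic tree and rescale it so the
    projected convex hull matches the target area.

    Growth model: a vertical trunk from the soma to just below the
    pedicle layer, 4–6 primary dendrites radiating at jittered angles,
    each extended by short segments with angular wiggle and recursive
    bifurcations (probability 0.35 per step, depth ≤ 3).
    """
    arbor = _Arbor(cell_id, cell_type)
    soma = arbor.add(np.array([*soma_xy, soma_z]), -1, radius=2.5)
    trunk = arbor.add(np.array([*soma_xy, dendrite_z]), soma, radius=0.8)

    n_primary = int(rng.integers(4, 7))
    base_angles = np.linspace(0, 2 * np.pi, n_primary, endpoint=False)
    base_angles = base_angles + rng.uniform(-0.4, 0.4, n_primary) + rng.uniform(0, 2 * np.pi)

    def extend(parent: int, angle: float, depth: int):
        pos = arbor.xyz[parent]
        n_steps = int(rng.integers(2, 5))
        node = parent
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.35)
            step = rng.uniform(1.2, 2.8)
            new = arbor.xyz[node] + np.array(
                [step * math.cos(angle), step * math.sin(angle), rng.normal(0.05, 0.1)]
            )
            node = arbor.add(new, node, radius=max(0.1, 0.5 - 0.12 * depth))
            if depth < 3 and rng.random() < 0.35:
                extend(node, angle + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1), depth + 1)
        return node

    for a in base_angles:
        extend(trunk, a, 0)

    # rescale xy about the soma so the hull hits the target area
    pts = arbor.positions()[:, :2]
    hull_pts = pts[2:]  # exclude soma and trunk (same xy as soma)
    try:
        area = ConvexHull(hull_pts).volume
    except Exception:
        area = 0.0
    if area > 0:
        scale = math.sqrt(target_hull_area / area)
        for i in range(2, arbor.n):
            d = arbor.xyz[i][:2] - soma_xy
            arbor.xyz[i] = np.array([*(soma_xy + d * scale), arbor.xyz[i][2]])
    return arbor


def _mosaic_region(
    config: OplSimConfig, params: BCTypeParams
) -> tuple[float, float, float, float]:
    """Soma-placement rectangle (xmin, xmax, ymin, ymax) sized so the
    union of dendritic hulls realises the target coverage.

    The union of densely packed hulls approximates the placement
    rectangle dilated by the hull radius, so the rectangle is solved
    from (w + 2r)(h + 2r) = n·A / coverage with the field's aspect
    ratio.  Hulls may extend beyond the nominal field, as they do for
    border cells in a real reconstruction.
    """
    w_f, h_f = config.field_size
    aspect = w_f / h_f
    n, A, gamma = params.count, params.hull_area, params.coverage
    target_union = n * A / gamma
    r = math.sqrt(A / math.pi)
    # (w + 2r)(w/aspect + 2r) = target_union
    a_ = 1.0 / aspect
    b_ = 2 * r * (1 + 1.0 / aspect)
    c_ = 4 * r * r - target_union
    disc = b_ * b_ - 4 * a_ * c_
    w = (-b_ + math.sqrt(max(disc, 0.0))) / (2 * a_) if disc > 0 else 0.0
    w = max(w, 1.0)
    h = w / aspect
    cx, cy = w_f / 2.0, h_f / 2.0
    return cx - w / 2.0, cx + w / 2.0, cy - h / 2.0, cy + h / 2.0


def _calibrate_mosaic_spread(
    arbors: list[tuple[np.ndarray, _Arbor]],
    target_coverage: float,
    center: np.ndarray,
) -> None:
    """Radially rescale soma positions about the field centre so the
    realised hull coverage (Σ areas / union area) hits the target.

    Coverage decreases monotonically with mosaic spread, so a short
    bisection on the spread factor suffices; the per-cell hulls are
    unchanged (cells translate rigidly).
    """
    from shapely.affinity import translate
    from shapely.ops import unary_union

    if len(arbors) < 2:
        return
    hulls = [_hull_polygon(arb) for _, arb in arbors]
    somata = np.array([s[:2] for s, _ in arbors])
    total = sum(h.area for h in hulls)

    def coverage(s: float) -> float:
        moved = [
            translate(h, *((s - 1.0) * (xy - center)))
            for h, xy in zip(hulls, somata)
        ]
        return total / unary_union(moved).area

    lo, hi = 0.35, 3.0
    c_lo, c_hi = coverage(lo), coverage(hi)
    if target_coverage >= c_lo:
        s = lo
    elif target_coverage <= c_hi:
        s = hi
    else:
        for _ in range(14):
            s = 0.5 * (lo + hi)
            if coverage(s) > target_coverage:
                lo = s
            else:
                hi = s
        s = 0.5 * (lo + hi)
    if abs(s - 1.0) < 1e-3:
        return
    for soma, arb in arbors:
        shift = (s - 1.0) * (soma[:2] - center)
        soma[:2] += shift
        for i in range(arb.n):
            arb.xyz[i] = arb.xyz[i] + np.array([shift[0], shift[1], 0.0])


def _generate_bc_arbors(
    config: OplSimConfig, type_name: str, rng=None
) -> list[tuple[np.ndarray, _Arbor]]:
    """Soma mosaic plus grown (mutable) arbors of one BC type, with the
    mosaic spread calibrated to the target coverage factor."""
    if type_name not in config.bc_type_params:
        raise ValueError(f"unknown BC type {type_name!r}")
    params = config.bc_type_params[type_name]
    type_idx = sorted(config.bc_type_params).index(type_name)
    rng = rng if rng is not None else _stage_rng(config, 10 + type_idx)
    xmin, xmax, ymin, ymax = _mosaic_region(config, params)
    n = params.count
    cols = max(1, int(round(math.sqrt(n * (xmax - xmin) / max(ymax - ymin, 1e-9)))))
    rows = int(math.ceil(n / cols))
    dx = (xmax - xmin) / cols
    dy = (ymax - ymin) / rows
    out = []
    order = rng.permutation(rows * cols)
    slots = sorted(order[:n])
    for k, slot in enumerate(slots):
        iy, ix = divmod(int(slot), cols)
        sx = xmin + (ix + 0.5) * dx + rng.normal(0, 0.18 * dx)
        sy = ymin + (iy + 0.5) * dy + rng.normal(0, 0.18 * dy)
        soma_xy = np.array([sx, sy])
        area = max(10.0, rng.normal(params.hull_area, params.hull_area_sd))
        cell_id = f"{type_name}_{k:03d}"
        arbor = _grow_arbor(rng, cell_id, type_name, soma_xy, area)
        out.append((np.array([sx, sy, -8.0]), arbor))
    w_f, h_f = config.field_size
    _calibrate_mosaic_spread(
        out, params.coverage, np.array([w_f / 2.0, h_f / 2.0])
    )
    return out


def generate_bc_population(
    config: OplSimConfig, type_name: str, rng=None
) -> list[tuple[np.ndarray, Skeleton]]:
    """Generate the soma mosaic and dendritic skeletons of one BC type.

    Somata sit on a jittered grid whose spread is calibrated so the
    realised hull coverage factor matches the configured target;
    per-cell hull areas are drawn around the configured mean and the
    grown trees rescaled to match them.
    """
    config.validate()
    cells = _generate_bc_arbors(config, type_name, rng=rng)
    return [(soma, arbor.to_skeleton()) for soma, arbor in cells]


# ---------------------------------------------------------------------------
# wiring
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Hidden labels of one synthetic realisation."""

    set_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    contact_styles: dict[tuple[str, str], str] = field(default_factory=dict)
    cone_spectral: dict[str, str] = field(default_factory=dict)
    cbc5_subtype: dict[str, str] = field(default_factory=dict)
    wiring: set = field(default_factory=set)

    def is_synaptic(self, bc_id: str, terminal_id: str) -> bool:
        return self.set_labels.get((bc_id, terminal_id)) == "synaptic"


def _lognormal(rng, median, sigma):
    return float(median * math.exp(rng.normal(0.0, sigma)))


def _hull_polygon(arbor: _Arbor):
    from shapely.geometry import MultiPoint

    pts = arbor.positions()[2:, :2]
    return MultiPoint([tuple(p) for p in pts]).convex_hull


class _Wirer:
    """Places contact sets and extends arbors with terminal twigs."""

    def __init__(self, config: OplSimConfig, rng: np.random.Generator):
        self.config = config
        self.noise = config.contact_noise
        self.rng = rng
        self.points: list[ContactPoint] = []
        self.truth = GroundTruth()

    # -- helpers ------------------------------------------------------------

    def _sample_position(self, frame: ConePedicle, ecc_range, height_range):
        rng = self.rng
        ecc = rng.uniform(*ecc_range) * frame.radius
        phi = rng.uniform(0, 2 * np.pi)
        c = rng.uniform(*height_range)
        base = frame.base_point
        planar = np.array([math.cos(phi), math.sin(phi), 0.0]) * ecc
        return base + planar + frame.axis * (c * frame.height)

    def _attach_twig(self, arbor: _Arbor, pos: np.ndarray, axial: bool) -> int:
        """Add a two-node terminal twig ending exactly at the contact
        position; axial twigs (invaginating) run along the optical axis,
        lateral ones (basal/tip) approach obliquely."""
        arbor.freeze_backbone()
        pts = arbor.positions()[: arbor.backbone_n]
        d = np.linalg.norm(pts[:, :2] - pos[:2], axis=1)
        anchor = int(np.argmin(d))
        if axial:
            pre = pos - np.array([0.0, 0.0, 0.9]) + np.append(
                self.rng.normal(0, 0.05, 2), 0.0
            )
        else:
            lat = self.rng.normal(0, 1, 2)
            lat = lat / (np.linalg.norm(lat) + 1e-12)
            pre = pos - np.append(0.7 * lat, 0.25)
        pre_i = arbor.add(pre, anchor, radius=0.15)
        tip_i = arbor.add(pos, pre_i, radius=0.1)
        return tip_i

    def _nearest_node_id(self, arbor: _Arbor, pos: np.ndarray) -> int:
        # peripheral touches come from the passing arbor proper, not
        # from terminal contact twigs
        arbor.freeze_backbone()
        pts = arbor.positions()[: arbor.backbone_n]
        return int(np.argmin(np.linalg.norm(pts - pos, axis=1))) + 1

    def add_synaptic_set(
        self, arbor: _Arbor, frame: ConePedicle, terminal_id: str, style: str,
        n_points: int | None = None, near: np.ndarray | None = None,
    ):
        noise = self.noise
        rng = self.rng
        if style == "invaginating":
            ecc_r, h_r = noise.invag_ecc, noise.invag_height
            med, sig = noise.invag_area_median, noise.invag_area_sigma
            lo, hi = noise.invag_points
            axial = True
        elif style == "basal":
            ecc_r, h_r = noise.basal_ecc, noise.basal_height
            med, sig = noise.basal_area_median, noise.basal_area_sigma
            lo, hi = noise.basal_points
            axial = False
        elif style == "tip":
            ecc_r, h_r = noise.tip_ecc, noise.tip_height
            med, sig = noise.tip_area_median, noise.tip_area_sigma
            lo, hi = 1, 2
            axial = False
        else:
            raise ValueError(style)
        if n_points is None:
            n_points = int(rng.integers(lo, hi + 1))
        first = None
        for j in range(n_points):
            if near is not None and j == 0:
                pos = near + np.append(rng.normal(0, 0.25, 2), rng.normal(0, 0.1))
            elif first is None:
                pos = self._sample_position(frame, ecc_r, h_r)
            else:
                pos = first + np.append(rng.normal(0, 0.6, 2), rng.normal(0, 0.15))
            if first is None:
                first = pos
            tip_i = self._attach_twig(arbor, pos, axial)
            self.points.append(
                ContactPoint(
                    bc_id=arbor.cell_id,
                    terminal_id=terminal_id,
                    position=pos,
                    area=_lognormal(rng, med, sig),
                    node_id=tip_i + 1,
                )
            )
        key = (arbor.cell_id, terminal_id)
        self.truth.set_labels[key] = "synaptic"
        self.truth.contact_styles[key] = style
        self.truth.wiring.add(key)

    def add_peripheral_set(self, arbor: _Arbor, frame: ConePedicle, terminal_id: str):
        """Spurious touch of a passing dendrite: eccentric, often high on
        the terminal flank, attached to an existing (usually mid-branch)
        node without adding a twig."""
        noise = self.noise
        rng = self.rng
        n_points = int(rng.integers(*noise.periph_points) if noise.periph_points[0] < noise.periph_points[1] else noise.periph_points[0])
        n_points = max(1, n_points)
        first = None
        for j in range(n_points):
            if first is None:
                pos = self._sample_position(frame, noise.periph_ecc, noise.periph_height)
                first = pos
            else:
                pos = first + np.append(rng.normal(0, 0.6, 2), rng.normal(0, 0.2))
            node_id = self._nearest_node_id(arbor, pos)
            self.points.append(
                ContactPoint(
                    bc_id=arbor.cell_id,
                    terminal_id=terminal_id,
                    position=pos,
                    area=_lognormal(rng, noise.periph_area_median, noise.periph_area_sigma),
                    node_id=node_id,
                )
            )
        key = (arbor.cell_id, terminal_id)
        self.truth.set_labels[key] = "non_synaptic"
        self.truth.contact_styles[key] = "peripheral"


@dataclass
class WiringResult:
    contact_points: list[ContactPoint]
    contact_sets: list[ContactSet]
    truth: GroundTruth
    skeletons: dict[str, Skeleton]
    somata: dict[str, np.ndarray]
    cell_types: dict[str, str]


def wire_contacts(
    cones: list[ConePedicle],
    rods: list[RodSpherule],
    bcs: dict[str, list[tuple[np.ndarray, "_Arbor | Skeleton"]]],
    config: OplSimConfig,
    rng=None,
) -> WiringResult:
    """Wire synaptic and spurious contacts between the populations.

    Rules (per BC type polarity/style):

    * OFF CBCs make basal contacts with each in-field cone with the
      type's contact fraction; ON CBCs make invaginating tip contacts.
    * CBCX contacts ~20% of in-field cones, mostly via atypical 'tip'
      contacts (invaginating with probability ``cbcx_invag_prob``).
    * CBC9 makes invaginating, branch-terminating contacts with every
      S-cone whose centre its dendritic hull covers, plus rare single
      contacts on M-cones.
    * Each rod receives 0–2 invaginating RBC contacts from distinct
      RBCs; a configurable fraction of RBCs also contact cones
      (invaginating).  OFF types CBC3A/3B/4 (and marginally CBC1/2)
      receive basal rod contacts placed next to the rod's RBC contact.
    * Unwired in-reach (BC, cone) pairs get spurious peripheral contact
      sets at the configured rate.
    """
    config.validate()
    rng = rng if rng is not None else _stage_rng(config, 40)
    wirer = _Wirer(config, rng)

    # accept frozen skeletons too (rebuild mutable arbors)
    arbors: dict[str, list[tuple[np.ndarray, _Arbor]]] = {}
    for tname, cells in bcs.items():
        lst = []
        for soma, sk in cells:
            if isinstance(sk, Skeleton):
                arb = _Arbor(sk.cell_id, sk.cell_type)
                arb.xyz = [p.copy() for p in sk.xyz]
                arb.parent = [int(p) for p in sk.parent_idx]
                arb.radius = [float(r) for r in sk.radii]
            else:
                arb = sk
            lst.append((soma, arb))
        arbors[tname] = lst

    for cone in cones:
        wirer.truth.cone_spectral[cone.terminal_id] = cone.spectral_type

    cone_xy = np.array([c.center[:2] for c in cones]) if cones else np.empty((0, 2))
    hulls = {
        tname: [_hull_polygon(arb) for _, arb in cells]
        for tname, cells in arbors.items()
    }

    from shapely.geometry import Point

    def in_field_cone_ids(hull) -> list[int]:
        if len(cone_xy) == 0:
            return []
        minx, miny, maxx, maxy = hull.bounds
        out = []
        for i, (x, y) in enumerate(cone_xy):
            if x < minx or x > maxx or y < miny or y > maxy:
                continue
            if hull.covers(Point(x, y)):
                out.append(i)
        return out

    # ---- cone wiring per BC type -----------------------------------------
    for tname in sorted(arbors):
        params = config.bc_type_params[tname]
        for (soma, arb), hull in zip(arbors[tname], hulls[tname]):
            infield = in_field_cone_ids(hull)
            wired = set()
            if params.style == "scone_selective":
                for ci in infield:
                    cone = cones[ci]
                    if cone.spectral_type == "S":
                        # CBC9-S-cone pairs carry several invaginating sites
                        # (~2-3 per pair in the source reconstruction)
                        wirer.add_synaptic_set(
                            arb, cone, cone.terminal_id, "invaginating",
                            n_points=int(rng.integers(2, 4)),
                        )
                        wired.add(ci)
                    elif rng.random() < config.cbc9_m_cone_rate:
                        wirer.add_synaptic_set(
                            arb, cone, cone.terminal_id, "invaginating", n_points=1
                        )
                        wired.add(ci)
            elif params.polarity == RBC:
                if infield and rng.random() < config.rbc_cone_fraction:
                    k = 1 + int(rng.poisson(config.rbc_cone_mean_extra))
                    k = min(k, len(infield))
                    soma_xy = soma[:2]
                    d = [np.linalg.norm(cone_xy[i] - soma_xy) for i in infield]
                    chosen = [infield[j] for j in np.argsort(d)[:k]]
                    for ci in chosen:
                        wirer.add_synaptic_set(
                            arb, cones[ci], cones[ci].terminal_id, "invaginating"
                        )
                        wired.add(ci)
            elif params.style == "tip_mixed":
                for ci in infield:
                    if rng.random() < params.contact_fraction:
                        style = (
                            "invaginating"
                            if rng.random() < config.cbcx_invag_prob
                            else "tip"
                        )
                        wirer.add_synaptic_set(
                            arb, cones[ci], cones[ci].terminal_id, style
                        )
                        wired.add(ci)
            else:
                style = "invaginating" if params.polarity == ON else "basal"
                for ci in infield:
                    if rng.random() < params.contact_fraction:
                        wirer.add_synaptic_set(
                            arb, cones[ci], cones[ci].terminal_id, style
                        )
                        wired.add(ci)
            # spurious peripheral contacts on unwired in-reach cones
            for ci in infield:
                if ci not in wired and rng.random() < config.contact_noise.spurious_rate:
                    wirer.add_peripheral_set(arb, cones[ci], cones[ci].terminal_id)

    # ---- rod wiring -------------------------------------------------------
    rbc_cells = arbors.get("RBC", [])
    xmin, xmax, ymin, ymax = rod_region_bounds(config)
    # only RBCs with their soma inside the rod-bearing area take part,
    # mirroring the half-field restriction of the rod analysis
    eligible = [
        (soma, arb)
        for soma, arb in rbc_cells
        if xmin <= soma[0] <= xmax and ymin <= soma[1] <= ymax
    ]
    rod_rbc_contact_pos: dict[str, list[np.ndarray]] = {}
    if rods and eligible:
        somata_xy = np.array([s[:2] for s, _ in eligible])
        tree = cKDTree(somata_xy)
        probs = np.array(config.rod_rbc_partners)
        for rod in rods:
            m = int(rng.choice(len(probs), p=probs))
            if m == 0:
                continue
            k = min(max(4, m), len(eligible))
            _, idx = tree.query(rod.center[:2], k=k)
            idx = np.atleast_1d(idx)
            chosen = idx[:m]
            frame = rod.as_frame()
            for j in chosen:
                _, arb = eligible[int(j)]
                wirer.add_synaptic_set(
                    arb, frame, rod.terminal_id, "invaginating",
                    n_points=1,
                )
                rod_rbc_contact_pos.setdefault(rod.terminal_id, []).append(
                    wirer.points[-1].position
                )

    # OFF-CBC rod contacts, placed next to the rod's RBC contact
    rods_by_id = {r.terminal_id: r for r in rods}
    rod_ids_with_rbc = [r.terminal_id for r in rods if r.terminal_id in rod_rbc_contact_pos]
    if rod_ids_with_rbc:
        rod_xy = np.array([rods_by_id[rid].center[:2] for rid in rod_ids_with_rbc])
        rod_tree = cKDTree(rod_xy)
        for tname, target in sorted(config.off_rod_targets.items()):
            if tname not in arbors:
                continue
            for soma, arb in arbors[tname]:
                if not (xmin <= soma[0] <= xmax and ymin <= soma[1] <= ymax):
                    continue
                n_rods = int(rng.poisson(target))
                if n_rods == 0:
                    continue
                k = min(max(n_rods * 2, 4), len(rod_ids_with_rbc))
                _, idx = rod_tree.query(soma[:2], k=k)
                idx = np.atleast_1d(idx)
                chosen = rng.permutation(idx)[:n_rods]
                for j in chosen:
                    rid = rod_ids_with_rbc[int(j)]
                    rod = rods_by_id[rid]
                    anchor = rod_rbc_contact_pos[rid][
                        int(rng.integers(len(rod_rbc_contact_pos[rid])))
                    ]
                    wirer.add_synaptic_set(
                        arb, rod.as_frame(), rid, "basal", n_points=1, near=anchor
                    )
        # spurious peripheral rod touches by passing OFF-CBC and RBC dendrites
        rate = config.contact_noise.rod_spurious_rate
        if rate > 0:
            all_rod_ids = [r.terminal_id for r in rods]
            all_rod_xy = np.array([rods_by_id[rid].center[:2] for rid in all_rod_ids])
            all_tree = cKDTree(all_rod_xy)
            for tname in sorted(set(config.off_rod_targets) | {"RBC"}):
                if tname not in arbors:
                    continue
                for soma, arb in arbors[tname]:
                    if not (xmin <= soma[0] <= xmax and ymin <= soma[1] <= ymax):
                        continue
                    k = min(30, len(all_rod_ids))
                    _, idx = all_tree.query(soma[:2], k=k)
                    for j in np.atleast_1d(idx):
                        rid = all_rod_ids[int(j)]
                        if (arb.cell_id, rid) in wirer.truth.set_labels:
                            continue
                        if rng.random() < rate:
                            wirer.add_peripheral_set(
                                arb, rods_by_id[rid].as_frame(), rid
                            )

    skeletons = {}
    somata = {}
    cell_types = {}
    for tname, cells in arbors.items():
        for soma, arb in cells:
            skeletons[arb.cell_id] = arb.to_skeleton()
            somata[arb.cell_id] = soma
            cell_types[arb.cell_id] = tname
    csets = group_contact_sets(wirer.points)
    return WiringResult(
        contact_points=wirer.points,
        contact_sets=csets,
        truth=wirer.truth,
        skeletons=skeletons,
        somata=somata,
        cell_types=cell_types,
    )


# ---------------------------------------------------------------------------
# SAC bands and CBC5 axons
# ---------------------------------------------------------------------------

@dataclass
class SacBandData:
    on_points: np.ndarray            # (N, 3) SAC dendrite point cloud, ON band
    off_points: np.ndarray
    true_on: Callable[[np.ndarray, np.ndarray], np.ndarray]
    true_off: Callable[[np.ndarray, np.ndarray], np.ndarray]
    axon_clouds: dict[str, np.ndarray]   # per-CBC5-cell axonal points (N, 3)
    subtype_truth: dict[str, str]        # cell_id -> '5T' | '5O' | '5I'
    planted_depths: dict[str, float]     # subtype -> corrected depth


def _warped_surface(z0, amplitude, wavelengths, phase):
    lx, ly = wavelengths

    def f(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return z0 + amplitude * np.sin(2 * np.pi * x / lx + phase) * np.cos(
            2 * np.pi * y / ly + 0.7 * phase
        )

    return f


def generate_sac_bands_and_cbc5_axons(
    config: OplSimConfig,
    cbc5_cells: dict[str, tuple[np.ndarray, str]] | None = None,
    rng=None,
) -> SacBandData:
    """Two smooth, non-intersecting warped SAC (ChAT) band surfaces and
    per-CBC5-cell axonal point clouds at three planted corrected depths.

    ``cbc5_cells`` maps cell_id → (soma, subtype); if omitted, subtype
    mosaics are generated from the configured CBC5T/O/I counts.  The ON
    band lies below the OFF band everywhere (z_on < z_off), and the
    corrected depth maps ON → 0 and OFF → 1.
    """
    config.validate()
    rng = rng if rng is not None else _stage_rng(config, 60)
    p = config.cbc5
    w, h = config.field_size
    true_on = _warped_surface(p.sac_z_on, p.sac_warp_amplitude, p.sac_warp_wavelength, 0.3)
    true_off = _warped_surface(p.sac_z_off, p.sac_warp_amplitude, p.sac_warp_wavelength, 1.9)

    def cloud(fn):
        xy = rng.uniform([0, 0], [w, h], size=(p.sac_n_points, 2))
        z = fn(xy[:, 0], xy[:, 1]) + rng.normal(0, p.sac_depth_noise, p.sac_n_points)
        return np.column_stack([xy, z])

    on_pts = cloud(true_on)
    off_pts = cloud(true_off)

    subtypes = ("5T", "5O", "5I")
    if cbc5_cells is None:
        cbc5_cells = {}
        for st, tname in zip(subtypes, ("CBC5T", "CBC5O", "CBC5I")):
            params = config.bc_type_params.get(tname)
            count = params.count if params is not None else 22
            xmin, xmax, ymin, ymax = (
                _mosaic_region(config, params)
                if params is not None
                else (0, w, 0, h)
            )
            cols = max(1, int(round(math.sqrt(count))))
            rows = int(math.ceil(count / cols))
            dx, dy = (xmax - xmin) / cols, (ymax - ymin) / rows
            k = 0
            for iy in range(rows):
                for ix in range(cols):
                    if k >= count:
                        break
                    sx = xmin + (ix + 0.5) * dx + rng.normal(0, 0.15 * dx)
                    sy = ymin + (iy + 0.5) * dy + rng.normal(0, 0.15 * dy)
                    cbc5_cells[f"CBC{st}_{k:03d}"] = (np.array([sx, sy, -8.0]), st)
                    k += 1

    planted = dict(zip(subtypes, p.subtype_depths))
    clouds: dict[str, np.ndarray] = {}
    subtype_truth: dict[str, str] = {}
    for cell_id in sorted(cbc5_cells):
        soma, st = cbc5_cells[cell_id]
        tname = f"CBC{st}"
        area = config.bc_type_params.get(tname, BCTypeParams(22, 256, 38, 1.2)).ipl_hull_area
        r = math.sqrt(area / math.pi)
        n = p.n_axon_points
        xy = soma[:2] + rng.normal(0, r / 2.0, (n, 2))
        depth = rng.normal(planted[st], p.profile_sd, n)
        z_on = true_on(xy[:, 0], xy[:, 1])
        z_off = true_off(xy[:, 0], xy[:, 1])
        z = z_on + depth * (z_off - z_on)
        clouds[cell_id] = np.column_stack([xy, z])
        subtype_truth[cell_id] = st

    return SacBandData(
        on_points=on_pts,
        off_points=off_pts,
        true_on=true_on,
        true_off=true_off,
        axon_clouds=clouds,
        subtype_truth=subtype_truth,
        planted_depths=planted,
    )


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class OplDataset:
    """One synthetic OPL realisation: populations, wiring and hidden truth."""

    config: OplSimConfig
    cones: list[ConePedicle]
    rods: list[RodSpherule]
    skeletons: dict[str, Skeleton]
    somata: dict[str, np.ndarray]
    cell_types: dict[str, str]
    contact_points: list[ContactPoint]
    contact_sets: list[ContactSet]
    truth: GroundTruth
    sac: SacBandData | None = None

    def cones_by_id(self) -> dict[str, ConePedicle]:
        return {c.terminal_id: c for c in self.cones}

    def rods_by_id(self) -> dict[str, RodSpherule]:
        return {r.terminal_id: r for r in self.rods}

    def labeled_sets(self) -> list[ContactSet]:
        """Contact sets with ground-truth labels attached (copies are
        not made; labels are written onto the sets)."""
        for s in self.contact_sets:
            s.label = self.truth.set_labels.get(
                (s.bc_id, s.terminal_id), "unlabeled"
            )
        return self.contact_sets

    def cells_of_type(self, *types: str) -> list[str]:
        return [cid for cid, t in sorted(self.cell_types.items()) if t in types]


def generate_dataset(
    config: OplSimConfig,
    bc_types: Sequence[str] | None = None,
    with_sac: bool = True,
) -> OplDataset:
    """Generate a complete synthetic dataset from one config.

    ``bc_types`` restricts generation to a subset of BC types (useful
    for focused, faster experiments); default is every configured type.
    """
    config.validate()
    cones = generate_cone_mosaic(config)
    rods = generate_rod_field(config)
    names = list(bc_types) if bc_types is not None else sorted(config.bc_type_params)
    bcs = {t: _generate_bc_arbors(config, t) for t in names}
    wiring = wire_contacts(cones, rods, bcs, config)
    sac = None
    if with_sac:
        cbc5_cells = {}
        for tname, st in (("CBC5T", "5T"), ("CBC5O", "5O"), ("CBC5I", "5I")):
            for cid in sorted(wiring.cell_types):
                if wiring.cell_types[cid] == tname:
                    cbc5_cells[cid] = (wiring.somata[cid], st)
        sac = generate_sac_bands_and_cbc5_axons(
            config, cbc5_cells=cbc5_cells or None
        )
        wiring.truth.cbc5_subtype = dict(sac.subtype_truth)
    return OplDataset(
        config=config,
        cones=cones,
        rods=rods,
        skeletons=wiring.skeletons,
        somata=wiring.somata,
        cell_types=wiring.cell_types,
        contact_points=wiring.contact_points,
        contact_sets=wiring.contact_sets,
        truth=wiring.truth,
        sac=sac,
    )
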