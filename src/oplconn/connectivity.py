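"""Connectivity quantifications: convergence, divergence, in-field cone
counts, coverage factors, contact-distance KDEs, rod connectivity, the
two-group RBC comparison and percentile-bootstrap confidence intervals.

Conventions:

* The dendritic field of a cell is the convex hull of its skeleton
  nodes projected along the optical axis (z); a cone is "in field" when
  its centre projects inside or on the hull boundary.
* Hull coverage of a type = Σ hull areas / area of the union of hulls;
  cone coverage = Σ per-cell in-field cone counts / number of cones in
  the union of the fields.
* Convergence/divergence statistics are restricted to complete cones
  and, optionally, to cells away from the field border (inset margin),
  since border cells see truncated cone complements.
* All confidence intervals are seeded percentile bootstrap intervals
  over case resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from shapely.geometry import MultiPoint, Point
from shapely.ops import unary_union

from .geometry import SYNAPTIC, ConePedicle, ContactSet, RodSpherule, Skeleton


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval via case resampling."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    stats = np.array([statistic(values[row]) for row in idx])
    alpha = (1.0 - level) / 2.0
    return (
        float(np.percentile(stats, 100 * alpha)),
        float(np.percentile(stats, 100 * (1 - alpha))),
    )


# ---------------------------------------------------------------------------
# hulls and fields
# ---------------------------------------------------------------------------

def dendritic_hull(skel: Skeleton, exclude_soma: bool = True):
    """Projected (xy) convex hull of a skeleton as a shapely polygon.

    The soma/trunk nodes (first two) are excluded by default, since the
    dendritic field is defined by the arbor.  Degenerate inputs (< 3
    non-collinear points) yield a zero-area geometry.
    """
    pts = skel.xyz[2:, :2] if exclude_soma and len(skel) > 4 else skel.xyz[:, :2]
    return MultiPoint([tuple(p) for p in pts]).convex_hull


def hull_area(skel: Skeleton) -> float:
    return float(dendritic_hull(skel).area)


def cones_in_field(
    skel: Skeleton, cones: Sequence[ConePedicle], hull=None
) -> list[str]:
    """Cones whose centre projects inside or on the dendritic hull."""
    if hull is None:
        hull = dendritic_hull(skel)
    out = []
    for c in cones:
        if hull.covers(Point(c.center[0], c.center[1])):
            out.append(c.terminal_id)
    return out


@dataclass
class CoverageRow:
    """One row of the type table: hull area, hull coverage and
    cone-counting coverage of one BC type."""

    type_name: str
    n_cells: int
    hull_area_mean: float
    hull_area_sem: float
    hull_coverage: float
    cone_coverage: float | None


def coverage_factors(
    skels: Sequence[Skeleton],
    cones: Sequence[ConePedicle] | None = None,
    type_name: str = "",
) -> CoverageRow:
    """Coverage factors of one type's mosaic.

    hull coverage = Σ A_i / area(∪ hulls); cone coverage = Σ_i |cones in
    field of cell i| / |cones in the union of the fields| (None when no
    cones are supplied or none fall in the union).
    """
    if not skels:
        raise ValueError("need at least one cell")
    hulls = [dendritic_hull(s) for s in skels]
    areas = np.array([h.area for h in hulls])
    union = unary_union(hulls)
    if union.area <= 0:
        raise ValueError("union of hulls has zero area")
    hull_cov = float(np.sum(areas) / union.area)
    cone_cov = None
    if cones:
        per_cell = sum(
            len(cones_in_field(s, cones, hull=h)) for s, h in zip(skels, hulls)
        )
        in_union = sum(
            1 for c in cones if union.covers(Point(c.center[0], c.center[1]))
        )
        if in_union > 0:
            cone_cov = per_cell / in_union
    n = len(skels)
    return CoverageRow(
        type_name=type_name,
        n_cells=n,
        hull_area_mean=float(np.mean(areas)),
        hull_area_sem=float(np.std(areas, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        hull_coverage=hull_cov,
        cone_coverage=cone_cov,
    )


# ---------------------------------------------------------------------------
# convergence / divergence
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityTable:
    """Per-cell and per-cone connectivity records with summaries.

    per_cell: one row per BC with counts of contacted S/M cones and
    in-field cone counts; per_cone: one row per cone with counts of
    contacting BCs per type.  Summaries carry bootstrap CIs.
    """

    per_cell: pd.DataFrame
    per_cone: pd.DataFrame
    convergence: pd.DataFrame
    divergence: pd.DataFrame


def convergence_divergence(
    classified_sets: Sequence[ContactSet],
    skeletons: dict[str, Skeleton],
    cell_types: dict[str, str],
    cones: Sequence[ConePedicle],
    spectral: dict[str, str] | None = None,
    inset_margin: float | None = None,
    field_size: tuple[float, float] | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> ConnectivityTable:
    """Convergence (cones per BC) and divergence (BCs per cone) tables.

    Only synaptic sets count.  Restricted to complete cones; when an
    ``inset_margin`` and ``field_size`` are given, cells and cones
    within the margin of the field border are excluded (border cells
    face truncated cone complements).
    """
    spectral = spectral or {c.terminal_id: c.spectral_type for c in cones}
    cones_by_id = {c.terminal_id: c for c in cones}

    def keep_cone(cid: str) -> bool:
        c = cones_by_id.get(cid)
        if c is None or not c.complete:
            return False
        if inset_margin and field_size:
            w, h = field_size
            x, y = c.center[0], c.center[1]
            if not (
                inset_margin <= x <= w - inset_margin
                and inset_margin <= y <= h - inset_margin
            ):
                return False
        return True

    def keep_cell(cid: str) -> bool:
        if inset_margin and field_size:
            sk = skeletons[cid]
            x, y = sk.xyz[0, 0], sk.xyz[0, 1]
            w, h = field_size
            return (
                inset_margin <= x <= w - inset_margin
                and inset_margin <= y <= h - inset_margin
            )
        return True

    contacted: dict[str, set] = {cid: set() for cid in skeletons}
    contacted_by: dict[str, set] = {c.terminal_id: set() for c in cones}
    for s in classified_sets:
        if s.label != SYNAPTIC or s.terminal_id not in cones_by_id:
            continue
        if s.bc_id in contacted:
            contacted[s.bc_id].add(s.terminal_id)
        contacted_by.setdefault(s.terminal_id, set()).add(s.bc_id)

    cell_rows = []
    for cid in sorted(skeletons):
        if not keep_cell(cid):
            continue
        sk = skeletons[cid]
        hull = dendritic_hull(sk)
        infield = [
            t for t in cones_in_field(sk, cones, hull=hull)
            if cones_by_id[t].complete
        ]
        hits = [t for t in contacted[cid] if keep_cone(t)]
        cell_rows.append(
            {
                "cell_id": cid,
                "type": cell_types.get(cid, ""),
                "n_S": sum(1 for t in hits if spectral.get(t) == "S"),
                "n_M": sum(1 for t in hits if spectral.get(t) == "M"),
                "n_contacted": len(hits),
                "n_in_field": len(infield),
            }
        )
    per_cell = pd.DataFrame(cell_rows)

    types = sorted(set(cell_types.values()))
    cone_rows = []
    for c in cones:
        if not keep_cone(c.terminal_id):
            continue
        row = {
            "cone_id": c.terminal_id,
            "spectral": spectral.get(c.terminal_id, "unknown"),
        }
        partners = contacted_by.get(c.terminal_id, set())
        for t in types:
            row[t] = sum(1 for b in partners if cell_types.get(b) == t)
        row["n_total"] = len(partners)
        cone_rows.append(row)
    per_cone = pd.DataFrame(cone_rows)

    conv_rows = []
    if len(per_cell):
        for t, grp in per_cell.groupby("type"):
            for cls, col in (("S", "n_S"), ("M", "n_M"), ("all", "n_contacted")):
                vals = grp[col].to_numpy(dtype=float)
                lo, hi = bootstrap_ci(vals, n_boot=n_boot, seed=seed)
                conv_rows.append(
                    {
                        "type": t,
                        "cone_class": cls,
                        "mean": float(vals.mean()),
                        "ci_low": lo,
                        "ci_high": hi,
                        "n_cells": len(vals),
                    }
                )
    convergence = pd.DataFrame(conv_rows)

    div_rows = []
    if len(per_cone):
        for cls, grp in per_cone.groupby("spectral"):
            for t in types:
                vals = grp[t].to_numpy(dtype=float)
                lo, hi = bootstrap_ci(vals, n_boot=n_boot, seed=seed)
                div_rows.append(
                    {
                        "cone_class": cls,
                        "type": t,
                        "mean": float(vals.mean()),
                        "ci_low": lo,
                        "ci_high": hi,
                        "n_cones": len(vals),
                    }
                )
    divergence = pd.DataFrame(div_rows)
    return ConnectivityTable(per_cell, per_cone, convergence, divergence)


# ---------------------------------------------------------------------------
# contact-distance KDEs
# ---------------------------------------------------------------------------

def contact_distance_kde(
    somata: dict[str, np.ndarray],
    classified_sets: Sequence[ContactSet],
    cones: Sequence[ConePedicle],
    cell_types: dict[str, str],
    skeletons: dict[str, Skeleton] | None = None,
    normalize: bool = False,
    bandwidth: str | float = "silverman",
    grid: np.ndarray | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-type Gaussian KDE of soma-to-contacted-cone planar distances.

    With ``normalize`` the distances are divided by the cell's
    equivalent hull radius sqrt(A/π) (requires skeletons).  Returns
    type → (grid, density); each density integrates to 1.
    """
    cones_by_id = {c.terminal_id: c for c in cones}
    dists: dict[str, list[float]] = {}
    radii: dict[str, float] = {}
    for s in classified_sets:
        if s.label != SYNAPTIC or s.terminal_id not in cones_by_id:
            continue
        if s.bc_id not in somata:
            continue
        t = cell_types.get(s.bc_id, "")
        d = float(
            np.linalg.norm(
                cones_by_id[s.terminal_id].center[:2] - np.asarray(somata[s.bc_id])[:2]
            )
        )
        if normalize:
            if skeletons is None:
                raise ValueError("normalized KDE requires skeletons")
            if s.bc_id not in radii:
                radii[s.bc_id] = float(
                    np.sqrt(max(hull_area(skeletons[s.bc_id]), 1e-9) / np.pi)
                )
            d = d / radii[s.bc_id]
        dists.setdefault(t, []).append(d)

    out = {}
    for t in sorted(dists):
        vals = np.asarray(dists[t], dtype=float)
        if len(vals) < 2 or np.std(vals) == 0:
            g = grid if grid is not None else np.linspace(0, max(vals.max(), 1), 200)
            dens = np.zeros_like(g)
            dens[np.argmin(np.abs(g - vals.mean()))] = 1.0 / (g[1] - g[0])
            out[t] = (g, dens)
            continue
        kde = gaussian_kde(vals, bw_method=bandwidth)
        g = grid if grid is not None else np.linspace(
            vals.min() - 4 * vals.std(), vals.max() + 4 * vals.std(), 400
        )
        out[t] = (g, kde(g))
    return out


# ---------------------------------------------------------------------------
# rod connectivity
# ---------------------------------------------------------------------------

@dataclass
class RodConnectivity:
    rods_per_rbc: pd.Series           # cell_id -> count
    rbcs_per_rod: pd.Series           # rod_id -> count (synaptic RBC partners)
    rbc_per_rod_histogram: dict[str, int]   # '0' | '1' | '2' | '>2'
    rods_per_off_type: dict[str, pd.Series]
    n_rods_excluded: int              # rods without synaptic RBC contact


def rod_connectivity(
    classified_rod_sets: Sequence[ContactSet],
    rods: Sequence[RodSpherule],
    cell_types: dict[str, str],
    off_types: Sequence[str] = ("CBC1", "CBC2", "CBC3A", "CBC3B", "CBC4"),
) -> RodConnectivity:
    """Rod-to-BC connectivity summaries.

    OFF-CBC counts are restricted to rods with at least one synaptic
    RBC contact (the same restriction used when classifying OFF-CBC rod
    contacts); the number of excluded rods is reported.
    """
    rod_ids = [r.terminal_id for r in rods]
    rbc_partners: dict[str, set] = {rid: set() for rid in rod_ids}
    off_partners: dict[str, list[tuple[str, str]]] = {rid: [] for rid in rod_ids}
    rods_per_rbc: dict[str, set] = {}
    for s in classified_rod_sets:
        if s.label != SYNAPTIC or s.terminal_id not in rbc_partners:
            continue
        t = cell_types.get(s.bc_id, "")
        if t == "RBC":
            rbc_partners[s.terminal_id].add(s.bc_id)
            rods_per_rbc.setdefault(s.bc_id, set()).add(s.terminal_id)
        elif t in off_types:
            off_partners[s.terminal_id].append((s.bc_id, t))

    rbcs_per_rod = pd.Series(
        {rid: len(v) for rid, v in rbc_partners.items()}, dtype=int
    )
    hist = {
        "0": int((rbcs_per_rod == 0).sum()),
        "1": int((rbcs_per_rod == 1).sum()),
        "2": int((rbcs_per_rod == 2).sum()),
        ">2": int((rbcs_per_rod > 2).sum()),
    }
    rods_with_rbc = {rid for rid, v in rbc_partners.items() if v}
    excluded = len(rod_ids) - len(rods_with_rbc)

    per_off: dict[str, dict[str, int]] = {t: {} for t in off_types}
    for rid in rods_with_rbc:
        for bc_id, t in off_partners[rid]:
            per_off[t][bc_id] = per_off[t].get(bc_id, 0) + 1
    rods_per_off = {
        t: pd.Series(per_off[t], dtype=int).sort_index() for t in off_types
    }
    return RodConnectivity(
        rods_per_rbc=pd.Series(
            {k: len(v) for k, v in sorted(rods_per_rbc.items())}, dtype=int
        ),
        rbcs_per_rod=rbcs_per_rod,
        rbc_per_rod_histogram=hist,
        rods_per_off_type=rods_per_off,
        n_rods_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# RBC two-group comparison
# ---------------------------------------------------------------------------

@dataclass
class RbcGroupReport:
    n_rod_only: int
    n_rod_and_cone: int
    rod_counts: dict[str, np.ndarray]
    hull_areas: dict[str, np.ndarray]
    axon_peak_depths: dict[str, np.ndarray] | None
    diff_rod_count_ci: tuple[float, float] | None
    diff_hull_area_ci: tuple[float, float] | None
    degenerate: bool


def rbc_group_compare(
    rbc_ids: Sequence[str],
    classified_sets: Sequence[ContactSet],
    skeletons: dict[str, Skeleton],
    cones: Sequence[ConePedicle],
    rods: Sequence[RodSpherule],
    axon_peak_depth: dict[str, float] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> RbcGroupReport:
    """Compare rod-only RBCs with RBCs that also contact cones.

    Groups are defined by the presence of >= 1 synaptic cone contact;
    differences in rod-contact counts and dendritic hull areas are given
    as bootstrap CIs of the group-mean difference (cone-group minus
    rod-only).  A degenerate flag marks an empty group.
    """
    cone_ids = {c.terminal_id for c in cones}
    rod_ids = {r.terminal_id for r in rods}
    has_cone: dict[str, bool] = {r: False for r in rbc_ids}
    rods_per: dict[str, int] = {r: 0 for r in rbc_ids}
    for s in classified_sets:
        if s.label != SYNAPTIC or s.bc_id not in has_cone:
            continue
        if s.terminal_id in cone_ids:
            has_cone[s.bc_id] = True
        elif s.terminal_id in rod_ids:
            rods_per[s.bc_id] += 1

    g_cone = [r for r in rbc_ids if has_cone[r]]
    g_rod = [r for r in rbc_ids if not has_cone[r]]
    rod_counts = {
        "rod_only": np.array([rods_per[r] for r in g_rod], dtype=float),
        "rod_and_cone": np.array([rods_per[r] for r in g_cone], dtype=float),
    }
    hulls = {
        "rod_only": np.array([hull_area(skeletons[r]) for r in g_rod]),
        "rod_and_cone": np.array([hull_area(skeletons[r]) for r in g_cone]),
    }
    peaks = None
    if axon_peak_depth is not None:
        peaks = {
            "rod_only": np.array([axon_peak_depth[r] for r in g_rod if r in axon_peak_depth]),
            "rod_and_cone": np.array(
                [axon_peak_depth[r] for r in g_cone if r in axon_peak_depth]
            ),
        }
    degenerate = len(g_cone) == 0 or len(g_rod) == 0

    def diff_ci(a: np.ndarray, b: np.ndarray):
        if degenerate:
            return None
        rng = np.random.default_rng(seed)
        diffs = [
            float(
                np.mean(rng.choice(a, a.size, replace=True))
                - np.mean(rng.choice(b, b.size, replace=True))
            )
            for _ in range(n_boot)
        ]
        return (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))

    return RbcGroupReport(
        n_rod_only=len(g_rod),
        n_rod_and_cone=len(g_cone),
        rod_counts=rod_counts,
        hull_areas=hulls,
        axon_peak_depths=peaks,
        diff_rod_count_ci=diff_ci(rod_counts["rod_and_cone"], rod_counts["rod_only"]),
        diff_hull_area_ci=diff_ci(hulls["rod_and_cone"], hulls["rod_only"]),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# invaginating vs tip tally
# ---------------------------------------------------------------------------

def contact_type_tally(
    on_sets: Sequence[ContactSet],
    cell_types: dict[str, str],
    height_threshold: float = 0.15,
    cones: Sequence[ConePedicle] | None = None,
) -> pd.DataFrame:
    """Tally invaginating vs. tip contacts per ON-CBC type.

    A synaptic ON contact set counts as invaginating when its contact
    height exceeds ``height_threshold`` (the dendritic tip reaches into
    the pedicle) and its eccentricity stays within the pedicle radius;
    otherwise it is a tip contact.  Row sums equal the number of
    synaptic sets per type.
    """
    radius = {c.terminal_id: c.radius for c in cones} if cones else {}
    counts: dict[str, dict[str, int]] = {}
    for s in on_sets:
        if s.label != SYNAPTIC:
            continue
        if s.features is None:
            raise ValueError("contact sets must carry features")
        t = cell_types.get(s.bc_id, "")
        row = counts.setdefault(t, {"invaginating": 0, "tip": 0})
        r = radius.get(s.terminal_id, np.inf)
        invag = (
            s.features["c_contact_height"] > height_threshold
            and s.features["b_eccentricity"] <= r
        )
        row["invaginating" if invag else "tip"] += 1
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    if not df.empty:
        df = df[["invaginating", "tip"]].sort_index()
    return df
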