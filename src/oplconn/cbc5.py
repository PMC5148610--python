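"""CBC5 subtype classification from SAC-band-corrected axonal depth
profiles.

Type 5 cone bipolar cells split into three subtypes (5T, 5O, 5I) whose
axons stratify at slightly different depths of the inner plexiform
layer.  Because the IPL itself is warped, raw z coordinates are first
normalised against the two starburst amacrine cell (SAC / ChAT) dendritic
bands: the peak depth of each band is fitted with a bivariate cubic
B-spline surface over (x, y), and every point's depth is mapped affinely
per (x, y) column so that the ON band lies at corrected depth 0 and the
OFF band at 1.

Per cell, a length-weighted histogram of corrected axonal depths (the
depth profile) is computed, profiles are reduced to their first three
principal components, and a 3-component full-covariance Gaussian mixture
provides the initial subtype assignment.  Because each subtype should
approximately tile the retina, the assignment is then refined by a
greedy shift/swap heuristic minimising a cost that combines the mixture
(Mahalanobis) term with convex-hull overlap penalties of same-cluster
cells in both the OPL (dendritic fields) and the IPL (axonal fields):

    L = λ1 Σ_i (x_i − μ_ci)ᵀ Σ_ci⁻¹ (x_i − μ_ci)
      + λ2 Σ_{i≠j} δ(c_i, c_j) O_ij,OPL / Σ_i A_i,OPL
      + λ2 Σ_{i≠j} δ(c_i, c_j) O_ij,IPL / Σ_i A_i,IPL

Overlap sums count ordered pairs (both (i, j) and (j, i)); self-overlap
is excluded.  The default uses the inverse covariance (a proper
Mahalanobis/GMM penalty); the literal form without the inverse is
available behind ``use_inverse_covariance=False``.  Defaults λ1 = 1 and
λ2 = n_cells balance the per-cell distance sum against the field-level
overlap ratios.

Final cluster labels are assigned by ascending mean profile peak depth:
5T < 5O < 5I.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline, griddata
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

DEPTH_BIN_RANGE = (-0.5, 1.5)
N_DEPTH_BINS = 50
GMM_RESTARTS = 20
RIDGE = 1e-6  # covariance regulariser


# ---------------------------------------------------------------------------
# SAC band surfaces
# ---------------------------------------------------------------------------

class SacSurface:
    """Bivariate cubic B-spline surface z(x, y) fitted to per-column SAC
    band peak depths."""

    def __init__(self, spline: RectBivariateSpline, bounds: tuple[float, float, float, float]):
        self._spline = spline
        self.bounds = bounds  # xmin, xmax, ymin, ymax

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return self._spline.ev(x, y)


def sac_band_surface(
    points: np.ndarray,
    grid: tuple[int, int] = (10, 8),
    depth_bin: float = 0.5,
    smoothing: float = 0.0,
) -> SacSurface:
    """Fit a SAC band surface from a dendritic point cloud.

    The field is divided into an (nx, ny) grid; per grid cell the depth
    histogram (bin height ``depth_bin`` µm) is computed and its peak bin
    (highest density; ties resolved to the first/lowest bin by argmax)
    taken as the band depth there.  Cells without points are filled by
    nearest-neighbour interpolation before a cubic B-spline surface is
    fitted through the grid of peaks.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("empty SAC point cloud")
    nx, ny = grid
    if nx < 4 or ny < 4:
        raise ValueError("grid must be at least 4x4 for a cubic surface")
    xmin, xmax = points[:, 0].min(), points[:, 0].max()
    ymin, ymax = points[:, 1].min(), points[:, 1].max()
    xe = np.linspace(xmin, xmax, nx + 1)
    ye = np.linspace(ymin, ymax, ny + 1)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    zmin, zmax = points[:, 2].min(), points[:, 2].max()
    nz = max(1, int(np.ceil((zmax - zmin) / depth_bin)))
    ze = np.linspace(zmin, zmin + nz * depth_bin, nz + 1)
    zc = 0.5 * (ze[:-1] + ze[1:])

    ix = np.clip(np.searchsorted(xe, points[:, 0], side="right") - 1, 0, nx - 1)
    iy = np.clip(np.searchsorted(ye, points[:, 1], side="right") - 1, 0, ny - 1)

    peak = np.full((nx, ny), np.nan)
    for i in range(nx):
        for j in range(ny):
            mask = (ix == i) & (iy == j)
            if not np.any(mask):
                continue
            zs = points[mask, 2]
            hist, _ = np.histogram(zs, bins=ze)
            k = int(np.argmax(hist))
            # refine the modal bin with the median of the points near it,
            # which is robust to band tilt across the grid cell
            near = zs[np.abs(zs - zc[k]) <= 2.0 * depth_bin]
            peak[i, j] = float(np.median(near)) if near.size else zc[k]

    if np.isnan(peak).any():
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        known = ~np.isnan(peak)
        if known.sum() == 0:
            raise ValueError("no grid cell contains points")
        peak = griddata(
            (xx[known], yy[known]), peak[known], (xx, yy), method="nearest"
        )

    spline = RectBivariateSpline(xc, yc, peak, kx=3, ky=3, s=smoothing)
    return SacSurface(spline, (float(xmin), float(xmax), float(ymin), float(ymax)))


def flatten_depth(
    points: np.ndarray, on_surface: SacSurface, off_surface: SacSurface
) -> np.ndarray:
    """Affine per-(x, y)-column depth correction: ON band → 0, OFF band
    → 1, linear in between and extrapolated outside.

    Raises if the two surfaces coincide at any queried column.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    z_on = on_surface(points[:, 0], points[:, 1])
    z_off = off_surface(points[:, 0], points[:, 1])
    gap = z_off - z_on
    if np.any(np.abs(gap) < 1e-9):
        raise ValueError("SAC surfaces coincide at a queried (x, y) column")
    return (points[:, 2] - z_on) / gap


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Unit-normalised corrected-depth density of one cell's axonal arbor."""

    cell_id: str
    bin_centers: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("profile density must be non-negative")

    @property
    def peak_depth(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.density))])


def axon_profiles(
    clouds: dict[str, np.ndarray],
    on_surface: SacSurface,
    off_surface: SacSurface,
    n_bins: int = N_DEPTH_BINS,
    depth_range: tuple[float, float] = DEPTH_BIN_RANGE,
    weights: dict[str, np.ndarray] | None = None,
) -> list[DepthProfile]:
    """Histogram the corrected depths of each cell's axonal points.

    ``clouds`` maps cell_id → (N, 3) point array (e.g. resampled
    skeleton points); optional per-cell ``weights`` (e.g. segment
    lengths) weight the histogram.  Profiles are normalised to unit sum.
    """
    edges = np.linspace(depth_range[0], depth_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = []
    for cell_id in sorted(clouds):
        pts = np.asarray(clouds[cell_id], dtype=float)
        d = flatten_depth(pts, on_surface, off_surface)
        w = None if weights is None else weights.get(cell_id)
        hist, _ = np.histogram(np.clip(d, *depth_range), bins=edges, weights=w)
        total = hist.sum()
        if total <= 0:
            raise ValueError(f"cell {cell_id} has an empty depth profile")
        out.append(DepthProfile(cell_id, centers, hist / total))
    return out


def skeleton_axon_cloud(skel) -> tuple[np.ndarray, np.ndarray]:
    """Edge-midpoint cloud of a skeleton with edge-length weights, for
    length-weighted depth profiles."""
    pts, w = [], []
    for i in range(len(skel)):
        p = skel.parent_idx[i]
        if p < 0:
            continue
        pts.append(0.5 * (skel.xyz[i] + skel.xyz[p]))
        w.append(skel.edge_length(i))
    return np.array(pts), np.array(w)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterState:
    """State of the CBC5 subtype clustering.

    x: (n, 3) PC scores; assignments in {0, 1, 2}; mixture means and
    covariances; λ weights; per-cell hull areas and pairwise overlap
    matrices for OPL and IPL.
    """

    cell_ids: list[str]
    x: np.ndarray
    assignments: np.ndarray
    means: np.ndarray            # (3, 3)
    covariances: np.ndarray      # (3, 3, 3)
    lambda1: float
    lambda2: float
    area_opl: np.ndarray         # (n,)
    area_ipl: np.ndarray
    overlap_opl: np.ndarray      # (n, n), symmetric, diag = areas
    overlap_ipl: np.ndarray
    use_inverse_covariance: bool = True
    profiles: list[DepthProfile] | None = None

    def copy(self) -> "ClusterState":
        st = ClusterState(
            cell_ids=list(self.cell_ids),
            x=self.x,
            assignments=self.assignments.copy(),
            means=self.means,
            covariances=self.covariances,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            area_opl=self.area_opl,
            area_ipl=self.area_ipl,
            overlap_opl=self.overlap_opl,
            overlap_ipl=self.overlap_ipl,
            use_inverse_covariance=self.use_inverse_covariance,
            profiles=self.profiles,
        )
        return st


def pca_scores(profiles: list[DepthProfile], n_components: int = 3) -> np.ndarray:
    """First principal-component scores of the mean-centred profiles."""
    M = np.array([p.density for p in profiles])
    if len(M) < n_components:
        raise ValueError("need at least as many cells as components")
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(M)


def pca_gmm_init(
    profiles: list[DepthProfile],
    seed: int = 0,
    lambda1: float = 1.0,
    lambda2: float | None = None,
    area_opl: np.ndarray | None = None,
    area_ipl: np.ndarray | None = None,
    overlap_opl: np.ndarray | None = None,
    overlap_ipl: np.ndarray | None = None,
    use_inverse_covariance: bool = True,
) -> ClusterState:
    """Initial clustering: PCA to 3 components, then a 3-component
    full-covariance Gaussian mixture with seeded restarts.

    Hull areas/overlaps default to zeros (pure GMM clustering) when not
    supplied.
    """
    n = len(profiles)
    if n < 3:
        raise ValueError("need at least 3 cells")
    x = pca_scores(profiles, 3)
    gmm = GaussianMixture(
        n_components=3,
        covariance_type="full",
        n_init=GMM_RESTARTS,
        random_state=int(seed) % (2**31),
        reg_covar=RIDGE,
    )
    assign = gmm.fit_predict(x)
    if lambda2 is None:
        lambda2 = float(n)
    zeros_v = np.zeros(n)
    zeros_m = np.zeros((n, n))
    return ClusterState(
        cell_ids=[p.cell_id for p in profiles],
        x=x,
        assignments=np.asarray(assign),
        means=gmm.means_,
        covariances=gmm.covariances_,
        lambda1=lambda1,
        lambda2=float(lambda2),
        area_opl=zeros_v if area_opl is None else np.asarray(area_opl, float),
        area_ipl=zeros_v if area_ipl is None else np.asarray(area_ipl, float),
        overlap_opl=zeros_m if overlap_opl is None else np.asarray(overlap_opl, float),
        overlap_ipl=zeros_m if overlap_ipl is None else np.asarray(overlap_ipl, float),
        use_inverse_covariance=use_inverse_covariance,
        profiles=profiles,
    )


def _mixture_term(state: ClusterState) -> float:
    total = 0.0
    for c in range(3):
        mask = state.assignments == c
        if not np.any(mask):
            continue
        d = state.x[mask] - state.means[c]
        S = state.covariances[c]
        if state.use_inverse_covariance:
            S = np.linalg.inv(S + RIDGE * np.eye(S.shape[0]))
        total += float(np.einsum("ij,jk,ik->", d, S, d))
    return total


def _overlap_term(state: ClusterState, O: np.ndarray, A: np.ndarray) -> float:
    tot_area = float(np.sum(A))
    if tot_area <= 0:
        return 0.0
    same = state.assignments[:, None] == state.assignments[None, :]
    np.fill_diagonal(same, False)
    return float(np.sum(O[same])) / tot_area


def cluster_cost(state: ClusterState) -> float:
    """The clustering cost L (mixture term + OPL and IPL overlap terms)."""
    return (
        state.lambda1 * _mixture_term(state)
        + state.lambda2 * _overlap_term(state, state.overlap_opl, state.area_opl)
        + state.lambda2 * _overlap_term(state, state.overlap_ipl, state.area_ipl)
    )


def refine_assignments(state: ClusterState, max_iter: int = 200) -> ClusterState:
    """Greedy descent over single-cell shifts and pairwise swaps.

    Per iteration the best strictly cost-decreasing move is applied;
    terminates at a local minimum or after ``max_iter`` iterations.  The
    returned cost never exceeds the input cost.
    """
    state = state.copy()
    n = len(state.cell_ids)
    current = cluster_cost(state)
    for _ in range(max_iter):
        best_cost = current
        best_move = None
        for i in range(n):
            old = state.assignments[i]
            for c in range(3):
                if c == old:
                    continue
                state.assignments[i] = c
                cost = cluster_cost(state)
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best_move = ("shift", i, c)
            state.assignments[i] = old
        for i, j in itertools.combinations(range(n), 2):
            ci, cj = state.assignments[i], state.assignments[j]
            if ci == cj:
                continue
            state.assignments[i], state.assignments[j] = cj, ci
            cost = cluster_cost(state)
            if cost < best_cost - 1e-12:
                best_cost = cost
                best_move = ("swap", i, j)
            state.assignments[i], state.assignments[j] = ci, cj
        if best_move is None:
            break
        if best_move[0] == "shift":
            _, i, c = best_move
            state.assignments[i] = c
        else:
            _, i, j = best_move
            state.assignments[i], state.assignments[j] = (
                state.assignments[j],
                state.assignments[i],
            )
        current = best_cost
    return state


SUBTYPE_ORDER = ("5T", "5O", "5I")


def subtype_labels(state: ClusterState) -> dict[str, str]:
    """Map clusters to subtype names by ascending mean profile peak
    depth (5T shallowest, then 5O, then 5I)."""
    if state.profiles is None:
        raise ValueError("state carries no profiles to order clusters by")
    peaks = {p.cell_id: p.peak_depth for p in state.profiles}
    means = []
    for c in range(3):
        ids = [cid for cid, a in zip(state.cell_ids, state.assignments) if a == c]
        means.append(np.mean([peaks[i] for i in ids]) if ids else np.inf)
    order = np.argsort(means)
    name_of = {int(order[k]): SUBTYPE_ORDER[k] for k in range(3)}
    return {
        cid: name_of[int(a)] for cid, a in zip(state.cell_ids, state.assignments)
    }
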