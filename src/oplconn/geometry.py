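"""Core data model of the outer plexiform layer (OPL) and geometric
contact features.

The objects here mirror what an EM reconstruction of the outer retina
provides: skeletonised bipolar cells (BCs), volume-reconstructed
photoreceptor terminals (cone pedicles and rod spherules) and a table of
membrane contact points between BC dendrites and terminals.  All contact
points between one BC and one terminal are grouped into a *contact set*,
the unit that is classified as synaptic or non-synaptic downstream.

For every contact set a small geometric feature vector is extracted:

a. total contact area (µm²) summed over the points of the set,
b. eccentricity — planar distance of the closest contact point to the
   terminal centre, measured perpendicular to the optical axis (µm),
c. contact height — axial position of the minimal-eccentricity point
   above the pedicle base, normalised by pedicle height (unitless),
d. arc distance along the dendrite to the nearest branch point (µm),
e. arc distance along the dendrite to the nearest dendritic tip (µm),
f. smallest angle between the contacting dendrite and the optical axis
   (radians, folded into [0, π/2]),
g. number of contact points in the set,
h. (rod contacts only) Euclidean distance to the nearest synaptic rod
   bipolar cell (RBC) contact on the same spherule (µm).

Invaginating ON-type contacts sit near the pedicle centre with the
dendrite ending at the cone and running parallel to the axis; basal
OFF-type contacts sit at the pedicle base with small areas; peripheral
(non-synaptic) touches are eccentric, high on the pedicle flank or on
telodendria, typically made by passing dendrites far from any tip.

Coordinates are µm.  The optical axis of simulated terminals is the
global +z axis, pointing from the pedicle base towards the pedicle top;
BC somata lie at negative z and the inner plexiform layer (IPL) further
below.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SYNAPTIC = "synaptic"
NON_SYNAPTIC = "non_synaptic"
UNLABELED = "unlabeled"

FEATURE_NAMES = (
    "a_contact_area",
    "b_eccentricity",
    "c_contact_height",
    "d_dist_branch",
    "e_dist_tip",
    "f_axis_angle",
    "g_n_points",
)
ROD_EXTRA_FEATURE = "h_dist_rbc_contact"


# ---------------------------------------------------------------------------
# skeletons
# ---------------------------------------------------------------------------

class SkeletonError(ValueError):
    """Raised for malformed skeletons (cycles, dangling parents, ...)."""


class Skeleton:
    """A rooted tree of 3-D nodes with radii, one cell's arbor.

    Parameters
    ----------
    node_ids : sequence of int
        Arbitrary unique node identifiers.
    parent_ids : sequence of int
        Parent identifier per node; -1 marks the single root.
    xyz : (n, 3) array
        Node positions in µm.
    radii : (n,) array
        Node radii in µm.
    """

    def __init__(self, node_ids, parent_ids, xyz, radii, cell_id="", cell_type=""):
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        self.parent_ids = np.asarray(parent_ids, dtype=np.int64)
        self.xyz = np.asarray(xyz, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.cell_id = cell_id
        self.cell_type = cell_type
        self._validate()
        self._index = {int(nid): i for i, nid in enumerate(self.node_ids)}
        # parent index per node (-1 for root)
        self.parent_idx = np.array(
            [self._index[int(p)] if p != -1 else -1 for p in self.parent_ids],
            dtype=np.int64,
        )
        self._children: list[list[int]] = [[] for _ in range(len(self.node_ids))]
        for i, p in enumerate(self.parent_idx):
            if p >= 0:
                self._children[p].append(i)

    def _validate(self):
        n = len(self.node_ids)
        if n == 0:
            raise SkeletonError("empty skeleton")
        if len(np.unique(self.node_ids)) != n:
            raise SkeletonError("duplicate node ids")
        if not np.all(np.isfinite(self.xyz)):
            raise SkeletonError("non-finite coordinates")
        roots = np.sum(self.parent_ids == -1)
        if roots != 1:
            raise SkeletonError(f"expected exactly one root, found {roots}")
        idset = set(int(i) for i in self.node_ids)
        for nid, pid in zip(self.node_ids, self.parent_ids):
            if pid != -1 and int(pid) not in idset:
                raise SkeletonError(f"node {nid}: parent {pid} not in skeleton")
        # cycle check via parent chain walk
        index = {int(nid): k for k, nid in enumerate(self.node_ids)}
        state = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 on path, 2 done
        for start in range(n):
            path = []
            k = start
            while k != -1 and state[k] == 0:
                state[k] = 1
                path.append(k)
                pid = int(self.parent_ids[k])
                k = index[pid] if pid != -1 else -1
            if k != -1 and state[k] == 1:
                raise SkeletonError(
                    f"cycle detected involving node {int(self.node_ids[k])}"
                )
            for j in path:
                state[j] = 2

    # -- basic topology -----------------------------------------------------

    def __len__(self):
        return len(self.node_ids)

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent_idx == -1)[0][0])

    def index_of(self, node_id: int) -> int:
        try:
            return self._index[int(node_id)]
        except KeyError:
            raise KeyError(f"node {node_id} not in skeleton {self.cell_id}")

    def children(self, i: int) -> list[int]:
        return self._children[i]

    def degree(self, i: int) -> int:
        return len(self._children[i]) + (1 if self.parent_idx[i] >= 0 else 0)

    def is_leaf(self, i: int) -> bool:
        return len(self._children[i]) == 0

    def is_branch_point(self, i: int) -> bool:
        return self.degree(i) >= 3

    @property
    def leaves(self) -> np.ndarray:
        return np.array([i for i in range(len(self)) if self.is_leaf(i)])

    @property
    def branch_points(self) -> np.ndarray:
        return np.array(
            [i for i in range(len(self)) if self.is_branch_point(i)], dtype=np.int64
        )

    def edge_length(self, i: int) -> float:
        """Length of the edge from node i to its parent (0 for the root)."""
        p = self.parent_idx[i]
        if p < 0:
            return 0.0
        return float(np.linalg.norm(self.xyz[i] - self.xyz[p]))

    def adjacency(self):
        """(neighbour indices, edge lengths) per node, cached."""
        if not hasattr(self, "_adj"):
            adj: list[list[tuple[int, float]]] = [[] for _ in range(len(self))]
            for i in range(len(self)):
                p = self.parent_idx[i]
                if p >= 0:
                    w = self.edge_length(i)
                    adj[i].append((int(p), w))
                    adj[p].append((i, w))
            self._adj = adj
        return self._adj

    def geodesic_to_nearest(self, sources: Iterable[int], targets: set[int]) -> float:
        """Shortest along-tree distance from any source node to any target node."""
        targets = set(targets)
        if not targets:
            return float("inf")
        adj = self.adjacency()
        dist = {int(s): 0.0 for s in sources}
        heap = [(0.0, int(s)) for s in sources]
        heapq.heapify(heap)
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, np.inf):
                continue
            if u in targets:
                return d
            for v, w in adj[u]:
                nd = d + w
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        return float("inf")

    def local_direction(self, i: int) -> np.ndarray:
        """Unit direction of the dendrite at node i.

        Central difference across the node when it has both a parent and
        at least one child; otherwise the single incident edge.
        """
        p = self.parent_idx[i]
        ch = self._children[i]
        if p >= 0 and ch:
            v = self.xyz[ch[0]] - self.xyz[p]
        elif p >= 0:
            v = self.xyz[i] - self.xyz[p]
        elif ch:
            v = self.xyz[ch[0]] - self.xyz[i]
        else:
            raise SkeletonError("isolated node has no direction")
        n = np.linalg.norm(v)
        if n == 0:
            return np.array([0.0, 0.0, 1.0])
        return v / n

    def translated(self, offset) -> "Skeleton":
        return Skeleton(
            self.node_ids,
            self.parent_ids,
            self.xyz + np.asarray(offset, dtype=float),
            self.radii,
            cell_id=self.cell_id,
            cell_type=self.cell_type,
        )


# ---------------------------------------------------------------------------
# photoreceptor terminals
# ---------------------------------------------------------------------------

@dataclass
class ConePedicle:
    """A cone axon terminal.

    The basal plane (``basal_z``) is the pedicle base where ribbon
    synapses sit; the optical axis is the unit vector perpendicular to
    it through the centre.
    """

    terminal_id: str
    center: np.ndarray          # 3-D, µm
    basal_z: float              # axial coordinate of the pedicle base
    height: float               # µm, > 0
    axis: np.ndarray            # unit vector
    radius: float               # planar extent, µm
    spectral_type: str = "unknown"   # 'S' | 'M' | 'unknown'
    complete: bool = True

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.height <= 0:
            raise ValueError("pedicle height must be > 0")
        if not np.isclose(np.linalg.norm(self.axis), 1.0, atol=1e-8):
            raise ValueError("optical axis must be unit-norm")

    @property
    def base_point(self) -> np.ndarray:
        """The point on the basal plane on the optical axis."""
        c = self.center.copy()
        # shift centre along the axis so it sits on the basal plane
        t = (self.basal_z - self.center[2]) / self.axis[2] if self.axis[2] != 0 else 0.0
        return c + t * self.axis


@dataclass
class RodSpherule:
    """A rod axon terminal, modelled as a small sphere."""

    terminal_id: str
    center: np.ndarray
    radius: float = 1.2

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("spherule radius must be > 0")

    def as_frame(self) -> ConePedicle:
        """View the spherule in the cone feature frame.

        Eccentricity and height of rod contacts are measured relative to
        the spherule centre along the global optical axis (+z), with the
        'base' at the bottom of the sphere and height the diameter.
        """
        return ConePedicle(
            terminal_id=self.terminal_id,
            center=self.center,
            basal_z=float(self.center[2] - self.radius),
            height=2.0 * self.radius,
            axis=np.array([0.0, 0.0, 1.0]),
            radius=self.radius,
        )


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactPoint:
    bc_id: str
    terminal_id: str
    position: np.ndarray        # 3-D, µm
    area: float                 # µm², >= 0
    node_id: int                # nearest skeleton node of the BC

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.area < 0:
            raise ValueError("contact area must be >= 0")


@dataclass
class ContactSet:
    """All contact points between one BC and one photoreceptor terminal."""

    bc_id: str
    terminal_id: str
    points: list[ContactPoint]
    features: dict | None = None
    label: str = UNLABELED

    def __post_init__(self):
        if not self.points:
            raise ValueError("contact set must contain at least one point")
        for p in self.points:
            if p.bc_id != self.bc_id or p.terminal_id != self.terminal_id:
                raise ValueError("contact point does not belong to this pair")

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.points])


def group_contact_sets(points: Sequence[ContactPoint]) -> list[ContactSet]:
    """Group contact points into one set per (BC, terminal) pair.

    Order of sets follows first appearance of each pair; every point is
    assigned to exactly one set.
    """
    groups: dict[tuple[str, str], list[ContactPoint]] = {}
    for p in points:
        groups.setdefault((p.bc_id, p.terminal_id), []).append(p)
    return [
        ContactSet(bc_id=k[0], terminal_id=k[1], points=v) for k, v in groups.items()
    ]


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def contact_area(cset: ContactSet) -> float:
    """Total contact area of the set (µm²), summed over points."""
    return float(np.sum(cset.areas))


def _planar_offsets(cset: ContactSet, cone: ConePedicle) -> np.ndarray:
    """Per-point displacement from the cone centre, projected onto the
    plane perpendicular to the optical axis."""
    d = cset.positions - cone.center
    axial = d @ cone.axis
    return d - np.outer(axial, cone.axis)


def eccentricity(cset: ContactSet, cone: ConePedicle) -> float:
    """Planar distance of the closest contact point to the cone centre (µm)."""
    return float(np.min(np.linalg.norm(_planar_offsets(cset, cone), axis=1)))


def _min_ecc_point(cset: ContactSet, cone: ConePedicle) -> int:
    """Index of the minimal-eccentricity point.

    Ties are broken by the smallest axial coordinate (closest to the
    pedicle base).
    """
    ecc = np.linalg.norm(_planar_offsets(cset, cone), axis=1)
    axial = (cset.positions - cone.base_point) @ cone.axis
    order = np.lexsort((axial, np.round(ecc, 9)))
    return int(order[0])


def contact_height(cset: ContactSet, cone: ConePedicle) -> float:
    """Normalised axial height of the minimal-eccentricity point.

    0 at the pedicle base, 1 at the pedicle top; signed, so points below
    the base give negative values.
    """
    i = _min_ecc_point(cset, cone)
    axial = float((cset.positions[i] - cone.base_point) @ cone.axis)
    return axial / cone.height


def arc_distances(cset: ContactSet, skel: Skeleton) -> tuple[float, float]:
    """Along-dendrite distances (µm) to the nearest branch point and the
    nearest dendritic tip, minimised over the points of the set.

    A tree without any branch point uses the root as the branch
    reference.
    """
    sources = [skel.index_of(p.node_id) for p in cset.points]
    branch = set(int(b) for b in skel.branch_points)
    if not branch:
        branch = {skel.root}
    tips = set(int(t) for t in skel.leaves)
    d_branch = skel.geodesic_to_nearest(sources, branch)
    d_tip = skel.geodesic_to_nearest(sources, tips)
    return d_branch, d_tip


def axis_angle(cset: ContactSet, skel: Skeleton, cone: ConePedicle) -> float:
    """Smallest acute angle between the contacting dendrite and the
    optical axis over the points of the set (radians, in [0, π/2])."""
    best = np.pi / 2
    for p in cset.points:
        v = skel.local_direction(skel.index_of(p.node_id))
        c = abs(float(np.dot(v, cone.axis)))
        best = min(best, float(np.arccos(np.clip(c, -1.0, 1.0))))
    return best


def rod_extra_feature(
    cset: ContactSet, synaptic_rbc_points: Sequence[ContactPoint]
) -> float:
    """Minimum Euclidean distance (µm) from the set to any synaptic RBC
    contact point on the same rod spherule.

    Synaptic OFF-CBC contacts on rods sit immediately next to the
    invaginating RBC dendrites, so this distance is small for true
    contacts.  Raises ``ValueError`` if the rod has no RBC contacts (the
    rod is then excluded from the OFF-CBC rod analysis).
    """
    same_rod = [p for p in synaptic_rbc_points if p.terminal_id == cset.terminal_id]
    if not same_rod:
        raise ValueError(
            f"rod {cset.terminal_id} has no synaptic RBC contact; "
            "excluded from OFF-CBC rod analysis"
        )
    rbc_pos = np.array([p.position for p in same_rod])
    d = np.linalg.norm(
        cset.positions[:, None, :] - rbc_pos[None, :, :], axis=2
    )
    return float(np.min(d))


def extract_features(
    cset: ContactSet,
    skel: Skeleton,
    terminal: ConePedicle | RodSpherule,
    synaptic_rbc_points: Sequence[ContactPoint] | None = None,
) -> dict:
    """Populate the feature vector of a contact set.

    For rod spherules the pedicle-frame features are computed in the
    spherule's frame (centre, global optical axis); if
    ``synaptic_rbc_points`` is given, the rod-specific distance to the
    nearest synaptic RBC contact is added.
    """
    if isinstance(terminal, RodSpherule):
        frame = terminal.as_frame()
    else:
        frame = terminal
    d_branch, d_tip = arc_distances(cset, skel)
    feats = {
        "a_contact_area": contact_area(cset),
        "b_eccentricity": eccentricity(cset, frame),
        "c_contact_height": contact_height(cset, frame),
        "d_dist_branch": d_branch,
        "e_dist_tip": d_tip,
        "f_axis_angle": axis_angle(cset, skel, frame),
        "g_n_points": len(cset.points),
    }
    if isinstance(terminal, RodSpherule) and synaptic_rbc_points is not None:
        feats[ROD_EXTRA_FEATURE] = rod_extra_feature(cset, synaptic_rbc_points)
    cset.features = feats
    return feats


def features_frame(csets: Sequence[ContactSet]) -> pd.DataFrame:
    """Tabulate extracted features, one row per contact set."""
    rows = []
    for s in csets:
        if s.features is None:
            raise ValueError(f"features not extracted for pair ({s.bc_id}, {s.terminal_id})")
        row = {"bc_id": s.bc_id, "terminal_id": s.terminal_id, "label": s.label}
        row.update(s.features)
        rows.append(row)
    return pd.DataFrame(rows)
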