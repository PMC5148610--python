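"""File formats: SWC skeletons, CSV tables, manifest.

Skeletons are exchanged as standard whitespace-delimited SWC
(id, type, x, y, z, radius, parent; µm units; node type 1 for the soma
node, 3 for dendrite nodes).  Tabular data is UTF-8 CSV with headers;
units (µm / µm²) are documented in a sidecar schema file written with
each dataset.  A manifest echoes the generating config, the seed and a
file inventory with content hashes, making runs reproducible and
comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ConePedicle, ContactPoint, RodSpherule, Skeleton, SkeletonError


class SwcParseError(ValueError):
    pass


def write_swc(skel: Skeleton, path) -> None:
    """Write a skeleton as SWC (one line per node)."""
    path = Path(path)
    lines = [f"# cell_id {skel.cell_id}", f"# cell_type {skel.cell_type}"]
    for k in range(len(skel)):
        nid = int(skel.node_ids[k])
        pid = int(skel.parent_ids[k])
        ntype = 1 if pid == -1 else 3
        x, y, z = skel.xyz[k]
        lines.append(
            f"{nid} {ntype} {x:.6f} {y:.6f} {z:.6f} {skel.radii[k]:.6f} {pid}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_swc(path, cell_id: str | None = None, cell_type: str = "") -> Skeleton:
    """Parse an SWC file into a Skeleton.

    Malformed files (wrong column count, duplicate ids, missing parents,
    cycles) raise :class:`SwcParseError` naming the offending line or
    node.
    """
    path = Path(path)
    ids, parents, xyz, radii = [], [], [], []
    meta = {"cell_id": cell_id or path.stem, "cell_type": cell_type}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split(maxsplit=1)
            if parts and parts[0] in ("cell_id", "cell_type") and len(parts) == 2:
                if cell_id is None or parts[0] != "cell_id":
                    meta[parts[0]] = parts[1].strip()
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SwcParseError(f"{path}:{lineno}: expected 7 fields, got {len(fields)}")
        try:
            nid = int(fields[0])
            x, y, z, r = map(float, fields[2:6])
            pid = int(fields[6])
        except ValueError as e:
            raise SwcParseError(f"{path}:{lineno}: {e}") from None
        ids.append(nid)
        parents.append(pid)
        xyz.append((x, y, z))
        radii.append(r)
    try:
        return Skeleton(
            ids, parents, np.array(xyz), np.array(radii),
            cell_id=meta["cell_id"], cell_type=meta["cell_type"],
        )
    except SkeletonError as e:
        raise SwcParseError(f"{path}: {e}") from None


# ---------------------------------------------------------------------------
# dataset directory layout
# ---------------------------------------------------------------------------

SCHEMA = {
    "cells.csv": "cell_id, type, soma_x/soma_y/soma_z [µm]",
    "cones.csv": "terminal_id, x/y/z centre [µm], basal_z [µm], height [µm], radius [µm], complete flag",
    "rods.csv": "terminal_id, x/y/z centre [µm], radius [µm]",
    "contacts.csv": "contact_point_id, bc_id, terminal_id, x/y/z [µm], area [µm²], node_id (nearest skeleton node)",
    "truth.csv": "hidden labels: record kind, ids, label",
    "features.csv": "per contact set: bc_id, terminal_id, features a–h",
    "skeletons/": "one SWC file per cell, µm units",
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _config_to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _config_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def save_dataset(dataset, out_dir, emit_truth: bool = False) -> Path:
    """Write a synthetic dataset to a directory.

    Ground-truth labels go to truth.csv only when ``emit_truth`` is set;
    the analysis-facing files never carry them.
    """
    out = Path(out_dir)
    (out / "skeletons").mkdir(parents=True, exist_ok=True)
    for cid in sorted(dataset.skeletons):
        write_swc(dataset.skeletons[cid], out / "skeletons" / f"{cid}.swc")

    pd.DataFrame(
        [
            {
                "cell_id": cid,
                "type": dataset.cell_types[cid],
                "soma_x": dataset.somata[cid][0],
                "soma_y": dataset.somata[cid][1],
                "soma_z": dataset.somata[cid][2],
            }
            for cid in sorted(dataset.skeletons)
        ]
    ).to_csv(out / "cells.csv", index=False)

    pd.DataFrame(
        [
            {
                "terminal_id": c.terminal_id,
                "x": c.center[0], "y": c.center[1], "z": c.center[2],
                "basal_z": c.basal_z, "height": c.height, "radius": c.radius,
                "complete": c.complete,
            }
            for c in dataset.cones
        ]
    ).to_csv(out / "cones.csv", index=False)

    pd.DataFrame(
        [
            {
                "terminal_id": r.terminal_id,
                "x": r.center[0], "y": r.center[1], "z": r.center[2],
                "radius": r.radius,
            }
            for r in dataset.rods
        ]
    ).to_csv(out / "rods.csv", index=False)

    pd.DataFrame(
        [
            {
                "contact_point_id": i,
                "bc_id": p.bc_id,
                "terminal_id": p.terminal_id,
                "x": p.position[0], "y": p.position[1], "z": p.position[2],
                "area": p.area,
                "node_id": p.node_id,
            }
            for i, p in enumerate(dataset.contact_points)
        ]
    ).to_csv(out / "contacts.csv", index=False)

    if emit_truth:
        rows = []
        for (bc, term), lab in sorted(dataset.truth.set_labels.items()):
            rows.append({"kind": "contact_set", "id1": bc, "id2": term, "label": lab})
        for cid, lab in sorted(dataset.truth.cone_spectral.items()):
            rows.append({"kind": "cone_spectral", "id1": cid, "id2": "", "label": lab})
        for cid, lab in sorted(dataset.truth.cbc5_subtype.items()):
            rows.append({"kind": "cbc5_subtype", "id1": cid, "id2": "", "label": lab})
        pd.DataFrame(rows).to_csv(out / "truth.csv", index=False)

    if dataset.sac is not None:
        np.savetxt(out / "sac_on.csv", dataset.sac.on_points, delimiter=",",
                   header="x,y,z", comments="")
        np.savetxt(out / "sac_off.csv", dataset.sac.off_points, delimiter=",",
                   header="x,y,z", comments="")

    (out / "schema.json").write_text(json.dumps(SCHEMA, indent=2))
    inventory = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": _config_to_jsonable(dataset.config),
        "seed": int(dataset.config.seed),
        "coordinate_frame": "µm; optical axis = +z from pedicle base toward "
                            "pedicle top; BC somata and IPL at negative z",
        "files": inventory,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_contacts(path) -> list[ContactPoint]:
    df = pd.read_csv(path)
    return [
        ContactPoint(
            bc_id=str(r.bc_id),
            terminal_id=str(r.terminal_id),
            position=np.array([r.x, r.y, r.z]),
            area=float(r.area),
            node_id=int(r.node_id),
        )
        for r in df.itertuples()
    ]


def load_cones(path) -> list[ConePedicle]:
    df = pd.read_csv(path)
    return [
        ConePedicle(
            terminal_id=str(r.terminal_id),
            center=np.array([r.x, r.y, r.z]),
            basal_z=float(r.basal_z),
            height=float(r.height),
            axis=np.array([0.0, 0.0, 1.0]),
            radius=float(r.radius),
            complete=bool(r.complete),
        )
        for r in df.itertuples()
    ]


def load_rods(path) -> list[RodSpherule]:
    df = pd.read_csv(path)
    return [
        RodSpherule(
            terminal_id=str(r.terminal_id),
            center=np.array([r.x, r.y, r.z]),
            radius=float(r.radius),
        )
        for r in df.itertuples()
    ]


def load_skeletons(directory) -> dict[str, Skeleton]:
    directory = Path(directory)
    out = {}
    for p in sorted(directory.glob("*.swc")):
        sk = read_swc(p)
        out[sk.cell_id] = sk
    return out
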