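"""Pipeline orchestration: simulate → features → classify → S-cone
identification → CBC5 typing → connectivity.

The stages are plain functions over in-memory objects, so they can be
composed in scripts and tests; :func:`run_pipeline` ties them together
into a reproducible run directory with a manifest (config echo, seed,
file hashes).  Every random operation draws from a stream derived from
the single run seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cbc5 as cbc5mod
from . import classify as clf
from . import connectivity as conn
from . import scones as sconemod
from .geometry import (
    NON_SYNAPTIC,
    SYNAPTIC,
    ContactSet,
    extract_features,
    features_frame,
)
from .io import save_dataset
from .synthetic import OplSimConfig, OplDataset, generate_dataset

logger = logging.getLogger("oplconn")

#: training-set sizes per classifier group (sampled from the manually
#: labelled pool), mirroring the published training regime
TRAIN_SIZES = {
    "OFF_CBC_cone": 50,
    "ON_CBC_cone": 108,
    "RBC_cone": 67,
    "RBC_rod": 100,
    "OFF_CBC_rod": 97,   # 5 CBC1 + 32 CBC2 + 20 each CBC3A/3B/4
}

ON_TYPES = ("CBC5T", "CBC5O", "CBC5I", "CBCX", "CBC6", "CBC7", "CBC8", "CBC9")
OFF_TYPES = ("CBC1", "CBC2", "CBC3A", "CBC3B", "CBC4")


def group_of(cell_type: str, terminal_kind: str) -> str | None:
    """Classifier group of a (BC type, terminal kind) combination."""
    if terminal_kind == "cone":
        if cell_type in OFF_TYPES:
            return "OFF_CBC_cone"
        if cell_type in ON_TYPES:
            return "ON_CBC_cone"
        if cell_type == "RBC":
            return "RBC_cone"
    elif terminal_kind == "rod":
        if cell_type in OFF_TYPES:
            return "OFF_CBC_rod"
        if cell_type == "RBC":
            return "RBC_rod"
    return None


# ---------------------------------------------------------------------------
# feature stage
# ---------------------------------------------------------------------------

def extract_dataset_features(dataset: OplDataset) -> list[ContactSet]:
    """Extract features a–g for every contact set of the dataset.

    The rod-specific distance feature h depends on which RBC contacts
    are synaptic and is filled in during classification.
    """
    cones = dataset.cones_by_id()
    rods = dataset.rods_by_id()
    for s in dataset.contact_sets:
        terminal = cones.get(s.terminal_id) or rods.get(s.terminal_id)
        if terminal is None:
            raise KeyError(f"unknown terminal {s.terminal_id}")
        extract_features(s, dataset.skeletons[s.bc_id], terminal)
    return dataset.contact_sets


def _add_rod_distance_feature(
    rod_sets: list[ContactSet], synaptic_rbc_sets: list[ContactSet]
) -> tuple[list[ContactSet], list[ContactSet]]:
    """Fill in feature h for OFF-CBC rod sets; returns (kept, excluded)
    where excluded sets sit on rods without any synaptic RBC contact."""
    points = [p for s in synaptic_rbc_sets for p in s.points]
    by_rod: dict[str, list] = {}
    for p in points:
        by_rod.setdefault(p.terminal_id, []).append(p)
    kept, excluded = [], []
    for s in rod_sets:
        pts = by_rod.get(s.terminal_id)
        if not pts:
            excluded.append(s)
            continue
        from .geometry import rod_extra_feature

        s.features[clf.ROD_EXTRA_FEATURE] = rod_extra_feature(s, pts)
        kept.append(s)
    return kept, excluded


# ---------------------------------------------------------------------------
# classification stage
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    sets: list[ContactSet]                   # all sets, with predicted labels
    reports: dict[str, clf.CvReport]
    excluded_off_rod: list[ContactSet]       # rods without RBC contacts
    training_ids: dict[str, list[tuple[str, str]]]


def run_classification(
    dataset: OplDataset, seed: int = 0, train_sizes: dict[str, int] | None = None
) -> ClassificationResult:
    """Train per-group classifiers on ground-truth-labelled samples and
    predict synaptic/non-synaptic for every contact set.

    Training samples are drawn at the configured per-group sizes from
    the generator's labelled pool (the stand-in for manual labels); the
    ON-CBC cone group excludes CBCX sets, whose contacts are atypical.
    The rod-distance feature h is computed from the *predicted* synaptic
    RBC–rod contacts before the OFF-CBC rod group is classified, and
    rods without RBC contacts are excluded from that group.
    """
    train_sizes = dict(TRAIN_SIZES, **(train_sizes or {}))
    rng = np.random.default_rng([int(seed) % (2**31), 7])
    cone_ids = {c.terminal_id for c in dataset.cones}
    truth = dataset.truth

    by_group: dict[str, list[ContactSet]] = {g: [] for g in clf.GROUPS}
    for s in dataset.contact_sets:
        kind = "cone" if s.terminal_id in cone_ids else "rod"
        g = group_of(dataset.cell_types.get(s.bc_id, ""), kind)
        if g is not None:
            by_group[g].append(s)

    def truth_label(s: ContactSet) -> str:
        return truth.set_labels.get((s.bc_id, s.terminal_id), NON_SYNAPTIC)

    reports: dict[str, clf.CvReport] = {}
    models: dict[str, clf.TrainedModel] = {}
    training_ids: dict[str, list[tuple[str, str]]] = {}

    def train_group(gname: str, pool: list[ContactSet]):
        n_req = min(train_sizes[gname], len(pool))
        pos = [s for s in pool if truth_label(s) == SYNAPTIC]
        neg = [s for s in pool if truth_label(s) == NON_SYNAPTIC]
        if not pos or not neg:
            raise ValueError(f"group {gname}: training pool has a single class")
        # stratified draw, at least 3 per class
        n_pos = max(3, int(round(n_req * len(pos) / len(pool))))
        n_pos = min(n_pos, len(pos), n_req - 3)
        n_neg = min(n_req - n_pos, len(neg))
        sel = [pos[i] for i in rng.choice(len(pos), n_pos, replace=False)]
        sel += [neg[i] for i in rng.choice(len(neg), n_neg, replace=False)]
        train_sets = []
        for s in sel:
            t = ContactSet(s.bc_id, s.terminal_id, s.points, label=truth_label(s))
            t.features = s.features
            train_sets.append(t)
        models[gname] = clf.train(train_sets, gname, seed=seed)
        reports[gname] = clf.loo_cross_validate(train_sets, gname, seed=seed)
        training_ids[gname] = [(s.bc_id, s.terminal_id) for s in train_sets]

    for gname in ("OFF_CBC_cone", "ON_CBC_cone", "RBC_cone", "RBC_rod"):
        pool = by_group[gname]
        if gname == "ON_CBC_cone":
            pool = [
                s
                for s in pool
                if dataset.cell_types.get(s.bc_id)
                not in clf.ON_TRAINING_EXCLUDED_TYPES
            ]
        if pool:
            train_group(gname, pool)
            clf.predict(models[gname], by_group[gname])

    # OFF-CBC rod group needs the distance-to-RBC-contact feature, which
    # depends on the predicted synaptic RBC-rod sets
    excluded: list[ContactSet] = []
    if by_group["OFF_CBC_rod"]:
        synaptic_rbc = [s for s in by_group["RBC_rod"] if s.label == SYNAPTIC]
        kept, excluded = _add_rod_distance_feature(by_group["OFF_CBC_rod"], synaptic_rbc)
        for s in excluded:
            s.label = NON_SYNAPTIC
        if kept:
            train_group("OFF_CBC_rod", kept)
            clf.predict(models["OFF_CBC_rod"], kept)

    return ClassificationResult(
        sets=dataset.contact_sets,
        reports=reports,
        excluded_off_rod=excluded,
        training_ids=training_ids,
    )


# ---------------------------------------------------------------------------
# S-cone stage
# ---------------------------------------------------------------------------

def run_scone_identification(
    dataset: OplDataset,
    classified_sets: list[ContactSet] | None = None,
    mode: str = "strict",
) -> dict:
    """Identify S-cones from classified CBC9–cone contact sets.

    The denominator is the number of cones within the dendritic field
    (projected convex hull) of at least one CBC9.
    """
    sets = classified_sets if classified_sets is not None else dataset.contact_sets
    cone_ids = {c.terminal_id for c in dataset.cones}
    cbc9_ids = set(dataset.cells_of_type("CBC9"))
    cbc9_sets = [
        s for s in sets if s.bc_id in cbc9_ids and s.terminal_id in cone_ids
    ]
    in_reach: set[str] = set()
    for cid in sorted(cbc9_ids):
        hull = conn.dendritic_hull(dataset.skeletons[cid])
        in_reach.update(conn.cones_in_field(dataset.skeletons[cid], dataset.cones, hull=hull))
    candidates = sconemod.find_candidates(cbc9_sets)
    rule = sconemod.classify_strict if mode == "strict" else sconemod.classify_liberal
    labels = rule(candidates)
    n_reach = max(len(in_reach), 1)
    n_s = sum(1 for v in labels.values() if v == "S")
    full_labels = {cid: labels.get(cid, "M") for cid in sorted(in_reach)}
    full_labels.update(labels)
    return {
        "mode": mode,
        "n_candidates": len(candidates),
        "n_S": n_s,
        "n_in_reach": len(in_reach),
        "fraction_pct": sconemod.scone_fraction(labels, n_reach),
        "binomial_p": sconemod.binomial_test_exact(n_s, n_reach, 0.05),
        "labels": full_labels,
    }


# ---------------------------------------------------------------------------
# CBC5 stage
# ---------------------------------------------------------------------------

def run_cbc5_typing(
    dataset: OplDataset, seed: int = 0, lambda1: float = 1.0,
    lambda2: float | None = None, refine: bool = True,
) -> dict:
    """SAC-corrected depth profiles → PCA → GMM → shift/swap refinement
    → subtype labels for the CBC5 population."""
    if dataset.sac is None:
        raise ValueError("dataset has no SAC band data; enable with_sac")
    from shapely.geometry import MultiPoint

    sac = dataset.sac
    on_surface = cbc5mod.sac_band_surface(sac.on_points)
    off_surface = cbc5mod.sac_band_surface(sac.off_points)
    clouds = sac.axon_clouds
    profiles = cbc5mod.axon_profiles(clouds, on_surface, off_surface)
    ids = [p.cell_id for p in profiles]

    hulls_opl = []
    hulls_ipl = []
    for cid in ids:
        hulls_opl.append(conn.dendritic_hull(dataset.skeletons[cid]))
        hulls_ipl.append(MultiPoint([tuple(p[:2]) for p in clouds[cid]]).convex_hull)
    n = len(ids)
    O_opl = np.zeros((n, n))
    O_ipl = np.zeros((n, n))
    for i in range(n):
        O_opl[i, i] = hulls_opl[i].area
        O_ipl[i, i] = hulls_ipl[i].area
        for j in range(i + 1, n):
            o1 = hulls_opl[i].intersection(hulls_opl[j]).area
            o2 = hulls_ipl[i].intersection(hulls_ipl[j]).area
            O_opl[i, j] = O_opl[j, i] = o1
            O_ipl[i, j] = O_ipl[j, i] = o2

    state = cbc5mod.pca_gmm_init(
        profiles,
        seed=seed,
        lambda1=lambda1,
        lambda2=lambda2,
        area_opl=np.diag(O_opl),
        area_ipl=np.diag(O_ipl),
        overlap_opl=O_opl,
        overlap_ipl=O_ipl,
    )
    init_cost = cbc5mod.cluster_cost(state)
    if refine:
        state = cbc5mod.refine_assignments(state)
    final_cost = cbc5mod.cluster_cost(state)
    labels = cbc5mod.subtype_labels(state)
    return {
        "labels": labels,
        "state": state,
        "initial_cost": init_cost,
        "final_cost": final_cost,
        "profiles": profiles,
        "surfaces": (on_surface, off_surface),
    }


# ---------------------------------------------------------------------------
# connectivity stage
# ---------------------------------------------------------------------------

def run_connectivity(
    dataset: OplDataset,
    classified_sets: list[ContactSet] | None = None,
    spectral: dict[str, str] | None = None,
    seed: int = 0,
    n_boot: int = 500,
) -> dict:
    """All headline connectivity quantifications on classified sets."""
    sets = classified_sets if classified_sets is not None else dataset.contact_sets
    cone_ids = {c.terminal_id for c in dataset.cones}
    table = conn.convergence_divergence(
        sets,
        dataset.skeletons,
        dataset.cell_types,
        dataset.cones,
        spectral=spectral,
        n_boot=n_boot,
        seed=seed,
    )
    coverage = {}
    for t in sorted(set(dataset.cell_types.values())):
        skels = [dataset.skeletons[c] for c in dataset.cells_of_type(t)]
        if skels:
            coverage[t] = conn.coverage_factors(skels, dataset.cones, type_name=t)
    kde = conn.contact_distance_kde(
        dataset.somata, sets, dataset.cones, dataset.cell_types
    )
    rod_sets = [s for s in sets if s.terminal_id not in cone_ids]
    rods_summary = conn.rod_connectivity(rod_sets, dataset.rods, dataset.cell_types)
    rbc_ids = dataset.cells_of_type("RBC")
    rbc_report = None
    if rbc_ids:
        rbc_report = conn.rbc_group_compare(
            rbc_ids, sets, dataset.skeletons, dataset.cones, dataset.rods,
            seed=seed,
        )
    on_sets = [
        s
        for s in sets
        if s.terminal_id in cone_ids
        and dataset.cell_types.get(s.bc_id) in ON_TYPES
    ]
    tally = conn.contact_type_tally(
        on_sets, dataset.cell_types, cones=dataset.cones
    )
    return {
        "table": table,
        "coverage": coverage,
        "kde": kde,
        "rods": rods_summary,
        "rbc_groups": rbc_report,
        "contact_type_tally": tally,
    }


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str = "run"
    seed: int = 0
    sim: OplSimConfig = field(default_factory=OplSimConfig)
    bc_types: list[str] | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True,
            "features": True,
            "classify": True,
            "scones": True,
            "cbc5": True,
            "connectivity": True,
        }
    )
    emit_truth: bool = False
    n_boot: int = 500


class StageDependencyError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order and write results
    plus a manifest into the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        stages = config.stages
        config.sim.seed = config.seed
        dataset: OplDataset | None = None
        if stages.get("simulate"):
            logger.info("simulate: generating synthetic dataset")
            dataset = generate_dataset(config.sim, bc_types=config.bc_types)
            save_dataset(dataset, out / "dataset", emit_truth=config.emit_truth)
        classified = None
        if stages.get("features"):
            if dataset is None:
                raise StageDependencyError("features requires the simulate stage")
            logger.info("features: extracting contact-set features")
            extract_dataset_features(dataset)
            features_frame(dataset.contact_sets).to_csv(
                out / "features.csv", index=False
            )
        if stages.get("classify"):
            if dataset is None or dataset.contact_sets[0].features is None:
                raise StageDependencyError("classify requires the features stage")
            logger.info("classify: training and predicting contact sets")
            result = run_classification(dataset, seed=config.seed)
            classified = result.sets
            pd.DataFrame(
                [
                    {"bc_id": s.bc_id, "terminal_id": s.terminal_id, "label": s.label}
                    for s in classified
                ]
            ).to_csv(out / "predictions.csv", index=False)
            (out / "cv_reports.json").write_text(
                json.dumps({g: r.as_dict() for g, r in result.reports.items()}, indent=2)
            )
        if stages.get("scones"):
            if classified is None:
                raise StageDependencyError("scones requires the classify stage")
            logger.info("scones: identifying S-cones")
            summary = {
                mode: run_scone_identification(dataset, classified, mode=mode)
                for mode in ("strict", "liberal")
            }
            pd.DataFrame(
                [
                    {"cone_id": k, "label": v}
                    for k, v in sorted(summary["strict"]["labels"].items())
                ]
            ).to_csv(out / "cone_labels.csv", index=False)
            (out / "scone_summary.json").write_text(
                json.dumps(
                    {
                        m: {k: v for k, v in s.items() if k != "labels"}
                        for m, s in summary.items()
                    },
                    indent=2,
                )
            )
        if stages.get("cbc5"):
            if dataset is None:
                raise StageDependencyError("cbc5 requires the simulate stage")
            if dataset.sac is not None:
                logger.info("cbc5: subtype clustering")
                res = run_cbc5_typing(dataset, seed=config.seed)
                pd.DataFrame(
                    [
                        {"cell_id": k, "subtype": v}
                        for k, v in sorted(res["labels"].items())
                    ]
                ).to_csv(out / "cbc5_assignments.csv", index=False)
        if stages.get("connectivity"):
            if classified is None:
                raise StageDependencyError("connectivity requires the classify stage")
            logger.info("connectivity: computing summaries")
            res = run_connectivity(
                dataset, classified, seed=config.seed, n_boot=config.n_boot
            )
            res["table"].per_cell.to_csv(out / "connectivity_per_cell.csv", index=False)
            res["table"].per_cone.to_csv(out / "connectivity_per_cone.csv", index=False)
            res["table"].convergence.to_csv(out / "convergence.csv", index=False)
            res["table"].divergence.to_csv(out / "divergence.csv", index=False)
            pd.DataFrame(
                [dataclasses.asdict(r) for r in res["coverage"].values()]
            ).to_csv(out / "coverage.csv", index=False)
            res["contact_type_tally"].to_csv(out / "contact_type_tally.csv")

        inventory = {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        }
        manifest = {
            "seed": config.seed,
            "stages": config.stages,
            "files": inventory,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
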