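"""Tests of the connectivity statistics: hulls, coverage, convergence /
divergence, KDEs, rod connectivity, the RBC comparison and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

import oplconn as oc
from oplconn.connectivity import (
    bootstrap_ci,
    cones_in_field,
    contact_distance_kde,
    contact_type_tally,
    convergence_divergence,
    coverage_factors,
    dendritic_hull,
    rbc_group_compare,
    rod_connectivity,
)
from oplconn.geometry import NON_SYNAPTIC, SYNAPTIC, ContactPoint, ContactSet


def skeleton_from_xy(xy, z=0.0, soma_pad=False):
    """Star skeleton over the given xy nodes; with ``soma_pad`` two
    leading soma/trunk nodes (duplicating the first point) are added so
    the dendritic-field soma exclusion is inert."""
    xy = np.asarray(xy, float)
    if soma_pad:
        xy = np.vstack([xy[:1], xy[:1], xy])
    n = len(xy)
    xyz = np.column_stack([xy, np.full(n, z)])
    ids = np.arange(1, n + 1)
    parents = np.array([-1] + [1] * (n - 1))
    return oc.Skeleton(ids, parents, xyz, np.full(n, 0.2))


def cone_at(x, y, cid="c", spectral="M", complete=True):
    return oc.ConePedicle(
        terminal_id=cid, center=np.array([x, y, 1.0]), basal_z=0.0, height=2.0,
        axis=np.array([0.0, 0.0, 1.0]), radius=3.0, spectral_type=spectral,
        complete=complete,
    )


def synaptic_set(bc, term, label=SYNAPTIC):
    p = ContactPoint(bc, term, np.zeros(3), 0.1, 1)
    s = ContactSet(bc, term, [p], label=label)
    s.features = {"b_eccentricity": 0.5, "c_contact_height": 0.3}
    return s


class TestHulls:
    def test_unit_square_area(self):
        sk = skeleton_from_xy([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert dendritic_hull(sk, exclude_soma=False).area == pytest.approx(1.0)

    def test_triangle_area(self):
        sk = skeleton_from_xy([(0, 0), (4, 0), (0, 3)])
        assert dendritic_hull(sk, exclude_soma=False).area == pytest.approx(6.0)

    def test_degenerate_collinear_arbor_has_zero_area(self):
        sk = skeleton_from_xy([(0, 0), (1, 0), (2, 0)])
        assert dendritic_hull(sk, exclude_soma=False).area == 0.0

    def test_random_arbors_match_scipy_hull_oracle(self, rng):
        for _ in range(100):
            xy = rng.normal(0, 5, (rng.integers(4, 30), 2))
            sk = skeleton_from_xy(xy)
            assert dendritic_hull(sk, exclude_soma=False).area == pytest.approx(
                ConvexHull(xy).volume
            )


class TestConesInField:
    def test_no_cones_inside(self):
        sk = skeleton_from_xy([(0, 0), (1, 0), (0, 1)])
        assert cones_in_field(sk, [cone_at(10, 10)]) == []

    def test_boundary_cone_included(self):
        sk = skeleton_from_xy([(0, 0), (2, 0), (2, 2), (0, 2)])
        assert cones_in_field(sk, [cone_at(1.0, 0.0, "edge")]) == ["edge"]

    def test_matches_point_in_polygon_oracle(self, rng):
        from shapely.geometry import MultiPoint, Point

        for _ in range(50):
            xy = rng.normal(0, 5, (12, 2))
            sk = skeleton_from_xy(xy)
            cones = [cone_at(*rng.normal(0, 5, 2), cid=f"c{i}") for i in range(20)]
            # the dendritic field excludes the soma/trunk nodes (first two)
            hull = MultiPoint([tuple(p) for p in xy[2:]]).convex_hull
            expected = [
                c.terminal_id
                for c in cones
                if hull.covers(Point(c.center[0], c.center[1]))
            ]
            assert cones_in_field(sk, cones) == expected
            assert cones_in_field(sk, cones, hull=hull) == expected


class TestCoverage:
    def test_single_cell_both_coverages_one(self):
        sk = skeleton_from_xy([(0, 0), (5, 0), (5, 5), (0, 5)])
        cones = [cone_at(2, 2, "c1"), cone_at(3, 3, "c2")]
        row = coverage_factors([sk], cones)
        assert row.hull_coverage == pytest.approx(1.0)
        assert row.cone_coverage == pytest.approx(1.0)

    def test_disjoint_hulls_coverage_one(self):
        sk1 = skeleton_from_xy([(0, 0), (2, 0), (2, 2), (0, 2)])
        sk2 = skeleton_from_xy([(10, 10), (12, 10), (12, 12), (10, 12)])
        cones = [cone_at(1, 1, "a"), cone_at(11, 11, "b")]
        row = coverage_factors([sk1, sk2], cones)
        assert row.hull_coverage == pytest.approx(1.0)
        assert row.cone_coverage == pytest.approx(1.0)

    def test_union_area_zero_rejected(self):
        sk = skeleton_from_xy([(0, 0), (1, 0)])
        with pytest.raises(ValueError):
            coverage_factors([sk])

    def test_hull_coverage_matches_monte_carlo_union(self, rng):
        skels = [
            skeleton_from_xy(
                rng.normal(0, 4, (10, 2)) + rng.uniform(-6, 6, 2), soma_pad=True
            )
            for _ in range(5)
        ]
        row = coverage_factors(skels)
        # Monte-Carlo union-area oracle
        hulls = [dendritic_hull(s) for s in skels]
        lo = np.min([h.bounds[:2] for h in hulls], axis=0)
        hi = np.max([h.bounds[2:] for h in hulls], axis=0)
        pts = rng.uniform(lo, hi, (200_000, 2))
        from shapely import points as shapely_points
        from shapely.ops import unary_union

        union = unary_union(hulls)
        inside = union.covers(shapely_points(pts))
        union_mc = inside.mean() * np.prod(hi - lo)
        total = sum(h.area for h in hulls)
        assert row.hull_coverage == pytest.approx(total / union_mc, rel=0.01)


class TestConvergenceDivergence:
    def _simple_setup(self):
        skels = {
            "A_000": skeleton_from_xy([(0, 0), (6, 0), (6, 6), (0, 6)]),
            "B_000": skeleton_from_xy([(4, 4), (10, 4), (10, 10), (4, 10)]),
        }
        types = {"A_000": "A", "B_000": "B"}
        cones = [cone_at(2, 2, "c1", "M"), cone_at(5, 5, "c2", "S"), cone_at(9, 9, "c3", "M")]
        return skels, types, cones

    def test_no_synaptic_sets_gives_zero_counts(self):
        skels, types, cones = self._simple_setup()
        sets = [synaptic_set("A_000", "c1", label=NON_SYNAPTIC)]
        t = convergence_divergence(sets, skels, types, cones, n_boot=100)
        assert t.per_cell.n_contacted.sum() == 0
        assert t.per_cone.n_total.sum() == 0

    def test_counts_match_planted_wiring(self):
        skels, types, cones = self._simple_setup()
        sets = [
            synaptic_set("A_000", "c1"),
            synaptic_set("A_000", "c2"),
            synaptic_set("B_000", "c2"),
            synaptic_set("B_000", "c3"),
        ]
        t = convergence_divergence(sets, skels, types, cones, n_boot=100)
        cell = t.per_cell.set_index("cell_id")
        assert cell.loc["A_000", "n_contacted"] == 2
        assert cell.loc["A_000", "n_S"] == 1
        assert cell.loc["B_000", "n_M"] == 1
        cone = t.per_cone.set_index("cone_id")
        assert cone.loc["c2", "n_total"] == 2

    def test_duality_total_contacts_equal(self):
        skels, types, cones = self._simple_setup()
        sets = [
            synaptic_set("A_000", "c1"),
            synaptic_set("A_000", "c2"),
            synaptic_set("B_000", "c3"),
        ]
        t = convergence_divergence(sets, skels, types, cones, n_boot=100)
        assert t.per_cell.n_contacted.sum() == t.per_cone.n_total.sum()

    def test_incomplete_cones_excluded(self):
        skels, types, _ = self._simple_setup()
        cones = [cone_at(2, 2, "c1", complete=False)]
        sets = [synaptic_set("A_000", "c1")]
        t = convergence_divergence(sets, skels, types, cones, n_boot=100)
        assert t.per_cell.n_contacted.sum() == 0
        assert len(t.per_cone) == 0


class TestKde:
    def test_density_integrates_to_one(self, small_dataset):
        ds = small_dataset
        ds.labeled_sets()
        curves = contact_distance_kde(
            ds.somata, ds.contact_sets, ds.cones, ds.cell_types
        )
        assert curves
        for t, (grid, dens) in curves.items():
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_single_distance_has_mode_there(self):
        somata = {"A_000": np.array([0.0, 0, 0]), "A_001": np.array([0.0, 0, 0])}
        cones = [cone_at(5, 0, "c1"), cone_at(5.3, 0, "c2")]
        sets = [synaptic_set("A_000", "c1"), synaptic_set("A_001", "c2")]
        curves = contact_distance_kde(somata, sets, cones, {"A_000": "A", "A_001": "A"})
        grid, dens = curves["A"]
        assert abs(grid[np.argmax(dens)] - 5.15) < 1.0

    def test_planted_ring_mode_recovered(self, rng):
        somata = {}
        cones = []
        sets = []
        types = {}
        r = 12.0
        for i in range(60):
            cid = f"cell_{i:03d}"
            somata[cid] = np.zeros(3)
            types[cid] = "T"
            phi = rng.uniform(0, 2 * np.pi)
            cones.append(cone_at(r * np.cos(phi), r * np.sin(phi), f"c{i}"))
            sets.append(synaptic_set(cid, f"c{i}"))
        grid, dens = contact_distance_kde(somata, sets, cones, types)["T"]
        assert abs(grid[np.argmax(dens)] - r) < 2.0


class TestRodConnectivity:
    def test_partner_histogram_and_restriction(self):
        rods = [
            oc.RodSpherule(f"r{i}", np.array([float(i), 0, 3.0])) for i in range(4)
        ]
        types = {"RBC_0": "RBC", "RBC_1": "RBC", "OFF_0": "CBC3A"}
        sets = [
            synaptic_set("RBC_0", "r0"),
            synaptic_set("RBC_1", "r0"),
            synaptic_set("RBC_0", "r1"),
            synaptic_set("OFF_0", "r0"),
            synaptic_set("OFF_0", "r3"),  # rod without RBC contact
        ]
        rc = rod_connectivity(sets, rods, types)
        assert rc.rbc_per_rod_histogram == {"0": 2, "1": 1, "2": 1, ">2": 0}
        assert rc.n_rods_excluded == 2
        # r3 has no RBC contact, so OFF_0 keeps only the r0 contact
        assert rc.rods_per_off_type["CBC3A"].to_dict() == {"OFF_0": 1}
        assert rc.rods_per_rbc.to_dict() == {"RBC_0": 2, "RBC_1": 1}

    def test_generator_rod_load_matches_configured_expectation(self, small_dataset):
        """Mean rods per RBC in the synthetic field sits in the ~35
        rods/RBC regime the generator is parameterised for."""
        ds = small_dataset
        ds.labeled_sets()
        cone_ids = {c.terminal_id for c in ds.cones}
        rod_sets = [s for s in ds.contact_sets if s.terminal_id not in cone_ids]
        rc = rod_connectivity(rod_sets, ds.rods, ds.cell_types)
        mean = rc.rods_per_rbc.mean()
        lo, hi = bootstrap_ci(rc.rods_per_rbc.to_numpy(dtype=float), n_boot=1000)
        assert lo <= 35.0 <= hi or abs(mean - 35.0) / 35.0 < 0.10

    def test_two_rbc_rods_come_from_distinct_cells(self, small_dataset):
        ds = small_dataset
        partners = {}
        for (bc, term), lab in ds.truth.set_labels.items():
            if lab == "synaptic" and term.startswith("rod_") and ds.cell_types[bc] == "RBC":
                partners.setdefault(term, []).append(bc)
        two = [v for v in partners.values() if len(v) == 2]
        assert two and all(len(set(v)) == 2 for v in two)


class TestRbcGroups:
    def _dataset(self, seed):
        cfg = oc.OplSimConfig(seed=seed)
        ds = oc.generate_dataset(cfg, bc_types=["RBC"], with_sac=False)
        ds.labeled_sets()
        return ds

    def test_all_rod_only_flags_degenerate(self):
        cfg = oc.OplSimConfig(seed=3, rbc_cone_fraction=0.0)
        ds = oc.generate_dataset(cfg, bc_types=["RBC"], with_sac=False)
        ds.labeled_sets()
        rep = rbc_group_compare(
            ds.cells_of_type("RBC"), ds.contact_sets, ds.skeletons,
            ds.cones, ds.rods,
        )
        assert rep.degenerate
        assert rep.n_rod_and_cone == 0

    def test_identical_groups_ci_contains_zero(self):
        hits = 0
        for seed in [21, 22, 23]:
            ds = self._dataset(seed)
            rep = rbc_group_compare(
                ds.cells_of_type("RBC"), ds.contact_sets, ds.skeletons,
                ds.cones, ds.rods, seed=seed,
            )
            lo, hi = rep.diff_hull_area_ci
            hits += lo <= 0.0 <= hi
        assert hits >= 2

    def test_planted_hull_difference_detected(self, rng):
        # direct construction: cone-contacting RBCs get 2x hulls
        skels = {}
        sets = []
        cones = [cone_at(0, 0, "c1")]
        rods = [oc.RodSpherule("r1", np.array([0.0, 0, 3.0]))]
        ids = []
        for i in range(40):
            cid = f"RBC_{i:03d}"
            ids.append(cid)
            scale = 2.0 if i < 20 else 1.0
            skels[cid] = skeleton_from_xy(rng.normal(0, 3 * np.sqrt(scale), (12, 2)))
            if i < 20:
                sets.append(synaptic_set(cid, "c1"))
            sets.append(synaptic_set(cid, "r1"))
        rep = rbc_group_compare(ids, sets, skels, cones, rods, seed=0)
        lo, hi = rep.diff_hull_area_ci
        assert lo > 0  # cone group has larger hulls


class TestBootstrap:
    def test_constant_sample_zero_width(self):
        lo, hi = bootstrap_ci([4.2] * 30, n_boot=200, seed=1)
        assert lo == hi == pytest.approx(4.2)

    def test_seed_makes_endpoints_stable(self):
        x = np.random.default_rng(0).normal(size=50)
        assert bootstrap_ci(x, seed=7) == bootstrap_ci(x, seed=7)

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0, 2.0], n_boot=10)

    def test_coverage_of_nominal_level(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(0, 1, 200)
            lo, hi = bootstrap_ci(x, n_boot=300, seed=int(rng.integers(2**31)))
            hits += lo <= 0.0 <= hi
        assert abs(hits / reps - 0.95) < 0.04

    def test_interval_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(9)
        widths = []
        for n in (50, 200, 800):
            w = []
            for _ in range(20):
                x = rng.normal(0, 1, n)
                lo, hi = bootstrap_ci(x, n_boot=400, seed=int(rng.integers(2**31)))
                w.append(hi - lo)
            widths.append(np.mean(w))
        slope = np.polyfit(np.log([50, 200, 800]), np.log(widths), 1)[0]
        assert abs(slope + 0.5) < 0.12


class TestContactTypeTally:
    def _set_with(self, bc, term, height, ecc):
        s = synaptic_set(bc, term)
        s.features = {"c_contact_height": height, "b_eccentricity": ecc}
        return s

    def test_all_invaginating_leaves_tip_column_zero(self):
        sets = [self._set_with(f"b{i}", "c1", 0.4, 0.5) for i in range(5)]
        df = contact_type_tally(sets, {f"b{i}": "CBC6" for i in range(5)})
        assert df.loc["CBC6", "tip"] == 0
        assert df.loc["CBC6", "invaginating"] == 5

    def test_reported_contact_type_counts_reproduced(self):
        # printed contingency: CBCX 3 invaginating / 16 tip; other
        # ON-CBCs 71 invaginating / 10 tip
        sets = []
        types = {}
        k = 0
        for n_inv, n_tip, t in [(3, 16, "CBCX"), (71, 10, "CBC6")]:
            for _ in range(n_inv):
                sets.append(self._set_with(f"b{k}", "c1", 0.4, 0.5)); types[f"b{k}"] = t; k += 1
            for _ in range(n_tip):
                sets.append(self._set_with(f"b{k}", "c1", 0.05, 0.5)); types[f"b{k}"] = t; k += 1
        df = contact_type_tally(sets, types)
        assert df.loc["CBCX"].to_dict() == {"invaginating": 3, "tip": 16}
        assert df.loc["CBC6"].to_dict() == {"invaginating": 71, "tip": 10}

    def test_row_sums_equal_synaptic_sets_per_type(self, small_dataset):
        ds = small_dataset
        ds.labeled_sets()
        cone_ids = {c.terminal_id for c in ds.cones}
        on_sets = [
            s for s in ds.contact_sets
            if s.terminal_id in cone_ids and ds.cell_types[s.bc_id] in ("CBC6", "CBC9")
        ]
        df = contact_type_tally(on_sets, ds.cell_types, cones=ds.cones)
        n_syn = {}
        for s in on_sets:
            if s.label == SYNAPTIC:
                t = ds.cell_types[s.bc_id]
                n_syn[t] = n_syn.get(t, 0) + 1
        for t in df.index:
            assert df.loc[t].sum() == n_syn[t]
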