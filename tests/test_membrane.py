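"""Tests for leaflet assignment, lipid selection, thickness and order."""

import dataclasses

import numpy as np
import pytest

from foldkit import (CGFrame, DegenerateDataError, LipidSelection, Trajectory,
                     assign_leaflets, order_parameters, profile_trajectories,
                     select_lipids, thickness)
from foldkit.membrane import burn_in_slice


def flat_frame(n_side=4, spacing=10.0, half_z=11.5, chain_beads=2,
               protein_xyz=None, protein_resids=None, box_z=60.0):
    """Minimal bilayer: lipids on a grid, straight vertical chains."""
    edge = np.arange(n_side) * spacing + spacing / 2
    xx, yy = np.meshgrid(edge, edge, indexing="ij")
    xy = np.column_stack([xx.ravel(), yy.ravel()])
    n = xy.shape[0]
    cz = box_z / 2
    po4, gl1, chains = [], [], []
    for sign in (1.0, -1.0):
        p = np.column_stack([xy[:, 0], xy[:, 1], np.full(n, cz + sign * half_z)])
        po4.append(p)
        gl1.append(p + [0, 0, -sign * 3.0])
    po4 = np.vstack(po4)
    gl1 = np.vstack(gl1)
    gl2 = gl1 + [2.0, 0.0, 0.0]
    sign_col = np.repeat([1.0, -1.0], n)
    chain_a = np.stack(
        [gl1 + np.column_stack([np.zeros(2 * n), np.zeros(2 * n),
                                -sign_col * 4.7 * (b + 1)])
         for b in range(chain_beads)], axis=1)
    chain_b = np.stack(
        [gl2 + np.column_stack([np.zeros(2 * n), np.zeros(2 * n),
                                -sign_col * 4.7 * (b + 1)])
         for b in range(chain_beads)], axis=1)
    kw = {}
    if protein_xyz is not None:
        kw = dict(protein_xyz=np.asarray(protein_xyz, float),
                  protein_resids=np.asarray(protein_resids, int))
    return CGFrame(box=np.array([n_side * spacing, n_side * spacing, box_z]),
                   lipid_resids=np.arange(1, 2 * n + 1),
                   po4=po4, gl1=gl1, gl2=gl2,
                   chain_a=chain_a, chain_b=chain_b, **kw)


def all_lipids(frame):
    return LipidSelection(mode="bulk", indices=np.arange(frame.n_lipids))


class TestLeaflets:
    def test_sign_split_about_midplane(self):
        frame = assign_leaflets(flat_frame(half_z=12.0))
        upper = frame.po4[frame.leaflet > 0, 2]
        lower = frame.po4[frame.leaflet < 0, 2]
        assert np.all(upper > lower.max())
        assert (frame.leaflet > 0).sum() == (frame.leaflet < 0).sum()

    def test_monolayer_rejected(self):
        frame = flat_frame()
        # every PO4 at the same height: no lipid sits above the midplane
        mono = dataclasses.replace(
            frame, po4=frame.po4 * [1, 1, 0] + [0, 0, 30.0])
        with pytest.raises(DegenerateDataError):
            assign_leaflets(mono)


class TestSelectLipids:
    def test_cutoff_boundary_inclusive_for_annular(self):
        frame = flat_frame(protein_xyz=[[5.0, 5.0, 41.5]], protein_resids=[7])
        # lipid 0 sits at exactly (5, 5, 41.5): distance 0; pick a cutoff equal
        # to the distance of another phosphate to make the boundary explicit
        d = np.array([_mi_dist(p.copy(), np.array([5.0, 5.0, 41.5]), frame.box)
                      for p in frame.po4])
        target = np.sort(d)[1]
        sel = select_lipids(frame, "near_residue", 7, cutoff=target)
        assert (d <= target + 1e-9)[sel.indices].all()
        assert np.isclose(d[sel.indices], target).any()  # boundary included

    def test_bulk_strict_exclusion(self):
        # one protein bead exactly at a phosphate position: that lipid has
        # distance 0; a cutoff equal to another lipid's distance must exclude
        # the boundary lipid from the bulk set (strict >)
        frame = flat_frame(protein_xyz=[[5.0, 5.0, 41.5]], protein_resids=[1])
        d = np.array([_mi_dist(p.copy(), np.array([5.0, 5.0, 41.5]), frame.box)
                      for p in frame.po4])
        target = float(np.sort(d)[1])
        sel = select_lipids(frame, "bulk", cutoff=target)
        assert np.all(d[sel.indices] > target + 1e-12)
        boundary = np.nonzero(np.isclose(d, target))[0]
        assert not set(boundary) & set(sel.indices)

    def test_no_protein_means_all_bulk(self):
        frame = flat_frame()
        sel = select_lipids(frame, "bulk")
        assert sel.indices.size == frame.n_lipids

    def test_unknown_anchor_rejected(self):
        frame = flat_frame(protein_xyz=[[5.0, 5.0, 30.0]], protein_resids=[1])
        with pytest.raises(DegenerateDataError):
            select_lipids(frame, "near_residue", 99, 12.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle_on_random_frames(self, seed):
        """Annular and bulk member sets match an explicit all-pairs scan
        with x/y minimum-image distances."""
        rng = np.random.default_rng(seed)
        frame = _random_frame(rng, n_lipids=50, n_prot=12)
        anchor = int(frame.protein_resids[0])
        got = set(select_lipids(frame, "near_residue", anchor, 12.0).indices)
        assert got == _brute_force_near(frame, anchor, 12.0)
        got_bulk = set(select_lipids(frame, "bulk", cutoff=18.0).indices)
        assert got_bulk == _brute_force_bulk(frame, 18.0)


def _random_frame(rng, n_lipids, n_prot):
    box = np.array([60.0, 60.0, 80.0])
    po4 = rng.uniform(0, 1, (n_lipids, 3)) * box
    gl1 = po4 + rng.normal(0, 1, (n_lipids, 3))
    gl2 = po4 + rng.normal(0, 1, (n_lipids, 3))
    chain_a = po4[:, None, :] + rng.normal(0, 2, (n_lipids, 3, 3))
    chain_b = po4[:, None, :] + rng.normal(0, 2, (n_lipids, 3, 3))
    prot = rng.uniform(0, 1, (n_prot, 3)) * box
    resids = np.repeat(np.arange(101, 101 + n_prot // 2), 2)[:n_prot]
    return CGFrame(box=box, lipid_resids=np.arange(1, n_lipids + 1), po4=po4,
                   gl1=gl1, gl2=gl2, chain_a=chain_a, chain_b=chain_b,
                   protein_xyz=prot, protein_resids=resids)


def _mi_dist(a, b, box):
    d = a - b
    for ax in (0, 1):
        if d[ax] > box[ax] / 2:
            d[ax] -= box[ax]
        elif d[ax] < -box[ax] / 2:
            d[ax] += box[ax]
    return float(np.sqrt(np.sum(d * d)))


def _brute_force_near(frame, anchor, cutoff):
    beads = frame.protein_xyz[frame.protein_resids == anchor]
    out = set()
    for i in range(frame.n_lipids):
        dmin = min(_mi_dist(frame.po4[i].copy(), b.copy(), frame.box)
                   for b in beads)
        if dmin <= cutoff:
            out.add(i)
    return out


def _brute_force_bulk(frame, cutoff):
    out = set()
    for i in range(frame.n_lipids):
        dmin = min(_mi_dist(frame.po4[i].copy(), b.copy(), frame.box)
                   for b in frame.protein_xyz)
        if dmin > cutoff:
            out.add(i)
    return out


class TestThickness:
    def test_flat_leaflets_construction(self):
        frame = assign_leaflets(flat_frame(half_z=11.5))
        assert thickness(frame, all_lipids(frame)) == pytest.approx(23.0)

    def test_z_translation_invariance_and_reflection(self):
        frame = assign_leaflets(flat_frame(half_z=11.5))
        base = thickness(frame, all_lipids(frame))
        shifted = dataclasses.replace(frame, po4=frame.po4 + [0, 0, 7.3])
        shifted = assign_leaflets(shifted)
        assert thickness(shifted, all_lipids(shifted)) == pytest.approx(base)
        reflected = dataclasses.replace(
            frame, po4=frame.po4 * [1, 1, -1] + [0, 0, frame.box[2]])
        reflected = assign_leaflets(reflected)
        assert thickness(reflected, all_lipids(reflected)) == pytest.approx(base)

    def test_single_leaflet_selection_is_missing(self):
        frame = assign_leaflets(flat_frame())
        upper_only = LipidSelection(
            mode="bulk", indices=np.nonzero(frame.leaflet > 0)[0][:5])
        assert thickness(frame, upper_only) is None


class TestOrderParameters:
    @pytest.mark.parametrize("theta_deg, expected", [
        (0.0, 1.0),
        (90.0, -0.5),
        (54.7356, 0.0),
    ])
    def test_formula_limits(self, theta_deg, expected):
        frame = _cone_frame(theta_deg)
        s = order_parameters(frame, all_lipids(frame))
        for val in s.values():
            assert val == pytest.approx(expected, abs=1e-6)

    def test_isotropic_bonds_average_to_zero(self):
        rng = np.random.default_rng(42)
        n = 100_000
        v = rng.normal(size=(n, 3))
        cos2 = (v[:, 2] / np.linalg.norm(v, axis=1)) ** 2
        s = float(np.mean(0.5 * (3 * cos2 - 1)))
        assert abs(s) < 3.0 / np.sqrt(n)

    def test_order_bounds_on_random_frames(self):
        rng = np.random.default_rng(7)
        frame = _random_frame(rng, 40, 4)
        for val in order_parameters(frame, all_lipids(frame)).values():
            assert -0.5 <= val <= 1.0


def _cone_frame(theta_deg, chain_beads=4, n=16):
    """Chains with every bond at fixed polar angle theta, random azimuth."""
    from foldkit.synthetic import BilayerSpec, generate_bilayer_trajectory

    spec = BilayerSpec(chain_beads=chain_beads, cone_angle_bulk_deg=theta_deg,
                       n_frames=1, n_replicas=1, seed=3)
    traj, _ = generate_bilayer_trajectory(spec)
    return traj.frames[0]


class TestProfileTrajectories:
    def test_burn_in_index_arithmetic(self):
        assert burn_in_slice(30, 1.0 / 6.0) == slice(5, 30)

    def test_single_frame_single_replica_sd_zero(self):
        from foldkit.synthetic import BilayerSpec, generate_bilayer_trajectory

        spec = BilayerSpec(n_frames=1, n_replicas=1, seed=5)
        traj, _ = generate_bilayer_trajectory(spec)
        prof = profile_trajectories([traj], anchors=[808], burn_in_fraction=0.0)
        bulk = prof.selections["bulk"]
        assert bulk.thickness_sd == 0.0
        assert all(sd == 0.0 for sd in bulk.order_sd.values())

    def test_replica_sd_shrinks_with_jitter(self):
        from foldkit.synthetic import BilayerSpec, generate_bilayer_trajectories

        sds = []
        for jitter in (1.5, 0.1):
            spec = BilayerSpec(n_frames=4, n_replicas=3, seed=9,
                               positional_jitter=jitter)
            trajs, _ = generate_bilayer_trajectories(spec)
            prof = profile_trajectories(trajs, anchors=[808],
                                        burn_in_fraction=0.0)
            sds.append(prof.selections["bulk"].thickness_sd)
        assert sds[1] < sds[0]

    def test_differing_bond_sets_rejected(self):
        from foldkit.synthetic import BilayerSpec, generate_bilayer_trajectory

        t2, _ = generate_bilayer_trajectory(BilayerSpec(
            chain_beads=2, bulk_thickness=25.0, n_frames=1, n_replicas=1))
        t4, _ = generate_bilayer_trajectory(BilayerSpec(
            chain_beads=4, n_frames=1, n_replicas=1))
        with pytest.raises(DegenerateDataError):
            profile_trajectories([t2, t4], anchors=[808])

    def test_bond_labels_follow_chain_length(self):
        from foldkit.synthetic import BilayerSpec, generate_bilayer_trajectory

        traj, _ = generate_bilayer_trajectory(BilayerSpec(
            chain_beads=2, bulk_thickness=25.0, n_frames=1, n_replicas=1))
        prof = profile_trajectories([traj], anchors=[808], burn_in_fraction=0.0)
        assert set(prof.selections["bulk"].order_mean) == {"G-1", "1-2"}
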