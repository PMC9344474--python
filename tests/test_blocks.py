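"""Superposition, water association/transfer and block assembly."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from watblocks.blocks import (AssociationParams, AssociatedWater, BlockLibrary,
                              HydratedBlock, associate_waters, build_block,
                              kabsch_superpose, transfer_water)
from watblocks.structure_io import AtomRecord

from conftest import random_rotation


def quaternion_superpose(moving, target):
    """Independent oracle: Horn's closed-form quaternion method."""
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    A = moving - mc
    B = target - tc
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    diff = A @ R.T - B
    rmsd = np.sqrt((diff ** 2).sum() / len(A))
    return R, tc - R @ mc, rmsd


def _water_at(pos, num=101, sid="w"):
    return AtomRecord(atom_name="O", element="O", residue_name="HOH",
                      chain_id="A", residue_number=num, insertion_code="",
                      position=np.asarray(pos, float), occupancy=1.0,
                      b_factor=20.0, is_water=True, structure_id=sid)


def _transform_step(step, R, t):
    def move(res):
        atoms = [dataclasses.replace(a, position=R @ a.position + t) for a in res.atoms]
        return dataclasses.replace(res, atoms=atoms)
    return dataclasses.replace(step, first=move(step.first), second=move(step.second))


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, np.zeros(3), atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_90_degree_rotation(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        R, t, rmsd = kabsch_superpose(pts, pts @ Rz.T)
        np.testing.assert_allclose(R, Rz, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_quaternion_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(3, 21)
            moving = rng.normal(scale=3.0, size=(n, 3))
            target = moving @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
            target += rng.normal(scale=0.2, size=(n, 3))
            R1, t1, r1 = kabsch_superpose(moving, target)
            R2, t2, r2 = quaternion_superpose(moving, target)
            assert abs(r1 - r2) < 1e-9
            np.testing.assert_allclose(R1, R2, atol=1e-7)

    def test_rotation_is_proper(self):
        # a near-reflection case must still return det +1
        rng = np.random.default_rng(3)
        moving = rng.normal(size=(5, 3))
        target = moving.copy()
        target[:, 2] *= -1  # mirrored set
        R, _, _ = kabsch_superpose(moving, target)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_degenerate_collinear_rejected(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)

    def test_too_few_points_rejected(self):
        pts = np.zeros((2, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(pts, pts)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_rmsd_invariant_under_rigid_motion_of_both_sets(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(7, 3))
        b = a + rng.normal(scale=0.3, size=(7, 3))
        _, _, r0 = kabsch_superpose(a, b)
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        _, _, r1 = kabsch_superpose(a @ R.T + t, b)
        assert abs(r0 - r1) < 1e-9


class TestAssociateWaters:
    def _far_point(self, step, distance):
        atoms = np.stack([a.position for _, a in step.heavy_atoms()])
        centroid = atoms.mean(axis=0)
        far = atoms[np.argmax(np.linalg.norm(atoms - centroid, axis=1))]
        return far + distance * (far - centroid) / np.linalg.norm(far - centroid)

    def test_water_inside_cutoff_associated(self, ideal_step):
        w = _water_at(self._far_point(ideal_step, 3.9))
        assert len(associate_waters(ideal_step, [w])) == 1

    def test_water_outside_cutoff_ignored(self, ideal_step):
        w = _water_at(self._far_point(ideal_step, 4.1))
        assert associate_waters(ideal_step, [w]) == []

    def test_dual_category_flags(self, ideal_step):
        base_pos = np.stack([a.position for a in ideal_step.base_atoms()])
        bb_pos = np.stack([a.position for a in ideal_step.backbone_atoms()])
        # a point within 3.4 A of both a base and a backbone atom
        n9 = ideal_step.first.atom("N9") or ideal_step.first.atom("N1")
        c1 = ideal_step.first.atom("C1'")
        mid = (n9.position + c1.position) / 2
        w = _water_at(mid + np.array([0.0, 0, 1.5]))
        assoc = associate_waters(ideal_step, [w])
        assert len(assoc) == 1
        db = np.linalg.norm(base_pos - assoc[0].position, axis=1).min()
        dk = np.linalg.norm(bb_pos - assoc[0].position, axis=1).min()
        assert assoc[0].near_base == (db <= 3.4)
        assert assoc[0].near_backbone == (dk <= 3.4)
        assert assoc[0].near_base and assoc[0].near_backbone

    def test_association_count_invariant_to_order(self, ideal_step):
        rng = np.random.default_rng(4)
        centroid = ideal_step.heavy_coords().mean(axis=0)
        waters = [_water_at(centroid + rng.uniform(-8, 8, 3), 100 + i)
                  for i in range(20)]
        a1 = associate_waters(ideal_step, waters)
        a2 = associate_waters(ideal_step, list(reversed(waters)))
        assert len(a1) == len(a2)
        ids1 = sorted(w.source_id for w in a1)
        assert ids1 == sorted(w.source_id for w in a2)


class TestTransferWater:
    def test_identity_transfer(self, ideal_step, assoc_params):
        w = AssociatedWater(position=ideal_step.heavy_coords().mean(axis=0) + 3.0,
                            source_id="w", near_base=True, near_backbone=False,
                            nearest_distance=3.0)
        out = transfer_water(w, ideal_step, ideal_step.labeled_coords(), assoc_params)
        np.testing.assert_allclose(out.position, w.position, atol=1e-9)

    def test_equivariance_under_rigid_motion(self, ideal_step, assoc_params):
        rng = np.random.default_rng(6)
        reference = ideal_step.labeled_coords()
        w0 = ideal_step.heavy_coords().mean(axis=0) + np.array([2.5, 1.0, -1.0])
        for _ in range(20):
            R = random_rotation(rng)
            t = rng.uniform(-15, 15, 3)
            moved_step = _transform_step(ideal_step, R, t)
            w = AssociatedWater(position=R @ w0 + t, source_id="w",
                                near_base=True, near_backbone=False,
                                nearest_distance=2.0)
            out = transfer_water(w, moved_step, reference, assoc_params)
            np.testing.assert_allclose(out.position, w0, atol=1e-6)

    def test_six_atom_selection_matches_brute_force_sort(self, ideal_step, assoc_params):
        from watblocks.blocks import _six_nearest
        # water near residue i+1
        anchor = ideal_step.second.atom("N4") or ideal_step.second.atom("N7")
        wpos = anchor.position + np.array([0.0, 0, 2.0])
        labels = _six_nearest(ideal_step, wpos, set(ideal_step.labeled_coords()))
        pairs = sorted(((np.linalg.norm(a.position - wpos), lab)
                        for lab, a in ideal_step.heavy_atoms()),
                       key=lambda p: (p[0], p[1]))
        assert labels == [lab for _, lab in pairs[:6]]

    def test_distorted_frame_dropped(self, ideal_step):
        params = AssociationParams(transfer_rmsd_max=0.1)
        rng = np.random.default_rng(8)
        noisy = _transform_step(ideal_step, np.eye(3), np.zeros(3))
        noisy = dataclasses.replace(
            noisy,
            first=dataclasses.replace(
                noisy.first,
                atoms=[dataclasses.replace(a, position=a.position + rng.normal(0, 0.5, 3))
                       for a in noisy.first.atoms]))
        w = AssociatedWater(position=noisy.first.atoms[0].position + 2.0,
                            source_id="w", near_base=True, near_backbone=False,
                            nearest_distance=2.0)
        assert transfer_water(w, noisy, ideal_step.labeled_coords(), params) is None


class TestBuildBlock:
    def test_empty_block(self, assoc_params):
        block = build_block("BB00", "GC", [], params=assoc_params)
        assert block.n_waters == 0
        assert block.n_steps == 0
        assert not block.reliable

    def test_three_copies_with_two_waters_each(self, ideal_step, assoc_params):
        ideal_step.ntc = "BB00"
        centroid = ideal_step.heavy_coords().mean(axis=0)
        assoc = associate_waters(
            ideal_step,
            [_water_at(centroid + np.array([2.0, 0, 0]), 101),
             _water_at(centroid + np.array([-2.0, 0, 0]), 102)],
            assoc_params)
        assert len(assoc) == 2
        hydrated = [(ideal_step, assoc)] * 3
        block = build_block("BB00", "GC", hydrated, reference=ideal_step,
                            params=assoc_params)
        assert block.n_steps == 3
        assert block.n_waters == 6

    def test_reliability_boundary_is_inclusive(self, ideal_step):
        params = AssociationParams(min_waters_reliable=800)
        ideal_step.ntc = "BB00"
        centroid = ideal_step.heavy_coords().mean(axis=0)
        rng = np.random.default_rng(10)
        waters = [_water_at(centroid + 2.5 * v / np.linalg.norm(v), 100 + i)
                  for i, v in enumerate(rng.normal(size=(8, 3)))]
        assoc = associate_waters(ideal_step, waters, params)
        assert len(assoc) == 8
        block = build_block("BB00", "GC", [(ideal_step, assoc)] * 100,
                            reference=ideal_step, params=params)
        assert block.n_waters == 800
        assert block.reliable  # exactly at the threshold

    def test_mixed_combinations_rejected(self, ideal_step, assoc_params):
        ideal_step.ntc = "BB00"
        other = dataclasses.replace(ideal_step, ntc="BB07")
        with pytest.raises(ValueError):
            build_block("BB00", "GC", [(ideal_step, []), (other, [])],
                        params=assoc_params)

    def test_water_count_conservation(self, small_corpus, ideal_step,
                                      bb00_classifier, assoc_params):
        from watblocks.fragments import assign_ntc, extract_steps
        hydrated = []
        for m in small_corpus.models:
            step = extract_steps(list(m.chains["A"]), structure_id=m.structure_id)[0]
            step.ntc = assign_ntc(step, bb00_classifier, "nearest-centroid")
            hydrated.append((step, associate_waters(step, m.waters, assoc_params)))
        block = build_block("BB00", "GC", hydrated, reference=ideal_step,
                            params=assoc_params)
        assert block.n_waters == sum(len(a) for _, a in hydrated)


class TestBlockLibraryPersistence:
    def test_round_trip(self, tmp_path, ideal_step, small_corpus,
                        bb00_classifier, assoc_params):
        from watblocks.fragments import assign_ntc, extract_steps
        hydrated = []
        for m in small_corpus.models[:10]:
            step = extract_steps(list(m.chains["A"]), structure_id=m.structure_id)[0]
            step.ntc = assign_ntc(step, bb00_classifier, "nearest-centroid")
            hydrated.append((step, associate_waters(step, m.waters, assoc_params)))
        block = build_block("BB00", "GC", hydrated, reference=ideal_step,
                            params=assoc_params)
        lib = BlockLibrary(params=assoc_params)
        lib.add(block)
        lib.save(tmp_path / "lib")
        back = BlockLibrary.load(tmp_path / "lib")
        b2 = back.get("BB00", "GC")
        assert b2.n_steps == block.n_steps
        assert b2.n_waters == block.n_waters
        got = np.sort(np.stack([w.position for w in b2.waters]), axis=0)
        want = np.sort(np.stack([w.position for w in block.waters]), axis=0)
        np.testing.assert_allclose(got, want, atol=1e-5)
        for label, xyz in block.reference.items():
            np.testing.assert_allclose(b2.reference[label], xyz, atol=2e-3)

    def test_malformed_manifest_rejected(self, tmp_path):
        d = tmp_path / "lib"
        d.mkdir()
        (d / "manifest.json").write_text("{not json")
        with pytest.raises(ValueError):
            BlockLibrary.load(d)

    def test_missing_manifest_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            BlockLibrary.load(tmp_path)
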