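"""Block overlay, whole-structure prediction and evaluation."""

import dataclasses

import numpy as np
import pytest

from watblocks.app import RunConfig, build_library
from watblocks.blocks import AssociatedWater, BlockLibrary, HydratedBlock
from watblocks.density import HydrationSite
from watblocks.fragments import ClassifierTable, extract_steps
from watblocks.predict import (EvaluationReport, PredictionResult,
                               evaluate_prediction, overlay_block,
                               predict_hydration)
from watblocks.structure_io import AtomRecord, Residue, StructureModel

from conftest import random_rotation


def _w(pos, weight=1.0, near_base=True, near_backbone=False):
    return AssociatedWater(position=np.asarray(pos, float), source_id="w",
                           near_base=near_base, near_backbone=near_backbone,
                           nearest_distance=2.0, weight=weight)


def _water_atom(pos, num=200):
    return AtomRecord(atom_name="O", element="O", residue_name="HOH",
                      chain_id="A", residue_number=num, insertion_code="",
                      position=np.asarray(pos, float), occupancy=1.0,
                      b_factor=20.0, is_water=True)


def _block_from(ideal_step, waters, n_steps):
    step = dataclasses.replace(ideal_step, ntc="BB00")
    return HydratedBlock(ntc="BB00", seq2=step.seq2,
                         reference=step.labeled_coords(), waters=waters,
                         n_steps=n_steps, min_waters_reliable=1)


def _target_from_step(step, R=None, t=None, waters=()):
    R = np.eye(3) if R is None else R
    t = np.zeros(3) if t is None else t
    residues = []
    for res in (step.first, step.second):
        atoms = [dataclasses.replace(a, position=R @ a.position + t)
                 for a in res.atoms]
        residues.append(Residue(name=res.residue_name, chain_id="A",
                                number=res.number, insertion_code="", atoms=atoms))
    return StructureModel(structure_id="target", resolution=1.0,
                          chains={"A": residues}, waters=list(waters),
                          cell=None, spacegroup_ops=None)


class TestOverlayBlock:
    def test_identity_target_reproduces_cloud(self, ideal_step):
        waters = [_w(ideal_step.heavy_coords().mean(axis=0) + v)
                  for v in ([2.0, 0, 0], [0, 2.5, 0])]
        block = _block_from(ideal_step, waters, n_steps=1)
        target = dataclasses.replace(ideal_step, ntc="BB00")
        out = overlay_block(block, target)
        for w_in, w_out in zip(waters, out):
            np.testing.assert_allclose(w_out.position, w_in.position, atol=1e-9)

    def test_weights_scaled_inversely_to_population(self, ideal_step):
        waters = [_w(ideal_step.heavy_coords().mean(axis=0))] * 3
        block = _block_from(ideal_step, waters, n_steps=50)
        out = overlay_block(block, dataclasses.replace(ideal_step, ntc="BB00"))
        assert all(w.weight == pytest.approx(0.02) for w in out)

    def test_rotated_target_gives_rotated_cloud(self, ideal_step):
        rng = np.random.default_rng(0)
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        w0 = ideal_step.heavy_coords().mean(axis=0) + np.array([2.0, 1.0, 0.5])
        block = _block_from(ideal_step, [_w(w0)], n_steps=1)

        def move(res):
            atoms = [dataclasses.replace(a, position=R @ a.position + t)
                     for a in res.atoms]
            return dataclasses.replace(res, atoms=atoms)

        target = dataclasses.replace(ideal_step, ntc="BB00",
                                     first=move(ideal_step.first),
                                     second=move(ideal_step.second))
        out = overlay_block(block, target)
        np.testing.assert_allclose(out[0].position, R @ w0 + t, atol=1e-6)

    def test_mismatched_combination_rejected(self, ideal_step):
        block = _block_from(ideal_step, [], n_steps=1)
        target = dataclasses.replace(ideal_step, ntc="BB07")
        with pytest.raises(ValueError):
            overlay_block(block, target)


@pytest.fixture(scope="module")
def gc_library(small_corpus, bb00_classifier):
    from watblocks.synthetic import make_ideal_step
    ref = make_ideal_step("GC", "B")
    cfg = RunConfig(classifier_mode="nearest-centroid")
    cfg.association.min_waters_reliable = 20
    lib, _ = build_library(small_corpus.models, bb00_classifier, cfg,
                           references={("BB00", "GC"): ref})
    return lib


class TestPredictHydration:
    def test_identity_target_recovers_block_sites(self, ideal_step, gc_library,
                                                  bb00_classifier, planted_sites):
        cfg = RunConfig(classifier_mode="nearest-centroid")
        target = _target_from_step(ideal_step)
        result = predict_hydration(target, gc_library, bb00_classifier,
                                   "nearest-centroid",
                                   density_params=cfg.density,
                                   assoc_params=cfg.association,
                                   allow_unreliable=True)
        planted = np.array([s.offset for s in planted_sites])
        assert len(result.sites) == len(planted_sites)
        for s in result.sites:
            assert np.linalg.norm(planted - s.position, axis=1).min() < 0.5

    def test_rigid_motion_equivariance(self, ideal_step, gc_library, bb00_classifier):
        rng = np.random.default_rng(21)
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        cfg = RunConfig(classifier_mode="nearest-centroid")
        r0 = predict_hydration(_target_from_step(ideal_step), gc_library,
                               bb00_classifier, "nearest-centroid",
                               density_params=cfg.density,
                               assoc_params=cfg.association, allow_unreliable=True)
        r1 = predict_hydration(_target_from_step(ideal_step, R, t), gc_library,
                               bb00_classifier, "nearest-centroid",
                               density_params=cfg.density,
                               assoc_params=cfg.association, allow_unreliable=True)
        assert len(r0.sites) == len(r1.sites)
        got = np.stack([s.position for s in r1.sites])
        for s in r0.sites:
            moved = R @ s.position + t
            assert np.linalg.norm(got - moved, axis=1).min() <= cfg.density.spacing

    def test_weight_conservation(self, ideal_step, gc_library, bb00_classifier):
        cfg = RunConfig(classifier_mode="nearest-centroid")
        result = predict_hydration(_target_from_step(ideal_step), gc_library,
                                   bb00_classifier, "nearest-centroid",
                                   density_params=cfg.density,
                                   assoc_params=cfg.association,
                                   allow_unreliable=True)
        block = gc_library.get("BB00", "GC")
        assert result.total_weight == block.n_waters / block.n_steps

    def test_all_nant_steps_are_skipped_with_log(self, ideal_step, gc_library):
        empty_classifier = ClassifierTable()  # lookup with no assignments -> NANT
        target = _target_from_step(ideal_step)
        result = predict_hydration(target, gc_library, empty_classifier, "lookup")
        assert result.sites == []
        assert len(result.per_step_log) == 1
        assert not result.per_step_log[0].used
        assert "NANT" in result.per_step_log[0].reason

    def test_unreliable_block_skipped_by_default(self, ideal_step, gc_library,
                                                 bb00_classifier):
        cfg = RunConfig(classifier_mode="nearest-centroid")
        lib = BlockLibrary(params=gc_library.params)
        block = gc_library.get("BB00", "GC")
        lib.add(HydratedBlock(ntc="BB00", seq2="GC", reference=block.reference,
                              waters=block.waters, n_steps=block.n_steps,
                              min_waters_reliable=10 ** 6))
        result = predict_hydration(_target_from_step(ideal_step), lib,
                                   bb00_classifier, "nearest-centroid",
                                   density_params=cfg.density,
                                   assoc_params=cfg.association)
        assert result.sites == []
        assert "unreliable" in result.per_step_log[0].reason

    def test_empty_library_rejected(self, ideal_step, bb00_classifier):
        with pytest.raises(ValueError):
            predict_hydration(_target_from_step(ideal_step), BlockLibrary(),
                              bb00_classifier, "nearest-centroid")


def _result_with_sites(positions, categories):
    base = [HydrationSite(position=np.asarray(p, float), peak_value=1.0,
                          occupancy=0.5, category=c, n_support=1)
            for p, c in zip(positions, categories) if c == "base"]
    backbone = [HydrationSite(position=np.asarray(p, float), peak_value=1.0,
                              occupancy=0.5, category=c, n_support=1)
                for p, c in zip(positions, categories) if c == "backbone"]
    return PredictionResult(target_id="t", base_grid=None, backbone_grid=None,
                            base_sites=base, backbone_sites=backbone,
                            per_step_log=[])


class TestEvaluatePrediction:
    def test_coincident_site_in_first_bin(self):
        result = _result_with_sites([[0, 0, 0]], ["base"])
        report = evaluate_prediction(result, [_water_atom([0, 0, 0])])
        assert report.histogram["overall"][0] == 1
        assert report.frac_within_1A["overall"] == 1.0

    def test_seven_tenths_angstrom_in_second_bin(self):
        result = _result_with_sites([[0.7, 0, 0]], ["base"])
        report = evaluate_prediction(result, [_water_atom([0, 0, 0])])
        assert report.histogram["overall"][0] == 0
        assert report.histogram["overall"][1] == 1
        assert report.frac_within_1A["overall"] == 1.0

    def test_symmetry_mate_can_be_the_nearest_water(self):
        result = _result_with_sites([[0, 0, 0]], ["base"])
        asu = _water_atom([2.0, 0, 0], 201)
        mate = dataclasses.replace(_water_atom([0.8, 0, 0], 202),
                                   sym_op=1, sym_shift=(0, 0, 0))
        report = evaluate_prediction(result, [asu, mate])
        assert report.distances["overall"][0] == pytest.approx(0.8)

    def test_histogram_conserves_counts_and_ignores_order(self):
        rng = np.random.default_rng(30)
        positions = rng.uniform(0, 5, (12, 3))
        cats = ["base" if i % 2 else "backbone" for i in range(12)]
        waters = [_water_atom(rng.uniform(0, 5, 3), 300 + i) for i in range(6)]
        r1 = _result_with_sites(positions, cats)
        r2 = _result_with_sites(positions[::-1], cats[::-1])
        rep1 = evaluate_prediction(r1, waters)
        rep2 = evaluate_prediction(r2, waters)
        assert rep1.histogram["overall"].sum() == 12
        np.testing.assert_array_equal(rep1.histogram["overall"],
                                      rep2.histogram["overall"])
        total = rep1.histogram["base"].sum() + rep1.histogram["backbone"].sum()
        assert total == 12

    def test_no_observed_waters_rejected(self):
        result = _result_with_sites([[0, 0, 0]], ["base"])
        with pytest.raises(ValueError):
            evaluate_prediction(result, [])

    def test_fraction_matches_first_two_bins(self):
        positions = [[0.1, 0, 0], [0.7, 0, 0], [1.7, 0, 0], [3.0, 0, 0]]
        result = _result_with_sites(positions, ["base"] * 4)
        report = evaluate_prediction(result, [_water_atom([0, 0, 0])])
        h = report.histogram["overall"]
        assert report.frac_within_1A["overall"] == pytest.approx((h[0] + h[1]) / 4)
        assert report.frac_within_1A["overall"] == pytest.approx(0.5)
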