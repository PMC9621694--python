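"""The composite loss family: analytic values, oracle comparisons,
and distribution-space invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_distribution
from motifscaffold.contigs import parse_contigs, sample_placement
from motifscaffold.geometry import (
    BackboneStructure,
    kabsch_superpose,
    make_fixture,
    sixd_features,
)
from motifscaffold.losses import (
    CertaintyLoss,
    LossConfig,
    LossContext,
    MeanPAE,
    MotifCoordRMSD,
    MotifDistogramCE,
    RepulsionLoss,
    RogLoss,
    composite_loss,
    certainty_loss,
    motif_coord_rmsd,
    rog_loss,
)
from motifscaffold.predictor import (
    PlantedLandscape,
    sequence_to_distribution,
    toy_predict,
)


def ctx_for(world, contig="12,A13-18,12"):
    placement = sample_placement(parse_contigs(contig), seed=0)
    motif = world.structure.subset(placement.motif_positions)
    return LossContext(placement=placement, motif_geom=sixd_features(motif),
                       native_motif=motif), placement, motif


class TestMotifDistogramCE:
    def test_correct_one_hot_is_epsilon_level(self, world30):
        ctx, _, _ = ctx_for(world30)
        pred = toy_predict(sequence_to_distribution(world30.target_sequence),
                           world30)
        loss = MotifDistogramCE().evaluate(pred, ctx)
        assert 0.0 <= loss < 1e-7

    def test_uniform_prediction_gives_ln_B_per_channel(self, world30):
        ctx, _, _ = ctx_for(world30)
        # a sequence matching s* nowhere gives c = 0 -> exactly uniform Q
        wrong = "".join("W" if a != "W" else "Y"
                        for a in world30.target_sequence)
        pred = toy_predict(sequence_to_distribution(wrong), world30)
        for ch in ("distance", "omega", "theta", "phi"):
            B = world30.bins.n_states(ch)
            loss = MotifDistogramCE(channel_weights={ch: 1.0}).evaluate(pred, ctx)
            assert loss == pytest.approx(np.log(B), rel=1e-6)

    def test_target_beats_uniform_on_seeded_worlds(self):
        for seed in (0, 1, 2):
            world = PlantedLandscape.from_fixture("helix", 30, seed=seed)
            ctx, _, _ = ctx_for(world)
            at_target = MotifDistogramCE().evaluate(
                toy_predict(sequence_to_distribution(world.target_sequence),
                            world), ctx)
            at_uniform = MotifDistogramCE().evaluate(
                toy_predict(np.full((30, 20), 0.05), world), ctx)
            assert at_target < at_uniform

    def test_empty_motif_errors(self, world30):
        pred = toy_predict(np.full((30, 20), 0.05), world30)
        with pytest.raises(ValueError):
            MotifDistogramCE().evaluate(pred, LossContext())

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegative_on_random_predictions(self, world30, seed):
        ctx, _, _ = ctx_for(world30)
        pred = toy_predict(random_distribution(30, seed), world30)
        assert MotifDistogramCE().evaluate(pred, ctx) >= 0.0


class TestMotifCoordRMSD:
    def test_embedded_unchanged_motif_is_zero(self, world30):
        ctx, placement, motif = ctx_for(world30)
        pred = toy_predict(np.full((30, 20), 0.05), world30)
        assert MotifCoordRMSD().evaluate(pred, ctx) == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_rigid_rotation_is_zero(self, world30):
        _, placement, motif = ctx_for(world30)
        from motifscaffold.geometry import _rotation_about
        R = _rotation_about(np.array([0.0, 0.0, 1.0]), 33.0)
        moved = world30.structure.transformed(R, np.array([1.0, -2.0, 0.5]))
        assert motif_coord_rmsd(moved, motif, placement) < 1e-9

    def test_gaussian_perturbation_matches_direct_oracle(self, world30):
        import dataclasses
        _, placement, motif = ctx_for(world30)
        rng = np.random.default_rng(0)
        s = world30.structure
        noisy = dataclasses.replace(
            s, n=s.n + rng.normal(scale=0.5, size=s.n.shape),
            ca=s.ca + rng.normal(scale=0.5, size=s.ca.shape),
            c=s.c + rng.normal(scale=0.5, size=s.c.shape), cb=None)
        value = motif_coord_rmsd(noisy, motif, placement)
        # independent two-step oracle: explicit Kabsch + direct formula
        pred_pts = noisy.subset(placement.motif_positions).backbone_coords()
        nat_pts = motif.backbone_coords()
        fit = kabsch_superpose(pred_pts, nat_pts)
        moved = pred_pts @ fit.rotation.T + fit.translation
        expected = np.sqrt(((moved - nat_pts) ** 2).sum(axis=1).mean())
        assert value == pytest.approx(expected, rel=1e-9)

    def test_too_small_motif_errors(self, world30):
        placement = sample_placement(parse_contigs("14,A15-16,14"), seed=0)
        motif = world30.structure.subset(placement.motif_positions)
        ctx = LossContext(placement=placement, native_motif=motif)
        pred = toy_predict(np.full((30, 20), 0.05), world30)
        with pytest.raises(ValueError):
            MotifCoordRMSD().evaluate(pred, ctx)


class TestCertainty:
    def test_uniform_entropy_is_ln_B(self, world30):
        wrong = "".join("W" if a != "W" else "Y"
                        for a in world30.target_sequence)
        pred = toy_predict(sequence_to_distribution(wrong), world30)
        for ch in ("distance", "omega", "theta", "phi"):
            B = world30.bins.n_states(ch)
            val = CertaintyLoss(channel_weights={ch: 1.0}).evaluate(
                pred, LossContext())
            assert val == pytest.approx(np.log(B), rel=1e-9)

    def test_one_hot_entropy_zero_and_kl_ln_B(self, world30):
        pred = toy_predict(sequence_to_distribution(world30.target_sequence),
                           world30)
        assert certainty_loss(pred) == pytest.approx(0.0, abs=1e-9)
        for ch in ("distance", "phi"):
            B = world30.bins.n_states(ch)
            kl = CertaintyLoss(mode="kl_background",
                               channel_weights={ch: 1.0}).evaluate(
                pred, LossContext())
            # loss is negative KL; KL(one-hot || uniform) = ln B
            assert kl == pytest.approx(-np.log(B), rel=1e-9)

    def test_entropy_strictly_decreasing_in_mixture_weight(self, world30):
        values = []
        for lam in np.linspace(0, 1, 11):
            P = (1 - lam) * np.full((30, 20), 0.05) + \
                lam * sequence_to_distribution(world30.target_sequence)
            pred = toy_predict(P, world30)
            values.append(certainty_loss(pred))
        assert np.all(np.diff(values) < 0)

    def test_interchain_selection(self, world16_two_chain):
        P = random_distribution(16, 0)
        pred = toy_predict(P, world16_two_chain)
        val = CertaintyLoss(pairs="interchain").evaluate(pred, LossContext())
        # manual: entropy averaged over the two off-diagonal blocks
        b = pred.chain_boundary
        mask = np.zeros((16, 16), dtype=bool)
        mask[:b, b:] = True
        mask[b:, :b] = True
        manual = 0.0
        for ch, arr in pred.geometry.channels.items():
            Q = arr[mask]
            H = -(Q * np.log(np.where(Q > 0, Q, 1))).sum(axis=1)
            manual += H.mean() / 4
        assert val == pytest.approx(manual, rel=1e-12)

    def test_empty_mask_errors(self, world30):
        pred = toy_predict(np.full((30, 20), 0.05), world30)
        with pytest.raises(ValueError):
            CertaintyLoss(explicit_mask=np.zeros((30, 30), bool)).evaluate(
                pred, LossContext())

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_entropy_bounds_random_distributions(self, world30, seed):
        pred = toy_predict(random_distribution(30, seed), world30)
        for ch in ("distance", "omega", "theta", "phi"):
            B = world30.bins.n_states(ch)
            val = CertaintyLoss(channel_weights={ch: 1.0}).evaluate(
                pred, LossContext())
            assert -1e-12 <= val <= np.log(B) + 1e-12
            kl = -CertaintyLoss(mode="kl_background",
                                channel_weights={ch: 1.0}).evaluate(
                pred, LossContext())
            assert kl >= -1e-12  # Gibbs


class TestRepulsion:
    def test_zero_when_no_contact_mass(self, world16_two_chain):
        world = world16_two_chain
        pred = toy_predict(
            sequence_to_distribution(world.target_sequence), world)
        # force every pair fully into the no-contact state
        arr = pred.geometry.channels["distance"]
        arr[:] = 0.0
        arr[:, :, -1] = 1.0
        assert RepulsionLoss().evaluate(pred, LossContext()) == 0.0

    def test_all_disallowed_in_contact_is_one(self, world16_two_chain):
        world = world16_two_chain
        pred = toy_predict(np.full((16, 20), 0.05), world)
        arr = pred.geometry.channels["distance"]
        arr[:] = 0.0
        arr[:, :, 0] = 1.0  # every pair fully in the first (2.0-2.5 A) bin
        assert RepulsionLoss().evaluate(pred, LossContext()) == 1.0

    def test_brute_force_enumeration_with_allowed_pairs(self, world16_two_chain):
        world = world16_two_chain
        pred = toy_predict(sequence_to_distribution(world.target_sequence),
                           world)
        b = pred.chain_boundary
        k = int(np.sum(world.bins.edges("distance")[1:] <= 8.0))
        # planted interface contacts
        contacts = [(i, j) for i in range(b) for j in range(b, 16)
                    if world.planted_bins["distance"][i, j] < k]
        assert len(contacts) >= 3
        allowed = frozenset(contacts[:2]) | frozenset(
            (j, i) for (i, j) in contacts[:2])
        loss = RepulsionLoss(allowed_pairs=allowed).evaluate(pred, LossContext())
        # brute force: enumerate every ordered cross-chain pair
        total, count = 0.0, 0
        for i in range(16):
            for j in range(16):
                cross = (i < b) != (j < b)
                if not cross or (i, j) in allowed:
                    continue
                total += pred.geometry.channels["distance"][i, j, :k].sum()
                count += 1
        assert loss == pytest.approx(total / count, rel=1e-12)

    def test_single_chain_errors(self, world30):
        pred = toy_predict(np.full((30, 20), 0.05), world30)
        with pytest.raises(ValueError):
            RepulsionLoss().evaluate(pred, LossContext())


class TestRog:
    def test_single_residue_zero(self):
        fix = make_fixture("helix", 1, seed=0)
        assert rog_loss(fix, rg_max=0.0) == 0.0

    def test_compact_helix_generous_rgmax(self):
        fix = make_fixture("helix", 20, seed=0)
        assert rog_loss(fix, rg_max=50.0) == 0.0

    def test_square_hand_computation(self):
        # four CA atoms at corners of a 2 A square: Rg = sqrt(2), loss = 2
        ca = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], float)
        square = BackboneStructure(
            chain_ids=np.array(["A"] * 4),
            residue_numbers=np.arange(1, 5),
            sequence="AAAA",
            n=ca + np.array([0.0, 0.0, 1.0]), ca=ca,
            c=ca + np.array([1.0, 0.0, 0.0]))
        assert rog_loss(square, rg_max=0.0) == pytest.approx(2.0, rel=1e-12)


class TestComposite:
    def test_zero_weights_populate_breakdown(self, world30):
        ctx, _, _ = ctx_for(world30)
        pred = toy_predict(np.full((30, 20), 0.05), world30)
        config = LossConfig([(CertaintyLoss(), 0.0), (MotifDistogramCE(), 0.0)])
        total, breakdown = composite_loss(pred, config, ctx)
        assert total == 0.0
        assert set(breakdown) == {"certainty", "motif_distogram_ce"}
        assert breakdown["certainty"]["value"] > 0

    def test_single_term_identity(self, world30):
        pred = toy_predict(np.full((30, 20), 0.05), world30)
        config = LossConfig([(CertaintyLoss(), 1.0)])
        total, breakdown = composite_loss(pred, config, LossContext())
        assert total == pytest.approx(certainty_loss(pred))
        assert breakdown["certainty"]["weighted"] == total

    def test_weighted_sum_matches_independent_summation(self, world30):
        ctx, _, _ = ctx_for(world30)
        pred = toy_predict(random_distribution(30, 5), world30)
        t1 = CertaintyLoss().evaluate(pred, ctx)
        t2 = MotifDistogramCE().evaluate(pred, ctx)
        config = LossConfig([(CertaintyLoss(), 2.0), (MotifDistogramCE(), 0.5)])
        total, _ = composite_loss(pred, config, ctx)
        assert total == pytest.approx(2.0 * t1 + 0.5 * t2, rel=1e-12)

    def test_config_yaml_roundtrip(self):
        text = """
- name: certainty
  weight: 1.5
  params: {mode: entropy, pairs: all}
- name: rog
  weight: 0.25
  params: {rg_max: 12.0}
"""
        config = LossConfig.from_yaml(text)
        assert len(config.terms) == 2
        assert config.terms[0][1] == 1.5
        d = config.to_dict()
        again = LossConfig.from_dict(d)
        assert again.to_dict() == d

    def test_missing_context_errors(self, world30):
        pred = toy_predict(np.full((30, 20), 0.05), world30)
        config = LossConfig([(MotifDistogramCE(), 1.0)])
        with pytest.raises(ValueError):
            composite_loss(pred, config, LossContext())
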