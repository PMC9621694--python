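"""Sequence-space optimizers: Metropolis criterion, annealing, gradient
descent on logits, staged protocols, and trajectory contracts."""

import math

import numpy as np
import pytest

from motifscaffold.contigs import parse_contigs, sample_placement
from motifscaffold.geometry import sixd_features
from motifscaffold.losses import (
    CertaintyLoss,
    LossConfig,
    LossContext,
    MeanPAE,
    MotifDistogramCE,
)
from motifscaffold.optimize import (
    AnnealSchedule,
    Stage,
    gradient_design,
    mcmc_design,
    metropolis_accept,
    staged_protocol,
)
from motifscaffold.predictor import ToyPredictor


@pytest.fixture(scope="module")
def setup30(world30, placement30):
    predictor = ToyPredictor(world30)
    motif_seq = "".join(world30.target_sequence[p]
                        for p in placement30.motif_positions)
    motif = world30.structure.subset(placement30.motif_positions)
    ctx = LossContext(placement=placement30, motif_geom=sixd_features(motif),
                      native_motif=motif)
    return predictor, motif_seq, ctx


def nonmotif_recovery(sequence, world, placement):
    idx = np.flatnonzero(~placement.motif_mask)
    return np.mean([sequence[i] == world.target_sequence[i] for i in idx])


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-1.0, t, rng)
                   for t in (1e-6, 1.0, 100.0))

    def test_uphill_vanishes_as_T_to_zero(self):
        rng = np.random.default_rng(0)
        accepts = sum(metropolis_accept(1.0, 1e-12, rng) for _ in range(1000))
        assert accepts == 0

    def test_acceptance_fraction_matches_closed_form(self):
        rng = np.random.default_rng(12345)
        n = 10_000
        frac = sum(metropolis_accept(1.0, 1.0, rng) for _ in range(n)) / n
        p = math.exp(-1.0)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_nonpositive_temperature_errors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)

    def test_schedule_geometric(self):
        s = AnnealSchedule(steps=100, t0=1.0, tf=0.01)
        assert s.temperature(0) == pytest.approx(1.0)
        assert s.temperature(100) == pytest.approx(0.01)
        assert s.temperature(50) == pytest.approx(0.1)
        with pytest.raises(ValueError):
            AnnealSchedule(steps=10, t0=0.01, tf=1.0)


class TestMcmc:
    def test_zero_steps_returns_init_only(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(CertaintyLoss(), 1.0)])
        traj = mcmc_design(predictor, config, placement30,
                           motif_sequence=motif_seq, steps=0, seed=0, ctx=ctx)
        assert len(traj.records) == 1
        assert traj.best_sequence == traj.records[0].sequence

    def test_final_phase_is_effectively_greedy(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(CertaintyLoss(), 1.0)])
        traj = mcmc_design(predictor, config, placement30,
                           motif_sequence=motif_seq, steps=400, seed=1,
                           ctx=ctx)
        # in the last tenth of the schedule no uphill move is accepted
        tail = traj.records[-40:]
        for prev, rec in zip(tail, tail[1:]):
            if rec.accepted:
                assert rec.total <= prev.total + 1e-9

    def test_bit_identical_under_same_seed(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(CertaintyLoss(), 1.0)])
        a = mcmc_design(predictor, config, placement30,
                        motif_sequence=motif_seq, steps=150, seed=7, ctx=ctx)
        b = mcmc_design(predictor, config, placement30,
                        motif_sequence=motif_seq, steps=150, seed=7, ctx=ctx)
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]
        assert [r.total for r in a.records] == [r.total for r in b.records]
        assert [r.accepted for r in a.records] == [r.accepted for r in b.records]

    def test_motif_positions_never_mutate(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(CertaintyLoss(), 1.0)])
        traj = mcmc_design(predictor, config, placement30,
                           motif_sequence=motif_seq, steps=300, seed=3,
                           ctx=ctx)
        pos = placement30.motif_positions
        for rec in traj.records:
            assert "".join(rec.sequence[p] for p in pos) == motif_seq

    def test_best_so_far_non_increasing(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(CertaintyLoss(), 1.0)])
        traj = mcmc_design(predictor, config, placement30,
                           motif_sequence=motif_seq, steps=300, seed=5,
                           ctx=ctx)
        series = traj.best_so_far_series()
        assert np.all(np.diff(series) <= 1e-12)
        assert traj.best_total == series[-1]

    def test_no_mutable_positions_errors(self, world30):
        placement = sample_placement(parse_contigs("0,A1-30,0"), seed=0)
        predictor = ToyPredictor(world30)
        config = LossConfig([(CertaintyLoss(), 1.0)])
        with pytest.raises(ValueError):
            mcmc_design(predictor, config, placement,
                        motif_sequence=world30.target_sequence, steps=10,
                        seed=0)

    def test_default_alphabet_excludes_cysteine(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(CertaintyLoss(), 1.0)])
        traj = mcmc_design(predictor, config, placement30,
                           motif_sequence=motif_seq, steps=200, seed=11,
                           ctx=ctx)
        for rec in traj.records:
            assert "C" not in rec.sequence


class TestGradient:
    def test_zero_learning_rate_is_identity(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(MeanPAE(), 1.0)])
        traj = gradient_design(predictor, config, placement30,
                               motif_sequence=motif_seq, steps=20,
                               learning_rate=0.0, seed=0, ctx=ctx)
        assert traj.records[0].sequence == traj.records[-1].sequence
        assert traj.records[0].total == pytest.approx(traj.records[-1].total)

    def test_zero_steps_returns_init(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(MeanPAE(), 1.0)])
        traj = gradient_design(predictor, config, placement30,
                               motif_sequence=motif_seq, steps=0, seed=0,
                               ctx=ctx)
        assert len(traj.records) == 1

    def test_bit_identical_under_same_seed(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(MeanPAE(), 1.0)])
        a = gradient_design(predictor, config, placement30,
                            motif_sequence=motif_seq, steps=30, seed=4,
                            ctx=ctx)
        b = gradient_design(predictor, config, placement30,
                            motif_sequence=motif_seq, steps=30, seed=4,
                            ctx=ctx)
        assert [r.total for r in a.records] == [r.total for r in b.records]
        assert a.best_sequence == b.best_sequence

    def test_motif_rows_clamped(self, setup30, placement30, world30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(MeanPAE(), 1.0)])
        traj = gradient_design(predictor, config, placement30,
                               motif_sequence=motif_seq, steps=50,
                               learning_rate=1.0, seed=0, ctx=ctx)
        pos = placement30.motif_positions
        for rec in traj.records:
            assert "".join(rec.sequence[p] for p in pos) == motif_seq

    def test_requires_gradient_capability(self, placement30):
        class NoGrad:
            def predict(self, P):  # pragma: no cover - never reached
                raise AssertionError
        config = LossConfig([(MeanPAE(), 1.0)])
        with pytest.raises(TypeError):
            gradient_design(NoGrad(), config, placement30, steps=1)


class TestStaged:
    def test_single_stage_equals_direct_call(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(CertaintyLoss(), 1.0)])
        record, trajs = staged_protocol(
            [Stage("mcmc", config, 100)], predictor, placement30,
            motif_sequence=motif_seq, seed=9, ctx=ctx)
        direct = mcmc_design(predictor, config, placement30,
                             motif_sequence=motif_seq, steps=100, seed=9,
                             ctx=ctx)
        assert [r.sequence for r in trajs[0].records] == \
            [r.sequence for r in direct.records]
        assert record.sequence == direct.best_sequence

    def test_handoff_contract(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(CertaintyLoss(), 1.0)])
        _, trajs = staged_protocol(
            [Stage("mcmc", config, 120), Stage("mcmc", config, 120)],
            predictor, placement30, motif_sequence=motif_seq, seed=2, ctx=ctx)
        assert trajs[1].records[0].sequence == trajs[0].best_sequence

    def test_two_stage_loss_composition(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        stage1 = LossConfig([(CertaintyLoss(), 1.0)])
        stage2 = LossConfig([(CertaintyLoss(), 1.0), (MotifDistogramCE(), 1.0)])
        record, trajs = staged_protocol(
            [Stage("mcmc", stage1, 200), Stage("mcmc", stage2, 200)],
            predictor, placement30, motif_sequence=motif_seq, seed=0, ctx=ctx)
        assert set(record.loss_breakdown) == {"certainty", "motif_distogram_ce"}
        ce_initial = trajs[1].records[0].breakdown["motif_distogram_ce"]["value"]
        ce_best = record.loss_breakdown["motif_distogram_ce"]["value"]
        assert ce_best <= ce_initial + 1e-12

    def test_mcmc_to_gradient_lifting(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        record, trajs = staged_protocol(
            [Stage("mcmc", LossConfig([(CertaintyLoss(), 1.0)]), 100),
             Stage("gradient", LossConfig([(MeanPAE(), 1.0)]), 30,
                   params={"learning_rate": 1.0})],
            predictor, placement30, motif_sequence=motif_seq, seed=1, ctx=ctx)
        assert len(trajs) == 2
        assert record.provenance["stages"][1]["optimizer"] == "gradient"
        series = trajs[1].best_so_far_series()
        assert np.all(np.diff(series) <= 1e-12)

    def test_empty_stages_error(self, setup30, placement30):
        predictor, motif_seq, ctx = setup30
        with pytest.raises(ValueError):
            staged_protocol([], predictor, placement30)


class TestPlantedRecovery:
    """Desk-scale analogs of designs whose sequences strongly encode
    their structures: both optimizers must recover the planted sequence
    (thresholds fixed by an initial calibration run, enforced as
    regressions)."""

    def test_mcmc_recovers_planted_sequence_small(self, setup30, placement30,
                                                  world30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(CertaintyLoss(), 1.0)])
        fracs = []
        for seed in range(3):
            traj = mcmc_design(predictor, config, placement30,
                               motif_sequence=motif_seq, steps=3000,
                               seed=seed, ctx=ctx)
            fracs.append(nonmotif_recovery(traj.best_sequence, world30,
                                           placement30))
        assert np.mean(fracs) >= 0.9

    def test_gradient_recovers_planted_sequence_small(self, setup30,
                                                      placement30, world30):
        predictor, motif_seq, ctx = setup30
        config = LossConfig([(MeanPAE(), 1.0)])
        fracs = []
        for seed in range(2):
            traj = gradient_design(predictor, config, placement30,
                                   motif_sequence=motif_seq, steps=500,
                                   learning_rate=1.0, seed=seed, ctx=ctx)
            fracs.append(nonmotif_recovery(traj.best_sequence, world30,
                                           placement30))
        assert np.mean(fracs) >= 0.95
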