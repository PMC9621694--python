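"""Sequence-space optimizers for constrained hallucination.

Two optimizers over the composite loss: Metropolis simulated annealing on
hard sequences (single-position proposals, geometric cooling) and
steepest descent on per-position logits (soft sequences through a
row-wise softmax) for predictors exposing the gradient capability. A
staged runner chains heterogeneous stages, carrying the best design
forward, so stage-specific loss functions (e.g. certainty first, motif
reconstruction added later) compose without special cases.

Motif positions are frozen to the native motif letters end to end — the
functional site's sequence is part of its specification. The default
mutation alphabet excludes cysteine (common de novo design practice, to
avoid spurious disulfides); pass ``alphabet=`` to override. All
stochastic operations take an explicit seed; there is no global RNG
state, and identical seeds and configs give bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy.special import softmax

from .contigs import MotifPlacement
from .geometry import AA_ALPHABET, AA_INDEX
from .losses import LossConfig, LossContext, composite_loss
from .predictor import (
    distribution_to_sequence,
    sequence_to_distribution,
)
from .records import DesignRecord, config_hash

__all__ = [
    "AnnealSchedule",
    "StepRecord",
    "DesignTrajectory",
    "metropolis_accept",
    "mcmc_design",
    "gradient_design",
    "Stage",
    "staged_protocol",
    "DEFAULT_MUTATION_ALPHABET",
]

#: Design alphabet used for proposals: all canonical residues minus cysteine.
DEFAULT_MUTATION_ALPHABET = "".join(a for a in AA_ALPHABET if a != "C")


# ---------------------------------------------------------------------------
# Annealing schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling: T_k = T0 * (Tf/T0)^(k/K)."""

    steps: int
    t0: float
    tf: float

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if not (self.t0 >= self.tf > 0):
            raise ValueError("need T0 >= Tf > 0")

    def temperature(self, k: int) -> float:
        if self.steps == 0:
            return self.t0
        return self.t0 * (self.tf / self.t0) ** (k / self.steps)


def metropolis_accept(delta_loss: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion: downhill always accepted, uphill with
    probability exp(-delta/T). Requires T > 0."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_loss < 0:
        return True
    return bool(rng.random() < math.exp(-delta_loss / temperature))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    step: int
    sequence: str
    total: float
    breakdown: dict[str, dict[str, float]]
    accepted: bool


@dataclass
class DesignTrajectory:
    """Per-step history plus the best-so-far design.

    ``best_total`` is non-increasing over the run by construction; tests
    assert it on every trajectory they touch.
    """

    records: list[StepRecord] = field(default_factory=list)
    best_sequence: str = ""
    best_total: float = math.inf
    best_breakdown: dict[str, dict[str, float]] = field(default_factory=dict)
    best_logits: np.ndarray | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def log(self, rec: StepRecord, logits: np.ndarray | None = None) -> None:
        self.records.append(rec)
        if rec.total < self.best_total:
            self.best_total = rec.total
            self.best_sequence = rec.sequence
            self.best_breakdown = rec.breakdown
            if logits is not None:
                self.best_logits = logits.copy()

    def best_so_far_series(self) -> np.ndarray:
        """Running minimum of the per-step totals."""
        return np.minimum.accumulate([r.total for r in self.records])

    def loss_table(self) -> "list[dict[str, float]]":
        """Flat per-step rows (step, total, accepted, per-term values) for
        TSV logging."""
        rows = []
        for r in self.records:
            row: dict[str, Any] = {"step": r.step, "total": r.total,
                                   "accepted": int(r.accepted)}
            for name, d in r.breakdown.items():
                row[name] = d["value"]
            rows.append(row)
        return rows


# ---------------------------------------------------------------------------
# MCMC design
# ---------------------------------------------------------------------------

def _apply_motif(sequence: str, placement: MotifPlacement,
                 motif_sequence: str | None) -> str:
    if motif_sequence is None:
        return sequence
    pos = placement.motif_positions
    if len(motif_sequence) != len(pos):
        raise ValueError("motif sequence length does not match placement")
    chars = list(sequence)
    for p, aa in zip(pos, motif_sequence):
        chars[p] = aa
    return "".join(chars)


def _random_sequence(L: int, rng: np.random.Generator, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=L))


def _auto_schedule(predictor, config: LossConfig, ctx: LossContext,
                   sequence: str, mutable: np.ndarray, alphabet: str,
                   steps: int, rng: np.random.Generator,
                   n_probe: int = 24) -> AnnealSchedule:
    """Set the temperature scale from the loss-*change* scale.

    The absolute composite loss carries large state-independent offsets
    (e.g. the entropy of a near-uniform distogram), so the Metropolis
    temperature is calibrated against proposal deltas instead: T0 = 0.1 x
    mean |delta loss| over a short probe of random single mutations from
    the initial sequence, Tf = T0/100.
    """
    base_total, _ = composite_loss(predictor.predict(
        sequence_to_distribution(sequence)), config, ctx)
    deltas = []
    for _ in range(n_probe):
        pos = int(rng.choice(mutable))
        current = sequence[pos]
        options = [a for a in alphabet if a != current]
        aa = str(rng.choice(options))
        trial = sequence[:pos] + aa + sequence[pos + 1:]
        total, _ = composite_loss(predictor.predict(
            sequence_to_distribution(trial)), config, ctx)
        deltas.append(abs(total - base_total))
    scale = float(np.mean(deltas)) if deltas else 0.0
    if scale <= 0.0:
        scale = max(abs(base_total), 1.0) * 1e-6  # flat probe: near-greedy
    t0 = 0.1 * scale
    return AnnealSchedule(steps=steps, t0=t0, tf=t0 / 100.0)


def mcmc_design(
    predictor,
    config: LossConfig,
    placement: MotifPlacement,
    motif_sequence: str | None = None,
    init_sequence: str | None = None,
    schedule: AnnealSchedule | None = None,
    steps: int = 1000,
    seed: int = 0,
    ctx: LossContext | None = None,
    alphabet: str = DEFAULT_MUTATION_ALPHABET,
) -> DesignTrajectory:
    """Simulated-annealing design in sequence space.

    Proposals mutate a single non-motif position to a uniformly drawn
    letter of the (cysteine-free by default) alphabet; acceptance is
    Metropolis under geometric cooling. Motif positions hold the native
    motif letters (from ``motif_sequence``, or from ``init_sequence`` if
    not given) and are never proposed. The current state's prediction is
    cached so each proposal costs one predictor call. Deterministic under
    ``seed``; returns the full trajectory (step 0 is the initial state).
    """
    ctx = ctx or LossContext()
    rng = np.random.default_rng(seed)
    L = placement.total_length
    mutable = np.flatnonzero(~placement.motif_mask)
    if mutable.size == 0:
        raise ValueError("no mutable positions: the whole design is motif")

    if init_sequence is None:
        init_sequence = _random_sequence(L, rng, alphabet)
    if len(init_sequence) != L:
        raise ValueError("init sequence length does not match placement")
    sequence = _apply_motif(init_sequence, placement, motif_sequence)

    if schedule is None:
        schedule = _auto_schedule(predictor, config, ctx, sequence, mutable,
                                  alphabet, steps, rng)
    K = schedule.steps

    total, breakdown = composite_loss(
        predictor.predict(sequence_to_distribution(sequence)), config, ctx)
    traj = DesignTrajectory()
    traj.provenance = {
        "seed": seed, "schedule": {"steps": K, "t0": schedule.t0,
                                   "tf": schedule.tf},
        "alphabet": alphabet}
    traj.log(StepRecord(0, sequence, total, breakdown, True))

    for k in range(1, K + 1):
        pos = int(rng.choice(mutable))
        current = sequence[pos]
        options = [a for a in alphabet if a != current]
        aa = str(rng.choice(options))
        trial = sequence[:pos] + aa + sequence[pos + 1:]
        trial_total, trial_breakdown = composite_loss(
            predictor.predict(sequence_to_distribution(trial)), config, ctx)
        accepted = metropolis_accept(trial_total - total,
                                     schedule.temperature(k), rng)
        if accepted:
            sequence, total, breakdown = trial, trial_total, trial_breakdown
        traj.log(StepRecord(k, sequence, total, breakdown, accepted))
    return traj


# ---------------------------------------------------------------------------
# Gradient design
# ---------------------------------------------------------------------------

def _clamped_distribution(logits: np.ndarray, placement: MotifPlacement,
                          motif_onehot: np.ndarray | None) -> np.ndarray:
    P = softmax(logits, axis=1)
    if motif_onehot is not None:
        P[placement.motif_mask] = motif_onehot
    return P


def gradient_design(
    predictor,
    config: LossConfig,
    placement: MotifPlacement,
    motif_sequence: str | None = None,
    init_logits: np.ndarray | None = None,
    steps: int = 100,
    learning_rate: float | Callable[[int], float] = 1.0,
    seed: int = 0,
    ctx: LossContext | None = None,
) -> DesignTrajectory:
    """Steepest descent on sequence logits.

    The optimization variable is an L x 20 logit matrix; the predictor
    sees its row-wise softmax (softmax temperature fixed at 1). Motif
    rows are clamped to the one-hot native letters and receive no
    updates. Requires a predictor with the gradient capability
    (``loss_gradient``); the loss gradient with respect to logits follows
    from the softmax Jacobian. The recorded per-step sequence is the
    per-position argmax; the returned best design is the argmax of the
    best-scoring logits.
    """
    if not hasattr(predictor, "loss_gradient"):
        raise TypeError("predictor does not expose the gradient capability")
    ctx = ctx or LossContext()
    rng = np.random.default_rng(seed)
    L = placement.total_length
    if init_logits is None:
        init_logits = 0.01 * rng.standard_normal((L, len(AA_ALPHABET)))
    logits = np.array(init_logits, dtype=float, copy=True)
    if logits.shape != (L, len(AA_ALPHABET)):
        raise ValueError("init logits must be (L, 20)")

    motif_onehot = None
    if motif_sequence is not None:
        motif_onehot = sequence_to_distribution(motif_sequence)
        if motif_onehot.shape[0] != placement.n_motif:
            raise ValueError("motif sequence length does not match placement")

    lr_of = learning_rate if callable(learning_rate) else (lambda k: learning_rate)
    mutable = ~placement.motif_mask

    traj = DesignTrajectory()
    P = _clamped_distribution(logits, placement, motif_onehot)
    total, breakdown = composite_loss(predictor.predict(P), config, ctx)
    traj.log(StepRecord(0, distribution_to_sequence(P), total, breakdown, True),
             logits=logits)

    for k in range(1, steps + 1):
        g = predictor.loss_gradient(config, P, ctx)     # dL/dP
        inner = (g * P).sum(axis=1, keepdims=True)
        g_logits = P * (g - inner)                       # softmax Jacobian
        logits[mutable] -= lr_of(k) * g_logits[mutable]
        P = _clamped_distribution(logits, placement, motif_onehot)
        total, breakdown = composite_loss(predictor.predict(P), config, ctx)
        traj.log(StepRecord(k, distribution_to_sequence(P), total, breakdown,
                            True), logits=logits)
    return traj


# ---------------------------------------------------------------------------
# Staged protocol
# ---------------------------------------------------------------------------

@dataclass
class Stage:
    """One stage of a multi-stage design protocol."""

    optimizer: str                  # "mcmc" | "gradient"
    config: LossConfig
    steps: int
    params: dict[str, Any] = field(default_factory=dict)


#: Logit magnitude used to lift a hard sequence into soft logits when an
#: MCMC stage hands off to a gradient stage (softmax ~0.87 on the letter).
ONE_HOT_LOGIT = 3.0


def staged_protocol(
    stages: Sequence[Stage],
    predictor,
    placement: MotifPlacement,
    motif_sequence: str | None = None,
    init_sequence: str | None = None,
    seed: int = 0,
    ctx: LossContext | None = None,
    design_id: str = "design_0",
    contig: str = "",
) -> tuple[DesignRecord, list[DesignTrajectory]]:
    """Run stages in order, initializing each from the previous best.

    A hard sequence entering a gradient stage is lifted to one-hot logits
    (scaled by :data:`ONE_HOT_LOGIT`); a gradient stage's best argmax
    sequence seeds a following MCMC stage. Provenance records every
    stage's optimizer, step count and loss-config hash. Returns the final
    :class:`~motifscaffold.records.DesignRecord` and all stage
    trajectories.
    """
    if not stages:
        raise ValueError("staged protocol needs at least one stage")
    ctx = ctx or LossContext()
    trajectories: list[DesignTrajectory] = []
    carry_sequence = init_sequence
    carry_logits: np.ndarray | None = None
    stage_provenance = []

    for s_idx, stage in enumerate(stages):
        stage_seed = seed + s_idx
        if stage.optimizer == "mcmc":
            traj = mcmc_design(
                predictor, stage.config, placement,
                motif_sequence=motif_sequence,
                init_sequence=carry_sequence,
                steps=stage.steps, seed=stage_seed, ctx=ctx,
                **stage.params)
        elif stage.optimizer == "gradient":
            if carry_logits is None and carry_sequence is not None:
                carry_logits = ONE_HOT_LOGIT * sequence_to_distribution(
                    carry_sequence)
            traj = gradient_design(
                predictor, stage.config, placement,
                motif_sequence=motif_sequence,
                init_logits=carry_logits,
                steps=stage.steps, seed=stage_seed, ctx=ctx,
                **stage.params)
        else:
            raise ValueError(f"unknown optimizer {stage.optimizer!r}")
        trajectories.append(traj)
        carry_sequence = traj.best_sequence
        carry_logits = traj.best_logits
        stage_provenance.append({
            "optimizer": stage.optimizer,
            "steps": stage.steps,
            "loss_config": stage.config.to_dict(),
        })

    final = trajectories[-1]
    record = DesignRecord(
        design_id=design_id,
        contig=contig,
        placement=placement,
        sequence=final.best_sequence,
        loss_breakdown=final.best_breakdown,
        provenance={
            "seed": seed,
            "stages": stage_provenance,
            "config_hash": config_hash(stage_provenance),
        },
    )
    return record, trajectories
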