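"""The composite loss family for constrained hallucination.

Each loss term is a pure, deterministic function of a prediction (and
static context: motif placement, native motif geometry, pair masks) and is
*minimized* — lower is always better — so optimizer code stays uniform.
The composite loss combines a structure-certainty (hallucination) term
with a motif-reconstruction term and optional task-specific terms
(inter-chain certainty, repulsion against unwanted contacts, compactness).

Terms are duck-typed over any object with the ``PredictionResult`` fields
(``geometry``, ``coords``, ``plddt``, ``pae``, ``chain_boundary``); no
predictor import is needed here. For the closed-form planted-landscape
predictor every differentiable term additionally exposes
``toy_grad_c_a``, its analytic sensitivity with respect to that
predictor's pair-confidence field c and agreement field a — the hook
:func:`motifscaffold.predictor.toy_gradient` assembles into d(loss)/dP.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any, Iterable, Sequence

import numpy as np
import yaml

from .contigs import MotifPlacement
from .geometry import BackboneStructure, PairwiseGeometry, kabsch_superpose

__all__ = [
    "LossContext",
    "LossConfig",
    "NotDifferentiableError",
    "MotifDistogramCE",
    "MotifCoordRMSD",
    "CertaintyLoss",
    "RepulsionLoss",
    "RogLoss",
    "MeanPAE",
    "composite_loss",
    "motif_distogram_ce",
    "motif_coord_rmsd",
    "certainty_loss",
    "repulsion_loss",
    "rog_loss",
    "TERM_REGISTRY",
]

#: Cross-entropy floor: bounds the loss under an adversarial one-hot mismatch.
CE_EPS = 1e-8

CHANNELS = ("distance", "omega", "theta", "phi")


class NotDifferentiableError(Exception):
    """Raised when a loss configuration has no analytic toy gradient."""


@dataclass
class LossContext:
    """Static inputs a loss term may need beyond the prediction itself.

    ``motif_geom`` is the one-hot pairwise geometry of the *extracted*
    native motif (rows in segment order); ``placement`` maps those rows
    into design indices; ``native_motif`` carries the motif coordinates
    for RMSD-type terms; ``allowed_pairs`` lists ordered cross-chain pairs
    exempt from the repulsion penalty.
    """

    placement: MotifPlacement | None = None
    motif_geom: PairwiseGeometry | None = None
    native_motif: BackboneStructure | None = None
    pair_mask: np.ndarray | None = None
    allowed_pairs: frozenset[tuple[int, int]] = frozenset()


def _require(value, name: str, term: str):
    if value is None:
        raise ValueError(f"loss term {term!r} requires context field {name!r}")
    return value


def _channel_weights(weights: dict[str, float] | None) -> dict[str, float]:
    """Normalized per-channel aggregation weights (default: unweighted mean)."""
    if weights is None:
        weights = {ch: 1.0 for ch in CHANNELS}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("channel weights must have positive sum")
    return {ch: weights.get(ch, 0.0) / total for ch in CHANNELS}


# ---------------------------------------------------------------------------
# Motif reconstruction terms
# ---------------------------------------------------------------------------

@dataclass
class MotifDistogramCE:
    """Motif reconstruction loss in distribution space.

    Mean over ordered motif-motif pairs (i != j, both endpoints in the
    motif — the site's internal geometry is the specification) and over
    the four geometric channels of -log(predicted mass on the native bin
    + eps). Non-negative; ~0 when the prediction is one-hot and correct
    on every motif pair; a uniform prediction contributes ln(B) per
    channel.
    """

    eps: float = CE_EPS
    channel_weights: dict[str, float] | None = None
    name: str = "motif_distogram_ce"

    def evaluate(self, pred, ctx: LossContext) -> float:
        placement = _require(ctx.placement, "placement", self.name)
        motif_geom = _require(ctx.motif_geom, "motif_geom", self.name)
        pos = placement.motif_positions
        M = len(pos)
        if M == 0:
            raise ValueError("empty motif")
        if motif_geom.length != M:
            raise ValueError("motif geometry size does not match placement")
        w = _channel_weights(self.channel_weights)
        off = ~np.eye(M, dtype=bool)
        total = 0.0
        for ch in CHANNELS:
            true_bins = motif_geom.argmax_states(ch)          # (M, M)
            pred_ch = pred.geometry.channels[ch]              # (L, L, B)
            sub = pred_ch[np.ix_(pos, pos)]                   # (M, M, B)
            mass = np.take_along_axis(sub, true_bins[:, :, None], axis=2)[..., 0]
            # eps floors the log; the clip keeps the loss >= 0 at mass 1
            total += w[ch] * float(
                -np.log(np.minimum(mass[off] + self.eps, 1.0)).mean())
        return total

    def toy_grad_c_a(self, pred, ctx: LossContext, toy):
        placement = ctx.placement
        motif_geom = ctx.motif_geom
        pos = placement.motif_positions
        M = len(pos)
        L = toy.c.shape[0]
        w = _channel_weights(self.channel_weights)
        off = ~np.eye(M, dtype=bool)
        n_pairs = int(off.sum())
        Gc = np.zeros((L, L))
        for ch in CHANNELS:
            B = toy.world.bins.n_states(ch)
            true_bins = motif_geom.argmax_states(ch)
            planted = toy.world.planted_bins[ch][np.ix_(pos, pos)]
            delta = (true_bins == planted).astype(float)
            c_sub = toy.c[np.ix_(pos, pos)]
            q_t = c_sub * delta + (1.0 - c_sub) / B
            d_dc = -(delta - 1.0 / B) / (q_t + self.eps)      # d(-ln)/dc per pair
            contrib = np.where(off, d_dc, 0.0) * (w[ch] / n_pairs)
            Gc[np.ix_(pos, pos)] += contrib
        return Gc, np.zeros(L)


@dataclass
class MotifCoordRMSD:
    """Motif reconstruction at the coordinate level: Kabsch-superposed
    backbone RMSD (Angstrom) between predicted motif positions and the
    native motif. Requires >= 3 motif residues. Atoms default to N/CA/C;
    CA-only available."""

    atoms: tuple[str, ...] = ("N", "CA", "C")
    name: str = "motif_coord_rmsd"

    def evaluate(self, pred, ctx: LossContext) -> float:
        placement = _require(ctx.placement, "placement", self.name)
        native = _require(ctx.native_motif, "native_motif", self.name)
        pos = placement.motif_positions
        if len(pos) < 3:
            raise ValueError("motif coordinate RMSD undefined for < 3 residues")
        pred_motif = pred.coords.subset(pos)
        return kabsch_superpose(
            pred_motif.backbone_coords(self.atoms),
            native.backbone_coords(self.atoms),
        ).rmsd

    def toy_grad_c_a(self, pred, ctx: LossContext, toy):
        # planted-landscape coordinates are constant in the sequence input
        L = toy.c.shape[0]
        return np.zeros((L, L)), np.zeros(L)


# ---------------------------------------------------------------------------
# Certainty (hallucination) term
# ---------------------------------------------------------------------------

def _resolve_pair_mask(pred, pairs: str, explicit: np.ndarray | None) -> np.ndarray:
    L = pred.geometry.length
    if explicit is not None:
        mask = np.asarray(explicit, dtype=bool)
        if mask.shape != (L, L):
            raise ValueError("pair mask must be (L, L)")
    elif pairs == "all":
        mask = np.ones((L, L), dtype=bool)
    elif pairs == "offdiag":
        mask = ~np.eye(L, dtype=bool)
    elif pairs == "interchain":
        b = pred.chain_boundary
        if b is None:
            raise ValueError("interchain pair selection needs a two-chain prediction")
        mask = np.zeros((L, L), dtype=bool)
        mask[:b, b:] = True
        mask[b:, :b] = True
    else:
        raise ValueError(f"unknown pair selection {pairs!r}")
    if not mask.any():
        raise ValueError("pair mask selects no pairs")
    return mask


@dataclass
class CertaintyLoss:
    """Structure-certainty loss: rewards confident (low-entropy) predicted
    pair distributions.

    ``entropy`` mode: mean Shannon entropy of the selected pair
    distributions (0 for one-hot, ln B for uniform). ``kl_background``
    mode: negative mean KL divergence from a background distribution
    (uniform unless supplied), so lower loss = further from background.
    With the inter-chain pair selection this is the inter-chain entropy
    loss used for binder design.
    """

    mode: str = "entropy"
    pairs: str = "all"                       # all | offdiag | interchain
    explicit_mask: np.ndarray | None = None
    background: PairwiseGeometry | None = None
    channel_weights: dict[str, float] | None = None
    name: str = "certainty"

    def _masked(self, pred, ctx: LossContext) -> np.ndarray:
        explicit = self.explicit_mask if self.explicit_mask is not None else ctx.pair_mask
        return _resolve_pair_mask(pred, self.pairs, explicit)

    def evaluate(self, pred, ctx: LossContext) -> float:
        mask = self._masked(pred, ctx)
        w = _channel_weights(self.channel_weights)
        total = 0.0
        for ch in CHANNELS:
            Q = pred.geometry.channels[ch][mask]          # (n_pairs, B)
            with np.errstate(divide="ignore", invalid="ignore"):
                logQ = np.where(Q > 0, np.log(np.where(Q > 0, Q, 1.0)), 0.0)
            H = -(Q * logQ).sum(axis=1)
            if self.mode == "entropy":
                total += w[ch] * float(H.mean())
            elif self.mode == "kl_background":
                B = Q.shape[1]
                if self.background is None:
                    kl = np.log(B) - H
                else:
                    bg = self.background.channels[ch][mask]
                    kl = (Q * (logQ - np.log(bg + 1e-30))).sum(axis=1)
                total += w[ch] * float(-kl.mean())
            else:
                raise ValueError(f"unknown certainty mode {self.mode!r}")
        return total

    def toy_grad_c_a(self, pred, ctx: LossContext, toy):
        if self.mode == "kl_background" and self.background is not None:
            raise NotDifferentiableError(
                "analytic toy gradient implemented for uniform background only")
        mask = self._masked(pred, ctx)
        n_sel = int(mask.sum())
        w = _channel_weights(self.channel_weights)
        L = toy.c.shape[0]
        c = np.clip(toy.c, 0.0, 1.0 - 1e-12)
        Gc = np.zeros((L, L))
        for ch in CHANNELS:
            B = toy.world.bins.n_states(ch)
            q0 = (1.0 - c) / B
            q1 = c + q0
            # dH/dc for the planted mixture Q = c*onehot + (1-c)*uniform
            dH = (1.0 - 1.0 / B) * (np.log(q0) - np.log(q1))
            # kl_background (uniform) loss is H - ln B: same derivative
            Gc += (w[ch] / n_sel) * np.where(mask, dH, 0.0)
        return Gc, np.zeros(L)


# ---------------------------------------------------------------------------
# Task-specific terms
# ---------------------------------------------------------------------------

def _contact_bins(bins, cutoff: float) -> int:
    """Number of distance bins lying entirely below the contact cutoff."""
    edges = bins.edges("distance")
    return int(np.sum(edges[1:] <= cutoff))


def _cross_chain_pairs(L: int, boundary: int) -> np.ndarray:
    mask = np.zeros((L, L), dtype=bool)
    mask[:boundary, boundary:] = True
    mask[boundary:, :boundary] = True
    return mask


@dataclass
class RepulsionLoss:
    """Penalty on predicted cross-chain contacts beyond a designated
    allowed set (e.g. the scaffolded epitope's own antibody contacts).

    Contact probability of an ordered pair is the distance-channel mass in
    bins below ``contact_cutoff`` (8 A C-beta - C-beta, the conventional
    contact definition). The loss is the mean contact probability over
    cross-chain ordered pairs not in ``allowed_pairs``; it lies in [0, 1].
    """

    contact_cutoff: float = 8.0
    allowed_pairs: frozenset[tuple[int, int]] = frozenset()
    name: str = "repulsion"

    def _disallowed(self, pred, ctx: LossContext) -> np.ndarray:
        if pred.chain_boundary is None:
            raise ValueError("repulsion loss requires a two-chain prediction")
        L = pred.geometry.length
        allowed = self.allowed_pairs or ctx.allowed_pairs
        mask = _cross_chain_pairs(L, pred.chain_boundary)
        for (i, j) in allowed:
            mask[i, j] = False
        if not mask.any():
            raise ValueError("no disallowed cross-chain pairs")
        return mask

    def evaluate(self, pred, ctx: LossContext) -> float:
        mask = self._disallowed(pred, ctx)
        bins = pred.geometry.bins
        k = _contact_bins(bins, self.contact_cutoff)
        p = pred.geometry.channels["distance"][..., :k].sum(axis=2)
        return float(p[mask].mean())

    def toy_grad_c_a(self, pred, ctx: LossContext, toy):
        mask = self._disallowed(pred, ctx)
        bins = toy.world.bins
        k = _contact_bins(bins, self.contact_cutoff)
        B = bins.n_states("distance")
        planted_contact = (toy.world.planted_bins["distance"] < k).astype(float)
        dp_dc = planted_contact - k / B
        L = toy.c.shape[0]
        Gc = np.where(mask, dp_dc, 0.0) / int(mask.sum())
        return Gc, np.zeros(L)


@dataclass
class RogLoss:
    """Compactness regularizer: max(0, Rg - rg_max)^2 on the CA radius of
    gyration, in Angstrom^2. Zero for any structure already compact
    enough; a single residue has Rg = 0."""

    rg_max: float = 15.0
    name: str = "rog"

    def evaluate(self, pred, ctx: LossContext) -> float:
        ca = pred.coords.ca
        center = ca.mean(axis=0)
        rg = float(np.sqrt(((ca - center) ** 2).sum(axis=1).mean()))
        return max(0.0, rg - self.rg_max) ** 2

    def toy_grad_c_a(self, pred, ctx: LossContext, toy):
        L = toy.c.shape[0]
        return np.zeros((L, L)), np.zeros(L)


@dataclass
class MeanPAE:
    """Mean predicted aligned error (Angstrom) over selected ordered pairs
    (``all`` or ``interchain``). A simple confidence-style loss used in
    the toy-gradient examples and available against real predictors."""

    pairs: str = "all"
    name: str = "mean_pae"

    def _mask(self, pred) -> np.ndarray:
        return _resolve_pair_mask(pred, self.pairs, None)

    def evaluate(self, pred, ctx: LossContext) -> float:
        mask = self._mask(pred)
        return float(pred.pae[mask].mean())

    def toy_grad_c_a(self, pred, ctx: LossContext, toy):
        mask = self._mask(pred)
        L = toy.c.shape[0]
        Gc = np.where(mask, -toy.world.max_pae, 0.0) / int(mask.sum())
        return Gc, np.zeros(L)


# ---------------------------------------------------------------------------
# Composite loss and configuration
# ---------------------------------------------------------------------------

TERM_REGISTRY = {
    "motif_distogram_ce": MotifDistogramCE,
    "motif_coord_rmsd": MotifCoordRMSD,
    "certainty": CertaintyLoss,
    "repulsion": RepulsionLoss,
    "rog": RogLoss,
    "mean_pae": MeanPAE,
}


@dataclass
class LossConfig:
    """Ordered, weighted collection of loss terms."""

    terms: list[tuple[Any, float]] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("loss config needs at least one term")
        for _, w in self.terms:
            if not np.isfinite(w):
                raise ValueError("loss weights must be finite")

    @classmethod
    def from_dict(cls, spec: Iterable[dict]) -> "LossConfig":
        terms = []
        for entry in spec:
            name = entry["name"]
            if name not in TERM_REGISTRY:
                raise KeyError(f"unknown loss term {name!r}")
            params = dict(entry.get("params", {}))
            if "allowed_pairs" in params:
                params["allowed_pairs"] = frozenset(
                    tuple(p) for p in params["allowed_pairs"])
            term = TERM_REGISTRY[name](**params)
            terms.append((term, float(entry.get("weight", 1.0))))
        return cls(terms)

    @classmethod
    def from_yaml(cls, text: str) -> "LossConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_dict(self) -> list[dict]:
        out = []
        for term, weight in self.terms:
            params = {}
            for f in term.__dataclass_fields__:
                if f == "name":
                    continue
                v = getattr(term, f)
                if isinstance(v, frozenset):
                    v = sorted(list(p) for p in v)
                if isinstance(v, np.ndarray) or isinstance(v, PairwiseGeometry):
                    continue  # array-valued params are not round-tripped
                params[f] = v
            out.append({"name": term.name, "weight": weight, "params": params})
        return out


def composite_loss(pred, config: LossConfig, ctx: LossContext
                   ) -> tuple[float, dict[str, dict[str, float]]]:
    """Weighted sum of the configured terms.

    Returns ``(total, breakdown)`` where ``breakdown`` maps a unique term
    key to its unweighted value, weight and weighted contribution. The
    breakdown is populated even for zero-weight terms.
    """
    total = 0.0
    breakdown: dict[str, dict[str, float]] = {}
    for idx, (term, weight) in enumerate(config.terms):
        key = term.name if term.name not in breakdown else f"{term.name}_{idx}"
        value = term.evaluate(pred, ctx)
        total += weight * value
        breakdown[key] = {"value": value, "weight": weight,
                          "weighted": weight * value}
    return total, breakdown


# ---------------------------------------------------------------------------
# Functional conveniences mirroring the term classes
# ---------------------------------------------------------------------------

def motif_distogram_ce(pred, motif_geom: PairwiseGeometry,
                       placement: MotifPlacement, eps: float = CE_EPS) -> float:
    return MotifDistogramCE(eps=eps).evaluate(
        pred, LossContext(placement=placement, motif_geom=motif_geom))


def motif_coord_rmsd(pred_coords: BackboneStructure,
                     native_motif: BackboneStructure,
                     placement: MotifPlacement,
                     atoms: Sequence[str] = ("N", "CA", "C")) -> float:
    class _P:  # minimal prediction shim carrying only coordinates
        coords = pred_coords
    return MotifCoordRMSD(atoms=tuple(atoms)).evaluate(
        _P, LossContext(placement=placement, native_motif=native_motif))


def certainty_loss(pred, pair_mask: np.ndarray | None = None,
                   mode: str = "entropy",
                   background: PairwiseGeometry | None = None) -> float:
    term = CertaintyLoss(mode=mode, background=background,
                         explicit_mask=pair_mask)
    return term.evaluate(pred, LossContext())


def repulsion_loss(pred, allowed_pairs: Iterable[tuple[int, int]] = (),
                   contact_cutoff: float = 8.0) -> float:
    term = RepulsionLoss(contact_cutoff=contact_cutoff,
                         allowed_pairs=frozenset(allowed_pairs))
    return term.evaluate(pred, LossContext())


def rog_loss(coords: BackboneStructure, rg_max: float) -> float:
    class _P:
        pass
    _P.coords = coords
    return RogLoss(rg_max=rg_max).evaluate(_P, LossContext())
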