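"""The predictor contract and the planted-landscape toy predictor.

Every design loop in this package consumes a *predictor*: something that
maps a per-position amino-acid distribution to coordinates, binned
pairwise geometry, per-residue confidence (pLDDT, 0-100) and pairwise
aligned error (PAE, Angstrom). Real structure-prediction networks
(trRosetta / RosettaFold / AlphaFold class) implement this contract
behind adapters; this package deliberately ships none of them. What it
does ship is a deterministic, closed-form *planted landscape*: a hidden
target structure X* and sequence s* such that predictions become
confident exactly to the degree the input sequence locally matches s*.
Optimizers that work must therefore recover s* — a desk-scale,
exactly-analyzable stand-in for "the sequence strongly encodes the
structure".

Toy model, with P the L x 20 input distribution and w a window radius:

    match       m_i  = P_i(s*_i)
    agreement   a_i  = mean of m over the window [i-w, i+w], clipped to
                       the chain containing i
    confidence  c_ij = a_i * a_j
    geometry    Q_ij = c_ij * onehot(features(X*)_ij) + (1 - c_ij) * uniform
    coords           = X*
    plddt_i          = 100 * a_i
    pae_ij           = max_pae * (1 - c_ij)

All outputs are closed-form in P, so every differentiable loss has an
analytic gradient (:func:`toy_gradient`), checkable against finite
differences. The entropy of Q_ij strictly decreases as c_ij grows, which
is the hook that makes certainty-based hallucination losses recover s*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    AA_ALPHABET,
    AA_INDEX,
    BackboneStructure,
    BinScheme,
    PairwiseGeometry,
    make_fixture,
    sixd_features,
)
from .losses import LossConfig, LossContext, composite_loss

__all__ = [
    "AA_ALPHABET",
    "sequence_to_distribution",
    "distribution_to_sequence",
    "validate_distribution",
    "PredictionResult",
    "PlantedLandscape",
    "ToyPredictor",
    "toy_predict",
    "toy_gradient",
]


# ---------------------------------------------------------------------------
# Sequence distributions
# ---------------------------------------------------------------------------

def sequence_to_distribution(sequence: str) -> np.ndarray:
    """One-hot L x 20 matrix for a hard sequence (alphabet: ACDE...WY)."""
    P = np.zeros((len(sequence), len(AA_ALPHABET)))
    for i, aa in enumerate(sequence):
        if aa not in AA_INDEX:
            raise ValueError(f"non-canonical residue {aa!r} at position {i}")
        P[i, AA_INDEX[aa]] = 1.0
    return P


def distribution_to_sequence(P: np.ndarray) -> str:
    """Per-position argmax decoding of an L x 20 distribution."""
    return "".join(AA_ALPHABET[k] for k in np.argmax(P, axis=1))


def validate_distribution(P: np.ndarray, atol: float = 1e-9) -> None:
    P = np.asarray(P)
    if P.ndim != 2 or P.shape[1] != len(AA_ALPHABET):
        raise ValueError("sequence distribution must be (L, 20)")
    if np.any(P < -atol) or np.any(P > 1 + atol):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > atol):
        raise ValueError("rows must sum to 1")


# ---------------------------------------------------------------------------
# Prediction result
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """What any predictor returns for one sequence (distribution).

    ``chain_boundary``, when set, is the index of the first residue of the
    second chain in a binder/target complex; inter-chain blocks of ``pae``
    then gauge interface confidence.
    """

    coords: BackboneStructure
    geometry: PairwiseGeometry
    plddt: np.ndarray          # (L,), 0-100
    pae: np.ndarray            # (L, L), Angstrom, >= 0
    chain_boundary: int | None = None

    def validate(self) -> None:
        self.geometry.validate()
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValueError("plddt must lie in [0, 100]")
        if np.any(self.pae < 0):
            raise ValueError("pae must be non-negative")
        L = len(self.coords)
        if self.plddt.shape != (L,) or self.pae.shape != (L, L):
            raise ValueError("plddt/pae shapes inconsistent with coordinates")


# ---------------------------------------------------------------------------
# Planted landscape
# ---------------------------------------------------------------------------

@dataclass
class PlantedLandscape:
    """A synthetic test world: hidden target structure and sequence.

    Parameters
    ----------
    structure : the planted backbone X* (single- or two-chain).
    target_sequence : s*, same length as the structure.
    window : agreement window radius w (residues), default 2.
    max_pae : PAE cap in Angstrom, default 30 (order of magnitude of real
        predictors' error cap).
    bins : discretization used for the planted geometry.
    """

    structure: BackboneStructure
    target_sequence: str
    window: int = 2
    max_pae: float = 30.0
    bins: BinScheme = field(default_factory=BinScheme)

    def __post_init__(self) -> None:
        if len(self.target_sequence) != len(self.structure):
            raise ValueError("target sequence length must match structure")
        if self.window < 0:
            raise ValueError("window radius must be >= 0")
        geom = sixd_features(self.structure, self.bins)
        #: one-hot pairwise geometry of X* and its modal bin per channel
        self.planted_geometry = geom
        self.planted_bins = {ch: geom.argmax_states(ch)
                             for ch in geom.channels}
        self._window_matrix = self._build_window_matrix()
        self._uniforms = {
            ch: np.full(self.bins.n_states(ch), 1.0 / self.bins.n_states(ch))
            for ch in geom.channels}

    @property
    def length(self) -> int:
        return len(self.structure)

    @property
    def chain_boundary(self) -> int | None:
        intervals = self.structure.chain_intervals()
        return intervals[1][1] if len(intervals) == 2 else None

    @property
    def target_indices(self) -> np.ndarray:
        """Alphabet index of s* at each position."""
        return np.array([AA_INDEX[a] for a in self.target_sequence])

    def _build_window_matrix(self) -> np.ndarray:
        """W with a = W @ m: W[i, k] = 1/n_i for k in i's clipped window."""
        L = self.length
        W = np.zeros((L, L))
        for chain, start, stop in self.structure.chain_intervals():
            for i in range(start, stop):
                lo = max(start, i - self.window)
                hi = min(stop, i + self.window + 1)
                W[i, lo:hi] = 1.0 / (hi - lo)
        return W

    # -- serialization ------------------------------------------------------

    def to_json(self, pdb_path: str | Path) -> str:
        """JSON description referencing the fixture PDB holding X*."""
        return json.dumps({
            "pdb_path": str(pdb_path),
            "target_sequence": self.target_sequence,
            "window": self.window,
            "max_pae": self.max_pae,
            "alphabet": AA_ALPHABET,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str,
                  read_structure=None) -> "PlantedLandscape":
        from .pdbio import read_structure as _read
        d = json.loads(text)
        reader = read_structure or _read
        structure = reader(d["pdb_path"])
        return cls(structure=structure,
                   target_sequence=d["target_sequence"],
                   window=int(d["window"]),
                   max_pae=float(d["max_pae"]))

    @classmethod
    def from_fixture(cls, kind: str = "helix", n: int = 30, seed: int = 0,
                     window: int = 2, max_pae: float = 30.0
                     ) -> "PlantedLandscape":
        """Convenience: plant a landscape on a synthetic fixture backbone,
        using the fixture's own (cysteine-free) sequence as s*."""
        structure = make_fixture(kind, n, seed=seed)
        return cls(structure=structure, target_sequence=structure.sequence,
                   window=window, max_pae=max_pae)


@dataclass
class _ToyInternals:
    """Intermediate fields of one toy forward pass, used by the analytic
    gradient."""

    m: np.ndarray    # (L,)  per-position match with s*
    a: np.ndarray    # (L,)  windowed agreement
    c: np.ndarray    # (L,L) pair confidence a_i * a_j
    world: PlantedLandscape


def _forward(P: np.ndarray, world: PlantedLandscape) -> _ToyInternals:
    P = np.asarray(P, dtype=float)
    if P.shape != (world.length, len(AA_ALPHABET)):
        raise ValueError(
            f"sequence distribution shape {P.shape} does not match "
            f"landscape length {world.length}")
    m = P[np.arange(world.length), world.target_indices]
    a = world._window_matrix @ m
    c = np.outer(a, a)
    return _ToyInternals(m=m, a=a, c=c, world=world)


def toy_predict(P: np.ndarray, world: PlantedLandscape) -> PredictionResult:
    """Deterministic closed-form prediction for the planted landscape.

    See the module docstring for the model. ``P`` rows need not be
    normalized (the forward map reads only the s* column), which keeps
    finite-difference probes of the gradient well-defined.
    """
    t = _forward(P, world)
    channels = {}
    for ch, onehot in world.planted_geometry.channels.items():
        B = world.bins.n_states(ch)
        cexp = t.c[:, :, None]
        channels[ch] = cexp * onehot + (1.0 - cexp) / B
    geometry = PairwiseGeometry(channels=channels, bins=world.bins)
    plddt = 100.0 * np.clip(t.a, 0.0, 1.0)
    pae = world.max_pae * (1.0 - t.c)
    return PredictionResult(coords=world.structure, geometry=geometry,
                            plddt=plddt, pae=pae,
                            chain_boundary=world.chain_boundary)


def toy_gradient(config: LossConfig, P: np.ndarray, world: PlantedLandscape,
                 ctx: LossContext | None = None) -> np.ndarray:
    """Analytic d(composite loss)/dP for the planted-landscape predictor.

    Each differentiable term reports its sensitivity (Gc, Ga) with respect
    to the pair-confidence field c and agreement field a; the chain rule
    through c = a a^T, a = W m, m_k = P[k, s*_k] collapses to an L x 20
    matrix that is nonzero only in the s* column. Terms without an
    analytic form raise :class:`~motifscaffold.losses.NotDifferentiableError`.
    """
    ctx = ctx or LossContext()
    t = _forward(P, world)
    pred = toy_predict(P, world)
    L = world.length
    Gc = np.zeros((L, L))
    Ga = np.zeros(L)
    for term, weight in config.terms:
        if weight == 0.0:
            continue
        if not hasattr(term, "toy_grad_c_a"):
            from .losses import NotDifferentiableError
            raise NotDifferentiableError(
                f"term {term.name!r} has no analytic toy gradient")
        gc, ga = term.toy_grad_c_a(pred, ctx, t)
        Gc += weight * gc
        Ga += weight * ga
    # c_ij = a_i a_j  (ordered pairs, diagonal included)
    dL_da = Gc @ t.a + Gc.T @ t.a + Ga
    dL_dm = world._window_matrix.T @ dL_da
    grad = np.zeros((L, len(AA_ALPHABET)))
    grad[np.arange(L), world.target_indices] = dL_dm
    return grad


def plant_motif_landscape(motif: BackboneStructure, placement,
                          seed: int = 0, window: int = 2,
                          max_pae: float = 30.0,
                          scaffold_kind: str = "helix") -> PlantedLandscape:
    """Plant a landscape whose target structure embeds a real motif.

    A synthetic scaffold backbone of the placement's total length is
    generated, the motif is rigidly fitted (one joint Kabsch transform,
    so its internal geometry is exactly preserved) onto the scaffold's
    motif positions, and the motif coordinates and letters replace the
    scaffold's at those positions. The result is the hidden target X*/s*
    of a toy design problem whose motif-reconstruction loss is exactly
    minimized by recovering s*. The backbone is discontinuous at
    motif/scaffold seams — acceptable in a toy world that is never fed
    to a physical model.
    """
    from .geometry import kabsch_superpose

    L = placement.total_length
    pos = placement.motif_positions
    if len(motif) != len(pos):
        raise ValueError("motif length does not match placement")
    scaffold = make_fixture(scaffold_kind, L, seed=seed)
    fit = kabsch_superpose(motif.ca, scaffold.ca[pos])
    moved = motif.transformed(fit.rotation, fit.translation)
    n, ca, c = scaffold.n.copy(), scaffold.ca.copy(), scaffold.c.copy()
    n[pos], ca[pos], c[pos] = moved.n, moved.ca, moved.c
    seq = list(scaffold.sequence)
    for k, p in enumerate(pos):
        seq[p] = motif.sequence[k]
    import dataclasses as _dc
    structure = _dc.replace(scaffold, n=n, ca=ca, c=c, cb=None,
                            sequence="".join(seq)).with_virtual_cb()
    return PlantedLandscape(structure=structure,
                            target_sequence="".join(seq),
                            window=window, max_pae=max_pae)


class ToyPredictor:
    """Object form of the toy predictor, satisfying the design-loop
    contract: ``predict(P)`` plus the optional gradient capability
    ``loss_gradient(config, P, ctx)``."""

    def __init__(self, world: PlantedLandscape):
        self.world = world

    @property
    def length(self) -> int:
        return self.world.length

    def predict(self, P: np.ndarray) -> PredictionResult:
        return toy_predict(P, self.world)

    def loss_gradient(self, config: LossConfig, P: np.ndarray,
                      ctx: LossContext | None = None) -> np.ndarray:
        return toy_gradient(config, P, self.world, ctx)
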