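"""Backbone coordinate math.

Everything downstream — motif losses, design metrics, the inpainting
benchmark — reduces to a handful of geometric primitives on protein
backbones: least-squares rigid superposition (Kabsch), RMSD, an idealized
virtual C-beta, and the binned pairwise distance/orientation features
("distograms" in the wide sense) that structure-prediction networks emit.
This module owns those primitives plus synthetic fixture backbones
(ideal helices/strands and a two-chain complex) used throughout the tests
and the desk-scale planted-landscape predictor.

Coordinates are in Angstrom. Internally residues are indexed 0-based
half-open; the 1-based inclusive PDB numbering appears only in the
``residue_numbers`` field, which mirrors the file convention.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BackboneStructure",
    "PairwiseGeometry",
    "BinScheme",
    "SuperposeResult",
    "kabsch_superpose",
    "rmsd",
    "virtual_cb",
    "sixd_features",
    "make_fixture",
    "DEFAULT_BINS",
]

#: Canonical amino-acid one-letter alphabet, alphabetical order. This is the
#: column order of every L x 20 sequence-distribution matrix in the package.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


def three_to_one(resname: str) -> str:
    """Map a 3-letter residue name to 1-letter code ('X' if unknown)."""
    return _THREE_TO_ONE.get(resname.upper(), "X")


def one_to_three(letter: str) -> str:
    return _ONE_TO_THREE.get(letter.upper(), "UNK")


# ---------------------------------------------------------------------------
# BackboneStructure
# ---------------------------------------------------------------------------

@dataclass
class BackboneStructure:
    """Ordered per-residue backbone coordinates with chain/residue labels.

    Parameters
    ----------
    chain_ids : (L,) array of single-letter chain identifiers.
    residue_numbers : (L,) int array, 1-based, strictly increasing per chain.
    sequence : length-L string of one-letter codes ('X' for unknown).
    n, ca, c : (L, 3) float arrays of backbone atom coordinates in Angstrom.
    cb : optional (L, 3) array; rows may be NaN where no C-beta is stored.

    All of N, CA, C must be present (finite) for every residue; structures
    with missing backbone atoms are rejected here and filtered at ingest
    (see :mod:`motifscaffold.pdbio`).
    """

    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    sequence: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    cb: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype="U1")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        for name in ("n", "ca", "c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} coordinates must be (L, 3)")
            setattr(self, name, arr)
        if self.cb is not None:
            self.cb = np.asarray(self.cb, dtype=float)
        L = len(self.sequence)
        shapes = {self.chain_ids.shape[0], self.residue_numbers.shape[0],
                  self.n.shape[0], self.ca.shape[0], self.c.shape[0], L}
        if len(shapes) != 1:
            raise ValueError("inconsistent per-residue field lengths")
        if not (np.isfinite(self.n).all() and np.isfinite(self.ca).all()
                and np.isfinite(self.c).all()):
            raise ValueError("backbone coordinates must be finite")
        # duplicate (chain, number) pairs are always invalid; strict
        # monotonic numbering is enforced at file ingest (an extracted
        # multi-segment motif legitimately restarts its numbering)
        pairs = list(zip(self.chain_ids.tolist(),
                         self.residue_numbers.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (chain, residue number) pair")

    def __len__(self) -> int:
        return len(self.sequence)

    # -- derived views ------------------------------------------------------

    def chain_intervals(self) -> list[tuple[str, int, int]]:
        """Half-open [start, stop) index ranges per chain, in order."""
        out: list[tuple[str, int, int]] = []
        ids = self.chain_ids.tolist()
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                out.append((ids[start], start, i))
                start = i
        return out

    def with_virtual_cb(self) -> "BackboneStructure":
        """Return a copy whose CB is recomputed from N/CA/C at every position.

        The virtual C-beta is always rebuilt (never trusted from file) so
        glycine and mutated positions are handled uniformly.
        """
        cb = virtual_cb(self.n, self.ca, self.c)
        return dataclasses.replace(self, cb=cb)

    def backbone_coords(self, atoms: Sequence[str] = ("N", "CA", "C")) -> np.ndarray:
        """Stack the requested backbone atoms into an (L * k, 3) point set.

        Atoms are interleaved per residue (res0 N, res0 CA, res0 C, res1 N, ...)
        so corresponding rows of two equal-length structures correspond.
        """
        cols = {"N": self.n, "CA": self.ca, "C": self.c, "CB": self.cb}
        stacked = [cols[a.upper()] for a in atoms]
        if any(s is None for s in stacked):
            raise ValueError("requested atom not present")
        return np.stack(stacked, axis=1).reshape(-1, 3)

    def subset(self, indices: Iterable[int]) -> "BackboneStructure":
        idx = np.asarray(list(indices), dtype=int)
        return BackboneStructure(
            chain_ids=self.chain_ids[idx],
            residue_numbers=self.residue_numbers[idx],
            sequence="".join(self.sequence[i] for i in idx),
            n=self.n[idx], ca=self.ca[idx], c=self.c[idx],
            cb=None if self.cb is None else self.cb[idx],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        """Apply x -> R x + t to every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        f = lambda x: x @ R.T + t
        return dataclasses.replace(
            self, n=f(self.n), ca=f(self.ca), c=f(self.c),
            cb=None if self.cb is None else f(self.cb))

    @staticmethod
    def concatenate(parts: Sequence["BackboneStructure"]) -> "BackboneStructure":
        """Join chains into one structure (chain ids must not interleave)."""
        return BackboneStructure(
            chain_ids=np.concatenate([p.chain_ids for p in parts]),
            residue_numbers=np.concatenate([p.residue_numbers for p in parts]),
            sequence="".join(p.sequence for p in parts),
            n=np.concatenate([p.n for p in parts]),
            ca=np.concatenate([p.ca for p in parts]),
            c=np.concatenate([p.c for p in parts]),
            cb=(np.concatenate([p.with_virtual_cb().cb for p in parts])
                if any(p.cb is not None for p in parts) else None),
        )


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperposeResult:
    """Rigid transform mapping ``mobile`` onto ``reference``: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False  # near-collinear input; transform still valid


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    allow_reflection: bool = False,
) -> SuperposeResult:
    """Least-squares rigid superposition of two equal-size point sets.

    Closed-form Kabsch solution via SVD of the covariance matrix. By default
    the rotation is proper (det +1); an improper optimum is corrected by
    sign-flipping the smallest singular direction. Nearly collinear inputs
    (rank-deficient covariance) are flagged ``degenerate`` rather than
    raised, because sampled gap geometries can be nearly collinear; the
    returned transform is still the closed-form optimum.

    Returns rotation R, translation t and the RMSD after applying
    x -> R x + t to ``mobile``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3) with equal n")
    if P.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    if not (np.isfinite(P).all() and np.isfinite(Q).all()):
        raise ValueError("coordinates must be finite")

    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    # covariance rank < 2 => rotation about the degenerate axis is unresolved
    scale = max(S[0], 1.0)
    degenerate = bool(S[1] <= 1e-8 * scale)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.ones(3)
    if not allow_reflection:
        D[2] = d
    R = Vt.T @ np.diag(D) @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    value = float(np.sqrt((diff * diff).sum() / P.shape[0]))
    return SuperposeResult(rotation=R, translation=t, rmsd=value,
                           degenerate=degenerate)


def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation between matched point sets, in Angstrom.

    With ``superpose`` the optimal-rigid-superposition (Kabsch) RMSD is
    returned; without, the raw per-point deviation in the given frames.
    """
    A = np.asarray(a, dtype=float)
    B = np.asarray(b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("point sets must have equal shapes")
    if A.shape[0] < 1:
        raise ValueError("need at least one point")
    if superpose:
        return kabsch_superpose(A, B).rmsd
    diff = A - B
    return float(np.sqrt((diff * diff).sum() / A.shape[0]))


# ---------------------------------------------------------------------------
# Virtual C-beta
# ---------------------------------------------------------------------------

# Ideal-geometry expansion coefficients for CB in the (b, c, b x c) frame,
# b = CA - N, c = C - CA. Standard constants from idealized sp3 geometry.
_CB_A = -0.58273431
_CB_B = 0.56802827
_CB_C = -0.54067466


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealized C-beta position(s) from backbone N/CA/C.

    Accepts single 3-vectors or (L, 3) arrays. The construction places CB at
    a fixed linear combination of the intra-residue frame vectors, so
    |CB - CA| is a constant of the backbone geometry and the result is
    equivariant under rigid transforms. Collinear or coincident N/CA/C make
    the frame degenerate and raise ``ValueError``.
    """
    N = np.atleast_2d(np.asarray(n, dtype=float))
    CA = np.atleast_2d(np.asarray(ca, dtype=float))
    C = np.atleast_2d(np.asarray(c, dtype=float))
    if not (np.isfinite(N).all() and np.isfinite(CA).all() and np.isfinite(C).all()):
        raise ValueError("coordinates must be finite")
    b = CA - N
    cvec = C - CA
    a = np.cross(b, cvec)
    norm = np.linalg.norm(a, axis=-1)
    if np.any(norm < 1e-6):
        raise ValueError("collinear or coincident N/CA/C: C-beta frame undefined")
    cb = _CB_A * a + _CB_B * b + _CB_C * cvec + CA
    return cb[0] if np.asarray(n).ndim == 1 else cb


# ---------------------------------------------------------------------------
# Binned pairwise features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    """Discretization of the four inter-residue channels.

    Defaults follow the published trRosetta conventions: distance in 36
    equal bins over 2-20 A plus a no-contact state (37 states); omega and
    theta dihedrals in 24 bins of 15 degrees plus no-contact; the planar
    phi angle in 12 bins of 15 degrees plus no-contact. Pairs whose
    C-beta distance falls beyond the last distance bin edge are assigned
    the no-contact state in all four channels, as is the diagonal.
    """

    distance_min: float = 2.0
    distance_max: float = 20.0
    n_distance_bins: int = 36
    n_omega_bins: int = 24
    n_theta_bins: int = 24
    n_phi_bins: int = 12

    @property
    def channels(self) -> tuple[str, ...]:
        return ("distance", "omega", "theta", "phi")

    def n_states(self, channel: str) -> int:
        """Number of states in a channel including its no-contact state."""
        return {
            "distance": self.n_distance_bins + 1,
            "omega": self.n_omega_bins + 1,
            "theta": self.n_theta_bins + 1,
            "phi": self.n_phi_bins + 1,
        }[channel]

    def edges(self, channel: str) -> np.ndarray:
        if channel == "distance":
            return np.linspace(self.distance_min, self.distance_max,
                               self.n_distance_bins + 1)
        if channel in ("omega", "theta"):
            return np.linspace(-180.0, 180.0, getattr(self, f"n_{channel}_bins") + 1)
        if channel == "phi":
            return np.linspace(0.0, 180.0, self.n_phi_bins + 1)
        raise KeyError(channel)

    def no_contact_state(self, channel: str) -> int:
        return self.n_states(channel) - 1


DEFAULT_BINS = BinScheme()


@dataclass
class PairwiseGeometry:
    """Per-pair probability distributions over binned geometric channels.

    ``channels`` maps channel name -> (L, L, B) array of probability vectors
    (one-hot in the discretized-structure case, soft for predictor output).
    The distance and omega channels are symmetric under (i,j) <-> (j,i);
    theta and phi need not be. Diagonal entries sit in the designated
    no-contact state.
    """

    channels: dict[str, np.ndarray]
    bins: BinScheme = field(default_factory=BinScheme)

    @property
    def length(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    def validate(self, atol: float = 1e-6) -> None:
        """Check the probability-distribution invariants; raise on violation."""
        for name, arr in self.channels.items():
            if arr.ndim != 3 or arr.shape[0] != arr.shape[1]:
                raise ValueError(f"channel {name} must be (L, L, B)")
            if arr.shape[2] != self.bins.n_states(name):
                raise ValueError(f"channel {name} has wrong state count")
            if np.any(arr < -atol) or np.any(arr > 1 + atol):
                raise ValueError(f"channel {name} has entries outside [0, 1]")
            sums = arr.sum(axis=2)
            if np.any(np.abs(sums - 1.0) > atol):
                raise ValueError(f"channel {name} rows do not sum to 1")

    def argmax_states(self, channel: str) -> np.ndarray:
        """(L, L) int array of the modal state per pair."""
        return np.argmax(self.channels[channel], axis=2)


def _dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle(s) in degrees, vectorized over leading dims."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def _planar_angle(p0, p1, p2) -> np.ndarray:
    """Angle at p1 in degrees, vectorized."""
    u = p0 - p1
    v = p2 - p1
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def sixd_features(structure: BackboneStructure,
                  bins: BinScheme = DEFAULT_BINS) -> PairwiseGeometry:
    """One-hot binned inter-residue geometry of a backbone.

    Per ordered pair (i, j): the CB(i)-CB(j) distance; the omega dihedral
    CA(i)-CB(i)-CB(j)-CA(j); the theta dihedral N(i)-CA(i)-CB(i)-CB(j); and
    the planar angle phi CA(i)-CB(i)-CB(j). C-beta is always the virtual
    C-beta recomputed from N/CA/C. Distances below the first edge clip into
    the first bin; pairs beyond the last edge — and the diagonal — are
    assigned the no-contact state in all four channels.
    """
    L = len(structure)
    if L < 2:
        raise ValueError("pairwise features require at least 2 residues")
    s = structure.with_virtual_cb()
    cb, ca, n = s.cb, s.ca, s.n

    diff = cb[:, None, :] - cb[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))

    no_contact = (dist >= bins.distance_max) | np.eye(L, dtype=bool)

    CAi = np.broadcast_to(ca[:, None, :], (L, L, 3))
    CBi = np.broadcast_to(cb[:, None, :], (L, L, 3))
    CBj = np.broadcast_to(cb[None, :, :], (L, L, 3))
    CAj = np.broadcast_to(ca[None, :, :], (L, L, 3))
    Ni = np.broadcast_to(n[:, None, :], (L, L, 3))

    with np.errstate(invalid="ignore", divide="ignore"):
        omega = _dihedral(CAi, CBi, CBj, CAj)
        theta = _dihedral(Ni, CAi, CBi, CBj)
        phi = _planar_angle(CAi, CBi, CBj)

    def bin_channel(values: np.ndarray, channel: str) -> np.ndarray:
        edges = bins.edges(channel)
        B = bins.n_states(channel)
        idx = np.digitize(values, edges) - 1
        idx = np.clip(idx, 0, B - 2)  # clip below-range into first bin
        idx = np.where(no_contact | ~np.isfinite(values),
                       bins.no_contact_state(channel), idx)
        out = np.zeros((L, L, B))
        ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
        out[ii, jj, idx] = 1.0
        return out

    channels = {
        "distance": bin_channel(dist, "distance"),
        "omega": bin_channel(omega, "omega"),
        "theta": bin_channel(theta, "theta"),
        "phi": bin_channel(phi, "phi"),
    }
    return PairwiseGeometry(channels=channels, bins=bins)


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

# Ideal backbone covalent geometry (lengths in Angstrom, angles in degrees).
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}


def _place_atom(a, b, c, length, angle_deg, torsion_deg) -> np.ndarray:
    """NeRF atom placement: position d with |c-d|=length, angle(b,c,d),
    torsion(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n_vec = np.cross(ab, bc)
    n_vec /= np.linalg.norm(n_vec)
    m = np.cross(n_vec, bc)
    d_local = np.array([
        -length * math.cos(angle),
        length * math.sin(angle) * math.cos(torsion),
        length * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n_vec


def _ideal_chain(n_res: int, phi: float, psi: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backbone N/CA/C arrays of an ideal chain with uniform (phi, psi)."""
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_BOND_N_CA, 0.0, 0.0)
    ang = math.radians(_ANG_N_CA_C)
    C[0] = CA[0] + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1],
                           _BOND_C_N, _ANG_CA_C_N, psi)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i],
                            _BOND_N_CA, _ANG_C_N_CA, 180.0)  # trans omega
        C[i] = _place_atom(C[i - 1], N[i], CA[i],
                           _BOND_CA_C, _ANG_N_CA_C, phi)
    return N, CA, C


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _random_sequence(n: int, rng: np.random.Generator,
                     exclude: str = "C") -> str:
    letters = [a for a in AA_ALPHABET if a not in exclude]
    return "".join(rng.choice(list(letters), size=n))


def make_fixture(kind: str, n: int, seed: int = 0) -> BackboneStructure:
    """Generate an idealized synthetic backbone for tests and toy landscapes.

    ``kind`` is one of ``helix``, ``strand`` or ``two_chain_complex`` (two
    antiparallel-packed helices labelled chains A and B, close enough to
    form cross-chain C-beta contacts). Geometry uses canonical torsions and
    ideal covalent parameters; the seed controls the random global rigid
    placement and the fixture amino-acid sequence (drawn cysteine-free so
    fixtures are reachable by the default design alphabet). Deterministic
    under seed.
    """
    if n < 1:
        raise ValueError("fixture needs at least one residue")
    rng = np.random.default_rng(seed)

    def finish(parts: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]]) -> BackboneStructure:
        R = _random_rotation(rng)
        t = rng.uniform(-5.0, 5.0, size=3)
        chains, numbers, seqs, Ns, CAs, Cs = [], [], [], [], [], []
        for chain_id, N, CA, C in parts:
            k = len(N)
            chains.extend([chain_id] * k)
            numbers.extend(range(1, k + 1))
            seqs.append(_random_sequence(k, rng))
            Ns.append(N @ R.T + t)
            CAs.append(CA @ R.T + t)
            Cs.append(C @ R.T + t)
        return BackboneStructure(
            chain_ids=np.array(chains), residue_numbers=np.array(numbers),
            sequence="".join(seqs),
            n=np.concatenate(Ns), ca=np.concatenate(CAs), c=np.concatenate(Cs),
        ).with_virtual_cb()

    if kind in _TORSIONS:
        phi, psi = _TORSIONS[kind]
        N, CA, C = _ideal_chain(n, phi, psi)
        return finish([("A", N, CA, C)])

    if kind == "two_chain_complex":
        n_a = max(1, n // 2)
        n_b = n - n_a
        if n_b < 1:
            raise ValueError("two_chain_complex needs at least 2 residues")
        phi, psi = _TORSIONS["helix"]
        Na, CAa, Ca = _ideal_chain(n_a, phi, psi)
        Nb, CAb, Cb = _ideal_chain(n_b, phi, psi)
        # pack chain B antiparallel alongside A at ~9 A axis offset so the
        # interface has genuine sub-8 A C-beta contacts
        axis_a = CAa[-1] - CAa[0]
        axis_a /= max(np.linalg.norm(axis_a), 1e-9)
        flip = _rotation_about(np.array([0.0, 1.0, 0.0]), 180.0)
        Nb, CAb, Cb = (x @ flip.T for x in (Nb, CAb, Cb))
        offset = CAa.mean(axis=0) - CAb.mean(axis=0) + 9.0 * _perp(axis_a)
        Nb, CAb, Cb = (x + offset for x in (Nb, CAb, Cb))
        return finish([("A", Na, CAa, Ca), ("B", Nb, CAb, Cb)])

    raise ValueError(f"unknown fixture kind: {kind!r}")


def _perp(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to v."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, v)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = trial - np.dot(trial, v) * v
    return p / np.linalg.norm(p)


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)
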