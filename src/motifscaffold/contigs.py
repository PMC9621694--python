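"""Contig specifications: which residues form the functional motif and how
it is embedded in a design.

A contig string is a compact, comma-separated encoding of motif segments
and scaffold gaps, e.g. ``"5,A163-181,10-25"``: a fixed 5-residue gap, the
motif taken from chain A residues 163-181 of the source structure
(1-based inclusive, so 19 residues), then a gap sampled uniformly between
10 and 25 residues. Segment order in the design follows token order.

Insertion codes and negative residue numbers are unsupported (documented
limitation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .geometry import BackboneStructure

__all__ = [
    "MotifSegment",
    "Gap",
    "ContigSpec",
    "MotifPlacement",
    "parse_contigs",
    "format_contigs",
    "extract_motif",
    "sample_placement",
]


@dataclass(frozen=True)
class MotifSegment:
    """A contiguous run of motif residues in the source structure,
    1-based inclusive on both ends (PDB convention)."""

    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if len(self.chain_id) != 1 or not self.chain_id.isalpha():
            raise ValueError(f"chain id must be a single letter: {self.chain_id!r}")
        if self.start < 1:
            raise ValueError("negative or zero residue numbers unsupported")
        if self.start > self.end:
            raise ValueError(
                f"reversed range {self.chain_id}{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Gap:
    """A scaffold gap of length sampled uniformly in [min_len, max_len]."""

    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.min_len < 0 or self.max_len < self.min_len:
            raise ValueError(f"invalid gap bounds {self.min_len}-{self.max_len}")


@dataclass(frozen=True)
class ContigSpec:
    """Parsed contig string: an ordered mix of motif segments and gaps."""

    tokens: tuple[MotifSegment | Gap, ...]

    def __post_init__(self) -> None:
        if not any(isinstance(t, MotifSegment) for t in self.tokens):
            raise ValueError("contig spec must contain at least one motif segment")

    @property
    def segments(self) -> list[MotifSegment]:
        return [t for t in self.tokens if isinstance(t, MotifSegment)]

    @property
    def motif_length(self) -> int:
        """Total motif residue count (inclusive range arithmetic)."""
        return sum(len(s) for s in self.segments)

    @property
    def min_length(self) -> int:
        return self.motif_length + sum(
            t.min_len for t in self.tokens if isinstance(t, Gap))

    @property
    def max_length(self) -> int:
        return self.motif_length + sum(
            t.max_len for t in self.tokens if isinstance(t, Gap))


_SEGMENT_RE = re.compile(r"^([A-Za-z])(\d+)-(\d+)$")
_FIXED_GAP_RE = re.compile(r"^(\d+)$")
_RANGE_GAP_RE = re.compile(r"^(\d+)-(\d+)$")


def parse_contigs(spec: str) -> ContigSpec:
    """Parse a contig string into a :class:`ContigSpec`.

    Token grammar: letter-prefixed range = motif segment ("A163-181"),
    bare integer = fixed gap ("5"), integer range = sampled gap ("10-25").
    Raises ``ValueError`` on empty input, unknown token shapes, or
    reversed ranges.
    """
    if not spec or not spec.strip():
        raise ValueError("empty contig spec")
    tokens: list[MotifSegment | Gap] = []
    for raw in spec.split(","):
        tok = raw.strip()
        if not tok:
            raise ValueError(f"empty token in contig spec: {spec!r}")
        if m := _SEGMENT_RE.match(tok):
            tokens.append(MotifSegment(m.group(1), int(m.group(2)), int(m.group(3))))
        elif m := _FIXED_GAP_RE.match(tok):
            g = int(m.group(1))
            tokens.append(Gap(g, g))
        elif m := _RANGE_GAP_RE.match(tok):
            lo, hi = int(m.group(1)), int(m.group(2))
            tokens.append(Gap(lo, hi))
        else:
            raise ValueError(f"unrecognized contig token: {tok!r}")
    return ContigSpec(tuple(tokens))


def format_contigs(spec: ContigSpec) -> str:
    """Inverse of :func:`parse_contigs` (round-trips on valid specs)."""
    parts = []
    for t in spec.tokens:
        if isinstance(t, MotifSegment):
            parts.append(f"{t.chain_id}{t.start}-{t.end}")
        elif t.min_len == t.max_len:
            parts.append(str(t.min_len))
        else:
            parts.append(f"{t.min_len}-{t.max_len}")
    return ",".join(parts)


def extract_motif(spec: ContigSpec, source: BackboneStructure
                  ) -> tuple[BackboneStructure, list[str]]:
    """Pull the motif residues out of a source structure.

    Returns the motif as a :class:`BackboneStructure` (residues in token
    order, original coordinates, numbering and amino acids retained) plus
    the per-segment native sequences. A segment residue absent from the
    source raises ``KeyError`` naming the chain and number.
    """
    index = {(c, int(r)): i for i, (c, r) in
             enumerate(zip(source.chain_ids.tolist(),
                           source.residue_numbers.tolist()))}
    picked: list[int] = []
    seg_seqs: list[str] = []
    for seg in spec.segments:
        rows = []
        for num in range(seg.start, seg.end + 1):
            key = (seg.chain_id, num)
            if key not in index:
                raise KeyError(
                    f"residue {seg.chain_id}{num} not found in source structure")
            rows.append(index[key])
        picked.extend(rows)
        seg_seqs.append("".join(source.sequence[i] for i in rows))
    return source.subset(picked), seg_seqs


@dataclass(frozen=True)
class MotifPlacement:
    """A concrete embedding of the motif into a design of length L.

    ``motif_mask`` is True at motif positions; ``index_map`` maps each
    design position to its (segment id, offset into segment), covering
    exactly the motif positions; ``gap_lengths`` are the realized gaps in
    token order.
    """

    total_length: int
    motif_mask: np.ndarray
    index_map: dict[int, tuple[int, int]] = field(repr=False)
    gap_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        mask = np.asarray(self.motif_mask, dtype=bool)
        object.__setattr__(self, "motif_mask", mask)
        if mask.shape[0] != self.total_length:
            raise ValueError("motif mask length mismatch")
        if set(self.index_map) != set(np.flatnonzero(mask).tolist()):
            raise ValueError("index_map must cover exactly the motif positions")

    @property
    def motif_positions(self) -> np.ndarray:
        """Design indices of motif residues, in segment/token order."""
        pos = sorted(self.index_map, key=lambda p: self.index_map[p])
        return np.array(pos, dtype=int)

    @property
    def n_motif(self) -> int:
        return int(self.motif_mask.sum())

    def to_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "motif_positions": self.motif_positions.tolist(),
            "index_map": {str(k): list(v) for k, v in self.index_map.items()},
            "gap_lengths": list(self.gap_lengths),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotifPlacement":
        L = int(d["total_length"])
        index_map = {int(k): (int(v[0]), int(v[1]))
                     for k, v in d["index_map"].items()}
        mask = np.zeros(L, dtype=bool)
        mask[list(index_map)] = True
        return cls(total_length=L, motif_mask=mask, index_map=index_map,
                   gap_lengths=tuple(int(g) for g in d.get("gap_lengths", ())))


def sample_placement(spec: ContigSpec, seed: int = 0) -> MotifPlacement:
    """Realize a design length by sampling each gap uniformly over its
    closed integer interval. Deterministic under seed; the motif residue
    count (and hence the mask's true count) is independent of the draw.
    """
    rng = np.random.default_rng(seed)
    gap_lengths: list[int] = []
    layout: list[tuple[str, int]] = []  # ("gap", len) or ("seg", seg_id)
    seg_id = 0
    for tok in spec.tokens:
        if isinstance(tok, Gap):
            g = int(rng.integers(tok.min_len, tok.max_len + 1))
            gap_lengths.append(g)
            layout.append(("gap", g))
        else:
            layout.append(("seg", seg_id))
            seg_id += 1

    index_map: dict[int, tuple[int, int]] = {}
    pos = 0
    for kind, val in layout:
        if kind == "gap":
            pos += val
        else:
            seg = spec.segments[val]
            for off in range(len(seg)):
                index_map[pos] = (val, off)
                pos += 1
    L = pos
    mask = np.zeros(L, dtype=bool)
    mask[list(index_map)] = True
    return MotifPlacement(total_length=L, motif_mask=mask,
                          index_map=index_map, gap_lengths=tuple(gap_lengths))
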