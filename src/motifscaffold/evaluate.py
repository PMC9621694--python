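"""Design-quality metrics and the threshold filter pipeline.

The in-silico screen used throughout motif-scaffolding campaigns: predict
the design's structure with an independent network, then demand high
confidence (pLDDT), accurate recapitulation of the functional site
(motif RMSD), and — for binder/target complexes — a confident interface
(inter-PAE) and a binder that lands where intended after aligning only
the target (target-aligned binder RMSD). Comparators are strict
inequalities as printed in the usual filter sets ("pLDDT > 80",
"motif RMSD < 1.4 A"): boundary-equal values fail.

This module computes the metrics from any :class:`PredictionResult`-shaped
object and applies declarative criteria; it does not run any prediction
network itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

from .contigs import MotifPlacement
from .geometry import BackboneStructure, kabsch_superpose, rmsd
from .losses import MotifCoordRMSD, LossContext

__all__ = [
    "DesignMetrics",
    "Criterion",
    "FilterCriteria",
    "motif_rmsd_metric",
    "region_mean_plddt",
    "inter_pae",
    "target_aligned_rmsd",
    "filter_designs",
]


@dataclass
class DesignMetrics:
    """Metric bundle for one design. Two-chain-only fields stay ``None``
    for monomers."""

    plddt_mean: float
    motif_rmsd: float | None = None
    inter_pae: float | None = None
    target_aligned_rmsd: float | None = None
    extras: dict[str, float] = field(default_factory=dict)

    def get(self, name: str) -> float:
        if name in self.extras:
            return self.extras[name]
        value = getattr(self, name, None)
        if value is None:
            raise KeyError(f"metric {name!r} not present")
        return value


def motif_rmsd_metric(pred_coords: BackboneStructure,
                      native_motif: BackboneStructure,
                      placement: MotifPlacement,
                      atoms: Sequence[str] = ("N", "CA", "C")) -> float:
    """Kabsch-superposed backbone RMSD of the predicted motif region
    against the native motif (reporting-side alias of the coordinate
    motif-reconstruction loss). Default atoms N/CA/C; pass ``("CA",)``
    for CA-only."""
    class _P:
        coords = pred_coords
    return MotifCoordRMSD(atoms=tuple(atoms)).evaluate(
        _P, LossContext(placement=placement, native_motif=native_motif))


def region_mean_plddt(plddt: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean confidence over the selected residues."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    return float(np.asarray(plddt, dtype=float)[mask].mean())


def inter_pae(pae: np.ndarray, chain_boundary: int,
              aggregate: str = "mean") -> float:
    """Aggregate predicted aligned error over the two off-diagonal chain
    blocks of a binder/target complex (mean by default, median via
    ``aggregate``)."""
    pae = np.asarray(pae, dtype=float)
    L = pae.shape[0]
    if not (0 < chain_boundary < L):
        raise ValueError("chain boundary out of range")
    values = np.concatenate([
        pae[:chain_boundary, chain_boundary:].ravel(),
        pae[chain_boundary:, :chain_boundary].ravel(),
    ])
    if aggregate == "mean":
        return float(values.mean())
    if aggregate == "median":
        return float(np.median(values))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def target_aligned_rmsd(pred: BackboneStructure,
                        reference: BackboneStructure,
                        chain_boundary: int,
                        atoms: Sequence[str] = ("N", "CA", "C")) -> float:
    """Binder-chain RMSD after superposing only the target chain.

    The complex is split at ``chain_boundary`` into binder [0, boundary)
    and target [boundary, L). The predicted target chain is superposed
    onto the reference target chain; the resulting transform is applied
    to the whole prediction and the binder RMSD is measured *without*
    re-superposition, so rigid displacement of the binder relative to the
    target is fully visible.
    """
    if len(pred) != len(reference):
        raise ValueError("complex length mismatch")
    L = len(pred)
    if not (0 < chain_boundary < L):
        raise ValueError("chain boundary out of range")
    target_idx = range(chain_boundary, L)
    binder_idx = range(0, chain_boundary)
    if len(range(chain_boundary, L)) < 3:
        raise ValueError("target chain too short for superposition")
    fit = kabsch_superpose(
        pred.subset(target_idx).backbone_coords(atoms),
        reference.subset(target_idx).backbone_coords(atoms))
    moved = pred.transformed(fit.rotation, fit.translation)
    return rmsd(moved.subset(binder_idx).backbone_coords(atoms),
                reference.subset(binder_idx).backbone_coords(atoms),
                superpose=False)


# ---------------------------------------------------------------------------
# Filter pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Criterion:
    """One strict-inequality threshold on a named metric."""

    metric: str
    comparator: str     # "<" or ">"
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in ("<", ">"):
            raise ValueError("comparator must be '<' or '>'")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def passes(self, value: float) -> bool:
        return value < self.threshold if self.comparator == "<" \
            else value > self.threshold


@dataclass(frozen=True)
class FilterCriteria:
    """A conjunction of criteria: a design passes iff all hold."""

    criteria: tuple[Criterion, ...]

    @classmethod
    def from_list(cls, entries: Iterable[dict]) -> "FilterCriteria":
        return cls(tuple(
            Criterion(e["metric"], e["comparator"], float(e["threshold"]))
            for e in entries))

    @classmethod
    def from_yaml(cls, text: str) -> "FilterCriteria":
        return cls.from_list(yaml.safe_load(text))

    def to_list(self) -> list[dict]:
        return [{"metric": c.metric, "comparator": c.comparator,
                 "threshold": c.threshold} for c in self.criteria]


#: The monomer screen used for most campaigns: confident prediction and
#: accurate site recapitulation.
MONOMER_CRITERIA = FilterCriteria((
    Criterion("plddt_mean", ">", 80.0),
    Criterion("motif_rmsd", "<", 1.4),
))

#: The two-chain binder screen (the published set also includes an
#: atom-level surface-aggregation score, out of scope here).
BINDER_CRITERIA = FilterCriteria((
    Criterion("inter_pae", "<", 7.0),
    Criterion("target_aligned_rmsd", "<", 5.0),
    Criterion("plddt_mean", ">", 85.0),
))


def filter_designs(metrics: Sequence[DesignMetrics],
                   criteria: FilterCriteria
                   ) -> tuple[list[bool], dict[str, int]]:
    """Apply the criteria to every design.

    Returns per-design pass flags plus a summary with total, passing and
    per-criterion failure counts. An empty criteria list passes
    everything; a missing metric raises ``KeyError``.
    """
    flags: list[bool] = []
    fail_counts = {f"{c.metric}{c.comparator}{c.threshold:g}": 0
                   for c in criteria.criteria}
    for m in metrics:
        ok = True
        for c in criteria.criteria:
            if not c.passes(m.get(c.metric)):
                fail_counts[f"{c.metric}{c.comparator}{c.threshold:g}"] += 1
                ok = False
        flags.append(ok)
    summary = {"n_designs": len(flags), "n_pass": sum(flags),
               **{f"n_fail[{k}]": v for k, v in fail_counts.items()}}
    return flags, summary
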