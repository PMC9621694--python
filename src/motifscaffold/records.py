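"""Design records: the serializable carrier for one design's sequence,
structure reference, loss breakdown, metrics and provenance.

Provenance (seed, config hash, tool version, stage list) is sufficient to
re-run a design deterministically; serialization round-trips losslessly
through JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

from .contigs import MotifPlacement

__all__ = ["DesignRecord", "config_hash"]


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DesignRecord:
    """One designed protein and how it was produced."""

    design_id: str
    contig: str
    placement: MotifPlacement | None
    sequence: str
    structure_path: str | None = None
    loss_breakdown: dict[str, dict[str, float]] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "design_id": self.design_id,
            "contig": self.contig,
            "placement": self.placement.to_dict() if self.placement else None,
            "sequence": self.sequence,
            "structure_path": self.structure_path,
            "loss_breakdown": self.loss_breakdown,
            "metrics": self.metrics,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignRecord":
        placement = (MotifPlacement.from_dict(d["placement"])
                     if d.get("placement") else None)
        return cls(
            design_id=d["design_id"],
            contig=d["contig"],
            placement=placement,
            sequence=d["sequence"],
            structure_path=d.get("structure_path"),
            loss_breakdown=d.get("loss_breakdown", {}),
            metrics=d.get("metrics", {}),
            provenance=d.get("provenance", {}),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DesignRecord":
        return cls.from_dict(json.loads(text))
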