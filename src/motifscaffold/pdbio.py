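"""PDB-format reading/writing and design-record output.

Only ATOM records of backbone atoms are consumed; residues missing any of
N/CA/C are dropped with a logged warning (they violate the backbone
invariant). On output the B-factor column carries per-residue confidence
(pLDDT, 0-100), a common convention for predicted structures. mmCIF,
multi-model files, altlocs and insertion codes are out of scope.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np

from .geometry import BackboneStructure, one_to_three, three_to_one
from .records import DesignRecord

__all__ = ["read_structure", "write_structure", "write_design"]

logger = logging.getLogger(__name__)

_BACKBONE = ("N", "CA", "C")


def read_structure(path: str | Path) -> BackboneStructure:
    """Parse the first model of a PDB file into a backbone structure.

    Chains and 1-based residue numbers are preserved. Duplicate
    (chain, residue, atom) entries are an error; a file with no parsable
    ATOM records is an error.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    chains, numbers, letters = [], [], []
    coords = {a: [] for a in _BACKBONE}
    n_atoms = 0
    for chain in model:
        for residue in chain:
            atoms: dict[str, np.ndarray] = {}
            for atom in residue:
                if atom.name in _BACKBONE:
                    if atom.name in atoms:
                        raise ValueError(
                            f"duplicate atom {atom.name} in "
                            f"{chain.name}{residue.seqid.num}")
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z])
                    n_atoms += 1
            if not atoms:
                continue
            missing = [a for a in _BACKBONE if a not in atoms]
            if missing:
                logger.warning(
                    "dropping residue %s%d: missing backbone atom(s) %s",
                    chain.name, residue.seqid.num, ",".join(missing))
                continue
            chains.append(chain.name[:1] or "A")
            numbers.append(residue.seqid.num)
            letters.append(three_to_one(residue.name))
            for a in _BACKBONE:
                coords[a].append(atoms[a])
    if n_atoms == 0:
        raise ValueError(f"no parsable backbone ATOM records in {path}")
    if not chains:
        raise ValueError(f"no complete backbone residues in {path}")
    # file-convention invariant: numbering strictly increasing per chain
    for cid in dict.fromkeys(chains):
        nums = [n for c, n in zip(chains, numbers) if c == cid]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(
                f"residue numbers not strictly increasing in chain {cid}")
    return BackboneStructure(
        chain_ids=np.array(chains), residue_numbers=np.array(numbers),
        sequence="".join(letters),
        n=np.array(coords["N"]), ca=np.array(coords["CA"]),
        c=np.array(coords["C"]))


def write_structure(structure: BackboneStructure, path: str | Path,
                    plddt: np.ndarray | None = None) -> None:
    """Write backbone ATOM records; B-factor column = per-residue
    confidence when given (0-100), else 0."""
    st = gemmi.Structure()
    st.name = Path(path).stem
    model = gemmi.Model("1")
    bfac = np.zeros(len(structure)) if plddt is None else np.asarray(plddt)
    current_chain = None
    chain_obj = None
    for i in range(len(structure)):
        cid = str(structure.chain_ids[i])
        if cid != current_chain:
            chain_obj = gemmi.Chain(cid)
            model.add_chain(chain_obj)
            chain_obj = model[-1]
            current_chain = cid
        res = gemmi.Residue()
        res.name = one_to_three(structure.sequence[i])
        res.seqid = gemmi.SeqId(int(structure.residue_numbers[i]), " ")
        for name, arr, elem in (("N", structure.n, "N"),
                                ("CA", structure.ca, "C"),
                                ("C", structure.c, "C")):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*arr[i])
            atom.occ = 1.0
            atom.b_iso = float(bfac[i])
            res.add_atom(atom)
        chain_obj.add_residue(res)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_design(record: DesignRecord, outdir: str | Path,
                 structure: BackboneStructure | None = None,
                 plddt: np.ndarray | None = None) -> dict[str, Path]:
    """Emit the standard design outputs into ``outdir``.

    Writes ``<id>.pdb`` (when a structure is given; confidence in the
    B-factor column), ``<id>.fasta`` (header carries the design id and
    contig string) and ``<id>.json`` (the full record). Idempotent:
    re-running with the same inputs rewrites identical files. Returns the
    paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if structure is not None:
        pdb_path = outdir / f"{record.design_id}.pdb"
        write_structure(structure, pdb_path, plddt=plddt)
        record.structure_path = pdb_path.name
        paths["pdb"] = pdb_path
    fasta_path = outdir / f"{record.design_id}.fasta"
    header = f">{record.design_id} contig={record.contig}"
    fasta_path.write_text(f"{header}\n{record.sequence}\n")
    paths["fasta"] = fasta_path
    json_path = outdir / f"{record.design_id}.json"
    json_path.write_text(record.to_json() + "\n")
    paths["json"] = json_path
    return paths
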