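"""Crystal-structure contact analysis around the helix-bundle-crossing gate.

Reads PDB/mmCIF coordinates, builds the tetrameric biological assembly from
the file's operators, measures Cbeta-Cbeta distances within or between
subunits in the HBC-open versus HBC-closed structures, and applies a simple
steric heuristic: a bulkier side chain at a contact that is tighter in the
open structure destabilizes the open gate and shifts the conformational
equilibrium toward the closed (C) state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "StructureModel",
    "Assembly",
    "ContactChange",
    "MutationEffect",
    "RESIDUE_VOLUMES_A3",
    "read_structure",
    "build_assembly",
    "cb_distance",
    "contact_change_table",
    "predict_equilibrium_shift",
    "fetch_structure",
]

#: Mean amino-acid side-chain/residue volumes (A^3), Zamyatnin (1972).
#: Only the sign of a volume change is used by the prediction heuristic.
#: Note Ile and Leu share the same mean volume in this table, so isomeric
#: substitutions register as "no volume change".
RESIDUE_VOLUMES_A3 = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}


@dataclass
class StructureModel:
    """First model of a coordinate file with its assembly operators.

    ``atoms`` maps ``(chain, residue_number, atom_name)`` to
    ``(residue_name, xyz)`` after altloc resolution (highest occupancy, ties
    broken alphabetically).  ``assembly_ops`` is a list of ``(R, t)`` pairs.
    """

    source_id: str
    atoms: dict
    assembly_ops: list

    def chains(self) -> list:
        return sorted({key[0] for key in self.atoms})

    def default_chain(self, lo: int = 22, hi: int = 124) -> str:
        """Chain with the most residues numbered in [lo, hi] (the KcsA
        transmembrane pore range)."""
        counts: dict = {}
        for (chain, resnum, atom) in self.atoms:
            if atom == "CA" and lo <= resnum <= hi:
                counts[chain] = counts.get(chain, 0) + 1
        if not counts:  # fall back to any atom
            for (chain, resnum, _a) in self.atoms:
                if lo <= resnum <= hi:
                    counts[chain] = counts.get(chain, 0) + 1
        if not counts:
            raise ValueError("no chain has residues in the expected range")
        return max(sorted(counts), key=counts.get)


@dataclass
class Assembly:
    """Symmetry copies of one structure; ``copies[k]`` is an atom dict like
    :attr:`StructureModel.atoms` transformed by operator k."""

    source_id: str
    copies: list


def read_structure(path: str) -> StructureModel:
    """Parse a PDB or mmCIF file (first model only).

    Altloc alternatives are resolved to the highest-occupancy atom (ties ->
    alphabetically first altloc id); biological-assembly operators are taken
    from the file's first assembly (REMARK 350 / _pdbx_struct_assembly), with
    identity-only as the warned fallback.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    atoms: dict = {}
    best: dict = {}
    for chain in model:
        for res in chain:
            for atom in res:
                key = (chain.name, res.seqid.num, atom.name)
                rank = (atom.occ, -ord(atom.altloc or "A"))
                if key not in best or rank > best[key]:
                    best[key] = rank
                    atoms[key] = (
                        res.name,
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
    ops = []
    if len(st.assemblies) > 0:
        asm = st.assemblies[0]
        for gen in asm.generators:
            for op in gen.operators:
                tr = op.transform
                r = np.array(tr.mat.tolist())
                t = np.array(tr.vec.tolist())
                ops.append((r, t))
    if not ops:
        warnings.warn(
            f"{path}: no biological-assembly operators found; using identity "
            f"only (inter-subunit distances unavailable)",
            stacklevel=2,
        )
        ops = [(np.eye(3), np.zeros(3))]
    return StructureModel(source_id=st.name or str(path), atoms=atoms,
                          assembly_ops=ops)


def build_assembly(model: StructureModel) -> Assembly:
    """Apply every assembly operator to every atom."""
    copies = []
    for r, t in model.assembly_ops:
        det = np.linalg.det(r)
        if abs(det - 1.0) > 1e-3:
            raise ValueError(
                f"non-orthonormal rotation (det={det:.6f}) in assembly operators"
            )
        copy = {
            key: (resname, r @ xyz + t)
            for key, (resname, xyz) in model.atoms.items()
        }
        copies.append(copy)
    return Assembly(source_id=model.source_id, copies=copies)


def _get_cb(copy: dict, chain: str, resnum: int) -> np.ndarray:
    key = (chain, resnum, "CB")
    if key not in copy:
        name = next(
            (rn for (c, r, _a), (rn, _x) in copy.items()
             if c == chain and r == resnum),
            None,
        )
        if name is None:
            raise KeyError(f"residue {resnum} not found in chain {chain}")
        raise KeyError(
            f"residue {chain}:{resnum} ({name}) has no CB atom"
            + (" (glycine has no side chain)" if name == "GLY" else "")
        )
    return copy[key][1]


def cb_distance(
    assembly: Assembly,
    residue_a: int,
    residue_b: int,
    chain: str,
    pairing_mode: str = "intra",
) -> float:
    """Cbeta-Cbeta distance in Angstrom between two residues.

    ``intra``: within the same assembly copy; ``inter``: minimum over pairs
    of distinct copies; ``min``: min(intra, inter).  Reported at full
    precision; round to 0.1 A for display.
    """
    if pairing_mode not in ("intra", "inter", "min"):
        raise ValueError("pairing_mode must be intra, inter or min")
    n = len(assembly.copies)
    pos_a = [_get_cb(c, chain, residue_a) for c in assembly.copies]
    pos_b = [_get_cb(c, chain, residue_b) for c in assembly.copies]
    intra = min(
        float(np.linalg.norm(pos_a[k] - pos_b[k])) for k in range(n)
    )
    if pairing_mode == "intra":
        return intra
    if n < 2:
        raise ValueError("inter-subunit distance needs >= 2 assembly copies")
    inter = min(
        float(np.linalg.norm(pos_a[k] - pos_b[m]))
        for k in range(n)
        for m in range(n)
        if k != m
    )
    return inter if pairing_mode == "inter" else min(intra, inter)


@dataclass
class ContactChange:
    """Open-vs-closed change of one Cbeta-Cbeta contact."""

    residue_a: int
    residue_b: int
    d_closed: float
    d_open: float
    pairing_mode: str = "intra"

    @property
    def delta(self) -> float:
        return self.d_open - self.d_closed


def contact_change_table(
    closed_assembly: Assembly,
    open_assembly: Assembly,
    pairs: list,
    chain_closed: str,
    chain_open: str,
    pairing_mode: str = "intra",
) -> tuple[list, list]:
    """One ContactChange per residue pair, sorted by delta.

    Unresolvable pairs (missing residue or Cbeta in either structure) go to
    the returned error list instead of aborting the whole table.
    """
    rows, errors = [], []
    for a, b in pairs:
        try:
            d_c = cb_distance(closed_assembly, a, b, chain_closed, pairing_mode)
            d_o = cb_distance(open_assembly, a, b, chain_open, pairing_mode)
            rows.append(ContactChange(a, b, d_c, d_o, pairing_mode))
        except KeyError as exc:
            errors.append((a, b, str(exc)))
    rows.sort(key=lambda r: r.delta)
    return rows, errors


@dataclass
class MutationEffect:
    site: int
    wt_residue: str
    mut_residue: str
    volume_change_a3: float
    prediction: str  # toward_C | none | toward_open


def predict_equilibrium_shift(
    change: ContactChange, wt_residue: str, mut_residue: str
) -> MutationEffect:
    """Steric prediction of the conformational-equilibrium shift.

    A bulkier side chain at a contact that is tighter in the open structure
    (delta < 0) disfavors the open gate -> ``toward_C``; a bulkier side chain
    at a contact that is not tighter when open -> ``none``; a smaller side
    chain at a tight open contact relieves the strain -> ``toward_open``.
    """
    wt = wt_residue.upper()
    mut = mut_residue.upper()
    for code in (wt, mut):
        if code not in RESIDUE_VOLUMES_A3:
            raise ValueError(f"unknown residue code {code!r}")
    dv = RESIDUE_VOLUMES_A3[mut] - RESIDUE_VOLUMES_A3[wt]
    tighter_open = change.delta < 0
    if dv > 0 and tighter_open:
        prediction = "toward_C"
    elif dv < 0 and tighter_open:
        prediction = "toward_open"
    else:
        prediction = "none"
    return MutationEffect(
        site=change.residue_b,
        wt_residue=wt,
        mut_residue=mut,
        volume_change_a3=dv,
        prediction=prediction,
    )


def fetch_structure(pdb_id: str, cache_dir: str = "scratch/structures") -> str:
    """Locate (or download) a PDB entry and return the local file path.

    Looks for ``<cache_dir>/<id>.pdb`` or ``.cif`` first; otherwise attempts
    an RCSB download, which requires network access.
    """
    import pathlib
    import urllib.request

    pdb_id = pdb_id.upper()
    cache = pathlib.Path(cache_dir)
    for ext in (".pdb", ".cif"):
        p = cache / f"{pdb_id}{ext}"
        if p.exists():
            return str(p)
    cache.mkdir(parents=True, exist_ok=True)
    url = f"https://files.rcsb.org/download/{pdb_id}.cif"
    dest = cache / f"{pdb_id}.cif"
    try:
        with urllib.request.urlopen(url, timeout=15) as resp:
            dest.write_bytes(resp.read())
    except Exception as exc:
        raise FileNotFoundError(
            f"{pdb_id} not cached under {cache_dir} and RCSB download failed "
            f"({exc}); place the coordinate file there to run structure checks"
        ) from exc
    return str(dest)
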