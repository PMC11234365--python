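"""Atomic structure I/O, selections, superposition and RMSD.

Structures are plain records of atoms with coordinates in Å and masses in
amu. PDB reading/writing is delegated to gemmi; only the first model of a
multi-model file is read and only altloc '' / 'A' atoms are kept, so a
given file always yields the same deterministic atom list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import gemmi
import numpy as np

__all__ = [
    "Structure",
    "RigidTransform",
    "ParseError",
    "read_structure",
    "write_structure",
    "write_multi_model",
    "kabsch_superpose",
    "rmsd",
    "select_ca",
    "select_heavy",
    "common_selection",
]

# Masses in amu for the elements that occur in protein/nucleic structures.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "MN": 54.938, "NA": 22.990, "K": 39.098, "CL": 35.45,
    "CU": 63.546, "F": 18.998, "BR": 79.904, "I": 126.904,
}
DEFAULT_MASS = 12.011  # unknown elements are treated as carbon-like


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass
class Structure:
    """Atom records with coordinates (Å) and per-atom masses (amu).

    ``ss`` holds a one-letter secondary-structure code per atom
    ('H' helix, 'E' strand, 'C' coil), used by the secondary-structure
    restraints of the dynamics engine.
    """

    names: np.ndarray          # (N,) str atom names
    elements: np.ndarray       # (N,) str element symbols, upper case
    res_names: np.ndarray      # (N,) str residue names
    res_ids: np.ndarray        # (N,) int residue sequence numbers
    chain_ids: np.ndarray      # (N,) str chain identifiers
    coords: np.ndarray         # (N,3) float Å
    masses: np.ndarray         # (N,) float amu
    ss: np.ndarray | None = None  # (N,) str in {H,E,C}

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("structure must contain at least one atom")
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,):
            raise ValueError("masses/coords length mismatch")
        if not np.all(self.masses > 0):
            raise ValueError("all masses must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for attr in ("names", "elements", "res_names", "res_ids", "chain_ids"):
            setattr(self, attr, np.asarray(getattr(self, attr)))
        if self.ss is None:
            self.ss = np.full(n, "C", dtype="U1")
        else:
            self.ss = np.asarray(self.ss, dtype="U1")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Structure":
        return Structure(
            names=self.names.copy(), elements=self.elements.copy(),
            res_names=self.res_names.copy(), res_ids=self.res_ids.copy(),
            chain_ids=self.chain_ids.copy(), coords=self.coords.copy(),
            masses=self.masses.copy(), ss=self.ss.copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float).reshape(-1, 3))

    def residue_keys(self):
        """(chain, resid) per atom — the block key used by RTB and restraints."""
        return list(zip(self.chain_ids.tolist(), self.res_ids.tolist()))


@dataclass
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray    # (3,3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def _element_from_name(name: str) -> str:
    """Heuristic element from a PDB atom name (fallback when the element
    column is blank): strip digits/primes, try two-letter then one-letter."""
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        return ""
    # Names like FE/ZN/MG are genuine two-letter elements; names starting
    # with C/N/O/H/S/P (CA, ND1, OG, ...) are protein atoms of that element.
    if stripped[:2] in ELEMENT_MASSES and stripped[0] not in "CNOHSP":
        return stripped[:2]
    return stripped[0]


def read_structure(path) -> Structure:
    """Read the first model of a PDB file.

    Elements come from the element column when present, otherwise from an
    atom-name heuristic; masses from a built-in element table. Altlocs other
    than '' / 'A' are dropped.
    """
    # gemmi coerces malformed numeric fields to 0; validate coordinate
    # columns up front so a bad line fails loudly with its line number
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise ParseError(
                        f"{path}: unparsable coordinate field "
                        f"{fieldtxt!r} on line {lineno}") from None
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    model = st[0]

    names, elements, res_names, res_ids, chain_ids, coords = [], [], [], [], [], []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                el = atom.element.name.upper()
                if el in ("", "X"):
                    el = _element_from_name(atom.name)
                names.append(atom.name)
                elements.append(el)
                res_names.append(res.name)
                res_ids.append(res.seqid.num)
                chain_ids.append(chain.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not names:
        raise ParseError(f"{path}: no atoms in first model")
    masses = np.array([ELEMENT_MASSES.get(e, DEFAULT_MASS) for e in elements])
    return Structure(
        names=np.array(names), elements=np.array(elements),
        res_names=np.array(res_names), res_ids=np.array(res_ids, dtype=int),
        chain_ids=np.array(chain_ids), coords=np.array(coords),
        masses=masses,
    )


def _to_gemmi(s: Structure, model_num: int = 1) -> gemmi.Model:
    model = gemmi.Model(model_num)
    chain = None
    res = None
    prev = (None, None)
    serial = 0
    for i in range(s.n_atoms):
        cid = str(s.chain_ids[i])
        rid = int(s.res_ids[i])
        if chain is None or cid != chain.name:
            chain = model.add_chain(gemmi.Chain(cid))
            prev = (None, None)
        if prev != (cid, rid):
            r = gemmi.Residue()
            r.name = str(s.res_names[i])
            r.seqid = gemmi.SeqId(rid, " ")
            res = chain.add_residue(r)
            prev = (cid, rid)
        atom = gemmi.Atom()
        atom.name = str(s.names[i])
        # serial numbers wrap at 100000 (PDB fixed-column convention)
        serial += 1
        atom.serial = serial % 100000
        atom.element = gemmi.Element(str(s.elements[i]).capitalize())
        atom.pos = gemmi.Position(*s.coords[i])
        res.add_atom(atom)
    return model


def write_structure(s: Structure, path) -> None:
    """Write a Structure as a single-model PDB file."""
    st = gemmi.Structure()
    st.add_model(_to_gemmi(s))
    st.setup_entities()
    st.write_pdb(str(path))


def write_multi_model(structures, path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    st = gemmi.Structure()
    for i, s in enumerate(structures, start=1):
        st.add_model(_to_gemmi(s, model_num=i))
    st.setup_entities()
    st.write_pdb(str(path))


def select_ca(s: Structure) -> np.ndarray:
    """Indices of Cα atoms (falls back to all atoms if none are named CA)."""
    idx = np.flatnonzero(s.names == "CA")
    return idx if idx.size else np.arange(s.n_atoms)


def select_heavy(s: Structure) -> np.ndarray:
    """Indices of non-hydrogen atoms."""
    return np.flatnonzero(s.elements != "H")


def common_selection(a: Structure, b: Structure, names=("CA",)):
    """Matched selections over the intersection of (chain, resid, atom name).

    Used when start and target structures differ in residue content
    (e.g. crystal structures with different termini).
    """
    def keymap(s, names):
        out = {}
        for i in range(s.n_atoms):
            if names is not None and s.names[i] not in names:
                continue
            out[(str(s.chain_ids[i]), int(s.res_ids[i]), str(s.names[i]))] = i
        return out

    ka, kb = keymap(a, names), keymap(b, names)
    keys = sorted(set(ka) & set(kb))
    return (np.array([ka[k] for k in keys], dtype=int),
            np.array([kb[k] for k in keys], dtype=int))


def _validate_selection(s: Structure, sel) -> np.ndarray:
    if sel is None:
        return np.arange(s.n_atoms)
    sel = np.asarray(sel, dtype=int)
    if sel.size and (sel.min() < 0 or sel.max() >= s.n_atoms):
        raise IndexError("selection index out of range")
    if np.unique(sel).size != sel.size:
        raise ValueError("selection indices must be unique")
    return sel


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Rotation R and translation t minimising |R P + t - Q|² (row vectors)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def kabsch_superpose(mobile: Structure, reference: Structure,
                     sel=None, sel_ref=None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(RigidTransform, rmsd)`` where the transform applied to the
    mobile coordinates minimises the RMSD over the selection.
    """
    sa = _validate_selection(mobile, sel)
    sb = _validate_selection(reference, sel_ref if sel_ref is not None else sel)
    if sa.size != sb.size:
        raise ValueError("selection lengths differ")
    if sa.size < 3:
        raise ValueError("need at least 3 atoms to superpose")
    P, Q = mobile.coords[sa], reference.coords[sb]
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection")
    R, t = _kabsch(P, Q)
    tr = RigidTransform(R, t)
    diff = tr.apply(P) - Q
    return tr, float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd(a: Structure, b: Structure, sel=None, sel_b=None,
         superpose: bool = True) -> float:
    """RMSD in Å between two structures over a selection (default: all atoms;
    pass ``select_ca(a)`` for the conventional Cα RMSD).

    With ``superpose=True`` the Kabsch-minimised RMSD is returned, otherwise
    the raw coordinate RMSD.
    """
    sa = _validate_selection(a, sel)
    sb = _validate_selection(b, sel_b if sel_b is not None else sel)
    if sa.size != sb.size:
        raise ValueError("selection lengths differ")
    if superpose:
        _, value = kabsch_superpose(a, b, sa, sb)
        return value
    diff = a.coords[sa] - b.coords[sb]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
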