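"""Coordinate data model: structure models, bundles, selections and PDB I/O.

A :class:`StructureModel` is a flat, array-backed record of atoms
(residue index, residue type, atom name, element, chain, xyz).  A
:class:`StructureBundle` is an ordered list of models sharing one
topology (identical atom ordering), as deposited NMR ensembles are.

Selections use a small mini-language::

    selection  := clause ( "and" clause )*
    clause     := "all"
                | "backbone" | "heavy" | "sidechain"
                | "resid" range ( range )*        # range := INT | INT "-" INT
                | "name" NAME+
                | "chain" NAME+

e.g. ``"resid 6-165 and backbone"`` or ``"resid 21-32 and name CA CB"``.
Clauses are conjunctive; within a clause, alternatives are disjunctive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL"
).split()


class SelectionError(ValueError):
    """Raised for malformed selection strings or degenerate selections."""


@dataclass
class StructureModel:
    """One coordinate model over a fixed set of atoms.

    Parameters
    ----------
    res_index : (n,) int array, 1-based residue numbers, non-decreasing.
    res_type : (n,) array of 3-letter residue codes.
    atom_name : (n,) array of atom names, unique within a residue.
    element : (n,) array of element symbols.
    coords : (n, 3) float array, Angstrom.
    chain : (n,) array of single-letter chain identifiers.
    model_id : integer label (PDB MODEL number).
    """

    res_index: np.ndarray
    res_type: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    chain: np.ndarray = field(default=None)  # type: ignore[assignment]
    model_id: int = 1

    def __post_init__(self) -> None:
        self.res_index = np.asarray(self.res_index, dtype=int)
        self.res_type = np.asarray(self.res_type, dtype="U4")
        self.atom_name = np.asarray(self.atom_name, dtype="U5")
        self.element = np.asarray(self.element, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.res_index)
        if self.chain is None:
            self.chain = np.full(n, "A", dtype="U2")
        else:
            self.chain = np.asarray(self.chain, dtype="U2")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        # residue indices non-decreasing within each chain
        for ch in np.unique(self.chain):
            idx = self.res_index[self.chain == ch]
            if np.any(np.diff(idx) < 0):
                raise ValueError(f"residue indices decrease within chain {ch}")
        keys = list(zip(self.chain, self.res_index, self.atom_name))
        if len(set(keys)) != n:
            raise ValueError("duplicate atom name within a residue")

    @property
    def n_atoms(self) -> int:
        return len(self.res_index)

    @property
    def residues(self) -> np.ndarray:
        """Sorted unique residue indices."""
        return np.unique(self.res_index)

    def copy(self, coords: np.ndarray | None = None, model_id: int | None = None
             ) -> "StructureModel":
        return StructureModel(
            self.res_index.copy(), self.res_type.copy(), self.atom_name.copy(),
            self.element.copy(),
            self.coords.copy() if coords is None else np.asarray(coords, float),
            self.chain.copy(),
            self.model_id if model_id is None else model_id,
        )

    # -- selection ---------------------------------------------------------

    def select(self, selection: str) -> np.ndarray:
        """Return the boolean atom mask for a selection expression."""
        return _parse_selection(selection)(self)

    def atom_index(self, res_index: int, atom_name: str,
                   chain: str | None = None) -> int:
        """Index of a single atom; raises ``KeyError`` if absent or ambiguous."""
        mask = (self.res_index == res_index) & (self.atom_name == atom_name)
        if chain is not None:
            mask &= self.chain == chain
        hits = np.flatnonzero(mask)
        if len(hits) == 0:
            raise KeyError(f"atom {res_index}/{atom_name} not found")
        if len(hits) > 1:
            raise KeyError(f"atom {res_index}/{atom_name} is ambiguous "
                           f"({len(hits)} matches); specify chain")
        return int(hits[0])


@dataclass
class StructureBundle:
    """Ordered set of topologically identical models."""

    models: list

    def __post_init__(self) -> None:
        if len(self.models) < 1:
            raise ValueError("bundle needs at least one model")
        ref = self.models[0]
        for m in self.models[1:]:
            same = (
                m.n_atoms == ref.n_atoms
                and np.array_equal(m.res_index, ref.res_index)
                and np.array_equal(m.atom_name, ref.atom_name)
                and np.array_equal(m.chain, ref.chain)
            )
            if not same:
                raise ValueError("models in a bundle must share atom ordering")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]

    @property
    def topology(self) -> StructureModel:
        return self.models[0]

    @property
    def coords(self) -> np.ndarray:
        """(n_models, n_atoms, 3) stacked coordinates."""
        return np.stack([m.coords for m in self.models])


# ---------------------------------------------------------------------------
# selection mini-language


def _parse_ranges(tokens: list) -> set:
    out: set = set()
    for tok in tokens:
        if "-" in tok:
            lo, hi = tok.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(tok))
    return out


def _parse_selection(text: str):
    clauses = []
    for part in text.split(" and "):
        toks = part.split()
        if not toks:
            raise SelectionError(f"empty clause in {text!r}")
        head, rest = toks[0].lower(), toks[1:]
        if head == "all":
            clauses.append(lambda m: np.ones(m.n_atoms, bool))
        elif head == "backbone":
            clauses.append(lambda m: np.isin(m.atom_name, BACKBONE_ATOMS))
        elif head == "heavy":
            clauses.append(lambda m: m.element != "H")
        elif head == "sidechain":
            clauses.append(lambda m: (~np.isin(m.atom_name, BACKBONE_ATOMS))
                           & (m.element != "H"))
        elif head == "resid":
            if not rest:
                raise SelectionError("resid needs at least one range")
            wanted = _parse_ranges(rest)
            clauses.append(
                lambda m, w=np.array(sorted(wanted)): np.isin(m.res_index, w))
        elif head == "name":
            if not rest:
                raise SelectionError("name needs at least one atom name")
            clauses.append(lambda m, names=tuple(rest): np.isin(m.atom_name, names))
        elif head == "chain":
            if not rest:
                raise SelectionError("chain needs at least one identifier")
            clauses.append(lambda m, ch=tuple(rest): np.isin(m.chain, ch))
        else:
            raise SelectionError(f"unknown selection keyword {head!r}")

    def apply(model: StructureModel) -> np.ndarray:
        mask = np.ones(model.n_atoms, bool)
        for c in clauses:
            mask &= c(model)
        return mask

    return apply


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)


def _to_atom_array(model: StructureModel):
    import biotite.structure as struc

    arr = struc.AtomArray(model.n_atoms)
    arr.res_id = model.res_index
    arr.res_name = model.res_type
    arr.atom_name = model.atom_name
    arr.element = model.element
    arr.chain_id = model.chain
    arr.coord = model.coords
    arr.hetero = np.zeros(model.n_atoms, bool)
    return arr


def _from_atom_array(arr, model_id: int) -> StructureModel:
    return StructureModel(
        res_index=np.asarray(arr.res_id),
        res_type=np.asarray(arr.res_name),
        atom_name=np.asarray(arr.atom_name),
        element=np.asarray(arr.element),
        coords=np.asarray(arr.coord, float),
        chain=np.asarray(arr.chain_id),
        model_id=model_id,
    )


def write_pdb(path, obj) -> None:
    """Write a model or bundle as a (multi-MODEL) PDB v3.3 file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    models = obj.models if isinstance(obj, StructureBundle) else [obj]
    arrays = [_to_atom_array(m) for m in models]
    stack = struc.stack(arrays)
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_pdb(path) -> StructureBundle:
    """Read a PDB file into a bundle (single-model files give length 1)."""
    from biotite.structure.io.pdb import PDBFile

    f = PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    # drop waters / hetero and hydrogens are kept; caller filters by selection
    models = [_from_atom_array(stack[i], model_id=i + 1)
              for i in range(stack.stack_depth())]
    return StructureBundle(models)


def pdb_string(obj) -> str:
    """PDB text for a model or bundle (convenience for tests)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    models = obj.models if isinstance(obj, StructureBundle) else [obj]
    stack = struc.stack([_to_atom_array(m) for m in models])
    f = PDBFile()
    f.set_structure(stack)
    buf = io.StringIO()
    f.write(buf)
    return buf.getvalue()
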