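"""Structure-bundle analytics: superposition, RMSD, H-bonds, helix building.

Regional RMSD follows the global-then-local convention: superpose on the
global selection, then evaluate the RMSD over the region *without*
re-fitting (``fit='local'`` switches to an independent regional fit).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import StructureBundle, StructureModel


@dataclass
class Superposition:
    rotation: np.ndarray     # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float
    selection: str = ""

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class HBond:
    donor: tuple             # (res_index, atom_name)
    acceptor: tuple
    distance: float          # heavy-atom donor..acceptor, Angstrom
    angle: float | None = None  # D-H...A, degrees, when H present


@dataclass
class HelicalParams:
    """Per-subunit helical twist (degrees) and rise (Angstrom)."""

    twist: float
    rise: float
    n_subunits: int

    def __post_init__(self):
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple:
    """Least-squares rotation/translation mapping ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` the fitted mapping.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("need matched selections of >= 3 atoms")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    a = mobile - mc
    b = target - tc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:
        raise ValueError("degenerate (collinear) selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = tc - rot @ mc
    fitted = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return rot, t, rmsd


def superpose_rmsd(a: StructureModel, b: StructureModel,
                   selection: str = "all") -> Superposition:
    """Optimal superposition of ``b`` onto ``a`` over a shared selection."""
    mask_a = a.select(selection)
    mask_b = b.select(selection)
    xa, xb = a.coords[mask_a], b.coords[mask_b]
    if xa.shape != xb.shape:
        raise ValueError(
            f"selection {selection!r} maps {mask_a.sum()} atoms in A but "
            f"{mask_b.sum()} in B")
    rot, t, rmsd = kabsch(xb, xa)
    return Superposition(rotation=rot, translation=t, rmsd=rmsd,
                         selection=selection)


def bundle_pairwise_rmsd(bundle: StructureBundle, selection: str = "all"
                         ) -> tuple:
    """Mean and sd of superposed RMSD over all model pairs."""
    if len(bundle) < 2:
        raise ValueError("pairwise RMSD needs >= 2 models")
    vals = [superpose_rmsd(bundle[i], bundle[j], selection).rmsd
            for i, j in itertools.combinations(range(len(bundle)), 2)]
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def region_rmsd(a: StructureModel, b: StructureModel,
                global_selection: str, region_selection: str,
                fit: str = "global") -> tuple:
    """(global rmsd, regional rmsd) with the stated fitting convention."""
    sup = superpose_rmsd(a, b, global_selection)
    if fit == "local":
        return sup.rmsd, superpose_rmsd(a, b, region_selection).rmsd
    mask_a = a.select(region_selection)
    mask_b = b.select(region_selection)
    xa, xb = a.coords[mask_a], b.coords[mask_b]
    if len(xa) == 0:
        raise ValueError(f"empty region selection {region_selection!r}")
    if xa.shape != xb.shape:
        raise ValueError("region selection size mismatch between models")
    fitted = sup.apply(xb)
    regional = float(np.sqrt(np.mean(np.sum((fitted - xa) ** 2, axis=1))))
    return sup.rmsd, regional


def atom_distance(model: StructureModel, sel1: tuple, sel2: tuple) -> float:
    """Euclidean distance between two uniquely selected atoms.

    Selectors are ``(res_index, atom_name)`` or ``(res_index, atom_name,
    chain)`` tuples.
    """
    k1 = model.atom_index(*sel1)
    k2 = model.atom_index(*sel2)
    return float(np.linalg.norm(model.coords[k1] - model.coords[k2]))


def detect_hbonds(obj, donor_name: str = "N", acceptor_name: str = "O",
                  cutoff: float = 3.5, angle_min: float = 120.0,
                  min_separation: int = 2):
    """Hydrogen bonds by heavy-atom geometry.

    Pairs with donor..acceptor distance <= ``cutoff`` are reported; when an
    amide hydrogen is present the D-H...A angle must also be >=
    ``angle_min``.  Donor/acceptor pairs closer than ``min_separation`` in
    sequence are skipped (they are covalent neighbours, not H-bonds).

    For a bundle, returns ``(hbonds_of_first_model, per_pair_mean_distance)``
    where the mean is over all models for every pair detected in any model.
    """
    if isinstance(obj, StructureBundle):
        per_model = [detect_hbonds(m, donor_name, acceptor_name, cutoff,
                                   angle_min, min_separation) for m in obj]
        pairs = sorted({(hb.donor, hb.acceptor)
                        for hbs in per_model for hb in hbs})
        means = {}
        for donor, acceptor in pairs:
            ds = [atom_distance(m, donor, acceptor) for m in obj]
            means[(donor, acceptor)] = float(np.mean(ds))
        return per_model[0], means

    model = obj
    donors = np.flatnonzero(model.atom_name == donor_name)
    acceptors = np.flatnonzero(model.atom_name == acceptor_name)
    out = []
    for kd in donors:
        for ka in acceptors:
            if abs(int(model.res_index[kd]) - int(model.res_index[ka])) \
                    < min_separation:
                continue
            d = float(np.linalg.norm(model.coords[kd] - model.coords[ka]))
            if d > cutoff:
                continue
            angle = None
            try:
                kh = model.atom_index(int(model.res_index[kd]),
                                      "H" + donor_name[1:])
            except KeyError:
                kh = None
            if kh is not None:
                v1 = model.coords[kd] - model.coords[kh]
                v2 = model.coords[ka] - model.coords[kh]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1)
                                           * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if angle < angle_min:
                    continue
            out.append(HBond(
                donor=(int(model.res_index[kd]), donor_name),
                acceptor=(int(model.res_index[ka]), acceptor_name),
                distance=d, angle=angle))
    return out


# ---------------------------------------------------------------------------
# helical assembly

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def rotation_about_z(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_helical_assembly(protomer: StructureModel, params: HelicalParams
                           ) -> StructureModel:
    """Filament from one protomer: subunit k is rotated by ``k * twist``
    about z and translated ``k * rise`` along z; chains lettered in order.
    """
    if params.n_subunits > len(_CHAIN_IDS):
        raise ValueError(f"at most {len(_CHAIN_IDS)} subunits supported")
    parts = []
    for k in range(params.n_subunits):
        rot = rotation_about_z(k * params.twist)
        coords = protomer.coords @ rot.T
        coords = coords + np.array([0.0, 0.0, k * params.rise])
        parts.append((coords, _CHAIN_IDS[k]))
    n = protomer.n_atoms
    return StructureModel(
        res_index=np.tile(protomer.res_index, params.n_subunits),
        res_type=np.tile(protomer.res_type, params.n_subunits),
        atom_name=np.tile(protomer.atom_name, params.n_subunits),
        element=np.tile(protomer.element, params.n_subunits),
        coords=np.concatenate([c for c, _ in parts]),
        chain=np.concatenate([np.full(n, ch, dtype="U2")
                              for _, ch in parts]),
        model_id=protomer.model_id)
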