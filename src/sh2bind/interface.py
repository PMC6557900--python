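"""Interface metrics for protein-peptide complexes.

Reads PDB/mmCIF coordinates (via gemmi), computes Shrake-Rupley solvent-
accessible surface areas (SASA), buried surface area (BSA) between two
selections, residue-residue distances, and hydrogen-bond / hydrophobic
contact lists.  Intended for SH2 domain-phosphopeptide complexes, where the
peptide-side buried area is the headline number, but works on any two
disjoint chain selections.

Phosphotyrosine (PTR) is treated as a standard peptide residue.  Crystal
structures rarely contain hydrogens, so hydrogen bonds are assessed on
heavy-atom geometry: a donor/acceptor N-O pair within the distance cutoff,
with the angle criterion applied at the acceptor through its covalent
antecedent where one exists (distance-only otherwise, flagged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

import gemmi

__all__ = [
    "Atom",
    "StructureModel",
    "InterfaceReport",
    "Contact",
    "read_structure",
    "compute_sasa",
    "total_sasa",
    "buried_surface_area",
    "residue_distance",
    "list_contacts",
    "VDW_RADII",
]

logger = logging.getLogger(__name__)

# fixed published van der Waals set (Angstrom); configurable per call
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4

# residues treated as polymer despite being HETATM records in many files
_PEPTIDE_HET = {"PTR", "SEP", "TPO"}
_WATER = {"HOH", "WAT", "DOD"}

_COVALENT_CUTOFF = 1.8  # heavy-atom bond detection (A)


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    is_water: bool = False


@dataclass(frozen=True)
class StructureModel:
    atoms: tuple[Atom, ...]
    model_id: str = "1"

    def __post_init__(self) -> None:
        if not all(all(math.isfinite(c) for c in a.xyz) for a in self.atoms):
            raise ValueError("non-finite coordinates in structure")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def select(
        self,
        chains: Iterable[str] | None = None,
        include_waters: bool = False,
        include_hetero: bool = False,
        include_hydrogens: bool = False,
    ) -> "StructureModel":
        chain_set = set(chains) if chains is not None else None
        kept = []
        for a in self.atoms:
            if chain_set is not None and a.chain_id not in chain_set:
                continue
            if a.is_water and not include_waters:
                continue
            if a.is_hetero and not a.is_water and not include_hetero:
                continue
            if a.element == "H" and not include_hydrogens:
                continue
            kept.append(a)
        return StructureModel(atoms=tuple(kept), model_id=self.model_id)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class Contact:
    kind: str  # "hbond" | "hydrophobic"
    atom_a: Atom
    atom_b: Atom
    distance: float
    angle_deg: float | None = None
    distance_only: bool = False


@dataclass(frozen=True)
class InterfaceReport:
    bsa_peptide: float
    bsa_receptor: float
    hbonds: tuple[Contact, ...] = ()
    hydrophobic_contacts: tuple[Contact, ...] = ()

    @property
    def interface_area(self) -> float:
        return 0.5 * (self.bsa_peptide + self.bsa_receptor)


# ---------------------------------------------------------------------------
# reading


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Only the first model is used.  Among alternate locations of an atom, the
    highest-occupancy one is retained (ties broken by altloc letter).
    """
    path = Path(path)
    if format is None:
        format = "mmCIF" if path.suffix.lower() in {".cif", ".mmcif"} else "PDB"
    try:
        if format.lower() == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:
        raise ValueError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    st.setup_entities()
    model = st[0]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            resname = residue.name.strip()
            is_water = resname in _WATER
            is_het = (
                residue.het_flag == "H" and resname not in _PEPTIDE_HET
            ) or is_water
            # keep best altloc per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ or (
                    atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~")
                ):
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_name=resname,
                        residue_number=residue.seqid.num,
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                        altloc=atom.altloc or "",
                        is_hetero=is_het,
                        is_water=is_water,
                    )
                )
    return StructureModel(atoms=tuple(atoms), model_id=str(getattr(model, "num", 1)))


# ---------------------------------------------------------------------------
# SASA


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(model: StructureModel, radii: dict[str, float], default: float) -> np.ndarray:
    out = np.empty(len(model))
    warned: set[str] = set()
    for i, a in enumerate(model.atoms):
        r = radii.get(a.element)
        if r is None:
            if a.element not in warned:
                logger.warning(
                    "unknown element %r: using default radius %.2f A", a.element, default
                )
                warned.add(a.element)
            r = default
        out[i] = r
    return out


def compute_sasa(
    model: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    default_radius: float = DEFAULT_RADIUS,
) -> np.ndarray:
    """Per-atom Shrake-Rupley solvent-accessible surface areas (A^2).

    Each atom's solvent-accessible sphere (vdW + probe radius) is sampled at
    ``n_points`` deterministic quasi-uniform points; points falling inside any
    neighbouring atom's accessible sphere are occluded.  Deterministic for a
    given ``n_points``.  Hydrogens should be excluded beforehand (they are by
    :meth:`StructureModel.select`).
    """
    if len(model) == 0:
        return np.zeros(0)
    radii = VDW_RADII if radii is None else radii
    xyz = model.coords()
    rad = _radii_for(model, radii, default_radius) + probe_radius
    unit = _sphere_points(n_points)

    tree = cKDTree(xyz)
    max_r = float(rad.max())
    areas = np.empty(len(model))
    for i in range(len(model)):
        pts = xyz[i] + rad[i] * unit
        neighbours = [j for j in tree.query_ball_point(xyz[i], rad[i] + max_r) if j != i]
        if neighbours:
            nb_xyz = xyz[neighbours]
            nb_rad = rad[neighbours]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 > (nb_rad**2)[None, :] - 1e-12, axis=1)
            frac = float(np.count_nonzero(exposed)) / n_points
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * rad[i] ** 2
    return areas


def total_sasa(model: StructureModel, **kwargs) -> float:
    return float(np.sum(compute_sasa(model, **kwargs)))


def buried_surface_area(
    model: StructureModel,
    selection_a: Iterable[str],
    selection_b: Iterable[str],
    with_contacts: bool = False,
    **sasa_kwargs,
) -> InterfaceReport:
    """Buried surface areas between two disjoint chain selections.

    bsa_peptide (side A) = SASA(A alone) - SASA(A within the A+B complex);
    bsa_receptor analogously for side B; the reported interface area is the
    mean of the two sides.  Selection A is conventionally the peptide.
    """
    sel_a, sel_b = set(selection_a), set(selection_b)
    if sel_a & sel_b:
        raise ValueError(f"selections overlap: {sorted(sel_a & sel_b)}")
    a = model.select(chains=sel_a)
    b = model.select(chains=sel_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty selection")
    complex_model = StructureModel(atoms=a.atoms + b.atoms, model_id=model.model_id)
    sasa_complex = compute_sasa(complex_model, **sasa_kwargs)
    sasa_a = compute_sasa(a, **sasa_kwargs)
    sasa_b = compute_sasa(b, **sasa_kwargs)
    na = len(a)
    bsa_a = float(np.sum(sasa_a) - np.sum(sasa_complex[:na]))
    bsa_b = float(np.sum(sasa_b) - np.sum(sasa_complex[na:]))
    hbonds: tuple[Contact, ...] = ()
    hydroph: tuple[Contact, ...] = ()
    if with_contacts:
        contacts = list_contacts(model, sel_a, sel_b)
        hbonds = tuple(c for c in contacts if c.kind == "hbond")
        hydroph = tuple(c for c in contacts if c.kind == "hydrophobic")
    return InterfaceReport(bsa_peptide=max(bsa_a, 0.0), bsa_receptor=max(bsa_b, 0.0),
                           hbonds=hbonds, hydrophobic_contacts=hydroph)


# ---------------------------------------------------------------------------
# distances and contacts


def residue_distance(
    model: StructureModel,
    spec_a: tuple[str, int],
    spec_b: tuple[str, int],
    atom_name: str = "CA",
) -> float:
    """Euclidean distance (A) between a named atom of two residues.

    ``spec`` is (chain_id, residue_number).
    """

    def find(spec: tuple[str, int]) -> Atom:
        chain, num = spec
        for a in model.atoms:
            if a.chain_id == chain and a.residue_number == num and a.atom_name == atom_name:
                return a
        raise ValueError(f"atom {atom_name!r} not found in residue {chain}/{num}")

    pa, pb = find(spec_a), find(spec_b)
    return float(np.linalg.norm(np.array(pa.xyz) - np.array(pb.xyz)))


def _apolar_carbons(model: StructureModel) -> np.ndarray:
    """Mask of carbons with no covalently bonded N/O (apolar carbons)."""
    xyz = model.coords()
    is_c = np.array([a.element == "C" for a in model.atoms])
    is_polar = np.array([a.element in ("N", "O") for a in model.atoms])
    if not is_polar.any():
        return is_c
    tree = cKDTree(xyz[is_polar])
    mask = is_c.copy()
    idx_c = np.flatnonzero(is_c)
    for i in idx_c:
        if tree.query_ball_point(xyz[i], _COVALENT_CUTOFF):
            mask[i] = False
    return mask


def _antecedent(model: StructureModel, index: int) -> int | None:
    """Closest covalently bonded heavy atom of atom ``index`` (same chain)."""
    xyz = model.coords()
    best, best_d = None, _COVALENT_CUTOFF
    for j, a in enumerate(model.atoms):
        if j == index or a.element == "H":
            continue
        d = float(np.linalg.norm(xyz[j] - xyz[index]))
        if d < best_d:
            best, best_d = j, d
    return best


def list_contacts(
    model: StructureModel,
    selection_a: Iterable[str],
    selection_b: Iterable[str],
    hbond_cutoff: float = 3.5,
    hbond_angle: float = 120.0,
    hydrophobic_cutoff: float = 4.5,
) -> list[Contact]:
    """Hydrogen-bond and hydrophobic contacts between two chain selections.

    H-bonds: N/O pairs across the interface within ``hbond_cutoff``; where
    the acceptor has a covalent antecedent, the donor-acceptor-antecedent
    angle must exceed ``hbond_angle`` degrees (an approximately linear
    heavy-atom geometry); isolated acceptors fall back to distance-only,
    flagged on the contact.  Hydrophobic contacts: apolar-carbon pairs within
    ``hydrophobic_cutoff``.  Output is deterministically ordered.
    """
    sel_a, sel_b = set(selection_a), set(selection_b)
    idx_a = [i for i, a in enumerate(model.atoms) if a.chain_id in sel_a]
    idx_b = [i for i, a in enumerate(model.atoms) if a.chain_id in sel_b]
    xyz = model.coords()
    apolar = _apolar_carbons(model)

    contacts: list[Contact] = []
    for i in idx_a:
        ai = model.atoms[i]
        for j in idx_b:
            aj = model.atoms[j]
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if ai.element in ("N", "O") and aj.element in ("N", "O") and d <= hbond_cutoff:
                # symmetric heavy-atom geometry: evaluate the angle through
                # each partner's covalent antecedent where one exists
                ok, angles = True, []
                for center, other in ((j, i), (i, j)):
                    ante = _antecedent(model, center)
                    if ante is None:
                        continue
                    v1 = xyz[other] - xyz[center]
                    v2 = xyz[ante] - xyz[center]
                    cosang = float(np.dot(v1, v2) /
                                   (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    angles.append(ang)
                    ok = ok and ang >= hbond_angle
                if ok:
                    contacts.append(Contact("hbond", ai, aj, d,
                                            min(angles) if angles else None,
                                            distance_only=not angles))
            if apolar[i] and apolar[j] and d <= hydrophobic_cutoff:
                contacts.append(Contact("hydrophobic", ai, aj, d))
    contacts.sort(key=lambda c: (c.kind, c.distance,
                                 c.atom_a.chain_id, c.atom_a.residue_number,
                                 c.atom_a.atom_name, c.atom_b.chain_id,
                                 c.atom_b.residue_number, c.atom_b.atom_name))
    return contacts
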