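"""Structure handling: coordinate I/O, backbone-dihedral model quality,
rigid superposition onto the dimer template, and cofactor transfer.

Homology-model construction itself sits behind :class:`ModelingBackend`;
this package qualifies, aligns and decorates models, it does not build
them.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .seqprep import PairwiseAlignment

__all__ = [
    "Atom",
    "StructureModel",
    "RamachandranAssessment",
    "QualificationConfig",
    "RigidTransform",
    "DEFAULT_CORE_REGIONS",
    "read_structure",
    "write_structure",
    "dihedral",
    "ramachandran_qualify",
    "kabsch_superpose",
    "align_to_template",
    "transfer_cofactor",
    "ModelingBackend",
    "FixtureModelingBackend",
]

#: Rectangular favorable/core Ramachandran regions, degrees, inclusive.
#: Each region is a list of (phi_min, phi_max, psi_min, psi_max) boxes.
DEFAULT_CORE_REGIONS: dict[str, list[tuple[float, float, float, float]]] = {
    "core": [
        (-180.0, -30.0, -90.0, 45.0),
        (-180.0, -30.0, 90.0, 180.0),
    ]
}

_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)
#: protonation-variant residue names mapped to their parent
RESNAME_NORMALIZATION = {
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS",
    "ASH": "ASP", "GLH": "GLU", "LYN": "LYS",
}


def normalize_resname(name: str) -> str:
    return RESNAME_NORMALIZATION.get(name, name)


def is_protein_resname(name: str) -> bool:
    return normalize_resname(name) in _STANDARD_AA


@dataclass
class Atom:
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    xyz: np.ndarray
    hetero: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError("xyz must be a 3-vector")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be finite")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def copy(self) -> "Atom":
        return Atom(
            name=self.name,
            element=self.element,
            residue_name=self.residue_name,
            residue_index=self.residue_index,
            chain_id=self.chain_id,
            xyz=self.xyz.copy(),
            hetero=self.hetero,
        )


@dataclass
class StructureModel:
    """An ordered collection of atoms grouped into chains and residues."""

    model_id: str
    atoms: list[Atom]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(a.chain_id, a.residue_index, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(
                f"model {self.model_id!r}: duplicate atoms {dupes[:3]}"
            )

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def chains(self) -> dict[str, list[Atom]]:
        out: dict[str, list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.chain_id, []).append(a)
        return out

    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        """Atoms grouped by (chain_id, residue_index), in file order."""
        out: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.residue_index), []).append(a)
        return out

    def protein_residues(self) -> dict[tuple[str, int], list[Atom]]:
        return {
            k: v
            for k, v in self.residues().items()
            if is_protein_resname(v[0].residue_name)
        }

    def find_atoms(
        self, *, name: str | None = None, residue_name: str | None = None
    ) -> list[Atom]:
        hits = self.atoms
        if residue_name is not None:
            hits = [a for a in hits if a.residue_name == residue_name]
        if name is not None:
            hits = [a for a in hits if a.name == name]
        return hits

    def transformed(self, transform: "RigidTransform") -> "StructureModel":
        moved = [a.copy() for a in self.atoms]
        for a in moved:
            a.xyz = transform.apply(a.xyz)
        return StructureModel(
            model_id=self.model_id, atoms=moved, metadata=dict(self.metadata)
        )


@dataclass(frozen=True)
class QualificationConfig:
    """Model acceptance rule: at least ``cutoff_fraction`` of assessed
    residues must fall in favorable/core backbone-dihedral regions."""

    cutoff_fraction: float = 0.90
    region_definition: Mapping[str, list[tuple[float, float, float, float]]] = (
        None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff_fraction <= 1.0:
            raise ValueError("cutoff_fraction must be in (0, 1]")
        if self.region_definition is None:
            object.__setattr__(
                self, "region_definition", DEFAULT_CORE_REGIONS
            )


@dataclass(frozen=True)
class RamachandranAssessment:
    core_fraction: float
    qualified: bool
    per_residue: list[tuple[float, float, str]]


@dataclass(frozen=True)
class RigidTransform:
    """x -> x @ rotation + translation (row-vector convention)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation + self.translation


# ---------------------------------------------------------------------------
# PDB-dialect I/O

_PDB_RECORDS = ("ATOM  ", "HETATM")


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() or name[:1]
    except (ValueError, IndexError) as exc:
        raise ValueError(f"line {lineno}: unparseable coordinate record: "
                         f"{line.rstrip()!r}") from exc
    return Atom(
        name=name,
        element=element,
        residue_name=resname,
        residue_index=resseq,
        chain_id=chain,
        xyz=np.array([x, y, z]),
        hetero=line.startswith("HETATM"),
    )


def read_structure(path: str | Path) -> StructureModel:
    """Read a protein coordinate file (PDB dialect, ATOM/HETATM/TER/END)."""
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in _PDB_RECORDS:
                atoms.append(_parse_atom_line(line, lineno))
            elif rec.strip() in {"TER", "END", "ENDMDL", "MODEL", "REMARK",
                                 "HEADER", "TITLE", "CRYST1", "CONECT", ""}:
                continue
            elif line.strip():
                raise ValueError(
                    f"{path}: line {lineno}: unrecognized record "
                    f"{line.rstrip()!r}"
                )
    return StructureModel(model_id=Path(path).stem, atoms=atoms)


def _format_atom_line(atom: Atom, serial: int) -> str:
    record = "HETATM" if atom.hetero else "ATOM  "
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (
        f"{record}{serial:5d} {name:4s} {atom.residue_name:>3s} "
        f"{atom.chain_id:1s}{atom.residue_index:4d}    "
        f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
    )


def write_structure(model: StructureModel, path: str | Path) -> None:
    lines = []
    prev_chain: str | None = None
    serial = 0
    for atom in model.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        serial += 1
        lines.append(_format_atom_line(atom, serial))
        prev_chain = atom.chain_id
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry

def dihedral(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Standard convention: invariant under reversal of the atom order,
    negated by mirror reflection.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: three consecutive points "
                         "are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:
        angle += 360.0
    return angle


def _in_regions(
    phi: float,
    psi: float,
    regions: Mapping[str, list[tuple[float, float, float, float]]],
) -> str:
    for label, boxes in regions.items():
        for phi_lo, phi_hi, psi_lo, psi_hi in boxes:
            if phi_lo <= phi <= phi_hi and psi_lo <= psi <= psi_hi:
                return label
    return "outside"


def ramachandran_qualify(
    model: StructureModel,
    cfg: QualificationConfig = QualificationConfig(),
) -> RamachandranAssessment:
    """Assess backbone dihedrals against favorable/core regions.

    phi/psi are computed for every residue with a complete backbone and
    both neighbors present; the model qualifies when the core fraction
    reaches ``cfg.cutoff_fraction`` (inclusive). Chains with fewer than
    three residues are skipped with a warning.
    """
    per_residue: list[tuple[float, float, str]] = []
    n_core = 0
    for chain_id, chain_atoms in model.chains().items():
        residues: dict[int, dict[str, Atom]] = {}
        for a in chain_atoms:
            if is_protein_resname(a.residue_name):
                residues.setdefault(a.residue_index, {})[a.name] = a
        indices = sorted(residues)
        if len(indices) < 3:
            if indices:
                warnings.warn(
                    f"chain {chain_id!r} has fewer than 3 residues; skipped"
                )
            continue
        for idx in indices:
            prev_res = residues.get(idx - 1)
            next_res = residues.get(idx + 1)
            res = residues[idx]
            if prev_res is None or next_res is None:
                continue
            needed = (
                prev_res.get("C"), res.get("N"), res.get("CA"),
                res.get("C"), next_res.get("N"),
            )
            if any(a is None for a in needed):
                continue
            c_prev, n, ca, c, n_next = needed  # type: ignore[misc]
            phi = dihedral(c_prev.xyz, n.xyz, ca.xyz, c.xyz)
            psi = dihedral(n.xyz, ca.xyz, c.xyz, n_next.xyz)
            label = _in_regions(phi, psi, cfg.region_definition)
            per_residue.append((phi, psi, label))
            if label != "outside":
                n_core += 1
    if not per_residue:
        raise ValueError(
            f"model {model.model_id!r}: no assessable residues"
        )
    core_fraction = n_core / len(per_residue)
    return RamachandranAssessment(
        core_fraction=core_fraction,
        qualified=core_fraction >= cfg.cutoff_fraction,
        per_residue=per_residue,
    )


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> RigidTransform:
    """Least-squares optimal rigid superposition of paired points.

    Returns the transform (proper rotation + translation) minimizing the
    RMSD of ``mobile`` onto ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal shapes")
    if len(mobile) < 3:
        raise ValueError("at least 3 paired points are required")
    centered = mobile - mobile.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    sup = SVDSuperimposer()
    sup.set(reference, mobile)
    sup.run()
    rot, tran = sup.get_rotran()
    if np.linalg.det(rot) < 0:
        raise ValueError("superposition produced an improper rotation")
    return RigidTransform(
        rotation=rot, translation=tran, rmsd=float(sup.get_rms())
    )


ResiduePair = tuple[tuple[str, int], tuple[str, int]]


def align_to_template(
    model: StructureModel,
    template: StructureModel,
    pairing: Sequence[ResiduePair],
) -> StructureModel:
    """Superpose a model onto the template via paired CA atoms.

    ``pairing`` lists ((model_chain, model_resid), (template_chain,
    template_resid)) pairs; the CA-fit transform is applied to every
    atom of the model.
    """
    if not pairing:
        raise ValueError("empty residue pairing")
    model_res = model.residues()
    template_res = template.residues()
    mobile, reference = [], []
    for mkey, tkey in pairing:
        mkey = (mkey[0], int(mkey[1]))
        tkey = (tkey[0], int(tkey[1]))
        for key, res_map, what in (
            (mkey, model_res, "model"), (tkey, template_res, "template")
        ):
            if key not in res_map:
                raise ValueError(f"{what} has no residue {key}")
        m_ca = next((a for a in model_res[mkey] if a.name == "CA"), None)
        t_ca = next((a for a in template_res[tkey] if a.name == "CA"), None)
        if m_ca is None:
            raise ValueError(f"model residue {mkey} has no CA atom")
        if t_ca is None:
            raise ValueError(f"template residue {tkey} has no CA atom")
        mobile.append(m_ca.xyz)
        reference.append(t_ca.xyz)
    transform = kabsch_superpose(np.array(mobile), np.array(reference))
    aligned = model.transformed(transform)
    aligned.metadata["alignment_rmsd"] = transform.rmsd
    return aligned


def transfer_cofactor(
    model: StructureModel,
    template: StructureModel,
    cofactor_resname: str = "NAP",
) -> StructureModel:
    """Copy the template's cofactor group into an aligned model.

    The cofactor atoms keep their template coordinates; existing model
    atoms are untouched. The model must not already carry the cofactor.
    """
    cof_atoms = template.find_atoms(residue_name=cofactor_resname)
    if not cof_atoms:
        raise ValueError(
            f"template {template.model_id!r} has no residue "
            f"{cofactor_resname!r}"
        )
    if model.find_atoms(residue_name=cofactor_resname):
        raise ValueError(
            f"model {model.model_id!r} already contains {cofactor_resname!r}"
        )
    new_atoms = [a.copy() for a in model.atoms]
    for a in cof_atoms:
        copied = a.copy()
        copied.hetero = True
        new_atoms.append(copied)
    return StructureModel(
        model_id=model.model_id, atoms=new_atoms, metadata=dict(model.metadata)
    )


# ---------------------------------------------------------------------------
# Modeling backend contract

class ModelingBackend(ABC):
    """Builds a dimeric structural model from a doubled alignment.

    Real engines (comparative-modeling packages) plug in here; the
    shipped :class:`FixtureModelingBackend` serves pre-built models.
    """

    @abstractmethod
    def build_model(
        self,
        query_id: str,
        alignment: PairwiseAlignment,
        template: StructureModel,
    ) -> StructureModel: ...


class FixtureModelingBackend(ModelingBackend):
    """Serves pre-built models from a directory (``<query_id>.pdb``) or
    an in-memory mapping keyed by query id."""

    def __init__(
        self,
        directory: str | Path | None = None,
        models: Mapping[str, StructureModel] | None = None,
    ) -> None:
        self.directory = Path(directory) if directory else None
        self.models = dict(models) if models else {}

    def build_model(
        self,
        query_id: str,
        alignment: PairwiseAlignment,
        template: StructureModel,
    ) -> StructureModel:
        if query_id in self.models:
            return self.models[query_id]
        if self.directory is not None:
            path = self.directory / f"{query_id}.pdb"
            if path.exists():
                return read_structure(path)
        raise KeyError(f"no fixture model for query {query_id!r}")
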