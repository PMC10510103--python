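"""Docking-box construction and the docking backend contract.

The search box is centered on the template's bound reference ligand and
sized from the substrate's radius of gyration; pose generation itself is
delegated to a backend (an external docking engine, or the shipped
fixture backend serving stored pose sets).
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .structmodel import Atom, StructureModel

__all__ = [
    "DockingBox",
    "Pose",
    "DockingConfig",
    "radius_of_gyration",
    "compute_box",
    "DockingBackend",
    "FixtureDockingBackend",
    "read_poses",
    "write_poses",
    "read_substrate",
]


@dataclass(frozen=True)
class DockingBox:
    """Cubic (by default) search region, Å."""

    center: np.ndarray
    edge: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float)
        )
        edge = np.asarray(self.edge, dtype=float)
        if edge.ndim == 0:
            edge = np.full(3, float(edge))
        object.__setattr__(self, "edge", edge)
        if np.any(self.edge <= 0):
            raise ValueError("box edges must be positive")


@dataclass
class Pose:
    """One docked substrate pose with its engine binding score.

    ``n_atom_index`` is the 1-based index of the imine nitrogen within
    ``substrate_atoms``; lower ``vina_score`` means stronger predicted
    binding.
    """

    pose_index: int
    substrate_atoms: list[Atom]
    vina_score: float
    n_atom_index: int

    def __post_init__(self) -> None:
        if self.pose_index < 1:
            raise ValueError("pose_index is 1-based")
        if not np.isfinite(self.vina_score):
            raise ValueError("vina_score must be finite")
        if not 1 <= self.n_atom_index <= len(self.substrate_atoms):
            raise ValueError(
                f"n_atom_index {self.n_atom_index} outside substrate atom "
                f"range 1..{len(self.substrate_atoms)}"
            )

    @property
    def nitrogen(self) -> Atom:
        return self.substrate_atoms[self.n_atom_index - 1]

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.substrate_atoms], dtype=float)


@dataclass(frozen=True)
class DockingConfig:
    exhaustiveness: int = 10
    box_scale: float = 2.9
    min_edge: float = 10.0

    def __post_init__(self) -> None:
        if self.exhaustiveness < 1:
            raise ValueError("exhaustiveness must be >= 1")
        if self.box_scale <= 0:
            raise ValueError("box_scale must be positive")


def radius_of_gyration(coords: np.ndarray | Sequence) -> float:
    """Unweighted radius of gyration: RMS distance to the centroid."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(coords) == 0:
        raise ValueError("radius_of_gyration of an empty coordinate set")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def compute_box(
    reference_ligand: Sequence[Atom],
    substrate: Sequence[Atom],
    cfg: DockingConfig = DockingConfig(),
) -> DockingBox:
    """Docking box centered on the reference ligand's centroid.

    The cubic edge is ``box_scale`` times the substrate's radius of
    gyration, floored at ``min_edge`` so small substrates still get a
    searchable volume.
    """
    if not reference_ligand or not substrate:
        raise ValueError("reference ligand and substrate must be nonempty")
    center = np.mean([a.xyz for a in reference_ligand], axis=0)
    rg = radius_of_gyration([a.xyz for a in substrate])
    edge = max(cfg.box_scale * rg, cfg.min_edge)
    return DockingBox(center=center, edge=np.full(3, edge))


class DockingBackend(ABC):
    """Generates scored substrate poses inside a docking box."""

    @abstractmethod
    def dock(
        self,
        receptor: StructureModel,
        substrate: Sequence[Atom],
        box: DockingBox,
        cfg: DockingConfig,
    ) -> list[Pose]: ...


class FixtureDockingBackend(DockingBackend):
    """Serves stored pose sets keyed by (receptor id, substrate id).

    Pose sets come from an in-memory mapping or a directory of pose
    files named ``<receptor_id>__<substrate_id>.poses.pdb``. Poses are
    returned sorted by binding score, best (lowest) first; each call's
    configuration is appended to :attr:`provenance`.
    """

    def __init__(
        self,
        directory: str | Path | None = None,
        pose_sets: Mapping[tuple[str, str], list[Pose]] | None = None,
        substrate_id: str = "substrate",
    ) -> None:
        self.directory = Path(directory) if directory else None
        self.pose_sets = dict(pose_sets) if pose_sets else {}
        self.substrate_id = substrate_id
        self.provenance: list[dict] = []

    def dock(
        self,
        receptor: StructureModel,
        substrate: Sequence[Atom],
        box: DockingBox,
        cfg: DockingConfig = DockingConfig(),
    ) -> list[Pose]:
        key = (receptor.model_id, self.substrate_id)
        if key in self.pose_sets:
            poses = self.pose_sets[key]
        elif self.directory is not None and (
            path := self.directory / f"{key[0]}__{key[1]}.poses.pdb"
        ).exists():
            poses = read_poses(path)
        else:
            raise KeyError(f"no fixture pose set for {key}")
        self.provenance.append(
            {
                "receptor": key[0],
                "substrate": key[1],
                "exhaustiveness": cfg.exhaustiveness,
                "box_center": [float(v) for v in box.center],
                "box_edge": [float(v) for v in box.edge],
            }
        )
        return sorted(poses, key=lambda p: p.vina_score)


# ---------------------------------------------------------------------------
# Pose file I/O (MODEL/ENDMDL blocks with score and N-index remarks)

_SCORE_PREFIX = "REMARK VINA RESULT:"
_NIDX_PREFIX = "REMARK N ATOM INDEX:"


def write_poses(poses: Sequence[Pose], path: str | Path) -> None:
    from .structmodel import _format_atom_line

    lines: list[str] = []
    for pose in poses:
        lines.append(f"MODEL {pose.pose_index:8d}")
        lines.append(f"{_SCORE_PREFIX} {pose.vina_score:10.3f}")
        lines.append(f"{_NIDX_PREFIX} {pose.n_atom_index}")
        for serial, atom in enumerate(pose.substrate_atoms, start=1):
            lines.append(_format_atom_line(atom, serial))
        lines.append("ENDMDL")
    Path(path).write_text("\n".join(lines) + "\n")


def read_poses(path: str | Path) -> list[Pose]:
    """Read a multi-pose file; every pose block must carry a score."""
    from .structmodel import _parse_atom_line

    poses: list[Pose] = []
    in_model = False
    atoms: list[Atom] = []
    score: float | None = None
    n_index: int | None = None
    pose_index = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                in_model = True
                pose_index += 1
                atoms, score, n_index = [], None, None
            elif line.startswith(_SCORE_PREFIX):
                score = float(line[len(_SCORE_PREFIX):].strip())
            elif line.startswith(_NIDX_PREFIX):
                n_index = int(line[len(_NIDX_PREFIX):].strip())
            elif line[:6] in ("ATOM  ", "HETATM"):
                atoms.append(_parse_atom_line(line, lineno))
            elif line.startswith("ENDMDL"):
                if score is None:
                    raise ValueError(
                        f"{path}: pose {pose_index} lacks a score remark"
                    )
                if n_index is None:
                    raise ValueError(
                        f"{path}: pose {pose_index} lacks an N-atom-index "
                        "remark"
                    )
                poses.append(
                    Pose(
                        pose_index=pose_index,
                        substrate_atoms=atoms,
                        vina_score=score,
                        n_atom_index=n_index,
                    )
                )
                in_model = False
    if in_model:
        raise ValueError(f"{path}: unterminated MODEL block")
    return poses


def read_substrate(path: str | Path) -> list[Atom]:
    """Read substrate atoms from an SD/MOL file (via RDKit) or a PDB file.

    Heavy-atom coordinates only; atom order follows the file, so a
    1-based imine-nitrogen index refers to the same atom the user sees
    in a structure editor.
    """
    path = Path(path)
    if path.suffix.lower() in {".mol", ".sdf", ".sd"}:
        from rdkit import Chem

        mol = Chem.MolFromMolFile(str(path), removeHs=True)
        if mol is None:
            raise ValueError(f"{path}: unparseable MOL/SD file")
        conf = mol.GetConformer()
        atoms = []
        for i, rd_atom in enumerate(mol.GetAtoms()):
            pos = conf.GetAtomPosition(i)
            elem = rd_atom.GetSymbol()
            atoms.append(
                Atom(
                    name=f"{elem}{i + 1}",
                    element=elem,
                    residue_name="SUB",
                    residue_index=1,
                    chain_id="S",
                    xyz=np.array([pos.x, pos.y, pos.z]),
                    hetero=True,
                )
            )
        return atoms
    from .structmodel import read_structure

    return list(read_structure(path).atoms)
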