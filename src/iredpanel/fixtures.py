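"""Deterministic synthetic fixtures for every pipeline stage.

The generators place residues at exact, re-verified distances from a
substrate, build backbones with prescribed phi/psi dihedrals, emit pose
sets at controlled C4···N separations, and draw screening panels whose
conversions either are uniform or track a known linear score. Every
geometric claim a generator makes is re-measured after construction and
stored in the emitted object's metadata, so tests can assert against
achieved rather than merely intended values.

The geometry is deliberately minimal — single-representative-atom side
chains, idealized backbone internal coordinates — which is sufficient
for the distance, dihedral and counting semantics the pipeline relies
on, and nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .calibrate import CalibrationRecord, ScreeningOutcome
from .docking import Pose
from .scoring import ScoringWeights
from .structmodel import Atom, StructureModel

__all__ = [
    "ReceptorSpec",
    "PanelSpec",
    "make_receptor",
    "make_pose_set",
    "make_panel",
    "build_backbone",
    "make_ramachandran_chain",
    "DEFAULT_SUBSTRATE",
]

#: A small iminium-like substrate: five heavy atoms, N at 1-based index 2.
DEFAULT_SUBSTRATE: tuple[tuple[str, tuple[float, float, float]], ...] = (
    ("C", (0.00, 0.00, 0.00)),
    ("N", (1.28, 0.00, 0.00)),
    ("C", (2.05, 1.20, 0.00)),
    ("C", (-0.75, 1.25, 0.00)),
    ("C", (-0.70, -1.30, 0.00)),
)


@dataclass(frozen=True)
class ReceptorSpec:
    """Recipe for a toy receptor around a substrate.

    ``placements`` lists (residue_name, target minimum heavy-atom
    distance from the substrate in Å); the generator solves for exact
    positions and verifies them post hoc.
    """

    placements: tuple[tuple[str, float], ...] = ()
    cofactor_c4_xyz: tuple[float, float, float] = (0.0, 0.0, 4.0)
    substrate_atoms: tuple[tuple[str, tuple[float, float, float]], ...] = (
        DEFAULT_SUBSTRATE
    )
    n_atom_index: int = 2
    vina_score: float = -8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.placements):
            raise ValueError("placement distances must be positive")


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a synthetic screening panel.

    Defaults emulate the largest published IRED panel used for weight
    calibration: 93 sequences with conversions linked to a known linear
    score through a strictly monotone map plus Gaussian noise (5
    percentage points)."""

    n_sequences: int = 93
    conversion_model: Literal["uniform", "score_linked"] = "score_linked"
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# Internal-coordinate backbone construction

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position atom d such that |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (natural-extension reference frame)."""
    angle = math.radians(angle_deg)
    torsion = -math.radians(torsion_deg)  # sign matches dihedral()
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + bc * d_local[0] + m * d_local[1] + n * d_local[2]


def build_backbone(
    phi_psi: Sequence[tuple[float, float]],
    chain_id: str = "A",
    residue_name: str = "ALA",
    start_index: int = 1,
) -> list[Atom]:
    """Build an N-CA-C backbone with the given per-residue (phi, psi).

    The first residue's phi and the last residue's psi are geometrically
    undefined and ignored; peptide bonds are planar trans (omega 180°).
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    coords: list[tuple[str, np.ndarray]] = []
    # seed triad for residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords += [("N", n0), ("CA", ca0), ("C", c0)]
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = (
            coords[3 * (i - 1) + j][1] for j in range(3)
        )
        psi_prev = phi_psi[i - 1][1]
        n_i = _place_atom(n_prev, ca_prev, c_prev,
                          _BOND_C_N, _ANGLE_CA_C_N, psi_prev)
        ca_i = _place_atom(ca_prev, c_prev, n_i,
                           _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        c_i = _place_atom(c_prev, n_i, ca_i,
                          _BOND_CA_C, _ANGLE_N_CA_C, phi_psi[i][0])
        coords += [("N", n_i), ("CA", ca_i), ("C", c_i)]
    atoms = []
    for i in range(n_res):
        for j, (name, xyz) in enumerate(coords[3 * i : 3 * i + 3]):
            atoms.append(
                Atom(
                    name=name,
                    element=name[0],
                    residue_name=residue_name,
                    residue_index=start_index + i,
                    chain_id=chain_id,
                    xyz=xyz.copy(),
                )
            )
    return atoms


def make_ramachandran_chain(
    n_assessed: int = 100,
    core_fraction: float = 1.0,
    core_angles: tuple[float, float] = (-60.0, -45.0),
    outside_angles: tuple[float, float] = (60.0, 60.0),
    model_id: str = "rama_fixture",
) -> StructureModel:
    """A chain whose assessed residues hit an exact core fraction.

    Two flanking residues are added so that exactly ``n_assessed``
    interior residues carry both phi and psi; ``round(core_fraction *
    n_assessed)`` of them sit at ``core_angles`` and the rest at
    ``outside_angles``.
    """
    if n_assessed < 1:
        raise ValueError("n_assessed must be >= 1")
    n_core = round(core_fraction * n_assessed)
    if not 0 <= n_core <= n_assessed:
        raise ValueError("core_fraction must be in [0, 1]")
    phi_psi = [core_angles]
    phi_psi += [core_angles] * n_core
    phi_psi += [outside_angles] * (n_assessed - n_core)
    phi_psi += [core_angles]
    model = StructureModel(
        model_id=model_id,
        atoms=build_backbone(phi_psi),
        metadata={"n_assessed": n_assessed, "n_core": n_core},
    )
    return model


# ---------------------------------------------------------------------------
# Receptor / pose generation

def _spiral_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-spiral points on a sphere)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + math.sqrt(5)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
         np.cos(phi)]
    )


def _min_distance(point: np.ndarray, coords: np.ndarray) -> float:
    # same arithmetic as the shell census: squared sums, then sqrt
    return float(np.sqrt(np.min(np.sum((coords - point) ** 2, axis=1))))


def _refine_placement(
    p: np.ndarray, anchor: np.ndarray, substrate_xyz: np.ndarray,
    distance: float,
) -> np.ndarray:
    """Nudge ``p`` radially from ``anchor`` until the measured minimum
    distance is <= ``distance`` and within 1e-9 of it, so a residue
    requested exactly at a shell boundary is counted under the
    inclusive rule."""
    for k in range(60):
        dmin = _min_distance(p, substrate_xyz)
        if dmin <= distance and distance - dmin < 1e-9:
            return p
        scale = distance / dmin
        if k > 20:  # break rounding ping-pong
            scale *= 1.0 - 1e-13
        p = anchor + (p - anchor) * scale
    raise ValueError(
        f"placement at {distance} Å did not converge (got {dmin})"
    )


def _solve_placement(
    substrate_xyz: np.ndarray, placement_index: int, distance: float
) -> np.ndarray:
    """Exact-distance placement of a single residue atom.

    The first six placements go along the coordinate axes from the
    substrate atom extreme in that direction, which makes the minimum
    distance exact to the last bit; further placements fall back to a
    bracketing solve along well-separated sphere directions. Either way
    the result is refined so the achieved distance never exceeds the
    request by more than rounding allows.
    """
    if placement_index < 6:
        axis = np.zeros(3)
        axis[placement_index // 2] = 1.0 if placement_index % 2 == 0 else -1.0
        anchor = substrate_xyz[int(np.argmax(substrate_xyz @ axis))]
        p = anchor + distance * axis
    else:
        direction = _spiral_directions(placement_index + 1)[placement_index]
        centroid = substrate_xyz.mean(axis=0)

        def gap(t: float) -> float:
            return _min_distance(centroid + t * direction, substrate_xyz) - distance

        t_hi = distance + float(
            np.max(np.linalg.norm(substrate_xyz - centroid, axis=1))
        ) + 1.0
        if gap(0.0) >= 0:
            raise ValueError(
                f"placement at {distance} Å unsatisfiable along "
                f"{direction}"
            )
        t = brentq(gap, 0.0, t_hi, xtol=1e-10)
        p = centroid + t * direction
        anchor = substrate_xyz[
            int(np.argmin(np.linalg.norm(substrate_xyz - p, axis=1)))
        ]
    return _refine_placement(p, anchor, substrate_xyz, distance)


def make_receptor(spec: ReceptorSpec) -> tuple[StructureModel, Pose]:
    """Build a toy receptor and one docked pose around its substrate.

    The receptor carries: one single-atom residue per requested
    placement (chain A, at the exact requested min distance), a distant
    anchor helix (chain B, outside any plausible shell, giving the
    model a qualifiable backbone), and a cofactor group (chain X,
    residue NAP) with its C4 atom at the requested position. Achieved
    distances are re-measured and stored in ``model.metadata``.
    """
    substrate_atoms = [
        Atom(
            name=f"{elem}{i + 1}",
            element=elem,
            residue_name="SUB",
            residue_index=1,
            chain_id="S",
            xyz=np.array(xyz, dtype=float),
            hetero=True,
        )
        for i, (elem, xyz) in enumerate(spec.substrate_atoms)
    ]
    sub_xyz = np.array([a.xyz for a in substrate_atoms])

    atoms: list[Atom] = []
    achieved: list[tuple[str, float, float]] = []
    for i, (resname, dist) in enumerate(spec.placements):
        pos = _solve_placement(sub_xyz, i, dist)
        atoms.append(
            Atom(
                name="CB",
                element="C",
                residue_name=resname,
                residue_index=i + 1,
                chain_id="A",
                xyz=pos,
            )
        )
        got = _min_distance(pos, sub_xyz)
        if abs(got - dist) > 1e-6:
            raise ValueError(
                f"placement {resname}@{dist} verified at {got}, off target"
            )
        achieved.append((resname, dist, got))

    # distant anchor helix so the model always has an assessable backbone
    max_d = max((d for _, d in spec.placements), default=0.0)
    helix = build_backbone([(-60.0, -45.0)] * 6, chain_id="B")
    helix_xyz = np.array([a.xyz for a in helix])
    offset = (
        sub_xyz.mean(axis=0)
        + np.array([0.0, 0.0, max_d + 40.0])
        - helix_xyz.mean(axis=0)
    )
    for a in helix:
        a.xyz = a.xyz + offset
    atoms.extend(helix)
    helix_min = float(
        np.min(
            np.linalg.norm(
                (helix_xyz + offset)[:, None, :] - sub_xyz[None, :, :],
                axis=2,
            )
        )
    )

    c4 = np.array(spec.cofactor_c4_xyz, dtype=float)
    for name, off in (
        ("C4", (0.0, 0.0, 0.0)),
        ("C3", (1.40, 0.0, 0.0)),
        ("C2", (2.10, 1.21, 0.0)),
        ("N1", (0.70, 2.42, 0.0)),
    ):
        atoms.append(
            Atom(
                name=name,
                element=name[0],
                residue_name="NAP",
                residue_index=1,
                chain_id="X",
                xyz=c4 + np.array(off),
                hetero=True,
            )
        )

    pose = Pose(
        pose_index=1,
        substrate_atoms=[a.copy() for a in substrate_atoms],
        vina_score=spec.vina_score,
        n_atom_index=spec.n_atom_index,
    )
    c4n = float(np.linalg.norm(c4 - pose.nitrogen.xyz))
    model = StructureModel(
        model_id=f"receptor_seed{spec.seed}",
        atoms=atoms,
        metadata={
            "placements": achieved,
            "c4_n_distance": c4n,
            "anchor_helix_min_distance": helix_min,
        },
    )
    return model, pose


def make_pose_set(
    distances: Sequence[float],
    scores: Sequence[float],
    base: Pose,
    c4_xyz: Sequence[float] = (0.0, 0.0, 0.0),
    direction: Sequence[float] = (1.0, 0.0, 0.0),
) -> list[Pose]:
    """Rigid translations of ``base`` placing the imine N at each
    requested C4···N distance, with the given binding scores attached."""
    if len(distances) != len(scores):
        raise ValueError("distances and scores must have equal length")
    c4 = np.asarray(c4_xyz, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    poses = []
    for i, (d, s) in enumerate(zip(distances, scores), start=1):
        target = c4 + d * u
        shift = target - base.nitrogen.xyz
        moved = [a.copy() for a in base.substrate_atoms]
        for a in moved:
            a.xyz = a.xyz + shift
        # snap the nitrogen itself so the C4···N distance is exact
        moved[base.n_atom_index - 1].xyz = target.copy()
        pose = Pose(
            pose_index=i,
            substrate_atoms=moved,
            vina_score=float(s),
            n_atom_index=base.n_atom_index,
        )
        got = float(np.linalg.norm(c4 - pose.nitrogen.xyz))
        if abs(got - d) > 1e-9:
            raise ValueError(f"pose {i}: achieved distance {got} != {d}")
        poses.append(pose)
    return poses


def make_panel(
    spec: PanelSpec,
    weights: ScoringWeights = ScoringWeights(),
) -> tuple[list[ScreeningOutcome], list[CalibrationRecord]]:
    """Draw a synthetic screening panel with its calibration table.

    In ``score_linked`` mode the conversion is a strictly decreasing
    logistic map of each candidate's true refined score (computed with
    ``weights``) plus Gaussian noise, so better-scored candidates
    convert more; ``uniform`` mode draws conversions uniformly on
    [0, 100], the null model for baseline checks.
    """
    from .scoring import ActiveSiteProfile, refined_score

    rng = np.random.default_rng(spec.seed)
    ids = [f"SEQ{i:03d}" for i in range(1, spec.n_sequences + 1)]
    vina = rng.normal(-8.0, 1.0, size=spec.n_sequences)
    n_acidic = rng.integers(0, 4, size=spec.n_sequences)
    n_basic = rng.integers(0, 3, size=spec.n_sequences)
    n_his = rng.integers(0, 2, size=spec.n_sequences)
    profiles = [
        ActiveSiteProfile(int(a), int(b), int(h))
        for a, b, h in zip(n_acidic, n_basic, n_his)
    ]
    scores = np.array(
        [refined_score(v, p, weights) for v, p in zip(vina, profiles)]
    )
    if spec.conversion_model == "uniform":
        conversions = rng.uniform(0.0, 100.0, size=spec.n_sequences)
    elif spec.conversion_model == "score_linked":
        midpoint = float(np.median(scores))
        clean = 100.0 / (1.0 + np.exp((scores - midpoint) / 4.0))
        noise = (
            rng.normal(0.0, spec.noise_sd, size=spec.n_sequences)
            if spec.noise_sd > 0
            else 0.0
        )
        conversions = np.clip(clean + noise, 0.0, 100.0)
    else:
        raise ValueError(f"unknown conversion model {spec.conversion_model!r}")
    outcomes = [
        ScreeningOutcome(i, float(c)) for i, c in zip(ids, conversions)
    ]
    calibration = [
        CalibrationRecord(i, float(v), p, float(c))
        for i, v, p, c in zip(ids, vina, profiles, conversions)
    ]
    return outcomes, calibration
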