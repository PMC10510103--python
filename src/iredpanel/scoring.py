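"""Catalytic-geometry pose selection and active-site rescoring.

An IRED reduces its docked iminium substrate by hydride transfer from
the C4 atom of the NADPH nicotinamide ring, so only poses whose
C4···N(imine) distance lies in a catalytically competent window
(3.5–6.0 Å by default; ~4 Å in crystal structures) are retained, and
the closest surviving pose represents the candidate. The binding score
of that pose is then refined with counts of acidic, basic and histidine
residues in the active-site shell:

    refined = w_vina * Vina + w_acidic * N_acidic
              - w_his * N_His + w_basic * N_basic

with default weights 4.0, 1.0, 9.0, 9.0. Acidic residues and the
conserved active-site histidine stabilize the iminium intermediate and
supply the proton for transfer (His lowers, i.e. improves, the score);
basic residues compete with the iminium and are penalized. Lower
refined score ranks better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .docking import Pose
from .structmodel import StructureModel, normalize_resname

__all__ = [
    "PoseFilterConfig",
    "ShellConfig",
    "ScoringWeights",
    "ActiveSiteProfile",
    "CandidateStatus",
    "ScoredCandidate",
    "c4_n_distance",
    "select_best_pose",
    "active_site_profile",
    "refined_score",
    "rank_candidates",
    "select_panel",
    "write_ranking_csv",
    "read_ranking_csv",
]


@dataclass(frozen=True)
class PoseFilterConfig:
    """C4···N distance window for catalytically plausible poses.

    Poses strictly below ``min_distance`` clash with the nicotinamide
    ring; poses strictly above ``max_distance`` are beyond hydride-
    transfer range. Both are removed.
    """

    min_distance: float = 3.5
    max_distance: float = 6.0
    c4_atom_name: str = "C4"
    cofactor_resname: str = "NAP"

    def __post_init__(self) -> None:
        if not 0 < self.min_distance < self.max_distance:
            raise ValueError("require 0 < min_distance < max_distance")


@dataclass(frozen=True)
class ShellConfig:
    """Active-site shell: residues whose minimum heavy-atom distance to
    any substrate heavy atom is within ``radius`` (inclusive)."""

    radius: float = 8.0
    acidic_set: frozenset[str] = frozenset({"ASP", "GLU"})
    basic_set: frozenset[str] = frozenset({"LYS", "ARG"})
    his_set: frozenset[str] = frozenset({"HIS"})

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if (
            self.acidic_set & self.basic_set
            or self.acidic_set & self.his_set
            or self.basic_set & self.his_set
        ):
            raise ValueError("residue class sets must be disjoint")


@dataclass(frozen=True)
class ScoringWeights:
    """Coefficients of the refined scoring function; ``w_his`` enters
    with a negative sign."""

    w_vina: float = 4.0
    w_acidic: float = 1.0
    w_his: float = 9.0
    w_basic: float = 9.0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_vina, self.w_acidic, self.w_his, self.w_basic)


@dataclass(frozen=True)
class ActiveSiteProfile:
    """Residue-class counts inside the active-site shell.

    ``n_his`` records presence/absence (0 or 1) of histidine, not the
    histidine count.
    """

    n_acidic: int
    n_basic: int
    n_his: int
    shell_residues: tuple = ()

    def __post_init__(self) -> None:
        if self.n_acidic < 0 or self.n_basic < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_his not in (0, 1):
            raise ValueError("n_his is a presence flag: 0 or 1")


class CandidateStatus(str, Enum):
    SCORED = "scored"
    NO_VALID_POSE = "no_valid_pose"
    MODEL_UNQUALIFIED = "model_unqualified"
    NOT_HOMOLOG = "not_homolog"
    FAILED = "failed"


@dataclass
class ScoredCandidate:
    """One candidate's rescoring outcome (one row of the ranking)."""

    sequence_id: str
    status: CandidateStatus
    selected_pose: Pose | None = None
    c4_n_distance: float | None = None
    profile: ActiveSiteProfile | None = None
    refined_score: float | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        complete = all(
            v is not None
            for v in (
                self.selected_pose,
                self.c4_n_distance,
                self.profile,
                self.refined_score,
            )
        )
        if (self.status is CandidateStatus.SCORED) != complete:
            raise ValueError(
                f"candidate {self.sequence_id!r}: status "
                f"{self.status.value!r} inconsistent with populated fields"
            )


def _find_c4(receptor: StructureModel, cfg: PoseFilterConfig):
    hits = [
        a
        for a in receptor.atoms
        if a.residue_name == cfg.cofactor_resname and a.name == cfg.c4_atom_name
    ]
    if len(hits) != 1:
        raise ValueError(
            f"receptor {receptor.model_id!r}: expected exactly one "
            f"{cfg.cofactor_resname}:{cfg.c4_atom_name} atom, found {len(hits)}"
        )
    return hits[0]


def c4_n_distance(
    pose: Pose,
    receptor: StructureModel,
    cfg: PoseFilterConfig = PoseFilterConfig(),
) -> float:
    """Distance (Å) from the cofactor C4 atom to the pose's imine N."""
    c4 = _find_c4(receptor, cfg)
    return float(np.linalg.norm(c4.xyz - pose.nitrogen.xyz))


def select_best_pose(
    poses: Sequence[Pose],
    distances: Sequence[float],
    cfg: PoseFilterConfig = PoseFilterConfig(),
) -> tuple[Pose, float] | None:
    """Keep poses inside the distance window and return the closest.

    Ties on distance break toward the lower binding score, then the
    lower pose index. Returns ``None`` when no pose survives.
    """
    if len(poses) != len(distances):
        raise ValueError("poses and distances must be aligned")
    survivors = [
        (d, p.vina_score, p.pose_index, p)
        for p, d in zip(poses, distances)
        if cfg.min_distance <= d <= cfg.max_distance
    ]
    if not survivors:
        return None
    d, _, _, pose = min(survivors, key=lambda t: (t[0], t[1], t[2]))
    return pose, d


def active_site_profile(
    receptor: StructureModel,
    pose: Pose,
    cfg: ShellConfig = ShellConfig(),
) -> ActiveSiteProfile:
    """Count acidic/basic/His residues within the shell of the pose.

    Residue-to-substrate distance is the minimum over heavy-atom pairs;
    hetero groups (cofactor, ligands) are excluded from the census and
    both chains of the dimer are considered. Protonation-variant
    residue names (HID/HIE/HIP, ASH, GLH, LYN) are normalized before
    classification.
    """
    protein = receptor.protein_residues()
    if not protein:
        raise ValueError(
            f"receptor {receptor.model_id!r} has no protein residues"
        )
    sub_xyz = np.array(
        [a.xyz for a in pose.substrate_atoms if a.is_heavy], dtype=float
    )
    if len(sub_xyz) == 0:
        raise ValueError("pose has no heavy atoms")
    shell: list[tuple[str, int, str, float]] = []
    n_acidic = n_basic = 0
    any_his = False
    for (chain, idx), atoms in protein.items():
        res_xyz = np.array(
            [a.xyz for a in atoms if a.is_heavy], dtype=float
        )
        if len(res_xyz) == 0:
            continue
        dmin = float(
            np.sqrt(
                np.min(
                    np.sum(
                        (res_xyz[:, None, :] - sub_xyz[None, :, :]) ** 2,
                        axis=2,
                    )
                )
            )
        )
        if dmin <= cfg.radius:
            resname = normalize_resname(atoms[0].residue_name)
            shell.append((chain, idx, resname, dmin))
            if resname in cfg.acidic_set:
                n_acidic += 1
            elif resname in cfg.basic_set:
                n_basic += 1
            elif resname in cfg.his_set:
                any_his = True
    return ActiveSiteProfile(
        n_acidic=n_acidic,
        n_basic=n_basic,
        n_his=int(any_his),
        shell_residues=tuple(shell),
    )


def refined_score(
    vina_score: float,
    profile: ActiveSiteProfile,
    w: ScoringWeights = ScoringWeights(),
) -> float:
    """Active-site-modified binding score; lower is better."""
    return (
        w.w_vina * vina_score
        + w.w_acidic * profile.n_acidic
        - w.w_his * profile.n_his
        + w.w_basic * profile.n_basic
    )


def rank_candidates(
    candidates: Sequence[ScoredCandidate],
) -> list[ScoredCandidate]:
    """Sort scored candidates by refined score ascending (best first).

    Ties break toward the lower binding score, then lexicographic
    sequence id; unscored candidates are appended after the ranked
    block, keeping their status visible.
    """
    scored = [c for c in candidates if c.status is CandidateStatus.SCORED]
    rest = [c for c in candidates if c.status is not CandidateStatus.SCORED]
    scored.sort(
        key=lambda c: (
            c.refined_score,
            c.selected_pose.vina_score,  # type: ignore[union-attr]
            c.sequence_id,
        )
    )
    return scored + rest


def select_panel(
    ranked: Sequence[ScoredCandidate], k: int = 20
) -> list[ScoredCandidate]:
    """First ``k`` scored candidates of a ranking — the screening panel."""
    if k < 0:
        raise ValueError("panel size must be nonnegative")
    scored = [c for c in ranked if c.status is CandidateStatus.SCORED]
    return scored[:k]


RANKING_COLUMNS = [
    "rank",
    "sequence_id",
    "vina_score",
    "c4_n_distance",
    "n_acidic",
    "n_basic",
    "n_his",
    "refined_score",
    "status",
]


def write_ranking_csv(
    ranked: Sequence[ScoredCandidate], path: str | Path
) -> pd.DataFrame:
    """Write the ranking table; unscored rows carry empty numeric fields."""
    rows = []
    rank = 0
    for c in ranked:
        if c.status is CandidateStatus.SCORED:
            rank += 1
            rows.append(
                {
                    "rank": rank,
                    "sequence_id": c.sequence_id,
                    "vina_score": c.selected_pose.vina_score,
                    "c4_n_distance": round(c.c4_n_distance, 3),
                    "n_acidic": c.profile.n_acidic,
                    "n_basic": c.profile.n_basic,
                    "n_his": c.profile.n_his,
                    "refined_score": round(c.refined_score, 3),
                    "status": c.status.value,
                }
            )
        else:
            rows.append(
                {
                    "rank": "",
                    "sequence_id": c.sequence_id,
                    "vina_score": "",
                    "c4_n_distance": "",
                    "n_acidic": "",
                    "n_basic": "",
                    "n_his": "",
                    "refined_score": "",
                    "status": c.status.value,
                }
            )
    df = pd.DataFrame(rows, columns=RANKING_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_ranking_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RANKING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing ranking columns {sorted(missing)}")
    return df
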