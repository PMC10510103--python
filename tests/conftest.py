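"""Shared fixtures: toy receptors and a complete file-based pipeline
asset set (sequences, template structure, pre-built models, pose sets),
all generated programmatically."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from iredpanel.docking import write_poses
from iredpanel.fixtures import ReceptorSpec, make_pose_set, make_receptor
from iredpanel.seqprep import SequenceRecord, write_fasta
from iredpanel.structmodel import Atom, StructureModel, write_structure
from iredpanel.fixtures import make_ramachandran_chain

# a Rossmann-motif-like 42-mer standing in for the dimer template's chain
TEMPLATE_SEQ = "MKAVLITGAGSGIGLAIAKRFAEEGARVVLADINAEGAERVA"
DECOY_SEQ = "WNPYHQCWNPYHQCWNPYHQCWNPYHQCWNPYHQCWNPYHQC"


def mutate(seq: str, positions: dict[int, str]) -> str:
    chars = list(seq)
    for pos, aa in positions.items():
        chars[pos] = aa
    return "".join(chars)


@pytest.fixture(scope="session")
def shell_receptor():
    """Receptor with ASP@5.0, GLU@7.9, LYS@8.1, HIS@6.0 around the
    substrate (the canonical profile example: 2 acidic, 0 basic, His)."""
    return make_receptor(
        ReceptorSpec(
            placements=(
                ("ASP", 5.0), ("GLU", 7.9), ("LYS", 8.1), ("HIS", 6.0),
            )
        )
    )


@pytest.fixture(scope="session")
def bare_receptor():
    """Receptor with no placements: empty shell, anchor helix only."""
    return make_receptor(ReceptorSpec())


@pytest.fixture(scope="session")
def query_sequences():
    return [
        SequenceRecord("q1", mutate(TEMPLATE_SEQ, {5: "V"})),
        SequenceRecord("q2", mutate(TEMPLATE_SEQ, {10: "A", 20: "S"})),
        SequenceRecord("q3", mutate(TEMPLATE_SEQ, {3: "I"})),
        SequenceRecord("q4", mutate(DECOY_SEQ, {2: "A"})),
        SequenceRecord("q5", mutate(TEMPLATE_SEQ, {30: "L", 40: "I"})),
    ]


@pytest.fixture(scope="session")
def template_library():
    return [
        SequenceRecord("5OCM", TEMPLATE_SEQ),
        SequenceRecord("1ABC", DECOY_SEQ),
    ]


def _with_reference_ligand(receptor: StructureModel) -> StructureModel:
    """Template structure = receptor + a bound reference ligand (9RH)
    occupying the substrate site."""
    atoms = [a.copy() for a in receptor.atoms]
    for i, (elem, xyz) in enumerate(
        [("C", (0.0, 0.0, 0.0)), ("C", (1.4, 0.0, 0.0)),
         ("N", (2.1, 1.2, 0.0))]
    ):
        atoms.append(
            Atom(
                name=f"{elem}{i + 1}",
                element=elem,
                residue_name="9RH",
                residue_index=1,
                chain_id="L",
                xyz=np.array(xyz),
                hetero=True,
            )
        )
    return StructureModel(
        model_id="template_5OCM", atoms=atoms, metadata=dict(receptor.metadata)
    )


@pytest.fixture(scope="session")
def pipeline_assets(tmp_path_factory, query_sequences, template_library):
    """File-based assets for the full workflow with fixture backends.

    Designed outcomes: q1 and q5 scored, q2 has no pose in the
    catalytic window, q3's model fails Ramachandran qualification, q4's
    best template is not a characterized IRED.
    """
    root = tmp_path_factory.mktemp("pipeline_assets")
    receptor, base_pose = make_receptor(
        ReceptorSpec(
            placements=(("ASP", 5.0), ("HIS", 6.0), ("GLU", 7.0)),
        )
    )
    template_structure = _with_reference_ligand(receptor)
    c4 = next(a for a in receptor.atoms if a.name == "C4").xyz

    seq_path = root / "queries.fasta"
    write_fasta(query_sequences, seq_path)
    tmpl_db_path = root / "templates.fasta"
    write_fasta(template_library, tmpl_db_path)
    tmpl_struct_path = root / "template.pdb"
    write_structure(template_structure, tmpl_struct_path)

    substrate_path = root / "substrate.pdb"
    write_structure(
        StructureModel("substrate", [a.copy() for a in base_pose.substrate_atoms]),
        substrate_path,
    )

    models_dir = root / "models"
    models_dir.mkdir()
    for qid in ("q1", "q2", "q5"):
        m = StructureModel(qid, [a.copy() for a in receptor.atoms])
        write_structure(m, models_dir / f"{qid}.pdb")
    # q3: a model dominated by non-core backbone dihedrals
    bad = make_ramachandran_chain(20, core_fraction=0.5, model_id="q3")
    write_structure(bad, models_dir / "q3.pdb")

    poses_dir = root / "poses"
    poses_dir.mkdir()
    pose_sets = {
        "q1": ([3.0, 3.6, 4.2, 6.5], [-9.0, -8.5, -8.0, -7.0]),
        "q2": ([3.0, 6.5], [-9.0, -8.0]),  # nothing in the window
        "q5": ([4.0, 5.5], [-7.5, -7.0]),
    }
    for qid, (dists, scores) in pose_sets.items():
        poses = make_pose_set(dists, scores, base_pose, c4_xyz=c4)
        write_poses(poses, poses_dir / f"{qid}__substrate.poses.pdb")

    return {
        "root": root,
        "sequences": seq_path,
        "template_db": tmpl_db_path,
        "template_structure": tmpl_struct_path,
        "substrate": substrate_path,
        "models_dir": models_dir,
        "poses_dir": poses_dir,
        "receptor": receptor,
        "base_pose": base_pose,
        "template_structure_obj": template_structure,
        "c4": c4,
    }
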