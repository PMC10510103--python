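"""Catalytic-geometry pose selection, active-site profiling, the
refined scoring function and panel ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iredpanel.docking import Pose
from iredpanel.fixtures import (
    DEFAULT_SUBSTRATE,
    ReceptorSpec,
    make_pose_set,
    make_receptor,
)
from iredpanel.scoring import (
    ActiveSiteProfile,
    CandidateStatus,
    PoseFilterConfig,
    ScoredCandidate,
    ScoringWeights,
    ShellConfig,
    active_site_profile,
    c4_n_distance,
    rank_candidates,
    read_ranking_csv,
    refined_score,
    select_best_pose,
    select_panel,
    write_ranking_csv,
)
from iredpanel.structmodel import Atom, StructureModel


def _single_atom_pose(xyz, score=-8.0):
    atom = Atom(
        name="N1", element="N", residue_name="SUB", residue_index=1,
        chain_id="S", xyz=np.asarray(xyz, dtype=float), hetero=True,
    )
    return Pose(pose_index=1, substrate_atoms=[atom], vina_score=score,
                n_atom_index=1)


def _receptor_with_c4(c4_xyz):
    atoms = [
        Atom(name="CA", element="C", residue_name="ALA", residue_index=i,
             chain_id="A", xyz=np.array([20.0 + i, 0.0, 0.0]))
        for i in range(1, 4)
    ]
    atoms.append(
        Atom(name="C4", element="C", residue_name="NAP", residue_index=1,
             chain_id="X", xyz=np.asarray(c4_xyz, dtype=float), hetero=True)
    )
    return StructureModel("r", atoms)


class TestC4NDistance:
    def test_three_four_five_triangle(self):
        receptor = _receptor_with_c4((0.0, 0.0, 0.0))
        pose = _single_atom_pose((0.0, 3.0, 4.0))
        assert c4_n_distance(pose, receptor) == pytest.approx(5.0)

    def test_coincident_atoms(self):
        receptor = _receptor_with_c4((1.0, 1.0, 1.0))
        pose = _single_atom_pose((1.0, 1.0, 1.0))
        assert c4_n_distance(pose, receptor) == 0.0

    def test_generator_requested_separation_recovered(self):
        spec = ReceptorSpec(cofactor_c4_xyz=(1.28, 0.0, 4.2))
        receptor, pose = make_receptor(spec)
        # substrate N sits at (1.28, 0, 0): requested separation 4.2
        assert receptor.metadata["c4_n_distance"] == pytest.approx(
            4.2, abs=1e-9
        )
        assert c4_n_distance(pose, receptor) == pytest.approx(4.2, abs=1e-9)

    def test_multiple_c4_atoms_rejected(self):
        receptor = _receptor_with_c4((0.0, 0.0, 0.0))
        receptor.atoms.append(
            Atom(name="C4", element="C", residue_name="NAP",
                 residue_index=2, chain_id="X", xyz=np.ones(3), hetero=True)
        )
        with pytest.raises(ValueError, match="exactly one"):
            c4_n_distance(_single_atom_pose((0, 0, 1.0)), receptor)


class TestSelectBestPose:
    def _poses(self, scores):
        return [
            Pose(pose_index=i + 1,
                 substrate_atoms=_single_atom_pose((0, 0, 0)).substrate_atoms,
                 vina_score=s, n_atom_index=1)
            for i, s in enumerate(scores)
        ]

    def test_window_filter_then_closest(self):
        poses = self._poses([-9.0, -8.0, -7.0, -6.0])
        got = select_best_pose(poses, [3.0, 3.6, 4.2, 6.5])
        assert got is not None
        pose, dist = got
        assert dist == 3.6
        assert pose.pose_index == 2

    def test_both_printed_cutoffs_exclusive_outside(self):
        poses = self._poses([-9.0, -8.0])
        assert select_best_pose(poses, [3.4, 6.1]) is None

    def test_boundaries_inclusive(self):
        poses = self._poses([-9.0, -8.0])
        got = select_best_pose(poses, [3.5, 6.0])
        assert got is not None and got[1] == 3.5

    def test_distance_tie_broken_by_vina_score(self):
        poses = self._poses([-7.0, -9.0])
        got = select_best_pose(poses, [4.0, 4.0])
        assert got is not None and got[0].vina_score == -9.0

    def test_full_tie_broken_by_pose_index(self):
        poses = self._poses([-8.0, -8.0])
        got = select_best_pose(poses, [4.0, 4.0])
        assert got is not None and got[0].pose_index == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            select_best_pose(self._poses([-8.0]), [4.0, 5.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.5, max_value=10.0), min_size=1,
                 max_size=8)
    )
    def test_selection_always_inside_window(self, distances):
        poses = self._poses([-8.0] * len(distances))
        cfg = PoseFilterConfig()
        got = select_best_pose(poses, distances, cfg)
        in_window = [d for d in distances
                     if cfg.min_distance <= d <= cfg.max_distance]
        if in_window:
            assert got is not None
            assert got[1] == min(in_window)
        else:
            assert got is None


class TestActiveSiteProfile:
    def test_placed_residues_counted_with_boundary_exclusion(
        self, shell_receptor
    ):
        receptor, pose = shell_receptor
        profile = active_site_profile(receptor, pose)
        # ASP@5.0 and GLU@7.9 acidic, LYS@8.1 outside, HIS@6.0 present
        assert (profile.n_acidic, profile.n_basic, profile.n_his) == (2, 0, 1)

    def test_empty_shell(self, bare_receptor):
        receptor, pose = bare_receptor
        profile = active_site_profile(receptor, pose)
        assert (profile.n_acidic, profile.n_basic, profile.n_his) == (0, 0, 0)

    def test_histidine_is_presence_flag_not_count(self):
        receptor, pose = make_receptor(
            ReceptorSpec(placements=(("HIS", 5.0), ("HIS", 6.0)))
        )
        assert active_site_profile(receptor, pose).n_his == 1

    def test_protonation_variants_normalized(self):
        receptor, pose = make_receptor(
            ReceptorSpec(placements=(("HID", 5.0), ("ASH", 6.0),
                                     ("LYN", 6.5)))
        )
        profile = active_site_profile(receptor, pose)
        assert (profile.n_acidic, profile.n_basic, profile.n_his) == (1, 1, 1)

    def test_no_protein_residues_rejected(self):
        receptor = StructureModel(
            "r",
            [Atom(name="C4", element="C", residue_name="NAP",
                  residue_index=1, chain_id="X", xyz=np.zeros(3),
                  hetero=True)],
        )
        with pytest.raises(ValueError, match="protein"):
            active_site_profile(receptor, _single_atom_pose((0, 0, 1.0)))

    def test_shell_membership_monotone_in_radius(self, shell_receptor):
        receptor, pose = shell_receptor
        members = []
        for radius in (4.0, 6.0, 8.0, 10.0):
            p = active_site_profile(receptor, pose,
                                    ShellConfig(radius=radius))
            members.append({(c, i) for c, i, _, _ in p.shell_residues})
        for smaller, larger in zip(members, members[1:]):
            assert smaller <= larger

    def test_matches_brute_force_on_random_receptors(self):
        rng = np.random.default_rng(12)
        names = ["ASP", "GLU", "LYS", "ARG", "HIS", "ALA", "SER", "TRP"]
        cfg = ShellConfig()
        for _ in range(30):
            placements = tuple(
                (str(rng.choice(names)), float(rng.uniform(3.0, 12.0)))
                for _ in range(rng.integers(1, 8))
            )
            receptor, pose = make_receptor(ReceptorSpec(placements=placements))
            profile = active_site_profile(receptor, pose, cfg)
            # brute force: python loops, no vectorization
            acidic = basic = 0
            his = False
            sub = [a.xyz for a in pose.substrate_atoms if a.is_heavy]
            for (chain, idx), atoms in receptor.protein_residues().items():
                dmin = min(
                    float(np.sqrt(np.sum((a.xyz - s) ** 2)))
                    for a in atoms if a.is_heavy
                    for s in sub
                )
                if dmin <= cfg.radius:
                    r = atoms[0].residue_name
                    if r in ("ASP", "GLU"):
                        acidic += 1
                    elif r in ("LYS", "ARG"):
                        basic += 1
                    elif r == "HIS":
                        his = True
            assert (profile.n_acidic, profile.n_basic, profile.n_his) == (
                acidic, basic, int(his)
            )


profiles = st.builds(
    ActiveSiteProfile,
    n_acidic=st.integers(0, 5),
    n_basic=st.integers(0, 5),
    n_his=st.integers(0, 1),
)


class TestRefinedScore:
    def test_zero_everything_is_zero(self):
        assert refined_score(0.0, ActiveSiteProfile(0, 0, 0)) == 0.0

    def test_vina_coefficient_is_four(self):
        assert refined_score(1.0, ActiveSiteProfile(0, 0, 0)) == 4.0

    def test_printed_equation_on_full_profile(self):
        # 4*(-8) + 1*2 - 9*1 + 9*1
        assert refined_score(-8.0, ActiveSiteProfile(2, 1, 1)) == -30.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(profiles, st.floats(-12, 0))
    def test_linear_in_each_count(self, profile, vina):
        w = ScoringWeights()
        base = refined_score(vina, profile, w)
        more_basic = ActiveSiteProfile(
            profile.n_acidic, profile.n_basic + 1, profile.n_his
        )
        assert refined_score(vina, more_basic, w) - base == pytest.approx(
            w.w_basic
        )
        more_acidic = ActiveSiteProfile(
            profile.n_acidic + 1, profile.n_basic, profile.n_his
        )
        assert refined_score(vina, more_acidic, w) - base == pytest.approx(
            w.w_acidic
        )

    def test_histidine_improves_score(self):
        without = refined_score(-8.0, ActiveSiteProfile(0, 0, 0))
        with_his = refined_score(-8.0, ActiveSiteProfile(0, 0, 1))
        assert with_his == without - 9.0


def _scored(seq_id, refined, vina=-8.0):
    pose = _single_atom_pose((0, 0, 0), score=vina)
    return ScoredCandidate(
        sequence_id=seq_id,
        status=CandidateStatus.SCORED,
        selected_pose=pose,
        c4_n_distance=4.0,
        profile=ActiveSiteProfile(0, 0, 0),
        refined_score=refined,
    )


class TestRankingAndPanel:
    def test_ascending_refined_score(self):
        ranked = rank_candidates(
            [_scored("a", -30.0), _scored("b", -12.0), _scored("c", -45.0)]
        )
        assert [c.refined_score for c in ranked] == [-45.0, -30.0, -12.0]

    def test_tie_broken_by_vina_then_id(self):
        ranked = rank_candidates(
            [_scored("a", -30.0, vina=-6.0), _scored("b", -30.0, vina=-8.0)]
        )
        assert [c.sequence_id for c in ranked] == ["b", "a"]
        ranked = rank_candidates(
            [_scored("b", -30.0), _scored("a", -30.0)]
        )
        assert [c.sequence_id for c in ranked] == ["a", "b"]

    def test_unscored_appended_after_scored(self):
        failed = ScoredCandidate("z", CandidateStatus.NO_VALID_POSE)
        ranked = rank_candidates([failed, _scored("a", -30.0)])
        assert [c.sequence_id for c in ranked] == ["a", "z"]

    def test_empty_input(self):
        assert rank_candidates([]) == []

    def test_ranking_is_permutation_and_shuffle_stable(self):
        rng = np.random.default_rng(13)
        cands = [_scored(f"s{i}", float(rng.normal())) for i in range(30)]
        ranked = rank_candidates(cands)
        assert sorted(c.sequence_id for c in ranked) == sorted(
            c.sequence_id for c in cands
        )
        shuffled = list(cands)
        rng.shuffle(shuffled)
        assert [c.sequence_id for c in rank_candidates(shuffled)] == [
            c.sequence_id for c in ranked
        ]

    def test_panel_truncates_to_twenty_by_default(self):
        ranked = rank_candidates(
            [_scored(f"s{i:02d}", float(-i)) for i in range(50)]
        )
        assert len(select_panel(ranked)) == 20

    def test_small_ranking_returned_whole(self):
        ranked = [_scored(f"s{i}", float(i)) for i in range(12)]
        assert len(select_panel(ranked, 20)) == 12
        assert select_panel(ranked, 0) == []

    def test_status_field_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ScoredCandidate("x", CandidateStatus.SCORED)

    def test_ranking_csv_roundtrip(self, tmp_path):
        ranked = rank_candidates(
            [_scored("a", -30.0), _scored("b", -12.0),
             ScoredCandidate("z", CandidateStatus.NOT_HOMOLOG)]
        )
        path = tmp_path / "ranking.csv"
        write_ranking_csv(ranked, path)
        df = read_ranking_csv(path)
        assert list(df["sequence_id"]) == ["a", "b", "z"]
        assert list(df["status"]) == ["scored", "scored", "not_homolog"]
        assert df.loc[0, "refined_score"] == -30.0
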