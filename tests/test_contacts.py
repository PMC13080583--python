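"""Interaction detectors, census bookkeeping, RMSD and oracle equivalence."""

import math

import numpy as np
import pytest

from conftest import (
    brute_hbond_pairs,
    brute_salt_bridge_pairs,
    brute_stack_pairs,
    build_random_frame,
    random_planted_spec,
    random_rotation,
)
from rsdomain.contacts import (
    AtomRecord,
    Frame,
    GeometryConfig,
    Trajectory,
    aggregate_replicates,
    backbone_rmsd_series,
    detect_all,
    detect_hbonds,
    detect_salt_bridges,
    detect_stacking,
    kabsch_rmsd,
    per_residue_profile,
    read_multimodel_pdb,
    summarize_frames,
)
from rsdomain.simulate import (
    GenConfig,
    PlantedComplexSpec,
    build_planted_complex,
    write_trajectory_pdb,
)


def _atom(name, resname, idx, chain, xyz):
    return AtomRecord(name=name, residue_name=resname, residue_index=idx,
                      chain_id=chain, xyz=np.array(xyz, dtype=float))


def _hexagon(center, radius=1.39, tilt_deg=0.0):
    """Planar 6-ring around center; optionally tilted about the y axis."""
    pts = []
    t = math.radians(tilt_deg)
    rot = np.array(
        [[math.cos(t), 0, math.sin(t)], [0, 1, 0], [-math.sin(t), 0, math.cos(t)]]
    )
    for k in range(6):
        a = k * math.pi / 3
        pts.append(rot @ np.array([radius * math.cos(a), radius * math.sin(a), 0.0]) + center)
    return pts


def _phe(idx, chain, center, tilt_deg=0.0):
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    return [
        _atom(n, "PHE", idx, chain, p)
        for n, p in zip(names, _hexagon(np.array(center), tilt_deg=tilt_deg))
    ]


class TestSaltBridgeDetector:
    def test_single_pair_within_cutoff(self):
        frame = Frame([
            _atom("NH1", "ARG", 1, "A", (0, 0, 0)),
            _atom("OD1", "ASP", 2, "A", (3.0, 0, 0)),
        ])
        events = detect_salt_bridges(frame)
        assert len(events) == 1
        assert events[0].kind == "salt_bridge"
        assert events[0].span == "intra"
        assert events[0].distance == pytest.approx(3.0)

    def test_pair_beyond_cutoff_ignored(self):
        frame = Frame([
            _atom("NH1", "ARG", 1, "A", (0, 0, 0)),
            _atom("OD1", "ASP", 2, "A", (5.5, 0, 0)),
        ])
        assert detect_salt_bridges(frame, GeometryConfig(saltbridge_cutoff=4.0)) == []

    def test_residue_pair_deduplication(self):
        # two donor N's both within range of two acceptor O's -> one event
        frame = Frame([
            _atom("NH1", "ARG", 1, "A", (0, 0, 0)),
            _atom("NH2", "ARG", 1, "A", (0, 2.0, 0)),
            _atom("OD1", "ASP", 2, "B", (3.0, 0, 0)),
            _atom("OD2", "ASP", 2, "B", (3.0, 2.0, 0)),
        ])
        events = detect_salt_bridges(frame)
        assert len(events) == 1
        assert events[0].span == "inter"

    def test_phosphoserine_is_acceptor(self):
        frame = Frame([
            _atom("NZ", "LYS", 1, "A", (0, 0, 0)),
            _atom("O2P", "SEP", 2, "B", (3.5, 0, 0)),
        ])
        events = detect_salt_bridges(frame)
        assert len(events) == 1


class TestHbondDetector:
    def test_ideal_linear_geometry(self):
        frame = Frame([
            _atom("OG", "SER", 1, "A", (0, 0, 0)),
            _atom("HG", "SER", 1, "A", (1.0, 0, 0)),
            _atom("OG1", "THR", 2, "A", (2.9, 0, 0)),
        ])
        events = detect_hbonds(frame)
        assert len(events) == 1
        assert events[0].angle == pytest.approx(180.0)

    def test_bent_geometry_rejected(self):
        frame = Frame([
            _atom("OG", "SER", 1, "A", (0, 0, 0)),
            _atom("HG", "SER", 1, "A", (1.0, 0, 0)),
            _atom("OG1", "THR", 2, "A", (0, 2.9, 0)),  # ~90 deg at H
        ])
        assert detect_hbonds(frame) == []

    def test_salt_bridge_pairs_excluded(self):
        frame = Frame([
            _atom("NZ", "LYS", 1, "A", (0, 0, 0)),
            _atom("HZ1", "LYS", 1, "A", (1.0, 0, 0)),
            _atom("OE1", "GLU", 2, "A", (2.9, 0, 0)),
        ])
        assert detect_salt_bridges(frame)  # it's a salt bridge...
        assert detect_hbonds(frame) == []  # ...so not an H-bond

    def test_missing_hydrogen_raises_without_inference(self):
        frame = Frame([
            _atom("OG", "SER", 1, "A", (0, 0, 0)),
            _atom("OG1", "THR", 2, "A", (2.9, 0, 0)),
        ])
        with pytest.raises(RuntimeError):
            detect_hbonds(frame)
        events = detect_hbonds(frame, GeometryConfig(infer_hydrogens=True))
        assert len(events) == 1


class TestStackingDetector:
    def test_parallel_phe_rings(self):
        frame = Frame(_phe(1, "A", (0, 0, 0)) + _phe(2, "B", (0, 0, 3.8)))
        events = detect_stacking(frame)
        assert len(events) == 1
        assert events[0].kind == "pi_pi"
        assert events[0].distance == pytest.approx(3.8)
        assert events[0].angle == pytest.approx(0.0, abs=1e-9)

    def test_thirty_degree_tilt_rejected(self):
        frame = Frame(_phe(1, "A", (0, 0, 0)) + _phe(2, "B", (0, 0, 3.8), tilt_deg=30.0))
        assert detect_stacking(frame) == []

    def test_tilt_within_threshold_accepted(self):
        frame = Frame(_phe(1, "A", (0, 0, 0)) + _phe(2, "B", (0, 0, 3.8), tilt_deg=15.0))
        events = detect_stacking(frame)
        assert len(events) == 1
        assert events[0].angle == pytest.approx(15.0, abs=1e-6)

    def test_arg_on_tyr_is_cation_pi(self):
        guanidinium = [
            _atom("CZ", "ARG", 1, "A", (0, 0, 0)),
            _atom("NE", "ARG", 1, "A", (1.33, 0, 0)),
            _atom("NH1", "ARG", 1, "A", (-0.67, 1.15, 0)),
            _atom("NH2", "ARG", 1, "A", (-0.67, -1.15, 0)),
        ]
        ring = _phe(2, "B", (0, 0, 4.0))
        for a in ring:
            a.residue_name = "TYR"
        events = detect_stacking(Frame(guanidinium + ring))
        assert len(events) == 1
        assert events[0].kind == "cation_pi"

    def test_collinear_plane_is_geometry_error(self):
        frame = Frame([
            _atom("CZ", "ARG", 1, "A", (0, 0, 0)),
            _atom("NE", "ARG", 1, "A", (1.0, 0, 0)),
            _atom("NH1", "ARG", 1, "A", (2.0, 0, 0)),
            _atom("NH2", "ARG", 1, "A", (3.0, 0, 0)),
        ])
        with pytest.raises(ValueError):
            detect_stacking(frame)


class TestOracleEquivalence:
    def test_detectors_match_brute_force_on_random_frames(self, rng):
        """All three detectors agree with an independent all-pairs oracle
        on dense random frames."""
        config = GeometryConfig()
        n_with_events = 0
        for _ in range(50):
            frame = build_random_frame(rng)
            sb = detect_salt_bridges(frame, config)
            sb_pairs = {tuple(sorted((e.partner_a, e.partner_b))) for e in sb}
            assert sb_pairs == brute_salt_bridge_pairs(frame)

            hb = detect_hbonds(frame, config, salt_bridge_pairs=sb_pairs)
            hb_pairs = {tuple(sorted((e.partner_a, e.partner_b))) for e in hb}
            assert hb_pairs == brute_hbond_pairs(frame, exclude=sb_pairs)

            st = detect_stacking(frame, config)
            st_pairs = {
                tuple(sorted((e.partner_a, e.partner_b))): e.kind for e in st
            }
            assert st_pairs == brute_stack_pairs(frame)
            if sb_pairs or hb_pairs or st_pairs:
                n_with_events += 1
        assert n_with_events >= 25  # the random frames genuinely exercise the detectors

    def test_planted_ground_truth_recovered_on_random_specs(self, rng):
        """Detector totals equal planted ground truth on every frame across
        >= 20 random specs."""
        for _ in range(20):
            spec = random_planted_spec(rng)
            built = build_planted_complex(spec, GenConfig(seed=int(rng.integers(2**31)),
                                                          noise_sd=0.05))
            for i, frame in enumerate(built.trajectory.frames):
                counts: dict = {}
                for e in detect_all(frame, frame_index=i):
                    counts[(e.kind, e.span)] = counts.get((e.kind, e.span), 0) + 1
                assert counts == built.ground_truth_counts


@pytest.fixture(scope="module")
def planted():
    spec = PlantedComplexSpec(
        chain_a_seq="R S R sep D F Y R K",
        chain_b_seq="R sep E S K Y W H T",
        planted_salt_bridges=[("A", 1, "B", 2), ("A", 9, "A", 5)],
        planted_hbonds=[("B", 4, "B", 3)],
        planted_stacks=[("A", 6, "B", 6), ("A", 8, "B", 7)],
        n_frames=6,
    )
    return build_planted_complex(spec, GenConfig(seed=4, noise_sd=0.05))


class TestCensusInvariants:

    def test_intra_plus_inter_equals_total(self, planted):
        for i, frame in enumerate(planted.trajectory.frames):
            events = detect_all(frame, frame_index=i)
            for kind in {e.kind for e in events}:
                intra = sum(1 for e in events if e.kind == kind and e.span == "intra")
                inter = sum(1 for e in events if e.kind == kind and e.span == "inter")
                total = sum(1 for e in events if e.kind == kind)
                assert intra + inter == total

    def test_rigid_motion_invariance(self, planted, rng):
        frame = planted.trajectory.frames[0]
        rot = random_rotation(rng)
        moved = frame.transformed(rot, np.array([11.0, -7.0, 3.0]))
        ev_orig = detect_all(frame)
        ev_moved = detect_all(moved)
        key = lambda e: (e.kind, e.partner_a, e.partner_b)
        assert sorted(map(key, ev_orig)) == sorted(map(key, ev_moved))
        for a, b in zip(sorted(ev_orig, key=key), sorted(ev_moved, key=key)):
            assert a.distance == pytest.approx(b.distance, abs=1e-9)

    def test_identical_replicates_have_zero_sd(self, planted):
        s = summarize_frames(planted.trajectory)
        agg = aggregate_replicates([s, s, s])
        assert all(v == 0.0 for v in agg.sd.values())
        assert agg.mean == s.mean_counts

    def test_replicate_mean_and_sd_hand_computed(self):
        def summary(v):
            from rsdomain.contacts import FrameSummary

            counts = {(k, s): 0.0 for k in ("salt_bridge",) for s in ("intra", "inter")}
            counts[("salt_bridge", "inter")] = v
            return FrameSummary(mean_counts=counts, n_frames=10)

        agg = aggregate_replicates([summary(2.0), summary(4.0), summary(6.0)])
        assert agg.mean[("salt_bridge", "inter")] == pytest.approx(4.0)
        assert agg.sd[("salt_bridge", "inter")] == pytest.approx(2.0)  # sample SD

    def test_mismatched_summary_keys_rejected(self):
        from rsdomain.contacts import FrameSummary

        a = FrameSummary(mean_counts={("salt_bridge", "intra"): 1.0}, n_frames=5)
        b = FrameSummary(mean_counts={("hbond", "intra"): 1.0}, n_frames=5)
        with pytest.raises(ValueError):
            aggregate_replicates([a, b])

    def test_separated_chains_intra_counts_match_single_chain_runs(self):
        """A two-chain fixture with only intrachain plants gives the same
        intra counts as the two chains analysed separately."""
        gen = GenConfig(seed=6, noise_sd=0.0)
        both = build_planted_complex(
            PlantedComplexSpec(
                chain_a_seq="R S D S", chain_b_seq="K E S S",
                planted_salt_bridges=[("A", 1, "A", 3), ("B", 1, "B", 2)],
                n_frames=3,
            ),
            gen,
        )
        alone_a = build_planted_complex(
            PlantedComplexSpec(chain_a_seq="R S D S",
                               planted_salt_bridges=[("A", 1, "A", 3)], n_frames=3),
            gen,
        )
        alone_b = build_planted_complex(
            PlantedComplexSpec(chain_a_seq="K E S S",
                               planted_salt_bridges=[("A", 1, "A", 2)], n_frames=3),
            gen,
        )
        s_both = summarize_frames(both.trajectory)
        s_a = summarize_frames(alone_a.trajectory)
        s_b = summarize_frames(alone_b.trajectory)
        assert s_both.mean_counts[("salt_bridge", "intra")] == (
            s_a.mean_counts[("salt_bridge", "intra")]
            + s_b.mean_counts[("salt_bridge", "intra")]
        )
        assert s_both.mean_counts[("salt_bridge", "inter")] == 0.0


class TestFrameWindows:
    def test_window_of_150ns_at_150ps_is_1000_frames(self):
        spec = PlantedComplexSpec(
            chain_a_seq="R S", chain_b_seq="D S",
            planted_salt_bridges=[("A", 1, "B", 1)], n_frames=1100,
        )
        built = build_planted_complex(spec, GenConfig(seed=0, noise_sd=0.05))
        assert built.trajectory.frame_interval == 150.0
        summary = summarize_frames(built.trajectory, window_ns=150.0)
        assert summary.n_frames == 1000
        assert summary.mean_counts[("salt_bridge", "inter")] == 1.0

    def test_window_longer_than_trajectory_rejected(self):
        spec = PlantedComplexSpec(chain_a_seq="R S", n_frames=5)
        built = build_planted_complex(spec, GenConfig(seed=0))
        with pytest.raises(ValueError):
            summarize_frames(built.trajectory, window_ns=150.0)


class TestPerResidueProfile:
    def test_single_planted_bridge_profile(self):
        spec = PlantedComplexSpec(
            chain_a_seq="S S S S R S", chain_b_seq="D S",
            planted_salt_bridges=[("A", 5, "B", 1)], n_frames=8,
        )
        built = build_planted_complex(spec, GenConfig(seed=1, noise_sd=0.05))
        profile = per_residue_profile(built.trajectory, "A")
        assert profile.per_residue[5] == 1.0
        assert all(v == 0.0 for k, v in profile.per_residue.items() if k != 5)
        assert profile.overall_mean == pytest.approx(1.0 / 6.0)

    def test_profile_sums_match_event_accounting(self):
        """Sum of per-residue counts equals 2x intra + once per interchain
        event touching the chain."""
        spec = PlantedComplexSpec(
            chain_a_seq="R S R S D S", chain_b_seq="K sep",
            planted_salt_bridges=[("A", 1, "A", 5), ("B", 1, "B", 2), ("A", 3, "B", 2)],
            n_frames=4,
        )
        # A3-B2 conflicts with B1-B2 (B2 reused) -> use separate acceptor
        spec.planted_salt_bridges = [("A", 1, "A", 5), ("A", 3, "B", 2)]
        built = build_planted_complex(spec, GenConfig(seed=2, noise_sd=0.05))
        profile = per_residue_profile(built.trajectory, "A")
        events = detect_all(built.trajectory.frames[0])
        sb = [e for e in events if e.kind == "salt_bridge"]
        intra_a = sum(1 for e in sb if e.span == "intra" and e.partner_a[0] == "A")
        inter_touch_a = sum(
            1 for e in sb if e.span == "inter"
            and ("A" in (e.partner_a[0], e.partner_b[0]))
        )
        assert sum(profile.per_residue.values()) == pytest.approx(
            2 * intra_a + inter_touch_a
        )

    def test_missing_chain_rejected(self):
        spec = PlantedComplexSpec(chain_a_seq="R S", n_frames=2)
        built = build_planted_complex(spec, GenConfig(seed=0))
        with pytest.raises(ValueError):
            per_residue_profile(built.trajectory, "Z")


class TestRmsd:
    def _traj(self, n_frames=5, noise=0.1):
        spec = PlantedComplexSpec(chain_a_seq="R S D F", n_frames=n_frames)
        return build_planted_complex(spec, GenConfig(seed=3, noise_sd=noise)).trajectory

    def test_frame_vs_itself_is_zero(self):
        traj = self._traj()
        r = backbone_rmsd_series(traj)
        assert r.series[0] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_copy_superposes_to_zero(self, rng):
        traj = self._traj(n_frames=1, noise=0.0)
        frame = traj.frames[0]
        moved = frame.transformed(random_rotation(rng), np.array([5.0, 6.0, 7.0]))
        moved_traj = Trajectory(frames=[frame, moved], frame_interval=150.0)
        r = backbone_rmsd_series(moved_traj)
        assert r.series[1] == pytest.approx(0.0, abs=1e-10)

    def test_uniform_displacement_without_superposition(self):
        traj = self._traj(n_frames=1, noise=0.0)
        frame = traj.frames[0]
        shifted = frame.transformed(np.eye(3), np.array([1.0, 0.0, 0.0]))
        pair = Trajectory(frames=[frame, shifted], frame_interval=150.0)
        no_fit = backbone_rmsd_series(pair, superpose=False)
        assert no_fit.series[1] == pytest.approx(1.0, abs=1e-12)
        with_fit = backbone_rmsd_series(pair, superpose=True)
        assert with_fit.series[1] == pytest.approx(0.0, abs=1e-10)

    def test_kabsch_agrees_with_scipy(self, rng):
        from scipy.spatial.transform import Rotation

        ref = rng.normal(size=(12, 3))
        rot = random_rotation(rng)
        mobile = (rot @ (ref + rng.normal(scale=0.2, size=ref.shape)).T).T + 4.0
        mine = kabsch_rmsd(mobile, ref)
        est, rssd = Rotation.align_vectors(
            ref - ref.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        assert mine == pytest.approx(rssd / np.sqrt(len(ref)), abs=1e-8)

    def test_jittered_stationary_trajectory_is_equilibrated(self):
        traj = self._traj(n_frames=40, noise=0.05)
        r = backbone_rmsd_series(traj, slope_threshold=0.05)
        assert r.equilibrated


class TestPdbIO:
    def test_multimodel_round_trip(self, tmp_path):
        spec = PlantedComplexSpec(
            chain_a_seq="R S sep", chain_b_seq="D S",
            planted_salt_bridges=[("A", 1, "B", 1)], n_frames=10,
        )
        built = build_planted_complex(spec, GenConfig(seed=8, noise_sd=0.05))
        path = tmp_path / "traj.pdb"
        write_trajectory_pdb(built.trajectory, path)
        back = read_multimodel_pdb(path)
        assert len(back) == 10
        assert len(back.frames[0]) == len(built.trajectory.frames[0])
        assert back.frame_interval == 150.0
        np.testing.assert_allclose(
            back.frames[3].coords, built.trajectory.frames[3].coords, atol=2e-3
        )
        summary = summarize_frames(back)
        assert summary.mean_counts[("salt_bridge", "inter")] == 1.0

    def test_single_model_file(self, tmp_path):
        spec = PlantedComplexSpec(chain_a_seq="R S", n_frames=1)
        built = build_planted_complex(spec, GenConfig(seed=0))
        path = tmp_path / "one.pdb"
        write_trajectory_pdb(built.trajectory, path)
        assert len(read_multimodel_pdb(path)) == 1

    def test_sep_phosphate_oxygens_are_acceptor_sites(self, tmp_path):
        spec = PlantedComplexSpec(chain_a_seq="sep", n_frames=1)
        built = build_planted_complex(spec, GenConfig(seed=0))
        path = tmp_path / "sep.pdb"
        write_trajectory_pdb(built.trajectory, path)
        frame = read_multimodel_pdb(path).frames[0]
        sep_oxy = [
            a.name for a in frame.atoms
            if a.residue_name == "SEP" and a.name in ("O1P", "O2P", "O3P")
        ]
        assert sorted(sep_oxy) == ["O1P", "O2P", "O3P"]

    def test_inconsistent_atom_counts_rejected(self, tmp_path):
        spec = PlantedComplexSpec(chain_a_seq="R S", n_frames=2)
        built = build_planted_complex(spec, GenConfig(seed=0))
        path = tmp_path / "bad.pdb"
        write_trajectory_pdb(built.trajectory, path)
        lines = path.read_text().splitlines()
        # drop one ATOM line from the second model
        for i in range(len(lines) - 1, 0, -1):
            if lines[i].startswith("ATOM"):
                del lines[i]
                break
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError):
            read_multimodel_pdb(path)

    def test_unknown_residue_warns_and_skips_sites(self):
        with pytest.warns(UserWarning):
            frame = Frame([_atom("CA", "XYZ", 1, "A", (0, 0, 0))])
        assert detect_all(frame) == []
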