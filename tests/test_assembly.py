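import numpy as np
import pytest

from combasm import correspondence as cr
from combasm import fixtures as fx
from combasm import representation as rp
from combasm.assembly_core import (
    AssemblyConfig,
    ClashContext,
    SubComplex,
    assemble,
    clash_filter,
    cluster_subcomplexes,
    connectivity_filter,
    correspondence_rmsd,
    merge,
    symmetry_reward,
)
from combasm.errors import AssemblyError, ConfigFormatError
from combasm.geometry import RigidTransform, random_rotation, rmsd
from combasm.model_io import AssemblyGroupSpec, SubunitDefinition
from combasm.representation import RepresentativeSubunit
from combasm.scoring_metrics import assembly_vs_truth_rmsd

from oracles import brute_force_clash_fractions, enumerate_assemblies


def _line_rep(name, n_res, spacing=20.0, plddt=90.0):
    """Backbone atoms far apart on a line: no unintended clashes."""
    bb = np.zeros((n_res, 4, 3))
    idx = np.arange(n_res * 4).reshape(n_res, 4)
    bb[:, :, 0] = idx * spacing
    return RepresentativeSubunit(
        name=name, backbone=bb, plddt=np.full(n_res, plddt),
        provenance="synthetic", mean_plddt=plddt,
    )


def _single(name):
    return SubComplex(
        placements={(name, 0): RigidTransform.identity()}, nodes=(),
        raw_score=0.0, tree_repr=name,
    )


class TestMerge:
    def test_single_application_matches_truth(self, chain_fixture):
        gt, models, reps, library = chain_fixture
        entry = next(e for e in library if {e.subunit_a, e.subunit_b} == {"A", "B"})
        lib_idx = library.index(entry)
        sub = merge(
            _single(entry.subunit_a), _single(entry.subunit_b), entry,
            (entry.subunit_a, 0), (entry.subunit_b, 0), lib_idx, reps,
        )
        assert sub.size == 2
        assert sub.raw_score == pytest.approx(entry.score)
        placed = sub.placements[(entry.subunit_b, 0)].apply(reps[entry.subunit_b].ca)
        assert np.abs(placed - entry.transform.apply(reps[entry.subunit_b].ca)).max() < 1e-9

    def test_cardinality(self, tree_fixture):
        gt, models, reps, library = tree_fixture
        ranked_left = assemble(reps, library, gt.definitions()[:3], AssemblyConfig())
        ranked_right = assemble(reps, library, gt.definitions()[3:], AssemblyConfig())
        left, right = ranked_left[0], ranked_right[0]
        sides = ({n for n, _ in left.placements}, {n for n, _ in right.placements})
        usable = [
            (i, e) for i, e in enumerate(library)
            if e.subunit_a in sides[0] and e.subunit_b in sides[1]
        ]
        assert usable, "tree fixture should offer a cross-side transform"
        i, e = usable[0]
        merged = merge(left, right, e, (e.subunit_a, 0), (e.subunit_b, 0), i, reps)
        assert merged.size == left.size + right.size

    def test_shared_placement_rejected(self, chain_fixture):
        gt, models, reps, library = chain_fixture
        entry = library[0]
        sub = _single(entry.subunit_a)
        with pytest.raises(AssemblyError):
            merge(sub, sub, entry, (entry.subunit_b, 0), (entry.subunit_b, 0),
                  0, reps)

    def test_associativity_of_geometry(self, chain_fixture):
        """(A+B)+C and A+(B+C) give the same geometry after superposition."""
        gt, models, reps, library = chain_fixture
        e_ab = next(e for e in library if {e.subunit_a, e.subunit_b} == {"A", "B"})
        e_bc = next(e for e in library if {e.subunit_a, e.subunit_b} == {"B", "C"})
        i_ab, i_bc = library.index(e_ab), library.index(e_bc)
        if e_ab.subunit_a != "A":
            e_ab = e_ab.inverted()
        if e_bc.subunit_a != "B":
            e_bc = e_bc.inverted()
        left = merge(
            merge(_single("A"), _single("B"), e_ab, ("A", 0), ("B", 0), i_ab, reps),
            _single("C"), e_bc, ("B", 0), ("C", 0), i_bc, reps,
        )
        right = merge(
            _single("A"),
            merge(_single("B"), _single("C"), e_bc, ("B", 0), ("C", 0), i_bc, reps),
            e_ab, ("A", 0), ("B", 0), i_ab, reps,
        )
        assert correspondence_rmsd(left, right, reps) < 1e-6


class TestSymmetryReward:
    @pytest.mark.parametrize(
        "score,expected", [(100.0, 100.0), (50.0, 75.0), (1.0, 1.99), (99.0, 99.99)]
    )
    def test_formula(self, score, expected):
        assert symmetry_reward(score, True) == pytest.approx(expected)

    def test_not_qualifying_returns_unchanged(self):
        assert symmetry_reward(50.0, False) == 50.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigFormatError):
            symmetry_reward(0.5)

    def test_six_ring_rewarded_five_ring_not(self):
        """The reward needs more than five identical copies in one orbit."""
        for copies, rewarded in ((5, False), (6, True), (8, True)):
            spec = fx.ToyComplexSpec(
                topology="ring", subunit_specs=(("A", 20, copies),), seed=1
            )
            gt, models = fx.fabricate_predictions(spec)
            reps = rp.select_representatives(models)
            library = rp.build_transform_library(models, reps)
            ranked = assemble(reps, library, gt.definitions(),
                              AssemblyConfig(beam_width=8))
            top = ranked[0]
            assert top.size == copies
            boosted = [n for n in top.nodes if n.score > 99.5]
            assert bool(boosted) is rewarded


class TestClashFilter:
    def test_far_apart_keeps(self):
        reps = {"A": _line_rep("A", 25), "B": _line_rep("B", 25)}
        sub = SubComplex(
            placements={
                ("A", 0): RigidTransform.identity(),
                ("B", 0): RigidTransform(np.eye(3), np.array([0.0, 5000.0, 0.0])),
            },
            nodes=(), raw_score=0.0,
        )
        keep, report = clash_filter(sub, reps, AssemblyConfig())
        assert keep
        assert max(report["max_clash_fraction"].values()) == 0.0

    def test_total_overlap_discards(self, chain_fixture):
        gt, models, reps, library = chain_fixture
        sub = SubComplex(
            placements={
                ("A", 0): RigidTransform.identity(),
                ("A", 1): RigidTransform.identity(),
            },
            nodes=(), raw_score=0.0,
        )
        keep, report = clash_filter(sub, reps, AssemblyConfig())
        assert not keep
        assert max(report["max_clash_fraction"].values()) > 0.99

    @pytest.mark.parametrize("n_overlap,expected_keep", [(4, True), (6, False)])
    def test_constructed_fraction_boundary(self, n_overlap, expected_keep):
        """4% of 100 atoms penetrating keeps; 6% discards (threshold 5%)."""
        rep_a = _line_rep("A", 25)
        bb_b = rep_a.backbone.copy() + np.array([0.0, 1000.0, 0.0])
        flat = bb_b.reshape(-1, 3)
        flat[:n_overlap] = rep_a.backbone.reshape(-1, 3)[:n_overlap]  # d=0 overlap
        rep_b = RepresentativeSubunit(
            name="B", backbone=bb_b, plddt=np.full(25, 90.0),
            provenance="synthetic", mean_plddt=90.0,
        )
        reps = {"A": rep_a, "B": rep_b}
        config = AssemblyConfig()
        sub = SubComplex(
            placements={
                ("A", 0): RigidTransform.identity(),
                ("B", 0): RigidTransform.identity(),
            },
            nodes=(), raw_score=0.0,
        )
        keep, report = clash_filter(sub, reps, config)
        assert keep is expected_keep
        # cross-check the fast path against the all-pairs distance oracle
        ctx = ClashContext(reps, config)
        fa, fb = ctx.pair_clash_fractions(
            "A", RigidTransform.identity(), "B", RigidTransform.identity()
        )
        oa, ob = brute_force_clash_fractions(
            ctx.atoms["A"], ctx.radii["A"], ctx.atoms["B"], ctx.radii["B"],
            config.clash_penetration,
        )
        assert (fa, fb) == (oa, ob) == (n_overlap / 100, n_overlap / 100)

    def test_low_plddt_atoms_excluded(self):
        """Only confident (plDDT > 80) atoms participate in clash tests, so a
        disordered region overlapping another subunit is tolerated."""
        rep_a = _line_rep("A", 25)
        bb = rep_a.backbone.copy() + np.array([0.0, 1000.0, 0.0])
        bb.reshape(-1, 3)[:40] = rep_a.backbone.reshape(-1, 3)[:40]  # overlap
        sub = SubComplex(
            placements={
                ("A", 0): RigidTransform.identity(),
                ("B", 0): RigidTransform.identity(),
            },
            nodes=(), raw_score=0.0,
        )
        confident = np.full(25, 90.0)
        disordered = confident.copy()
        disordered[:10] = 50.0  # the 40 overlapping atoms become unconfident
        for plddt, expected_keep in ((confident, False), (disordered, True)):
            rep_b = RepresentativeSubunit(
                name="B", backbone=bb, plddt=plddt,
                provenance="synthetic", mean_plddt=float(plddt.mean()),
            )
            reps = {"A": rep_a, "B": rep_b}
            keep, _ = clash_filter(sub, reps, AssemblyConfig())
            assert keep is expected_keep
        ctx = ClashContext({"A": rep_a, "B": rep_b}, AssemblyConfig())
        assert len(ctx.atoms["B"]) == 60  # only confident atoms considered


class TestConnectivityFilter:
    def _segmented_defs(self, seq_n, seq_c, linker=2):
        return [
            SubunitDefinition(name="N", sequence=seq_n, chain_names=("A",),
                              start_res=1),
            SubunitDefinition(name="C", sequence=seq_c, chain_names=("A",),
                              start_res=1 + len(seq_n) + linker),
        ]

    def _reps(self, n_len, c_len):
        return {"N": _line_rep("N", n_len, spacing=1.0),
                "C": _line_rep("C", c_len, spacing=1.0)}

    def _sub_with_gap(self, reps, gap):
        # place C so that Ca(last of N) -> Ca(first of C) = gap
        end = reps["N"].ca[-1]
        start = reps["C"].ca[0]
        shift = end - start + np.array([gap, 0.0, 0.0])
        return SubComplex(
            placements={
                ("N", 0): RigidTransform.identity(),
                ("C", 0): RigidTransform(np.eye(3), shift),
            },
            nodes=(), raw_score=0.0,
        )

    def test_distant_same_chain_segments_discarded(self):
        defs = self._segmented_defs("A" * 10, "G" * 10, linker=2)
        reps = self._reps(10, 10)
        sub = self._sub_with_gap(reps, 100.0)
        assert not connectivity_filter(sub, defs, AssemblyConfig(), reps)

    def test_close_segments_kept(self):
        defs = self._segmented_defs("A" * 10, "G" * 10, linker=2)
        reps = self._reps(10, 10)
        sub = self._sub_with_gap(reps, 5.0)  # allowance (2+1)*3 = 9
        assert connectivity_filter(sub, defs, AssemblyConfig(), reps)

    def test_boundary_is_allowance_exactly(self):
        defs = self._segmented_defs("A" * 10, "G" * 10, linker=2)
        reps = self._reps(10, 10)
        assert connectivity_filter(
            self._sub_with_gap(reps, 9.0), defs, AssemblyConfig(), reps
        )
        assert not connectivity_filter(
            self._sub_with_gap(reps, 9.01), defs, AssemblyConfig(), reps
        )

    def test_different_chains_never_tested(self):
        defs = [
            SubunitDefinition(name="N", sequence="A" * 10, chain_names=("A",)),
            SubunitDefinition(name="C", sequence="G" * 10, chain_names=("B",)),
        ]
        reps = self._reps(10, 10)
        sub = self._sub_with_gap(reps, 500.0)
        assert connectivity_filter(sub, defs, AssemblyConfig(), reps)


class TestClustering:
    def _noisy_copy(self, sub, reps, sigma, seed, score):
        rng = np.random.default_rng(seed)
        placements = {}
        for unit, t in sub.placements.items():
            jitter = RigidTransform(
                np.eye(3), rng.normal(scale=sigma, size=3)
            )
            placements[unit] = jitter.compose(t)
        return SubComplex(placements=placements, nodes=sub.nodes,
                          raw_score=score, tree_repr=f"n{seed}")

    def test_identical_geometries_collapse_keeping_best(self, chain_fixture):
        gt, models, reps, library = chain_fixture
        ranked = assemble(reps, library, gt.definitions(), AssemblyConfig())
        a = self._noisy_copy(ranked[0], reps, 0.0, 1, score=90.0)
        b = self._noisy_copy(ranked[0], reps, 0.0, 2, score=80.0)
        leaders = cluster_subcomplexes([a, b], AssemblyConfig(), reps)
        assert len(leaders) == 1
        assert leaders[0].raw_score == 90.0

    def test_distinct_geometries_stay_apart(self, chain_fixture):
        gt, models, reps, library = chain_fixture
        ranked = assemble(reps, library, gt.definitions(), AssemblyConfig())
        a = ranked[0]
        shifted = {
            u: RigidTransform(np.eye(3), np.array([10.0, 0, 0])).compose(t)
            if u[0] == "C" else t
            for u, t in a.placements.items()
        }
        b = SubComplex(placements=shifted, nodes=a.nodes, raw_score=a.raw_score,
                       tree_repr="shifted")
        leaders = cluster_subcomplexes([a, b], AssemblyConfig(), reps)
        assert len(leaders) == 2

    def test_noisy_replicas_form_one_cluster(self, chain_fixture):
        gt, models, reps, library = chain_fixture
        ranked = assemble(reps, library, gt.definitions(), AssemblyConfig())
        replicas = [
            self._noisy_copy(ranked[0], reps, 0.1, seed, score=100.0 - seed)
            for seed in range(100)
        ]
        leaders = cluster_subcomplexes(replicas, AssemblyConfig(), reps)
        assert len(leaders) == 1


class TestCorrespondence:
    def _ring_sub(self, reps, copies, seed=0, relabel=True, jitter=0.0):
        spec = fx.ToyComplexSpec(
            topology="ring", subunit_specs=(("A", 20, copies),), seed=1
        )
        gt = fx.build_ground_truth(spec)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(copies) if relabel else np.arange(copies)
        frame = RigidTransform(random_rotation(rng), rng.normal(scale=10.0, size=3))
        placements = {
            ("A", int(i)): frame.compose(gt.placements[("A", int(perm[i]))])
            for i in range(copies)
        }
        return SubComplex(placements=placements, nodes=(), raw_score=0.0)

    def test_relabeling_invariance(self, small_ring_fixture):
        gt, models, reps, library = small_ring_fixture
        a = self._ring_sub(reps, 6, seed=1, relabel=False)
        b = self._ring_sub(reps, 6, seed=2, relabel=True)
        assert correspondence_rmsd(a, b, reps) < 1e-6

    @pytest.mark.parametrize("p", [2, 3])
    def test_matches_factorial_enumeration(self, p):
        """Heuristic equals the p!-enumeration minimum for small copy counts."""
        rng_master = np.random.default_rng(42)
        for trial in range(25):
            rng = np.random.default_rng([p, trial])
            base = rng.normal(scale=5.0, size=(12, 3))
            units_a = []
            for _ in range(p):
                r = random_rotation(rng)
                units_a.append(("X", base @ r.T + rng.normal(scale=15.0, size=3)))
            other = rng.normal(scale=5.0, size=(10, 3))
            units_a.append(("Y", other + rng.normal(scale=15.0, size=3)))
            # relabeled + rigidly moved copy
            frame_r = random_rotation(rng)
            frame_t = rng.normal(scale=10.0, size=3)
            perm = rng.permutation(p)
            units_b = [units_a[int(i)] for i in perm] + [units_a[p]]
            units_b = [(n, ca @ frame_r.T + frame_t) for n, ca in units_b]
            heur = cr.min_rmsd(units_a, units_b)
            brute = cr.brute_force_min_rmsd(units_a, units_b)
            assert heur == pytest.approx(brute, abs=1e-9)

    def test_near_symmetric_ring_p4_within_tolerance(self):
        """Adversarial 4-fold ring: heuristic within 0.5 A of the 4! optimum."""
        gaps = []
        for trial in range(100):
            rng = np.random.default_rng([4, trial])
            base = rng.normal(scale=4.0, size=(12, 3))
            units_a = []
            for i in range(4):
                ang = np.pi / 2 * i + rng.normal(scale=0.02)
                rot = np.array([
                    [np.cos(ang), -np.sin(ang), 0],
                    [np.sin(ang), np.cos(ang), 0],
                    [0, 0, 1],
                ])
                units_a.append(("X", (base + [12, 0, 0]) @ rot.T))
            frame_r = random_rotation(rng)
            frame_t = rng.normal(scale=10.0, size=3)
            perm = rng.permutation(4)
            units_b = [
                ("X", units_a[int(i)][1] @ frame_r.T + frame_t) for i in perm
            ]
            gaps.append(
                cr.min_rmsd(units_a, units_b)
                - cr.brute_force_min_rmsd(units_a, units_b)
            )
        assert max(gaps) <= 0.5

    def test_composition_mismatch_rejected(self, chain_fixture):
        gt, models, reps, library = chain_fixture
        a = _single("A")
        b = _single("B")
        with pytest.raises(AssemblyError):
            correspondence_rmsd(a, b, reps)


class TestAssemblyDriver:
    def test_ring_recovery_small(self, small_ring_fixture):
        gt, models, reps, library = small_ring_fixture
        ranked = assemble(reps, library, gt.definitions(),
                          AssemblyConfig(beam_width=8))
        assert ranked[0].size == 6
        assert assembly_vs_truth_rmsd(ranked[0], gt, reps) < 1.0

    def test_tree_recovery_with_decoys(self, tree_fixture):
        gt, models, reps, library = tree_fixture
        ranked = assemble(reps, library, gt.definitions(),
                          AssemblyConfig(beam_width=20))
        assert ranked[0].size == 6
        assert assembly_vs_truth_rmsd(ranked[0], gt, reps) < 1.0

    def test_partial_assembly_when_unreachable(self, chain_fixture):
        gt, models, reps, library = chain_fixture
        ab_only = [e for e in library if {e.subunit_a, e.subunit_b} == {"A", "B"}]
        ranked = assemble(reps, ab_only, gt.definitions(), AssemblyConfig())
        assert ranked[0].size == 2
        assert dict(ranked[0].composition) == {"A": 1, "B": 1}

    def test_empty_library_raises(self, chain_fixture):
        gt, models, reps, library = chain_fixture
        with pytest.raises(AssemblyError):
            assemble(reps, [], gt.definitions(), AssemblyConfig())

    def test_monotone_beam(self, tree_fixture):
        """Widening the beam never lowers the top-1 score."""
        gt, models, reps, library = tree_fixture
        scores = []
        for k in (2, 5, 20):
            ranked = assemble(reps, library, gt.definitions(),
                              AssemblyConfig(beam_width=k))
            scores.append(ranked[0].score)
        assert scores[0] <= scores[1] + 1e-9 <= scores[2] + 2e-9

    def test_deterministic(self, tree_fixture):
        gt, models, reps, library = tree_fixture
        r1 = assemble(reps, library, gt.definitions(), AssemblyConfig(beam_width=10))
        r2 = assemble(reps, library, gt.definitions(), AssemblyConfig(beam_width=10))
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert a.raw_score == b.raw_score
            assert a.tree_repr == b.tree_repr
            for u in a.placements:
                assert np.abs(
                    a.placements[u].translation - b.placements[u].translation
                ).max() < 1e-12

    def test_groups_enforce_assembly_order(self, tree_fixture):
        gt, models, reps, library = tree_fixture
        groups = AssemblyGroupSpec(groups=(("A", "B"),))
        ranked = assemble(reps, library, gt.definitions(),
                          AssemblyConfig(beam_width=10), groups=groups)
        assert ranked[0].size == 6
        with pytest.raises(ConfigFormatError):
            assemble(reps, library, gt.definitions(), AssemblyConfig(),
                     groups=AssemblyGroupSpec(groups=(("A", "Zz"),)))


class TestOracleEquivalence:
    def _check(self, gt, reps, library, config):
        ranked = assemble(reps, library, gt.definitions(), config)
        oracle = enumerate_assemblies(reps, library, gt.definitions(), config)
        assert oracle, "oracle found no full assemblies"
        best_score = max(s for s, _ in oracle)
        n_units = len(gt.spec.units)
        assert ranked[0].size == n_units
        assert ranked[0].raw_score == pytest.approx(best_score, abs=1e-9)
        best_placements = max(oracle, key=lambda sp: sp[0])[1]
        units_oracle = [
            (name, t.apply(reps[name].ca))
            for (name, _c), t in sorted(best_placements.items())
        ]
        units_beam = [
            (u[0], ranked[0].placements[u].apply(reps[u[0]].ca))
            for u in sorted(ranked[0].placements)
        ]
        # exact correspondence resolution (N <= 4, all relabelings enumerable)
        assert cr.brute_force_min_rmsd(units_oracle, units_beam) < 1e-3

    def test_hetero_tree_of_four(self):
        """Beam assembly equals exhaustive tree x transform enumeration."""
        spec = fx.ToyComplexSpec(
            topology="tree",
            subunit_specs=tuple((c, 14, 1) for c in "ABCD"),
            seed=7,
            n_decoys=3,
        )
        gt, models = fx.fabricate_predictions(spec)
        reps = rp.select_representatives(models)
        library = rp.build_transform_library(models, reps)
        assert len(library) <= 6
        self._check(gt, reps, library, AssemblyConfig(beam_width=50))

    def test_homomer_ring_of_four(self):
        spec = fx.ToyComplexSpec(
            topology="ring", subunit_specs=(("A", 16, 4),), seed=5
        )
        gt, models = fx.fabricate_predictions(spec)
        reps = rp.select_representatives(models)
        library = rp.build_transform_library(models, reps)
        self._check(gt, reps, library, AssemblyConfig(beam_width=50))
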