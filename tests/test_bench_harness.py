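"""Synthetic fixtures, the mock docking backend and the ratio sweep."""

import numpy as np
import pytest
from scipy import stats

from dockbox.bench_harness import (
    MockComplex,
    compare_protocols,
    mock_dock,
    run_ratio_sweep,
    synth_complex,
    synth_ligand,
    synth_ranked_library,
)
from dockbox.boxing import DockingBox, SweepSpec
from dockbox.chem_io import LigandStructure, ProteinResidue, ProteinStructure
from dockbox.geometry import PocketSpec, geometric_center, radius_of_gyration
from dockbox.pose_eval import binding_residues, heavy_atom_rmsd
from dockbox.screening_metrics import (
    MetricReport,
    enrichment_auc,
    mann_whitney_u,
    score_class_summary,
)


def ring_complex(n_atoms: int = 12, radius: float = 5.0) -> MockComplex:
    """A planar ring ligand: any orientation that fits a tight cube is far
    from the native one, which makes the sampling-failure mode explicit."""
    angles = 2 * np.pi * np.arange(n_atoms) / n_atoms
    native = np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n_atoms)]
    )
    ligand = LigandStructure("ring", ["C"] * n_atoms, native[None])
    shell = [
        ProteinResidue(
            "A", i + 1, "PSD", ["C"],
            (native[i] * (radius + 3.5) / radius)[None, :],
        )
        for i in range(n_atoms)
    ]
    return MockComplex(
        ProteinStructure("ring-cpx", shell), ligand, native,
        PocketSpec((0.0, 0.0, 0.0)),
    )


class TestSynthLigand:
    def test_single_atom_rg_zero(self):
        ligand = synth_ligand(1, seed=0)
        assert radius_of_gyration(ligand) == 0.0

    def test_two_atoms_rg_half_bond(self):
        ligand = synth_ligand(2, bond_length=1.5, seed=1)
        assert radius_of_gyration(ligand) == pytest.approx(0.75)

    def test_bond_lengths_exact_and_self_avoiding(self):
        ligand = synth_ligand(20, seed=3)
        coords = ligand.coords(0)
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        np.testing.assert_allclose(steps, 1.5, atol=1e-9)
        dists = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        off_bond = dists[np.triu_indices(20, k=2)]
        assert off_bond.min() >= 1.5 - 1e-9

    def test_deterministic_per_seed(self):
        a = synth_ligand(10, seed=9)
        b = synth_ligand(10, seed=9)
        np.testing.assert_array_equal(a.conformers, b.conformers)

    def test_rg_grows_with_size(self):
        """Polymer scaling: mean Rg rises monotonically with chain length.

        100 seeded chains (10 seeds at each of 10 sizes); the per-size
        mean Rg must be almost perfectly rank-correlated with size.
        """
        sizes = range(5, 55, 5)
        mean_rgs = [
            np.mean(
                [
                    radius_of_gyration(synth_ligand(n, seed=10 * n + s))
                    for s in range(10)
                ]
            )
            for n in sizes
        ]
        rho = stats.spearmanr(list(sizes), mean_rgs).statistic
        assert rho > 0.9


class TestSynthComplex:
    def test_native_pose_on_pocket_center(self):
        cpx = synth_complex(12, seed=4)
        offset = np.linalg.norm(
            geometric_center(cpx.native_pose) - cpx.pocket.xyz
        )
        assert offset < 1.0

    def test_native_contacts_exist_at_default_cutoff(self):
        for seed in range(5):
            cpx = synth_complex(10, seed=seed)
            assert len(binding_residues(cpx.receptor, cpx.native_pose)) > 0

    def test_deterministic_per_seed(self):
        a = synth_complex(8, seed=6)
        b = synth_complex(8, seed=6)
        np.testing.assert_array_equal(a.native_pose, b.native_pose)
        assert len(a.receptor.residues) == len(b.receptor.residues)


class TestMockDock:
    def test_fixed_seed_identical_poses(self):
        cpx = synth_complex(12, seed=1)
        box = DockingBox((0, 0, 0), (12.0, 12.0, 12.0), "sweep")
        run1 = mock_dock(cpx, box, seed=5)
        run2 = mock_dock(cpx, box, seed=5)
        assert [p.score for p in run1] == [p.score for p in run2]
        np.testing.assert_array_equal(run1[0].coords, run2[0].coords)

    def test_pose_atoms_inside_box(self):
        cpx = synth_complex(12, seed=2)
        box = DockingBox((0, 0, 0), (14.0, 14.0, 14.0), "sweep")
        for pose in mock_dock(cpx, box, seed=3):
            assert box.contains(pose.coords)
            assert box.contains(geometric_center(pose.coords))

    def test_tiny_box_sampling_failure_is_empty(self):
        cpx = synth_complex(12, seed=3)
        box = DockingBox((0, 0, 0), (2.0, 2.0, 2.0), "sweep")
        assert mock_dock(cpx, box, seed=1) == []

    def test_box_below_native_extent_rarely_recovers(self):
        """A box smaller than the ligand's native extent forces failure.

        For a ring of diameter 10 A, an 8.3 A cube admits only strongly
        misoriented placements (or none): in at least 90% of seeds the
        result is either a sampling failure or a top pose above 5 A RMSD.
        """
        cpx = ring_complex()
        box = DockingBox((0, 0, 0), (8.3, 8.3, 8.3), "sweep")
        bad = 0
        trials = 100
        for seed in range(trials):
            poses = mock_dock(cpx, box, seed=seed)
            if not poses or heavy_atom_rmsd(
                cpx.native_pose, poses[0].coords
            ) > 5.0:
                bad += 1
        assert bad / trials >= 0.9

    def test_near_optimal_edge_beats_oversized_box(self):
        """Median top-pose RMSD at edge 2.9 x Rg beats a 36 A box."""
        optimal, oversized = [], []
        for seed in range(100):
            cpx = synth_complex(12, seed=seed)
            rg = radius_of_gyration(cpx.ligand)
            for edge, sink in ((2.9 * rg, optimal), (36.0, oversized)):
                box = DockingBox((0, 0, 0), (edge,) * 3, "sweep")
                poses = mock_dock(cpx, box, seed=seed)
                sink.append(
                    heavy_atom_rmsd(cpx.native_pose, poses[0].coords)
                    if poses else np.inf
                )
        assert np.median(optimal) < np.median(oversized)


class TestRatioSweep:
    def test_single_complex_single_edge(self):
        cpx = synth_complex(12, seed=0)
        curve = run_ratio_sweep(
            [cpx], SweepSpec(12, 12, 2), seed=1, min_bin_count=1
        )
        assert len(curve.points) == 1
        assert curve.points[0].n == 1

    def test_end_to_end_determinism(self):
        complexes = [synth_complex(10, seed=i) for i in range(4)]
        c1 = run_ratio_sweep(complexes, seed=11)
        c2 = run_ratio_sweep(complexes, seed=11)
        assert c1.points == c2.points
        assert c1.failures == c2.failures

    def test_interior_optimum_and_consistent_contact_peak(self):
        """The accuracy curves recover the interior optimum: RMSD is
        U-shaped and the contact-recovery curves peak in the same interior
        region, neither at the smallest nor the largest ratio."""
        cx = [synth_complex(12, seed=100 + i) for i in range(20)]
        curve = run_ratio_sweep(cx, seed=42)
        rmsds = [p.mean_rmsd for p in curve.points]
        contacts = [p.mean_frac_specific_contacts for p in curve.points]
        k_rmsd = int(np.argmin(rmsds))
        k_contact = int(np.argmax(contacts))
        assert 0 < k_rmsd < len(curve.points) - 1
        assert 0 < k_contact < len(curve.points) - 1
        assert abs(k_rmsd - k_contact) <= 2

    def test_failures_recorded_not_fatal(self):
        cpx = synth_complex(12, seed=5)
        curve = run_ratio_sweep([cpx], SweepSpec(2, 8, 2), seed=0,
                                min_bin_count=1)
        assert curve.failures  # the 2 A box cannot hold the ligand


class TestSyntheticLibrary:
    def test_large_sample_separation(self):
        lib = synth_ranked_library(5000, 5000, sd_active=2.1, sd_decoy=2.1,
                                   seed=0)
        _, p = mann_whitney_u(lib.scores[lib.labels], lib.scores[~lib.labels])
        assert p < 1e-10

    def test_null_model_auc_half(self):
        lib = synth_ranked_library(
            5000, 5000, mean_active=-8.0, mean_decoy=-8.0,
            sd_active=2.0, sd_decoy=2.0, seed=1,
        )
        assert enrichment_auc(lib) == pytest.approx(0.5, abs=0.02)

    def test_requested_means_recovered(self):
        lib = synth_ranked_library(5000, 5000, seed=2)
        summary = score_class_summary(lib)
        assert summary.mean_active == pytest.approx(-8.70, abs=0.1)
        assert summary.mean_decoy == pytest.approx(-7.85, abs=0.1)

    def test_deterministic_per_seed(self):
        a = synth_ranked_library(50, 200, seed=9)
        b = synth_ranked_library(50, 200, seed=9)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestCompareProtocols:
    def _report(self, ef1=8.0, ef10=3.3, bed=0.23, auc=0.70, act=0.24):
        return MetricReport(ef1, ef10, bed, auc, act)

    def test_identical_arms_tie_convention(self):
        arms = [self._report() for _ in range(10)]
        table = compare_protocols(arms, arms)
        assert (table["optimized_win_pct"] == 50.0).all()
        assert table["wilcoxon_p"].isna().all()

    def test_planted_uniform_improvement(self):
        default = [self._report(ef1=8.0 + 0.01 * i) for i in range(20)]
        optimized = [
            self._report(ef1=8.1 + 0.01 * i) for i in range(20)
        ]
        table = compare_protocols(default, optimized)
        assert table.loc["EF1%", "optimized_win_pct"] == 100.0
        assert table.loc["EF1%", "wilcoxon_p"] < 0.001

    def test_act50_direction_lower_is_better(self):
        default = [self._report(act=0.30)] * 4
        optimized = [self._report(act=0.20)] * 4
        table = compare_protocols(default, optimized)
        assert table.loc["ACT-50%", "optimized_win_pct"] == 100.0

    def test_swapping_arms_flips_win_fraction(self):
        rng = np.random.default_rng(8)
        default = [self._report(ef1=float(v)) for v in rng.normal(8, 1, 15)]
        optimized = [self._report(ef1=float(v)) for v in rng.normal(8.5, 1, 15)]
        fwd = compare_protocols(default, optimized)
        rev = compare_protocols(optimized, default)
        assert fwd.loc["EF1%", "optimized_win_pct"] == pytest.approx(
            100.0 - rev.loc["EF1%", "optimized_win_pct"]
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            compare_protocols([self._report()], [])
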