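"""Contact maps, PRE proxy, Rg, distance scaling, segment compaction."""

import numpy as np
import pytest

from lcdphase import conformation as cf
from lcdphase.sequence import ProteinSequence

from conftest import bead_trajectory


def brute_force_contact_map(traj, cutoff, mode, exclusion=1):
    """O(N^2) python double loop over heavy-atom pairs, every frame."""
    topo = traj.topology
    n_res = topo.n_residues
    counts = np.zeros((n_res, n_res))
    heavy = np.nonzero(topo.heavy)[0]
    chain = topo.chain_of_atom
    for f in range(traj.n_frames):
        for x, a in enumerate(heavy):
            for b in heavy[x + 1:]:
                ra, rb = topo.residue_index[a], topo.residue_index[b]
                same = chain[a] == chain[b]
                if mode == "intramolecular":
                    if not same or abs(ra - rb) <= exclusion:
                        continue
                    d = traj.xyz[f, a] - traj.xyz[f, b]
                else:
                    if same:
                        continue
                    d = traj.xyz[f, a] - traj.xyz[f, b]
                    if traj.box is not None:
                        d = d - traj.box[f] * np.round(d / traj.box[f])
                if np.dot(d, d) < cutoff ** 2:
                    counts[ra, rb] += 1
                    counts[rb, ra] += 1
    return counts


class TestContactMap:
    def test_threshold_behavior(self):
        xyz = np.array([[0, 0, 0], [0, 0, 0.59], [0, 0, 5.0]])
        traj = bead_trajectory(xyz)
        cmap = cf.contact_map(traj, 0.6, "intramolecular", exclusion=0)
        assert cmap.counts[0, 1] == 1 and cmap.counts[0, 2] == 0
        xyz2 = np.array([[0, 0, 0], [0, 0, 0.61], [0, 0, 5.0]])
        cmap2 = cf.contact_map(bead_trajectory(xyz2), 0.6, "intramolecular",
                               exclusion=0)
        assert cmap2.counts[0, 1] == 0

    def test_symmetry_on_random_frames(self, rng):
        xyz = rng.random((5, 12, 3)) * 2.0
        cmap = cf.contact_map(bead_trajectory(xyz), 0.6)
        np.testing.assert_array_equal(cmap.counts, cmap.counts.T)

    @pytest.mark.parametrize("mode", ["intramolecular", "intermolecular"])
    def test_equals_brute_force(self, rng, mode):
        n = 30
        xyz = rng.random((4, n, 3)) * 3.0
        chains = np.repeat([0, 1, 2], n // 3)
        traj = bead_trajectory(xyz, chain_of_residue=chains, box=(10, 10, 10))
        cmap = cf.contact_map(traj, 0.8, mode)
        ref = brute_force_contact_map(traj, 0.8, mode)
        np.testing.assert_array_equal(cmap.counts, ref)

    def test_intramolecular_excludes_bonded_neighbors(self):
        xyz = np.array([[0, 0, 0], [0, 0, 0.38], [0, 0, 0.76]])
        cmap = cf.contact_map(bead_trajectory(xyz), 0.6)
        assert cmap.counts[0, 1] == 0 and cmap.counts[1, 2] == 0

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            cf.contact_map(bead_trajectory(np.zeros((1, 2, 3))), -1.0)


class TestResidueTypeContacts:
    def test_type_aggregation_and_conservation(self, rng):
        seq = ProteinSequence("x", "YGYSG")
        xyz = rng.random((6, 5, 3)) * 1.2
        cmap = cf.contact_map(bead_trajectory(xyz, codes=seq.residues), 0.8)
        table = cf.residue_type_contacts(cmap, seq)
        # symmetric, and the unordered grand total is conserved
        np.testing.assert_array_equal(table.to_numpy(), table.to_numpy().T)
        assert np.triu(table.to_numpy()).sum() == pytest.approx(cmap.total)

    def test_single_type_pair(self):
        xyz = np.array([[0, 0, 0], [0, 0, 0.3], [0, 0, 0.5]])
        seq = ProteinSequence("x", "YGY")
        cmap = cf.contact_map(bead_trajectory(xyz, codes="YGY"), 0.6)
        table = cf.residue_type_contacts(cmap, seq)
        assert table.loc["Y", "Y"] == 1  # only the 1-3 pair survives exclusion
        assert table.to_numpy().sum() == 1  # same-type pairs sit on the diagonal

    def test_dimension_mismatch_rejected(self, rng):
        xyz = rng.random((1, 5, 3))
        cmap = cf.contact_map(bead_trajectory(xyz), 0.6)
        with pytest.raises(ValueError):
            cf.residue_type_contacts(cmap, ProteinSequence("x", "YG"))


class TestPerResidueContacts:
    def test_zero_map(self):
        xyz = np.array([[0, 0, 0], [0, 0, 5], [0, 5, 0]])
        cmap = cf.contact_map(bead_trajectory(xyz), 0.6)
        np.testing.assert_array_equal(cf.per_residue_contacts(cmap), 0.0)

    def test_profile_total_twice_map_total(self, rng):
        xyz = rng.random((3, 15, 3)) * 2.0
        cmap = cf.contact_map(bead_trajectory(xyz), 0.8)
        profile = cf.per_residue_contacts(cmap)
        assert profile.sum() * cmap.n_frames == pytest.approx(2 * cmap.total)

    def test_sticky_patch_peaks(self, rng):
        # 20 beads on a loose line; beads 8-11 collapse into one cluster
        # (bonded neighbors are excluded, so the patch needs >= 4 beads)
        xyz = np.zeros((1, 20, 3))
        xyz[0, :, 0] = np.arange(20) * 1.0
        xyz[0, 8:12, 0] = 9.5 + 0.1 * np.arange(4)
        cmap = cf.contact_map(bead_trajectory(xyz), 0.6)
        profile = cf.per_residue_contacts(cmap)
        assert profile[8:12].min() > profile[:7].max()


class TestPREProxy:
    def test_normalizing_residue_is_one_and_far_residue_zero(self):
        xyz = np.zeros((1, 4, 3))
        xyz[0, :, 0] = [0.0, 0.5, 1.0, 50.0]
        prof = cf.pre_proxy(bead_trajectory(xyz), label_residue=0,
                            cutoff_nm=3.5)
        assert prof.values[0] == 1.0
        assert prof.values[3] == 0.0

    def test_rigid_five_bead_chain_hand_computed(self):
        spacing = 0.7
        xyz = np.zeros((1, 5, 3))
        xyz[0, :, 0] = spacing * np.arange(5)
        prof = cf.pre_proxy(bead_trajectory(xyz), label_residue=0,
                            cutoff_nm=3.5)
        expected = (spacing * np.arange(1, 5)) ** -6.0
        expected = expected / expected.max()
        np.testing.assert_allclose(prof.values[1:], expected, rtol=1e-12)

    def test_scale_covariance(self, rng):
        xyz = rng.random((3, 8, 3)) * 2.0
        a = cf.pre_proxy(bead_trajectory(xyz), 2, cutoff_nm=3.5)
        s = 1.7
        b = cf.pre_proxy(bead_trajectory(xyz * s), 2, cutoff_nm=3.5 * s)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-10)

    def test_replica_sem(self, rng):
        trajs = [bead_trajectory(rng.random((5, 6, 3)) * 1.5)
                 for _ in range(4)]
        prof = cf.pre_proxy(trajs, 0)
        assert np.all(prof.sem >= 0) and prof.sem[0] == 0.0


class TestRadiusOfGyration:
    def test_coincident_beads_zero(self):
        traj = bead_trajectory(np.zeros((2, 6, 3)))
        rg = cf.radius_of_gyration(traj)
        np.testing.assert_allclose(rg.to_numpy(), 0.0, atol=1e-14)

    def test_collinear_rod_closed_form(self):
        n, b = 11, 0.38
        xyz = np.zeros((1, n, 3))
        xyz[0, :, 2] = b * np.arange(n)
        rg = cf.radius_of_gyration(bead_trajectory(xyz))
        expected = np.sqrt(b ** 2 * (n ** 2 - 1) / 12.0)
        assert rg.iloc[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_parallel_axis_combination(self, rng):
        """Whole-chain Rg^2 from segment Rg^2 + center dispersion."""
        xyz = rng.random((1, 12, 3)) * 3.0
        traj = bead_trajectory(xyz)
        whole = cf.radius_of_gyration(traj).iloc[0, 0]
        halves = [xyz[0, :6], xyz[0, 6:]]
        total = 0.0
        com = xyz[0].mean(axis=0)
        for part in halves:
            pc = part.mean(axis=0)
            rg2 = np.mean(np.sum((part - pc) ** 2, axis=1))
            total += 6 * (rg2 + np.sum((pc - com) ** 2))
        assert whole ** 2 == pytest.approx(total / 12, rel=1e-10)

    def test_wrapped_chain_detected(self):
        xyz = np.zeros((1, 3, 3))
        xyz[0, :, 0] = [0.2, 9.8, 0.6]  # bond jumps across the boundary
        traj = bead_trajectory(xyz, box=(10, 10, 10))
        with pytest.raises(ValueError):
            cf.radius_of_gyration(traj)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            cf.radius_of_gyration(bead_trajectory(np.zeros((1, 3, 3))),
                                  atom_indices=[])


class TestRgCorrelationTime:
    def test_ar1_recovery(self):
        """AR(1) series with lag-1 coefficient phi has ACF phi^k."""
        tau_true = 25.0
        phi = np.exp(-1.0 / tau_true)
        rng = np.random.default_rng(12)
        n = 200_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        tau = cf.rg_correlation_time(x, dt_ps=1.0)
        assert tau == pytest.approx(tau_true, rel=0.10)

    def test_white_noise_below_one_interval(self):
        rng = np.random.default_rng(0)
        tau = cf.rg_correlation_time(rng.standard_normal(5000), dt_ps=1.0)
        assert tau < 1.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            cf.rg_correlation_time(np.full(100, 2.0))


class TestDistanceScaling:
    def test_rigid_rod_exponent_one(self):
        n = 30
        xyz = np.zeros((1, n, 3))
        xyz[0, :, 0] = 0.38 * np.arange(n)
        ds = cf.distance_scaling(bead_trajectory(xyz))
        assert ds.exponent == pytest.approx(1.0, abs=1e-9)
        assert ds.mean_distance_nm[0] == 0.0

    def test_ideal_chain_exponent_half(self, rng):
        """Gaussian-chain ensemble: <r(s)> ~ s^0.5."""
        n, b, frames = 60, 0.38, 400
        steps = rng.normal(size=(frames, n - 1, 3))
        steps *= b / np.linalg.norm(steps, axis=2, keepdims=True)
        xyz = np.concatenate([np.zeros((frames, 1, 3)),
                              np.cumsum(steps, axis=1)], axis=1)
        ds = cf.distance_scaling(bead_trajectory(xyz),
                                 fit_window=(4, n // 2))
        assert ds.exponent == pytest.approx(0.5, abs=0.05)

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            cf.distance_scaling(bead_trajectory(np.zeros((1, 3, 3))))


class TestSegmentCompaction:
    def test_single_residue_segment_zero(self):
        xyz = np.random.default_rng(1).random((3, 10, 3))
        df = cf.segment_compaction(bead_trajectory(xyz), [(4, 4)])
        np.testing.assert_allclose(df["4-4"], 0.0, atol=1e-14)

    def test_homogeneous_chain_segments_indistinguishable(self, rng):
        from scipy import stats
        n, b, frames = 60, 0.38, 300
        steps = rng.normal(size=(frames, n - 1, 3))
        steps *= b / np.linalg.norm(steps, axis=2, keepdims=True)
        xyz = np.concatenate([np.zeros((frames, 1, 3)),
                              np.cumsum(steps, axis=1)], axis=1)
        df = cf.segment_compaction(bead_trajectory(xyz),
                                   [(1, 20), (21, 40), (41, 60)])
        ks = stats.ks_2samp(df["1-20"], df["21-40"])
        assert ks.pvalue > 0.01

    def test_collapsed_block_ranked_most_compact(self, rng):
        frames, n = 20, 30
        xyz = rng.random((frames, n, 3)) * 3.0
        xyz[:, 10:20, :] = xyz[:, 10:20, :] * 0.1  # collapsed middle block
        df = cf.segment_compaction(bead_trajectory(xyz),
                                   [(1, 10), (11, 20), (21, 30)])
        assert df.attrs["ranking"][0] == "11-20"

    def test_overlapping_segments_rejected_when_strict(self, rng):
        traj = bead_trajectory(rng.random((2, 10, 3)))
        with pytest.raises(ValueError):
            cf.segment_compaction(traj, [(1, 5), (4, 8)], strict=True)
        out = cf.segment_compaction(traj, [(1, 5), (4, 8)], strict=False)
        assert list(out.columns) == ["1-5", "4-8"]
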