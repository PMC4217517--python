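"""Measurement devices: timing, flow-sort, combing, rates, indices."""

import numpy as np
import pandas as pd
import pytest

import forksim as fs
from forksim.engine import EnsembleRecord, Snapshot
from forksim.instruments import _combing_one_mask, mask_runs


def empty_record(n_bins=10, binsize=500, ncells=4, nfork=4):
    return EnsembleRecord(
        n_bins=n_bins, binsize=binsize, ncells=ncells, nfork=nfork,
        timing_sum=np.zeros(n_bins), timing_sumsq=np.zeros(n_bins),
        n_cycles=0, init_counts=np.zeros(n_bins, dtype=np.int64),
        events_by_count=np.zeros(n_bins + 1, dtype=np.int64),
        exposure_by_count=np.zeros(n_bins + 1),
    )


def snapshot_from_masks(masks, time_in_s=None, engaged=None, in_s=None,
                        global_sweep=0):
    masks = np.asarray(masks, dtype=bool)
    ncells = masks.shape[0]
    in_s = np.ones(ncells, bool) if in_s is None else np.asarray(in_s, bool)
    t = (np.zeros(ncells, np.int64) if time_in_s is None
         else np.asarray(time_in_s, np.int64))
    eng = (np.zeros(ncells, np.int64) if engaged is None
           else np.asarray(engaged, np.int64))
    frac = masks.mean(axis=1)
    frac[~in_s] = 0.0
    return Snapshot(global_sweep=global_sweep, in_s=in_s, frac=frac,
                    engaged=eng, time_in_s=t, masks=masks)


class TestTimingProfile:
    def test_mean_over_cycles(self):
        rec = empty_record(n_bins=2)
        rec.timing_sum[:] = [3 + 5, 4 + 2]
        rec.timing_sumsq[:] = [9 + 25, 16 + 4]
        rec.n_cycles = 2
        tp = fs.timing_profile(rec)
        assert np.allclose(tp.mean_sweep, [4.0, 3.0])

    def test_normalized_form_zero_mean_unit_var_early_high(self):
        rec = empty_record(n_bins=5)
        rec.timing_sum[:] = [0, 1, 2, 3, 4]
        rec.n_cycles = 1
        z = fs.timing_profile(rec).normalized
        assert abs(z.mean()) < 1e-12 and abs(z.std() - 1) < 1e-12
        assert z[0] > z[-1]  # earliest bin scores highest

    def test_requires_completed_cycle(self):
        with pytest.raises(ValueError, match="no completed"):
            fs.timing_profile(empty_record())

    def test_bedgraph_output(self, tmp_path):
        rec = empty_record(n_bins=3, binsize=500)
        rec.timing_sum[:] = [1, 2, 3]
        rec.n_cycles = 1
        out = tmp_path / "t.bedgraph"
        fs.timing_profile(rec).to_bedgraph(out, chrom="chrTest")
        df = pd.read_csv(out, sep="\t", header=None)
        assert list(df[1]) == [0, 500, 1000]
        assert list(df[2]) == [500, 1000, 1500]
        assert list(df[0].unique()) == ["chrTest"]


class TestMaskRuns:
    def test_reference_mask(self):
        # 0011100110 -> eyes 1500,1000 bp; holes 1000,1000,500; e2e 2250
        mask = np.array([0, 0, 1, 1, 1, 0, 0, 1, 1, 0], bool)
        eyes, holes, e2e = _combing_one_mask(mask, 500)
        assert eyes == [1500, 1000]
        assert holes == [1000, 1000, 500]
        assert e2e == [2250.0]

    def test_all_unreplicated(self):
        eyes, holes, e2e = _combing_one_mask(np.zeros(8, bool), 500)
        assert eyes == [] and e2e == []
        assert holes == [8 * 500]

    def test_all_replicated(self):
        eyes, holes, e2e = _combing_one_mask(np.ones(8, bool), 500)
        assert eyes == [8 * 500] and holes == [] and e2e == []

    def test_boundary_eyes_excluded_from_e2e(self):
        # eye touching the left end has a censored center
        mask = np.array([1, 1, 0, 1, 0, 1, 0], bool)
        eyes, holes, e2e = _combing_one_mask(mask, 100)
        assert eyes == [200, 100, 100]
        assert e2e == [200.0]  # only the two interior eyes (bins 3 and 5)

    def test_runs_partition_mask(self):
        rng = np.random.default_rng(1)
        mask = rng.random(50) < 0.4
        eyes, holes = mask_runs(mask)
        covered = sorted([r for s, e in eyes + holes for r in range(s, e)])
        assert covered == list(range(50))


class TestSingleMoleculeStats:
    def test_time_binned_means(self):
        rec = empty_record(n_bins=10, binsize=500)
        early = snapshot_from_masks(
            [[0, 0, 1, 1, 1, 0, 0, 1, 1, 0]], time_in_s=[2])
        late = snapshot_from_masks(
            [[1, 1, 1, 1, 1, 1, 0, 1, 1, 1]], time_in_s=[8])
        rec.snapshots = [early, late]
        df = fs.single_molecule_stats(rec, time_bins=2)
        assert len(df) == 2
        assert df.loc[0, "mean_eye_bp"] == 1250.0   # (1500+1000)/2
        assert df.loc[0, "mean_hole_bp"] == pytest.approx(2500 / 3)
        assert df.loc[0, "mean_e2e_bp"] == 2250.0
        assert df.loc[1, "mean_hole_bp"] == 500.0
        assert df.loc[1, "n_cells"] == 1

    def test_validates_inputs(self):
        rec = empty_record()
        with pytest.raises(ValueError):
            fs.single_molecule_stats(rec, time_bins=0)
        with pytest.raises(ValueError, match="no snapshots"):
            fs.single_molecule_stats(rec, time_bins=2)


class TestFlowSort:
    def test_cell_assigned_to_containing_interval(self):
        rec = empty_record(n_bins=10)
        mask = np.zeros((1, 10), bool)
        mask[0, :3] = True  # 30% replicated
        rec.snapshots = [snapshot_from_masks(mask)]
        res = fs.flow_sort(rec, [0, 0.5, 1.0])
        assert res.cells_per_interval.tolist() == [1, 0]
        assert res.counts[0, :3].tolist() == [1, 1, 1]
        assert res.counts.sum() == 3

    def test_boundary_value_goes_right_and_last_closed(self):
        rec = empty_record(n_bins=10)
        m_half = np.zeros((1, 10), bool); m_half[0, :5] = True   # exactly 0.5
        m_full = np.ones((1, 10), bool)                          # exactly 1.0
        rec.snapshots = [snapshot_from_masks(m_half),
                         snapshot_from_masks(m_full)]
        res = fs.flow_sort(rec, [0, 0.5, 1.0])
        assert res.cells_per_interval.tolist() == [0, 2]

    def test_derived_timing_degenerate_first_interval(self):
        rec = empty_record(n_bins=4)
        mask = np.zeros((1, 4), bool)
        mask[0, 0] = True  # fraction 0.25, bin 0 replicated
        rec.snapshots = [snapshot_from_masks(mask)]
        res = fs.flow_sort(rec, [0, 0.5, 1.0])
        assert res.derived_timing[0] == 0.25  # midpoint of [0, 0.5)
        assert np.isnan(res.derived_timing[1])  # bin never replicated

    def test_counts_sum_matches_sorted_pairs(self):
        L = fs.synthetic_landscape("uniform", 8, p=0.6)
        cfg = fs.SimulationConfig(ncells=10, nfork=4, ntherm=5,
                                  nmeas=6, stepsize=4, seed=3)
        rec = fs.run_simulation(cfg, L)
        res = fs.flow_sort(rec, [0, 0.25, 0.5, 0.75, 1.0])
        expected = np.zeros(8, dtype=int)
        for snap in rec.snapshots:
            for i in np.flatnonzero(snap.in_s):
                expected += snap.masks[i]
        assert np.array_equal(res.counts.sum(axis=0), expected)

    @pytest.mark.parametrize("bad", [[0.5], [0, 0.5, 0.5, 1], [0, 1.2], [-0.1, 1]])
    def test_validates_boundaries(self, bad):
        rec = empty_record()
        with pytest.raises(ValueError):
            fs.flow_sort(rec, bad)


class TestInitiationRate:
    def test_events_over_exposure(self):
        rec = empty_record(n_bins=100)
        rec.events_by_count[0] = 2       # fired while 0 bins replicated
        rec.exposure_by_count[0] = 100.0
        df = fs.initiation_rate(rec, fraction_bins=10)
        assert df.loc[0, "rate"] == pytest.approx(0.02)

    def test_zero_exposure_reported_missing(self):
        rec = empty_record(n_bins=100)
        rec.exposure_by_count[0] = 50.0  # only the first fraction bin exposed
        df = fs.initiation_rate(rec, fraction_bins=4)
        assert df.loc[0, "rate"] == 0.0
        assert df.loc[3, "rate"] != df.loc[3, "rate"]  # NaN, not zero

    def test_delta_landscape_all_events_at_zero_fraction(self, delta10):
        cfg = fs.SimulationConfig(ncells=10, nfork=2, ntherm=10,
                                  nmeas=3, stepsize=40, seed=2)
        rec = fs.run_simulation(cfg, delta10)
        df = fs.initiation_rate(rec, fraction_bins=5)
        assert df["events"].sum() > 0
        assert df.loc[1:, "events"].sum() == 0  # single origin fires first


class TestNascentProfile:
    def test_delta_counts_concentrate_at_origin(self, delta10):
        cfg = fs.SimulationConfig(ncells=10, nfork=2, ntherm=10,
                                  nmeas=3, stepsize=40, seed=2)
        rec = fs.run_simulation(cfg, delta10)
        counts = fs.nascent_profile(rec)
        assert counts[0] == rec.n_cycles
        assert counts[1:].sum() == 0

    def test_uniform_counts_approximately_uniform(self):
        L = fs.synthetic_landscape("uniform", 6, p=1.0)
        cfg = fs.SimulationConfig(ncells=100, nfork=2, ntherm=10,
                                  nmeas=4, stepsize=60, seed=8)
        rec = fs.run_simulation(cfg, L)
        counts = fs.nascent_profile(rec)
        from scipy import stats
        assert counts.sum() > 2000
        # the FIRST event of each cycle is uniform; later picks favour
        # whatever remains, which is still symmetric-uniform here
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_no_cycles_all_zero(self):
        assert fs.nascent_profile(empty_record()).sum() == 0


class TestIndices:
    def test_fractions(self):
        rec = empty_record(n_bins=10, ncells=4, nfork=50)
        masks = np.zeros((4, 10), bool)
        snap = snapshot_from_masks(
            masks, in_s=[True, True, True, False], engaged=[4, 6, 0, 0])
        rec.snapshots = [snap]
        df = fs.indices(rec)
        assert df.loc[0, "s_fraction"] == 0.75
        assert df.loc[0, "engagement"] == pytest.approx(10 / (50 * 3))

    def test_all_g_population(self):
        rec = empty_record(ncells=4)
        rec.snapshots = [snapshot_from_masks(np.zeros((4, 10), bool),
                                             in_s=[False] * 4)]
        df = fs.indices(rec)
        assert df.loc[0, "s_fraction"] == 0.0
        assert df.loc[0, "engagement"] == 0.0


class TestPearsonRmsd:
    def test_identical_vectors(self):
        r, rmsd = fs.pearson_rmsd([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0) and rmsd == 0.0

    def test_anticorrelated(self):
        v = np.array([1.0, 2.0, 5.0])
        r, _ = fs.pearson_rmsd(v, -v)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        r, rmsd = fs.pearson_rmsd([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.9819805, abs=1e-6)
        assert rmsd == pytest.approx(np.sqrt(1 / 3), abs=1e-9)

    def test_pairwise_deletion_and_errors(self):
        r, rmsd = fs.pearson_rmsd([1, 2, 3, np.nan, 5],
                                  [1, 2, 3, 10.0, 5.5])
        assert r > 0.99
        with pytest.raises(ValueError, match="3 complete"):
            fs.pearson_rmsd([1, np.nan, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="variance"):
            fs.pearson_rmsd([1, 1, 1], [1, 2, 3])
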