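import numpy as np
import pandas as pd
import pytest
from scipy import stats

from switchseq import facsseq, readcount, rnaseq_quant
from switchseq.readcount import CountTable
from switchseq.synthetic_data import (
    SimConfig,
    default_barcodes,
    default_template,
    expected_counts,
    simulate_counts,
    simulate_facs,
    simulate_ground_truth,
    simulate_reads,
)


def small_config(**overrides):
    defaults = dict(seed=7, n_variants=50, depth_dna=50_000, depth_rna=50_000,
                    n_replicates=2)
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestGroundTruth:
    def test_zero_dispersion_equal_weights(self):
        gt = simulate_ground_truth(small_config(sigma_dna=0.0))
        lib = gt.table[~gt.table.is_control]
        assert (lib.w == 1.0).all()

    def test_no_switching_means_unit_ar(self):
        gt = simulate_ground_truth(small_config(p_switch=0.0))
        assert np.allclose(gt.table.true_ar, 1.0)
        assert np.allclose(gt.table.f0, gt.table.f1)

    def test_seed_determinism(self):
        a = simulate_ground_truth(small_config())
        b = simulate_ground_truth(small_config())
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_truth_invariants(self):
        gt = simulate_ground_truth(small_config(p_switch=0.5))
        t = gt.table
        assert ((t.f0 > 0) & (t.f0 <= t.f1) & (t.f1 <= 1)).all()
        assert (t.w > 0).all()
        assert (t.true_ar >= 1).all()

    def test_full_enumeration_when_requested(self):
        gt = simulate_ground_truth(small_config(n_variants=256, loop_lengths=(4,)))
        lib = gt.table[~gt.table.is_control]
        assert len(lib) == 256
        assert lib.index.is_unique

    def test_controls_present_with_reference(self):
        gt = simulate_ground_truth(small_config())
        assert "sTRSVctl" in gt.table.index
        assert gt.table.loc["sTRSVctl", "f0"] == 1.0

    def test_seed_mandatory(self):
        with pytest.raises(TypeError):
            SimConfig()  # seed has no default


class TestSimulateCounts:
    def test_depth_conservation(self):
        cfg = small_config()
        gt = simulate_ground_truth(cfg)
        table = simulate_counts(gt, cfg)
        for col in table.counts.columns:
            depth = cfg.depth_dna if col[0] == "DNA" else cfg.depth_rna
            assert table.counts[col].sum() == depth

    def test_expected_counts_give_exact_rd(self):
        # analytic: on expectation counts, RD = 100 * f_v / f_ctl exactly
        cfg = small_config()
        gt = simulate_ground_truth(cfg)
        exp = expected_counts(gt, cfg)
        cols = {(assay, cond, 1): exp[(assay, cond)]
                for assay in ("DNA", "RNA") for cond in ("minus", "plus")}
        frame = pd.DataFrame(cols)
        frame.columns = pd.MultiIndex.from_tuples(
            frame.columns, names=("assay", "condition", "replicate"))
        table = CountTable(frame, frozenset(c.name for c in gt.controls))
        rd = rnaseq_quant.rd_normalize(table)
        for cond, fcol in (("minus", "f0"), ("plus", "f1")):
            assert np.allclose(rd[(cond, 1)].to_numpy(),
                               100.0 * gt.table[fcol].to_numpy())

    def test_expected_ar_exact(self):
        cfg = small_config()
        gt = simulate_ground_truth(cfg)
        exp = expected_counts(gt, cfg)
        rd_minus = exp[("RNA", "minus")] / exp[("DNA", "minus")]
        rd_plus = exp[("RNA", "plus")] / exp[("DNA", "plus")]
        ar = rnaseq_quant.activation_ratio(rd_minus, rd_plus)
        # per-variant normalizer totals differ between conditions by a
        # constant, so AR equals f1/f0 up to that constant for every variant
        ratio = ar.to_numpy() / gt.table.true_ar.to_numpy()
        assert np.allclose(ratio, ratio[0])

    def test_deep_sequencing_recovers_truth(self):
        cfg = SimConfig(seed=11, n_variants=1000, depth_dna=10**6,
                        depth_rna=10**6, sigma_dna=0.5, p_switch=0.0)
        gt = simulate_ground_truth(cfg)
        table = simulate_counts(gt, cfg)
        rd = rnaseq_quant.rd_normalize(table)
        truth = 100.0 * gt.table.f0
        est = rd["minus"].mean(axis=1)
        joined = pd.concat([np.log10(est.rename("est")),
                            np.log10(truth.rename("truth"))], axis=1).dropna()
        r = np.corrcoef(joined.est, joined.truth)[0, 1]
        assert r ** 2 > 0.95
        rho = stats.spearmanr(joined.est, joined.truth).statistic
        assert rho > 0.95


class TestSimulateReads:
    def test_zero_error_round_trip(self):
        cfg = small_config(n_variants=20, depth_dna=2000, depth_rna=2000,
                           n_replicates=1)
        gt = simulate_ground_truth(cfg)
        counts = simulate_counts(gt, cfg)
        template = default_template(cfg.loop_lengths)
        barcodes = default_barcodes(list(counts.counts.columns))
        reads = [seq for _, seq in simulate_reads(
            counts, template, barcodes, gt.controls, error_rate=0.0)]
        streams, discarded = readcount.demultiplex(reads, barcodes)
        assert discarded == 0
        matched = readcount.match_stream(streams, template, gt.controls)
        recovered = readcount.count_variants(
            matched, gt.controls, conditions=list(barcodes.values()))
        lhs = recovered.counts.sort_index().sort_index(axis=1)
        rhs = counts.counts.sort_index().sort_index(axis=1)
        pd.testing.assert_frame_equal(lhs, rhs, check_dtype=False)

    def test_total_error_kills_matching(self, rng):
        cfg = small_config(n_variants=5, depth_dna=200, depth_rna=200,
                           n_replicates=1)
        gt = simulate_ground_truth(cfg)
        counts = simulate_counts(gt, cfg)
        template = default_template(cfg.loop_lengths)
        barcodes = default_barcodes(list(counts.counts.columns))
        reads = [seq for _, seq in simulate_reads(
            counts, template, barcodes, gt.controls, error_rate=1.0, rng=rng)]
        streams, _ = readcount.demultiplex(reads, barcodes)
        matched = list(readcount.match_stream(streams, template, gt.controls))
        assert len(matched) < 0.01 * len(reads)

    def test_matched_fraction_tracks_error_rate(self, rng):
        cfg = small_config(n_variants=10, depth_dna=4000, depth_rna=4000,
                           n_replicates=1, error_rate=0.01)
        gt = simulate_ground_truth(cfg)
        counts = simulate_counts(gt, cfg)
        template = default_template(cfg.loop_lengths)
        barcodes = default_barcodes(list(counts.counts.columns))
        reads = [seq for _, seq in simulate_reads(
            counts, template, barcodes, gt.controls, error_rate=0.01, rng=rng)]
        streams, discarded = readcount.demultiplex(reads, barcodes)
        matched = sum(1 for _ in readcount.match_stream(streams, template,
                                                        gt.controls))
        read_len = len(reads[0])
        expected = (1 - 0.01) ** read_len
        observed = matched / len(reads)
        # loop-substituted reads still match as a different variant, so the
        # observed rate slightly exceeds the all-correct probability
        assert observed == pytest.approx(expected, abs=0.05)


class TestSimulateFacs:
    def test_no_cell_noise_single_bin(self):
        cfg = small_config(sigma_cell=0.0, n_cells=100)
        gt = simulate_ground_truth(cfg)
        data = simulate_facs(gt, cfg, "minus")
        cells = facsseq.estimate_cells(data)
        occupied = (cells.to_numpy() > 0).sum(axis=1)
        # each variant's cells land in exactly one bin (reads may be zero)
        counts = np.array([np.count_nonzero(
            np.histogram([t], bins=np.nan_to_num(data.bin_edges,
                                                 neginf=-1e9, posinf=1e9))[0])
            for t in np.log10(100 * gt.table.f0)])
        assert (occupied <= 1).all() or (counts == 1).all()

    def test_control_splits_top_two_bins(self):
        cfg = small_config(sigma_cell=0.2, n_cells=4000)
        gt = simulate_ground_truth(cfg)
        data = simulate_facs(gt, cfg, "minus")
        cells = facsseq.estimate_cells(data)
        ctl = cells.loc["sTRSVctl"].to_numpy()
        top_two = ctl[-2:].sum()
        assert top_two / ctl.sum() > 0.95
        assert ctl[-2] == pytest.approx(ctl[-1], rel=0.2)

    def test_read_depth_per_bin(self):
        cfg = small_config(facs_reads_per_bin=10_000)
        gt = simulate_ground_truth(cfg)
        data = simulate_facs(gt, cfg, "minus")
        occupied = data.cells_sorted > 0
        assert (data.reads.sum(axis=0).to_numpy()[occupied] == 10_000).all()

    def test_end_to_end_rfu_recovery(self, control_fractions):
        cfg = SimConfig(seed=21, n_variants=60, sigma_cell=0.15, n_cells=3000,
                        facs_reads_per_bin=200_000)
        gt = simulate_ground_truth(cfg)
        data = simulate_facs(gt, cfg, "minus")
        fits = facsseq.fit_all(data, min_cells=2000)
        fits = facsseq.calibrate_and_normalize(
            fits, {c.name: c.reference_rfu for c in gt.controls})
        truth = 100.0 * gt.table.f0
        checked = 0
        for v in fits.index:
            if fits.loc[v, "n_cells_est"] >= 2000 and fits.loc[v, "converged"]:
                assert fits.loc[v, "rfu"] == pytest.approx(truth[v], rel=0.10)
                checked += 1
        assert checked > 30


class TestCrossAssayAgreement:
    def test_rna_and_facs_ar_monotone(self):
        cfg = SimConfig(seed=5, n_variants=100, depth_dna=10**6, depth_rna=10**6,
                        p_switch=0.8, switch_beta=(2.0, 1.0), sigma_cell=0.15,
                        n_cells=3000, facs_reads_per_bin=300_000)
        gt = simulate_ground_truth(cfg)
        rng = cfg.rng()
        table = simulate_counts(gt, cfg, rng)
        rd = rnaseq_quant.rd_normalize(table)
        rna_ar = rnaseq_quant.activation_ratio(
            rd["minus"].mean(axis=1), rd["plus"].mean(axis=1))
        rfu = {}
        levels = {c.name: c.reference_rfu for c in gt.controls}
        for condition in ("minus", "plus"):
            data = simulate_facs(gt, cfg, condition, rng)
            fits = facsseq.calibrate_and_normalize(
                facsseq.fit_all(data, min_cells=1000), levels)
            rfu[condition] = fits["rfu"]
        facs_ar = facsseq.facs_activation_ratio(rfu["minus"], rfu["plus"])
        joined = pd.concat([rna_ar.rename("rna"), facs_ar.rename("facs")],
                           axis=1).dropna()
        assert len(joined) > 80
        rho = stats.spearmanr(joined.rna, joined.facs).statistic
        assert rho > 0.9
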