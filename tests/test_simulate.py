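"""Synthetic-data generators: plates, reads, gels, and their ground truth."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonegrid.plates import PlateLayout
from clonegrid.simulate import (
    CloneSimParams,
    ReadSimConfig,
    generate_plate_timelapse,
    simulate_amplicon_reads,
    simulate_gel_table,
)

SMALL = PlateLayout(grid_rows=4, grid_cols=4)


class TestPlateTimelapse:
    def test_empty_plate_at_zero_seeding(self):
        params = CloneSimParams(seeding_density_lambda=0.0, noise_sd=0.0, rng_seed=1)
        images, truth = generate_plate_timelapse(SMALL, params, 2)
        assert (truth["true_count"] == 0).all()
        for img in images.values():
            assert img.max() <= params.background_level + 1

    def test_deterministic_doubling_without_stochasticity(self):
        params = CloneSimParams(
            growth_rate_per_day=math.log(2), death_prob_per_day=0.0, rng_seed=0
        )
        layout = PlateLayout(grid_rows=1, grid_cols=1)
        _, truth = generate_plate_timelapse(
            layout, params, 4, seed_counts={(1, 0, 0): 1}
        )
        assert truth.sort_values("day")["true_count"].tolist() == [1, 2, 4, 8]

    def test_poisson_seeding_mean_within_three_se(self):
        lam = 1.0
        params = CloneSimParams(seeding_density_lambda=lam, rng_seed=5)
        layout = PlateLayout()  # 400 features
        _, truth = generate_plate_timelapse(layout, params, 1)
        seeded = truth.query("day == 0")["true_count"]
        assert len(seeded) == 400
        se = math.sqrt(lam / len(seeded))
        assert abs(seeded.mean() - lam) <= 3 * se

    def test_counts_nondecreasing_without_death(self):
        params = CloneSimParams(
            seeding_density_lambda=2.0, growth_rate_per_day=0.4,
            death_prob_per_day=0.0, rng_seed=3,
        )
        _, truth = generate_plate_timelapse(SMALL, params, 4)
        for _, grp in truth.groupby(["well", "grid_row", "grid_col"]):
            counts = grp.sort_values("day")["true_count"].tolist()
            assert counts == sorted(counts)

    def test_bit_reproducible_for_fixed_seed(self):
        params = CloneSimParams(seeding_density_lambda=1.0, rng_seed=11)
        a_imgs, a_truth = generate_plate_timelapse(SMALL, params, 2)
        b_imgs, b_truth = generate_plate_timelapse(SMALL, params, 2)
        pd.testing.assert_frame_equal(a_truth, b_truth)
        for k in a_imgs:
            assert np.array_equal(a_imgs[k], b_imgs[k])

    def test_images_are_16bit_with_one_per_feature_day(self):
        params = CloneSimParams(rng_seed=2)
        images, truth = generate_plate_timelapse(SMALL, params, 3)
        assert len(images) == 16 * 3 == len(truth)
        assert all(img.dtype == np.uint16 for img in images.values())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CloneSimParams(seeding_density_lambda=-1)
        with pytest.raises(ValueError):
            CloneSimParams(death_prob_per_day=1.5)
        with pytest.raises(ValueError):
            generate_plate_timelapse(SMALL, CloneSimParams(), 0)


class TestAmpliconReads:
    def test_unedited_error_free_reads_equal_reference(self, amplicon):
        cfg = ReadSimConfig(n_reads=20, edit_fraction=0.0, seq_error_rate=0.0,
                            rng_seed=1)
        recs, truth = simulate_amplicon_reads(amplicon, cfg)
        assert len(recs) == 20
        assert all(str(r.seq) == amplicon.sequence for r in recs)
        assert (truth["label"] == "WT").all()

    def test_deletion_length_bookkeeping(self, amplicon):
        cfg = ReadSimConfig(
            n_reads=1, edit_fraction=1.0, p_deletion_given_indel=1.0,
            indel_length_dist={3: 1.0}, positional_jitter_sd=0.0,
            seq_error_rate=0.0, rng_seed=0,
        )
        recs, truth = simulate_amplicon_reads(amplicon, cfg)
        assert len(str(recs[0].seq)) == len(amplicon.sequence) - 3
        assert truth.loc[0, "label"] == "deletion"
        assert truth.loc[0, "length"] == 3

    def test_edited_fraction_within_binomial_99ci(self, amplicon):
        n, p = 10_000, 0.5
        cfg = ReadSimConfig(n_reads=n, edit_fraction=p, rng_seed=42)
        _, truth = simulate_amplicon_reads(amplicon, cfg)
        k = int((truth["label"] != "WT").sum())
        lo, hi = stats.binom.interval(0.99, n, p)
        assert lo <= k <= hi

    def test_ground_truth_labels_complete(self, amplicon):
        cfg = ReadSimConfig(n_reads=50, edit_fraction=0.7, rng_seed=9)
        recs, truth = simulate_amplicon_reads(amplicon, cfg)
        assert len(truth) == len(recs)
        assert set(truth["label"]) <= {"WT", "deletion", "insertion"}
        assert truth["read_id"].is_unique

    def test_reproducible_for_fixed_seed(self, amplicon):
        cfg = ReadSimConfig(n_reads=30, edit_fraction=0.5, seq_error_rate=0.01,
                            rng_seed=4)
        a, _ = simulate_amplicon_reads(amplicon, cfg)
        b, _ = simulate_amplicon_reads(amplicon, cfg)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]

    def test_cut_site_outside_window_rejected(self, amplicon):
        cfg = ReadSimConfig(n_reads=1, read_length=50, rng_seed=0)
        with pytest.raises(ValueError):
            simulate_amplicon_reads(amplicon, cfg)  # cut at 115 > 50


class TestGelTable:
    def test_all_wt_single_band(self, paired_designs):
        bands, truth = simulate_gel_table(
            20, {"WT": 1.0}, paired_designs, rng_seed=0
        )
        assert (truth["genotype"] == "WT").all()
        assert (bands["bands_bp"] == "1000").all()

    def test_homozygous_biallelic_single_band(self, paired_designs):
        d = paired_designs[0]  # 300-bp deletion, wt 1000
        bands, truth = simulate_gel_table(
            1, {"biallelic": 1.0}, [d], rng_seed=0
        )
        assert truth.loc[0, "genotype"] == "biallelic"
        assert bands.loc[0, "bands_bp"] == "700"

    def test_genotype_counts_sum_and_multinomial_99ci(self, paired_designs):
        n = 1000
        fracs = {"WT": 0.18, "monoallelic": 0.46, "biallelic": 0.36}
        _, truth = simulate_gel_table(n, fracs, paired_designs, rng_seed=17)
        counts = truth["genotype"].value_counts()
        assert counts.sum() == n
        for g, p in fracs.items():
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= counts[g] <= hi, g

    def test_band_sizes_consistent_with_genotype(self, paired_designs):
        wt = paired_designs[0].wt_amplicon_bp
        del_sizes = {d.edited_amplicon_bp for d in paired_designs}
        bands, truth = simulate_gel_table(
            200, {"WT": 0.2, "monoallelic": 0.4, "biallelic": 0.4},
            paired_designs, rng_seed=8,
        )
        merged = bands.merge(truth, on="clone_id")
        for _, row in merged.iterrows():
            sizes = {int(b) for b in row["bands_bp"].split(";")}
            if row["genotype"] == "WT":
                assert sizes == {wt}
            elif row["genotype"] == "monoallelic":
                assert wt in sizes and len(sizes - {wt}) == 1
                assert sizes - {wt} <= del_sizes
            else:
                assert wt not in sizes and 1 <= len(sizes) <= 2
                assert sizes <= del_sizes

    def test_bad_fractions_rejected(self, paired_designs):
        with pytest.raises(ValueError):
            simulate_gel_table(5, {"WT": 0.5}, paired_designs)
        with pytest.raises(ValueError):
            simulate_gel_table(5, {"biallelic": 1.0}, [])
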