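"""Read alignment, indel calling, edit summaries, profiles, gel genotypes."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonegrid.indels import (
    AmpliconReference,
    IndelCall,
    align_read,
    call_indels,
    expected_inframe_fraction,
    genotype_from_gel,
    per_base_profile,
    summarize,
    uniform_length_distribution,
)
from clonegrid.simulate import ReadSimConfig, simulate_amplicon_reads
from oracles import brute_force_semiglobal_score

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestAlignRead:
    def test_perfect_match(self, amplicon):
        aln = align_read(amplicon.sequence, amplicon)
        assert aln.events == ()
        assert aln.score == 2 * len(amplicon.sequence)
        assert (aln.ref_start, aln.ref_end) == (0, len(amplicon.sequence))

    def test_single_internal_deletion_recovered(self, amplicon):
        seq = amplicon.sequence
        read = seq[:100] + seq[103:]
        aln = align_read(read, amplicon)
        dels = [e for e in aln.events if e.kind == "del"]
        assert len(dels) == 1
        assert dels[0].length == 3

    def test_gap_removal_recovers_inputs(self, amplicon):
        seq = amplicon.sequence
        read = seq[:80] + "ACGTT" + seq[80:]
        aln = align_read(read, amplicon)
        assert aln.aligned_read.replace("-", "") == read
        assert aln.aligned_ref.replace("-", "") == seq

    def test_reference_overhang_end_gaps_free(self):
        aln = align_read("ACGT", "TTTTACGTTTTT")
        assert aln.score == 8.0
        assert aln.events == ()
        assert (aln.ref_start, aln.ref_end) == (4, 8)

    def test_indels_left_aligned_in_repeats(self):
        # deleting any one A of the run is equivalent; canonical form is leftmost
        ref = "GGGC" + "AAAA" + "CTTT"
        read = "GGGC" + "AAA" + "CTTT"
        aln = align_read(read, ref)
        dels = [e for e in aln.events if e.kind == "del"]
        assert dels[0].ref_pos == 4

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            align_read("", "ACGT")
        with pytest.raises(ValueError):
            align_read("ACGT", "")

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(dna, dna)
    def test_score_matches_exhaustive_oracle(self, read, ref):
        aln = align_read(read, ref)
        assert aln.score == pytest.approx(brute_force_semiglobal_score(read, ref))


class TestCallIndels:
    def test_perfect_read_is_wt(self, amplicon):
        aln = align_read(amplicon.sequence, amplicon)
        call = call_indels(aln, amplicon)
        assert call.classification == "WT"
        assert call.frame == "NA"

    def test_three_nt_deletion_in_frame(self, amplicon):
        cut = amplicon.cut_sites[0]
        seq = amplicon.sequence
        read = seq[: cut - 1] + seq[cut + 2 :]
        call = call_indels(align_read(read, amplicon), amplicon)
        assert (call.classification, call.frame, call.net_length) == (
            "indel", "in_frame", -3,
        )

    def test_76_nt_deletion_is_frameshift(self, amplicon):
        cut = amplicon.cut_sites[0]
        seq = amplicon.sequence
        read = seq[: cut - 38] + seq[cut + 38 :]
        call = call_indels(align_read(read, amplicon), amplicon)
        assert call.classification == "indel"
        assert call.net_length == -76
        assert call.frame == "frameshift"  # 76 % 3 != 0

    def test_substitutions_never_classify_as_indel(self, amplicon):
        cut = amplicon.cut_sites[0]
        seq = amplicon.sequence
        base = "A" if seq[cut] != "A" else "C"
        read = seq[:cut] + base + seq[cut + 1 :]
        call = call_indels(align_read(read, amplicon), amplicon)
        assert call.classification == "WT"

    def test_indel_outside_window_not_counted(self, amplicon):
        seq = amplicon.sequence
        read = seq[:30] + seq[33:]  # deletion far from the cut (115)
        call = call_indels(align_read(read, amplicon), amplicon, window_nt=100)
        assert call.classification == "WT"

    def test_window_outside_reference_rejected(self, amplicon):
        aln = align_read(amplicon.sequence, amplicon)
        with pytest.raises(ValueError):
            call_indels(aln, amplicon, window_nt=10_000)


class TestSummarize:
    def test_all_wt(self):
        calls = [IndelCall(f"r{i}", "WT", "NA", 0) for i in range(5)]
        s = summarize(calls)
        assert s.frac_indel == 0.0
        assert s.frac_wt == 1.0

    def test_partition_and_inframe_bound(self, amplicon):
        cfg = ReadSimConfig(n_reads=400, edit_fraction=0.6, rng_seed=2)
        recs, _ = simulate_amplicon_reads(amplicon, cfg)
        calls = [
            call_indels(align_read(str(r.seq), amplicon, read_id=r.id), amplicon)
            for r in recs
        ]
        s = summarize(calls)
        assert s.frac_wt + s.frac_indel == pytest.approx(1.0)
        assert s.frac_inframe <= s.frac_indel

    def test_recovers_simulated_edit_fraction_within_99ci(self, amplicon):
        n, p = 2000, 0.5
        cfg = ReadSimConfig(n_reads=n, edit_fraction=p, rng_seed=31)
        recs, _ = simulate_amplicon_reads(amplicon, cfg)
        calls = [
            call_indels(align_read(str(r.seq), amplicon), amplicon) for r in recs
        ]
        s = summarize(calls)
        lo, hi = stats.binom.interval(0.99, n, p)
        assert lo <= s.frac_indel * n <= hi

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestPerBaseProfile:
    def test_wt_reads_all_ones_outside_mask(self, amplicon):
        alns = [align_read(amplicon.sequence, amplicon) for _ in range(3)]
        prof = per_base_profile(alns, amplicon)
        inner = prof[~prof["masked"]]
        assert (inner["match_freq"] == 1.0).all()
        assert prof["masked"].sum() == sum(amplicon.primer_lengths)

    def test_shared_deletion_zeroes_exact_positions(self, amplicon):
        p = 100
        read = amplicon.sequence[:p] + amplicon.sequence[p + 3 :]
        alns = [align_read(read, amplicon) for _ in range(4)]
        prof = per_base_profile(alns, amplicon).set_index("position")
        assert (prof.loc[p : p + 2, "match_freq"] == 0.0).all()
        others = prof.drop(index=range(p, p + 3))
        assert (others["match_freq"] == 1.0).all()

    def test_empty_rejected(self, amplicon):
        with pytest.raises(ValueError):
            per_base_profile([], amplicon)


class TestGelGenotype:
    def test_wt_band_only(self, paired_designs):
        g = genotype_from_gel([1000], paired_designs, tol_bp=20)
        assert g.call == "WT"

    def test_wt_plus_deletion_monoallelic(self, paired_designs):
        g = genotype_from_gel([1000, 700], paired_designs, tol_bp=20)
        assert g.call == "monoallelic"

    def test_two_deletions_no_wt_biallelic(self, paired_designs):
        g = genotype_from_gel([700, 460], paired_designs, tol_bp=20)
        assert g.call == "biallelic"

    def test_empty_band_list_no_call(self, paired_designs, caplog):
        with caplog.at_level("WARNING"):
            g = genotype_from_gel([], paired_designs)
        assert g.call == "no_call"

    def test_exhaustive_truth_table_three_guide_design(self, paired_designs):
        # band sizes of the 3-sgRNA design: wt plus three deletion products
        wt = paired_designs[0].wt_amplicon_bp
        del_sizes = sorted({d.edited_amplicon_bp for d in paired_designs})
        assert len(del_sizes) == 3
        universe = [wt] + del_sizes
        for mask in itertools.product([0, 1], repeat=4):
            bands = [s for s, m in zip(universe, mask) if m]
            got = genotype_from_gel(bands, paired_designs, tol_bp=5).call
            has_wt, has_del = bool(mask[0]), any(mask[1:])
            if not bands:
                expected = "no_call"
            elif has_wt and not has_del:
                expected = "WT"
            elif has_wt and has_del:
                expected = "monoallelic"
            else:
                expected = "biallelic"
            assert got == expected, bands

    def test_tolerance_defaults_to_ten_percent(self, paired_designs):
        # 1080 bp is within 10% of the 1000-bp WT amplicon
        assert genotype_from_gel([1080], paired_designs).call == "WT"
        assert genotype_from_gel([1150], paired_designs).call == "no_call"


class TestExpectedInframeFraction:
    def test_uniform_1_to_30_is_one_third(self):
        assert expected_inframe_fraction(uniform_length_distribution(1, 30)) == (
            pytest.approx(10 / 30)
        )

    def test_point_mass_on_three(self):
        assert expected_inframe_fraction({3: 1.0}) == 1.0

    def test_uniform_1_to_31_enumeration(self):
        assert expected_inframe_fraction(uniform_length_distribution(1, 31)) == (
            pytest.approx(10 / 31)
        )

    def test_empty_or_invalid_support_rejected(self):
        with pytest.raises(ValueError):
            expected_inframe_fraction({})
        with pytest.raises(ValueError):
            expected_inframe_fraction({0: 1.0})
        with pytest.raises(ValueError):
            expected_inframe_fraction({3: 0.5})


class TestEndToEndRecovery:
    """Summaries on simulated reads recover the generator's mixture."""

    def test_mixture_recovery_within_99ci(self, amplicon):
        n = 2000
        cfg = ReadSimConfig(
            n_reads=n, edit_fraction=0.5, p_deletion_given_indel=0.85, rng_seed=5
        )
        recs, truth = simulate_amplicon_reads(amplicon, cfg)
        calls = [
            call_indels(align_read(str(r.seq), amplicon), amplicon) for r in recs
        ]
        s = summarize(calls)
        n_indel = s.n_deletion_reads + s.n_insertion_reads
        lo, hi = stats.binom.interval(0.99, n_indel, 0.85)
        assert lo <= s.n_deletion_reads <= hi
        # in-frame fraction among indels ~ uniform-1..30 expectation
        inframe_frac = s.frac_inframe / s.frac_indel
        lo_f, hi_f = stats.binom.interval(0.999, n_indel, 1 / 3)
        assert lo_f / n_indel <= inframe_frac <= hi_f / n_indel
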