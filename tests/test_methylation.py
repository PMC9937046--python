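"""Bisulfite clone calling, CpG percentages, allele partitioning, DMR calls."""

import numpy as np
import pandas as pd
import pytest

from imprintase import methylation as meth
from imprintase.methylation import (
    BisulfiteClone,
    RegionMethylation,
    call_clone_from_sequence,
    classify_dmr,
    clones_from_matrix,
    cpg_percentages,
    partition_by_allele,
)
from imprintase.simulate import (
    bisulfite_reference,
    render_clone_sequences,
    simulate_bisulfite_clones,
)


class TestSequenceCalling:
    def test_hand_converted_seven_mer(self):
        # reference ACGTCGA has CpGs at offsets 1 and 4; the clone retains
        # the first C (methylated) and converts the second (unmethylated)
        clone = call_clone_from_sequence("ACGTCGA", "ACGTTGA")
        assert clone.calls == ["M", "U"]
        assert clone.non_cpg_conversion_rate is None  # no non-CpG cytosine
        assert not clone.excluded

    def test_unconverted_clone_is_excluded(self):
        ref = bisulfite_reference(4)  # TCACGA x 4: one non-CpG C per unit
        clone = call_clone_from_sequence(ref, ref)  # all Cs retained
        assert clone.non_cpg_conversion_rate == 0.0
        assert clone.excluded

    def test_fully_converted_clone_all_u_rate_one(self):
        ref = bisulfite_reference(3)
        converted = ref.replace("C", "T")
        clone = call_clone_from_sequence(ref, converted)
        assert clone.calls == ["U", "U", "U"]
        assert clone.non_cpg_conversion_rate == 1.0
        assert not clone.excluded

    def test_ambiguous_base_gives_missing_call(self):
        clone = call_clone_from_sequence("ACGTCGA", "AAGTTGA")
        assert clone.calls == [".", "U"]

    def test_length_mismatch_is_parse_error(self):
        with pytest.raises(ValueError, match="length"):
            call_clone_from_sequence("ACGT", "ACG")


class TestPercentages:
    def test_hand_counted_matrix(self):
        # 3 clones x 4 CpGs: MMMU / UUUU / MUMU
        matrix = pd.DataFrame({
            "clone_id": ["c1", "c2", "c3"],
            "cpg_1": ["M", "U", "M"], "cpg_2": ["M", "U", "U"],
            "cpg_3": ["M", "U", "M"], "cpg_4": ["U", "U", "U"],
        })
        sites, region = cpg_percentages(clones_from_matrix(matrix))
        assert sites["percent_methylated"].tolist() == pytest.approx(
            [200 / 3, 100 / 3, 200 / 3, 0.0])
        assert region.mean_percent == pytest.approx(0.41666, abs=1e-4)
        assert region.n_clones == 3 and region.n_cpgs == 4

    def test_missing_calls_leave_denominator(self):
        matrix = pd.DataFrame({"clone_id": ["c1", "c2", "c3", "c4"],
                               "cpg_1": ["M", ".", ".", "U"]})
        sites, _ = cpg_percentages(clones_from_matrix(matrix))
        assert sites["n_calls"].iloc[0] == 2
        assert sites["percent_methylated"].iloc[0] == pytest.approx(50.0)

    def test_excluded_clones_do_not_contribute(self):
        clones = [BisulfiteClone("ok", ["M", "U"]),
                  BisulfiteClone("bad", ["M", "M"], excluded=True)]
        sites, region = cpg_percentages(clones)
        assert region.n_clones == 1
        assert sites["percent_methylated"].tolist() == [100.0, 0.0]

    def test_no_passing_clones_gives_empty(self):
        sites, region = cpg_percentages([BisulfiteClone("bad", ["M"], excluded=True)])
        assert region is None and len(sites) == 0

    def test_half_half_mixture_is_exactly_half(self):
        clones = [BisulfiteClone(f"m{i}", ["M"] * 6, "maternal") for i in range(10)]
        clones += [BisulfiteClone(f"u{i}", ["U"] * 6, "paternal") for i in range(10)]
        _, region = cpg_percentages(clones)
        assert region.mean_percent == 0.5


class TestAllelePartition:
    def test_pure_alleles(self):
        clones = [BisulfiteClone("m", ["M", "M"], "maternal"),
                  BisulfiteClone("p", ["U", "U"], "paternal"),
                  BisulfiteClone("x", ["M", "U"], "unknown")]
        means = partition_by_allele(clones)
        assert means["maternal"] == 1.0 and means["paternal"] == 0.0
        assert not means["one_sided"]

    def test_one_allele_absent_is_one_sided(self):
        means = partition_by_allele([BisulfiteClone("m", ["M"], "maternal")])
        assert means["one_sided"] and means["paternal"] is None

    def test_no_tags_leaves_partition_unknown_but_region_mean_reported(self):
        clones = [BisulfiteClone("a", ["M", "U"]), BisulfiteClone("b", ["U", "U"])]
        means = partition_by_allele(clones)
        assert means["maternal"] is None and means["paternal"] is None
        _, region = cpg_percentages(clones)
        assert region.mean_percent == pytest.approx(0.25)

    def test_recovery_from_simulated_clones(self):
        clones_df, _ = simulate_bisulfite_clones(200, 12, 0.96, 0.18,
                                                 with_allele_snp=True, seed=13)
        means = partition_by_allele(clones_from_matrix(clones_df))
        assert means["maternal"] == pytest.approx(0.96, abs=0.03)
        assert means["paternal"] == pytest.approx(0.18, abs=0.05)


class TestDmrClassification:
    def _region(self, mean, alleles=None):
        return RegionMethylation("r", mean, 20, 12, per_allele_means=alleles)

    def test_differential_alleles_at_half_methylation_is_dmr(self):
        call = classify_dmr(self._region(0.50, (0.96, 0.18)))
        assert call.classification == "DMR" and call.methylated_parent == "maternal"

    def test_unmethylated_promoter(self):
        assert classify_dmr(self._region(0.02)).classification == "unmethylated"

    def test_methylated_promoter(self):
        assert classify_dmr(self._region(0.92)).classification == "methylated"

    def test_balanced_alleles_unresolved(self):
        call = classify_dmr(self._region(0.50, (0.50, 0.50)))
        assert call.classification == "intermediate_unresolved"

    def test_no_allele_data_unresolved(self):
        assert classify_dmr(self._region(0.50)).classification == "intermediate_unresolved"

    def test_monotone_in_allele_difference(self):
        """Growing |maternal - paternal| never turns a DMR back into a
        non-DMR at fixed region mean."""
        was_dmr = False
        for diff in np.linspace(0, 1, 21):
            call = classify_dmr(self._region(0.5, (0.5 + diff / 2, 0.5 - diff / 2)))
            if was_dmr:
                assert call.classification == "DMR"
            was_dmr = call.classification == "DMR"
        assert was_dmr


def test_sequence_path_equals_matrix_path():
    """Calling clones from rendered bisulfite sequences reproduces the truth
    matrix exactly when conversion is complete."""
    clones_df, _ = simulate_bisulfite_clones(50, 8, 0.7, 0.2,
                                             conversion_failure_rate=0.0,
                                             with_allele_snp=True, seed=21)
    ref = bisulfite_reference(8)
    seqs = render_clone_sequences(ref, clones_df, conversion_failure_rate=0.0)
    from_seq = [call_clone_from_sequence(ref, s, clone_id=cid, allele_tag=tag)
                for s, cid, tag in zip(seqs, clones_df["clone_id"],
                                       clones_df["allele_tag"])]
    from_matrix = clones_from_matrix(clones_df)
    for a, b in zip(from_seq, from_matrix):
        assert a.calls == b.calls
        assert not a.excluded
    sites_a, region_a = cpg_percentages(from_seq)
    sites_b, region_b = cpg_percentages(from_matrix)
    pd.testing.assert_frame_equal(sites_a, sites_b)
    assert region_a.mean_percent == region_b.mean_percent
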