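"""SNP discovery, stock genotyping, informativeness, and masking."""

import numpy as np
import pandas as pd
import pytest

from imprintase import io, snps


def test_discover_pooled_depth_boundary():
    counts = pd.DataFrame({
        "chrom": ["chr1", "chr1"], "pos": [10, 20], "ref": ["A", "C"], "alt": ["G", "T"],
        "s1:REF": [20, 20], "s1:ALT": [10, 10], "s2:REF": [10, 9], "s2:ALT": [0, 0],
    })
    kept = snps.discover_candidate_snps(counts, min_pooled_depth=40)
    assert kept["pos"].tolist() == [10]  # depth 40 retained, 39 dropped
    empty = snps.discover_candidate_snps(counts.iloc[:0], min_pooled_depth=40)
    assert len(empty) == 0


@pytest.mark.parametrize("ll1_counts, expected", [
    ((20, 0), "ref_hom"),
    ((10, 9), "het"),
    ((3, 2), "unknown"),      # depth 5 < 8
    ((19, 1), "ref_hom"),     # minor fraction 0.05 within error tolerance
    ((9, 1), "unknown"),      # minor fraction 0.10: between hom and het rules
])
def test_genotype_stock_rules(ll1_counts, expected):
    counts = pd.DataFrame({
        "chrom": ["chr1"], "pos": [10], "ref": ["A"], "alt": ["G"],
        "p1:REF": [ll1_counts[0]], "p1:ALT": [ll1_counts[1]],
        "p2:REF": [0], "p2:ALT": [18],
    })
    meta = pd.DataFrame([
        dict(sample_id="p1", role="parental", stock="LL1", tissue="fetal_brain"),
        dict(sample_id="p2", role="parental", stock="LL2", tissue="fetal_brain"),
    ])
    gt = snps.genotype_stocks(counts, meta)
    assert gt["ll1_genotype"].iloc[0] == expected
    assert gt["ll2_genotype"].iloc[0] == "alt_hom"


def test_genotype_requires_parental_samples():
    counts = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "ref": ["A"], "alt": ["G"],
                           "p1:REF": [9], "p1:ALT": [0]})
    meta = pd.DataFrame([dict(sample_id="p1", role="parental", stock="LL1",
                              tissue="fetal_brain")])
    with pytest.raises(ValueError, match="LL2"):
        snps.genotype_stocks(counts, meta)


class TestInformativeness:
    def _gt(self, counts, meta, **kw):
        return snps.assess_informativeness(
            snps.genotype_stocks(counts, meta), counts, meta, **kw)

    def test_opposite_homozygotes_informative_with_origin_map(self, tiny_counts):
        counts, meta = tiny_counts
        informative = self._gt(counts, meta)
        assert len(informative) == 3
        # LL1 is ref-fixed, so in the LL1(dam) x LL2 cross ref is maternal
        assert (informative["ll1_allele"] == "ref").all()
        assert (informative["maternal_allele_LL1xLL2"] == "ref").all()
        assert (informative["maternal_allele_LL2xLL1"] == "alt").all()

    def test_origin_map_symmetry(self, tiny_counts):
        """Swapping direction labels swaps maternal/paternal exactly."""
        counts, meta = tiny_counts
        informative = self._gt(counts, meta)
        a = informative["maternal_allele_LL1xLL2"]
        b = informative["maternal_allele_LL2xLL1"]
        assert (a != b).all()

    def test_shared_heterozygous_uninformative(self, tiny_counts):
        counts, meta = tiny_counts
        counts = counts.copy()
        counts.loc[0, ["LL1_1:REF", "LL1_1:ALT", "LL2_1:REF", "LL2_1:ALT"]] = [10, 10, 9, 9]
        informative = self._gt(counts, meta)
        assert 101 not in informative["pos"].tolist()

    def test_requires_three_of_four_f1_covered(self, tiny_counts):
        counts, meta = tiny_counts
        counts = counts.copy()
        f1 = meta.loc[meta["role"] == "f1", "sample_id"].tolist()
        for sid in f1[:2]:  # leave only 2 F1 libraries covered at SNP 101
            counts.loc[0, [f"{sid}:REF", f"{sid}:ALT"]] = [3, 2]
        informative = self._gt(counts, meta)
        assert 101 not in informative["pos"].tolist()
        assert informative["f1_samples_covered"].min() >= 3

    def test_monotone_in_depth_and_coverage(self, tiny_counts):
        counts, meta = tiny_counts
        base = self._gt(counts, meta)
        stricter_depth = self._gt(counts, meta, min_depth=12)
        stricter_cover = self._gt(counts, meta, min_f1_covered=4)
        assert set(map(tuple, stricter_depth[["chrom", "pos"]].to_numpy())) <= \
            set(map(tuple, base[["chrom", "pos"]].to_numpy()))
        assert set(map(tuple, stricter_cover[["chrom", "pos"]].to_numpy())) <= \
            set(map(tuple, base[["chrom", "pos"]].to_numpy()))

    def test_genotype_override_removes_informative_status(self, tiny_counts):
        counts, meta = tiny_counts
        gt = snps.genotype_stocks(counts, meta)
        override = pd.DataFrame([dict(chrom="chr1", pos=101,
                                      ll1_genotype="het", ll2_genotype="het")])
        informative = snps.assess_informativeness(
            snps.apply_genotype_override(gt, override), counts, meta)
        assert 101 not in informative["pos"].tolist()
        assert {205, 387} <= set(informative["pos"])


class TestMasks:
    def _snps(self, positions):
        return pd.DataFrame({"chrom": "chr1", "pos": positions})

    def test_repeat_interval_coordinate_convention(self):
        # 0-based half-open [99, 100) covers exactly 1-based position 100
        masks = snps.MaskSet(repeat_intervals={"chr1": np.array([[99, 100]])})
        kept, log = snps.apply_masks(self._snps([99, 100, 101]), masks)
        assert kept["pos"].tolist() == [99, 101]
        assert log["removed_repeat"] == 1

    def test_boundary_distance(self):
        masks = snps.MaskSet(exon_boundaries={"chr1": np.array([500])},
                             boundary_distance=5)
        kept, log = snps.apply_masks(self._snps([494, 496, 500, 505, 506]), masks)
        assert kept["pos"].tolist() == [494, 506]  # 6 bp away kept, <=5 removed
        assert log["removed_boundary"] == 3

    def test_empty_maskset_is_identity(self):
        table = self._snps([1, 2, 3])
        kept, log = snps.apply_masks(table, snps.MaskSet())
        assert kept["pos"].tolist() == [1, 2, 3]
        assert log == {"removed_repeat": 0, "removed_boundary": 0}

    def test_boundaries_from_exons_are_internal_edges_only(self):
        exons = pd.DataFrame([
            dict(gene_id="g", chrom="chr1", start=100, end=200),
            dict(gene_id="g", chrom="chr1", start=300, end=400),
        ])
        masks = snps.MaskSet.from_inputs(exons=exons, boundary_distance=0)
        assert masks.exon_boundaries["chr1"].tolist() == [200, 300]

    def test_unsorted_bed_sorted_with_warning(self, tmp_path):
        bed = tmp_path / "repeats.bed"
        bed.write_text("chr1\t50\t60\nchr1\t10\t20\n")
        with pytest.warns(UserWarning, match="unsorted"):
            intervals = io.read_bed_intervals(bed)
        assert intervals["chr1"].tolist() == [[10, 20], [50, 60]]


def _brute_force_informative(counts, meta, min_depth=8, min_f1_covered=3):
    """Independent per-SNP oracle: enumerate the 9 stock genotype pairs."""
    parental = meta[meta["role"] == "parental"]
    f1 = meta[meta["role"] == "f1"]
    informative_positions = []
    for _, row in counts.iterrows():
        calls = {}
        pooled = {}
        for stock in ("LL1", "LL2"):
            ref = alt = 0
            for sid in parental.loc[parental["stock"] == stock, "sample_id"]:
                ref += row[f"{sid}:REF"]
                alt += row[f"{sid}:ALT"]
            pooled[stock] = (ref, alt)
            depth = ref + alt
            if depth < min_depth:
                calls[stock] = "unknown"
            else:
                minor = min(ref, alt) / depth
                if minor <= 0.05:
                    calls[stock] = "ref_hom" if ref >= alt else "alt_hom"
                elif minor >= 0.20:
                    calls[stock] = "het"
                else:
                    calls[stock] = "unknown"
        verdict = False
        for g1 in ("ref_hom", "alt_hom", "het"):
            for g2 in ("ref_hom", "alt_hom", "het"):
                if (calls["LL1"], calls["LL2"]) != (g1, g2):
                    continue
                if {g1, g2} != {"ref_hom", "alt_hom"}:
                    continue
                ll1_own = pooled["LL1"][0] if g1 == "ref_hom" else pooled["LL1"][1]
                ll2_own = pooled["LL2"][0] if g2 == "ref_hom" else pooled["LL2"][1]
                if ll1_own < min_depth or ll2_own < min_depth:
                    continue
                covered = sum(
                    1 for sid in f1["sample_id"]
                    if row[f"{sid}:REF"] + row[f"{sid}:ALT"] >= min_depth)
                if covered >= min_f1_covered:
                    verdict = True
        if verdict:
            informative_positions.append((row["chrom"], row["pos"]))
    return set(informative_positions)


def _random_structured_counts(rng, n=200):
    """Random SNP table whose stocks mix homozygous / heterozygous /
    low-depth patterns, so informativeness outcomes of both kinds occur."""
    meta = pd.DataFrame(
        [dict(sample_id=f"P_{s}_{i}", role="parental", stock=s, dam_stock=s,
              sire_stock=s, tissue="fetal_brain") for s in ("LL1", "LL2") for i in (1, 2)]
        + [dict(sample_id=f"F1_{d}x{s}_{i}", role="f1", stock="", dam_stock=d,
                sire_stock=s, tissue="fetal_brain")
           for d, s in (("LL1", "LL2"), ("LL2", "LL1")) for i in (1, 2)])
    counts = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n + 1),
                           "ref": "A", "alt": "G"})
    patterns = ("hom_ref", "hom_alt", "het", "low")
    for stock in ("LL1", "LL2"):
        pattern = rng.choice(patterns, size=n, p=[0.35, 0.35, 0.2, 0.1])
        for i in (1, 2):
            major = rng.integers(3, 15, n)
            stray = rng.integers(0, 2, n)  # exercises the 5% hom tolerance
            het_a, het_b = rng.integers(3, 12, n), rng.integers(3, 12, n)
            low_a, low_b = rng.integers(0, 3, n), rng.integers(0, 3, n)
            ref = np.select([pattern == "hom_ref", pattern == "hom_alt",
                             pattern == "het"], [major, stray, het_a], low_a)
            alt = np.select([pattern == "hom_ref", pattern == "hom_alt",
                             pattern == "het"], [stray, major, het_b], low_b)
            counts[f"P_{stock}_{i}:REF"] = ref
            counts[f"P_{stock}_{i}:ALT"] = alt
    for sid in meta.loc[meta["role"] == "f1", "sample_id"]:
        counts[f"{sid}:REF"] = rng.integers(0, 12, n)
        counts[f"{sid}:ALT"] = rng.integers(0, 12, n)
    return counts, meta


def test_informativeness_matches_brute_force_enumeration():
    """Vectorized filter equals the genotype-pair enumeration oracle on 200
    random SNPs."""
    counts, meta = _random_structured_counts(np.random.default_rng(23))
    n = len(counts)
    genotypes = snps.genotype_stocks(counts, meta)
    informative = snps.assess_informativeness(genotypes, counts, meta)
    got = set(map(tuple, informative[["chrom", "pos"]].to_numpy()))
    expected = _brute_force_informative(counts, meta)
    assert got == expected
    assert len(expected) > 0  # the fixture must exercise both outcomes
    assert len(expected) < n
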