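"""Loading-gap block detection, haplotype anchoring, and classification."""

import numpy as np
import pandas as pd
import pytest

from popstruct import (MISSING, PCAFit, SampleTable, block_haplotypes,
                       block_regional_summary, block_removal_contrast,
                       classify_block_genotypes, linkage_map_join,
                       loading_block_detect)

from conftest import make_gm


def _fit_from_loadings(values):
    v = np.asarray(values, dtype=float)
    load = (v / np.linalg.norm(v)).reshape(-1, 1)
    return PCAFit(center=np.zeros(len(v)), eigenvalues=np.array([1.0]),
                  scores=np.zeros((2, 1)), loadings=load,
                  loci=[f"l{j}" for j in range(len(v))])


class TestLoadingBlockDetect:
    def test_reported_loading_profile_gives_block_of_three(self):
        """Top three loadings nearly equal (0.33245-0.32102), fourth at
        0.19763: the 3->4 relative drop is ~38% > 25%, so the block is the
        top three loci."""
        tail = np.linspace(0.19763, 0.01, 30)
        fit = _fit_from_loadings([0.33245, 0.32861, 0.32102, *tail])
        rep = loading_block_detect(fit, axis=1, tau=0.25)
        assert rep.members == ["l0", "l1", "l2"]
        assert rep.gap == pytest.approx((0.32102 - 0.19763) / 0.32102, rel=1e-6)

    def test_geometric_decay_has_no_block(self):
        fit = _fit_from_loadings(0.5 * 0.9 ** np.arange(40))
        rep = loading_block_detect(fit, axis=1, tau=0.25)
        assert rep.empty

    def test_block_of_two(self):
        fit = _fit_from_loadings([0.5, 0.49, 0.1, 0.09, 0.08, 0.07])
        rep = loading_block_detect(fit, axis=1, tau=0.25)
        assert rep.members == ["l0", "l1"]

    def test_single_outlier_below_min_size_rejected(self):
        fit = _fit_from_loadings([0.9, 0.1, 0.09, 0.08])
        rep = loading_block_detect(fit, axis=1, tau=0.25, min_size=2)
        assert rep.empty

    def test_tau_bounds_checked(self):
        fit = _fit_from_loadings([0.5, 0.4, 0.1])
        with pytest.raises(ValueError, match="tau"):
            loading_block_detect(fit, axis=1, tau=1.5)


def _block_gm(dosage_rows, ref="AAG", alt="GCA"):
    codes = np.asarray(dosage_rows, dtype=np.int8)
    return make_gm(codes, ref=list(ref), alt=list(alt))


class TestBlockHaplotypes:
    def test_recovers_planted_haplotypes(self):
        # hom_A rows are dosage 0 everywhere -> hap A = ref alleles "A,A,G"
        rows = [[0, 0, 0]] * 5 + [[1, 1, 1]] * 4 + [[2, 2, 2]] * 2
        hap_a, hap_b = block_haplotypes(_block_gm(rows), ["l0", "l1", "l2"])
        assert hap_a == ["A", "A", "G"]
        assert hap_b == ["G", "C", "A"]

    def test_all_heterozygous_is_ambiguous(self):
        rows = [[1, 1, 1]] * 6
        with pytest.raises(ValueError, match="all-homozygous"):
            block_haplotypes(_block_gm(rows), ["l0", "l1", "l2"])

    def test_single_homozygous_class_anchors(self):
        rows = [[2, 2, 2]] * 3 + [[1, 1, 1]] * 5
        hap_a, hap_b = block_haplotypes(_block_gm(rows), ["l0", "l1", "l2"])
        assert hap_a == ["G", "C", "A"]     # alt alleles
        assert hap_b == ["A", "A", "G"]


class TestClassify:
    @pytest.mark.parametrize("row,expected", [
        ([0, 0, 0], "hom_A"),
        ([1, 1, 1], "het"),
        ([2, 2, 2], "hom_B"),
        ([0, 1, 0], "other"),
        ([0, MISSING, 0], "excluded"),
    ])
    def test_patterns(self, row, expected):
        gm = _block_gm([[0, 0, 0], row])
        hap_a, hap_b = ["A", "A", "G"], ["G", "C", "A"]
        classes = classify_block_genotypes(gm, ["l0", "l1", "l2"], hap_a, hap_b)
        assert classes.iloc[1] == expected

    def test_swapping_haplotypes_swaps_hom_labels(self):
        rows = [[0, 0, 0], [1, 1, 1], [2, 2, 2], [0, 2, 0]]
        gm = _block_gm(rows)
        members = ["l0", "l1", "l2"]
        a = classify_block_genotypes(gm, members, ["A", "A", "G"], ["G", "C", "A"])
        b = classify_block_genotypes(gm, members, ["G", "C", "A"], ["A", "A", "G"])
        swap = {"hom_A": "hom_B", "hom_B": "hom_A"}
        assert list(b) == [swap.get(c, c) for c in a]


class TestRegionalSummary:
    def _st(self, regions):
        return SampleTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(regions))],
            "locality_id": "L", "latitude": 40.0, "longitude": -80.0,
            "region": regions}))

    def test_single_region_all_hom_a(self):
        classes = pd.Series(["hom_A"] * 4, index=[f"s{i}" for i in range(4)])
        pct, unit = block_regional_summary(classes, self._st(["eastern"] * 4))
        assert pct.loc["eastern", "hom_A"] == pytest.approx(100.0)
        assert unit == pytest.approx(1.0)

    def test_hw_on_haplotypes_class_proportions(self):
        """With hapB frequency q and no recombination the classes follow
        Hardy-Weinberg on haplotypes: ((1-q)^2, 2q(1-q), q^2, 0)."""
        from scipy import stats as sps
        rng = np.random.default_rng(0)
        q = 0.5
        copies = rng.binomial(2, q, size=600)
        names = np.array(["hom_A", "het", "hom_B"])
        classes = pd.Series(names[copies],
                            index=[f"s{i}" for i in range(600)])
        pct, unit = block_regional_summary(classes, self._st(["eastern"] * 600))
        assert unit == pytest.approx(1.0)
        counts = np.array([(classes == c).sum() for c in names])
        p = sps.chisquare(counts, 600 * np.array([0.25, 0.5, 0.25])).pvalue
        assert p > 0.01

    def test_percentages_sum_to_100_and_excluded_dropped(self):
        classes = pd.Series(["hom_A", "het", "excluded", "other"],
                            index=[f"s{i}" for i in range(4)])
        pct, unit = block_regional_summary(classes, self._st(["central"] * 4))
        assert pct.loc["central"].sum() == pytest.approx(100.0)
        assert unit == pytest.approx(2 / 3)


class TestRemovalContrast:
    def _structured_gm(self, seed=0, n=90, m=40):
        """Block loci carry the only structure; background is iid noise."""
        rng = np.random.default_rng(seed)
        codes = rng.choice([0, 1, 2], size=(n, m), p=[0.25, 0.5, 0.25]).astype(np.int8)
        copies = np.repeat([0, 1, 2], n // 3)
        for j in range(3):
            codes[:, j] = copies
        return make_gm(codes), ["l0", "l1", "l2"]

    def test_planted_block_separation_collapses_after_removal(self):
        gm, members = self._structured_gm()
        before, after, ratio = block_removal_contrast(gm, members, axis=1)
        assert before > 0.5
        assert after < 0.1
        assert ratio < 0.2

    def test_empty_member_list_no_contrast(self):
        gm, members = self._structured_gm()
        hap_a, hap_b = block_haplotypes(gm, members)
        classes = classify_block_genotypes(gm, members, hap_a, hap_b)
        before, after, ratio = block_removal_contrast(gm, [], axis=1,
                                                      classes=classes)
        assert before == after
        assert ratio == pytest.approx(1.0)


class TestLinkageMapJoin:
    def _map(self):
        return pd.DataFrame({
            "locus": ["l0", "l1", "l3", "l4"],
            "linkage_group": ["LG4", "LG4", "LG4", "LG7"],
            "cM": [40.68, 40.68, 37.33, 12.0]})

    def test_all_members_one_group(self):
        out = linkage_map_join(["l0", "l1"], self._map())
        assert out.attrs["modal_group"] == "LG4"
        assert out.attrs["modal_fraction"] == 1.0

    def test_unmapped_member_reported(self):
        out = linkage_map_join(["l0", "l9"], self._map())
        assert out.set_index("locus").loc["l9", "linkage_group"] == "unmapped"
        assert out.attrs["modal_fraction"] == 1.0   # among mapped members

    def test_mixed_groups_modal_fraction(self):
        out = linkage_map_join(["l0", "l1", "l4"], self._map())
        assert out.attrs["modal_group"] == "LG4"
        assert out.attrs["modal_fraction"] == pytest.approx(2 / 3)

    def test_duplicate_map_entries_rejected(self):
        bad = pd.concat([self._map(), self._map().iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            linkage_map_join(["l0"], bad)

    def test_extended_scan_stops_after_run_of_foreign_loci(self):
        map_table = pd.DataFrame({
            "locus": [f"l{j}" for j in range(12)],
            "linkage_group": ["LG4", "LG4", "LG4", "LG4", "LG1", "LG4",
                              "LG2", "LG2", "LG3", "LG1", "LG4", "LG4"],
            "cM": np.arange(12, dtype=float)})
        ranked = [f"l{j}" for j in range(12)]
        out = linkage_map_join(["l0", "l1", "l2"], map_table,
                               ranked_loci=ranked, stop_run=3)
        extra = out[~out["in_block"]]["locus"].tolist()
        # l3 (LG4), l5 (LG4) collected; the run l6,l7,l8 (3 foreign) stops
        # the scan before l10/l11
        assert extra == ["l3", "l5"]
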