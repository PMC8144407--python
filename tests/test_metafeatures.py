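import itertools

import numpy as np
import pandas as pd
import pytest

import hidgenome as hg
from hidgenome.catalog import VariantKey
from hidgenome.metafeatures import (COMPLEMENT, EpigenomeTrack, SBS96_LABELS,
                                    assemble_meta_design, assign_region,
                                    assign_sbs96, build_epigenome_metafeatures,
                                    build_gene_indicators, loglog1p,
                                    reverse_complement)

from conftest import make_catalog


class TestAssignSbs96:
    def test_pyrimidine_reference_labeled_directly(self):
        v = VariantKey("1", 10, "T", "C", "A", "G")
        assert assign_sbs96(v) == "T>C A.G"

    def test_purine_reference_reverse_complemented(self):
        # sequence CAT with A>G: revcomp(CAT) = ATG, so T>C in A.G context
        v = VariantKey("1", 10, "A", "G", "C", "T")
        assert assign_sbs96(v) == "T>C A.G"

    def test_enumeration_gives_96_categories_twice_covered(self):
        from collections import Counter
        hits = Counter()
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                for f5 in "ACGT":
                    for f3 in "ACGT":
                        hits[assign_sbs96(VariantKey("1", 1, ref, alt, f5, f3))] += 1
        assert len(hits) == 96
        assert set(hits.values()) == {2}
        assert set(hits) == set(SBS96_LABELS)

    def test_strand_invariance(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        for _ in range(50):
            ref, alt = rng.choice(list(bases), 2, replace=False)
            f5, f3 = rng.choice(list(bases), 2)
            v = VariantKey("1", 5, ref, alt, f5, f3)
            rc = VariantKey("1", 5, COMPLEMENT[ref], COMPLEMENT[alt],
                            COMPLEMENT[f3], COMPLEMENT[f5])
            assert assign_sbs96(v) == assign_sbs96(rc)

    def test_ambiguous_flank_unassignable(self):
        assert assign_sbs96(VariantKey("1", 10, "C", "T", "N", "A")) is None
        assert assign_sbs96(VariantKey("1", 10, "C", "T", None, None)) is None


class TestAssignRegion:
    LEN = {"1": 10_000_000, "2": 10_000_000}

    @pytest.mark.parametrize("chrom,pos,expected", [
        ("2", 3_200_000, ("2", 4)),
        ("1", 1_000_000, ("1", 1)),
        ("1", 1_000_001, ("1", 2)),
        ("1", 1, ("1", 1)),
    ])
    def test_bin_convention(self, chrom, pos, expected):
        v = VariantKey(chrom, pos, "C", "T")
        assert assign_region(v, self.LEN) == expected

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            assign_region(VariantKey("7", 5, "C", "T"), self.LEN)

    def test_position_beyond_length_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            assign_region(VariantKey("1", 10_000_001, "C", "T"), self.LEN)


class TestGeneIndicators:
    def _genes(self):
        return pd.DataFrame(
            [("1", 100, 200, "GA"), ("1", 150, 300, "GB"), ("2", 0, 50, "GC")],
            columns=["chrom", "start", "end", "name"],
        )

    def test_membership_against_brute_force(self):
        variants = [VariantKey("1", p, "C", "T") for p in (101, 120, 180, 250, 500)]
        variants.append(VariantKey("2", 10, "C", "T"))
        M, names = build_gene_indicators(variants, self._genes())
        M = M.toarray()
        genes = self._genes()
        for j, v in enumerate(variants):
            for l, g in enumerate(names):
                rows = genes[genes["name"] == g]
                expect = any(
                    r.chrom == v.chrom and r.start <= v.pos - 1 < r.end
                    for r in rows.itertuples(index=False)
                )
                assert M[j, l] == expect

    def test_intergenic_variant_all_zero(self):
        M, _ = build_gene_indicators([VariantKey("1", 5000, "C", "T")], self._genes())
        assert M.sum() == 0

    def test_overlapping_genes_both_set(self):
        M, names = build_gene_indicators([VariantKey("1", 180, "C", "T")], self._genes())
        row = dict(zip(names, M.toarray()[0]))
        assert row["GA"] == 1 and row["GB"] == 1


class TestEpigenomeScores:
    def _track(self, rows, sites):
        df = pd.DataFrame(rows, columns=["chrom", "bin", "sample", "signal"])
        return EpigenomeTrack(mark="dnase", data=df, sample_sites=sites)

    def test_all_equal_signals_score_zero(self):
        rows = [("1", b, s, 5.0) for b in (1, 2) for s in ("a", "b")]
        track = self._track(rows, {"a": "X", "b": "Y"})
        scores = build_epigenome_metafeatures(track, ["X", "Y"])
        assert (scores.to_numpy() == 0).all()

    def test_closed_form_of_transform(self):
        # one site, one sample, one bin whose thresholded total is e - 1
        rows = [("1", 1, "a", np.e - 1.0), ("1", 2, "a", 0.1), ("1", 3, "a", 0.2)]
        track = self._track(rows, {"a": "X"})
        scores = build_epigenome_metafeatures(track, ["X"])
        # global median is 0.2; only e-1 exceeds it -> f(e-1) = log 2
        assert scores.loc[("1", 1), "X"] == pytest.approx(np.log(2.0), abs=1e-12)

    def test_transform_increasing_and_zero_at_zero(self):
        x = np.linspace(0, 50, 200)
        y = loglog1p(x)
        assert y[0] == 0.0
        assert (np.diff(y) > 0).all()

    def test_ten_sites_three_marks_give_30_columns(self, tiny_cohort):
        catalog, tables, _ = tiny_cohort
        sites = [f"site{i}" for i in range(10)]
        rng = np.random.default_rng(3)
        tracks = []
        for mark in ("dnase", "h3k36me3", "h3k4me1"):
            rows = []
            sample_sites = {}
            for s in sites:
                smp = f"{s}_0"
                sample_sites[smp] = s
                rows += [("1", b, smp, float(rng.gamma(2, 10))) for b in range(1, 6)]
            tracks.append(EpigenomeTrack(mark=mark,
                                         data=pd.DataFrame(rows, columns=["chrom", "bin", "sample", "signal"]),
                                         sample_sites=sample_sites))
        md = assemble_meta_design(
            catalog, chrom_lengths={"1": 60_000_000, "2": 60_000_000},
            epitracks=tracks, sites=sites,
            include_sbs96=False, include_regions=False, include_intercept=False,
        )
        assert md.p == 30
        assert all(f == "epigenome" for f in md.families)

    def test_invariant_to_sample_duplication_and_order(self):
        rows = [("1", 1, "a", 9.0), ("1", 2, "a", 1.0), ("1", 1, "b", 3.0),
                ("1", 2, "b", 7.0)]
        t1 = self._track(rows, {"a": "X", "b": "X"})
        s1 = build_epigenome_metafeatures(t1, ["X"])
        # duplicate the site's sample set and shuffle rows
        rows2 = [("1", 1, "a2", 9.0), ("1", 2, "a2", 1.0), ("1", 1, "b2", 3.0),
                 ("1", 2, "b2", 7.0)] + rows
        rng = np.random.default_rng(1)
        rows2 = [rows2[i] for i in rng.permutation(len(rows2))]
        t2 = self._track(rows2, {"a": "X", "b": "X", "a2": "X", "b2": "X"})
        s2 = build_epigenome_metafeatures(t2, ["X"])
        pd.testing.assert_frame_equal(s1, s2)

    def test_site_without_samples_errors(self):
        track = self._track([("1", 1, "a", 1.0)], {"a": "X"})
        with pytest.raises(ValueError, match="Y"):
            build_epigenome_metafeatures(track, ["X", "Y"])

    def test_negative_signal_errors(self):
        with pytest.raises(ValueError, match="negative"):
            self._track([("1", 1, "a", -1.0)], {"a": "X"})


class TestAssembleMetaDesign:
    def test_intercept_only(self, tiny_cohort):
        catalog, _, _ = tiny_cohort
        md = assemble_meta_design(catalog, include_sbs96=False,
                                  include_regions=False)
        assert md.p == 1
        assert np.all(md.U.toarray() == 1.0)

    def test_column_count_arithmetic(self, tiny_config, tiny_cohort):
        catalog, tables, _ = tiny_cohort
        md = assemble_meta_design(catalog, chrom_lengths=tiny_config.chrom_lengths,
                                  gene_intervals=tables["genes"])
        n_regions = 60 + 60
        assert md.p == 1 + 10 + 96 + n_regions
        fams = md.family_groups
        assert [len(fams[f]) for f in ("intercept", "gene", "sbs96", "region")] == \
            [1, 10, 96, n_regions]

    def test_each_variant_in_one_sbs_and_one_region(self, tiny_config, tiny_cohort):
        catalog, _, _ = tiny_cohort
        md = assemble_meta_design(catalog, chrom_lengths=tiny_config.chrom_lengths)
        fams = np.asarray(md.families)
        S = md.U[:, fams == "sbs96"].toarray()
        R = md.U[:, fams == "region"].toarray()
        assert set(S.sum(axis=1)) <= {0.0, 1.0}
        assert np.all(R.sum(axis=1) == 1.0)

    def test_no_components_errors(self, tiny_cohort):
        catalog, _, _ = tiny_cohort
        with pytest.raises(ValueError, match="no meta-features"):
            assemble_meta_design(catalog, include_intercept=False,
                                 include_sbs96=False, include_regions=False)
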