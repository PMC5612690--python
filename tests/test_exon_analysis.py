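import numpy as np
import pandas as pd
import pytest

from exomethyl.exon_analysis import (
    FIRST,
    INCLUDED,
    INTERNAL,
    LAST,
    NOT_EVALUABLE,
    PROFILE_PARAMS,
    SKIPPED,
    ExonRecord,
    boundary_profile,
    classify_exon_positions,
    classify_inclusion,
    compare_lengths_by_status,
    compare_methylation_by_class,
    exon_methylation_status,
)
from exomethyl.io_formats import GeneModel, Transcript
from exomethyl.methylation_core import Methylome


def _gene(gene_id, strand, exons, chrom="c"):
    t = Transcript(f"{gene_id}.t", sorted(exons))
    return GeneModel(gene_id, chrom, strand, [t], f"{gene_id}.t")


def _methylome(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_unmeth"])


class TestClassification:
    def test_five_exon_plus_strand(self):
        g = _gene("g", "+", [(0, 10), (20, 30), (40, 50), (60, 70), (80, 90)])
        res = classify_exon_positions([g])
        assert [r.position_class for r in res.records] == [
            FIRST, INTERNAL, INTERNAL, INTERNAL, LAST,
        ]
        assert [r.rank for r in res.records] == [1, 2, 3, 4, 5]

    def test_two_exon_gene_excluded(self):
        res = classify_exon_positions([_gene("g", "+", [(0, 10), (20, 30)])])
        assert res.records == []
        assert res.n_genes_excluded == 1

    def test_minus_strand_first_is_highest_coordinate(self):
        g = _gene("g", "-", [(0, 10), (20, 30), (40, 50)])
        res = classify_exon_positions([g])
        first = next(r for r in res.records if r.position_class == FIRST)
        assert (first.start, first.end) == (40, 50)

    def test_partition_counts(self, small_dataset):
        """Every included transcript yields exactly (1, n-2, 1) records."""
        res = classify_exon_positions(small_dataset.genes.values())
        by_gene = {}
        for r in res.records:
            by_gene.setdefault(r.gene_id, []).append(r.position_class)
        total = 0
        for gene_id, classes in by_gene.items():
            n = len(classes)
            assert classes.count(FIRST) == 1
            assert classes.count(LAST) == 1
            assert classes.count(INTERNAL) == n - 2
            total += n
        assert total == len(res.records)
        n_small = sum(
            1
            for g in small_dataset.genes.values()
            if g.representative.n_exons < 3
        )
        assert res.n_genes_excluded == n_small


class TestExonStatus:
    def test_one_mcpg_is_methylated(self):
        r = ExonRecord("g", "t", "c", 100, 200, "+", 2, INTERNAL)
        meth = Methylome(_methylome([("c", 150, 5, 5)]))
        exon_methylation_status(r, meth)
        assert r.is_methylated
        assert r.meth.n_mcpg == 1

    def test_covered_but_unmethylated(self):
        r = ExonRecord("g", "t", "c", 100, 200, "+", 2, INTERNAL)
        meth = Methylome(_methylome([("c", 150, 0, 10)]))
        exon_methylation_status(r, meth)
        assert r.is_methylated is False
        assert r.meth.has_data

    def test_no_covered_cpgs_flagged(self):
        r = ExonRecord("g", "t", "c", 100, 200, "+", 2, INTERNAL)
        meth = Methylome(_methylome([("c", 150, 1, 1)]))
        exon_methylation_status(r, meth)
        assert r.is_methylated is False
        assert not r.meth.has_data


class TestComparisons:
    def _records(self, lengths, methylated, cls=INTERNAL):
        out = []
        for i, (L, m) in enumerate(zip(lengths, methylated)):
            r = ExonRecord("g", "t", "c", 0, L, "+", 2, cls)
            r.is_methylated = m
            out.append(r)
        return out

    def test_length_difference_detected(self):
        """Methylated ~N(300,50) vs unmethylated ~N(200,50): all of 20
        seeded replicates significant at p < 0.001 with the right sign."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            lengths = np.concatenate(
                [rng.normal(300, 50, 500), rng.normal(200, 50, 500)]
            ).round()
            flags = [True] * 500 + [False] * 500
            cmp = compare_lengths_by_status(self._records(lengths, flags), INTERNAL)
            assert cmp.p_value < 0.001
            assert cmp.median_a > cmp.median_b

    def test_null_lengths_uniform_p(self):
        """With both groups from one distribution the p-value is uniform:
        checked by a KS test over 200 replicates."""
        from scipy import stats as sps

        rng = np.random.default_rng(29)
        ps = []
        for _ in range(200):
            lengths = rng.normal(250, 50, 120).round()
            flags = [True] * 60 + [False] * 60
            ps.append(
                compare_lengths_by_status(self._records(lengths, flags), INTERNAL).p_value
            )
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_exact_small_sample_case(self):
        cmp = compare_lengths_by_status(
            self._records([4, 5, 6, 1, 2, 3], [True] * 3 + [False] * 3), INTERNAL
        )
        # two-sided exact p for a complete separation of 3 vs 3
        assert cmp.p_value == pytest.approx(0.1)

    def test_empty_group_not_computable(self):
        cmp = compare_lengths_by_status(
            self._records([10, 20, 30], [True, True, True]), INTERNAL
        )
        assert not cmp.computable
        assert cmp.p_value is None

    def test_class_ordering_recovered(self, small_dataset):
        """On simulated data with true levels first=0.10 < last=0.20 <
        internal=0.30 the median ordering is recovered."""
        from exomethyl.exon_analysis import classify_exon_positions

        meth = Methylome(small_dataset.calls["meth_sample_1"])
        truth = small_dataset.truth_genes
        meth_ids = set(truth.loc[truth["methylated"], "gene_id"])
        res = classify_exon_positions(small_dataset.genes.values())
        records = [r for r in res.records if r.gene_id in meth_ids]
        for r in records:
            exon_methylation_status(r, meth)
        cmp = compare_methylation_by_class(records)
        med = {}
        for cls in (FIRST, INTERNAL, LAST):
            med[cls] = np.median(
                [r.meth.level for r in records
                 if r.position_class == cls and r.meth.has_data]
            )
        assert med[FIRST] < med[LAST] < med[INTERNAL]
        assert all(c.p_value < 0.001 for c in cmp.values())

    def test_single_exon_per_class_not_computable(self):
        recs = []
        for cls in (FIRST, INTERNAL, LAST):
            r = ExonRecord("g", "t", "c", 0, 100, "+", 1, cls)
            r.meth = None
            recs.append(r)
        cmp = compare_methylation_by_class(recs)
        assert all(not c.computable for c in cmp.values())


class TestInclusion:
    def _record(self):
        return ExonRecord("g", "t", "c", 0, 100, "+", 2, INTERNAL)

    @pytest.mark.parametrize(
        "exon_fpkm, gene_fpkm, gene_level, expected",
        [
            (5.0, 10.0, 0.3, INCLUDED),
            (0.2, 10.0, 0.3, SKIPPED),
            (5.0, 10.0, 0.05, NOT_EVALUABLE),  # gene below methylation filter
            (5.0, 0.5, 0.3, NOT_EVALUABLE),  # gene not expressed
            (None, 10.0, 0.3, NOT_EVALUABLE),  # missing expression entry
        ],
    )
    def test_rules(self, exon_fpkm, gene_fpkm, gene_level, expected):
        assert (
            classify_inclusion(self._record(), exon_fpkm, gene_fpkm, gene_level)
            == expected
        )

    def test_thresholds_are_inclusive(self):
        # FPKM >= 1 and level >= 0.1 are evaluable boundaries
        assert classify_inclusion(self._record(), 1.0, 1.0, 0.1) == INCLUDED


class TestBoundaryProfile:
    def _one_exon(self, strand="+", start=1000, end=1300):
        r = ExonRecord("g", "t", "c", start, end, strand, 2, INTERNAL)
        r.inclusion["s"] = INCLUDED
        return r

    def test_bin_geometry(self):
        flank, n_bins = PROFILE_PARAMS[INTERNAL]
        assert (flank, n_bins) == (200, 20)
        assert 2 * flank // n_bins == 20
        flank, n_bins = PROFILE_PARAMS[FIRST]
        assert (flank, n_bins) == (150, 15)
        assert 2 * flank // n_bins == 20

    def test_anchor_boundary_cpg_goes_to_first_inside_bin(self):
        """A CpG exactly on the start anchor lands in the first bin inside
        the exon (bin 10 of 20 for internal exons)."""
        r = self._one_exon()
        meth = Methylome(_methylome([("c", 1001, 8, 2)]))  # 1-based pos 1001 = 0-based 1000
        pm = boundary_profile([r], INTERNAL, INCLUDED, meth, sample="s")
        assert pm.sum_cov["start"][10] == 10
        assert pm.sum_cov["start"].sum() == 10

    def test_conservation_of_coverage(self, small_dataset):
        """Summed per-bin coverage equals the total covered-CpG coverage in
        the flanking windows (each CpG in exactly one bin per window)."""
        meth = Methylome(small_dataset.calls["meth_sample_1"])
        res = classify_exon_positions(small_dataset.genes.values())
        records = res.records[:200]
        for r in records:
            r.inclusion["s"] = INCLUDED
        pm = boundary_profile(records, INTERNAL, INCLUDED, meth, sample="s")
        flank, _ = PROFILE_PARAMS[INTERNAL]
        expected = {"start": 0, "end": 0}
        for r in records:
            if r.position_class != INTERNAL:
                continue
            for anchor in ("start", "end"):
                if anchor == "start":
                    a = r.start if r.strand == "+" else r.end
                else:
                    a = r.end if r.strand == "+" else r.start
                _, m, u = meth.region("sim1", a - flank, a + flank)
                cov = m + u
                expected[anchor] += int(cov[cov >= 5].sum())
        assert pm.sum_cov["start"].sum() == expected["start"]
        assert pm.sum_cov["end"].sum() == expected["end"]

    def test_mirror_symmetry(self):
        """Reflecting coordinates and strand leaves the profile unchanged."""
        rng = np.random.default_rng(31)
        pos = np.sort(rng.choice(np.arange(700, 1700), 80, replace=False))
        m = rng.binomial(20, 0.3, 80)
        rows = [("c", int(p) + 1, int(mm), int(20 - mm)) for p, mm in zip(pos, m)]
        meth = Methylome(_methylome(rows))
        r = self._one_exon("+")
        pm_fwd = boundary_profile([r], INTERNAL, INCLUDED, meth, sample="s")

        M = 3000  # mirror: position p -> M-1-p (0-based), interval flips
        rows_m = [("c", M - (p_1b - 1), mm, u) for (_, p_1b, mm, u) in rows]
        meth_m = Methylome(_methylome(rows_m))
        r_m = ExonRecord("g", "t", "c", M - 1300, M - 1000, "-", 2, INTERNAL)
        r_m.inclusion["s"] = INCLUDED
        pm_rev = boundary_profile([r_m], INTERNAL, INCLUDED, meth_m, sample="s")
        for anchor in ("start", "end"):
            np.testing.assert_array_equal(
                pm_fwd.sum_c[anchor], pm_rev.sum_c[anchor]
            )
            np.testing.assert_array_equal(
                pm_fwd.sum_cov[anchor], pm_rev.sum_cov[anchor]
            )

    def test_uniform_methylome_flat_profile(self):
        """Uniform true level 0.25 with binomial counts: every bin's pooled
        level within 3 binomial SEs of 0.25."""
        rng = np.random.default_rng(37)
        records = []
        rows = []
        for i in range(150):
            start = 2000 * i + 600
            r = ExonRecord("g", "t", "c", start, start + 300, "+", 2, INTERNAL)
            r.inclusion["s"] = INCLUDED
            records.append(r)
            pos = np.arange(start - 250, start + 560, 18)
            for p in pos:
                mm = rng.binomial(20, 0.25)
                rows.append(("c", int(p) + 1, int(mm), int(20 - mm)))
        meth = Methylome(_methylome(rows))
        pm = boundary_profile(records, INTERNAL, INCLUDED, meth, sample="s")
        for anchor in ("start", "end"):
            lv = pm.level(anchor)
            cov = pm.sum_cov[anchor]
            se = np.sqrt(0.25 * 0.75 / cov)
            assert (np.abs(lv - 0.25) < 3 * se).all()

    def test_included_above_skipped_profile(self, small_dataset):
        """Included internal exons (true level 0.30) sit above skipped ones
        (0.10) in every bin of both anchors."""
        meth = Methylome(small_dataset.calls["meth_sample_1"])
        truth = small_dataset.truth_exons.set_index(
            ["transcript_id", "rank"]
        )["inclusion"]
        res = classify_exon_positions(small_dataset.genes.values())
        gene_meth = small_dataset.truth_genes.set_index("gene_id")["methylated"]
        records = []
        for r in res.records:
            if not gene_meth.loc[r.gene_id]:
                continue
            r.inclusion["s"] = truth.loc[(r.transcript_id, r.rank)]
            records.append(r)
        inc = boundary_profile(records, INTERNAL, INCLUDED, meth, sample="s")
        skp = boundary_profile(records, INTERNAL, SKIPPED, meth, sample="s")
        for anchor in ("start", "end"):
            diff = inc.level(anchor) - skp.level(anchor)
            assert (diff > 0).all()
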