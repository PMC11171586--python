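import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svcoseg.sv_cohort import (
    CohortFrequency,
    FrequencyTier,
    MatchParams,
    SVRecord,
    assign_tier,
    cluster_svs,
    control_frequency,
    read_sv_vcf,
    write_merged_vcf,
)

from conftest import rec

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr18,length=80000000>
##contig=<ID=chr2,length=100000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def write_vcf(tmp_path, body, name="test.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadSvVcf:
    def test_del_row_with_end(self, tmp_path):
        # 491 bp deletion spanning chr18:13647104-13647595.
        p = write_vcf(
            tmp_path,
            "chr18\t13647104\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=13647595\tGT\t0/1\t0/0\n",
        )
        records = read_sv_vcf(p)
        assert len(records) == 1
        r = records[0]
        assert (r.chrom, r.pos, r.end, r.svtype, r.svlen) == ("chr18", 13647104, 13647595, "DEL", -491)
        assert r.sample_id == "S1"

    def test_homref_sample_emits_nothing(self, tmp_path):
        p = write_vcf(
            tmp_path, "chr18\t100\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=600\tGT\t0/0\t0/0\n"
        )
        assert read_sv_vcf(p) == []

    def test_ins_without_end(self, tmp_path):
        p = write_vcf(
            tmp_path, "chr2\t13096390\t.\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=55\tGT\t1/1\t0/0\n"
        )
        (r,) = read_sv_vcf(p)
        assert r.end == r.pos == 13096390
        assert r.svlen == 55 and r.genotype == "1/1"

    def test_end_from_svlen_fallback(self, tmp_path):
        p = write_vcf(
            tmp_path, "chr2\t1000\t.\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;SVLEN=500\tGT\t0/1\t0/0\n"
        )
        (r,) = read_sv_vcf(p)
        assert r.end == 1500

    def test_missing_end_and_svlen_skipped(self, tmp_path, caplog):
        p = write_vcf(
            tmp_path,
            "chr2\t1000\t.\tN\t<INV>\t.\tPASS\tSVTYPE=INV\tGT\t0/1\t0/0\n"
            "chr2\t9000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=9500\tGT\t0/1\t0/0\n",
        )
        records = read_sv_vcf(p)
        assert [r.pos for r in records] == [9000]

    def test_missing_genotypes_optional(self, tmp_path):
        body = "chr2\t1000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=2000\tGT\t0/1\t./.\n"
        p = write_vcf(tmp_path, body)
        assert len(read_sv_vcf(p)) == 1
        records = read_sv_vcf(p, include_missing=True)
        assert len(records) == 2
        assert {r.genotype for r in records} == {"0/1", "missing"}

    def test_malformed_vcf_errors(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("this is not a vcf\n")
        with pytest.raises(Exception):
            read_sv_vcf(p)


class TestClustering:
    def test_identical_dels_cluster(self):
        clusters = cluster_svs([rec("S1"), rec("S2")])
        assert len(clusters) == 1
        assert clusters[0].carrier_samples == {"S1", "S2"}

    def test_low_overlap_splits(self):
        # 10% reciprocal overlap: two clusters.
        a = rec("S1", pos=1000, end=2000)
        b = rec("S2", pos=1900, end=2900)
        assert len(cluster_svs([a, b], MatchParams(breakpoint_tol=2000))) == 2

    def test_single_linkage_chain(self):
        # A~B and B~C but A and C differ at both ends by > tol under a loose
        # overlap requirement: still one cluster via B (verified by explicit
        # pairwise linkage + connected components below).
        params = MatchParams(reciprocal_overlap=0.5, breakpoint_tol=60)
        a = rec("S1", pos=1000, end=2000)
        b = rec("S2", pos=1050, end=2050)
        c = rec("S3", pos=1100, end=2100)

        def link(x, y):
            if abs(x.pos - y.pos) > 60 or abs(x.end - y.end) > 60:
                return False
            shared = min(x.end, y.end) - max(x.pos, y.pos) + 1
            return shared / x.span >= 0.5 and shared / y.span >= 0.5

        assert link(a, b) and link(b, c) and not link(a, c)
        clusters = cluster_svs([a, b, c], params)
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_type_and_chrom_separate(self):
        records = [
            rec("S1", svtype="DEL", svlen=-1000),
            rec("S1", svtype="DUP", svlen=1000),
            rec("S1", chrom="chr2"),
        ]
        assert len(cluster_svs(records)) == 3

    def test_insertion_matching(self):
        a = rec("S1", pos=5000, end=5000, svtype="INS", svlen=100)
        b = rec("S2", pos=5030, end=5030, svtype="INS", svlen=80)
        c = rec("S3", pos=5030, end=5030, svtype="INS", svlen=10)  # ratio 0.1
        clusters = cluster_svs([a, b, c])
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]

    def test_bnd_excluded(self):
        records = [rec("S1"), SVRecord("S1", "chr1", 500, 500, "BND", 0)]
        clusters = cluster_svs(records)
        assert sum(len(c.members) for c in clusters) == 1

    def test_conservation(self, rng):
        records = []
        for i in range(50):
            pos = int(rng.integers(1000, 1_000_000))
            records.append(rec(f"S{i % 7}", pos=pos, end=pos + 500))
        clusters = cluster_svs(records)
        assert sum(len(c.members) for c in clusters) == len(records)

    def test_idempotent_on_consensus(self):
        base = [rec("S1", pos=1000, end=2000), rec("S2", pos=1010, end=2010)]
        clusters = cluster_svs(base)
        consensus = [
            rec("X", pos=c.pos, end=c.end, svtype=c.svtype, svlen=c.svlen) for c in clusters
        ]
        again = cluster_svs(consensus)
        assert [(c.chrom, c.pos, c.end, c.svtype) for c in again] == [
            (c.chrom, c.pos, c.end, c.svtype) for c in clusters
        ]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance(self, seed):
        rnd = random.Random(seed)
        records = []
        for i in range(30):
            pos = rnd.randrange(1000, 50_000)
            records.append(rec(f"S{i % 5}", pos=pos, end=pos + rnd.randrange(100, 2000)))
        baseline = cluster_svs(records)
        shuffled = records[:]
        rnd.shuffle(shuffled)
        permuted = cluster_svs(shuffled)
        key = lambda cs: sorted(
            tuple(sorted((m.sample_id, m.pos, m.end) for m in c.members)) for c in cs
        )
        assert key(baseline) == key(permuted)


class TestControlFrequency:
    def make_cluster(self, carriers):
        records = [rec(s) for s in carriers]
        (cluster,) = cluster_svs(records)
        return cluster

    def test_one_of_102(self):
        cluster = self.make_cluster(["CTRL_001"])
        freq = control_frequency(cluster, {f"CTRL_{i:03d}" for i in range(102)})
        assert freq.n_carriers == 1 and freq.n_controls == 102
        assert freq.percent == pytest.approx(0.98, abs=0.005)

    def test_five_of_102(self):
        cluster = self.make_cluster([f"CTRL_{i:03d}" for i in range(5)])
        freq = control_frequency(cluster, {f"CTRL_{i:03d}" for i in range(102)})
        assert freq.percent == pytest.approx(4.90, abs=0.005)

    def test_family_carriers_not_counted(self):
        cluster = self.make_cluster(["FAM_A_01"])
        freq = control_frequency(cluster, {"CTRL_000"})
        assert freq.n_carriers == 0

    def test_empty_controls_error(self):
        cluster = self.make_cluster(["S1"])
        with pytest.raises(ValueError):
            control_frequency(cluster, set())


class TestTiers:
    @pytest.mark.parametrize(
        "n,total,tier",
        [
            (0, 102, FrequencyTier.ABSENT),
            (1, 102, FrequencyTier.RARE),      # 0.98%
            (2, 102, FrequencyTier.UNCOMMON),  # 1.96%
            (5, 102, FrequencyTier.UNCOMMON),  # 4.90%
            (6, 102, FrequencyTier.COMMON),    # 5.88%
        ],
    )
    def test_study_boundaries(self, n, total, tier):
        assert assign_tier(CohortFrequency(n, total)) is tier

    @pytest.mark.parametrize(
        "n,total,tier",
        [
            (9999, 1_000_000, FrequencyTier.RARE),      # 0.9999%
            (1, 100, FrequencyTier.UNCOMMON),           # exactly 1%
            (49999, 1_000_000, FrequencyTier.UNCOMMON), # 4.9999%
            (5, 100, FrequencyTier.COMMON),             # exactly 5%
        ],
    )
    def test_strict_boundaries(self, n, total, tier):
        assert assign_tier(CohortFrequency(n, total)) is tier

    @given(n=st.integers(0, 102))
    @settings(max_examples=103, deadline=None)
    def test_tiers_partition(self, n):
        tier = assign_tier(CohortFrequency(n, 102))
        pct = 100 * n / 102
        expected = (
            FrequencyTier.ABSENT
            if pct == 0
            else FrequencyTier.RARE
            if pct < 1
            else FrequencyTier.UNCOMMON
            if pct < 5
            else FrequencyTier.COMMON
        )
        assert tier is expected


class TestMergedVcfOutput:
    def test_round_trip(self, tmp_path):
        clusters = cluster_svs([rec("S1"), rec("S2", pos=1010, end=2010)])
        out = tmp_path / "merged.vcf"
        write_merged_vcf(clusters, ["S1", "S2"], out)
        back = read_sv_vcf(out)
        assert {r.sample_id for r in back} == {"S1", "S2"}
        assert back[0].svtype == "DEL"
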