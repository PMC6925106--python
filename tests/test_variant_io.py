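import numpy as np
import pandas as pd
import pytest

from acidsel.variant_io import (
    AlleleCountMatrix,
    FilterSpec,
    SampleMeta,
    allele_frequency,
    build_snp_panel,
    read_sample_meta,
    read_sync,
    read_vcf_ad,
    write_sample_meta,
    write_sync,
    write_vcf,
)


def _matrix(ref, alt, contigs=None, sample_ids=None):
    ref = np.atleast_2d(ref)
    alt = np.atleast_2d(alt)
    n = ref.shape[0]
    snps = pd.DataFrame(
        {
            "contig": contigs or [f"c{i}" for i in range(n)],
            "pos": np.arange(1, n + 1) * 10,
            "ref": ["A"] * n,
            "alt": ["C"] * n,
        }
    )
    return AlleleCountMatrix(
        snps=snps,
        ref_depth=ref,
        alt_depth=alt,
        sample_ids=sample_ids or [f"s{j}" for j in range(ref.shape[1])],
    )


class TestSync:
    def test_direct_parse(self, tmp_path):
        path = tmp_path / "toy.sync"
        path.write_text("c1\t10\tA\t7:0:3:0:0:0\n")
        counts = read_sync(path, alleles={("c1", 10): ("A", "C")})
        assert counts.ref_depth[0, 0] == 7
        assert counts.alt_depth[0, 0] == 3
        assert counts.snps["alt"].iat[0] == "C"

    def test_roundtrip_bit_exact(self, tmp_path, rng):
        ref = rng.integers(0, 200, size=(20, 4))
        alt = rng.integers(1, 200, size=(20, 4))  # alt > 0 so inference is determined
        m = _matrix(ref, alt)
        path = tmp_path / "rt.sync"
        write_sync(m, path)
        back = read_sync(path, sample_ids=m.sample_ids)
        assert m.equals(back)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.sync"
        path.write_text("c1\t10\tA\t7:0:3:0:0:0\nc1\t20\tA\t7:0:3\n")
        with pytest.raises(ValueError, match="line 2"):
            read_sync(path)

    def test_multiallelic_policy(self, tmp_path):
        path = tmp_path / "multi.sync"
        path.write_text("c1\t10\tA\t7:2:3:0:0:0\n")  # A, T and C all segregate
        with pytest.raises(ValueError, match="segregating"):
            read_sync(path, on_multiallelic="error")
        with pytest.warns(UserWarning, match="multiallelic"):
            counts = read_sync(path, on_multiallelic="drop")
        assert counts.n_snps == 0


class TestVcf:
    def test_roundtrip_matches_matrix(self, tmp_path, rng):
        ref = rng.integers(0, 150, size=(30, 3))
        alt = rng.integers(0, 150, size=(30, 3))
        m = _matrix(ref, alt, contigs=[f"ctg{i // 3}" for i in range(30)])
        path = tmp_path / "toy.vcf"
        write_vcf(m, path)
        back, n_skipped = read_vcf_ad(path)
        assert n_skipped == 0
        assert m.equals(back)

    def test_multiallelic_skipped_and_counted(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
            "##contig=<ID=c1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\n"
        )
        body = "c1\t10\t.\tA\tC\t.\t.\t.\tAD\t12,8\n" "c1\t20\t.\tA\tC,G\t.\t.\t.\tAD\t5,3,2\n"
        path = tmp_path / "m.vcf"
        path.write_text(header + body)
        counts, n_skipped = read_vcf_ad(path)
        assert n_skipped == 1
        assert counts.n_snps == 1
        assert counts.ref_depth[0, 0] == 12 and counts.alt_depth[0, 0] == 8

    def test_missing_ad_errors(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            "##contig=<ID=c1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\n"
            "c1\t10\t.\tA\tC\t.\t.\t.\tDP\t20\n"
        )
        path = tmp_path / "noad.vcf"
        path.write_text(header)
        with pytest.raises(ValueError, match="AD"):
            read_vcf_ad(path)


class TestFrequencies:
    @pytest.mark.parametrize(
        "ref,alt,expected", [(50, 50, 0.5), (100, 0, 0.0), (60, 40, 0.4)]
    )
    def test_alt_over_total(self, ref, alt, expected):
        m = _matrix([[ref]], [[alt]])
        assert allele_frequency(m)[0, 0] == pytest.approx(expected)

    def test_zero_depth_is_missing_not_zero(self):
        m = _matrix([[0]], [[0]])
        assert np.isnan(allele_frequency(m)[0, 0])


class TestPanelFilter:
    def _founders(self, n_snps, n_founders=8, depth=40):
        # heterozygous-looking founders: MAF 0.5, always callable
        ref = np.full((n_snps, n_founders), depth // 2)
        alt = np.full((n_snps, n_founders), depth // 2)
        return _matrix(ref, alt, sample_ids=[f"f{j}" for j in range(n_founders)])

    def test_toy_attrition_table(self):
        # 5 SNPs, two violate exactly one pool rule each
        ref = np.array([[50, 60], [50, 60], [49, 60], [100, 80], [199, 60]])
        alt = np.array([[50, 60], [50, 60], [0, 0], [100, 80], [1, 40]])
        pools = _matrix(ref, alt, sample_ids=["p1", "p2"])
        founders = self._founders(5)
        panel, report = build_snp_panel(pools, founders, FilterSpec())
        assert panel.n_snps == 3
        assert report.n_kept == 3
        assert sum(report.removed_by_rule.values()) == 2
        assert report.removed_by_rule["pool_depth"] == 1  # SNP with 49x sample
        assert report.removed_by_rule["pool_maf"] == 1  # SNP with freq 0.005 sample

    @pytest.mark.parametrize(
        "field,tight",
        [
            ("pool_depth_min", 80),
            ("pool_maf_min", 0.2),
            ("founder_maf_min", 0.6),
            ("founder_max_missing", 1.0),
        ],
    )
    def test_tightening_never_grows_panel(self, rng, field, tight):
        ref = rng.integers(20, 200, size=(60, 5))
        alt = rng.integers(0, 120, size=(60, 5))
        pools = _matrix(ref, alt, sample_ids=[f"p{j}" for j in range(5)])
        fref = rng.integers(0, 60, size=(60, 8))
        falt = rng.integers(0, 60, size=(60, 8))
        founders = _matrix(fref, falt, sample_ids=[f"f{j}" for j in range(8)])

        def kept(spec):
            try:
                panel, _ = build_snp_panel(pools, founders, spec)
                return panel.n_snps
            except ValueError:
                return 0

        assert kept(FilterSpec(**{field: tight})) <= kept(FilterSpec())

    def test_idempotent(self, rng):
        ref = rng.integers(40, 200, size=(80, 4))
        alt = rng.integers(5, 150, size=(80, 4))
        pools = _matrix(ref, alt, sample_ids=[f"p{j}" for j in range(4)])
        founders = self._founders(80)
        spec = FilterSpec()
        panel1, _ = build_snp_panel(pools, founders, spec)
        keep_keys = set(zip(panel1.snps["contig"], panel1.snps["pos"]))
        fkeep = founders.select_snps(
            np.array([(c, p) in keep_keys for c, p in zip(founders.snps["contig"], founders.snps["pos"])])
        )
        panel2, report2 = build_snp_panel(panel1, fkeep, spec)
        assert panel1.equals(panel2)
        assert sum(report2.removed_by_rule.values()) == 0

    def test_empty_panel_raises_with_attrition(self):
        pools = _matrix([[10]], [[0]], sample_ids=["p1"])
        founders = self._founders(1)
        with pytest.raises(ValueError, match="attrition"):
            build_snp_panel(pools, founders, FilterSpec())


class TestSampleMeta:
    def test_roundtrip_and_select(self, tmp_path):
        t = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "day": [0, 26],
                "treatment": ["day0", "low_pH"],
                "replicate": ["pool", "r4"],
                "size_class": ["all", "all"],
                "pool_min": [1000, 50],
                "pool_max": [1000, 50],
            }
        )
        meta = SampleMeta(table=t)
        path = tmp_path / "meta.tsv"
        write_sample_meta(meta, path)
        back = read_sample_meta(path)
        assert back.select(day=26, treatment="low_pH") == ["b"]

    def test_invalid_treatment_rejected(self):
        t = pd.DataFrame(
            {
                "sample_id": ["a"],
                "day": [0],
                "treatment": ["mystery"],
                "replicate": ["r1"],
                "size_class": ["all"],
                "pool_min": [1],
                "pool_max": [1],
            }
        )
        with pytest.raises(ValueError, match="treatment"):
            SampleMeta(table=t)
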