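import numpy as np
import pytest

from rohmap import geno_io
from rohmap.geno_io import (
    FormatError,
    GenotypeDataset,
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    Marker,
    Sample,
    read_pedmap,
    read_vcf,
    write_pedmap,
)
from rohmap.simdata import SimConfig, simulate_cohort

from conftest import make_dataset


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPedmap:
    def test_minimal_single_case(self, tmp_path):
        ped = write(tmp_path, "x.ped", "f1 s1 0 0 0 2 A A\n")
        mp = write(tmp_path, "x.map", "25 m1 0 100\n")
        ds = read_pedmap(ped, mp)
        assert [s.phenotype for s in ds.samples] == ["case"]
        assert ds.markers[0].id == "m1" and ds.markers[0].pos_bp == 100
        assert ds.calls[0, 0] == HOM_A

    def test_phenotype_codes_and_missing(self, tmp_path):
        ped = write(
            tmp_path, "x.ped",
            "f s1 0 0 0 1 A G\nf s2 0 0 0 2 G G\nf s3 0 0 0 0 0 0\nf s4 0 0 0 -9 G A\n",
        )
        mp = write(tmp_path, "x.map", "1 m1 0 500\n")
        ds = read_pedmap(ped, mp)
        assert [s.phenotype for s in ds.samples] == ["control", "case", "unknown", "unknown"]
        # het order normalized, missing as MISSING
        assert list(ds.calls[:, 0]) == [HET, HOM_B, MISSING, HET]
        assert (ds.markers[0].allele_a, ds.markers[0].allele_b) == ("A", "G")

    def test_study_cohort_phenotype_totals(self, tmp_path):
        cfg = SimConfig(seed=5, chromosomes=[("25", 2_000_000)], n_snp=50)
        ds, _ = simulate_cohort(cfg)
        write_pedmap(ds, tmp_path / "study")
        back = read_pedmap(tmp_path / "study.ped", tmp_path / "study.map")
        assert len(back.cases) == 6
        assert len(back.controls) == 3

    def test_row_length_mismatch_names_line(self, tmp_path):
        ped = write(tmp_path, "x.ped", "f s1 0 0 0 2 A A\nf s2 0 0 0 2 A A G G\n")
        mp = write(tmp_path, "x.map", "1 m1 0 500\n")
        with pytest.raises(FormatError, match="x.ped:2"):
            read_pedmap(ped, mp)

    def test_triallelic_marker_names_marker(self, tmp_path):
        ped = write(tmp_path, "x.ped", "f s1 0 0 0 2 A A\nf s2 0 0 0 1 C G\n")
        mp = write(tmp_path, "x.map", "1 rs77 0 500\n")
        with pytest.raises(FormatError, match="rs77"):
            read_pedmap(ped, mp)

    def test_unsorted_positions_rejected(self, tmp_path):
        ped = write(tmp_path, "x.ped", "f s1 0 0 0 2 A A G G\n")
        mp = write(tmp_path, "x.map", "1 m1 0 500\n1 m2 0 400\n")
        with pytest.raises(FormatError, match="m2"):
            read_pedmap(ped, mp)


class TestRoundTrip:
    def test_round_trip_simulated_cohort(self, tmp_path):
        cfg = SimConfig(
            seed=11, chromosomes=[("1", 1_000_000), ("2", 1_000_000)], n_snp=25,
            genotype_missing_rate=0.05,
        )
        ds, _ = simulate_cohort(cfg)
        write_pedmap(ds, tmp_path / "a")
        back = read_pedmap(tmp_path / "a.ped", tmp_path / "a.map")
        # simulator output is in first-observed-allele gauge: exact identity
        assert np.array_equal(back.calls, ds.calls)
        for orig, rb in zip(ds.markers, back.markers):
            if rb.allele_b is not None:  # both alleles observed in the file
                assert (rb.allele_a, rb.allele_b) == (orig.allele_a, orig.allele_b)
            elif rb.allele_a is not None:  # monomorphic: first allele agrees
                assert rb.allele_a == orig.allele_a
        assert [m.id for m in back.markers] == [m.id for m in ds.markers]
        assert [s.phenotype for s in back.samples] == [s.phenotype for s in ds.samples]
        # write-read-write is byte-identical
        write_pedmap(back, tmp_path / "b")
        assert (tmp_path / "a.ped").read_text() == (tmp_path / "b.ped").read_text()
        assert (tmp_path / "a.map").read_text() == (tmp_path / "b.map").read_text()

    def test_missing_serializes_as_zero_zero(self, tmp_path):
        ds = make_dataset([[MISSING, HOM_A]])
        write_pedmap(ds, tmp_path / "m")
        fields = (tmp_path / "m.ped").read_text().split()
        assert fields[6:8] == ["0", "0"]

    def test_empty_dataset(self, tmp_path):
        ds = GenotypeDataset([], [Marker("m1", "1", 10, "A", "G")],
                             np.empty((0, 1), dtype=np.int8))
        ped, mp = write_pedmap(ds, tmp_path / "e")
        back = read_pedmap(ped, mp)
        assert back.n_samples == 0 and back.n_markers == 1


class TestVcf:
    def vcf_text(self, records, samples=("s1", "s2", "s3", "s4")):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        return header + "".join(records)

    def test_gt_code_mapping(self, tmp_path):
        vcf = write(
            tmp_path, "x.vcf",
            self.vcf_text(["25\t100\tm1\tA\tG\t.\t.\t.\tGT\t0/0\t0|1\t1/1\t./.\n"]),
        )
        tab = write(tmp_path, "ph.tsv",
                    "sample\tphenotype\ns1\tcase\ns2\tcase\ns3\tcontrol\ns4\tcontrol\n")
        ds = read_vcf(vcf, tab)
        assert list(ds.calls[:, 0]) == [HOM_A, HET, HOM_B, MISSING]
        assert (ds.markers[0].allele_a, ds.markers[0].allele_b) == ("A", "G")

    def test_multiallelic_record_skipped(self, tmp_path):
        recs = [
            "1\t100\tm1\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t0/0\t0/0\n",
            "1\t200\tm2\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/0\t0/0\t0/0\n",
            "1\t300\tm3\tC\tT\t.\t.\t.\tGT\t0/0\t0/0\t0/0\t0/0\n",
        ]
        vcf = write(tmp_path, "x.vcf", self.vcf_text(recs))
        tab = write(tmp_path, "ph.tsv",
                    "sample\tphenotype\ns1\tcase\ns2\tcase\ns3\tcontrol\ns4\tcontrol\n")
        with pytest.warns(UserWarning, match="non-biallelic"):
            ds = read_vcf(vcf, tab)
        assert [m.id for m in ds.markers] == ["m1", "m3"]

    def test_vcf_matches_equivalent_pedmap(self, tmp_path):
        recs = [
            "7\t100\tm1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t./.\n",
            "7\t250\tm2\tC\tT\t.\t.\t.\tGT\t1/1\t0/0\t0/1\t0/0\n",
        ]
        vcf = write(tmp_path, "x.vcf", self.vcf_text(recs))
        tab = write(tmp_path, "ph.tsv",
                    "sample\tphenotype\ns1\tcase\ns2\tcase\ns3\tcontrol\ns4\tcontrol\n")
        ds_v = read_vcf(vcf, tab)
        ped = write(
            tmp_path, "x.ped",
            "f s1 0 0 0 2 A A T T\nf s2 0 0 0 2 A G C C\n"
            "f s3 0 0 0 1 G G C T\nf s4 0 0 0 1 0 0 C C\n",
        )
        mp = write(tmp_path, "x.map", "7 m1 0 100\n7 m2 0 250\n")
        ds_p = read_pedmap(ped, mp)
        # m2's PED first-observed allele is T (ALT); compare phenotype-free codes
        assert np.array_equal(ds_v.calls[:, 0], ds_p.calls[:, 0])
        # m2: PED assigns allele_a=T so codes swap relative to REF/ALT
        assert ds_p.markers[1].allele_a == "T"
        assert list(ds_v.calls[:, 1]) == [HOM_B, HOM_A, HET, HOM_A]
        assert list(ds_p.calls[:, 1]) == [HOM_A, HOM_B, HET, HOM_B]

    def test_unlisted_sample_becomes_unknown(self, tmp_path):
        vcf = write(
            tmp_path, "x.vcf",
            self.vcf_text(["1\t100\tm1\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t0/0\t0/0\n"]),
        )
        tab = write(tmp_path, "ph.tsv", "sample\tphenotype\ns1\tcase\ns2\tcase\ns3\tcontrol\n")
        with pytest.warns(UserWarning, match="s4"):
            ds = read_vcf(vcf, tab)
        assert ds.samples[3].phenotype == "unknown"


class TestModelValidation:
    def test_chrom_names_are_opaque(self):
        m1 = Marker("a", "25", 100, "A", "G")
        m2 = Marker("b", "chr25", 50, "A", "G")
        # distinct chromosomes: no sort conflict even with decreasing positions
        ds = GenotypeDataset([Sample("s1")], [m1, m2], np.zeros((1, 2), dtype=np.int8))
        assert ds.chroms == ["25", "chr25"]

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="invalid genotype"):
            make_dataset([[5]])

    def test_same_alleles_rejected(self):
        with pytest.raises(ValueError, match="allele_a"):
            Marker("m", "1", 100, "A", "A")
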