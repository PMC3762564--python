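import numpy as np
import pytest

from rohmap.geno_io import HET, HOM_A, HOM_B, MISSING
from rohmap.ibd_mapping import (
    filter_by_controls,
    map_recessive,
    refine_by_identity,
    shared_roh_loci,
)
from rohmap.roh import ROHSegment, RohParams
from rohmap.simdata import simulate_cohort, study_config

from conftest import make_dataset


def seg(case, chrom, start, end, n=200):
    return ROHSegment(case, chrom, start, end, n)


class TestSharedLoci:
    def test_six_case_overlap_is_intersection(self):
        segs = {
            f"case{i}": [seg(f"case{i}", "25", 5_000_000 - i * 100_000, 7_000_000 + i * 50_000)]
            for i in range(1, 7)
        }
        loci = shared_roh_loci(segs)
        assert loci == [("25", (4_900_000, 7_050_000))]

    def test_missing_in_one_case_drops_chromosome(self):
        segs = {f"case{i}": [seg(f"case{i}", "25", 5_000_000, 7_000_000)] for i in range(1, 6)}
        segs["case6"] = [seg("case6", "13", 1_000_000, 3_000_000)]
        assert shared_roh_loci(segs) == []

    def test_single_case_passes_through(self):
        segs = {"case1": [seg("case1", "2", 100, 500), seg("case1", "3", 900, 1500)]}
        assert shared_roh_loci(segs) == [("2", (100, 500)), ("3", (900, 1500))]

    def test_study_simulation_emits_five_loci(self):
        from rohmap.roh import call_roh

        ds, truth = simulate_cohort(study_config(2))
        segs = {s.id: call_roh(ds, s) for s in ds.cases}
        loci = shared_roh_loci(segs)
        chroms = {c for c, _ in loci}
        assert {"6", "17", "21", "25", "35"} <= chroms
        assert len(loci) == 5


class TestRefineByIdentity:
    def base_dataset(self, extra_rows=None):
        # 6 cases identical hom across m4..m12; flanks m1..m3 / m13..m15 vary
        calls = np.zeros((6, 15), dtype=np.int8)
        calls[:, 3:12] = [HOM_A, HOM_B, HOM_A, HOM_A, HOM_B, HOM_A, HOM_B, HOM_B, HOM_A]
        if extra_rows is not None:
            for (r, c), v in extra_rows.items():
                calls[r, c] = v
        return make_dataset(calls, ["case"] * 6, spacing_bp=10_000)

    def test_interval_grows_over_identical_flanks(self):
        # all flanks hom_a and identical: interval extends to chromosome ends
        ds = self.base_dataset()
        locus = ("25", (ds.markers[3].pos_bp, ds.markers[11].pos_bp))
        cand = refine_by_identity(ds, locus)
        assert cand.refined_interval == (ds.markers[0].pos_bp, ds.markers[14].pos_bp)
        assert len(cand.shared_haplotype) == 15

    def test_opposite_homozygotes_trim_boundary(self):
        # marker m13 (index 12): case1 hom_a vs case2 hom_b blocks extension
        ds = self.base_dataset({(0, 12): HOM_A, (1, 12): HOM_B, (0, 2): HET})
        locus = ("25", (ds.markers[3].pos_bp, ds.markers[11].pos_bp))
        cand = refine_by_identity(ds, locus)
        assert cand.refined_interval == (ds.markers[3].pos_bp, ds.markers[11].pos_bp)

    def test_missing_inside_core_is_compatible(self):
        ds = self.base_dataset({(2, 6): MISSING, (0, 2): HET, (0, 12): HET})
        locus = ("25", (ds.markers[3].pos_bp, ds.markers[11].pos_bp))
        cand = refine_by_identity(ds, locus)
        assert cand.refined_interval == (ds.markers[3].pos_bp, ds.markers[11].pos_bp)
        # the shared allele at the missing-in-one-case marker is still called
        assert cand.shared_haplotype[ds.markers[6].id] == "A"

    def test_majority_identity_failure_discards(self):
        rows = {(0, j): HET for j in range(3, 12)}  # case1 het across the core
        ds = self.base_dataset(rows)
        locus = ("25", (ds.markers[3].pos_bp, ds.markers[11].pos_bp))
        cand = refine_by_identity(ds, locus)
        assert cand.refined_interval is None
        assert "identity fails" in cand.discarded_reason

    def test_interval_never_ends_on_het_or_missing(self):
        ds = self.base_dataset({(0, 11): MISSING, (1, 2): HET, (0, 12): HET})
        locus = ("25", (ds.markers[3].pos_bp, ds.markers[11].pos_bp))
        cand = refine_by_identity(ds, locus)
        # m12 (missing in case1) cannot terminate the interval
        assert cand.refined_interval == (ds.markers[3].pos_bp, ds.markers[10].pos_bp)


class TestFilterByControls:
    def locus_and_dataset(self, control_calls):
        calls = np.concatenate(
            [np.zeros((6, 9), dtype=np.int8), np.array(control_calls, dtype=np.int8)]
        )
        ds = make_dataset(calls, ["case"] * 6 + ["control"] * len(control_calls),
                          spacing_bp=10_000)
        locus = ("25", (ds.markers[0].pos_bp, ds.markers[8].pos_bp))
        return filter_by_controls(refine_by_identity(ds, locus), ds), ds

    def test_carrier_controls_exclude_locus(self):
        cand, _ = self.locus_and_dataset(
            [[HOM_A] * 9, [HOM_A] * 9, [HOM_B] * 9]
        )
        assert cand.control_carriers == ["s7", "s8"]
        assert cand.retained is False

    def test_no_carrier_retains(self):
        cand, _ = self.locus_and_dataset(
            [[HOM_B] * 9, [HET] * 9, [HOM_B] * 9]
        )
        assert cand.control_carriers == []
        assert cand.retained is True

    def test_het_anywhere_breaks_carriage(self):
        row = [HOM_A] * 9
        row[4] = HET
        cand, _ = self.locus_and_dataset([row])
        assert cand.control_carriers == []

    def test_missing_calls_compatible_with_carriage(self):
        row = [HOM_A] * 9
        row[4] = MISSING
        cand, _ = self.locus_and_dataset([row])
        assert cand.control_carriers == ["s7"]


class TestMapRecessive:
    def test_study_scenario_retains_only_planted_locus(self):
        ds, truth = simulate_cohort(study_config(1))
        ranked, report = map_recessive(ds)
        retained = [c for c in ranked if c.retained]
        assert len(retained) == 1
        cand = retained[0]
        assert cand.chrom == truth.disease_locus.chrom
        lo, hi = cand.refined_interval
        t0, t1 = truth.disease_marker_span
        idx = [
            i for i, m in enumerate(ds.markers)
            if m.chrom == cand.chrom and lo <= m.pos_bp <= hi
        ]
        assert abs(idx[0] - t0) <= 2 and abs(idx[-1] - t1) <= 2
        # excluded loci name their carriers in the report
        excluded = report[~report.RETAINED & (report.NOTE == "")]
        assert (excluded.CONTROL_CARRIERS != "").all()

    def test_retained_locus_ranked_first_and_peak_overlap_consistent(self):
        from rohmap.assoc import gwas, top_hits

        ds, _ = simulate_cohort(study_config(1))
        ranked, _ = map_recessive(ds)
        assert ranked[0].retained
        # top_assoc_overlap agrees with an independent peak count
        peaks = top_hits(gwas(ds))
        for cand in ranked:
            if cand.refined_interval is None:
                continue
            lo, hi = cand.refined_interval
            expected = (
                (peaks.CHR == cand.chrom) & (peaks.BP >= lo) & (peaks.BP <= hi)
            ).sum()
            assert cand.top_assoc_overlap == expected

    def test_invariant_to_sample_order(self):
        ds, _ = simulate_cohort(study_config(6))
        ranked, _ = map_recessive(ds)
        order = [s.id for s in ds.samples]
        shuffled = ds.subset_samples(order[::-1])
        ranked2, _ = map_recessive(shuffled)
        assert [(c.chrom, c.refined_interval, c.retained) for c in ranked] == [
            (c.chrom, c.refined_interval, c.retained) for c in ranked2
        ]

    def test_null_scenario_retains_nothing(self):
        from rohmap.simdata import null_config

        n_zero = 0
        for s in range(25):
            ds, _ = simulate_cohort(null_config(s))
            ranked, _ = map_recessive(ds)
            if not any(c.retained for c in ranked):
                n_zero += 1
        assert n_zero >= 24
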