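"""Synthetic inbred cohorts and transcripts with known ground truth.

The cohort generator emulates the population structure that makes
homozygosity mapping work in a breed isolate: all samples descend from a
small pool of founder haplotypes (default 8), so long stretches of the
genome are homozygous identical by descent.  Within a planted *disease
locus* every case carries two copies of one designated founder
haplotype and every control at most one; *decoy loci* force a shared
homozygous haplotype into all cases **and** one or more listed controls,
reproducing the scenario where most cross-case shared homozygous blocks
are breed-wide autozygosity rather than the causal interval.

Sample gametes are mosaics of founder haplotypes with crossovers from a
Haldane (no-interference) map at ``recomb_rate`` cM/Mb; marker positions
are uniformly spaced with jitter; genotyping error (hom<->het flips) and
missingness are injected last.  Disease/decoy intervals are painted onto
the sampled gametes post hoc rather than produced by explicit pedigree
coalescence — this trades realism for exact control of the planted
truth, which :class:`SimTruth` records for parameter-recovery tests.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rohmap.geno_io import (
    GenotypeDataset,
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    Marker,
    Sample,
)
from rohmap.seqann import Transcript

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class PlantedLocus:
    chrom: str
    start_bp: int
    end_bp: int
    # controls forced to carry the shared haplotype homozygously (decoys)
    carrier_controls: tuple[str, ...] = ()


@dataclass
class SimConfig:
    """Study-condition parameters for cohort simulation.

    Defaults reproduce the mapping-cohort conditions: 6 cases and 3
    controls drawn from 8 founder haplotypes, array-like marker density,
    full penetrance, no phenocopies, no genotyping noise.
    """

    seed: int
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("25", 25_000_000)]
    )
    n_snp: dict[str, int] | int = 2000
    n_founder_haplotypes: int = 8
    n_cases: int = 6
    n_controls: int = 3
    disease_locus: PlantedLocus | None = None
    decoy_shared_loci: list[PlantedLocus] = field(default_factory=list)
    recomb_rate_cM_per_Mb: float = 1.0
    genotype_missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0

    def __post_init__(self) -> None:
        chrom_len = dict(self.chromosomes)
        for rate in (self.genotype_missing_rate, self.genotype_error_rate,
                     self.penetrance, self.phenocopy_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.n_founder_haplotypes < 1:
            raise ValueError("need at least one founder haplotype")
        planted = list(self.decoy_shared_loci)
        if self.disease_locus is not None:
            planted.append(self.disease_locus)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for loc in planted:
            if loc.chrom not in chrom_len:
                raise ValueError(f"planted locus on unknown chromosome {loc.chrom}")
            if not 1 <= loc.start_bp <= loc.end_bp <= chrom_len[loc.chrom]:
                raise ValueError(
                    f"locus {loc.chrom}:{loc.start_bp}-{loc.end_bp} outside chromosome"
                )
            by_chrom.setdefault(loc.chrom, []).append((loc.start_bp, loc.end_bp))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (_s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"planted intervals overlap on chromosome {chrom}")
        for chrom, _ in self.chromosomes:
            if self.snp_count(chrom) < 2:
                raise ValueError("need n_snp >= 2 per chromosome")

    def snp_count(self, chrom: str) -> int:
        if isinstance(self.n_snp, dict):
            return self.n_snp[chrom]
        return int(self.n_snp)


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated cohort."""

    disease_locus: PlantedLocus | None
    disease_marker_span: tuple[int, int] | None  # global marker index range, inclusive
    decoy_loci: list[PlantedLocus]
    decoy_marker_spans: list[tuple[int, int]]
    carrier_status: dict[str, int]  # copies of the disease haplotype per sample
    affected: dict[str, bool]
    founder_freqs: dict[str, np.ndarray]


def _marker_positions(rng: np.random.Generator, length: int, m: int) -> np.ndarray:
    """Uniform spacing with jitter, strictly increasing within [1, length]."""
    base = np.linspace(1, length, m)
    jitter = rng.uniform(-0.3, 0.3, m) * (length / m)
    pos = np.clip(np.round(base + jitter), 1, length).astype(np.int64)
    for j in range(1, m):
        if pos[j] <= pos[j - 1]:
            pos[j] = pos[j - 1] + 1
    return pos


def _haldane_gamete(
    rng: np.random.Generator,
    founders: np.ndarray,  # (n_founders, m) 0/1 alleles
    pos: np.ndarray,
    length: int,
    rate_per_bp: float,
) -> np.ndarray:
    """One gamete as a founder-haplotype mosaic (Haldane crossovers)."""
    n_f = founders.shape[0]
    if n_f == 1 or rate_per_bp <= 0:
        if rate_per_bp <= 0:
            return founders[rng.integers(n_f)].copy()
    # crossover points: exponential gaps along the chromosome
    breaks = []
    x = rng.exponential(1.0 / rate_per_bp)
    while x < length:
        breaks.append(x)
        x += rng.exponential(1.0 / rate_per_bp)
    n_seg = len(breaks) + 1
    chosen = np.empty(n_seg, dtype=np.int64)
    chosen[0] = rng.integers(n_f)
    for k in range(1, n_seg):  # switch to a *different* founder at each crossover
        chosen[k] = (chosen[k - 1] + 1 + rng.integers(n_f - 1)) % n_f if n_f > 1 else 0
    seg_idx = np.searchsorted(np.array(breaks), pos)
    return founders[chosen[seg_idx], np.arange(len(pos))].copy()


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate a case/control cohort with planted IBD structure.

    Returns the dataset and the :class:`SimTruth` describing exactly
    what was planted (marker spans are global marker indices).
    """
    rng = np.random.default_rng(cfg.seed)
    sample_ids = [f"case{i + 1}" for i in range(cfg.n_cases)] + [
        f"ctrl{i + 1}" for i in range(cfg.n_controls)
    ]
    case_ids = sample_ids[: cfg.n_cases]
    control_ids = sample_ids[cfg.n_cases :]
    n_samples = len(sample_ids)
    rate_per_bp = cfg.recomb_rate_cM_per_Mb / 100.0 / 1e6
    disease_founder = 0  # designated risk haplotype id

    markers: list[Marker] = []
    per_chrom_gametes: list[np.ndarray] = []
    founder_freqs: dict[str, np.ndarray] = {}
    chrom_offsets: dict[str, int] = {}
    disease_span: tuple[int, int] | None = None
    carrier_status: dict[str, int] = {sid: 0 for sid in sample_ids}

    for chrom, length in cfg.chromosomes:
        m = cfg.snp_count(chrom)
        pos = _marker_positions(rng, length, m)
        freqs = rng.uniform(0.1, 0.9, m)
        founder_freqs[chrom] = freqs
        founders = (rng.uniform(size=(cfg.n_founder_haplotypes, m)) < freqs).astype(np.int8)
        gametes = np.empty((n_samples, 2, m), dtype=np.int8)
        for si in range(n_samples):
            for g in range(2):
                gametes[si, g] = _haldane_gamete(rng, founders, pos, length, rate_per_bp)

        def plant_boundary(span: np.ndarray) -> None:
            # A planted interval ends at a recombination breakpoint: at the
            # marker immediately flanking each side, one case carries a
            # discordant haplotype, so the shared segment has a well-defined
            # marker-resolution boundary (a single het; tolerated by the
            # window criterion but a genuine identity break).
            idx = np.where(span)[0]
            for j in (idx[0] - 1, idx[-1] + 1):
                if 0 <= j < span.size:
                    gametes[0, 0, j], gametes[0, 1, j] = 0, 1

        # paint decoys: all cases plus listed controls, homozygous.  The
        # carrier controls' segments are painted with a margin around the
        # shared core: a real carrier's autozygous segment does not end at
        # the exact boundary of the cross-case intersection.
        margin = 500_000
        for loc in (l for l in cfg.decoy_shared_loci if l.chrom == chrom):
            span = (pos >= loc.start_bp) & (pos <= loc.end_bp)
            wide = (pos >= loc.start_bp - margin) & (pos <= loc.end_bp + margin)
            hap = founders[disease_founder, span]
            hap_wide = founders[disease_founder, wide]
            for si, sid in enumerate(sample_ids):
                if sid in case_ids:
                    gametes[si, 0, span] = hap
                    gametes[si, 1, span] = hap
                elif sid in loc.carrier_controls:
                    gametes[si, 0, wide] = hap_wide
                    gametes[si, 1, wide] = hap_wide
            plant_boundary(span)

        # paint the disease locus: cases homozygous, controls at most one copy
        if cfg.disease_locus is not None and cfg.disease_locus.chrom == chrom:
            loc = cfg.disease_locus
            span = (pos >= loc.start_bp) & (pos <= loc.end_bp)
            hap = founders[disease_founder, span]
            for si, sid in enumerate(sample_ids):
                if sid in case_ids:
                    gametes[si, 0, span] = hap
                    gametes[si, 1, span] = hap
                elif np.array_equal(gametes[si, 0, span], hap) and np.array_equal(
                    gametes[si, 1, span], hap
                ):
                    # controls carry at most one copy: break accidental IBD2
                    gametes[si, 1, span] = 1 - hap
            plant_boundary(span)
            span_idx = np.where(span)[0]
            disease_span = (
                len(markers) + int(span_idx[0]),
                len(markers) + int(span_idx[-1]),
            )
            for si, sid in enumerate(sample_ids):
                carrier_status[sid] = sum(
                    np.array_equal(gametes[si, g, span], hap) for g in range(2)
                )

        chrom_offsets[chrom] = len(markers)
        for j in range(m):
            markers.append(
                Marker(id=f"snp_{chrom}_{j + 1}", chrom=chrom, pos_bp=int(pos[j]),
                       allele_a="A", allele_b="G")
            )
        per_chrom_gametes.append(gametes)

    allg = np.concatenate(per_chrom_gametes, axis=2)
    calls = (allg[:, 0, :] + allg[:, 1, :]).astype(np.int8)  # 0/1/2 -> HOM_A/HET/HOM_B

    # phenotype assignment (penetrance / phenocopies only matter with a locus)
    affected: dict[str, bool] = {}
    for sid in sample_ids:
        if cfg.disease_locus is None:
            affected[sid] = sid in case_ids
        elif carrier_status[sid] == 2:
            affected[sid] = bool(rng.uniform() < cfg.penetrance)
        else:
            affected[sid] = bool(rng.uniform() < cfg.phenocopy_rate)

    # genotyping noise, injected last
    if cfg.genotype_error_rate > 0:
        flip = rng.uniform(size=calls.shape) < cfg.genotype_error_rate
        target_hom = np.where(rng.uniform(size=calls.shape) < 0.5, HOM_A, HOM_B)
        new = calls.copy()
        new[flip & (calls != HET)] = HET
        het_flip = flip & (calls == HET)
        new[het_flip] = target_hom[het_flip].astype(np.int8)
        calls = new
    if cfg.genotype_missing_rate > 0:
        miss = rng.uniform(size=calls.shape) < cfg.genotype_missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)

    # canonicalize to the first-observed-allele gauge: PED text carries no
    # allele metadata, so a reader assigns allele_a by first observation;
    # emitting that gauge makes write -> read the identity on codes.
    markers = list(markers)
    for mi in range(calls.shape[1]):
        col = calls[:, mi]
        obs = col[col != MISSING]
        if obs.size and obs[0] == HOM_B:
            col[col == HOM_A] = 3
            col[col == HOM_B] = HOM_A
            col[col == 3] = HOM_B
            mk = markers[mi]
            markers[mi] = Marker(mk.id, mk.chrom, mk.pos_bp, mk.allele_b, mk.allele_a)

    samples = []
    for sid in sample_ids:
        if cfg.disease_locus is not None and (cfg.penetrance < 1 or cfg.phenocopy_rate > 0):
            pheno = "case" if affected[sid] else "control"
        else:
            pheno = "case" if sid in case_ids else "control"
        samples.append(Sample(id=sid, phenotype=pheno))

    decoy_spans = []
    for loc in cfg.decoy_shared_loci:
        off = chrom_offsets[loc.chrom]
        m = cfg.snp_count(loc.chrom)
        posc = np.array([markers[off + j].pos_bp for j in range(m)])
        ci = np.where((posc >= loc.start_bp) & (posc <= loc.end_bp))[0]
        decoy_spans.append((int(off + ci[0]), int(off + ci[-1])))

    dataset = GenotypeDataset(samples, markers, calls)
    truth = SimTruth(
        disease_locus=cfg.disease_locus,
        disease_marker_span=disease_span,
        decoy_loci=list(cfg.decoy_shared_loci),
        decoy_marker_spans=decoy_spans,
        carrier_status=carrier_status,
        affected=affected,
        founder_freqs=founder_freqs,
    )
    return dataset, truth


def study_config(seed: int) -> SimConfig:
    """The default "study" scenario: the mapping conditions at desk scale.

    Five 25-Mb chromosomes at 2,000 SNPs each (10k markers, 80 SNPs/Mb —
    array-like density), 6 cases / 3 controls from 8 founder haplotypes,
    one 2.09-Mb disease locus on chromosome 25 and four decoy shared
    homozygous loci (chromosomes 6/17/21/35, sizes ~2.5–3 Mb) each
    carried homozygously by at least one control.
    """
    return SimConfig(
        seed=seed,
        chromosomes=[(c, 25_000_000) for c in ("6", "17", "21", "25", "35")],
        n_snp=2000,
        disease_locus=PlantedLocus("25", 10_000_000, 12_090_000),
        decoy_shared_loci=[
            PlantedLocus("6", 8_000_000, 10_940_000, carrier_controls=("ctrl1", "ctrl2")),
            PlantedLocus("17", 5_000_000, 7_960_000, carrier_controls=("ctrl1", "ctrl2")),
            PlantedLocus("21", 12_000_000, 14_730_000, carrier_controls=("ctrl2",)),
            PlantedLocus("35", 6_000_000, 8_500_000, carrier_controls=("ctrl1", "ctrl3")),
        ],
    )


def null_config(seed: int, n_founder_haplotypes: int = 24) -> SimConfig:
    """A no-locus scenario with outbred founders (no planted intervals)."""
    return SimConfig(
        seed=seed,
        chromosomes=[("1", 25_000_000), ("2", 25_000_000)],
        n_snp=2000,
        n_founder_haplotypes=n_founder_haplotypes,
        disease_locus=None,
    )


def simulate_transcript(
    n_codons: int, next_stop_offset_nt: int, utr_len: int, seed: int
) -> Transcript:
    """Random transcript whose stop-loss consequence is fully determined.

    The CDS has ``n_codons`` coded residues (ATG first) and ends in TGA.
    The 3'UTR contains no in-frame stop codon before
    ``next_stop_offset_nt`` bases past the TGA and an in-frame TAG
    exactly there, so a stop-loss at the TGA extends the protein by
    exactly ``next_stop_offset_nt/3 + 1`` residues.  When the UTR is
    long enough an AATAAA polyadenylation signal is placed 37 bp
    downstream of that alternative stop.
    """
    if next_stop_offset_nt % 3:
        raise ValueError("next_stop_offset_nt must be a multiple of 3")
    if next_stop_offset_nt < 0 or n_codons < 1:
        raise ValueError("n_codons >= 1 and next_stop_offset_nt >= 0 required")
    if utr_len < next_stop_offset_nt + 3:
        raise ValueError(
            f"utr_len {utr_len} too short for a stop {next_stop_offset_nt} nt downstream"
        )
    rng = np.random.default_rng(seed)
    sense = list(_SENSE_CODONS)
    codons = ["ATG"] + [sense[rng.integers(len(sense))] for _ in range(n_codons - 1)]
    cds = "".join(codons) + "TGA"

    n_free = next_stop_offset_nt // 3
    head = "".join(sense[rng.integers(len(sense))] for _ in range(n_free)) + "TAG"
    tail_len = utr_len - len(head)
    tail = "".join("ACGT"[rng.integers(4)] for _ in range(tail_len))
    polya_pos: int | None = None
    if tail_len >= 43:  # room for the signal 37 bp past the alternative stop
        tail = tail[:37] + "AATAAA" + tail[43:]
        polya_pos = len(cds) + len(head) + 37 + 1  # 1-based within the mRNA

    return Transcript(
        id=f"sim_tx_{n_codons}aa_ext{n_free + 1}",
        mrna_seq=cds + head + tail,
        cds_start=1,
        cds_end=len(cds),
        polya_signal_pos=polya_pos,
    )
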