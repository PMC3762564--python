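"""Cross-case shared homozygosity mapping with control exclusion.

The mapping logic for a fully penetrant autosomal recessive trait
inherited identical by descent: every affected individual must be
homozygous for the same ancestral haplotype across the disease locus,
and no aged unaffected control may be.  The pipeline therefore

1. intersects per-case ROH segments into *shared loci* — maximal
   intervals covered by at least one segment of every case, on
   chromosomes where every case has a segment;
2. *refines* each locus by haplotype identity: verifies all cases are
   homozygous for the same allele at every informative marker, trims
   around identity violations, then extends the interval outward while
   identity continues to hold (refined intervals can therefore be
   smaller or larger than the raw ROH consensus);
3. *excludes* loci whose shared haplotype is carried homozygously by
   any control — under full penetrance an aged unaffected control
   cannot be homozygous for the causal haplotype;
4. ranks surviving candidates by overlap with the peak association
   markers, then by size.

Missing calls are treated as compatible with identity throughout (a
no-call is not evidence against the shared haplotype), but an interval
never starts or ends on a marker that is missing or heterozygous in
any case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rohmap.assoc import gwas, top_hits
from rohmap.geno_io import GenotypeDataset, HET, HOM_A, HOM_B, MISSING
from rohmap.roh import ROHSegment, RohParams, call_roh, round_mb

logger = logging.getLogger(__name__)


@dataclass
class CandidateLocus:
    """A cross-case shared homozygous interval and its fate.

    ``roh_core`` is the raw intersection of case ROH; ``refined_interval``
    the interval after haplotype-identity refinement (it may shrink or
    grow).  ``shared_haplotype`` maps marker id -> shared allele (None
    where every case is missing).  ``retained`` is True iff no control
    is homozygous for the shared haplotype.
    """

    chrom: str
    roh_core: tuple[int, int]
    refined_interval: tuple[int, int] | None = None
    shared_haplotype: dict[str, str | None] = field(default_factory=dict)
    case_support: dict[str, bool] = field(default_factory=dict)
    control_carriers: list[str] = field(default_factory=list)
    retained: bool = False
    discarded_reason: str | None = None
    top_assoc_overlap: int = 0

    @property
    def core_size_mb(self) -> float:
        return round_mb(self.roh_core[1] - self.roh_core[0] + 1)

    @property
    def refined_size_mb(self) -> float | None:
        if self.refined_interval is None:
            return None
        return round_mb(self.refined_interval[1] - self.refined_interval[0] + 1)


def shared_roh_loci(
    segments_per_case: dict[str, list[ROHSegment]]
) -> list[tuple[str, tuple[int, int]]]:
    """Maximal intervals covered by >= 1 ROH segment of *every* case.

    Chromosomes where any case lacks a segment are dropped outright.
    Returns ``(chrom, (start_bp, end_bp))`` in chromosome/position order.
    """
    if len(segments_per_case) < 2:
        # intersection of one case is its own segment list
        out = []
        for segs in segments_per_case.values():
            out.extend((s.chrom, (s.start_bp, s.end_bp)) for s in segs)
        return out
    per_case_chroms = [
        {s.chrom for s in segs} for segs in segments_per_case.values()
    ]
    common = set.intersection(*per_case_chroms) if per_case_chroms else set()
    loci: list[tuple[str, tuple[int, int]]] = []
    chrom_order: dict[str, int] = {}
    for segs in segments_per_case.values():
        for s in segs:
            chrom_order.setdefault(s.chrom, len(chrom_order))
    for chrom in sorted(common, key=chrom_order.get):
        shared = None  # list of disjoint sorted intervals
        for segs in segments_per_case.values():
            ivs = sorted(
                (s.start_bp, s.end_bp) for s in segs if s.chrom == chrom
            )
            merged = _merge(ivs)
            shared = merged if shared is None else _intersect(shared, merged)
        loci.extend((chrom, iv) for iv in (shared or []))
    return loci


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _identity_status(col: np.ndarray) -> tuple[bool, str | int | None]:
    """Identity check for one marker across case rows.

    Returns (ok, shared_code) where shared_code is HOM_A/HOM_B, or None
    when every case is missing (compatible but uninformative).  A het in
    any case, or two cases homozygous for opposite alleles, violates.
    """
    if (col == HET).any():
        return False, None
    have_a = (col == HOM_A).any()
    have_b = (col == HOM_B).any()
    if have_a and have_b:
        return False, None
    if have_a:
        return True, HOM_A
    if have_b:
        return True, HOM_B
    return True, None


def refine_by_identity(
    dataset: GenotypeDataset,
    locus: tuple[str, tuple[int, int]],
    cases: list[str] | None = None,
) -> CandidateLocus:
    """Refine a shared-ROH locus by exact haplotype identity.

    Starting from the core, markers violating identity (any case het, or
    cases homozygous for opposite alleles) trim the interval to the
    largest violation-free sub-interval containing the majority of core
    markers; the interval is then extended marker-by-marker in both
    directions while identity holds.  Terminal markers must be fully
    observed homozygous in every case.  A locus whose core violates
    identity at more than half its markers is discarded.
    """
    chrom, (core_start, core_end) = locus
    case_ids = cases or [s.id for s in dataset.cases]
    rows = [dataset.sample_index(c) for c in case_ids]
    sl = dataset.chrom_slice(chrom)
    pos = dataset.positions(chrom)
    calls = dataset.calls[np.ix_(rows, range(sl.start, sl.stop))]
    m = len(pos)

    core_idx = np.where((pos >= core_start) & (pos <= core_end))[0]
    out = CandidateLocus(chrom=chrom, roh_core=(core_start, core_end),
                         case_support={c: True for c in case_ids})
    if core_idx.size == 0:
        out.discarded_reason = "no markers in core"
        return out

    ok = np.empty(m, dtype=bool)
    code = np.full(m, MISSING, dtype=np.int8)
    for j in range(m):
        o, c = _identity_status(calls[:, j])
        ok[j] = o
        code[j] = MISSING if c is None else c

    core_ok = ok[core_idx]
    n_viol = int((~core_ok).sum())
    if n_viol > 0.5 * core_idx.size:
        out.discarded_reason = (
            f"haplotype identity fails at {n_viol}/{core_idx.size} core markers"
        )
        logger.info("locus %s:%d-%d discarded: %s", chrom, core_start, core_end,
                    out.discarded_reason)
        return out

    # largest violation-free run of core markers (ties: containing most of core
    # resolves to the longest; first on further tie)
    best: tuple[int, int] | None = None
    start = None
    for k, good in enumerate(core_ok):
        if good and start is None:
            start = k
        elif not good and start is not None:
            if best is None or (k - 1 - start) > (best[1] - best[0]):
                best = (start, k - 1)
            start = None
    if start is not None and (best is None or (len(core_ok) - 1 - start) > (best[1] - best[0])):
        best = (start, len(core_ok) - 1)
    if best is None:
        out.discarded_reason = "no violation-free core run"
        return out
    lo = int(core_idx[best[0]])
    hi = int(core_idx[best[1]])

    # extend outward while identity holds
    while lo - 1 >= 0 and ok[lo - 1]:
        lo -= 1
    while hi + 1 < m and ok[hi + 1]:
        hi += 1

    # interval must not start/end on a het or missing marker in any case
    def fully_hom(j: int) -> bool:
        return bool(np.all((calls[:, j] == HOM_A) | (calls[:, j] == HOM_B))) and ok[j]

    while lo <= hi and not fully_hom(lo):
        lo += 1
    while hi >= lo and not fully_hom(hi):
        hi -= 1
    if lo > hi:
        out.discarded_reason = "no fully-observed homozygous marker in interval"
        return out

    out.refined_interval = (int(pos[lo]), int(pos[hi]))
    markers = dataset.markers[sl]
    hap: dict[str, str | None] = {}
    for j in range(lo, hi + 1):
        mk = markers[j]
        if code[j] == HOM_A:
            hap[mk.id] = mk.allele_a
        elif code[j] == HOM_B:
            hap[mk.id] = mk.allele_b
        else:
            hap[mk.id] = None
    out.shared_haplotype = hap
    return out


def filter_by_controls(
    locus: CandidateLocus, dataset: GenotypeDataset, controls: list[str] | None = None,
    max_carrier_controls: int = 0,
) -> CandidateLocus:
    """Mark control carriers of the shared haplotype and set retention.

    A control *carries* the locus iff it is homozygous for the shared
    allele at every informative marker of the refined interval (missing
    calls compatible; a het anywhere, or homozygosity for the opposite
    allele, breaks carriage).  Under the recessive model the locus is
    retained iff the carrier count does not exceed
    ``max_carrier_controls`` (default 0 — exclusion is absolute; raise
    it only to explore incomplete penetrance).
    """
    if locus.refined_interval is None:
        locus.retained = False
        return locus
    control_ids = controls or [s.id for s in dataset.controls]
    sl = dataset.chrom_slice(locus.chrom)
    markers = dataset.markers[sl]
    idx_by_id = {mk.id: sl.start + j for j, mk in enumerate(markers)}
    carriers = []
    for cid in control_ids:
        row = dataset.sample_index(cid)
        carrier = True
        for mid, allele in locus.shared_haplotype.items():
            if allele is None:
                continue
            mk = dataset.markers[idx_by_id[mid]]
            call = dataset.calls[row, idx_by_id[mid]]
            if call == MISSING:
                continue
            hom_code = HOM_A if allele == mk.allele_a else HOM_B
            if call != hom_code:
                carrier = False
                break
        if carrier:
            carriers.append(cid)
    locus.control_carriers = carriers
    locus.retained = len(carriers) <= max_carrier_controls
    return locus


def map_recessive(
    dataset: GenotypeDataset,
    params: RohParams | None = None,
    max_carrier_controls: int = 0,
) -> tuple[list[CandidateLocus], pd.DataFrame]:
    """Full recessive-mapping pipeline: association + shared ROH + exclusion.

    Runs the allelic association scan, calls ROH per case, intersects
    them into shared loci, refines each by haplotype identity, excludes
    loci carried by controls, and ranks the survivors by the number of
    peak-association markers they contain, then by refined size.

    Returns the ranked retained loci (first) followed by excluded and
    discarded loci, plus a per-locus report table (start, end and size
    before/after refinement, named control carriers, inclusion verdict).
    An empty retained set is a valid outcome, not an error.
    """
    if len(dataset.cases) < 1 or len(dataset.controls) < 1:
        raise ValueError("map_recessive requires cases and controls")
    params = params or RohParams()
    assoc = gwas(dataset)
    peaks = top_hits(assoc)
    segments = {s.id: call_roh(dataset, s, params) for s in dataset.cases}
    loci = shared_roh_loci(segments)
    out: list[CandidateLocus] = []
    for locus in loci:
        cand = refine_by_identity(dataset, locus)
        if cand.refined_interval is not None:
            filter_by_controls(cand, dataset, max_carrier_controls=max_carrier_controls)
            lo, hi = cand.refined_interval
            cand.top_assoc_overlap = int(
                ((peaks["CHR"] == cand.chrom) & (peaks["BP"] >= lo) & (peaks["BP"] <= hi)).sum()
            )
        out.append(cand)
    ranked = sorted(
        out,
        key=lambda c: (
            not c.retained,
            -c.top_assoc_overlap,
            -(c.refined_size_mb or 0.0),
        ),
    )
    report = pd.DataFrame(
        {
            "CHR": [c.chrom for c in ranked],
            "START": [c.roh_core[0] for c in ranked],
            "END": [c.roh_core[1] for c in ranked],
            "SIZE_MB": [c.core_size_mb for c in ranked],
            "REFINED_START": [
                c.refined_interval[0] if c.refined_interval else pd.NA for c in ranked
            ],
            "REFINED_END": [
                c.refined_interval[1] if c.refined_interval else pd.NA for c in ranked
            ],
            "REFINED_SIZE_MB": [c.refined_size_mb for c in ranked],
            "TOP_ASSOC_SNPS": [c.top_assoc_overlap for c in ranked],
            "CONTROL_CARRIERS": [",".join(c.control_carriers) for c in ranked],
            "RETAINED": [c.retained for c in ranked],
            "NOTE": [c.discarded_reason or "" for c in ranked],
        }
    )
    return ranked, report
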