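"""Runs-of-homozygosity detection by the sliding-window method.

A window of ``window_snp`` consecutive SNPs is *homozygous* if it
contains at most ``window_max_het`` heterozygous and at most
``window_max_missing`` missing calls.  Each SNP is scored with the
fraction of overlapping windows that are homozygous; SNPs with a
fraction >= ``snp_hit_threshold`` form candidate runs.  Runs are split
at inter-SNP gaps above ``seg_max_gap_kb``, trimmed so both terminal
SNPs are confidently homozygous (non-missing, non-het), and kept only
if they satisfy all three segment criteria: minimum length
``seg_min_kb``, minimum SNP count ``seg_min_snp``, and maximum mean
density ``seg_max_density_kb_per_snp`` (segment kb per SNP).

Defaults reproduce the standard array-scale parameterization: window
150 SNPs / 1 het / 5 missing, threshold 0.05; segments >= 1,000 kb,
>= 150 SNPs, <= 50 kb/SNP.  Windows are defined by SNP count only; the
1,000-kb window length is recorded in :class:`RohParams` for
documentation but not enforced, matching the effective behavior of
PLINK 1.07 ``--homozyg`` with these flags.  Missing calls inside a run
are retained — they are not evidence of homozygosity but do not break
the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rohmap.geno_io import GenotypeDataset, HET, MISSING, Sample


@dataclass(frozen=True)
class RohParams:
    window_snp: int = 150
    window_kb: float = 1000.0  # documentation-only, not enforced
    window_max_het: int = 1
    window_max_missing: int = 5
    snp_hit_threshold: float = 0.05
    seg_min_kb: float = 1000.0
    seg_min_snp: int = 150
    seg_max_density_kb_per_snp: float = 50.0
    seg_max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        numeric = (
            self.window_snp, self.window_kb, self.window_max_het + 1,
            self.window_max_missing + 1, self.snp_hit_threshold,
            self.seg_min_kb, self.seg_min_snp,
            self.seg_max_density_kb_per_snp, self.seg_max_gap_kb,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("RohParams fields must be positive (het/missing >= 0)")
        if self.snp_hit_threshold > 1:
            raise ValueError("snp_hit_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one sample.

    ``start_bp``/``end_bp`` are the 1-based inclusive positions of the
    first and last SNP of the run; length is inclusive
    (``end - start + 1``).
    """

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snp: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1e3

    @property
    def length_mb(self) -> float:
        """Display size in Mb, rounded half-up to 2 decimals."""
        return round_mb(self.length_bp)

    @property
    def density_kb_per_snp(self) -> float:
        return self.length_kb / self.n_snp


def round_mb(length_bp: int) -> float:
    """bp -> Mb rounded half-up to 2 decimals (report convention)."""
    import decimal

    mb = decimal.Decimal(length_bp) / decimal.Decimal(1_000_000)
    return float(mb.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def window_hom_fraction(calls: np.ndarray, params: RohParams) -> np.ndarray:
    """Per-SNP fraction of overlapping windows that are homozygous.

    ``calls`` is one sample's genotype vector on one chromosome, ordered
    by position.  A chromosome shorter than ``window_snp`` is scanned as
    a single whole-chromosome window.  Near chromosome ends the
    denominator is the reduced number of windows that actually exist.
    """
    calls = np.asarray(calls)
    m = len(calls)
    if m == 0:
        return np.zeros(0)
    w = min(params.window_snp, m)
    is_het = (calls == HET).astype(np.int64)
    is_mis = (calls == MISSING).astype(np.int64)
    # sliding sums over all m - w + 1 windows
    kern = np.ones(w, dtype=np.int64)
    het_in_win = np.convolve(is_het, kern, mode="valid")
    mis_in_win = np.convolve(is_mis, kern, mode="valid")
    hom_win = (
        (het_in_win <= params.window_max_het)
        & (mis_in_win <= params.window_max_missing)
    ).astype(np.int64)
    # windows containing SNP j start at i in [max(0, j-w+1), min(j, m-w)]
    csum = np.concatenate([[0], np.cumsum(hom_win)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, m - w)
    n_win = hi - lo + 1
    n_hom = csum[hi + 1] - csum[lo]
    return n_hom / n_win


def _runs_from_hits(hits: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True values as (start, end) inclusive."""
    runs = []
    start = None
    for i, h in enumerate(hits):
        if h and start is None:
            start = i
        elif not h and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(hits) - 1))
    return runs


def call_roh(
    dataset: GenotypeDataset, sample: Sample | str, params: RohParams | None = None
) -> list[ROHSegment]:
    """Call ROH segments for one sample across every chromosome."""
    params = params or RohParams()
    sid = sample.id if isinstance(sample, Sample) else sample
    row = dataset.sample_index(sid)
    segments: list[ROHSegment] = []
    for chrom in dataset.chroms:
        sl = dataset.chrom_slice(chrom)
        calls = dataset.calls[row, sl]
        pos = dataset.positions(chrom)
        frac = window_hom_fraction(calls, params)
        hits = frac >= params.snp_hit_threshold
        for lo, hi in _runs_from_hits(hits):
            # split where the inter-SNP gap exceeds seg_max_gap_kb
            pieces: list[tuple[int, int]] = []
            start = lo
            for i in range(lo, hi):
                if (pos[i + 1] - pos[i]) / 1e3 > params.seg_max_gap_kb:
                    pieces.append((start, i))
                    start = i + 1
            pieces.append((start, hi))
            for a, b in pieces:
                # trim to terminal confidently-homozygous calls
                while a <= b and calls[a] in (HET, MISSING):
                    a += 1
                while b >= a and calls[b] in (HET, MISSING):
                    b -= 1
                if a > b:
                    continue
                n_snp = b - a + 1
                length_kb = (pos[b] - pos[a] + 1) / 1e3
                if (
                    length_kb >= params.seg_min_kb
                    and n_snp >= params.seg_min_snp
                    and length_kb / n_snp <= params.seg_max_density_kb_per_snp
                ):
                    segments.append(
                        ROHSegment(sid, chrom, int(pos[a]), int(pos[b]), n_snp)
                    )
    return segments


def roh_table(dataset: GenotypeDataset, params: RohParams | None = None):
    """ROH calls for every sample as a tidy DataFrame (one row per segment)."""
    import pandas as pd

    rows = []
    for s in dataset.samples:
        for seg in call_roh(dataset, s, params):
            rows.append(
                {
                    "IID": seg.sample_id,
                    "CHR": seg.chrom,
                    "POS1": seg.start_bp,
                    "POS2": seg.end_bp,
                    "NSNP": seg.n_snp,
                    "KB": seg.length_kb,
                    "DENSITY": seg.density_kb_per_snp,
                }
            )
    return pd.DataFrame(
        rows, columns=["IID", "CHR", "POS1", "POS2", "NSNP", "KB", "DENSITY"]
    )
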