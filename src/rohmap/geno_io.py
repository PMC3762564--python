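"""Genotype dataset model and PLINK-text / VCF ingestion.

The in-memory model is deliberately minimal: an ordered sample list, an
ordered marker list (grouped by chromosome, strictly sorted by physical
position within each chromosome), and a dense ``int8`` call matrix with
codes :data:`HOM_A`, :data:`HET`, :data:`HOM_B`, :data:`MISSING`.

Genotype codes are *relative to the per-marker allele pair*
``(allele_a, allele_b)``, assigned by first observation order in the
source file (PED carries no REF/ALT); nothing downstream assumes
``allele_a`` is the minor or the reference allele.  Coordinates are
1-based inclusive throughout, matching PLINK MAP convention.  Chromosome
names are opaque strings: ``"25"`` and ``"chr25"`` are distinct unless
``normalize_chrom=True`` strips a leading ``chr``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

# genotype codes in the call matrix
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")

_PHENO_FROM_PED = {"1": "control", "2": "case", "0": "unknown", "-9": "unknown"}
_PHENO_TO_PED = {"control": "1", "case": "2", "unknown": "0"}


class FormatError(ValueError):
    """Malformed or inconsistent genotype file content."""


@dataclass(frozen=True)
class Marker:
    """One biallelic SNP with its physical map position.

    ``allele_a``/``allele_b`` are the two observed alleles in first
    observation order; either may be ``None`` while unobserved
    (monomorphic or all-missing markers).
    """

    id: str
    chrom: str
    pos_bp: int
    allele_a: str | None = None
    allele_b: str | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.id}: pos_bp must be >= 1, got {self.pos_bp}")
        for al in (self.allele_a, self.allele_b):
            if al is not None and al not in _VALID_BASES:
                raise ValueError(f"marker {self.id}: invalid allele {al!r}")
        if self.allele_a is not None and self.allele_a == self.allele_b:
            raise ValueError(f"marker {self.id}: allele_a == allele_b == {self.allele_a!r}")


@dataclass(frozen=True)
class Sample:
    id: str
    phenotype: str = "unknown"  # case | control | unknown
    tags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.phenotype not in ("case", "control", "unknown"):
            raise ValueError(f"sample {self.id}: bad phenotype {self.phenotype!r}")


class GenotypeDataset:
    """Samples x markers diploid call matrix with a physical map.

    Parameters
    ----------
    samples
        Ordered samples; ids must be unique.
    markers
        Ordered markers.  Within each chromosome (in order of first
        appearance) positions must be strictly increasing; violations
        raise :class:`FormatError` rather than silently reordering.
    calls
        ``int8`` array of shape ``(n_samples, n_markers)`` over
        ``{HOM_A, HET, HOM_B, MISSING}``.
    """

    def __init__(self, samples: list[Sample], markers: list[Marker], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(markers)):
            raise ValueError(
                f"call matrix shape {calls.shape} != ({len(samples)}, {len(markers)})"
            )
        bad = ~np.isin(calls, (HOM_A, HET, HOM_B, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} invalid genotype codes in call matrix")
        ids = [s.id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        mids = [m.id for m in markers]
        if len(set(mids)) != len(mids):
            raise ValueError("duplicate marker ids")
        _validate_sorted(markers)
        self.samples = list(samples)
        self.markers = list(markers)
        self.calls = calls

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chroms(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.chrom, None)
        return list(seen)

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.id == sample_id:
                return i
        raise KeyError(sample_id)

    def samples_with_phenotype(self, phenotype: str) -> list[Sample]:
        return [s for s in self.samples if s.phenotype == phenotype]

    @property
    def cases(self) -> list[Sample]:
        return self.samples_with_phenotype("case")

    @property
    def controls(self) -> list[Sample]:
        return self.samples_with_phenotype("control")

    def chrom_slice(self, chrom: str) -> slice:
        """Column slice of the (contiguous) markers on one chromosome."""
        idx = [i for i, m in enumerate(self.markers) if m.chrom == chrom]
        if not idx:
            raise KeyError(chrom)
        if idx[-1] - idx[0] + 1 != len(idx):
            raise FormatError(f"markers of chromosome {chrom} are not contiguous")
        return slice(idx[0], idx[-1] + 1)

    def positions(self, chrom: str) -> np.ndarray:
        sl = self.chrom_slice(chrom)
        return np.array([m.pos_bp for m in self.markers[sl]], dtype=np.int64)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeDataset":
        rows = [self.sample_index(sid) for sid in sample_ids]
        return GenotypeDataset(
            [self.samples[i] for i in rows], self.markers, self.calls[rows]
        )


def _validate_sorted(markers: list[Marker]) -> None:
    last: dict[str, int] = {}
    done: set[str] = set()
    prev_chrom: str | None = None
    for m in markers:
        if m.chrom != prev_chrom:
            if m.chrom in done:
                raise FormatError(f"chromosome {m.chrom} appears in two separate blocks")
            if prev_chrom is not None:
                done.add(prev_chrom)
            prev_chrom = m.chrom
        if m.chrom in last and m.pos_bp <= last[m.chrom]:
            raise FormatError(
                f"marker {m.id} at {m.chrom}:{m.pos_bp} not strictly after "
                f"previous position {last[m.chrom]}"
            )
        last[m.chrom] = m.pos_bp


def _norm_chrom(chrom: str, normalize: bool) -> str:
    if normalize and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_pedmap(ped_path, map_path, normalize_chrom: bool = False) -> GenotypeDataset:
    """Read a PLINK text PED/MAP pair.

    The MAP file has 4 whitespace-separated columns (chrom, id, cM, bp);
    each PED row has 6 leading columns (family, sample, father, mother,
    sex, phenotype) followed by two allele fields per marker.  Phenotype
    column 6 maps 1 -> control, 2 -> case, 0/-9 -> unknown.  ``"0 0"``
    allele pairs are missing.  Per-marker allele_a/allele_b are assigned
    in first observation order; heterozygote allele order is normalized.

    Raises
    ------
    FormatError
        On a PED row whose length disagrees with the MAP marker count, on
        more than two distinct non-missing alleles at a marker, or on
        unsorted marker positions.
    """
    markers_raw: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
            chrom, mid, _cm, bp = parts
            markers_raw.append((_norm_chrom(chrom, normalize_chrom), mid, int(bp)))
    n_mark = len(markers_raw)

    samples: list[Sample] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_mark:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_mark} fields "
                    f"for {n_mark} markers, got {len(parts)}"
                )
            _fid, iid, _f, _m, _sex, pheno = parts[:6]
            if pheno not in _PHENO_FROM_PED:
                raise FormatError(f"{ped_path}:{lineno}: bad phenotype code {pheno!r}")
            samples.append(Sample(id=iid, phenotype=_PHENO_FROM_PED[pheno]))
            rows.append(parts[6:])

    calls = np.full((len(samples), n_mark), MISSING, dtype=np.int8)
    alleles: list[list[str]] = [[] for _ in range(n_mark)]
    for si, row in enumerate(rows):
        for mi in range(n_mark):
            a1, a2 = row[2 * mi], row[2 * mi + 1]
            if a1 == "0" or a2 == "0":
                if a1 != a2:
                    raise FormatError(
                        f"half-missing genotype {a1}/{a2} for sample "
                        f"{samples[si].id} at marker {markers_raw[mi][1]}"
                    )
                continue
            obs = alleles[mi]
            for al in (a1, a2):
                if al not in obs:
                    obs.append(al)
            if len(obs) > 2:
                raise FormatError(
                    f"marker {markers_raw[mi][1]}: more than two alleles observed ({obs})"
                )
            if a1 == a2:
                calls[si, mi] = HOM_A if a1 == obs[0] else HOM_B
            else:
                calls[si, mi] = HET

    markers = [
        Marker(
            id=mid,
            chrom=chrom,
            pos_bp=bp,
            allele_a=alleles[mi][0] if len(alleles[mi]) > 0 else None,
            allele_b=alleles[mi][1] if len(alleles[mi]) > 1 else None,
        )
        for mi, (chrom, mid, bp) in enumerate(markers_raw)
    ]
    return GenotypeDataset(samples, markers, calls)


def write_pedmap(dataset: GenotypeDataset, prefix) -> tuple[str, str]:
    """Write ``<prefix>.ped`` / ``<prefix>.map`` readable by :func:`read_pedmap`.

    Missing calls serialize as ``0 0``.  Unobserved alleles fall back to
    placeholder bases (``A``/``C``) so homozygous monomorphic markers stay
    representable; round-trip preserves genotype codes, marker order and
    phenotypes exactly.
    """
    prefix = str(prefix)
    ped_path, map_path = prefix + ".ped", prefix + ".map"
    with open(map_path, "w") as fh:
        for m in dataset.markers:
            fh.write(f"{m.chrom}\t{m.id}\t0\t{m.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for si, s in enumerate(dataset.samples):
            fields = [s.id, s.id, "0", "0", "0", _PHENO_TO_PED[s.phenotype]]
            for mi, m in enumerate(dataset.markers):
                a = m.allele_a or "A"
                b = m.allele_b or ("C" if a != "C" else "G")
                code = dataset.calls[si, mi]
                if code == HOM_A:
                    fields += [a, a]
                elif code == HET:
                    fields += [a, b]
                elif code == HOM_B:
                    fields += [b, b]
                else:
                    fields += ["0", "0"]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phenotype_table(path) -> dict[str, str]:
    """Read a TSV with header ``sample<TAB>phenotype`` into a dict."""
    table: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample", "phenotype"]:
            raise FormatError(f"{path}: expected header 'sample\\tphenotype'")
        for line in fh:
            if not line.strip():
                continue
            sid, pheno = line.rstrip("\n").split("\t")[:2]
            if pheno not in ("case", "control", "unknown"):
                raise FormatError(f"{path}: bad phenotype {pheno!r} for sample {sid}")
            table[sid] = pheno
    return table


def read_vcf(vcf_path, phenotype_table, normalize_chrom: bool = False) -> GenotypeDataset:
    """Read biallelic SNP records from a VCF v4.x into the dataset model.

    ``phenotype_table`` is a path to a TSV (``sample\\tphenotype``) or an
    already-parsed dict.  ``allele_a`` is REF and ``allele_b`` is ALT.
    Phased and unphased GT are both accepted; half-calls become missing
    (counted and logged); multi-allelic or non-SNP records are skipped
    with a warning.  Samples absent from the phenotype table are labeled
    unknown with a warning.
    """
    from cyvcf2 import VCF

    pheno = (
        phenotype_table
        if isinstance(phenotype_table, dict)
        else read_phenotype_table(phenotype_table)
    )
    vcf = VCF(str(vcf_path))
    samples = []
    for sid in vcf.samples:
        if sid not in pheno:
            warnings.warn(f"sample {sid} absent from phenotype table; labeled unknown")
        samples.append(Sample(id=sid, phenotype=pheno.get(sid, "unknown")))

    markers: list[Marker] = []
    columns: list[np.ndarray] = []
    n_skipped_records = 0
    n_half_calls = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1 \
                or rec.REF not in _VALID_BASES or alts[0] not in _VALID_BASES:
            warnings.warn(f"skipping non-biallelic-SNP record at {rec.CHROM}:{rec.POS}")
            n_skipped_records += 1
            continue
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for si, gt in enumerate(rec.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                if a1 >= 0 or a2 >= 0:  # half-call
                    n_half_calls += 1
                continue
            if a1 > 1 or a2 > 1:
                n_half_calls += 1
                continue
            col[si] = a1 + a2  # 0/0 -> HOM_A, 0/1 -> HET, 1/1 -> HOM_B
        markers.append(
            Marker(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=_norm_chrom(rec.CHROM, normalize_chrom),
                pos_bp=rec.POS,
                allele_a=rec.REF,
                allele_b=alts[0],
            )
        )
        columns.append(col)
    if n_skipped_records or n_half_calls:
        logger.info(
            "VCF import: skipped %d records, nulled %d half/invalid calls",
            n_skipped_records, n_half_calls,
        )
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeDataset(samples, markers, calls)


def relabel_phenotypes(dataset: GenotypeDataset, pheno: dict[str, str]) -> GenotypeDataset:
    """Return a copy of the dataset with phenotypes replaced from a mapping."""
    samples = [
        replace(s, phenotype=pheno.get(s.id, s.phenotype)) for s in dataset.samples
    ]
    return GenotypeDataset(samples, dataset.markers, dataset.calls)
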