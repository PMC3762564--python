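"""Genotype–phenotype segregation analysis of a candidate variant.

Cross-tabulates per-individual genotypes (hom_ref / het / hom_alt) against
phenotype categories (normal / affected / suspicious / unknown), then
tests segregation under a recessive model by collapsing to the 2x2
affected-vs-normal x hom_alt-vs-other table with a two-sided Fisher
exact test.  Suspicious and unknown phenotypes are reported
descriptively but excluded from inference (their diagnosis is
tentative).  Discordant individuals are enumerated: *phenocopies*
(affected but not hom_alt — e.g. a second disease locus or
misdiagnosis) and *non-penetrant* carriers (normal but hom_alt — e.g.
examined before onset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PHENOTYPES = ("normal", "affected", "suspicious", "unknown")
GENOTYPES = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class SurveyRecord:
    sample_id: str
    phenotype: str  # normal | affected | suspicious | unknown
    genotype: str | None  # hom_ref | het | hom_alt | None (missing)
    traits: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"{self.sample_id}: bad phenotype {self.phenotype!r}")
        if self.genotype is not None and self.genotype not in GENOTYPES:
            raise ValueError(f"{self.sample_id}: bad genotype {self.genotype!r}")


@dataclass
class SurveyTable:
    """Phenotype x genotype contingency counts, with optional records."""

    counts: pd.DataFrame  # index PHENOTYPES, columns GENOTYPES
    missing_by_phenotype: pd.Series
    records: list[SurveyRecord] = field(default_factory=list)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum() + self.missing_by_phenotype.sum())


@dataclass
class SegregationReport:
    table2x2: tuple[int, int, int, int]  # (aff hom_alt, aff other, norm hom_alt, norm other)
    concordant_count: int
    phenocopies: list[str]
    non_penetrant: list[str]
    fisher_p: float
    odds_ratio: float
    haldane_corrected: bool
    insufficient_data: bool = False


def crosstab(records: list[SurveyRecord]) -> SurveyTable:
    """Tally records into the phenotype x genotype table.

    Missing genotypes are tallied separately per phenotype, never mixed
    into the genotype columns.
    """
    counts = pd.DataFrame(0, index=list(PHENOTYPES), columns=list(GENOTYPES), dtype=int)
    missing = pd.Series(0, index=list(PHENOTYPES), dtype=int)
    for r in records:
        if r.genotype is None:
            missing[r.phenotype] += 1
        else:
            counts.loc[r.phenotype, r.genotype] += 1
    return SurveyTable(counts, missing, list(records))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is <= the observed table's (with 1e-7
    relative slack for floating-point ties).  A zero margin gives p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return 1.0 if p > 1 - 1e-9 else p


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    if 0 in (a, b, c, d):
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
        return (a2 * d2) / (b2 * c2), True
    return (a * d) / (b * c), False


def segregation_report(table: SurveyTable, risk_genotype: str = "hom_alt") -> SegregationReport:
    """Segregation of the risk genotype under a recessive model.

    Collapses to affected/normal x risk/other and tests with Fisher.
    Discordant individuals (phenocopies, non-penetrant carriers) are
    named when per-record data are attached.
    """
    if risk_genotype not in GENOTYPES:
        raise ValueError(f"bad risk genotype {risk_genotype!r}")
    other = [g for g in GENOTYPES if g != risk_genotype]
    aff_risk = int(table.counts.loc["affected", risk_genotype])
    aff_other = int(table.counts.loc["affected", other].sum())
    norm_risk = int(table.counts.loc["normal", risk_genotype])
    norm_other = int(table.counts.loc["normal", other].sum())
    n_classified = aff_risk + aff_other + norm_risk + norm_other
    insufficient = n_classified == 0
    fisher_p = 1.0 if insufficient else fisher_exact_2x2(aff_risk, aff_other, norm_risk, norm_other)
    oddsr, haldane = (math.nan, False) if insufficient else _odds_ratio(
        aff_risk, aff_other, norm_risk, norm_other
    )
    phenocopies = [
        r.sample_id for r in table.records
        if r.phenotype == "affected" and r.genotype is not None and r.genotype != risk_genotype
    ]
    non_penetrant = [
        r.sample_id for r in table.records
        if r.phenotype == "normal" and r.genotype == risk_genotype
    ]
    concordant = aff_risk + norm_other
    return SegregationReport(
        table2x2=(aff_risk, aff_other, norm_risk, norm_other),
        concordant_count=concordant,
        phenocopies=phenocopies,
        non_penetrant=non_penetrant,
        fisher_p=fisher_p,
        odds_ratio=oddsr,
        haldane_corrected=haldane,
        insufficient_data=insufficient,
    )


def trait_association(
    records: list[SurveyRecord], trait_label: str, risk_genotype: str = "hom_alt"
) -> SegregationReport:
    """Association between a boolean trait tag and the risk genotype.

    Records carrying ``trait_label`` are treated as "affected" and the
    rest as "normal", then the same 2x2 machinery applies — e.g. the
    fundus-bronzing vs genotype check.
    """
    available = sorted({t for r in records for t in r.traits})
    if trait_label not in available:
        raise KeyError(f"unknown trait {trait_label!r}; available: {available}")
    relabeled = [
        SurveyRecord(
            r.sample_id,
            "affected" if trait_label in r.traits else "normal",
            r.genotype,
            r.traits,
        )
        for r in records
    ]
    return segregation_report(crosstab(relabeled), risk_genotype)


def read_survey_tsv(path) -> list[SurveyRecord]:
    """Read records from a TSV with columns sample, phenotype, genotype
    and optional boolean trait columns (values 0/1 or true/false)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "phenotype", "genotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    trait_cols = [c for c in df.columns if c not in required]
    records = []
    for _, row in df.iterrows():
        geno = row["genotype"]
        geno = None if pd.isna(geno) or geno in ("", "missing", "NA") else geno
        traits = frozenset(
            c for c in trait_cols
            if str(row[c]).strip().lower() in ("1", "true", "yes")
        )
        records.append(SurveyRecord(row["sample"], row["phenotype"], geno, traits))
    return records


def basenji_sag_survey() -> SurveyTable:
    """The published 80-dog Basenji survey of the SAG c.1216T>C genotype.

    Counts by ophthalmoscopic phenotype and genotype (T = wild type,
    C = mutant): normal 7/10/1, PRA-affected 2/0/17, PRA-suspicious
    0/2/4, phenotype unavailable 16/19/2 (hom_ref/het/hom_alt).
    Per-dog records are reconstructed from the counts with synthetic
    ids; individual identities beyond the counts were never published.
    """
    published = {
        "normal": (7, 10, 1),
        "affected": (2, 0, 17),
        "suspicious": (0, 2, 4),
        "unknown": (16, 19, 2),
    }
    records = []
    k = 0
    for pheno, row in published.items():
        for geno, count in zip(GENOTYPES, row):
            for _ in range(count):
                k += 1
                records.append(SurveyRecord(f"dog{k:03d}", pheno, geno))
    return crosstab(records)
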