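"""Per-marker case/control allelic association.

The test is the basic 1-df allelic chi-square on the 2x2 allele-count
table (cases vs controls x allele A vs allele B), the default
case/control scan of PLINK's ``--assoc``: no Yates continuity correction
and no Fisher fallback.  With 6 cases and 3 controls and no missing
calls, complete separation (cases homozygous for one allele, controls
for the other) gives chi2 = 18 and -log10(P) ~ 4.6557, the genome-wide
ceiling such a cohort can attain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rohmap.geno_io import GenotypeDataset, HET, HOM_A, HOM_B, Marker


@dataclass(frozen=True)
class Allelic2x2:
    """Allele counts: rows cases/controls, columns allele A / allele B."""

    case_a: int
    case_b: int
    ctrl_a: int
    ctrl_b: int

    def __post_init__(self) -> None:
        if min(self.case_a, self.case_b, self.ctrl_a, self.ctrl_b) < 0:
            raise ValueError("negative allele count")

    @property
    def total(self) -> int:
        return self.case_a + self.case_b + self.ctrl_a + self.ctrl_b


@dataclass(frozen=True)
class AssocResult:
    marker_id: str
    chi2: float
    df: int
    p: float
    neg_log10_p: float
    odds_ratio: float  # nan when undefined
    testable: bool = True


def allelic_counts(dataset: GenotypeDataset, marker: Marker | str) -> Allelic2x2:
    """Count alleles by phenotype group at one marker.

    Missing genotypes are excluded; a heterozygote contributes one copy
    to each allele.
    """
    mid = marker.id if isinstance(marker, Marker) else marker
    try:
        mi = next(i for i, m in enumerate(dataset.markers) if m.id == mid)
    except StopIteration:
        raise KeyError(mid) from None
    col = dataset.calls[:, mi]
    case_rows = [i for i, s in enumerate(dataset.samples) if s.phenotype == "case"]
    ctrl_rows = [i for i, s in enumerate(dataset.samples) if s.phenotype == "control"]

    def count(rows: list[int]) -> tuple[int, int]:
        g = col[rows]
        a = 2 * int((g == HOM_A).sum()) + int((g == HET).sum())
        b = 2 * int((g == HOM_B).sum()) + int((g == HET).sum())
        return a, b

    ca, cb = count(case_rows)
    ua, ub = count(ctrl_rows)
    return Allelic2x2(ca, cb, ua, ub)


def allelic_chi2(table: Allelic2x2, marker_id: str = "") -> AssocResult:
    """1-df chi-square on an allele-count 2x2 table.

    chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the p-value is the
    upper tail of the chi-square distribution with one degree of freedom.
    A zero margin makes the statistic undefined: the result is flagged
    untestable (p and chi2 NaN) rather than raising.
    """
    a, b, c, d = table.case_a, table.case_b, table.ctrl_a, table.ctrl_b
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if n == 0 or 0 in margins:
        return AssocResult(marker_id, math.nan, 1, math.nan, math.nan, math.nan, False)
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    neg_log10_p = float(-stats.chi2.logsf(chi2, df=1) / math.log(10))
    if b * c > 0:
        oddsr = (a * d) / (b * c)
    elif a * d > 0:
        oddsr = math.inf
    else:
        oddsr = math.nan
    return AssocResult(marker_id, float(chi2), 1, p, neg_log10_p, oddsr, True)


def gwas(dataset: GenotypeDataset) -> pd.DataFrame:
    """Allelic association scan over every marker, in genome order.

    Returns one row per marker with columns CHR, SNP, BP, A1, A2,
    CASE_A, CASE_B, CTRL_A, CTRL_B, CHISQ, P, NEG_LOG10_P, TESTABLE.
    Monomorphic markers are reported with chi2 = 0, p = 1 (kept so the
    output row count equals the marker count); markers with no
    informative samples in either group are flagged untestable.
    Neg-log10 p-values are carried at full double precision; rounding is
    display-only.
    """
    if not dataset.cases or not dataset.controls:
        raise ValueError("gwas requires at least one case and one control")
    case_rows = np.array(
        [i for i, s in enumerate(dataset.samples) if s.phenotype == "case"]
    )
    ctrl_rows = np.array(
        [i for i, s in enumerate(dataset.samples) if s.phenotype == "control"]
    )

    def group_counts(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = dataset.calls[rows]
        a = 2 * (g == HOM_A).sum(axis=0) + (g == HET).sum(axis=0)
        b = 2 * (g == HOM_B).sum(axis=0) + (g == HET).sum(axis=0)
        return a.astype(np.int64), b.astype(np.int64)

    ca, cb = group_counts(case_rows)
    ua, ub = group_counts(ctrl_rows)
    n = ca + cb + ua + ub
    r1, r2 = ca + cb, ua + ub  # group (row) margins
    c1, c2 = ca + ua, cb + ub  # allele (column) margins

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = r1 * r2 * c1 * c2
        chi2 = np.where(denom > 0, n * (ca * ub - cb * ua) ** 2.0 / np.where(denom > 0, denom, 1), np.nan)
    untestable = (r1 == 0) | (r2 == 0)
    monomorphic = ~untestable & ((c1 == 0) | (c2 == 0))
    chi2 = np.where(monomorphic, 0.0, chi2)
    p = np.full(dataset.n_markers, np.nan)
    nlp = np.full(dataset.n_markers, np.nan)
    ok = ~untestable
    p[ok] = stats.chi2.sf(chi2[ok], df=1)
    nlp[ok] = -stats.chi2.logsf(chi2[ok], df=1) / math.log(10)
    p[monomorphic] = 1.0
    nlp[monomorphic] = 0.0

    return pd.DataFrame(
        {
            "CHR": [m.chrom for m in dataset.markers],
            "SNP": [m.id for m in dataset.markers],
            "BP": [m.pos_bp for m in dataset.markers],
            "A1": [m.allele_a for m in dataset.markers],
            "A2": [m.allele_b for m in dataset.markers],
            "CASE_A": ca, "CASE_B": cb, "CTRL_A": ua, "CTRL_B": ub,
            "CHISQ": chi2, "P": p, "NEG_LOG10_P": nlp,
            "TESTABLE": ~untestable,
        }
    )


def top_hits(results: pd.DataFrame, rel_tol: float = 1e-9) -> pd.DataFrame:
    """Markers attaining the maximum -log10(P), grouped by chromosome.

    The peak-association summary: every marker whose -log10(P) ties the
    genome-wide maximum (within a relative tolerance absorbing float
    noise), in genome order.
    """
    testable = results[results["TESTABLE"]]
    if testable.empty or testable["NEG_LOG10_P"].isna().all():
        return testable.iloc[0:0]
    best = testable["NEG_LOG10_P"].max()
    hits = testable[testable["NEG_LOG10_P"] >= best * (1 - rel_tol)]
    return hits.sort_index()


def write_assoc_tsv(results: pd.DataFrame, path) -> None:
    """Plot-ready association TSV (Manhattan-plot input)."""
    out = results.copy()
    out["COUNTS"] = (
        out["CASE_A"].astype(str) + "," + out["CASE_B"].astype(str) + ","
        + out["CTRL_A"].astype(str) + "," + out["CTRL_B"].astype(str)
    )
    cols = ["CHR", "SNP", "BP", "A1", "A2", "COUNTS", "CHISQ", "P", "NEG_LOG10_P"]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
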