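"""Coding-variant consequence deduction on a transcript model.

Centred on *non-stop* (stop-loss) substitutions: a point mutation that
converts the natural stop codon into a sense codon, so that translation
reads through into the 3'UTR until the first downstream in-frame stop.
The deduced extension is reported both in the compact dialect
``p.*<wt_len><res>ext*<n>`` (star = wild-type stop; residue number =
count of coded residues before the stop) and in standard HGVS
(``p.Ter<wt_len+1><Res3>extTer<n+1>``).

Also provides ProtParam-style statistics of a deduced protein: charged
residue counts and the isoelectric point by bisection on the
Henderson–Hasselbalch net-charge function with the Bjellqvist pKa set,
including the residue-dependent N-terminal pKa.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
_STOPS = set(_TABLE.stop_codons)  # {TAA, TAG, TGA}
_FORWARD = dict(_TABLE.forward_table)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

AMINO_ACIDS = frozenset(_AA3)


class TranslationError(ValueError):
    """Translation crossed an unresolvable codon."""


@dataclass(frozen=True)
class Transcript:
    """An mRNA with CDS coordinates (1-based inclusive within the mRNA).

    The CDS must begin with ATG, end with a stop codon and have length
    divisible by 3.  IUPAC ambiguity codes are allowed only outside the
    CDS (e.g. a known 3'UTR SNP).
    """

    id: str
    mrna_seq: str
    cds_start: int
    cds_end: int
    polya_signal_pos: int | None = None

    def __post_init__(self) -> None:
        seq = self.mrna_seq.upper()
        object.__setattr__(self, "mrna_seq", seq)
        if not (1 <= self.cds_start < self.cds_end <= len(seq)):
            raise ValueError(f"{self.id}: CDS {self.cds_start}..{self.cds_end} outside mRNA")
        cds = self.cds
        if len(cds) % 3:
            raise ValueError(f"{self.id}: CDS length {len(cds)} not divisible by 3")
        if cds[:3] != "ATG":
            raise ValueError(f"{self.id}: CDS does not begin with ATG")
        if cds[-3:] not in _STOPS:
            raise ValueError(f"{self.id}: CDS does not end with a stop codon")
        bad = set(cds) - set("ACGT")
        if bad:
            raise ValueError(f"{self.id}: ambiguity codes {sorted(bad)} inside CDS")
        if set(seq) - set(_IUPAC):
            raise ValueError(f"{self.id}: non-IUPAC characters in mRNA")

    @property
    def cds(self) -> str:
        return self.mrna_seq[self.cds_start - 1 : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.mrna_seq[self.cds_end :]

    @property
    def n_codons(self) -> int:
        """Coded residues (stop codon excluded)."""
        return len(self.cds) // 3 - 1


@dataclass(frozen=True)
class CdnaVariant:
    """A c. substitution: position counted from the first base of ATG."""

    c_pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.c_pos < 1:
            raise ValueError(f"c. position must be >= 1, got {self.c_pos}")
        for b in (self.ref, self.alt):
            if b not in "ACGT":
                raise ValueError(f"invalid base {b!r}")

    def __str__(self) -> str:
        return f"c.{self.c_pos}{self.ref}>{self.alt}"


_HGVS_C = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")


def parse_hgvs_c(s: str) -> CdnaVariant:
    """Parse ``c.<pos><ref>><alt>`` (e.g. ``c.1216T>C``)."""
    m = _HGVS_C.match(s.strip())
    if not m:
        raise ValueError(f"cannot parse {s!r} as a c. substitution (c.<int><base>><base>)")
    pos = int(m.group(1))
    if pos < 1:
        raise ValueError(f"{s!r}: c. positions are >= 1")
    return CdnaVariant(pos, m.group(2), m.group(3))


@dataclass(frozen=True)
class ProteinConsequence:
    kind: str  # synonymous | missense | nonsense | stop_loss | no_change
    wt_protein: str
    wt_len: int
    mutant_protein: str | None
    extension_len: int = 0
    ext_first_residue: str | None = None
    next_stop_offset_nt: int | None = None
    notation: str | None = None  # compact dialect, e.g. p.*405Rext*25
    hgvs_p: str | None = None  # e.g. p.Ter406ArgextTer26
    no_stop_found: bool = False
    alternatives: tuple["ProteinConsequence", ...] = field(default_factory=tuple)


def _translate_cds(cds: str) -> str:
    aas = []
    for i in range(0, len(cds) - 3, 3):
        codon = cds[i : i + 3]
        if codon in _STOPS:
            raise TranslationError(f"internal stop codon {codon} at CDS position {i + 1}")
        aas.append(_FORWARD[codon])
    return "".join(aas)


def _resolve_codon(codon: str) -> set[str]:
    """All concrete codons an IUPAC-ambiguous codon can stand for."""
    out = {""}
    for base in codon:
        choices = _IUPAC.get(base)
        if choices is None:
            raise TranslationError(f"non-IUPAC base {base!r} in codon {codon}")
        out = {pre + c for pre in out for c in choices}
    return out


def _scan_extension(downstream: str) -> tuple[str, bool, list[tuple[str, bool]]]:
    """Translate in-frame codons until a stop; returns (aa_string, stop_found,
    alternative readings when ambiguity codes make them differ)."""
    readings: list[tuple[str, bool]] = [("", False)]
    for i in range(0, len(downstream) - len(downstream) % 3, 3):
        codon = downstream[i : i + 3]
        concrete = _resolve_codon(codon)
        new: list[tuple[str, bool]] = []
        for aa_so_far, stopped in readings:
            if stopped:
                new.append((aa_so_far, True))
                continue
            for c in sorted(concrete):
                if c in _STOPS:
                    new.append((aa_so_far, True))
                else:
                    new.append((aa_so_far + _FORWARD[c], False))
        # dedupe
        readings = sorted(set(new))
        if all(s for _, s in readings):
            break
    primary = readings[0]
    return primary[0], primary[1], readings


def consequence(tx: Transcript, v: CdnaVariant) -> ProteinConsequence:
    """Deduce the protein-level effect of a c. substitution.

    The wild-type CDS is translated with the standard genetic code; the
    substitution is applied; if the natural stop codon is abolished,
    translation continues into the 3'UTR until the first in-frame stop.
    If the 3'UTR carries IUPAC ambiguity codes and the alternative
    resolutions disagree in residue content or stop placement, every
    distinct reading is attached under ``alternatives``.  If no in-frame
    stop exists before the transcript end, the extension is open-ended
    and flagged ``no_stop_found``.
    """
    cds = tx.cds
    if v.c_pos > len(cds):
        raise ValueError(f"{v}: position beyond CDS length {len(cds)}")
    if cds[v.c_pos - 1] != v.ref:
        raise ValueError(
            f"{v}: reference mismatch, transcript has {cds[v.c_pos - 1]!r} at c.{v.c_pos}"
        )
    wt_protein = _translate_cds(cds)
    wt_len = len(wt_protein)
    mut_cds = cds[: v.c_pos - 1] + v.alt + cds[v.c_pos :]

    codon_idx = (v.c_pos - 1) // 3
    wt_codon = cds[3 * codon_idx : 3 * codon_idx + 3]
    mut_codon = mut_cds[3 * codon_idx : 3 * codon_idx + 3]

    if v.ref == v.alt or wt_codon == mut_codon:
        return ProteinConsequence("no_change", wt_protein, wt_len, wt_protein)

    is_last_codon = codon_idx == len(cds) // 3 - 1
    if is_last_codon:
        if mut_codon in _STOPS:
            # stop-preserving change at the stop codon
            return ProteinConsequence("no_change", wt_protein, wt_len, wt_protein)
        # stop-loss: read through into the 3'UTR
        first_res = _FORWARD[mut_codon]
        ext_tail, stop_found, readings = _scan_extension(tx.utr3)
        ext = first_res + ext_tail
        mutant = wt_protein + ext
        ext_len = len(ext)
        offset_nt = 3 * (ext_len - 1)
        alts: list[ProteinConsequence] = []
        if len(readings) > 1:
            for tail, stopped in readings[1:]:
                alt_ext = first_res + tail
                alts.append(
                    ProteinConsequence(
                        "stop_loss", wt_protein, wt_len, wt_protein + alt_ext,
                        extension_len=len(alt_ext), ext_first_residue=first_res,
                        next_stop_offset_nt=3 * (len(alt_ext) - 1),
                        notation=f"p.*{wt_len}{first_res}ext*{len(alt_ext)}",
                        hgvs_p=f"p.Ter{wt_len + 1}{_AA3[first_res]}extTer{len(alt_ext) + 1}",
                        no_stop_found=not stopped,
                    )
                )
        return ProteinConsequence(
            "stop_loss", wt_protein, wt_len, mutant,
            extension_len=ext_len, ext_first_residue=first_res,
            next_stop_offset_nt=offset_nt,
            notation=f"p.*{wt_len}{first_res}ext*{ext_len}",
            hgvs_p=f"p.Ter{wt_len + 1}{_AA3[first_res]}extTer{ext_len + 1}",
            no_stop_found=not stop_found,
            alternatives=tuple(alts),
        )

    wt_aa = _FORWARD[wt_codon]
    if mut_codon in _STOPS:
        mutant = wt_protein[:codon_idx]
        return ProteinConsequence(
            "nonsense", wt_protein, wt_len, mutant,
            notation=f"p.{wt_aa}{codon_idx + 1}*",
            hgvs_p=f"p.{_AA3[wt_aa]}{codon_idx + 1}Ter",
        )
    mut_aa = _FORWARD[mut_codon]
    if mut_aa == wt_aa:
        return ProteinConsequence(
            "synonymous", wt_protein, wt_len, wt_protein,
            notation=f"p.{wt_aa}{codon_idx + 1}=",
            hgvs_p=f"p.{_AA3[wt_aa]}{codon_idx + 1}=",
        )
    mutant = wt_protein[:codon_idx] + mut_aa + wt_protein[codon_idx + 1 :]
    return ProteinConsequence(
        "missense", wt_protein, wt_len, mutant,
        notation=f"p.{wt_aa}{codon_idx + 1}{mut_aa}",
        hgvs_p=f"p.{_AA3[wt_aa]}{codon_idx + 1}{_AA3[mut_aa]}",
    )


_EXT_NOTATION = re.compile(r"^p\.\*(\d+)([A-Z])ext\*(\d+)$")


def parse_ext_notation(s: str) -> tuple[int, str, int]:
    """Round-trip helper: ``p.*405Rext*25`` -> (405, 'R', 25)."""
    m = _EXT_NOTATION.match(s)
    if not m:
        raise ValueError(f"not an extension notation: {s!r}")
    return int(m.group(1)), m.group(2), int(m.group(3))


# ---------------------------------------------------------------------------
# ProtParam-style statistics
# ---------------------------------------------------------------------------

# Bjellqvist pKa set.  Side chains; C-terminal carboxyl; N-terminal amine
# (residue-dependent, default 7.5).
_PKA_POS_SIDE = {"K": 10.0, "R": 12.0, "H": 5.98}
_PKA_NEG_SIDE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PKA_CTERM = 3.55
_PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
_PKA_NTERM_DEFAULT = 7.5


@dataclass(frozen=True)
class ProteinStats:
    length: int
    count_positive: int  # Arg + Lys (His excluded, the ProtParam convention)
    count_negative: int  # Asp + Glu
    pI: float


def net_charge(protein: str, pH: float) -> float:
    """Henderson–Hasselbalch net charge at a given pH (Bjellqvist pKas)."""
    charge = 0.0
    nterm_pka = _PKA_NTERM.get(protein[0], _PKA_NTERM_DEFAULT)
    charge += 1.0 / (1.0 + 10 ** (pH - nterm_pka))
    charge -= 1.0 / (1.0 + 10 ** (_PKA_CTERM - pH))
    for aa, pka in _PKA_POS_SIDE.items():
        n = protein.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (pH - pka))
    for aa, pka in _PKA_NEG_SIDE.items():
        n = protein.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka - pH))
    return charge


def isoelectric_point(protein: str, ph_tol: float = 1e-4) -> float:
    """pI by bisection on the net-charge function over pH 0..14.

    Net charge is monotone decreasing in pH, so bisection lands on the
    unique zero; iterating to the pH tolerance (rather than stopping at
    a small-charge threshold) keeps the answer accurate even for
    near-flat charge curves (few ionizable groups).
    """
    lo, hi = 0.0, 14.0
    while hi - lo > ph_tol:
        mid = (lo + hi) / 2
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def protein_stats(protein: str) -> ProteinStats:
    """Charged-residue counts and isoelectric point of a protein.

    ``count_positive`` counts Arg + Lys; ``count_negative`` Asp + Glu.
    """
    bad = set(protein) - AMINO_ACIDS
    if bad or not protein:
        raise ValueError(f"non-standard residue(s): {sorted(bad) or 'empty sequence'}")
    return ProteinStats(
        length=len(protein),
        count_positive=protein.count("R") + protein.count("K"),
        count_negative=protein.count("D") + protein.count("E"),
        pI=isoelectric_point(protein),
    )


# ---------------------------------------------------------------------------
# File-level plumbing
# ---------------------------------------------------------------------------

def load_transcript(fasta_path, cds_start: int, cds_end: int,
                    polya_signal_pos: int | None = None) -> Transcript:
    """Load the first record of an mRNA FASTA as a :class:`Transcript`."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    return Transcript(rec.id, str(rec.seq), cds_start, cds_end, polya_signal_pos)
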