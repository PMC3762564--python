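"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by direct enumeration, sharing no code
with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

HET = 1
MISSING = -1


def roh_fractions_bruteforce(calls, window_snp, max_het, max_missing):
    """Per-SNP homozygous-window fraction by materializing every window."""
    m = len(calls)
    w = min(window_snp, m)
    windows = []
    for start in range(m - w + 1):
        chunk = list(calls[start : start + w])
        n_het = sum(1 for c in chunk if c == HET)
        n_mis = sum(1 for c in chunk if c == MISSING)
        windows.append((start, n_het <= max_het and n_mis <= max_missing))
    fracs = []
    for j in range(m):
        containing = [hom for start, hom in windows if start <= j <= start + w - 1]
        fracs.append(sum(containing) / len(containing))
    return np.array(fracs)


def roh_segments_bruteforce(calls, pos, params):
    """Segment calls by naive scanning; mirrors the published criteria only.

    ``params`` needs window_snp, window_max_het, window_max_missing,
    snp_hit_threshold, seg_min_kb, seg_min_snp,
    seg_max_density_kb_per_snp, seg_max_gap_kb attributes.
    """
    frac = roh_fractions_bruteforce(
        calls, params.window_snp, params.window_max_het, params.window_max_missing
    )
    hits = [f >= params.snp_hit_threshold for f in frac]
    segments = []
    i = 0
    m = len(calls)
    while i < m:
        if not hits[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and hits[j + 1]:
            j += 1
        # split at large gaps
        pieces = []
        start = i
        for k in range(i, j):
            if (pos[k + 1] - pos[k]) / 1e3 > params.seg_max_gap_kb:
                pieces.append((start, k))
                start = k + 1
        pieces.append((start, j))
        for a, b in pieces:
            while a <= b and calls[a] in (HET, MISSING):
                a += 1
            while b >= a and calls[b] in (HET, MISSING):
                b -= 1
            if a > b:
                continue
            n_snp = b - a + 1
            kb = (pos[b] - pos[a] + 1) / 1e3
            if (
                kb >= params.seg_min_kb
                and n_snp >= params.seg_min_snp
                and kb / n_snp <= params.seg_max_density_kb_per_snp
            ):
                segments.append((int(pos[a]), int(pos[b]), n_snp))
        i = j + 1
    return segments


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by exact rational enumeration of all tables."""
    from fractions import Fraction
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 in (0, n) or c1 in (0, n):
        return 1.0
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def pi_grid_search(protein, step=1e-5):
    """Isoelectric point by fine pH-grid search on the same charge model.

    Re-implements the Henderson–Hasselbalch sum directly (no bisection);
    returns the grid pH with net charge closest to zero.
    """
    pos_side = {"K": 10.0, "R": 12.0, "H": 5.98}
    neg_side = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    nterm = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}

    def charge(ph):
        q = 1.0 / (1.0 + 10 ** (ph - nterm.get(protein[0], 7.5)))
        q -= 1.0 / (1.0 + 10 ** (3.55 - ph))
        for aa, pk in pos_side.items():
            q += protein.count(aa) / (1.0 + 10 ** (ph - pk))
        for aa, pk in neg_side.items():
            q -= protein.count(aa) / (1.0 + 10 ** (pk - ph))
        return q

    # charge is monotone decreasing: binary search on the grid index
    import numpy as np

    grid = np.arange(0.0, 14.0 + step, step)
    lo, hi = 0, len(grid) - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if charge(grid[mid]) > 0:
            lo = mid
        else:
            hi = mid
    return grid[lo] if abs(charge(grid[lo])) < abs(charge(grid[hi])) else grid[hi]


def extension_by_codon_scan(mrna, cds_start, cds_end, alt_base, c_pos):
    """Residues appended by a stop-loss, by enumerating downstream codons."""
    table = {
        "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
        "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
        "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
        "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
        "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
        "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
        "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
        "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
        "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
        "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
        "GGG": "G",
    }
    stops = {"TAA", "TAG", "TGA"}
    seq = list(mrna)
    seq[cds_start - 1 + c_pos - 1] = alt_base
    seq = "".join(seq)
    # walk codons from the (former) stop codon onward
    stop0 = cds_end - 3  # 0-based index of first base of natural stop
    n = 0
    i = stop0
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if codon in stops:
            return n, True
        n += 1
        i += 3
    return n, False
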