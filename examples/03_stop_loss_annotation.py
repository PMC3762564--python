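"""Consequence deduction for a non-stop (stop-loss) substitution.

Builds a 405-codon transcript whose 3'UTR carries its first in-frame
stop codon 72 nt past the natural TGA, then applies c.1216T>C — the
substitution that recodes the stop to arginine (TGA -> CGA).
Translation reads through into the 3'UTR, appending 25 residues
(24 codons of UTR plus the recoded stop itself).
"""

from rohmap.seqann import consequence, parse_hgvs_c
from rohmap.simdata import simulate_transcript

tx = simulate_transcript(n_codons=405, next_stop_offset_nt=72, utr_len=200, seed=11)
res = consequence(tx, parse_hgvs_c("c.1216T>C"))

print(f"transcript: {tx.n_codons} codons, CDS {tx.cds_start}..{tx.cds_end}, "
      f"3'UTR {len(tx.utr3)} nt")
print(f"kind:               {res.kind}")
print(f"wild-type length:   {res.wt_len} aa")
print(f"extension:          {res.extension_len} aa, first residue "
      f"{res.ext_first_residue} (Arg)")
print(f"next in-frame stop: {res.next_stop_offset_nt} nt past the abolished stop")
print(f"notation:           {res.notation}  /  {res.hgvs_p}")
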