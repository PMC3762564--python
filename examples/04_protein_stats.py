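"""ProtParam-style statistics of a wild-type and a stop-loss-extended protein.

Translates a simulated transcript, extends it through its stop-loss
variant, and compares charged-residue counts and isoelectric points.
The pI comes from bisection on the Henderson-Hasselbalch net-charge
function with the Bjellqvist pKa set (including the residue-dependent
N-terminal pKa); a C-terminal extension rich in basic residues shifts
the pI upward.
"""

from rohmap.seqann import consequence, parse_hgvs_c, protein_stats
from rohmap.simdata import simulate_transcript

tx = simulate_transcript(n_codons=405, next_stop_offset_nt=72, utr_len=200, seed=11)
res = consequence(tx, parse_hgvs_c("c.1216T>C"))

for label, protein in [("wild-type", res.wt_protein), ("mutant", res.mutant_protein)]:
    st = protein_stats(protein)
    print(f"{label:10s} length={st.length:4d}  Arg+Lys={st.count_positive:3d}  "
          f"Asp+Glu={st.count_negative:3d}  pI={st.pI:.2f}")
ext = res.mutant_protein[res.wt_len:]
print(f"extension sequence ({len(ext)} aa): {ext}")
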