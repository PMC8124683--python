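"""Classify proteins by intrinsic disorder: CH-plot, PPIDR, MDS, CH-CDF quadrant.

Builds three archetypal sequences, scores them with the windowed
charge–hydropathy scorer, and prints each protein's summary.  An ordered
protein should land in Q1 with low PPIDR; a charged, low-hydropathy protein
in Q3 with high PPIDR.
"""

from stemdis import ProteinRecord, summarize_protein

proteins = {
    # hydrophobic, foldable composition
    "ordered_like": "MVLIVFWCLIYVNVLIFCWVLIVNYFLCVIWLVFYNILCVWFIVLYNCVLIWFV",
    # charged/polar, disorder-promoting composition
    "disordered_like": "MSEEKRPQGSAEKRPEGQSPKREAGSQPEKRGSEQPAKREGSPQEKRAGSEPQKR",
    # half and half: an ordered core with a disordered tail
    "hybrid_like": "MVLIVFWCLIYVNVLIFCWVLIVNSEEKRPQGSAEKRPEGQSPKREAGSQPEKRG",
}

for name, seq in proteins.items():
    s = summarize_protein(ProteinRecord(name, seq))
    print(
        f"{name:16s} PPIDR={s.ppidr:5.1f}%  MDS={s.mds:4.2f}  "
        f"CH={s.ch_distance:+.3f}  CDF={s.cdf_distance:+.3f}  "
        f"quadrant={s.quadrant}  bins=({s.ppidr_bin}, {s.mds_bin})"
    )

print()
print("PPIDR = % residues scoring > 0.5; MDS = mean residue score.")
print("CH > 0 means disordered by charge-hydropathy; CDF > 0 means ordered")
print("by the score CDF, so Q1 = ordered by both, Q3 = disordered by both,")
print("Q2 = compact but disordered by CDF (molten globule / hybrid).")
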