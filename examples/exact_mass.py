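"""Identity check for a synthesized tracer: monoisotopic [M+H]+ from its
molecular formula, as printed in an HRMS-ESI table."""

import mstkit as mk

# Cy5-labeled morphine hapten; the printed formula is the protonated-ion
# composition, so its plain monoisotopic atom sum is the reported m/z
formula = "C58H69N6O12S3"
mz = mk.monoisotopic_mh(formula, protonated_composition=True)
print(f"[M+H]+ calculated for {formula}: {mz:.4f}")

# neutral-formula convention for comparison: water + proton
print(f"[M+H]+ of H2O (neutral formula + proton): {mk.monoisotopic_mh('H2O'):.4f}")
print("Agreement of calculated and found m/z to ~1 mDa confirms the")
print("elemental composition of the conjugate.")
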