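"""How many footfalls must be averaged for a reliable COP measurement?

Applies the Spearman-Brown prophecy to the published single-footfall ICCs
of every COP parameter (both walking speeds) and inverts it at the
customary reliability cut-off of 0.50.
"""

from copmat import required_k, spearman_brown
from copmat.reference_values import load_reference_table

ref = load_reference_table()
ref = ref.assign(required=[required_k(r, 0.50) for r in ref["icc21"]])

worst = ref.sort_values("required", ascending=False).head(3)
print("least reliable parameters (single footfall):")
print(worst[["category", "subphase", "condition", "icc21", "required"]]
      .to_string(index=False))

k_needed = int(ref["required"].max())
print(f"\nfootfalls required so every parameter reaches R_k >= 0.50: {k_needed}")

row = ref[(ref.category == "dur") & (ref.subphase == "ICP")
          & (ref.condition == "comfortable")].iloc[0]
print(f"check: prophesied 7-footfall ICC for ICP duration = "
      f"{spearman_brown(row['icc21'], 7):.3f} (published {row['icc2k']:.2f})")
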