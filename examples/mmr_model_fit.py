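"""Fit the slippage + MMR channel model to the published [GT/CA]19 panel.

The polymerase generates deletion-biased slippage errors; genotype-dependent
(MutS, MutL) repair channels remove nascent-strand (expansion-precursor) and
template-strand (deletion-precursor) IDLs.  Fitting per-channel repair
efficiencies to the four cell-line class frequencies reproduces the observed
bias flip: expansion-biased in MutLa-proficient lymphoblastoid lines,
deletion-biased (polymerase-like) in the HCT116 lines.
"""

from maturems import fit_repair_efficiencies, load_gtca19_panel

panel, pol, n = load_gtca19_panel()
print(f"polymerase anchor at n={n}: expansion {pol.e_exp(n):.2g}, "
      f"deletion {pol.e_del(n):.2g} (deletion-biased in vitro)")

fit = fit_repair_efficiencies(panel, pol, n)
print("fitted repair efficiencies (channel -> probability an IDL is removed):")
for (muts, mutl, cls), value in sorted(fit.efficiencies.as_dict().items()):
    print(f"  {muts}.{mutl:6s} {cls:9s} r = {value:.3f}")

print("predicted expansion:deletion ratio by genotype (observed side of 1 in "
      "parentheses):")
observed_side = {"LCL721": ">1", "LCL1261": ">1", "HCT116+chr3": "<1", "HCT116": "<1"}
for label in ("LCL721", "LCL1261", "HCT116+chr3", "HCT116"):
    ratio = fit.predicted_ratio[label]
    print(f"  {label:12s} {ratio:8.3f}  ({observed_side[label]})")
print("ratios > 1 are expansion-biased; the MMR-null HCT116 line stays at the "
      "polymerase's deletion bias, showing the expansion bias is made by MMR, "
      "not by the polymerase.")
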