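"""Simulate one mosaic clone and quantify its allele frequencies.

Builds a clone that is 50 % intended edit, 6 % bystander subclone and 44 %
wild type, sequences it in silico at 10,000 fragments, and reads the
fractions back off the pileup.
"""

from ampliclone import Haplotype, SimConfig, quantify_sample, simulate_clone
from ampliclone.auts2 import BYSTANDER_H044, TARGET_H044, build_reference

ref = build_reference()
target = ref.to_offset(TARGET_H044) + 1
bystander = ref.to_offset(BYSTANDER_H044) + 1

haplotypes = [
    Haplotype("wt", (), 0.44),
    Haplotype("edit", ((target, "G"),), 0.50),
    Haplotype("bystander", ((bystander, "G"),), 0.06),
]
clone = simulate_clone(ref, haplotypes, SimConfig(depth=10_000, seed=11), "demo")
quant = quantify_sample(clone.r1, clone.r2, ref, sample_id="demo")

print(f"fragments mapped: {quant.n_mapped_fragments}/{quant.n_fragments}")
for label, pos in (("target  chr7:%d" % TARGET_H044, TARGET_H044),
                   ("bystander chr7:%d" % BYSTANDER_H044, BYSTANDER_H044)):
    est = quant.alt_fraction(pos, "G")
    print(f"  {label}: G fraction {est:.4f} at depth {quant.depth_at(pos)}")
print(f"ground truth draws: edit {clone.truth_fraction('edit'):.4f}, "
      f"bystander {clone.truth_fraction('bystander'):.4f}")
print("The estimates match the simulated draws to binomial precision; the 6 %")
print("bystander subclone exceeds the 5 % mosaicism threshold and would flag")
print("this clone as mosaic in classification.")
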