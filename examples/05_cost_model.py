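"""Sanger vs amplicon-NGS genotyping cost and the crossover sample count.

Uses the package's illustrative dual-index costing: NGS pays a fixed run
cost plus 2*ceil(sqrt(N)) index primers, so its per-sample cost falls with
N while Sanger stays linear.
"""

from ampliclone import cost_curves, crossover, example_cost_params, primers_needed

params = example_cost_params()
curves = cost_curves(params, 150)

print("N     Sanger   NGS(no primers)  NGS(with primers)  primers")
for n in (1, 7, 8, 20, 50, 80, 81, 100, 150):
    row = curves[curves.n_samples == n].iloc[0]
    print(f"{n:<5} {row.sanger:<8.0f} {row.ngs_without_primers:<16.0f} "
          f"{row.ngs_with_primers:<18.1f} {primers_needed(n)}")

print()
print(f"crossover with primer synthesis:    N = {crossover(params, include_primers=True)}")
print(f"crossover reusing an existing set:  N = {crossover(params, include_primers=False)}")
print("Past the crossover, every additional clone genotyped by NGS costs less")
print("than a Sanger reaction; primer synthesis only delays, never removes, it.")
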