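# ampliclone

Amplicon-NGS genotyping of base-edited cell clones: per-position allele
frequency quantification, zygosity and mosaicism classification, read-backed
phasing of an induced edit against a germline variant, and a Sanger-vs-NGS
cost model.

## The problem

Generating a cell line with one intended single-nucleotide edit — for
example, an adenine-base-editor (ABE) A→G substitution that synonymously
marks one allele of a gene — requires screening many picked colonies.
Each colony can be unedited, heterozygous, homozygous, carry bystander
edits at neighbouring window adenines, or be a *mosaic* mixture of
subclones.  Sanger sequencing of the amplicon reads an averaged trace and
only resolves alleles above ~20 % abundance; deep paired-end sequencing of
the same amplicon (~10,000 fragments per clone) turns genotyping into a
counting problem with ~2 % sensitivity and per-allele resolution.

`ampliclone` implements that counting problem end to end for a known
amplicon:

* **simulate** — paired-end 150 bp reads from clones with arbitrary
  haplotype mixtures (weights, bystanders, germline phase), fixed fragment
  length, per-base error rate, fully seeded;
* **align & quantify** — semi-global alignment of every read to the
  amplicon (free end-gaps on the reference, unit costs), mate
  reconciliation (overlap agreement counted once, disagreement masked,
  quality floor), per-position A/C/G/T/del/ins pileups and the
  samples × positions allele-frequency matrix;
* **classify** — per-clone target-edit fraction *f* banded as
  unedited (*f* < 2 %), low-fraction (2–30 %), heterozygous candidate
  (30–65 %) or potential homozygote (≥ 65 %); mosaic flag when any
  unintended allele reaches 5 %; bystander report per window position;
* **phase** — fragment-level joint alleles over (edit site, germline
  heterozygous SNV), cis/trans call with purity, and a monoclonality
  verdict combining germline balance, phase purity and zygosity band;
* **cost** — Sanger cost `s·N` vs NGS cost `F + c·N + u·2⌈√N⌉`
  (dual-index primers per axis scale as √N), with exact crossover scan.

The built-in design (`ampliclone.auts2`) models an ABE assay in exon 10 of
human *AUTS2* (chr7, hg38): guides N044 (`CAAAAGTTGACCCATTCTAC`, plus
strand, target chr7:70768044, a third-position A of an AAA lysine codon
inside a four-adenine run) and N068 (`TCACACTGTGCCGGTAGAAT`, minus strand,
target chr7:70768068, AGT→AGC serine), phased against rs3829006 G/A at
chr7:70768282, 238 bp from the edit.  No public reads accompany the assay,
so the bundled 363 bp reference is a *synthetic surrogate*: the 33 bp core
pinned by the two published protospacers, the germline site and the coding
frame are exact; filler bases are deterministic.

## Worked example

```python
from ampliclone import Haplotype, SimConfig, quantify_sample, simulate_clone
from ampliclone.auts2 import build_reference, TARGET_H044, BYSTANDER_H044

ref = build_reference()
target = ref.to_offset(TARGET_H044) + 1
bystander = ref.to_offset(BYSTANDER_H044) + 1
clone = simulate_clone(ref, [
    Haplotype("wt", (), 0.44),
    Haplotype("edit", ((target, "G"),), 0.50),
    Haplotype("bystander", ((bystander, "G"),), 0.06),
], SimConfig(depth=10_000, seed=11), "demo")
quant = quantify_sample(clone.r1, clone.r2, ref, sample_id="demo")
print(quant.alt_fraction(TARGET_H044, "G"), quant.alt_fraction(BYSTANDER_H044, "G"))
```

prints

```
0.4939 0.0582
```

— the measured G fractions at the target and bystander positions, matching
the simulated draws (0.4942 and 0.0579) to binomial precision.  Classified
at the default thresholds this clone is a heterozygous candidate but is
flagged **mosaic**, because the 5.8 % bystander subpopulation exceeds the
5 % unintended-allele threshold.

The `examples/` directory holds one short script per capability
(guide geometry, single-clone quantification, cohort screening with report
export, cis/trans phasing with a mixed-colony counterexample, cost
curves); each prints its numbers with a line on what they mean.  A thin
CLI mirrors the same steps (`ampliclone init-example | simulate | quantify
| classify | phase | report | cost`).

## Layout

```
src/ampliclone/    reference.py  guide geometry + codon logic
                   auts2.py      built-in synthetic study design
                   simulate.py   paired-end read simulator
                   align.py      trimming, semi-global alignment, mate merging
                   quantify.py   pileups and allele-frequency matrices
                   classify.py   zygosity bands, mosaicism, bystanders
                   phasing.py    joint-allele tables, cis/trans, monoclonality
                   cost.py       Sanger-vs-NGS cost model
                   report.py     cohort exports and plots
                   pipeline.py   end-to-end composition
                   io.py, cli.py file formats and the CLI
docs/methods.md    model, assumptions, parameter choices, limitations
examples/          narrative scripts, one per capability
tests/             pytest suite (unit, property and end-to-end)
```
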