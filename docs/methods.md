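# Methods

This note documents the models and procedures `ampliclone` implements, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Coordinate and guide model

All user-facing coordinates are 1-based inclusive genomic plus-strand
positions; internal arrays are 0-based half-open.  A protospacer is
numbered 1–20 from the PAM-distal (5′) end.  For a plus-strand guide,
protospacer position *k* maps to `anchor + k − 1`; for a minus-strand
guide to `anchor − (k − 1)`, and the protospacer base equals the
complement of the plus-strand reference base there.  The ABE editing
window defaults to protospacer positions 4–7 and is configurable per
guide; published descriptions of deaminase windows vary between 4–6 and
4–7 for the same enzyme, so the window is data, not a constant.  An
adenine run is the maximal block of consecutive protospacer adenines
containing a given position; long runs predict bystander conversions.

Codon classification reconstructs the codon containing a substituted
position on the declared coding strand (`frame_offset` anchors the first
complete codon), applies the substitution and translates both codons under
the standard nuclear genetic code (Biopython).  The test suite checks this
exhaustively against an independent hard-coded 64-codon table.

## The built-in design and its synthetic reference

The bundled design targets exon 10 of human *AUTS2* (chr7, hg38).  The two
guide protospacers overlap over chr7:70768053–70768059 and are mutually
consistent there; together they pin the plus-strand sequence
chr7:70768040–70768072 exactly, including the AAA lysine codon at
70768042–70768044 (third-position A→G is synonymous, AAA→AAG) and the AGT
serine codon at 70768066–70768068 (T→C on the plus strand is the
minus-strand A→G, AGT→AGC).  Both reconstructed protospacers carry NGG
PAMs.  The germline phasing marker rs3829006 G/A sits at chr7:70768282,
238 bp from the chr7:70768044 edit.

No sequencing data for the assay is publicly deposited, so the 363 bp
reference amplicon is a synthetic surrogate: every base with an external
constraint (the 33 bp guide core, the germline G, the reading frame) is
placed exactly; the remaining bases are drawn once from a fixed-seed RNG
and never change.  Coordinate arithmetic, codon logic and all distances
are therefore real; only filler sequence content is invented.  Results
that depend on sequence *content* outside the constrained positions (e.g.
alignability of random filler) are design-independent at the error rates
modelled here.

## Read simulator

A clone is a weighted mixture of haplotypes (substitution lists over the
amplicon; weights sum to 1 within 1e-9).  Each of `depth` fragments is
drawn i.i.d. from the mixture; R1 is the fragment's 5′ prefix of
`read_length`, R2 the reverse complement of its 3′ suffix.  Defaults
follow the assay being modelled: 150 bp paired reads, a 363 bp fragment
(the phasing PCR product; the two mates then cover disjoint windows with a
63 bp uncovered middle), 10,000 fragments for quantification and 5,000
pairs for phasing, constant base quality Q30.

Sequencing noise is i.i.d. per-base substitution at `per_base_error`
(default 1e-3, a stated assumption — the assay's platform error profile is
not published), uniform over the three alternative bases.  Substitutions
are the error model of interest because ABE chemistry produces
substitutions; an optional per-fragment single-base deletion rate exists
only to exercise indel handling.  Not emulated: PCR jackpotting and
chimeras, index hopping, quality-score structure along the read, fragment
length jitter (an amplicon has one defined product), and strand bias.
Passing tests therefore demonstrate correctness of the counting and
calling machinery under binomial sampling plus uniform noise, not
robustness to library-preparation artifacts; on real data those artifacts
inflate the low-frequency background, which is why the noise floor below
is configurable.

Read names carry the ground-truth haplotype label, so any downstream
estimate can be audited by recounting tags.  Identical inputs and seed
give byte-identical FASTQ.

## Alignment and quantification

Reads come from one known short amplicon, so instead of a genome mapper
each read is aligned semi-globally (free end-gaps on the reference, unit
mismatch/gap costs) with the `edlib` C library, trying both orientations
and keeping the better.  This exact Levenshtein alignment replaces the
banded approximation a generic implementation might use; the test suite
verifies it against a naive full dynamic-programming oracle on reads up to
60 nt with up to 6 mixed edits.  A read whose distance exceeds 20 % of its
length is flagged unmapped and counted, never silently dropped.

One normalization is applied to the optimal path: under unit costs, two
nearby substitutions can be rendered as an equal-cost balanced
deletion+insertion pair, which would erase base calls at intervening
positions (observed at ~2·10⁻³ per fragment at error 1e-3).  When an
alignment contains both an I and a D op and a substitution-only placement
of equal or better cost exists within one position of the reported start,
the substitution-only interpretation is used.  This mirrors the standard
amplicon-caller preference for substitutions on ties and removes a small
systematic deficit at high-frequency alleles.

Mates are reconciled per fragment before counting: each amplicon position
receives at most one call per fragment; overlapping agreeing calls count
once, disagreements are masked, and bases below the quality floor
(default Q20) are masked.  Pileups tally A/C/G/T/deletion per position
(counts sum to depth by construction) and insertion starts separately;
insertions anchored past the final reference base are attributed to that
final position.  Two frequency notions are kept distinct: the
non-reference fraction (mosaicism scans) and the specific-alternate
fraction (intended-edit quantification).  Zero-depth positions are
missing (NaN), not zero.  Pre-aligned SAM/BAM is an alternative input
path; there the caller's placements are trusted as-is.

## Clone classification

The target-edit fraction *f* (specific alternate at the mapped target) is
banded with inclusive lower edges: unedited < 2 % ≤ low-fraction < 30 % ≤
heterozygous candidate < 65 % ≤ potential homozygous.  The 2 % and 30 %
thresholds are the assay's published operating points; 65 % is this
package's default for the homozygosity edge — chosen so that observed
fractions of 0.68 and 0.89, both described as potential homozygotes, fall
in the band, since no explicit cutoff is published.  All four thresholds
are configurable.

A clone is mosaic when any unintended allele — any substitution, deletion
or insertion other than the intended edit at the target — reaches 5 %.
Unintended alleles above a noise floor of 0.5 % are listed even when below
the mosaic threshold; the floor separates sequencing noise (~0.03 % per
alternate base at error 1e-3) from true subclonal alleles and is a
calibration of this package, not a published constant.  Bystander edits
(the intended base change at a non-target editable window position) are
reported per protospacer position at the detection threshold.  Efficiency
summaries are integer percentages rounded half-up, which reproduces all
published ratio→percent conversions (e.g. 37/69 → 54 %, 15/48 → 31 %).

## Phasing and monoclonality

With the edit and the germline SNV 238 bp apart and 150 bp reads, no
single read covers both sites: the phasing unit is the fragment, R1
covering the edit and R2 the SNV.  Each fragment with unmasked,
allele-matching calls at both sites increments one cell of the 2×2 joint
table; everything else is uninformative.  Among edited fragments, purity
is the majority germline-allele share; the cis/trans call requires at
least `min_fragments` (default 100) edited fragments and purity ≥ 0.9,
otherwise the result is ambiguous — a value, not an error.  The defaults
are conservative for ~5,000-pair depth and are not published constants
(the original assay phased manually in a genome browser).

Monoclonality of a colony is certified when three criteria hold, each
reported individually on failure: germline balance within 0.15 of 50 %
(balanced template from two chromosomes), phase purity ≥ 0.9 (edit
confined to one allele), and edit fraction inside the expected zygosity
band (default the heterozygous band).  A colony mixing subclones edited
on opposite alleles keeps a perfect 50 % balance but collapses to ~50 %
purity, which is why balance alone is insufficient.

## Cost model

Sanger cost is `s·N`.  NGS cost is `F + c·N` plus, when index primers
must be synthesised, `u · 2⌈√N⌉`: with two index axes, ⌈√N⌉ primers per
axis index N samples, the standard dual-index combinatorics that yields
the √N scaling of primer cost.  Crossovers are found by exact integer
scan because the ceiling makes the curves locally non-monotone.  The
published cost table behind the assay's figures is not available, so
`example_cost_params()` is an illustrative calibration (Sanger 10/sample,
NGS 1/sample + 65 fixed, primer unit 36.5) whose crossovers — 81 samples
with primer synthesis, 8 without — match the reported qualitative
behaviour (">80" and ">7" samples); the parameters, not the crossovers,
are the package's claim.

## Problem sizes and numerical choices

The test suite and the acceptance script run at sizes chosen as this
package's own verification scale: the 117-clone screening cohort at
2,000 fragments/clone (the per-clone binomial SD at 2,000× keeps every
designed haplotype weight ≥ 4σ clear of each classification threshold, so
cohort-level counts are deterministic by design); parameter recovery at
the full 10,000× with 200 clones in tests and 50 in the acceptance
script; phasing at 5,000 pairs × 100 clones in tests and 2,000 × 30 in
the script.  Exact central binomial intervals (`scipy.stats.binom.ppf`)
are used for recovery checks; they are conservative at the boundary
weights 0 and 1.  All randomness flows from explicit seeds through
`numpy.random.default_rng`; per-clone seeds are spawned from one master
seed and kept below 2³¹.

## Known limitations

* The simulator's noise model is deliberately minimal (see above); the
  classifier's noise floor and mosaic threshold should be recalibrated on
  real libraries where PCR artifacts raise the background.
* Direct allele-depth counting replaces a likelihood-based variant caller;
  at amplicon depths (10³–10⁴×) the allele-depth fractions are the
  quantity of interest, but at low depth a genotype-likelihood model would
  be preferable.
* Phasing handles exactly two bi-allelic sites; no multi-site haplotype
  assembly.
* Indels are counted and reported (deletions per spanned position,
  insertion starts per anchor) but never classified as edits — ABE
  outcomes are substitutions.
* The SAM ingestion path trusts the external aligner's placements and does
  not re-reconcile mate overlaps.
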