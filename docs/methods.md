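# Methods

This note records the models implemented in mitomodkit, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions used throughout.

## Coordinates and sequence model

All coordinates are 1-based inclusive, in a named parent system (e.g.
"human 16S rRNA"); the 16S→mtDNA offset is +1670, so rRNA position 947 is
mtDNA 2617. RNA and DNA alphabets are kept distinct, with
`transcribe`/`reverse_transcribe` as the only crossings — the editing and
RFLP operations work on DNA, the mass operations on RNA, and implicit
coercion is a classic source of coordinate and alphabet bugs.

Modified sequences use a compact shorthand: `m1` before a base is a base
methyl (registry-checked; `m1A` requires A), `m` after a base is
2′-O-ribose methylation, trailing `p` is a 3′-phosphate and `>p` a
2′,3′-cyclic phosphate. Parsing and rendering round-trip exactly. The
modification registry (label, base constraint, mass delta) is extensible
at run time so additional marks need no code change.

## Oligonucleotide masses and ions

Masses are monoisotopic only; the study-style printed values match
monoisotopic, not average, masses. An internal residue contributes its
nucleoside-3′-monophosphate mass minus water (A 329.05252, C 305.04129,
G 345.04744, U 306.02530 Da); every methyl adds CH₂ = 14.01565 Da
regardless of position. Terminal chemistry then fixes the neutral mass
(5′-OH/3′-P: +H₂O; 5′-OH/3′-OH: +H₂O−HPO₃; 5′-OH/3′-cyclicP: +0;
5′-P/3′-P: +H₂O+HPO₃). Negative-mode m/z is (M − n·1.0072765)/n.

Nuclease digestion products default to the **linear 3′-phosphate** form:
the printed fragment masses (e.g. the 12-mer at 3833.5 Da and the
tetramer at 1325.21 Da) are consistent with linear 3′-P, not the cyclic
intermediate; the cyclic form is available by flag. RNase T1 cleaves 3′
of guanosine and RNase A 3′ of pyrimidines, in strict single-nucleotide
context; a 2′-O-methyl on the residue 5′ of the scissile bond blocks
cleavage (the di-methylated 11-mer containing Um/Gm survives T1 intact,
which fixes this rule empirically). Missed cleavages emit unions of up
to k+1 adjacent complete fragments, flagged.

CID series follow the standard oligonucleotide nomenclature. For a 5′-OH
parent: cᵢ = prefix + H₂O, aᵢ = cᵢ − HPO₃, (a−B)ᵢ additionally loses the
neutral base of residue i (the methylated base mass when modified);
yₖ keeps the parent's own 3′ terminus with a free 5′-OH and
wₖ = yₖ + HPO₃. A 5′-P parent shifts the 5′-side series by +HPO₃. The
defaults (series c/y/w, charges 1–2) are the assignments routinely made
in negative-mode spectra of short oligomers. Complementary ions obey
cᵢ + yₙ₋ᵢ = aᵢ + wₙ₋ᵢ = M + H₂O for every terminus combination; the test
suite verifies this against masses rebuilt independently from elemental
compositions.

Printed values are reproduced to the printed precision (two decimals →
±0.01, one decimal → ±0.05). One known outlier: the triply charged 11-mer
ion printed as m/z 1177.2 differs by ~0.06 from the monoisotopic
prediction (1177.14); whether that figure is an observed centroid or a
theoretical value is not stated, so it is excluded from exact checks.

## RDD calling

"High quality" is not defined numerically in the original filtering
description, so the pileup defaults are explicit and conservative:
minimum base quality 30, minimum MAPQ 20, and exclusion of calls within
5 nt of either read end (`edge_trim`). These are configurable, and any
reanalysis should report them.

Filter A requires ≥ 1000 quality-passing reads (waivable per sample for
shallow datasets, as the original analysis did for one species). Filter B
requires the strongest non-reference base to reach ≥ 1.6% of total
coverage **and** ≥ 0.8% of the reads of each strand; the per-strand
denominator is that strand's own coverage. Boundary semantics are
inclusive (≥) at all three thresholds.

Manual read-edge inspection is automated as a one-sided binomial test:
under uniformity, a variant call lands within `window` of a read end with
probability 2·window/read_length; an excess at α = 0.01 flags the site.

The m¹A signature score combines the misincorporation rate
(freq(T)+freq(G) at an A site) with the coverage drop
1 − cov(site)/median(flank coverage), flank ±25 nt by default, floored at
zero. "RDD level" (the prevalence-style number) is defined as
1 − freq(reference base); the underlying per-sample read counts for the
published prevalence percentages are not in the text, so this definition
is the package's stated assumption.

Two-sample comparisons use the uncorrected Pearson χ² on the 2×2
(modified, unmodified) table — counts in this setting are in the
thousands, where the continuity correction only biases — with a Fisher
exact p-value fallback when any expected cell is below 5. The statistic
reported is always the Pearson value.

## Ortholog anchoring

The anchoring procedure is a reconstruction, not a published algorithm:
the human window (±30 nt around the site; 61 nt is unique in a 16–17 kb
mtDNA yet small enough for exact alignment) is locally aligned against
the target with match +2, mismatch −1, linear gap −2 (no affine
extension; indels immediately beside this conserved site are rare and
simplicity wins). The anchor is the target column aligned to the window
centre; anchoring fails below 60% of the maximal score, when the centre
falls in a gap, or when two co-optimal alignments disagree. Tests verify
agreement with an exhaustive ungapped placement oracle on
substitution-only targets.

## Editing and construct design

MAGE oligos are 90-mers with the edited base at offset 46 and
phosphorothioate bonds on the two outermost linkages of each end — both
conventions were derived from the two published oligo sequences (the
offset from the position of the bold edited base, the protection from the
asterisk placement; the "exactly two per end" reading of the typography
is an inference, flagged here). The lagging-strand oligo is the reverse
complement of the gene-strand window carrying the complement of the new
base.

MluCI is modelled as "cut immediately 5′ of AATT" (5′-overhang
convention); since only fragment lengths are reported, the overhang
detail does not affect any output. Site detection is strand-agnostic for
this palindromic site. Note that the published 90-mers also contain a
constant AATT distal to the edit; genotype discrimination rests on the
site *created at the edited position*, which is what the package and its
checks assert. Fragment lengths always sum to the amplicon length.

Template assembly is greedy exact suffix/prefix merging with a minimum
overlap of 15 nt, accepting either orientation per oligo (terminal
primers are conventionally written reverse-complemented); fragments fully
contained in another are absorbed first. Assembly is invariant to input
order and to flipping any oligo, and ties between incompatible merges are
an error rather than an arbitrary choice. T7 run-off transcription
requires the class III promoter followed by G at +1 and transcribes to
the template end. The four published template oligos assemble to 133 nt
and yield the 114-nt helix-71 segment (16S 866–979).

## Reporter kinetics

The production rate is the published definition, rₜ = (Fₜ − Fₜ₋₁)/ODₜ,
computed on raw (unsmoothed) series — whether the original curves were
smoothed is not stated, so raw is the default and smoothing is left to
the caller. Total production integrates the rate series by the trapezoid
rule on the sampling grid ("area under it" names no rule; trapezoid is
the standard choice and converges to the Riemann limit within 1% on
smooth curves at 30-min sampling). Maximal growth rate is the largest
5-point sliding-window slope of ln OD — the original comparison was
qualitative, so this is the package's own operationalization. The printed
strain percentages (64.4/76.2/75/83.6/109/110.1%) depend on the raw plate
data and are not recomputable from the text; the tests instead verify
that a simulated strain at 85% relative production is recovered within
5 percentage points.

## Synthetic data: what it does and does not emulate

The read generator emulates the m¹A footprint: uniform read starts at a
target depth (default 2000×), 50-nt single-end reads (the study's HiSeq
configuration), a site-specific misincorporation mixture (defaults
p_T = 0.60, p_G = 0.12 — "mostly T, less G", totalling ≈72%, the
total-RNA level), balanced strands, uniform sequencing error 10⁻³, and
RT arrest with probability p_trunc = 0.10 (a slight coverage dip).

Arrest is emitted, by default, as a single-base skip of the site (the
read aligns around the site with a 1-base deletion — RT jump-over, a
documented m¹A behaviour). This choice keeps flanking coverage flat so
that site/flank-median = 1 − p_trunc in expectation, making the coverage
drop a clean recoverable parameter. True 5′-clipping at the arrest point
(which produces a one-sided coverage shoulder over a read length, as in
strand-aware RT-stop protocols) is available via `rt_stop_directional`.
Base qualities are constant Q37 unless noise is requested, keeping the
quality-filter tests deterministic.

Not emulated: indels, quality miscalibration, library-prep or coverage
biases beyond the site signature, paired-end structure, and mapping
ambiguity. Passing the recovery tests therefore demonstrates correctness
of the estimators under the stated generative model, not robustness to
real-library artifacts.

The kinetics generator produces logistic OD (carrying capacity 1.5, rate
0.02 min⁻¹, lag 120 min, inoculum 0.015 — a typical 1:100 back-dilution
in rich medium) sampled every 30 min, with fluorescence increments
prod_rate·OD·Δt plus Gaussian noise, 42 replicates by default. In the
noise-free limit the per-minute recovered rate equals the generating
parameter exactly during growth.

All generators take a single integer seed, derive per-replicate /
per-species seeds deterministically (kept below 2³¹), and stamp truth
records with the package version.

## Problem sizes and numerics

Defaults used by the test suite and demo: 400-nt references at 2000–2500×
depth (≈16k reads per sample), 9-species panels at 400 nt, 42 kinetics
replicates over 12 h. These sizes put every boundary and recovery check
well inside 3-SE resolution while keeping the whole suite fast on a
single CPU. Mass comparisons use absolute tolerances (0.01 Da at
two-decimal precision, 0.05 at one); the mass-constant table is rounded
at 5 decimals, so oracle comparisons from full elemental compositions
agree to < 0.0005 Da on ≤ 15-mers. Ties in `match_ions` resolve to the
smallest |Δppm|; zero-variant edge tests return p = 1 without flagging;
degenerate inputs (empty pileups, zero-coverage columns, zero-margin
tables) raise explicit errors rather than propagating NaNs.
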