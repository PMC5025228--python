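# mitomodkit

In-silico toolkit for detecting and characterizing the 1-methyladenosine
(m¹A) modification of mitochondrial 16S rRNA position 947 (mtDNA 2617),
and its bacterial 23S rRNA counterpart (position 1954 in *E. coli*).

m¹A blocks Watson–Crick pairing, so reverse transcriptase either
misincorporates (RNA-seq reads show T or G at the A site) or arrests
(a local coverage dip). These two footprints make the modification
detectable as an RNA–DNA difference (RDD) in ordinary RNA-seq, while
mass spectrometry of nuclease digestion products confirms the methyl
mark directly (+14.0157 Da on the fragment carrying the site).

The package is aimed at epitranscriptomics researchers who want to
reproduce or extend this style of analysis: every stage runs on synthetic
data with machine-readable ground truth, so no sequence downloads are
needed.

## What it computes

- **`rna_mass`** — modification-aware in-silico RNase T1/A digestion
  (2′-*O*-methyl blocks cleavage), monoisotopic masses of modified
  oligomers with explicit 5′/3′ terminal chemistry, negative-mode m/z
  ((M − n·1.0072765)/n), CID product-ion series (c/y/w/a/a−B) and
  ppm-tolerant ion assignment.
- **`rdd_caller`** — strand-aware quality-filtered pileups from SAM, the
  two-stage RDD filter (filter A: ≥ 1000 high-quality reads; filter B:
  secondary base ≥ 1.6% of coverage and ≥ 0.8% of each strand's reads),
  a binomial read-edge-artifact test, the m¹A signature score
  (freq(T)+freq(G) plus the flanking-median coverage drop), and a Pearson
  χ² comparison of modification levels between samples.
- **`conservation`** — local-alignment anchoring of the human site in
  another species' mtDNA and genotype (A vs T) versus RDD tabulation.
- **`edit_design`** — 90-nt lagging-strand MAGE oligo design with terminal
  phosphorothioates, MluCI (AATT) restriction-site detection, RFLP
  fragment-length prediction, overlap assembly of T7 transcription
  templates and run-off transcript prediction.
- **`growth_translation`** — reporter production rate
  r_t = (F_t − F_{t−1})/OD_t, maximal rate, total production (trapezoidal
  area), max sliding-window growth rate of ln OD, replicate averaging.
- **`simdata`** — seed-deterministic generators for references, aligned
  reads with a programmable single-site signature, multi-species panels
  and logistic growth with a noisy proportional reporter.

## Worked example

The RNase T1 fragment of human mitochondrial 16S rRNA spanning positions
939–950 carries the m¹A at position 947. Digest it in silico with RNase A:

```bash
$ mitomodkit mass digest --enzyme rnasea --seq UUCCUUAAm1AUAGp
# mitomodkit v0.1.0; coordinates 1-based inclusive; masses Da
fragment  span_start  span_end  missed  neutral_mass  mz_-1      mz_-2
Up        1           1         0       324.0359      323.0286   161.0107
Up        2           2         0       324.0359      323.0286   161.0107
Cp        3           3         0       323.0519      322.0446   160.5187
Cp        4           4         0       323.0519      322.0446   160.5187
Up        5           5         0       324.0359      323.0286   161.0107
Up        6           6         0       324.0359      323.0286   161.0107
AAm1AUp   7           10        0       1325.2091     1324.2018  661.5973
AGp       11          12        0       692.1105      691.1032   345.0480
```

The methylated tetramer `AAm1AUp` (spanning 945–948 of the parent rRNA)
has monoisotopic mass 1325.21 Da; its doubly charged negative ion sits at
m/z 661.60 and the singly charged CID precursor at 1324.20 — the values
by which the modified fragment is distinguished from its unmodified
counterpart (1311.19 Da, m/z 654.59) in LC/MS.

The all-synthetic demo pipeline simulates a "total RNA" sample and a
"mitoribosome" sample at the same adenosine site, calls RDDs under the
published thresholds and tests the enrichment of the modified fraction:

```bash
$ mitomodkit --seed 0 demo --outdir demo_out
{
  "enrichment": {
    "chi2": 202.63046219393206,
    "p_value": 5.569605486047309e-46,
    "counts": {
      "total_rna": [1153, 486],
      "mitoribosome": [1453, 157]
    }
  }
}
```

Here the non-reference (modified) read fraction rises from ~70% in the
total-RNA sample to ~90% in the mitoribosome sample, and the χ² test
rejects equality decisively — the same qualitative behaviour seen when
mature mitoribosomes are compared against total mitochondrial RNA.
Per-site TSV reports and a JSON report with a provenance block are
written to `demo_out/`.

## Layout

```
src/mitomodkit/    library modules (seq_core, rna_mass, rdd_caller,
                   conservation, edit_design, growth_translation,
                   simdata, cli)
tests/             pytest suite with brute-force oracles
scripts/           acceptance script
docs/methods.md    modelling assumptions, defaults and limitations
```
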