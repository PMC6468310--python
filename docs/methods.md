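# Methods

## The prediction problem

Plastid (chloroplast) genomes are gene-dense, usually circular molecules of
100–200 kb whose genes — like their cyanobacterial ancestors' — are often
transcribed as polycistronic primary transcripts (operons).  Given only an
annotated plastome, `plastoperon` decides for every pair of genomically
adjacent genes whether the two are co-transcribed (an *operon pair*, OP) or
transcribed separately (a *non-operon pair*, NOP), and concatenates
positively classified pairs into a genome-wide operon map.

The decision is made by a supervised random-forest ensemble over
sequence-derived features of each pair.  The feature families exploit the
signatures that separate OPs from NOPs in plastomes:

* **Intergenic distance** — the signed length of the spacer (IGS) between
  the upstream gene's end and the downstream gene's start.  Transcribed
  spacers are short; spacers between transcription units are long.
* **Spacer GC content** — transcribed spacers are AT-rich relative to
  untranscribed ones.
* **Gene-order conservation** — whether the two gene names occur adjacently,
  in the same order and orientation, in a panel of reference plastomes.
  Matching is name-based (plastid gene nomenclature is strongly
  standardized), not homology-based.
* **mRNA folding-energy profile similarity** — a plastid-specific signal:
  the minimum-free-energy (MFE) profile of a 40-nt window slid over the
  region −100..+50 nt around each start codon; OP members tend to have
  correlated profiles (Pearson r), plausibly reflecting co-regulation of
  translation initiation.  Per-position absolute energy margins are also
  exported as features.
* **Coding-sequence comparisons** (CDS pairs only) — Euclidean distance
  between the genes' 59-dimensional relative synonymous codon usage (RSCU)
  vectors, and the absolute difference of Kyte–Doolittle GRAVY scores of
  the encoded proteins.

Because codon- and protein-level features exist only for protein-coding
genes, pairs are split into a **CDS group** (both members CDS) and a
**mixed group** (at least one tRNA/rRNA member), each with its own feature
schema and its own classifier.  Missing features are *omitted* (NaN /
empty cell), never zero-filled; forests consume them through a median
imputer fitted per training split.

## Classifier

For each group, `train_bootstrap` repeats `rounds = 10` times: draw a
simple random (unstratified) 70/30 train/validation split, fit a
1000-tree random forest (scikit-learn defaults otherwise; all per-round
seeds derived from one user seed and recorded in the model), and score
accuracy = (TP+TN)/N on the held-out 30%.  The headline metric is the mean
of the 10 round accuracies.  Genome-wide prediction takes the majority
vote of the 10 round forests; the vote fraction is exposed as a 0–1 operon
score, thresholded at 0.5 with the 5/10 tie resolving to "operon" (a fixed
documented rule rather than platform-dependent rounding).  Opposite-strand
neighbours are classified like any other pair with `same_strand` as a
feature; a strict mode that forces them negative is available at the
assembly layer via the prediction input.

**Feature selection** is wrapped backward elimination: evaluate the current
set by mean cv accuracy, drop the feature(s) with the lowest mean impurity
importance, repeat to exhaustion.  The returned set is the smallest one
within one standard deviation of the best mean accuracy — a deterministic
stand-in for choosing by eye from the accuracy trace, which is returned in
full so a human can override.

**Label-error robustness**: for k = 0..19, flip k labels (type I: 0→1,
type II: 1→0), retrain on the corrupted labels, and score against the
*original* labels; the curve's trend quantifies tolerance to mislabelled
training pairs.

## Statistics

* `permutation_test(a, b)` — two-sided test on |mean(a) − mean(b)|: pool,
  re-split at the original sizes n times, p = fraction of permuted margins
  ≥ the observed one (ties count as extreme, so identical constant groups
  give p = 1).  If p = 0 at n = 10⁴ the test escalates to 10⁵; if still 0
  it reports the censored bound p < 10⁻⁵ with a machine-readable flag —
  never p = 0.
* `empiric_pvalue` — repeatedly draw 50-item subsamples from each group
  (without replacement when the group allows) and report the fraction of
  rounds in which one sample mean exceeds the other; ≈0.5 indicates no
  difference, ≈1 supports the stated direction.
* `enrichment_index((Xi/N − Ki/M)/(Xi/N))` — normalized over/under-
  representation of gene class i among operon genes (Xi operon genes of
  the class, N operon genes, Ki class genes, M genes total); ≤ 1 always,
  −∞ sentinel ("fully depleted") when Xi = 0.  `hypergeometric_enrichment`
  attaches the matching tail probability (upper tail when enriched, lower
  when depleted) under Hypergeom(M, Ki, N), and `bh_fdr` applies
  Benjamini–Hochberg step-up control across classes or features.
* `functional_enrichment_resampling` — scores each multi-gene operon by the
  fraction of its internal adjacent pairs sharing a functional class, under
  the real gene→class map and under a label-shuffled copy.  The returned
  distributions are n_samples resampled draws (for display); the z and p
  come from a two-tailed rank-sum test on the *per-operon* scores.  Testing
  the resampled arrays directly would let z grow with √n_samples on pure
  resampling noise, which is why the test size is the operon count.

## Folding engine

The MFE of a window is delegated to a one-method engine contract.  The
default engine binds the ViennaRNA thermodynamic folder (37 °C, T→U applied
before folding); tests verify each window against the standalone RNAfold
binary to 10⁻⁶ kcal/mol.  When the bindings are absent, a built-in
Nussinov-style base-pair-maximisation folder (GC −3, AU −2, GU −1 kcal/mol,
minimum loop 3 nt) keeps the pipeline functional; it preserves the
properties the pipeline relies on (energies ≤ 0, homopolymers fold to
exactly 0, similar sequences get similar profiles) but its absolute
energies are not thermodynamic.  Profile lengths obey
⌊(L − window)/step⌋ + 1 exactly; profiles shorter than 3 windows make the
similarity feature undefined (omitted).

A caution for users of the similarity feature: adjacent sliding windows
(step 1) overlap 39/40 of their sequence, so profile values are strongly
autocorrelated and the *null* distribution of the Pearson r between two
unrelated profiles is much wider than an i.i.d. intuition suggests
(sd ≈ 0.3 for a 150-nt region).  Classification is unaffected — the OP/NOP
contrast survives — but the r of a single pair should not be read against
N(0, 1/√windows).

## The synthetic-plastome generator

`simulate_plastome(SimConfig)` emits a circular annotated genome with known
truth labels so every stage is testable without downloads.  Defaults (one
seeded rng drives everything):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 60 | genes per genome |
| `class_mix` | CDS .80 / tRNA .15 / rRNA .05 | gene classes |
| `operon_length_distribution` | 1:.35, 2:.20, 3:.20, 4:.15, 5:.10 | operon sizes |
| `op_igs_length` | (30, 12) nt | OP spacer normal |
| `nop_igs_length` | (150, 40) nt | NOP spacer normal |
| `op_igs_gc` / `nop_igs_gc` | 0.22 / 0.40 | spacer GC |
| `fold_profile_correlation_op` | 0.80 | target profile r for OP pairs |
| `rna_monocistron_bias` | 0.70 | P(RNA gene placed monocistronic) |
| `genome_gc` | 0.35 | gene-body base composition |
| `effect_scale` | 1.0 | 0 = OP ≡ NOP (null), 1 = full contrasts |

CDSs are ATG + stop-free GC-tuned codons + TAA (so translation-based
features are always defined); tRNA/rRNA lengths are 75/400 nt.  Operons
occupy consecutive genes on one strand and never cross the origin, so the
wrap pair is always a NOP pair (assembly across the origin is exercised
with crafted labels instead).  `effect_scale` linearly interpolates every
OP parameter toward its NOP counterpart, and the defaults are deliberately
strongly separated ("strong" preset, for fast decisive tests);
`SimConfig.realistic()` gives overlapping distributions closer to real
plastomes.

**Folding-similarity planting.**  For each OP pair in transcription order,
the −100..+50 region of the downstream gene is rewritten as a copy of the
upstream gene's region, mutated at a rate found by bisection until the
profile Pearson r lands in target ± 0.05 (profiles measured with the
configured engine at step 2 inside the generator).  Constraints: the
downstream ATG is preserved, bases belonging to unrelated genes are never
touched, and any stop codons the copy introduces into either gene's frame
are recoded (third base → C) with the terminal TAA restored.  Those frame
repairs make a handful of bases uncopyable, capping the attainable r at a
per-pair "exact-copy ceiling" (typically ≈0.9, occasionally much lower
when a repaired base sits in a high-leverage stem).  When the target
exceeds a pair's ceiling the maximal copy is kept; if more than half of
the operon pairs fall short, the configuration is rejected with an error
suggesting a lower target.  Because the copy overwrites the OP spacer, the
spacer-GC contrast is preserved by giving the copy *source* band (the
spacer tail just upstream of an operon's first start codon) OP-level GC,
so AT-rich spacers propagate down the copy chain; this also dilutes the
NOP spacer GC of operon-preceding spacers slightly (band ≤ 60 nt), which
is visible in the measured NOP GC mean (~0.34 rather than 0.40).

`make_reference_panel` derives shuffled-block annotations from a base
genome, breaking each inter-gene adjacency independently with probability
`rearrangement_rate` before shuffling the blocks — pair conservation then
has a known expectation (≈1 − rate, plus a 1/n chance floor).

**What the generator does not emulate** — and hence what green tests do
*not* establish about real plastomes: RNA editing, introns and spliced
transcripts, transcript processing into isoforms, inverted repeats,
promoter/terminator motifs, real codon-usage structure, and realistic
overlap between OP and NOP feature distributions (the default preset is
nearly separable, so classifier accuracies near 1.0 on synthetic data say
the pipeline recovers planted structure, not that real plastomes are this
easy — reported accuracies on real labeled data are substantially lower).

## Problem sizes and numerical choices

The test and acceptance runs use: a 400-gene training genome with mean
operon size 2 (≈200 OP + ≈200 NOP pairs), 120-gene held-out genomes,
10 bootstrap rounds with 1000 trees for headline accuracy, and reduced
settings (3–5 rounds, 60–200 trees) for the elimination and robustness
sweeps, which repeat training dozens of times; these sizes give stable
statistics while keeping a full run in minutes on one CPU.  The
backward-elimination recovery check uses a directly constructed feature
matrix with five *block-wise* informative features (each separating the
classes only in its own fifth of the samples) against 20 noise features —
redundant informative features would be legitimately discarded by any
sound selector, so non-redundancy is part of the planted design.

Other fixed choices: 0-based half-open coordinates internally (GenBank's
1-based inclusive converted at the boundary); duplicate gene names get a
coordinate suffix; genes with compound locations use the spliced sequence
for sequence features but the outermost span for adjacency; overlapping
genes have negative intergenic distance and no spacer-GC feature; the
plastid (bacterial) codon table 11 throughout; RSCU families with a single
codon (Met, Trp) and stop codons are excluded, giving 59 dimensions, and
absent families contribute zeros; vote ties go to "operon"; all fractions
are reported in [0,1] and all folding energies clamped at ≤ 0.

## Known limitations

* Conservation is name-based; unnamed or non-standard annotations silently
  lose the feature (it is omitted, and pairs failing >50% of applicable
  features are refused rather than classified).
* The fallback folding engine is a structural stand-in, not a
  thermodynamic model; cross-engine absolute energies are not comparable.
* The classifier transfers across genomes only as far as the feature
  distributions do; models trained on the synthetic generator are for
  pipeline validation, not for annotating real plastomes.
* Wrap-origin operons are assembled and flagged, but the generator never
  plants them, so that path is covered only by constructed cases.
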