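# Methods

This note records the models implemented in homoeokit, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
generators do and do not emulate.

## Retention classes

A homoeolog group with copy vector (n_A, n_B, n_C) is classified as

* **triad** iff (1, 1, 1);
* **duplet** iff exactly two subgenomes carry exactly one copy each;
* **singleton** iff exactly one subgenome carries exactly one copy;
* **other_multicopy** otherwise, i.e. whenever any present subgenome
  contributes more than one copy.

The strict single-copy reading of duplet and singleton keeps the four
classes a disjoint, exhaustive partition of all valid copy vectors: a
(2, 0, 0) group is a copy-number variant, not a singleton. Genes that
belong to no homoeolog group are counted as singletons by default — they
have one visible copy in one subgenome, and this choice makes per-class
percentages partition the full per-subgenome totals, which is how
published per-subgenome tables are arranged. It can be disabled
(`ungrouped_as_singleton=False`) to restrict summaries to grouped genes.
Percentages are reported to two decimals with round-half-even; unrounded
fractions are always retained, and the absence-bearing fraction
(duplet% + singleton%) is summed before rounding.

Only three subgenome labels (A, B, C) are accepted; the tool targets
hexaploids and does not attempt to generalize to other ploidies.

## Expression-bias classification

Replicates are collapsed by the arithmetic mean per tissue (median is
available) before filtering and normalization; expression summaries are
per-tissue, and mean TPM is the natural summary for that unit. A triad is
expressed in a tissue when the summed homoeolog TPM strictly exceeds the
threshold (default 0.5 TPM). Non-expressed triads are carried through the
outputs with status `not_expressed` and are never classified.

Seven ideal categories are used: balanced (1/3, 1/3, 1/3), three dominant
vertices, three suppressed edge midpoints. Distances are Euclidean on the
raw 3-vector of proportions (not on planar ternary coordinates; the two
differ only by a global scale, but fixing one convention makes distance
columns reproducible). Ties are broken by centroid declaration order
(balanced, A/B/C-dominant, A/B/C-suppressed) — deterministic and
documented; exact ties have measure zero for continuous data.

Headline fractions pool tissue-observations (each expressed triad × tissue
counts once); per-tissue tables are also emitted, since either pooling can
be found in the literature and the two disagree slightly whenever the
expressed sets differ between tissues.

## 4DTv

A third codon position is counted iff (i) the codon column has no gap, N
or stop in either sequence, (ii) the first two codon positions are
identical between the sequences, and (iii) the shared prefix belongs to
one of the eight fourfold families (Ala, Gly, Val, Pro, Arg₄, Leu₄, Ser₄,
Thr). This is the strictest common convention; it avoids crediting sites
whose degeneracy differs between the sequences. The statistic is the raw
transversion proportion at counted sites — no multiple-hit correction is
applied, since the raw proportion is what comparative studies usually
plot; it is symmetric under swapping the sequences and undefined (flagged,
not an error) when no site is counted.

## NG86 Ka/Ks

Synonymous site counts per codon take, at each position, the fraction of
the three possible single-nucleotide changes that preserve the amino acid.
Changes that would create a stop codon are not synonymous and are folded
into the nonsynonymous fraction, so S + N = 3 per counted codon — this
keeps site totals an exact partition of codon positions rather than a
stop-dependent quantity. Site counts are averaged over the two sequences.
Codons differing at 2–3 positions are resolved by averaging synonymous /
nonsynonymous step counts over all minimal substitution pathways,
excluding pathways through stop codons; when every pathway is blocked the
average falls back to the full pathway set (the conventional fallback).
Proportions p_s = S_d/S and p_n = N_d/N are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is reported as a saturation flag rather
than a number. The estimator choice (NG86 + JC) is the classical counting
method implemented by the common collinearity toolchains; it is fully
specified and checkable against exhaustive pathway enumeration, which the
test suite does for every codon pair with ≤ 2 differences.

Sequences are accepted pre-aligned (equal length, multiple of 3). The
core statistics never depend on an aligner.

## Collinear blocks

Anchors (homologous gene pairs) are chained per chromosome pair by
dynamic programming on 0-based gene ranks. A chain must be strictly
monotone in both rank coordinates (increasing on genome 2 for "same"
orientation, decreasing for "inverted") with at most `max_gap` intervening
genes between consecutive anchors on *each* genome (intervening count =
rank difference − 1). Chains shorter than `min_pairs` are discarded;
defaults are min_pairs = 10 and max_gap = 6. Score is chain length; ties
prefer the smaller total rank span, then the lexicographically smallest
first anchor, then end anchor, with "same" orientation tried before
"inverted" on full ties. Chains are extracted greedily by descending
score, and each anchor joins at most one block. This is deliberately not a
full MCScanX reimplementation (no e-value weighting or tandem-array
handling); it realizes exactly the two printed thresholds with a
deterministic, oracle-checkable algorithm.

## Peak detection

Gaussian KDE (scipy) with Silverman's bandwidth by default, or an absolute
kernel standard deviation, evaluated on an even 512-point grid over a
configured range — (0, 1] for 4DTv, (0, 2] for Ks by default. Peaks are
strict local maxima of the gridded density; peaks closer than two grid
steps are merged, keeping the denser one. At least 10 in-range values are
required.

## Synthetic data

All generators draw from `numpy.random.default_rng` streams derived from
the single mandatory seed (one decoupled stream per stage), and equal
configurations produce byte-identical files.

* **Retention**: classes i.i.d. from a mixture (default 15% triad, 33%
  duplet, 4% singleton, 48% multicopy — a mixture of the magnitude seen in
  hexaploid bamboo retention tables); copy-vector patterns uniform within
  each class, multicopy components bounded by 3.
* **Expression**: the default category mixture follows the headline
  fractions reported for hexaploid bamboo triads (≈37% balanced, ≈23%
  dominant with B rarest, ≈40% suppressed), normalized to sum to 1; two
  tissues (leaf, root) × 3 replicates. True proportions are Dirichlet
  about the category centroid with concentration 200 (zero components
  clipped to 1e-3 and renormalized, because the Dirichlet is undefined at
  zero); a `None`/infinite concentration yields the exact centroid, which
  is the noise-free limit used to verify 100% recovery. Triad totals are
  log-normal (μ = 2, σ = 1 on the log scale, median ≈ 7.4 TPM) floored at
  twice the expression threshold so truth-expressed triads always pass the
  filter; a configurable fraction (default 5%) is instead simulated at 0.1
  TPM total so the not-expressed path is always exercised. Replicate TPMs
  multiply the expected value by log-normal noise with CV 10% (mean 1).
* **Codon pairs**: ancestral codons uniform over the 32 fourfold-family
  codons; each lineage evolves half the pair distance under K80 with
  transition/transversion rate ratio κ (default 2). For a 4DTv target q
  the pair distance is the closed-form inversion
  d = −(κ+2)/4 · ln(1 − 2q), valid for q < 0.5 (larger targets are
  rejected as unattainable); the transition matrix is verified against a
  matrix-exponential oracle in the tests. For a Ks target the distance is
  found by a 1-D root solve on the *exact* expected NG86 estimate,
  computed from the sense-codon transition matrix and the NG86 site /
  pathway tables. Descendant stop codons are rejected by per-lineage
  resampling (the calibration matrices condition on sense codons the same
  way).
* **Gene orders**: blocks of configured size / internal gap / orientation
  are planted into single-chromosome gene orders with a 12-gene spacer
  between regions, so chains cannot bridge plants at the default gap
  budget; optional noise pairs are labelled −1 in the truth table.

What the generators do *not* emulate: read-level sequencing noise, mapping
and quantification error, annotation error, tandem arrays, segmental
duplications overlapping planted blocks, codon-usage and GC heterogeneity,
and selection-driven rate variation among sites. Passing recovery tests
therefore demonstrates correctness of the statistics and algorithms under
their stated models, not robustness to every artefact of real data.

## Problem sizes and tolerances

The test suite and the acceptance script run the stochastic checks at
2,000 triads (bias recovery), 5,000 pairs × 300 codons (peak recovery),
and 500 pairs (Ks calibration) — sizes at which the relevant standard
errors are an order of magnitude below the asserted tolerances (±3
percentage points on category fractions, ±0.015 / ±0.03 on 4DTv / Ks mode
locations, ±15% on median Ks). Retention arithmetic is exact and checked
to the printed two decimals.

## Known limitations

* Hexaploid-specific: exactly three subgenomes.
* NG86 is a counting estimator; codon-model ML estimators (YN00-style)
  are out of scope, as are corrected 4DTv variants.
* Block calling ignores homology scores; anchors are unweighted.
* The CLI reports wall time on stderr only, keeping every output file
  deterministic for a fixed seed.
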