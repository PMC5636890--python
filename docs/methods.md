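# Methods

This note documents the models, parameter choices and numerical decisions
behind `viropop`, stage by stage, and what the synthetic-data tests do and
do not establish about real data.

## Genome discovery

A contig is a virophage (or NCLDV) candidate when one of its predicted
proteins hits a marker reference — the major capsid protein — with bit
score ≥ 50, E ≤ 10⁻³, and an aligned fraction of the reference marker
length ≥ 0.8. All three thresholds are parameters of
`detect_marker_contigs`; marker completeness is measured against the
*reference* length, so a fragmented gene on a long contig is not rescued by
its own length.

Completeness is a pure function of topology and length: circular or
TIR-flanked contigs are complete genomes, linear contigs ≥ 13,000 bp
(the low end of known complete virophage genomes) are near-complete,
everything else partial. Topology detection parameters the underlying
assembly literature leaves open are exposed explicitly:

* **Circularity** — longest exact prefix/suffix match, minimum 20 bp
  (default). On a ~20-kb contig a chance 20-mer terminal repeat has
  probability ≈ L·4⁻²⁰ < 10⁻⁷, so exact matching at 20 bp makes false
  circularity negligible without needing mismatch handling. The overlap is
  capped at half the contig so the two copies are disjoint.
* **TIR** — longest prefix whose reverse complement equals a suffix,
  reported when ≥ 100 bp; mismatch-free by default (a mismatch budget would
  be a natural extension but is not needed for the generator's exact TIRs).
  Calling TIR detection on a circular contig is a precondition violation,
  not a silent "no".

Deduplication links contigs > 99% nucleotide identity (identities are an
input table; alignment itself is out of scope), takes connected components
of the links — so chains of pairwise-similar contigs collapse together —
and keeps the longest member, ties broken by lexicographically smallest id
for determinism.

## Protein clusters and the gene-sharing network

The all-vs-all protein similarity graph (edges at E ≤ 10⁻³, weight
−log₁₀E capped at 200 to absorb E = 0) is clustered with an in-package
dense-matrix **MCL**: unit self-loops after scaling the adjacency to unit
maximum (making the result invariant under global weight scaling),
column-stochastic normalisation, then alternating expansion (matrix power
2) and inflation (entrywise power 2.0, renormalise), pruning entries
< 10⁻⁶, until the largest entrywise change falls below 10⁻⁸ or 200
iterations (non-convergence returns the current clustering with a
warning). Clusters are read from attractor rows; overlapping attractor
supports are merged. Inflation 2.0 is the conventional default; it is a
parameter everywhere MCL is used (protein graph, genome network,
Bray–Curtis network).

PC merging after profile-level comparison is deliberately a literal
single-pass greedy pass: PCs sorted by decreasing size (ties by id), each
unabsorbed seed absorbs its directly-similar unabsorbed partners, and an
absorbed PC never recruits its own neighbours. The procedure is
deterministic under input shuffling.

Gene sharing between two genomes with *a* and *b* PCs out of *N* total is
scored by the exact upper-tail hypergeometric probability, computed in
integer rational arithmetic (`math.comb` / `Fraction`) rather than
floating-point library tails so that the subset-enumeration oracle test can
demand *exact* agreement; a scipy cross-check test keeps the two routes
honest. The significance score is −log₁₀(P · n_comparisons), clamped to 0,
with n_comparisons defaulting to the number of genome pairs actually tested
among retained (≥ 13 kb) genomes — the natural reading of a Bonferroni
correction over the comparisons made; it is overridable. Edges require
score ≥ 9; MCL clusters of ≥ 2 genomes are candidate genera.

Prevalence classes: core = present in all genomes but at most one;
near-core = prevalence strictly > 0.68 (a parameter; the 68% figure is an
observed prevalence in the motivating data, not a theoretical constant);
signature(genus) = present in 100% of a cluster's members and 0% of
non-members, with singleton clusters excluded. Note core and near-core can
only coexist as distinct classes when the genome count allows a prevalence
strictly between 0.68 and (n−1)/n — for n ≤ 9 the band is empty.

Gene affiliation is a strict tier cascade (reference virophages → other
viral/cellular → peer virophages excluding the gene's own genome and its
>99%-identical duplicates → ORFan), and genome-level affiliation by
signature votes requires at least one vote and a strict majority; ties are
unaffiliated.

## Population genetics

SNPs are called on pileups pooled across all samples/time points: any
non-reference allele with ≥ 4 supporting reads is a SNP, each qualifying
alternate allele reported separately. Fixed differences from the assembly
consensus (reference count 0) are counted as SNPs, as an
mpileup-based pipeline would. Indels are out of scope; only substitutions
are modelled, and no minimum allele *frequency* is applied beyond the
absolute count.

Coding classification translates the codon containing the site in coding
orientation (minus-strand genes reverse-complemented); stop gain/loss is
non-synonymous, stop-to-stop synonymous. A SNP inside overlapping genes is
classified independently per gene and flagged; densities count the site
once. Expected site counts are Nei–Gojobori with equal rates — each codon's
9 single-nucleotide mutations are labelled, and each position contributes
its synonymous fraction — because the neutral model is not further
specified; site counts per codon sum to exactly 3. pN/pS = (n_obs/n_sites)
/ (s_obs/s_sites) and is *undefined* (reported with a reason, never 0 or ∞)
when fewer than `min_syn` = 1 synonymous SNPs were observed.

The per-gene pN/pS ratio estimator is biased upward at low synonymous
counts (Jensen's inequality applied to 1/s_obs): at ~11 expected synonymous
SNPs per gene the mean ratio under neutrality is ≈ 1.14, at ~22 it is
≈ 1.05. The parameter-recovery simulations therefore use 120 planted SNPs
on 400-codon genes, where the estimator mean sits within [0.9, 1.1] while
the ω = 0.2 condition still yields pN/pS < 0.5 almost surely. This is a
property of the estimator, not of the implementation; real low-polymorphism
genes carry the same bias.

## Dynamics and associations

Coverage is normalised per Gbp sequenced; detection requires breadth
strictly > 0.75. Z-scores use the sample standard deviation (ddof = 1,
so (1,2,3) → (−1,0,1)); constant series return zeros with a degenerate
flag, and missing values are ignored in the moments and propagated.

The Bray–Curtis stage mirrors its source: similarities = 1 − dissimilarity,
a null built from 10 matrices in which every row is independently permuted
across samples (preserving marginal abundance distributions, destroying
temporal coupling), threshold = the maximum null similarity (the most
conservative quantile; the quantile is a parameter), edges above threshold,
MCL clusters, and virophage–host pairs read from co-clustering. The
empirical threshold is recomputed per data set, never hard-coded.

**LSA** rank-transforms both series to Blom normal scores
(Φ⁻¹((rank−3/8)/(n+1/4)), average ranks on ties) and maximises the
contiguous partial sum of aligned products over offsets |d| ≤ 3, tracking
positive and negative association separately; the score is the maximum
divided by n. Significance is by seeded permutation of one series (2,000
permutations by default, p = (1+exceedances)/(1+B)), with
Benjamini–Hochberg q-values across all tested pairs — a deliberate,
documented divergence from the theoretical-approximation p-values used at
full scale, appropriate at desk scale. Consequence: p-values are bounded
below by 1/(B+1), so the full-scale filter p, q ≤ 10⁻⁵ (kept as the
default of `filter_lsa_pairs`) is unreachable under permutation; the
synthetic end-to-end pipeline uses the desk-scale analogues p ≤ 0.005 and
q ≤ 0.05 (the conventional FDR level; with B = 1000 and ~125 pairs the
attainable q floor is ≈ 0.025), with the span rule ≥ 30 of 45 samples
unchanged.

WGCNA is not reimplemented: the combiner ingests an external
(entity, module) table. For synthetic runs `emulate_wgcna_modules`
reproduces the shape of the procedure — Hellinger normalisation, log
transform, soft-thresholded adjacency |r|^12 — and reads modules off
connected components of adjacency > 0.25 (≈ |r| > 0.89). Because modules
are computed from the data rather than looked up from planted truth, decoys
can in principle enter modules, keeping the end-to-end recovery test
non-circular.

Combination priority: rank 1 = all three methods; rank 2 = WGCNA ∧ LSA;
rank 3 = exactly one of WGCNA/LSA; pairs supported only by the Bray–Curtis
network rank 4 (the motivating analysis found no BC-only detections);
within a rank, delay-0 pairs precede lagged ones. Pearson correlation
screening uses pairwise-complete samples and excludes degenerate series.

## Motif scanning

Upstream regions are the 30 nt 5′ of each CDS in coding orientation,
truncated (and flagged) at linear contig edges, wrapped on circular
contigs. Scanning is ambiguity-aware Hamming: a window position matches
when its base is in the IUPAC set of the pattern character — full match or
mismatch, no partial credit — with a budget of 1 mismatch by default, on
both strands (reverse-strand hits are found with the reverse-complemented
pattern and reported at forward coordinates). De novo discovery is out of
scope; motifs are inputs, with an optional AT-rich filter rejecting motifs
whose positions are > 85% A/T-only codes (the cutoff is a parameterised
stand-in, since "AT-rich" has no canonical definition).

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions of the test suite.

* **Gene content.** 4 core PCs (exactly one genome missing one, mirroring
  the "all but one" core definition), 4 near-core PCs at presence
  probability 0.9 (with realised prevalence re-drawn into the valid
  near-core band when the genome count makes it realisable; otherwise the
  planted class records the construction intent), 10 signature PCs per
  genus, and 4 accessory PCs per genome from a pool of 150. These counts
  were derived analytically from the hypergeometric tail *before* running
  recovery tests: with ~21-gene repertoires in a ~190-PC universe,
  within-genus sharing (≥ 14 PCs) scores ≥ 9.7 even in the worst case,
  while cross-genus sharing (≤ 11 PCs, core + near-core + chance accessory
  overlap) never exceeds ≈ 3.5 — so the score-9 network threshold separates
  genera by construction, which is precisely the regime the taxonomy
  claims to operate in.
* **Proteins and genes.** Each PC has a random ancestor protein
  (150–300 aa); members are per-site mutated copies (rate 0.02, keeping
  within-family identity ≈ 96%, far above similarity-detection cutoffs)
  reverse-translated through uniformly chosen synonymous codons, laid out
  with random spacers and strands. Genome ends carry a 30-bp terminal
  repeat (circular), a 120-bp TIR, or nothing, cycling within each genus.
* **Reads.** The aligner is out of scope, so alignment *summaries* are
  emitted directly. Identities follow a sequence-discrete mixture: 83% of
  mapped reads in the ≥ 99%-identity core class, 17% in a 95–99% cloud,
  optional cross-population reads below 90% (weight 0 by default). Pileups
  draw Poisson coverage and binomial alternate counts at planted allele
  frequencies, plus uniform per-base errors.
* **SNPs.** Planted by uniform proposal over gene positions and alternate
  bases — exactly the equal-rate neutral model the site counting assumes —
  with non-synonymous proposals accepted at probability ω.
* **Abundances.** Each planted pair shares a smooth latent log-signal
  (Gaussian-filtered noise, correlation time σ = 1 sample — chosen so
  independent decoy pairs keep |r| < 0.5 about 95% of the time at 45
  samples, the separability regime the association stage assumes); the
  virophage copy is delayed by the pair's lag (0–3), log-normal noise
  (sd 0.3) is added, and each entity is zeroed during its own lowest-15%
  latent period, emulating seasonal non-detection. Decoys are independent.
  Environmental covariates (temperature sinusoid, chlorophyll a, DOC) are
  emitted for the z-score/association interfaces.

Not emulated: assembly artifacts and chimeras, read quality, indels,
mapping bias, compositionality of relative abundances, shared environmental
forcing of non-interacting taxa, and uneven sampling intervals. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under its own assumptions — not that real lake communities
satisfy those assumptions.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 1,000 (tests) / 300
(script) hypergeometric oracle instances at N ≤ 12; all 64 codons; 200
genes × 120 SNPs per pN/pS condition; one ~10-kb genome × 2 samples for the
SNP caller; 20 seeded designs (2–4 genera, 6–12 genomes) for genus
recovery; 500 (tests) / 200 (script) brute-force LSA instances at n ≤ 25
plus 100 lag-2 replicates; 20 seeded 45-sample association runs with 5
planted pairs and 20 decoys (B = 1000 permutations); 200 null pairs at
B = 500 for calibration. The full suite runs in ~25 s, the script in
~25 s, on one CPU.
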