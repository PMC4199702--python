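# Methods

## Model

A biparental selfed population descends from a uniformly heterozygous F1.
For a pair of linked loci the ten genotypes reduce, by the symmetry of
selfing, to five classes: (1) parental fixed, (2) recombinant fixed,
(3) one locus still segregating, (4) coupling-phase double heterozygote,
(5) repulsion-phase double heterozygote.  One generation of selfing is a
Markov chain on these classes with transition matrix **T**(r, h):

* classes 1 and 2 are absorbing;
* a class-3 parent's segregating locus resolves as
  (1−h)/2 : h : (1−h)/2 over the two homozygotes and the heterozygote,
  where h is the per-generation heterozygosity retention (h = 0.5 is
  Mendelian segregation);
* a class-4 (or 5) parent's offspring classes are weighted
  2(1−r)² : 2r² : 8ur(1−r) : 2u²(1−r)² : 2u²r² (phases swapped for class 5),
  normalised by d = 2(1−r)² + 8ur(1−r) + 2r² + 2u²[(1−r)² + r²],
  where u is the relative viability of a heterozygous genotype.

u is not a free parameter.  It is fixed, per (h, r), by requiring that the
heterozygosity retained across the class-4/5 transition equal h:
h = p(class 3)/2 + p(class 4) + p(class 5).  Substituting the transition
entries gives 2a(h−1)u² + b(2h−1)u + 2ah = 0 with a = (1−r)² + r² and
b = 4r(1−r).  For h ∈ (0, 1) the leading coefficient is negative and the
constant term positive, so exactly one positive root exists; it is taken in
closed form.  At h = 0.5 the root is u = 1 at every r and the whole model
collapses to the classical Mendelian selfing recursion (verified to 1e-12
against an independently coded classical recursion for t ≤ 20).

Class probabilities at generation t are obtained by applying **T** (t−1)
times to (0, 0, 0, 1, 0)′.  We iterate numerically rather than using a
symbolic eigendecomposition: for any practical t this is exact to machine
precision and avoids transcribing a closed form that cannot be
cross-checked.  The observable 3×3 genotype-pair table unfolds from the
class vector assuming members of a class are equiprobable (the same symmetry
that justifies the collapse); the two double-heterozygote phases merge into
the centre cell because they cannot be distinguished by unphased genotypes.
Both marginals of the table equal H = h^(t−1), which is also the identity
used to estimate h from data: h = exp(ln H/(t−1)).

### Assumptions

* A single h applies to all loci and generations (a global average; real
  populations show regional variation in heterozygosity).
* The population is a single F_t; mixed-generation panels are treated by
  choosing one effective t.
* No crossover interference (Haldane mapping), no mutation, no gene
  conversion.
* Marker order is taken from physical positions; no de novo ordering.

## Estimation

Per adjacent marker pair, individuals missing at either marker are dropped
(pairwise, not listwise, to keep every informative observation) and the 3×3
count table is formed.  The multinomial log-likelihood under the model table
at (h, t) is maximised over r by golden-section search on
[1e-6, 0.5 − 1e-6] to a tolerance of 1e-6 (≈30 iterations; the likelihood
is smooth and, in every case we have exercised, unimodal — a 10^5-point grid
search agrees to 1e-4 in the test suite).  Degenerate single-cell tables
yield a boundary estimate with a warning rather than an error.  Estimates at
the upper bracket end mean "no linkage detected"; map assembly refuses to
sum them and names the offending pairs.  Map positions are cumulative
Haldane distances anchored at 0 at each chromosome's first marker;
map-length differences are also reported as recombinations per meiosis via
the 50 cM ↔ 1 recombination reporting convention.

Fitting data generated under h > 0.5 with the Mendelian model biases r̂
upward at t = 7 (map expansion); the direction reverses at small t (t = 3),
where unmodelled excess heterozygosity instead causes underestimation.  Both
directions are asserted in the test suite from expected-count tables.

## Quality control

Order: missingness (markers, then individuals, threshold ≥60% by default) →
duplicate-individual collapse (genotype concordance ≥90% over mutually
non-missing markers, connected components, keep the least-missing member,
ties by input order) → redundant-marker collapse (consecutive markers within
2 kbp with identical genotype vectors on shared individuals; keep the
least-missing) → tight-double-recombination masking → outlier-individual
flagging (Tukey fences, k·IQR with k = 3, on per-individual A/H/B
proportions; removal is opt-in) → segregation-distortion filtering with
iterative re-estimation of H.

The distortion test is a df-2 chi-square against expected proportions
((1−H)/2, H, (1−H)/2).  Using the observed H as the null instead of the
Mendelian H is the point: under excess heterozygosity a Mendelian null
wrongly rejects well-behaved markers genome-wide.  P-values are compared on
the log scale (`chi2.logsf`) so thresholds like 1e-30 — far below where the
p-value itself underflows — remain meaningful.  Per-chromosome threshold
overrides accommodate regions with known biological distortion.  The
iterative filter re-tests the original marker set each round with the
updated H and stops when the retained set is stable (two passes in
practice).

Masking: a run of identical calls whose nearest non-missing flanks agree
with each other, differ from the run, and lie within a window (2 kbp
physical, or 2 cM given a map) is set to missing — such tight double
recombinations are overwhelmingly genotyping errors.  Missing calls are
transparent; chromosome ends are never masked; masking repeats until stable
(removing a run can fuse its neighbours into a new tight pattern), which
also makes the operation idempotent.  Masking only ever sets calls to
missing.  The choice of flank-to-flank (rather than interior-run) span for
the window is a documented convention.

A caveat observed on simulated data: on a *short, dense, single* linkage
group, genuine RILs can share >90% of genotypes by descent (a few large
blocks dominate), so the duplicate filter and the outlier flagger are only
meaningful when genotypes sample many independently segregating regions —
as they do on a real multi-chromosome genome.  Tests of "clean data passes
QC untouched" therefore use widely spaced markers.

## Simulation

`simulate_population` (the primary generator) draws each individual's
genotypes as a first-order Markov chain along the chromosome: marker 1 from
the single-locus marginal ((1−H)/2, H, (1−H)/2), each next marker from the
conditional of the model's adjacent-pair table at the equal-spacing r.  By
construction the simulated data obey *exactly* the marginal and adjacent
pairwise distributions the estimator assumes, which makes
simulation-estimation round trips well-posed; dependence beyond adjacent
pairs is only first-order, and no genotyping-error correlation structure is
modelled (errors and missingness are i.i.d., symmetric across codes).
Defaults are the reference experiment: 1000 individuals, 1000 markers,
200 cM, t = 7, h = 0.6373, no noise.  Physical positions are synthetic
(10 kb spacing).

`simulate_forward` is a deliberately independent oracle: explicit
generation-by-generation single-seed descent from an all-heterozygous F1,
gametes formed with per-interval recombination, offspring accepted by
rejection sampling against a viability weight.  In `class_conditional` mode
(two loci) offspring of double-heterozygous parents are weighted u^k (k =
offspring heterozygous loci, u from the viability constraint at the pair's
r) and offspring of single-heterozygous parents are weighted v^k with
v = h/(1−h) — the weight that retains heterozygosity at rate h at an
isolated segregating locus.  This parent-conditional weighting is what the
class model actually implies: a single constant per-locus viability cannot
reproduce both the class-3 and the class-4/5 columns simultaneously, because
the u that satisfies the double-heterozygote constraint differs from
h/(1−h).  A `per_locus` constant-u mode is retained for the plain multilocus
viability interpretation (any number of loci); it matches the
double-heterozygote transitions only.  The oracle agrees with the matrix
iteration within Monte-Carlo error at 10^5 lines across
(r, h, t) ∈ {0.05, 0.2} × {0.5, 0.6373} × {2, 7}.

We also probed a genome-wide multiplicative viability u^(#het loci) over
1000 tightly linked markers: selection on whole-genome heterozygote count
under tight linkage retains vastly more heterozygosity than the per-locus
target (H ≈ 0.85 instead of 0.067 at F7 with u = h/(1−h)), so no principled
single-u forward simulation of the full-scale experiment exists; the chain
generator is the defined study condition.

## Numerical choices

* Probability comparisons at 1e-10 absolute unless stated; transition
  columns sum to 1 within 1e-12 across the tested (r, h) grid.
* Golden-section bracket [1e-6, 0.5 − 1e-6], tolerance 1e-6.
* r = 0 and r = 0.5 need no special-casing: the viability quadratic and all
  transition entries are well-defined there (d > 0 always).
* Chi-square p-values on the log scale for extreme statistics.
* All randomness flows from a single integer seed per run
  (`numpy.random.default_rng`); simulator output is bit-reproducible.

## Problem sizes

The reference simulation experiment runs at full size (1000 × 1000, three
replicates) in the acceptance script and test suite — roughly 20–25 s on one
CPU.  Stochastic cross-checks (forward oracle, chain marginals, noise rates)
use 4×10^4–10^5 lines with 3-standard-error bands; MLE consistency uses 200
replicates of n = 1000 per r value.  These sizes were chosen so every
stochastic assertion has comfortable power while the whole suite stays
interactive.

## Known limitations

* h is global; per-marker-pair or per-region heterozygosity modelling is out
  of scope (a single population-level or per-linkage-group h is supported).
* The likelihood is pairwise (adjacent markers), not a multipoint HMM, so
  genotyping error is handled by QC masking rather than by an error term in
  the emission model.
* Only the Haldane mapping function is provided.
* The chain simulator's higher-order (beyond adjacent-pair) dependence is an
  approximation to a true forward process; conclusions that hinge on
  long-range genotype correlations should use the forward oracle at small
  marker counts.
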