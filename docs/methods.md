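# Methods

## SSR detection

A perfect SSR is a maximal tandem repeat of a primitive motif of 1–6 bp
reaching a per-unit-length minimum repeat count (defaults 10/6/5/5/5/5 for
mono- through hexa-nucleotides, the MISA convention; the phrasing "more
than 10X" in common usage means *at least* 10 — a strict-greater mode is a
config switch).  Only whole repeat units count toward a tract, coordinates
are 1-based inclusive, and a tract reportable at several unit lengths is
reported once at the smallest unit length whose motif is primitive, at the
leftmost whole-unit alignment of the periodic run.  `N` breaks any tract;
other IUPAC ambiguity codes are rejected at parse time; soft-masked
(lowercase) input is uppercased.  Perfect loci separated by at most
100 bp (configurable) are additionally reported as one compound locus;
headline counts use perfect loci only, with compounds in their own
category.

Motif classes are strand- and rotation-invariant: the class of a motif is
the set of its cyclic rotations together with the rotations of its reverse
complement, labelled by the lexicographically smallest rotation of each
strand (`CGG → CCG/CGG`); self-complementary classes collapse to a single
label (`AT`).  The miner is verified exactly — tract set equality — against
an independent character-scan enumerator on thousands of random sequences,
and against planted tracts with known coordinates.

## Assembly length summaries

N50 (N90) is the length at which the descending cumulative length sum
first reaches ≥ 50% (90%) of total bases.  Some tools use a strict `>`
threshold, which can differ on exact ties.  Printed per-assembly mean
lengths are reproduced with round-half-away-from-zero to whole bp; raw
means are retained internally.

## Dominant-marker informativeness

Bands are scored 0/1 per accession × fragment; each fragment belongs to
one primer pair.  With band frequency *f* per fragment:
PIC = 2*f*(1−*f*) ∈ [0, 0.5] and Ib = 1 − 2|0.5 − *f*| ∈ [0, 1], both
symmetric in *f* ↔ 1−*f*.  Per primer: PIC is the unweighted mean over
its fragments; NPF counts fragments with 0 < *f* < 1; PP = NPF divided by
all scored fragments (monomorphic-absent lanes stay in the denominator,
configurable); EMR = PP × NPF with PP as a proportion, not a percent;
MI = PIC × EMR; Rp = ΣIb.  Panel tables are unweighted means of
per-primer values within primer groups (repeat type or repeat count) —
group-level aggregates are therefore not recomputable from one another's
means, which is worth remembering when comparing to published panel
tables that only print the group means.

## Diversity indices

Each fragment is treated as a biallelic locus with band(+) allele
frequency p and null allele q = 1 − p.  Under the default `dominant_hwe`
model the band-absent fraction of accessions estimates q², so q = √(1−P);
the `phenotypic` mode takes p = P directly and is offered because bulked
DNA templates (many plants pooled per accession) weaken the per-accession
HWE premise.  Per locus: Na = alleles with frequency > 0, Ne = 1/(p²+q²),
I = −Σ p ln p (natural log), He = 2pq.  Group tables compute P within
group per locus, average indices over loci unweighted, and add an
unweighted mean row over groups; each accession's banding profile is one
sampled unit.  Absolute index values depend on which allele-frequency
model is chosen, so cross-study comparisons should fix the model first.

## Distances, UPGMA, bootstrap, ΔK

Genetic distance between band profiles is 1 − 2a/(2a+b+c) (a shared
presences, b and c private presences) — the Dice/Nei–Li band-sharing
distance; two all-absent profiles are at distance 0 by convention.  UPGMA
merges the closest pair, updates distances by size-weighted means, and
places each merge node at half the merge distance, yielding an ultrametric
tree; ties in merge order are broken by the lexicographically smallest
pair of cluster labels (smallest member leaf) so results are deterministic.
The implementation is checked for exact topology-and-height agreement
against a naive O(n³) re-averaging oracle and against SciPy's average
linkage.

Bootstrap support resamples fragments (band columns) with replacement —
the only exchangeable unit for dominant data — rebuilds distance + UPGMA
per replicate (default 1000), and reports for each original clade the
percentage of replicates containing the same leaf set.  Rendered Newick
suppresses supports ≤ 40% by default while the tree object keeps all of
them.  The Evanno helper computes ΔK = |L′(K+1) − L′(K)| / sd(L(K)) from
replicate mean ln-likelihoods per K (≥3 consecutive K, ≥2 runs each; zero
sd is an error since ΔK is then undefined).

## Phenotypes, PCA and Mantel

Traits are in heterogeneous units (cm, mm, g/plant, days, counts), so
Euclidean distances and PCA default to z-scored traits (sample sd,
ddof = 1); a raw-scale flag is exposed since published analyses do not
always state their choice.  CV% = 100·sd/mean; zero-variance traits are
dropped from distance/PCA with a warning; zero-mean traits get an
undefined CV flag.  PCA is an eigendecomposition of the correlation
(standardized) or covariance matrix, with component signs fixed by making
each loading vector's largest-magnitude entry positive.

The Mantel statistic is the Pearson correlation of upper-triangle entries
of two distance matrices over identically ordered labels; the null
distribution permutes rows and columns of the second matrix
simultaneously; the test is one-sided for positive association with the
+1 correction p = (#{r\* ≥ r} + 1)/(B + 1), B = 999 by default.  The
per-trait variant builds a single-trait standardized Euclidean matrix per
trait.  The statistic is validated against scikit-bio's implementation
and its type-I error against the permutation grid (empirically 0.04–0.05
at α = 0.05 over 2000 null replicates).

## Synthetic data

The generators emulate the three data layers of an EST-SSR diversity
study and emit machine-readable ground truth; all are deterministic given
a seed.

* **Transcriptome** — i.i.d. background bases at configurable GC; SSR
  tracts planted at a Poisson rate per kb (default 1/7.8 kb, a typical
  grass-transcriptome density) with motif-class weights favouring C/G-rich
  tri-repeats as seen in coding sequence.  The bases flanking each planted
  tract are chosen to break the repeat periodicity on both sides, so the
  miner reports exactly the planted coordinates; a density that cannot
  physically fit its tracts raises an error.  Background sequence can
  still contain chance repeats; those are confirmed against the
  brute-force oracle rather than counted as false positives.
* **Band matrix** — per fragment an ancestral band-allele frequency p₀
  (Beta-distributed, clipped away from fixation to keep loci informative);
  per group g a frequency from the Balding–Nichols distribution
  Beta(p₀(1−θ)/θ, (1−p₀)(1−θ)/θ), so one θ ∈ (0,1) controls divergence
  (θ → 0 is panmixia).  An accession carries the band with probability
  1 − q_g² — the same dominant-HWE mapping the diversity module inverts,
  which closes the parameter-recovery loop.  Optional Dirichlet admixture
  mixes group frequencies per accession.  Default panel shape mirrors a
  small diversity study: 52 primer pairs averaging 3 fragments, K = 3
  groups of 8 accessions (24 total).
* **Phenotypes** — trait = w · (standardized ±1-weighted sum over a random
  locus subset) + (1−w) · Gaussian noise.  w = 0 gives pure noise (Mantel
  r centred at zero, rejection rate ≈ α); r increases monotonically in w.
  Because 11 traits are a low-rank random projection of the band space, a
  fully genetic 11-trait table plateaus around r ≈ 0.6–0.75 at moderate
  divergence; r > 0.8 requires a strongly divergent panel and a
  trait-richer table, and the tests exercise exactly that configuration.

What the simulations do *not* model: linkage disequilibrium between
fragments, scoring errors/missing bands, size homoplasy of co-migrating
fragments, and expression-level effects — so green tests demonstrate
correctness of the estimators under the stated generative model, not
robustness to those real-data artefacts.

## Problem sizes and numerical choices

The shipped checks use 1000 random sequences of 0.2–3 kb for miner-oracle
equivalence, 500 random matrices (n ≤ 7) for UPGMA-oracle equivalence,
2000 null replicates × 199 permutations for Mantel type-I calibration,
500 accessions/group for He recovery (observed max error < 0.01 against
the analytic 2pq), and K = 3, θ = 0.5, 30 accessions/group × 1000
bootstraps for group recovery — sizes at which every stochastic check is
comfortably away from its threshold while the whole battery runs in well
under a minute.  Ultrametricity and cophenetic identities are asserted at
1e−9; PCA score/distance agreement at 1e−8.  Pipeline stages draw their
seeds from a single master seed via `numpy` SeedSequence spawning, and a
run manifest (config snapshot, input/output checksums, per-stage seeds
and timings) makes re-runs skip unchanged stages and reproduce stochastic
outputs byte-identically.

## Known limitations

* Imperfect (interrupted/approximate) SSRs are not detected; compound
  merging is the only concession to interruptions.
* Co-dominant genotypes, F-statistics/AMOVA and admixture inference are
  out of scope; the ΔK helper only post-processes externally computed
  ln-likelihoods.
* Published study-level absolute values that depend on unpublished raw
  band matrices (panel-mean PIC, distance ranges, per-trait Mantel r)
  can only be checked structurally, not numerically.
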