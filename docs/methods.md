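# Methods

## The model

A *coding system* is a pair of stochastic matrices. The **code matrix**
`P` (64 × 21) gives, for each of the 64 DNA codons, a probability
distribution over 21 encoded labels — 20 amino-acid-like items plus a
stop-like item, all treated identically and without any physicochemical
properties. The **reading matrix** `R` (21 × 3) gives, for each label, a
probability distribution over three codon-reading mechanisms that differ in
how sloppily a codon is recognized:

* **M1** (wobble-like): the neighborhood of a reference codon contains the
  codon itself plus the 3 codons differing only at the third position
  (|N1| = 4);
* **M2**: the codon plus the 6 codons differing at exactly one of the first
  two positions (|N2| = 7);
* **M3**: the codon plus all 9 single-nucleotide variants (|N3| = 10).

Which position M1 varies is configurable (`m1_position`, default the third
position, matching biological wobble); M2 then varies the other two.

Codons are indexed 0–63 by `16·b1 + 4·b2 + b3` with A=0, C=1, G=2, T=3.
Nothing in the model depends on this choice; it is fixed so that serialized
matrices are bit-reproducible.

### Coding strength

For each label `l` the *Bayes-path codon* `c_l` is the codon maximizing the
posterior P(c | l) under a uniform prior over codons — equivalently the
argmax of column `l` of `P`, ties broken to the lowest codon index (the
posterior, hence the path, is invariant under rescaling a column). A
reading mechanism `j_l` is drawn from row `l` of `R`, and the fitness is

    F = prod_l  ( r[l, j_l] / |N_{j_l}(c_l)| ) · sum_{c' in N_{j_l}(c_l)} p[c', l]

Each factor is the joint probability that the label's neighborhood is
chosen and that a codon in it encodes the label, normalized by the
neighborhood size. The product form is identical to the literal sum of
products over all combinations of one codon per label, because the 21
neighborhood sums range over disjoint product dimensions; the test suite
verifies this against exhaustive enumeration on small label subsets.

F rewards codes that concentrate coding probability inside the chosen
neighborhood of the path codon, and reading rows that commit to the
mechanism whose neighborhood the code actually fills. Because M1 divides by
4 where M2 divides by 7 and M3 by 10, a maximally concentrated code favors
wobble-like reading — this is the error-minimization pressure that drives
the emergent block structure.

All fitness arithmetic is in natural-log space: a random initial system has
F around e^-90, far below double-precision underflow for a 21-factor
product. A factor of exactly zero yields log F = −∞; such individuals are
valid and rank below every finite-fitness individual.

Two evaluation modes exist. `sampled` (default) draws one mechanism per
label per evaluation, as above; the reading draw is refreshed every
generation for every individual, which makes the reading distribution
itself selectable. `expected` replaces each factor by its expectation over
the draw, `sum_j r[l,j]² / |N_j| · S_j` — the square arises because the
sampled factor already carries the draw probability linearly. Expected mode
is deterministic for a fixed individual and is used for regression tests
(with elitism it gives a provably non-decreasing best-fitness trajectory).

### Quality measures

* `Hc = −Σ_c Σ_l p log p` — sum of row entropies of the code matrix
  (0 … 64·ln 21 ≈ 194.85 nats): coding ambiguity.
* `Hr = −Σ_l Σ_j r log r` — same for the reading matrix
  (0 … 21·ln 3 ≈ 23.07 nats): reading ambiguity.
* Expected labels per mechanism, `E_j = Σ_l r[l,j]`; the three components
  sum to 21. A fully homogeneous wobble system gives (21, 0, 0).
* **Codon blocks** at threshold t: `block(l) = {c : p[c,l] > t}` with a
  strict inequality, default t = 0.8. Above t = 0.5 the blocks are
  pairwise disjoint. Size-0 blocks are reported, so early snapshots are
  representable.
* `m1_consistency`: the fraction of non-empty blocks whose codons all share
  the first two positions (i.e. fit inside one wobble family).
* The reference spectrum of the standard genetic code (NCBI translation
  table 1) for comparison: 5 four-codon, 9 two-codon, 2 one-codon and
  3 six-codon amino acids; isoleucine and the stop signal have three codons
  each; each six-codon family is organized as a 4 + 2 pair of subgroups.

## The evolutionary algorithm

A population of coding systems is initialized with every row drawn from the
flat Dirichlet — the maximum-entropy distribution on the simplex,
representing fully ambiguous primordial assignments. Each generation:

1. every individual's log-fitness is evaluated (fresh reading draw in
   sampled mode, elites included);
2. tournament selection with elitism fills the next generation: the
   `elite_count` fittest individuals are copied unchanged, each remaining
   slot is filled by the best of `tournament_size` uniform draws with
   replacement (ties resolve uniformly among tied entries; if every
   individual is at −∞ the procedure degenerates to uniform copying and a
   warning is logged);
3. each non-elite row of each matrix is, independently with its mutation
   probability, resampled from `Dirichlet(κ · row + 0.01)` — a kernel
   centered on the current row whose spread is controlled by the
   concentration κ, with a small floor keeping the support full.

Tournament selection is scale-free, which matters because log-fitness spans
hundreds of log units early in a run; fitness-proportionate selection
degenerates numerically there.

### Why two mutation concentrations

The code matrix and the reading matrix play different dynamical roles and
get different κ defaults:

* **Code rows** (`mutation_concentration = 200`): a high concentration
  makes mutation a small, smooth perturbation (total-variation step of a
  few percent), so codon assignments sharpen gradually — code entropy
  declines over thousands of generations, as a gradual reduction of coding
  ambiguity should.
* **Reading rows** (`mutation_reading_concentration = 0.05`): a near-zero
  concentration makes mutation approximately a fresh draw from
  `Dirichlet(0.01, 0.01, 0.01)`, i.e. a reset to a random near-corner of
  the simplex. Reading rows are under very strong direct selection (the
  draw probability multiplies every fitness factor), so any committed row
  stays committed through selection alone; what the reset kernel adds is
  continual re-testing of the alternatives. Without it, a label that
  happens to commit early to a sloppier mechanism is frozen by the
  self-reinforcement of the draw probability before the code is
  concentrated enough for the wobble advantage (1/4 vs 1/7 vs 1/10
  normalization) to decide the competition; with it, wrongly committed rows
  keep being re-exposed to selection and the wobble mechanism takes over
  label by label.

The per-row mutation probabilities default to 0.02 per generation for code
rows and 0.3 for reading rows. The asymmetry has the same rationale as the
kernel asymmetry: a reading row that commits to a sloppy mechanism while
the code is still diffuse must be re-decided many times before the label's
codon block starts to grow, because the first block codon recruited under
M2 reading lands in an M2-neighborhood position and makes the wobble flip
locally deleterious from then on (a coadaptation trap). High reading churn
maximizes the number of re-decisions inside that window. The tournament
size default of 4 strengthens per-flip selection against the
Hill–Robertson interference that a 21-locus genome without recombination
experiences in a population of hundreds.

Even so, complete fixation of wobble reading for all 21 labels within a
scaled-down run is stochastic: a minority of labels can end wobble-
inconsistent because their coadaptation trap closed early. This mirrors
the full-scale dynamics, where the intermediate mechanism persists for a
substantial fraction of the run before disappearing, and is the main
respect in which the scaled protocol under-delivers relative to the
reference one.

### Randomness and reproducibility

One master seed spawns four independent named PCG64 streams —
initialization, reading draws, mutation, selection — so switching one
operator off does not shift another's draws. Runs are bit-reproducible
from the configuration alone; artifacts (trajectory TSV, matrix TSVs,
summary JSON) are byte-identical across repeats.

## Problem sizes

The reference protocol is a population of 1000 systems evolved for 100,000
generations (the package defaults). The package's own replication studies
and the acceptance script use a scaled-down protocol — population 200,
20,000 generations, five seeds — which reproduces the qualitative dynamics
(fitness rise and stabilization, entropy collapse with reading preceding
code, wobble dominance, small wobble-consistent blocks) at about a minute
per run on one CPU. Population 200 has measurably stronger drift than
1000: early stochastic commitment of reading rows is more frequent, which
is precisely the regime the reset-style reading mutation compensates for.

## What the simulations do and do not show

The model is deliberately abstract: labels carry no physicochemical
properties, there is no chemistry of base pairing or modified bases, no
tRNA population, no crossover, and no addition schedule of amino acids.
Convergence to low-entropy, wobble-consistent block structure therefore
demonstrates only that error-minimizing selection on ambiguous assignments
with competing reading mechanisms suffices to produce SGC-like block
organization — not that the historical genetic code evolved this way, and
not anything about specific codon-to-amino-acid ascriptions (which are
exchangeable under relabeling).

## Numerical choices

* Row-stochastic validation tolerance 1e-9; TSV serialization at 12
  significant digits round-trips below that tolerance.
* Entropy uses `xlogy`, so exact zeros contribute exactly zero.
* Bayes-path ties break to the lowest codon index; block membership is a
  strict inequality at the threshold.
* The brute-force fitness oracle refuses more than 4 labels (10^4
  combinations) — it exists to verify the factorized path, not to be run
  at full size.
* Seeds below 2^31 everywhere; derived seeds come from `SeedSequence`.
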