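# Methods

## The problem

An outbred F1 family ("full-sib pedigree") segregates markers in four
configurations: lm×ll (1:1, informative for the female parent only),
nn×np (1:1, male only), ab×cd (1:1:1:1, informative for both parents
after recoding each parent's allele separately) and hk×hk (1:2:1, not
phaseable into either parent's testcross and therefore excluded from
mapping). Under the two-way pseudo-testcross strategy each parent gets
its own linkage map. Bin mapping places new markers on those maps by
genotyping only a small, maximally informative subset of offspring.

## SSR mining

Detection reports every *maximal perfect* tandem run whose unit is
primitive (not itself a repetition of a shorter unit) with unit length
2–6 and repeat count at least 5/4/3/3/3 for di- to hexanucleotides. A
partial trailing unit never counts toward the repeat number and is
trimmed from the reported span, so `end − start = unit_len × n_repeats`.
Runs containing N are dropped. Three reporting conventions matter:

* **Canonical motif class** = lexicographic minimum over the cyclic
  rotations of the unit and of its reverse complement. This makes mining
  strand-symmetric (a property test re-mines the reverse complement of
  every sequence and demands identical class counts).
* **End filter**: a run is kept iff `start ≥ margin` and
  `seq_len − end ≥ margin` (margin 35 nt, boundary inclusive) — runs too
  close to a sequence end leave no room for primer design. The rule is
  applied to the run span, not its midpoint.
* **Merging**: surviving runs separated by a gap strictly below 30 nt
  collapse (transitively) into one *compound* locus which counts once in
  all totals but contributes to no motif-class table, its class being
  ambiguous.

Only perfect repeats are modelled; approximate-repeat detection with a
mismatch resolution parameter is out of scope, which also means hexamer
counts are not comparable with detectors that tolerate imperfections.
The miner is verified against an independent brute-force enumeration
(per-start extension with an explicit left-maximality check) on a
thousand random sequences, and against planted ground truth.

Electronic PCR reports *every* placement where the forward primer
matches a template and the reverse primer's reverse complement matches
downstream, with at most `max_mismatch` mismatches per primer (default
0); the product size spans both primer footprints.

## The synthetic pedigree

The generator's defaults are the study conditions the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `n_lg` | 12 | linkage groups per parental map (haploid chromosome number) |
| `lg_length_cM` | 75 | group length, giving ~900 cM per parental map |
| `n_framework_per_map` | 64 | framework markers per parental map (~128 distinct overall) |
| `anchors_per_lg` | 2 | ab×cd anchors shared by both maps at identical positions |
| `n_offspring` | 278 | full-sib family size |
| `missing_rate` | 0.05 | independent missing-call mask |
| `error_rate` | 0.01 | symmetric flip to another legal call |
| `seg_mix` | 77:65:135:6 /283 | test-marker segregation mix (female/male testcross, outcross, intercross) |

Meiosis has no crossover interference: per group the crossover count is
Poisson(length/100) with uniform positions and a fair-coin starting
phase, so true recombination fractions follow the Haldane map function
(verified within 3 binomial SE at 10,000 gametes). Downstream distances
may be expressed with Kosambi as is conventional for such maps; the mild
mismatch is tolerated by the recovery thresholds. Genotyping error is a
symmetric flip among the legal codes, which is exactly what produces the
spurious isolated double crossovers the selection stage guards against.
hk×hk markers are generated but flagged non-assignable.

What the generator does *not* emulate: clustered marker spacing (real
AFLP framework maps concentrate markers near centromeres; positions here
are uniform), segregation distortion, locus-specific error/missing
rates, and crossover interference. Passing tests therefore demonstrate
correctness of the machinery under idealised meiosis, not performance on
any real data set.

The planted-SSR generator writes specified motif runs into random
sequences and re-mines each assembled sequence, redrawing the background
until detection recovers exactly the planted spans — so the fixture's
truth is guaranteed by construction, not assumed.

## Two-point linkage

Linkage phase of a new marker is unknown, so the recombinant count uses
the allele orientation that minimises it: `R = min(m, N−m)` over the N
jointly informative meioses. The LOD is evaluated at `r̂ = R/N` with
`0·log 0 ≡ 0` and clamps to exactly (0.5, 0) when `2R ≥ N`. A grid
search confirms `r̂` maximises the likelihood. Orientation minimisation
makes the null tail two-sided, which slightly inflates false linkage —
the grouping helper is therefore typically run at LOD 4 rather than 3
when clustering whole maps. Individuals with ≥50% missing data are
dropped (strict threshold); framework status ("LOD support for local
ordering ≥ 3") is accepted as upstream metadata since multipoint
ordering is out of scope.

## Bin-set selection

Breakpoints are observable only at framework-interval resolution: one
breakpoint per sign change between successive non-missing calls,
localised to the open interval between the flanking informative markers
(missing calls widen it). An isolated call differing from both
non-missing neighbours counts as a double crossover.

Selection maximises the number of **distinct** breakpoint intervals
across both parental maps — two individuals recombining in the same
interval contribute one — among offspring with <10% missing data, minus
`dc_weight` (default 1) per double crossover carried. The unit penalty
reflects that an isolated flip is more likely a genotyping error than
two real crossovers, and without it the objective measurably *selects
for* error-rich individuals. Ties break deterministically: fewer double
crossovers, smaller maximum resulting bin, lower missingness,
lexicographic id. Greedy forward selection is followed by a 1-swap local
search; on all exhaustively checkable instances (n ≤ 8, k ≤ 4) this
reaches the global optimum, and the whole procedure is deterministic
given its input. The two-stage "software + visual inspection" practice
this formalises is replaced by the explicit objective and tie-breaks; no
attempt is made to replicate any particular selective-mapping program's
internals.

## Bin construction

Each framework marker carries a genotype signature over the bin set,
with missing calls imputed from the individual's piecewise-constant
genotype along the group (flips at the midpoints of the localising
intervals). A **bin** is a maximal run of consecutive framework markers
with identical signatures; the boundary between two bins is the midpoint
of the framework interval separating them, and each group partitions
[0, group length] exactly. Representing every breakpoint as its own cut
point was rejected: missing-data-widened intervals then spawn
near-duplicate boundaries and artifact micro-bins (measured: ~101 bins
per parent and ~70% ambiguous assignments, versus ~54 bins and ~2
genotypic points between adjacent bins with the run construction, which
also matches how graphical genotyping is read in practice). Bins are
coded `LG.index` in positional order.

**Bin-count saturation.** With 278 candidates all drawn from the same
no-interference meiosis, a coverage-maximising 14-plant bin set hits
nearly every one of the ~52 framework intervals per map, so simulated
bin counts settle at ~52–62 per parent — the number of framework
markers is the ceiling. Real bin sets chosen from small usable pools on
maps with clustered markers leave many short intervals uncut and yield
fewer bins; this is a structural property of the idealised generator,
not of the selection code.

## Assignment

A marker's bin-set profile is compared with every bin signature by
Hamming distance, skipping missing calls, under both global allele
orientations (phase unknown). Resolution order:

1. distance 0 to exactly one bin → **exact**;
2. profile explained by one extra breakpoint strictly between two
   adjacent bins (every informative call matches one of the two flanking
   signatures, with ≥1 mismatch to each, and the pair attains the global
   minimum distance) → **intermediate**, both codes reported — no new
   bin is created, since bins are defined by framework markers only;
3. a unique minimum-distance bin whose mismatches (each an implied extra
   double crossover) do not exceed `max_double_crossovers` (default 1)
   → **double-crossover adjusted** — a deterministic replacement for
   what is otherwise resolved by eye;
4. otherwise **ambiguous**. Profiles with fewer than `min_informative`
   calls (default 10, clamped to the bin-set size) are not assigned.

Two equally perfect adjacent bins count as intermediate; equally perfect
non-adjacent bins (signature collisions across groups, which a 14-plant
signature cannot always exclude) are ambiguous.

## Validation and diversity

For each assigned marker the *nearest framework marker* is the one with
maximal two-point LOD on the extended progeny (ties: larger informative
count, then id) — LOD rather than r̂ because the class-D rule is
LOD-based. With a strict threshold (>2 for 46, >3 for 92 progeny):
class A if that framework marker lies in the assigned bin (either
flanking bin for intermediates), B if in a bin sharing a boundary on the
same group, C otherwise, D below the threshold. The headline rate is
A+B; A+B+C is reported alongside because published second-set male rates
count it that way. Synteny checks map each female group to the male
group holding the majority of shared markers and compute Kendall's τ
plus the count of adjacent-pair inversions.

Gene diversity is the unbiased `He = N/(N−1)·(1 − Σ(Nᵢ/N)²)` over N ≥ 2
gene copies. Rarefied allelic richness `A_g = Σᵢ[1 − C(N−Nᵢ,g)/C(N,g)]`
is evaluated with exact integer binomials (`C(a,b) = 0` for `a < b`),
so `A₁ = 1` and `A_N` equals the observed allele count; `g` is always
expressed in **gene copies** (2× individuals for diploids), and set
comparisons use the smallest complete count over all loci of both sets.
A Monte-Carlo subsampling check (10,000 draws) agrees within 3 SE.

## Problem sizes and determinism

The test suite and the acceptance script run the full experiment at the
design scale above (one seeded replicate each; the miner oracle uses
1,000 random 500-nt sequences; meiosis checks use 10,000 gametes), which
keeps a complete run within a few seconds on one CPU. Every stochastic
component consumes a `numpy` Generator seeded from a single integer;
identical seeds give bitwise-identical outputs end to end.

## Known limitations

* Perfect SSRs only; no coding/UTR localisation or primer design.
* No multipoint ordering — framework maps are inputs, and map-length
  discrepancies between mapping programs are out of scope.
* No crossover interference; single-family simulation only.
* Assignment is combinatorial, not likelihood-based; with 14-plant
  signatures, cross-group signature collisions occasionally force
  markers into the ambiguous class.
* Diversity statistics stop at He and rarefied richness — no
  F-statistics or bootstrap intervals.
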