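# Methods

This note documents the model behind `haplothread`, the tunable parameters,
the synthetic-data generator, and the numerical/design choices that were
genuinely open.

## Problem setting

Input is an allele matrix: `m` reads × `n` biallelic heterozygous SNVs over
{0, 1, −}, for a sample of ploidy `k`, optionally with a polyploid genotype
`g_i` (alt-allele count) per variant.  The goal is `k` haplotype sequences
over {0, 1, −} close to the true haplotypes, partitioned into phase blocks
where the data cannot connect them confidently.  The model assumes biallelic
SNVs, independent variants, a constant ploidy across the region, reads that
are equally likely to originate from each haplotype, and (for rate
estimation) roughly equal pairwise dissimilarity between haplotypes.

## Stage 1: pair scoring and cluster editing

**Rates.**  Variants are partitioned into windows of the rounded mean read
span (min 1).  Within a window, the Hamming rates (`dis/olp`, within-window
portion) of all read pairs with total overlap ≥ 2 are collected; since a
read pair has a 1/k chance of being same-haplotype, `d_same` is the mean of
the lowest ⌈#pairs/k⌉ rates, `d_all` the mean of all, and `d_diff` is solved
from `d_all ≈ (1/k)·d_same + ((k−1)/k)·d_diff`.  All rates are clamped into
[ε, 0.5 − ε] (ε = 10⁻³, configurable) to keep scores finite, and
`d_same < d_diff` is enforced (degenerate windows log a warning).  Windows
without pairs fall back to global estimates; a matrix without any pair falls
back to defaults (0.07 / 0.35) chosen to reflect error-corrected long reads
versus typical inter-haplotype divergence.  A pair spanning several windows
uses the overlap-weighted mean of the window rates.

**Score.**  The binomial log-likelihood ratio (natural log; the base only
scales all downstream comparisons) in its closed form; pairs with overlap
< 2 are neutral (exactly 0) and never materialized as edges.

**Cluster editing.**  The greedy permanent/forbidden heuristic with induced
costs

    icf(u,v) = max(0, w(u,v)) + Σ_{z: w(u,z)>0, w(v,z)>0} min(w(u,z), w(v,z))
    icp(u,v) = max(0, −w(u,v)) + Σ_{z: w(u,z)·w(v,z)<0} min(|w(u,z)|, |w(v,z)|)

always decides the undecided nonzero edge maximizing max(icp, icf) (ties:
larger |w|, then lexicographic ids); if icf ≥ icp the edge becomes permanent
and its endpoints are contracted (parallel edges summed, −∞ propagating),
otherwise forbidden (−∞).  Induced costs are maintained incrementally under
every weight change, and candidates live in a lazy max-heap: increases push
fresh entries, stale entries are detected on pop and replaced, so the
selected edge is always a true argmax.  The heuristic runs per connected
component; a configurable component-size guard (default 10⁵ nodes) aborts
clearly instead of thrashing.  Zero-edges are skipped entirely — a zero-edge
between reads that end up in one contracted node is implicitly inserted.
An alternative selection order (by |w|) is available behind
`ClusterEditingConfig.tie_break="weight"` for experiments.

## Stage 2: threading

Per cluster `c` and position `i`: consensus `cons(c,i)` (majority allele,
ties toward 0 — the major-allele coding makes 0 the safer default) and
relative coverage `cov(c,i)` (reads of `c` at `i` over all reads at `i`).
Expected copy number: `cn_exp = ⌈k·cov − 1/(2k)⌉`, clamped to [0, k].

Eligible tuples at `i` are multisets of size `k` over clusters covering `i`
with consensus genotype equal to `g_i`; if none exists, a deviation of 1 is
allowed; failing that, all multisets.  A missing genotype constrains
nothing.  Two guards bound the combinatorics: only the `2k`
highest-coverage clusters per position are considered (noise singletons
carry cov ≈ 1/coverage and cn_exp 0), and at most `tuple_cap` (10⁵)
multisets are kept, preferring low coverage cost.

The DP minimizes Σ costs_cov + Σ costs_switch over tuple sequences with
`S[i,0] = costs_cov` and
`S[i,j] = costs_cov + min_r (S[r,j−1] + costs_switch(r,i))`.
States are canonical (sorted) multisets; the transition cost is
`p_switch · (k − Σ_c min(mult_prev(c), mult_next(c)))`, the minimum number
of component changes over all orderings — ordering the successor tuple
greedily left-to-right realizes every junction minimum simultaneously, so
the multiset DP attains the same optimum as the ordered-tuple formulation
without the k! state blow-up.  Ties break toward the lowest predecessor row
(canonical order), making the threading deterministic.  Thread identities
are fixed in a post-pass that keeps each thread in its cluster whenever the
successor multiset allows.  Positions covered by no read stay unphased and
restart the recursion (and the blocks).  Coverage cost counts mismatched
slots: a cluster occupied three times with cn_exp 2 pays 3·p_cov, not
1·p_cov — the printed sum ranges over tuple slots.  Clusters absent from the
tuple are not penalized for cn_exp > 0 (the sum ranges over slots only).

**Cost constants.**  `p_cov = 8`, `p_switch = 32` by default.  Only their
ratio matters for the argmin; switches are priced four coverage deviations
apiece so that haplotypes stay in a cluster through short coverage dips
(hysteresis) yet five consecutive deviating positions justify a move.  Both
are CLI-configurable.

## Block cuts

Sensitivity levels nest: (1) no-connectivity cuts only — no single read
covers both adjacent variants (the connected-component block definition of
MEC-style tools, useful for like-for-like comparisons); (2) + multi-switch
cuts (≥ 2 threads change cluster: the continuation is ambiguous, whereas a
single switching thread is resolved by elimination); (3, default)
+ separation cuts: a collapsed cluster's multiplicity drops while its
co-resident threads entered at different positions or from different
predecessor clusters, so which thread leaves changes the haplotypes;
(4) + single-switch cuts.  Entry bookkeeping resets at every cut (threads
resident since block start may leave arbitrarily).  The 4-level integer flag
is an interpretation of a qualitative spectrum; levels 1 and 3 are the two
externally meaningful configurations.  PS interrupts all haplotypes at every
cut (one phase set per variant, the representable form in a VCF); the
auxiliary HS field interrupts only the threads involved, giving longer
per-haplotype blocks.

## Evaluation metrics

* HE / HR: HE = min over haplotype permutations of the mean Hamming
  distance (solved exactly as a linear assignment; brute force over k!
  is the test oracle).  Block-wise HR = Σ HE_block ÷ phased variants, with
  the permutation chosen per block (consistent with block-wise aggregation;
  a global-permutation alternative would mix independent blocks).
* SER (vector error rate): per position, the consistent one-to-one
  truth-to-prediction mappings Π_j; SER = min over mapping sequences of the
  summed per-junction mapping changes, ÷ k·(junctions).  Positions whose
  predicted genotype is wrong admit no mapping; they are excluded and
  counted (with unphased positions) in MV.  Aggregation divides the summed
  changes by k times the compared variants minus one per block.
* N50: smallest block span (bp from variant coordinates, or variant count
  for coordinate-free matrices) such that blocks at least that long cover
  half the region; 0 if half is never reached.
* Collapsing regions: maximal intervals ≥ 50 variants where some haplotype
  pair is identical, overlapping pairs merged.

## Genotype tools

Re-genotyping compares the observed alt fraction with g/k for g = 0..k and
keeps the closest (ties toward smaller g; a binomial-likelihood variant is
available behind `method="binomial"`).  Verification keeps a variant iff the
recomputed genotype matches the input and is heterozygous.  Haplotagging
compares a read with the phased haplotypes inside the block holding most of
its variants and requires a unique maximizer — ties (collapsed stretches)
leave the read untagged rather than contaminating downstream per-haplotype
assemblies.

## Synthetic data

The generator emulates long-read allele observations after variant calling,
at the package's reference study conditions: k = 4, n = 2000 variants, 40×
coverage, mean read span 20 variants, 5% allele error.  Haplotype alleles
are i.i.d. Bernoulli(q) with 2q(1−q) equal to the configured pairwise
difference rate (default 0.4 — separating the different-haplotype
disagreement rate ≈ 0.42 clearly from the error-driven same-haplotype rate
≈ 0.1 at 5% error, as expected for error-corrected long reads); homozygous
columns are resampled, which conditions the realized pairwise rate to
2q(1−q)/(1 − q^k − (1−q)^k), slightly above nominal.  Reads start uniformly
over the variant columns (so the first ~span columns see a coverage ramp),
span a geometric-around-mean number of variants (min 2, truncated at the
region end), originate from a uniform haplotype, and flip each allele
independently; optional dropout masks alleles inside the span.  Collapses
copy one haplotype onto another over an interval before the heterozygosity
repair.  Everything is driven by one `numpy` generator per stage, so outputs
are byte-identical under a fixed seed.

What the generator does **not** emulate: alignment and calling artifacts,
indels/multiallelic sites, position-dependent error rates, chimeric reads,
non-uniform haplotype representation, and reference bias.  Passing tests on
this data therefore demonstrates the algorithmic behavior (clustering,
threading, cuts, metrics), not robustness to real-data artifacts.

## Problem sizes used in tests

Oracle-equivalence checks run at exhaustively enumerable sizes (≤ 10 nodes
for exact cluster editing, ≤ 8 variants for mapping-sequence enumeration,
≤ 5 positions for threading).  End-to-end checks use the reference study
conditions above (2000 variants, ~4000 reads), which a single core phases in
under a minute.

## Known limitations

* The greedy edge order is one defensible instantiation; different orders
  can yield different (rarely better) clusterings on ambiguous data.
* Collapsing-region boundaries are intrinsically blurred by read length:
  reads spanning a collapse boundary are haplotype-specific, so the
  collapsed cluster's coverage — and hence its threaded multiplicity —
  ramps up over roughly one read span at each end, and how much of a
  planted collapse is threaded at multiplicity 2 varies considerably with
  the realized read sample.
* Block-wise SER aggregation divides by junctions; adding a cut that removes
  no switch error can therefore raise the rate by a sliver even though the
  error count never increases with cut sensitivity.
* Ploidy is constant per run (no local ploidy estimation); realignment,
  error correction, and variant calling are out of scope.
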