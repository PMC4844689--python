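# Methods

This note documents the models implemented in `horizonte`, the choices
made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Consensus building

`build_consensus` is a per-column majority rule over the unambiguous
residues (A/C/G/T) of an aligned copy set.  A residue is called when it
has a strict plurality, its fraction of counted residues is at least
`majority_fraction` (default 0.5) and the counted depth is at least
`min_depth` (default 3); all other columns are written as `N`.  Columns
in which gaps hold a strict majority of all rows are removed: the
consensus models the element itself, not the alignment.  Ties are always
`N` — a deterministic stand-in for the manual curation that consensus
reconstruction traditionally involves.  Two consequences are worth
noting: a single-row alignment only reproduces the row at
`min_depth=1`, and adding a duplicate of a *minority* row can turn a
call into `N` by creating a tie (the tie rule takes precedence over any
"duplicates are harmless" intuition; doubling the entire alignment is
harmless).

The depth default of 3 reflects what the 5′-truncated copy sets produced
by LINE-like retrotransposition look like: coverage thins toward the 5′
end, and calls supported by one or two copies are more likely to be copy
idiosyncrasies than ancestral states.

## K2P distances and CpG handling

`k2p_distance` implements the closed form
d = −½·ln(1−2P−Q) − ¼·ln(1−2Q) with uniform rates and pairwise deletion:
any site with a gap, `N` or another ambiguity code in either sequence is
excluded (ambiguity codes are treated as missing rather than as partial
observations).  Non-positive logarithm arguments raise a distinct
saturation error; zero comparable sites raise another.  The operation
never aligns — alignment is an explicit upstream input.

Per-copy divergence to consensus removes both positions of every
consensus CpG dinucleotide before counting (`cpg_mode="exclude"`),
reading CpG context on the consensus with gap columns skipped.  CpG
transitions are the dominant hypermutable class in vertebrate genomes
and would otherwise inflate apparent copy ages.  Two alternatives are
provided: `"adjust"` keeps the columns but counts transitions at CpG
columns at half weight, and `"none"` disables the handling.  Exclusion
is deliberately literal: it conditions on the *present* consensus
context, so sites that left CpG context through mutation escape it.  In
simulations with a 10× CpG rate multiplier the residual inflation of
mean divergence is measurable (none > adjust > exclude); with
hypermutability off the three modes agree in expectation.  This leakage
is a real property of consensus-conditioned CpG correction, not an
implementation artifact.

The pairwise matrix reports the grand mean over all off-diagonal
unordered pairs, with failed pairs recorded as missing; the bundled
table of 55 published consensus-pair distances reproduces its published
grand mean of 0.101 substitutions/site to three decimals.

## Landscapes, activity intervals and dating

A divergence landscape weights each copy by `aligned_bp`, the number of
sites actually compared for that copy, so fragmentary copies count for
what they contribute.  Quantiles are computed on the **un-binned**
per-copy values with integer bp weights — the 1%-wide bins exist only
for plotting — using an interpolation exactly equivalent to
`numpy.quantile` on the bp-expanded list.  "95% of the distribution" is
read as the central interval (2.5th–97.5th bp-weighted percentiles);
one-sided variants are available, since the convention is not forced by
the definition.

Ages are *t* = *d* / (2µ).  The factor 2 encodes the master-gene model:
a copy of age *t* has diverged from the present-day master lineage along
two branches of length *t* (its own dead-copy branch plus the master's
continuing branch), so divergence to a reference representing the
present master state accumulates at 2µ per year.  Per-generation rates
are converted with a 365.25-day year and the configured generation time
(default 90 days, the standard assumption for filarial nematodes).  Myr
values are reported to one decimal in tables.

An important caveat, demonstrated by the simulator: a consensus built
from the copies themselves approximates the master state near the
*median* insertion time, not the present.  For a long activity window
this re-centring compresses apparent ages — in the limiting case of
dating the oldest copies it can halve them.  The parameter-recovery
benchmarks therefore measure divergence against the simulator's
present-day master state, which is the reference the d/(2µ) rule
assumes; when only a copy-built consensus is available (as with real
genomes), invasion minima should be read as the conservative lower
bounds they are.

The burst ("wave") test is a two-sided two-sample t-test on invasion
minima, Welch by default (equal variances between waves have no
justification); Student's pooled test is available and the flavor is
recorded in the result.  Two constant equal groups return p = 1 by
convention rather than NaN.

## Transfer-only reconciliation

`min_transfers` computes exact event parsimony over mappings of TE-tree
nodes to host-tree nodes (both rooted, binary; leaf images fixed by the
host map, many TE leaves per host allowed):

* **cospeciation** (cost 0): the node maps to the host node whose two
  child subtrees separate the images of the node's children;
* **duplication** (cost 0): both children map to the same *terminal*
  host genome as the node — TE subfamilies diversify freely within a
  genome;
* **loss** (free, implicit): between events a TE lineage may descend
  from its current host to any node of that host's subtree;
* **host switch** (cost 1): one child's image escapes the host subtree
  of its parent's image.  By default the recipient must be incomparable
  to the donor (the standard undated admissibility); `"any"` relaxes
  this to any node outside the donor subtree.

Restricting free duplication to terminal genomes is essential: with free
duplication at internal host nodes and free losses, any incongruence
could be explained at zero cost by duplicating at the host root, and the
parsimony would be vacuous.  Under this model a host-congruent TE tree
costs exactly 0, and the count is the number of topological conflicts
attributed to horizontal transfer — the quantity a manual "how many
switches are required" argument estimates.

The DP is O(TE nodes × host nodes²) with an exact co-optimal count and a
deterministic lexicographic backtrace (`enumerate_optimal`).  The
reconciliation is undated; a Stolzer-style precedence-graph cycle check
flags (as a warning, not an error) optimal mappings whose transfers
cannot be ordered consistently in time.

## DIVA ancestral areas

`diva_reconstruct` is classic dispersal–vicariance parsimony on a fixed
rooted binary tree: at a node the ancestral set either splits by
vicariance into two non-empty disjoint parts (free) or, when it is a
single area, passes to both daughters by duplication/sympatry (free);
along branches each area gained costs 1 (dispersal) and each lost costs
1 (extinction).  Ancestral sets are capped at `max_areas` (default 2,
matching the observation that bird lineages rarely occupy more than two
avifaunal regions at once).  Observed leaf ranges wider than the cap can
be accepted with `enforce_leaf_limit=False` — only the searched
ancestral states are capped; this is needed for "widest distribution"
codings of widespread taxa.

The optimisation is exact over all subsets of size ≤ `max_areas`, and an
inside–outside pass counts *all* co-optimal reconstructions, giving
exact per-node frequencies of each ancestral set.  `filter_display`
applies the strict > threshold display rule (default one third).
Frequencies are over co-optimal reconstructions on the single input
tree; averaging over tree samples is out of scope.  Three leaf-coding
variants for the AviRTE-bearing lineages over the five tropical
avifaunal regions (widest ranges, fossil-augmented, and a main coding
narrowed by phylogenetic evidence) ship as data files.

## Copy annotation

`find_full_length` keeps copies whose aligned span covers at least
`min_fraction` (default 0.9) of the consensus and whose termini lie
within `end_margin` (default 50 bp) of the consensus ends — "full
length" has no canonical numeric definition, so both knobs are explicit.
`orf_integrity` is alignment-guided: frameshifts are maximal runs of
indel columns within the ORF whose length is not a multiple of 3
(mixed insertion/deletion runs are scored by run length, so a +1/−1 pair
counts as a frameshift even though the net frame is restored);
premature stops are read codon-by-codon in the consensus frame, the
frame re-anchored by consensus coordinates after every indel, insertions
skipped, and codons containing gaps or ambiguity never counted as stops.
A `strand="-"` flag lets reverse-complement-stored alignments be read on
the coding strand, making the counts orientation-invariant.

## The simulator: what it emulates, and what it does not

`simulate_amplification` implements the master-gene model: a single
active element, drawn uniformly at random, evolves neutrally throughout
a bounded activity window; copies branch off the master state at
insertion times drawn uniformly within the window, evolve independently
to the present under a continuous-time K2P process (transition bias κ,
default 2; per-event exact Gillespie simulation when CpG hypermutability
is enabled), and are 5′-truncated by a geometric number of bp (default
mean ≈ 250 bp of a 1000-bp element, the heavy truncation typical of
LINE insertions; at least `min_copy_bp` bp survive).  The ground truth
(insertion times, per-copy substitution events, truncations, and the
present-day master state) suffices to recompute every expected
statistic without re-simulation, and all draws derive from a single
PCG64 generator, so runs are bit-reproducible for a given seed.

Defaults follow the benchmark scenario used throughout the tests: a
1000-bp element, 500 copies, activity 20 → 15 Myr ago,
µ = 2.5×10⁻⁹/site/year.  CpG hypermutability is off by default because
the dating identity E[d] = 2µt presumes the uniform-rates K2P model the
estimator itself assumes; the multiplier exists to study robustness (see
the CpG section above).  Features of real data deliberately *not*
emulated: indels (distances use pairwise deletion regardless), within-
genome rate heterogeneity beyond CpG, gene conversion between copies,
population-level fixation dynamics, and annotation artifacts (chimeric
or spurious hits).  Passing recovery tests therefore shows the
statistical machinery is correct under its own model — not that real
landscapes are free of those complications; the benchmarks do expose
the two honest failure modes (consensus re-centring, CpG leakage)
described above.

`simulate_transfers` grows a host-congruent TE tree and applies k host
switches, each copying the TE lineage from a donor edge into a randomly
chosen recipient subtree incomparable to the donor, where it
cospeciates; recipients are pairwise non-nested so no event overwrites
another.  The planted k upper-bounds the parsimony minimum by
construction; across seeded replicates the minimum equals k in ≈98% of
cases (the rare shortfalls are genuine — some event combinations admit a
cheaper explanation).

`simulate_areas` draws a root set of one or two areas, lets it evolve by
free vicariance/duplication, and plants d dispersals on branches whose
incoming set is a single area (keeping every node within the two-area
cap); the planted d upper-bounds the reconstruction cost.

## Numerical and engineering choices

* Weighted quantiles reproduce `numpy.quantile` (linear interpolation)
  on the bp-expanded sample exactly, without materialising it.
* Distance failures inside the pairwise matrix become missing values;
  failures for single copies are skipped (fragment behaviour) unless
  `skip_failed=False`.
* Polytomies are rejected by default (`polytomy="resolve"` binarises
  arbitrarily with zero-length edges); both parsimony DPs require
  binary trees and refuse otherwise.
* Reconciliation co-optimal counts are exact up to 2⁵³ (float
  accumulation); beyond that −1 is reported.
* The pipeline manifest records SHA-256 checksums of every output;
  identical configs reproduce identical bytes, which the test suite
  checks against a committed golden manifest.

## Known limitations

* Absolute dates inherit the full uncertainty of the substitution rates
  supplied; the pipeline treats rates as config inputs and makes no
  attempt to estimate them.
* The reconciliation is undated: a topological minimum may require a
  time-inconsistent event ordering (flagged, not forbidden).
* DIVA frequencies quantify ambiguity among co-optimal parsimony
  solutions only — they are not posterior probabilities.
* The ORF frameshift count scores alignment indel runs, so its value
  depends on the upstream aligner's gap placement.
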