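# Methods

## Model

The clonal development of several tumors in one patient is modelled as a
rooted tree: the root is a normal cell, the leaves are the sampled tumors,
and internal nodes are unobserved common precursor clones.  Chromosomal
aberrations are interval gains and losses on a shared probe grid; each
aberration creates one 'up' and one 'down' breakpoint, and breakpoints are
inherited by all descendants of the clone in which they arose.  Working with
breakpoints rather than aberration intervals lets imbricated, overlapping
events accumulated over several steps be disentangled.

Each chromosome is first divided into *homogeneous segments*: the coarsest
partition on which every sample is constant, delimited by the union of all
samples' status change-points (plus chromosome ends, where a non-normal
terminal status also counts as a breakpoint).  The partition is fixed once
from the observed tumors; every reconstructed ancestor lives on it.  A
chromosome's segment vector `s ∈ {-2,-1,0,1,2}^N` maps bijectively to the
breakpoint vector `b` (first difference with end terms) and to the
non-negative amplitude vector `a` (up and down amplitudes in separate
slots).  Any `b` derived from a real profile telescopes to zero; balance is
the viability criterion for reconstructed breakpoint sets.

### Agglomeration

Starting from the front of observed tumors, the pair with the highest
identical breakpoint score — the sum of shared amplitudes
`min(aⁱk, aʲk)`, each weighted by `1 − Fk` with `Fk` the breakpoint's
frequency in a reference cohort — is joined; ties fall back to the smallest
weighted amplitude distance `Σ |aⁱk − aʲk| (1 − Fk)`, then to
lexicographic node order (reproducibility).  The pair's common precursor
replaces the two nodes, and the process repeats until one ancestor remains;
a normal-cell root is attached above it, with the ancestor's events
decomposed onto the root edge by greedily peeling unit-level intervals of
uniform sign (stacked levels yield stacked events; the decomposition is not
unique and this convention is ours).

Two same-sign breakpoints in different samples are deemed identical when
their probe distance is at most the *tolerance*; matching is greedy
nearest-first one-to-one, the shared amplitude is the minimum of the two,
placed at the slot of the larger-amplitude sample (ties: lower slot), and
any excess amplitude remains sample-specific — a breakpoint can be common
and specific at once.

### Precursor reconstruction and corrections

Per chromosome, the shared amplitudes form the candidate precursor.  If the
implied breakpoint vector is unbalanced (`δ = Σ bk ≠ 0`), either a shared
breakpoint is a coincidence (independent events in the two lineages sharing
a boundary) or a genuinely ancestral breakpoint was erased in one lineage by
a later opposite-sign breakpoint at the same location.  Balance is restored
by `|δ|` unit corrections — removing a unit of shared amplitude of
`sign(δ)` or adopting a unit of sample-specific amplitude of `sign(−δ)` —
selected by exhaustive enumeration under three criteria, in order:

1. **feasibility**: the corrected precursor's statuses stay in the
   authorized range;
2. **minimal breakpoint usage** of the implied scenario: precursor events
   plus both edge event sets (counting amplitude-weighted breakpoints);
3. **support**: among cost-tied candidates, the one whose adopted
   breakpoints are carried by the most *other* samples of the patient (and
   whose removed breakpoints by the fewest) wins; residual ties prefer
   removal (with support information available, an unsupported tie is most
   likely a coincidental match), then the lowest genomic slot.

The two generative scenarios can produce byte-identical data, so no rule
resolves every case; the support criterion decides correctly whenever the
disputed breakpoint is ancestral beyond the joined pair.  The tie policy was
selected by measuring ancestral-profile error on simulated trees (see
Validation).  Each correction is recorded (`CorrectionRecord`) with every
alternative considered and its cost, so a fit is auditable.  A balanced
shared-breakpoint set whose cumulative statuses still leave the authorized
range — possible when stacked amplitudes coincide — sheds one unit of the
bounding shared breakpoint and rebalances, in a bounded repair loop; this
guard is not normally entered.

On noisy data, a second matching pass *rescues* shared breakpoints displaced
beyond the tolerance: residual same-sign breakpoints within `2·tol + 1`
probes are paired only when another sample independently carries that
breakpoint within tolerance.

### Amplicons

High-level amplifications (+2) arise by mechanisms other than stepwise gain,
so in `amplicon_mode="interval"` (default, intended for real array data)
they are clamped to +1 for the breakpoint arithmetic and tracked as probe
intervals: an amplicon ascends to a precursor only when present in both
children with boundaries within tolerance (the precursor receives the
intersection, a conservative choice), otherwise it becomes an edge event.
In `amplicon_mode="breakpoint"`, +2 participates in the vector arithmetic
like any level, so two stacked unit gains are reconstructed as such; this is
the correct semantics for the simulator, whose +2 statuses *are* stacked
gains, and is what the benchmark uses.  Homozygous deletions (−2) are always
ordinary accumulable losses.

## Reference breakpoint frequencies

`Fk` is the fraction of reference samples (independent tumors on the same
probe grid) carrying a same-sign breakpoint within the tolerance window of
slot *k*; a sample counts once per slot however many breakpoints fall in the
window.  The same tolerance is used for reference matching as for
inter-sample matching (the natural reading; nothing else is specified).
With no reference cohort `F ≡ 0` and the score reduces to the plain shared
amplitude count.  Frequencies are computed on demand at the patient's slots.

## Simulator

`simulate_tree` emulates clonal expansion: a first precursor is created from
the normal cell, then a random leaf of the growing tree is split into two
children until the requested number of tumors exists.  Every new node adds
`n_ab ~ Uniform{3..15}` interval aberrations (gain or loss with equal
probability; boundaries drawn uniformly within a chromosome chosen by probe
weight, or by supplied breakpoint weights); draws that would leave
{-2..2} are discarded and replaced.  The default grid has 2,360 probes on
22 chromosomes with human-proportional sizes.  These defaults are the
validation conditions and are not tuned per experiment.

The noise model converts a status `N = s + 2` copies to
`log2((N(1−C) + 2C)/2)` — the tumor signal diluted by a fraction `C` of
diploid normal cells — plus Gaussian noise of sd `S` (log base 2, the array
convention; copy ratios are floored at 0.05 so a pure homozygous deletion
maps to a finite value).  `C ∈ [0, 0.8]` and `S ∈ [0, 0.2]`; the realistic
ranges used in the benchmark are `C ∈ [0.10, 0.40]` and `S ∈ [0.03, 0.11]`,
drawn per sample.

Re-discretization segments each chromosome by a recursive mean-shift window
scan (circular-binary-segmentation style: the best interior window or edge
split is carved when its residual-sum-of-squares reduction, normalized by a
median-absolute-difference noise variance, exceeds a BIC-style penalty of
`3 log(#windows)`; minimum segment length 3 probes, so single-probe spikes
are never segments), then calls each segment's status by the nearest
contamination-adjusted theoretical level using the segment *median* (robust
to lone artefact probes).  When the noise estimate is ~0 the signal is
segmented at its exact change points, so noiseless input round-trips
exactly.  Measured probe accuracy is ≥ 99.7% across the realistic noise
range (99.9% at S = 0.05, C = 0.2); the 95th percentile of breakpoint
relocation error is 1 probe.

What the simulator does not emulate: wavy baselines and GC artefacts,
correlated probe noise, subclonal mixtures within one sample, allele-specific
signal, and real breakpoint hotspots (boundaries are uniform unless weights
are supplied).  Passing benchmarks therefore demonstrate correctness of the
reconstruction logic under the stated noise model, not performance on any
particular array platform.

## Evaluation

Topology is compared by Robinson–Foulds distance (symmetric difference of
non-trivial leaf bipartitions).  The benchmark's "correct topology" gate
includes the normal root as a labelled leaf, which makes the comparison
sensitive to the rooted shape — necessary for matching ancestral nodes by
their descendant sets (for three tumors all rooted shapes induce the same
unrooted topology).  Ancestral accuracy is the mean, over precursor nodes of
topology-correct replicates, of the per-probe status mismatch against the
simulated truth.

Benchmark tolerances: 0 probes for noiseless input (breakpoints are exact);
2 probes under noise — twice the segmenter's 95th-percentile relocation
error, since matching must absorb the relative displacement of two samples'
calls.  The package default for externally discretized real arrays remains
10 probes, appropriate for the coarser smoothing those datasets went
through.

### Validation results (computed by the test suite)

* Noiseless, 100 replicates each at 2–6 tumors: topology recovered in
  **100%** of replicates.  Ancestral-profile error is not exactly zero
  (≈ 0.3% of probes): coincidentally shared breakpoints and erased
  breakpoints produce data that are provably identical under two different
  histories, and the minimum-change resolution cannot always match the
  simulated truth.  This ambiguity floor grows slowly with the number of
  accumulated events.
* Noisy (S ∈ [0.03, 0.11], C ∈ [0.10, 0.40], 5 tumors, 200 replicates):
  topology recovered in ≥ 98% of replicates (measured 100%), ancestral
  probe error ≤ 1.6% (measured ≈ 1.3–1.4%).

## Cohort statistics

`fisher_two_tailed` uses the minimum-likelihood two-sided convention (sum of
hypergeometric probabilities not exceeding the observed table's), delegated
to `scipy.stats.fisher_exact` and verified against exhaustive enumeration.
The early/late analysis requires three-edge trees (normal → precursor →
primary/recurrence); an arm aberration is present on an edge when ≥ 60% of
the arm's probes change in its direction along that edge, the recurrence
edge is excluded (treatment effects), and each aberration's early vs late
occurrence counts over the patients form the 2×2 table.  Co-occurrence
pools all edges of all trees, keeps aberrations on ≥ 3 edges, and controls
FDR by Benjamini–Hochberg (a q-value density fit is unstable at these test
counts); whether edges should instead be conditioned per tree is untestable
at these sizes and pooling is the plain reading.  Clade probabilities use
the space of rooted binary leaf-labelled topologies, `(2n−3)!!` of them,
with the clade count `(2k−3)!!(2(n−k+1)−3)!!`; exact enumeration is used up
to n = 9 and cross-checked against the closed form.  Per-patient fractions
multiply across patients (independent null topologies).

## Degenerate inputs and numerical choices

Missing statuses are rejected, not imputed (unassessable probes should be
removed upstream, consistently across samples).  Chromosomes are independent
string-labelled units; no karyotype is assumed and sex chromosomes receive
no special handling.  Probe indices are 0-based half-open internally;
exported segment tables use 1-based inclusive base-pair positions.  All
randomness flows through `numpy.random.default_rng` seeded per replicate
from the user seed.  Reported benchmark sizes (100–200 replicates; 2,360
probes) are the package's validation sizes; the simulator accepts any grid.

## Known limitations

* Reconstruction is pairwise-greedy; a globally optimal (likelihood or
  parsimony) search over trees is out of scope.
* The ancestral-profile ambiguity floor above is irreducible from copy-number
  data alone; resolving it needs additional markers (e.g. SNVs).
* The early/late and co-occurrence analyses assume the supplied aberration
  catalogue; they do not discover de-novo recurrent regions.
* `amplicon_mode="interval"` matches amplicon boundaries within the same
  tolerance as breakpoints; amplicons remodelled by later events in one
  lineage may fail to ascend and remain on edges.
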