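# tumult

Reconstruction of tumor lineage trees — and of the copy-number profiles of
their unobserved ancestral clones — from the discretized copy-number
profiles of multiple tumors removed from one patient.

## Who this is for

When a patient presents several tumors (metachronous recurrences,
synchronous multifocal disease, or multiple metastases), the samples descend
from a single transformed cell and share part of their chromosomal history.
Ordering that history — which aberrations came first, which clone seeded
which tumor — is not readable from any single sample: the primary tumor
accumulates private events and is a poor proxy for the founding clone.
`tumult` infers the rooted lineage tree (normal cell → common precursors →
observed tumors), assigns every aberration to an edge, and reconstructs the
full copy-number profile of every precursor clone, from ordinary
probe-level discrete copy-number calls (array CGH or SNP arrays).

## The method

A chromosome profile over *N* homogeneous segments, `s ∈ {-2,-1,0,1,2}^N`,
is encoded by its breakpoint vector

```
b1 = s1,   bi = si − si−1 (2 ≤ i ≤ N),   bN+1 = −sN
```

and, separating 'up' from 'down' breakpoints, by a non-negative amplitude
vector `a` of length 2(N+1).  Every aberration creates one 'up' and one
'down' breakpoint, so any real chromosome satisfies `Σ bi = 0`.  Because
breakpoints are inherited by daughter clones, the two samples that separated
last share the most breakpoints.  The algorithm therefore scores every pair
of nodes by the identical breakpoint score

```
IBS(aⁱ, aʲ) = Σk  min(aⁱk, aʲk) · (1 − Fk)
```

where `Fk` is the breakpoint's frequency in a reference cohort of unrelated
tumors (frequent breakpoints arise independently and carry less lineage
signal), greedily joins the best pair, reconstructs their common precursor
from the shared breakpoints — rebalancing chromosomes whose shared
breakpoints do not sum to zero by the minimum-usage removal/addition of a
single breakpoint — and repeats until one ancestor remains, under a normal
root.  A tolerance (in probes) absorbs small breakpoint relocations
introduced by segmentation of noisy arrays, and high-level amplifications
can be handled as interval events outside the breakpoint arithmetic
(`amplicon_mode="interval"`).

The package also ships the validation machinery: a progression-tree
simulator (random topologies, 3–15 aberrations per edge, 2,360 genome-wide
probes), a log-ratio noise/contamination model with a change-point
re-discretizer, Robinson–Foulds topology scoring and ancestral-profile
error, and cohort statistics over collections of trees (early/late Fisher
tests, edge co-occurrence with FDR control, ancestral-clone aberration
frequencies, clade probabilities among random topologies).

## Worked example

```python
import numpy as np
from tumult import LineageModel, simulate_tree, SimulationConfig, DiscreteProfile

truth = simulate_tree(SimulationConfig(n_tumors=3, seed=42))
leaves = [DiscreteProfile(l, truth.probe_profile(l))
          for l in sorted(truth.leaf_ids())]
model = LineageModel(leaves, truth.partition.marker_map,
                     tolerance=0, amplicon_mode="breakpoint")
result = model.fit()
print(result.summary())
```

prints

```
Tumor lineage reconstruction
============================================================
samples:             3
probes:              2360 on 22 chromosomes
homogeneous segments:   105
tolerance:           0 probes
reference cohort:    0 samples (unweighted IBS)

joins (identical breakpoint score):
step joined                          IBS   distance
   1 T2 + T3                      16.000     42.000
   2 T1 + CP1                      8.000     34.000

unbalanced-chromosome corrections: 0

edge aberration counts:
  CP1 -> T2: 6
  CP1 -> T3: 15
  CP2 -> T1: 13
  CP2 -> CP1: 4
  normal -> CP2: 4
```

T2 and T3 share 16 breakpoint units — their lineages separated last — and
are joined first; their precursor CP1 then joins T1 under the ancestor CP2,
which carries 4 aberrations on the trunk (the events of the founding
clone).  `result.to_newick()` gives `((T1,(T2,T3)CP1)CP2)normal;`, here
identical to the simulated topology, and `result.nodes_frame()` /
`result.edges_frame()` expose every ancestral profile and edge event;
`result.save(outdir)` writes DOT/Newick/TSV/JSON.

The same pipeline is available from the shell:

```
tumult simulate --tumors 5 --seed 1 --noise-sd 0.03:0.11 \
    --contamination 0.1:0.4 --out sim/
tumult build --input sim/leaves.tsv --tolerance 2 --out tree/
tumult stats clade-prob --leaves 5,4,6 --subset 3,2,2
```

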