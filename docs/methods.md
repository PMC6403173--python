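# Methods

This document records the model, the defaults, and the reasoning behind
them. Everything described here is a parameter of the corresponding
dataclass (`FilterParams`, `ScoringParams`, `EdgeCriteria`,
`SimulationConfig`, `PipelineConfig`) unless stated otherwise.

## Data model

A *proteome set* is a collection of organisms, each contributing protein
records. A record carries: sequence (20 standard residues plus `X`),
organism, replicon (chromosome or plasmid), 1-based inclusive genomic
coordinates, strand, and a free-text annotation label. Invariants
(unique ids, valid residues, start ≤ end, metadata/FASTA agreement both
ways) are enforced at load time so downstream stages never defend
against malformed input.

## Candidate prefilter

All-vs-all Smith–Waterman over *N* sequences is quadratic in *N* with a
large constant; almost all pairs are unrelated. Two cheap necessary-ish
conditions prune them:

1. **Length ratio** — min/max length ≥ 0.8. Homologs that would later
   pass the 80 %-coverage edge criterion cannot differ in length by more
   than 20 %, so this filter discards nothing an accepted edge could
   use.
2. **Shared exact 7-mer** — true homologs at the identity levels the
   edge criteria demand (≥ 40 % identity over ≥ 80 % of the longer
   sequence) essentially always share a short exact word; random
   unrelated sequences rarely do at k = 7 (20⁷ ≈ 1.3 × 10⁹ words).

The 7-mer test is evaluated for the whole collection at once: all
length-7 windows of the concatenated sequences (separated by sentinels)
are sorted lexicographically (numpy `sliding_window_view` + `lexsort`),
and each run of identical windows yields the sequence pairs that share
that word. This is equivalent to a generalized suffix array truncated at
depth *k*, costs O(total length · log), and never enumerates
non-candidate pairs.

## Alignment and edge acceptance

Candidates are aligned with local (Smith–Waterman) alignment under
BLOSUM62 with affine gap costs: a gap of length ℓ costs
10 + (ℓ − 1) · 1. The three-matrix (Gotoh) recurrence is JIT-compiled
with numba (int32 scores); traceback is ordinary Python since only the
best path is needed. `X` (unknown residue) scores 0 against everything,
so runs of `X` neither attract nor repel alignments. When several cells
tie for the optimum the first one in row-major order is taken, and at
traceback ties prefer diagonal, then gap-open — fixed conventions that
make results reproducible across platforms.

A candidate alignment becomes a graph edge only if all three hold
(*L* = longer sequence length, *self* = score of the longer sequence
against itself, i.e. the sum of its diagonal BLOSUM62 entries):

- **coverage**: alignment length ≥ 0.8 · *L*, counting *all* alignment
  columns including gap columns — this is what makes the criterion a
  genuine near-full-length requirement;
- **identity**: identical columns ≥ 0.4 · alignment length;
- **score**: alignment score ≥ 0.3 · *self*.

Coverage keeps domain-only matches (one shared domain in otherwise
different proteins) out of the graph; identity and relative score keep
low-complexity and marginal similarities out. The relative-score test
adapts to composition: a sequence of cheap residues must reach a
proportionally lower absolute score. Edge weight is the alignment score.

## Graph clustering

The weighted homology graph is partitioned by Louvain modularity
optimization: repeated local moving (each vertex to the neighboring
community with the best modularity gain, minimum accepted gain 1e-9 of
2m) followed by graph aggregation, until no move improves Q. Newman
weighted modularity is the objective and is also reported.

Greedy local moving depends on visit order, so the vertex order is a
seeded random permutation, ties between equally good target communities
go to the lowest community id, and the whole procedure is restarted
(default 5 times) from different seeded orders, keeping the best-Q
partition. Cluster ids are relabeled by first appearance over the
sorted vertex order; with a fixed seed the output is byte-identical
across runs. Isolated vertices (sequences with no accepted edge) come
out as singletons.

Clusters are classified into three census classes: **singleton** (one
member), **single-organism** (≥ 2 members, one organism — pure paralog
clusters), and **multi-organism** (the putative core of homolog
families).

## Descriptive statistics conventions

- Length statistics per cluster: min / mean / max and the *sample*
  (n − 1) standard deviation, printed to one decimal; undefined (shown
  as `-`) for singletons.
- Label censuses count annotation strings after whitespace
  normalization (strip + collapse internal runs); percentages are
  computed exactly in decimal and rounded half-up to two decimals, so
  printed tables are reproducible regardless of float formatting.
- Representation of a cluster is the fraction of *all* organisms in the
  set that have ≥ 1 member; the representation profile reports the
  fraction of non-singleton clusters at or above a chosen representation
  level q.
- Copy-number reports split counts by replicon type (chromosome vs
  plasmid) per organism.

## Anomaly detectors

All detectors work *relative to the clustering*: a cluster of homologs
provides the expected length, the expected organism census, and the
expected annotation, against which individual records are screened.

- **Truncated / overlong**: in clusters of ≥ 3, members outside
  [0.9, 1.1] × cluster median length, ranked by deviation.
- **Fragment pairs** (frameshift-split genes): two records of the same
  organism, replicon, and strand, ≤ 300 bp apart, whose summed length is
  within ±10 % of the median length of a reference cluster containing at
  least one of them. Such pairs typically fail the 80 %-coverage edge
  criterion individually, so they surface as singletons — the genomic
  adjacency test recovers them.
- **Merged genes** (fusion calls): a record whose length matches
  medianA + medianB within ±10 % and whose alignments cover ≥ 0.8 of
  each family's median.
- **Missing members**: for clusters whose representation is ≥ 0.9, each
  absent organism is reported. The gate matters: below it, absence is
  not evidence of a problem, so drops in sparsely represented families
  are silent by design.
- **Mislabeled sequences**: user-supplied annotation patterns are mapped
  to "home" clusters by strict majority; pattern-matching records
  outside their home cluster, and non-matching records inside it, are
  flagged. Patterns without a majority home are skipped with a warning.
- **Synteny check**: for two clusters, per-organism strand-aware
  adjacency (downstream gene starts within 2,000 bp of the upstream
  gene's end, orientation-corrected) classifies each organism as
  conserved / broken / absent.

## Synthetic pan-proteome generator

The generator exists to give every detector a measurable ground truth.
Per family it draws an ancestral sequence (uniform over the 20 residues)
of length 200–600 aa, then evolves one descendant per organism to a
target identity drawn from 0.75–0.95 (point substitutions plus
geometric-length indels at rate 0.005), optionally adds paralogs
(probability 0.1) and places a family on a plasmid (probability 0.05).
Genes are laid out in family order along the replicon with 200–2,000 bp
intergenic gaps, 90 % of families on the forward strand, so synteny is
conserved by construction. Annotation labels per family mix a canonical
name (60 %), a variant form (20 %), a "putative" form (10 %) and
"hypothetical protein" (10 %), mimicking real annotation heterogeneity.

Six corruption modes are planted at configurable per-record rates and
recorded in the truth table: **fragment** (split into two parts 1–100 bp
apart, ids `_p1`/`_p2`), **truncate** (keep 40–75 % from either end),
**wrong_start** (keep 75–95 %, 5′ loss), **drop_annotation** (record
removed entirely), **merge** (partner sequence appended, partner record
consumed), **relabel** (label swapped to another family's canonical
name). All randomness flows from one root seed through derived child
seeds (kept below 2³¹), so a config + seed pair is fully reproducible.

What the generator does *not* emulate: real substitution processes
(no BLOSUM-biased substitutions — identity, not similarity, is
controlled), domain architecture, horizontal transfer, genome
rearrangements, or GC/codon effects. It is a calibration instrument for
the pipeline's decision rules, not a sequence-evolution simulator.

## Numerical and engineering choices

- Alignment scores are exact integers (int32); no floating point enters
  until modularity, which is plain float64 arithmetic.
- The BLOSUM62 matrix is loaded once (Biopython's substitution matrices)
  into a read-only 21 × 21 int32 array and cached.
- Percent and standard-deviation formatting use decimal arithmetic with
  half-up rounding so printed tables are stable across platforms.
- Typical validated problem sizes: hundreds to a few thousand sequences
  cluster in seconds (the demo's 219 sequences → 2,056 edges takes a few
  seconds including JIT compilation). The prefilter keeps the alignment
  count near-linear in practice for family-structured data; truly
  all-similar inputs degrade to quadratic.

## Limitations

- Louvain is a heuristic; restarts make small-graph optima reliable but
  global optimality is not guaranteed on large graphs.
- Edge criteria are tuned for full-length homology. Multi-domain
  proteins sharing one domain are deliberately *not* connected; if you
  want domain-level clustering, lower the coverage threshold knowingly.
- The fragment detector requires a reference cluster of ≥ 3 members and
  genomic adjacency; fragments of rare genes or trans-located fragments
  are missed.
- The missing-member detector only reasons about near-universal
  clusters (representation ≥ 0.9 by default).
- Detector output is a screen, not a verdict: findings are ranked
  evidence intended for manual review.
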