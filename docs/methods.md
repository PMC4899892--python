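# Methods

## The staged-evolution model

The package analyses a *stage series*: an ordered set of cell populations
(parental → intermediate sub-lines → final resistant) isolated during
stepwise drug-dose escalation, each exome-sequenced. The underlying
biological assumption is that resistance evolves clonally: variation that
confers a survival advantage under drug pressure is acquired at some stage
and then carried by the expanding resistant clone through every later
stage, whereas neutral or deleterious variation drifts in and out.

### Acquisition and assessability

A variant is acquired at the earliest stage *i* ≥ 1 where it is called
while the preceding stage shows positive evidence of absence: not called,
read depth strictly greater than four, and zero reads supporting the
alternative allele. "Greater than four" is implemented as depth ≥ 5. A
call/no-call transition whose preceding stage has depth ≤ 4, or no reported
depth, cannot be assessed; if a variant has only such transitions it is
flagged unassessable rather than forced into either class. Unknown depth
(missing DP in the VCF) is deliberately distinct from depth zero for this
reason. Variants already called in the parental stage are never acquired.
When a variant is called, lost, and called again, only the earliest
transition satisfying the rule counts; re-appearances do not create second
acquisition events.

"Called" is taken from the genotype field of the multi-sample VCF when
present (the calls come from an upstream joint genotyper that this package
does not run); records without GT fall back to `alt_depth > 0` with a
warning.

### Selection and transience

An acquired variant is a selective event iff it is called at every stage
after acquisition up to and including the final resistant stage.
Acquisition at the final stage itself is vacuously selected — there are no
later stages to contradict persistence, and final-stage acquisitions are
reported as selected in the per-stage summary. Acquired variants that
disappear at any later stage are transient and excluded from downstream
candidate selection.

### Functional triage

Selective events are classed per transcript annotation:

* **A (likely functional):** splice donor/acceptor, stop gained/lost,
  frameshift, initiator codon, TF binding site; missense when SIFT calls it
  deleterious, PolyPhen calls it probably/possibly damaging, or it falls in
  an annotated protein domain.
* **B (indeterminate):** in-frame insertions/deletions, benign missense,
  splice region, incomplete terminal codon, mature miRNA, NMD transcript,
  and regulatory-type terms (regulatory region, feature elongation/
  truncation).
* **C (likely silent):** synonymous, stop retained, 5′/3′ UTR, non-coding
  exon, nc-transcript, intron, upstream/downstream, intergenic.

The consequence vocabulary is closed (27 terms); unknown terms are rejected
rather than coerced, so upstream annotation drift surfaces as an error. A
variant's label is the most severe class over its annotations (A < B < C,
ties need no intra-class ordering). Consequence tallies are per
variant-transcript annotation, not per variant, which is why tally totals
exceed variant counts in the stage reports.

## Copy-number detection

The caller is deliberately simple and regional: the capture regions the
counts come in are the unit of analysis (no base-level re-binning, no
cross-region segmentation). Counts from test and reference stages are
normalised to counts-per-million, stabilised with a 0.5 pseudocount, and
compared as log2 ratios. Normalising before adding the pseudocount makes
the ratios exactly invariant to library-size scaling and exactly
antisymmetric under swapping test and reference. Significance uses an
empirical null estimated from all regions — appropriate because the large
majority of regions are copy-neutral — centred at the median with spread
1.4826·MAD, two-sided normal p-values and Benjamini–Hochberg correction
across regions; calls require q ≤ α (default 0.05). A degenerate null
(MAD = 0) yields no calls instead of dividing by zero. At least 20 regions
are required to estimate the null. Because the reference is always the
parental or a preceding stage, every call is by construction acquired; both
reference choices are supported via configuration.

Segments map to genes by any ≥ 1-base overlap (1-based inclusive
coordinates throughout; BED input is converted at the boundary). A gene
call is *persistent* if re-detected in the final stage in the same
direction, or rescued by expression concordance: a significant
final-vs-parental log2 fold change in the direction of the copy-number
change. The significance flag is required, not just the sign, because
microarray fold changes are noisy near zero.

## Random-walk prioritization

Candidate genes are scored by the steady state of
`p ← (1−r)·W·p + r·p0` with `W` the column-normalised weighted adjacency
and `p0` uniform over the seed set. Defaults: restart probability r = 0.5
(the field's usual mid-range choice; there is no published value to match
for this analysis), convergence when the L1 change drops below 1e-12.
Dangling (degree-0) columns hand their mass back to `p0`, which keeps the
score vector an exact probability distribution at every iteration; isolated
candidates therefore score 0 and rank last. A dense linear-solve
implementation of the same fixed point is provided as an independent
cross-check and agrees with the iteration to better than 1e-8 on small
graphs. Ranking is by descending score with lexicographic tie-breaking so
reports are deterministic. The edge-list file format cannot represent
isolated nodes, so candidates absent from the loaded network are excluded
with a warning rather than scored.

Hallmark mapping tallies candidate genes over the eleven acquired-
capability categories H1–H11 from a curated two-column file; genes without
a mapping are listed separately. Over-representation per annotation term
uses the exact hypergeometric upper tail with BH correction — an explicit,
reproducible substitute for web-tool enrichment scores whose clustering
heuristics cannot be re-run offline.

## Growth kinetics

Doubling time assumes exponential growth `N = N0·e^(kt)` with absorbance
proportional to cell number: `k` comes from ordinary least squares of
`ln N` on `t` inside a user-supplied exponential window (no automatic
window detection — plateau points would silently bias the fit), and the
doubling time is `ln 2 / k`; `k ≤ 0` is an error. Survival ratio is
sub-line viability over parental viability at the same dose; viabilities
slightly above 1 are tolerated for assay noise.

## The synthetic data generator

The generator emulates the study design of the two cell-line models: six
stages by default (parental, four intermediates, final resistant) with an
MCF-7-like dose escalation (0, 0.27, 1.2, 7.5, 45, 65 nM). Defaults: 500
variants, 40 % acquired, half of those selected; depth ~ Poisson(30), clonal
VAF 0.5 (the true clonal fraction and purity of real sub-lines is unknown,
so this is a free parameter, not an estimate), flat error rate 0.001 on
non-carrier stages; 200 regions at ~100 reads each with 5 planted
copy-number changes of |log2| = 1; expression coupled to planted CNA genes
with probability 0.8; a 300-node network with 10 seeds and 5 planted
seed-proximal genes wired to three seeds each at weight 5 over a random
background of average degree ~4.

Construction guarantees planted labels are consistent with the
classification rules: all stages before a planted acquisition have depth
≥ 5 and zero alternative reads, carrier stages are called with at least one
alternative read, and transient variants vanish from a chosen stage through
the final one. The flat error rate puts occasional stray alternative reads
in non-carrier stages of unplanted variants, exercising the
prior-evidence and assessability branches. One seed sequence spawns an
independent child stream per component (variants, annotations, regions,
expression, network, hallmarks), so the same seed reproduces the bundle
byte-for-byte and changing one component's size does not perturb the
others.

What the generator does **not** emulate: alignment artifacts, mapping-bias
or GC-dependent coverage, subclonal mixtures and drifting allele fractions,
linkage between variants, probe-level microarray noise, or realistic
network topology (the background is Erdős–Rényi-like). Passing recovery
tests therefore demonstrates correctness of the classification and
detection logic under the stated statistical model, not performance on real
exomes — planted-event recovery is near-perfect by design because planted
events satisfy the rules exactly; the interesting failure modes on real
data (low coverage, impure populations) enter through the unassessable
branch and the error model.

## Numerical and design choices

- Internal coordinates are 1-based inclusive everywhere; BED's 0-based
  half-open intervals are converted on read and back on write (an exact
  involution). Chromosome names are normalised to the un-prefixed dialect.
- Readers reject malformed input instead of repairing it; writer/reader
  pairs are exact inverses on valid data (expression floats are parsed
  with round-trip precision for this reason).
- Multi-allelic VCF records are split into biallelic observations at read
  time; no further decomposition.
- Library-size invariance of the CNA ratios is bit-exact for power-of-two
  scalings and holds to ~1e-15 otherwise (floating-point cancellation).
- Reports are TSV with JSON mirrors and contain no timestamps, so reruns on
  identical inputs are byte-identical; the run log carries the config hash,
  seed and input checksums instead.
- Pipeline failures remove partial outputs and name the failing stage.

## Known limitations

- The CNA caller is a regional simplification; it does not reproduce
  base-level callers' segment boundaries, and published gene-level CNA
  lists from real data are not a reproduction target.
- Seed-gene lists, functional networks and hallmark assignments are
  curated inputs; the package ships no curation.
- Acceptance-style recovery figures use problem sizes (500 variants, 200
  regions, 300-node networks, 50 replicates) chosen to exercise every code
  path at interactive runtimes; the machinery is vectorised or sparse and
  scales to exome-sized inputs.
- No replicate-aggregation rule is implemented for doubling times; each
  curve is fit independently.
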