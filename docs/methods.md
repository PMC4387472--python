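# Methods

This note documents the models and procedures implemented in `cennest`,
the parameters that matter, and what the synthetic benchmarks do and do
not demonstrate.

## Coordinates and conventions

All genomic and consensus coordinates are 0-based half-open internally.
Files in 1-based-inclusive formats (GFF3, RepeatMasker `.out` tables) are
converted at the I/O boundary.  Minus-strand repeat hits carry
consensus-forward intervals (`cstart < cend`); the genomic start of a
minus-strand hit corresponds to the consensus end.  Softmasked input
sequence is uppercased on load, since masking state is irrelevant to these
analyses.  Printed summary values (densities, ratios, percentages) are
rounded half away from zero at the stated precision, because that is how
such tables are conventionally printed (8.25% → 8.3%).

## The synthetic centromere model

The simulator is the package's oracle: it produces sequences whose full
insertion history is known exactly, so curation, nesting, dating,
comparison and read assignment can all be scored against planted truth.

**Insertion mechanics.**  Starting from a random backbone, `n_insertions`
element copies are inserted oldest-first.  Each insertion cuts the target
at position *x*, duplicates the `tsd_length` bases immediately left of the
cut as a target-site duplication (TSD), and splices in the copy, so the
element ends up flanked by two identical TSDs — the signal the curation
stage must detect.  The TSD bases are copied from the target sequence, not
generated randomly, matching the biological mechanism.  With probability
`nesting_bias` the cut lands inside an existing element (splitting one of
its fragments in two and making the new element its nested child);
otherwise it lands in backbone.  All previously recorded coordinates are
re-projected after every insertion, so the event log carries exact final
intervals, and nesting parentage is recorded directly.

**Placement constraints.**  Cut sites keep a margin (default 60 bp) from
fragment boundaries, and backbone cuts avoid existing TSD copies and anchor
genes.  This serves two purposes: fragments never drop below the published
50-bp hit-length filter, and planted TSDs are never destroyed by later
insertions, keeping the TSD-identity invariant exact.  Real centromeres do
contain insertions that truncate neighbours; the simulator deliberately
trades that realism for exact ground truth.

**Structural variants.**  With probability `solo_ltr_prob` an LTR-element
insertion is emitted as a single LTR plus TSD pair, emulating solo LTRs
produced by intra-element recombination.  Class II families carry exact
terminal inverted repeats; Helitrons have neither TIRs nor TSDs
(`tsd_length` 0).

**Divergence.**  After all insertions, each copy receives substitutions at
rate `mutation_rate_per_age_unit × (n_insertions − age_rank)`, so older
copies are more diverged — which is what makes LTR dating testable.  The
default divergence model is substitutions-only: indels would break the
exact coordinate bookkeeping the oracle tests rely on.  This is the main
respect in which the synthetic data is easier than real data; passing the
round-trip benchmarks shows the pipeline logic is correct, not that it is
robust to indel-rich, deletion-eroded real repeats.

**Lineage pairs.**  `diverge_pair` resumes the (pre-mutation) ancestral
state twice, adds lineage-tagged insertions to each copy, then applies
substitutions with ages continuing from the ancestral ranks plus uniform
backbone divergence proportional to the lineage's elapsed age.  Ancestral
insertions are never deleted, so the planted ortholog map is the identity
on ancestral event ids.  Conserved "anchor genes" are planted as
insertion-free backbone islands; real centromere genes are conserved but
not insertion-free, so anchor quality is idealised here.

**Read sampling.**  `simulate_chip_reads` draws read start positions with
probability proportional to the enrichment weight of the family at the
read midpoint (the `"backbone"` key weights unannotated sequence), labels
each read by that same midpoint family, and reverse-complements half the
reads.  Reads carry no sequencing error; divergence of the underlying
copies from their consensus is the only noise source.

**Default study conditions.**  The benchmark configurations use
centromere-like densities at desk scale: 0.3–1 Mb backbones, 30–150
insertions, nesting bias 0.4–0.6 (nested blocks reach 5–6 layers),
solo-LTR probability 0.1, and per-age-unit substitution rates of 0 (exact
round trip), 5×10⁻⁵ (≤0.5% divergence, ortholog calling), 2×10⁻⁴ (read
assignment) and 1×10⁻³ (dating, giving the oldest copies ~10% LTR
divergence).  Simulated libraries hold ~10 families (half Class I LTR
families of 3–8 kb with 250–500 bp LTRs and 5-bp TSDs; half Class II
families of 0.15–2.5 kb with superfamily-typical TSD lengths, e.g. 9 bp
Mutator, 3 bp CACTA, 0 bp Helitron).  Problem sizes were chosen so the
full suite and the acceptance script each run in well under a minute on
one CPU while leaving every stage's behaviour measurable.

## Curation

The stages formalise manual repeat-annotation practice:

1. **Filter** — keep hits with alignment score strictly greater than 300
   and genomic length strictly greater than 50 bp (the published cutoffs).
2. **Overlap resolution** — process hits by descending score (ties: longer
   hit, earlier start, family name); later hits are trimmed to unclaimed
   bases, with consensus intervals trimmed colinearly (an indel-free
   approximation adequate for short trims).  Remainders shorter than the
   length filter are dropped.
3. **Fragment chaining** — same-family, same-strand hits are chained into
   one element when their consensus intervals advance colinearly (gap
   ≤ 50 bp, overlap ≤ 20 bp, evaluated in element orientation) and the
   genomic gap between them is either ≤ 50 bp or ≥ 90% covered by other
   hits — the signature of a host split open by nested insertions.  Among
   equally colinear open chains the nearest, most recently opened chain
   wins: nested same-family copies close LIFO, like brackets, so the inner
   chain is the correct continuation.
4. **TSD detection** — k-mers within ±3 bp of the block boundaries are
   compared at the family's expected TSD length (scanning k ∈ [4,6] for
   unknown families), allowing 1 mismatch; the best pair is recorded.
   Families with expected TSD length 0 report no TSD.
5. **Structure class** — *intact* requires ≥ 80% consensus coverage
   including ≥ 80% of both terminal repeats; *solo-LTR* requires ≥ 80% of
   one LTR and ≤ 10% of the internal region; anything else is *truncated*.
   These thresholds are package choices (the original inspection was
   manual) and all are exposed in `CurationConfig`.

One merged element counts as one copy in content tables; counting
fragments would inflate copy numbers in nested regions.

## Nesting

Element B is nested in host A when B's block span lies inside the gap
between two consecutive fragments of A; with several candidate hosts the
smallest enclosing gap wins, which identifies the immediate host because
ancestors' gaps strictly contain it.  Containment makes the relation
acyclic; layers follow by traversal (backbone = 0 children at layer 1).
A nested block is a layer-1 host with at least one descendant; block size
is the genomic span of the root from first fragment start to last fragment
end, the only definition that grows as multi-layer content accumulates.
The four-way insertion-preference table classifies each TE-hosted element
by (its class → its immediate host's class); the preference ratio is
RNA→RNA over RNA→DNA, reported to one decimal.

## LTR dating

Only intact Class I LTR elements are dated.  The two LTR sub-sequences are
extracted through the fragment/consensus mapping (stitched across nested
splits and reverse-complemented for minus-strand copies) and globally
aligned with edlib; gap columns are excluded and mismatch columns counted.
With p = mismatches / aligned columns, the Jukes–Cantor distance is
K = −¾ ln(1 − 4p/3), undefined for p ≥ 0.75, and the age is T = K/(2r).
The default rate r = 1.3×10⁻⁸ substitutions/site/year is the grass
intergenic convention and is exposed everywhere; dating output should be
read as relative unless the rate is calibrated for the taxon at hand.
Kimura-style transition/transversion corrections and maximum-likelihood
distances are out of scope.

## Ortholog calling between assemblies

Coordinates are not comparable between repeat-dense assemblies, so
comparison is anchored on conserved genes.  Shared gene ids are sorted by
assembly-A position and crossing anchors removed by keeping the longest
subsequence that also increases in B.  Elements are assigned to
inter-anchor gaps by block midpoint; elements outside the anchored
interval are excluded from totals, mirroring the exclusion of regions
without a clearly orthologous counterpart.

Within a gap, candidate pairs must share a family, have a length ratio of
at least `min_cov` (default 0.8), and align (shorter contained in longer)
at identity ≥ `min_identity` (default 0.9).  Candidates are scored by

```
2·[TSD sequences equal] + 2·flank_identity + element_identity − 0.02·|Δrank|
```

and matched greedily one-to-one with deterministic tie-breaks.  The three
terms correspond to the three classical lines of evidence: structure/TSD,
sequence alignment, and flanking context.  Two design points deserve
justification.  First, detected TSDs that disagree by more than one
substitution veto the pair: independent insertions duplicate different
target sites, and a one-substitution allowance absorbs post-divergence
mutation of a flank.  Second, element identity alone is a misleading
ranking signal among same-family copies — a diverged ancestral copy is
*more* similar to a young independent insertion than to its true, equally
diverged ortholog — so the 30-bp flanking context on each side, which is
shared only by true orthologs, is weighted as strongly as TSD equality,
and pairs whose flanks fail to align at 0.75 identity are rejected.
Positional rank is computed within (gap, family) because same-family
copies preserve relative order across lineages while gap-wide ranks shift
whenever a lineage-specific element lands in the gap.

The comparison table reports shared counts (symmetric by construction),
per-genome totals and unshared counts with a retrotransposon subcount, and
polymorphic rates (unshared/total, percent to one decimal).

## Locus reports

Window tracks assign each element once, to the window containing its block
midpoint, so window counts always sum to the element count regardless of
boundary-spanning blocks.  Gene/TE overlap classification assigns a
gene-overlapping element to the compartment (CDS, UTR, intron) with the
largest base-pair overlap, with the precedence CDS > UTR > intron breaking
ties; intergenic elements are excluded from the table.  Genes whose CDS is
≥ 50% covered by TE annotation are dropped beforehand as TE-protein genes
(threshold exposed).

## Read-to-family assignment

A k-mer index (k = 12, both strands) nominates candidate families; each
candidate is scored by containment alignment of the read within the
consensus, with score S = read_length − 3·edits and a
Karlin–Altschul-style significance E = K·m·n·e^(−λS) (K = 0.1, λ = 0.5,
n = total indexed bases).  A read is assigned to its single best family
when E ≤ 10⁻⁵; exact score ties are reported as ambiguous, and
assigned + unassigned + ambiguous always equals the read count.  The
parameters were chosen so that, like a BLAST-style search at the same
threshold, full-length reads at up to ~15% divergence from their family
remain significant while random 100-mers (which typically align no better
than ~70% identity anywhere in a small library) never do.  Absolute
E-values are not comparable to any particular external search tool — only
the thresholding behaviour is contractual.  Raising the threshold can only
grow the assigned set (score and search space are fixed per read).

## Known limitations

* The divergence model has no indels by default; coordinate-exact oracles
  would otherwise require alignment-based lift-over.
* Tandem satellite arrays (e.g. CentO-like monomers) are not modelled; the
  backbone is random sequence.
* Orthology is pairwise; three-way comparisons are run as pairs.
* The simulator never deletes or truncates elements beyond the solo-LTR
  reduction, so curation is not tested against erosion artefacts.
* Insertion ages are uniform ranks, declared rather than fitted to any
  empirical age distribution.
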