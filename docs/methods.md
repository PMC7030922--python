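# Methods

This note documents the models, parameters, numerical conventions, and design
choices behind each analysis stage, and what the synthetic-data generators do
and do not emulate.

## Cross-link data model

A cross-link's identity is the unordered residue pair
{(accession, position), (accession, position)} in 1-based UniProt-style
sequence coordinates; chemistry and charge-state variants of the same residue
pair collapse into one link. Duplicates merge their sample sets and keep the
minimum identification FDR. The default FDR cutoff is 0.02 (2%), the standard
operating point for cross-link identification, and is configurable per
dataset. Links inferred from peptides shared by more than one protein are
retained but flagged *ambiguous*; they are excluded from protein-pair counts
and network edges unless the caller opts in, because a shared peptide cannot
attribute the interaction to a single protein pair.

Structure author numbering is never assumed to match sequence numbering;
the two are reconciled by a global pairwise alignment (match +1, mismatch −1,
gap −2, Biopython `PairwiseAligner`) keeping only aligned identical residues.
An alignment identity below 30% over aligned columns aborts the mapping — in
practice this only happens when the wrong chain was requested.

## Distance restraints

The restraint threshold defaults to 33.4 Å: the ~23.4 Å Cα–Cα reach of a
DSSO-class lysine-reactive cross-linker plus ~10 Å allowance for in-solution
flexibility. It is a per-run parameter; stricter values (e.g. 23.4 Å alone,
or 27 Å) are used in docking-oriented workflows where the geometry matters
more than detection.

For homo-oligomers a cross-link cannot be assigned to a specific chain copy.
We enumerate every placement of the two endpoints over the supplied chain
maps and take the **minimum** distance: a link is explained if *any* copy
pair satisfies it. The degenerate placement of one residue onto itself in
the same chain is excluded. Residues missing from the deposited model are
reported unmappable, never imputed — loop modelling is out of scope — and
unmappable links are flagged rather than dropped, so the denominator of the
satisfaction fraction is always the mapped links. Distance histograms use
5 Å right-open bins starting at 0.

When several structures are supplied, each link's pooled distance is its
minimum over the structures where it maps, consistent with the
minimum-placement rule; per-structure summaries are also reported.

## Topology checks

Each endpoint takes the label of the annotated region containing it;
transmembrane and "other" regions count as unannotated, as does any position
outside all regions (UniProt topology is sparse; regions need not tile the
protein). A link is a *violation* only when its two sides are exactly
{cytoplasmic, extracellular}; the rate's denominator contains only links with
**both** endpoints annotated. Positions beyond the protein length are data
errors, not unannotated positions.

## Network statistics

The interaction graph has one node per protein and one undirected edge per
interprotein-linked pair, with the number of unique links and of supporting
samples kept as edge metadata. All topology statistics (betweenness,
modularity, paths) run on the **unweighted** graph; nothing in the analysis
design calls for weighted clustering, and the counts remain available as
metadata. Hyper-connected contaminant-like hubs can be excluded by accession
at build time.

Girvan–Newman clustering iteratively removes the edge with the highest
unweighted edge-betweenness, breaking ties toward the lexicographically
smallest edge so the procedure is fully deterministic. Every time the
component count grows, the partition is scored by Newman–Girvan modularity
*on the original graph*; the best-scoring partition wins, with the trivial
single-community partition (Q = 0) as baseline, so structureless graphs come
back as one cluster. Exact modularity values depend on this stopping rule;
other implementations may return slightly different partitions on graphs
with near-tied splits.

The permutation null rewires the graph by double-edge swaps: each of the
(default 100) permutations attempts 10·|E| swaps, rejecting any that would
create a self-loop or multi-edge. The degree sequence is preserved exactly by
construction; 10 attempts per edge is a standard mixing heuristic. The
co-annotation statistic (fraction of edges whose endpoints share a term,
default restricted to terms with > 50 annotated proteins in the graph) and
the cluster-consistency statistic (per-node fraction of labelled neighbors in
the same cluster) are both compared to their null distributions with
two-sided two-sample Kolmogorov–Smirnov tests. Term enrichment uses one-sided
(greater) Fisher's exact tests with Benjamini–Hochberg adjustment across
terms; interface enrichment uses the two-sided test, since depletion there is
equally informative.

Degree power-law fits are ordinary least squares through
(log₁₀ degree, log₁₀ frequency) over nonzero-frequency degrees and require at
least three distinct degrees; R² near 1 with negative slope is the scale-free
signature.

## Evidence tiers and replication

Tier boundaries follow the ≥-inclusive reading: STRING 400 → medium,
700 → high (the 400–700 interval right-open); InWEB 0.2 → medium,
0.7 → high, absent score → low; BioGRID low-throughput → high, all else low.
A pair's tier is the best over its records, and "high confidence" means high
in at least one source. Tier classification is total and deterministic over
the score domain.

Replicate agreement counts, per interprotein pair, the number of replicate
datasets containing it; the histogram is invariant under dataset order.
Neighbor agreement evaluates the edges of the *older* network against the
newer one, restricted to shared nodes: direct (edge present), indirect
(≥ 1 common neighbor), unconnected — the three fractions sum to one exactly.

The abundance–lysine correlation correlates, per protein, the number of
distinct cross-linked lysines against abundance divided by total lysine
count, both log₁₀-transformed. "Corrected for the total number of lysines"
is implemented as this ratio; it is a documented modelling assumption, as no
canonical formula exists.

## Binding sites

Cross-species lysine transfer uses the identical-prefix rule: a position maps
confidently only when the destination sequence is identical to the source
over positions 1..pos. This is deliberately conservative — any upstream indel
or substitution invalidates the coordinate — and is transitively consistent.

Array quantification follows the experimental normalisation chain: subtract
the array background, divide by the background-subtracted positive-control
(antibody antigen) spot, subtract the mean of the equally normalised tag-only
negative-control spots, average technical replicates, subtract the same
quantity from the nonspecific-binding control experiment, and clip negatives
to zero (intensities are physical). The pipeline is linear in the raw signal
above background until the final clip. A positive control at or below
background is an error: normalisation is undefined.

Binding regions require at least two sequence-overlapping peptides above the
positivity threshold; a region spans the union of its supporting peptides, so
called regions are pairwise disjoint, and isolated positive spots are
rejected as nonreproducible. The default threshold is the mean + 2 SD of the
normalised negative-control spots — a conventional filtering rule supplied
because no universal numeric cutoff exists; it is configurable. Interface
enrichment takes as background all lysines of the proteins under
consideration, with the cross-linked ones as the selected class.

## Synthetic worlds

Every generator consumes a `numpy.random.default_rng` seed; a single global
seed fans out to per-generator streams through fixed offsets, so worlds are
reproducible bit-for-bit without coupling the generators.

- **Toy complexes** are self-avoiding random walks with exact 3.8 Å steps
  (the Cα–Cα virtual bond length) and a 4.0 Å non-adjacent clash limit,
  within and across chains; chains start 6 Å from the previous chain's
  surface. ~15% of residues are lysine, a typical lysine frequency.
- **Simulated cross-links** draw a Binomial(n, v) number of violating links
  from lysine pairs beyond the threshold and the rest from pairs within it,
  sampling without replacement so links are unique. The binomial draw (rather
  than a deterministic round(v·n)) gives recovery tests their correct
  sampling distribution.
- **Topology worlds** give each membrane protein a cytoplasmic region, a
  20-residue transmembrane segment at a random depth, and an extracellular
  region; each link crosses sides independently with the target rate.
- **Replicates** detect each pair per replicate with probability
  logistic(intercept + slope·log₁₀ min-partner abundance): detection is
  limited by the scarcer protein. The logistic form is a phenomenological
  stand-in — no mechanistic detection model is implied — and the default
  operating point (slope 1.5, intercept −3 on abundances ~10²) puts median
  detection near 0.5, the regime where replicate histograms are informative.
- **Planted networks** are standard planted-partition graphs (within-module
  edge probability p_in, between p_out < p_in) with one annotation term per
  module plus an optional spill-over fraction of outside nodes.
- **Evidence databases** sample each pair's tier from a target mix and then a
  source and score consistent with that tier; BioGRID has no medium tier
  under the rules, so medium pairs draw from STRING or InWEB.
- **Arrays** tile the target with 20-mers at offset 10, plant specific signal
  in the true regions on the normalised scale, add optional nonspecific
  signal shared with the control experiment and Gaussian noise, and convert
  back to raw fluorescence units.

The default full world uses a 5-chain × 150-residue complex with 400
simulated links at 1% violation, 1000 topology links at 0.87% cross-side
rate, a 4×25 planted network (p_in 0.3, p_out 0.01), 3 replicates, a
(0.5, 0.3, 0.2) tier mix, and evidence covering 51% of pairs — the regime of
a high-quality cross-linking study. These problem sizes keep every stage
comfortably fast on one CPU while leaving all strata well populated.

What the generators do **not** emulate: spectra, peptide digestion,
chromatographic fractionation, identification errors correlated across
replicates, annotation bias, or structures with realistic secondary
structure. Passing recovery tests on these worlds therefore demonstrates the
correctness of the statistical machinery under its stated assumptions, not
the end-to-end fidelity of any acquisition pipeline.

## Numerical conventions and limitations

- Ties in component sizes resolve toward the component containing the
  lexicographically smallest node; edge-betweenness ties toward the
  lexicographically smallest edge; altloc occupancy ties keep the first
  encountered atom. All are logged where relevant.
- Undefined statistics (violation rate with no mapped link, correlation on a
  constant variable, power-law fit on < 3 distinct degrees) raise typed
  errors rather than returning NaN.
- The headline counts of any given published dataset can only be reproduced
  from that dataset's own distributed tables and structures; the test suite
  carries a check that consumes such tables from `data/external/` when the
  user supplies them, and fails otherwise.
- Solvent-accessible-surface distances are not computed; all restraint
  distances are Euclidean. Spectral search, docking, homology modelling, and
  annotation curation are out of scope.
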