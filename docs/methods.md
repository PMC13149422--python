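# Methods

This note documents the models, defaults and numerical choices behind
`peff`, and what the synthetic-data tests do and do not establish about
real data.

## Scope and data regime

The package re-creates, at desk scale, the computational chain of a
phosphorus-efficiency screen in the *Medicago sativa* complex: a
k-mer presence/absence GWAS from raw short reads, candidate-gene
windows around significant fragments, phosphorus-efficiency indices
from pot-experiment tables, and root-system-architecture (RSA) traits
from scanned root masks.  All inputs are produced by the `simdata`
module; the defaults are chosen to mirror the study conditions
(200 accessions, three replicates per treatment, canonical 31-mers with
a per-sample count floor of 5, MAF ≥ 0.01, −log10 p thresholds 5/4,
±50 kb windows, 600 dpi scans) on a deliberately scaled-down genome of
one 200 kb contig with ten 2 kb genes.  Problem sizes throughout
(genome length, read depth, marker counts) are chosen so a complete
five-seed recovery experiment runs on a single CPU in minutes.

## Presence/absence alleles

Causal variants are modelled as *presence/absence segments*: blocks of
reference sequence carried with Bernoulli(frequency) by each accession
and deleted from non-carriers.  The reference assembly represents the
presence allele, so the diagnostic k-mers of a planted locus (those
overlapping the segment, unique in the genome and absent from the
deletion haplotype) assemble into a fragment that maps exactly back to
the planted position — the behaviour needed to exercise the
window/annotation logic end to end.  The deletion haplotype gains a
handful of junction k-mers; these associate with the opposite sign and
map nowhere, exactly like the unplaced loci that occur in practice when
an associated allele is missing from the assembly.  An alternative
design — novel insertions absent from the reference — produces
diagnostic k-mers whose fragments cannot be placed by exact matching at
all, which would leave the annotation stage untested; it can still be
emulated by interpreting the "deletion" haplotype as the reference
carrier.

Accessions are single haplotypes by default.  Real genebank accessions
are heterogeneous populations; a `pool_pairs` flag mixes two haplotypes
per accession (shared carriage, independent background SNPs) as a
sensitivity hook, but no attempt is made to model tetraploid dosage.

## Generator defaults and why

* **Phenotype scale.** The default simulated trait mimics shoot dry
  matter: μ = 4.82 g/pot, LP treatment shift −1.14 g (≈ −24 %),
  replicate noise σ²_e = 1.0, polygenic variance σ²_g = 0.5, three
  replicates per treatment.  Root dry matter (μ = 1.43, shift −0.33)
  and shoot P concentration (μ = 4.2 mg/g, shift −1.5) use the same
  machinery; values are clipped at a small positive floor because a
  Gaussian replicate model can stray below zero on the RDM scale.
* **Polygenic background.** The polygenic term g ~ N(0, σ²_g·K_truth)
  uses a kinship built from the *neutral* loci carriage matrix only.
  Including the causal carriage in K_truth would double-count the fixed
  effect being estimated and is a model error, not a modelling choice.
* **Background density.** 40 neutral presence/absence segments
  (~one per 5 kb) segregate alongside the causal locus.  This keeps the
  *share* of kinship weight carried by any single locus small, which is
  the regime of a real genome-wide marker panel: with only a few
  background loci on a 200 kb toy genome, the causal locus's ~100
  diagnostic columns would dominate the kinship matrix and the mixed
  model would absorb much of the signal into the random effect — a
  proximal-contamination artifact of down-scaling, not a property of
  the method.
* **Background SNPs.** Private substitutions at 2 × 10⁻⁵ per base per
  accession.  Each SNP silently removes ~k reference k-mers from one
  accession; at n = 200 these near-monomorphic columns mostly fall
  under the MAF filter, and the rate keeps the residual marker count
  (~6×10³) proportionate to the toy genome.
* **Reads.** Single-end 100 bp, uniform start positions, strand flipped
  with probability ½, i.i.d. substitution errors, constant FASTQ
  quality characters; 30× default depth.  No restriction-site model,
  PCR duplicates or indel errors — the counting stage only needs
  presence/absence fidelity, for which uniform coverage is adequate.

What passing the synthetic tests shows: the counting, matrix, mixed
model, fragment and window code are internally correct and recover
planted truth under the stated noise model.  What it does not show:
robustness to GBS coverage artefacts, library effects, population
structure beyond the simulated kinship, or tetraploid allele dosage.

## k-mer stage

Canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement; k odd so no self-complementary k-mers) are counted per
sample with a floor of 5 on the orientation-summed count — the floor is
read as per-sample, matching the per-sample counting workflow.  K-mers
containing ambiguous bases are skipped and tallied to the log.  Strand
is resolved by majority vote on canonical vs reverse-complement
observation counts aggregated across samples, ties keeping the
canonical form.  The presence/absence matrix is the union of retained
sets; MAF = min(f, 1−f) of the presence frequency, and monomorphic
columns are always dropped (a constant predictor is untestable — at
n = 200 the MAF < 0.01 rule subsumes this, but not in small tests).
Internally k-mers are 2-bit-packed uint64 codes; base order A<C<G<T
makes numeric order equal lexicographic order, so everything stays in
integer space until strings are needed.  Fixed-length read arrays take
a vectorised rolling-hash path, cross-checked in tests against the
generic per-read path and a dictionary oracle.

## Association model

Per k-mer x, the model is y = 1μ + xβ + u + ε with u ~ N(0, σ²_g K),
ε ~ N(0, σ²_e I), y the per-accession replicate mean for one
treatment.  K = Xc·Xcᵀ/m from the column-centred presence matrix (the
standard estimator for binary panels; a per-column standardised variant
sits behind `normalize=True`).  Both null and alternative models are
fitted by maximum likelihood — not REML, because the likelihood-ratio
test compares fixed-effect structures and nested-model validity
requires ML.  One eigendecomposition of K serves all markers; the
profile likelihood is maximised over λ = σ²_g/σ²_e on a 21-point log₁₀
grid spanning [1e−5, 1e5], refined by bounded scalar minimisation
(xatol 1e−7).  Variance components are re-optimised under the
alternative (exact LRT; holding them at null values is the score-test
shortcut and is not the default).  LRT = 2(ℓ_alt − ℓ_null) is clamped
at zero against round-off and referred to χ²₁; p-values are floored at
1e−300 with a warning rather than truncated to zero.  Selection is
two-tier: strictly above 5 on the −log10 scale, else inclusively at or
above 4, else none.  No multiple-testing correction is applied beyond
these fixed thresholds.

Calibration: with β = 0 and a polygenic signal simulated on the
panel's own kinship (5 seeds × 2,000 markers × 200 accessions), the
empirical type-I rate at α = 0.05 sits near 0.05 and a
Kolmogorov–Smirnov test does not reject p-value uniformity — the
asymptotic χ²₁ reference is adequate at n = 200.

## Fragments and windows

Selected k-mers are merged through an overlap graph with exact
(k−1)-suffix/prefix edges, a k-mer and its reverse complement forming
one node.  Maximal unambiguous paths (unitigs) become fragments;
branches and isolated k-mers stay singletons; output is reported in
canonical orientation and sorted, so the result is independent of input
order.  Mapping is exact substring search on both strands — the real
fragments are only 31–52 bp, and no mismatch-tolerant scoring is
described for this step; fragments without a placement are retained
with empty hits and logged.  Windows are edge-extended ±50 kb clipped
to contig bounds (window ≤ 100,001 bp), and candidate genes are all
annotated genes intersecting the window by ≥ 1 bp, strand-agnostic.
Multi-hit fragments produce one window per hit and are flagged;
`unique_only` reproduces single-placement reporting.

## Phenotype indices

Shoot P content = SDM × shoot P concentration (mg/pot); PUE =
SDM / shoot P content (g DM per mg P), so PUE × content returns the
same pot's SDM identically.  STI = Y_p·Y_s / (mean Y_p)² with mean Y_p
taken over **all** accessions in the analysis set under HP.  ΔRDM =
mean(RDM | HP) − mean(RDM | LP) per accession, ranked signed and
descending; accessions with more root mass under LP rank at the bottom
and fall into the Low pool.  The 10-of-30 subset choice in the original
design also weighed biostatus and geographic origin — criteria that are
not computable from the tables — so the picker is a pluggable hook
whose default takes the most extreme by signed ΔRDM.  RSR, where
needed, is computed per pot as RDM/SDM (ratio of pot values, not ratio
of means).  The two-way ANOVA is a fixed-effects OLS with an additive
replicate block and type-I sums of squares in the order block,
treatment, group, treatment × group — a contract-level approximation of
a replicate-random-effect mixed model; with balanced designs the
treatment-term F-tests agree closely, and no published mixed-model
p-value is treated as a reproduction target.

Redundancy pruning: uncorrected p-distance over pairwise-complete
sites; per round, pairs at or above 99.97 % similarity are linked, each
connected component keeps the accession with least missing data (ties
by lexicographic id), and the procedure runs three rounds or to a fixed
point.  Pairs with zero overlapping sites are non-comparable and
treated as non-redundant with a warning; a post-condition audit logs
any surviving redundant pair.

## Root-system architecture

Pixels convert to mm via 25.4/dpi.  Length is the weighted skeleton
length (unit orthogonal steps, √2 diagonals, with corner-cutting
diagonals suppressed when the pair is already linked through a shared
4-neighbour — otherwise staircase skeletons double-count corners).
Area is foreground count × scale².  The scanning software's internal
formulas are not published; the cylinder model stands in: diameter =
area/length, volume = π(d/2)²·L, surface = π·d·L.  The published trait
units force specific root length = L/V = 1/(π(d/2)²), and the reported
HP means (SRL 5.33 mm·mm⁻³, d 0.51 mm) are mutually consistent with it.
Hull geometry uses foreground pixel centres (so a filled w×h rectangle
has hull area (w−1)(h−1)·scale² exactly); specific hull area =
hull area / root area.

Known discretisation limits, stated rather than hidden: 8-connected
skeleton length is near-exact only for strokes near 0°, 45° and 90° and
can overestimate arbitrary orientations by several percent; strokes of
even pixel width rasterise one pixel wider than nominal under the
centre-inclusive distance test; and for a *thin convex* mask (a single
straight bar) the pixel-centre hull is necessarily slightly smaller
than the stroke area, so specific hull area ≥ 1 is guaranteed only for
branched, root-like shapes — which is also the only regime where the
trait is informative.  Fixture tolerances (length ±3 %, area ±2 %,
hull ±3 %) are met on axis-aligned, diagonal and branched fixtures with
stroke width ≥ 5 px, and all mm-valued traits are stable within 3 %
under simultaneous image and dpi doubling.

The multivariate summary z-scores every trait × treatment column
(population SD; zero-variance columns dropped with a warning) and
clusters accessions by complete-linkage agglomeration on Euclidean
distances (SciPy), cut either at a height or into a fixed number of
groups; a brute-force linkage oracle checks the implementation on small
fixtures, and partitions are invariant to row order on tie-free data.

## Pipeline and reproducibility

`run_pipeline` chains all stages and writes TSV/FASTA/GFF3 outputs plus
a manifest with SHA-256 checksums of every artifact; identical
configuration and seed give identical checksums.  All randomness
derives from one integer seed through `numpy` seed sequences, spawned
per stage and per accession so that iteration order cannot leak between
streams.  Reads are streamed accession-by-accession and not persisted
unless `write_reads` is set.  In external-data mode (`simulate =
false`) the driver computes the phenotype indices and contrast groups
from a user-supplied table and reports a named error if it is missing.

## Known limitations

* Exact-match mapping only; diverged flanking sequence would defeat it.
* The λ grid bounds [1e−5, 1e5] cap extreme heritability ratios.
* The ANOVA block approximation differs from a REML mixed model for
  unbalanced designs.
* The generator's uniform-coverage reads cannot probe
  restriction-site-biased dropout patterns of real GBS libraries.
* Trait extraction assumes pre-binarised masks; the Otsu-style
  greyscale option is a convenience, not a segmentation method.
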