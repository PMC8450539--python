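# Methods

`skimrepeats` re-creates, at desk scale, the comparative repeat-landscape
workflow used to explain a ~1.9× genome-size difference between two
congeneric plants from genome-skimming data: similarity-based clustering
of low-coverage reads into repeat families, lineage annotation,
two-species abundance comparison, tag-based solo-LTR quantification
(Rsf), and maximum-likelihood ancestral genome-size reconstruction under
Brownian motion. Everything runs on synthetic data produced by the
package's own generator, so the pipeline is fully testable without any
download.

## The synthetic study system

Two toy genomes stand in for the studied species pair: 1.0 Mb
("HKOR", 1C = 1.0 Mb) and 1.9 Mb ("HUMB", 1C = 1.9 Mb), a 1/1000-scale
model of the real 2,480 / 4,680 Mb pair. They share eight repeat
families — five LTR-retrotransposon lineages (Angela, Ale, Retand,
Tekay, Athila), a CACTA-like DNA transposon, an rDNA-like unit and a
26-bp-monomer tandem satellite ("HeloSAT"-like). Copy numbers in the
large genome are ~1.9× those of the small one (equal genome proportion,
GP), with two deliberate exceptions that mirror the real contrast: the
Athila-like family has a *higher* GP in the small genome, and the
satellite occupies ~10% of the large genome versus ~1% of the small
one. The small genome also carries a higher solo:full LTR ratio for the
two dominant lineages, emulating stronger unequal recombination.

Design choices that matter:

* **Scaled-down elements.** Repeat templates are ~200–260 bp (LTRs
  60 bp, internals 110–140 bp) rather than the 5–10 kb of real LTR
  elements. At 1/1000-scale genomes and the study's sampling depths,
  read chains in element coordinate space would otherwise be far too
  sparse to form connected components; scaling element length with
  genome size keeps the read-overlap connectivity in the same regime as
  the real analysis. Consequences of the short elements are discussed
  under *Limitations*.
* **Placement.** Repeat copies and solo LTRs are placed uniformly and
  non-overlapping: the generator draws one uniform cut point per unit
  over the single-copy background and interleaves the shuffled units
  with the resulting gaps. This is the uniform non-overlapping layout
  by construction, keeps GP accounting exact at any occupancy, and has
  no rejection-sampling pathologies at the 30–70% repeat fractions of
  interest.
* **Divergence is substitutions-only** (default 2% per copy), so
  pairwise read identities are analytically predictable: two reads from
  different copies of one family differ by ~4% plus sequencing error,
  comfortably above the 90% identity threshold; different families are
  unrelated random sequences (~25% identity). An indel-bearing
  divergence model is deliberately out of scope.
* **Reads** are 100-nt pairs from 500-bp fragments with uniform starts;
  the mate count is `round(coverage × G / 200)` exactly. Sequencing
  errors are substitutions at rate 0.005. Qualities follow a two-state
  model (Q38 bases; 10% of reads carry error-prone stretches of Q12
  bases at rate 0.3) — just enough structure to exercise the full-length
  Q20 filter. Per-pair provenance is the majority overlap of the
  fragment with the truth intervals; ties are "ambiguous".
* **Contamination.** Organelle reads are spiked from synthetic plastid
  (20 kb) and mitochondrial (30 kb) references at a configurable
  fraction of pairs (default 5%).

## Read preparation

Pairs are kept only if *every* base of both mates reaches Q20 — the
strictest reading of a "full-length" quality filter (a mean-quality mode
is available). Organelle matching is k-mer-seeded (canonical 13-mers)
followed by local-alignment verification at ≥90% identity over ≥80% of
the read; a pair is dropped when either mate matches. Survivors are
down-sampled without replacement, keeping mates together, to a read
budget of `round(GP × 1C / read_length)` — GP 0.015 for the
single-species runs and 0.013 for the comparative run, as in the
original design.

## Clustering

Reads are vertices; an edge is a strand-aware local alignment with ≥90%
identity over ≥55% of the shorter read (N never matches; the identity
denominator is aligned columns). Candidate pairs must share ≥2
canonical 13-mers, which makes all-vs-all comparison tractable; the
test suite proves on ≤500-read fixtures that the pre-filtered partition
is identical to brute-force all-pairs clustering. Clusters are
connected components, ordered CL1, CL2, … by (size desc, smallest read
id); components below 0.01% of analyzed reads (never fewer than 2
reads) are pooled into the low/single-copy fraction. Clusters linked by
≥5 mate pairs (a package default; the original threshold is not
published) are grouped into superclusters. In comparative mode the two
species' reads carry four-letter id prefixes and per-species counts are
tracked per cluster; "shared" clusters have reads from both.

A Louvain community-refinement flag (`refine_communities`) can split
components whose split is strongly modular (> 0.3); it is **off by
default**, since plain connected components are the documented base
behavior.

## Annotation

Cluster reads are searched (both strands, edlib infix alignment, ≥80%
identity) against a packaged mini reference: lineage-labeled exemplars
generated from the simulator's own templates plus decoy lineages absent
from the genomes. The winning lineage is the one hitting the largest
read fraction; below 10% support a cluster stays "unclassified"; exact
ties break to the lexicographically smaller label. The reference is
nucleotide-only — a full protein-domain database and translated search
are out of scope, and with template-derived exemplars a translated
search would add nothing. Tandem satellites are detected on the cluster
consensus (majority vote of reads aligned to the highest-degree seed
read) as the smallest period p ≤ 50 bp with ≥80% self-alignment
identity at shift p over ≥2p bases; a satellite detection overrides the
mobile-element label.

## Quantification

GP(%) of a cluster in a species is `100 × cluster reads / analyzed
reads`; abundance is `GP/100 × 1C` Mb. Per-species tables carry full
precision plus rounded display columns, and always include the
unclassified and low/single-copy rows so each species sums to 100% and
to its 1C. The comparative table reports per-cluster read counts, GPs
and `log2(GP_B/GP_A)` (zero = equal genomic proportion; defined only
when both GPs are positive). The read-scatter slope is estimated as the
ratio `Σreads_B / Σreads_A` over shared clusters — the through-origin
weighted least-squares estimator with Poisson weights — excluding
satellites; at equal sampled GP its expectation is the genome-size
ratio (1.9), and it is adjusted with a warning if the two species were
sampled at unequal GP. Regressions of species-B on species-A abundance
across shared clusters (per lineage, all LTR elements pooled, and "all
repeats" with/without satellites) use closed-form OLS with a two-sided
slope t-test; the implementation is validated against statsmodels in
the tests.

## Solo-LTR quantification (Rsf)

For a chosen LTR family, 30-nt tags are taken from the last 30 bases of
the LTR (LTR-3′ end) and the first 30 bases of the internal region
(5′-UTR); their 60-nt concatenation marks the junction. Reads fully
containing the LTR-3′ tag form the candidate set (count Lx); candidates
also matching the 5′-UTR tag and confirmed against the combined tag are
junction-spanning (LU ⊆ Lx); Rsf = (Lx − LU)/LU, undefined when
LU = 0. Matching slides the whole tag along the read (both strands)
allowing ≤2 substitutions per 30 nt (min identity ≈ 0.93) — no partial-
tag credit and no end-trimming, chosen so the counter is exactly
consistent with the analytic oracle below. Because Lx counts *all*
LTR-3′ hits, even a genome of pure full-length elements has Rsf > 0
(each element's 3′ LTR ends in the tag but is followed by background);
what matters is the *increase* of Rsf with solo-LTR load and its
between-species contrast.

The analytic expectation used in tests counts, in the truth genome, the
positions matching each tag within the same mismatch budget (hamming
sliding window — exact for the substitutions-only simulator) and
multiplies by the eligible read-window count (L − t + 1); the expected
Rsf is the ratio of those totals, independent of coverage. The grid
experiment (`solo_full_grid`) uses a paired design: one read set over a
base genome of full-length elements is shared across all solo:full grid
points, and solo-block reads are nested by prefix, so LU is constant,
Lx is non-decreasing, and the estimated Rsf isolates the solo effect
from resampling noise.

## Ancestral genome size under Brownian motion

Tip 1C values on a rooted, branch-length-bearing tree are modeled as
Brownian motion: jointly Gaussian with covariance σ² × shared
root-to-tip path length. The ML ancestral state at any node equals the
GLS mean of the tree re-rooted at that node,
`â = (1ᵀC_a⁻¹x)/(1ᵀC_a⁻¹1)` with `C_a[i,j]` the shared path length of
tips i, j seen from the node; its variance `σ²/(1ᵀC_a⁻¹1)` (the
re-rooting variance, which is what the reported confidence intervals
mean) and the ML rate `σ² = rᵀC⁻¹r/n` from the root residuals. Tip
estimates equal observations; estimates are invariant to tip order and
to uniform branch-length rescaling. Polytomies are resolved arbitrarily
with epsilon branches (1e-8 of tree height) — the ML solution is
continuous in branch lengths, so the resolution is harmless and is
logged. The tests check the closed form against a brute-force numerical
likelihood maximization (1e-6 relative) and against the independent R
implementation (`ape::ace`, ML under BM), and verify root-value recovery
over 200 simulated replicates.

The packaged six-tip tree (`default_demo_tree`) is a **synthetic
stand-in**: the genus phylogeny used in the original analysis is not
published in a reusable form. Its two focal tips carry the observed
2,480 and 4,680 Mb so the demo output is on a realistic scale, but its
root estimate is a property of the toy tree only.

## What the toy scale does and does not reproduce

Numbers that depend only on printed inputs are reproduced exactly by
the package's arithmetic: GP 10.20% of 4,680 Mb ≈ 477 Mb; the 1C ratio
4,680/2,480 = 1.89 ("c. 1.90"); expansion +1,658 Mb and reduction
−542 Mb of the two species against an ancestral value of 3,022 Mb; the
1,015,000-read comparative pool; the >6-fold shared-satellite GP
contrast (14.24% vs 2.33%).

The following published values are **not reproduced** here, because
they require the deposited sequencing runs or the external phylogeny,
neither of which is an input to this package: the per-lineage repeat
composition table (GPs such as 26.92%/21.06% for the Angela lineage),
the regression coefficients (R² 0.818/0.762/0.969/0.259/0.875), the
Rsf values 11.41 and 4.22 (small-genome species) and 7.94 and 3.88
(large-genome species), and the ancestral value Anc1C = 3,022 Mb
itself. In their place the test suite pins down the corresponding
*properties* on synthetic data: truth-GP recovery, the scatter slope
converging on the genome-size ratio, Rsf monotonicity in the solo:full
ratio with agreement to an analytic oracle, and BM estimator
correctness against independent implementations.

## Precision at the study's sampling depth

The study-scale sampling depth, applied to 1/1000-scale genomes,
leaves very few analyzed reads (GP 0.015 of 1.0/1.9 Mb = 150/284
reads). A GP estimated from n sampled fragments has binomial standard
deviation `sqrt(p(1−p)/n)` — at n = 75 fragments this is 2.5
percentage points for a 5% family and 3.5 pp for a 10% family, and the
shared-cluster slope estimator inherits similar noise. Pipeline runs at
this depth therefore show per-family GP errors of several percentage
points and slope errors above 10% (the acceptance suite records this
measurement honestly), while the identical experiment at tenfold depth
(GP 0.10; 1,000/1,900 reads) recovers every truth GP within ±2 pp and
the slope within ~3% (see `tests/test_recovery.py`). Precision is a
pure sampling-depth effect, `∝ 1/√n`, exactly as in the real analysis
where the same GPs rest on hundreds of thousands of reads.

## Known limitations

* **Short toy elements bias read-level GP slightly downward** relative
  to base-level truth GP: reads overlapping an element by less than the
  55-nt similarity span cannot join its cluster, and with ~250-bp
  elements that boundary zone is a noticeable fraction of each copy.
  With realistically long elements (≫ insert size) the effect vanishes.
* **Genomic-adjacency chaining.** Junction-spanning reads at insertion
  sites can, when two of them co-overlap, bridge otherwise unrelated
  clusters; at high repeat occupancy and deep sampling this occasionally
  merges a high-copy satellite cluster with a neighboring family
  (observed in seeded runs as an rDNA cluster absorbed into the
  satellite cluster). Real pipelines meet the same phenomenon with
  read-through chimeras. The Louvain refinement flag splits strongly
  modular chains, but stays off by default.
* The generator does not model insertion-age distributions, nested
  insertions, indel divergence, methylation, or adapter/duplicate
  artifacts — passing tests say nothing about robustness to those.
* Consensus sequences are majority votes over reads aligned to a seed
  read, adequate for satellite periodicity and annotation at toy scale,
  not an assembler.
* The annotation reference is generated from the simulator's own
  templates plus decoys; recovery statistics measure pipeline
  self-consistency, not discrimination power against a realistic
  protein-domain database.
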