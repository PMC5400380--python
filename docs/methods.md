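# Methods

`allofound` reconstructs the founding of a selfing allotetraploid species
from genotype matrices of its two subgenomes and panels of its two parental
species. This note documents the models, the parameters that matter, the
synthetic-data generator used for validation, and the numerical and design
choices made where the design was genuinely open.

## Data model

All samples are naturally inbred (selfing) lines, modelled as
haploid-equivalent sequences: one allele code per site per accession
(`GenotypeTable`). Residual heterozygous calls — in an allopolyploid mostly
artifacts of reads mapping to the homoeologous subgenome — are kept but
flagged; `filter_heterozygous` sets heterozygous calls to missing at any
site where two or more accessions carry one (a single het call may be
genuine residual heterozygosity and is retained). Filtering is
set-to-missing rather than site removal so that completeness denominators
are preserved. Coordinates are 0-based half-open internally; VCF/TSV
positions convert on read and write. Sites absent from a variant-only table
are treated as monomorphic reference, the standard all-sites reading on a
shared reference genome. Analyses use only sites called in at least 80% of
accessions in every population involved (`completeness_mask`, boundary
inclusive).

## Polymorphism classification

On the union coordinate system of a subgenome table and its parental panel,
each site is labelled:

- **shared** — polymorphic in both populations with at least one common
  segregating allele (the common-allele requirement keeps two coincident
  but different private mutations from masquerading as retained ancestral
  variation);
- **private** — polymorphic in the polyploid but not explained by parental
  variation;
- **fixed_diff** — both populations monomorphic, for different alleles;
- **monomorphic** — the focal population is monomorphic (including sites
  polymorphic only in the parent: the reported densities describe the
  polyploid's polymorphism);
- **excluded** — completeness below threshold in either population.

The headline statistic is `shared / (shared + private)` over focal
polymorphisms. Site-frequency spectra are folded (minor allele), since no
outgroup polarization is in scope.

## Dating: T = π/(2μ)

In a genomic region inherited from one inbred founder, every sampled
lineage descends star-like from a single haplotype at the founding time
`T`, so `E[π] = 2μT` and `T̂ = π/(2μ)`. π is the average pairwise
difference per aligned site, with missing calls excluded pairwise from the
difference count and the aligned length as denominator. The defaults are
`μ = 7×10⁻⁹` substitutions/site/generation and one generation per year (an
annual plant), so `T` in generations doubles as an age in years. The point
estimate over single-founder windows is the median of per-window `T̂`, with
a 95% basic bootstrap CI (resample windows, `(2m̂ − Q₁₋α/₂, 2m̂ − Qα/₂)` on
bootstrap medians); windows are weighted equally. No correction is made for
coalescence within the founding bottleneck — the estimator deliberately
treats descent as star-like, which is also how the generator simulates it.

A caveat the acceptance script quantifies: under idealized conditions
(equal window lengths, complete data, infinite sites) per-window `T̂` is
lattice-valued with spacing `2/(n·w·2μ)` (~48 generations at n=15, w=200
kb), the sample median is nearly degenerate on a lattice atom, and the
basic-bootstrap CI for a median undercovers — a discreteness artifact, not
estimator bias (the measured relative bias is zero). Real data break the
lattice through heterogeneous callable lengths. Separately, with a
variant-only table any missing call removes pair differences that cannot be
restored from the table (the invariant-site callability is unobserved), so
π is biased down by roughly the squared call rate; dating validation
therefore runs at `missing_rate = 0`.

## Founder-haplotype counting

Per 200-kb window: (1) select, for each polyploid accession, its 5 closest
panel accessions by window-restricted divergence (union of selections,
ties broken by accession identifier); (2) build the merged haplotype
matrix and cluster with Ward linkage (the ward.D2 convention —
`scipy.cluster.hierarchy.linkage(…, 'ward')` on the Hamming
pairwise-complete distance matrix, verified against a hand-coded
Lance–Williams recurrence); (3) assess cluster uncertainty with
approximately unbiased (AU) p-values from multiscale bootstrap resampling:
the site axis is resampled at 10 scales `r ∈ {0.5,…,1.4}` (default 1,000
replicates per scale, configurable), per-cluster recovery rates are
probit-transformed and fit by weighted least squares to
`z(r) = a√r + b/√r` with binomial delta-method weights, and
`AU = 1 − Φ(a − b)`; `BP` is the recovery rate at scale 1. Clusters
recovered always get AU = 1, never-recovered clusters AU = 0 with a flag.
For speed, resampling is drawn as multinomial column weights so each
replicate's distance matrix is one matrix product over precomputed per-pair
mismatch indicators — distributionally identical to index resampling.

**Counting rule.** Each polyploid accession is assigned to the *smallest*
cluster with AU above the threshold (default 0.99) that contains it
together with at least one parental accession; the window's founder count
is the number of distinct clusters chosen. The root is an admissible
(maximally coarse) assignment. This per-accession rule was adopted after a
root-down scan ("take the first AU-passing mixed node on each path") proved
structurally wrong in two ways on generated data: a single-founder window
has star-like descent, so the only mixed cluster covering the whole cohort
is the root itself; and a *true* deep clade containing two founder groups
(founders that are genealogical neighbours within the parental species)
passes AU and stops the scan prematurely. Under the per-accession rule the
window count matches the generator's surviving-founder truth in ≥90% of
windows for 1–4 founders, and unstructured noise data yield AU > 0.99 in
far less than 5% of clusters.

Windows are fixed 200-kb tiles rather than LD-defined blocks: fully selfed
lines are already phased, so the phasing/block-definition step a
diploid-data pipeline would need is unnecessary.

The genome-wide histogram of per-window counts (`FounderDistribution`) has
a hard interpretation: a window with `k` supported founder clusters
requires at least `k` founders, so the maximum observed class is a lower
bound on the founder number. For the observed 2,648-block table
(1,273/1,267/106/2 blocks with 1/2/3/4 clusters) that bound is four.

## Lineage counting and founder-number ABC

The founding model is linear growth: backward in time,
`N(t) = N0 + (Nf − N0)·t/T`, from the contemporary size `N0` to `Nf`
founders at the founding time `T`; queries beyond `T` clamp to `Nf`. Each
accession contributes one haploid-equivalent lineage and a pair coalesces
at rate `1/(2N(t))` per generation. (The literature's scaling here is
ambiguous for selfing tetraploids; the package parameterizes directly in
individuals and generations and uses `2N(t)`, so `N` is the
haploid-equivalent number of genomes.) Waiting times are drawn exactly by
analytic inversion of the integrated rate — with `N(t) = N0 + st`,
`Λ(t0,t1) = c/(2s)·ln(N(t1)/N(t0))` for `s ≠ 0` — no per-generation
thinning, which keeps a million-locus run tractable. The constant-size
special case is validated against the closed-form expected lineage count
(falling/rising-factorial series).

Per parameter draw, the distribution of ancestral-lineage counts at
`t = 16,000` over independent loci is compared with the observed
founder-lineage distribution by least squares on class *frequencies*
(zero-padded common support); frequencies rather than raw counts make the
score invariant to locus-number mismatches in scaled-down runs. The full
grid (`N0 ∈ [10³, 10⁵]`, `Nf ∈ [1, 10³]`, 100,000 draws) and the rejection
ABC (10⁶ draws at fixed `N0 = 5,000`, keep 1,000) are available at their
original sizes; validation runs use scaled-down sizes stated in the tests.

A structural identifiability limit the acceptance script quantifies: with
`N0 = 5,000` declining to a small `Nf` over 16,000 generations, the
integrated pair-coalescence rate is ~10, so all sampled loci coalesce to
one lineage for every `Nf` up to several tens — the observed summary
saturates, the likelihood is flat over that region, and a posterior median
cannot localize a small true `Nf` (the posterior mass simply fills the
saturated region). This mirrors the original analysis's conclusion that
the block distribution is compatible with a wide range of parameters and
that the haplotype-count lower bound is the firmest statement.

## Haplotype sharing

Pairwise divergence is mismatches per pairwise-comparable aligned site
(window length minus incomparable positions). The longest shared haplotype
between two accessions is the longest interval whose mismatch proportion
is at most the threshold (default 0.1%), with the comparable-site count as
denominator. Since extending an interval without crossing a mismatch only
adds comparable sites, the optimum always extends maximally between
mismatches; the scan therefore enumerates mismatch-bounded candidate
intervals (O(M²) in the number of mismatches, vectorized, with a
best-length pruning bound) and is tested for exact equivalence against a
brute-force all-intervals oracle. Ties resolve leftmost; intervals are
physical bp, 0-based half-open.

## Synthetic-data generator

The generator emulates the founding of a selfing allotetraploid and
records complete ground truth (per-window founder assignments, per-site
ancestral/post-founding origin), so every downstream stage is scorable.

- **Parental panels** — neutral constant-size coalescent at
  mutation–drift equilibrium, one independent genealogy per 200-kb window
  (free recombination between windows), infinite-sites mutations at
  `θ = 4·N_anc·μ` per site on uniformly random positions. Validated
  against the Watterson segregating-sites and pairwise-diversity
  expectations and cross-checked against msprime.
- **Founding** — `k` founder haplotypes per subgenome drawn from the
  panel. Per window, the sampled cohort lineages run a coalescent under
  the linear-growth model truncated at `T_found`; surviving lineages land
  uniformly on founders (lineages coalescing more recently than the
  founding share a founder). Adjacent windows are correlated (an accession
  keeps its previous founder with probability 0.9), creating contiguous
  founder tracts for the haplotype-sharing scan.
- **Post-founding mutation** — star-like: each accession accumulates
  `Poisson(μ·T_found·L)` mutations on never-used positions. This matches
  the dating estimator's star assumption exactly, making `E[π] = 2μT` an
  identity rather than an approximation.
- **Noise** — missing calls at `missing_rate` (default 0.05) and optional
  heterozygous-call errors (default 0) to exercise the het filter.

Defaults are the emulated study's conditions: 15 polyploid accessions,
`T_found = 16,000` generations, `μ = 7×10⁻⁹`, 200-kb windows,
`N0 = 5,000`. The panel size `N_anc` defaults to `2×10⁵`, i.e. per-site
panel diversity `4·N_anc·μ = 5.6×10⁻³` — the order observed in the real
parental species — so parental haplotypes are ~25× more diverged from one
another than cohort members sharing a founder. Shallower panels are both
unrealistic and structurally hostile to AU-supported founder counting
(founder groups separate from the background by barely twice the
post-founding noise). Analyses insensitive to panel depth (dating) pass a
small `N_anc`/panel size explicitly to reduce simulated site counts;
problem sizes used by the validation suite are stated in the tests and in
`scripts/acceptance.py`.

What the generator does **not** emulate: within-window recombination
(windows are founder-pure mosaics, whereas real blocks have internal
breakpoints), gene conversion, selection, tetrasomic inheritance, mapping
or calling error beyond the flat missing/het rates, and heterogeneous
callable length per window. Passing tests therefore demonstrate
correctness of the inference machinery under the stated model, not
robustness to alignment artifacts or recombination within blocks.

## Numerical choices

- Ties in parent selection and clustering break by accession identifier;
  `cluster_window` sorts rows by label first, so results are invariant to
  input order.
- AU fitting uses only scales with informative recovery (0 < rate < 1);
  all-recovered → AU 1, never-recovered → AU 0 (flagged); a singular WLS
  system falls back to the mean recovery rate.
- Bootstrap and coalescent randomness flow through
  `numpy.random.Generator`; every public simulation entry point takes a
  seed or generator, and the pipeline derives per-stage seeds from the
  global seed by a fixed counter scheme so stages re-run independently.
- Degenerate inputs are explicit: π with fewer than two callable
  accessions raises; an empty founder distribution raises; a one-locus
  bootstrap returns a point interval; windows with no aligned sites report
  missing densities.
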