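# Methods notes

## Model and assumptions

`covbin` treats a metagenome co-assembly as a mixture of population
genomes observed through two signals per contig: a coverage profile
(mean read depth in each of S ≥ 3 related samples) and a composition
signature (canonical tetranucleotide frequencies). The central
assumption is that contigs of one population have *proportional*
coverage profiles — the population's relative abundance varies between
samples, but all its contigs inherit the same variation — while
composition is population-specific but noisier on short contigs. The
binner therefore clusters primarily in coverage-profile space and uses
composition only to purify candidate bins and to inform refinement and
recruitment.

Three samples is a hard floor: with two, the relative profile has a
single degree of freedom and distinct populations frequently collide.

## The transformed coverage space

Coverage profiles live on a ray through the origin of R^S (scaling a
profile changes abundance, not identity), so clustering directly on
depths conflates abundance with profile shape. We project the relative
profile p = c/Σc by star coordinates — axis k at angle 2πk/S, in the
sample order given on the command line — onto a plane:
x = Σ p_k cos θ_k, y = Σ p_k sin θ_k. This is scale-invariant and
continuous; profiles that co-vary coincide. Total abundance is kept as
z = log10(1 + Σ c_k), finite at zero coverage. All-zero rows are
pinned to (0, 0, 0) and flagged.

The projection is not injective for S > 3 (distinct profiles can
collide in the plane); z separates many such collisions and
composition pruning catches others, but a genuine collision of two
populations in all three coordinates is a known, documented failure
mode that the refine stage's composition split addresses.

Composition enters as the first P = 3 principal components of the
column-centred 136-class tetramer matrix. Component signs are fixed by
the largest-magnitude-loading-positive rule so results are
deterministic across BLAS implementations.

## Core binning

Contigs ≥ 1 kbp (`core_min_len`) deposit their *length* into a 128³
histogram over (x, y, z) — evidence is assembled bases, not contig
count. The histogram is smoothed with an isotropic Gaussian
(σ = 1.5 cells) and bins are carved off iteratively: take the global
maximum; flood-fill the set of cells reachable from it by 26-connected
paths along which density never increases and stays ≥ α = 0.15 of the
peak (expansion in descending density order, so every monotone path is
found); prune composition outliers at robust z > 3.5 (MAD-scaled, per
PCA component); accept at ≥ 50 kbp or ≥ 5 members; zero the region and
repeat until the field is empty. Ties in peak selection break on the
lowest flat cell index, making the procedure fully deterministic.

Scaling note: each axis is min–max scaled onto the grid, but the
scaling span is floored at 2.0 per axis — the natural width of the
star-coordinate plane ([-1, 1]) and two decades of total depth in z.
Without the floor, a dataset consisting of a single tight cluster (one
population, or several populations sharing one profile) would have its
pure measurement noise stretched across the whole grid and be shredded
into rejected slivers; with it, such data collapses into the single
bin it should be. Whenever the data genuinely spans the space the
floor is inactive and scaling is plain min–max.

The rejected-candidate and pruned contigs stay unbinned and remain
available to the recruit stage; they are never reconsidered by the
coring loop itself (their cells are zeroed), which guarantees
termination.

## Refinement and recruitment

Merge, split and delete are journaled, append-only actions; replaying
a journal against the pre-refine state reproduces the refined state
exactly because splits are seeded k-means (k fixed, restarts over
seeds 0–9, best inertia, ties to the lowest seed) over a deterministic
feature space (coverage (x, y, z), TF-PCA scores, or log10 length).

Automatic refinement is optional and purely marker-driven. Split pass:
bins with contamination > 10 points are trial-split (coverage first,
then composition) and the split is kept if the children's summed
contamination is below the parent's. Merge pass: candidate pairs in
ascending (x, y) centroid distance merge when the union's completeness
exceeds the better part by ≥ 10 points while its contamination stays
within 5 points of the cleaner part. Passes repeat to a fixpoint; each
accepted action strictly reduces contamination or raises completeness,
so the process is finite. The three thresholds are exposed flags; they
are conservative defaults, not fitted values, since curation of real
bins is ultimately a judgment call.

Recruitment computes, per bin, a scatter vector (median absolute
deviation per coordinate over the 3 coverage axes and P TF axes,
floored at 1e-6) and a radius (the 0.95 quantile of its own members'
scatter-normalised distances). An unbinned contig ≥ 500 bp joins its
nearest bin only if it falls inside that bin's radius; rounds repeat
with refreshed centroids until nothing moves (≤ 10 rounds). Tight bins
therefore recruit conservatively and diffuse bins broadly, without any
global distance threshold. Core members are never reassigned.

## Marker QC

Completeness = 100 · |markers present ≥ once| / M;
contamination = 100 · Σ max(0, copies − 1) / M. Contamination counts
*excess copies*, not merely the fraction of multi-copy markers: a
marker present five times contributes four excess copies. Both scores
are monotone under bin union, which the merge logic relies on. The
marker set is an input file (one id per line); hit rows referencing
unknown contigs are warned about and ignored, hits for markers outside
the set are ignored silently (the set defines the universe).

## Evaluation

Verified-bin collapse rewrites every id in a strain group to the
group's lexicographically smallest id; groups must be disjoint.
Matching: each predicted bin proposes the verified bin holding the
plurality of its contigs (plurality rather than strict majority, which
need not exist; ties break by larger cumulative member length in the
candidate, then lexicographic verified id). Conflicting proposals are
ranked by cumulative length of contigs belonging to the contested
verified bin (ties: lexicographic predicted id); only the top keeps
it, losers re-propose among verified bins not yet taken, and a bin
that exhausts its candidates couples to a fresh placeholder so the
coupling stays injective and total. Scoring then classifies each truth
contig as correct (its bin's coupled verified bin matches), incorrect,
or unassigned, and reports percentages by contig count (TNC) and by
assembled bases (TAB).

## Synthetic communities

The generator emulates exactly the statistics the binner consumes:

- **Genomes.** Order-3 Markov chains; each genome draws a base
  composition from Dirichlet(5,5,5,5) and its 64 context rows from
  Dirichlet with concentration 24 × base-composition, giving coherent
  within-genome and distinct between-genome tetramer signatures.
- **Abundances.** log a_gs = b_g + σ·e_gs with b_g ~ N(0, 0.6²) (a
  genome's overall abundance level) and e_gs ~ N(0, 1) per
  genome-and-sample; σ is the `profile_separation` preset: low 0.25,
  medium 0.75, high 1.5. At "high", profile ratios between samples
  span roughly an order of magnitude — clearly distinct profiles, the
  regime differential-coverage binning is designed for; "low" produces
  nearly flat profiles where the method is expected to degrade.
- **Depth.** A genome's expected depth in a sample is
  a_gs × `depth_factor` (default 20, a typical per-sample depth for a
  moderately abundant population). Per contig and sample the read
  count is Poisson(depth × L/read_length), reads are 100 bp,
  error-free, uniformly placed, written as sorted+indexed BAM (MAPQ
  60, full-match CIGAR, primary only). The realized mean depth of a
  contig is exactly count × read_length / L, so parsed coverage equals
  expectation up to Poisson error — the generator also emits the
  expectation matrix for direct comparison.
- **Contigs.** Genomes fragment into log-normal lengths
  (μ = 8.2, σ = 0.55; median ≈ 3.6 kbp, range mostly 1–15 kbp),
  truncated at genome ends. Default genomes are 100–200 kbp: large
  enough that every genome comfortably exceeds the 50 kbp core-bin
  acceptance threshold and forms a dense cluster, small enough that
  the full 10-genome, 3-sample pipeline runs in about a minute.

What it does *not* emulate: sequencing error, paired-end inserts,
inter-genome repeats, chimeric contigs, strain mixtures, and assembly
dropout of low-coverage genomes. Passing the pipeline tests on this
generator demonstrates that the clustering machinery recovers
populations whose coverage profiles are separated and whose depth is
measurable; it does not certify performance on real assemblies, where
repeat-induced mosaic contigs and strain heterogeneity are the
dominant error sources.

## Numerical choices and degenerate inputs

- Depth definition: sum of CIGAR match/mismatch block lengths over
  primary, non-duplicate, non-supplementary, MAPQ-filtered reads,
  divided by contig length; insertions and clips contribute nothing,
  so the value is identical across aligners that clip differently.
- Tetramer windows containing N are skipped; a sequence with no valid
  window gets an all-zero vector. Non-IUPAC characters are an error
  naming the offending character.
- Coordinates are 0-based half-open throughout.
- All-zero coverage rows are flagged and placed at the origin rather
  than dropped, so the store stays row-aligned with the FASTA.
- Outlier pruning skips PCA components with zero MAD; candidates with
  fewer than 3 members pass through unpruned.
- Bins with one member have zero scatter; the 1e-6 scatter floor keeps
  recruitment distances finite (such bins recruit only near-exact
  matches, which is the intended conservative behavior).
- The simulation seed fans out through `numpy.random.SeedSequence`
  spawning, so genome content, abundances and read placement are
  independently reproducible streams.

## Known limitations

- Populations sharing both coverage profile and composition cannot be
  separated automatically (by design; the split tooling exists for
  manual or marker-guided rescue).
- The star-coordinate plane can superimpose distinct profiles when
  S > 3; increasing sample count helps the biology but not the
  geometry of this particular projection.
- Automatic refinement optimises marker scores only; it will not
  reunite a genome split into two clean halves that the merge gain
  threshold does not reach.
- TNC/TAB evaluation requires every predicted-bin contig to carry a
  truth label; partial truth tables are rejected rather than silently
  ignored.

## Problem sizes

The bundled tests and the acceptance script run entirely on generated
data: communities of 1–10 genomes of 20–200 kbp over 3 samples
(hundreds of contigs, a few hundred thousand reads), 50-BAM parsing
oracles, and 200-instance randomized matching checks. These sizes were
chosen so the whole suite completes in a few minutes while every
statistic being tested (Poisson depth error, profile separation,
cluster density) is in the same regime the method sees on real data.
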