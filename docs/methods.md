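# Methods

`snfold` implements the analysis stack for high-coverage single-nucleus
Hi-C (snHi-C) of the kind produced for *Drosophila* BG3 cells: contact
annotation from chimeric reads, sparse single-cell contact maps, TAD
segmentation by two independent methods, random-graph null models, and
contact-constrained polymer reconstruction. This note documents the
models, the defaults, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Contact annotation (ORBITA)

snHi-C amplifies the proximity-ligated DNA of one nucleus with Phi29
polymerase, which spontaneously switches templates and creates chimeric
molecules indistinguishable, at the read-pair level, from true ligation
products. The discriminating signal is the position of the chimeric
breakpoint: a true ligation junction joins two restriction fragments at
DpnII (GATC) cut sites, a template switch lands anywhere.

Each read is treated independently. A read with one uniquely mapped
segment is a plain pair side (type P) and carries no junction evidence;
per the one-read-based design, P reads are never converted to contacts.
A read with exactly two uniquely mapped segments (MAPQ > 1 each) is a
candidate junction: the two *ligated ends* are the read-orientation
3′ end of the left segment and 5′ end of the right segment, mapped to
genomic coordinates strand-aware (a `+` segment's read-3′ end is its
genomic end coordinate, a `−` segment's is its genomic start). If both
ligated ends fall strictly within 10 bp of a restriction site, the read
is a junction (J) and yields one contact between the two fragments that
contain the segment bodies; otherwise it is a template switch (H).
Reads with three or more mapped segments are discarded. Same-fragment
junctions (self-circles, dangling ends) are dropped: they carry no
spatial information and the first map diagonal is removed downstream
anyway.

Duplicates: amplification is followed by sonication, so mapping
positions cannot identify duplicates; instead all copies of each
unordered restriction-fragment pair are collapsed to one contact.
Valency: a fragment has two ends per genome copy, so a diploid fragment
supports at most 4 unique contacts and a haploid (male X) fragment at
most 2; fragments exceeding the bound are removed together with all
their contacts (they indicate copy-number artifacts, mismapping, or
residual template switches).

Tolerance is the single tunable (default 10 bp, strict inequality).
Sub-tolerance template switches are undetectable in principle; the read
simulator therefore never generates them (breakpoints are placed at
least tolerance+1 bp from every site), which is what makes the 100%
round-trip accuracy check meaningful rather than optimistic.

## Contact maps and statistics

Maps are binned at a fixed bin size (default 10 kb), stored as
upper-triangle triplets per chromosome, cis only. Single-cell maps drop
the main diagonal; bulk maps drop the first two diagonals and are
balanced by iterative correction (marginal-equalizing weights, update
`w ← w / (marginal/mean)`, NaN on empty bins).

The contact probability `P_c(s)` uses two normalizations. Bulk: mean
count per bin pair at separation s. Single-cell: total count at s
divided by the number of bins covered by at least one contact in at
least one experiment — the union-coverage denominator is robust to the
missing-data pattern of sparse cells. Neither corrects the `(N−s)`
pair-count falloff; on real chromosomes the fitted s-range is far below
N so the bias is negligible, and tests fit below 0.2·N where it stays
under 0.05 in the exponent.

Two shuffles serve as controls: per-distance (each diagonal's contacts
redistributed uniformly along that diagonal; per-diagonal histogram
conserved exactly) and marginal+scaling (distance-weighted stub
matching that preserves per-bin marginals exactly and `P_c(s)`
approximately — the sampling analogue of the MSS null below).

The recovered-contact percentage divides the unique contact count by
the restriction-fragment pool Σ n_fragments × copy number (each
fragment's valency bound of two ends per copy makes the pool size the
theoretical maximum). It is computed post-deduplication,
pre-valency-filter by default.

## TAD calling by modularity dynamic programming

A chromosome of N bins is partitioned to maximize the sum of segment
modularity scores

    score(a,b; γ) = W(a,b)/T − γ (M(a,b)/2T)²

with W the within-segment contact sum, M the segment marginal sum, T
the total map sum, and γ the resolution parameter. Single bins may
remain unassigned ("null" segments scoring 0). With prefix sums every
segment score is O(1) and the exact optimum is an O(N²) dynamic
program; tie-breaks prefer the shorter segment, so empty flanking bins
are left unassigned rather than absorbed. Segments of ≤ 3 bins (30 kb
at 10-kb resolution; 60/120 kb at 20/40 kb) are relabeled inter-TAD.
The exact functional form is the main drift risk against the original
package that popularized this scoring; it is pinned by an
exhaustive-partition oracle (all 2^(N−1) contiguous partitions, N ≤ 12)
and by the behavioral γ-curves below.

The γ-sweep protocol scans a grid (production grid 0–375 step 0.1; the
test suite and acceptance script use steps of 0.5–1.0, which bracket
the same γ_max plateau at a fraction of the cost), records
number / median size / coverage of domains per γ, and selects γ_max
(maximum number of domains, first attained) as the sub-TAD scale and
γ_max/2 as the TAD scale — the value at which planted 9-bin-median
domains are recovered. Note the informative γ range scales with map
density and size: the dense 500-bin synthetic cells peak near γ ≈ 30,
genome-scale sparse cells peak far higher; the wide default grid covers
both extremes.

Boundary robustness is assessed by re-segmenting contact-subsampled
maps (levels 95%..5%, ten draws each, same γ): a bin-grid edge's
support at a level is the fraction of draws placing a boundary within
one bin; boundaries with mean support > 0.45 at the 90–95% levels form
the refined set; ROC AUC against the full-map boundaries (interior TAD
bins as negatives) summarizes predictiveness per level.

Segmentations are compared by (i) the percentage of the first
segmentation's boundaries with a boundary of the second within one bin
(asymmetric) and (ii) the Jaccard index over interior TAD bins
(symmetric). Boundaries are represented as bin-grid *edges* so adjacent
TADs share one boundary. Significance comes from shuffling the order of
a segmentation's segments (preserving the multiset of TAD/inter-TAD
sizes per chromosome), 1000 replicates by default, Gaussian
approximation to the null scores. Cross-cell boundary classes: stable
(≥ 50% of cells, one-bin offset), cell-specific (exactly one cell),
unstable (the rest).

Sub-TAD hierarchy: for adjacent sub-TAD pairs (γ_max call) nested in
one TAD (γ_max/2 call), the contacts in the rectangle between the two
blocks are counted in the real map and in a background map; identical
distributions mean the apparent hierarchy is noise.

## TAD calling by the non-backtracking operator

Sparse single-cell maps defeat adjacency/Laplacian/modularity spectra
(eigenvectors localize on hubs). The non-backtracking operator on
directed edges,

    B_{i→j,k→l} = δ_{il} (1 − δ_{jk}),

stays informative down to the detectability limit. Preprocessing
removes entries beyond 100 bins (~1 Mb; compartment-scale signal),
binarizes, and fills the first sub-diagonal with 1 (the chain
backbone). The spectrum of the 2E×2E operator is a bulk disc plus
isolated real eigenvalues; the spectral edge r_c is taken as the real
part of the largest-magnitude complex eigenvalue (empirical rule; the
closed form √(⟨d⟩⁻¹⟨d/(d−1)⟩), averaged over nodes — the averaging
convention is ambiguous in the source description — is logged as a
diagnostic). Dense solve below ~600 directed edges, ARPACK above; the
2N×2N Ihara–Bass reduction serves as an independent oracle in tests.

Nodes are embedded by summing incoming-edge components of the k
isolated eigenvectors (a convention pinned by tests, not dictated by
the operator itself), then clustered by spherical k-means (L2-
normalized rows, cosine Lloyd iterations, k-means++-style seeding, ten
restarts keeping the best objective; zero-norm rows inherit the nearest
labeled neighbor along the chain). The default cluster count 2.5·k
mirrors the production choice that matches modularity sub-TAD
granularity on real data; on clean planted block models k itself equals
the block count and `cluster_factor=1.0` is the appropriate setting —
the tests use it for the block-recovery checks. Label runs become
segments (contiguity enforced by run extraction); runs under 3 bins or
whose internal links are only the l−1 backbone edges are inter-TAD.

## MS and MSS null models

Observed maps are compared against random graphs with independent
links. MS: `p_ij ∝ P_c(|i−j|)`, normalized so Σ_{i<j} p_ij = N_c (the
observed contact count) — exactly, pre-capping, to machine precision.
MSS adds per-bin stickiness: `p_ij ∝ k_i k_j P_c(|i−j|)`, same
normalization; uniform k reduces MSS to MS and k is scale-invariant.
Stickiness is fitted to the merged-map coverage k̃ through the
fixed-point system k̃_i = k_i α_i with activity
α_i = Σ_j k_j P_c(|i−j|)/Z, Z = Σ_{i<j} k_i k_j P_c(|i−j|)/N_c,
iterated from k⁽⁰⁾ = k̃ to residual < 1e-8. The plain iteration can
enter a 2-cycle on sparse coverage profiles; a damped retry (0.5) is
attempted automatically before raising. Zero-coverage bins are
excluded and flagged. Null maps are independent Bernoulli draws
(probabilities capped at 1 with a flag; sampling is binary adjacency
by design).

Window statistics: the chromosome is tiled by non-overlapping W-bin
triangular windows on the main diagonal (the "non-intersecting" reading
of the source's self-contradictory phrasing); the incomplete tail is
discarded. Counts are tested against Poisson(λ̂ = mean) by a χ² GOF
with histogram cells merged left-to-right until each expects ≥ 5
(dof = cells − 2; degenerate inputs return p = 1 flagged). MS-sampled
maps pass at α = 1e-5 in ≥ 95/100 seeds, while planted-TAD maps on a
fly-chromosome-scale grid (2110 bins) reject overwhelmingly at W = 10
and recover non-rejection by W ≈ 40–80 bins — a few TAD sizes, the
qualitative crossover seen in real cells.

## Compartments and aggregates

E1 is the leading eigenvector of the per-chromosome Pearson correlation
of the distance-normalized (O/E by diagonal) balanced cis matrix, sign-
oriented by an external track (GC or activity); chromosomes with < 10
informative bins yield NaN. Sparse cells are aggregated over an E1 mask
into 5×5 saddles: bins ranked by E1 into five equal groups, block
enrichment computed as Σ observed / Σ expected-at-distance (ratio of
sums — a mean of per-pixel O/E is dominated by rare large values on
sparse diagonals and does not calibrate), log2 against the mean.
Per-distance-shuffled maps give flat saddles.

Average loops: the top-N track-scored anchors; pairs > 600 kb apart
with ≤ 50 intervening anchors; square windows centered on each pair are
summed and displayed as log10(sum+1). Chromatin-state bin classes use
the >0.5-fraction rules (active, then inactive, then Polycomb, first
match wins) and zero-inflated expression quantile groups.
State-restricted `P_c(s)` counts only same-state pairs, normalized by
the covered bins of that state. Boundary-class track profiles are mean
track values over ±flank bins (default ±100 kb).

## DPD polymer reconstruction

One bead per 10-kb bin (≈ 50 nucleosomes), explicit solvent,
dissipative particle dynamics: soft conservative repulsion
a_ij(1−r/R_c) within R_c = 1, pairwise dissipative −γ_d w² (r̂·v) r̂ and
random σ_n w θ/√dt forces with w = 1−r/R_c and σ_n² = 2 γ_d k_BT
(fluctuation–dissipation; γ_d = 4.5, σ_n = 3 at k_BT = 1 — the
standard pairing, as the dissipative pair is not constrained by the
conservative parameter set), harmonic bonds F = −k(r−l₀) with k = 40,
l₀ = 0.5, dt = 0.04, number density σ = 3, periodic box. Repulsions
a_pp = a_ss = 25, a_ps = 26.63 put the chain at the theta point
(χ = 0.306·(a_ps−a_pp) ≈ 0.5): soft potential, chains may
self-intersect, no topology enforcement. Integration is the modified
velocity-Verlet for DPD with velocity-prediction factor λ = 0.65, which
holds the kinetic temperature within ~1% of k_BT at this dt (λ = 0.5
runs ~3% hot); momentum is conserved to round-off by pairwise
antisymmetry. Forces use cell lists (O(N) per step); positions are
stored unwrapped (wrapping happens inside the kernel), so chain
distance matrices need no minimum-image bookkeeping.

The chain initializes as a random walk in a central sub-cube; solvent
fills the box to density σ. Binary single-cell contacts add removable
harmonic bonds for |i−j| > 1 (bin-level counts are not trusted beyond
presence, since restriction fragments are much smaller than a bin).
After equilibration, overstretched removable bonds (> l_max = 1.5) are
removed one at a time — always the currently longest — with
re-equilibration after each; backbone bonds are never removed. Distance
matrices average the last n_conf frames; model contact maps count
snapshots with D_ij < R_cut = 0.7 (the mean bond length), excluding the
self and backbone diagonals.

Structure comparison uses the coefficient of difference
K = ‖D−D′‖_F / ‖D+D′‖_F (0 for identical structures; the /2 factors of
the symmetric/antisymmetric decomposition cancel; the printed source
formula repeats the same numerator for both norms, an evident typo),
optionally restricted to genomic-separation bands. `R(s)` is the mean
spatial distance at backbone separation s with log-log slopes fitted
per range; an ideal chain (all repulsion zero — the pairwise thermostat
then acts through bonded neighbors, so the solvent can be dropped and
long runs are cheap) reproduces the random-walk exponent 0.5 ± 0.05.
Chromosome-territory depth is the minimal distance to the convex
hull's face planes (hull vertices at 0) — exact for the compact,
near-convex bead clouds this is applied to; path smoothing is a
centered moving average (window 15 beads, shrinking at the ends).

Problem sizes: the full production configuration (22³ box, σ = 3,
2242-bead X chromosome, 10⁶-step equilibration, 20k-step
re-equilibration per removed bond) is available through `DPDParams`
and the CLI; the test suite and acceptance script run the same physics
in a 8–12 unit box with 100–150-bead chains, thousand-step
equilibrations and 300-step re-equilibrations, which keeps every check
within minutes while preserving temperature, momentum, chain
statistics, and the contact-map round trip.

## Synthetic data: what it emulates, and what not

The generator plants a ground-truth architecture on one chromosome:
a TAD partition with log-normal sizes around a 9-bin (90-kb) median,
alternating A/B compartment blocks (~30 bins), log-normal per-bin
stickiness (σ = 0.35), a power-law contact decay `P_c(s) ∝ s^−1.5`,
and an intra-TAD enrichment factor (default 8). A cell is sampled by
independent Poisson draws per bin pair with rates
∝ k_i k_j P_c(|i−j|) × enrichment, normalized to the target contact
count N_c; with enrichment 1 and uniform stickiness the rates reduce
exactly to the MS null. Counts above 1 per bin pair are intentional:
a 10-kb bin holds ~25 restriction fragments, so bin-level multiplicity
is real even though fragment-level contacts are unique. Chimeric reads
are generated per contact with ligated ends exactly at cut sites (J),
or breakpoints ≥ tolerance+1 bp from every site (H; near-site switches
are undetectable in principle and not generated), plus plain P reads
and sonication-style amplification duplicates sharing the fragment
pair.

Not emulated: sequencing errors and base-level read sequences,
alignment ambiguity, trans contacts, copy-number variation, cell-cycle
structure, locus-specific loops. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated
generative model — power-law polymer background plus block-enriched
domains — not robustness to every artifact of real libraries; the
ORBITA checks in particular quantify classification of *detectable*
template switches.

## Reproducibility

Every stochastic routine takes a seed; pipeline stages derive per-stage
seeds from the global seed via a counter, so stages are individually
reproducible and full reruns are byte-identical. On-disk formats are
plain text: TSV triplets for maps, PAIRS for contacts, BED/bedGraph for
segmentations and coverage, YAML for configuration, JSON for run logs.
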