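# Methods

## The analysis model

The pipeline treats per-site pileups of a circular mtDNA reference as the
primary data. For each individual *j* and reference position *i* it keeps
strand-summed read-base counts (n_A, n_C, n_G, n_T), a deletion tally, and
depth = n_A + n_C + n_G + n_T. All coordinates are 0-based half-open
internally; 1-based coordinates exist only at the pileup/CLI boundary.

**Circular handling.** Reads are assumed mapped against a linearized
reference extended by an *o*-bp copy of its start (so origin-spanning reads
map); `fold_circular_overlap` adds the extension's coverage back onto
positions 0..*o*−1, conserving total mass. Ends of the folded profile and
the repeat-rich control region are unreliable after mapping, so a
configurable 1-based inclusive span [first_kept, last_kept] is retained; no
span is hard-coded — the classic 16,537-bp case with keep = [29, 15,816]
retains 15,788 sites and trims 749 bp only when configured so.

**GC bias.** Window tables pair mean coverage with GC fraction
((#G+#C)/#non-N) in windows anchored at the region's first retained site;
trailing partial windows are discarded (15,788 sites at w = s = 50 give 315
windows, hence 313 residual df for the 2-parameter fit). Degree-1 and
degree-2 OLS fits are compared with Gaussian AIC,
`n·ln(RSS/n) + 2·(degree+2)`, counting the variance parameter; an RSS floor
of `eps·n·var(y)` keeps noiseless fixtures finite, and makes the ΔAIC of a
tie exactly +2 (the extra parameter). The A/T-vs-G/C per-site test is
Welch's *t* (a pooled test would force integer df = n−2); its sign is
positive when A/T sites have higher mean coverage. The site-level ANCOVA is
`coverage ~ C(base) + C(gene_type) + gc50` with treatment coding
(alphabetical reference levels, stated in the output) and Type II sums of
squares; gc50 is the GC fraction of a 50-bp window centered on the site,
truncated at region edges.

**Error profile.** The site error rate is substitution-only:
e = (depth − n_consensus)/depth with deletions excluded from both numerator
and depth. The substitution table pools counts across individuals; entry
(x→y) is the pooled count of read base y at consensus-x sites over pooled
depth there, so each defined row sums to 1 and the diagonal is the match
rate. ti/tv pools A↔G + C↔T mismatches against all others; uniform random
error drives it to 0.5 (one transition vs two transversions per base),
far from the ≫1 typical of real variation — which is the argument for
reading the background as error.

**Motifs.** The IUPAC scanner reports all overlapping matches of the
pattern on the + strand and of its reverse complement (as strand −), with
optional origin wrapping for circular sequences; hit counts are invariant
under rotation in circular mode. The error-prone flank of a hit is placed
upstream of a +-strand `CCNGCC` (equivalently downstream of `GGCNG` on −):
the focal high-error base sits directly upstream of the motif in its own
orientation. In the proximity analysis each site inside any flank enters
once with its minimum 1-based distance to a motif edge; coverage vs
distance is summarized by Spearman's r (average ranks, t-approximation
p, df = n−2). Constant coverage is reported as r = 0 there (all ranks tie,
no association), whereas the generic rank-correlation helper reports a
constant input as undefined (NaN).

**Heteroplasmy.** A site is called in a cohort of ≥2 individuals when
exactly one individual carries one specific non-consensus base at frequency
≥ high_freq (default 0.01) with depth ≥ min_depth (default 100), and the
rest of the cohort carries that base only at background. The background
check defaults to the pooled frequency across the other individuals
≤ low_freq (default 0.001): with low_freq equal to the baseline per-base
error rate, a per-individual threshold is a coin flip against the Poisson
tail of a single shallow library (a lone 4-read fluctuation in one of ten
individuals vetoes a true call ~10% of the time per site), while the pooled
frequency concentrates tightly around e₀/3 and separates cleanly. The
strict per-individual variant remains available (`others_rule="each"`).
Sites where ≥2 individuals exceed high_freq are emitted as shared variants,
not heteroplasmy — in practice these are SSE focal sites, whose elevated
error (~2%) straddles the high threshold in several individuals at once.

**k-mer spectrum.** Counting is exact and hash-based (canonical by
default: each k-mer maps to min(kmer, revcomp)), sized for desk-scale sets
(≤ ~10⁷ k-mer instances). The error threshold is the multiplicity of the
first local minimum of 3-bin moving-median-smoothed log counts that has
higher smoothed counts on both sides; spectra without such a valley raise
and ask for an explicit cutoff. Error fraction = instances below the
cutoff / total instances; per-base error divides by k, since one miscall
corrupts the k overlapping k-mers. The spectrum "peak" M (mean k-mer
coverage) is the distinct-k-mer-weighted mean multiplicity of the genuine
component — the modal bin wanders several multiplicities at desk scale
while the mean does not. Base coverage follows N = M·L/(L−k+1): a read of
length L covers each base but contributes only L−k+1 k-mers. Note that
error-bearing instances are lost from genuine k-mers, so M underestimates
error-free k-mer coverage by the factor (1−e₀)^k (≈2.5% at e₀ = 0.001,
k = 25).

**Concordance.** Within-species repeatability is the Spearman correlation
of scaled per-site profiles for every unordered pair, plus a per-window
cross-individual coefficient of variation ranked most-concordant-first.
Cross-species correlation maps coordinates through a two-rows-per-block
aligned FASTA; only columns ungapped in both species are used, pooled
across blocks (per-block r is reported alongside), df = n_sites − 2.

## The synthetic generator

`SimulationConfig` defaults describe the emulated study design: a 16,500-bp
circular reference at 40% GC; 11 individuals at 4,000X mean depth; 22
planted `CCNGCC` motifs (random N base and strand) of which 3 are active;
baseline per-base error e₀ = 0.001 with errors spread uniformly over the
three alternatives (substitution matrix configurable); elevated error
e_motif = 0.02 at active-motif focal sites; 6 heteroplasmic
(site, individual) pairs with frequencies uniform on [0.013, 0.679].

Expected coverage at site *i* for individual *j* is

    mu_ij = mean_depth_j · mult_i · eta_ij,
    mult_i ∝ exp(c·(gc50_i − v)²) · s_i · dip_i   (normalized to mean 1)

with vertex v = 0.27 and curvature c = −8 in log-mean coverage (a ~2.5-fold
GC-driven span over the realized GC range, essentially negative above the
vertex), a shared lognormal site effect s_i (σ = 0.25) carrying the
repeatable overdispersion, lognormal individual noise eta_ij (σ = 0.10),
and a motif dip multiplying coverage by 1 − dip_depth at the motif, decaying
linearly to 1 over 100 bp on the error-prone side (the true decay shape in
real data is unknown; linear is the simplest localized choice). Realized
depth is Poisson — overdispersion lives in the shared site effect — and
base counts are multinomial given depth. These noise scales put pairwise
cross-individual Spearman correlations near 0.9 and are tunable down to ~0.

Reads for the k-mer stage are drawn uniformly on the circle with i.i.d.
substitution errors. Everything derives from one integer seed; the same
seed reproduces sequences, cohorts and FASTQ byte-for-byte.

**What the generator does not emulate:** fragment-level (insert-spanning)
coverage, read-length/quality heterogeneity, strand-specific error, mapping
artefacts in repeat regions (the trim exists precisely because real data
have them), and library-specific GC curves. Passing recovery tests
therefore shows the estimators are correct under the stated generative
model, not that real libraries satisfy that model.

## Parameter-recovery conventions

The GC-vertex recovery check fits the quadratic to window-mean **log**
coverage against window-mean **gc50** — the generator's own response scale
and covariate, aggregated identically on both sides. The field-style raw
regression on aligned-window GC is kept as the analysis output, but it
cannot pin the vertex: exp of a quadratic is not a quadratic (the raw-scale
vertex is displaced at strong curvature), and aligned-window GC is a
smoothed proxy for the centered gc50 sites respond to, an
errors-in-variables attenuation that shifts the apparent vertex ~0.04 lower
even noiselessly. With matched aggregation the recovery is unbiased with
SD ≈ 0.012 at 330 windows.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 16,500-bp, 11-individual
cohort (seconds per cohort); replicate-based properties use 100
single-individual cohorts. The k-mer stage uses reads at 60X from the full
reference (~10⁶ k-mer instances). Degenerate inputs are errors, not
silence: constant GC, single-level ANCOVA terms, unimodal spectra,
zero-mean profiles and out-of-range spans all raise with the offending
term named. Zero-depth sites yield 'N' consensus and NaN error rates;
consensus ties break toward the provided reference base, else
alphabetically.
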