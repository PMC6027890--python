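# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each module. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical* structure the estimators rely
on, not the mechanistic detail of real sequencing or real genomes.

- **Diploid genomes** are i.i.d. base sequences at a configurable GC
  fraction (default 0.37, a typical broadleaf-tree nuclear value) with
  heterozygous sites placed by independent Bernoulli(het) draws,
  substitutions only. Real genomes add repeats, indels, CpG effects and
  clustered polymorphism; none of these is modeled, so passing recovery
  tests demonstrate estimator correctness under the model, not robustness
  to repeat-rich genomes.
- **Reads** are uniform over both haplotypes and strands with i.i.d.
  substitution errors and constant quality (qualities are unused
  downstream). `depth` is fold coverage of the haplotype pair relative to
  haploid length: total bases ≈ depth × length, so each haplotype is
  covered depth/2 times. No coverage bias, duplicates, or indel errors.
- **Species sets** evolve by Jukes–Cantor along a user tree. Each branch
  applies the exact JC transition kernel (change probability
  (3/4)(1 − e^(−4t/3)), uniform among the three other bases), so branch
  composition is exact and the observed leaf-pair mismatch fraction is
  Binomial(L, p(d)) with d the tree path length — the property the
  divergence tests check. No rate heterogeneity across sites.
- **Codon sets** propose point mutations at Poisson rate t per nucleotide
  site per branch with a ts/tv bias κ (default 2), reject stop-creating
  changes, and accept synonymous proposals with probability min(1, 1/ω)
  and nonsynonymous ones with min(1, ω), so the realized acceptance odds
  equal the branch's ω for any ω ≥ 0. Applied mutations are counted per
  branch as ground truth. Note that the κ bias interacts with
  Nei–Gojobori counting (below): at κ = 2 an ω = 1 branch reads back
  slightly below 1, which is the documented NG86 behaviour, not a bug;
  rank order across branches is unaffected.
- **Polymorphism samples** use msprime's neutral coalescent per
  non-recombining block (default 10 kb) with ploidy 1 and population size
  1, binary mutations at rate θ/2 per site per generation, giving
  E[π] = θ per site exactly. Blocks are independent, which understates
  the variance of π relative to a single linked locus and ignores
  recombination within blocks — adequate for testing an estimator whose
  expectation is the target.
- **Planted gene copies** insert a gene identically into both haplotypes,
  then either replace one haplotype's copy with a diverged version
  (allelic; copy-specific k-mers land on one haplotype) or insert the
  diverged copy downstream on both haplotypes (tandem duplicate;
  copy-specific k-mers land on both).

All generators are pure functions of their arguments including the seed;
each call owns one `numpy.random.Generator`.

## k-mer spectrum profiling

Counting is canonical (lexicographic minimum of each window and its
reverse complement), 2-bit encoded, k odd and ≤ 31 so a window fits one
signed 64-bit word; windows containing non-ACGT bases are skipped. The
rolling-code loop is numba-compiled and counts come from a single
`np.unique`, which keeps 10⁷–10⁸ window inputs tractable in memory on one
CPU. The default k = 31 matches common practice for plant genome surveys.

**Error cutoff.** The smoothed spectrum (centered moving average, window
3 — the smallest window that suppresses single-bin noise) is scanned for
its first local maximum (the sequencing-error peak, which smoothing can
displace off depth 1) and the cutoff is the depth at which the spectrum
first rises again. A spectrum that never rises has no separable error
peak and raises rather than guessing.

**Peaks.** Local maxima above the cutoff are filtered to ≥ 5% of the
tallest and then de-duplicated: within any 1.4× depth window only the
tallest maximum survives, since shot noise on a broad peak otherwise
fabricates neighbours. The haploid/diploid pair must have a depth ratio
in [1.6, 2.4]; a clear second peak outside that band is an error with
diagnostics (it usually means contamination or a collapsed polyploid). A
single peak is a homozygous genome: haploid area 0. Peak areas integrate
raw distinct-k-mer counts between flanking minima; the valley bin joins
the nearer peak (tie → haploid).

**Genome size.** With canonical counting the homozygous peak depth d
equals the full k-mer coverage 2c, and the haploid genome size is
G = T/d with T the above-cutoff k-mer volume. Strand-specific counters
split each locus's occurrences between a k-mer and its reverse
complement, halving apparent peak depths; for such histograms the same
estimator reads G = T/(2d), exposed via `strand_collapsed=False`. The
printed worked example in the tests uses the strand-specific form, which
is how the historical histograms it reproduces were computed. G is
insensitive (±2%) to ±1 changes of the error cutoff because the error
bins carry little volume.

**Heterozygosity ranking** sorts on the haploid-peak area fraction
A_h/(A_h + A_d). This is a monotone proxy, not an estimate of per-base
heterozygosity: both haplotype versions of a het-spanning window land in
the haploid peak, so the fraction is roughly 2(1 − (1−h)^k) normalized,
saturating for hk ≫ 1. Ties keep input order, share the smaller rank and
are flagged.

## Alignment statistics

Segment tables follow MUMmer `show-coords -T -l` conventions (1-based
inclusive; reversed query coordinates mean minus strand); internal
coordinates are 0-based half-open. Mismatches per segment are recovered
as round(aligned_query_len · (1 − %IDY/100)) — exact counts are not in
the file, and rounding error is bounded by half a mismatch per segment.
The 1000 bp minimum applies to the reference *sequence* (strictly
greater than), both for dropping segments and for the coverage
denominator. Overlapping segments are not merged (an upstream best-tiling
filter is assumed); overlapping bp are reported as a diagnostic instead.
The symmetric distance pools mismatches and aligned bases over both
orientations — concatenation semantics, i.e. a base-weighted average.
Divergence with zero aligned bases is `None`, never 0.

The micro-synteny verdict requires one query scaffold to cover ≥ 80%
(configurable) of both gene intervals with consistently ordered,
single-orientation segments.

## Phylogeny

`jukes_cantor` refuses p ≥ 0.75 (saturation) rather than returning NaN.
Neighbor joining is the classical Saitou–Nei algorithm; Q-matrix ties
break on the first index pair in row-major order, making results
deterministic; negative branch lengths are clamped to zero with the total
deficit reported on the tree; the last three lineages join at a
trifurcation (standard unrooted form). NJ is exact on additive matrices,
which the tests verify against both the generating trees and an
independent implementation.

Bootstrap supports resample alignment columns with replacement and count
replicates containing each internal bipartition of the full-data tree.
Bipartitions subtended by (near-)zero-length branches are not counted as
splits, so uninformative data yields no supported bipartitions instead of
an arbitrary resolution. Replicates whose resampled p-distance saturates
are skipped (they cannot be JC-corrected).

The chronogram uses mean-path-length clock smoothing: each node's height
is the tip-count-weighted mean of its children's heights plus branch
lengths (equivalently the mean path to its descendant tips), heights are
forced weakly monotone up the tree, and all heights are scaled so the
calibration node — named directly or as the LCA of given tips — sits at
the calibration age (default 45 Mya, the walnut crown-group anchor).
Branch lengths become age differences, so ultrametricity is exact by
construction. This is a least-squares projection under a strict clock; it
has no rate-variation model and no confidence intervals, and an ML
chronogram can differ where rates vary among lineages.

Distance-based NJ (not maximum likelihood) is the tree method throughout:
the package's distance track feeds directly on pairwise genome-alignment
divergences, and ML tree search is deliberately out of scope.

## Population genetics and selection

**π.** Per segregating site the unbiased pairwise heterozygosity
2p̂(1−p̂)·n/(n−1) with n the alleles actually called at that site; sites
with more than two alleles are excluded (biallelic SNP filtering), and
monomorphic callable sites contribute only to the denominator. Coverage
classes are depth windows (quantile defaults 2.5%/99% of the aligned
depth histogram); per-class π values combine by callable-site weights, so
if all classes agree the weights cancel. A site whose depth matches no
class is an error, not silently dropped. VCFs are read with cyvcf2;
haploid simulation columns pair into diploid VCF samples.

**Relative rate.** m₁ and m₂ count sites where exactly one ingroup
sequence differs from outgroup = other ingroup; three-state sites are
uninformative. χ² = (m₁−m₂)²/(m₁+m₂) with one degree of freedom, an
upper-tail p.

**HKA-like test.** Plain 2×2 χ² of {polymorphism, divergence} ×
{locus 1, locus 2} from row/column margins, *without* Yates continuity
correction — the full multilocus HKA variance model is out of scope.
Expected cells below 1 raise; below 5 warn. With the correction the test
would be conservative for the small-count tables this is used on.

**Ka/Ks.** Nei–Gojobori (1986): per-codon synonymous site counts are the
per-position fraction of the three alternative bases preserving the
amino acid (stop-creating changes count as nonsynonymous, so sites sum
to 3 per codon), averaged over the two sequences; differences average
over all minimal mutational pathways, excluding paths through stop
codons unless every path is blocked; pa and ps get the Jukes–Cantor
multiple-hit correction. Lineage-specific rates apply this to each
(parent, child) pair of a Fitch-parsimony ancestral reconstruction: the
up-pass computes state sets per nucleotide position, the down-pass
resolves each node to its parent's state when available, else the first
set state in A < C < G < T order — one canonical most-parsimonious
reconstruction. The count of ambiguous (site, node) pairs is reported as
a diagnostic; enumerating and averaging all resolutions is not done,
because at the low per-branch divergences this method targets the
alternative resolutions differ at a vanishing fraction of sites.
Reconstruction can occasionally assemble a stop codon at an internal
node; the lineage path skips such codons rather than failing. Parsimony
systematically shortens branches where multiple hits coincide, so
per-branch Ka and Ks are slight underestimates at high divergence —
rank order across branches, which the recovery study checks, is robust.

## Duplicate-vs-allele classification

Copy-specific k-mer sets are exact canonical set differences. The median
(not mean) read depth of the specific k-mers resists repeat-overlapping
outliers. The verdict compares the median m to the profile's haploid and
diploid peaks on a log scale: allelic if |log(m/h)| < |log(m/d)| and
m < (h+d)/2, duplicated in the mirror case, ambiguous when fewer than 20
specific k-mers exist (the median of a handful is noise) or when the two
log-distances differ by less than log(1.2) — a 20% margin, a free
parameter surfaced in configuration since no principled threshold exists.
Verdicts are symmetric under copy relabeling.

## Problem sizes in the test and acceptance runs

The recovery studies run at desk scale, chosen so the full suite
completes in a few minutes on one CPU while keeping every statistical
bound meaningful: 200 kb genomes at 100× coverage (five heterozygosity
levels × five seeds) for profiling; 100 kb six-taxon alignments × five
seeds for divergence and topology; 500 kb, n = 20 coalescent samples ×
ten replicates per θ for π; 10⁴ codons for Ka/Ks; forty 30 kb planted-
copy scenarios at 80× for classification. Divergence is compared to the
Jukes–Cantor closed form on mismatch counts pooled across seeds (the
concatenation semantics the symmetric distance itself uses); per-seed
per-pair bounds would run 75 correlated 3-SD comparisons and fail
occasionally by construction.

## Known limitations

- In-memory k-mer counting: genomes beyond a few tens of Mb of read data
  per profile need a disk-backed counter; this package targets desk-scale
  validation and gene-level analyses.
- No ML phylogenetics, no rate-variation models, no chronogram
  confidence intervals.
- The HKA-like test is the 2×2 contingency approximation, not the full
  coalescent-variance HKA.
- π assumes biallelic SNPs and treats the callable-site counts as given;
  it does not call SNPs.
- The classifier presumes the genome profile's two peaks are well
  separated; heterozygosity below ~0.2% at moderate coverage merges the
  peaks and yields ambiguous verdicts by design.
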