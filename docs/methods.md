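# Methods

This note documents the models, estimators and numerical conventions used
in `rediplo`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Divergence model and dating

Two subgenomes that separated `T` years ago each accumulate substitutions
at `r` per synonymous site per year, so pairwise synonymous divergence is
`Ks = 2rT`. Dating inverts this: `T = Ks_peak / (2r) / 1e6` Mya. Defaults
`r = 3.51e-9` and `T = 1.23e6` give an expected `Ks = 0.0086`. The
arithmetic is linear in the peak and inverse in the rate, and is reported
rounded to two decimals.

Transposon insertion ages use a **single-lineage clock**:
`age = (pct_divergence/100) / r`, because a copy's divergence from the
family consensus is accumulated by that copy alone (the consensus stands
for the ancestral active element). This differs deliberately from the
pairwise `2r` denominator used for subgenome dating; comparing the two
scales requires keeping this convention in mind.

## NG86 Ka/Ks

Sites: for each codon, each of the nine single-base changes is classified
against the standard code; changes creating a stop count as nonsynonymous.
`S` per codon is the synonymous fraction × 3 and `N = 3 − S`; pair-level
`S`, `N` are the means over the two sequences, so `N + S = 3L` exactly for
`L` usable codons. Differences: codon pairs differing at `d` positions are
averaged with equal weights over all `d!` orderings of single-base steps,
excluding orderings that pass through a stop codon (if every ordering is
blocked — possible only for some 2–3-step pairs — steps are classified
directly so no difference is dropped). Proportions `ps = Sd/S`,
`pn = Nd/N` are Jukes–Cantor corrected, `k = −(3/4) ln(1 − 4p/3)`,
undefined (flagged, not raised) at `p ≥ 3/4`. The implementation agrees
with Biopython's independent NG86 (`cal_dn_ds`) to machine precision; the
test suite asserts this.

Codon alignment is protein-level global alignment (BLOSUM62, gap open −11,
extend −1) back-mapped to codons; gapped columns are excluded. Trailing
stop codons are stripped; internal stops reject the pair with a
diagnostic.

4DTv: a third-codon position is eligible only when the first two positions
are identical across the pair and define a fourfold-degenerate family
(conservative convention; alternatives exist in the literature and the
eligibility rule is therefore isolated in one function). The statistic is
transversions at eligible sites / eligible sites.

## The Ks peak and its bandwidth

`ks_mode` restricts values to [0, 99th percentile] and takes the argmax of
a Gaussian KDE (Silverman bandwidth by default, overridable) on a
2,048-point grid.

One numerical effect deserves emphasis. At `Ks ≈ 0.0086` a 1,500-bp CDS
carries only ~3 synonymous differences, so the empirical per-pair Ks
distribution is a **discretized Poisson ratio**: atoms at `k/S` whose
widths shrink with `k`. A kernel narrower than the per-pair counting error
resolves those atoms rather than the underlying peak and biases the mode
low by ~30%. `ks_mode` therefore accepts a bandwidth floor, and the
pipeline passes the median counting standard error `sqrt(Ks/S)`
(`counting_se`) — a measurement-error argument, not a tuned constant: no
feature of the divergence distribution narrower than the known sampling
noise of a single observation is estimable. With the floor, the recovered
mode sits within ~10% of the simulated value; without it, bandwidth
sensitivity can be explored through the `bandwidth` argument. Fewer than
30 defined values raise an error directing the user to report the median.

The selection scan flags a pair when `Ka/Ks > 1` and a one-sided Fisher
exact test on the rounded 2×2 count table (Nd, N−Nd; Sd, S−Sd) gives
`p < α`; Benjamini–Hochberg FDR is reported alongside. At the default
divergence (~3 synonymous counts per pair) this test has essentially no
power — a property of the counts, not the implementation — so power tests
run at branch lengths where the counts support inference (Ks ≈ 0.1).

## Homeolog pairing

Seeds are exact 15-mers (configurable, `k ≥ 11`); k-mers occurring more
than `max_occ = 8` times on a target contig are skipped, which silently
removes transposon bodies from the seed set — they then surface as chain
gaps, exactly where the indel caller looks. Same-diagonal anchors within
80 bp are merged into ungapped segments; segment identity is computed
exactly over all columns (not estimated from seeds). Segments ≥ 100 bp are
chained per contig pair and orientation by O(n²) sparse DP maximizing
total matches under colinearity with gaps ≤ 20 kb; ≤ k bp of overlap
between neighbours is trimmed with exact match recount. Contigs are paired
reciprocal-best by total chained aligned length with coverage of the
shorter contig ≥ 0.5; ties break lexicographically and are logged. On
substitution-only pairs the chain identity matches full Needleman–Wunsch
identity to < 0.5 pp (asserted against Biopython's aligner).

Ohnolog calling projects each gene through the chain (nearest-HSP
extrapolation inside gaps), scores candidate partners within ±5 kb by CDS
edit-distance identity (edlib; identity = 1 − d/max(len)), and keeps
reciprocal-best pairs at ≥ 80% identity. Genes without a surviving partner
are reported as singleton candidates.

## Indels and transposons

Each inter-HSP gap with span difference ≥ 50 bp (the typical TE scale)
yields one insertion event on the longer-span side; spans > 100 kb are set
aside as unresolved. Breakpoints are refined by extending the two gap
sequences into each other from both ends with an x-drop ungapped scan
(+1/−3, drop 12): the score climbs through diverged flank sequence and
collapses in the inserted sequence, localizing ~90% of junctions to ±2 bp.
Remaining ±1–2 bp ambiguity (chance matches between insertion and flank)
dilutes the *exact* breakpoint dinucleotide composition toward background,
so the TA target-site fraction of detected events underestimates the true
insertion preference while its *enrichment* over the genomic background
remains strong; exact-site composition is available from annotated
coordinates. Two insertions closer than the seed resolution merge into one
event — the main source of the ~5–10% miss rate in recovery tests.

TE classification intersects events with the annotation (intervaltree):
an event is TE-derived when ≥ 50% covered (merged, so nested records do
not double-count); the dominant family by overlap is recorded. Raising
the threshold can only lower the TE percentage (asserted as a property).

The identity–TE-density correlation lays non-overlapping windows (100 kb
default; 25 kb in the synthetic pipeline where contigs are 0.5 Mb) over
each paired contig, scores length-weighted mean HSP identity and TE
coverage, and reports Pearson r with two-sided p (Spearman attached as a
robustness check). Because a printed "R²" cannot be negative, r and r²
are reported separately. Zero-variance windows flag the result as
degenerate rather than guessing.

## SNP flanks

Flanks are ±500 bp of each TE boundary with all TE bodies subtracted and
overlapping flanks merged, so no SNP is counted twice (body variants are
deliberately excluded — they would otherwise inflate flank density).
Controls are length-matched intervals placed uniformly either ≥ 10 kb from
any TE ("remote") or anywhere outside TE bodies ("random"), with seeded
placement. Inference is a Welch t test plus a one-sided label-permutation
test on the mean difference (default 1,000 permutations; p = (1 + #≥obs) /
(n+1)). Calibration tests show type-I error ≤ 7.5% at α = 0.05 over 200
null replicates and > 90% power at a 3× hypermutation multiplier; the
distance-decay profile in fixed bins (0–0.5, 0.5–1, 1–2, 2–5 kb) drops
sharply beyond the hot zone.

## Expression groups

A gene "overlaps" a TE when its gene body intersects any TE record by
≥ 1 bp (a −2 kb promoter window is available, since regulatory insertions
are the hypothesized mechanism). Pairs partition into T/O/N (both / one /
neither). A gene is silenced in a tissue at FPKM < 1 (threshold explicit;
0.5/1/2 sensitivity is a one-argument change); fold change uses a +1
pseudocount, `|log2((a+1)/(b+1))|`. Group comparisons use two-proportion
z tests (off ratios) and Welch t tests with BH correction across
tissues × comparisons (fold changes).

## The synthetic genome generator

The generator emulates a young autotetraploid (single duplicated
ancestor): random-GC contigs with non-overlapping genes (gene body = 1 kb
UTR + CDS + 1 kb UTR, random strand; single-exon CDS with fixed start and
stop). Substitutions are codon-aware propose/accept: proposals are a
Poisson process with kappa-weighted (default 2) target choice; synonymous
changes are always accepted, nonsynonymous with probability ω (default
0.2), stop-creating never. The proposal intensity is calibrated so
accepted synonymous changes per lineage equal `S × rT` for the NG86 `S` of
the sequence — the realized Ks is `2rT` by construction, and the direct
count of introduced synonymous changes is stored as truth (the calibration
oracle). For ω > 1 additional directed amino-acid changes are drawn so
nonsynonymous divergence reaches `ω × rT` per site. Non-coding sequence
mutates at the synonymous rate by default (configurable).

Indels are insertions only (no deletions): an insertion on one lineage is
what "deletion on the other" looks like in a pairwise comparison, and the
conservation invariant (descendant length = ancestral + inserted bases)
stays assertable. 85% of indels (default) are transposon copies — family
drawn proportional to configured copy counts, sequence = family consensus
mutated by a per-copy age ~ Normal(burst mean 3 My, sd 0.4 My) × r —
and 15% are random sequence of 100–2,000 bp. Insertion points fall inside
a TA dinucleotide with probability 0.8, else uniformly; proposals landing
in a CDS are accepted with probability 0.05 (purifying selection against
coding disruption, keeping exonic insertions rare as in real genomes).
Each insertion registers a ±500 bp hot interval; the carrier lineage
receives extra flank substitutions at `(m − 1) × rT` per site (default
multiplier m = 3) — the insertional-mutagenesis signal that also drives
the negative identity–TE-density correlation. Population SNPs are Poisson
at 5/kb, multiplied by m inside hot intervals.

Expression: per-pair lognormal baselines (`ln FPKM ~ N(3, 1.2)`, shared
within a pair up to N(0, 0.2) drift) with N(0, 0.3) tissue noise. Each
pair draws **one shared silencing uniform per tissue**; a gene falls
silent when that draw is below its silencing probability (0.3, reduced by
0.15 for TE-overlapping genes). The shared draw encodes the inherited
common regulatory state of duplicates: pair members fall silent together
unless a TE has shifted one member's threshold, so asymmetric insertion —
not noise — decouples expression. In pairs where exactly one gene overlaps
a TE, that gene's baseline additionally gains 1 log2 unit. The silencing
and boost magnitudes are free parameters (no published effect sizes
exist); they are documented knobs, not estimates.

Default scale: 4 ancestral contigs × 500 kb (2 Mb), 60 genes/contig,
1,500-bp CDS, 400 indels. All randomness flows from one integer seed
through spawned child generators per stage; identical configuration gives
byte-identical output files.

### What the simulator does not capture

Real assemblies have multi-exon genes, nested and fragmented TE copies,
pre-WGD (shared) transposons, segmental losses, GC heterogeneity and
alignment-confounding repeats far beyond the simulator's clean bursts.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model — calibrated divergence, lineage-specific
insertions, localized hypermutation, pair-coupled silencing — not
performance on raw real-world assemblies, where pairing coverage
thresholds, k-mer occupancy limits and the indel-merge resolution would be
the first knobs to revisit.

## Numerical conventions and degenerate inputs

Internal coordinates are 0-based half-open everywhere; conversions happen
only at the GFF3/VCF boundaries (1-based). Pairings are stored once with
the lexicographically smaller contig first. Ks undefined at `p ≥ 3/4` is a
flag, not an exception; `ka/ks` with zero `ks` reports infinity and the
Fisher test is still computed. Zero-divergence inputs exercise exact
paths: identity 100, Ks mode 0 (degenerate KDE short-circuits), full
ohnolog recall. Contigs shorter than k are skipped with a warning; empty
TE tables, empty VCFs and missing expression matrices degrade to defined
no-op results rather than errors.

## Problem sizes used in tests

The shared synthetic fixture is a 0.4-Mb ancestral genome (two contigs);
acceptance-level checks run the full 2-Mb default once, 1,000 CDS pairs
for Ks recovery, 200 + 100 replicates for permutation-test calibration,
and 30 seeds per arm for the T/O/N ordering contracts. These sizes keep
the whole suite under a few minutes while leaving every statistical
assertion with clear margins.
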