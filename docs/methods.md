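# Methods

## Screen arm: from flanking reads to ranked genes

### Model of the experiment

A near-haploid cell population is mutagenized with a gene-trap retrovirus.
Because the cells are haploid for (almost) the whole genome and the trap
truncates transcription when integrated in the transcriptional direction of
a gene, a single sense-orientation insertion suffices to null that gene.
Drug selection then enriches cells whose nulled gene confers resistance.
Inverse PCR amplifies the genomic sequence flanking each surviving
provirus, and the amplicons are sequenced. Two properties of this readout
drive the analysis design:

* **Read counts per site are massively inflated** by clonal expansion
  during selection and by PCR amplification skew — sister insertion sites
  in the same gene can differ by four to five orders of magnitude in read
  count. Distinct junction *sites*, not reads, are therefore the counting
  unit for the enrichment statistics; read totals are reported alongside
  because screen reports conventionally rank by both.
* **Mapping artifacts masquerade as insertions**, so only reads that align
  uniquely with zero mismatches are kept. Unknown mismatch counts (a SAM
  record without an NM tag) are treated as failures, not as zero: unknown
  is not clean.

### Coordinate and junction conventions

Coordinates are 0-based, half-open throughout; BED input/output is used
as-is and GTF (1-based inclusive) is converted on read. An insertion's
*position* is the index of the first genomic base 3′ of the LTR–genome
junction. Since a flanking read begins at the junction by construction,
the junction base of a plus-strand read is its leftmost aligned base and
that of a minus-strand read its rightmost aligned base; the `AlignedRead`
record carries its reference span so the minus-strand junction is
computable. The gene body is the full annotated interval including introns
(gene traps act intronically), and a site overlapping several genes is
annotated once per gene rather than silently assigned to one.

### Alignment

The pipeline accepts any external aligner's SAM (via pysam; uniqueness is
approximated as MAPQ > 0 with no secondary/supplementary record for the
read, mismatches from the NM tag). For desk-scale work and for testing it
also ships an exact full-length matcher that scans both strands of the
reference: exact placements are counted by substring search, and a read
with no exact placement gets its best Hamming-distance placement reported
so the filter can account for it. No indel alignment is attempted — the
filter would discard such reads anyway.

### Enrichment test

For each gene, unique sense-site counts form the 2×2 table
`[[k_sel, n_sel − k_sel], [k_ctl, n_ctl − k_ctl]]`, where `n` is the total
number of unique sense sites in genes in each arm (intergenic sites are
excluded from both the per-gene summaries and the denominators). The
one-sided Fisher exact p — the upper hypergeometric tail
P(X ≥ k_sel | margins) — is computed via `scipy.stats.hypergeom.sf`, which
is the same quantity in closed form and vectorizes over genes; the test
suite checks it against an exhaustive exact-integer tail enumeration over
every table with margins up to 30. Benjamini–Hochberg q-values are
reported alongside raw p (the FDR procedure is a standard choice for
gene-level screens). Genes with no insertions in either arm stay in the
report with p = 1, keeping the schema stable. Two rankings are emitted:
`rank_unique` by unique sense sites and `rank_total` by total supporting
reads, each tie-broken by the other count and then by gene id, so ranks
are deterministic and input-order invariant.

The default control population is the unselected mutagenized library; any
second sequenced arm (e.g. a single-agent-only selection) can be supplied
as the control file instead.

## Synergy arm: median-effect and combination index

Each single-drug series is fitted to the median-effect equation
`fa/(1−fa) = (D/Dm)^m` by ordinary least squares of `log10(fa/(1−fa))` on
`log10 D`; `m` is the slope, `Dm = 10^(−intercept/m)`, and `r` the
correlation of the fit. Points with fa ≤ 0.005 or ≥ 0.995 are excluded
(configurable): the logit transform diverges there and such wells carry
essentially no dose information. A non-positive fitted slope flags the fit
invalid rather than raising, and a pipeline run with an invalid fit
completes with an empty CI table and a prominent warning. IC50 is reported
as Dm (the fa = 0.5 identity of the model) rather than via a separate
four-parameter fit — one coherent model throughout.

The combination index uses the mutually exclusive two-term form
`CI = d1/Dx1 + d2/Dx2` (no cross-term), matching the standard three-way
synergy/additive/antagonism classification, and is evaluated at each
combination point's own measured fa — the experimental design uses fixed
dose pairs, not a fixed ratio. fa is averaged across replicates before the
headline CI; per-replicate CI values are also emitted so dispersion is
visible. Interpretation is strictly categorical at CI = 1 with the numeric
CI always reported, so finer bands can be applied downstream. Isobologram
coordinates satisfy x + y = CI exactly by construction.

Replicate statistics follow plate-assay convention: condition means with
standard error sd/√n (missing when n = 1), and classical paired t-tests
labelled `*`, `**`, `***` below 0.05, 0.01, 0.001. Zero-variance
differences are handled by convention: identical pairs give t = 0, p = 1;
a constant nonzero difference gives t = ±∞, p = 0.

## Synthetic data: what it emulates and what it does not

The screen simulator draws one insertion per cell (the single-copy,
near-haploid assumption), uniform in position and provirus strand, over a
random genome packed with non-overlapping genes covering at most 80% of
the sequence. Selection is a single per-cell Bernoulli survival:
probability `p_survive_resistant` (default 0.95) for a sense insertion in
a designated resistance gene, `p_survive_background` (default 10⁻³)
otherwise. Each surviving site receives a log-normal read count (natural-
log mean 4.0, sd 2.5, rounded up to ≥ 1), chosen so counts span roughly
four to five orders of magnitude as real PCR/expansion-skewed insert
counts do. Reads are the exact flanking sequence 3′ of the junction on the
provirus strand, with optional substitution-only sequencing error — the
zero-mismatch filter only needs substitutions to be exercised. Defaults
(20,000 cells, 50 genes, 50 kb genome, 50 bp reads) are a desk-scale
analogue of a genome-wide screen of ~10⁸ cells.

Not modelled: selection kinetics over the treatment course or drug
dose-schedule effects (survival is one probability), integration-site
sequence preference, multi-copy integration, diploid regions, indels or
quality-dependent errors, and chimeric/adapter artifacts. Passing tests
therefore demonstrate correctness of the analysis under idealized
insertion and sequencing processes, not robustness to every artifact of a
real library.

The dose-response simulator generates fa from `logit(fa) = m(ln D − ln Dm)
+ ε` with ε ~ N(0, noise_sd) — noise on the logit scale keeps fa in (0,1)
and is exactly the scale on which the fit is linear, so noiseless data
round-trip to machine precision. Combinations are generated Loewe-
additively: the effect at (d1, d2) solves `I·d1/Dx1(fa) + I·d2/Dx2(fa) = 1`
(closed form when the slopes match or one dose is zero, bisection
otherwise), where the interaction multiplier `I` scales effective potency;
the recovered CI is exactly 1/I, giving ground truth for synergy (I > 1)
and antagonism (I < 1). Real combination data need not follow a Loewe
surface at all effect levels; the simulator provides calibration targets,
not a pharmacological model.

## Numerical choices and problem sizes

* Determinism: every simulator takes a seed; pipelines fan one global seed
  out to stages by fixed offsets, and a run's manifest records enough to
  regenerate it byte-identically.
* The Loewe solver uses Brent's method on the log-odds with tolerance
  1e-13, well inside the 1e-6 additivity checks.
* Ties in exact matching resolve to the leftmost placement, plus strand
  first.
* Reads whose site sits too close to a sequence end for a full-length read
  are skipped and counted, and excluded from round-trip ground truth.
* Test and acceptance problem sizes — 20,000-cell screens over 50 genes
  with up to 100 replicates, 5 kb genomes for full read-level round trips,
  margins ≤ 30 for the exhaustive Fisher sweep — were chosen so the full
  statistical behaviour is exercised while the suite completes in well
  under a minute per check.

## Known limitations

* The exact matcher is O(genome × read) in the worst (mismatch-scan) case
  and is intended for desk-scale references; genome-scale data should
  arrive as SAM from a production aligner.
* SAM uniqueness via MAPQ > 0 plus absence of secondary records is an
  approximation of "aligned uniquely"; aligners with nonstandard MAPQ
  conventions may need pre-filtering.
* The enrichment test conditions on total sense-site counts per arm and
  assumes sites are independent across cells; it does not correct for
  gene length or integration bias.
* Whether a published screen's "unique insertions" counts sense-only or
  all orientations varies; both counts are emitted so either definition
  can be recomputed.
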