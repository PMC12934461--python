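# Methods

`dsbskew` analyzes strand-resolved sequencing data around induced DNA
double-strand breaks (DSBs). This note documents the models, the
parameters that matter, the numerical choices, and what the bundled
synthetic-data generator does and does not emulate.

## Background and signal model

5'→3' end resection at a DSB degrades the 5'-terminated strand on each
side of the break, leaving 3'-terminated single-stranded DNA: the `+`
(top) strand is retained left of the cut and the `-` strand right of it.
A library preparation that preserves template-strand identity therefore
reports resection as a *skew* between `+`-strand and `-`-strand coverage
that is positive left of the cut and negative right of it, with mirror
antisymmetry when resection is symmetric. Fragments from intact duplex
DNA carry both strands and contribute equally (in expectation) to both
stranded tracks, so they cancel in the skew.

In a coordinate-sorted paired-end alignment the template strand is read
off the SAM flag pair: `{99, 147}` → `+` template, `{83, 163}` → `-`;
any other combination is `unassigned` and excluded from stranded
coverage. This makes the per-bin identity
`plus + minus = unstranded` exact by construction.

## Cut-site prediction

* **Restriction motif scan** (default `GCGATCGC`, the rare-cutting AsiSI
  octamer): every occurrence is reported, including overlapping ones.
  Because the octamer is palindromic, each duplex occurrence reads
  identically on both strands; the scanner searches the forward strand
  only and reports unoriented sites — a double-strand scan with
  deduplication yields the identical list (property-tested against a
  brute-force oracle). The cut is placed bluntly at the motif midpoint
  (`start + len/2`); the enzyme's 2-nt 3' overhang is below the
  resolution of 150-bp reads and binned tracks and is ignored.
* **Cas9**: exact 20-nt protospacer match with an `NGG` PAM; blunt cut
  between protospacer positions 17/18 (3 bp 5' of the PAM), mirrored
  arithmetic on the minus strand. Mismatch-tolerant search and off-target
  scoring are out of scope.

## Synthetic fragment generator

Each simulated fragment is drawn from an independently sampled molecule
(fragments subsample a large molecule population):

1. each DSB site is cut with probability `cut_efficiency` (default 0.8 —
   inducible nuclease systems cut a minority-to-majority fraction of
   alleles; exposed per experiment);
2. a cut molecule is rejoined with probability `rejoined_fraction`
   (default 0.2); an open cut is resected with probability
   `resected_fraction` (default 0.8), with per-end resected length drawn
   geometric with mean `resection_mean` (default 1,500 bp). The
   geometric law encodes memoryless per-base stopping; the distribution
   is a modelling choice, exposed in the configuration;
3. a binding position is drawn from an occupancy mixture: uniform
   background, Gaussian kernels at configured open-chromatin peaks
   (pre-loading), a Gaussian footprint at each cut (damage-induced
   loading; narrow preset sigma = 150 bp for an end-processing-nuclease
   profile, broad preset 1,000 bp for a spreading-clamp profile), and a
   uniform extra weight on resected spans (`ssdna_affinity`, a free
   parameter — the ssDNA/dsDNA binding partition of the emulated factor
   is not an estimated quantity);
4. a uniform fragment length from `fragment_len_range` (default
   200–600 bp, matching sonication shear) is laid over the position;
   fragments are truncated at open cuts — a sequencing fragment cannot
   cross a physically broken molecule — so with full cutting and no
   rejoining, no fragment spans a cut;
5. fragments wholly inside a resected span carry only the retained
   3'-terminated strand; all others are double-stranded and are assigned
   a library strand with probability 1/2 each at emission (a duplex
   yields both library strands equally);
6. fragments from rejoined molecules may span the cut and carry a
   configured junction deletion (`deletion_length`, preset 9 bp for an
   end-joining deletion scenario) as a `D` alignment gap.

Reads are emitted as proper pairs (150-bp reads by default, PE150
chemistry) with the flag convention above.

**Induction-fold calibration.** `dsb_induction_fold`,
`adjacent_induction_fold` and `preload_weight` are specified as
*window-mean* signal gains over background within ±`signal_window`
(default 1 kb) of the feature. The footprint component's mass is divided
by the expected truncation survival fraction (computed by deterministic
numeric integration over the anchor and fragment-length distributions)
so the delivered gain matches the configured fold despite fragments
being clipped at the open cut. Presets: 25-fold for damage-site loading
in a signalling-proficient regime, 5-fold under checkpoint-kinase
inhibition, 10-fold for the overall gain at a cut open-chromatin locus.

**What the generator does not emulate:** sequencing errors, PCR
duplicates beyond exact-coordinate collisions, mappability structure,
chromatin-state heterogeneity along the genome, cell-cycle mixtures, and
inter-site variability in cut efficiency. Passing tests therefore
demonstrate correctness of the analysis operations under a clean,
explicit generative model — not robustness to every artifact of real
libraries.

## Coverage, normalization and track algebra

Counting is fragment-level: each template span adds its bp overlap per
bin divided by the bin size (default 50 bp for profiles; 10-kb bins are
the intended scale for normalization count matrices). Filtering removes
blacklist-overlapping fragments (≥1 bp), exact-coordinate duplicates
(keep-first), and — in ATAC mode — non-proper pairs and mitochondrial
contigs. Blacklisting and deduplication commute, so filter order is
immaterial.

Between-sample scaling uses the trimmed mean of M-values (TMM):
reference = sample whose library-scaled 75th-percentile count is closest
to the mean over samples; M and A computed over bins non-zero in both;
30% two-sided trim on M and 5% on A; inverse-asymptotic-variance
weighting; factors rescaled to geometric mean 1. The implementation
reproduces `edgeR::calcNormFactors` to ~1e-8 (verified in the suite via
`Rscript`); coverage scale factors combine the TMM factor with the
library-size ratio. Skew is the raw per-bin difference `plus - minus`
(primary), with a depth-normalized variant
`(plus - minus)/(plus + minus + 1)` as a secondary output whose
pseudocount of one scaled count bounds it on sparse bins. Replicate
tracks combine by bin-wise mean; treatment/control by subtraction.

## Site metrics

* **Metaprofile**: windows `[cut - w, cut + w)` in track bins;
  minus-oriented sites are mirrored (coordinates reversed, strands
  swapped, skew negated) before the unweighted mean across sites.
* **Span/end classification** (tolerance default ±5 bp, exposed; no
  value is canonical): a fragment is *ending* if either terminus lies in
  the closed window around the cut, *spanning* if it covers the window
  entirely and is not ending, *other* if it merely overlaps. Alignment
  gaps do not break the span test — a deletion-carrying rejoined
  fragment still spans. The reported fraction is
  `ending / (ending + spanning)`; the denominator choice is recorded in
  the run manifest.
* **Deletion detection**: for spanning fragments, gap blocks overlapping
  the cut window contribute their lengths to a histogram; the modal
  length identifies a repair-junction deletion. Via the SAM path only
  read-covered gaps are observable (a deletion falling in the
  unsequenced middle of a long fragment is invisible), which mirrors
  real data.
* **DSB-adjacent open sites**: open intervals whose center lies
  1.5–50 kb from the *nearest* cut, excluding any interval overlapping a
  ±1.5 kb exclusion zone. Nearest-cut anchoring means a site between
  two cuts counts once.
* **Correlation**: pairwise Spearman (average ranks on ties) between
  sample columns of the site × sample mean-coverage matrix, classed
  strong (ρ ≥ 0.7), moderate (0.5 ≤ ρ < 0.7), weak (ρ < 0.5);
  zero-variance columns are reported as undefined rather than silently
  dropped. Mean (not max) window coverage is the site signal, matching
  window-averaged profile plots.
* **Fold change**: per-site `(b + pc)/(a + pc)` with a default
  pseudocount of one scaled count to bound folds at empty sites;
  summary is the median over sites.

## Resection length from skew decay

Under geometric resection the expected single-stranded span coverage at
distance *d* from the cut decays as `P(R > d) ≈ exp(-d/L)`, halving at
`L ln 2`. The measured |skew| profile is this decay convolved with the
fragment-placement geometry: because a fragment must lie wholly inside
the resected span to carry a single strand, the profile ramps up over
roughly one fragment length before entering the geometric tail, so the
half-max distance measured from the origin is biased upward by the peak
position. The estimator therefore measures the half-max decay distance
*from the profile peak*: `L̂ = (d_half - d_peak)/ln 2`, with light
3-bin smoothing and linear interpolation of the crossing. On 100k
fragments this recovers L = 1,500 bp within ±10% across seeds.

Resection-extent measurements are run with the damage footprint disabled
(`dsb_induction_fold = 1`): a strong break-centered binding footprint
adds a narrow spike of strand-specific signal at the cut (footprint
fragments truncated at the cut and wholly inside the span are
single-stranded) that shortens the apparent half-decay distance. This is
the simulation analogue of measuring resection extent from a
resection-tracking signal rather than from break-proximal factor
enrichment.

## %ssDNA (restriction-protection qPCR)

A restriction site at a known distance from the inducible DSB is cut in
double-stranded but not single-stranded (resected) DNA. With ΔCt =
Ct(digested) − Ct(mock), the single-stranded fraction is

    %ssDNA = 100 / (2^(ΔCt − 1) + 0.5)

(derivation in the module docstring: a duplex contributes two template
strands, an ssDNA molecule one, and digestion removes only duplexes).
QC follows the assay's practice: any reaction above 35 cycles is
non-usable and excluded with a logged reason; ΔCt down to −0.5 cycles is
tolerated as technical noise and clamped to 0 (=100%); larger negative
values are an assay-inversion error. The simulator emits Ct pairs by the
exact inverse of this formula plus Gaussian noise (default sd 0.1
cycles), so the zero-noise round trip is exact; zero ssDNA is censored
at 40 cycles. Default amplicon distances (335, 1,618, 3,500 bp) follow
the established assay; distances are data, not constants.

## Numerical and scale choices

* Coordinates are 0-based half-open everywhere; SAM converts at the
  boundary. Cuts are inter-base coordinates.
* One seed governs every stochastic stage; sub-streams are derived per
  stage (`[seed, stage]`), so genome, fragments, strand assignment and
  qPCR noise are independently reproducible.
* Test and demonstration problem sizes — 100–200 kb genomes, 2–3 cuts,
  10k–100k fragments, 50-bp bins — were chosen so that every stochastic
  check has comfortable statistical resolution (e.g. ~3 sampling SDs
  for null-skew bounds) while the whole suite runs in well under a
  minute.
* Degenerate inputs: empty fragment sets produce zero tracks; sites
  whose windows leave the contig are dropped and logged; an all-zero
  TMM sample is an error naming the sample; a zero-variance correlation
  column is reported as undefined.

## Known limitations

* The motif scanner is exact-match only (no ambiguity codes); genome
  assembly scope (which contigs to include) is the caller's choice when
  scanning a real reference.
* Exact-coordinate deduplication over-removes in very deep, small
  simulated genomes where distinct molecules collide by chance; analyses
  of dense simulations can skip deduplication, and the removal tally
  makes the effect visible.
* The span/end classification and deletion detection assume
  coordinate-faithful alignments; alignment artifacts around junctions
  (soft-clipping, multi-mapping) are not modelled.
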