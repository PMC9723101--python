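# Methods

## Scope and data model

`svecho` analyzes per-tumor somatic call sets: SNVs (chromosome, position,
ref, alt) and SVs (two breakpoints plus a class among duplication, inversion,
deletion, translocation). Internally all coordinates are 0-based with
half-open intervals; VCF POS (1-based) and BEDPE/BED (0-based half-open) are
converted at the I/O boundary and nowhere else. The breakpoint of a BEDPE end
is the start of its interval — single-position breakpoints are assumed, and
start-of-interval is the deterministic choice when callers emit 1 bp
intervals. Non-SNV VCF rows (indels, MNVs, symbolic alleles) are skipped and
counted rather than rejected, since real somatic VCFs mix variant types;
multi-allelic rows split into one record per ALT. Chromosome names are
matched exactly against the assembly, with an explicit opt-in flag to
reconcile `chr`-prefixed and bare dialects.

## Breakpoint-proximal enrichment

The number of SNVs expected by chance within ±R of a tumor's SV sites is

    E = n_SNV / L × n_SV × 2R,

genome-wide SNV density times a naive footprint of one ±R window per SV
event. The observed count O is the number of distinct SNVs within R
(inclusive on the boundary) of at least one breakpoint — both breakpoints of
every SV count as sites, and an SNV under several windows counts once.

Two deliberate ambiguities in the footprint are exposed rather than hidden:

* **Events vs breakpoints.** `sv_site_unit="event"` (default) counts one site
  per SV; `"breakpoint"` doubles n_SV for intra-chromosomal events. The
  default reads "each SV site" conservatively as one region per event, which
  matches SVs whose two breakpoints are close (the common case for
  deletions/duplications/inversions under ~1 Mb).
* **Overlap.** The naive footprint 2R·n_SV ignores window overlap. When
  breakpoints cluster — precisely the regime this analysis targets — the
  merged window length |W| can be several-fold smaller than the footprint, so
  O/E is biased even without any enrichment. The overlap-corrected
  expectation E* = (n_SNV/L)·|W| is therefore computed alongside E for every
  sample. Under uniform SNV placement O ~ Binomial(n_SNV, |W|/L), so E* is
  exactly the null mean and the cohort test built on it is calibrated; the
  naive E is retained as the conventional reported quantity. On desk-scale
  genomes (150 Mb, 40 breakpoints, R = 1 Mb) only the corrected expectation
  is usable for inference; on a 3 Gb genome with dispersed breakpoints the
  two converge.

Cohort inference: a paired two-sided t-test of O vs E (or E*) across tumors
(`paired_counts`, default), or a one-sample t-test of ln(O/E) against 0
(`log_ratio`, requiring positive counts). Degenerate inputs (zero variance of
differences) return an explicit degenerate flag with p = 1 when all
differences are zero and p = 0 otherwise, never an exception. Note that the
relative rate recovered for a planted enrichment factor f is
f·L / (L + (f−1)|W|), not f exactly: the proximal surplus inflates n_SNV and
with it the expectation. With |W| ≈ 5–10 % of the genome this attenuation is
≈ 10–15 %.

Per-gene tallies count SNVs and SV breakpoints in half-open regions,
optionally extended by a symmetric flank (10 kb–10 Mb flanks reproduce the
outside-gene distance strata).

## Tracks, peaks, and the echo profile

Variant positions are counted into fixed-width bins (bin of p is
floor(p/bin), default 1 Mb; 100 kb for fine-scale runs) and smoothed with a
centered moving average. "Within 10 Mb" smoothing over 1 Mb bins is realized
as span 11 (±5 Mb); a centered window keeps peaks aligned with their cause,
and at chromosome edges the window truncates to in-bounds bins (the mean
divides by the truncated size — zero-padding would fabricate depletion).

SV peaks are strict local maxima of the smoothed track that are at least
`fold_threshold` (2, alternatively 5) times the genomic average — the mean
over **all** bins of the assembly, including empty ones, unless a mask BED
excludes regions (bins whose midpoint falls in a masked interval). Plateaus
yield their midpoint bin with ties broken leftward; terminal bins qualify
when they exceed their single neighbour; a run spanning a whole chromosome is
not a peak. Curvature-based "inflection" detection was considered and
rejected in favour of the plain local-maximum reading.

The echo profile extracts the smoothed SNV values at offsets −flank..+flank
(default ±15 Mb) around each qualifying SV peak and averages across peaks per
offset, skipping offsets that fall off the chromosome (each offset's mean
uses only its actual contributors). Profiles from multiple tumors pool by
weighting each offset with its contributor count. The echo enrichment score
is the mean profile value over |offset| ≤ 1 Mb (the scale on which proximal
enrichment is strongest) divided by the SNV genomic average; it is invariant
under uniform scaling of the SNV track. Its null is estimated by circularly
rotating each chromosome's raw binned SNV counts by independent uniform
offsets before smoothing — rotation preserves the per-chromosome value
multiset while destroying alignment with the peaks.

## Kataegis and rainfall statistics

Rainfall points carry each SNV's distance to its predecessor on the same
chromosome (the first SNV per chromosome has none), with distance zones
< 1 kb, 1 kb–1 Mb, ≥ 1 Mb. Duplicate positions produce distance-0 points
that are flagged as ties and excluded from log-scale tests (they usually
reflect caller artifacts, and log10 is undefined there).

The cluster definition "three mutations within 1 kb" is genuinely ambiguous
between a chain rule and a fixed window. The default is the chain rule —
maximal runs of ≥ `min_count` (3) SNVs with every consecutive gap ≤
`max_gap` (1000 bp), so a cluster may span more than 1 kb — which matches
rainfall-plot practice; `rule="window"` gives the strict variant (≥ 3 SNVs
inside some 1 kb window, overlapping windows merged). Both are exact
maximal-disjoint calls, verified against exhaustive oracles.

SV-high bins are those with smoothed SV signal ≥ fold × genomic average;
every rainfall point takes the label of the bin containing its own position
(not the gap midpoint — deterministic and unambiguous at bin boundaries).
Inter-SNV distances in SV-high vs SV-low bins are compared with Welch's
two-sided t-test on log10 distances (raw scale available), optionally after
removing points inside called kataegis clusters so the broad-scale contrast
can be assessed regardless of kataegis.

## Supporting statistics

Pearson r with two-sided p from t = r·sqrt((n−2)/(1−r²)) on n−2 df; Fisher
r-to-z for comparing two correlations, z = (atanh r₁ − atanh r₂) /
sqrt(1/(n₁−3) + 1/(n₂−3)). When the two correlations share a variable (SNV
vs age and SNV vs SV on the same tumors) they are dependent and the
independent-sample z is an approximation; the result carries a note saying
so rather than silently substituting a dependent-correlation test. Welch's
t with Welch–Satterthwaite df; OLS slope/intercept; signature counts
normalized by the clock-like burden (SBS1+SBS5) with clock entries omitted
from the output. p-values are raw and two-sided throughout — no
multiple-testing correction is applied anywhere. Distribution tails come
from scipy's t and normal functions; the test suite checks each statistic
against independently coded textbook formulas at 1e-9 and verifies ~5 %
null rejection rates by simulation.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at a
desk scale chosen so the full suite runs in minutes: three 50 Mb chromosomes,
20 tumors per cohort. Per tumor:

* **SVs**: Poisson(20) events. 95 % draw both breakpoints inside one of 3
  recurrent 250 kb hotspots (hotspot translocations join two hotspots on
  different chromosomes); the rest place breakpoint 1 uniformly with
  log-uniform event size 10 kb–1 Mb. Strong hotspot concentration is the
  phenomenon of interest — tumor SV breakpoints cluster heavily, and on a
  small genome proportionally tight hotspots are needed for SV peaks to
  stand out against the genomic average and for breakpoint windows to cover
  a small genome fraction. Classes are uniform over the four types;
  translocations are forced inter-chromosomal.
* **Background SNVs**: homogeneous Poisson at λ = 1e-5/bp (≈ 0.5 /Mb/tumor
  of the human somatic ballpark, scaled for a small genome to keep per-tumor
  totals ≈ 1500).
* **Proximal SNVs**: within d = 1 Mb of any breakpoint the rate is f·λ
  (default f = 3), implemented by superposition — an independent process at
  (f−1)·λ on the *merged* windows — so the marginal rate is exact even where
  windows overlap. `decay="linear"` replaces the step by a linear taper to
  zero at distance d via thinning.
* **Kataegis**: each breakpoint sparks a burst with p = 0.05; a burst walks
  `kataegis_size` = 6 positions from the breakpoint with gaps uniform on
  [1, 1000] bp in a random direction. Planted cluster coordinates go into
  the truth record. p and burst size are unconstrained by any reported
  value and were fixed once at plausible magnitudes.
* **Age/clock-like component** (off by default): age ~ U[40, 80] years and
  clock-like count α + β·age + N(0, σ²) with α = 200, β = 15/yr, σ = 30,
  placed uniformly and mirrored in SBS1/SBS5 metadata counts. It is off by
  default because uniformly placed clock SNVs dilute proximal-enrichment
  recovery; analyses of the age linkage switch it on explicitly.
* **Bases**: ref is A/T with probability `at_fraction` = 0.4 (most somatic
  substitutions sit at G:C pairs), alt uniform over the three alternatives.

Randomness: one master seed; sample i uses an independent stream derived
from (seed, 1, i) and cohort-level hotspot placement from (seed, 0), so any
sample regenerates in isolation and cohorts are byte-reproducible.

Truth records partition each tumor's SNVs into background/proximal/kataegis/
clock components and carry hotspots, breakpoints and planted clusters. Two
derived conditions matter for validation:

* **Null cohorts** set f = 1 *and* kataegis probability 0. Kataegis bursts
  are anchored at breakpoints, i.e. they are themselves breakpoint-proximal
  SNV induction; leaving them on would make the "null" reject almost always,
  and correctly so.
* **Sparse-background recovery** runs use λ = 1e-8/bp and dispersed SVs, so
  that the expected number of background SNVs within max_gap of a planted
  cluster is ≪ 1 per *cohort* (≈ 0.02 over ~400 clusters), making exact
  recovery of every planted cluster the correct expectation.
  `kataegis_contamination_bound` computes the per-cluster bound for any
  configuration.

What the generator does **not** emulate: sequence context (no reference
genome, hence no trinucleotide channels, no APOBEC TpC strand coordination),
copy-number states and subclonal structure, chromosome-specific mutation
rates, unmappable regions (the mask machinery exists but simulated genomes
have none), and inter-tumor heterogeneity in f or λ. Passing recovery tests
therefore demonstrate correctness of the measurement machinery under the
stated model, not robustness to every property of real tumor genomes.

## Numerical policies and degenerate inputs

* Window boundaries are inclusive at exactly distance R; merged windows are
  half-open after clipping to the chromosome.
* The naive expectation multiplies before dividing so integer-valued cases
  stay exact in floating point.
* Zero-variance t-tests return degenerate flags, not exceptions; relative
  rates are None (not NaN) when the expectation is zero, and the CLI reports
  them as undefined without crashing.
* Empty peak lists yield an explicit empty echo profile; scoring one raises.
* Track bin arrays are ceil(length/bin) long; the terminal bin's reported
  center is clipped to the chromosome end.

## Known limitations

* The Fisher z comparison ignores the dependence between correlations
  sharing a variable (flagged in output); a Steiger-type test would need the
  third inter-correlation.
* Peak calling has no significance control — it is a descriptive threshold
  rule, faithful to the fold-over-average definition.
* The naive expectation is reported for fidelity but is not a calibrated
  null when breakpoint windows overlap appreciably; inference should use the
  corrected expectation (the default study analyses do).
* Mutational-signature decomposition, survival analysis, transcript-level
  annotation and Circos rendering are out of scope; `write_snv_subset`
  exports SV-proximal SNVs so external signature tools can consume them.
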