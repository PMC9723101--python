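# svecho

Co-localization analysis of somatic structural variants (SVs) and
single-nucleotide variants (SNVs) in tumor genomes.

In many cancers the SNV burden is far too high to be explained by replication
errors alone, and the excess mutations are not spread uniformly: they
concentrate around SV breakpoints, on two very different length scales.
Kataegis — localized hypermutation — puts several SNVs within a kilobase,
while a broader elevation of SNV density extends 0.1–10 Mb around SV sites, so
that smoothed SNV profiles look like *echoes* of the SV peaks. `svecho` gives
cancer-genomics analysts a tested toolkit for quantifying both phenomena from
ordinary somatic call sets (per-sample VCF for SNVs, BEDPE for SVs, a
chromosome-sizes table), plus a synthetic tumor-cohort simulator with known
ground truth so every stage of the pipeline can be validated by parameter
recovery.

## The statistics at the core

**Breakpoint-proximal enrichment.** For a tumor with $n_{\mathrm{SNV}}$ SNVs,
$n_{\mathrm{SV}}$ SV events and genome length $L$, the number of SNVs expected
by chance within $\pm R$ of the SV sites is

$$E = \frac{n_{\mathrm{SNV}}}{L} \times n_{\mathrm{SV}} \times 2R .$$

The observed count $O$ is the number of *distinct* SNVs within $R$ (inclusive)
of at least one breakpoint, and $O/E$ is the relative SNV rate near SV sites.
Because this naive footprint $2R\,n_{\mathrm{SV}}$ ignores window overlap and
the two breakpoints per SV, `svecho` also computes an overlap-corrected
expectation $E^{*} = (n_{\mathrm{SNV}}/L)\,|W|$, where $|W|$ is the merged
length of all $\pm R$ windows; $E^{*}$ has an exactly calibrated null
($O \sim \mathrm{Binomial}(n_{\mathrm{SNV}}, |W|/L)$ under uniform placement).
Cohort-level enrichment is tested with a paired t-test of $O$ vs $E$ across
tumors, or a one-sample t-test of $\ln(O/E)$ against 0.

**Kataegis.** A cluster is a maximal run of $\ge 3$ SNVs whose consecutive
gaps are each $\le 1$ kb (chain rule; a strict fixed-window variant is
available). Rainfall data (distance of each SNV to its predecessor) feed a
Welch t-test comparing log10 inter-SNV distances between SV-high and SV-low
genomic bins.

**Echo profiles.** Variant positions are counted in 1 Mb bins, smoothed with
an 11-bin centered moving average (a 10 Mb window), and SV peaks are called as
strict local maxima at least 2-fold (or 5-fold) above the genomic average. The
smoothed SNV signal is superimposed across peaks over ±15 Mb flanks; the echo
score is the central (±1 Mb) profile mean divided by the SNV genomic average,
with a per-chromosome rotation permutation null.

Classical supporting statistics (Pearson r with its t-test, Fisher r-to-z
comparison of two correlations, Welch/paired t-tests, OLS slopes, and
normalization of signature counts by the clock-like SBS1+SBS5 burden) live in
`svecho.stats`.

## Worked example

Simulate a small cohort (three 50 Mb chromosomes, ~20 SV events per tumor
clustered in three recurrent hotspots, background SNV rate $10^{-5}$/bp, and a
planted threefold SNV-rate elevation within 1 Mb of every breakpoint), then
measure the enrichment back:

```sh
svecho simulate --out-dir cohort --n-samples 8 --seed 11
svecho enrich --cohort-dir cohort --out-dir results --expectation corrected
```

```
Cohort SV-proximal SNV enrichment
================================================
samples:            8
range (±bp):        1000000
SV site unit:       event
expectation basis:  corrected
mean relative rate: 2.846
test mode:          paired_counts
t statistic:        11.29
two-sided p:        9.549e-06
```

The mean relative rate recovers the planted factor 3 (attenuated slightly
because the proximal extra SNVs also inflate each tumor's total, and hence the
expectation), and the paired t-test across the 8 tumors is decisive. The
per-sample table written to `results/enrichment.tsv` carries both expectations;
note how the naive formula's relative rates scatter around 0.5–1.5 here —
with 40 breakpoints clustered in a few hotspots on a 150 Mb genome its
footprint is far from the merged window length, which is exactly why the
corrected expectation exists.

The echo analysis on the same cohort:

```sh
svecho echo --cohort-dir cohort --out-dir results
```

```json
{
 "n_samples": 8,
 "n_peaks": 24,
 "fold_threshold": 2.0,
 "flank_bp": 15000000,
 "score": 1.3314879712258316,
 "snv_genomic_average": 11.498804242825074
}
```

24 SV peaks were called at the 2-fold threshold across the cohort, and the
SNV signal centered on them sits 33% above the genomic average — the echo.
`svecho kataegis`, `svecho correlate`, `svecho tallies` and `svecho report`
cover the rainfall/cluster, cohort-correlation, per-gene tally and
summary-merging stages; every command accepts a YAML config with flag
override precedence and writes a manifest echoing its effective
configuration.

The same machinery is available as a library; the cohort enrichment analysis
follows the model/results idiom:

```python
from svecho import CohortEnrichment
model = CohortEnrichment({sid: (snvs, svs) for ...}, range_bp=1_000_000)
res = model.fit(mode="paired_counts", expectation="corrected")
print(res.summary())
```

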