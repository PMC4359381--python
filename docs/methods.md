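# Methods

## Model and procedure

The detector assumes that, absent locus preference, each clone's mutations
fall independently and uniformly over the `M` mutable motif sites of its
deaminase class (WRC for AID-like, YCC for APOBEC3G-like, any C for the
EMS control; sites are counted on both strands at the mutable cytosine,
so a plus-strand G over a minus-strand C is a site at that coordinate).
Pooled counts in overlapping 150 bp windows are compared with
`Binomial(n = round(n̄), p = n̄/M)`, `n̄` the mean per-clone load. The
99th-percentile threshold `k*` is the smallest `k` with `CDF(k) ≥ 0.99`;
significance is strict exceedance (`count > k*`). Significant windows
merge when their intervals overlap or abut with zero gap. Merged regions
are refined over their *mutated* bases only: the 25th percentile (linear
interpolation), mean and population SD, and median are computed once over
the region's mutated-base counts, then bases failing any of the three
printed rules (count < Q25; count < mean − 4·SD; count = 1 when the
median exceeds 1) are dropped jointly, and the span snaps to the
surviving extremes. A refined region is a high-confidence MEL when it
holds ≥ 6 mutations (i.e. "more than 5") contributed by ≥ 4 distinct
clones, both computed over surviving bases. All stages are deterministic;
output is sorted by (chromosome, start).

Including unmutated bases in the refinement statistics would drive Q25
and the median to zero on any region wider than a few dozen bases and
make two of the three rules vacuous, so the mutated-bases-only reading is
the default; a switch (`refine_include_zeros`) exposes the alternative.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_size` | 150 bp | pooling window |
| `window_step` | 1 bp | exhaustive overlapping windows; cheap at yeast scale |
| `null_percentile` | 0.99 | binomial exceedance threshold |
| `refine_count_percentile` | 25 | per-base trim quantile over mutated bases |
| `refine_sd_multiplier` | 4 | mean − 4·SD trim (population SD; rarely active) |
| `final_min_mutations` | 6 | "more than 5 mutations" |
| `final_min_transformants` | 4 | independent clones supporting a MEL |
| `hom_af_threshold` | 0.8 | allele frequency at/above which a diploid call is homozygous |

The high-confidence SNV filter keeps records with caller score > 50
(strict), allele frequency ≥ 0.3, read depth ≥ 4 in the reference *or*
the sample (the criterion is printed disjunctively; the permissive rDNA
profile, which demands depth 10 "in both", shows the conjunctive form is
marked explicitly when intended), mean read-position fraction ≥ 0.1, mean
distance-to-3′ ≥ 0.1, mean base quality ≥ 30 and mean read length > 50 bp
(strict). Zygosity is taken from an explicit caller genotype when
present, otherwise from allele frequency ≥ 0.8 — in a diploid, an allele
frequency near 1 means both alleles carry the change.

Promoter windows are [TSS − 500, TSS + 50] on the feature strand for
mRNA/snoRNA/snRNA genes (the repeatedly used "550 bp" total; note that in
1-based inclusive coordinates this interval spans 551 positions — the
550 figure corresponds to `end − start`) and a 550 bp window centred on
the gene midpoint for tRNAs, whose internal RNAP III promoters sit inside
the gene body. Intronic snoRNAs inherit the host gene's promoter;
polycistronic snoRNA clusters get a single promoter at the cluster's
5′-most TSS. Windows truncated by a chromosome end are kept and flagged.

## Operating regime of the binomial null

The null's mean is `n̄²/M` per window, but the *data* are pooled over `K`
clones, so a background window carries on average `μ_pool = K·n̄·L/G`
mutations (`L` window size, `G` genome length). The detector is
discriminative only while `μ_pool` sits below the threshold `k*`; since
`k*` tracks `n̄²/M = n̄·(L·d)/L·...` with `d = M/G` the motif-site
density, the two scales balance exactly when `n̄ ≈ K·L·d`. The sequenced
diploid screens sit almost on this balance (n̄ ≈ 800, K = 50, L = 150,
d ≈ 0.1 on a 12.1 Mb genome) with both means near 0.5, which is why the
procedure separates promoter hotspots from background there.

On the 1 Mb toy genome the generator's default ("stated") loads of ~400
SNVs per clone put `μ_pool ≈ 1.7–1.8` *above* `k*`'s regime: ~27% of
class-C window starts exceed threshold on uniform data, merged background
regions easily clear the final filter, and the uniform control emits
hundreds of spurious MELs (the observed counts then match the
simulated-load expectation for every dataset — the detector reports
noise). The `density_matched()` configuration (λ = 50 per clone per Mb,
matching the screens' per-bp density; hotspot rate multiplier 150, giving
per-hotspot pooled loads of ~15–19 against the ~14 mutations per observed
MEL) restores the balance: planted hotspots are recovered with
sensitivity ~1.0, false-discovery fraction ~0–0.05, median boundary
offsets ~10 bp, and the uniform control yields a handful of MELs equal to
its simulated expectation. `analysis/03_recovery_calibration.py`
measures both regimes side by side.

## The synthetic generator

It emulates the statistical structure the analysis assumes: i.i.d.
genomes at GC 0.38 split over four chromosomes with a yeast-like size
spread (400/300/200/100 kb — at least three chromosomes are needed for
load–length rank correlations); non-overlapping gene bodies of five
classes with random strands, strand-aware TSSs, TATA elements 30–120 bp
upstream of mRNA TSSs and log-normal transcription rates; 30 clones with
Poisson loads placed on motif sites of the declared class on both
strands, sampled without replacement per clone (weighted
reservoir/Gumbel top-k), hotspot windows of 110 bp centred ~40 bp
upstream of the TSS of randomly chosen mRNA genes at an elevated per-site
rate; fixed C→T (G→A) substitutions as in a uracil-glycosylase-deficient
background; synthetic caller statistics that pass the high-confidence
profile; and a per-mutation second-allele probability (default 0.05) to
exercise the biallelic statistics.

What it does **not** emulate: real promoter sequence composition
(poly-dA:dT nucleosome exclusion), transcription-coupled strand
asymmetries, selection (e.g. canavanine-resistance loci), copy-number or
repeat structure (rDNA), alignment and calling artefacts, or clustered
kataegic mutations. Passing tests therefore demonstrate the statistical
machinery — null calibration, interval arithmetic, normalisations,
recovery scoring — not robustness to those properties of real data.

## Numerical choices

- `k*` via `scipy.stats.binom.cdf` (regularised incomplete beta — exact),
  with an explicit search enforcing `CDF(k*−1) < q ≤ CDF(k*)`; tests
  cross-check by direct pmf summation.
- Window counts by per-base `bincount` + prefix sums; the final partial
  windows of each chromosome are counted.
- Percentiles by numpy's linear interpolation; SDs are population SDs.
- Merging: significant windows merge iff start difference ≤ L (equivalent
  to interval overlap-or-abut for truncated end windows too).
- Nearest-anchor ties: prefer the feature on whose strand the mutation is
  downstream, then the smaller feature id. tRNA midpoints: floor of the
  mean. Location classes resolve overlap as promoter > ARS > gene body >
  intergenic.
- Empirical bootstrap p-values use the +1 correction; fragment placement
  draws the chromosome with probability proportional to its number of
  valid start positions, then a uniform start.
- Rank-sum comparisons use the exact null for tie-free samples up to
  n = 25 per group, midrank/normal approximation otherwise.
- Single-base MELs are excluded from strand-bias summaries (sentinel
  `None`).
- All randomness flows through a single seeded `numpy` Generator per run.

## Open design choices

- Plus- and minus-strand sites at the same coordinate are counted as two
  sites in `M` (a coordinate can host one site per strand).
- The final transformant threshold follows the operational definition
  (≥ 4); the alternative reading (≥ 3) is reachable via
  `final_min_transformants`.
- Biallelic targeting of a MEL in a genome uses ≥ 1 homozygous mutation
  or, as a proxy in the absence of phasing, ≥ 2 heterozygous mutations in
  the same MEL; a strict hom-only mode is provided.
- "Nearest TSS" competition defaults to mRNA genes only; other classes
  can be included via the `classes` argument.
- Non-clonal deduplication (variants shared across more than half the
  clones treated as pre-existing) is available as an optional pass
  (`drop_shared`).

## Known limitations

The binomial null ignores window-local motif content (it is global, as
printed); heavily motif-dense windows are slightly anti-conservative.
The detector's specificity degrades sharply once pooled density crosses
the null threshold (see "Operating regime") — for datasets much denser
than the screens it models, window counts should be referred to a pooled
null instead. MEL refinement assumes per-base counts are comparable
across a region; systematic coverage variation would bias the trim. The
VCF reader maps a SomaticSniper-style annotation set; other callers need
a field mapping or the TSV dialect.
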