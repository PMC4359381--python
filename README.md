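# melscan

Footprinting cytidine-deaminase activity on genomes by detecting
**mutation-enriched loci (MELs)** — narrow windows, roughly 70–150 bp wide,
where somatic C:G mutations pooled across independent clones pile up far
beyond what a random mutagenesis model allows. In budding yeast, AID-like
(WRC-context) and APOBEC3G-like (YCC-context) deaminases focus their
off-target mutations on such loci at the RNA-polymerase pre-initiation
region of active promoters, on both DNA strands, while a chemical mutagen
(EMS, any-C) control mutates uniformly. The package is written for people
analysing mutator-strain sequencing screens: per-clone SNV catalogs in,
refined MEL intervals, enrichment statistics and promoter/TSS metaprofiles
out.

## The statistic at the core

Mutations from all clones of a dataset are pooled and counted in
overlapping windows of `L = 150` bp (step 1 bp). With `n̄` the average
number of mutations per clone and `M` the genome-wide number of *mutable
motif* sites for the dataset's deaminase class (WRC, YCC or any C, counted
on both strands at the cytosine position), window counts are referred to
the null

&nbsp;&nbsp;&nbsp;&nbsp;`K ~ Binomial(n = round(n̄), p = n̄ / M)`,

and a window is significant when its pooled count strictly exceeds `k*`,
the smallest `k` with `CDF(k) ≥ 0.99` (exact CDF, no normal
approximation). Significant windows that overlap or abut are merged; each
merged region is trimmed to its reproducibly mutated bases (drop bases
with per-base count below the 25th percentile of the region's
mutated-base counts, below mean − 4·SD, and singleton bases when the
median count exceeds one); and only regions with **more than 5 mutations
from at least 4 independent transformants** are reported as
high-confidence MELs.

Around the detector sit: Monte Carlo nulls (random equal-size fragment
placement for feature-overlap expectations, simulated equal-load catalogs
for expected MEL counts), promoter definitions (500 bp upstream / 50 bp
downstream of the TSS; 550 bp centred on tRNA gene midpoints),
TSS/TTS/TATA-anchored normalised density profiles, down-sampling
bootstraps for promoter mutation frequencies, strand-bias and
trinucleotide-context signatures, and a synthetic-data generator with
planted-hotspot ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (1 Mb four-chromosome genome, 30 clones per dataset; seed 1):

```bash
python analysis/01_simulate_study.py
python analysis/02_call_mels.py
python analysis/03_recovery_calibration.py
python analysis/04_feature_association.py
python analysis/05_signatures.py
```

`02_call_mels.py` prints (abridged):

```
 regime  dataset  mels  expected_mels_simulated  pct_mutations_in_mels  pct_genome_covered  median_width_bp
matched AID_like    20                      0.7                   21.2                0.21               93
matched A3G_like    17                      0.7                   22.3                0.10               46
matched EMS_like     6                      6.0                    2.6                0.48              746
 stated AID_like   229                    251.0                   17.3                3.53              142
 stated EMS_like   723                    719.3                   60.4               30.50              357
```

In the `matched` regime — per-clone loads scaled to the sequenced screens'
per-bp density (~50 SNVs per clone per Mb) — the detector recovers all 20
planted promoter hotspots as MELs holding 21% of all mutations in 0.21%
of the genome, while the uniform EMS-like control yields 6 MELs, exactly
its simulated-load expectation (i.e. no signal above noise). In the
`stated` regime (~400 SNVs per clone per Mb) the pooled window counts
exceed the binomial threshold everywhere and observed counts match the
simulated expectation for *all* datasets: the null is no longer
discriminative at that density. `03_recovery_calibration.py` quantifies
this (matched: sensitivity 1.0, false-discovery fraction 0.01, median
boundary offset ~9 bp; stated: sensitivity 1.0 but false-discovery 0.91),
and `docs/methods.md` derives the operating-regime condition.

`04_feature_association.py` shows the localisation signal: every AID-like
MEL overlaps a promoter window against a Monte Carlo expectation of 8.7%
(empirical p = 0.001), mutated promoters differ from unmutated ones at
p < 1e-19 (rank-sum), per-chromosome loads track chromosome length
(Spearman ρ ≈ 0.78), and MELs capture most biallelically mutated loci.
`05_signatures.py` confirms the EMS-like control hits WRC context at the
genomic share of C sites (30.8% vs 31.1%) and that motif spacing inside
MELs matches the genome-wide distribution — hotspots are not explained by
motif clustering.

The same machinery is scriptable through a CLI (`melscan run
config.yaml`, plus `call-mels`, `simulate`, `profile`, `signature`,
`enrich` subcommands) for FASTA genomes with VCF/TSV mutation catalogs
and GFF3/BED/TSV annotations.

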