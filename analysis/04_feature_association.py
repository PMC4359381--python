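"""Relate mutations and MELs to genomic features (matched-density study).

Outputs, all under ``results/``:

* ``mel_location.tsv``       — fraction of MELs overlapping promoters /
  gene bodies / ARS / intergenic space, with the Monte Carlo expectation
  from 1000 cycles of randomly re-placed equal-size fragments.
* ``mutation_location.tsv``  — single-label classification counts for all
  mutations of each dataset.
* ``profiles/*.tsv``         — normalised mutation density against the
  distance to the nearest mRNA TSS, TTS and TATA element, and against the
  tRNA gene midpoint.
* ``promoter_frequency.tsv`` — bootstrap-mean mutation counts per promoter
  after down-sampling every dataset to half the EMS-like dataset's size,
  grouped by promoter class.
* ``chromosome_load.tsv``    — Spearman correlation of per-clone
  per-chromosome loads with chromosome length (mutations at C and at G).
* ``biallelic.tsv``          — per-genome biallelic-MEL fraction and the
  share of homozygous mutations captured by MELs.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

from melscan import (
    FragmentSet,
    LocationClassifier,
    biallelic_mel_stats,
    bootstrap_overlap,
    call_mels,
    chromosome_load_correlation,
    classify_catalog,
    define_promoters,
    density_profile,
    group_compare,
    promoter_mutation_frequency,
)

sys.path.insert(0, str(Path(__file__).resolve().parent))
sim = importlib.import_module("01_simulate_study")

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
PROFILES = RESULTS / "profiles"

MOTIF_OF = {"AID_like": "WRC", "A3G_like": "YCC", "EMS_like": "C"}


def main():
    RESULTS.mkdir(exist_ok=True)
    PROFILES.mkdir(exist_ok=True)
    study = sim.build_all()["matched"]
    genome, features = study.genome, study.features
    promoters = define_promoters(features, chrom_lengths=genome.chrom_lengths)
    clf = LocationClassifier(features, promoters)

    mel_rows, mut_rows, corr_rows, bi_rows = [], [], [], []
    all_mels = {}
    for label, cat in study.catalogs.items():
        mels = call_mels(cat, genome, study.motifs[MOTIF_OF[label]])
        all_mels[label] = mels

        # --- MEL location classes + Monte Carlo promoter-overlap null
        if mels:
            labels = pd.Series(
                [clf.classify_interval(m.chrom, m.start, m.end) for m in mels]
            ).value_counts()
            frag = FragmentSet([(m.chrom, m.start, m.end) for m in mels])
            ov = bootstrap_overlap(
                frag,
                [(w.chrom, w.start, w.end) for w in promoters],
                genome,
                n_cycles=1000,
                seed=sim.SEED + 31,
            )
            mel_rows.append(
                {
                    "dataset": label,
                    "n_mels": len(mels),
                    "frac_promoter": round(labels.get("promoter", 0) / len(mels), 3),
                    "frac_gene_body": round(labels.get("gene_body", 0) / len(mels), 3),
                    "frac_ARS": round(labels.get("ARS", 0) / len(mels), 3),
                    "frac_intergenic": round(
                        labels.get("intergenic", 0) / len(mels), 3
                    ),
                    "promoter_overlap_observed": round(ov.observed_fraction, 3),
                    "promoter_overlap_simulated_mean": round(
                        ov.simulated_mean_fraction, 3
                    ),
                    "promoter_overlap_simulated_sd": round(ov.simulated_sd, 4),
                    "p_enrichment": round(ov.empirical_p, 4),
                }
            )

        # --- per-mutation classification
        counts = classify_catalog(cat, features, promoters)
        mut_rows.append({"dataset": label, **counts.to_dict()})

        # --- anchor-relative density profiles
        for anchor, classes, rng_bp in (
            ("TSS", ("mRNA",), 500),
            ("TTS", ("mRNA",), 500),
            ("TATA", ("mRNA",), 500),
            ("midpoint", ("tRNA",), 250),
        ):
            prof = density_profile(cat, features, anchor, rng_bp, classes=classes)
            tag = "tRNA_mid" if anchor == "midpoint" else anchor
            prof.to_frame().to_csv(
                PROFILES / f"{label}.{tag}.tsv", sep="\t", index=False
            )

        # --- chromosome load vs length
        rho = chromosome_load_correlation(cat, genome)
        corr_rows.append(
            {
                "dataset": label,
                "spearman_rho_at_C": round(rho["C"][0], 3),
                "spearman_rho_at_G": round(rho["G"][0], 3),
            }
        )

        # --- biallelic targeting
        stats = biallelic_mel_stats(cat, mels)
        bi_rows.append(
            {
                "dataset": label,
                "per_genome_biallelic_fraction": round(
                    stats.per_genome_biallelic_fraction, 3
                ),
                "hom_in_mel_fraction": round(stats.hom_in_mel_fraction, 3),
                "n_hom": stats.n_hom,
            }
        )

    pd.DataFrame(mel_rows).to_csv(RESULTS / "mel_location.tsv", sep="\t", index=False)
    pd.DataFrame(mut_rows).to_csv(
        RESULTS / "mutation_location.tsv", sep="\t", index=False
    )
    pd.DataFrame(corr_rows).to_csv(
        RESULTS / "chromosome_load.tsv", sep="\t", index=False
    )
    pd.DataFrame(bi_rows).to_csv(RESULTS / "biallelic.tsv", sep="\t", index=False)

    # --- promoter mutation frequency with EMS-half down-sampling
    table = promoter_mutation_frequency(
        list(study.catalogs.values()),
        promoters,
        reference_label="EMS_like",
        n_bootstraps=1000,
        seed=sim.SEED + 47,
    )
    out = table.table.copy()
    out["class"] = table.promoter_class
    out.to_csv(RESULTS / "promoter_frequency.tsv", sep="\t")

    # hotspot-bearing vs other mRNA promoters, rank-sum on bootstrap means
    aid = table.table["AID_like"]
    mrna_ids = table.promoter_class[table.promoter_class == "mRNA"].index
    hot = aid[mrna_ids][aid[mrna_ids] > 0]
    cold = aid[mrna_ids][aid[mrna_ids] == 0]
    if len(hot) and len(cold):
        stat, p = group_compare(hot.to_numpy(), cold.to_numpy() + 1e-12)
        print(f"mutated vs unmutated mRNA promoters (AID-like): U={stat:.0f} p={p:.2g}")

    for name in ("mel_location", "mutation_location", "chromosome_load", "biallelic"):
        print(f"\n== {name} ==")
        print(pd.read_csv(RESULTS / f"{name}.tsv", sep="\t").to_string(index=False))


if __name__ == "__main__":
    main()
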