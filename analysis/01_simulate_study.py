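"""Generate the synthetic mutagenesis studies used by the downstream analyses.

Two studies over a 1 Mb four-chromosome toy genome (GC 0.38, 100 mRNA genes,
20 tRNAs, snoRNA/snRNA/ARS annotations, 30 clones each):

* ``stated``  — heavy per-clone loads (Poisson lambda = 400, hotspot rate
  multiplier 25): the pooled mutation density deliberately matches the
  generator's default conditions.
* ``matched`` — per-clone loads scaled to the sequenced screens' per-bp
  density (lambda = 50 per Mb, i.e. ~600 SNVs over a 12 Mb genome; rate
  multiplier 150, giving per-hotspot pooled loads near the ~14 mutations
  per observed MEL).

Each study has an AID-like (WRC), an A3G-like (YCC) and a uniform EMS-like
(any C) dataset plus planted-hotspot truth.  Small summaries go to
``results/``; full genomes and catalogs to ``scratch/`` (regenerable).
"""

import sys
from pathlib import Path

import pandas as pd

from melscan import SyntheticSpec, build_study

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "study"

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

REGIMES = {
    "stated": SyntheticSpec(),
    "matched": SyntheticSpec.density_matched(),
}


def build_all(seed: int = SEED):
    return {name: build_study(spec, seed=seed) for name, spec in REGIMES.items()}


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rows = []
    for regime, study in build_all().items():
        study.genome.write_fasta(SCRATCH / f"{regime}.genome.fa")
        for label, cat in study.catalogs.items():
            cat.write_tsv(SCRATCH / f"{regime}.{label}.mutations.tsv")
            truth = study.truths[label]
            counts = truth.label_counts()
            rows.append(
                {
                    "regime": regime,
                    "dataset": label,
                    "clones": cat.n_clones,
                    "total_mutations": cat.total_mutations,
                    "mean_load": round(cat.mean_load, 1),
                    "hotspot_mutations": counts["hotspot"],
                    "hotspot_fraction": round(
                        counts["hotspot"] / max(cat.total_mutations, 1), 4
                    ),
                }
            )
        with open(SCRATCH / f"{regime}.hotspots.bed", "w") as fh:
            for i, (c, s, e) in enumerate(study.hotspots):
                fh.write(f"{c}\t{s - 1}\t{e}\thotspot_{i}\t0\t.\n")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "study_summary.tsv", sep="\t", index=False)
    print(f"seed {SEED}: two regimes x three datasets generated")
    print(df.to_string(index=False))
    print(f"full catalogs under {SCRATCH}/")


if __name__ == "__main__":
    main()
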