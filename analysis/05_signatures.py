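"""Sequence-context signatures and motif statistics (matched-density study).

Writes, under ``results/``:

* ``signature_<dataset>.tsv`` — oriented base-frequency matrices (5 bp
  flanks) around mutated cytosines; the AID-like dataset shows the W/R
  preference at offsets -2/-1, the A3G-like dataset the Y/C preference,
  and the EMS-like control the genomic background.
* ``motif_fractions.tsv``     — fraction of each dataset's mutations in
  WRC / YCC / any-C context, against the genome-wide share of class-C
  sites in those contexts.
* ``strand_bias.tsv``         — per-MEL fraction of mutations at plus-
  strand Cs (single-base MELs excluded).
* ``motif_distances.tsv``     — quartiles of nearest-neighbour motif
  spacing inside MELs versus genome-wide.
"""

import importlib
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from melscan import (
    call_mels,
    context_matrix,
    mel_strand_bias,
    motif_distance_distribution,
    motif_fraction,
)

sys.path.insert(0, str(Path(__file__).resolve().parent))
sim = importlib.import_module("01_simulate_study")

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

MOTIF_OF = {"AID_like": "WRC", "A3G_like": "YCC", "EMS_like": "C"}


def main():
    RESULTS.mkdir(exist_ok=True)
    study = sim.build_all()["matched"]
    genome = study.genome

    frac_rows, bias_rows, dist_rows = [], [], []
    genome_share = {
        mc: study.motifs[mc].total_sites / study.motifs["C"].total_sites
        for mc in ("WRC", "YCC", "C")
    }
    for label, cat in study.catalogs.items():
        ctx = context_matrix(cat, genome, flank_size=5)
        ctx.to_frame().round(4).to_csv(RESULTS / f"signature_{label}.tsv", sep="\t")

        row = {"dataset": label}
        for mc in ("WRC", "YCC", "C"):
            row[f"frac_{mc}"] = round(motif_fraction(cat, genome, mc), 3)
            row[f"genome_share_{mc}"] = round(genome_share[mc], 3)
        frac_rows.append(row)

        mels = call_mels(cat, genome, study.motifs[MOTIF_OF[label]])
        for i, m in enumerate(mels):
            b = mel_strand_bias(m)
            if b is not None:
                bias_rows.append(
                    {"dataset": label, "mel": i, "fraction_at_c": round(b, 3)}
                )
        if mels and label != "EMS_like":
            motifs = study.motifs[MOTIF_OF[label]]
            inside = motif_distance_distribution(
                motifs, intervals=[(m.chrom, m.start, m.end) for m in mels]
            )
            genome_wide = motif_distance_distribution(motifs)
            for scope, d in (("MELs", inside), ("genome", genome_wide)):
                q1, q2, q3 = np.percentile(d, [25, 50, 75])
                dist_rows.append(
                    {
                        "dataset": label, "scope": scope, "n_gaps": len(d),
                        "q25_bp": q1, "median_bp": q2, "q75_bp": q3,
                    }
                )

    pd.DataFrame(frac_rows).to_csv(
        RESULTS / "motif_fractions.tsv", sep="\t", index=False
    )
    pd.DataFrame(bias_rows).to_csv(RESULTS / "strand_bias.tsv", sep="\t", index=False)
    pd.DataFrame(dist_rows).to_csv(
        RESULTS / "motif_distances.tsv", sep="\t", index=False
    )

    print(pd.DataFrame(frac_rows).to_string(index=False))
    if bias_rows:
        bias = pd.DataFrame(bias_rows)
        print("\nmedian per-MEL fraction of mutations at plus-strand C:")
        print(bias.groupby("dataset")["fraction_at_c"].median().to_string())
    print("\nmotif spacing (bp):")
    print(pd.DataFrame(dist_rows).to_string(index=False))


if __name__ == "__main__":
    main()
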