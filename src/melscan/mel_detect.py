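"""Mutation-Enriched Locus (MEL) detection.

The detector pools SNVs from all clones of a dataset, counts them in
overlapping fixed-width windows, and flags windows whose count exceeds the
99th percentile of a binomial null.  The null treats a window as a draw of
``n`` trials (the average per-clone mutation load, rounded) with success
probability ``n_bar / M`` where ``M`` is the genome-wide number of mutable
motif sites for the dataset's deaminase class.  Flagged windows are merged,
each merged region is trimmed to its reproducibly mutated bases, and only
regions with more than five mutations contributed by at least four
independent transformants are reported as high-confidence MELs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genome_io import GenomeIndex, MotifIndex
from .variant_ingest import MutationCatalog


@dataclass(frozen=True)
class MELParams:
    """Tunable parameters of the MEL detector (defaults follow the method)."""

    window_size: int = 150          # L, bp
    window_step: int = 1            # s, bp; 1 = exhaustive overlapping windows
    null_percentile: float = 0.99
    refine_count_percentile: float = 25.0   # Q25 over mutated-base counts
    refine_sd_multiplier: float = 4.0
    final_min_mutations: int = 6            # "more than 5"
    final_min_transformants: int = 4
    refine_include_zeros: bool = False      # Q25/SD over all bases, not just mutated

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (1 <= self.window_step <= self.window_size):
            raise ValueError("window_step must be in [1, window_size]")
        if not (0.0 < self.null_percentile < 1.0):
            raise ValueError("null_percentile must be in (0, 1)")


@dataclass
class BinomialNull:
    """Exact binomial window-count null and its percentile threshold.

    A window is significant when its pooled count is *strictly greater*
    than ``threshold_count`` (k*), the smallest k with CDF(k) >= percentile.
    """

    n: int
    p: float
    threshold_count: int
    mean_load: float
    total_motifs: int
    percentile: float = 0.99


@dataclass
class WindowCountTrack:
    """Pooled mutation counts for every window start, per chromosome."""

    window_size: int
    step: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def starts(self, chrom: str) -> np.ndarray:
        return np.arange(1, self.chrom_lengths[chrom] + 1, self.step, dtype=np.int64)


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int


@dataclass
class MEL:
    """A refined mutation-enriched locus."""

    chrom: str
    start: int
    end: int
    per_base_counts: dict[int, int]
    mutation_total: int
    transformant_count: int
    clone_ids: frozenset
    n_at_c: int                      # mutations recorded at a plus-strand C
    n_at_g: int                      # mutations recorded at G (minus-strand C)
    dataset_label: str = "dataset"

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def count_windows(
    catalog: MutationCatalog, genome: GenomeIndex, params: MELParams
) -> WindowCountTrack:
    """Pooled mutation count in every window of ``window_size`` bp.

    Window starts are 1, 1+s, 1+2s, ... up to the chromosome length; the
    final windows are truncated at the chromosome end but still counted.
    """
    track = WindowCountTrack(
        window_size=params.window_size,
        step=params.window_step,
        chrom_lengths=dict(genome.chrom_lengths),
    )
    by_chrom = catalog.positions_by_chrom()
    L, s = params.window_size, params.window_step
    for chrom, length in genome.chrom_lengths.items():
        starts = np.arange(1, length + 1, s, dtype=np.int64)
        sub = by_chrom.get(chrom)
        if sub is None or len(sub) == 0:
            track.counts[chrom] = np.zeros(len(starts), dtype=np.int32)
            continue
        pos = sub["pos"].to_numpy()
        if pos.min() < 1 or pos.max() > length:
            raise ValueError(
                f"mutation outside chromosome bounds on {chrom} "
                f"(length {length}, positions {pos.min()}..{pos.max()})"
            )
        base = np.bincount(pos, minlength=length + 1)[1:]
        prefix = np.concatenate(([0], np.cumsum(base)))
        ends = np.minimum(starts + L - 1, length)
        track.counts[chrom] = (prefix[ends] - prefix[starts - 1]).astype(np.int32)
    # positions on chromosomes absent from the genome are an error
    unknown = set(by_chrom) - set(genome.chrom_lengths)
    if unknown:
        raise ValueError(f"mutations on unknown chromosomes: {sorted(unknown)}")
    return track


def binomial_threshold(n: int, p: float, percentile: float = 0.99) -> int:
    """Smallest k with Binomial(n, p) CDF(k) >= percentile, by exact CDF.

    ``binom.cdf`` evaluates the regularised incomplete beta function, an
    exact (non-approximated) form of the CDF; the search enforces the
    defining property CDF(k*-1) < percentile <= CDF(k*).
    """
    if n == 0 or p == 0.0:
        return 0
    kstar = int(binom.ppf(percentile, n, p))
    # ppf can land one off at CDF plateaus; enforce the defining property
    while kstar > 0 and binom.cdf(kstar - 1, n, p) >= percentile:
        kstar -= 1
    while binom.cdf(kstar, n, p) < percentile:
        kstar += 1
    return kstar


def fit_binomial_null(
    catalog: MutationCatalog, motifs: MotifIndex, params: MELParams
) -> BinomialNull:
    """Binomial(round(n_bar), n_bar / M) and its exact percentile threshold.

    A window is significant when its pooled count strictly exceeds the
    returned threshold.
    """
    M = motifs.total_sites
    if M == 0:
        raise ValueError("motif index is empty (M = 0)")
    n_bar = catalog.mean_load
    if n_bar > M:
        raise ValueError(f"mean load {n_bar} exceeds motif count {M} (p > 1)")
    n = int(round(n_bar))
    p = n_bar / M
    kstar = binomial_threshold(n, p, params.null_percentile)
    return BinomialNull(
        n=n, p=p, threshold_count=kstar, mean_load=n_bar, total_motifs=M,
        percentile=params.null_percentile,
    )


def flag_and_merge(
    track: WindowCountTrack, null: BinomialNull
) -> list[CandidateRegion]:
    """Merge significant windows (count > k*) that overlap or abut."""
    regions: list[CandidateRegion] = []
    L = track.window_size
    kstar = null.threshold_count
    for chrom in track.counts:
        counts = track.counts[chrom]
        starts = track.starts(chrom)
        sig = starts[counts > kstar]
        if len(sig) == 0:
            continue
        length = track.chrom_lengths[chrom]
        # consecutive significant windows merge when the next window starts
        # no later than one past the previous window's end, i.e. gap <= L
        breaks = np.flatnonzero(np.diff(sig) > L)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [len(sig) - 1]))
        for a, b in zip(run_starts, run_ends):
            regions.append(
                CandidateRegion(
                    chrom=chrom,
                    start=int(sig[a]),
                    end=int(min(sig[b] + L - 1, length)),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def refine_region(
    region: CandidateRegion,
    per_base_counts: dict[int, int],
    params: MELParams = MELParams(),
) -> Optional[tuple[int, int, np.ndarray]]:
    """Trim a candidate region to its reproducibly mutated bases.

    Unmutated residues are removed first; the quartile, standard-deviation
    and single-count rules are then evaluated over the mutated-base counts
    (all three statistics on the same original count set, drops applied
    jointly).  Returns ``(start, end, surviving_positions)`` or ``None`` if
    no base survives.
    """
    positions = np.array(sorted(per_base_counts), dtype=np.int64)
    if len(positions) == 0:
        return None
    counts = np.array([per_base_counts[p] for p in positions], dtype=np.float64)
    if params.refine_include_zeros:
        width = region.end - region.start + 1
        stat_counts = np.zeros(width, dtype=np.float64)
        stat_counts[positions - region.start] = counts
    else:
        stat_counts = counts
    q = np.percentile(stat_counts, params.refine_count_percentile)
    mean = stat_counts.mean()
    sd = stat_counts.std()  # population SD
    median = np.median(stat_counts)
    keep = (counts >= q) & (counts >= mean - params.refine_sd_multiplier * sd)
    if median > 1:
        keep &= counts != 1
    if not keep.any():
        return None
    surviving = positions[keep]
    return int(surviving.min()), int(surviving.max()), surviving


def final_filter(
    refined: list[tuple[CandidateRegion, tuple[int, int, np.ndarray]]],
    catalog: MutationCatalog,
    params: MELParams = MELParams(),
) -> list[MEL]:
    """Keep refined regions with enough mutations from enough transformants.

    Mutation and transformant totals are computed from surviving bases only.
    """
    by_chrom = catalog.positions_by_chrom()
    mels: list[MEL] = []
    for region, (start, end, surviving) in refined:
        sub = by_chrom.get(region.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [start, end + 1])
        block = sub.iloc[lo:hi]
        mask = np.isin(block["pos"].to_numpy(), surviving)
        block = block.iloc[mask]
        total = len(block)
        clones = frozenset(block["clone_id"])
        if total < params.final_min_mutations:
            continue
        if len(clones) < params.final_min_transformants:
            continue
        counts = block.groupby("pos").size()
        refs = block["ref"].to_numpy()
        mels.append(
            MEL(
                chrom=region.chrom,
                start=start,
                end=end,
                per_base_counts={int(p): int(c) for p, c in counts.items()},
                mutation_total=total,
                transformant_count=len(clones),
                clone_ids=clones,
                n_at_c=int((refs == "C").sum()),
                n_at_g=int((refs == "G").sum()),
                dataset_label=catalog.dataset_label,
            )
        )
    mels.sort(key=lambda m: (m.chrom, m.start))
    return mels


def call_mels(
    catalog: MutationCatalog,
    genome: GenomeIndex,
    motifs: MotifIndex,
    params: MELParams = MELParams(),
) -> list[MEL]:
    """Full deterministic MEL pipeline, sorted by (chrom, start)."""
    if catalog.total_mutations == 0:
        return []
    track = count_windows(catalog, genome, params)
    null = fit_binomial_null(catalog, motifs, params)
    candidates = flag_and_merge(track, null)
    by_chrom = catalog.positions_by_chrom()
    refined = []
    for region in candidates:
        sub = by_chrom.get(region.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [region.start, region.end + 1])
        if hi == lo:
            continue
        vals, counts = np.unique(pos[lo:hi], return_counts=True)
        per_base = dict(zip(vals.tolist(), counts.tolist()))
        result = refine_region(region, per_base, params)
        if result is not None:
            refined.append((region, result))
    return final_filter(refined, catalog, params)


EXCLUDED_SINGLE_BASE = None


def mel_strand_bias(mel: MEL) -> Optional[float]:
    """Fraction of a MEL's mutations recorded at C on the plus strand.

    Single-base MELs are excluded and yield ``None``.
    """
    if mel.width == 1:
        return EXCLUDED_SINGLE_BASE
    if mel.mutation_total == 0:
        return EXCLUDED_SINGLE_BASE
    return mel.n_at_c / mel.mutation_total


# ---------------------------------------------------------------------------
# output


def mels_to_frame(mels: list[MEL]) -> pd.DataFrame:
    rows = []
    for i, m in enumerate(mels):
        bias = mel_strand_bias(m)
        rows.append(
            {
                "name": f"{m.dataset_label}:{i}",
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "width": m.width,
                "mutation_total": m.mutation_total,
                "transformant_count": m.transformant_count,
                "fraction_at_c": bias,
                "fraction_at_g": (None if bias is None else 1.0 - bias),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "chrom", "start", "end", "width", "mutation_total",
            "transformant_count", "fraction_at_c", "fraction_at_g",
        ],
    )


def write_mels_bed(mels: list[MEL], path) -> None:
    """BED6: 0-based half-open, score = mutation total."""
    with open(path, "w") as fh:
        for i, m in enumerate(mels):
            fh.write(
                f"{m.chrom}\t{m.start - 1}\t{m.end}\t{m.dataset_label}:{i}\t"
                f"{m.mutation_total}\t.\n"
            )


def write_mels_tsv(mels: list[MEL], path) -> None:
    mels_to_frame(mels).to_csv(path, sep="\t", index=False)
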