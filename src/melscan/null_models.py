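"""Monte Carlo baselines for MEL statistics.

Two nulls are provided: random re-placement of observed fragments (for
feature-overlap expectations) and simulated mutation datasets of equivalent
per-clone load drawn uniformly over the mutable-motif index (for expected
MEL counts under random mutagenesis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import FeatureSet, GenomeIndex, MotifIndex
from .variant_ingest import MutationCatalog, MutationRecord

#: caller statistics attached to simulated records so they pass the
#: high-confidence profile unchanged
_SYNTHETIC_FIELDS = dict(
    caller_score=99.0,
    ref_read_count=20,
    sample_read_count=20,
    mean_read_position_fraction=0.5,
    mean_distance_to_3prime=0.5,
    mean_base_quality=35.0,
    mean_read_length=100.0,
)


@dataclass
class FragmentSet:
    """A set of genomic intervals, observed or randomised."""

    fragments: list[tuple[str, int, int]]
    source: str = "observed_MELs"   # or "simulated"
    cycle_id: int | None = None

    def __len__(self) -> int:
        return len(self.fragments)

    def lengths(self) -> list[int]:
        return sorted(e - s + 1 for _, s, e in self.fragments)


@dataclass
class OverlapSummary:
    observed_fraction: float
    simulated_mean_fraction: float
    simulated_sd: float
    n_cycles: int
    empirical_p: float            # enrichment: P(simulated >= observed)
    empirical_p_depletion: float  # depletion: P(simulated <= observed)


def simulate_random_fragments(
    template: FragmentSet,
    genome: GenomeIndex,
    rng: np.random.Generator,
    cycle_id: int | None = None,
) -> FragmentSet:
    """Re-place every template fragment uniformly at random, lengths intact.

    The chromosome is chosen with probability proportional to the number of
    valid start positions (length - fragment_length + 1), then the start is
    uniform among them.
    """
    if len(template) == 0:
        raise ValueError("template fragment set is empty")
    chroms = genome.chrom_names
    chrom_lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.int64)
    placed: list[tuple[str, int, int]] = []
    for chrom, s, e in template.fragments:
        flen = e - s + 1
        slots = chrom_lengths - flen + 1
        slots = np.maximum(slots, 0)
        total = slots.sum()
        if total == 0:
            raise ValueError(f"fragment of length {flen} fits on no chromosome")
        ci = rng.choice(len(chroms), p=slots / total)
        start = int(rng.integers(1, slots[ci] + 1))
        placed.append((chroms[ci], start, start + flen - 1))
    return FragmentSet(placed, source="simulated", cycle_id=cycle_id)


def _merged_intervals(features) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (starts, ends) arrays for fast overlap tests."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    intervals = (
        features.intervals() if isinstance(features, FeatureSet) else list(features)
    )
    for chrom, s, e in intervals:
        per_chrom.setdefault(chrom, []).append((s, e))
    merged = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (
            np.array([s for s, _ in out], dtype=np.int64),
            np.array([e for _, e in out], dtype=np.int64),
        )
    return merged


def _fragment_overlaps(merged, chrom, s, e) -> bool:
    if chrom not in merged:
        return False
    starts, ends = merged[chrom]
    i = np.searchsorted(starts, e, side="right") - 1
    return i >= 0 and ends[i] >= s


def overlap_fraction(fragments: FragmentSet, features) -> float:
    """Fraction of fragments sharing at least 1 bp with any feature."""
    if len(fragments) == 0:
        return 0.0
    merged = _merged_intervals(features)
    hits = sum(
        _fragment_overlaps(merged, c, s, e) for c, s, e in fragments.fragments
    )
    return hits / len(fragments)


def bootstrap_overlap(
    fragments: FragmentSet,
    features,
    genome: GenomeIndex,
    n_cycles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> OverlapSummary:
    """Observed vs randomised feature-overlap fraction over ``n_cycles``.

    Empirical p-values use the +1 correction: (1 + #extreme) / (cycles + 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    merged = _merged_intervals(features)
    observed = overlap_fraction(fragments, features)
    sims = np.empty(n_cycles, dtype=np.float64)
    for i in range(n_cycles):
        placed = simulate_random_fragments(fragments, genome, rng, cycle_id=i)
        hits = sum(
            _fragment_overlaps(merged, c, s, e) for c, s, e in placed.fragments
        )
        sims[i] = hits / len(placed)
    ge = int((sims >= observed).sum())
    le = int((sims <= observed).sum())
    return OverlapSummary(
        observed_fraction=observed,
        simulated_mean_fraction=float(sims.mean()),
        simulated_sd=float(sims.std(ddof=1)) if n_cycles > 1 else 0.0,
        n_cycles=n_cycles,
        empirical_p=(1 + ge) / (n_cycles + 1),
        empirical_p_depletion=(1 + le) / (n_cycles + 1),
    )


def simulate_mutation_dataset(
    per_clone_loads: Sequence[int],
    motifs: MotifIndex,
    seed: int | np.random.Generator = 0,
    dataset_label: str = "simulated",
) -> MutationCatalog:
    """Uniform motif-constrained mutation catalog of the given loads.

    Each clone draws its stated number of sites uniformly *without
    replacement* from the motif index; substitutions are the deamination
    transition C->T on the site's strand (recorded as G->A at plus-strand
    coordinates for minus-strand sites).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = motifs.total_sites
    cidx, pos, minus = motifs.flat_arrays()
    chroms = motifs.chrom_order()
    catalog = MutationCatalog(dataset_label, strict=True)
    for k, load in enumerate(per_clone_loads):
        clone = f"sim{k:03d}"
        catalog.add_clone(clone)
        if load > M:
            raise ValueError(f"clone load {load} exceeds motif count {M}")
        chosen = rng.choice(M, size=int(load), replace=False)
        for j in chosen:
            on_minus = bool(minus[j])
            catalog.add(
                MutationRecord(
                    clone_id=clone,
                    chrom=chroms[cidx[j]],
                    pos=int(pos[j]),
                    ref_base="G" if on_minus else "C",
                    alt_base="A" if on_minus else "T",
                    allele_frequency=0.5,
                    zygosity="het",
                    **_SYNTHETIC_FIELDS,
                )
            )
    return catalog


def expected_mel_count(
    catalog: MutationCatalog,
    genome: GenomeIndex,
    motifs: MotifIndex,
    params=None,
    n_datasets: int = 5,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean MEL count over simulated datasets of equivalent per-clone loads."""
    from .mel_detect import MELParams, call_mels

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = params or MELParams()
    loads = sorted(catalog.per_clone_counts.values())
    counts = []
    for _ in range(n_datasets):
        sim = simulate_mutation_dataset(loads, motifs, rng, dataset_label="simulated")
        counts.append(len(call_mels(sim, genome, motifs, params)))
    return float(np.mean(counts))
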