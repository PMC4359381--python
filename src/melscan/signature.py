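"""Sequence-context and motif statistics for C:G-restricted catalogs.

Every mutation is oriented so the mutated base reads as a cytosine:
mutations recorded at a plus-strand G are minus-strand C events and their
flanking context is reverse-complemented before tallying.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeIndex, MotifIndex, revcomp
from .variant_ingest import MutationCatalog

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = ("A", "C", "G", "T")

_IUPAC = {"W": set("AT"), "R": set("AG"), "Y": set("CT"), "C": set("C")}
_MOTIF_PATTERNS = {"WRC": ("W", "R"), "YCC": ("Y", "C"), "C": ()}


@dataclass
class ContextMatrix:
    """Per-offset base frequencies around oriented mutated cytosines.

    Column ``offset 0`` is the mutated base itself and is 100% C after
    orientation.  Contexts running off a chromosome end contribute only
    their available offsets; each offset column is normalised by its own
    observation count.
    """

    flank_size: int
    frequencies: np.ndarray      # shape (2*flank+1, 4), rows = offsets
    offset_counts: np.ndarray    # observations per offset
    n_mutations: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank_size, self.flank_size + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, index=self.offsets, columns=BASES)


def _oriented_context(
    genome: GenomeIndex, chrom: str, pos: int, ref: str, flank: int
) -> tuple[str, int]:
    """Strand-local context string and the index of the mutated base in it."""
    length = genome.chrom_lengths[chrom]
    lo = max(1, pos - flank)
    hi = min(length, pos + flank)
    seq = genome.sequence(chrom, lo, hi)
    centre = pos - lo
    if ref == "G":
        seq = revcomp(seq)
        centre = len(seq) - 1 - centre
    return seq, centre


def context_matrix(
    catalog: MutationCatalog, genome: GenomeIndex, flank_size: int = 5
) -> ContextMatrix:
    """Base-frequency matrix of the oriented mutation neighbourhood."""
    k = 2 * flank_size + 1
    counts = np.zeros((k, 4), dtype=np.int64)
    n = 0
    for r in catalog.records():
        if r.ref_base not in ("C", "G"):
            raise ValueError(
                f"mutation at {r.ref_base} in {r.chrom}:{r.pos}; catalog must be "
                "restricted to C:G pairs before signature analysis"
            )
        seq, centre = _oriented_context(
            genome, r.chrom, r.pos, r.ref_base, flank_size
        )
        n += 1
        for i, base in enumerate(seq):
            offset = i - centre
            bi = _BASE_INDEX.get(base)
            if bi is not None:
                counts[offset + flank_size, bi] += 1
    offset_counts = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(
            offset_counts[:, None] > 0, counts / offset_counts[:, None], 0.0
        )
    return ContextMatrix(
        flank_size=flank_size,
        frequencies=freqs,
        offset_counts=offset_counts,
        n_mutations=n,
    )


def motif_fraction(
    catalog: MutationCatalog, genome: GenomeIndex, motif_class: str
) -> float | None:
    """Fraction of mutations whose oriented trinucleotide matches the class.

    The two bases 5' of the mutated cytosine (on the mutation strand) are
    tested against the class pattern.  Mutations whose 5' context runs off
    the chromosome are excluded from both numerator and denominator.
    Returns ``None`` for an empty catalog.
    """
    pattern = _MOTIF_PATTERNS[motif_class]
    matched = 0
    total = 0
    for r in catalog.records():
        if r.ref_base not in ("C", "G"):
            raise ValueError("catalog must be restricted to C:G pairs")
        seq, centre = _oriented_context(genome, r.chrom, r.pos, r.ref_base, 2)
        if centre < 2:
            continue  # 5' context truncated by the chromosome edge
        total += 1
        if motif_class == "C":
            matched += 1
            continue
        two5, one5 = seq[centre - 2], seq[centre - 1]
        if two5 in _IUPAC[pattern[0]] and one5 in _IUPAC[pattern[1]]:
            matched += 1
    if total == 0:
        return None
    return matched / total


def motif_distance_distribution(
    motifs: MotifIndex,
    intervals: list[tuple[str, int, int]] | None = None,
) -> np.ndarray:
    """Nearest-neighbour distances between motif sites along chromosomes.

    Sites from both strands are pooled by coordinate.  When ``intervals``
    are given, only sites inside them are considered and distances are
    taken between consecutive sites within the same interval.
    """
    dists: list[np.ndarray] = []
    for chrom in motifs.chrom_order():
        pos = np.sort(
            np.concatenate(
                [
                    motifs.plus.get(chrom, np.empty(0, dtype=np.int64)),
                    motifs.minus.get(chrom, np.empty(0, dtype=np.int64)),
                ]
            )
        )
        if intervals is None:
            if len(pos) >= 2:
                dists.append(np.diff(pos))
            continue
        for c, s, e in intervals:
            if c != chrom:
                continue
            lo, hi = np.searchsorted(pos, [s, e + 1])
            if hi - lo >= 2:
                dists.append(np.diff(pos[lo:hi]))
    if not dists:
        raise ValueError("fewer than 2 motif sites in scope")
    return np.concatenate(dists)
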