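"""Synthetic genomes, annotations and multi-clone mutation catalogs.

The generator emulates the statistical structure of deaminase mutagenesis
screens in diploid yeast: a few dozen independent clones, each carrying
hundreds of C:G transitions placed on motif-constrained cytosines on both
strands, with a subset of narrow promoter-anchored hotspot windows whose
per-site rate is strongly elevated, plus a uniform (EMS-like) control.
Planted-truth labels allow recovery scoring of the MEL detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .genome_io import Feature, FeatureSet, GenomeIndex, MotifIndex, scan_motifs
from .mel_detect import MEL
from .variant_ingest import MutationCatalog, MutationRecord

#: default chromosome split of the 1 Mb toy genome: four chromosomes with a
#: yeast-like size spread (enough points for per-chromosome correlations)
DEFAULT_CHROMS = {"chrI": 400_000, "chrII": 300_000, "chrIII": 200_000, "chrIV": 100_000}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    gc_fraction: float = 0.38           # S. cerevisiae genome-wide GC
    n_mrna: int = 100
    n_trna: int = 20
    n_snorna: int = 10
    n_snrna: int = 5
    n_ars: int = 10
    n_clones: int = 30
    load_lambda: float = 400.0          # Poisson mean per-clone SNV load
    fixed_load: Optional[int] = None    # overrides the Poisson draw when set
    motif_class: str = "WRC"            # WRC (AID-like), YCC (A3G-like), C (EMS-like)
    n_hotspots: int = 20
    hotspot_width: int = 110            # bp, the observed median MEL width
    hotspot_offset: int = -40           # centre offset from the TSS (upstream)
    hotspot_jitter: int = 20            # +/- uniform jitter on the offset
    rate_multiplier: float = 25.0       # per-site rate elevation inside hotspots
    hom_probability: float = 0.05       # chance a mutation hits both alleles

    def __post_init__(self):
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.rate_multiplier < 1:
            raise ValueError("rate_multiplier must be >= 1")

    @classmethod
    def density_matched(cls, **overrides) -> "SyntheticSpec":
        """Study conditions matching the observed per-bp mutation density.

        The sequenced diploid screens carry ~600-800 SNVs per clone over a
        12.1 Mb genome, i.e. ~50 mutations per clone per Mb; at that
        density the pooled 150 bp window counts stay below the binomial
        null's 99th-percentile threshold and the detector is calibrated
        (see docs/methods.md).  The hotspot rate multiplier is raised so
        per-hotspot pooled loads (~15-19 mutations) match the ~14
        mutations per observed MEL.
        """
        overrides.setdefault("load_lambda", 50.0)
        overrides.setdefault("rate_multiplier", 150.0)
        return cls(**overrides)


@dataclass
class SyntheticTruth:
    """Planted hotspots and per-mutation provenance labels."""

    hotspots: list[tuple[str, int, int]]
    labels: dict[tuple[str, str, int], str]  # (clone, chrom, pos) -> hotspot|background

    def label_counts(self) -> dict[str, int]:
        out = {"hotspot": 0, "background": 0}
        for v in self.labels.values():
            out[v] += 1
        return out


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_genome(spec: SyntheticSpec, seed=0) -> GenomeIndex:
    """I.i.d. genome with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2."""
    rng = _rng(seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for chrom, length in spec.chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} length must be > 0")
        draw = rng.choice(alphabet, size=length, p=probs)
        seqs[chrom] = draw.tobytes().decode("ascii")
    return GenomeIndex(seqs)


_GENE_CLASSES = (
    # (class, count attr, min_len, max_len)
    ("mRNA", "n_mrna", 800, 2000),
    ("tRNA", "n_trna", 70, 90),
    ("snoRNA", "n_snorna", 100, 200),
    ("snRNA", "n_snrna", 100, 300),
    ("ARS", "n_ars", 150, 300),
)


def generate_annotations(
    genome: GenomeIndex, spec: SyntheticSpec, seed=0
) -> FeatureSet:
    """Place non-overlapping gene bodies with random strands.

    The TSS sits at the strand-aware body start; a TATA element is placed
    uniformly 30-120 bp upstream of each mRNA TSS; mRNA genes get a
    log-normal transcription rate.
    """
    rng = _rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    chroms = genome.chrom_names
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.float64)
    probs = lengths / lengths.sum()
    features: list[Feature] = []
    counter = 0
    margin = 700  # keep promoters and TATA boxes within bounds
    for cls, attr, lo, hi in _GENE_CLASSES:
        n = getattr(spec, attr)
        for _ in range(n):
            placed = False
            for _attempt in range(2000):
                ci = rng.choice(len(chroms), p=probs)
                chrom = chroms[ci]
                L = int(genome.chrom_lengths[chrom])
                glen = int(rng.integers(lo, hi + 1))
                if L < glen + 2 * margin:
                    continue
                start = int(rng.integers(1 + margin, L - glen - margin + 2))
                end = start + glen - 1
                if any(s <= end + 50 and e >= start - 50 for s, e in occupied[chrom]):
                    continue
                occupied[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                tata = None
                tx = None
                if cls == "mRNA":
                    gap = int(rng.integers(30, 121))
                    tss = start if strand == "+" else end
                    tata = tss - gap if strand == "+" else tss + gap
                    tx = float(rng.lognormal(mean=0.0, sigma=1.0))
                features.append(
                    Feature(
                        feature_id=f"{cls}_{counter:04d}",
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        feature_class=cls,
                        tata_pos=tata,
                        tx_rate=tx,
                    )
                )
                counter += 1
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place a {cls} gene: genome too small or too full"
                )
    return FeatureSet(features)


def plant_hotspots(
    features: FeatureSet, spec: SyntheticSpec, seed=0
) -> list[tuple[str, int, int]]:
    """Promoter-anchored hotspot windows on randomly chosen mRNA genes.

    Each window is ``hotspot_width`` bp centred ``hotspot_offset`` (with
    uniform jitter) from the TSS on the gene's strand, i.e. in the
    nucleosome-free region where the pre-initiation complex assembles.
    """
    rng = _rng(seed)
    mrna = [f for f in features if f.feature_class == "mRNA"]
    if spec.n_hotspots > len(mrna):
        raise ValueError("more hotspots requested than mRNA genes available")
    chosen = rng.choice(len(mrna), size=spec.n_hotspots, replace=False)
    hotspots = []
    for i in sorted(chosen):
        f = mrna[i]
        jitter = int(rng.integers(-spec.hotspot_jitter, spec.hotspot_jitter + 1))
        offset = spec.hotspot_offset + jitter
        centre = f.tss + offset if f.strand != "-" else f.tss - offset
        half = spec.hotspot_width // 2
        start = centre - half
        end = centre + spec.hotspot_width - half - 1
        hotspots.append((f.chrom, start, end))
    return hotspots


def simulate_clones(
    genome: GenomeIndex,
    motifs: MotifIndex,
    spec: SyntheticSpec,
    seed=0,
    hotspots: list[tuple[str, int, int]] | None = None,
    dataset_label: str | None = None,
) -> tuple[MutationCatalog, SyntheticTruth]:
    """Draw per-clone mutation catalogs over the motif index.

    Sites inside hotspot windows carry sampling weight ``rate_multiplier``,
    all other sites weight 1; each clone samples its load without
    replacement (weighted reservoir via Gumbel top-k).  Substitutions are
    the deamination transition C->T on the site strand.  Records carry
    synthetic caller statistics that pass the high-confidence profile.
    """
    rng = _rng(seed)
    if hotspots is None:
        hotspots = []
    cidx, pos, minus = motifs.flat_arrays()
    chroms = motifs.chrom_order()
    M = len(pos)
    if M == 0:
        raise ValueError("motif index is empty")
    in_hotspot = np.zeros(M, dtype=bool)
    for chrom, s, e in hotspots:
        if chrom not in chroms:
            continue
        ci = chroms.index(chrom)
        in_hotspot |= (cidx == ci) & (pos >= s) & (pos <= e)
    if hotspots and not in_hotspot.any():
        raise ValueError("no motif site falls inside any hotspot window")
    log_w = np.where(in_hotspot, np.log(spec.rate_multiplier), 0.0)

    label = dataset_label or f"{spec.motif_class}_synthetic"
    catalog = MutationCatalog(label, strict=True)
    truth = SyntheticTruth(hotspots=list(hotspots), labels={})
    for k in range(spec.n_clones):
        clone = f"clone{k:03d}"
        catalog.add_clone(clone)
        if spec.fixed_load is not None:
            load = spec.fixed_load
        else:
            load = int(rng.poisson(spec.load_lambda))
        if load > M:
            raise ValueError(f"clone load {load} exceeds motif site count {M}")
        if load == 0:
            continue
        keys = log_w + rng.gumbel(size=M)
        chosen = np.argpartition(keys, M - load)[M - load:]
        for j in chosen:
            chrom = chroms[cidx[j]]
            p = int(pos[j])
            on_minus = bool(minus[j])
            hom = rng.random() < spec.hom_probability
            af = float(rng.uniform(0.9, 1.0) if hom else rng.uniform(0.35, 0.65))
            catalog.add(
                MutationRecord(
                    clone_id=clone,
                    chrom=chrom,
                    pos=p,
                    ref_base="G" if on_minus else "C",
                    alt_base="A" if on_minus else "T",
                    caller_score=float(rng.uniform(60, 250)),
                    allele_frequency=af,
                    ref_read_count=int(rng.integers(10, 40)),
                    sample_read_count=int(rng.integers(10, 40)),
                    mean_read_position_fraction=float(rng.uniform(0.3, 0.7)),
                    mean_distance_to_3prime=float(rng.uniform(0.3, 0.7)),
                    mean_base_quality=float(rng.uniform(32, 38)),
                    mean_read_length=float(rng.uniform(90, 110)),
                    zygosity="hom" if hom else "het",
                )
            )
            truth.labels[(clone, chrom, p)] = (
                "hotspot" if in_hotspot[j] else "background"
            )
    return catalog, truth


@dataclass
class RecoveryReport:
    sensitivity: float
    false_discovery_fraction: float
    median_boundary_offset: float   # nan when nothing was matched
    n_hotspots: int
    n_called: int
    n_recovered: int
    n_false: int


def evaluate_recovery(
    called_mels: list[MEL], truth: SyntheticTruth
) -> RecoveryReport:
    """Score called MELs against the planted hotspots (>=1 bp overlap).

    A hotspot is recovered if any MEL overlaps it; a MEL overlapping no
    hotspot is a false discovery.  Boundary offsets |called edge - true
    edge| are collected for every (MEL, hotspot) overlap pair and
    summarised by their median.
    """
    recovered = np.zeros(len(truth.hotspots), dtype=bool)
    offsets: list[int] = []
    n_false = 0
    for m in called_mels:
        hit = False
        for i, (chrom, s, e) in enumerate(truth.hotspots):
            if m.chrom == chrom and m.start <= e and m.end >= s:
                recovered[i] = True
                hit = True
                offsets.append(abs(m.start - s))
                offsets.append(abs(m.end - e))
        if not hit:
            n_false += 1
    n_hot = len(truth.hotspots)
    n_called = len(called_mels)
    return RecoveryReport(
        sensitivity=float(recovered.sum() / n_hot) if n_hot else 0.0,
        false_discovery_fraction=(n_false / n_called) if n_called else 0.0,
        median_boundary_offset=float(np.median(offsets)) if offsets else float("nan"),
        n_hotspots=n_hot,
        n_called=n_called,
        n_recovered=int(recovered.sum()),
        n_false=n_false,
    )


# ---------------------------------------------------------------------------
# a complete study: three mutator datasets over one genome


@dataclass
class SyntheticStudy:
    genome: GenomeIndex
    features: FeatureSet
    hotspots: list[tuple[str, int, int]]
    motifs: dict[str, MotifIndex]                 # per motif class
    catalogs: dict[str, MutationCatalog]          # AID-like / A3G-like / EMS-like
    truths: dict[str, SyntheticTruth]


def build_study(spec: SyntheticSpec | None = None, seed: int = 0) -> SyntheticStudy:
    """One genome with an AID-like (WRC, hotspot-planted), an A3G-like
    (YCC, hotspot-planted) and an EMS-like (any C, uniform) dataset."""
    spec = spec or SyntheticSpec()
    rng = _rng(seed)
    genome = generate_genome(spec, rng)
    features = generate_annotations(genome, spec, rng)
    hotspots = plant_hotspots(features, spec, rng)
    motifs = {mc: scan_motifs(genome, mc) for mc in ("WRC", "YCC", "C")}
    catalogs: dict[str, MutationCatalog] = {}
    truths: dict[str, SyntheticTruth] = {}
    for label, mc, spots in (
        ("AID_like", "WRC", hotspots),
        ("A3G_like", "YCC", hotspots),
        ("EMS_like", "C", []),
    ):
        sub = replace(spec, motif_class=mc)
        cat, truth = simulate_clones(
            genome, motifs[mc], sub, rng, hotspots=spots, dataset_label=label
        )
        catalogs[label] = cat
        truths[label] = truth
    return SyntheticStudy(
        genome=genome,
        features=features,
        hotspots=hotspots,
        motifs=motifs,
        catalogs=catalogs,
        truths=truths,
    )
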