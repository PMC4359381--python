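"""Association of mutations and MELs with genomic features.

Promoter windows, location classification, anchor-relative density
profiles, promoter mutation frequencies under down-sampling, interval
score aggregation and chromosome-load correlation.  All distances are
signed on the feature's strand: upstream of the anchor is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .genome_io import Feature, FeatureSet, GenomeIndex
from .mel_detect import MEL
from .variant_ingest import MutationCatalog


@dataclass(frozen=True)
class PromoterParams:
    upstream: int = 500     # bp upstream of the TSS
    downstream: int = 50    # bp downstream of the TSS
    trna_width: int = 550   # window centred on the tRNA gene midpoint


@dataclass
class PromoterWindow:
    feature_id: str
    chrom: str
    start: int
    end: int
    feature_class: str
    anchor: str          # "TSS" or "midpoint"
    strand: str
    truncated: bool = False
    tx_rate: Optional[float] = None

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def define_promoters(
    features: FeatureSet,
    params: PromoterParams = PromoterParams(),
    chrom_lengths: dict[str, int] | None = None,
) -> list[PromoterWindow]:
    """Promoter windows for mRNA/snoRNA/snRNA (TSS-anchored) and tRNA genes.

    mRNA-like classes get [TSS-upstream, TSS+downstream] on the plus strand
    and the mirror image on the minus strand; tRNA genes get a
    ``trna_width`` window centred on the gene midpoint.  Intronic snoRNAs
    inherit their host gene's promoter; polycistronic snoRNA clusters are
    assigned a single promoter anchored at the cluster's 5'-most TSS.
    Windows running off a chromosome end are truncated and flagged.
    """
    windows: list[PromoterWindow] = []
    seen_clusters: set[str] = set()
    for f in features:
        if f.feature_class in ("mRNA", "snoRNA", "snRNA"):
            anchor_feature = f
            if f.feature_class == "snoRNA":
                if f.host_feature_id is not None:
                    anchor_feature = features.by_id(f.host_feature_id)
                elif f.cluster_id is not None:
                    if f.cluster_id in seen_clusters:
                        continue
                    seen_clusters.add(f.cluster_id)
                    members = [
                        g for g in features
                        if g.cluster_id == f.cluster_id
                        and g.feature_class == "snoRNA"
                    ]
                    # 5'-most member on the cluster strand anchors the promoter
                    if f.strand == "-":
                        anchor_feature = max(members, key=lambda g: g.tss)
                    else:
                        anchor_feature = min(members, key=lambda g: g.tss)
            tss = anchor_feature.tss
            if anchor_feature.strand == "-":
                start, end = tss - params.downstream, tss + params.upstream
            else:
                start, end = tss - params.upstream, tss + params.downstream
            windows.append(
                _clip_window(
                    PromoterWindow(
                        feature_id=f.feature_id,
                        chrom=f.chrom,
                        start=start,
                        end=end,
                        feature_class=f.feature_class,
                        anchor="TSS",
                        strand=anchor_feature.strand,
                        tx_rate=f.tx_rate,
                    ),
                    chrom_lengths,
                )
            )
        elif f.feature_class == "tRNA":
            mid = f.midpoint
            half = params.trna_width // 2
            start = mid - half
            end = mid + params.trna_width - half - 1
            windows.append(
                _clip_window(
                    PromoterWindow(
                        feature_id=f.feature_id,
                        chrom=f.chrom,
                        start=start,
                        end=end,
                        feature_class="tRNA",
                        anchor="midpoint",
                        strand=f.strand,
                        tx_rate=f.tx_rate,
                    ),
                    chrom_lengths,
                )
            )
    return windows


def _clip_window(w: PromoterWindow, chrom_lengths) -> PromoterWindow:
    if w.start < 1:
        w.start, w.truncated = 1, True
    if chrom_lengths is not None and w.chrom in chrom_lengths:
        L = chrom_lengths[w.chrom]
        if w.end > L:
            w.end, w.truncated = L, True
    return w


# ---------------------------------------------------------------------------
# location classification

LOCATION_PRIORITY = ("promoter", "ARS", "gene_body", "intergenic")


def _interval_lookup(intervals: Sequence[tuple[str, int, int]]):
    per: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        tmp.setdefault(chrom, []).append((s, e))
    for chrom, ivs in tmp.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        per[chrom] = (
            np.array([s for s, _ in merged], dtype=np.int64),
            np.array([e for _, e in merged], dtype=np.int64),
        )
    return per


def _in_intervals(lookup, chrom: str, pos: int) -> bool:
    if chrom not in lookup:
        return False
    starts, ends = lookup[chrom]
    i = np.searchsorted(starts, pos, side="right") - 1
    return i >= 0 and ends[i] >= pos


class LocationClassifier:
    """Single-label classification with priority promoter > ARS > gene body."""

    def __init__(self, features: FeatureSet, promoters: list[PromoterWindow]):
        self._promoters = _interval_lookup(
            [(w.chrom, w.start, w.end) for w in promoters]
        )
        self._ars = _interval_lookup(
            [(f.chrom, f.start, f.end) for f in features if f.feature_class == "ARS"]
        )
        self._bodies = _interval_lookup(
            [
                (f.chrom, f.start, f.end)
                for f in features
                if f.feature_class in ("mRNA", "tRNA", "snoRNA", "snRNA")
            ]
        )

    def classify(self, chrom: str, pos: int) -> str:
        if _in_intervals(self._promoters, chrom, pos):
            return "promoter"
        if _in_intervals(self._ars, chrom, pos):
            return "ARS"
        if _in_intervals(self._bodies, chrom, pos):
            return "gene_body"
        return "intergenic"

    def classify_interval(self, chrom: str, start: int, end: int) -> str:
        """Classify an interval (e.g. a MEL) by overlap, same priority order."""
        for label, lookup in (
            ("promoter", self._promoters),
            ("ARS", self._ars),
            ("gene_body", self._bodies),
        ):
            if chrom in lookup:
                starts, ends = lookup[chrom]
                i = np.searchsorted(starts, end, side="right") - 1
                if i >= 0 and ends[i] >= start:
                    return label
        return "intergenic"


def classify_location(
    chrom: str,
    pos: int,
    features: FeatureSet,
    promoters: list[PromoterWindow],
) -> str:
    return LocationClassifier(features, promoters).classify(chrom, pos)


def classify_catalog(
    catalog: MutationCatalog,
    features: FeatureSet,
    promoters: list[PromoterWindow],
) -> pd.Series:
    """Label counts over the whole catalog (labels partition the catalog)."""
    clf = LocationClassifier(features, promoters)
    labels = [clf.classify(r.chrom, r.pos) for r in catalog.records()]
    return pd.Series(labels, dtype="object").value_counts().reindex(
        LOCATION_PRIORITY, fill_value=0
    )


# ---------------------------------------------------------------------------
# anchor distances and density profiles


def _anchor_position(f: Feature, anchor: str) -> Optional[int]:
    if anchor == "TSS":
        return f.tss
    if anchor == "TTS":
        return f.tts
    if anchor == "TATA":
        return f.tata_pos
    if anchor == "midpoint":
        return f.midpoint
    raise ValueError(f"unknown anchor {anchor!r}")


def distance_to_anchor(
    chrom: str,
    pos: int,
    features: FeatureSet,
    anchor: str = "TSS",
    classes: tuple[str, ...] = ("mRNA",),
) -> int:
    """Signed distance to the nearest feature anchor on that feature's strand.

    Negative = upstream of the anchor.  Nearest feature by absolute
    distance; ties prefer the feature on whose strand the position is
    downstream, then the lexicographically smaller feature id.
    """
    best: tuple[int, int, str] | None = None  # (|d|, preference, fid) -> signed d
    best_signed = None
    for f in features:
        if f.chrom != chrom or f.feature_class not in classes:
            continue
        a = _anchor_position(f, anchor)
        if a is None:
            continue
        signed = (pos - a) if f.strand != "-" else (a - pos)
        key = (abs(signed), 0 if signed >= 0 else 1, f.feature_id)
        if best is None or key < best:
            best = key
            best_signed = signed
    if best_signed is None:
        raise ValueError(f"no feature of classes {classes} with anchor {anchor}")
    return best_signed


@dataclass
class DensityProfile:
    """Normalised per-offset mutation density around an anchor class.

    Densities are mutation counts per offset divided by the *dataset* total,
    so the profile sums to the in-range fraction of mutations.
    """

    anchor_type: str
    offsets: np.ndarray
    density: np.ndarray
    total_mutations_in_range: int
    dataset_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "density": self.density})


def density_profile(
    catalog: MutationCatalog,
    features: FeatureSet,
    anchor: str = "TSS",
    range_bp: int = 500,
    bin_bp: int = 1,
    classes: tuple[str, ...] = ("mRNA",),
) -> DensityProfile:
    """Mutation density against signed distance to the nearest anchor."""
    anchors: dict[str, list[tuple[int, str]]] = {}
    for f in features:
        if f.feature_class not in classes:
            continue
        a = _anchor_position(f, anchor)
        if a is not None:
            anchors.setdefault(f.chrom, []).append((a, f.strand))
    sorted_anchors = {
        chrom: (
            np.array(sorted(a for a, _ in lst), dtype=np.int64),
            {a: s for a, s in lst},
        )
        for chrom, lst in anchors.items()
    }
    n_bins = (2 * range_bp) // bin_bp + 1
    edges = np.arange(-range_bp, range_bp + bin_bp + 1, bin_bp) - 0.5
    hist = np.zeros(n_bins, dtype=np.int64)
    in_range = 0
    for r in catalog.records():
        if r.chrom not in sorted_anchors:
            continue
        arr, strand_of = sorted_anchors[r.chrom]
        i = np.searchsorted(arr, r.pos)
        cands = [j for j in (i - 1, i) if 0 <= j < len(arr)]
        if not cands:
            continue
        j = min(cands, key=lambda j: abs(r.pos - arr[j]))
        a = int(arr[j])
        signed = (r.pos - a) if strand_of[a] != "-" else (a - r.pos)
        if -range_bp <= signed <= range_bp:
            in_range += 1
            hist[np.searchsorted(edges, signed, side="right") - 1] += 1
    total = catalog.total_mutations
    density = hist / total if total else hist.astype(float)
    centers = np.arange(-range_bp, range_bp + 1, bin_bp)
    return DensityProfile(
        anchor_type=anchor,
        offsets=centers,
        density=density,
        total_mutations_in_range=in_range,
        dataset_total=total,
    )


# ---------------------------------------------------------------------------
# promoter mutation frequency under down-sampling


@dataclass
class PromoterFrequencyTable:
    """Bootstrap-mean mutation counts per promoter per dataset."""

    table: pd.DataFrame             # index: feature_id; columns: dataset labels
    downsample_target: int
    n_bootstraps: int
    promoter_class: pd.Series       # feature_id -> class
    tx_rate: pd.Series              # feature_id -> transcription rate (may be NaN)


def promoter_mutation_frequency(
    catalogs: Sequence[MutationCatalog],
    promoters: list[PromoterWindow],
    reference_label: str | None = None,
    downsample_target: int | None = None,
    n_bootstraps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PromoterFrequencyTable:
    """Average per-promoter mutation counts after down-sampling bootstraps.

    Every catalog is repeatedly down-sampled without replacement to
    ``downsample_target`` mutations (default: half the size of the
    reference dataset, the EMS-role control) so the per-promoter counts are
    directly comparable across datasets; the reported count is the mean
    over bootstraps.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if downsample_target is None:
        ref = None
        if reference_label is not None:
            for c in catalogs:
                if c.dataset_label == reference_label:
                    ref = c
        if ref is None:
            ref = min(catalogs, key=lambda c: c.total_mutations)
        downsample_target = ref.total_mutations // 2
    lookup_rows = []
    for idx, w in enumerate(promoters):
        lookup_rows.append((w.chrom, w.start, w.end, idx))
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, s, e, idx in lookup_rows:
        per_chrom.setdefault(chrom, []).append((s, e, idx))
    columns = {}
    for cat in catalogs:
        n = cat.total_mutations
        if n < downsample_target:
            raise ValueError(
                f"dataset {cat.dataset_label!r} ({n} mutations) smaller than "
                f"down-sampling target {downsample_target}"
            )
        # membership pairs (mutation index, promoter index); windows may overlap
        mut_idx: list[int] = []
        prom_idx: list[int] = []
        for i, r in enumerate(cat.records()):
            for s, e, idx in per_chrom.get(r.chrom, ()):
                if s <= r.pos <= e:
                    mut_idx.append(i)
                    prom_idx.append(idx)
        mut_idx_a = np.array(mut_idx, dtype=np.int64)
        prom_idx_a = np.array(prom_idx, dtype=np.int64)
        acc = np.zeros(len(promoters), dtype=np.float64)
        for _ in range(n_bootstraps):
            chosen = np.zeros(n, dtype=bool)
            chosen[rng.choice(n, size=downsample_target, replace=False)] = True
            if len(mut_idx_a):
                sel = chosen[mut_idx_a]
                acc += np.bincount(prom_idx_a[sel], minlength=len(promoters))
        columns[cat.dataset_label] = acc / n_bootstraps
    ids = [w.feature_id for w in promoters]
    return PromoterFrequencyTable(
        table=pd.DataFrame(columns, index=pd.Index(ids, name="feature_id")),
        downsample_target=downsample_target,
        n_bootstraps=n_bootstraps,
        promoter_class=pd.Series(
            [w.feature_class for w in promoters], index=ids, name="class"
        ),
        tx_rate=pd.Series(
            [w.tx_rate if w.tx_rate is not None else np.nan for w in promoters],
            index=ids,
            name="tx_rate",
        ),
    )


# ---------------------------------------------------------------------------
# statistics


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test with midrank ties.

    Exact null distribution for small tie-free samples, normal
    approximation otherwise.  Returns (U statistic, p-value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and len(a) <= 25 and len(b) <= 25) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def aggregate_interval_scores(
    positions: np.ndarray,
    scores: np.ndarray,
    intervals: Sequence[tuple[str, int, int]] | Sequence[tuple[int, int]],
    chroms: np.ndarray | None = None,
) -> np.ndarray:
    """Sum of track scores at positions inside each interval.

    Intervals sharing positions each get the full sum (no double-count
    correction).  ``chroms`` (parallel to ``positions``) is required when
    intervals carry chromosome names.
    """
    positions = np.asarray(positions, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    out = np.zeros(len(intervals), dtype=np.float64)
    if len(positions) == 0:
        return out
    if intervals and len(intervals[0]) == 3:
        if chroms is None:
            raise ValueError("chromosome array required for 3-tuple intervals")
        chroms = np.asarray(chroms)
        for i, (chrom, s, e) in enumerate(intervals):
            m = chroms == chrom
            p, sc = positions[m], scores[m]
            order = np.argsort(p)
            p, sc = p[order], sc[order]
            prefix = np.concatenate(([0.0], np.cumsum(sc)))
            lo, hi = np.searchsorted(p, [s, e + 1])
            out[i] = prefix[hi] - prefix[lo]
        return out
    order = np.argsort(positions)
    p, sc = positions[order], scores[order]
    prefix = np.concatenate(([0.0], np.cumsum(sc)))
    for i, (s, e) in enumerate(intervals):
        lo, hi = np.searchsorted(p, [s, e + 1])
        out[i] = prefix[hi] - prefix[lo]
    return out


def chromosome_load_correlation(
    catalog: MutationCatalog, genome: GenomeIndex
) -> dict[str, tuple[float, float]]:
    """Spearman correlation of per-clone chromosome load with length.

    One point per (clone, chromosome); mutations at C and at G are
    correlated separately.  Constant inputs give rho = nan (documented
    degenerate case).  Requires at least three chromosomes.
    """
    if len(genome.chrom_names) < 3:
        raise ValueError("need at least 3 chromosomes for a rank correlation")
    df = catalog.to_frame()
    lengths = genome.chrom_lengths
    out: dict[str, tuple[float, float]] = {}
    for base in ("C", "G"):
        xs, ys = [], []
        sub = df[df["ref"] == base] if len(df) else df
        counts = (
            sub.groupby(["clone_id", "chrom"]).size() if len(sub) else pd.Series(dtype=int)
        )
        for clone in catalog.clones:
            for chrom in genome.chrom_names:
                xs.append(lengths[chrom])
                ys.append(int(counts.get((clone, chrom), 0)))
        import warnings

        with warnings.catch_warnings():
            # constant inputs are a documented degenerate case -> rho = nan
            warnings.simplefilter("ignore")
            rho, p = spearmanr(xs, ys)
        out[base] = (float(rho), float(p))
    return out


# ---------------------------------------------------------------------------
# biallelic / homozygous MEL statistics


@dataclass
class BiallelicStats:
    per_genome_biallelic_fraction: float  # genomes with >=1 biallelically hit MEL
    hom_in_mel_fraction: float            # hom mutations falling inside MELs
    n_genomes: int
    n_hom: int


def biallelic_mel_stats(
    catalog: MutationCatalog,
    mels: list[MEL],
    hom_af_threshold: float = 0.8,
    het_pair_counts: bool = True,
) -> BiallelicStats:
    """Both-allele MEL targeting per genome and hom-mutation capture by MELs.

    A genome counts as biallelic for a MEL if the MEL contains one of its
    homozygous mutations, or (proxy, when ``het_pair_counts``) at least two
    of its heterozygous mutations.  Also reports the fraction of all
    homozygous mutations that fall inside MELs.
    """
    from .variant_ingest import classify_zygosity

    mel_lookup = _interval_lookup([(m.chrom, m.start, m.end) for m in mels])
    mel_keys = [(m.chrom, m.start, m.end) for m in mels]

    def find_mel(chrom, pos):
        for i, (c, s, e) in enumerate(mel_keys):
            if c == chrom and s <= pos <= e:
                return i
        return None

    n_hom = 0
    n_hom_in_mel = 0
    biallelic_genomes = 0
    for clone_id, records in catalog.clones.items():
        hom_hits: set[int] = set()
        het_hits: dict[int, int] = {}
        for r in records:
            z = classify_zygosity(r, hom_af_threshold)
            inside = _in_intervals(mel_lookup, r.chrom, r.pos)
            if z == "hom":
                n_hom += 1
                if inside:
                    n_hom_in_mel += 1
                    idx = find_mel(r.chrom, r.pos)
                    if idx is not None:
                        hom_hits.add(idx)
            elif z == "het" and inside and het_pair_counts:
                idx = find_mel(r.chrom, r.pos)
                if idx is not None:
                    het_hits[idx] = het_hits.get(idx, 0) + 1
        if hom_hits or any(v >= 2 for v in het_hits.values()):
            biallelic_genomes += 1
    n_genomes = catalog.n_clones
    return BiallelicStats(
        per_genome_biallelic_fraction=(
            biallelic_genomes / n_genomes if n_genomes else 0.0
        ),
        hom_in_mel_fraction=(n_hom_in_mel / n_hom) if n_hom else 0.0,
        n_genomes=n_genomes,
        n_hom=n_hom,
    )
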