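"""Per-clone SNV catalogs: ingestion, high-confidence filtering, zygosity.

The catalogs hold somatic single-nucleotide variants called independently in
each sequenced transformant (clone).  Records carry the caller summary
statistics used by the high-confidence filter: caller score, allele
frequency, read depths, average read-position fractions, base quality and
read length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class MutationRecord:
    clone_id: str
    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    caller_score: Optional[float] = None
    allele_frequency: Optional[float] = None
    ref_read_count: Optional[int] = None
    sample_read_count: Optional[int] = None
    mean_read_position_fraction: Optional[float] = None
    mean_distance_to_3prime: Optional[float] = None
    mean_base_quality: Optional[float] = None
    mean_read_length: Optional[float] = None
    zygosity: str = "unknown"  # het | hom | unknown

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref == alt ({self.ref_base}) at {self.chrom}:{self.pos}")
        if len(self.ref_base) != 1 or len(self.alt_base) != 1:
            raise ValueError(f"not a SNV: {self.ref_base}>{self.alt_base}")
        for name in (
            "allele_frequency",
            "mean_read_position_fraction",
            "mean_distance_to_3prime",
        ):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1] at {self.chrom}:{self.pos}")


class MutationCatalog:
    """Multi-clone SNV dataset; the pipeline's central input."""

    def __init__(self, dataset_label: str = "dataset", strict: bool = True):
        self.dataset_label = dataset_label
        self.strict = strict
        self.clones: dict[str, list[MutationRecord]] = {}
        self._seen: set[tuple[str, str, int]] = set()
        self._df_cache: pd.DataFrame | None = None

    # -- construction -----------------------------------------------------
    def add(self, record: MutationRecord) -> None:
        key = (record.clone_id, record.chrom, record.pos)
        if key in self._seen:
            if self.strict:
                raise ValueError(f"duplicate mutation {key}")
            log.warning("dropping duplicate mutation %s", key)
            return
        self._seen.add(key)
        self.clones.setdefault(record.clone_id, []).append(record)
        self._df_cache = None

    def add_clone(self, clone_id: str) -> None:
        """Register a clone even if it carries no mutations."""
        self.clones.setdefault(clone_id, [])

    @classmethod
    def from_records(
        cls,
        records: Iterable[MutationRecord],
        dataset_label: str = "dataset",
        strict: bool = True,
    ) -> "MutationCatalog":
        cat = cls(dataset_label, strict=strict)
        for r in records:
            cat.add(r)
        return cat

    # -- summaries ---------------------------------------------------------
    @property
    def per_clone_counts(self) -> dict[str, int]:
        return {c: len(rs) for c, rs in self.clones.items()}

    @property
    def total_mutations(self) -> int:
        return sum(len(rs) for rs in self.clones.values())

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def mean_load(self) -> float:
        """Average number of mutations per clone (the binomial-null size)."""
        if not self.clones:
            return 0.0
        return self.total_mutations / self.n_clones

    def records(self) -> Iterator[MutationRecord]:
        for rs in self.clones.values():
            yield from rs

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (cached) with one row per mutation."""
        if self._df_cache is None:
            rows = [
                (r.clone_id, r.chrom, r.pos, r.ref_base, r.alt_base,
                 r.allele_frequency, r.zygosity)
                for r in self.records()
            ]
            self._df_cache = pd.DataFrame(
                rows,
                columns=["clone_id", "chrom", "pos", "ref", "alt", "af", "zygosity"],
            )
        return self._df_cache

    def positions_by_chrom(self) -> dict[str, pd.DataFrame]:
        """Per-chromosome frames sorted by position (pos, clone, ref)."""
        df = self.to_frame()
        if df.empty:
            return {}
        return {
            chrom: sub.sort_values("pos").reset_index(drop=True)
            for chrom, sub in df.groupby("chrom")
        }

    def subset(self, predicate) -> "MutationCatalog":
        out = MutationCatalog(self.dataset_label, strict=self.strict)
        for clone_id in self.clones:
            out.add_clone(clone_id)
        for r in self.records():
            if predicate(r):
                out.add(r)
        return out

    def write_tsv(self, path) -> None:
        rows = []
        for r in self.records():
            rows.append(
                {
                    "clone_id": r.clone_id,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "ref": r.ref_base,
                    "alt": r.alt_base,
                    "caller_score": r.caller_score,
                    "allele_frequency": r.allele_frequency,
                    "ref_read_count": r.ref_read_count,
                    "sample_read_count": r.sample_read_count,
                    "read_pos_fraction": r.mean_read_position_fraction,
                    "dist_to_3prime": r.mean_distance_to_3prime,
                    "base_quality": r.mean_base_quality,
                    "read_length": r.mean_read_length,
                    "zygosity": r.zygosity,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering


@dataclass(frozen=True)
class FilterProfile:
    """Thresholds over the caller statistics; directions fixed per statistic.

    ``min_score`` and ``min_read_length`` are strict (the criteria print
    ``>``); all other bounds are inclusive (``>=``).  ``min_read_count``
    applies to the reference *or* the sample depth.
    """

    profile_id: str = "custom"
    min_score: Optional[float] = None            # strict >
    min_allele_frequency: Optional[float] = None
    min_read_count: Optional[int] = None         # ref or sample depth
    min_read_count_both: Optional[int] = None    # ref and sample depth
    min_read_position_fraction: Optional[float] = None
    min_distance_to_3prime: Optional[float] = None
    min_base_quality: Optional[float] = None
    min_read_length: Optional[float] = None      # strict >

    def passes(self, r: MutationRecord, strict_fields: bool = True) -> bool:
        checks = [
            (self.min_score, r.caller_score, lambda v, t: v > t),
            (self.min_allele_frequency, r.allele_frequency, lambda v, t: v >= t),
            (self.min_read_position_fraction, r.mean_read_position_fraction,
             lambda v, t: v >= t),
            (self.min_distance_to_3prime, r.mean_distance_to_3prime,
             lambda v, t: v >= t),
            (self.min_base_quality, r.mean_base_quality, lambda v, t: v >= t),
            (self.min_read_length, r.mean_read_length, lambda v, t: v > t),
        ]
        for threshold, value, cmp in checks:
            if threshold is None:
                continue
            if value is None:
                if strict_fields:
                    raise ValueError(
                        f"record {r.chrom}:{r.pos} missing a field required by "
                        f"profile {self.profile_id!r}"
                    )
                return False
            if not cmp(value, threshold):
                return False
        if self.min_read_count is not None:
            rc, sc = r.ref_read_count, r.sample_read_count
            if rc is None and sc is None:
                if strict_fields:
                    raise ValueError(
                        f"record {r.chrom}:{r.pos} missing read counts required "
                        f"by profile {self.profile_id!r}"
                    )
                return False
            if not ((rc is not None and rc >= self.min_read_count)
                    or (sc is not None and sc >= self.min_read_count)):
                return False
        if self.min_read_count_both is not None:
            rc, sc = r.ref_read_count, r.sample_read_count
            if rc is None or sc is None:
                if strict_fields:
                    raise ValueError(
                        f"record {r.chrom}:{r.pos} missing read counts required "
                        f"by profile {self.profile_id!r}"
                    )
                return False
            if rc < self.min_read_count_both or sc < self.min_read_count_both:
                return False
        return True


#: The seven high-confidence SNV criteria used for the genome-wide catalogs.
HIGH_CONFIDENCE = FilterProfile(
    profile_id="high_confidence",
    min_score=50,
    min_allele_frequency=0.3,
    min_read_count=4,
    min_read_position_fraction=0.1,
    min_distance_to_3prime=0.1,
    min_base_quality=30,
    min_read_length=50,
)

#: Permissive profile used for the repetitive rDNA locus (depth in both).
RDNA_PERMISSIVE = FilterProfile(
    profile_id="rdna_permissive",
    min_score=50,
    min_read_count_both=10,
)

#: No-op profile (identity filter).
PERMISSIVE = FilterProfile(profile_id="permissive")

PROFILES = {
    "high_confidence": HIGH_CONFIDENCE,
    "rdna_permissive": RDNA_PERMISSIVE,
    "permissive": PERMISSIVE,
}


def filter_snvs(
    catalog: MutationCatalog,
    profile: FilterProfile,
    strict_fields: bool | None = None,
) -> MutationCatalog:
    """Keep only records passing every criterion of ``profile``."""
    strict = catalog.strict if strict_fields is None else strict_fields
    out = MutationCatalog(catalog.dataset_label, strict=catalog.strict)
    for clone_id in catalog.clones:
        out.add_clone(clone_id)
    for r in catalog.records():
        if profile.passes(r, strict_fields=strict):
            out.add(r)
    return out


def classify_zygosity(
    record: MutationRecord, hom_af_threshold: float = 0.8
) -> str:
    """``hom`` iff allele frequency >= threshold (default 0.8), else ``het``.

    An explicit hom call from the caller (``zygosity == 'hom'``) wins over
    the allele-frequency rule; a missing allele frequency gives ``unknown``.
    """
    if record.zygosity == "hom":
        return "hom"
    if record.allele_frequency is None:
        return "unknown"
    return "hom" if record.allele_frequency >= hom_af_threshold else "het"


def annotate_zygosity(
    catalog: MutationCatalog, hom_af_threshold: float = 0.8
) -> MutationCatalog:
    """Catalog copy with zygosity resolved for every record."""
    out = MutationCatalog(catalog.dataset_label, strict=catalog.strict)
    for clone_id in catalog.clones:
        out.add_clone(clone_id)
    for r in catalog.records():
        out.add(replace(r, zygosity=classify_zygosity(r, hom_af_threshold)))
    return out


def restrict_to_cg(catalog: MutationCatalog) -> MutationCatalog:
    """Keep only mutations whose reference base is C or G.

    Deaminase catalogs are overwhelmingly C:G events; A:T records (caller
    noise or unrelated processes) are excluded from all downstream analyses.
    """
    return catalog.subset(lambda r: r.ref_base in ("C", "G"))


def drop_shared(
    catalog: MutationCatalog, max_clones: int | None = None
) -> MutationCatalog:
    """Remove SNVs shared at identical (chrom, pos, alt) across many clones.

    Variants present in more than ``max_clones`` clones (default: half the
    clones) are treated as pre-existing in the transformation stock rather
    than induced, and removed entirely.
    """
    if max_clones is None:
        max_clones = max(1, catalog.n_clones // 2)
    counts: dict[tuple[str, int, str], int] = {}
    for r in catalog.records():
        key = (r.chrom, r.pos, r.alt_base)
        counts[key] = counts.get(key, 0) + 1
    return catalog.subset(
        lambda r: counts[(r.chrom, r.pos, r.alt_base)] <= max_clones
    )


# ---------------------------------------------------------------------------
# file ingestion

_TSV_COLUMNS = {
    "caller_score": "caller_score",
    "allele_frequency": "allele_frequency",
    "ref_read_count": "ref_read_count",
    "sample_read_count": "sample_read_count",
    "read_pos_fraction": "mean_read_position_fraction",
    "dist_to_3prime": "mean_distance_to_3prime",
    "base_quality": "mean_base_quality",
    "read_length": "mean_read_length",
}


def read_mutations(
    path,
    dialect: str,
    dataset_label: str | None = None,
    clone_id: str | None = None,
    strict: bool = True,
) -> MutationCatalog:
    """Read a per-clone SNV file (``TSV`` or ``VCF``) into a catalog.

    Non-SNV rows (indels, multi-allelic records) are skipped with a logged
    count.  For VCF, one clone per sample column; for TSV the ``clone_id``
    column (or the ``clone_id`` argument) attributes rows to clones.
    """
    dialect = dialect.upper()
    label = dataset_label or str(path)
    if dialect == "TSV":
        return _read_tsv(path, label, clone_id, strict)
    if dialect == "VCF":
        return _read_vcf(path, label, strict)
    raise ValueError(f"unknown mutation dialect {dialect!r}")


def _read_tsv(path, label, clone_id, strict) -> MutationCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cat = MutationCatalog(label, strict=strict)
    skipped = 0
    for row in df.itertuples(index=False):
        ref = str(row.ref)
        alt = str(row.alt)
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            skipped += 1
            continue
        kwargs = {}
        for col, attr in _TSV_COLUMNS.items():
            v = getattr(row, col, None)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                kwargs[attr] = v
        zyg = getattr(row, "zygosity", "unknown")
        if not isinstance(zyg, str):
            zyg = "unknown"
        cat.add(
            MutationRecord(
                clone_id=str(getattr(row, "clone_id", clone_id)),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_base=ref,
                alt_base=alt,
                zygosity=zyg,
                **kwargs,
            )
        )
    if skipped:
        log.info("%s: skipped %d non-SNV rows", path, skipped)
    cat.n_skipped = skipped
    return cat


def _read_vcf(path, label, strict) -> MutationCatalog:
    import pysam

    cat = MutationCatalog(label, strict=strict)
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for sample in samples:
            cat.add_clone(sample)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                skipped += 1
                continue
            score = rec.info.get("SSC")
            if isinstance(score, tuple):
                score = score[0]
            for sample in samples:
                fmt = rec.samples[sample]
                gt = fmt.get("GT")
                if gt is not None and set(g for g in gt if g is not None) == {0}:
                    continue  # sample carries only the reference allele
                af = fmt.get("AF")
                if isinstance(af, tuple):
                    af = af[0]
                if af is None and fmt.get("AD") is not None:
                    ad = fmt["AD"]
                    depth = sum(a for a in ad if a is not None)
                    if depth > 0:
                        af = ad[1] / depth
                zygosity = "unknown"
                if gt is not None and None not in gt:
                    zygosity = "hom" if len(set(gt)) == 1 and gt[0] != 0 else "het"
                cat.add(
                    MutationRecord(
                        clone_id=sample,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_base=ref,
                        alt_base=alt,
                        caller_score=float(score) if score is not None else None,
                        allele_frequency=float(af) if af is not None else None,
                        ref_read_count=_fmt_int(fmt, "RD"),
                        sample_read_count=_fmt_int(fmt, "DP"),
                        mean_base_quality=_fmt_float(fmt, "BQ"),
                        zygosity=zygosity,
                    )
                )
    if skipped:
        log.info("%s: skipped %d non-SNV records", path, skipped)
    cat.n_skipped = skipped
    return cat


def _fmt_int(fmt, key):
    v = fmt.get(key)
    if isinstance(v, tuple):
        v = v[0]
    return int(v) if v is not None else None


def _fmt_float(fmt, key):
    v = fmt.get(key)
    if isinstance(v, tuple):
        v = v[0]
    return float(v) if v is not None else None


def merge_catalogs(
    catalogs: Iterable[MutationCatalog], dataset_label: str
) -> MutationCatalog:
    """Pool several per-file catalogs; clone-id collisions are an error."""
    out = MutationCatalog(dataset_label, strict=True)
    for cat in catalogs:
        for clone_id in cat.clones:
            if clone_id in out.clones:
                raise ValueError(f"clone id {clone_id!r} appears in multiple files")
            out.add_clone(clone_id)
        for r in cat.records():
            out.add(r)
    return out
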