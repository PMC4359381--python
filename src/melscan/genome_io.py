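"""Genome sequence, motif indices and feature annotations.

All coordinates in this package are 1-based and inclusive, matching the
conventions of yeast genome browsers; BED input/output converts from the
0-based half-open convention at the boundary.

A *mutable motif site* is the cytosine a deaminase can act on, recorded at
the position of that cytosine.  Minus-strand sites appear as a G on the
stored plus strand; their context is read 5'->3' on the minus strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

MotifClass = Literal["WRC", "YCC", "C"]
VALID_MOTIF_CLASSES = ("WRC", "YCC", "C")

_VALID_BASES = set("ACGTN")

# byte codes for vectorised scans
_A, _C, _G, _T = 65, 67, 71, 84

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIndex:
    """In-memory genome with 1-based inclusive sequence access.

    Yeast-scale genomes (~12 Mb) fit comfortably in memory, so sequences are
    held as upper-case strings; byte views are cached for vectorised scans.
    """

    def __init__(self, sequences: dict[str, str]):
        self.chrom_names: list[str] = list(sequences.keys())
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-nucleotide characters: {sorted(bad)}"
                )
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has zero length")
            self._seqs[name] = seq
        self.chrom_lengths: dict[str, int] = {n: len(s) for n, s in self._seqs.items()}
        self._byte_cache: dict[str, np.ndarray] = {}

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` from ``start`` to ``end``, 1-based inclusive."""
        if start < 1 or end > self.chrom_lengths[chrom] or start > end:
            raise ValueError(
                f"query {chrom}:{start}-{end} outside bounds 1-{self.chrom_lengths[chrom]}"
            )
        return self._seqs[chrom][start - 1 : end]

    def byte_view(self, chrom: str) -> np.ndarray:
        """Read-only uint8 view of the chromosome sequence (0-based)."""
        if chrom not in self._byte_cache:
            arr = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
            self._byte_cache[chrom] = arr
        return self._byte_cache[chrom]

    def reverse_complement(self) -> "GenomeIndex":
        """A genome with every chromosome reverse-complemented (for symmetry checks)."""
        return GenomeIndex({n: revcomp(s) for n, s in self._seqs.items()})

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f">{name}\n")
                seq = self._seqs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> GenomeIndex:
    """Load a (multi-record) FASTA into a :class:`GenomeIndex`.

    Record order is preserved; duplicate headers are an error; lowercase
    sequence is upper-cased on load.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate chromosome name {record.id!r} in {path}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeIndex(sequences)


@dataclass
class MotifIndex:
    """Strand-resolved positions of mutable cytosines for one motif class.

    ``plus`` holds positions (1-based) of Cs whose 5' dinucleotide context on
    the plus strand matches the class pattern; ``minus`` holds plus-strand
    coordinates of Gs that are class-matching Cs on the minus strand.
    """

    motif_class: MotifClass
    plus: dict[str, np.ndarray] = field(default_factory=dict)
    minus: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_sites(self) -> int:
        return sum(len(v) for v in self.plus.values()) + sum(
            len(v) for v in self.minus.values()
        )

    def sites(self) -> Iterator[tuple[str, int, str]]:
        for chrom, arr in self.plus.items():
            for pos in arr:
                yield chrom, int(pos), "+"
        for chrom, arr in self.minus.items():
            for pos in arr:
                yield chrom, int(pos), "-"

    def flat_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(chrom_index, position, strand_is_minus) arrays over all sites.

        chrom_index refers to the order of ``sorted(set(chroms))`` as returned
        by :meth:`chrom_order`.  Used for weighted site sampling.
        """
        chroms = self.chrom_order()
        cidx, pos, minus = [], [], []
        for i, c in enumerate(chroms):
            p = self.plus.get(c, np.empty(0, dtype=np.int64))
            m = self.minus.get(c, np.empty(0, dtype=np.int64))
            cidx.append(np.full(len(p), i, dtype=np.int32))
            pos.append(p)
            minus.append(np.zeros(len(p), dtype=bool))
            cidx.append(np.full(len(m), i, dtype=np.int32))
            pos.append(m)
            minus.append(np.ones(len(m), dtype=bool))
        if not cidx:
            return (
                np.empty(0, dtype=np.int32),
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=bool),
            )
        return np.concatenate(cidx), np.concatenate(pos), np.concatenate(minus)

    def chrom_order(self) -> list[str]:
        return sorted(set(self.plus) | set(self.minus))

    def contains(self, chrom: str, pos: int, strand: str) -> bool:
        table = self.plus if strand == "+" else self.minus
        arr = table.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        i = np.searchsorted(arr, pos)
        return i < len(arr) and arr[i] == pos


def _mask(arr: np.ndarray, bases: tuple[int, ...]) -> np.ndarray:
    m = np.zeros(len(arr), dtype=bool)
    for b in bases:
        m |= arr == b
    return m


def scan_motifs(genome: GenomeIndex, motif_class: MotifClass) -> MotifIndex:
    """Index every mutable cytosine of ``motif_class`` on both strands.

    Plus-strand sites are Cs preceded (5') by a matching dinucleotide on the
    plus strand; minus-strand sites are plus-strand Gs whose two *following*
    plus-strand bases complement the pattern.  ``N`` never matches any IUPAC
    code.  Class ``C`` has no context requirement.
    """
    if motif_class not in VALID_MOTIF_CLASSES:
        raise ValueError(f"unknown motif class {motif_class!r}")
    index = MotifIndex(motif_class=motif_class)
    for chrom in genome.chrom_names:
        seq = genome.byte_view(chrom)
        is_c = seq == _C
        is_g = seq == _G
        if motif_class == "C":
            plus = np.flatnonzero(is_c)
            minus = np.flatnonzero(is_g)
        else:
            if motif_class == "WRC":
                m2 = (_A, _T)       # W two bases 5' of the C
                m1 = (_A, _G)       # R immediately 5' of the C
                r1 = (_T, _C)       # complement of R, plus-strand base after the G
                r2 = (_T, _A)       # complement of W, two after the G
            else:  # YCC
                m2 = (_C, _T)       # Y
                m1 = (_C, _T)       # second Y (the middle C of YCC is Y-matching)
                r1 = (_G, _A)
                r2 = (_G, _A)
            # the YCC middle base must literally be C; encode patterns exactly
            if motif_class == "YCC":
                m1 = (_C,)
                r1 = (_G,)
            plus = np.zeros(len(seq), dtype=bool)
            plus[2:] = is_c[2:] & _mask(seq[:-2], m2) & _mask(seq[1:-1], m1)
            minus = np.zeros(len(seq), dtype=bool)
            minus[:-2] = is_g[:-2] & _mask(seq[1:-1], r1) & _mask(seq[2:], r2)
            plus = np.flatnonzero(plus)
            minus = np.flatnonzero(minus)
        index.plus[chrom] = (plus + 1).astype(np.int64)
        index.minus[chrom] = (minus + 1).astype(np.int64)
    return index


@dataclass
class Feature:
    """One annotated genomic element (gene, ARS, TATA-bearing promoter owner)."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str = "other"  # mRNA, tRNA, snoRNA, snRNA, ARS, other
    tata_pos: Optional[int] = None
    tx_rate: Optional[float] = None
    taf1: Optional[str] = None
    host_feature_id: Optional[str] = None  # intronic snoRNAs: the host mRNA gene
    cluster_id: Optional[str] = None       # polycistronic snoRNA cluster

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"feature {self.feature_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.feature_id}: unknown strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start: 5' end on the feature strand."""
        return self.start if self.strand != "-" else self.end

    @property
    def tts(self) -> int:
        """Transcription termination: 3' end on the feature strand."""
        return self.end if self.strand != "-" else self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class FeatureSet:
    """Collection of features with per-chromosome interval lookup."""

    def __init__(self, features: list[Feature]):
        self.features = list(features)
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def by_class(self, *classes: str) -> "FeatureSet":
        return FeatureSet([f for f in self.features if f.feature_class in classes])

    def by_id(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def _ensure_trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for f in self.features:
                trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end + 1, f)
            self._trees = trees
        return self._trees

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        trees = self._ensure_trees()
        if chrom not in trees:
            return []
        return [iv.data for iv in trees[chrom].overlap(start, end + 1)]

    def intervals(self) -> list[tuple[str, int, int]]:
        return [(f.chrom, f.start, f.end) for f in self.features]


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")

# SGD-style feature types mapped onto the classes the analysis distinguishes
_DEFAULT_CLASS_MAP = {
    "gene": "mRNA",
    "mRNA": "mRNA",
    "tRNA": "tRNA",
    "tRNA_gene": "tRNA",
    "snoRNA": "snoRNA",
    "snoRNA_gene": "snoRNA",
    "snRNA": "snRNA",
    "snRNA_gene": "snRNA",
    "ARS": "ARS",
    "origin_of_replication": "ARS",
}


def read_annotations(path, dialect: str, class_map: dict | None = None) -> FeatureSet:
    """Read features from GFF3, 6-column BED or headered TSV.

    Coordinates are normalised to 1-based inclusive; BED converts from
    0-based half-open.  The TSV dialect expects the header
    ``feature_id chrom start end strand class [tata_pos] [tx_rate] [taf1]
    [host_feature_id] [cluster_id]``.
    """
    dialect = dialect.upper()
    if dialect == "TSV":
        return _read_tsv(path)
    if dialect == "BED":
        return _read_bed(path, class_map or {})
    if dialect == "GFF3":
        return _read_gff3(path, class_map)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_tsv(path) -> FeatureSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "feature_id": str})
    required = {"feature_id", "chrom", "start", "end", "strand", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSV annotation missing columns: {sorted(missing)}")
    df = df.rename(columns={"class": "feature_class"})
    feats = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            feats.append(
                Feature(
                    feature_id=str(row.feature_id),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                    feature_class=str(row.feature_class),
                    tata_pos=_opt_int(getattr(row, "tata_pos", None)),
                    tx_rate=_opt_float(getattr(row, "tx_rate", None)),
                    taf1=_opt_str(getattr(row, "taf1", None)),
                    host_feature_id=_opt_str(getattr(row, "host_feature_id", None)),
                    cluster_id=_opt_str(getattr(row, "cluster_id", None)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return FeatureSet(feats)


def _opt_int(v):
    import pandas as pd

    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    return int(v)


def _opt_float(v):
    import pandas as pd

    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    return float(v)


def _opt_str(v):
    import pandas as pd

    if v is None or (not isinstance(v, str) and pd.isna(v)):
        return None
    return str(v)


def _read_bed(path, class_map: dict) -> FeatureSet:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path} line {lineno}: fewer than 3 BED columns")
            chrom, bed_start, bed_end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"bed_{lineno}"
            strand = parts[5] if len(parts) > 5 else "."
            try:
                feats.append(
                    Feature(
                        feature_id=name,
                        chrom=chrom,
                        start=bed_start + 1,  # 0-based half-open -> 1-based inclusive
                        end=bed_end,
                        strand=strand,
                        feature_class=class_map.get(name, class_map.get("*", "other")),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
    return FeatureSet(feats)


def _read_gff3(path, class_map: dict | None) -> FeatureSet:
    cmap = dict(_DEFAULT_CLASS_MAP)
    if class_map:
        cmap.update(class_map)
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path} line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in cmap:
                continue
            attr = dict(_GFF_ATTR.findall(attrs))
            fid = attr.get("ID") or attr.get("Name") or f"{ftype}_{lineno}"
            try:
                feats.append(
                    Feature(
                        feature_id=fid,
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        feature_class=cmap[ftype],
                        tata_pos=int(attr["tata_pos"]) if "tata_pos" in attr else None,
                        tx_rate=float(attr["tx_rate"]) if "tx_rate" in attr else None,
                        taf1=attr.get("taf1"),
                        host_feature_id=attr.get("host"),
                        cluster_id=attr.get("cluster"),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
    return FeatureSet(feats)
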