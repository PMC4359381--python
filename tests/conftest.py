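"""Shared fixtures: tiny handcrafted genomes and a seeded synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from melscan import (
    GenomeIndex,
    MutationCatalog,
    MutationRecord,
    SyntheticSpec,
    build_study,
)

#: caller fields that pass the high-confidence profile, for handcrafted records
PASSING_FIELDS = dict(
    caller_score=99.0,
    allele_frequency=0.5,
    ref_read_count=20,
    sample_read_count=20,
    mean_read_position_fraction=0.5,
    mean_distance_to_3prime=0.5,
    mean_base_quality=35.0,
    mean_read_length=100.0,
)


def make_record(clone, chrom, pos, ref="C", alt=None, **overrides) -> MutationRecord:
    if alt is None:
        alt = {"C": "T", "G": "A", "A": "G", "T": "C"}[ref]
    fields = dict(PASSING_FIELDS)
    fields.update(overrides)
    return MutationRecord(
        clone_id=clone, chrom=chrom, pos=pos, ref_base=ref, alt_base=alt, **fields
    )


def make_catalog(entries, label="toy") -> MutationCatalog:
    """Catalog from (clone, chrom, pos[, ref]) tuples."""
    cat = MutationCatalog(label, strict=True)
    for entry in entries:
        cat.add(make_record(*entry))
    return cat


@pytest.fixture
def tiny_genome() -> GenomeIndex:
    return GenomeIndex({"chr1": "TAACGTTACCGGCATN" * 4})


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A compact two-chromosome study at calibrated mutation density."""
    return SyntheticSpec.density_matched(
        chrom_lengths={"chrA": 180_000, "chrB": 120_000},
        n_mrna=30,
        n_trna=8,
        n_snorna=4,
        n_snrna=2,
        n_ars=4,
        n_clones=20,
        n_hotspots=8,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    return build_study(small_spec, seed=11)


@pytest.fixture(scope="session")
def toy_study():
    """The default 1 Mb study at calibrated (paper-matched) density."""
    return build_study(SyntheticSpec.density_matched(), seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
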