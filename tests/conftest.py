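"""Shared fixtures: small hand-built pedigrees and variant records."""

from __future__ import annotations

import itertools

import pytest

from pedseg.pedio import Affection, Individual, Pedigree, Sex
from pedseg.variant_io import GenotypeCall, VariantRecord


def make_individual(
    iid,
    father=None,
    mother=None,
    sex=Sex.UNKNOWN,
    affection=Affection.UNKNOWN,
    family="F1",
):
    return Individual(family, iid, father, mother, sex, affection)


def make_record(
    genotypes: dict[str, tuple[int, ...] | None],
    chrom: str = "chr1",
    pos: int = 100,
    af: float | None = 0.001,
    depth: int | None = 30,
    consequences=("missense_variant",),
    filter_status: str = "pass",
    depths: dict[str, int | None] | None = None,
) -> VariantRecord:
    calls = {}
    for sample, alleles in genotypes.items():
        dp = depths.get(sample, depth) if depths else depth
        calls[sample] = GenotypeCall(alleles, dp)
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        filter_status=filter_status,
        pop_af=af,
        consequences=frozenset(consequences),
        calls=calls,
    )


DIPLOID = [(0, 0), (0, 1), (1, 1)]


def enumerate_records(sample_ids, chrom="chr1", **kwargs):
    """One record per genotype assignment over the samples (3^n records)."""
    records = []
    for i, combo in enumerate(itertools.product(DIPLOID, repeat=len(sample_ids))):
        records.append(
            make_record(
                dict(zip(sample_ids, combo)), chrom=chrom, pos=(i + 1) * 10, **kwargs
            )
        )
    return records


@pytest.fixture
def trio_ped() -> Pedigree:
    members = [
        make_individual("father", sex=Sex.MALE, affection=Affection.UNAFFECTED),
        make_individual("mother", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
        make_individual(
            "index", "father", "mother", sex=Sex.MALE, affection=Affection.AFFECTED
        ),
    ]
    return Pedigree(family_id="F1", members=members, index_id="index")


@pytest.fixture
def sibship_ped() -> Pedigree:
    """Index + 2 affected + 2 unaffected siblings; parents present, untyped."""
    U, A = Affection.UNAFFECTED, Affection.AFFECTED
    members = [
        make_individual("father", sex=Sex.MALE, affection=U),
        make_individual("mother", sex=Sex.FEMALE, affection=U),
        make_individual("index", "father", "mother", Sex.FEMALE, A),
        make_individual("aff1", "father", "mother", Sex.MALE, A),
        make_individual("aff2", "father", "mother", Sex.FEMALE, A),
        make_individual("un1", "father", "mother", Sex.MALE, U),
        make_individual("un2", "father", "mother", Sex.FEMALE, U),
    ]
    return Pedigree(family_id="F1", members=members, index_id="index")


@pytest.fixture
def quintet_ped() -> Pedigree:
    U, A = Affection.UNAFFECTED, Affection.AFFECTED
    members = [
        make_individual("father", sex=Sex.MALE, affection=U),
        make_individual("mother", sex=Sex.FEMALE, affection=U),
        make_individual("index", "father", "mother", Sex.MALE, A),
        make_individual("sib1", "father", "mother", Sex.FEMALE, A),
        make_individual("sib2", "father", "mother", Sex.MALE, U),
    ]
    return Pedigree(family_id="F1", members=members, index_id="index")
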