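"""Candidate-variant selection by family segregation.

The filters implemented here mirror the clinical shared/nonshared logic for
families ascertained through one affected index:

* recessive (homozygous) model — the index and every affected relative are
  homozygous for the alt allele, each unaffected parent is an obligate
  heterozygous carrier, and no unaffected relative is homozygous (carriers
  are allowed);
* de novo (heterozygous) model — the index and affected relatives carry the
  alt allele while the parents and unaffected relatives are homozygous
  reference.  With fully penetrant disease and unaffected parents this is
  the only consistent reading of heterozygous trio candidates; an
  "inherited" relaxation that lets parents and unaffected members carry one
  alt allele is available for sensitivity analysis.

Genotypes downgraded to MISSING (no call, or depth below threshold) are
non-informative by default: they neither satisfy nor violate a constraint,
except for the index, whose call anchors the analysis and must be
informative.  A strict policy that treats MISSING as incompatible is
available.

Candidate sets are stratified coding/noncoding (by most severe consequence)
and homozygous/heterozygous (by the index's zygosity).  Variants on male X
count as homozygous.  Mitochondrial sites are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .annotate import CODING, GeneModel, SeverityRanking, classify_region, default_ranking
from .genofilter import (
    FilterConfig,
    Zygosity,
    call_passes,
    effective_zygosity,
    is_mitochondrial,
    site_passes,
    zygosity as _zygosity,
)
from .pedio import Affection, Individual, Pedigree, MemberAdditionPlan, role_sets
from .variant_io import VariantRecord


class SegregationError(ValueError):
    """Raised when a filter is applied to an unsuitable family structure."""


class InheritanceModel(str, Enum):
    RECESSIVE = "recessive"
    DE_NOVO = "denovo"
    BOTH = "both"


class Role(str, Enum):
    INDEX = "index"
    PARENT = "parent"
    AFFECTED = "affected_relative"
    UNAFFECTED = "unaffected_relative"


PERMISSIVE = "permissive"
STRICT = "strict"

_SINGLE_MODELS = (InheritanceModel.RECESSIVE, InheritanceModel.DE_NOVO)


def _allowed_codes(
    model: InheritanceModel,
    role: Role,
    missing_policy: str = PERMISSIVE,
    het_mode: str = "denovo",
) -> frozenset[int]:
    """Zygosity codes compatible with ``role`` under a single model."""
    Z = Zygosity
    if model is InheritanceModel.RECESSIVE:
        table = {
            Role.INDEX: {Z.HOM_ALT},
            Role.AFFECTED: {Z.HOM_ALT},
            Role.PARENT: {Z.HET},
            Role.UNAFFECTED: {Z.HOM_REF, Z.HET},
        }
    elif model is InheritanceModel.DE_NOVO:
        if het_mode == "inherited":
            table = {
                Role.INDEX: {Z.HET, Z.HOM_ALT},
                Role.AFFECTED: {Z.HET, Z.HOM_ALT},
                Role.PARENT: {Z.HOM_REF, Z.HET},
                Role.UNAFFECTED: {Z.HOM_REF, Z.HET},
            }
        else:
            table = {
                Role.INDEX: {Z.HET, Z.HOM_ALT},
                Role.AFFECTED: {Z.HET, Z.HOM_ALT},
                Role.PARENT: {Z.HOM_REF},
                Role.UNAFFECTED: {Z.HOM_REF},
            }
    else:
        raise ValueError("allowed codes are defined per single model")
    allowed = {int(z) for z in table[role]}
    if role is not Role.INDEX and missing_policy == PERMISSIVE:
        allowed.add(int(Z.MISSING))
    return frozenset(allowed)


def member_compatible(
    record: VariantRecord,
    member: Individual,
    model: InheritanceModel,
    role: Role,
    cfg: FilterConfig | None = None,
    missing_policy: str = PERMISSIVE,
    het_mode: str = "denovo",
) -> bool:
    """Is one member's (depth-filtered) genotype compatible with its role?

    Under ``both`` a member is compatible when either single model accepts
    it; full-family candidacy under ``both`` is decided per model across all
    members, not member-by-member.
    """
    cfg = cfg if cfg is not None else FilterConfig()
    z = int(effective_zygosity(record, member.individual_id, member.sex, cfg))
    if model is InheritanceModel.BOTH:
        return any(
            z in _allowed_codes(m, role, missing_policy, het_mode)
            for m in _SINGLE_MODELS
        )
    return z in _allowed_codes(model, role, missing_policy, het_mode)


# ---------------------------------------------------------------------------
# candidate sets


@dataclass(frozen=True)
class CandidateVariant:
    key: tuple[str, int, str, str]
    region: str
    index_zygosity: Zygosity


@dataclass
class StratumCounts:
    hom: int = 0
    het: int = 0

    @property
    def total(self) -> int:
        return self.hom + self.het


@dataclass
class CandidateSet:
    """Variants surviving the filters, with coding x zygosity strata."""

    variants: list[CandidateVariant] = field(default_factory=list)

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def _counts(self, region: str) -> StratumCounts:
        hom = sum(
            1 for v in self.variants
            if v.region == region and v.index_zygosity is Zygosity.HOM_ALT
        )
        het = sum(
            1 for v in self.variants
            if v.region == region and v.index_zygosity is Zygosity.HET
        )
        return StratumCounts(hom=hom, het=het)

    @property
    def coding(self) -> StratumCounts:
        return self._counts(CODING)

    @property
    def noncoding(self) -> StratumCounts:
        return self._counts("noncoding")

    @property
    def total(self) -> int:
        return len(self.variants)


@dataclass
class ReductionStep:
    label: str
    member_added: str | None
    candidates: CandidateSet

    @property
    def total(self) -> int:
        return self.candidates.total


@dataclass
class ReductionCurve:
    """Candidate counts as family members are added (Index -> ... -> Octet)."""

    steps: list[ReductionStep]

    def totals(self) -> list[int]:
        return [s.total for s in self.steps]

    def labels(self) -> list[str]:
        return [s.label for s in self.steps]


@dataclass
class StrategyComparison:
    trio_candidate_count: int
    sibship_candidate_count: int
    shared_among_affected_sibs: int | None = None
    shared_among_unaffected_sibs: int | None = None


# ---------------------------------------------------------------------------
# vectorized engine


def derive_roles(ped: Pedigree, tested: Iterable[str]) -> dict[str, Role | None]:
    """Assign a segregation role to every tested member.

    The index's parents act as transmitting parents when not affected
    themselves; everyone else follows affection status.  Unknown-affection
    members (other than the index's parents) impose no constraint.
    """
    roles: dict[str, Role | None] = {}
    index = ped.index
    parent_ids = {p for p in (index.father_id, index.mother_id) if p}
    for mid in tested:
        m = ped.member(mid)
        if mid == ped.index_id:
            roles[mid] = Role.INDEX
        elif mid in parent_ids and m.affection is not Affection.AFFECTED:
            roles[mid] = Role.PARENT
        elif m.affection is Affection.AFFECTED:
            roles[mid] = Role.AFFECTED
        elif m.affection is Affection.UNAFFECTED:
            roles[mid] = Role.UNAFFECTED
        else:
            roles[mid] = None
    return roles


class SegregationEngine:
    """Precomputed per-site matrices for repeated candidate-set queries.

    Building the zygosity matrix once lets the incremental analysis evaluate
    each member-addition step as a vectorized constraint intersection.
    """

    def __init__(
        self,
        records: Sequence[VariantRecord],
        ped: Pedigree,
        cfg: FilterConfig | None = None,
        ranking: SeverityRanking | None = None,
        gene_model: GeneModel | None = None,
        missing_policy: str = PERMISSIVE,
        het_mode: str = "denovo",
    ):
        self.records = list(records)
        self.ped = ped
        self.cfg = cfg if cfg is not None else FilterConfig()
        self.ranking = ranking if ranking is not None else default_ranking()
        self.gene_model = gene_model
        self.missing_policy = missing_policy
        self.het_mode = het_mode

        n = len(self.records)
        self.site_ok = np.empty(n, dtype=bool)
        self.coding = np.empty(n, dtype=bool)
        # members with a genotype column in the data
        present: list[str] = []
        if self.records:
            sample_ids = set(self.records[0].calls)
            present = [m.individual_id for m in ped.members if m.individual_id in sample_ids]
        self.member_ids = present
        self._zyg: dict[str, np.ndarray] = {
            mid: np.empty(n, dtype=np.int8) for mid in present
        }
        self._depth_ok: dict[str, np.ndarray] = {
            mid: np.empty(n, dtype=bool) for mid in present
        }
        sexes = {mid: ped.member(mid).sex for mid in present}
        cfg_ = self.cfg
        for i, r in enumerate(self.records):
            self.site_ok[i] = site_passes(r, cfg_) and not is_mitochondrial(r.chrom)
            self.coding[i] = (
                classify_region(r, self.ranking, self.gene_model) == CODING
            )
            for mid in present:
                call = r.calls.get(mid)
                dp_ok = call is not None and call_passes(call, cfg_)
                self._depth_ok[mid][i] = dp_ok
                if not dp_ok:
                    self._zyg[mid][i] = int(Zygosity.MISSING)
                else:
                    self._zyg[mid][i] = int(_zygosity(call, r.chrom, sexes[mid]))

    def _model_mask(self, tested: Sequence[str], model: InheritanceModel) -> np.ndarray:
        roles = derive_roles(self.ped, tested)
        mask = self.site_ok.copy()
        if self.cfg.depth_scope == "site":
            for mid in tested:
                if mid in self._depth_ok:
                    mask &= self._depth_ok[mid]
        models = _SINGLE_MODELS if model is InheritanceModel.BOTH else (model,)
        union = np.zeros(len(self.records), dtype=bool)
        for m in models:
            ok = np.ones(len(self.records), dtype=bool)
            for mid in tested:
                role = roles[mid]
                if role is None:
                    continue
                if mid not in self._zyg:
                    raise SegregationError(
                        f"tested member {mid!r} has no genotype column"
                    )
                allowed = _allowed_codes(m, role, self.missing_policy, self.het_mode)
                ok &= np.isin(self._zyg[mid], list(allowed))
            union |= ok
        return mask & union

    def candidate_set(
        self, tested: Sequence[str], model: InheritanceModel
    ) -> CandidateSet:
        tested = list(tested)
        if not tested:
            raise SegregationError("tested member set is empty")
        if self.ped.index_id not in tested:
            raise SegregationError(
                f"index {self.ped.index_id!r} must be among the tested members"
            )
        if not self.records:
            return CandidateSet(variants=[])
        mask = self._model_mask(tested, model)
        izyg = self._zyg.get(self.ped.index_id)
        if izyg is None:
            raise SegregationError("index has no genotype column")
        variants = [
            CandidateVariant(
                key=self.records[i].key,
                region=CODING if self.coding[i] else "noncoding",
                index_zygosity=Zygosity(int(izyg[i])),
            )
            for i in np.flatnonzero(mask)
        ]
        return CandidateSet(variants=variants)


# ---------------------------------------------------------------------------
# public operations


def segregation_filter(
    records: Sequence[VariantRecord],
    ped: Pedigree,
    tested: Iterable[str],
    model: InheritanceModel = InheritanceModel.BOTH,
    cfg: FilterConfig | None = None,
    **engine_kwargs,
) -> CandidateSet:
    """Retain sites compatible with every tested member's role."""
    engine = SegregationEngine(records, ped, cfg=cfg, **engine_kwargs)
    return engine.candidate_set(list(tested), model)


def trio_filter(
    records: Sequence[VariantRecord],
    ped: Pedigree,
    cfg: FilterConfig | None = None,
    model: InheritanceModel = InheritanceModel.BOTH,
    **engine_kwargs,
) -> CandidateSet:
    """Index + both parents; recessive stratum is the parental-het rule."""
    index = ped.index
    if index.father_id is None or index.mother_id is None or (
        index.father_id not in ped or index.mother_id not in ped
    ):
        raise SegregationError(
            "trio analysis requires both parents of the index in the pedigree"
        )
    tested = [ped.index_id, index.father_id, index.mother_id]
    return segregation_filter(records, ped, tested, model, cfg, **engine_kwargs)


def sibship_filter(
    records: Sequence[VariantRecord],
    ped: Pedigree,
    cfg: FilterConfig | None = None,
    model: InheritanceModel = InheritanceModel.BOTH,
    **engine_kwargs,
) -> CandidateSet:
    """Index + siblings, parents never consulted even if genotyped."""
    sibs = sorted(role_sets(ped).siblings_of_index)
    if not sibs:
        raise SegregationError("sibship analysis requires at least one sibling")
    tested = [ped.index_id] + sibs
    return segregation_filter(records, ped, tested, model, cfg, **engine_kwargs)


def incremental_reduction(
    records: Sequence[VariantRecord],
    ped: Pedigree,
    plan: MemberAdditionPlan,
    model: InheritanceModel = InheritanceModel.BOTH,
    cfg: FilterConfig | None = None,
    **engine_kwargs,
) -> ReductionCurve:
    """Candidate counts after each member addition; sets are nested."""
    engine = SegregationEngine(records, ped, cfg=cfg, **engine_kwargs)
    steps = []
    for k in range(1, len(plan) + 1):
        tested = list(plan.members[:k])
        cs = engine.candidate_set(tested, model)
        steps.append(
            ReductionStep(
                label=plan.labels[k - 1],
                member_added=plan.members[k - 1] if k > 1 else None,
                candidates=cs,
            )
        )
    return ReductionCurve(steps=steps)


def reduction_percentages(curve: ReductionCurve) -> list[float]:
    """Per-step percent drops: 100 * (1 - total_k / total_{k-1}).

    A zero previous total yields a drop of 0 by convention.
    """
    totals = curve.totals()
    if len(totals) < 2:
        raise SegregationError("reduction percentages need at least two steps")
    drops = []
    for prev, cur in zip(totals, totals[1:]):
        drops.append(0.0 if prev == 0 else 100.0 * (1.0 - cur / prev))
    return drops


def compare_trio_vs_sibship(
    records: Sequence[VariantRecord],
    ped: Pedigree,
    cfg: FilterConfig | None = None,
    **engine_kwargs,
) -> StrategyComparison:
    """Coding recessive candidate counts: trio versus sibship strategy.

    Also counts coding sites homozygous-alt in every affected sibship member
    (index included) and in every unaffected sibling, when those sets exist.
    """
    roles = role_sets(ped)
    index = ped.index
    if index.father_id is None or index.mother_id is None:
        raise SegregationError("strategy comparison requires both parents")
    if len(roles.siblings_of_index) < 2:
        raise SegregationError(
            "strategy comparison requires at least two siblings of the index"
        )
    engine = SegregationEngine(records, ped, cfg=cfg, **engine_kwargs)
    trio_cs = engine.candidate_set(
        [ped.index_id, index.father_id, index.mother_id], InheritanceModel.BOTH
    )
    sibs = sorted(roles.siblings_of_index)
    sib_cs = engine.candidate_set([ped.index_id] + sibs, InheritanceModel.BOTH)

    def shared_hom(member_ids: list[str]) -> int | None:
        ids = [m for m in member_ids if m in engine._zyg]
        if not ids:
            return None
        mask = engine.site_ok & engine.coding
        for mid in ids:
            mask &= engine._zyg[mid] == int(Zygosity.HOM_ALT)
        return int(mask.sum())

    affected_sibship = [ped.index_id] + [
        s for s in sibs if s in roles.affected
    ]
    unaffected_sibs = [s for s in sibs if s in roles.unaffected]
    return StrategyComparison(
        trio_candidate_count=trio_cs.coding.hom,
        sibship_candidate_count=sib_cs.coding.hom,
        shared_among_affected_sibs=shared_hom(affected_sibship),
        shared_among_unaffected_sibs=(
            shared_hom(unaffected_sibs) if unaffected_sibs else None
        ),
    )


def candidates_tsv(
    cs: CandidateSet,
    records: Sequence[VariantRecord],
    tested: Sequence[str],
) -> str:
    """Render a candidate set as TSV with per-member genotype strings."""
    by_key = {r.key: r for r in records}
    lines = [
        "\t".join(
            ["chrom", "pos", "ref", "alt", "region", "index_zygosity"]
            + list(tested)
        )
    ]
    for v in sorted(cs.variants, key=lambda v: v.key):
        rec = by_key[v.key]
        gts = []
        for mid in tested:
            call = rec.calls.get(mid)
            if call is None or call.alleles is None:
                gts.append("./.")
            else:
                gts.append("/".join(str(a) for a in call.alleles))
        lines.append(
            "\t".join(
                [v.key[0], str(v.key[1]), v.key[2], v.key[3], v.region,
                 v.index_zygosity.name] + gts
            )
        )
    return "\n".join(lines) + "\n"
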