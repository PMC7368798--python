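"""Segregation filtering against an independent brute-force oracle.

The oracle below re-derives retention per variant per member straight from
the stated rules (recessive: homozygous index/affecteds, het parents,
no homozygous unaffected; de novo: carrier index/affecteds, hom-ref parents
and unaffecteds), with its own zygosity and role logic and no vectorized
machinery.
"""

import pytest

from pedseg.genofilter import FilterConfig
from pedseg.pedio import Affection, addition_order, Pedigree, Sex
from pedseg.segregation import (
    InheritanceModel,
    Role,
    SegregationError,
    compare_trio_vs_sibship,
    incremental_reduction,
    member_compatible,
    reduction_percentages,
    segregation_filter,
    sibship_filter,
    trio_filter,
)
from pedseg.simulate import SimulationConfig, simulate_genotypes

from conftest import enumerate_records, make_individual, make_record

R = InheritanceModel.RECESSIVE
D = InheritanceModel.DE_NOVO
BOTH = InheritanceModel.BOTH


# --- independent oracle ----------------------------------------------------

def _oracle_zyg(call, chrom, sex):
    if call is None or call.alleles is None or call.depth is None or call.depth < 20:
        return "missing"
    if sex is Sex.MALE and chrom.lower().lstrip("chr") in ("x", "y"):
        return "hom_alt" if 1 in call.alleles else "hom_ref"
    n = sum(call.alleles) if len(call.alleles) == 2 else 2 * call.alleles[0]
    return ["hom_ref", "het", "hom_alt"][n]


def _oracle_role(ped, mid):
    if mid == ped.index_id:
        return "index"
    m = ped.member(mid)
    index = ped.index
    if mid in (index.father_id, index.mother_id) and m.affection is not Affection.AFFECTED:
        return "parent"
    if m.affection is Affection.AFFECTED:
        return "affected"
    if m.affection is Affection.UNAFFECTED:
        return "unaffected"
    return None


def _oracle_member_ok(z, model, role):
    if z == "missing":
        return role != "index"
    if model is R:
        return {
            "index": z == "hom_alt",
            "affected": z == "hom_alt",
            "parent": z == "het",
            "unaffected": z != "hom_alt",
        }[role]
    return {
        "index": z in ("het", "hom_alt"),
        "affected": z in ("het", "hom_alt"),
        "parent": z == "hom_ref",
        "unaffected": z == "hom_ref",
    }[role]


def oracle_retained_keys(records, ped, tested, model):
    keys = set()
    for rec in records:
        if rec.filter_status != "pass":
            continue
        if rec.pop_af is not None and rec.pop_af >= 0.015:
            continue
        if rec.chrom.lower().lstrip("chr") in ("m", "mt"):
            continue
        models = [R, D] if model is BOTH else [model]
        for m in models:
            ok = True
            for mid in tested:
                role = _oracle_role(ped, mid)
                if role is None:
                    continue
                z = _oracle_zyg(rec.calls.get(mid), rec.chrom, ped.member(mid).sex)
                if not _oracle_member_ok(z, m, role):
                    ok = False
                    break
            if ok:
                keys.add(rec.key)
                break
    return keys


# --- exhaustive enumeration ------------------------------------------------

class TestTrioEnumeration:
    """All 27 diploid trio genotype assignments at one autosomal site."""

    @pytest.fixture()
    def records(self):
        return enumerate_records(["index", "father", "mother"])

    def test_recessive_retains_exactly_parental_het_pattern(self, trio_ped, records):
        cs = segregation_filter(records, trio_ped, ["index", "father", "mother"], R)
        assert cs.total == 1
        (kept,) = cs.variants
        rec = next(r for r in records if r.key == kept.key)
        assert rec.calls["index"].alleles == (1, 1)
        assert rec.calls["father"].alleles == (0, 1)
        assert rec.calls["mother"].alleles == (0, 1)

    def test_de_novo_retains_exactly_two_assignments(self, trio_ped, records):
        cs = segregation_filter(records, trio_ped, ["index", "father", "mother"], D)
        assert cs.total == 2
        for v in cs.variants:
            rec = next(r for r in records if r.key == v.key)
            assert rec.calls["father"].alleles == (0, 0)
            assert rec.calls["mother"].alleles == (0, 0)
            assert rec.calls["index"].alleles in ((0, 1), (1, 1))

    def test_both_is_union_and_matches_oracle(self, trio_ped, records):
        tested = ["index", "father", "mother"]
        both = segregation_filter(records, trio_ped, tested, BOTH)
        rec_keys = segregation_filter(records, trio_ped, tested, R).keys
        dn_keys = segregation_filter(records, trio_ped, tested, D).keys
        assert both.keys == rec_keys | dn_keys
        assert both.keys == oracle_retained_keys(records, trio_ped, tested, BOTH)

    def test_index_only_recessive_is_all_homozygous_sites(self, trio_ped, records):
        cs = segregation_filter(records, trio_ped, ["index"], R)
        expected = {
            r.key for r in records if r.calls["index"].alleles == (1, 1)
        }
        assert cs.keys == expected


class TestSibshipEnumeration:
    """All 243 assignments over index + 2 affected + 2 unaffected sibs."""

    def test_recessive_retains_exactly_four(self, sibship_ped):
        samples = ["index", "aff1", "aff2", "un1", "un2"]
        records = enumerate_records(samples)
        cs = sibship_filter(records, sibship_ped, model=R)
        assert cs.total == 4
        for v in cs.variants:
            rec = next(r for r in records if r.key == v.key)
            for aff in ("index", "aff1", "aff2"):
                assert rec.calls[aff].alleles == (1, 1)
            for un in ("un1", "un2"):
                assert rec.calls[un].alleles in ((0, 0), (0, 1))
        assert cs.keys == oracle_retained_keys(
            records, sibship_ped, samples, R
        )

    def test_all_homozygous_sibs_not_retained(self, sibship_ped):
        rec = make_record(
            {s: (1, 1) for s in ["index", "aff1", "aff2", "un1", "un2"]}
        )
        cs = sibship_filter([rec], sibship_ped, model=R)
        assert cs.total == 0

    def test_parents_not_consulted_even_if_typed(self, sibship_ped):
        # parental genotypes violate the trio rule but sibship ignores them
        rec = make_record(
            {
                "father": (1, 1),
                "mother": (0, 0),
                "index": (1, 1),
                "aff1": (1, 1),
                "aff2": (1, 1),
                "un1": (0, 1),
                "un2": (0, 0),
            }
        )
        cs = sibship_filter([rec], sibship_ped, model=R)
        assert cs.total == 1

    def test_no_siblings_is_an_error(self, trio_ped):
        with pytest.raises(SegregationError, match="sibling"):
            sibship_filter([], trio_ped)


class TestMemberCompatible:
    def test_parent_het_compatible_recessive(self, trio_ped):
        rec = make_record({"father": (0, 1)})
        assert member_compatible(rec, trio_ped.member("father"), R, Role.PARENT)

    def test_unaffected_hom_alt_incompatible(self, trio_ped):
        rec = make_record({"father": (1, 1)})
        assert not member_compatible(
            rec, trio_ped.member("father"), R, Role.UNAFFECTED
        )

    def test_missing_parent_permissive_vs_strict(self, trio_ped):
        rec = make_record({"father": None})
        father = trio_ped.member("father")
        assert member_compatible(rec, father, R, Role.PARENT)
        assert not member_compatible(
            rec, father, R, Role.PARENT, missing_policy="strict"
        )

    def test_low_depth_call_treated_as_missing(self, trio_ped):
        rec = make_record({"father": (1, 1)}, depth=5)
        assert member_compatible(rec, trio_ped.member("father"), R, Role.PARENT)


class TestTrioFilter:
    def test_quoted_recessive_rule(self, trio_ped):
        rec = make_record({"index": (1, 1), "father": (0, 1), "mother": (0, 1)})
        cs = trio_filter([rec], trio_ped)
        assert cs.total == 1 and cs.coding.hom == 1

    def test_homozygous_parent_not_in_recessive_stratum(self, trio_ped):
        rec = make_record({"index": (1, 1), "father": (1, 1), "mother": (0, 1)})
        assert trio_filter([rec], trio_ped, model=R).total == 0

    def test_de_novo_het_stratum(self, trio_ped):
        rec = make_record({"index": (0, 1), "father": (0, 0), "mother": (0, 0)})
        cs = trio_filter([rec], trio_ped)
        assert cs.total == 1 and cs.coding.het == 1

    def test_missing_parent_is_error(self):
        members = [make_individual("index", sex=Sex.MALE,
                                   affection=Affection.AFFECTED)]
        orphan = Pedigree("F1", members, "index")
        with pytest.raises(SegregationError, match="parent"):
            trio_filter([], orphan)


class TestIncrementalReduction:
    def test_counts_non_increasing_and_nested(self, quintet_ped):
        records, ped = simulate_genotypes(
            SimulationConfig(
                n_population_sites=800, n_family_sites=100,
                pedigree_template="quintet", seed=13,
            )
        )
        curve = incremental_reduction(records, ped, addition_order(ped))
        totals = curve.totals()
        assert all(a >= b for a, b in zip(totals, totals[1:]))
        key_sets = [s.candidates.keys for s in curve.steps]
        for bigger, smaller in zip(key_sets, key_sets[1:]):
            assert smaller <= bigger

    def test_steps_match_bruteforce_oracle(self, quintet_ped):
        records, ped = simulate_genotypes(
            SimulationConfig(
                n_population_sites=600, n_family_sites=80,
                pedigree_template="quintet", seed=17,
            )
        )
        plan = addition_order(ped)
        curve = incremental_reduction(records, ped, plan)
        for k, step in enumerate(curve.steps, start=1):
            expected = oracle_retained_keys(
                records, ped, list(plan.members[:k]), BOTH
            )
            assert step.candidates.keys == expected

    def test_single_step_plan(self, trio_ped):
        rec = make_record({"index": (1, 1), "father": (0, 1), "mother": (0, 1)})
        plan = addition_order(trio_ped, ["index"])
        curve = incremental_reduction([rec], trio_ped, plan)
        assert len(curve.steps) == 1
        assert curve.steps[0].label == "Index"

    def test_strata_sum_to_total(self, quintet_ped):
        records, ped = simulate_genotypes(
            SimulationConfig(
                n_population_sites=500, n_family_sites=60,
                pedigree_template="quintet", seed=19,
            )
        )
        curve = incremental_reduction(records, ped, addition_order(ped))
        for step in curve.steps:
            cs = step.candidates
            assert cs.coding.total + cs.noncoding.total == cs.total


class TestReductionPercentages:
    @pytest.mark.parametrize(
        "totals,expected",
        [
            ([100, 40, 30], [60.0, 25.0]),
            ([5, 5], [0.0]),
            ([7, 0, 0], [100.0, 0.0]),
        ],
    )
    def test_arithmetic(self, totals, expected, trio_ped):
        # build a fake curve with the desired totals via index-only steps
        from pedseg.segregation import (
            CandidateSet, CandidateVariant, ReductionCurve, ReductionStep,
        )
        from pedseg.genofilter import Zygosity

        steps = []
        for k, t in enumerate(totals):
            variants = [
                CandidateVariant(("chr1", i, "A", "G"), "coding", Zygosity.HOM_ALT)
                for i in range(t)
            ]
            steps.append(ReductionStep(str(k), None, CandidateSet(variants)))
        assert reduction_percentages(ReductionCurve(steps)) == pytest.approx(expected)

    def test_requires_two_steps(self):
        from pedseg.segregation import ReductionCurve

        with pytest.raises(SegregationError):
            reduction_percentages(ReductionCurve(steps=[]))


class TestCompareStrategies:
    def test_constructed_contrast(self, quintet_ped):
        # trio retains (het parents), sibship excludes (unaffected sib hom)
        rec = make_record(
            {
                "father": (0, 1),
                "mother": (0, 1),
                "index": (1, 1),
                "sib1": (1, 1),
                "sib2": (1, 1),
            }
        )
        comp = compare_trio_vs_sibship([rec], quintet_ped)
        assert comp.trio_candidate_count == 1
        assert comp.sibship_candidate_count == 0
        assert comp.shared_among_affected_sibs == 1
        assert comp.shared_among_unaffected_sibs == 1

    def test_empty_records_all_zero(self, quintet_ped):
        comp = compare_trio_vs_sibship([], quintet_ped)
        assert comp.trio_candidate_count == 0
        assert comp.sibship_candidate_count == 0

    def test_structure_requirements(self, trio_ped):
        with pytest.raises(SegregationError, match="sibling"):
            compare_trio_vs_sibship([], trio_ped)


class TestPolicies:
    def test_empty_tested_is_error(self, trio_ped):
        with pytest.raises(SegregationError, match="empty"):
            segregation_filter([], trio_ped, [], R)

    def test_index_must_be_tested(self, trio_ped):
        with pytest.raises(SegregationError, match="index"):
            segregation_filter([], trio_ped, ["father"], R)

    def test_strict_missing_excludes(self, trio_ped):
        rec = make_record(
            {"index": (1, 1), "father": None, "mother": (0, 1)}
        )
        tested = ["index", "father", "mother"]
        permissive = segregation_filter([rec], trio_ped, tested, R)
        strict = segregation_filter(
            [rec], trio_ped, tested, R, missing_policy="strict"
        )
        assert permissive.total == 1
        assert strict.total == 0

    def test_index_missing_never_retained(self, trio_ped):
        rec = make_record(
            {"index": None, "father": (0, 1), "mother": (0, 1)}
        )
        cs = segregation_filter(
            [rec], trio_ped, ["index", "father", "mother"], BOTH
        )
        assert cs.total == 0

    def test_mitochondrial_sites_excluded(self, trio_ped):
        rec = make_record(
            {"index": (1, 1), "father": (0, 1), "mother": (0, 1)}, chrom="chrM"
        )
        assert trio_filter([rec], trio_ped).total == 0

    def test_male_x_hemizygous_satisfies_recessive_index(self, trio_ped):
        rec = make_record(
            {"index": (1,), "father": (0,), "mother": (0, 1)}, chrom="chrX"
        )
        cs = segregation_filter([rec], trio_ped, ["index"], R)
        assert cs.total == 1 and cs.coding.hom == 1

    def test_depth_scope_site_drops_whole_site(self, trio_ped):
        rec = make_record(
            {"index": (1, 1), "father": (0, 1), "mother": (0, 1)},
            depths={"index": 30, "father": 10, "mother": 30},
        )
        tested = ["index", "father", "mother"]
        call_scope = segregation_filter([rec], trio_ped, tested, R)
        site_scope = segregation_filter(
            [rec], trio_ped, tested, R, cfg=FilterConfig(depth_scope="site")
        )
        assert call_scope.total == 1  # father's call downgraded, permissive
        assert site_scope.total == 0
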