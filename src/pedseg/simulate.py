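"""Synthetic consanguineous-cohort generator.

Emulates the genomic structure the segregation analysis is designed for:

* a rare-variant background — sites independent across the genome (no
  linkage), population allele frequencies log-uniform over a rare spectrum;
* family-enriched alleles — a subset of sites where the family's founders
  draw from a locally common allele pool while the *database* allele
  frequency stays rare (these are the alleles population-frequency filters
  cannot remove, and the reason family segregation filtering bites);
* a first-cousin mating loop — the parents of the sibship are first
  cousins through one shared great-grandparental couple, giving their
  children an expected inbreeding coefficient F = 1/16.  Founder-allele
  labels are carried through transmission, so autozygosity is emergent and
  measurable rather than asserted;
* Mendelian transmission with true X hemizygosity in males, per-offspring
  de novo mutations, per-call genotype error and Poisson read depth (a
  small fraction of calls is drawn at low depth to exercise the 20x rule);
* one planted coding recessive variant segregating perfectly with
  affection status: homozygous in all affecteds, heterozygous in both
  parents, never homozygous in unaffecteds.

Identical configuration and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pedio import Affection, Individual, Pedigree, Sex, write_ped
from .variant_io import GenotypeCall, VariantRecord, write_vcf


class SimulationError(ValueError):
    pass


_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]
_DIPLOID_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


@dataclass
class PlantedVariantSpec:
    """The causal recessive variant planted into the cohort.

    ``pop_af`` is the database allele frequency written for the site (kept
    under the frequency filter); unaffected siblings are carriers with
    probability ``unaffected_carrier_prob`` (2/3, the conditional carrier
    probability for the unaffected child of two carriers) and homozygous
    reference otherwise.
    """

    pop_af: float = 0.001
    unaffected_carrier_prob: float = 2.0 / 3.0


@dataclass
class SimulationConfig:
    """All generator knobs; defaults are the canonical study conditions.

    Depth defaults follow the exome profile (~90x mean, 20x minimum
    usable); use :meth:`wgs` for the ~30x genome profile.
    """

    n_population_sites: int = 100_000
    af_low: float = 1e-4
    af_high: float = 0.015
    n_family_sites: int = 1_000
    family_pool_af: float = 0.3
    coding_fraction: float = 0.02
    genotype_error_rate: float = 0.005
    de_novo_count_mean: float = 1.0
    mean_depth: float = 90.0
    low_depth_fraction: float = 0.01
    low_depth_mean: float = 10.0
    pedigree_template: str = "octet"
    n_affected_sibs: int | None = None
    n_unaffected_sibs: int | None = None
    x_fraction: float = 0.05
    causal: PlantedVariantSpec | None = field(default_factory=PlantedVariantSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.af_low < self.af_high <= 1):
            raise SimulationError("need 0 < af_low < af_high <= 1")
        for name in ("family_pool_af", "coding_fraction", "genotype_error_rate",
                     "x_fraction", "low_depth_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} {v} outside [0, 1]")
        if self.pedigree_template not in ("octet", "quintet"):
            raise SimulationError(
                f"unknown pedigree template {self.pedigree_template!r}"
            )

    @classmethod
    def wes(cls, **kwargs) -> "SimulationConfig":
        return cls(mean_depth=90.0, **kwargs)

    @classmethod
    def wgs(cls, **kwargs) -> "SimulationConfig":
        return cls(mean_depth=30.0, **kwargs)

    def sib_counts(self) -> tuple[int, int]:
        if self.pedigree_template == "octet":
            default = (2, 3)
            capacity = 5
        else:
            default = (1, 1)
            capacity = 2
        a = self.n_affected_sibs if self.n_affected_sibs is not None else default[0]
        u = self.n_unaffected_sibs if self.n_unaffected_sibs is not None else default[1]
        if a < 0 or u < 0 or a + u != capacity:
            raise SimulationError(
                f"{self.pedigree_template} template takes exactly {capacity} "
                f"siblings of the index, got {a} affected + {u} unaffected"
            )
        return a, u


#: Ancestor ids of the consanguinity loop: ggf/ggm are the shared
#: great-grandparental couple; pgf (paternal grandfather) and mgm (maternal
#: grandmother) are their children, so the father and mother are first
#: cousins; pgm and mgf married in.
ANCESTOR_IDS = ("ggf", "ggm", "pgf", "pgm", "mgf", "mgm")
FOUNDER_IDS = ("ggf", "ggm", "pgm", "mgf")


def _sib_affection_pattern(n_affected: int, n_unaffected: int) -> list[bool]:
    """Interleave affected sibs among unaffected: A first, shares of U after.

    For 2 affected + 3 unaffected this yields A,U,U,A,U — the addition
    sequence of the octet analysis.
    """
    if n_affected == 0:
        return [False] * n_unaffected
    base, extra = divmod(n_unaffected, n_affected)
    pattern: list[bool] = []
    for i in range(n_affected):
        pattern.append(True)
        pattern.extend([False] * (base + (1 if i < extra else 0)))
    return pattern


def build_template(cfg: SimulationConfig) -> Pedigree:
    """Extended pedigree with the first-cousin loop; sibship is tested.

    The index is the first (male) child; sibling sexes alternate starting
    from the seed's parity; ancestors are members but not tested.
    """
    n_aff, n_unaff = cfg.sib_counts()
    fam = "FAM1"

    def ind(iid, fa, mo, sex, aff):
        return Individual(fam, iid, fa, mo, sex, aff)

    U, A = Affection.UNAFFECTED, Affection.AFFECTED
    members = [
        ind("ggf", None, None, Sex.MALE, U),
        ind("ggm", None, None, Sex.FEMALE, U),
        ind("pgf", "ggf", "ggm", Sex.MALE, U),
        ind("pgm", None, None, Sex.FEMALE, U),
        ind("mgf", None, None, Sex.MALE, U),
        ind("mgm", "ggf", "ggm", Sex.FEMALE, U),
        ind("father", "pgf", "pgm", Sex.MALE, U),
        ind("mother", "mgf", "mgm", Sex.FEMALE, U),
        ind("index", "father", "mother", Sex.MALE, A),
    ]
    tested = ["index", "father", "mother"]
    pattern = _sib_affection_pattern(n_aff, n_unaff)
    first_female = cfg.seed % 2 == 0
    for i, affected in enumerate(pattern, start=1):
        sex = Sex.FEMALE if (i % 2 == 1) == first_female else Sex.MALE
        sid = f"sib{i}"
        members.append(ind(sid, "father", "mother", sex, A if affected else U))
        tested.append(sid)
    return Pedigree(
        family_id=fam, members=members, index_id="index", tested=tuple(tested)
    )


@dataclass
class SimResult:
    """Generator output plus internal truth used for calibration checks."""

    records: list[VariantRecord]
    ped: Pedigree
    #: database AF per site (what goes into INFO/AF)
    af_db: np.ndarray
    #: site masks, aligned with ``records``
    is_population: np.ndarray
    is_x: np.ndarray
    is_coding: np.ndarray
    #: pre-error genotype codes (0/1/2) per member id
    true_codes: dict[str, np.ndarray]
    #: index autozygosity: both allele labels trace to one founder allele
    index_autozygous: np.ndarray
    causal_index: int | None


def _layout_sites(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_population_sites + cfg.n_family_sites
    is_x = rng.random(n) < cfg.x_fraction
    is_coding = rng.random(n) < cfg.coding_fraction
    is_family = np.zeros(n, dtype=bool)
    fam_idx = rng.choice(n, size=cfg.n_family_sites, replace=False)
    is_family[fam_idx] = True
    # database AF: log-uniform rare spectrum, snapped to 4 decimals stored
    # as 32-bit floats so the value survives VCF text round-trips exactly
    af = np.exp(rng.uniform(np.log(cfg.af_low), np.log(cfg.af_high), n))
    af_db = np.maximum(np.round(af, 4), cfg.af_low).astype(np.float32).astype(float)
    af_true = np.where(is_family, cfg.family_pool_af, af_db)
    # chromosome layout: autosomal sites in contiguous blocks over chr1..22
    # (in site order), X sites in a final block -> records come out sorted
    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    auto_sites = np.flatnonzero(~is_x)
    x_sites = np.flatnonzero(is_x)
    n_auto = len(auto_sites)
    per_chrom = -(-n_auto // len(_AUTOSOMES)) if n_auto else 1
    for rank, site in enumerate(auto_sites):
        chrom[site] = _AUTOSOMES[rank // per_chrom]
        pos[site] = (rank % per_chrom + 1) * 100
    for rank, site in enumerate(x_sites):
        chrom[site] = "chrX"
        pos[site] = (rank + 1) * 100
    order = np.concatenate([auto_sites, x_sites])
    return n, order, chrom, pos, is_x, is_coding, is_family, af_db, af_true


class _Haplotypes:
    __slots__ = ("s0", "s1", "l0", "l1")

    def __init__(self, s0, s1, l0, l1):
        self.s0, self.s1, self.l0, self.l1 = s0, s1, l0, l1


def _founder_haps(
    rng: np.random.Generator, freq: np.ndarray, label_base: int,
    is_x: np.ndarray, male: bool,
) -> _Haplotypes:
    n = len(freq)
    s0 = (rng.random(n) < freq).astype(np.int8)
    s1 = (rng.random(n) < freq).astype(np.int8)
    l0 = np.full(n, label_base, dtype=np.int32)
    l1 = np.full(n, label_base + 1, dtype=np.int32)
    if male:
        # one X copy: mirror it so either "side" transmits the same allele
        s1 = np.where(is_x, s0, s1).astype(np.int8)
        l1 = np.where(is_x, l0, l1)
    return _Haplotypes(s0, s1, l0, l1)


def _gamete(rng: np.random.Generator, parent: _Haplotypes):
    sel = rng.integers(0, 2, len(parent.s0)).astype(bool)
    state = np.where(sel, parent.s1, parent.s0).astype(np.int8)
    label = np.where(sel, parent.l1, parent.l0)
    return state, label


def _child_haps(
    rng: np.random.Generator,
    father: _Haplotypes,
    mother: _Haplotypes,
    is_x: np.ndarray,
    male: bool,
    de_novo_mean: float,
) -> _Haplotypes:
    pat_s, pat_l = _gamete(rng, father)
    mat_s, mat_l = _gamete(rng, mother)
    n = len(pat_s)
    k = rng.poisson(de_novo_mean)
    if k:
        sites = rng.integers(0, n, k)
        mat_s[sites] = 1
    if male:
        # a son's X is his single maternal copy, mirrored on both sides
        pat_s = np.where(is_x, mat_s, pat_s).astype(np.int8)
        pat_l = np.where(is_x, mat_l, pat_l)
    return _Haplotypes(pat_s, mat_s, pat_l, mat_l)


def plant_causal(
    records: list[VariantRecord],
    ped: Pedigree,
    spec: PlantedVariantSpec,
    rng: np.random.Generator | None = None,
) -> int:
    """Overwrite one coding autosomal site with the causal pattern.

    The pattern — homozygous alt in the index and all affected siblings,
    het in both parents, never homozygous in unaffected siblings — is
    written error-free, depth is forced to at least 20 and the database AF
    below the frequency ceiling.  Ancestors of the built-in template, when
    present, carry the allele down one great-grandparental line.  Returns
    the record index planted.  Raises if no suitable site exists.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    from .genofilter import is_mitochondrial, is_x as _is_x, is_y as _is_y
    from .annotate import CODING, classify_region
    from .pedio import role_sets

    target = None
    for i, r in enumerate(records):
        if _is_x(r.chrom) or _is_y(r.chrom) or is_mitochondrial(r.chrom):
            continue
        if classify_region(r) == CODING:
            target = i
            break
    if target is None:
        raise SimulationError(
            "no autosomal coding site available to plant the causal variant"
        )
    rec = records[target]
    roles = role_sets(ped)
    index = ped.index
    pattern: dict[str, int] = {ped.index_id: 2}
    for sid in roles.siblings_of_index:
        if sid in roles.affected:
            pattern[sid] = 2
        elif sid in roles.unaffected:
            pattern[sid] = 1 if rng.random() < spec.unaffected_carrier_prob else 0
    for pid in (index.father_id, index.mother_id):
        if pid is not None:
            pattern[pid] = 1
    # carrier path through the template's great-grandfather, when present
    for aid, code in (("ggf", 1), ("pgf", 1), ("mgm", 1),
                      ("ggm", 0), ("pgm", 0), ("mgf", 0)):
        pattern.setdefault(aid, code)
    new_calls: dict[str, GenotypeCall] = {}
    for sample, call in rec.calls.items():
        code = pattern.get(sample)
        depth = max(20, call.depth if call.depth is not None else 20)
        if code is None:
            new_calls[sample] = GenotypeCall(call.alleles, depth)
        else:
            new_calls[sample] = GenotypeCall(_DIPLOID_ALLELES[code], depth)
    records[target] = VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alt=rec.alt,
        filter_status="pass",
        pop_af=float(np.float32(spec.pop_af)),
        consequences=frozenset({"missense_variant"}),
        calls=new_calls,
    )
    return target


def simulate_full(
    cfg: SimulationConfig, include_ancestors: bool = False
) -> SimResult:
    """Run the generator; see the module docstring for the model."""
    rng = np.random.default_rng(cfg.seed)
    ped = build_template(cfg)
    (n, order, chrom, pos, is_x, is_coding, is_family, af_db, af_true) = (
        _layout_sites(cfg, rng)
    )

    sexes = {m.individual_id: m.sex for m in ped.members}
    haps: dict[str, _Haplotypes] = {}
    for fi, fid in enumerate(FOUNDER_IDS):
        haps[fid] = _founder_haps(
            rng, af_true, 2 * fi, is_x, sexes[fid] is Sex.MALE
        )
    # non-founders in generation order
    for child, fa, mo in (
        ("pgf", "ggf", "ggm"),
        ("mgm", "ggf", "ggm"),
        ("father", "pgf", "pgm"),
        ("mother", "mgf", "mgm"),
    ):
        haps[child] = _child_haps(
            rng, haps[fa], haps[mo], is_x, sexes[child] is Sex.MALE,
            cfg.de_novo_count_mean,
        )
    sib_ids = [m for m in ped.tested_ids() if m not in ("father", "mother")]
    for sid in sib_ids:  # index first, then sib1..; plan order
        haps[sid] = _child_haps(
            rng, haps["father"], haps["mother"], is_x,
            sexes[sid] is Sex.MALE, cfg.de_novo_count_mean,
        )

    true_codes = {
        mid: (h.s0 + h.s1).astype(np.int8) for mid, h in haps.items()
    }
    hx = haps[ped.index_id]
    index_autozygous = (hx.l0 == hx.l1) & ~is_x

    included = list(ped.tested_ids())
    if include_ancestors:
        included += [a for a in ANCESTOR_IDS if a in ped]

    m = len(included)
    codes = np.stack([true_codes[mid] for mid in included])
    male_row = np.array([sexes[mid] is Sex.MALE for mid in included])
    # genotype error: flip to a uniformly chosen different code; male X
    # calls flip between the two hemizygous codes
    if cfg.genotype_error_rate > 0:
        flip = rng.random((m, n)) < cfg.genotype_error_rate
        delta = rng.integers(1, 3, (m, n)).astype(np.int8)
        flipped = (codes + delta) % 3
        hemi = male_row[:, None] & is_x[None, :]
        flipped = np.where(hemi, 2 - codes, flipped)
        codes = np.where(flip, flipped, codes).astype(np.int8)
    # depth: Poisson at the profile mean, with a low-coverage minority
    low = rng.random((m, n)) < cfg.low_depth_fraction
    lam = np.where(low, cfg.low_depth_mean, cfg.mean_depth)
    depth = rng.poisson(lam).astype(np.int32)

    records: list[VariantRecord] = []
    hemi_lookup = {0: (0,), 1: (1,), 2: (1,)}  # code 1 unreachable on male X
    for site in order:
        x_site = bool(is_x[site])
        calls: dict[str, GenotypeCall] = {}
        for row, mid in enumerate(included):
            code = int(codes[row, site])
            if x_site and male_row[row]:
                alleles = hemi_lookup[code]
            else:
                alleles = _DIPLOID_ALLELES[code]
            calls[mid] = GenotypeCall(alleles, int(depth[row, site]))
        records.append(
            VariantRecord(
                chrom=chrom[site],
                pos=int(pos[site]),
                ref="A",
                alt="G",
                filter_status="pass",
                pop_af=float(af_db[site]),
                consequences=frozenset(
                    {"missense_variant"} if is_coding[site] else {"intron_variant"}
                ),
                calls=calls,
            )
        )

    causal_index = None
    if cfg.causal is not None:
        causal_index = plant_causal(records, ped, cfg.causal, rng)

    return SimResult(
        records=records,
        ped=ped,
        af_db=af_db[order],
        is_population=~is_family[order],
        is_x=is_x[order],
        is_coding=is_coding[order],
        true_codes={mid: arr[order] for mid, arr in true_codes.items()},
        index_autozygous=index_autozygous[order],
        causal_index=causal_index,
    )


def simulate_genotypes(
    cfg: SimulationConfig, include_ancestors: bool = False
) -> tuple[list[VariantRecord], Pedigree]:
    """Generator output as (records, pedigree)."""
    result = simulate_full(cfg, include_ancestors=include_ancestors)
    return result.records, result.ped


def emit(
    records: Sequence[VariantRecord],
    ped: Pedigree,
    out_prefix: str | Path,
    include_ancestors: bool = False,
) -> tuple[Path, Path]:
    """Write PREFIX.vcf and PREFIX.ped for a simulated cohort.

    The VCF carries only the samples present in the records (tested members
    by default); the PED lists the same members, with untested ancestors
    noted in comments.
    """
    vcf_path = Path(f"{out_prefix}.vcf")
    ped_path = Path(f"{out_prefix}.ped")
    samples = list(records[0].calls) if records else list(ped.tested_ids())
    write_vcf(records, samples, vcf_path)
    written = set(samples)
    ancestors = [a for a in ANCESTOR_IDS if a in ped and a not in written]
    comments = (
        [f"untested ancestors: {', '.join(ancestors)}"] if ancestors else []
    )
    write_ped(ped, ped_path, members=samples, comments=comments)
    return vcf_path, ped_path
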