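"""Multi-sample VCF I/O normalized to biallelic records.

Reading goes through :mod:`pysam`; every site is split into one record per
ALT allele and per-sample genotypes are recoded so the retained alt is
allele index 1.  A genotype that carries a *different* alt than the record
under construction is conservatively recoded as missing: such a call neither
supports nor excludes segregation of the retained allele.

Coordinates are 1-based as in VCF and are never shifted (no left
normalization); inputs are assumed pre-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pysam


class VcfError(ValueError):
    """Raised on VCF content the analysis cannot consume."""


PASS = "pass"
FAIL = "fail"
UNSTATED = "unstated"


class GenotypeCall:
    """One sample's call: allele indices plus read depth.

    ``alleles`` is a pair for diploid calls, a 1-tuple for hemizygous calls
    and ``None`` for a missing genotype.  ``depth`` is the DP value or
    ``None`` when absent.
    """

    __slots__ = ("alleles", "depth")

    def __init__(self, alleles: tuple[int, ...] | None, depth: int | None = None):
        self.alleles = alleles
        self.depth = depth

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_hemizygous(self) -> bool:
        return self.alleles is not None and len(self.alleles) == 1

    def carries_alt(self) -> bool:
        return self.alleles is not None and 1 in self.alleles

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeCall)
            and self.alleles == other.alleles
            and self.depth == other.depth
        )

    def __repr__(self) -> str:
        return f"GenotypeCall(alleles={self.alleles!r}, depth={self.depth!r})"


class VariantRecord:
    """One normalized biallelic site with per-sample calls."""

    __slots__ = (
        "chrom",
        "pos",
        "ref",
        "alt",
        "filter_status",
        "pop_af",
        "consequences",
        "calls",
    )

    def __init__(
        self,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        filter_status: str = PASS,
        pop_af: float | None = None,
        consequences: frozenset[str] | set[str] = frozenset(),
        calls: dict[str, GenotypeCall] | None = None,
    ):
        if pop_af is not None and not (0.0 <= pop_af <= 1.0):
            raise VcfError(f"pop_af {pop_af} outside [0, 1] at {chrom}:{pos}")
        self.chrom = chrom
        self.pos = pos
        self.ref = ref
        self.alt = alt
        self.filter_status = filter_status
        self.pop_af = pop_af
        self.consequences = frozenset(consequences)
        self.calls = calls or {}

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __repr__(self) -> str:
        return f"VariantRecord({self.chrom}:{self.pos} {self.ref}>{self.alt})"


@dataclass
class RawSite:
    """A possibly multi-allelic site as parsed, before splitting.

    ``calls`` hold raw allele indices into ``(ref,) + alts``; ``pop_af`` is
    one value per alt when present.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    filter_status: str = PASS
    pop_af: tuple[float, ...] | None = None
    consequences: frozenset[str] = frozenset()
    calls: dict[str, GenotypeCall] = field(default_factory=dict)


def split_multiallelic(site: RawSite) -> list[VariantRecord]:
    """Split a raw site into one biallelic :class:`VariantRecord` per alt.

    Per-sample alleles are recoded 0/1 against the retained alt; calls
    containing another alt become missing (depth is kept).  Site AF must be
    one value per alt when present.
    """
    k = len(site.alts)
    if k < 1:
        raise VcfError(f"site {site.chrom}:{site.pos} has no ALT allele")
    if site.pop_af is not None and len(site.pop_af) != k:
        raise VcfError(
            f"site {site.chrom}:{site.pos}: AF has {len(site.pop_af)} "
            f"values for {k} alt alleles"
        )
    records = []
    for j, alt in enumerate(site.alts):
        alt_index = j + 1
        calls: dict[str, GenotypeCall] = {}
        for sample, call in site.calls.items():
            if call.alleles is None:
                calls[sample] = GenotypeCall(None, call.depth)
                continue
            if any(a not in (0, alt_index) for a in call.alleles):
                # carries a different alt: uninformative for this record
                calls[sample] = GenotypeCall(None, call.depth)
                continue
            recoded = tuple(1 if a == alt_index else 0 for a in call.alleles)
            calls[sample] = GenotypeCall(recoded, call.depth)
        records.append(
            VariantRecord(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=alt,
                filter_status=site.filter_status,
                pop_af=None if site.pop_af is None else site.pop_af[j],
                consequences=site.consequences,
                calls=calls,
            )
        )
    return records


def _parse_consequences(value) -> frozenset[str]:
    if value is None:
        return frozenset()
    if isinstance(value, (tuple, list)):
        parts = ",".join(str(v) for v in value)
    else:
        parts = str(value)
    terms = set()
    for chunk in parts.replace("|", ",").replace("&", ",").split(","):
        chunk = chunk.strip()
        if chunk:
            terms.add(chunk)
    return frozenset(terms)


def _parse_af(value, n_alts: int) -> tuple[float, ...] | None:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        vals = tuple(float(v) for v in value)
    else:
        vals = (float(value),)
    return vals


def read_vcf(
    path: str | Path,
    af_key: str = "AF",
    csq_key: str = "CSQ",
) -> list[VariantRecord]:
    """Read a VCF into biallelic records in file order.

    FILTER ``.`` or ``PASS`` map to pass, anything else to fail.  ``af_key``
    and ``csq_key`` name the INFO fields carrying the population allele
    frequency and the consequence terms; a missing AF leaves ``pop_af``
    absent.
    """
    with pysam.VariantFile(str(path)) as vf:
        if "GT" not in vf.header.formats:
            raise VcfError(f"{path}: VCF has no GT in FORMAT")
        out: list[VariantRecord] = []
        for rec in vf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            if not alts:
                continue
            filters = list(rec.filter.keys())
            status = PASS if (not filters or filters == ["PASS"]) else FAIL
            calls: dict[str, GenotypeCall] = {}
            for sample in rec.samples.values():
                gt = sample.get("GT")
                dp = sample.get("DP")
                depth = None if dp is None else int(dp)
                if gt is None or all(a is None for a in gt):
                    calls[sample.name] = GenotypeCall(None, depth)
                elif any(a is None for a in gt):
                    # partially missing diploid call -> missing
                    calls[sample.name] = GenotypeCall(None, depth)
                else:
                    calls[sample.name] = GenotypeCall(tuple(int(a) for a in gt), depth)
            site = RawSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=alts,
                filter_status=status,
                pop_af=_parse_af(rec.info.get(af_key), len(alts)),
                consequences=_parse_consequences(rec.info.get(csq_key)),
                calls=calls,
            )
            out.extend(split_multiallelic(site))
    return out


def _build_header(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    af_key: str,
    csq_key: str,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=FAIL,Description="Failed site-level quality filters">')
    header.add_line(
        f'##INFO=<ID={af_key},Number=A,Type=Float,'
        'Description="Population allele frequency">'
    )
    header.add_line(
        f'##INFO=<ID={csq_key},Number=.,Type=String,'
        'Description="Consequence terms">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    seen = []
    for r in records:
        if r.chrom not in seen:
            seen.append(r.chrom)
    for chrom in seen:
        header.contigs.add(chrom)
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    af_key: str = "AF",
    csq_key: str = "CSQ",
) -> None:
    """Write biallelic records as an uncompressed multi-sample VCF.

    Round-trips through :func:`read_vcf` preserve chrom/pos/ref/alt, GT, DP
    and AF for every record.  Hemizygous calls are written with a
    single-allele GT.
    """
    samples = list(samples)
    sample_set = set(samples)
    for r in records:
        extra = set(r.calls) - sample_set
        if extra:
            raise VcfError(
                f"record {r.chrom}:{r.pos} has calls for samples not in the "
                f"header: {sorted(extra)}"
            )
    header = _build_header(records, samples, af_key, csq_key)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in records:
            rec = vf.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt),
            )
            if r.filter_status == FAIL:
                rec.filter.add("FAIL")
            else:
                rec.filter.add("PASS")
            if r.pop_af is not None:
                rec.info[af_key] = (r.pop_af,)
            if r.consequences:
                rec.info[csq_key] = "|".join(sorted(r.consequences))
            for s in samples:
                call = r.calls.get(s, GenotypeCall(None, None))
                gt = call.alleles if call.alleles is not None else (None, None)
                rec.samples[s]["GT"] = gt
                if call.depth is not None:
                    rec.samples[s]["DP"] = call.depth
            vf.write(rec)
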