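"""Site/call-level filters and the zygosity rule.

Thresholds follow the study design they implement: a site survives when it
passed the caller's FILTER and its population allele frequency is strictly
below 1.5%; an individual call is trusted only at depth >= 20x (boundary
inclusive), otherwise it is downgraded to MISSING for segregation purposes.

On the X chromosome a male call carrying the alt allele is classified
homozygous (hemizygous = homozygous for this analysis), even when the
caller emitted a diploid het code.  Pseudoautosomal regions are not
special-cased.  Mitochondrial sites are excluded from segregation upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

from .pedio import Sex
from .variant_io import GenotypeCall, VariantRecord, PASS


class Zygosity(IntEnum):
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3


RETAIN = "retain"
DROP = "drop"


@dataclass
class FilterConfig:
    """Site- and call-level thresholds.

    min_depth
        Minimum per-call read depth (x coverage); calls below it become
        MISSING.  Inclusive boundary.
    max_af
        Population allele-frequency ceiling; sites with AF >= max_af are
        dropped (strict less-than survives).
    require_pass
        Drop sites whose FILTER is anything but PASS/"." .
    af_missing_policy
        What to do with sites lacking an AF annotation: "retain" or "drop".
    depth_scope
        "call": depth is enforced per call (failing calls become MISSING);
        "site": a site is dropped outright when any tested member's call
        fails the depth threshold.
    """

    min_depth: int = 20
    max_af: float = 0.015
    require_pass: bool = True
    af_missing_policy: str = RETAIN
    depth_scope: str = "call"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_af <= 1.0:
            raise ValueError(f"max_af {self.max_af} outside [0, 1]")
        if self.min_depth < 0:
            raise ValueError(f"min_depth {self.min_depth} negative")
        if self.af_missing_policy not in (RETAIN, DROP):
            raise ValueError(f"unknown af_missing_policy {self.af_missing_policy!r}")
        if self.depth_scope not in ("call", "site"):
            raise ValueError(f"unknown depth_scope {self.depth_scope!r}")


def load_filter_config(path: str | Path) -> FilterConfig:
    """Read a flat key=value / key: value config file into a FilterConfig."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, _, val = line.partition(sep)
                    values[key.strip()] = val.strip()
                    break
            else:
                raise ValueError(f"{path} line {lineno}: expected key=value")
    kwargs: dict = {}
    if "min_depth" in values:
        kwargs["min_depth"] = int(values["min_depth"])
    if "max_af" in values:
        kwargs["max_af"] = float(values["max_af"])
    if "require_pass" in values:
        kwargs["require_pass"] = values["require_pass"].lower() in ("1", "true", "yes")
    if "af_missing_policy" in values:
        kwargs["af_missing_policy"] = values["af_missing_policy"]
    if "depth_scope" in values:
        kwargs["depth_scope"] = values["depth_scope"]
    unknown = set(values) - {
        "min_depth", "max_af", "require_pass", "af_missing_policy", "depth_scope"
    }
    if unknown:
        raise ValueError(f"{path}: unknown filter config keys {sorted(unknown)}")
    return FilterConfig(**kwargs)


def _norm_chrom(chrom: str) -> str:
    c = chrom.lower()
    return c[3:] if c.startswith("chr") else c


def is_x(chrom: str) -> bool:
    return _norm_chrom(chrom) == "x"


def is_y(chrom: str) -> bool:
    return _norm_chrom(chrom) == "y"


def is_mitochondrial(chrom: str) -> bool:
    return _norm_chrom(chrom) in ("m", "mt")


def site_passes(record: VariantRecord, cfg: FilterConfig) -> bool:
    """Site-level decision: FILTER status and population AF (strict <)."""
    if cfg.require_pass and record.filter_status != PASS:
        return False
    if record.pop_af is None:
        return cfg.af_missing_policy == RETAIN
    return record.pop_af < cfg.max_af


def call_passes(call: GenotypeCall, cfg: FilterConfig) -> bool:
    """Call-level decision: depth present and >= min_depth."""
    return call.depth is not None and call.depth >= cfg.min_depth


def zygosity(call: GenotypeCall, chrom: str, sex: Sex) -> Zygosity:
    """Classify a biallelic call given chromosome and carrier sex.

    Autosomes (and female X): 0/0, 0/1, 1/1 -> HOM_REF/HET/HOM_ALT.  Male X
    and Y: any alt-carrying call is HOM_ALT, alt-free is HOM_REF.  Missing
    calls are MISSING.
    """
    if call.alleles is None:
        return Zygosity.MISSING
    if sex is Sex.MALE and (is_x(chrom) or is_y(chrom)):
        return Zygosity.HOM_ALT if 1 in call.alleles else Zygosity.HOM_REF
    if len(call.alleles) == 1:
        # hemizygous call outside male X/Y: treat the single allele as
        # homozygous for that allele
        return Zygosity.HOM_ALT if call.alleles[0] == 1 else Zygosity.HOM_REF
    n_alt = sum(call.alleles)
    return Zygosity(n_alt)


def effective_zygosity(
    record: VariantRecord, member_id: str, sex: Sex, cfg: FilterConfig
) -> Zygosity:
    """Zygosity after the depth filter: failing calls become MISSING."""
    call = record.calls.get(member_id)
    if call is None or not call_passes(call, cfg):
        return Zygosity.MISSING
    return zygosity(call, record.chrom, sex)
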