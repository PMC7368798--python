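"""Coding/noncoding classification by most severe consequence.

Each variant carries a set of consequence terms (sequence-ontology style);
its region class is that of the most severe term under a fixed severity
ranking.  The built-in ranking follows the canonical consequence hierarchy
used by the common annotators; splice-region, UTR and everything below map
to *noncoding* (the analysis dichotomy is exonic vs intronic), while
synonymous changes still count as coding.  Both the ordering and the
per-term class are overridable by constructing a custom ranking.

For synthetic data without annotation a simple interval gene model can
stand in: a variant is coding iff its position falls in a coding-exon
interval.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .variant_io import VariantRecord

CODING = "coding"
NONCODING = "noncoding"

# (term, class) from most to least severe; class flips to noncoding at
# splice_region_variant
_DEFAULT_ORDER: tuple[tuple[str, str], ...] = (
    ("transcript_ablation", CODING),
    ("frameshift_variant", CODING),
    ("stop_gained", CODING),
    ("stop_lost", CODING),
    ("start_lost", CODING),
    ("splice_acceptor_variant", CODING),
    ("splice_donor_variant", CODING),
    ("missense_variant", CODING),
    ("inframe_insertion", CODING),
    ("inframe_deletion", CODING),
    ("protein_altering_variant", CODING),
    ("incomplete_terminal_codon_variant", CODING),
    ("stop_retained_variant", CODING),
    ("synonymous_variant", CODING),
    ("splice_region_variant", NONCODING),
    ("5_prime_UTR_variant", NONCODING),
    ("3_prime_UTR_variant", NONCODING),
    ("non_coding_transcript_exon_variant", NONCODING),
    ("intron_variant", NONCODING),
    ("upstream_gene_variant", NONCODING),
    ("downstream_gene_variant", NONCODING),
    ("intergenic_variant", NONCODING),
)


@dataclass(frozen=True)
class SeverityRanking:
    """Total order over consequence terms plus a term -> class mapping.

    Unknown terms rank least severe and classify noncoding.
    """

    terms: tuple[str, ...]
    classes: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("severity ranking repeats a term")
        missing = [t for t in self.terms if t not in self.classes]
        if missing:
            raise ValueError(f"terms without a region class: {missing}")
        object.__setattr__(
            self, "_rank", {t: i for i, t in enumerate(self.terms)}
        )

    def rank(self, term: str) -> int:
        return self._rank.get(term, len(self.terms))

    def most_severe(self, terms: Iterable[str]) -> str | None:
        best: str | None = None
        best_rank = len(self.terms) + 1
        for t in sorted(terms):  # sort: deterministic among unknown terms
            r = self.rank(t)
            if r < best_rank:
                best, best_rank = t, r
        return best

    def classify_terms(self, terms: Iterable[str]) -> str:
        top = self.most_severe(terms)
        if top is None:
            return NONCODING
        return self.classes.get(top, NONCODING)


def default_ranking() -> SeverityRanking:
    """The built-in consequence severity ranking."""
    return SeverityRanking(
        terms=tuple(t for t, _ in _DEFAULT_ORDER),
        classes={t: c for t, c in _DEFAULT_ORDER},
    )


class GeneModel:
    """Coding-exon intervals (1-based, inclusive) for annotation fallback."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, cls in intervals:
            if start > end:
                raise ValueError(
                    f"malformed interval {chrom}:{start}-{end} (start > end)"
                )
            by_chrom.setdefault(chrom, []).append((start, end, cls))
        self._starts: dict[str, list[int]] = {}
        self._intervals: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            self._intervals[chrom] = ivals
            self._starts[chrom] = [s for s, _, _ in ivals]

    def is_coding(self, chrom: str, pos: int) -> bool:
        ivals = self._intervals.get(chrom)
        if not ivals:
            return False
        i = bisect.bisect_right(self._starts[chrom], pos)
        # scan left over intervals starting at or before pos
        for start, end, cls in reversed(ivals[:i]):
            if pos <= end and cls == "coding_exon":
                return True
        return False


def read_gene_model(path: str | Path, zero_based: bool = False) -> GeneModel:
    """Read a 4-column TSV gene model (chrom, start, end, class).

    ``start`` is 1-based inclusive by default (matching VCF coordinates);
    pass ``zero_based=True`` for BED-style half-open starts.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(
                    f"{path} line {lineno}: expected 4 tab-delimited columns"
                )
            chrom, start, end, cls = cols[:4]
            s = int(start) + 1 if zero_based else int(start)
            intervals.append((chrom, s, int(end), cls))
    return GeneModel(intervals)


def classify_region(
    record: VariantRecord,
    ranking: SeverityRanking | None = None,
    model: GeneModel | None = None,
) -> str:
    """Classify a variant as coding or noncoding.

    Consequence terms win when present; otherwise the gene model decides;
    with neither the variant is noncoding.
    """
    ranking = ranking if ranking is not None else default_ranking()
    if record.consequences:
        return ranking.classify_terms(record.consequences)
    if model is not None:
        return CODING if model.is_coding(record.chrom, record.pos) else NONCODING
    return NONCODING
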