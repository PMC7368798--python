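"""Pedigree structures and PED file I/O.

The PED dialect read here is the common 6-column whitespace-delimited layout
(family, individual, father, mother, sex, phenotype) with an optional 7th
column flagging the proband.  ``0`` marks an absent parent, sex ``1``/``2``
codes male/female, and phenotype ``2``/``1`` codes affected/unaffected; any
other code maps to *unknown*.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class PedigreeError(ValueError):
    """Raised on malformed PED input or inconsistent family structure."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


#: Step labels by number of tested individuals (the family-size nomenclature
#: used throughout: a trio is index plus both parents, an octet eight tested
#: members).
STEP_LABELS = {
    1: "Index",
    3: "Trio",
    4: "Quartet",
    5: "Quintet",
    6: "Sextet",
    7: "Septet",
    8: "Octet",
}

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFFECTION_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFFECTION_OUT = {
    Affection.AFFECTED: "2",
    Affection.UNAFFECTED: "1",
    Affection.UNKNOWN: "0",
}


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parent ids of ``None`` mean the parent is absent."""

    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affection: Affection

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A single family: members in file order plus the index (proband).

    ``tested`` optionally lists the members whose genotypes enter the
    analysis; simulated extended pedigrees carry their untested ancestors
    here too so transmission can be modelled.
    """

    family_id: str
    members: list[Individual]
    index_id: str
    tested: tuple[str, ...] | None = None

    _by_id: dict[str, Individual] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for m in self.members:
            if m.individual_id in self._by_id:
                raise PedigreeError(
                    f"duplicate individual id {m.individual_id!r} "
                    f"in family {self.family_id!r}"
                )
            if m.family_id != self.family_id:
                raise PedigreeError(
                    f"member {m.individual_id!r} belongs to family "
                    f"{m.family_id!r}, not {self.family_id!r}"
                )
            self._by_id[m.individual_id] = m
        if self.index_id not in self._by_id:
            raise PedigreeError(
                f"index {self.index_id!r} is not a member of family "
                f"{self.family_id!r}"
            )
        self._validate_parents()
        self._validate_acyclic()
        if self.tested is not None:
            for t in self.tested:
                if t not in self._by_id:
                    raise PedigreeError(f"tested member {t!r} not in pedigree")

    def _validate_parents(self) -> None:
        for m in self.members:
            for pid, want in ((m.father_id, Sex.FEMALE), (m.mother_id, Sex.MALE)):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"parent {pid!r} of {m.individual_id!r} is not a "
                        f"member of family {self.family_id!r}"
                    )
                # referenced as father -> must not be recorded female, and
                # vice versa; unknown sex is tolerated
                if parent.sex is want:
                    role = "father" if want is Sex.FEMALE else "mother"
                    raise PedigreeError(
                        f"{pid!r} is referenced as {role} of "
                        f"{m.individual_id!r} but has sex {parent.sex.value}"
                    )

    def _validate_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(mid: str, stack: list[str]) -> None:
            if state.get(mid) == 1:
                return
            if state.get(mid) == 0:
                raise PedigreeError(
                    f"pedigree cycle involving {' -> '.join(stack + [mid])}"
                )
            state[mid] = 0
            m = self._by_id[mid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid, stack + [mid])
            state[mid] = 1

        for m in self.members:
            visit(m.individual_id, [])

    # -- queries -----------------------------------------------------------

    def member(self, individual_id: str) -> Individual:
        try:
            return self._by_id[individual_id]
        except KeyError:
            raise PedigreeError(
                f"{individual_id!r} is not a member of family {self.family_id!r}"
            ) from None

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    @property
    def index(self) -> Individual:
        return self._by_id[self.index_id]

    @property
    def member_ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    def tested_ids(self) -> list[str]:
        if self.tested is not None:
            return list(self.tested)
        return self.member_ids


@dataclass(frozen=True)
class MemberAdditionPlan:
    """Ordered member ids for the incremental analysis, with step labels.

    Step k (counting tested individuals) carries the family-size label:
    Index, Trio, Quartet ... Octet.  A second step that adds a parent is an
    incomplete trio and is labelled ``Trio``; any other unlabelled size is
    labelled with the plain count.
    """

    members: tuple[str, ...]
    labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RoleSets:
    affected: frozenset[str]
    unaffected: frozenset[str]
    parents_of_index: tuple[str | None, str | None]
    siblings_of_index: frozenset[str]


def _parse_line(line: str, lineno: int) -> tuple[Individual, bool]:
    cols = line.split()
    if len(cols) < 6:
        raise PedigreeError(
            f"PED line {lineno}: expected >=6 whitespace-delimited columns, "
            f"got {len(cols)}"
        )
    fam, ind, fa, mo, sex, aff = cols[:6]
    proband = len(cols) >= 7 and cols[6] == "1"
    return (
        Individual(
            family_id=fam,
            individual_id=ind,
            father_id=None if fa == "0" else fa,
            mother_id=None if mo == "0" else mo,
            sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
            affection=_AFFECTION_CODES.get(aff, Affection.UNKNOWN),
        ),
        proband,
    )


def read_ped_families(path: str | Path) -> dict[str, Pedigree]:
    """Read a PED file and return one validated :class:`Pedigree` per family.

    The index of each family is the member flagged in the optional 7th
    (proband) column, else the first affected member in file order.
    """
    families: dict[str, list[Individual]] = {}
    probands: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            ind, proband = _parse_line(line, lineno)
            families.setdefault(ind.family_id, []).append(ind)
            if proband and ind.family_id not in probands:
                probands[ind.family_id] = ind.individual_id
    out: dict[str, Pedigree] = {}
    for fam, members in families.items():
        index_id = probands.get(fam)
        if index_id is None:
            for m in members:
                if m.affection is Affection.AFFECTED:
                    index_id = m.individual_id
                    break
        if index_id is None:
            raise PedigreeError(
                f"family {fam!r}: no proband flag and no affected member; "
                "cannot determine the index"
            )
        out[fam] = Pedigree(family_id=fam, members=members, index_id=index_id)
    return out


def read_ped(path: str | Path, family_id: str | None = None) -> Pedigree:
    """Read a single family from a PED file.

    ``family_id`` selects among several families; with one family it may be
    omitted.
    """
    families = read_ped_families(path)
    if not families:
        raise PedigreeError(f"no pedigree records in {path}")
    if family_id is not None:
        if family_id not in families:
            raise PedigreeError(f"family {family_id!r} not found in {path}")
        return families[family_id]
    if len(families) > 1:
        raise PedigreeError(
            f"{path} holds {len(families)} families "
            f"({', '.join(families)}); pass family_id to choose one"
        )
    return next(iter(families.values()))


def write_ped(
    ped: Pedigree,
    path: str | Path,
    members: Iterable[str] | None = None,
    proband_column: bool = True,
    comments: Sequence[str] = (),
) -> None:
    """Write ``ped`` (or the given subset of members) as a PED file.

    Parent references to members outside the written subset are zeroed so
    the file re-validates on its own.
    """
    ids = list(members) if members is not None else ped.member_ids
    written = set(ids)
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        for mid in ids:
            m = ped.member(mid)
            fa = m.father_id if m.father_id in written else None
            mo = m.mother_id if m.mother_id in written else None
            cols = [
                ped.family_id,
                m.individual_id,
                fa or "0",
                mo or "0",
                _SEX_OUT[m.sex],
                _AFFECTION_OUT[m.affection],
            ]
            if proband_column:
                cols.append("1" if mid == ped.index_id else "0")
            fh.write("\t".join(cols) + "\n")


def step_label(k: int, member_id: str, ped: Pedigree) -> str:
    if k == 2:
        index = ped.index
        if member_id in (index.father_id, index.mother_id):
            return "Trio"
        return "2"
    return STEP_LABELS.get(k, str(k))


def addition_order(
    ped: Pedigree, requested: Sequence[str] | None = None
) -> MemberAdditionPlan:
    """Build the member-addition plan for the incremental analysis.

    Default order: index, father, mother, then remaining tested members in
    file order.  A requested order must start with the index and name
    pedigree members.
    """
    index = ped.index
    if requested is not None:
        req = list(requested)
        if not req:
            raise PedigreeError("requested member order is empty")
        for mid in req:
            ped.member(mid)  # raises if unknown
        if req[0] != ped.index_id:
            raise PedigreeError(
                f"member order must start with the index {ped.index_id!r}, "
                f"got {req[0]!r}"
            )
        if len(set(req)) != len(req):
            raise PedigreeError("requested member order repeats a member")
        order = req
    else:
        order = [ped.index_id]
        for pid in (index.father_id, index.mother_id):
            if pid is not None and pid in ped and pid in set(ped.tested_ids()):
                order.append(pid)
        for mid in ped.tested_ids():
            if mid not in order:
                order.append(mid)
    labels = tuple(
        step_label(k, mid, ped) for k, mid in enumerate(order, start=1)
    )
    return MemberAdditionPlan(members=tuple(order), labels=labels)


def role_sets(ped: Pedigree) -> RoleSets:
    """Partition members by affection and locate the index's parents/siblings.

    Members with unknown affection fall in neither set; siblings share at
    least one resolved parent with the index (half-siblings count).
    """
    affected, unaffected = set(), set()
    for m in ped.members:
        if m.affection is Affection.AFFECTED:
            affected.add(m.individual_id)
        elif m.affection is Affection.UNAFFECTED:
            unaffected.add(m.individual_id)
    index = ped.index
    sibs = set()
    index_parents = {p for p in (index.father_id, index.mother_id) if p}
    if index_parents:
        for m in ped.members:
            if m.individual_id == index.individual_id:
                continue
            parents = {p for p in (m.father_id, m.mother_id) if p}
            if parents & index_parents:
                sibs.add(m.individual_id)
    return RoleSets(
        affected=frozenset(affected),
        unaffected=frozenset(unaffected),
        parents_of_index=(index.father_id, index.mother_id),
        siblings_of_index=frozenset(sibs),
    )
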