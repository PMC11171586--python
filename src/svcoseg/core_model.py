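"""Domain types for pedigrees, phenotypes, and segregation schemes.

A :class:`Pedigree` is a per-family directed acyclic parent->child graph of
:class:`Individual` records.  A :class:`SegregationScheme` partitions the
genotyped members of a family into obligate carriers, obligate non-carriers,
and unconstrained individuals; it is the unit against which every SV cluster
is evaluated downstream.

PED I/O uses a 7-column tab-separated dialect::

    family  id  father  mother  sex  phenotype  genotyped

with phenotype codes 0=UNKNOWN, 1=HEALTHY, 2=GTS, 3=TD, sex codes
1=male, 2=female, 0=unknown, genotyped 0/1, and ``#`` comment lines.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Sex",
    "Phenotype",
    "Individual",
    "Pedigree",
    "SegregationScheme",
    "PhenotypeCollapse",
    "default_scheme",
    "validate_pedigree",
    "read_ped",
    "write_ped",
    "read_schemes",
    "write_schemes",
]


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(enum.Enum):
    GTS = "GTS"
    TD = "TD"
    HEALTHY = "HEALTHY"
    UNKNOWN = "UNKNOWN"


#: PED column encodings.
_PHENO_CODES = {"0": Phenotype.UNKNOWN, "1": Phenotype.HEALTHY, "2": Phenotype.GTS, "3": Phenotype.TD}
_PHENO_TO_CODE = {v: k for k, v in _PHENO_CODES.items()}
_SEX_CODES = {"0": Sex.UNKNOWN, "1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_CODE = {v: k for k, v in _SEX_CODES.items()}


@dataclass
class Individual:
    """One family member; ``genotyped`` marks genome availability."""

    id: str
    family_code: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN
    genotyped: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A single family's pedigree.

    ``complete_single_parents`` (applied by :func:`read_ped` and by the
    synthetic generator) guarantees the both-parents-or-none invariant by
    inserting synthetic untyped founder spouses.
    """

    family_code: str
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {ind.id: ind for ind in self.individuals}

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def get(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [ind for ind in self.individuals if not ind.is_founder]

    @property
    def genotyped_ids(self) -> set[str]:
        return {ind.id for ind in self.individuals if ind.genotyped}

    def add(self, ind: Individual) -> None:
        if ind.id in self._by_id:
            raise ValueError(f"duplicate individual id {ind.id!r} in family {self.family_code}")
        self.individuals.append(ind)
        self._by_id[ind.id] = ind

    def complete_single_parents(self) -> None:
        """Insert a synthetic untyped founder spouse wherever exactly one
        parent is recorded, keeping the transmission model uniform."""
        counter = 0
        for ind in list(self.individuals):
            has_f, has_m = ind.father_id is not None, ind.mother_id is not None
            if has_f == has_m:
                continue
            counter += 1
            synth_id = f"_founder{counter}"
            while synth_id in self._by_id:
                counter += 1
                synth_id = f"_founder{counter}"
            synth = Individual(
                id=synth_id,
                family_code=self.family_code,
                sex=Sex.FEMALE if has_f else Sex.MALE,
                phenotype=Phenotype.UNKNOWN,
                genotyped=False,
            )
            self.add(synth)
            if has_f:
                ind.mother_id = synth_id
            else:
                ind.father_id = synth_id

    def topological_order(self) -> list[Individual]:
        """Founders first, every child after both parents.

        Raises ``ValueError`` on cycles or unresolved parent ids.
        """
        order: list[Individual] = []
        placed: set[str] = set()
        pending = list(self.individuals)
        while pending:
            progressed = False
            remaining = []
            for ind in pending:
                parents_ok = all(
                    pid is None or pid in placed for pid in (ind.father_id, ind.mother_id)
                )
                if parents_ok:
                    order.append(ind)
                    placed.add(ind.id)
                    progressed = True
                else:
                    remaining.append(ind)
            if not progressed:
                bad = ", ".join(ind.id for ind in remaining)
                raise ValueError(
                    f"family {self.family_code}: cycle or unresolved parents involving {bad}"
                )
            pending = remaining
        return order


@dataclass(frozen=True)
class SegregationScheme:
    """Accepted carrier pattern for one family.

    The three id sets are pairwise disjoint and together cover the family's
    genotyped members; obligate carriers must be non-empty.
    """

    scheme_id: str
    obligate_carriers: frozenset[str]
    obligate_noncarriers: frozenset[str]
    unconstrained: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.obligate_carriers:
            raise ValueError(f"scheme {self.scheme_id}: obligate_carriers must be non-empty")
        sets = [self.obligate_carriers, self.obligate_noncarriers, self.unconstrained]
        total = len(self.obligate_carriers | self.obligate_noncarriers | self.unconstrained)
        if total != sum(len(s) for s in sets):
            raise ValueError(f"scheme {self.scheme_id}: carrier/non-carrier/unconstrained sets overlap")

    @property
    def constrained_ids(self) -> frozenset[str]:
        return self.obligate_carriers | self.obligate_noncarriers

    @property
    def all_ids(self) -> frozenset[str]:
        return self.constrained_ids | self.unconstrained


@dataclass(frozen=True)
class PhenotypeCollapse:
    """Which phenotype labels count as 'patient' when deriving a scheme."""

    affected_labels: frozenset[Phenotype] = frozenset({Phenotype.GTS, Phenotype.TD})

    def __post_init__(self) -> None:
        if not self.affected_labels:
            raise ValueError("affected_labels must be non-empty")
        bad = self.affected_labels - set(Phenotype)
        if bad:
            raise ValueError(f"unknown phenotype labels: {bad}")


def default_scheme(
    pedigree: Pedigree, collapse: PhenotypeCollapse | None = None
) -> SegregationScheme:
    """Derive the family's default scheme: every genotyped patient is an
    obligate carrier, every genotyped healthy member an obligate
    non-carrier, genotyped unknowns are unconstrained.

    Raises ``ValueError`` ("scheme undefinable") when the family has no
    genotyped affected individual.
    """
    collapse = collapse or PhenotypeCollapse()
    carriers, noncarriers, unconstrained = set(), set(), set()
    for ind in pedigree:
        if not ind.genotyped:
            continue
        if ind.phenotype in collapse.affected_labels:
            carriers.add(ind.id)
        elif ind.phenotype is Phenotype.HEALTHY:
            noncarriers.add(ind.id)
        else:
            unconstrained.add(ind.id)
    if not carriers:
        raise ValueError(
            f"family {pedigree.family_code}: scheme undefinable (no genotyped affected individual)"
        )
    return SegregationScheme(
        scheme_id=f"{pedigree.family_code}_default",
        obligate_carriers=frozenset(carriers),
        obligate_noncarriers=frozenset(noncarriers),
        unconstrained=frozenset(unconstrained),
    )


def validate_pedigree(pedigree: Pedigree) -> list[str]:
    """Return human-readable invariant violations (empty list == valid)."""
    violations: list[str] = []
    seen: set[str] = set()
    ids = set()
    for ind in pedigree:
        if ind.id in seen:
            violations.append(f"{ind.id}: duplicate id within family {pedigree.family_code}")
        seen.add(ind.id)
        ids.add(ind.id)

    for ind in pedigree:
        has_f, has_m = ind.father_id is not None, ind.mother_id is not None
        if has_f != has_m:
            violations.append(f"{ind.id}: single known parent (father/mother must both be set or both absent)")
        for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
            if pid is not None and pid not in ids:
                violations.append(f"{ind.id}: {role}_id {pid!r} not found in family")
            if pid == ind.id:
                violations.append(f"{ind.id}: is its own {role}")

    if not any(ind.is_founder for ind in pedigree):
        violations.append(f"family {pedigree.family_code}: no founder")

    # Cycle detection via iterative DFS on the child->parent graph.
    WHITE, GREY, BLACK = 0, 1, 2
    color = {ind.id: WHITE for ind in pedigree}

    def parents(i: str) -> list[str]:
        ind = pedigree.get(i)
        return [p for p in (ind.father_id, ind.mother_id) if p is not None and p in ids]

    for start in list(color):
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        color[start] = GREY
        while stack:
            node, idx = stack[-1]
            ps = parents(node)
            if idx < len(ps):
                stack[-1] = (node, idx + 1)
                p = ps[idx]
                if color[p] == GREY:
                    violations.append(f"{p}: ancestry cycle detected")
                elif color[p] == WHITE:
                    color[p] = GREY
                    stack.append((p, 0))
            else:
                color[node] = BLACK
                stack.pop()
    return violations


# ---------------------------------------------------------------------------
# PED I/O


def read_ped(path: str | Path) -> dict[str, Pedigree]:
    """Read the 7-column PED dialect into per-family pedigrees.

    Single-parent records are completed with synthetic untyped founders.
    """
    families: dict[str, Pedigree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 tab-separated columns, got {len(fields)}")
            fam, iid, fid, mid, sex, pheno, geno = fields[:7]
            if pheno not in _PHENO_CODES:
                raise ValueError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
            ind = Individual(
                id=iid,
                family_code=fam,
                father_id=None if fid in ("0", "") else fid,
                mother_id=None if mid in ("0", "") else mid,
                sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                phenotype=_PHENO_CODES[pheno],
                genotyped=geno == "1",
            )
            families.setdefault(fam, Pedigree(family_code=fam)).add(ind)
    for ped in families.values():
        ped.complete_single_parents()
    return families


def write_ped(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#family\tid\tfather\tmother\tsex\tphenotype\tgenotyped\n")
        for ped in pedigrees:
            for ind in ped:
                fh.write(
                    "\t".join(
                        [
                            ped.family_code,
                            ind.id,
                            ind.father_id or "0",
                            ind.mother_id or "0",
                            _SEX_TO_CODE[ind.sex],
                            _PHENO_TO_CODE[ind.phenotype],
                            "1" if ind.genotyped else "0",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Scheme config I/O (YAML/JSON; JSON is a YAML subset)


def read_schemes(path: str | Path) -> dict[str, list[SegregationScheme]]:
    """Load per-family scheme lists from a YAML/JSON mapping keyed by family
    code; each entry lists ``scheme_id`` and the three id sets."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, list[SegregationScheme]] = {}
    for fam, entries in raw.items():
        schemes = []
        for entry in entries:
            schemes.append(
                SegregationScheme(
                    scheme_id=str(entry["scheme_id"]),
                    obligate_carriers=frozenset(entry.get("obligate_carriers", [])),
                    obligate_noncarriers=frozenset(entry.get("obligate_noncarriers", [])),
                    unconstrained=frozenset(entry.get("unconstrained", [])),
                )
            )
        out[fam] = schemes
    return out


def write_schemes(schemes: Mapping[str, Sequence[SegregationScheme]], path: str | Path) -> None:
    raw = {
        fam: [
            {
                "scheme_id": s.scheme_id,
                "obligate_carriers": sorted(s.obligate_carriers),
                "obligate_noncarriers": sorted(s.obligate_noncarriers),
                "unconstrained": sorted(s.unconstrained),
            }
            for s in fam_schemes
        ]
        for fam, fam_schemes in schemes.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def schemes_for_family(
    pedigree: Pedigree,
    configured: Mapping[str, Sequence[SegregationScheme]] | None = None,
    collapse: PhenotypeCollapse | None = None,
) -> list[SegregationScheme]:
    """Configured schemes for a family when present, else the default scheme."""
    if configured and pedigree.family_code in configured:
        return list(configured[pedigree.family_code])
    return [default_scheme(pedigree, collapse)]
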