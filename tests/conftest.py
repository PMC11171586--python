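"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from svcoseg.core_model import Individual, Pedigree, Phenotype, SegregationScheme, Sex
from svcoseg.sv_cohort import SVRecord


# ---------------------------------------------------------------------------
# Pedigree builders


def make_nuclear(
    family: str = "Z",
    n_children: int = 4,
    carriers: int = 2,
    noncarriers: int = 2,
) -> tuple[Pedigree, SegregationScheme]:
    """Founder couple with genotyped children; first ``carriers`` children
    are obligate carriers, next ``noncarriers`` are obligate non-carriers."""
    ped = Pedigree(family)
    ped.add(Individual("f", family, sex=Sex.MALE))
    ped.add(Individual("m", family, sex=Sex.FEMALE))
    for i in range(n_children):
        pheno = Phenotype.GTS if i < carriers else Phenotype.HEALTHY
        ped.add(
            Individual(f"c{i}", family, father_id="f", mother_id="m", genotyped=True, phenotype=pheno)
        )
    scheme = SegregationScheme(
        scheme_id=f"{family}_s",
        obligate_carriers=frozenset(f"c{i}" for i in range(carriers)),
        obligate_noncarriers=frozenset(f"c{i}" for i in range(carriers, carriers + noncarriers)),
        unconstrained=frozenset(
            f"c{i}" for i in range(carriers + noncarriers, n_children)
        ),
    )
    return ped, scheme


def random_small_pedigree(rng: np.random.Generator, max_nonfounders: int = 6):
    """Random pedigree with <= max_nonfounders non-founders and a random
    satisfiable-or-not scheme over its genotyped members; for oracle tests."""
    fam = "R"
    ped = Pedigree(fam)
    ped.add(Individual("f0", fam, sex=Sex.MALE))
    ped.add(Individual("m0", fam, sex=Sex.FEMALE))
    n_gen2 = int(rng.integers(2, min(5, max_nonfounders) + 1))
    gen2 = []
    for i in range(n_gen2):
        ind = Individual(f"c{i}", fam, father_id="f0", mother_id="m0")
        ped.add(ind)
        gen2.append(ind)
    budget = max_nonfounders - n_gen2
    gi = 0
    for ind in gen2:
        if budget <= 0:
            break
        if rng.random() < 0.5:
            spouse = Individual(f"s{gi}", fam, sex=Sex.FEMALE)
            ped.add(spouse)
            n_kids = int(rng.integers(1, min(3, budget) + 1))
            for k in range(n_kids):
                ped.add(
                    Individual(f"g{gi}_{k}", fam, father_id=ind.id, mother_id=spouse.id)
                )
            budget -= n_kids
            gi += 1

    members = [i for i in ped.individuals]
    n_typed = int(rng.integers(2, len(members) + 1))
    typed_idx = rng.choice(len(members), size=n_typed, replace=False)
    typed = [members[i] for i in typed_idx]
    for ind in typed:
        ind.genotyped = True
    carriers, noncarriers, unconstrained = set(), set(), set()
    for ind in typed:
        r = rng.random()
        if r < 0.45:
            carriers.add(ind.id)
        elif r < 0.85:
            noncarriers.add(ind.id)
        else:
            unconstrained.add(ind.id)
    if not carriers:
        carriers.add(typed[0].id)
        noncarriers.discard(typed[0].id)
        unconstrained.discard(typed[0].id)
    scheme = SegregationScheme(
        scheme_id="rs",
        obligate_carriers=frozenset(carriers),
        obligate_noncarriers=frozenset(noncarriers),
        unconstrained=frozenset(unconstrained),
    )
    return ped, scheme


def oracle_pseg(ped: Pedigree, scheme: SegregationScheme) -> float:
    """Brute-force oracle: enumerate all 4^m transmission vectors (two coins
    per non-founder; a coin transmits iff it is < the parent's allele count)
    and average the scheme-match indicator, maximised over founder origins.

    Independent of the engine's pruned recursion.
    """
    order = ped.topological_order()
    nonfounders = [i for i in order if not i.is_founder]
    m = len(nonfounders)
    assert m <= 8, "oracle is exponential; keep pedigrees small"
    best = 0.0
    for origin in ped.founders:
        successes = 0
        for bits in range(4**m):
            counts = {f.id: (1 if f.id == origin.id else 0) for f in ped.founders}
            b = bits
            for child in nonfounders:
                cf = b & 1
                b >>= 1
                cm = b & 1
                b >>= 1
                counts[child.id] = int(cf < counts[child.father_id]) + int(
                    cm < counts[child.mother_id]
                )
            ok = all(counts[i] > 0 for i in scheme.obligate_carriers) and all(
                counts[i] == 0 for i in scheme.obligate_noncarriers
            )
            successes += ok
        best = max(best, successes / 4**m)
    return best


# ---------------------------------------------------------------------------
# SV record helpers


def rec(
    sample: str,
    chrom: str = "chr1",
    pos: int = 1000,
    end: int = 2000,
    svtype: str = "DEL",
    svlen: int | None = None,
    genotype: str = "0/1",
) -> SVRecord:
    if svlen is None:
        svlen = -(end - pos) if svtype == "DEL" else (end - pos if svtype != "INS" else 100)
    return SVRecord(sample, chrom, pos, end, svtype, svlen, genotype)


@pytest.fixture
def nuclear_family():
    return make_nuclear()


@pytest.fixture
def rng():
    return np.random.default_rng(20240525)
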