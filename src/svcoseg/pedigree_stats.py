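"""Null co-segregation probabilities and composite observation statistics.

P(seg) is the probability, under Mendelian gene dropping of a single variant
allele introduced heterozygously in one founder, that the carrier pattern
among genotyped individuals matches a family's segregation scheme (all
obligate carriers carry >=1 allele, no obligate non-carrier does,
unconstrained members free).  The origin founder is unknown, so the
probability is maximised over single-founder origins.

The composite statistics combine P(seg) with either the exonic fraction of
detected variants (single-family form) or the control carrier fraction and a
Bonferroni factor over family combinations (multi-family form).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .core_model import Pedigree, SegregationScheme

__all__ = [
    "SegProbability",
    "ExonicFraction",
    "ObsProbability",
    "p_seg_enumerate",
    "p_seg_montecarlo",
    "estimate_p_exvar",
    "p_obs_single",
    "bonferroni_factor",
    "p_obs_multi",
    "round_report",
    "DEFAULT_MEIOSIS_CAP",
]

log = logging.getLogger(__name__)

#: Enumeration is refused above this many meioses (2 per non-founder).
DEFAULT_MEIOSIS_CAP = 22


@dataclass
class SegProbability:
    """Exact or estimated P(seg) for one (family, scheme)."""

    family_code: str
    scheme_id: str
    p_seg: float
    origin_founder: str | None
    method: str  # "enumeration" | "monte_carlo"
    mc_stderr: float | None = None
    per_founder: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_seg <= 1.0):
            raise ValueError(f"p_seg out of range: {self.p_seg}")
        if (self.method == "monte_carlo") != (self.mc_stderr is not None):
            raise ValueError("mc_stderr present iff method is monte_carlo")


@dataclass(frozen=True)
class ExonicFraction:
    """Fraction of detected variants that are exonic (coding exon or UTR)."""

    p_exvar: float
    n_exonic: int | None = None
    n_total: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_exvar <= 1.0):
            raise ValueError(f"p_exvar out of range: {self.p_exvar}")
        if self.n_total is not None and self.n_exonic is not None:
            if self.n_total <= 0:
                raise ValueError("n_total must be positive")
            expected = self.n_exonic / self.n_total
            if not math.isclose(self.p_exvar, expected, abs_tol=1e-12):
                raise ValueError("p_exvar inconsistent with n_exonic/n_total")


@dataclass
class ObsProbability:
    """Composite P(obs) with its components.

    Exactly one of ``p_exvar`` (single-family exonic form) or ``p_var``
    (multi-family form, the control carrier fraction) is populated, and
    ``p_obs`` always recomputes from the declared product.  ``p_obs`` is NaN
    when the multi-family form is undefined (zero MAF, default policy).
    """

    p_obs: float
    p_segs: list[SegProbability]
    p_exvar: float | None = None
    p_var: float | None = None
    p_anyvar: float = 1.0
    bonferroni: int = 1
    n_families_total: int = 1
    n_families_hit: int = 1

    def __post_init__(self) -> None:
        if (self.p_exvar is None) == (self.p_var is None):
            raise ValueError("exactly one of p_exvar / p_var must be populated")
        if self.p_var is not None:
            if self.bonferroni != math.comb(self.n_families_total, self.n_families_hit):
                raise ValueError("bonferroni must equal C(n_families_total, n_families_hit)")
        elif self.bonferroni != 1:
            raise ValueError("single-family form carries no Bonferroni correction")
        if not math.isnan(self.p_obs):
            prod = math.prod(sp.p_seg for sp in self.p_segs) * self.p_anyvar
            if self.p_exvar is not None:
                prod *= self.p_exvar
            else:
                prod *= self.p_var ** (self.n_families_hit - 1) * self.bonferroni
            if abs(prod - self.p_obs) > 1e-12:
                raise ValueError(f"p_obs {self.p_obs} does not recompute from components ({prod})")


# ---------------------------------------------------------------------------
# Gene-dropping engine


def _check_scheme_against(pedigree: Pedigree, scheme: SegregationScheme) -> None:
    missing = [i for i in scheme.all_ids if i not in pedigree]
    if missing:
        raise ValueError(f"scheme {scheme.scheme_id}: ids not in pedigree: {sorted(missing)}")


def _origin_probability(pedigree: Pedigree, scheme: SegregationScheme, origin_id: str) -> float:
    """Exact P(carrier pattern matches scheme | variant het in ``origin_id``,
    all other founders non-carriers).

    Recursion over non-founders in topological order; a transmission only
    branches when the parent currently carries the allele, so the number of
    explored paths is bounded by 2^(carrier-lineage meioses).  All branch
    probabilities are dyadic, hence exact in binary floats.
    """
    order = pedigree.topological_order()
    nonfounders = [ind for ind in order if not ind.is_founder]
    carriers_req = scheme.obligate_carriers
    noncarr_req = scheme.obligate_noncarriers

    state: dict[str, int] = {}
    for ind in order:
        if ind.is_founder:
            state[ind.id] = 1 if ind.id == origin_id else 0
    # Founder constraints are decided immediately.
    for ind in pedigree.founders:
        cnt = state[ind.id]
        if ind.id in carriers_req and cnt == 0:
            return 0.0
        if ind.id in noncarr_req and cnt > 0:
            return 0.0

    def rec(i: int, prob: float) -> float:
        if i == len(nonfounders):
            return prob
        child = nonfounders[i]
        total = 0.0
        fc = state[child.father_id]
        mc = state[child.mother_id]
        for from_f, pf in _transmit(fc):
            for from_m, pm in _transmit(mc):
                cnt = from_f + from_m
                if child.id in carriers_req and cnt == 0:
                    continue
                if child.id in noncarr_req and cnt > 0:
                    continue
                state[child.id] = cnt
                total += rec(i + 1, prob * pf * pm)
        state.pop(child.id, None)
        return total

    return rec(0, 1.0)


def _transmit(parent_count: int) -> list[tuple[int, float]]:
    if parent_count == 0:
        return [(0, 1.0)]
    if parent_count == 1:
        return [(0, 0.5), (1, 0.5)]
    return [(1, 1.0)]


def p_seg_enumerate(
    pedigree: Pedigree,
    scheme: SegregationScheme,
    max_meioses: int = DEFAULT_MEIOSIS_CAP,
) -> SegProbability:
    """Exact P(seg) by exhaustive enumeration of transmission outcomes,
    maximised over single-founder origins.

    Raises ``ValueError`` when the pedigree has more than ``max_meioses``
    meioses (2 per non-founder) — use :func:`p_seg_montecarlo` instead.
    A scheme unreachable from any single founder yields p_seg = 0 with a
    logged warning, not an error.
    """
    _check_scheme_against(pedigree, scheme)
    n_meioses = 2 * len(pedigree.nonfounders)
    if n_meioses > max_meioses:
        raise ValueError(
            f"family {pedigree.family_code}: {n_meioses} meioses exceeds enumeration cap "
            f"{max_meioses}; use p_seg_montecarlo"
        )
    per_founder = {f.id: _origin_probability(pedigree, scheme, f.id) for f in pedigree.founders}
    best_id, best_p = max(per_founder.items(), key=lambda kv: (kv[1], kv[0]))
    if best_p == 0.0:
        log.warning(
            "family %s scheme %s: carrier pattern unreachable from any single founder (p_seg = 0)",
            pedigree.family_code,
            scheme.scheme_id,
        )
        best_id = None
    return SegProbability(
        family_code=pedigree.family_code,
        scheme_id=scheme.scheme_id,
        p_seg=best_p,
        origin_founder=best_id,
        method="enumeration",
        per_founder=per_founder,
    )


def p_seg_montecarlo(
    pedigree: Pedigree,
    scheme: SegregationScheme,
    n_draws: int,
    seed: int,
) -> SegProbability:
    """Unbiased Monte Carlo estimate of the enumeration quantity.

    Gene dropping is vectorised across draws; the per-founder success
    proportion is maximised over origins and the binomial standard error of
    the winning proportion is reported.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    _check_scheme_against(pedigree, scheme)
    rng = np.random.default_rng(seed)
    order = pedigree.topological_order()
    carriers_req = scheme.obligate_carriers
    noncarr_req = scheme.obligate_noncarriers

    per_founder: dict[str, float] = {}
    for origin in pedigree.founders:
        counts: dict[str, np.ndarray] = {}
        for ind in order:
            if ind.is_founder:
                counts[ind.id] = np.full(n_draws, 1 if ind.id == origin.id else 0, dtype=np.int8)
            else:
                from_f = rng.random(n_draws) < counts[ind.father_id] / 2.0
                from_m = rng.random(n_draws) < counts[ind.mother_id] / 2.0
                counts[ind.id] = from_f.astype(np.int8) + from_m.astype(np.int8)
        ok = np.ones(n_draws, dtype=bool)
        for cid in carriers_req:
            ok &= counts[cid] > 0
        for nid in noncarr_req:
            ok &= counts[nid] == 0
        per_founder[origin.id] = float(ok.mean())

    best_id, best_p = max(per_founder.items(), key=lambda kv: (kv[1], kv[0]))
    stderr = math.sqrt(best_p * (1.0 - best_p) / n_draws)
    return SegProbability(
        family_code=pedigree.family_code,
        scheme_id=scheme.scheme_id,
        p_seg=best_p,
        origin_founder=best_id if best_p > 0 else None,
        method="monte_carlo",
        mc_stderr=stderr,
        per_founder=per_founder,
    )


def p_seg_auto(
    pedigree: Pedigree,
    scheme: SegregationScheme,
    max_meioses: int = DEFAULT_MEIOSIS_CAP,
    n_draws: int = 50_000,
    seed: int = 0,
) -> SegProbability:
    """Enumeration when within the cap, Monte Carlo otherwise."""
    if 2 * len(pedigree.nonfounders) <= max_meioses:
        return p_seg_enumerate(pedigree, scheme, max_meioses=max_meioses)
    return p_seg_montecarlo(pedigree, scheme, n_draws=n_draws, seed=seed)


# ---------------------------------------------------------------------------
# Composite statistics


def estimate_p_exvar(context_labels) -> ExonicFraction:
    """Exonic fraction over classified variant contexts (coding exon or UTR
    both count as exonic)."""
    labels = list(context_labels)
    if not labels:
        raise ValueError("cannot estimate exonic fraction from an empty list")
    n_exonic = sum(1 for c in labels if c.is_exonic)
    return ExonicFraction(p_exvar=n_exonic / len(labels), n_exonic=n_exonic, n_total=len(labels))


def p_obs_single(p_seg, p_exvar: float, n_families_total: int = 1) -> ObsProbability:
    """Single-family exonic form: P(obs) = P(seg) x P(exvar)."""
    sp = _as_segprob(p_seg)
    if not (0.0 <= p_exvar <= 1.0):
        raise ValueError("p_exvar must be in [0, 1]")
    return ObsProbability(
        p_obs=sp.p_seg * p_exvar,
        p_segs=[sp],
        p_exvar=p_exvar,
        bonferroni=1,
        n_families_total=n_families_total if n_families_total >= 1 else 1,
        n_families_hit=1,
    )


def bonferroni_factor(F: int, k: int) -> int:
    """Number of unordered k-subsets of F families, C(F, k)."""
    if k < 1 or F < 1:
        raise ValueError("F and k must be positive")
    if k > F:
        raise ValueError(f"k={k} exceeds F={F}")
    return math.comb(F, k)


def p_obs_multi(
    p_segs,
    maf: float,
    F: int,
    p_anyvar: float = 1.0,
    zero_maf_pvar: float | None = None,
) -> ObsProbability:
    """Multi-family form over k >= 2 families:

        P(obs) = (prod P(seg_i)) x P(anyvar) x maf^(k-1) x C(F, k)

    ``maf`` is the control carrier fraction.  With maf = 0 the statistic is
    undefined and reported as NaN unless ``zero_maf_pvar`` supplies an
    effective P(var).
    """
    sps = [_as_segprob(p) for p in p_segs]
    k = len(sps)
    if k < 2:
        raise ValueError("p_obs_multi requires >= 2 families; use p_obs_single")
    if k > F:
        raise ValueError(f"{k} families hit exceeds F={F}")
    if not (0.0 <= maf < 1.0):
        raise ValueError("maf must be in [0, 1)")
    for sp in sps:
        if sp.p_seg <= 0.0:
            raise ValueError("each p_seg must be in (0, 1]")
    C = bonferroni_factor(F, k)
    effective_maf = maf if maf > 0 else zero_maf_pvar
    if effective_maf is None:
        p_obs = math.nan
        p_var = 0.0
    else:
        p_var = effective_maf
        p_obs = math.prod(sp.p_seg for sp in sps) * p_anyvar * p_var ** (k - 1) * C
    return ObsProbability(
        p_obs=p_obs,
        p_segs=sps,
        p_var=p_var,
        p_anyvar=p_anyvar,
        bonferroni=C,
        n_families_total=F,
        n_families_hit=k,
    )


def _as_segprob(p) -> SegProbability:
    if isinstance(p, SegProbability):
        return p
    p = float(p)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability out of range: {p}")
    return SegProbability(family_code="", scheme_id="", p_seg=p, origin_founder=None, method="enumeration")


def round_report(p: float, decimals: int = 4) -> float:
    """Report rounding: half-away-from-zero to ``decimals`` places, falling
    back to one significant digit for values below 10**-decimals."""
    if math.isnan(p):
        return p
    if p != 0.0 and abs(p) < 10 ** (-decimals):
        exponent = math.floor(math.log10(abs(p)))
        decimals = -exponent
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(p)).quantize(q, rounding=ROUND_HALF_UP))
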