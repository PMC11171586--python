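"""End-to-end co-segregation pipeline: scheme filtering, tiering, recurrence,
statistics, SNV-overlap, and report rendering.

A cluster is accepted for a family when every obligate carrier of one of the
family's schemes carries at least one alternative allele and no obligate
non-carrier does.  Candidates are clusters passing in >=1 family whose
control-cohort tier is at most UNCOMMON.  The nested report categories are
private = ABSENT, rare = ABSENT+RARE, uncommon = ABSENT+RARE+UNCOMMON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import GeneIndex, GenomicContext
from .core_model import Pedigree, SegregationScheme
from .pedigree_stats import (
    ObsProbability,
    SegProbability,
    p_obs_multi,
    p_obs_single,
    round_report,
)
from .sv_cohort import (
    CohortFrequency,
    FrequencyTier,
    SVCluster,
    assign_tier,
    control_frequency,
)

__all__ = [
    "FamilyHit",
    "CandidateVariant",
    "SnvGeneList",
    "evaluate_scheme",
    "find_candidates",
    "attach_statistics",
    "summarize_counts",
    "snv_overlap",
    "read_snv_lists",
    "render_report",
]

TYPE_LABELS = {"DEL": "deletion", "DUP": "duplication", "INV": "inversion", "INS": "insertion"}

#: Nested tier unions used by the summary report.
NESTED_TIERS = {
    "uncommon": (FrequencyTier.ABSENT, FrequencyTier.RARE, FrequencyTier.UNCOMMON),
    "rare": (FrequencyTier.ABSENT, FrequencyTier.RARE),
    "private": (FrequencyTier.ABSENT,),
}


@dataclass
class FamilyHit:
    cluster_id: str
    family_code: str
    scheme_id: str
    passes: bool
    tier: FrequencyTier | None = None
    context: GenomicContext | None = None


@dataclass
class CandidateVariant:
    cluster: SVCluster
    families_hit: dict[str, list[str]]  # family -> scheme_ids that passed
    tier: FrequencyTier
    freq: CohortFrequency
    context: GenomicContext
    p_obs: ObsProbability | None = None
    p_segs_used: dict[str, SegProbability] = field(default_factory=dict)

    @property
    def cluster_id(self) -> str:
        return self.cluster.cluster_id

    @property
    def genes(self) -> list[str]:
        return self.context.genes


@dataclass(frozen=True)
class SnvGeneList:
    """One gene from an external SNV co-segregation list."""

    gene_name: str
    n_families_coseg: int
    tier_label: str = ""

    def __post_init__(self) -> None:
        if self.n_families_coseg < 1:
            raise ValueError("n_families_coseg must be >= 1")


def evaluate_scheme(
    cluster: SVCluster, scheme: SegregationScheme, missing_as_unknown: bool = False
) -> bool:
    """True iff the cluster's carriers satisfy the scheme: every obligate
    carrier has >=1 alt allele and every obligate non-carrier has none.

    A missing genotype at an obligate position fails the scheme (strict
    reading); ``missing_as_unknown`` relaxes obligate non-carriers only.
    """
    carriers = cluster.carrier_samples
    missing = cluster.missing_samples
    if not scheme.obligate_carriers <= carriers:
        return False
    if scheme.obligate_noncarriers & carriers:
        return False
    obligate_missing = (scheme.obligate_carriers | scheme.obligate_noncarriers) & missing
    if obligate_missing:
        if missing_as_unknown and obligate_missing <= scheme.obligate_noncarriers:
            return True
        return False
    return True


def find_candidates(
    clusters: Sequence[SVCluster],
    pedigrees: Mapping[str, Pedigree],
    schemes: Mapping[str, Sequence[SegregationScheme]],
    control_ids: Iterable[str],
    gene_index: GeneIndex,
    max_tier: FrequencyTier = FrequencyTier.UNCOMMON,
    missing_as_unknown: bool = False,
) -> list[CandidateVariant]:
    """Clusters passing >=1 scheme in >=1 family with control tier at most
    ``max_tier`` (COMMON is always excluded), annotated with context."""
    controls = set(control_ids)
    allowed = {FrequencyTier.ABSENT}
    if max_tier in (FrequencyTier.RARE, FrequencyTier.UNCOMMON):
        allowed.add(FrequencyTier.RARE)
    if max_tier is FrequencyTier.UNCOMMON:
        allowed.add(FrequencyTier.UNCOMMON)

    candidates = []
    for cluster in clusters:
        hits: dict[str, list[str]] = {}
        for fam, fam_schemes in schemes.items():
            passed = [
                s.scheme_id
                for s in fam_schemes
                if evaluate_scheme(cluster, s, missing_as_unknown=missing_as_unknown)
            ]
            if passed:
                hits[fam] = passed
        if not hits:
            continue
        freq = control_frequency(cluster, controls)
        tier = assign_tier(freq)
        if tier not in allowed:
            continue
        context = _classify(cluster, gene_index)
        candidates.append(
            CandidateVariant(cluster=cluster, families_hit=hits, tier=tier, freq=freq, context=context)
        )
    return candidates


def _classify(cluster: SVCluster, gene_index: GeneIndex) -> GenomicContext:
    from .annotation import classify_context

    return classify_context(cluster, gene_index)


def attach_statistics(
    candidates: Sequence[CandidateVariant],
    seg_probs: Mapping[tuple[str, str], SegProbability],
    p_exvar: float,
    total_families: int,
    p_anyvar: float = 1.0,
    zero_maf_pvar: float | None = None,
) -> list[CandidateVariant]:
    """Populate p_obs in place: single-family exonic candidates get
    P(seg) x P(exvar); multi-family candidates get the Bonferroni-corrected
    recurrence statistic with the control carrier fraction as P(var);
    single-family non-exonic candidates stay NA.

    When a family passed under several schemes the maximum P(seg) among them
    is used (most favorable accepted pattern).
    """
    for cand in candidates:
        segs: dict[str, SegProbability] = {}
        for fam, scheme_ids in sorted(cand.families_hit.items()):
            best: SegProbability | None = None
            for sid in scheme_ids:
                try:
                    sp = seg_probs[(fam, sid)]
                except KeyError:
                    raise KeyError(
                        f"no segregation probability for family {fam!r} scheme {sid!r}"
                    ) from None
                if best is None or sp.p_seg > best.p_seg:
                    best = sp
            segs[fam] = best
        cand.p_segs_used = segs
        k = len(segs)
        if k == 1:
            if cand.context.is_exonic:
                (sp,) = segs.values()
                cand.p_obs = p_obs_single(sp, p_exvar, n_families_total=total_families)
            else:
                cand.p_obs = None
        else:
            cand.p_obs = p_obs_multi(
                list(segs.values()),
                maf=cand.freq.fraction,
                F=total_families,
                p_anyvar=p_anyvar,
                zero_maf_pvar=zero_maf_pvar,
            )
    return list(candidates)


def summarize_counts(candidates: Sequence[CandidateVariant]) -> dict[str, dict[str, int]]:
    """Nested type x tier counts, e.g. summary["deletion"]["rare"]."""
    out: dict[str, dict[str, int]] = {}
    for label in list(TYPE_LABELS.values()) + ["total"]:
        out[label] = {name: 0 for name in NESTED_TIERS}
    for cand in candidates:
        label = TYPE_LABELS.get(cand.cluster.svtype, cand.cluster.svtype.lower())
        out.setdefault(label, {name: 0 for name in NESTED_TIERS})
        for name, tiers in NESTED_TIERS.items():
            if cand.tier in tiers:
                out[label][name] += 1
                out["total"][name] += 1
    return out


# ---------------------------------------------------------------------------
# SNV-overlap


def read_snv_lists(path: str | Path) -> list[SnvGeneList]:
    """TSV with columns gene, n_families, tier_label ('#' comments)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene\t"):
                continue
            fields = line.split("\t")
            out.append(
                SnvGeneList(
                    gene_name=fields[0],
                    n_families_coseg=int(fields[1]),
                    tier_label=fields[2] if len(fields) > 2 else "",
                )
            )
    return out


def snv_overlap(
    sv_gene_families: Mapping[str, int],
    snv_lists: Sequence[SnvGeneList],
    sv_min_families: int = 1,
    snv_min_families: int = 2,
) -> list[str]:
    """Genes with SV co-segregation in >= sv_min_families families and SNV
    co-segregation in >= snv_min_families families (>= semantics both)."""
    snv_ok = {
        e.gene_name for e in snv_lists if e.n_families_coseg >= snv_min_families
    }
    return sorted(
        g for g, n in sv_gene_families.items() if n >= sv_min_families and g in snv_ok
    )


# ---------------------------------------------------------------------------
# Report rendering


def _position_str(cluster: SVCluster) -> str:
    if cluster.svtype == "INS":
        return f"{cluster.chrom}:{cluster.pos}"
    return f"{cluster.chrom}:{cluster.pos}-{cluster.end}"


def _type_str(cluster: SVCluster) -> str:
    if cluster.svtype == "INS":
        return f"{abs(cluster.svlen)} bp insertion"
    return TYPE_LABELS.get(cluster.svtype, cluster.svtype.lower())


def _maf_str(freq: CohortFrequency) -> str:
    if freq.n_carriers == 0:
        return "0"
    return f"{freq.percent:.2f} ({freq.n_carriers}/{freq.n_controls})"


def _p_obs_str(p_obs: ObsProbability | None) -> str:
    if p_obs is None or math.isnan(p_obs.p_obs):
        return "NA"
    return f"{round_report(p_obs.p_obs):g}"


def build_report_rows(
    candidates: Sequence[CandidateVariant],
    seg_probs: Mapping[tuple[str, str], SegProbability],
) -> dict[str, list[dict]]:
    """Serializable report rows mirroring the family-overview, single-family
    exonic, and multi-family candidate tables."""
    fam_rows = [
        {
            "family": sp.family_code,
            "scheme": sp.scheme_id,
            "p_seg": sp.p_seg,
            "origin_founder": sp.origin_founder or "",
            "method": sp.method,
        }
        for (fam, sid), sp in sorted(seg_probs.items())
    ]

    def _base_row(cand: CandidateVariant) -> dict:
        return {
            "position": _position_str(cand.cluster),
            "type": _type_str(cand.cluster),
            "gene": ";".join(cand.genes),
            "location": cand.context.detail,
            "context": cand.context.context.value,
            "maf_controls": _maf_str(cand.freq),
            "tier": cand.tier.value,
            "families": ",".join(sorted(cand.families_hit)),
            "p_obs": _p_obs_str(cand.p_obs),
        }

    exonic_rows = [
        _base_row(c)
        for c in candidates
        if len(c.families_hit) == 1 and c.context.is_exonic
    ]
    multi_rows = [_base_row(c) for c in candidates if len(c.families_hit) >= 2]
    gene_set = sorted({g for c in candidates for g in c.genes})
    return {
        "families": fam_rows,
        "exonic_candidates": exonic_rows,
        "multifamily_candidates": multi_rows,
        "genes": [{"gene": g} for g in gene_set],
    }


_REPORT_COLUMNS = {
    "families": ["family", "scheme", "p_seg", "origin_founder", "method"],
    "exonic_candidates": [
        "position", "type", "gene", "location", "context", "maf_controls", "tier", "families", "p_obs",
    ],
    "multifamily_candidates": [
        "position", "type", "gene", "location", "context", "maf_controls", "tier", "families", "p_obs",
    ],
}


def render_report(rows: Mapping[str, list[dict]], out_dir: str | Path) -> dict[str, Path]:
    """Write report TSVs plus the gene list for external enrichment tools.

    Deterministic: re-rendering the same rows yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, columns in _REPORT_COLUMNS.items():
        p = out / f"{name}.tsv"
        with open(p, "w") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in rows.get(name, []):
                fh.write("\t".join(str(row[c]) for c in columns) + "\n")
        paths[name] = p
    p = out / "genes.txt"
    with open(p, "w") as fh:
        for row in rows.get("genes", []):
            fh.write(row["gene"] + "\n")
    paths["genes"] = p
    return paths


def save_rows(rows: Mapping[str, list[dict]], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=1, sort_keys=True)


def load_rows(path: str | Path) -> dict[str, list[dict]]:
    with open(path) as fh:
        return json.load(fh)
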