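"""SV VCF ingestion, cross-sample equivalence clustering, and control tiers.

Coordinates are 1-based inclusive throughout, matching VCF; for interval
types (DEL/DUP/INV) the magnitude of ``svlen`` is ``end - pos``, so a
deletion written ``chrN:pos-end`` spans ``end - pos`` bp.  Insertions carry
their inserted length in ``svlen`` and ``end == pos``.

Control frequency is a carrier frequency: the fraction of control
*individuals* with at least one alternative allele, not an allele frequency.
"""

from __future__ import annotations

import enum
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = [
    "SVType",
    "SVRecord",
    "MatchParams",
    "SVCluster",
    "CohortFrequency",
    "FrequencyTier",
    "read_sv_vcf",
    "cluster_svs",
    "control_frequency",
    "assign_tier",
    "write_clusters_tsv",
    "write_merged_vcf",
]

log = logging.getLogger(__name__)

INTERVAL_TYPES = frozenset({"DEL", "DUP", "INV"})


class SVType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"
    BND = "BND"


class FrequencyTier(str, enum.Enum):
    ABSENT = "ABSENT"      # 0% of controls
    RARE = "RARE"          # (0, 1)%
    UNCOMMON = "UNCOMMON"  # [1, 5)%
    COMMON = "COMMON"      # >= 5%


@dataclass
class SVRecord:
    """One SV call in one sample."""

    sample_id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    genotype: str = "0/1"  # "0/1", "1/1", or "missing"
    source_line: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.svtype in INTERVAL_TYPES and self.end < self.pos:
            raise ValueError(f"end < pos for {self.svtype} at {self.chrom}:{self.pos}")
        if self.svtype == "INS" and self.svlen <= 0:
            raise ValueError("INS requires svlen > 0")

    @property
    def is_carrier(self) -> bool:
        return self.genotype in ("0/1", "1/1")

    @property
    def span(self) -> int:
        return self.end - self.pos + 1


@dataclass(frozen=True)
class MatchParams:
    """Cross-sample SV matching thresholds."""

    reciprocal_overlap: float = 0.5
    breakpoint_tol: int = 50
    ins_len_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.reciprocal_overlap <= 1.0):
            raise ValueError("reciprocal_overlap must be in (0, 1]")
        if self.breakpoint_tol < 0:
            raise ValueError("breakpoint_tol must be >= 0")
        if not (0.0 < self.ins_len_ratio <= 1.0):
            raise ValueError("ins_len_ratio must be in (0, 1]")


@dataclass
class SVCluster:
    """Cross-sample equivalence class of SV calls (single linkage)."""

    cluster_id: str
    svtype: str
    chrom: str
    pos: int
    end: int
    svlen: int
    members: list[SVRecord] = field(default_factory=list)
    carrier_samples: set[str] = field(default_factory=set)
    missing_samples: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.pos, self.end, self.svtype)


@dataclass(frozen=True)
class CohortFrequency:
    """Carrier count over control individuals."""

    n_carriers: int
    n_controls: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_carriers <= self.n_controls):
            raise ValueError("need 0 <= n_carriers <= n_controls")
        if self.n_controls == 0:
            raise ValueError("n_controls must be positive")

    @property
    def fraction(self) -> float:
        return self.n_carriers / self.n_controls

    @property
    def percent(self) -> float:
        return 100.0 * self.n_carriers / self.n_controls


# ---------------------------------------------------------------------------
# VCF reading


def _alt_svtype(alt: str | None) -> str | None:
    if alt and alt.startswith("<") and alt.endswith(">"):
        return alt.strip("<>").split(":")[0]
    return None


def read_sv_vcf(path: str | Path, include_missing: bool = False) -> list[SVRecord]:
    """Read an SV VCF into per-sample records.

    Emits one record per (row, sample-with->=1-alt-allele); samples with 0/0
    contribute nothing, and samples with missing genotypes are emitted with
    ``genotype="missing"`` only when ``include_missing`` is set.  SVTYPE is
    taken from INFO or the symbolic ALT; END falls back to pos + |SVLEN| for
    interval types.  Rows missing both END and SVLEN (non-INS) are skipped
    with a warning; BND rows are retained but never clustered.
    """
    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for row in vcf:
            svtype = row.info.get("SVTYPE") or _alt_svtype(row.alts[0] if row.alts else None)
            if svtype is None:
                log.warning("%s: row %s:%s has no SVTYPE; skipped", path, row.chrom, row.pos)
                continue
            svlen_info = row.info.get("SVLEN")
            if isinstance(svlen_info, (tuple, list)):
                svlen_info = svlen_info[0]
            # pysam strips END from INFO and exposes it as the 0-based
            # exclusive stop, which equals the 1-based inclusive END; rows
            # without END get stop = pos + len(ref), i.e. pos for 1 bp REF.
            end_info = row.info.get("END")
            if end_info is None and row.stop > row.pos:
                end_info = row.stop

            pos = row.pos  # pysam exposes POS 1-based
            if svtype == "INS":
                end = pos
                if svlen_info is None:
                    alt = row.alts[0] if row.alts else ""
                    if alt and not alt.startswith("<"):
                        svlen_info = len(alt) - len(row.ref)
                    else:
                        log.warning("%s: INS at %s:%s lacks SVLEN; skipped", path, row.chrom, pos)
                        continue
                svlen = abs(int(svlen_info))
            elif svtype == "BND":
                end, svlen = pos, 0
            else:
                if end_info is not None:
                    end = int(end_info)
                elif svlen_info is not None:
                    end = pos + abs(int(svlen_info))
                else:
                    log.warning(
                        "%s: %s at %s:%s lacks both END and SVLEN; skipped", path, svtype, row.chrom, pos
                    )
                    continue
                svlen = end - pos
                if svtype == "DEL":
                    svlen = -svlen

            src = f"{path}:{row.chrom}:{pos}"
            for sample in samples:
                gt = row.samples[sample].get("GT")
                if gt is None or all(a is None for a in gt):
                    if include_missing:
                        records.append(
                            SVRecord(sample, row.chrom, pos, end, svtype, svlen or 1, "missing", src)
                        )
                    continue
                n_alt = sum(1 for a in gt if a not in (None, 0))
                if n_alt == 0:
                    continue
                genotype = "1/1" if n_alt >= 2 else "0/1"
                records.append(SVRecord(sample, row.chrom, pos, end, svtype, svlen, genotype, src))
    return records


# ---------------------------------------------------------------------------
# Clustering


def _records_link(a: SVRecord, b: SVRecord, params: MatchParams) -> bool:
    if a.svtype != b.svtype or a.chrom != b.chrom:
        return False
    if a.svtype == "INS":
        if abs(a.pos - b.pos) > params.breakpoint_tol:
            return False
        la, lb = abs(a.svlen), abs(b.svlen)
        return min(la, lb) / max(la, lb) >= params.ins_len_ratio
    if abs(a.pos - b.pos) > params.breakpoint_tol or abs(a.end - b.end) > params.breakpoint_tol:
        return False
    shared = min(a.end, b.end) - max(a.pos, b.pos) + 1
    if shared <= 0:
        return False
    return shared / a.span >= params.reciprocal_overlap and shared / b.span >= params.reciprocal_overlap


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_svs(records: Sequence[SVRecord], params: MatchParams | None = None) -> list[SVCluster]:
    """Single-linkage clustering of SV records into cross-sample clusters.

    Two records link iff same svtype and chrom and, for interval types,
    reciprocal overlap >= threshold with both breakpoints within tolerance;
    for insertions, position within tolerance and length ratio >= threshold.
    BND records are excluded (logged).  Deterministic and invariant to input
    order; consensus coordinates are member medians.
    """
    params = params or MatchParams()
    usable = sorted(
        (r for r in records if r.svtype != "BND"),
        key=lambda r: (r.chrom, r.svtype, r.pos, r.end, r.svlen, r.sample_id),
    )
    n_bnd = sum(1 for r in records if r.svtype == "BND")
    if n_bnd:
        log.info("%d BND records excluded from clustering", n_bnd)

    # Records with identical coordinates always link, so pairwise linking
    # runs over unique (chrom, svtype, pos, end, svlen) representatives only.
    key_records: dict[tuple, list[SVRecord]] = {}
    for r in usable:
        key_records.setdefault((r.chrom, r.svtype, r.pos, r.end, r.svlen), []).append(r)
    keys = sorted(key_records)
    reps = [key_records[k][0] for k in keys]

    uf = _UnionFind(len(reps))
    for i, a in enumerate(reps):
        for j in range(i + 1, len(reps)):
            b = reps[j]
            if (b.chrom, b.svtype) != (a.chrom, a.svtype) or b.pos - a.pos > params.breakpoint_tol:
                break
            if _records_link(a, b, params):
                uf.union(i, j)

    groups: dict[int, list[SVRecord]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(uf.find(i), []).extend(key_records[key])

    clusters = []
    for members in groups.values():
        pos = int(statistics.median_low([m.pos for m in members]))
        end = int(statistics.median_low([m.end for m in members]))
        svlen = int(statistics.median_low([m.svlen for m in members]))
        clusters.append(
            SVCluster(
                cluster_id="",
                svtype=members[0].svtype,
                chrom=members[0].chrom,
                pos=pos,
                end=end,
                svlen=svlen,
                members=members,
                carrier_samples={m.sample_id for m in members if m.is_carrier},
                missing_samples={m.sample_id for m in members if m.genotype == "missing"},
            )
        )
    clusters.sort(key=lambda c: (c.chrom, c.pos, c.end, c.svtype))
    for i, c in enumerate(clusters):
        c.cluster_id = f"sv{i:06d}"
    return clusters


# ---------------------------------------------------------------------------
# Control frequency and tiers


def control_frequency(cluster: SVCluster, control_ids: Iterable[str]) -> CohortFrequency:
    """Carrier frequency of a cluster among control individuals; missing
    control genotypes count as non-carrier (lower bound)."""
    controls = set(control_ids)
    if not controls:
        raise ValueError("control set must be non-empty")
    n_missing = len(cluster.missing_samples & controls)
    if n_missing:
        log.debug("cluster %s: %d control genotypes missing, counted as non-carrier",
                  cluster.cluster_id, n_missing)
    return CohortFrequency(n_carriers=len(cluster.carrier_samples & controls), n_controls=len(controls))


def assign_tier(freq: CohortFrequency) -> FrequencyTier:
    """Disjoint tier per the strict '<' boundaries: 0 -> ABSENT,
    (0,1)% -> RARE, [1,5)% -> UNCOMMON, >=5% -> COMMON."""
    pct = freq.percent
    if pct == 0.0:
        return FrequencyTier.ABSENT
    if pct < 1.0:
        return FrequencyTier.RARE
    if pct < 5.0:
        return FrequencyTier.UNCOMMON
    return FrequencyTier.COMMON


# ---------------------------------------------------------------------------
# Output


def write_clusters_tsv(clusters: Sequence[SVCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchrom\tpos\tend\tsvtype\tsvlen\tn_members\tcarrier_samples\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.chrom}\t{c.pos}\t{c.end}\t{c.svtype}\t{c.svlen}\t"
                f"{len(c.members)}\t{','.join(sorted(c.carrier_samples))}\n"
            )


def write_merged_vcf(clusters: Sequence[SVCluster], samples: Sequence[str], path: str | Path) -> None:
    """Merged multi-sample VCF at consensus coordinates with per-sample GT."""
    contigs = sorted({c.chrom for c in clusters})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for c in sorted(clusters, key=lambda c: (c.chrom, c.pos, c.end)):
            gts = {m.sample_id: m.genotype for m in c.members}
            gt_col = "\t".join(
                "./." if gts.get(s) == "missing" else gts.get(s, "0/0").replace("missing", "./.")
                for s in samples
            )
            info = f"SVTYPE={c.svtype};END={c.end};SVLEN={c.svlen}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.cluster_id}\tN\t<{c.svtype}>\t.\tPASS\t{info}\tGT\t{gt_col}\n"
            )
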