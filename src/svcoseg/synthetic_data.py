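"""Synthetic multiplex-family SV cohorts with known truth.

Emulates the study design — 17 multiplex families (4–14 genomes each, about
two-thirds of genotyped members affected), 102 unrelated controls, a few
hundred background SVs per genome dominated by deletions — on a small
synthetic genome (5 contigs x 10 Mb), with a configurable number of injected
variants that co-segregate under one family's scheme and are absent from
controls.  Every stage of the pipeline can be exercised against the emitted
truth records without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import (
    Individual,
    Pedigree,
    Phenotype,
    SegregationScheme,
    Sex,
    default_scheme,
    write_ped,
    write_schemes,
)
from .pedigree_stats import p_seg_auto
from .sv_cohort import SVRecord

__all__ = [
    "SimConfig",
    "Locus",
    "TruthRecord",
    "Cohort",
    "gen_pedigree",
    "drop_background",
    "inject_coseg",
    "generate_cohort",
    "records_from_cohort",
    "write_cohort",
]

SV_TYPE_NAMES = ("DEL", "DUP", "INS", "INV")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults scale the study design down ~9x."""

    n_families: int = 17
    genomes_min: int = 4
    genomes_max: int = 14
    n_controls: int = 102
    svs_per_genome: int = 300
    # DEL-dominated mix (study proportions renormalised to sum to 1).
    type_mix: tuple[float, float, float, float] = (0.75, 0.16, 0.04, 0.05)
    n_injected: int = 5
    affected_fraction: float = 80 / 124
    n_contigs: int = 5
    contig_length: int = 10_000_000
    genes_per_contig: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix proportions must sum to 1")
        if min(self.n_families, self.n_controls, self.svs_per_genome, self.n_injected + 1) <= 0:
            raise ValueError("counts must be positive")
        if not (0 < self.genomes_min <= self.genomes_max):
            raise ValueError("invalid genomes range")

    @property
    def family_codes(self) -> list[str]:
        alphabet = [c for c in "ABCDEFGHIJKLMNOPQRSTUVWXY"]
        return [
            alphabet[i] if i < len(alphabet) else f"F{i}" for i in range(self.n_families)
        ]

    @property
    def contigs(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_contigs)]


@dataclass(frozen=True)
class Locus:
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    allele_freq: float  # background founder/control allele frequency

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.pos, self.end, self.svtype)


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    pos: int
    end: int
    svtype: str
    injected: bool
    expected_families: frozenset[str]
    expected_tier: str


@dataclass
class Cohort:
    config: SimConfig
    pedigrees: dict[str, Pedigree]
    schemes: dict[str, list[SegregationScheme]]
    loci: list[Locus]
    genotypes: dict[str, np.ndarray]  # sample id -> allele counts per locus
    control_ids: list[str]
    truth: list[TruthRecord]
    gene_rows: list[tuple] = field(default_factory=list)  # GFF3 feature tuples

    @property
    def family_sample_ids(self) -> dict[str, list[str]]:
        return {
            fam: sorted(ped.genotyped_ids) for fam, ped in sorted(self.pedigrees.items())
        }


# ---------------------------------------------------------------------------
# Pedigree generation


def gen_pedigree(config: SimConfig, family_code: str, seed: int) -> Pedigree:
    """Random 2–3-generation pedigree with a genotyped-genome count drawn
    from the configured range, >=1 genotyped affected member, and phenotypes
    approximating the configured affected fraction.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    ped = Pedigree(family_code=family_code)
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{family_code}_{counter:03d}"

    def new_ind(father=None, mother=None, sex=None) -> Individual:
        if sex is None:
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        ind = Individual(
            id=new_id(), family_code=family_code, father_id=father, mother_id=mother, sex=sex
        )
        ped.add(ind)
        return ind

    target = int(rng.integers(config.genomes_min, config.genomes_max + 1))
    f0 = new_ind(sex=Sex.MALE)
    m0 = new_ind(sex=Sex.FEMALE)
    gen2 = [new_ind(father=f0.id, mother=m0.id) for _ in range(int(rng.integers(3, 6)))]
    for child in gen2:
        if len(ped) >= target + 4:
            break
        if rng.random() < 0.6:
            spouse = new_ind(sex=Sex.FEMALE if child.sex is Sex.MALE else Sex.MALE)
            father, mother = (child, spouse) if child.sex is Sex.MALE else (spouse, child)
            for _ in range(int(rng.integers(1, 4))):
                new_ind(father=father.id, mother=mother.id)
    members = list(ped.individuals)

    # Phenotypes arise from an actual single-founder gene drop (complete
    # penetrance, no phenocopies), so the affected pattern is always
    # reachable from one founder and the default scheme is satisfiable.
    order = ped.topological_order()
    for _attempt in range(200):
        counts = {}
        for ind in order:
            if ind.is_founder:
                counts[ind.id] = 1 if ind.id == f0.id else 0
            else:
                counts[ind.id] = int(rng.random() < counts[ind.father_id] / 2.0) + int(
                    rng.random() < counts[ind.mother_id] / 2.0
                )
        n_carriers = sum(1 for c in counts.values() if c > 0)
        want = max(2, round(config.affected_fraction * target))
        if want <= n_carriers < len(members):
            break
    for ind in members:
        if counts[ind.id] > 0:
            ind.phenotype = Phenotype.GTS if rng.random() < 0.5 else Phenotype.TD
        else:
            ind.phenotype = Phenotype.HEALTHY

    # Genotyping biased toward affected members to approximate the target
    # affected fraction among sequenced genomes.
    target = min(target, len(members))
    affected = [i for i, ind in enumerate(members) if ind.phenotype is not Phenotype.HEALTHY]
    healthy = [i for i, ind in enumerate(members) if ind.phenotype is Phenotype.HEALTHY]
    rng.shuffle(affected)
    rng.shuffle(healthy)
    n_aff = min(len(affected), max(1, round(config.affected_fraction * target)))
    chosen = affected[:n_aff] + healthy[: target - n_aff]
    if len(chosen) < target:
        chosen += affected[n_aff : n_aff + target - len(chosen)]
    for i in chosen:
        members[i].genotyped = True
    return ped


# ---------------------------------------------------------------------------
# Genotype simulation


def drop_background(pedigree: Pedigree, allele_freqs: np.ndarray, seed: int) -> dict[str, np.ndarray]:
    """Mendelian gene dropping of background loci through one family.

    Founder allele counts ~ Binomial(2, f) per locus; each meiosis transmits
    the variant allele with probability (parent count)/2.  Returns per-member
    allele-count vectors across all loci.
    """
    rng = np.random.default_rng(seed)
    n = len(allele_freqs)
    counts: dict[str, np.ndarray] = {}
    for ind in pedigree.topological_order():
        if ind.is_founder:
            counts[ind.id] = rng.binomial(2, allele_freqs).astype(np.int8)
        else:
            from_f = (rng.random(n) < counts[ind.father_id] / 2.0).astype(np.int8)
            from_m = (rng.random(n) < counts[ind.mother_id] / 2.0).astype(np.int8)
            counts[ind.id] = from_f + from_m
    return counts


def inject_coseg(
    pedigree: Pedigree,
    scheme: SegregationScheme,
    sv_template: Locus,
    seed: int = 0,
) -> tuple[dict[str, int], TruthRecord]:
    """Genotypes for one injected variant satisfying ``scheme`` by
    construction: heterozygous in every obligate carrier, absent elsewhere
    (the minimal satisfying state).  Errors on unsatisfiable schemes."""
    prob = p_seg_auto(pedigree, scheme, max_meioses=60, n_draws=2000, seed=seed)
    if prob.p_seg == 0.0:
        raise ValueError(
            f"scheme {scheme.scheme_id} is unsatisfiable under single-founder origin"
        )
    genotypes = {ind.id: 0 for ind in pedigree}
    for cid in scheme.obligate_carriers:
        genotypes[cid] = 1
    truth = TruthRecord(
        chrom=sv_template.chrom,
        pos=sv_template.pos,
        end=sv_template.end,
        svtype=sv_template.svtype,
        injected=True,
        expected_families=frozenset({pedigree.family_code}),
        expected_tier="ABSENT",
    )
    return genotypes, truth


# ---------------------------------------------------------------------------
# Gene model / locus placement


def _make_genes(config: SimConfig, rng: np.random.Generator) -> list[tuple]:
    """Synthetic gene features as (chrom, start, end, strand, gene_name,
    transcript rows).  Genes occupy the first 60% of each contig; the tail
    40% stays intergenic so injected/background intergenic placement is easy."""
    rows = []
    for ci, chrom in enumerate(config.contigs):
        span = int(config.contig_length * 0.6)
        pitch = span // (config.genes_per_contig + 1)
        for gi in range(config.genes_per_contig):
            anchor = pitch * (gi + 1) + int(rng.integers(0, pitch // 4))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(3, 6))
            exons = []
            cursor = anchor
            for _ in range(n_exons):
                length = int(rng.integers(150, 401))
                exons.append((cursor, cursor + length - 1))
                cursor += length + int(rng.integers(1000, 3001))
            cds_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
            cds_end = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2
            name = f"GENE{ci + 1}_{gi + 1}"
            rows.append((chrom, exons[0][0], exons[-1][1], strand, name, exons, (cds_start, cds_end)))
    return rows


def _gene_gff3_lines(gene_rows: list[tuple]) -> list[str]:
    lines = ["##gff-version 3"]
    for chrom, gstart, gend, strand, name, exons, (cds_s, cds_e) in gene_rows:
        gid = f"gene:{name}"
        tid = f"transcript:{name}.t1"
        lines.append(
            f"{chrom}\tsvcoseg_sim\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid};Name={name}"
        )
        lines.append(
            f"{chrom}\tsvcoseg_sim\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\tID={tid};Parent={gid}"
        )
        for i, (es, ee) in enumerate(exons, 1):
            lines.append(
                f"{chrom}\tsvcoseg_sim\texon\t{es}\t{ee}\t.\t{strand}\t.\t"
                f"ID={tid}.exon{i};Parent={tid}"
            )
            cs, ce = max(es, cds_s), min(ee, cds_e)
            if cs <= ce:
                lines.append(
                    f"{chrom}\tsvcoseg_sim\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\t"
                    f"ID={tid}.cds{i};Parent={tid}"
                )
    return lines


def _draw_background_loci(
    config: SimConfig, rng: np.random.Generator, forbidden: list[tuple[str, int, int]]
) -> list[Locus]:
    """Background loci with allele frequencies drawn until the expected
    per-genome carrier count reaches ``svs_per_genome``."""
    loci: list[Locus] = []
    expected = 0.0
    margin = 1000
    type_p = np.asarray(config.type_mix)
    while expected < config.svs_per_genome:
        chrom = config.contigs[int(rng.integers(0, config.n_contigs))]
        svtype = SV_TYPE_NAMES[int(rng.choice(4, p=type_p))]
        pos = int(rng.integers(margin, config.contig_length - 20_000))
        if any(c == chrom and abs(pos - s) < margin + 5000 for c, s, _ in forbidden):
            continue
        if svtype == "INS":
            length = int(rng.integers(50, 501))
            end = pos
            svlen = length
        else:
            length = int(rng.integers(60, 5001))
            end = pos + length
            svlen = -length if svtype == "DEL" else length
        freq = float(np.clip(rng.beta(0.5, 3.0), 0.002, 0.7))
        loci.append(Locus(chrom, pos, end, svtype, svlen, freq))
        expected += 1.0 - (1.0 - freq) ** 2
    return loci


# ---------------------------------------------------------------------------
# Cohort assembly


def generate_cohort(config: SimConfig | None = None, seed: int | None = None) -> Cohort:
    """Full in-memory cohort: pedigrees, schemes, loci, genotypes, truth."""
    config = config or SimConfig()
    root_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    (s_genes, s_ped, s_inject, s_bg, s_drop, s_ctrl) = ss.spawn(6)
    rng_genes = np.random.default_rng(s_genes)
    rng_inject = np.random.default_rng(s_inject)
    rng_bg = np.random.default_rng(s_bg)

    gene_rows = _make_genes(config, rng_genes)

    ped_seeds = s_ped.spawn(config.n_families)
    pedigrees: dict[str, Pedigree] = {}
    schemes: dict[str, list[SegregationScheme]] = {}
    for code, pseed in zip(config.family_codes, ped_seeds):
        ped = gen_pedigree(config, code, seed=int(pseed.generate_state(1)[0]))
        pedigrees[code] = ped
        schemes[code] = [default_scheme(ped)]

    # Injected co-segregating loci: round-robin over families, alternating
    # exonic (inside a CDS) and intergenic (gene-free tail) placement.
    injected: list[tuple[Locus, str]] = []
    truth: list[TruthRecord] = []
    codes = config.family_codes
    for i in range(config.n_injected):
        fam = codes[i % len(codes)]
        for _attempt in range(100):
            if i % 2 == 0:
                row = gene_rows[int(rng_inject.integers(0, len(gene_rows)))]
                chrom, _, _, _, _, exons, (cds_s, cds_e) = row
                exon = exons[0]
                pos = max(exon[0], cds_s)
                end = min(exon[1], pos + int(rng_inject.integers(80, 200)))
            else:
                chrom = config.contigs[int(rng_inject.integers(0, config.n_contigs))]
                pos = int(
                    rng_inject.integers(int(config.contig_length * 0.7), config.contig_length - 20_000)
                )
                end = pos + int(rng_inject.integers(100, 2000))
            # Injected loci must never cluster with one another.
            if all(loc.chrom != chrom or abs(loc.pos - pos) > 10_000 for loc, _ in injected):
                break
        else:
            raise RuntimeError("could not place injected locus away from existing ones")
        injected.append((Locus(chrom, pos, end, "DEL", -(end - pos), 0.0), fam))

    forbidden = [(loc.chrom, loc.pos, loc.end) for loc, _ in injected]
    background = _draw_background_loci(config, rng_bg, forbidden)
    loci = [loc for loc, _ in injected] + background
    freqs = np.array([loc.allele_freq for loc in loci])
    n_injected = len(injected)

    genotypes: dict[str, np.ndarray] = {}
    drop_seeds = s_drop.spawn(config.n_families)
    inject_seeds = s_inject.spawn(max(1, n_injected))
    for (code, ped), dseed in zip(pedigrees.items(), drop_seeds):
        counts = drop_background(ped, freqs, seed=int(dseed.generate_state(1)[0]))
        for ind in ped:
            genotypes[ind.id] = counts[ind.id]
    for i, ((locus, fam), iseed) in enumerate(zip(injected, inject_seeds)):
        scheme = schemes[fam][0]
        inj_gts, trec = inject_coseg(
            pedigrees[fam], scheme, locus, seed=int(iseed.generate_state(1)[0])
        )
        truth.append(trec)
        for code, ped in pedigrees.items():
            for ind in ped:
                genotypes[ind.id][i] = inj_gts.get(ind.id, 0) if code == fam else 0

    rng_ctrl = np.random.default_rng(s_ctrl)
    control_ids = [f"CTRL_{i:03d}" for i in range(config.n_controls)]
    for cid in control_ids:
        gt = rng_ctrl.binomial(2, freqs).astype(np.int8)
        gt[:n_injected] = 0  # injected variants are absent from all controls
        genotypes[cid] = gt

    for loc in background:
        truth.append(
            TruthRecord(loc.chrom, loc.pos, loc.end, loc.svtype, False, frozenset(), "")
        )

    return Cohort(
        config=config,
        pedigrees=pedigrees,
        schemes=schemes,
        loci=loci,
        genotypes=genotypes,
        control_ids=control_ids,
        truth=truth,
        gene_rows=gene_rows,
    )


def records_from_cohort(cohort: Cohort, sample_ids=None) -> list[SVRecord]:
    """Carrier SVRecords for the given samples (default: all genotyped family
    members plus controls), bypassing VCF round-trips."""
    if sample_ids is None:
        sample_ids = [
            iid for fam in sorted(cohort.pedigrees) for iid in sorted(cohort.pedigrees[fam].genotyped_ids)
        ] + list(cohort.control_ids)
    records = []
    for sid in sample_ids:
        counts = cohort.genotypes[sid]
        for idx in np.nonzero(counts)[0]:
            loc = cohort.loci[idx]
            records.append(
                SVRecord(
                    sample_id=sid,
                    chrom=loc.chrom,
                    pos=loc.pos,
                    end=loc.end,
                    svtype=loc.svtype,
                    svlen=loc.svlen,
                    genotype="1/1" if counts[idx] >= 2 else "0/1",
                    source_line="sim",
                )
            )
    return records


# ---------------------------------------------------------------------------
# File output (all plain text)


def _write_vcf(path: Path, samples: list[str], cohort: Cohort) -> None:
    order = sorted(range(len(cohort.loci)), key=lambda i: (cohort.loci[i].chrom, cohort.loci[i].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in cohort.config.contigs:
            fh.write(f"##contig=<ID={contig},length={cohort.config.contig_length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for idx in order:
            loc = cohort.loci[idx]
            gts = []
            any_alt = False
            for s in samples:
                c = int(cohort.genotypes[s][idx])
                gts.append("0/0" if c == 0 else ("0/1" if c == 1 else "1/1"))
                any_alt = any_alt or c > 0
            if not any_alt:
                continue
            info = f"SVTYPE={loc.svtype};END={loc.end};SVLEN={loc.svlen}"
            if loc.svtype == "INS":
                info = f"SVTYPE=INS;SVLEN={loc.svlen}"
            fh.write(
                f"{loc.chrom}\t{loc.pos}\tlocus{idx:05d}\tN\t<{loc.svtype}>\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as plain-text VCF/PED/YAML/GFF3/TSV files.

    Layout: ``families/<code>.vcf`` (multi-sample per family),
    ``controls/controls.vcf``, ``cohort.ped``, ``schemes.yaml``,
    ``genes.gff3``, ``truth.tsv``.  Deterministic bytes for a fixed cohort.
    """
    out = Path(out_dir)
    fam_dir = out / "families"
    ctrl_dir = out / "controls"
    fam_dir.mkdir(parents=True, exist_ok=True)
    ctrl_dir.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}
    for fam, samples in cohort.family_sample_ids.items():
        p = fam_dir / f"{fam}.vcf"
        _write_vcf(p, samples, cohort)
        paths[f"family_{fam}"] = p
    paths["controls"] = ctrl_dir / "controls.vcf"
    _write_vcf(paths["controls"], list(cohort.control_ids), cohort)

    paths["ped"] = out / "cohort.ped"
    write_ped(
        [cohort.pedigrees[f] for f in sorted(cohort.pedigrees)], paths["ped"]
    )
    paths["schemes"] = out / "schemes.yaml"
    write_schemes(cohort.schemes, paths["schemes"])

    paths["gff"] = out / "genes.gff3"
    with open(paths["gff"], "w") as fh:
        fh.write("\n".join(_gene_gff3_lines(cohort.gene_rows)) + "\n")

    paths["truth"] = out / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tpos\tend\tsvtype\tinjected\texpected_families\texpected_tier\n")
        for t in cohort.truth:
            fh.write(
                f"{t.chrom}\t{t.pos}\t{t.end}\t{t.svtype}\t{int(t.injected)}\t"
                f"{','.join(sorted(t.expected_families))}\t{t.expected_tier}\n"
            )
    return paths
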