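"""Synthetic study generator for the capture-panel analysis pipeline.

Emulates, without any external download, the statistical structure the
downstream modules assume:

* a multi-gene exon panel (toy reference sequences with defined reading
  frames) with a configurable fraction of target bases inside repeats;
* per-base depth profiles with high median coverage, short-range
  autocorrelation, and contiguous GC-dropout blocks forced below 10 reads;
* per-proband variant tables mixing shared common polymorphisms, dbSNP
  alleles, private rare variants, and an optionally planted causal allele
  with binomial read support at VAF ~0.5 (het) or ~0.995 (hom), plus
  optional cryptic-indel fixtures read as two adjacent ~25%-VAF SNVs;
* pedigrees segregating recessive or dominant alleles, and case/control
  cohorts drawn under Hardy-Weinberg at distinct founder-allele frequencies.

All outputs are deterministic functions of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .filter_cascade import AnnotationStubs
from .genes import Effect, GeneModel, classify_effect
from .intervals import GenomicInterval, Role, merge_intervals, write_bed
from .panel_design import expand_targets
from .segregation import Genotype, PedigreeMember, write_genotypes, write_ped
from .variant_model import VariantObservation, write_variant_table

__all__ = [
    "SimulationConfig",
    "Panel",
    "DepthProfile",
    "PlantedCausal",
    "TruthRecord",
    "StudyTables",
    "CohortSim",
    "simulate_panel",
    "simulate_depth",
    "simulate_proband_variants",
    "simulate_reads",
    "simulate_cohort",
    "simulate_family",
    "write_study",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_CAUSAL_MODELS = {"recessive_hom", "recessive_compound_het", "dominant_het"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the published study's magnitudes: an 11-proband cohort
    sequenced over a ~250-gene panel at median coverage near 937x with ~5%
    GC dropout, ~8% of target bases repeat-masked, and a founder allele at
    frequency 0.337 in 52 cases vs 0.028 in 282 controls with a second
    pathogenic allele at 0.058.
    """

    seed: int = 0
    n_genes: int = 246
    exons_per_gene: tuple[int, int] = (6, 26)
    exon_length: tuple[int, int] = (80, 360)
    repeat_fraction: float = 0.08
    median_depth: float = 937.0
    dropout_fraction: float = 0.05
    n_probands: int = 11
    common_poly_rate: float = 2.0  # sites per kb of target
    dbsnp_overlap: float = 0.9
    causal_model: str = "recessive_hom"
    case_allele_freq: float = 0.337
    control_allele_freq: float = 0.028
    # plumbing beyond the headline conditions
    n_cases: int = 52
    n_controls: int = 282
    compound_allele_freq: float = 0.058
    private_snv_mean: float = 25.0
    private_indel_mean: float = 35.0
    private_hom_fraction: float = 0.02
    n_families: int = 3

    def __post_init__(self) -> None:
        for name in (
            "repeat_fraction",
            "dropout_fraction",
            "dbsnp_overlap",
            "case_allele_freq",
            "control_allele_freq",
            "compound_allele_freq",
            "private_hom_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        for name in ("exons_per_gene", "exon_length"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or non-positive")
        if self.exon_length[0] < 30:
            raise ValueError("exon_length minimum must be >= 30 to fit a reading frame")
        if self.median_depth <= 0:
            raise ValueError("median_depth must be positive")
        if min(self.n_genes, self.n_probands, self.n_cases, self.n_controls) < 1:
            raise ValueError("counts must be >= 1")
        if self.causal_model not in _CAUSAL_MODELS:
            raise ValueError(f"causal_model must be one of {sorted(_CAUSAL_MODELS)}")
        if self.case_allele_freq + self.compound_allele_freq > 1.0:
            raise ValueError("case + compound allele frequencies exceed 1")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _rng(cfg: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, salt])


# -- panel --------------------------------------------------------------------


@dataclass
class Panel:
    genes: list[GeneModel]
    exons: list[GenomicInterval]
    repeats: list[GenomicInterval]
    targets: list[GenomicInterval]
    reference: dict[str, str]


def _coding_positions(exons, cds_start, cds_end, strand) -> list[int]:
    pos = [p for s, e in exons for p in range(max(s, cds_start), min(e, cds_end))]
    if strand == "-":
        pos.reverse()
    return pos


def simulate_panel(cfg: SimulationConfig) -> Panel:
    """Generate gene structures, toy reference sequences, targets and repeats."""
    rng = _rng(cfg, 1)
    genes_per_contig = 24
    genes: list[GeneModel] = []
    exons: list[GenomicInterval] = []
    layouts = []  # (name, chrom, exon tuples, cds_start, cds_end, strand)
    contig_cursor: dict[str, int] = {}

    for gi in range(cfg.n_genes):
        chrom = f"chr{gi // genes_per_contig + 1}"
        cursor = contig_cursor.get(chrom, 10_000)
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.8 else "-"
        ex = []
        pos = cursor
        for _ in range(n_ex):
            length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            ex.append((pos, pos + length))
            pos += length + int(rng.integers(200, 2001))
        name = f"GENE{gi + 1:03d}"
        utr5 = int(rng.integers(0, min(25, ex[0][1] - ex[0][0] - 3)))
        utr3 = int(rng.integers(0, min(25, ex[-1][1] - ex[-1][0] - 3)))
        cds_start = ex[0][0] + (utr5 if strand == "+" else utr3)
        cds_end = ex[-1][1] - (utr3 if strand == "+" else utr5)
        coding_len = sum(min(e, cds_end) - max(s, cds_start) for s, e in ex)
        cds_end -= coding_len % 3 if strand == "+" else 0
        if strand == "-":
            cds_start += coding_len % 3
        layouts.append((name, chrom, tuple(ex), cds_start, cds_end, strand))
        contig_cursor[chrom] = ex[-1][1] + int(rng.integers(5_000, 20_001))

    # one random sequence per contig, then purge in-frame premature stops
    contig_len = {c: cur + 1_000 for c, cur in contig_cursor.items()}
    reference: dict[str, str] = {}
    seq_arrays = {
        c: rng.choice(_BASES, size=n).astype("S1") for c, n in contig_len.items()
    }
    for name, chrom, ex, cds_start, cds_end, strand in layouts:
        arr = seq_arrays[chrom]
        positions = _coding_positions(ex, cds_start, cds_end, strand)
        for c0 in range(0, len(positions) - 3, 3):
            # positions are already in transcript order; '-' needs complement only
            codon = b"".join(arr[positions[c0 + i]] for i in range(3)).decode()
            if strand == "-":
                codon = codon.translate(_COMPLEMENT)
            if codon in _STOPS:
                # third transcript base -> T (never yields a stop)
                arr[positions[c0 + 2]] = b"T" if strand == "+" else b"A"
    for c, arr in seq_arrays.items():
        reference[c] = arr.tobytes().decode()

    for name, chrom, ex, cds_start, cds_end, strand in layouts:
        genes.append(
            GeneModel(
                name=name,
                chrom=chrom,
                exons=ex,
                cds_start=cds_start,
                cds_end=cds_end,
                seq=reference[chrom],
                strand=strand,
            )
        )
        exons.extend(
            GenomicInterval(chrom, s, e, role=Role.EXON, name=name, strand=strand)
            for s, e in ex
        )

    targets = expand_targets(exons, flank=40)
    repeats = _simulate_repeats(targets, cfg.repeat_fraction, rng)
    return Panel(genes=genes, exons=exons, repeats=repeats, targets=targets, reference=reference)


def _target_sampler(targets: Sequence[GenomicInterval]):
    lens = np.array([len(t) for t in targets], dtype=float)
    cum = np.cumsum(lens)
    return lens, cum


def _simulate_repeats(
    targets: Sequence[GenomicInterval], fraction: float, rng: np.random.Generator
) -> list[GenomicInterval]:
    if fraction <= 0.0:
        return []
    lens, cum = _target_sampler(targets)
    total = int(cum[-1])
    goal = int(round(fraction * total))
    # boolean mask over concatenated target bases for exact accounting
    mask = np.zeros(total, dtype=bool)
    offsets = np.concatenate([[0], cum[:-1]]).astype(int)
    blocks: list[GenomicInterval] = []
    covered = 0
    guard = 0
    while covered < goal and guard < 100_000:
        guard += 1
        ti = int(rng.integers(0, len(targets)))
        t = targets[ti]
        length = int(rng.integers(150, 601))
        length = min(length, len(t))
        off = int(rng.integers(0, len(t) - length + 1))
        lo, hi = offsets[ti] + off, offsets[ti] + off + length
        new = int(length - mask[lo:hi].sum())
        if new == 0:
            continue
        mask[lo:hi] = True
        covered += new
        blocks.append(
            GenomicInterval(t.chrom, t.start + off, t.start + off + length, role=Role.REPEAT)
        )
    return merge_intervals(blocks, role=Role.REPEAT)


# -- depth --------------------------------------------------------------------


@dataclass
class DepthProfile:
    targets: list[GenomicInterval]
    depths: list[np.ndarray]

    def all_depths(self) -> np.ndarray:
        return np.concatenate(self.depths) if self.depths else np.empty(0)

    def depth_at(self, chrom: str, pos0: int) -> int | None:
        for t, d in zip(self.targets, self.depths):
            if t.contains(chrom, pos0):
                return int(d[pos0 - t.start])
        return None


def simulate_depth(
    targets: Sequence[GenomicInterval], cfg: SimulationConfig
) -> DepthProfile:
    """Lognormal depth with short-range autocorrelation plus GC-dropout blocks.

    Contiguous dropout cores (totalling ``dropout_fraction`` of target bases)
    are forced below 10 reads, with ~40 bp log-linear shoulders on each side
    emulating the gradual coverage decay into GC-rich sequence.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("no targets supplied")
    rng = _rng(cfg, 2)
    rho, sigma = 0.99, 0.25
    c = sigma * math.sqrt(1.0 - rho * rho)
    depths: list[np.ndarray] = []
    from scipy.signal import lfilter

    for t in targets:
        z = rng.normal(0.0, 1.0, size=len(t))
        e = lfilter([1.0], [1.0, -rho], c * z)
        e += rng.normal(0.0, sigma) * rho ** np.arange(len(t))
        depths.append(np.maximum(0, np.rint(cfg.median_depth * np.exp(e))).astype(int))

    if cfg.dropout_fraction > 0.0:
        lens, cum = _target_sampler(targets)
        total = int(cum[-1])
        goal = int(round(cfg.dropout_fraction * total))
        offsets = np.concatenate([[0], cum[:-1]]).astype(int)
        mask = np.zeros(total, dtype=bool)
        covered = 0
        guard = 0
        shoulder = 40
        while covered < goal and guard < 100_000:
            guard += 1
            ti = int(rng.integers(0, len(targets)))
            d = depths[ti]
            length = min(int(rng.integers(200, 801)), len(d))
            off = int(rng.integers(0, len(d) - length + 1))
            lo, hi = offsets[ti] + off, offsets[ti] + off + length
            new = int(length - mask[lo:hi].sum())
            if new == 0:
                continue
            mask[lo:hi] = True
            covered += new
            core = rng.integers(0, 10, size=length)
            d[off : off + length] = core
            anchor = 5.0  # shoulder pivot depth
            for k in range(1, shoulder + 1):
                frac = k / (shoulder + 1)
                j = off - k
                if j >= 0 and d[j] > anchor:
                    d[j] = int(round(anchor ** (1 - frac) * max(d[j], anchor) ** frac))
                j = off + length - 1 + k
                if j < len(d) and d[j] > anchor:
                    d[j] = int(round(anchor ** (1 - frac) * max(d[j], anchor) ** frac))
    return DepthProfile(targets=targets, depths=depths)


def simulate_reads(
    targets: Sequence[GenomicInterval],
    n_reads: int,
    on_target: float = 0.66,
    read_length: int = 72,
    rng: np.random.Generator | None = None,
) -> list[GenomicInterval]:
    """Read placements with a given on-target fraction (off-target elsewhere)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    targets = list(targets)
    merged = merge_intervals(targets)
    extent = max(t.end for t in merged) + 50_000
    chroms = sorted({t.chrom for t in merged})
    reads = []
    for _ in range(n_reads):
        if rng.random() < on_target:
            ti = int(rng.integers(0, len(targets)))
            t = targets[ti]
            start = int(rng.integers(max(0, t.start - read_length + 1), t.end))
            reads.append(GenomicInterval(t.chrom, start, start + read_length))
        else:
            for _try in range(30):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                start = int(rng.integers(0, extent))
                iv = GenomicInterval(chrom, start, start + read_length)
                if not any(iv.intersects(t) for t in merged if t.chrom == chrom):
                    reads.append(iv)
                    break
            else:
                reads.append(GenomicInterval("chrUn", 0, read_length))
    return reads


# -- proband variant tables ---------------------------------------------------


@dataclass(frozen=True)
class PlantedCausal:
    """Specification of the causal allele(s) to plant in one proband."""

    proband_id: str
    model: str | None = None  # defaults to cfg.causal_model
    gene: str | None = None
    site: tuple[str, int] | None = None  # (chrom, 1-based pos); must lie in the panel
    with_cryptic_indel: bool = False


@dataclass
class TruthRecord:
    causal: list[tuple[str, int, str, str]] = field(default_factory=list)
    causal_proband: str | None = None
    causal_model: str | None = None
    causal_gene: str | None = None
    cryptic_indel: tuple[str, int, str, str] | None = None
    cryptic_member_sites: tuple[tuple[str, int], ...] = ()


@dataclass
class StudyTables:
    probands: list[str]
    tables: dict[str, list[VariantObservation]]
    stubs: AnnotationStubs
    truth: TruthRecord


def _site_depth(
    chrom: str, pos0: int, depth: DepthProfile | None, cfg, rng
) -> int:
    if depth is not None:
        d = depth.depth_at(chrom, pos0)
        if d is not None:
            return max(int(d), 1)
    return max(int(rng.lognormal(math.log(cfg.median_depth), 0.25)), 20)


def _random_target_pos(panel: Panel, cum, rng) -> tuple[str, int]:
    x = rng.random() * cum[-1]
    ti = int(np.searchsorted(cum, x, side="right"))
    t = panel.targets[ti]
    off = int(rng.integers(0, len(t)))
    return t.chrom, t.start + off


def _pick_coding_snv(
    gene: GeneModel, rng, want: set[Effect]
) -> tuple[int, str, str] | None:
    """A (1-based pos, ref, alt) in the CDS whose predicted effect is in ``want``."""
    positions = gene.coding_positions()
    for _ in range(200):
        p = positions[int(rng.integers(0, len(positions)))]
        ref = gene.base(p)
        for alt in "ACGT":
            if alt == ref:
                continue
            obs = VariantObservation(gene.chrom, p + 1, ref, alt, 50, 50)
            if classify_effect(obs, gene) in want:
                return p + 1, ref, alt
    return None


def simulate_proband_variants(
    panel: Panel,
    cfg: SimulationConfig,
    planted: PlantedCausal | None = None,
    depth: DepthProfile | None = None,
) -> StudyTables:
    """Per-proband variant tables plus annotation stubs and a truth record."""
    rng = _rng(cfg, 3)
    probands = [f"P{i + 1:02d}" for i in range(cfg.n_probands)]
    tables: dict[str, list[VariantObservation]] = {p: [] for p in probands}
    stubs = AnnotationStubs()
    truth = TruthRecord()
    lens, cum = _target_sampler(panel.targets)
    total_kb = float(cum[-1]) / 1000.0
    used: set[tuple[str, int]] = set()

    def reads(d: int, p: float) -> tuple[int, int]:
        var = int(rng.binomial(d, p))
        return d - var, var

    def fresh_pos() -> tuple[str, int]:
        for _ in range(50):
            chrom, pos0 = _random_target_pos(panel, cum, rng)
            if (chrom, pos0) not in used:
                used.add((chrom, pos0))
                return chrom, pos0
        raise RuntimeError("panel too small for requested variant density")

    # shared common polymorphisms (>= 4 carriers each)
    n_common = int(rng.poisson(cfg.common_poly_rate * total_kb))
    for _ in range(n_common):
        chrom, pos0 = fresh_pos()
        ref = panel.reference[chrom][pos0]
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        key = (chrom, pos0 + 1, ref, alt)
        f = float(rng.uniform(0.25, 0.85))
        k = min(cfg.n_probands, max(min(4, cfg.n_probands), int(rng.binomial(cfg.n_probands, f))))
        carriers = rng.choice(probands, size=k, replace=False)
        hom_given_carrier = f / (2.0 - f)
        for pid in carriers:
            d = _site_depth(chrom, pos0, depth, cfg, rng)
            p = 0.995 if rng.random() < hom_given_carrier else 0.5
            r, v = reads(d, p)
            if v == 0:
                v, r = 1, d - 1
            tables[pid].append(VariantObservation(chrom, pos0 + 1, ref, alt, r, v, pid))
        if rng.random() < cfg.dbsnp_overlap:
            stubs.dbsnp[key] = bool(rng.random() < 0.02)
            if rng.random() < 0.85:
                stubs.kgenomes.add(key)
        elif rng.random() < 0.4:
            stubs.kgenomes.add(key)
        stubs.phylop[(chrom, pos0 + 1)] = float(rng.uniform(-2.0, 2.5))

    # private rare variants
    for pid in probands:
        for _ in range(int(rng.poisson(cfg.private_snv_mean))):
            chrom, pos0 = fresh_pos()
            ref = panel.reference[chrom][pos0]
            alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
            d = _site_depth(chrom, pos0, depth, cfg, rng)
            p = 0.995 if rng.random() < cfg.private_hom_fraction else 0.5
            r, v = reads(d, p)
            if v == 0:
                v, r = 1, d - 1
            tables[pid].append(VariantObservation(chrom, pos0 + 1, ref, alt, r, v, pid))
            stubs.phylop[(chrom, pos0 + 1)] = float(rng.uniform(-1.5, 3.0))
            stubs.scores[(chrom, pos0 + 1, ref, alt)] = (
                float(rng.uniform(0, 1)),
                float(rng.uniform(0, 1)),
            )
        for _ in range(int(rng.poisson(cfg.private_indel_mean))):
            chrom, pos0 = fresh_pos()
            seq = panel.reference[chrom]
            if rng.random() < 0.6:  # deletion
                length = int(rng.integers(1, 7))
                ref_a = seq[pos0 : pos0 + 1 + length]
                alt_a = seq[pos0]
            else:  # insertion
                length = int(rng.integers(1, 7))
                ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=length))
                ref_a = seq[pos0]
                alt_a = seq[pos0] + ins
            d = _site_depth(chrom, pos0, depth, cfg, rng)
            p = 0.995 if rng.random() < cfg.private_hom_fraction else 0.5
            r, v = reads(d, p)
            if v == 0:
                v, r = 1, d - 1
            tables[pid].append(VariantObservation(chrom, pos0 + 1, ref_a, alt_a, r, v, pid))

    # planted causal allele(s)
    if planted is not None:
        model = planted.model or cfg.causal_model
        if model not in _CAUSAL_MODELS:
            raise ValueError(f"unknown causal model {model}")
        if planted.proband_id not in tables:
            raise ValueError(f"unknown proband {planted.proband_id}")
        if planted.site is not None:
            chrom, pos1 = planted.site
            if not any(t.contains(chrom, pos1 - 1) for t in panel.targets):
                raise ValueError(f"planted site {chrom}:{pos1} outside the panel")
        if planted.gene is not None:
            gene_pool = [g for g in panel.genes if g.name == planted.gene]
            if not gene_pool:
                raise ValueError(f"unknown gene {planted.gene}")
        else:
            gene_pool = panel.genes
        gene = gene_pool[int(rng.integers(0, len(gene_pool)))]
        n_alleles = 2 if model == "recessive_compound_het" else 1
        zyg_p = 0.995 if model == "recessive_hom" else 0.5
        pid = planted.proband_id
        for ai in range(n_alleles):
            if planted.site is not None and ai == 0:
                chrom_s, pos1 = planted.site
                gene = next(
                    (g for g in panel.genes if g.chrom == chrom_s and g.start <= pos1 - 1 < g.end),
                    gene,
                )
                ref = panel.reference[chrom_s][pos1 - 1]
                alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
            else:
                picked = None
                for _ in range(50):
                    picked = _pick_coding_snv(gene, rng, {Effect.MISSENSE, Effect.NONSENSE})
                    if picked is not None and (gene.chrom, picked[0] - 1) not in used:
                        break
                if picked is None:
                    raise RuntimeError("could not place a functional causal variant")
                pos1, ref, alt = picked
            used.add((gene.chrom, pos1 - 1))
            d = _site_depth(gene.chrom, pos1 - 1, depth, cfg, rng)
            r, v = reads(d, zyg_p)
            if v == 0:
                v, r = max(1, d // 2), d - max(1, d // 2)
            tables[pid].append(VariantObservation(gene.chrom, pos1, ref, alt, r, v, pid))
            stubs.phylop[(gene.chrom, pos1)] = float(rng.uniform(1.2, 3.0))
            stubs.scores[(gene.chrom, pos1, ref, alt)] = (
                float(rng.uniform(0.85, 1.0)),
                float(rng.uniform(0.0, 0.05)),
            )
            truth.causal.append((gene.chrom, pos1, ref, alt))
        truth.causal_proband = pid
        truth.causal_model = model
        truth.causal_gene = gene.name

        if planted.with_cryptic_indel:
            other = panel.genes[int(rng.integers(0, len(panel.genes)))]
            positions = other.coding_positions()
            mid = positions[len(positions) // 2]
            anchor = min(mid, other.cds_end - 4)
            seq = panel.reference[other.chrom]
            del_ref = seq[anchor : anchor + 3]
            truth.cryptic_indel = (other.chrom, anchor + 1, del_ref, del_ref[0])
            sites = []
            for pos0 in (anchor, anchor + 2):
                ref = seq[pos0]
                alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
                d = _site_depth(other.chrom, pos0, depth, cfg, rng)
                r, v = reads(d, 0.25)
                if v == 0:
                    v, r = max(1, d // 4), d - max(1, d // 4)
                tables[pid].append(
                    VariantObservation(other.chrom, pos0 + 1, ref, alt, r, v, pid)
                )
                stubs.phylop[(other.chrom, pos0 + 1)] = float(rng.uniform(1.0, 2.5))
                sites.append((other.chrom, pos0 + 1))
            truth.cryptic_member_sites = tuple(sites)

    for pid in probands:
        tables[pid].sort(key=lambda o: (o.chrom, o.pos))
    return StudyTables(probands=probands, tables=tables, stubs=stubs, truth=truth)


# -- cohorts and pedigrees ----------------------------------------------------


@dataclass
class CohortSim:
    cases: "CohortGenotypeCounts"
    controls: "CohortGenotypeCounts"
    pedigrees: list[dict[str, PedigreeMember]]


def _draw_genotype_counts(
    n: int, p: float, q: float, label: str, rng
) -> "CohortGenotypeCounts":
    from .cohort_stats import CohortGenotypeCounts

    chroms = rng.choice(3, size=(n, 2), p=[p, q, 1.0 - p - q])  # 0=A focal, 1=B, 2=wt
    n_hom = int(((chroms == 0).sum(axis=1) == 2).sum())
    n_compound = int(((chroms[:, 0] == 0) & (chroms[:, 1] == 1)).sum()) + int(
        ((chroms[:, 0] == 1) & (chroms[:, 1] == 0)).sum()
    )
    n_het = int((((chroms == 0).sum(axis=1) == 1) & ((chroms == 1).sum(axis=1) == 0)).sum())
    return CohortGenotypeCounts(
        n_individuals=n, n_hom=n_hom, n_compound_het=n_compound, n_het=n_het, label=label
    )


def _mendel_child(gf: Genotype, gm: Genotype, rng) -> Genotype:
    def transmit(g: Genotype) -> int:
        if g is Genotype.HOM:
            return 1
        if g is Genotype.HET:
            return int(rng.random() < 0.5)
        return 0

    dose = transmit(gf) + transmit(gm)
    return (Genotype.REF, Genotype.HET, Genotype.HOM)[dose]


def simulate_family(
    model: str,
    causal_alleles: Sequence[str],
    rng: np.random.Generator,
    benign: dict[str, Genotype] | None = None,
    n_children: int = 6,
    min_affected: int = 3,
    proband_id: str = "C1",
) -> dict[str, PedigreeMember]:
    """A multiplex family segregating the causal allele(s) under ``model``.

    The proband (a child) is forced to the causal genotype; sibling genotypes
    follow Mendelian transmission and affection status follows the model with
    full penetrance.  Families are redrawn until at least ``min_affected``
    members are affected, emulating the ascertainment of large multiplex
    kindreds (the enrolled families ranged from four affected members to nine
    affected plus unaffected relatives).  ``benign`` maps extra allele ids to
    the proband's observed genotype; relatives' genotypes for those alleles
    are drawn by Mendelian transmission conditioned on the proband.
    """
    if model not in _CAUSAL_MODELS:
        raise ValueError(f"unknown causal model {model}")
    a, b = "alleleA", "alleleB"
    compound = model == "recessive_compound_het"
    dominant = model == "dominant_het"
    alleles = list(causal_alleles)
    if compound and len(alleles) != 2:
        raise ValueError("compound model needs two causal allele ids")

    for _attempt in range(200):
        ped: dict[str, PedigreeMember] = {}
        if dominant:
            gf = {alleles[0]: Genotype.HET}
            gm = {alleles[0]: Genotype.REF}
        elif compound:
            gf = {alleles[0]: Genotype.HET, alleles[1]: Genotype.REF}
            gm = {alleles[0]: Genotype.REF, alleles[1]: Genotype.HET}
        else:
            gf = {alleles[0]: Genotype.HET}
            gm = {alleles[0]: Genotype.HET}
        ped["F"] = PedigreeMember("F", sex="1", affected=dominant, genotypes=dict(gf))
        ped["M"] = PedigreeMember("M", sex="2", affected=False, genotypes=dict(gm))
        n_affected = 1 if dominant else 0
        for ci in range(n_children):
            cid = f"C{ci + 1}"
            geno = {
                al: _mendel_child(gf[al], gm[al], rng) for al in gf
            }
            if cid == proband_id:
                if dominant:
                    geno = {alleles[0]: Genotype.HET}
                elif compound:
                    geno = {alleles[0]: Genotype.HET, alleles[1]: Genotype.HET}
                else:
                    geno = {alleles[0]: Genotype.HOM}
            if compound:
                affected = (
                    geno[alleles[0]] is Genotype.HET and geno[alleles[1]] is Genotype.HET
                ) or Genotype.HOM in (geno[alleles[0]], geno[alleles[1]])
            elif dominant:
                affected = geno[alleles[0]] is not Genotype.REF
            else:
                affected = geno[alleles[0]] is Genotype.HOM
            ped[cid] = PedigreeMember(
                cid,
                father_id="F",
                mother_id="M",
                sex=str(1 + ci % 2),
                affected=affected,
                genotypes=geno,
            )
        n_affected += sum(1 for cid in ped if cid.startswith("C") and ped[cid].affected)
        if n_affected >= min_affected:
            break
    else:  # pragma: no cover - probability ~0 with 200 attempts
        raise RuntimeError("could not draw a multiplex family")

    if benign:
        for allele, proband_g in benign.items():
            if proband_g is Genotype.HOM:
                pf = pm = Genotype.HET
            elif proband_g is Genotype.HET:
                if rng.random() < 0.5:
                    pf, pm = Genotype.HET, Genotype.REF
                else:
                    pf, pm = Genotype.REF, Genotype.HET
            else:
                pf = pm = Genotype.REF
            ped["F"].genotypes[allele] = pf
            ped["M"].genotypes[allele] = pm
            for cid in [k for k in ped if k.startswith("C")]:
                if cid == proband_id:
                    ped[cid].genotypes[allele] = proband_g
                else:
                    ped[cid].genotypes[allele] = _mendel_child(pf, pm, rng)
    return ped


def simulate_cohort(cfg: SimulationConfig) -> CohortSim:
    """Case/control genotype counts under Hardy-Weinberg, plus pedigrees."""
    rng = _rng(cfg, 4)
    q = cfg.compound_allele_freq
    cases = _draw_genotype_counts(cfg.n_cases, cfg.case_allele_freq, q, "cases", rng)
    controls = _draw_genotype_counts(
        cfg.n_controls, cfg.control_allele_freq, 0.0, "controls", rng
    )
    alleles = (
        ["alleleA", "alleleB"]
        if cfg.causal_model == "recessive_compound_het"
        else ["alleleA"]
    )
    pedigrees = [
        simulate_family(cfg.causal_model, alleles, rng) for _ in range(cfg.n_families)
    ]
    return CohortSim(cases=cases, controls=controls, pedigrees=pedigrees)


# -- export -------------------------------------------------------------------


def write_study(
    out_dir: str | Path,
    cfg: SimulationConfig,
    panel: Panel,
    study: StudyTables | None = None,
    cohort: CohortSim | None = None,
) -> None:
    """Dump a simulated study as plain-text files (BED/FASTA/TSV/PED/JSON)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed(panel.exons, out / "exons.bed")
    write_bed(panel.repeats, out / "repeats.bed")
    write_bed(panel.targets, out / "targets.bed")
    records = [
        SeqRecord(Seq(seq), id=chrom, description="synthetic reference")
        for chrom, seq in sorted(panel.reference.items())
    ]
    seqio_write(records, str(out / "reference.fa"), "fasta")
    cfg.to_json(out / "config.json")
    if study is not None:
        for pid, obs in study.tables.items():
            write_variant_table(obs, out / f"variants_{pid}.tsv")
        study.stubs.write(out)
    if cohort is not None:
        from .cohort_stats import write_cohort_counts

        write_cohort_counts([cohort.cases, cohort.controls], out / "cohort_counts.tsv")
        for i, ped in enumerate(cohort.pedigrees):
            write_ped(ped, out / f"family_{i + 1}.ped", family_id=f"FAM{i + 1}")
            write_genotypes(ped, out / f"family_{i + 1}_genotypes.tsv")
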