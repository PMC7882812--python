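"""Truth-annotated synthetic fixtures for the whole pipeline.

The generator emits a small genome (FASTA), multi-exon transcript models on
both strands (GTF), scored miRNA target sites (TSV), a miRNA expression
table, eCLIP-style narrowPeak replicates, and monocyte/macrophage
expression tables with planted fold changes — together with a JSON truth
table that locates every planted feature.

Study-condition defaults: 20 genes, 3 genes carrying a validated-QRE /
filter-surviving-site pair closer than 20 nt (one of them with the QRE
spanning an exon junction), and one decoy gene per failure class — distance
>= 20 nt, miRNA below median expression, mirSVR score >= -1, and no eCLIP
peak — so every rejection stage of the pipeline is exercised exactly once.

UTRs of genes that carry planted QREs are sanitised of accidental 'ACUAA'
occurrences, making their truth exact by construction; background genes
keep their natural background and the truth table records those
occurrences too (found with an independent regex scan, not the scanner
under test).
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .intervals import GenomicInterval, SplicedRegion
from .io import (
    Peak,
    TranscriptModel,
    write_genome,
    write_gtf,
    write_peaks,
    write_site_table,
)
from .mirna import MiRnaTargetSite

_CORE = "ACUAA"
_CORE_RE = re.compile("(?=ACUAA)")
_RNA = np.array(list("ACGU"))
_RNA_TO_DNA = str.maketrans("ACGU", "ACGT")
_RNA_COMPLEMENT_TO_DNA = str.maketrans("ACGU", "TGCA")

CONTIG = "chrSim"
GENE_SPACING = 500
CHUNK_MIN = 40  # minimum UTR bases per exon chunk
CDS_LEN = 300

ROLE_PROXIMAL = "proximal"
ROLE_DECOY_DISTANCE = "decoy_distance"
ROLE_DECOY_EXPRESSION = "decoy_expression"
ROLE_DECOY_SCORE = "decoy_score"
ROLE_DECOY_NOPEAK = "decoy_nopeak"
ROLE_BACKGROUND = "background"

DECOY_ROLES = (
    ROLE_DECOY_DISTANCE,
    ROLE_DECOY_EXPRESSION,
    ROLE_DECOY_SCORE,
    ROLE_DECOY_NOPEAK,
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    exons_per_transcript: tuple[int, int] = (2, 4)
    utr_length: tuple[int, int] = (200, 380)
    fraction_minus_strand: float = 0.5
    n_planted_proximal: int = 3
    planted_distance: tuple[int, int] = (4, 19)
    plant_junction_qre: bool = True
    decoy_distance_range: tuple[int, int] = (25, 40)
    n_decoy_qres: int = 3  # extra peak-less QREs in background genes
    n_decoy_sites: int = 3  # extra filter-passing sites in QRE-less genes
    n_background_peaks: int = 4  # intergenic noise peaks per replicate
    peak_coverage: float = 1.0
    peak_flank: tuple[int, int] = (8, 25)
    n_replicates: int = 2
    n_mirnas: int = 30
    site_length: int = 22
    noise_sd: float = 0.1
    fc_effects: dict[str, float | dict[str, float]] | None = None
    mask_background: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates not in (1, 2):
            raise ConfigError("n_replicates must be 1 or 2")
        if not 0 <= self.peak_coverage <= 1:
            raise ConfigError("peak_coverage must be in [0, 1]")
        if self.peak_coverage == 0 and self.n_planted_proximal > 0:
            raise ConfigError(
                "peak_coverage 0 cannot validate any planted proximal QRE"
            )
        if self.planted_distance[1] >= 20 or self.planted_distance[0] < 0:
            raise ConfigError("planted_distance must lie within [0, 20)")
        if self.decoy_distance_range[0] < 20:
            raise ConfigError("decoy distances must be >= 20 nt")
        if self.exons_per_transcript[0] < 2:
            raise ConfigError("transcripts need >= 2 exons (junction planting)")
        n_engineered = self.n_planted_proximal + len(DECOY_ROLES)
        if self.n_genes < n_engineered + 1:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {n_engineered} engineered "
                "genes plus background"
            )
        if self.utr_length[0] < CHUNK_MIN * self.exons_per_transcript[1]:
            raise ConfigError("utr_length too short for the exon chunking")


@dataclass
class TruthTable:
    """Every planted feature, locatable in the emitted files."""

    seed: int
    contig: str
    genes: list[dict] = field(default_factory=list)
    planted_qres: list[dict] = field(default_factory=list)
    background_qres: list[dict] = field(default_factory=list)
    sites: list[dict] = field(default_factory=list)
    proximal_genes: list[str] = field(default_factory=list)
    mirna_expression: dict[str, float] = field(default_factory=dict)
    fc_effects: dict = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class _GenePlan:
    symbol: str
    transcript_id: str
    strand: str
    role: str
    utr_len: int
    chunks: list[int]
    host_chunk: int  # UTR chunk carrying planted features (-1: none)
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_blocks: list[GenomicInterval] = field(default_factory=list)
    utr_region: SplicedRegion | None = None
    utr_rna: str | None = None
    qre_t: int | None = None
    spans_junction: bool = False
    site_t: tuple[int, int] | None = None
    planned_distance: int | None = None


def _draw_chunks(rng: np.random.Generator, utr_len: int, n_chunks: int) -> list[int]:
    """Split utr_len into n_chunks parts, each >= CHUNK_MIN."""
    free = utr_len - CHUNK_MIN * n_chunks
    cuts = np.sort(rng.integers(0, free + 1, size=n_chunks - 1)) if n_chunks > 1 else []
    bounds = [0, *cuts, free]
    return [CHUNK_MIN + int(bounds[i + 1] - bounds[i]) for i in range(n_chunks)]


def _sanitise(rna: list[str], protected: list[tuple[int, int]]) -> None:
    """Destroy every 'ACUAA' occurrence not starting a protected span.

    Mutating any of the five positions to G kills a match and can never
    create a new one ('ACUAA' contains no G); positions inside protected
    spans are left untouched.
    """
    protected_starts = {p[0] for p in protected}

    def covered(pos: int) -> bool:
        return any(lo <= pos < hi for lo, hi in protected)

    while True:
        text = "".join(rna)
        dirty = [
            m.start()
            for m in _CORE_RE.finditer(text)
            if m.start() not in protected_starts
        ]
        if not dirty:
            return
        for start in dirty:
            for pos in range(start, start + len(_CORE)):
                if not covered(pos):
                    rna[pos] = "G"
                    break
            else:  # fully inside protected territory: cannot happen by layout
                raise ConfigError("planted spans overlap an unplanned motif")


def _plan_genes(cfg: SimConfig, rng: np.random.Generator) -> list[_GenePlan]:
    roles = (
        [ROLE_PROXIMAL] * cfg.n_planted_proximal
        + list(DECOY_ROLES)
        + [ROLE_BACKGROUND] * (cfg.n_genes - cfg.n_planted_proximal - len(DECOY_ROLES))
    )
    plans = []
    for idx, role in enumerate(roles):
        n_exons = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
        strand = "-" if rng.random() < cfg.fraction_minus_strand else "+"
        junction_gene = role == ROLE_PROXIMAL and cfg.plant_junction_qre and idx == 0

        if role == ROLE_PROXIMAL:
            d = int(rng.integers(cfg.planted_distance[0], cfg.planted_distance[1] + 1))
        elif role == ROLE_DECOY_DISTANCE:
            d = int(rng.integers(cfg.decoy_distance_range[0], cfg.decoy_distance_range[1] + 1))
        elif role in DECOY_ROLES:
            d = int(rng.integers(cfg.planted_distance[0], cfg.planted_distance[1] + 1))
        else:
            d = None

        utr_len = int(rng.integers(cfg.utr_length[0], cfg.utr_length[1] + 1))
        chunks = _draw_chunks(rng, utr_len, n_exons)
        host = -1
        if d is not None:
            # the hosting chunk must fit QRE (+ flanks) + gap + site
            need = 12 + len(_CORE) + d + cfg.site_length + 12
            host = 1 if junction_gene else int(np.argmax(chunks))
            if chunks[host] < need:
                chunks[host] = need
                utr_len = sum(chunks)
        plans.append(
            _GenePlan(
                symbol=f"GENE{idx + 1:02d}",
                transcript_id=f"T{idx + 1:02d}",
                strand=strand,
                role=role,
                utr_len=utr_len,
                chunks=chunks,
                host_chunk=host,
                spans_junction=junction_gene,
                planned_distance=d,
            )
        )
    return plans


def _layout(plans: list[_GenePlan], cfg: SimConfig, rng: np.random.Generator) -> int:
    """Assign genomic exon coordinates; returns total contig length."""
    cursor = GENE_SPACING
    for plan in plans:
        # transcript-order exon lengths: exon 0 = CDS + UTR chunk 0
        exon_lens = [CDS_LEN + plan.chunks[0], *plan.chunks[1:]]
        introns = [int(rng.integers(60, 201)) for _ in exon_lens[:-1]]
        genomic_lens = exon_lens if plan.strand == "+" else exon_lens[::-1]
        genomic_introns = introns if plan.strand == "+" else introns[::-1]
        blocks = []
        pos = cursor
        for i, length in enumerate(genomic_lens):
            blocks.append(GenomicInterval(CONTIG, pos, pos + length, plan.strand))
            pos += length
            if i < len(genomic_introns):
                pos += genomic_introns[i]
        plan.exons = blocks
        exon_region = SplicedRegion(
            transcript_id=plan.transcript_id,
            gene_id=plan.symbol,
            gene_symbol=plan.symbol,
            strand=plan.strand,
            blocks=tuple(blocks),
        )
        plan.cds_blocks = exon_region.map_interval_to_genome(0, CDS_LEN)
        utr_blocks = exon_region.map_interval_to_genome(CDS_LEN, CDS_LEN + plan.utr_len)
        plan.utr_region = SplicedRegion(
            transcript_id=plan.transcript_id,
            gene_id=plan.symbol,
            gene_symbol=plan.symbol,
            strand=plan.strand,
            blocks=tuple(utr_blocks),
        )
        cursor = pos + GENE_SPACING
    return cursor


def _engineer_utr(plan: _GenePlan, cfg: SimConfig, rng: np.random.Generator) -> None:
    """Choose QRE/site transcript positions and build the UTR RNA string."""
    rna = list(rng.choice(_RNA, size=plan.utr_len))
    protected: list[tuple[int, int]] = []

    if plan.planned_distance is not None or plan.qre_t == -1:
        chunk_starts = np.concatenate([[0], np.cumsum(plan.chunks)]).astype(int)
        if plan.spans_junction:
            # core straddles the junction between chunk 0 and chunk 1 (2|3 split)
            q = int(chunk_starts[1]) - 2
        else:
            host_start = int(chunk_starts[plan.host_chunk])
            q = host_start + 8 + int(rng.integers(0, 4))
        plan.qre_t = q
        protected.append((q, q + len(_CORE)))
        if plan.planned_distance is not None:
            s_start = q + len(_CORE) + plan.planned_distance
            plan.site_t = (s_start, s_start + cfg.site_length)
            if s_start + cfg.site_length > plan.utr_len:
                raise ConfigError(f"UTR too short for planted site in {plan.symbol}")

    sanitise_needed = plan.qre_t is not None or cfg.mask_background
    if sanitise_needed:
        _sanitise(rna, protected)
    if plan.qre_t is not None:
        rna[plan.qre_t : plan.qre_t + len(_CORE)] = list(_CORE)
        _sanitise(rna, protected)  # planting may have re-created flanking hits
    plan.utr_rna = "".join(rna)


def _write_utr_into_genome(plan: _GenePlan, genome: list[str]) -> None:
    """Overwrite genomic UTR blocks with the engineered spliced RNA."""
    region = plan.utr_region
    offset = 0
    blocks = region.blocks if plan.strand == "+" else tuple(reversed(region.blocks))
    for b in blocks:
        chunk = plan.utr_rna[offset : offset + b.length]
        offset += b.length
        if plan.strand == "+":
            dna = chunk.translate(_RNA_TO_DNA)
        else:
            dna = chunk.translate(_RNA_COMPLEMENT_TO_DNA)[::-1]
        genome[b.start : b.end] = list(dna)


def generate_genome_and_annotation(
    cfg: SimConfig,
) -> tuple[dict[str, str], list[TranscriptModel], list[_GenePlan], TruthTable]:
    """Genome, annotation and truth-table skeleton for one seeded fixture."""
    rng = np.random.default_rng(cfg.seed)
    plans = _plan_genes(cfg, rng)

    # assign extra peak-less QREs and extra far sites to distinct background genes
    background = [p for p in plans if p.role == ROLE_BACKGROUND]
    if cfg.n_decoy_qres + cfg.n_decoy_sites > len(background):
        raise ConfigError("not enough background genes for extra decoy features")
    for p in background[: cfg.n_decoy_qres]:
        p.qre_t = -1  # placeholder: position chosen during engineering
        p.host_chunk = 0

    total = _layout(plans, cfg, rng)
    genome_list = list(rng.choice(np.array(list("ACGT")), size=total))
    for plan in plans:
        _engineer_utr(plan, cfg, rng)
        if plan.qre_t is not None or cfg.mask_background:
            _write_utr_into_genome(plan, genome_list)
        else:
            # natural background: read the spliced UTR back for the truth scan
            plan.utr_rna = _spliced_rna(plan, genome_list)
    genome = {CONTIG: "".join(genome_list)}

    models = []
    truth = TruthTable(seed=cfg.seed, contig=CONTIG)
    for plan in plans:
        models.append(
            TranscriptModel(
                transcript_id=plan.transcript_id,
                gene_id=plan.symbol,
                gene_symbol=plan.symbol,
                contig=CONTIG,
                strand=plan.strand,
                exons=list(plan.exons),
                cds=list(plan.cds_blocks),
            )
        )
        truth.genes.append(
            {
                "gene": plan.symbol,
                "transcript_id": plan.transcript_id,
                "strand": plan.strand,
                "role": plan.role,
                "utr_blocks": [[b.start, b.end] for b in plan.utr_region.blocks],
                "utr_length": plan.utr_len,
            }
        )
        if plan.qre_t is not None:
            expect_validated = plan.role in (
                ROLE_PROXIMAL,
                ROLE_DECOY_DISTANCE,
                ROLE_DECOY_EXPRESSION,
                ROLE_DECOY_SCORE,
            )
            qre_blocks = plan.utr_region.map_interval_to_genome(
                plan.qre_t, plan.qre_t + len(_CORE)
            )
            truth.planted_qres.append(
                {
                    "gene": plan.symbol,
                    "transcript_id": plan.transcript_id,
                    "t_start": plan.qre_t,
                    "spans_junction": len(qre_blocks) > 1,
                    "expect_validated": expect_validated,
                    "genomic_blocks": [[b.start, b.end] for b in qre_blocks],
                }
            )
        # independent regex scan of the constructed spliced UTR records every
        # occurrence, planted or natural
        for m in _CORE_RE.finditer(plan.utr_rna):
            if m.start() != plan.qre_t:
                truth.background_qres.append(
                    {"gene": plan.symbol, "t_start": m.start()}
                )
    truth.proximal_genes = [p.symbol for p in plans if p.role == ROLE_PROXIMAL]
    return genome, models, plans, truth


def _spliced_rna(plan: _GenePlan, genome_list: list[str]) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    parts = ["".join(genome_list[b.start : b.end]) for b in plan.utr_region.blocks]
    dna = "".join(parts)
    if plan.strand == "-":
        dna = "".join(comp[x] for x in reversed(dna))
    return dna.replace("T", "U")


def plant_regulatory_features(
    cfg: SimConfig, plans: list[_GenePlan], truth: TruthTable
) -> tuple[list[MiRnaTargetSite], dict[str, list[Peak]], pd.DataFrame]:
    """miRNA sites + expression and eCLIP peaks consistent with the plans."""
    rng = np.random.default_rng(cfg.seed + 1)

    # distinct miRNA expression values; top half strictly above the median
    n = cfg.n_mirnas if cfg.n_mirnas % 2 == 0 else cfg.n_mirnas + 1
    values = np.sort(rng.lognormal(mean=3.0, sigma=1.0, size=n))[::-1]
    values = values + np.arange(n)[::-1] * 1e-6  # enforce distinctness
    mirna_ids = [f"sim-miR-{i + 1:03d}" for i in range(n)]
    expression = {mid: float(v) for mid, v in zip(mirna_ids, values)}
    high_pool = mirna_ids[: n // 2]
    low_pool = mirna_ids[n // 2 :]
    truth.mirna_expression = expression

    sites: list[MiRnaTargetSite] = []
    peaks: dict[str, list[Peak]] = {
        f"rep{i + 1}": [] for i in range(cfg.n_replicates)
    }
    peak_counter = 0

    def add_site(plan: _GenePlan, mirna: str, score: float, klass: str) -> None:
        t0, t1 = plan.site_t
        blocks = plan.utr_region.map_interval_to_genome(t0, t1)
        assert len(blocks) == 1, "planted sites stay within one exon"
        site = MiRnaTargetSite(
            mirna_id=mirna,
            gene_symbol=plan.symbol,
            interval=blocks[0],
            mirsvr_score=round(score, 3),
            transcript_id=plan.transcript_id,
        )
        sites.append(site)
        truth.sites.append(
            {
                "mirna_id": mirna,
                "gene": plan.symbol,
                "mirsvr_score": site.mirsvr_score,
                "class": klass,
                "start": blocks[0].start,
                "end": blocks[0].end,
                "expect_expression_pass": mirna in high_pool,
                "expect_score_pass": site.mirsvr_score < -1.0,
                "planned_distance": plan.planned_distance,
            }
        )

    def add_peaks(plan: _GenePlan) -> None:
        nonlocal peak_counter
        qre_blocks = plan.utr_region.map_interval_to_genome(
            plan.qre_t, plan.qre_t + len(_CORE)
        )
        for rep in peaks:
            if rng.random() >= cfg.peak_coverage:
                continue
            block = qre_blocks[int(rng.integers(0, len(qre_blocks)))]
            fl1 = int(rng.integers(cfg.peak_flank[0], cfg.peak_flank[1] + 1))
            fl2 = int(rng.integers(cfg.peak_flank[0], cfg.peak_flank[1] + 1))
            peak_counter += 1
            interval = GenomicInterval(
                CONTIG, max(0, block.start - fl1), block.end + fl2
            )
            peaks[rep].append(
                Peak(
                    interval=interval,
                    name=f"peak{peak_counter:03d}_{plan.symbol}",
                    signal_value=round(float(rng.uniform(2, 10)), 3),
                    p_value_log=round(float(rng.uniform(5, 20)), 3),
                    q_value_log=round(float(rng.uniform(3, 15)), 3),
                    summit_offset=interval.length // 2,
                    replicate_id=rep,
                )
            )

    high_iter = iter(high_pool)
    low_iter = iter(low_pool)
    strong = lambda: float(rng.uniform(-2.5, -1.3))
    weak = lambda: float(rng.uniform(-0.9, -0.3))

    for plan in plans:
        if plan.role == ROLE_PROXIMAL:
            add_site(plan, next(high_iter), strong(), ROLE_PROXIMAL)
            add_peaks(plan)
        elif plan.role == ROLE_DECOY_DISTANCE:
            add_site(plan, next(high_iter), strong(), plan.role)
            add_peaks(plan)
        elif plan.role == ROLE_DECOY_EXPRESSION:
            add_site(plan, next(low_iter), strong(), plan.role)
            add_peaks(plan)
        elif plan.role == ROLE_DECOY_SCORE:
            add_site(plan, next(high_iter), weak(), plan.role)
            add_peaks(plan)
        elif plan.role == ROLE_DECOY_NOPEAK:
            add_site(plan, next(high_iter), strong(), plan.role)
            # no peaks: the QRE must fail eCLIP validation

    # extra filter-passing sites in QRE-less background genes
    background = [p for p in plans if p.role == ROLE_BACKGROUND and p.qre_t is None]
    for plan in background[: cfg.n_decoy_sites]:
        t0 = 10 + int(rng.integers(0, 5))
        plan.site_t = (t0, t0 + cfg.site_length)
        plan.planned_distance = None
        add_site(plan, next(high_iter), strong(), "far_site")

    # intergenic noise peaks (never overlap any gene span)
    spans = sorted((p.exons[0].start, p.exons[-1].end) for p in plans)
    gap_regions = []
    prev_end = 0
    for start, end in spans:
        if start - prev_end >= 200:
            gap_regions.append((prev_end + 20, start - 20))
        prev_end = end
    for rep in peaks:
        for _ in range(cfg.n_background_peaks):
            lo, hi = gap_regions[int(rng.integers(0, len(gap_regions)))]
            width = int(rng.integers(60, 151))
            start = int(rng.integers(lo, max(lo + 1, hi - width)))
            peak_counter += 1
            peaks[rep].append(
                Peak(
                    interval=GenomicInterval(CONTIG, start, start + width),
                    name=f"peak{peak_counter:03d}_noise",
                    signal_value=round(float(rng.uniform(1, 4)), 3),
                    p_value_log=round(float(rng.uniform(2, 8)), 3),
                    q_value_log=round(float(rng.uniform(1, 5)), 3),
                    summit_offset=width // 2,
                    replicate_id=rep,
                )
            )

    expr_frame = pd.DataFrame(
        {"mirna_id": mirna_ids, "monocyte": [expression[m] for m in mirna_ids]}
    ).set_index("mirna_id")
    return sites, peaks, expr_frame


def default_fc_effects(truth: TruthTable) -> dict[str, float]:
    """Planted log2 fold changes: proximal genes up, two decoys down, rest 0."""
    effects: dict[str, float] = {}
    downs = 0
    for g in truth.genes:
        if g["role"] == ROLE_PROXIMAL:
            effects[g["gene"]] = 1.2
        elif g["role"] in DECOY_ROLES and downs < 2:
            effects[g["gene"]] = -1.0
            downs += 1
        else:
            effects[g["gene"]] = 0.0
    return effects


def generate_expression_tables(
    cfg: SimConfig, truth: TruthTable
) -> dict[str, pd.DataFrame]:
    """Monocyte/macrophage tables for three pseudo-datasets + patient pair.

    One dataset is RNA-seq-like (n=1, integer counts) and two are
    microarray-like (n=3, continuous intensities), mirroring a heterogeneous
    trio of differentiation experiments.  Values are
    baseline * 2^(planted lfc) with multiplicative log-normal noise.
    The patient tables carry a planted deficit (half expression) on the
    proximal genes and on a QKI row.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    genes = [g["gene"] for g in truth.genes]
    effects = cfg.fc_effects if cfg.fc_effects is not None else default_fc_effects(truth)
    truth.fc_effects = effects

    baselines = {g: float(rng.uniform(50, 500)) for g in genes}
    datasets = {
        "sim_rnaseq": {"n": 1, "integer": True},
        "sim_array1": {"n": 3, "integer": False},
        "sim_array2": {"n": 3, "integer": False},
    }

    def lfc_for(gene: str, dataset: str) -> float:
        eff = effects.get(gene, 0.0)
        if isinstance(eff, dict):
            return float(eff.get(dataset, 0.0))
        return float(eff)

    def noisy(value: float) -> float:
        if cfg.noise_sd == 0:
            return value
        return value * float(np.exp(rng.normal(0.0, cfg.noise_sd)))

    tables: dict[str, pd.DataFrame] = {}
    for ds, meta in datasets.items():
        cols = [f"s{i + 1}" for i in range(meta["n"])]
        mono = {c: [] for c in cols}
        macro = {c: [] for c in cols}
        for g in genes:
            scale = 2.0 ** lfc_for(g, ds)
            for c in cols:
                m_val = noisy(baselines[g])
                M_val = noisy(baselines[g] * scale)
                if meta["integer"]:
                    m_val, M_val = round(m_val), round(M_val)
                mono[c].append(m_val)
                macro[c].append(M_val)
        tables[f"{ds}_monocyte"] = pd.DataFrame(mono, index=pd.Index(genes, name="gene"))
        tables[f"{ds}_macrophage"] = pd.DataFrame(macro, index=pd.Index(genes, name="gene"))

    # patient vs sibling: deficit on proximal genes and on QKI itself
    deficit_genes = set(truth.proximal_genes)
    rows_p, rows_s = [], []
    index = [*genes, "QKI"]
    for g in index:
        base_mono = baselines.get(g, 400.0)
        base_macro = base_mono * (2.0 if g == "QKI" else 1.0)
        factor = 0.5 if (g in deficit_genes or g == "QKI") else 1.0
        rows_s.append((noisy(base_mono), noisy(base_macro)))
        rows_p.append((noisy(base_mono * factor), noisy(base_macro * factor)))
    tables["sibling"] = pd.DataFrame(
        rows_s, index=pd.Index(index, name="gene"), columns=["monocyte", "macrophage"]
    )
    tables["patient"] = pd.DataFrame(
        rows_p, index=pd.Index(index, name="gene"), columns=["monocyte", "macrophage"]
    )
    return tables


def simulate_fixture(cfg: SimConfig, outdir: str | Path) -> TruthTable:
    """Generate and write the complete fixture; returns the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, models, plans, truth = generate_genome_and_annotation(cfg)
    sites, peaks, mirna_expr = plant_regulatory_features(cfg, plans, truth)
    tables = generate_expression_tables(cfg, truth)

    write_genome(genome, outdir / "genome.fa")
    write_gtf(models, outdir / "annotation.gtf")
    write_site_table(sites, outdir / "mirna_sites.tsv")
    mirna_expr.to_csv(outdir / "mirna_expression.tsv", sep="\t")
    truth.files = {
        "genome": "genome.fa",
        "annotation": "annotation.gtf",
        "sites": "mirna_sites.tsv",
        "mirna_expression": "mirna_expression.tsv",
    }
    for rep, rep_peaks in peaks.items():
        name = f"eclip_{rep}.narrowPeak"
        write_peaks(rep_peaks, outdir / name)
        truth.files[f"peaks_{rep}"] = name
    for name, frame in tables.items():
        fname = f"{name}.tsv"
        frame.to_csv(outdir / fname, sep="\t")
        truth.files[name] = fname
    truth.to_json(outdir / "truth.json")
    truth.files["truth"] = "truth.json"
    return truth
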