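"""Expression-side analyses for the neuronal-guidance-cue (NGC) panel.

Covers detectability (non-zero counts in at least one sample), log2 fold
changes with an optional pseudocount, thresholded direction calls
(|log2FC| >= 0.4 by default), the at-least-2-of-3 cross-dataset consensus
caller, the patient-vs-sibling comparison, the QKI–SEMA7A Pearson
correlation, and the join of per-gene QRE counts with fold changes.

A packaged call matrix (``data/ngc_call_matrix.tsv``) carries the worked
example of 17 regulated panel genes with their per-dataset direction calls
across one RNA-seq and two microarray monocyte-to-macrophage comparisons;
running the consensus caller over it yields 9 Up and 8 Down genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError
from .io import ExpressionTable

logger = logging.getLogger(__name__)

UP, DOWN, NONE = "Up", "Down", "None"


@dataclass(frozen=True)
class RegulationConfig:
    lfc_threshold: float = 0.4  # |log2 FC| at or above -> called
    min_support: int = 2  # datasets agreeing for a consensus
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0:
            raise ConfigError("lfc_threshold must be >= 0")
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")


@dataclass(frozen=True)
class DatasetCall:
    gene: str
    dataset_id: str
    log2fc: float | None
    call: str  # UP / DOWN / NONE
    significant: bool | None = None  # provenance metadata, unused by consensus


@dataclass(frozen=True)
class ConsensusCall:
    gene: str
    calls: tuple[DatasetCall, ...]
    consensus: str
    conflict: bool


def detectable_genes(expr: ExpressionTable, panel: Sequence[str]) -> set[str]:
    """Panel genes with a strictly positive value in at least one sample."""
    if not panel:
        raise InputError("gene panel is empty")
    detected = set()
    missing = []
    for gene in panel:
        if gene not in expr:
            missing.append(gene)
            continue
        if (expr.values_for(gene) > 0).any():
            detected.add(gene)
    if missing:
        logger.info("%d panel gene(s) absent from table: %s", len(missing), missing)
    return detected


def log2_fold_change(
    numerator: float, denominator: float, pseudocount: float = 1.0
) -> float:
    if numerator < 0 or denominator < 0:
        raise InputError("expression values must be >= 0")
    num = numerator + pseudocount
    den = denominator + pseudocount
    if num == 0 or den == 0:
        raise InputError(
            "zero expression with zero pseudocount: fold change undefined"
        )
    return math.log2(num / den)


def call_direction(log2fc: float, cfg: RegulationConfig | None = None) -> str:
    cfg = cfg or RegulationConfig()
    if not math.isfinite(log2fc):
        raise InputError(f"non-finite log2 fold change {log2fc}")
    if log2fc >= cfg.lfc_threshold:
        return UP
    if log2fc <= -cfg.lfc_threshold:
        return DOWN
    return NONE


def consensus_call(
    calls: Sequence[DatasetCall], cfg: RegulationConfig | None = None
) -> ConsensusCall:
    """Consensus over one gene's per-dataset calls.

    The consensus is the direction reaching ``min_support`` agreeing calls;
    the conflict flag is set whenever both directions appear at all.  If
    both directions independently reach support (possible with
    min_support=1) no consensus is declared.
    """
    cfg = cfg or RegulationConfig()
    if not calls:
        raise InputError("consensus needs at least one dataset call")
    genes = {c.gene for c in calls}
    if len(genes) != 1:
        raise InputError(f"calls mix genes: {sorted(genes)}")
    dataset_ids = [c.dataset_id for c in calls]
    if len(set(dataset_ids)) != len(dataset_ids):
        raise InputError(f"duplicate dataset_id among calls for {calls[0].gene}")
    n_up = sum(1 for c in calls if c.call == UP)
    n_down = sum(1 for c in calls if c.call == DOWN)
    conflict = n_up > 0 and n_down > 0
    if n_up >= cfg.min_support and n_down >= cfg.min_support:
        consensus = NONE
    elif n_up >= cfg.min_support:
        consensus = UP
    elif n_down >= cfg.min_support:
        consensus = DOWN
    else:
        consensus = NONE
    return ConsensusCall(
        gene=calls[0].gene, calls=tuple(calls), consensus=consensus, conflict=conflict
    )


def consensus_matrix(
    calls: Iterable[DatasetCall], cfg: RegulationConfig | None = None
) -> list[ConsensusCall]:
    """Group calls per gene and run the consensus caller over each."""
    per_gene: dict[str, list[DatasetCall]] = {}
    for c in calls:
        per_gene.setdefault(c.gene, []).append(c)
    return [consensus_call(per_gene[g], cfg) for g in sorted(per_gene)]


def load_call_matrix(path: str | Path | None = None) -> list[DatasetCall]:
    """Read a call matrix TSV (gene, dataset_id, call, [significant]).

    '-' in the call column means no call for that dataset.  With no path,
    the packaged NGC worked-example matrix is loaded.
    """
    if path is None:
        ref = resources.files("qremap").joinpath("data/ngc_call_matrix.tsv")
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene", "dataset_id", "call"}
    if not required <= set(frame.columns):
        raise InputError(f"call matrix needs columns {sorted(required)}")
    calls = []
    for row in frame.itertuples(index=False):
        raw = row.call.strip()
        call = NONE if raw in ("-", "", NONE) else raw
        if call not in (UP, DOWN, NONE):
            raise InputError(f"unknown call {row.call!r} for gene {row.gene}")
        significant = None
        if hasattr(row, "significant") and isinstance(row.significant, str):
            significant = row.significant.strip().lower() in ("true", "1", "yes")
        calls.append(
            DatasetCall(
                gene=row.gene,
                dataset_id=row.dataset_id,
                log2fc=None,
                call=call,
                significant=significant,
            )
        )
    return calls


def dataset_calls_from_tables(
    monocyte: ExpressionTable,
    macrophage: ExpressionTable,
    panel: Sequence[str],
    dataset_id: str,
    cfg: RegulationConfig | None = None,
) -> list[DatasetCall]:
    """Per-gene macrophage-vs-monocyte fold change and direction call.

    Expression per state is the mean across that table's samples; genes
    missing from either table are skipped with a log entry.
    """
    cfg = cfg or RegulationConfig()
    calls = []
    for gene in panel:
        if gene not in monocyte or gene not in macrophage:
            logger.info("%s: gene %s missing from a table; skipped", dataset_id, gene)
            continue
        lfc = log2_fold_change(
            float(macrophage.values_for(gene).mean()),
            float(monocyte.values_for(gene).mean()),
            cfg.pseudocount,
        )
        calls.append(
            DatasetCall(
                gene=gene, dataset_id=dataset_id, log2fc=lfc,
                call=call_direction(lfc, cfg),
            )
        )
    return calls


def patient_comparison(
    patient_expr: ExpressionTable,
    sibling_expr: ExpressionTable,
    panel: Sequence[str],
    cfg: RegulationConfig | None = None,
) -> list[DatasetCall]:
    """Patient-vs-sibling fold change per gene and shared cell state.

    Both tables are keyed by gene with one column per cell state
    (e.g. monocyte, macrophage); each shared column becomes one
    dataset_id in the output.
    """
    cfg = cfg or RegulationConfig()
    shared_states = [c for c in patient_expr.samples if c in sibling_expr.samples]
    if not shared_states:
        raise InputError("patient and sibling tables share no sample columns")
    calls = []
    for gene in panel:
        if gene not in patient_expr or gene not in sibling_expr:
            logger.info("patient comparison: gene %s missing; skipped", gene)
            continue
        for state in shared_states:
            lfc = log2_fold_change(
                float(patient_expr.values_for(gene)[state]),
                float(sibling_expr.values_for(gene)[state]),
                cfg.pseudocount,
            )
            calls.append(
                DatasetCall(
                    gene=gene, dataset_id=state, log2fc=lfc,
                    call=call_direction(lfc, cfg),
                )
            )
    return calls


def qki_correlation(paired_values: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Pearson r and two-sided p for paired expression measurements."""
    if len(paired_values) < 3:
        raise InputError("correlation needs n >= 3 pairs")
    xs = [p[0] for p in paired_values]
    ys = [p[1] for p in paired_values]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise InputError("constant vector: correlation undefined")
    result = stats.pearsonr(xs, ys)
    return float(result.statistic), float(result.pvalue)


def join_counts_fc(
    qre_counts: Mapping[str, int], calls: Sequence[DatasetCall]
) -> pd.DataFrame:
    """Inner join of per-gene QRE counts with per-dataset fold changes."""
    rows = [
        {
            "gene": c.gene,
            "dataset_id": c.dataset_id,
            "qre_count": qre_counts[c.gene],
            "log2fc": c.log2fc,
        }
        for c in calls
        if c.gene in qre_counts and c.log2fc is not None
    ]
    frame = pd.DataFrame(rows, columns=["gene", "dataset_id", "qre_count", "log2fc"])
    return frame.sort_values(["gene", "dataset_id"], kind="mergesort").reset_index(drop=True)


def consensus_to_frame(consensus: list[ConsensusCall]) -> pd.DataFrame:
    dataset_ids = sorted({c.dataset_id for cc in consensus for c in cc.calls})
    rows = []
    for cc in consensus:
        row = {"gene": cc.gene, "consensus": cc.consensus, "conflict": cc.conflict}
        by_ds = {c.dataset_id: c.call for c in cc.calls}
        for ds in dataset_ids:
            row[ds] = by_ds.get(ds, NONE)
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", *dataset_ids, "consensus", "conflict"])
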