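"""Intersect DE-miRNA target genes with QTL intervals and rank candidates.

This is the funnel that turns two genome-wide screens into a short candidate
list: a miRNA survives only if (i) it is differentially expressed under heat
in at least one contrast, (ii) it has a predicted target gene whose locus
overlaps a detected heat-tolerance QTL interval, and (iii) its expression is
anti-correlated with that target's across the matched condition cells —
the signature of miRNA-directed transcript cleavage.

Overlap rule: any overlap (>= 1 bp) between the gene interval and the QTL
interval counts as "in the QTL region" (half-open arithmetic); a strict
containment mode is available.  Genes whose mean abundance falls below an
expression floor (default mean TPM < 1 over all cells) are dropped as "not
expressed".  Remaining pairs are ranked by (Pearson r ascending, target
score ascending): the most anti-correlated, best-complementarity pairs
first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import stats as _stats

from .io_formats import GeneModel, MirqtlError
from .sssl_qtl import QTLResult
from .target_scoring import TargetAlignment

logger = logging.getLogger(__name__)

DEFAULT_EXPRESSION_FLOOR = 1.0  # mean TPM below which a gene is "not expressed"


class IntegrationError(MirqtlError):
    pass


@dataclass(frozen=True)
class ExpressionProfile:
    """Expression of one entity over ordered (genotype, timepoint) cells,
    as log2 relative-to-control values (control == 0)."""

    entity_id: str
    cells: tuple
    values: tuple

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.values):
            raise IntegrationError(f"{self.entity_id!r}: cells and values differ in length")


@dataclass
class CandidatePair:
    mirna_id: str
    gene_id: str
    qtl_id: str
    target_score: float
    de_evidence: tuple = ()  # ((genotype, timepoint, direction), ...)
    anticorrelation: float = float("nan")
    rank: int = 0
    gene: GeneModel | None = None
    dropped_reason: str = ""


def intersect_targets_with_qtls(
    hits: list[tuple[TargetAlignment, GeneModel]],
    qtls: list[QTLResult],
    containment: bool = False,
) -> list[CandidatePair]:
    """Emit one candidate per (miRNA, gene, QTL) whose gene interval overlaps
    the QTL interval; deduplicated, keeping each pair's best target score.

    Raises when the gene and QTL annotations plainly use different
    chromosome naming conventions (e.g. ``chr8`` vs ``8``).
    """
    qtl_chroms = {str(q.chromosome) for q in qtls}
    gene_chroms = {str(g.chromosome) for _, g in hits}
    if hits and qtls and not (gene_chroms & qtl_chroms):
        stripped = {c.removeprefix("chr") for c in gene_chroms} & {
            c.removeprefix("chr") for c in qtl_chroms
        }
        if stripped:
            raise IntegrationError(
                "chromosome label mismatch between gene models and QTLs: "
                f"genes use {sorted(gene_chroms)}, QTLs use {sorted(qtl_chroms)}"
            )

    trees: dict[str, IntervalTree] = {}
    for q in qtls:
        trees.setdefault(str(q.chromosome), IntervalTree()).addi(q.start_mb, q.end_mb, q)

    best: dict[tuple[str, str, str], CandidatePair] = {}
    for hit, gene in hits:
        tree = trees.get(str(gene.chromosome))
        if tree is None:
            continue
        for iv in tree.overlap(gene.start_mb, gene.end_mb):
            q: QTLResult = iv.data
            if containment and not (q.start_mb <= gene.start_mb and gene.end_mb <= q.end_mb):
                continue
            key = (hit.mirna_id, gene.gene_id, q.qtl_id)
            if key not in best or hit.score < best[key].target_score:
                best[key] = CandidatePair(
                    mirna_id=hit.mirna_id,
                    gene_id=gene.gene_id,
                    qtl_id=q.qtl_id,
                    target_score=hit.score,
                    gene=gene,
                )
    return sorted(best.values(), key=lambda c: (c.qtl_id, c.mirna_id, c.gene_id))


def anticorrelation(mirna_profile: ExpressionProfile, gene_profile: ExpressionProfile) -> float:
    """Pearson r between a miRNA's and a gene's profiles over shared cells."""
    shared = [c for c in mirna_profile.cells if c in gene_profile.cells]
    if len(shared) < 3:
        raise IntegrationError(
            f"profiles of {mirna_profile.entity_id!r} and {gene_profile.entity_id!r} "
            f"share only {len(shared)} cells; >= 3 required"
        )
    x = np.array([mirna_profile.values[mirna_profile.cells.index(c)] for c in shared])
    y = np.array([gene_profile.values[gene_profile.cells.index(c)] for c in shared])
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")  # undefined-correlation flag
    return float(_stats.pearsonr(x, y)[0])


def attach_evidence(
    pairs: list[CandidatePair],
    de_calls,
    mirna_profiles: dict[str, ExpressionProfile],
    gene_profiles: dict[str, ExpressionProfile],
) -> list[CandidatePair]:
    """Populate DE evidence and the miRNA-gene anti-correlation per pair."""
    de_by_mirna: dict[str, list] = {}
    for call in de_calls:
        if call.is_de:
            de_by_mirna.setdefault(call.mirna_id, []).append(
                (call.genotype, call.timepoint_hours, call.direction)
            )
    out = []
    for pair in pairs:
        evidence = tuple(sorted(de_by_mirna.get(pair.mirna_id, ())))
        r = float("nan")
        if pair.mirna_id in mirna_profiles and pair.gene_id in gene_profiles:
            r = anticorrelation(mirna_profiles[pair.mirna_id], gene_profiles[pair.gene_id])
        out.append(replace_fields(pair, de_evidence=evidence, anticorrelation=r))
    return out


def replace_fields(pair: CandidatePair, **kwargs) -> CandidatePair:
    data = pair.__dict__ | kwargs
    return CandidatePair(**data)


def rank_candidates(
    pairs: list[CandidatePair],
    gene_abundance: dict[str, float] | None = None,
    expression_floor: float = DEFAULT_EXPRESSION_FLOOR,
    r_max: float = 0.0,
) -> list[CandidatePair]:
    """Filter and rank candidate pairs.

    Drops pairs whose miRNA has no DE evidence, whose gene is not expressed
    (mean abundance below ``expression_floor``, when abundances are given),
    or whose correlation exceeds ``r_max`` (default 0: only anti-correlated
    pairs survive; NaN correlations are dropped as undetermined).  Survivors
    are ranked by (r ascending, target score ascending), with ids as the
    final tie-break so the output is invariant to input order.
    """
    kept = []
    for pair in pairs:
        if not pair.de_evidence:
            logger.info("dropping %s->%s: miRNA not DE", pair.mirna_id, pair.gene_id)
            continue
        if gene_abundance is not None and gene_abundance.get(pair.gene_id, 0.0) < expression_floor:
            logger.info("dropping %s->%s: gene not expressed", pair.mirna_id, pair.gene_id)
            continue
        if not np.isfinite(pair.anticorrelation) or pair.anticorrelation > r_max:
            logger.info(
                "dropping %s->%s: correlation %.3f above %.3f",
                pair.mirna_id, pair.gene_id, pair.anticorrelation, r_max,
            )
            continue
        kept.append(pair)
    kept.sort(key=lambda p: (p.anticorrelation, p.target_score, p.mirna_id, p.gene_id))
    return [replace_fields(p, rank=i + 1) for i, p in enumerate(kept)]


def candidate_table(pairs: list[CandidatePair]):
    """Ranked candidates as a DataFrame mirroring a published QTL/miRNA/
    target summary plus score, correlation and rank columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "qtl_id": p.qtl_id,
                "mirna_id": p.mirna_id,
                "gene_id": p.gene_id,
                "description": p.gene.description if p.gene else "",
                "target_score": p.target_score,
                "anticorrelation": p.anticorrelation,
                "de_evidence": ";".join(f"{g}:{t}h:{d}" for g, t, d in p.de_evidence),
                "rank": p.rank,
            }
            for p in pairs
        ]
    )
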