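"""QTL detection from a panel of chromosome single-segment substitution lines.

Each SSSL carries exactly one donor segment in an otherwise recurrent-parent
background, so a phenotypic difference between a line and the recurrent
parent maps a QTL to that line's segment — no linkage map or interval
mapping is needed.

Segment geometry from graphical genotypes: an interval flanked by two donor
markers (DD) counts as 100% donor, a donor/recipient-flanked interval (DR)
as 50%, so

    segment length = span(DD core) + 0.5 x span(left DR) + 0.5 x span(right DR).

When a donor run touches a chromosome's first or last marker there is no
recipient marker bounding the segment on that side; the default convention
extends the interval to the chromosome end and counts the marker-to-end span
fully (DD-like), configurable to 50%.

QTL testing: a two-sample t-test of each line's replicate phenotype against
the recurrent parent (pooled variance by default, Welch optional), declared
at raw p < alpha with no multiple-testing correction across lines (an
optional BH mode exists).  With replicate structure from independent
experiments, a QTL is declared only when significant in every experiment —
the consistency rule used with small replicated field designs.  Effects:

    additive effect     = (line mean - parent mean) / 2
    additive effect %   = additive effect / parent mean x 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io_formats import GenotypeMatrix, MarkerMap, MirqtlError, SegmentViolationError
from .de_calling import bh_adjust


class QTLError(MirqtlError):
    pass


@dataclass(frozen=True)
class Segment:
    """A line's substituted chromosome interval and donor-equivalent length."""

    line_id: str
    chromosome: str
    start_mb: float
    end_mb: float
    length_mb: float
    left_marker: str  # bounding recipient marker, or "Start"
    right_marker: str  # bounding recipient marker, or "End"
    marker_interval: str  # hyphen-joined markers spanning the segment


@dataclass(frozen=True)
class QTLResult:
    qtl_id: str
    line_id: str
    chromosome: str
    start_mb: float
    end_mb: float
    length_mb: float
    marker_interval: str
    t_statistic: float
    p_value: float
    additive_effect: float
    additive_effect_pct: float
    parent_mean: float  # the recurrent-parent phenotype the percentage refers to
    donor_direction: str  # "donor-increases" | "donor-decreases"


def segment_interval(
    line_id: str,
    codes: np.ndarray,
    markers: MarkerMap,
    terminal: str = "full",
) -> Segment:
    """Estimate a line's substituted segment from its marker codes.

    ``codes`` is the line's D/R vector in marker-map order.  ``terminal``
    sets how a donor run touching the first/last marker is handled: "full"
    (default) counts the marker-to-chromosome-end span as 100% donor,
    "half" as 50%.
    """
    if terminal not in {"full", "half"}:
        raise ValueError(f"terminal must be 'full' or 'half', got {terminal!r}")
    codes = np.asarray(codes, dtype="<U1")
    donor_idx = np.flatnonzero(codes == "D")
    if donor_idx.size == 0:
        raise SegmentViolationError(f"line {line_id!r} carries no donor marker")
    chroms = {markers.chromosomes[i] for i in donor_idx}
    if len(chroms) > 1:
        raise SegmentViolationError(
            f"line {line_id!r}: donor markers on multiple chromosomes {sorted(chroms)}"
        )
    chrom = chroms.pop()
    cidx = markers.chrom_indices(chrom)
    local = [cidx.index(i) for i in donor_idx]
    if local != list(range(local[0], local[-1] + 1)):
        raise SegmentViolationError(f"line {line_id!r}: more than one donor run")
    pos = markers.chrom_positions(chrom)
    names = markers.chrom_markers(chrom)
    i0, i1 = local[0], local[-1]

    core = float(pos[i1] - pos[i0])
    terminal_weight = 1.0 if terminal == "full" else 0.5

    if i0 > 0:
        start = float(pos[i0 - 1])
        left_len = 0.5 * (pos[i0] - pos[i0 - 1])
        left_marker = names[i0 - 1]
    else:
        start = 0.0
        left_len = terminal_weight * pos[i0]
        left_marker = "Start"
    if i1 < len(pos) - 1:
        end = float(pos[i1 + 1])
        right_len = 0.5 * (pos[i1 + 1] - pos[i1])
        right_marker = names[i1 + 1]
    else:
        end = float(markers.chromosome_end[chrom])
        right_len = terminal_weight * (end - pos[i1])
        right_marker = "End"

    span_markers = ([] if left_marker == "Start" else [left_marker]) + names[i0 : i1 + 1] + (
        [] if right_marker == "End" else [right_marker]
    )
    interval_label = "-".join(
        (["Start"] if left_marker == "Start" else []) + span_markers + (["End"] if right_marker == "End" else [])
    )
    return Segment(
        line_id=line_id,
        chromosome=chrom,
        start_mb=start,
        end_mb=end,
        length_mb=float(core + left_len + right_len),
        left_marker=left_marker,
        right_marker=right_marker,
        marker_interval=interval_label,
    )


def qtl_test(
    line_pheno, parent_pheno, alpha: float = 0.05, welch: bool = False
) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test of a line against the recurrent parent.

    Returns (t statistic, p value, declared) with declared = (p < alpha).
    Pooled variance by default; ``welch=True`` drops the equal-variance
    assumption.
    """
    line = np.asarray(line_pheno, dtype=float)
    parent = np.asarray(parent_pheno, dtype=float)
    if line.size < 2 or parent.size < 2:
        raise QTLError(
            f"t-test needs >= 2 replicates per group, got {line.size} and {parent.size}"
        )
    if line.std() == 0 and parent.std() == 0 and line.mean() == parent.mean():
        return 0.0, 1.0, False  # degenerate: identical constant samples
    t, p = _stats.ttest_ind(line, parent, equal_var=not welch)
    if np.isnan(p):
        t, p = 0.0, 1.0
    return float(t), float(p), bool(p < alpha)


def additive_effect(line_mean: float, parent_mean: float) -> tuple[float, float]:
    """(line - parent)/2 and that effect as a percent of the parent mean.

    The substituted segment carries two donor allele doses, hence the
    halving; a negative effect means the donor allele decreases the trait.
    """
    effect = (line_mean - parent_mean) / 2.0
    if parent_mean == 0:
        raise QTLError("parent mean is zero: additive effect percentage undefined")
    return effect, effect / parent_mean * 100.0


def _phenotype_groups(phenotypes: pd.DataFrame) -> pd.DataFrame:
    required = {"line_id", "value"}
    if not required.issubset(phenotypes.columns):
        raise QTLError(f"phenotype table needs columns {sorted(required)}")
    df = phenotypes.copy()
    if "experiment" not in df.columns:
        df["experiment"] = 1
    return df


def detect_qtls(
    panel: GenotypeMatrix,
    markers: MarkerMap,
    phenotypes: pd.DataFrame,
    parent_id: str,
    alpha: float = 0.05,
    welch: bool = False,
    terminal: str = "full",
    replicate_unit: str = "auto",
    bh_correct: bool = False,
) -> list[QTLResult]:
    """Test every SSSL against the recurrent parent and map declared QTLs to
    the lines' substituted segments.

    ``phenotypes`` has columns line_id, value and optionally experiment.
    ``replicate_unit`` chooses the declaration rule: "pooled" runs one
    t-test on all replicates; "experiment" runs one t-test per experiment
    and declares only lines significant in **every** experiment (reported
    p is the maximum across experiments); "auto" (default) uses
    "experiment" when >= 2 experiment labels are present.  ``bh_correct``
    optionally BH-adjusts the per-line p-values before declaration (off by
    default: declaration is at raw p < alpha).
    """
    df = _phenotype_groups(phenotypes)
    if parent_id not in set(df["line_id"]):
        raise QTLError(f"recurrent parent {parent_id!r} has no phenotype records")
    experiments = sorted(df["experiment"].unique())
    if replicate_unit == "auto":
        replicate_unit = "experiment" if len(experiments) > 1 else "pooled"
    if replicate_unit not in {"pooled", "experiment"}:
        raise ValueError(f"replicate_unit must be pooled|experiment|auto, got {replicate_unit!r}")

    parent_df = df[df["line_id"] == parent_id]
    candidates = []  # (line_id, segment, t, p, effect, pct, parent_mean)
    for line_id in panel.line_ids:
        if line_id == parent_id:
            continue
        line_df = df[df["line_id"] == line_id]
        if line_df.empty:
            continue
        segment = segment_interval(line_id, panel.row(line_id), markers, terminal=terminal)
        if replicate_unit == "pooled":
            t, p, _ = qtl_test(line_df["value"], parent_df["value"], alpha, welch)
            parent_mean = float(parent_df["value"].mean())
            effect, pct = additive_effect(float(line_df["value"].mean()), parent_mean)
        else:
            ts, ps, effects = [], [], []
            for exp in experiments:
                lv = line_df.loc[line_df["experiment"] == exp, "value"]
                pv = parent_df.loc[parent_df["experiment"] == exp, "value"]
                if lv.empty or pv.empty:
                    raise QTLError(
                        f"line {line_id!r} or parent missing replicates in experiment {exp!r}"
                    )
                t_e, p_e, _ = qtl_test(lv, pv, alpha, welch)
                ts.append(t_e)
                ps.append(p_e)
                effects.append((float(lv.mean()) - float(pv.mean())) / 2.0)
            # declared only if significant in every independent experiment
            t, p = float(np.mean(ts)), float(np.max(ps))
            effect = float(np.mean(effects))
            parent_mean = float(
                np.mean([parent_df.loc[parent_df["experiment"] == e, "value"].mean() for e in experiments])
            )
            if parent_mean == 0:
                raise QTLError("parent mean is zero: additive effect percentage undefined")
            pct = effect / parent_mean * 100.0
        candidates.append((line_id, segment, t, p, effect, pct, parent_mean))

    pvals = [c[3] for c in candidates]
    declared_p = bh_adjust(pvals) if (bh_correct and pvals) else np.asarray(pvals)
    declared = [c for c, q in zip(candidates, declared_p) if q < alpha]

    # name QTLs qHT-<chr>; distinct segments on one chromosome get .2, .3 ...
    declared.sort(key=lambda c: (str(c[1].chromosome), c[1].start_mb, c[0]))
    results: list[QTLResult] = []
    interval_names: dict[tuple, str] = {}
    per_chrom: dict[str, int] = {}
    for line_id, seg, t, p, effect, pct, parent_mean in declared:
        key = (seg.chromosome, round(seg.start_mb, 9), round(seg.end_mb, 9))
        if key not in interval_names:
            per_chrom[seg.chromosome] = per_chrom.get(seg.chromosome, 0) + 1
            nth = per_chrom[seg.chromosome]
            chrom_label = str(seg.chromosome).removeprefix("chr")
            interval_names[key] = f"qHT-{chrom_label}" + (f".{nth}" if nth > 1 else "")
        results.append(
            QTLResult(
                qtl_id=interval_names[key],
                line_id=line_id,
                chromosome=seg.chromosome,
                start_mb=seg.start_mb,
                end_mb=seg.end_mb,
                length_mb=seg.length_mb,
                marker_interval=seg.marker_interval,
                t_statistic=t,
                p_value=p,
                additive_effect=effect,
                additive_effect_pct=pct,
                parent_mean=parent_mean,
                donor_direction="donor-increases" if effect >= 0 else "donor-decreases",
            )
        )
    return results


def qtl_table(results: list[QTLResult]) -> pd.DataFrame:
    """QTL results as a table mirroring published SSSL QTL summaries."""
    return pd.DataFrame(
        [
            {
                "qtl_id": r.qtl_id,
                "line_id": r.line_id,
                "chromosome": r.chromosome,
                "marker_interval": r.marker_interval,
                "start_mb": r.start_mb,
                "end_mb": r.end_mb,
                "length_mb": r.length_mb,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "additive_effect": r.additive_effect,
                "additive_effect_pct": r.additive_effect_pct,
                "parent_mean": r.parent_mean,
                "donor_direction": r.donor_direction,
            }
            for r in results
        ]
    )
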