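"""Differential expression of miRNAs from pooled small-RNA count libraries.

The design has no biological replicates per condition: each (genotype,
treatment, timepoint) cell is a single pooled library.  Differential
expression of a miRNA in a heat-vs-control contrast is therefore assessed
with Fisher's exact test on raw read counts (the count of the miRNA against
the rest of the library), fold change is computed on TPM-normalised values,
and false discovery is controlled per contrast with Benjamini-Hochberg.

A miRNA is called DE only when all three gates pass:

* |log2 fold change| >= ``lfc`` (default 1.0, i.e. two-fold),
* Fisher two-sided ``p`` <= ``alpha`` (default 0.05),
* BH-adjusted FDR <= ``fdr`` (default 0.05).

Raw counts feed the exact test; TPM feeds only the fold change.  The
pseudo-count added to both TPM values before taking the ratio defaults to
0.25 TPM, small relative to the 10-read confirmation floor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, MirqtlError

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 10
DEFAULT_PSEUDO_TPM = 0.25


class ContrastError(MirqtlError):
    """A requested heat-vs-control contrast cannot be resolved."""


@dataclass
class TPMMatrix:
    """Transcripts-per-million values, same layout as the CountMatrix it came
    from.  Each library column sums to 1e6 over the normalisation set unless
    library totals were taken from metadata."""

    mirna_ids: list[str]
    library_ids: list[str]
    values: np.ndarray
    library_meta: dict

    def column(self, library_id: str) -> np.ndarray:
        return self.values[:, self.library_ids.index(library_id)]


@dataclass(frozen=True)
class Contrast:
    """One heat-vs-control comparison within a genotype at one time point."""

    genotype: str
    timepoint_hours: int

    def resolve(self, meta: dict) -> tuple[str, str]:
        """Return (heat_library, control_library) ids for this contrast."""
        heat = [
            lib
            for lib, m in meta.items()
            if m.genotype == self.genotype
            and m.timepoint_hours == self.timepoint_hours
            and m.treatment == "heat"
        ]
        ctrl = [
            lib
            for lib, m in meta.items()
            if m.genotype == self.genotype
            and m.timepoint_hours == self.timepoint_hours
            and m.treatment == "control"
        ]
        if len(heat) != 1 or len(ctrl) != 1:
            raise ContrastError(
                f"contrast ({self.genotype}, {self.timepoint_hours} h) needs exactly one "
                f"heat and one control library, found heat={heat}, control={ctrl}"
            )
        return heat[0], ctrl[0]


@dataclass(frozen=True)
class DECall:
    mirna_id: str
    genotype: str
    timepoint_hours: int
    log2_fold_change: float
    p_value: float
    fdr: float
    direction: str  # "up" | "down" | "ns"

    @property
    def is_de(self) -> bool:
        return self.direction != "ns"

    @property
    def sign(self) -> int:
        return {"up": 1, "down": -1, "ns": 0}[self.direction]


@dataclass(frozen=True)
class DECategory:
    mirna_id: str
    category: str


def confirm_mirnas(counts: CountMatrix, min_reads: int = DEFAULT_MIN_READS) -> CountMatrix:
    """Keep miRNAs observed ``min_reads`` times or more in at least one
    library (inclusive threshold); row order is preserved."""
    keep = counts.counts.max(axis=1) >= min_reads
    if not keep.any():
        logger.warning("no miRNA reaches %d reads in any library", min_reads)
    return CountMatrix(
        mirna_ids=[m for m, k in zip(counts.mirna_ids, keep) if k],
        library_ids=list(counts.library_ids),
        counts=counts.counts[keep],
        library_meta=dict(counts.library_meta),
    )


def library_totals(counts: CountMatrix, total_from: str = "matrix") -> np.ndarray:
    """Per-library totals used for TPM: the matrix column sum (default) or
    the ``total_reads`` metadata column when ``total_from='meta'``."""
    if total_from == "matrix":
        return counts.counts.sum(axis=0).astype(float)
    if total_from == "meta":
        totals = []
        for lib in counts.library_ids:
            t = counts.library_meta[lib].total_reads
            if t is None:
                raise MirqtlError(f"library {lib!r} has no total_reads in metadata")
            totals.append(float(t))
        return np.asarray(totals)
    raise ValueError(f"total_from must be 'matrix' or 'meta', got {total_from!r}")


def tpm_normalize(counts: CountMatrix, total_from: str = "matrix") -> TPMMatrix:
    """count / library_total * 1e6 per cell."""
    totals = library_totals(counts, total_from)
    zero = [lib for lib, t in zip(counts.library_ids, totals) if t <= 0]
    if zero:
        raise MirqtlError(f"libraries with zero total reads: {zero}")
    values = counts.counts / totals[None, :] * 1e6
    return TPMMatrix(
        mirna_ids=list(counts.mirna_ids),
        library_ids=list(counts.library_ids),
        values=values,
        library_meta=dict(counts.library_meta),
    )


def log2_fold_change(tpm_treat: float, tpm_ctrl: float, pseudo: float = DEFAULT_PSEUDO_TPM) -> float:
    """log2((treatment + pseudo) / (control + pseudo)); pseudo > 0 keeps the
    ratio finite when one side is zero."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")
    if tpm_treat < 0 or tpm_ctrl < 0:
        raise ValueError("TPM values must be >= 0")
    return math.log2((tpm_treat + pseudo) / (tpm_ctrl + pseudo))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Row 1 is (miRNA count, library total - count) in the treatment library,
    row 2 the same in the control library.  Two-sided by the conventional
    point-probability rule: sum of probabilities of all tables with the
    margins fixed whose probability is <= the observed one (ties included).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"table cells must be >= 0, got {cells}")
    if any(int(x) != x for x in cells):
        raise ValueError(f"table cells must be integers, got {cells}")
    return float(_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order,
    clipped at 1 and monotone non-decreasing in sorted-p order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    tpm: TPMMatrix,
    counts: CountMatrix,
    contrast: Contrast,
    lfc: float = 1.0,
    alpha: float = 0.05,
    fdr: float = 0.05,
    pseudo: float = DEFAULT_PSEUDO_TPM,
    total_from: str = "matrix",
) -> list[DECall]:
    """One DECall per confirmed miRNA for a heat-vs-control contrast.

    The FDR family is the set of all confirmed miRNAs within this contrast.
    Direction is "up" iff log2FC >= lfc AND p <= alpha AND FDR <= fdr;
    "down" with log2FC <= -lfc analogously; otherwise "ns".
    """
    if tpm.mirna_ids != counts.mirna_ids or tpm.library_ids != counts.library_ids:
        raise MirqtlError("TPM and count matrices are not aligned")
    heat_lib, ctrl_lib = contrast.resolve(counts.library_meta)
    totals = library_totals(counts, total_from)
    heat_total = int(totals[counts.library_ids.index(heat_lib)])
    ctrl_total = int(totals[counts.library_ids.index(ctrl_lib)])
    heat_counts = counts.column(heat_lib)
    ctrl_counts = counts.column(ctrl_lib)
    heat_tpm = tpm.column(heat_lib)
    ctrl_tpm = tpm.column(ctrl_lib)

    lfcs = np.array(
        [log2_fold_change(t, c, pseudo) for t, c in zip(heat_tpm, ctrl_tpm)]
    )
    pvals = np.array(
        [
            fisher_exact_2x2(int(hc), heat_total - int(hc), int(cc), ctrl_total - int(cc))
            for hc, cc in zip(heat_counts, ctrl_counts)
        ]
    )
    fdrs = bh_adjust(pvals)

    calls = []
    for mirna, l2fc, p, q in zip(counts.mirna_ids, lfcs, pvals, fdrs):
        if l2fc >= lfc and p <= alpha and q <= fdr:
            direction = "up"
        elif l2fc <= -lfc and p <= alpha and q <= fdr:
            direction = "down"
        else:
            direction = "ns"
        calls.append(
            DECall(mirna, contrast.genotype, contrast.timepoint_hours, float(l2fc), float(p), float(q), direction)
        )
    return calls


def all_contrasts(meta: dict) -> list[Contrast]:
    """Every (genotype, timepoint) contrast present in the metadata, in
    stable (genotype, timepoint) order."""
    seen = sorted({(m.genotype, m.timepoint_hours) for m in meta.values()})
    return [Contrast(g, t) for g, t in seen]


def call_all_de(counts: CountMatrix, min_reads: int = DEFAULT_MIN_READS, **kwargs) -> list[DECall]:
    """Confirm, normalise and call DE across every contrast in the metadata."""
    confirmed = confirm_mirnas(counts, min_reads)
    tpm = tpm_normalize(confirmed, total_from=kwargs.get("total_from", "matrix"))
    calls: list[DECall] = []
    for contrast in all_contrasts(counts.library_meta):
        calls.extend(call_de(tpm, confirmed, contrast, **kwargs))
    return calls


def _genotype_sign(calls: list[DECall], tie_break: str) -> int:
    """Majority sign over a genotype's DE timepoints; 0 encodes an exact tie."""
    total = sum(c.sign for c in calls if c.is_de)
    if total > 0:
        return 1
    if total < 0:
        return -1
    if tie_break == "latest":
        latest = max((c for c in calls if c.is_de), key=lambda c: c.timepoint_hours)
        return latest.sign
    return 0  # tie -> treated as opposite-capable


def categorize_de(
    calls_by_genotype: dict[str, list[DECall]], tie_break: str = "opposite"
) -> list[DECategory]:
    """Assign each DE miRNA to one of four cross-genotype categories.

    With genotypes A and B: DE in both with the same majority sign ->
    ``co-regulated-same-direction``; DE in both with opposite (or tied,
    under the default tie policy) signs -> ``co-regulated-opposite``; DE in
    only one genotype -> ``<genotype>-specific``.  ``tie_break`` controls
    how a within-genotype exact sign tie is resolved: ``"opposite"``
    (default, tie counts as opposite-capable) or ``"latest"`` (sign at the
    latest DE timepoint).
    """
    if len(calls_by_genotype) != 2:
        raise MirqtlError(
            f"categorisation needs exactly two genotypes, got {sorted(calls_by_genotype)}"
        )
    if tie_break not in {"opposite", "latest"}:
        raise ValueError(f"tie_break must be 'opposite' or 'latest', got {tie_break!r}")
    (geno_a, calls_a), (geno_b, calls_b) = sorted(calls_by_genotype.items())
    de_a = {c.mirna_id for c in calls_a if c.is_de}
    de_b = {c.mirna_id for c in calls_b if c.is_de}

    categories = []
    for mirna in sorted(de_a | de_b):
        if mirna in de_a and mirna in de_b:
            sign_a = _genotype_sign([c for c in calls_a if c.mirna_id == mirna], tie_break)
            sign_b = _genotype_sign([c for c in calls_b if c.mirna_id == mirna], tie_break)
            if sign_a != 0 and sign_a == sign_b:
                cat = "co-regulated-same-direction"
            else:
                cat = "co-regulated-opposite"
        elif mirna in de_a:
            cat = f"{geno_a}-specific"
        else:
            cat = f"{geno_b}-specific"
        categories.append(DECategory(mirna, cat))
    return categories
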