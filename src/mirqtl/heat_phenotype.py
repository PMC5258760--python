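"""Spikelet-fertility phenotyping and the heat tolerance index (HI).

Per plant, spikelet fertility is SFP = FSP / TSP x 100 (percent of filled
spikelets).  A line x condition summary is the mean and sample standard
deviation over replicate plants (typically 10).  Heat tolerance is the ratio

    HI = SFP(heat) / SFP(control)

computed on the condition means ("ratio of means"), which reproduces
published line-level HI values exactly; a paired mean-of-per-plant-ratios
mode is available for uncertainty estimation.  HI ~ 1 means no fertility
loss under stress; HI near 0 means near-complete sterility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import MirqtlError, PlantRecord


class PhenotypeError(MirqtlError):
    pass


@dataclass(frozen=True)
class FertilitySummary:
    line_id: str
    condition: str
    sfp_mean: float  # percent
    sfp_sd: float  # percent, sample sd (ddof=1); 0 for a single plant
    n_plants: int


@dataclass(frozen=True)
class HIRecord:
    line_id: str
    hi: float
    hi_sd: float  # delta-method propagation of the two condition sds


def spikelet_fertility(plants: list[PlantRecord]) -> FertilitySummary:
    """Mean and sd of per-plant SFP = FSP/TSP x 100 for one line x condition."""
    if not plants:
        raise PhenotypeError("no plant records given")
    lines = {p.line_id for p in plants}
    conditions = {p.condition for p in plants}
    if len(lines) != 1 or len(conditions) != 1:
        raise PhenotypeError(
            f"records mix lines {sorted(lines)} / conditions {sorted(conditions)}"
        )
    sfp = np.array([p.fsp / p.tsp * 100.0 for p in plants])
    sd = float(sfp.std(ddof=1)) if len(sfp) > 1 else 0.0
    return FertilitySummary(
        line_id=plants[0].line_id,
        condition=plants[0].condition,
        sfp_mean=float(sfp.mean()),
        sfp_sd=sd,
        n_plants=len(plants),
    )


def heat_tolerance_index(stress: FertilitySummary, control: FertilitySummary) -> HIRecord:
    """HI = stressed SFP mean / control SFP mean for one line."""
    if stress.line_id != control.line_id:
        raise PhenotypeError(
            f"line mismatch: stress {stress.line_id!r} vs control {control.line_id!r}"
        )
    if control.sfp_mean <= 0:
        raise PhenotypeError(
            f"line {control.line_id!r}: control fertility is zero, HI undefined"
        )
    hi = stress.sfp_mean / control.sfp_mean
    # delta-method sd of a ratio of independent means
    rel_var = 0.0
    if stress.sfp_mean > 0:
        rel_var += (stress.sfp_sd / math.sqrt(stress.n_plants) / stress.sfp_mean) ** 2
    rel_var += (control.sfp_sd / math.sqrt(control.n_plants) / control.sfp_mean) ** 2
    return HIRecord(stress.line_id, hi, hi * math.sqrt(rel_var))


def heat_tolerance_index_per_plant(
    stress_plants: list[PlantRecord], control_plants: list[PlantRecord]
) -> HIRecord:
    """Mean of per-plant SFP ratios, pairing plants by index.

    Requires equally sized groups; intended for uncertainty estimation, not
    for reproducing line-level published HI values (which are ratios of
    means).
    """
    if len(stress_plants) != len(control_plants):
        raise PhenotypeError(
            "per-plant HI needs equally many stress and control plants "
            f"({len(stress_plants)} vs {len(control_plants)})"
        )
    ratios = []
    for s, c in zip(stress_plants, control_plants):
        c_sfp = c.fsp / c.tsp
        if c_sfp == 0:
            raise PhenotypeError(f"control plant {c.plant} of {c.line_id!r} has zero fertility")
        ratios.append((s.fsp / s.tsp) / c_sfp)
    arr = np.array(ratios)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return HIRecord(stress_plants[0].line_id, float(arr.mean()), sd)


def summarize_lines(plants: list[PlantRecord]) -> list[HIRecord]:
    """Group plant records by line, summarise each condition, and compute HI
    for every line that has both conditions."""
    by_line: dict[str, dict[str, list[PlantRecord]]] = {}
    for p in plants:
        by_line.setdefault(p.line_id, {}).setdefault(p.condition, []).append(p)
    records = []
    for line_id in sorted(by_line):
        groups = by_line[line_id]
        if set(groups) != {"control", "heat"}:
            raise PhenotypeError(
                f"line {line_id!r} needs both control and heat plants, has {sorted(groups)}"
            )
        stress = spikelet_fertility(groups["heat"])
        ctrl = spikelet_fertility(groups["control"])
        records.append(heat_tolerance_index(stress, ctrl))
    return records
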