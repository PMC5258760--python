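"""Synthetic inputs with the statistical structure the pipeline assumes.

Every external input the analysis consumes can be generated here with known
ground truth, so each stage — and the whole funnel from count libraries to
ranked candidate genes — is testable without any download:

* pooled small-RNA count libraries (negative binomial, designated
  heat-responsive miRNAs spiked at stated fold changes),
* a 23-line single-segment substitution panel tiling 12 chromosomes, with
  percent-scale stress-fertility phenotypes driven by planted QTL effects
  plus Gaussian noise, replicated over independent experiments,
* a toy genome annotation plus miRNA/transcript sequences in which true
  target transcripts carry planted complementary sites and a stated
  fraction of true target genes falls inside planted QTL intervals,
* per-plant spikelet counts and expression profiles for the phenotyping and
  integration stages.

All generators are pure functions of (config, seed): a fixed seed gives
byte-identical outputs.  Defaults echo the study design this pipeline is
built for: 12 libraries (2 genotypes x control/heat x 1/6/24 h), depth 1e6,
23 lines, 4 planted QTLs on chromosomes 3/6/8/12 with additive effects
{3.59, 5.60, 9.24, 2.72} on a percent-scale phenotype with parent mean 18.5,
noise sd 1.5, 3 experiments x 10 plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GeneModel,
    GenotypeMatrix,
    LibraryMeta,
    MarkerMap,
    MirqtlError,
    PlantRecord,
)
from .integration import ExpressionProfile
from .target_scoring import _to_rna

_RNA = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class SimulationError(MirqtlError):
    pass


@dataclass(frozen=True)
class PlantedQTL:
    chromosome: str
    additive_effect: float
    start_mb: float | None = None  # None: derived from the carrier segment
    end_mb: float | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    # small-RNA libraries
    n_mirnas: int = 200
    n_de: int = 20
    spike_log2fc: float = 2.0
    fraction_up: float = 0.25  # most heat-responsive miRNAs go down
    library_depth: int = 1_000_000
    dispersion: float = 0.1  # NB variance mu + phi mu^2
    genotypes: tuple[str, ...] = ("GXN", "HJX")
    timepoints: tuple[int, ...] = (1, 6, 24)
    spike_pattern: str = "staggered"  # "staggered" | "all-cells"
    second_genotype_spike_prob: float = 0.4
    abundance_sigma: float = 1.5  # lognormal spread of baseline abundances
    min_spike_mean: float = 100.0  # spikes drawn from the expressed stratum
    # SSSL panel
    n_lines: int = 23
    n_chromosomes: int = 12
    markers_per_chromosome: int = 8
    chromosome_length_mb: float = 30.0
    planted_qtls: tuple[PlantedQTL, ...] = (
        PlantedQTL("3", 3.59),
        PlantedQTL("6", 5.60),
        PlantedQTL("8", 9.24),
        PlantedQTL("12", 2.72),
    )
    parent_id: str = "HJX"
    parent_mean: float = 18.5  # percent-scale stress fertility
    phenotype_sd: float = 1.5
    n_experiments: int = 3
    plants_per_line: int = 10
    # annotation / targets
    n_genes: int = 60
    fraction_targets_in_qtl: float = 0.5
    n_unexpressed_targets: int = 2
    planted_mismatches: tuple[int, ...] = (0, 1, 2)
    transcript_length_nt: int = 300
    mirna_length_nt: int = 21
    gene_length_mb: float = 0.003

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# substream ids, one per generator so outputs are independently reproducible
_STREAM_COUNTS, _STREAM_PANEL, _STREAM_TARGETS, _STREAM_PROFILES, _STREAM_PLANTS = range(5)


@dataclass
class SimulatedCounts:
    counts: CountMatrix
    truth: pd.DataFrame  # mirna_id, genotype, timepoint_hours, log2fc
    expected_means: pd.DataFrame  # mirna x library expected NB means


def library_id(genotype: str, timepoint: int, treatment: str) -> str:
    return f"{genotype}-{timepoint}h{'T' if treatment == 'heat' else 'C'}"


def simulate_counts(config: SimulationConfig) -> SimulatedCounts:
    """Negative-binomial miRNA count libraries with spiked heat responses.

    Baseline relative abundances are lognormal and shared across libraries;
    spiked miRNAs multiply their heat-library mean by 2**(+-spike_log2fc)
    at their designated (genotype, timepoint) cells, emulating confirmed
    heat-responsive miRNAs.  Under the default "staggered" spike pattern
    each spiked miRNA responds from a per-genotype onset time point onward:
    always in the first (tolerant-like) genotype, starting at the first or
    second time point, and with probability ``second_genotype_spike_prob``
    in the second genotype, starting no earlier than the second time point —
    the tolerant genotype responds more and earlier.  "all-cells" spikes
    every heat cell.  The truth table records every spiked (miRNA,
    genotype, timepoint, signed log2fc).
    """
    if config.library_depth <= 0:
        raise SimulationError(f"library depth must be > 0, got {config.library_depth}")
    rng = config.rng(_STREAM_COUNTS)
    n = config.n_mirnas
    mirna_ids = [f"mir-{i:04d}" for i in range(1, n + 1)]

    rel = np.exp(rng.normal(0.0, config.abundance_sigma, size=n))
    rel /= rel.sum()
    base_mean = rel * config.library_depth

    expressed = np.flatnonzero(base_mean >= config.min_spike_mean)
    if expressed.size < config.n_de:
        raise SimulationError(
            f"only {expressed.size} miRNAs reach the spike abundance floor; "
            f"cannot spike {config.n_de}"
        )
    spiked = np.sort(rng.choice(expressed, size=config.n_de, replace=False))
    n_up = int(round(config.fraction_up * config.n_de))
    signs = np.array([1] * n_up + [-1] * (config.n_de - n_up))
    rng.shuffle(signs)
    onsets = _spike_onsets(config, rng)

    libraries, meta = [], {}
    for genotype in config.genotypes:
        for tp in config.timepoints:
            for treatment in ("control", "heat"):
                lib = library_id(genotype, tp, treatment)
                libraries.append(lib)
                meta[lib] = LibraryMeta(genotype, treatment, tp)

    means = np.tile(base_mean[:, None], (1, len(libraries)))
    truth_rows = []
    for j, lib in enumerate(libraries):
        m = meta[lib]
        if m.treatment != "heat":
            continue
        for k, (idx, sign) in enumerate(zip(spiked, signs)):
            onset = onsets[k].get(m.genotype)
            if onset is None or m.timepoint_hours < onset:
                continue
            lfc = float(sign * config.spike_log2fc)
            means[idx, j] = base_mean[idx] * 2.0**lfc
            truth_rows.append(
                {
                    "mirna_id": mirna_ids[idx],
                    "genotype": m.genotype,
                    "timepoint_hours": m.timepoint_hours,
                    "log2fc": lfc,
                }
            )

    counts = _nb_draw(rng, means, config.dispersion)
    cm = CountMatrix(mirna_ids, libraries, counts, meta)
    truth = pd.DataFrame(truth_rows, columns=["mirna_id", "genotype", "timepoint_hours", "log2fc"])
    expected = pd.DataFrame(means, index=mirna_ids, columns=libraries)
    return SimulatedCounts(cm, truth, expected)


def _spike_onsets(
    config: SimulationConfig, rng: np.random.Generator
) -> list[dict[str, int]]:
    """Per spiked miRNA, the heat-response onset time point per genotype
    (absent key: never spiked in that genotype)."""
    tps = sorted(config.timepoints)
    onsets: list[dict[str, int]] = []
    for _ in range(config.n_de):
        pattern: dict[str, int] = {}
        for gi, genotype in enumerate(config.genotypes):
            if config.spike_pattern == "all-cells":
                pattern[genotype] = tps[0]
                continue
            if gi == 0:
                # tolerant-like genotype: always responsive, often from the start
                pattern[genotype] = tps[0] if rng.random() < 0.5 else tps[min(1, len(tps) - 1)]
            else:
                if rng.random() < config.second_genotype_spike_prob:
                    late = tps[1:] or tps
                    pattern[genotype] = int(late[int(rng.integers(len(late)))])
        onsets.append(pattern)
    return onsets


def _nb_draw(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, phi) with variance mu + phi mu^2; phi = 0 is the Poisson limit."""
    if dispersion < 0:
        raise SimulationError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(means).astype(np.int64)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + means)
    return rng.negative_binomial(size_param, p).astype(np.int64)


@dataclass
class SimulatedPanel:
    markers: MarkerMap
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # line_id, experiment, plant, value
    truth: pd.DataFrame  # line_id, chromosome, qtl_start_mb, qtl_end_mb, additive_effect
    qtl_intervals: list[tuple[str, float, float, float]]  # chrom, start, end, effect
    carrier_segments: list[tuple[str, float, float]] = field(default_factory=list)


def simulate_sssl_panel(config: SimulationConfig) -> SimulatedPanel:
    """A single-segment substitution panel with planted QTL effects.

    Lines tile the chromosomes round-robin with disjoint donor runs; each
    planted QTL is assigned one carrier line and its interval is the
    carrier's donor-marker core, so exactly one line covers each QTL.
    Phenotype replicates are Normal(parent_mean + 2 x effect, sd) for
    carriers and Normal(parent_mean, sd) otherwise, drawn per experiment
    and plant; the recurrent parent is all-R.
    """
    if len(config.planted_qtls) > config.n_lines:
        raise SimulationError("more planted QTLs than panel lines")
    rng = config.rng(_STREAM_PANEL)
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    m = config.markers_per_chromosome
    if m < 6:
        raise SimulationError("need >= 6 markers per chromosome to place disjoint segments")
    positions = np.linspace(
        config.chromosome_length_mb * 0.05, config.chromosome_length_mb * 0.95, m
    )
    marker_ids, marker_chroms, marker_pos = [], [], []
    for chrom in chroms:
        for k in range(m):
            marker_ids.append(f"RM{chrom}_{k + 1}")
            marker_chroms.append(chrom)
            marker_pos.append(positions[k])
    markers = MarkerMap(
        marker_ids,
        marker_chroms,
        np.array(marker_pos),
        {c: config.chromosome_length_mb for c in chroms},
    )

    qtl_by_chrom = {q.chromosome: q for q in config.planted_qtls}
    if len(qtl_by_chrom) != len(config.planted_qtls):
        raise SimulationError("planted QTLs must sit on distinct chromosomes")
    unknown = set(qtl_by_chrom) - set(chroms)
    if unknown:
        raise SimulationError(f"planted QTLs on unknown chromosomes {sorted(unknown)}")

    # two disjoint donor-run slots per chromosome: markers [1,2] and [m-3, m-2]
    slots = [(1, 2), (m - 3, m - 2)]
    line_ids = [f"SSSL-{i:02d}" for i in range(1, config.n_lines + 1)]
    codes = np.full((config.n_lines + 1, len(marker_ids)), "R", dtype="<U1")
    line_chrom: dict[str, str] = {}
    carriers: dict[str, str] = {}  # chromosome -> carrier line
    # QTL chromosomes first so every planted QTL gets its slot-0 carrier
    chrom_cycle = [c for c in chroms if c in qtl_by_chrom] + [
        c for c in chroms if c not in qtl_by_chrom
    ]
    for i, line in enumerate(line_ids):
        chrom = chrom_cycle[i % len(chrom_cycle)]
        slot = slots[(i // len(chrom_cycle)) % len(slots)]
        cidx = markers.chrom_indices(chrom)
        for k in range(slot[0], slot[1] + 1):
            codes[i, cidx[k]] = "D"
        line_chrom[line] = chrom
        if chrom in qtl_by_chrom and chrom not in carriers and slot == slots[0]:
            carriers[chrom] = line
    missing = sorted(set(qtl_by_chrom) - set(carriers))
    if missing:
        raise SimulationError(f"no carrier line assigned for QTLs on chromosomes {missing}")

    all_lines = line_ids + [config.parent_id]
    geno = GenotypeMatrix(all_lines, codes, markers)

    # planted QTL interval = the carrier's donor-marker core
    qtl_intervals = []
    carrier_segments = []
    truth_rows = []
    for chrom, q in qtl_by_chrom.items():
        pos = markers.chrom_positions(chrom)
        start = q.start_mb if q.start_mb is not None else float(pos[slots[0][0]])
        end = q.end_mb if q.end_mb is not None else float(pos[slots[0][1]])
        qtl_intervals.append((chrom, start, end, q.additive_effect))
        # the carrier's full detectable interval: one recipient marker beyond
        # the donor core on each side
        carrier_segments.append((chrom, float(pos[slots[0][0] - 1]), float(pos[slots[0][1] + 1])))
        truth_rows.append(
            {
                "line_id": carriers[chrom],
                "chromosome": chrom,
                "qtl_start_mb": start,
                "qtl_end_mb": end,
                "additive_effect": q.additive_effect,
            }
        )
    carrier_effect = {row["line_id"]: row["additive_effect"] for row in truth_rows}

    pheno_rows = []
    for line in all_lines:
        mean = config.parent_mean + 2.0 * carrier_effect.get(line, 0.0)
        for exp in range(1, config.n_experiments + 1):
            values = rng.normal(mean, config.phenotype_sd, size=config.plants_per_line)
            for plant, v in enumerate(values, 1):
                pheno_rows.append(
                    {"line_id": line, "experiment": exp, "plant": plant, "value": float(v)}
                )
    phenotypes = pd.DataFrame(pheno_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["line_id", "chromosome", "qtl_start_mb", "qtl_end_mb", "additive_effect"],
    )
    return SimulatedPanel(markers, geno, phenotypes, truth, qtl_intervals, carrier_segments)


@dataclass
class SimulatedTargets:
    genes: list[GeneModel]
    mirna_records: list[tuple[str, str]]  # (id, RNA sequence)
    transcript_records: list[tuple[str, str]]  # (gene id, RNA sequence)
    truth_pairs: pd.DataFrame  # mirna_id, gene_id, n_mismatches, in_qtl, expressed


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_RNA), size=length))


def _revcomp_rna(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _mutate_outside_seed(
    rng: np.random.Generator, site: str, mirna: str, n_mut: int, seed_range: tuple[int, int]
) -> str:
    """Introduce n_mut mismatches into a planted site at non-seed miRNA
    positions (avoiding G:U wobbles so each mutation scores as a mismatch)."""
    L = len(mirna)
    # miRNA position i (1-based) pairs site index L - i
    candidates = [i for i in range(1, L + 1) if not seed_range[0] <= i <= seed_range[1]]
    chosen = rng.choice(candidates, size=n_mut, replace=False)
    site_list = list(site)
    for i in chosen:
        j = L - i
        mir_base = mirna[i - 1]
        forbidden = {_COMPLEMENT[mir_base]}
        if mir_base == "G":
            forbidden.add("U")
        if mir_base == "U":
            forbidden.add("G")
        options = [b for b in _RNA if b not in forbidden]
        site_list[j] = options[int(rng.integers(len(options)))]
    return "".join(site_list)


def simulate_annotation_and_targets(
    config: SimulationConfig,
    counts_truth: pd.DataFrame,
    qtl_intervals: list[tuple[str, float, float, float]],
    avoid_intervals: list[tuple[str, float, float]] | None = None,
) -> SimulatedTargets:
    """Gene models, miRNA and transcript sequences with planted target sites.

    Every spiked miRNA receives one true target gene; a fraction
    ``fraction_targets_in_qtl`` of those genes is placed inside planted QTL
    intervals, the rest (and all decoy genes) strictly outside every
    interval in ``avoid_intervals`` (default: the QTL intervals; pass the
    carrier lines' full segment intervals so outside genes stay clear of
    any detectable QTL region).
    True target transcripts embed the reverse complement of their miRNA with
    0-2 planted mismatches outside the seed.  The first
    ``n_unexpressed_targets`` in-QTL targets are flagged unexpressed,
    mirroring candidate genes that drop out on expression grounds.
    """
    rng = config.rng(_STREAM_TARGETS)
    spiked = sorted(counts_truth["mirna_id"].unique())
    if not spiked:
        raise SimulationError("no spiked miRNAs in the counts truth table")
    mirna_seqs = {m: _random_rna(rng, config.mirna_length_nt) for m in spiked}

    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    if config.gene_length_mb >= config.chromosome_length_mb:
        raise SimulationError("gene longer than chromosome")
    avoid = avoid_intervals or [(c, s, e) for c, s, e, _ in qtl_intervals]
    by_chrom: dict[str, list[tuple[float, float]]] = {}
    for chrom, start, end in avoid:
        by_chrom.setdefault(chrom, []).append((start, end))

    def place_inside_qtl(k: int) -> tuple[str, float, float]:
        chrom, start, end, _ = qtl_intervals[k % len(qtl_intervals)]
        lo = start
        hi = max(end - config.gene_length_mb, lo)
        s = float(rng.uniform(lo, hi))
        return chrom, s, s + config.gene_length_mb

    def place_outside_qtls() -> tuple[str, float, float]:
        for _ in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            s = float(rng.uniform(0, config.chromosome_length_mb - config.gene_length_mb))
            e = s + config.gene_length_mb
            if all(e <= qs or s >= qe for qs, qe in by_chrom.get(chrom, [])):
                return chrom, s, e
        raise SimulationError("could not place a gene outside the QTL intervals")

    n_in = int(round(config.fraction_targets_in_qtl * len(spiked)))
    genes: list[GeneModel] = []
    transcripts: list[tuple[str, str]] = []
    truth_rows = []
    scheme_seed = (2, 13)
    for k, mirna in enumerate(spiked):
        gene_id = f"LOC_T{k + 1:03d}"
        in_qtl = k < n_in
        chrom, s, e = place_inside_qtl(k) if in_qtl else place_outside_qtls()
        desc = "synthetic true target" + (" (in QTL)" if in_qtl else "")
        genes.append(GeneModel(gene_id, chrom, s, e, desc))
        n_mut = int(config.planted_mismatches[k % len(config.planted_mismatches)])
        site = _revcomp_rna(mirna_seqs[mirna])
        site = _mutate_outside_seed(rng, site, mirna_seqs[mirna], n_mut, scheme_seed)
        tx = _random_rna(rng, config.transcript_length_nt)
        insert_at = int(rng.integers(0, config.transcript_length_nt - len(site) + 1))
        tx = tx[:insert_at] + site + tx[insert_at + len(site):]
        transcripts.append((gene_id, tx))
        expressed = not (in_qtl and k < config.n_unexpressed_targets)
        truth_rows.append(
            {
                "mirna_id": mirna,
                "gene_id": gene_id,
                "n_mismatches": n_mut,
                "in_qtl": in_qtl,
                "expressed": expressed,
                "site_start": insert_at,
            }
        )

    for d in range(config.n_genes - len(spiked)):
        gene_id = f"LOC_D{d + 1:03d}"
        chrom, s, e = place_outside_qtls()
        genes.append(GeneModel(gene_id, chrom, s, e, "synthetic decoy gene"))
        transcripts.append((gene_id, _random_rna(rng, config.transcript_length_nt)))

    mirna_records = [(m, mirna_seqs[m]) for m in spiked]
    truth = pd.DataFrame(
        truth_rows,
        columns=["mirna_id", "gene_id", "n_mismatches", "in_qtl", "expressed", "site_start"],
    )
    return SimulatedTargets(genes, mirna_records, transcripts, truth)


def simulate_expression_profiles(
    config: SimulationConfig,
    counts_truth: pd.DataFrame,
    target_truth: pd.DataFrame,
    profile_noise_sd: float = 0.2,
) -> tuple[dict[str, ExpressionProfile], dict[str, float]]:
    """Gene expression profiles over (genotype, timepoint) cells plus mean
    abundances (TPM scale).

    True target genes track the negative of their miRNA's planted response
    (plus Gaussian noise), emulating cleavage-driven anti-correlation;
    unexpressed targets get zero abundance; decoys get independent noise.
    """
    rng = config.rng(_STREAM_PROFILES)
    cells = tuple((g, t) for g in config.genotypes for t in config.timepoints)
    spike = {
        (row["mirna_id"], row["genotype"], row["timepoint_hours"]): row["log2fc"]
        for _, row in counts_truth.iterrows()
    }
    profiles: dict[str, ExpressionProfile] = {}
    abundance: dict[str, float] = {}
    for _, row in target_truth.iterrows():
        gene, mirna = row["gene_id"], row["mirna_id"]
        values = tuple(
            float(-0.8 * spike.get((mirna, g, t), 0.0) + rng.normal(0.0, profile_noise_sd))
            for g, t in cells
        )
        profiles[gene] = ExpressionProfile(gene, cells, values)
        abundance[gene] = 50.0 if row["expressed"] else 0.0
    return profiles, abundance


def mirna_profiles_from_tpm(tpm, pseudo: float = 0.25) -> dict[str, ExpressionProfile]:
    """Observed miRNA profiles: log2((heat + pseudo)/(control + pseudo)) per
    (genotype, timepoint) cell, from a TPM matrix."""
    meta = tpm.library_meta
    cells = sorted(
        {(m.genotype, m.timepoint_hours) for m in meta.values()},
        key=lambda c: (c[0], c[1]),
    )
    columns = {}
    for g, t in cells:
        heat = [lib for lib, m in meta.items() if (m.genotype, m.timepoint_hours, m.treatment) == (g, t, "heat")]
        ctrl = [lib for lib, m in meta.items() if (m.genotype, m.timepoint_hours, m.treatment) == (g, t, "control")]
        if len(heat) == 1 and len(ctrl) == 1:
            columns[(g, t)] = (tpm.column(heat[0]), tpm.column(ctrl[0]))
    profiles = {}
    for i, mirna in enumerate(tpm.mirna_ids):
        values = tuple(
            float(np.log2((columns[c][0][i] + pseudo) / (columns[c][1][i] + pseudo)))
            for c in columns
        )
        profiles[mirna] = ExpressionProfile(mirna, tuple(columns), values)
    return profiles


def simulate_plant_records(
    config: SimulationConfig,
    fertilities: dict[str, tuple[float, float]],
    tsp_mean: int = 150,
) -> list[PlantRecord]:
    """Per-plant spikelet counts for given (control%, heat%) fertilities.

    TSP ~ shifted Poisson(tsp_mean); FSP ~ Binomial(TSP, fertility/100).
    """
    rng = config.rng(_STREAM_PLANTS)
    records = []
    for line_id, (ctrl_pct, heat_pct) in fertilities.items():
        for condition, pct in (("control", ctrl_pct), ("heat", heat_pct)):
            for plant in range(1, config.plants_per_line + 1):
                tsp = int(rng.poisson(tsp_mean)) + 1
                fsp = int(rng.binomial(tsp, pct / 100.0))
                records.append(PlantRecord(line_id, condition, plant, tsp, fsp))
    return records


def _check_planted_sites(targets: SimulatedTargets) -> None:
    """Sanity check used by tests: planted sites really are the reverse
    complement of their miRNA up to the planted mismatches."""
    seqs = dict(targets.mirna_records)
    tx = dict(targets.transcript_records)
    for _, row in targets.truth_pairs.iterrows():
        mir = _to_rna(seqs[row["mirna_id"]])
        site = tx[row["gene_id"]][row["site_start"] : row["site_start"] + len(mir)]
        diff = sum(a != b for a, b in zip(site, _revcomp_rna(mir)))
        if diff != row["n_mismatches"]:
            raise SimulationError(
                f"planted site for {row['mirna_id']} has {diff} mismatches, "
                f"expected {row['n_mismatches']}"
            )
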