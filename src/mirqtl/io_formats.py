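"""Readers, writers and validated in-memory containers for every external file
the pipeline touches.

All downstream modules operate on the domain types defined here
(:class:`CountMatrix`, :class:`MarkerMap`, :class:`GenotypeMatrix`,
:class:`PlantRecord`, :class:`GeneModel`); file parsing happens only in this
module and fails loudly rather than coercing silently.

Coordinate convention
---------------------
Genomic intervals are stored 0-based, half-open, in **megabases** (float),
matching the megabase segment lengths used in SSSL QTL tables.  Converters
from GFF3 (1-based, closed) and BED (0-based, half-open, bp) are provided and
are exact inverses of each other up to one base of rounding.  Gene annotations
are treated as authoritative for their own coordinate system; this module only
converts representation, never lifts over.

All tabular files are tab-separated UTF-8 with a mandatory header row; lines
starting with ``#`` are comments.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_TREATMENTS = frozenset({"control", "heat"})
CANONICAL_TIMEPOINTS = (1, 6, 24)


class MirqtlError(Exception):
    """Base class for all pipeline errors."""


class TableFormatError(MirqtlError):
    """A file's structure or a cell's value violates the expected format."""


class MetadataError(MirqtlError):
    """A library is missing from, or inconsistent with, its metadata table."""


class SegmentViolationError(MirqtlError):
    """An SSSL graphical genotype does not carry exactly one donor segment."""


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

BP_PER_MB = 1_000_000


def bed_to_internal(start_bp: int, end_bp: int) -> tuple[float, float]:
    """BED (0-based half-open, bp) -> internal (0-based half-open, Mb)."""
    return start_bp / BP_PER_MB, end_bp / BP_PER_MB


def gff3_to_internal(start_1based: int, end_1based: int) -> tuple[float, float]:
    """GFF3 (1-based closed, bp) -> internal (0-based half-open, Mb)."""
    return (start_1based - 1) / BP_PER_MB, end_1based / BP_PER_MB


def internal_to_bed(start_mb: float, end_mb: float) -> tuple[int, int]:
    return round(start_mb * BP_PER_MB), round(end_mb * BP_PER_MB)


def internal_to_gff3(start_mb: float, end_mb: float) -> tuple[int, int]:
    return round(start_mb * BP_PER_MB) + 1, round(end_mb * BP_PER_MB)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryMeta:
    """Per-library annotation: which genotype/treatment/time point it profiles.

    ``total_reads``, when given, is the total sequenced reads of the library
    and may be used for TPM normalisation instead of the matrix column sum.
    """

    genotype: str
    treatment: str  # "control" | "heat"
    timepoint_hours: int
    total_reads: int | None = None

    def __post_init__(self) -> None:
        if self.treatment not in VALID_TREATMENTS:
            raise MetadataError(
                f"treatment must be one of {sorted(VALID_TREATMENTS)}, "
                f"got {self.treatment!r}"
            )
        if int(self.timepoint_hours) <= 0:
            raise MetadataError(f"timepoint_hours must be positive, got {self.timepoint_hours}")


@dataclass
class CountMatrix:
    """miRNA x library raw read counts with complete library metadata.

    Invariants (checked by :meth:`validate`): counts are non-negative
    integers; library ids unique; every library has metadata; every
    (genotype, timepoint) group present carries both a control and a heat
    library, so each contrast is well defined.
    """

    mirna_ids: list[str]
    library_ids: list[str]
    counts: np.ndarray
    library_meta: dict[str, LibraryMeta]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if self.counts.shape != (len(self.mirna_ids), len(self.library_ids)):
            raise TableFormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.library_ids)} libraries"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise TableFormatError("counts must be integers")
        if (self.counts < 0).any():
            raise TableFormatError("counts must be non-negative")
        if len(set(self.library_ids)) != len(self.library_ids):
            raise TableFormatError("library ids are not unique")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise TableFormatError("miRNA ids are not unique")
        missing = [lib for lib in self.library_ids if lib not in self.library_meta]
        if missing:
            raise MetadataError(f"libraries without metadata: {missing}")
        groups: dict[tuple[str, int], set[str]] = {}
        for lib in self.library_ids:
            m = self.library_meta[lib]
            groups.setdefault((m.genotype, m.timepoint_hours), set()).add(m.treatment)
        incomplete = sorted(k for k, v in groups.items() if v != VALID_TREATMENTS)
        if incomplete:
            raise MetadataError(
                "every (genotype, timepoint) needs one control and one heat "
                f"library; incomplete groups: {incomplete}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column(self, library_id: str) -> np.ndarray:
        return self.counts[:, self.library_ids.index(library_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.mirna_ids, columns=self.library_ids)


@dataclass
class MarkerMap:
    """Ordered molecular markers with Mb positions plus chromosome lengths.

    ``chromosome_end`` maps each chromosome label to its end coordinate in Mb;
    when a map file carries no explicit ends the last marker position is used
    (terminal segment extension then adds nothing).
    """

    marker_ids: list[str]
    chromosomes: list[str]
    positions_mb: np.ndarray
    chromosome_end: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions_mb = np.asarray(self.positions_mb, dtype=float)
        if not (len(self.marker_ids) == len(self.chromosomes) == len(self.positions_mb)):
            raise TableFormatError("marker map columns have unequal lengths")
        if (self.positions_mb < 0).any():
            raise TableFormatError("marker positions must be non-negative")
        for chrom in dict.fromkeys(self.chromosomes):
            pos = self.chrom_positions(chrom)
            if not np.all(np.diff(pos) > 0):
                raise TableFormatError(
                    f"marker positions on chromosome {chrom!r} are not strictly increasing"
                )
            end = self.chromosome_end.setdefault(chrom, float(pos[-1]))
            if pos[-1] > end:
                raise TableFormatError(
                    f"marker beyond chromosome end on {chrom!r}: {pos[-1]} > {end}"
                )

    def chrom_indices(self, chrom: str) -> list[int]:
        return [i for i, c in enumerate(self.chromosomes) if c == chrom]

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.positions_mb[self.chrom_indices(chrom)]

    def chrom_markers(self, chrom: str) -> list[str]:
        return [self.marker_ids[i] for i in self.chrom_indices(chrom)]


GENOTYPE_CODES = frozenset({"D", "R"})


@dataclass
class GenotypeMatrix:
    """Graphical genotypes of an SSSL panel: one D/R code per line x marker.

    Marker order matches the :class:`MarkerMap` the matrix was read with.
    Each line must carry at most one maximal run of donor (D) codes, confined
    to a single chromosome; the all-R line is the recurrent parent.
    """

    line_ids: list[str]
    codes: np.ndarray  # dtype '<U1', shape (n_lines, n_markers)
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.shape != (len(self.line_ids), len(self.markers.marker_ids)):
            raise TableFormatError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.markers.marker_ids)} markers"
            )
        bad = sorted(set(self.codes.ravel()) - GENOTYPE_CODES)
        if bad:
            hint = " ('H' heterozygous codes are rejected: SSSLs are fixed lines)" if "H" in bad else ""
            raise TableFormatError(f"unknown genotype codes {bad}{hint}")
        for line, row in zip(self.line_ids, self.codes):
            self._check_single_segment(line, row)

    def _check_single_segment(self, line: str, row: np.ndarray) -> None:
        donor_idx = np.flatnonzero(row == "D")
        if donor_idx.size == 0:
            return  # recurrent parent
        chroms = {self.markers.chromosomes[i] for i in donor_idx}
        if len(chroms) > 1:
            raise SegmentViolationError(
                f"line {line!r} carries donor markers on multiple chromosomes: {sorted(chroms)}"
            )
        chrom_idx = self.markers.chrom_indices(chroms.pop())
        in_run = [i for i in chrom_idx if row[i] == "D"]
        first, last = in_run[0], in_run[-1]
        expected = [i for i in chrom_idx if first <= i <= last]
        if in_run != expected:
            raise SegmentViolationError(
                f"line {line!r} has more than one donor run (single-segment violation)"
            )

    def row(self, line_id: str) -> np.ndarray:
        return self.codes[self.line_ids.index(line_id)]


@dataclass(frozen=True)
class PlantRecord:
    """Spikelet counts of one plant: TSP total, FSP filled."""

    line_id: str
    condition: str  # "control" | "heat"
    plant: int
    tsp: int
    fsp: int

    def __post_init__(self) -> None:
        if self.condition not in VALID_TREATMENTS:
            raise TableFormatError(
                f"condition must be one of {sorted(VALID_TREATMENTS)}, got {self.condition!r}"
            )
        if self.tsp <= 0:
            raise TableFormatError(
                f"plant {self.plant} of line {self.line_id!r}: TSP must be > 0, got {self.tsp}"
            )
        if not 0 <= self.fsp <= self.tsp:
            raise TableFormatError(
                f"plant {self.plant} of line {self.line_id!r}: need 0 <= FSP <= TSP, "
                f"got FSP={self.fsp}, TSP={self.tsp}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus in internal coordinates (0-based, half-open, Mb)."""

    gene_id: str
    chromosome: str
    start_mb: float
    end_mb: float
    description: str = ""

    def __post_init__(self) -> None:
        if not self.start_mb < self.end_mb:
            raise TableFormatError(
                f"gene {self.gene_id!r}: start must be < end, got [{self.start_mb}, {self.end_mb})"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_count_table(path: str | os.PathLike, meta_path: str | os.PathLike) -> CountMatrix:
    """Read a miRNA x library count TSV plus a library metadata TSV.

    The count table's first column holds miRNA ids; remaining column headers
    are library ids.  Every cell must parse as a non-negative integer; the
    offending row and column are named otherwise.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: count table needs an id column plus >=1 library column")
    mirna_ids = df.iloc[:, 0].tolist()
    library_ids = list(df.columns[1:])
    counts = np.zeros((len(mirna_ids), len(library_ids)), dtype=np.int64)
    for j, lib in enumerate(library_ids):
        for i, raw in enumerate(df[lib]):
            try:
                counts[i, j] = int(raw)
                if counts[i, j] < 0 or str(int(raw)) != raw.strip():
                    raise ValueError
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"{path}: cell ({mirna_ids[i]!r}, {lib!r}) is not a "
                    f"non-negative integer: {raw!r}"
                ) from None
    meta = read_library_meta(meta_path)
    missing = [lib for lib in library_ids if lib not in meta]
    if missing:
        raise MetadataError(f"{meta_path}: no metadata for libraries {missing}")
    return CountMatrix(mirna_ids, library_ids, counts, meta)


def read_library_meta(path: str | os.PathLike) -> dict[str, LibraryMeta]:
    df = _read_tsv(path)
    required = {"library_id", "genotype", "treatment", "timepoint_hours"}
    if not required.issubset(df.columns):
        raise MetadataError(f"{path}: metadata needs columns {sorted(required)}")
    meta: dict[str, LibraryMeta] = {}
    for _, row in df.iterrows():
        total = row.get("total_reads", "")
        meta[row["library_id"]] = LibraryMeta(
            genotype=row["genotype"],
            treatment=row["treatment"],
            timepoint_hours=int(row["timepoint_hours"]),
            total_reads=int(total) if str(total).strip() else None,
        )
    return meta


def write_count_table(cm: CountMatrix, path: str | os.PathLike, meta_path: str | os.PathLike) -> None:
    frame = cm.to_frame()
    frame.index.name = "mirna_id"
    frame.to_csv(path, sep="\t")
    rows = []
    for lib in cm.library_ids:
        m = cm.library_meta[lib]
        rows.append(
            {
                "library_id": lib,
                "genotype": m.genotype,
                "treatment": m.treatment,
                "timepoint_hours": m.timepoint_hours,
                "total_reads": "" if m.total_reads is None else m.total_reads,
            }
        )
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def read_genotypes(
    map_path: str | os.PathLike, geno_path: str | os.PathLike
) -> tuple[MarkerMap, GenotypeMatrix]:
    """Read a marker map (marker, chrom, pos_mb[, chrom_end_mb]) and a
    line x marker D/R genotype table, cross-validated against each other."""
    mdf = _read_tsv(map_path)
    required = {"marker_id", "chromosome", "pos_mb"}
    if not required.issubset(mdf.columns):
        raise TableFormatError(f"{map_path}: marker map needs columns {sorted(required)}")
    ends: dict[str, float] = {}
    if "chrom_end_mb" in mdf.columns:
        for chrom, end in zip(mdf["chromosome"], mdf["chrom_end_mb"]):
            if str(end).strip():
                ends[chrom] = float(end)
    markers = MarkerMap(
        marker_ids=mdf["marker_id"].tolist(),
        chromosomes=mdf["chromosome"].tolist(),
        positions_mb=mdf["pos_mb"].astype(float).to_numpy(),
        chromosome_end=ends,
    )
    gdf = _read_tsv(geno_path)
    if gdf.columns[0] != "line_id":
        raise TableFormatError(f"{geno_path}: first column must be 'line_id'")
    marker_cols = list(gdf.columns[1:])
    if marker_cols != markers.marker_ids:
        raise TableFormatError(
            f"{geno_path}: genotype marker columns do not match the marker map order"
        )
    geno = GenotypeMatrix(
        line_ids=gdf["line_id"].tolist(),
        codes=gdf[marker_cols].to_numpy(dtype="<U1"),
        markers=markers,
    )
    return markers, geno


def write_genotypes(
    markers: MarkerMap, geno: GenotypeMatrix, map_path: str | os.PathLike, geno_path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {
            "marker_id": markers.marker_ids,
            "chromosome": markers.chromosomes,
            "pos_mb": markers.positions_mb,
            "chrom_end_mb": [markers.chromosome_end[c] for c in markers.chromosomes],
        }
    ).to_csv(map_path, sep="\t", index=False)
    gdf = pd.DataFrame(geno.codes, index=geno.line_ids, columns=markers.marker_ids)
    gdf.index.name = "line_id"
    gdf.to_csv(geno_path, sep="\t")


def read_plant_records(path: str | os.PathLike) -> list[PlantRecord]:
    """Read per-plant spikelet counts (line_id, condition, plant, TSP, FSP)."""
    df = _read_tsv(path)
    required = {"line_id", "condition", "plant", "TSP", "FSP"}
    if not required.issubset(df.columns):
        raise TableFormatError(f"{path}: plant table needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        try:
            tsp, fsp, plant = int(row["TSP"]), int(row["FSP"]), int(row["plant"])
        except ValueError:
            raise TableFormatError(
                f"{path}: non-integer TSP/FSP/plant for line {row['line_id']!r}"
            ) from None
        records.append(PlantRecord(row["line_id"], row["condition"], plant, tsp, fsp))
    return records


def write_plant_records(records: list[PlantRecord], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {"line_id": r.line_id, "condition": r.condition, "plant": r.plant, "TSP": r.tsp, "FSP": r.fsp}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene loci from BED (4+ columns) or GFF3, converting to internal
    0-based half-open Mb coordinates.

    BED input is taken as 0-based half-open; GFF3 as 1-based closed.  The
    annotation is treated as authoritative for its own assembly; no liftover.
    """
    name = str(path).lower()
    if name.endswith((".bed",)):
        genes = _read_bed(path)
    elif name.endswith((".gff", ".gff3")):
        genes = _read_gff3(path)
    else:
        raise TableFormatError(
            f"{path}: unknown gene-model extension (expected .bed, .gff or .gff3)"
        )
    if not genes:
        logger.warning("%s: no gene models found", path)
    return genes


def _read_bed(path: str | os.PathLike) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TableFormatError(f"{path}:{ln}: BED gene line needs >= 4 columns")
            chrom, start, end, gene_id = fields[:4]
            start_mb, end_mb = bed_to_internal(int(start), int(end))
            desc = fields[6] if len(fields) > 6 else ""
            genes.append(GeneModel(gene_id, chrom, start_mb, end_mb, desc))
    return genes


def _read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        start_mb, end_mb = gff3_to_internal(feat.start, feat.end)
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        desc = ";".join(
            feat.attributes.get("description", feat.attributes.get("Note", []))
        )
        genes.append(GeneModel(gene_id, feat.seqid, start_mb, end_mb, desc))
    return genes


def write_gene_models_bed(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            start, end = internal_to_bed(g.start_mb, g.end_mb)
            fh.write(f"{g.chromosome}\t{start}\t{end}\t{g.gene_id}\t.\t+\t{g.description}\n")
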