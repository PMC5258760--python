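"""Plant-style miRNA-target complementarity scoring.

Plant miRNAs direct cleavage of near-perfectly complementary sites, so
target prediction reduces to scanning transcripts for windows whose
antisense pairing to the miRNA accumulates a small penalty.  The scheme here
is a reconstruction of the conventions shared by the widely used plant
predictors (penalty points per mismatch/G:U/gap, doubled inside the 5'
seed, a reporting ceiling of a few points, gaps forbidden in the 5' half):
mismatch 1.0, G:U wobble 0.5, gap 2.0, penalties x2 within miRNA positions
2-13, sites reported at score <= 3.0 (strict mode <= 2.0), and at most one
gap, only 3' of miRNA position 10.  Scores are scheme-dependent and are
labelled as such in outputs; a score of 0 is a perfect, gap-free antisense
match.

Alignment geometry: the miRNA is written 5'->3' and pairs the target site
3'->5', i.e. miRNA position 1 pairs the 3'-most base of the site.  The
predicted cleavage position is the transcript coordinate pairing miRNA
position 11 — slicing occurs between the bases opposite miRNA positions 10
and 11.  T and U are equivalent on input; internally the alphabet is RNA.

A gap column (one bulged target base, or one unpaired miRNA base) is
weighted by the miRNA position it sits at: the unpaired miRNA position
itself, or for a target bulge the position immediately 3' of the insertion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import MirqtlError

logger = logging.getLogger(__name__)

MATCH, WOBBLE, MISMATCH, GAP = "match", "wobble", "mismatch", "gap"
_STATES = {MATCH, WOBBLE, MISMATCH, GAP}

_BASES = "ACGU"
_IDX = {b: i for i, b in enumerate(_BASES)}
# pair class of (miRNA base, target base): 0 match, 1 wobble, 2 mismatch
_PAIR_CLASS = np.full((4, 4), 2, dtype=np.int8)
for _m, _t in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PAIR_CLASS[_IDX[_m], _IDX[_t]] = 0
for _m, _t in (("G", "U"), ("U", "G")):
    _PAIR_CLASS[_IDX[_m], _IDX[_t]] = 1
_STATE_OF_CLASS = {0: MATCH, 1: WOBBLE, 2: MISMATCH}

_CODE = np.zeros(128, dtype=np.int8)
for _b, _i in _IDX.items():
    _CODE[ord(_b)] = _i


class ScoringError(MirqtlError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Penalty parameters; all penalties >= 0, seed positions 1-based from
    the miRNA 5' end."""

    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    gap_penalty: float = 2.0
    seed_range: tuple[int, int] = (2, 13)
    seed_multiplier: float = 2.0
    max_score: float = 3.0
    gap_position_limit: int = 10  # no gaps at or before this miRNA position

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.wobble_penalty, self.gap_penalty) < 0:
            raise ScoringError("penalties must be >= 0")
        if self.seed_range[0] < 1 or self.seed_range[0] > self.seed_range[1]:
            raise ScoringError(f"invalid seed range {self.seed_range}")

    def in_seed(self, position: int) -> bool:
        return self.seed_range[0] <= position <= self.seed_range[1]

    def penalty(self, state: str, position: int) -> float:
        if state not in _STATES:
            raise ScoringError(f"unknown alignment state {state!r}")
        base = {
            MATCH: 0.0,
            WOBBLE: self.wobble_penalty,
            MISMATCH: self.mismatch_penalty,
            GAP: self.gap_penalty,
        }[state]
        return base * (self.seed_multiplier if self.in_seed(position) else 1.0)


STRICT_MAX_SCORE = 2.0


@dataclass(frozen=True)
class AlignmentColumn:
    """One pairing column: miRNA position (1-based, None for a target bulge),
    transcript position (0-based, None for a miRNA bulge) and state."""

    mirna_pos: int | None
    target_pos: int | None
    state: str


@dataclass
class TargetAlignment:
    mirna_id: str
    gene_id: str
    score: float
    site_start: int  # transcript nt, 0-based half-open
    site_end: int
    columns: list[AlignmentColumn] = field(default_factory=list)
    mirna_seq: str = ""
    site_seq: str = ""


def _to_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set(_BASES)
    if bad:
        raise ScoringError(f"sequence contains non-ACGU/T characters: {sorted(bad)}")
    return seq


def _codes(seq_rna: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq_rna.encode(), dtype=np.uint8)]


def complementarity_score(alignment_states, scheme: ScoringScheme) -> float:
    """Sum per-column penalties under the scheme.

    ``alignment_states`` is an iterable of (mirna_position, state) pairs or
    :class:`AlignmentColumn` objects covering every miRNA position.  A gap
    column whose miRNA position is None (target bulge) is weighted by the
    miRNA position immediately 3' of the insertion.
    """
    total = 0.0
    prev_pos = 0
    for col in alignment_states:
        if isinstance(col, AlignmentColumn):
            pos, state = col.mirna_pos, col.state
        else:
            pos, state = col
        if pos is None:
            pos = prev_pos + 1
        else:
            prev_pos = int(pos)
        total += scheme.penalty(state, int(pos))
    return total


@dataclass(frozen=True)
class _GapSpec:
    kind: str  # "none" | "target_bulge" | "mirna_bulge"
    gap_pos: int = 0  # miRNA position at/3'-adjacent to the gap (1-based)

    def site_len(self, mir_len: int) -> int:
        return mir_len + {"none": 0, "target_bulge": 1, "mirna_bulge": -1}[self.kind]


def _gap_specs(mir_len: int, scheme: ScoringScheme):
    """All allowed gap placements: none, one bulged target base between
    miRNA positions g-1 and g, or miRNA position g unpaired; g strictly 3'
    of the gap position limit."""
    yield _GapSpec("none")
    for g in range(scheme.gap_position_limit + 1, mir_len + 1):
        yield _GapSpec("target_bulge", g)
        yield _GapSpec("mirna_bulge", g)


def _pair_offsets(mir_len: int, spec: _GapSpec) -> tuple[np.ndarray, np.ndarray]:
    """(mirna positions 1-based, transcript offset from site start) for every
    paired column of a candidate alignment."""
    L, g = mir_len, spec.gap_pos
    if spec.kind == "none":
        i = np.arange(1, L + 1)
        off = L - i
    elif spec.kind == "target_bulge":
        i = np.arange(1, L + 1)
        off = np.where(i < g, L + 1 - i, L - i)
    else:  # mirna_bulge
        i = np.concatenate([np.arange(1, g), np.arange(g + 1, L + 1)])
        off = np.where(i < g, L - 1 - i, L - i)
    return i, off


def _candidate_scores(
    mir_codes: np.ndarray, tx_codes: np.ndarray, spec: _GapSpec, scheme: ScoringScheme,
    mult: np.ndarray, penal: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised scores of one gap placement at every site start."""
    L = mir_codes.size
    site_len = spec.site_len(L)
    n = tx_codes.size - site_len + 1
    if n <= 0:
        return np.empty(0, dtype=int), np.empty(0)
    i, off = _pair_offsets(L, spec)
    starts = np.arange(n)
    classes = _PAIR_CLASS[mir_codes[i - 1][None, :], tx_codes[starts[:, None] + off[None, :]]]
    scores = (penal[classes] * mult[i - 1][None, :]).sum(axis=1)
    if spec.kind != "none":
        scores = scores + scheme.penalty(GAP, spec.gap_pos)
    return starts, scores


def _alignment_columns(
    mir_rna: str, tx_rna: str, start: int, spec: _GapSpec
) -> list[AlignmentColumn]:
    """Explicit pairing columns (5'->3' in the miRNA) for one candidate."""
    L = len(mir_rna)
    site_len = spec.site_len(L)
    i, off = _pair_offsets(L, spec)
    paired = {
        int(ii): AlignmentColumn(
            int(ii),
            start + int(oo),
            _STATE_OF_CLASS[int(_PAIR_CLASS[_IDX[mir_rna[ii - 1]], _IDX[tx_rna[start + oo]]])],
        )
        for ii, oo in zip(i, off)
    }
    cols: list[AlignmentColumn] = []
    for pos in range(1, L + 1):
        if spec.kind == "target_bulge" and pos == spec.gap_pos:
            # bulged target base sits 5' of the base pairing position gap_pos
            cols.append(AlignmentColumn(None, paired[pos].target_pos + 1, GAP))
        if spec.kind == "mirna_bulge" and pos == spec.gap_pos:
            cols.append(AlignmentColumn(pos, None, GAP))
            continue
        cols.append(paired[pos])
    assert len(cols) == L + (1 if spec.kind == "target_bulge" else 0)
    del site_len
    return cols


def score_site(
    mir_seq: str, tx_seq: str, start: int, spec: _GapSpec, scheme: ScoringScheme
) -> float:
    """Score of one explicit candidate site (used for spot checks)."""
    mir_rna, tx_rna = _to_rna(mir_seq), _to_rna(tx_seq)
    return complementarity_score(_alignment_columns(mir_rna, tx_rna, start, spec), scheme)


def predict_targets(
    mirnas, transcripts, scheme: ScoringScheme | None = None
) -> list[TargetAlignment]:
    """Exhaustively score every miRNA against every transcript window.

    ``mirnas`` and ``transcripts`` are iterables of Biopython ``SeqRecord``s
    or (id, sequence) pairs.  Returns every site with score <=
    ``scheme.max_score``, allowing at most one gap strictly 3' of the gap
    position limit (best placement per site reported), sorted by (score,
    position) within each miRNA x transcript pair.
    """
    scheme = scheme or ScoringScheme()
    mir_list = [_as_pair(r) for r in mirnas]
    tx_list = [_as_pair(r) for r in transcripts]
    if not mir_list or not tx_list:
        logger.warning("empty miRNA or transcript input: no targets predicted")
        return []

    penal = np.array([0.0, scheme.wobble_penalty, scheme.mismatch_penalty])
    hits: list[TargetAlignment] = []
    for mir_id, mir_seq in mir_list:
        mir_rna = _to_rna(mir_seq)
        L = len(mir_rna)
        mir_codes = _codes(mir_rna)
        mult = np.array(
            [scheme.seed_multiplier if scheme.in_seed(i) else 1.0 for i in range(1, L + 1)]
        )
        specs = list(_gap_specs(L, scheme))
        for tx_id, tx_seq in tx_list:
            tx_rna = _to_rna(tx_seq)
            tx_codes = _codes(tx_rna)
            # best candidate per (start, site length): a gapped alignment of a
            # window competes only against other placements of the same window
            best: dict[tuple[int, int], tuple[float, _GapSpec]] = {}
            for spec in specs:
                starts, scores = _candidate_scores(
                    mir_codes, tx_codes, spec, scheme, mult, penal
                )
                ok = np.flatnonzero(scores <= scheme.max_score)
                site_len = spec.site_len(L)
                for s in ok:
                    key = (int(s), site_len)
                    sc = float(scores[s])
                    if key not in best or sc < best[key][0]:
                        best[key] = (sc, spec)
            per_pair = []
            for (s, site_len), (sc, spec) in best.items():
                cols = _alignment_columns(mir_rna, tx_rna, s, spec)
                per_pair.append(
                    TargetAlignment(
                        mir_id, tx_id, sc, s, s + site_len, cols, mir_rna,
                        tx_rna[s : s + site_len],
                    )
                )
            per_pair.sort(key=lambda h: (h.score, h.site_start, h.site_end))
            hits.extend(per_pair)
    return hits


def _as_pair(record) -> tuple[str, str]:
    if isinstance(record, tuple):
        return record[0], str(record[1])
    return record.id, str(record.seq)


def cleavage_position(hit: TargetAlignment) -> int:
    """Transcript coordinate opposite the bond between miRNA positions 10
    and 11: returns the (0-based) position pairing miRNA position 11;
    slicing occurs between it and the next position toward the site 3' end.
    """
    paired = [c for c in hit.columns if c.mirna_pos is not None and c.target_pos is not None]
    if len(paired) < 11:
        raise ScoringError("site pairs fewer than 11 miRNA positions: cleavage undefined")
    for c in hit.columns:
        if c.mirna_pos == 11:
            if c.target_pos is None:
                raise ScoringError("miRNA position 11 is unpaired: cleavage undefined")
            return c.target_pos
    raise ScoringError("alignment does not cover miRNA position 11")


def alignment_text(hit: TargetAlignment) -> str:
    """Three-line text rendering (miRNA 5'->3', pairing row, site 3'->5')."""
    mir_row, bond_row, tgt_row = [], [], []
    for c in hit.columns:
        mir_row.append(hit.mirna_seq[c.mirna_pos - 1] if c.mirna_pos else "-")
        if c.target_pos is not None:
            tgt_row.append(hit.site_seq[c.target_pos - hit.site_start])
        else:
            tgt_row.append("-")
        bond_row.append({MATCH: "|", WOBBLE: "o", MISMATCH: " ", GAP: " "}[c.state])
    return (
        f"miRNA  5' {''.join(mir_row)} 3'\n"
        f"          {''.join(bond_row)}\n"
        f"target 3' {''.join(tgt_row)} 5'  score={hit.score:g}"
    )
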