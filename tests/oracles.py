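"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (definitions, exhaustive
enumeration) and deliberately shares no code path with the package.
"""

import math

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration: sum the
    probabilities of every table with the observed margins whose point
    probability does not exceed the observed one (ties included)."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = math.comb(n, col1)

    def pmf(x: int) -> float:
        return math.comb(row1, x) * math.comb(row2, col1 - x) / denom

    p_obs = pmf(a)
    lo, hi = max(0, col1 - row2), min(row1, col1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-12))


def bh_stepup(pvals):
    """Hand step-up BH: p(i) * m / i from the largest rank down, running
    minimum, clipped at 1, returned in input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def _pair_state(mir_base: str, tgt_base: str) -> str:
    if _COMP[mir_base] == tgt_base:
        return "match"
    if (mir_base, tgt_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def naive_site_score(mirna: str, site: str, kind: str, g: int, scheme) -> float:
    """Score one candidate alignment by explicit column construction.

    ``kind`` is "none", "target_bulge" (extra target base between miRNA
    positions g-1 and g) or "mirna_bulge" (miRNA position g unpaired);
    ``site`` is the forward transcript slice of the matching length.
    """
    rsite = site[::-1]
    columns = []  # (miRNA position, state)
    L = len(mirna)
    if kind == "none":
        for i in range(1, L + 1):
            columns.append((i, _pair_state(mirna[i - 1], rsite[i - 1])))
    elif kind == "target_bulge":
        for i in range(1, g):
            columns.append((i, _pair_state(mirna[i - 1], rsite[i - 1])))
        columns.append((g, "gap"))
        for i in range(g, L + 1):
            columns.append((i, _pair_state(mirna[i - 1], rsite[i])))
    elif kind == "mirna_bulge":
        for i in range(1, g):
            columns.append((i, _pair_state(mirna[i - 1], rsite[i - 1])))
        columns.append((g, "gap"))
        for i in range(g + 1, L + 1):
            columns.append((i, _pair_state(mirna[i - 1], rsite[i - 2])))
    else:
        raise ValueError(kind)

    total = 0.0
    for pos, state in columns:
        pen = {
            "match": 0.0,
            "wobble": scheme.wobble_penalty,
            "mismatch": scheme.mismatch_penalty,
            "gap": scheme.gap_penalty,
        }[state]
        if scheme.seed_range[0] <= pos <= scheme.seed_range[1]:
            pen *= scheme.seed_multiplier
        total += pen
    return total


def naive_all_hits(mirna: str, transcript: str, scheme) -> dict:
    """Best score per (site start, site length) over all windows and all
    allowed gap placements, keeping only scores <= scheme.max_score."""
    L = len(mirna)
    combos = [("none", 0, L)]
    for g in range(scheme.gap_position_limit + 1, L + 1):
        combos.append(("target_bulge", g, L + 1))
        combos.append(("mirna_bulge", g, L - 1))
    best: dict = {}
    for kind, g, site_len in combos:
        for s in range(len(transcript) - site_len + 1):
            score = naive_site_score(mirna, transcript[s : s + site_len], kind, g, scheme)
            key = (s, site_len)
            if score <= scheme.max_score and (key not in best or score < best[key]):
                best[key] = score
    return best
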