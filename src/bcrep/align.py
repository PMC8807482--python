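"""Banded local alignment of reads against germline segments.

A Gotoh affine-gap Smith-Waterman, restricted to a diagonal band centred on the
best shared-k-mer diagonal (falling back to the full dynamic-programming matrix
when no seed exists, e.g. for short or highly divergent pairs).  The simulator
emits substitution-only repertoires, so the band is a pure speed device: on
in-model data the optimal alignment lies on a single diagonal.

Scoring (defaults): match +2, mismatch -2, gap open -6 plus gap extend -1 per
gapped base (a length-L gap scores -6 - L).  Ties inside the matrix prefer
diagonal moves; ties between candidate cells keep the first encountered in row
then band order, so results are deterministic.

Coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from numba import njit

NEG = -(1 << 29)

_CHAR_CODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CHAR_CODE[ord(_c)] = _i
    _CHAR_CODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes (A=0..T=3, anything else 4)."""
    return _CHAR_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -2
    gap_open: int = -6  # charged once per gap, on top of the per-base extend
    gap_extend: int = -1

    @property
    def first_gap(self) -> int:
        return self.gap_open + self.gap_extend


DEFAULT_SCORING = Scoring()

# traceback op codes
_OP_MATCH, _OP_SUB, _OP_INS, _OP_DEL = 0, 1, 2, 3
_OP_CHAR = {_OP_MATCH: "=", _OP_SUB: "X", _OP_INS: "I", _OP_DEL: "D"}


@njit(cache=True)
def _sw_banded(read, ref, match, mismatch, first_gap, extend, lo, hi):  # pragma: no cover
    n = read.shape[0]
    m = ref.shape[0]
    W = hi - lo + 1
    H = np.full((n + 1, W), NEG, dtype=np.int64)
    E = np.full((n + 1, W), NEG, dtype=np.int64)
    F = np.full((n + 1, W), NEG, dtype=np.int64)
    ptrH = np.zeros((n + 1, W), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = np.zeros((n + 1, W), dtype=np.uint8)  # 1 = continue in E
    ptrF = np.zeros((n + 1, W), dtype=np.uint8)
    for k in range(W):
        j = 0 + lo + k
        if 0 <= j <= m:
            H[0, k] = 0
    best = 0
    bi = -1
    bk = -1
    for i in range(1, n + 1):
        for k in range(W):
            j = i + lo + k
            if j < 0 or j > m:
                continue
            if j == 0:
                H[i, k] = 0
                continue
            # E: gap in read (consume ref base j), from (i, j-1) = (i, k-1)
            e = NEG
            if k - 1 >= 0:
                a = H[i, k - 1] + first_gap
                b = E[i, k - 1] + extend
                if b > a:
                    e = b
                    ptrE[i, k] = 1
                else:
                    e = a
                    ptrE[i, k] = 0
            E[i, k] = e
            # F: gap in ref (consume read base i), from (i-1, j) = (i-1, k+1)
            f = NEG
            if k + 1 < W:
                a = H[i - 1, k + 1] + first_gap
                b = F[i - 1, k + 1] + extend
                if b > a:
                    f = b
                    ptrF[i, k] = 1
                else:
                    f = a
                    ptrF[i, k] = 0
            F[i, k] = f
            # diagonal from (i-1, j-1) = (i-1, k)
            d = H[i - 1, k]
            if d > NEG // 2:
                ra = read[i - 1]
                rb = ref[j - 1]
                if ra == rb and ra < 4:
                    d += match
                else:
                    d += mismatch
            h = 0
            p = 0
            if d >= h:
                h = d
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            if h == 0:
                p = 0  # local alignment restarts here; traceback stops
            H[i, k] = h
            ptrH[i, k] = p
            if h > best:
                best = h
                bi = i
                bk = k
    # traceback
    max_ops = n + m + 2
    ops = np.empty(max_ops, dtype=np.int8)
    nops = 0
    sub_read = np.empty(max_ops, dtype=np.int64)
    sub_ref = np.empty(max_ops, dtype=np.int64)
    nsub = 0
    read_end = 0
    ref_end = 0
    read_start = 0
    ref_start = 0
    if bi >= 0:
        i = bi
        k = bk
        read_end = i
        ref_end = i + lo + k
        state = 0  # 0 = H, 1 = E, 2 = F
        while True:
            j = i + lo + k
            if state == 0:
                p = ptrH[i, k]
                if p == 0:
                    break
                if p == 1:
                    if read[i - 1] == ref[j - 1] and read[i - 1] < 4:
                        ops[nops] = _OP_MATCH
                    else:
                        ops[nops] = _OP_SUB
                        sub_read[nsub] = i - 1
                        sub_ref[nsub] = j - 1
                        nsub += 1
                    nops += 1
                    i -= 1
                    # k unchanged for diagonal
                elif p == 2:
                    state = 1
                else:
                    state = 2
            elif state == 1:
                ops[nops] = _OP_DEL  # ref base consumed, gap in read
                nops += 1
                cont = ptrE[i, k]
                k -= 1
                if cont == 0:
                    state = 0
            else:
                ops[nops] = _OP_INS  # read base consumed, gap in ref
                nops += 1
                cont = ptrF[i, k]
                i -= 1
                k += 1
                if cont == 0:
                    state = 0
        read_start = i
        ref_start = i + lo + k
    return (best, read_start, read_end, ref_start, ref_end,
            ops[:nops][::-1].copy(), sub_read[:nsub][::-1].copy(), sub_ref[:nsub][::-1].copy())


@dataclass
class VAlignment:
    """Local alignment of a read against one germline segment."""

    segment_name: str
    score: int
    read_interval: Tuple[int, int]
    germline_interval: Tuple[int, int]
    operations: List[Tuple[str, int]]  # run-length CIGAR-style, ops =/X/I/D
    substitution_read_positions: Tuple[int, ...]
    substitution_germline_positions: Tuple[int, ...]
    scoring: Scoring = DEFAULT_SCORING

    @property
    def aligned_length(self) -> int:
        return sum(n for _, n in self.operations)

    @property
    def n_substitutions(self) -> int:
        return len(self.substitution_read_positions)

    def recompute_score(self) -> int:
        """Score implied by the operation list (consistency check)."""
        s = 0
        for op, n in self.operations:
            if op == "=":
                s += n * self.scoring.match
            elif op == "X":
                s += n * self.scoring.mismatch
            else:
                s += self.scoring.gap_open + n * self.scoring.gap_extend
        return s

    def read_position_of(self, germline_pos: int) -> Optional[int]:
        """Project a germline coordinate onto the read through the alignment.

        Returns None if the position is unaligned or falls in a read gap.
        """
        gs, ge = self.germline_interval
        if not (gs <= germline_pos < ge):
            return None
        r = self.read_interval[0]
        g = gs
        for op, n in self.operations:
            if op in ("=", "X"):
                if g <= germline_pos < g + n:
                    return r + (germline_pos - g)
                r += n
                g += n
            elif op == "D":  # germline consumed, read gap
                if g <= germline_pos < g + n:
                    return None
                g += n
            else:  # "I": read consumed
                r += n
        return None


def _runlength(ops_raw: np.ndarray) -> List[Tuple[str, int]]:
    out: List[Tuple[str, int]] = []
    for code in ops_raw:
        ch = _OP_CHAR[int(code)]
        if out and out[-1][0] == ch:
            out[-1] = (ch, out[-1][1] + 1)
        else:
            out.append((ch, 1))
    return out


def seed_diagonal(read_codes: np.ndarray, kmer_index: Dict[bytes, list], k: int) -> Optional[int]:
    """Most-voted diagonal (ref_pos - read_pos) over shared k-mers, or None."""
    votes: Dict[int, int] = {}
    rb = read_codes.tobytes()
    for i in range(0, len(rb) - k + 1):
        hits = kmer_index.get(rb[i : i + k])
        if hits:
            for j in hits:
                d = j - i
                votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    return max(votes, key=lambda d: (votes[d], -abs(d), d))


def build_kmer_index(ref_codes: np.ndarray, k: int) -> Dict[bytes, list]:
    idx: Dict[bytes, list] = {}
    b = ref_codes.tobytes()
    for j in range(0, len(b) - k + 1):
        idx.setdefault(b[j : j + k], []).append(j)
    return idx


def align_segment(
    read,
    segment,
    scoring: Scoring = DEFAULT_SCORING,
    band: Optional[int] = 16,
    seed_k: int = 12,
    _kmer_index: Optional[Dict[bytes, list]] = None,
) -> VAlignment:
    """Align a read (str or int8 codes) to one germline segment.

    ``band`` is the half-width around the seeded diagonal; ``band=None`` (or no
    seed found) runs the full DP matrix and is exactly optimal.
    """
    read_codes = encode(read) if isinstance(read, str) else read
    if isinstance(segment, str):
        ref_codes, name = encode(segment), "?"
    else:
        ref_codes, name = encode(segment.sequence), segment.name
    n, m = len(read_codes), len(ref_codes)
    lo, hi = -n, m
    if band is not None:
        idx = _kmer_index if _kmer_index is not None else build_kmer_index(ref_codes, seed_k)
        d0 = seed_diagonal(read_codes, idx, seed_k)
        if d0 is not None:
            lo, hi = max(-n, d0 - band), min(m, d0 + band)
    score, rs, re_, gs, ge, ops_raw, sub_r, sub_g = _sw_banded(
        read_codes, ref_codes, scoring.match, scoring.mismatch,
        scoring.first_gap, scoring.gap_extend, lo, hi,
    )
    return VAlignment(
        segment_name=name,
        score=int(score),
        read_interval=(int(rs), int(re_)),
        germline_interval=(int(gs), int(ge)),
        operations=_runlength(ops_raw),
        substitution_read_positions=tuple(int(x) for x in sub_r),
        substitution_germline_positions=tuple(int(x) for x in sub_g),
        scoring=scoring,
    )
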