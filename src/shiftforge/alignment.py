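"""Global sequence alignment and percent identity.

Needleman-Wunsch with match=+1, mismatch=0, linear gap=-1.  Identity is
matched columns / total alignment columns x 100, so any gap breaks 100 %.

Among co-optimal alignments the DP maximizes (score, matches, aligned
pairs) lexicographically.  Matches pins the identity numerator; aligned
pairs pins the column count (columns = len(a) + len(b) - aligned pairs);
together they make the reported identity a function of the sequence pair
alone, hence symmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MATCH, MISMATCH, GAP = 1, 0, -1

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# composite packing: value = score * 2^20 + matches * 2^10 + aligned_pairs;
# valid while matches, aligned < 1024, i.e. sequences shorter than 1023.
_MAX_LEN = 1022
_S = 1 << 20
_M = 1 << 10


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    identity: float  # percent, 0..100
    score: int
    matches: int
    columns: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def _check(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence for {label}")
    if len(seq) > _MAX_LEN:
        raise ValueError(f"sequence {label} longer than {_MAX_LEN} residues")
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid letters in {label}: {sorted(bad)}")
    return seq


def global_align(seq_a: str, seq_b: str) -> AlignmentResult:
    """Optimal global alignment of two one-letter residue sequences."""
    seq_a = _check(seq_a, "seq_a")
    seq_b = _check(seq_b, "seq_b")
    n, m = len(seq_a), len(seq_b)
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)

    gap_step = GAP * _S
    prev = np.arange(m + 1, dtype=np.int64) * gap_step
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    for i in range(1, n + 1):
        eq = (b == a[i - 1])
        diag_step = np.where(eq, MATCH * _S + _M + 1, 1)
        diag = prev[:-1] + diag_step
        up = prev[1:] + gap_step
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = prev[0] + gap_step
        # rowwise: left-dependency forces a scan, but diag/up are vectorized
        best = np.maximum(diag, up)
        best_ptr = np.where(diag >= up, 0, 1).astype(np.uint8)
        running = cur[0]
        row_ptr = ptr[i]
        for j in range(1, m + 1):
            left = running + gap_step
            if best[j - 1] >= left:
                running = best[j - 1]
                row_ptr[j] = best_ptr[j - 1]
            else:
                running = left
                row_ptr[j] = 2
            cur[j] = running
        prev = cur

    final = int(prev[m])
    aligned_pairs = final & (_M - 1)
    matches = (final >> 10) & (_M - 1)
    score = final >> 20

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    columns = n + m - aligned_pairs
    identity = 100.0 * matches / columns
    return AlignmentResult(aligned_a, aligned_b, identity, int(score),
                           int(matches), int(columns))


def percent_identity(seq_a: str, seq_b: str) -> float:
    return global_align(seq_a, seq_b).identity


def alignment_column_map(aligned_a: str, aligned_b: str) -> dict[int, int]:
    """Map 1-based positions of a onto 1-based positions of b.

    Only columns where both sequences have a residue are mapped; this is
    what re-anchors shift lists onto structure residues across indels.
    """
    out: dict[int, int] = {}
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if ca != "-" and cb != "-":
            out[ia] = ib
    return out
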