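"""Hand-designed protein pairs with exact identity/coverage values.

Columns of the identity pairs all score positive under BLOSUM62
(identities are W; mismatches are conservative pairs like I/V, K/R, D/E,
F/Y), so the optimal local alignment is the full ungapped alignment and
the identity fraction equals the designed column count exactly.
"""

from __future__ import annotations

import random

MISMATCH_PAIRS = [("I", "V"), ("K", "R"), ("D", "E"), ("F", "Y")]

# conserved anchor motif shared by every designed pair, as true homologs
# share conserved blocks; counts toward the identical columns
ANCHOR = "WYFWH"


def identity_pair(n_identical: int, n_total: int = 100,
                  seed: int = 42) -> tuple[str, str]:
    """Two proteins whose best local alignment has exactly
    ``n_identical / n_total`` identity and coverage 1.0."""
    assert n_identical > len(ANCHOR) + 1
    rng = random.Random(seed)
    positions = list(range(len(ANCHOR) + 1, n_total - 1))
    rng.shuffle(positions)
    ident_pos = set(range(len(ANCHOR))) | {n_total - 1} | \
        set(positions[:n_identical - len(ANCHOR) - 1])
    a, b = [], []
    for i in range(n_total):
        if i < len(ANCHOR):
            a.append(ANCHOR[i])
            b.append(ANCHOR[i])
        elif i in ident_pos:
            a.append("W")
            b.append("W")
        else:
            x, y = MISMATCH_PAIRS[i % len(MISMATCH_PAIRS)]
            a.append(x)
            b.append(y)
    return "".join(a), "".join(b)


def coverage_pair(n_shared: int, n_total: int = 100) -> tuple[str, str]:
    """Two proteins of equal length whose best local alignment covers
    exactly ``n_shared / n_total`` of each, at identity 1.0."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    prefix = "".join(alphabet[i % 20] for i in range(n_shared))
    tail = n_total - n_shared
    return prefix + "W" * tail, prefix + "D" * tail
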