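"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's shift-extension algorithm: placement
equivalence is checked by literally enumerating every contiguous deletion
window and comparing the resulting mutant strings.
"""

from __future__ import annotations


def enumerate_placements(seq: str, start: int, end: int, ins: str = "") -> list[int]:
    """All start positions whose deletion (+ fixed insertion) gives the same mutant."""
    size = end - start
    mutant = seq[:start] + ins + seq[end:]
    return [
        s
        for s in range(0, len(seq) - size + 1)
        if seq[:s] + ins + seq[s + size:] == mutant
    ]


def oracle_mh_len(seq: str, start: int, end: int, ins: str = "") -> int:
    return len(enumerate_placements(seq, start, end, ins)) - 1


def oracle_canonical_start(seq: str, start: int, end: int, ins: str = "") -> int:
    return min(enumerate_placements(seq, start, end, ins))
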