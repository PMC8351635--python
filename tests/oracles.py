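"""Independent brute-force oracles used by the tests.

These deliberately share no code with the scanner: matching is done by
recursive enumeration of every gap expansion at every start position.
"""

from fesurvey.motifs import Alternation, Fixed, Gap, Wildcard
from fesurvey.proteome import STANDARD_AA


def oracle_match_from(seq: str, elements, start: int, end: int | None = None) -> bool:
    """True iff some gap expansion matches at 0-based ``start`` (ending
    exactly at 0-based-exclusive ``end`` when given)."""

    def rec(pos: int, idx: int) -> bool:
        if idx == len(elements):
            return end is None or pos == end
        if pos >= len(seq) and not (
            isinstance(elements[idx], Gap) and elements[idx].min == 0
        ):
            return False
        el = elements[idx]
        if isinstance(el, Fixed):
            return (
                seq[pos] == el.aa
                and seq[pos] in STANDARD_AA
                and rec(pos + 1, idx + 1)
            )
        if isinstance(el, Alternation):
            return (
                seq[pos] in el.residues
                and seq[pos] in STANDARD_AA
                and rec(pos + 1, idx + 1)
            )
        if isinstance(el, Wildcard):
            return rec(pos + 1, idx + 1)
        for g in range(el.min, el.max + 1):
            if pos + g > len(seq):
                break
            if rec(pos + g, idx + 1):
                return True
        return False

    return rec(start, 0)


def oracle_match_starts(seq: str, pattern) -> list[int]:
    """All 1-based match starts by exhaustive enumeration."""
    return [
        i + 1
        for i in range(len(seq))
        if oracle_match_from(seq, pattern.elements, i)
    ]


def column_identity(a: str, b: str) -> float:
    """Brute-force column-wise identity of two equal-length sequences."""
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def jaccard_pair(row_a, row_b) -> float:
    """Set-arithmetic Jaccard dissimilarity for two binary rows."""
    a = {i for i, v in enumerate(row_a) if v}
    b = {i for i, v in enumerate(row_b) if v}
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)
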