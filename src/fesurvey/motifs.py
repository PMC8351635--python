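"""Cofactor-binding motif grammar: parsing, scanning, and proteome summaries.

Motifs here are the short cysteine/glycine-anchored grammars used to flag
covalent heme *c* attachment sites (CXXCH and variants), the heme *b* pocket
signature GX(H/R)XCXGX, the siroheme cysteine cluster CX{4,5}CXnCX{3}C, and
[Fe-S] cluster ligand spacings such as the [4Fe-4S] ferredoxin pattern
CX{2}CX{2}CX{3}C.

Grammar accepted by :func:`parse_motif`:

* capital letters other than ``X`` — fixed residues;
* ``X`` — a single wildcard position;
* ``(A/B/...)`` — alternation over the listed residues;
* ``X{m}`` / ``X{m,n}`` — a bounded run of wildcards (a "gap");
* the literal token ``Xn`` — an open-length gap from the source notation,
  compiled to a configurable bounded gap (default 1..50).

Coordinates are 1-based inclusive residue spans.  Ambiguity letters
(B, Z, J, U, O, X) in a *sequence* satisfy wildcard and gap positions but
never fixed or alternation positions: an ambiguous residue should not create
a fixed-anchor hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .proteome import Proteome, STANDARD_AA

DEFAULT_GAP_BOUNDS = (1, 50)

# A fixed/alternation position only ever matches an unambiguous residue.
_CERTAIN = "".join(sorted(STANDARD_AA))


@dataclass(frozen=True)
class Fixed:
    aa: str


@dataclass(frozen=True)
class Wildcard:
    pass


@dataclass(frozen=True)
class Alternation:
    residues: frozenset[str]


@dataclass(frozen=True)
class Gap:
    min: int
    max: int


@dataclass(frozen=True)
class MotifPattern:
    """A compiled motif with length bounds and a scan-ready regex."""

    pattern_id: str
    elements: tuple
    min_len: int
    max_len: int
    cofactor_class: str | None = None
    _regex: re.Pattern = field(repr=False, compare=False, default=None)

    def render(self) -> str:
        """Render back to grammar notation (round-trip of :func:`parse_motif`)."""
        out = []
        for el in self.elements:
            if isinstance(el, Fixed):
                out.append(el.aa)
            elif isinstance(el, Wildcard):
                out.append("X")
            elif isinstance(el, Alternation):
                out.append("(" + "/".join(sorted(el.residues)) + ")")
            else:
                if el.min == el.max:
                    out.append(f"X{{{el.min}}}")
                else:
                    out.append(f"X{{{el.min},{el.max}}}")
        return "".join(out)


@dataclass(frozen=True)
class MotifMatch:
    protein_id: str
    pattern_id: str
    start: int  # 1-based inclusive
    end: int


class MotifParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _element_regex(el) -> str:
    if isinstance(el, Fixed):
        return re.escape(el.aa)
    if isinstance(el, Wildcard):
        return "[A-Z]"
    if isinstance(el, Alternation):
        return "[" + "".join(sorted(el.residues)) + "]"
    # Non-greedy: variable gaps expand to their shortest satisfying length,
    # so each start yields exactly one reported match.
    if el.min == el.max:
        return f"[A-Z]{{{el.min}}}"
    return f"[A-Z]{{{el.min},{el.max}}}?"


def _compile(elements, pattern_id, cofactor_class) -> MotifPattern:
    min_len = sum(e.min if isinstance(e, Gap) else 1 for e in elements)
    max_len = sum(e.max if isinstance(e, Gap) else 1 for e in elements)
    regex = re.compile("".join(_element_regex(e) for e in elements))
    return MotifPattern(
        pattern_id=pattern_id,
        elements=tuple(elements),
        min_len=min_len,
        max_len=max_len,
        cofactor_class=cofactor_class,
        _regex=regex,
    )


def parse_motif(
    spec: str,
    pattern_id: str | None = None,
    cofactor_class: str | None = None,
    default_gap: tuple[int, int] = DEFAULT_GAP_BOUNDS,
) -> MotifPattern:
    """Compile a motif grammar string into a :class:`MotifPattern`."""
    elements: list = []
    i, n = 0, len(spec)
    while i < n:
        ch = spec[i]
        if ch == "(":
            j = spec.find(")", i)
            if j < 0:
                raise MotifParseError("unterminated alternation", i + 1)
            body = spec[i + 1 : j]
            residues = body.split("/")
            if not body or any(len(r) != 1 or not r.isupper() for r in residues):
                raise MotifParseError(f"malformed alternation ({body!r})", i + 1)
            elements.append(Alternation(frozenset(residues)))
            i = j + 1
        elif ch == "X":
            if i + 1 < n and spec[i + 1] == "{":
                j = spec.find("}", i)
                if j < 0:
                    raise MotifParseError("unterminated gap bound", i + 2)
                body = spec[i + 2 : j]
                m = re.fullmatch(r"(\d+)(?:,(\d+))?", body)
                if not m:
                    raise MotifParseError(f"malformed gap bound ({body!r})", i + 2)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                if hi < lo:
                    raise MotifParseError("gap max below gap min", i + 2)
                elements.append(Gap(lo, hi))
                i = j + 1
            elif i + 1 < n and spec[i + 1] == "n":
                elements.append(Gap(*default_gap))
                i += 2
            else:
                elements.append(Wildcard())
                i += 1
        elif ch.isupper() and ch.isalpha():
            elements.append(Fixed(ch))
            i += 1
        else:
            raise MotifParseError(f"unexpected character {ch!r}", i + 1)
    if not elements:
        raise MotifParseError("empty motif", 1)
    return _compile(elements, pattern_id or spec, cofactor_class)


_LOOKAHEAD_CACHE: dict[str, re.Pattern] = {}


def _certain_positions_ok(segment: str, pattern: MotifPattern) -> bool:
    # Reject matches where an ambiguity letter landed on a fixed or
    # alternation position.
    pos = 0
    for el in pattern.elements:
        if isinstance(el, Fixed) or isinstance(el, Alternation):
            if segment[pos] not in STANDARD_AA:
                return False
            pos += 1
        elif isinstance(el, Wildcard):
            pos += 1
        else:
            # variable gap — recompute its realised length lazily below
            return _backtrack_certain(segment, pattern.elements)
    return True


def _backtrack_certain(segment: str, elements) -> bool:
    """Check fixed/alternation positions for the shortest-gap expansion."""

    def rec(pos: int, idx: int) -> bool:
        if idx == len(elements):
            return pos == len(segment)
        el = elements[idx]
        if isinstance(el, Fixed):
            return (
                pos < len(segment)
                and segment[pos] == el.aa
                and segment[pos] in STANDARD_AA
                and rec(pos + 1, idx + 1)
            )
        if isinstance(el, Alternation):
            return (
                pos < len(segment)
                and segment[pos] in el.residues
                and segment[pos] in STANDARD_AA
                and rec(pos + 1, idx + 1)
            )
        if isinstance(el, Wildcard):
            return pos < len(segment) and rec(pos + 1, idx + 1)
        for g in range(el.min, el.max + 1):
            if pos + g <= len(segment) and rec(pos + g, idx + 1):
                return True
        return False

    return rec(0, 0)


def scan_protein(sequence: str, pattern: MotifPattern, protein_id: str = "") -> list[MotifMatch]:
    """Report every match start of ``pattern`` in ``sequence``.

    Overlapping matches at distinct starts are all reported; variable gaps
    expand to their shortest satisfying lengths, so each start contributes at
    most one match.
    """
    matches: list[MotifMatch] = []
    if not sequence:
        return matches
    core = pattern._regex.pattern
    lookahead = _LOOKAHEAD_CACHE.get(core)
    if lookahead is None:
        lookahead = re.compile(f"(?=({core}))")
        _LOOKAHEAD_CACHE[core] = lookahead
    for m in lookahead.finditer(sequence):
        segment = m.group(1)
        if not _certain_positions_ok(segment, pattern):
            continue
        start = m.start() + 1
        matches.append(
            MotifMatch(protein_id, pattern.pattern_id, start, start + len(segment) - 1)
        )
    return matches


@dataclass
class MotifHitTable:
    """Per-proteome motif scan result.

    ``protein_counts`` counts *distinct proteins* with at least one match per
    pattern — a protein with three CXXCH matches contributes one, matching how
    genome tables count motif-bearing proteins.  ``annotations`` carries
    companion flags: CX{15}CH / CXXCK hits are flagged when the same protein
    also holds a CXXCH (such hits co-occur with a canonical motif), and CPV
    hits are flagged as CcmB-associated (the heme exporter subunit B carries
    this motif).
    """

    genome_id: str
    matches: list[MotifMatch]
    protein_counts: dict[str, int]
    annotations: dict[tuple[str, str], str] = field(default_factory=dict)


_COMPANION_PATTERNS = {"CX{15}CH", "CXXCK"}


def scan_proteome(proteome: Proteome, library: list[MotifPattern]) -> MotifHitTable:
    """Scan every protein of a proteome against a motif library."""
    if not library:
        raise ValueError("motif library must be non-empty")
    seen_ids = set()
    for rec in proteome:
        if rec.protein_id in seen_ids:
            raise ValueError(f"duplicate protein id {rec.protein_id!r}")
        seen_ids.add(rec.protein_id)

    all_matches: list[MotifMatch] = []
    proteins_by_pattern: dict[str, set[str]] = {p.pattern_id: set() for p in library}
    for rec in proteome:
        per_protein: dict[str, list[MotifMatch]] = {}
        for pat in library:
            hits = scan_protein(rec.sequence, pat, rec.protein_id)
            if hits:
                per_protein[pat.pattern_id] = hits
                proteins_by_pattern[pat.pattern_id].add(rec.protein_id)
                all_matches.extend(hits)
    table = MotifHitTable(
        genome_id=proteome.genome_id,
        matches=all_matches,
        protein_counts={
            pid: len(prots) for pid, prots in proteins_by_pattern.items()
        },
    )
    matched = {}
    for m in all_matches:
        matched.setdefault(m.protein_id, set()).add(m.pattern_id)
    for pid, pats in matched.items():
        for pat in pats & _COMPANION_PATTERNS:
            if "CXXCH" in pats:
                table.annotations[(pid, pat)] = "companion_CXXCH"
        if "CPV" in pats:
            table.annotations[(pid, "CPV")] = "CcmB_associated"
    return table


def fes_fraction(proteome: Proteome, fes_library: list[MotifPattern]) -> float:
    """Fraction of proteins predicted to bind an [Fe-S] cluster.

    Defined as (proteins with at least one [Fe-S] motif) / (total proteins);
    the per-genome quantity averaged per taxonomic group in survey tables.
    """
    if len(proteome) == 0:
        raise ValueError("fes_fraction undefined for an empty proteome")
    bearing = 0
    for rec in proteome:
        if any(scan_protein(rec.sequence, pat) for pat in fes_library):
            bearing += 1
    return bearing / len(proteome)


def verify_required_motif(sequence: str, required: list[MotifPattern]) -> bool:
    """True iff every required pattern matches at least once (vacuously true)."""
    return all(scan_protein(sequence, pat) for pat in required)


def default_motif_library(
    gap_max: int = DEFAULT_GAP_BOUNDS[1], include_msms: bool = False
) -> list[MotifPattern]:
    """The survey's motif library.

    Heme *c*: CXXCH (canonical), CPV, CX{15}CH, CXXCK.  Heme *b*:
    GX(H/R)XCXGX.  Siroheme: CX{4,5}CXnCX{3}C (shared with a [4Fe-4S]
    center).  [Fe-S]: the [4Fe-4S] ferredoxin spacing plus the siroheme-type
    cysteine cluster.  The open-length siroheme gap is bounded at ``gap_max``.
    The optional CXXXAH pattern covers the MsmS single-cysteine heme ligation
    and is off by default.
    """
    gap = (DEFAULT_GAP_BOUNDS[0], gap_max)
    lib = [
        parse_motif("CXXCH", "CXXCH", "heme_c"),
        parse_motif("CPV", "CPV", "heme_c"),
        parse_motif("CX{15}CH", "CX{15}CH", "heme_c"),
        parse_motif("CXXCK", "CXXCK", "heme_c"),
        parse_motif("GX(H/R)XCXGX", "GX(H/R)XCXGX", "heme_b"),
        parse_motif("CX{4,5}CXnCX{3}C", "siroheme_cluster", "siroheme", default_gap=gap),
        parse_motif("CX{2}CX{2}CX{3}C", "ferredoxin_4Fe4S", "fes"),
        parse_motif("CX{4,5}CXnCX{3}C", "fes_cluster", "fes", default_gap=gap),
    ]
    if include_msms:
        lib.append(parse_motif("CXXXAH", "CXXXAH", "heme_c"))
    return lib


def fes_patterns(library: list[MotifPattern]) -> list[MotifPattern]:
    return [p for p in library if p.cofactor_class == "fes"]
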