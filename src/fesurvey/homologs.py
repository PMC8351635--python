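"""Tiered homolog classification of protein similarity-search hits.

The decision procedure mirrors conservative comparative-genomics screening:
hits first pass an E-value screen (default 1e-5), then a query-coverage
screen (>30%).  Hits with >=30% identity are accepted outright; hits in the
20-30% identity "rescue band" are kept only with independent domain evidence
(a COG/Pfam-style assignment, abstracted here as a pluggable boolean
provider).  Stringent targets (siroheme-destination sulfite/nitrite
reductases) use an override policy of E<=1e-30 with 50% identity and 50%
coverage and no rescue band.  Gene synteny can upgrade partial hits whose
operon neighbours are confidently present.

Hits may come from external BLAST tabular (outfmt 6) files via
:func:`parse_hit_table` or from the built-in desk-scale Smith-Waterman
backend (:func:`pairwise_search`, Biopython ``PairwiseAligner`` with
BLOSUM62); both flow through identical classification logic.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .motifs import MotifPattern, verify_required_motif
from .proteome import Proteome

# Gapped Karlin-Altschul constants for BLOSUM62, gap open 11 / extend 1.
# The built-in backend's E-values are approximate and documented as such;
# classification depends only on relative separations, never on these
# absolute values.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class AcceptancePolicy:
    """Thresholds of the tiered screen.

    ``rescue_band`` is the half-open identity interval [low, high) in which a
    hit may be kept with domain evidence; ``None`` disables rescue (used for
    the stringent siroheme-destination screen).
    """

    e_max: float = 1.0e-5
    identity_min: float = 30.0
    coverage_min: float = 30.0
    rescue_band: tuple[float, float] | None = (20.0, 30.0)
    require_domain_for_rescue: bool = True

    def __post_init__(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if self.rescue_band is not None:
            lo, hi = self.rescue_band
            if not (0 <= lo < hi <= self.identity_min):
                raise ValueError(
                    "rescue band must satisfy 0 <= low < high <= identity_min"
                )


#: Stringent screen for siroheme-destination proteins (Dsr/Fsr/aSir/NasD).
SIROHEME_POLICY = AcceptancePolicy(
    e_max=1.0e-30, identity_min=50.0, coverage_min=50.0, rescue_band=None
)


@dataclass(frozen=True)
class QueryFamily:
    """A query gene family: seeds, thresholds, required motifs, operon."""

    family_name: str
    seed_sequences: tuple[str, ...]
    policy_override: AcceptancePolicy | None = None
    required_motifs: tuple[MotifPattern, ...] = ()
    operon: str | None = None

    def __post_init__(self) -> None:
        if not self.seed_sequences:
            raise ValueError(f"family {self.family_name} needs >=1 seed sequence")

    def policy(self, default: AcceptancePolicy) -> AcceptancePolicy:
        return self.policy_override or default


@dataclass(frozen=True)
class HitRecord:
    family_name: str
    genome_id: str
    subject_protein_id: str
    e_value: float
    bit_score: float
    percent_identity: float
    percent_query_coverage: float
    query_length: int
    subject_locus: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent_identity out of [0, 100]")
        if not (0 <= self.percent_query_coverage <= 100):
            raise ValueError("percent_query_coverage out of [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


ACCEPTED = "accepted"
RESCUED = "rescued"
REJECTED = "rejected"

REASON_OK = "ok"
REASON_EVALUE = "evalue"
REASON_IDENTITY = "identity"
REASON_COVERAGE = "coverage"
REASON_NO_DOMAIN = "no_domain_evidence"
REASON_MOTIF = "motif_failed"


@dataclass(frozen=True)
class HomologCall:
    hit: HitRecord
    status: str
    reason: str
    synteny_support: bool = False

    def __post_init__(self) -> None:
        if (self.status == REJECTED) != (self.reason != REASON_OK):
            raise ValueError("status=rejected iff reason != ok")


def parse_hit_table(
    source,
    query_lengths: dict[str, int],
    genome_id: str | None = None,
) -> list[HitRecord]:
    """Read 12-column BLAST outfmt-6 rows into :class:`HitRecord` objects.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  qseqid must name a known query family; query
    coverage is computed as 100*(qend-qstart+1)/query_length.  Subject ids of
    the form ``genome|protein|locus`` are split; otherwise ``genome_id`` is
    used and the locus defaults to 0.
    """
    if hasattr(source, "read"):
        handle = source
        close = False
    elif hasattr(source, "__fspath__") or (
        isinstance(source, str) and "\n" not in source and "\t" not in source
    ):
        handle = open(source)
        close = True
    else:
        handle = io.StringIO(source)
        close = False
    records: list[HitRecord] = []
    errors: list[str] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                errors.append(f"line {lineno}: expected 12 columns, got {len(fields)}")
                continue
            qseqid, sseqid = fields[0], fields[1]
            if qseqid not in query_lengths:
                raise ValueError(f"line {lineno}: unknown query id {qseqid!r}")
            try:
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric field ({exc})") from exc
            qlen = query_lengths[qseqid]
            coverage = 100.0 * (qend - qstart + 1) / qlen
            parts = sseqid.split("|")
            if len(parts) == 3:
                gid, pid, locus = parts[0], parts[1], int(parts[2])
            else:
                gid, pid, locus = genome_id or "unknown", sseqid, 0
            records.append(
                HitRecord(
                    family_name=qseqid,
                    genome_id=gid,
                    subject_protein_id=pid,
                    e_value=evalue,
                    bit_score=bitscore,
                    percent_identity=pident,
                    percent_query_coverage=min(coverage, 100.0),
                    query_length=qlen,
                    subject_locus=locus,
                )
            )
    finally:
        if close:
            handle.close()
    if errors:
        raise ValueError("malformed hit table rows: " + "; ".join(errors))
    return records


def write_hit_table(records: list[HitRecord], path) -> None:
    """Write records back in the outfmt-6 dialect (round-trip of the reader)."""
    with open(path, "w") as out:
        for r in records:
            qend = round(r.percent_query_coverage * r.query_length / 100.0)
            sseqid = f"{r.genome_id}|{r.subject_protein_id}|{r.subject_locus}"
            out.write(
                "\t".join(
                    [
                        r.family_name,
                        sseqid,
                        f"{r.percent_identity:.3f}",
                        str(qend),
                        "0",
                        "0",
                        "1",
                        str(qend),
                        "1",
                        str(qend),
                        f"{r.e_value:.3e}",
                        f"{r.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _alignment_stats(alignment) -> tuple[float, int, int]:
    """(identity %, aligned query span, alignment columns) from one alignment.

    ``alignment.aligned`` is (target blocks, query blocks); the query here is
    the family seed.  Identity counts identical columns over all alignment
    columns, including internal gap columns.
    """
    tblocks, qblocks = alignment.aligned
    qspan = int(qblocks[-1][1] - qblocks[0][0]) if len(qblocks) else 0
    identical = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for a, b in zip(alignment.target[ts:te], alignment.query[qs:qe]):
            columns += 1
            if a == b:
                identical += 1
    for i in range(1, len(qblocks)):
        columns += int(qblocks[i][0] - qblocks[i - 1][1])
        columns += int(tblocks[i][0] - tblocks[i - 1][1])
    identity = 100.0 * identical / columns if columns else 0.0
    return identity, qspan, columns


def bit_score(raw_score: float) -> float:
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / math.log(2.0)


def approximate_evalue(raw_score: float, query_length: int, db_residues: int) -> float:
    """Karlin-Altschul E = m*n*2^-bits; monotone decreasing in the raw score."""
    bits = bit_score(raw_score)
    return query_length * max(db_residues, 1) * 2.0 ** (-bits)


def pairwise_search(
    family: QueryFamily,
    proteome: Proteome,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    min_bit_score: float = 25.0,
) -> list[HitRecord]:
    """Local-alignment search of every seed against every protein.

    Returns the best hit per subject protein (bit score, then lower E-value,
    then lexicographic subject id).  ``min_bit_score`` skips alignment
    traceback for clearly insignificant score pairs.
    """
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    db_residues = sum(len(p.sequence) for p in proteome)
    best: dict[str, HitRecord] = {}
    for seed in family.seed_sequences:
        qlen = len(seed)
        for rec in proteome:
            raw = aligner.score(rec.sequence, seed)
            bits = bit_score(raw)
            if bits < min_bit_score:
                continue
            alignment = aligner.align(rec.sequence, seed)[0]
            identity, qspan, _ = _alignment_stats(alignment)
            coverage = 100.0 * qspan / qlen
            hit = HitRecord(
                family_name=family.family_name,
                genome_id=proteome.genome_id,
                subject_protein_id=rec.protein_id,
                e_value=approximate_evalue(raw, qlen, db_residues),
                bit_score=bits,
                percent_identity=min(identity, 100.0),
                percent_query_coverage=min(coverage, 100.0),
                query_length=qlen,
                subject_locus=rec.locus,
            )
            prev = best.get(rec.protein_id)
            if prev is None or _hit_sort_key(hit) < _hit_sort_key(prev):
                best[rec.protein_id] = hit
    return sorted(best.values(), key=lambda h: h.subject_locus)


def _hit_sort_key(hit: HitRecord):
    return (-hit.bit_score, hit.e_value, hit.subject_protein_id)


def best_hits_per_subject(hits: list[HitRecord]) -> list[HitRecord]:
    """Bit-score filtering: keep the best hit per (family, subject) pair."""
    best: dict[tuple[str, str, str], HitRecord] = {}
    for hit in hits:
        key = (hit.family_name, hit.genome_id, hit.subject_protein_id)
        prev = best.get(key)
        if prev is None or _hit_sort_key(hit) < _hit_sort_key(prev):
            best[key] = hit
    return sorted(
        best.values(), key=lambda h: (h.family_name, h.genome_id, h.subject_locus)
    )


def classify_hit(
    hit: HitRecord,
    policy: AcceptancePolicy,
    domain_evidence: bool = False,
    motif_ok: bool = True,
) -> HomologCall:
    """Apply the tiered decision procedure to one hit.

    Boundary conventions: E <= e_max passes; coverage must be strictly above
    coverage_min; identity >= identity_min accepts; the rescue band is
    half-open [low, high).
    """
    if hit.e_value > policy.e_max:
        return HomologCall(hit, REJECTED, REASON_EVALUE)
    if hit.percent_query_coverage <= policy.coverage_min:
        return HomologCall(hit, REJECTED, REASON_COVERAGE)
    if hit.percent_identity >= policy.identity_min:
        if motif_ok:
            return HomologCall(hit, ACCEPTED, REASON_OK)
        return HomologCall(hit, REJECTED, REASON_MOTIF)
    if policy.rescue_band is not None:
        lo, hi = policy.rescue_band
        if lo <= hit.percent_identity < hi:
            if not motif_ok:
                return HomologCall(hit, REJECTED, REASON_MOTIF)
            if domain_evidence or not policy.require_domain_for_rescue:
                return HomologCall(hit, RESCUED, REASON_OK)
            return HomologCall(hit, REJECTED, REASON_NO_DOMAIN)
    return HomologCall(hit, REJECTED, REASON_IDENTITY)


def apply_synteny(
    calls: list[HomologCall],
    operon_definitions: dict[str, set[str]],
    k: int = 2,
    w: int = 5,
) -> list[HomologCall]:
    """Upgrade partial operon-member hits with confident operon neighbours.

    A rejected(coverage) or rejected(identity) call for a family belonging to
    a defined operon becomes rescued (synteny_support=True) iff at least ``k``
    *other* families of the same operon have accepted/rescued calls within
    ``w`` loci of the hit.  Calls must belong to a single genome.
    """
    family_operon: dict[str, str] = {}
    for name, fams in operon_definitions.items():
        for fam in fams:
            family_operon[fam] = name
    confident: list[tuple[str, str, int]] = [
        (family_operon[c.hit.family_name], c.hit.family_name, c.hit.subject_locus)
        for c in calls
        if c.status in (ACCEPTED, RESCUED) and c.hit.family_name in family_operon
    ]
    out: list[HomologCall] = []
    for call in calls:
        fam = call.hit.family_name
        if (
            call.status == REJECTED
            and call.reason in (REASON_COVERAGE, REASON_IDENTITY)
            and fam in family_operon
        ):
            op = family_operon[fam]
            neighbours = {
                other_fam
                for op_name, other_fam, locus in confident
                if op_name == op
                and other_fam != fam
                and abs(locus - call.hit.subject_locus) <= w
            }
            if len(neighbours) >= k:
                out.append(
                    HomologCall(call.hit, RESCUED, REASON_OK, synteny_support=True)
                )
                continue
        out.append(call)
    return out


def check_operons_defined(families: list[QueryFamily], operon_definitions) -> None:
    for fam in families:
        if fam.operon is not None and fam.operon not in operon_definitions:
            raise ValueError(
                f"operon {fam.operon!r} of family {fam.family_name} is not defined"
            )


def family_presence(calls: list[HomologCall]) -> dict[str, bool]:
    """Family present iff >=1 accepted or rescued call (order-independent)."""
    presence: dict[str, bool] = {}
    for call in calls:
        fam = call.hit.family_name
        presence.setdefault(fam, False)
        if call.status in (ACCEPTED, RESCUED):
            presence[fam] = True
    return presence


def default_domain_provider(family: QueryFamily, sequence: str) -> bool:
    """Desk-scale stand-in for COG/Pfam evidence: required-motif satisfaction.

    Families without required motifs yield no evidence (False) so a motif-less
    family cannot be rescued for free.
    """
    if not family.required_motifs:
        return False
    return verify_required_motif(sequence, list(family.required_motifs))


def operon_definitions_from_families(families: list[QueryFamily]) -> dict[str, set[str]]:
    ops: dict[str, set[str]] = {}
    for fam in families:
        if fam.operon:
            ops.setdefault(fam.operon, set()).add(fam.family_name)
    return ops


def search_and_classify(
    families: list[QueryFamily],
    proteome: Proteome,
    policy: AcceptancePolicy | None = None,
    domain_provider=default_domain_provider,
    synteny_k: int = 2,
    synteny_w: int = 5,
    **search_kwargs,
) -> list[HomologCall]:
    """Run the built-in backend and full tier + synteny pipeline on one genome."""
    policy = policy or AcceptancePolicy()
    operons = operon_definitions_from_families(families)
    check_operons_defined(families, operons)
    calls: list[HomologCall] = []
    for family in families:
        hits = pairwise_search(family, proteome, **search_kwargs)
        fam_policy = family.policy(policy)
        for hit in hits:
            seq = proteome.get(hit.subject_protein_id).sequence
            motif_ok = verify_required_motif(seq, list(family.required_motifs))
            evidence = bool(domain_provider(family, seq)) if domain_provider else False
            calls.append(classify_hit(hit, fam_policy, evidence, motif_ok))
    return apply_synteny(calls, operons, k=synteny_k, w=synteny_w)
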