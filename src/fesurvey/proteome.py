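"""Per-genome proteome container and FASTA I/O.

A proteome is an ordered list of predicted proteins for one genome or MAG.
Gene order (the locus index) is retained because operon synteny is used as
supporting evidence when classifying partial homologs in incomplete genomes.

FASTA headers use the dialect ``>genomeID|proteinID|locusIndex``; plain
headers are accepted, in which case proteins are assigned to a caller-supplied
genome id and loci follow file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = set("BZJUOX")
ALLOWED_AA = STANDARD_AA | AMBIGUOUS_AA


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein: id, uppercase sequence, and its gene-order index."""

    protein_id: str
    sequence: str
    locus: int


@dataclass
class Proteome:
    """Ordered predicted proteome of one genome/MAG."""

    genome_id: str
    proteins: list[ProteinRecord] = field(default_factory=list)
    taxon_group: str | None = None
    complete: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        prev_locus = 0
        offenders: list[str] = []
        for rec in self.proteins:
            if rec.protein_id in seen:
                raise ValueError(
                    f"duplicate protein id {rec.protein_id!r} in genome {self.genome_id}"
                )
            seen.add(rec.protein_id)
            if rec.locus <= prev_locus:
                raise ValueError(
                    f"locus indices must be strictly increasing in genome "
                    f"{self.genome_id} (protein {rec.protein_id})"
                )
            prev_locus = rec.locus
            bad = set(rec.sequence) - ALLOWED_AA
            if bad:
                offenders.append(f"{rec.protein_id}: {''.join(sorted(bad))}")
        if offenders:
            raise ValueError(
                "illegal sequence characters: " + "; ".join(offenders)
            )

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    def get(self, protein_id: str) -> ProteinRecord:
        for rec in self.proteins:
            if rec.protein_id == protein_id:
                return rec
        raise KeyError(protein_id)

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]


def _clean_sequence(raw: str, protein_id: str) -> str:
    seq = raw.upper()
    if "*" in seq:
        warnings.warn(
            f"stripping stop character '*' from {protein_id}", stacklevel=3
        )
        seq = seq.replace("*", "")
    if not seq:
        raise ValueError(f"empty sequence record {protein_id!r}")
    return seq


def read_fasta(path, genome_id: str | None = None) -> list[Proteome]:
    """Read one multi-FASTA file into proteomes.

    Headers of the form ``genome|protein|locus`` are split into their parts;
    ``genome|protein`` headers get loci assigned by file order; plain headers
    require ``genome_id`` and also use file order.
    """
    by_genome: dict[str, list[ProteinRecord]] = {}
    order_counter: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 3:
            gid, pid, locus_s = parts
            locus = int(locus_s)
        elif len(parts) == 2:
            gid, pid = parts
            locus = order_counter.get(gid, 0) + 1
        else:
            if genome_id is None:
                raise ValueError(
                    f"plain FASTA header {rec.id!r} needs an explicit genome_id"
                )
            gid, pid = genome_id, rec.id
            locus = order_counter.get(gid, 0) + 1
        order_counter[gid] = locus
        seq = _clean_sequence(str(rec.seq), pid)
        by_genome.setdefault(gid, []).append(ProteinRecord(pid, seq, locus))
    if not by_genome:
        raise ValueError(f"no FASTA records found in {path}")
    return [Proteome(gid, prots) for gid, prots in by_genome.items()]


def write_fasta(proteomes, path) -> None:
    """Write proteomes as multi-FASTA with ``genome|protein|locus`` headers."""
    if isinstance(proteomes, Proteome):
        proteomes = [proteomes]
    records = []
    for prot in proteomes:
        for rec in prot.proteins:
            records.append(
                SeqRecord(
                    Seq(rec.sequence),
                    id=f"{prot.genome_id}|{rec.protein_id}|{rec.locus}",
                    description="",
                )
            )
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
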