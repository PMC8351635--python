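"""Synthetic proteome cohorts with planted ground truth.

The generator emulates the structure of a genome survey cohort: proteomes
partitioned into taxon groups, each group carrying each gene family with a
characteristic probability; homologs are planted as substitution-mutated
copies of family seed sequences at controlled percent identity; cofactor
motifs are planted into designated proteins; MAG incompleteness is simulated
by random whole-protein dropout that preserves gene order.

All randomness flows from a single integer seed through per-genome
``numpy`` generators, so a fixed seed yields byte-identical FASTA and truth
output.  The ``cysteine_free`` background policy removes cysteine from
background and gap residues; because every default motif is C- or G+C-
anchored, this gives a zero-false-positive regime in which planted counts
are exactly recoverable by the scanner.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .homologs import QueryFamily, SIROHEME_POLICY
from .motifs import (
    Alternation,
    Fixed,
    Gap,
    MotifPattern,
    Wildcard,
    parse_motif,
    scan_protein,
)
from .proteome import Proteome, ProteinRecord, STANDARD_AA

FULL20 = "".join(sorted(STANDARD_AA))
CYSTEINE_FREE = FULL20.replace("C", "")

_POLICIES = {"full20": FULL20, "cysteine_free": CYSTEINE_FREE}


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class GroupProfile:
    """Per-taxon-group generative profile."""

    group_name: str
    carriage: dict[str, float]
    planted_fes_fraction: float = 0.0
    target_identity: dict[str, float] = field(default_factory=dict)
    default_identity: float = 60.0

    def __post_init__(self) -> None:
        for fam, p in self.carriage.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"carriage[{fam}] out of [0, 1]")
        for fam, ident in self.target_identity.items():
            if not (0.0 < ident <= 100.0):
                raise ValueError(f"target_identity[{fam}] out of (0, 100]")

    def identity_for(self, family: str) -> float:
        return self.target_identity.get(family, self.default_identity)


@dataclass
class CohortConfig:
    groups: list[GroupProfile]
    families: list[QueryFamily]
    n_genomes_per_group: int = 20
    background_proteins_per_genome: int = 40
    background_length_range: tuple[int, int] = (120, 260)
    background_alphabet_policy: str = "cysteine_free"
    completeness: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.completeness <= 1.0):
            raise ValueError("completeness must be in (0, 1]")
        if self.background_alphabet_policy not in _POLICIES:
            raise ValueError(
                f"unknown background_alphabet_policy {self.background_alphabet_policy!r}"
            )
        names = {f.family_name for f in self.families}
        for grp in self.groups:
            unknown = set(grp.carriage) - names
            if unknown:
                raise ValueError(
                    f"group {grp.group_name} references undefined families: {sorted(unknown)}"
                )

    @property
    def alphabet(self) -> str:
        return _POLICIES[self.background_alphabet_policy]


@dataclass
class PlantedMotif:
    protein_id: str
    pattern_id: str
    start: int  # 1-based inclusive
    end: int
    cofactor_class: str | None = None


@dataclass
class GenomeTruth:
    genome_id: str
    group_name: str
    planted_families: dict[str, str]  # family -> protein id
    planted_motifs: list[PlantedMotif]
    dropped_protein_ids: list[str]
    n_proteins_before_dropout: int
    rng_seed: int

    def retained_families(self) -> dict[str, bool]:
        dropped = set(self.dropped_protein_ids)
        return {
            fam: pid not in dropped for fam, pid in self.planted_families.items()
        }


@dataclass
class SyntheticTruth:
    """Complete manifest of what was planted, sufficient to recompute
    expected downstream calls."""

    rng_seed: int
    genomes: dict[str, GenomeTruth]

    def expected_family_presence(self, family_names: list[str]) -> dict[str, dict[str, bool]]:
        """Per genome: family present iff planted and its protein survived dropout."""
        out = {}
        for gid, gt in self.genomes.items():
            retained = gt.retained_families()
            out[gid] = {fam: retained.get(fam, False) for fam in family_names}
        return out

    def expected_motif_protein_count(self, genome_id: str, pattern_ids: set[str]) -> int:
        gt = self.genomes[genome_id]
        dropped = set(gt.dropped_protein_ids)
        proteins = {
            pm.protein_id
            for pm in gt.planted_motifs
            if pm.pattern_id in pattern_ids and pm.protein_id not in dropped
        }
        return len(proteins)

    def expected_fes_fraction(self, genome_id: str) -> float:
        """Expected scanner [Fe-S] fraction after dropout.

        Counts planted motifs of class "fes" plus "siroheme" — the siroheme
        cysteine cluster embeds a [4Fe-4S] center and is matched by the
        [Fe-S] library's cluster pattern.
        """
        gt = self.genomes[genome_id]
        dropped = set(gt.dropped_protein_ids)
        proteins = {
            pm.protein_id
            for pm in gt.planted_motifs
            if pm.cofactor_class in ("fes", "siroheme") and pm.protein_id not in dropped
        }
        retained = gt.n_proteins_before_dropout - len(gt.dropped_protein_ids)
        return len(proteins) / retained

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        genomes = {}
        for gid, g in raw["genomes"].items():
            genomes[gid] = GenomeTruth(
                genome_id=g["genome_id"],
                group_name=g["group_name"],
                planted_families=g["planted_families"],
                planted_motifs=[PlantedMotif(**pm) for pm in g["planted_motifs"]],
                dropped_protein_ids=g["dropped_protein_ids"],
                n_proteins_before_dropout=g["n_proteins_before_dropout"],
                rng_seed=g["rng_seed"],
            )
        return cls(rng_seed=raw["rng_seed"], genomes=genomes)


def mutate_to_identity(
    seed_sequence: str,
    target_identity: float,
    rng_seed: int,
    alphabet: str = FULL20,
) -> str:
    """Point-substitute a seed down to a controlled percent identity.

    Exactly ``round(L*(1 - identity/100))`` positions are substituted, each to
    a residue different from the original, so the column-wise identity to the
    seed is forced by construction.  No indels.
    """
    if not seed_sequence:
        raise ValueError("empty seed sequence")
    if not (0.0 < target_identity <= 100.0):
        raise ValueError("target_identity must be in (0, 100]")
    if len(seed_sequence) < 10:
        raise ValueError("seed sequence must be >= 10 residues")
    L = len(seed_sequence)
    n_sub = _round_half_up(L * (1.0 - target_identity / 100.0))
    if n_sub == 0:
        return seed_sequence
    rng = np.random.default_rng(rng_seed)
    positions = rng.choice(L, size=n_sub, replace=False)
    chars = list(seed_sequence)
    for pos in sorted(positions.tolist()):
        choices = [c for c in alphabet if c != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def instantiate_motif(
    pattern: MotifPattern, rng: np.random.Generator, alphabet: str
) -> str:
    """One concrete string satisfying the pattern; gap/wildcard residues are
    drawn from ``alphabet``, gap lengths uniformly within their bounds."""
    out = []
    for el in pattern.elements:
        if isinstance(el, Fixed):
            out.append(el.aa)
        elif isinstance(el, Wildcard):
            out.append(alphabet[rng.integers(len(alphabet))])
        elif isinstance(el, Alternation):
            residues = sorted(el.residues)
            out.append(residues[rng.integers(len(residues))])
        elif isinstance(el, Gap):
            glen = int(rng.integers(el.min, el.max + 1))
            out.append(
                "".join(alphabet[i] for i in rng.integers(len(alphabet), size=glen))
            )
    return "".join(out)


def plant_motif(
    sequence: str,
    pattern: MotifPattern,
    position: int | str = "random",
    rng_seed: int = 0,
    alphabet: str = CYSTEINE_FREE,
) -> tuple[str, tuple[int, int]]:
    """Overwrite a stretch of ``sequence`` with a concrete motif instance.

    ``position`` is the 1-based start, or "random".  Returns the new sequence
    and the 1-based inclusive span; outside the span the sequence is
    unchanged.
    """
    rng = np.random.default_rng(rng_seed)
    instance = instantiate_motif(pattern, rng, alphabet)
    if len(instance) > len(sequence):
        raise ValueError(
            f"pattern {pattern.pattern_id} ({len(instance)} aa) longer than "
            f"sequence ({len(sequence)} aa)"
        )
    if position == "random":
        start0 = int(rng.integers(0, len(sequence) - len(instance) + 1))
    else:
        start0 = int(position) - 1
        if start0 < 0 or start0 + len(instance) > len(sequence):
            raise ValueError("position does not fit the instantiated pattern")
    new_seq = sequence[:start0] + instance + sequence[start0 + len(instance):]
    return new_seq, (start0 + 1, start0 + len(instance))


def apply_dropout(
    proteome: Proteome, completeness: float, rng_seed: int
) -> tuple[Proteome, list[str]]:
    """Retain exactly ``round(N*completeness)`` proteins, order preserved.

    Returns the reduced proteome and the dropped protein ids (simulating MAG
    incompleteness; relative gene order is kept so synteny remains
    meaningful).
    """
    if not (0.0 < completeness <= 1.0):
        raise ValueError("completeness must be in (0, 1]")
    n = len(proteome)
    keep = _round_half_up(n * completeness)
    if keep == n:
        return proteome, []
    rng = np.random.default_rng(rng_seed)
    kept_idx = set(rng.choice(n, size=keep, replace=False).tolist())
    kept, dropped = [], []
    for i, rec in enumerate(proteome.proteins):
        if i in kept_idx:
            kept.append(rec)
        else:
            dropped.append(rec.protein_id)
    reduced = Proteome(
        proteome.genome_id,
        kept,
        taxon_group=proteome.taxon_group,
        complete=completeness >= 1.0,
    )
    return reduced, dropped


def _random_protein(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


_FES_PLANT_PATTERN = parse_motif("CX{2}CX{2}CX{3}C", "ferredoxin_4Fe4S", "fes")


def _genome_seed(base_seed: int, group_idx: int, genome_idx: int) -> int:
    # stable, collision-free derived seed below 2**31
    return zlib.crc32(f"{base_seed}:{group_idx}:{genome_idx}".encode()) % (2**31)


def generate_cohort(config: CohortConfig) -> tuple[list[Proteome], SyntheticTruth]:
    """Generate one cohort of proteomes plus its complete truth manifest."""
    families = {f.family_name: f for f in config.families}
    proteomes: list[Proteome] = []
    truths: dict[str, GenomeTruth] = {}
    alphabet = config.alphabet
    lo, hi = config.background_length_range
    for g_idx, group in enumerate(config.groups):
        for n_idx in range(config.n_genomes_per_group):
            genome_id = f"{group.group_name}_g{n_idx:03d}"
            gseed = _genome_seed(config.rng_seed, g_idx, n_idx)
            rng = np.random.default_rng(gseed)

            # items: single background proteins or operon blocks of homologs
            carried = [
                fam
                for fam in sorted(group.carriage)
                if rng.random() < group.carriage[fam]
            ]
            homolog_seqs: dict[str, tuple[str, list[PlantedMotif]]] = {}
            for fam_name in carried:
                family = families[fam_name]
                seed_seq = family.seed_sequences[0]
                ident = group.identity_for(fam_name)
                mut_seed = int(rng.integers(2**31))
                seq = mutate_to_identity(seed_seq, ident, mut_seed, alphabet=alphabet)
                planted: list[PlantedMotif] = []
                # restore required motifs so controlled mutation never
                # destroys the family's diagnostic motif: copy the seed's own
                # motif region back at its span (identity can only increase)
                for pat in family.required_motifs:
                    seed_hits = scan_protein(seed_seq, pat)
                    if seed_hits:
                        s, e = seed_hits[0].start, seed_hits[0].end
                        seq = seq[: s - 1] + seed_seq[s - 1 : e] + seq[e:]
                        span = (s, e)
                    else:
                        pos_seed = int(rng.integers(2**31))
                        seq, span = plant_motif(
                            seq, pat, position="random", rng_seed=pos_seed, alphabet=alphabet
                        )
                    planted.append(
                        PlantedMotif("", pat.pattern_id, span[0], span[1], pat.cofactor_class)
                    )
                homolog_seqs[fam_name] = (seq, planted)

            # group carried families into operon blocks (adjacent) + singles
            blocks: list[list[str]] = []
            by_operon: dict[str, list[str]] = {}
            for fam_name in carried:
                op = families[fam_name].operon
                if op:
                    by_operon.setdefault(op, []).append(fam_name)
                else:
                    blocks.append([fam_name])
            for op in sorted(by_operon):
                blocks.append(sorted(by_operon[op]))

            n_bg = config.background_proteins_per_genome
            bg_seqs = [
                _random_protein(rng, int(rng.integers(lo, hi + 1)), alphabet)
                for _ in range(n_bg)
            ]
            items: list[tuple[str, object]] = [("bg", s) for s in bg_seqs]
            insert_at = rng.integers(0, len(items) + 1, size=len(blocks))
            for pos, block in sorted(
                zip(insert_at.tolist(), blocks), key=lambda t: t[0], reverse=True
            ):
                items.insert(pos, ("block", block))

            # flatten into records with final ids/loci
            records: list[ProteinRecord] = []
            planted_families: dict[str, str] = {}
            planted_motifs: list[PlantedMotif] = []
            counter = 0
            for kind, payload in items:
                if kind == "bg":
                    counter += 1
                    records.append(
                        ProteinRecord(f"p{counter:04d}", payload, counter)
                    )
                else:
                    for fam_name in payload:
                        counter += 1
                        pid = f"p{counter:04d}_{fam_name}"
                        seq, planted = homolog_seqs[fam_name]
                        records.append(ProteinRecord(pid, seq, counter))
                        planted_families[fam_name] = pid
                        for pm in planted:
                            planted_motifs.append(
                                PlantedMotif(pid, pm.pattern_id, pm.start, pm.end, pm.cofactor_class)
                            )

            # plant [Fe-S] motifs into motif-free background proteins
            n_total = len(records)
            n_fes = _round_half_up(n_total * group.planted_fes_fraction)
            bg_indices = [
                i for i, r in enumerate(records) if "_" not in r.protein_id
            ]
            if n_fes > len(bg_indices):
                raise ValueError(
                    "planted_fes_fraction too high for the number of background proteins"
                )
            chosen = rng.choice(len(bg_indices), size=n_fes, replace=False)
            for j in sorted(chosen.tolist()):
                idx = bg_indices[j]
                rec = records[idx]
                pos_seed = int(rng.integers(2**31))
                seq, span = plant_motif(
                    rec.sequence,
                    _FES_PLANT_PATTERN,
                    position="random",
                    rng_seed=pos_seed,
                    alphabet=alphabet,
                )
                records[idx] = ProteinRecord(rec.protein_id, seq, rec.locus)
                planted_motifs.append(
                    PlantedMotif(rec.protein_id, _FES_PLANT_PATTERN.pattern_id, span[0], span[1], "fes")
                )

            proteome = Proteome(
                genome_id,
                records,
                taxon_group=group.group_name,
                complete=config.completeness >= 1.0,
            )
            drop_seed = int(rng.integers(2**31))
            proteome, dropped = apply_dropout(proteome, config.completeness, drop_seed)
            proteomes.append(proteome)
            truths[genome_id] = GenomeTruth(
                genome_id=genome_id,
                group_name=group.group_name,
                planted_families=planted_families,
                planted_motifs=planted_motifs,
                dropped_protein_ids=dropped,
                n_proteins_before_dropout=n_total,
                rng_seed=gseed,
            )
    return proteomes, SyntheticTruth(rng_seed=config.rng_seed, genomes=truths)


# ---------------------------------------------------------------------------
# Default study-condition families and cohort
# ---------------------------------------------------------------------------

_SIROHEME_MOTIF = parse_motif("CX{4,5}CXnCX{3}C", "siroheme_cluster", "siroheme")
_HEME_B_MOTIF = parse_motif("GX(H/R)XCXGX", "GX(H/R)XCXGX", "heme_b")

_SEED_LENGTH = 240


def _family_seed_sequence(name: str, motif: MotifPattern | None = None) -> str:
    """Deterministic synthetic stand-in for a real query protein.

    Cysteine-free random backbone (so planted motifs are the only C-anchored
    signal), with the family's diagnostic motif planted at a fixed offset
    when one exists.
    """
    rng = np.random.default_rng(zlib.crc32(f"seed:{name}".encode()) % (2**31))
    seq = _random_protein(rng, _SEED_LENGTH, CYSTEINE_FREE)
    if motif is not None:
        seq, _ = plant_motif(seq, motif, position=100, rng_seed=rng.integers(2**31), alphabet=CYSTEINE_FREE)
    return seq


def default_families() -> list[QueryFamily]:
    """The survey's core query families with synthetic seed sequences.

    Covers Fe(II) uptake (FeoA/FeoB), [Fe-S] assembly (SufB/C/S), siroheme
    biosynthesis (SirA/SirC) and destinations (Dsr, Fsr; stringent policy,
    required siroheme motif), the alternative heme pathway operon (AhbA-D),
    and heme-b users (VhoC, HdrE, KatG; required heme-b motif).  SirB/CbiX
    chelatases are deliberately absent: primary sequence cannot demarcate
    them from paralogs, so the family list marks them unsupported.
    """
    fams: list[QueryFamily] = []

    def plain(name: str, operon: str | None = None) -> QueryFamily:
        return QueryFamily(name, (_family_seed_sequence(name),), operon=operon)

    fams += [plain("FeoA", operon="feo"), plain("FeoB", operon="feo")]
    fams += [plain("SufB", operon="suf"), plain("SufC", operon="suf"), plain("SufS", operon="suf")]
    fams += [plain("SirA"), plain("SirC")]
    for name in ("AhbA", "AhbB", "AhbC", "AhbD"):
        fams.append(plain(name, operon="ahb"))
    for name in ("Dsr", "Fsr"):
        fams.append(
            QueryFamily(
                name,
                (_family_seed_sequence(name, _SIROHEME_MOTIF),),
                policy_override=SIROHEME_POLICY,
                required_motifs=(_SIROHEME_MOTIF,),
            )
        )
    for name in ("VhoC", "HdrE", "KatG"):
        fams.append(
            QueryFamily(
                name,
                (_family_seed_sequence(name, _HEME_B_MOTIF),),
                required_motifs=(_HEME_B_MOTIF,),
            )
        )
    return fams


def default_cohort_config(rng_seed: int = 0) -> CohortConfig:
    """Two-group cohort whose carriage probabilities follow the per-group
    prevalences observed across the survey's taxon groups.

    ``type_I`` mirrors the deeply diverging lineages (FeoAB-rich, SufBC
    near-universal, no heme pathway, siroheme destinations rare) and
    ``type_II_ms`` mirrors the heme-synthesizing recently diverging lineage
    (AhbABCD, Dsr, heme-b users common).
    """
    type_i = GroupProfile(
        group_name="type_I",
        carriage={
            "FeoA": 0.91,
            "FeoB": 0.95,
            "SufB": 0.95,
            "SufC": 0.95,
            "SufS": 0.82,
            "SirA": 0.95,
            "SirC": 0.98,
            "Dsr": 0.12,
            "Fsr": 0.21,
            "KatG": 0.10,
        },
        planted_fes_fraction=0.068,
        default_identity=60.0,
    )
    type_ii = GroupProfile(
        group_name="type_II_ms",
        carriage={
            "FeoA": 0.85,
            "FeoB": 0.95,
            "SufB": 0.96,
            "SufC": 0.96,
            "SufS": 0.96,
            "SirA": 0.99,
            "SirC": 0.92,
            "Dsr": 0.92,
            "Fsr": 0.06,
            "AhbA": 0.86,
            "AhbB": 0.86,
            "AhbC": 0.86,
            "AhbD": 0.86,
            "VhoC": 0.66,
            "HdrE": 0.80,
            "KatG": 0.24,
        },
        planted_fes_fraction=0.055,
        default_identity=60.0,
    )
    return CohortConfig(
        groups=[type_i, type_ii],
        families=default_families(),
        n_genomes_per_group=20,
        background_proteins_per_genome=40,
        background_length_range=(120, 260),
        background_alphabet_policy="cysteine_free",
        completeness=0.9,
        rng_seed=rng_seed,
    )
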