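"""Pathway-level presence/absence calling from per-genome family presence.

Counting rules follow the survey conventions for draft-genome tolerance:
the [Fe-S] scaffold SufBC is positive only when *both* SufB and SufC are
present; the tetrapyrrole trunk HemBCD is positive when *any* of HemB, HemC,
HemD is present (an incomplete draft should not mask the pathway); the
alternative heme pathway AhbABCD requires all four subunits, with a
companion ``Ahb_partial`` any-of feature retaining draft-genome signal.
Fe(II) uptake is categorised into the mutually exclusive states
FeoAB / FeoA_only / FeoB_only / none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class Rule:
    """Boolean expression over family names: all_of and/or any_of."""

    all_of: tuple[str, ...] = ()
    any_of: tuple[str, ...] = ()

    def families(self) -> set[str]:
        return set(self.all_of) | set(self.any_of)

    def evaluate(self, presence: dict[str, bool]) -> bool:
        ok = True
        if self.all_of:
            ok = all(presence.get(f, False) for f in self.all_of)
        if ok and self.any_of:
            ok = any(presence.get(f, False) for f in self.any_of)
        return ok


@dataclass
class PathwayRuleSet:
    rules: dict[str, Rule]
    known_families: set[str] | None = None
    #: manual per-genome overrides: (genome_id, feature) -> value, for the
    #: rare curated exception (e.g. a homolog known to sit just outside the
    #: search thresholds); applications are logged via the returned vector.
    overrides: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.known_families is not None:
            for feature, rule in self.rules.items():
                unknown = rule.families() - self.known_families
                if unknown:
                    raise ValueError(
                        f"rule {feature!r} references unknown families: {sorted(unknown)}"
                    )


FEO_STATES = ("FeoAB", "FeoA_only", "FeoB_only", "none")

DEFAULT_HEME_USER_FAMILIES = frozenset({"VhoC", "HdrE", "KatG", "CydAB"})


def default_ruleset(known_families: set[str] | None = None) -> PathwayRuleSet:
    rules = {
        "SufBC": Rule(all_of=("SufB", "SufC")),
        "HemBCD": Rule(any_of=("HemB", "HemC", "HemD")),
        "AhbABCD": Rule(all_of=("AhbA", "AhbB", "AhbC", "AhbD")),
        "Ahb_partial": Rule(any_of=("AhbA", "AhbB", "AhbC", "AhbD")),
    }
    if known_families is not None:
        rules = {
            feat: rule
            for feat, rule in rules.items()
            if rule.families() <= known_families
        }
    return PathwayRuleSet(rules, known_families=known_families)


@dataclass
class FeatureVector:
    genome_id: str
    bits: dict[str, int]
    feo_state: str
    flags: dict[str, bool] = field(default_factory=dict)
    applied_overrides: list[str] = field(default_factory=list)


def _feo_state(presence: dict[str, bool]) -> str:
    a = presence.get("FeoA", False)
    b = presence.get("FeoB", False)
    if a and b:
        return "FeoAB"
    if a:
        return "FeoA_only"
    if b:
        return "FeoB_only"
    return "none"


def call_features(
    presence: dict[str, bool],
    rules: PathwayRuleSet,
    genome_id: str = "",
    heme_user_families: frozenset[str] = DEFAULT_HEME_USER_FAMILIES,
) -> FeatureVector:
    """Evaluate family bits, pathway rules, the Feo category, and flags.

    Families referenced by rules but absent from the presence map default to
    False.
    """
    bits = {fam: int(bool(v)) for fam, v in presence.items()}
    applied: list[str] = []
    for feature, rule in rules.rules.items():
        value = rule.evaluate(presence)
        key = (genome_id, feature)
        if key in rules.overrides:
            value = rules.overrides[key]
            applied.append(feature)
        bits[feature] = int(value)
    vec = FeatureVector(
        genome_id=genome_id,
        bits=bits,
        feo_state=_feo_state(presence),
        applied_overrides=applied,
    )
    vec.flags["heme_auxotroph_candidate"] = flag_heme_auxotrophy(vec, heme_user_families)
    vec.flags["siroheme_orphan"] = flag_siroheme_orphan(vec)
    return vec


def flag_heme_auxotrophy(
    vector: FeatureVector, heme_user_families: frozenset[str] = DEFAULT_HEME_USER_FAMILIES
) -> bool:
    """Heme-user families present without a complete heme biosynthesis
    pathway — the signature of environmentally derived heme usage."""
    uses_heme = any(vector.bits.get(f, 0) for f in heme_user_families)
    return uses_heme and not vector.bits.get("AhbABCD", 0)


def flag_siroheme_orphan(vector: FeatureVector) -> bool:
    """Siroheme biosynthesis (SirA and SirC) without any known siroheme
    destination (neither Dsr nor Fsr)."""
    return bool(
        vector.bits.get("SirA", 0)
        and vector.bits.get("SirC", 0)
        and not vector.bits.get("Dsr", 0)
        and not vector.bits.get("Fsr", 0)
    )


@dataclass
class PresenceAbsenceMatrix:
    """Genomes x features binary matrix (pandas DataFrame backed)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate genome ids: {dups}")
        values = self.data.to_numpy()
        if not ((values == 0) | (values == 1)).all():
            raise ValueError("matrix values must be binary 0/1")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="genome")

    @classmethod
    def from_tsv(cls, path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="genome")
        return cls(df.astype(int))


def build_matrix(
    vectors: list[FeatureVector],
    feature_order: list[str] | None = None,
    feo_as_binary: bool = True,
) -> PresenceAbsenceMatrix:
    """Assemble feature vectors into a presence/absence matrix.

    ``feo_as_binary`` encodes the Feo category as three binary columns
    (FeoAB / FeoA_only / FeoB_only); otherwise the raw FeoA/FeoB family bits
    stand alone.  Row order follows input order; column order is
    ``feature_order`` or first-seen order.
    """
    rows = {}
    for vec in vectors:
        if vec.genome_id in rows:
            raise ValueError(f"duplicate genome id {vec.genome_id!r}")
        bits = dict(vec.bits)
        if feo_as_binary:
            for state in ("FeoAB", "FeoA_only", "FeoB_only"):
                bits[state] = int(vec.feo_state == state)
        rows[vec.genome_id] = bits
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if feature_order is not None:
        df = df.reindex(columns=feature_order, fill_value=0)
    else:
        seen: list[str] = []
        for vec in vectors:
            for feat in rows[vec.genome_id]:
                if feat not in seen:
                    seen.append(feat)
        df = df.reindex(columns=seen, fill_value=0)
    return PresenceAbsenceMatrix(df)
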