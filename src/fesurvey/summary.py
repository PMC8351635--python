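"""Per-taxon prevalence tables and pooled/conditional prevalences.

Reproduces the arithmetic of genome-survey distribution tables: per-group
positive-genome counts for each feature, integer percentages rounded
half-up (95.4 -> 95, 76.8 -> 77), and group-mean [Fe-S]-motif proteome
fractions rendered as percent with two decimals.  Denominators are always
derived from the matrix itself; a caller-supplied denominator that
disagrees is logged rather than silently adopted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .pathways import PresenceAbsenceMatrix

logger = logging.getLogger(__name__)


def _half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class TaxonSummary:
    group_name: str
    n_genomes: int
    n_complete: int
    n_draft: int
    feature_counts: dict[str, int] = field(default_factory=dict)
    mean_fes_fraction: float | None = None  # percent, 2 decimals

    def __post_init__(self) -> None:
        if self.n_complete + self.n_draft != self.n_genomes:
            raise ValueError("n_complete + n_draft must equal n_genomes")
        for feat, count in self.feature_counts.items():
            if not (0 <= count <= self.n_genomes):
                raise ValueError(f"count for {feat} out of [0, n_genomes]")


def prevalence(k: int, n: int) -> int:
    """Nearest-integer percent, half-up: prevalence(311, 326) == 95."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return _half_up(100.0 * k / n)


def mean_fes_percent(fractions: list[float]) -> float:
    """Unweighted mean of per-genome fractions, as percent at 2 decimals."""
    mean = sum(fractions) / len(fractions)
    return math.floor(mean * 10000 + 0.5) / 100.0


def summarize_groups(
    matrix: PresenceAbsenceMatrix,
    fractions: dict[str, float] | None,
    taxon_map: dict[str, str],
    complete_map: dict[str, bool] | None = None,
    expected_totals: dict[str, int] | None = None,
) -> list[TaxonSummary]:
    """One :class:`TaxonSummary` per taxon group, sorted by group name.

    ``fractions`` maps genome id -> [Fe-S] proteome fraction (in [0, 1]);
    ``complete_map`` marks finished genomes (default: all complete).
    ``expected_totals`` lets a caller assert printed per-group denominators;
    mismatches are logged and the matrix-derived totals kept.
    """
    unlabeled = [g for g in matrix.genome_ids if g not in taxon_map]
    if unlabeled:
        raise ValueError(f"genomes without a taxon label: {unlabeled}")
    groups: dict[str, list[str]] = {}
    for gid in matrix.genome_ids:
        groups.setdefault(taxon_map[gid], []).append(gid)
    summaries = []
    for name in sorted(groups):
        members = groups[name]
        sub = matrix.data.loc[members]
        n = len(members)
        if expected_totals and name in expected_totals and expected_totals[name] != n:
            logger.warning(
                "group %s: supplied denominator %d disagrees with matrix-derived %d; "
                "using %d",
                name,
                expected_totals[name],
                n,
                n,
            )
        n_complete = (
            sum(1 for g in members if complete_map.get(g, True))
            if complete_map is not None
            else n
        )
        summary = TaxonSummary(
            group_name=name,
            n_genomes=n,
            n_complete=n_complete,
            n_draft=n - n_complete,
            feature_counts={feat: int(sub[feat].sum()) for feat in matrix.features},
            mean_fes_fraction=(
                mean_fes_percent([fractions[g] for g in members])
                if fractions is not None
                else None
            ),
        )
        summaries.append(summary)
    return summaries


def conditional_prevalence(
    matrix: PresenceAbsenceMatrix,
    feature: str,
    condition_feature: str,
    taxon_map: dict[str, str] | None = None,
    group_filter: str | None = None,
) -> int:
    """Prevalence of ``feature`` among genomes positive for
    ``condition_feature``, optionally restricted to one taxon group."""
    genomes = matrix.genome_ids
    if group_filter is not None:
        if taxon_map is None:
            raise ValueError("group_filter requires a taxon_map")
        genomes = [g for g in genomes if taxon_map.get(g) == group_filter]
    sub = matrix.data.loc[genomes]
    condition = sub[sub[condition_feature] == 1]
    if len(condition) == 0:
        raise ValueError("empty condition subset")
    return prevalence(int(condition[feature].sum()), len(condition))


def pooled_prevalence(
    summaries: list[TaxonSummary], feature: str, groups: list[str]
) -> int:
    """round(100 * sum(k) / sum(n)) over the selected groups."""
    if not groups:
        raise ValueError("groups must be non-empty")
    by_name = {s.group_name: s for s in summaries}
    missing = [g for g in groups if g not in by_name]
    if missing:
        raise ValueError(f"unknown groups: {missing}")
    k = sum(by_name[g].feature_counts[feature] for g in groups)
    n = sum(by_name[g].n_genomes for g in groups)
    return prevalence(k, n)


def summaries_to_frame(summaries: list[TaxonSummary]):
    """Survey-table-shaped DataFrame: one row per group, counts per feature."""
    import pandas as pd

    rows = []
    for s in summaries:
        row = {
            "group": s.group_name,
            "n_genomes": s.n_genomes,
            "n_complete": s.n_complete,
            "n_draft": s.n_draft,
        }
        row.update(s.feature_counts)
        if s.mean_fes_fraction is not None:
            row["mean_fes_pct"] = s.mean_fes_fraction
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
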