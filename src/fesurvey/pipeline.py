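"""End-to-end pipeline: simulate/load -> scan -> classify -> call -> summarize -> ordinate.

Each stage writes a plain-text artifact (TSV or JSON) into the output
directory, plus a provenance record (package version, seed, parameters,
input hashes) so every output is regenerable from the logged configuration.
Reruns with the same inputs and seed produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .homologs import (
    AcceptancePolicy,
    QueryFamily,
    family_presence,
    search_and_classify,
)
from .motifs import MotifPattern, default_motif_library, fes_fraction, fes_patterns, scan_proteome
from .ordination import jaccard, pco
from .pathways import PathwayRuleSet, build_matrix, call_features, default_ruleset
from .proteome import Proteome, read_fasta, write_fasta
from .simulate import CohortConfig, generate_cohort
from .summary import summaries_to_frame, summarize_groups

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``cohort`` (simulate a synthetic cohort) or ``proteome_paths``
    (FASTA inputs, with ``taxon_map``) must be provided.
    """

    out_dir: str
    cohort: CohortConfig | None = None
    proteome_paths: list[str] = field(default_factory=list)
    taxon_map: dict[str, str] = field(default_factory=dict)
    families: list[QueryFamily] = field(default_factory=list)
    motif_library: list[MotifPattern] | None = None
    policy: AcceptancePolicy = field(default_factory=AcceptancePolicy)
    ruleset: PathwayRuleSet | None = None
    synteny_k: int = 2
    synteny_w: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort is None and not self.proteome_paths:
            raise ValueError("need either a cohort config or proteome paths")
        if self.cohort is None and not self.taxon_map:
            raise ValueError("external proteomes require a taxon map")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


@dataclass
class PipelineResult:
    out_dir: Path
    proteomes: list[Proteome]
    truth: object | None
    motif_tables: dict
    fractions: dict[str, float]
    calls: dict[str, list]
    presence: dict[str, dict[str, bool]]
    matrix: object
    summaries: list
    dissimilarity: object
    ordination: object


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library = config.motif_library or default_motif_library()
    fes_lib = fes_patterns(library)

    # --- stage: simulate or load -------------------------------------------
    truth = None
    if config.cohort is not None:
        proteomes, truth = generate_cohort(config.cohort)
        families = config.cohort.families
        taxon_map = {p.genome_id: p.taxon_group for p in proteomes}
        fasta_path = out / "cohort.fasta"
        write_fasta(proteomes, fasta_path)
        (out / "truth.json").write_text(truth.to_json())
        logger.info("simulate: %d genomes written", len(proteomes))
    else:
        proteomes = []
        for path in config.proteome_paths:
            proteomes.extend(read_fasta(path))
        families = config.families
        taxon_map = dict(config.taxon_map)
        for p in proteomes:
            if p.genome_id not in taxon_map:
                raise ValueError(f"genome {p.genome_id} missing from taxon map")
            p.taxon_group = taxon_map[p.genome_id]
        logger.info("load: %d genomes read", len(proteomes))
    if not families:
        raise ValueError("no query families configured")

    # --- stage: motif scan --------------------------------------------------
    motif_tables = {}
    fractions = {}
    scan_rows = []
    for prot in proteomes:
        table = scan_proteome(prot, library)
        motif_tables[prot.genome_id] = table
        fractions[prot.genome_id] = fes_fraction(prot, fes_lib)
        for m in table.matches:
            scan_rows.append(
                {
                    "genome": prot.genome_id,
                    "protein": m.protein_id,
                    "pattern": m.pattern_id,
                    "start": m.start,
                    "end": m.end,
                }
            )
    _write_tsv(pd.DataFrame(scan_rows, columns=["genome", "protein", "pattern", "start", "end"]), out / "motif_hits.tsv")
    _write_tsv(
        pd.DataFrame(
            {"genome": list(fractions), "fes_fraction": [f"{fractions[g]:.6f}" for g in fractions]}
        ),
        out / "fes_fractions.tsv",
    )
    logger.info("scan: %d motif matches", len(scan_rows))

    # --- stage: homolog search + classification ----------------------------
    calls = {}
    call_rows = []
    for prot in proteomes:
        genome_calls = search_and_classify(
            families,
            prot,
            policy=config.policy,
            synteny_k=config.synteny_k,
            synteny_w=config.synteny_w,
        )
        calls[prot.genome_id] = genome_calls
        for c in genome_calls:
            call_rows.append(
                {
                    "genome": prot.genome_id,
                    "protein": c.hit.subject_protein_id,
                    "family": c.hit.family_name,
                    "status": c.status,
                    "reason": c.reason,
                    "synteny_support": int(c.synteny_support),
                }
            )
    _write_tsv(
        pd.DataFrame(
            call_rows,
            columns=["genome", "protein", "family", "status", "reason", "synteny_support"],
        ),
        out / "calls.tsv",
    )
    n_acc = sum(1 for r in call_rows if r["status"] in ("accepted", "rescued"))
    logger.info("classify: %d hits, %d accepted/rescued", len(call_rows), n_acc)

    # --- stage: pathway calling --------------------------------------------
    family_names = sorted(f.family_name for f in families)
    ruleset = config.ruleset or default_ruleset(set(family_names))
    presence = {}
    vectors = []
    for prot in proteomes:
        pres = family_presence(calls[prot.genome_id])
        for fam in family_names:
            pres.setdefault(fam, False)
        presence[prot.genome_id] = pres
        vectors.append(call_features(pres, ruleset, genome_id=prot.genome_id))
    feature_order = family_names + sorted(ruleset.rules) + [
        "FeoAB",
        "FeoA_only",
        "FeoB_only",
    ]
    matrix = build_matrix(vectors, feature_order=feature_order)
    matrix.to_tsv(out / "matrix.tsv")
    pres_df = pd.DataFrame(
        {g: {f: int(v) for f, v in p.items()} for g, p in presence.items()}
    ).T.reindex(columns=family_names, fill_value=0)
    pres_df.index.name = "genome"
    pres_df.to_csv(out / "presence.tsv", sep="\t")

    pd.DataFrame(
        {"genome": list(taxon_map), "group": [taxon_map[g] for g in taxon_map]}
    ).to_csv(out / "taxon_map.tsv", sep="\t", index=False, header=False)

    # --- stage: summarize ---------------------------------------------------
    complete_map = {p.genome_id: p.complete for p in proteomes}
    summaries = summarize_groups(matrix, fractions, taxon_map, complete_map)
    frame = summaries_to_frame(summaries)
    frame.to_csv(out / "summary.tsv", sep="\t")
    (out / "summary.json").write_text(
        json.dumps(
            [dataclasses.asdict(s) for s in summaries], indent=1, sort_keys=True
        )
    )

    # --- stage: ordinate ----------------------------------------------------
    dissim = jaccard(matrix)
    dissim.to_frame().to_csv(out / "dissimilarity.tsv", sep="\t", index_label="genome")
    result = pco(dissim)
    result.coordinates.to_csv(out / "coordinates.tsv", sep="\t", index_label="genome")
    eig_df = pd.DataFrame(
        {
            "axis": [f"PCO{i + 1}" for i in range(len(result.eigenvalues))],
            "eigenvalue": [f"{v:.10g}" for v in result.eigenvalues],
        }
    )
    var_map = {
        f"PCO{i + 1}": f"{result.variance_explained[i]:.4f}"
        for i in range(result.n_axes)
    }
    eig_df["variance_explained_pct"] = [var_map.get(a, "") for a in eig_df["axis"]]
    _write_tsv(eig_df, out / "eigenvalues.tsv")

    # --- provenance ---------------------------------------------------------
    artifacts = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "provenance.json"
    )
    provenance = {
        "fesurvey_version": __version__,
        "rng_seed": config.rng_seed if config.cohort is None else config.cohort.rng_seed,
        "policy": dataclasses.asdict(config.policy),
        "synteny": {"k": config.synteny_k, "w": config.synteny_w},
        "n_genomes": len(proteomes),
        "families": family_names,
        "motif_patterns": [p.pattern_id for p in library],
        "artifact_hashes": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return PipelineResult(
        out_dir=out,
        proteomes=proteomes,
        truth=truth,
        motif_tables=motif_tables,
        fractions=fractions,
        calls=calls,
        presence=presence,
        matrix=matrix,
        summaries=summaries,
        dissimilarity=dissim,
        ordination=result,
    )
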