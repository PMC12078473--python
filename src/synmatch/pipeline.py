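"""End-to-end orchestration: filter -> normalize -> DE per study -> call ->
integrate -> QC -> classify -> enrich -> pair-score -> rank."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as sio
from .deg import (
    call_degs,
    contamination_score,
    filter_min_counts,
    integrate_deg_sets,
    test_differential_expression,
)
from .scoring import classify_interneuron_subpopulations, score_population
from .simulate import MICROGLIAL_MARKERS, ScenarioBundle
from .types import (
    CountMatrix,
    DEGCallSet,
    InterneuronProfile,
    LigandReceptorTable,
    PipelineConfig,
    SampleTable,
    ValidationError,
)

logger = logging.getLogger("synmatch")

#: Config keys that must be stated explicitly in a pipeline config file —
#: the decision thresholds are the contract of a run.
REQUIRED_PARAM_KEYS = ("min_count", "fc_threshold", "alpha")


@dataclass
class PipelineResult:
    deg_tables: dict  # study_id -> DataFrame
    call_sets: dict  # study_id -> DEGCallSet
    integrated: DEGCallSet
    qc_reports: dict  # study_id -> DataFrame
    ranked: dict  # population -> DataFrame
    enrichments: dict  # population -> {receptor -> EnrichmentRecord}
    manifest: dict = field(default_factory=dict)


def run_on_bundle(
    studies: Sequence[tuple[CountMatrix, SampleTable]],
    profile: InterneuronProfile,
    pairs: LigandReceptorTable,
    config: Optional[PipelineConfig] = None,
    qc_markers: Sequence[str] = MICROGLIAL_MARKERS,
    fc_study_ids: Optional[Sequence[str]] = None,
    study_roles: Optional[dict] = None,
    use_provided_labels: bool = False,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    ``study_roles`` maps study_id to one of primary/reference/early for the
    integration rule; with fewer than three studies the integration
    degenerates to the union of the available call sets. ``fc_study_ids``
    selects the studies whose expression feeds the L5 fold-change score
    (default: primary and reference when roles are known, else all).
    """
    config = config or PipelineConfig()
    if not studies:
        raise ValidationError("no studies supplied")
    t0 = time.perf_counter()

    matrices = [cm for cm, _ in studies]
    kept = filter_min_counts(matrices, config.min_count)

    deg_tables: dict[str, pd.DataFrame] = {}
    call_sets: dict[str, DEGCallSet] = {}
    for cm, st in studies:
        table = test_differential_expression(cm, st, kept, config)
        table.attrs["study_id"] = cm.study_id
        deg_tables[cm.study_id] = table
        call_sets[cm.study_id] = call_degs(table, config)

    if study_roles is None:
        ids = [cm.study_id for cm in matrices]
        study_roles = {}
        for role in ("primary", "reference", "early"):
            if role in ids:
                study_roles[role] = role
        if not study_roles and len(ids) >= 3:
            study_roles = {"primary": ids[0], "reference": ids[1], "early": ids[2]}

    if {"primary", "reference", "early"} <= set(study_roles):
        integrated = integrate_deg_sets(
            call_sets[study_roles["primary"]],
            call_sets[study_roles["reference"]],
            call_sets[study_roles["early"]],
            rule=config.integration_rule,
        )
    else:
        # degenerate integration: union of whatever studies exist
        calls: dict[str, str] = {}
        dropped = set()
        for cs in call_sets.values():
            for gene, direction in cs.calls.items():
                if calls.get(gene, direction) != direction:
                    dropped.add(gene)
                else:
                    calls[gene] = direction
        for gene in dropped:
            calls.pop(gene, None)
            logger.warning("gene %s dropped: conflicting directions across studies", gene)
        integrated = DEGCallSet(study_id="integrated", calls=calls)
        logger.info("degenerate integration over %d studies: %d genes", len(call_sets), len(calls))

    qc_reports = {
        cm.study_id: contamination_score(cm, qc_markers, config.qc_flag_z)
        for cm, _ in studies
    }

    # the classification stage runs from markers unless the caller opts in
    # to pre-existing labels; a labeled profile is stripped first so the
    # quantile rules are actually exercised
    if not use_provided_labels and profile.is_labeled:
        profile = InterneuronProfile(profile.expression, None)
    labeled = classify_interneuron_subpopulations(
        profile, config.cck_gene, config.pv_gene, config.q_hi, config.q_lo
    )

    if fc_study_ids is None:
        if {"primary", "reference"} <= set(study_roles):
            fc_study_ids = [study_roles["primary"], study_roles["reference"]]
        else:
            fc_study_ids = list(deg_tables)
    fc_tables = [deg_tables[s] for s in fc_study_ids]

    ranked = {}
    enrichments = {}
    for population in ("IT", "ET"):
        candidates = integrated.genes_toward(population)
        table, enr = score_population(
            fc_tables, candidates, population, labeled, pairs, config
        )
        ranked[population] = table
        enrichments[population] = enr
        logger.info(
            "%s: %d DEG candidates, %d ranked (top: %s)",
            population, len(candidates), len(table),
            table["gene"].iloc[0] if len(table) else "-",
        )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_kept_genes": len(kept),
        "n_integrated_degs": len(integrated.calls),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return PipelineResult(
        deg_tables=deg_tables,
        call_sets=call_sets,
        integrated=integrated,
        qc_reports=qc_reports,
        ranked=ranked,
        enrichments=enrichments,
        manifest=manifest,
    )


def run_bundle_object(bundle: ScenarioBundle, config: Optional[PipelineConfig] = None,
                      **kwargs) -> PipelineResult:
    """Convenience wrapper running the pipeline on a ScenarioBundle."""
    return run_on_bundle(bundle.studies, bundle.profile, bundle.pairs, config, **kwargs)


def run_pipeline(config_path, out_dir=None) -> PipelineResult:
    """Run the pipeline from a YAML config file and write all artifacts.

    The config must name the input files and state the decision thresholds
    (min_count, fc_threshold, alpha) explicitly under ``params``.
    """
    raw = sio.read_config(config_path)
    params = raw.get("params", {})
    config = sio.pipeline_config_from_dict(params, require=REQUIRED_PARAM_KEYS)

    inputs = raw.get("inputs", {})
    study_specs = inputs.get("studies", [])
    if not study_specs:
        raise ValidationError("config missing required key 'inputs.studies'")
    for key in ("profile", "pairs"):
        if key not in inputs:
            raise ValidationError(f"config missing required key 'inputs.{key}'")

    base = Path(config_path).parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    studies = []
    study_roles = {}
    for entry in study_specs:
        for key in ("counts", "metadata"):
            if key not in entry:
                raise ValidationError(f"study entry missing required key {key!r}")
        counts_path = resolve(entry["counts"])
        meta_path = resolve(entry["metadata"])
        for p in (counts_path, meta_path):
            if not p.exists():
                raise ValidationError(f"input file not found: {p}")
        cm, st = sio.read_count_matrix(counts_path, meta_path)
        studies.append((cm, st))
        if "role" in entry:
            study_roles[entry["role"]] = cm.study_id

    profile_path = resolve(inputs["profile"])
    pairs_path = resolve(inputs["pairs"])
    for p in (profile_path, pairs_path):
        if not p.exists():
            raise ValidationError(f"input file not found: {p}")
    labels_path = resolve(inputs["profile_labels"]) if inputs.get("profile_labels") else None
    use_labels = bool(raw.get("scoring", {}).get("use_provided_labels", False))
    profile = sio.read_interneuron_profile(
        profile_path, labels_path if use_labels else None
    )
    kwargs_labels = use_labels
    pairs = sio.read_lr_pairs(pairs_path)

    qc_markers = raw.get("qc", {}).get("marker_genes", list(MICROGLIAL_MARKERS))
    fc_study_ids = raw.get("scoring", {}).get("fc_studies")

    result = run_on_bundle(
        studies, profile, pairs, config,
        qc_markers=qc_markers,
        fc_study_ids=fc_study_ids,
        study_roles=study_roles or None,
        use_provided_labels=kwargs_labels,
    )

    out = Path(out_dir) if out_dir is not None else resolve(raw.get("out_dir", "synmatch_run"))
    out.mkdir(parents=True, exist_ok=True)
    for study_id, table in result.deg_tables.items():
        sio.write_deg_table(table, out / f"deg_{study_id}.tsv")
    for study_id, report in result.qc_reports.items():
        report.to_csv(out / f"qc_{study_id}.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame(
        sorted(result.integrated.calls.items()), columns=["gene", "direction"]
    ).to_csv(out / "integrated_degs.tsv", sep="\t", index=False)
    for population, table in result.ranked.items():
        sio.write_ranked_candidates(table, out / f"ranked_{population}.tsv")
        enr = result.enrichments[population]
        pd.DataFrame(
            [
                {
                    "receptor": r.receptor_gene,
                    "target_class": r.target_class,
                    "log2_enrichment": r.log2_enrichment,
                    "retained": r.retained,
                }
                for r in sorted(enr.values(), key=lambda e: e.receptor_gene)
            ]
        ).to_csv(out / f"enrichment_{population}.tsv", sep="\t", index=False,
                 float_format="%.10g")
    result.manifest["seed"] = raw.get("seed")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline artifacts written to %s", out)
    return result
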