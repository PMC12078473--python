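"""Readers and writers for the pipeline's tabular formats.

All tables are plain TSV with a header row. Gene IDs are case-sensitive and
matched exactly across bulk studies, the interneuron profile and the pair
table; any mismatch surfaces as a loud validation error rather than a silent
drop.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    CountMatrix,
    InterneuronProfile,
    LigandReceptorTable,
    PipelineConfig,
    SampleTable,
    ValidationError,
)

logger = logging.getLogger("synmatch")

PathLike = Union[str, Path]

RANKED_COLUMNS = (
    "gene",
    "population",
    "fc_score",
    "specificity_raw",
    "specificity_scaled",
    "total_score",
    "rank",
)


def read_count_matrix(path: PathLike, metadata_path: PathLike) -> tuple[CountMatrix, SampleTable]:
    """Read a gene x sample count TSV plus its sample metadata TSV.

    The count file has a header row of sample IDs and gene IDs in the first
    column. Metadata must cover exactly the samples of the matrix.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "study_id": str})
    samples = SampleTable(meta)
    matrix_samples = set(raw.columns)
    meta_samples = set(samples.sample_ids)
    missing_meta = sorted(matrix_samples - meta_samples)
    if missing_meta:
        raise ValidationError(f"sample {missing_meta[0]!r} in count matrix has no metadata row")
    missing_matrix = sorted(meta_samples - matrix_samples)
    if missing_matrix:
        raise ValidationError(f"sample {missing_matrix[0]!r} in metadata absent from count matrix")
    study_ids = meta["study_id"].unique()
    if len(study_ids) != 1:
        raise ValidationError(f"metadata mixes studies {sorted(study_ids)}; one study per matrix")
    # order samples as in metadata for deterministic downstream output
    counts = CountMatrix(raw[samples.sample_ids], study_id=str(study_ids[0]))
    logger.info(
        "read count matrix %s: %d genes x %d samples (study %s)",
        path, len(counts.gene_ids), len(counts.sample_ids), counts.study_id,
    )
    return counts, samples


def write_count_matrix(counts: CountMatrix, samples: SampleTable,
                       path: PathLike, metadata_path: PathLike) -> None:
    counts.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    samples.table.to_csv(metadata_path, sep="\t", index=False)


def read_lr_pairs(path: PathLike) -> LigandReceptorTable:
    """Read a 2- or 3-column delimited ligand-receptor pair list.

    The delimiter (tab or comma) is sniffed from the first data line. A
    header line is recognized by its first field starting with
    ``postsynaptic``. Duplicate (post, pre) rows are collapsed with a
    logged warning; otherwise row order is preserved.
    """
    lines = Path(path).read_text().splitlines()
    rows = []
    seen = set()
    n_dup = 0
    delim: Optional[str] = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if delim is None:
            delim = "\t" if "\t" in line else ","
        fields = [f.strip() for f in line.split(delim)]
        if lineno == 1 and fields[0].lower().startswith("postsynaptic"):
            continue
        if not 2 <= len(fields) <= 3:
            raise ValidationError(f"line {lineno}: expected 2-3 fields, got {len(fields)}")
        if any(not f for f in fields[:2]):
            raise ValidationError(f"line {lineno}: empty gene field")
        key = (fields[0], fields[1])
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        rows.append({
            "postsynaptic_gene": fields[0],
            "presynaptic_gene": fields[1],
            "source_tag": fields[2] if len(fields) == 3 else "",
        })
    if not rows:
        raise ValidationError(f"pair file {path} contains no pairs")
    if n_dup:
        logger.warning("collapsed %d duplicate pair row(s) in %s", n_dup, path)
    return LigandReceptorTable(pd.DataFrame(rows))


def write_lr_pairs(pairs: LigandReceptorTable, path: PathLike) -> None:
    pairs.pairs.to_csv(path, sep="\t", index=False)


def read_interneuron_profile(path: PathLike,
                             labels_path: Optional[PathLike] = None) -> InterneuronProfile:
    """Read a cell x gene expression TSV, optionally with a label TSV
    (columns cell_id, subpopulation)."""
    expr = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        for col in ("cell_id", "subpopulation"):
            if col not in lab.columns:
                raise ValidationError(f"label table missing column {col!r}")
        labels = lab.set_index("cell_id")["subpopulation"]
    return InterneuronProfile(expr, labels)


def write_interneuron_profile(profile: InterneuronProfile, path: PathLike,
                              labels_path: Optional[PathLike] = None) -> None:
    profile.expression.rename_axis("cell_id").to_csv(path, sep="\t", float_format="%.6g")
    if labels_path is not None and profile.subpopulation is not None:
        (profile.subpopulation.rename("subpopulation").rename_axis("cell_id")
         .reset_index().to_csv(labels_path, sep="\t", index=False))


def write_ranked_candidates(table: pd.DataFrame, path: PathLike) -> None:
    """Write a ranked candidate table as TSV.

    The input must already be sorted by rank, with ranks consecutive from 1.
    Output bytes are deterministic for a fixed table.
    """
    missing = [c for c in RANKED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"ranked table missing columns: {missing}")
    ranks = table["rank"].to_numpy()
    if len(ranks) and not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
        raise ValidationError("ranks must be consecutive from 1")
    out = table.loc[:, list(RANKED_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_deg_table(deg: pd.DataFrame, path: PathLike) -> None:
    cols = ["log2fc", "p_raw", "p_adj", "called", "direction"]
    out = deg.loc[:, [c for c in cols if c in deg.columns]]
    out.rename_axis("gene").to_csv(path, sep="\t", float_format="%.10g")


def read_config(path: PathLike) -> dict:
    """Load a YAML (or JSON, a YAML subset) pipeline or scenario config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return data


def pipeline_config_from_dict(params: dict, require: tuple[str, ...] = ()) -> PipelineConfig:
    for key in require:
        if key not in params:
            raise ValidationError(f"config missing required key {key!r}")
    return PipelineConfig.from_mapping(params)
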