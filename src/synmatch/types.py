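"""Core domain types shared across the pipeline.

Every container validates its invariants at construction time and raises
:class:`ValidationError` with a message naming the offending entry, so that
malformed inputs fail loudly at the boundary rather than corrupting a score
three stages later.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

POPULATIONS = ("IT", "ET")

#: Interneuron target classes whose connectivity specificity is scored.
TARGET_CLASSES = ("PV", "CCK")


class ValidationError(ValueError):
    """A domain object or input file violated one of its invariants."""


def other_population(population: str) -> str:
    if population not in POPULATIONS:
        raise ValidationError(f"unknown population {population!r}; expected one of {POPULATIONS}")
    return "ET" if population == "IT" else "IT"


def _check_unique(values, what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise ValidationError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class CountMatrix:
    """Gene x sample matrix of raw read counts for one bulk RNA-seq study.

    ``counts`` is indexed by gene ID with sample IDs as columns; entries are
    non-negative integers (read counts).
    """

    counts: pd.DataFrame
    study_id: str

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene ID")
        _check_unique(self.counts.columns, "sample ID")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValidationError("counts must be numeric")
            neg = np.argwhere(values < 0)
            if neg.size:
                g, s = neg[0]
                raise ValidationError(
                    f"negative count {values[g, s]} at gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
            frac = np.argwhere(values != np.floor(values))
            if frac.size:
                g, s = frac[0]
                raise ValidationError(
                    f"non-integer count {values[g, s]} at gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
        self.counts = self.counts.astype(np.int64).rename_axis("gene_id")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class SampleTable:
    """Sample metadata: study membership, population (IT/ET) and replicate."""

    table: pd.DataFrame  # columns: sample_id, study_id, population, replicate

    REQUIRED = ("sample_id", "study_id", "population", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        _check_unique(self.table["sample_id"], "sample ID")
        bad = set(self.table["population"]) - set(POPULATIONS)
        if bad:
            raise ValidationError(f"unknown population labels {sorted(bad)}; expected {POPULATIONS}")
        reps = self.table["replicate"].to_numpy()
        if np.any(reps != np.floor(reps)) or np.any(reps < 1):
            raise ValidationError("replicate must be a positive integer")
        for study, grp in self.table.groupby("study_id"):
            for pop in POPULATIONS:
                n = int((grp["population"] == pop).sum())
                if n < 2:
                    raise ValidationError(
                        f"study {study!r} has {n} {pop} sample(s); >=2 per population "
                        "are required for dispersion estimation"
                    )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_in(self, population: str) -> list[str]:
        if population not in POPULATIONS:
            raise ValidationError(f"unknown population {population!r}")
        mask = self.table["population"] == population
        return list(self.table.loc[mask, "sample_id"])


@dataclass
class LigandReceptorTable:
    """Postsynaptic gene <-> presynaptic partner pairs (homophilic allowed)."""

    pairs: pd.DataFrame  # columns: postsynaptic_gene, presynaptic_gene, source_tag

    def __post_init__(self) -> None:
        for col in ("postsynaptic_gene", "presynaptic_gene"):
            if col not in self.pairs.columns:
                raise ValidationError(f"pair table missing column {col!r}")
        if "source_tag" not in self.pairs.columns:
            self.pairs = self.pairs.assign(source_tag="")
        dup = self.pairs.duplicated(subset=["postsynaptic_gene", "presynaptic_gene"])
        if dup.any():
            row = self.pairs.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate pair ({row['postsynaptic_gene']}, {row['presynaptic_gene']})"
            )
        self.pairs = self.pairs.reset_index(drop=True)

    def partners_of(self, postsynaptic_gene: str) -> list[str]:
        mask = self.pairs["postsynaptic_gene"] == postsynaptic_gene
        return list(self.pairs.loc[mask, "presynaptic_gene"])

    @property
    def postsynaptic_genes(self) -> list[str]:
        return list(pd.unique(self.pairs["postsynaptic_gene"]))


@dataclass
class InterneuronProfile:
    """Cell x gene expression with per-cell interneuron subpopulation labels.

    ``subpopulation`` may be ``None`` for an unlabeled profile awaiting
    marker-based classification; all labeled profiles must contain at least
    two distinct subpopulations.
    """

    expression: pd.DataFrame  # cells x genes, non-negative
    subpopulation: Optional[pd.Series] = None  # indexed by cell ID

    def __post_init__(self) -> None:
        _check_unique(self.expression.index, "cell ID")
        _check_unique(self.expression.columns, "gene ID")
        values = self.expression.to_numpy()
        if values.size and (values < 0).any():
            c, g = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression at cell {self.expression.index[c]!r}, "
                f"gene {self.expression.columns[g]!r}"
            )
        self.expression = self.expression.rename_axis("cell_id")
        if self.subpopulation is not None:
            self.subpopulation = self.subpopulation.reindex(self.expression.index)
            if self.subpopulation.isna().any():
                cell = self.subpopulation.index[self.subpopulation.isna()][0]
                raise ValidationError(f"cell {cell!r} has no subpopulation label")
            if self.subpopulation.nunique() < 2:
                raise ValidationError(
                    "labeled profile must contain >=2 distinct subpopulations"
                )

    @property
    def cell_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def is_labeled(self) -> bool:
        return self.subpopulation is not None

    def cells_in(self, subpopulation: str) -> list[str]:
        if self.subpopulation is None:
            raise ValidationError("profile is unlabeled")
        return list(self.subpopulation.index[self.subpopulation == subpopulation])

    def subpopulations(self) -> list[str]:
        if self.subpopulation is None:
            raise ValidationError("profile is unlabeled")
        return sorted(self.subpopulation.unique())


@dataclass(frozen=True)
class EnrichmentRecord:
    """log2 enrichment of one receptor in a target interneuron class."""

    receptor_gene: str
    target_class: str
    log2_enrichment: float

    @property
    def retained(self) -> bool:
        # Only receptors positively enriched in the target class count as
        # evidence of a matching partner.
        return self.log2_enrichment > 0


@dataclass
class DEGCallSet:
    """Set of differential-expression calls (gene -> direction) for a study."""

    study_id: str
    calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {d for d in self.calls.values()} - set(POPULATIONS)
        if bad:
            raise ValidationError(f"unknown call directions {sorted(bad)}")

    @property
    def genes(self) -> set[str]:
        return set(self.calls)

    def genes_toward(self, population: str) -> set[str]:
        if population not in POPULATIONS:
            raise ValidationError(f"unknown population {population!r}")
        return {g for g, d in self.calls.items() if d == population}


_INTEGRATION_RULES = ("union_then_early", "union_all")
_COMBINATIONS = ("sum", "product")
_BASELINES = ("subpop_mean", "pooled")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the canonical defaults.

    The defaults encode the published decision rules: genes need >=10 reads
    in every sample of every study, differential expression requires a
    1.5-fold change and a Bonferroni-adjusted p below 0.05.
    """

    min_count: int = 10
    fc_threshold: float = 1.5
    alpha: float = 0.05
    correction: str = "bonferroni"
    pseudocount: float = 0.5          # on normalized group means (bulk fold changes)
    enrichment_pseudocount: float = 0.1  # on interneuron class means
    q_hi: float = 0.75                # "high" marker expression quantile (nonzero values)
    q_lo: float = 0.50                # "moderate/low" marker expression quantile
    cck_gene: str = "Cck"
    pv_gene: str = "Pvalb"
    integration_rule: str = "union_then_early"
    score_combination: str = "sum"
    enrichment_baseline: str = "subpop_mean"
    dispersion_floor: float = 1e-8
    qc_flag_z: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValidationError("min_count must be >= 0")
        if self.fc_threshold < 1:
            raise ValidationError("fc_threshold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.pseudocount < 0 or self.enrichment_pseudocount < 0:
            raise ValidationError("pseudocounts must be >= 0")
        if self.correction != "bonferroni":
            raise ValidationError(f"unknown correction {self.correction!r}")
        if self.integration_rule not in _INTEGRATION_RULES:
            raise ValidationError(
                f"unknown integration_rule {self.integration_rule!r}; expected {_INTEGRATION_RULES}"
            )
        if self.score_combination not in _COMBINATIONS:
            raise ValidationError(
                f"unknown score_combination {self.score_combination!r}; expected {_COMBINATIONS}"
            )
        if self.enrichment_baseline not in _BASELINES:
            raise ValidationError(
                f"unknown enrichment_baseline {self.enrichment_baseline!r}; expected {_BASELINES}"
            )
        if not 0 < self.q_lo <= 1 or not 0 < self.q_hi <= 1:
            raise ValidationError("classification quantiles must be in (0, 1]")
        if self.dispersion_floor <= 0:
            raise ValidationError("dispersion_floor must be > 0")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise ValidationError(f"unknown config key {sorted(unknown)[0]!r}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
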