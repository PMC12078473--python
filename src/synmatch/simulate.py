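"""Ground-truth-labeled synthetic data for every pipeline stage.

The generator emulates the three input classes the analysis consumes:
negative-binomial bulk count studies with planted IT/ET log2 fold changes
(and optional microglial contamination of chosen ET samples), interneuron
expression profiles with planted receptor enrichments in named
subpopulations, and a ligand-receptor pair table mixing planted matches
with explicitly typed decoys (no partner / unenriched partner /
wrong-class partner), so tests can assert not just that a decoy loses but
why it should.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CountMatrix,
    InterneuronProfile,
    LigandReceptorTable,
    SampleTable,
    ValidationError,
)

#: Canonical microglial marker panel used for the contamination QC.
MICROGLIAL_MARKERS = ("C1qa", "C1qb", "Csf1r", "Cx3cr1", "P2ry12", "Tmem119", "Trem2", "Hexb")

DECOY_TYPES = ("no_partner", "unenriched_partner", "wrong_class_partner")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion a (var = mu + a*mu^2)."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = r / (r + np.maximum(mean, 1e-300))
    return rng.negative_binomial(r, p)


def simulate_bulk_study(
    n_genes: int,
    n_per_group: int,
    baseline_mean,
    dispersion: float,
    planted_log2fc,
    seed: int,
    study_id: str = "sim",
    gene_ids: Optional[Sequence[str]] = None,
    libsize_sigma: float = 0.2,
) -> tuple[CountMatrix, SampleTable]:
    """Simulate one two-population bulk RNA-seq study.

    Group means are ``baseline * 2**(+lfc/2)`` for IT and ``2**(-lfc/2)``
    for ET (positive planted lfc = IT-enriched), so the baseline is the
    geometric mean of the two groups. Per-sample library-size factors are
    log-normal with the given sigma. Deterministic for a fixed seed.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if dispersion <= 0:
        raise ValidationError("dispersion must be > 0")
    baseline = np.broadcast_to(np.asarray(baseline_mean, dtype=float), (n_genes,)).copy()
    if (baseline <= 0).any():
        raise ValidationError("baseline_mean must be > 0")
    lfc = np.broadcast_to(np.asarray(planted_log2fc, dtype=float), (n_genes,)).copy()
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValidationError("gene_ids length must equal n_genes")

    rng = _rng(seed)
    n_samples = 2 * n_per_group
    size_factors = rng.lognormal(0.0, libsize_sigma, n_samples)
    mu_it = baseline * 2.0 ** (lfc / 2.0)
    mu_et = baseline * 2.0 ** (-lfc / 2.0)
    mu = np.concatenate(
        [np.repeat(mu_it[:, None], n_per_group, axis=1),
         np.repeat(mu_et[:, None], n_per_group, axis=1)],
        axis=1,
    ) * size_factors[None, :]
    counts = _nb_draw(rng, mu, dispersion)

    sample_ids = [f"{study_id}_IT_{i+1}" for i in range(n_per_group)] + \
                 [f"{study_id}_ET_{i+1}" for i in range(n_per_group)]
    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "study_id": study_id,
            "population": ["IT"] * n_per_group + ["ET"] * n_per_group,
            "replicate": list(range(1, n_per_group + 1)) * 2,
        }
    )
    return CountMatrix(frame, study_id=study_id), SampleTable(meta)


def simulate_interneuron_profiles(
    n_cells_per_subpop: int,
    subpops: Sequence[str],
    baseline,
    planted_enrichments: Mapping[tuple[str, str], float],
    noise_dispersion: float,
    seed: int,
    gene_ids: Optional[Sequence[str]] = None,
    n_genes: Optional[int] = None,
) -> InterneuronProfile:
    """Simulate a labeled interneuron expression profile.

    Expression is NB around ``baseline * multiplier`` where the multiplier
    comes from ``planted_enrichments[(gene, subpop)]`` (1 elsewhere).
    """
    if "PV" not in subpops or "CCK" not in subpops:
        raise ValidationError("subpops must include PV and CCK")
    if noise_dispersion <= 0:
        raise ValidationError("noise_dispersion must be > 0")
    if gene_ids is None:
        if n_genes is None:
            raise ValidationError("provide gene_ids or n_genes")
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    baseline = np.broadcast_to(np.asarray(baseline, dtype=float), (len(gene_ids),)).copy()
    for (gene, subpop), mult in planted_enrichments.items():
        if subpop not in subpops:
            raise ValidationError(f"unknown subpopulation {subpop!r} in planted enrichments")
        if gene not in gene_index:
            raise ValidationError(f"unknown gene {gene!r} in planted enrichments")
        if mult <= 0:
            raise ValidationError("planted multipliers must be > 0")

    rng = _rng(seed)
    blocks = []
    cell_ids = []
    labels = []
    for subpop in subpops:
        mean = baseline.copy()
        for (gene, sp), mult in planted_enrichments.items():
            if sp == subpop:
                mean[gene_index[gene]] *= mult
        mu = np.repeat(mean[None, :], n_cells_per_subpop, axis=0)
        blocks.append(_nb_draw(rng, mu, noise_dispersion).astype(float))
        cell_ids += [f"{subpop}_{i+1}" for i in range(n_cells_per_subpop)]
        labels += [subpop] * n_cells_per_subpop
    expr = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(cell_ids, name="cell_id"), columns=list(gene_ids)
    )
    return InterneuronProfile(expr, pd.Series(labels, index=expr.index, name="subpopulation"))


@dataclass
class ScenarioConfig:
    """Study conditions for a full synthetic scenario.

    Defaults mirror the replicate structure of the real analysis: three
    bulk studies with three replicates per population, and five interneuron
    subpopulations of 50 cells each.
    """

    n_genes: int = 2000
    n_studies: int = 3
    n_per_group: int = 3
    bulk_baseline_range: tuple[float, float] = (20.0, 2000.0)
    bulk_dispersion: float = 0.05
    libsize_sigma: float = 0.2

    candidate_it: str = "Cdh12"
    candidate_et: str = "Cdh13"
    #: set False for a decoy-only scenario: the candidate genes then carry
    #: no bulk effect and no partner enrichment
    plant_candidates: bool = True
    candidate_log2fc: float = 2.0
    candidate_baseline: float = 300.0
    n_decoys_per_population: int = 50
    decoy_log2fc_range: tuple[float, float] = (0.7, 1.8)
    decoy_baseline_range: tuple[float, float] = (100.0, 1000.0)
    n_background_pairs: int = 20

    subpops: tuple[str, ...] = ("PV", "CCK", "Sst", "Vip", "Lamp5")
    n_cells_per_subpop: int = 50
    profile_baseline_range: tuple[float, float] = (0.2, 20.0)
    profile_dispersion: float = 0.3
    marker_baseline: float = 2.0
    marker_multiplier: float = 25.0
    receptor_baseline: float = 2.0
    receptor_multiplier: float = 4.0

    contamination_fraction: float = 0.0
    n_contaminated_samples: int = 1
    contamination_mean: float = 1000.0
    microglial_baseline: float = 5.0

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ScenarioConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise ValidationError(f"unknown scenario config key {sorted(unknown)[0]!r}")
        kwargs = dict(mapping)
        for key, value in kwargs.items():
            if isinstance(value, list):
                kwargs[key] = tuple(value)
        return cls(**kwargs)


@dataclass
class ScenarioTruth:
    """Everything planted into a scenario, for recovery assertions."""

    planted_log2fc: pd.Series  # signed, positive = IT-enriched
    planted_candidate_it: str
    planted_candidate_et: str
    planted_receptor_enrichments: dict  # (gene, subpop) -> multiplier
    decoys: pd.DataFrame  # columns: gene, population, decoy_type, partner
    contamination_samples: list[str]
    contamination_fraction: float
    rng_seed: int


@dataclass
class ScenarioBundle:
    studies: list[tuple[CountMatrix, SampleTable]]
    profile: InterneuronProfile
    pairs: LigandReceptorTable
    truth: ScenarioTruth


def make_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> ScenarioBundle:
    """Generate a complete input bundle with planted candidates and decoys.

    The planted IT candidate is a true DEG toward IT in every study and is
    paired (homophilically) with itself, enriched in CCK+ cells; the ET
    candidate mirrors this with PV+ cells. Decoy DEGs cycle through the
    three decoy types. Optional contamination adds a microglial signature
    to chosen ET samples of the primary study.
    """
    config = config or ScenarioConfig()
    master = _rng(seed)
    child = lambda: int(master.integers(2**31))  # noqa: E731

    special = [config.candidate_it, config.candidate_et, "Cck", "Pvalb", *MICROGLIAL_MARKERS]
    n_decoys = 2 * config.n_decoys_per_population
    n_receptors = n_decoys + 2 * config.n_background_pairs
    receptor_genes = [f"r{i:03d}" for i in range(n_receptors)]
    n_generic = config.n_genes - len(special) - n_receptors
    if n_generic < n_decoys:
        raise ValidationError("n_genes too small for the requested decoys and receptors")
    generic = [f"g{i:04d}" for i in range(n_generic)]
    gene_ids = special + receptor_genes + generic

    # ---- planted bulk effects -------------------------------------------
    struct_rng = _rng(child())
    lfc = pd.Series(0.0, index=gene_ids)
    planted_enr: dict[tuple[str, str], float] = {
        ("Cck", "CCK"): config.marker_multiplier,
        ("Pvalb", "PV"): config.marker_multiplier,
    }
    if config.plant_candidates:
        lfc[config.candidate_it] = config.candidate_log2fc
        lfc[config.candidate_et] = -config.candidate_log2fc
        planted_enr[(config.candidate_it, "CCK")] = config.receptor_multiplier
        planted_enr[(config.candidate_et, "PV")] = config.receptor_multiplier
    decoy_genes = list(struct_rng.choice(generic, size=n_decoys, replace=False))
    decoy_rows = []
    receptor_cursor = 0
    pair_rows = [
        (config.candidate_it, config.candidate_it, "planted"),
        (config.candidate_et, config.candidate_et, "planted"),
    ]
    lo, hi = config.decoy_log2fc_range
    for k, gene in enumerate(decoy_genes):
        population = "IT" if k < config.n_decoys_per_population else "ET"
        sign = 1.0 if population == "IT" else -1.0
        lfc[gene] = sign * struct_rng.uniform(lo, hi)
        decoy_type = DECOY_TYPES[k % len(DECOY_TYPES)]
        partner = ""
        if decoy_type != "no_partner":
            partner = receptor_genes[receptor_cursor]
            receptor_cursor += 1
            pair_rows.append((gene, partner, f"decoy:{decoy_type}"))
            if decoy_type == "wrong_class_partner":
                wrong = "PV" if population == "IT" else "CCK"
                planted_enr[(partner, wrong)] = config.receptor_multiplier
        decoy_rows.append(
            {"gene": gene, "population": population, "decoy_type": decoy_type, "partner": partner}
        )
    # background pairs between non-DEG genes keep the table from being
    # informative by mere membership
    background_post = list(
        struct_rng.choice([g for g in generic if g not in decoy_genes],
                          size=config.n_background_pairs, replace=False)
    )
    for gene in background_post:
        partner = receptor_genes[receptor_cursor]
        receptor_cursor += 1
        pair_rows.append((gene, partner, "background"))
    pairs = LigandReceptorTable(
        pd.DataFrame(pair_rows, columns=["postsynaptic_gene", "presynaptic_gene", "source_tag"])
    )

    # ---- bulk studies ---------------------------------------------------
    b_lo, b_hi = config.bulk_baseline_range
    baseline = np.exp(struct_rng.uniform(np.log(b_lo), np.log(b_hi), len(gene_ids)))
    baseline = pd.Series(baseline, index=gene_ids)
    baseline[config.candidate_it] = config.candidate_baseline
    baseline[config.candidate_et] = config.candidate_baseline
    d_lo, d_hi = config.decoy_baseline_range
    baseline[decoy_genes] = np.exp(
        struct_rng.uniform(np.log(d_lo), np.log(d_hi), len(decoy_genes))
    )
    baseline[list(MICROGLIAL_MARKERS)] = config.microglial_baseline

    study_ids = ["primary", "reference", "early"][: config.n_studies]
    if config.n_studies > 3:
        study_ids += [f"extra{i}" for i in range(config.n_studies - 3)]
    studies = []
    for study_id in study_ids:
        cm, st = simulate_bulk_study(
            n_genes=len(gene_ids),
            n_per_group=config.n_per_group,
            baseline_mean=baseline.to_numpy(),
            dispersion=config.bulk_dispersion,
            planted_log2fc=lfc.to_numpy(),
            seed=child(),
            study_id=study_id,
            gene_ids=gene_ids,
            libsize_sigma=config.libsize_sigma,
        )
        studies.append((cm, st))

    # ---- contamination --------------------------------------------------
    contaminated: list[str] = []
    if config.contamination_fraction > 0:
        cm, st = studies[0]
        et_samples = st.samples_in("ET")
        contaminated = et_samples[: config.n_contaminated_samples]
        contam_rng = _rng(child())
        extra_mean = config.contamination_fraction * config.contamination_mean
        for sample in contaminated:
            extra = _nb_draw(
                contam_rng,
                np.full(len(MICROGLIAL_MARKERS), extra_mean),
                config.bulk_dispersion,
            )
            cm.counts.loc[list(MICROGLIAL_MARKERS), sample] += extra

    # ---- interneuron profile -------------------------------------------
    p_lo, p_hi = config.profile_baseline_range
    prof_baseline = np.exp(struct_rng.uniform(np.log(p_lo), np.log(p_hi), len(gene_ids)))
    prof_baseline = pd.Series(prof_baseline, index=gene_ids)
    prof_baseline[["Cck", "Pvalb"]] = config.marker_baseline
    prof_baseline[receptor_genes] = config.receptor_baseline
    prof_baseline[[config.candidate_it, config.candidate_et]] = config.receptor_baseline
    profile = simulate_interneuron_profiles(
        n_cells_per_subpop=config.n_cells_per_subpop,
        subpops=list(config.subpops),
        baseline=prof_baseline.to_numpy(),
        planted_enrichments=planted_enr,
        noise_dispersion=config.profile_dispersion,
        seed=child(),
        gene_ids=gene_ids,
    )

    truth = ScenarioTruth(
        planted_log2fc=lfc,
        planted_candidate_it=config.candidate_it,
        planted_candidate_et=config.candidate_et,
        planted_receptor_enrichments=planted_enr,
        decoys=pd.DataFrame(decoy_rows),
        contamination_samples=contaminated,
        contamination_fraction=config.contamination_fraction,
        rng_seed=seed,
    )
    if config.plant_candidates:
        for candidate, target in ((config.candidate_it, "CCK"), (config.candidate_et, "PV")):
            partners = pairs.partners_of(candidate)
            if not partners:
                raise ValidationError(f"planted candidate {candidate!r} absent from pair table")
            if not any(planted_enr.get((p, target), 1.0) > 1.0 for p in partners):
                raise ValidationError(
                    f"planted candidate {candidate!r} has no partner enriched in {target}"
                )
    return ScenarioBundle(studies=studies, profile=profile, pairs=pairs, truth=truth)
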