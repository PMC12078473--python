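"""Matching-partner scoring: from DEG tables and an interneuron profile to a
ranked list of cell-surface candidate genes per L5 population.

The score has two [0, 1]-scaled components per candidate gene:

* an L5 fold-change score — how strongly the gene favors its population
  (IT or ET) in bulk expression, min-max scaled across the population's
  candidate set;
* a presynaptic specificity score — the mean log2 enrichment of the gene's
  positively-enriched ligand-receptor partners in the matching interneuron
  class (CCK+ basket cells for IT candidates, PV+ for ET), min-max scaled
  across the ranked set.

Their combination (sum by default) ranks the candidates.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    EnrichmentRecord,
    InterneuronProfile,
    LigandReceptorTable,
    PipelineConfig,
    ValidationError,
    other_population,
)

logger = logging.getLogger("synmatch")


def _nonzero_quantile(values: np.ndarray, q: float) -> float:
    nz = values[values > 0]
    if nz.size == 0:
        raise ValidationError("marker gene has no nonzero expression; cannot set quantile threshold")
    return float(np.quantile(nz, q))


def classify_interneuron_subpopulations(
    profile: InterneuronProfile,
    cck_gene: str = "Cck",
    pv_gene: str = "Pvalb",
    q_hi: float = 0.75,
    q_lo: float = 0.50,
) -> InterneuronProfile:
    """Label cells as PV, CCK or other by marker-gene quantile rules.

    PV+ cells show high Pvalb (>= the ``q_hi`` quantile of nonzero Pvalb
    values across all cells); CCK+ cells show high Cck together with
    moderate/low Pvalb (<= the ``q_lo`` nonzero quantile). The PV rule wins
    when both fire (logged). If the profile already carries both PV and CCK
    labels, it is validated and returned unchanged.
    """
    if profile.is_labeled:
        present = set(profile.subpopulation.unique())
        if {"PV", "CCK"} <= present:
            return profile
    for gene in (cck_gene, pv_gene):
        if gene not in profile.expression.columns:
            raise ValidationError(f"marker gene {gene!r} absent from profile")
    cck = profile.expression[cck_gene].to_numpy(dtype=float)
    pv = profile.expression[pv_gene].to_numpy(dtype=float)
    t_hi_cck = _nonzero_quantile(cck, q_hi)
    t_hi_pv = _nonzero_quantile(pv, q_hi)
    t_lo_pv = _nonzero_quantile(pv, q_lo)

    is_pv = pv >= t_hi_pv
    is_cck = (cck >= t_hi_cck) & (pv <= t_lo_pv)
    both = is_pv & is_cck
    if both.any():
        logger.info("%d cell(s) matched both PV and CCK rules; PV label wins", int(both.sum()))
    labels = np.where(is_pv, "PV", np.where(is_cck, "CCK", ""))
    if profile.is_labeled:
        other = profile.subpopulation.to_numpy(dtype=object)
    else:
        other = np.full(len(labels), "other", dtype=object)
    final = np.where(labels != "", labels, other)
    series = pd.Series(final, index=profile.expression.index, name="subpopulation")
    if series.nunique() < 2:
        raise ValidationError("classification produced a single class; comparisons undefined")
    labeled = InterneuronProfile(profile.expression, series)
    sizes = series.value_counts().to_dict()
    logger.info("interneuron classification: %s", sizes)
    return labeled


def compute_l5_foldchange_score(
    deg_tables: Sequence[pd.DataFrame],
    candidates: Iterable[str],
    population: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Fold-difference of normalized means toward ``population``, combined
    across studies by geometric mean, then min-max scaled to [0, 1].

    Returns a DataFrame indexed by gene with columns ``fc_raw`` (combined
    fold-difference) and ``fc_score``. With a single candidate, or when all
    candidates tie, every score is 1.
    """
    genes = sorted(set(candidates))
    if not genes:
        return pd.DataFrame(columns=["fc_raw", "fc_score"])
    if not deg_tables:
        raise ValidationError("no DEG tables supplied")
    other = other_population(population)
    col_pop = f"mean_normalized_{population}"
    col_other = f"mean_normalized_{other}"
    log_fold = np.zeros(len(genes))
    for table in deg_tables:
        missing = [g for g in genes if g not in table.index]
        if missing:
            raise ValidationError(f"candidate {missing[0]!r} absent from a DEG table")
        m_pop = table.loc[genes, col_pop].to_numpy(dtype=float)
        m_other = table.loc[genes, col_other].to_numpy(dtype=float)
        zero_both = (m_pop == 0) & (m_other == 0)
        if zero_both.any():
            raise ValidationError(
                f"candidate {genes[int(np.argmax(zero_both))]!r} has zero mean in both populations"
            )
        log_fold += np.log((m_pop + pseudocount) / (m_other + pseudocount))
    fc_raw = np.exp(log_fold / len(deg_tables))  # geometric mean across studies
    lo, hi = fc_raw.min(), fc_raw.max()
    if hi > lo:
        fc_score = (fc_raw - lo) / (hi - lo)
    else:
        fc_score = np.ones_like(fc_raw)
    return pd.DataFrame({"fc_raw": fc_raw, "fc_score": fc_score},
                        index=pd.Index(genes, name="gene"))


def compute_receptor_enrichment(
    profile: InterneuronProfile,
    receptor: str,
    target_class: str,
    pseudocount: float = 0.1,
    baseline: str = "subpop_mean",
) -> EnrichmentRecord:
    """log2 enrichment of a receptor in the target interneuron class.

    The numerator is the receptor's mean expression over target-class cells.
    The denominator under ``baseline='subpop_mean'`` (default) is the
    unweighted mean of the per-subpopulation means over all non-target
    subpopulations, so a single large subpopulation cannot dominate;
    ``baseline='pooled'`` instead pools all non-target cells.
    """
    if receptor not in profile.expression.columns:
        raise ValidationError(f"receptor {receptor!r} absent from profile")
    if not profile.is_labeled:
        raise ValidationError("profile must be labeled before enrichment")
    labels = profile.subpopulation
    target_cells = labels.index[labels == target_class]
    if len(target_cells) == 0:
        raise ValidationError(f"no cells labeled {target_class!r}")
    non_target = [s for s in profile.subpopulations() if s != target_class]
    if not non_target:
        raise ValidationError("no non-target subpopulation")
    expr = profile.expression[receptor]
    target_mean = float(expr.loc[target_cells].mean())
    if baseline == "subpop_mean":
        sub_means = [float(expr.loc[labels.index[labels == s]].mean()) for s in non_target]
        base = float(np.mean(sub_means))
    elif baseline == "pooled":
        base = float(expr.loc[labels.index[labels != target_class]].mean())
    else:
        raise ValidationError(f"unknown enrichment baseline {baseline!r}")
    log2_enr = float(np.log2((target_mean + pseudocount) / (base + pseudocount)))
    return EnrichmentRecord(receptor_gene=receptor, target_class=target_class,
                            log2_enrichment=log2_enr)


def score_candidate_pairs(
    candidates: Iterable[str],
    pairs: LigandReceptorTable,
    enrichments: Mapping[str, EnrichmentRecord],
) -> pd.Series:
    """Average retained-partner enrichments into a per-candidate specificity.

    Only partners with positive enrichment in the target class are retained;
    a candidate whose partners are all unretained, or which has no partner
    in the table at all, is excluded from ranking (and logged), never scored
    zero — "no partner" and "unspecific partner" are different statements.
    """
    scores = {}
    for gene in sorted(set(candidates)):
        partners = pairs.partners_of(gene)
        if not partners:
            logger.info("candidate %s has no partner in the pair table; excluded", gene)
            continue
        missing = [p for p in partners if p not in enrichments]
        if missing:
            raise ValidationError(f"no enrichment computed for partner {missing[0]!r} of {gene!r}")
        retained = [enrichments[p].log2_enrichment for p in partners if enrichments[p].retained]
        if not retained:
            logger.info("candidate %s has no positively enriched partner; excluded", gene)
            continue
        scores[gene] = float(np.mean(retained))
    return pd.Series(scores, name="specificity_raw", dtype=float).rename_axis("gene")


def rank_candidates(
    fc_scores: pd.DataFrame,
    specificity_raw: pd.Series,
    population: str,
    combination: str = "sum",
) -> pd.DataFrame:
    """Combine the two score components and rank candidates.

    specificity_raw is min-max scaled over the ranked set (all-tie or
    singleton -> 1 for every gene, mirroring the fold-change convention);
    total = fc_score + specificity_scaled (``sum``) or their product.
    Ties break by higher fc_score, then lexicographic gene ID.
    """
    if combination not in ("sum", "product"):
        raise ValidationError(f"unknown score combination {combination!r}")
    genes = [g for g in specificity_raw.index if g in fc_scores.index]
    missing = [g for g in specificity_raw.index if g not in fc_scores.index]
    if missing:
        raise ValidationError(f"no fold-change score for ranked gene {missing[0]!r}")
    if not genes:
        return pd.DataFrame(
            columns=["gene", "population", "fc_raw", "fc_score",
                     "specificity_raw", "specificity_scaled", "total_score", "rank"]
        )
    spec = specificity_raw.loc[genes].to_numpy(dtype=float)
    lo, hi = spec.min(), spec.max()
    spec_scaled = (spec - lo) / (hi - lo) if hi > lo else np.ones_like(spec)
    fc = fc_scores.loc[genes, "fc_score"].to_numpy(dtype=float)
    total = fc + spec_scaled if combination == "sum" else fc * spec_scaled
    out = pd.DataFrame(
        {
            "gene": genes,
            "population": population,
            "fc_raw": fc_scores.loc[genes, "fc_raw"].to_numpy(dtype=float),
            "fc_score": fc,
            "specificity_raw": spec,
            "specificity_scaled": spec_scaled,
            "total_score": total,
        }
    )
    out = out.sort_values(
        by=["total_score", "fc_score", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def score_population(
    deg_tables: Sequence[pd.DataFrame],
    candidates: Iterable[str],
    population: str,
    profile: InterneuronProfile,
    pairs: LigandReceptorTable,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, EnrichmentRecord]]:
    """Run the full scoring chain for one population's candidate genes.

    IT candidates are scored against CCK+ basket cells, ET candidates
    against PV+ cells. Returns the ranked table and the partner enrichment
    records used.
    """
    target_class = "CCK" if population == "IT" else "PV"
    candidates = sorted(set(candidates))
    partner_genes = sorted(
        {p for g in candidates for p in pairs.partners_of(g) if p in profile.expression.columns}
    )
    skipped = {p for g in candidates for p in pairs.partners_of(g)} - set(partner_genes)
    if skipped:
        logger.warning(
            "%d partner gene(s) absent from interneuron profile: %s",
            len(skipped), sorted(skipped)[:5],
        )
    enrichments = {
        p: compute_receptor_enrichment(
            profile, p, target_class,
            pseudocount=config.enrichment_pseudocount,
            baseline=config.enrichment_baseline,
        )
        for p in partner_genes
    }
    # only pairs whose partner is measured in the profile can contribute
    usable = LigandReceptorTable(
        pairs.pairs[pairs.pairs["presynaptic_gene"].isin(partner_genes)].copy()
    ) if len(pairs.pairs) else pairs
    spec = score_candidate_pairs(candidates, usable, enrichments)
    fc = compute_l5_foldchange_score(
        deg_tables, spec.index, population, pseudocount=config.pseudocount
    )
    ranked = rank_candidates(fc, spec, population, combination=config.score_combination)
    return ranked, enrichments
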