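import math

import numpy as np
import pandas as pd
import pytest

from synmatch import (
    InterneuronProfile,
    LigandReceptorTable,
    EnrichmentRecord,
    ValidationError,
    classify_interneuron_subpopulations,
    compute_l5_foldchange_score,
    compute_receptor_enrichment,
    rank_candidates,
    score_candidate_pairs,
)
from conftest import make_deg_table


def profile_from(expr_dict, labels=None, cells=None):
    frame = pd.DataFrame(expr_dict, dtype=float)
    if cells is not None:
        frame.index = cells
    lab = pd.Series(labels, index=frame.index) if labels is not None else None
    return InterneuronProfile(frame, lab)


def pairs_from(rows):
    return LigandReceptorTable(
        pd.DataFrame(rows, columns=["postsynaptic_gene", "presynaptic_gene"])
    )


class TestClassification:
    def _profile(self):
        # 20 cells: Cck spans 1..20, Pvalb spans 20..1 -> clear extremes
        cck = np.arange(1.0, 21.0)
        pv = np.arange(20.0, 0.0, -1.0)
        return profile_from({"Cck": cck, "Pvalb": pv},
                            cells=[f"c{i}" for i in range(20)])

    def test_high_cck_low_pvalb_is_cck(self):
        labeled = classify_interneuron_subpopulations(self._profile())
        # top-Cck cells carry the lowest Pvalb
        assert labeled.subpopulation["c19"] == "CCK"
        assert labeled.subpopulation["c0"] == "PV"
        # mid-range cells stay unassigned
        assert labeled.subpopulation["c10"] == "other"

    def test_pv_rule_wins_when_both_fire(self):
        expr = {"Cck": [10.0, 10.0, 1.0, 1.0, 1.0, 1.0],
                "Pvalb": [10.0, 0.0, 1.0, 1.0, 1.0, 1.0]}
        labeled = classify_interneuron_subpopulations(
            profile_from(expr, cells=list("abcdef"))
        )
        assert labeled.subpopulation["a"] == "PV"
        assert labeled.subpopulation["b"] == "CCK"

    def test_all_zero_cell_is_other(self):
        expr = {"Cck": [0.0, 5.0, 9.0, 1.0], "Pvalb": [0.0, 9.0, 1.0, 2.0]}
        labeled = classify_interneuron_subpopulations(
            profile_from(expr, cells=list("wxyz"))
        )
        assert labeled.subpopulation["w"] == "other"

    def test_missing_marker_rejected(self):
        with pytest.raises(ValidationError, match="Pvalb"):
            classify_interneuron_subpopulations(profile_from({"Cck": [1.0, 2.0]}))

    def test_single_class_rejected(self):
        expr = {"Cck": [1.0, 1.0], "Pvalb": [1.0, 1.0]}
        with pytest.raises(ValidationError):
            classify_interneuron_subpopulations(profile_from(expr))

    def test_prelabeled_profile_passes_through(self, labeled_profile):
        out = classify_interneuron_subpopulations(labeled_profile)
        assert out.subpopulation.equals(labeled_profile.subpopulation)


class TestFoldChangeScore:
    def _table(self, means):
        return make_deg_table({
            g: dict(mean_normalized_IT=it, mean_normalized_ET=et)
            for g, (it, et) in means.items()
        })

    def test_min_max_scaling(self):
        table = self._table({"gA": (3.0, 1.0), "gB": (1.5, 1.0), "gC": (1.0, 1.0)})
        out = compute_l5_foldchange_score([table], {"gA", "gB", "gC"}, "IT", pseudocount=0.0)
        assert out.loc["gA", "fc_score"] == pytest.approx(1.0)
        assert out.loc["gB", "fc_score"] == pytest.approx(0.25)
        assert out.loc["gC", "fc_score"] == pytest.approx(0.0)

    def test_single_candidate_scores_one(self):
        table = self._table({"gA": (3.0, 1.0)})
        out = compute_l5_foldchange_score([table], {"gA"}, "IT", pseudocount=0.0)
        assert out.loc["gA", "fc_score"] == 1.0

    def test_geometric_mean_across_studies(self):
        t1 = self._table({"gA": (2.0, 1.0), "gB": (1.0, 1.0)})
        t2 = self._table({"gA": (4.0, 1.0), "gB": (1.0, 1.0)})
        out = compute_l5_foldchange_score([t1, t2], {"gA", "gB"}, "IT", pseudocount=0.0)
        assert out.loc["gA", "fc_raw"] == pytest.approx(math.sqrt(8.0))

    def test_et_direction_uses_reciprocal_means(self):
        table = self._table({"gA": (1.0, 4.0), "gB": (1.0, 2.0)})
        out = compute_l5_foldchange_score([table], {"gA", "gB"}, "ET", pseudocount=0.0)
        assert out.loc["gA", "fc_raw"] == pytest.approx(4.0)

    def test_zero_in_both_populations_rejected(self):
        table = self._table({"gA": (0.0, 0.0)})
        with pytest.raises(ValidationError):
            compute_l5_foldchange_score([table], {"gA"}, "IT")

    def test_empty_candidates_give_empty_output(self):
        table = self._table({"gA": (1.0, 1.0)})
        assert compute_l5_foldchange_score([table], set(), "IT").empty


class TestReceptorEnrichment:
    def _profile(self, target_vals, other_vals):
        n = len(target_vals) + len(other_vals)
        expr = {"R": list(target_vals) + list(other_vals)}
        labels = ["CCK"] * len(target_vals) + ["PV"] * len(other_vals)
        return profile_from(expr, labels, cells=[f"c{i}" for i in range(n)])

    def test_closed_form(self):
        profile = self._profile([8.0, 8.0], [2.0, 2.0])
        rec = compute_receptor_enrichment(profile, "R", "CCK", pseudocount=0.0)
        assert rec.log2_enrichment == pytest.approx(2.0)
        assert rec.retained

    def test_equal_means_not_retained(self):
        profile = self._profile([2.0, 2.0], [2.0, 2.0])
        rec = compute_receptor_enrichment(profile, "R", "CCK", pseudocount=0.0)
        assert rec.log2_enrichment == pytest.approx(0.0)
        assert not rec.retained

    def test_pseudocount_bounds_zero_baseline(self):
        profile = self._profile([8.0, 8.0], [0.0, 0.0])
        rec = compute_receptor_enrichment(profile, "R", "CCK", pseudocount=0.1)
        assert rec.log2_enrichment == pytest.approx(math.log2(8.1 / 0.1), abs=1e-9)

    def test_subpop_mean_baseline_is_unweighted(self):
        # PV mean 4 (2 cells), Sst mean 1 (6 cells): unweighted baseline 2.5
        expr = {"R": [8.0, 4.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]}
        labels = ["CCK"] + ["PV"] * 2 + ["Sst"] * 6
        profile = profile_from(expr, labels, cells=[f"c{i}" for i in range(9)])
        rec = compute_receptor_enrichment(profile, "R", "CCK", pseudocount=0.0)
        assert rec.log2_enrichment == pytest.approx(math.log2(8.0 / 2.5))
        pooled = compute_receptor_enrichment(profile, "R", "CCK", pseudocount=0.0,
                                             baseline="pooled")
        assert pooled.log2_enrichment == pytest.approx(math.log2(8.0 / (14 / 8)))

    def test_scale_invariance_without_pseudocount(self):
        profile = self._profile([8.0, 6.0], [2.0, 3.0])
        scaled = InterneuronProfile(profile.expression * 37.0, profile.subpopulation)
        r1 = compute_receptor_enrichment(profile, "R", "CCK", pseudocount=0.0)
        r2 = compute_receptor_enrichment(scaled, "R", "CCK", pseudocount=0.0)
        assert r1.log2_enrichment == pytest.approx(r2.log2_enrichment, abs=1e-12)

    def test_missing_receptor_rejected(self):
        profile = self._profile([1.0], [1.0])
        with pytest.raises(ValidationError):
            compute_receptor_enrichment(profile, "Nope", "CCK")


def rec(gene, enr, target="CCK"):
    return EnrichmentRecord(gene, target, enr)


class TestPairScoring:
    def test_retained_partners_averaged(self):
        pairs = pairs_from([("cand", "R1"), ("cand", "R2")])
        spec = score_candidate_pairs(
            ["cand"], pairs, {"R1": rec("R1", 2.0), "R2": rec("R2", 1.0)}
        )
        assert spec["cand"] == pytest.approx(1.5)

    def test_homophilic_candidate_uses_own_enrichment(self):
        pairs = pairs_from([("cand", "cand")])
        spec = score_candidate_pairs(["cand"], pairs, {"cand": rec("cand", 3.0)})
        assert spec["cand"] == pytest.approx(3.0)

    def test_negative_partner_not_retained(self):
        pairs = pairs_from([("cand", "R1")])
        spec = score_candidate_pairs(["cand"], pairs, {"R1": rec("R1", -0.5)})
        assert "cand" not in spec.index

    def test_mixed_partners_only_positive_count(self):
        pairs = pairs_from([("cand", "R1"), ("cand", "R2")])
        spec = score_candidate_pairs(
            ["cand"], pairs, {"R1": rec("R1", 2.0), "R2": rec("R2", -1.0)}
        )
        assert spec["cand"] == pytest.approx(2.0)

    def test_no_pairs_excluded_not_error(self):
        pairs = pairs_from([("other", "R1")])
        spec = score_candidate_pairs(["cand"], pairs, {"R1": rec("R1", 1.0)})
        assert len(spec) == 0


class TestRanking:
    def _fc(self, scores):
        frame = pd.DataFrame(
            {"fc_raw": [2.0] * len(scores), "fc_score": list(scores.values())},
            index=pd.Index(scores.keys(), name="gene"),
        )
        return frame

    def test_sum_combination_and_order(self):
        fc = self._fc({"X": 1.0, "Y": 0.25})
        spec = pd.Series({"X": 0.5, "Y": 1.0})
        # raw specs 0.5 and 1.0 min-max to 0 and 1
        out = rank_candidates(fc, spec, "IT")
        assert list(out["gene"]) == ["Y", "X"]
        y = out[out["gene"] == "Y"].iloc[0]
        assert y["total_score"] == pytest.approx(0.25 + 1.0)
        assert list(out["rank"]) == [1, 2]

    def test_tie_breaks_by_fc_then_gene(self):
        fc = self._fc({"b": 0.5, "a": 0.5, "c": 1.0})
        spec = pd.Series({"b": 1.0, "a": 1.0, "c": 1.0})
        # all specificity ties -> scaled 1 for all; c wins on fc; a before b
        out = rank_candidates(fc, spec, "IT")
        assert list(out["gene"]) == ["c", "a", "b"]

    def test_product_combination(self):
        fc = self._fc({"X": 0.5, "Y": 1.0})
        spec = pd.Series({"X": 2.0, "Y": 1.0})
        out = rank_candidates(fc, spec, "IT", combination="product")
        x = out[out["gene"] == "X"].iloc[0]
        assert x["total_score"] == pytest.approx(0.5 * 1.0)

    def test_unknown_combination_rejected(self):
        fc = self._fc({"X": 1.0})
        with pytest.raises(ValidationError):
            rank_candidates(fc, pd.Series({"X": 1.0}), "IT", combination="max")

    def test_scores_stay_in_unit_interval(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(15)]
        fc = pd.DataFrame({"fc_raw": rng.uniform(0.5, 5, 15),
                           "fc_score": rng.uniform(0, 1, 15)},
                          index=pd.Index(genes, name="gene"))
        spec = pd.Series(rng.normal(1, 2, 15), index=genes)
        out = rank_candidates(fc, spec, "ET")
        assert ((out["specificity_scaled"] >= 0) & (out["specificity_scaled"] <= 1)).all()
        assert ((out["total_score"] >= 0) & (out["total_score"] <= 2)).all()
        assert list(out["rank"]) == list(range(1, 16))

    def test_class_relabeling_is_symmetric(self, labeled_profile):
        # swapping the PV and CCK labels mirrors the enrichment values
        swapped = labeled_profile.subpopulation.map(
            {"PV": "CCK", "CCK": "PV", "Sst": "Sst"}
        )
        mirror = InterneuronProfile(labeled_profile.expression, swapped)
        r1 = compute_receptor_enrichment(labeled_profile, "R1", "CCK", pseudocount=0.1)
        r2 = compute_receptor_enrichment(mirror, "R1", "PV", pseudocount=0.1)
        assert r1.log2_enrichment == pytest.approx(r2.log2_enrichment, abs=1e-12)
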