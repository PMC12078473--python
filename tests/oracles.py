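"""Independent straight-line reimplementations used as test oracles.

Everything here is deliberately written with explicit Python loops and
elementary formulas, independently of the vectorized package code, so that
agreement between the two routes is meaningful.
"""

import math

import numpy as np


def oracle_filter_min_counts(study_frames, min_count):
    """Exhaustive scan of every cell of every study."""
    universe = set(study_frames[0].index)
    for frame in study_frames[1:]:
        universe &= set(frame.index)
    survivors = set()
    for gene in universe:
        ok = True
        for frame in study_frames:
            for sample in frame.columns:
                if frame.at[gene, sample] < min_count:
                    ok = False
        if ok:
            survivors.add(gene)
    return survivors


def oracle_size_factors(frame):
    """Median-of-ratios, computed gene by gene."""
    eligible = [g for g in frame.index if all(frame.at[g, s] > 0 for s in frame.columns)]
    geo = {}
    for g in eligible:
        log_sum = 0.0
        for s in frame.columns:
            log_sum += math.log(frame.at[g, s])
        geo[g] = math.exp(log_sum / len(frame.columns))
    factors = {}
    for s in frame.columns:
        ratios = sorted(frame.at[g, s] / geo[g] for g in eligible)
        n = len(ratios)
        if n % 2 == 1:
            factors[s] = ratios[n // 2]
        else:
            factors[s] = 0.5 * (ratios[n // 2 - 1] + ratios[n // 2])
    return factors


def _nb_cumulants(mu, s, a):
    lam = s * mu
    k2 = (lam + a * lam**2) / s**2
    k3 = (lam + 3 * a * lam**2 + 2 * a**2 * lam**3) / s**3
    k4 = (lam + 7 * a * lam**2 + 12 * a**2 * lam**3 + 6 * a**3 * lam**4) / s**4
    return k2, k3, k4


def oracle_de_table(frame, it_samples, et_samples, genes, pseudocount=0.5,
                    alpha=0.05, fc_threshold=1.5, floor=1e-8):
    """Full recomputation of the NB Wald DE table, gene by gene.

    Returns dict gene -> dict with the same quantities as the package's
    DE table.
    """
    from scipy.stats import norm

    sf = oracle_size_factors(frame)
    genes = sorted(genes)
    norm_counts = {
        g: {s: frame.at[g, s] / sf[s] for s in frame.columns} for g in genes
    }
    inv_it = sum(1.0 / sf[s] for s in it_samples) / len(it_samples)
    inv_et = sum(1.0 / sf[s] for s in et_samples) / len(et_samples)
    n_it, n_et = len(it_samples), len(et_samples)

    stats = {}
    for g in genes:
        q_it = [norm_counts[g][s] for s in it_samples]
        q_et = [norm_counts[g][s] for s in et_samples]
        m_it = sum(q_it) / n_it
        m_et = sum(q_et) / n_et
        v_it = sum((x - m_it) ** 2 for x in q_it) / (n_it - 1)
        v_et = sum((x - m_et) ** 2 for x in q_et) / (n_et - 1)
        num = (n_it - 1) * (v_it - m_it * inv_it) + (n_et - 1) * (v_et - m_et * inv_et)
        den = (n_it - 1) * max(m_it**2 - v_it / n_it, 0.0) + \
            (n_et - 1) * max(m_et**2 - v_et / n_et, 0.0)
        a_raw = num / den if den > 0 else float("nan")
        mean_all = sum(norm_counts[g][s] for s in frame.columns) / len(frame.columns)
        stats[g] = dict(m_it=m_it, m_et=m_et, a_raw=a_raw, mean_all=mean_all)

    # dispersion trend a(mu) = a0 + a1/mu, min-norm least squares via pinv
    rows = [g for g in genes if math.isfinite(stats[g]["a_raw"]) and stats[g]["mean_all"] > 0]
    if rows:
        X = np.array([[1.0, 1.0 / stats[g]["mean_all"]] for g in rows])
        y = np.array([stats[g]["a_raw"] for g in rows])
        coef = np.linalg.pinv(X) @ y
    else:
        coef = np.array([0.0, 0.0])

    out = {}
    for g in genes:
        st = stats[g]
        m_it, m_et = st["m_it"], st["m_et"]
        if rows and st["mean_all"] > 0:
            a = max(coef[0] + coef[1] / st["mean_all"], floor)
        else:
            a = floor
        lfc = math.log2(m_it + pseudocount) - math.log2(m_et + pseudocount)
        K2_it = K4_it = 0.0
        for s in it_samples:
            c2, _, c4 = _nb_cumulants(np.array(m_it), sf[s], np.array(a))
            K2_it += float(c2)
            K4_it += float(c4)
        K2_it /= n_it**2
        K4_it /= n_it**4
        K2_et = K4_et = 0.0
        for s in et_samples:
            c2, _, c4 = _nb_cumulants(np.array(m_et), sf[s], np.array(a))
            K2_et += float(c2)
            K4_et += float(c4)
        K2_et /= n_et**2
        K4_et /= n_et**4
        ln2 = math.log(2.0)
        d_it = 1.0 / ((m_it + pseudocount) * ln2)
        d_et = 1.0 / ((m_et + pseudocount) * ln2)
        var = K2_it * d_it**2 + K2_et * d_et**2
        z = lfc / math.sqrt(var) if var > 0 else 0.0
        if var > 0:
            kappa4 = (K4_it * d_it**4 + K4_et * d_et**4) / var**2
        else:
            kappa4 = 0.0
        z_corr = z - (z**3 - 3 * z) * kappa4 / 24.0
        if abs(z_corr) < abs(z):
            z = z_corr
        p_raw = 2.0 * float(norm.sf(abs(z)))
        p_adj = min(p_raw * len(genes), 1.0)
        called = p_adj < alpha and abs(lfc) >= math.log2(fc_threshold)
        direction = ("IT" if lfc > 0 else "ET") if called else "none"
        out[g] = dict(
            mean_normalized_IT=m_it, mean_normalized_ET=m_et, log2fc=lfc,
            p_raw=p_raw, p_adj=p_adj, called=called, direction=direction,
        )
    return out


def oracle_enrichment(expression, labels, receptor, target_class, pseudocount,
                      baseline="subpop_mean"):
    """log2 enrichment of one receptor, computed cell by cell."""
    target = [c for c in expression.index if labels[c] == target_class]
    target_mean = sum(expression.at[c, receptor] for c in target) / len(target)
    others = sorted({labels[c] for c in expression.index if labels[c] != target_class})
    if baseline == "subpop_mean":
        sub_means = []
        for sub in others:
            cells = [c for c in expression.index if labels[c] == sub]
            sub_means.append(sum(expression.at[c, receptor] for c in cells) / len(cells))
        base = sum(sub_means) / len(sub_means)
    else:
        cells = [c for c in expression.index if labels[c] != target_class]
        base = sum(expression.at[c, receptor] for c in cells) / len(cells)
    return math.log2((target_mean + pseudocount) / (base + pseudocount))


def oracle_fc_scores(deg_oracles, candidates, population, pseudocount):
    """Geometric mean of per-study fold-differences, then min-max."""
    other = "ET" if population == "IT" else "IT"
    fc_raw = {}
    for gene in sorted(candidates):
        prod = 1.0
        for table in deg_oracles:
            m_pop = table[gene][f"mean_normalized_{population}"]
            m_other = table[gene][f"mean_normalized_{other}"]
            prod *= (m_pop + pseudocount) / (m_other + pseudocount)
        fc_raw[gene] = prod ** (1.0 / len(deg_oracles))
    values = list(fc_raw.values())
    lo, hi = min(values), max(values)
    if hi > lo:
        fc_score = {g: (v - lo) / (hi - lo) for g, v in fc_raw.items()}
    else:
        fc_score = {g: 1.0 for g in fc_raw}
    return fc_raw, fc_score


def oracle_specificity(candidates, pair_list, enrichments):
    """Mean of retained partner enrichments; None when excluded."""
    out = {}
    for gene in sorted(candidates):
        partners = [pre for post, pre in pair_list if post == gene]
        retained = [enrichments[p] for p in partners if p in enrichments and enrichments[p] > 0]
        if retained:
            out[gene] = sum(retained) / len(retained)
    return out


def oracle_rank(fc_raw, fc_score, specificity_raw, population, combination="sum"):
    """Scale, combine and sort with the documented tie policy."""
    genes = sorted(specificity_raw)
    values = [specificity_raw[g] for g in genes]
    lo, hi = min(values), max(values)
    if hi > lo:
        spec_scaled = {g: (specificity_raw[g] - lo) / (hi - lo) for g in genes}
    else:
        spec_scaled = {g: 1.0 for g in genes}
    rows = []
    for g in genes:
        total = (fc_score[g] + spec_scaled[g]) if combination == "sum" else fc_score[g] * spec_scaled[g]
        rows.append((g, total))
    rows.sort(key=lambda item: (-item[1], -fc_score[item[0]], item[0]))
    ranked = []
    for rank, (g, total) in enumerate(rows, start=1):
        ranked.append(dict(
            gene=g, population=population, fc_raw=fc_raw[g], fc_score=fc_score[g],
            specificity_raw=specificity_raw[g], specificity_scaled=spec_scaled[g],
            total_score=total, rank=rank,
        ))
    return ranked
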