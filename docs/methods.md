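# Methods

## Inputs and conventions

All tables are TSV with a header row. Gene symbols are case-sensitive and
matched exactly across bulk studies, the interneuron profile and the
ligand-receptor pair table; mismatches raise validation errors rather than
being dropped silently. Counts must be non-negative integers — fractional
upstream estimates are the caller's responsibility to round, because the
downstream model is a count model. The two pyramidal populations are labeled
IT and ET throughout; positive log2 fold changes mean IT-enriched.

## Gene filtering

A gene survives when it has at least `min_count` (default 10) reads in
*every* sample of *every* study supplied; the gene universe is the
intersection of the studies' gene lists. The filter is monotone in
`min_count` and is applied once, before any per-study testing, so all
studies test the same genes and the Bonferroni correction within each study
uses the same m.

## Normalization

Median-of-ratios size factors: for sample j, the factor is the median over
reference genes (nonzero in all samples of the study) of
count_gj / (geometric mean of gene g across samples). Factors are relative —
rescaling every library by a common constant leaves them unchanged — and
the estimator fails loudly when no gene is nonzero everywhere.

## Differential expression

Counts are modeled as negative binomial with mean s_j * mu_g(group) and
dispersion a_g, Var(K) = mu + a*mu^2.

**Dispersion.** A per-gene method-of-moments estimate is computed from
within-group variances of normalized counts, using the unbiased second
moment m^2 - v/n in the denominator (the naive m^2 is biased low by roughly
the squared coefficient of variation of the group mean, a few percent at
triplicate sample sizes). These per-gene estimates carry only ~4 degrees of
freedom at n = 3 per group and are far too noisy to use directly: a Wald
statistic with per-gene moment dispersions has t-like tails and is severely
anti-conservative. The engine therefore pools information across genes
through a two-parameter mean-dispersion trend a(mu) = a0 + a1/mu, fitted by
least squares to the per-gene estimates and floored at 1e-8; every gene's
test uses its trend value. The trend follows the standard extra-Poisson
structure of RNA-seq counts (a shot-noise term decaying as 1/mu plus an
asymptotic biological coefficient of variation). The cost is that per-gene
dispersion variation around the trend is not modeled; genes that are
genuinely far more variable than the trend will be tested liberally. A
least-squares fit is also sensitive to extreme moment estimates on
heavy-tailed real data; with thousands of genes this averages out, but the
trend should be inspected when sample sizes are very small.

**Test statistic.** log2fc = log2(m_IT + c) - log2(m_ET + c) with
pseudocount c = 0.5 on normalized group means. The standard error comes
from the delta method with model-based variances of the group means
(library-size factors enter through a mean 1/s term). Because the group
means average only three highly dispersed counts, their distribution has
noticeable excess kurtosis and the normal reference would overstate
significance far in the tails — exactly the regime that matters under a
Bonferroni threshold. The Wald statistic is therefore adjusted with a
fourth-cumulant Cornish-Fisher correction computed from closed-form NB
cumulants before the two-sided normal reference; the correction only ever
shrinks |z|. Under the global-null simulation at the package's default
conditions this yields uniform raw p-values (KS) and a slightly
conservative extreme tail.

**Calling.** A gene is a DEG when its fold change is at least
`fc_threshold` (1.5) in either direction, i.e. |log2fc| >= log2(1.5), and
its Bonferroni-adjusted p (p_raw times the number of tested genes, clipped
at 1) is strictly below `alpha` (0.05).

## Cross-study integration

Two rules are provided. `union_then_early` (default): genes called in the
primary or reference study are retained only when the early-timepoint
study also called them. `union_all`: plain union of all three call sets.
Genes called in opposite directions by different studies are dropped and
logged — a candidate enriched in opposite populations in different datasets
is uninterpretable for partner matching. Whether direction consistency
should be enforced at all is a judgment call; enforcing it costs nothing
on clean data and protects the ranking on discordant data.

## Contamination QC

Per sample, the mean log1p normalized expression of a marker panel
(default: eight canonical microglial genes) is z-scored across the samples
of a study; samples above `qc_flag_z` (default 2, a conventional outlier
cut) are flagged. This is a lightweight screen for cross-cell-type
contamination in sorted bulk samples, not a deconvolution: it reports which
samples carry an unusual marker load relative to their study but not the
contaminating fraction. With few samples per study the z-score is bounded
(max ~2.2 at n = 6 with a population SD), so the flag is only sensitive to
contamination concentrated in a minority of samples.

## Interneuron classification

Cells are labeled by quantile rules on the two marker genes: PV+ when
Pvalb >= the q_hi quantile (default 0.75) of nonzero Pvalb values across
all cells; CCK+ when Cck >= its q_hi nonzero quantile while Pvalb <= the
q_lo (default 0.50) nonzero quantile; the PV rule wins when both fire.
"High" and "moderate/low" are inherently qualitative; quantile thresholds
on nonzero values make the rule reproducible across normalizations and
configurable. Profiles arriving with PV and CCK labels already assigned are
validated and passed through. The rule misassigns a small fraction of cells
when marker expression is not cleanly bimodal; scoring uses class means, so
modest misclassification dilutes enrichments without reordering strong
candidates.

## Partner scoring and ranking

For each candidate population the target interneuron class is fixed (IT ->
CCK, ET -> PV). For every presynaptic partner gene of every candidate, the
log2 enrichment is log2((mean in target-class cells + c) / (baseline + c))
with c = 0.1 (single-cell class means can be zero; the pseudocount bounds
the log ratio). The baseline is by default the *unweighted* mean of
per-subpopulation means over all non-target subpopulations, so one large
subpopulation cannot dominate the comparison; pooling all non-target cells
is available as a config switch. Partners with positive enrichment are
retained; a candidate's specificity is the arithmetic mean of its retained
partners' enrichments. Candidates with no partner in the table, or no
retained partner, are excluded from the ranking and logged rather than
scored zero — "no known partner" and "unspecific partner" are different
statements and should not collapse onto the same rank.

The L5 fold-change component is the fold-difference of pseudocounted
normalized group means toward the candidate's population, combined across
the designated expression studies by geometric mean (fold-differences are
ratios). Both components are min-max scaled to [0, 1] within the ranked set
of that population — the same scaling convention for both puts them on a
common footing; degenerate sets (singleton or all-tied) scale to 1. With
exactly two ranked candidates, min-max necessarily maps each component to
{0, 1}, so the two totals can tie at 1 when the candidates split the
components; the tie policy then decides by fold-change score — one reason a
candidate's rank should be read together with its raw component values for
very small ranked sets. The
total score is their sum by default (a zero component then cannot
annihilate the other; the product is available by config). Ties break by
higher fold-change score, then lexicographically. Partner expression level
in the target class is exported alongside the enrichment table but does not
enter the total score, since only the specificity component has a defined
combination rule.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
defaults chosen as the package's study conditions: three bulk studies
(primary / reference / early) of 3 + 3 replicates, 2000 genes with
per-gene baselines log-uniform on [20, 2000], NB dispersion 0.05, and
log-normal library-size factors (sigma 0.2) so the size-factor estimator
faces realistic imbalance; an interneuron profile of five subpopulations
(PV, CCK, Sst, Vip, Lamp5) x 50 cells with NB noise (dispersion 0.3);
marker genes Cck/Pvalb at baseline 2 with a 25x multiplier in their own
class, making the classifier's quantile rules recover labels with high
purity. The planted IT candidate (Cdh12, log2fc +2, baseline 300) pairs
homophilically and carries a 4x CCK enrichment; the ET candidate (Cdh13,
log2fc -2) mirrors it with PV. Decoy DEGs (50 per population, |log2fc|
uniform on [0.7, 1.8]) cycle through three explicit types — no partner,
unenriched partner, wrong-class partner — so tests can assert why each
decoy loses. Optional contamination adds an NB microglial-marker signature
(mean = fraction x 1000) to chosen ET samples of the primary study.

What the generator does *not* emulate: transcriptome-wide co-expression
structure, batch effects beyond library size, single-cell dropout beyond NB
zeros, and annotation noise in the pair table. Passing the planted-recovery
tests therefore shows the pipeline's decision logic is correct under its
own model assumptions, not that the ranking is robust to misannotated
partners or confounded real data.

## Numerical choices and degenerate inputs

Dispersion floor 1e-8; identical group columns give log2fc exactly 0 and
p = 1; all-zero genes get p = 1 rather than an error (the min-count filter
removes them in normal operation); a z of a constant marker vector is 0
(population SD); empty candidate sets produce empty, well-formed outputs.
All pipeline stages are deterministic given inputs; the only randomness in
the package lives in the generator, which is a pure function of (config,
seed). Reported problem sizes in the test suite (e.g., 20-replicate null
calibration at 2000 genes, 50-seed planted recovery on the default
scenario) keep the whole suite in the tens of seconds while leaving the
Monte Carlo error of each checked rate well below its acceptance margin.
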