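# Methods

This note documents the statistical procedures the package implements,
the assumptions behind them, the design of the synthetic study
generator, and the numerical choices that were genuinely open.

## The analysis chain

The package covers the downstream half of a shotgun-lipidomics study of
chronic corticosterone stress and antidepressant co-treatment in rats:
six arms (vehicle control; corticosterone 40 mg/kg s.c.; corticosterone
plus St. John's wort extract Ze 117 at 30, 90 or 180 mg/kg p.o.;
corticosterone plus escitalopram 10 mg/kg p.o.), two tissues (plasma and
hippocampus), eight animals per arm entering lipidomics, and a modified
forced swim test (FST) read out as total immobility and latency to first
immobility over 600 s.

Upstream identification and pmol quantification are out of scope; the
input is a species × samples table of pmol amounts in sum-composition
shorthand (`LPE 22:6`, `PE O-38:5`).

### Nomenclature

Species names are parsed by greedy longest-prefix matching against a
class registry (CE, DAG, TAG, the diacyl and ether glycerophospholipids,
their lyso forms, Cer, HexCer, SM; extensible as data). The `C:D` field
is read as total acyl carbons and total C=C double bonds summed over
chains, regardless of chain count — sn-position- or chain-resolved
nomenclature is deliberately not modelled. Both `PE O-38:5` and
`PE O- 38:5` are accepted (vendor exports differ); the canonical output
form is space-free after the ether marker. A trailing `;n` hydroxylation
field is carried verbatim and ignored by all statistics.

### Filtering and normalization

Two identification criteria are applied when the corresponding QC
columns exist, both as strict inequalities: signal-to-noise ratio > 5
and signal intensity > 5-fold the blank intensity. Values strictly
below the limit of detection (LOD) are replaced by zero; the mask of
replaced cells is retained. The LOD may be a global scalar or
per-species column and defaults to 0 (no censoring) when absent, since
real LODs are instrument-specific and rarely published.

Amounts are then expressed as mol% of the summed lipid amount of the
same sample (0–100 scale). Censored zeros stay in the denominator; an
all-zero sample is an error, not a silent NaN.

### Structural statistics

The average number of double bonds and average chain length over a
species set S with per-species mol% weights w_i are the weighted
arithmetic means

    DB_av = Σ_{i∈S} DB_i·w_i / Σ_{i∈S} w_i
    CL_av = Σ_{i∈S} N_c,i·w_i / Σ_{i∈S} w_i .

The weighted mean is invariant to the normalization constant of the
weights, so the same formula serves both the per-class scope and the
"all analyzed lipids" scope; within-class values need no re-derived
normalization. The alternative reading — averaging per-class values
across classes — is noted but not implemented: it disagrees with the
magnitudes such studies report (plasma DB_av ≈ 2.7 with CL_av ≈ 33
requires species-level weighting across classes).

The saturation partition splits a class' mol% (per total lipids) into
the DB = 0 and DB ≥ 1 fractions; a species is saturated iff it carries
zero double bonds in any chain.

Arm-level comparisons of these statistics use one-way ANOVA over all
arms followed by pairwise t-tests of each arm against a reference arm
(corticosterone by default) with the pooled within-group variance
(df = N − k), adjusted by the Holm–Šídák step-down rule
adj_(i) = max_{j≤i} 1 − (1 − p_(j))^(m−j+1). Identical groups with zero
between- and within-group variance define F = 0, p = 1. Arm summaries
are mean ± SEM with SEM = SD/√n.

### Per-lipid contrasts

For each lipid, a one-factor cell-means linear model is fitted on the
mol% scale over all six arms jointly; the residual variance pools
across arms (df = N − k). Homoscedastic pooling was chosen over
per-contrast variance because the design has exactly one factor and
standard least-squares contrast machinery behaves this way; with only
two arms the contrast reduces exactly to the classical pooled
two-sample t-test (a tested identity). Five contrasts are tested
two-sided: corticosterone vs control, and each co-treatment arm vs
corticosterone.

A lipid enters a contrast only if both conditions contain at least one
value above the LOD; excluded lipids keep auditable `included=False`
rows. log2 fold change is log2 of the group-mean ratio; a zero group
mean yields a flagged missing value rather than a pseudo-count, which
would invent an offset the data do not contain. Benjamini–Hochberg FDR
(step-up, q_(i) = min_{j≥i} p_(j)·m/j) is applied separately per
contrast across all included lipids of one tissue. Volcano tables
report log2fc, −log10 p, FDR and an FDR < 0.05 flag; QQ tables pair
observed −log10 p with uniform order-statistic quantiles (i − ½)/m.

Degenerate zero-variance lipids get p = 1 when the estimate is 0 and a
flagged p = 0 boundary otherwise.

### Behavior

Spearman's rank correlation (average ranks for ties; rho = Pearson
correlation of ranks) associates each species' mol% with the latency to
first immobility. The two-sided p uses the t approximation
t = ρ√((n−2)/(1−ρ²)) with n − 2 df — adequate at the n = 8–48 of this
design; an exact permutation p is available for n ≤ 10. A perfect
monotone arrangement is reported at the continuity floor 2/n!, its
exact two-sided permutation p for untied ranks. Two arm subsets are
built in: all six arms, and corticosterone plus the three Ze 117
co-treatment arms (the subset in which the lipid–latency coupling is
visible); an escitalopram-including variant exists but is not the
default, as the co-treated analysis is defined around the Ze 117 dose
series.

Arm-level FST statistics reuse the ANOVA/Holm–Šídák machinery. The
n = 15 → n = 8 subgroup selection ("excluding top and bottom
outliers") is implemented as deterministic symmetric alternating
extreme-trimming — drop the current maximum, then the current minimum,
ties broken by input order — because the original selection rule is
not recoverable in more detail and reproducibility requires a fixed
convention.

## The synthetic study generator

The generator emulates the study design so every stage is testable with
known ground truth; it does not simulate spectra, adducts, isotopes or
instrument drift.

Two independent random streams are used. The *catalog* stream (fixed
seed) draws the species catalog, per-species baselines and the random
effect-target subsets — so all simulation seeds share identical
ground-truth structure. The *noise* stream (the user seed) draws only
measurement and behavioral noise.

**Catalog.** Class composition follows typical shotgun profiles of the
two matrices (plasma rich in CE/TAG, hippocampus in diacyl and ether
glycerophospholipids), with species drawn without replacement from
per-class carbon/double-bond grids: 696 plasma and 953 hippocampal
species by default. The 14-species LPE panel (4 saturated, 10
unsaturated members, including 18:1, 20:1, 20:3, 20:4, 22:4, 22:5,
22:6) is fixed rather than sampled, and receives a narrow (one order of
magnitude) within-class abundance spread: it is the quantified,
response-carrying part of the design, so none of its members may fall
below the LOD.

**Abundances.** Per-species baselines are log-uniform over four orders
of magnitude (0.05–500 pmol). Each measurement is
baseline × 2^(arm log2fc) × LogNormal(−σ²/2, σ) with
σ² = ln(1 + CV²) and within-arm CV = 0.20 by default — consistent with
the class-sum standard errors such studies report once the ~10-member
class sum averages the per-species noise down to 6–13%. True
between-animal variance components are unknowable from published
summaries; the CV is a documented free knob. The LOD is the 2%
quantile of each tissue's generated amounts, so the zero-replacement
path is always exercised.

**Calibration.** Plasma baselines are exponentially tilted
(b_i ← b_i·e^(α·DB_i + β·C_i), α and β solved by root-finding) so the
unstressed mol%-weighted averages sit at DB_av = 2.70 and
CL_av = 33.0. Effects are multiplicative per arm:

* a broad pattern-free upshift (random 60% of plasma species,
  log2fc = 0.5) in every corticosterone arm — the systemic stress
  signature, identical in all stressed arms so co-treatment contrasts
  stay null in plasma;
* a TAG surge (log2fc = 1.49, all corticosterone arms), the
  glucocorticoid-driven lipolysis/VLDL signature, solved from the
  tilted composition to lift the stressed CL_av to ≈36 carbons while
  leaving DB_av essentially unchanged (TAG mean DB ≈ the lipidome
  average);
* a polyunsaturate reduction (log2fc = −0.3 on DB ≥ 4 species) under
  Ze 117 180 mg/kg and escitalopram, reproducing the treatment-driven
  DB_av decrease toward ≈2.5;
* the dose-ordered hippocampal rise of *unsaturated* LPE only:
  log2fc = 0.15 / 0.28 / log2(0.29/0.22) ≈ 0.398 at Ze 117 30/90/180,
  and log2(0.31/0.22) ≈ 0.494 under escitalopram, anchored to the
  class totals 0.22 → 0.29 / 0.31 mol%; the 30 and 90 mg/kg values
  interpolate the dose ordering, which is not numerically published.

**Behavior.** Latency is linearly coupled to each animal's hippocampal
unsaturated-LPE mol%: latency = −76 + 660·x (+90 s for the unstressed
arm) + N(0, 20²), truncated to [0, 600]. The slope and intercept are
anchored so the corticosterone arm sits at ≈69 s and the Ze 117
180 mg/kg arm at ≈115 s. The control offset encodes that unstressed
animals keep a long latency (~160 s) without any LPE shift; it is
calibrated so pooling all arms abolishes the lipid–latency rank
correlation that the corticosterone/co-treated subset shows — the
study's qualitative pattern. A consequence of the single global slope
is that the escitalopram arm's latency (~128 s) overshoots the
published ~106 s; a per-arm coupling could fix this but would add
parameters the published summaries cannot constrain. Total immobility
is drawn per arm (means 256.5 s corticosterone, 155.4 s at Ze 117
180 mg/kg; SD 70 s) without lipid coupling.

**What passing tests do and do not show.** The generator reproduces
the design's group structure, censoring, and effect topology with
independent lognormal noise. Real data add correlated biological
variation across species, batch structure, heteroscedastic per-species
CVs and non-lognormal tails; tests passing on synthetic data therefore
validate the statistical machinery and its calibration behavior, not
the biological conclusions of any particular dataset.

## Problem sizes and runtime choices

Simulation-based checks use 10–50 replicate draws at the full design
size (48 samples × 696/953 species); these sizes give stable Monte
Carlo estimates of the monitored fractions (type-I fraction, detection
fraction, mean rho) at a few seconds per batch. The vectorized
contrast runner is tested to agree with the per-species scalar path to
1e-10.

## Known limitations

* Power at the published effect sizes: with CV 0.20 and n = 8/arm, the
  anchored LPE effects (log2fc ≈ 0.4–0.5) yield contrast
  noncentralities of ≈3.2–4.1, below what Benjamini–Hochberg at
  FDR < 0.05 across ~950 species demands (|t| ≳ 3.9–4.4) — so only a
  minority of effect-carrying species is FDR-flagged per draw, even
  though fold-change recovery (MAE ≈ 0.11) and dose ordering are
  reliable. Detection reaches ≥80% only for log2fc ≈ 1 effects or
  per-species CVs near 0.10.
* The identification filter covers the two quantified criteria (S/N,
  blank ratio); mass-accuracy, occupancy and background filters have
  no published thresholds and are out of scope.
* mol% carries a compositional constraint (shared denominator) that
  the independence-assuming per-lipid tests ignore, as did the
  original analysis.
* No covariates, batch terms or mixed effects: the model is a single
  treatment factor by design.
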