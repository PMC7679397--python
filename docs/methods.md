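# Methods

This note documents the models and procedures implemented in `idiorsa`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data tests do and do not establish about real data.

## Similarity space

All comparisons happen between *similarity vectors*: the S(S-1)/2 lower
triangle of an inter-scenario Pearson correlation matrix, Fisher-z
(arctanh) transformed. Correlations are clipped to ±(1 − 1e−7) before
arctanh so degenerate, perfectly correlated inputs stay finite. The triangle
is traversed in `scipy.spatial.distance.squareform` order (upper triangle
row-major = lower triangle column-major); any consistent order is valid
because every comparison uses the same one, and exports record the
convention in their headers.

## Personal models

**Verbal.** Descriptions are lowercase-folded, punctuation-stripped, filtered
against a shipped function-word stoplist (replaceable — there is no canonical
stoplist) and against the lexicon; surviving tokens keep their order and
multiplicity, and the scenario vector is the exact pointwise sum of their
embedding vectors. Duplicates are deliberately kept: composition is pure
addition, so a repeated word weights the sum. A description with no
modelable content word is an error rather than a silent zero row.

**Attributes.** Ratings (integers 0–6 on 20 attributes) are standardized per
attribute within participant. Population SD (divide by N) is the default
z-score convention; `ddof=1` is available. A constant column cannot be
standardized and is set to zero with a warning, preserving matrix shape.

**Fusion.** The verbal and attribute similarity vectors are z-scored over
their entries and summed. Summation and averaging differ by a factor of two
and are rank-identical, so every downstream (rank-based) statistic is
unaffected by that choice.

## Brain patterns

Within each run, every voxel series and every nuisance series (six motion
parameters, linear trend) is z-scored, and voxels are OLS-residualized
against the nuisance design with intercept. Volumes are indexed 0-based; the
volume at offset m from onset covers [m·TR, (m+1)·TR), and a window (start,
end) keeps the offsets whose interval lies inside it — with TR = 2.5 s and
the default (5 s, 15 s) window this is offsets +2…+5, four volumes, whose
residuals are averaged per presentation. Voxel stability is the mean of the
C(R,2) arctanh-transformed inter-run correlations of the voxel's S-scenario
profile; pairs with a zero-variance profile contribute 0 by default (a
`drop` policy is available). The top-k voxels per region (default k = 100,
all voxels when the region is smaller) are kept, with ties broken by
ascending voxel index for determinism. Scenario patterns are replicate
averages, then each voxel is z-scored across scenarios; zero-variance voxels
are zeroed with a warning. Discarding pre-steady-state volumes is the
caller's responsibility in real-data mode; the generator can emulate the
resulting 4-replicate scenario with `drop_first_presentation`.

## RSA, partial RSA, and their permutation nulls

RSA is Spearman correlation with average ranks on ties. Its null shuffles
scenario order: rows and columns of the brain similarity matrix are permuted
together, the triangle re-vectorized, and the coefficient recomputed
(default 1,000 permutations). The p-value is the plain fraction of null
coefficients ≥ the observed one — it can be exactly 0; a `(b+1)/(B+1)`
estimator is available for users who need positive p.

Partial RSA ranks all three vectors and computes the first-order partial
Pearson correlation on the ranks. Its permutation null must not destroy the
brain-to-control relationship, so it permutes residuals: regress the ranked
brain vector on the ranked G-1 vector (with intercept — the intercept is
part of the fitted component that is restored after shuffling), fold the
residuals into the S x S triangle positions, shuffle rows and columns at the
*scenario* level, re-vectorize, add the fitted component back, and
partial-correlate against the ranked personal vector controlling the ranked
G-1 vector. With the identity shuffle this reconstruction reproduces the
ranked brain vector exactly (a tested 1e−10 identity), so the observed
statistic is recovered.

## Group inference

Per region (or searchlight center), the participants' Fisher-z coefficients
are tested against zero with a one-tailed one-sample t-test, d = t/√n, and
Benjamini–Hochberg FDR across regions (Benjamini–Yekutieli available).
Region selection takes regions with adjusted p < q (default q = 0.05, a
display threshold of 0.1 is exposed separately for maps). The leave-one-out
variant selects regions for a target participant from the other n−1
participants' personal-model RSA only, so the target's data cannot influence
their own selection. Searchlights are cubes of side 2r+1 (default radius 3;
the demonstration scale uses 2) intersected with the common mask, skipped
below 10 voxels; the partial map is computed only at centers significant in
the group-model map, as an unrestricted mode exists for exploration; FDR is
applied to each map separately.

## The synthetic cohort generator

The generator emulates the study design it is meant to exercise: 26
participants, 20 scenarios shown once per run in randomized order over 5
runs, TR 2.5 s, 3-volume prompts with 3-volume gaps, 20 attributes,
GloVe-dialect vocabulary files. Each participant's scenario geometry is
`(1−λ)·group + λ·personal` with independent personal latents; all three
channels read out the same participant latents:

- voxels: signal regions apply a shared linear readout of the active
  scenario's latent as a boxcar delayed 2 volumes and lasting 4 (matching
  the 5–15 s averaging window) — a deliberate alternative to a canonical
  hemodynamic model, whose latency/duration assumptions the averaging
  approach avoids; plus motion-coupled artifact, a linear drift, and white
  noise;
- ratings: latent projections affinely mapped to 0–6 and rounded (ties and
  end-clipping are kept, as in real Likert data) with small per-person
  noise;
- descriptions: the k = 8 vocabulary words nearest the scenario latent in
  embedding space, from a vocabulary organized around orthogonal topic
  centroids.

**Noise defaults and why.** Per-volume voxel noise is 10x the signal pattern
scale. This is the realistic regime for single-volume cognitive contrasts
and was anchored to the effect sizes this kind of study reports:
at these settings the desk-scale brain-to-model RSA coefficients
fall in the 0.1–0.3 range and pairwise decoding at λ = 0.5 lands near
80–100%, rather than the saturated values a low-noise generator produces.
The calibration also matters statistically: partial correlation with an
*estimated* control (the G-1 model) carries a positive residual-confounding
bias proportional to the brain-truth correlation times the per-person
channel noise, so an unrealistically clean generator makes the λ = 0
permutation p-values anticonservative. With the default noise levels the
λ = 0 p-values are uniform (tested by KS across independent cohorts).
Per-person rating noise is 0.1 Likert SD before rounding; rounding itself
amplifies small noise to roughly ±1 jumps near thresholds, which sets the
effective floor of person-specific behavioral noise. λ defaults to 0.5 — the
relative magnitude of person-specific vs. shared signal is not known
quantitatively, so a mid-range value was fixed once as the demonstration
condition.

**What the generator does not emulate:** anatomical geometry, physiological
(cardiac/respiratory) noise, spatial autocorrelation of the BOLD signal,
field inhomogeneities, or session effects. Passing tests therefore show that
the *statistics* behave correctly under the assumed generative structure —
calibrated nulls, recovered planted signal — not that the pipeline is robust
to every artifact of real acquisitions.

## Test-scale choices and known limitations

- Desk-scale tests use reduced voxel grids (120–360 voxels, 2–4 regions)
  chosen so each region still holds 40–120 voxels; permutation counts are
  reduced to 99–500 where only calibration, not precision, is at stake.
- The null-calibration KS test draws two participants from each of 100
  independent cohorts: p-values within a cohort share the group latent and
  the G-1 controls and are therefore dependent, which would invalidate a KS
  test across one cohort's participants.
- Exact region-set recovery is capped near 95% by FDR itself: at q = 0.05 a
  false region enters in ~5% of cohorts even with perfectly calibrated
  nulls. The recovery test asserts ≥ 90% over 60 seeds against that ceiling.
- Permutation p-values use the plain fraction and are granular at 1/B.
- The partial-RSA null remains mildly anticonservative when the brain-truth
  correlation is pushed far above the realistic range (see noise defaults) —
  an inherent property of partialling out an estimated control, worth
  remembering when interpreting real-data partial RSA with small cohorts.
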