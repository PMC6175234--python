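# Methods

This note documents the statistical models, the processing chains, the
synthetic-data generators and the numerical choices behind `necrosip`, in
enough detail to judge what passing tests do — and do not — demonstrate
about real sediment data.

## Responder detection

**Model.** Each sequencing library (a sample × molecule combination, DNA for
16S rRNA genes, RNA for transcripts) is treated as a draw of `n` reads, of
which `x` belong to a given phylotype. For a treatment library paired with
its control, the null hypothesis of equal underlying proportions is tested
with the pooled two-proportion z-test,

    z = (x₁/n₁ − x₂/n₂) / √( p̂(1−p̂)(1/n₁ + 1/n₂) ),   p̂ = (x₁+x₂)/(n₁+n₂),

one-sided (*greater*), because an enrichment claim is directional. Equal
proportions and degenerate pooled proportions (0 or 1) return p = 1, so
phylotypes absent from both libraries stay in the testing family without
special-casing; this keeps the Benjamini–Hochberg family size stable across
phylotype subsets. Continuity correction is off by default and switchable
(`AnalysisConfig.continuity_correction`); the literature that uses this test
on amplicon libraries does not state a correction, and one documented
formula is preferable to two. BH adjustment is applied across all
phylotypes *within one library pair* — per-comparison correction semantics;
nothing is corrected across pairs, because the responder rule itself
("enriched in at least `min_libraries` = 2 pairs") already demands
replicated evidence.

**Calls.** Per phylotype and substrate, `responsive ⇔ (#enriched DNA pairs +
#enriched RNA pairs) ≥ 2`. Response mode is `growth` whenever at least one
DNA pair contributes (gene-level shifts imply population growth, and growing
populations also carry more ribosomes) and `activity` when the evidence is
RNA-only. Sulfate-reducer (SRM) status uses the same machinery with the
uninhibited substrate libraries as treatment and the molybdate-inhibited
parallels as control (n = 8 pairs by default: 2 substrates × 2 late sampling
days × DNA/RNA at high dose). Guild assignment is the deterministic
decision table documented in `classify_guilds`, total on all eight boolean
combinations; the combination (spirulina ∧ ¬acetate ∧ srm) has no guild
interpretation in the degradation-cascade model and is left `unclassified`.

**Pairing.** Which libraries form the n = 4 (substrate) and n = 8
(inhibition) families is explicit configuration: a list of
(treatment, control) sample pairs. The default builder matches on
(day, molecule), replicate-matched when possible, at the two latest sampling
days and high dose — late time points are where a substrate response has had
time to develop. Explicit pairs override the builder entirely.

**Prefilter.** A minimum-abundance prefilter exists
(`AnalysisConfig.min_abundance`) but is off by default: abundance context is
descriptive, not part of the test.

## Single-cell Raman ¹³C quantification

¹³C assimilation shifts the phenylalanine ring-breathing band from
~1002 cm⁻¹ to ~965 cm⁻¹. The processing chain is fixed as
**baseline → align → normalize → ratio**:

1. *Baseline*: iterative polynomial fitting with peak masking — fit a
   degree-5 polynomial (default), clip the working spectrum to the fit,
   refit, 10 iterations (default), subtract the final fit from the original
   spectrum. Degree 5 spans fluorescence backgrounds without chasing peaks;
   both degree and iteration count are parameters. Small negative residuals
   are left in place (clamping happens only in the normalization total).
2. *Alignment*: each spectrum is shifted (linear interpolation back onto the
   common grid) so its dominant peak within the union of the two
   phenylalanine windows ± 5 cm⁻¹ lands on the anchor — by default the
   per-set consensus (median) peak position snapped to the grid. Shifts are
   capped at ± 5 cm⁻¹: a heavily labeled cell peaks ~37 cm⁻¹ away from an
   unlabeled anchor, and the cap prevents alignment from dragging one band
   onto the other; such cells are flagged and kept unshifted. Cells with no
   signal in the alignment region are flagged `unaligned` and excluded, and
   counted in the report.
3. *Normalization*: divide by total intensity (negatives clamped to zero for
   the total); scale-invariance of the ratio is tested explicitly.
4. *Ratio*: "height" is the windowed maximum of the processed spectrum
   (floored at 0), not a fitted amplitude — robust to residual misalignment
   given the 10 cm⁻¹ and 5 cm⁻¹ window widths. A vanishing ¹²C height with
   positive ¹³C height yields an infinite ratio, reported as labeled.

A cell is *labeled* when its ratio exceeds mean + 3 sd (n−1 denominator) of
the ¹²C control cells' ratios. Under approximately normal negative ratios
this three-sigma rule bounds the false-call rate near 1–2%, which the f = 0
recovery test checks. Population-level significance is a one-sided Wilcoxon
rank-sum test (population > control) at α = 0.001; sidedness is a parameter.

## Statistical primitives

The Wilcoxon rank-sum test reports the rank sum of the first sample with
midranks for ties. The p-value is exact (full enumeration) when the pooled
sample size is ≤ 12 with no ties, matching common statistical-package
behaviour and keeping exactness where Raman populations are small; otherwise
the normal approximation with tie and continuity correction is used. BH
adjustment follows the standard step-up definition (delegated to a reference
implementation; the test suite verifies it against a brute-force
reimplementation of the definition on random vectors). Note that step-up BH
is *not* idempotent in general — re-adjusting an adjusted vector re-inflates
tied values by m/rank — so no such invariant is claimed.

## Community metrics

Rarefaction draws `depth` reads per sample *without replacement*
(multivariate hypergeometric), 100 re-samples at 3250 reads by default;
samples below depth are excluded and reported, never silently dropped. The
mean observed richness over re-samples is validated against the closed-form
expectation E[S_d] = Σᵢ (1 − C(N−Nᵢ, d)/C(N, d)). Alpha diversity reports
observed richness and Shannon entropy (natural log). Beta diversity is
Bray–Curtis, d = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), identical on counts and proportions
for equal-depth samples. PCoA double-centers −d²/2 (Gower), eigendecomposes,
and keeps coordinates only for positive eigenvalues; negative eigenvalues
(expected for Bray–Curtis, which is non-Euclidean) are reported but their
axes dropped — no correction by default, with the Cailliez correction
available as an option. Euclidean-embeddable inputs are reconstructed to
machine precision, which the tests assert at 1e-8.

## Energetics

ΔG = ΔG⁰(T,p) + RT ln Q for acetate⁻ + SO₄²⁻ → 2 HCO₃⁻ + HS⁻, with
R = 8.314462618 J mol⁻¹ K⁻¹ and Q the mass-action quotient of dimensionless
activities (γ·c/c⁰ when concentrations and coefficients are supplied;
coefficients default to 1). ΔG⁰(T,p) is an **input**, computed externally
from thermodynamic property tables (SUPCRT92-style); re-implementing an
aqueous-species equation of state is out of scope. Sign convention:
negative = exergonic; `above_limit` is true when ΔG is more negative than
the −30 kJ mol⁻¹ energetic limit of microbial sulfate reduction. A
Davies-equation helper (log₁₀ γ = −A z² (√I/(1+√I) − 0.3 I)) is provided as
a convenience for building condition files; it is an extension, not part of
the core computation. The shipped example conditions file contains
representative synthetic values for cold sulfidic porewater and is labeled
as such; real in-situ energy yields require measured site values entered
into the template.

## Synthetic data: what it emulates, what it does not

**Count tables.** A baseline composition is drawn once from a symmetric
Dirichlet (α = 0.3 per phylotype → realistically skewed rank-abundance);
each library perturbs it with independent log-normal noise (σ = 0.2),
applies planted multiplicative effects, renormalizes, and draws reads
multinomially at a depth ~ Normal(4732, 10%) — the observed mean library
size of the emulated experiments. The design covers no-substrate controls
and spirulina/acetate amendments at two doses with molybdate parallels, DNA
and RNA libraries, at four sampling days (0, 13, 20, 32) by default; the
full eight-day schedule is available via `default_design(days=...)`.
Planted responders multiply their proportion by the substrate fold change
(default 8×, separately for DNA and RNA) from their onset day (default 13),
also under molybdate — fermenters are not silenced by a sulfate-reduction
inhibitor. Planted SRM are divided by the suppression factor (default 10×)
in molybdate libraries. Effects act on the composition *before*
renormalization, so other phylotypes shrink slightly — the compositional
coupling real relative-abundance data has.

Planted phylotypes are re-seated at detectably abundant baselines:
responders at 0.2–1% (the abundance range of observed substrate responders
in such experiments), SRM at 0.5–2%. The higher SRM floor is a power
requirement of the inhibition contrast, not a convenience: suppression
empties the *control* library, so the test's information is bounded by the
uninhibited count alone, z ≈ 0.86·√(N·b) for suppression ≫ 1 — at ~4700
reads a sulfate reducer below ~0.5% baseline is structurally undetectable
at BH-corrected α = 0.01 no matter the detector. Molybdate-sensitive taxa
in sulfidic sediments are in fact abundant community members, so the range
is also the realistic one.

**Spectra.** Each cell is baseline + A·[(1−s)·G(1002) + s·G(965)] + noise on
a 600–1800 cm⁻¹ grid (1 cm⁻¹ step): Gaussian bands of 4 cm⁻¹ FWHM, a random
degree-≤5 polynomial baseline kept positive, additive Gaussian noise
(σ = 0.01 relative to unit peak amplitude), and a shared per-cell axis
jitter ≤ ±2 cm⁻¹. Labeled cells draw the label share s uniformly from
(0.2, 0.8); s = 0 otherwise. The generated peak-height ratio of a clean
cell is s/(1−s) exactly, which anchors the ratio oracle.

**Limitations.** The generators reproduce the *statistical structure* the
analysis assumes — overdispersed compositional counts, two-band spectra with
smooth backgrounds — not sequencing chemistry (no chimeras, denoising
artifacts or taxonomy), not biological replication structure (one replicate
per design cell), not cosmic-ray spikes, band distortions or
cell-to-cell biomass variation beyond intensity scaling. Recovery results
on synthetic data therefore demonstrate correctness and calibration of the
inference chain under its own model assumptions; they do not certify
performance on real sediment libraries, where overdispersion can exceed the
planted σ and effects are not cleanly multiplicative.

## Problem sizes

Defaults were chosen as desk-scale versions of the emulated experiments:
2000 phylotypes × ~72 libraries per simulated community (the experiments'
~340k reads over 11.5k phylotypes and ~73 libraries sit one order above),
20 replicates for recovery studies, 100 cells per Raman population, 100
rarefaction re-samples at 3250 reads. All generators and analyses are
seeded end-to-end; `necrosip run-all` writes a manifest (config snapshot,
input checksums, seed, version) and its stage reports are byte-identical
under a fixed seed.
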