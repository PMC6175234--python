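# necrosip

Analysis pipeline for **stable-isotope-probing (SIP) incubation experiments in
anoxic marine sediments**: who degrades fresh organic matter (cyanobacterial
necromass), who consumes the resulting volatile fatty acids, and whether
sulfate reducers earn enough energy doing it.

The package is aimed at microbial ecologists running substrate-amended
sediment microcosms with sequential 16S rRNA gene/transcript amplicon
sequencing, CARD-FISH-targeted single-cell Raman microspectroscopy, and
porewater geochemistry. It provides, as tested library code with a CLI:

- **Responder detection** — for each phylotype and each treatment-vs-control
  library pair, a one-sided pooled two-proportion z-test
  `z = (p̂₁ − p̂₂) / √(p̂(1−p̂)(1/n₁ + 1/n₂))`, Benjamini–Hochberg corrected
  across phylotypes within each pair; a phylotype is *responsive* when
  enriched (adjusted p ≤ 0.01) in ≥ 2 library pairs. DNA-level enrichment is
  interpreted as **growth**, RNA-only enrichment as ribosomal **activity**.
- **Sulfate-reducer identification** — the same machinery contrasting
  uninhibited substrate incubations against molybdate-inhibited parallels
  (molybdate blocks sulfate activation, selectively silencing sulfate
  reducers), and a deterministic decision table mapping
  (spirulina-responsive, acetate-responsive, molybdate-inhibited) onto
  functional guilds: hydrolysers/fermenters, acetate-utilizing SRM, SRM on
  other electron donors, non-SRM VFA utilizers.
- **Single-cell Raman ¹³C quantification** — iterative polynomial baseline
  correction, phenylalanine-region peak alignment, total-intensity
  normalization, and the ¹³C/¹²C phenylalanine peak-height ratio
  (960–970 cm⁻¹ vs 1000–1005 cm⁻¹ window maxima). Cells above the
  mean + 3 σ threshold of the ¹²C control count as labeled; populations are
  tested against the control with a one-sided Wilcoxon rank-sum test
  (p < 0.001).
- **Community summaries** — rarefaction without replacement (default
  100 re-samples at 3250 reads), observed richness and Shannon entropy,
  Bray–Curtis dissimilarities and principal-coordinates analysis.
- **Energetics** — the in-situ Gibbs energy of acetoclastic sulfate
  reduction, ΔG = ΔG⁰(T,p) + RT ln Q with
  Q = a(HCO₃⁻)²·a(HS⁻) / (a(Ac⁻)·a(SO₄²⁻)), compared against the
  −30 kJ mol⁻¹ energetic limit of the process.
- **Synthetic data** — seeded generators for amplicon count tables
  (Dirichlet-multinomial community, log-normal overdispersion, planted
  responder/SRM effects) and single-cell spectra (planted labeled fractions),
  each returning its ground truth, so every stage is testable without
  sequencing data.

## Worked example

```python
import necrosip as ns

# a full incubation design with 10 planted responders and 5 planted
# sulfate reducers, ~4700 reads per library across 2000 phylotypes
table, meta, truth = ns.simulate_counts(ns.default_community_config(seed=1))
results = ns.ResponderModel(table, meta).fit()
print(results.summary())
```

```
Responder detection summary
===========================
alpha=0.01  min_libraries=2  phylotypes=2000
 spirulina: 5 responsive (5 growth, 0 activity-only) over 4 library pairs
   acetate: 5 responsive (5 growth, 0 activity-only) over 4 library pairs
       SRM: 6 molybdate-inhibited phylotypes over 8 library pairs
         4 x hydrolyser_fermenter
         5 x srm_other_donor
         5 x vfa_utilizer_non_srm
```

All ten planted responders are recovered (five per substrate); six
phylotypes are flagged as molybdate-inhibited — the five planted sulfate
reducers plus one false positive, which is what an empirical FDR of a few
percent looks like at this scale. The guild table combines the three
boolean axes: spirulina-only responders become hydrolysers/fermenters,
molybdate-inhibited non-responders SRM on other donors, and
substrate-responsive uninhibited phylotypes VFA utilizers.

```python
spectra, _ = ns.simulate_spectra(ns.default_spectra_config(
    seed=1, n_cells=100, fractions={"probe_2011": 0.37}, n_negative=50))
print(ns.RamanModel(spectra).fit().summary())
```

```
Single-cell Raman 13C-labeling summary
======================================
threshold (neg mean + 3 sd): 0.0455   excluded cells: 0
      probe_2011: n=100  labeled= 37.0% p=1.12e-05 ***
        negative: n=50   labeled=  0.0% p=1.00e+00
```

A population with a planted 37% labeled fraction is recovered exactly, and
its rank-sum test against the ¹²C control clears the 0.001 significance
level (starred).

```python
import importlib.resources
cond = ns.ReactionConditions.from_yaml(
    importlib.resources.files("necrosip.data") / "example_conditions_synthetic.yaml")
print(ns.delta_g(cond).summary())
```

```
dG = -45.9 kJ/mol (Q = 2.116e+00); limit -30.0 kJ/mol -> more exergonic than the limit (process energetically feasible)
```

The shipped conditions file is a synthetic stand-in for cold sulfidic
porewater; substitute measured temperature, ΔG⁰(T,p) and species activities
(template in `src/necrosip/data/conditions_template.yaml`) to compute a real
in-situ energy yield.

The same workflow is available from the shell:

```sh
necrosip simulate counts --seed 1 --out-prefix sim/
necrosip detect --counts sim/counts.tsv --metadata sim/metadata.tsv --out detect.json
necrosip run-all --seed 1 --out run/      # all stages + reproducibility manifest
```

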