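# twinmet

Urinary metabolomics biomarker analysis for twin cohorts: urine-dilution
normalization anchored in a control group, neurotransmitter
anabolism/catabolism ratios, a three-phase discovery–replication–validation
association cascade with FDR control, sensitivity re-analysis, and ACE twin
variance decomposition — together with a synthetic twin-cohort metabolome
generator so that every stage is testable without access to cohort data.

## Who this is for

Biomarker studies of behavioral phenotypes in twin registers face three
linked statistical problems:

1. **Urine dilution.** Urinary concentrations vary with hydration.  Instead
   of creatinine normalization (problematic when creatinine itself tracks
   the phenotype), each metabolite *m* is corrected by its own dilution
   slope, estimated in a control group:

   ```
   [m_i]' = [m_i] / (β_m · (d_i − d_w))
   ```

   where `d_i` is the specific gravity of sample *i*, `d_w = 1` is the
   density of pure water, and `β_m` is the least-squares slope of the
   (percent-of-median) concentration on `(d_i − d_w)` in controls.  After
   correction the package verifies that density no longer explains the
   normalized values.

2. **Family clustering and confounding.** Twins are not independent.
   Between-family contrasts use linear GEE with an exchangeable working
   correlation and robust (sandwich) standard errors; within discordant
   pairs, paired t-tests on sex/age-residualized values cancel every
   family-level confounder (and, for MZ pairs, genotype).

3. **Multiplicity across a staged design.** Discovery (concordant-high vs
   concordant-low twins), replication (discordant pairs) and validation
   (clinical cases vs reserved twin controls) run on independent samples
   with Benjamini–Hochberg FDR within declared test families, top-25%
   forwarding between phases and a congruent-direction requirement.

The phenotype itself is decomposed with the classical ACE twin model
(additive genetic a², shared environment c², unique environment e²; MZ pair
covariance a²+c², DZ covariance ½a²+c²), fitted by boundary-constrained
maximum likelihood with 90% profile-likelihood confidence intervals.

## Worked example

```python
from twinmet import SimulationConfig, CascadeConfig, simulate_dataset, run_cascade

cohort, matrix, truth = simulate_dataset(SimulationConfig(seed=7))
report = run_cascade(cohort, matrix, CascadeConfig(), seed=7)
print(report.discovery_features.sort_values("p").head(5)[
    ["panel", "n", "beta", "se", "p", "fdr_p"]].round(3))
```

```
           panel    n   beta     se    p  fdr_p
id
amine_51  amines  968 -0.494  0.068  0.0    0.0
amine_38  amines  968  0.379  0.064  0.0    0.0
amine_18  amines  968  0.364  0.064  0.0    0.0
amine_43  amines  968 -0.364  0.067  0.0    0.0
amine_56  amines  968  0.351  0.065  0.0    0.0
```

The five strongest discovery associations are exactly the features the
generator planted effects on (`truth["associated_features"]`), with
standardized GEE effects around ±0.35–0.49 and sandwich SEs near 0.065.
The cascade forwards the top 25% per panel (16 amines, 5 organic acids, 2
other biomarkers) into within-pair replication, then the five best
congruent-direction biomarkers and the top congruent ratio into case–control
validation:

```python
print(report.candidate_features)   # ['amine_51', 'amine_38', 'amine_18', 'amine_43', 'amine_56']
print(report.candidate_ratio)      # 'L-glutamine:L-glutamic acid'
```

The ACE decomposition on simulated liabilities at register scale
(751 MZ + 1,149 DZ pairs, generating fractions 0.63/0.14/0.23):

```python
from twinmet import simulate_ace_phenotypes, ACEModel
df = simulate_ace_phenotypes(751, 1149, 0.63, 0.14, 0.23, seed=7)
pairs = lambda z: df[df.zygosity == z].phenotype.to_numpy().reshape(-1, 2)
m = ACEModel().fit(pairs("MZ"), pairs("DZ"))
```

```
a2=0.660 (90% CI 0.579-0.744)
c2=0.099 (90% CI 0.021-0.173)
e2=0.241 (90% CI 0.220-0.264)
```

A command-line interface mirrors the library
(`twinmet simulate | preprocess | cascade | ace`); see `twinmet --help`.

## Layout

- `src/twinmet/simulate.py` — synthetic cohort + metabolome generator
- `src/twinmet/preprocess.py` — RSDqc filter, LOD imputation, density
  normalization (`DensityNormalizer`), inverse normal transform
- `src/twinmet/ratios.py` — the seven neurotransmitter ratios
- `src/twinmet/gee.py` — exchangeable linear GEE with sandwich errors
- `src/twinmet/cascade.py` — the three-phase cascade + sensitivity re-runs
- `src/twinmet/ace.py` — ACE maximum likelihood (`ACEModel`)
- `src/twinmet/io.py`, `src/twinmet/cli.py` — files, reports, CLI
- `docs/methods.md` — model assumptions, defaults and limitations
- `docs/data_dictionary.md` — column schemas for all interchange files
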