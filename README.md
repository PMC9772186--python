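# reefcore

Tools for the coupled analysis that links coral bleaching history, skeletal
growth, reef temperature regimes, and host population structure — the kind of
study design used to find thermally tolerant *Porites* cf. *lobata*
populations on Palau's warm Rock Island reefs.

The package is aimed at coral reef ecologists and molecular ecologists who
have three loosely coupled data streams about the same colonies and want one
reproducible path from raw-ish inputs to lineage × habitat statistics:

1. **Skeletal cores** (`reefcore.densitometry`) — 1D density profiles
   ρ(z) (g cm⁻³ vs mm from the living surface, as extracted from CT scans).
   Annual bands are segmented at troughs of the smoothed density; per-band
   extension *E* (cm yr⁻¹), mean density *D* (g cm⁻³) and calcification
   *C = D · E* (g cm⁻² yr⁻¹) are averaged over 1999–2009 to avoid bleaching
   years. **Stress bands** — the skeletal record of bleaching — are called as
   regions ≥ 1 mm thick whose density exceeds 2 whole-core SDs above the
   whole-core mean and that contain a density-gradient excursion above the
   same threshold, then attributed to calendar years (1998, 2010 heatwaves).
2. **Temperature loggers** (`reefcore.thermal`) — weekly climatology, a
   zero-phase Butterworth band-pass isolating 5–36 h variability, daily
   ranges (max − min of the filtered series per day), and an annual warm-tail
   metric (mean across years of each year's 90th-percentile temperature).
3. **Genotypes** (`reefcore.popgen`) — microsatellite curation (three-rule
   multi-allele resolution; >40% missing loci dropped, then under-genotyped
   samples), biallelic SNPs from VCF, maximum-likelihood admixture (EM over
   Q, the individuals × K ancestry proportions, and P, the population allele
   frequencies), majority-rule (>50%) lineage assignment, pairwise Nei's
   FST = 1 − ΣₗHs/ΣₗHt with a 100-resample locus bootstrap, and genotype PCA.

`reefcore.stats` joins everything into a cohort table and runs the contrast
battery: one-way ANOVAs with Tukey HSD on growth metrics across lineages and
lineage × habitat groups, and chi-squared tests on stress-band prevalence.
`reefcore.simulate` generates all three data streams with known ground truth
(sinusoidal annual banding with injected stress anomalies; seasonal + diurnal
temperature structure; Balding–Nichols genotypes with calibrated pairwise
FST), so the whole pipeline is testable end to end.

## Worked example

Simulate a 15-year core with a 1998 stress event, then analyze it:

```python
from reefcore import simulate
from reefcore.densitometry import (
    segment_annual_bands, detect_stress_bands, mean_growth, attribute_stress_years,
)

spec = simulate.CoreSimSpec(
    n_years=15, extension_by_year=1.1, mean_density=1.25,
    noise_sd=0.05, collection_year=2012,
    stress_events=((1998, 4.0, 2.0),),  # year, amplitude (SD), thickness (mm)
    seed=7,
)
profile, truth = simulate.simulate_core(spec)
bands = segment_annual_bands(profile)
print(bands.records.head(3).round(3).to_string(index=False))
print(mean_growth(bands))
calls = detect_stress_bands(profile)
print(attribute_stress_years(calls, bands))
```

prints

```
 year  top_mm  bottom_mm  extension_cm  density_g_cm3  calcification_g_cm2_yr
 2011     0.0       10.2          1.02          1.262                   1.287
 2010    10.2       22.1          1.19          1.236                   1.471
 2009    22.1       32.4          1.03          1.259                   1.296
{'mean_extension_cm': 1.097..., 'mean_density_g_cm3': 1.248..., 'mean_calcification_g_cm2_yr': 1.368..., 'n_years': 11}
{1998: True, 2010: False}
```

The topmost complete band is the last calendar year before collection
(2011), extension is recovered near the simulated 1.1 cm yr⁻¹, the growth
means cover the 11 window years 1999–2009, and the injected 1998 anomaly is
detected (one call at 147.7–149.4 mm, peak density z = 5.1) and attributed to
1998 while 2010 is correctly flagged absent.

The same analyses are available from the shell:

```bash
reefcore run --seed 11 --out runs/demo        # full synthetic pipeline
reefcore cores --profiles profiles/ --out out/ --window 1999:2009
reefcore thermal --loggers loggers/ --band 5:36 --out out/
reefcore popgen --vcf snps.vcf --k 4 --restarts 5 --boot 100 --seed 1 --out out/
reefcore reproduce --growth core_data.txt --strata strata_all_samples.txt --out out/
```

`reefcore reproduce` ingests published-style per-core growth and stress-band
strata tables (column names declared via `--column-map`) and recomputes the
growth ANOVAs/Tukey tables and prevalence chi-squared statistics from them.

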