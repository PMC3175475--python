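# clinezone

Maximum-likelihood analysis of narrow hybrid zones between two diagnosably
distinct taxa, built around the contact between the terminal forms of the
*Ensatina eschscholtzii* salamander ring species (the coastal
*eschscholtzii* and inland *klauberi* lineages, "E" and "K"). Given a
per-individual table of coordinates, habitat covariates and
diagnostic-marker genotypes, the package estimates where the zone runs,
how wide it is, which markers introgress asymmetrically, where genetic
disequilibrium concentrates, and whether habitat structures the zone —
the standard evidence for distinguishing a dispersal-selection tension
zone from habitat-driven spatial sorting.

## What it computes

- **Transect orientation** — the compass heading that maximizes the summed
  likelihood of model-free monotone (pool-adjacent-violators) allele-
  frequency clines across loci.
- **Tanh clines** — per-locus and shared fits of
  `p(x) = (1 + tanh[2(x − c)/w]) / 2`
  (center *c*, width *w* = inverse maximum slope) by binomial ML, with
  profile-likelihood two-unit support limits, plus likelihood-ratio tests
  for coincident centers and concordant widths across loci.
- **Barton's concordance** — per-locus deviation from equal introgression,
  `HI_loc = HI + He·[α + β(2·HI − 1)]`, `He = 2·HI(1 − HI)`, fitted by
  binomial ML with a G-test against α = β = 0.
- **Disequilibria in a 200 m sliding window** — ML heterozygote deficit,
  EM-resolved gametic D between nuclear loci, and closed-form cytonuclear
  D, each bounded in [−0.25, 0.25].
- **Hybrid classification** — threshold calls on an admixture proportion
  and a closed-form posterior over six genotype-frequency classes
  (parentals, F1, F2, backcrosses) exact for diagnostic loci.
- **Habitat tests** — class-by-vegetation chi-square, per-class elevation
  ANOVA, and a "habitat-and-cline" vs "cline-only" LRT.
- **Synthetic zones** — a generator with known ground truth (cline
  parameters, disequilibrium from parental immigration, asymmetric mtDNA
  inheritance, an ecotone) so every estimator can be validated end to end.

Estimators follow scikit-learn conventions (`TanhClineFitter`,
`ConcordanceModel`, `GenotypeClassClassifier`, ... with `fit`/`predict`
and trailing-underscore attributes); module-level functions wrap them for
one-call use, and a `clinezone` CLI wraps the pipeline.

## Worked example

Simulate a zone at the default study conditions (335 individuals on a
3.5 × 1.75 km strip, cline widths ≈ 0.72–0.80 km, mtDNA center offset
−0.105 km, disequilibrium concentrated on the E flank) and analyze it:

```python
import numpy as np
from clinezone import (SimConfig, simulate_zone, fit_orientation,
                       project_positions, fit_cline, fit_concordance, ld_scan)
from clinezone.transect import cline_observations

cfg = SimConfig(seed=11)
ds = simulate_zone(cfg)

orient = fit_orientation(ds)
print(f"heading {orient.heading:.1f} deg, support {orient.support}")

proj = project_positions(ds, orient.heading)
obs = cline_observations(proj, "all")
shared = fit_cline(obs, share=list(obs))
print(f"shared width {shared.width:.3f} km "
      f"(support {shared.support_width[0]:.3f}, {shared.support_width[1]:.3f})")

nd4 = fit_concordance(ds, "ND4")
print(f"ND4 concordance alpha={nd4.alpha:.3f} beta={nd4.beta:.3f} "
      f"p={nd4.lrt.p:.2g}")

ld = ld_scan(proj)
print(f"peak between-locus D {np.nanmax(ld['D_between']):.3f}")
```

```
heading 205.4 deg, support (205.0, 205.415788081135)
shared width 0.798 km (support 0.724, 0.880)
ND4 concordance alpha=0.918 beta=-0.801 p=1.4e-11
peak between-locus D 0.120
```

The heading recovers the simulated 207°; the shared width lands near the
~0.75–0.80 km truth; the mitochondrial marker shows strong positive α
(introgressed K-ward — nearly all mixed-ancestry individuals carry K
mtDNA), and between-locus disequilibrium peaks near the zone center. The
same pipeline runs from a file:

```bash
clinezone simulate --seed 11 --out zone.tsv
clinezone orient --in zone.tsv
clinezone fit --in zone.tsv --heading 207 --share width
clinezone ldscan --in zone.tsv --heading 207 --window 200 --step 100 --out ld.tsv
```

or end to end with a YAML config via `clinezone run --config run.yaml`,
which writes every stage's output plus a checksummed manifest.

## Layout

| module | contents |
| --- | --- |
| `clinezone.io` | genotype-table reading/validation/writing, result serialization |
| `clinezone.simulate` | `SimConfig`, `simulate_zone`, `sample_genotype_at` |
| `clinezone.transect` | projection, PAVA monotone clines, orientation ML |
| `clinezone.cline` | tanh clines, profiles, support limits, shared-parameter LRTs |
| `clinezone.concordance` | hybrid indices, Barton's (α, β) |
| `clinezone.disequilibrium` | heterozygote deficit, gametic & cytonuclear D, window scan |
| `clinezone.classify` | Q-threshold calls, genotype-frequency-class posteriors |
| `clinezone.habitat` | association chi-square, habitat-and-cline LRT, elevation ANOVA |
| `clinezone.pipeline` | `RunConfig`, `run_all`, manifest |

See `docs/methods.md` for the statistical details, assumptions and known
limitations.
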