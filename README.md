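# uspio-t2star

Quantification of ferumoxytol (USPIO) uptake from multi-echo gradient-echo
MRI via T2\*/R2\* relaxometry.

Ultrasmall superparamagnetic particles of iron oxide (USPIO) are engulfed by
tissue-resident macrophages, and the resulting local iron shortens the
effective transverse relaxation time T2\*. Comparing the relaxation rate
R2\* = 1000 / T2\*[ms] (s⁻¹) before and ~24 h after infusion therefore
measures macrophage-mediated contrast uptake: ΔR2\* = R2\*_post − R2\*_pre.
This package implements the full quantification chain for researchers
working with (or planning) USPIO-enhanced cardiac and abdominal studies:

- **`phantom`** — synthetic short-axis digital phantoms: per-tissue
  mono-exponential decay `S(TE) = S0·exp(−TE·R2*/1000)`, Rician magnitude
  noise, late-echo "blooming" artifact injection, and paired pre/post
  cohort sampling (with a BMI covariate) from published normal values at
  1.5 T and 3 T.
- **`relaxometry`** — log-linear, nonlinear (optionally with a
  background-noise offset) and noise-floor-truncated decay fits, and
  vectorized per-pixel T2\*/R2\* mapping with an r² > 0.85 quality gate.
- **`artifact_qc`** — automated detection of artifact-corrupted late echoes
  from the initial decay trajectory, exclusion-and-refit, and down-weighted
  fitting.
- **`roi`** — organ ROIs and AHA 16-segment myocardial sectors; ROI R2\* as
  the inverse of the mean T2\*; panmyocardial averaging; ΔR2\*.
- **`cohort`** — paired pre/post tests (two-level repeated-measures ANOVA ≡
  paired t²), Welch field-strength contrasts, BMI correlation, and a
  normal-values summary table.
- **`io` / `pipeline` / `cli`** — 4D NIfTI + JSON-sidecar interchange, map
  products (including a 0–60 ms T2\* colourmap PNG), provenance hashing,
  and the `uspio` command line (`simulate | map | roi | cohort | report | run`).

## Worked example

```python
import numpy as np
from uspio_t2star import (PhantomSpec, make_phantom, simulate_multiecho,
                          compute_map, roi_statistics, delta_r2star)

stats = {}
for session, r2star_truth in (("pre", 22.0), ("post", 358.3)):  # spleen, 1.5 T
    truth = make_phantom(PhantomSpec(tissue_r2star={"spleen": r2star_truth}))
    r2map = compute_map(simulate_multiecho(truth, session=session))
    stats[session] = roi_statistics(r2map, truth.mask("spleen"), tissue="spleen",
                                    session=session)
print(f"spleen ΔR2* = {delta_r2star(stats['pre'], stats['post']):.1f} s^-1")
```

prints `spleen ΔR2* = 336.3 s^-1`: a noiseless phantom generated at the
1.5 T spleen normal values and pushed through mapping and ROI aggregation
returns exactly the post-minus-pre change those values imply.

The numbered drivers under `analysis/` run the study-style analyses end to
end and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py   # sample cohorts, write example stacks
python analysis/02_fit_maps.py          # per-pixel maps + 0-60 ms colourmaps
python analysis/03_artifact_workflow.py # blooming inject -> detect -> refit
python analysis/04_roi_segments.py      # AHA segments + per-ROI statistics
python analysis/05_cohort_summary.py    # normal-values table + statistics
```

`03_artifact_workflow.py`, for example, reports (500 noisy replicates,
true R2\* 60.5 s⁻¹, blooming from echo 4, first-echo SNR 20):

```
detection rate: 100.0% (500 replicates)
median |error|: naive fit 156.9 s^-1 -> refit after exclusion 32.5 s^-1
median r^2: before 0.835 -> after 0.899
```

i.e. the automated late-echo exclusion recovers most of the accuracy the
artifact destroys, while the r² improvement alone would understate how
corrupted the naive fit was.

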