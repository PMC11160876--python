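# netprog

Longitudinal brain-network progression analysis for prodromal
parkinsonism.  Isolated REM sleep behavior disorder (iRBD) precedes
Parkinson's disease and dementia with Lewy bodies by years; metabolic
imaging shows the disease-related motor (PDRP) and cognitive (PDCP)
covariance patterns rising before diagnosis while striatal dopamine
transporter (DAT) binding falls.  `netprog` implements the complete
analysis chain for such studies as a tested Python package, exercisable
end to end on a synthetic longitudinal cohort generator:

* **Pattern expression scoring** — a subject's expression of a
  region-weighted topography `w` is the inner product
  `s = Σ_r w_r (q_r − q̄ − ref_r)` of the weights with the subject's
  mean-centred log regional profile after subtracting the healthy
  reference profile, z-scored against healthy controls (controls score
  0 ± 1 by construction).  Global-metabolic-rate (GMR) ratio
  normalisation and nodal two-sample comparisons are included.
* **Gain and loss of metabolic connections** — group adjacency matrices
  as entrywise medians of Pearson correlations over 100 subject-level
  bootstrap resamples; an edge is *gained* when |r| ≥ 0.6 in cases but
  not controls with |Δr| > 0.4 (cutoff calibrated by 1000 label
  permutations of the healthy graph), *lost* for the mirrored predicate;
  detections are bootstrap-confirmed, restricted to anatomically
  plausible pairs (≤ 2 hops), and tallied by network category
  (within-motor, bridging, within-cognitive).
* **Weighted graph metrics** — degree centrality (edges per node),
  Onnela weighted clustering, characteristic path length (edge length
  1/w), small-worldness `S = (C/C_null)/(L/L_null)` against a
  degree-preserving rewired null, and degree assortativity, swept over
  correlation thresholds r = 0.30…0.65 with Bonferroni-corrected group
  comparisons.
* **Growth-model progression rates** — individual growth models (linear
  mixed models with subject-level random intercepts and slopes, ML fit)
  for expression and DAT trajectories, repeated-measures ANOVA with
  paired Bonferroni post-hocs, Bland–Altman within-subject correlation,
  and noncentral-t power/sample-size computation.
* **Phenoconversion prediction** — DAT binding as the striatal-to-
  occipital ratio (S − O)/O expressed as % of the healthy mean; the
  dual-threshold predictor extrapolates expression upward at the cohort
  rate and putamen DAT downward until *both* early-disease thresholds
  (z ≥ +1.5, DAT ≤ 40 % of normal) are crossed, with high/intermediate/
  low risk-zone classification and baseline-expression survival-time
  correlations.

## Worked example

```python
from netprog.cohort import CohortConfig, generate_cohort
from netprog.expression import score_profiles
from netprog.longitudinal import fit_igm
from netprog.phenoconversion import predict_conversion_time
import pandas as pd

coh = generate_cohort(CohortConfig.paper_longitudinal(seed=5))

case_z, hc_z, _ = score_profiles(
    coh.case_profiles_by_timepoint, coh.hc_profiles, coh.patterns["PDRP"]
)
rows = [(s, ss.timepoint, z) for ss in case_z
        for s, z in zip(ss.subject_ids, ss.z)]
est = fit_igm(pd.DataFrame(rows, columns=["subject", "time", "value"]))
print(f"motor-pattern progression: {est.slope:+.3f} z/year "
      f"(SE {est.slope_se:.3f}, p {est.p_value:.2g})")

pred = predict_conversion_time(pdrp_z=1.04, putamen_pct=100.0)
print(f"years to both thresholds: {pred.t_predicted:.1f} "
      f"(expression {pred.t_pdrp:.1f}, DAT {pred.t_dat:.1f})")
```

Output:

```
motor-pattern progression: +0.238 z/year (SE 0.042, p 1.7e-08)
years to both thresholds: 12.5 (expression 2.0, DAT 12.5)
```

The fitted slope recovers the cohort's planted drift of 0.23 z-points
per year from the scored profiles alone.  The predictor extrapolates a
subject at z = 1.04 and 100 % DAT: expression crosses +1.5 after
(1.5 − 1.04)/0.23 = 2.0 years, DAT crosses 40 % after
(100 − 40)/4.8 = 12.5 years, and phenoconversion is predicted when the
later threshold is reached.

A command-line umbrella mirrors the library:

```bash
netprog simulate --out cohort_dir --seed 1
netprog progress --data cohort_dir/trajectories.csv --measure PDRP_z --out rate.json
netprog run --out full_run --seed 1     # simulate → score → connect → graph → progress → predict
```

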