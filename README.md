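# npcmorph

Permutation and non-parametric-combination (NPC) group statistics for
ROI-based brain morphometry, built for two-group clinical studies of
cortical thickness (CTh), surface area (CSA) and volume — the typical
setting being a patient cohort (e.g. adolescents with anorexia nervosa)
against matched controls, with questionnaire batteries alongside the
imaging measures.

Thickness and area are developmentally distinct quantities that can move
at different rates or in opposite directions, so collapsing them into
volume can mask focal effects. The NPC approach tests each metric
separately with a permutation Mann–Whitney U test and combines the
per-permutation p-values with Fisher's method,

    T = −2 · Σᵢ ln pᵢ ,

using the *same* group-label shuffles for every metric (synchronized
permutations preserve the thickness–area dependence). The joint p-value
is read off the permutation distribution of T with the add-one
convention p = (r + 1)/(B + 1), and Benjamini–Hochberg FDR controls
multiplicity across regions.

Around that core the package provides the full analysis toolkit such a
study needs:

- **`npcmorph.io`** — FreeSurfer `aparcstats2table`/`asegstats2table`
  dialect reader/writer, hemisphere combination (volume summed, CTh/CSA
  averaged), optional ICV normalization.
- **`npcmorph.group_stats`** — Shapiro–Wilk/Levene-gated pooled-t /
  Welch / Mann–Whitney comparisons, Cohen's *d* and *r* = Z/√N effect
  sizes, summary-statistic t-tests, BH-FDR.
- **`npcmorph.npc`** — permutation tests (Monte-Carlo and exhaustive),
  Fisher combination, synchronized NPC, regional batteries.
- **`npcmorph.association`** — Kendall tau-b screens with per-table FDR
  families; LMS-based BMI-SDS (z = ((BMI/M)^L − 1)/(L·S)) with a
  clearly-labelled synthetic growth reference for tests and demos.
- **`npcmorph.regression`** — OLS with standardized betas, VIF, and
  SPSS-style backward elimination (POUT = 0.10).
- **`npcmorph.power`** — Monte Carlo power for the permutation U test
  and the analytic minimum detectable effect size.
- **`npcmorph.synthetic`** — a seeded cohort generator (default 26
  patients / 24 controls, focal precuneus-thickness deficit,
  severity-factor-driven integer questionnaire scores) so the whole
  pipeline is testable without clinical data.
- **`npcmorph.pipeline` / `npcmorph.cli`** — config-driven end-to-end
  orchestration (`npcmorph run --config cfg.yaml --seed 1 --out results`).

## Worked example

The numbered scripts under `analysis/` run the full sequence on the
bundled synthetic cohort; `python analysis/01_simulate_cohort.py` then
`python analysis/04_regional_npc.py` prints:

```
                  region  p_thickness   p_area  fisher_statistic  joint_p  joint_p_adjusted
 caudalanteriorcingulate     0.210958 0.402919              4.93 0.286543          0.358178
rostralanteriorcingulate     0.265347 0.166367              6.24 0.179364          0.358178
      posteriorcingulate     0.926215 0.961808              0.23 0.992402          0.992402
        isthmuscingulate     0.500900 0.129174              5.48 0.235353          0.358178
               precuneus     0.000200 0.260948             19.72 0.001000          0.004999

minimum adjusted thickness p: precuneus (adj p = 0.0010)
```

The generator injected a standardized thickness deficit of d = −1.1 in
the precuneus only. The per-metric column shows the permutation test
finding it (empirical p = 0.0002 at B = 5000, the add-one minimum being
1/5001), area remaining null, and the Fisher combination carrying the
one-metric effect through to a joint p of 0.001 (FDR-adjusted 0.005
across the five a-priori regions) — exactly the behaviour the joint
test is designed for. The other scripts cover clinical comparisons
(`02`), the null global-volume battery (`03`), the tau-b correlation
screen on FDR-surviving regions (`05`), backward-elimination regression
(`06`), Monte Carlo power with the analytic minimum detectable
d ≈ 0.79 at n = 26/24 (`07`), and the exploratory battery (`08`).

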