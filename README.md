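# multipattern

Multimorbidity — living with two or more chronic conditions — is the most
common clinical presentation of chronicity in adults, and chronic diseases
do not co-occur at random: they cluster into *multimorbidity patterns*
whose membership shifts over time.  `multipattern` is a Python package for
discovering these patterns in longitudinal electronic-health-record
cohorts, characterising them clinically, linking them into trajectories,
and estimating their association with mortality and acute disease.  It is
aimed at epidemiologists and biostatisticians working with closed
chronic-disease cohorts followed over repeated cross-sections (waves).

Because real primary-care extracts are access-restricted, the package
ships a first-class synthetic-cohort generator (a Bernoulli-mixture model
over a ~130-condition catalog with logistic mortality, losses to
follow-up, incident disease, and ATC-coded dispensations) so that every
stage is testable end to end.

## Method

Given a closed cohort of multimorbid adults (≥2 chronic conditions at
baseline, ages 18–65), at each wave the package:

1. **builds a binary disease matrix** `x[i,j] ∈ {0,1}` over the patients
   still included (dead and lost-to-follow-up patients are excluded) and
   the conditions with wave prevalence ≥ 1.0% (inclusive);
2. **partitions patients with k-means under Jaccard distance**.  Lloyd's
   algorithm runs with real-valued centroids (within-cluster prevalence
   vectors) and the generalised (Tanimoto) Jaccard distance
   `d(x, c) = 1 − Σ_j min(x_j, c_j) / Σ_j max(x_j, c_j)`,
   which reduces to the set Jaccard distance `1 − |A∩B|/|A∪B|` on binary
   profiles.  The number of patterns k is the smallest candidate whose
   Caliński–Harabasz score is within a tolerance (default 10%) of the best
   among *clinically valid* candidates;
3. **profiles each pattern** by the prevalence ratio `PR = OP/EP`, where
   OP is a condition's observed prevalence inside the pattern and EP its
   expected prevalence in the wave population.  A condition is *essential*
   to a pattern when `PR ≥ 2.0 and OP ≥ 10%`, or `OP ≥ 20% and PR ≥ 1.5`;
   a partition is valid only if every pattern has ≥1 essential condition;
4. **links waves into trajectories**: flows of patients between
   wave-specific patterns, with absorbing Death and Lost states, exported
   as a flow table and an alluvial diagram whose box/stripe sizes are
   proportional to counts;
5. **estimates adjusted associations**: age- and sex-adjusted logistic
   regression of death-by-horizon on pattern membership (reference = the
   pattern with the lowest crude mortality), and multinomial logistic
   regression of pattern membership on acute-disease exposure during the
   preceding follow-up period (baseline category = the smallest pattern).
   Effects are odds ratios with Wald 95% CIs, `exp(β ± 1.96·SE)`.

Drug use is counted as distinct fourth-level ATC groups (chemical
subgroup, first five code characters) per follow-up period; repeated acute
diagnoses are likewise counted once per period.

## Worked example

Run the full pipeline on a 5,000-patient synthetic demonstration cohort
(three planted patterns, two 4-year follow-up periods):

```sh
multipattern run --seed 42 --n-patients 5000 --out demo/
```

or equivalently from Python:

```python
import multipattern as mp
manifest = mp.run_pipeline(mp.demo_run_config("demo/", seed=42, n_patients=5000))
```

With seed 42 this prints/writes (`demo/manifest.json`,
`demo/kselection_2011.json`, `demo/patterns_2011.json`, ...):

```
included:  [5000, 4884, 4742]   deaths: [23, 60]   lost: [93, 198]
chosen_k:  3   CH: {2: 1635.1, 3: 1857.7, 4: 1306.9, 5: 1030.2}
pattern 0  "C013 & C020"  n=1230 (24.60%)  8-year mortality 27 (2.20%)
pattern 1  "C007 & C000"  n=1965 (39.30%)  8-year mortality 23 (1.17%)
pattern 2  "C028 & C027"  n=1805 (36.10%)  8-year mortality 10 (0.55%)
mortality OR (ref = pattern 2): pattern 0 → 4.20 (2.02–8.76),
                                pattern 1 → 2.08 (0.99–4.41)
```

Reading this output: the closed cohort starts at 5,000 and attrition
(death/loss) is conserved wave by wave; the Caliński–Harabasz curve peaks
at the planted k = 3; each pattern is named mechanically from its top
essential conditions by prevalence ratio; and the pattern planted with the
highest mortality log-odds shows an adjusted odds ratio above 1 against
the lowest-mortality reference.  Other artifacts include per-wave
labels (`labels.csv`), descriptive tables (`table_<wave>.csv`),
trajectory flows and the alluvial plot (`trajectories/`), and the
adjusted-OR tables (`associations.json`).

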