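# ecgcreativity

Analysis pipeline for detecting **creativity states from single-lead ECG**.
The scientific question: when a person moves from rest into figural
creative-thinking tasks, does the autonomic nervous system leave a
measurable trace in heart-rate variability (HRV) — and is that trace strong
enough to classify the recording condition, and to separate high- from
low-creativity individuals?

The package implements the full chain for a four-condition protocol (rest
plus three creativity tasks, each subject carrying a 0–100 creativity
score):

- **Synthetic cohorts** (`ecgsim`): lead-II-like ECG with controllable mean
  heart rate, SDNN, LF/HF spectral balance, 50 Hz powerline interference,
  baseline wander and broadband noise, plus per-subject creativity scores
  coupled to task physiology. No data download is needed — everything is
  generated, seeded and reproducible.
- **Preprocessing** (`preprocess`): 50 Hz notch, order-4 Chebyshev II
  band-pass (0.3–250 Hz), 0.6 s lead-in trim, 2-minute analysis segment,
  5 s windows.
- **Beat detection** (`beats`): Pan-Tompkins-style R-peak detector and the
  NN-interval series with a 250–3000 ms physiologic gate.
- **Features**: the 19-column panel — time-domain NN statistics
  (mean, SDNN, RMSSD, NN50, pNN50, min/max/median), spectral band powers
  (total, ULF, VLF, LF, HF and the LF/HF sympathovagal index, from a Welch
  PSD of the 4 Hz-resampled tachogram), and nonlinear descriptors (Katz
  fractal dimension `D = log₁₀n / (log₁₀n + log₁₀(d/L))`, order-α Renyi
  entropy `(1−α)⁻¹ log Σ pᵢ^α`, and Shannon / log-energy / norm entropies of
  orthogonal wavelet coefficients).
- **Statistics** (`stats_compare`): two-sided Wilcoxon rank-sum tables over
  all six condition pairs, exact by enumeration for small samples, starred
  at p < 0.05.
- **Classification** (`classify`, `anfis`): RBF-kernel SVM and a
  from-scratch first-order Sugeno ANFIS (subtractive-clustering rule
  initialization, Gaussian memberships, hybrid least-squares/gradient
  training), evaluated over repeated stratified 70/30 splits with
  accuracy, sensitivity, specificity, LR+ = sens/(1−spec),
  LR− = (1−sens)/spec and error rate.
- **Orchestration** (`pipeline`): one seeded command runs
  simulate → preprocess → features → statistics → classification,
  including creativity-score normalization and high (>70) / low (<30)
  group formation.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from ecgcreativity.core import Condition
from ecgcreativity.classify import SplitSpec, format_lr
from ecgcreativity.ecgsim import simulate_cohort
from ecgcreativity.pipeline import LINEAR_FEATURES, classify_pair, extract_features
from ecgcreativity.stats_compare import pairwise_wilcoxon, significance_table

records = simulate_cohort(8, seed=42)          # 8 subjects x 4 conditions
table = extract_features(records)              # one row per 5 s window
print(f"{len(table)} windows from {table['subject_id'].nunique()} subjects")

pvals = pairwise_wilcoxon(table, ["mean_nn", "sdnn", "lf_hf_ratio"])
print(significance_table(pvals).to_string())

rep = classify_pair(table, (Condition.REST, Condition.TASK1), LINEAR_FEATURES,
                    "svm", SplitSpec(n_runs=20, seed=1))
print(f"accuracy {rep.accuracy:.2f}%  sensitivity {rep.sensitivity:.2f}%  "
      f"specificity {rep.specificity:.2f}%  LR+ {format_lr(rep.lr_pos)}")
```

Output:

```
768 windows from 8 subjects
            rest_vs_task1 rest_vs_task2 rest_vs_task3 task1_vs_task2 task1_vs_task3 task2_vs_task3
mean_nn          <0.0001*      <0.0001*      <0.0001*       <0.0001*       <0.0001*       <0.0001*
sdnn             <0.0001*       0.0002*      <0.0001*        0.0059*         0.0854         0.3387
lf_hf_ratio      <0.0001*      <0.0001*       0.0002*       <0.0001*       <0.0001*         0.2887
accuracy 98.28%  sensitivity 98.36%  specificity 98.19%  LR+ 45.57
```

Reading it: the simulated task conditions raise heart rate (shorter mean NN
interval) and shift sympathovagal balance (higher LF/HF) relative to rest,
the rank-sum tables flag those shifts as significant, and the 14
linear features separate rest from task 1 at ~98 % mean accuracy over 20
random 70/30 splits.  A likelihood ratio printed as `>100` marks a run
average with perfect specificity.

The same stages are available from the shell:

```sh
ecgcreativity simulate -n 20 -s 1 --out recs/
ecgcreativity features --in recs/ --out feats.csv
ecgcreativity stats --features feats.csv --out tables/
ecgcreativity classify --features feats.csv --pair rest,task1 --model svm
ecgcreativity run-all -n 20 -s 1 --out study/     # everything, one seed
```

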