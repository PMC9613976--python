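# speechdx

Composite acoustic speech indices for differential diagnosis of parkinsonian
syndromes (Parkinson's disease, progressive supranuclear palsy, multiple
system atrophy) at desk scale.

The package covers the full chain:

1. **Cohort synthesis** — a calibrated generator that draws 26 acoustic
   features for HC/PD/PSP/MSA subjects from published-style group statistics,
   with a latent severity that also drives a synthetic clinical score
   (NNIPPS-style), plus a WAV generator for vowel and syllable-train tasks.
2. **Acoustic front-end** — pitch tracking, voiced/unvoiced/pause
   segmentation, syllable-train analysis and the derived features
   (stdF0, jitter, PSI, stdPSD, VD, DDKI, DDKR, EST, RST, AST, GVI)
   from mono WAV files via `scipy.io.wavfile`.
3. **Normalization** — impairment-oriented z-scores referenced to the HC
   group, with per-feature direction conventions.
4. **Indices** — subsystem scores (F_resp, F_phon, F_art, F_pros, F_time and
   the hypokinetic/ataxic/spastic components), the summary indices SSI1/SSI2
   and the dysarthria-type indices DTI1/DTI2.
5. **Combination search** — exhaustive best-subset search per subsystem with
   a deterministic three-stage decision rule, verified against a brute-force
   oracle.
6. **Statistics** — normality-screened omnibus tests (ANOVA or
   Kruskal–Wallis) with Tukey post hocs, and normality-routed
   Pearson/Spearman correlations against clinical scores.
7. **Classification** — leave-one-subject-out logistic regression per
   contrast (PSP vs MSA, PD vs MSA, PD vs PSP) with AUC, Youden operating
   point and decision-boundary export.
8. **CLI & report** — a `speechdx` command-line tool and a deterministic,
   byte-reproducible report-bundle pipeline with stage-specific exit codes.

## Worked example

### Command line

Simulate a default cohort (150 HC / 20 PD / 20 PSP / 25 MSA), compute
indices, and classify PSP vs MSA with the combined DTI predictors:

```sh
$ speechdx simulate --seed 1 --out features.csv --clinical-out clinical.csv
wrote 215 subjects to features.csv

$ speechdx indices features.csv --out indices.csv
wrote indices for 215 subjects to indices.csv

$ speechdx classify indices.csv --contrast PSP_vs_MSA --predictors CDTI
{
  "accuracy": 71.11111111111111,
  "auc": 0.748,
  ...
  "sensitivity": 60.0,
  "specificity": 80.0,
  ...
}
```

Run the best-subset search for a contrast:

```sh
$ speechdx search features.csv --contrast PSP MSA
{
  "F_art": {
    "p_value": 6.242182789292755e-06,
    "stage": "single-significant",
    "subsets": [["RFA_m", "RFA_t"]],
    ...
```

Produce a complete, byte-reproducible report bundle from a YAML config:

```sh
$ cat config.yaml
seed: 42
n_per_group: {HC: 40, PD: 10, PSP: 10, MSA: 12}
severity_coupling: 0.5

$ speechdx report --config config.yaml --out bundle
report bundle written to bundle (18 classification rows)
```

The bundle contains the features, z-scores, indices, search results,
group-comparison and correlation tables, per-contrast LOSO predictions,
a Markdown report, and a `MANIFEST` with SHA-256 checksums of every file.
Rerunning with the same config yields byte-identical files.

Extract vowel or syllable-train features directly from a WAV file:

```sh
$ speechdx extract recording.wav --task a
```

### Python API

```python
from speechdx import (CohortSpec, simulate_feature_cohort, fit_normalizer,
                      apply_normalizer, compute_indices, loso_logistic)

table, clinical = simulate_feature_cohort(CohortSpec(seed=1))
z = apply_normalizer(fit_normalizer(table), table)
ind = compute_indices(z)
print(ind.groupby("group")[["SSI1", "SSI2", "DTI1", "DTI2"]].mean().round(2))
```

```
       SSI1  SSI2  DTI1  DTI2
group
HC     0.00 -0.00  0.00 -0.00
MSA    2.80  2.02  5.37  2.37
PD     0.96 -0.24  1.16 -0.42
PSP    3.77  1.99  8.43  2.55
```

```python
sub = ind[ind["group"].isin(("PSP", "MSA"))]
rep = loso_logistic(sub[["DTI1", "DTI2"]], sub["group"].to_numpy(),
                    positive_label="PSP")
print(f"CDTI PSP vs MSA: accuracy {rep.accuracy:.1f}%, AUC {rep.auc:.2f}")
# CDTI PSP vs MSA: accuracy 71.1%, AUC 0.75
```

HC rows average to exactly zero by construction (indices are HC-referenced
z-score composites); PSP and MSA score highest on the hypokinetic-spastic
(DTI1) and ataxic-leaning (DTI2) axes respectively.

## Documentation

See `docs/methods.md` for the generative model, front-end algorithms,
index definitions, statistical routing and reproducibility guarantees.
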