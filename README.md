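# recallorg

Analysis pipeline for the organization of free recall: lag
conditional-response probabilities (lag-CRP), rank-based Temporal and
Semantic Factor scores, serial-position and probability-of-first-recall
curves, intrusion/repetition scoring, semantically constrained study-list
construction, a synthetic cue-mixture recall generator, and the
condition-contrast statistics layer (mixed ANOVA, Welch t,
sign-flipping permutation tests, correlations).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` carries the acceptance criteria. One test —
the no-temporal-effect clause of the qualitative study reproduction — is
expected to fail: under the default generator parameters the semantic
cue weight that separates the conditions necessarily shifts temporal
clustering as well (see the module docstring there).

## Command line

Everything is reachable through the `recallorg` entry point:

```sh
# constrained study lists from a similarity matrix CSV
recallorg makelists --sim-matrix sim.csv --n-lists 1 --length 32 \
    --pairs 16 --threshold 0.7 --orderings 4 --seed 1 --out lists/

# synthetic two-condition cohort (transcripts + ground-truth YAML)
recallorg simulate --subjects 141 --seed 1 --lam-same 0.15 \
    --lam-diff 0.45 --rho-same 0.05 --rho-diff 0.10 --out cohort/

# per-subject measures, lag-CRP and serial-position CSVs
recallorg score --lists cohort/study_lists.csv \
    --recalls cohort/recalls.csv --sim-matrix cohort/similarity.csv \
    --edit-distance 1 --out scored/

# condition contrasts
recallorg analyze --measures scored/measures.csv --n-perm 10000 \
    --seed 1 --out contrasts/

# everything end to end, with a reproducibility manifest
recallorg pipeline --seed 1 --out run/
```

`pipeline` accepts a YAML config (`--config run.yaml`) mirroring the
flags; each stage gets a logged sub-seed derived from the master seed,
and reruns with the same config reproduce every CSV byte for byte.

## File formats

All artifacts are plain UTF-8 CSV/YAML:

- study lists: `list_id,serial_position,word[,pair_id]`;
- similarity matrix: square CSV, first row/column = vocabulary,
  symmetric values in [0, 1], unit diagonal;
- recall transcripts: `subject_id,condition,condition_order,
  output_position,response[,list_id]`;
- measures: one row per subject × condition with recall counts, factor
  scores, intrusion counts and first-recall position.

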