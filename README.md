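# plaspred

SVM-based prediction of **plasminogen activators** (Pg-activators) and
their subfamilies from protein sequence composition.

Plasminogen activators convert plasminogen into plasmin, the protease
that dissolves fibrin clots, and are the backbone of thrombolytic
therapy. They fall into four subfamilies: the bacterial *indirect*
activators **staphylokinase (SAK)** and **streptokinase (SK)**, which
form stoichiometric complexes with plasminogen, and the eukaryotic
*direct* activators **tissue plasminogen activator (tPA)** and
**urokinase (UK)**, trypsin-like serine proteases that cleave
plasminogen themselves. The prokaryotic families are cysteine- and
tryptophan-free and lysine-rich; the eukaryotic ones contain Cys/Trp —
composition alone carries a strong family signal, which is what this
package exploits.

## Method

A sequence is encoded as a fixed-length composition vector:

- **AC** (20-dim): amino-acid composition, `AC_i = n_i / L`;
- **DC** (400-dim): dipeptide composition over the `L − 1` overlapping
  adjacent pairs, `DC_ij = n_ij / (L − 1)`;
- **PSSM** (400-dim): PSI-BLAST profile scores squashed through a
  logistic sigmoid and pooled per (sequence residue, profile column);
- **HYBRID** (420-dim): AC ‖ DC.

Classification is hierarchical with RBF-kernel SVMs,
`K(x, y) = exp(−γ‖x − y‖²)`:

1. a **level-1 gate** (all four subfamilies vs. non-activators) calls
   PG when its decision score is ≥ a user threshold (default 0);
2. four **one-vs-rest subclass models** (each subfamily vs. the other
   three) assign gated sequences to the argmax subfamily.

Per-model optimised (γ, C) values ship as defaults. Performance is
evaluated by five-fold cross-validation with accuracy, sensitivity,
specificity, MCC, multiclass confusion tables and ROC/AUC.

Because curated training sequences cannot be bundled, a seeded
**synthetic benchmark** emulates the real dataset: five compositional
families with the real class sizes (69 SAK, 167 SK, 11 tPA, 109 UK,
501 negatives), Cys/Trp-free Lys-rich prokaryotic profiles, and a
Markov dipeptide signal for SK.

## Worked example

```sh
plaspred simulate --seed 7 --fasta bench.fasta --manifest bench.tsv
# wrote 857 sequences ({'SAK': 69, 'SK': 167, 'tPA': 11, 'UK': 109, 'NEG': 501})

plaspred train --fasta bench.fasta --manifest bench.tsv --method DC --out bundle
plaspred evaluate --fasta bench.fasta --manifest bench.tsv --method DC --seed 7
```

```text
fold    ACC      SN       SP       MCC
0       90.1163  82.3529  95.1923  0.7925
1       93.6047  91.5493  95.0495  0.8679
2       91.8129  93.1507  90.8163  0.8348
3       92.3977  92.9577  92.0000  0.8449
4       91.2281  90.4110  91.8367  0.8211
mean    91.8319  90.0843  92.9790  0.8322
```

Each row is one held-out fold of the activator-vs-non gate; the mean
row is the unweighted fold average (ACC/SN/SP in percent, MCC in
[−1, 1]).

```sh
plaspred predict --model bundle --input query.fasta
```

```text
sequence_id  level1_score  level1_call  threshold  subclass_call  score_SAK  score_SK  score_tPA  score_UK
q1           10.9897       PG           0.0000     SAK            2.1425     -0.2444   -3.2167    -2.6110
```

`level1_score` ≥ threshold gates the sequence as an activator (PG);
the four one-vs-rest scores are then computed and the argmax
(here SAK, a Lys-rich Cys-free query) is the subfamily call. Raising
`--threshold` trades sensitivity for precision and can only remove PG
calls. `plaspred stats` prints molecular weight, residue counts and
percent composition per sequence.

The same workflow is available as a library:

```python
from plaspred import PgActivatorModel, default_benchmark

data = default_benchmark(seed=7)
results = PgActivatorModel(data, method="DC").fit()
print(results.summary())
calls = results.predict(data.sequences[:3])
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the pipeline from scratch: it generates the default synthetic
benchmark, five-fold cross-validates the DC gate at the shipped
defaults, cross-validates the full two-stage hierarchical prediction
(printing the multiclass confusion table and pooled held-out ROC AUC),
and trains and summarises a complete model bundle, logging progress to
stderr and writing the JSON result object to `--out`.

## Layout

- `src/plaspred/seqio.py` — FASTA I/O, validation policies, CD-HIT-style
  greedy redundancy filter, molecular weight/composition statistics
- `src/plaspred/features.py` — AC/DC/PSSM/HYBRID encoders, ASCII PSSM
  parsing, PSI-BLAST/mock/precomputed profile providers
- `src/plaspred/model.py` — `PgActivatorModel` / `PgActivatorResults`,
  bundle persistence, default (γ, C) tables
- `src/plaspred/evaluation.py` — folds, metrics, confusion tables, ROC
- `src/plaspred/synthetic.py` — seeded family profiles and benchmark
- `src/plaspred/cli.py` — `plaspred` command-line interface

See `docs/methods.md` for modelling assumptions and numerical choices.
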