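# Methods

## The prediction problem

Plasminogen activators convert plasminogen to plasmin and drive
fibrinolysis. The four subfamilies differ sharply in composition: the
prokaryotic indirect activators staphylokinase (SAK, ~136 residues) and
streptokinase (SK, ~414 residues) contain no cysteine or tryptophan and
are strongly lysine-enriched, while the eukaryotic direct activators
tPA (~530 residues) and urokinase (~411 residues) are Cys/Trp-containing
multi-domain serine proteases. plaspred predicts, from sequence alone,
(1) whether a protein is an activator and (2) if so, its subfamily.

## Feature encodings

All encodings are fixed-length, order-stable vectors in [0, 1].
Residues are indexed alphabetically by one-letter code
(`ACDEFGHIKLMNPQRSTVWY`) and dipeptides row-major (first residue
major); the ordering is checksummed into every saved model bundle so a
bundle refuses to score features from an incompatible layout.

- **AC** (20): fraction of each amino acid, `n_i / L`.
- **DC** (400): fraction of each ordered adjacent pair among the
  `L − 1` overlapping windows. The denominator `L − 1` (occurrences in
  the sequence, not `20²`) is the standard convention for this encoding
  family; DC therefore sums to exactly 1, as AC does.
- **PSSM** (400): given an `L × 20` PSI-BLAST log-odds profile, each
  score `s` is normalised with the logistic sigmoid `σ(s) = 1/(1+e^−s)`
  and entry `(a, b)` is `Σ_{p: seq[p]=a} σ(score[p, b]) / L`. The
  sigmoid guarantees the [0, 1] range; dividing by `L` rather than by
  per-residue counts makes absent residues contribute exact zeros.
  This normalise-then-pool definition is a documented stand-in: the
  upstream profile toolchain's exact reduction is not published.
- **HYBRID** (420): AC ‖ DC concatenation.

Profiles come from one of three providers: `external` shells out to
PSI-BLAST (3 iterations, inclusion e-value 0.001 — conventional
profile-construction settings) against a user-supplied database;
`precomputed` reads `<id>.pssm` ASCII files; `mock` builds a
deterministic seeded profile (uniform integers in [−5, 5] plus a +4
bias on each position's own residue column) so the whole PSSM pipeline
is testable offline. Mock profiles emulate only self-conservation, not
real homology structure: a green PSSM test establishes pipeline
correctness, not biological performance.

## Classifier

Soft-margin RBF SVMs (scikit-learn/libsvm) with
`K(x, y) = exp(−γ‖x − y‖²)` — the same parameterisation as SVM-light,
so the shipped per-model (γ, C) defaults transfer directly, e.g. the
level-1 DC gate uses γ = 3, C = 375.

Hierarchy: the level-1 gate trains all four subfamilies (pooled) as
positives against the non-activator set; each subclass model trains one
subfamily against the other three, with the non-activator class
excluded — the gate, not the subclass models, is responsible for
rejecting non-activators. A sequence is called PG when its level-1
decision score is ≥ the threshold (default 0, the SVM margin; exposed
on the CLI). Subclass assignment is the argmax of the four one-vs-rest
decision scores; how to combine one-vs-rest scores is a genuinely open
design point, and argmax of raw decision values was chosen for
simplicity and monotonicity, with ties broken in the fixed order
SAK < SK < tPA < UK so the call is total and deterministic. Scores are
uncalibrated margins, not probabilities; calibration is out of scope.

A fitted bundle serialises to a directory of per-model joblib files
plus a JSON manifest (method, ordering checksum, γ/C, training counts
and accuracy); loading verifies the checksum.

## Evaluation

- ACC, SN, SP (percent) and MCC from binary confusion counts, with the
  standard forms `SP = TN/(TN+FP)` and the square-rooted MCC
  denominator. A metric whose defining marginal is zero is reported as
  NaN with a warning, never silently as 0.
- Five-fold cross-validation: seeded shuffle, round-robin assignment
  (fold sizes differ by ≤ 1), unweighted per-fold metric averaging;
  pooled counts are retained for inspection. Unstratified splitting is
  the default for the binary gate; the hierarchical CV stratifies by
  default because an 11-member class can otherwise vanish from a
  training fold.
- ROC via threshold sweep over unique scores (ties grouped into one
  step) with trapezoidal AUC; the suite checks it against an exhaustive
  pairwise-comparison oracle to 1e-12.

## Synthetic benchmark

Families are compositional nulls: lengths uniform in a per-family
range bracketing the real proteins, residues i.i.d. from a per-family
distribution, except SK which is a first-order Markov chain (each
row of the transition matrix boosts the alphabetical successor residue
by a factor 5) to plant a dipeptide-order signal that AC cannot see.
Class sizes replicate the real dataset (69/167/11/109 + 501) so the
severe tPA imbalance — the known source of tPA/UK confusion — is
exercised. Profiles: SAK (K 15%, N 7.5%, Y 5.5%, no C/W), SK (K 12%,
E 10%, I 8%, D 7.5%, no C/W), tPA (C 4%, W 2.5%, A 11.5%, G 10.5%,
R 8.5%), UK (C 3.5%, W 1.8%, S 10.5%, G 9.5%, T 8%, D 7%), negatives at
SwissProt-like background frequencies; non-overridden residues are
rescaled so each profile sums to 100%. These shifts were set once so
the benchmark is "hard but learnable" — DC five-fold CV lands at
91–93% across seeds with residual tPA↔UK confusion, qualitatively
mirroring real behaviour. Profiles are editable YAML
(`plaspred simulate --profiles`, template via `--dump-profiles`).

What the generator does **not** emulate: homology, phylogeny, domain
architecture, substitution processes. A green parameter-recovery test
shows the pipeline can learn compositional family structure at realistic
class imbalance; it says nothing about accuracy on real proteins, which
additionally requires the curated database snapshot and real PSSMs.

## Numerical and edge-case choices

- Validation policies for non-standard residues: `strict` (raise),
  `drop`, and the default `map` (B→D, Z→E, U→C, J→L, O→K, X dropped) —
  residue-level handling in the original curation is unrecorded, so the
  default is a documented choice.
- Redundancy filter: transparent greedy clustering, longest-first;
  identity = exact matches at the best ungapped offset divided by the
  shorter length; the removal boundary is inclusive (≥ threshold), so
  threshold 1.0 removes exactly the duplicates. The contract tested is
  CD-HIT's: no retained pair above threshold.
- Molecular weight uses average (not monoisotopic) residue masses plus
  one water, 18.0153 Da.
- Training requires both classes; a missing subfamily downgrades the
  bundle with a warning rather than failing.
- libsvm solves to a tolerance, so decision scores after permuting the
  training set agree only to ~1e-4; serialisation round-trips are
  bit-exact.
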