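# genosl

Super Learner analysis of binary genotype data for predicting virologic
response, at small-cohort scale.

The package takes a binary mutation matrix (patients × resistance mutations)
with a continuous outcome (change in log10 viral load) and runs a full
ensemble analysis:

- **genotype** — mutation-pattern parsing (`M41L`, `T215Y/F`, `M184VI`),
  mutation calling of aligned amino-acid sequences against a reference, and
  validated dataset CSV I/O.
- **learners** — six candidate learners behind one fit/predict/selected-features
  contract: main-terms least squares (`lm1`), least squares with all two-way
  interactions (`lm2`, minimum-norm when rank-deficient), a cost-complexity
  pruned regression tree (`cart`, cp = 0.01), a random forest (`rf`,
  1000 trees, m_try = p/3), a deletion/substitution/addition polynomial model
  search (`dsa`, maxsize = 2p, interaction order ≤ 2, internal CV), and
  single-tree logic regression fitted by simulated annealing (`logicreg`).
- **crossval** — seeded near-equal k-fold partitions (k ∈ {10, 4, 3, 2}), two
  losses (squared error and one minus Pearson correlation), cross-validated
  risk, out-of-fold (level-one) prediction matrices, and mean-rank ranking
  with exact-tie averaging.
- **superlearner** — discrete selection of the minimum-risk learner, and
  weighted combination with non-negative weights summing to one fitted on the
  level-one matrix (convex QP for squared error; multi-start local search for
  the correlation loss, with every vertex evaluated so the combination never
  loses to a single candidate). An honest nested-CV risk variant is available.
- **evaluate** — full-dataset squared error, pooled 1 − R, R² (squared Pearson
  correlation), responder classification accuracy at thresholds −0.5 and −0.6
  log10 copies/mL, and per-model selected-mutations reports.
- **synthetic_data** — a cohort generator (n = 102, ten mutations with fixed
  prevalences, calibrated outcome median ≈ −0.56 with IQR ≈ (−1.2, −0.14),
  optional Gaussian-copula co-occurrence and censoring floor) plus
  planted-truth generators for learner-recovery tests.
- **pipeline** — end-to-end orchestration with shared fold assignments,
  deterministic seed fan-out, and CSV/JSON outputs per run directory.

## CLI

```sh
# synthetic cohort -> dataset CSV
genosl simulate --seed 1 --out cohort.csv

# call mutations from aligned FASTA against a reference
genosl call-mutations --fasta seqs.fasta --mutations panel.txt \
    --reference ref.fasta --out genotypes.csv

# full analysis (defaults: k in {10,4,3,2}, both losses, 5- and 6-learner
# rosters); --config takes a JSON analysis config
genosl analyze --seed 1 --out runs/demo

# print the tables of an existing run
genosl report --out runs/demo
```

The run directory contains `tables/` (per-loss/roster cross-validated risk
tables with mean-rank columns, full-model report), `weights/` (Super Learner
weights per fold scheme), `figures_data/` (accuracy long-format CSV,
selected-mutations JSON), and `meta.json` (seeds and settings for exact
re-runs).

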