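# narrecall

Semantic narrative networks and mixed-model analyses of multi-session
naturalistic recall.

`narrecall` turns annotated narrative events into semantic networks, scores
multi-session recall transcripts against them, and fits the associated
statistical models — all exercisable end to end on synthetic data with known
ground truth:

- **data_model** — domain types for video event annotations, scored recall
  transcripts (event/error/comment/other segments; central/peripheral
  details), and subjective ratings; JSON/CSV readers and writers; and the
  long-format participant × video × event × session analysis table.
- **embedding** — pluggable sentence embedders behind one contract: a
  deterministic signed bag-of-words hashing backend (512-d, no downloads)
  and an optional pretrained 512-d sentence-encoder backend; cosine
  similarity.
- **network** — per-video semantic narrative networks (nodes = events, edge
  weights = cosine similarities of description embeddings) and semantic
  centrality: weighted degree, normalized by the sum of degrees, z-scored
  within video.
- **agreement** — event-boundary matching with a ±1 s tolerance (greedy
  one-to-one matching, precision/recall/F1, mean |Δt|), ICC(2,1)/ICC(2,k)
  intraclass correlation, and a paired test on per-video event counts.
- **consistency** — Jaccard lexical overlap of recall wording, within a
  participant across sessions and between participants within group ×
  session (events recalled by ≥ 3 participants).
- **inference** — logistic/Poisson/linear mixed models with crossed
  participant and video random intercepts (Laplace maximum likelihood,
  implemented in `_glmm.py`), Type III Wald χ² tests, simple slopes, Pearson
  correlations with Fisher intervals, and a simulation-based power analysis
  with exact Clopper–Pearson binomial CIs.
- **synthetic** — seeded generation of complete studies (annotations,
  boundary raters, transcripts with word-level recall text, ratings) whose
  generative parameters match the models above, with the realized ground
  truth stored alongside.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle-equivalence
checks, GLMM parameter recovery and type-I calibration at full study scale,
power-engine checks); it takes a few minutes on one CPU. Everything else
runs in seconds.

## CLI

The console script is `narrecall` (equivalently `python -m narrecall.cli`):

```bash
# generate a full synthetic study
narrecall simulate --out study/ --seed 42

# semantic networks + centrality from annotations
narrecall network build --annotations study/annotations.json --backend hash --out nets/

# boundary agreement between two raters
narrecall agreement --ref study/boundaries.csv --obs study/boundaries.csv \
    --ref-rater rater1 --obs-rater rater2 --tol 1.0

# Jaccard consistency analyses
narrecall consistency within  --recalls study/recalls.csv --out within.csv
narrecall consistency between --recalls study/recalls.csv \
    --group young --session day1 --min-recallers 3

# mixed models on a long-format analysis table
narrecall analyze recall  --table table.csv --session day1
narrecall analyze details --table table.csv --session day2 --detail peripheral

# simulation-based power for the group x centrality interaction
narrecall power --effect 0.1 --nsim 1000 --seed 7

# validate files against the data model
narrecall validate --annotations study/annotations.json --recalls study/recalls.csv
```

All stochastic commands require an explicit seed and are fully reproducible
from it. Reports are JSON on stdout (or `--out`); logs go to stderr.

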