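# targetfish

Consensus in-silico target fishing for compound classes.

`targetfish` answers the inverse virtual-screening question: *given a family
of related compounds (for example, the dihydrochalcone natural products),
which protein targets are they likely to act on that nobody has reported
yet?* No single ligand-based prediction method is reliable on its own —
especially for natural products — so the package runs several independent
channels, subtracts what is already known from public bioactivity records,
and keeps only predictions on which multiple methods agree.

## The method

**Channels.** Each prediction channel asserts (compound, target) pairs:

- a *similarity-ensemble* channel (SEA-style): a target is described by the
  set of its known ligands; a query scores against a target by the sum of
  all pairwise Tanimoto similarities `T(a,b) = |a∧b| / |a∨b|` (ECFP4-class
  circular fingerprints) that reach a threshold (default 0.57). The raw sum
  is standardized against a background fitted on random ligand ensembles —
  mean linear in the set-size product `n·m`, standard deviation a power law
  `a·(n·m)^b` — and the z-score is converted to a BLAST-like expectation
  value through the standard Gumbel upper tail:

  `E = N · [1 − exp(−exp(−(z·π/√6 + γ)))]`

  with `N` the number of targets screened and `γ` the Euler–Mascheroni
  constant. A second similarity-ensemble channel with its own reference
  sets plays the SuperPred role.
- a *hybrid 2D/3D* channel (SwissTargetPrediction-style): per target, the
  best path-fingerprint Tanimoto `s2D` and the best electroshape similarity
  `s3D = 1/(1 + mean |Δ|)` of the query to the target's ligands are fused by
  a logistic model `P = σ(β₀ + β₁·s2D + β₂·s3D)`.
- *external matrices*: channels the package does not compute (an in-house
  pharmacophore-database screen, saved web-server downloads) are ingested
  from CSV and binarized at a per-channel cutoff. Exactly one channel is
  the **anchor**: a pair is only *eligible* if the anchor asserts it.

**Consensus.** Known interactions are mined from assay records (compound →
identifier → active assays → single-protein filter → gene → pathways) and
subtracted. Each surviving pair gets a consensus score **CS = number of
asserting methods** (anchor included): a pair predicted by the anchor and
two servers has CS = 3. Targets are then ranked by how many library
compounds reach each CS level, and selected by four criteria: high-CS hits
on the assay panel (I), library-wide frequency (II), pathway-level
consistency plus novelty (III), and assay availability (IV). Assay results
are classified with the activity rule: a mean percent inhibition is
*active* iff it is ≥ 30%, positive, and its relative standard deviation
`100·sd/|mean|` is ≤ 20%.

## Worked example

Run the whole fixture-backed pipeline (synthetic compound class with five
planted true targets among 50, plus fallible simulated prediction servers)
and inspect the target ranking:

```python
from targetfish.pipeline import RunConfig, run_full_chain
run_full_chain(RunConfig(outdir="run", seed=42))
```

`run/ranking.csv` then starts (CS level 2):

```
rank target  frequency
   1 PLT3    39
   2 PLT4    35
   3 PLT2    34
   4 PLT1    33
   4 PLT5    33
   6 CNF08   13
```

All five planted targets (`PLT*`) lead the ranking; the best impostor
(`CNF08`, a target whose ligands merely resemble the library) trails far
behind. `run/enrichment.json` quantifies why the consensus is worth the
trouble — the fold-enrichment of known interactions in the top-ranked
predictions versus a random ranking:

```json
{"PHDB": 2.40, "SEA": 2.60, "SRV1": 2.98, "SRV2": 1.63, "consensus": 4.90}
```

Every stand-alone channel is beaten by the consensus.

Classifying the bundled ten-compound inhibition panel (six candidate
targets, percent inhibition at 10 µM):

```python
from targetfish.consensus import classify_assay_results, confirmed_target_count
from targetfish.datasets import dhc_panel_inhibition

calls = classify_assay_results(dhc_panel_inhibition())
print(confirmed_target_count(calls))   # -> 4
print(sorted({c.target_id for c in calls if c.call == "active"}))
# -> ['AKR1C3', 'ALOX5', 'HSD17B3', 'PTGS1']
```

Four of the six candidate targets are experimentally confirmed — 5-LO
(ALOX5) and COX-1 (PTGS1) from the arachidonic-acid cascade, and 17β-HSD3
(HSD17B3) and AKR1C3 from steroid metabolism.

The same stages are available from the shell:

```bash
targetfish run --outdir run --seed 42
targetfish classify-assays --config assay_config.yaml
```

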