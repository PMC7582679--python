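# Methods

This note documents the models, parameter defaults, numerical choices and
limitations of `targetfish`. It describes what the code computes; every
number quoted here is produced by the test suite or `scripts/acceptance.py`.

## Compound standardization and fingerprints

Input structures are reduced to a canonical parent: the largest covalently
bonded fragment is kept (ties broken by heavy-atom count, then molecular
weight, then lexicographic canonical SMILES), charges are neutralized where
chemically possible, and the canonical SMILES is recomputed. Entries that
fail to parse go to a rejects report rather than being silently dropped.

Compounds with unspecified stereocenters are expanded to all concrete
stereoisomers — both tetrahedral centers and stereogenic double bonds, under
one cap of 6 unspecified centers (≤ 64 isomers; records above the cap pass
through unexpanded and are flagged). Natural-product libraries are often
curated without absolute configurations, and the downstream similarity
methods are stereo-aware, so expansion is the default. Meso-degenerate
assignments are deduplicated by canonical SMILES. Every expanded record
keeps a `parent_id` so that known bioactivity and known-space subtraction
can be attributed at the compound level.

Two fingerprints describe each molecule: a circular substructure
fingerprint of radius 2 and a linear-path fingerprint of maximum path
length 7, both 2048 bits (the community-standard ECFP4/FP2 operating
points; lengths configurable). Tautomer canonicalization is off by default
because it silently changes fingerprints; enabling it must be an explicit
choice.

## Similarity-ensemble scoring

A target is a set of ligand fingerprints. The raw ensemble score of a query
set against a target set is the sum of all pairwise Tanimoto coefficients
at or above a threshold (default 0.57 on circular fingerprints, the
canonical operating point of the approach). The raw score is accumulated
sequentially in row-major pair order, which makes it bit-identical to a
plain double loop — the invariant the oracle tests assert exactly.

Because raw scores grow with set sizes, they are standardized against a
background fitted on random ensembles drawn from a decoy pool: for each
requested size pair (n, m), disjoint random sets are raw-scored (default
100 samples per size pair), the empirical means are fitted linearly in the
product n·m, and the empirical standard deviations as a power law a·(n·m)^b
on a log-log scale. Size cells whose empirical sd is zero (no
above-threshold pair ever sampled at tiny n·m) carry no scale information
and are excluded from the sd fit; the fitted power law is positive
everywhere, so z-scores are always defined. A fit with fewer than two
positive-sd cells is refused as degenerate.

z-scores convert to expectation values through the upper tail of the
standard Gumbel law matched to zero mean and unit variance,
p(z) = 1 − exp(−exp(−(z·π/√6 + γ))), multiplied by the number of reference
targets screened (the BLAST-style database-size correction; the comparison
count is a deliberate, recorded choice since ensemble methods differ here)
and clamped to [0, N]. The per-channel boolean cutoff defaults to
E ≤ 1e−5; public servers do not publish their inclusion thresholds, so this
is configuration, not an imitation of any specific server.

Calibration is checked, not assumed: on fresh random ensembles the z-scores
must have sample mean within ±0.15 and sample sd within (0.8, 1.2) at
n = 1000 — the acceptance script recomputes both numbers at every run.

The second similarity-ensemble channel (the SuperPred role) is the same
engine with its own reference sets and cutoff; there is deliberately no
separate scorer.

## Hybrid 2D/3D channel

The 3D descriptor is an electroshape variant fixed precisely so vectors are
reproducible: heavy atoms of one energy-minimized conformer (ETKDG
embedding, MMFF/UFF refinement, deterministic under the seed) are lifted to
4D by appending `charge_scale · q` with iterative Gasteiger partial charges
q and `charge_scale = 25` distance units per elementary charge. Five
reference points are chosen deterministically — the centroid, the atom
farthest from it, the atom farthest from that atom, and the centroid
displaced by ±`charge_scale` along the charge axis — and for each the first
three moments of the atom-distance distribution are recorded (mean,
standard deviation, signed cube root of the third central moment): 15
numbers, invariant under rigid rotation and translation of the conformer
(verified to 1e−8 in the tests, with a closed-form check on a two-point
geometry). Vectors are compared by Manhattan distance, mapped to the
bounded similarity s3D = 1/(1 + mean absolute difference) — a monotone
transform is required for the logistic stage, and this one fixes
s3D ∈ (0, 1].

Per target, s2D is the maximum path-fingerprint Tanimoto and s3D the
maximum electroshape similarity over the target's ligands
(nearest-neighbour logic; the mean is available by configuration). The
fusion model P = σ(β₀ + β₁·s2D + β₂·s3D) is fitted by Newton/IRLS maximum
likelihood; on complete separation the fit automatically falls back to a
ridge penalty of 1e−4. The fitter is implemented in-package because the
contract requires bit-for-bit determinism under fixed seed and input order
plus that exact fallback; a statsmodels MLE fit serves as the independent
oracle in the tests (agreement to 2 decimals per coefficient). A query
whose conformer embedding fails is excluded from the 3D channel only and
scored by a 2D-only fallback. One conformer per molecule is the default;
multi-conformer averaging is an extension, not a claim about any reference
implementation.

The shipped default model is trained on synthetic same-scaffold/random
pairs — no public training corpus exists for this channel — and is
labelled as synthetic wherever it is stored.

## External matrices and the anchor rule

External channels arrive as wide or long CSV matrices; blank or "nan" cells
mean *no prediction* and create no entry. Score semantics are explicit
(`lower_better` for E-values, `higher_better` for probabilities and
pharmacophore fit scores, `boolean`). Binarization keeps entries meeting
the cutoff, retains the numeric scores for rank-based evaluation, is
idempotent and never creates entries. The pharmacophore channel binarizes
at any positive hit by default — no public fit-score cutoff separates a
"hit" from a near miss, so any-hit is the recorded assumption. Target
labels are harmonized case-insensitively through an alias table that must
cover every label (unmapped labels are a hard error listing all
offenders); entries collapsing onto one canonical target merge by best
score. Exactly one matrix per consensus run carries the anchor flag.

## Bioactivity mining

The known space is built by resolving each compound's canonical SMILES to a
database identifier, collecting assay records flagged *active*, dropping
assays that do not map to exactly one protein (the single-protein rule
removes cell-based and panel assays), annotating genes with protein entry
names and human pathway memberships, and aggregating to (compound, target)
interactions whose integer weight counts the distinct supporting assay
records. Resolution failures are reported, never fatal; only a library
with zero resolved compounds aborts. Activity found for a stereoisomer is
also attributed to its parent compound, because subtraction from the
predicted space happens at the compound level. The network exports as a
SIF file (relation word fixed to `binds`) plus an edge-attribute CSV, and
the export round-trips exactly.

Two backends implement the lookup contract: a fixture backend over four
local CSV tables (all tests run on it) and a live REST client on the
standard library's HTTP machinery (5 requests/s, 3 retries with exponential
backoff, memoized per session) for integration use only.

## Consensus, criteria, enrichment, activity calls

CS counts the asserting methods, anchor included. Records without an
anchor hit keep their CS but are ineligible rather than deleted, so
near-misses remain visible in diagnostics. Known-space subtraction is a
set difference on (compound, target) pairs — including the parent
compound's pairs — and is idempotent.

Criterion II ranks targets per CS level by the number of library compounds
with an eligible record at or above that level; ties share the lower rank
number and are listed lexicographically. Frequencies are monotonically
non-increasing in the CS level by construction. Criterion III reports, per
candidate target, the other predicted or known targets sharing at least
one pathway name, plus a novelty flag (no known interaction for any panel
compound). Criterion IV is data, not computation: a target → availability
table. The final `selected` flag is availability AND novelty; the
remaining criteria are reported as evidence for human judgment.

Enrichment is a recovery test and therefore skips known-space subtraction:
the prediction universe is every pair asserted by at least one method, a
ranking's enrichment factor is (fraction of recoverable known pairs in its
top k) / (k / universe size) — the fold improvement over a uniformly random
ranking. Single channels rank their own entries by score; the consensus
ranks by (CS, best within-method rank goodness) descending, ties
lexicographic. The default slice is k = twice the known-pair count, which
covers the whole top consensus stratum and keeps the estimate from being
dominated by tie-break noise inside one CS level.

Activity calls implement the stated rule literally: active iff
mean ≥ 30%, mean > 0 and 100·sd/|mean| ≤ 20; negative means and noisy
replicates are ambiguous, hence inactive. On the bundled ten-compound ×
six-target inhibition panel this rule confirms exactly four distinct
targets (ALOX5, PTGS1, HSD17B3, AKR1C3). Two individual panel rows are
known to sit on the wrong side of the rule relative to their narrative
descriptions elsewhere (48.1 ± 12.0 has a relative sd of 24.9%; 7.7 ± 6.0
is below the 30% floor); the rule as stated is applied, and the
confirmed-target count is unaffected.

## The synthetic fixture

The generator is a pure function of its `FixtureSpec`: identical specs
give byte-identical files. Its defaults define the study conditions of
every end-to-end test:

- **60 library compounds** decorated on a 1,3-diarylpropan-1-one
  (dihydrochalcone-like) core with OH, OMe and a pyranose-like O-glycoside
  — the substitution chemistry of the natural compound class, at desk
  scale.
- **50 targets, 8 ligands each**: 5 *planted* true targets whose ligand
  sets share the library scaffold; 10 *confuser* targets whose ligand sets
  share ligand chemotypes with the library (half their ligands are library
  molecules) without being true targets — the characteristic failure mode
  of similarity-only methods, which assert them with full confidence; and
  35 decoy targets drawn from 15 unrelated scaffold families.
- **Decoy pool of 300 molecules**, clustered into the same scaffold
  families. Real screening databases are clustered by chemical series, and
  the clustering is what makes above-threshold Tanimoto pairs occur at
  realistic rates in the background fit.
- **Truth** is every (library compound, planted target) pair; a
  `known_fraction` of 0.3 is exposed as active single-protein assay records
  (1–4 records per pair, giving the weights), alongside distractor records
  that exercise the mining filters (multi-gene assays, inactive flags).
- **Simulated prediction channels** (one anchor + two servers) emit truth
  pairs with probability 0.85 and non-truth pairs with probability 0.15,
  with independent noise per channel. Wrongly asserted pairs draw scores
  reaching nearly the top of the truth score range: single channels are
  realistically fallible — none of the established tools performs well
  alone on natural-product-like input — and it is exactly this fallibility
  that the consensus corrects.

Under these conditions the full pipeline recovers 100% of unexposed
planted truths in the top 10 targets at CS ≥ 2 (the acceptance bound is
≥ 80%), and the consensus enrichment factor exceeds every single channel's
by a wide margin (typically ≈ 5 versus ≤ 3).

What the fixture does **not** emulate: real assay noise and activity-value
heterogeneity, cross-species target mapping, tautomer/protomer ambiguity,
and the actual chemical diversity of public bioactivity databases. Passing
these tests therefore demonstrates the correctness and calibration of the
machinery, not the real-world hit rate of any prediction server.

## Determinism and orchestration

Every stochastic step takes an explicit seed; two runs with identical
configuration produce byte-identical primary outputs (manifests record
content hashes; logs and the echoed config are excluded from the
comparison). Stage outputs are written atomically (temp file + rename),
and a stage whose inputs are missing fails naming the stage that produces
them. Exit codes: 0 success, 2 configuration error, 3 input error, 4
computation error.

## Problem sizes

Default problem sizes (60 compounds, 50 targets, 8 ligands per target,
300-decoy background, 100–200 background samples per size cell, 1000
calibration draws) were chosen as the smallest scale at which every
statistical property under test is comfortably resolved; the full pipeline
runs in a few seconds on one CPU, and the complete acceptance computation
in under a minute.

## Known limitations

- The similarity-ensemble background assumes the decoy pool is
  representative of the reference sets' chemistry; a pool with no
  above-threshold pairs at any sampled size is rejected rather than
  silently producing meaningless z-scores.
- The hybrid channel's default coefficients come from synthetic training
  data and should be retrained on real labeled pairs for production use.
- The live REST backend is a minimal integration client; bulk mirroring of
  public databases is explicitly out of scope.
- Criterion II double ranks reported for specific historical server outputs
  are not recomputable without those outputs; the implementation reproduces
  the ranking mechanics.
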