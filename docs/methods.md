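# Methods

This note documents the models and procedures implemented in `guideforest`,
the parameters that matter, the synthetic data the tests run on, and the
design choices made where the design was genuinely open.

## Guide encoding

A guide is the 20-nt protospacer on the target strand, positions numbered
1–20 with position 20 PAM-proximal (immediately 5' of the NGG).  Feature
blocks, in their declared order:

* **raw** (5 features): GC fraction in [0, 1]; Watson–Crick melting
  temperature `Tm(°C) = 64.9 + 41·(nG + nC − 16.4)/(nA + nT + nG + nC)`
  (an affine function of GC count at fixed length — see *pruning* below);
  minimum free energy (kcal/mol) of the spacer folded as RNA; distance (in
  bases) from position 20 to the nearest downstream NGG; location relative
  to the target gene.  Gene location is stored as one ordinal column
  (TSS = 0, Q1..Q4 = 1..4, TTS = 5) so that the raw block is literally five
  columns; tree models split ordinals without assuming linearity, and a
  six-indicator one-hot expansion is available (`expand_gene_location=True`)
  for models that need it.  Missing genome context raises a feature-level
  error — never a silent zero.
* **onehot** (384 + counts): 4 bits × 20 positions and 16 bits × 19 adjacent
  ordered pairs; exactly one bit per group, 39 bits set per guide.  The
  position-independent block adds 4 base counts (sum 20), 16 ordered
  dinucleotide counts (sum 19) and, when PAMs are annotated, 4 indicator
  columns for the PAM's N base.
* **quantum**: sliding windows of k = 1..4 stacked base pairs.  Each window
  (k, start p ∈ 1..21−k) is looked up, per duplex class (DNA:DNA target
  duplex for melting, DNA:RNA hybrid for guide binding) and per property
  (H–L gap, hydrogen-bond energy, stacking energy, total energy, electron
  count), in the property table; Σₖ (21−k) = 74 columns per property per
  class.  The table must be complete over the k-mers encountered; a gap is
  a hard lookup error naming the missing fragment.

**Minimum free energy** is a pluggable provider.  The default shells out to
`RNAfold`; when no engine is available the provider reports an explicit
"unavailable" state and the column is omitted with a warning.  No built-in
approximation is passed off as MFE.

**Normalization.** The response (empirical cutting efficiency) is min–max
scaled to [0, 1].  The map is affine, so every shape property of the
distribution — in particular its skew, which differs between organisms — is
preserved exactly.

**Correlation pruning.** After concatenation, any feature pair with
|Pearson r| > 0.9 loses its later member: columns are scanned in block order
(raw, onehot, quantum, species) and a column is kept only if it clears every
previously kept column.  The scan is deterministic and idempotent; constant
columns are defined to correlate with nothing.  Correlations are clipped to
[−1, 1] so a threshold of 1.0 disables pruning exactly.  Note that Tm is
affinely related to GC content for fixed-length guides, so with default
settings the pruner keeps `gc` and drops `tm` — the raw *block* still has
five features; pruning is a property of the assembled matrix.

**Species.** With two or more species tags among the guides, binary
indicator columns (one per species beyond the first, alphabetically) are
appended with provenance tag `species`.

## Iterative Random Forest

The forest is a bagged ensemble of CART trees grown by variance reduction,
with the method's defining twist: at **every node**, the `⌈√p⌉` candidate
features are drawn *without replacement with probability proportional to a
weight vector*.  Iteration 1 uses uniform weights (a plain random forest);
iteration t > 1 uses iteration t−1's normalized impurity-decrease (MDI)
importances, floored at `weight_floor` (default 1e-6) so no feature is
permanently culled mid-run.  This implements the boosting/culling loop that
amplifies repeatedly informative features.

Implementation notes:

* The grower is written here (numba-jitted) because per-node weighted
  candidate sampling is not expressible through standard forest libraries;
  sklearn supplies only metrics (R², ROC AUC) and serves as an independent
  oracle in tests (its uniform forest must agree with ours on which planted
  features rank top).
* Weighted sampling without replacement uses Efraimidis–Spirakis keys
  (`log(u)/w` ordering); a zero weight with zero floor means the feature is
  never drawn, so weights (1, 0, …, 0) route every split through feature 1.
* For a 0/1 response, within-node variance equals p(1−p) — half the Gini
  impurity — so the same grower serves binary classification; leaves predict
  the class-1 probability and evaluation reports ROC AUC.
* Defaults mirror the method's standard run: 10 iterations × 1000 trees,
  5-fold cross-validation inside an 80/20 train/test split.  The 80/20 split
  is made first; CV partitions the 80% (refit with final-iteration weights),
  and held-out metrics use the untouched 20%.  `min_samples_leaf` defaults
  to 5 and `max_depth` to 64 (a bound on path length, effectively unpruned).
* Everything is deterministic given `(matrix, config, seed)`: per-iteration
  forest seeds and per-tree seeds derive from `numpy.random.SeedSequence`.

**Explainability metrics.** Normalized importances sum to 1.  A feature's
*effect score* has direction = sign of the Pearson correlation between the
feature column and the response (0 for constant columns, with a warning) and
magnitude = normalized importance; the signed product is also reported as a
single summary value.
*Samples affected* is, per feature, the mean over trees of the fraction of
training rows whose root-to-leaf path crosses at least one split on that
feature (features repeated along a path count once).

**Tail labels.** For classification-style validation, responses are labelled
by order statistics: the `n_tail` lowest → class 0, `n_tail` highest →
class 1, middle excluded; ties break by stable input order, and an all-equal
response vector is rejected (tails undefined).

## Random Intersection Trees

Decision paths are reduced to feature sets (order ignored, duplicates
collapsed), tagged with the leaf's in-bag row count and, in classification
mode, the leaf's predicted class; RIT runs separately per class stratum.

Each intersection tree starts from the full candidate feature set and
narrows it: every node draws `n_children` **distinct** path sets (uniformly,
or leaf-size-weighted on request) and intersects them into its current set,
then spawns `n_children` children that narrow further, to `depth` levels.
Non-empty depth-level sets survive.  Drawing distinct paths within a node
makes degenerate cases exact: two disjoint paths can never produce a
survivor, and identical paths always survive unchanged.  "Co-occurrence
along a path" is set membership, not adjacency — strict adjacency is not
well defined once duplicate splits collapse.

Metrics per candidate set S: observed prevalence = fraction of paths
containing S; expected prevalence = ∏ of members' marginal path
prevalences; adjusted RIT = observed − expected (0 in expectation for
independently occurring features — verified to |·| < 0.02 at q = 0.5 over
10 000 paths); set importance = observed prevalence × mean normalized
importance of members (an explicit artifact definition); samples captured =
leaf-count-weighted fraction of training rows on paths containing S.

## Duplex k-mer geometry

K-mers are enumerated as strand-1 sequences over {A, C, G, T} per duplex
class with Watson–Crick complements implied (T↔A, G↔C; A→U on the RNA
strand of a hybrid): 4 pairs, 16 dimers, 64 trimers, 256 tetramers per
class.  Identifiers are `<class>|<strand-1 5'→3'>`, lexicographically
ordered.

Base-pair templates are **idealized flat nucleobases** (regular-polygon
rings with standard-table bond lengths: 1.39 Å aromatic, 1.23 Å C=O,
1.34 Å C–N), not crystallographic coordinates — the builder's contract is
geometric and no quantum calculation is run here.  A canonical frame has
its centroid at the origin, the base plane in the xy-plane, the pyrimidine
C2→O2 carbonyl along +x (the final in-plane rotation), and the pyrimidine
N1 at y ≥ 0 (resolving the remaining two-fold flip).  `canonicalize` is
idempotent to 1e-6 Å and recovers the canonical frame from any proper
rotation + translation.

A k-mer stacks canonical frames with pair i rotated (i−1)·twist about +z
(right-handed) and translated (i−1)·rise along +z; defaults rise = 3.5 Å,
twist = 36°, so a tetramer spans 10.5 Å — inside the 14 Å (4-bp)
interaction cut-off.  Structures serialize as XYZ and fixed-column PDB
(chain A = strand 1, chain B = strand 2, one residue per base per pair);
the PDB writer groups atoms by strand, so round-trips compare coordinates
as point sets.

## Quantum property tables

Records are keyed by (k-mer strand-1 sequence, duplex class, method tag)
with columns total_energy, homo, lumo, hl_gap, hbond_energy,
stacking_energy, electron_count.  Invariants: `hl_gap = lumo − homo` to
1e-8 when all three are present, `hl_gap ≥ 0`, electron count a positive
integer; validation reports *every* violating record.  Units are whatever
the table header declares (`# unit col=...` lines); the gap check assumes
homo/lumo/gap share a unit and nothing is converted implicitly.  Interaction
energies use the supermolecular convention at fixed geometry:
`E_int = E(whole) − Σ E(parts)` — the minimal standard definition, since the
properties are named but no formula is fixed upstream.

`synth_table` produces a deterministic, complete synthetic stand-in:
positive gaps (0.05–0.25 hartree with homo ≈ −0.3), negative-leaning
hydrogen-bond energies that strengthen with GC content, stacking energies
scaling with the number of steps, electron counts growing with k.  It is a
labelled synthetic fixture for pipeline testing, not a physical prediction.

## Screen scoring

Per design and run, abundance = perfect reads / merged pairs (zero perfect
reads is a valid absent design; zero merged pairs is a data error).  The
corrected host abundance subtracts wash-control carry-over:
`host_avg − wash_host_abundance × mass_ratio × donor_abundance`, mass ratio
defaulting to 1000 (1 µg DNA : 1 ng wash plasmid), floored at 0 with a
warning since a physical abundance cannot be negative (and log₂ of a
negative is undefined).  The "wash-control abundance" factor is read as the
wash sequence's host abundance itself (already a ratio by construction).
`delta = corrected / donor average`; `log2delta = log₂ delta`.  The p-value
is a two-tailed unequal-variance (Welch) t-test comparing the host vs donor
replicate abundance vectors — the two-sample reading of "heteroscedastic
t-test"; paired alternatives are not offered.  Filters: designs with
average donor reads < 10 **or** p ≥ 0.05 (boundary inclusive) go to the
graveyard and are excluded downstream; zero donor abundance is a reasoned
graveyard entry, not an exception.

## Synthetic data

The guide generator draws uniform (optionally GC-biased) 20-mers and builds
efficiency as Σ coefficient × feature + Σ interaction products + N(0,
noise_sd), followed by a monotone power transform (`skew`) so that
shape-preservation under min–max normalization is testable.  Planted feature
names must be producible by the encoder (raw `gc`/`tm`, one-hot `G@20`,
counts `count_GG`, …) — anything else is a spec error.  Every dataset comes
with a ground-truth ledger of the planted coefficients, so tests never
re-derive truth from the data.  The numeric benchmark
(`generate_regression`) plants linear (and optional product) signal among
standard-normal noise columns; the recovery conditions used throughout are
n = 2000 rows, 200 noise columns, coefficients (3, 2), noise σ = 0.5.

The counts generator emulates a pooled depletion screen: donor abundance
≈ 1/n_designs, host abundance scaled by each design's true delta, per-run
lognormal dispersion (σ = 0.05) and binomial read sampling at an expected
depth of 10 000 perfect reads per design per run, 3 donor + 2 host runs,
plus a spiked wash-control design at 1e-7 abundance.

What the synthetic data does *not* emulate: real position-specific sequence
biases, chromatin or expression context, PCR/jackpot artefacts in counts,
or the empirical efficiency distributions of any particular organism beyond
location/scale/skew.  Passing tests therefore demonstrate that the
machinery recovers known structure under its stated assumptions — not that
any particular biological conclusion transfers to a real screen.

## Benchmark problem sizes

The recovery benchmark fits 3 weighting iterations × 50 trees per seed over
20 seeds (n = 2000, 202 features); the package's full-scale default
(10 × 1000 trees) is the same code path at a larger setting.  The
acceptance script (`scripts/acceptance.py --seed N --out f.json`)
recomputes all reported quantities from scratch in about a minute on one
CPU.

## Known limitations

* The forest grower scans split candidates by per-node sorting; it is fast
  (numba) but not as cache-optimized as sklearn's; very large matrices
  (thousands of columns × 10⁵ rows at 10 × 1000 trees) are CPU-hours, not
  minutes.
* Quantum property values are synthetic unless a real table is supplied;
  the geometry builder emits initial coordinates for external engines and
  performs no optimization, solvent model, or energy evaluation.
* RIT survivor sets depend on the drawing distribution over paths; uniform
  is the default, leaf-size weighting optional, and no bootstrap stability
  score across forests is computed.
* Multi-class (beyond binary) classification is out of scope; so is
  off-target scoring, genome-wide guide discovery, and FASTQ processing
  (screen counts enter as tables).
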