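# Methods

## The model

The predictor treats a protein's reconstructed evolutionary lineage as a
time series in physicochemical space and asks, per alignment column, where
that series is heading. Inputs are a rooted phylogenetic tree with uniquely
labelled internal nodes (ancestral-reconstruction output), aligned sequences
for every node on the root→target path, and the target's identifier. The
chain of nodes from the root to the target leaf — the *main path* — provides,
at each alignment column, an ordered residue series (a *trajectory*) with a
branch-length coordinate for every node.

Each trajectory is collapsed into *groups*: maximal runs of identical
consecutive residues. A residue conserved across several successive ancestors
is a single evolutionary state; only boundaries between groups (*transitions*)
are substitutions. Sites with fewer than three transitions are excluded
(boundary inclusive: exactly three qualifies), as are sites where the target
holds a gap.

For each of nine descriptor scales (AAindex accessions FASG760101,
FASG760102, GOLD730102, WOLR790101, BHAR880101, BULH740101, FAUJ880108,
ZIMJ680103, ZIMJ680104 — size, melting point, hydrophobicity, flexibility,
transfer energy, electrical effect, polarity, isoelectric point) the
trajectory is mapped to one (x, y) point per group: x is the cumulative
root distance of the group's first node, y the group residue's scale value in
native units. A weighted least-squares line is fitted and extrapolated one
*step* beyond the last group, where the step is the mean branch length
between consecutive main-path nodes. The extrapolated descriptor value is
inverted to a residue by nearest scale value (alphabetical tie-break). The
same fitted slope defines the trend direction used by the scores.

### Scores

- **Sequentiality** (0–100): 100 × (transitions whose descriptor change has
  the slope's sign) / (total transitions). Ties (zero descriptor change, as
  between isoleucine and leucine on molecular weight) never count against the
  trend. With a zero slope only ties count as consistent.
- **Fluctuation**: distinct residues ÷ number of groups, in (0, 1].
- **Break trend**: true when the most recent transition's descriptor change
  opposes the slope. A `penultimate` mode inspecting the preceding transition
  instead is available behind a flag; the grammar of the underlying rule is
  ambiguous and we default to the most recent transition because that is the
  change a successor would extend or revert.

Predictions rank by: no break first, then sequentiality descending,
fluctuation descending, then (site, accession, residue) for a deterministic
total order.

### Aggregation and bundling

Identical (site, wild type, residue, scale) predictions from different trees
are merged with arithmetically averaged scores; the boolean break flag
becomes the fraction of supporting trees flagging a break (0 or 1 in the
single-tree case). Sites are expressed in 1-based coordinates on the ungapped
target sequence so they align across trees; a wild-type mismatch between
trees at one site aborts the merge as a coordinate bug.

Merged predictions are bundled into three tiers: **MAP** when ≥ 2 scales
agree on the identical substitution (two supports suffice), **SAP** when
scales agree on the site but not the residue, **Prediction** for singletons.
A mutation-agreeing substitution at a contested site stays MAP; its
competitors remain SAPs. Self-predictions (successor equals the wild type)
are dropped from mutation output and logged — with a short extrapolation
step they are common, and they carry no engineering action.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_transitions` | 3 | transitions | inclusive eligibility threshold |
| `weighting` | `linear-recency` | — | sample weight w = 1 + d/dmax, so the most recent group weighs 2× the root; `uniform` available |
| `normalize` | on | — | x divided by transition count before fitting, making slope magnitudes comparable across sites |
| `break_mode` | `last` | — | which transition the break flag inspects |
| identity window | 0.30–0.90 | fraction | homolog filter, boundaries inclusive |
| length window | 0.80–1.20 | fraction of target length | homolog filter |
| sequences per file | 150 | sequences | one phylogenetic tree per file |

Two genuinely open readings were fixed as package design choices: the
distance weighting is a monotone recency weighting (value-on-distance
regression is the only formulation under which "predict the next step along
a regression curve" is well defined), and transition-count normalisation is
applied to the x axis (slope comparability), with both exposed as options
and echoed into output metadata.

## Synthetic histories

`ssp.simulate.make_history` generates a root→target backbone of labelled
ancestors (each with a decoy side leaf so the tree is properly bifurcating),
with branch lengths uniform on 0.05–0.15 substitutions/site — the
inter-ancestor distance range typical of the ~10-node paths the predictor
consumes — and a default path of 10 nodes. Planted columns follow a chosen
scale monotonically (strictly, when noiseless) with a prescribed transition
count; Gaussian noise in scale units perturbs the ideal trend values before
residue selection. Background columns are conserved (default) or i.i.d.
random.

The generator emulates the *shape* of ancestral-reconstruction output, not
the substitution process: no rate matrix, no site-rate heterogeneity, no
alignment error, no reconstruction uncertainty. Planted-trend recovery
therefore demonstrates that the trend machinery detects what it is defined
to detect; it says nothing about how often real lineages carry linear
physicochemical trends.

Synthetic enrichment tables emulate a site-saturation selection readout:
six antibiotics × four concentrations, background mutations centred on 0.8
(mildly deleterious on average, matching the intuition that random point
mutations reduce fitness), predicted sets boosted above 1, lognormal
multiplicative noise. With zero noise group means are exact, which the AAC
tests exploit; a realistic full table is dominated by the background set,
since predictions are a small fraction of the mutational space.

## Numerical notes

- Regression uses scikit-learn's `LinearRegression` with sample weights; the
  tests verify it against closed-form weighted normal equations at 1e-9
  relative tolerance, and noiseless planted slopes are recovered to 1e-9.
- Degenerate fits (all group positions identical, or a single group with a
  scale value) skip that (site, scale) pair rather than aborting the run.
- Residue groups without a scale value (`X`) are skipped with a warning.
- Pairwise identity uses a global Needleman–Wunsch alignment (BLOSUM62,
  gap open −10, extend −0.5) with the full alignment length as denominator;
  a `shorter`-sequence denominator is available. Sequence-file construction
  uses a seeded PRNG; all outputs embed the configuration hash, and equal
  hashes give byte-identical reports.

## Problem sizes in the test-suite and acceptance runs

Synthetic checks use 10-node paths, 3–50 columns, and 1–2 trees; noise-
robustness uses 200 seeded replicates at noise σ = 10 % of the scale range.
These sizes exercise every code path while keeping the whole suite a
few-second run; the pipeline itself is linear in columns × trees and runs
comfortably at the 150-sequence, many-tree scale of real inputs.

## Known limitations

- Trends are linear per scale; saturating or oscillating physicochemical
  histories are flagged only indirectly (low sequentiality, break flag).
- The method consumes one main path per tree; reconstruction uncertainty at
  internal nodes is not propagated (posterior probabilities are not used).
- Tree inference, rooting, alignment, and ancestral reconstruction are
  upstream inputs; their errors propagate silently into trajectories.
- Cross-tree aggregation assumes consistent target coordinates; re-aligned
  path extractions that shift columns must be reconciled upstream.
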