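# ssp — Successor Sequence Predictor

Protein engineers routinely ask which substitutions a protein could tolerate
— or benefit from — next. `ssp` answers by extrapolation rather than
retrospection: given a rooted phylogenetic tree whose internal nodes carry
reconstructed ancestral sequences, it reads each alignment column along the
root→target lineage as a trajectory in physicochemical space, fits the trend,
and proposes the residue one evolutionary step *beyond* the target. Ancestral
sequence reconstruction looks back; this package extrapolates forward.

## The method in brief

For the main path root → target with cumulative branch-length coordinates
x₀ < x₁ < … < xₙ, each alignment column yields residue groups (maximal runs
of identical residues; boundaries between groups are the substitutions).
For each of nine AAindex descriptor scales *f* (molecular weight, melting
point, residue volume, hydrophobicity, flexibility, transfer energy,
electrical effect, polarity, isoelectric point), a weighted least-squares
line is fitted through (x_g, f(residue_g)) with recency weights
w = 1 + x/x_max, and evaluated at x_last + s, where s is the mean inter-node
distance on the path. The nearest residue on the scale to the extrapolated
value is the predicted successor. Sites with fewer than three substitutions
are excluded.

Each prediction carries three diagnostics — *sequentiality* (0–100, how
consistently the descriptor moved with the trend), *fluctuation* (distinct
residues ÷ groups), and a *break-trend* flag (the latest substitution moved
against the trend) — and predictions are merged across trees, then bundled:
**MAP** when ≥ 2 scales agree on one substitution, **SAP** when scales agree
on the site but not the residue, **Prediction** for singletons.

## Worked example

Generate a synthetic history with two planted trends (ascending molecular
weight at column 5, descending hydrophobicity at column 13, 1-based) and run
the predictor:

```sh
ssp fixtures --seed 3 --n-sites 30 --plant 4:FASG760101:+1 --plant 12:WOLR790101:-1
ssp predict --tree ssp_fixtures/tree.nwk --fasta ssp_fixtures/nodes.fasta \
            --target target --out-dir out
```

which prints the top bundles:

```
Y5V    MAP  Flexibility;TransferEnergy
R13Q   SAP  TransferEnergy
Y5D    SAP  Hydrophobicity
Y5L    SAP  MeltingPoint
```

Both planted columns — and only those, since conserved background columns
are ineligible — surface as predictions. `Y5V MAP` means: at target position
5 (wild-type tyrosine), two independent descriptor scales (flexibility and
transfer energy) extrapolate to the same successor, valine; the single-scale
proposals at the same sites are site-agreeing (SAP) alternatives.
`out/bundled.tsv` adds the scores, e.g.

```
mutation  tier  supports                    n_supporting_indices  sequentiality  fluctuation  break_fraction
Y5V       MAP   Flexibility;TransferEnergy  2                     50.0           1.0          0.0
R13Q      SAP   TransferEnergy              1                     100.0          1.0          0.0
```

`R13Q` has sequentiality 100: every substitution in its trajectory moved the
transfer-energy value in the trend's direction. A mutational-enrichment
table can then score a prediction set: `ssp eval-aac ssp_fixtures/enrichment.tsv`
prints `AAC = 1` (the mean enrichment across all rows and conditions; ~1 is
wild-type-like, above 1 indicates enrichment).

Other subcommands: `ssp indices` (inspect/export the nine scales and their
correlation matrix), `ssp prep` (homolog filtering at 30–90 % identity and
80–120 % length, plus 150-sequence file construction from a cluster table),
`ssp bundle` (re-bundle a prediction dump), `ssp overlap` (predicted vs
experimental set counts).

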