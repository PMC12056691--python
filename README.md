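# coronacause

Actual-causality analysis of protein corona composition under small-molecule
plasma treatments.

## The problem

When nanoparticles contact plasma they acquire a protein corona whose
composition determines their biological identity. Spiking small molecules
(lipids, metabolites, vitamins, nutrient mixtures) into plasma before
incubation reshapes the corona — desirably by *depleting* highly abundant
plasma proteins (albumin and friends) and *enriching* low-abundance ones,
which deepens plasma proteome coverage. Correlation analysis alone cannot say
*which* treatment actually caused such a change: a confounder can make two
events co-occur without either causing the other (in summer, both ice-cream
sales and shark attacks rise).

`coronacause` answers the token-level question with Halpern–Pearl **actual
causality**. Given a long-format table of per-protein log2 fold changes
(`Protein_ID`, `Small_Molecule`, `Concentration_of_Molecule`, `log2FC`), a
candidate assignment X ← x (e.g. `Small_Molecule ← PtdChos`) is an actual
cause of the effect φ when

- **AC1** — X ← x and φ co-occur in some observed record;
- **PC2** (probability raising, the probabilistic stand-in for the
  counterfactual clause AC2) — P(φ | actual world, X = x) strictly exceeds
  P(φ | counterfactual worlds): records identical in every other variable
  (same protein, same concentration) but with X ≠ x;
- **AC3** — minimality, automatic for the singleton causes searched here.

The effect φ is a dual-threshold rule on log2FC: for highly abundant
proteins (packaged 25-accession list) φ fires at log2FC ≤ θ_abundant
(depletion); for the rest at log2FC > θ_rest (enrichment). Identified causes
are ranked by the conditional probability P(φ | X = x) =
count(X = x ∧ φ)/count(X = x). Because the verdict depends on where the
thresholds sit, a 2-D **threshold sweep** re-runs the search over a grid of
(θ_abundant, θ_rest) pairs and reports, per rank, the percentage of cells
each molecule occupies — the robustness of the attribution.

All probabilities are exact integer ratios (`fractions.Fraction`); no
floating-point comparison decides a verdict. Two PC2 aggregations are
provided: `pooled` (all matched counterfactual records in one pool) and
`standardized` (per-context probabilities weighted by the actual world's
context frequencies; default, immune to Simpson-type confounding — it
rejects the ice-cream "cause" that the pooled mode is fooled by).

## Worked example

Generate a synthetic corona table with a planted cause (PtdChos shifts the 5
abundant proteins by −1 log2 unit and the 15 others by +1; nine null
treatments carry only nuisance shifts), then search for causes at the
default thresholds θ = 0.1/0.1:

```
$ coronacause simulate --seed 7 --out synth.csv
$ coronacause find-causes --input synth.csv \
      --abundant-list synth.csv.abundant.txt --out causes.tsv
rank 1: Small_Molecule <- PtdChos (P(effect|cause) = 1.0000)
rank 2: Small_Molecule <- Triglyceride (P(effect|cause) = 0.6000)
```

`causes.tsv` holds one row per candidate assignment:

```
rank  variable        value         p_actual  p_counterfactual  conditional_probability  n_support  verdict
1     Small_Molecule  PtdChos       1         0.381481481481    1                        60         cause
2     Small_Molecule  Triglyceride  0.6       0.425925925926    0.6                      60         cause
NA    Small_Molecule  Diglycerol    0.35      0.453703703704    0.35                     60         non-cause
```

PtdChos raises the effect probability from 0.38 (counterfactual worlds) to
1.0 (all 60 of its records show the effect) — an actual cause, ranked first.
The threshold sweep shows the attribution is not an artifact of one
threshold choice:

```
$ coronacause reproduce --input synth.csv \
      --abundant-list synth.csv.abundant.txt --out-dir rep
Grid: 20 x 21 = 420 threshold cells, mode=standardized
PtdChos rank-1 frequency: 100.00% of cells
PtdChos top-3 membership: 100.00% of cells
```

On real study data (`coronacause reproduce --input <supplementary log2FC
table> --out-dir rep`, using the packaged abundant-protein list by default)
the same command prints the rank-frequency table over all 420 threshold
cells and the two headline percentages for the molecule of interest.

A `sweep` subcommand exposes the grid directly (per-rank TSV maps with the
literal token `None` for cause-free cells), and `simulate --config sim.yaml`
accepts generator overrides. The same functionality is importable:
`coronacause.find_causes`, `run_sweep`, `frequency_table`,
`generate`, `generate_confounded`.

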