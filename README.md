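# foldchron

Structural-phylogenomic chronologies of protein domain families from
proteome censuses.

Starting from a census of domain-family abundance counts across proteomes
labeled by supergroup (Archaea, Bacteria, Eukarya, viruses), the package

- encodes abundances into ordered multistate (Wagner) phylogenetic
  characters (24 states, log-scaled per proteome) and serializes them as
  NEXUS;
- infers maximum-parsimony trees of domains (Sankoff dynamic programming on
  the linear state graph, stepwise addition, NNI/SPR branch swapping,
  character bootstrap, retention index, g1 skewness);
- roots trees by Lundberg optimization with a maximum- or minimum-state
  hypothetical ancestor and derives a node-distance chronology
  (nd in [0, 1], 0 = oldest) with a configurable linear clock calibration
  to Gya;
- assigns Venn groups over {A, B, E, V}, delimits the six evolutionary
  phases from marker-group first appearances, and computes accumulation
  curves, phase count/ratio tables, specificity summaries and the
  group-by-phase presence grid;
- computes f-value (occupancy) distributions and rank-sum comparisons of
  cell-unique versus virus-shared features;
- builds NeighborNet circular split networks from Venn-incidence data with
  uncorrected-P distances, NNLS split weights and column-bootstrap supports;
- projects loop prototypes onto the domain chronology through
  prototype-to-family maps (e-value < 0.001, non-modular filter);
- generates synthetic censuses with known ground truth (birth order,
  staged Venn trajectories, nested lineage-like occupancy, abundance
  growth, reductive loss, horizontal transfer) for end-to-end validation.

## Tests

```
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: parsimony and
rooting oracle equivalence, NeighborNet consistency on tree metrics,
chronology recovery on the default synthetic fixture, worked examples over
the published per-phase counts, and behavioral reproductions of the
qualitative claims.

## CLI

The console script `foldchron` wraps each stage:

```
foldchron simulate --families 50 --seed 1 \
    --out-census census.tsv --out-labels labels.tsv --out-truth truth.json
foldchron run census.tsv labels.tsv --out-dir out/ --seed 1
foldchron encode census.tsv labels.tsv --out matrix.nex
foldchron search census.tsv labels.tsv --out tree.nwk --seed 1
foldchron root census.tsv labels.tsv tree.nwk --mode max --out rooted.nwk
foldchron chronology census.tsv labels.tsv tree.nwk --out chronology.tsv
foldchron venn census.tsv labels.tsv chronology.tsv --out features.tsv
foldchron fvalue census.tsv labels.tsv --out fvalues.tsv
foldchron network census.tsv labels.tsv --bootstrap 200 --out splits.nex
foldchron loops map.tsv chronology.tsv features.tsv --out prototypes.tsv
foldchron evaluate truth.json chronology.tsv
```

`foldchron run` executes the full pipeline (census -> coding -> MP search ->
Lundberg rooting -> chronology -> Venn timeline -> f-values -> split
network -> optional prototype projection) and writes a `manifest.json` with
seeds, stage statistics and artifact checksums. Census input is TSV (header
row of proteome ids, first column of family ids) plus a label TSV
(proteome id, code, subgroup).

## File formats

- census/labels: TSV as above
- characters: NEXUS DATA block, SYMBOLS="0123456789ABCDEFGHIJKLMN",
  ordered (Wagner) characters declared in an ASSUMPTIONS block
- trees: Newick with single-quoted labels (SCOP-style ids contain dots)
- split networks: NEXUS TAXA + SPLITS blocks (SplitsTree-compatible CYCLE,
  weights, optional CONFIDENCES)
- chronologies, phase tables, f-values, prototype maps: TSV
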