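# gemproject

Scaffold-based projection of genome-scale metabolic models (GSMMs), with
flux-balance validation against growth/no-growth experiment tables.

Building a GSMM for a newly sequenced organism from scratch takes years of
curation. When a phylogenetically related species already has a curated,
*functional* model (one that predicts growth from available nutrients), a
draft for the target species can instead be **projected**: every reaction of
the scaffold model whose gene requirements are conserved in the target genome
is carried over, with its Gene-Protein-Reaction association (GPR) rewritten
in terms of target genes. This package implements that workflow for users
building draft eukaryotic models — e.g. projecting a *Saccharomyces
cerevisiae* consensus model onto an oleaginous yeast — and the validation
loop that tells curators how good the draft is.

## What it does

- **`gemproject.model`** — compartmentalized metabolic network container with
  SBML round-trip I/O (Level 2 Version 4 with COBRA-style
  `GENE_ASSOCIATION` notes on write; that dialect plus fbc-v2 on read), and a
  reaction **census** partitioning reactions into transport/exchange/enzymatic
  with or without a gene association.
- **`gemproject.gpr`** — GPR boolean formulas: parsing, evaluation,
  normalization to *minimal gene sets* (the alternative complete gene
  combinations each sufficient for the reaction), and rewriting through a
  homolog map. Each rewrite is classified into the evolutionary cases
  **M1** (gene loss) … **M7** (family expansion in the target).
- **`gemproject.orthology`** — consensus voting over several ortholog/paralog
  maps: candidate target groups are formed per scaffold gene and each group
  scores one vote per supporting method; divergent predictions are settled by
  keeping the top-voted group(s).
- **`gemproject.projection`** — the projection itself: conserved reactions
  (≥1 complete rewritten gene set) are copied with new GPRs, spontaneous
  reactions/exchanges/compartments are carried over verbatim, species-specific
  reactions can be inserted (M2 gains), lost reactions are reported for
  manual review, and the biomass DNA-precursor coefficients are re-balanced
  for the target genome's GC content.
- **`gemproject.gapfill`** — dead-end metabolites, flux-variability-blocked
  reactions, unreachable biomass precursors, and ranked candidate fixes from
  EC-annotated target genes.
- **`gemproject.simulate`** — media as exchange bounds, knockout propagation
  through GPRs, FBA (maximize biomass flux subject to S·v = 0 and bounds,
  solved with HiGHS), growth binarization for simulations and OD curves.
- **`gemproject.validate`** — run an experiment table (medium, knocked-out
  genes, observed growth) through the simulator and score predictions as a
  confusion matrix with geometric-mean accuracy
  √(sensitivity × specificity).
- **`gemproject.fixtures`** — a deterministic generator of synthetic
  scaffolds, ortholog maps with planted M1–M7 events, and experiment tables
  with planted false positives/negatives, used throughout the test suite.

## Worked example

```python
from gemproject import fixtures as fx
from gemproject.model import census
from gemproject.orthology import build_consensus
from gemproject.projection import project
from gemproject.validate import run_experiments, score

spec = fx.FixtureSpec(seed=1)                 # a toy study: 6 carbon pathways
scaffold = fx.make_scaffold(spec)             # functional scaffold model
maps, truth = fx.make_ortholog_maps(scaffold, spec)
target, report = project(scaffold, build_consensus(maps))
print(len(report.conserved), len(report.lost))

media = fx.make_media_config(spec)
experiments = fx.make_experiments(target, spec, media)  # 152 rows, 98 observed
cm = score(run_experiments(target, experiments, media))
print(cm.tp, cm.tn, cm.fp, cm.fn, round(cm.gmean_accuracy, 2))
```

prints

```
44 1
39 25 16 18 0.65
```

— 44 of the 45 GPR-bearing scaffold reactions are conserved (one planted
gene-loss reaction is reported lost), and validating the projected model
against the synthetic experiment table gives 39 true positives, 25 true
negatives, 16 false positives and 18 false negatives: 64 exact agreements of
98 scored experiments, geometric-mean accuracy 0.65. The false-negative list
is what a curator would take back to gene annotation; the false positives
point at over-permissive flux routes.

The same workflow is available from a shell:

```bash
gemproject fixture --seed 1 --out-dir study/
gemproject project study/scaffold.xml -m m0=study/orthologs_method0.tsv \
    -m m1=study/orthologs_method1.tsv -o draft.xml --report-prefix proj
gemproject census draft.xml
gemproject validate study/target.xml --experiments study/experiments.tsv \
    --media study/media.tsv
gemproject gaps draft.xml --media study/media.tsv --medium MED0
```

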