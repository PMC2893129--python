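# plantloc

Multi-label prediction of plant protein subcellular localization among twelve
sites (cell membrane, cell wall, chloroplast, cytoplasm, endoplasmic
reticulum, extracellular, Golgi apparatus, mitochondrion, nucleus, peroxisome,
plastid, vacuole).

A protein is represented in up to three descriptor modes:

* **GO** — binary vector over a GO-term catalogue, transferred from the
  protein's *homology set* (its significant database matches above an
  identity floor) via a pre-computed homology table and annotation index;
* **FunD** — binary vector over a conserved-domain catalogue, thresholded from
  pre-computed domain hits;
* **PsePSSM** — a fixed-length evolution descriptor built from a
  position-specific scoring matrix: row-standardized scores collapsed to a
  20-component mean profile plus lag-correlation blocks, dimension
  20·(1+λ).

Classification uses an **evidence-theoretic K-nearest-neighbor** rule: each
neighbor contributes a Dempster–Shafer mass `α·exp(−γ_q·d²)` on its class,
aggregated with Dempster's rule of combination; per-class rates γ can be
fitted by minimizing a leave-one-out squared error.  An **ensemble** over K
(and λ) grids routes GO-productive queries to the GO engine alone and all
others to a FunD ⊕ PsePSSM fusion; member votes are tallied into normalized
scores and every location scoring ≥ τ·max is reported, so single- and
multi-location proteins share one decision rule.

Evaluation follows **locative-protein accounting** (a protein in k locations
counts k times) with leave-one-out (jackknife) cross-validation, per-location
and overall success rates, and separate over-/under-prediction tallies.

Live BLAST/PSI-BLAST/RPS-BLAST searches are out of scope: homology, GO
annotation, and domain hits enter as plain TSV tables, and scoring matrices
as PSI-BLAST ASCII files.  A fully seeded synthetic generator
(`plantloc.synthetic`) emits complete benchmarks — sequences, tables,
matrices, labels — with controllable class separation and multi-location
fraction, so everything is testable offline.

## CLI

```sh
# generate a synthetic fixture tree
plantloc simulate --out data/ --locations 4 --per-location 20 \
    --separation 0.9 --multi-fraction 0.08 --seed 1

# build descriptors and fit the ensemble
plantloc train --data data/ --model model/

# predict location sets for FASTA queries (multi-location ";"-joined)
plantloc predict --model model/ --fasta data/sequences.fasta \
    --data data/ --out predictions.tsv

# jackknife evaluation with a per-location report
plantloc evaluate --data data/ --out eval/
```

A YAML file passed as `--config` overrides the corresponding flags.  Queries
shorter than 50 residues trigger a fragment warning but are still predicted;
queries without a scoring matrix fall back to GO/domain routing.

## Layout

```
src/plantloc/
  records.py       protein records, locative datasets, the 12-site frame
  descriptors/     GO / domain / PSSM descriptor construction + PSSM parser
  etknn.py         evidence-theoretic KNN, Dempster combination, γ fitting
  ensemble.py      routing, member grids, vote fusion, multi-label decision
  evaluation.py    locative accounting, scoring, jackknife
  synthetic.py     seeded benchmark generator
  features.py      descriptor pipeline over pre-computed tables
  formats.py       TSV / FASTA dialects
  model_io.py      plain-text model bundles
  cli.py           simulate | train | predict | evaluate
```
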