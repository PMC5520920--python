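# omicnet

Integrated multi-omic network phenotyping on a protein-interaction
background, plus splice-variant proteoform prediction. The package chains:

1. **synthetic data** (`omicnet.synth`) — interactomes with planted
   overlapping modules, correlated transcript/protein/phosphosite layers
   with group effects concentrated in chosen modules, and toy multi-exon
   gene models, so every downstream stage is testable offline;
2. **differential statistics** (`omicnet.diffexpr`) — row z-scoring,
   per-feature one-way ANOVA, hierarchical clustering of features with a
   random-substitution specificity score, signature overlap counting;
3. **seed networks** (`omicnet.netbuild`) — differential features become
   seeds; the seed network is the interactome subgraph induced on seeds and
   their immediate neighbors;
4. **overlapping modules** (`omicnet.modules`) — an influence-landscape
   community detection: each link injects influence proportional to the
   weighted-Jaccard similarity of its endpoints' neighborhoods, spread over
   a bounded number of degree-normalized steps with attenuation; module
   cores are landscape maxima, membership is diffused from the cores, and
   modules are ranked by summed membership (centrality) and coarsened into
   a hierarchy;
5. **exact statistics** (`omicnet.modstats`) — Fisher's exact test in
   exact rational arithmetic, Woolf confidence intervals with a
   Haldane–Anscombe zero-cell rule, upper-tail hypergeometric overlap
   probabilities, Benjamini–Hochberg correction, module connectivity
   enrichment, cross-dataset module comparison;
6. **module dynamics** (`omicnet.dynamics`) — persist / reposition / split
   / merge / dissolve / form classification of module transitions between
   two conditions under documented overlap thresholds, plus a per-node
   tri-layer (transcript / protein / phosphosite) state overlay;
7. **splice variants** (`omicnet.splice`) — exon-skip transcript
   construction, frame and premature-stop classification, translation with
   recomputation of junction-spanning and locally frame-shifted residues,
   in-silico PCR, Keil-rule tryptic digestion, and variant-specific
   junction-peptide selection.

## Command line

```sh
omicnet run --seed 1 --outdir out            # full synthetic pipeline
omicnet simulate --seed 1 --outdir sim       # inputs only
omicnet de --matrix sim/transcript.tsv --out de.tsv
omicnet network --interactome sim/interactome.tsv --de de.tsv --out-prefix net
omicnet modules --edges-tsv net_edges.tsv --out-prefix mod
omicnet stats --membership mod_membership.tsv --study-edges net_edges.tsv \
    --interactome sim/interactome.tsv --out enrichment.tsv
omicnet dynamics --membership-a a.tsv --membership-b b.tsv --out events.tsv
omicnet splice --gene-model sim/gene_model.gff3 --fasta sim/gene_model.fasta \
    --skip 5,7 --out-prefix var
```

`omicnet run` accepts a flat YAML config (`--config`); unknown keys are
rejected and every parameter lands in the provenance section of
`out/results.json`. Outputs are byte-identical across reruns at a fixed
seed.

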