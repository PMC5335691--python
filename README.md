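# mitokit

Comparative mitogenomics toolkit for decapod-style studies: GenBank
annotation quality control, signed circular gene-order rearrangement
analysis against the pancrustacean ground pattern (with phylogenetic
consistency checking), codon-usage bias statistics (codon counts under the
invertebrate mitochondrial code, RSCU, per-amino-acid chi-square among
groups, classical MDS), per-record composition summaries, and a synthetic
mitogenome generator so the whole pipeline is testable offline.

## Modules

| module | what it does |
| --- | --- |
| `mitokit.genbank_io` | parse/write GenBank flat files, normalize gene names onto a 38-token vocabulary, screen for annotation defects (missing/duplicated genes, inverted/absent/out-of-range coordinates, unknown names) |
| `mitokit.gene_order` | signed circular gene orders: extraction, canonicalization (cox1-anchored, mirror-normalized), breakpoint distances, greedy replayable rearrangement-event inference, pattern clustering, Fitch-parsimony consistency of patterns on a Newick tree |
| `mitokit.codon_usage` | codon counting (translation table 5), RSCU, pooled per-group chi-square per amino acid, Euclidean RSCU distances, Torgerson classical MDS |
| `mitokit.composition_stats` | AT content, gene counts by category, intergenic spacers (overlaps negative), control-region length |
| `mitokit.synthetic_data` | seeded generator of fully annotated mitogenomes with scripted rearrangements, planted per-group third-position AT bias, AT-rich non-coding regions, optional planted annotation defects, plus manifest and tree |
| `mitokit.cli` | `mitokit` command-line pipeline |

A bundled study manifest (45 accessions: 33 ingroup across Axiidea,
Gebiidea and Caridea plus 12 Dendrobranchiata outgroups) and matching
Newick topology are available via `mitokit.load_study_manifest()` /
`mitokit.load_study_tree()`.

## CLI

```sh
mitokit simulate --out fixture --seed 1            # 45 records + manifest + tree
mitokit qc --records fixture/records --out qc.tsv  # exit 1 if defects found
mitokit gene-order --records fixture/records \
    --manifest fixture/manifest.tsv --tree fixture/tree.nwk --out go_out
mitokit codon-usage --records fixture/records \
    --manifest fixture/manifest.tsv --out cu_out
mitokit summary --records fixture/records --out summary.tsv
```

Exit codes: 0 clean, 1 findings (QC defects), 2 usage/configuration error.
All outputs are UTF-8 TSV with header rows; identical inputs and seed give
byte-identical outputs.

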