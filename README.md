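# spagi

Signaling pathway inference from scored protein–protein interaction (PPI)
networks and gene expression profiles.

The package builds a *background* of receptor → kinase → transcription-factor
(TF) signaling paths from a confidence-scored PPI table, then ranks the
pathways implied by a query expression profile:

1. **`spagi.ppi_graph`** — load role lists (receptors / kinases / TFs),
   filter interactions by confidence (`combined_score >= 700` by default),
   optionally merge two species under a one-to-one ortholog map, and build a
   directed graph restricted to the permitted edge categories
   (R→R bridging, R→K, K↔K, K→TF) with edge weight `1000 − combined_score`.
2. **`spagi.path_enumeration`** — one minimum-weight *complete* path
   (3–7 nodes, ≤ 2 receptor layers, ≤ 5 kinase layers, one terminal TF) per
   (receptor, TF) pair via Dijkstra with deterministic lexicographic
   tie-breaking; paths made only of housekeeping genes are removed.
   `strict_layered=True` (CLI `--strict-layered`) searches role-layered
   states so the returned path is the cheapest *complete* one.
3. **`spagi.housekeeping`** — housekeeping genes from a multi-tissue panel:
   expressed (`log2 value >= 1.5`) in at least 75 % of samples.
4. **`spagi.activity_scoring`** — average replicates, keep paths whose
   members are all expressed, compute per-path active proportions `p_i`
   against a high-expression threshold (KDE peak of expressed genes by
   default), score each pathway `A_s = Σ p_i / n`, and rank.
5. **`spagi.permutation_fpr`** — false-positive rate by permuting gene
   labels against expression values and re-running the pipeline.
6. **`spagi.synthetic_data`** — seeded generators for role-labelled networks
   with planted signal routes, housekeeping panels and query profiles, used
   by the test-suite and for offline benchmarking.

## Command line

```bash
spagi simulate --spec spec.yaml --out-dir sim/            # synthetic dataset
spagi build-graph --ppi sim/ppi.tsv --receptors sim/receptors.txt \
    --kinases sim/kinases.txt --tfs sim/tfs.txt --out graph.json
spagi housekeeping --panel sim/panel.tsv --out hk.txt
spagi build-background --graph graph.json --housekeeping hk.txt \
    --out background.tsv
spagi score --background background.tsv --expression sim/expression.tsv \
    --out-prefix scored
spagi fpr --background background.tsv --expression sim/expression.tsv \
    --reps 10 --seed 1 --out fpr.json
```

Two-species inputs: `build-graph --ppi2 <file> --orthologs <tsv>` and
`housekeeping --panel2 <file> --orthologs <tsv>`.  A YAML `--config` file
supplies parameter defaults; explicit flags win.

File formats are plain text: 3-column PPI TSV (optional header
auto-detected), one-symbol-per-line role lists, TSV expression matrices with
a header row, and TSV/JSON background serializations.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exhaustive
brute-force oracle equivalence for path enumeration, a bit-reproducible
worked scoring example, exact housekeeping recovery, planted-pathway
recovery across 50 seeds, permutation-FPR sanity (identity-hook mean of
exactly 1.0; planted-signal FPR below 1 and decreasing with signal
strength), monotonicity properties, and writer/reader round-trips.

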