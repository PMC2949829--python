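# dheascreen

A tested, reusable re-implementation of a liver-transcriptomics screening
pipeline for prohormone (DHEA) abuse in cattle, built around a two-colour
common-reference microarray design with two divergent control groups
(CTR1/CTR3) and two administration routes (intramuscular IM, oral PO):

1. **simulate** — synthetic spot-level two-channel experiments mirroring the
   13-animal design (3 IM, 3 PO, 3 CTR1, 4 CTR3), with a pooled Cy3 common
   reference, replicate spots per gene, a control-group batch effect, planted
   treatment signatures (route-specific and shared), and a JSON ground-truth
   sidecar, so every downstream stage is testable without any download.
2. **preprocess** — 2×-background signal filter, two-step median-ratio
   normalization (per-spot Cy3 median for the random error, per-array overall
   Cy5 median for the systematic error), intensity flooring at 130, log2
   transform, per-gene mean centering; PCA and average-linkage gene
   clustering as unsupervised views.
3. **de** — the replicate-wise selection rule: a spot is regulated when the
   Student t-test gives p < 0.05 **and** every treated replicate is displaced
   from the control mean by more than log2(1.5), all in one direction; spots
   collapse to unique genes and to direction-split gene sets
   (`DHEA_<route>_vs_<control>_<UP|DOWN>`, standard GMT).
4. **gsea** — from-scratch gene set enrichment analysis: signal-to-noise
   ranking (SD floored at 0.2·|mean|), weighted running-sum enrichment score,
   **gene-set permutation** null, nominal p, NES and FDR q; a set is
   significant when p < 0.05 and FDR < 0.25.
5. **crossval** — every derived set is evaluated in every other
   (route × control) context; cells are partitioned into cross-control,
   cross-route and self, and summarized as a Table-2-shaped TSV plus JSON
   counts. Literature sets from GMT files ride along as external rows.

## CLI

All stages are exposed under one `dheascreen` command (also
`python -m dheascreen.cli`); `-v/-vv` raise log verbosity, seeds are
mandatory wherever randomness is involved.

```sh
dheascreen simulate --config sim.yaml --seed 7 --out run/
dheascreen preprocess --spots run/spots --samples run/samples.tsv --floor 130 --out run/
dheascreen de --matrix run/matrix.tsv --samples run/samples.tsv \
    --treated IM --control CTR1 --p 0.05 --fc 1.5 --out run/
dheascreen build-sets --de run/de_IM_vs_CTR1.tsv --out run/sets.gmt
dheascreen gsea --matrix run/matrix.tsv --samples run/samples.tsv \
    --sets run/sets.gmt --classA IM --classB CTR3 --nperm 1000 --seed 7 --out run/gsea.tsv
dheascreen crossval --matrix run/matrix.tsv --samples run/samples.tsv \
    --p 0.05 --fc 1.5 --fdr 0.25 --nperm 1000 --seed 7 --out run/
dheascreen report --table run/summary.json
dheascreen run --config pipeline.yaml --seed 7 --out run/   # umbrella
```

`dheascreen run` executes simulate → preprocess → DE → gene sets → GSEA →
crossval → report in one go; with a fixed seed the whole output tree is
byte-reproducible.

Spot tables are plain TSV (`probe_id`, `gene_id`, `cy5`, `cy3`, `bg5`,
`bg3`), one file per array; real data (e.g. converted Agilent Feature
Extraction exports) can be fed through the same path via
`--spots`/`--samples`.

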