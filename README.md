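# phoskin

Upstream kinase activity inference from serine/threonine kinome
peptide-array kinetics.

## The problem

Kinome chips (e.g. PamChip-style STK arrays) expose a lysate to ~140
immobilized 12–15-mer peptides with phosphorylatable Ser/Thr residues and
read fluorescence over a series of camera exposures. The biological question
is rarely about the peptides themselves: it is *which upstream kinases*
changed activity between two experimental groups (knockout vs control,
treated vs vehicle). `phoskin` implements that inference as a reusable,
tested pipeline for anyone analyzing two-group kinome-array experiments:

1. **Signal extraction** — each (sample, peptide) kinetic curve is reduced
   to the least-squares slope of intensity vs exposure time, scaled ×100,
   clamped at zero and stabilized as `log2(1 + scaled slope)`; curves must
   pass a QC gate (fit R² ≥ 0.8 in every sample of the comparison, maximum
   intensity ≥ 5 in at least one) to enter the statistics.
2. **Kinase→peptide mapping** — from a PhosphoNET/Kinexus-style score
   table: per kinase, sites scoring strictly >300 are rank-ordered and the
   top 12 kept (ranks 1–12); in-vitro confirmed substrates join at rank 0.
3. **The kinase statistic** — for a kinase with n mapped, QC-passing
   peptides, with per-group sample means p̄ᵢⱼ and variances s²ᵢⱼ:

   τ = (1/n) · Σᵢ (p̄ᵢ₁ − p̄ᵢ₂) / √(s²ᵢ₁ + s²ᵢ₂)

4. **Permutation scores** — a **significance score** permutes sample group
   labels (how much τ depends on the grouping) and a **specificity score**
   draws random peptide sets of size n (how much τ depends on the mapping);
   both are −log10 of the pseudo-counted two-sided permutation p-value
   (1 + b)/(B + 1). The **final score** is their sum; kinases above 1.5
   are flagged for the ranked report.
5. **Peptide-level output** — Welch t per peptide with BH FDR, a top-75
   differentially-regulated selection, and a row-z-scored, hierarchically
   clustered heatmap matrix.

Because raw chip data for such studies are rarely deposited, the package
ships a first-class synthetic experiment generator
(`phoskin.simulate`) whose kinetic model is the exact inverse of the
extraction transform, with planted kinase-activity differences and full
ground truth — every stage is testable without any download.

## Worked example

`python examples/run_full_pipeline.py` simulates a control-vs-knockout chip
(6 samples/group, 140 peptides, 20 kinases, four of them planted with
activity deltas 1.5, 0.7, 0.35 and 0.12 in the control group), writes the
four input TSVs, and runs the full pipeline. It prints the ranked kinase
table; abridged:

```
kinase     tau  significance  specificity  final_score  n_peptides direction  report
   K01  2.0693        2.6646       3.0000       5.6646          11  up_in_g1    True
   K02  1.1485        2.6646       3.0000       5.6646          11  up_in_g1    True
   K03  0.8343        2.6646       1.9586       4.6232          11  up_in_g1    True
   ...
   K20  0.2417        0.8321       0.3054       1.1375          11  up_in_g1   False
   K17 -0.0036        0.0105       0.0048       0.0153          11  up_in_g2   False
```

The two strongly planted kinases saturate both permutation scores
(significance 2.66 = −log10(1/462), the exhaustive 6v6 label-permutation
floor; specificity 3.0 = −log10(1/1000) at B = 999); weakly planted K04
(delta 0.12) stays indistinguishable from the unplanted kinases, and ten
kinases clear the 1.5 reporting cut-off. `tau > 0` (`up_in_g1`) means the
kinase's substrates are phosphorylated faster in the control group.

Other examples: `simulate_and_extract.py` (signal extraction and QC),
`build_kinase_map.py` (threshold/top-12/rank-0 mapping rules),
`differential_peptides.py` (Welch statistics and the heatmap matrix).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's acceptance quantity from scratch: it simulates a
seeded chip experiment whose kinase final scores straddle the reporting
cut-off, runs the complete pipeline through the config/artifact layer, and
reports the minimum final score among report-flagged kinases (with the
number of scored kinases) as JSON.

## Layout

- `src/phoskin/io.py` — validated TSV readers/writers for every table
- `src/phoskin/kinetics.py` — curve → signal extraction, QC gate
- `src/phoskin/mapping.py` — score-table → kinase map, homology expansion
- `src/phoskin/differential.py` — Welch stats, top-N selection, heatmap
- `src/phoskin/uka.py` — τ, permutation scores, final ranking
- `src/phoskin/simulate.py` — synthetic experiments with ground truth
- `src/phoskin/pipeline.py` — RunConfig, orchestration, figures
- `docs/methods.md` — model, assumptions, numerical choices, limitations
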