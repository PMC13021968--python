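# danscreen

Multi-stage triage of RNAi screen candidates acting downstream of the
cohesin complex in *Drosophila* dopamine neurons.

## The problem

A differential-expression experiment hands you 160 candidate genes; at the
end you need one. This package implements, as a tested and reusable
pipeline, the analysis chain a dopamine-neuron (DAN) screening campaign
uses to get there:

1. **Catalog accounting** — which DEGs have inducible RNAi lines (KK / GD /
   TRiP libraries), which crosses are lethal, and hence which genes and
   lines actually enter the screen.
2. **Primary behavioral screen** — aversive olfactory memory read out as a
   performance index, PI = (CS⁻ − CS⁺)/(CS⁻ + CS⁺), per counterbalanced
   pair of ~60-fly vials. Four data points per line, the point farthest
   from the four-point mean is discarded, and the trimmed mean is divided
   by the library-matched screen-wide control average to give a **memory
   score**. Scores beyond 1 ± 0.25 (strict) are hits; a hit is kept only if
   **concordant** with the gene's transcriptional direction (high memory ×
   significant decrease, low memory × significant increase).
3. **Secondary synaptic-vesicle-marker screen** — Syt:eGFP fluorescence in
   a fixed ROI, hemispheres averaged per animal, line mean over control
   mean; ratios beyond 1 ± 0.25 in the direction matching the memory
   phenotype pass.
4. **Replication gate** — dedicated retests of both phenotypes; a
   candidate survives only if both are significant (two-tailed, α = 0.05;
   behavioral data tested parametrically, imaging data gated by
   Shapiro–Wilk between Student's t and Mann–Whitney U) and in the
   expected direction.
5. **Expression re-validation** — nCounter-style count panels under
   pan-neuronal knockdown of each of two cohesin subunits, normalized by
   geometric-mean scaling against six housekeeping genes (αTub84B, Gapdh2,
   Act5C, brp, unc-104, dicer2); expression ratio = mean(KD)/mean(control);
   plus RT-qPCR fold changes as 2^(−ΔΔCt).
6. **Cross-modality intersection** — replicated survivors ∩ genes
   down-regulated under knockdown of subunit 1 ∩ genes down-regulated under
   knockdown of subunit 2. In the modeled campaign this isolates exactly
   one gene, *Neprilysin 1* (*Nep1*).

Downstream functional readouts are covered too: ΔF/F = ((F_t − F₀)/F₀) ×
100% for shock-evoked dopamine-sensor traces (12 × 90 V × 1.25 s pulses at
5 s intervals, 4 Hz sampling), trapezoidal area under the curve over
responses 7–12 as the sustained-release statistic, and ANOVA + Tukey
classifiers for overexpression-rescue and double-knockdown epistasis
experiments.

Because the original per-vial and per-animal tables are not redistributable,
the package ships a seeded **synthetic-study generator**
(`danscreen.synthetic`) that emits every input table with planted
true-positive genes, day effects, negative-binomial panel counts, and
interleaved controls — so the entire pipeline is exercisable and testable
without any external data.

## Worked example

The decision layer applied to the modeled campaign's published per-gene
outcomes:

```python
from danscreen.deg_catalog import catalog_accounting
from danscreen.examples import example_catalog, example_stage_ledger

degs, catalog = example_catalog()
print(catalog_accounting(degs, catalog))
print(example_stage_ledger().summary()["final_candidates"])
```

```
{'n_genes_with_lines': 156, 'n_lines_obtained': 169, 'n_lethal_lines': 6,
 'n_lines_tested': 163, 'n_genes_tested': 150}
['Nep1']
```

Of 160 DEGs, 156 had at least one of 169 obtained RNAi lines; 6 lines were
lethal and were the sole line for their gene, so 163 lines against 150
genes entered the primary screen. Flowing the published stage outcomes
through the ledger (10 secondary candidates → 5 replicated → intersect with
both knockdown panels) leaves exactly `Nep1`.

A complete synthetic study, end to end:

```python
from danscreen import StudyConfig, gen_study, run_study_from_synthetic

study = gen_study(StudyConfig(seed=1))
ledger, report = run_study_from_synthetic(study)
print(report["stage_counts"])
print("final:", report["final_candidates"], " planted:", sorted(study.planted_genes))
```

```
{'in_catalog': 156, 'tested_primary': 150, 'primary_hit': 12,
 'primary_concordant': 9, 'secondary_hit': 3, 'secondary_concordant': 3,
 'replicated': 3, 'sa_kd_downregulated': 3, 'smc1_kd_downregulated': 3,
 'final_candidate': 3}
final: ['g025', 'g106', 'g139']  planted: ['g019', 'g025', 'g106', 'g139', 'g144']
```

Seed 1 plants five downstream genes; three survive every stage (the primary
screen's ±25% ratio threshold is the sensitivity bottleneck — see
`docs/methods.md`), and no false positives reach the final set. The same
run is available from the shell:

```sh
danscreen simulate --seed 1 --out study/
danscreen run --config run.yaml        # paths + thresholds in YAML
danscreen triage --replicated "Su(z)12,CG17698,COX7C,Nep1,ttm2" \
    --sa-down "Lkr,Octbeta1R,Nep1" \
    --smc1-down "Octbeta1R,CG17698,COX7C,Nep1,atms,TfIIB,tra2,Cpsf160,CG9008,Ras64B,CG15657"
# {"final_candidates": ["Nep1"]}
```

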