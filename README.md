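# emtlink

Integration of transcription-factor ChIP-seq binding with knockdown
expression profiling, built for studies that ask whether a chromatin
factor *drives* the gene programs it sits on — the design used to dissect
LSD1's role in inducible EMT/CSC programs of breast cancer cells.

## The problem

A stimulated epithelial-to-mesenchymal transition (EMT) experiment with a
factor knockdown produces four expression arms per probe:
baseline/stimulated × mock/siRNA. The analysis chain this package
implements:

1. **Direction calling.** A probe is *induced* when
   `stim_mock − baseline_mock > 0.5` log2 units, *repressed* below −0.5
   (strict inequalities), else unchanged.
2. **Knockdown sensitivity ("reversibility").** An induced probe is
   sensitive when the knockdown contrast `stim_sirna − stim_mock` crosses
   the same 0.5 log2 threshold in the opposing direction (symmetric for
   repressed probes). The per-direction percent reversible is the
   headline statistic of such screens.
3. **Region annotation.** Binding regions with < 12.2 normalized reads
   (per 10 M library) are discarded; each surviving region is assigned
   its nearest same-chromosome TSS by centre distance (ties to the
   lexicographically smallest gene id), a genomic feature (promoter =
   centre strictly < 1 kb from a TSS), and the chromatin-state segment of
   maximal overlap. Cumulative distance-bin proportions and strand-aware
   TSS metaprofiles (100 bp bins, ±1.5 kb) summarize where the factor
   sits relative to regulated genes.
4. **Direct vs indirect targets.** A sensitive gene with a region centre
   within 5 kb (inclusive) of its TSS is a *direct* target; a sensitive
   gene without one is *indirect*; insensitive genes are untargeted.
5. **Enrichment statistics.** Upper-tail hypergeometric enrichment of
   gene sets, and two-sided Fisher exact tests (point-probability
   ordering, exact integer arithmetic) for CSC-vs-NCSC compartment
   contingencies.
6. **Co-binding.** Overlapping regions of two factors (any shared bp,
   half-open coordinates) are transitively merged, standardized to 300 bp
   around the merged midpoint, and the two factors' tag counts are
   Pearson-correlated over nested region subsets (all co-bound →
   promoter-proximal → promoter-proximal at sensitive genes).
7. **Companion quantification.** Peptide-array kinase-substrate positives
   at mean + 2 SD; total nuclear/cell fluorescence intensity
   (TNFI/TCFI = masked sum − background × area); pixel colocalization
   PCC; and the partition of cells into high/moderate/low intensity
   phenotypes (e.g. TNFI > 1100 / 500–1100 / < 500).

Every stage has a synthetic-data generator (`emtlink.simulate`) that
plants recorded ground truth — gene directions, sensitivity, direct
targets, co-binding correlation tiers, peptide hits, pixel correlation —
so the whole chain is testable without any external download.

## Worked example

```python
from emtlink import SimConfig, RunConfig, run_pipeline

cfg = RunConfig(outdir="demo", seed=1, simulation=SimConfig())
report = run_pipeline(cfg)
print(report["stages"]["expression"]["reversibility"].to_string(index=False))
```

prints, for the default 1000-gene synthetic study:

```
direction  n_total  n_reversible  percent
  induced      186            71     38.2
repressed      171            41     24.0
```

i.e. 186 probes were called induced on stimulation and 71 of them (38.2%)
reverted on knockdown — the simulated study plants reversibility rates of
41.7% (induced) and 23.6% (repressed), recovered here up to calling noise.
The same report carries the target classification

```
directness: {'untargeted': 888, 'direct': 89, 'indirect': 23}
```

(89 sensitive genes have binding within 5 kb of the TSS), the nested
co-binding tag correlations, the CSC-compartment Fisher p-value among
induced genes (`3.3e-05` at this seed), and the peptide-array call
(`15 of 201` positive at threshold `mean + 2 SD = 32.1`).

The same stages are available from the shell:

```bash
emtlink simulate --seed 1 --outdir demo
emtlink sensitivity --expression demo/expression.tsv --out demo/calls.tsv
emtlink run --config my_run.yaml
```

## Layout

| module | role |
| --- | --- |
| `emtlink.simulate` | synthetic study generators with planted truth |
| `emtlink.expression` | direction / sensitivity / compartment-bias calls |
| `emtlink.annotate` | region filtering, nearest-TSS, features, states, metaprofiles |
| `emtlink.integrate` | direct/indirect targets, Fisher & hypergeometric tests |
| `emtlink.cobind` | overlap, merge/standardize, tag-count correlation |
| `emtlink.signals` | peptide hits, motif scan, TNFI/TCFI, pixel PCC, phenotypes |
| `emtlink.pipeline` / `emtlink.cli` | orchestration, config, report |

See `docs/methods.md` for the statistical conventions, simulator design,
and known limitations.
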