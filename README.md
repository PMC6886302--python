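# burstquant

Quantification of stochastic transcriptional bursting from
single-molecule FISH (smFISH) spot tables, together with an exact
telegraph-model simulator of promoter switching driven by pulsatile
transcription-factor (p53-like) dynamics.

The package is aimed at quantitative biologists who count transcripts
and transcription-site (TSS) signals per cell — e.g. with
FISH-quant-style spot detection — and want to turn those tables into
burst-frequency and burst-size proxies, RNA degradation rates,
expression-noise statistics and promoter time-course classifications,
with a fully simulated ground truth to validate every step against.

## The model and the statistics

Each gene is transcribed from `n` genomic loci, each carrying a
two-state (random telegraph) promoter: off→on at `k_on`, on→off at
`k_off`, initiation at rate `r` while on, first-order degradation of
mature RNA at `d_RNA`. Stationary copy numbers have

    mean = n · k_on/(k_on+k_off) · r/d,
    Fano = 1 + r·k_off / ((k_on+k_off)(k_on+k_off+d)),

Poissonian (`Fano = 1`) for a constitutive promoter and strongly
super-Poissonian for bursty ones. From smFISH-style tables the package
computes the standard burst quantification:

- **fraction of active promoters** `f = #TSS/n` per cell and population
  (burst-frequency proxy), with strong (≥ 75% of loci) / weak binning;
- **RNAP2 occupancy** `M = Int_TSS/(κ·η·mInt_mRNA)`, the nascent TSS
  signal in median-single-mRNA units, corrected by `κ = 1.5` and by the
  probe-position factor `η = (1/N_p)·Σ(l−p_i)/l`;
- **transcription rate** `μ = M·v/l` per active site (burst-size proxy),
  with `v = 3 kb/min` elongation, and `μ_sum = M_sum·v/l` per cell;
- **degradation rate** from the steady-state balance
  `X_RNA = n·f·μ/d_RNA` over active cells, and `t_1/2 = ln 2/d_RNA`;
- **noise statistics** `CV² = σ²/μ²` and Fano `σ²/μ` per compartment,
  plus the frequency-modulation guide hyperbolas `CV² = b/⟨mRNA⟩`;
- **archetype classification** of `f` time courses over the p53 pulse
  train (basal, 3, 6, 9 h) into sustained / pulsatile / transient, with
  a score vector for ambiguous genes.

The simulator generates the same tables from known parameters — including
treatment regimes that make p53 pulse, fire once, or stay high, and
promoter archetypes that track, ignore, or latch onto those dynamics — so
the whole inference chain can be validated by parameter recovery.
See `docs/methods.md` for assumptions, bias analysis and limitations.

## Worked example

```python
import numpy as np
from burstquant import (GeneModel, ExperimentDesign, TelegraphParams,
                        sample_population, infer_burst_parameters,
                        assemble_timecourse, classify_archetype)

gene = GeneModel(
    name="CDKN1A_like", length_nt=10_000, n_loci=4,
    exon_probe_positions_nt=tuple(np.linspace(300, 9700, 30).astype(int)),
    intron_probe_positions_nt=tuple(np.linspace(200, 5000, 10).astype(int)),
)
params = TelegraphParams(k_on_basal=0.5, k_off=1.5, init_rate=160.0,
                         deg_rate=0.4, export_rate=2.4, archetype="pulsatile")
design = ExperimentDesign(treatment="IR_pulsatile",
                          n_cells_per_timepoint=500, seed=11)

sample = sample_population(gene, params, design)
ests = infer_burst_parameters(sample.spots, sample.cells, gene, design)
for est in ests:
    print(f"t={est.timepoint_h:>3g} h  f={est.f:.2f}  "
          f"median M={est.median_M:.1f}  median mu={est.median_mu:.0f}/h  "
          f"d={est.d_RNA:.2f}/h  t1/2={est.t_half_h:.1f} h")
tc = classify_archetype(assemble_timecourse(ests))
print("archetype:", tc.archetype_call)
```

prints

```
t=  0 h  f=0.27  median M=8.3  median mu=149/h  d=0.39/h  t1/2=1.8 h
t=  3 h  f=0.69  median M=8.1  median mu=147/h  d=0.63/h  t1/2=1.1 h
t=  6 h  f=0.32  median M=8.3  median mu=149/h  d=0.26/h  t1/2=2.7 h
t=  9 h  f=0.69  median M=8.3  median mu=150/h  d=0.54/h  t1/2=1.3 h
archetype: pulsatile
```

Reading this: basal activity (27% of loci transcribing) jumps to 69% at
the first p53 peak, collapses at the 6 h trough and returns at the
second peak — the promoter is modulated in burst *frequency* (the median
rate per active site, ~150 RNA/h matching the initiation rate `r = 160/h`
within sampling error, barely moves), and the shape classifier calls the
time course pulsatile. The basal degradation estimate 0.39/h recovers
the generative 0.4/h; at non-stationary time points it is an effective
rate.

The same pipeline runs from the shell on TSV tables:

```sh
burst simulate --config src/burstquant/data/genes_demo.yaml --seed 17 --out run/
burst infer    --spots run/spots.tsv --cells run/cells.tsv \
               --config src/burstquant/data/genes_demo.yaml --out run/
burst noise    --spots run/spots.tsv --cells run/cells.tsv --out run/
burst classify --estimates run/estimates.tsv --out run/
burst report   --dir run/
```

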