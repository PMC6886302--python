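# Methods

## The generative model

Each gene is transcribed from `n` independent genomic loci (2–4 in the
aneuploid cell lines this package emulates). Every locus carries a
two-state ("random telegraph") promoter: it switches from the inactive to
the active state at rate `k_on(t)` and back at rate `k_off`; while active,
transcripts initiate as a Poisson process with rate `r`. Each nascent
transcript elongates deterministically at the RNAP2 speed `v`
(default 180,000 nt/h, i.e. 3 kb/min) and joins the nuclear mature pool on
reaching the transcript end `l`. Mature RNA is exported to the cytoplasm
at rate `k_exp` and degraded with a single first-order rate `d_RNA`.

Degradation is applied to the whole mature pool, nuclear and cytoplasmic
alike; export only relabels the compartment. Two consequences motivate
this choice. First, the total mature copy number then follows the
standard telegraph birth–death process exactly, so the closed-form
stationary moments

    mean = n · p_on · r / d,          p_on = k_on / (k_on + k_off)
    Fano = 1 + r·k_off / ((k_on + k_off)(k_on + k_off + d))

hold for the simulator without approximation (`Fano = 1` for a
constitutive promoter, `k_off = 0`). Second, the inference model's
steady-state balance `X_RNA = n·f·μ/d_RNA` treats "RNAs per cell" as one
pool with one decay rate; a cytoplasm-only sink would make the total
count exceed `p_on·r/d` by a factor `(1 + d/k_exp)` and silently bias the
inferred degradation rate. Under this kinetics the stationary
nuclear-to-cytoplasmic mean ratio is `d_RNA/k_exp`, constant over time —
the behaviour observed for most genes in the system emulated here. The
elongation delay `l/v` shifts the initiation process without changing its
stationary counting statistics, so the moments above apply to the full
simulator including the nascent stage.

### p53 input and promoter archetypes

DNA damage at `t = 0` triggers nuclear p53 dynamics that depend on the
treatment: *pulsatile* (ionising radiation) — Gaussian pulses of width
1.1 h centred at 3 h and 9 h with a deep trough at 6 h; *transient* (IR
plus Chk2 inhibition) — the first pulse only; *sustained* (IR plus
Nutlin-3) — a rise complete by 3 h followed by a plateau at peak level.
Profiles are normalised so the maximum over the first 4 h is 1.

Target promoters respond by **frequency modulation**:
`k_on(t) = k_on_basal · (1 + (F − 1)·u(t))` with induced fold-change
`F` (default 6) and a response `u(t) ∈ [0, 1]` set by the gene's
archetype: *pulsatile* promoters track p53 directly, *sustained*
promoters latch to the running maximum of the drive, and *transient*
promoters follow the first pulse but are then suppressed by a
desensitisation envelope `exp(−(t − 3 h)/τ)` (default `τ = 2 h`), so the
second p53 peak does not re-activate them. `k_off`, `r` and `d_RNA` are
held constant — burst frequency is the only regulated quantity, which is
the modulation mode the noise-scaling analysis probes.

### Exact sampling

Promoter trajectories are sampled interval-by-interval; the
inhomogeneous off→on waiting time is drawn by thinning against the
global bound `max_t k_on(t)`, which is exact. Initiation events are
Poisson within on-intervals, and each transcript's
maturation/export/degradation fate is an independent pair of exponential
clocks, so an entire snapshot population vectorises. The scheme is
statistically identical to a Gillespie simulation of the same network; a
classical SSA (`gillespie_telegraph`) is kept in the package purely as an
independent cross-check oracle. Every population starts from the basal
stationary promoter occupancy with empty RNA pools at
`t₀ = T − max(9/d, 10·l/v, 6/(k_on+k_off))`, which leaves a relative
initialisation bias below `e⁻⁹` at the observation time `T`. Time points
are independent cell populations (cells are fixed, not tracked), and all
randomness derives from one seed through spawned substreams, so
identical configurations give byte-identical output tables.

### Emulated measurement

Mature RNAs become individual spot records with LogNormal intensities
(median `mInt = 1` a.u., CV 25%). An allele holding ≥ 1 nascent
transcript emits a candidate TSS whose exon-channel intensity is
`κ·mInt·Σ_j φ_j`, where `φ_j` is the fraction of exon probes whose
3′-most nucleotide the j-th polymerase has passed, plus Gaussian noise
(σ = 10% of signal, floored at 0); it carries an intron mark iff some
polymerase has passed the first intron-probe position. The noise
magnitudes are configuration, not claims about any instrument. Features
of real images the generator does **not** emulate: segmentation errors,
spot-detection false positives/negatives, z-stack truncation, probe
off-target binding, cell-cycle and volume covariation, and
transcriptional pausing (elongation is deterministic, as the inference
formula also assumes). Passing tests therefore validate the inference
chain against its own model assumptions, not against microscopy
artefacts.

## The inference chain

Per time point: the single-mRNA intensity calibration `mInt_mRNA` is the
median cytoplasmic mature-spot intensity (falling back to all mature
spots, with a warning, below 50 cytoplasmic spots). A TSS is called iff
nuclear, intron-marked and above the intensity floor (default
`0.5·mInt_mRNA` — half a mature-spot equivalent; real pipelines embed
comparable thresholds in their fitting settings). Cells reporting more
sites than loci are capped at `n_loci`, keeping the brightest.

- fraction of active promoters `f = Σ#TSS / (n_cells·n)` (burst-frequency
  proxy); per-cell binning: strong ≥ 75% of loci active, weak otherwise
  (the boundary value 75% itself, e.g. 3 of 4 loci, is assigned to
  strong);
- RNAP2 occupancy `M = Int_TSS/(κ·η·mInt_mRNA)` with fixed `κ = 1.5` and
  probe-position correction `η = (1/N_p)·Σ_i (l − p_i)/l`, the expected
  hybridised probe fraction under a uniform polymerase position;
- transcription rate `μ = M·v/l` per site and `μ_sum = M_sum·v/l` per
  cell (burst-size proxy);
- degradation `d_RNA = n·f·mean(μ)/X̄` with `X̄` the mean RNA count over
  actively transcribing cells (total pool by default; a cytoplasmic-only
  switch is exposed), and `t_1/2 = ln 2/d_RNA`. The definition makes the
  conservation identity `n·f·mean(μ)/d_RNA = X̄` exact by construction.

## Validity regime of the estimators

Two biases are predictable from the model and bound the regime in which
the recovery experiments operate; both are derived before any tuning and
verified numerically.

1. **Residual nascent signal inflates `f`.** After a promoter switches
   off, polymerases keep running for up to `l/v`, so TSS detection lags
   the promoter state by the residence time. The expected inflation is
   ≈ `p_on·k_off·l/v`. The validation gene is 10 kb (`l/v` = 3.3 min)
   with `k_off ≤ 1.6/h`, predicting ≤ 0.03 inflation (measured ≤ 0.02).
   Conversely an on-allele needs `r·l/v ≳ 5` expected nascents for
   near-certain detection; validation sets use loads of 7–10.
2. **Active-cell conditioning biases `d_RNA` low.** Restricting the
   balance to cells with a visible TSS selects cells whose promoters
   were recently on and whose counts sit above the population mean by
   `Cov(X, active)/P(active)`. For `n` independent loci the relative
   bias of `d̂` is ≈ `d·(1−p_on)ⁿ / ((d + k_on + k_off)(1 − (1−p_on)ⁿ))`.
   It vanishes when switching is fast relative to RNA turnover and when
   most cells are active. Validation sets use `n = 4`,
   `p_on = 0.2–0.33` and switching 4–7× faster than degradation,
   predicting ≤ ~10% (measured ≤ 8%). Outside this regime — stable
   transcripts with rare bursts — the same estimator underestimates
   `d_RNA` by 25–35%; this is a limitation of the steady-state balance
   itself, not of its implementation.

The noise-scaling sweep holds `b = r/k_off = 30` (inside the 5–70 guide
range) with `k_off/k_on ≥ 19` across the sweep, since the fixed-burst
hyperbola `CV² = b/⟨mRNA⟩` is the `k_off ≫ k_on` limit; the analytic
log–log slope over the chosen grid is −1.02 to −1.03.

## Archetype classification

Archetypes are shape, not level, distinctions, so the four-point `f`
series (basal, 3, 6, 9 h) is min–max normalised and assigned to the
nearest template by Euclidean distance: sustained `(0, 1, 1, 1)`,
pulsatile `(0, 1, 0, 1)`, transient `(0, 1, 0.5, 0.25)`. The templates
encode the verbal definitions (persistence through the trough;
pulse-tracking; first-pulse-only with decay) — real promoters fall on a
continuum, so the softmax score vector over negative distances
(temperature 0.25) is retained as the primary output for ambiguous
genes, and the hard call is the argmin with ties broken in template
order. Series without induction (`f(3 h) ≤ f(0 h)`) are labelled
unresponsive; series with missing time points are flagged and not
called. Classification is invariant to affine rescaling of `f` by
construction.

## Numerical and statistical choices

- Unbiased (`n−1`) variance estimators everywhere; mean-zero populations
  return NaN-flagged noise statistics rather than infinities.
- Monte-Carlo agreement checks use 3-standard-error bands; the SE of the
  Fano factor is computed by the delta method with sample third/fourth
  central moments. With ~12 simultaneous z-scores per moment check, an
  occasional |z| slightly above 3 is expected by chance at the few-percent
  level even for an exact simulator.
- The master equation `dp/dt = k_on(t)(1−p) − k_off·p` is integrated with
  `scipy.integrate.solve_ivp` (RK45, rtol 1e-8) to fill the truth table's
  analytic `P(on at T)`, the quantity the per-time-point `f` estimator
  targets; for constant rates it equals `k_on/(k_on+k_off)`.
- Problem sizes: moment checks at 10,000 cells; parameter recovery at
  2,000 cells per time point, five telegraph sets × three seeds;
  archetype recovery at 2,000 cells per time point, ten seeds per
  archetype; η oracle at 100,000 polymerase draws on 20 random layouts.
- `η` is evaluated as the exact uniform-occupancy expectation rather
  than any discretised approximation of it; probe coordinates are the
  3′-most nucleotide of each probe on a single transcript-length axis
  shared by nascent and mature molecules.

## Known limitations

- The steady-state degradation balance assumes the population is at
  (quasi-)steady state; at time points shortly after strong induction it
  returns an effective, not instantaneous, rate.
- No likelihood-based inference of `(k_on, k_off)` from count
  distributions is attempted; `f` and `μ` are moment-style proxies for
  burst frequency and size.
- The guide-curve burst size follows the `b = μ/k_on` convention used in
  the noise-scaling analysis this package reproduces; the more common
  telegraph burst size is initiation rate over `k_off`. Both are simple
  to compute; the discrepancy between conventions is documented here and
  deliberately not resolved.
- Allele identity is not tracked across time points (populations are
  independent), so per-allele temporal correlation is out of reach by
  design.
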