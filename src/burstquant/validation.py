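"""Validation experiments: simulator vs closed forms, parameter recovery.

Each function runs a self-contained in-silico experiment with the
package's own simulator and inference chain and returns plain numbers.
The parameter sets are fixed study conditions chosen inside the regime
the inference model assumes: bursty promoters (k_off > k_on), polymerase
residence times (l / v, minutes) short against switching times (hours),
on-state polymerase loads of roughly 7-10, and promoter switching fast
relative to RNA turnover so that the steady-state degradation balance
over actively transcribing cells is unbiased (see docs/methods.md for
the bias analysis behind these bounds).
"""

from __future__ import annotations

import numpy as np

from .core_model import ExperimentDesign, GeneModel, compute_eta
from .inference import infer_burst_parameters
from .noise import fano_standard_error, log_noise_scaling_slope, noise_summary
from .simulate import (
    TelegraphParams,
    _simulate_population,
    constant_kon,
    sample_population,
    steady_state_moments,
)
from .timecourse import assemble_timecourse, classify_archetype

#: reference gene used by the recovery experiments: 10 kb transcript,
#: 4 loci, 30 exon probes spread along the gene, introns in the 5' half
RECOVERY_GENE = GeneModel(
    name="SYN10K",
    length_nt=10_000,
    n_loci=4,
    exon_probe_positions_nt=tuple(np.linspace(300, 9700, 30).astype(int)),
    intron_probe_positions_nt=tuple(np.linspace(200, 5000, 10).astype(int)),
)

#: (k_on, k_off, init_rate, deg_rate) per hour - telegraph sets for the
#: parameter-recovery experiment; export is fixed at 6x degradation
RECOVERY_SETS: tuple[tuple[float, float, float, float], ...] = (
    (0.50, 1.50, 160.0, 0.40),
    (0.60, 1.20, 140.0, 0.80),
    (0.45, 1.05, 126.0, 0.40),
    (0.40, 1.60, 180.0, 0.35),
    (0.55, 1.10, 150.0, 0.45),
)

#: telegraph sets for the moment-oracle comparison, spanning Fano 1-30
MOMENT_SETS: tuple[tuple[float, float, float, float], ...] = (
    (1.0, 0.0, 20.0, 1.0),     # constitutive, Fano = 1
    (2.0, 2.0, 20.0, 1.0),     # Fano = 3
    (1.0, 9.0, 100.0, 1.0),    # Fano ~ 9.2
    (0.5, 9.5, 150.0, 1.0),    # Fano ~ 14
    (0.5, 4.5, 150.0, 1.0),    # Fano ~ 23.5
    (0.2, 1.8, 95.0, 1.0),     # Fano ~ 29.5
)

#: archetype-recovery conditions (pulsatile IR input, 2 loci)
ARCHETYPE_GENE = GeneModel(
    name="SYN10K2",
    length_nt=10_000,
    n_loci=2,
    exon_probe_positions_nt=RECOVERY_GENE.exon_probe_positions_nt,
    intron_probe_positions_nt=RECOVERY_GENE.intron_probe_positions_nt,
)
ARCHETYPE_PARAMS = dict(k_on_basal=0.35, k_off=1.4, init_rate=130.0,
                        deg_rate=0.8, export_rate=4.8)


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31 derived from one master seed."""
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _snapshot_counts(gene: GeneModel, params: TelegraphParams, n_cells: int,
                     seed: int) -> np.ndarray:
    """Stationary total mature counts of ``n_cells`` single-allele cells."""
    rng = np.random.default_rng(seed)
    horizon = max(9.0 / params.deg_rate, 10.0 * gene.dwell_time_h,
                  6.0 / max(params.k_on_basal + params.k_off, 1e-9))
    sim = _simulate_population(gene, params, constant_kon(params.k_on_basal),
                               -horizon, 0.0, n_cells, rng)
    return sim["nuc_count"] + sim["cyt_count"]


def poisson_anchor(seed: int, n_cells: int = 10_000) -> dict:
    """Fano factor of a constitutively active promoter (expected 1).

    Simulates ``n_cells`` cells with k_off = 0 (no bursting) and returns
    the sample Fano factor with its Monte-Carlo standard error.
    """
    params = TelegraphParams(k_on_basal=1.0, k_off=0.0, init_rate=20.0,
                             deg_rate=1.0, export_rate=6.0)
    gene = ARCHETYPE_GENE
    counts = _snapshot_counts(gene, params, n_cells, seed)
    s = noise_summary(counts)
    return {"fano": s.fano, "se": fano_standard_error(counts), "n": n_cells}


def moment_agreement(seed: int, n_cells: int = 10_000) -> list[dict]:
    """Simulated vs closed-form stationary moments for the telegraph sets.

    For each parameter set, returns the simulated mean and Fano, the
    closed-form values and the z-scores (deviation / Monte-Carlo SE).
    """
    out = []
    for sub, (k_on, k_off, r, d) in zip(_sub_seeds(seed, len(MOMENT_SETS)), MOMENT_SETS):
        params = TelegraphParams(k_on_basal=k_on, k_off=k_off, init_rate=r,
                                 deg_rate=d, export_rate=6.0 * d)
        counts = _snapshot_counts(ARCHETYPE_GENE, params, n_cells, sub)
        s = noise_summary(counts)
        ref = steady_state_moments(params, n_alleles=1)
        mean_se = float(np.sqrt(s.variance / counts.size))
        fano_se = fano_standard_error(counts)
        out.append({
            "k_on": k_on, "k_off": k_off, "r": r, "d": d,
            "mean": s.mean, "mean_ref": ref["mean"],
            "fano": s.fano, "fano_ref": ref["fano"],
            "mean_z": (s.mean - ref["mean"]) / mean_se,
            "fano_z": (s.fano - ref["fano"]) / fano_se,
            "n": counts.size,
        })
    return out


def recovery_experiment(seed: int, n_cells: int = 2_000, n_seeds: int = 3) -> list[dict]:
    """Recover f, mu and d_RNA from simulated populations at known truth.

    For every telegraph set in :data:`RECOVERY_SETS` and ``n_seeds``
    replicate populations of ``n_cells`` cells, runs the full spot-table
    inference and reports the error of the promoter-activity fraction
    against k_on/(k_on+k_off), of the mean per-site rate against the
    initiation rate, and of the degradation-rate estimate, plus the
    relative residual of the steady-state conservation identity
    ``n * f * mean(mu) / d_RNA = mean active-cell RNA count``.
    """
    gene = RECOVERY_GENE
    runs = []
    subs = _sub_seeds(seed, len(RECOVERY_SETS) * n_seeds)
    i = 0
    for (k_on, k_off, r, d) in RECOVERY_SETS:
        params = TelegraphParams(k_on_basal=k_on, k_off=k_off, init_rate=r,
                                 deg_rate=d, export_rate=6.0 * d)
        p_on = params.p_on_basal
        for _ in range(n_seeds):
            design = ExperimentDesign(timepoints_h=(0.0,), treatment="untreated",
                                      n_cells_per_timepoint=n_cells, seed=subs[i])
            i += 1
            sample = sample_population(gene, params, design)
            est = infer_burst_parameters(sample.spots, sample.cells, gene, design)[0]
            recon = gene.n_loci * est.f * est.mean_mu / est.d_RNA
            runs.append({
                "k_on": k_on, "k_off": k_off, "r": r, "d": d,
                "f_hat": est.f, "f_true": p_on, "f_error": est.f - p_on,
                "mu_hat": est.mean_mu, "mu_rel_error": est.mean_mu / r - 1.0,
                "d_hat": est.d_RNA, "d_rel_error": est.d_RNA / d - 1.0,
                "conservation_rel_residual":
                    abs(recon - est.mean_active_rna) / est.mean_active_rna,
                "n": n_cells,
            })
    return runs


def eta_mc_check(seed: int, n_layouts: int = 20, n_draws: int = 100_000) -> list[dict]:
    """Probe-position correction vs a Monte-Carlo polymerase-draw oracle.

    For random probe layouts, draws uniform polymerase positions on
    [0, l], counts hybridised probes per draw and compares the mean
    hybridised fraction against :func:`compute_eta`.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_layouts):
        length = int(rng.integers(1_000, 100_000))
        n_probes = int(rng.integers(2, 48))
        probes = np.sort(rng.integers(0, length + 1, n_probes))
        eta = compute_eta(probes, length)
        x = rng.uniform(0.0, length, n_draws)
        # fraction of probes with p_i <= x for each draw
        frac = np.searchsorted(probes, x, side="right") / n_probes
        mc = float(frac.mean())
        se = float(frac.std(ddof=1) / np.sqrt(n_draws))
        out.append({"length": length, "n_probes": n_probes, "eta": eta,
                    "mc": mc, "se": se, "z": (mc - eta) / se if se > 0 else 0.0,
                    "n": n_draws})
    return out


def fm_scaling_slope(seed: int, n_cells: int = 8_000) -> dict:
    """Noise scaling under pure burst-frequency modulation.

    Sweeps k_on at fixed (k_off >> k_on, r, d) and regresses log CV^2 on
    log mean over the sweep; frequency modulation slides the population
    along a fixed-burst-size hyperbola CV^2 = b/<mRNA>, slope -1.
    """
    # k_off >> k_on over the whole sweep (ratio >= 19) so the burst size
    # b = r / k_off = 30 stays effectively constant while k_on moves the mean
    k_off, r, d = 30.0, 900.0, 1.0
    k_ons = (0.1, 0.2, 0.4, 0.8, 1.6)
    gene = GeneModel("SYN10K1", 10_000, 1,
                     RECOVERY_GENE.exon_probe_positions_nt,
                     RECOVERY_GENE.intron_probe_positions_nt)
    means, cv2s = [], []
    for sub, k_on in zip(_sub_seeds(seed, len(k_ons)), k_ons):
        params = TelegraphParams(k_on_basal=k_on, k_off=k_off, init_rate=r,
                                 deg_rate=d, export_rate=6.0)
        counts = _snapshot_counts(gene, params, n_cells, sub)
        s = noise_summary(counts)
        means.append(s.mean)
        cv2s.append(s.cv2)
    return {"slope": log_noise_scaling_slope(means, cv2s),
            "means": means, "cv2": cv2s, "n": n_cells}


def archetype_recovery(seed: int, n_seeds: int = 10, n_cells: int = 2_000) -> dict:
    """Classification accuracy on populations generated per archetype.

    Simulates pulsatile-IR time courses under each promoter archetype's
    k_on response, runs the full inference chain and the shape
    classifier, and reports the fraction of runs recovering the
    generative archetype.
    """
    archetypes = ("transient", "pulsatile", "sustained")
    subs = _sub_seeds(seed, len(archetypes) * n_seeds)
    i = 0
    correct, results = 0, []
    for arch in archetypes:
        params = TelegraphParams(archetype=arch, **ARCHETYPE_PARAMS)
        for _ in range(n_seeds):
            design = ExperimentDesign(treatment="IR_pulsatile",
                                      n_cells_per_timepoint=n_cells, seed=subs[i])
            i += 1
            sample = sample_population(ARCHETYPE_GENE, params, design)
            ests = infer_burst_parameters(sample.spots, sample.cells,
                                          ARCHETYPE_GENE, design)
            tc = classify_archetype(assemble_timecourse(ests))
            results.append({"truth": arch, "call": tc.archetype_call,
                            "f_series": list(tc.f_series)})
            correct += tc.archetype_call == arch
    n_runs = len(results)
    return {"accuracy": correct / n_runs, "n_runs": n_runs,
            "n_cells": n_cells, "results": results}
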