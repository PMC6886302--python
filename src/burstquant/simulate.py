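"""Stochastic simulation of bursty transcription driven by p53 dynamics.

The generative model is a random-telegraph promoter per genomic locus:
the promoter switches off->on at rate ``k_on(t)`` (modulated by nuclear
p53) and on->off at rate ``k_off``; while on, transcripts initiate at rate
``r``.  Each nascent transcript elongates deterministically at speed ``v``
and becomes a mature nuclear RNA on reaching the transcript end; mature
RNA is exported to the cytoplasm at rate ``k_exp`` and degraded with
first-order rate ``d_RNA``.  Degradation applies to the whole mature pool
(nuclear and cytoplasmic), so the total mature copy number follows the
standard telegraph birth-death process and the closed-form moments in
:func:`steady_state_moments` are exact.

Simulation is exact: promoter trajectories are sampled interval-by-interval
(with thinning against the running maximum for the inhomogeneous off->on
rate), initiation events are Poisson within on-intervals, and each
transcript's maturation/export/degradation fate is drawn independently.
This is statistically equivalent to a Gillespie simulation of the same
reaction network but samples a snapshot population in vectorised form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core_model import ExperimentDesign, GeneModel, probe_fraction_completed

ARCHETYPES = ("transient", "pulsatile", "sustained")
PROFILE_MODES = ("pulsatile", "transient", "sustained")

#: width (h) of the Gaussian p53 pulses centred at 3 h and 9 h
_PULSE_SIGMA_H = 1.1
#: treatment label -> p53 profile mode (None = no induction)
TREATMENT_PROFILE = {
    "untreated": None,
    "IR_pulsatile": "pulsatile",
    "IR_chk2i_transient": "transient",
    "IR_nutlin_sustained": "sustained",
}


@dataclass(frozen=True)
class TelegraphParams:
    """Kinetic parameters of the two-state promoter model (rates per hour)."""

    k_on_basal: float = 0.5
    k_off: float = 1.5
    init_rate: float = 160.0
    deg_rate: float = 0.5
    export_rate: float = 3.0
    archetype: str = "pulsatile"
    #: fold-increase of k_on at full p53 occupancy (frequency modulation)
    kon_fold_induced: float = 6.0
    #: relaxation time (h) of the transient archetype's desensitisation
    relax_time_h: float = 2.0

    def __post_init__(self) -> None:
        for name in ("k_on_basal", "k_off", "init_rate", "deg_rate", "export_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.kon_fold_induced < 1:
            raise ValueError("kon_fold_induced must be >= 1")
        if self.relax_time_h <= 0:
            raise ValueError("relax_time_h must be positive")

    @property
    def p_on_basal(self) -> float:
        """Stationary probability of the active state under basal k_on."""
        if self.k_off == 0:
            return 1.0
        return self.k_on_basal / (self.k_on_basal + self.k_off)


@dataclass(frozen=True)
class DynamicsProfile:
    """Sampled nuclear-p53 time course, normalised to first-peak = 1."""

    times_h: tuple[float, ...]
    p53_level: tuple[float, ...]
    mode: str

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.p53_level):
            raise ValueError("times_h and p53_level must have the same length")
        if any(v < 0 for v in self.p53_level):
            raise ValueError("p53 levels must be non-negative")


@dataclass(frozen=True)
class NoiseConfig:
    """Optical/measurement noise of the emulated smFISH readout.

    ``mInt`` is the median single-mRNA spot intensity (arbitrary units);
    mature spot intensities are LogNormal with this median and the given
    coefficient of variation, and TSS intensities carry additive Gaussian
    noise proportional to signal, floored at zero.
    """

    mInt: float = 1.0
    spot_intensity_cv: float = 0.25
    tss_noise_frac: float = 0.10


@dataclass
class CellSnapshot:
    """Generative truth for one allele (or cell) at the observation time."""

    promoter_on: bool
    nascent_positions_nt: np.ndarray
    nuclear_count: int
    cytoplasmic_count: int


@dataclass
class PopulationSample:
    """Spot/cell tables plus the hidden generative truth table."""

    spots: pd.DataFrame
    cells: pd.DataFrame
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# p53 dynamics and k_on modulation


def _raw_drive(mode: str, t: np.ndarray) -> np.ndarray:
    """Unnormalised p53 drive; zero before damage at t = 0."""
    t = np.asarray(t, dtype=float)
    s2 = 2.0 * _PULSE_SIGMA_H**2
    if mode == "pulsatile":
        out = np.exp(-((t - 3.0) ** 2) / s2) + np.exp(-((t - 9.0) ** 2) / s2)
    elif mode == "transient":
        out = np.exp(-((t - 3.0) ** 2) / s2)
    elif mode == "sustained":
        out = np.clip(t / 3.0, 0.0, 1.0)
    else:
        raise ValueError(f"unknown p53 profile mode {mode!r}")
    return np.where(t <= 0.0, 0.0, out)


def _drive_norm(mode: str) -> float:
    grid = np.linspace(0.0, 4.0, 2001)
    return float(_raw_drive(mode, grid).max())


def p53_profile(mode: str, times_h: Sequence[float]) -> DynamicsProfile:
    """Nuclear p53 level over time for one treatment regime.

    ``pulsatile`` gives undamped pulses peaking at 3 h and 9 h with a
    trough at 6 h (ionising radiation); ``transient`` a single pulse at
    3 h decaying back to basal (Chk2 inhibition after IR); ``sustained``
    a rise complete by 3 h followed by a plateau at peak level (Nutlin-3).
    Levels are normalised so the maximum over the first 4 h equals 1.
    """
    times = np.asarray(list(times_h), dtype=float)
    if times.size and (times.min() < 0.0 or times.max() > 12.0):
        raise ValueError("profile times must lie within [0, 12] h")
    levels = _raw_drive(mode, times) / _drive_norm(mode)
    return DynamicsProfile(tuple(times.tolist()), tuple(levels.tolist()), mode)


class KonFunction:
    """Time-varying off->on switching rate with a known upper bound.

    Callable on scalar or array times; ``max_rate`` bounds the rate over
    all times and is used for exact thinning in the simulator.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], max_rate: float):
        self._fn = fn
        self.max_rate = float(max_rate)

    def __call__(self, t) -> np.ndarray:
        return self._fn(np.asarray(t, dtype=float))


def constant_kon(rate: float) -> KonFunction:
    """A constant off->on rate wrapped in the simulator's rate interface."""
    return KonFunction(lambda t: np.full_like(np.asarray(t, dtype=float), rate), rate)


def kon_modulation(params: TelegraphParams, profile: DynamicsProfile | None) -> KonFunction:
    """Build k_on(t) from the p53 profile and the gene's response archetype.

    Frequency modulation: ``k_on(t) = k_on_basal * (1 + (F - 1) * u(t))``
    where ``F`` is the induced fold-change and ``u(t)`` in [0, 1] is the
    archetype response to the normalised p53 drive:

    - ``pulsatile``  - tracks p53(t) directly;
    - ``sustained``  - latches to the running maximum of p53(t);
    - ``transient``  - tracks the first pulse, then a desensitisation
      envelope ``exp(-(t - 3)/tau)`` suppresses any later response, so the
      second p53 peak does not re-activate the promoter.
    """
    basal = params.k_on_basal
    if profile is None:
        return constant_kon(basal)
    mode = profile.mode
    norm = _drive_norm(mode)
    amp = basal * (params.kon_fold_induced - 1.0)

    def drive(t: np.ndarray) -> np.ndarray:
        return _raw_drive(mode, t) / norm

    if params.archetype == "pulsatile":
        response = drive
    elif params.archetype == "sustained":
        latch_grid = np.linspace(0.0, 12.5, 2501)
        latched = np.maximum.accumulate(drive(latch_grid))

        def response(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            return np.where(t <= 0.0, 0.0, np.interp(t, latch_grid, latched))
    else:  # transient
        tau = params.relax_time_h

        def response(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            env = np.where(t > 3.0, np.exp(-(t - 3.0) / tau), 1.0)
            return drive(t) * env

    grid = np.linspace(-1.0, 12.5, 2701)
    max_rate = basal + amp * float(np.max(response(grid))) * (1.0 + 1e-9)

    def kon(t: np.ndarray) -> np.ndarray:
        return basal + amp * response(t)

    return KonFunction(kon, max_rate)


def p_on_trajectory(params: TelegraphParams, kon: KonFunction,
                    t_start: float, t_eval: Sequence[float]) -> np.ndarray:
    """Analytic P(on at t) from the two-state master equation.

    Integrates ``dp/dt = k_on(t) (1 - p) - k_off p`` starting from the
    basal stationary occupancy at ``t_start``; used to fill the truth
    table against which inferred promoter-activity fractions are scored.
    """
    t_eval = np.asarray(t_eval, dtype=float)

    def rhs(t, p):
        return float(kon(t)) * (1.0 - p) - params.k_off * p

    sol = solve_ivp(rhs, (t_start, float(t_eval.max())), [params.p_on_basal],
                    t_eval=t_eval, rtol=1e-8, atol=1e-10, max_step=0.05)
    return sol.y[0]


# ---------------------------------------------------------------------------
# exact allele simulation


def _promoter_intervals(params: TelegraphParams, kon: KonFunction,
                        t_start: float, t_end: float, n_alleles: int,
                        rng: np.random.Generator, initial_state: str):
    """Sample promoter trajectories for all alleles; return on-intervals.

    Off->on waiting times under the inhomogeneous rate are sampled by
    thinning against ``kon.max_rate`` (proposals at the bound rate,
    accepted with probability k_on(t)/max_rate), which is exact.
    """
    k_off, k_max = params.k_off, kon.max_rate
    t = np.full(n_alleles, t_start, dtype=float)
    if initial_state == "stationary":
        state = rng.random(n_alleles) < params.p_on_basal
    elif initial_state == "on":
        state = np.ones(n_alleles, dtype=bool)
    elif initial_state == "off":
        state = np.zeros(n_alleles, dtype=bool)
    else:
        raise ValueError(f"unknown initial_state {initial_state!r}")
    on_since = np.where(state, t_start, np.nan)
    active = t < t_end
    starts, ends, owners = [], [], []

    while np.any(active):
        on_idx = np.flatnonzero(active & state)
        off_idx = np.flatnonzero(active & ~state)
        if on_idx.size:
            if k_off > 0:
                dt = rng.exponential(1.0 / k_off, on_idx.size)
            else:
                dt = np.full(on_idx.size, np.inf)
            t_new = t[on_idx] + dt
            finished = t_new >= t_end
            fin = on_idx[finished]
            starts.append(on_since[fin]); ends.append(np.full(fin.size, t_end)); owners.append(fin)
            t[fin] = t_end
            active[fin] = False
            sw = on_idx[~finished]
            starts.append(on_since[sw]); ends.append(t_new[~finished]); owners.append(sw)
            t[sw] = t_new[~finished]
            state[sw] = False
            on_since[sw] = np.nan
        if off_idx.size:
            if k_max > 0:
                dt = rng.exponential(1.0 / k_max, off_idx.size)
            else:
                dt = np.full(off_idx.size, np.inf)
            t_new = t[off_idx] + dt
            finished = t_new >= t_end
            fin = off_idx[finished]
            t[fin] = t_end
            active[fin] = False
            cand = off_idx[~finished]
            t_cand = t_new[~finished]
            if cand.size:
                accept = rng.random(cand.size) * k_max < kon(t_cand)
                t[cand] = t_cand
                turn_on = cand[accept]
                state[turn_on] = True
                on_since[turn_on] = t_cand[accept]

    if starts:
        return (np.concatenate(starts), np.concatenate(ends),
                np.concatenate(owners), state)
    return (np.empty(0), np.empty(0), np.empty(0, dtype=int), state)


def _simulate_population(gene: GeneModel, params: TelegraphParams, kon: KonFunction,
                         t_start: float, t_end: float, n_alleles: int,
                         rng: np.random.Generator, initial_state: str = "stationary"):
    """Exact snapshot of ``n_alleles`` independent alleles at ``t_end``.

    Returns per-allele promoter state and counts plus the flat arrays of
    nascent polymerase positions with their owning allele index.
    """
    v = gene.elongation_speed_nt_per_h
    dwell = gene.dwell_time_h
    starts, ends, owners, state = _promoter_intervals(
        params, kon, t_start, t_end, n_alleles, rng, initial_state)

    durations = ends - starts
    n_init = rng.poisson(params.init_rate * durations) if durations.size else np.empty(0, int)
    allele = np.repeat(owners, n_init).astype(int)
    t_init = (np.repeat(starts, n_init)
              + rng.random(allele.size) * np.repeat(durations, n_init))

    t_complete = t_init + dwell
    is_nascent = t_complete > t_end
    nascent_allele = allele[is_nascent]
    nascent_pos = (t_end - t_init[is_nascent]) * v

    mat_allele = allele[~is_nascent]
    mat_done = t_complete[~is_nascent]
    n_mat = mat_allele.size
    if params.deg_rate > 0:
        death = mat_done + rng.exponential(1.0 / params.deg_rate, n_mat)
    else:
        death = np.full(n_mat, np.inf)
    if params.export_rate > 0:
        export = mat_done + rng.exponential(1.0 / params.export_rate, n_mat)
    else:
        export = np.full(n_mat, np.inf)
    alive = death > t_end
    nuclear = alive & (export > t_end)
    cyto = alive & ~nuclear
    nuc_count = np.bincount(mat_allele[nuclear], minlength=n_alleles)
    cyt_count = np.bincount(mat_allele[cyto], minlength=n_alleles)

    return {
        "promoter_on": state,
        "nascent_allele": nascent_allele,
        "nascent_pos": nascent_pos,
        "nuc_count": nuc_count,
        "cyt_count": cyt_count,
    }


def simulate_allele(gene: GeneModel, params: TelegraphParams,
                    k_on_t: KonFunction | float, t_end: float, seed: int,
                    t_start: float = 0.0, initial_state: str = "stationary") -> CellSnapshot:
    """Exact stochastic simulation of a single allele up to ``t_end``.

    Identical (gene, params, rate function, seed) give an identical
    snapshot.  ``initial_state`` is 'stationary' (basal promoter
    occupancy), 'on' or 'off'; the RNA pools always start empty, so
    callers wanting a stationary molecule content should set ``t_start``
    several RNA lifetimes before ``t_end``.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if isinstance(k_on_t, (int, float)):
        if not np.isfinite(k_on_t):
            raise ValueError("k_on must be finite")
        k_on_t = constant_kon(float(k_on_t))
    rng = np.random.default_rng(seed)
    res = _simulate_population(gene, params, k_on_t, t_start, t_end, 1, rng, initial_state)
    return CellSnapshot(
        promoter_on=bool(res["promoter_on"][0]),
        nascent_positions_nt=np.sort(res["nascent_pos"]),
        nuclear_count=int(res["nuc_count"][0]),
        cytoplasmic_count=int(res["cyt_count"][0]),
    )


# ---------------------------------------------------------------------------
# closed-form moments and an independent Gillespie oracle


def steady_state_moments(params: TelegraphParams, n_alleles: int = 1):
    """Closed-form stationary mean/variance/Fano of the total mature count.

    For the telegraph model with constant rates,

        mean = n * k_on/(k_on + k_off) * r / d
        Fano = 1 + r * k_off / ((k_on + k_off) * (k_on + k_off + d))

    with ``Fano = 1`` (Poisson) for a constitutive promoter (k_off = 0).
    Alleles are independent, so means and variances add and the Fano
    factor is allele-number invariant.
    """
    if params.deg_rate <= 0:
        raise ValueError("no stationary distribution without degradation (deg_rate > 0)")
    k_on, k_off, r, d = params.k_on_basal, params.k_off, params.init_rate, params.deg_rate
    p_on = params.p_on_basal
    mean = n_alleles * p_on * r / d
    if k_off == 0:
        fano = 1.0
    else:
        ks = k_on + k_off
        fano = 1.0 + r * k_off / (ks * (ks + d))
    return {"mean": mean, "variance": fano * mean, "fano": fano}


def gillespie_telegraph(params: TelegraphParams, n_cells: int, t_end: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Direct stochastic simulation (SSA) of the basic telegraph model.

    Tracks only (promoter state, mature count) with constant basal rates;
    serves as an independent cross-check of both the closed-form moments
    and the interval-based population simulator.  Returns the mature
    count per cell at ``t_end``.
    """
    k_on, k_off, r, d = params.k_on_basal, params.k_off, params.init_rate, params.deg_rate
    t = np.zeros(n_cells)
    s = rng.random(n_cells) < params.p_on_basal
    x = np.zeros(n_cells, dtype=np.int64)
    active = np.ones(n_cells, dtype=bool)
    while np.any(active):
        idx = np.flatnonzero(active)
        r_sw = np.where(s[idx], k_off, k_on)
        r_b = np.where(s[idx], r, 0.0)
        r_d = x[idx] * d
        tot = r_sw + r_b + r_d
        stuck = tot <= 0
        active[idx[stuck]] = False
        idx = idx[~stuck]
        if idx.size == 0:
            break
        tot = tot[~stuck]
        dt = rng.exponential(1.0, idx.size) / tot
        t[idx] += dt
        done = t[idx] >= t_end
        active[idx[done]] = False
        idx = idx[~done]
        if idx.size == 0:
            continue
        u = rng.random(idx.size) * tot[~done]
        # state has not changed yet, so recomputing the rates is exact
        r_sw = np.where(s[idx], k_off, k_on)
        r_b = np.where(s[idx], r, 0.0)
        ev_switch = u < r_sw
        ev_birth = ~ev_switch & (u < r_sw + r_b)
        ev_death = ~ev_switch & ~ev_birth
        s[idx[ev_switch]] = ~s[idx[ev_switch]]
        x[idx[ev_birth]] += 1
        x[idx[ev_death]] -= 1
    return x


# ---------------------------------------------------------------------------
# population sampling into spot tables


def _burn_in_h(gene: GeneModel, params: TelegraphParams) -> float:
    """Pre-observation window long enough to reach molecular stationarity."""
    parts = [10.0 * gene.dwell_time_h]
    if params.deg_rate > 0:
        parts.append(9.0 / params.deg_rate)
    ks = params.k_on_basal + params.k_off
    if ks > 0:
        parts.append(6.0 / ks)
    return max(parts)


def sample_population(gene: GeneModel, params: TelegraphParams,
                      design: ExperimentDesign,
                      noise_cfg: NoiseConfig | None = None) -> PopulationSample:
    """Simulate independent cell populations per time point and emit tables.

    Each time point is an independently fixed population (as in the
    experiment); every cell carries ``gene.n_loci`` independent alleles
    started from the basal stationary state well before damage at t = 0.
    Mature RNAs become individual spot records with LogNormal intensities;
    each allele holding at least one nascent transcript emits a candidate
    TSS record whose exon intensity is ``kappa * mInt * sum_j phi_j``
    (``phi_j`` the fraction of exon probes completed by nascent ``j``)
    plus proportional Gaussian noise, with an intron mark iff some
    polymerase has passed the first intron-probe position.
    """
    if design.n_cells_per_timepoint < 1:
        raise ValueError("need at least one cell per time point")
    noise_cfg = noise_cfg or NoiseConfig()
    profile_mode = TREATMENT_PROFILE[design.treatment]
    profile = (p53_profile(profile_mode, design.timepoints_h)
               if profile_mode is not None else None)
    kon = kon_modulation(params, profile)
    burn = _burn_in_h(gene, params)
    n_cells = design.n_cells_per_timepoint
    n_alleles = n_cells * gene.n_loci
    sigma_ln = float(np.sqrt(np.log1p(noise_cfg.spot_intensity_cv**2)))
    first_intron = (min(gene.intron_probe_positions_nt)
                    if gene.intron_probe_positions_nt else 0.0)

    children = np.random.SeedSequence(design.seed).spawn(len(design.timepoints_h))
    spot_frames, cell_rows, truth_rows = [], [], []

    for tp_idx, (tp, child) in enumerate(zip(design.timepoints_h, children)):
        rng = np.random.default_rng(child)
        t_start = tp - burn
        sim = _simulate_population(gene, params, kon, t_start, tp, n_alleles, rng)
        p_on_t = float(p_on_trajectory(params, kon, t_start, [tp])[0])

        cell_of_allele = np.arange(n_alleles) // gene.n_loci
        cell_ids = np.array(
            [f"{design.treatment}_t{tp:g}_c{i:04d}" for i in range(n_cells)])

        # mature RNA spot records, one row per molecule
        nuc_cells = np.repeat(cell_of_allele, sim["nuc_count"])
        cyt_cells = np.repeat(cell_of_allele, sim["cyt_count"])
        mat_cells = np.concatenate([nuc_cells, cyt_cells])
        mat_comp = np.concatenate([np.repeat("nuc", nuc_cells.size),
                                   np.repeat("cyt", cyt_cells.size)])
        mat_int = noise_cfg.mInt * np.exp(rng.normal(0.0, sigma_ln, mat_cells.size))

        # candidate TSS records, one row per allele with nascent transcripts
        phi = probe_fraction_completed(gene, sim["nascent_pos"])
        sum_phi = np.bincount(sim["nascent_allele"], weights=phi, minlength=n_alleles)
        nasc_n = np.bincount(sim["nascent_allele"], minlength=n_alleles)
        has_nascent = nasc_n > 0
        tss_alleles = np.flatnonzero(has_nascent)
        signal = gene.kappa * noise_cfg.mInt * sum_phi[tss_alleles]
        tss_int = np.clip(
            signal + rng.normal(0.0, 1.0, signal.size) * noise_cfg.tss_noise_frac * signal,
            0.0, None)
        passed = np.bincount(
            sim["nascent_allele"][sim["nascent_pos"] >= first_intron],
            minlength=n_alleles)
        intron_mark = passed[tss_alleles] > 0

        frame = pd.DataFrame({
            "gene": gene.name,
            "cell_id": np.concatenate([cell_ids[mat_cells], cell_ids[cell_of_allele[tss_alleles]]]),
            "timepoint_h": tp,
            "treatment": design.treatment,
            "spot_type": np.concatenate([np.repeat("mRNA", mat_cells.size),
                                         np.repeat("TSS", tss_alleles.size)]),
            "compartment": np.concatenate([mat_comp, np.repeat("nuc", tss_alleles.size)]),
            "intensity": np.concatenate([mat_int, tss_int]),
            "allele_id": np.concatenate([np.full(mat_cells.size, -1),
                                         tss_alleles % gene.n_loci]),
            "has_intron": np.concatenate([np.zeros(mat_cells.size, dtype=int),
                                          intron_mark.astype(int)]),
        })
        spot_frames.append(frame)

        nuc_per_cell = np.bincount(cell_of_allele, weights=sim["nuc_count"],
                                   minlength=n_cells).astype(int)
        cyt_per_cell = np.bincount(cell_of_allele, weights=sim["cyt_count"],
                                   minlength=n_cells).astype(int)
        on_per_cell = np.bincount(cell_of_allele, weights=sim["promoter_on"],
                                  minlength=n_cells).astype(int)
        nasc_per_cell = np.bincount(cell_of_allele, weights=nasc_n,
                                    minlength=n_cells).astype(int)
        cell_rows.append(pd.DataFrame({
            "gene": gene.name,
            "cell_id": cell_ids, "timepoint_h": tp, "treatment": design.treatment,
            "n_loci": gene.n_loci,
        }))
        truth_rows.append(pd.DataFrame({
            "gene": gene.name,
            "cell_id": cell_ids, "timepoint_h": tp,
            "f_true": p_on_t,
            "n_alleles_on": on_per_cell,
            "nascent_total": nasc_per_cell,
            "nuc_count": nuc_per_cell, "cyt_count": cyt_per_cell,
            "k_on_basal": params.k_on_basal, "k_off": params.k_off,
            "init_rate": params.init_rate, "deg_rate": params.deg_rate,
            "export_rate": params.export_rate,
        }))

    return PopulationSample(
        spots=pd.concat(spot_frames, ignore_index=True),
        cells=pd.concat(cell_rows, ignore_index=True),
        truth=pd.concat(truth_rows, ignore_index=True),
    )
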