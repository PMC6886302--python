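"""Burst-parameter inference from smFISH spot tables.

Implements the spot-table quantification of stochastic transcription:
transcription sites (TSS) are called from intron/exon co-localised nuclear
signals; the fraction of active promoters ``f = #TSS / n`` proxies burst
frequency; the RNAP2 occupancy of a site is
``M = Int_TSS / (kappa * eta * mInt_mRNA)`` with ``mInt_mRNA`` the median
single-mRNA spot intensity, ``kappa`` the fixed occupancy correction and
``eta`` the probe-position correction; the per-site transcription rate
``mu = M * v / l`` proxies burst size; and the degradation rate closes the
steady-state balance ``X_RNA = n * f * mu / d_RNA`` over actively
transcribing cells, giving half-lives ``t_1/2 = ln 2 / d_RNA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import ExperimentDesign, GeneModel

logger = logging.getLogger(__name__)

#: per-cell activity above this fraction of loci counts as "strongly active"
STRONG_ACTIVITY_FRACTION = 0.75
#: default TSS floor, in units of the median single-mRNA intensity
DEFAULT_FLOOR_MINT_FRACTION = 0.5
#: below this many cytoplasmic spots the median falls back to all mature spots
MIN_CYT_SPOTS_FOR_MEDIAN = 50


@dataclass(frozen=True)
class TssRecord:
    """One called transcription site."""

    cell_id: str
    timepoint_h: float
    intensity: float
    has_intron_mark: bool = True


@dataclass
class BurstEstimate:
    """Inferred bursting parameters for one gene at one time point."""

    gene: str
    timepoint_h: float
    f: float
    frac_strong: float
    frac_weak: float
    M_values: np.ndarray
    mu_values: np.ndarray
    mu_sum_values: np.ndarray
    mInt_mRNA: float
    mean_active_rna: float
    d_RNA: float
    t_half_h: float
    n_cells: int
    n_tss: int
    treatment: str = ""

    @property
    def median_M(self) -> float:
        return float(np.median(self.M_values)) if self.M_values.size else np.nan

    @property
    def median_mu(self) -> float:
        return float(np.median(self.mu_values)) if self.mu_values.size else np.nan

    @property
    def mean_mu(self) -> float:
        return float(np.mean(self.mu_values)) if self.mu_values.size else np.nan


def median_mrna_intensity(spots: pd.DataFrame) -> float:
    """Median fluorescence intensity of a single mature mRNA spot.

    Uses cytoplasmic spots; if fewer than ``MIN_CYT_SPOTS_FOR_MEDIAN`` are
    available the median falls back to all mature spots with a warning.
    """
    mature = spots[spots["spot_type"] == "mRNA"]
    cyt = mature[mature["compartment"] == "cyt"]
    if len(cyt) >= MIN_CYT_SPOTS_FOR_MEDIAN:
        return float(cyt["intensity"].median())
    if len(mature) == 0:
        raise ValueError("no mature mRNA spots to calibrate intensity against")
    logger.warning("only %d cytoplasmic spots; using all %d mature spots for mInt",
                   len(cyt), len(mature))
    return float(mature["intensity"].median())


def call_tss(spot_table: pd.DataFrame, gene: GeneModel,
             intensity_floor: float) -> pd.DataFrame:
    """Call transcription sites from candidate TSS spot records.

    A site is called iff it is nuclear, carries the intron co-localisation
    mark and its summed exon intensity reaches ``intensity_floor``.  Cells
    reporting more called sites than the gene has genomic loci are capped
    at ``n_loci`` by keeping the brightest candidates (dimmer extras are
    the most likely false detections); each cap is logged.
    """
    cand = spot_table[(spot_table["spot_type"] == "TSS")
                      & (spot_table["compartment"] == "nuc")]
    called = cand[(cand["has_intron"] > 0) & (cand["intensity"] >= intensity_floor)]
    if len(called) == 0:
        return called.copy()
    capped = (called.sort_values("intensity", ascending=False)
              .groupby("cell_id", sort=False).head(gene.n_loci))
    n_dropped = len(called) - len(capped)
    if n_dropped:
        logger.warning("%s: dropped %d TSS candidates exceeding n_loci=%d "
                       "(kept the brightest per cell)", gene.name, n_dropped, gene.n_loci)
    return capped.sort_index()


def fraction_active(tss_per_cell: np.ndarray, n_loci: int):
    """Population promoter activity and strong/weak cell fractions.

    ``f`` is the ratio of all called TSS to all genomic loci analysed,
    ``f = sum(#TSS) / (n_cells * n_loci)``.  Cells are binned by their own
    activity: strongly active when at least 75% of their loci fire,
    weakly active when some but fewer than 75% fire.
    """
    counts = np.asarray(tss_per_cell, dtype=int)
    if counts.size == 0:
        raise ValueError("no cells")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if counts.min() < 0 or counts.max() > n_loci:
        raise ValueError("per-cell TSS counts must lie in [0, n_loci]")
    f = counts.sum() / (counts.size * n_loci)
    activity = counts / n_loci
    frac_strong = float(np.mean(activity >= STRONG_ACTIVITY_FRACTION))
    frac_weak = float(np.mean((activity > 0) & (activity < STRONG_ACTIVITY_FRACTION)))
    return float(f), frac_strong, frac_weak


def rnap2_occupancy(Int_TSS, mInt_mRNA: float, kappa: float, eta: float):
    """RNAP2 occupancy ``M = Int_TSS / (kappa * eta * mInt_mRNA)``.

    The summed nascent exon signal at a site, expressed in median
    single-mRNA equivalents and corrected for probe position (eta) and
    polymerase occupancy (kappa), counts the engaged polymerases.
    """
    if mInt_mRNA <= 0:
        raise ValueError(f"mInt_mRNA must be positive, got {mInt_mRNA}")
    if eta <= 0 or kappa <= 0:
        raise ValueError(f"kappa ({kappa}) and eta ({eta}) must be positive; "
                         "check the probe layout (all probes at the 3' end give eta = 0)")
    return np.asarray(Int_TSS, dtype=float) / (kappa * eta * mInt_mRNA)


def transcription_rate(M, gene: GeneModel):
    """Per-site transcription rate ``mu = M * v / l`` in RNA/h.

    With occupancy ``M`` polymerases on a gene of length ``l`` traversed
    at speed ``v``, sites complete ``M * v / l`` transcripts per hour.
    The same formula applies cell-wise to the summed occupancy ``M_sum``.
    """
    if gene.length_nt <= 0:
        raise ValueError("gene length must be positive")
    return np.asarray(M, dtype=float) * gene.elongation_speed_nt_per_h / gene.length_nt


def degradation_rate(mean_total_RNA: float, n_loci: int, f: float, mean_mu: float):
    """Degradation rate from the steady-state balance, plus the half-life.

    Solves ``X_RNA = n * f * mu / d_RNA`` for ``d_RNA`` using the mean RNA
    count over actively transcribing cells, and returns
    ``(d_RNA, t_1/2 = ln 2 / d_RNA)``.
    """
    if f <= 0 or mean_mu <= 0:
        raise ValueError("no active transcription: f and mean_mu must be positive")
    if mean_total_RNA <= 0:
        raise ValueError("no active transcription: mean RNA count must be positive")
    d = n_loci * f * mean_mu / mean_total_RNA
    return float(d), float(np.log(2.0) / d)


def infer_burst_parameters(spots: pd.DataFrame, cells: pd.DataFrame, gene: GeneModel,
                           design: ExperimentDesign | None = None,
                           floor_mint_fraction: float = DEFAULT_FLOOR_MINT_FRACTION,
                           rna_pool: str = "total") -> list[BurstEstimate]:
    """Full inference chain, one :class:`BurstEstimate` per time point.

    Per time point: calibrate ``mInt_mRNA``, call TSS above the intensity
    floor, compute ``f`` and the strong/weak binning, per-site occupancies
    and rates, cell-wise summed rates, and close the steady-state balance
    for ``d_RNA`` over cells with at least one active site.  ``rna_pool``
    selects whether that balance uses total or cytoplasmic RNA counts.
    Time points with no cells are recorded as missing (skipped), never
    fabricated.
    """
    if rna_pool not in ("total", "cytoplasmic"):
        raise ValueError("rna_pool must be 'total' or 'cytoplasmic'")
    eta = gene.eta
    timepoints = (design.timepoints_h if design is not None
                  else tuple(sorted(cells["timepoint_h"].unique())))
    estimates: list[BurstEstimate] = []
    for tp in timepoints:
        cells_tp = cells[cells["timepoint_h"] == tp]
        if len(cells_tp) == 0:
            logger.warning("%s: no cells at t = %g h; time point recorded as missing",
                           gene.name, tp)
            continue
        spots_tp = spots[spots["timepoint_h"] == tp]
        treatment = str(cells_tp["treatment"].iloc[0]) if "treatment" in cells_tp else ""
        mInt = median_mrna_intensity(spots_tp)
        tss = call_tss(spots_tp, gene, intensity_floor=floor_mint_fraction * mInt)

        counts = (tss.groupby("cell_id").size()
                  .reindex(cells_tp["cell_id"], fill_value=0).to_numpy())
        f, frac_strong, frac_weak = fraction_active(counts, gene.n_loci)

        M = rnap2_occupancy(tss["intensity"].to_numpy(), mInt, gene.kappa, eta)
        mu = transcription_rate(M, gene)
        tss_with_m = tss.assign(M=M)
        M_sum = tss_with_m.groupby("cell_id")["M"].sum()
        mu_sum = transcription_rate(M_sum.to_numpy(), gene)

        active_ids = set(tss["cell_id"])
        mature = spots_tp[spots_tp["spot_type"] == "mRNA"]
        if rna_pool == "cytoplasmic":
            mature = mature[mature["compartment"] == "cyt"]
        rna_per_cell = (mature.groupby("cell_id").size()
                        .reindex(cells_tp["cell_id"], fill_value=0))
        active_mask = rna_per_cell.index.isin(active_ids)
        mean_active_rna = float(rna_per_cell[active_mask].mean()) if active_mask.any() else np.nan

        if f > 0 and mu.size and mean_active_rna > 0:
            d_RNA, t_half = degradation_rate(mean_active_rna, gene.n_loci, f,
                                             float(np.mean(mu)))
        else:
            d_RNA, t_half = np.nan, np.nan

        estimates.append(BurstEstimate(
            gene=gene.name, timepoint_h=float(tp), f=f,
            frac_strong=frac_strong, frac_weak=frac_weak,
            M_values=M, mu_values=mu, mu_sum_values=mu_sum,
            mInt_mRNA=mInt, mean_active_rna=mean_active_rna,
            d_RNA=d_RNA, t_half_h=t_half,
            n_cells=len(cells_tp), n_tss=int(len(tss)), treatment=treatment,
        ))
    return estimates


def estimates_frame(estimates: list[BurstEstimate]) -> pd.DataFrame:
    """Summarise estimates as one row per gene x time point."""
    rows = []
    for e in estimates:
        rows.append({
            "gene": e.gene, "treatment": e.treatment, "timepoint_h": e.timepoint_h,
            "f": e.f, "frac_strong": e.frac_strong, "frac_weak": e.frac_weak,
            "median_M": e.median_M, "median_mu": e.median_mu, "mean_mu": e.mean_mu,
            "mInt_mRNA": e.mInt_mRNA, "mean_active_rna": e.mean_active_rna,
            "d_RNA": e.d_RNA, "t_half_h": e.t_half_h,
            "n_cells": e.n_cells, "n_tss": e.n_tss,
        })
    return pd.DataFrame(rows)


def distributions_frame(estimates: list[BurstEstimate]) -> pd.DataFrame:
    """Per-TSS occupancy/rate distributions as a long table."""
    frames = []
    for e in estimates:
        frames.append(pd.DataFrame({
            "gene": e.gene, "timepoint_h": e.timepoint_h,
            "M": e.M_values, "mu": e.mu_values,
        }))
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["gene", "timepoint_h", "M", "mu"]))
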