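"""Expression-noise statistics and noise-scaling analysis.

Dispersion of per-cell RNA counts is summarised as total noise
``CV^2 = sigma^2 / mu^2`` and noise strength (Fano factor)
``sigma^2 / mu``; a Poisson (constitutive) promoter has Fano = 1, while
bursty transcription gives Fano >> 1.  When the burst frequency (k_on) is
the regulated quantity at fixed burst size ``b``, the population moves
along the hyperbola ``CV^2 = b / <mRNA>``, i.e. a slope of -1 in log-log
coordinates of CV^2 against the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class NoiseSummary:
    """Dispersion summary of one count population.

    ``cv2``/``fano`` are NaN (flagged via :attr:`defined`) for mean-zero
    populations rather than infinities, so downstream report code can
    skip them.
    """

    mean: float
    variance: float
    cv2: float
    fano: float
    n: int
    compartment: str = "total"

    @property
    def defined(self) -> bool:
        return np.isfinite(self.cv2)


def noise_summary(counts, compartment: str = "total") -> NoiseSummary:
    """Mean, unbiased variance, CV^2 and Fano factor of RNA counts."""
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two cells to estimate dispersion")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if mean > 0:
        cv2, fano = var / mean**2, var / mean
    else:
        cv2, fano = np.nan, np.nan
    return NoiseSummary(mean=mean, variance=var, cv2=cv2, fano=fano,
                        n=int(x.size), compartment=compartment)


def counts_per_cell(spots: pd.DataFrame, cells: pd.DataFrame,
                    compartment: str | None = None) -> pd.Series:
    """Mature-RNA count per cell, including zero-count cells.

    ``compartment`` restricts to 'nuc' or 'cyt'; None counts all mature
    spots.  Cells present in the cell table but without spots count 0.
    """
    mature = spots[spots["spot_type"] == "mRNA"]
    if compartment is not None:
        if "compartment" not in mature.columns:
            raise ValueError("spot table has no compartment labels")
        mature = mature[mature["compartment"] == compartment]
    return mature.groupby("cell_id").size().reindex(cells["cell_id"], fill_value=0)


def compartment_noise(spots: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point noise summaries for nuclear/cytoplasmic/total counts.

    Also reports the nuclear-to-cytoplasmic mean-count ratio per time
    point (NaN-flagged when the cytoplasmic mean is zero); under
    first-order export the stationary ratio is ``d_RNA / k_export`` and
    stays stable across time points.
    """
    if "compartment" not in spots.columns:
        raise ValueError("spot table has no compartment labels")
    rows = []
    for tp in sorted(cells["timepoint_h"].unique()):
        cells_tp = cells[cells["timepoint_h"] == tp]
        spots_tp = spots[spots["timepoint_h"] == tp]
        by_comp = {}
        for comp, label in ((None, "total"), ("nuc", "nuclear"), ("cyt", "cytoplasmic")):
            s = noise_summary(counts_per_cell(spots_tp, cells_tp, comp), label)
            by_comp[label] = s
            rows.append({"timepoint_h": tp, "compartment": label, "mean": s.mean,
                         "variance": s.variance, "cv2": s.cv2, "fano": s.fano, "n": s.n})
        cyt_mean = by_comp["cytoplasmic"].mean
        ratio = by_comp["nuclear"].mean / cyt_mean if cyt_mean > 0 else np.nan
        for row in rows[-3:]:
            row["nuc_cyt_ratio"] = ratio
    return pd.DataFrame(rows)


def noise_scaling_expected(b: float, mean_grid) -> np.ndarray:
    """Guide hyperbola ``CV^2 = b / <mRNA>`` for burst size ``b``.

    These are the frequency-modulation guide curves (burst size fixed,
    k_on regulated, assuming k_off >> k_on); typical guide values of
    ``b`` range from 5 to 70.
    """
    if b <= 0:
        raise ValueError("burst size b must be positive")
    means = np.asarray(mean_grid, dtype=float)
    if np.any(means <= 0):
        raise ValueError("means must be positive")
    return b / means


def log_noise_scaling_slope(means, cv2s) -> float:
    """Regression slope of log CV^2 on log mean across conditions.

    A slope of -1 is the signature of pure frequency modulation (the
    population slides along a fixed-burst-size hyperbola).
    """
    x = np.log(np.asarray(means, dtype=float))
    y = np.log(np.asarray(cv2s, dtype=float))
    if x.size < 2:
        raise ValueError("need at least two (mean, CV^2) points")
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def fano_standard_error(counts) -> float:
    """Delta-method standard error of the sample Fano factor.

    For ``F = s^2 / xbar``, combines the large-sample variances of the
    sample variance (via the fourth central moment) and of the mean with
    their covariance (third central moment).
    """
    x = np.asarray(counts, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least four observations")
    m = x.mean()
    c = x - m
    s2 = x.var(ddof=1)
    mu3 = np.mean(c**3)
    mu4 = np.mean(c**4)
    var_s2 = (mu4 - s2**2 * (n - 3) / (n - 1)) / n
    var_m = s2 / n
    cov = mu3 / n
    var_f = var_s2 / m**2 + (s2**2 / m**4) * var_m - 2.0 * (s2 / m**3) * cov
    return float(np.sqrt(max(var_f, 0.0)))
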