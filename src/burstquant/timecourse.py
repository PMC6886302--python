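"""Gene time courses, promoter archetypes and treatment comparisons.

Per-time-point burst estimates are assembled into ordered time courses of
promoter activity ``f`` and median transcription rate, and the shape of
the ``f`` series over the p53 pulse train is classified into one of three
promoter archetypes:

- **sustained**  - activation persists through the trough and second peak;
- **pulsatile**  - activity tracks the p53 pulses (down at 6 h, up at 9 h);
- **transient**  - activation during the first pulse only, with no
  re-activation at the second peak.

Archetypes are shape distinctions, not level distinctions, so the series
is min-max normalised before nearest-template assignment; a softmax score
vector over the three templates is retained for ambiguous genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import BurstEstimate

#: template f-shapes at (basal, 3 h, 6 h, 9 h) after min-max normalisation
ARCHETYPE_TEMPLATES: dict[str, tuple[float, ...]] = {
    "sustained": (0.0, 1.0, 1.0, 1.0),
    "pulsatile": (0.0, 1.0, 0.0, 1.0),
    "transient": (0.0, 1.0, 0.5, 0.25),
}
#: softmax temperature on negative template distances
SCORE_TEMPERATURE = 0.25

EXPECTED_TIMEPOINTS = (0.0, 3.0, 6.0, 9.0)


@dataclass
class TimeCourse:
    """Ordered per-gene series of burst estimates across time points."""

    gene: str
    treatment: str
    timepoints_h: tuple[float, ...]
    f_series: tuple[float, ...]
    mu_median_series: tuple[float, ...]
    has_gaps: bool = False
    archetype_call: str | None = None
    archetype_scores: dict[str, float] = field(default_factory=dict)


def assemble_timecourse(estimates: list[BurstEstimate],
                        expected_timepoints=EXPECTED_TIMEPOINTS) -> TimeCourse:
    """Order per-time-point estimates into a gene time course.

    Requires at least three distinct time points including basal (0 h);
    duplicate time points are an error.  If any expected time point is
    missing the series is flagged gapped and archetype calling is
    suppressed downstream.
    """
    if not estimates:
        raise ValueError("no estimates to assemble")
    genes = {e.gene for e in estimates}
    if len(genes) > 1:
        raise ValueError(f"estimates mix genes: {sorted(genes)}")
    ordered = sorted(estimates, key=lambda e: e.timepoint_h)
    tps = [e.timepoint_h for e in ordered]
    if len(set(tps)) != len(tps):
        raise ValueError("duplicate time points in estimates")
    if len(tps) < 3 or 0.0 not in tps:
        raise ValueError("need >= 3 distinct time points including basal (0 h)")
    has_gaps = any(t not in tps for t in expected_timepoints)
    return TimeCourse(
        gene=ordered[0].gene,
        treatment=ordered[0].treatment,
        timepoints_h=tuple(tps),
        f_series=tuple(e.f for e in ordered),
        mu_median_series=tuple(e.median_mu for e in ordered),
        has_gaps=has_gaps,
    )


def classify_archetype(tc: TimeCourse,
                       templates: dict[str, tuple[float, ...]] | None = None) -> TimeCourse:
    """Assign a promoter archetype to a complete four-point time course.

    The ``f`` series is min-max normalised to [0, 1] (classification is
    therefore invariant to affine rescaling of ``f``) and assigned to the
    nearest template by Euclidean distance; scores are the softmax of the
    negative distances.  Series without induction (f(3 h) <= f(0 h)) are
    labelled 'unresponsive'; gapped series keep ``archetype_call = None``.
    """
    templates = templates or ARCHETYPE_TEMPLATES
    if tc.has_gaps or len(tc.f_series) != len(EXPECTED_TIMEPOINTS):
        tc.archetype_call = None
        tc.archetype_scores = {}
        return tc
    f = np.asarray(tc.f_series, dtype=float)
    idx3 = tc.timepoints_h.index(3.0)
    if f[idx3] <= f[0]:
        tc.archetype_call = "unresponsive"
        tc.archetype_scores = {}
        return tc
    span = f.max() - f.min()
    norm = (f - f.min()) / span if span > 0 else np.zeros_like(f)
    names = list(templates)
    dists = np.array([np.linalg.norm(norm - np.asarray(templates[k])) for k in names])
    logits = -dists / SCORE_TEMPERATURE
    w = np.exp(logits - logits.max())
    scores = w / w.sum()
    # ties broken by template order: argmin returns the first minimum
    tc.archetype_call = names[int(np.argmin(dists))]
    tc.archetype_scores = {k: float(s) for k, s in zip(names, scores)}
    return tc


def timecourses_from_frame(estimates_df) -> list[TimeCourse]:
    """Rebuild time courses from a written estimates.tsv summary table.

    One :class:`TimeCourse` per (gene, treatment) group, using the ``f``
    and ``median_mu`` columns; gap flags follow the expected four-point
    design.
    """
    courses = []
    for (gene_name, treatment), grp in estimates_df.groupby(["gene", "treatment"], sort=True):
        grp = grp.sort_values("timepoint_h")
        tps = tuple(float(t) for t in grp["timepoint_h"])
        if len(set(tps)) != len(tps):
            raise ValueError(f"{gene_name}: duplicate time points")
        courses.append(TimeCourse(
            gene=str(gene_name), treatment=str(treatment), timepoints_h=tps,
            f_series=tuple(float(v) for v in grp["f"]),
            mu_median_series=tuple(float(v) for v in grp["median_mu"]),
            has_gaps=any(t not in tps for t in EXPECTED_TIMEPOINTS),
        ))
    return courses


def compare_treatments(tc_ref: TimeCourse, tc_alt: TimeCourse) -> dict:
    """Per-time-point fold changes of ``f`` and median mu vs a reference.

    ``fold_f(t) = f_alt(t) / f_ref(t)`` and likewise for the median
    transcription rate; zero-denominator time points are NaN-flagged.
    """
    if tc_ref.gene != tc_alt.gene:
        raise ValueError(f"gene mismatch: {tc_ref.gene} vs {tc_alt.gene}")
    if tc_ref.timepoints_h != tc_alt.timepoints_h:
        raise ValueError("time points do not match between treatments")
    f_ref = np.asarray(tc_ref.f_series, dtype=float)
    f_alt = np.asarray(tc_alt.f_series, dtype=float)
    mu_ref = np.asarray(tc_ref.mu_median_series, dtype=float)
    mu_alt = np.asarray(tc_alt.mu_median_series, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_f = np.where(f_ref > 0, f_alt / f_ref, np.nan)
        fold_mu = np.where(mu_ref > 0, mu_alt / mu_ref, np.nan)
    return {
        "gene": tc_ref.gene,
        "timepoints_h": tc_ref.timepoints_h,
        "fold_f": tuple(fold_f.tolist()),
        "fold_mu": tuple(fold_mu.tolist()),
    }
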