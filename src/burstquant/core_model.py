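"""Gene models, experiment designs and the probe-position correction factor.

A :class:`GeneModel` describes one smFISH target: transcript length ``l``,
the number of genomic loci ``n`` (from DNA FISH), the transcript coordinates
of the exon and intron probe sets, the RNAP2 elongation speed ``v`` and the
fixed occupancy correction ``kappa``.  The probe-position correction factor
``eta`` — the expected fraction of exon probes hybridised to a nascent
transcript whose polymerase position is uniform on ``[0, l]`` — is derived
from the exon probe layout and enters the occupancy formula
``M = Int_TSS / (kappa * eta * mInt_mRNA)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a gene model or experiment design is internally invalid."""


#: minutes-scale elongation speed, 3 kb/min expressed per hour
DEFAULT_ELONGATION_SPEED_NT_PER_H = 180_000.0
#: fixed multiplicative RNAP2-occupancy correction
DEFAULT_KAPPA = 1.5

TREATMENTS = ("untreated", "IR_pulsatile", "IR_chk2i_transient", "IR_nutlin_sustained")


@dataclass(frozen=True)
class GeneModel:
    """Static description of one smFISH target gene.

    Parameters
    ----------
    name
        Gene label used in output tables.
    length_nt
        Transcript length ``l`` in nucleotides. A single shared coordinate
        axis of length ``l`` is used for mature and nascent transcripts.
    n_loci
        Number of genomic loci ``n`` carrying the gene (2-4 in aneuploid
        lines, determined by DNA FISH).
    exon_probe_positions_nt
        0-based transcript coordinate of each exon probe's 3'-most
        nucleotide, sorted 5'->3'. A probe contributes signal on a nascent
        transcript only once the polymerase has passed its 3' end.
    intron_probe_positions_nt
        Same convention for the intron probe set (used only for TSS
        detection, not for intensity quantification).
    elongation_speed_nt_per_h
        RNAP2 elongation speed ``v`` (default 180,000 nt/h = 3 kb/min).
    kappa
        Fixed RNAP2-occupancy correction (default 1.5).
    """

    name: str
    length_nt: int
    n_loci: int
    exon_probe_positions_nt: tuple[int, ...]
    intron_probe_positions_nt: tuple[int, ...] = ()
    elongation_speed_nt_per_h: float = DEFAULT_ELONGATION_SPEED_NT_PER_H
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_probe_positions_nt",
                           tuple(int(p) for p in self.exon_probe_positions_nt))
        object.__setattr__(self, "intron_probe_positions_nt",
                           tuple(int(p) for p in self.intron_probe_positions_nt))
        if self.length_nt <= 0:
            raise ConfigurationError(f"{self.name}: length_nt must be positive")
        if self.n_loci < 1:
            raise ConfigurationError(f"{self.name}: n_loci must be >= 1")
        if not self.exon_probe_positions_nt:
            raise ConfigurationError(f"{self.name}: at least one exon probe required")
        if self.elongation_speed_nt_per_h <= 0:
            raise ConfigurationError(f"{self.name}: elongation speed must be positive")
        if self.kappa <= 0:
            raise ConfigurationError(f"{self.name}: kappa must be positive")
        for label, probes in (("exon", self.exon_probe_positions_nt),
                              ("intron", self.intron_probe_positions_nt)):
            if any(p < 0 or p > self.length_nt for p in probes):
                raise ConfigurationError(
                    f"{self.name}: {label} probe positions must lie in [0, {self.length_nt}]")
            if any(b < a for a, b in zip(probes, probes[1:])):
                raise ConfigurationError(
                    f"{self.name}: {label} probe positions must be sorted ascending")

    @property
    def eta(self) -> float:
        """Probe-position correction factor for the exon probe set."""
        return compute_eta(self.exon_probe_positions_nt, self.length_nt)

    @property
    def dwell_time_h(self) -> float:
        """Time a polymerase needs to traverse the gene, l/v in hours."""
        return self.length_nt / self.elongation_speed_nt_per_h


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of one smFISH time-course experiment.

    Time points default to the p53-pulse landmarks used throughout:
    basal (0 h), first peak (3 h), trough (6 h) and second peak (9 h)
    after 10 Gy ionising radiation.
    """

    timepoints_h: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0)
    treatment: str = "IR_pulsatile"
    n_cells_per_timepoint: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints_h", tuple(float(t) for t in self.timepoints_h))
        if any(t < 0 for t in self.timepoints_h):
            raise ConfigurationError("timepoints must be non-negative")
        if any(b <= a for a, b in zip(self.timepoints_h, self.timepoints_h[1:])):
            raise ConfigurationError("timepoints must be strictly increasing")
        if self.treatment not in TREATMENTS:
            raise ConfigurationError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}")
        if self.n_cells_per_timepoint < 1:
            raise ConfigurationError("n_cells_per_timepoint must be >= 1")


def compute_eta(exon_probe_positions_nt: Sequence[int], length_nt: int) -> float:
    """Expected fraction of exon probes hybridised on a nascent transcript.

    Assumes the polymerase position ``x`` of a nascent transcript is uniform
    on ``[0, l]`` and that probe ``i`` (3' end at ``p_i``) is hybridised iff
    ``x >= p_i``, giving

        eta = (1 / N_p) * sum_i (l - p_i) / l.

    ``eta`` is 1 when every probe sits at the 5' end (every nascent
    transcript carries the full probe set) and 0 when every probe sits at
    the 3' end (no incomplete transcript carries any probe).
    """
    if length_nt <= 0:
        raise ConfigurationError("length_nt must be positive")
    probes = np.asarray(exon_probe_positions_nt, dtype=float)
    if probes.size == 0:
        raise ConfigurationError("cannot compute eta from an empty probe list")
    if np.any(probes < 0) or np.any(probes > length_nt):
        raise ValueError("probe positions must lie within [0, length_nt]")
    return float(np.mean((length_nt - probes) / length_nt))


def probe_fraction_completed(gene: GeneModel, positions_nt: np.ndarray) -> np.ndarray:
    """Fraction of exon probes completed by polymerases at ``positions_nt``.

    Vectorised helper shared by the simulator (to synthesise nascent
    intensities) and by tests; for a position ``x`` it returns
    ``#{p_i <= x} / N_p``.
    """
    probes = np.asarray(gene.exon_probe_positions_nt, dtype=float)
    x = np.asarray(positions_nt, dtype=float)
    return np.searchsorted(np.sort(probes), x, side="right") / probes.size


# ---------------------------------------------------------------------------
# configuration files


def _gene_from_dict(d: dict) -> GeneModel:
    return GeneModel(
        name=d["name"],
        length_nt=int(d["length_nt"]),
        n_loci=int(d["n_loci"]),
        exon_probe_positions_nt=tuple(d["exon_probe_positions_nt"]),
        intron_probe_positions_nt=tuple(d.get("intron_probe_positions_nt", ())),
        elongation_speed_nt_per_h=float(
            d.get("elongation_speed_nt_per_h", DEFAULT_ELONGATION_SPEED_NT_PER_H)),
        kappa=float(d.get("kappa", DEFAULT_KAPPA)),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON config with ``genes`` and optional ``design`` blocks.

    Returns a dict with keys ``genes`` (list of :class:`GeneModel`),
    ``design`` (:class:`ExperimentDesign` or None) and ``raw`` (the parsed
    document, so that simulator blocks can be picked up downstream).
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(doc, dict) or "genes" not in doc:
        raise ConfigurationError(f"{path}: expected a mapping with a 'genes' list")
    genes = [_gene_from_dict(g) for g in doc["genes"]]
    design = None
    if "design" in doc and doc["design"] is not None:
        d = doc["design"]
        design = ExperimentDesign(
            timepoints_h=tuple(d.get("timepoints_h", (0.0, 3.0, 6.0, 9.0))),
            treatment=d.get("treatment", "IR_pulsatile"),
            n_cells_per_timepoint=int(d.get("n_cells_per_timepoint", 200)),
            seed=int(d.get("seed", 0)),
        )
    return {"genes": genes, "design": design, "raw": doc}


def demo_config_path() -> Path:
    """Path of the bundled six-gene demo configuration."""
    return Path(__file__).parent / "data" / "genes_demo.yaml"
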