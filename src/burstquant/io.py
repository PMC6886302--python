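"""Tab-separated table I/O with deterministic formatting.

All tables are written with a fixed float format so that identical
configurations and seeds produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .inference import BurstEstimate, distributions_frame, estimates_frame
from .simulate import PopulationSample

FLOAT_FORMAT = "%.6g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_population(sample: PopulationSample, outdir: str | Path) -> dict[str, Path]:
    """Write spots.tsv, cells.tsv and truth.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"spots": outdir / "spots.tsv", "cells": outdir / "cells.tsv",
             "truth": outdir / "truth.tsv"}
    _write(sample.spots, paths["spots"])
    _write(sample.cells, paths["cells"])
    _write(sample.truth, paths["truth"])
    return paths


def read_spots(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_estimates(estimates: list[BurstEstimate], outdir: str | Path) -> dict[str, Path]:
    """Write estimates.tsv (summary) and distributions.tsv (per-TSS)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"estimates": outdir / "estimates.tsv",
             "distributions": outdir / "distributions.tsv"}
    _write(estimates_frame(estimates), paths["estimates"])
    _write(distributions_frame(estimates), paths["distributions"])
    return paths


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_noise(noise: pd.DataFrame, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "noise.tsv"
    _write(noise, path)
    return path
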