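"""Data model and tabular I/O for individual-level stable-isotope measurements.

The canonical in-memory container is a tidy :class:`pandas.DataFrame` with one
row per fish and the columns ``species, site, year, length, d13C, d15N, c_to_n``
(δ13C in ‰ vs VPDB, δ15N in ‰ vs atmospheric air, C:N as a mass ratio).
``length`` and ``c_to_n`` may be missing (NaN); δ13C and δ15N must be present
and finite for a row to enter the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("isoniche")

#: canonical column order of the measurement table
COLUMNS = ["species", "site", "year", "length", "d13C", "d15N", "c_to_n"]

#: columns that must be present (after schema mapping) for a file to be read
REQUIRED = ["species", "d13C", "d15N"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class DegenerateDataError(ValueError):
    """The point configuration cannot support the requested fit."""


@dataclass(frozen=True)
class IsotopeMeasurement:
    """A single fish's bivariate isotopic signature plus covariates."""

    species: str
    d13C: float
    d15N: float
    site: str = ""
    year: int | None = None
    length: float | None = None
    c_to_n: float | None = None

    def __post_init__(self):
        if not self.species:
            raise ValueError("species label must be non-empty")
        if not (np.isfinite(self.d13C) and np.isfinite(self.d15N)):
            raise ValueError("d13C and d15N must be finite")
        if self.c_to_n is not None and not self.c_to_n > 0:
            raise ValueError("c_to_n must be positive when present")


@dataclass
class SpeciesDataset:
    """All measurements of one species, exposing the (δ13C, δ15N) point cloud."""

    species: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if not self.species:
            raise ValueError("species label must be non-empty")
        missing = [c for c in ("d13C", "d15N") if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of (δ13C, δ15N) pairs."""
        return self.data[["d13C", "d15N"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return self.n


@dataclass
class PipelineConfig:
    """Run-wide knobs shared by every randomized or discretized stage.

    Defaults follow the study design: 1005 bootstrap replicates at a fixed
    resample size of 50, 10,000 posterior draws, a C:N screening threshold of
    3.5, and the strict ``count > 5`` unique-site rule.
    """

    bootstrap_reps: int = 1005
    bootstrap_n: int = 50
    posterior_draws: int = 10_000
    seed: int = 0
    overlap_vertices: int = 1024
    cn_threshold: float = 3.5
    unique_site_min: int = 5

    def __post_init__(self):
        for name in ("bootstrap_reps", "bootstrap_n", "posterior_draws", "overlap_vertices"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.cn_threshold > 0:
            raise ValueError("cn_threshold must be positive")


def read_measurements(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a measurement CSV into the canonical tidy frame.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row.
    schema : dict, optional
        Mapping from canonical names (``species``, ``d13C``, ...) to the
        column headers actually present in the file.  Unmapped canonical
        names default to themselves.

    Rows with missing δ13C or δ15N are dropped (count logged); missing
    length/C:N are kept as NaN.  Sentinel numerics such as -999 are *not*
    auto-detected.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path)
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)

    for col in REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"required column '{col}' not found (after schema mapping)")
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("site",) else np.nan

    for col in ("d13C", "d15N", "length", "c_to_n"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"unparsable numeric value in column '{col}' at line(s) {lines}") from exc

    keep = df["d13C"].notna() & df["d15N"].notna() & df["species"].notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d row(s) with missing species/d13C/d15N", dropped)
    df = df.loc[keep, COLUMNS].reset_index(drop=True)
    df["species"] = df["species"].astype(str)
    bad_cn = df["c_to_n"].notna() & (df["c_to_n"] <= 0)
    if bad_cn.any():
        raise ValueError("c_to_n must be positive where present")
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write the canonical measurement table; floats keep full repr precision."""
    df.to_csv(path, index=False)


def group_by_species(measurements: pd.DataFrame) -> list[SpeciesDataset]:
    """Partition a measurement frame into per-species datasets.

    Species order is lexicographic; the partition is exact (group sizes sum
    to the input size and no columns are dropped).
    """
    if len(measurements) == 0:
        raise ValueError("cannot group an empty measurement table")
    out = []
    for sp in sorted(measurements["species"].astype(str).unique()):
        sub = measurements[measurements["species"].astype(str) == sp].reset_index(drop=True)
        out.append(SpeciesDataset(species=sp, data=sub))
    return out


def as_dataset(points: np.ndarray | pd.DataFrame | SpeciesDataset, species: str = "sample") -> SpeciesDataset:
    """Coerce an (n, 2) array / frame / dataset to a :class:`SpeciesDataset`."""
    if isinstance(points, SpeciesDataset):
        return points
    if isinstance(points, pd.DataFrame):
        return SpeciesDataset(species=species, data=points)
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (d13C, d15N)")
    return SpeciesDataset(species=species, data=pd.DataFrame(arr, columns=["d13C", "d15N"]))
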