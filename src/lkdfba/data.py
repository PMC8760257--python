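"""Time-course dataset container and tidy CSV I/O.

The on-disk dialect is a tidy table with columns
``time, species_id, species_type{metabolite|flux|pooling}, value, replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimecourseDataset", "read_timecourse_csv", "write_timecourse_csv"]

REQUIRED_COLUMNS = ["time", "species_id", "species_type", "value"]
SPECIES_TYPES = {"metabolite": "concentrations", "flux": "fluxes", "pooling": "pooling_fluxes"}


@dataclass
class TimecourseDataset:
    """Sampled concentrations (and optionally fluxes) on a common time grid.

    Attributes
    ----------
    times
        Strictly increasing sample times, length nT.
    concentrations
        DataFrame (time x metabolite).
    fluxes, pooling_fluxes
        Optional DataFrames (time x reaction / time x metabolite).
    provenance
        Free-form metadata: e.g. {"source": "simulated"} or
        {"source": "noisy", "cov": 0.15, "replicate": 3, "seed": 17}.
    """

    times: np.ndarray
    concentrations: pd.DataFrame
    fluxes: pd.DataFrame | None = None
    pooling_fluxes: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two sample times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        for name in ("concentrations", "fluxes", "pooling_fluxes"):
            tab = getattr(self, name)
            if tab is None:
                continue
            tab = tab.copy()
            tab.index = pd.Index(self.times, name="time")
            if len(tab) != len(self.times):
                raise ValueError(f"{name} has {len(tab)} rows, expected {len(self.times)}")
            setattr(self, name, tab)
        if not np.all(np.isfinite(self.concentrations.to_numpy())):
            raise ValueError("concentrations contain non-finite values")

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.fluxes.columns) if self.fluxes is not None else []

    def copy(self) -> "TimecourseDataset":
        return TimecourseDataset(
            self.times.copy(),
            self.concentrations.copy(),
            None if self.fluxes is None else self.fluxes.copy(),
            None if self.pooling_fluxes is None else self.pooling_fluxes.copy(),
            dict(self.provenance),
        )

    def to_tidy(self, replicate: int | None = None) -> pd.DataFrame:
        frames = []
        rep = replicate if replicate is not None else self.provenance.get("replicate", 0)
        for stype, attr in SPECIES_TYPES.items():
            tab = getattr(self, attr)
            if tab is None:
                continue
            long = tab.reset_index().melt(id_vars="time", var_name="species_id", value_name="value")
            long = long.dropna(subset=["value"])
            long["species_type"] = stype
            long["replicate"] = rep
            frames.append(long)
        tidy = pd.concat(frames, ignore_index=True)
        return tidy[["time", "species_id", "species_type", "value", "replicate"]]

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, replicate: int | None = None) -> "TimecourseDataset":
        missing = [c for c in REQUIRED_COLUMNS if c not in tidy.columns]
        if missing:
            raise ValueError(f"tidy time-course table missing column(s): {missing}")
        if "replicate" in tidy.columns and replicate is not None:
            tidy = tidy[tidy["replicate"] == replicate]
            if tidy.empty:
                raise ValueError(f"no rows for replicate {replicate}")
        bad = set(tidy["species_type"]) - set(SPECIES_TYPES)
        if bad:
            raise ValueError(f"unknown species_type value(s): {sorted(bad)}")
        tables: dict[str, pd.DataFrame] = {}
        for stype, attr in SPECIES_TYPES.items():
            sub = tidy[tidy["species_type"] == stype]
            if sub.empty:
                continue
            wide = sub.pivot_table(index="time", columns="species_id", values="value", sort=True)
            wide.columns.name = None
            wide.index.name = "time"
            tables[attr] = wide
        if "concentrations" not in tables:
            raise ValueError("tidy table contains no metabolite rows")
        times = tables["concentrations"].index.to_numpy(dtype=float)
        # species missing at some times (e.g. fluxes start one step after t0)
        # are re-aligned onto the concentration grid with NaN
        for attr in ("fluxes", "pooling_fluxes"):
            if attr in tables:
                tables[attr] = tables[attr].reindex(tables["concentrations"].index)
        return cls(
            times,
            tables["concentrations"],
            tables.get("fluxes"),
            tables.get("pooling_fluxes"),
            provenance={"source": "file"},
        )


def write_timecourse_csv(dataset: TimecourseDataset, path) -> None:
    dataset.to_tidy().to_csv(path, index=False)


def read_timecourse_csv(path, replicate: int | None = None) -> TimecourseDataset:
    tidy = pd.read_csv(path)
    try:
        return TimecourseDataset.from_tidy(tidy, replicate=replicate)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
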