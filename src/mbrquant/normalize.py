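"""Run-to-run intensity normalization over ten equal-population m/z bins.

Each run is assumed to differ from the others by a single multiplicative
intensity factor.  The pooled ion m/z range is split into ten bins holding
equal numbers of ions; per run and bin, the median log-intensity offset to
the cross-run per-ion median is computed over ions shared with other runs,
and the run factor is exp(-median over bins).  Binning makes the estimate
robust for sparse data and samples with large abundance differences.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .model import QuantRow

log = logging.getLogger(__name__)

N_BINS = 10


@dataclasses.dataclass
class NormalizationModel:
    """Fitted per-run multiplicative correction factors."""

    bin_edges: np.ndarray  # 11 edges spanning the pooled ion m/z range
    run_factors: dict[str, float]

    def factor(self, run_id: str) -> float:
        try:
            return self.run_factors[run_id]
        except KeyError:
            raise KeyError(f"run {run_id!r} not present in normalization model")


def fit_normalization(table: pd.DataFrame) -> NormalizationModel:
    """Fit per-run factors from an ion intensity table.

    ``table`` columns: ``run_id``, ``ion`` (hashable), ``mz``, ``intensity``
    (one row per ion per run, intensities > 0 where present).  A single run
    yields the identity model; runs sharing no ions with the others get
    factor 1 with a warning.
    """
    runs = sorted(table["run_id"].unique())
    pooled = table.drop_duplicates("ion")
    edges = np.quantile(pooled["mz"].to_numpy(dtype=float),
                        np.linspace(0.0, 1.0, N_BINS + 1))
    if len(runs) < 2:
        return NormalizationModel(bin_edges=edges,
                                  run_factors={r: 1.0 for r in runs})

    df = table[table["intensity"] > 0].copy()
    counts = df.groupby("ion")["run_id"].nunique()
    shared = counts.index[counts >= 2]
    if len(shared) < N_BINS:
        log.warning("fewer than %d ions shared across runs; identity normalization",
                    N_BINS)
        return NormalizationModel(bin_edges=edges,
                                  run_factors={r: 1.0 for r in runs})
    df = df[df["ion"].isin(set(shared))]
    df["log_i"] = np.log(df["intensity"].to_numpy(dtype=float))
    ref = df.groupby("ion")["log_i"].median()
    df["offset"] = df["log_i"] - df["ion"].map(ref)
    df["bin"] = np.clip(np.searchsorted(edges, df["mz"].to_numpy(dtype=float),
                                        side="right") - 1, 0, N_BINS - 1)

    factors: dict[str, float] = {}
    per_run_bin = df.groupby(["run_id", "bin"])["offset"].median()
    for run in runs:
        if run in per_run_bin.index.get_level_values(0):
            offsets = per_run_bin.loc[run]
            factors[run] = float(np.exp(-np.median(offsets.to_numpy())))
        else:
            log.warning("run %s shares no ions with other runs; factor 1", run)
            factors[run] = 1.0
    return NormalizationModel(bin_edges=edges, run_factors=factors)


def apply_normalization(model: NormalizationModel, rows: list[QuantRow]) -> list[QuantRow]:
    """Multiply every row's intensity by its run factor (returns new rows)."""
    out = []
    for r in rows:
        f = model.factor(r.run_id)
        out.append(dataclasses.replace(r, intensity=r.intensity * f))
    return out
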