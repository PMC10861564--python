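"""Labeling metrics: isotopologue distributions, average labeling and
pool-size-scaled tracer quantities.

Definitions used throughout (N = number of labelable atoms of the tracer
element, MID = mass isotopomer distribution over shifts 0..N):

* average labeling (%)    = 100 * sum_k k * MID_k / N
* nmol labeled product    = pool_nmol * (1 - MID_0), the molar amount of
  molecules carrying at least one tracer atom (steady-state pool assumed)
* natom equivalents       = pool_nmol * sum_k k * MID_k, the molar amount of
  tracer atoms incorporated; identically pool * N * avg_labeling / 100

Bucket quantification converts analyte intensity to nmol against each of
several spiked internal standards ("buckets") and averages the answers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import IsotopologueGrid, project_marginal, project_nominal

__all__ = [
    "mid",
    "average_labeling",
    "nmol_labeled",
    "natom_equivalents",
    "bucket_quantify",
    "MIDSeries",
    "build_mid_series",
    "replicate_summary",
]


def mid(intensities: np.ndarray) -> np.ndarray:
    """Fractional isotopologue abundances (vector / sum)."""
    v = np.asarray(intensities, dtype=float)
    if np.any(v < 0):
        raise ValueError("intensities must be non-negative")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero intensity vector: MID undefined")
    return v / total


def average_labeling(mid_vector: np.ndarray, n_atoms: int) -> float:
    """Atom-fraction enrichment in percent over shifts 0..N."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    v = np.asarray(mid_vector, dtype=float)
    k = np.arange(len(v))
    return float(100.0 * (k * v).sum() / n_atoms)


def nmol_labeled(mid_corrected: np.ndarray, pool_nmol: float) -> float:
    """nmol of labeled product formed: pool size times the labeled fraction.

    The sum of all labeled isotopologues (M1..Mn) of a steady-state pool,
    i.e. pool * (1 - M0).
    """
    if pool_nmol <= 0:
        raise ValueError("pool_nmol must be positive")
    v = np.asarray(mid_corrected, dtype=float)
    return float(pool_nmol * (1.0 - v[0]))


def natom_equivalents(mid_corrected: np.ndarray, pool_nmol: float) -> float:
    """nmol of tracer atoms incorporated: pool * mean heavy atoms per molecule."""
    if pool_nmol <= 0:
        raise ValueError("pool_nmol must be positive")
    v = np.asarray(mid_corrected, dtype=float)
    k = np.arange(len(v))
    return float(pool_nmol * (k * v).sum())


def bucket_quantify(
    analyte_intensity: float,
    standards: Sequence[Dict[str, float]],
) -> float:
    """Single-point quantification against multiple internal standards.

    Each standard dict holds ``intensity`` and ``amount_nmol``; every
    standard is a "bucket" giving analyte / standard * amount, and the mean
    over valid buckets is the reported quantity.  Zero-intensity buckets
    are excluded with a warning.
    """
    if analyte_intensity < 0:
        raise ValueError("analyte intensity must be non-negative")
    estimates = []
    for s in standards:
        if s["intensity"] <= 0:
            warnings.warn("bucket with non-positive standard intensity excluded", stacklevel=2)
            continue
        estimates.append(analyte_intensity / s["intensity"] * s["amount_nmol"])
    if not estimates:
        raise ValueError("no valid quantification bucket")
    return float(np.mean(estimates))


@dataclass
class MIDSeries:
    """Per-compound labeling time course over the isotopologue grid.

    Holds raw and NA-corrected fraction vectors per sample plus the derived
    per-sample metrics, with samples in canonical (time, replicate) order.
    """

    compound: str
    grid: IsotopologueGrid
    sample_ids: List[str]
    time_h: np.ndarray
    raw: np.ndarray  # (n_grid, n_samples) fractions
    corrected: np.ndarray  # (n_grid, n_samples) fractions
    pool_nmol: Optional[float] = None

    def __post_init__(self):
        for arr in (self.raw, self.corrected):
            sums = arr.sum(axis=0)
            ok = np.isclose(sums, 1.0, atol=1e-6) | (sums == 0)
            if not ok.all():
                raise ValueError("MID columns must each sum to 1 (or be all zero)")

    def nominal(self, corrected: bool = True) -> np.ndarray:
        """Nominal-shift MIDs, (max_shift+1, n_samples)."""
        src = self.corrected if corrected else self.raw
        return np.column_stack([project_nominal(self.grid, src[:, i]) for i in range(src.shape[1])])

    def marginal(self, tracer, corrected: bool = True) -> np.ndarray:
        src = self.corrected if corrected else self.raw
        return np.column_stack(
            [project_marginal(self.grid, src[:, i], tracer) for i in range(src.shape[1])]
        )

    def metrics_table(self) -> pd.DataFrame:
        """Long-format per-sample metrics (nominal plus per-tracer views)."""
        rows = []
        nom = self.nominal(corrected=True)
        n_total = self.grid.max_nominal_shift
        for i, s in enumerate(self.sample_ids):
            rows.append(
                dict(
                    compound=self.compound,
                    sample=s,
                    time_h=float(self.time_h[i]),
                    metric="average_labeling_pct",
                    value=average_labeling(nom[:, i], n_total),
                )
            )
            if self.pool_nmol:
                rows.append(
                    dict(
                        compound=self.compound,
                        sample=s,
                        time_h=float(self.time_h[i]),
                        metric="nmol_labeled",
                        value=nmol_labeled(nom[:, i], self.pool_nmol),
                    )
                )
            for t in self.grid.tracers:
                marg = self.marginal(t)[:, i]
                n_t = self.grid.neutral[t.element]
                if n_t == 0:
                    continue
                rows.append(
                    dict(
                        compound=self.compound,
                        sample=s,
                        time_h=float(self.time_h[i]),
                        metric=f"average_labeling_{t.label}_pct",
                        value=average_labeling(marg, n_t),
                    )
                )
                if self.pool_nmol and t.label == "13C":
                    rows.append(
                        dict(
                            compound=self.compound,
                            sample=s,
                            time_h=float(self.time_h[i]),
                            metric="natom_13C_nmol",
                            value=natom_equivalents(marg, self.pool_nmol),
                        )
                    )
        return pd.DataFrame(rows)


def build_mid_series(
    grid: IsotopologueGrid,
    intensity_matrix: np.ndarray,
    corrected_mids: np.ndarray,
    sample_ids: Sequence[str],
    metadata: pd.DataFrame,
    pool_nmol: Optional[float] = None,
) -> MIDSeries:
    """Assemble raw + corrected MID vectors into a time series object."""
    meta = metadata.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta = meta.set_index("sample_id").loc[list(sample_ids)]
    raw = np.zeros_like(intensity_matrix, dtype=float)
    for i in range(intensity_matrix.shape[1]):
        col = intensity_matrix[:, i]
        if col.sum() > 0:
            raw[:, i] = col / col.sum()
    return MIDSeries(
        compound=grid.compound,
        grid=grid,
        sample_ids=list(sample_ids),
        time_h=meta["time_h"].to_numpy(dtype=float),
        raw=raw,
        corrected=np.asarray(corrected_mids, dtype=float),
        pool_nmol=pool_nmol,
    )


def replicate_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD per compound x metric x time point over replicates."""
    g = metrics.groupby(["compound", "metric", "time_h"])["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["std"] = out["std"].fillna(0.0)
    return out
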