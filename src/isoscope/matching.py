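"""Identify isotopologues of library compounds in pre-processed feature tables.

Upstream peak-picking software (XCMS, MZmine) exports a table of features —
m/z, retention time and one intensity column per sample.  Given a compound
database (name, neutral formula, retention time, adduct) the matcher looks
up every isotopologue of every compound inside user-set m/z (ppm) and RT
(seconds) tolerance windows and assembles fixed-length intensity vectors in
grid order, with unmatched isotopologues kept as explicit zeros so the
downstream NA correction always sees full-length vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    ADDUCTS,
    IsotopologueGrid,
    MolecularFormula,
    TracerSpec,
    enumerate_isotopologues,
    parse_formula,
)

__all__ = [
    "FeatureTable",
    "IsotopologueMeasurement",
    "read_feature_table",
    "read_sample_metadata",
    "read_compound_db",
    "match_isotopologues",
    "assemble_intensity_matrix",
    "compound_identified",
]

log = logging.getLogger(__name__)

DEFAULT_MZ_TOL_PPM = 5.0
DEFAULT_RT_TOL_S = 10.0


@dataclass
class FeatureTable:
    """Pre-processed untargeted features plus sample metadata.

    ``data`` holds columns feature_id, mz, rt and one column per sample;
    ``metadata`` holds sample_id, time_h, replicate.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        for col in ("mz", "rt"):
            if col not in self.data.columns:
                raise ValueError(f"feature table lacks required column {col!r}")
        if (self.data["mz"] <= 0).any():
            raise ValueError("all feature m/z must be positive")
        if (self.data["rt"] < 0).any():
            raise ValueError("retention times must be non-negative")
        missing = set(self.sample_ids) - set(self.data.columns)
        if missing:
            raise ValueError(f"metadata samples missing from table: {sorted(missing)}")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.metadata["sample_id"])

    def ordered_samples(self) -> pd.DataFrame:
        """Metadata sorted canonically by (time_h, replicate, sample_id)."""
        return self.metadata.sort_values(
            ["time_h", "replicate", "sample_id"]
        ).reset_index(drop=True)


@dataclass
class IsotopologueMeasurement:
    """One grid slot of one compound, matched (or not) to a feature."""

    compound: str
    index: Tuple[int, ...]
    theoretical_mz: float
    matched_feature_id: Optional[str]
    observed_mz: float
    ppm_error: float
    rt_error_s: float
    intensities: Dict[str, float]

    @property
    def matched(self) -> bool:
        return self.matched_feature_id is not None


def _read_delimited(path) -> pd.DataFrame:
    # autodetect comma/tab; skip metadata header comments
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.empty:
        raise ValueError(f"empty table: {path}")
    return df


def read_sample_metadata(path) -> pd.DataFrame:
    meta = _read_delimited(path)
    required = {"sample_id", "time_h", "replicate"}
    if not required.issubset(meta.columns):
        raise ValueError(f"sample metadata needs columns {sorted(required)}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    return meta


def read_feature_table(
    path,
    metadata: pd.DataFrame | str,
    column_map: Optional[Dict[str, str]] = None,
) -> FeatureTable:
    """Read an XCMS/MZmine-style delimited feature export.

    ``column_map`` renames nonstandard headers (e.g. {"mzmed": "mz"}).
    Sample columns are those named in the metadata's sample_id column.
    """
    df = _read_delimited(path)
    if column_map:
        df = df.rename(columns=column_map)
    if isinstance(metadata, (str, bytes)) or hasattr(metadata, "read"):
        metadata = read_sample_metadata(metadata)
    for col in ("mz", "rt"):
        if col not in df.columns:
            raise ValueError(f"feature table lacks column {col!r}")
    if "feature_id" not in df.columns:
        df.insert(0, "feature_id", [f"F{i:05d}" for i in range(len(df))])
    df["feature_id"] = df["feature_id"].astype(str)
    sample_cols = [str(s) for s in metadata["sample_id"]]
    df.columns = [str(c) for c in df.columns]
    for s in sample_cols:
        if s not in df.columns:
            raise ValueError(f"sample column {s!r} missing from feature table")
        if not np.issubdtype(df[s].dtype, np.number):
            raise ValueError(f"non-numeric intensities in sample column {s!r}")
    dup = df["feature_id"].duplicated()
    if dup.any():
        warnings.warn(f"{dup.sum()} duplicated feature rows preserved", stacklevel=2)
    return FeatureTable(
        data=df[["feature_id", "mz", "rt", *sample_cols]].copy(), metadata=metadata
    )


def read_compound_db(path) -> pd.DataFrame:
    """Compound library: name, formula, rt_seconds, adduct[, polarity, pool_nmol]."""
    db = _read_delimited(path)
    required = {"name", "formula", "rt_seconds", "adduct"}
    if not required.issubset(db.columns):
        raise ValueError(f"compound database needs columns {sorted(required)}")
    if "carbon_count" not in db.columns:
        db["carbon_count"] = [parse_formula(f)["C"] for f in db["formula"]]
    return db


def match_isotopologues(
    features: FeatureTable,
    grid: IsotopologueGrid,
    compound_rt: float,
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol_s: float = DEFAULT_RT_TOL_S,
) -> List[IsotopologueMeasurement]:
    """Match every grid isotopologue against the feature table.

    Candidates must sit within the RT window around the library RT and the
    ppm window around the theoretical m/z.  Within a compound each feature
    serves at most one grid index (its nearest theoretical m/z); for each
    index the candidate with the smallest |ppm error| wins, ties broken by
    higher summed intensity.  Unmatched indices are kept with zero
    intensities — absence is data.
    """
    if mz_tol_ppm <= 0 or rt_tol_s <= 0:
        raise ValueError("tolerances must be positive")
    df = features.data
    sample_ids = features.sample_ids
    in_rt = df[(df["rt"] - compound_rt).abs() <= rt_tol_s]

    mz = in_rt["mz"].to_numpy()
    # nearest grid index per candidate feature (within-compound uniqueness)
    nearest_idx = (
        np.abs(mz[:, None] - grid.theoretical_mz[None, :]).argmin(axis=1)
        if len(in_rt)
        else np.array([], dtype=int)
    )

    out: List[IsotopologueMeasurement] = []
    for j, (index, theo) in enumerate(zip(grid.indices, grid.theoretical_mz)):
        ppm = (mz - theo) / theo * 1e6
        cand = np.flatnonzero((np.abs(ppm) <= mz_tol_ppm) & (nearest_idx == j))
        if len(cand):
            abs_ppm = np.abs(ppm[cand])
            best = abs_ppm.min()
            tied = cand[np.isclose(abs_ppm, best, rtol=0, atol=1e-12)]
            if len(tied) > 1:
                sums = in_rt.iloc[tied][sample_ids].sum(axis=1).to_numpy()
                row = in_rt.iloc[tied[int(np.argmax(sums))]]
            else:
                row = in_rt.iloc[int(tied[0])]
            out.append(
                IsotopologueMeasurement(
                    compound=grid.compound,
                    index=index,
                    theoretical_mz=float(theo),
                    matched_feature_id=str(row["feature_id"]),
                    observed_mz=float(row["mz"]),
                    ppm_error=float((row["mz"] - theo) / theo * 1e6),
                    rt_error_s=float(row["rt"] - compound_rt),
                    intensities={s: float(row[s]) for s in sample_ids},
                )
            )
        else:
            out.append(
                IsotopologueMeasurement(
                    compound=grid.compound,
                    index=index,
                    theoretical_mz=float(theo),
                    matched_feature_id=None,
                    observed_mz=float("nan"),
                    ppm_error=float("nan"),
                    rt_error_s=float("nan"),
                    intensities={s: 0.0 for s in sample_ids},
                )
            )
    return out


def compound_identified(
    measurements: Sequence[IsotopologueMeasurement],
    metadata: Optional[pd.DataFrame] = None,
    require_time0: bool = True,
) -> bool:
    """A compound counts as identified when its M0 isotopologue matched.

    With metadata and ``require_time0``, M0 must additionally carry signal
    in at least one unlabeled (time 0) sample — the reference channel that
    anchors the labeling time course.
    """
    m0 = next(m for m in measurements if all(i == 0 for i in m.index))
    if not m0.matched:
        return False
    if require_time0 and metadata is not None and (metadata["time_h"] == 0).any():
        t0 = metadata.loc[metadata["time_h"] == 0, "sample_id"].astype(str)
        return any(m0.intensities.get(s, 0.0) > 0 for s in t0)
    return True


def assemble_intensity_matrix(
    measurements: Sequence[IsotopologueMeasurement],
    metadata: pd.DataFrame,
) -> Tuple[np.ndarray, List[str]]:
    """Dense [isotopologue x sample] matrix in grid order.

    Columns follow the canonical sample order (time_h, then replicate);
    the same matrix results from any permutation of the input sample order.
    """
    compounds = {m.compound for m in measurements}
    if len(compounds) != 1:
        raise ValueError(f"measurements span multiple compounds: {compounds}")
    meta = metadata.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    order = list(
        meta.sort_values(["time_h", "replicate", "sample_id"])["sample_id"]
    )
    for m in measurements:
        if set(order) - set(m.intensities):
            raise ValueError("inconsistent sample sets across measurements")
    mat = np.array([[m.intensities[s] for s in order] for m in measurements])
    if np.any(mat < 0):
        raise ValueError("negative intensity")
    return mat, order
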