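"""Table export with provenance headers and flux-software-ready MID tables.

Every table is written as delimited text with a ``#``-prefixed metadata
header (software version, config hash, seed) so outputs are traceable and
re-importable: ``read_table`` round-trips any file written here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chem import IsotopologueGrid, project_marginal, project_nominal

__all__ = ["write_table", "read_table", "export_flux_tables"]


def write_table(
    df: pd.DataFrame,
    path,
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
    index: bool = False,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# isoscope-version: {__version__}\n")
        if config_hash is not None:
            fh.write(f"# config-hash: {config_hash}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, index=index)
    return path


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def export_flux_tables(
    grid: IsotopologueGrid,
    corrected_mids: np.ndarray,
    sample_ids: Sequence[str],
) -> Dict[str, pd.DataFrame]:
    """MID tables in the layout downstream flux software ingests.

    For a dual-tracer grid three views are emitted per compound: one
    marginal per tracer (rows M+0..M+N_e) and the nominal sum (rows
    M+0..M+(sum N_e)); a single-tracer grid yields its one marginal plus
    the identical nominal view.  Columns are samples; rows are labeled
    ``M+k``.
    """
    corrected = np.asarray(corrected_mids, dtype=float)
    if corrected.shape != (len(grid), len(sample_ids)):
        raise ValueError("corrected MID matrix shape mismatch")
    out: Dict[str, pd.DataFrame] = {}
    for t in grid.tracers:
        marg = np.column_stack(
            [project_marginal(grid, corrected[:, i], t) for i in range(corrected.shape[1])]
        )
        out[f"marginal_{t.label}"] = pd.DataFrame(
            marg,
            index=[f"M+{k}" for k in range(marg.shape[0])],
            columns=list(sample_ids),
        )
    nom = np.column_stack(
        [project_nominal(grid, corrected[:, i]) for i in range(corrected.shape[1])]
    )
    out["nominal"] = pd.DataFrame(
        nom, index=[f"M+{k}" for k in range(nom.shape[0])], columns=list(sample_ids)
    )
    return out
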