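"""Run configuration: tracers, tolerances, correction settings, paths."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .chem import ADDUCTS, ISOTOPE_MASS_SHIFT, AdductSpec, TracerSpec

__all__ = ["RunConfig", "load_config"]

_KNOWN_TRACERS = {
    "13C": ("C", ISOTOPE_MASS_SHIFT["13C"]),
    "15N": ("N", ISOTOPE_MASS_SHIFT["15N"]),
    "2H": ("H", ISOTOPE_MASS_SHIFT["2H"]),
}


@dataclass
class RunConfig:
    """Validated settings shared by every pipeline stage.

    Serialized (with a content hash) into the metadata header of every
    output table so results are traceable to their settings.
    """

    tracers: List[str] = field(default_factory=lambda: ["13C", "15N"])
    tracer_purity: Dict[str, float] = field(default_factory=dict)
    mz_tol_ppm: float = 5.0
    rt_tol_s: float = 10.0
    correction_mode: str = "resolved"
    instrument_resolution: float = 140_000.0
    resolution_reference_mz: float = 200.0
    seed: int = 0
    features_path: Optional[str] = None
    compound_db_path: Optional[str] = None
    metadata_path: Optional[str] = None
    output_dir: str = "isoscope_out"
    cluster_k: int = 3
    cluster_metric: str = "nmol_labeled"
    make_plots: bool = False
    extra_adducts: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        if self.mz_tol_ppm <= 0 or self.rt_tol_s <= 0:
            raise ValueError("tolerances must be positive")
        if self.correction_mode not in ("resolved", "nominal"):
            raise ValueError(f"invalid correction_mode {self.correction_mode!r}")
        if self.instrument_resolution <= 0:
            raise ValueError("instrument_resolution must be positive")
        for t in self.tracers:
            if t not in _KNOWN_TRACERS:
                raise ValueError(f"unknown tracer {t!r}; known: {sorted(_KNOWN_TRACERS)}")
        for t, p in self.tracer_purity.items():
            if not (0 < p <= 1):
                raise ValueError(f"purity for {t} outside (0, 1]")

    def tracer_specs(self) -> List[TracerSpec]:
        out = []
        for t in self.tracers:
            el, shift = _KNOWN_TRACERS[t]
            out.append(TracerSpec(el, shift, t, purity=self.tracer_purity.get(t, 1.0)))
        return out

    def adduct_table(self) -> Dict[str, AdductSpec]:
        table = dict(ADDUCTS)
        for name, d in self.extra_adducts.items():
            table[name] = AdductSpec(name, d["formula_delta"], int(d["charge"]))
        return table

    def content_hash(self) -> str:
        """Hash of the analysis-relevant settings (paths excluded, so the
        same analysis rerun from a different directory hashes identically)."""
        d = asdict(self)
        for key in ("features_path", "compound_db_path", "metadata_path", "output_dir"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
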