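"""Run configuration: the file-backed knobs binding the workflow together.

Every default that fills a gap the underlying method leaves open (FA pool,
co-elution tolerance, multiplicity ratio bands, retention-model
coefficients, internal-standard map) lives here so it is visible and
overridable from one YAML file; ``lipidmrm config --show-defaults`` prints
the full set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .chem import FattyAcyl
from .panel import DEFAULT_FA_POOL
from .resolve import RATIO_TOL, RT_TOL_MIN
from .simulate import DEFAULT_RETENTION_MODELS, GAUSS_SIGMA_MIN, NoiseParams

__all__ = ["RunConfig", "load_config", "DEFAULT_IS_MAP", "DEFAULT_POLAR_RT_MIN"]

#: Default class -> (internal standard species, spiked nmol) map, following
#: the platform's glycerol-D5 standard mix plus hydrogenated galactolipids.
DEFAULT_IS_MAP: Mapping[str, tuple[str, float]] = {
    "MG": ("MG 17:0", 1.0),
    "DG": ("DG 35:1 (17:0_18:1)[D5]", 1.0),
    "TG": ("TG 53:3 (18:1_17:1_18:1)[D5]", 1.0),
    "MGDG": ("MGDG 34:0 (16:0_18:0)", 25.0),
    "DGDG": ("DGDG 36:0 (18:0_18:0)", 25.0),
    "PC": ("PC 31:1 (14:1_17:0)[D5]", 1.0),
    "PE": ("PE 31:1 (14:1_17:0)[D5]", 1.0),
    "PG": ("PG 31:1 (14:1_17:0)[D5]", 1.0),
    "PI": ("PI 31:1 (14:1_17:0)[D5]", 1.0),
    "PS": ("PS 31:1 (14:1_17:0)[D5]", 1.0),
    "LPC": ("LPC 15:0[D5]", 1.0),
    "LPE": ("LPE 15:0[D5]", 1.0),
    "LPG": ("LPG 15:0[D5]", 1.0),
    "LPI": ("LPI 15:0[D5]", 1.0),
    "LPS": ("LPS 15:0[D5]", 1.0),
}

#: Expected retention times (min) for the scheduled polar panel's internal
#: standards on the amine HILIC method.
DEFAULT_POLAR_RT_MIN: Mapping[str, float] = {
    "MGDG 34:0 (16:0_18:0)": 2.8,
    "DGDG 36:0 (18:0_18:0)": 4.5,
    "LPC 15:0[D5]": 5.3,
    "LPE 15:0[D5]": 7.7,
    "LPG 15:0[D5]": 9.0,
    "LPI 15:0[D5]": 10.1,
    "LPS 15:0[D5]": 12.4,
    "PC 31:1 (14:1_17:0)[D5]": 3.9,
    "PE 31:1 (14:1_17:0)[D5]": 6.3,
    "PG 31:1 (14:1_17:0)[D5]": 7.6,
    "PI 31:1 (14:1_17:0)[D5]": 8.7,
    "PS 31:1 (14:1_17:0)[D5]": 10.1,
    "LPE 18:1": 7.5,
}


@dataclass
class RunConfig:
    fa_pool: tuple[str, ...] = tuple(fa.name for fa in DEFAULT_FA_POOL)
    is_map: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_IS_MAP.items()})
    tissue_mg: dict = field(default_factory=dict)  # sample -> mg
    polar_rt_min: dict = field(default_factory=lambda: dict(DEFAULT_POLAR_RT_MIN))
    rt_tol_min: float = RT_TOL_MIN
    ratio_tol: tuple[float, float] = RATIO_TOL
    mz_decimals: int = 1
    peak_sigma_min: float = GAUSS_SIGMA_MIN
    baseline_frac: float = NoiseParams().baseline_frac
    noise_cv: float = NoiseParams().noise_cv
    rt_jitter_sd: float = NoiseParams().rt_jitter_sd
    retention: dict = field(
        default_factory=lambda: {
            cls: {
                "intercept": m.intercept,
                "coef_c": m.coef_c,
                "coef_db": m.coef_db,
                "window": list(m.window),
            }
            for cls, m in DEFAULT_RETENTION_MODELS.items()
        }
    )
    seed: int = 0
    outdir: str = "lipidmrm_out"

    def __post_init__(self):
        if self.rt_tol_min <= 0 or self.peak_sigma_min <= 0:
            raise ValueError("tolerances must be positive")
        lo, hi = self.ratio_tol
        if not (0 < lo < 1 <= hi):
            raise ValueError("ratio tolerance band must bracket 1")
        for fa in self.fa_pool:  # must be parseable
            FattyAcyl.parse(fa)

    @property
    def pool(self) -> tuple[FattyAcyl, ...]:
        return tuple(FattyAcyl.parse(fa) for fa in self.fa_pool)

    @property
    def noise(self) -> NoiseParams:
        return NoiseParams(self.baseline_frac, self.noise_cv, self.rt_jitter_sd)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["ratio_tol"] = list(self.ratio_tol)
        return d

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "ratio_tol" in data:
        data["ratio_tol"] = tuple(data["ratio_tol"])
    if "fa_pool" in data:
        data["fa_pool"] = tuple(data["fa_pool"])
    return RunConfig(**data)
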