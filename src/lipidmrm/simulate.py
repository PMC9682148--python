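"""Synthetic MRM chromatogram generator.

Emulates the structure the acyl-composition resolver relies on, without an
instrument: every fatty-acid neutral-loss channel of one TG molecular
species co-elutes as a Gaussian peak at a retention time predicted from a
reverse-phase elution model, with channel height proportional to
abundance x FA multiplicity (the 18:3_22:1_22:1 pattern, where the 22:1
channel runs at twice the 18:3 channel).  Noise is an additive baseline
plus a Gaussian term proportional to the local signal; all randomness is
driven by a seeded generator, so traces are bitwise reproducible.

What it does *not* emulate: gradient programs, peak asymmetry, ion
suppression, isotope envelopes, or per-species response-factor
differences (all channels share one response factor, as the downstream
quantification assumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import FattyAcyl, LipidSpecies, MRMTransition
from .panel import DEFAULT_FA_POOL, TGComposition

__all__ = [
    "RetentionModel",
    "DEFAULT_RETENTION_MODELS",
    "NoiseParams",
    "SyntheticSample",
    "XICTrace",
    "predict_rt",
    "make_trace",
    "simulate_xics",
    "peak_area_analytic",
    "simulate_area_table",
    "random_tg_sample",
    "GAUSS_SIGMA_MIN",
    "RESPONSE_PER_NMOL",
]

#: Default Gaussian peak sigma (minutes), consistent with baseline-resolved
#: isobaric TG species ~0.5 min apart on a C30 core-shell column.
GAUSS_SIGMA_MIN = 0.08

#: Detector response: peak apex height (counts) per nmol of analyte.
RESPONSE_PER_NMOL = 1.0e5


@dataclass(frozen=True)
class RetentionModel:
    """Linear reverse-phase elution model for one lipid class.

    ``rt = intercept + coef_c * total_C - coef_db * total_DB``, clipped to
    the class elution window.  Longer chains retain more strongly, double
    bonds weaken retention — the equivalent-carbon-number behaviour of
    reverse-phase lipid chromatography.  The defaults use coef_db =
    2 x coef_c (retention driven by ECN = C - 2*DB) and are anchored on
    observed class elution extremes.
    """

    intercept: float
    coef_c: float
    coef_db: float
    window: tuple[float, float]
    jitter_sd: float = 0.0  # min, between-channel jitter (0 = ideal co-elution)

    def __post_init__(self):
        if self.coef_c <= 0 or self.coef_db <= 0:
            raise ValueError("retention coefficients must be positive")

    def rt(self, total_c: int, total_db: int) -> float:
        raw = self.intercept + self.coef_c * total_c - self.coef_db * total_db
        return float(np.clip(raw, *self.window))


def _ecn_model(ecn1, rt1, ecn2, rt2, window) -> RetentionModel:
    k = (rt2 - rt1) / (ecn2 - ecn1)
    return RetentionModel(rt1 - k * ecn1, k, 2 * k, window)


#: Per-class defaults anchored on the platform's observed elution ranges:
#: MG 1.8-3.9 min, DG 5.2-15.9 min, TG 9.7-26.7 min.
DEFAULT_RETENTION_MODELS: Mapping[str, RetentionModel] = {
    "MG": _ecn_model(17, 2.3, 22, 3.9, (1.8, 3.9)),
    "DG": _ecn_model(29, 5.2, 44, 15.9, (5.2, 15.9)),
    "TG": _ecn_model(36, 9.7, 66, 26.7, (9.7, 26.7)),
}


def predict_rt(
    s: LipidSpecies | TGComposition,
    model: RetentionModel | None = None,
) -> float:
    """Predicted apex retention time (minutes) for a species with explicit
    chains (or a TG composition)."""
    if isinstance(s, TGComposition):
        c, db = s.total_carbons, s.total_double_bonds
        model = model or DEFAULT_RETENTION_MODELS["TG"]
    else:
        if s.chains is None and model is None:
            raise ValueError("explicit chains (or a model) required")
        c, db = s.carbons, s.double_bonds
        model = model or DEFAULT_RETENTION_MODELS[s.lipid_class]
    return model.rt(c, db)


@dataclass(frozen=True)
class NoiseParams:
    """Noise model: constant baseline (as a fraction of the internal-
    standard apex height) plus Gaussian noise with SD proportional to the
    local intensity."""

    baseline_frac: float = 0.005
    noise_cv: float = 0.02
    rt_jitter_sd: float = 0.0  # min, per-channel apex jitter

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(baseline_frac=0.0, noise_cv=0.0, rt_jitter_sd=0.0)


@dataclass(frozen=True)
class SyntheticSample:
    """Ground truth for one simulated extract."""

    name: str
    species: tuple[tuple[LipidSpecies, float], ...]  # (species, nmol)
    tissue_mg: float = 10.0
    is_spikes: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    # lipid class -> (IS species name, spiked nmol)

    def __post_init__(self):
        if self.tissue_mg <= 0:
            raise ValueError("tissue mass must be positive")
        for sp, nmol in self.species:
            if nmol < 0:
                raise ValueError(f"negative abundance for {sp.name}")


@dataclass
class XICTrace:
    """Time/intensity series for one MRM transition."""

    transition: MRMTransition
    times: np.ndarray  # minutes, uniform, strictly increasing
    intensities: np.ndarray  # counts, >= 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("time grid must be a 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def transition_id(self) -> str:
        return self.transition.transition_id


def _gauss(t: np.ndarray, apex: float, height: float, sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((t - apex) / sigma) ** 2)


def _max_is_height(sample: SyntheticSample) -> float:
    spikes = [nmol for _, nmol in sample.is_spikes.values()]
    ref_nmol = max(spikes) if spikes else 1.0
    return ref_nmol * RESPONSE_PER_NMOL


def simulate_xics(
    sample: SyntheticSample,
    panel: Sequence[MRMTransition],
    model: RetentionModel | None = None,
    noise: NoiseParams = NoiseParams(),
    seed: int | np.random.Generator = 0,
    grid_step: float = 0.01,
    sigma: float = GAUSS_SIGMA_MIN,
    window: tuple[float, float] | None = None,
) -> list[XICTrace]:
    """Simulate one XIC per panel transition.

    Each ground-truth species with explicit chains contributes a Gaussian
    peak to every acyl-loss channel whose FA occurs in its composition,
    with apex height = nmol x multiplicity x response factor.  Species
    whose precursor has no transition in the panel are skipped with a
    warning.
    """
    import warnings

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = model or DEFAULT_RETENTION_MODELS["TG"]
    if window is None:
        lo, hi = model.window
        window = (lo - 1.0, hi + 1.0)
    times = np.arange(window[0], window[1] + grid_step / 2, grid_step)

    by_precursor: dict[tuple[int, int], list[MRMTransition]] = {}
    for t in panel:
        by_precursor.setdefault(t.species.sum_composition, []).append(t)

    # peaks per transition id
    peaks: dict[str, list[tuple[float, float]]] = {t.transition_id: [] for t in panel}
    baseline = noise.baseline_frac * _max_is_height(sample)
    for sp, nmol in sample.species:
        if sp.chains is None:
            warnings.warn(f"{sp.name}: no explicit chains, skipped", stacklevel=2)
            continue
        trans = by_precursor.get(sp.sum_composition)
        if not trans:
            warnings.warn(f"{sp.name}: no panel transition, skipped", stacklevel=2)
            continue
        apex_rt = model.rt(sp.carbons, sp.double_bonds)
        comp = TGComposition(sp.chains) if sp.lipid_class == "TG" else None
        for t in trans:
            fa = None
            if t.channel.startswith("acyl_loss:"):
                fa = FattyAcyl.parse(t.channel.split(":", 1)[1])
            if comp is not None and fa is not None:
                mult = comp.multiplicity(fa)
                if mult == 0:
                    continue
            else:
                mult = 1
            jitter = rng.normal(0.0, noise.rt_jitter_sd) if noise.rt_jitter_sd else 0.0
            height = nmol * mult * RESPONSE_PER_NMOL
            peaks[t.transition_id].append((apex_rt + jitter, height))

    traces = []
    for t in panel:
        signal = np.zeros_like(times)
        for apex, height in peaks[t.transition_id]:
            signal += _gauss(times, apex, height, sigma)
        intensity = signal + baseline
        if noise.noise_cv > 0:
            intensity = intensity + rng.normal(0.0, noise.noise_cv * (intensity + 1.0))
        traces.append(XICTrace(t, times, np.clip(intensity, 0.0, None)))
    return traces


def make_trace(
    transition: MRMTransition,
    peaks: Sequence[tuple[float, float]],
    window: tuple[float, float],
    grid_step: float = 0.01,
    sigma: float = GAUSS_SIGMA_MIN,
    baseline: float = 0.0,
) -> XICTrace:
    """Construct an XIC with Gaussian peaks at explicit (rt, height)
    positions — the building block for scripted co-elution scenarios where
    apex positions are dictated rather than modelled."""
    times = np.arange(window[0], window[1] + grid_step / 2, grid_step)
    signal = np.full_like(times, baseline, dtype=float)
    for apex, height in peaks:
        signal += _gauss(times, apex, height, sigma)
    return XICTrace(transition, times, signal)


def peak_area_analytic(height: float, sigma: float = GAUSS_SIGMA_MIN) -> float:
    """Closed-form area of a Gaussian peak (height x sigma x sqrt(2 pi))."""
    return height * sigma * np.sqrt(2.0 * np.pi)


def simulate_area_table(
    samples: Iterable[SyntheticSample],
    species_rows: Sequence[str] | None = None,
    noise: NoiseParams = NoiseParams(),
    seed: int | np.random.Generator = 0,
    sigma: float = GAUSS_SIGMA_MIN,
) -> pd.DataFrame:
    """Wide peak-area table (rows = species and IS rows, columns =
    samples), consistent with integrating the simulated XICs.

    Areas are the analytic Gaussian integrals of the peaks, with the same
    relative noise the traces carry.  Internal-standard rows are named by
    the IS species with an ``IS:`` prefix and carry the spiked amounts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = list(samples)
    rows: list[str] = list(species_rows) if species_rows is not None else []
    if species_rows is None:
        seen = dict()
        for s in samples:
            for sp, _ in s.species:
                seen.setdefault(sp.name, None)
            for cls, (is_name, _) in s.is_spikes.items():
                seen.setdefault(f"IS:{is_name}", None)
        rows = list(seen)

    table = pd.DataFrame(0.0, index=rows, columns=[s.name for s in samples])
    for s in samples:
        amounts = {sp.name: nmol for sp, nmol in s.species}
        for cls, (is_name, nmol) in s.is_spikes.items():
            amounts[f"IS:{is_name}"] = nmol
        for row in rows:
            nmol = amounts.get(row, 0.0)
            if nmol <= 0:
                continue
            area = peak_area_analytic(nmol * RESPONSE_PER_NMOL, sigma)
            if noise.noise_cv > 0:
                area *= 1.0 + rng.normal(0.0, noise.noise_cv)
            table.loc[row, s.name] = max(area, 0.0)
    return table


def random_tg_sample(
    name: str,
    rng: np.random.Generator,
    n_species: int = 10,
    pool: Sequence[FattyAcyl] = DEFAULT_FA_POOL,
    nmol_range: tuple[float, float] = (0.5, 20.0),
    tissue_mg: float = 10.0,
    is_spikes: Mapping[str, tuple[str, float]] | None = None,
) -> SyntheticSample:
    """Draw a ground-truth TG sample: *n_species* compositions from the
    pool with distinct sum compositions (isobaric pairs co-elute exactly
    under the deterministic retention model and are therefore excluded
    from the default study conditions) and log-uniform abundances."""
    from itertools import combinations_with_replacement

    all_trips = [
        TGComposition(t) for t in combinations_with_replacement(sorted(pool), 3)
    ]
    rng.shuffle(all_trips)
    chosen: list[TGComposition] = []
    seen_sum: set[tuple[int, int]] = set()
    for comp in all_trips:
        key = (comp.total_carbons, comp.total_double_bonds)
        if key in seen_sum:
            continue
        seen_sum.add(key)
        chosen.append(comp)
        if len(chosen) == n_species:
            break
    species = tuple(
        (
            LipidSpecies.from_chains("TG", comp.fas),
            float(np.exp(rng.uniform(np.log(nmol_range[0]), np.log(nmol_range[1])))),
        )
        for comp in chosen
    )
    if is_spikes is None:
        is_spikes = {"TG": ("TG 53:3 (18:1_17:1_18:1)[D5]", 1.0)}
    return SyntheticSample(
        name=name, species=species, tissue_mg=tissue_mg, is_spikes=dict(is_spikes)
    )
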