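"""Internal-standard normalization and quantitative summaries.

Quantification is single-point: each lipid class has one spiked internal
standard (IS), and an analyte's amount is

    nmol/mg = area x IS_nmol / IS_area / tissue_mg

— the integrated analyte peak scaled by the molar amount of the class IS,
divided by the IS peak area and the extracted tissue mass.  TG molecular
species use divisor-corrected areas from the acyl-composition resolver so
that triplets with repeated fatty acids are not over-counted.

Summaries: per-class totals (mean and sample SD over replicates), fatty
acid mol% derived from resolved TG triplets, and a statistics-ready
samples x features export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import FattyAcyl, parse_species
from .panel import TGComposition
from .resolve import CompositionCall

__all__ = [
    "ISMap",
    "normalize_species",
    "quantify_area_table",
    "quantify_calls",
    "class_totals",
    "fa_mol_percent",
    "export_stats_table",
]


@dataclass(frozen=True)
class ISMap:
    """Per-class internal standard: class -> (IS row id, spiked nmol)."""

    standards: Mapping[str, tuple[str, float]]

    def __post_init__(self):
        for cls, (name, nmol) in self.standards.items():
            if nmol <= 0:
                raise ValueError(f"IS amount for class {cls} must be positive")

    def __getitem__(self, cls: str) -> tuple[str, float]:
        return self.standards[cls]

    def __contains__(self, cls: str) -> bool:
        return cls in self.standards

    def classes(self) -> tuple[str, ...]:
        return tuple(self.standards)


def normalize_species(
    area: float, is_area: float, is_nmol: float, tissue_mg: float
) -> float:
    """area x IS_nmol / IS_area / tissue_mg -> nmol per mg tissue."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    if tissue_mg <= 0:
        raise ValueError("tissue mass must be positive")
    return area * is_nmol / is_area / tissue_mg


def quantify_area_table(
    areas: pd.DataFrame,
    is_map: ISMap,
    tissue_mg: Mapping[str, float],
) -> pd.DataFrame:
    """Normalize a wide peak-area table (rows = species ids plus ``IS:``
    rows, columns = samples) to nmol/mg.

    Returns a tidy frame: sample, lipid_class, species, nmol_per_mg.
    Raises a named error when a sample's class IS row is missing or zero.
    """
    records = []
    for sample in areas.columns:
        if sample not in tissue_mg:
            raise ValueError(f"no tissue mass for sample {sample!r}")
        mg = tissue_mg[sample]
        for row in areas.index:
            if row.startswith("IS:"):
                continue
            sp = parse_species(row)
            cls = sp.lipid_class
            if cls not in is_map:
                raise ValueError(f"no internal standard configured for class {cls}")
            is_name, is_nmol = is_map[cls]
            is_row = f"IS:{is_name}"
            if is_row not in areas.index:
                raise ValueError(
                    f"internal-standard row {is_row!r} missing from the area table"
                )
            is_area = float(areas.loc[is_row, sample])
            if is_area <= 0:
                raise ValueError(
                    f"internal standard {is_name!r} has zero area in sample "
                    f"{sample!r} (class {cls})"
                )
            records.append(
                {
                    "sample": sample,
                    "lipid_class": cls,
                    "species": sp.name,
                    "nmol_per_mg": normalize_species(
                        float(areas.loc[row, sample]), is_area, is_nmol, mg
                    ),
                }
            )
    return pd.DataFrame.from_records(records)


def quantify_calls(
    calls: Sequence[CompositionCall],
    is_area: float,
    is_nmol: float,
    tissue_mg: float,
    sample: str = "",
    include_tentative: bool = False,
) -> pd.DataFrame:
    """nmol/mg per resolved TG molecular species from divisor-corrected
    quantifier areas.  Tentative calls are excluded by default and, when
    included, carry their flags."""
    records = []
    for c in calls:
        if c.confidence != "confirmed" and not include_tentative:
            continue
        if c.area_corrected is None:
            continue
        records.append(
            {
                "sample": sample,
                "lipid_class": "TG",
                "species": f"TG {c.precursor[0]}:{c.precursor[1]} ({c.composition.name})",
                "composition": c.composition.name,
                "confidence": c.confidence,
                "nmol_per_mg": normalize_species(
                    c.area_corrected, is_area, is_nmol, tissue_mg
                ),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "sample",
            "lipid_class",
            "species",
            "composition",
            "confidence",
            "nmol_per_mg",
        ],
    )


def class_totals(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-class totals: sum species within each sample, then mean and
    sample (n-1) SD across replicate samples.  With a single replicate the
    SD column is left empty."""
    per_sample = (
        quant.groupby(["lipid_class", "sample"])["nmol_per_mg"].sum().reset_index()
    )
    out = (
        per_sample.groupby("lipid_class")["nmol_per_mg"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan, n="count")
        .reset_index()
    )
    return out


def fa_mol_percent(
    amounts: Iterable[tuple[TGComposition | str, float]]
) -> dict[str, float]:
    """Fatty-acid mol% of a TG profile.

    Each resolved triplet contributes amount x multiplicity moles of each
    of its FAs; percentages are over total FA moles and sum to 100.
    """
    mol: dict[FattyAcyl, float] = {}
    for comp, amount in amounts:
        if isinstance(comp, str):
            comp = TGComposition.parse(comp)
        for fa in comp.distinct_fas:
            mol[fa] = mol.get(fa, 0.0) + amount * comp.multiplicity(fa)
    total = sum(mol.values())
    if total <= 0:
        return {}
    return {fa.name: 100.0 * v / total for fa, v in sorted(mol.items())}


def export_stats_table(
    quant: pd.DataFrame, groups: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Samples x features table for downstream multivariate statistics,
    with an optional group-label column; feature columns follow the
    canonical (sorted) species order and values carry full precision."""
    wide = quant.pivot_table(
        index="sample", columns="species", values="nmol_per_mg", aggfunc="sum"
    ).sort_index(axis=1)
    wide.columns.name = None
    if groups is not None:
        wide.insert(0, "group", [groups.get(s, "") for s in wide.index])
    return wide.reset_index()
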