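"""MRM panel construction.

Two panels are produced:

* the **TG-FA panel** — for every triacylglycerol sum composition, all
  fatty-acid compositions consistent with the precursor mass are enumerated
  from a configurable fatty-acid pool, and one NH3+fatty-acid neutral-loss
  transition is emitted per distinct candidate FA; and
* the **scheduled polar panel** — one carboxylate (or headgroup) quantifier
  transition per polar species with a retention-time window.

Isobaric enumeration is the combinatorial heart of the acyl-composition
resolver: a TG precursor mass fixes only the total carbons and double
bonds, and each candidate triplet of pool FAs with matching totals is a
hypothesis the XIC overlay later accepts or rejects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Sequence

from .chem import (
    CHAIN_COUNT,
    FattyAcyl,
    LipidSpecies,
    MRMTransition,
    NONPOLAR_CLASSES,
    build_transition,
)

__all__ = [
    "DEFAULT_FA_POOL",
    "FattyAcidPool",
    "TGComposition",
    "enumerate_tg_compositions",
    "build_tg_panel",
    "build_polar_panel",
    "composition_table",
    "SCHEDULED_WINDOW_MIN",
]

#: Fatty acids expected in pennycress (field-pennycress seed/leaf tissue):
#: palmitic, stearic, oleic, linoleic, linolenic, arachidic, gondoic,
#: erucic and nervonic acids.
DEFAULT_FA_POOL: tuple[FattyAcyl, ...] = tuple(
    FattyAcyl.parse(t)
    for t in ("16:0", "18:0", "18:1", "18:2", "18:3", "20:0", "20:1", "22:1", "24:1")
)

#: Scheduled-MRM window width (minutes); 180 s centred on the expected RT.
SCHEDULED_WINDOW_MIN = 3.0


class FattyAcidPool(tuple):
    """An ordered, duplicate-free pool of allowed fatty acyls."""

    def __new__(cls, fas: Iterable[FattyAcyl | str] = DEFAULT_FA_POOL):
        items = tuple(
            fa if isinstance(fa, FattyAcyl) else FattyAcyl.parse(fa) for fa in fas
        )
        if not items:
            raise ValueError("fatty-acid pool must not be empty")
        if len(set(items)) != len(items):
            raise ValueError("fatty-acid pool contains duplicates")
        return super().__new__(cls, sorted(items))


@dataclass(frozen=True)
class TGComposition:
    """A multiset of exactly three fatty acyls assigned to one TG precursor."""

    fas: tuple[FattyAcyl, FattyAcyl, FattyAcyl]

    def __post_init__(self):
        object.__setattr__(self, "fas", tuple(sorted(self.fas)))
        if len(self.fas) != 3:
            raise ValueError("a TG composition has exactly 3 chains")

    @property
    def total_carbons(self) -> int:
        return sum(fa.carbons for fa in self.fas)

    @property
    def total_double_bonds(self) -> int:
        return sum(fa.double_bonds for fa in self.fas)

    @property
    def distinct_fas(self) -> tuple[FattyAcyl, ...]:
        return tuple(dict.fromkeys(self.fas))

    def multiplicity(self, fa: FattyAcyl) -> int:
        return self.fas.count(fa)

    @property
    def name(self) -> str:
        return "_".join(fa.name for fa in self.fas)

    @classmethod
    def parse(cls, text: str) -> "TGComposition":
        return cls(tuple(FattyAcyl.parse(t) for t in text.split("_")))

    def __str__(self) -> str:
        return self.name


def enumerate_tg_compositions(
    total_c: int, total_db: int, pool: Sequence[FattyAcyl] = DEFAULT_FA_POOL
) -> list[TGComposition]:
    """All 3-multisets from *pool* whose carbons and double bonds sum to the
    precursor totals, in canonical (sorted) order.

    An empty result is valid: it means the pool cannot explain the
    precursor.
    """
    out = []
    for trip in combinations_with_replacement(sorted(pool), 3):
        if (
            sum(fa.carbons for fa in trip) == total_c
            and sum(fa.double_bonds for fa in trip) == total_db
        ):
            out.append(TGComposition(trip))
    for comp in out:  # conservation asserted on every call
        assert comp.total_carbons == total_c
        assert comp.total_double_bonds == total_db
    return sorted(out, key=lambda comp: comp.fas)


def build_tg_panel(
    tg_species: Iterable[LipidSpecies | str],
    pool: Sequence[FattyAcyl] = DEFAULT_FA_POOL,
) -> list[MRMTransition]:
    """One acyl-loss transition per distinct FA appearing in any candidate
    composition of each TG precursor; no duplicate (q1, q3) pairs.

    A TG with no candidate under the pool raises a warning and contributes
    no product channels.
    """
    from .chem import parse_species

    transitions: list[MRMTransition] = []
    seen: set[tuple[float, float]] = set()
    for sp in tg_species:
        if isinstance(sp, str):
            sp = parse_species(sp)
        if sp.lipid_class != "TG":
            raise ValueError(f"{sp.name} is not a TG")
        candidates = enumerate_tg_compositions(sp.carbons, sp.double_bonds, pool)
        if not candidates:
            warnings.warn(
                f"no candidate FA composition for {sp.name} under the pool",
                stacklevel=2,
            )
            continue
        fas = sorted({fa for comp in candidates for fa in comp.fas})
        for fa in fas:
            t = build_transition(sp, f"acyl_loss:{fa.name}")
            key = (round(t.q1_mz, 4), round(t.q3_mz, 4))
            if key not in seen:
                seen.add(key)
                transitions.append(t)
    return transitions


def _default_quantifier_fa(sp: LipidSpecies) -> FattyAcyl:
    """Quantifier FA for a polar species: the lower-product-m/z (lighter)
    chain, matching the platform's choice for its internal standards."""
    if sp.chains is None:
        if CHAIN_COUNT[sp.lipid_class] == 1:
            return FattyAcyl(sp.carbons, sp.double_bonds)
        raise ValueError(
            f"{sp.name}: explicit chains required to pick a quantifier FA"
        )
    return min(sp.chains, key=lambda fa: (fa.carbons, -fa.double_bonds))


def build_polar_panel(
    species: Iterable[LipidSpecies | str],
    rt_min: dict[str, float] | None = None,
    scheduled: bool = True,
    quantifier_fa: dict[str, FattyAcyl] | None = None,
) -> list[MRMTransition]:
    """Scheduled polar-lipid panel: one quantifier transition per species.

    ``rt_min`` maps species names to expected retention times (minutes);
    in scheduled mode every species must have one, and the transition gets
    a 180-second window centred on it.  Glycerol-D5 LPS species use the
    deuterated glycerophosphate headgroup fragment; every other class uses
    the carboxylate of the quantifier FA (override per species via
    ``quantifier_fa``).
    """
    from .chem import parse_species

    rt_min = rt_min or {}
    quantifier_fa = quantifier_fa or {}
    out: list[MRMTransition] = []
    for sp in species:
        if isinstance(sp, str):
            sp = parse_species(sp)
        if sp.lipid_class in NONPOLAR_CLASSES:
            raise ValueError(f"{sp.name} is not a polar class")
        if sp.lipid_class == "LPS" and sp.label == "D5":
            channel = "headgroup_d5"
        else:
            fa = quantifier_fa.get(sp.name) or _default_quantifier_fa(sp)
            channel = f"carboxylate:{fa.name}"
        window = None
        if scheduled:
            if sp.name not in rt_min:
                raise ValueError(
                    f"scheduled panel needs an expected RT for {sp.name}"
                )
            rt = rt_min[sp.name]
            window = (rt - SCHEDULED_WINDOW_MIN / 2, rt + SCHEDULED_WINDOW_MIN / 2)
        out.append(build_transition(sp, channel, rt_window=window))
    return out


def composition_table(
    tg_species: Iterable[LipidSpecies | str],
    pool: Sequence[FattyAcyl] = DEFAULT_FA_POOL,
) -> list[dict]:
    """Candidate-composition records: tg_species, composition, n_candidates."""
    from .chem import parse_species

    rows = []
    for sp in tg_species:
        if isinstance(sp, str):
            sp = parse_species(sp)
        candidates = enumerate_tg_compositions(sp.carbons, sp.double_bonds, pool)
        for comp in candidates:
            rows.append(
                {
                    "tg_species": sp.name,
                    "composition": comp.name,
                    "n_candidates": len(candidates),
                }
            )
    return rows
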