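"""Lipid nomenclature, elemental formulas, monoisotopic masses and MRM
transition chemistry.

The chemistry implemented here covers the lipid classes measured by a
two-method plant lipidomics platform: neutral acylglycerols (MG, DG, TG)
ionized in positive mode as ammonium adducts, and polar glycerolipids
(phospholipids, lysophospholipids and galactolipids) ionized in negative
mode as deprotonated species or, for (L)PC, acetate adducts.

Fragmentation channels:

* DG/TG  -- neutral loss of NH3 plus one fatty acid, leaving a mono- or
  diacylglycerol-like cation.
* MG     -- loss of NH3 + glycerol yields the fatty acyl acylium cation
  [RCO]+ (the default), or loss of NH3 + H2O (used for some saturated
  odd-chain standards).
* polar  -- the deprotonated fatty acid (carboxylate anion) of one chain.
* glycerol-D5 LPS -- a glycerophosphate-derived headgroup fragment
  (C3HD5O5P-) replaces the carboxylate.

All masses are monoisotopic, taken from the NIST atomic mass table shipped
with :mod:`pyteomics`, with electron-mass correction for charged species.
Deuterium is tracked as its own element symbol ``D``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

__all__ = [
    "ELEMENT_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "FattyAcyl",
    "LipidSpecies",
    "Adduct",
    "MRMTransition",
    "ADDUCTS",
    "LIPID_CLASSES",
    "CHAIN_COUNT",
    "formula_of_fatty_acyl",
    "formula_of_species",
    "monoisotopic_mz",
    "precursor_adduct",
    "precursor_mz",
    "product_formula",
    "product_mz",
    "build_transition",
    "parse_species",
    "round_mz",
    "transitions_to_csv",
]

# ---------------------------------------------------------------------------
# Atomic masses
# ---------------------------------------------------------------------------

ELEMENT_MASS: Mapping[str, float] = {
    "C": _pmass.nist_mass["C"][0][0],
    "H": _pmass.nist_mass["H"][0][0],
    "D": _pmass.nist_mass["H"][2][0],  # deuterium, distinct symbol
    "N": _pmass.nist_mass["N"][0][0],
    "O": _pmass.nist_mass["O"][0][0],
    "P": _pmass.nist_mass["P"][0][0],
}

ELECTRON_MASS: float = _pmass.nist_mass["e*"][0][0]

_ELEMENT_ORDER = ("C", "H", "D", "N", "O", "P")


def round_mz(x: float, decimals: int = 1) -> float:
    """Round half-up, as instrument method editors do (not banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Elemental formulas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts plus a net charge.

    Supports element-wise addition and subtraction; subtraction that would
    drive any count negative raises ``ValueError`` because it indicates an
    impossible neutral-loss bookkeeping step.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if el not in ELEMENT_MASS:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged, self.charge + other.charge)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(
                    f"subtraction gives negative {el} count "
                    f"({self.hill()} - {other.hill()})"
                )
        return ElementalFormula(merged, self.charge - other.charge)

    def with_charge(self, charge: int) -> "ElementalFormula":
        return replace(self, charge=charge)

    def substitute_h_with_d(self, n: int) -> "ElementalFormula":
        """Replace *n* hydrogens by deuterium (isotopic labelling)."""
        if self.counts.get("H", 0) < n:
            raise ValueError("not enough H to substitute")
        merged = dict(self.counts)
        merged["H"] -= n
        merged["D"] = merged.get("D", 0) + n
        return ElementalFormula(merged, self.charge)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da, electron-corrected for the charge."""
        m = sum(ELEMENT_MASS[el] * n for el, n in self.counts.items())
        return m - self.charge * ELECTRON_MASS

    def hill(self) -> str:
        parts = []
        for el in _ELEMENT_ORDER:
            n = self.counts.get(el, 0)
            if n:
                parts.append(el if n == 1 else f"{el}{n}")
        sign = {1: "+", -1: "-", 0: ""}.get(self.charge, f"{self.charge:+d}")
        return "".join(parts) + sign

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hill()


def F(charge: int = 0, **counts: int) -> ElementalFormula:
    """Terse constructor used for the fixed chemistry constants below."""
    return ElementalFormula(counts, charge)


WATER = F(H=2, O=1)
AMMONIA = F(N=1, H=3)
GLYCEROL = F(C=3, H=8, O=3)
PROTON = F(H=1)

# Headgroup deltas: the condensed headgroup contribution to the neutral
# species, i.e. head alcohol minus one H2O lost in the phosphodiester /
# glycosidic bond to the glycerol backbone.
_HEAD_DELTA: Mapping[str, ElementalFormula] = {
    "PC": F(C=5, H=12, N=1, O=3, P=1),  # phosphocholine - H2O
    "PE": F(C=2, H=6, N=1, O=3, P=1),  # phosphoethanolamine - H2O
    "PG": F(C=3, H=7, O=5, P=1),  # phosphoglycerol - H2O
    "PI": F(C=6, H=11, O=8, P=1),  # phosphoinositol - H2O
    "PS": F(C=3, H=6, N=1, O=5, P=1),  # phosphoserine - H2O
    "MGDG": F(C=6, H=10, O=5),  # one anhydro-galactose
    "DGDG": F(C=12, H=20, O=10),  # two anhydro-galactoses
}

# Glycerophosphate-derived headgroup fragment observed for glycerol-D5 LPS.
LPS_D5_HEAD_FRAGMENT = F(charge=-1, C=3, H=1, D=5, O=5, P=1)

CHAIN_COUNT: Mapping[str, int] = {
    "MG": 1,
    "LPC": 1,
    "LPE": 1,
    "LPG": 1,
    "LPI": 1,
    "LPS": 1,
    "DG": 2,
    "PC": 2,
    "PE": 2,
    "PG": 2,
    "PI": 2,
    "PS": 2,
    "MGDG": 2,
    "DGDG": 2,
    "TG": 3,
}

LIPID_CLASSES = tuple(CHAIN_COUNT)

NONPOLAR_CLASSES = frozenset({"MG", "DG", "TG"})


# ---------------------------------------------------------------------------
# Fatty acyls
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty acyl chain described by carbon count and double bonds.

    Double-bond positions are deliberately not modelled; the MRM chemistry
    only depends on the elemental composition.
    """

    carbons: int
    double_bonds: int = 0

    def __post_init__(self):
        if self.carbons < 2:
            raise ValueError(f"fatty acyl needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double bond count must be >= 0")
        if self.double_bonds > self.carbons / 2 - 1:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} is not a valid chain "
                "(too many double bonds)"
            )

    @property
    def name(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    @classmethod
    def parse(cls, token: str) -> "FattyAcyl":
        m = re.fullmatch(r"(\d+):(\d+)", token.strip())
        if not m:
            raise ValueError(f"cannot parse fatty acyl {token!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return self.name


def formula_of_fatty_acyl(fa: FattyAcyl, form: str = "free_acid") -> ElementalFormula:
    """Elemental formula of a fatty acyl in one of its three MRM-relevant
    incarnations.

    ``free_acid``          CnH(2n-2d)O2, neutral
    ``acylium_cation``     free acid - OH, charge +1   (e.g. C17H33O+)
    ``carboxylate_anion``  free acid - H, charge -1    (e.g. C18H35O2-)
    """
    n, d = fa.carbons, fa.double_bonds
    acid = F(C=n, H=2 * n - 2 * d, O=2)
    if form == "free_acid":
        return acid
    if form == "acylium_cation":
        return (acid - F(O=1, H=1)).with_charge(+1)
    if form == "carboxylate_anion":
        return (acid - F(H=1)).with_charge(-1)
    raise ValueError(f"unknown form {form!r}")


# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(
    r"""^\s*
    (?P<cls>[A-Z]+)
    [\s-]+
    (?P<c>\d+):(?P<db>\d+)
    \s*
    (?:\(\s*(?P<chains>[\d:/_\s]+?)\s*\))?
    \s*
    (?:\[(?P<label>[Dd]5)\])?
    \s*$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species: class, acyl chains (explicit or sum composition)
    and an optional glycerol-D5 label.

    Explicit chains are stored as a sorted tuple (an unordered multiset);
    sn-position information is not retained.
    """

    lipid_class: str
    carbons: int
    double_bonds: int
    chains: tuple[FattyAcyl, ...] | None = None
    label: str | None = None  # None or "D5"

    def __post_init__(self):
        if self.lipid_class not in CHAIN_COUNT:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.label not in (None, "D5"):
            raise ValueError(f"unsupported label {self.label!r}")
        if self.chains is not None:
            chains = tuple(sorted(self.chains))
            object.__setattr__(self, "chains", chains)
            if len(chains) != CHAIN_COUNT[self.lipid_class]:
                raise ValueError(
                    f"{self.lipid_class} takes {CHAIN_COUNT[self.lipid_class]} "
                    f"chains, got {len(chains)}"
                )
            c = sum(fa.carbons for fa in chains)
            db = sum(fa.double_bonds for fa in chains)
            if (c, db) != (self.carbons, self.double_bonds):
                raise ValueError(
                    f"chains {('_'.join(fa.name for fa in chains))} do not sum "
                    f"to {self.carbons}:{self.double_bonds}"
                )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_chains(
        cls, lipid_class: str, chains: Iterable[FattyAcyl | str], label: str | None = None
    ) -> "LipidSpecies":
        fas = tuple(
            fa if isinstance(fa, FattyAcyl) else FattyAcyl.parse(fa) for fa in chains
        )
        return cls(
            lipid_class,
            sum(fa.carbons for fa in fas),
            sum(fa.double_bonds for fa in fas),
            chains=fas,
            label=label,
        )

    @property
    def sum_composition(self) -> tuple[int, int]:
        return (self.carbons, self.double_bonds)

    @property
    def name(self) -> str:
        s = f"{self.lipid_class} {self.carbons}:{self.double_bonds}"
        if self.chains is not None and CHAIN_COUNT[self.lipid_class] > 1:
            s += " (" + "_".join(fa.name for fa in self.chains) + ")"
        if self.label:
            s += "[D5]"
        return s

    def __str__(self) -> str:
        return self.name


def parse_species(text: str) -> LipidSpecies:
    """Parse shorthand nomenclature.

    Accepted forms: ``"TG 58:5"``, ``"MG-17:0"``, ``"PC 34:2 (18:2_16:0)"``,
    ``"DG 44:2 (22:1/22:1)"``, ``"LPC-15:0[D5]"``. ``/`` separators (known
    sn-positions) are accepted but the position information is discarded;
    ``0:0`` placeholder chains are dropped.
    """
    m = _NAME_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse lipid species name {text!r}")
    lipid_class = m.group("cls")
    if lipid_class not in CHAIN_COUNT:
        raise ValueError(f"unknown lipid class {lipid_class!r} in {text!r}")
    chains = None
    if m.group("chains"):
        toks = [t for t in re.split(r"[/_]", m.group("chains")) if t.strip()]
        fas = [FattyAcyl.parse(t) for t in toks if t.strip() != "0:0"]
        chains = tuple(fas)
    label = "D5" if m.group("label") else None
    return LipidSpecies(
        lipid_class,
        int(m.group("c")),
        int(m.group("db")),
        chains=chains,
        label=label,
    )


def formula_of_species(s: LipidSpecies) -> ElementalFormula:
    """Neutral elemental formula: glycerol backbone + headgroup + acyls,
    minus one water per ester bond; the glycerol-D5 label substitutes five
    backbone hydrogens with deuterium.

    For the neutral acylglycerol classes the formula depends only on the
    sum composition, so explicit chains are not required there.
    """
    n_chains = CHAIN_COUNT[s.lipid_class]
    if s.chains is not None:
        acids = [formula_of_fatty_acyl(fa, "free_acid") for fa in s.chains]
        acyl_sum = sum(acids[1:], acids[0])
    else:
        # Sum-composition: total ester carbons/H depend only on totals.
        c, db = s.sum_composition
        acyl_sum = F(C=c, H=2 * c - 2 * db, O=2 * n_chains)
        # per-chain acid formula CnH(2n-2d)O2 summed over chains gives
        # H = 2*C_total - 2*DB_total regardless of the split
    f = GLYCEROL + acyl_sum
    for _ in range(n_chains):
        f = f - WATER
    cls = s.lipid_class
    head = _HEAD_DELTA.get(cls[1:] if cls.startswith("L") else cls)
    if head is not None:
        f = f + head
    if s.label == "D5":
        f = f.substitute_h_with_d(5)
    return f


def monoisotopic_mz(f: ElementalFormula) -> float:
    """m/z of a charged formula (Da); neutral mass if charge is zero."""
    if f.charge == 0:
        return f.mass
    return f.mass / abs(f.charge)


# ---------------------------------------------------------------------------
# Adducts and transitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Adduct:
    name: str
    delta: ElementalFormula
    charge: int


ADDUCTS: Mapping[str, Adduct] = {
    "[M+NH4]+": Adduct("[M+NH4]+", F(N=1, H=4), +1),
    "[M+H]+": Adduct("[M+H]+", F(H=1), +1),
    "[M-H]-": Adduct("[M-H]-", F(), -1),  # delta handled in adduct_formula
    "[M+CH3COO]-": Adduct("[M+CH3COO]-", F(C=2, H=3, O=2), -1),
}


def adduct_formula(s: LipidSpecies, adduct: Adduct) -> ElementalFormula:
    neutral = formula_of_species(s)
    if adduct.name == "[M-H]-":
        return (neutral - F(H=1)).with_charge(-1)
    return (neutral + adduct.delta).with_charge(adduct.charge)


def precursor_adduct(s: LipidSpecies) -> Adduct:
    """Class rule for the dominant precursor adduct: acylglycerols ionize
    as ammonium adducts in positive mode; PC/LPC as acetate adducts and
    all other polar classes as [M-H]- in negative mode."""
    if s.lipid_class in NONPOLAR_CLASSES:
        return ADDUCTS["[M+NH4]+"]
    if s.lipid_class in ("PC", "LPC"):
        return ADDUCTS["[M+CH3COO]-"]
    return ADDUCTS["[M-H]-"]


def precursor_mz(s: LipidSpecies) -> tuple[Adduct, float]:
    adduct = precursor_adduct(s)
    return adduct, monoisotopic_mz(adduct_formula(s, adduct))


# -- product channels -------------------------------------------------------

_CHANNEL_RE = re.compile(r"^(acyl_loss|carboxylate):(\d+:\d+)$")


def _channel_fa(channel: str) -> FattyAcyl | None:
    m = _CHANNEL_RE.match(channel)
    return FattyAcyl.parse(m.group(2)) if m else None


def _check_fa_plausible(s: LipidSpecies, fa: FattyAcyl) -> None:
    if s.chains is not None:
        if fa not in s.chains:
            raise ValueError(f"{fa} is not a chain of {s.name}")
        return
    # sum composition: the FA must be able to fit in the totals
    n = CHAIN_COUNT[s.lipid_class]
    rest_c = s.carbons - fa.carbons
    rest_db = s.double_bonds - fa.double_bonds
    if rest_c < 2 * (n - 1) or rest_db < 0:
        raise ValueError(f"{fa} cannot be part of {s.name}")


def product_formula(s: LipidSpecies, channel: str) -> ElementalFormula:
    """Elemental formula of the product ion for a fragmentation channel.

    Channels: ``acyl_loss:<c>:<db>`` (DG/TG), ``acylium`` and
    ``nh3_h2o_loss`` (MG), ``carboxylate:<c>:<db>`` (polar classes) and
    ``headgroup_d5`` (glycerol-D5 LPS).
    """
    cls = s.lipid_class
    fa = _channel_fa(channel)
    if channel.startswith("acyl_loss:"):
        if cls not in ("DG", "TG"):
            raise ValueError(f"acyl-loss channel is only valid for DG/TG, not {cls}")
        _check_fa_plausible(s, fa)
        prec = adduct_formula(s, ADDUCTS["[M+NH4]+"])
        return prec - AMMONIA - formula_of_fatty_acyl(fa, "free_acid")
    if channel == "acylium":
        if cls != "MG":
            raise ValueError("acylium channel is only valid for MG")
        chain = s.chains[0] if s.chains else FattyAcyl(s.carbons, s.double_bonds)
        return formula_of_fatty_acyl(chain, "acylium_cation")
    if channel == "nh3_h2o_loss":
        if cls != "MG":
            raise ValueError("NH3+H2O-loss channel is only valid for MG")
        prec = adduct_formula(s, ADDUCTS["[M+NH4]+"])
        return prec - AMMONIA - WATER
    if channel.startswith("carboxylate:"):
        if cls in NONPOLAR_CLASSES:
            raise ValueError("carboxylate channel is only valid for polar classes")
        _check_fa_plausible(s, fa)
        return formula_of_fatty_acyl(fa, "carboxylate_anion")
    if channel == "headgroup_d5":
        if cls != "LPS" or s.label != "D5":
            raise ValueError("headgroup_d5 channel is only valid for LPS ...[D5]")
        return LPS_D5_HEAD_FRAGMENT
    raise ValueError(f"unknown channel {channel!r}")


def product_mz(s: LipidSpecies, channel: str) -> float:
    return monoisotopic_mz(product_formula(s, channel))


# -- instrument parameter defaults (V), per class, from the platform's
#    compound-optimization of representative standards --------------------

_CLASS_PARAMS: Mapping[str, tuple[int, int, int, int]] = {
    #        DP    EP   CE   CXP
    "MG": (60, 10, 21, 14),
    "DG": (50, 10, 26, 15),
    "TG": (80, 10, 37, 28),
    "MGDG": (-80, -10, -30, -15),
    "DGDG": (-180, -10, -40, -15),
    "LPC": (-40, -10, -40, -13),
    "LPE": (-110, -10, -30, -13),
    "LPG": (-100, -10, -34, -17),
    "LPI": (-110, -10, -44, -13),
    "LPS": (-40, -10, -34, -9),
    "PC": (-65, -10, -52, -15),
    "PE": (-120, -10, -38, -13),
    "PG": (-120, -10, -44, -13),
    "PI": (-55, -10, -60, -15),
    "PS": (-60, -10, -50, -13),
}


@dataclass(frozen=True)
class MRMTransition:
    """A precursor/product m/z pair with polarity, channel semantics and
    instrument parameters.

    ``q1_mz``/``q3_mz`` are kept at full internal precision; use
    :func:`round_mz` (round-half-up, one decimal) for instrument export.
    """

    species: LipidSpecies
    channel: str
    q1_mz: float
    q3_mz: float
    polarity: str  # "+" or "-"
    dp: float = 0.0
    ep: float = 0.0
    ce: float = 0.0
    cxp: float = 0.0
    rt_window: tuple[float, float] | None = None  # minutes

    @property
    def transition_id(self) -> str:
        return f"{self.species.name}|{self.channel}"

    @property
    def q1_display(self) -> float:
        return round_mz(self.q1_mz)

    @property
    def q3_display(self) -> float:
        return round_mz(self.q3_mz)


def build_transition(
    s: LipidSpecies,
    channel: str,
    params: tuple[float, float, float, float] | None = None,
    rt_window: tuple[float, float] | None = None,
) -> MRMTransition:
    """Assemble a complete MRM transition for a species and channel.

    Instrument voltages default to the per-class optimized values; pass
    ``params=(dp, ep, ce, cxp)`` to override.
    """
    adduct, q1 = precursor_mz(s)
    q3 = product_mz(s, channel)
    polarity = "+" if adduct.charge > 0 else "-"
    if params is None:
        if s.lipid_class not in _CLASS_PARAMS:
            raise ValueError(
                f"no default instrument parameters for class {s.lipid_class}; "
                "supply params explicitly"
            )
        params = _CLASS_PARAMS[s.lipid_class]
    dp, ep, ce, cxp = params
    return MRMTransition(
        species=s,
        channel=channel,
        q1_mz=q1,
        q3_mz=q3,
        polarity=polarity,
        dp=dp,
        ep=ep,
        ce=ce,
        cxp=cxp,
        rt_window=rt_window,
    )


def transitions_to_csv(transitions: Iterable[MRMTransition]) -> str:
    """Instrument-export CSV with one-decimal m/z values."""
    lines = [
        "species,label,channel,q1_mz,q3_mz,polarity,dp,ep,ce,cxp,rt_window_s"
    ]
    for t in transitions:
        rt = ""
        if t.rt_window is not None:
            rt = f"{(t.rt_window[1] - t.rt_window[0]) * 60:.0f}"
        sp = t.species
        base = f"{sp.lipid_class} {sp.carbons}:{sp.double_bonds}"
        if sp.chains is not None and CHAIN_COUNT[sp.lipid_class] > 1:
            base += " (" + "_".join(fa.name for fa in sp.chains) + ")"
        lines.append(
            f"{base},{sp.label or ''},{t.channel},{t.q1_display:.1f},"
            f"{t.q3_display:.1f},{t.polarity},{t.dp:g},{t.ep:g},{t.ce:g},"
            f"{t.cxp:g},{rt}"
        )
    return "\n".join(lines) + "\n"
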