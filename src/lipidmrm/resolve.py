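"""Triacylglycerol acyl-composition resolution from overlaid XICs.

A TG precursor mass (sum composition, e.g. TG 58:5) is compatible with
several fatty-acid triplets.  The platform monitors one neutral-loss MRM
per candidate FA and resolves the triplet chromatographically: the
channels of one molecular species co-elute, and their apex heights are
proportional to how many times each FA occurs in the triplet.  This
module re-implements that workflow:

1. peak detection on each channel XIC;
2. single-linkage grouping of peaks sharing a precursor by apex RT;
3. per-group candidate matching with multiplicity inference from channel
   height ratios (confirmed vs tentative calls);
4. selection of one multiplicity-corrected quantifier transition per
   call, so no precursor peak is counted twice.

Height, not area, drives multiplicity inference (robust to integration
boundary choices); area is what quantification consumes.  Equal detector
response across FA channels is assumed throughout — a caveat shared with
the manual workflow this automates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .chem import FattyAcyl
from .panel import TGComposition, enumerate_tg_compositions, DEFAULT_FA_POOL
from .simulate import XICTrace

__all__ = [
    "DetectedPeak",
    "CoelutionGroup",
    "CompositionCall",
    "detect_peaks",
    "estimate_noise_sd",
    "group_by_coelution",
    "call_compositions",
    "select_quantifiers",
    "resolve_sample",
    "RT_TOL_MIN",
    "RATIO_TOL",
]

#: Apex co-elution tolerance (minutes); below a typical peak half-width.
RT_TOL_MIN = 0.05

#: Multiplicity acceptance band: observed ratio r accepted for integer m
#: when r/m lies in [RATIO_TOL[0], RATIO_TOL[1]].
RATIO_TOL = (0.7, 1.4)


@dataclass(frozen=True)
class DetectedPeak:
    transition_id: str
    channel_fa: FattyAcyl | None
    precursor: tuple[int, int]  # TG sum composition (C, DB)
    apex_rt: float
    height: float
    area: float
    left: float
    right: float

    def __post_init__(self):
        if not (self.left <= self.apex_rt <= self.right):
            raise ValueError("peak bounds must bracket the apex")
        if self.area <= 0:
            raise ValueError("peak area must be positive")


@dataclass(frozen=True)
class CoelutionGroup:
    precursor: tuple[int, int]
    peaks: tuple[DetectedPeak, ...]

    @property
    def consensus_rt(self) -> float:
        """Height-weighted mean apex RT of the member peaks."""
        h = np.array([p.height for p in self.peaks])
        rt = np.array([p.apex_rt for p in self.peaks])
        return float(np.average(rt, weights=h))

    def peak_for(self, fa: FattyAcyl) -> DetectedPeak | None:
        for p in self.peaks:
            if p.channel_fa == fa:
                return p
        return None


@dataclass(frozen=True)
class CompositionCall:
    composition: TGComposition
    precursor: tuple[int, int]
    rt: float
    confidence: str  # "confirmed" | "tentative"
    evidence: tuple[tuple[FattyAcyl, float, int], ...]  # (FA, height, inferred mult)
    quantifier_transition: str | None = None
    quantifier_fa: FattyAcyl | None = None
    divisor: int | None = None
    area_raw: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def area_corrected(self) -> float | None:
        if self.area_raw is None or not self.divisor:
            return None
        return self.area_raw / self.divisor


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------


def estimate_noise_sd(x: XICTrace, quiet_region: tuple[float, float] | None = None) -> float:
    """Baseline noise SD.

    With a designated signal-free region, the plain SD there; otherwise a
    robust estimate from the median absolute first difference of the
    whole trace (insensitive to peaks).
    """
    y = x.intensities
    if quiet_region is not None:
        mask = (x.times >= quiet_region[0]) & (x.times <= quiet_region[1])
        if mask.sum() < 2:
            raise ValueError("quiet region contains fewer than 2 samples")
        return float(np.std(y[mask]))
    d = np.abs(np.diff(y))
    return float(1.4826 * np.median(d) / np.sqrt(2.0))


def detect_peaks(
    x: XICTrace,
    min_height: float = 0.0,
    min_snr: float = 5.0,
    boundary_frac: float = 0.01,
    min_separation: float = RT_TOL_MIN,
) -> list[DetectedPeak]:
    """Local maxima above max(min_height, min_snr x noise SD), with bounds
    at the surrounding valleys or where intensity drops below
    ``boundary_frac`` of the apex, and trapezoidal areas.

    Maxima closer than ``min_separation`` (the chromatographic resolution
    limit) are one peak: noise on a flat apex otherwise splits it in two.
    """
    y = x.intensities
    t = x.times
    baseline = float(np.median(y))
    noise_sd = estimate_noise_sd(x)
    thr = max(min_height, baseline + min_snr * noise_sd)
    # prominence keeps noise wiggles on the flank of a real peak from
    # registering as their own (high-intensity) local maxima
    raw_idx, _ = find_peaks(y, height=thr, prominence=max(min_height, min_snr * noise_sd))
    # merge maxima within min_separation, keeping the tallest
    idx: list[int] = []
    for i in sorted(raw_idx):
        if idx and t[i] - t[idx[-1]] <= min_separation:
            if y[i] > y[idx[-1]]:
                idx[-1] = i
        else:
            idx.append(i)
    sp = x.transition.species
    fa = None
    if x.transition.channel.startswith("acyl_loss:"):
        fa = FattyAcyl.parse(x.transition.channel.split(":", 1)[1])
    out = []
    for k, i in enumerate(idx):
        apex = y[i]
        floor = max(boundary_frac * apex, baseline)
        # hard limits: the valley (intensity minimum) towards each
        # neighbouring detected apex, so overlapping peaks split there
        lim_l = 0 if k == 0 else idx[k - 1] + int(np.argmin(y[idx[k - 1] : i + 1]))
        lim_r = (
            len(y) - 1
            if k == len(idx) - 1
            else i + int(np.argmin(y[i : idx[k + 1] + 1]))
        )
        li = i
        while li > lim_l and y[li - 1] > floor:
            li -= 1
        ri = i
        while ri < lim_r and y[ri + 1] > floor:
            ri += 1
        area = float(np.trapezoid(np.clip(y[li : ri + 1] - baseline, 0, None), t[li : ri + 1]))
        if area <= 0:
            continue
        out.append(
            DetectedPeak(
                transition_id=x.transition_id,
                channel_fa=fa,
                precursor=sp.sum_composition,
                apex_rt=float(t[i]),
                height=float(apex - baseline),
                area=area,
                left=float(t[li]),
                right=float(t[ri]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Co-elution grouping
# ---------------------------------------------------------------------------


def group_by_coelution(
    peaks: Iterable[DetectedPeak], rt_tol: float = RT_TOL_MIN
) -> list[CoelutionGroup]:
    """Single-linkage clustering of same-precursor peaks on apex RT.

    In one dimension single linkage reduces to splitting the RT-sorted
    peak list wherever consecutive apexes are more than ``rt_tol`` apart.
    """
    by_prec: dict[tuple[int, int], list[DetectedPeak]] = {}
    for p in peaks:
        by_prec.setdefault(p.precursor, []).append(p)
    groups = []
    for prec, ps in sorted(by_prec.items()):
        ps = sorted(ps, key=lambda p: p.apex_rt)
        start = 0
        for i in range(1, len(ps) + 1):
            if i == len(ps) or ps[i].apex_rt - ps[i - 1].apex_rt > rt_tol:
                groups.append(CoelutionGroup(prec, tuple(ps[start:i])))
                start = i
    return groups


# ---------------------------------------------------------------------------
# Composition calling
# ---------------------------------------------------------------------------


def _ratio_matches(ratio: float, m: int, ratio_tol: tuple[float, float]) -> bool:
    return ratio_tol[0] <= ratio / m <= ratio_tol[1]


def call_compositions(
    group: CoelutionGroup,
    candidates: Sequence[TGComposition] | None = None,
    ratio_tol: tuple[float, float] = RATIO_TOL,
    pool: Sequence[FattyAcyl] = DEFAULT_FA_POOL,
) -> list[CompositionCall]:
    """Match a co-elution group against its candidate compositions.

    A candidate is *supported* when every distinct FA of the triplet has
    a member peak.  The channel heights are then fitted to the candidate's
    multiplicities through a single scale s = (sum of supported heights)/3
    (the triplet always carries three chains); the candidate is
    ``confirmed`` when every height/s ratio matches its multiplicity
    within ``ratio_tol``, and ``tentative`` when only the presence
    pattern matches.  A ratio-consistent candidate whose FA set is a
    strict subset of another confirmed candidate's is demoted to
    tentative, because its evidence is fully absorbed by the larger
    composition.  A group supporting no candidate returns an empty list
    with a structured warning.
    """
    if candidates is None:
        candidates = enumerate_tg_compositions(group.precursor[0], group.precursor[1], pool)
    calls: list[CompositionCall] = []
    for comp in candidates:
        fas = comp.distinct_fas
        peaks = {fa: group.peak_for(fa) for fa in fas}
        if any(p is None for p in peaks.values()):
            continue
        heights = {fa: peaks[fa].height for fa in fas}
        scale = sum(heights.values()) / 3.0
        inferred = []
        ok = True
        for fa in fas:
            m = comp.multiplicity(fa)
            ratio = heights[fa] / scale
            inferred.append((fa, heights[fa], min(3, max(1, int(round(ratio))))))
            if not _ratio_matches(ratio, m, ratio_tol):
                ok = False
        calls.append(
            CompositionCall(
                composition=comp,
                precursor=group.precursor,
                rt=group.consensus_rt,
                confidence="confirmed" if ok else "tentative",
                evidence=tuple(inferred),
            )
        )
    if not calls:
        warnings.warn(
            f"co-elution group for TG {group.precursor[0]}:{group.precursor[1]} at "
            f"{group.consensus_rt:.2f} min supports no candidate composition",
            stacklevel=2,
        )
        return []
    # subsumption guard
    confirmed_sets = [
        set(c.composition.distinct_fas) for c in calls if c.confidence == "confirmed"
    ]
    out = []
    for c in calls:
        s = set(c.composition.distinct_fas)
        if c.confidence == "confirmed" and any(
            s < other for other in confirmed_sets if other != s
        ):
            c = replace(
                c, confidence="tentative", flags=c.flags + ("subsumed_by_larger_call",)
            )
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Quantifier selection
# ---------------------------------------------------------------------------


def select_quantifiers(
    calls: Sequence[CompositionCall],
    groups: Sequence[CoelutionGroup],
    q3_of: dict[tuple[tuple[int, int], FattyAcyl], float] | None = None,
) -> list[CompositionCall]:
    """Attach exactly one quantifier transition (and its multiplicity
    divisor) to each composition call.

    Channels supporting more than one call of the same precursor are
    avoided: preference is (1) a channel unique to the call, (2) lowest
    multiplicity, (3) lowest product m/z — deterministic.  The divisor is
    the multiplicity of the chosen FA within the triplet, so summing
    corrected areas never double-counts a precursor peak.  When the only
    evidence for two calls is one shared channel, both are flagged
    tentative and the shared area is *not* split.
    """
    group_at = {}
    for g in groups:
        group_at[(g.precursor, round(g.consensus_rt, 6))] = g

    # how many calls of this precursor does each channel FA support?
    support: dict[tuple[tuple[int, int], FattyAcyl], int] = {}
    for c in calls:
        for fa in c.composition.distinct_fas:
            key = (c.precursor, fa)
            support[key] = support.get(key, 0) + 1

    out: list[CompositionCall] = []
    for c in calls:
        g = group_at.get((c.precursor, round(c.rt, 6)))
        choices = []
        for fa in c.composition.distinct_fas:
            shared = support[(c.precursor, fa)] > 1
            mult = c.composition.multiplicity(fa)
            q3 = q3_of.get((c.precursor, fa), 0.0) if q3_of else 0.0
            choices.append((shared, mult, q3, fa))
        choices.sort(key=lambda x: (x[0], x[1], x[2], x[3]))
        shared, mult, _, fa = choices[0]
        peak = g.peak_for(fa) if g else None
        flags = c.flags
        confidence = c.confidence
        if shared:  # only shared evidence left for this call
            flags = flags + ("quantifier_shared_channel",)
            confidence = "tentative"
        out.append(
            replace(
                c,
                confidence=confidence,
                quantifier_transition=peak.transition_id if peak else None,
                quantifier_fa=fa,
                divisor=mult,
                area_raw=peak.area if peak else None,
                flags=flags,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Whole-sample pipeline
# ---------------------------------------------------------------------------


def resolve_sample(
    traces: Sequence[XICTrace],
    pool: Sequence[FattyAcyl] = DEFAULT_FA_POOL,
    rt_tol: float = RT_TOL_MIN,
    ratio_tol: tuple[float, float] = RATIO_TOL,
    min_snr: float = 5.0,
    min_height: float = 0.0,
) -> list[CompositionCall]:
    """Detect, group, call and select quantifiers for one sample's TG-FA
    XIC traces.  Deterministic: identical traces yield identical calls."""
    peaks: list[DetectedPeak] = []
    q3_of: dict[tuple[tuple[int, int], FattyAcyl], float] = {}
    for tr in traces:
        if not tr.transition.channel.startswith("acyl_loss:"):
            continue
        fa = FattyAcyl.parse(tr.transition.channel.split(":", 1)[1])
        q3_of[(tr.transition.species.sum_composition, fa)] = tr.transition.q3_mz
        peaks.extend(detect_peaks(tr, min_height=min_height, min_snr=min_snr))
    groups = group_by_coelution(peaks, rt_tol=rt_tol)
    calls: list[CompositionCall] = []
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        for g in groups:
            calls.extend(call_compositions(g, ratio_tol=ratio_tol, pool=pool))
    return select_quantifiers(calls, groups, q3_of=q3_of)


def calls_to_records(calls: Sequence[CompositionCall], sample: str = "") -> list[dict]:
    """Flatten calls for CSV export."""
    rows = []
    for c in calls:
        rows.append(
            {
                "sample": sample,
                "tg_species": f"TG {c.precursor[0]}:{c.precursor[1]}",
                "composition": c.composition.name,
                "rt_min": round(c.rt, 3),
                "confidence": c.confidence,
                "quantifier_channel": c.quantifier_fa.name if c.quantifier_fa else "",
                "divisor": c.divisor or "",
                "area_raw": c.area_raw if c.area_raw is not None else "",
                "area_corrected": c.area_corrected if c.area_corrected is not None else "",
                "flags": ";".join(c.flags),
            }
        )
    return rows
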