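"""Engineered QC features for chromatographic peak quality.

The registry defines 32 metrics in 9 groups (jaggedness, similarity,
symmetry, fwhm, modality, shift, intensity, area_ratio, retention_time) at
4 levels:

* ``transition``  — one trace (one fragment, one label);
* ``isotope``     — aggregate over all fragments of one label;
* ``transition_pair`` — the endogenous/standard pair of one fragment;
* ``peak_group``  — aggregate over every trace of the group, both labels.

Transition- and isotope-level metrics depend on the label, so the model
input duplicates them for the endogenous and standard sides (suffixes
``.endo`` / ``.std``); 20 of the 32 metrics are label-specific, giving
32 + 20 = 52 assembled entries per transition pair.

All shape metrics operate on the boundary-clipped peak region only, on the
sampled grid as-is (no resampling, no smoothing, zero baseline). Metrics
that compare a peak against the rest of the dataset ("consistency" scores)
use cross-run reference medians held in a :class:`PeakContext`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (FeatureVector, Label, PeakGroup, TransitionPair,
                        TransitionTrace, peak_region)
from .errors import (ConstantHalf, ConstantTrace, FeatureUnavailable,
                     IncompletePair, SingletonGroup, TooFewPoints,
                     ZeroDenominator, ZeroPeak)

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["FileName", "PeptideModifiedSequence", "PrecursorCharge",
               "FragmentIon", "ProductCharge"]


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureRegistryEntry:
    """One metric definition: name, QC group, and computation level."""

    name: str        # "<group>.<metric>.<level>"
    group: str       # one of the 9 QC groups
    level: str       # transition | isotope | transition_pair | peak_group

    @property
    def label_specific(self) -> bool:
        return self.level in ("transition", "isotope")


def _entry(group: str, metric: str, level: str) -> FeatureRegistryEntry:
    return FeatureRegistryEntry(f"{group}.{metric}.{level}", group, level)


#: The declarative metric registry. Order is the fixed output order.
REGISTRY: tuple[FeatureRegistryEntry, ...] = (
    # transition level (per fragment, per label) -- 12
    _entry("jaggedness", "score", "transition"),
    _entry("symmetry", "score", "transition"),
    _entry("modality", "score", "transition"),
    _entry("fwhm", "width", "transition"),
    _entry("fwhm", "base_ratio", "transition"),
    _entry("shift", "score", "transition"),
    _entry("intensity", "boundary", "transition"),
    _entry("intensity", "max", "transition"),
    _entry("area_ratio", "fraction", "transition"),
    _entry("area_ratio", "fraction_consistency", "transition"),
    _entry("retention_time", "apex", "transition"),
    _entry("retention_time", "apex_consistency", "transition"),
    # isotope level (aggregate over fragments of one label) -- 8
    _entry("jaggedness", "mean", "isotope"),
    _entry("symmetry", "mean", "isotope"),
    _entry("modality", "max", "isotope"),
    _entry("similarity", "mean", "isotope"),
    _entry("fwhm", "mean", "isotope"),
    _entry("shift", "mean", "isotope"),
    _entry("intensity", "total_max", "isotope"),
    _entry("area_ratio", "fraction_rmsd", "isotope"),
    # transition-pair level (endo vs std of one fragment) -- 7
    _entry("similarity", "pair", "transition_pair"),
    _entry("area_ratio", "pair_ratio_consistency", "transition_pair"),
    _entry("area_ratio", "isotope_ratio", "transition_pair"),
    _entry("area_ratio", "isotope_ratio_consistency", "transition_pair"),
    _entry("area_ratio", "area_correlation", "transition_pair"),
    _entry("fwhm", "pair_consistency", "transition_pair"),
    _entry("shift", "pair", "transition_pair"),
    # peak-group level (all traces, both labels) -- 5
    _entry("jaggedness", "mean", "peak_group"),
    _entry("symmetry", "mean", "peak_group"),
    _entry("modality", "max", "peak_group"),
    _entry("similarity", "mean", "peak_group"),
    _entry("shift", "max", "peak_group"),
)

assert len(REGISTRY) == 32
assert sum(e.label_specific for e in REGISTRY) == 20


def feature_names() -> list[str]:
    """The 52 assembled model-input names in fixed order.

    Label-specific registry entries expand to two columns, ``.endo`` before
    ``.std``; registry order is preserved otherwise.
    """
    names = []
    for e in REGISTRY:
        if e.label_specific:
            names.append(e.name + ".endo")
            names.append(e.name + ".std")
        else:
            names.append(e.name)
    return names


N_FEATURES = len(feature_names())  # 52


# ---------------------------------------------------------------------------
# scalar metric primitives (all operate on the boundary-clipped region)
# ---------------------------------------------------------------------------

def jaggedness(intensities_sub: Sequence[float]) -> float:
    """Fraction of interior points where the signal changes direction,
    excluding the peak apex; 0.0 for a smooth peak, near 1.0 for noise.

    Zero first-differences inherit the previous non-zero sign (a flat step
    is not a direction change). The apex is the first global maximum; it is
    excluded only when it is an interior point. Denominator is n - 2.
    """
    y = np.asarray(intensities_sub, dtype=float)
    n = len(y)
    if n < 4:
        raise TooFewPoints(f"jaggedness needs >= 4 points, got {n}")
    d = np.diff(y)
    signs = np.sign(d)
    nonzero = np.flatnonzero(signs)
    if len(nonzero) == 0:  # perfectly flat trace: no direction changes
        return 0.0
    # forward-fill zero signs with the previous non-zero sign; leading zeros
    # take the first non-zero sign so they can never register a flip
    filled = signs.copy()
    last = signs[nonzero[0]]
    for i in range(len(filled)):
        if filled[i] == 0:
            filled[i] = last
        else:
            last = filled[i]
    flips = filled[1:] != filled[:-1]          # flip at interior point i+1 ?
    flip_points = np.flatnonzero(flips) + 1    # indices into y, all interior
    apex = int(np.argmax(y))
    count = int(np.sum(flip_points != apex))
    return count / (n - 2)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ConstantTrace("correlation undefined for a constant vector")
    return float(a @ b) / denom


def similarity(intensities_a: Sequence[float], intensities_b: Sequence[float]) -> float:
    """Pearson correlation between two co-eluting peak intensity vectors.

    1.0 for peaks that mirror each other's shape; lower when shapes differ.
    """
    a = np.asarray(intensities_a, dtype=float)
    b = np.asarray(intensities_b, dtype=float)
    if len(a) != len(b):
        raise FeatureUnavailable(
            f"similarity requires equal lengths, got {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise TooFewPoints("similarity needs >= 3 points")
    return _pearson(a, b)


def symmetry(intensities_sub: Sequence[float]) -> float:
    """Correlation of the first half against the reversed second half.

    1.0 for a peak exactly mirror-symmetric about its time midpoint; with an
    odd number of points the midpoint sample is excluded.
    """
    y = np.asarray(intensities_sub, dtype=float)
    n = len(y)
    if n < 6:
        raise TooFewPoints(f"symmetry needs >= 6 points, got {n}")
    h = n // 2
    left, right = y[:h], y[-h:][::-1]
    try:
        return _pearson(left, right)
    except ConstantTrace as exc:
        raise ConstantHalf(str(exc)) from exc


def fwhm(times_sub: Sequence[float], intensities_sub: Sequence[float],
         boundary_start: float, boundary_end: float) -> tuple[float, float]:
    """Full width at half maximum and its ratio to the peak base width.

    Half-max is max/2 against a zero baseline. The leftmost and rightmost
    crossings of the half-max level are located by linear interpolation
    between adjacent samples; a side that never drops below half-max falls
    back to the boundary on that side. When the signal never crosses
    half-max at all, fwhm = base and ratio = 1 (warning logged).
    """
    t = np.asarray(times_sub, dtype=float)
    y = np.asarray(intensities_sub, dtype=float)
    if len(y) < 3:
        raise TooFewPoints("fwhm needs >= 3 points")
    peak = y.max()
    if peak <= 0:
        raise ZeroPeak("fwhm undefined for an all-zero peak")
    base = boundary_end - boundary_start
    half = peak / 2.0
    rel = y - half
    cross_ts = []
    for i in range(len(y) - 1):
        if rel[i] == 0.0:
            cross_ts.append(t[i])
        elif rel[i] * rel[i + 1] < 0:
            frac = rel[i] / (rel[i] - rel[i + 1])
            cross_ts.append(t[i] + frac * (t[i + 1] - t[i]))
    if rel[-1] == 0.0:
        cross_ts.append(t[-1])
    if not cross_ts:
        logger.warning("signal never crosses half-max inside bounds; fwhm = base")
        return base, 1.0
    left = t[0] if rel[0] >= 0 else min(cross_ts)
    right = t[-1] if rel[-1] >= 0 else max(cross_ts)
    width = right - left
    return width, float(np.clip(width / base, 0.0, 1.0))


def modality(intensities_sub: Sequence[float]) -> float:
    """Largest interior dip normalized by peak height; 0 when unimodal.

    The dip at point i is min(running max from the left, running max from
    the right) minus the intensity at i.
    """
    y = np.asarray(intensities_sub, dtype=float)
    if len(y) < 3:
        raise TooFewPoints("modality needs >= 3 points")
    peak = y.max()
    if peak <= 0:
        raise ZeroPeak("modality undefined for an all-zero peak")
    lmax = np.maximum.accumulate(y)
    rmax = np.maximum.accumulate(y[::-1])[::-1]
    dips = np.minimum(lmax, rmax) - y
    return max(0.0, float(dips[1:-1].max())) / peak


def apex_time(times_sub: Sequence[float], intensities_sub: Sequence[float]) -> float:
    """Retention time of the apex (first global maximum)."""
    y = np.asarray(intensities_sub, dtype=float)
    return float(np.asarray(times_sub, dtype=float)[int(np.argmax(y))])


def shift(apex: float, other_apexes: Sequence[float], base_width: float) -> float:
    """Apex displacement from the co-eluting group, in base-width units.

    |apex - median(other traces' apexes)| / (boundary_end - boundary_start).
    """
    others = np.asarray(other_apexes, dtype=float)
    if len(others) == 0:
        raise SingletonGroup("shift needs at least one other trace in the group")
    if base_width <= 0:
        raise ZeroDenominator("shift needs a positive base width")
    return abs(apex - float(np.median(others))) / base_width


def boundary_intensity(intensities_sub: Sequence[float]) -> float:
    """Mean of the first and last in-bounds intensities over the max.

    High values indicate the peak sits on background or interference.
    """
    y = np.asarray(intensities_sub, dtype=float)
    peak = y.max()
    if peak <= 0:
        raise ZeroPeak("boundary intensity undefined for an all-zero peak")
    return float((y[0] + y[-1]) / 2.0 / peak)


def peak_area(times_sub: Sequence[float], intensities_sub: Sequence[float]) -> float:
    """Trapezoidal integral of the peak region (intensity * minutes)."""
    t = np.asarray(times_sub, dtype=float)
    y = np.asarray(intensities_sub, dtype=float)
    if len(y) < 2:
        raise TooFewPoints("area needs >= 2 points")
    return float(np.trapezoid(y, t))


# ---------------------------------------------------------------------------
# cross-run reference context
# ---------------------------------------------------------------------------

@dataclass
class PeakContext:
    """Dataset-wide reference statistics against which "consistency" is
    judged.

    Keyed by (peptide, fragment_ion, product_charge, label-value) for
    per-trace statistics and by (peptide, fragment_ion, product_charge) for
    the endo/std area ratio. Medians are taken over runs with non-missing
    values; quality status is unknown at feature time, so every run
    contributes.
    """

    apex_rt_median: dict = field(default_factory=dict)
    fwhm_median: dict = field(default_factory=dict)
    fraction_median: dict = field(default_factory=dict)
    fraction_cv: dict = field(default_factory=dict)
    ratio_median: dict = field(default_factory=dict)
    areas_by_run: dict = field(default_factory=dict)  # trace key4 -> {run: area}
    n_runs: int = 0

    def pair_area_correlation(self, pep: str, frag: str, pq: int) -> float:
        """Cross-run Pearson correlation of endo vs std areas (>= 3 runs)."""
        endo = self.areas_by_run.get((pep, frag, pq, Label.ENDOGENOUS.value), {})
        std = self.areas_by_run.get((pep, frag, pq, Label.STANDARD.value), {})
        runs = sorted(set(endo) & set(std))
        if len(runs) < 3:
            raise FeatureUnavailable("area correlation needs >= 3 shared runs")
        a = np.array([endo[r] for r in runs])
        b = np.array([std[r] for r in runs])
        return _pearson(a, b)


@dataclass
class _TraceMetrics:
    """Per-trace primitives cached while building context/features."""

    apex: float = math.nan
    area: float = math.nan
    fwhm_width: float = math.nan
    fwhm_ratio: float = math.nan
    jaggedness: float = math.nan
    symmetry: float = math.nan
    modality: float = math.nan
    boundary_intensity: float = math.nan
    max_intensity: float = math.nan
    region: tuple = ()


def _trace_metrics(trace: TransitionTrace) -> _TraceMetrics:
    m = _TraceMetrics()
    t, y = peak_region(trace)
    m.region = (t, y)
    m.max_intensity = float(y.max())
    m.apex = apex_time(t, y)
    for attr, fn in (("jaggedness", jaggedness), ("symmetry", symmetry),
                     ("modality", modality), ("boundary_intensity", boundary_intensity)):
        try:
            setattr(m, attr, fn(y))
        except FeatureUnavailable:
            pass
    try:
        m.fwhm_width, m.fwhm_ratio = fwhm(t, y, trace.boundary_start, trace.boundary_end)
    except FeatureUnavailable:
        pass
    try:
        m.area = peak_area(t, y)
    except FeatureUnavailable:
        pass
    return m


def _group_metrics(group: PeakGroup) -> dict:
    """Per-trace metrics plus per-label area fractions for one group."""
    metrics = {t.key: _trace_metrics(t) for t in group.traces}
    fractions: dict = {}
    for label in Label:
        traces = group.traces_for_label(label)
        areas = {t.key.fragment_key: metrics[t.key].area for t in traces}
        total = float(np.nansum(list(areas.values())))
        for frag, a in areas.items():
            if total > 0 and not math.isnan(a):
                fractions[(frag, label)] = a / total
    return {"trace": metrics, "fractions": fractions}


def build_context(groups: Iterable[PeakGroup]) -> PeakContext:
    """Accumulate cross-run reference medians from every peak group."""
    acc_apex: dict = {}
    acc_fwhm: dict = {}
    acc_frac: dict = {}
    acc_ratio: dict = {}
    ctx = PeakContext()
    runs = set()
    groups = list(groups)
    gm_cache = {}
    for g in groups:
        runs.add(g.run_id)
        gm = _group_metrics(g)
        gm_cache[(g.run_id, g.peptide_sequence)] = gm
        for t in g.traces:
            m = gm["trace"][t.key]
            k4 = (t.key.peptide_sequence, t.key.fragment_ion,
                  t.key.product_charge, t.key.label.value)
            if not math.isnan(m.apex):
                acc_apex.setdefault(k4, []).append(m.apex)
            if not math.isnan(m.fwhm_width):
                acc_fwhm.setdefault(k4, []).append(m.fwhm_width)
            if not math.isnan(m.area):
                ctx.areas_by_run.setdefault(k4, {})[g.run_id] = m.area
        for (frag, label), f in gm["fractions"].items():
            k4 = (g.peptide_sequence, frag[0], frag[1], label.value)
            acc_frac.setdefault(k4, []).append(f)
        # endo/std area ratio per fragment
        for pair in g.complete_pairs():
            ae = gm["trace"][pair.endo.key].area
            as_ = gm["trace"][pair.std.key].area
            if not math.isnan(ae) and not math.isnan(as_) and as_ > 0:
                k3 = (g.peptide_sequence, pair.fragment_ion, pair.product_charge)
                acc_ratio.setdefault(k3, []).append(ae / as_)
    ctx.apex_rt_median = {k: float(np.median(v)) for k, v in acc_apex.items()}
    ctx.fwhm_median = {k: float(np.median(v)) for k, v in acc_fwhm.items()}
    ctx.fraction_median = {k: float(np.median(v)) for k, v in acc_frac.items()}
    for k, v in acc_frac.items():
        mean = float(np.mean(v))
        ctx.fraction_cv[k] = float(np.std(v, ddof=1) / mean) if len(v) > 1 and mean > 0 else math.nan
    ctx.ratio_median = {k: float(np.median(v)) for k, v in acc_ratio.items()}
    ctx.n_runs = len(runs)
    ctx._group_metrics_cache = gm_cache  # reuse when assembling features
    return ctx


# ---------------------------------------------------------------------------
# named score operations (public surface; assembly picks from their outputs)
# ---------------------------------------------------------------------------

def area_ratio_features(pair: TransitionPair, group: PeakGroup,
                        context: PeakContext,
                        _gm: Optional[dict] = None) -> dict[str, float]:
    """Transition-ratio scores for one pair: per-label area fractions, their
    endo/std agreement, the isotope ratio and its cross-run consistency, the
    cross-run fraction CV per label and the cross-run endo/std area
    correlation. Individually unavailable scores come back as NaN."""
    gm = _gm if _gm is not None else _group_metrics(group)
    out: dict[str, float] = {}
    pep = group.peptide_sequence
    frag = (pair.fragment_ion, pair.product_charge)
    for label, suffix in ((Label.ENDOGENOUS, "endo"), (Label.STANDARD, "std")):
        f = gm["fractions"].get((frag, label), math.nan)
        out[f"fraction.{suffix}"] = f
        k4 = (pep, frag[0], frag[1], label.value)
        med = context.fraction_median.get(k4, math.nan)
        out[f"fraction_consistency.{suffix}"] = (
            abs(f - med) if not (math.isnan(f) or math.isnan(med)) else math.nan)
        out[f"fraction_cv.{suffix}"] = context.fraction_cv.get(k4, math.nan)
    fe, fs = out["fraction.endo"], out["fraction.std"]
    out["pair_ratio_consistency"] = (
        abs(fe - fs) if not (math.isnan(fe) or math.isnan(fs)) else math.nan)
    ae = gm["trace"][pair.endo.key].area
    as_ = gm["trace"][pair.std.key].area
    r = ae / as_ if (not math.isnan(ae) and not math.isnan(as_) and as_ > 0) else math.nan
    out["isotope_ratio"] = r
    med_r = context.ratio_median.get((pep, frag[0], frag[1]), math.nan)
    out["isotope_ratio_consistency"] = (
        abs(r - med_r) / med_r
        if not (math.isnan(r) or math.isnan(med_r)) and med_r > 0 else math.nan)
    try:
        out["area_correlation"] = context.pair_area_correlation(pep, frag[0], frag[1])
    except FeatureUnavailable:
        out["area_correlation"] = math.nan
    return out


def retention_time_features(trace: TransitionTrace, context: PeakContext) -> dict[str, float]:
    """Apex RT, its deviation from the cross-run median, and FWHM
    consistency relative to the cross-run median FWHM."""
    m = _trace_metrics(trace)
    k4 = (trace.key.peptide_sequence, trace.key.fragment_ion,
          trace.key.product_charge, trace.key.label.value)
    out = {"apex": m.apex}
    med = context.apex_rt_median.get(k4, math.nan)
    out["apex_consistency"] = abs(m.apex - med) if not math.isnan(med) else math.nan
    med_fwhm = context.fwhm_median.get(k4, math.nan)
    out["fwhm_consistency"] = (
        abs(m.fwhm_width - med_fwhm) / med_fwhm
        if not (math.isnan(m.fwhm_width) or math.isnan(med_fwhm)) and med_fwhm > 0
        else math.nan)
    return out


def compute_isotope_level(group: PeakGroup, label: Label,
                          context: Optional[PeakContext] = None,
                          _gm: Optional[dict] = None) -> dict[str, float]:
    """Per-label aggregates over fragments: mean jaggedness/symmetry, max
    modality, mean pairwise similarity, mean FWHM, mean shift, summed max
    intensity and the RMS relative deviation of the label's transition
    fractions from their cross-run medians."""
    gm = _gm if _gm is not None else _group_metrics(group)
    traces = group.traces_for_label(label)
    ms = [gm["trace"][t.key] for t in traces]

    def nanagg(fn, vals):
        vals = [v for v in vals if not math.isnan(v)]
        return float(fn(vals)) if vals else math.nan

    out = {
        "jaggedness_mean": nanagg(np.mean, [m.jaggedness for m in ms]),
        "symmetry_mean": nanagg(np.mean, [m.symmetry for m in ms]),
        "modality_max": nanagg(np.max, [m.modality for m in ms]),
        "fwhm_mean": nanagg(np.mean, [m.fwhm_width for m in ms]),
        "total_max_intensity": nanagg(np.sum, [m.max_intensity for m in ms]),
    }
    # mean pairwise similarity among same-label fragments
    sims = []
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            try:
                sims.append(similarity(ms[i].region[1], ms[j].region[1]))
            except FeatureUnavailable:
                pass
    out["similarity_mean"] = float(np.mean(sims)) if sims else math.nan
    # mean shift of each trace against the rest of the whole group
    all_apexes = {t.key: gm["trace"][t.key].apex for t in group.traces}
    shifts = []
    for t in traces:
        others = [a for k, a in all_apexes.items() if k != t.key and not math.isnan(a)]
        try:
            shifts.append(shift(all_apexes[t.key], others, group.base_width))
        except FeatureUnavailable:
            pass
    out["shift_mean"] = float(np.mean(shifts)) if shifts else math.nan
    # RMS relative deviation of fractions from context medians
    if context is not None:
        devs = []
        for t in traces:
            frag = t.key.fragment_key
            f = gm["fractions"].get((frag, label), math.nan)
            med = context.fraction_median.get(
                (group.peptide_sequence, frag[0], frag[1], label.value), math.nan)
            if not math.isnan(f) and not math.isnan(med) and med > 0:
                devs.append(((f - med) / med) ** 2)
        out["fraction_rmsd"] = math.sqrt(float(np.mean(devs))) if devs else math.nan
    else:
        out["fraction_rmsd"] = math.nan
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_features(pair: TransitionPair, group: PeakGroup,
                      context: PeakContext,
                      _gm: Optional[dict] = None) -> FeatureVector:
    """Evaluate every registry entry for one complete transition pair.

    Label-specific entries are evaluated once per label (suffixes ``.endo``
    and ``.std``); the result always has exactly 52 entries in the fixed
    registry order, with unavailable scores masked as missing.
    """
    if pair.endo is None or pair.std is None:
        raise IncompletePair(f"pair {pair.fragment_ion} lacks a label")
    gm = _gm if _gm is not None else _group_metrics(group)
    values: dict[str, float] = {}

    trace_m = {"endo": gm["trace"][pair.endo.key], "std": gm["trace"][pair.std.key]}
    all_apexes = {t.key: gm["trace"][t.key].apex for t in group.traces}
    ar = area_ratio_features(pair, group, context, _gm=gm) if context is not None else {}

    def trace_level(suffix: str) -> dict[str, float]:
        trace = pair.endo if suffix == "endo" else pair.std
        m = trace_m[suffix]
        k4 = (group.peptide_sequence, pair.fragment_ion, pair.product_charge,
              trace.key.label.value)
        others = [a for k, a in all_apexes.items() if k != trace.key and not math.isnan(a)]
        try:
            shift_score = shift(m.apex, others, group.base_width)
        except FeatureUnavailable:
            shift_score = math.nan
        med_apex = context.apex_rt_median.get(k4, math.nan)
        med_fwhm = context.fwhm_median.get(k4, math.nan)
        return {
            "jaggedness.score.transition": m.jaggedness,
            "symmetry.score.transition": m.symmetry,
            "modality.score.transition": m.modality,
            "fwhm.width.transition": m.fwhm_width,
            "fwhm.base_ratio.transition": m.fwhm_ratio,
            "shift.score.transition": shift_score,
            "intensity.boundary.transition": m.boundary_intensity,
            "intensity.max.transition": m.max_intensity,
            "area_ratio.fraction.transition": ar.get(f"fraction.{suffix}", math.nan),
            "area_ratio.fraction_consistency.transition":
                ar.get(f"fraction_consistency.{suffix}", math.nan),
            "retention_time.apex.transition": m.apex,
            "retention_time.apex_consistency.transition":
                abs(m.apex - med_apex) if not math.isnan(med_apex) else math.nan,
        }

    iso = {suffix: compute_isotope_level(group, label, context, _gm=gm)
           for suffix, label in (("endo", Label.ENDOGENOUS), ("std", Label.STANDARD))}

    for entry in REGISTRY:
        if entry.level == "transition":
            for suffix in ("endo", "std"):
                values[entry.name + "." + suffix] = trace_level(suffix)[entry.name]
        elif entry.level == "isotope":
            iso_key = {"jaggedness.mean.isotope": "jaggedness_mean",
                       "symmetry.mean.isotope": "symmetry_mean",
                       "modality.max.isotope": "modality_max",
                       "similarity.mean.isotope": "similarity_mean",
                       "fwhm.mean.isotope": "fwhm_mean",
                       "shift.mean.isotope": "shift_mean",
                       "intensity.total_max.isotope": "total_max_intensity",
                       "area_ratio.fraction_rmsd.isotope": "fraction_rmsd"}[entry.name]
            for suffix in ("endo", "std"):
                values[entry.name + "." + suffix] = iso[suffix][iso_key]
        elif entry.level == "transition_pair":
            if entry.name == "similarity.pair.transition_pair":
                try:
                    v = similarity(trace_m["endo"].region[1], trace_m["std"].region[1])
                except FeatureUnavailable:
                    v = math.nan
            elif entry.name == "area_ratio.pair_ratio_consistency.transition_pair":
                v = ar.get("pair_ratio_consistency", math.nan)
            elif entry.name == "area_ratio.isotope_ratio.transition_pair":
                v = ar.get("isotope_ratio", math.nan)
            elif entry.name == "area_ratio.isotope_ratio_consistency.transition_pair":
                v = ar.get("isotope_ratio_consistency", math.nan)
            elif entry.name == "area_ratio.area_correlation.transition_pair":
                v = ar.get("area_correlation", math.nan)
            elif entry.name == "fwhm.pair_consistency.transition_pair":
                we, ws = trace_m["endo"].fwhm_width, trace_m["std"].fwhm_width
                v = (abs(we - ws) / ((we + ws) / 2.0)
                     if not (math.isnan(we) or math.isnan(ws)) and (we + ws) > 0
                     else math.nan)
            elif entry.name == "shift.pair.transition_pair":
                ae_, as2 = trace_m["endo"].apex, trace_m["std"].apex
                v = (abs(ae_ - as2) / group.base_width
                     if group.base_width > 0 else math.nan)
            values[entry.name] = v
        else:  # peak_group: aggregates over both labels jointly
            ms = [gm["trace"][t.key] for t in group.traces]
            if entry.name == "jaggedness.mean.peak_group":
                v = _nanmean([m.jaggedness for m in ms])
            elif entry.name == "symmetry.mean.peak_group":
                v = _nanmean([m.symmetry for m in ms])
            elif entry.name == "modality.max.peak_group":
                v = _nanmax([m.modality for m in ms])
            elif entry.name == "similarity.mean.peak_group":
                sims = []
                for i in range(len(ms)):
                    for j in range(i + 1, len(ms)):
                        try:
                            sims.append(similarity(ms[i].region[1], ms[j].region[1]))
                        except FeatureUnavailable:
                            pass
                v = float(np.mean(sims)) if sims else math.nan
            elif entry.name == "shift.max.peak_group":
                shifts = []
                for t in group.traces:
                    others = [a for k, a in all_apexes.items()
                              if k != t.key and not math.isnan(a)]
                    try:
                        shifts.append(shift(all_apexes[t.key], others, group.base_width))
                    except FeatureUnavailable:
                        pass
                v = float(np.max(shifts)) if shifts else math.nan
            values[entry.name] = v

    ordered = {name: values[name] for name in feature_names()}
    mask = {name: bool(math.isnan(v)) for name, v in ordered.items()}
    return FeatureVector(pair_key=pair.pair_key, values=ordered, missing_mask=mask)


def _nanmean(vals) -> float:
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


def _nanmax(vals) -> float:
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.max(vals)) if vals else math.nan


def compute_features(groups: Iterable[PeakGroup],
                     context: Optional[PeakContext] = None) -> pd.DataFrame:
    """Assemble feature vectors for every complete pair of every group.

    Returns a DataFrame with the 5 key columns followed by the 52 feature
    columns, sorted by key. The cross-run context is built from the given
    groups when not supplied.
    """
    groups = list(groups)
    if context is None:
        context = build_context(groups)
    cache = getattr(context, "_group_metrics_cache", {})
    rows = []
    for g in groups:
        gm = cache.get((g.run_id, g.peptide_sequence)) or _group_metrics(g)
        for pair in g.complete_pairs():
            fv = assemble_features(pair, g, context, _gm=gm)
            row = dict(zip(KEY_COLUMNS, fv.pair_key))
            row.update(fv.values)
            rows.append(row)
    df = pd.DataFrame(rows, columns=KEY_COLUMNS + feature_names())
    return df.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
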