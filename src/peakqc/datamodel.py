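"""Core in-memory types for targeted-MS chromatographic peak QC.

A *transition* is one (peptide precursor, fragment ion) pair monitored over
chromatographic time; its recorded trace is a pair of time/intensity vectors.
Each transition is acquired twice per run: once for the endogenous ("light")
peptide and once for the spiked stable-isotope-labelled standard ("heavy").
All traces of one peptide in one run form a *peak group*, sharing a single
pair of integration boundaries, and the endogenous/standard traces of the
same fragment form a *transition pair* — the unit on which quality is judged.

Times are minutes throughout; intensities are detector counts (arbitrary
units, non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

from .errors import EmptyPeakRegion, IncompletePair, PeakQCError


class Label(str, Enum):
    """Isotope label of a trace: endogenous analyte or spiked-in standard."""

    ENDOGENOUS = "endogenous"
    STANDARD = "standard"


@dataclass(frozen=True, order=True)
class TransitionKey:
    """Unique identity of one trace within a dataset.

    The 6-tuple (run, peptide, precursor charge, fragment ion, product
    charge, label) uniquely identifies a chromatographic trace.
    """

    run_id: str
    peptide_sequence: str  # modified sequence, kept verbatim
    precursor_charge: int
    fragment_ion: str
    product_charge: int
    label: Label

    def __post_init__(self):
        if self.precursor_charge < 1 or self.product_charge < 1:
            raise PeakQCError(f"charges must be positive integers: {self}")
        if not isinstance(self.label, Label):
            object.__setattr__(self, "label", Label(self.label))

    @property
    def pair_key(self) -> tuple:
        """The 5-tuple identifying the endo/std pair (label dropped)."""
        return (self.run_id, self.peptide_sequence, self.precursor_charge,
                self.fragment_ion, self.product_charge)

    @property
    def fragment_key(self) -> tuple:
        """(fragment_ion, product_charge) — the fragment within a group."""
        return (self.fragment_ion, self.product_charge)


@dataclass
class TransitionTrace:
    """One chromatographic trace plus its integration boundaries.

    ``times`` must be strictly increasing minutes; ``intensities`` are
    non-negative and the same length. Boundaries may be unset (None) until
    the boundary table is joined on; all shape features are computed on the
    closed interval [boundary_start, boundary_end] only.
    """

    key: TransitionKey
    times: np.ndarray
    intensities: np.ndarray
    boundary_start: Optional[float] = None
    boundary_end: Optional[float] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.intensities.ndim != 1:
            raise PeakQCError("times and intensities must be 1-D vectors")
        if len(self.times) != len(self.intensities) or len(self.times) < 1:
            raise PeakQCError(
                f"times ({len(self.times)}) and intensities "
                f"({len(self.intensities)}) must have equal length >= 1: {self.key}")
        if np.any(np.diff(self.times) <= 0):
            raise PeakQCError(f"times must be strictly increasing: {self.key}")
        if np.any(self.intensities < 0):
            raise PeakQCError(f"intensities must be non-negative: {self.key}")
        if self.boundary_start is not None and self.boundary_end is not None:
            if not self.boundary_start < self.boundary_end:
                raise PeakQCError(
                    f"boundary_start must precede boundary_end: {self.key}")

    @property
    def has_boundaries(self) -> bool:
        return self.boundary_start is not None and self.boundary_end is not None


def peak_region(trace: TransitionTrace) -> tuple[np.ndarray, np.ndarray]:
    """Clip a trace to its peak boundaries (closed interval, no resampling).

    Returns the sampled (times, intensities) with
    boundary_start <= t <= boundary_end, order preserved and edge samples
    unmodified. Raises :class:`EmptyPeakRegion` when no sample falls inside.
    """
    if not trace.has_boundaries:
        raise PeakQCError(f"trace has no boundaries set: {trace.key}")
    mask = (trace.times >= trace.boundary_start) & (trace.times <= trace.boundary_end)
    if not mask.any():
        raise EmptyPeakRegion(
            f"no sampled time in [{trace.boundary_start}, {trace.boundary_end}] "
            f"for {trace.key}")
    return trace.times[mask], trace.intensities[mask]


@dataclass
class TransitionPair:
    """Endogenous + standard traces of the same fragment in one run."""

    group: "PeakGroup"
    fragment_ion: str
    product_charge: int
    endo: TransitionTrace
    std: TransitionTrace

    def __post_init__(self):
        if self.endo.key.label is not Label.ENDOGENOUS:
            raise IncompletePair("endo trace must carry the endogenous label")
        if self.std.key.label is not Label.STANDARD:
            raise IncompletePair("std trace must carry the standard label")
        if (self.endo.key.fragment_key != (self.fragment_ion, self.product_charge)
                or self.std.key.fragment_key != (self.fragment_ion, self.product_charge)):
            raise IncompletePair("pair traces must share fragment ion and product charge")

    @property
    def pair_key(self) -> tuple:
        return self.endo.key.pair_key

    def trace(self, label: Label) -> TransitionTrace:
        return self.endo if label is Label.ENDOGENOUS else self.std


@dataclass
class PeakGroup:
    """All traces of one peptide in one run (every fragment, both labels)."""

    run_id: str
    peptide_sequence: str
    traces: list[TransitionTrace] = field(default_factory=list)

    def __post_init__(self):
        for t in self.traces:
            if (t.key.run_id, t.key.peptide_sequence) != (self.run_id, self.peptide_sequence):
                raise PeakQCError(
                    f"trace {t.key} does not belong to group "
                    f"({self.run_id}, {self.peptide_sequence})")
        bounds = {(t.boundary_start, t.boundary_end) for t in self.traces}
        if len(bounds) > 1:
            raise PeakQCError(
                f"all traces of a peak group must share boundaries: "
                f"({self.run_id}, {self.peptide_sequence}) has {sorted(bounds)}")

    @property
    def boundary_start(self) -> Optional[float]:
        return self.traces[0].boundary_start if self.traces else None

    @property
    def boundary_end(self) -> Optional[float]:
        return self.traces[0].boundary_end if self.traces else None

    @property
    def base_width(self) -> float:
        """Boundary span in minutes (the peak's base width)."""
        return self.boundary_end - self.boundary_start

    def traces_for_label(self, label: Label) -> list[TransitionTrace]:
        return [t for t in self.traces if t.key.label is label]

    def fragment_keys(self) -> list[tuple]:
        """Sorted distinct (fragment_ion, product_charge) in the group."""
        return sorted({t.key.fragment_key for t in self.traces})

    def complete_pairs(self) -> list[TransitionPair]:
        """Fragments with both labels present, as pairs, sorted by fragment."""
        by_frag: dict[tuple, dict[Label, TransitionTrace]] = {}
        for t in self.traces:
            by_frag.setdefault(t.key.fragment_key, {})[t.key.label] = t
        pairs = []
        for frag in sorted(by_frag):
            d = by_frag[frag]
            if Label.ENDOGENOUS in d and Label.STANDARD in d:
                pairs.append(TransitionPair(self, frag[0], frag[1],
                                            d[Label.ENDOGENOUS], d[Label.STANDARD]))
        return pairs

    def incomplete_fragments(self) -> list[tuple]:
        """Fragments missing one isotope label."""
        by_frag: dict[tuple, set] = {}
        for t in self.traces:
            by_frag.setdefault(t.key.fragment_key, set()).add(t.key.label)
        return sorted(f for f, labels in by_frag.items() if len(labels) < 2)


@dataclass(frozen=True)
class Annotation:
    """Analyst verdict for one transition pair: 'ok' or 'flag'."""

    run_id: str
    peptide_sequence: str
    precursor_charge: int
    fragment_ion: str
    product_charge: int
    status: str

    def __post_init__(self):
        from .errors import InvalidStatus
        s = self.status.strip().lower()
        if s not in ("ok", "flag"):
            raise InvalidStatus(f"status must be ok or flag, got {self.status!r}")
        object.__setattr__(self, "status", s)

    @property
    def pair_key(self) -> tuple:
        return (self.run_id, self.peptide_sequence, self.precursor_charge,
                self.fragment_ion, self.product_charge)


@dataclass
class FeatureVector:
    """The 52-entry numeric QC descriptor of one transition pair.

    ``values`` preserves the registry's fixed entry order; entries that could
    not be computed are NaN with the corresponding ``missing_mask`` bit set.
    """

    pair_key: tuple
    values: dict[str, float]
    missing_mask: dict[str, bool]

    def __post_init__(self):
        if set(self.values) != set(self.missing_mask):
            raise PeakQCError("values and missing_mask must share keys")
        for name, v in self.values.items():
            if np.isnan(v) and not self.missing_mask[name]:
                raise PeakQCError(f"NaN value without missing mask: {name}")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def group_traces(traces: Iterable[TransitionTrace]) -> dict[tuple, PeakGroup]:
    """Partition traces into peak groups keyed by (run_id, peptide)."""
    out: dict[tuple, list[TransitionTrace]] = {}
    for t in traces:
        out.setdefault((t.key.run_id, t.key.peptide_sequence), []).append(t)
    return {k: PeakGroup(k[0], k[1], v) for k, v in sorted(out.items())}
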