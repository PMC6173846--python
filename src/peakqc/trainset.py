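"""Assemble the annotated training set from chromatograms, boundaries and
analyst annotations.

Two filters mirror standard practice when preparing supervised peak-QC
data: peptide/run groups without integration boundaries are dropped (there
is no peak region to score), and fragments missing either isotope label are
dropped (the classification unit is the endogenous/standard pair). Pairs
that survive but carry no annotation are kept in a separate prediction
pool, so the same merge serves both training and whole-dataset scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .datamodel import Annotation, PeakGroup, TransitionTrace, group_traces
from .errors import EmptyResult, InvalidStatus, KeyCollision
from .features import KEY_COLUMNS, build_context, compute_features
from .io_skyline import BoundaryTableRow, attach_boundaries, write_table


@dataclass
class AnnotatedSet:
    """Feature vectors joined to analyst status, plus provenance counts.

    ``rows`` carry a ``Status`` column ('ok'/'flag'); ``pool`` holds valid
    but unannotated pairs awaiting model prediction. ``dropped`` counts
    casualties per filter: groups without boundaries, fragments without an
    isotope partner, annotations that matched no surviving pair.
    """

    rows: pd.DataFrame
    pool: pd.DataFrame
    dropped: dict = field(default_factory=dict)
    groups: list = field(default_factory=list)

    @property
    def class_counts(self) -> dict:
        return self.rows["Status"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.rows)


def _normalize_status(s: str) -> str:
    v = str(s).strip().lower()
    if v not in ("ok", "flag"):
        raise InvalidStatus(f"annotation status must be ok or flag, got {s!r}")
    return v


def merge_and_filter(traces: Iterable[TransitionTrace],
                     boundaries: Iterable[BoundaryTableRow],
                     annotations: Optional[Iterable[Annotation]] = None
                     ) -> AnnotatedSet:
    """Join boundaries onto traces, apply the pairing/boundary filters,
    compute features for survivors and join annotations.

    Deterministic: output rows are sorted by the 5-part pair key. Raises
    :class:`KeyCollision` on duplicate trace keys and :class:`EmptyResult`
    when nothing survives.
    """
    traces = list(traces)
    seen = set()
    for t in traces:
        if t.key in seen:
            raise KeyCollision(f"duplicate trace key {t.key}")
        seen.add(t.key)

    boundaries = list(boundaries)
    attach_boundaries(traces, boundaries)
    dropped = {"missing_boundary_groups": 0, "missing_isotope_pair_fragments": 0,
               "unmatched_annotations": 0}

    with_bounds = [t for t in traces if t.has_boundaries]
    all_group_keys = {(t.key.run_id, t.key.peptide_sequence) for t in traces}
    kept_group_keys = {(t.key.run_id, t.key.peptide_sequence) for t in with_bounds}
    dropped["missing_boundary_groups"] = len(all_group_keys) - len(kept_group_keys)

    groups = list(group_traces(with_bounds).values())
    for g in groups:
        dropped["missing_isotope_pair_fragments"] += len(g.incomplete_fragments())
    groups = [g for g in groups if g.complete_pairs()]
    if not groups:
        raise EmptyResult("no peak group survived the boundary/pairing filters")

    features = compute_features(groups)

    if annotations is not None:
        ann_rows = []
        for a in annotations:
            ann_rows.append(dict(zip(KEY_COLUMNS, a.pair_key),
                                 Status=_normalize_status(a.status)))
        ann = pd.DataFrame(ann_rows, columns=KEY_COLUMNS + ["Status"])
        if ann["Status"].isna().any():
            raise InvalidStatus("annotation with missing status")
        if len(ann) != len(ann.drop_duplicates(KEY_COLUMNS)):
            raise KeyCollision("duplicate annotation keys")
        merged = features.merge(ann, on=KEY_COLUMNS, how="left")
        rows = merged[merged["Status"].notna()].reset_index(drop=True)
        pool = (merged[merged["Status"].isna()]
                .drop(columns=["Status"]).reset_index(drop=True))
        dropped["unmatched_annotations"] = int(
            len(ann) - rows[KEY_COLUMNS].merge(ann, on=KEY_COLUMNS).shape[0])
    else:
        rows = features.iloc[0:0].assign(Status=pd.Series(dtype=str))
        pool = features

    return AnnotatedSet(rows=rows, pool=pool, dropped=dropped, groups=groups)


def annotation_template(traces: Iterable[TransitionTrace],
                        boundaries: Iterable[BoundaryTableRow],
                        path) -> pd.DataFrame:
    """Write a CSV with one row per candidate pair and an empty Status
    column for the analyst; pairs failing the filters are absent."""
    aset = merge_and_filter(traces, boundaries, annotations=None)
    template = aset.pool[KEY_COLUMNS].copy()
    template["Status"] = ""
    write_table(path, template)
    return template
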