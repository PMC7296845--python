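"""Cross-competition normalization and blocking-group inference.

Raw fluorescence from sequential two-antibody exposures is mapped to
percent blocking by linear interpolation between two anchors: the signal
after preincubation with a control mAb defines 0% blocking and the signal
after preincubation with the identical mAb defines 100%.  Groups are the
connected components of the mutual-blocking graph; antibodies that fail to
block even themselves are flagged as non-blockers, and pairs blocking in
only one direction are recorded separately and never create edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingAnchorError, SpecValidationError, UndefinedNormalizationError
from .synthetic import RawCompetitionTable

log = logging.getLogger(__name__)

__all__ = [
    "BlockingMatrix",
    "BlockingGroups",
    "percent_blocking",
    "build_matrix",
    "infer_groups",
]


def percent_blocking(raw: float, control_anchor: float, self_anchor: float) -> float:
    """Linear two-anchor normalization of a raw competition fluorescence.

    ``raw == control_anchor`` maps to 0% and ``raw == self_anchor`` to
    100%; values are not clipped, so noise can push results outside
    [0, 100].
    """
    span = control_anchor - self_anchor
    if span == 0 or abs(span) < 1e-12 * max(abs(control_anchor), abs(self_anchor), 1.0):
        raise UndefinedNormalizationError(
            f"control anchor ({control_anchor}) and self anchor ({self_anchor}) "
            "coincide; the assay failed to separate its anchors"
        )
    # divide before scaling so the anchor identities are floating-point exact
    return 100.0 * ((control_anchor - raw) / span)


@dataclass
class BlockingMatrix:
    """mAb x mAb percent blocking (rows: first/blocker, columns: second)."""

    percent: pd.DataFrame
    mab_ids: list[str]
    failed_self_block: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if list(self.percent.index) != self.mab_ids or list(self.percent.columns) != self.mab_ids:
            raise SpecValidationError("percent", "matrix must be indexed by mab_ids on both axes")


@dataclass
class BlockingGroups:
    groups: list[frozenset[str]]
    non_blockers: frozenset[str]
    one_way_pairs: list[tuple[str, str]]  # (blocker, non_reciprocated)
    threshold: float


def build_matrix(
    table: RawCompetitionTable,
    min_self_separation: float = 0.25,
) -> BlockingMatrix:
    """Normalize a raw competition table into a percent-blocking matrix.

    mAb ids are ordered lexicographically, so the result is independent of
    the input row order.  A mAb whose self anchor removes less than
    ``min_self_separation`` of the control signal lacks self-blocking
    capacity: its column cannot be anchored, is filled with NaN, and the
    mAb is recorded in ``failed_self_block``.  Diagonal entries are 100%
    by construction wherever the self anchor holds.
    """
    table.validate()
    mab_ids = sorted(table.mab_ids)
    percent = pd.DataFrame(np.nan, index=mab_ids, columns=mab_ids, dtype=float)
    failed: set[str] = set()

    for second in mab_ids:
        try:
            control = table.control_entries[second]
            self_anchor = table.self_entries[second]
        except KeyError as exc:
            raise MissingAnchorError(
                f"mAb {second!r} lacks a control or self anchor"
            ) from exc
        if control <= 0:
            raise SpecValidationError("control_entries", f"control anchor for {second!r} <= 0")
        separation = (control - self_anchor) / control
        if separation < min_self_separation:
            failed.add(second)
            log.warning(
                "mAb %s fails self-blocking (self anchor removes %.1f%% of control); "
                "its column is left unnormalized",
                second,
                100 * separation,
            )
            continue
        percent.loc[second, second] = 100.0  # self-anchored by construction
        for first in mab_ids:
            if first == second:
                continue
            try:
                raw = table.entries[(first, second)]
            except KeyError as exc:
                raise MissingAnchorError(
                    f"missing raw entry for pair ({first!r}, {second!r})"
                ) from exc
            value = percent_blocking(raw, control, self_anchor)
            if not (0.0 <= value <= 100.0):
                log.info(
                    "percent blocking %.1f for (%s, %s) outside [0, 100]; kept unclipped",
                    value,
                    first,
                    second,
                )
            percent.loc[first, second] = value

    return BlockingMatrix(percent=percent, mab_ids=mab_ids, failed_self_block=failed)


def infer_groups(matrix: BlockingMatrix, threshold: float = 50.0) -> BlockingGroups:
    """Cross-blocking groups, one-way blockers and non-blockers.

    A mAb is a non-blocker when it fails self-blocking (no valid self
    anchor, or diagonal below threshold).  Among the rest, an undirected
    edge joins A and B iff both directions block at or above ``threshold``;
    pairs with exactly one direction above threshold are recorded as
    ``(blocker, non_reciprocated)`` and create no edge.  Groups are the
    connected components of the edge graph; every self-blocking mAb appears
    in a group, singletons included.
    """
    percent = matrix.percent
    if percent.shape[0] != percent.shape[1]:
        raise SpecValidationError("percent", "matrix must be square")
    mabs = matrix.mab_ids

    non_blockers = set(matrix.failed_self_block)
    for m in mabs:
        diag = percent.loc[m, m]
        if np.isnan(diag) or diag < threshold:
            non_blockers.add(m)

    blockers = [m for m in mabs if m not in non_blockers]
    parent = {m: m for m in blockers}

    def find(m: str) -> str:
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    one_way: list[tuple[str, str]] = []
    for i, a in enumerate(blockers):
        for b in blockers[i + 1 :]:
            ab = percent.loc[a, b]
            ba = percent.loc[b, a]
            ab_blocks = bool(np.isfinite(ab) and ab >= threshold)
            ba_blocks = bool(np.isfinite(ba) and ba >= threshold)
            if ab_blocks and ba_blocks:
                parent[find(a)] = find(b)
            elif ab_blocks:
                one_way.append((a, b))
            elif ba_blocks:
                one_way.append((b, a))

    components: dict[str, set[str]] = {}
    for m in blockers:
        components.setdefault(find(m), set()).add(m)
    groups = sorted((frozenset(c) for c in components.values()), key=lambda g: sorted(g))

    return BlockingGroups(
        groups=groups,
        non_blockers=frozenset(non_blockers),
        one_way_pairs=sorted(one_way),
        threshold=float(threshold),
    )
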