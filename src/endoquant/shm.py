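"""Replacement/silent somatic-mutation counting for V-region alignments.

Input is a gap-free germline/mature nucleotide alignment (alignment itself
is upstream).  Per codon in the given reading frame, a single-base
difference is a replacement if the encoded amino acids differ and silent
otherwise.  Codons carrying more than one difference, or an N, are tallied
as ambiguous; the default policy still classifies multi-difference codons
by translating the whole mutated codon against the germline codon, while
N-containing codons are never classified (their base differences count
toward the total only).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .errors import SpecValidationError
from .synthetic import _CODON_AA

log = logging.getLogger(__name__)

__all__ = [
    "IgAlignedPair",
    "MutationSummary",
    "CohortSummary",
    "count_mutations",
    "summarize_cohort",
]

_ALPHABET = set("ACGTN")


@dataclass
class IgAlignedPair:
    germline: str
    mature: str
    reading_frame_offset: Literal[0, 1, 2] = 0

    def __post_init__(self) -> None:
        self.germline = self.germline.upper()
        self.mature = self.mature.upper()
        if len(self.germline) != len(self.mature):
            raise SpecValidationError("mature", "germline and mature lengths differ")
        if set(self.germline) - _ALPHABET or set(self.mature) - _ALPHABET:
            raise SpecValidationError("germline", "alphabet must be {A,C,G,T,N}")
        if self.reading_frame_offset not in (0, 1, 2):
            raise SpecValidationError("reading_frame_offset", "must be 0, 1 or 2")


@dataclass
class MutationSummary:
    total_mutations: int
    replacement: int
    silent: int
    ambiguous_codons: int  # codons with >1 mutated base or containing N
    unclassified: int  # base differences excluded from replacement/silent
    rs_ratio: Optional[float]  # None when silent == 0
    rs_defined: bool
    trailing_bases_ignored: int = 0


def count_mutations(
    pair: IgAlignedPair,
    ambiguous_policy: Literal["translate", "exclude"] = "translate",
    strict_frame: bool = False,
) -> MutationSummary:
    """Count and classify base differences between germline and mature.

    ``ambiguous_policy="translate"`` (default) classifies every difference
    in a multi-difference codon by comparing the translation of the whole
    mutated codon with the germline codon (one event per changed base,
    shared classification).  ``"exclude"`` leaves those differences
    unclassified.  N-containing codons are never classified.  The
    conservation invariant ``replacement + silent + unclassified ==
    total_mutations`` always holds.
    """
    g, m = pair.germline, pair.mature
    offset = pair.reading_frame_offset
    usable = len(g) - offset
    trailing = usable % 3
    if strict_frame and (offset > 0 or trailing):
        raise SpecValidationError(
            "reading_frame_offset", "sequence is not a clean multiple of 3 in strict mode"
        )
    if trailing:
        log.info("ignoring %d trailing bases beyond the last full codon", trailing)
    # leading bases before the frame offset are also outside any codon
    total = sum(1 for a, b in zip(g, m) if a != b)
    in_frame_positions = range(offset, offset + usable - trailing)

    replacement = silent = ambiguous = unclassified = 0
    for start in range(offset, offset + usable - trailing, 3):
        cg = g[start : start + 3]
        cm = m[start : start + 3]
        diffs = sum(1 for a, b in zip(cg, cm) if a != b)
        if diffs == 0:
            continue
        has_n = "N" in cg or "N" in cm
        if diffs > 1 or has_n:
            ambiguous += 1
        if has_n or (diffs > 1 and ambiguous_policy == "exclude"):
            unclassified += diffs
            continue
        same_aa = _CODON_AA[cg] == _CODON_AA[cm]
        if same_aa:
            silent += diffs
        else:
            replacement += diffs

    # differences outside any full codon (offset prefix / trailing suffix)
    outside = total - sum(
        1 for i in in_frame_positions if g[i] != m[i]
    )
    unclassified += outside

    rs_defined = silent > 0
    return MutationSummary(
        total_mutations=total,
        replacement=replacement,
        silent=silent,
        ambiguous_codons=ambiguous,
        unclassified=unclassified,
        rs_ratio=(replacement / silent) if rs_defined else None,
        rs_defined=rs_defined,
        trailing_bases_ignored=trailing + offset,
    )


@dataclass
class CohortSummary:
    per_group: dict[str, list[MutationSummary]]
    median_total: dict[str, float]
    median_rs: dict[str, float]  # NaN when no pair in the group has a defined R:S
    statistic: Optional[float] = None  # difference in group medians of totals
    p_value: Optional[float] = None
    exact: bool = False
    permutations: int = 0


def _median_diff(values: np.ndarray, mask_first: np.ndarray) -> float:
    return float(np.median(values[mask_first]) - np.median(values[~mask_first]))


def summarize_cohort(
    groups: Mapping[str, Sequence[IgAlignedPair]],
    seed: int = 0,
    max_exact: int = 20_000,
    n_permutations: int = 10_000,
    **count_kwargs,
) -> CohortSummary:
    """Per-group mutation summaries plus a two-group comparison.

    With exactly two groups, the total mutation counts are compared by the
    absolute difference in group medians under an exact permutation test
    (all group reassignments enumerated when their number is at most
    ``max_exact``, else a seeded Monte-Carlo permutation test).
    """
    if not groups:
        raise SpecValidationError("groups", "need at least one group")
    per_group: dict[str, list[MutationSummary]] = {}
    for name, pairs in groups.items():
        if len(pairs) == 0:
            raise SpecValidationError("groups", f"group {name!r} is empty")
        per_group[name] = [count_mutations(p, **count_kwargs) for p in pairs]

    median_total = {
        name: float(np.median([s.total_mutations for s in summaries]))
        for name, summaries in per_group.items()
    }
    median_rs = {}
    for name, summaries in per_group.items():
        defined = [s.rs_ratio for s in summaries if s.rs_defined]
        median_rs[name] = float(np.median(defined)) if defined else float("nan")

    result = CohortSummary(per_group=per_group, median_total=median_total, median_rs=median_rs)

    if len(per_group) == 2:
        (name_a, sums_a), (name_b, sums_b) = per_group.items()
        values = np.array(
            [s.total_mutations for s in sums_a] + [s.total_mutations for s in sums_b],
            dtype=float,
        )
        n_a = len(sums_a)
        n = len(values)
        obs_mask = np.zeros(n, dtype=bool)
        obs_mask[:n_a] = True
        obs = _median_diff(values, obs_mask)
        tol = 1e-12

        from math import comb

        if comb(n, n_a) <= max_exact:
            count = total = 0
            for combo in itertools.combinations(range(n), n_a):
                mask = np.zeros(n, dtype=bool)
                mask[list(combo)] = True
                if abs(_median_diff(values, mask)) >= abs(obs) - tol:
                    count += 1
                total += 1
            result.p_value = count / total
            result.exact = True
            result.permutations = total
        else:
            rng = np.random.default_rng(seed)
            count = 0
            idx = np.arange(n)
            for _ in range(n_permutations):
                perm = rng.permutation(idx)
                mask = np.zeros(n, dtype=bool)
                mask[perm[:n_a]] = True
                if abs(_median_diff(values, mask)) >= abs(obs) - tol:
                    count += 1
            result.p_value = (count + 1) / (n_permutations + 1)
            result.exact = False
            result.permutations = n_permutations
        result.statistic = obs

    return result
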