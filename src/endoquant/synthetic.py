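"""Synthetic-data generators with known ground truth.

Everything the analysis modules consume can be generated here at desk
scale: time-lapse stacks with planted internalization clusters, one-site
titration curves, raw cross-competition tables with planted blocking-group
structure, dilution series with known titres, and germline/mature V-region
pairs with controlled replacement/silent mutation counts.

All generators are seed-deterministic: the same spec and seed produce
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InfeasibleSpecError, SpecValidationError
from .imaging import FrameStack

__all__ = [
    "ClusterSpec",
    "StackSpec",
    "SimulatedStack",
    "simulate_stack",
    "TitrationSpec",
    "TitrationCurve",
    "simulate_titration",
    "CompetitionSpec",
    "RawCompetitionTable",
    "simulate_blocking_matrix",
    "DilutionSpec",
    "simulate_dilution_series",
    "IgPairSpec",
    "SimulatedIgPair",
    "simulate_ig_pair",
]

# --------------------------------------------------------------------------
# Imaging stacks


@dataclass
class ClusterSpec:
    """A hard disk of signal switching on at ``onset_frame``.

    ``amplitude_curve[j]`` is the intensity added to every disk pixel at
    frame ``onset_frame + j``; the last value persists for later frames.
    """

    center: tuple[int, int]
    radius: float
    onset_frame: int
    amplitude_curve: Sequence[float]

    def validate(self, n_frames: int) -> None:
        if self.radius < 1:
            raise SpecValidationError("radius", "must be >= 1")
        if not (0 <= self.onset_frame < n_frames):
            raise SpecValidationError(
                "onset_frame", f"must lie within the stack (0..{n_frames - 1})"
            )
        if len(self.amplitude_curve) == 0:
            raise SpecValidationError("amplitude_curve", "must be non-empty")
        if any(a < 0 for a in self.amplitude_curve):
            raise SpecValidationError("amplitude_curve", "amplitudes must be non-negative")


@dataclass
class StackSpec:
    height: int
    width: int
    n_frames: int
    frame_interval: float = 15.0
    background_level: float = 100.0
    background_noise_sd: float = 0.0
    # deterministic checkerboard texture: pixels with odd (row+col) sit at
    # background_level + this amplitude.  With even image area exactly half
    # the pixels deviate, so zero-noise stacks stay non-degenerate under
    # MAD normalization while the baseline 99th percentile still equals the
    # maximum normalized value (baseline S_int is exactly 0).
    background_checker_amplitude: float = 0.0
    clusters: Sequence[ClusterSpec] = field(default_factory=list)
    global_gain_drift: Optional[Sequence[float]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0:
            raise SpecValidationError("height", "must be positive")
        if self.width <= 0:
            raise SpecValidationError("width", "must be positive")
        if self.n_frames < 4:
            raise SpecValidationError(
                "n_frames", "must be >= 4 (time-lapse threshold needs four baseline frames)"
            )
        if self.frame_interval <= 0:
            raise SpecValidationError("frame_interval", "must be positive")
        if self.background_level < 0:
            raise SpecValidationError("background_level", "must be >= 0")
        if self.background_noise_sd < 0:
            raise SpecValidationError("background_noise_sd", "must be >= 0")
        if self.background_checker_amplitude < 0:
            raise SpecValidationError("background_checker_amplitude", "must be >= 0")
        if self.global_gain_drift is not None:
            if len(self.global_gain_drift) != self.n_frames:
                raise SpecValidationError(
                    "global_gain_drift", "length must equal n_frames"
                )
            if any(g <= 0 for g in self.global_gain_drift):
                raise SpecValidationError(
                    "global_gain_drift", "gain factors must be strictly positive"
                )
        for c in self.clusters:
            c.validate(self.n_frames)


@dataclass
class SimulatedStack:
    """A generated stack plus its ground truth."""

    stack: FrameStack
    cluster_labels: np.ndarray  # (height, width); 0 = background, 1..n = clusters
    onset_frames: list[int]


def _disk_mask(height: int, width: int, center: tuple[int, int], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:height, :width]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def simulate_stack(spec: StackSpec) -> SimulatedStack:
    """Generate a stack: ``frame[t] = gain[t] * clip(background + noise + signal, 0)``.

    Cluster signal at frame ``t`` adds ``amplitude_curve[t - onset]`` (last
    value held) to each pixel of the cluster's disk once ``t >= onset``.
    Gaussian noise is clipped at 0 (fluorescence cannot be negative), and
    the per-frame multiplicative gain drift is applied last so the robust
    normalization's affine invariance can be exercised.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gain = (
        np.ones(spec.n_frames)
        if spec.global_gain_drift is None
        else np.asarray(spec.global_gain_drift, dtype=float)
    )
    labels = np.zeros((spec.height, spec.width), dtype=int)
    disks = []
    for i, cluster in enumerate(spec.clusters, start=1):
        mask = _disk_mask(spec.height, spec.width, cluster.center, cluster.radius)
        labels[mask] = i
        disks.append(mask)

    rr, cc = np.indices((spec.height, spec.width))
    checker = spec.background_checker_amplitude * ((rr + cc) % 2)

    frames = np.empty((spec.n_frames, spec.height, spec.width))
    for t in range(spec.n_frames):
        frame = np.full((spec.height, spec.width), float(spec.background_level)) + checker
        if spec.background_noise_sd > 0:
            frame += rng.normal(0.0, spec.background_noise_sd, size=frame.shape)
        for cluster, mask in zip(spec.clusters, disks):
            if t >= cluster.onset_frame:
                j = min(t - cluster.onset_frame, len(cluster.amplitude_curve) - 1)
                frame[mask] += cluster.amplitude_curve[j]
        np.clip(frame, 0.0, None, out=frame)
        frames[t] = gain[t] * frame

    stack = FrameStack(frames=frames, frame_interval=spec.frame_interval)
    return SimulatedStack(
        stack=stack,
        cluster_labels=labels,
        onset_frames=[c.onset_frame for c in spec.clusters],
    )


# --------------------------------------------------------------------------
# Titrations


@dataclass
class TitrationSpec:
    true_Kd: float
    true_Bmax: float
    concentrations: Sequence[float]
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.true_Kd <= 0:
            raise SpecValidationError("true_Kd", "must be > 0")
        if self.true_Bmax <= 0:
            raise SpecValidationError("true_Bmax", "must be > 0")
        if any(x < 0 for x in self.concentrations):
            raise SpecValidationError("concentrations", "must be non-negative")
        if len(set(self.concentrations)) < 4:
            raise SpecValidationError("concentrations", "need at least 4 distinct values")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")


@dataclass
class TitrationCurve:
    """Antibody concentration (x, µg/ml) vs specific binding (y, a.u.)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise SpecValidationError("x/y", "must have equal lengths")
        if self.x.size < 4:
            raise SpecValidationError("x", "need at least 4 points")
        if np.any(self.x < 0):
            raise SpecValidationError("x", "concentrations must be >= 0")
        if len(np.unique(self.x)) < 3:
            raise SpecValidationError("x", "need at least 3 distinct concentrations")


def one_site(x: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """One-site specific-binding hyperbola ``y = Bmax * x / (x + Kd)``."""
    x = np.asarray(x, dtype=float)
    return bmax * x / (x + kd)


def simulate_titration(spec: TitrationSpec) -> TitrationCurve:
    """Evaluate the one-site hyperbola at the spec's grid and add clipped noise.

    With ``noise_sd == 0`` the curve reproduces the model exactly at every
    grid point (machine precision).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.concentrations, dtype=float)
    y = one_site(x, spec.true_Bmax, spec.true_Kd)
    if spec.noise_sd > 0:
        y = np.clip(y + rng.normal(0.0, spec.noise_sd, size=y.shape), 0.0, None)
    return TitrationCurve(x=x, y=y)


# --------------------------------------------------------------------------
# Cross-competition

NON_BLOCKER = "non-blocker"


@dataclass
class CompetitionSpec:
    """Planted cross-blocking structure.

    ``group_assignment`` maps each mAb to a group label, or to
    ``"non-blocker"`` for antibodies lacking self-blocking capacity.
    ``one_way_pairs`` lists ordered ``(blocker, non_reciprocated)`` pairs
    within a group: the blocker blocks its partner, but not vice versa.
    """

    mab_ids: Sequence[str]
    group_assignment: Mapping[str, str]
    one_way_pairs: Sequence[tuple[str, str]] = field(default_factory=list)
    signal_control: float = 1000.0
    signal_self: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0
    control_id: str = "ctrl"

    def validate(self) -> None:
        if len(set(self.mab_ids)) != len(self.mab_ids):
            raise SpecValidationError("mab_ids", "must be unique")
        if self.control_id in self.mab_ids:
            raise SpecValidationError("control_id", "must not collide with a mAb id")
        for m in self.mab_ids:
            if m not in self.group_assignment:
                raise SpecValidationError("group_assignment", f"missing mAb {m!r}")
        if not (self.signal_control > self.signal_self >= 0):
            raise SpecValidationError(
                "signal_control", "must satisfy signal_control > signal_self >= 0"
            )
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")
        for a, b in self.one_way_pairs:
            ga, gb = self.group_assignment.get(a), self.group_assignment.get(b)
            if ga is None or gb is None:
                raise SpecValidationError("one_way_pairs", f"unknown mAb in ({a}, {b})")
            if ga != gb or ga == NON_BLOCKER:
                raise SpecValidationError(
                    "one_way_pairs", f"pair ({a}, {b}) must lie within a single group"
                )

    def blocks(self, first: str, second: str) -> bool:
        """Whether preincubation with ``first`` blocks binding of ``second``."""
        gf = self.group_assignment[first]
        gs = self.group_assignment[second]
        if gf == NON_BLOCKER or gs == NON_BLOCKER:
            return False
        if gf != gs:
            return False
        # (blocker=second, non_reciprocated=first) means first fails to
        # block second even though they share a group.
        if (second, first) in tuple(self.one_way_pairs):
            return False
        return True


@dataclass
class RawCompetitionTable:
    """Raw fluorescence from sequential two-antibody exposures.

    ``entries[(first, second)]`` is the fluorescence of labelled ``second``
    after preincubation with ``first``; ``control_entries`` / ``self_entries``
    are the anchors with the control mAb, resp. the identical mAb, first.
    """

    mab_ids: list[str]
    entries: dict[tuple[str, str], float]
    control_entries: dict[str, float]
    self_entries: dict[str, float]
    control_id: str = "ctrl"

    def validate(self) -> None:
        for (first, second) in self.entries:
            if second not in self.control_entries or second not in self.self_entries:
                raise SpecValidationError(
                    "entries", f"pair ({first}, {second}) lacks control/self anchors"
                )
        if any(v < 0 for v in self.entries.values()):
            raise SpecValidationError("entries", "raw fluorescence must be >= 0")


def simulate_blocking_matrix(spec: CompetitionSpec) -> RawCompetitionTable:
    """Generate raw competition fluorescence for every ordered mAb pair.

    Blocked pairs read near ``signal_self``, unblocked near
    ``signal_control``; control rows anchor 0% and self rows anchor 100%
    blocking.  A non-blocker's self row sits at the control level (it fails
    to block even itself).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    def noisy(level: float) -> float:
        if spec.noise_sd == 0:
            return float(level)
        return float(max(0.0, level + rng.normal(0.0, spec.noise_sd)))

    entries: dict[tuple[str, str], float] = {}
    control_entries: dict[str, float] = {}
    self_entries: dict[str, float] = {}
    for second in spec.mab_ids:
        control_entries[second] = noisy(spec.signal_control)
        self_level = (
            spec.signal_self if spec.blocks(second, second) else spec.signal_control
        )
        self_entries[second] = noisy(self_level)
        for first in spec.mab_ids:
            if first == second:
                continue
            level = spec.signal_self if spec.blocks(first, second) else spec.signal_control
            entries[(first, second)] = noisy(level)

    table = RawCompetitionTable(
        mab_ids=list(spec.mab_ids),
        entries=entries,
        control_entries=control_entries,
        self_entries=self_entries,
        control_id=spec.control_id,
    )
    table.validate()
    return table


# --------------------------------------------------------------------------
# Dilution series


@dataclass
class DilutionSpec:
    """A serial dilution with a planted end-point titre.

    ``true_titre`` is the largest reciprocal dilution still positive; 0
    plants an all-negative series.
    """

    dilutions: Sequence[int]
    true_titre: int
    positive_level: float = 500.0
    negative_level: float = 20.0
    control_level: float = 20.0
    control_sd: float = 2.0
    n_controls: int = 8
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        d = list(self.dilutions)
        if len(d) < 2 or any(b <= a for a, b in zip(d, d[1:])):
            raise SpecValidationError("dilutions", "must be strictly increasing, length >= 2")
        if self.true_titre != 0 and self.true_titre not in d:
            raise SpecValidationError("true_titre", "must be 0 or one of the dilutions")
        if self.positive_level <= self.negative_level:
            raise SpecValidationError("positive_level", "must exceed negative_level")
        if self.n_controls < 2:
            raise SpecValidationError("n_controls", "need >= 2 control wells")


def simulate_dilution_series(spec: DilutionSpec):
    """Generate (dilutions, signals, control_signals) with a known titre."""
    from .binding import DilutionSeries  # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    signals = []
    for d in spec.dilutions:
        level = spec.positive_level if (spec.true_titre and d <= spec.true_titre) else spec.negative_level
        if spec.noise_sd > 0:
            level = max(0.0, level + rng.normal(0.0, spec.noise_sd))
        signals.append(float(level))
    controls = np.clip(
        rng.normal(spec.control_level, spec.control_sd, size=spec.n_controls), 0.0, None
    )
    return DilutionSeries(
        dilutions=list(spec.dilutions),
        signals=signals,
        control_signals=controls.tolist(),
    )


# --------------------------------------------------------------------------
# Ig V-region pairs

_BASES = "ACGT"


def _translate_table() -> dict[str, str]:
    from Bio.Seq import Seq

    return {
        a + b + c: str(Seq(a + b + c).translate())
        for a in _BASES
        for b in _BASES
        for c in _BASES
    }


_CODON_AA = _translate_table()
_STOPS = {c for c, aa in _CODON_AA.items() if aa == "*"}


def _single_base_variants(codon: str):
    for pos in range(3):
        for base in _BASES:
            if base != codon[pos]:
                yield codon[:pos] + base + codon[pos + 1 :]


def _synonymous_variants(codon: str) -> list[str]:
    aa = _CODON_AA[codon]
    return [v for v in _single_base_variants(codon) if _CODON_AA[v] == aa]


def _replacement_variants(codon: str) -> list[str]:
    aa = _CODON_AA[codon]
    return [
        v for v in _single_base_variants(codon) if _CODON_AA[v] != aa and v not in _STOPS
    ]


@dataclass
class IgPairSpec:
    v_region_length: int
    n_replacement: int
    n_silent: int
    seed: int = 0
    germline: Optional[str] = None  # explicit germline overrides generation

    def validate(self) -> None:
        if self.v_region_length < 3 or self.v_region_length % 3 != 0:
            raise SpecValidationError(
                "v_region_length", "must be a positive multiple of 3, >= 3"
            )
        if self.n_replacement < 0 or self.n_silent < 0:
            raise SpecValidationError("n_replacement", "mutation counts must be >= 0")
        if self.n_replacement + self.n_silent > self.v_region_length:
            raise SpecValidationError(
                "n_replacement", "total mutations cannot exceed the sequence length"
            )
        if self.germline is not None:
            if len(self.germline) != self.v_region_length:
                raise SpecValidationError("germline", "length must equal v_region_length")
            if set(self.germline) - set(_BASES):
                raise SpecValidationError("germline", "alphabet must be {A,C,G,T}")


@dataclass
class SimulatedIgPair:
    germline: str
    mature: str
    replacement_codons: list[int]
    silent_codons: list[int]


def simulate_ig_pair(spec: IgPairSpec) -> SimulatedIgPair:
    """Generate a germline/mature pair with planted mutation counts.

    At most one substitution is placed per codon so downstream counting
    recovers the planted (replacement, silent) counts exactly.  Silent
    mutations are placed only at codons scanning left-to-right that admit a
    synonymous single-base change; if too few exist the spec is infeasible.
    Stop codons are avoided in both sequences.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.germline is not None:
        germline = spec.germline
        if any(germline[i : i + 3] in _STOPS for i in range(0, len(germline), 3)):
            raise SpecValidationError("germline", "must not contain stop codons")
    else:
        sense = sorted(set(_CODON_AA) - _STOPS)
        n_codons = spec.v_region_length // 3
        germline = "".join(rng.choice(sense, size=n_codons))

    codons = [germline[i : i + 3] for i in range(0, len(germline), 3)]
    silent_capable = [i for i, c in enumerate(codons) if _synonymous_variants(c)]
    if len(silent_capable) < spec.n_silent:
        raise InfeasibleSpecError(
            f"requested {spec.n_silent} silent mutations but only "
            f"{len(silent_capable)} codons admit a synonymous single-base change"
        )
    n_total = spec.n_replacement + spec.n_silent
    if n_total > len(codons):
        raise InfeasibleSpecError(
            f"requested {n_total} mutated codons but the sequence has only {len(codons)}"
        )

    silent_idx = sorted(
        rng.choice(silent_capable, size=spec.n_silent, replace=False).tolist()
    ) if spec.n_silent else []
    remaining = [i for i in range(len(codons)) if i not in silent_idx]
    if len(remaining) < spec.n_replacement:
        raise InfeasibleSpecError("not enough codons left for replacement mutations")
    repl_idx = sorted(
        rng.choice(remaining, size=spec.n_replacement, replace=False).tolist()
    ) if spec.n_replacement else []

    mature = list(codons)
    for i in silent_idx:
        mature[i] = str(rng.choice(_synonymous_variants(codons[i])))
    for i in repl_idx:
        variants = _replacement_variants(codons[i])
        if not variants:  # pragma: no cover - every sense codon has one
            raise InfeasibleSpecError(f"codon {codons[i]} admits no replacement variant")
        mature[i] = str(rng.choice(variants))

    return SimulatedIgPair(
        germline=germline,
        mature="".join(mature),
        replacement_codons=repl_idx,
        silent_codons=silent_idx,
    )
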