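"""Synthetic fixtures: feature tables with planted structure and
procedural toy SWC trees.

The table generator emulates the shape of real morphometric data —
severely imbalanced classes, a handful of genuinely class-informative
features, noisy linear copies of them (redundant), and pure noise — with
class-conditional Gaussian features.  Column names reuse the 43-metric
catalog abbreviations so pipelines look like the real thing, but the
values are synthetic and not morphometrically consistent with each other.

The tree generator grows rooted trees by recursive branching with
class-dependent statistics and emits standard SWC text, so the
morphometry path is testable without any download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from bmsf.morphometry import ALL_FEATURE_NAMES

__all__ = [
    "TableSpec",
    "TreeSpec",
    "GroundTruth",
    "largest_remainder_counts",
    "generate_feature_table",
    "generate_toy_swc",
    "planted_benchmark_spec",
    "hierarchy_benchmark_spec",
    "TABLE1_PROPORTIONS",
    "TABLE1_CLASS_NAMES",
]

#: Class proportions mirroring the 7-type neuron corpus (pyramidal
#: dominating at ~81%, Purkinje rarest at ~0.3%).
TABLE1_PROPORTIONS: tuple[float, ...] = (
    0.811, 0.076, 0.067, 0.024, 0.012, 0.006, 0.003)
TABLE1_CLASS_NAMES: tuple[str, ...] = (
    "pyramidal", "motoneuron", "sensory", "tripolar", "bipolar",
    "multipolar", "purkinje")

#: Default planted-informative features (names the selector is expected
#: to recover) and the redundant copies layered on top of them.
DEFAULT_INFORMATIVE: tuple[str, ...] = ("N_s", "NW", "HT", "Ta2", "SS")
DEFAULT_REDUNDANT: tuple[str, ...] = ("RP", "Bar", "PDR", "Lpd", "Pa")


def largest_remainder_counts(n: int, proportions: Sequence[float],
                             ) -> list[int]:
    """Integer class counts summing exactly to n (largest-remainder
    apportionment; ties go to the earlier class)."""
    props = np.asarray(proportions, dtype=float)
    props = props / props.sum()
    raw = props * n
    base = np.floor(raw).astype(int)
    leftover = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:leftover]:
        base[i] += 1
    return base.tolist()


@dataclass(frozen=True)
class GroundTruth:
    """Which generated columns carry signal."""

    informative: tuple[str, ...]
    redundant: dict[str, str]       # redundant column -> source column
    noise: tuple[str, ...]


@dataclass(frozen=True)
class TableSpec:
    """Recipe for a planted-structure feature table.

    ``informative`` maps feature name -> (per-class mean shifts, SD).
    The default plants 3-SD one-hot signatures: informative feature i
    shifts class ``1 + i mod (n_classes - 1)`` by ``shift_sd`` standard
    deviations, so every informative feature is required to tell its
    marked class from the baseline class.  Redundant features are
    ``alpha * source + noise``; everything else is standard normal.
    """

    n_samples: int = 586
    class_proportions: tuple[float, ...] = TABLE1_PROPORTIONS
    class_names: tuple[str, ...] = TABLE1_CLASS_NAMES
    feature_names: tuple[str, ...] = ALL_FEATURE_NAMES
    informative: Mapping[str, tuple[tuple[float, ...], float]] | None = None
    redundant: Mapping[str, str] | None = None
    shift_sd: float = 3.0
    redundant_alpha: float = 0.8
    redundant_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_proportions) != len(self.class_names):
            raise ValueError("one proportion per class name required")
        if abs(sum(self.class_proportions) - 1.0) > 0.01:
            raise ValueError("class proportions must sum to 1")

    def resolve_plant(self) -> tuple[dict[str, tuple[tuple[float, ...],
                                                     float]],
                                     dict[str, str]]:
        """Fill in the default informative/redundant plan."""
        n_classes = len(self.class_names)
        if self.informative is not None:
            informative = {k: (tuple(v[0]), float(v[1]))
                           for k, v in self.informative.items()}
        else:
            informative = {}
            names = [f for f in DEFAULT_INFORMATIVE
                     if f in self.feature_names]
            for i, name in enumerate(names):
                shifts = [0.0] * n_classes
                shifts[1 + i % (n_classes - 1)] = self.shift_sd
                informative[name] = (tuple(shifts), 1.0)
        if self.redundant is not None:
            redundant = dict(self.redundant)
        else:
            sources = list(informative)
            redundant = {
                name: sources[i % len(sources)]
                for i, name in enumerate(
                    f for f in DEFAULT_REDUNDANT if f in self.feature_names)
            } if sources else {}
        for name, (shifts, sd) in informative.items():
            if name not in self.feature_names:
                raise ValueError(f"informative feature {name!r} not in "
                                 "feature_names")
            if len(shifts) != n_classes or sd <= 0:
                raise ValueError(f"bad informative spec for {name!r}")
        for name, src in redundant.items():
            if src not in informative:
                raise ValueError(f"redundant {name!r} copies non-"
                                 f"informative {src!r}")
        return informative, redundant


def generate_feature_table(spec: TableSpec,
                           ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a labeled table with planted structure.

    Returns the table (feature columns in spec order plus ``label``) and
    the ground truth listing informative / redundant / noise columns.
    Reproducible from ``spec.seed``; a class receiving zero samples at
    the requested size is an error.
    """
    counts = largest_remainder_counts(spec.n_samples,
                                      spec.class_proportions)
    empty = [c for c, n in zip(spec.class_names, counts) if n == 0]
    if empty:
        raise ValueError(
            f"classes {empty} receive 0 samples at n={spec.n_samples}; "
            "increase n_samples or merge classes")
    informative, redundant = spec.resolve_plant()
    rng = np.random.default_rng(spec.seed)
    labels = np.repeat(spec.class_names, counts)
    class_index = np.repeat(np.arange(len(counts)), counts)
    n = spec.n_samples

    columns: dict[str, np.ndarray] = {}
    for name, (shifts, sd) in informative.items():
        mu = np.asarray(shifts, dtype=float)[class_index]
        columns[name] = mu + sd * rng.standard_normal(n)
    for name, src in redundant.items():
        columns[name] = (spec.redundant_alpha * columns[src]
                         + spec.redundant_noise_sd * rng.standard_normal(n))
    noise_names = tuple(f for f in spec.feature_names
                        if f not in columns)
    for name in noise_names:
        columns[name] = rng.standard_normal(n)

    table = pd.DataFrame({f: columns[f] for f in spec.feature_names})
    table["label"] = labels
    truth = GroundTruth(informative=tuple(informative),
                        redundant=dict(redundant), noise=noise_names)
    return table, truth


def planted_benchmark_spec(n_samples: int = 300, seed: int = 0) -> TableSpec:
    """The planted-recovery study table: 40 generic features over six
    imbalanced classes.

    Features ``f0..f4`` are informative one-hot marks: feature i shifts
    class i+1 by 3 SD while class 0 stays baseline, so *every*
    informative feature is strictly necessary (dropping f_i merges class
    i+1 into the baseline and costs that class's share of accuracy).
    ``f5..f9`` are noisy linear copies of the informative five;
    ``f10..f39`` are pure noise.  Class proportions (0.30, 0.20, 0.15,
    0.13, 0.12, 0.10) keep the rarest class stratifiable at ten folds
    for n >= 300.
    """
    names = tuple(f"f{i}" for i in range(40))
    n_classes = 6
    informative = {}
    for i in range(5):
        shifts = [0.0] * n_classes
        shifts[i + 1] = 3.0
        informative[f"f{i}"] = (tuple(shifts), 1.0)
    return TableSpec(
        n_samples=n_samples,
        class_proportions=(0.30, 0.20, 0.15, 0.13, 0.12, 0.10),
        class_names=tuple(f"class{i}" for i in range(n_classes)),
        feature_names=names,
        informative=informative,
        redundant={f"f{i + 5}": f"f{i}" for i in range(5)},
        seed=seed,
    )


def hierarchy_benchmark_spec(n_samples: int = 350, seed: int = 0,
                             ) -> TableSpec:
    """Seven imbalanced classes, each with its own strong (4-SD)
    class-specific signature, for the one-vs-rest hierarchy study.

    Every class i gets a private informative mark g_i — every one-vs-
    rest level's positive class is then characterised by a feature of
    its own, the condition the cascade is designed for.  Nine further
    features are pure noise, so per-level selection has something to
    discard.  n defaults to 350 so the smallest positive class keeps
    enough test samples that a single misclassified neuron cannot
    dominate its recall.
    """
    n_classes = 7
    informative = {}
    for i in range(n_classes):
        shifts = [0.0] * n_classes
        shifts[i] = 4.0
        informative[f"g{i}"] = (tuple(shifts), 1.0)
    names = tuple(f"g{i}" for i in range(16))
    return TableSpec(
        n_samples=n_samples,
        class_proportions=(0.30, 0.18, 0.14, 0.12, 0.10, 0.09, 0.07),
        class_names=tuple(f"type{i}" for i in range(n_classes)),
        feature_names=names,
        informative=informative,
        redundant={},
        seed=seed,
    )


@dataclass(frozen=True)
class TreeSpec:
    """Recipe for one procedural toy neuron.

    Branches are chains of ``compartments_per_branch`` segments with
    Gaussian lengths; at the end of each branch the tree bifurcates with
    probability ``branch_prob`` (always, at probability 1) until
    ``max_depth``; radii shrink by ``taper`` per branch.  ``jitter``
    bends compartment directions so paths are not collinear.
    """

    branch_prob: float = 0.5
    segment_length_mean: float = 20.0
    segment_length_sd: float = 4.0
    compartments_per_branch: int = 3
    taper: float = 0.85
    max_depth: int = 5
    stem_count: int = 2
    initial_radius: float = 1.0
    soma_radius: float = 5.0
    jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.segment_length_mean <= 0:
            raise ValueError("segment lengths must be positive")


def generate_toy_swc(spec: TreeSpec) -> str:
    """Grow one tree and emit standard 7-column SWC text."""
    rng = np.random.default_rng(spec.seed)
    lines = ["# procedural toy neuron (synthetic)",
             f"1 1 0.0 0.0 0.0 {spec.soma_radius} -1"]
    next_id = 2

    def unit(v: np.ndarray) -> np.ndarray:
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else np.array([1.0, 0.0, 0.0])

    def seg_length() -> float:
        return max(0.5, rng.normal(spec.segment_length_mean,
                                   spec.segment_length_sd))

    def grow(parent_id: int, pos: np.ndarray, direction: np.ndarray,
             radius: float, depth: int) -> None:
        nonlocal next_id
        # one branch: a run of compartments
        for _ in range(spec.compartments_per_branch):
            direction = unit(direction
                             + spec.jitter * rng.standard_normal(3))
            pos = pos + seg_length() * direction
            lines.append(
                f"{next_id} 3 {pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f} "
                f"{radius:.4f} {parent_id}")
            parent_id = next_id
            next_id += 1
        if depth < spec.max_depth and rng.random() < spec.branch_prob:
            axis = unit(np.cross(direction, rng.standard_normal(3)))
            for sign in (1.0, -1.0):
                d = unit(direction + sign * 0.7 * axis)
                grow(parent_id, pos, d, radius * spec.taper, depth + 1)

    for s in range(spec.stem_count):
        angle = 2.0 * math.pi * s / spec.stem_count
        direction = np.array([math.cos(angle), math.sin(angle), 0.0])
        grow(1, np.zeros(3), direction, spec.initial_radius, depth=0)
    return "\n".join(lines) + "\n"
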