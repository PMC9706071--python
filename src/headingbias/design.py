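"""Heading-distribution designs and trial schedules.

A block of a heading-perception experiment shows a fixed multiset of
heading angles (the "previous heading distribution") in random order.
Angles are in degrees, positive rightward of the ego-centric
(straight-ahead) direction at 0°.

Six preset designs are provided, covering two uniform blocks with
different widths and means, two narrow uniform blocks, and a pair of
600-trial blocks in which one distribution is right-heavied (more
trials on rightward headings, count-weighted mean 12°).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np

__all__ = [
    "HeadingDistribution",
    "TrialSchedule",
    "PRESET_NAMES",
    "make_distribution",
    "distribution_mean",
    "generate_schedule",
    "export_presets",
]


@dataclass(frozen=True)
class HeadingDistribution:
    """A named set of heading angles with per-heading trial counts."""

    name: str
    headings: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "headings", tuple(float(h) for h in self.headings))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.headings) != len(self.counts):
            raise ValueError(
                f"{self.name}: {len(self.headings)} headings but {len(self.counts)} counts"
            )
        if len(self.headings) < 1:
            raise ValueError(f"{self.name}: empty heading set")
        diffs = np.diff(self.headings)
        if not np.all(diffs > 0):
            raise ValueError(f"{self.name}: headings must be strictly increasing")
        if any(c < 1 for c in self.counts):
            raise ValueError(f"{self.name}: all counts must be >= 1")
        if any(abs(h) > 90 for h in self.headings):
            raise ValueError(f"{self.name}: |heading| must be <= 90 deg")

    @property
    def n_trials(self) -> int:
        return int(sum(self.counts))

    def trial_multiset(self) -> np.ndarray:
        """All trials' headings as a sorted array (one entry per trial)."""
        return np.repeat(np.asarray(self.headings), np.asarray(self.counts))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "headings": list(self.headings),
            "counts": list(self.counts),
        }


@dataclass(frozen=True)
class TrialSchedule:
    """A randomized, reproducible ordering of a distribution's trials."""

    distribution: HeadingDistribution
    order: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        expected = np.sort(self.distribution.trial_multiset())
        got = np.sort(np.asarray(self.order, dtype=float))
        if got.shape != expected.shape or not np.array_equal(got, expected):
            raise ValueError(
                "schedule order is not a permutation of the distribution's trials"
            )

    def __len__(self) -> int:
        return len(self.order)


_WIDE = tuple(range(-33, 34, 6))  # ±3, ±9, ±15, ±21, ±27, ±33
_RIGHT_HEAVIED_COUNTS = (16, 16, 16, 16, 16, 22, 42, 84, 124, 124, 82, 42)

_PRESETS: dict[str, HeadingDistribution] = {
    d.name: d
    for d in (
        HeadingDistribution("symmetric_wide_uniform", _WIDE, (50,) * 12),
        HeadingDistribution(
            "right_shifted_narrow_uniform", (3, 9, 15, 21, 27, 33), (50,) * 6
        ),
        HeadingDistribution(
            "symmetric_narrow_uniform", (-15, -9, -3, 3, 9, 15), (50,) * 6
        ),
        HeadingDistribution(
            "left_shifted_narrow_uniform", (-33, -27, -21, -15, -9, -3), (50,) * 6
        ),
        HeadingDistribution("symmetric_uniform_exp3", _WIDE, (50,) * 12),
        HeadingDistribution("right_heavied_nonuniform", _WIDE, _RIGHT_HEAVIED_COUNTS),
    )
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)


def make_distribution(name: str) -> HeadingDistribution:
    """Return one of the preset heading distributions by name.

    Raises
    ------
    KeyError
        If ``name`` is not a known preset; the message lists valid names.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown design preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None


def distribution_mean(dist: HeadingDistribution) -> float:
    """Count-weighted mean heading of a distribution, in degrees."""
    h = np.asarray(dist.headings, dtype=float)
    c = np.asarray(dist.counts, dtype=float)
    return float(np.sum(h * c) / np.sum(c))


def generate_schedule(dist: HeadingDistribution, seed: int) -> TrialSchedule:
    """Uniformly random permutation of the block's trials, fixed by ``seed``."""
    if seed < 0:
        raise ValueError("seed must be a nonnegative integer")
    rng = np.random.default_rng(seed)
    order = dist.trial_multiset().copy()
    rng.shuffle(order)
    return TrialSchedule(distribution=dist, order=tuple(order), seed=int(seed))


def export_presets(path) -> None:
    """Write all presets as a machine-readable JSON design file."""
    payload = [make_distribution(n).to_dict() for n in PRESET_NAMES]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
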