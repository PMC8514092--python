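"""The Radical Stability Score and stability-map coordinates.

The two descriptors — maximum heavy-atom fractional spin (thermodynamic
delocalization, lower is more stabilized) and percent buried volume at
the radical center (kinetic steric protection, higher is more protected)
— combine linearly into a single score:

    RSS = %V_bur + w × (1 − max_spin),   w = 50 by default

The weight of 50 gives the spin term (0–50) roughly the same span as the
observed buried volumes (≈13–65%), so both contributions carry
comparable weight. RSS is an ordinal stability metric: higher means a
better joint claim to thermodynamic and kinetic stability, not a
predicted half-life.
"""

from __future__ import annotations

from dataclasses import dataclass

from .buried_volume import GridSpec, buried_volume
from .molio import MolecularStructure
from .spin_analysis import fractional_spins

__all__ = [
    "ScoreConfig",
    "StabilityRecord",
    "radical_stability_score",
    "score_structure",
    "map_coordinates",
    "quadrant",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Weight on the spin term of the score (default 50)."""

    weight: float = 50.0

    def __post_init__(self) -> None:
        if not self.weight >= 0:
            raise ValueError(f"weight must be non-negative, got {self.weight}")


@dataclass(frozen=True)
class StabilityRecord:
    """One radical's position on the stability map and its score."""

    id: str
    max_fraction: float
    percent_buried: float
    rss: float
    center_element: str
    center_index: int


def radical_stability_score(
    percent_buried: float, max_fraction: float, config: ScoreConfig | None = None
) -> float:
    """``percent_buried + weight × (1 − max_fraction)``.

    ``percent_buried`` is on the 0–100 percent scale; ``max_fraction``
    must lie in (0, 1]. Strictly increasing in buried volume, strictly
    decreasing in max fraction; with ``weight=0`` it degenerates to the
    buried volume alone.
    """
    if config is None:
        config = ScoreConfig()
    if not 0 < max_fraction <= 1:
        raise ValueError(f"max_fraction must be in (0, 1], got {max_fraction}")
    if not 0 < percent_buried <= 100:
        raise ValueError(f"percent_buried must be in (0, 100], got {percent_buried}")
    return percent_buried + config.weight * (1.0 - max_fraction)


def score_structure(
    structure: MolecularStructure,
    spins,
    grid: GridSpec | None = None,
    config: ScoreConfig | None = None,
) -> StabilityRecord:
    """Full descriptor pipeline for one radical.

    Normalizes spins to heavy-atom fractions, assigns the radical center
    (maximum fraction, ties to the lowest index), integrates the buried
    volume around that center, and combines the two into the RSS.
    """
    fr = fractional_spins(structure, spins)
    bv = buried_volume(structure, fr.center_index, grid)
    return StabilityRecord(
        id=structure.id,
        max_fraction=fr.max_fraction,
        percent_buried=bv.percent_buried,
        rss=radical_stability_score(bv.percent_buried, fr.max_fraction, config),
        center_element=fr.center_element,
        center_index=fr.center_index,
    )


def map_coordinates(record: StabilityRecord) -> tuple[float, float]:
    """Stability-map point ``(max_fraction, percent_buried)``.

    x decreasing = more thermodynamic stabilization; y increasing = more
    kinetic protection. Known stable radicals (TEMPO, proxyl, trityl)
    sit top-left; methyl sits lower-right.
    """
    return (record.max_fraction, record.percent_buried)


def quadrant(
    record: StabilityRecord, spin_threshold: float = 0.5, vbur_threshold: float = 40.0
) -> str:
    """Heuristic map quadrant: NW/NE/SW/SE.

    West = delocalized (max_fraction < spin_threshold); North = protected
    (percent_buried >= vbur_threshold). The default thresholds are
    conventions for orientation on the map, not physical cutoffs.
    """
    ns = "N" if record.percent_buried >= vbur_threshold else "S"
    ew = "W" if record.max_fraction < spin_threshold else "E"
    return ns + ew
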