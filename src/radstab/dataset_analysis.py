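"""Dataset-level analytics: composition, enrichment, correlations, robustness.

Operates on deposit-style tables: one CSV row per atom with columns
``molecule_id, atom_index, element, fractional_spin, percent_buried`` and
optional molecule-level ``bde`` / ``rse`` annotations (kcal/mol, consumed
as given, never computed here). Per-molecule center assignments are
recomputed from the per-atom data and cross-checked against any provided
summary columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .buried_volume import GridSpec, buried_volume
from .molio import MolecularStructure, read_sdf

__all__ = [
    "DatasetRecord",
    "load_dataset",
    "element_counts",
    "percentile_rank",
    "stable_enrichment",
    "r_squared",
    "radius_robustness",
]

REQUIRED_COLUMNS = ("molecule_id", "atom_index", "element", "fractional_spin", "percent_buried")


@dataclass
class DatasetRecord:
    """One molecule's per-atom descriptors plus derived summary fields."""

    molecule_id: str
    elements: list[str]
    fractional_spin: np.ndarray
    percent_buried: np.ndarray
    center_index: int
    max_fraction: float
    percent_buried_at_center: float
    center_element: str
    bde: float | None = None
    rse: float | None = None
    is_known_stable: bool = False
    structure: MolecularStructure | None = field(default=None, repr=False)

    @property
    def rss(self) -> float:
        return self.percent_buried_at_center + 50.0 * (1.0 - self.max_fraction)


def load_dataset(
    csv_source: IO[str] | str,
    sdf_source: IO[str] | str | None = None,
    stable_ids: Sequence[str] = (),
) -> list[DatasetRecord]:
    """Load a deposit-style per-atom CSV (optionally joined to an SDF).

    Rows are grouped by ``molecule_id``; within each molecule
    ``atom_index`` must be a permutation of ``0..n-1`` (the SDF atom
    order is the join key). The radical center is recomputed as the
    heavy atom of maximum fractional spin.
    """
    df = pd.read_csv(csv_source) if not isinstance(csv_source, pd.DataFrame) else csv_source
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset CSV is missing required columns: {missing}")
    structures: dict[str, MolecularStructure] = {}
    if sdf_source is not None:
        for s in read_sdf(sdf_source):
            structures[s.id] = s
    stable = set(stable_ids)
    records: list[DatasetRecord] = []
    for mol_id, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("atom_index")
        idx = grp["atom_index"].to_numpy()
        n = len(grp)
        if not np.array_equal(idx, np.arange(n)):
            raise ValueError(
                f"molecule {mol_id!r}: atom_index is not a permutation of 0..{n - 1}"
            )
        elements = [str(e) for e in grp["element"]]
        spin = grp["fractional_spin"].to_numpy(dtype=float)
        vbur = grp["percent_buried"].to_numpy(dtype=float)
        heavy = np.array([e != "H" for e in elements])
        if not heavy.any() or not np.any(spin[heavy] > 0):
            raise ValueError(f"molecule {mol_id!r}: no heavy atom with positive spin")
        masked = np.where(heavy, spin, -np.inf)
        center = int(np.argmax(masked))
        struct = structures.get(str(mol_id))
        if struct is not None:
            if struct.n_atoms != n:
                raise ValueError(
                    f"molecule {mol_id!r}: CSV has {n} atoms but SDF record has "
                    f"{struct.n_atoms}"
                )
            if struct.symbols != elements:
                raise ValueError(f"molecule {mol_id!r}: element mismatch between CSV and SDF")
        rec = DatasetRecord(
            molecule_id=str(mol_id),
            elements=elements,
            fractional_spin=spin,
            percent_buried=vbur,
            center_index=center,
            max_fraction=float(spin[center]),
            percent_buried_at_center=float(vbur[center]),
            center_element=elements[center],
            bde=float(grp["bde"].iloc[0]) if "bde" in grp and pd.notna(grp["bde"].iloc[0]) else None,
            rse=float(grp["rse"].iloc[0]) if "rse" in grp and pd.notna(grp["rse"].iloc[0]) else None,
            is_known_stable=str(mol_id) in stable,
            structure=struct,
        )
        # cross-check any molecule-level summary columns shipped with the CSV
        for col, val in (("max_fraction", rec.max_fraction),
                         ("percent_buried_at_center", rec.percent_buried_at_center)):
            if col in grp.columns:
                given = float(grp[col].iloc[0])
                if abs(given - val) > 1e-6:
                    raise ValueError(
                        f"molecule {mol_id!r}: column {col} = {given} disagrees with "
                        f"recomputed value {val}"
                    )
        records.append(rec)
    return records


def element_counts(records: Sequence[DatasetRecord]) -> dict[str, int]:
    """Number of radicals per center element; values sum to ``len(records)``."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.center_element] = counts.get(r.center_element, 0) + 1
    return counts


def percentile_rank(values: Sequence[float], x: float) -> float:
    """Percentile of ``x`` in ``values``: ``100 × #{v <= x} / N``.

    The weak-inequality convention: an element equal to the maximum ranks
    100. Monotone non-decreasing in ``x``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile_rank requires a nonempty value list")
    return 100.0 * float(np.count_nonzero(values <= x)) / values.size


def stable_enrichment(
    dataset_rss: Sequence[float], stable_rss: Sequence[float]
) -> float:
    """Minimum RSS percentile (within the dataset) over the known-stable set.

    A value ≥ 97 means every known stable radical scores in or above the
    97th percentile of the dataset's RSS distribution. Invariant under
    any strictly increasing transform applied to both inputs.
    """
    stable_rss = np.asarray(stable_rss, dtype=float)
    if stable_rss.size == 0:
        raise ValueError("stable_enrichment requires a nonempty stable set")
    return min(percentile_rank(dataset_rss, x) for x in stable_rss)


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("r_squared requires equal-length inputs of size >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("r_squared is undefined for zero-variance input")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def radius_robustness(
    structures: Sequence[MolecularStructure],
    centers: Sequence[int],
    radii: Sequence[float] = (2.5, 3.0, 3.5, 4.0),
    grid: GridSpec | None = None,
) -> np.ndarray:
    """Pairwise R² between buried-volume vectors at different sphere radii.

    For each radius the buried volume of every structure (at its given
    center) forms one vector; the result is the symmetric matrix of
    squared Pearson correlations between those vectors, with unit
    diagonal. High off-diagonal values mean the steric ranking is robust
    to the sphere-radius choice.
    """
    if len(structures) < 3:
        raise ValueError("radius_robustness requires at least 3 structures")
    if len(centers) != len(structures):
        raise ValueError("one center index per structure is required")
    if grid is None:
        grid = GridSpec()
    from dataclasses import replace

    vectors = []
    for r in radii:
        g = replace(grid, sphere_radius=r)
        vectors.append(
            [buried_volume(s, c, g).percent_buried for s, c in zip(structures, centers)]
        )
    k = len(radii)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = r_squared(vectors[i], vectors[j])
    return mat
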