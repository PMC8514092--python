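"""Heavy-atom fractional spin densities and radical-center assignment.

Raw per-atom signed spin densities (Mulliken-style population analysis)
are converted to fractional spins: the absolute magnitudes of the
heavy-atom spins are summed — spin on hydrogens, which is small and
sign-polarized, is neglected entirely — and each heavy atom is assigned
its share of that total, so heavy-atom fractions sum to one. The radical
center is the heavy atom carrying the maximum fraction; exact ties break
to the lowest atom index. The maximum fraction is the thermodynamic
(delocalization) descriptor: 1 means fully localized (e.g. methyl),
values near 0.2 the most delocalized systems.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import IO

import numpy as np

from .molio import MolecularStructure, _normalize_symbol

__all__ = [
    "FractionalSpins",
    "fractional_spins",
    "radical_center",
    "parse_spin_table",
    "parse_qm_mulliken_block",
    "SpinAnalysisError",
]


class SpinAnalysisError(ValueError):
    """Raised for degenerate or inconsistent spin input."""


@dataclass(frozen=True)
class FractionalSpins:
    """Normalized heavy-atom spin fractions for one structure.

    Attributes
    ----------
    fractions : (n_atoms,) ndarray
        Per-atom fraction in [0, 1]; exactly 0 on every hydrogen; sums to
        1 over heavy atoms.
    center_index : int
        Atom index of the radical center (maximum fraction, ties to the
        lowest index).
    max_fraction : float
        Fraction at the center; the global maximum.
    center_element : str
        Element symbol of the center atom.
    """

    fractions: np.ndarray
    center_index: int
    max_fraction: float
    center_element: str


def fractional_spins(
    structure: MolecularStructure, spins: np.ndarray
) -> FractionalSpins:
    """Normalize signed per-atom spin densities to heavy-atom fractions.

    ``fraction_i = |spin_i| / Σ_heavy |spin_j|`` for heavy atoms, 0 for
    hydrogens. Fractions are invariant under a global sign flip or a
    uniform rescaling of the raw spins, and independent of the hydrogen
    spin values.

    Raises
    ------
    SpinAnalysisError
        If the spin vector length differs from the atom count, any value
        is non-finite, or every heavy-atom spin is zero (no radical
        center is definable).
    """
    spins = np.asarray(spins, dtype=float)
    if spins.shape != (structure.n_atoms,):
        raise SpinAnalysisError(
            f"spin vector has {spins.size} entries for a "
            f"{structure.n_atoms}-atom structure"
        )
    if not np.all(np.isfinite(spins)):
        raise SpinAnalysisError("spin densities must be finite")
    heavy = structure.heavy_mask()
    if not heavy.any():
        raise SpinAnalysisError("structure has no heavy atoms")
    abs_heavy = np.where(heavy, np.abs(spins), 0.0)
    total = abs_heavy.sum()
    if total == 0.0:
        raise SpinAnalysisError(
            "all heavy-atom spin densities are zero: no radical center definable"
        )
    fractions = abs_heavy / total
    center = int(np.argmax(fractions))  # argmax takes the lowest index on ties
    return FractionalSpins(
        fractions=fractions,
        center_index=center,
        max_fraction=float(fractions[center]),
        center_element=structure.symbols[center],
    )


def radical_center(fractions: FractionalSpins) -> int:
    """Atom index of the maximum heavy-atom fraction (ties → lowest index)."""
    return fractions.center_index


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

def parse_spin_table(
    source: IO[str] | str,
    structure: MolecularStructure | None = None,
    one_based: bool = False,
) -> np.ndarray:
    """Read a per-atom spin table into a dense vector in atom order.

    Accepts two-column ``atom_index, spin`` or three-column
    ``atom_index, element, spin`` rows; the delimiter (comma, tab or
    whitespace) is autodetected. Indexing is 0-based unless
    ``one_based=True`` or the table carries an ``# index-base: 1`` header
    line. When an element column is present and a structure is given,
    every element is cross-checked against the structure.
    """
    text = source if isinstance(source, str) else source.read()
    rows: list[tuple[int, str | None, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*index-base\s*:\s*(\d)", line)
            if m:
                one_based = m.group(1) == "1"
            continue
        parts = [p for p in re.split(r"[,\t]|\s+", line) if p]
        if len(parts) == 2:
            idx_s, spin_s, el = parts[0], parts[1], None
        elif len(parts) == 3:
            idx_s, el, spin_s = parts
        else:
            raise SpinAnalysisError(f"line {lineno}: expected 2 or 3 columns, got {line!r}")
        if idx_s.lower() in ("atom_index", "index", "i"):  # header row
            continue
        try:
            idx = int(idx_s)
            spin = float(spin_s)
        except ValueError:
            raise SpinAnalysisError(f"line {lineno}: unparseable row {line!r}") from None
        rows.append((idx, el, spin))
    if not rows:
        raise SpinAnalysisError("spin table contains no data rows")
    offset = 1 if one_based else 0
    indices = [idx - offset for idx, _, _ in rows]
    n = len(rows)
    if sorted(indices) != list(range(n)):
        seen: set[int] = set()
        for idx in indices:
            if idx in seen:
                raise SpinAnalysisError(f"duplicate atom index {idx + offset} in spin table")
            seen.add(idx)
        missing = sorted(set(range(n)) - seen)
        raise SpinAnalysisError(
            f"spin table indices are not contiguous; missing {missing}"
        )
    vector = np.empty(n)
    for (idx, el, spin), i in zip(rows, indices):
        vector[i] = spin
        if el is not None and structure is not None:
            expected = structure.symbols[i]
            if _normalize_symbol(el) != expected:
                raise SpinAnalysisError(
                    f"atom {idx}: table says {el!r} but structure has {expected!r}"
                )
    if structure is not None and n != structure.n_atoms:
        raise SpinAnalysisError(
            f"spin table has {n} rows for a {structure.n_atoms}-atom structure"
        )
    return vector


_MULLIKEN_HEADER = re.compile(
    r"Mulliken (?:charges(?: and spin densities)?|atomic spin densities)",
    re.IGNORECASE,
)


def parse_qm_mulliken_block(source: IO[str] | str, use_last: bool = False) -> np.ndarray:
    """Extract the spin-density column of a Mulliken population block.

    Parses the common quantum-chemistry log layout::

        Mulliken charges and spin densities:
                   1  2
            1  C  -0.3  1.05
            2  H   0.1 -0.02

    i.e. a header, a column-label line, then ``index element charge spin``
    rows. A closed-shell log (charge column only) has no spin column and
    is rejected. If the log contains several blocks, ``use_last=True``
    selects the final one; otherwise multiplicity is an error.
    """
    text = source if isinstance(source, str) else source.read()
    lines = text.splitlines()
    blocks: list[np.ndarray] = []
    i = 0
    while i < len(lines):
        if _MULLIKEN_HEADER.search(lines[i]):
            j = i + 1
            # skip column-label lines (no leading atom index + element)
            row_re = re.compile(r"^\s*(\d+)\s+([A-Z][a-z]?)\s+(\S+)(?:\s+(\S+))?\s*$")
            spins: list[float] = []
            has_spin = True
            while j < len(lines):
                m = row_re.match(lines[j])
                if m:
                    if m.group(4) is None:
                        has_spin = False
                        spins.append(float("nan"))
                    else:
                        spins.append(float(m.group(4)))
                elif spins:
                    break
                j += 1
            if spins:
                if not has_spin:
                    raise SpinAnalysisError(
                        "Mulliken block has no spin column (closed-shell log?)"
                    )
                blocks.append(np.array(spins))
            i = j
        else:
            i += 1
    if not blocks:
        raise SpinAnalysisError("no Mulliken spin-density block found in log")
    if len(blocks) > 1 and not use_last:
        raise SpinAnalysisError(
            f"log contains {len(blocks)} Mulliken blocks; pass use_last=True "
            "to take the final one"
        )
    return blocks[-1]
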