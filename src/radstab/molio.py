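"""Molecular geometry I/O and van der Waals reference data.

Geometries are plain element-symbol + Cartesian-coordinate records in
Ångström. Atom order is significant throughout the package: per-atom spin
and buried-volume tables are keyed by atom index, so readers and writers
preserve file atom order exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np

__all__ = [
    "MolecularStructure",
    "RadiiTable",
    "BONDI",
    "bondi_radius",
    "read_xyz",
    "write_xyz",
    "read_sdf",
    "write_sdf",
    "ParseError",
]


class ParseError(ValueError):
    """Raised when a geometry file cannot be parsed."""


#: Element subset the package supports end-to-end (the Bondi-table span:
#: organic radicals plus the common halogens and phosphorus).
SUPPORTED_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"}
)


def _normalize_symbol(symbol: str, require_supported: bool = False) -> str:
    s = symbol.strip()
    if not s or not s.isalpha() or len(s) > 2:
        raise ParseError(f"invalid element symbol {symbol!r}")
    s = s[0].upper() + s[1:].lower()
    if require_supported and s not in SUPPORTED_ELEMENTS:
        raise ParseError(f"unsupported element {s!r}")
    return s


@dataclass
class MolecularStructure:
    """One radical geometry: element symbols and Cartesian coordinates (Å).

    Parameters
    ----------
    symbols : list of str
        Element symbols in file atom order (case-normalized).
    coords : (n_atoms, 3) ndarray
        Cartesian coordinates in Ångström.
    title : str
        Free-text title (XYZ comment line / SDF title line).
    charge : int
        Net molecular charge; informational metadata only.
    id : str
        Stable identifier; defaults to the title.
    bonds : list of (int, int, int)
        Optional (atom_i, atom_j, order) triples retained from SDF input
        for provenance. No computation in this package uses connectivity.
    """

    symbols: list[str]
    coords: np.ndarray
    title: str = ""
    charge: int = 0
    id: str = ""
    bonds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.symbols = [_normalize_symbol(s) for s in self.symbols]
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) == 0:
            raise ValueError("structure must contain at least one atom")
        if self.coords.shape[0] != len(self.symbols):
            raise ValueError(
                f"{len(self.symbols)} symbols but {self.coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.id:
            self.id = self.title

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask selecting non-hydrogen atoms."""
        return np.array([s != "H" for s in self.symbols])

    def __len__(self) -> int:
        return self.n_atoms


@dataclass(frozen=True)
class RadiiTable:
    """Mapping element symbol → van der Waals radius (Å).

    Lookup of an element absent from the table is an explicit ``KeyError``;
    there is no silent default radius.
    """

    radii: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if not r > 0:
                raise ValueError(f"radius for {el} must be positive, got {r}")

    def __getitem__(self, element: str) -> float:
        el = _normalize_symbol(element)
        try:
            return self.radii[el]
        except KeyError:
            raise KeyError(
                f"element {el!r} has no radius in table {self.name!r}"
            ) from None

    def __contains__(self, element: str) -> bool:
        try:
            return _normalize_symbol(element) in self.radii
        except ParseError:
            return False


#: Unscaled van der Waals radii of Bondi (J. Phys. Chem. 1964, 68, 441),
#: the standard set for buried-volume style steric descriptors.
BONDI = RadiiTable(
    radii={
        "H": 1.20,
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "F": 1.47,
        "P": 1.80,
        "S": 1.80,
        "Cl": 1.75,
        "Br": 1.85,
        "I": 1.98,
    },
    name="bondi",
)


def bondi_radius(element: str, table: RadiiTable = BONDI) -> float:
    """Return the tabulated van der Waals radius (Å) for ``element``."""
    return table[element]


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(source: IO[str] | str) -> MolecularStructure:
    """Parse a standard XYZ file (count line, comment, one atom per line)."""
    text = source if isinstance(source, str) else source.read()
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ input")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"line 1: expected atom count, got {lines[0]!r}") from None
    if n < 1:
        raise ParseError(f"line 1: atom count must be >= 1, got {n}")
    title = lines[1].strip() if len(lines) > 1 else ""
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) < n:
        raise ParseError(
            f"header declares {n} atoms but only {len(atom_lines)} atom lines follow"
        )
    symbols: list[str] = []
    coords: list[list[float]] = []
    for i, ln in enumerate(atom_lines[:n]):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"atom line {i + 3}: expected 'El x y z', got {ln!r}")
        symbols.append(_normalize_symbol(parts[0], require_supported=True))
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise ParseError(f"atom line {i + 3}: unparseable coordinate in {ln!r}") from None
    return MolecularStructure(symbols=symbols, coords=np.array(coords), title=title)


def write_xyz(structure: MolecularStructure) -> str:
    """Serialize a structure to XYZ text."""
    lines = [str(structure.n_atoms), structure.title]
    for sym, (x, y, z) in zip(structure.symbols, structure.coords):
        lines.append(f"{sym:<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SDF (V2000)
# ---------------------------------------------------------------------------

def read_sdf(source: IO[str] | str) -> list[MolecularStructure]:
    """Parse a (possibly multi-record) SDF V2000 file.

    Atom order equals the SDF atom-block order; that order is the key for
    per-atom spin and buried-volume tables. Bond blocks are retained for
    provenance only.
    """
    text = source if isinstance(source, str) else source.read()
    records = text.split("$$$$")
    structures: list[MolecularStructure] = []
    for rec_idx, rec in enumerate(records):
        if not rec.strip():
            continue
        lines = rec.lstrip("\n").splitlines()
        if len(lines) < 4:
            raise ParseError(f"record {rec_idx}: truncated molfile header")
        title = lines[0].strip()
        counts = lines[3]
        try:
            n_atoms = int(counts[0:3])
            n_bonds = int(counts[3:6])
        except ValueError:
            raise ParseError(
                f"record {rec_idx}: unparseable counts line {counts!r}"
            ) from None
        if n_atoms < 1:
            raise ParseError(f"record {rec_idx}: atom count must be >= 1")
        if not any(ln.startswith("M  END") for ln in lines):
            raise ParseError(f"record {rec_idx}: missing 'M  END'")
        atom_lines = lines[4 : 4 + n_atoms]
        if len(atom_lines) < n_atoms:
            raise ParseError(f"record {rec_idx}: atom block shorter than counts line")
        symbols: list[str] = []
        coords: list[list[float]] = []
        for i, ln in enumerate(atom_lines):
            try:
                x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
                sym = _normalize_symbol(ln[31:34], require_supported=True)
            except (ValueError, ParseError):
                raise ParseError(
                    f"record {rec_idx}: unparseable atom line {i + 1}: {ln!r}"
                ) from None
            symbols.append(sym)
            coords.append([x, y, z])
        bonds: list[tuple[int, int, int]] = []
        for ln in lines[4 + n_atoms : 4 + n_atoms + n_bonds]:
            try:
                bonds.append((int(ln[0:3]) - 1, int(ln[3:6]) - 1, int(ln[6:9])))
            except ValueError:
                raise ParseError(f"record {rec_idx}: unparseable bond line {ln!r}") from None
        charge = 0
        for ln in lines:
            if ln.startswith("M  CHG"):
                fields = ln.split()
                charge = sum(int(v) for v in fields[4::2])
        structures.append(
            MolecularStructure(
                symbols=symbols,
                coords=np.array(coords),
                title=title,
                charge=charge,
                bonds=bonds,
            )
        )
    if not structures:
        raise ParseError("no records found in SDF input")
    return structures


def write_sdf(structures: Iterable[MolecularStructure]) -> str:
    """Serialize structures to multi-record SDF V2000 text."""
    out: list[str] = []
    for s in structures:
        lines = [s.title, "  radstab", ""]
        lines.append(
            f"{s.n_atoms:3d}{len(s.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
        )
        for sym, (x, y, z) in zip(s.symbols, s.coords):
            lines.append(
                f"{x:10.4f}{y:10.4f}{z:10.4f} {sym:<3s} 0  0  0  0  0  0  0  0  0  0  0  0"
            )
        for i, j, order in s.bonds:
            lines.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0")
        if s.charge:
            lines.append(f"M  CHG  1 {1:3d} {s.charge:3d}")
        lines.append("M  END")
        lines.append("$$$$")
        out.append("\n".join(lines))
    return "\n".join(out) + "\n"
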