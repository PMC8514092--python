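"""Idealized geometries, synthetic spin vectors, and synthetic datasets.

Everything here is built from closed-form internal coordinates (standard
bond lengths and angles) or frozen once from a force-field optimization,
so the rest of the package is testable without any quantum-chemistry
input. Spin vectors are hand-designed to be plausible — correct
polarization signs and rough magnitudes, near-degeneracy on the
nitroxide — not DFT-accurate; nothing downstream depends on their
absolute values except through the normalization rules.

The packaged TEMPO conformer (``data/tempo_synthetic_mmff.sdf``) is a
synthetic stand-in: an MMFF94-optimized geometry generated once and
frozen, standing in for a DFT-optimized structure.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .dataset_analysis import DatasetRecord
from .molio import MolecularStructure, read_sdf

__all__ = [
    "ideal_methyl",
    "ideal_ethyl",
    "ideal_allyl",
    "ideal_pentadienyl",
    "ideal_tert_butyl",
    "ideal_crowded_cage",
    "ideal_delocalized_cage",
    "tempo",
    "fixture_library",
    "synthetic_dataset",
    "dataset_to_frame",
]

CH = 1.09  # sp3 C–H bond length, Å
CC = 1.54  # C–C single bond, Å
CC_CONJ = 1.40  # conjugated C–C, Å
TETRA = np.arccos(-1.0 / 3.0)  # tetrahedral angle


def _tetra_dirs(u: np.ndarray, phi0: float = 0.0) -> list[np.ndarray]:
    """Three unit vectors at the tetrahedral angle to the existing bond -u.

    ``u`` points along an existing bond from the atom; the returned
    directions complete an ideal sp3 frame, azimuth offset ``phi0``.
    """
    u = u / np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    out = []
    for k in range(3):
        phi = phi0 + 2.0 * np.pi * k / 3.0
        v = -u / 3.0 + (np.sqrt(8.0) / 3.0) * (np.cos(phi) * e1 + np.sin(phi) * e2)
        out.append(v / np.linalg.norm(v))
    return out


def ideal_methyl(ch_bond: float = 1.08) -> tuple[MolecularStructure, np.ndarray]:
    """Planar D3h methyl radical with synthetic Mulliken-style spins.

    C at the origin, three H at 120° spacing in the xy-plane. Spins are
    C: +1.05 and H: −0.02 each, mimicking the positive carbon density
    and small negative hydrogen polarization of an open-shell
    population analysis; the heavy-atom fractional spin is therefore
    exactly 1 on carbon.
    """
    if not 0.8 < ch_bond < 1.3:
        raise ValueError(f"ch_bond must be in (0.8, 1.3) Å, got {ch_bond}")
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        a = 2.0 * np.pi * k / 3.0
        coords.append([ch_bond * np.cos(a), ch_bond * np.sin(a), 0.0])
    struct = MolecularStructure(
        symbols=["C", "H", "H", "H"], coords=np.array(coords), title="methyl", id="methyl"
    )
    spins = np.array([1.05, -0.02, -0.02, -0.02])
    return struct, spins


def ideal_ethyl() -> tuple[MolecularStructure, np.ndarray]:
    """Staggered ethyl radical: planar CH2 center, sp3 methyl."""
    c0 = np.array([0.0, 0.0, 0.0])
    c1 = np.array([1.49, 0.0, 0.0])
    symbols = ["C", "C"]
    coords = [c0, c1]
    for sign in (1.0, -1.0):  # planar radical center
        a = np.deg2rad(120.0)
        coords.append(c0 + 1.08 * np.array([np.cos(a), sign * np.sin(a), 0.0]))
        symbols.append("H")
    for d in _tetra_dirs(c0 - c1, phi0=np.pi / 2):
        coords.append(c1 + CH * d)
        symbols.append("H")
    struct = MolecularStructure(symbols=symbols, coords=np.array(coords), title="ethyl", id="ethyl")
    spins = np.array([1.10, -0.08, -0.02, -0.02, 0.01, 0.01, 0.01])
    return struct, spins


def _zigzag_chain(n: int, bond: float) -> list[np.ndarray]:
    """Planar zig-zag carbon chain with 120° internal angles."""
    pts = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    up = True
    for _ in range(n - 1):
        a = np.deg2rad(30.0 if up else -30.0)
        step = bond * np.array([np.cos(a), np.sin(a), 0.0])
        pts.append(pts[-1] + step)
        up = not up
    return pts


def _chain_hydrogens(pts: list[np.ndarray], ch: float = 1.085) -> tuple[list[str], list[np.ndarray]]:
    """In-plane H completion of a planar conjugated chain (2 terminal, 1 inner)."""
    symbols: list[str] = []
    coords: list[np.ndarray] = []
    n = len(pts)
    for i, p in enumerate(pts):
        neighbors = [pts[j] for j in (i - 1, i + 1) if 0 <= j < n]
        if len(neighbors) == 1:
            u = (p - neighbors[0]) / np.linalg.norm(p - neighbors[0])
            perp = np.cross(np.array([0.0, 0.0, 1.0]), u)
            for s in (1.0, -1.0):
                d = np.cos(np.deg2rad(60.0)) * u + s * np.sin(np.deg2rad(60.0)) * perp
                symbols.append("H")
                coords.append(p + ch * d)
        else:
            bisector = -((neighbors[0] - p) + (neighbors[1] - p))
            bisector /= np.linalg.norm(bisector)
            symbols.append("H")
            coords.append(p + ch * bisector)
    return symbols, coords


def ideal_allyl() -> tuple[MolecularStructure, np.ndarray]:
    """Planar allyl radical; spin split over the two terminal carbons."""
    pts = _zigzag_chain(3, CC_CONJ)
    hs, hc = _chain_hydrogens(pts)
    struct = MolecularStructure(
        symbols=["C"] * 3 + hs, coords=np.array(pts + hc), title="allyl", id="allyl"
    )
    spins = np.concatenate([[0.55, -0.10, 0.55], np.full(len(hs), -0.01)])
    return struct, spins


def ideal_pentadienyl() -> tuple[MolecularStructure, np.ndarray]:
    """Planar pentadienyl radical: strongly delocalized, sterically open."""
    pts = _zigzag_chain(5, CC_CONJ)
    hs, hc = _chain_hydrogens(pts)
    struct = MolecularStructure(
        symbols=["C"] * 5 + hs, coords=np.array(pts + hc), title="pentadienyl", id="pentadienyl"
    )
    spins = np.concatenate([[0.40, -0.08, 0.34, -0.08, 0.40], np.full(len(hs), -0.01)])
    return struct, spins


def ideal_tert_butyl() -> tuple[MolecularStructure, np.ndarray]:
    """tert-Butyl radical: planar sp2 center bearing three sp3 methyls."""
    c0 = np.zeros(3)
    symbols = ["C"]
    coords = [c0]
    spins = [1.08]
    for k in range(3):
        a = 2.0 * np.pi * k / 3.0
        cm = c0 + CC * np.array([np.cos(a), np.sin(a), 0.0])
        symbols.append("C")
        coords.append(cm)
        spins.append(-0.04)
        for d in _tetra_dirs(c0 - cm, phi0=np.pi / 2):
            symbols.append("H")
            coords.append(cm + CH * d)
            spins.append(0.01)
    struct = MolecularStructure(
        symbols=symbols, coords=np.array(coords), title="tert-butyl", id="tert-butyl"
    )
    return struct, np.array(spins)


def ideal_crowded_cage() -> tuple[MolecularStructure, np.ndarray]:
    """Tri-tert-butylmethyl: localized spin buried in a quaternary-carbon cage.

    A planar radical center bonded to three C(CH3)3 groups — the
    localized-but-protected archetype (high max fraction, high buried
    volume).
    """
    c0 = np.zeros(3)
    symbols = ["C"]
    coords = [c0]
    spins = [1.10]
    for k in range(3):
        a = 2.0 * np.pi * k / 3.0
        cq = c0 + 1.58 * np.array([np.cos(a), np.sin(a), 0.0])
        symbols.append("C")
        coords.append(cq)
        spins.append(-0.03)
        for d in _tetra_dirs(c0 - cq, phi0=np.pi / 2):
            cm = cq + CC * d
            symbols.append("C")
            coords.append(cm)
            spins.append(0.01)
            for dh in _tetra_dirs(cq - cm):
                symbols.append("H")
                coords.append(cm + CH * dh)
                spins.append(0.0)
    struct = MolecularStructure(
        symbols=symbols, coords=np.array(coords), title="crowded-cage", id="crowded-cage"
    )
    return struct, np.array(spins)


def ideal_delocalized_cage() -> tuple[MolecularStructure, np.ndarray]:
    """Delocalized-and-protected archetype (trityl-like corner of the map).

    The tri-tert-butylmethyl cage geometry carrying a spread synthetic
    spin pattern (0.40 on the center, 0.20 on each flanking quaternary
    carbon), so the maximum fraction drops below 0.5 while the center
    stays heavily buried.
    """
    struct, _ = ideal_crowded_cage()
    spins = np.zeros(struct.n_atoms)
    heavy = [i for i, s in enumerate(struct.symbols) if s == "C"]
    spins[heavy[0]] = 0.40
    for q in (1, 5, 9):  # the three quaternary carbons
        spins[heavy[q]] = 0.20
    struct.id = struct.title = "delocalized-cage"
    return struct, spins


def tempo() -> tuple[MolecularStructure, np.ndarray]:
    """Packaged TEMPO conformer with a nitroxide-localized synthetic spin split.

    The geometry is the frozen MMFF94 conformer shipped with the package
    (a synthetic force-field stand-in for a DFT geometry). Spins place
    0.45 on the nitroxide N and 0.55 on the O, with zero elsewhere —
    the characteristic near-even N/O split of nitroxide radicals.
    """
    text = resources.files("radstab.data").joinpath("tempo_synthetic_mmff.sdf").read_text()
    struct = read_sdf(text)[0]
    struct.id = struct.title = "tempo"
    spins = np.zeros(struct.n_atoms)
    for i, sym in enumerate(struct.symbols):
        if sym == "N":
            spins[i] = 0.45
        elif sym == "O":
            spins[i] = 0.55
    return struct, spins


def fixture_library() -> list[tuple[str, MolecularStructure, np.ndarray]]:
    """Named (structure, spins) fixtures spanning the stability map.

    Covers all four quadrants under the default thresholds: methyl and
    ethyl (localized, open — SE), allyl and pentadienyl (delocalized,
    open — SW), tert-butyl and the tri-tert-butylmethyl cage (localized,
    protected — NE), and TEMPO (delocalized nitroxide, protected — NW).
    """
    out = []
    for builder in (
        ideal_methyl,
        ideal_ethyl,
        ideal_allyl,
        ideal_pentadienyl,
        ideal_tert_butyl,
        ideal_crowded_cage,
        ideal_delocalized_cage,
        tempo,
    ):
        struct, spins = builder()
        out.append((struct.id, struct, spins))
    return out


# ---------------------------------------------------------------------------
# Synthetic dataset
# ---------------------------------------------------------------------------

#: Center-element draw probabilities for the synthetic dataset, matching
#: the C-majority composition typical of organic radical libraries.
ELEMENT_PROBS = {"C": 0.8182, "N": 0.1085, "O": 0.0571, "S": 0.0162}

#: Fraction of synthetic molecules placed in the designated-stable tail.
STABLE_FRACTION = 0.02


def synthetic_dataset(
    n: int, seed: int
) -> tuple[list[DatasetRecord], list[str]]:
    """Generate a deposit-style synthetic dataset plus its stable-id list.

    The bulk of the population sits at high maximum fractional spin and
    low buried volume (most organic radicals are localized and
    unprotected: max_fraction ~ Beta(6, 2) clipped to [0.15, 1], buried
    volume ~ N(26, 7) clipped to [13, 55]). A small designated-stable
    tail (2% of n, at least 3 molecules) sits at low spin and high
    volume (max_fraction ~ U(0.15, 0.35), buried volume ~ U(55, 68)).
    Center elements are drawn C-majority. Deterministic under ``seed``.

    This emulates the *shape* of a real radical library — the dense
    lower-right corner and the sparse stable frontier — not its
    chemistry: per-atom spin patterns and volumes are random fills
    consistent with the molecule-level draws.
    """
    if n < 10:
        raise ValueError(f"synthetic_dataset requires n >= 10, got {n}")
    rng = np.random.default_rng(seed)
    n_stable = max(3, int(round(STABLE_FRACTION * n)))
    elements = list(ELEMENT_PROBS)
    probs = np.array(list(ELEMENT_PROBS.values()))
    probs = probs / probs.sum()
    records: list[DatasetRecord] = []
    stable_ids: list[str] = []
    for i in range(n):
        is_stable = i < n_stable
        if is_stable:
            m = rng.uniform(0.15, 0.35)
            v = rng.uniform(55.0, 68.0)
        else:
            m = float(np.clip(rng.beta(6.0, 2.0), 0.15, 1.0))
            v = float(np.clip(rng.normal(26.0, 7.0), 13.0, 55.0))
        center_el = str(rng.choice(elements, p=probs))
        # enough heavy atoms that the non-center fill can stay below m
        n_heavy_min = max(3, int(np.ceil(1.0 / m)) + 1)
        n_heavy = int(rng.integers(n_heavy_min, n_heavy_min + 8))
        n_h = int(rng.integers(0, 2 * n_heavy))
        # per-atom fractions: the center takes m, the rest share 1 - m
        base = (1.0 - m) / (n_heavy - 1)
        others = base * rng.uniform(0.7, 1.3, n_heavy - 1)
        others *= (1.0 - m) / others.sum()
        if others.max() >= m:  # jitter pushed past the center; use the even fill
            others = np.full(n_heavy - 1, base)
        fractions = np.concatenate([[m], others, np.zeros(n_h)])
        heavy_els = [center_el] + [
            str(rng.choice(elements, p=probs)) for _ in range(n_heavy - 1)
        ]
        els = heavy_els + ["H"] * n_h
        vbur = np.concatenate(
            [[v], rng.uniform(10.0, 60.0, n_heavy - 1), rng.uniform(5.0, 30.0, n_h)]
        )
        mol_id = f"synthetic-{i:06d}"
        records.append(
            DatasetRecord(
                molecule_id=mol_id,
                elements=els,
                fractional_spin=fractions,
                percent_buried=vbur,
                center_index=0,
                max_fraction=m,
                percent_buried_at_center=v,
                center_element=center_el,
                is_known_stable=is_stable,
            )
        )
        if is_stable:
            stable_ids.append(mol_id)
    return records, stable_ids


def dataset_to_frame(records: list[DatasetRecord]):
    """Flatten records to the deposit-style per-atom table (one row per atom)."""
    import pandas as pd

    rows = []
    for r in records:
        for idx, (el, fs, vb) in enumerate(
            zip(r.elements, r.fractional_spin, r.percent_buried)
        ):
            rows.append(
                {
                    "molecule_id": r.molecule_id,
                    "atom_index": idx,
                    "element": el,
                    "fractional_spin": fs,
                    "percent_buried": vb,
                }
            )
    return pd.DataFrame(rows)
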