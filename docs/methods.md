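# Methods

## Model

`radstab` treats radical stability as a two-axis property. The
thermodynamic axis is electron delocalization, measured from per-atom
signed spin densities supplied by the user (any Mulliken-style
population analysis). The kinetic axis is steric shielding of the
radical center, measured purely from the 3D geometry. The two are
combined linearly into the Radical Stability Score (RSS). The score is
ordinal: it ranks candidates, it does not predict half-lives or rate
constants.

### Fractional spins

Raw spins are converted to heavy-atom fractions

    fraction_i = |spin_i| / Σ_heavy |spin_j|,   fraction_H ≡ 0.

Hydrogen spins are excluded from both the sum and the assignment,
whatever their magnitude — the simplest convention, and the one that
makes a methyl radical score exactly 1. Absolute values are used, so
spin-polarized negative densities count toward delocalization.
Consequences tested as invariants: fractions are unchanged by a global
sign flip, by uniform rescaling of the spin vector, and by arbitrary
perturbation of hydrogen spins; permuting atoms permutes fractions
identically. An all-zero heavy-atom spin vector is a hard error (no
radical center is definable), never a silent default.

The radical center is the heavy atom of maximum fraction; an exact tie
breaks to the lowest atom index (deterministic; ties are a
measure-zero event in real data). Which population analysis or level of
theory produced the spins is not validated — callers own that
consistency.

### Percent buried volume

%V_bur is the occupied percent of a probe sphere of radius `R` centered
on a chosen atom. Occupancy is integrated on an axis-aligned Cartesian
grid anchored at the center atom: a voxel belongs to the sphere if its
center lies within `R` of the anchor, and is occupied if its center
lies within the van der Waals radius of any included atom. No partial
voxel weighting is used; no re-orientation of the molecule is
performed. Atoms whose van der Waals sphere cannot intersect the probe
sphere are skipped (a pure optimization, bit-identical result).

Parameters, defaults, and rationale:

| parameter | default | meaning |
|---|---|---|
| `sphere_radius` | 3.5 Å | probe sphere; rankings at 2.5–4.0 Å are strongly correlated, so the conventional 3.5 Å is kept |
| `spacing` | 0.05 Å | voxel edge; must be ≤ `sphere_radius`/10 |
| `radii` | Bondi | unscaled van der Waals radii (Bondi 1964) |
| `include_center_atom` | true | the center atom's own sphere occupies voxels |
| `include_hydrogens` | true | hydrogens occupy voxels |

Two conventions deserve emphasis because the organometallic buried
volume literature differs. First, the center atom's own sphere counts:
"all atoms" occupy voxels. With the center included an isolated carbon
gives the analytic floor 100·(1.70/3.5)³ ≈ 11.5% and methyl lands at
14.6%, consistent with the expected ≈13–15% floor for the smallest
radicals; excluding the center (the ligand-style convention) is exposed
as a flag for sensitivity studies only. Second, hydrogens count, again
with an exclusion toggle for diagnostics.

Numerical accuracy at the defaults, all enforced by tests: the
single-sphere grid value agrees with the closed form to ≤ 0.2
percentage points, and the error decreases strictly through spacings
0.2 → 0.1 → 0.05 Å (measured 0.245 / 0.029 / 0.025 points); rigid
rotation + translation of the molecule changes the result by well under
0.15 points (grid-alignment jitter); multi-sphere results agree with an
independent Monte-Carlo union-volume estimate (10⁶ points) within the
larger of 0.2 points and 3σ. Adding an atom can never decrease the
percent. Results are reported on the 0–100 percent scale.

### Radical Stability Score

    RSS = %V_bur + w · (1 − max. spin),   w = 50 by default

with %V_bur on the percent scale. The weight 50 makes the spin term
(0–50) span comparable to observed buried volumes (≈13–65%), so the
two contributions carry roughly equal weight; `w` is configurable but
fixed at 50 everywhere in tests and CLI defaults, and `w = 0`
degenerates the score to the buried volume exactly. RSS is strictly
increasing in %V_bur and strictly decreasing in max spin. Stability-map
coordinates are the identity projection (max spin, %V_bur); the
NW/NE/SW/SE quadrant labels use heuristic, user-adjustable thresholds
(spin 0.5, %V_bur 40) — orientation aids, not physical cutoffs.

### Pareto selection

A record is dominated if another record has buried volume ≥ and max
spin ≤ with at least one strict inequality. The frontier keeps all
exact duplicates (no strict inequality between them). The
implementation is a sorted sweep (sort by buried volume descending,
track the running minimum of max spin, handle equal-volume groups as
blocks); tests require exact agreement, ties included, with the O(n²)
dominance definition on seeded random sets up to n = 2000, and
invariance under strictly monotone transforms of either axis.
Stratification is by center element; elements outside C/N/O/S form
their own strata rather than being dropped, so a globally dominated
stratum still has its own frontier.

### Dataset analytics

Deposit-style tables (one CSV row per atom, keyed by `molecule_id` and
0-based `atom_index` matching the SDF atom order) are regrouped per
molecule, and the center assignment is recomputed from the per-atom
data; shipped summary columns are cross-checked, and a non-contiguous
atom index set is an error naming the molecule. Percentiles use the
weak-inequality convention, 100·#{v ≤ x}/N, so a stable radical equal
to the dataset maximum ranks 100 — consistent with reading "in or
above" a percentile. Enrichment is the minimum percentile of the
known-stable set and is invariant under order-preserving transforms of
both inputs. R² is the squared Pearson correlation (Spearman is
available but unused in any reference check). BDE/RSE columns
(kcal/mol) are carried as annotations, never computed.

## Synthetic data

The fixture library is built from closed-form internal coordinates
(standard bond lengths/angles): planar methyl, staggered ethyl, planar
allyl and pentadienyl chains, tert-butyl, a tri-tert-butylmethyl cage,
the same cage with a spread spin pattern, and a frozen MMFF94 TEMPO
conformer shipped as text SDF (a synthetic force-field stand-in for a
DFT geometry; its nitroxide spin split N 0.45 / O 0.55 is hand-set).
Spin vectors are plausible, not DFT-accurate: correct polarization
signs and rough magnitudes only. The library deliberately spans all
four quadrants of the stability map.

The synthetic dataset generator emulates the *shape* of a large radical
library: a dense bulk at high spin / low volume (max fraction ~
Beta(6,2) clipped to [0.15,1]; %V_bur ~ N(26,7) clipped to [13,55]) and
a sparse designated-stable tail (2% of n, ≥3 molecules; max fraction ~
U(0.15,0.35); %V_bur ~ U(55,68)), with C-majority center elements
(P(C,N,O,S) = 0.818, 0.109, 0.057, 0.016). It does not emulate real
chemistry: per-atom spin patterns and volumes are random fills
consistent with the molecule-level draws, there is no geometry behind
the rows, and descriptor correlations with bond strengths do not exist
in it. Passing tests on this stand-in therefore demonstrate that the
*analytics* (grouping, percentiles, enrichment, counts) are correct,
not that any particular enrichment level holds for real compound
libraries. Everything is deterministic under the seed.

## Problem sizes and numerical choices

The default grid at 3.5 Å / 0.05 Å integrates ≈1.44 million in-sphere
voxels per center — about 0.3 s per typical fixture on one core — and
the test suite uses coarser spacings (0.1–0.2 Å) wherever only ordering
or consistency, not absolute accuracy, is asserted. Property tests use
fixed seeds throughout. Pareto checks go to n = 2000 with quantized
coordinates to force tie handling.

## Known limitations

- Descriptors depend on a single conformer; no ensemble averaging.
- Mulliken spins are basis-set-sensitive in general; the package
  accepts any per-atom signed densities and leaves level-of-theory
  consistency to the caller.
- Voxel-center occupancy (no sub-voxel weighting) and the axis-aligned
  anchored grid trade exactness for speed; the bounds above quantify
  the residual error at the defaults.
- SDF V2000 fixes coordinates at 4 decimal places, so SDF round-trips
  are exact to 1e-4 Å (XYZ round-trips to 1e-6 Å).
- The radius-robustness matrix on the 8-fixture library shows adjacent
  sphere radii correlating at R² > 0.9, but the extreme 2.5↔4.0 Å pair
  drops to ≈0.89 because the cage archetype saturates the smallest
  sphere; large chemically sampled libraries correlate more tightly
  across the full span.
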