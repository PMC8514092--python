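# radstab

Quantitative stability scoring for organic radicals.

Long-lived ("stable") organic radicals — the TEMPO / proxyl / trityl
family — are rare because persistence needs two independent things at
once: **thermodynamic stabilization** of the unpaired electron
(delocalization over π-systems or lone pairs) and **kinetic protection**
of the radical center (steric shielding against dimerization and
H-abstraction). `radstab` computes one descriptor for each and combines
them into a single ranking metric, for chemists screening candidate
radicals for redox batteries, organic electronics, or spin labels.

## The descriptors and the score

Given a 3D geometry and per-atom signed spin densities (Mulliken-style,
from any quantum-chemistry code):

- **Maximum fractional spin** — the absolute heavy-atom spin densities
  are summed (hydrogen spin is neglected) and normalized to sum to one;
  the *radical center* is the heavy atom carrying the largest fraction.
  A methyl radical scores exactly 1 (fully localized); strongly
  delocalized systems approach 0.2.
- **Percent buried volume (%V_bur)** — the percent of a sphere of
  radius 3.5 Å centered on the radical center that is occupied by the
  van der Waals spheres (unscaled Bondi radii) of *all* atoms, evaluated
  by voxel integration on a Cartesian grid with 0.05 Å spacing. Small
  radicals like •CH₃ sit near 13–15%; heavily shielded nitroxides reach
  around 65%.

These combine into the **Radical Stability Score**:

    RSS = %V_bur + 50 × (1 − max. spin)

where the factor 50 gives the spin term (0–50) roughly the same span as
observed buried volumes. Higher RSS = a stronger joint claim to
stability. The package also extracts **Pareto-optimal** candidate sets
(maximize %V_bur, minimize max spin), stratified by the element of the
radical center, and ships dataset analytics (composition counts,
percentile enrichment of known-stable radicals, descriptor
correlations, sphere-radius robustness scans).

## Worked example

Score the built-in idealized methyl radical (planar CH₃, C–H 1.08 Å,
synthetic spins C +1.05 / H −0.02):

```sh
radstab fixtures emit --name methyl --out methyl.xyz
radstab fixtures emit --name methyl --format spins --out methyl.spins
radstab score methyl.xyz --spins methyl.spins --format json
```

```json
{
  "records": [
    {
      "id": "methyl",
      "max_fraction": 1.0,
      "percent_buried": 14.60632859227248,
      "rss": 14.60632859227248,
      "center_element": "C",
      "center_index": 0
    }
  ]
}
```

The spin is fully localized on carbon (`max_fraction` = 1.0), so the
spin term contributes nothing and the RSS equals the buried volume,
14.6% — an archetypally unstable radical (lower-right corner of the
stability map). Compare the packaged TEMPO conformer, where the
nitroxide oxygen carries the maximum fraction:

```sh
radstab fixtures emit --name tempo --format sdf --out tempo.sdf
radstab fixtures emit --name tempo --format spins --out tempo.spins
radstab burvol tempo.sdf --center auto --spins tempo.spins
```

```text
id,center_index,center_element,percent_buried,occupied_voxels,total_voxels
tempo,10,O,46.923067284452515,674063,1436528
```

and 67.5% around the nitroxide nitrogen (`--center 9`) — the shielded,
delocalized corner of the map where experimentally stable radicals
live.

Other commands: `radstab spin` (normalize a spin table), `radstab
pareto records.csv --by-element` (flag non-dominated candidates),
`radstab map` (stability-map coordinates and quadrants), `radstab
dataset counts|enrich|corr|radii` (deposit-style analytics), `radstab
fixtures dataset` (synthetic benchmark dataset). The same operations
are importable from `radstab` as plain functions.

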