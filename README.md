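# oraikit

Quantitative analysis of hydration gating in hexameric ion channels —
built around the Orai1 CRAC channel, whose opening is controlled not by a
steric plug but by the wetting and dewetting of hydrophobic sections of the
pore and of the peripheral TM3/TM4 helix interface.

`oraikit` is for computational biophysicists and channel physiologists who
have (a) trajectory frames of a channel (multi-MODEL PDB or XYZ), (b)
protein sequences, and/or (c) confocal microscopy rasters, and want the
standard quantitative read-outs of a hydration-gating study:

* **Pore geometry** — a maximal-sphere cavity profile: at each axial slice
  `z_k`, the pore radius is `max_c min_i (‖(c, z_k) − x_i‖ − r_vdW,i)`,
  with the in-plane probe centre `c` either pinned to the pore axis or
  refined by a deterministic optimizer.
* **Hydration** — axial histograms of water oxygens inside cylinders around
  the pore axis (10 Å for the conducting pore, 30 Å for the peripheral
  "back pore"), and water counts in spherical shells around a chosen side
  chain (6 Å around the Cα of residue 181), with replica mean ± SD of the
  mean.
* **Conformation** — membrane-plane side-chain rotation angle relative to
  the pore direction, in-plane distance of charged moieties (ammonium,
  carboxylate, guanidinium) from the pore centre, Cα triangle areas,
  torsions, and Kabsch-fitted per-helix RMSD.
* **Hydropathy** — sliding-window hydrophobicity profiles (Roseman scale by
  default, windows 9–25).
* **Microscopy** — pixel-wise 3-cube sensitized-emission FRET efficiency

      E_app = (I_FRET − a·I_YFP − b·I_CFP) / (I_FRET − a·I_YFP + (G − b)·I_CFP)

  with bleed-through calibration (a, b), microscope constant G and
  CFP:YFP ratio gating, plus NFAT nucleus/cytosol translocation scoring
  (inactive < 0.85 ≤ homogeneous ≤ 1.15 < active).
* **Synthetic ground truth** — generators for pseudo-hexameric channels
  with planted side-chain orientations and Poisson-placed waters, and for
  FRET/NFAT image sets with planted efficiencies and ratios, so every
  analysis stage is testable without MD trajectories or microscope time.

See `docs/methods.md` for definitions, conventions and limitations.

## Worked example

Generate a three-replica synthetic channel with bulk-like pore water,
~18 shell waters per channel and side chains planted at 60° from the pore
direction, then run the main analyses:

```python
import numpy as np
from oraikit import (
    ChannelSpec, build_channel, profile_over_trajectory,
    axial_water_histogram, shell_count_distribution,
    series_over_trajectory, rotation_angle,
)

spec = ChannelSpec(pore_water_density=0.02, shell_water_density=0.003316,
                   orientation_mu_deg=60, orientation_kappa=8,
                   n_frames=20, n_replicas=3, seed=11)
trajs, truth = build_channel(spec)

prof = profile_over_trajectory(trajs, z_range=(-3, 3), dz=1.0)
for z, r, sd in zip(prof.z, prof.mean, prof.sd_of_mean):
    print(f"z={z:+.0f} A  radius={r:.2f} +- {sd:.3f} A")

hist = axial_water_histogram(trajs, cylinder_radius=10.0, dz=1.0, z_range=(-3, 3))
print("waters/bin:", np.round(hist.mean, 2))

dist = shell_count_distribution(trajs, residue=181, cutoff=6.0)
print(f"waters per channel: {dist.channel_mean:.1f}")

ang = series_over_trajectory(trajs, lambda f, s: rotation_angle(f, 181, s))
print(f"rotation angle mean: {ang.pooled().mean():.1f} deg")
```

prints

```
z=-3 A  radius=6.30 +- 0.000 A
z=-2 A  radius=6.32 +- 0.000 A
z=-1 A  radius=6.32 +- 0.000 A
z=+0 A  radius=6.30 +- 0.000 A
z=+1 A  radius=6.32 +- 0.000 A
z=+2 A  radius=6.32 +- 0.000 A
z=+3 A  radius=6.30 +- 0.000 A
waters/bin: [6.53 6.8  6.25 6.23 6.27 6.08]
waters per channel: 17.7
rotation angle mean: 58.5 deg
```

The pore-lining TM1 rods sit at ring radius 8 Å with carbon vdW 1.70 Å, so
the analytic slice radius is 6.30 Å — recovered exactly, with zero
replica scatter because the rods are rigid. Waters were planted at
0.02 Å⁻³ inside the 10 Å cylinder, so each 1 Å bin expects
ρπr²dz = 6.28 waters; the per-bin means scatter around that within Poisson
error. The per-channel shell count (sum over the six subunit shells) was
planted at Poisson mean 18 and the orientation at 60° — both recovered
within sampling error.

The FRET/NFAT side works the same way from planted images:

```python
from oraikit import (ImageSpec, make_fret_images, fret_eapp_map,
                     make_nfat_population, measure_nfat_cells, nfat_summarize)

triple, t = make_fret_images(ImageSpec(noise="poisson", e_true=0.3,
                                       background=50, seed=1))
emap = fret_eapp_map(triple, t["calibration"])
print(f"recovered E_app: {emap.summary(mask=t['labels'] > 0):.3f}")
# -> recovered E_app: 0.301   (planted 0.300, G = 2.75, shot noise at ~1000 counts)

img, nuc, cyt, _ = make_nfat_population(
    ImageSpec(n_cells=10, category_fractions=(0.2, 0.3, 0.5), background=30))
print(nfat_summarize(measure_nfat_cells(img, nuc, cyt, background=30))["fractions"])
# -> {'inactive': 0.2, 'homogeneous': 0.3, 'active': 0.5}
```

## Command line

Every analysis is a subcommand of `oraikit`, writing CSV/JSON plus a
`*.manifest.json` (parameters, input digests, seed, version) for
reproducibility:

```sh
oraikit simulate channel --spec channel.yaml --seed 7 --out traj.pdb
oraikit pore-profile --traj traj.pdb --dz 1.0 --optimize-center --out pore.csv
oraikit hydration axial --traj traj.pdb --radius 10 --dz 1 --out hydration.csv
oraikit hydration shell --traj traj.pdb --residue 181 --cutoff 6 --out shell.csv
oraikit geometry angle --traj traj.pdb --residue 181 --out angle.csv
oraikit hydropathy --fasta orai1.fa --scale roseman --window 19 --out prof.csv
oraikit fret --cfp c.tif --yfp y.tif --fret-img f.tif --a 0.1 --b 0.5 --out fret.json
oraikit nfat --image i.tif --nuclei n.tif --cytosol cy.tif --out nfat.json
```

Flags beat `--config` YAML entries, which beat built-in defaults.

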