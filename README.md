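# hydromix

Trajectory analysis for hydrogen-bonded molecular mixtures (disaccharide +
water model systems): hydrogen-bond detection, census and reactive-flux
kinetics; radial, spatial and combined distribution functions; dihedral
distributions; periodic cluster analysis with percolation detection;
Einstein-relation self-diffusion with Arrhenius diagnostics;
glass-transition extraction from density–temperature curves; and pairwise
Lennard-Jones + Coulomb interaction-energy decomposition.

A first-class `synth` module generates every kind of input with known
ground truth — rigid pseudo-trehalose molecules carrying the full site-label
set (O1–O4 ×2 rings, Ob, Oe ×2, ring carbons), 3-site waters, Brownian
walkers with prescribed diffusion coefficients, telegraph (two-state)
bond/unbond dynamics with prescribed rate constants, clustered/percolating
aggregates, and density curves with prescribed maxima — so the whole
analysis stack is testable without an MD engine.

## Conventions

Coordinates in Å, time in ps, energy in kJ/mol, temperature in K, charges
in elementary charges. Orthorhombic periodic boxes only. Hydrogen bonds:
donor–acceptor oxygen separation ≤ 3.5 Å and donor-centred angle
H–O(donor)–O(acceptor) ≤ 60°, both inclusive and configurable; ring oxygens
(Ob, Oe) excluded as acceptors by default.

## File formats

* Trajectories: XYZ with an extended comment line
  (`Lattice="Lx 0 0 0 Ly 0 0 0 Lz" Time=… Properties=…`, optionally with a
  second unwrapped-coordinate triple per atom), or PDB with CRYST1.
* Topology sidecar: tab-separated table with columns
  `atom_index element site_label molecule_id molecule_type mass charge
  lj_sigma lj_epsilon` (XYZ/PDB cannot carry charges/LJ terms).
* Analysis outputs: tab-separated tables; SDF grids as Gaussian cube files.

## CLI

```sh
hydromix generate --mode hydrated --n-thal 2 --box 60 --seed 1 --output traj.xyz
hydromix rdf   --topology traj.topology.tsv --trajectory traj.xyz \
               --type-a THAL --sites-a O1 --type-b WATER --sites-b Ow \
               --r-max 6.0 --output rdf.tsv
hydromix nint  … --r-cut 3.5 --output n.json
hydromix hbond … --output census.tsv
hydromix hbond-kinetics … --output rates.tsv
hydromix cluster … --site-label Ob --cutoff 6.0 --output clusters.tsv
hydromix msd   … --species A --output msd.tsv
hydromix arrhenius --input d_vs_t.csv --output fit.json
hydromix tg    --input curves.csv --output tg.tsv
hydromix energy … --cutoff 15.0 --output energy.tsv
hydromix sdf / cdf / dihedral …
hydromix composition --n-water 1500 --omega-target 0.760
```

Generator modes: `gas`, `hydrated`, `clustered`, `brownian`, `telegraph`,
`density-curves`. Analysis parameters may also come from a `key = value`
config file via `--config`; explicit flags win. Site labels accept an
occurrence qualifier `label@k` (k-th occurrence within the molecule) to
disambiguate per-ring labels, e.g. `C1@2`.

## Library example

```python
from hydromix import synth, structure
from hydromix.core import Box, select_sites

traj = synth.generate_hydrated_trehalose(3, waters_per_site=2, d_hb=2.8,
                                         box=Box((60, 60, 60)), seed=1)
o1 = select_sites(traj.topology, "THAL", {"O1"})
ow = select_sites(traj.topology, "WATER", {"Ow"})
rdf = structure.compute_rdf(traj, o1, ow, r_max=6.0)
structure.compute_running_integral(rdf, 3.5)   # -> 2.0 by construction
```

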