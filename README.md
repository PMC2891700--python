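# cgfold

A coarse-grained (CG) protein modelling toolkit built around a five-site-type
representation: one backbone site per residue at the Cα position plus up to
four typed sidechain sites (apolar, polar, positive, negative), each grouping
1–3 heavy atoms at their mass centre.

Pipeline stages, one module each:

| module            | what it does |
|-------------------|--------------|
| `cgfold.mapping`  | residue→site mapping scheme, structure mapping, force mapping, chain topology (bonds, tagged angles, sequence-keyed pseudo-torsions, ring impropers, exclusion rule) |
| `cgfold.bonded`   | Boltzmann inversion of bond/angle/torsion distributions (r², sin θ volume factors), harmonic/quartic fits, cosine-series torsion library with global 0.54 scaling |
| `cgfold.forcematch` | variational force matching: linear-spline pair-force basis, per-block normal-equation least squares, block averaging, half-data convergence check |
| `cgfold.tables`   | force-curve integration, cubic B-spline smoothing, linear switching, Mie(9,6) soft-core builder from the shipped pair-minima parameter file, native/GROMACS-style table I/O |
| `cgfold.simulate` | BAOAB Langevin CG-MD over tabulated nonbonded (cubic-Hermite, gradient-exact) + fitted bonded terms; 2 fs step, 2 ps inverse friction, 1.2 nm cutoff, Verlet neighbour list, harmonic position restraints |
| `cgfold.remd`     | replica exchange: exponential 100–700 K ladders, Metropolis swaps with velocity rescaling, alternating neighbour sweeps, occupancy/acceptance bookkeeping |
| `cgfold.analysis` | heat capacity from energy fluctuations + transition temperature (and its 0.6× reference), Kabsch RMSD with fit/measure selections, ΔD_RMSD, radius of gyration, nonbonded Cα RDF |
| `cgfold.fixtures` | synthetic oracles: exact-force toy fluids, bonded-coordinate samplers, ideal-geometry toy peptides, shipped structures and parameter files |

Shipped data (`src/cgfold/data/`): the default mapping scheme
(`mapping.yaml`), the 15-row pair-minima parameter file
(`pair_minima.tsv`), and three all-atom structures (`pdb/`): open/closed
adenylate kinase (4AKE/1AKE-derived) and a Trpzip2-sequence model.

## CLI

```sh
cgfold map structure.pdb -o topo.json        # all-atom -> CG sites/topology
cgfold tables --outdir tables/               # build the 15 soft-core tables
cgfold md --sequence AAAAAAAAAA --steps 100000 --temperature 300 --seed 1
cgfold remd --sequence AAAAA --replicas 4 --steps 20000 --seed 1
cgfold analyze energies.tsv --temperatures 100,200,300
cgfold fixtures --what pair-minima
```

## Units

nm, ps, K, kJ/mol, amu internally; Å at I/O boundaries (PDB files, RMSD
and pair-minimum reporting).
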