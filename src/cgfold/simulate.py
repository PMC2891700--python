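"""Langevin CG-MD over tabulated nonbonded and fitted bonded potentials.

Protocol defaults: 2 fs timestep, 2 ps inverse friction, 1.2 nm cutoff,
nonbonded between sites separated by at least three bonds.  The integrator
is the BAOAB splitting, which reduces to velocity Verlet at zero friction.

Nonbonded energies interpolate the (V, f) table with a cubic Hermite whose
node slopes are -f, so the evaluated force is the exact negative gradient
of the evaluated energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import KB
from .forcematch import minimum_image, pair_key


class SimulationError(RuntimeError):
    pass


def _cross(a, b):
    # np.cross without its moveaxis overhead (hot path)
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


# ----------------------------------------------------------------------
# bonded term potentials: callables (value, derivative) in internal units
# (nm for bonds, radians for angles/torsions)

@dataclass(frozen=True)
class Harmonic:
    k: float
    x0: float

    def value(self, x):
        return 0.5 * self.k * (x - self.x0) ** 2

    def deriv(self, x):
        return self.k * (x - self.x0)


@dataclass(frozen=True)
class PeriodicHarmonic:
    """Harmonic in the wrapped deviation from x0 (for impropers), radians."""
    k: float
    x0: float = 0.0

    def _d(self, x):
        return (x - self.x0 + np.pi) % (2 * np.pi) - np.pi

    def value(self, x):
        return 0.5 * self.k * self._d(x) ** 2

    def deriv(self, x):
        return self.k * self._d(x)


@dataclass(frozen=True)
class CosinePlanarity:
    """V = k/2 (1 - cos 2phi): smooth planarity restraint with minima at
    phi = 0 and 180 degrees (both planar arrangements)."""
    k: float

    def value(self, phi):
        return 0.5 * self.k * (1.0 - np.cos(2.0 * phi))

    def deriv(self, phi):
        return self.k * np.sin(2.0 * phi)


class PolynomialTerm:
    """Adapter for bonded.PolynomialPotential; converts degrees->radians for
    angle-kind polynomials fit on degree grids."""

    def __init__(self, poly, degrees: bool = False):
        self.poly = poly
        self.degrees = degrees

    def value(self, x):
        xx = np.degrees(x) if self.degrees else x
        return self.poly(xx)

    def deriv(self, x):
        xx = np.degrees(x) if self.degrees else x
        d = self.poly.derivative(xx)
        return d * (180.0 / np.pi) if self.degrees else d


class CosineSeriesTerm:
    """Adapter for bonded.CosineSeries (defined on degrees)."""

    def __init__(self, series):
        self.series = series

    def value(self, phi):
        return self.series(np.degrees(phi))

    def deriv(self, phi):
        return self.series.derivative_deg(np.degrees(phi)) * (180.0 / np.pi)


@dataclass
class BondedForceField:
    """Keyed bonded terms with '*' fallbacks; keys come from the topology."""
    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)      # key or tag -> term
    torsions: dict = field(default_factory=dict)    # (res_i, res_j) or '*'
    impropers: dict = field(default_factory=dict)

    def bond_term(self, key):
        return self.bonds.get(key) or self.bonds.get("*")

    def angle_term(self, key, tag):
        return self.angles.get(key) or self.angles.get(tag) or self.angles.get("*")

    def torsion_term(self, key):
        return self.torsions.get(tuple(key)) or self.torsions.get("*")

    def improper_term(self, key):
        return self.impropers.get(key) or self.impropers.get("*")


# ----------------------------------------------------------------------
# tabulated nonbonded evaluation

class PairTableSet:
    """Stacked pair tables on a common grid for vectorised lookup."""

    def __init__(self, tables: dict, v_max: float = 1e5):
        keys = sorted(tables)
        grids = [tables[k].r for k in keys]
        g0 = grids[0]
        for g in grids[1:]:
            if len(g) != len(g0) or not np.allclose(g, g0):
                raise SimulationError("pair tables must share one grid")
        self.keys = keys
        self.index = {k: i for i, k in enumerate(keys)}
        self.r = g0.copy()
        self.h = float(np.diff(g0).mean())
        if not np.allclose(np.diff(g0), self.h, rtol=1e-6):
            raise SimulationError("pair-table grid must be uniform")
        self.V = np.stack([tables[k].V for k in keys])
        self.F = np.stack([tables[k].f for k in keys])
        self.v_max = v_max
        self.wall_hits = 0

    @property
    def cutoff(self):
        return float(self.r[-1])

    def table_id(self, type_a, type_b):
        key = pair_key(type_a, type_b)
        if key not in self.index:
            raise SimulationError(f"missing pair table for {key}")
        return self.index[key]

    def evaluate(self, tid: np.ndarray, r: np.ndarray):
        """Energy and force magnitude (+ = repulsive) at separations r."""
        V = np.zeros_like(r)
        f = np.zeros_like(r)
        below = r < self.r[0]
        if below.any():
            self.wall_hits += int(below.sum())
            d = self.r[0] - r[below]
            V[below] = np.minimum(self.V[tid[below], 0] + self.F[tid[below], 0] * d,
                                  self.v_max)
            f[below] = self.F[tid[below], 0]
        inside = (~below) & (r <= self.r[-1])
        if inside.any():
            ri = r[inside]
            ti = tid[inside]
            idx = np.clip(((ri - self.r[0]) / self.h).astype(int), 0,
                          len(self.r) - 2)
            t = (ri - self.r[idx]) / self.h
            V0 = self.V[ti, idx]
            V1 = self.V[ti, idx + 1]
            m0 = -self.F[ti, idx] * self.h
            m1 = -self.F[ti, idx + 1] * self.h
            t2 = t * t
            t3 = t2 * t
            h00 = 2 * t3 - 3 * t2 + 1
            h10 = t3 - 2 * t2 + t
            h01 = -2 * t3 + 3 * t2
            h11 = t3 - t2
            V[inside] = h00 * V0 + h10 * m0 + h01 * V1 + h11 * m1
            d00 = 6 * t2 - 6 * t
            d10 = 3 * t2 - 4 * t + 1
            d01 = -d00
            d11 = 3 * t2 - 2 * t
            dVdr = (d00 * V0 + d10 * m0 + d01 * V1 + d11 * m1) / self.h
            f[inside] = -dVdr
        return V, f


# ----------------------------------------------------------------------

@dataclass
class SimulationConfig:
    timestep: float = 0.002         # ps
    inverse_friction: float = 2.0   # ps; gamma = 1/inverse_friction
    temperature: float = 300.0      # K
    cutoff: float = 1.2             # nm
    skin: float = 0.3               # nm neighbor-list skin
    seed: int = 0
    box: np.ndarray | None = None
    restraint_ids: tuple = ()
    restraint_k: float = 1000.0     # kJ/mol/nm^2
    v_max: float = 1e5

    @property
    def gamma(self):
        return 0.0 if self.inverse_friction in (0, np.inf) else 1.0 / self.inverse_friction


@dataclass
class SimulationState:
    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    step: int = 0
    forces: np.ndarray | None = None
    energies: dict = field(default_factory=dict)

    def kinetic_energy(self):
        return 0.5 * float((self.masses[:, None] * self.velocities ** 2).sum())

    def kinetic_temperature(self):
        ndof = 3 * len(self.masses)
        return 2 * self.kinetic_energy() / (ndof * KB)


@dataclass
class Trajectory:
    times: list = field(default_factory=list)
    frames: list = field(default_factory=list)
    energies: list = field(default_factory=list)    # dicts per sample
    stride: int = 1

    def positions_array(self):
        return np.array(self.frames)

    def energy_series(self, term="potential"):
        return np.array([e[term] for e in self.energies])


class NeighborList:
    """Verlet list over the non-excluded pair set, rebuilt on skin violation."""

    def __init__(self, topology, cutoff, skin, box=None):
        n = topology.n_sites
        excl = topology.exclusion_pairs()
        ii, jj = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) not in excl:
                    ii.append(i)
                    jj.append(j)
        self.all_i = np.array(ii, dtype=int)
        self.all_j = np.array(jj, dtype=int)
        self.cutoff = cutoff
        self.skin = skin
        self.box = box
        self.ref_positions = None
        self.pairs = (self.all_i, self.all_j)
        self.keep_indices = np.arange(len(self.all_i))

    def rebuild(self, X):
        dx = minimum_image(X[self.all_i] - X[self.all_j], self.box)
        r2 = (dx ** 2).sum(axis=1)
        keep = r2 <= (self.cutoff + self.skin) ** 2
        self.keep_indices = np.where(keep)[0]
        self.pairs = (self.all_i[keep], self.all_j[keep])
        self.ref_positions = X.copy()

    def maybe_rebuild(self, X):
        if self.ref_positions is None:
            self.rebuild(X)
            return True
        disp = np.abs(X - self.ref_positions).max()
        if disp > 0.5 * self.skin:
            self.rebuild(X)
            return True
        return False


class System:
    """Bound topology + potentials, able to evaluate forces and energies."""

    def __init__(self, topology, tables, bonded: BondedForceField,
                 config: SimulationConfig, reference_positions=None):
        self.topology = topology
        self.bonded = bonded
        self.config = config
        self.tables = (tables if isinstance(tables, PairTableSet)
                       else PairTableSet(tables, v_max=config.v_max))
        if config.cutoff > self.tables.cutoff + 1e-9:
            raise SimulationError("cutoff exceeds table range")
        self.nlist = NeighborList(topology, config.cutoff, config.skin,
                                  config.box)
        types = topology.site_types()
        self.pair_tid = {}
        self._tid_all = np.array([self.tables.table_id(types[i], types[j])
                                  for i, j in zip(self.nlist.all_i,
                                                  self.nlist.all_j)], dtype=int)
        self.reference_positions = (None if reference_positions is None
                                    else np.asarray(reference_positions, float))
        self._check_terms()
        self._index_bonded()

    def _index_bonded(self):
        """Group bonded terms by potential object for vectorised evaluation."""
        topo = self.topology

        def group(entries, term_of):
            by_term = {}
            for n, e in enumerate(entries):
                t = term_of(e)
                by_term.setdefault(id(t), (t, []))[1].append(n)
            return [(t, np.array(idx)) for t, idx in by_term.values()]

        self._bond_ij = (np.array([b[0] for b in topo.bonds], dtype=int),
                         np.array([b[1] for b in topo.bonds], dtype=int))
        self._bond_groups = group(topo.bond_keys, self.bonded.bond_term)
        self._angle_ijk = (np.array([a.i for a in topo.angles], dtype=int),
                           np.array([a.j for a in topo.angles], dtype=int),
                           np.array([a.k for a in topo.angles], dtype=int))
        self._angle_groups = group(topo.angles,
                                   lambda a: self.bonded.angle_term(a.key, a.tag))
        quads = ([(t.i, t.j, t.k, t.l) for t in topo.torsions]
                 + [(m.i, m.j, m.k, m.l) for m in topo.impropers])
        self._dihedral_ijkl = tuple(
            np.array([q[d] for q in quads], dtype=int) for d in range(4))
        terms = ([self.bonded.torsion_term(t.key) for t in topo.torsions]
                 + [self.bonded.improper_term(m.key) for m in topo.impropers])
        labels = (["torsion"] * len(topo.torsions)
                  + ["improper"] * len(topo.impropers))
        by_term = {}
        for n, (t, lab) in enumerate(zip(terms, labels)):
            by_term.setdefault((id(t), lab), (t, lab, []))
            by_term[(id(t), lab)][2].append(n)
        self._dihedral_groups = [(t, lab, np.array(idx))
                                 for t, lab, idx in by_term.values()]

    def _check_terms(self):
        topo = self.topology
        for key in topo.bond_keys:
            if self.bonded.bond_term(key) is None:
                raise SimulationError(f"no bond potential for key {key!r}")
        for a in topo.angles:
            if self.bonded.angle_term(a.key, a.tag) is None:
                raise SimulationError(f"no angle potential for {a.key!r}")
        for t in topo.torsions:
            if self.bonded.torsion_term(t.key) is None:
                raise SimulationError(f"no torsion potential for {t.key!r}")
        for m in topo.impropers:
            if self.bonded.improper_term(m.key) is None:
                raise SimulationError(f"no improper potential for {m.key!r}")

    # -- force evaluation ----------------------------------------------
    def compute_forces(self, X, use_neighbor_list=True):
        cfg = self.config
        box = cfg.box
        n = self.topology.n_sites
        F = np.zeros((n, 3))
        energies = {"bond": 0.0, "angle": 0.0, "torsion": 0.0,
                    "improper": 0.0, "nonbonded": 0.0, "restraint": 0.0}

        # nonbonded
        if use_neighbor_list:
            self.nlist.maybe_rebuild(X)
            pi, pj = self.nlist.pairs
            tid = self._tid_all[self.nlist.keep_indices]
        else:
            pi, pj = self.nlist.all_i, self.nlist.all_j
            tid = self._tid_all
        if len(pi):
            dx = minimum_image(X[pi] - X[pj], box)
            r = np.linalg.norm(dx, axis=1)
            inside = (r <= cfg.cutoff) & (r > 0)
            if inside.any():
                V, fmag = self.tables.evaluate(tid[inside], r[inside])
                energies["nonbonded"] = float(V.sum())
                fv = (fmag / r[inside])[:, None] * dx[inside]
                np.add.at(F, pi[inside], fv)
                np.add.at(F, pj[inside], -fv)

        # bonds (vectorised per term group)
        topo = self.topology
        bi, bj = self._bond_ij
        if len(bi):
            dx = minimum_image(X[bi] - X[bj], box)
            r = np.linalg.norm(dx, axis=1)
            dvdr = np.zeros_like(r)
            for term, idx in self._bond_groups:
                energies["bond"] += float(np.sum(term.value(r[idx])))
                dvdr[idx] = term.deriv(r[idx])
            fv = (-dvdr / r)[:, None] * dx
            np.add.at(F, bi, fv)
            np.add.at(F, bj, -fv)

        # angles
        ai, aj, ak = self._angle_ijk
        if len(ai):
            u = minimum_image(X[ai] - X[aj], box)
            v = minimum_image(X[ak] - X[aj], box)
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos_t = np.clip((u * v).sum(axis=1) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(cos_t)
            dv = np.zeros_like(theta)
            for term, idx in self._angle_groups:
                energies["angle"] += float(np.sum(term.value(theta[idx])))
                dv[idx] = term.deriv(theta[idx])
            sin_t = np.maximum(np.sqrt(1.0 - cos_t ** 2), 1e-8)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            dth_di = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
            dth_dk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
            np.add.at(F, ai, -dv[:, None] * dth_di)
            np.add.at(F, ak, -dv[:, None] * dth_dk)
            np.add.at(F, aj, dv[:, None] * (dth_di + dth_dk))

        # torsions and impropers share the dihedral geometry
        ti, tj, tk, tl = self._dihedral_ijkl
        if len(ti):
            b1 = minimum_image(X[tj] - X[ti], box)
            b2 = minimum_image(X[tk] - X[tj], box)
            b3 = minimum_image(X[tl] - X[tk], box)
            n1 = _cross(b1, b2)
            n2 = _cross(b2, b3)
            nb2 = np.sqrt((b2 ** 2).sum(axis=1))
            n1sq = (n1 ** 2).sum(axis=1)
            n2sq = (n2 ** 2).sum(axis=1)
            ok = (n1sq > 1e-14) & (n2sq > 1e-14) & (nb2 > 1e-10)
            phi = np.zeros(len(ti))
            phi[ok] = np.arctan2(
                (_cross(n1[ok], n2[ok]) * b2[ok]).sum(axis=1) / nb2[ok],
                (n1[ok] * n2[ok]).sum(axis=1))
            dv = np.zeros_like(phi)
            for term, label, idx in self._dihedral_groups:
                sel = idx[ok[idx]]
                if len(sel):
                    energies[label] += float(np.sum(term.value(phi[sel])))
                    dv[sel] = term.deriv(phi[sel])
            safe_n1sq = np.where(ok, n1sq, 1.0)
            safe_n2sq = np.where(ok, n2sq, 1.0)
            dv = np.where(ok, dv, 0.0)
            fi = (dv * nb2 / safe_n1sq)[:, None] * n1
            fl = (-dv * nb2 / safe_n2sq)[:, None] * n2
            nb2sq = np.where(ok, nb2 ** 2, 1.0)
            s12 = ((b1 * b2).sum(axis=1) / nb2sq)[:, None]
            s32 = ((b3 * b2).sum(axis=1) / nb2sq)[:, None]
            fj = -(1.0 + s12) * fi + s32 * fl
            fk = s12 * fi - (1.0 + s32) * fl
            np.add.at(F, ti, fi)
            np.add.at(F, tj, fj)
            np.add.at(F, tk, fk)
            np.add.at(F, tl, fl)

        # harmonic position restraints
        if self.config.restraint_ids and self.reference_positions is not None:
            ids = np.asarray(self.config.restraint_ids, dtype=int)
            d = X[ids] - self.reference_positions[ids]
            energies["restraint"] = float(0.5 * self.config.restraint_k
                                          * (d ** 2).sum())
            F[ids] -= self.config.restraint_k * d

        energies["bonded"] = (energies["bond"] + energies["angle"]
                              + energies["torsion"] + energies["improper"])
        energies["potential"] = (energies["bonded"] + energies["nonbonded"]
                                 + energies["restraint"])
        return F, energies

    def potential_energy(self, X):
        return self.compute_forces(X, use_neighbor_list=False)[1]["potential"]


def initial_state(system: System, positions, temperature=None, rng=None):
    cfg = system.config
    masses = system.topology.masses()
    X = np.asarray(positions, dtype=float).copy()
    V = np.zeros_like(X)
    T = cfg.temperature if temperature is None else temperature
    if rng is not None and T > 0:
        V = rng.standard_normal(X.shape) * np.sqrt(KB * T / masses)[:, None]
    state = SimulationState(X, V, masses)
    state.forces, state.energies = system.compute_forces(X)
    return state


def langevin_step(system: System, state: SimulationState, rng,
                  temperature=None):
    """One BAOAB step; with gamma = 0 this is velocity Verlet."""
    cfg = system.config
    dt = cfg.timestep
    T = cfg.temperature if temperature is None else temperature
    m = state.masses[:, None]
    if state.forces is None or not np.isfinite(state.forces).all():
        raise SimulationError(f"non-finite forces at step {state.step}")
    v = state.velocities + 0.5 * dt * state.forces / m
    x = state.positions + 0.5 * dt * v
    gamma = cfg.gamma
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 ** 2) * KB * T / state.masses)[:, None]
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    F, energies = system.compute_forces(x)
    if not np.isfinite(F).all():
        raise SimulationError(f"non-finite forces at step {state.step + 1}")
    v = v + 0.5 * dt * F / m
    state.positions = x
    state.velocities = v
    state.forces = F
    state.energies = energies
    state.step += 1
    return state


def run(system: System, positions, n_steps: int, stride: int = 100,
        rng=None, temperature=None, velocities=None) -> Trajectory:
    """Run Langevin MD; returns sampled trajectory incl. the initial frame."""
    cfg = system.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    state = initial_state(system, positions, temperature=temperature, rng=rng)
    if velocities is not None:
        state.velocities = np.asarray(velocities, float).copy()
    traj = Trajectory(stride=stride)

    def record():
        e = dict(state.energies)
        e["kinetic"] = state.kinetic_energy()
        e["total"] = e["kinetic"] + e["potential"]
        traj.times.append(state.step * cfg.timestep)
        traj.frames.append(state.positions.copy())
        traj.energies.append(e)

    record()
    for _ in range(n_steps):
        langevin_step(system, state, rng, temperature=temperature)
        if state.step % stride == 0:
            record()
    traj.final_state = state
    return traj


def export_ca_pdb(traj: Trajectory, topology, path):
    """Write the backbone C-alpha trace as a multi-model PDB (nm -> A)."""
    bb = topology.backbone_ids()
    lines = []
    for m, X in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for n, i in enumerate(bb, start=1):
            x, y, z = X[i] * 10.0
            res = topology.sites[i].residue_name
            ri = topology.sites[i].residue_index
            lines.append(f"ATOM  {n:5d}  CA  {res:<3s} A{ri:4d}    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
        lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_energy_log(traj: Trajectory, path):
    """Energy log as TSV: time + every logged energy term."""
    keys = sorted(traj.energies[0])
    lines = ["time_ps\t" + "\t".join(keys)]
    for t, e in zip(traj.times, traj.energies):
        lines.append(f"{t:.6g}\t" + "\t".join(f"{e[k]:.8g}" for k in keys))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def randomize_chain(system: System, positions, T_high: float = 700.0,
                    n_steps: int = 20000, seed: int = 0) -> np.ndarray:
    """High-temperature run returning the final frame as an unfolded start."""
    rng = np.random.default_rng(seed)
    traj = run(system, positions, n_steps, stride=max(1, n_steps), rng=rng,
               temperature=T_high)
    return traj.frames[-1]
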