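"""Synthetic-data generators with exact oracles, plus shipped data loaders.

Every stage of the pipeline is testable offline: toy fluids whose frames
carry forces evaluated exactly from a known pair law (for force matching),
i.i.d. bonded-coordinate samplers with the correct volume factors (for
Boltzmann inversion), ideal-geometry CG peptides, the pair-minima parameter
file and builder, and local copies of the benchmark structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .units import KB
from .bonded import CoordinateHistogram
from .forcematch import CGFrame, minimum_image, pair_key
from .mapping import MappingScheme, build_topology, CGTopology
from .pdbio import read_structure
from .simulate import (BondedForceField, CosinePlanarity, Harmonic,
                       PeriodicHarmonic, PolynomialTerm)
from . import tables as _tables

_STRUCTURE_FILES = {
    "trpzip2": "trpzip2_model.pdb",    # sequence model standing in for 1LE1
    "adk_open": "adk_open.pdb",        # 4AKE-derived all-atom structure
    "adk_closed": "adk_closed.pdb",    # 1AKE-derived all-atom structure
}

# AdK domain residue ranges (external convention, user-overridable)
ADK_DOMAINS = {"NMP": (30, 67), "LID": (118, 160)}


def structure_path(name: str):
    try:
        fname = _STRUCTURE_FILES[name]
    except KeyError:
        raise KeyError(f"unknown shipped structure {name!r}; "
                       f"have {sorted(_STRUCTURE_FILES)}")
    return resources.files("cgfold.data.pdb").joinpath(fname)


def load_structure(name: str, **kw):
    import contextlib
    with contextlib.ExitStack() as stack:
        path = stack.enter_context(resources.as_file(structure_path(name)))
        return read_structure(path, **kw)


def adk_domain_indices(topology: CGTopology, domains=None):
    """Site-index selections for NMP, LID and CORE (= remainder)."""
    domains = domains or ADK_DOMAINS
    out = {}
    claimed = set()
    for name, (lo, hi) in domains.items():
        out[name] = [s.site_id for s in topology.sites
                     if lo <= s.residue_index <= hi]
        claimed.update(range(lo, hi + 1))
    out["CORE"] = [s.site_id for s in topology.sites
                   if s.residue_index not in claimed]
    return out


# ----------------------------------------------------------------------
# oracle fluid for force matching

@dataclass
class PairLaw:
    """Closed-form pair law: V(r) and force magnitude f(r) = -dV/dr."""
    v: callable
    f: callable

    @classmethod
    def mie(cls, r_min: float, epsilon: float) -> "PairLaw":
        return cls(lambda r: _tables.mie96(r, r_min, epsilon),
                   lambda r: _tables.mie96_force(r, r_min, epsilon))

    @classmethod
    def piecewise_linear_force(cls, knots, values) -> "PairLaw":
        """Force law inside the hat-spline span: exact-recovery mode."""
        knots = np.asarray(knots, dtype=float)
        values = np.asarray(values, dtype=float)

        def f(r):
            return np.interp(r, knots, values, left=values[0], right=0.0)

        def v(r):
            # integrate -f from the last knot inward (for completeness)
            grid = np.linspace(knots[0], knots[-1], 2001)
            fg = f(grid)
            seg = 0.5 * (fg[1:] + fg[:-1]) * np.diff(grid)
            Vg = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
            return np.interp(r, grid, Vg)

        return cls(v, f)


def exact_forces(X, law: PairLaw, box=None):
    """Newton's-third-law-exact pairwise forces from the known law."""
    n = len(X)
    F = np.zeros_like(X)
    ii, jj = np.triu_indices(n, k=1)
    dx = minimum_image(X[ii] - X[jj], box)
    r = np.linalg.norm(dx, axis=1)
    fmag = law.f(r)
    fv = (fmag / r)[:, None] * dx
    np.add.at(F, ii, fv)
    np.add.at(F, jj, -fv)
    return F


def make_oracle_fluid(n: int, law: PairLaw, T: float, n_frames: int,
                      seed: int = 0, box_length: float = 3.0,
                      n_equil: int = 200, sample_interval: int = 20,
                      dt: float = 2e-4, min_start: float = 0.45):
    """Overdamped (Brownian) sampling of n particles under the pair law.

    Stored forces are evaluated exactly from the law, making the frames an
    exact oracle for the MS-CG solver.  Reproducible under fixed seed.
    """
    rng = np.random.default_rng(seed)
    box = np.full(3, float(box_length))
    # start on a jittered lattice to avoid overlaps below support
    per_side = int(np.ceil(n ** (1 / 3)))
    grid = (np.stack(np.meshgrid(*[np.arange(per_side)] * 3, indexing="ij"), -1)
            .reshape(-1, 3)[:n]) * (box_length / per_side)
    X = grid + rng.uniform(0, 0.05, size=(n, 3))
    d0 = box_length / per_side
    if d0 < min_start:
        raise ValueError("box too small: initial overlap below potential support")
    sigma = np.sqrt(2 * KB * T * dt)
    max_move = 0.05     # nm; trust-region cap keeps steep cores stable
    frames = []
    total = n_equil + n_frames * sample_interval
    for step in range(total):
        F = exact_forces(X, law, box)
        drift = F * dt
        norm = np.linalg.norm(drift, axis=1, keepdims=True)
        drift = np.where(norm > max_move, drift * (max_move / norm), drift)
        X = X + drift + sigma * rng.standard_normal(X.shape)
        if step >= n_equil and (step - n_equil) % sample_interval == 0:
            Xs = X.copy()
            frames.append(CGFrame(Xs, exact_forces(Xs, law, box), box.copy()))
    return frames[:n_frames]


# ----------------------------------------------------------------------
# bonded-coordinate samplers (i.i.d., rejection method)

def sample_bonded(kind: str, potential, T: float, n: int, seed: int = 0,
                  domain=None):
    """Draw i.i.d. samples from exp(-V/kT) x Jacobian over the domain.

    kind 'bond': Jacobian r^2, domain in nm; 'angle': sin(theta), degrees;
    'torsion': flat, degrees on (-180, 180].
    """
    rng = np.random.default_rng(seed)
    if kind == "bond":
        lo, hi = domain or (0.05, 1.0)
        jac = lambda x: x ** 2
    elif kind == "angle":
        lo, hi = domain or (1.0, 179.0)
        jac = lambda x: np.sin(np.radians(x))
    elif kind == "torsion":
        lo, hi = -180.0, 180.0
        jac = lambda x: np.ones_like(x)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    grid = np.linspace(lo, hi, 4001)
    dens = np.exp(-(np.asarray(potential(grid)) - np.min(potential(grid)))
                  / (KB * T)) * jac(grid)
    peak = dens.max()
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("unnormalizable density")
    out = np.empty(0)
    while len(out) < n:
        m = max(2 * (n - len(out)), 1000)
        x = rng.uniform(lo, hi, size=m)
        y = rng.uniform(0, peak, size=m)
        dx_dens = np.exp(-(np.asarray(potential(x)) - np.min(potential(grid)))
                         / (KB * T)) * jac(x)
        out = np.concatenate([out, x[y < dx_dens]])
    return out[:n]


def bonded_histogram(kind, potential, T, n, seed=0, domain=None,
                     bin_width=None) -> CoordinateHistogram:
    samples = sample_bonded(kind, potential, T, n, seed, domain)
    return CoordinateHistogram.from_samples(kind, samples, T, bin_width,
                                            range_=domain)


# ----------------------------------------------------------------------
# pair-minima parameter file -> soft-core force field

def table2_forcefield(cutoff: float = _tables.DEFAULT_CUTOFF):
    """Load the shipped pair-minima file and build the 15 soft-core tables."""
    minima = _tables.read_pair_minima()
    return _tables.build_softcore(minima, cutoff=cutoff), minima


# ----------------------------------------------------------------------
# ideal-geometry toy peptides

CA_CA = 0.38        # nm consecutive C-alpha virtual bond
SC_OFFSET = 0.25    # nm backbone->sidechain-site spacing in templates


def toy_peptide(sequence, geometry: str = "extended",
                scheme: MappingScheme | None = None,
                min_separation: int = 3):
    """Ideal-geometry CG chain; returns (topology, positions nm)."""
    scheme = scheme or MappingScheme.default()
    topo = build_topology(list(sequence), scheme, min_separation)
    n = len(sequence)
    if geometry == "extended":
        # flat zig-zag with exact 0.38 nm consecutive spacing
        dy = 0.05
        dx = np.sqrt(CA_CA ** 2 - (2 * dy) ** 2)
        bb = np.array([[i * dx, dy * (-1) ** i, 0.0] for i in range(n)])
    elif geometry == "helixlike":
        radius, rise, turn = 0.23, 0.15, np.radians(100.0)
        bb = np.array([[radius * np.cos(i * turn), radius * np.sin(i * turn),
                        i * rise] for i in range(n)])
        # uniform scaling so consecutive spacing is exactly CA_CA
        d = np.linalg.norm(bb[1] - bb[0])
        bb *= CA_CA / d
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    X = np.zeros((topo.n_sites, 3))
    for s in topo.sites:
        ri = s.residue_index - 1
        if s.local_index == 0:
            X[s.site_id] = bb[ri]
        else:
            # stack sidechain sites outward, perpendicular to the chain axis
            if geometry == "extended":
                axis = np.array([0.0, 0.0, 1.0])
            else:
                radial = bb[ri] - np.array([0.0, 0.0, bb[ri][2]])
                nr = np.linalg.norm(radial)
                axis = radial / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
            X[s.site_id] = bb[ri] + axis * SC_OFFSET * s.local_index
    return topo, X


def default_bonded(bond_k: float = 8000.0, angle_k: float = 40.0,
                   backbone_angle=None) -> BondedForceField:
    """Simple stable bonded force field for toy CG chains.

    Backbone angles default to a quartic with minima bracketing 90 and 120
    degrees (helix/sheet-like interconversion); sidechain geometry is
    harmonic; torsions are unrestricted by default; impropers planar.
    """
    ff = BondedForceField()
    ff.bonds["BB-BB"] = Harmonic(bond_k, CA_CA)
    ff.bonds["*"] = Harmonic(bond_k, SC_OFFSET)
    if backbone_angle is None:
        # quartic in radians with wells near 1.57 and 2.1 rad
        th1, th2 = np.radians(90.0), np.radians(120.0)
        mid = 0.5 * (th1 + th2)

        class _DoubleWell:
            amp = 30.0

            def value(self, x):
                return self.amp * ((x - mid) ** 2 - (th2 - mid) ** 2) ** 2 \
                    / (th2 - mid) ** 4

            def deriv(self, x):
                return self.amp * 4 * (x - mid) * ((x - mid) ** 2
                                                   - (th2 - mid) ** 2) \
                    / (th2 - mid) ** 4

        ff.angles["BB"] = _DoubleWell()
    else:
        ff.angles["BB"] = backbone_angle
    ff.angles["to_previous"] = Harmonic(angle_k, np.radians(100.0))
    ff.angles["to_next"] = Harmonic(angle_k, np.radians(100.0))
    ff.angles["*"] = Harmonic(angle_k, np.radians(110.0))
    ff.torsions["*"] = PeriodicHarmonic(0.0, 0.0)   # unrestricted
    ff.impropers["*"] = CosinePlanarity(20.0)
    return ff
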