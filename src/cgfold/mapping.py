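"""Coarse-grained representation: site typing, structure mapping, topology.

One backbone site per residue at the C-alpha position plus up to four typed
sidechain sites per residue, each grouping 1-3 heavy atoms at their mass
centre.  Five site types exist: backbone, apolar, polar, positive, negative.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

from .units import NM_PER_A, element_mass

SITE_TYPES = ("backbone", "apolar", "polar", "positive", "negative")

H_MASS = element_mass("H")
CA_MASS = element_mass("C")


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class SiteDefinition:
    site_type: str
    atoms: tuple
    hydrogens: int = 0

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise MappingError(f"unknown site type {self.site_type!r}")
        if not 1 <= len(self.atoms) <= 3:
            raise MappingError(f"site must group 1-3 heavy atoms, got {self.atoms}")


@dataclass(frozen=True)
class ResidueMapping:
    name: str
    sites: tuple            # SiteDefinition, sidechain only (local indices 1..n)
    bonds: tuple            # intra-residue (local_i, local_j), 0 = backbone
    improper: tuple | None = None

    @property
    def n_sites(self):
        return 1 + len(self.sites)


class MappingScheme:
    """Per-residue grouping of heavy atoms into typed CG sites."""

    def __init__(self, residues: dict, include_hydrogen_mass: bool = True):
        self.residues = residues
        self.include_hydrogen_mass = include_hydrogen_mass
        self.validate()

    def __getitem__(self, resname: str) -> ResidueMapping:
        try:
            return self.residues[resname]
        except KeyError:
            raise MappingError(f"residue {resname!r} not in mapping scheme")

    def __contains__(self, resname):
        return resname in self.residues

    def validate(self):
        for name, rm in self.residues.items():
            if len(rm.sites) > 4:
                raise MappingError(f"{name}: more than 4 sidechain sites")
            claimed = []
            for sd in rm.sites:
                claimed.extend(sd.atoms)
            if len(claimed) != len(set(claimed)):
                raise MappingError(f"{name}: atom claimed by more than one site")
            if "CA" in claimed:
                raise MappingError(f"{name}: CA belongs to the backbone site")
            n = rm.n_sites
            for i, j in rm.bonds:
                if not (0 <= i < n and 0 <= j < n) or i == j:
                    raise MappingError(f"{name}: bad intra-residue bond ({i},{j})")

    @classmethod
    def from_yaml(cls, path_or_stream, **kw) -> "MappingScheme":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        residues = {}
        for name, block in raw.items():
            sites = tuple(
                SiteDefinition(s["type"], tuple(s["atoms"]), int(s.get("hydrogens", 0)))
                for s in block.get("sites", [])
            )
            if "bonds" in block:
                bonds = tuple((int(i), int(j)) for i, j in block["bonds"])
            else:
                bonds = tuple((k, k + 1) for k in range(len(sites)))
            improper = tuple(block["improper"]) if "improper" in block else None
            residues[name] = ResidueMapping(name, sites, bonds, improper)
        return cls(residues, **kw)

    @classmethod
    def default(cls, **kw) -> "MappingScheme":
        ref = resources.files("cgfold.data").joinpath("mapping.yaml")
        with ref.open() as fh:
            return cls.from_yaml(fh, **kw)

    def site_mass(self, resname: str, local_index: int, elements=None) -> float:
        """Mass of a site: member heavy atoms plus (optionally) implicit H."""
        rm = self[resname]
        if local_index == 0:
            mass = CA_MASS
            n_h = 2 if resname == "GLY" else 1
        else:
            sd = rm.sites[local_index - 1]
            if elements:
                mass = sum(element_mass(elements.get(a, a[0])) for a in sd.atoms)
            else:
                mass = sum(element_mass(_element_from_name(a)) for a in sd.atoms)
            n_h = sd.hydrogens
        if self.include_hydrogen_mass:
            mass += n_h * H_MASS
        return mass


def _element_from_name(atom_name: str) -> str:
    if atom_name[:2] in ("SD", "SG"):
        return "S"
    return atom_name[0]


@dataclass
class CGSite:
    site_id: int
    residue_index: int      # 1-based
    residue_name: str
    local_index: int        # 0 = backbone, 1.. = sidechain
    site_type: str
    mass: float             # amu
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))  # nm
    atoms: tuple = ()       # member heavy-atom names

    def to_dict(self):
        return {
            "site_id": self.site_id, "residue_index": self.residue_index,
            "residue_name": self.residue_name, "local_index": self.local_index,
            "site_type": self.site_type, "mass": round(self.mass, 6),
            "atoms": list(self.atoms),
        }


@dataclass(frozen=True)
class Angle:
    i: int
    j: int
    k: int
    tag: str                # backbone | to_previous | to_next | sidechain_internal
    key: str


@dataclass(frozen=True)
class Torsion:
    i: int
    j: int
    k: int
    l: int
    key: tuple              # middle-residue-pair names
    tag: str = "backbone"


@dataclass(frozen=True)
class Improper:
    i: int
    j: int
    k: int
    l: int
    key: str


class CGTopology:
    """Sites, bonded terms and the nonbonded exclusion rule for one chain."""

    def __init__(self, sites, bonds, bond_keys, angles, torsions, impropers,
                 min_separation: int = 3):
        self.sites = list(sites)
        self.bonds = list(bonds)
        self.bond_keys = list(bond_keys)
        self.angles = list(angles)
        self.torsions = list(torsions)
        self.impropers = list(impropers)
        self.min_separation = int(min_separation)
        self._excl = None

    @property
    def n_sites(self):
        return len(self.sites)

    def masses(self):
        return np.array([s.mass for s in self.sites])

    def site_types(self):
        return [s.site_type for s in self.sites]

    def backbone_ids(self):
        return [s.site_id for s in self.sites if s.site_type == "backbone"]

    def bond_graph(self):
        adj = {i: set() for i in range(self.n_sites)}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def bond_separations(self, max_depth: int) -> dict:
        """Shortest bond-path length for all pairs up to max_depth (BFS)."""
        adj = self.bond_graph()
        sep = {}
        for src in range(self.n_sites):
            dist = {src: 0}
            q = deque([src])
            while q:
                u = q.popleft()
                if dist[u] >= max_depth:
                    continue
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            for v, d in dist.items():
                if v > src:
                    sep[(src, v)] = d
        return sep

    def exclusion_pairs(self) -> set:
        """Pairs with bond separation < min_separation (1-2, 1-3 by default)."""
        if self._excl is None:
            sep = self.bond_separations(self.min_separation - 1)
            self._excl = {p for p, d in sep.items() if d < self.min_separation}
        return self._excl

    # --- serialization -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "min_separation": self.min_separation,
            "sites": [s.to_dict() for s in self.sites],
            "bonds": [[i, j, k] for (i, j), k in zip(self.bonds, self.bond_keys)],
            "angles": [[a.i, a.j, a.k, a.tag, a.key] for a in self.angles],
            "torsions": [[t.i, t.j, t.k, t.l, list(t.key), t.tag] for t in self.torsions],
            "impropers": [[m.i, m.j, m.k, m.l, m.key] for m in self.impropers],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CGTopology":
        doc = json.loads(text)
        sites = [CGSite(site_id=d["site_id"], residue_index=d["residue_index"],
                        residue_name=d["residue_name"], local_index=d["local_index"],
                        site_type=d["site_type"], mass=d["mass"],
                        atoms=tuple(d["atoms"])) for d in doc["sites"]]
        sites.sort(key=lambda s: s.site_id)
        bonds = [(b[0], b[1]) for b in doc["bonds"]]
        bond_keys = [b[2] for b in doc["bonds"]]
        angles = [Angle(*a[:3], tag=a[3], key=a[4]) for a in doc["angles"]]
        torsions = [Torsion(*t[:4], key=tuple(t[4]), tag=t[5]) for t in doc["torsions"]]
        impropers = [Improper(*m[:4], key=m[4]) for m in doc["impropers"]]
        return cls(sites, bonds, bond_keys, angles, torsions, impropers,
                   doc["min_separation"])


def build_topology(sequence: Sequence[str], scheme: MappingScheme,
                   min_separation: int = 3) -> CGTopology:
    """Build the bonded topology for a linear chain of residue names."""
    if not sequence:
        raise MappingError("empty sequence")
    sites = []
    site_id = 0
    bb = []           # backbone site id per residue
    local_of = []     # residue -> {local_index: site_id}
    for ri, resname in enumerate(sequence, start=1):
        rm = scheme[resname]
        ids = {}
        for li in range(rm.n_sites):
            stype = "backbone" if li == 0 else rm.sites[li - 1].site_type
            atoms = ("CA",) if li == 0 else rm.sites[li - 1].atoms
            sites.append(CGSite(site_id=site_id, residue_index=ri, residue_name=resname,
                                local_index=li, site_type=stype,
                                mass=scheme.site_mass(resname, li), atoms=atoms))
            ids[li] = site_id
            site_id += 1
        bb.append(ids[0])
        local_of.append(ids)

    bonds, bond_keys = [], []
    for ri in range(len(sequence) - 1):
        bonds.append((bb[ri], bb[ri + 1]))
        bond_keys.append("BB-BB")
    for ri, resname in enumerate(sequence):
        rm = scheme[resname]
        for (li, lj) in rm.bonds:
            bonds.append((local_of[ri][li], local_of[ri][lj]))
            bond_keys.append(f"{resname}:{li}-{lj}")

    n = len(sequence)
    angles = []
    for ri in range(1, n - 1):
        angles.append(Angle(bb[ri - 1], bb[ri], bb[ri + 1], "backbone", "BB"))
    # sidechain sites bonded directly to the backbone: i-1 and i+1 triples
    intra_adj = [dict() for _ in sequence]
    for ri, resname in enumerate(sequence):
        rm = scheme[resname]
        adj = {li: set() for li in range(rm.n_sites)}
        for (li, lj) in rm.bonds:
            adj[li].add(lj)
            adj[lj].add(li)
        intra_adj[ri] = adj
    for ri, resname in enumerate(sequence):
        for sc in sorted(intra_adj[ri].get(0, ())):
            s = local_of[ri][sc]
            if ri > 0:
                angles.append(Angle(bb[ri - 1], bb[ri], s, "to_previous",
                                    f"{resname}:{sc}:prev"))
            if ri < n - 1:
                angles.append(Angle(s, bb[ri], bb[ri + 1], "to_next",
                                    f"{resname}:{sc}:next"))
        # angles internal to the sidechain (centre on a sidechain site)
        adj = intra_adj[ri]
        for centre in sorted(adj):
            if centre == 0:
                continue
            nbrs = sorted(adj[centre])
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    angles.append(Angle(local_of[ri][nbrs[a]], local_of[ri][centre],
                                        local_of[ri][nbrs[b]], "sidechain_internal",
                                        f"{resname}:{nbrs[a]}-{centre}-{nbrs[b]}"))

    torsions = []
    for ri in range(n - 3):
        torsions.append(Torsion(bb[ri], bb[ri + 1], bb[ri + 2], bb[ri + 3],
                                key=(sequence[ri + 1], sequence[ri + 2])))

    impropers = []
    for ri, resname in enumerate(sequence):
        rm = scheme[resname]
        if rm.improper is not None:
            ids = [local_of[ri][li] for li in rm.improper]
            impropers.append(Improper(*ids, key=f"{resname}:improper"))

    return CGTopology(sites, bonds, bond_keys, angles, torsions, impropers,
                      min_separation=min_separation)


class AtomToSiteMap:
    """Resolved atom->site assignment for one structure."""

    def __init__(self, entries, n_sites, n_atoms):
        self.entries = entries          # list of (atom_flat_index, site_id)
        self.n_sites = n_sites
        self.n_atoms = n_atoms

    def map_forces(self, atom_forces: np.ndarray) -> np.ndarray:
        """Sum per-atom force vectors into per-site vectors (linear map)."""
        atom_forces = np.asarray(atom_forces, dtype=float)
        if atom_forces.shape != (self.n_atoms, 3):
            raise MappingError(
                f"force array shape {atom_forces.shape} != ({self.n_atoms}, 3)")
        out = np.zeros((self.n_sites, 3))
        for ai, si in self.entries:
            out[si] += atom_forces[ai]
        return out


def map_structure(structure, scheme: MappingScheme, skip_incomplete_sites=False):
    """Map an atomistic structure to CG sites.

    Returns (sites, atom_map): the backbone site sits exactly on the CA atom,
    each sidechain site at the unweighted mass centre of its member heavy
    atoms.  Coordinates are converted Angstrom -> nm.  atom_map indexes atoms
    by their flat order of appearance (residue order, then the residue's atom
    dict order) and maps the CA atom alone to the backbone site.
    """
    sites = []
    entries = []
    site_id = 0
    atom_flat = {}
    flat = 0
    for res in structure.residues:
        for name in res.atoms:
            atom_flat[(res.index, name)] = flat
            flat += 1
    for res in structure.residues:
        rm = scheme[res.name]
        if "CA" not in res.atoms:
            raise MappingError(f"residue {res.name} {res.index}: no CA atom")
        pos = np.asarray(res.atoms["CA"]) * NM_PER_A
        sites.append(CGSite(site_id, res.index, res.name, 0, "backbone",
                            scheme.site_mass(res.name, 0), pos, ("CA",)))
        entries.append((atom_flat[(res.index, "CA")], site_id))
        site_id += 1
        for li, sd in enumerate(rm.sites, start=1):
            missing = [a for a in sd.atoms if a not in res.atoms]
            if missing:
                if skip_incomplete_sites:
                    continue
                raise MappingError(
                    f"residue {res.name} {res.index}: missing atoms {missing}")
            coords = np.array([res.atoms[a] for a in sd.atoms]) * NM_PER_A
            masses = np.array([element_mass(res.elements.get(a, _element_from_name(a)))
                               for a in sd.atoms])
            com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
            sites.append(CGSite(site_id, res.index, res.name, li, sd.site_type,
                                scheme.site_mass(res.name, li, res.elements),
                                com, sd.atoms))
            for a in sd.atoms:
                entries.append((atom_flat[(res.index, a)], site_id))
            site_id += 1
    atom_map = AtomToSiteMap(entries, site_id, flat)
    return sites, atom_map


def map_forces(atom_forces, atom_map: AtomToSiteMap) -> np.ndarray:
    return atom_map.map_forces(atom_forces)


def topology_from_structure(structure, scheme: MappingScheme,
                            min_separation: int = 3,
                            skip_incomplete_sites: bool = False):
    """Topology + mapped positions for a structure; returns (topology, X nm).

    With skip_incomplete_sites the topology is rebuilt to contain only the
    sites actually mapped, so positions and topology stay congruent.
    """
    sites, _ = map_structure(structure, scheme,
                             skip_incomplete_sites=skip_incomplete_sites)
    topo = build_topology(structure.sequence(), scheme, min_separation)
    if len(sites) != topo.n_sites:
        present = {(s.residue_index, s.local_index) for s in sites}
        topo = _prune_topology(topo, present)
    pos_of = {(s.residue_index, s.local_index): s.position for s in sites}
    X = np.array([pos_of[(s.residue_index, s.local_index)] for s in topo.sites])
    return topo, X


def _prune_topology(topo: CGTopology, present: set) -> CGTopology:
    keep = [s for s in topo.sites if (s.residue_index, s.local_index) in present]
    old_to_new = {}
    new_sites = []
    for new_id, s in enumerate(keep):
        old_to_new[s.site_id] = new_id
        new_sites.append(CGSite(new_id, s.residue_index, s.residue_name,
                                s.local_index, s.site_type, s.mass,
                                s.position, s.atoms))
    def ok(*ids):
        return all(i in old_to_new for i in ids)
    bonds, keys = [], []
    for (i, j), k in zip(topo.bonds, topo.bond_keys):
        if ok(i, j):
            bonds.append((old_to_new[i], old_to_new[j]))
            keys.append(k)
    angles = [Angle(old_to_new[a.i], old_to_new[a.j], old_to_new[a.k], a.tag, a.key)
              for a in topo.angles if ok(a.i, a.j, a.k)]
    torsions = [Torsion(old_to_new[t.i], old_to_new[t.j], old_to_new[t.k],
                        old_to_new[t.l], t.key, t.tag)
                for t in topo.torsions if ok(t.i, t.j, t.k, t.l)]
    impropers = [Improper(old_to_new[m.i], old_to_new[m.j], old_to_new[m.k],
                          old_to_new[m.l], m.key)
                 for m in topo.impropers if ok(m.i, m.j, m.k, m.l)]
    return CGTopology(new_sites, bonds, keys, angles, torsions, impropers,
                      topo.min_separation)
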