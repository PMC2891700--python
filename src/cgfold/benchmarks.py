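"""Benchmark quantities recomputed from shipped data.

Each function runs the full pipeline path for one headline number: table
combinatorics and minima from the pair-parameter file, CG mapping counts for
the Trpzip-sequence model, and the AdK open/closed structural coordinates.

The shipped AdK structures derive from the 4AKE (open) and 1AKE (closed)
crystal structures; the Trpzip structure is an all-atom model built from the
Trpzip2 sequence (12 residues).
"""

from __future__ import annotations

import numpy as np

from . import analysis
from .fixtures import adk_domain_indices, load_structure, table2_forcefield
from .mapping import MappingScheme, topology_from_structure
from .forcematch import pair_key


def count_softcore_tables() -> int:
    pots, _ = table2_forcefield()
    return len(pots)


def softcore_depth_kjmol(type_a: str, type_b: str) -> float:
    """Magnitude of the pre-shift potential minimum for a pair table."""
    pots, _ = table2_forcefield()
    pot = pots[pair_key(type_a, type_b)]
    _, v_at = pot.argmin()
    return -(v_at + pot.shift)


def softcore_argmin_angstrom(type_a: str, type_b: str) -> float:
    pots, _ = table2_forcefield()
    r_at, _ = pots[pair_key(type_a, type_b)].argmin()
    return r_at * 10.0


def trpzip_backbone_site_count(scheme: MappingScheme | None = None) -> int:
    scheme = scheme or MappingScheme.default()
    from .mapping import map_structure
    sites, _ = map_structure(load_structure("trpzip2"), scheme)
    return sum(1 for s in sites if s.site_type == "backbone")


def _adk_common_cg():
    """CG-map both AdK forms over their common site set.

    Returns (open X, closed X, backbone indices, site keys) with rows aligned
    across the two structures.
    """
    scheme = MappingScheme.default()
    topo_o, Xo = topology_from_structure(load_structure("adk_open"), scheme,
                                         skip_incomplete_sites=True)
    topo_c, Xc = topology_from_structure(load_structure("adk_closed"), scheme,
                                         skip_incomplete_sites=True)
    ko = {(s.residue_index, s.local_index): s.site_id for s in topo_o.sites}
    kc = {(s.residue_index, s.local_index): s.site_id for s in topo_c.sites}
    common = sorted(set(ko) & set(kc))
    A = Xo[[ko[k] for k in common]]
    B = Xc[[kc[k] for k in common]]
    bb = [n for n, k in enumerate(common) if k[1] == 0]
    return A, B, bb, common, topo_o, ko


def adk_delta_d_rmsd_open() -> float:
    """Delta-D_RMSD of the open structure against open/closed references,
    over all CG sites after backbone superposition (Angstrom)."""
    A, B, bb, _, _, _ = _adk_common_cg()
    return analysis.delta_d_rmsd(A, A, B, fit_idx=bb)


def adk_delta_d_rmsd_closed() -> float:
    A, B, bb, _, _, _ = _adk_common_cg()
    return analysis.delta_d_rmsd(B, A, B, fit_idx=bb)


def adk_domain_rmsds() -> dict:
    """Per-domain backbone RMSD between open and closed forms, each domain
    independently superimposed (Angstrom)."""
    A, B, bb, common, topo_o, ko = _adk_common_cg()
    doms = adk_domain_indices(topo_o)
    out = {}
    for name, ids in doms.items():
        idset = set(ids)
        sel = [n for n, k in enumerate(common)
               if ko[k] in idset and k[1] == 0]
        out[name] = analysis.rmsd(A, B, fit_idx=sel, measure_idx=sel)
    return out
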