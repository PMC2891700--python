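"""Folding-landscape observables.

Heat capacity from potential-energy fluctuations per ladder temperature,
the transition temperature from its maximum (and the 0.6 multiple used for
native-state runs), Kabsch RMSD with separate fit/measure selections, the
open-minus-closed Delta-D_RMSD coordinate, radius of gyration (optionally
relative to the native value), and the nonbonded C-alpha RDF.

RMSD values are reported in Angstrom at the interface; coordinates come in
as nm (internal units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import KB, A_PER_NM
from .forcematch import minimum_image


class AnalysisError(ValueError):
    pass


# ----------------------------------------------------------------------
# heat capacity

@dataclass
class HeatCapacityCurve:
    temperatures: np.ndarray
    cv: np.ndarray                  # kJ/mol/K
    stderr: np.ndarray
    t_transition: float             # argmax temperature
    tie: bool = False
    tied_temperatures: tuple = ()


def heat_capacity(energy_series, temperatures, discard_fraction: float = 0.2,
                  n_blocks: int = 5, min_samples: int = 100) -> HeatCapacityCurve:
    """C_v(T) = (<U^2> - <U>^2) / (k_B T^2) per temperature.

    energy_series: one potential-energy sequence per ladder temperature.
    Uncertainty is estimated by block averaging over n_blocks blocks.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if len(energy_series) != len(temperatures):
        raise AnalysisError("one energy series per temperature required")
    cv = np.zeros(len(temperatures))
    err = np.zeros(len(temperatures))
    for k, (series, T) in enumerate(zip(energy_series, temperatures)):
        u = np.asarray(series, dtype=float)
        u = u[int(len(u) * discard_fraction):]
        if len(u) < min_samples:
            raise AnalysisError(
                f"temperature {T:g} K: {len(u)} samples < {min_samples}")
        cv[k] = u.var() / (KB * T ** 2)
        blocks = np.array_split(u, n_blocks)
        bvals = np.array([b.var() / (KB * T ** 2) for b in blocks if len(b) > 1])
        err[k] = bvals.std(ddof=1) / np.sqrt(len(bvals)) if len(bvals) > 1 else 0.0
    imax = int(np.argmax(cv))
    ties = np.where(np.isclose(cv, cv[imax], rtol=0, atol=1e-12))[0]
    return HeatCapacityCurve(temperatures, cv, err,
                             float(temperatures[imax]),
                             tie=len(ties) > 1,
                             tied_temperatures=tuple(temperatures[ties]))


def reference_temperature(curve: HeatCapacityCurve):
    """(T_transition, 0.6 * T_transition); raises on a tied maximum."""
    if curve.tie:
        raise AnalysisError(
            f"no unique heat-capacity maximum: ties at {curve.tied_temperatures}")
    return curve.t_transition, 0.6 * curve.t_transition


# ----------------------------------------------------------------------
# superposition / RMSD

def kabsch_rotation(P, Q):
    """Proper rotation (det +1) minimising |R P - Q| for centred P, Q."""
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile, reference, fit_idx=None):
    """Return mobile coordinates rigidly fitted onto reference."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise AnalysisError("selection mismatch between structures")
    idx = np.arange(len(mobile)) if fit_idx is None else np.asarray(fit_idx)
    if len(idx) < 3:
        raise AnalysisError("need at least 3 fit sites")
    cm = mobile[idx].mean(axis=0)
    cr = reference[idx].mean(axis=0)
    R = kabsch_rotation(mobile[idx] - cm, reference[idx] - cr)
    return (mobile - cm) @ R.T + cr


def rmsd(conformation, reference, fit_idx=None, measure_idx=None,
         in_angstrom: bool = True) -> float:
    """Kabsch RMSD: superpose on fit_idx, measure over measure_idx."""
    fitted = superpose(conformation, reference, fit_idx)
    reference = np.asarray(reference, dtype=float)
    m = np.arange(len(fitted)) if measure_idx is None else np.asarray(measure_idx)
    d = fitted[m] - reference[m]
    val = float(np.sqrt((d ** 2).sum(axis=1).mean()))
    return val * A_PER_NM if in_angstrom else val


def delta_d_rmsd(conformation, open_ref, closed_ref, fit_idx=None,
                 measure_idx=None) -> float:
    """RMSD(conf, open) - RMSD(conf, closed), Angstrom; negative = open-like."""
    return (rmsd(conformation, open_ref, fit_idx, measure_idx)
            - rmsd(conformation, closed_ref, fit_idx, measure_idx))


def radius_of_gyration(positions, masses=None, native_rg: float | None = None):
    """Mass-weighted Rg (nm), or the ratio to a native Rg when given."""
    X = np.asarray(positions, dtype=float)
    if X.ndim != 2 or len(X) < 1:
        raise AnalysisError("need at least one site")
    m = np.ones(len(X)) if masses is None else np.asarray(masses, dtype=float)
    if m.sum() <= 0:
        raise AnalysisError("zero total mass")
    com = (X * m[:, None]).sum(axis=0) / m.sum()
    rg = np.sqrt((m * ((X - com) ** 2).sum(axis=1)).sum() / m.sum())
    return float(rg / native_rg) if native_rg else float(rg)


# ----------------------------------------------------------------------
# nonbonded C-alpha RDF

@dataclass
class RdfResult:
    r: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    n_pairs: int
    n_frames: int


def rdf_nonbonded_ca(frames, topology=None, molecule_of=None, bins=None,
                     r_max: float = 2.0, box=None,
                     backbone_idx=None) -> RdfResult:
    """RDF over C-alpha pairs separated by >= 3 bonds plus all
    intermolecular pairs; shell-volume (and, with a box, density) normalised.

    frames: iterable of (n, 3) coordinate arrays.
    molecule_of: per-site molecule id (all intramolecular when omitted).
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise AnalysisError("no frames")
    n = frames[0].shape[0]
    if topology is not None:
        bb = np.asarray(topology.backbone_ids())
        sep = topology.bond_separations(2)
        near = {p for p, d in sep.items() if d < 3}
    else:
        bb = np.arange(n) if backbone_idx is None else np.asarray(backbone_idx)
        near = set()
    mol = np.zeros(n, dtype=int) if molecule_of is None else np.asarray(molecule_of)
    ii, jj = [], []
    for a in range(len(bb)):
        for b in range(a + 1, len(bb)):
            i, j = int(bb[a]), int(bb[b])
            if mol[i] == mol[j] and (min(i, j), max(i, j)) in near:
                continue
            ii.append(i)
            jj.append(j)
    if not ii:
        raise AnalysisError("no eligible pairs")
    ii = np.array(ii)
    jj = np.array(jj)
    if bins is None:
        bins = np.linspace(0.0, r_max, 101)
    bins = np.asarray(bins, dtype=float)
    counts = np.zeros(len(bins) - 1)
    for X in frames:
        dx = minimum_image(X[ii] - X[jj], None if box is None else np.asarray(box))
        r = np.linalg.norm(dx, axis=1)
        c, _ = np.histogram(r, bins=bins)
        counts += c
    centers = 0.5 * (bins[:-1] + bins[1:])
    shell = 4.0 / 3.0 * np.pi * (bins[1:] ** 3 - bins[:-1] ** 3)
    if box is not None:
        volume = float(np.prod(box))
        ideal = len(ii) * shell / volume
        g = counts / (len(frames) * ideal)
    else:
        g = counts / (len(frames) * len(ii) * shell)   # shell-normalised only
    return RdfResult(centers, g, counts, len(ii), len(frames))


# ----------------------------------------------------------------------
# TSV emitters

def write_series_tsv(path_or_stream, columns: dict):
    names = list(columns)
    arrays = [np.asarray(columns[c]) for c in names]
    lines = ["\t".join(names)]
    for row in zip(*arrays):
        lines.append("\t".join(f"{v:.8g}" for v in row))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)
    return text
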