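"""Tabulated pair potentials.

Force curves are integrated to energies, smoothed with a cubic B-spline,
optionally switched linearly to zero over a distance window, and written as
(r, V, f) text tables.  A soft-core Mie(9,6) builder produces stand-in
tables from (r_min, epsilon) pair-minimum parameters: the 9-6 form keeps the
minimum location and depth of the 12-6 form with a gentler core.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .forcematch import ForceCurve, pair_key

DEFAULT_CUTOFF = 1.2        # nm, MD cutoff (distinct from the 2 nm FM range)
DEFAULT_GRID_START = 0.04   # nm
DEFAULT_GRID_STEP = 0.002   # nm

SITE_TYPES = ("backbone", "apolar", "polar", "positive", "negative")


class TableError(ValueError):
    pass


@dataclass
class TabulatedPairPotential:
    key: tuple                  # unordered pair-type key
    r: np.ndarray               # nm, ascending, last point = cutoff
    V: np.ndarray               # kJ/mol, V(cutoff) = 0
    f: np.ndarray               # -dV/dr, kJ/mol/nm
    provenance: str = "user"    # force-matched | softcore-analytic | user
    shift: float = 0.0          # constant subtracted to put V(cutoff)=0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if not (len(self.r) == len(self.V) == len(self.f)):
            raise TableError("grid/V/f length mismatch")

    @property
    def cutoff(self):
        return float(self.r[-1])

    def argmin(self):
        i = int(np.argmin(self.V))
        return float(self.r[i]), float(self.V[i])

    def check_consistency(self, r_from: float = 0.3):
        """f vs -dV/dr by interior central differences, relative to max|f|.

        Checked from r_from outward: inside the r^-10 core the h^2/r^2
        truncation error of central differences exceeds any useful tolerance
        on this grid, and that region sits above the capped inner wall that
        simulations never sample (the smallest pair minimum is 0.32 nm).
        """
        h = float(np.diff(self.r).mean())
        if not np.allclose(np.diff(self.r), h, rtol=1e-3):
            dv = (self.V[2:] - self.V[:-2]) / (self.r[2:] - self.r[:-2])
            inner = slice(1, -1)
        else:
            # 4th-order central difference: truncation ~ h^4 V^(5)/30
            V = self.V
            dv = (V[:-4] - 8 * V[1:-3] + 8 * V[3:-1] - V[4:]) / (12 * h)
            inner = slice(2, -2)
        mask = self.r[inner] >= r_from
        scale = np.abs(self.f[inner][mask]).max() or 1.0
        return float(np.abs(self.f[inner] + dv)[mask].max() / scale)


def integrate_force_curve(curve: ForceCurve, cutoff: float = DEFAULT_CUTOFF,
                          key=None) -> TabulatedPairPotential:
    """V(r) = integral_r^cutoff f(s) ds (trapezoid on the knot grid)."""
    sampled = curve.sampled
    if not sampled.any():
        raise TableError("empty force curve")
    first = int(np.argmax(sampled))
    r_all = curve.knots
    if r_all[sampled].max() < cutoff:
        raise TableError(f"curve sampled only to {r_all[sampled].max():g} nm "
                         f"< cutoff {cutoff:g} nm")
    # require contiguous support from the first sampled knot to the cutoff
    upto = np.searchsorted(r_all, cutoff, side="right")
    gap = np.where(~sampled[first:upto])[0]
    if gap.size:
        raise TableError(
            f"unsampled interior knots at r={r_all[first + gap[:5]]} nm")
    r = r_all[first:upto]
    f = curve.values[first:upto]
    if r[-1] < cutoff:
        # cutoff falls between knots: close the grid with a linearly
        # interpolated force value (requires the bracketing knot sampled)
        if upto >= len(r_all) or not sampled[upto]:
            raise TableError("cutoff beyond the last sampled knot")
        t = (cutoff - r_all[upto - 1]) / (r_all[upto] - r_all[upto - 1])
        r = np.append(r, cutoff)
        f = np.append(f, (1 - t) * curve.values[upto - 1] + t * curve.values[upto])
    # integrate inward from the cutoff
    segments = 0.5 * (f[1:] + f[:-1]) * np.diff(r)
    V = np.concatenate([np.cumsum(segments[::-1])[::-1], [0.0]])
    return TabulatedPairPotential(key or curve.key, r, V, f,
                                  provenance="force-matched")


def smooth_bspline(pot: TabulatedPairPotential,
                   lam: float | None = None) -> TabulatedPairPotential:
    """Cubic smoothing-spline fit of V; f is the exact negative spline
    derivative, so the output is internally consistent."""
    if len(pot.r) < 8:
        raise TableError("need at least 8 grid points to smooth")
    spl = make_smoothing_spline(pot.r, pot.V, lam=lam)
    V = spl(pot.r)
    f = -spl.derivative()(pot.r)
    V = V - V[-1]   # re-pin V(cutoff) = 0
    return TabulatedPairPotential(pot.key, pot.r.copy(), V, f,
                                  provenance=pot.provenance, shift=pot.shift,
                                  meta=dict(pot.meta, smoothed=True))


def apply_linear_switch(pot: TabulatedPairPotential, r_on: float = 1.0,
                        r_off: float = 1.2) -> TabulatedPairPotential:
    """Multiply V by a linear switch s(r): 1 below r_on, 0 above r_off.

    The force is recomputed by the product rule
    f' = s*f + V*ds/dr-with-sign, keeping f' = -d(sV)/dr exactly.
    """
    if not r_on < r_off <= pot.cutoff + 1e-12:
        raise TableError("need r_on < r_off <= cutoff")
    r = pot.r
    s = np.clip((r_off - r) / (r_off - r_on), 0.0, 1.0)
    ds = np.where((r > r_on) & (r < r_off), -1.0 / (r_off - r_on), 0.0)
    V = pot.V * s
    f = pot.f * s - pot.V * ds      # f = -dV/dr => -(s V)' = s f - V s'
    return TabulatedPairPotential(pot.key, r.copy(), V, f,
                                  provenance=pot.provenance, shift=pot.shift,
                                  meta=dict(pot.meta, switch=(r_on, r_off)))


@dataclass(frozen=True)
class PairMinimum:
    key: tuple
    r_min: float            # Angstrom (as printed in the parameter file)
    epsilon: float          # kJ/mol
    repulsive_only: bool = False

    def __post_init__(self):
        if self.r_min <= 0:
            raise TableError("r_min must be positive")
        if self.epsilon < 0:
            raise TableError("epsilon must be non-negative")


def read_pair_minima(path_or_stream=None) -> dict:
    """Read the pair-minima parameter file (defaults to the shipped one)."""
    if path_or_stream is None:
        ref = resources.files("cgfold.data").joinpath("pair_minima.tsv")
        text = ref.read_text()
    elif hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
    else:
        with open(path_or_stream) as fh:
            text = fh.read()
    out = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise TableError(f"pair-minima line {ln}: expected 4 fields, "
                             f"got {line!r}")
        a, b = parts[0].split("-")
        key = pair_key(a, b)
        out[key] = PairMinimum(key, float(parts[1]), float(parts[2]),
                               bool(int(parts[3])))
    return out


def mie96(r_nm, r_min_nm: float, epsilon: float):
    """Mie(9,6): V(r) = eps * [2 (r_min/r)^9 - 3 (r_min/r)^6]; min (r_min, -eps)."""
    x = r_min_nm / np.asarray(r_nm, dtype=float)
    return epsilon * (2.0 * x ** 9 - 3.0 * x ** 6)


def mie96_force(r_nm, r_min_nm: float, epsilon: float):
    """-dV/dr for the Mie(9,6) form."""
    r = np.asarray(r_nm, dtype=float)
    x = r_min_nm / r
    return epsilon * (18.0 * x ** 9 - 18.0 * x ** 6) / r


def build_softcore(minima: dict, cutoff: float = DEFAULT_CUTOFF,
                   grid_start: float = DEFAULT_GRID_START,
                   grid_step: float = DEFAULT_GRID_STEP,
                   switch_like_charges: bool = True) -> dict:
    """Build the 15 soft-core stand-in tables from pair-minimum parameters.

    Tables are cutoff-shifted so V(cutoff) = 0; the applied shift is stored.
    positive-positive and negative-negative tables get the 1.0-1.2 nm linear
    switch on top of the shift.
    """
    required = {pair_key(a, b) for i, a in enumerate(SITE_TYPES)
                for b in SITE_TYPES[i:]}
    missing = required - set(minima)
    if missing:
        raise TableError(f"missing pair parameters: {sorted(missing)}")
    n = int(round((cutoff - grid_start) / grid_step))
    r = grid_start + grid_step * np.arange(n + 1)
    r[-1] = cutoff
    out = {}
    for key in sorted(required):
        pm = minima[key]
        r_min_nm = pm.r_min * 0.1
        shift = float(mie96(cutoff, r_min_nm, pm.epsilon))
        V = mie96(r, r_min_nm, pm.epsilon) - shift
        f = mie96_force(r, r_min_nm, pm.epsilon)
        pot = TabulatedPairPotential(
            key, r.copy(), V, f, provenance="softcore-analytic", shift=shift,
            meta={"r_min_A": pm.r_min, "epsilon": pm.epsilon,
                  "repulsive_only": pm.repulsive_only})
        if switch_like_charges and key in (("positive", "positive"),
                                           ("negative", "negative")):
            pot = apply_linear_switch(pot, 1.0, min(1.2, cutoff))
        out[key] = pot
    return out


def switch_error(pot_unswitched: TabulatedPairPotential,
                 pot_switched: TabulatedPairPotential,
                 r_on: float = 1.0, r_off: float = 1.2) -> float:
    """Max |V_switched - V_unswitched| over the switching region (reported)."""
    m = (pot_unswitched.r >= r_on) & (pot_unswitched.r <= r_off)
    return float(np.abs(pot_switched.V[m] - pot_unswitched.V[m]).max())


# --- table file I/O ----------------------------------------------------

def write_table(pot: TabulatedPairPotential, path_or_stream,
                dialect: str = "native"):
    if dialect == "native":
        out = io.StringIO()
        out.write(f"# pair={pot.key[0]}-{pot.key[1]} provenance={pot.provenance} "
                  f"cutoff={pot.cutoff:.6g} shift={pot.shift:.10g}\n")
        out.write("# r_nm\tV_kJmol\tf_kJmolnm\n")
        for r, v, f in zip(pot.r, pot.V, pot.f):
            out.write(f"{r:.17g}\t{v:.17g}\t{f:.17g}\n")
        text = out.getvalue()
    elif dialect == "gromacs":
        # xvg-style 7-column layout: r  1/r(placeholder 0)  0  V  f  0  0
        out = io.StringIO()
        out.write(f"# GROMACS-style table for {pot.key[0]}-{pot.key[1]}\n")
        for r, v, f in zip(pot.r, pot.V, pot.f):
            out.write(f"{r:12.6f} {0.0:14.6e} {0.0:14.6e} "
                      f"{v:14.6e} {f:14.6e} {0.0:14.6e} {0.0:14.6e}\n")
        text = out.getvalue()
    else:
        raise TableError(f"unknown dialect {dialect!r}")
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)
    return text


def read_table(path_or_stream, dialect: str = "native") -> TabulatedPairPotential:
    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
    else:
        with open(path_or_stream) as fh:
            text = fh.read()
    header = {}
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(("#", "@")):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    header[k] = v
            continue
        parts = line.split()
        want = 3 if dialect == "native" else 7
        if len(parts) != want:
            raise TableError(f"line {ln}: expected {want} columns, got "
                             f"{len(parts)}")
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise TableError(f"line {ln}: non-numeric field in {line!r}")
        if dialect == "native":
            rows.append(vals)
        else:
            rows.append([vals[0], vals[3], vals[4]])
    if not rows:
        raise TableError("no data rows")
    arr = np.asarray(rows)
    key = tuple(sorted(header.get("pair", "X-X").split("-")))
    return TabulatedPairPotential(key, arr[:, 0], arr[:, 1], arr[:, 2],
                                  provenance=header.get("provenance", "user"),
                                  shift=float(header.get("shift", 0.0)))
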