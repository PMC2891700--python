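"""Bonded potentials from coordinate distributions.

Bond, angle and torsion potentials are obtained by Boltzmann inversion of
observed coordinate histograms with the appropriate volume normalisation
(r^2 for bonds, sin(theta) for angles, none for torsions), then fit to
harmonic/quartic polynomials or periodic cosine series.  A sequence-keyed
torsion library applies a global scale factor (default 0.54) to every entry.

Conventions: bond grids in nm, angle/torsion grids in degrees, energies in
kJ/mol.  All inverted potentials are shifted so their minimum is zero.
Zero-count bins are "unsupported" and excluded from fits (no pseudo-counts).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .units import KB

DEFAULT_BIN_WIDTHS = {"bond": 0.002, "angle": 2.0, "torsion": 5.0}

_STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class InversionError(ValueError):
    pass


@dataclass
class CoordinateHistogram:
    kind: str               # bond | angle | torsion
    edges: np.ndarray       # nm or degrees, contiguous ascending
    counts: np.ndarray
    temperature: float      # K

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.kind not in ("bond", "angle", "torsion"):
            raise ValueError(f"bad histogram kind {self.kind!r}")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("counts/edges length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def centers(self):
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @classmethod
    def from_samples(cls, kind, samples, temperature, bin_width=None,
                     range_=None):
        bw = bin_width or DEFAULT_BIN_WIDTHS[kind]
        samples = np.asarray(samples, dtype=float)
        if kind == "torsion":
            lo, hi = -180.0, 180.0
            samples = (samples + 180.0) % 360.0 - 180.0
        elif range_ is not None:
            lo, hi = range_
        else:
            lo, hi = samples.min() - bw, samples.max() + bw
        nbins = max(1, int(round((hi - lo) / bw)))
        counts, edges = np.histogram(samples, bins=nbins, range=(lo, hi))
        return cls(kind, edges, counts.astype(float), temperature)


@dataclass
class InvertedPotential:
    kind: str
    grid: np.ndarray        # bin centers
    values: np.ndarray      # kJ/mol, min-shifted; NaN where unsupported
    temperature: float
    normalization: str      # r2 | sin | none

    @property
    def supported(self):
        return np.isfinite(self.values)

    def min_shift(self):
        sup = self.supported
        if sup.any():
            self.values = self.values - np.nanmin(self.values[sup])
        return self


def _invert(hist: CoordinateHistogram, T: float, jacobian, norm_label):
    if T <= 0:
        raise InversionError("temperature must be positive")
    counts = hist.counts
    if not np.any(counts > 0):
        raise InversionError("all-zero histogram")
    x = hist.centers
    p = counts / counts.sum()
    jac = jacobian(x)
    v = np.full_like(p, np.nan)
    ok = (p > 0) & (jac > 0)
    v[ok] = -KB * T * np.log(p[ok] / jac[ok])
    pot = InvertedPotential(hist.kind, x, v, T, norm_label)
    return pot.min_shift()


def invert_bond(hist: CoordinateHistogram, T: float | None = None):
    """V(r) = -kT ln(p(r)/r^2), min-shifted; r in nm."""
    if hist.kind != "bond":
        raise InversionError("histogram kind must be 'bond'")
    return _invert(hist, T or hist.temperature, lambda r: r ** 2, "r2")


def invert_angle(hist: CoordinateHistogram, T: float | None = None,
                 sin_floor: float = 1e-8):
    """V(theta) = -kT ln(p/sin theta); theta in degrees, interior of (0, 180).

    Bins whose sin(theta) falls below sin_floor are treated as unsupported
    (regularisation at the poles).
    """
    if hist.kind != "angle":
        raise InversionError("histogram kind must be 'angle'")

    def jac(theta_deg):
        s = np.sin(np.radians(theta_deg))
        s[s < sin_floor] = 0.0
        return s

    return _invert(hist, T or hist.temperature, jac, "sin")


def invert_torsion(hist: CoordinateHistogram, T: float | None = None):
    """V(phi) = -kT ln p(phi), periodic on (-180, 180]."""
    if hist.kind != "torsion":
        raise InversionError("histogram kind must be 'torsion'")
    return _invert(hist, T or hist.temperature, lambda x: np.ones_like(x), "none")


@dataclass
class PolynomialPotential:
    coefficients: np.ndarray    # ascending, length order+1
    domain: tuple               # (lo, hi) in the grid's units
    kind: str
    rms_residual: float = 0.0
    use_table: bool = False     # fit rejected; fall back to the raw table

    @property
    def order(self):
        return len(self.coefficients) - 1

    def __call__(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, float),
                                                self.coefficients)

    def derivative(self, x):
        dc = np.polynomial.polynomial.polyder(self.coefficients)
        return np.polynomial.polynomial.polyval(np.asarray(x, float), dc)


def fit_polynomial(pot: InvertedPotential, order: int = 2,
                   residual_threshold: float | None = None,
                   weights=None) -> PolynomialPotential:
    """Weighted least-squares polynomial fit over supported bins.

    residual_threshold (kJ/mol RMS) flags the fit as 'use_table' when the
    data are not polynomial-like (e.g. bimodal wells for order=2).
    """
    if order not in (2, 4):
        raise ValueError("order must be 2 (harmonic) or 4 (quartic)")
    sup = pot.supported
    x, y = pot.grid[sup], pot.values[sup]
    if len(x) < order + 1:
        raise InversionError(
            f"underdetermined fit: {len(x)} supported points for order {order}")
    w = None if weights is None else np.asarray(weights)[sup]
    coefs = np.polynomial.polynomial.polyfit(x, y, order, w=w)
    resid = np.sqrt(np.mean((np.polynomial.polynomial.polyval(x, coefs) - y) ** 2))
    use_table = residual_threshold is not None and resid > residual_threshold
    return PolynomialPotential(coefs, (float(x.min()), float(x.max())),
                               pot.kind, float(resid), use_table)


@dataclass
class CosineSeries:
    """V(phi) = sum_n a_n cos(n phi), phi in degrees, periodic."""
    coefficients: np.ndarray    # a_0 .. a_max_order
    rms_residual: float = 0.0

    def __call__(self, phi_deg):
        phi = np.radians(np.asarray(phi_deg, dtype=float))
        n = np.arange(len(self.coefficients))
        return np.cos(np.multiply.outer(phi, n)) @ self.coefficients

    def derivative_deg(self, phi_deg):
        """dV/dphi in kJ/mol per degree."""
        phi = np.radians(np.asarray(phi_deg, dtype=float))
        n = np.arange(len(self.coefficients))
        per_rad = -np.sin(np.multiply.outer(phi, n)) @ (self.coefficients * n)
        return per_rad * np.pi / 180.0

    def scaled(self, s: float) -> "CosineSeries":
        # scale the min-shifted potential: V' - min V' = s (V - min V)
        c = self.coefficients.copy() * s
        grid = np.linspace(-180.0, 180.0, 721)
        base = CosineSeries(c)
        c[0] -= base(grid).min()
        return CosineSeries(c, self.rms_residual * s)


def fit_cosine_series(pot: InvertedPotential, max_order: int = 4) -> CosineSeries:
    """Least-squares pure-cosine series fit of a periodic torsion potential."""
    if pot.kind != "torsion":
        raise InversionError("cosine series fits torsion potentials")
    sup = pot.supported
    phi = np.radians(pot.grid[sup])
    y = pot.values[sup]
    if len(phi) < max_order + 1:
        raise InversionError("too few supported bins for the requested order")
    design = np.cos(np.multiply.outer(phi, np.arange(max_order + 1)))
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = np.sqrt(np.mean((design @ coefs - y) ** 2))
    return CosineSeries(coefs, float(resid))


class TorsionLibrary:
    """Backbone pseudo-torsion series keyed by the ordered middle-residue pair."""

    def __init__(self, entries: dict, scale: float = 0.54,
                 fallback_key=None, prescaled: bool = False):
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.scale = float(scale)
        self.fallback_key = fallback_key
        self.missing_pairs = []
        if prescaled:
            self.entries = dict(entries)
        else:
            self.entries = {k: v.scaled(self.scale) for k, v in entries.items()}

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, pair) -> CosineSeries:
        pair = tuple(pair)
        if pair in self.entries:
            return self.entries[pair]
        if self.fallback_key is not None and self.fallback_key in self.entries:
            self.missing_pairs.append(pair)
            return self.entries[self.fallback_key]
        raise KeyError(f"no torsion entry for residue pair {pair}")

    @classmethod
    def from_distributions(cls, histograms: dict, scale: float = 0.54,
                           max_order: int = 4, **kw) -> "TorsionLibrary":
        entries = {}
        for pair, hist in histograms.items():
            entries[tuple(pair)] = fit_cosine_series(invert_torsion(hist), max_order)
        return cls(entries, scale, **kw)

    @classmethod
    def from_coefficients(cls, rows, scale: float = 0.54, **kw) -> "TorsionLibrary":
        """rows: iterable of (res1, res2, a0..a4) or a keyed text stream."""
        entries = {}
        for row in rows:
            r1, r2, *coefs = row
            entries[(str(r1), str(r2))] = CosineSeries(np.asarray(coefs, float))
        return cls(entries, scale, **kw)

    @classmethod
    def read(cls, path_or_stream, scale: float = 0.54, **kw) -> "TorsionLibrary":
        if hasattr(path_or_stream, "read"):
            text = path_or_stream.read()
        else:
            with open(path_or_stream) as fh:
                text = fh.read()
        rows = []
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"torsion library line {ln}: expected "
                                 f"'RES1 RES2 a0 a1 a2 a3 a4', got {line!r}")
            rows.append((parts[0], parts[1], *map(float, parts[2:])))
        return cls.from_coefficients(rows, scale, **kw)

    def write(self, path_or_stream):
        out = io.StringIO()
        out.write("# RES1 RES2 a0 a1 a2 a3 a4  (kJ/mol, phi in degrees; "
                  f"scale {self.scale} already applied)\n")
        for (r1, r2), series in sorted(self.entries.items()):
            coefs = " ".join(f"{c:.8g}" for c in series.coefficients)
            out.write(f"{r1} {r2} {coefs}\n")
        text = out.getvalue()
        if hasattr(path_or_stream, "write"):
            path_or_stream.write(text)
        else:
            with open(path_or_stream, "w") as fh:
                fh.write(text)
        return text

    def check_complete(self, residues=_STANDARD_RESIDUES):
        missing = [(a, b) for a in residues for b in residues
                   if (a, b) not in self.entries]
        return missing


def build_torsion_library(source, scale: float = 0.54, **kw) -> TorsionLibrary:
    """Build the sequence-dependent torsion library from distributions or
    a coefficient table, applying the global scale factor."""
    if isinstance(source, dict):
        first = next(iter(source.values()), None)
        if isinstance(first, CoordinateHistogram):
            return TorsionLibrary.from_distributions(source, scale, **kw)
        return TorsionLibrary.from_coefficients(
            [(k[0], k[1], *np.asarray(v, float)) for k, v in source.items()],
            scale, **kw)
    return TorsionLibrary.read(source, scale, **kw)


def backbone_angle_potential(pooled_hist: CoordinateHistogram,
                             T: float | None = None) -> PolynomialPotential:
    """Single sequence-independent quartic for all backbone CA-CA-CA angles."""
    pot = invert_angle(pooled_hist, T)
    return fit_polynomial(pot, order=4)


# --- two-column text serialization ------------------------------------

def write_potential(pot: InvertedPotential, path_or_stream):
    out = io.StringIO()
    out.write(f"# kind={pot.kind} T={pot.temperature:g} "
              f"normalization={pot.normalization}\n")
    for x, v in zip(pot.grid, pot.values):
        out.write(f"{x:.8g}\t{v if np.isfinite(v) else 'nan'}\n")
    text = out.getvalue()
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)
    return text


def read_potential(path_or_stream) -> InvertedPotential:
    if hasattr(path_or_stream, "read"):
        text = path_or_stream.read()
    else:
        with open(path_or_stream) as fh:
            text = fh.read()
    header = {}
    xs, vs = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    header[k] = v
            continue
        a, b = line.split()
        xs.append(float(a))
        vs.append(float(b))
    return InvertedPotential(header.get("kind", "bond"), np.array(xs),
                             np.array(vs), float(header.get("T", 0) or 0),
                             header.get("normalization", "none"))
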