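"""Variational force matching of pairwise CG interactions.

Pair forces are expanded in a linear (hat-function) spline basis in the pair
distance; the coefficients — force values at the knots — are obtained by
least squares against the mapped site forces, block by block, then averaged
across blocks.  Normal equations are accumulated per block so the full
design matrix is never materialised across blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse import coo_matrix


class ForceMatchError(ValueError):
    pass


@dataclass
class CGFrame:
    positions: np.ndarray       # (n, 3) nm
    forces: np.ndarray          # (n, 3) kJ/mol/nm
    box: np.ndarray | None = None   # (3,) orthorhombic box lengths, nm

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.positions.shape != self.forces.shape:
            raise ForceMatchError("positions/forces shape mismatch")
        if not (np.isfinite(self.positions).all() and np.isfinite(self.forces).all()):
            raise ForceMatchError("non-finite frame data")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)


def minimum_image(dx: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return dx
    return dx - box * np.round(dx / box)


def write_frames(frames, path, fmt: str = "text"):
    """Persist CG frames.

    'text': plain columns (frame x y z fx fy fz) with a box header line —
    the dialect used by small tests.  'hdf5': positions/forces/box datasets.
    """
    frames = list(frames)
    if fmt == "text":
        lines = []
        box = frames[0].box
        lines.append("# box\t" + ("none" if box is None else
                                  "\t".join(f"{b:.8g}" for b in box)))
        lines.append("# frame\tx\ty\tz\tfx\tfy\tfz")
        for k, fr in enumerate(frames):
            for (x, y, z), (fx, fy, fz) in zip(fr.positions, fr.forces):
                lines.append(f"{k}\t{x:.8g}\t{y:.8g}\t{z:.8g}"
                             f"\t{fx:.8g}\t{fy:.8g}\t{fz:.8g}")
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)
    elif fmt == "hdf5":
        import h5py
        with h5py.File(path, "w") as h5:
            h5.create_dataset("positions",
                              data=np.stack([f.positions for f in frames]))
            h5.create_dataset("forces",
                              data=np.stack([f.forces for f in frames]))
            if frames[0].box is not None:
                h5.create_dataset("box", data=frames[0].box)
    else:
        raise ForceMatchError(f"unknown frame format {fmt!r}")


def read_frames(path, fmt: str = "text"):
    if fmt == "text":
        if hasattr(path, "read"):
            text = path.read()
        else:
            with open(path) as fh:
                text = fh.read()
        box = None
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("# box"):
                parts = line.split("\t")[1:]
                if parts and parts[0] != "none":
                    box = np.array([float(p) for p in parts])
                continue
            if line.startswith("#"):
                continue
            rows.append([float(p) for p in line.split()])
        arr = np.asarray(rows)
        frames = []
        for k in sorted(set(arr[:, 0].astype(int))):
            sel = arr[arr[:, 0].astype(int) == k]
            frames.append(CGFrame(sel[:, 1:4], sel[:, 4:7],
                                  None if box is None else box.copy()))
        return frames
    if fmt == "hdf5":
        import h5py
        with h5py.File(path, "r") as h5:
            pos = h5["positions"][...]
            frc = h5["forces"][...]
            box = h5["box"][...] if "box" in h5 else None
        return [CGFrame(p, f, None if box is None else box.copy())
                for p, f in zip(pos, frc)]
    raise ForceMatchError(f"unknown frame format {fmt!r}")


@dataclass
class SplineBasis:
    """Hat functions on a strictly increasing knot grid over (r_low, r_high]."""
    knots: np.ndarray

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if np.any(np.diff(self.knots) <= 0):
            raise ForceMatchError("knots must be strictly increasing")

    @classmethod
    def uniform(cls, r_low: float = 0.2, r_high: float = 2.0,
                spacing: float = 0.02) -> "SplineBasis":
        n = int(round((r_high - r_low) / spacing))
        return cls(np.linspace(r_low, r_high, n + 1))

    @property
    def n_knots(self):
        return len(self.knots)

    @property
    def r_max(self):
        return float(self.knots[-1])

    @property
    def r_min(self):
        return float(self.knots[0])

    def weights(self, r: np.ndarray):
        """Hat weights: returns (idx_lo, w_lo, w_hi); weights sum to 1 in range."""
        r = np.asarray(r, dtype=float)
        idx = np.clip(np.searchsorted(self.knots, r, side="right") - 1,
                      0, self.n_knots - 2)
        lo = self.knots[idx]
        hi = self.knots[idx + 1]
        t = (r - lo) / (hi - lo)
        return idx, 1.0 - t, t

    def evaluate(self, coefs: np.ndarray, r: np.ndarray) -> np.ndarray:
        idx, w0, w1 = self.weights(r)
        return w0 * coefs[idx] + w1 * coefs[idx + 1]


def pair_key(type_a: str, type_b: str) -> tuple:
    """Unordered (symmetrised) pair-type key."""
    return tuple(sorted((type_a, type_b)))


@dataclass
class LinearSystem:
    """Accumulated normal equations for one block."""
    basis: SplineBasis
    pair_keys: list                 # column-block order
    gram: np.ndarray                # (K*P, K*P)
    rhs: np.ndarray                 # (K*P,)
    yty: float
    n_rows: int
    n_frames: int
    knot_samples: np.ndarray        # per-column pair-visit counts

    def column(self, key, knot_index):
        return self.pair_keys.index(key) * self.basis.n_knots + knot_index


def _eligible_pairs(topology, n_sites, exclusion_rule):
    """(i, j, key) triples for nonbonded pairs; i<j."""
    if topology is not None:
        types = topology.site_types()
        excluded = topology.exclusion_pairs()
        if exclusion_rule is not None and exclusion_rule != topology.min_separation:
            sep = topology.bond_separations(exclusion_rule - 1)
            excluded = {p for p, d in sep.items() if d < exclusion_rule}
    else:
        types = ["X"] * n_sites
        excluded = set()
    out = []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            if (i, j) in excluded:
                continue
            out.append((i, j, pair_key(types[i], types[j])))
    return out


def build_block(frames, basis: SplineBasis, topology=None,
                exclusion_rule: int | None = None) -> LinearSystem:
    """Accumulate the least-squares normal equations for one block of frames.

    The model: the force on site i is the sum over eligible partners j of
    f(r_ij) * u_ij with u_ij the unit vector from j to i, f expanded in the
    hat basis.  Each in-range pair contributes opposite-sign weights to its
    two partner rows (Newton's third law is built into the design).
    """
    frames = list(frames)
    if not frames:
        raise ForceMatchError("no frames")
    n_sites = frames[0].positions.shape[0]
    pairs = _eligible_pairs(topology, n_sites, exclusion_rule)
    if not pairs:
        raise ForceMatchError("all pairs excluded")
    keys = sorted({k for _, _, k in pairs})
    K = basis.n_knots
    P = len(keys)
    key_col = {k: p * K for p, k in enumerate(keys)}

    gram = np.zeros((K * P, K * P))
    rhs = np.zeros(K * P)
    yty = 0.0
    knot_samples = np.zeros(K * P)
    n_rows = 0
    any_in_range = False

    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    cols0 = np.array([key_col[p[2]] for p in pairs])

    for frame in frames:
        X, F = frame.positions, frame.forces
        dx = minimum_image(X[ii] - X[jj], frame.box)
        r = np.linalg.norm(dx, axis=1)
        in_range = (r > basis.r_min) & (r <= basis.r_max) & (r > 0)
        if not in_range.any():
            n_rows += 3 * n_sites
            yty += float((F ** 2).sum())
            continue
        any_in_range = True
        u = dx[in_range] / r[in_range, None]
        idx, w0, w1 = basis.weights(r[in_range])
        pi = ii[in_range]
        pj = jj[in_range]
        c0 = cols0[in_range] + idx
        c1 = c0 + 1

        # sparse per-frame design: rows are (site, xyz) force components;
        # pair p contributes +w*u to row-block i and -w*u to row-block j,
        # so Newton's third law is built into the columns.
        rows_i = pi
        rows_j = pj
        data = np.concatenate([
            (w0[:, None] * u).ravel(), (w1[:, None] * u).ravel(),
            (-w0[:, None] * u).ravel(), (-w1[:, None] * u).ravel()])
        row_idx = np.concatenate([
            (rows_i[:, None] * 3 + np.arange(3)).ravel(),
            (rows_i[:, None] * 3 + np.arange(3)).ravel(),
            (rows_j[:, None] * 3 + np.arange(3)).ravel(),
            (rows_j[:, None] * 3 + np.arange(3)).ravel()])
        col_idx = np.concatenate([
            np.repeat(c0, 3), np.repeat(c1, 3),
            np.repeat(c0, 3), np.repeat(c1, 3)])
        A = coo_matrix((data, (row_idx, col_idx)),
                       shape=(3 * n_sites, K * P)).tocsr()
        y = F.ravel()
        gram += (A.T @ A).toarray()
        rhs += A.T @ y
        yty += float(y @ y)
        n_rows += 3 * n_sites
        np.add.at(knot_samples, c0, w0)
        np.add.at(knot_samples, c1, w1)

    if not any_in_range:
        raise ForceMatchError("no interacting pairs in basis range")
    return LinearSystem(basis, keys, gram, rhs, yty, n_rows, len(frames),
                        knot_samples)


@dataclass
class BlockSolution:
    basis: SplineBasis
    pair_keys: list
    coefficients: dict          # key -> (K,) force values at knots
    sampled: dict               # key -> (K,) bool, knot visited in this block
    residual_norm: float
    n_frames: int


def solve_block(system: LinearSystem) -> BlockSolution:
    """Minimum-norm least-squares solution of a block's normal equations."""
    if system.n_rows == 0:
        raise ForceMatchError("empty system")
    x, *_ = scipy.linalg.lstsq(system.gram, system.rhs,
                               lapack_driver="gelsd")
    resid2 = max(system.yty - 2 * x @ system.rhs + x @ system.gram @ x, 0.0)
    K = system.basis.n_knots
    coefs, sampled = {}, {}
    for p, key in enumerate(system.pair_keys):
        coefs[key] = x[p * K:(p + 1) * K]
        sampled[key] = system.knot_samples[p * K:(p + 1) * K] > 0
    return BlockSolution(system.basis, list(system.pair_keys), coefs, sampled,
                         float(np.sqrt(resid2)), system.n_frames)


@dataclass
class ForceCurve:
    key: tuple
    knots: np.ndarray
    values: np.ndarray          # mean force at knots; NaN where unsampled
    stderr: np.ndarray
    n_blocks: np.ndarray        # per-knot number of contributing blocks

    @property
    def sampled(self):
        return np.isfinite(self.values)

    def write(self, path_or_stream):
        lines = [f"# pair={self.key[0]}-{self.key[1]}  columns: r f stderr n_blocks"]
        for r, f, s, n in zip(self.knots, self.values, self.stderr, self.n_blocks):
            lines.append(f"{r:.6f}\t{f:.8g}\t{s:.8g}\t{int(n)}")
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_stream, "write"):
            path_or_stream.write(text)
        else:
            with open(path_or_stream, "w") as fh:
                fh.write(text)
        return text


def average_blocks(solutions) -> dict:
    """Count-weighted per-knot mean and standard error across blocks."""
    solutions = list(solutions)
    if not solutions:
        raise ForceMatchError("no block solutions")
    basis = solutions[0].basis
    for s in solutions[1:]:
        if s.basis.n_knots != basis.n_knots or \
                not np.allclose(s.basis.knots, basis.knots):
            raise ForceMatchError("block bases differ")
    keys = sorted({k for s in solutions for k in s.pair_keys})
    K = basis.n_knots
    out = {}
    for key in keys:
        vals = np.full((len(solutions), K), np.nan)
        wts = np.zeros((len(solutions), K))
        for b, s in enumerate(solutions):
            if key in s.coefficients:
                mask = s.sampled[key]
                vals[b, mask] = s.coefficients[key][mask]
                wts[b, mask] = s.n_frames
        wsum = wts.sum(axis=0)
        mean = np.full(K, np.nan)
        stderr = np.zeros(K)
        nb = (wts > 0).sum(axis=0)
        ok = wsum > 0
        with np.errstate(invalid="ignore"):
            mean[ok] = np.nansum(np.where(wts > 0, vals * wts, 0), axis=0)[ok] / wsum[ok]
            var = np.nansum(np.where(wts > 0, wts * (vals - mean) ** 2, 0), axis=0)
            multi = ok & (nb > 1)
            stderr[multi] = np.sqrt(var[multi] / wsum[multi] / (nb[multi] - 1))
        out[key] = ForceCurve(key, basis.knots.copy(), mean, stderr,
                              nb.astype(float))
    return out


@dataclass
class ConvergenceReport:
    per_pair_max: dict
    per_pair_rms: dict
    unsampled_knots: dict       # key -> indices compared-excluded

    def max_deviation(self):
        return max(self.per_pair_max.values(), default=np.nan)


def check_convergence(frames, basis: SplineBasis, topology=None,
                      exclusion_rule: int | None = None) -> ConvergenceReport:
    """Half-data check: solve on each half and compare over sampled knots."""
    frames = list(frames)
    if len(frames) < 2:
        raise ForceMatchError("too few frames to split")
    half = len(frames) // 2
    sols = []
    for part in (frames[:half], frames[half:]):
        sols.append(solve_block(build_block(part, basis, topology, exclusion_rule)))
    a, b = sols
    keys = sorted(set(a.pair_keys) & set(b.pair_keys))
    pmax, prms, unsampled = {}, {}, {}
    for key in keys:
        both = a.sampled[key] & b.sampled[key]
        unsampled[key] = np.where(~both)[0]
        if not both.any():
            pmax[key] = np.nan
            prms[key] = np.nan
            continue
        d = a.coefficients[key][both] - b.coefficients[key][both]
        pmax[key] = float(np.abs(d).max())
        prms[key] = float(np.sqrt(np.mean(d ** 2)))
    return ConvergenceReport(pmax, prms, unsampled)
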