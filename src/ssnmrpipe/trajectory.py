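"""Trajectory-ensemble statistics.

Contact occupancy pools contact and total frame counts over all
simulations and interfaces before dividing (the double-sum convention);
``per_simulation_average=True`` switches to averaging per-simulation
percentages instead.

TICA solves the generalized symmetric eigenproblem C(tau) v = lambda
C(0) v on mean-free features, with the time-lagged covariance
symmetrized and low-variance directions discarded before whitening.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .bundle import kabsch
from .model import StructureModel
from .synthetic import TrajectoryEnsemble, _sidechain_indices


@dataclass
class ContactSpec:
    pairs: list                       # [(res_a, res_b), ...] one interface
    cutoff: float = 3.4               # Angstrom, sidechain heavy atoms
    interfaces: list | None = None    # optional list of pair lists

    def interface_list(self) -> list:
        if self.interfaces is not None:
            return self.interfaces
        return [self.pairs]


@dataclass
class OccupancyTable:
    occupancy: dict                   # (res_a, res_b) -> percent
    contact_frames: dict              # (sim, interface, pair) -> int
    total_frames: dict                # (sim, interface) -> int


def _min_sidechain_distance(topology: StructureModel, frame: np.ndarray,
                            ia: np.ndarray, ib: np.ndarray) -> float:
    pa, pb = frame[ia], frame[ib]
    d = np.sqrt(((pa[:, None] - pb[None]) ** 2).sum(-1))
    return float(d.min())


def contact_occupancy(ensemble: TrajectoryEnsemble, spec: ContactSpec,
                      per_simulation_average: bool = False) -> OccupancyTable:
    """Percent of pooled frames in which each residue pair is in contact.

    Contact: minimum sidechain heavy-atom distance <= cutoff (CA stands in
    for glycine).  Pooling follows the double sum over simulations and
    interfaces: sum of contact frames over sum of total frames, x100.
    """
    interfaces = spec.interface_list()
    top = ensemble.topology
    side_cache = {int(r): _sidechain_indices(top, int(r))
                  for iface in interfaces for pair in iface for r in pair}
    for r, idx in side_cache.items():
        if len(idx) == 0:
            raise KeyError(f"residue {r} not found in topology")

    contact_frames: dict = {}
    total_frames: dict = {}
    all_pairs = []
    for j, iface in enumerate(interfaces):
        for pair in iface:
            if pair not in all_pairs:
                all_pairs.append(pair)

    for i, sim in enumerate(ensemble.simulations):
        nf = sim.shape[0]
        for j, iface in enumerate(interfaces):
            total_frames[(i, j)] = nf
            for pair in iface:
                ia = side_cache[int(pair[0])]
                ib = side_cache[int(pair[1])]
                n = 0
                for f in range(nf):
                    if _min_sidechain_distance(top, sim[f], ia, ib) \
                            <= spec.cutoff:
                        n += 1
                contact_frames[(i, j, pair)] = n

    occ = {}
    for pair in all_pairs:
        if per_simulation_average:
            vals = []
            for i in range(ensemble.n_sims):
                num = sum(contact_frames.get((i, j, pair), 0)
                          for j in range(len(interfaces)))
                den = sum(total_frames[(i, j)] for j in range(len(interfaces))
                          if (i, j, pair) in contact_frames)
                if den:
                    vals.append(100.0 * num / den)
            occ[pair] = float(np.mean(vals)) if vals else 0.0
        else:
            num = sum(v for (i, j, p), v in contact_frames.items() if p == pair)
            den = sum(total_frames[(i, j)] for (i, j, p) in contact_frames
                      if p == pair)
            occ[pair] = 100.0 * num / den if den else 0.0

    return OccupancyTable(occupancy=occ, contact_frames=contact_frames,
                          total_frames=total_frames)


def rmsf(frames: np.ndarray, selection_mask: np.ndarray | None = None,
         superpose: bool = True, reference: np.ndarray | None = None
         ) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure.

    ``frames``: (n_frames, n_atoms, 3).  With ``superpose`` each frame is
    first least-squares fitted to the reference (default: first frame) on
    the selection, removing rigid-body motion.
    """
    frames = np.asarray(frames, float)
    if frames.shape[0] < 2:
        raise ValueError("RMSF needs >= 2 frames")
    mask = np.ones(frames.shape[1], bool) if selection_mask is None \
        else np.asarray(selection_mask, bool)
    work = frames.copy()
    if superpose:
        ref = frames[0] if reference is None else np.asarray(reference, float)
        for f in range(work.shape[0]):
            rot, t, _ = kabsch(work[f][mask], ref[mask])
            work[f] = work[f] @ rot.T + t
    mean = work.mean(axis=0)
    return np.sqrt(((work - mean) ** 2).sum(-1).mean(axis=0))


def pairwise_distance_map(coords, selection_mask: np.ndarray | None = None
                          ) -> np.ndarray:
    """Symmetric atom-atom distance matrix (mean over frames for a stack)."""
    arr = np.asarray(coords, float)
    if arr.ndim == 2:
        arr = arr[None]
    if selection_mask is not None:
        arr = arr[:, np.asarray(selection_mask, bool)]
    diff = arr[:, :, None, :] - arr[:, None, :, :]
    return np.sqrt((diff ** 2).sum(-1)).mean(axis=0)


def distance_map_difference(map_a: np.ndarray, map_b: np.ndarray
                            ) -> np.ndarray:
    a, b = np.asarray(map_a), np.asarray(map_b)
    if a.shape != b.shape:
        raise ValueError(f"distance map shapes differ: {a.shape} vs {b.shape}")
    return a - b


# ---------------------------------------------------------------------------
# TICA


@dataclass
class TICAModel:
    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray              # symmetrized
    eigenvalues: np.ndarray       # descending
    components: np.ndarray        # (n_features, n_components), C0-orthonormal
    n_components: int


def tica_fit(series, lag: int, n_components: int = 10,
             variance_floor: float = 1e-8) -> TICAModel:
    """Fit TICA over one or more feature time series.

    ``series``: array (T, d) or list of such arrays; lagged products never
    cross series boundaries.  C(0) directions holding less than
    ``variance_floor`` of the total variance are discarded before the
    whitened eigenproblem, which makes collinear features harmless.
    """
    if isinstance(series, np.ndarray) and series.ndim <= 2:
        series = [series]
    series = [np.atleast_2d(np.asarray(s, float).T).T if np.asarray(s).ndim == 1
              else np.asarray(s, float) for s in series]
    if not series:
        raise ValueError("need at least one series")
    lag = int(lag)
    for s in series:
        if s.shape[0] <= lag:
            raise ValueError("every series must be longer than the lag")
    d = series[0].shape[1]

    total = sum(s.shape[0] for s in series)
    mean = sum(s.sum(axis=0) for s in series) / total

    c0 = np.zeros((d, d))
    ctau = np.zeros((d, d))
    n0 = nt = 0
    for s in series:
        x = s - mean
        head, tail = x[:-lag], x[lag:]
        c0 += head.T @ head + tail.T @ tail
        ctau += head.T @ tail
        n0 += 2 * head.shape[0]
        nt += head.shape[0]
    c0 /= n0
    ctau /= nt
    ctau = 0.5 * (ctau + ctau.T)

    evals, evecs = np.linalg.eigh(c0)
    floor = variance_floor * float(evals.sum())
    keep = evals > max(floor, 0.0)
    if not keep.any():
        raise ValueError("C(0) is singular; raise the variance floor "
                         "or check the features")
    l_half = evecs[:, keep] / np.sqrt(evals[keep])
    m = l_half.T @ ctau @ l_half
    lam, v = np.linalg.eigh(m)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    comps = l_half @ v[:, order]

    k = min(n_components, comps.shape[1])
    return TICAModel(lag=lag, mean=mean, c0=c0, ctau=ctau,
                     eigenvalues=lam[:k], components=comps[:, :k],
                     n_components=k)


def tica_transform(model: TICAModel, series: np.ndarray) -> np.ndarray:
    """Project features onto the model's independent components."""
    x = np.asarray(series, float)
    if x.ndim == 1:
        x = x[:, None]
    return (x - model.mean) @ model.components


# ---------------------------------------------------------------------------
# free-energy surfaces


@dataclass
class FESGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray      # kT units; empty bins +inf; minimum 0
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def bin_of(self, x: float, y: float) -> tuple:
        i = int(np.clip(np.searchsorted(self.x_edges, x, side="right") - 1,
                        0, len(self.x_edges) - 2))
        j = int(np.clip(np.searchsorted(self.y_edges, y, side="right") - 1,
                        0, len(self.y_edges) - 2))
        return i, j


def free_energy_surface(projections: np.ndarray, n_bins: int = 32
                        ) -> FESGrid:
    """F = -ln(p / p_max) per 2-D histogram bin (kT units)."""
    p = np.asarray(projections, float)
    if p.ndim != 2 or p.shape[1] < 2 or p.shape[0] < 1:
        raise ValueError("projections must be (n_samples, >=2)")
    counts, xe, ye = np.histogram2d(p[:, 0], p[:, 1], bins=n_bins)
    with np.errstate(divide="ignore"):
        f = -np.log(counts / counts.max())
    f[counts == 0] = np.inf
    return FESGrid(x_edges=xe, y_edges=ye, free_energy=f, counts=counts)


def estimate_barrier(fes: FESGrid, basin_a: tuple, basin_b: tuple,
                     connectivity: int = 8) -> float:
    """Barrier (kT) between two basins: minimax-path saddle minus the
    higher of the two basin minima.  Returns ``inf`` when disconnected.
    """
    f = fes.free_energy
    nx, ny = f.shape
    a, b = tuple(basin_a), tuple(basin_b)
    for p in (a, b):
        if not (0 <= p[0] < nx and 0 <= p[1] < ny):
            raise ValueError(f"basin {p} outside grid {f.shape}")
        if not np.isfinite(f[p]):
            return np.inf

    if connectivity == 4:
        steps = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    elif connectivity == 8:
        steps = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                 if (dx, dy) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")

    # Dijkstra on the bottleneck (minimax) objective
    best = np.full(f.shape, np.inf)
    best[a] = f[a]
    heap = [(f[a], a)]
    while heap:
        cost, (x, y) = heapq.heappop(heap)
        if (x, y) == b:
            break
        if cost > best[x, y]:
            continue
        for dx, dy in steps:
            u, v = x + dx, y + dy
            if not (0 <= u < nx and 0 <= v < ny):
                continue
            c = max(cost, f[u, v])
            if c < best[u, v]:
                best[u, v] = c
                heapq.heappush(heap, (c, (u, v)))
    saddle = best[b]
    if not np.isfinite(saddle):
        return np.inf
    return float(saddle - max(f[a], f[b]))
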