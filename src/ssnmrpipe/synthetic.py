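"""Synthetic inputs with known ground truth.

Every generator takes an explicit ``seed`` and owns its own
``numpy.random.Generator``; no global randomness.  Units are Angstrom,
ppm and degrees throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .labeling import DEFAULT_THRESHOLD, LabelingScheme
from .model import StructureBundle, StructureModel
from .peaks import CrossPeak, PeakList, ShiftTable

_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL"
).split()

# ideal alpha-helix: 1.5 A rise and 100 deg turn per residue; the CA radius
# follows from the 3.8 A consecutive-CA distance
HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0
_CA_RADIUS = np.sqrt(3.8**2 - HELIX_RISE**2) / (2 * np.sin(np.deg2rad(HELIX_TURN_DEG / 2)))


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated artifacts.

    ``peak_truth`` maps peak_id -> ((res_i, atom_i), (res_j, atom_j));
    ``contact_schedule`` holds, per simulation, a mapping
    ``(res_a, res_b) -> bool array over frames``; ``states`` is the hidden
    state sequence of a two-state series.
    """

    peak_truth: dict = field(default_factory=dict)
    contact_schedule: list = field(default_factory=list)
    states: np.ndarray | None = None


@dataclass
class TrajectoryEnsemble:
    """n independent simulations over one shared topology."""

    topology: StructureModel
    simulations: list            # list of (n_frames, n_atoms, 3) arrays
    frame_interval: float = 1.0  # arbitrary time units

    def __post_init__(self) -> None:
        if len(self.simulations) < 1:
            raise ValueError("ensemble needs at least one simulation")
        n = self.topology.n_atoms
        self.simulations = [np.asarray(s, float) for s in self.simulations]
        for k, sim in enumerate(self.simulations):
            if sim.ndim != 3 or sim.shape[1:] != (n, 3):
                raise ValueError(
                    f"simulation {k} shape {sim.shape} does not match "
                    f"topology with {n} atoms")

    @property
    def n_sims(self) -> int:
        return len(self.simulations)

    @property
    def n_frames(self) -> list:
        return [s.shape[0] for s in self.simulations]


def make_helix_model(n_res: int, seed: int) -> StructureModel:
    """Ideal alpha-helix backbone (N, CA, C, O) plus a CB pseudo-sidechain.

    Residue types are drawn uniformly from the 20 standard amino acids;
    glycines get no CB.  Deterministic for a fixed seed.
    """
    if n_res < 2:
        raise ValueError("n_res must be >= 2")
    rng = np.random.default_rng(seed)
    res_types = rng.choice(_AA3, size=n_res)

    rows = []
    dtheta = np.deg2rad(HELIX_TURN_DEG)
    for i in range(n_res):
        theta = i * dtheta
        u = np.array([np.cos(theta), np.sin(theta), 0.0])      # outward radial
        w = np.array([-np.sin(theta), np.cos(theta), 0.0])     # tangential
        ez = np.array([0.0, 0.0, 1.0])
        ca = _CA_RADIUS * u + np.array([0.0, 0.0, HELIX_RISE * i])
        n_at = ca + 1.46 * (-0.8 * w - 0.6 * ez)
        c_at = ca + 1.52 * (0.8 * w + 0.6 * ez)
        o_at = c_at + 1.23 * (0.9165 * u - 0.4 * ez)
        res = res_types[i]
        rows.append((i + 1, res, "N", "N", n_at))
        rows.append((i + 1, res, "CA", "C", ca))
        rows.append((i + 1, res, "C", "C", c_at))
        rows.append((i + 1, res, "O", "O", o_at))
        if res != "GLY":
            rows.append((i + 1, res, "CB", "C", ca + 1.54 * u))

    return StructureModel(
        res_index=np.array([r[0] for r in rows]),
        res_type=np.array([r[1] for r in rows]),
        atom_name=np.array([r[2] for r in rows]),
        element=np.array([r[3] for r in rows]),
        coords=np.array([r[4] for r in rows]),
    )


def perturb_bundle(model: StructureModel, n_models: int, sigma: float,
                   seed: int) -> StructureBundle:
    """Bundle of copies with iid Gaussian displacement (std ``sigma``/coord)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    models = []
    for k in range(n_models):
        noise = rng.normal(0.0, sigma, size=model.coords.shape) if sigma > 0 \
            else np.zeros_like(model.coords)
        models.append(model.copy(coords=model.coords + noise, model_id=k + 1))
    return StructureBundle(models)


# ---------------------------------------------------------------------------
# shift tables


def make_shift_table(model: StructureModel, seed: int, mode: str = "grid",
                     spacing: float = 0.45, degenerate_fraction: float = 0.0
                     ) -> ShiftTable:
    """Synthetic per-atom shift table for all C and N atoms of ``model``.

    ``mode='grid'`` spaces shifts of each atom type evenly (``spacing`` ppm
    apart, shuffled) so that distinct atoms are never closer than
    ``spacing``; ``mode='random'`` draws from packaged average shift ranges,
    giving realistic accidental degeneracy.

    ``degenerate_fraction`` engineers shift degeneracy: that fraction of
    residues (rounded down to pairs) copy their CA and CB shifts from a
    partner residue.  Partners are chosen non-adjacent so that degenerate
    pairs cannot masquerade as sequential correlations.
    """
    rng = np.random.default_rng(seed)
    ranges = _shift_ranges()

    entries: dict = {}
    for atom_type in ("N", "CA", "CB", "C"):
        idx = np.flatnonzero(model.atom_name == atom_type)
        if len(idx) == 0:
            continue
        mean, sd = ranges[atom_type]
        if mode == "grid":
            offs = (np.arange(len(idx)) - (len(idx) - 1) / 2) * spacing
            rng.shuffle(offs)
            shifts = mean + offs
        elif mode == "random":
            shifts = rng.normal(mean, sd, size=len(idx))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for k, s in zip(idx, shifts):
            entries[(int(model.res_index[k]), atom_type)] = (
                str(model.res_type[k]), float(s))

    if degenerate_fraction > 0:
        n_res = len(model.residues)
        n_pairs = int(degenerate_fraction * n_res) // 2
        # even residue indices only: copies are never sequence-adjacent
        pool = [int(r) for r in model.residues if r % 2 == 0]
        chosen = rng.choice(pool, size=min(2 * n_pairs, len(pool) - len(pool) % 2),
                            replace=False)
        for src, dst in zip(chosen[0::2], chosen[1::2]):
            for atom_type in ("CA", "CB"):
                if (src, atom_type) in entries and (dst, atom_type) in entries:
                    res_t, _ = entries[(dst, atom_type)]
                    entries[(dst, atom_type)] = (res_t, entries[(src, atom_type)][1])

    return ShiftTable(
        (res, res_t, atom, shift)
        for (res, atom), (res_t, shift) in sorted(entries.items()))


def _shift_ranges() -> dict:
    ref = resources.files("ssnmrpipe.data") / "shift_ranges.tsv"
    df = pd.read_csv(ref.open(), sep="\t", comment="#")
    return {r.atom_name: (float(r.mean_ppm), float(r.sd_ppm))
            for r in df.itertuples()}


# ---------------------------------------------------------------------------
# peak lists


def simulate_peaklist(model: StructureModel, shifts: ShiftTable,
                      scheme: LabelingScheme, r_max: float,
                      shift_noise: float, seed: int,
                      experiment: str = "CORD", mixing_time: float = 50.0,
                      threshold: float = DEFAULT_THRESHOLD,
                      ) -> tuple:
    """One CC cross peak per ordered pair of observable carbons within ``r_max``.

    Peak coordinates are the true shifts plus Gaussian noise of std
    ``shift_noise``.  Returns ``(PeakList, SyntheticTruth)`` where the truth
    map is a bijection peaks -> atom pairs.
    """
    if r_max <= 0:
        raise ValueError("r_max must be > 0")
    rng = np.random.default_rng(seed)

    carbon = np.flatnonzero(model.element == "C")
    observable = []
    for k in carbon:
        res_i = int(model.res_index[k])
        res_t = str(model.res_type[k])
        name = str(model.atom_name[k])
        if not scheme.is_observable(res_t, name, threshold):
            continue
        if (res_i, name) not in shifts:
            raise KeyError(
                f"shift table is missing observable atom {res_i}/{name}")
        observable.append(k)
    observable = np.array(observable, dtype=int)

    coords = model.coords[observable]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))

    peaks, truth = [], {}
    pid = 0
    for ai in range(len(observable)):
        for bi in range(len(observable)):
            if ai == bi or dist[ai, bi] > r_max:
                continue
            a, b = observable[ai], observable[bi]
            sa = shifts.shift(int(model.res_index[a]), str(model.atom_name[a]))
            sb = shifts.shift(int(model.res_index[b]), str(model.atom_name[b]))
            noise = rng.normal(0.0, shift_noise, size=2) if shift_noise > 0 \
                else np.zeros(2)
            peaks.append(CrossPeak(shifts=(sa + noise[0], sb + noise[1]),
                                   experiment=experiment,
                                   mixing_time=mixing_time, peak_id=pid))
            truth[pid] = ((int(model.res_index[a]), str(model.atom_name[a])),
                          (int(model.res_index[b]), str(model.atom_name[b])))
            pid += 1

    return PeakList(peaks), SyntheticTruth(peak_truth=truth)


# ---------------------------------------------------------------------------
# trajectories


def _sidechain_indices(model: StructureModel, res: int) -> np.ndarray:
    """Sidechain heavy atoms of a residue; CA fallback when none (GLY)."""
    in_res = model.res_index == res
    side = in_res & model.select("sidechain")
    if not side.any():
        side = in_res & (model.atom_name == "CA")
    return np.flatnonzero(side)


def simulate_trajectory_ensemble(model: StructureModel, n_sims: int,
                                 n_frames: int, fluct_sigma: float,
                                 contact_schedule, seed: int,
                                 frame_interval: float = 1.0,
                                 contact_distance: float = 3.0,
                                 apart_distance: float = 5.4,
                                 ) -> TrajectoryEnsemble:
    """Reference + iid Gaussian fluctuations, with scheduled contacts.

    ``contact_schedule`` is a :class:`SyntheticTruth` (or a bare list): per
    simulation a mapping ``(res_a, res_b) -> bool array`` over frames.  On
    scheduled frames residue ``b`` is rigidly translated so the minimum
    sidechain heavy-atom distance to ``a`` equals ``contact_distance``; on
    unscheduled frames it is pushed out to at least ``apart_distance``.
    Scheduled pairs should not share residues.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    schedule = (contact_schedule.contact_schedule
                if isinstance(contact_schedule, SyntheticTruth)
                else list(contact_schedule or []))
    if schedule and len(schedule) not in (1, n_sims):
        raise ValueError("schedule must cover 1 or n_sims simulations")

    residues = set(int(r) for r in model.residues)
    for per_sim in schedule:
        for (a, b), flags in per_sim.items():
            if a not in residues or b not in residues:
                raise ValueError(f"schedule references absent residue pair ({a}, {b})")
            if len(flags) != n_frames:
                raise ValueError(f"schedule for pair ({a}, {b}) does not cover "
                                 f"all {n_frames} frames")

    rng = np.random.default_rng(seed)
    sims = []
    for s in range(n_sims):
        frames = np.repeat(model.coords[None], n_frames, axis=0)
        if fluct_sigma > 0:
            frames = frames + rng.normal(0.0, fluct_sigma, size=frames.shape)
        per_sim = {}
        if schedule:
            per_sim = schedule[0] if len(schedule) == 1 else schedule[s]
        for (a, b), flags in per_sim.items():
            ia = _sidechain_indices(model, a)
            ib = _sidechain_indices(model, b)
            res_b_atoms = np.flatnonzero(model.res_index == b)
            for f in range(n_frames):
                pa, pb = frames[f][ia], frames[f][ib]
                d = np.sqrt(((pa[:, None] - pb[None]) ** 2).sum(-1))
                k, l = np.unravel_index(np.argmin(d), d.shape)
                dmin = d[k, l]
                target = contact_distance if flags[f] else (
                    dmin if dmin >= apart_distance else apart_distance)
                if dmin == 0:
                    raise ValueError("coincident scheduled sidechains")
                shift = (target / dmin - 1.0) * (pb[l] - pa[k])
                frames[f, res_b_atoms] += shift
        sims.append(frames)

    return TrajectoryEnsemble(topology=model, simulations=sims,
                              frame_interval=frame_interval)


def simulate_two_state_series(p_flip: float, n_steps: int, seed: int,
                              noise_sigma: float = 0.05) -> tuple:
    """Symmetric two-state Markov chain emitting +-1 plus Gaussian noise.

    Returns ``(series, states)``; the lag-1 autocorrelation of the state
    sequence is 1 - 2*p_flip in expectation.
    """
    if not 0.0 < p_flip < 0.5:
        raise ValueError("p_flip must lie strictly inside (0, 0.5)")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    flips = rng.random(n_steps - 1) < p_flip
    states = np.empty(n_steps, dtype=float)
    states[0] = rng.choice([-1.0, 1.0])
    signs = np.where(flips, -1.0, 1.0)
    states[1:] = states[0] * np.cumprod(signs)
    series = states + rng.normal(0.0, noise_sigma, size=n_steps)
    return series, states
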