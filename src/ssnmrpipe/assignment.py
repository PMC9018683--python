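"""Cross-peak to distance-restraint assignment.

The pipeline per peak is: shift matching within tolerance and labeling
observability -> unambiguity criteria (in fixed order: unique match,
single intra-residue possibility, single sequential possibility, single
spin-system-corroborated possibility) -> homolog distance filter for
peaks the criteria leave ambiguous -> ambiguity cap (peaks with more
than ``max_candidates`` surviving possibilities contribute nothing).

If two criteria select *different* candidates the peak is demoted to
ambiguous rather than trusting either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .labeling import CC, NC, LabelingScheme, pair_observable
from .model import StructureModel
from .peaks import CrossPeak, PeakList, ShiftTable
from .restraints import DistanceRestraint, RestraintSet, to_bounds

logger = logging.getLogger(__name__)

_EXPERIMENT_DIMS = {
    "CORD": ("C", "C"),
    "PAIN-CP": ("N", "C"),
    "NCACX": ("N", "C", "C"),
    "NCOCX": ("N", "C", "C"),
}


@dataclass
class AssignmentConfig:
    tol_C: float = 0.2            # ppm
    tol_N: float = 0.3            # ppm
    homolog_cutoff: float = 9.0   # Angstrom
    max_candidates: int = 3       # 'fewer than 4 possibilities'
    region: tuple | None = None   # residue range for re-inspection
    labeling_threshold: float = 0.1
    bounds: dict | None = None

    def __post_init__(self):
        if self.tol_C <= 0 or self.tol_N <= 0:
            raise ValueError("tolerances must be > 0")
        if self.homolog_cutoff <= 0:
            raise ValueError("homolog_cutoff must be > 0")


@dataclass(frozen=True)
class AssignmentCandidate:
    """One atom-pair explanation of a cross peak."""

    pair: tuple                   # ((res_i, atom_i), (res_j, atom_j))
    res_types: tuple              # (res_type_i, res_type_j)
    deviations: tuple             # ppm per dim
    intra: bool = False
    sequential: bool = False
    labeling_allowed: bool = True
    spin_system_corroborated: bool = False
    homolog_distance: float | None = None
    unfilterable: bool = False

    @property
    def total_deviation(self) -> float:
        return float(sum(abs(d) for d in self.deviations))

    @property
    def residue_pair(self) -> frozenset:
        return frozenset((self.pair[0][0], self.pair[1][0]))


@dataclass
class Resolution:
    status: str                   # unambiguous | ambiguous | unassigned
    chosen: AssignmentCandidate | None = None
    survivors: list = field(default_factory=list)
    reason: str = ""


@dataclass
class PeakContext:
    """Candidate residue pairs of every peak, for spin-system corroboration."""

    by_peak: dict = field(default_factory=dict)
    # peak_id -> (experiment, set of frozenset residue pairs)

    def __post_init__(self):
        self._index: dict = {}
        for pid, (exp, pairs) in self.by_peak.items():
            for rp in pairs:
                self._index.setdefault((exp, rp), set()).add(pid)

    def corroboration(self, peak_id: int, experiment: str,
                      residue_pair: frozenset) -> int:
        pids = self._index.get((experiment, residue_pair), set())
        return len(pids) - (1 if peak_id in pids else 0)


def _dim_tolerances(peak: CrossPeak, cfg: AssignmentConfig) -> tuple:
    try:
        elements = _EXPERIMENT_DIMS[peak.experiment]
    except KeyError:
        raise ValueError(f"unknown experiment tag {peak.experiment!r}")
    if len(elements) != peak.dims:
        raise ValueError(
            f"{peak.experiment} expects {len(elements)} dims, peak has "
            f"{peak.dims}")
    tols = tuple(cfg.tol_N if e == "N" else cfg.tol_C for e in elements)
    return elements, tols


def match_candidates(peak: CrossPeak, shifts: ShiftTable,
                     scheme: LabelingScheme, cfg: AssignmentConfig
                     ) -> list:
    """All atom pairs matching every dimension within tolerance and passing
    the labeling observability filter, sorted by total shift deviation.

    For 3-D peaks the restraint pair comes from the last two dimensions;
    the first (nitrogen) dimension acts as an amide filter on the residue
    of the second-dimension atom.
    """
    if len(shifts) == 0:
        return []
    elements, tols = _dim_tolerances(peak, cfg)
    labeling_exp = CC if peak.experiment == "CORD" else NC

    matches = [shifts.atoms_near(w, tol, element=e)
               for w, tol, e in zip(peak.shifts, tols, elements)]

    if peak.dims == 3:
        # amide filter: dim-2 atom's residue must carry an N shift matching dim 1
        n_ok = {m[0] for m in matches[0]}
        pair_dims = (1, 2)
    else:
        n_ok = None
        pair_dims = (0, 1)

    out = []
    da, db = pair_dims
    for ra, ta, aa, sa in matches[da]:
        if n_ok is not None and ra not in n_ok:
            continue
        for rb, tb, ab, sb in matches[db]:
            if (ra, aa) == (rb, ab):
                continue
            if not pair_observable(scheme, (ta, aa), (tb, ab), labeling_exp,
                                   cfg.labeling_threshold):
                continue
            devs = (abs(sa - peak.shifts[da]), abs(sb - peak.shifts[db]))
            out.append(AssignmentCandidate(
                pair=((ra, aa), (rb, ab)), res_types=(ta, tb),
                deviations=devs, intra=(ra == rb),
                sequential=(abs(ra - rb) == 1)))
    out.sort(key=lambda c: (c.total_deviation, c.pair))
    return out


def resolve_unambiguity(candidates: list, peak: CrossPeak | None = None,
                        context: PeakContext | None = None) -> Resolution:
    """Apply the unambiguity criteria in order; conflicts demote to ambiguous."""
    if not candidates:
        return Resolution(status="unassigned", reason="no shift match")
    if len(candidates) == 1:
        return Resolution(status="unambiguous", chosen=candidates[0],
                          reason="unique match")

    picks = []
    intra = [c for c in candidates if c.intra]
    if len(intra) == 1:
        picks.append(("intra-residue", intra[0]))
    seq = [c for c in candidates if c.sequential]
    if len(seq) == 1:
        picks.append(("sequential", seq[0]))
    if context is not None and peak is not None:
        corrob = []
        for c in candidates:
            n = context.corroboration(peak.peak_id, peak.experiment,
                                      c.residue_pair)
            if n >= 2:
                corrob.append(replace(c, spin_system_corroborated=True))
        if len(corrob) == 1:
            picks.append(("spin-system", corrob[0]))

    chosen_pairs = {p[1].pair for p in picks}
    if len(chosen_pairs) == 1:
        reason, cand = picks[0]
        return Resolution(status="unambiguous", chosen=cand, reason=reason)
    if len(chosen_pairs) > 1:
        return Resolution(status="ambiguous", survivors=list(candidates),
                          reason="criteria conflict")
    return Resolution(status="ambiguous", survivors=list(candidates),
                      reason="no criterion applies")


def homolog_distance_filter(candidates: list, homolog: StructureModel,
                            cfg: AssignmentConfig,
                            residue_map: dict | None = None) -> list:
    """Drop candidates farther than ``homolog_cutoff`` in a homolog structure.

    Candidates whose atoms the homolog lacks are kept and flagged
    ``unfilterable`` (conservative).  Survivors carry the homolog distance.
    """
    out = []
    for c in candidates:
        (ri, ai), (rj, aj) = c.pair
        if residue_map is not None:
            ri = residue_map.get(ri, ri)
            rj = residue_map.get(rj, rj)
        try:
            ka = homolog.atom_index(ri, ai)
            kb = homolog.atom_index(rj, aj)
        except KeyError:
            out.append(replace(c, unfilterable=True))
            continue
        d = float(np.linalg.norm(homolog.coords[ka] - homolog.coords[kb]))
        if d > cfg.homolog_cutoff:
            continue
        out.append(replace(c, homolog_distance=d))
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class AssignmentResult:
    restraints: RestraintSet
    audit: list = field(default_factory=list)
    # audit rows: dict(peak_id, status, reason, n_candidates)

    def recovery(self, truth) -> dict:
        """Compare unambiguous restraints against a generator truth map.

        Returns recovered fraction of truth pairs, plus the count of
        unambiguous restraints whose pair is not a truth pair at all.
        """
        truth_pairs = {frozenset(p) for p in truth.peak_truth.values()}
        assigned = {frozenset(r.options[0]) for r in self.restraints.unambiguous}
        recovered = truth_pairs & assigned
        return {
            "n_truth_pairs": len(truth_pairs),
            "n_unambiguous": len(assigned),
            "recovered_fraction": len(recovered) / len(truth_pairs)
            if truth_pairs else 1.0,
            "false_unambiguous": len(assigned - truth_pairs),
        }


def _canonical_pair(pair: tuple) -> tuple:
    return tuple(sorted(pair))


def _restraint_kind(pair: tuple) -> str:
    return "intra-residue" if pair[0][0] == pair[1][0] else "inter-residue"


def assign_peaklist(peaks: PeakList, shifts: ShiftTable,
                    scheme: LabelingScheme,
                    homolog: StructureModel | None = None,
                    cfg: AssignmentConfig | None = None,
                    residue_map: dict | None = None) -> AssignmentResult:
    """Full pipeline: match -> resolve -> homolog filter -> cap -> restraints.

    Identical pairs arising from multiple peaks are merged into one
    restraint (non-redundant set); every peak's fate is recorded in the
    audit with a reason.
    """
    cfg = cfg or AssignmentConfig()

    all_candidates = {p.peak_id: match_candidates(p, shifts, scheme, cfg)
                      for p in peaks}
    context = PeakContext(by_peak={
        p.peak_id: (p.experiment,
                    {c.residue_pair for c in all_candidates[p.peak_id]})
        for p in peaks})

    unambig: dict = {}   # canonical pair -> (candidate, peak_ids, experiment)
    ambig: dict = {}     # frozenset of canonical pairs -> (options, peak_ids, exp)
    audit = []

    for peak in peaks:
        cands = all_candidates[peak.peak_id]
        res = resolve_unambiguity(cands, peak, context)

        if res.status == "ambiguous" and homolog is not None:
            filtered = homolog_distance_filter(res.survivors, homolog, cfg,
                                               residue_map)
            if not filtered:
                res = Resolution(status="unassigned",
                                 reason="all candidates beyond homolog cutoff")
            elif len(filtered) == 1:
                res = Resolution(status="unambiguous", chosen=filtered[0],
                                 reason="homolog distance filter")
            else:
                res = resolve_unambiguity(filtered, peak, context)
                if res.status == "ambiguous":
                    res.reason += " (after homolog filter)"

        if res.status == "unassigned":
            audit.append({"peak_id": peak.peak_id, "status": "unassigned",
                          "reason": res.reason, "n_candidates": len(cands)})
            logger.debug("peak %d unassigned: %s", peak.peak_id, res.reason)
            continue

        if res.status == "unambiguous":
            key = _canonical_pair(res.chosen.pair)
            entry = unambig.setdefault(key, ([], peak.experiment))
            entry[0].append(peak.peak_id)
            audit.append({"peak_id": peak.peak_id, "status": "unambiguous",
                          "reason": res.reason, "n_candidates": len(cands)})
            continue

        survivors = res.survivors
        if len(survivors) > cfg.max_candidates:
            audit.append({"peak_id": peak.peak_id, "status": "discarded",
                          "reason": f"{len(survivors)} possibilities exceed "
                                    f"cap of {cfg.max_candidates}",
                          "n_candidates": len(cands)})
            logger.debug("peak %d discarded: too many possibilities",
                         peak.peak_id)
            continue
        key = frozenset(_canonical_pair(c.pair) for c in survivors)
        entry = ambig.setdefault(key, ([], peak.experiment))
        entry[0].append(peak.peak_id)
        audit.append({"peak_id": peak.peak_id, "status": "ambiguous",
                      "reason": res.reason, "n_candidates": len(survivors)})

    restraints = []
    for pair, (pids, exp) in sorted(unambig.items()):
        lo, hi = to_bounds(_restraint_kind(pair), cfg.bounds)
        restraints.append(DistanceRestraint(
            options=(pair,), lower=lo, upper=hi, experiment=exp,
            peak_ids=tuple(sorted(pids))))
    for key, (pids, exp) in sorted(ambig.items(), key=lambda kv: sorted(kv[0])):
        opts = tuple(sorted(key))
        kind = ("intra-residue"
                if all(_restraint_kind(o) == "intra-residue" for o in opts)
                else "inter-residue")
        lo, hi = to_bounds(kind, cfg.bounds)
        restraints.append(DistanceRestraint(
            options=opts, lower=lo, upper=hi, experiment=exp,
            peak_ids=tuple(sorted(pids))))

    return AssignmentResult(restraints=RestraintSet(restraints), audit=audit)


def refilter_region(rset: RestraintSet, new_structure: StructureModel,
                    region: tuple, cfg: AssignmentConfig | None = None
                    ) -> tuple:
    """Re-inspect restraints touching a residue region against a new structure.

    Returns ``(rset, report)``; nothing is removed automatically — the
    report lists proposed actions (idempotent for identical inputs).
    Report rows: restraint index, action in {keep, remove, unfilterable,
    outside-region}, distance in the new structure.
    """
    cfg = cfg or AssignmentConfig()
    report = []
    if region is None or (region[1] < region[0]):
        logger.warning("refilter_region: empty region, nothing to do")
        return rset, report
    lo_res, hi_res = int(region[0]), int(region[1])

    for idx, r in enumerate(rset):
        touches = any(lo_res <= res <= hi_res
                      for opt in r.options for (res, _a) in opt)
        if not touches:
            report.append({"restraint": idx, "action": "outside-region",
                           "distance": None})
            continue
        dists = []
        missing = False
        for (ri, ai), (rj, aj) in r.options:
            try:
                ka = new_structure.atom_index(ri, ai)
                kb = new_structure.atom_index(rj, aj)
            except KeyError:
                missing = True
                continue
            dists.append(float(np.linalg.norm(
                new_structure.coords[ka] - new_structure.coords[kb])))
        if not dists:
            report.append({"restraint": idx, "action": "unfilterable",
                           "distance": None})
            continue
        dmin = min(dists)
        action = "remove" if dmin > cfg.homolog_cutoff else "keep"
        report.append({"restraint": idx, "action": action,
                       "distance": round(dmin, 3)})
    return rset, report
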