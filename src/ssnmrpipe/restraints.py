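"""Distance/torsion restraint model, statistics and file I/O.

Sequence-separation categories partition |i-j| as 0 (intra), 1
(sequential), 2..4 (medium) and >=5 (long).  The printed category table
this mirrors leaves |i-j| = 4 unassigned between "medium" and "long";
here it belongs to medium by default (``medium_max`` switches it).

Supported dialects: a lossless native TSV, the XPLOR/CNS NOE ``assign``
table (read/write, OR-groups supported), minimal NMR-STAR v3 restraint
loops (read) and TALOS-style torsion prediction tables (read).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import StructureBundle, StructureModel

INTRA = "intra"
SEQUENTIAL = "sequential"
MEDIUM = "medium"
LONG = "long"

#: correlation-to-distance bound constants (Angstrom)
DEFAULT_BOUNDS = {"intra-residue": (1.5, 6.5), "inter-residue": (2.0, 7.2)}


def classify(separation: int, medium_max: int = 4) -> str:
    """Category for a sequence separation |i-j|."""
    if separation < 0:
        raise ValueError("sequence separation must be >= 0")
    if separation == 0:
        return INTRA
    if separation == 1:
        return SEQUENTIAL
    if separation <= medium_max:
        return MEDIUM
    return LONG


def to_bounds(kind: str, bounds: dict | None = None) -> tuple:
    """Distance boundary (lower, upper) for a restraint kind."""
    table = DEFAULT_BOUNDS if bounds is None else bounds
    try:
        lo, hi = table[kind]
    except KeyError:
        raise ValueError(f"unknown restraint kind {kind!r}; "
                         f"expected one of {sorted(table)}")
    if not lo < hi:
        raise ValueError(f"bounds for {kind!r} must satisfy lower < upper")
    return (float(lo), float(hi))


@dataclass(frozen=True)
class DistanceRestraint:
    """Atom-pair (or ambiguous OR-group) distance restraint.

    ``options`` is a tuple of ``((res_i, atom_i), (res_j, atom_j))``
    candidates; a single option is an unambiguous restraint.
    """

    options: tuple
    lower: float
    upper: float
    experiment: str = ""
    peak_ids: tuple = ()

    def __post_init__(self):
        if not self.options:
            raise ValueError("restraint needs at least one atom-pair option")
        if not 0 < self.lower < self.upper:
            raise ValueError(f"invalid bounds ({self.lower}, {self.upper})")
        opts = tuple(
            (((int(a[0]), str(a[1])), (int(b[0]), str(b[1]))))
            for a, b in self.options)
        object.__setattr__(self, "options", opts)

    @property
    def ambiguous(self) -> bool:
        return len(self.options) > 1

    @property
    def separation(self) -> int:
        """|i-j| (minimum over options for ambiguous groups)."""
        return min(abs(a[0] - b[0]) for a, b in self.options)

    @property
    def category(self) -> str:
        return classify(self.separation)

    @property
    def nucleus_pair(self) -> str:
        """'CC' or 'NC' from the first option's atom names."""
        (_, a), (_, b) = self.options[0]
        n_count = sum(1 for x in (a, b) if x.startswith("N"))
        return "NC" if n_count == 1 else "CC"


@dataclass(frozen=True)
class TorsionRestraint:
    res_index: int
    angle: str          # "phi" | "psi"
    center: float       # degrees in (-180, 180]
    half_width: float   # degrees

    def __post_init__(self):
        if self.angle not in ("phi", "psi"):
            raise ValueError(f"unknown torsion angle {self.angle!r}")
        if not -180.0 < self.center <= 180.0:
            raise ValueError("center must lie in (-180, 180]")
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")


@dataclass
class RestraintSet:
    restraints: list = field(default_factory=list)

    def __len__(self):
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, i):
        return self.restraints[i]

    @property
    def unambiguous(self) -> list:
        return [r for r in self.restraints if not r.ambiguous]

    @property
    def ambiguous(self) -> list:
        return [r for r in self.restraints if r.ambiguous]


# ---------------------------------------------------------------------------
# statistics


def tabulate(rset: RestraintSet) -> pd.DataFrame:
    """Category count table: unambiguous per category, ambiguous, CC/NC split."""
    cats = [INTRA, SEQUENTIAL, MEDIUM, LONG]
    counts = {c: {"CC": 0, "NC": 0} for c in cats}
    n_ambig = {"CC": 0, "NC": 0}
    for r in rset:
        if r.ambiguous:
            n_ambig[r.nucleus_pair] += 1
        else:
            counts[r.category][r.nucleus_pair] += 1
    rows = []
    for c in cats:
        rows.append({"category": c, "CC_unambiguous": counts[c]["CC"],
                     "NC": counts[c]["NC"],
                     "total": counts[c]["CC"] + counts[c]["NC"]})
    total_unambig = sum(r["total"] for r in rows)
    rows.append({"category": "ambiguous",
                 "CC_unambiguous": 0, "NC": 0,
                 "total": n_ambig["CC"] + n_ambig["NC"]})
    rows.append({"category": "total_unambiguous",
                 "CC_unambiguous": sum(counts[c]["CC"] for c in cats),
                 "NC": sum(counts[c]["NC"] for c in cats),
                 "total": total_unambig})
    return pd.DataFrame(rows)


def per_residue_counts(rset: RestraintSet, include_ambiguous: bool = False
                       ) -> dict:
    """Restraint count per residue (each restraint increments both partners)."""
    counts: dict = {}
    for r in rset:
        if r.ambiguous and not include_ambiguous:
            continue
        (i, _), (j, _) = r.options[0]
        counts[i] = counts.get(i, 0) + 1
        counts[j] = counts.get(j, 0) + 1
    return counts


@dataclass
class ViolationReport:
    per_model_distance_mean: np.ndarray   # (n_models,)
    max_distance: float
    per_model_torsion_mean: np.ndarray | None = None
    max_torsion: float | None = None

    @property
    def distance_mean(self) -> float:
        return float(np.mean(self.per_model_distance_mean))

    @property
    def distance_sd(self) -> float:
        return float(np.std(self.per_model_distance_mean, ddof=1)) \
            if len(self.per_model_distance_mean) > 1 else 0.0

    @property
    def torsion_mean(self) -> float | None:
        if self.per_model_torsion_mean is None:
            return None
        return float(np.mean(self.per_model_torsion_mean))


def _wrap_angle(deg: np.ndarray) -> np.ndarray:
    """Wrap degrees into (-180, 180]."""
    return -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees) over four points."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_torsion(model: StructureModel, res_index: int, angle: str
                     ) -> float:
    """phi/psi for one residue (KeyError when flanking atoms are absent)."""
    ai = model.atom_index
    if angle == "phi":
        pts = [ai(res_index - 1, "C"), ai(res_index, "N"),
               ai(res_index, "CA"), ai(res_index, "C")]
    elif angle == "psi":
        pts = [ai(res_index, "N"), ai(res_index, "CA"),
               ai(res_index, "C"), ai(res_index + 1, "N")]
    else:
        raise ValueError(f"unknown torsion angle {angle!r}")
    c = model.coords
    return dihedral(c[pts[0]], c[pts[1]], c[pts[2]], c[pts[3]])


def _effective_distance(model: StructureModel, restraint: DistanceRestraint,
                        index_cache: dict) -> float:
    """r^-6-summed effective distance over the restraint's options."""
    inv6 = 0.0
    missing = []
    for (i, a), (j, b) in restraint.options:
        try:
            ka = index_cache.get((i, a))
            if ka is None:
                ka = index_cache[(i, a)] = model.atom_index(i, a)
            kb = index_cache.get((j, b))
            if kb is None:
                kb = index_cache[(j, b)] = model.atom_index(j, b)
        except KeyError:
            missing.append(f"{i}/{a}-{j}/{b}")
            continue
        d = float(np.linalg.norm(model.coords[ka] - model.coords[kb]))
        inv6 += d ** -6
    if inv6 == 0.0:
        raise KeyError(
            "restraint atoms unresolvable in bundle topology: "
            + ", ".join(missing))
    return inv6 ** (-1.0 / 6.0)


def compute_violations(bundle: StructureBundle, restraints: RestraintSet,
                       torsions: list | None = None) -> ViolationReport:
    """Distance/torsion violations per model, aggregated across the bundle.

    Distance violation per restraint is ``max(0, d - upper, lower - d)``
    with ambiguous groups collapsed by r^-6 summation; torsion violation is
    the angular excess beyond ``center +- half_width`` after periodic wrap.
    """
    per_model_d, max_d = [], 0.0
    cache: dict = {}
    for model in bundle:
        viols = []
        for r in restraints:
            # atom ordering is shared across the bundle, so one index cache
            d = _effective_distance(model, r, cache)
            v = max(0.0, d - r.upper, r.lower - d)
            viols.append(v)
            max_d = max(max_d, v)
        per_model_d.append(float(np.mean(viols)) if viols else 0.0)

    per_model_t, max_t = None, None
    if torsions:
        per_model_t, max_t = [], 0.0
        for model in bundle:
            viols = []
            for t in torsions:
                try:
                    ang = backbone_torsion(model, t.res_index, t.angle)
                except KeyError:
                    continue  # chain-terminal torsion not computable
                excess = max(0.0, abs(float(_wrap_angle(ang - t.center)))
                             - t.half_width)
                viols.append(excess)
                max_t = max(max_t, excess)
            per_model_t.append(float(np.mean(viols)) if viols else 0.0)
        per_model_t = np.array(per_model_t)

    return ViolationReport(
        per_model_distance_mean=np.array(per_model_d),
        max_distance=max_d,
        per_model_torsion_mean=per_model_t,
        max_torsion=max_t)


# ---------------------------------------------------------------------------
# native TSV dialect (lossless round-trip)


def write_tsv(rset: RestraintSet, path) -> None:
    rows = []
    for rid, r in enumerate(rset):
        for m, ((i, a), (j, b)) in enumerate(r.options):
            rows.append({"restraint_id": rid, "member": m,
                         "res_i": i, "atom_i": a, "res_j": j, "atom_j": b,
                         "lower": r.lower, "upper": r.upper,
                         "experiment": r.experiment,
                         "peak_ids": ";".join(str(p) for p in r.peak_ids)})
    pd.DataFrame(rows, columns=["restraint_id", "member", "res_i", "atom_i",
                                "res_j", "atom_j", "lower", "upper",
                                "experiment", "peak_ids"]
                 ).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> RestraintSet:
    df = pd.read_csv(path, sep="\t", dtype={"experiment": str,
                                            "peak_ids": str})
    if len(df) == 0:
        return RestraintSet([])
    out = []
    for _, grp in df.groupby("restraint_id", sort=True):
        grp = grp.sort_values("member")
        opts = tuple(((int(r.res_i), str(r.atom_i)),
                      (int(r.res_j), str(r.atom_j)))
                     for r in grp.itertuples())
        first = grp.iloc[0]
        exp = "" if pd.isna(first.experiment) else str(first.experiment)
        pk = () if pd.isna(first.peak_ids) or first.peak_ids == "" else \
            tuple(int(x) for x in str(first.peak_ids).split(";"))
        out.append(DistanceRestraint(options=opts, lower=float(first.lower),
                                     upper=float(first.upper),
                                     experiment=exp, peak_ids=pk))
    return RestraintSet(out)


# ---------------------------------------------------------------------------
# XPLOR/CNS NOE table dialect

_XPLOR_SEL = re.compile(
    r"\(\s*resid\s+(\d+)\s+and\s+name\s+([A-Za-z0-9#*]+)\s*\)", re.I)
_XPLOR_NUMS = re.compile(r"(-?\d+\.?\d*)\s+(-?\d+\.?\d*)\s+(-?\d+\.?\d*)\s*$")


def write_xplor(rset: RestraintSet, path) -> None:
    """Emit ``assign (resid i and name X)(resid j and name Y) d dminus dplus``.

    Bounds encode as d = (lower+upper)/2 with symmetric dminus/dplus, so
    d - dminus = lower and d + dplus = upper.
    """
    lines = []
    for r in rset:
        d = (r.lower + r.upper) / 2.0
        half = (r.upper - r.lower) / 2.0
        (i, a), (j, b) = r.options[0]
        lines.append(f"assign (resid {i} and name {a})"
                     f"(resid {j} and name {b}) "
                     f"{d:.3f} {half:.3f} {half:.3f}")
        for (i2, a2), (j2, b2) in r.options[1:]:
            lines.append(f"    or (resid {i2} and name {a2})"
                         f"(resid {j2} and name {b2})")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_xplor(path) -> RestraintSet:
    out = []
    current = None  # (options, lower, upper)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("!", "#")):
                continue
            low = line.lower()
            if low.startswith("assign"):
                if current is not None:
                    out.append(DistanceRestraint(
                        options=tuple(current[0]), lower=current[1],
                        upper=current[2]))
                sels = _XPLOR_SEL.findall(line)
                nums = _XPLOR_NUMS.search(line)
                if len(sels) != 2 or nums is None:
                    raise ValueError(f"{path}:{lineno}: malformed assign line")
                d, dminus, dplus = (float(x) for x in nums.groups())
                opt = ((int(sels[0][0]), sels[0][1].upper()),
                       (int(sels[1][0]), sels[1][1].upper()))
                current = ([opt], d - dminus, d + dplus)
            elif low.startswith("or"):
                if current is None:
                    raise ValueError(f"{path}:{lineno}: 'or' before 'assign'")
                sels = _XPLOR_SEL.findall(line)
                if len(sels) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed or line")
                current[0].append(((int(sels[0][0]), sels[0][1].upper()),
                                   (int(sels[1][0]), sels[1][1].upper())))
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized line {line!r}")
    if current is not None:
        out.append(DistanceRestraint(options=tuple(current[0]),
                                     lower=current[1], upper=current[2]))
    return RestraintSet(out)


# ---------------------------------------------------------------------------
# minimal NMR-STAR v3 restraint loops (read only)


def _star_loops(text: str):
    """Yield (tags, rows) for every loop in a STAR file (tolerant tokenizer)."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip() == "loop_":
            tags = []
            i += 1
            while i < len(lines) and lines[i].strip().startswith("_"):
                tags.append(lines[i].strip().split()[0])
                i += 1
            rows = []
            while i < len(lines):
                s = lines[i].strip()
                if s in ("stop_",) or s.startswith(("loop_", "save_")):
                    break
                if s and not s.startswith("#"):
                    rows.append(s.split())
                i += 1
            yield tags, rows
        i += 1


def _tag_col(tags: list, suffix: str) -> int | None:
    for k, t in enumerate(tags):
        if t.split(".")[-1] == suffix:
            return k
    return None


def read_nmrstar(path) -> tuple:
    """Extract distance and dihedral restraints from an NMR-STAR v3 file.

    Returns ``(RestraintSet, list_of_TorsionRestraint)``.  Ambiguity is
    reconstructed from shared ``ID`` values within a distance-constraint
    loop (both OR-group and per-pair listings collapse correctly).
    """
    text = open(path).read()
    dists, torsions = [], []
    for tags, rows in _star_loops(text):
        if not tags:
            continue
        prefix = tags[0].split(".")[0]
        if prefix == "_Gen_dist_constraint":
            cid = _tag_col(tags, "ID")
            ci1 = _tag_col(tags, "Comp_index_ID_1")
            ca1 = _tag_col(tags, "Atom_ID_1")
            ci2 = _tag_col(tags, "Comp_index_ID_2")
            ca2 = _tag_col(tags, "Atom_ID_2")
            clo = _tag_col(tags, "Distance_lower_bound_val")
            cup = _tag_col(tags, "Distance_upper_bound_val")
            if None in (cid, ci1, ca1, ci2, ca2, clo, cup):
                continue
            groups: dict = {}
            for row in rows:
                if len(row) < len(tags):
                    raise ValueError(f"{path}: short row in distance loop")
                gid = row[cid]
                opt = ((int(row[ci1]), row[ca1]), (int(row[ci2]), row[ca2]))
                lo = float(row[clo]) if row[clo] not in (".", "?") else 1.8
                up = float(row[cup])
                groups.setdefault(gid, ([], lo, up))[0].append(opt)
            for gid, (opts, lo, up) in groups.items():
                # drop exact duplicates while preserving order
                seen, uniq = set(), []
                for o in opts:
                    if o not in seen:
                        seen.add(o)
                        uniq.append(o)
                dists.append(DistanceRestraint(options=tuple(uniq),
                                               lower=lo, upper=up))
        elif prefix == "_Torsion_angle_constraint":
            ci = _tag_col(tags, "Comp_index_ID_2")
            cname = _tag_col(tags, "Torsion_angle_name")
            clo = _tag_col(tags, "Angle_lower_bound_val")
            cup = _tag_col(tags, "Angle_upper_bound_val")
            if None in (ci, cname, clo, cup):
                continue
            for row in rows:
                name = row[cname].strip("'\"").lower()
                if name not in ("phi", "psi"):
                    continue
                lo, up = float(row[clo]), float(row[cup])
                center = _wrap_angle((lo + up) / 2.0)
                half = (up - lo) / 2.0
                if half <= 0:
                    half = 20.0
                torsions.append(TorsionRestraint(
                    res_index=int(row[ci]), angle=name,
                    center=float(center), half_width=half))
    return RestraintSet(dists), torsions


# ---------------------------------------------------------------------------
# TALOS-style torsion prediction tables (read only)


def read_talos(path, fallback_half_width: float = 20.0) -> list:
    """Torsion restraints from a TALOS ``pred.tab``-style table.

    Uses the DPHI/DPSI uncertainty columns as half-widths, with a fixed
    fallback when they are zero or missing; rows classified as unreliable
    (``CLASS`` not Good/Strong/Generous) are skipped.
    """
    vars_line = None
    rows = []
    for raw in open(path):
        s = raw.strip()
        if not s or s.startswith(("REMARK", "DATA", "FORMAT")):
            continue
        if s.startswith("VARS"):
            vars_line = s.split()[1:]
            continue
        rows.append(s.split())
    if vars_line is None:
        raise ValueError(f"{path}: no VARS header found")
    col = {name: k for k, name in enumerate(vars_line)}
    for need in ("RESID", "PHI", "PSI"):
        if need not in col:
            raise ValueError(f"{path}: missing column {need}")
    out = []
    for row in rows:
        if "CLASS" in col and row[col["CLASS"]] not in (
                "Good", "Strong", "Generous"):
            continue
        resid = int(row[col["RESID"]])
        for angle, dcol in (("phi", "DPHI"), ("psi", "DPSI")):
            val = float(row[col[angle.upper()]])
            if abs(val) > 360:       # 9999.000 convention for 'no prediction'
                continue
            half = fallback_half_width
            if dcol in col:
                dval = float(row[col[dcol]])
                if dval > 0:
                    half = dval
            out.append(TorsionRestraint(res_index=resid, angle=angle,
                                        center=float(_wrap_angle(val)),
                                        half_width=half))
    return out
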