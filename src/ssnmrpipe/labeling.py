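"""Sparse isotope-labeling schemes and pair observability.

A scheme maps ``(residue_type, atom_name) -> label fraction`` and records
whether nitrogen sites are uniformly labeled.  Lookup resolves in order:
exact ``(res, atom)``, wildcard residue ``(*, atom)``, wildcard atom
``(res, *)``, then global ``(*, *)``; in strict mode an unresolved pair
raises instead of falling through to wildcards beyond the exact entry.

The packaged sparse-glucose tables are literature-derived approximations
of biosynthetic labeling patterns and are deliberately user-overridable
data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

CC = "CC"
NC = "NC"

DEFAULT_THRESHOLD = 0.1


class LabelingError(ValueError):
    pass


@dataclass
class LabelingScheme:
    name: str
    table: dict = field(default_factory=dict)
    nitrogen_labeled: bool = True
    strict: bool = False

    def __post_init__(self) -> None:
        for (res, atom), frac in self.table.items():
            if not 0.0 <= float(frac) <= 1.0:
                raise LabelingError(
                    f"fraction {frac} for ({res}, {atom}) outside [0, 1]")

    def fraction(self, res_type: str, atom_name: str) -> float:
        """Label fraction for one site (wildcard fallback, see module docs)."""
        for key in ((res_type, atom_name), ("*", atom_name),
                    (res_type, "*"), ("*", "*")):
            if key in self.table:
                if self.strict and key != (res_type, atom_name):
                    break
                return float(self.table[key])
        raise LabelingError(
            f"labeling scheme {self.name!r} has no entry for "
            f"({res_type}, {atom_name})")

    def is_observable(self, res_type: str, atom_name: str,
                      threshold: float = DEFAULT_THRESHOLD) -> bool:
        if atom_name.startswith("N"):
            return self.nitrogen_labeled
        return self.fraction(res_type, atom_name) > threshold


def uniform_scheme(name: str = "U-13C6") -> LabelingScheme:
    """Uniform 13C / 15N labeling: every carbon fraction 1.0."""
    return LabelingScheme(name=name, table={("*", "*"): 1.0},
                          nitrogen_labeled=True)


_BUILTIN_FILES = {
    "2-13C-glucose": "scheme_2_13C_glucose.tsv",
    "1,6-13C-glucose": "scheme_16_13C_glucose.tsv",
}


def load_scheme(source) -> LabelingScheme:
    """Load a scheme by built-in name or from a TSV table file.

    The TSV has a header ``residue_type\tatom_name\tfraction`` plus optional
    ``# nitrogen_labeled: true|false`` comment; ``*`` wildcards allowed.
    """
    if isinstance(source, str) and source in ("U-13C6", "U13C6"):
        return uniform_scheme()
    if isinstance(source, str) and source in _BUILTIN_FILES:
        ref = resources.files("ssnmrpipe.data") / _BUILTIN_FILES[source]
        return _parse_scheme_text(ref.read_text(), name=source)
    path = Path(source)
    if not path.exists():
        raise LabelingError(f"unknown scheme or missing file: {source}")
    return _parse_scheme_text(path.read_text(), name=path.stem)


def _parse_scheme_text(text: str, name: str) -> LabelingScheme:
    table: dict = {}
    nitrogen = True
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "nitrogen_labeled" in line:
                nitrogen = line.split(":")[-1].strip().lower() in ("true", "1", "yes")
            continue
        parts = line.split("\t")
        if parts[0] == "residue_type":
            continue
        if len(parts) != 3:
            raise LabelingError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        res, atom, frac_s = parts
        try:
            frac = float(frac_s)
        except ValueError as exc:
            raise LabelingError(f"line {lineno}: non-numeric fraction {frac_s!r}") from exc
        if not 0.0 <= frac <= 1.0:
            raise LabelingError(f"line {lineno}: fraction {frac} outside [0, 1]")
        table[(res, atom)] = frac
    return LabelingScheme(name=name, table=table, nitrogen_labeled=nitrogen)


def pair_observable(scheme: LabelingScheme, a, b, experiment: str,
                    threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Can sites ``a`` and ``b`` (``(res_type, atom_name)`` tuples) correlate?

    ``CC`` needs both carbon fractions above ``threshold``; ``NC`` needs one
    nitrogen site (observable only under uniform 15N labeling) and one
    carbon above threshold.
    """
    if experiment == CC:
        return (scheme.fraction(*a) > threshold
                and scheme.fraction(*b) > threshold)
    if experiment == NC:
        a_is_n = a[1].startswith("N")
        b_is_n = b[1].startswith("N")
        if a_is_n == b_is_n:
            return False
        n_site, c_site = (a, b) if a_is_n else (b, a)
        return scheme.nitrogen_labeled and scheme.fraction(*c_site) > threshold
    raise LabelingError(f"unknown experiment tag {experiment!r}")
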