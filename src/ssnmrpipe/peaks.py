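"""Cross-peak and chemical-shift-table containers with TSV I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CrossPeak:
    """One observed correlation: ``dims`` shift coordinates plus metadata."""

    shifts: tuple              # ppm per dimension
    experiment: str = "CORD"   # CORD, PAIN-CP, NCACX, NCOCX
    mixing_time: float = 50.0  # ms
    intensity: float | None = None
    peak_id: int = -1

    def __post_init__(self):
        object.__setattr__(self, "shifts", tuple(float(s) for s in self.shifts))
        if not all(np.isfinite(self.shifts)):
            raise ValueError("non-finite peak shift")

    @property
    def dims(self) -> int:
        return len(self.shifts)


@dataclass
class PeakList:
    peaks: list = field(default_factory=list)

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_tsv(self, path) -> None:
        rows = []
        for p in self.peaks:
            row = {"peak_id": p.peak_id, "experiment": p.experiment,
                   "mixing_time": p.mixing_time,
                   "intensity": "" if p.intensity is None else p.intensity}
            for d, s in enumerate(p.shifts, 1):
                row[f"w{d}"] = s
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PeakList":
        df = pd.read_csv(path, sep="\t")
        dim_cols = sorted(c for c in df.columns if c.startswith("w"))
        peaks = []
        for _, r in df.iterrows():
            inten = r.get("intensity")
            if inten is not None and (pd.isna(inten) or inten == ""):
                inten = None
            peaks.append(CrossPeak(
                shifts=tuple(float(r[c]) for c in dim_cols if not pd.isna(r[c])),
                experiment=str(r["experiment"]),
                mixing_time=float(r["mixing_time"]),
                intensity=None if inten is None else float(inten),
                peak_id=int(r["peak_id"])))
        return cls(peaks)


class ShiftTable:
    """Per-atom chemical-shift reference.

    One shift per ``(residue_index, atom_name)``; duplicate entries raise.
    """

    def __init__(self, entries):
        # entries: iterable of (res_index, res_type, atom_name, shift_ppm)
        self._map: dict = {}
        recs = []
        for res_index, res_type, atom_name, shift in entries:
            key = (int(res_index), str(atom_name))
            if key in self._map:
                raise ValueError(f"duplicate shift entry for {key}")
            if not np.isfinite(shift):
                raise ValueError(f"non-finite shift for {key}")
            self._map[key] = (str(res_type), float(shift))
            recs.append((int(res_index), str(res_type), str(atom_name),
                         float(shift)))
        self._records = recs
        self._res_index = np.array([r[0] for r in recs], dtype=int)
        self._res_type = np.array([r[1] for r in recs], dtype="U4")
        self._atom_name = np.array([r[2] for r in recs], dtype="U5")
        self._shift = np.array([r[3] for r in recs], dtype=float)
        order = np.argsort(self._shift, kind="stable")
        self._order = order
        self._sorted_shift = self._shift[order]

    def __len__(self):
        return len(self._records)

    def __contains__(self, key):
        return (int(key[0]), str(key[1])) in self._map

    def shift(self, res_index: int, atom_name: str) -> float:
        try:
            return self._map[(int(res_index), str(atom_name))][1]
        except KeyError:
            raise KeyError(f"no shift for residue {res_index} atom {atom_name}")

    def res_type(self, res_index: int, atom_name: str) -> str:
        return self._map[(int(res_index), str(atom_name))][0]

    def atoms_near(self, ppm: float, tol: float, element: str | None = None
                   ) -> list:
        """All ``(res_index, res_type, atom_name, shift)`` within ``tol`` ppm.

        ``element='C'``/``'N'`` restricts by atom-name leading character.
        """
        lo = np.searchsorted(self._sorted_shift, ppm - tol, side="left")
        hi = np.searchsorted(self._sorted_shift, ppm + tol, side="right")
        out = []
        for k in self._order[lo:hi]:
            name = self._atom_name[k]
            if element is not None and not name.startswith(element):
                continue
            out.append((int(self._res_index[k]), str(self._res_type[k]),
                        str(name), float(self._shift[k])))
        return out

    def to_tsv(self, path) -> None:
        pd.DataFrame(self._records, columns=[
            "res_index", "res_type", "atom_name", "shift_ppm"
        ]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ShiftTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df[["res_index", "res_type", "atom_name", "shift_ppm"]
                      ].itertuples(index=False, name=None))
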