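"""Chemical-shift referencing and secondary-structure classification.

Backbone 13C chemical shifts carry secondary structure: relative to the
random-coil value, Calpha and C' move downfield (positive secondary shift)
in alpha-helices and upfield in beta-sheets, while Cbeta moves the opposite
way.  This module applies the standard referencing corrections (TMS vs DSS
carbon scales differ by 2.67 ppm), computes secondary shifts against a
packaged random-coil table, and calls helix/sheet/coil per residue by a
majority vote over the available Calpha/Cbeta/C' shifts with a configurable
threshold tau (default 0.7 ppm).  15N shifts are parsed and stored but take
no part in the vote.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DSS_MINUS_TMS_PPM",
    "ShiftRecord",
    "RandomCoilTable",
    "ResidueClassification",
    "reference_correct",
    "secondary_shift",
    "classify_residue",
    "classify_table",
    "read_shift_table",
    "load_random_coil_table",
]

#: carbon chemical shifts on the DSS scale exceed the TMS scale by this amount
DSS_MINUS_TMS_PPM = 2.67

_ATOMS = ("CA", "CB", "C")
_CARBONS = ("CA", "CB", "C")
_SCHEMES = ("TMS", "DSS")
_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ShiftRecord:
    """One observed chemical shift."""

    index: int            # 1-based residue number
    residue: str          # one-letter code
    atom: str             # CA, CB, C (carbonyl) or N
    shift_ppm: float
    scheme: str = "DSS"
    conformer: str | None = None

    def __post_init__(self) -> None:
        if self.residue not in _AA:
            raise ValueError(f"unknown residue {self.residue!r}")
        if self.atom not in (*_ATOMS, "N"):
            raise ValueError(f"unknown atom {self.atom!r}")
        if self.residue == "G" and self.atom == "CB":
            raise ValueError("glycine has no CB")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown reference scheme {self.scheme!r}")
        if not np.isfinite(self.shift_ppm):
            raise ValueError("shift must be finite")


class RandomCoilTable:
    """Random-coil 13C shifts (DSS scale) for the 20 standard residues."""

    def __init__(self, frame: pd.DataFrame):
        need = {"residue", "CA", "CB", "C"}
        if not need.issubset(frame.columns):
            raise ValueError(f"random-coil table needs columns {sorted(need)}")
        self._table = frame.set_index("residue")
        missing = _AA - set(self._table.index)
        if missing:
            raise ValueError(f"random-coil table incomplete: missing {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RandomCoilTable":
        frame = pd.read_csv(path, sep="\t", comment="#",
                            names=["residue", "CA", "CB", "C"], na_values=["NA"])
        return cls(frame)

    def shift(self, residue: str, atom: str) -> float:
        if atom not in _CARBONS:
            raise KeyError(f"no random-coil reference for atom {atom!r}")
        try:
            v = self._table.at[residue, atom]
        except KeyError:
            raise KeyError(f"no random-coil entry for residue {residue!r}") from None
        if pd.isna(v):
            raise KeyError(f"no random-coil {atom} shift for residue {residue!r}")
        return float(v)


def load_random_coil_table() -> RandomCoilTable:
    """The packaged random-coil reference table."""
    ref = resources.files("fiberfold.data") / "random_coil_shifts.tsv"
    with resources.as_file(ref) as path:
        return RandomCoilTable.from_tsv(path)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def reference_correct(record: ShiftRecord, target: str = "DSS") -> ShiftRecord:
    """Convert a carbon shift between TMS and DSS referencing (idempotent)."""
    if target not in _SCHEMES:
        raise ValueError(f"unknown reference scheme {target!r}")
    if record.scheme == target or record.atom == "N":
        return replace(record, scheme=target) if record.atom == "N" else record
    delta = DSS_MINUS_TMS_PPM if target == "DSS" else -DSS_MINUS_TMS_PPM
    return replace(record, shift_ppm=record.shift_ppm + delta, scheme=target)


def secondary_shift(record: ShiftRecord, table: RandomCoilTable) -> float:
    """Secondary shift Delta-delta = observed - random coil (DSS scale)."""
    if record.scheme != "DSS":
        raise ValueError("record must be DSS-referenced; apply reference_correct first")
    return record.shift_ppm - table.shift(record.residue, record.atom)


@dataclass(frozen=True)
class ResidueClassification:
    """Per-residue class with the individual atom votes behind it."""

    index: int
    residue: str
    conformer: str | None
    secondary_shifts: dict  # atom -> Delta-delta (ppm)
    votes: dict             # atom -> helix | sheet | coil
    label: str              # helix | sheet | coil | ambiguous
    tau: float


def _vote(atom: str, dd: float, tau: float) -> str:
    """Sign convention: CA and C' move downfield in helices, upfield in
    sheets; CB the other way around."""
    sign = -1.0 if atom == "CB" else 1.0
    v = sign * dd
    if v > tau:
        return "helix"
    if v < -tau:
        return "sheet"
    return "coil"


def classify_residue(records: list[ShiftRecord], table: RandomCoilTable,
                     tau: float = 0.7) -> ResidueClassification:
    """Majority vote over the carbon secondary shifts of one residue.

    Ties and missing majorities yield ``ambiguous``.  15N records are
    ignored.
    """
    carbons = [r for r in records if r.atom in _CARBONS]
    if not carbons:
        raise ValueError("need at least one CA/CB/C shift")
    idx = {r.index for r in records}
    res = {r.residue for r in records}
    conf = {r.conformer for r in records}
    if len(idx) != 1 or len(res) != 1 or len(conf) != 1:
        raise ValueError("records must belong to a single residue/conformer group")
    dds, votes = {}, {}
    for r in carbons:
        r = reference_correct(r, "DSS")
        dd = secondary_shift(r, table)
        dds[r.atom] = dd
        votes[r.atom] = _vote(r.atom, dd, tau)
    counts = pd.Series(list(votes.values())).value_counts()
    label = "ambiguous"
    if counts.iloc[0] > len(votes) / 2:
        label = str(counts.index[0])
    return ResidueClassification(index=idx.pop(), residue=res.pop(),
                                 conformer=conf.pop(), secondary_shifts=dds,
                                 votes=votes, label=label, tau=tau)


def classify_table(records: list[ShiftRecord] | pd.DataFrame,
                   table: RandomCoilTable | None = None,
                   tau: float = 0.7) -> tuple[list[ResidueClassification], pd.DataFrame]:
    """Classify every (residue index, conformer) group in a shift table.

    Returns the per-group classifications and a residue-type x class
    cross-tab.  Multiple conformers of the same residue (distinct conformer
    labels at one index) are classified separately.
    """
    table = table or load_random_coil_table()
    if isinstance(records, pd.DataFrame):
        records = frame_to_records(records)
    groups: dict[tuple, list[ShiftRecord]] = {}
    for r in records:
        groups.setdefault((r.index, r.conformer), []).append(r)
    for (idx, _), grp in groups.items():
        if len({g.residue for g in grp}) != 1:
            raise ValueError(f"conflicting residue types at index {idx}")
    results = [classify_residue(grp, table, tau) for grp in groups.values()]
    results.sort(key=lambda c: (c.index, c.conformer or ""))
    summary = pd.crosstab([c.residue for c in results],
                          [c.label for c in results],
                          rownames=["residue"], colnames=["class"])
    return results, summary


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def frame_to_records(frame: pd.DataFrame) -> list[ShiftRecord]:
    out = []
    for _, row in frame.iterrows():
        conf = row.get("conformer")
        if pd.isna(conf) if conf is not None else True:
            conf = None
        out.append(ShiftRecord(index=int(row["index"]), residue=str(row["residue"]),
                               atom=str(row["atom"]), shift_ppm=float(row["shift_ppm"]),
                               scheme=str(row.get("scheme", "DSS")), conformer=conf))
    return out


def read_shift_table(path: str | Path) -> list[ShiftRecord]:
    """Read a TSV with columns index, residue, atom, shift_ppm, scheme
    and optional conformer."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    return frame_to_records(frame)
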