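"""Sequence-level fibrillation-hotspot analysis and steric-zipper geometry.

Short sequence segments can drive amyloid-like fibrillation by forming
steric zippers: two tightly interdigitated beta-sheets of the same
hexapeptide.  This module combines three per-residue evidence streams into
hotspot calls on a protein sequence:

* steric-zipper stability: per-hexapeptide Rosetta-scale energies (parsed
  from a ZipperDB-style TSV export) thresholded at -23 kcal/mol (inclusive),
* cross-beta aggregation propensity: per-residue percentages (TANGO-style
  export) thresholded on minimum run length,
* hydropathy: normalized Kyte-Doolittle sliding-window profiles.

It also measures the inter-sheet distance of a zipper structure (least-
squares plane fit to each sheet's C-alpha atoms) and computes peptide masses
including N-terminal acetylation, C-terminal amidation and disulfide-linked
dimers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.SeqUtils import molecular_weight

__all__ = [
    "KYTE_DOOLITTLE",
    "SequenceRecord",
    "HydropathyProfile",
    "ZipperWindow",
    "AggregationProfile",
    "HotspotSegment",
    "ZipperStructure",
    "hydropathy_profile",
    "call_zipper_hotspots",
    "call_aggregation_hotspots",
    "merge_segments",
    "consensus_hotspots",
    "intersheet_distance",
    "peptide_mass",
    "read_fasta",
    "read_zipper_windows",
    "read_aggregation_profile",
    "read_zipper_pdb",
    "write_zipper_pdb",
    "load_ct_helices",
    "HELIX4_PEPTIDE",
]

#: Kyte & Doolittle hydropathicity scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_KD_MIN, _KD_MAX = -4.5, 4.5
_AA = set(KYTE_DOOLITTLE)

#: the helix N4 region peptide (residues 51-80 of the CT domain),
#: N-terminally acetylated and C-terminally amidated
HELIX4_PEPTIDE_SEQ = "GASGCEVIVQALLEVITALVQIVSSSSVGY"

# modification mass deltas (Da): acetyl = +C2H2O, amide = +NH2 - OH
_ACETYL = {"average": 42.0367, "monoisotopic": 42.0106}
_AMIDE = {"average": -0.9848, "monoisotopic": -0.98402}
_H2 = {"average": 2.01588, "monoisotopic": 2.01565}


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with numbering offset and terminal modifications."""

    id: str
    sequence: str
    first_residue: int = 1
    n_term: str = "none"   # none | acetyl
    c_term: str = "none"   # none | amide

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence is empty")
        bad = set(self.sequence) - _AA
        if bad:
            raise ValueError(f"nonstandard residues {sorted(bad)}")
        if self.n_term not in ("none", "acetyl") or self.c_term not in ("none", "amide"):
            raise ValueError("unknown terminal modification")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def last_residue(self) -> int:
        return self.first_residue + len(self.sequence) - 1


HELIX4_PEPTIDE = SequenceRecord("CT_51-80_helix_N4", HELIX4_PEPTIDE_SEQ,
                                first_residue=51, n_term="acetyl", c_term="amide")


# ---------------------------------------------------------------------------
# hydropathy
# ---------------------------------------------------------------------------

@dataclass
class HydropathyProfile:
    """Normalized Kyte-Doolittle sliding-window means, one per residue.

    Scores are min-max normalized over the scale extremes so a poly-Ile
    window scores 1.0 and a poly-Arg window 0.0.  Residues whose window runs
    off the sequence ends are computed on the truncated window and flagged.
    """

    window: int
    scores: np.ndarray
    edge_flags: np.ndarray
    first_residue: int = 1

    def score_at(self, residue_number: int) -> float:
        return float(self.scores[residue_number - self.first_residue])

    def mean_over(self, start: int, end: int) -> float:
        i = start - self.first_residue
        j = end - self.first_residue + 1
        return float(np.mean(self.scores[i:j]))


def hydropathy_profile(seq: SequenceRecord, window: int = 9) -> HydropathyProfile:
    """Per-residue normalized Kyte-Doolittle hydropathy."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    vals = np.array([KYTE_DOOLITTLE[a] for a in seq.sequence])
    half = window // 2
    n = len(vals)
    scores = np.empty(n)
    edge = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        scores[i] = vals[lo:hi].mean()
        edge[i] = (hi - lo) < window
    scores = (scores - _KD_MIN) / (_KD_MAX - _KD_MIN)
    return HydropathyProfile(window=window, scores=scores, edge_flags=edge,
                             first_residue=seq.first_residue)


# ---------------------------------------------------------------------------
# hotspot calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZipperWindow:
    """A hexapeptide window with its steric-zipper stability energy."""

    start: int            # 1-based
    hexapeptide: str
    energy: float         # kcal/mol, Rosetta scale (more negative = stabler)
    intersheet_d: float | None = None  # Angstrom, when measured

    def __post_init__(self) -> None:
        if len(self.hexapeptide) != 6:
            raise ValueError("zipper windows are hexapeptides")

    @property
    def end(self) -> int:
        return self.start + 5


@dataclass
class AggregationProfile:
    """Per-residue cross-beta aggregation propensity in percent."""

    propensity: np.ndarray
    condition: str = ""
    first_residue: int = 1

    def __post_init__(self) -> None:
        self.propensity = np.asarray(self.propensity, dtype=float)
        if np.any((self.propensity < 0) | (self.propensity > 100)):
            raise ValueError("propensities must lie in [0, 100]")


@dataclass(frozen=True)
class HotspotSegment:
    """A sequence interval flagged as fibrillation-prone (1-based, inclusive)."""

    start: int
    end: int
    evidence: frozenset = frozenset()
    mean_hydropathy: float | None = None
    helix_overlap: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")
        if not self.evidence:
            raise ValueError("a hotspot needs at least one evidence flag")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def merge_segments(segments: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or directly adjacent intervals (idempotent)."""
    if not segments:
        return []
    segs = sorted(segments)
    out = [list(segs[0])]
    for s, e in segs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(se) for se in out]


def call_zipper_hotspots(windows: list[ZipperWindow],
                         threshold: float = -23.0) -> list[HotspotSegment]:
    """Maximal segments of hexapeptide windows at or below the energy
    threshold (inclusive: -23.0 qualifies, -22.9 does not)."""
    qual = [(w.start, w.end) for w in windows if w.energy <= threshold]
    return [HotspotSegment(s, e, frozenset({"zipper"}))
            for s, e in merge_segments(qual)]


def call_aggregation_hotspots(profile: AggregationProfile, cutoff: float = 5.0,
                              min_run: int = 5) -> list[HotspotSegment]:
    """Maximal runs of >= min_run consecutive residues with propensity >=
    cutoff percent."""
    if not 0.0 < cutoff <= 100.0:
        raise ValueError("cutoff must lie in (0, 100]")
    above = profile.propensity >= cutoff
    out = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                out.append(HotspotSegment(i + profile.first_residue,
                                          j + profile.first_residue,
                                          frozenset({"aggregation"})))
            i = j + 1
        else:
            i += 1
    return out


def consensus_hotspots(zipper: list[HotspotSegment],
                       aggregation: list[HotspotSegment],
                       hydropathy: HydropathyProfile | None = None,
                       helices: dict[str, tuple[int, int]] | None = None,
                       ) -> list[HotspotSegment]:
    """Interval intersection of zipper and aggregation hotspots, annotated
    with mean hydropathy and residue-count overlap with each named helix."""
    out = []
    for z in zipper:
        for a in aggregation:
            s, e = max(z.start, a.start), min(z.end, a.end)
            if s > e:
                continue
            mh = None
            if hydropathy is not None:
                lo = hydropathy.first_residue
                hi = lo + len(hydropathy.scores) - 1
                if s < lo or e > hi:
                    raise ValueError("hotspot numbering outside hydropathy profile")
                mh = hydropathy.mean_over(s, e)
            overlap = {}
            for name, (hs, he) in (helices or {}).items():
                ov = min(e, he) - max(s, hs) + 1
                if ov > 0:
                    overlap[name] = ov
            out.append(HotspotSegment(s, e, frozenset({"zipper", "aggregation"}),
                                      mean_hydropathy=mh, helix_overlap=overlap))
    out.sort(key=lambda h: h.start)
    return out


# ---------------------------------------------------------------------------
# steric-zipper geometry
# ---------------------------------------------------------------------------

@dataclass
class ZipperStructure:
    """C-alpha coordinates of a two-sheet steric zipper.

    ``sheets`` maps a sheet label (chain group) to an (n, 3) coordinate
    array in Angstrom.
    """

    sheets: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.sheets = {k: np.asarray(v, dtype=float) for k, v in self.sheets.items()}
        for label, xyz in self.sheets.items():
            if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] < 2:
                raise ValueError(f"sheet {label!r} needs >= 2 C-alpha atoms (n, 3)")


def _fit_plane(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (centroid, unit normal)."""
    centroid = xyz.mean(axis=0)
    u, s, vt = np.linalg.svd(xyz - centroid)
    if s[1] < 1e-8 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) sheet: plane fit undefined")
    return centroid, vt[2]


def intersheet_distance(structure: ZipperStructure) -> float:
    """Distance between the two beta-sheets of a zipper.

    A least-squares plane is fitted to each sheet's C-alpha atoms; the
    distance is the mean over both plane normals of the projection of the
    centroid separation, which makes the result invariant under rigid
    motions and under swapping the sheet labels.
    """
    if len(structure.sheets) != 2:
        raise ValueError("exactly two sheets required")
    (la, a), (lb, b) = structure.sheets.items()
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("each sheet needs >= 3 C-alpha atoms for a plane fit")
    ca, na = _fit_plane(a)
    cb, nb = _fit_plane(b)
    sep = cb - ca
    return 0.5 * (abs(float(sep @ na)) + abs(float(sep @ nb)))


# ---------------------------------------------------------------------------
# peptide mass
# ---------------------------------------------------------------------------

def peptide_mass(seq: SequenceRecord, mass_type: str = "average") -> float:
    """Peptide mass in Da including terminal-modification deltas."""
    if mass_type not in ("average", "monoisotopic"):
        raise ValueError("mass_type must be 'average' or 'monoisotopic'")
    m = molecular_weight(seq.sequence, seq_type="protein",
                         monoisotopic=(mass_type == "monoisotopic"))
    if seq.n_term == "acetyl":
        m += _ACETYL[mass_type]
    if seq.c_term == "amide":
        m += _AMIDE[mass_type]
    return float(m)


def disulfide_dimer_mass(monomer_mass: float, mass_type: str = "average") -> float:
    """Mass of a disulfide-linked homodimer: 2 M - 2 H."""
    return 2.0 * monomer_mass - _H2[mass_type]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceRecord:
    """Read the first record of a FASTA file.

    Terminal modifications are carried in the header as ``[Ac]`` / ``[NH2]``
    tags; a ``start=<n>`` tag sets the numbering offset.
    """
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(path), "fasta"))
    desc = rec.description
    first = 1
    for tok in desc.split():
        if tok.startswith("start="):
            first = int(tok.split("=", 1)[1])
    return SequenceRecord(
        id=rec.id,
        sequence=str(rec.seq).upper(),
        first_residue=first,
        n_term="acetyl" if "[Ac]" in desc else "none",
        c_term="amide" if "[NH2]" in desc else "none",
    )


def read_zipper_windows(path: str | Path, sequence: SequenceRecord | None = None
                        ) -> list[ZipperWindow]:
    """Read a ZipperDB-style TSV: columns start, hexapeptide, energy
    (kcal/mol) and optional intersheet_d (Angstrom)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in frame.iterrows():
        w = ZipperWindow(start=int(row["start"]), hexapeptide=str(row["hexapeptide"]),
                         energy=float(row["energy"]),
                         intersheet_d=float(row["intersheet_d"])
                         if "intersheet_d" in frame.columns and pd.notna(row.get("intersheet_d"))
                         else None)
        if sequence is not None:
            i = w.start - sequence.first_residue
            if sequence.sequence[i:i + 6] != w.hexapeptide:
                raise ValueError(f"hexapeptide at start {w.start} does not match sequence")
        out.append(w)
    return sorted(out, key=lambda w: w.start)


def read_aggregation_profile(path: str | Path, condition: str = "",
                             first_residue: int = 1) -> AggregationProfile:
    """Read a TANGO-style TSV: columns index, residue, beta_agg (percent)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame = frame.sort_values("index")
    return AggregationProfile(propensity=frame["beta_agg"].to_numpy(float),
                              condition=condition,
                              first_residue=int(frame["index"].iloc[0]))


def read_zipper_pdb(path: str | Path) -> ZipperStructure:
    """Read C-alpha coordinates from a PDB file, one sheet per chain group.

    Chains A-M go to sheet "1", chains N-Z to sheet "2" unless exactly two
    chains are present, in which case each chain is its own sheet.
    """
    from Bio.PDB import PDBParser
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("zipper", str(path))[0]
    by_chain: dict[str, list] = {}
    for chain in model:
        cas = [atom.coord for res in chain for atom in res if atom.get_name() == "CA"]
        if cas:
            by_chain[chain.id] = cas
    if len(by_chain) == 2:
        sheets = {cid: np.array(v) for cid, v in by_chain.items()}
    else:
        sheets = {"1": [], "2": []}
        for cid, v in by_chain.items():
            sheets["1" if cid.upper() <= "M" else "2"].extend(v)
        sheets = {k: np.array(v) for k, v in sheets.items() if v}
    return ZipperStructure(sheets=sheets)


def write_zipper_pdb(structure: ZipperStructure, path: str | Path) -> None:
    """Write C-alpha-only ATOM records; chain IDs distinguish sheets."""
    chain_ids = "AB"
    lines = []
    serial = 1
    for (label, xyz), cid in zip(structure.sheets.items(), chain_ids):
        for i, (x, y, z) in enumerate(xyz, start=1):
            lines.append(
                f"ATOM  {serial:5d}  CA  GLY {cid}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
            serial += 1
        lines.append(f"TER   {serial:5d}      GLY {cid}{len(xyz):4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def load_ct_helices() -> dict[str, tuple[int, int]]:
    """The packaged nominal CT helix annotation (helix N4 = residues 51-80)."""
    ref = resources.files("fiberfold.data") / "ct_helices.yaml"
    data = yaml.safe_load(ref.read_text())
    return {k: tuple(v) for k, v in data["helices"].items()}
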