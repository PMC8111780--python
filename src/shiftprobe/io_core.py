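"""Domain types and file I/O.

Holds the shared in-memory containers (residues, amide peaks, peak lists,
chemical-shift tables, analysis reports) and readers/writers for the external
formats: the repository CSV peak-list schema, Sparky-style ``.list`` files,
NMR-STAR v3 assigned-chemical-shift loops, single-record FASTA and JSON
reports.

CSV peak-list schema (header required)::

    residue_index,residue_code,h_ppm,n_ppm,intensity

Residue numbering is 1-based throughout.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import seq1

from .errors import DuplicateResidueError, FormatError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Amide shifts outside these windows are physically unusual and trigger a warning.
H_RANGE = (4.0, 13.0)
N_RANGE = (95.0, 140.0)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Residue:
    """A 1-based sequence position with its one-letter amino-acid code."""

    index: int
    one_letter: str

    def __post_init__(self):
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if self.one_letter not in AMINO_ACIDS and self.one_letter != "X":
            raise ValueError(f"unknown residue code {self.one_letter!r}")


@dataclass(frozen=True)
class Peak:
    """One backbone-amide resonance: 1H and 15N shifts (ppm), optional intensity."""

    residue: Residue
    delta_h: float
    delta_n: float
    intensity: Optional[float] = None

    def __post_init__(self):
        import math

        if not (math.isfinite(self.delta_h) and math.isfinite(self.delta_n)):
            raise ValueError(f"non-finite shift for residue {self.residue.index}")
        if not (H_RANGE[0] <= self.delta_h <= H_RANGE[1]):
            warnings.warn(
                f"1H shift {self.delta_h} ppm at residue {self.residue.index} "
                f"is outside the typical amide window {H_RANGE}",
                stacklevel=2,
            )
        if not (N_RANGE[0] <= self.delta_n <= N_RANGE[1]):
            warnings.warn(
                f"15N shift {self.delta_n} ppm at residue {self.residue.index} "
                f"is outside the typical amide window {N_RANGE}",
                stacklevel=2,
            )


class PeakList:
    """A set of peaks keyed by residue index (at most one peak per residue)."""

    def __init__(self, peaks=(), label: str = ""):
        self.label = label
        self._peaks: Dict[int, Peak] = {}
        for p in peaks:
            self.add(p)

    def add(self, peak: Peak) -> None:
        idx = peak.residue.index
        if idx in self._peaks:
            raise DuplicateResidueError(f"duplicate peak for residue {idx}")
        self._peaks[idx] = peak

    def __len__(self) -> int:
        return len(self._peaks)

    def __contains__(self, index: int) -> bool:
        return index in self._peaks

    def __getitem__(self, index: int) -> Peak:
        return self._peaks[index]

    def __iter__(self) -> Iterator[Peak]:
        for idx in sorted(self._peaks):
            yield self._peaks[idx]

    def residues(self):
        return sorted(self._peaks)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakList):
            return NotImplemented
        return self._peaks == other._peaks

    def __repr__(self) -> str:
        return f"PeakList(label={self.label!r}, n={len(self)})"


class ShiftTable:
    """Assigned chemical shifts: (residue index, atom name) -> shift in ppm.

    Also records the one-letter residue code seen for each residue so that
    downstream sequence-consistency checks are possible.
    """

    def __init__(self):
        self._shifts: Dict[int, Dict[str, float]] = {}
        self.codes: Dict[int, str] = {}

    def set(self, index: int, code: str, atom: str, value: float) -> None:
        row = self._shifts.setdefault(index, {})
        if atom in row:
            raise DuplicateResidueError(
                f"duplicate shift for residue {index} atom {atom}"
            )
        row[atom] = value
        self.codes[index] = code

    def get(self, index: int, atom: str) -> Optional[float]:
        return self._shifts.get(index, {}).get(atom)

    def ca_shifts(self) -> Dict[int, float]:
        """Residue index -> Cα shift, for residues that have one."""
        return {
            i: atoms["CA"] for i, atoms in sorted(self._shifts.items()) if "CA" in atoms
        }

    def residues(self):
        return sorted(self._shifts)

    def __len__(self) -> int:
        return sum(len(a) for a in self._shifts.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ShiftTable):
            return NotImplemented
        return self._shifts == other._shifts and self.codes == other.codes


@dataclass
class AnalysisReport:
    """Serializable container for pipeline stage results plus provenance."""

    provenance: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "schema_version": self.schema_version,
            "provenance": self.provenance,
            "stages": self.stages,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        payload = json.loads(text)
        return cls(
            provenance=payload["provenance"],
            stages=payload["stages"],
            schema_version=payload["schema_version"],
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read(cls, path) -> "AnalysisReport":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["residue_index", "residue_code", "h_ppm", "n_ppm", "intensity"]

# Sparky-style assignment like "R81N-H" (residue code, index, 15N name, 1H name)
_SPARKY_ASSIGNMENT = re.compile(r"^([A-Z])(\d+)N\d*-?H")


def read_peak_list(path, dialect: str = "csv") -> PeakList:
    """Read a peak list from ``csv`` (repository schema) or ``sparky`` text.

    Sparky ``.list`` rows are ``assignment  w1(15N)  w2(1H)  [height]``.
    """
    path = Path(path)
    if dialect == "csv":
        return _read_peak_list_csv(path)
    if dialect == "sparky":
        return _read_peak_list_sparky(path)
    raise FormatError(f"unknown peak-list dialect {dialect!r}")


def _read_peak_list_csv(path: Path) -> PeakList:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (no header)") from None
    for col in _CSV_COLUMNS[:4]:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    peaks = PeakList(label=path.stem)
    for _, row in df.iterrows():
        intensity = None
        if "intensity" in df.columns and pd.notna(row.get("intensity")):
            intensity = float(row["intensity"])
        peaks.add(
            Peak(
                residue=Residue(int(row["residue_index"]), str(row["residue_code"])),
                delta_h=float(row["h_ppm"]),
                delta_n=float(row["n_ppm"]),
                intensity=intensity,
            )
        )
    return peaks


def _read_peak_list_sparky(path: Path) -> PeakList:
    peaks = PeakList(label=path.stem)
    seen_any = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        parts = line.split()
        m = _SPARKY_ASSIGNMENT.match(parts[0])
        if m is None:
            raise FormatError(f"{path}: unparseable assignment {parts[0]!r}")
        if len(parts) < 3:
            raise FormatError(f"{path}: row has fewer than 3 columns: {line!r}")
        code, idx = m.group(1), int(m.group(2))
        delta_n, delta_h = float(parts[1]), float(parts[2])
        intensity = float(parts[3]) if len(parts) > 3 else None
        peaks.add(Peak(Residue(idx, code), delta_h, delta_n, intensity))
        seen_any = True
    if not seen_any:
        raise FormatError(f"{path}: no peaks found")
    return peaks


def write_peak_list(peaks: PeakList, path) -> None:
    """Write the repository CSV schema."""
    rows = [
        {
            "residue_index": p.residue.index,
            "residue_code": p.residue.one_letter,
            "h_ppm": p.delta_h,
            "n_ppm": p.delta_n,
            "intensity": "" if p.intensity is None else repr(p.intensity),
        }
        for p in peaks
    ]
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# shift tables
# ---------------------------------------------------------------------------


def read_shift_table(path, format: str = "nmrstar") -> ShiftTable:
    """Read assigned chemical shifts from NMR-STAR v3 or CSV.

    The NMR-STAR reader consumes only the ``_Atom_chem_shift`` loop (deposited
    shift tables); anything else in the file is ignored.  CSV columns:
    ``residue_index, residue_code, atom, shift_ppm``.
    """
    path = Path(path)
    if format == "nmrstar":
        return _read_shift_table_star(path)
    if format == "csv":
        return _read_shift_table_csv(path)
    raise FormatError(f"unknown shift-table format {format!r}")


def _read_shift_table_csv(path: Path) -> ShiftTable:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (no header)") from None
    for col in ("residue_index", "residue_code", "atom", "shift_ppm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    table = ShiftTable()
    for _, row in df.iterrows():
        table.set(
            int(row["residue_index"]),
            str(row["residue_code"]),
            str(row["atom"]),
            float(row["shift_ppm"]),
        )
    return table


def _read_shift_table_star(path: Path) -> ShiftTable:
    """Minimal NMR-STAR v3 parser for the assigned-chemical-shift loop."""
    lines = path.read_text().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() == "loop_":
            tags = []
            j = i + 1
            while j < n and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                return _parse_shift_loop(tags, lines, j, path)
            i = j
        else:
            i += 1
    raise FormatError(f"{path}: no _Atom_chem_shift loop found")


def _parse_shift_loop(tags, lines, start, path) -> ShiftTable:
    names = [t.split(".", 1)[1] for t in tags]

    def col(*candidates):
        for c in candidates:
            if c in names:
                return names.index(c)
        raise FormatError(f"{path}: shift loop lacks required tag {candidates[0]}")

    i_seq = col("Seq_ID", "Comp_index_ID")
    i_comp = col("Comp_ID")
    i_atom = col("Atom_ID")
    i_val = col("Val")

    table = ShiftTable()
    for line in lines[start:]:
        s = line.strip()
        if s == "stop_":
            break
        if not s or s.startswith("#"):
            continue
        fields = s.split()
        if len(fields) < len(names):
            continue
        comp = fields[i_comp]
        code = comp if len(comp) == 1 else _three_to_one(comp)
        table.set(int(fields[i_seq]), code, fields[i_atom], float(fields[i_val]))
    return table


def _three_to_one(comp: str) -> str:
    code = seq1(comp.capitalize())
    return code if code in AMINO_ACIDS else "X"


def write_shift_table(table: ShiftTable, path) -> None:
    rows = []
    for idx in table.residues():
        for atom in sorted(table._shifts[idx]):
            rows.append(
                {
                    "residue_index": idx,
                    "residue_code": table.codes[idx],
                    "atom": atom,
                    "shift_ppm": table._shifts[idx][atom],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def read_fasta(path) -> str:
    """Read a single-record FASTA file and return the sequence as a string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FormatError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise FormatError(f"{path}: expected exactly one record, found {len(records)}")
    return str(records[0].seq).upper()


def run_titration_pipeline(config):
    """Run the end-to-end CSP/binding pipeline (see :mod:`shiftprobe.pipeline`)."""
    from .pipeline import run_titration_pipeline as _run

    return _run(config)
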