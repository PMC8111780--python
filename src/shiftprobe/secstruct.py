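"""Secondary chemical shifts and α-helix segmentation.

The Cα secondary chemical shift of a residue is the observed Cα shift minus
the residue-specific random-coil value; runs of consecutive positive values
mark α-helical structure.  Segmentation keeps maximal runs of at least
``min_run`` residues above a threshold, tolerating at most one interior
residue that dips below the threshold while staying positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

from ._random_coil import DEFAULT_TABLE, RANDOM_COIL_CA
from .errors import ConsistencyError, ValidationError
from .io_core import ShiftTable


@dataclass
class SecondaryShiftProfile:
    """Per-residue ΔδCα (ppm) and the random-coil table used to compute it."""

    values: Dict[int, float]
    table_id: str

    def residues(self):
        return sorted(self.values)


@dataclass(frozen=True)
class HelixSegment:
    """Inclusive residue-index range of one helix."""

    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(f"helix end {self.end} before start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, index: int) -> bool:
        return self.start <= index <= self.end


def secondary_shifts(
    shifts: ShiftTable, sequence: str, table: str = DEFAULT_TABLE
) -> SecondaryShiftProfile:
    """ΔδCα = observed Cα − random coil, per residue with an observed Cα.

    ``sequence`` is the full 1-based protein sequence; every shift-table
    residue must fall inside it and agree on the amino-acid code (shift rows
    with code 'X' are accepted as unknown).
    """
    if table not in RANDOM_COIL_CA:
        raise ValidationError(f"unknown random-coil table {table!r}")
    rc = RANDOM_COIL_CA[table]
    values: Dict[int, float] = {}
    for idx, obs in shifts.ca_shifts().items():
        if idx > len(sequence):
            raise ConsistencyError(
                f"residue {idx} outside the {len(sequence)}-residue sequence"
            )
        seq_code = sequence[idx - 1]
        table_code = shifts.codes.get(idx, "X")
        if table_code != "X" and table_code != seq_code:
            raise ConsistencyError(
                f"residue {idx}: sequence says {seq_code}, shift table says {table_code}"
            )
        if seq_code not in rc:
            raise ConsistencyError(f"residue {idx}: no random-coil value for {seq_code!r}")
        values[idx] = obs - rc[seq_code]
    return SecondaryShiftProfile(values=values, table_id=table)


def segment_helices(
    profile: SecondaryShiftProfile,
    threshold: float = 0.7,
    min_run: int = 4,
    dip_tolerance: int = 1,
) -> List[HelixSegment]:
    """Maximal helix runs from a secondary-shift profile.

    A run is a block of consecutive residue indices with ΔδCα above
    ``threshold``; up to ``dip_tolerance`` interior residues per run may fall
    between 0 and the threshold.  Residues absent from the profile break
    runs.  Runs shorter than ``min_run`` are discarded; segments are returned
    sorted and non-overlapping.
    """
    if not profile.values:
        raise ValidationError("empty secondary-shift profile")
    indices = profile.residues()
    segments: List[HelixSegment] = []

    run_start = None
    dips_used = 0
    last_strong = None  # last index with value > threshold in the current run

    def close_run():
        nonlocal run_start, dips_used, last_strong
        if run_start is not None and last_strong is not None:
            if last_strong - run_start + 1 >= min_run:
                segments.append(HelixSegment(run_start, last_strong))
        run_start, dips_used, last_strong = None, 0, None

    prev_idx = None
    for idx in indices:
        v = profile.values[idx]
        contiguous = prev_idx is not None and idx == prev_idx + 1
        if not contiguous:
            close_run()
        if v > threshold:
            if run_start is None:
                run_start, dips_used = idx, 0
            last_strong = idx
        elif v > 0 and run_start is not None and dips_used < dip_tolerance:
            dips_used += 1  # interior dip, provisionally bridged
        else:
            close_run()
        prev_idx = idx
    close_run()
    return segments
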