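"""PSI-BLAST profile handling.

Parses ASCII PSSM files (``-out_ascii_pssm`` dialect), slices
window-aligned profile blocks, and synthesizes one-hot pseudo-profiles so
the profile-based encoder is usable when no PSI-BLAST output exists.

Profile columns follow the PSI-BLAST header order A R N D C Q E G H I L K
M F P S T W Y V; only the log-odds block (first 20 numeric columns) is
used, because the encoder clamps negative values to zero — a clamp that
only makes sense on signed log-odds scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AA_ORDER, AA_TO_COL
from .seq_io import PeptideWindow

logger = logging.getLogger(__name__)


@dataclass
class PSSM:
    """Per-position 20-column substitution score profile for one protein."""

    protein_id: str
    scores: np.ndarray  # (protein_length, 20), rows 1-based-aligned to sequence
    source: str = "psiblast"  # or "pseudo"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"PSSM scores must be (L, 20), got {self.scores.shape}")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class WindowProfile:
    """W x 20 profile block aligned to a peptide window; pad rows all-zero."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"WindowProfile must be (W, 20), got {self.scores.shape}")

    def __len__(self) -> int:
        return self.scores.shape[0]


def parse_psiblast_pssm(path: str | Path, protein_id: str | None = None,
                        sequence: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM file (log-odds block).

    Expects the standard dialect: blank/header lines, then one row per
    residue carrying position, residue, 20 log-odds integers, 20
    percentage columns and two trailing reals. Only the first 20 numeric
    columns are kept. Row residues are cross-checked against ``sequence``
    when given.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    rows: list[list[float]] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            # data rows start with an integer position then a residue letter
            if len(fields) < 2 or not fields[0].isdigit() or len(fields[1]) != 1 \
                    or not fields[1].isalpha():
                continue
            if len(fields) < 22:
                raise ValueError(f"{path}:{lineno}: truncated PSSM row "
                                 f"({len(fields)} fields, need >= 22)")
            pos = int(fields[0])
            if pos != len(rows) + 1:
                raise ValueError(f"{path}:{lineno}: expected position {len(rows) + 1}, "
                                 f"got {pos}")
            try:
                rows.append([float(x) for x in fields[2:22]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed score field: {exc}")
            residues.append(fields[1].upper())
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    if sequence is not None:
        if len(sequence) != len(rows):
            raise ValueError(f"{path}: {len(rows)} rows vs sequence length {len(sequence)}")
        for i, (a, b) in enumerate(zip(residues, sequence.upper()), start=1):
            if a != b and b in AA_ORDER:
                raise ValueError(f"{path}: row {i} residue {a!r} != sequence {b!r}")
    return PSSM(protein_id=protein_id, scores=np.array(rows), source="psiblast")


def write_psiblast_pssm(pssm: PSSM, sequence: str, path: str | Path) -> None:
    """Write a PSSM in the ASCII dialect that :func:`parse_psiblast_pssm` reads.

    Used for fixtures and round-trip checks; percentage columns and the
    trailing statistics are filled with zeros.
    """
    if len(sequence) != len(pssm):
        raise ValueError("sequence length must match PSSM rows")
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted observed "
                 "percentages rounded down, information per position, and relative "
                 "weight of gapless real matches to pseudocounts\n")
        fh.write("            " + "  ".join(AA_ORDER) + "   " + "  ".join(AA_ORDER) + "\n")
        for i, (res, row) in enumerate(zip(sequence, pssm.scores), start=1):
            scores = " ".join(f"{int(round(v)):3d}" for v in row)
            pct = " ".join("0" for _ in range(20))
            fh.write(f"{i:5d} {res} {scores}  {pct}  0.00 0.00\n")


def slice_profile(pssm: PSSM, position: int, window_size: int) -> WindowProfile:
    """Profile rows for the window centered at a 1-based position.

    Rows falling outside the protein are all-zero, mirroring window
    padding.
    """
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError(f"window_size must be odd and >= 3, got {window_size}")
    if not (1 <= position <= len(pssm)):
        raise ValueError(f"position {position} out of bounds for PSSM of length {len(pssm)}")
    half = (window_size - 1) // 2
    out = np.zeros((window_size, 20))
    for t in range(window_size):
        src = position - 1 - half + t
        if 0 <= src < len(pssm):
            out[t] = pssm.scores[src]
    return WindowProfile(out)


def pseudo_profile(window: PeptideWindow, scale: float = 1.0) -> WindowProfile:
    """One-hot fallback profile: ``scale`` at the observed residue's column.

    Pad and ambiguous rows are all-zero. With scale 1 the profile-based
    pair encoder reduces exactly to the sequence-based one, which doubles
    as a correctness oracle.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    out = np.zeros((len(window), 20))
    for t, res in enumerate(window.residues):
        col = AA_TO_COL.get(res)
        if col is not None:
            out[t, col] = scale
    return WindowProfile(out)


def load_profiles(directory: str | Path, protein_ids: list[str],
                  sequences: dict[str, str] | None = None) -> dict[str, PSSM]:
    """Load ``<protein_id>.pssm`` files from a directory for the given ids.

    Missing files are simply absent from the result; the caller decides
    whether a pseudo-profile fallback is acceptable.
    """
    directory = Path(directory)
    profiles: dict[str, PSSM] = {}
    for pid in protein_ids:
        path = directory / f"{pid}.pssm"
        if path.exists():
            seq = sequences.get(pid) if sequences else None
            profiles[pid] = parse_psiblast_pssm(path, protein_id=pid, sequence=seq)
    return profiles
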