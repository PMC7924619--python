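"""Sequence and site I/O: FASTA reading, lysine enumeration, window
extraction, redundancy reduction and dataset balancing.

Windows are fixed-length fragments centered on a candidate lysine
(default 57 residues, offsets -28..+28). Annotation positions are 1-based
on the protein; array indexing is 0-based internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import SeqIO

from .alphabet import AMBIGUOUS, PAD, TOLERATED

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 57


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence; residues uppercase, ambiguity codes tolerated."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for i, ch in enumerate(self.residues):
            if ch not in TOLERATED:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SiteAnnotation:
    """A candidate site: 1-based lysine position on a protein with a label."""

    protein_id: str
    position: int
    label: int  # 1 positive, 0 negative


@dataclass(frozen=True)
class PeptideWindow:
    """Fixed-length lysine-centered fragment.

    ``residues`` has odd length W with 'K' at index (W-1)/2; positions
    outside the protein carry the pad character, only as a contiguous
    prefix and/or suffix.
    """

    residues: str
    label: int | None = None  # 1 / 0 / None (unknown)
    source: tuple[str, int] | None = None  # (protein_id, 1-based position)
    pad_char: str = PAD

    def __post_init__(self) -> None:
        w = len(self.residues)
        if w % 2 == 0 or w < 3:
            raise ValueError(f"window length must be odd and >= 3, got {w}")
        if self.residues[self.center_index] != "K":
            raise ValueError(
                f"window center must be 'K', got {self.residues[self.center_index]!r}"
            )
        core = self.residues.strip(self.pad_char)
        if self.pad_char in core:
            raise ValueError("pad characters must be a contiguous prefix/suffix")

    @property
    def center_index(self) -> int:
        return (len(self.residues) - 1) // 2

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Dataset:
    """Ordered window collection with its declared class ratio and seed."""

    windows: list[PeptideWindow]
    ratio: str = "all"
    seed: int | None = None

    def __post_init__(self) -> None:
        seen = set()
        for w in self.windows:
            if w.source is not None:
                if w.source in seen:
                    raise ValueError(f"duplicate window source {w.source}")
                seen.add(w.source)

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=int)

    def __len__(self) -> int:
        return len(self.windows)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Sequences are uppercased; characters outside the tolerated alphabet
    raise a ValueError naming the record and offset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ambiguous = [r.id for r in records if set(r.residues) & AMBIGUOUS]
    if ambiguous:
        logger.warning(
            "records with ambiguity codes (treated as zero-contribution): %s",
            ", ".join(ambiguous[:10]),
        )
    return records


def read_annotations(path: str | Path, records: Sequence[SequenceRecord] | None = None
                     ) -> list[SiteAnnotation]:
    """Read a site TSV (header: protein_id, position, label; 1-based positions).

    When ``records`` is given, each site is checked to fall on a lysine;
    a non-K site is a loud error, never silently skipped.
    """
    path = Path(path)
    by_id = {r.id: r for r in records} if records is not None else None
    sites: list[SiteAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein_id", "position", "label"]:
            raise ValueError(f"{path}: expected header protein_id<TAB>position<TAB>label")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            pid, pos_s, label_s = fields[0], fields[1], fields[2]
            pos, label = int(pos_s), int(label_s)
            if label not in (0, 1):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1")
            if by_id is not None:
                rec = by_id.get(pid)
                if rec is None:
                    raise ValueError(f"{path}:{lineno}: unknown protein {pid!r}")
                if not (1 <= pos <= len(rec)):
                    raise ValueError(f"{path}:{lineno}: position {pos} out of bounds for {pid!r}")
                if rec.residues[pos - 1] != "K":
                    raise ValueError(
                        f"{path}:{lineno}: residue at {pid!r}:{pos} is "
                        f"{rec.residues[pos - 1]!r}, not 'K'"
                    )
            sites.append(SiteAnnotation(pid, pos, label))
    return sites


def enumerate_lysines(record: SequenceRecord) -> list[int]:
    """1-based positions of every 'K' in the sequence, ascending."""
    return [i + 1 for i, ch in enumerate(record.residues) if ch == "K"]


def extract_window(record: SequenceRecord, position: int,
                   window_size: int = DEFAULT_WINDOW_SIZE,
                   label: int | None = None) -> PeptideWindow:
    """Extract the window of ``window_size`` residues centered on a lysine.

    ``position`` is 1-based; out-of-protein positions are filled with the
    pad character so the center lysine always sits at index (W-1)/2.
    """
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError(f"window_size must be odd and >= 3, got {window_size}")
    if not (1 <= position <= len(record)):
        raise ValueError(f"position {position} out of bounds for record {record.id!r}")
    if record.residues[position - 1] != "K":
        raise ValueError(
            f"record {record.id!r}: residue at position {position} is "
            f"{record.residues[position - 1]!r}, not 'K'"
        )
    half = (window_size - 1) // 2
    start = position - 1 - half
    chars = []
    for i in range(start, start + window_size):
        chars.append(record.residues[i] if 0 <= i < len(record) else PAD)
    return PeptideWindow("".join(chars), label=label, source=(record.id, position))


def extract_windows(records: Sequence[SequenceRecord],
                    sites: Iterable[SiteAnnotation],
                    window_size: int = DEFAULT_WINDOW_SIZE) -> list[PeptideWindow]:
    by_id = {r.id: r for r in records}
    return [
        extract_window(by_id[s.protein_id], s.position, window_size, label=s.label)
        for s in sites
    ]


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Computed from the optimal Needleman–Wunsch path (unit costs) via edlib:
    matches = columns - edits.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"]
    columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            columns += int(num)
            num = ""
    return (columns - res["editDistance"]) / columns


def reduce_redundancy(records: Sequence[SequenceRecord],
                      identity_threshold: float = 0.8) -> list[SequenceRecord]:
    """Greedy longest-first identity clustering (CD-HIT-style approximation).

    Records are visited sorted by length descending then id ascending; a
    record is discarded when its global pairwise identity to any
    already-retained record is >= the threshold. Deterministic and
    idempotent.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    if not records:
        raise ValueError("reduce_redundancy needs at least one record")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    retained: list[SequenceRecord] = []
    for rec in ordered:
        if all(pairwise_identity(rec.residues, kept.residues) < identity_threshold
               for kept in retained):
            retained.append(rec)
        else:
            logger.debug("discarding redundant record %s", rec.id)
    return retained


def balance_dataset(positives: Sequence[PeptideWindow],
                    negatives: Sequence[PeptideWindow],
                    ratio: str = "1:1", seed: int = 0) -> Dataset:
    """Subsample negatives (without replacement) to the declared ratio.

    ``ratio`` is "1:1", "1:2" or "all". Positives are kept untouched;
    the subsample is reproducible for a fixed seed.
    """
    if not positives or not negatives:
        raise ValueError("both positive and negative collections must be non-empty")
    positives = list(positives)
    negatives = list(negatives)
    if ratio == "all":
        chosen = negatives
    else:
        try:
            one, mult = ratio.split(":")
            mult = int(mult)
            assert one == "1" and mult >= 1
        except (ValueError, AssertionError):
            raise ValueError(f"ratio must be '1:1', '1:2' or 'all', got {ratio!r}")
        n_needed = len(positives) * mult
        if n_needed > len(negatives):
            raise ValueError(
                f"ratio {ratio} needs {n_needed} negatives, only {len(negatives)} available"
            )
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(negatives), size=n_needed, replace=False))
        chosen = [negatives[i] for i in idx]
    return Dataset(windows=list(positives) + chosen, ratio=ratio, seed=seed)


def write_manifest(dataset: Dataset, path: str | Path) -> None:
    """Write the dataset as TSV: protein_id, position, label, window."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\twindow\n")
        for w in dataset.windows:
            pid, pos = w.source if w.source else ("?", 0)
            fh.write(f"{pid}\t{pos}\t{w.label}\t{w.residues}\n")


def read_manifest(path: str | Path, ratio: str = "all",
                  seed: int | None = None) -> Dataset:
    windows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["protein_id", "position", "label", "window"]:
            raise ValueError(f"{path}: not a dataset manifest")
        for line in fh:
            if not line.strip():
                continue
            pid, pos, label, win = line.rstrip("\n").split("\t")
            windows.append(PeptideWindow(win, label=int(label), source=(pid, int(pos))))
    return Dataset(windows, ratio=ratio, seed=seed)
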