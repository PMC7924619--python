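"""Window feature encoders.

Five schemes, each with an exact dimension contract for a window of W
residues (W = 57 by default, k_max = 4, 15 physicochemical indices):

==========  =====================  =========
encoding    dimension              at defaults
==========  =====================  =========
Binary      20 * W                 1140
AAI         W * n_indices          855
TPC         20**3                  8000
CKSAAP      400 * (k_max + 1)      2000
pbCKSAAP    400 * (k_max + 1)      2000
==========  =====================  =========

CKSAAP counts ordered residue pairs separated by exactly k intervening
positions, normalized by (W - k - 1). pbCKSAAP scores the same pair
structure on a position-specific profile: for pair (a, b) at spacing k,

    S_ab  = sum_t max(min(P[t, a], P[t + k + 1, b]), 0)
    S'_ab = S_ab / (W - k - 1)

so negative profile values are clamped out and the result stays
length-normalized. Pad and ambiguity characters contribute nothing to any
encoder; the nominal denominators are kept regardless of padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alphabet import AA_ORDER, AA_TO_COL
from .seq_io import Dataset, PeptideWindow
from .pssm_profiles import PSSM, WindowProfile, pseudo_profile, slice_profile

ENCODINGS = ("AAI", "Binary", "TPC", "CKSAAP", "pbCKSAAP")


@dataclass
class AAIndexSet:
    """Ordered collection of named per-residue physicochemical scales."""

    ids: list[str]
    values: np.ndarray  # (n_indices, 20) in the canonical column order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), 20):
            raise ValueError("AAIndexSet values must be (n_indices, 20)")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AAIndexSet":
        """Load scales from TSV: index_id column + one column per residue."""
        ids, rows = [], []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "index_id" or sorted(header[1:]) != sorted(AA_ORDER):
                raise ValueError(f"{path}: header must be index_id + the 20 residues")
            col_of = [header[1:].index(a) for a in AA_ORDER]
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                ids.append(fields[0])
                vals = [float(x) for x in fields[1:]]
                rows.append([vals[c] for c in col_of])
        return cls(ids=ids, values=np.array(rows))

    @classmethod
    def default(cls) -> "AAIndexSet":
        """The packaged set of 15 classical physicochemical scales."""
        with resources.as_file(
            resources.files("pupfuse").joinpath("data/aaindex15.tsv")
        ) as p:
            return cls.from_tsv(p)


@dataclass
class FeatureVector:
    encoding: str
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")


@dataclass
class FeatureMatrix:
    """Rows = windows in dataset order, with aligned labels and names."""

    encoding: str
    X: np.ndarray
    names: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("X must be 2-D with one column per feature name")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != self.X.shape[0]:
                raise ValueError("labels must align 1:1 with rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _offsets(window_size: int) -> list[int]:
    half = (window_size - 1) // 2
    return list(range(-half, half + 1))


def binary_names(window_size: int) -> list[str]:
    return [f"Binary|pos={o:+d}|{a}" for o in _offsets(window_size) for a in AA_ORDER]


def aai_names(window_size: int, index_set: AAIndexSet) -> list[str]:
    return [f"AAI|pos={o:+d}|index={iid}"
            for o in _offsets(window_size) for iid in index_set.ids]


def tpc_names() -> list[str]:
    return [f"TPC|{a}{b}{c}" for a, b, c in product(AA_ORDER, repeat=3)]


def cksaap_names(k_max: int, prefix: str = "CKSAAP") -> list[str]:
    return [f"{prefix}|k={k}|{a}-{b}"
            for k in range(k_max + 1) for a in AA_ORDER for b in AA_ORDER]


def encode_binary(window: PeptideWindow) -> FeatureVector:
    """One-hot position encoding; pad/ambiguous positions give a zero block."""
    w = len(window)
    values = np.zeros(20 * w)
    for t, res in enumerate(window.residues):
        col = AA_TO_COL.get(res)
        if col is not None:
            values[20 * t + col] = 1.0
    return FeatureVector("Binary", values, binary_names(w))


def encode_aai(window: PeptideWindow, index_set: AAIndexSet | None = None) -> FeatureVector:
    """Per-position physicochemical scale values; pad/ambiguous give zeros."""
    if index_set is None:
        index_set = AAIndexSet.default()
    w, n = len(window), len(index_set)
    values = np.zeros(w * n)
    for t, res in enumerate(window.residues):
        col = AA_TO_COL.get(res)
        if col is not None:
            values[n * t:n * (t + 1)] = index_set.values[:, col]
    return FeatureVector("AAI", values, aai_names(w, index_set))


def encode_tpc(window: PeptideWindow) -> FeatureVector:
    """Tripeptide composition: frequency of each contiguous standard triple.

    Triples containing pad/ambiguous characters are skipped; counts are
    divided by the number of fully standard triple positions (zero vector
    when none exist).
    """
    values = np.zeros(20 ** 3)
    seq = window.residues
    valid = 0
    for t in range(len(seq) - 2):
        cols = [AA_TO_COL.get(seq[t + i]) for i in range(3)]
        if None in cols:
            continue
        valid += 1
        values[cols[0] * 400 + cols[1] * 20 + cols[2]] += 1.0
    if valid:
        values /= valid
    return FeatureVector("TPC", values, tpc_names())


def encode_cksaap(window: PeptideWindow, k_max: int = 4) -> FeatureVector:
    """k-spaced amino-acid pair composition for k = 0..k_max.

    Pair (a, b) at spacing k counts positions t with residue a at t and b
    at t + k + 1 (both standard), normalized by (W - k - 1).
    """
    w = len(window)
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if k_max + 2 > w:
        raise ValueError(f"k_max={k_max} too large for window of {w}")
    seq = window.residues
    values = np.zeros(400 * (k_max + 1))
    for k in range(k_max + 1):
        base = 400 * k
        for t in range(w - k - 1):
            a = AA_TO_COL.get(seq[t])
            b = AA_TO_COL.get(seq[t + k + 1])
            if a is not None and b is not None:
                values[base + a * 20 + b] += 1.0
        values[base:base + 400] /= (w - k - 1)
    return FeatureVector("CKSAAP", values, cksaap_names(k_max))


def encode_pbcksaap(window: PeptideWindow, profile: WindowProfile,
                    k_max: int = 4) -> FeatureVector:
    """Profile-based k-spaced pair encoding (min/clamp on PSSM scores).

    For each spacing k and ordered pair (a, b):
    S_ab = sum over t of max(min(profile[t, a], profile[t+k+1, b]), 0),
    normalized by (W - k - 1).
    """
    w = len(window)
    if len(profile) != w:
        raise ValueError(f"profile has {len(profile)} rows, window has {w}")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if k_max + 2 > w:
        raise ValueError(f"k_max={k_max} too large for window of {w}")
    P = profile.scores
    values = np.zeros(400 * (k_max + 1))
    for k in range(k_max + 1):
        left = P[: w - k - 1, :, None]   # (t, a, 1)
        right = P[k + 1:, None, :]       # (t, 1, b)
        s = np.clip(np.minimum(left, right), 0.0, None).sum(axis=0)  # (a, b)
        values[400 * k:400 * (k + 1)] = s.ravel() / (w - k - 1)
    return FeatureVector("pbCKSAAP", values, cksaap_names(k_max, prefix="pbCKSAAP"))


def _window_profile(window: PeptideWindow, profiles: Mapping[str, PSSM] | None,
                    allow_pseudo: bool, pseudo_scale: float) -> WindowProfile:
    if profiles is not None and window.source is not None:
        pssm = profiles.get(window.source[0])
        if pssm is not None:
            return slice_profile(pssm, window.source[1], len(window))
    if not allow_pseudo:
        raise ValueError(
            f"no profile for window {window.source} and pseudo fallback disabled"
        )
    return pseudo_profile(window, scale=pseudo_scale)


def encode_dataset(dataset: Dataset, encoding: str, *, k_max: int = 4,
                   index_set: AAIndexSet | None = None,
                   profiles: Mapping[str, PSSM] | None = None,
                   allow_pseudo: bool = False,
                   pseudo_scale: float = 1.0) -> FeatureMatrix:
    """Encode every window of a dataset into a feature matrix.

    Row order follows the dataset; labels are carried alongside. For
    pbCKSAAP each window's profile is sliced from ``profiles`` by its
    source protein, falling back to a one-hot pseudo-profile only when
    ``allow_pseudo`` is set.
    """
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; choose from {ENCODINGS}")
    if len(dataset) == 0:
        raise ValueError("cannot encode an empty dataset")
    if encoding == "AAI" and index_set is None:
        index_set = AAIndexSet.default()

    rows, names = [], None
    for window in dataset.windows:
        if encoding == "Binary":
            fv = encode_binary(window)
        elif encoding == "AAI":
            fv = encode_aai(window, index_set)
        elif encoding == "TPC":
            fv = encode_tpc(window)
        elif encoding == "CKSAAP":
            fv = encode_cksaap(window, k_max)
        else:
            profile = _window_profile(window, profiles, allow_pseudo, pseudo_scale)
            fv = encode_pbcksaap(window, profile, k_max)
        rows.append(fv.values)
        names = fv.names
    labels = dataset.labels if all(w.label is not None for w in dataset.windows) else None
    return FeatureMatrix(encoding, np.vstack(rows), names, labels)


def write_feature_matrix(matrix: FeatureMatrix, dataset: Dataset,
                         path: str | Path) -> None:
    """Persist a matrix as TSV: sample_id, label, then one column per feature."""
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\t" + "\t".join(matrix.names) + "\n")
        for i, w in enumerate(dataset.windows):
            sid = f"{w.source[0]}:{w.source[1]}" if w.source else str(i)
            row = "\t".join(format(v, ".6g") for v in matrix.X[i])
            fh.write(f"{sid}\t{w.label}\t{row}\n")
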