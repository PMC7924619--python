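"""Encode one lysine-centered window under all five feature schemes.

Each encoder maps the 57-residue window to a fixed-dimension vector:
Binary 1140 (one-hot per position), AAI 855 (15 physicochemical scales
per position), TPC 8000 (tripeptide frequencies), CKSAAP 2000 (k-spaced
residue-pair composition, k = 0..4), and pbCKSAAP 2000 (the same pair
structure scored on a PSSM profile with min/clamp and length
normalization).
"""

import numpy as np

from pupfuse import (encode_aai, encode_binary, encode_cksaap,
                     encode_pbcksaap, encode_tpc, extract_window,
                     pseudo_profile)
from pupfuse.seq_io import SequenceRecord

protein = SequenceRecord(
    "demo", "MSDLLRRYAKLVPQGTRYLNDEKAVRYLAKRGDEWLPKYRLMAAKEPQRSTVNDLLK")
window = extract_window(protein, position=10, window_size=57)
print("window:", window.residues)

for fv in (encode_binary(window), encode_aai(window), encode_tpc(window),
           encode_cksaap(window, k_max=4),
           encode_pbcksaap(window, pseudo_profile(window), k_max=4)):
    nz = int(np.count_nonzero(fv.values))
    top = max(range(len(fv.values)), key=lambda i: fv.values[i])
    print(f"{fv.encoding:>9}: dim {len(fv.values):5d}, {nz:4d} nonzero, "
          f"largest = {fv.names[top]} ({fv.values[top]:.3f})")
# dimensions are the contract: any window of 57 residues encodes to the
# same vector length, so matrices from different proteins align.
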