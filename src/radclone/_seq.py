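"""Shared nucleotide-sequence helpers (byte-level, uppercase ACGTN)."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 byte value -> base index (A=0, C=1, G=2, T=3); everything else -> 4
BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODE[_b] = _i
    BASE_CODE[_b + 32] = _i  # lowercase
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Encode a sequence as A/C/G/T = 0..3, other bytes = 4."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return BASE_CODE[np.frombuffer(seq, dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return BASE_BYTES[codes].tobytes().decode("ascii")
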