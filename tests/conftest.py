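"""Shared fixtures and independent oracles for the test suite.

The Levenshtein implementations here are written from scratch (classic DP,
plus a numpy-vectorized batch version for larger scans) so that barcode
assignment can be checked against an implementation that shares no code with
the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from sebyl import BarcodeLibrary, DecodeConfig


def levenshtein(a: str, b: str) -> int:
    """Reference edit distance (substitution/insertion/deletion), plain DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein_matrix(reads: list[str], refs: list[str]) -> np.ndarray:
    """All-pairs edit distances, vectorized over (reads x refs).

    Requires equal-length reads and equal-length refs (the barcode case).
    Cross-checked against :func:`levenshtein` in the decoder tests.
    """
    r = np.array([[ord(ch) for ch in s] for s in reads], dtype=np.int16)
    t = np.array([[ord(ch) for ch in s] for s in refs], dtype=np.int16)
    n, l1 = r.shape
    m, l2 = t.shape
    # D[j] holds column j of the DP table for every (read, ref) pair
    d = np.broadcast_to(np.arange(l2 + 1, dtype=np.int16),
                        (n, m, l2 + 1)).copy()
    for i in range(1, l1 + 1):
        prev_diag = d[:, :, 0].copy()
        d[:, :, 0] = i
        for j in range(1, l2 + 1):
            sub = prev_diag + (r[:, i - 1][:, None] != t[:, j - 1][None, :])
            prev_diag = d[:, :, j].copy()
            d[:, :, j] = np.minimum(np.minimum(d[:, :, j] + 1,
                                               d[:, :, j - 1] + 1), sub)
    return d[:, :, l2].astype(np.int64)


ADAPTERS = DecodeConfig(
    adapters_up=("ACGTACGTAC", "GTCAGTCAGT"),
    adapters_dn=("TGCATGCATG", "CATGCATGCA"),
)


@pytest.fixture
def decode_config() -> DecodeConfig:
    return DecodeConfig(ADAPTERS.adapters_up, ADAPTERS.adapters_dn)


@pytest.fixture
def tiny_library() -> BarcodeLibrary:
    return BarcodeLibrary({
        "strainA": ("ACGTACGTACGTACGTACGT", "TTTTCCCCGGGGAAAATTTT"),
        "strainB": ("GGGGTTTTAAAACCCCGGGG", "CACACACACACACACACACA"),
        "strainC": ("TGCATGCAAACCGGTTTGCA", None),
    })


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def mutate_positions(seq: str, k: int, rng: np.random.Generator) -> str:
    """Substitute exactly k distinct positions with a different base."""
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)
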