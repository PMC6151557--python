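"""K-skip-N-gram gapped composition features.

A *k-skip-n-gram* is an n-letter pattern read off a sequence where the
selected positions may skip up to ``k`` intervening residues. For the
default ``n = 2`` every ordered residue pair ``(i, i + d + 1)`` with skip
distance ``d`` in ``0..k`` contributes one gram, so ``d = 0`` is the
classical contiguous dipeptide and the feature vector has ``20**2 = 400``
components: the frequency of each possible gram among all grams enumerated.

The union over skip distances is a multiset — the same two-letter pattern
arising at several distances is counted once per occurrence — so the
frequencies always sum to exactly 1 when at least one gram exists. The
per-sequence skip cap is ``min(k, L - n)`` so that short sequences still
admit at least the contiguous grams.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product

import numpy as np

from .io_formats import AMINO_ACIDS, FeatureMatrix, ProteinSequence


@dataclass(frozen=True)
class KSNGConfig:
    """Gram size ``n`` and maximum skip ``k`` (capped per sequence)."""

    k: int = 3
    n: int = 2

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not 1 <= self.n <= 3:
            raise ValueError("n must be in 1..3 (larger grams blow up 20**n)")


def gram_vocabulary(n: int) -> list[str]:
    """All ``20**n`` grams in lexicographic order of the canonical alphabet."""
    return ["".join(t) for t in product(AMINO_ACIDS, repeat=n)]


def enumerate_skip_grams(seq: ProteinSequence, cfg: KSNGConfig) -> Counter:
    """Multiset of grams taken at every skip distance ``d`` in ``0..k``.

    For ``n = 2`` the gram at distance ``d`` is ``(s[i], s[i + d + 1])``;
    general ``n`` uses a uniform skip ``d`` between consecutive selected
    positions. Raises if the sequence is shorter than ``n``.
    """
    s = seq.residues
    L = len(s)
    if L < cfg.n:
        raise ValueError(
            f"sequence {seq.identifier!r} of length {L} admits no {cfg.n}-gram"
        )
    step_max = min(cfg.k, L - cfg.n)
    grams: Counter = Counter()
    span = cfg.n - 1  # selected positions beyond the first
    for d in range(step_max + 1):
        stride = d + 1
        reach = span * stride
        for i in range(L - reach):
            grams["".join(s[i + j * stride] for j in range(cfg.n))] += 1
    return grams


def encode_k_skip_n_grams(seq: ProteinSequence, cfg: KSNGConfig | None = None) -> np.ndarray:
    """Frequency vector over all ``20**n`` grams (length 400 for n=2)."""
    cfg = cfg or KSNGConfig()
    grams = enumerate_skip_grams(seq, cfg)
    total = sum(grams.values())
    vocab = gram_vocabulary(cfg.n)
    vec = np.array([grams.get(g, 0) for g in vocab], dtype=float)
    return vec / total


def feature_names(cfg: KSNGConfig | None = None) -> list[str]:
    cfg = cfg or KSNGConfig()
    return [f"ksng.{g}" for g in gram_vocabulary(cfg.n)]


def encode_dataset(
    sequences: list[ProteinSequence], cfg: KSNGConfig | None = None
) -> FeatureMatrix:
    """Encode a list of sequences into the ``20**n``-column gram block."""
    cfg = cfg or KSNGConfig()
    values = np.vstack([encode_k_skip_n_grams(s, cfg) for s in sequences])
    return FeatureMatrix(
        sample_ids=[s.identifier for s in sequences],
        feature_names=feature_names(cfg),
        values=values,
    )
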