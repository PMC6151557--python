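"""Composition-level information-theoretic features.

Three scalars summarise the amino-acid composition of a sequence:

* Shannon entropy ``SEn = -sum_i p_i log2 p_i`` (bits), where ``p_i`` is the
  frequency of amino acid *i* in the sequence;
* relative Shannon entropy ``RSEn = sum_i p_i log2(p_i / p0)``, the
  Kullback-Leibler divergence from the uniform distribution ``p0 = 1/20``;
* information gain score ``IGS = SEn - RSEn``.

``0 * log2 0`` is taken as 0 throughout.
"""

from __future__ import annotations

import numpy as np

from .io_formats import AMINO_ACIDS, AA_INDEX, FeatureMatrix, ProteinSequence

FEATURE_NAMES: list[str] = ["it.SEn", "it.RSEn", "it.IGS"]


def composition(seq: ProteinSequence) -> np.ndarray:
    """Amino-acid frequencies of ``seq`` in canonical order (sums to 1)."""
    counts = np.zeros(20)
    for ch in seq.residues:
        counts[AA_INDEX[ch]] += 1
    return counts / counts.sum()


def shannon_entropy(seq: ProteinSequence) -> float:
    """Shannon entropy of the composition, in bits; lies in [0, log2 20]."""
    p = composition(seq)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def relative_shannon_entropy(seq: ProteinSequence) -> float:
    """KL divergence (bits) of the composition from uniform; always >= 0."""
    p = composition(seq)
    nz = p[p > 0]
    return float((nz * np.log2(nz * 20.0)).sum())


def information_gain_score(seq: ProteinSequence) -> float:
    """Shannon entropy minus relative Shannon entropy."""
    return shannon_entropy(seq) - relative_shannon_entropy(seq)


def encode_information_theory(seq: ProteinSequence) -> np.ndarray:
    """The three-component feature vector ``[SEn, RSEn, IGS]``."""
    sen = shannon_entropy(seq)
    rsen = relative_shannon_entropy(seq)
    return np.array([sen, rsen, sen - rsen])


def encode_dataset(sequences: list[ProteinSequence]) -> FeatureMatrix:
    """Encode a list of sequences into a 3-column feature block."""
    values = np.vstack([encode_information_theory(s) for s in sequences])
    return FeatureMatrix(
        sample_ids=[s.identifier for s in sequences],
        feature_names=list(FEATURE_NAMES),
        values=values,
    )
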