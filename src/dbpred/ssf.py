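"""Sequential and structural features (SSF): 473 features per protein.

The block combines evolutionary information from a PSSM with predicted
secondary structure:

* 20 per-amino-acid average PSSM scores;
* a 420-component weighted n-gram vector over the PSSM *consensus sequence*
  (the residue maximising the background-weighted exponentiated score
  ``2**S[i,j] * p_j`` at each position): the 20 1-gram frequencies weighted
  ``20/420`` concatenated with the 400 contiguous 2-gram frequencies weighted
  ``400/420``, so the whole vector sums to 1;
* 6 secondary-structure sequence features: the H/E/C state fractions, the
  normalised longest H and E runs, and the frequency of the strand-helix-
  strand (E-H-E) motif among consecutive run triplets of the coil-free
  segment sequence;
* 3 global structural features (column means of the L x 3 probability
  matrix, order C/H/E) and ``lambda * 3`` local ones from splitting the rows
  into ``lambda`` contiguous segments (default ``lambda = 8``).

With the defaults (``lambda = 8``, structural order ``n = 1``) the layout is
``20 + 420 + 6 + 3 + 24 = 473``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    FeatureMatrix,
    PSSMProfile,
    ProteinSequence,
    SecondaryStructureProfile,
    SS_COLUMNS,
)


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Background amino-acid frequencies ``p_j`` (canonical order).

    Used to weight exponentiated PSSM scores when forming the consensus
    sequence. The default is uniform ``1/20``; users with database-derived
    frequencies (e.g. from the PDB) can supply their own.
    """

    p: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (20,):
            raise ValueError("background must have 20 components")
        if np.any(p <= 0):
            raise ValueError("background frequencies must be positive")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class SSFConfig:
    """Parameters of the SSF encoder.

    ``lambda_segments`` (default 8) controls the local structural split and
    ``n_order`` the structural product order; only ``n_order = 1`` — the
    setting that yields the 473-feature layout — is supported. ``pssm_scale``
    selects raw log-odds scores (default) or sigmoid-squashed ones for the
    20 averages.
    """

    lambda_segments: int = 8
    n_order: int = 1
    background: BackgroundFrequencies = field(default_factory=BackgroundFrequencies)
    pssm_scale: str = "raw"

    def __post_init__(self) -> None:
        if self.lambda_segments < 1:
            raise ValueError("lambda_segments must be >= 1")
        if self.n_order != 1:
            raise ValueError(
                "only structural order n = 1 is supported (it yields the "
                "473-feature layout); higher orders are not implemented"
            )
        if self.pssm_scale not in {"raw", "sigmoid"}:
            raise ValueError("pssm_scale must be 'raw' or 'sigmoid'")

    @property
    def n_features(self) -> int:
        return 20 + 420 + 6 + 3**self.n_order * (1 + self.lambda_segments)


def pssm_average_scores(pssm: PSSMProfile, scale: str = "raw") -> np.ndarray:
    """Column means of the PSSM: one average substitution score per amino acid."""
    if len(pssm) == 0:
        raise ValueError("empty PSSM profile")
    scores = pssm.scores
    if scale == "sigmoid":
        scores = 1.0 / (1.0 + np.exp(-scores))
    elif scale != "raw":
        raise ValueError("scale must be 'raw' or 'sigmoid'")
    return scores.mean(axis=0)


def consensus_sequence(
    pssm: PSSMProfile, bg: BackgroundFrequencies | None = None
) -> ProteinSequence:
    """Consensus residue per position: ``argmax_j 2**S[i,j] * p_j``.

    Ties resolve to the alphabetically first amino acid (argmax returns the
    first maximal index and columns are in canonical order).
    """
    bg = bg or BackgroundFrequencies()
    weighted = np.exp2(pssm.scores) * bg.p  # L x 20
    idx = np.argmax(weighted, axis=1)
    return ProteinSequence(
        identifier=pssm.sequence_id,
        residues="".join(AMINO_ACIDS[j] for j in idx),
    )


_ONE_GRAMS = list(AMINO_ACIDS)
_TWO_GRAMS = ["".join(t) for t in product(AMINO_ACIDS, repeat=2)]


def consensus_ngram_features(consensus: ProteinSequence) -> np.ndarray:
    """Weighted 1-gram + contiguous 2-gram frequencies of the consensus (420)."""
    s = consensus.residues
    L = len(s)
    if L < 2:
        raise ValueError("consensus shorter than 2 admits no 2-gram")
    c1 = np.zeros(20)
    for ch in s:
        c1[AMINO_ACIDS.index(ch)] += 1
    f1 = c1 / L
    c2: dict[str, int] = {}
    for i in range(L - 1):
        g = s[i : i + 2]
        c2[g] = c2.get(g, 0) + 1
    f2 = np.array([c2.get(g, 0) for g in _TWO_GRAMS], dtype=float) / (L - 1)
    return np.concatenate([(20.0 / 420.0) * f1, (400.0 / 420.0) * f2])


def _runs(states: str) -> list[tuple[str, int]]:
    """Run-length encoding of a state string."""
    return [(m.group(1), len(m.group(0))) for m in re.finditer(r"(.)\1*", states)]


def ss_sequence_features(ssp: SecondaryStructureProfile) -> np.ndarray:
    """Six features from the secondary-structure state string.

    ``[f_H, f_E, f_C, maxrun_H/L, maxrun_E/L, EHE-motif frequency]`` where
    the motif frequency counts E,H,E among consecutive run triplets of the
    coil-free segment sequence, divided by the number of triplet windows
    (at least 1 to keep short sequences defined).
    """
    states = ssp.states
    L = len(states)
    f_h = states.count("H") / L
    f_e = states.count("E") / L
    f_c = states.count("C") / L
    runs = _runs(states)
    maxrun_h = max((n for st, n in runs if st == "H"), default=0) / L
    maxrun_e = max((n for st, n in runs if st == "E"), default=0) / L
    # segment sequence: ordered H/E runs after removing coil
    seg = [st for st, _ in runs if st != "C"]
    windows = max(1, len(seg) - 2)
    ehe = sum(
        1
        for i in range(len(seg) - 2)
        if seg[i] == "E" and seg[i + 1] == "H" and seg[i + 2] == "E"
    )
    return np.array([f_h, f_e, f_c, maxrun_h, maxrun_e, ehe / windows])


def ss_global_features(ssp: SecondaryStructureProfile, n: int = 1) -> np.ndarray:
    """Column means of the structural probability matrix (3 values at n=1)."""
    if n != 1:
        raise ValueError("only structural order n = 1 is supported")
    return ssp.probabilities.mean(axis=0)


def ss_local_features(
    ssp: SecondaryStructureProfile, lambda_segments: int = 8, n: int = 1
) -> np.ndarray:
    """Per-segment column means after splitting rows into ``lambda`` parts.

    Segment sizes differ by at most one, remainder rows going to the earliest
    segments (the `np.array_split` convention).
    """
    if n != 1:
        raise ValueError("only structural order n = 1 is supported")
    L = len(ssp)
    if L < lambda_segments:
        raise ValueError(
            f"profile of length {L} cannot be split into {lambda_segments} segments"
        )
    parts = np.array_split(ssp.probabilities, lambda_segments, axis=0)
    return np.concatenate([part.mean(axis=0) for part in parts])


def feature_names(cfg: SSFConfig | None = None) -> list[str]:
    cfg = cfg or SSFConfig()
    names = [f"ssf.pssm_avg.{a}" for a in _ONE_GRAMS]
    names += [f"ssf.consensus.1g.{g}" for g in _ONE_GRAMS]
    names += [f"ssf.consensus.2g.{g}" for g in _TWO_GRAMS]
    names += [
        "ssf.ss_seq.f_H",
        "ssf.ss_seq.f_E",
        "ssf.ss_seq.f_C",
        "ssf.ss_seq.maxrun_H",
        "ssf.ss_seq.maxrun_E",
        "ssf.ss_seq.ehe_freq",
    ]
    names += [f"ssf.ss_glob.{c}" for c in SS_COLUMNS]
    for s in range(cfg.lambda_segments):
        names += [f"ssf.ss_loc.seg{s}.{c}" for c in SS_COLUMNS]
    return names


def encode_ssf(
    pssm: PSSMProfile,
    ssp: SecondaryStructureProfile,
    cfg: SSFConfig | None = None,
) -> np.ndarray:
    """The full 473-component SSF vector for one protein."""
    cfg = cfg or SSFConfig()
    if len(pssm) != len(ssp):
        raise ValueError(
            f"profile length mismatch for {pssm.sequence_id!r}: "
            f"PSSM has {len(pssm)} rows, secondary structure has {len(ssp)}"
        )
    consensus = consensus_sequence(pssm, cfg.background)
    return np.concatenate(
        [
            pssm_average_scores(pssm, scale=cfg.pssm_scale),
            consensus_ngram_features(consensus),
            ss_sequence_features(ssp),
            ss_global_features(ssp, n=cfg.n_order),
            ss_local_features(ssp, cfg.lambda_segments, n=cfg.n_order),
        ]
    )


def encode_dataset(
    pssms: list[PSSMProfile],
    ssps: list[SecondaryStructureProfile],
    cfg: SSFConfig | None = None,
) -> FeatureMatrix:
    """Encode paired profile lists into the 473-column SSF block."""
    cfg = cfg or SSFConfig()
    if len(pssms) != len(ssps):
        raise ValueError("need one secondary-structure profile per PSSM")
    values = np.vstack([encode_ssf(p, s, cfg) for p, s in zip(pssms, ssps)])
    return FeatureMatrix(
        sample_ids=[p.sequence_id for p in pssms],
        feature_names=feature_names(cfg),
        values=values,
    )
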