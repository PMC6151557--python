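"""Synthetic benchmark generator: sequences, profiles and labels.

Real DNA-binding benchmarks couple each protein with a PSI-BLAST PSSM and a
PSI-PRED secondary-structure prediction, neither of which can be fabricated
from the sequence alone without the external tools and databases. This
module instead *simulates* all three inputs with a controllable class
signal so every pipeline stage can be exercised end to end:

* positive-class sequences draw residues from a composition shifted by
  ``signal_strength`` toward the subset {K, R, G, S} (a plausible, purely
  synthetic stand-in for a binding-associated composition bias); negatives
  draw uniformly;
* PSSM rows are integer log-odds with the emitted residue's score elevated,
  bounded in [-9, 13] as in real PSI-BLAST output;
* secondary-structure probability rows are Dirichlet draws with the helix
  component enriched by ``ss_bias`` in positives; the state string is the
  per-row argmax.

Everything is deterministic given the seed. ``signal_strength = 0`` and
``ss_bias = 0`` make the two classes statistically indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    PSSMProfile,
    ProteinSequence,
    SecondaryStructureProfile,
    write_fasta,
    write_labels,
    write_pssm,
    write_ss2,
)

#: Residues whose frequency is boosted in the positive class (synthetic
#: signal carrier; not a biological claim).
SIGNAL_RESIDUES: str = "KRGS"


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and signal of a generated dataset."""

    n_positive: int = 50
    n_negative: int = 50
    length_range: tuple[int, int] = (50, 80)
    seed: int = 0
    signal_strength: float = 0.5
    ss_bias: float = 0.3

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("both classes need at least one sequence")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError("length range must satisfy 10 <= min <= max")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if not 0.0 <= self.ss_bias <= 1.0:
            raise ValueError("ss_bias must lie in [0, 1]")


@dataclass
class FixtureDataset:
    """In-memory result of a generation run (file writing is optional)."""

    sequences: list[ProteinSequence]
    pssms: list[PSSMProfile]
    ss_profiles: list[SecondaryStructureProfile]
    labels: np.ndarray


def _residue_distribution(signal_strength: float) -> np.ndarray:
    """Mixture of uniform and a point mass spread over the signal residues."""
    p = np.full(20, (1.0 - signal_strength) / 20.0)
    for aa in SIGNAL_RESIDUES:
        p[AMINO_ACIDS.index(aa)] += signal_strength / len(SIGNAL_RESIDUES)
    return p


def _make_pssm(seq: ProteinSequence, rng: np.random.Generator) -> PSSMProfile:
    L = len(seq)
    scores = rng.integers(-6, 3, size=(L, 20))  # background log-odds noise
    for i, aa in enumerate(seq.residues):
        scores[i, AMINO_ACIDS.index(aa)] = rng.integers(4, 9)  # conserved residue
    return PSSMProfile(
        sequence_id=seq.identifier,
        scores=np.clip(scores, -9, 13),
        row_residues=seq.residues,
    )


def _make_ss2(
    seq: ProteinSequence, ss_bias: float, rng: np.random.Generator
) -> SecondaryStructureProfile:
    L = len(seq)
    # Dirichlet over (C, H, E); helix concentration raised by the bias
    alpha = np.array([2.0, 2.0 + 8.0 * ss_bias, 2.0])
    probs = rng.dirichlet(alpha, size=L)
    probs = np.round(probs, 3)
    probs[:, 0] = np.clip(np.round(1.0 - probs[:, 1] - probs[:, 2], 3), 0.0, 1.0)
    states = "".join("CHE"[j] for j in np.argmax(probs, axis=1))
    return SecondaryStructureProfile(
        sequence_id=seq.identifier, states=states, probabilities=probs
    )


def generate_fixture_dataset(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> FixtureDataset:
    """Generate a balanced-by-construction labelled dataset.

    When ``out_dir`` is given, writes ``sequences.fasta``, ``labels.csv``
    and per-sequence ``pssm/<id>.pssm`` and ``ss2/<id>.ss2`` files, all of
    which parse cleanly back through :mod:`dbpred.io_formats`.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    p_pos = _residue_distribution(spec.signal_strength)
    p_neg = np.full(20, 0.05)

    sequences: list[ProteinSequence] = []
    pssms: list[PSSMProfile] = []
    ss_profiles: list[SecondaryStructureProfile] = []
    labels: list[int] = []

    aa_array = np.array(list(AMINO_ACIDS))
    for cls, count, p in ((1, spec.n_positive, p_pos), (0, spec.n_negative, p_neg)):
        tag = "pos" if cls == 1 else "neg"
        for i in range(count):
            L = int(rng.integers(lo, hi + 1))
            residues = "".join(rng.choice(aa_array, size=L, p=p))
            seq = ProteinSequence(identifier=f"{tag}{i:04d}", residues=residues)
            sequences.append(seq)
            pssms.append(_make_pssm(seq, rng))
            ss_profiles.append(
                _make_ss2(seq, spec.ss_bias if cls == 1 else 0.0, rng)
            )
            labels.append(cls)

    dataset = FixtureDataset(
        sequences=sequences,
        pssms=pssms,
        ss_profiles=ss_profiles,
        labels=np.array(labels, dtype=int),
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(dataset: FixtureDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "pssm").mkdir(exist_ok=True)
    (out_dir / "ss2").mkdir(exist_ok=True)
    write_fasta(dataset.sequences, out_dir / "sequences.fasta")
    write_labels(
        [s.identifier for s in dataset.sequences], dataset.labels, out_dir / "labels.csv"
    )
    for seq, pssm, ssp in zip(dataset.sequences, dataset.pssms, dataset.ss_profiles):
        write_pssm(pssm, out_dir / "pssm" / f"{seq.identifier}.pssm")
        write_ss2(ssp, seq.residues, out_dir / "ss2" / f"{seq.identifier}.ss2")
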