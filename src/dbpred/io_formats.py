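"""Readers, writers and domain containers for the external file formats.

The package consumes three kinds of per-protein inputs:

* multi-record FASTA protein sequences,
* PSI-BLAST ASCII position-specific scoring matrices (the layout written by
  ``psiblast -out_ascii_pssm``), of which only the first, log-odds, 20-column
  block is used,
* PSI-PRED ``.ss2`` VFORMAT secondary-structure predictions (per-residue
  H/E/C state plus a coil/helix/strand probability triple).

All 20-wide amino-acid vectors throughout the package use the canonical
alphabetical one-letter order ``ACDEFGHIKLMNPQRSTVWY``; file column orders
are remapped to it on read so downstream feature vectors are bit-stable
regardless of the order a tool happened to print.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Canonical order of the 20 standard amino acids (alphabetical one-letter).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Secondary-structure probability columns in .ss2 file order.
SS_COLUMNS: tuple[str, str, str] = ("C", "H", "E")
SS_STATES: frozenset[str] = frozenset("HEC")

#: Replacements applied under the ``map`` residue policy; anything else
#: non-standard is dropped.
_RESIDUE_MAP = {"B": "D", "Z": "E", "U": "C"}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20-letter amino-acid alphabet."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.identifier!r} is empty")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"sequence {self.identifier!r} contains non-standard residues "
                f"{sorted(bad)}; sanitize before constructing"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PSSMProfile:
    """Position-specific scoring matrix aligned to one sequence.

    ``scores`` has one row per sequence position and 20 columns in canonical
    amino-acid order (log-odds integers as printed by PSI-BLAST).
    """

    sequence_id: str
    scores: np.ndarray
    row_residues: str

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != len(AMINO_ACIDS):
            raise ValueError("PSSM scores must be an L x 20 matrix")
        if scores.shape[0] != len(self.row_residues):
            raise ValueError(
                f"PSSM for {self.sequence_id!r}: {scores.shape[0]} score rows "
                f"but {len(self.row_residues)} residues"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError("PSSM scores must be finite")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class SecondaryStructureProfile:
    """Per-residue secondary-structure states and probabilities.

    ``probabilities`` columns follow the ``.ss2`` convention (C, H, E).
    """

    sequence_id: str
    states: str
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ValueError("probabilities must be an L x 3 matrix")
        if probs.shape[0] != len(self.states):
            raise ValueError(
                f"profile {self.sequence_id!r}: {len(self.states)} states but "
                f"{probs.shape[0]} probability rows"
            )
        bad = set(self.states) - SS_STATES
        if bad:
            raise ValueError(f"unknown secondary-structure states {sorted(bad)}")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 0.05):
            raise ValueError("probability rows must sum to 1 within 0.05")
        object.__setattr__(self, "probabilities", probs)

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class FeatureMatrix:
    """Samples x named-features matrix with encoder-block provenance.

    Feature names are block-prefixed (``it.``, ``ksng.``, ``ssf.`` ...) so a
    fused matrix records which encoder produced each column.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, d = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError("row count must equal number of sample ids")
        if d != len(self.feature_names):
            raise ValueError("column count must equal number of feature names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(
            sample_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            values=self.values[:, idx],
        )


@dataclass
class LabeledDataset:
    """Feature matrix plus one binary label per sample (1 = DNA binding)."""

    features: FeatureMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != self.features.n_samples:
            raise ValueError("need exactly one label per sample")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.features.n_samples

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            features=FeatureMatrix(
                sample_ids=[self.features.sample_ids[i] for i in idx],
                feature_names=list(self.features.feature_names),
                values=self.features.values[idx],
            ),
            labels=self.labels[idx],
        )


# ---------------------------------------------------------------------------
# sanitization


def sanitize_residues(raw: str, policy: str = "drop") -> str:
    """Case-fold, strip whitespace and resolve non-standard residue codes.

    policy ``drop``: remove every character outside the 20-letter alphabet.
    policy ``map``: B→D, Z→E, U→C; other non-standard letters dropped.
    """
    if policy not in {"drop", "map"}:
        raise ValueError(f"unknown residue policy {policy!r}")
    out = []
    for ch in raw.upper():
        if ch.isspace():
            continue
        if ch in AA_INDEX:
            out.append(ch)
        elif policy == "map" and ch in _RESIDUE_MAP:
            out.append(_RESIDUE_MAP[ch])
        # else: dropped
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, policy: str = "drop") -> list[ProteinSequence]:
    """Read a multi-record FASTA file into sanitized :class:`ProteinSequence`s."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    sequences = []
    for rec in records:
        residues = sanitize_residues(str(rec.seq), policy=policy)
        if not residues:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        sequences.append(ProteinSequence(identifier=rec.id, residues=residues))
    return sequences


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.identifier}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(path: str | Path, sequence_id: str | None = None) -> PSSMProfile:
    """Parse the first (log-odds) block of a PSI-BLAST ASCII PSSM file.

    The header line carries the amino-acid column letters (20 of them, or 40
    when the percentage block is present); scores are remapped to canonical
    alphabetical order. The percentage block and the trailing information
    columns, if present, are ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_letters: list[str] | None = None
    header_idx = -1
    for i, line in enumerate(lines):
        tokens = line.split()
        if (
            len(tokens) >= 20
            and all(len(t) == 1 and t in AA_INDEX for t in tokens[:20])
        ):
            header_letters = tokens[:20]
            header_idx = i
            break
    if header_letters is None:
        raise FormatError(f"{path}: no PSSM header line with 20 amino-acid columns")

    col_order = [AA_INDEX[a] for a in header_letters]
    if sorted(col_order) != list(range(20)):
        raise FormatError(f"{path}: header does not name all 20 amino acids once")

    rows: list[list[int]] = []
    residues: list[str] = []
    expected_index = 1
    for line in lines[header_idx + 1 :]:
        tokens = line.split()
        if not tokens:
            continue
        if not tokens[0].lstrip("-").isdigit():
            break  # footer (K/Lambda statistics) reached
        if len(tokens) < 22:
            raise FormatError(
                f"{path}: truncated PSSM row at position {tokens[0]}: "
                f"expected at least 22 fields, got {len(tokens)}"
            )
        pos = int(tokens[0])
        if pos != expected_index:
            raise FormatError(f"{path}: non-consecutive row index {pos}")
        expected_index += 1
        residue = tokens[1].upper()
        if residue not in AA_INDEX:
            raise FormatError(f"{path}: unknown residue {residue!r} in row {pos}")
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer score in row {pos}") from exc
        residues.append(residue)
        rows.append(scores)

    if not rows:
        raise FormatError(f"{path}: no score rows found")

    raw = np.array(rows, dtype=float)
    canonical = np.empty_like(raw)
    canonical[:, col_order] = raw
    return PSSMProfile(
        sequence_id=sequence_id or path.stem,
        scores=canonical,
        row_residues="".join(residues),
    )


def write_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile back out in the PSI-BLAST ASCII layout (log-odds block)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted, "
            "observed percentages, and information per position\n"
        )
        fh.write("      " + "  ".join(AMINO_ACIDS) + "\n")
        for i, (residue, row) in enumerate(
            zip(profile.row_residues, profile.scores), start=1
        ):
            cells = " ".join(f"{int(v):3d}" for v in row)
            fh.write(f"{i:5d} {residue} {cells}\n")


# ---------------------------------------------------------------------------
# PSI-PRED .ss2


def read_ss2(
    path: str | Path,
    sequence_id: str | None = None,
    expected_length: int | None = None,
) -> SecondaryStructureProfile:
    """Parse a PSI-PRED VFORMAT ``.ss2`` prediction file.

    Each data row holds: residue index, residue letter, state (H/E/C) and the
    coil, helix, strand probabilities. ``expected_length`` cross-checks the
    row count against the accompanying sequence.
    """
    path = Path(path)
    states: list[str] = []
    probs: list[list[float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 6:
            raise FormatError(f"{path}: malformed .ss2 row {line!r}")
        state = tokens[2]
        if state not in SS_STATES:
            raise FormatError(f"{path}: unknown state letter {state!r}")
        try:
            triple = [float(t) for t in tokens[3:6]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric probability in {line!r}") from exc
        states.append(state)
        probs.append(triple)

    if not states:
        raise FormatError(f"{path}: no prediction rows found")
    if expected_length is not None and len(states) != expected_length:
        raise FormatError(
            f"{path}: {len(states)} rows but sequence length {expected_length}"
        )
    return SecondaryStructureProfile(
        sequence_id=sequence_id or path.stem,
        states="".join(states),
        probabilities=np.array(probs, dtype=float),
    )


def write_ss2(profile: SecondaryStructureProfile, residues: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (PSIPRED V4.0)\n\n")
        for i, (aa, state, row) in enumerate(
            zip(residues, profile.states, profile.probabilities), start=1
        ):
            fh.write(
                f"{i:4d} {aa} {state}  {row[0]:6.3f} {row[1]:6.3f} {row[2]:6.3f}\n"
            )


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(
    fm: FeatureMatrix,
    path: str | Path,
    format: str = "csv",
    labels: np.ndarray | None = None,
) -> None:
    """Write a feature matrix as CSV (header row of names) or LIBSVM.

    LIBSVM output uses 1-based feature indices and labels +1/-1; ``labels``
    is required for that format (0/1 labels are mapped to -1/+1).
    """
    path = Path(path)
    if format == "csv":
        df = fm.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, float_format="%.12g")
    elif format == "libsvm":
        if labels is None:
            raise ValueError("libsvm format requires labels")
        labels = np.asarray(labels, dtype=int)
        if len(labels) != fm.n_samples:
            raise ValueError("one label per sample required")
        with open(path, "w") as fh:
            for row, y in zip(fm.values, labels):
                sign = "+1" if y == 1 else "-1"
                cells = " ".join(
                    f"{j + 1}:{v:.12g}" for j, v in enumerate(row) if v != 0.0
                )
                fh.write(f"{sign} {cells}\n".rstrip() + "\n")
    else:
        raise ValueError(f"unknown feature-table format {format!r}")


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read back a CSV feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, index_col=0)
    return FeatureMatrix.from_dataframe(df)


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a two-column ``sample_id,label`` CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: label table needs sample_id and label columns")
    return [str(s) for s in df.iloc[:, 0]], df.iloc[:, 1].to_numpy(dtype=int)


def write_labels(sample_ids: Sequence[str], labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "label": np.asarray(labels, dtype=int)}).to_csv(
        path, index=False
    )
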