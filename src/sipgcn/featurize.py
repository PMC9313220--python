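"""Fixed-length descriptors from variable-length PSSM profiles.

Two schemes are provided.  ``pssm_composition`` is the main 400-dimensional
residue-grouped composition of the logistic-normalised profile, used as the
layer-0 node features of the graph network.  ``ac_features`` is the
autocovariance baseline: lagged covariances of each profile column,
yielding 20 x lag values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from sipgcn.io_formats import PSSMMatrix, STANDARD_AMINO_ACIDS


@dataclass
class FeatureVector:
    """A fixed-length protein descriptor with its scheme tag."""

    values: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.values.size


def normalize_pssm(pssm: PSSMMatrix) -> PSSMMatrix:
    """Squash raw log-odds scores into (0, 1) with the logistic function.

    Each score x becomes 1 / (1 + exp(-x)), reconciling the log-odds content
    of PSI-BLAST profiles with a probability-like scale and bounding the
    features fed to the graph network.  Idempotent only on the raw scale;
    callers normalise exactly once.
    """
    squashed = 1.0 / (1.0 + np.exp(-pssm.scores))
    return PSSMMatrix(
        scores=squashed, residues=pssm.residues, column_order=pssm.column_order
    )


def _is_normalized(scores: np.ndarray) -> bool:
    return bool(np.all(scores > 0.0) and np.all(scores < 1.0))


def pssm_composition(pssm: PSSMMatrix) -> FeatureVector:
    """Residue-grouped 20 x 20 composition of the normalised profile.

    Row a, column j of the composition matrix is the mean normalised score
    in profile column j over the positions whose residue is amino acid a;
    rows for amino acids absent from the sequence are zero.  Rows are
    ordered alphabetically over the 20 standard amino acids and flattened
    row-major to 400 values.  Raw (un-normalised) input is normalised
    internally; ambiguous residues (X/B/Z/...) contribute no rows.
    """
    scores = pssm.scores
    if not _is_normalized(scores):
        scores = 1.0 / (1.0 + np.exp(-scores))
    comp = np.zeros((20, 20))
    residues = np.frombuffer(pssm.residues.encode("ascii"), dtype=np.uint8)
    any_standard = False
    for a, aa in enumerate(STANDARD_AMINO_ACIDS):
        mask = residues == ord(aa)
        if mask.any():
            comp[a] = scores[mask].mean(axis=0)
            any_standard = True
    if not any_standard:
        raise ValueError("sequence contains no standard amino acids")
    return FeatureVector(values=comp.ravel(), scheme="pssm_composition")


def ac_features(pssm: PSSMMatrix, lg: int = 5) -> FeatureVector:
    """Autocovariance descriptor of the normalised profile.

    For each profile column j and lag l in 1..lg,

        AC(l, j) = (1 / (N - l)) * sum_{i=1}^{N-l} (S[i,j] - mu_j) (S[i+l,j] - mu_j)

    where S is the logistic-normalised score matrix and mu_j its column
    mean.  Output is length 20 * lg, ordered column-major (all lags of
    column 1, then column 2, ...).
    """
    if lg < 1:
        raise ValueError(f"lag bound must be >= 1, got {lg}")
    n = pssm.n_residues
    if n <= lg:
        raise ValueError(
            f"protein of length {n} is too short for lag bound {lg} (need N > lg)"
        )
    scores = pssm.scores
    if not _is_normalized(scores):
        scores = 1.0 / (1.0 + np.exp(-scores))
    centered = scores - scores.mean(axis=0, keepdims=True)
    out = np.empty((20, lg))
    for l in range(1, lg + 1):
        out[:, l - 1] = (centered[:-l] * centered[l:]).sum(axis=0) / (n - l)
    return FeatureVector(values=out.ravel(), scheme="ac")


def feature_matrix(
    pssms: Dict[str, PSSMMatrix],
    ids: Sequence[str],
    scheme: str = "pssm_composition",
    *,
    ac_lag: int = 5,
) -> np.ndarray:
    """Stack per-protein descriptors into an (n_proteins x dim) matrix."""
    rows: List[np.ndarray] = []
    for pid in ids:
        pssm = pssms[pid]
        if scheme == "pssm_composition":
            fv = pssm_composition(pssm)
        elif scheme == "ac":
            fv = ac_features(pssm, lg=ac_lag)
        else:
            raise ValueError(f"unknown feature scheme {scheme!r}")
        rows.append(fv.values)
    return np.vstack(rows)


def save_feature_matrix(
    matrix: np.ndarray, ids: Sequence[str], path, delimiter: str = "\t"
) -> None:
    """Export a feature matrix as delimited text, protein id in the first column."""
    with open(path, "w") as fh:
        for pid, row in zip(ids, matrix):
            fh.write(pid + delimiter + delimiter.join(f"{v:.10g}" for v in row) + "\n")
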