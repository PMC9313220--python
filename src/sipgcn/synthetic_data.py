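"""Synthetic labelled proteins with PSSM-like profiles and a planted class signal.

The generator emulates the on-disk layout of a curated SIP dataset —
FASTA sequences, one PSI-BLAST-style ASCII profile per protein, and a
label table — without running PSI-BLAST.  Profile entries are independent
discretised Gaussian log-odds scores (mean 0, sd 2); the class signal is a
mean shift of size ``shift`` added to a designated subset of the 20
profile columns for positive-class proteins, so the composition featuriser
provably carries the signal.  With ``shift=0`` the two classes are
exchangeable draws from the same distribution.

Imbalance presets mirror the curated human (1441 SIPs : 15,938 non-SIPs,
about 1:11) and yeast (710 : 5511, about 1:7.8) class ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from sipgcn.io_formats import (
    PSIBLAST_COLUMN_ORDER,
    ProteinRecord,
    PSSMMatrix,
    write_fasta,
    write_labels,
    write_psiblast_pssm,
)

#: Curated-dataset class counts usable as (n_pos, n_neg) presets.
IMBALANCE_PRESETS: Dict[str, Tuple[int, int]] = {
    "human": (1441, 15938),
    "yeast": (710, 5511),
}

_SCORE_SD = 2.0


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    ``shift`` is the effect size delta added to ``signal_cols`` (profile
    column indices, 0-19) of positive-class score matrices before
    discretisation; lengths are drawn uniformly from ``length_range``
    (default [50, 300], the lower end of the curated 50-5000 filter, kept
    short so whole pipelines stay fast).
    """

    n_pos: int
    n_neg: int
    length_range: Tuple[int, int] = (50, 300)
    shift: float = 3.0
    signal_cols: Tuple[int, ...] = (0, 1, 2, 3, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")
        lo, hi = self.length_range
        if not (1 <= lo <= hi <= 5000):
            raise ValueError(f"length_range must lie within [1, 5000], got {self.length_range}")
        if self.shift != 0 and len(self.signal_cols) == 0:
            raise ValueError("shift is non-zero but signal_cols is empty")
        if any(c < 0 or c > 19 for c in self.signal_cols):
            raise ValueError("signal_cols must be profile column indices in 0..19")


def generate_records(
    spec: SyntheticSpec,
) -> Tuple[List[ProteinRecord], Dict[str, PSSMMatrix]]:
    """Generate labelled records and their profile matrices in memory.

    Sequences are uniform over the 20 standard amino acids; scores are
    round(N(0, 2) + delta * 1[positive and signal column]).  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: List[ProteinRecord] = []
    pssms: Dict[str, PSSMMatrix] = {}
    alphabet = np.array(list(PSIBLAST_COLUMN_ORDER))
    for label, count, prefix in ((1, spec.n_pos, "sip"), (0, spec.n_neg, "neg")):
        for i in range(count):
            pid = f"{prefix}{i:05d}"
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(alphabet[rng.integers(0, 20, size=length)])
            scores = rng.normal(0.0, _SCORE_SD, size=(length, 20))
            if label == 1 and spec.shift != 0:
                scores[:, list(spec.signal_cols)] += spec.shift
            scores = np.rint(scores)
            records.append(ProteinRecord(id=pid, sequence=seq, label=label))
            pssms[pid] = PSSMMatrix(scores=scores, residues=seq)
    return records, pssms


def generate_dataset(spec: SyntheticSpec, outdir) -> Dict[str, Path]:
    """Generate a dataset and write it in the layout the loader consumes.

    Writes ``proteins.fasta``, ``pssm/<id>.pssm`` and ``labels.tsv`` under
    ``outdir`` and returns their paths.  Byte-identical for identical specs.
    """
    records, pssms = generate_records(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "proteins.fasta"
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    labels = outdir / "labels.tsv"
    write_fasta(records, fasta)
    for rec in records:
        write_psiblast_pssm(pssms[rec.id], pssm_dir / f"{rec.id}.pssm")
    write_labels({r.id: r.label for r in records}, labels)
    return {"fasta": fasta, "pssm_dir": pssm_dir, "labels": labels}
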