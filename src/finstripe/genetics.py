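"""Misclassification-rate matrices, K2P genetic distances and the Mantel test.

The question these connect: do the classifier's confusions fall between
genetically close species? The pairwise misclassification rate between two
classes is compared (Mantel permutation test) against the Kimura
two-parameter distance between their mitochondrial ND2 sequences; a
negative Mantel r means closer relatives are confused more often.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .classify import ConfusionMatrix
from .errors import LabelMismatchError, SaturationError


@dataclass
class DistanceMatrix:
    """Symmetric non-negative m x m matrix with a zero diagonal."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.labels)
        if self.values.shape != (m, m):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != m:
            raise ValueError("duplicate labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")
        if (self.values < 0).any():
            raise ValueError("negative distances")

    @property
    def m(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.m, k=1)
        return self.values[iu]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float),
                   labels=[str(c) for c in df.columns])


def misclassification_matrix(cm: ConfusionMatrix) -> DistanceMatrix:
    """Symmetric pooled pairwise misclassification rates.

    rate(i, j) = (times i predicted as j + times j predicted as i)
                 / (total predictions of i + total predictions of j),
    with a zero diagonal.
    """
    counts = cm.counts.to_numpy()
    totals = cm.column_sums.to_numpy()
    if (totals == 0).any():
        raise ValueError("class with zero predictions")
    m = len(totals)
    rates = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            # counts[p, a]: actual a predicted as p
            cross = counts[j, i] + counts[i, j]
            rates[i, j] = rates[j, i] = cross / (totals[i] + totals[j])
    return DistanceMatrix(values=rates, labels=[str(c) for c in cm.classes])


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance, substitutions per site.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q), with P and Q the transition
    and transversion proportions over sites where both sequences carry an
    unambiguous A/C/G/T (pairwise deletion of gaps and ambiguities).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    n = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError("no comparable sites")
    p = transitions / n
    q = transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("saturated: K2P distance undefined")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def k2p_matrix(sequences: dict[str, str]) -> DistanceMatrix:
    """All pairwise K2P distances of a label -> aligned-sequence mapping.

    Classes that share an identical sequence (e.g. the two sexes of one
    species mapped to the same accession) get distance 0.
    """
    labels = list(sequences)
    m = len(labels)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = k2p_distance(sequences[labels[i]], sequences[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(values=values, labels=labels)


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into a label -> sequence mapping."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(s) for s in records.values()}
    if len(lengths) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return records


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    alternative: str


def mantel_test(a: DistanceMatrix, b: DistanceMatrix, n_perm: int = 9999,
                seed: int = 0, alternative: str = "less") -> MantelResult:
    """Mantel permutation test of correlation between two distance matrices.

    r is the Pearson correlation of the m(m-1)/2 upper-triangle entries;
    the null distribution permutes rows and columns of ``b`` jointly. The
    default alternative "less" tests for a negative association (closer
    genetic distance, higher misclassification); "greater" and
    "two-sided" are available. p = (exceedances + 1) / (n_perm + 1).
    """
    if a.labels != b.labels:
        raise LabelMismatchError("distance matrices have different labels")
    if a.m < 4:
        raise ValueError("need at least 4 labels for a Mantel test")
    if alternative not in {"less", "greater", "two-sided"}:
        raise ValueError(f"unknown alternative {alternative!r}")

    x = a.upper_triangle()
    y = b.upper_triangle()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in off-diagonal distances")

    def corr(y_vals: np.ndarray) -> float:
        return float(np.corrcoef(x, y_vals)[0, 1])

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(a.m, k=1)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.m)
        permuted = b.values[np.ix_(perm, perm)]
        r_perm = corr(permuted[iu])
        if alternative == "less":
            exceed += r_perm <= r_obs
        elif alternative == "greater":
            exceed += r_perm >= r_obs
        else:
            exceed += abs(r_perm) >= abs(r_obs)
    p = (exceed + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=n_perm,
                        alternative=alternative)
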