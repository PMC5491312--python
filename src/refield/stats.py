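"""Empirical constraints the model is fitted to.

Three statistic families are extracted from a pair alignment: single-site
frequencies ``f1[i, a]``, joint frequencies ``f2[i, j, a, b]`` for i < j, and
the repeat-identity distribution ``pid[k]`` over match counts k = 0..L/2
between the two halves of each row.  Gap is a full state throughout and a
gap aligned with a gap counts as a match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import PROTEIN, Alphabet
from .errors import ValidationError
from .msa import Alignment

_ATOL = 1e-12


def count_identity(row: str | np.ndarray) -> tuple[int, float]:
    """Match count and fractional identity between the two halves of a row.

    Positions where both halves carry a gap count as matches.
    """
    L = len(row)
    if L % 2:
        raise ValidationError("pair sequence length must be even")
    half = L // 2
    if isinstance(row, str):
        matches = sum(row[i] == row[i + half] for i in range(half))
    else:
        matches = int(np.count_nonzero(row[:half] == row[half:]))
    return matches, matches / half


def matrix_f1(mat: np.ndarray, q: int) -> np.ndarray:
    """Single-site frequencies of an (n, L) integer matrix."""
    n, L = mat.shape
    f1 = np.empty((L, q))
    for i in range(L):
        f1[i] = np.bincount(mat[:, i], minlength=q) / n
    return f1


def matrix_f2(mat: np.ndarray, q: int) -> np.ndarray:
    """Joint frequencies, dense (L, L, q, q), populated for i < j only."""
    n, L = mat.shape
    f2 = np.zeros((L, L, q, q))
    flat = mat.astype(np.int32)
    for i in range(L):
        for j in range(i + 1, L):
            counts = np.bincount(flat[:, i] * q + flat[:, j], minlength=q * q)
            f2[i, j] = counts.reshape(q, q) / n
    return f2


def matrix_pid(mat: np.ndarray) -> np.ndarray:
    """Repeat-identity distribution over match counts 0..L/2."""
    n, L = mat.shape
    if L % 2:
        raise ValidationError("pair alignment width must be even")
    half = L // 2
    matches = np.count_nonzero(mat[:, :half] == mat[:, half:], axis=1)
    return np.bincount(matches, minlength=half + 1) / n


@dataclass(frozen=True)
class FrequencyStatistics:
    """Single-site, joint and repeat-identity statistics of a pair alignment."""

    f1: np.ndarray  # (L, q)
    f2: np.ndarray  # (L, L, q, q), i < j
    pid: np.ndarray  # (L/2 + 1,)
    n_effective: int
    alphabet: Alphabet = PROTEIN

    def __post_init__(self) -> None:
        self.validate()

    @property
    def L(self) -> int:
        return self.f1.shape[0]

    @property
    def q(self) -> int:
        return self.f1.shape[1]

    def validate(self) -> None:
        L, q = self.f1.shape
        if self.f2.shape != (L, L, q, q):
            raise ValidationError("f2 shape inconsistent with f1")
        if self.pid.shape != (L // 2 + 1,):
            raise ValidationError("pid must have L/2 + 1 bins")
        if np.any(self.f1 < 0) or np.any(self.f2 < 0) or np.any(self.pid < 0):
            raise ValidationError("negative frequency entry")
        if not np.allclose(self.f1.sum(axis=1), 1.0, atol=_ATOL):
            raise ValidationError("f1 rows must sum to 1")
        iu, ju = np.triu_indices(L, k=1)
        sums = self.f2[iu, ju].sum(axis=(1, 2))
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("f2 tables must sum to 1")
        # marginal consistency: sum_b f2(i,j,a,b) = f1(i,a)
        marg_i = self.f2[iu, ju].sum(axis=2)
        if not np.allclose(marg_i, self.f1[iu], atol=1e-9):
            raise ValidationError("f2 does not marginalize to f1")
        if not np.isclose(self.pid.sum(), 1.0, atol=_ATOL):
            raise ValidationError("pid must sum to 1")

    def save(self, path: str | Path) -> None:
        """Write metadata + pid as JSON alongside an .npz array container."""
        path = Path(path)
        meta = {
            "format_version": 1,
            "L": int(self.L),
            "q": int(self.q),
            "alphabet": self.alphabet.symbols,
            "n_effective": int(self.n_effective),
            "pid": self.pid.tolist(),
            "arrays": path.with_suffix(path.suffix + ".npz").name,
        }
        path.write_text(json.dumps(meta, indent=1))
        np.savez_compressed(
            path.with_suffix(path.suffix + ".npz"), f1=self.f1, f2=self.f2
        )

    @classmethod
    def load(cls, path: str | Path) -> "FrequencyStatistics":
        path = Path(path)
        meta = json.loads(path.read_text())
        arrays = np.load(path.parent / meta["arrays"])
        return cls(
            f1=arrays["f1"],
            f2=arrays["f2"],
            pid=np.asarray(meta["pid"], dtype=float),
            n_effective=meta["n_effective"],
            alphabet=Alphabet(meta["alphabet"]),
        )


def statistics_from_matrix(
    mat: np.ndarray,
    q: int,
    pseudocount: float = 0.0,
    alphabet: Alphabet = PROTEIN,
) -> FrequencyStatistics:
    """Counting backend shared by the empirical and model-sample paths."""
    f1 = matrix_f1(mat, q)
    f2 = matrix_f2(mat, q)
    pid = matrix_pid(mat)
    if pseudocount > 0:
        pc = pseudocount
        f1 = (1 - pc) * f1 + pc / q
        L = mat.shape[1]
        iu, ju = np.triu_indices(L, k=1)
        f2[iu, ju] = (1 - pc) * f2[iu, ju] + pc / q**2
    return FrequencyStatistics(
        f1=f1, f2=f2, pid=pid, n_effective=mat.shape[0], alphabet=alphabet
    )


def compute_frequencies(
    aln: Alignment, pseudocount: float = 1e-5
) -> FrequencyStatistics:
    """Count f1, f2 and pid over a pair alignment.

    Counts are divided by the number of rows and then mixed with the uniform
    distribution at weight ``pseudocount`` (f1 with 1/q, f2 with 1/q^2) so the
    log-frequency initialization of the fit is finite.  pid is left unmixed.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if not aln.pair_flag:
        raise ValidationError("frequencies are computed on a pair alignment")
    return statistics_from_matrix(
        aln.to_matrix(), aln.alphabet.q, pseudocount, aln.alphabet
    )
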