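"""The evolutionary-field parameters and energy evaluation.

A sequence of two concatenated repeats is scored as

    E(s) = - sum_i h_i(s_i) + sum_{i<j} J_ij(s_i, s_j) - lambda[k(s)]

where k(s) is the number of positions at which the two halves carry the same
state (gap included).  Lower energy means a sequence more compatible with the
family.  Couplings are stored for i < j only; J_ii is identically zero, and a
symmetric accessor covers i > j.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import PROTEIN, Alphabet
from .errors import ValidationError
from .stats import count_identity

FORMAT_VERSION = 1


def parameter_counts(L: int, q: int = 21) -> tuple[int, int, int]:
    """Numbers of field, coupling and identity parameters for width L.

    n_h = L*q, n_J = ((L*q)^2 - L*q)/2 (distinct position-state pairs),
    n_lambda = L/2 + 1 (match counts 0..L/2).
    """
    if L % 2:
        raise ValidationError("pair alignment width L must be even")
    if q < 2:
        raise ValidationError("alphabet size q must be >= 2")
    n_h = L * q
    n_j = (n_h * n_h - n_h) // 2
    n_lam = L // 2 + 1
    return n_h, n_j, n_lam


@dataclass
class ModelParameters:
    """Fields h[i, a], couplings J[i, j, a, b] (i < j) and identity
    potentials lam[k]."""

    h: np.ndarray  # (L, q)
    J: np.ndarray  # (L, L, q, q), strictly upper triangular in (i, j)
    lam: np.ndarray  # (L/2 + 1,)
    alphabet: Alphabet = field(default_factory=lambda: PROTEIN)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.J = np.asarray(self.J, dtype=np.float64)
        self.lam = np.asarray(self.lam, dtype=np.float64)
        L, q = self.h.shape
        if L % 2:
            raise ValidationError("L must be even")
        if self.J.shape != (L, L, q, q):
            raise ValidationError("J shape inconsistent with h")
        if self.lam.shape != (L // 2 + 1,):
            raise ValidationError("lam must have L/2 + 1 entries")
        if not (
            np.all(np.isfinite(self.h))
            and np.all(np.isfinite(self.J))
            and np.all(np.isfinite(self.lam))
        ):
            raise ValidationError("parameters must be finite")
        il, jl = np.tril_indices(L)
        if np.any(self.J[il, jl]):
            raise ValidationError("J must be strictly upper triangular in (i, j)")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @property
    def half(self) -> int:
        return self.L // 2

    @classmethod
    def zeros(cls, L: int, q: int = 21, alphabet: Alphabet = PROTEIN) -> "ModelParameters":
        return cls(
            h=np.zeros((L, q)),
            J=np.zeros((L, L, q, q)),
            lam=np.zeros(L // 2 + 1),
            alphabet=alphabet,
        )

    def coupling(self, i: int, j: int, a: int, b: int) -> float:
        """Symmetric access: J(i,j,a,b) = J(j,i,b,a); zero on the diagonal."""
        if i == j:
            return 0.0
        if i < j:
            return float(self.J[i, j, a, b])
        return float(self.J[j, i, b, a])

    def symmetric_couplings(self) -> np.ndarray:
        """Dense (L, L, q, q) table with Jsym[i, j, a, b] = coupling(i, j, a, b)."""
        return self.J + self.J.transpose(1, 0, 3, 2)

    def nonzero_couplings(self) -> int:
        return int(np.count_nonzero(self.J))

    # ------------------------------------------------------------------ I/O

    def save(self, path: str | Path) -> None:
        """JSON container: header plus sparse (i, j, a, b, value) couplings."""
        i, j, a, b = np.nonzero(self.J)
        payload = {
            "format_version": FORMAT_VERSION,
            "L": int(self.L),
            "q": int(self.q),
            "alphabet": self.alphabet.symbols,
            "h": self.h.tolist(),
            "lam": self.lam.tolist(),
            "J_sparse": [
                [int(ii), int(jj), int(aa), int(bb), float(v)]
                for ii, jj, aa, bb, v in zip(i, j, a, b, self.J[i, j, a, b])
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != FORMAT_VERSION:
            raise ValidationError("unsupported parameter file version")
        L, q = payload["L"], payload["q"]
        J = np.zeros((L, L, q, q))
        for i, j, a, b, v in payload["J_sparse"]:
            J[i, j, a, b] = v
        return cls(
            h=np.asarray(payload["h"], dtype=np.float64),
            J=J,
            lam=np.asarray(payload["lam"], dtype=np.float64),
            alphabet=Alphabet(payload["alphabet"]),
        )


def _encode(seq: str | np.ndarray, params: ModelParameters) -> np.ndarray:
    s = params.alphabet.encode(seq) if isinstance(seq, str) else np.asarray(seq)
    if s.shape != (params.L,):
        raise ValidationError(f"sequence length {s.shape} does not match L={params.L}")
    return s.astype(np.intp)


def energy(
    seq: str | np.ndarray, params: ModelParameters, use_lambda: bool = True
) -> float:
    """Energy of one pair sequence; lower is more favorable."""
    s = _encode(seq, params)
    iu, ju = np.triu_indices(params.L, k=1)
    e = -params.h[np.arange(params.L), s].sum()
    e += params.J[iu, ju, s[iu], s[ju]].sum()
    if use_lambda:
        matches, _ = count_identity(s)
        e -= params.lam[matches]
    return float(e)


def energies(
    mat: np.ndarray, params: ModelParameters, use_lambda: bool = True
) -> np.ndarray:
    """Vectorized energy of an (n, L) integer matrix."""
    mat = np.asarray(mat, dtype=np.intp)
    n, L = mat.shape
    if L != params.L:
        raise ValidationError("matrix width does not match model L")
    iu, ju = np.triu_indices(L, k=1)
    e = -params.h[np.arange(L), mat].sum(axis=1)
    e += params.J[iu, ju, mat[:, iu], mat[:, ju]].sum(axis=1)
    if use_lambda:
        half = L // 2
        matches = np.count_nonzero(mat[:, :half] == mat[:, half:], axis=1)
        e -= params.lam[matches]
    return e


@dataclass(frozen=True)
class MutationSet:
    """Point substitutions applied to a reference sequence.

    Positions are 0-based on the full sequence; each new state must differ
    from the reference state at that position.
    """

    reference: str
    mutations: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for pos, new in self.mutations:
            if not 0 <= pos < len(self.reference):
                raise ValidationError(f"mutation position {pos} outside sequence")
            if pos in seen:
                raise ValidationError(f"duplicate mutation position {pos}")
            if self.reference[pos] == new:
                raise ValidationError(
                    f"mutation at {pos} does not change the residue"
                )
            seen.add(pos)

    def apply(self) -> str:
        chars = list(self.reference)
        for pos, new in self.mutations:
            chars[pos] = new
        return "".join(chars)


def delta_energy(
    muts: MutationSet, params: ModelParameters, use_lambda: bool = True
) -> float:
    """E(mutant) - E(wildtype), computed incrementally.

    Only field and coupling terms touching the mutated positions are
    re-evaluated; the identity term is recomputed from the updated match
    count.
    """
    s = _encode(muts.reference, params)
    t = s.copy()
    for pos, new in muts.mutations:
        t[pos] = params.alphabet.index(new)
    touched = sorted(pos for pos, _ in muts.mutations)
    if not touched:
        return 0.0

    d = 0.0
    for pos in touched:
        d -= params.h[pos, t[pos]] - params.h[pos, s[pos]]
    touched_set = set(touched)
    L = params.L
    for pos in touched:
        for j in range(L):
            if j == pos:
                continue
            if j in touched_set and j < pos:
                continue  # pair handled once, with both ends updated
            other_new = t[j] if j in touched_set else s[j]
            d += params.coupling(pos, j, t[pos], other_new) - params.coupling(
                pos, j, s[pos], s[j]
            )
    if use_lambda:
        k_old, _ = count_identity(s)
        k_new, _ = count_identity(t)
        d -= params.lam[k_new] - params.lam[k_old]
    return float(d)


@dataclass(frozen=True)
class EnergyDecomposition:
    """Per-repeat internal energies and per-interface interaction energies."""

    internal: tuple[float, ...]
    interface: tuple[float, ...]

    @property
    def total(self) -> float:
        return float(sum(self.internal) + sum(self.interface))


def _internal_energy(s: np.ndarray, params: ModelParameters) -> float:
    """Intra-repeat energy of one repeat using the first-repeat block."""
    half = params.half
    e = -params.h[np.arange(half), s].sum()
    iu, ju = np.triu_indices(half, k=1)
    e += params.J[iu, ju, s[iu], s[ju]].sum()
    return float(e)


def decompose_array(
    repeats: Sequence[str | np.ndarray], params: ModelParameters
) -> EnergyDecomposition:
    """Energy decomposition of a repeat array where only adjacent repeats
    interact.

    Each repeat contributes an internal energy evaluated with the
    first-repeat parameter block; each adjacent pair contributes an
    interface energy defined as the pair energy of the concatenation minus
    the two internal terms.  For a two-repeat array the total therefore
    equals ``energy`` of the concatenation exactly, and totals compose
    associatively for longer arrays.
    """
    if len(repeats) < 1:
        raise ValidationError("need at least one repeat")
    half = params.half
    enc = []
    for r in repeats:
        s = params.alphabet.encode(r) if isinstance(r, str) else np.asarray(r, dtype=np.intp)
        if s.shape != (half,):
            raise ValidationError(f"repeat length must be L/2 = {half}")
        enc.append(s.astype(np.intp))

    internal = [_internal_energy(s, params) for s in enc]
    interface = []
    for r in range(len(enc) - 1):
        pair = np.concatenate([enc[r], enc[r + 1]])
        e_pair = energy(pair, params)
        interface.append(e_pair - internal[r] - internal[r + 1])
    return EnergyDecomposition(internal=tuple(internal), interface=tuple(interface))
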