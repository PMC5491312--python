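import numpy as np
import pytest

from refield.alphabet import PROTEIN, Alphabet
from refield.model import ModelParameters
from refield.msa import Alignment, RepeatRecord


def random_parameters(L, q=21, seed=0, density=0.1, alphabet=PROTEIN):
    """Dense-ish random parameters for oracle comparisons."""
    rng = np.random.default_rng(seed)
    h = rng.normal(size=(L, q))
    J = np.zeros((L, L, q, q))
    iu, ju = np.triu_indices(L, k=1)
    mask = rng.random((len(iu), q, q)) < density
    vals = rng.normal(size=(len(iu), q, q))
    J[iu, ju] = np.where(mask, vals, 0.0)
    lam = rng.normal(size=L // 2 + 1)
    return ModelParameters(h=h, J=J, lam=lam, alphabet=alphabet)


def naive_energy(seq, params, use_lambda=True):
    """Literal three-loop evaluator, independent of the vectorized path."""
    s = [params.alphabet.index(c) for c in seq] if isinstance(seq, str) else list(seq)
    L = params.L
    e = 0.0
    for i in range(L):
        e -= params.h[i, s[i]]
    for i in range(L):
        for j in range(i + 1, L):
            e += params.J[i, j, s[i], s[j]]
    if use_lambda:
        half = L // 2
        k = sum(1 for i in range(half) if s[i] == s[i + half])
        e -= params.lam[k]
    return e


def make_alignment(seqs, ids=None, pair_flag=False, alphabet=PROTEIN, **meta):
    ids = ids or [f"s{k}" for k in range(len(seqs))]
    recs = tuple(
        RepeatRecord(sequence=s, protein_id=i, **meta) for s, i in zip(seqs, ids)
    )
    return Alignment(records=recs, pair_flag=pair_flag, alphabet=alphabet)


@pytest.fixture
def toy_alphabet():
    """Three-state alphabet (two residues + gap) for enumeration oracles."""
    return Alphabet("AC-")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
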