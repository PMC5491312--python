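"""Ground-truth models and alignments for download-free testing.

Generated models have sparse couplings (optionally planted on a given set of
position pairs), Gaussian fields, and an identity potential whose heavy-tail
profile enriches highly similar repeat pairs — the statistical structure the
inference machinery assumes, with no biochemical realism intended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import PROTEIN, Alphabet
from .errors import ValidationError
from .model import ModelParameters
from .msa import Alignment
from .sampler import SamplerConfig, metropolis_sample

LAMBDA_PROFILES = ("none", "linear", "heavy_tail")


@dataclass(frozen=True)
class GeneratorSpec:
    """Shape and sparsity of a synthetic ground-truth model."""

    L: int = 12
    q: int = 21
    n_sequences: int = 5000
    seed: int = 0
    field_scale: float = 1.0
    coupling_density: float = 0.15
    coupling_scale: float = 1.0
    combos_per_pair: int = 8  # nonzero (a, b) entries per coupled pair
    lambda_profile: str = "heavy_tail"
    lambda_scale: float = 12.0
    lambda_power: float = 3.0
    planted_contacts: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.L % 2:
            raise ValidationError("L must be even")
        if not 0 <= self.coupling_density <= 1:
            raise ValidationError("coupling_density must be in [0, 1]")
        if self.lambda_profile not in LAMBDA_PROFILES:
            raise ValidationError(f"unknown lambda_profile {self.lambda_profile!r}")
        if self.planted_contacts is not None:
            for i, j in self.planted_contacts:
                if not 0 <= i < j < self.L:
                    raise ValidationError("planted contacts must satisfy 0 <= i < j < L")


def desk_spec(seed: int = 0, **overrides) -> GeneratorSpec:
    """Desk-scale preset: two repeats of 6 over the full 21-state alphabet."""
    return GeneratorSpec(L=12, q=21, n_sequences=5000, seed=seed, **overrides)


def _lambda_values(spec: GeneratorSpec) -> np.ndarray:
    half = spec.L // 2
    k = np.arange(half + 1) / half
    if spec.lambda_profile == "none":
        return np.zeros(half + 1)
    if spec.lambda_profile == "linear":
        return spec.lambda_scale * k
    return spec.lambda_scale * k**spec.lambda_power


def make_model(spec: GeneratorSpec) -> ModelParameters:
    """Draw a ground-truth model; deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    L, q = spec.L, spec.q
    if q != PROTEIN.q:
        raise ValidationError("synthetic models use the 21-state protein alphabet")
    h = rng.normal(0.0, spec.field_scale, size=(L, q))
    J = np.zeros((L, L, q, q))

    if spec.planted_contacts is not None:
        pairs = list(spec.planted_contacts)
    else:
        iu, ju = np.triu_indices(L, k=1)
        n_pairs = len(iu)
        n_pick = int(round(spec.coupling_density * n_pairs))
        picked = rng.choice(n_pairs, size=n_pick, replace=False)
        pairs = [(int(iu[k]), int(ju[k])) for k in picked]
    for i, j in pairs:
        flat = rng.choice(q * q, size=min(spec.combos_per_pair, q * q), replace=False)
        vals = rng.normal(0.0, spec.coupling_scale, size=len(flat))
        J[i, j, flat // q, flat % q] = vals

    return ModelParameters(h=h, J=J, lam=_lambda_values(spec), alphabet=PROTEIN)


def make_alignment(
    params: ModelParameters,
    n: int,
    seed: int = 0,
    thin: int = 200,
    burn_in: int | None = None,
) -> Alignment:
    """Sample n pair sequences from a ground-truth model."""
    cfg = SamplerConfig(n_sequences=n, thin=thin, burn_in=burn_in, seed=seed)
    aln = metropolis_sample(params, cfg)
    return aln
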