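"""Downstream analyses: consensus, identity relations, stability-change
prediction and coupling-vs-contact comparison."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .model import ModelParameters, MutationSet, decompose_array, energies
from .msa import Alignment
from .stats import FrequencyStatistics

#: Accepted declarations of the experimental sign convention.
#: ``destab_positive``: a destabilizing mutation has ddG > 0.
#: ``destab_negative``: a destabilizing mutation has ddG < 0.
CONVENTIONS = ("destab_positive", "destab_negative")


def consensus_sequence(stats: FrequencyStatistics) -> str:
    """Most frequent amino acid per column; the gap state never wins.

    Ties break toward the earlier symbol in the alphabet.
    """
    gap = stats.alphabet.gap_index
    freqs = stats.f1.copy()
    freqs[:, gap] = -1.0
    best = np.argmax(freqs, axis=1)  # argmax takes the first maximum
    return stats.alphabet.decode(best)


def identity_to_consensus(seq: str, consensus: str) -> float:
    if len(seq) != len(consensus):
        raise ValidationError("sequence and consensus lengths differ")
    return sum(a == b for a, b in zip(seq, consensus)) / len(seq)


def energy_vs_identity(
    ensemble: Alignment,
    params: ModelParameters,
    consensus: str | None = None,
) -> pd.DataFrame:
    """Per-sequence energy, repeat identity and (optionally) consensus identity."""
    if not ensemble.pair_flag:
        raise ValidationError("energy_vs_identity expects a pair alignment")
    mat = ensemble.to_matrix()
    half = params.half
    e = energies(mat, params)
    matches = np.count_nonzero(mat[:, :half] == mat[:, half:], axis=1)
    data = {
        "id": [r.id for r in ensemble.records],
        "energy": e,
        "matches": matches,
        "pct_id_between_repeats": matches / half,
    }
    if consensus is not None:
        cons = params.alphabet.encode(consensus)
        data["pct_id_to_consensus"] = np.count_nonzero(mat == cons, axis=1) / params.L
    return pd.DataFrame(data)


@dataclass(frozen=True)
class MutationExperiment:
    """One experimental stability measurement on a repeat-array protein.

    ``wt_sequence`` is the full repeat array (length a multiple of L/2);
    ``mutations`` use the "A12G" notation with 1-based positions on that
    array.  ``convention`` declares the sign of a destabilizing ddG.
    """

    protein_id: str
    wt_sequence: str
    mutations: tuple[str, ...]
    ddg: float
    ddg_sd: float = 0.0
    convention: str = "destab_positive"
    exclude: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg):
            raise ValidationError("ddG must be finite")
        if self.convention not in CONVENTIONS:
            raise ValidationError(f"unknown ddG convention {self.convention!r}")
        for m in self.mutations:
            self._parse_one(m)

    def _parse_one(self, m: str) -> tuple[int, str]:
        if len(m) < 3:
            raise ValidationError(f"malformed mutation {m!r}")
        wt, new = m[0], m[-1]
        try:
            pos = int(m[1:-1]) - 1
        except ValueError:
            raise ValidationError(f"malformed mutation {m!r}") from None
        if not 0 <= pos < len(self.wt_sequence):
            raise ValidationError(f"mutation {m!r} outside sequence")
        if self.wt_sequence[pos] != wt:
            raise ValidationError(
                f"mutation {m!r}: wildtype has {self.wt_sequence[pos]!r} at {pos + 1}"
            )
        return pos, new

    def mutation_set(self) -> MutationSet:
        return MutationSet(
            reference=self.wt_sequence,
            mutations=tuple(self._parse_one(m) for m in self.mutations),
        )

    @property
    def destabilization(self) -> float:
        """ddG mapped so that positive always means destabilizing."""
        return self.ddg if self.convention == "destab_positive" else -self.ddg


def _split_repeats(seq: str, half: int) -> list[str]:
    if len(seq) % half:
        raise ValidationError(
            f"array length {len(seq)} is not a multiple of the repeat length {half}"
        )
    return [seq[k : k + half] for k in range(0, len(seq), half)]


def array_energy(seq: str, params: ModelParameters) -> float:
    """Total adjacent-interaction energy of a repeat array."""
    return decompose_array(_split_repeats(seq, params.half), params).total


def predict_ddG(
    experiments: Sequence[MutationExperiment], params: ModelParameters
) -> tuple[pd.DataFrame, dict]:
    """Predicted energy changes vs experimental ddG.

    Returns a per-experiment table and a summary with the least-squares line
    of delta_E on the sign-aligned ddG, its R^2, and the sign-agreement
    fraction (delta_E > 0 predicted for destabilizing mutations).  Rows with
    ``exclude`` set (e.g. structural disruptors) are kept in the table and
    the sign statistics but left out of the linear fit.
    """
    if not experiments:
        raise ValidationError("no experiments supplied")
    rows = []
    for exp in experiments:
        wt_e = array_energy(exp.wt_sequence, params)
        mut_e = array_energy(exp.mutation_set().apply(), params)
        de = mut_e - wt_e
        rows.append(
            {
                "protein_id": exp.protein_id,
                "mutations": ";".join(exp.mutations),
                "delta_E": de,
                "ddG": exp.ddg,
                "ddG_destab": exp.destabilization,
                "ddG_sd": exp.ddg_sd,
                "excluded_from_fit": exp.exclude,
            }
        )
    table = pd.DataFrame(rows)

    both_nonzero = (table["delta_E"] != 0) & (table["ddG_destab"] != 0)
    agree = np.sign(table["delta_E"]) == np.sign(table["ddG_destab"])
    sign_agreement = float(agree[both_nonzero].mean()) if both_nonzero.any() else np.nan

    fit_rows = table[~table["excluded_from_fit"]]
    if len(fit_rows) >= 2 and fit_rows["ddG_destab"].nunique() > 1:
        res = sps.linregress(fit_rows["ddG_destab"], fit_rows["delta_E"])
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    else:
        slope = intercept = r2 = np.nan
    summary = {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": float(r2),
        "sign_agreement": sign_agreement,
        "n_fit": int(len(fit_rows)),
        "n_total": int(len(table)),
    }
    return table, summary


def read_mutation_table(path: str | Path) -> list[MutationExperiment]:
    """TSV columns: id, wt_sequence, mutations ("A12G;S30P"), ddG, ddG_sd,
    convention, exclude (0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(
            MutationExperiment(
                protein_id=str(row["id"]),
                wt_sequence=str(row["wt_sequence"]),
                mutations=tuple(str(row["mutations"]).split(";")),
                ddg=float(row["ddG"]),
                ddg_sd=float(row.get("ddG_sd", 0.0)),
                convention=str(row.get("convention", "destab_positive")),
                exclude=bool(int(row.get("exclude", 0))),
            )
        )
    return out


@dataclass(frozen=True)
class ContactMap:
    """Symmetric binary contact matrix over the L positions of a repeat pair."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("contact map must be square")
        if not np.array_equal(m, m.T):
            raise ValidationError("contact map must be symmetric")
        if np.any(np.diag(m)):
            raise ValidationError("contact map diagonal must be zero")
        if not np.isin(m, (0, 1)).all():
            raise ValidationError("contact map entries must be 0/1")
        object.__setattr__(self, "matrix", m.astype(np.int8))

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def read(cls, path: str | Path) -> "ContactMap":
        return cls(np.loadtxt(path, dtype=int))


def extreme_couplings(
    params: ModelParameters, top_k: int = 200, bottom_k: int = 200
) -> list[tuple[int, int, int, str]]:
    """Position pairs carrying the largest and smallest nonzero couplings.

    Returns (i, j, n_state_combinations, tag) with tag "top" (highest J) or
    "bottom" (lowest J); counts say how many selected (a, b) combinations
    fall on that position pair.  When fewer nonzero couplings exist than
    requested, all of them are returned.
    """
    i, j, a, b = np.nonzero(params.J)
    values = params.J[i, j, a, b]
    order = np.argsort(values, kind="stable")
    out: list[tuple[int, int, int, str]] = []
    for tag, idx in (
        ("top", order[::-1][: min(top_k, len(order))]),
        ("bottom", order[: min(bottom_k, len(order))]),
    ):
        pairs: dict[tuple[int, int], int] = {}
        for k in idx:
            key = (int(i[k]), int(j[k]))
            pairs[key] = pairs.get(key, 0) + 1
        out.extend(
            (pi, pj, count, tag)
            for (pi, pj), count in sorted(
                pairs.items(), key=lambda kv: (-kv[1], kv[0])
            )
        )
    return out


def coupling_contact_overlap(
    extremes: Sequence[tuple[int, int, int, str]],
    cmap: ContactMap,
    repeat_offset: int,
) -> float:
    """Fraction of extreme-coupling position pairs that are native contacts
    or equivalent positions in the adjacent repeat (j = i + offset)."""
    pairs = {(i, j) for i, j, _, _ in extremes}
    if not pairs:
        raise ValidationError("no extreme couplings supplied")
    for i, j in pairs:
        if not (0 <= i < cmap.width and 0 <= j < cmap.width):
            raise ValidationError("coupling position outside contact map")
    hits = sum(
        1
        for i, j in pairs
        if cmap.matrix[i, j] == 1 or abs(j - i) == repeat_offset
    )
    return hits / len(pairs)
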