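"""Alignment I/O and preprocessing for repeat-pair alignments.

Single-repeat alignments are read from FASTA or Stockholm files whose record
ids follow the PFAM ``proteinID/start-end`` convention.  Consecutive repeats
of the same parent protein are concatenated into pair rows, insertion-heavy
columns are dropped, and redundancy is reduced by greedy identity clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import GAP, PROTEIN, Alphabet
from .errors import ValidationError

logger = logging.getLogger(__name__)

_FORMATS = {"fasta": "fasta", "stockholm": "stockholm"}


@dataclass(frozen=True)
class RepeatRecord:
    """One aligned repeat (or repeat pair) with its provenance metadata."""

    sequence: str
    protein_id: str
    repeat_index: int = 0
    start: int | None = None
    end: int | None = None

    @property
    def id(self) -> str:
        if self.start is not None and self.end is not None:
            return f"{self.protein_id}/{self.start}-{self.end}"
        return self.protein_id


@dataclass(frozen=True)
class Alignment:
    """Fixed-width alignment over the 21-letter alphabet.

    When ``pair_flag`` is set every row is the concatenation of two repeats
    of length ``width // 2``.
    """

    records: tuple[RepeatRecord, ...]
    pair_flag: bool = False
    alphabet: Alphabet = PROTEIN

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("alignment has no records")
        w = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != w:
                raise ValidationError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.sequence)}, expected {w}"
                )
        if self.pair_flag and w % 2:
            raise ValidationError("pair alignment width must be even")

    @property
    def width(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def to_matrix(self) -> np.ndarray:
        """Integer-encode all rows as an (n, L) int8 matrix."""
        out = np.empty((len(self.records), self.width), dtype=np.int8)
        for k, rec in enumerate(self.records):
            out[k] = self.alphabet.encode(rec.sequence)
        return out

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        ids: Sequence[str] | None = None,
        pair_flag: bool = False,
        alphabet: Alphabet = PROTEIN,
    ) -> "Alignment":
        n = matrix.shape[0]
        ids = ids if ids is not None else [f"seq{k}" for k in range(n)]
        recs = tuple(
            RepeatRecord(sequence=alphabet.decode(row), protein_id=str(ids[k]))
            for k, row in enumerate(matrix)
        )
        return cls(records=recs, pair_flag=pair_flag, alphabet=alphabet)


def _parse_header(header: str) -> tuple[str, int | None, int | None]:
    """Split a PFAM-style ``proteinID/start-end`` id; coordinates optional."""
    if "/" in header:
        pid, _, coords = header.rpartition("/")
        if "-" in coords:
            s, _, e = coords.partition("-")
            try:
                return pid, int(s), int(e)
            except ValueError:
                pass
    return header, None, None


def _sanitize(seq: str, alphabet: Alphabet) -> tuple[str, int]:
    """Uppercase, map '.' and non-alphabet symbols to gap; count replacements."""
    seq = seq.upper().replace(".", GAP)
    bad = sum(1 for c in seq if c not in alphabet)
    if bad:
        seq = "".join(c if c in alphabet else GAP for c in seq)
    return seq, bad


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    alphabet: Alphabet = PROTEIN,
    pair_flag: bool = False,
) -> Alignment:
    """Read an alignment; non-alphabet characters become gaps (logged).

    Repeat indices are assigned per protein by rank of the start coordinate
    (file order when coordinates are absent).
    """
    if format not in _FORMATS:
        raise ValidationError(f"unknown alignment format {format!r}")
    path = Path(path)
    raw = list(SeqIO.parse(str(path), _FORMATS[format]))
    if not raw:
        raise ValidationError(f"no sequences found in {path}")

    n_replaced = 0
    parsed = []
    for rec in raw:
        seq, bad = _sanitize(str(rec.seq), alphabet)
        n_replaced += bad
        pid, start, end = _parse_header(rec.id)
        parsed.append(RepeatRecord(sequence=seq, protein_id=pid, start=start, end=end))
    if n_replaced:
        logger.warning(
            "%s: %d non-alphabet characters mapped to gap", path, n_replaced
        )

    # rank repeats within each protein to get ordinal repeat indices
    by_protein: dict[str, list[int]] = {}
    for k, rec in enumerate(parsed):
        by_protein.setdefault(rec.protein_id, []).append(k)
    for pid, idxs in by_protein.items():
        order = sorted(
            idxs, key=lambda k: parsed[k].start if parsed[k].start is not None else k
        )
        for rank, k in enumerate(order):
            parsed[k] = replace(parsed[k], repeat_index=rank)

    return Alignment(records=tuple(parsed), pair_flag=pair_flag, alphabet=alphabet)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write FASTA with ``proteinID/start-end`` headers."""
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def build_pairs(aln: Alignment) -> Alignment:
    """Concatenate consecutive repeats of each protein into pair rows.

    One output row per (protein, k) with both repeats k and k+1 present;
    output is sorted by protein id then repeat index.
    """
    if aln.pair_flag:
        raise ValidationError("alignment is already a pair alignment")
    by_protein: dict[str, dict[int, RepeatRecord]] = {}
    for rec in aln.records:
        if rec.protein_id is None or rec.repeat_index is None:
            raise ValidationError("records must carry protein_id and repeat_index")
        slot = by_protein.setdefault(rec.protein_id, {})
        if rec.repeat_index in slot:
            raise ValidationError(
                f"duplicate repeat_index {rec.repeat_index} for {rec.protein_id}"
            )
        slot[rec.repeat_index] = rec

    pairs = []
    for pid in sorted(by_protein):
        repeats = by_protein[pid]
        for k in sorted(repeats):
            if k + 1 in repeats:
                first, second = repeats[k], repeats[k + 1]
                pairs.append(
                    RepeatRecord(
                        sequence=first.sequence + second.sequence,
                        protein_id=pid,
                        repeat_index=k,
                        start=first.start,
                        end=second.end,
                    )
                )
    if not pairs:
        raise ValidationError("no consecutive repeat pairs found")
    return Alignment(records=tuple(pairs), pair_flag=True, alphabet=aln.alphabet)


def remove_gappy_columns(
    aln: Alignment, max_gap_fraction: float = 0.8
) -> tuple[Alignment, np.ndarray]:
    """Drop columns whose gap fraction strictly exceeds the threshold.

    On pair alignments a column i < L/2 and its partner i + L/2 are removed
    jointly, and only when both exceed the threshold, so the positional
    correspondence between the two halves is preserved.
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValidationError("max_gap_fraction must be in (0, 1]")
    mat = aln.to_matrix()
    gap_frac = (mat == aln.alphabet.gap_index).mean(axis=0)
    if aln.pair_flag:
        half = aln.width // 2
        drop_half = (gap_frac[:half] > max_gap_fraction) & (
            gap_frac[half:] > max_gap_fraction
        )
        drop = np.concatenate([drop_half, drop_half])
    else:
        drop = gap_frac > max_gap_fraction
    kept = np.flatnonzero(~drop)
    if kept.size == 0:
        raise ValidationError("all columns exceed the gap threshold")
    if kept.size == aln.width:
        return aln, kept
    records = tuple(
        replace(rec, sequence="".join(rec.sequence[i] for i in kept))
        for rec in aln.records
    )
    return Alignment(records=records, pair_flag=aln.pair_flag, alphabet=aln.alphabet), kept


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def cluster_representatives(
    aln: Alignment, identity_threshold: float = 0.9, seed: int = 0
) -> Alignment:
    """Greedy incremental clustering in the CD-HIT style; one representative
    per cluster.

    Rows are visited by decreasing residue count (lexicographic, then input
    order, as tie-breaks); a row joins the first cluster whose representative
    matches it at >= threshold identity over the aligned columns, otherwise
    it seeds a new cluster.  The procedure is deterministic; ``seed`` is
    accepted for interface symmetry only.
    """
    if not 0 < identity_threshold <= 1:
        raise ValidationError("identity_threshold must be in (0, 1]")
    order = sorted(
        range(len(aln.records)),
        key=lambda k: (
            -sum(c != GAP for c in aln.records[k].sequence),
            aln.records[k].sequence,
            k,
        ),
    )
    reps: list[int] = []
    for k in order:
        seq = aln.records[k].sequence
        for r in reps:
            if _identity(seq, aln.records[r].sequence) >= identity_threshold:
                break
        else:
            reps.append(k)
    reps.sort()
    return Alignment(
        records=tuple(aln.records[k] for k in reps),
        pair_flag=aln.pair_flag,
        alphabet=aln.alphabet,
    )
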