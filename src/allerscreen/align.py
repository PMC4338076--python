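"""Optimal local alignment with affine gaps and shuffle-based E-values.

The screen aligns query proteins against allergen databases with exact
Smith–Waterman/Gotoh dynamic programming under BLOSUM50 and the
-12/-2 affine gap cost (a gap of length g costs 12 + 2*(g-1)).  The
original regulatory searches ran the FASTA heuristic with the same
scoring; exact DP is its deterministic, reproducible replacement, and
an optional ktup=2 word-match prefilter mirrors FASTA's seeding step
as a database skip.

E-values are calibrated per query by aligning against residue-shuffled
database sequences and fitting a Gumbel (type-I extreme value) law by
maximum likelihood; ``evalue`` then reports the expected number of
chance database hits at or above a score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import gumbel_r

from . import _kernels
from .seqio import AllergenRecord, SequenceRecord, SubstitutionMatrix, load_blosum50


class AlphabetError(ValueError):
    """A residue is not covered by the substitution matrix."""


class CalibrationError(RuntimeError):
    """The shuffle score distribution cannot support a Gumbel fit."""


class UndefinedStatisticsError(ValueError):
    """Percent identity/similarity are undefined for an empty alignment."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters: substitution matrix, affine gap costs, ktup."""

    matrix: SubstitutionMatrix = field(default_factory=load_blosum50)
    gap_open: int = 12
    gap_extend: int = 2
    ktup: int | None = None

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.ktup is not None and self.ktup < 1:
            raise ValueError("ktup must be a positive word size")


@dataclass(frozen=True)
class LocalAlignment:
    """An optimal local alignment and its column statistics.

    Intervals are 1-based inclusive residue ranges in the ungapped
    parents; ``n_columns`` counts aligned columns including gap
    columns (the overlap length used as the identity denominator).
    """

    score: int
    query_interval: tuple[int, int] | None
    subject_interval: tuple[int, int] | None
    n_columns: int
    n_identities: int
    n_positives: int
    aligned_query: str
    aligned_subject: str

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0

    @property
    def percent_identity(self) -> float:
        if self.is_empty:
            return 0.0
        return 100.0 * self.n_identities / self.n_columns

    @property
    def percent_similarity(self) -> float:
        if self.is_empty:
            return 0.0
        return 100.0 * self.n_positives / self.n_columns


@dataclass(frozen=True)
class EVDCalibration:
    """A fitted Gumbel null for one query against one database."""

    location: float
    scale: float
    n_samples: int
    seed: int
    db_size: int

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise CalibrationError("Gumbel scale must be positive")

    @property
    def lam(self) -> float:
        """Decay rate lambda = 1/scale of the score tail."""
        return 1.0 / self.scale


@dataclass(frozen=True)
class AlignmentHit:
    """One database hit: subject, alignment and its E score."""

    subject: AllergenRecord
    alignment: LocalAlignment
    e_score: float
    passes_profile: bool = False


_EMPTY = LocalAlignment(
    score=0,
    query_interval=None,
    subject_interval=None,
    n_columns=0,
    n_identities=0,
    n_positives=0,
    aligned_query="",
    aligned_subject="",
)


def _encode(residues: str, matrix: SubstitutionMatrix) -> np.ndarray:
    index = {c: i for i, c in enumerate(matrix.alphabet)}
    try:
        return np.array([index[c] for c in residues], dtype=np.int64)
    except KeyError:
        bad = sorted(set(residues) - set(matrix.alphabet))
        raise AlphabetError(
            f"residue(s) outside matrix alphabet: {', '.join(bad)}"
        ) from None


def smith_waterman(
    query: SequenceRecord, subject: SequenceRecord, params: AlignmentParams
) -> LocalAlignment:
    """Exact optimal local alignment of two validated sequences.

    Traceback is deterministic: among equal maximal cells the one with
    the smallest (query index, subject index) wins, and at each step
    the move preference is diagonal > gap-in-subject > gap-in-query.
    """
    if not query.residues or not subject.residues:
        raise ValueError("sequences must be nonempty")
    sub = params.matrix.as_array()
    q = _encode(query.residues, params.matrix)
    s = _encode(subject.residues, params.matrix)
    H, E, F = _kernels.gotoh_matrices(q, s, sub, params.gap_open, params.gap_extend)
    best = int(H.max())
    if best == 0:
        return _EMPTY
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)  # first in row-major order
    return _traceback(query.residues, subject.residues, sub, q, s, H, E, F,
                      int(i), int(j), params)


def _traceback(qres, sres, sub, q, s, H, E, F, i, j, params) -> LocalAlignment:
    go, ge = params.gap_open, params.gap_extend
    end_q, end_s = i, j
    aq: list[str] = []
    asub: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]:
                aq.append(qres[i - 1])
                asub.append(sres[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == "F":  # gap in subject row, consumes query
            aq.append(qres[i - 1])
            asub.append("-")
            closes = F[i, j] == H[i - 1, j] - go
            i -= 1
            if closes:
                state = "H"
        else:  # gap in query row, consumes subject
            aq.append("-")
            asub.append(sres[j - 1])
            closes = E[i, j] == H[i, j - 1] - go
            j -= 1
            if closes:
                state = "H"
    aligned_q = "".join(reversed(aq))
    aligned_s = "".join(reversed(asub))
    n_id = sum(a == b for a, b in zip(aligned_q, aligned_s) if a != "-" and b != "-")
    n_pos = sum(
        1
        for a, b in zip(aligned_q, aligned_s)
        if a != "-" and b != "-" and sub[q_idx(a, params), q_idx(b, params)] > 0
    )
    return LocalAlignment(
        score=int(H[end_q, end_s]),
        query_interval=(i + 1, end_q),
        subject_interval=(j + 1, end_s),
        n_columns=len(aligned_q),
        n_identities=n_id,
        n_positives=n_pos,
        aligned_query=aligned_q,
        aligned_subject=aligned_s,
    )


def q_idx(c: str, params: AlignmentParams) -> int:
    return params.matrix.alphabet.index(c)


def sw_score(
    query: SequenceRecord, subject: SequenceRecord, params: AlignmentParams
) -> int:
    """Score-only Smith–Waterman (linear memory), for bulk scans."""
    sub = params.matrix.as_array()
    q = _encode(query.residues, params.matrix)
    s = _encode(subject.residues, params.matrix)
    return int(_kernels.sw_score(q, s, sub, params.gap_open, params.gap_extend))


def align_stats(alignment: LocalAlignment) -> tuple[float, float]:
    """(percent identity, percent similarity) on the 0-100 scale."""
    if alignment.is_empty:
        raise UndefinedStatisticsError("statistics undefined for empty alignment")
    return alignment.percent_identity, alignment.percent_similarity


def shares_word(query: str, subject: str, ktup: int) -> bool:
    """FASTA-style seed test: do the sequences share an exact ktup word?"""
    words = {query[i : i + ktup] for i in range(len(query) - ktup + 1)}
    return any(subject[i : i + ktup] in words for i in range(len(subject) - ktup + 1))


def fit_gumbel(scores: Sequence[float]) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (location, scale) fit to score samples."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.ptp(scores) == 0:
        raise CalibrationError("degenerate score distribution (no spread)")
    loc, scale = gumbel_r.fit(scores)
    return float(loc), float(scale)


def _shuffle_residues(residues: str, rng: np.random.Generator) -> str:
    arr = np.array(list(residues))
    rng.shuffle(arr)
    return "".join(arr)


def calibrate_evd(
    query: SequenceRecord,
    db: Sequence[AllergenRecord],
    params: AlignmentParams,
    n_shuffles: int = 100,
    seed: int = 0,
) -> EVDCalibration:
    """Fit the chance-score Gumbel null from residue-shuffled subjects.

    Database sequences are cycled (shuffled independently each time)
    until ``n_shuffles`` scores are collected; identical inputs and
    seed give a bit-identical calibration.
    """
    if not db:
        raise ValueError("database must be nonempty")
    if n_shuffles < 30:
        raise ValueError("n_shuffles must be at least 30 for a usable fit")
    rng = np.random.default_rng(seed)
    sub = params.matrix.as_array()
    q = _encode(query.residues, params.matrix)
    scores = np.empty(n_shuffles, dtype=float)
    for k in range(n_shuffles):
        subject = db[k % len(db)]
        shuffled = _shuffle_residues(subject.residues, rng)
        s = _encode(shuffled, params.matrix)
        scores[k] = _kernels.sw_score(q, s, sub, params.gap_open, params.gap_extend)
    loc, scale = fit_gumbel(scores)
    return EVDCalibration(
        location=loc, scale=scale, n_samples=n_shuffles, seed=seed, db_size=len(db)
    )


def evalue(score: float, cal: EVDCalibration) -> float:
    """Expected number of chance database hits scoring >= ``score``."""
    return float(cal.db_size * gumbel_r.sf(score, loc=cal.location, scale=cal.scale))
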