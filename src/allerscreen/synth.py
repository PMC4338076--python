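"""Seeded generators for every input the pipeline consumes.

The generators let the whole assessment run and be tested without any
licensed database snapshot or clinical data:

* decoy allergen databases whose residue composition is score-separated
  from a designated query alphabet, so chance window identities are
  structurally zero rather than merely improbable;
* planted homologous 80-mers at an exact, constructively guaranteed
  identity level, for exercising the >35% window rule at its boundary;
* specific-IgE OD tables built by inverting the percent-binding
  formula, so classification recovers planted category counts exactly;
* band-by-time matrices with stable / partial / digested trajectories.

Everything is a pure function of its arguments plus a seed.

Construction note: queries are drawn from the alphabet {C, G, P, W}
and decoys from the 14 residues {A,R,N,D,Q,E,H,I,L,K,M,S,T,V}; under
BLOSUM50 no cross pair of the two sets scores positively, so no local
alignment between a decoy segment and a query can start.  Planted
mismatches substitute each residue with a partner scoring exactly -1
against it (C->A, G->D, P->S, W->M), and mismatch positions are spread
evenly between match positions that include both window ends; since
every mismatch run costs less than the smallest self-score (G-G = 8),
the optimal local alignment spans the full planted window and realises
exactly (window - n_mismatch) identities over window columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentParams, smith_waterman
from .seqio import AllergenRecord, DbSource, SequenceRecord
from .serology import DEFAULT_TIME_POINTS, BandMatrix, Category, Group, ODTable

QUERY_ALPHABET = "CGPW"
DECOY_ALPHABET = "ARNDQEHILKMSTV"

#: substitution scoring exactly -1 against the original under BLOSUM50
MILD_SUBSTITUTION = {"C": "A", "G": "D", "P": "S", "W": "M"}


class PlantingError(RuntimeError):
    """The planted window's verification alignment missed its guarantee."""


def make_query(length: int, seed: int, id: str = "query") -> SequenceRecord:
    """A random query over the score-separated query alphabet."""
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list(QUERY_ALPHABET), size=length))
    return SequenceRecord(id=id, residues=residues)


def make_decoy_db(
    n: int,
    length_range: tuple[int, int] = (150, 400),
    seed: int = 0,
    alphabet: str = DECOY_ALPHABET,
) -> list[AllergenRecord]:
    """i.i.d. decoy allergen records over the (separated) decoy alphabet.

    Pass ``alphabet`` with all 20 residues to get unseparated
    random-composition decoys instead.
    """
    if n < 1:
        raise ValueError("need at least one decoy record")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(list(alphabet), size=length))
        records.append(
            AllergenRecord(
                id=f"decoy{i + 1}",
                residues=residues,
                description="synthetic decoy",
                allergen_name=f"Dec o {i + 1}",
                source_organism="synthetic",
                db_source=DbSource.CUSTOM,
            )
        )
    return records


@dataclass(frozen=True)
class PlantSpec:
    """Where and how to plant a mutated query window into a decoy db."""

    query: SequenceRecord
    target_index: int
    n_mismatch: int
    window: int = 80
    query_start: int = 0  # 0-based window origin within the query
    target_offset: int = 0  # 0-based placement within the target record
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_mismatch <= self.window:
            raise ValueError("n_mismatch must lie in [0, window]")
        if self.query_start + self.window > self.query.length:
            raise ValueError("window does not fit in the query at query_start")

    @property
    def planted_identity(self) -> float:
        """Guaranteed percent identity of the planted alignment."""
        return 100.0 * (self.window - self.n_mismatch) / self.window


def _match_positions(window: int, n_match: int) -> list[int]:
    """Evenly spread match positions including both window ends."""
    if n_match <= 0:
        return []
    if n_match == 1:
        return [0]
    step = (window - 1) / (n_match - 1)
    return [int(j * step + 0.5) for j in range(n_match)]


def mutate_window(window_residues: str, n_mismatch: int) -> str:
    """Substitute ``n_mismatch`` evenly spread positions with -1 partners."""
    w = len(window_residues)
    matches = set(_match_positions(w, w - n_mismatch))
    out = []
    for i, c in enumerate(window_residues):
        out.append(c if i in matches else MILD_SUBSTITUTION[c])
    return "".join(out)


def plant_homolog(
    db: Sequence[AllergenRecord],
    spec: PlantSpec,
    params: AlignmentParams | None = None,
    verify: bool = True,
) -> list[AllergenRecord]:
    """Copy a mutated query window into one decoy record.

    With ``verify`` (default) the construction is checked by aligning
    the source window against the modified record and asserting that
    the optimal alignment attains exactly ``window - n_mismatch``
    identities over ``window`` columns (skipped when fewer than two
    matches remain, where no meaningful alignment exists).
    """
    if not 0 <= spec.target_index < len(db):
        raise ValueError("target_index out of range")
    target = db[spec.target_index]
    if spec.target_offset + spec.window > target.length:
        raise ValueError("planted window does not fit in the target record")
    source = spec.query.residues[spec.query_start : spec.query_start + spec.window]
    mutated = mutate_window(source, spec.n_mismatch)
    residues = (
        target.residues[: spec.target_offset]
        + mutated
        + target.residues[spec.target_offset + spec.window :]
    )
    planted = AllergenRecord(
        id=target.id,
        residues=residues,
        description=target.description + " (planted)",
        allergen_name=target.allergen_name,
        source_organism=target.source_organism,
        db_source=target.db_source,
    )
    out = list(db)
    out[spec.target_index] = planted
    n_match = spec.window - spec.n_mismatch
    if verify and n_match >= 2:
        window_rec = SequenceRecord(id="plant-check", residues=source)
        aln = smith_waterman(window_rec, planted, params or AlignmentParams())
        if aln.n_identities != n_match or aln.n_columns != spec.window:
            raise PlantingError(
                f"planted alignment realised {aln.n_identities} identities over "
                f"{aln.n_columns} columns; expected {n_match} over {spec.window}"
            )
    return out


@dataclass(frozen=True)
class SerologySpec:
    """Target category counts per antigen for a synthetic OD table."""

    n_patients: int
    n_controls: int
    category_counts: Mapping[str, tuple[int, int, int, int]]  # low/mod/sig/very_high
    control_baseline: float = 0.03
    max_positive_od: float = 0.85
    noise_scale: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least two patients and two controls")
        for antigen, counts in self.category_counts.items():
            if len(counts) != 4 or any(c < 0 for c in counts):
                raise ValueError(f"{antigen}: counts must be four non-negatives")
            if sum(counts) != self.n_patients:
                raise ValueError(
                    f"{antigen}: counts sum to {sum(counts)}, expected "
                    f"{self.n_patients} patients"
                )


#: open percent intervals well inside each category band, avoiding boundaries
_CATEGORY_BANDS = {
    Category.LOW: (2.0, 12.0),
    Category.MODERATE: (17.0, 28.0),
    Category.SIGNIFICANT: (33.0, 57.0),
    Category.VERY_HIGH: (63.0, 95.0),
}
#: assignment order: positive categories go to the lowest-indexed patients so
#: the jointly selected set across antigens is exactly the min positive count
_ASSIGN_ORDER = [
    Category.SIGNIFICANT,
    Category.VERY_HIGH,
    Category.MODERATE,
    Category.LOW,
]


def make_od_table(spec: SerologySpec) -> ODTable:
    """Invert the percent-binding formula to hit planted counts exactly.

    Control ODs sit near a low baseline; one positive-control row
    anchors the denominator; each patient's OD is back-computed from a
    target percent drawn inside the requested category band.
    """
    rng = np.random.default_rng(spec.seed)
    patients = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    controls = [f"C{i + 1:02d}" for i in range(spec.n_controls)]
    groups: dict[str, Group] = {s: Group.PATIENT for s in patients}
    groups.update({s: Group.CONTROL for s in controls})
    groups["POS"] = Group.POSITIVE_CONTROL
    od: dict[str, dict[str, float]] = {s: {} for s in groups}
    for antigen, counts in spec.category_counts.items():
        control_ods = np.clip(
            spec.control_baseline
            + rng.normal(0.0, spec.noise_scale, size=spec.n_controls),
            0.0,
            None,
        )
        c = float(control_ods.mean())
        m = spec.max_positive_od
        if m <= c:
            raise ValueError("max_positive_od must exceed the control baseline")
        for s, v in zip(controls, control_ods):
            od[s][antigen] = float(v)
        od["POS"][antigen] = m
        by_cat = dict(zip(_CATEGORY_BANDS, counts))
        idx = 0
        for cat in _ASSIGN_ORDER:
            lo, hi = _CATEGORY_BANDS[cat]
            for _ in range(by_cat[cat]):
                pct = float(rng.uniform(lo, hi))
                od[patients[idx]][antigen] = c + pct / 100.0 * (m - c)
                idx += 1
    frame = pd.DataFrame.from_dict(od, orient="index")[
        list(spec.category_counts)
    ].loc[patients + controls + ["POS"]]
    return ODTable(od=frame, groups=groups)


def make_band_matrix(
    extract: str,
    n_fractions: int,
    stable_indices: Sequence[int],
    seed: int = 0,
    time_points: Sequence[int] = DEFAULT_TIME_POINTS,
) -> BandMatrix:
    """A digestion matrix with chosen stable fractions and seeded dropouts.

    Unstable fractions stay present up to a random dropout time, show
    faint at that time point, and are absent afterwards (a dropout at
    the final time point therefore yields a partial call).
    """
    if not set(stable_indices) <= set(range(n_fractions)):
        raise ValueError("stable_indices out of range")
    rng = np.random.default_rng(seed)
    masses = np.sort(rng.choice(np.arange(8, 180), size=n_fractions, replace=False))[
        ::-1
    ].astype(float)
    T = len(time_points)
    rows = []
    for i in range(n_fractions):
        if i in stable_indices:
            rows.append("p" * T)
        else:
            drop = int(rng.integers(1, T))
            rows.append("p" * drop + "f" + "a" * (T - drop - 1))
    return BandMatrix.from_codes(
        extract, tuple(masses), rows, time_points=tuple(time_points)
    )
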