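"""Serology and gel-assay scoring rules for GM vs non-GM comparisons.

Covers the wet-data side of the assessment:

* specific-IgE ELISA percent binding,
  ``100 * (OD_patient - OD_control) / (OD_max_positive - OD_control)``,
  classified into the four Kauffman-style groups <15 / 15-30 / 30-60 /
  >60 %, with >30% binding counted as positive;
* the qualitative GM ELISA call (positive when the sample mean OD
  exceeds blank mean + 0.1);
* Welch two-sample comparison of patient vs control OD groups,
  reported as mean +/- SEM with a two-tailed p-value;
* simulated-gastric-fluid (SGF, pepsin pH 1.2) band-stability calling
  over the 0/1/5/15/30/45/60-minute sampling grid;
* immunoblot band concordance across sera and extracts, with
  tolerance-based matching of apparent molecular masses in kD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class AnchorError(ValueError):
    """The control / max-positive OD anchors cannot be resolved."""


class BandMatrixError(ValueError):
    """A band-by-time matrix violates its structural invariants."""


class Group(str, enum.Enum):
    PATIENT = "patient"
    CONTROL = "control"
    BLANK = "blank"
    POSITIVE_CONTROL = "positive_control"


class Category(str, enum.Enum):
    LOW = "low"  # < 15 %
    MODERATE = "moderate"  # [15, 30) %
    SIGNIFICANT = "significant"  # [30, 60] %
    VERY_HIGH = "very_high"  # > 60 %


CATEGORY_ORDER = [Category.LOW, Category.MODERATE, Category.SIGNIFICANT, Category.VERY_HIGH]

#: percent binding above which a serum counts as sIgE-positive
POSITIVITY_THRESHOLD = 30.0


def percent_binding(od_patient: float, od_control: float, od_max_positive: float) -> float:
    """Normalised specific-IgE signal on the 0-100 scale (not clipped)."""
    denom = od_max_positive - od_control
    if denom <= 0:
        raise AnchorError(
            "max-positive OD must exceed control OD (degenerate anchor)"
        )
    return 100.0 * (od_patient - od_control) / denom


def categorize(percent: float) -> Category:
    """Four-group classification; boundaries [15,30), [30,60], (60,inf)."""
    if percent < 15.0:
        return Category.LOW
    if percent < 30.0:
        return Category.MODERATE
    if percent <= 60.0:
        return Category.SIGNIFICANT
    return Category.VERY_HIGH


def is_positive(percent: float) -> bool:
    return percent > POSITIVITY_THRESHOLD


@dataclass(frozen=True)
class PercentBindingResult:
    subject: str
    antigen: str
    percent: float
    category: Category

    @property
    def positive(self) -> bool:
        return is_positive(self.percent)


@dataclass
class ODTable:
    """Optical densities of subjects x antigens with group labels.

    ``od`` is a DataFrame indexed by subject with antigen columns;
    ``groups`` maps subject -> :class:`Group`.
    """

    od: pd.DataFrame
    groups: Mapping[str, Group]

    def __post_init__(self) -> None:
        missing = set(self.od.index) - set(self.groups)
        if missing:
            raise ValueError(f"subjects without group label: {sorted(missing)}")
        if (self.od.to_numpy(dtype=float) < 0).any():
            raise ValueError("optical densities must be non-negative")

    def subjects(self, group: Group) -> list[str]:
        return [s for s in self.od.index if self.groups[s] is group]

    @property
    def antigens(self) -> list[str]:
        return list(self.od.columns)

    def to_tidy(self) -> pd.DataFrame:
        tidy = self.od.reset_index(names="subject").melt(
            id_vars="subject", var_name="antigen", value_name="od"
        )
        tidy["group"] = tidy["subject"].map(lambda s: self.groups[s].value)
        return tidy[["subject", "group", "antigen", "od"]]

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame) -> "ODTable":
        groups = {
            row.subject: Group(row.group)
            for row in tidy.drop_duplicates("subject").itertuples()
        }
        od = tidy.pivot(index="subject", columns="antigen", values="od")
        od = od.loc[tidy["subject"].drop_duplicates().tolist()]
        od.columns.name = None
        return cls(od=od, groups=groups)


@dataclass(frozen=True)
class ClassifiedTable:
    """Per-antigen category counts and the jointly selected sera."""

    results: tuple[PercentBindingResult, ...]
    counts: pd.DataFrame  # index antigen, columns category values
    selected_sera: tuple[str, ...]
    anchors: pd.DataFrame  # index antigen, columns control / max_positive


def _anchors(table: ODTable, antigen: str) -> tuple[float, float]:
    controls = table.subjects(Group.CONTROL)
    if not controls:
        raise AnchorError(f"{antigen}: no control sera to anchor percent binding")
    control = float(table.od.loc[controls, antigen].mean())
    pos = table.subjects(Group.POSITIVE_CONTROL)
    if pos:
        max_positive = float(table.od.loc[pos, antigen].max())
    else:
        patients = table.subjects(Group.PATIENT)
        if not patients:
            raise AnchorError(f"{antigen}: no patients and no positive-control row")
        max_positive = float(table.od.loc[patients, antigen].max())
    if max_positive <= control:
        raise AnchorError(f"{antigen}: max-positive anchor does not exceed control")
    return control, max_positive


def classify_table(table: ODTable) -> ClassifiedTable:
    """Percent binding + category for every patient/antigen cell.

    The control anchor is the pooled (mean) control OD per antigen; the
    max-positive anchor is the highest positive-control OD when such
    rows exist, else the highest patient OD.  Selected sera are the
    patients classified significant or very high for every antigen
    simultaneously (the shortlist carried forward to immunoblot).
    """
    patients = table.subjects(Group.PATIENT)
    if not patients:
        raise AnchorError("table contains no patient sera")
    results: list[PercentBindingResult] = []
    anchor_rows = []
    per_subject_positive: dict[str, int] = {s: 0 for s in patients}
    counts = pd.DataFrame(
        0, index=table.antigens, columns=[c.value for c in CATEGORY_ORDER]
    )
    for antigen in table.antigens:
        control, max_positive = _anchors(table, antigen)
        anchor_rows.append(
            {"antigen": antigen, "control": control, "max_positive": max_positive}
        )
        for subject in patients:
            pct = percent_binding(
                float(table.od.loc[subject, antigen]), control, max_positive
            )
            cat = categorize(pct)
            results.append(
                PercentBindingResult(
                    subject=subject, antigen=antigen, percent=pct, category=cat
                )
            )
            counts.loc[antigen, cat.value] += 1
            if cat in (Category.SIGNIFICANT, Category.VERY_HIGH):
                per_subject_positive[subject] += 1
    n_antigens = len(table.antigens)
    selected = tuple(
        s for s in patients if per_subject_positive[s] == n_antigens
    )
    anchors = pd.DataFrame(anchor_rows).set_index("antigen")
    return ClassifiedTable(
        results=tuple(results), counts=counts, selected_sera=selected, anchors=anchors
    )


@dataclass(frozen=True)
class QualAssayResult:
    """Qualitative GM ELISA call: positive iff OD > blank mean + 0.1."""

    sample_mean: float
    blank_mean: float
    cutoff_margin: float = 0.1

    @property
    def cutoff(self) -> float:
        return self.blank_mean + self.cutoff_margin

    @property
    def positive(self) -> bool:
        return self.sample_mean > self.cutoff


def qualitative_gm_call(
    sample_ods: Sequence[float], blank_ods: Sequence[float]
) -> QualAssayResult:
    if len(sample_ods) < 1 or len(blank_ods) < 1:
        raise ValueError("need at least one replicate per group")
    return QualAssayResult(
        sample_mean=float(np.mean(sample_ods)), blank_mean=float(np.mean(blank_ods))
    )


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare_groups(
    patient_ods: Sequence[float], control_ods: Sequence[float]
) -> GroupComparison:
    """Welch two-sample two-tailed comparison, reported as mean +/- SEM."""
    a = np.asarray(patient_ods, dtype=float)
    b = np.asarray(control_ods, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_a=float(a.mean()),
        sem_a=float(stats.sem(a)),
        mean_b=float(b.mean()),
        sem_b=float(stats.sem(b)),
        t_statistic=float(t),
        p_value=float(p),
    )


class Presence(str, enum.Enum):
    PRESENT = "present"
    FAINT = "faint"
    ABSENT = "absent"


class StabilityCall(str, enum.Enum):
    STABLE = "stable"
    PARTIAL = "partial"
    DIGESTED = "digested"


#: the pepsin-digest sampling grid, minutes
DEFAULT_TIME_POINTS = (0, 1, 5, 15, 30, 45, 60)


@dataclass
class BandMatrix:
    """Gel band presence per (fraction kD, digestion time in minutes)."""

    extract: str
    fractions: tuple[float, ...]
    time_points: tuple[int, ...]
    presence: pd.DataFrame  # index fraction kD, columns time, values Presence

    def __post_init__(self) -> None:
        self.fractions = tuple(self.fractions)
        self.time_points = tuple(self.time_points)
        if any(b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise BandMatrixError("time points must be strictly increasing")
        for kd in self.fractions:
            if self.presence.loc[kd, self.time_points[0]] is not Presence.PRESENT:
                raise BandMatrixError(
                    f"fraction {kd} kD absent at time {self.time_points[0]} min"
                )

    @classmethod
    def from_codes(
        cls,
        extract: str,
        fractions: Sequence[float],
        rows: Sequence[str],
        time_points: Sequence[int] = DEFAULT_TIME_POINTS,
    ) -> "BandMatrix":
        """Build from compact per-fraction strings of p/f/a codes."""
        code = {"p": Presence.PRESENT, "f": Presence.FAINT, "a": Presence.ABSENT}
        data = {
            kd: [code[c] for c in row] for kd, row in zip(fractions, rows, strict=True)
        }
        presence = pd.DataFrame.from_dict(
            data, orient="index", columns=list(time_points)
        )
        return cls(
            extract=extract,
            fractions=tuple(fractions),
            time_points=tuple(time_points),
            presence=presence,
        )


@dataclass(frozen=True)
class BandCall:
    fraction: float
    call: StabilityCall
    last_seen: int  # minutes; last time point with any visible band


@dataclass(frozen=True)
class StabilityResult:
    calls: tuple[BandCall, ...]

    def by_call(self, call: StabilityCall) -> tuple[BandCall, ...]:
        return tuple(c for c in self.calls if c.call is call)

    @property
    def n_stable(self) -> int:
        return len(self.by_call(StabilityCall.STABLE))

    @property
    def counts(self) -> dict[str, int]:
        return {c.value: len(self.by_call(c)) for c in StabilityCall}

    def stable_fractions(self) -> tuple[float, ...]:
        return tuple(c.fraction for c in self.by_call(StabilityCall.STABLE))


def sgf_stability(matrix: BandMatrix) -> StabilityResult:
    """Call each fraction stable / partial / digested from the final lane.

    Stable: still a full band at the last time point.  Partial: only a
    faint band remains.  Digested: gone by the last time point;
    ``last_seen`` records the final time a band was visible at all.
    """
    calls = []
    final_t = matrix.time_points[-1]
    for kd in matrix.fractions:
        row = matrix.presence.loc[kd, list(matrix.time_points)]
        state = row[final_t]
        if state is Presence.PRESENT:
            call = StabilityCall.STABLE
        elif state is Presence.FAINT:
            call = StabilityCall.PARTIAL
        else:
            call = StabilityCall.DIGESTED
        seen = [t for t in matrix.time_points if row[t] is not Presence.ABSENT]
        calls.append(BandCall(fraction=kd, call=call, last_seen=seen[-1]))
    return StabilityResult(calls=tuple(calls))


@dataclass(frozen=True)
class ImmunoblotTable:
    """IgE-reactive bands (kD) one serum recognised in one extract."""

    case_id: str
    extract: str
    bands: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(kd <= 0 for kd in self.bands):
            raise ValueError("band masses must be positive")
        if len(set(self.bands)) != len(self.bands):
            raise ValueError("bands must be unique within a (case, extract)")


@dataclass(frozen=True)
class BandMatching:
    pairs: tuple[tuple[float, float], ...]
    unmatched_a: tuple[float, ...]
    unmatched_b: tuple[float, ...]


def match_bands(
    set_a: Sequence[float], set_b: Sequence[float], rel_tol: float = 0.10
) -> BandMatching:
    """Greedy nearest-mass matching within a relative tolerance.

    Bands a, b match iff |a-b| / max(a, b) <= rel_tol; each band is
    used at most once, closest relative distance first.
    """
    if not 0 < rel_tol < 0.5:
        raise ValueError("rel_tol must lie in (0, 0.5)")
    candidates = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            d = abs(a - b) / max(a, b)
            if d <= rel_tol:
                candidates.append((d, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((set_a[i], set_b[j]))
    return BandMatching(
        pairs=tuple(pairs),
        unmatched_a=tuple(a for i, a in enumerate(set_a) if i not in used_a),
        unmatched_b=tuple(b for j, b in enumerate(set_b) if j not in used_b),
    )


def _merge_bands(bands: Iterable[float], rel_tol: float) -> tuple[float, ...]:
    """Collapse masses within tolerance to one representative (the first seen)."""
    out: list[float] = []
    for kd in bands:
        if not any(abs(kd - ref) / max(kd, ref) <= rel_tol for ref in out):
            out.append(kd)
    return tuple(sorted(out))


@dataclass(frozen=True)
class ConcordanceResult:
    per_extract_union: dict[str, tuple[float, ...]]
    shared: tuple[float, ...]

    def union_size(self, extract: str) -> int:
        return len(self.per_extract_union[extract])


def read_od_table(path) -> ODTable:
    """Tidy TSV with columns subject, group, antigen, od."""
    tidy = pd.read_csv(path, sep="\t")
    required = {"subject", "group", "antigen", "od"}
    if not required <= set(tidy.columns):
        raise ValueError(f"OD table needs columns {sorted(required)}")
    return ODTable.from_tidy(tidy)


def read_band_matrix(path, extract: str | None = None) -> BandMatrix:
    """TSV: first column ``fraction`` (kD), remaining columns time points in
    minutes, cells p/f/a (present/faint/absent)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "fraction":
        raise BandMatrixError("first column must be 'fraction'")
    times = [int(c) for c in df.columns[1:]]
    fractions = [float(v) for v in df["fraction"]]
    rows = ["".join(str(v) for v in df.iloc[i, 1:]) for i in range(len(df))]
    return BandMatrix.from_codes(
        extract or str(path), fractions, rows, time_points=times
    )


def read_immunoblot_tables(path) -> list[ImmunoblotTable]:
    """Tidy TSV with columns case, extract, band_kd (one band per row)."""
    df = pd.read_csv(path, sep="\t")
    required = {"case", "extract", "band_kd"}
    if not required <= set(df.columns):
        raise ValueError(f"immunoblot table needs columns {sorted(required)}")
    out = []
    for (case, extract), sub in df.groupby(["case", "extract"], sort=False):
        out.append(
            ImmunoblotTable(
                case_id=str(case),
                extract=str(extract),
                bands=tuple(float(v) for v in sub["band_kd"]),
            )
        )
    return out


def immunoblot_concordance(
    tables: Sequence[ImmunoblotTable], rel_tol: float = 0.10
) -> ConcordanceResult:
    """Union of distinct bands per extract and the cross-extract shared set.

    Distinctness uses tolerance-based merging; the shared set contains
    the bands of the first extract's union that match (within
    tolerance) a band in every other extract's union.
    """
    if not tables:
        raise ValueError("need at least one immunoblot table")
    per_extract: dict[str, list[float]] = {}
    for t in tables:
        per_extract.setdefault(t.extract, []).extend(t.bands)
    union = {ex: _merge_bands(bands, rel_tol) for ex, bands in per_extract.items()}
    extracts = list(union)
    shared = list(union[extracts[0]])
    for other in extracts[1:]:
        matched = match_bands(shared, union[other], rel_tol)
        shared = sorted(a for a, _ in matched.pairs)
    return ConcordanceResult(per_extract_union=union, shared=tuple(shared))
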