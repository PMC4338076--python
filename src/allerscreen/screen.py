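"""Two-tier in-silico allergenicity screen.

Tier 1 — full-length homology: the query is aligned against every
database record; hits are ranked by shuffle-calibrated E score, with a
database-profile reporting threshold (AllergenOnline/FARRP convention
E < 1; SDAP convention E <= 0.01) and the Aalberse full-length rule
(identity > 50% suggests likely allergenicity).

Tier 2 — the Codex-derived 80-mer sliding window: every contiguous
80-residue query segment is locally aligned to every allergen; any
window whose optimal alignment exceeds 35% identity flags potential
IgE cross-reactivity.

Verdicts aggregate both tiers: a flagged window or a high-identity
full-length hit means "potential-cross-reactive"; a reported
full-length hit at <=50% identity (the classic borderline case: a Cry
toxin vs a Candida albicans allergen at E = 0.9 and 26% identity) means
"requires-further-testing"; otherwise "no-evidence".
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .align import (
    AlignmentHit,
    AlignmentParams,
    LocalAlignment,
    calibrate_evd,
    evalue,
    shares_word,
    smith_waterman,
)
from .seqio import AllergenRecord, DbSource, SequenceRecord


class ConsistencyError(ValueError):
    """The two screening tiers were run with different configurations."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the two-tier screen.

    Identity thresholds are strict greater-than comparisons on
    unrounded percentages; rounding to 0.1% happens only in reports.
    """

    window_size: int = 80
    window_identity_threshold: float = 35.0
    full_identity_threshold: float = 50.0
    e_report_threshold_farrp: float = 1.0
    e_report_threshold_sdap: float = 0.01
    e_search_cutoff: float = 10.0
    n_shuffles: int = 100
    params: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        for t in (self.window_identity_threshold, self.full_identity_threshold):
            if not 0 < t < 100:
                raise ValueError("identity thresholds must lie in (0, 100)")
        for e in (
            self.e_report_threshold_farrp,
            self.e_report_threshold_sdap,
            self.e_search_cutoff,
        ):
            if e <= 0:
                raise ValueError("E thresholds must be positive")

    def passes_profile(self, e_score: float, profile: DbSource) -> bool:
        if profile is DbSource.SDAP:
            return e_score <= self.e_report_threshold_sdap
        # FARRP and custom profiles use the strict E < 1 convention
        return e_score < self.e_report_threshold_farrp


class Verdict(str, enum.Enum):
    NO_EVIDENCE = "no-evidence"
    POTENTIAL_CROSS_REACTIVE = "potential-cross-reactive"
    REQUIRES_FURTHER_TESTING = "requires-further-testing"


@dataclass(frozen=True)
class WindowHit:
    """One (query window, allergen) alignment above the identity rule."""

    window_start: int
    allergen: AllergenRecord
    alignment: LocalAlignment
    percent_identity: float


@dataclass(frozen=True)
class FullLengthResult:
    hits: tuple[AlignmentHit, ...]
    profile: DbSource
    config: ScreenConfig


@dataclass(frozen=True)
class WindowResult:
    table: pd.DataFrame  # per-allergen best window identity, descending
    flagged: tuple[WindowHit, ...]
    config: ScreenConfig


@dataclass(frozen=True)
class ScreenReport:
    """Aggregated verdict of both tiers for one query."""

    query_id: str
    query_length: int
    full_length: FullLengthResult
    windows: WindowResult
    verdict: Verdict
    reasons: tuple[str, ...]
    mode: str

    def to_frame(self) -> pd.DataFrame:
        """One row per allergen; fixed column order."""
        full_best: dict[str, AlignmentHit] = {}
        for hit in self.full_length.hits:
            key = hit.subject.allergen_name
            if key not in full_best:
                full_best[key] = hit
        flagged_by_allergen: dict[str, list[WindowHit]] = {}
        for wh in self.windows.flagged:
            flagged_by_allergen.setdefault(wh.allergen.allergen_name, []).append(wh)
        rows = []
        for _, row in self.windows.table.iterrows():
            name = row["allergen_name"]
            hit = full_best.get(name)
            flags = ";".join(
                f"window@{wh.window_start}"
                for wh in flagged_by_allergen.get(name, [])
            )
            rows.append(
                {
                    "allergen_name": name,
                    "best_full_E": round(hit.e_score, 4) if hit else float("nan"),
                    "best_full_identity": (
                        round(hit.alignment.percent_identity, 1) if hit else float("nan")
                    ),
                    "best_full_similarity_per_query": (
                        round(100.0 * hit.alignment.n_positives / self.query_length, 1)
                        if hit
                        else float("nan")
                    ),
                    "best_window_identity": round(row["best_window_identity"], 1),
                    "window_start": int(row["window_start"]),
                    "flags": flags,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "allergen_name",
                "best_full_E",
                "best_full_identity",
                "best_full_similarity_per_query",
                "best_window_identity",
                "window_start",
                "flags",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def verdict_block(self) -> dict:
        cfg = self.windows.config
        return {
            "query": self.query_id,
            "query_length": self.query_length,
            "verdict": self.verdict.value,
            "reasons": list(self.reasons),
            "mode": self.mode,
            "profile": self.full_length.profile.value,
            "thresholds": {
                "window_size": cfg.window_size,
                "window_identity_gt": cfg.window_identity_threshold,
                "full_identity_gt": cfg.full_identity_threshold,
                "e_report_farrp_lt": cfg.e_report_threshold_farrp,
                "e_report_sdap_le": cfg.e_report_threshold_sdap,
                "e_search_cutoff": cfg.e_search_cutoff,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.verdict_block(), indent=2) + "\n")


def enumerate_windows(
    query: SequenceRecord, window_size: int = 80
) -> list[tuple[int, SequenceRecord]]:
    """All contiguous windows with 1-based start offsets (1-80, 2-81, ...).

    A query shorter than the window is screened as a single
    whole-sequence window.
    """
    L = query.length
    if L <= window_size:
        return [(1, query)]
    out = []
    for start in range(L - window_size + 1):
        out.append(
            (
                start + 1,
                SequenceRecord(
                    id=f"{query.id}:{start + 1}-{start + window_size}",
                    residues=query.residues[start : start + window_size],
                ),
            )
        )
    return out


def full_length_screen(
    query: SequenceRecord,
    db: Sequence[AllergenRecord],
    cfg: ScreenConfig,
    profile: DbSource = DbSource.FARRP,
    seed: int = 0,
) -> FullLengthResult:
    """Tier 1: whole-query alignment against every database record."""
    if not db:
        warnings.warn("empty allergen database: no full-length hits", stacklevel=2)
        return FullLengthResult(hits=(), profile=profile, config=cfg)
    alignments: dict[str, LocalAlignment] = {}
    candidates = []
    for rec in db:
        if cfg.params.ktup and not shares_word(query.residues, rec.residues, cfg.params.ktup):
            continue
        alignments[rec.id] = smith_waterman(query, rec, cfg.params)
        candidates.append(rec)
    if not candidates or max(a.score for a in alignments.values()) == 0:
        # no positive-scoring alignment exists at all: nothing to calibrate
        warnings.warn(
            "query produces no positive-scoring alignment against the database",
            stacklevel=2,
        )
        return FullLengthResult(hits=(), profile=profile, config=cfg)
    cal = calibrate_evd(query, db, cfg.params, n_shuffles=cfg.n_shuffles, seed=seed)
    hits = []
    for rec in candidates:
        aln = alignments[rec.id]
        if aln.is_empty:
            continue
        e = evalue(aln.score, cal)
        if e < cfg.e_search_cutoff:
            hits.append(
                AlignmentHit(
                    subject=rec,
                    alignment=aln,
                    e_score=e,
                    passes_profile=cfg.passes_profile(e, profile),
                )
            )
    hits.sort(key=lambda h: (h.e_score, -h.alignment.score, h.subject.id))
    return FullLengthResult(hits=tuple(hits), profile=profile, config=cfg)


def window_screen(
    query: SequenceRecord,
    db: Sequence[AllergenRecord],
    cfg: ScreenConfig,
) -> WindowResult:
    """Tier 2: optimal alignment of every (80-mer window, allergen) pair."""
    if not db:
        warnings.warn("empty allergen database: no window hits", stacklevel=2)
        empty = pd.DataFrame(
            columns=["allergen_name", "best_window_identity", "window_start"]
        )
        return WindowResult(table=empty, flagged=(), config=cfg)
    windows = enumerate_windows(query, cfg.window_size)
    rows = []
    flagged: list[WindowHit] = []
    for rec in db:
        if cfg.params.ktup and not shares_word(query.residues, rec.residues, cfg.params.ktup):
            rows.append(
                {"allergen_name": rec.allergen_name, "best_window_identity": 0.0,
                 "window_start": 0}
            )
            continue
        best_pid = 0.0
        best_start = windows[0][0]
        for start, win in windows:
            aln = smith_waterman(win, rec, cfg.params)
            pid = aln.percent_identity
            if pid > best_pid:
                best_pid, best_start = pid, start
            if pid > cfg.window_identity_threshold:
                flagged.append(
                    WindowHit(
                        window_start=start,
                        allergen=rec,
                        alignment=aln,
                        percent_identity=pid,
                    )
                )
        rows.append(
            {
                "allergen_name": rec.allergen_name,
                "best_window_identity": best_pid,
                "window_start": best_start,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(
            ["best_window_identity", "allergen_name"], ascending=[False, True]
        )
        .reset_index(drop=True)
    )
    return WindowResult(table=table, flagged=tuple(flagged), config=cfg)


def aggregate_verdict(
    query: SequenceRecord,
    full: FullLengthResult,
    windows: WindowResult,
) -> ScreenReport:
    """Combine both tiers into a verdict with explicit reasons."""
    if full.config is not windows.config and full.config != windows.config:
        raise ConsistencyError("full-length and window screens used different configs")
    cfg = windows.config
    reasons: list[str] = []
    for wh in windows.flagged:
        reasons.append(
            f"window {wh.window_start} vs {wh.allergen.allergen_name}: "
            f"{wh.percent_identity:.1f}% identity > "
            f"{cfg.window_identity_threshold:g}% over "
            f"{wh.alignment.n_columns} aligned columns"
        )
    high_full = False
    reported_full = False
    for hit in full.hits:
        if not hit.passes_profile:
            continue
        pid = hit.alignment.percent_identity
        if pid > cfg.full_identity_threshold:
            high_full = True
            reasons.append(
                f"full-length hit {hit.subject.allergen_name}: E={hit.e_score:.3g} "
                f"passes {full.profile.value} threshold with {pid:.1f}% identity > "
                f"{cfg.full_identity_threshold:g}%"
            )
        else:
            reported_full = True
            reasons.append(
                f"full-length hit {hit.subject.allergen_name}: E={hit.e_score:.3g} "
                f"passes {full.profile.value} threshold but identity {pid:.1f}% <= "
                f"{cfg.full_identity_threshold:g}% (inconclusive)"
            )
    if windows.flagged or high_full:
        verdict = Verdict.POTENTIAL_CROSS_REACTIVE
    elif reported_full:
        verdict = Verdict.REQUIRES_FURTHER_TESTING
    else:
        verdict = Verdict.NO_EVIDENCE
        reasons.append(
            f"no window > {cfg.window_identity_threshold:g}% identity and no "
            f"full-length hit passing the {full.profile.value} E threshold"
        )
    mode = "exact-dp" + (f"+ktup{cfg.params.ktup}" if cfg.params.ktup else "")
    return ScreenReport(
        query_id=query.id,
        query_length=query.length,
        full_length=full,
        windows=windows,
        verdict=verdict,
        reasons=tuple(reasons),
        mode=mode,
    )


def screen_query(
    query: SequenceRecord,
    db: Sequence[AllergenRecord],
    cfg: ScreenConfig | None = None,
    profile: DbSource = DbSource.FARRP,
    seed: int = 0,
) -> ScreenReport:
    """Run both tiers and aggregate: the end-to-end screen for one query."""
    cfg = cfg or ScreenConfig()
    full = full_length_screen(query, db, cfg, profile=profile, seed=seed)
    windows = window_screen(query, db, cfg)
    return aggregate_verdict(query, full, windows)
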