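"""Protein sequence records, FASTA I/O and the BLOSUM50 substitution matrix.

The screening pipeline works on plain protein FASTA: query transgene
proteins (e.g. the Bt Cry toxins) and an allergen database such as a
FARRP/AllergenOnline-style or SDAP-style export.  Records carry optional
allergen metadata (IUIS-style name, source organism) supplied either in
the header or in a tab-separated sidecar file.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices

#: 20 canonical residues plus the ambiguity codes B, Z and X.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX"
_ALPHABET_SET = frozenset(ALPHABET)


class FastaFormatError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


class SequenceValidationError(ValueError):
    """A sequence violates the residue alphabet or is empty."""


class DbSource(str, enum.Enum):
    """Threshold conventions of the allergen database a record came from."""

    FARRP = "farrp"
    SDAP = "sdap"
    CUSTOM = "custom"


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with identity metadata.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    the remainder is kept as ``description``.  ``accession`` is parsed
    from ``db|ACC|name`` style headers when present.
    """

    id: str
    residues: str
    description: str = ""
    accession: str = ""

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclass(frozen=True)
class AllergenRecord(SequenceRecord):
    """A database entry: a sequence plus allergen nomenclature."""

    allergen_name: str = ""
    source_organism: str = ""
    db_source: DbSource = DbSource.CUSTOM

    def __post_init__(self) -> None:
        if not self.allergen_name:
            # default the display name to the record id
            object.__setattr__(self, "allergen_name", self.id)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-pair scoring table."""

    name: str
    alphabet: str
    _scores: dict = field(repr=False)

    def score(self, a: str, b: str) -> int:
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(
                f"residue pair ({a!r}, {b!r}) not covered by matrix {self.name}"
            ) from None

    def __call__(self, a: str, b: str) -> int:
        return self.score(a, b)

    def as_array(self, alphabet: str | None = None):
        """Dense integer score array over ``alphabet`` (default: own order)."""
        import numpy as np

        ab = alphabet or self.alphabet
        n = len(ab)
        arr = np.empty((n, n), dtype=np.int32)
        for i, a in enumerate(ab):
            for j, b in enumerate(ab):
                arr[i, j] = self.score(a, b)
        return arr


def load_blosum50() -> SubstitutionMatrix:
    """The standard published BLOSUM50 table over the 23-letter alphabet.

    Backed by the table Biopython distributes; the stop-codon row is
    dropped since stop characters are stripped at parse time.
    """
    raw = substitution_matrices.load("BLOSUM50")
    scores: dict[tuple[str, str], int] = {}
    for a in ALPHABET:
        for b in ALPHABET:
            scores[(a, b)] = int(raw[a, b])
    return SubstitutionMatrix(name="BLOSUM50", alphabet=ALPHABET, _scores=scores)


def validate_sequence(record: SequenceRecord) -> SequenceRecord:
    """Uppercase the residues and enforce the alphabet; idempotent."""
    residues = record.residues.upper()
    if not residues:
        raise SequenceValidationError(f"record {record.id!r}: empty sequence")
    bad = sorted(set(residues) - _ALPHABET_SET)
    if bad:
        raise SequenceValidationError(
            f"record {record.id!r}: residues outside alphabet: {', '.join(bad)}"
        )
    if residues == record.residues:
        return record
    return replace(record, residues=residues)


def _parse_header(line: str) -> tuple[str, str, str]:
    body = line[1:].strip()
    if not body:
        raise FastaFormatError("empty FASTA header")
    token, _, description = body.partition(" ")
    accession = ""
    if "|" in token:
        parts = token.split("|")
        if len(parts) >= 3 and parts[1]:
            accession = parts[1]
    return token, description.strip(), accession


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a protein FASTA file into validated records.

    Accepts LF/CRLF endings and arbitrary line wrapping; ``*`` stop
    characters are stripped with a warning.  Illegal residues raise
    :class:`FastaFormatError` naming the line number.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: tuple[str, str, str] | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaFormatError(
                f"{path}:{header_line}: record {header[0]!r} has no sequence"
            )
        records.append(
            SequenceRecord(
                id=header[0],
                residues=residues,
                description=header[1],
                accession=header[2],
            )
        )

    with path.open("r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                chunks = []
                header_line = lineno
                try:
                    header = _parse_header(line)
                except FastaFormatError as exc:
                    raise FastaFormatError(f"{path}:{lineno}: {exc}") from None
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                seq = line.strip().upper()
                if "*" in seq:
                    warnings.warn(
                        f"{path}:{lineno}: stripped stop character(s) '*'",
                        stacklevel=2,
                    )
                    seq = seq.replace("*", "")
                bad = sorted(set(seq) - _ALPHABET_SET)
                if bad:
                    raise FastaFormatError(
                        f"{path}:{lineno}: illegal residue character(s): "
                        f"{', '.join(bad)}"
                    )
                chunks.append(seq)
    flush()
    if header is None and not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            handle.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


def dedupe_ids(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Disambiguate duplicate ids with an ordinal suffix (isoallergens)."""
    seen: dict[str, int] = {}
    out: list[SequenceRecord] = []
    for rec in records:
        n = seen.get(rec.id, 0)
        seen[rec.id] = n + 1
        out.append(rec if n == 0 else replace(rec, id=f"{rec.id}.{n + 1}"))
    return out


def read_allergen_db(
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
    db_source: DbSource = DbSource.CUSTOM,
) -> list[AllergenRecord]:
    """Read an allergen database FASTA plus an optional metadata sidecar.

    The sidecar is tab-separated with columns ``id``, ``allergen_name``,
    ``organism``.  Records missing from the sidecar default their
    allergen name to the FASTA id.
    """
    meta: dict[str, tuple[str, str]] = {}
    if metadata_path is not None:
        for lineno, raw in enumerate(
            Path(metadata_path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 2:
                raise FastaFormatError(
                    f"{metadata_path}:{lineno}: expected id<TAB>allergen_name[<TAB>organism]"
                )
            meta[parts[0]] = (parts[1], parts[2] if len(parts) > 2 else "")
    out: list[AllergenRecord] = []
    for rec in dedupe_ids([validate_sequence(r) for r in read_fasta(fasta_path)]):
        name, organism = meta.get(rec.id, ("", ""))
        out.append(
            AllergenRecord(
                id=rec.id,
                residues=rec.residues,
                description=rec.description,
                accession=rec.accession,
                allergen_name=name,
                source_organism=organism,
                db_source=db_source,
            )
        )
    return out
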