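# allerscreen

Regulatory allergenicity assessment of transgene proteins — for example
the *Bacillus thuringiensis* Cry toxins (Cry 1Ab, Cry 1Ac, Cry 1C)
expressed in insect-resistant GM maize — combines an *in silico*
sequence screen against curated allergen databases with wet-lab
comparisons of the GM and parental crop. `allerscreen` implements the
computational side of that workflow as a reusable Python library and
CLI, for biosafety analysts and students who want the screening and
scoring rules to be explicit, deterministic and testable rather than
locked inside web servers and spreadsheets.

## What it computes

**Two-tier sequence screen.** Each query protein is compared with every
allergen record by exact Smith–Waterman/Gotoh local alignment under
BLOSUM50 with affine gap cost 12 + 2·(g−1) for a gap of length g (the
classic FASTA −12/−2 parameterisation; an optional ktup=2 word-match
prefilter mirrors FASTA's seeding step as a database skip):

* *Full-length homology.* Hits are ranked by expectation score
  E = N·P(S ≥ s), where the chance-score law P is a Gumbel (type-I
  extreme value) distribution fitted by maximum likelihood to
  alignments of the query against residue-shuffled database sequences,
  and N is the database size. Reporting thresholds follow the database
  profile: AllergenOnline/FARRP convention E < 1, SDAP convention
  E ≤ 0.01. Full-length identity > 50% (the Aalberse rule) marks likely
  allergenicity.
* *Codex 80-mer sliding window.* Every contiguous 80-residue segment
  (1–80, 2–81, …) is aligned to every allergen; a window whose optimal
  alignment exceeds **35% identity** (identities / aligned columns,
  gap columns included) flags potential IgE cross-reactivity.

Verdicts: `potential-cross-reactive` (any flagged window, or a
reported full-length hit above 50% identity), `requires-further-testing`
(a reported full-length hit at ≤ 50% identity — e.g. an E = 0.9 hit at
26% identity), else `no-evidence`.

**Serology and gel scoring.** Specific-IgE ELISA percent binding
100·(OD_patient − OD_control)/(OD_max-positive − OD_control), classified
into the four groups <15 / 15–30 / 30–60 / >60 %, with >30% counted
positive; the qualitative GM ELISA call (positive iff mean OD > blank
mean + 0.1); Welch two-sample patient/control comparison reported as
mean ± SEM; simulated-gastric-fluid (SGF) band-stability calling over
the 0–60 min pepsin digestion grid; and immunoblot band concordance
across sera and extracts with tolerance-based kD matching.

**Synthetic data.** Seeded generators produce decoy allergen databases
whose composition is score-separated from the query alphabet, planted
homologous 80-mers at constructively exact identity levels, OD tables
that invert the percent-binding formula to hit target category counts
exactly, and band-by-time digestion matrices — so the whole pipeline is
testable without licensed database snapshots or clinical data.

## Worked example

Plant an 80-mer mutated at 51 of 80 positions (36.25% identity — just
over the 35% rule) into a decoy database, then screen:

```sh
$ allerscreen simulate plant --query-length 80 --n-mismatch 51 --seed 7 query.fa db.fa
planted identity 36.25% -> db.fa
$ allerscreen screen query.fa db.fa --out-dir out
query	potential-cross-reactive	out/query.screen.tsv
$ echo $?
3
```

Exit code 3 means the screen *flagged* the query (a finding, not an
error). The verdict JSON records every triggering rule and the exact
thresholds used:

```
"reasons": [
  "window 1 vs decoy1: 36.2% identity > 35% over 80 aligned columns",
  "full-length hit decoy1: E=7.05e-36 passes farrp threshold but identity 36.2% <= 50% (inconclusive)"
]
```

With `--n-mismatch 52` the planted identity is exactly 35.0%, which
does **not** exceed the strict threshold: the screen reports
`no-evidence` and exits 0.

On the assay side, calling SGF stability on the encoded non-GM maize
digestion matrix (12 fractions sampled at 0/1/5/15/30/45/60 min):

```python
>>> from allerscreen.maize_study import band_matrices
>>> from allerscreen.serology import sgf_stability
>>> result = sgf_stability(band_matrices()["nonGM"])
>>> result.counts
{'stable': 6, 'partial': 6, 'digested': 0}
>>> sorted(result.stable_fractions())
[10.0, 14.0, 19.0, 28.0, 38.0, 60.0]
```

Six fractions (60, 38, 28, 19, 14, 10 kD) survive the full hour of
pepsin digestion as intense bands — pepsin resistance being one of the
classical correlates of allergenic potential — while the six high-mass
fractions persist only as faint bands (partial digestion).

## Layout

```
src/allerscreen/
  seqio.py        FASTA I/O, sequence records, BLOSUM50
  align.py        Smith–Waterman/Gotoh, E-value calibration
  screen.py       two-tier screen and verdict aggregation
  serology.py     percent binding, qualitative calls, SGF, immunoblot
  synth.py        seeded generators for all pipeline inputs
  maize_study.py  encoded published assay outcomes (inputs to scoring)
  cli.py          `allerscreen` command-line interface
```
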