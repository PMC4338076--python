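# Methods

## Alignment model

The screen computes *exact* optimal local alignments by the Gotoh
affine-gap dynamic programme rather than the FASTA heuristic that
regulatory web servers historically ran with the same scoring. The two
agree whenever the heuristic finds the optimum; exact DP is preferred
here because it is deterministic, parameter-complete and reproducible.
Reports record the mode (`exact-dp`, or `exact-dp+ktup2` when the
optional word-match prefilter is enabled; the prefilter only skips
database records sharing no exact 2-word with the query and never
alters scores of retained records).

Scoring: BLOSUM50 over the 20 canonical residues plus B/Z/X, as
distributed with standard alignment suites (Biopython's table). A gap
of length g costs `gap_open + gap_extend·(g−1)` with defaults 12 and 2
— the "−12/−2" convention, stated explicitly because other tools charge
`open + g·extend`. Residue pairs absent from the matrix raise an error;
nothing is silently scored zero.

Traceback is made deterministic by fixed tie-breaks: the start cell is
the maximal DP cell with the smallest (query index, subject index) in
row-major order; at each step the move preference is diagonal, then
gap-in-subject, then gap-in-query; within a gap run the gap is closed
as early as possible. Identity and similarity percentages use the
aligned column count *including gap columns* as denominator (the
alignment's overlap length); comparisons against thresholds always use
unrounded values, with rounding to 0.1% only at report time.

The DP kernels are numba-compiled (an O(mn) matrix-filling kernel with
Python traceback for full alignments, and an O(n)-memory score-only
kernel for bulk scans). Correctness is established in the test suite by
two independent oracles: Biopython's `PairwiseAligner` in local mode on
500 random short pairs, and a no-memoisation exhaustive path enumerator
at tiny lengths.

## E-values

The expectation score of a hit is `E = N · P(S ≥ s)` with N the
database size and P a Gumbel law, the asymptotic distribution of
optimal ungapped local alignment scores and a good approximation for
gapped scores. Location and scale are fitted by maximum likelihood
(scipy) to scores of the query against residue-shuffled database
sequences (shuffling preserves composition and length). Defaults:
100 shuffles per query (minimum 30 enforced), seeded; identical inputs
and seed give a bit-identical calibration. A degenerate shuffle sample
(zero spread) raises a calibration error — except that the full-length
screen first short-circuits the case where *no* database record yields
a positive-scoring alignment at all, returning an empty hit list with a
warning, since there is then nothing to rank.

Because the calibration is internal (fitted on the same database), E
values printed by external servers are comparable only qualitatively.
A corollary worth knowing: when the database itself is drawn from the
null, roughly `e` records are expected below any threshold `E < e`, so
an occasional E < 1 decoy hit is correct behaviour, not a defect.

## The two-tier screen

Tier 1 retains full-length hits with E below a search cutoff (default
10) and marks those passing the database-profile reporting threshold —
strict `E < 1` for AllergenOnline/FARRP-style databases, `E ≤ 0.01` for
SDAP-style. Full-length reports carry both identity over the aligned
overlap and positives normalised by query length, because published
full-length "similarity" percentages are ambiguous between the two.

Tier 2 enumerates all `L − 79` contiguous 80-mers (a query shorter than
the window is screened as one whole-sequence window, following FAO/WHO
practice) and aligns each against each allergen; any window whose
optimal alignment strictly exceeds 35% identity is flagged, and the
per-allergen maximum is tabulated.

Verdict aggregation: flagged window or profile-passing full-length hit
above 50% identity → `potential-cross-reactive`; profile-passing hit at
≤ 50% identity → `requires-further-testing`; otherwise `no-evidence`.
Every triggering rule is listed verbatim in the report's reasons.

A caveat inherent to the sliding-window method: the identity of the
*best-scoring* local alignment is not monotone in homology. Against an
unrelated protein the optimal alignment can be very short and therefore
show high identity over few columns; and windows shifted a few residues
off a genuinely homologous segment trim terminal mismatches and realise
marginally higher identity ratios (e.g. 27/77 = 35.1% beside an exact
28/80 = 35.0% segment). Boundary-exact tests therefore use
single-window (80-residue) queries; users interpreting flags near the
threshold should inspect the aligned columns, which the report exposes.

## Serology scoring

Percent binding is `100·(OD_patient − OD_control)/(OD_max-positive −
OD_control)`; out-of-range values are reported, never clipped, and the
statistic is invariant under affine rescaling of the whole plate
(od → a·od + b, a > 0). The four groups are resolved as `< 15`,
`[15, 30)`, `[30, 60]`, `> 60` percent so that the published "more than
30% binding" positivity rule coincides exactly with the third group;
the published group labels overlap at their endpoints and one
convention had to be fixed. The control anchor is the mean control OD
per antigen (standing in for a pooled control serum); the max-positive
anchor is the highest positive-control OD when such rows exist,
otherwise the highest patient OD. The positive-control fallback matters:
with a patient-maximum anchor the top patient is always at 100%
binding, so tables intended to have an empty >60% group must carry an
explicit positive-control row (the generator always emits one).

Group comparison is a Welch two-sample two-tailed test (no named test
accompanies published "p < 0.05 (two-tailed)" statements; Welch is the
safe default under unequal variances and group sizes such as 39 vs 11),
reported as mean ± SEM. The >30% category and the group test are
reported separately and never conflated.

## Gel assays

SGF stability is called from the final time point: a full band at
60 min is `stable`, only a faint band `partial`, none `digested`;
`last_seen` records the last visible time. Faintness is an input
annotation read off the gel, not inferred — no densitometry. Every
fraction must be present at time 0.

Immunoblot concordance merges bands within a relative mass tolerance
(default 10%, reflecting the approximation of gel kD estimates) to form
per-extract unions across sera, then intersects unions across extracts
by greedy nearest-mass matching (each band used once, closest relative
distance first). The IgE-binding vs SGF-stable overlap is reported as a
tolerance-dependent set, never asserted as a fixed count.

## Synthetic data

Queries for screening tests are drawn from the alphabet {C, G, P, W}
and decoys from {A, R, N, D, Q, E, H, I, L, K, M, S, T, V}; under
BLOSUM50 no cross pair of these sets scores positively, so a decoy
segment can never seed an alignment against a query — chance window
identities are structurally zero, not merely improbable. Planted
homologs substitute each mismatched residue with a partner scoring
exactly −1 against the original (C→A, G→D, P→S, W→M) at positions
spread evenly between match positions that include both window ends;
every mismatch run then costs less than the smallest self-score
(G–G = 8), so the optimal alignment provably spans the full window and
realises exactly `window − n_mismatch` identities over `window`
columns. Each planting is verified by an actual alignment at
construction time and fails loudly otherwise.

OD tables are built backwards from the percent-binding formula: control
ODs near a 0.03 baseline (Gaussian noise, σ = 0.005, floored at 0), a
0.85 positive-control anchor, and patient ODs back-computed from target
percentages drawn inside each category band, keeping clear of the
15/30/60 boundaries. Positive categories are assigned to the
lowest-indexed patients so the jointly-selected set across antigens
equals the minimum per-antigen positive count by construction. Band
matrices give unstable fractions a seeded dropout time with a terminal
faint lane.

What the generators do *not* emulate: realistic proteome composition,
ELISA optics and plate effects, inter-gel mobility variation. Passing
tests on synthetic data therefore demonstrate correctness of the
scoring rules and their boundary behaviour, not field performance
against real allergen databases — on real data, window identities near
the threshold and short-alignment artefacts (above) require human
review.

## Study inputs and problem sizes

The encoded study inputs (`maize_study.py`) are the published
band-by-time digestion outcomes of the four maize extracts, the five
sera's immunoblot band assignments, the qualitative ELISA absorbances,
and the specific-IgE category-count patterns over 39 patients and 11
controls. The published non-GM count pattern sums to 40 over 39 sera
(an internal inconsistency); synthetic reconstructions use the
consistent 16/14/9/0 analogue and the three GM patterns as printed.
Tests and the acceptance script run at desk scale: 80-residue queries,
decoy databases of 3–50 records of 100–400 residues, 30–100 calibration
shuffles, 200 replicates for the power check, 1000 samples for Gumbel
recovery — sizes chosen so the full suite completes in seconds while
keeping every statistical assertion comfortably powered.

## Known limitations

* E-value calibration is per-query and database-internal; absolute E
  values differ from FASTA's regression-based estimates.
* The 35% window rule is applied to the optimal local alignment of each
  window, with the overlap length as denominator; servers that use the
  full window length as denominator will report lower percentages for
  trimmed alignments.
* No motif/domain-level comparison and no short exact-match epitope
  (6–8-mer) search; the screen is sequence-identity based.
* Accession metadata is carried but never fetched; users supply their
  own database FASTA (licensed allergen lists cannot be redistributed).
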