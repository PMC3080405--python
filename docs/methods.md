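# Methods

## Model

The scorer treats cleavage-site recognition as peptide-neighborhood
similarity. A scissile bond is represented by its CCP(m, n) window — m
residues ending at P1, n residues starting at P1′ — and scored as the mean
clamped substitution-matrix similarity to the set of experimentally
verified cleavage peptides:

    score(c) = (1/|P|) Σ_{p∈P} max(0, Σᵢ Score(cᵢ, pᵢ))

Assumptions worth making explicit:

- **Similarity is additive over positions** and carried entirely by a
  21×21 integer substitution table; no pairwise-position or structural
  features.
- **Clamping happens per pair, before averaging.** A reference peptide can
  contribute zero but never negative evidence.
- **`*` is informationless.** Terminal padding scores 0 against everything
  at initialization and is frozen there; training cannot manufacture
  signal from proximity to a terminus.
- **One model for all calpain isoforms** — the curated site lists rarely
  resolve which calpain cut, so the method does not try to.

Because each pairwise similarity is an integer, all reference-set sums are
accumulated as int64 and divided once. This makes scores exact rationals
rounded once to float, evaluation order-invariant, and k-fold CV at
k = #positives *bitwise* equal to leave-one-out.

## Training

Order is fixed: window first, matrix second (the window is selected under
the un-mutated matrix), thresholds last.

- **MLS** evaluates every (m, n) in the configured grids by LOO Sn at the
  working Sp (default 0.90). Implementation detail: all windows are
  extracted once at (m_max, n_max) and each cell is a contiguous column
  slice, so one cumulative sum over positions serves the whole grid.
  Tie-break (the selection rule is otherwise under-determined on
  saturated data): higher Sn, then smaller m+n, then smaller m — compact
  motifs preferred. A consequence: when sensitivity saturates at 1.0 (very
  strong planted signal), the selected window is the *smallest* one that
  saturates, not the full motif span.
- **MaM** proposes a uniformly random ordered pair (a, b) of the 20 amino
  acids and a random ±1, and accepts iff LOO Sn at the working Sp strictly
  increases. Mutations are directional — (a, b) is the (candidate,
  reference) direction and the mirror entry is untouched (symmetric
  mutation exists as an option, default off), the weakest assumption since
  the comparison itself is directional. Each proposal is evaluated
  incrementally: changing entry (a, b) by δ shifts a pair's raw sum by
  δ × #positions where the candidate shows a against a reference b, a
  boolean matrix product; a test confirms equivalence with full
  recomputation. Termination: the plateau criterion "no further increase"
  is operationalized as `max_stale` consecutive rejections (default 2000,
  configurable); when Sn = 1.0 the loop exits immediately, since no strict
  improvement exists. Sn improves in steps of 1/#positives, so `max_stale`
  trades runtime against the chance of escaping a shallow plateau.
- **Thresholds.** The cutoff at specificity target t is the smallest
  *observed* score whose achieved Sp ≥ t (calls at score ≥ cutoff); if no
  observed score reaches t, a sentinel above the maximum is used (Sn = 0,
  Sp = 1). On discrete scores the achieved Sp is therefore the least
  attainable value ≥ t. High/medium/low use t = 0.95/0.90/0.85 on the
  final LOO distributions, which nests the cutoffs by construction.

## Evaluation

Ac, Sn, Sp and MCC follow the standard confusion-matrix definitions; a
metric with a zero denominator is reported as NaN, never coerced to 0.
ROC curves keep every distinct cutoff (ties grouped, diagonal segments)
and AROC is the trapezoidal area, equal to the Mann–Whitney statistic
P(pos > neg) + ½P(pos = neg).

Cross-validation partitions **positive sites** into k seeded folds.
Negatives never enter the reference set, so they need no fold exclusion;
each negative is scored against every fold's retained positives and its
integer sums pooled into one averaged score (the design was open — this
choice keeps one score per negative and collapses exactly onto LOO at
k = #positives). Self-consistency scores everything against the full
positive set, self-matches included, and hence upper-bounds LOO.

## Synthetic benchmark

The generator emulates a curated cleavage-site collection: ~130 substrates
(uniform lengths 200–600), 1–5 sites each, i.i.d. background residues
(uniform by default; real proteomes are mildly non-uniform, which the
generator deliberately ignores), and at each planted site a per-position
redraw from a motif profile mixed with the background at signal strength
λ. The default profile concentrates P2 on {L: .4, T: .3, V: .3} and P1 on
{K: .4, Y: .3, R: .3} — the preferences reported from calpain peptide
libraries — with milder enrichments (0.3 mass) of T@P4, P@P3, S@P1′,
P@P2′ echoing the TPLK|SPPPSPR super-substrate. λ defaults to 0.8,
a single a-priori choice of "strong but imperfectly conserved" signal;
λ = 1 gives the clean-motif stress test and λ = 0 the null.

What passing synthetic tests shows: the pipeline recovers a planted
position-specific preference, calibrates thresholds to their specificity
targets, and stays at chance on signal-free data. What it does not show:
performance on real calpain substrates, whose sites are homology-filtered,
non-independent, composition-biased and annotated with curation noise. The
four curated-benchmark tests exist for that purpose and require the
external data described in the README.

## Problem sizes and numerical choices

- The acceptance script trains on the full default generator conditions
  (130 substrates) with the MLS grid reduced to m ≤ 12, n ≤ 6 — wide
  enough to contain the plausible optimum for the planted profile — and
  MaM patience 300; the test suite uses 12–50 substrates and smaller
  grids/patience. These are the package's own problem-size choices for its
  bundled studies; all are constructor parameters.
- Score ties in thresholding are resolved by the explicit smallest-
  qualifying-cutoff rule above; no epsilon fudging.
- Windows longer than a sequence are handled by padding everywhere,
  including scanning — never an error.
- Sites annotated at a substrate's final residue have no following bond
  and are dropped with a warning (curation artifacts occur); the substrate
  still contributes negatives.
- Degenerate inputs rejected loudly: <2 positives for LOO/MaM, empty
  score lists, k outside [2, #positives], all-zero confusion counts,
  non-alphabet residues (named with their position).

## Known limitations

- Hill climbing with ±1 steps and strict-improvement acceptance finds a
  local optimum; no restarts or annealing are built in.
- MaM optimizes Sn at one operating point (Sp = 0.90); other regions of
  the ROC curve improve only incidentally.
- The scorer is sequence-only; accessibility, disorder and PEST context —
  known to modulate calpain cleavage — are out of scope.
- Redundancy filtering of homologous training sites (done upstream with
  clustering + pairwise re-alignment in curated data) is not
  re-implemented; the loaders assume a pre-deduplicated site table.
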