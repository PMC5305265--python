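# Methods

## The language and its description length

Stimuli are sequences of the eight vertices of a regular octagon, labeled
0–7 clockwise (flat-top convention).  A program describes such a sequence
as a chain of primitive transitions — rotations `+1, -1, +2, -2`, the four
axial reflections `H, V, A, B`, and the point (half-turn) symmetry `P` —
optionally compressed by two combinators:

* **Plain repetition** `[x]^n`: execute the block `n` times, continuing
  from the current position.
* **Repetition with variation** `[x]^n<v>`: treat the entry position plus
  the block's emissions as a *figure* and redraw it `n` times, applying the
  transform `v` (a start offset `±1, ±2, ±3, +4` or a global symmetry)
  pointwise at each repetition.  On a blank screen the first figure shows
  its entry; mid-sequence the entry is the location already on display.

Every primitive and transform is an affine map `x → ±x + c (mod 8)`.  The
four axial symmetries use the **edge-bisector axes** `c ∈ {7, 3, 1, 5}`
(H, V, A, B): this is the unique reflection convention under which every
one of the 7 displacements between distinct vertices is one instruction
away, which in turn is what makes the plain list of transitions a universal
(cost-16) description of any 8-location sequence.

The description length of a program is

* 2 units per primitive instruction,
* `ceil(log2 n)` units per repetition (so even a single repetition
  shortens a description: 2 + 1 < 2 + 2, and a 3-fold repetition costs an
  integer 2),
* for a variation, additionally the transform's 2 units plus a 1-unit
  flag.

The complexity `K` of a displayed sequence is the minimal cost over all
programs and over all (free, uncosted, undisplayed) anchor positions.

### The closed-tour rule

Two syntactic-semantic rules restrict what plain repetition may do:

1. a repeated block that draws **more than one location** must return to
   its entry on every iteration (repetition of closed loops, e.g.
   `[-2 +2]^4` alternating two points, or a four-point tour executed
   twice);
2. an **executed** repetition — one not nested inside a variation figure —
   must close its whole tour (`m^n = identity`): the full circle `[+1]^8`,
   a reflection iterated an even number of times, a square `[+2]^4`.
   Inside a variation figure a single instruction may trace an open stroke
   (`[+2]^3`, the three sides of a square that the variation completes).

These rules are part of the language definition and carry real calibrating
force.  Without them, open mixed strokes would repeat and the calibration
collapses: the two-squares sequence would compress to 7 via
`[H [+2]^3]^2`, the two-crosses sequence to 6 via `[-1 P]^4`, and — most
diagnostically — in the rotations-only control language the
parallel-segments zigzag would compress to 6 via `[+3 -1]^4` instead of
staying at the maximal 16 that defines it as the control's failure case.
With the rules in place, all eleven nominal complexities of the named
constructions (5, 6, 7, 7, 7, 7, 8, 8, 9, 10, 16) are attained
simultaneously, the enumerated space has maximum 16 with exactly 768
incompressible sequences, and the minimum 5 is attained by exactly the two
plain progressions.  The emitter enforces both rules at run time, so an
invalid repetition instantiation raises rather than emitting.

## Exact search

`minimal_description` is an exact interval dynamic program.  Every
sub-program is summarized by its *affine signature* — the tuple of maps
sending its entry position to each emitted position.  For a concrete
target subsequence at most two affine maps are feasible per position
(one rotation-like, one reflection-like), so signature dictionaries stay
tiny, and plain repetition is decidable locally: a block re-executed from
a new entry must reproduce the next stretch through the same maps.
Sub-solutions are memoized by `(entry, targets, context)` content rather
than by interval indices, so the full enumeration of all 5040 sequences
shares almost all of its work (a few seconds on one core).  Restricted
languages (no `P`, single-level repetition, the rotations-only control)
run through the same engine with a different instruction set.

The test suite checks the search against an independent brute-force
enumerator that structurally generates candidate items, executes each with
the emitter, and backtracks over decompositions — on the named
constructions, on 200 random sequences, and under the restricted
languages — plus a soundness property on random programs (the complexity
of an emitted sequence never exceeds the emitting program's cost) and
invariance of `K` under the dihedral symmetries of the display.

## The atlas

`ComplexityAtlas.build` enumerates all `7! = 5040` no-revisit sequences
from a fixed origin and stores, per sequence: `K`, the complexity in the
no-`P` and single-level-repetition languages (`-1` when inexpressible —
without `P` no sequence containing a half-turn transition can be produced
at all), the derived resource flags (`uses_P`, `uses_nesting`: reaching
the sequence's minimal complexity requires the resource), and up to three
minimal witness programs in canonical notation.  Rows are lexicographic,
so prefix lookup is two binary searches.  `K` is invariant under rotation,
so a single origin-anchored table serves arbitrary starts.

## The predictor

Given a prefix of at least two locations, the model:

1. collects every atlas sequence consistent with the prefix (matched up to
   rotation; past position 8 the trial repeats the sequence, so candidates
   continue cyclically and shrink to one);
2. perturbs each candidate's effective complexity with i.i.d. Gaussian
   noise of standard deviation `sigma` (redrawn per response — the minimal
   reading of the selection rule; the same noisy sample is used for both
   the argmin and the capacity test);
3. follows the noisy-minimal candidate (exact ties break uniformly), if
   its noisy complexity is within the capacity `K_max = 12`; otherwise it
   guesses uniformly among the 7 vertices other than the current one
   (guessing over all 8 would allow predicting a stay, which no stimulus
   contains; a configuration switch exposes the alternative);
4. with probability `sigma2` the response is overwritten by such a guess
   (an execution error).

Limited languages are modeled per run: two Bernoulli draws (`p_nest`,
`p_p`) decide whether nested repetitions and the instruction `P` are
available.  By default a sequence whose flags conflict with the run's
resources has its effective complexity set to `K_max` — the capping
shortcut, motivated by the fact that the restricted language cannot even
express every sequence.  An alternative mode (`restricted_k=True`) uses
the true restricted-language complexity where it is finite.

Prefixes that leave the no-revisit hypothesis space — which happens only
in the 2- and 4-location span-control stimuli once a location repeats —
have an empty candidate set; the simulator treats them as over-capacity
(chance responses).  Those families are excluded from all fits anyway:
fitting uses the eight shared full-span families only.

## Protocols and the synthetic cohort

A trial presents the 8-location sequence twice (16 positions).  Adults
guess every position from the 3rd on.  Children answer in two phases:
view 5 / guess 3 (ordinals 6–8), then re-view the first 3 and guess 5
(ordinals 12–16, conditioning only on the re-shown opening).  An error in
the task is immediately corrected and the sequence replays veridically, so
the model's conditioning prefix is always the true stream and each ordinal
is scored once; restarts need no further bookkeeping.  Passive preview
viewings are recorded on the trial but cannot change a memoryless model's
responses — the simulated preview experiment reproduces a null difference
by construction.

The adult battery holds 17 trials (2 repeat, 2 alternate, 2 2squares,
2 2arcs, 4 4segments spanning the four axes, 1 4diagonals, 1 2rectangles,
1 2crosses, 2 irregular); the child battery 14 (one exemplar per family,
alternate replaced by repeat+2, the span controls added, 4segments kept at
four).  A repeat trial always comes first; the rest shuffle.  Starts,
directions and axes randomize per subject under the constraint that each
instance keeps its family's nominal complexity — the constructor verifies
every instance against the search and repairs the one degenerate
combination (a distance-1 segment shifted along its own direction, which
would collapse into the plain progression).  Incompressible instances are
drawn uniformly from the 768; 4-point loops are drawn from the loops whose
cyclic encoding attains the 4-loop maximum (K = 9, 180 of 210 loops).

One cohort seed spawns independent per-subject streams
(`numpy.random.SeedSequence`), so tables are byte-reproducible and any
subject can be regenerated alone.

## Fitting

Curves are per-family per-position correct rates.  Fits minimize the mean
squared error between model and observed curves with equal weight on every
(family, position) cell over the eight shared families; the default
scoring window is all collected ordinals (3–16 as available under the
protocol), with the first-presentation window (3–8) available as an
option.  Grids default to `sigma ∈ {0, 0.5, …, 6}` and
`p ∈ {0, 0.1, …, 1}`, bracketing all presets.  Each grid point simulates a
fresh cohort of `n_runs = 300` model runs.  All grid points share one
simulation seed (common random numbers): grid comparisons are then not
blurred by independent Monte-Carlo noise, and the Bernoulli resource
draws couple monotonically in the probabilities — without this the
resource surface, which is genuinely shallow along `p_nest` in the
high-`p_nest` regime, lets sampling noise wander the argmin.  The
`flat_region` helper reports every grid point within a tolerance of the
minimum, because a near-flat surface is a finding, not a nuisance.

The reference baseline is the simplest possible fit: one constant
accuracy per family (8 parameters), against which the one-parameter model
is compared.  The ideal-observer chance curve for a guesser who avoids
visited locations is closed-form: expected error `1 − 1/(9 − p)` at
position `p ∈ 3..8` (50% at position 7, 0% at position 8).

Parameter-recovery checks in the test suite generate cohorts at known
parameters (`sigma ∈ {0,1,2,3}`; resource truths (0.14, 0.18) and
(0.54, 0.26) at `sigma = 3`) and require the argmin within one grid step;
the qualitative checks require a positive rank correlation of family
error with `K` and that a resource-free model fits resource-dependent
curves worse than the generating values.

## What the synthetic data does and does not emulate

The simulator reproduces the *structure* of the experiments: protocols,
battery composition, randomization, per-position discrete outcomes,
restart-and-correct bookkeeping, per-subject resource variability.  Its
subjects are the model itself, so passing recovery tests demonstrates
that the pipeline identifies the model's parameters from data of the
experiments' shape and size — not that the model is true of humans.
Human phenomena outside the model are absent by design: no rote memory
across presentations (the model is memoryless given the prefix, so its
irregular curves stay at chance in the second presentation), no learning
across trials, no reaction times, no lapses beyond the two noise
parameters.  Human percentages, human correlation coefficients and the
published MSE magnitudes against human curves are properties of human
data and are not reproduced here; only language-level quantities and
model-level contracts are.

## Numerical choices and problem sizes

Integer costs make all complexity comparisons exact; ties are explicit
everywhere (witness sets capped at 50 with deterministic ordering; fit
ties reported, never silently broken).  Gaussian noise ties occur with
probability zero for `sigma > 0` and are broken uniformly at `sigma = 0`.
Default problem sizes: the full 5040-sequence atlas builds in a few
seconds; cohorts of 300 runs per grid point (the fitted protocol size)
keep a full resource-grid scan around a minute on one core.  Degenerate
inputs fail loudly: sequences longer than 8, consecutive duplicates,
empty tables, constant error profiles (rank correlation flagged
undefined), inconsistent prefixes.

## Known limitations

* The octagon (8 vertices) is fixed; the language is not parameterized by
  polygon size.
* The exact instruction inventory of the original formal definition is
  reconstructed from its printed consequences; the closed-tour rule is
  the package's resolution of that constraint system, validated by the
  768-sequence discriminator rather than by the original source text.
* A small set of 4segments instances (constant −3-step zigzags along the
  oblique axes) is rotations-only expressible, so their *control-language*
  complexity is 5 rather than 16; the nominal full-language complexity 7
  holds for every instance.
* The capping shortcut makes a resource-restricted subject indifferent
  among all capped candidates rather than reasoning in its restricted
  language; the `restricted_k` mode softens but does not remove this.
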