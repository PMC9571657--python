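# Methods

This note records the modeling conventions behind `cannasym`: what the
rule systems assume, how geometry is encoded, what the synthetic generator
does and does not emulate, and where genuinely open design choices were
resolved.

## Trees, frames and angles

A partial florescence (PF) is encoded as a rooted ordered tree.  The root
is a stub of the main florescence axis (`kind="axis"`, order 0); flowers
are nodes whose `subtending_bract` marks their axillary origin, and whose
children are the proceeding-order branches.  A child's subtending bract is
a "next-higher-order bract" of its parent flower — the developmental
marker used by both rule systems.  Bracts of aborted branches are kept in
the tree and participate fully: the higher-order meristem exerted its
influence whether or not its flower matured (the 4-flowered cyme, whose
third-order flowers all abort while their tertiary bracts persist, is the
type case).

Every angular quantity lives in the local transverse frame of the flower
it concerns: 0° is adaxial (toward the subtending axis), angles increase
counter-clockwise viewed from the distal pole, so +90° is the flower's
left.  For thyrse pair members — paired first-order flowers under
conjoined primary bracts — the dorsoventral reference is the pair midline:
"dorsal" for such flowers means midline-ward, which is where their fused
secondary bracts and fertile thecae sit.

All packaged fixtures and all generator output use multiples of 45°.
Sums of unit influence vectors on that grid live in the ring
Z + Z·(√2/2) per component, so cancellation (an opposed dichasium) is
decided exactly, with no floating-point tolerance.  Continuous angles are
accepted through the same API with a 1e-9 snap; exactness is only promised
on the grid.

## The AF model

AF1 (preceding order) is 0 for a solitary or top flower and a unit
adaxial vector for every lateral flower; AF2 (proceeding order) is the
normalized resultant of unit vectors toward all flanking next-order
bracts, kept at zero when the branches offset exactly.

**Combination semantics.** SUM_AF is the number of transverse axes
(dorsoventral, mediolateral) on which AF1 *or* AF2 has a nonzero
component — an axis-indicator (L1-on-axes) combination rather than the
Euclidean norm of the vector sum.  Two consequences are deliberate:

1. A lateral monochasium (adaxial AF1, lateral AF2) scores 2, not √2.
2. When AF1 and AF2 are collinear and opposed — the trichasium case,
   where the three branch directions resolve to a net abaxial vector —
   their signed components cancel in the net vector, but the shared axis
   still counts once: an influence along an axis breaks the *orthogonal*
   mirror plane, never its own.  The trichasium-flanked primary flower is
   therefore predicted zygomorphic, matching its observed phenotype.

0 → actinomorphic, 1 → zygomorphic (the recorded `zygomorphy_axis` is the
loaded axis; the surviving mirror plane is the orthogonal one's
complement, i.e. the plane containing the loaded axis), 2 → asymmetric.

**Verification oracle.** An independent brute-force check classifies a
flower by reflection invariance of its influence multiset.  Influences are
typed — the preceding-order attachment is not interchangeable with a
proceeding-order branch — and candidate mirror planes are the two
anatomical axes of the floral diagram (dorsoventral and mediolateral).
Diagonal planes are not candidates: a floral diagram's organ whorls admit
median or transverse mirror symmetry, and a configuration such as
{attachment at 0°, branch at 90°}, though geometrically mirror-symmetric
about the 45° diagonal, belongs to the normal cincinnus flower, which is
asymmetric.  With these conventions the oracle and the AF classifier agree
on every topology the generator emits; the equivalence is enforced by a
property test over 10⁴ random trees and would fail the suite on any
divergence.  The equivalence is a theorem only over the emitted typology:
a hand-built influence set with a single opposite-diagonal pair (e.g.
branches at 45° and 225°) would sum to zero while being invariant about
neither anatomical axis, and the two classifiers would part ways.  No
observed or generated partial florescence has that form.

## The androecial petaloidy rule

Flanking bract count → theca count: 0 → 2, 1 → 1, 2 or 3 → 0.  More than
three flanking bracts is outside the observed typology and raises an
explicit out-of-model error rather than extrapolating.  With exactly one
flanking bract the appendage develops on the half of the dorsal stamen
distal to the bract and the theca on the proximal half; the appendage side
is reported as left/right by the mediolateral sign of the distal
direction, or as adaxial/abaxial when the bract lies exactly on the
dorsoventral axis (a placement the API admits even though the packaged
thyrse transcriptions use the midline-ward diagonal, see below).

Merosity (sepal/petal/locule counts) and style form are observed
covariates: the rule system does not predict them and the predictor leaves
those fields unset.

## Fixture transcription conventions

The 16 aberrant records and 2 normal-type cincinni are transcribed from
diagrammatic descriptions, discretized to 45° sectors.  Interpretive
placements are flagged in each record's annotations; the notable ones:

- 1-flowered cymes: the "more abaxial" secondary-bract pair sits at
  ±135°, the "more adaxial" pair at ±45°.
- Thyrse members: each pair member carries one secondary bract at the
  midline-ward diagonal (45°/315° in the member frames, mirror-symmetric),
  where the fused bract pair meets.  This reproduces the described
  geometry — thecae adjacent to the midline, appendages distal — and the
  observed *asymmetry* of thyrse primary flowers (a bract exactly on the
  dv axis would instead predict zygomorphy).
- Secondary flowers' continuation (tertiary) bracts sit at the
  abaxial-lateral diagonal opposite their birth side (225° for a
  left-hand secondary, 135° for a right-hand one), which makes
  left/right secondaries exact mirror images, as described.
- The conjoined-flower complex (2-flowered thyrse) has only complex-level
  perianth counts (4 shared sepals, 7 shared petals); per-flower merosity
  fields are left unset and the shared counts live in annotations.
- One supernumerary fertile stamen (a transformed inner staminode in the
  left secondary flower of one 3-flowered cyme) has no home in the rule
  system; it is carried as an annotation plus a per-flower
  `rule_exception` flag, which the concordance stage reports rather than
  scoring.

## Concordance

Per mature observed flower, three comparisons: theca count, appendage
orientation (only when a half-fertile stamen is predicted; otherwise
n/a), and symmetry class.  Observed `intermediate` symmetry — one theca
with appendages on both sides, a transition stage — is a third outcome,
never folded into match or mismatch.  A theca mismatch in which the
observed count exceeds the prediction of a multi-flanked flower is
flagged a *timing deviation* (see the delay mechanism).  Aggregation is
purely descriptive counting per PF class, at both flower and record
granularity; no hypothesis test is computed because none is meaningful at
n = 16.

## Synthetic generator

`GeneratorConfig` defaults define the study conditions:

| parameter | default | meaning |
|-----------|---------|---------|
| `p_continue` | 0.4 | a cincinnus flower initiates its next order (cincinni mostly bear 1–2 flowers) |
| `p_dichasium` | 0.2 | dichasial first order (cyme typology) |
| `p_trichasium` | 0.05 | trichasial first order |
| `p_thyrse` | 0.1 | paired first order under conjoined bracts |
| `p_dextrorse` | 0.01 | right-handed cincinnus (observed frequency < 1%) |
| `p_delay` | 0.0 | developmental-delay noise (off by default) |
| `max_depth` | 4 | cincinnus chain cap |

Aberrant classes are deliberately oversampled: in the field, aberrant
partial florescences occur at well under 1%, which would leave most
simulated batches without a single cyme or thyrse.  The generator's job is
to exercise the pipeline, not to emulate prevalence.

One RNG stream (`random.Random(seed)`) is consumed in documented pre-order
draw order — handedness, PF form, then per-flower continuation decisions —
so one seed reproduces one record exactly within this implementation;
bit-equality across implementations is not promised.

Simplifications to know about: a generated monochasial chain terminates
*without* a continuation bract (so chain-terminal flowers come out
two-thecate and zygomorphic), whereas real normal cincinni retain a
terminal continuation meristem; cyme secondaries and thyrse members never
extend beyond one continuation order, keeping mature counts within the
observed 1–4 range; merosity covariates are filled by stamen form
(trimerous for half-fertile, tetramerous/filamentous-styled for fully
petaloid, dimerous for the single-flower reduction), mimicking the
observed covariation without claiming a rule for it.  Passing tests on
generated data therefore demonstrate internal consistency of the rule
system under the encoded typology, not fidelity to field prevalence,
continuous bract geometry, or merosity determination.

**Delay mechanism.**  With probability `p_delay`, a multi-flanked flower
develops as if its later-initiated flanking branch — second in child
order, since dichasia emerge alternately rather than simultaneously —
were absent.  A delayed dichasium-flanked flower thus shows the
half-fertile asymmetric form, or (half of the time) the transitional
"intermediate" form with appendages on both sides: exactly the observed
deviation spectrum of 3-flowered-cyme primaries.  A delayed
trichasium-flanked flower keeps zero thecae (two bracts still flank it)
and is phenotypically silent in the theca channel.

**Rate recovery.**  `estimate_delay` is the fraction of *exactly
two-flanked* flowers whose observed theca count exceeds the prediction,
with a Wilson binomial interval.  Trichasium-flanked flowers are excluded
as uninformative (see above); among two-flanked flowers the deviation
indicator is Bernoulli(`p_delay`) by construction, so the estimator is
unbiased and the interval has nominal coverage.  With no eligible flower
the estimate is an explicit undefined sentinel.

## Numerical and procedural choices

- Exact sector arithmetic decides all cancellations; no tolerance is
  applied on the 45° grid.  Phenotype angular equality is exact on the
  grid (tolerance parameter available for off-grid use).
- Flower ids are root-relative child-index paths ("0/1/0"): stable,
  format-independent, order-significant.
- Conjoined bracts are two `BractPlacement` entries cross-referencing each
  other via `fused_with`, never one merged bract, so bract counts match
  organ-level descriptions.
- Canonical FDF serialization (sorted keys, integral angles as integers)
  makes write∘read and read∘write byte-stable identities; a JSON-Schema
  document shipped under `data/` states the contract, enforced by the
  structural validator in `cannasym.fixtures`.
- Classification never falls back silently: anything outside the typology
  returns an explicit `unclassified` label with a reason.

## Problem sizes

The property suites run at the sizes that make their guarantees
meaningful: oracle equivalence over 10⁴ generated topologies, mirror-image
prediction over 2×10³ trees, zero-noise concordance over 10³ records, and
delay recovery at 10⁴ records per rate (99% Wilson intervals).  The whole
test suite completes in well under a minute on one core.

## Known limitations

- The rule system is positional only: no weighting of influences by organ
  size, age or distance, and no continuous developmental timing — delay
  is a per-flower Bernoulli abstraction.
- Merosity changes (tetramerous whorls, supernumerary sepals) are
  observed but not predicted; no rule for them is encoded.
- Labellum identity among the inner staminodes and style laminarity are
  recorded covariates, not predictions.
- Phyllotaxis of the primary bracts along the main axis is reduced to
  handedness; the main axis itself is not grown.
- The fixture transcriptions inherit the diagrammatic precision of their
  source: sector placements marked interpretive should not be read as
  angular measurements.
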