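# cannasym

Inflorescence architecture and floral symmetry modeling for *Canna*
(Cannaceae).

*Canna* is one of the few angiosperm genera with truly asymmetric flowers.
The asymmetry is androecial: the single fertile stamen is only half
fertile, bearing one theca plus a laminar petaloid appendage, and which of
its halves stays fertile — indeed whether any theca forms at all — tracks
the flower's position in the branching system of the inflorescence.
`cannasym` implements that positional rule system as a tested library for
botanists and evo-devo modelers: it encodes partial-florescence branching
topologies (cincinni, aberrant cymes and thyrses), predicts per-flower
symmetry class and stamen form from topology alone, quantifies agreement
with transcribed observations of 16 aberrant collections from *C. indica*
and *C. glauca*, and simulates seeded synthetic partial florescences with a
developmental-delay noise mechanism.

## The model

Each flower sits in a local transverse frame (dorsoventral axis dv,
positive adaxial; mediolateral axis ml, positive left; for thyrse pair
members, dv points at the pair midline).  Two influence vectors act on it:

- **AF1**, from the preceding order: `AF1 = 0` for a solitary or top
  flower (the primordium arises vertically), a unit adaxial vector for
  every lateral (axillary) flower;
- **AF2**, from the proceeding order: the resultant of unit vectors toward
  all next-order branches (marked by their subtending bracts, whether or
  not the branch matured), normalized when nonzero — an opposed dichasium
  cancels exactly.

`SUM_AF` counts the transverse axes on which AF1 or AF2 carries a nonzero
component, and predicts

| SUM_AF | predicted symmetry |
|--------|--------------------|
| 0      | actinomorphic      |
| 1      | zygomorphic (mirror plane orthogonal to the loaded axis) |
| 2      | asymmetric         |

A brute-force mirror-plane oracle (reflection invariance of the typed
influence multiset about the anatomical axes) verifies the classifier on
every generated topology.

The **androecial petaloidy rule** reads the flanking next-higher-order
bracts of a flower: 0 bracts → a fully fertile two-theca stamen; 1 bract →
a half-fertile stamen whose petaloid appendage sits on the half *distal*
to the bract (the theca proximal); 2–3 bracts → a fully petaloid stamen,
no thecae.

## Worked example

```python
>>> from cannasym import get_collection, predict_all, floral_formula
>>> record = get_collection("Cg-7")          # the 4-flowered cyme
>>> for fid, p in sorted(predict_all(record.topology).items()):
...     print(fid, floral_formula(p))
0 Th0 PA:none Sym:zyg(dv)
0/0 Th1 PA:left Sym:asym
0/1 Th1 PA:right Sym:asym
0/2 Th1 PA:right Sym:asym
```

The trichasium-flanked primary flower (`0`) is predicted fully petaloid
(`Th0`) and zygomorphic about the dorsoventral plane — its three branch
influences (left, right, abaxial) resolve to a net abaxial pull that
leaves only the dv axis loaded.  Each secondary flower is an ordinary
monochasium member: one theca (`Th1`), appendage distal to its single
tertiary bract, asymmetric — the normal *Canna* phenotype.  All four
predictions agree with the transcribed observations of that collection.

The `examples/` directory holds one short narrative script per capability
(AF model cases, per-collection prediction, registry-wide concordance,
simulation with delay-rate recovery, SVG rendering); each prints the
numbers it computes and a line on what they mean.  A thin CLI wraps the
same functions:

```
cannasym list-fixtures
cannasym predict --builtin all --format csv
cannasym simulate --n 100 --seed 7 --p-delay 0.3 -o sims/
cannasym render --builtin Ci-8 -o Ci-8.svg
```

## Layout

- `cannasym.topology` — branching trees, bract placements, local frames,
  partial-florescence classification, validation
- `cannasym.morphology` — floral diagrams, reflection, mirror-image
  comparison, floral formulas
- `cannasym.symmetry` — AF vectors, SUM_AF, symmetry prediction, the
  mirror-plane oracle
- `cannasym.androecium` — the petaloidy rule and full per-flower prediction
- `cannasym.fixtures` — the FDF format and the builtin 18-record registry
- `cannasym.concordance` — prediction-vs-observation reports and summaries
- `cannasym.synthetic` — seeded generator, delay noise, rate recovery
- `cannasym.render`, `cannasym.cli` — SVG schemes and the command-line
  surface

See `docs/methods.md` for the modeling conventions, parameter defaults and
known limitations.
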