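"""Seeded generator of partial-florescence topologies and phenotypes.

The generator emulates the observed typology — single flowers, 1-4-flowered
cymes (dichasial or trichasial first order reverting to monochasial),
2-4-flowered thyrses with midline-ward fused secondary bracts, and normal
monochasial cincinni — with bract placements on the 45-degree sector grid,
handedness, and phenotypes produced by the prediction rules themselves.

An optional developmental-delay mechanism perturbs observations: with
probability ``p_delay`` a multi-flanked flower develops as if the
later-initiated flanking branch (second in child order) were absent,
reproducing the observed deviation spectrum in which a dichasium-flanked
primary flower shows a half-fertile, asymmetric — or transitional
"intermediate" — form instead of the fully petaloid zygomorphic one.

A single RNG stream is consumed in documented pre-order traversal order, so
a seed reproduces a record exactly within this implementation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

from scipy.stats import binomtest

from .androecium import predict_appendage_side, predict_flower_phenotype, predict_theca_count
from .fixtures import CollectionRecord
from .morphology import FloralPhenotype
from .symmetry import AsymmetryVector, af1, predict_symmetry, sum_af
from ._sector import vec_sum
from .topology import (
    ABORTED,
    BractPlacement,
    DEXTRORSE,
    FlorescenceNode,
    MATURE,
    SINISTRORSE,
    assign_ids,
    classify_partial_florescence,
    flanking_bracts,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults oversample the aberrant classes relative to their field
    frequency (which is far below 1%) so that every branch of the typology
    is exercised; p_dextrorse keeps the observed <1% frequency of
    right-handed cincinni; p_continue reflects cincinni bearing one or two
    flowers.  p_delay defaults to 0: observations equal predictions unless
    the timing mechanism is switched on.
    """

    p_continue: float = 0.4
    p_dichasium: float = 0.2
    p_trichasium: float = 0.05
    p_thyrse: float = 0.1
    p_dextrorse: float = 0.01
    p_delay: float = 0.0
    max_depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_continue", "p_dichasium", "p_trichasium", "p_thyrse", "p_dextrorse", "p_delay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_dichasium + self.p_trichasium + self.p_thyrse > 1.0 + 1e-12:
            raise ValueError("branching probabilities must sum to at most 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


def _flower(order: int, angle: float, status: str = MATURE, fused: Optional[str] = None) -> FlorescenceNode:
    return FlorescenceNode(
        kind="flower",
        order=order,
        subtending_bract=BractPlacement(order_index=order, angle_deg=angle, fused_with=fused),
        status=status,
    )


def _continuation_angle(sb_angle: float) -> float:
    """Tertiary-bract sector for a secondary flower, in its own frame.

    Cincinnus orders alternate sides; secondary flowers of cymes and
    thyrses carry their continuation bract at the abaxial-lateral diagonal
    opposite the side they were born on (mirror-symmetric between a
    left-hand and a right-hand secondary).
    """
    ml = vec_sum([sb_angle])[1]
    if ml > 0:  # born to the parent's left -> own continuation right-abaxial
        return 225.0
    if ml < 0:
        return 135.0
    return 90.0  # abaxial (ventral) secondary: lateral continuation


def generate_topology(config: GeneratorConfig, rng: Optional[random.Random] = None) -> FlorescenceNode:
    """One partial-florescence tree; deterministic given the config seed.

    Draw order (single stream): handedness, PF form, then per-flower
    continuation decisions in pre-order.
    """
    rng = random.Random(config.seed) if rng is None else rng
    hand = DEXTRORSE if rng.random() < config.p_dextrorse else SINISTRORSE
    s = 1.0 if hand == SINISTRORSE else -1.0

    def ang(a: float) -> float:
        """Reflect a sector angle for dextrorse handedness."""
        return a if s > 0 else (360.0 - a) % 360.0

    u = rng.random()
    root = FlorescenceNode(kind="axis", order=0, handedness=hand)

    if u < config.p_thyrse:
        # paired first-order flowers, conjoined primary bracts, midline-ward
        # fused secondary bracts; each member bears 0 or 1 secondary flower
        members = []
        for side_angle in (ang(45.0), ang(315.0)):
            member = _flower(1, 180.0)
            if rng.random() < config.p_continue:
                f2 = _flower(2, side_angle)
                f2.children.append(_flower(3, _continuation_angle(side_angle), status=ABORTED))
            else:
                f2 = _flower(2, side_angle, status=ABORTED)
            member.children.append(f2)
            members.append(member)
        root.children = members
        tree = assign_ids(root)
        # cross-reference the conjoined bracts
        tree.children[0].subtending_bract.fused_with = tree.children[1].id
        tree.children[1].subtending_bract.fused_with = tree.children[0].id
        tree.children[0].children[0].subtending_bract.fused_with = tree.children[1].children[0].id
        tree.children[1].children[0].subtending_bract.fused_with = tree.children[0].children[0].id
        return tree

    f1 = _flower(1, 180.0)
    root.children = [f1]
    if u < config.p_thyrse + config.p_dichasium + config.p_trichasium:
        if u < config.p_thyrse + config.p_dichasium:
            variant = rng.randrange(3)  # lateral / adaxial-lateral / abaxial-lateral
            sb_angles = [
                (ang(90.0), ang(270.0)),
                (ang(45.0), ang(315.0)),
                (ang(135.0), ang(225.0)),
            ][variant]
        else:
            sb_angles = (ang(90.0), ang(270.0), 180.0)
        for sb in sb_angles:
            if rng.random() < config.p_continue:
                f2 = _flower(2, sb)
                f2.children.append(_flower(3, _continuation_angle(sb), status=ABORTED))
            else:
                f2 = _flower(2, sb, status=ABORTED)
            f1.children.append(f2)
        return assign_ids(root)

    # monochasial chain (normal typology): each flower continues with
    # probability p_continue; a terminator bears no continuation bract
    current, depth = f1, 1
    side = ang(90.0)
    while depth < config.max_depth and rng.random() < config.p_continue:
        nxt = _flower(depth + 1, side)
        current.children.append(nxt)
        current, depth = nxt, depth + 1
        side = (360.0 - side) % 360.0  # cincinnus alternation
    return assign_ids(root)


def _fill_covariates(p: FloralPhenotype) -> FloralPhenotype:
    """Merosity/style covariates by stamen form, mimicking the observed pattern.

    Not part of the prediction rules: half-fertile flowers get the normal
    trimerous plan, fully petaloid ones the tetramerous/filamentous aberrant
    plan, fully fertile single-flower reductions the dimerous plan.
    """
    if p.theca_count == 1:
        return replace(p, sepal_count=3, petal_count=3, locule_count=3, style_form="laminar")
    if p.theca_count == 0:
        return replace(p, sepal_count=4, petal_count=4, locule_count=4, style_form="filamentous")
    return replace(p, sepal_count=2, petal_count=2, locule_count=2, style_form="laminar")


def _delayed_phenotype(
    tree: FlorescenceNode, flower_id: str, intermediate: bool
) -> FloralPhenotype:
    """Phenotype developed as if the later-initiated flanking branch were absent."""
    node = tree.find(flower_id)
    bracted = [c for c in node.children if c.subtending_bract is not None]
    remaining = [c.subtending_bract for i, c in enumerate(bracted) if i != 1]
    theca = predict_theca_count(remaining)
    a2_angles = [b.angle_deg for b in remaining]
    dv, ml = vec_sum(a2_angles)
    norm = (dv * dv + ml * ml) ** 0.5
    a2 = (
        AsymmetryVector(dv=dv / norm, ml=ml / norm, source="AF2")
        if norm > 1e-9
        else AsymmetryVector(dv=0.0, ml=0.0, source="AF2")
    )
    symmetry, axis = predict_symmetry(sum_af(af1(tree, flower_id), a2))
    if theca == 1 and intermediate:
        # partial delay: the late branch still suppresses its half a little —
        # one theca with appendages on both sides, the transition stage
        return _fill_covariates(
            FloralPhenotype(theca_count=1, appendage_side="both", symmetry="intermediate")
        )
    side = predict_appendage_side(remaining) if theca == 1 else "none"
    return _fill_covariates(
        FloralPhenotype(theca_count=theca, appendage_side=side, symmetry=symmetry, zygomorphy_axis=axis)
    )


def generate_phenotypes(
    tree: FlorescenceNode, config: GeneratorConfig, rng: Optional[random.Random] = None
) -> CollectionRecord:
    """Rule-consistent observations for a tree, with optional delay noise.

    With ``p_delay = 0`` every observed phenotype equals the model
    prediction (plus filled-in merosity covariates).  With probability
    ``p_delay`` per multi-flanked flower, the flower develops as if its
    later-initiated flanking branch were absent; half of those deviants
    show the transitional both-sided-appendage form.  Deviated flowers are
    listed in the record annotations.
    """
    rng = random.Random(config.seed) if rng is None else rng
    observed: dict[str, FloralPhenotype] = {}
    delayed: list[str] = []
    for flower in tree.flowers(status=MATURE):  # pre-order
        if len(flanking_bracts(tree, flower.id)) >= 2 and rng.random() < config.p_delay:
            intermediate = rng.random() < 0.5
            observed[flower.id] = _delayed_phenotype(tree, flower.id, intermediate)
            delayed.append(flower.id)
        else:
            observed[flower.id] = _fill_covariates(predict_flower_phenotype(tree, flower.id))
    pf = classify_partial_florescence(tree)
    return CollectionRecord(
        id=f"synthetic-{config.seed}",
        species="Canna sp. (synthetic)",
        pf_class=pf.label,
        topology=tree,
        observed=observed,
        annotations={"synthetic": True, "delayed_flowers": delayed},
    )


def generate_record(config: GeneratorConfig, rng: Optional[random.Random] = None) -> CollectionRecord:
    """Topology plus phenotypes from one RNG stream."""
    rng = random.Random(config.seed) if rng is None else rng
    tree = generate_topology(config, rng)
    return generate_phenotypes(tree, config, rng)


def generate_records(config: GeneratorConfig, n: int) -> list[CollectionRecord]:
    """n records from a single stream seeded by config.seed; ids made unique."""
    rng = random.Random(config.seed)
    records = []
    for i in range(n):
        record = generate_record(config, rng)
        record.id = f"synthetic-{config.seed}-{i}"
        records.append(record)
    return records


@dataclass(frozen=True)
class DelayEstimate:
    """Recovered delay probability with a binomial (Wilson) confidence interval."""

    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_eligible: int
    n_deviated: int
    confidence: float = 0.95

    @property
    def defined(self) -> bool:
        return self.estimate is not None


def estimate_delay(records: list[CollectionRecord], confidence: float = 0.95) -> DelayEstimate:
    """Recover p_delay from the theca excess of dichasium-flanked flowers.

    Eligible flowers have exactly two flanking bracts: there the delay is
    phenotypically visible as an observed theca count exceeding the
    prediction (1 vs 0); with three flanking bracts, removing one branch
    leaves the stamen fully petaloid, so such flowers carry no signal and
    are excluded.  With no eligible flower the estimate is undefined
    (None fields).
    """
    n = k = 0
    for record in records:
        for flower in record.topology.flowers(status=MATURE):
            if len(flanking_bracts(record.topology, flower.id)) != 2:
                continue
            obs = record.observed.get(flower.id)
            if obs is None or obs.theca_count is None:
                continue
            pred = predict_theca_count(flanking_bracts(record.topology, flower.id))
            n += 1
            if obs.theca_count > pred:
                k += 1
    if n == 0:
        return DelayEstimate(None, None, None, 0, 0, confidence)
    ci = binomtest(k, n).proportion_ci(confidence_level=confidence, method="wilson")
    return DelayEstimate(k / n, ci.low, ci.high, n, k, confidence)
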