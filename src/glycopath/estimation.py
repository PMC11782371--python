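"""Glycan presence estimation and TPM-threshold calibration.

Presence is a three-state call derived from reachability through the scored
reaction network: a structure is *present* when some root-to-structure path
uses only expressed reactions, *rare* when every usable path passes through
at least one limited (or unknown) reaction but none that is absent, and
*absent* otherwise.  Formally each structure receives the best (max over
paths) bottleneck (min over path edges) of the edge ranks
expressed=2 > limited=unknown=1 > absent=0; roots are always present.

Threshold calibration sweeps candidate TPM cutoffs against binary
presence/absence labels via a ROC curve: AUC by trapezoidal integration
(exactly the Mann-Whitney concordance under the midpoint sweep used here),
with the operating threshold picked by Youden's J (sensitivity +
specificity - 1) or the F1 score (harmonic mean of precision and
sensitivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .expression_io import generate_synthetic_expression
from .pathway_model import Pathway
from .scoring import (
    AggregationPolicy,
    DEFAULT_POLICY,
    ReactionState,
    score_requirement,
)

__all__ = [
    "PRESENCE_ORDER",
    "estimate_structures",
    "structure_bottleneck_scores",
    "RocPoint",
    "RocResult",
    "roc_curve",
    "optimal_threshold",
    "calibrate_on_synthetic",
]

#: Ordering used by the monotone-repair property: present > rare > absent.
PRESENCE_ORDER = {"absent": 0, "rare": 1, "present": 2}

_EDGE_RANK = {"expressed": 2, "limited": 1, "unknown": 1, "absent": 0}
_CALL_BY_RANK = {2: "present", 1: "rare", 0: "absent"}


def _best_bottleneck(
    pathway: Pathway,
    edge_value: dict[str, float],
    root_value: float,
) -> dict[str, float]:
    """Max-over-paths min-over-edges propagation from the roots.

    Monotone fixpoint iteration; terminates on cyclic pathways as well
    because values only increase and are bounded by ``root_value``.
    """
    best = {
        sid: (root_value if s.is_root else -math.inf)
        for sid, s in pathway.structures.items()
    }
    reactions = sorted(pathway.reactions.values(), key=lambda r: r.id)
    changed = True
    while changed:
        changed = False
        for r in reactions:
            cand = min(best[r.substrate_id], edge_value[r.id])
            if cand > best[r.product_id]:
                best[r.product_id] = cand
                changed = True
    return best


def estimate_structures(
    pathway: Pathway, states: dict[str, ReactionState]
) -> dict[str, str]:
    """Three-state presence call per structure id.

    ``states`` must cover every reaction of the pathway.
    """
    missing = sorted(set(pathway.reactions) - set(states))
    if missing:
        raise KeyError(f"no reaction state for {missing}")
    ranks = {rid: float(_EDGE_RANK[states[rid].klass]) for rid in pathway.reactions}
    best = _best_bottleneck(pathway, ranks, root_value=2.0)
    return {
        sid: _CALL_BY_RANK[max(0, int(best[sid]))] if best[sid] > -math.inf
        else "absent"
        for sid in sorted(pathway.structures)
    }


def structure_bottleneck_scores(
    pathway: Pathway, reaction_scores: dict[str, float]
) -> dict[str, float]:
    """Continuous analogue of the presence call: per-structure best
    bottleneck TPM score over all paths from the roots.

    Roots get ``+inf`` (they need no reaction); unreachable structures get
    0.  A structure is "present" at TPM threshold ``t`` exactly when its
    bottleneck score is >= ``t``, which is what threshold calibration
    sweeps.
    """
    values = {rid: float(reaction_scores.get(rid, 0.0)) for rid in pathway.reactions}
    best = _best_bottleneck(pathway, values, root_value=math.inf)
    return {
        sid: (best[sid] if best[sid] > -math.inf else 0.0)
        for sid in sorted(pathway.structures)
    }


# ---------------------------------------------------------------------------
# ROC / threshold calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float
    precision: float
    youden_j: float
    f1: float


@dataclass(frozen=True)
class RocResult:
    points: tuple[RocPoint, ...]
    auc: float
    best_youden_threshold: float
    best_f1_threshold: float


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC over the threshold sweep "predict positive iff score >= t".

    Thresholds are the midpoints between consecutive distinct sorted scores
    plus -inf/+inf sentinels, which makes the sweep exhaustive for every
    step-function metric and handles ties.  The AUC is accumulated from
    integer confusion counts, so it equals the Mann-Whitney concordance
    ``(#(pos > neg) + 0.5 #(ties)) / (n_pos * n_neg)`` exactly.

    Precision at thresholds with no positive prediction is reported as 1.0
    (no false positives); the F1 there is 0.
    """
    scores = [float(s) for s in scores]
    labels = [int(l) for l in labels]
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if len(scores) < 2:
        raise ValueError("need at least two observations")
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present (AUC undefined)")

    distinct = sorted(set(scores))
    thresholds = (
        [-math.inf]
        + [(a + b) / 2.0 for a, b in zip(distinct, distinct[1:])]
        + [math.inf]
    )

    points: list[RocPoint] = []
    counts: list[tuple[int, int]] = []  # (tp, fp) per threshold
    for t in thresholds:
        tp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 0)
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos
        spec = tn / n_neg
        prec = tp / (tp + fp) if (tp + fp) > 0 else 1.0
        f1 = (2 * prec * sens / (prec + sens)) if tp > 0 else 0.0
        points.append(RocPoint(t, sens, spec, prec, sens + spec - 1.0, f1))
        counts.append((tp, fp))

    # trapezoid over (FPR, TPR) accumulated on integer counts: equals the
    # Mann-Whitney U statistic divided by n_pos * n_neg
    acc = 0
    for (tp0, fp0), (tp1, fp1) in zip(counts, counts[1:]):
        acc += (fp0 - fp1) * (tp0 + tp1)
    auc = acc / (2 * n_pos * n_neg)

    result = RocResult(
        points=tuple(points),
        auc=auc,
        best_youden_threshold=_argmax_threshold(points, "youden_j"),
        best_f1_threshold=_argmax_threshold(points, "f1"),
    )
    return result


def _argmax_threshold(points: Sequence[RocPoint], attr: str) -> float:
    best = points[0]
    for pt in points[1:]:
        if getattr(pt, attr) > getattr(best, attr):  # ties keep the smaller t
            best = pt
    return best.threshold


def optimal_threshold(roc: RocResult, criterion: str = "youden") -> float:
    """Threshold maximizing Youden's J or F1; ties go to the smallest."""
    if criterion == "youden":
        return _argmax_threshold(roc.points, "youden_j")
    if criterion == "f1":
        return _argmax_threshold(roc.points, "f1")
    raise ValueError(f"criterion must be 'youden' or 'f1', got {criterion!r}")


def calibrate_on_synthetic(
    pathway: Pathway,
    n_samples: int,
    true_threshold: float = 1.0,
    label_noise: float = 0.0,
    seed: int = 0,
    active_fraction: float = 0.8,
    lognormal_params: tuple[float, float] = (2.0, 1.0),
    policy: AggregationPolicy = DEFAULT_POLICY,
) -> RocResult:
    """End-to-end threshold-recovery harness on synthetic expression.

    Draws ``n_samples`` random profiles over the pathway's gene universe,
    derives the ground-truth presence of every non-root structure at
    ``true_threshold`` (bottleneck score >= threshold), flips each label
    independently with probability ``label_noise``, and returns the ROC of
    the continuous bottleneck scores against the noisy labels.  With zero
    noise the sweep recovers the generating threshold (the midpoint of the
    empty score interval containing it) and the AUC is 1.  Deterministic
    per seed.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if not 0.0 <= label_noise < 0.5:
        raise ValueError("label_noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    genes = pathway.genes
    non_roots = [sid for sid in sorted(pathway.structures)
                 if not pathway.structures[sid].is_root]

    all_scores: list[float] = []
    all_labels: list[int] = []
    for _ in range(n_samples):
        profile = generate_synthetic_expression(
            genes,
            seed=int(rng.integers(0, 2**31)),
            active_fraction=active_fraction,
            lognormal_params=lognormal_params,
        )
        rscores = {
            r.id: (
                0.0 if r.requirement is None
                else score_requirement(r.requirement, profile, policy)
            )
            for r in pathway.reactions.values()
        }
        bottleneck = structure_bottleneck_scores(pathway, rscores)
        for sid in non_roots:
            score = bottleneck[sid]
            label = 1 if score >= true_threshold else 0
            if label_noise > 0 and rng.random() < label_noise:
                label = 1 - label
            all_scores.append(score)
            all_labels.append(label)
    return roc_curve(all_scores, all_labels)
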