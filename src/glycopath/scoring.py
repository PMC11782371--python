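"""Per-reaction expression scores, classes, arrow styling and comparisons.

A reaction's score is the aggregated TPM of its gene requirement: by
default the *maximum* across isoenzyme alternatives (OR) and the *minimum*
across obligate complex subunits (AND); both rules can be switched to
mean/min/max.  Scores are classified against a TPM threshold (default 1):
at or above the threshold a reaction is "expressed" (black arrow, width
scaling with expression), between the noise floor and the threshold it is
"limited" (red), at or below the floor it is "absent" (pink).  Reactions
with an unidentified gene are "unknown" (gray).

Two-sample comparison works on reaction scores after aggregation, so an
isoenzyme switch (gene A down, gene B up) is reported as the net reaction
change.  Fold changes use a pseudocount so that silent reactions do not
produce infinite folds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from statistics import fmean
from typing import Optional

from .expression_io import ExpressionProfile
from .pathway_model import And, Gene, Or, Pathway, Requirement

__all__ = [
    "AggregationPolicy",
    "DEFAULT_POLICY",
    "DEFAULT_TPM_THRESHOLD",
    "DEFAULT_FLOOR",
    "DEFAULT_FOLD_THRESHOLD",
    "DEFAULT_EPSILON",
    "ReactionState",
    "ComparisonState",
    "score_requirement",
    "classify_reaction",
    "arrow_width",
    "score_pathway",
    "compare_profiles",
    "states_to_json",
    "states_to_tsv",
]

#: Default classification threshold: TPM = 1 for a gene required in a step.
DEFAULT_TPM_THRESHOLD = 1.0
#: Scores at or below this are classified "absent"; sub-0.1 TPM is noise.
DEFAULT_FLOOR = 0.1
#: Comparison highlight boundary: more than double / less than half.
DEFAULT_FOLD_THRESHOLD = 2.0
#: Pseudocount added to both scores when computing fold changes.
DEFAULT_EPSILON = 0.1

_RULES = {"max": max, "min": min, "mean": fmean}

CLASS_COLOR_NAMES = {
    "expressed": "black",
    "limited": "red",
    "absent": "pink",
    "unknown": "gray",
}


@dataclass(frozen=True)
class AggregationPolicy:
    """How to collapse a requirement tree to one score.

    ``or_rule`` applies across isoenzyme alternatives (default ``max``:
    the most expressed isoenzyme carries the reaction), ``and_rule`` across
    complex subunits (default ``min``: the scarcest subunit limits the
    complex).  Each rule is one of ``max`` / ``mean`` / ``min``.
    """

    or_rule: str = "max"
    and_rule: str = "min"

    def __post_init__(self) -> None:
        for rule in (self.or_rule, self.and_rule):
            if rule not in _RULES:
                raise ValueError(
                    f"aggregation rule must be one of {sorted(_RULES)}, got {rule!r}"
                )


DEFAULT_POLICY = AggregationPolicy()


@dataclass(frozen=True)
class ReactionState:
    """Scored reaction: class, arrow width (px) and color name."""

    reaction_id: str
    score: Optional[float]
    klass: str
    width: float
    color: str


@dataclass(frozen=True)
class ComparisonState:
    """Two-sample comparison of one reaction."""

    reaction_id: str
    score_a: Optional[float]
    score_b: Optional[float]
    fold: Optional[float]
    status: str


def score_requirement(
    req: Requirement,
    profile: ExpressionProfile,
    policy: AggregationPolicy = DEFAULT_POLICY,
) -> float:
    """Evaluate a requirement tree against a profile.

    Leaves evaluate to the gene's TPM (0 when missing from the profile); OR
    nodes combine children with ``policy.or_rule`` and AND nodes with
    ``policy.and_rule``, recursively.
    """
    if isinstance(req, Gene):
        return profile.get(req.symbol)
    children = [score_requirement(c, profile, policy) for c in req.children]
    rule = policy.or_rule if isinstance(req, Or) else policy.and_rule
    return float(_RULES[rule](children))


def classify_reaction(
    score: float,
    threshold: float = DEFAULT_TPM_THRESHOLD,
    floor: float = DEFAULT_FLOOR,
) -> str:
    """Classify a score as ``expressed`` / ``limited`` / ``absent``."""
    if not threshold > floor >= 0:
        raise ValueError(f"need threshold > floor >= 0, got {threshold}, {floor}")
    if score >= threshold:
        return "expressed"
    if score > floor:
        return "limited"
    return "absent"


def arrow_width(score: float, threshold: float = DEFAULT_TPM_THRESHOLD) -> float:
    """Arrow width (px) for an expressed reaction.

    ``1.0 + 1.5 * log10(score / threshold + 1)`` capped at 8.0 — strictly
    increasing in score up to the cap, equals ~1.45 px right at the
    threshold.
    """
    if score < threshold:
        raise ValueError("arrow_width applies only to expressed reactions")
    return min(8.0, 1.0 + 1.5 * math.log10(score / threshold + 1.0))


_BASE_WIDTH = 1.0  # width used for limited/absent/unknown arrows


def score_pathway(
    pathway: Pathway,
    profile: ExpressionProfile,
    policy: AggregationPolicy = DEFAULT_POLICY,
    threshold: float = DEFAULT_TPM_THRESHOLD,
    floor: float = DEFAULT_FLOOR,
) -> dict[str, ReactionState]:
    """Score and classify every reaction of a pathway.

    Reactions with an unidentified gene get class ``unknown`` and no score.
    """
    out: dict[str, ReactionState] = {}
    for rid in sorted(pathway.reactions):
        reaction = pathway.reactions[rid]
        if reaction.requirement is None:
            out[rid] = ReactionState(rid, None, "unknown", _BASE_WIDTH, "gray")
            continue
        score = score_requirement(reaction.requirement, profile, policy)
        klass = classify_reaction(score, threshold, floor)
        width = arrow_width(score, threshold) if klass == "expressed" else _BASE_WIDTH
        out[rid] = ReactionState(rid, score, klass, width, CLASS_COLOR_NAMES[klass])
    return out


def compare_profiles(
    pathway: Pathway,
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    policy: AggregationPolicy = DEFAULT_POLICY,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    epsilon: float = DEFAULT_EPSILON,
) -> dict[str, ComparisonState]:
    """Per-reaction fold change of sample B over sample A.

    ``fold = (score_b + epsilon) / (score_a + epsilon)``; a reaction is
    ``increased`` when ``fold > fold_threshold``, ``decreased`` when
    ``fold < 1 / fold_threshold`` and ``unchanged`` otherwise.  Reactions
    whose gene is unknown, or whose score is below the resolution floor
    ``epsilon`` in *both* samples, are ``undefined``.
    """
    if not fold_threshold > 1:
        raise ValueError("fold_threshold must be > 1")
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    out: dict[str, ComparisonState] = {}
    for rid in sorted(pathway.reactions):
        reaction = pathway.reactions[rid]
        if reaction.requirement is None:
            out[rid] = ComparisonState(rid, None, None, None, "undefined")
            continue
        sa = score_requirement(reaction.requirement, profile_a, policy)
        sb = score_requirement(reaction.requirement, profile_b, policy)
        fold = (sb + epsilon) / (sa + epsilon)
        if sa < epsilon and sb < epsilon:
            status = "undefined"
        elif fold > fold_threshold:
            status = "increased"
        elif fold < 1.0 / fold_threshold:
            status = "decreased"
        else:
            status = "unchanged"
        out[rid] = ComparisonState(rid, sa, sb, fold, status)
    return out


def states_to_json(states: dict[str, ReactionState] | dict[str, ComparisonState]) -> str:
    """JSON array of state records, sorted by reaction id."""
    records = [asdict(states[rid]) for rid in sorted(states)]
    return json.dumps(records, indent=1, sort_keys=True)


def states_to_tsv(states: dict[str, ReactionState] | dict[str, ComparisonState]) -> str:
    """Flat TSV of state records for spreadsheets."""
    ids = sorted(states)
    if not ids:
        return ""
    fields = list(asdict(states[ids[0]]).keys())
    lines = ["\t".join(fields)]
    for rid in ids:
        record = asdict(states[rid])
        lines.append("\t".join(
            "" if record[f] is None else
            (f"{record[f]:.6g}" if isinstance(record[f], float) else str(record[f]))
            for f in fields
        ))
    return "\n".join(lines) + "\n"
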