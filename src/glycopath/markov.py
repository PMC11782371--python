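"""Quantitative glycan-profile estimation via an absorbing Markov chain.

A scored pathway is converted into an absorbing Markov chain over glycan
structures: a glycan in progress hops from structure to structure along
reactions, choosing among the outgoing reactions of its current structure
with probability proportional to their expression scores (the minimal law
consistent with expression-weighted flux; proteins carriers, compartments
and sugar-nucleotide pools are deliberately omitted).  Terminal structures
— and structures whose every outgoing reaction is silent — absorb.  An
optional ``exit_weight`` adds, at every transient structure, a constant-
weight escape to a synthetic absorbing state ``exited@<id>`` modelling
premature secretion/transport.

With transient-to-transient block Q and transient-to-absorbing block R, the
fundamental matrix N = (I - Q)^-1 gives expected visit counts and B = N R
the absorption probabilities; both are obtained from linear solves rather
than explicit inversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .expression_io import ExpressionProfile
from .pathway_model import Pathway
from .scoring import (
    AggregationPolicy,
    DEFAULT_FLOOR,
    DEFAULT_POLICY,
    DEFAULT_TPM_THRESHOLD,
    ReactionState,
    score_pathway,
)

__all__ = [
    "MarkovModel",
    "MarkovError",
    "build_markov",
    "absorption_distribution",
    "expected_visits",
    "knockdown_scan",
    "profile_report",
]

logger = logging.getLogger(__name__)

_COND_WARN = 1e10


class MarkovError(ValueError):
    """Chain construction or solve failure."""


@dataclass
class MarkovModel:
    """Absorbing chain: ordered state lists plus the Q and R blocks.

    ``Q[i, j]`` is the one-step probability transient i -> transient j,
    ``R[i, k]`` transient i -> absorbing k; every row of [Q | R] sums to 1.
    ``source`` is the structure where synthesis starts.
    """

    transient_states: list[str]
    absorbing_states: list[str]
    Q: np.ndarray
    R: np.ndarray
    source: str

    def row_sums(self) -> np.ndarray:
        return self.Q.sum(axis=1) + self.R.sum(axis=1)


def build_markov(
    pathway: Pathway,
    states: dict[str, ReactionState],
    exit_weight: float = 0.0,
    source: str | None = None,
) -> MarkovModel:
    """Convert a scored pathway into an absorbing Markov chain.

    Absorbing states are the terminal structures plus every structure whose
    outgoing reactions all score zero when ``exit_weight`` is zero (such
    dead ends are converted, with a logged warning, rather than rejected:
    real expression data silences branches and product then accumulates
    there).  Unknown-requirement reactions score 0.  For transient state i
    with outgoing scores ``s_ij``, ``p_ij = s_ij / (sum_j s_ij +
    exit_weight)``; any remainder goes to the synthetic absorbing state
    ``exited@i``.
    """
    if exit_weight < 0:
        raise ValueError("exit_weight must be >= 0")
    missing = sorted(set(pathway.reactions) - set(states))
    if missing:
        raise KeyError(f"no reaction state for {missing}")

    def rscore(rid: str) -> float:
        st = states[rid]
        if st.klass == "unknown" or st.score is None:
            return 0.0
        return max(0.0, float(st.score))

    outgoing: dict[str, list[tuple[str, float]]] = {
        sid: [] for sid in pathway.structures
    }
    for rid in sorted(pathway.reactions):
        r = pathway.reactions[rid]
        outgoing[r.substrate_id].append((r.product_id, rscore(rid)))

    absorbing: set[str] = {
        sid for sid, s in pathway.structures.items() if s.is_terminal
    }
    for sid in sorted(pathway.structures):
        if sid in absorbing:
            continue
        total = sum(score for _, score in outgoing[sid])
        if not outgoing[sid] or (total <= 0.0 and exit_weight == 0.0):
            if outgoing[sid]:
                logger.warning(
                    "structure %s has no expressed outgoing reaction; "
                    "converted to absorbing", sid,
                )
            absorbing.add(sid)

    transient = [sid for sid in sorted(pathway.structures) if sid not in absorbing]
    absorbing_list = sorted(absorbing)
    if exit_weight > 0:
        absorbing_list += [f"exited@{sid}" for sid in transient]
    if not absorbing_list:
        raise MarkovError("no absorbing state derivable from this pathway")

    t_index = {sid: i for i, sid in enumerate(transient)}
    a_index = {sid: i for i, sid in enumerate(absorbing_list)}
    Q = np.zeros((len(transient), len(transient)))
    R = np.zeros((len(transient), len(absorbing_list)))
    for sid in transient:
        i = t_index[sid]
        total = sum(score for _, score in outgoing[sid]) + exit_weight
        for product, score in outgoing[sid]:
            if score <= 0.0:
                continue
            p = score / total
            if product in t_index:
                Q[i, t_index[product]] += p
            else:
                R[i, a_index[product]] += p
        if exit_weight > 0:
            R[i, a_index[f"exited@{sid}"]] += exit_weight / total
        norm = Q[i].sum() + R[i].sum()
        if norm > 0:  # renormalize to machine precision
            Q[i] /= norm
            R[i] /= norm

    roots = pathway.roots
    if source is None:
        if not roots:
            raise MarkovError("pathway has no root to use as chain source")
        source = roots[0]
    if source not in pathway.structures:
        raise MarkovError(f"source {source!r} is not a structure of the pathway")
    return MarkovModel(
        transient_states=transient,
        absorbing_states=absorbing_list,
        Q=Q,
        R=R,
        source=source,
    )


def _trapped_states(m: MarkovModel) -> list[str]:
    """Transient states from which no absorbing state is reachable."""
    n = len(m.transient_states)
    can_exit = (m.R.sum(axis=1) > 0.0)
    adj = m.Q > 0.0
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if not can_exit[i] and np.any(adj[i] & can_exit):
                can_exit[i] = True
                changed = True
    return [sid for i, sid in enumerate(m.transient_states) if not can_exit[i]]


def _source_row_of_fundamental(m: MarkovModel) -> np.ndarray:
    """Row of N = (I - Q)^-1 for the source state, via a linear solve."""
    trapped = _trapped_states(m)
    if trapped:
        raise MarkovError(
            "transient component cannot reach absorption (singular I - Q); "
            f"trapped states: {trapped}"
        )
    n = len(m.transient_states)
    ImQ = np.eye(n) - m.Q
    if n > 0:
        cond = np.linalg.cond(ImQ)
        if cond > _COND_WARN:
            logger.warning("I - Q is ill-conditioned (cond=%.3g)", cond)
    e = np.zeros(n)
    e[m.transient_states.index(m.source)] = 1.0
    try:
        return np.linalg.solve(ImQ.T, e)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise MarkovError(f"singular I - Q: {exc}") from exc


def absorption_distribution(m: MarkovModel) -> dict[str, float]:
    """Probability of ending in each absorbing structure, starting from the
    source.  Masses sum to 1 (within numerical tolerance)."""
    if m.source in m.absorbing_states:
        return {
            sid: (1.0 if sid == m.source else 0.0) for sid in m.absorbing_states
        }
    if m.source not in m.transient_states:
        raise MarkovError(f"source {m.source!r} is not a state of the chain")
    visits = _source_row_of_fundamental(m)
    mass = visits @ m.R
    return {sid: float(mass[k]) for k, sid in enumerate(m.absorbing_states)}


def expected_visits(m: MarkovModel) -> dict[str, float]:
    """Expected number of visits to each transient structure before
    absorption (source row of the fundamental matrix)."""
    if m.source in m.absorbing_states:
        return {sid: 0.0 for sid in m.transient_states}
    visits = _source_row_of_fundamental(m)
    return {sid: float(visits[i]) for i, sid in enumerate(m.transient_states)}


def knockdown_scan(
    pathway: Pathway,
    profile: ExpressionProfile,
    gene: str,
    factors: list[float],
    policy: AggregationPolicy = DEFAULT_POLICY,
    threshold: float = DEFAULT_TPM_THRESHOLD,
    floor: float = DEFAULT_FLOOR,
    exit_weight: float = 0.0,
) -> list[dict[str, float]]:
    """Absorption profiles after scaling one gene's TPM by each factor.

    ``factors`` are fractions of the baseline expression in [0, 1]; a factor
    of 1 reproduces the baseline profile exactly.
    """
    gene = gene.upper()
    if gene not in profile.tpm:
        raise KeyError(
            f"gene {gene!r} is not in profile {profile.sample!r}"
        )
    results: list[dict[str, float]] = []
    for factor in factors:
        if not 0.0 <= factor <= 1.0:
            raise ValueError(f"knockdown factor must be in [0, 1], got {factor}")
        tpm = dict(profile.tpm)
        tpm[gene] = tpm[gene] * factor
        knocked = ExpressionProfile(sample=f"{profile.sample}:{gene}x{factor:g}", tpm=tpm)
        states = score_pathway(pathway, knocked, policy, threshold, floor)
        model = build_markov(pathway, states, exit_weight=exit_weight)
        results.append(absorption_distribution(model))
    return results


def profile_report(m: MarkovModel, exit_weight: float = 0.0) -> dict:
    """JSON-ready summary: absorption masses and expected visit counts."""
    return {
        "source": m.source,
        "exit_weight": exit_weight,
        "absorbing": absorption_distribution(m),
        "expected_visits": expected_visits(m),
    }
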