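"""Petri-net compilation and simulation of one regulatory model.

A :class:`~epinet.model_space.ModelSpec` is compiled into a small Petri
net: one place per node, one transition per activating edge (input arc
weight fixed to 1; output arc weight equal to the edge magnitude).
Simulation fires all enabled transitions synchronously for a fixed
number of steps (maximal parallel execution, enablement judged on the
pre-step marking); when simultaneous token demands exceed a place's
supply, enabled transitions are applied in randomly shuffled order and
unfundable ones are skipped — the sole source of stochasticity.

Token provisioning is regulator-centric.  A regulator starts with
``initial_tokens`` (its mRNA resource) unless the other regulator
activates it, in which case it starts empty and receives tokens through
that transition.  Genes always start empty and are driven only by their
activating inputs.

Inhibition edges carry no output arc; they act through inhibitor arcs:

* regulator-to-regulator inhibition leaves the target's token stock in
  place but *silences* it — the target's outgoing transitions are
  disabled while the inhibiting regulator holds tokens;
* any other inhibition (into a gene, or from a gene into a regulator)
  *gates* production into the target: transitions delivering tokens to
  the target are disabled while the inhibitor is active ("inhibition
  dominates" for mixed activator/inhibitor input pairs), and can
  additionally drain the target at the edge magnitude per step
  (``inhibitor_removal``).

A node *acts* only while it is active: a silenced regulator neither
fires its outgoing transitions nor represses its targets, even though it
holds tokens.  A gene whose only inputs are inhibitory receives basal
expression from a constitutive source (``initial_tokens / steps`` tokens
per step) gated by those inhibitors, so that repression and
de-repression are observable as expression changes.

The gate-versus-silence rule for gene-directed inhibition is pluggable
(:class:`InhibitionMode`) because the firing rules for inhibitor arcs
admit more than one Petri-net reading; the regulator-silencing rule for
regulator pairs is fixed, since it is what reproduces the behavior of
the minimal inversion motif.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable

import numpy as np

from .model_space import (
    GENES,
    Logic,
    ModelSpec,
    R1,
    R2,
    REGULATORS,
)

#: Deletion conditions in fixed order: wild type, R1d, R2d, double mutant.
CONDITIONS: tuple[frozenset, ...] = (
    frozenset(),
    frozenset({R1}),
    frozenset({R2}),
    frozenset({R1, R2}),
)
CONDITION_NAMES = ("WT", "R1d", "R2d", "R1dR2d")


class InhibitionMode(str, Enum):
    """Firing rule for inhibition edges other than regulator-regulator.

    ``GATE_TARGET`` (default): transitions producing into the inhibited
    node are disabled while the inhibitor holds tokens.

    ``SILENCE_TARGET``: the inhibited node's outgoing transitions are
    disabled instead, as for regulator-regulator inhibition.
    """

    GATE_TARGET = "gate_target"
    SILENCE_TARGET = "silence_target"


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``initial_tokens`` is the mRNA resource provided to regulators that
    are not activated by the other regulator.  ``pseudo_count`` is added
    to token counts before the log2 ratio to avoid division by zero.
    """

    initial_tokens: int = 200
    steps: int = 50
    runs: int = 5
    pseudo_count: int = 1
    strong_weight: int = 5
    seed: int = 0
    inhibition: InhibitionMode = InhibitionMode.GATE_TARGET
    inhibitor_removal: str = "all"
    genes_consume: bool = True

    def __post_init__(self) -> None:
        for name in ("initial_tokens", "steps", "runs", "pseudo_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.strong_weight not in (5, 9):
            raise ValueError("strong_weight must be 5 or 9")
        if self.inhibitor_removal not in ("none", "genes", "all"):
            raise ValueError("inhibitor_removal must be 'none', 'genes' or 'all'")

    @property
    def source_rate(self) -> int:
        """Basal production rate of inhibitor-only genes (tokens per step)."""
        return self.initial_tokens // self.steps

    def with_strong_weight(self, strong: int) -> "SimConfig":
        return replace(self, strong_weight=strong)


DEFAULT_CONFIG = SimConfig()


@dataclass(frozen=True)
class Transition:
    """One compiled transition.

    ``sources`` are input places (arc weight 1 each); ``consume`` lists
    the subset whose tokens are removed on firing.  ``gates`` is a tuple
    of ``(places, mode, test)`` groups: the transition is disabled when
    any group is on (``mode`` — ``"all"``: every place qualifies,
    ``"any"``: at least one does; ``test`` — ``"tokens"``: a place
    qualifies by holding a token, ``"active"``: by holding a token while
    not silenced).  ``target`` is ``None`` when the output arc was
    removed by deletion surgery.
    """

    sources: tuple[int, ...]
    target: int | None
    delta: int
    consume: tuple[int, ...] = ()
    gates: tuple[tuple[tuple[int, ...], str, str], ...] = ()


@dataclass
class PetriNet:
    """A compiled net: transitions, removal rules, initial marking.

    ``silencers[x]`` is the regulator that silences node ``x`` (or
    ``None``); a place is *active* when it holds a token and is not
    silenced.
    """

    spec: ModelSpec
    deleted: frozenset
    transitions: list[Transition]
    removals: list[tuple[tuple[int, ...], str, int, int]]  # (triggers, mode, target, w)
    initial_marking: np.ndarray
    silencers: tuple[int | None, int | None, int | None, int | None] = (None,) * 4


def _incoming(matrix: np.ndarray, node: int):
    col = matrix[:, node]
    activators = [(i, int(col[i])) for i in range(4) if col[i] > 0]
    inhibitors = [(i, int(-col[i])) for i in range(4) if col[i] < 0]
    return activators, inhibitors


def _regulator_silencer(matrix: np.ndarray, node: int) -> int | None:
    """The other regulator, when it inhibits ``node`` (a regulator)."""
    if node in REGULATORS and matrix[R1 + R2 - node, node] < 0:
        return R1 + R2 - node
    return None


def _generic_inhibitors(matrix: np.ndarray, node: int) -> list[tuple[int, int]]:
    """Inhibitors of ``node`` other than a regulator-regulator silencer."""
    _, inhibitors = _incoming(matrix, node)
    sil = _regulator_silencer(matrix, node)
    return [(i, w) for i, w in inhibitors if i != sil]


def _inhibitor_group(
    spec: ModelSpec, node: int, inhibitors: list[tuple[int, int]]
) -> tuple[tuple[int, ...], str, str] | None:
    if not inhibitors:
        return None
    places = tuple(i for i, _ in inhibitors)
    mode = "all" if (spec.logic[node] == Logic.AND and len(places) == 2) else "any"
    return (places, mode, "active")


def compile(
    spec: ModelSpec,
    condition: Iterable[int] | frozenset = frozenset(),
    config: SimConfig = DEFAULT_CONFIG,
) -> PetriNet:
    """Compile a model plus a deletion condition into a Petri net.

    Deletion surgery removes the deleted place's tokens and every output
    arc delivering tokens into it; transitions keep their input arcs, so
    a transition whose target was deleted still consumes from its
    sources.
    """
    deleted = frozenset(condition)
    if any(d in GENES for d in deleted):
        raise ValueError("only regulators (R1, R2) can be deleted")
    m = spec.matrix
    silence_all = config.inhibition is InhibitionMode.SILENCE_TARGET

    def silencer_gates(sources: tuple[int, ...]) -> list:
        groups = []
        for s in sources:
            sil = _regulator_silencer(m, s)
            if sil is not None:
                groups.append(((sil,), "any", "tokens"))
            if silence_all:
                g = _inhibitor_group(spec, s, _generic_inhibitors(m, s))
                if g is not None:
                    groups.append(g)
        return groups

    transitions: list[Transition] = []
    removals: list[tuple[tuple[int, ...], str, int, int]] = []
    for j in range(4):
        activators, _ = _incoming(m, j)
        generic = _generic_inhibitors(m, j)
        target = None if j in deleted else j

        target_gate = None
        if not silence_all:
            target_gate = _inhibitor_group(spec, j, generic)

        def gates_for(sources: tuple[int, ...]) -> tuple:
            groups = silencer_gates(sources)
            if target_gate is not None:
                groups.append(target_gate)
            return tuple(groups)

        def consume_of(sources: tuple[int, ...]) -> tuple[int, ...]:
            if config.genes_consume:
                return sources
            return tuple(s for s in sources if s in REGULATORS)

        if len(activators) == 2 and spec.logic[j] == Logic.AND:
            srcs = (activators[0][0], activators[1][0])
            transitions.append(
                Transition(srcs, target, activators[0][1], consume_of(srcs), gates_for(srcs))
            )
        else:
            for i, w in activators:
                transitions.append(
                    Transition((i,), target, w, consume_of((i,)), gates_for((i,)))
                )

        # basal expression for an inhibitor-only gene: a constitutive
        # source gated by the inhibitors, so repression is observable
        if j in GENES and j not in deleted and not activators and generic:
            gate = _inhibitor_group(spec, j, generic)
            transitions.append(
                Transition((), j, config.source_rate, (), (gate,))
            )

        removal_here = config.inhibitor_removal == "all" or (
            config.inhibitor_removal == "genes" and j in GENES
        )
        if removal_here and generic and j not in deleted:
            if spec.logic[j] == Logic.AND and len(generic) == 2:
                removals.append(
                    ((generic[0][0], generic[1][0]), "all", j, generic[0][1])
                )
            else:
                for i, w in generic:
                    removals.append(((i,), "any", j, w))

    marking = np.zeros(4, dtype=np.int64)
    for r in REGULATORS:
        if r not in deleted and m[R1 + R2 - r, r] <= 0:
            marking[r] = config.initial_tokens
    silencers = tuple(_regulator_silencer(m, x) for x in range(4))
    return PetriNet(spec, deleted, transitions, removals, marking, silencers)


def _is_active(net: PetriNet, marking: np.ndarray, place: int) -> bool:
    if marking[place] < 1:
        return False
    sil = net.silencers[place]
    return sil is None or marking[sil] < 1


def _group_on(
    net: PetriNet, marking: np.ndarray, places: tuple[int, ...], mode: str, test: str
) -> bool:
    if test == "active":
        hits = [_is_active(net, marking, p) for p in places]
    else:
        hits = [marking[p] >= 1 for p in places]
    return all(hits) if mode == "all" else any(hits)


def enabled_transitions(net: PetriNet, marking: np.ndarray) -> list[Transition]:
    """Transitions enabled on the given (pre-step) marking."""
    out = []
    for t in net.transitions:
        if any(marking[s] < 1 for s in t.sources):
            continue
        if any(_group_on(net, marking, *g) for g in t.gates):
            continue
        out.append(t)
    return out


def step(net: PetriNet, marking: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One synchronous firing step; returns the new marking."""
    enabled = enabled_transitions(net, marking)
    order = rng.permutation(len(enabled))
    pool = marking.copy()
    delta = np.zeros(4, dtype=np.int64)
    for k in order:
        t = enabled[k]
        if any(pool[p] < 1 for p in t.consume):
            continue  # no longer fundable this step
        for p in t.consume:
            pool[p] -= 1
        if t.target is not None:
            delta[t.target] += t.delta
    for triggers, mode, target, w in net.removals:
        if _group_on(net, marking, triggers, mode, "active"):
            delta[target] -= w
    new = np.maximum(pool + delta, 0)
    for d in net.deleted:
        new[d] = 0
    return new


def run_condition(
    spec: ModelSpec,
    condition: frozenset,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one condition for ``config.steps`` steps; final marking."""
    net = compile(spec, condition, config)
    marking = net.initial_marking.copy()
    for _ in range(config.steps):
        marking = step(net, marking, rng)
    return marking


def m_value(tokens_mut: int, tokens_wt: int, pseudo: int = 1) -> float:
    """log2 fold-change of token counts, pseudo-count added to both."""
    if tokens_mut < 0 or tokens_wt < 0:
        raise ValueError("token counts must be non-negative")
    return float(np.log2((tokens_mut + pseudo) / (tokens_wt + pseudo)))


@dataclass(frozen=True)
class SimResult:
    """Final token counts and M values for the two downstream genes.

    ``tokens`` has shape (4 conditions, 2 genes) in :data:`CONDITIONS`
    order; ``m_values[g]`` is ``(M_R1d, M_R2d, M_R1dR2d)`` for gene ``g``
    (0 = G1, 1 = G2), each a log2 fold-change against the wild type.
    """

    tokens: np.ndarray
    pseudo_count: int = 1

    @property
    def m_values(self) -> np.ndarray:
        p = self.pseudo_count
        wt = self.tokens[0]
        return np.log2((self.tokens[1:] + p) / (wt + p)).T

    def m_for(self, gene: int) -> tuple[float, float, float]:
        return tuple(float(v) for v in self.m_values[gene])


def simulate(
    spec: ModelSpec,
    config: SimConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Simulate all four deletion conditions once; see :class:`SimResult`."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tokens = np.zeros((4, 2), dtype=np.int64)
    for c, cond in enumerate(CONDITIONS):
        final = run_condition(spec, cond, config, rng)
        tokens[c] = final[list(GENES)]
    return SimResult(tokens, config.pseudo_count)
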