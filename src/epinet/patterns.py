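"""Genetic-interaction pattern classification from M-value triples.

For a gene *i* and a mutant pair (x, y), the interaction effect is the
deviation of the double-mutant expression change from the additive
expectation of the single mutants::

    epsilon_i = | M_i,xy - (M_i,x + M_i,y) |

Genes whose deviation exceeds a threshold are assigned one of six
patterns from the direction calls of the three M values (up, down, or
unchanged):

* **buffering** — unchanged in both singles, changed in the double;
* **quantitative buffering** — double changed in the singles' shared
  direction, more strongly than expected;
* **suppression** — changed in a single, restored to wild type in the
  double;
* **quantitative suppression** — double in the shared direction but
  weaker than expected;
* **masking** — singles change in opposite directions and the double
  follows the dominant single;
* **inversion** — double changes opposite to the singles' shared
  direction.

The same rule table serves simulated profiles (directions from
``|M| > log2(1.7)``) and expression data (directions from an adjusted
p-value cutoff plus the sign of M); the direction caller is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .petri import SimResult

LOG2_17 = float(np.log2(1.7))
LOG2_15 = float(np.log2(1.5))


class GIPattern(IntEnum):
    NONE = 0
    BUFFERING = 1
    QUANT_BUFFERING = 2
    SUPPRESSION = 3
    QUANT_SUPPRESSION = 4
    MASKING = 5
    INVERSION = 6

    @property
    def label(self) -> str:
        return self.name.lower()


#: Pattern order used in tabular outputs.
PATTERN_ORDER = tuple(GIPattern)


@dataclass(frozen=True)
class PatternThresholds:
    """Thresholds for pattern calling.

    ``epsilon``: minimum deviation from additivity for any pattern call
    (simulation: log2(1.7); expression: log2(1.5)).  ``direction``: |M|
    threshold for calling a simulated profile changed.  Both are on the
    log2 fold-change scale and must be positive.
    """

    epsilon: float = LOG2_17
    direction: float = LOG2_17

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.direction <= 0:
            raise ValueError("thresholds must be positive")


SIMULATION_THRESHOLDS = PatternThresholds()
EXPRESSION_THRESHOLDS = PatternThresholds(epsilon=LOG2_15, direction=LOG2_15)


def epsilon(m1: float, m2: float, observed: float) -> float:
    """Deviation of the double-mutant change from additivity."""
    return abs(observed - (m1 + m2))


def direction_from_m(m: float, threshold: float = LOG2_17) -> int:
    """Simulated-profile direction call: sign of M beyond a magnitude cutoff."""
    if m > threshold:
        return 1
    if m < -threshold:
        return -1
    return 0


def classify(
    m1: float,
    m2: float,
    observed: float,
    d1: int,
    d2: int,
    d_obs: int,
    thresholds: PatternThresholds = SIMULATION_THRESHOLDS,
) -> GIPattern:
    """Classify one gene from M values plus direction calls.

    The rule table is total: exactly one pattern (possibly ``NONE``) is
    returned for any input.  ``d1, d2, d_obs`` are the direction calls in
    {-1, 0, +1} for the two singles and the double.
    """
    if epsilon(m1, m2, observed) <= thresholds.epsilon:
        return GIPattern.NONE
    if d1 == 0 and d2 == 0:
        return GIPattern.BUFFERING if d_obs != 0 else GIPattern.NONE
    if d_obs == 0:
        return GIPattern.SUPPRESSION
    if d1 != 0 and d2 != 0 and d1 == -d2:
        dominant = m1 if abs(m1) >= abs(m2) else m2
        if abs(observed - dominant) <= thresholds.epsilon:
            return GIPattern.MASKING
        return GIPattern.NONE
    shared = d1 if d1 != 0 else d2
    if d_obs == -shared:
        return GIPattern.INVERSION
    residual = observed - (m1 + m2)
    sign_residual = 1 if residual > 0 else -1
    if d_obs == shared:
        if sign_residual == shared:
            return GIPattern.QUANT_BUFFERING
        return GIPattern.QUANT_SUPPRESSION
    return GIPattern.NONE


def classify_simulated(
    m1: float,
    m2: float,
    observed: float,
    thresholds: PatternThresholds = SIMULATION_THRESHOLDS,
) -> GIPattern:
    """Classify a simulated triple, deriving directions from |M|."""
    t = thresholds.direction
    return classify(
        m1,
        m2,
        observed,
        direction_from_m(m1, t),
        direction_from_m(m2, t),
        direction_from_m(observed, t),
        thresholds,
    )


def classify_model(
    result: SimResult,
    thresholds: PatternThresholds = SIMULATION_THRESHOLDS,
) -> tuple[GIPattern, GIPattern]:
    """Pattern calls for (G1, G2) of one simulation result."""
    return tuple(
        classify_simulated(*result.m_for(g), thresholds) for g in (0, 1)
    )


def classify_arrays(
    m1: np.ndarray,
    m2: np.ndarray,
    observed: np.ndarray,
    d1: np.ndarray,
    d2: np.ndarray,
    d_obs: np.ndarray,
    thresholds: PatternThresholds = SIMULATION_THRESHOLDS,
) -> np.ndarray:
    """Vectorized rule table; returns int8 :class:`GIPattern` codes."""
    m1 = np.asarray(m1, dtype=np.float64)
    m2 = np.asarray(m2, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    residual = observed - (m1 + m2)
    eps = np.abs(residual)
    out = np.zeros(m1.shape, dtype=np.int8)

    interacting = eps > thresholds.epsilon
    singles_null = (d1 == 0) & (d2 == 0)
    opposite = (d1 != 0) & (d2 != 0) & (d1 == -d2)
    shared = np.where(d1 != 0, d1, d2)
    dominant = np.where(np.abs(m1) >= np.abs(m2), m1, m2)
    sign_residual = np.where(residual > 0, 1, -1)

    buffering = singles_null & (d_obs != 0)
    suppression = ~singles_null & (d_obs == 0)
    masking = (
        ~singles_null
        & (d_obs != 0)
        & opposite
        & (np.abs(observed - dominant) <= thresholds.epsilon)
    )
    considered = ~singles_null & (d_obs != 0) & ~opposite
    inversion = considered & (d_obs == -shared)
    quant_buf = considered & (d_obs == shared) & (sign_residual == shared)
    quant_sup = considered & (d_obs == shared) & (sign_residual == -shared)

    out[buffering] = GIPattern.BUFFERING
    out[suppression] = GIPattern.SUPPRESSION
    out[masking] = GIPattern.MASKING
    out[inversion] = GIPattern.INVERSION
    out[quant_buf] = GIPattern.QUANT_BUFFERING
    out[quant_sup] = GIPattern.QUANT_SUPPRESSION
    out[~interacting] = GIPattern.NONE
    return out


def classify_simulated_arrays(
    m: np.ndarray,
    thresholds: PatternThresholds = SIMULATION_THRESHOLDS,
) -> np.ndarray:
    """Vectorized simulated-triple classification.

    ``m``: array with last axis (M_R1d, M_R2d, M_R1dR2d); returns pattern
    codes with that axis dropped.
    """
    m = np.asarray(m, dtype=np.float64)
    t = thresholds.direction
    d = np.where(m > t, 1, np.where(m < -t, -1, 0))
    return classify_arrays(
        m[..., 0], m[..., 1], m[..., 2], d[..., 0], d[..., 1], d[..., 2], thresholds
    )


def m_values_from_tokens(tokens: np.ndarray, pseudo: int = 1) -> np.ndarray:
    """Batch token counts (..., 4 conditions, genes) -> M triples (..., genes, 3)."""
    tokens = np.asarray(tokens, dtype=np.float64)
    wt = tokens[..., 0:1, :]
    m = np.log2((tokens[..., 1:, :] + pseudo) / (wt + pseudo))
    return np.swapaxes(m, -1, -2)
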