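"""Survey of the model space: batch simulation, stability, aggregates.

Every logic-expanded canonical model is simulated under the four
deletion conditions for several independent runs.  A model is *stable*
when its (G1, G2) pattern tuple is identical across runs; unstable
models are flagged and excluded from aggregate statistics.  Aggregates
cover: pattern frequency by model complexity, the co-pattern
distribution of the companion downstream gene for inversion models, the
association between a quantitative edge difference and a buffering
companion node, and the persistence of inversion when the strong edge
weight is changed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import model_space as ms
from ._batch import model_identity, simulate_batch
from .patterns import (
    GIPattern,
    PatternThresholds,
    SIMULATION_THRESHOLDS,
    classify_simulated_arrays,
    m_values_from_tokens,
)
from .petri import SimConfig

BUFFERING_SUPERCLASS = (GIPattern.BUFFERING, GIPattern.QUANT_BUFFERING)


@dataclass
class ModelSample:
    """A set of expanded models: matrices (n, 16) plus logic tags (n, 4)."""

    matrices: np.ndarray
    logics: np.ndarray

    def __len__(self) -> int:
        return len(self.matrices)

    def with_strong_weight(self, strong: int) -> "ModelSample":
        """Relabel strong edges (weight-class preserving, e.g. 5 -> 9)."""
        m = self.matrices.astype(np.int64)
        mags = np.abs(m)
        strong_mask = mags > ms.WEAK
        out = np.where(strong_mask, np.sign(m) * strong, m).astype(np.int8)
        return ModelSample(out, self.logics)


def logic_tags_for_variant(flat: np.ndarray, variant: np.ndarray) -> np.ndarray:
    """Decode AND/OR variant indices into per-node logic tags.

    ``variant`` indexes the 2**k AND/OR combinations of each matrix in
    the order of its eligible nodes (ascending node index); bit 0 of the
    variant selects the first eligible node, value 1 meaning AND.
    """
    n = len(flat)
    tags = np.zeros((n, 4), dtype=np.int8)
    m = flat.reshape(n, 4, 4).astype(np.int64)
    bit = np.zeros(n, dtype=np.int64)
    for j in range(4):
        col = np.abs(m[:, :, j])
        nz = (col != 0).sum(axis=1)
        s = np.sort(np.where(col == 0, np.iinfo(np.int64).max, col), axis=1)
        eligible = (nz == 2) & (s[:, 0] == s[:, 1])
        two_diff = (nz == 2) & ~eligible
        tags[two_diff, j] = ms.Logic.OR
        chosen_and = eligible & ((variant >> bit) & 1 == 1)
        tags[eligible, j] = np.where(chosen_and[eligible], ms.Logic.AND, ms.Logic.OR)
        bit += eligible.astype(np.int64)
    return tags


def expand_all(canonical: np.ndarray) -> ModelSample:
    """Every logic-expanded model of the given canonical matrices."""
    k = ms.and_or_exponents(canonical).astype(np.int64)
    reps = (np.int64(1) << k)
    mat_idx = np.repeat(np.arange(len(canonical)), reps)
    variant = np.concatenate([np.arange(r, dtype=np.int64) for r in reps])
    flat = canonical[mat_idx]
    return ModelSample(flat, logic_tags_for_variant(flat, variant))


def sample_models(
    n: int,
    seed: int,
    canonical: np.ndarray | None = None,
    replace: bool = False,
) -> ModelSample:
    """Uniform random sample of n logic-expanded models."""
    if canonical is None:
        canonical = ms.canonical_matrices()
    k = ms.and_or_exponents(canonical).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(np.int64(1) << k)])
    total = int(cum[-1])
    rng = np.random.default_rng(seed)
    if replace or n > total:
        u = rng.integers(0, total, size=n)
    else:
        u = rng.choice(total, size=n, replace=False)
    u = np.sort(u)
    mat_idx = np.searchsorted(cum, u, side="right") - 1
    variant = u - cum[mat_idx]
    flat = canonical[mat_idx]
    return ModelSample(flat, logic_tags_for_variant(flat, variant))


def run_survey(
    sample: ModelSample,
    config: SimConfig,
    thresholds: PatternThresholds = SIMULATION_THRESHOLDS,
) -> pd.DataFrame:
    """Simulate a model sample; one row per model.

    Columns: ``model_id`` (content-based uint64), per-gene consensus
    pattern codes ``g1``/``g2`` (valid when ``stable``), ``stable``,
    ``complexity``, ``quant_diff``.
    """
    tokens = simulate_batch(sample.matrices, sample.logics, config)
    m = m_values_from_tokens(tokens, config.pseudo_count)  # (n, runs, 2, 3)
    codes = classify_simulated_arrays(m, thresholds)  # (n, runs, 2)
    stable = (codes == codes[:, :1]).all(axis=(1, 2))
    return pd.DataFrame(
        {
            "model_id": model_identity(sample.matrices, sample.logics),
            "g1": codes[:, 0, 0],
            "g2": codes[:, 0, 1],
            "stable": stable,
            "complexity": ms.complexity_counts(sample.matrices),
            "quant_diff": ms.quant_edge_difference_flags(sample.matrices),
        }
    )


def _stable(outcomes: pd.DataFrame) -> pd.DataFrame:
    return outcomes[outcomes["stable"]]


def unstable_fraction(outcomes: pd.DataFrame) -> float:
    return float(1.0 - outcomes["stable"].mean())


def shows_inversion(outcomes: pd.DataFrame) -> pd.Series:
    return (outcomes["g1"] == GIPattern.INVERSION) | (
        outcomes["g2"] == GIPattern.INVERSION
    )


def inversion_fraction(outcomes: pd.DataFrame) -> float:
    """Fraction of stable models with inversion in G1, G2 or both."""
    st = _stable(outcomes)
    return float(shows_inversion(st).mean())


def companion_patterns(outcomes: pd.DataFrame) -> pd.Series:
    """Pattern of the non-inversion downstream gene, for inversion models.

    Models are oriented so the inversion gene plays the G1 role (gene
    mirroring); when both genes show inversion the companion is itself
    inversion.
    """
    st = _stable(outcomes)
    inv = st[shows_inversion(st)]
    g1_inv = inv["g1"] == GIPattern.INVERSION
    return pd.Series(
        np.where(g1_inv, inv["g2"], inv["g1"]).astype(np.int8), index=inv.index
    )


def co_pattern_distribution(outcomes: pd.DataFrame) -> pd.Series:
    """Distribution (%) of companion-gene patterns for inversion models."""
    comp = companion_patterns(outcomes)
    counts = comp.value_counts().reindex([int(p) for p in GIPattern], fill_value=0)
    counts.index = [GIPattern(c).label for c in counts.index]
    return 100.0 * counts / counts.sum()


def pattern_by_complexity(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per complexity and pattern: model counts, split by quant-difference.

    A model counts toward a pattern when either downstream gene shows it.
    """
    st = _stable(outcomes)
    rows = []
    for pattern in GIPattern:
        if pattern == GIPattern.NONE:
            continue
        has = (st["g1"] == pattern) | (st["g2"] == pattern)
        sub = st[has]
        grouped = sub.groupby(["complexity", "quant_diff"]).size()
        total = st.groupby("complexity").size()
        for (cx, qd), count in grouped.items():
            rows.append(
                {
                    "pattern": pattern.label,
                    "complexity": cx,
                    "quant_diff": bool(qd),
                    "models": int(count),
                    "pct_of_complexity": 100.0 * count / total[cx],
                }
            )
    return pd.DataFrame(rows)


def inversion_no_quantdiff_fraction(outcomes: pd.DataFrame) -> float:
    """Fraction (%) of stable inversion models lacking a quantitative edge difference."""
    st = _stable(outcomes)
    inv = st[shows_inversion(st)]
    if len(inv) == 0:
        return float("nan")
    return float(100.0 * (~inv["quant_diff"]).mean())


def quantdiff_buffering_contingency(outcomes: pd.DataFrame) -> dict:
    """Association of a quantitative edge difference with a buffering companion.

    For inversion models the companion is the non-inversion downstream
    gene; for the all-models reference, the flag is buffering or
    quantitative buffering in either downstream gene.  Returns cell
    counts, both-true shares (%), and a chi-square p-value comparing the
    both-true rate of inversion models against the remaining models.
    """
    st = _stable(outcomes)
    inv_mask = shows_inversion(st)
    inv = st[inv_mask]
    comp = companion_patterns(outcomes)
    inv_buf = comp.isin([int(p) for p in BUFFERING_SUPERCLASS])
    all_buf = st["g1"].isin([int(p) for p in BUFFERING_SUPERCLASS]) | st["g2"].isin(
        [int(p) for p in BUFFERING_SUPERCLASS]
    )

    def cells(qd: pd.Series, buf: pd.Series) -> dict:
        n = len(qd)
        out = {}
        for b in (True, False):
            for q in (True, False):
                key = f"buf_{'yes' if b else 'no'}_quant_{'yes' if q else 'no'}"
                count = int(((qd == q) & (buf == b)).sum())
                out[key] = {"count": count, "pct": 100.0 * count / n if n else float("nan")}
        return out

    inv_cells = cells(inv["quant_diff"], inv_buf)
    all_cells = cells(st["quant_diff"], all_buf)

    both_inv = inv["quant_diff"] & inv_buf
    rest = st[~inv_mask]
    both_rest = rest["quant_diff"] & (all_buf[~inv_mask])
    table = np.array(
        [
            [int(both_inv.sum()), int((~both_inv).sum())],
            [int(both_rest.sum()), int((~both_rest).sum())],
        ]
    )
    if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
        if table.min() < 5:
            p = stats.fisher_exact(table)[1]
        else:
            p = stats.chi2_contingency(table, correction=False)[1]
    else:
        p = float("nan")
    return {
        "inversion_models": inv_cells,
        "all_models": all_cells,
        "n_inversion": len(inv),
        "n_all": len(st),
        "p_value": float(p),
    }


def sensitivity_rerun(
    sample: ModelSample,
    outcomes: pd.DataFrame,
    config: SimConfig,
    strong: int = 9,
    thresholds: PatternThresholds = SIMULATION_THRESHOLDS,
) -> dict:
    """Re-simulate the stable inversion models with a different strong weight.

    Returns the persistence fraction (%) of inversion under the new
    weight and the no-quant-difference share (%) among persisting models.
    """
    st_mask = outcomes["stable"].to_numpy()
    inv_mask = st_mask & shows_inversion(outcomes).to_numpy()
    sub = ModelSample(sample.matrices[inv_mask], sample.logics[inv_mask])
    sub9 = sub.with_strong_weight(strong)
    out9 = run_survey(sub9, config.with_strong_weight(strong), thresholds)
    persists = out9["stable"] & shows_inversion(out9)
    frac = float(100.0 * persists.mean()) if len(out9) else float("nan")
    no_qd = (
        float(100.0 * (~out9.loc[persists, "quant_diff"]).mean())
        if persists.any()
        else float("nan")
    )
    return {
        "n_inversion_w5": int(inv_mask.sum()),
        "persistence_pct": frac,
        "no_quant_diff_pct_w9": no_qd,
    }
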