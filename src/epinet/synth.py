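"""Synthetic mutant-pair cohorts with planted ground truth.

Generates gene-expression profiles for mutant pairs in the exact TSV
dialect the expression pipeline consumes, with known per-gene pattern
labels.  Each planted gene receives an (M_x, M_y, M_xy) triple that
satisfies its pattern's rule-table definition with a margin of at least
twice the calling threshold before noise; remaining genes are null.
Independent Gaussian noise is added to all M values, adjusted p-values
are synthesized from z = M / noise_sd with Benjamini-Hochberg
correction, and a shared slow-growth signature component — a smooth
random unit vector scaled per mutant — is superimposed on all three
profiles, emulating the common expression program of slow-growing
strains.

The generator emulates the statistical structure of genetic-interaction
profiles (planted pattern mixes, additive noise, a fitness-scaled common
signature); it does not emulate microarray intensity data, replicate
structure, or gene-gene correlation beyond the single shared signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import GrowthRecord, PairProfile
from .patterns import GIPattern, LOG2_15

#: Default planted gene counts per pattern (one mid-sized profile).
DEFAULT_PLANTED = {
    GIPattern.BUFFERING: 40,
    GIPattern.QUANT_BUFFERING: 20,
    GIPattern.SUPPRESSION: 20,
    GIPattern.QUANT_SUPPRESSION: 15,
    GIPattern.MASKING: 10,
    GIPattern.INVERSION: 25,
}


@dataclass(frozen=True)
class PlantedPairConfig:
    """Ground-truth recipe for one synthetic pair.

    ``effect`` is the planted log2 fold-change unit (default 1.5, well
    above the log2(1.5) calling threshold); ``noise_sd`` the Gaussian
    noise on every M value; ``loadings`` the per-mutant slow-growth
    signature amplitude (per-gene scale, applied to a unit-RMS signature);
    ``fitness`` the (W_x, W_y, W_xy) triple on the ratio scale.
    """

    pair: str = "synth_x-synth_y"
    n_genes: int = 6000
    planted: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED))
    effect: float = 1.5
    noise_sd: float = 0.2
    loadings: tuple[float, float, float] = (0.2, 0.1, 0.5)
    fitness: tuple[float, float, float] = (0.85, 0.9, 0.55)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect < 2 * LOG2_15:
            raise ValueError("effect size below twice the calling threshold")
        if sum(self.planted.values()) > self.n_genes:
            raise ValueError("planted counts exceed the number of genes")


@dataclass(frozen=True)
class SyntheticPair:
    """One generated pair: profile, truth labels, growth record, signature.

    ``signature`` is a gene-indexed unit vector aligned with the profile
    rows.
    """

    profile: PairProfile
    truth: pd.Series  # gene -> planted GIPattern label
    growth: GrowthRecord
    signature: pd.Series


def generate_signature(n_genes: int, seed: int) -> np.ndarray:
    """A smooth random unit vector standing in for the slow-growth
    principal component of a deletion-strain compendium."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(n_genes)
    # moving-average smoothing gives the signature gene-block structure
    kernel = np.ones(25) / 25.0
    smooth = np.convolve(raw, kernel, mode="same")
    return smooth / np.linalg.norm(smooth)


def _pattern_triple(
    pattern: GIPattern, effect: float, sign: int, swap: bool
) -> tuple[float, float, float]:
    """A clean (M_x, M_y, M_xy) triple realizing one pattern.

    ``sign`` flips the overall direction; ``swap`` exchanges which single
    mutant carries the effect.  All triples keep epsilon and every
    direction call at least ``effect`` away from the thresholds.
    """
    e = effect * sign
    if pattern == GIPattern.BUFFERING:
        m1, m2, mo = 0.0, 0.0, e
    elif pattern == GIPattern.QUANT_BUFFERING:
        m1, m2, mo = e, 0.0, 2 * e
    elif pattern == GIPattern.SUPPRESSION:
        m1, m2, mo = e, 0.0, 0.0
    elif pattern == GIPattern.QUANT_SUPPRESSION:
        m1, m2, mo = 2 * e, 0.0, e
    elif pattern == GIPattern.MASKING:
        # dominant single well separated so noise cannot flip dominance
        m1, m2, mo = 2 * e, -e, 2 * e
    elif pattern == GIPattern.INVERSION:
        m1, m2, mo = e, 0.0, -e
    else:
        raise ValueError(f"cannot plant pattern {pattern!r}")
    if swap:
        m1, m2 = m2, m1
    return m1, m2, mo


def generate_pair(
    config: PlantedPairConfig,
    signature: np.ndarray | None = None,
) -> SyntheticPair:
    """Generate one pair profile with planted patterns; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    if signature is None:
        signature = generate_signature(n, config.seed + 104729)
    if len(signature) != n:
        raise ValueError("signature length does not match n_genes")

    m = np.zeros((n, 3))
    truth = np.full(n, GIPattern.NONE.label, dtype=object)
    cursor = 0
    for pattern, count in sorted(config.planted.items(), key=lambda kv: int(kv[0])):
        for g in range(cursor, cursor + count):
            sign = 1 if rng.random() < 0.5 else -1
            swap = bool(rng.random() < 0.5)
            m[g] = _pattern_triple(GIPattern(pattern), config.effect, sign, swap)
            truth[g] = GIPattern(pattern).label
        cursor += count

    # shared slow-growth component: unit-RMS signature scaled per mutant
    unit_rms = signature * np.sqrt(n)
    for k, loading in enumerate(config.loadings):
        m[:, k] += loading * unit_rms
    m += rng.normal(0.0, config.noise_sd, size=m.shape)

    z = m / config.noise_sd
    p = 2.0 * _norm_sf(np.abs(z))
    p_adj = np.column_stack(
        [multipletests(p[:, k], method="fdr_bh")[1] for k in range(3)]
    )
    genes = pd.Index([f"gene{g:04d}" for g in range(n)], name="gene")
    data = pd.DataFrame(
        {
            "m_x": m[:, 0],
            "p_x": p_adj[:, 0],
            "m_y": m[:, 1],
            "p_y": p_adj[:, 1],
            "m_xy": m[:, 2],
            "p_xy": p_adj[:, 2],
        },
        index=genes,
    )
    order = rng.permutation(n)  # planted genes are not block-ordered
    data = data.iloc[order]
    truth = pd.Series(truth[order], index=data.index, name="pattern")
    sig = pd.Series(signature[order], index=data.index, name="loading")
    growth = GrowthRecord(config.pair, *config.fitness)
    return SyntheticPair(PairProfile(config.pair, data), truth, growth, sig)


def _norm_sf(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.sf(x)


#: Cohort archetypes mirroring the observed profile clusters: pairs
#: dominated by buffering (redundancy), pairs dominated by inversion, and
#: mixed-epistasis pairs.
ARCHETYPES: dict[str, dict[GIPattern, int]] = {
    "buffering": {
        GIPattern.BUFFERING: 70,
        GIPattern.QUANT_BUFFERING: 20,
        GIPattern.SUPPRESSION: 5,
        GIPattern.INVERSION: 5,
    },
    "inversion": {
        GIPattern.INVERSION: 60,
        GIPattern.BUFFERING: 15,
        GIPattern.MASKING: 10,
        GIPattern.QUANT_BUFFERING: 5,
    },
    "mixed": {
        GIPattern.SUPPRESSION: 25,
        GIPattern.MASKING: 20,
        GIPattern.QUANT_SUPPRESSION: 20,
        GIPattern.BUFFERING: 15,
        GIPattern.QUANT_BUFFERING: 10,
        GIPattern.INVERSION: 10,
    },
}


@dataclass(frozen=True)
class SyntheticCohort:
    """A labeled collection of synthetic pairs."""

    pairs: list[SyntheticPair]
    archetypes: pd.Series  # pair label -> archetype name


def generate_cohort(
    n_pairs: int,
    mix: dict[str, float] | None = None,
    n_genes: int = 6000,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a cohort of pairs drawn from the archetype mix.

    ``mix`` maps archetype name to proportion (must sum to 1); pairs are
    assigned round-robin proportionally, planted counts jittered by up to
    20% so pairs within an archetype are similar but not identical.
    """
    if mix is None:
        mix = {"buffering": 1 / 3, "inversion": 1 / 3, "mixed": 1 / 3}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("archetype proportions must sum to 1")
    counts = {a: int(round(f * n_pairs)) for a, f in mix.items()}
    while sum(counts.values()) < n_pairs:
        counts[max(mix, key=mix.get)] += 1
    while sum(counts.values()) > n_pairs:
        counts[max(counts, key=counts.get)] -= 1

    rng = np.random.default_rng(seed)
    signature = generate_signature(n_genes, seed + 15485863)
    pairs: list[SyntheticPair] = []
    labels = {}
    idx = 0
    for archetype, k in sorted(counts.items()):
        for _ in range(k):
            planted = {
                p: max(1, int(round(c * rng.uniform(0.8, 1.2))))
                for p, c in ARCHETYPES[archetype].items()
            }
            name = f"{archetype}_{idx:02d}"
            cfg = PlantedPairConfig(
                pair=name,
                n_genes=n_genes,
                planted=planted,
                noise_sd=noise_sd,
                loadings=tuple(rng.uniform(0.05, 0.3, size=3)),
                fitness=(
                    float(rng.uniform(0.8, 1.0)),
                    float(rng.uniform(0.8, 1.0)),
                    float(rng.uniform(0.4, 0.65)),
                ),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            pairs.append(generate_pair(cfg, signature))
            labels[name] = archetype
            idx += 1
    return SyntheticCohort(pairs, pd.Series(labels, name="archetype"))
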