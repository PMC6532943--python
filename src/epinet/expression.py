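"""Expression- and growth-based genetic-interaction scoring of mutant pairs.

Inputs are per-gene log2 fold-changes (M values) with adjusted p-values
for the two single deletion mutants and the double mutant of a gene
pair, plus colony-fitness measurements.  The module covers the full
profile pipeline:

* growth scores ``epsilon_growth = W_xy - W_x * W_y`` with Z-scores
  against a null distribution and Benjamini-Hochberg correction;
* pair selection (a significant negative growth interaction and at least
  one single mutant with a wild-type-like expression profile);
* slow-growth correction: removing the projection of each profile onto a
  common expression signature of slow-growing deletion strains;
* per-gene interaction effects ``epsilon_txpn`` and six-pattern calls
  (see :mod:`epinet.patterns`), aggregated into per-pair pattern-count
  vectors;
* average-linkage clustering of pairs by cosine similarity of their
  pattern counts, group comparisons (two-sided Mann-Whitney), and
  hypergeometric enrichment with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .patterns import (
    EXPRESSION_THRESHOLDS,
    GIPattern,
    PatternThresholds,
    classify_arrays,
)

LOG2_17 = float(np.log2(1.7))

#: Columns required in a pair-profile table (genes as index).
PROFILE_COLUMNS = ("m_x", "p_x", "m_y", "p_y", "m_xy", "p_xy")

#: Background population for enrichment tests (annotated genes).
DEFAULT_BACKGROUND = 6359


@dataclass(frozen=True)
class PairProfile:
    """Expression profiles of one mutant pair (x, y, and double xy).

    ``data`` is a gene-indexed table with columns :data:`PROFILE_COLUMNS`
    — M value and adjusted p-value for each of the three mutants.
    """

    pair: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROFILE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"profile table lacks columns {missing}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index


@dataclass(frozen=True)
class GrowthRecord:
    """Fitness values of one pair and its growth-interaction score."""

    pair: str
    w_x: float
    w_y: float
    w_xy: float

    def __post_init__(self) -> None:
        if min(self.w_x, self.w_y, self.w_xy) <= 0:
            raise ValueError("fitness values must be positive")

    @property
    def epsilon(self) -> float:
        return growth_epsilon(self.w_x, self.w_y, self.w_xy)


def growth_epsilon(w_x: float, w_y: float, w_xy: float) -> float:
    """Deviation of double-mutant fitness from the multiplicative expectation."""
    if min(w_x, w_y, w_xy) <= 0:
        raise ValueError("fitness values must be positive")
    return float(w_xy - w_x * w_y)


def growth_significance(
    eps: np.ndarray | list[float],
    null_mean: float,
    null_sd: float,
) -> pd.DataFrame:
    """Z-scores and BH-adjusted one-sided p-values for negative interactions.

    ``null_mean``/``null_sd`` parametrize the background distribution of
    interaction scores; the one-sided p-value is the lower normal tail
    (a negative interaction = slower growth than expected).
    """
    if null_sd <= 0:
        raise ValueError("null standard deviation must be positive")
    eps = np.asarray(eps, dtype=float)
    z = (eps - null_mean) / null_sd
    p = stats.norm.cdf(z)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"epsilon": eps, "z": z, "p": p, "p_adj": adj, "significant": adj < 0.05}
    )


def wt_similarity(
    m: np.ndarray | pd.Series,
    p_adj: np.ndarray | pd.Series,
    max_changed: int = 8,
    fc_threshold: float = LOG2_17,
    p_threshold: float = 0.05,
) -> bool:
    """Whether a single-mutant profile looks like wild type.

    True when fewer than ``max_changed`` genes change significantly
    (adjusted p below ``p_threshold`` and |M| above ``fc_threshold``).
    """
    m = np.asarray(m, dtype=float)
    p_adj = np.asarray(p_adj, dtype=float)
    changed = (p_adj < p_threshold) & (np.abs(m) > fc_threshold)
    return int(changed.sum()) < max_changed


def slow_growth_correct(m: np.ndarray, signature: np.ndarray) -> np.ndarray:
    """Remove a profile's projection onto the slow-growth signature.

    ``signature`` is normalized to unit length; the returned vector is
    orthogonal to it.  Idempotent and norm-non-increasing.
    """
    m = np.asarray(m, dtype=float)
    v = np.asarray(signature, dtype=float)
    if m.shape != v.shape:
        raise ValueError("profile and signature lengths differ")
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("signature vector is zero")
    v = v / norm
    return m - (m @ v) * v


def correct_profile(profile: PairProfile, signature: np.ndarray) -> PairProfile:
    """Slow-growth-correct all three M columns of a pair profile."""
    data = profile.data.copy()
    for col in ("m_x", "m_y", "m_xy"):
        data[col] = slow_growth_correct(data[col].to_numpy(), signature)
    return PairProfile(profile.pair, data)


def _directions(
    m: np.ndarray, p_adj: np.ndarray, p_threshold: float, m_threshold: float
) -> np.ndarray:
    """Direction call: sign of M where significant and above the FC cutoff."""
    changed = (p_adj <= p_threshold) & (np.abs(m) > m_threshold)
    return np.where(changed, np.sign(m), 0.0).astype(np.int8)


@dataclass(frozen=True)
class PairGIResult:
    """Per-gene calls and summary counts for one pair."""

    pair: str
    calls: pd.DataFrame  # epsilon, pattern per gene
    interaction_score: int  # number of genes with epsilon above threshold
    excluded: bool  # fewer than min_genes contributing genes
    pattern_counts: pd.Series  # six patterns
    changed_no_pattern: tuple[int, int]  # per single mutant

    @property
    def count_vector(self) -> np.ndarray:
        return self.pattern_counts.to_numpy(dtype=float)


def pair_gi_profile(
    profile: PairProfile,
    thresholds: PatternThresholds = EXPRESSION_THRESHOLDS,
    direction_p: float = 0.01,
    min_genes: int = 10,
) -> PairGIResult:
    """Score and classify every gene of one pair profile.

    Per-gene effects are ``epsilon = |m_xy - (m_x + m_y)|``; genes with
    ``epsilon`` above the threshold are classified into the six-pattern
    scheme with direction calls from adjusted p-values and M signs.  The
    pair's interaction score is the number of contributing genes; pairs
    below ``min_genes`` are flagged excluded.
    """
    d = profile.data
    m1 = d["m_x"].to_numpy(float)
    m2 = d["m_y"].to_numpy(float)
    mo = d["m_xy"].to_numpy(float)
    codes = classify_arrays(
        m1,
        m2,
        mo,
        _directions(m1, d["p_x"].to_numpy(float), direction_p, thresholds.direction),
        _directions(m2, d["p_y"].to_numpy(float), direction_p, thresholds.direction),
        _directions(mo, d["p_xy"].to_numpy(float), direction_p, thresholds.direction),
        thresholds,
    )
    eps = np.abs(mo - (m1 + m2))
    calls = pd.DataFrame(
        {
            "epsilon": eps,
            "pattern": [GIPattern(c).label for c in codes],
        },
        index=d.index,
    )
    score = int((eps > thresholds.epsilon).sum())
    patterns = [p for p in GIPattern if p != GIPattern.NONE]
    counts = pd.Series(
        {p.label: int((codes == p).sum()) for p in patterns}, name=profile.pair
    )
    no_pattern = codes == GIPattern.NONE
    changed_x = int(
        (no_pattern
         & (_directions(m1, d["p_x"].to_numpy(float), direction_p,
                        thresholds.direction) != 0)).sum()
    )
    changed_y = int(
        (no_pattern
         & (_directions(m2, d["p_y"].to_numpy(float), direction_p,
                        thresholds.direction) != 0)).sum()
    )
    return PairGIResult(
        pair=profile.pair,
        calls=calls,
        interaction_score=score,
        excluded=score < min_genes,
        pattern_counts=counts,
        changed_no_pattern=(changed_x, changed_y),
    )


def select_pairs(
    growth: pd.DataFrame,
    wt_like: dict[str, tuple[bool, bool]],
) -> pd.Series:
    """Pair-selection rule: significant negative growth score and a
    wild-type-like single mutant.

    ``growth`` must carry columns ``epsilon`` and ``significant`` indexed
    by pair; ``wt_like[pair]`` gives the WT-similarity of the two singles.
    """
    keep = {}
    for pair, row in growth.iterrows():
        wx, wy = wt_like.get(pair, (False, False))
        keep[pair] = bool(
            row["significant"] and row["epsilon"] < 0 and (wx or wy)
        )
    return pd.Series(keep, name="selected")


# ---------------------------------------------------------------------------
# clustering and group statistics


def cluster_pairs(count_vectors: pd.DataFrame) -> dict:
    """Average-linkage clustering of pairs on cosine distance.

    ``count_vectors``: rows = pairs, columns = pattern counts.  Rows are
    sorted by label first so equal-distance merges resolve
    deterministically.  Returns the linkage matrix, the leaf order
    (pair labels), and a Newick string of the dendrogram.
    """
    if len(count_vectors) < 2:
        raise ValueError("need at least two pairs to cluster")
    if (count_vectors.sum(axis=1) == 0).any():
        bad = count_vectors.index[count_vectors.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero count vectors: {bad}")
    ordered = count_vectors.sort_index()
    dist = pdist(ordered.to_numpy(dtype=float), metric="cosine")
    linkage = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(linkage)
    labels = [str(ordered.index[i]) for i in leaves]
    tree = hierarchy.to_tree(linkage)
    newick = _to_newick(tree, [str(l) for l in ordered.index])
    return {"linkage": linkage, "labels": ordered.index.tolist(),
            "leaf_order": labels, "newick": newick}


def _to_newick(node, labels: list[str]) -> str:
    def recurse(n, parent_dist: float) -> str:
        length = max(parent_dist - n.dist, 0.0)
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        left = recurse(n.left, n.dist)
        right = recurse(n.right, n.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(node, node.dist) + ";"


def cut_clusters(linkage: np.ndarray, labels: list, k: int) -> dict:
    """Cut the dendrogram into ``k`` flat clusters: label -> cluster id."""
    assign = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return dict(zip(labels, (int(a) for a in assign)))


def compare_inversion_fraction(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests on per-pair inversion shares.

    ``groups`` maps group name to the per-pair inversion percentages;
    p-values are BH-adjusted across the group comparisons.
    """
    names = sorted(groups)
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} has fewer than two pairs")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            u, p = stats.mannwhitneyu(
                groups[a], groups[b], alternative="two-sided", method="exact"
            )
            rows.append({"group_a": a, "group_b": b, "u": float(u), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def hypergeom_enrich(
    hits: set,
    annotations: dict[str, set],
    background: int = DEFAULT_BACKGROUND,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with Bonferroni correction.

    For each annotation set A: the p-value of drawing at least
    ``|hits & A|`` annotated genes when sampling ``|hits|`` genes from a
    background of ``background``.
    """
    if len(hits) > background:
        raise ValueError("hit set larger than the background population")
    rows = []
    for name, ann in sorted(annotations.items()):
        if len(ann) > background:
            raise ValueError(f"annotation {name!r} larger than the background")
        overlap = len(hits & ann)
        # P(X >= overlap), X ~ Hypergeom(background, |ann|, |hits|)
        p = float(stats.hypergeom.sf(overlap - 1, background, len(ann), len(hits)))
        rows.append({"annotation": name, "overlap": overlap,
                     "annotated": len(ann), "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


# ---------------------------------------------------------------------------
# TSV interfaces


def read_profile(path, pair: str) -> PairProfile:
    """Read a gene x column TSV profile (columns :data:`PROFILE_COLUMNS`)."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    return PairProfile(pair, data)


def read_fitness(path) -> pd.DataFrame:
    """Read a fitness TSV: pair, w_x, w_y, w_xy."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_signature(path) -> pd.Series:
    """Read a signature TSV: gene, loading."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]
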