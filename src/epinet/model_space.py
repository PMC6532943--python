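"""Enumeration of the four-node edge-weight-matrix model space.

The model universe is built from four nodes in fixed order — two upstream
regulators ``R1, R2`` and two downstream genes ``G1, G2`` — connected by
signed, weighted edges drawn from the five-letter alphabet
``{0, +1, +W, -1, -W}`` (weak/strong activation, weak/strong inhibition,
absent).  A model topology is a 4x4 integer matrix with rows as edge
sources and columns as edge targets.

Three structural conditions prune the raw ``5**16`` space:

1. no self-edges (zero diagonal);
2. at most two incoming edges per node (at most two nonzero entries per
   column);
3. at least two regulator-to-gene edges that share a source regulator or
   a target gene.

The surviving matrices are deduplicated under the mirror symmetries
(swapping the two regulators and/or the two genes), and each canonical
matrix is expanded into Petri-net model variants by assigning AND/OR
input logic to nodes with two incoming edges of equal magnitude.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterator, Sequence

import numpy as np

#: Node order used everywhere: rows/columns of the edge-weight matrix.
NODES = ("R1", "R2", "G1", "G2")
R1, R2, G1, G2 = range(4)
REGULATORS = (R1, R2)
GENES = (G1, G2)

WEAK = 1
DEFAULT_STRONG = 5

#: Mirror group: identity, regulator swap, gene swap, both.
MIRROR_PERMS = ((0, 1, 2, 3), (1, 0, 2, 3), (0, 1, 3, 2), (1, 0, 3, 2))


class Logic(IntEnum):
    """Input-logic tag for one node.

    ``SINGLE`` marks nodes with at most one incoming edge.  ``OR`` and
    ``AND`` are the two-input combination variants.  A node whose two
    incoming edges point in opposite directions is simulated with
    inhibition-dominant semantics regardless of its tag; the tag then only
    distinguishes formally generated model variants.
    """

    SINGLE = 0
    OR = 1
    AND = 2

    @property
    def short(self) -> str:
        return {Logic.SINGLE: "S", Logic.OR: "O", Logic.AND: "A"}[self]


#: Effective two-input semantics for mixed-direction input pairs.
INHIBITION_DOMINANT = "INHIBITION_DOMINANT"


def alphabet(strong: int = DEFAULT_STRONG) -> tuple[int, ...]:
    """The five admissible edge weights for a given strong-edge magnitude."""
    return (0, WEAK, strong, -WEAK, -strong)


def _as_matrix(matrix: Sequence) -> np.ndarray:
    m = np.asarray(matrix, dtype=np.int64)
    if m.shape == (16,):
        m = m.reshape(4, 4)
    if m.shape != (4, 4):
        raise ValueError(f"edge-weight matrix must be 4x4, got {m.shape}")
    return m


def _check_alphabet(m: np.ndarray, strong: int) -> None:
    ok = np.isin(m, alphabet(strong))
    if not ok.all():
        bad = sorted(set(m[~ok].tolist()))
        raise ValueError(f"values {bad} outside the weight alphabet for W={strong}")


def passes_conditions(matrix: Sequence, strong: int = DEFAULT_STRONG) -> bool:
    """Whether a matrix satisfies the three structural conditions.

    Condition 3 is read as: among the four regulator-to-gene entries there
    are two nonzero edges sharing a source regulator or a target gene (a
    lone "crossing" pair R1->Ga, R2->Gb with a != b does not qualify).
    """
    m = _as_matrix(matrix)
    _check_alphabet(m, strong)
    if np.any(np.diag(m) != 0):
        return False
    if np.any((m != 0).sum(axis=0) > 2):
        return False
    a, b = m[R1, G1], m[R2, G1]
    c, d = m[R1, G2], m[R2, G2]
    return bool((a and b) or (c and d) or (a and c) or (b and d))


# ---------------------------------------------------------------------------
# column-wise enumeration


def column_states() -> np.ndarray:
    """All admissible incoming-edge states of one node, weight-class coded.

    Returns a ``(61, 3)`` array over codes ``0..4`` standing for
    ``(0, +1, +W, -1, -W)``: the three off-diagonal entries of one column,
    with at most two nonzero.  61 = 5**3 - 4**3.
    """
    states = [
        s
        for s in itertools.product(range(5), repeat=3)
        if sum(v != 0 for v in s) <= 2
    ]
    return np.asarray(states, dtype=np.int8)


def _decode(codes: np.ndarray, strong: int) -> np.ndarray:
    return np.asarray(alphabet(strong), dtype=np.int8)[codes]


def gene_column_pairs() -> np.ndarray:
    """Index pairs (into :func:`column_states`) of admissible (G1, G2) columns.

    A pair is admissible when the four regulator-to-gene entries jointly
    satisfy condition 3.  2,496 of the 61*61 pairs qualify.
    """
    st = column_states()
    # in column G1 the row order is (R1, R2, G2); in column G2 it is (R1, R2, G1)
    a = st[:, 0][:, None] != 0  # R1->G1
    b = st[:, 1][:, None] != 0  # R2->G1
    c = st[None, :, 0] != 0  # R1->G2
    d = st[None, :, 1] != 0  # R2->G2
    ok = (a & b) | (c & d) | (a & c) | (b & d)
    i, j = np.nonzero(ok)
    return np.stack([i, j], axis=1)


def count_matrices() -> int:
    """Closed-form count of matrices passing the three conditions."""
    n_states = len(column_states())
    return n_states * n_states * len(gene_column_pairs())


def _assemble_chunk(
    r1_state: np.ndarray, r2_idx: np.ndarray, gene_idx: np.ndarray, strong: int
) -> np.ndarray:
    """Build (n, 16) row-major matrices from per-column state selections."""
    st = column_states()
    pairs = gene_column_pairs()
    n = len(r2_idx)
    out = np.zeros((n, 16), dtype=np.int8)
    # column j holds entries for source rows i != j, in increasing i
    col_rows = {j: [i for i in range(4) if i != j] for j in range(4)}

    def put(col: int, codes: np.ndarray) -> None:
        vals = _decode(codes, strong)
        for k, i in enumerate(col_rows[col]):
            out[:, 4 * i + col] = vals[:, k]

    put(0, np.broadcast_to(r1_state, (n, 3)))
    put(1, st[r2_idx])
    put(2, st[pairs[gene_idx, 0]])
    put(3, st[pairs[gene_idx, 1]])
    return out


def iter_matrix_chunks(strong: int = DEFAULT_STRONG) -> Iterator[np.ndarray]:
    """Stream every matrix passing the conditions, as (n, 16) int8 chunks.

    Chunks are grouped by the R1 column state (61 chunks of 61 * 2,496
    matrices each); concatenating all chunks yields each admissible matrix
    exactly once, in a deterministic order.
    """
    st = column_states()
    pairs = gene_column_pairs()
    n_r2, n_gp = len(st), len(pairs)
    r2_idx = np.repeat(np.arange(n_r2), n_gp)
    gene_idx = np.tile(np.arange(n_gp), n_r2)
    for r1 in st:
        yield _assemble_chunk(r1, r2_idx, gene_idx, strong)


def enumerate_matrices(strong: int = DEFAULT_STRONG) -> Iterator[np.ndarray]:
    """Yield every admissible 4x4 matrix exactly once (int8, row-major 4x4)."""
    for chunk in iter_matrix_chunks(strong):
        for row in chunk:
            yield row.reshape(4, 4)


# ---------------------------------------------------------------------------
# mirror symmetry and canonical forms

_POW5 = (5 ** np.arange(15, -1, -1)).astype(np.uint64)


def _perm_position_map(perm: Sequence[int]) -> np.ndarray:
    """Flat-index map: image[k] = source position whose entry lands at k."""
    pm = np.empty(16, dtype=np.int64)
    for i in range(4):
        for j in range(4):
            pm[4 * perm[i] + perm[j]] = 4 * i + j
    return pm


_POS_MAPS = [_perm_position_map(p) for p in MIRROR_PERMS]


def apply_mirror(matrix: Sequence, perm: Sequence[int]) -> np.ndarray:
    """Relabel nodes by ``perm`` (rows and columns jointly)."""
    m = _as_matrix(matrix)
    out = np.empty_like(m)
    for i in range(4):
        for j in range(4):
            out[perm[i], perm[j]] = m[i, j]
    return out


def mirror_orbit(matrix: Sequence) -> list[np.ndarray]:
    """The distinct images of a matrix under the mirror group (size 1, 2 or 4)."""
    m = _as_matrix(matrix)
    seen: dict[bytes, np.ndarray] = {}
    for p in MIRROR_PERMS:
        img = apply_mirror(m, p)
        seen.setdefault(img.tobytes(), img)
    return list(seen.values())


def _codes(flat: np.ndarray, strong: int) -> np.ndarray:
    """Base-5 digit codes (0..4) for flat int matrices."""
    lut = np.zeros(2 * strong + 1, dtype=np.uint64)
    for code, v in enumerate(alphabet(strong)):
        lut[v + strong] = code
    return lut[flat.astype(np.int64) + strong]


def matrix_code(matrix: Sequence, strong: int = DEFAULT_STRONG) -> int:
    """Stable integer key of a matrix: base-5 digits in row-major order."""
    m = _as_matrix(matrix).reshape(1, 16)
    return int(_codes(m, strong) @ _POW5)


def canonical_codes(flat_chunk: np.ndarray, strong: int = DEFAULT_STRONG) -> np.ndarray:
    """Vectorized canonical key: minimum code over the mirror orbit."""
    digs = _codes(flat_chunk, strong)
    best = None
    for pm in _POS_MAPS:
        code = digs[:, pm] @ _POW5
        best = code if best is None else np.minimum(best, code)
    return best


def decode_codes(codes: np.ndarray, strong: int = DEFAULT_STRONG) -> np.ndarray:
    """Inverse of :func:`matrix_code`: (n,) uint64 -> (n, 16) int8 matrices."""
    x = np.asarray(codes, dtype=np.uint64).copy()
    out = np.empty((len(x), 16), dtype=np.int8)
    letters = np.asarray(alphabet(strong), dtype=np.int8)
    for k in range(15, -1, -1):
        out[:, k] = letters[(x % 5).astype(np.int64)]
        x //= 5
    return out


def canonicalize(matrix: Sequence, strong: int = DEFAULT_STRONG) -> np.ndarray:
    """Lexicographically smallest mirror image (row-major base-5 order)."""
    m = _as_matrix(matrix).reshape(1, 16).astype(np.int8)
    code = canonical_codes(m, strong)
    return decode_codes(code, strong)[0].reshape(4, 4)


def canonical_matrices(strong: int = DEFAULT_STRONG) -> np.ndarray:
    """All canonical matrices, as an (N, 16) int8 array sorted by code.

    Runs the full streamed enumeration (about ten seconds); N = 2,324,136.
    """
    uniq: list[np.ndarray] = []
    for chunk in iter_matrix_chunks(strong):
        uniq.append(np.unique(canonical_codes(chunk, strong)))
    codes = np.unique(np.concatenate(uniq))
    return decode_codes(codes, strong)


# ---------------------------------------------------------------------------
# descriptive statistics of a matrix


def complexity(matrix: Sequence) -> int:
    """Number of edges (nonzero entries)."""
    return int((_as_matrix(matrix) != 0).sum())


def active_nodes(matrix: Sequence) -> frozenset[str]:
    """Nodes with at least one incident edge."""
    m = _as_matrix(matrix)
    inc = (m != 0).any(axis=0) | (m != 0).any(axis=1)
    return frozenset(NODES[i] for i in np.nonzero(inc)[0])


def has_quant_edge_difference(matrix: Sequence) -> bool:
    """True when the edge set mixes weak and strong magnitudes."""
    m = np.abs(_as_matrix(matrix))
    mags = set(m[m != 0].tolist())
    return len(mags) > 1


def quant_edge_difference_flags(flat_chunk: np.ndarray) -> np.ndarray:
    """Vectorized :func:`has_quant_edge_difference` over (n, 16) chunks."""
    mags = np.abs(flat_chunk.astype(np.int64))
    has_weak = (mags == WEAK).any(axis=1)
    has_strong = (mags > WEAK).any(axis=1)
    return has_weak & has_strong


def complexity_counts(flat_chunk: np.ndarray) -> np.ndarray:
    return (flat_chunk != 0).sum(axis=1)


# ---------------------------------------------------------------------------
# AND/OR logic expansion


@dataclass(frozen=True)
class ModelSpec:
    """A simulable model: an edge-weight matrix plus per-node input logic."""

    matrix: np.ndarray
    logic: tuple[Logic, Logic, Logic, Logic]

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", _as_matrix(self.matrix).astype(np.int8))
        object.__setattr__(self, "logic", tuple(Logic(l) for l in self.logic))

    @property
    def id(self) -> str:
        flat = ",".join(str(v) for v in self.matrix.reshape(16))
        tags = "".join(l.short for l in self.logic)
        return f"{flat}|{tags}"

    def effective_logic(self, node: int):
        """Semantics actually applied at a node (see :class:`Logic`)."""
        col = self.matrix[:, node]
        nz = col[col != 0]
        if len(nz) == 2 and (nz > 0).any() and (nz < 0).any():
            return INHIBITION_DOMINANT
        return self.logic[node]

    def serialize(self) -> str:
        flat = "\t".join(str(v) for v in self.matrix.reshape(16))
        return f"{flat}\t{''.join(l.short for l in self.logic)}"

    @classmethod
    def parse(cls, line: str) -> "ModelSpec":
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 17:
            raise ValueError("expected 16 matrix entries and a logic tag")
        m = np.asarray([int(v) for v in parts[:16]], dtype=np.int8).reshape(4, 4)
        tag_map = {"S": Logic.SINGLE, "O": Logic.OR, "A": Logic.AND}
        logic = tuple(tag_map[c] for c in parts[16])
        return cls(m, logic)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ModelSpec)
            and np.array_equal(self.matrix, other.matrix)
            and self.logic == other.logic
        )

    def __hash__(self) -> int:
        return hash((self.matrix.tobytes(), self.logic))


def expansion_exponent(matrix: Sequence) -> int:
    """Number of nodes receiving both an AND and an OR variant.

    A node doubles the model count when its two incoming edges have equal
    magnitude ("same weight"); two incoming edges of different magnitude
    combine with OR logic only.
    """
    m = _as_matrix(matrix)
    k = 0
    for j in range(4):
        col = m[:, j]
        nz = col[col != 0]
        if len(nz) == 2 and abs(nz[0]) == abs(nz[1]):
            k += 1
    return k


def and_or_exponents(flat_chunk: np.ndarray) -> np.ndarray:
    """Vectorized :func:`expansion_exponent` over (n, 16) chunks."""
    n = len(flat_chunk)
    k = np.zeros(n, dtype=np.int8)
    m = flat_chunk.reshape(n, 4, 4)
    for j in range(4):
        col = np.abs(m[:, :, j].astype(np.int64))
        nz = (col != 0).sum(axis=1)
        s = np.sort(np.where(col == 0, np.iinfo(np.int64).max, col), axis=1)
        k += ((nz == 2) & (s[:, 0] == s[:, 1])).astype(np.int8)
    return k


def node_logic_options(matrix: Sequence) -> list[tuple[Logic, ...]]:
    """Admissible logic tags per node, in node order."""
    m = _as_matrix(matrix)
    options: list[tuple[Logic, ...]] = []
    for j in range(4):
        col = m[:, j]
        nz = col[col != 0]
        if len(nz) < 2:
            options.append((Logic.SINGLE,))
        elif abs(nz[0]) == abs(nz[1]):
            options.append((Logic.OR, Logic.AND))
        else:
            options.append((Logic.OR,))
    return options


def expand_logic(matrix: Sequence) -> list[ModelSpec]:
    """All Petri-net model variants of one matrix (2**k specs)."""
    m = _as_matrix(matrix)
    specs = [
        ModelSpec(m, logic)
        for logic in itertools.product(*node_logic_options(m))
    ]
    return specs


def count_expanded_models(strong: int = DEFAULT_STRONG) -> tuple[int, int]:
    """(number of canonical matrices, number of logic-expanded models)."""
    canon = canonical_matrices(strong)
    k = and_or_exponents(canon)
    return len(canon), int((np.int64(2) ** k.astype(np.int64)).sum())
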