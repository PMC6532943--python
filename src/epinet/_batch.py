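"""Vectorized batch simulation (numba kernel).

Mirrors the reference semantics in :mod:`epinet.petri` for large model
surveys.  Each (model, run, condition) simulation draws its shuffle
stream from a counter-based seed derived from the global seed and the
model's content-based identity, so chunked, reordered, or parallel
surveys reproduce single-pass results exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .petri import InhibitionMode, SimConfig

_U64 = np.uint64
_MASK = _U64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + _U64(0x9E3779B97F4A7C15)) & _MASK
    z = x
    z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _MASK
    return (z ^ (z >> _U64(31))) & _MASK


@njit(cache=True, inline="always")
def _lcg(state):
    return (state * _U64(6364136223846793005) + _U64(1442695040888963407)) & _MASK


@njit(cache=True)
def _simulate_all(
    mats,
    logics,
    model_seeds,
    n_runs,
    steps,
    init_tokens,
    source_rate,
    silence,
    removal,
    genes_consume,
    out,
):
    n = mats.shape[0]
    for idx in range(n):
        M = mats[idx]
        lg = logics[idx]
        # incoming-edge structure per node; generic inhibitors exclude a
        # regulator-regulator silencer
        n_act = np.zeros(4, np.int64)
        act_src = np.full((4, 2), -1, np.int64)
        act_w = np.zeros((4, 2), np.int64)
        n_inh = np.zeros(4, np.int64)
        inh_src = np.full((4, 2), -1, np.int64)
        inh_w = np.zeros((4, 2), np.int64)
        reg_sil = np.full(4, -1, np.int64)
        for j in range(2):
            if M[1 - j, j] < 0:
                reg_sil[j] = 1 - j
        for j in range(4):
            for i in range(4):
                w = M[i, j]
                if w > 0:
                    act_src[j, n_act[j]] = i
                    act_w[j, n_act[j]] = w
                    n_act[j] += 1
                elif w < 0 and i != reg_sil[j]:
                    inh_src[j, n_inh[j]] = i
                    inh_w[j, n_inh[j]] = -w
                    n_inh[j] += 1
        for run in range(n_runs):
            for cond in range(4):
                del1 = cond == 1 or cond == 3
                del2 = cond == 2 or cond == 3
                state = _splitmix64(
                    model_seeds[idx]
                    ^ (_U64(run) * _U64(0xA3EC647659359ACD))
                    ^ (_U64(cond) * _U64(0x9E6C63D0876A9F4B))
                )
                state = _splitmix64(state)

                tokens = np.zeros(4, np.int64)
                if not del1 and M[1, 0] <= 0:
                    tokens[0] = init_tokens
                if not del2 and M[0, 1] <= 0:
                    tokens[1] = init_tokens

                # scratch transition lists (at most 8 edge transitions)
                t_s1 = np.empty(8, np.int64)
                t_s2 = np.empty(8, np.int64)
                t_tgt = np.empty(8, np.int64)
                t_dw = np.empty(8, np.int64)
                order = np.empty(8, np.int64)
                inh_on = np.zeros(4, np.bool_)
                active = np.zeros(4, np.bool_)
                sil = np.zeros(4, np.bool_)
                pool = np.zeros(4, np.int64)
                delta = np.zeros(4, np.int64)

                for _ in range(steps):
                    # a place is active when it holds a token and is not
                    # silenced by the other regulator
                    for j in range(4):
                        active[j] = tokens[j] >= 1 and not (
                            reg_sil[j] >= 0 and tokens[reg_sil[j]] >= 1
                        )
                    for j in range(4):
                        if n_inh[j] == 0:
                            inh_on[j] = False
                        elif lg[j] == 2 and n_inh[j] == 2:
                            inh_on[j] = (
                                active[inh_src[j, 0]] and active[inh_src[j, 1]]
                            )
                        else:
                            on = False
                            for k in range(n_inh[j]):
                                if active[inh_src[j, k]]:
                                    on = True
                            inh_on[j] = on
                        sil[j] = reg_sil[j] >= 0 and tokens[reg_sil[j]] >= 1
                        if silence and inh_on[j]:
                            sil[j] = True

                    nt = 0
                    for i in range(4):
                        delta[i] = 0
                        pool[i] = tokens[i]
                    for j in range(4):
                        deleted_j = (j == 0 and del1) or (j == 1 and del2)
                        tgt = -1 if deleted_j else j
                        gated_j = (not silence) and n_inh[j] > 0 and inh_on[j]
                        if n_act[j] == 2 and lg[j] == 2:
                            s1, s2 = act_src[j, 0], act_src[j, 1]
                            if (
                                tokens[s1] >= 1
                                and tokens[s2] >= 1
                                and not sil[s1]
                                and not sil[s2]
                                and not gated_j
                            ):
                                t_s1[nt] = s1
                                t_s2[nt] = s2
                                t_tgt[nt] = tgt
                                t_dw[nt] = act_w[j, 0]
                                nt += 1
                        else:
                            for k in range(n_act[j]):
                                s = act_src[j, k]
                                if tokens[s] >= 1 and not sil[s] and not gated_j:
                                    t_s1[nt] = s
                                    t_s2[nt] = -1
                                    t_tgt[nt] = tgt
                                    t_dw[nt] = act_w[j, k]
                                    nt += 1
                        # basal expression of an inhibitor-only gene
                        if (
                            j >= 2
                            and not deleted_j
                            and n_act[j] == 0
                            and n_inh[j] > 0
                            and not inh_on[j]
                        ):
                            delta[j] += source_rate
                        if (
                            (removal == 2 or (removal == 1 and j >= 2))
                            and n_inh[j] > 0
                            and not deleted_j
                        ):
                            if lg[j] == 2 and n_inh[j] == 2:
                                if inh_on[j]:
                                    delta[j] -= inh_w[j, 0]
                            else:
                                for k in range(n_inh[j]):
                                    if active[inh_src[j, k]]:
                                        delta[j] -= inh_w[j, k]

                    for k in range(nt):
                        order[k] = k
                    for k in range(nt - 1, 0, -1):
                        state = _lcg(state)
                        r = np.int64((state >> _U64(33)) % _U64(k + 1))
                        tmp = order[k]
                        order[k] = order[r]
                        order[r] = tmp

                    for o in range(nt):
                        t = order[o]
                        s1, s2 = t_s1[t], t_s2[t]
                        c1 = s1 >= 0 and (genes_consume or s1 <= 1)
                        c2 = s2 >= 0 and (genes_consume or s2 <= 1)
                        if c1 and pool[s1] < 1:
                            continue
                        if c2 and pool[s2] < 1:
                            continue
                        if c1:
                            pool[s1] -= 1
                        if c2:
                            pool[s2] -= 1
                        if t_tgt[t] >= 0:
                            delta[t_tgt[t]] += t_dw[t]

                    for i in range(4):
                        v = pool[i] + delta[i]
                        tokens[i] = v if v > 0 else 0
                    if del1:
                        tokens[0] = 0
                    if del2:
                        tokens[1] = 0

                out[idx, run, cond, 0] = tokens[2]
                out[idx, run, cond, 1] = tokens[3]


def model_identity(mats: np.ndarray, logics: np.ndarray) -> np.ndarray:
    """Content-based uint64 identity of each (matrix, logic) model."""
    mats = np.ascontiguousarray(mats, dtype=np.int8).reshape(len(mats), 16)
    lut = np.zeros(19, dtype=np.uint64)
    codes_by_value = {0: 0, 1: 1, 5: 2, -1: 3, -5: 4, 9: 2, -9: 4}
    for v, c in codes_by_value.items():
        lut[v + 9] = c
    pow5 = (5 ** np.arange(15, -1, -1)).astype(np.uint64)
    code = lut[mats.astype(np.int64) + 9] @ pow5
    lbits = np.zeros(len(mats), dtype=np.uint64)
    for j in range(4):
        lbits |= logics[:, j].astype(np.uint64) << np.uint64(2 * j)
    return (code << np.uint64(8)) | lbits


def _model_seeds(ids: np.ndarray, seed: int) -> np.ndarray:
    with np.errstate(over="ignore"):
        x = ids + np.uint64(0x9E3779B97F4A7C15) * np.uint64(seed + 1)
        for _ in range(2):
            x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
            x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
            x ^= x >> np.uint64(31)
    return x


def simulate_batch(
    mats: np.ndarray,
    logics: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    """Simulate many models; returns int32 tokens (n, runs, 4 conditions, 2 genes).

    ``mats``: (n, 16) or (n, 4, 4) signed edge-weight matrices;
    ``logics``: (n, 4) logic tags (:class:`~epinet.model_space.Logic`).
    Matrices must already use the weights of ``config.strong_weight``.
    """
    mats = np.ascontiguousarray(mats, dtype=np.int8).reshape(len(mats), 4, 4)
    logics = np.ascontiguousarray(logics, dtype=np.int8)
    ids = model_identity(mats, logics)
    seeds = _model_seeds(ids, config.seed)
    out = np.zeros((len(mats), config.runs, 4, 2), dtype=np.int32)
    _simulate_all(
        mats,
        logics,
        seeds,
        config.runs,
        config.steps,
        config.initial_tokens,
        config.source_rate,
        config.inhibition is InhibitionMode.SILENCE_TARGET,
        {"none": 0, "genes": 1, "all": 2}[config.inhibitor_removal],
        config.genes_consume,
        out,
    )
    return out
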