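"""The threading HMM: state spaces, transitions, emissions, forward/backward.

Re-threading one haploid lineage into a partial ARG is done with a hidden
Markov model along the genome.  At every compressed column the hidden state
is a triple ``(branch, time, population path)``: the branch of the local tree
the new lineage coalesces onto, the discrete grid time of that coalescence,
and the population path the new branch follows (resident, or crossing one
migration band).

Transitions follow a discretized sequentially-Markov coalescent: between
adjacent columns the state persists with probability ``exp(-r * b * span)``
(``r`` recombination rate per bp per generation, ``b`` the new branch length
in generations, ``span`` the column width in bases); the complementary
recombination mass is redistributed over all states proportional to the
discretized structured-coalescent prior, in which interval ``m`` contributes
coalescence intensity ``c_m / (2 N_pop(m))`` (``c_m`` co-located branches)
and every migration-band opportunity on a path multiplies in ``p_M`` (taken)
or ``1 - p_M`` (passed).

Emissions are Felsenstein-pruning likelihoods under a symmetric two-state
substitution model with per-column rates, conditioned on the ancestral state
(allele 0) at the root; compressed invariant columns carry their
width-scaled rate, so an invariant column's emission is the probability that
its bases accumulated no visible mutation on the tree.

The per-column recursions and per-span message passes are jit-compiled with
numba when available, with equivalent pure-Python fallbacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .arg import ABSENT, ARG, LocalTree, NULL
from .demography import DemographicModel

__all__ = [
    "StateSpace",
    "EmissionContext",
    "enumerate_states",
    "transition_terms",
    "emission_likelihood",
    "span_emissions",
    "forward_filter",
    "backward_sample",
    "sample_threading",
]

try:  # optional numba acceleration
    from numba import njit as _njit

    def _jit(f):
        return _njit(cache=False, fastmath=False)(f)
except Exception:  # pragma: no cover
    def _jit(f):
        return f


@dataclass
class EmissionContext:
    """Observed data for a window of compressed columns.

    ``alleles`` holds 0/1 for the two observed alleles and -1 for missing;
    ``mu_eff`` is the per-generation substitution rate of each column (the
    site rate multiplied by the column width for invariant columns);
    ``widths`` the number of bases each column represents.
    """

    alleles: np.ndarray  # (n_slots, L) int8
    mu_eff: np.ndarray   # (L,) float
    widths: np.ndarray   # (L,) float (bases)

    @property
    def L(self) -> int:
        return self.alleles.shape[1]

    def slice(self, a: int, b: int) -> "EmissionContext":
        return EmissionContext(self.alleles[:, a:b], self.mu_eff[a:b], self.widths[a:b])

    def slice_cols(self, idx: np.ndarray) -> "EmissionContext":
        return EmissionContext(self.alleles[:, idx], self.mu_eff[idx], self.widths[idx])


@dataclass
class StateSpace:
    """Enumerated coalescence states of one local tree for one new lineage."""

    branch: np.ndarray   # (S,) node id in the partial tree
    time: np.ndarray     # (S,) grid time index of coalescence
    path: np.ndarray     # (S,) global population-path id of the new branch
    w: np.ndarray        # (S,) re-coalescence prior (sums to 1)
    blen: np.ndarray     # (S,) new branch length in generations
    key: np.ndarray      # (S,) leaf-set key of `branch` (stable across SPRs)
    n: int               # haploid lineages in the local tree (incl. the new one)
    k: int               # grid size
    P: int               # paths available to the new lineage
    code: np.ndarray = None        # (S,) packed (key, time, path) identity
    code_sorted: np.ndarray = None
    code_order: np.ndarray = None

    def __post_init__(self):
        if self.code is None:
            self.code = (self.key.astype(np.int64) << 10) \
                | (self.time.astype(np.int64) << 5) | self.path.astype(np.int64)
        self.code_order = np.argsort(self.code)
        self.code_sorted = self.code[self.code_order]

    @property
    def S(self) -> int:
        return len(self.branch)

    def index(self) -> dict[tuple[int, int, int], int]:
        return {
            (int(self.key[i]), int(self.time[i]), int(self.path[i])): i
            for i in range(self.S)
        }

    def map_into(self, other: "StateSpace") -> np.ndarray:
        """Index of each of our states in ``other`` (-1 if absent)."""
        pos = np.searchsorted(other.code_sorted, self.code)
        pos_c = np.minimum(pos, other.S - 1)
        match = other.code_sorted[pos_c] == self.code
        out = np.full(self.S, -1, dtype=np.int64)
        out[match] = other.code_order[pos_c[match]]
        return out


# ------------------------------------------------------------------ #
# state enumeration with the structured-coalescent prior
# ------------------------------------------------------------------ #

def _model_arrays(model: DemographicModel):
    """Per-model constant arrays for the enumeration kernel (cached)."""
    arr = getattr(model, "_threading_arrays", None)
    if arr is not None:
        return arr
    K = model.K
    n_paths = len(model.paths)
    n_pops = len(model.populations)
    path_pops = np.empty((n_paths, K), dtype=np.int64)
    path_bandj = np.full(n_paths, -1, dtype=np.int64)
    for i, p in enumerate(model.paths):
        path_pops[i] = p.pops
        if p.band is not None:
            path_bandj[i] = p.band_j
    # migration-band weight per (path, half-time): p_M if taken, 1-p_M if the
    # path sits in the band's destination and passes, else 1
    mult = np.ones((n_paths, K - 1))
    for bi, b in enumerate(model.bands):
        j = model._band_j[bi]
        dest = model.pop_index[b.dest]
        for i, p in enumerate(model.paths):
            if p.band == bi and p.band_j == j:
                mult[i, j] *= b.prior_rate
            elif p.pops[j] == dest:
                mult[i, j] *= 1.0 - b.prior_rate
    # coalescence intensity coefficient dt/(2N) per (pop, interval); 0 where
    # coalescence is impossible (ghost populations)
    ratecoef = np.zeros((n_pops, K - 1))
    for pi in range(n_pops):
        for m in range(K - 1):
            N = model.size_at(pi, m)
            if math.isfinite(N) and N > 0:
                ratecoef[pi, m] = model.interval_gens(m) / (2.0 * N)
    coal_gens = np.asarray(model._coal_gens, dtype=float)
    arr = (path_pops, path_bandj, mult, ratecoef, coal_gens)
    model._threading_arrays = arr
    return arr


def _enum_kernel_py(node_ids, node_time, node_top, node_path, cand,
                    path_pops, path_bandj, mult_all, ratecoef, coal_gens,
                    a, K, out_branch, out_time, out_path, out_w, out_blen):
    n_pops = ratecoef.shape[0]
    n_nodes = len(node_ids)
    counts = np.zeros((K - 1, n_pops), dtype=np.int64)
    for vi in range(n_nodes):
        pid = node_path[vi]
        for m in range(node_time[vi], node_top[vi]):
            counts[m, path_pops[pid, m + 1]] += 1
    S = 0
    for ci in range(len(cand)):
        pid = cand[ci]
        bj = path_bandj[pid]
        surv = 1.0
        top_first = -1  # states at the oldest time, for leftover mass
        top_count = 0
        for m in range(a, K - 1):
            popm = path_pops[pid, m + 1]
            mlt = mult_all[pid, m]
            c = counts[m, popm]
            rate = c * ratecoef[popm, m]
            p_coal = -math.expm1(-rate) if rate > 0 else 0.0
            j = m + 1
            if c > 0 and (p_coal > 0.0 or j == K - 1) and (bj < 0 or j >= bj + 1):
                mass = surv * mlt * p_coal / c
                if j == K - 1:
                    top_first = S
                for vi in range(n_nodes):
                    if (node_time[vi] <= m and node_top[vi] >= j
                            and path_pops[node_path[vi], m + 1] == popm):
                        out_branch[S] = node_ids[vi]
                        out_time[S] = j
                        out_path[S] = pid
                        out_w[S] = mass
                        out_blen[S] = coal_gens[j] - coal_gens[a]
                        S += 1
                if j == K - 1:
                    top_count = S - top_first
            surv *= mlt * (1.0 - p_coal)
        # force coalescence by the oldest grid time: the path's leftover
        # survival mass joins its states at K-1, keeping relative path
        # weights (p_M vs 1-p_M) exact
        if top_count > 0 and surv > 0.0:
            extra = surv / top_count
            for si in range(top_first, top_first + top_count):
                out_w[si] += extra
    return S


_enum_kernel = _jit(_enum_kernel_py)


def enumerate_states(
    tree: LocalTree,
    model: DemographicModel,
    lineage: int,
    allow_migrant: bool = True,
    max_one_migration: bool = True,
) -> StateSpace:
    """All population-compatible ``(branch, time, path)`` coalescence states
    for re-threading ``lineage`` into ``tree``, with their coalescent prior.

    Under the max-one-migration constraint, migrant paths are pruned whenever
    the fixed tree already contains a migrant branch; coalescing below a
    fixed migrant branch (inherited introgression) remains available through
    resident-path states.
    """
    K = model.K
    a = model.lineage_ages[lineage]
    pop0 = model.lineage_pops[lineage]
    path_ids = list(model.path_ids_for(pop0))
    if not allow_migrant or (max_one_migration and tree.crossing_nodes(model)):
        path_ids = [pid for pid in path_ids if not model.paths[pid].is_migrant]
    else:
        path_ids = [
            pid for pid in path_ids
            if not model.paths[pid].is_migrant or model.paths[pid].band_j >= a
        ]
    path_pops, path_bandj, mult, ratecoef, coal_gens = _model_arrays(model)

    nodes = [v for v in range(tree.n_nodes)
             if not (v < tree.n_slots and tree.parent[v] == ABSENT)]
    node_ids = np.asarray(nodes, dtype=np.int64)
    node_time = tree.time[node_ids].astype(np.int64)
    node_top = np.asarray([tree.parent_time(int(v), K) for v in nodes],
                          dtype=np.int64)
    node_path = tree.path[node_ids].astype(np.int64)
    cand = np.asarray(path_ids, dtype=np.int64)

    cap = len(nodes) * (K - 1) * len(cand) + 1
    ob = np.empty(cap, dtype=np.int64)
    ot = np.empty(cap, dtype=np.int64)
    op = np.empty(cap, dtype=np.int64)
    ow = np.empty(cap, dtype=float)
    obl = np.empty(cap, dtype=float)
    S = _enum_kernel(node_ids, node_time, node_top, node_path, cand,
                     path_pops, path_bandj, mult, ratecoef, coal_gens,
                     a, K, ob, ot, op, ow, obl)
    if S == 0 or ow[:S].sum() <= 0:
        raise ValueError(f"no valid coalescence state for lineage {lineage}")
    keys = tree.keys()
    w = ow[:S] / ow[:S].sum()  # truncate mass escaping past the oldest time
    return StateSpace(
        branch=ob[:S].copy(),
        time=ot[:S].copy(),
        path=op[:S].copy(),
        w=w,
        blen=obl[:S].copy(),
        key=keys[ob[:S]].astype(np.int64),
        n=len(tree.leaves) + 1,
        k=K,
        P=len(path_ids),
    )


def _stay_probs(states: StateSpace, r: float, span_bp: float) -> np.ndarray:
    return np.exp(-r * states.blen * span_bp)


def transition_terms(
    states_i: StateSpace,
    states_j: StateSpace,
    r: float,
    span_bp: float,
) -> np.ndarray:
    """Dense stochastic transition matrix between two adjacent columns.

    Rows: states of the left column; columns: states of the right column.
    With identical state spaces the no-recombination mass sits on the
    diagonal; across a fixed-ARG recombination breakpoint states are carried
    over by (branch key, time, path) identity, and survival mass of states
    with no counterpart is forced through re-coalescence.
    """
    s = _stay_probs(states_i, r, span_bp)
    mp = states_i.map_into(states_j)
    M = np.zeros((states_i.S, states_j.S))
    for i in range(states_i.S):
        if mp[i] >= 0:
            M[i, mp[i]] += s[i]
            M[i, :] += (1.0 - s[i]) * states_j.w
        else:
            M[i, :] += states_j.w  # forced re-coalescence
    return M


# ------------------------------------------------------------------ #
# emissions
# ------------------------------------------------------------------ #

def _leaf_message(alleles_row: np.ndarray) -> np.ndarray:
    L = len(alleles_row)
    U = np.ones((L, 2))
    U[alleles_row == 0, 1] = 0.0
    U[alleles_row == 1, 0] = 0.0
    return U


def _messages_kernel_py(pre, parent, ch0, ch1, nslots, alleles, blen, mu,
                        U, O, root):
    """Upward (U) and outside (O) two-state pruning messages, per column.

    ``pre`` is a preorder of the present nodes; leaf messages come from the
    observed alleles (missing = 1,1); each branch applies the symmetric flip
    probability 0.5*(1-exp(-2*mu*len)).
    """
    n = len(pre)
    L = len(mu)
    for oi in range(n - 1, -1, -1):  # children before parents
        v = pre[oi]
        if v < nslots:
            for c in range(L):
                a = alleles[v, c]
                U[v, c, 0] = 0.0 if a == 1 else 1.0
                U[v, c, 1] = 0.0 if a == 0 else 1.0
        if parent[v] >= 0:
            pa = parent[v]
            for c in range(L):
                p = 0.5 * -math.expm1(-2.0 * mu[c] * blen[v])
                t0 = (1 - p) * U[v, c, 0] + p * U[v, c, 1]
                t1 = (1 - p) * U[v, c, 1] + p * U[v, c, 0]
                U[pa, c, 0] *= t0
                U[pa, c, 1] *= t1
    for c in range(L):
        O[root, c, 0] = 1.0
        O[root, c, 1] = 0.0
    for oi in range(n):  # parents before children
        v = pre[oi]
        if ch0[v] < 0:
            continue
        for c in range(L):
            if v == root:
                oa0 = O[v, c, 0]
                oa1 = O[v, c, 1]
            else:
                p = 0.5 * -math.expm1(-2.0 * mu[c] * blen[v])
                oa0 = (1 - p) * O[v, c, 0] + p * O[v, c, 1]
                oa1 = (1 - p) * O[v, c, 1] + p * O[v, c, 0]
            for which in range(2):
                kid = ch0[v] if which == 0 else ch1[v]
                sib = ch1[v] if which == 0 else ch0[v]
                ps = 0.5 * -math.expm1(-2.0 * mu[c] * blen[sib])
                s0 = (1 - ps) * U[sib, c, 0] + ps * U[sib, c, 1]
                s1 = (1 - ps) * U[sib, c, 1] + ps * U[sib, c, 0]
                O[kid, c, 0] = oa0 * s0
                O[kid, c, 1] = oa1 * s1


_messages_kernel = _jit(_messages_kernel_py)


def _tree_messages(tree: LocalTree, model: DemographicModel, ctx: EmissionContext):
    """U and O messages (n_nodes, L, 2) for the fixed tree, per column."""
    K = model.K
    L = ctx.L
    n = tree.n_nodes
    ch = tree.children()
    root = tree.root
    pre = [root]
    i = 0
    while i < len(pre):
        pre.extend(ch.get(pre[i], []))
        i += 1
    ch0 = np.full(n, -1, dtype=np.int64)
    ch1 = np.full(n, -1, dtype=np.int64)
    for v, kids in ch.items():
        ch0[v], ch1[v] = kids[0], kids[1]
    blen = np.zeros(n)
    for v in pre:
        blen[v] = model.time_gens(tree.parent_time(v, K)) \
            - model.time_gens(int(tree.time[v]))
    U = np.ones((n, L, 2))
    O = np.ones((n, L, 2))
    _messages_kernel(np.asarray(pre, dtype=np.int64),
                     tree.parent.astype(np.int64), ch0, ch1, tree.n_slots,
                     ctx.alleles, blen, ctx.mu_eff, U, O, root)
    return U, O


def span_emissions(
    tree: LocalTree,
    model: DemographicModel,
    lineage: int,
    states: StateSpace,
    ctx: EmissionContext,
) -> np.ndarray:
    """Per-column emission likelihood for every state; shape (L, S).

    States sharing a (branch, time) pair share emissions; population paths
    do not affect the substitution process.
    """
    K = model.K
    mu = ctx.mu_eff
    a_gens = model.time_gens(model.lineage_ages[lineage])
    U, O = _tree_messages(tree, model, ctx)
    Unew = _leaf_message(ctx.alleles[lineage])
    root = tree.root
    pair_code = states.branch * (K + 1) + states.time
    upair, pair_of_state = np.unique(pair_code, return_inverse=True)
    vs = (upair // (K + 1)).astype(np.int64)
    ts = (upair % (K + 1)).astype(np.int64)
    t_g = np.asarray(model._coal_gens)[ts]
    tops = np.asarray([model.time_gens(tree.parent_time(int(v), K)) for v in vs])
    bots = np.asarray(model._coal_gens)[tree.time[vs]]
    Ov = O[vs]  # (P, L, 2)
    Uv = U[vs]

    def flip(tlen):  # (P,) -> (P, L, 1)
        return (0.5 * -np.expm1(
            -2.0 * np.maximum(tlen, 0.0)[:, None] * mu[None, :]))[..., None]

    def transport(X, p):
        return (1 - p) * X + p * X[..., ::-1]

    Om = transport(Ov, flip(tops - t_g))
    Om[vs == root, :, 0] = 1.0  # attach on the root's upward extension:
    Om[vs == root, :, 1] = 0.0  # the ancestral-state prior sits at the new root
    Lb = transport(Uv, flip(t_g - bots))
    Ln = transport(Unew[None, :, :], flip(t_g - a_gens))
    e_pairs = (Om * Lb * Ln).sum(axis=2)  # (P, L)
    return e_pairs[pair_of_state].T.copy()


def emission_likelihood(
    tree: LocalTree,
    model: DemographicModel,
    alleles_col: np.ndarray,
    mu_eff: float,
) -> float:
    """Likelihood of one column under a full local tree (pruning).

    Missing entries contribute likelihood 1; a fully missing column gives 1.
    """
    ctx = EmissionContext(
        alleles=np.ascontiguousarray(
            np.asarray(alleles_col, dtype=np.int8).reshape(-1, 1)),
        mu_eff=np.asarray([mu_eff], dtype=float),
        widths=np.ones(1),
    )
    U, _ = _tree_messages(tree, model, ctx)
    return float(U[tree.root, 0, 0])


# ------------------------------------------------------------------ #
# forward filtering / backward sampling (generic dense interface)
# ------------------------------------------------------------------ #

def forward_filter(
    emissions: Sequence[np.ndarray],
    transitions: Sequence[np.ndarray],
    prior: np.ndarray,
) -> tuple[list[np.ndarray], float]:
    """Scaled forward algorithm over per-column dense matrices.

    ``emissions[c]`` is the (S_c,) emission vector, ``transitions[c]`` the
    (S_c, S_{c+1}) stochastic matrix, ``prior`` the state prior at column 0.
    Returns per-column normalized forward vectors and the log-likelihood.
    """
    L = len(emissions)
    f = np.asarray(prior, dtype=float) * emissions[0]
    norm = f.sum()
    if norm <= 0:
        raise FloatingPointError("column 0 has zero likelihood in every state")
    loglik = math.log(norm)
    f = f / norm
    out = [f]
    for c in range(1, L):
        f = (out[-1] @ transitions[c - 1]) * emissions[c]
        norm = f.sum()
        if norm <= 0:
            raise FloatingPointError(f"column {c} has zero likelihood in every state")
        loglik += math.log(norm)
        out.append(f / norm)
    return out, loglik


def backward_sample(
    forward: Sequence[np.ndarray],
    transitions: Sequence[np.ndarray],
    rng: np.random.Generator,
) -> list[int]:
    """Stochastic traceback: sample a state path from the exact posterior."""
    L = len(forward)
    path = [0] * L
    f = forward[-1]
    path[-1] = int(rng.choice(len(f), p=f / f.sum()))
    for c in range(L - 2, -1, -1):
        w = forward[c] * transitions[c][:, path[c + 1]]
        w = w / w.sum()
        path[c] = int(rng.choice(len(w), p=w))
    return path


# ------------------------------------------------------------------ #
# span-structured fast path used by the MCMC sampler
# ------------------------------------------------------------------ #

def _forward_span_py(f0, E, R, w, F, norms):
    Lc, S = E.shape
    F[0] = f0
    for c in range(1, Lc):
        tot = 0.0
        staysum = 0.0
        for i in range(S):
            tot += F[c - 1, i]
            staysum += F[c - 1, i] * R[c - 1, i]
        move = (tot - staysum)
        n = 0.0
        for i in range(S):
            f = E[c, i] * (F[c - 1, i] * R[c - 1, i] + move * w[i])
            F[c, i] = f
            n += f
        norms[c] = n
        for i in range(S):
            F[c, i] /= n


_forward_span = _jit(_forward_span_py)


def _sample_span_py(F, R, w, u, states_out, last_state):
    """Backward sampling within one span; fills states_out (length Lc)."""
    Lc, S = F.shape
    states_out[Lc - 1] = last_state
    for c in range(Lc - 2, -1, -1):
        j = states_out[c + 1]
        move_total = 0.0
        for i in range(S):
            move_total += F[c, i] * (1.0 - R[c, i])
        stay_m = F[c, j] * R[c, j]
        move_m = w[j] * move_total
        tot = stay_m + move_m
        if u[c] * tot < stay_m:
            states_out[c] = j
        else:
            target = (u[c] * tot - stay_m) / w[j] if w[j] > 0 else 0.0
            acc = 0.0
            pick = 0
            for i in range(S):
                acc += F[c, i] * (1.0 - R[c, i])
                pick = i
                if acc >= target:
                    break
            states_out[c] = pick


_sample_span = _jit(_sample_span_py)


def sample_threading(
    partial: ARG,
    model: DemographicModel,
    ctx: EmissionContext,
    lineage: int,
    rng: np.random.Generator,
    recomb_rate: float,
    allow_migrant: bool = True,
    state_cache: Optional[dict] = None,
) -> tuple[list[tuple[int, int, tuple[int, int, int]]], float]:
    """Sample coalescence states for ``lineage`` along the whole window.

    Returns ``(pieces, loglik)`` where ``pieces`` feed :func:`arg.thread`:
    maximal runs of constant state as ``(start, end, (branch_key, time,
    path_id))``.
    """
    segs = list(partial.segments())
    spans = []
    for start, end, tree in segs:
        if state_cache is not None:
            key = (tree.parent.tobytes(), tree.time.tobytes(),
                   tree.path.tobytes(), lineage, allow_migrant)
            st = state_cache.get(key)
            if st is None:
                st = enumerate_states(tree, model, lineage,
                                      allow_migrant=allow_migrant)
                if len(state_cache) > 50_000:
                    state_cache.clear()
                state_cache[key] = st
        else:
            st = enumerate_states(tree, model, lineage, allow_migrant=allow_migrant)
        sub = ctx.slice(start, end)
        # emissions are shared between columns with identical data and rate
        # (the bulk: invariant unmasked columns); recombination factors are
        # shared between equal-width columns — group before computing
        sig = np.vstack([sub.alleles,
                         np.ascontiguousarray(sub.mu_eff).view(np.int8)
                         .reshape(8, -1, order="F")])
        _, uidx, inv = np.unique(sig, axis=1, return_index=True,
                                 return_inverse=True)
        E = span_emissions(tree, model, lineage, st, sub.slice_cols(uidx))[inv]
        uw, winv = np.unique(sub.widths, return_inverse=True)
        R = np.exp(-recomb_rate * np.outer(uw, st.blen))[winv]
        spans.append((start, end, st, E, R))

    loglik = 0.0
    F_all = []
    prev_f = None
    prev_span = None
    for si, (start, end, st, E, R) in enumerate(spans):
        Lc = end - start
        if prev_f is None:
            f0 = st.w * E[0]
        else:
            pst, pR = prev_span
            mp = pst.map_into(st)
            stay = prev_f * pR[-1]
            f0 = np.zeros(st.S)
            ok = mp >= 0
            np.add.at(f0, mp[ok], stay[ok])
            move_mass = prev_f.sum() - stay[ok].sum()
            f0 = (f0 + move_mass * st.w) * E[0]
        n0 = f0.sum()
        if n0 <= 0:
            raise FloatingPointError(f"zero likelihood at column {start}")
        loglik += math.log(n0)
        f0 = f0 / n0
        F = np.empty((Lc, st.S))
        norms = np.ones(Lc)
        _forward_span(f0, E, R, st.w, F, norms)
        loglik += float(np.log(norms[1:]).sum())
        F_all.append(F)
        prev_f = F[-1]
        prev_span = (st, R)

    # backward pass, span by span from the right
    pieces_rev: list[tuple[int, int, tuple[int, int, int]]] = []
    next_choice = None  # (StateSpace, state index) in the following span
    for si in range(len(spans) - 1, -1, -1):
        start, end, st, E, R = spans[si]
        Lc = end - start
        F = F_all[si]
        if next_choice is None:
            p = F[-1] / F[-1].sum()
            last = int(rng.choice(st.S, p=p))
        else:
            # condition on the sampled first state of the span to the right:
            # P(i) ∝ f_i * T[i, j]; survival mass of states without a
            # counterpart on the right is forced through re-coalescence
            nst, nj = next_choice
            w_j = float(nst.w[nj])
            mp = st.map_into(nst)
            stay_vec = np.where(mp == nj, R[-1], 0.0)
            forced = np.where(mp < 0, R[-1] * w_j, 0.0)
            wgt = F[-1] * (stay_vec + (1.0 - R[-1]) * w_j + forced)
            wgt = wgt / wgt.sum()
            last = int(rng.choice(st.S, p=wgt))
        choice = np.empty(Lc, dtype=np.int64)
        u = rng.random(max(Lc - 1, 1))
        _sample_span(F, R, st.w, u, choice, last)
        run_state = int(choice[Lc - 1])
        run_end = end
        for c in range(Lc - 1, -1, -1):
            if int(choice[c]) != run_state:
                pieces_rev.append((start + c + 1, run_end,
                                   _state_tuple(st, run_state)))
                run_state = int(choice[c])
                run_end = start + c + 1
        pieces_rev.append((start, run_end, _state_tuple(st, run_state)))
        next_choice = (st, int(choice[0]))
    pieces = list(reversed(pieces_rev))
    return pieces, loglik


def _state_tuple(st: StateSpace, i: int) -> tuple[int, int, int]:
    return (int(st.key[i]), int(st.time[i]), int(st.path[i]))
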