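"""Marker ordering and multipoint genetic-map estimation.

Ordering minimises obligate crossovers: the smallest number of
recombination events that can explain an individual's ordered call
sequence.  For intercross codes (0/1/2 = number of B alleles) the minimum
over gamete configurations reduces to the sum of ``|g_{k+1} - g_k|`` over
consecutive non-missing calls -- each unit change in genotype needs at
least one gamete switch, and a path achieving exactly that many always
exists.  A seriation start order is polished by a rippling local search
that exhaustively permutes a sliding window of markers (default 7) and
keeps strictly better arrangements, breaking ties among improvements with
a seeded RNG; repeated seeded runs are compared by multipoint likelihood.

Inter-marker distances come from a hidden Markov chain over the true
genotype per individual: transition probabilities per interval derive from
its recombination fraction through independent gamete recombinations,
observed calls are emitted with a symmetric genotyping-error rate, and
missing calls are uninformative.  EM (forward-backward expected
recombinant-gamete counts) estimates every interval's fraction, converted
to cM positions with the Haldane function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeMatrix
from .errors import ConfigError, MapEstimationError
from .twopoint import TwoPointMatrix, _em_batch, haldane_cM

_MAX_WINDOW = 8  # window! permutations are enumerated exhaustively
_RIPPLE_MAX_PASSES = 60


@dataclass(frozen=True)
class OrderingParams:
    window: int = 7
    error_prob: float = 1e-4
    n_runs: int = 9
    map_function: str = "haldane"
    seed: int = 0

    def __post_init__(self):
        if self.window < 2:
            raise ConfigError("window must be >= 2")
        if self.window > _MAX_WINDOW:
            raise ConfigError(f"window must be <= {_MAX_WINDOW} (exhaustive permutation)")
        if not 0.0 <= self.error_prob < 0.5:
            raise ConfigError("error_prob must be in [0, 0.5)")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if self.map_function != "haldane":
            raise ConfigError("only the haldane map function is supported")


@dataclass
class LinkageGroupMap:
    """An ordered linkage group with estimated cM positions."""

    group_id: str
    marker_ids: list
    positions_cM: np.ndarray
    interval_rf: np.ndarray
    loglik: float  # summed log10 multipoint likelihood
    n_iter: int = 0
    loglik_trajectory: list = field(default_factory=list)

    def __post_init__(self):
        self.positions_cM = np.asarray(self.positions_cM, dtype=float)
        self.interval_rf = np.asarray(self.interval_rf, dtype=float)
        if np.any(np.diff(self.positions_cM) < 0):
            raise ConfigError("cM positions must be non-decreasing")

    @property
    def length_cM(self) -> float:
        return float(self.positions_cM[-1]) if len(self.positions_cM) else 0.0


# ---------------------------------------------------------------------------
# obligate crossovers
# ---------------------------------------------------------------------------

def _obligate_per_individual(G: np.ndarray) -> np.ndarray:
    """Minimal crossover count per individual for ordered calls ``G``
    (individuals x markers, -1 missing)."""
    n, m = G.shape
    cur = np.full(n, -1, dtype=np.int16)
    total = np.zeros(n, dtype=np.int64)
    for k in range(m):
        g = G[:, k].astype(np.int16)
        typed = g >= 0
        valid = typed & (cur >= 0)
        total[valid] += np.abs(g[valid] - cur[valid])
        cur[typed] = g[typed]
    return total


def count_obligate_xo(order, matrix: GenotypeMatrix):
    """Per-individual minimal crossover counts for a marker order.

    Missing calls are skipped.  Adjacent A<->B implies two events (both
    gametes recombine), A<->H or H<->B one.

    Returns ``(per_individual, total)``.
    """
    cols = [matrix.marker_index[m] for m in order]
    per = _obligate_per_individual(matrix.calls[:, cols])
    return per, int(per.sum())


# ---------------------------------------------------------------------------
# seriation start order
# ---------------------------------------------------------------------------

def initial_order(group, twopoint: TwoPointMatrix):
    """Greedy seriation of a linkage group from pairwise linkage.

    Starts from the closest pair and repeatedly inserts the remaining
    marker with the cheapest insertion cost (Haldane-transformed rf, so
    costs are approximately additive along a chromosome).  Deterministic:
    ties resolve to the first candidate in id order.
    """
    group = list(group)
    if len(group) < 2:
        return group
    sub = twopoint.submatrix(sorted(group))
    rf = np.where(np.isnan(sub.rf), 0.5, sub.rf)
    D = -50.0 * np.log1p(-2.0 * np.clip(rf, 0.0, 0.49995))
    m = len(sub.marker_ids)
    iu, ju = np.triu_indices(m, k=1)
    k = int(np.argmin(D[iu, ju]))
    chain = [int(iu[k]), int(ju[k])]
    unplaced = [i for i in range(m) if i not in chain]
    while unplaced:
        X = np.array(unplaced)
        a = np.array(chain[:-1])
        b = np.array(chain[1:])
        mid = D[np.ix_(a, X)] + D[np.ix_(b, X)] - D[a, b][:, None]  # (len-1, |X|)
        head = D[chain[0], X][None, :]
        tail = D[chain[-1], X][None, :]
        cost = np.vstack([head, mid, tail])  # slot s: insert before position s
        s, xi = np.unravel_index(np.argmin(cost), cost.shape)
        chain.insert(int(s), int(X[xi]))
        unplaced.remove(int(X[xi]))
    return [sub.marker_ids[i] for i in chain]


# ---------------------------------------------------------------------------
# ripple local search
# ---------------------------------------------------------------------------

def _next_typed(calls, cols, from_pos):
    n = calls.shape[0]
    nxt = np.full(n, -1, dtype=np.int8)
    for p in range(from_pos, len(cols)):
        need = nxt < 0
        if not need.any():
            break
        col = calls[:, cols[p]]
        fill = need & (col >= 0)
        nxt[fill] = col[fill]
    return nxt


def _window_costs(U, perms):
    """Obligate-crossover cost of each window permutation per signature row.

    ``U`` is ``(u, w+2)``: boundary genotype before, the ``w`` window
    genotypes in current order, boundary genotype after (-1 = none).
    Returns ``(u, n_perms)`` costs.
    """
    w = U.shape[1] - 2
    block = U[:, 1:-1][:, perms]  # (u, P, w)
    cur = np.repeat(U[:, 0][:, None], perms.shape[0], axis=1).astype(np.int16)
    cost = np.zeros(cur.shape, dtype=np.int64)
    for k in range(w):
        g = block[:, :, k].astype(np.int16)
        typed = g >= 0
        valid = typed & (cur >= 0)
        cost += np.where(valid, np.abs(g - cur), 0)
        cur = np.where(typed, g, cur)
    gn = U[:, -1][:, None].astype(np.int16)
    valid = (gn >= 0) & (cur >= 0)
    cost += np.where(valid, np.abs(gn - cur), 0)
    return cost


def ripple_window(order, matrix: GenotypeMatrix, window: int = 7,
                  rng: np.random.Generator | None = None):
    """Slide a window over the order, exhaustively permuting its markers.

    At each position every ``window!`` arrangement is scored by total
    obligate crossovers; a strictly better arrangement is adopted (ties
    among the best improvements broken by ``rng``).  Passes repeat until a
    full sweep makes no improvement.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    order = list(order)
    w = min(window, len(order))
    if w > _MAX_WINDOW:
        raise ConfigError(f"window must be <= {_MAX_WINDOW}")
    if w < 2:
        return order
    perms = np.array(list(itertools.permutations(range(w))), dtype=np.intp)
    cols = np.array([matrix.marker_index[m] for m in order], dtype=np.intp)
    calls = matrix.calls
    n = calls.shape[0]
    for _pass in range(_RIPPLE_MAX_PASSES):
        improved = False
        prev = np.full(n, -1, dtype=np.int8)
        for start in range(len(cols) - w + 1):
            Wg = calls[:, cols[start:start + w]]
            nxt = _next_typed(calls, cols, start + w)
            rows = np.column_stack([prev, Wg, nxt])
            U, counts = np.unique(rows, axis=0, return_counts=True)
            totals = counts @ _window_costs(U, perms)
            best = totals.min()
            if best < totals[0]:  # perms[0] is the identity
                cand = np.flatnonzero(totals == best)
                pick = cand[0] if len(cand) == 1 else cand[int(rng.integers(len(cand)))]
                cols[start:start + w] = cols[start:start + w][perms[pick]]
                improved = True
            first = calls[:, cols[start]]
            typed = first >= 0
            prev[typed] = first[typed]
        if not improved:
            break
    return [matrix.marker_ids[c] for c in cols]


# ---------------------------------------------------------------------------
# multipoint HMM map estimation
# ---------------------------------------------------------------------------

def _transition_matrices(r: np.ndarray) -> np.ndarray:
    """(m-1, 3, 3) genotype transition matrices for interval fractions r."""
    q = 1.0 - r
    T = np.empty((len(r), 3, 3))
    T[:, 0, 0] = q * q
    T[:, 0, 1] = 2.0 * r * q
    T[:, 0, 2] = r * r
    T[:, 1, 0] = r * q
    T[:, 1, 1] = q * q + r * r
    T[:, 1, 2] = r * q
    T[:, 2, 0] = r * r
    T[:, 2, 1] = 2.0 * r * q
    T[:, 2, 2] = q * q
    return T


def _recombinant_gamete_counts(r: np.ndarray) -> np.ndarray:
    """(m-1, 3, 3) expected recombinant gametes per genotype transition."""
    K = np.empty((len(r), 3, 3))
    K[:] = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    q2r2 = (1.0 - r) ** 2 + r ** 2
    K[:, 1, 1] = np.where(q2r2 > 0, 2.0 * r ** 2 / q2r2, 0.0)
    return K


def _emissions(G: np.ndarray, error_prob: float) -> np.ndarray:
    n, m = G.shape
    E = np.ones((n, m, 3))
    typed = G >= 0
    ti, tk = np.nonzero(typed)
    E[ti, tk, :] = error_prob / 2.0
    E[ti, tk, G[ti, tk]] = 1.0 - error_prob
    return E


def estimate_map(order, matrix: GenotypeMatrix, error_prob: float = 1e-4,
                 map_function: str = "haldane", tol: float = 1e-9,
                 max_iter: int = 500, group_id: str = "LG") -> LinkageGroupMap:
    """EM-estimate inter-marker distances for a fixed order.

    Interval recombination fractions are initialised from adjacent
    two-point estimates and refined by forward-backward EM; converged
    fractions are accumulated into cM positions with the Haldane function
    (first marker at 0).
    """
    if map_function != "haldane":
        raise ConfigError("only the haldane map function is supported")
    order = list(order)
    if len(order) < 2:
        raise ConfigError("need at least two markers to estimate a map")
    cols = [matrix.marker_index[m] for m in order]
    G = matrix.calls[:, cols]
    n, m = G.shape

    # adjacent two-point initialisation
    adj = np.empty((m - 1, 3, 3))
    left, right = G[:, :-1], G[:, 1:]
    for g1 in range(3):
        for g2 in range(3):
            adj[:, g1, g2] = ((left == g1) & (right == g2)).sum(axis=0)
    r0, _ = _em_batch(adj)
    r = np.clip(np.where(np.isnan(r0), 0.125, r0), 1e-6, 0.49)

    E = _emissions(G, error_prob)
    pi = np.array([0.25, 0.5, 0.25])
    loglik = np.nan
    trajectory = []
    it = 0
    for it in range(1, max_iter + 1):
        T = _transition_matrices(r)
        K = _recombinant_gamete_counts(r)
        # scaled forward pass
        alphas = np.empty((m, n, 3))
        logc = np.zeros(n)
        a = pi[None, :] * E[:, 0, :]
        c = a.sum(axis=1)
        if np.any(c <= 0) or not np.all(np.isfinite(c)):
            raise MapEstimationError("non-finite likelihood at the first marker")
        a /= c[:, None]
        logc += np.log(c)
        alphas[0] = a
        for k in range(m - 1):
            a = (a @ T[k]) * E[:, k + 1, :]
            c = a.sum(axis=1)
            if np.any(c <= 0) or not np.all(np.isfinite(c)):
                raise MapEstimationError(
                    f"non-finite likelihood in interval {k} "
                    f"({order[k]!r} - {order[k + 1]!r}, rf={r[k]:.3g})"
                )
            a /= c[:, None]
            logc += np.log(c)
            alphas[k + 1] = a
        # backward pass + expected recombinant gametes per interval
        b = np.ones((n, 3))
        r_new = np.empty_like(r)
        for k in range(m - 2, -1, -1):
            eb = E[:, k + 1, :] * b  # (n, 3)
            xi = alphas[k][:, :, None] * T[k][None, :, :] * eb[:, None, :]
            xi /= xi.sum(axis=(1, 2))[:, None, None]
            r_new[k] = (xi * K[k][None, :, :]).sum() / (2.0 * n)
            b = (T[k] * eb[:, None, :]).sum(axis=2)
            b /= b.max(axis=1)[:, None]
        loglik = float(logc.sum() / np.log(10.0))
        trajectory.append(loglik)
        r_new = np.clip(r_new, 0.0, 0.5 - 1e-12)
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new
    positions = np.concatenate([[0.0], np.cumsum(haldane_cM(r))])
    return LinkageGroupMap(group_id=group_id, marker_ids=order,
                           positions_cM=positions, interval_rf=r,
                           loglik=loglik, n_iter=it, loglik_trajectory=trajectory)


def order_likelihood(order, matrix: GenotypeMatrix, error_prob: float = 1e-4) -> float:
    """log10 multipoint likelihood of an order at its EM-converged map."""
    return estimate_map(order, matrix, error_prob=error_prob).loglik


def order_markers(group, matrix: GenotypeMatrix, params: OrderingParams = OrderingParams(),
                  twopoint: TwoPointMatrix | None = None, metadata=None):
    """Best marker order for one linkage group.

    Runs ``n_runs`` seeded ripple searches from a common greedy seriation
    (runs differ through their tie-break streams), compares the resulting
    orders by multipoint likelihood, and normalises the winner's
    orientation: physical positions of the majority scaffold increase
    along the map when ``metadata`` is provided, otherwise the first
    marker id is lexicographically smaller than the last.
    """
    group = list(group)
    if len(group) == 0:
        raise ConfigError("empty linkage group")
    if len(group) == 1:
        return group
    if twopoint is None:
        from .twopoint import twopoint_all
        sub = matrix.select_markers(group)
        twopoint = twopoint_all(sub, min_informative=1)
    start = initial_order(group, twopoint)
    window = min(params.window, len(group))
    best_order, best_ll = None, -np.inf
    scored = {}
    for run in range(params.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence((int(params.seed), run)))
        order = ripple_window(start, matrix, window, rng)
        key = tuple(order) if order[0] <= order[-1] else tuple(reversed(order))
        if key not in scored:
            scored[key] = order_likelihood(list(key), matrix, params.error_prob)
        if scored[key] > best_ll:
            best_ll, best_order = scored[key], list(key)
    return _orient(best_order, metadata)


def _orient(order, metadata=None):
    if metadata is not None:
        meta = metadata.set_index("marker_id") if "marker_id" in metadata.columns else metadata
        present = [m for m in order if m in meta.index]
        if present:
            scaffolds = meta.loc[present, "scaffold"]
            majority = scaffolds.value_counts().index[0]
            on_maj = [m for m in present if meta.at[m, "scaffold"] == majority]
            if len(on_maj) >= 2:
                bp = meta.loc[on_maj, "pos_bp"].to_numpy(dtype=float)
                rank = np.arange(len(bp))
                slope = np.corrcoef(rank, bp)[0, 1]
                if slope < 0:
                    return list(reversed(order))
                return list(order)
    return list(order) if order[0] <= order[-1] else list(reversed(order))


def map_gaps(lg_map: LinkageGroupMap, threshold_cM: float = 10.0):
    """Largest inter-marker gap and the count of gaps above a threshold."""
    gaps = np.diff(lg_map.positions_cM)
    if len(gaps) == 0:
        return 0.0, 0
    return float(gaps.max()), int((gaps > threshold_cM).sum())
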