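"""Two-point recombination-fraction and LOD estimation for S1/F2 genotypes.

For a pair of markers in a selfed heterozygote, each of the two gametes of
an individual is independently recombinant with probability r.  The joint
genotype distribution over {A,H,B}^2 is the convolution over the two
gametes; the number of recombinant gametes per individual is latent only
in the double-heterozygote cell, which makes maximum likelihood a textbook
EM with closed-form steps:

* E step: expected recombinant gametes for the (H,H) cell is
  ``2 r^2 / ((1-r)^2 + r^2)``; every other cell is deterministic
  (0, 1 or 2).
* M step: ``r <- total expected recombinant gametes / (2 n)``.

The LOD score compares the likelihood at the estimate with independence
(r = 1/2).  The Haldane map function converts between r and cM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix
from .errors import ConfigError

#: deterministic recombinant-gamete counts per joint-genotype cell
#: (the [1,1] double-het cell is the latent one, filled per E step)
_K_DET = np.array([[0.0, 1.0, 2.0],
                   [1.0, np.nan, 1.0],
                   [2.0, 1.0, 0.0]])

_EM_TOL = 1e-12
_EM_MAX_ITER = 1000


def haldane_cM(r) -> np.ndarray | float:
    """Map distance in cM for recombination fraction ``r`` (no interference).

    ``d = -50 ln(1 - 2r)``; ``r = 0.5`` maps to ``inf``.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any((r_arr < 0) | (r_arr > 0.5)):
        raise ConfigError("recombination fraction must be in [0, 0.5]")
    with np.errstate(divide="ignore"):
        d = -50.0 * np.log1p(-2.0 * r_arr)
    return float(d) if np.isscalar(r) else d


def haldane_inv(d) -> np.ndarray | float:
    """Inverse Haldane map: ``r = (1 - e^(-2d/100)) / 2`` for ``d >= 0`` cM."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ConfigError("map distance must be >= 0")
    r = 0.5 * -np.expm1(-2.0 * d_arr / 100.0)
    return float(r) if np.isscalar(d) else r


def joint_genotype_probs(r: float) -> np.ndarray:
    """3x3 table P(g1, g2) for genotype pairs in {A,H,B}^2 at fraction ``r``.

    Built from two independent gametes, each recombinant with probability
    ``r``; entries sum to 1.
    """
    if not 0.0 <= r <= 0.5:
        raise ConfigError("recombination fraction must be in [0, 0.5]")
    return _joint_probs(np.asarray(r, dtype=float))


def _joint_probs(r):
    """Vectorised joint table; r of shape S -> output of shape S + (3, 3)."""
    r = np.asarray(r, dtype=float)
    q = 1.0 - r
    corner_nr = q * q / 4.0      # both gametes non-recombinant
    corner_rr = r * r / 4.0      # both recombinant
    edge = r * q / 2.0           # exactly one recombinant
    mid = (q * q + r * r) / 2.0  # double het: 0 or 2 recombinant gametes
    out = np.empty(r.shape + (3, 3), dtype=float)
    out[..., 0, 0] = corner_nr
    out[..., 0, 1] = edge
    out[..., 0, 2] = corner_rr
    out[..., 1, 0] = edge
    out[..., 1, 1] = mid
    out[..., 1, 2] = edge
    out[..., 2, 0] = corner_rr
    out[..., 2, 1] = edge
    out[..., 2, 2] = corner_nr
    return out


def _em_batch(counts: np.ndarray, tol: float = _EM_TOL, max_iter: int = _EM_MAX_ITER,
              track_loglik: bool = False):
    """EM over a batch of 3x3 joint-genotype count tables.

    Parameters
    ----------
    counts : (..., 3, 3) array
    track_loglik : bool
        When true, also return the log10-likelihood trajectory (used by
        monotonicity tests); adds one likelihood evaluation per iteration.

    Returns
    -------
    r : (...) estimates clamped to [0, 0.5]
    lod : (...) LOD scores vs r = 0.5
    (trajectory) : list of (...) arrays, if requested
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum(axis=(-2, -1))
    safe_n = np.where(n > 0, n, 1.0)
    k_det = np.where(np.isnan(_K_DET), 0.0, _K_DET)
    base_rec = (c * k_det).sum(axis=(-2, -1))  # recombinant gametes outside (H,H)
    c_hh = c[..., 1, 1]
    r = np.full(n.shape, 0.25)
    traj = []
    for _ in range(max_iter):
        if track_loglik:
            traj.append(_log10_lik(c, r))
        q2r2 = (1.0 - r) ** 2 + r ** 2
        e_hh = np.where(q2r2 > 0, 2.0 * r ** 2 / q2r2, 0.0)
        r_new = (base_rec + c_hh * e_hh) / (2.0 * safe_n)
        r_new = np.clip(r_new, 0.0, 0.5)
        delta = np.abs(r_new - r)
        r = r_new
        if np.nanmax(delta, initial=0.0) < tol:
            break
    lod = _log10_lik(c, r) - _log10_lik(c, np.full_like(r, 0.5))
    lod = np.maximum(lod, 0.0)
    if track_loglik:
        traj.append(_log10_lik(c, r))
        return r, lod, traj
    return r, lod


def _log10_lik(counts, r):
    p = _joint_probs(r)
    lp = np.log10(np.where(p > 0, p, 1.0))
    term = counts * lp
    # a positive count on a zero-probability cell means -inf likelihood
    term = np.where((counts > 0) & (p <= 0), -np.inf, term)
    return term.sum(axis=(-2, -1))


def estimate_rf_em(joint_counts: np.ndarray):
    """Estimate (r, LOD) from one 3x3 joint-genotype count table.

    Raises for an empty table (all counts zero).
    """
    c = np.asarray(joint_counts, dtype=float)
    if c.shape != (3, 3):
        raise ConfigError("joint_counts must be 3x3")
    if c.sum() <= 0:
        raise ConfigError("joint count table is empty")
    r, lod = _em_batch(c)
    return float(r), float(lod)


@dataclass
class TwoPointMatrix:
    """Symmetric all-pairs linkage summaries over a marker set."""

    marker_ids: np.ndarray
    rf: np.ndarray        # (m, m) recombination fractions, nan where unusable
    lod: np.ndarray       # (m, m) LOD scores, nan where unusable
    n_cotyped: np.ndarray  # (m, m) co-typed individual counts

    def __post_init__(self):
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        m = len(self.marker_ids)
        for name in ("rf", "lod", "n_cotyped"):
            arr = getattr(self, name)
            if arr.shape != (m, m):
                raise ConfigError(f"{name} must be ({m}, {m})")

    def submatrix(self, marker_ids) -> "TwoPointMatrix":
        index = {m: i for i, m in enumerate(self.marker_ids)}
        idx = np.array([index[m] for m in marker_ids], dtype=int)
        return TwoPointMatrix(
            np.asarray(marker_ids, dtype=object),
            self.rf[np.ix_(idx, idx)], self.lod[np.ix_(idx, idx)],
            self.n_cotyped[np.ix_(idx, idx)],
        )


def pair_counts(matrix: GenotypeMatrix) -> np.ndarray:
    """All-pairs 3x3 joint genotype counts, shape (m, m, 3, 3)."""
    X = matrix.calls.T  # markers x individuals
    hots = [(X == g).astype(np.float32) for g in (0, 1, 2)]
    m = matrix.n_markers
    counts = np.empty((m, m, 3, 3), dtype=np.float64)
    for g1 in range(3):
        for g2 in range(3):
            counts[:, :, g1, g2] = hots[g1] @ hots[g2].T
    return counts


def twopoint_all(matrix: GenotypeMatrix, min_informative: int = 20,
                 n_jobs: int = 1) -> TwoPointMatrix:
    """Pairwise rf/LOD over all markers of a genotype matrix.

    Pairs with fewer than ``min_informative`` co-typed individuals are
    reported as ``nan`` (unstable estimates).  ``n_jobs`` chunks the
    independent per-pair EM batches across a thread pool.
    """
    if matrix.n_markers < 2:
        raise ConfigError("need at least two markers")
    counts = pair_counts(matrix)
    m = matrix.n_markers
    n_cotyped = counts.sum(axis=(-2, -1)).astype(np.int64)

    if n_jobs > 1:
        from concurrent.futures import ThreadPoolExecutor

        flat = counts.reshape(m * m, 3, 3)
        chunks = np.array_split(np.arange(m * m), n_jobs * 4)
        r = np.empty(m * m)
        lod = np.empty(m * m)

        def work(idx):
            r[idx], lod[idx] = _em_batch(flat[idx])

        with ThreadPoolExecutor(max_workers=n_jobs) as pool:
            list(pool.map(work, [c for c in chunks if c.size]))
        r = r.reshape(m, m)
        lod = lod.reshape(m, m)
    else:
        r, lod = _em_batch(counts)

    bad = n_cotyped < min_informative
    r[bad] = np.nan
    lod[bad] = np.nan
    np.fill_diagonal(r, 0.0)
    # symmetrise exactly (counts are symmetric up to transpose of the table,
    # and the likelihood is transpose-invariant, but float reduction order
    # can differ)
    r = (r + r.T) / 2.0
    lod_diag = lod.diagonal().copy()
    lod = (lod + lod.T) / 2.0
    np.fill_diagonal(lod, lod_diag)
    return TwoPointMatrix(matrix.marker_ids.copy(), r, lod, n_cotyped)
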