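"""Marker and individual quality-control cascade.

The cascade mirrors the funnel used to distil an informative marker set
from raw genotype calls:

1. drop individuals typed at too few markers;
2. drop markers typed in too few individuals;
3. remove one member of each suspiciously similar individual pair
   (double-sampling);
4. drop markers with an excessive heterozygote fraction;
5. collapse groups of markers with mutually identical genotypes down to
   their best-typed representative.

Every step is idempotent and reports exactly what it removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import GenotypeMatrix
from .errors import ConfigError


@dataclass(frozen=True)
class FilterParams:
    min_markers_per_individual: int = 3500
    min_individuals_per_marker: int = 300
    dup_similarity: float = 0.90
    max_het_fraction: float = 0.90

    def __post_init__(self):
        if self.min_markers_per_individual < 0 or self.min_individuals_per_marker < 0:
            raise ConfigError("count thresholds must be >= 0")
        if not 0.0 < self.dup_similarity <= 1.0:
            raise ConfigError("dup_similarity must be in (0, 1]")
        if not 0.0 <= self.max_het_fraction <= 1.0:
            raise ConfigError("max_het_fraction must be in [0, 1]")


def filter_individuals(matrix: GenotypeMatrix, min_markers: int = 3500):
    """Remove individuals with fewer than ``min_markers`` non-missing calls."""
    typed = matrix.typed_per_individual()
    keep = typed >= min_markers
    removed = list(matrix.individual_ids[~keep])
    return matrix.select_individuals(keep), removed


def filter_markers(matrix: GenotypeMatrix, min_individuals: int = 300):
    """Remove markers typed in fewer than ``min_individuals`` individuals."""
    typed = matrix.typed_per_marker()
    keep = typed >= min_individuals
    removed = list(matrix.marker_ids[~keep])
    return matrix.select_markers(keep), removed


def suggest_individual_threshold(matrix: GenotypeMatrix) -> float:
    """Tukey lower fence (Q1 - 1.5 IQR) of the typed-markers-per-individual
    distribution; an automatic alternative to a fixed outlier threshold."""
    typed = matrix.typed_per_individual().astype(float)
    q1, q3 = np.percentile(typed, [25, 75])
    return q1 - 1.5 * (q3 - q1)


def _one_hot(calls: np.ndarray):
    """Boolean per-genotype indicator stacks (float32 for fast matmul)."""
    return [(calls == g).astype(np.float32) for g in (0, 1, 2)]


def similarity_matrix(matrix: GenotypeMatrix):
    """All-pairs individual similarity.

    Returns ``(sim, n_shared)``: fraction of matching calls among markers
    typed in both individuals, and the count of such markers.  Pairs with
    no shared typed marker get ``nan``.
    """
    X = matrix.calls
    hots = _one_hot(X)
    agree = sum(h @ h.T for h in hots)
    typed = (X >= 0).astype(np.float32)
    shared = typed @ typed.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(shared > 0, agree / shared, np.nan)
    return sim, shared.astype(np.int64)


def genotype_similarity(ind_i: np.ndarray, ind_j: np.ndarray) -> float:
    """Similarity of two call vectors: matches / markers typed in both.

    Returns ``nan`` when the two individuals share no typed marker.
    """
    x = np.asarray(ind_i)
    y = np.asarray(ind_j)
    both = (x >= 0) & (y >= 0)
    if not both.any():
        return float("nan")
    return float((x[both] == y[both]).mean())


def remove_duplicate_individuals(matrix: GenotypeMatrix, dup_similarity: float = 0.90):
    """Drop one member of each pair of unusually similar individuals.

    Pairs at or above ``dup_similarity`` are processed greedily by
    descending similarity; from each still-intact pair the member with more
    missing data is removed (ties: the lexicographically larger id).
    Transitive clusters are therefore whittled down pair by pair.
    """
    sim, _ = similarity_matrix(matrix)
    n = matrix.n_individuals
    iu, ju = np.triu_indices(n, k=1)
    hit = np.nan_to_num(sim[iu, ju], nan=-1.0) >= dup_similarity
    pairs = sorted(
        zip(sim[iu[hit], ju[hit]], iu[hit], ju[hit]),
        key=lambda t: (-t[0], matrix.individual_ids[t[1]], matrix.individual_ids[t[2]]),
    )
    missing = (matrix.calls < 0).sum(axis=1)
    alive = np.ones(n, dtype=bool)
    removed_pairs = []
    for s, i, j in pairs:
        if not (alive[i] and alive[j]):
            continue
        ids = matrix.individual_ids
        if missing[i] > missing[j]:
            drop, keep = i, j
        elif missing[j] > missing[i]:
            drop, keep = j, i
        else:
            drop, keep = (i, j) if ids[i] > ids[j] else (j, i)
        alive[drop] = False
        removed_pairs.append((ids[keep], ids[drop], float(s)))
    return matrix.select_individuals(alive), removed_pairs


def filter_excess_het(matrix: GenotypeMatrix, max_het_fraction: float = 0.90):
    """Drop markers whose heterozygote fraction among typed calls exceeds
    ``max_het_fraction`` (strictly greater)."""
    typed = matrix.typed_per_marker().astype(float)
    n_het = (matrix.calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(typed > 0, n_het / typed, 0.0)
    keep = frac <= max_het_fraction
    removed = list(matrix.marker_ids[~keep])
    return matrix.select_markers(keep), removed


def collapse_redundant_markers(matrix: GenotypeMatrix):
    """Collapse markers with mutually identical genotypes.

    Two markers *match* when their calls agree at every individual typed in
    both (and they share at least one typed individual).  The match
    relation is not transitive, so groups are its union-find closure; from
    each group the marker with the fewest missing calls survives (ties:
    smallest id).

    Returns ``(matrix, groups)`` where ``groups`` lists the redundancy
    groups (including singletons) as lists of marker ids, the survivor
    first.
    """
    X = matrix.calls.T  # markers x individuals
    hots = [(X == g).astype(np.float32) for g in (0, 1, 2)]
    agree = sum(h @ h.T for h in hots)
    typed = (X >= 0).astype(np.float32)
    shared = typed @ typed.T
    match = (np.abs(agree - shared) < 0.5) & (shared >= 1)
    n_comp, labels = connected_components(csr_matrix(match), directed=False)
    missing = (X < 0).sum(axis=1)
    ids = matrix.marker_ids
    groups = []
    keep_mask = np.zeros(matrix.n_markers, dtype=bool)
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        best = min(members, key=lambda m: (missing[m], ids[m]))
        keep_mask[best] = True
        groups.append([ids[best]] + [ids[m] for m in members if m != best])
    # preserve input marker order in the output matrix
    order = np.flatnonzero(keep_mask)
    return matrix.select_markers(order), groups


def apply_filter_cascade(matrix: GenotypeMatrix, params: FilterParams = FilterParams()):
    """Run the full QC cascade; returns ``(matrix, stages)``.

    ``stages`` is a list of dicts logging, per stage, the markers and
    individuals going in, removed, and coming out.
    """
    stages = []

    def log(stage, before, after, removed):
        stages.append({
            "stage": stage,
            "individuals_in": before.n_individuals, "markers_in": before.n_markers,
            "individuals_out": after.n_individuals, "markers_out": after.n_markers,
            "removed": removed,
        })

    m0 = matrix
    m1, removed = filter_individuals(m0, params.min_markers_per_individual)
    log("individuals_min_typed", m0, m1, removed)
    m2, removed = filter_markers(m1, params.min_individuals_per_marker)
    log("markers_min_typed", m1, m2, removed)
    m3, removed_pairs = remove_duplicate_individuals(m2, params.dup_similarity)
    log("duplicate_individuals", m2, m3, removed_pairs)
    m4, removed = filter_excess_het(m3, params.max_het_fraction)
    log("excess_het_markers", m3, m4, removed)
    m5, groups = collapse_redundant_markers(m4)
    log("redundant_markers", m4, m5, [g[1:] for g in groups if len(g) > 1])
    return m5, stages
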