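"""Mirror-marker phasing: augmentation, linkage grouping, phase resolution.

Calls of a selfed population are phase-unknown: whether a marker's "A"
homozygote came from parental haplotype 1 or 2 is arbitrary, so two
tightly linked markers recorded in opposite phase look unlinked (their
apparent recombination fraction is reflected above 1/2 and clamped).  The
mirror strategy makes phase explicit: every marker gets an artificial
twin with complementary calls (A<->B, H and missing unchanged).  After
grouping, each chromosome appears as a *pair* of complementary linkage
groups; keeping one group per pair selects a consistent phase for every
marker in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import GenotypeMatrix
from .errors import ConfigError, PhaseInconsistencyError
from .twopoint import TwoPointMatrix

#: reserved suffix marking mirror twins
MIRROR_SUFFIX = "_mir"


@dataclass(frozen=True)
class GroupingParams:
    """Linkage-group formation thresholds.

    Markers are directly linked when ``rf <= max_rf`` **and**
    ``lod >= min_lod``; groups are the connected components of that
    relation.  Defaults follow the published run (max.rf 0.05, min.lod 10);
    ``min_group_size`` 8 drops the stray groups ("at most 7 markers").
    """

    max_rf: float = 0.05
    min_lod: float = 10.0
    min_group_size: int = 8
    expected_chromosomes: int | None = None

    def __post_init__(self):
        if not 0.0 < self.max_rf <= 0.5:
            raise ConfigError("max_rf must be in (0, 0.5]")
        if self.min_lod < 0:
            raise ConfigError("min_lod must be >= 0")
        if self.min_group_size < 1:
            raise ConfigError("min_group_size must be >= 1")


@dataclass
class MirrorSet:
    """Bijection between original markers and their mirror twins."""

    originals: np.ndarray
    mirrors: np.ndarray

    def __post_init__(self):
        self.originals = np.asarray(self.originals, dtype=object)
        self.mirrors = np.asarray(self.mirrors, dtype=object)
        self._partner = {}
        for o, m in zip(self.originals, self.mirrors):
            self._partner[o] = m
            self._partner[m] = o

    def partner(self, marker_id: str) -> str:
        return self._partner[marker_id]

    def is_mirror(self, marker_id: str) -> bool:
        return marker_id.endswith(MIRROR_SUFFIX)

    @staticmethod
    def base_id(marker_id: str) -> str:
        return marker_id[:-len(MIRROR_SUFFIX)] if marker_id.endswith(MIRROR_SUFFIX) else marker_id


def mirror_call(call):
    """Complementary call: A<->B, H->H, missing unchanged.

    Accepts an integer code (or array of codes) or a call character.
    """
    if isinstance(call, str):
        return {"A": "B", "B": "A", "H": "H", "NA": "NA", "-": "-"}[call]
    codes = np.asarray(call)
    out = np.where(codes >= 0, 2 - codes, codes)
    if np.isscalar(call) or codes.shape == ():
        return int(out)
    return out.astype(np.int8)


def mirror_augment(matrix: GenotypeMatrix):
    """Double the marker set with complementary mirror twins.

    Mirror ids are the original ids with the reserved suffix appended;
    augmenting an already-augmented matrix is refused.

    Returns ``(augmented_matrix, mirrorset)``.
    """
    for m in matrix.marker_ids:
        if m.endswith(MIRROR_SUFFIX):
            raise ConfigError(
                f"marker {m!r} already carries the mirror suffix {MIRROR_SUFFIX!r}"
            )
    mirrors = np.array([m + MIRROR_SUFFIX for m in matrix.marker_ids], dtype=object)
    calls = np.concatenate([matrix.calls, mirror_call(matrix.calls)], axis=1)
    ids = np.concatenate([matrix.marker_ids, mirrors])
    return (GenotypeMatrix(calls, matrix.individual_ids.copy(), ids),
            MirrorSet(matrix.marker_ids.copy(), mirrors))


def form_linkage_groups(twopoint: TwoPointMatrix, params: GroupingParams = GroupingParams()):
    """Partition markers into linkage groups by the rf/LOD link rule.

    Returns groups as lists of marker ids, sorted by decreasing size
    (ties: smallest member id), singletons included.
    """
    rf, lod = twopoint.rf, twopoint.lod
    with np.errstate(invalid="ignore"):
        linked = (rf <= params.max_rf) & (lod >= params.min_lod)
    linked &= ~np.isnan(rf) & ~np.isnan(lod)
    np.fill_diagonal(linked, False)
    n_comp, labels = connected_components(csr_matrix(linked), directed=False)
    ids = twopoint.marker_ids
    groups = [list(ids[labels == c]) for c in range(n_comp)]
    groups.sort(key=lambda g: (-len(g), min(g)))
    return groups


def pair_mirror_groups(groups, mirrorset: MirrorSet):
    """Match linkage groups into mirror pairs.

    Two groups pair when the mirror image of one's marker set equals the
    other's.  Groups without a partner are returned as orphans.  A group
    containing both a marker and its own mirror is a phase inconsistency
    and raises.

    Returns ``(pairs, orphans)`` with each pair ordered
    ``(group, mirror_group)`` by smallest contained base id.
    """
    group_sets = [frozenset(g) for g in groups]
    for g in group_sets:
        for m in g:
            if mirrorset.partner(m) in g:
                raise PhaseInconsistencyError(
                    f"group contains marker {m!r} and its mirror {mirrorset.partner(m)!r}"
                )
    lookup = {g: i for i, g in enumerate(group_sets)}
    paired = [False] * len(groups)
    pairs, orphans = [], []
    for i, g in enumerate(group_sets):
        if paired[i]:
            continue
        image = frozenset(mirrorset.partner(m) for m in g)
        j = lookup.get(image)
        if j is None or j == i or paired[j]:
            continue
        paired[i] = paired[j] = True
        # orient the pair so its first group holds the smallest base id
        # as an original (unsuffixed) marker
        first, second = (i, j)
        smallest = min(MirrorSet.base_id(m) for m in g)
        if smallest not in g:
            first, second = j, i
        pairs.append((groups[first], groups[second]))
    for i in range(len(groups)):
        if not paired[i]:
            orphans.append(groups[i])
    return pairs, orphans


def resolve_phase(matrix: GenotypeMatrix, pairs, params: GroupingParams,
                  mirrorset: MirrorSet):
    """Keep one phase-consistent group per mirror pair and restore ids.

    From each pair the group containing the lexicographically smallest
    original (unsuffixed) marker id is retained -- a deterministic stand-in
    for an arbitrary choice.  Pairs whose groups are smaller than
    ``min_group_size`` are dropped; when ``expected_chromosomes`` is set,
    only the largest ``expected_chromosomes`` pairs are kept.  Mirror ids
    in retained groups have their suffix stripped (their complementary
    calls *are* the phase assignment).

    Returns ``(phased_matrix, kept_groups, flipped)`` where ``kept_groups``
    lists marker ids (restored) per retained group and ``flipped`` maps
    each restored marker id to True when its mirror twin was the retained
    copy.
    """
    kept_pairs = [(a, b) for a, b in pairs if len(a) >= params.min_group_size]
    kept_pairs.sort(key=lambda p: (-len(p[0]), min(MirrorSet.base_id(m) for m in p[0])))
    if params.expected_chromosomes is not None:
        kept_pairs = kept_pairs[:params.expected_chromosomes]

    kept_groups = []
    flipped = {}
    keep_cols = []
    new_ids = []
    for group, _mirror_group in kept_pairs:
        restored = []
        for m in sorted(group):
            base = MirrorSet.base_id(m)
            keep_cols.append(m)
            new_ids.append(base)
            flipped[base] = mirrorset.is_mirror(m)
            restored.append(base)
        kept_groups.append(restored)
    sub = matrix.select_markers(keep_cols)
    phased = GenotypeMatrix(sub.calls, sub.individual_ids, np.asarray(new_ids, dtype=object))
    return phased, kept_groups, flipped


def phase_markers(matrix: GenotypeMatrix, twopoint_fn, params: GroupingParams = GroupingParams(),
                  min_informative: int = 20, n_jobs: int = 1):
    """Full phasing stage: augment -> two-point -> group -> pair -> resolve.

    ``twopoint_fn`` is usually :func:`capmap.twopoint.twopoint_all` (passed
    in to keep this module free of the pairwise numerics).

    Returns a dict with the phased matrix, kept groups, flips, the raw
    group partition, pairs, orphans, and the augmented two-point matrix.
    """
    augmented, mirrorset = mirror_augment(matrix)
    tp = twopoint_fn(augmented, min_informative=min_informative, n_jobs=n_jobs)
    groups = form_linkage_groups(tp, params)
    pairs, orphans = pair_mirror_groups(groups, mirrorset)
    phased, kept_groups, flipped = resolve_phase(augmented, pairs, params, mirrorset)
    return {
        "matrix": phased,
        "groups": kept_groups,
        "flipped": flipped,
        "partition": groups,
        "pairs": pairs,
        "orphans": orphans,
        "twopoint": tp,
        "mirrorset": mirrorset,
    }
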