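"""Truth-known simulation of a selfed (S1) mapping population.

A single heterozygous parent is selfed; each offspring is the fusion of two
independently drawn gametes.  Meioses follow the Haldane model: the number
of crossovers on a chromosome of genetic length L cM is Poisson with mean
L/100 and crossover positions are uniform (no interference).  Every marker
is heterozygous in the parent, with a randomised linkage phase, so that
downstream mirror-marker phasing is genuinely exercised.

Read counts are emitted per (marker, individual) cell with a
negative-binomial depth distribution (long right tail, default variance
roughly three times the mean), binomial allele sampling given the true
genotype, a small rate of non-parental base calls, and a configurable
fraction of dropped (zero-depth) cells.

Optional selection reshapes segregation ratios by rejection sampling:

* ``zygotic``       -- a zygote carrying the disfavoured *genotype* at the
  selection locus survives with probability ``strength``;
* ``gametic_one_sex`` -- the first gamete of each fusion (one parental sex)
  carrying the disfavoured *allele* survives with probability ``strength``;
* ``gametic_both``  -- both gametes are subject to the allele test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .errors import ConfigError, SimulationError

#: Genetic lengths (cM) of the twelve linkage groups of the apple-mint map,
#: used as the default simulated chromosome lengths.
TABLE2_LENGTHS_CM = (
    87.65, 89.48, 63.96, 77.20, 66.11, 122.61,
    84.09, 58.26, 56.32, 92.64, 57.72, 86.14,
)

_REJECTION_CAP = 10_000  # attempts per individual before giving up

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SelectionSpec:
    """One selection locus acting on a simulated population.

    ``disfavored`` is an allele (``"A"``/``"B"``) for the gametic modes and
    a homozygous genotype (``"AA"``/``"BB"``) for ``zygotic``.  ``strength``
    is the survival probability of a carrier (0 = fully lethal).
    """

    chromosome: int
    position_cM: float
    mode: str
    disfavored: str
    strength: float

    def __post_init__(self):
        if self.mode not in ("zygotic", "gametic_one_sex", "gametic_both"):
            raise ConfigError(f"unknown selection mode {self.mode!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigError("selection strength must be in [0, 1]")
        expected = ("AA", "BB") if self.mode == "zygotic" else ("A", "B")
        if self.disfavored not in expected:
            raise ConfigError(
                f"disfavored must be one of {expected} for mode {self.mode!r}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated S1 capture-genotyping experiment.

    Defaults emulate the study conditions of the apple-mint map: 12
    chromosomes with the published genetic lengths, n=415 individuals,
    mean on-target coverage 96X with an overdispersed (negative binomial)
    tail, and ~3% missing cells.
    """

    chrom_lengths_cM: Sequence[float] = TABLE2_LENGTHS_CM
    markers_per_chromosome: object = 100  # int, or list of explicit cM position arrays
    n_individuals: int = 415
    coverage_mean: float = 96.0
    coverage_dispersion: float = 48.0  # NB shape k; var = mu + mu^2/k (~3x mean at default)
    seq_error_rate: float = 0.001
    missing_rate: float = 0.03
    selection_loci: tuple = ()
    seed: int = 0
    # synthetic physical coordinates: Mbp per cM and the central recombination
    # coldspot (a cM-compressed segment occupying a large bp share)
    mbp_per_cM: float = 0.56
    coldspot_cM_range: tuple = (0.4, 0.6)
    coldspot_bp_fraction: float = 0.5

    def __post_init__(self):
        if len(self.chrom_lengths_cM) == 0:
            raise ConfigError("need at least one chromosome")
        if any(L <= 0 for L in self.chrom_lengths_cM):
            raise ConfigError("chromosome lengths must be > 0")
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        for name in ("seq_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ConfigError("coverage parameters must be positive")
        for spec in self.selection_loci:
            c = spec.chromosome
            if not 0 <= c < len(self.chrom_lengths_cM):
                raise ConfigError(f"selection chromosome {c} out of range")
            if not 0.0 <= spec.position_cM <= self.chrom_lengths_cM[c]:
                raise ConfigError("selection position outside its chromosome")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths_cM)

    def marker_positions(self) -> list:
        """Per-chromosome arrays of strictly increasing marker positions (cM)."""
        out = []
        if isinstance(self.markers_per_chromosome, (int, np.integer)):
            n = int(self.markers_per_chromosome)
            if n < 1:
                raise ConfigError("markers_per_chromosome must be >= 1")
            for L in self.chrom_lengths_cM:
                out.append(np.linspace(0.0, L, n) if n > 1 else np.array([L / 2.0]))
        else:
            if len(self.markers_per_chromosome) != self.n_chromosomes:
                raise ConfigError("one marker position array per chromosome required")
            for L, pos in zip(self.chrom_lengths_cM, self.markers_per_chromosome):
                pos = np.asarray(pos, dtype=float)
                if np.any(np.diff(pos) <= 0):
                    raise ConfigError("marker positions must be strictly increasing")
                if pos.size and (pos[0] < 0 or pos[-1] > L):
                    raise ConfigError("marker positions outside chromosome length")
                out.append(pos)
        return out


@dataclass
class SimTruth:
    """Ground truth of one simulated population.

    ``phase`` records, per marker, which parental haplotype (0 or 1) carries
    the ``A`` allele.  ``gamete_haps`` holds, for each of the two gametes of
    each individual, the parental-haplotype indicator at every marker, so the
    true genotype code (number of B alleles) is recomputable under any phase.
    """

    config: SimConfig
    metadata: pd.DataFrame          # marker_id, chromosome, position_cM, scaffold, pos_bp, alleles
    phase: np.ndarray               # (n_markers,) int8 in {0,1}
    positions: list                 # per-chromosome cM arrays
    selection_markers: list = field(default_factory=list)  # snapped marker index per SelectionSpec
    gamete_haps: np.ndarray = None  # (2, n_individuals, n_markers) int8
    crossovers: list = None         # [individual][gamete][chromosome] -> cM array
    individual_ids: np.ndarray = None

    @property
    def marker_ids(self) -> np.ndarray:
        return self.metadata["marker_id"].to_numpy()

    @property
    def chromosome_of(self) -> np.ndarray:
        return self.metadata["chromosome"].to_numpy()

    def genotypes(self, phase: np.ndarray | None = None) -> GenotypeMatrix:
        """True genotype matrix under ``phase`` (default: the recorded phase).

        Flipping the phase of a marker subset yields exactly the
        complementary calls at those markers -- the mirror-flip invariance
        the phasing stage relies on.
        """
        if self.gamete_haps is None:
            raise SimulationError("population not simulated yet")
        p = self.phase if phase is None else np.asarray(phase, dtype=np.int8)
        codes = ((self.gamete_haps[0] != p[None, :]).astype(np.int8)
                 + (self.gamete_haps[1] != p[None, :]).astype(np.int8))
        return GenotypeMatrix(codes, self.individual_ids, self.marker_ids)

    def crossovers_frame(self) -> pd.DataFrame:
        rows = []
        for i, per_gamete in enumerate(self.crossovers):
            for g, per_chrom in enumerate(per_gamete):
                for c, breaks in enumerate(per_chrom):
                    for x in breaks:
                        rows.append((self.individual_ids[i], g, c, float(x)))
        return pd.DataFrame(rows, columns=["individual_id", "gamete", "chromosome", "position_cM"])


# ---------------------------------------------------------------------------
# seeding: one master seed; independent deterministic streams per purpose and
# per individual, so growing n_individuals never reshuffles earlier ones.
# ---------------------------------------------------------------------------
_STREAM_PARENT = 0
_STREAM_INDIVIDUAL = 1
_STREAM_READS = 2


def _rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def _physical_positions(pos_cM: np.ndarray, length_cM: float, config: SimConfig) -> np.ndarray:
    """Monotone cM -> bp map with a compressed central coldspot."""
    lo, hi = config.coldspot_cM_range
    f = pos_cM / length_cM if length_cM > 0 else np.zeros_like(pos_cM)
    cold = config.coldspot_bp_fraction
    edge = (1.0 - cold) / 2.0
    bp_frac = np.interp(f, [0.0, lo, hi, 1.0], [0.0, edge, edge + cold, 1.0])
    total_bp = length_cM * config.mbp_per_cM * 1e6
    bp = np.round(bp_frac * total_bp).astype(np.int64) + 1
    # guard against collisions from rounding
    for i in range(1, len(bp)):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
    return bp


def simulate_parent(config: SimConfig) -> SimTruth:
    """Lay out markers and draw the parent's per-marker linkage phase.

    Every marker is heterozygous in the parent by construction; the phase
    (which haplotype carries the A allele) is randomised per marker.
    """
    positions = config.marker_positions()
    rng = _rng(config.seed, _STREAM_PARENT)
    rows = []
    for c, (L, pos) in enumerate(zip(config.chrom_lengths_cM, positions)):
        bp = _physical_positions(pos, L, config)
        for j, (cm, b) in enumerate(zip(pos, bp)):
            rows.append((f"c{c + 1:02d}m{j + 1:04d}", c, float(cm), f"S{c + 1:02d}", int(b)))
    metadata = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_cM", "scaffold", "pos_bp"])
    n_markers = len(metadata)
    phase = rng.integers(0, 2, size=n_markers).astype(np.int8)
    allele_idx = rng.integers(0, 4, size=(n_markers, 2))
    # force the two parental alleles to differ
    clash = allele_idx[:, 0] == allele_idx[:, 1]
    allele_idx[clash, 1] = (allele_idx[clash, 1] + 1 + rng.integers(0, 3, clash.sum())) % 4
    metadata["allele_a"] = _BASES[allele_idx[:, 0]]
    metadata["allele_b"] = _BASES[allele_idx[:, 1]]

    snapped = []
    for spec in config.selection_loci:
        pos = positions[spec.chromosome]
        local = int(np.argmin(np.abs(pos - spec.position_cM)))
        offset = int(np.searchsorted(metadata["chromosome"].to_numpy(), spec.chromosome))
        snapped.append(offset + local)
    return SimTruth(config=config, metadata=metadata, phase=phase,
                    positions=positions, selection_markers=snapped)


def simulate_gamete(truth: SimTruth, chromosome: int, rng: np.random.Generator):
    """Draw one gamete for one chromosome.

    Returns ``(hap, breakpoints)`` where ``hap`` gives the parental
    haplotype (0/1) carried at each marker of the chromosome and
    ``breakpoints`` the sorted crossover positions in cM.
    """
    if not 0 <= chromosome < truth.config.n_chromosomes:
        raise ConfigError(f"chromosome {chromosome} out of range")
    L = truth.config.chrom_lengths_cM[chromosome]
    pos = truth.positions[chromosome]
    n_xo = rng.poisson(L / 100.0)
    breaks = np.sort(rng.uniform(0.0, L, size=n_xo))
    start = int(rng.integers(0, 2))
    hap = (start + np.searchsorted(breaks, pos, side="right")) % 2
    return hap.astype(np.int8), breaks


def _allele_at(hap: int, phase: int) -> str:
    return "A" if hap == phase else "B"


def simulate_s1_population(truth: SimTruth, config: SimConfig | None = None) -> SimTruth:
    """Self the parent: fuse two independent gametes per individual.

    Selection is applied by rejection sampling (see module docstring);
    after ``10_000`` rejected attempts for one individual a
    :class:`~capmap.errors.SimulationError` is raised.
    """
    config = config or truth.config
    n_ind = config.n_individuals
    n_markers = len(truth.metadata)
    chrom_of = truth.chromosome_of
    chrom_slices = [np.flatnonzero(chrom_of == c) for c in range(config.n_chromosomes)]

    gametic = [(spec, truth.selection_markers[k])
               for k, spec in enumerate(config.selection_loci)
               if spec.mode in ("gametic_one_sex", "gametic_both")]
    zygotic = [(spec, truth.selection_markers[k])
               for k, spec in enumerate(config.selection_loci)
               if spec.mode == "zygotic"]

    haps = np.empty((2, n_ind, n_markers), dtype=np.int8)
    crossovers = []
    for i in range(n_ind):
        rng = _rng(config.seed, _STREAM_INDIVIDUAL, i)
        attempts = 0
        while True:
            ind_haps = np.empty((2, n_markers), dtype=np.int8)
            ind_breaks = [[None] * config.n_chromosomes for _ in range(2)]
            for g in range(2):
                for c in range(config.n_chromosomes):
                    while True:
                        hap, breaks = simulate_gamete(truth, c, rng)
                        ok = True
                        for spec, midx in gametic:
                            if spec.chromosome != c:
                                continue
                            if spec.mode == "gametic_one_sex" and g != 0:
                                continue
                            local = midx - chrom_slices[c][0]
                            allele = _allele_at(hap[local], truth.phase[midx])
                            if allele == spec.disfavored and rng.random() >= spec.strength:
                                ok = False
                                break
                        if ok:
                            break
                        attempts += 1
                        if attempts > _REJECTION_CAP:
                            raise SimulationError(
                                f"individual {i}: gamete rejection exceeded {_REJECTION_CAP} attempts"
                            )
                    ind_haps[g, chrom_slices[c]] = hap
                    ind_breaks[g][c] = breaks
            accept = True
            for spec, midx in zygotic:
                code = int(ind_haps[0, midx] != truth.phase[midx]) + int(ind_haps[1, midx] != truth.phase[midx])
                genotype = {0: "AA", 1: "AB", 2: "BB"}[code]
                if genotype == spec.disfavored and rng.random() >= spec.strength:
                    accept = False
                    break
            if accept:
                break
            attempts += 1
            if attempts > _REJECTION_CAP:
                raise SimulationError(
                    f"individual {i}: zygote rejection exceeded {_REJECTION_CAP} attempts"
                )
        haps[:, i, :] = ind_haps
        crossovers.append(ind_breaks)

    truth.gamete_haps = haps
    truth.crossovers = crossovers
    truth.individual_ids = np.array([f"ind{i + 1:04d}" for i in range(n_ind)], dtype=object)
    return truth


def simulate_read_counts(genotypes: GenotypeMatrix, config: SimConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit a long-format allele-count table for a true genotype matrix.

    Depth per cell is negative binomial around ``coverage_mean``; a
    binomial share ``seq_error_rate`` of reads are non-parental ("other")
    base calls; the remaining parental reads split binomially with allele-A
    probability 1-e / 0.5 / e for true genotypes AA / AB / BB.  A
    ``missing_rate`` fraction of cells is zeroed out entirely.  The output
    satisfies ``count_a + count_b + count_other == depth`` in every row.
    """
    rng = rng or _rng(config.seed, _STREAM_READS)
    g = genotypes.calls  # (n_ind, n_markers)
    n_ind, n_markers = g.shape
    size = g.size
    mu, k = config.coverage_mean, config.coverage_dispersion
    depth = rng.negative_binomial(k, k / (k + mu), size=size)
    e = config.seq_error_rate
    other = rng.binomial(depth, e)
    rem = depth - other
    p_a = np.array([1.0 - e, 0.5, e])[g.ravel()]
    count_a = rng.binomial(rem, p_a)
    count_b = rem - count_a
    if config.missing_rate > 0:
        drop = rng.random(size) < config.missing_rate
        depth = np.where(drop, 0, depth)
        count_a = np.where(drop, 0, count_a)
        count_b = np.where(drop, 0, count_b)
        other = np.where(drop, 0, other)
    table = pd.DataFrame({
        "marker_id": np.tile(genotypes.marker_ids, n_ind),
        "individual_id": np.repeat(genotypes.individual_ids, n_markers),
        "depth": depth,
        "count_a": count_a,
        "count_b": count_b,
        "count_other": other,
    })
    return table


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: parent -> population -> read counts.

    Returns ``(truth, counts)`` where ``counts`` is the long-format
    allele-count table.
    """
    truth = simulate_parent(config)
    simulate_s1_population(truth, config)
    counts = simulate_read_counts(truth.genotypes(), config)
    return truth, counts
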