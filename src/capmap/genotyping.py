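"""Genotype calling from targeted-capture allele counts.

A cell is called from its read depth and the split of reads between the two
parental alleles:

* depth outside ``[min_cov, max_cov]`` -> missing (``NA``);
* with ``f`` the minor parental-allele fraction over parental reads only:
  homozygous if the minor allele is absent or ``f < homo_minor_max``;
  heterozygous if both parental fractions are ``>= het_min``;
  anything in between -> ``NA``.

Markers for which too few individuals have in-range coverage are dropped
entirely (``marker_cov_fraction``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, validate_allele_counts
from .errors import ConfigError, GenotypingError


@dataclass(frozen=True)
class CallingParams:
    """Coverage and allele-fraction thresholds for genotype calling.

    Defaults: depth window 20-1000X, homozygote minor-allele ceiling 5%
    (strict ``<``), heterozygote floor 30% per allele (inclusive ``>=``),
    and markers kept only when at least 80% of individuals have in-range
    coverage.
    """

    min_cov: int = 20
    max_cov: int = 1000
    homo_minor_max: float = 0.05
    het_min: float = 0.30
    marker_cov_fraction: float = 0.80

    def __post_init__(self):
        if not 0 <= self.homo_minor_max < self.het_min <= 0.5:
            raise ConfigError("need 0 <= homo_minor_max < het_min <= 0.5")
        if not 0 < self.min_cov < self.max_cov:
            raise ConfigError("need 0 < min_cov < max_cov")
        if not 0.0 <= self.marker_cov_fraction <= 1.0:
            raise ConfigError("marker_cov_fraction must be in [0, 1]")


def _call_codes(count_a, count_b, count_other, params: CallingParams) -> np.ndarray:
    """Vectorised calling; returns int8 codes (-1/0/1/2)."""
    a = np.asarray(count_a, dtype=np.int64)
    b = np.asarray(count_b, dtype=np.int64)
    o = np.asarray(count_other, dtype=np.int64)
    if (a < 0).any() or (b < 0).any() or (o < 0).any():
        raise GenotypingError("allele counts must be non-negative")
    depth = a + b + o
    out = np.full(a.shape, -1, dtype=np.int8)
    parental = a + b
    usable = (depth >= params.min_cov) & (depth <= params.max_cov) & (parental > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.where(parental > 0, a / parental, 0.0)
        fb = np.where(parental > 0, b / parental, 0.0)
    call_a = usable & ((b == 0) | (fb < params.homo_minor_max))
    call_b = usable & ((a == 0) | (fa < params.homo_minor_max))
    call_h = usable & (fa >= params.het_min) & (fb >= params.het_min)
    out[call_a] = 0
    out[call_h] = 1
    out[call_b] = 2
    return out


def call_genotype(count_a: int, count_b: int, count_other: int,
                  params: CallingParams = CallingParams()) -> str:
    """Call a single cell; returns ``"A"``, ``"H"``, ``"B"`` or ``"NA"``."""
    code = int(_call_codes([count_a], [count_b], [count_other], params)[0])
    return {0: "A", 1: "H", 2: "B", -1: "NA"}[code]


def call_matrix(table: pd.DataFrame, params: CallingParams = CallingParams()):
    """Call every (marker, individual) cell of an allele-count table.

    Cells absent from the table are treated as zero depth.  Markers whose
    fraction of individuals with in-range coverage falls below
    ``params.marker_cov_fraction`` are dropped.

    Returns
    -------
    matrix : GenotypeMatrix
    coverage_fraction : pandas.Series
        Per input marker, the fraction of individuals with in-range depth.
    dropped : list of str
        Marker ids removed by the coverage-fraction rule.
    """
    validate_allele_counts(table)
    if table.duplicated(["marker_id", "individual_id"]).any():
        dup = table[table.duplicated(["marker_id", "individual_id"])].iloc[0]
        raise GenotypingError(
            f"duplicate allele-count row for marker {dup['marker_id']!r}, "
            f"individual {dup['individual_id']!r}"
        )
    m_codes, m_ids = pd.factorize(table["marker_id"])
    i_codes, i_ids = pd.factorize(table["individual_id"])
    shape = (len(i_ids), len(m_ids))
    a = np.zeros(shape, dtype=np.int64)
    b = np.zeros(shape, dtype=np.int64)
    o = np.zeros(shape, dtype=np.int64)
    a[i_codes, m_codes] = table["count_a"].to_numpy()
    b[i_codes, m_codes] = table["count_b"].to_numpy()
    o[i_codes, m_codes] = table["count_other"].to_numpy()

    codes = _call_codes(a, b, o, params)
    depth = a + b + o
    in_range = (depth >= params.min_cov) & (depth <= params.max_cov)
    frac = in_range.mean(axis=0)
    coverage_fraction = pd.Series(frac, index=list(m_ids), name="in_range_fraction")
    keep = frac >= params.marker_cov_fraction
    dropped = [m for m, k in zip(m_ids, keep) if not k]
    matrix = GenotypeMatrix(codes[:, keep], np.asarray(i_ids, dtype=object),
                            np.asarray(m_ids, dtype=object)[keep])
    return matrix, coverage_fraction, dropped


def enrichment_stats(on_target_mean_cov: float, off_target_mean_cov: float) -> float:
    """Capture fold enrichment: on-target over off-target mean coverage.

    A zero off-target mean with positive on-target coverage reports
    ``inf`` (perfect enrichment) rather than raising.
    """
    if on_target_mean_cov < 0 or off_target_mean_cov < 0:
        raise ConfigError("mean coverages must be non-negative")
    if off_target_mean_cov == 0:
        return 0.0 if on_target_mean_cov == 0 else math.inf
    return on_target_mean_cov / off_target_mean_cov
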