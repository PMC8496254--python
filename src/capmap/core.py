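"""Core in-memory containers shared across the pipeline.

Genotypes of a selfed (S1) population are coded like an F2 intercross:
``A`` and ``B`` are the two parental homozygotes, ``H`` the heterozygote,
and ``-`` a missing call.  Internally calls are small integers:

====  ====
code  call
====  ====
 0    A
 1    H
 2    B
-1    missing
====  ====

The integer coding is chosen so that the heterozygote sits between the two
homozygotes: the genotype code equals the number of "B" alleles carried,
which makes mirror flipping (``g -> 2 - g``) and obligate-crossover
arithmetic (``|g1 - g2|``) one-liners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

#: genotype call characters indexed by code (missing handled separately)
CALL_CHARS = np.array(["A", "H", "B"], dtype=object)

#: accepted spellings of a missing call on input
MISSING_STRINGS = frozenset({"-", "NA", "", "N/A", "nan"})

CHAR_TO_CODE = {"A": 0, "H": 1, "B": 2}


def codes_to_chars(codes: np.ndarray) -> np.ndarray:
    """Map an integer call array to characters, missing -> ``-``."""
    out = np.full(codes.shape, "-", dtype=object)
    typed = codes >= 0
    out[typed] = CALL_CHARS[codes[typed]]
    return out


def chars_to_codes(chars) -> np.ndarray:
    """Map call characters (A/H/B plus missing spellings) to integer codes."""
    arr = np.asarray(chars, dtype=object)
    out = np.empty(arr.shape, dtype=np.int8)
    flat_in = arr.ravel()
    flat_out = out.ravel()
    for i, c in enumerate(flat_in):
        s = str(c).strip()
        if s in CHAR_TO_CODE:
            flat_out[i] = CHAR_TO_CODE[s]
        elif s in MISSING_STRINGS:
            flat_out[i] = -1
        else:
            raise ConfigError(f"unknown genotype code {c!r}")
    return out


@dataclass
class GenotypeMatrix:
    """Rectangular individuals x markers matrix of genotype calls.

    Parameters
    ----------
    calls:
        ``(n_individuals, n_markers)`` int8 array with values in
        ``{-1, 0, 1, 2}``.
    individual_ids, marker_ids:
        Unique string identifiers for rows and columns.
    """

    calls: np.ndarray
    individual_ids: np.ndarray
    marker_ids: np.ndarray
    _marker_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.calls = np.ascontiguousarray(np.asarray(self.calls, dtype=np.int8))
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.calls.ndim != 2:
            raise ConfigError("calls must be 2-D (individuals x markers)")
        if self.calls.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ConfigError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        bad = (self.calls < -1) | (self.calls > 2)
        if bad.any():
            raise ConfigError("genotype codes must be in {-1, 0, 1, 2}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ConfigError("individual ids are not unique")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ConfigError("marker ids are not unique")
        self._marker_index = None

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_index(self) -> dict:
        if self._marker_index is None:
            self._marker_index = {m: i for i, m in enumerate(self.marker_ids)}
        return self._marker_index

    def typed_per_individual(self) -> np.ndarray:
        """Number of non-missing calls per individual."""
        return (self.calls >= 0).sum(axis=1)

    def typed_per_marker(self) -> np.ndarray:
        """Number of non-missing calls per marker."""
        return (self.calls >= 0).sum(axis=0)

    # -- subsetting ------------------------------------------------------
    def select_individuals(self, keep) -> "GenotypeMatrix":
        keep = self._as_row_indexer(keep, self.individual_ids)
        return GenotypeMatrix(self.calls[keep], self.individual_ids[keep], self.marker_ids)

    def select_markers(self, keep) -> "GenotypeMatrix":
        keep = self._as_row_indexer(keep, self.marker_ids)
        return GenotypeMatrix(self.calls[:, keep], self.individual_ids, self.marker_ids[keep])

    def marker_calls(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_index[marker_id]]

    @staticmethod
    def _as_row_indexer(keep, ids):
        keep = np.asarray(keep)
        if keep.dtype == bool:
            return np.flatnonzero(keep)
        if keep.dtype.kind in "iu":
            return keep
        index = {m: i for i, m in enumerate(ids)}
        return np.array([index[k] for k in keep], dtype=int)

    # -- conversion ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Character DataFrame (individuals as rows, markers as columns)."""
        return pd.DataFrame(
            codes_to_chars(self.calls),
            index=pd.Index(self.individual_ids, name="individual_id"),
            columns=list(self.marker_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        return cls(
            chars_to_codes(frame.to_numpy()),
            np.asarray(frame.index, dtype=object),
            np.asarray(frame.columns, dtype=object),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy(), self.individual_ids.copy(), self.marker_ids.copy())


#: required columns of the long-format allele-count table
ALLELE_COUNT_COLUMNS = ("marker_id", "individual_id", "depth", "count_a", "count_b", "count_other")

#: required columns of the marker metadata table
METADATA_COLUMNS = ("marker_id", "scaffold", "pos_bp", "allele_a", "allele_b")


def validate_allele_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Check the allele-count invariants (counts >= 0, they sum to depth)."""
    missing = [c for c in ALLELE_COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigError(f"allele-count table lacks columns: {missing}")
    counts = table[["count_a", "count_b", "count_other"]].to_numpy()
    if (counts < 0).any() or (table["depth"].to_numpy() < 0).any():
        raise ConfigError("allele counts must be non-negative")
    if not np.array_equal(counts.sum(axis=1), table["depth"].to_numpy()):
        raise ConfigError("count_a + count_b + count_other must equal depth")
    return table
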