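"""On-disk formats: allele-count and metadata TSV, qtl-style cross CSV,
map TSV, truth tables, and optional VCF ingestion.

All writers are deterministic (stable row order, floats at 6 significant
digits) so identical inputs produce byte-identical files.  Readers accept
gzip-compressed input transparently (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (ALLELE_COUNT_COLUMNS, METADATA_COLUMNS, GenotypeMatrix,
                   MISSING_STRINGS, chars_to_codes, codes_to_chars,
                   validate_allele_counts)
from .errors import FormatError

_FLOAT_FMT = "%.6g"


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_tsv(path, required, dtypes) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for col, dtype in dtypes.items():
        if dtype is int:
            converted = pd.to_numeric(table[col], errors="coerce")
            bad = converted.isna() | (converted != converted.round())
            if bad.any():
                line = int(bad.idxmax()) + 2  # header is line 1
                raise FormatError(f"{path}: line {line}: non-integer value in column {col!r}")
            table[col] = converted.astype(np.int64)
    return table


def read_allele_counts(path) -> pd.DataFrame:
    """Read a long-format allele-count TSV (optionally gzipped)."""
    table = _read_tsv(path, ALLELE_COUNT_COLUMNS,
                      {c: int for c in ("depth", "count_a", "count_b", "count_other")})
    try:
        validate_allele_counts(table)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return table[list(ALLELE_COUNT_COLUMNS)]


def write_allele_counts(table: pd.DataFrame, path) -> None:
    validate_allele_counts(table)
    out = table[list(ALLELE_COUNT_COLUMNS)]
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_marker_metadata(path) -> pd.DataFrame:
    table = _read_tsv(path, METADATA_COLUMNS, {"pos_bp": int})
    if (table["pos_bp"] < 1).any():
        raise FormatError(f"{path}: pos_bp must be 1-based (>= 1)")
    return table


def write_marker_metadata(metadata: pd.DataFrame, path) -> None:
    cols = [c for c in metadata.columns]
    with _open_text(path, "wt") as fh:
        metadata[cols].to_csv(fh, sep="\t", index=False, lineterminator="\n",
                              float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# cross CSV (qtl intercross dialect)
# ---------------------------------------------------------------------------

def write_cross_csv(matrix: GenotypeMatrix, path, groups=None, positions=None) -> None:
    """Write the qtl-style intercross CSV.

    Row 1: individual-id column header then marker ids; row 2: linkage
    group per marker; row 3: cM position (blank before mapping); body:
    calls in ``{A,H,B,-}``.
    """
    groups = {} if groups is None else groups
    positions = {} if positions is None else positions
    chars = codes_to_chars(matrix.calls)
    with _open_text(path, "wt") as fh:
        fh.write(",".join(["id"] + list(matrix.marker_ids)) + "\n")
        fh.write(",".join([""] + [str(groups.get(m, "1")) for m in matrix.marker_ids]) + "\n")
        fh.write(",".join([""] + [
            (_FLOAT_FMT % positions[m]) if m in positions else ""
            for m in matrix.marker_ids]) + "\n")
        for i, ind in enumerate(matrix.individual_ids):
            fh.write(",".join([str(ind)] + list(chars[i])) + "\n")


def read_cross_csv(path):
    """Read a qtl-style intercross CSV.

    Returns ``(matrix, groups, positions)``; ``groups`` maps marker id to
    its group label, ``positions`` (possibly empty) to its cM position.
    """
    with _open_text(path, "rt") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4:
        raise FormatError(f"{path}: expected 3 header rows plus at least one individual")
    header = lines[0].split(",")
    marker_ids = header[1:]
    group_row = lines[1].split(",")[1:]
    pos_row = lines[2].split(",")[1:]
    if len(group_row) != len(marker_ids) or len(pos_row) != len(marker_ids):
        raise FormatError(f"{path}: header rows have inconsistent widths")
    groups = dict(zip(marker_ids, group_row))
    positions = {}
    for m, p in zip(marker_ids, pos_row):
        if p.strip():
            try:
                positions[m] = float(p)
            except ValueError as exc:
                raise FormatError(f"{path}: bad cM position {p!r} for marker {m!r}") from exc
    ind_ids, rows = [], []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(marker_ids) + 1:
            raise FormatError(f"{path}: line {lineno}: expected {len(marker_ids) + 1} fields")
        ind_ids.append(parts[0])
        for j, cell in enumerate(parts[1:]):
            s = cell.strip()
            if s not in ("A", "H", "B") and s not in MISSING_STRINGS:
                raise FormatError(
                    f"{path}: line {lineno}: unknown genotype code {cell!r} "
                    f"(individual {parts[0]!r}, marker {marker_ids[j]!r})"
                )
        rows.append(parts[1:])
    codes = chars_to_codes(np.array(rows, dtype=object))
    matrix = GenotypeMatrix(codes, np.array(ind_ids, dtype=object),
                            np.array(marker_ids, dtype=object))
    return matrix, groups, positions


# ---------------------------------------------------------------------------
# map + truth tables
# ---------------------------------------------------------------------------

def write_map_tsv(maps, path, metadata: pd.DataFrame | None = None) -> None:
    """One row per mapped marker, sorted by group then position."""
    meta = metadata.set_index("marker_id") if metadata is not None else None
    rows = []
    for lg in maps:
        for m, cm in zip(lg.marker_ids, lg.positions_cM):
            scaffold, bp = "", ""
            if meta is not None and m in meta.index:
                scaffold = meta.at[m, "scaffold"]
                bp = int(meta.at[m, "pos_bp"])
            rows.append((lg.group_id, m, cm, scaffold, bp))
    out = pd.DataFrame(rows, columns=["linkage_group", "marker_id", "position_cM",
                                      "scaffold", "pos_bp"])
    out = out.sort_values(["linkage_group", "position_cM"], kind="stable")
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format=_FLOAT_FMT)


def write_truth(truth, out_dir) -> None:
    """Write simulator ground truth: phase, crossovers, true genotypes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phase = truth.metadata[["marker_id"]].copy()
    phase["phase"] = truth.phase
    with _open_text(out_dir / "truth_phase.tsv", "wt") as fh:
        phase.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    with _open_text(out_dir / "truth_crossovers.tsv", "wt") as fh:
        truth.crossovers_frame().to_csv(fh, sep="\t", index=False, lineterminator="\n",
                                        float_format=_FLOAT_FMT)
    frame = truth.genotypes().to_frame()
    with _open_text(out_dir / "truth_genotypes.tsv", "wt") as fh:
        frame.to_csv(fh, sep="\t", lineterminator="\n")


def write_twopoint_heatmap_table(twopoint, path) -> None:
    """Long-format rf/LOD export for heat-map style review of an order."""
    ids = twopoint.marker_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    out = pd.DataFrame({
        "marker_1": ids[iu], "marker_2": ids[ju],
        "rf": twopoint.rf[iu, ju], "lod": twopoint.lod[iu, ju],
        "n_cotyped": twopoint.n_cotyped[iu, ju],
    })
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def read_vcf_allele_depths(path, metadata: pd.DataFrame):
    """Build an allele-count table from a VCF with per-sample AD fields.

    Sites are matched to ``metadata`` rows by contig + position; the two
    parental alleles are looked up among REF/ALT and their depths
    extracted (all remaining depth is "other").  Sites absent from the
    metadata are skipped and counted.

    Returns ``(table, n_skipped)``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment guard
        raise FormatError("reading VCF requires the cyvcf2 package") from exc
    meta = metadata.set_index(["scaffold", "pos_bp"])
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    n_skipped = 0
    for variant in vcf:
        key = (variant.CHROM, variant.POS)
        if key not in meta.index:
            n_skipped += 1
            continue
        rec = meta.loc[key]
        marker_id = rec["marker_id"]
        alleles = [variant.REF] + list(variant.ALT)
        ad = variant.format("AD")
        if ad is None:
            raise FormatError(f"{path}: site {variant.CHROM}:{variant.POS} lacks the AD field")
        ad = np.maximum(np.asarray(ad, dtype=np.int64), 0)

        def depth_of(allele):
            return ad[:, alleles.index(allele)] if allele in alleles else np.zeros(len(samples), dtype=np.int64)

        da = depth_of(rec["allele_a"])
        db = depth_of(rec["allele_b"])
        total = ad.sum(axis=1)
        other = total - da - db
        for s, sample in enumerate(samples):
            rows.append((marker_id, sample, int(total[s]), int(da[s]), int(db[s]), int(other[s])))
    table = pd.DataFrame(rows, columns=list(ALLELE_COUNT_COLUMNS))
    return table, n_skipped
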