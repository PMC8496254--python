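"""Map assessment: segregation distortion, crossover screening, Marey
comparison, and per-group summary tables.

An S1 (selfed-heterozygote) population segregates 1:2:1 (AA:AB:BB).
Distortion is a chi-square goodness-of-fit against that expectation per
marker, with a Bonferroni-adjusted significance threshold over the final
marker count.  Distorted markers are flagged, never removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix
from .errors import ConfigError
from .ordering import LinkageGroupMap, count_obligate_xo, map_gaps


def segregation_test(counts) -> dict:
    """Chi-square goodness-of-fit of (n_AA, n_H, n_BB) against 1:2:1.

    Returns a record dict; all-zero counts give an NA record.
    """
    n_aa, n_h, n_bb = (int(c) for c in counts)
    if min(n_aa, n_h, n_bb) < 0:
        raise ConfigError("genotype counts must be non-negative")
    total = n_aa + n_h + n_bb
    if total == 0:
        return {"n_AA": 0, "n_H": 0, "n_BB": 0,
                "chi_square": np.nan, "p_value": np.nan}
    expected = np.array([0.25, 0.5, 0.25]) * total
    chi2, p = stats.chisquare([n_aa, n_h, n_bb], f_exp=expected)
    return {"n_AA": n_aa, "n_H": n_h, "n_BB": n_bb,
            "chi_square": float(chi2), "p_value": float(p)}


def distortion_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker segregation-distortion records (no flags yet)."""
    rows = []
    for j, mid in enumerate(matrix.marker_ids):
        col = matrix.calls[:, j]
        rec = segregation_test(((col == 0).sum(), (col == 1).sum(), (col == 2).sum()))
        rec["marker_id"] = mid
        rows.append(rec)
    return pd.DataFrame(rows)[["marker_id", "n_AA", "n_H", "n_BB", "chi_square", "p_value"]]


def flag_distorted(records: pd.DataFrame, alpha: float = 0.05,
                   n_tests: int | None = None) -> pd.DataFrame:
    """Bonferroni flagging: distorted iff ``p < alpha / n_tests``.

    ``n_tests`` defaults to the number of records (the final marker count).
    """
    if n_tests is None:
        n_tests = len(records)
    if n_tests < 1:
        raise ConfigError("n_tests must be >= 1")
    out = records.copy()
    out["distorted"] = out["p_value"] < (alpha / n_tests)
    out.loc[out["p_value"].isna(), "distorted"] = False
    return out


def crossover_screen(maps, matrix: GenotypeMatrix, bounds=None) -> pd.DataFrame:
    """Obligate crossover totals per individual across all linkage groups.

    ``bounds = (lo, hi)`` flags individuals outside the inclusive range;
    by default nothing is flagged (report only).  Nothing is removed here.
    """
    total = np.zeros(matrix.n_individuals, dtype=np.int64)
    for lg in maps:
        per, _ = count_obligate_xo(lg.marker_ids, matrix)
        total += per
    out = pd.DataFrame({"individual_id": matrix.individual_ids, "n_crossovers": total})
    if bounds is not None:
        lo, hi = bounds
        out["flagged"] = (total < lo) | (total > hi)
    else:
        out["flagged"] = False
    return out


def _longest_discordant_run(bp: np.ndarray, direction: int) -> int:
    """Length (in markers) of the longest run moving against ``direction``."""
    if len(bp) < 2:
        return 0
    step_ok = np.sign(np.diff(bp)) == direction
    worst = run = 0
    for ok in step_ok:
        run = 0 if ok else run + 1
        worst = max(worst, run)
    return worst + 1 if worst else 0


def marey_table(maps, marker_metadata: pd.DataFrame):
    """Genetic-vs-physical comparison per mapped marker and per group.

    Returns ``(per_marker, per_group)``.  Per group: the majority
    scaffold, counts of markers from other scaffolds / unintegrated
    contigs, the absolute Spearman correlation of cM with bp among
    majority-scaffold markers, and the longest discordant (anti-monotone)
    marker run -- a proxy for an inversion.
    """
    meta = marker_metadata.set_index("marker_id")
    marker_rows, group_rows = [], []
    for lg in maps:
        missing = [m for m in lg.marker_ids if m not in meta.index]
        if missing:
            raise ConfigError(f"metadata missing for mapped markers, e.g. {missing[0]!r}")
        scaffolds = np.array([meta.at[m, "scaffold"] for m in lg.marker_ids], dtype=object)
        bp = np.array([meta.at[m, "pos_bp"] for m in lg.marker_ids], dtype=float)
        for m, cm, sc, b in zip(lg.marker_ids, lg.positions_cM, scaffolds, bp):
            marker_rows.append((lg.group_id, m, float(cm), sc, int(b)))
        majority = pd.Series(scaffolds).value_counts().index[0]
        on_maj = scaffolds == majority
        is_contig = np.array([not str(s).startswith("S") for s in scaffolds])
        n_other = int((~on_maj & ~is_contig).sum())
        n_contig = int((~on_maj & is_contig).sum())
        if on_maj.sum() >= 2:
            rho = stats.spearmanr(lg.positions_cM[on_maj], bp[on_maj]).statistic
            direction = int(np.sign(rho)) or 1
            run = _longest_discordant_run(bp[on_maj], direction)
            rho = abs(float(rho))
        else:
            rho, run = np.nan, 0
        group_rows.append((lg.group_id, majority, n_other, n_contig, rho, run))
    per_marker = pd.DataFrame(
        marker_rows, columns=["linkage_group", "marker_id", "position_cM", "scaffold", "pos_bp"])
    per_group = pd.DataFrame(
        group_rows, columns=["linkage_group", "majority_scaffold", "n_from_other_scaffold",
                             "n_from_contig", "abs_spearman", "longest_discordant_run"])
    return per_marker, per_group


def map_summary(maps, distortion: pd.DataFrame | None = None,
                metadata: pd.DataFrame | None = None,
                gap_threshold_cM: float = 10.0) -> pd.DataFrame:
    """Per-linkage-group summary rows plus a totals row.

    Marker density is length/n_markers rounded to 2 decimals; the percent
    of distorted markers is rounded to 2 decimals.
    """
    flagged = {}
    if distortion is not None:
        if "distorted" not in distortion.columns:
            raise ConfigError("distortion table lacks the 'distorted' flag column")
        flagged = dict(zip(distortion["marker_id"], distortion["distorted"]))
    per_group_meta = None
    if metadata is not None:
        _, per_group_meta = marey_table(maps, metadata)
        per_group_meta = per_group_meta.set_index("linkage_group")
    rows = []
    for lg in maps:
        n = len(lg.marker_ids)
        if n == 0:
            raise ConfigError(f"linkage group {lg.group_id!r} is empty")
        largest, n_gaps = map_gaps(lg, gap_threshold_cM)
        n_dist = int(sum(bool(flagged.get(m, False)) for m in lg.marker_ids))
        n_other = n_contig = 0
        if per_group_meta is not None:
            n_other = int(per_group_meta.at[lg.group_id, "n_from_other_scaffold"])
            n_contig = int(per_group_meta.at[lg.group_id, "n_from_contig"])
        rows.append({
            "linkage_group": lg.group_id,
            "n_markers": n,
            "n_from_other_scaffold": n_other,
            "n_from_contig": n_contig,
            "density_cM": round(lg.length_cM / n, 2),
            "length_cM": lg.length_cM,
            "largest_gap_cM": largest,
            "n_gaps_gt_threshold": n_gaps,
            "n_distorted": n_dist,
            "pct_distorted": round(100.0 * n_dist / n, 2),
        })
    out = pd.DataFrame(rows)
    totals = {
        "linkage_group": "total",
        "n_markers": int(out["n_markers"].sum()),
        "n_from_other_scaffold": int(out["n_from_other_scaffold"].sum()),
        "n_from_contig": int(out["n_from_contig"].sum()),
        "density_cM": round(out["length_cM"].sum() / out["n_markers"].sum(), 2),
        "length_cM": float(out["length_cM"].sum()),
        "largest_gap_cM": float(out["largest_gap_cM"].max()),
        "n_gaps_gt_threshold": int(out["n_gaps_gt_threshold"].sum()),
        "n_distorted": int(out["n_distorted"].sum()),
        "pct_distorted": round(100.0 * out["n_distorted"].sum() / out["n_markers"].sum(), 2),
    }
    return pd.concat([out, pd.DataFrame([totals])], ignore_index=True)


def scaffold_summary(table: pd.DataFrame, not_targeted_mbp: float = 0.0) -> pd.DataFrame:
    """Targeted-sequence summary with totals (per-scaffold/contig rows).

    ``table`` columns: ``name``, ``type`` ("scaffold" or "contig"),
    ``size_mbp``, ``n_targeted``, ``n_retained``.  Percent of genome uses
    the grand total including any untargeted space (``not_targeted_mbp``).
    """
    required = {"name", "type", "size_mbp", "n_targeted", "n_retained"}
    if not required.issubset(table.columns):
        raise ConfigError(f"scaffold table needs columns {sorted(required)}")
    total_genome = table["size_mbp"].sum() + not_targeted_mbp
    out = table.copy()
    out["pct_genome"] = (out["size_mbp"] / total_genome * 100.0).round(2)
    totals = []
    for kind in ("scaffold", "contig"):
        sub = out[out["type"] == kind]
        if len(sub) == 0:
            continue
        totals.append({
            "name": f"{kind}_total", "type": kind,
            "size_mbp": float(sub["size_mbp"].sum()),
            "n_targeted": int(sub["n_targeted"].sum()),
            "n_retained": int(sub["n_retained"].sum()),
            "pct_genome": round(float(sub["size_mbp"].sum()) / total_genome * 100.0, 3),
        })
    if not_targeted_mbp:
        totals.append({
            "name": "not_targeted", "type": "untargeted",
            "size_mbp": float(not_targeted_mbp),
            "n_targeted": 0, "n_retained": 0,
            "pct_genome": round(not_targeted_mbp / total_genome * 100.0, 3),
        })
    return pd.concat([out, pd.DataFrame(totals)], ignore_index=True)
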