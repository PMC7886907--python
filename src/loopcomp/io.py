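"""Genomic file formats and candidate-pair bookkeeping.

Tables and conventions
----------------------
All coordinates are 0-based half-open (BED convention) internally; all
distances are midpoint-to-midpoint in bp.

* **sites**: one row per CTCF-binding site with columns
  ``site_id, chrom, peak_start, peak_end, pos, orientation, signal_raw, x``
  (``pos`` is the motif midpoint once orientation is annotated, the peak
  summit/midpoint before; ``orientation`` is "forward" / "reverse" /
  "ambiguous"; ``x`` is signal normalized to genome mean 1).
* **pairs**: one row per candidate site pair with columns
  ``chrom, i, j, pos_i, pos_j, d, x_i, x_j, ori_i, ori_j, ori_class,
  label, pet_count`` plus the model terms once scored.
* **loops**: measured loop records with columns
  ``chrom, anchor1_start, anchor1_end, anchor2_start, anchor2_end,
  pet_count`` read from BEDPE (PET count in the score column).

The tab-separated pair table (header ``chrom pos_i pos_j x_i x_j ori_i ori_j
label pet_count``) is the exchange format between pipeline stages and
round-trips exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import AMBIGUOUS, FORWARD, REVERSE, orientation_class

__all__ = [
    "read_narrowpeak",
    "write_narrowpeak",
    "normalize_signal",
    "read_loops_bedpe",
    "write_loops_bedpe",
    "read_pairs_table",
    "write_pairs_table",
    "enumerate_pairs",
    "label_pairs",
    "LabelReport",
]

SITE_COLUMNS = ["site_id", "chrom", "peak_start", "peak_end", "pos", "orientation", "signal_raw"]
LOOP_COLUMNS = ["chrom", "anchor1_start", "anchor1_end", "anchor2_start", "anchor2_end", "pet_count"]
PAIR_TABLE_COLUMNS = ["chrom", "pos_i", "pos_j", "x_i", "x_j", "ori_i", "ori_j", "label", "pet_count"]

_NARROWPEAK_SIGNAL_COLS = {"score": 4, "signalValue": 6, "pValue": 7, "qValue": 8}


def _data_lines(path):
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_narrowpeak(path, signal_col: str = "signalValue") -> pd.DataFrame:
    """Read ENCODE narrowPeak / BED6+ peaks into a site table.

    ``signal_col`` selects which column is taken as binding intensity
    ("score", "signalValue", "pValue" or "qValue").  ``pos`` is set to the
    summit (start + 10th-column offset) when available, else the peak
    midpoint; orientation is left "ambiguous" until annotated.  Malformed
    lines are rejected with their line number.
    """
    if signal_col not in _NARROWPEAK_SIGNAL_COLS:
        raise ValueError(f"signal_col must be one of {sorted(_NARROWPEAK_SIGNAL_COLS)}")
    want = _NARROWPEAK_SIGNAL_COLS[signal_col]
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) <= want:
            raise ValueError(
                f"{path}:{lineno}: expected at least {want + 1} columns for "
                f"signal column {signal_col!r}, got {len(fields)}"
            )
        try:
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            signal = float(fields[want])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})") from exc
        if start < 0 or start >= end:
            raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        pos = (start + end) // 2
        if len(fields) >= 10:
            try:
                summit = int(fields[9])
            except ValueError:
                summit = -1
            if summit >= 0:
                pos = start + summit
        rows.append((chrom, start, end, pos, signal))
    df = pd.DataFrame(rows, columns=["chrom", "peak_start", "peak_end", "pos", "signal_raw"])
    df.insert(0, "site_id", [f"site_{k:06d}" for k in range(len(df))])
    df["orientation"] = AMBIGUOUS
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_narrowpeak(sites: pd.DataFrame, path) -> None:
    """Write a site table as narrowPeak (signal in column 7, summit offset from pos)."""
    with open(path, "w") as out:
        for row in sites.itertuples(index=False):
            strand = {"forward": "+", "reverse": "-"}.get(row.orientation, ".")
            summit = int(row.pos) - int(row.peak_start)
            out.write(
                f"{row.chrom}\t{int(row.peak_start)}\t{int(row.peak_end)}\t{row.site_id}\t0\t"
                f"{strand}\t{row.signal_raw:.6g}\t-1\t-1\t{summit}\n"
            )


def normalize_signal(sites: pd.DataFrame, genome_mean: float | None = None) -> pd.DataFrame:
    """Add the normalized intensity ``x = signal_raw / genome-average signal``.

    By default the average is taken over the retained sites themselves, so
    mean(x) is exactly 1.  When the genome-wide track average is known (it
    is background-dominated and much smaller than peak signals), pass it as
    ``genome_mean``; occupancies are then substantially higher.
    """
    if "signal_raw" not in sites.columns or sites["signal_raw"].isna().any():
        raise ValueError("signal_raw must be present for all sites")
    mean = sites["signal_raw"].mean() if genome_mean is None else float(genome_mean)
    if not len(sites) or mean <= 0:
        raise ValueError("cannot normalize: site signals are empty or all zero")
    out = sites.copy()
    out["x"] = out["signal_raw"] / mean
    return out


def read_loops_bedpe(path) -> pd.DataFrame:
    """Read intra-chromosomal loops from BEDPE; PET count is the score column.

    Requires anchor1 upstream of and non-overlapping with anchor2 on the same
    chromosome; violations are reported with their line number.
    """
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: BEDPE needs at least 6 columns")
        try:
            c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
            c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
            pet = int(float(fields[7])) if len(fields) >= 8 else 1
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})") from exc
        if c1 != c2:
            raise ValueError(f"{path}:{lineno}: inter-chromosomal loop {c1} vs {c2}")
        if s1 >= e1 or s2 >= e2:
            raise ValueError(f"{path}:{lineno}: invalid anchor interval")
        if e1 > s2:
            raise ValueError(f"{path}:{lineno}: anchors must be ordered and non-overlapping")
        if pet < 1:
            raise ValueError(f"{path}:{lineno}: pet_count must be >= 1, got {pet}")
        rows.append((c1, s1, e1, s2, e2, pet))
    return pd.DataFrame(rows, columns=LOOP_COLUMNS)


def write_loops_bedpe(loops: pd.DataFrame, path) -> None:
    with open(path, "w") as out:
        for k, row in enumerate(loops.itertuples(index=False)):
            out.write(
                f"{row.chrom}\t{int(row.anchor1_start)}\t{int(row.anchor1_end)}\t"
                f"{row.chrom}\t{int(row.anchor2_start)}\t{int(row.anchor2_end)}\t"
                f"loop_{k:06d}\t{int(row.pet_count)}\n"
            )


def write_pairs_table(pairs: pd.DataFrame, path) -> None:
    """Write the tab-separated exchange table for candidate pairs."""
    out = pd.DataFrame(
        {
            "chrom": pairs["chrom"],
            "pos_i": pairs["pos_i"].astype(int),
            "pos_j": pairs["pos_j"].astype(int),
            "x_i": pairs["x_i"],
            "x_j": pairs["x_j"],
            "ori_i": pairs["ori_i"],
            "ori_j": pairs["ori_j"],
            "label": pairs.get("label", pd.Series(0, index=pairs.index)).astype(int),
            "pet_count": pairs.get("pet_count", pd.Series(0, index=pairs.index)).astype(int),
        }
    )
    for col in ("p_ij", "w_ij", "D_ij", "LC_ij"):
        if col in pairs.columns:
            out[col] = pairs[col]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pairs_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a pair table; returns (sites, pairs) reconstructed from it.

    Sites are deduplicated on (chrom, pos); pair rows reference them through
    generated ids so the result plugs directly into the model functions.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PAIR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pair table missing columns {missing}")
    left = df[["chrom", "pos_i", "x_i", "ori_i"]].rename(
        columns={"pos_i": "pos", "x_i": "x", "ori_i": "orientation"}
    )
    right = df[["chrom", "pos_j", "x_j", "ori_j"]].rename(
        columns={"pos_j": "pos", "x_j": "x", "ori_j": "orientation"}
    )
    sites = (
        pd.concat([left, right])
        .drop_duplicates(["chrom", "pos"])
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    sites["site_id"] = [f"site_{k:06d}" for k in range(len(sites))]
    sites["peak_start"] = sites["pos"] - 1
    sites["peak_end"] = sites["pos"] + 1
    sites["signal_raw"] = sites["x"]
    lookup = sites.set_index(["chrom", "pos"])["site_id"]
    pairs = df.copy()
    pairs["i"] = lookup.loc[list(zip(df["chrom"], df["pos_i"]))].to_numpy()
    pairs["j"] = lookup.loc[list(zip(df["chrom"], df["pos_j"]))].to_numpy()
    pairs["d"] = pairs["pos_j"] - pairs["pos_i"]
    pairs["ori_class"] = orientation_class(pairs["ori_i"].to_numpy(), pairs["ori_j"].to_numpy())
    return sites, pairs


def enumerate_pairs(sites: pd.DataFrame, max_span: int = 1_000_000) -> pd.DataFrame:
    """All same-chromosome site pairs with 0 < d <= max_span.

    Sites with ambiguous orientation are excluded (their loop geometry is
    undefined); the default 1 Mb span covers over 96% of measured loops.
    """
    usable = sites[sites["orientation"].isin([FORWARD, REVERSE])]
    usable = usable.sort_values(["chrom", "pos"], kind="mergesort")
    frames = []
    for chrom, grp in usable.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        n = len(grp)
        if n < 2:
            continue
        hi = np.searchsorted(pos, pos + max_span, side="right")
        i_idx = np.repeat(np.arange(n), hi - np.arange(n) - 1)
        j_idx = np.concatenate([np.arange(k + 1, hi[k]) for k in range(n)]) if n else np.array([], int)
        # drop zero-distance duplicates (co-located midpoints)
        keep = pos[j_idx] > pos[i_idx]
        i_idx, j_idx = i_idx[keep], j_idx[keep]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "i": grp["site_id"].to_numpy()[i_idx],
                    "j": grp["site_id"].to_numpy()[j_idx],
                    "pos_i": pos[i_idx],
                    "pos_j": pos[j_idx],
                    "d": pos[j_idx] - pos[i_idx],
                    "x_i": grp["x"].to_numpy()[i_idx] if "x" in grp else np.nan,
                    "x_j": grp["x"].to_numpy()[j_idx] if "x" in grp else np.nan,
                    "ori_i": grp["orientation"].to_numpy()[i_idx],
                    "ori_j": grp["orientation"].to_numpy()[j_idx],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "i", "j", "pos_i", "pos_j", "d", "x_i", "x_j", "ori_i", "ori_j", "ori_class"]
        )
    pairs = pd.concat(frames, ignore_index=True)
    pairs["ori_class"] = orientation_class(pairs["ori_i"].to_numpy(), pairs["ori_j"].to_numpy())
    return pairs


@dataclass
class LabelReport:
    """Bookkeeping of how measured loops mapped onto candidate pairs."""

    n_loops: int = 0
    n_positive: int = 0
    n_ambiguous_anchor: int = 0
    n_unmatched_anchor: int = 0
    n_below_min_pet: int = 0
    n_outside_candidates: int = 0
    dropped_lines: list = field(default_factory=list)


def label_pairs(
    pairs: pd.DataFrame,
    sites: pd.DataFrame,
    loops: pd.DataFrame,
    min_pet: int = 4,
) -> tuple[pd.DataFrame, LabelReport]:
    """Label candidate pairs from measured loops.

    A pair is positive iff each anchor of some loop overlaps (>= 1 bp)
    exactly one retained site's peak, those sites are the pair's anchors, and
    the loop's PET count reaches ``min_pet`` (4 is the GM12878-style filter,
    3 the HeLa-style one).  Loops whose anchor hits more than one peak are
    ambiguous and dropped (counted in the report); all other pairs are
    negatives.  Emits a warning when no anchor overlaps any peak, the
    signature of an assembly mismatch.
    """
    report = LabelReport(n_loops=len(loops))
    trees: dict[str, IntervalTree] = {}
    for row in sites.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.peak_start, row.peak_end, row.site_id
        )
    pairs = pairs.reset_index(drop=True).copy()
    pairs["label"] = 0
    pairs["pet_count"] = 0
    index = {(row.i, row.j): k for k, row in enumerate(pairs.itertuples(index=False))}
    pos_by_id = sites.set_index("site_id")["pos"]

    any_overlap = False
    for ln, loop in enumerate(loops.itertuples(index=False)):
        tree = trees.get(loop.chrom)
        hits1 = sorted(h.data for h in tree.overlap(loop.anchor1_start, loop.anchor1_end)) if tree else []
        hits2 = sorted(h.data for h in tree.overlap(loop.anchor2_start, loop.anchor2_end)) if tree else []
        if hits1 or hits2:
            any_overlap = True
        if len(hits1) > 1 or len(hits2) > 1:
            report.n_ambiguous_anchor += 1
            report.dropped_lines.append(ln)
            continue
        if not hits1 or not hits2:
            report.n_unmatched_anchor += 1
            continue
        i, j = hits1[0], hits2[0]
        if pos_by_id[i] > pos_by_id[j]:
            i, j = j, i
        key = (i, j)
        if key not in index:
            report.n_outside_candidates += 1
            continue
        k = index[key]
        pairs.loc[k, "pet_count"] = max(pairs.loc[k, "pet_count"], loop.pet_count)
        if loop.pet_count >= min_pet:
            pairs.loc[k, "label"] = 1
            report.n_positive += 1
        else:
            report.n_below_min_pet += 1
    if len(loops) and not any_overlap:
        warnings.warn(
            "no loop anchor overlaps any peak; peaks and loops may come from "
            "different assemblies",
            stacklevel=2,
        )
    return pairs, report
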