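"""Predicting the effect of CTCF-site and Cohesin-cycle perturbations.

Because loop competition couples neighboring loops, disrupting one binding
site does more than kill its own loops: every pair spanning the site is
released from competition and gains probability, while pairs on disjoint
intervals are untouched.  This module applies site-level edits (deletion,
inversion, intensity scaling), summarizes the before/after probabilities,
builds the binned contact-ratio map used to classify "Crossing" vs
"Outside" interactions around a disrupted site, and scans the Cohesin
pass-through probability ``s`` to emulate WAPL knockout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import enumerate_pairs
from .model import FORWARD, REVERSE, ModelParams, score_pairs

__all__ = [
    "Perturbation",
    "apply_perturbation",
    "perturbation_report",
    "CrossingOutsideMap",
    "crossing_outside_map",
    "waplko_scan",
]


@dataclass
class Perturbation:
    """A single-site edit.

    ``delete`` zeroes the site's intensity (the site row is retained so the
    competition bookkeeping stays explicit, but its occupancy becomes 0);
    ``invert`` flips the motif orientation, leaving intensity unchanged
    unless a measured post-edit intensity is supplied; ``scale`` multiplies
    the intensity by ``scale_factor`` (a factor < 1 models a weakened
    motif).
    """

    site_id: str
    action: str
    scale_factor: float | None = None
    replacement_x: float | None = None

    def __post_init__(self) -> None:
        if self.action not in ("delete", "invert", "scale"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "scale":
            if self.scale_factor is None or self.scale_factor < 0:
                raise ValueError("scale requires scale_factor >= 0")


def apply_perturbation(sites: pd.DataFrame, pert: Perturbation) -> pd.DataFrame:
    """Return a modified copy of the site table."""
    if pert.site_id not in set(sites["site_id"]):
        raise KeyError(f"unknown site_id {pert.site_id!r}")
    out = sites.copy().reset_index(drop=True)
    k = out.index[out["site_id"] == pert.site_id][0]
    if pert.action == "delete":
        out.loc[k, "x"] = 0.0
        out.loc[k, "signal_raw"] = 0.0
    elif pert.action == "invert":
        ori = out.loc[k, "orientation"]
        out.loc[k, "orientation"] = {FORWARD: REVERSE, REVERSE: FORWARD}.get(ori, ori)
        if pert.replacement_x is not None:
            out.loc[k, "x"] = pert.replacement_x
    else:
        out.loc[k, "x"] = out.loc[k, "x"] * pert.scale_factor
        if pert.replacement_x is not None:
            out.loc[k, "x"] = pert.replacement_x
    return out


def perturbation_report(
    sites: pd.DataFrame,
    pairs: pd.DataFrame,
    pert: Perturbation,
    params: ModelParams,
    lc: str = "approx",
) -> pd.DataFrame:
    """Per-pair probabilities before and after the edit.

    Inverted sites keep their candidate pairs but change orientation class;
    the returned table carries p_before, p_after and their ratio for the
    user to juxtapose with 4C-style measurements.
    """
    before = score_pairs(sites, pairs, params, lc=lc)
    mutated = apply_perturbation(sites, pert)
    drop_cols = [c for c in ("ori_class",) if c in pairs.columns and pert.action == "invert"]
    after_input = pairs.drop(columns=drop_cols)
    after = score_pairs(mutated, after_input, params, lc=lc)
    out = before[["chrom", "i", "j", "pos_i", "pos_j", "d", "ori_class"]].copy()
    out["p_before"] = before["p_ij"]
    out["p_after"] = after["p_ij"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio"] = np.where(out["p_before"] > 0, out["p_after"] / out["p_before"], np.nan)
    return out


@dataclass
class CrossingOutsideMap:
    bins: np.ndarray  # bin start coordinates
    ratio: np.ndarray  # (n_bins, n_bins) upper-triangular perturbed/baseline ratios
    classes: np.ndarray  # same shape, "crossing" / "outside" / "gray" / ""
    contact_before: np.ndarray  # summed baseline loop probability per bin pair
    contact_after: np.ndarray
    target_pos: int


def crossing_outside_map(
    sites: pd.DataFrame,
    params: ModelParams,
    pert: Perturbation,
    window: int = 800_000,
    bin_size: int = 40_000,
    max_span: int = 1_000_000,
    lc: str = "approx",
) -> CrossingOutsideMap:
    """Binned predicted contact-ratio matrix around a weakened site.

    Predicted contact of a bin pair is the summed loop probability of all
    candidate site pairs whose anchors fall in the two bins; the map reports
    the perturbed/baseline ratio on the +-``window`` neighborhood in
    ``bin_size`` bins.  Bin pairs flanking the target from both sides are
    "crossing" (competition release predicts ratios >= 1 there for a
    weakening edit), same-side pairs are "outside", and bins containing the
    disrupted site itself are grayed out of both classes.
    """
    if window < bin_size:
        raise ValueError("window must be at least one bin wide")
    if pert.action == "invert":
        raise ValueError("crossing/outside maps are defined for weakening edits")
    target = sites.loc[sites["site_id"] == pert.site_id]
    if not len(target):
        raise KeyError(f"unknown site_id {pert.site_id!r}")
    tpos = int(target["pos"].iloc[0])
    tchrom = target["chrom"].iloc[0]

    local = sites[
        (sites["chrom"] == tchrom)
        & (sites["pos"] >= tpos - window - max_span)
        & (sites["pos"] <= tpos + window + max_span)
    ]
    pairs = enumerate_pairs(local, max_span=max_span)
    before = score_pairs(local, pairs, params, lc=lc)
    after = score_pairs(apply_perturbation(local, pert), pairs, params, lc=lc)

    edges = np.arange(tpos - window, tpos + window + bin_size, bin_size)
    n_bins = len(edges) - 1
    bi = np.digitize(before["pos_i"].to_numpy(), edges) - 1
    bj = np.digitize(before["pos_j"].to_numpy(), edges) - 1
    in_map = (bi >= 0) & (bi < n_bins) & (bj >= 0) & (bj < n_bins)

    contact_before = np.zeros((n_bins, n_bins))
    contact_after = np.zeros((n_bins, n_bins))
    np.add.at(contact_before, (bi[in_map], bj[in_map]), before["p_ij"].to_numpy()[in_map])
    np.add.at(contact_after, (bi[in_map], bj[in_map]), after["p_ij"].to_numpy()[in_map])

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            contact_before > 0,
            contact_after / contact_before,
            np.where(contact_after > 0, np.inf, 1.0),
        )

    target_bin = int(np.digitize(tpos, edges)) - 1
    classes = np.full((n_bins, n_bins), "", dtype=object)
    for a in range(n_bins):
        for b in range(a + 1, n_bins):
            if a == target_bin or b == target_bin:
                classes[a, b] = "gray"
            elif a < target_bin < b:
                classes[a, b] = "crossing"
            else:
                classes[a, b] = "outside"
    return CrossingOutsideMap(
        bins=edges[:-1],
        ratio=ratio,
        classes=classes,
        contact_before=contact_before,
        contact_after=contact_after,
        target_pos=tpos,
    )


def waplko_scan(
    sites: pd.DataFrame,
    params: ModelParams,
    s_values,
    call_threshold: float = 0.1,
    max_span: int = 1_000_000,
    lc: str = "approx",
) -> pd.DataFrame:
    """Called-loop count and mean loop length as the pass-through ``s`` varies.

    For each ``s`` the landscape is rescored and pairs with p_ij >=
    ``call_threshold`` are called loops.  Raising ``s`` weakens every
    competition factor, so both outputs are nondecreasing in ``s`` on a
    fixed landscape: the loop-number and loop-size growth seen under WAPL
    knockout.  Deterministic given sites and params.
    """
    pairs = enumerate_pairs(sites, max_span=max_span)
    rows = []
    for s in s_values:
        scored = score_pairs(sites, pairs, params.replace(s=float(s)), lc=lc)
        called = scored[scored["p_ij"] >= call_threshold]
        rows.append(
            {
                "s": float(s),
                "n_loops": int(len(called)),
                "mean_length": float(called["d"].mean()) if len(called) else 0.0,
            }
        )
    return pd.DataFrame(rows)
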