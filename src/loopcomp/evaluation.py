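"""Scoring metrics and model-interrogation analyses.

Covers the ranking metrics used throughout (AUPRC as average precision,
AUROC), matched-negative sampling that isolates the contribution of loop
competition from that of genomic distance, the enhancer-promoter constraint
analysis (do regulatory links avoid crossing CTCF loops?), and comparison of
loop sets between cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm

__all__ = [
    "auprc",
    "auroc",
    "EvalResult",
    "evaluate_pairs",
    "matched_negatives",
    "EPResult",
    "ep_constraint",
    "CelltypeResult",
    "celltype_compare",
    "subsample_ci",
]


def _check_classes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size == 0 or labels.min() == labels.max():
        raise ValueError("need at least one positive and one negative label")
    return labels


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve as average precision (step
    interpolation), the standard for heavily imbalanced interaction data."""
    labels = _check_classes(labels)
    return float(_skm.average_precision_score(labels, np.asarray(scores, float)))


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic; ties averaged)."""
    labels = _check_classes(labels)
    return float(_skm.roc_auc_score(labels, np.asarray(scores, float)))


@dataclass
class EvalResult:
    auprc: float
    auroc: float
    pr_curve: pd.DataFrame
    roc_curve: pd.DataFrame
    pet_correlation: float | None
    n_positive: int
    n_negative: int


def evaluate_pairs(pairs: pd.DataFrame, score_col: str = "p_ij") -> EvalResult:
    """Full ranking evaluation of scored, labelled pairs.

    ``pet_correlation`` is the Pearson correlation between the predicted
    probability and log(1 + PET count) over all pairs (negatives enter with
    count 0), mirroring the quantitative check that predicted probabilities
    track interaction frequency.
    """
    labels = _check_classes(pairs["label"].to_numpy())
    scores = pairs[score_col].to_numpy(dtype=float)
    prec, rec, _ = _skm.precision_recall_curve(labels, scores)
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    corr = None
    if "pet_count" in pairs.columns:
        corr = float(stats.pearsonr(scores, np.log1p(pairs["pet_count"].to_numpy()))[0])
    return EvalResult(
        auprc=auprc(scores, labels),
        auroc=auroc(scores, labels),
        pr_curve=pd.DataFrame({"precision": prec, "recall": rec}),
        roc_curve=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pet_correlation=corr,
        n_positive=int(labels.sum()),
        n_negative=int((1 - labels).sum()),
    )


def matched_negatives(
    pairs: pd.DataFrame,
    mode: str = "distance",
    factor: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Positive/negative subsets matched on everything but one feature.

    For each positive pair a negative with the same orientation class is
    drawn whose joint occupancy p_i*p_j AND second feature (``D_ij`` in
    "distance" mode, ``LC_ij`` in "loop_competition" mode) both lie within
    ``factor`` of the positive's.  Distance-matching leaves loop competition
    free to differ (and vice versa), isolating its predictive value.
    Sampling is without replacement and seeded; positives with no candidate
    are dropped and counted.  Returns (matched pairs, n_dropped).
    """
    if mode not in ("distance", "loop_competition"):
        raise ValueError(f"unknown mode {mode!r}")
    if factor <= 1:
        raise ValueError("matching factor must be > 1")
    for col in ("p_i", "p_j", "D_ij", "LC_ij", "label", "ori_class"):
        if col not in pairs.columns:
            raise ValueError(f"pairs must be scored first (missing {col!r})")
    feat = "D_ij" if mode == "distance" else "LC_ij"
    rng = np.random.default_rng(seed)
    log_f = np.log(factor)

    df = pairs.reset_index(drop=True)
    with np.errstate(divide="ignore"):
        log_bi = np.log(df["p_i"].to_numpy() * df["p_j"].to_numpy())
        log_feat = np.log(df[feat].to_numpy())
    pos_idx = np.flatnonzero(df["label"].to_numpy() == 1)
    neg_idx = np.flatnonzero(df["label"].to_numpy() == 0)
    taken: set[int] = set()
    chosen: list[int] = []
    kept_pos: list[int] = []
    dropped = 0

    neg_by_class: dict[str, np.ndarray] = {
        c: neg_idx[df["ori_class"].to_numpy()[neg_idx] == c]
        for c in np.unique(df["ori_class"].to_numpy())
    }
    order = pos_idx.copy()
    rng.shuffle(order)
    for p in order:
        cands = neg_by_class.get(df["ori_class"].iloc[p], np.empty(0, int))
        ok = cands[
            (np.abs(log_bi[cands] - log_bi[p]) <= log_f)
            & (np.abs(log_feat[cands] - log_feat[p]) <= log_f)
        ]
        ok = np.array([c for c in ok if c not in taken], dtype=int)
        if ok.size == 0:
            dropped += 1
            continue
        pick = int(rng.choice(ok))
        taken.add(pick)
        chosen.append(pick)
        kept_pos.append(int(p))

    rows = df.iloc[kept_pos + chosen].copy()
    rows["match_group"] = np.concatenate([np.arange(len(kept_pos)), np.arange(len(chosen))])
    # matching constraints hold by construction; assert post-hoc anyway
    _assert_matched(rows, feat, factor)
    return rows.reset_index(drop=True), dropped


def _assert_matched(matched: pd.DataFrame, feat: str, factor: float) -> None:
    pos = matched[matched["label"] == 1].set_index("match_group")
    neg = matched[matched["label"] == 0].set_index("match_group")
    if len(pos) != len(neg) or not pos.index.equals(neg.index):
        raise AssertionError("matched sets must pair one negative per positive")
    tol = factor * (1 + 1e-9)
    bi_p = (pos["p_i"] * pos["p_j"]).to_numpy()
    bi_n = (neg["p_i"] * neg["p_j"]).to_numpy()
    f_p = pos[feat].to_numpy()
    f_n = neg[feat].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (
            (np.maximum(bi_p / bi_n, bi_n / bi_p) <= tol)
            & (np.maximum(f_p / f_n, f_n / f_p) <= tol)
            & (pos["ori_class"].to_numpy() == neg["ori_class"].to_numpy())
        )
    if not np.all(ok):
        raise AssertionError("emitted matched pair violates its matching constraint")


@dataclass
class EPResult:
    links: pd.DataFrame  # per-link cross_n / contain_n counts
    ratio_no_cross: float
    ratio_cross: float
    ratio_contain: float
    ratio_no_contain: float
    enrichment_no_cross: float
    enrichment_contain: float
    pseudocount_used: bool


def _tf_ratio(n_true: int, n_false: int) -> tuple[float, bool]:
    """True/false ratio with a Haldane +0.5 continuity correction on zeros."""
    if n_true == 0 or n_false == 0:
        return (n_true + 0.5) / (n_false + 0.5), True
    return n_true / n_false, False


def ep_constraint(links: pd.DataFrame, loops: pd.DataFrame) -> EPResult:
    """Crossing/containment statistics of enhancer-promoter links vs loops.

    ``links`` columns: chrom, enh_start, enh_end, prom_start, prom_end,
    label (1 = validated interacting).  ``loops`` may be measured records
    (anchor columns) or predicted loops; the loop span runs between anchor
    midpoints.  A link *crosses* a loop when exactly one loop anchor
    midpoint lies strictly inside the link span; a loop *contains* a link
    when both link endpoints lie strictly inside the loop span.  Reported
    enrichments compare the true/false link ratio between groups, with a
    +0.5 pseudo-count when a raw count is zero.
    """
    required = {"chrom", "enh_start", "enh_end", "prom_start", "prom_end", "label"}
    if not required <= set(links.columns):
        raise ValueError(f"links table needs columns {sorted(required)}")
    if len(loops):
        lo = ((loops["anchor1_start"] + loops["anchor1_end"]) // 2).to_numpy()
        hi = ((loops["anchor2_start"] + loops["anchor2_end"]) // 2).to_numpy()
        lchrom = loops["chrom"].to_numpy()
    else:
        lo = hi = np.empty(0, int)
        lchrom = np.empty(0, object)

    cross_n = np.zeros(len(links), dtype=int)
    contain_n = np.zeros(len(links), dtype=int)
    links = links.reset_index(drop=True)
    for k, row in enumerate(links.itertuples(index=False)):
        e_mid = (row.enh_start + row.enh_end) // 2
        p_mid = (row.prom_start + row.prom_end) // 2
        span_lo, span_hi = min(e_mid, p_mid), max(e_mid, p_mid)
        same = lchrom == row.chrom
        a_in = (lo[same] > span_lo) & (lo[same] < span_hi)
        b_in = (hi[same] > span_lo) & (hi[same] < span_hi)
        cross_n[k] = int(np.sum(a_in ^ b_in))
        contain_n[k] = int(np.sum((lo[same] < span_lo) & (hi[same] > span_hi)))

    out = links.copy()
    out["cross_n"] = cross_n
    out["contain_n"] = contain_n
    lab = out["label"].to_numpy().astype(bool)

    def _group(mask):
        return int((lab & mask).sum()), int((~lab & mask).sum())

    r_nc, f1 = _tf_ratio(*_group(cross_n == 0))
    r_c, f2 = _tf_ratio(*_group(cross_n > 0))
    r_in, f3 = _tf_ratio(*_group(contain_n > 0))
    r_out, f4 = _tf_ratio(*_group(contain_n == 0))
    return EPResult(
        links=out,
        ratio_no_cross=r_nc,
        ratio_cross=r_c,
        ratio_contain=r_in,
        ratio_no_contain=r_out,
        enrichment_no_cross=r_nc / r_c,
        enrichment_contain=r_in / r_out,
        pseudocount_used=any((f1, f2, f3, f4)),
    )


@dataclass
class CelltypeResult:
    shared_a: pd.DataFrame
    shared_b: pd.DataFrame
    specific_a: pd.DataFrame
    specific_b: pd.DataFrame
    frac_shared_a: float
    frac_shared_b: float


def _anchors_overlap(loop, others: pd.DataFrame) -> bool:
    same = others["chrom"] == loop.chrom
    o = others[same]
    a = (o["anchor1_start"] < loop.anchor1_end) & (loop.anchor1_start < o["anchor1_end"])
    b = (o["anchor2_start"] < loop.anchor2_end) & (loop.anchor2_start < o["anchor2_end"])
    return bool((a & b).any())


def celltype_compare(
    loops_a: pd.DataFrame, loops_b: pd.DataFrame, top_n: int = 10_000
) -> CelltypeResult:
    """Partition each cell type's strongest loops into shared and specific.

    The ``top_n`` loops by PET count are selected per set (sequencing-depth
    control); a loop is shared iff BOTH anchors overlap (>= 1 bp) the
    anchors of some loop in the other set.  Warns and uses all loops when
    fewer than ``top_n`` are available.
    """
    import warnings

    tops = []
    for name, loops in (("A", loops_a), ("B", loops_b)):
        if len(loops) < top_n:
            warnings.warn(f"set {name} has {len(loops)} < top_n={top_n} loops; using all")
        tops.append(loops.nlargest(min(top_n, len(loops)), "pet_count", keep="first"))
    top_a, top_b = tops
    shared_a_mask = np.array([_anchors_overlap(l, top_b) for l in top_a.itertuples(index=False)])
    shared_b_mask = np.array([_anchors_overlap(l, top_a) for l in top_b.itertuples(index=False)])
    if not len(top_a):
        shared_a_mask = np.empty(0, bool)
    if not len(top_b):
        shared_b_mask = np.empty(0, bool)
    return CelltypeResult(
        shared_a=top_a[shared_a_mask],
        shared_b=top_b[shared_b_mask],
        specific_a=top_a[~shared_a_mask],
        specific_b=top_b[~shared_b_mask],
        frac_shared_a=float(shared_a_mask.mean()) if len(top_a) else float("nan"),
        frac_shared_b=float(shared_b_mask.mean()) if len(top_b) else float("nan"),
    )


def subsample_ci(
    scores,
    labels,
    metric=auprc,
    frac: float = 0.1,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile 95% CI of a metric under repeated 10% down-sampling."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_repeats):
        keep = rng.random(len(labels)) < frac
        if labels[keep].size and labels[keep].min() != labels[keep].max():
            vals.append(metric(scores[keep], labels[keep]))
    vals = np.array(vals)
    return float(vals.mean()), float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))
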