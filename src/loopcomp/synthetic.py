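"""Synthetic CTCF landscapes and model-consistent loop labels.

Every downstream stage (scoring, calibration, evaluation, perturbation) is
testable without downloads: this module generates chromosomes of CTCF sites
with geometric spacing, log-normal binding intensities and random strand
orientations, then draws loop labels from the model itself.

Two labelling mechanisms are provided:

* ``bernoulli_closed_form`` — each candidate pair is an independent
  Bernoulli draw from the approximate-LC closed-form probability; this is
  the population-average picture and the default for calibration tests.
* ``occupancy_then_extrude`` — a single-cell style realization: site
  occupancy is sampled per site, then the chromosome is walked left to
  right, each candidate loop between occupied sites is accepted with
  probability w_ij * D_ij, and an accepted loop blocks every overlapping
  candidate (mutual exclusion, the mechanistic origin of loop competition).

:func:`brute_force_pij` enumerates the occupancy-then-extrude process
exactly on tiny instances and is the oracle for the sampler.  The default
scale is 10 chromosomes x 5 Mb x 200 sites with 25 kb mean spacing and
log-normal intensities whose mean emulates a ~30-fold peak enrichment over
the genome-average signal.  Note that model-consistent labels are bounded
by site occupancy (the summed loop probability anchored at a site cannot
exceed its occupancy), so the positive:negative ratio of the default
landscape (~1:120) is sparser than the ~1:20-1:40 measured in deeply
sequenced interaction data, where a large cell population lets one site
anchor several alternative loops at once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import enumerate_pairs
from .model import (
    FORWARD,
    REVERSE,
    ModelParams,
    binding_probability,
    distance_decay,
    orientation_weight_from_class,
    score_pairs,
)

__all__ = [
    "SyntheticConfig",
    "generate_sites",
    "generate_labels",
    "sample_extrusion",
    "brute_force_pij",
    "simulate_dataset",
    "demo_ctcf_motif",
    "write_demo_genome",
]


def _default_params() -> ModelParams:
    # distance term disabled by default: interaction data is fit best without it
    return ModelParams(a=8.5, w=3.0, lam=None, decay_kind="none")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic landscape.

    ``spacing_mean`` is the mean of the geometric inter-site spacing (bp);
    ``intensity_sigma`` the log-normal shape of raw binding signal (heavy
    right tail, as in ChIP-seq); ``pet_scale`` scales the Poisson PET counts
    of positives so the median lands near the PET-count filters (~6).

    ``peak_enrichment`` emulates the normalization of real data, where the
    binding intensity x is the local signal divided by its *genome* average:
    the genome average is background-dominated, so x at peaks is large.
    The generated x values have mean exactly ``peak_enrichment``.
    """

    n_chromosomes: int = 10
    chrom_length: int = 5_000_000
    n_sites: int = 200
    spacing_mean: float = 25_000.0
    intensity_sigma: float = 1.0
    peak_enrichment: float = 30.0
    forward_prob: float = 0.5
    params: ModelParams = field(default_factory=_default_params)
    mechanism: str = "bernoulli_closed_form"
    max_span: int = 1_000_000
    pet_scale: float = 25.0
    on_overflow: str = "regenerate"  # or "error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites per chromosome")
        if self.spacing_mean <= 1 or self.chrom_length <= 0:
            raise ValueError("invalid spacing or chromosome length")
        if not 0 <= self.forward_prob <= 1:
            raise ValueError("forward_prob must be in [0, 1]")
        if self.mechanism not in ("bernoulli_closed_form", "occupancy_then_extrude"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.on_overflow not in ("regenerate", "error"):
            raise ValueError("on_overflow must be 'regenerate' or 'error'")


def generate_sites(cfg: SyntheticConfig) -> pd.DataFrame:
    """Sorted, normalized, oriented site table; deterministic under the seed."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        for attempt in range(1000):
            spacings = rng.geometric(1.0 / cfg.spacing_mean, size=cfg.n_sites)
            pos = np.cumsum(spacings)
            if pos[-1] < cfg.chrom_length:
                break
            if cfg.on_overflow == "error":
                raise ValueError(
                    f"{chrom}: sites exceed chrom_length {cfg.chrom_length}"
                )
        else:
            raise ValueError(f"{chrom}: could not place {cfg.n_sites} sites")
        signal = rng.lognormal(mean=0.0, sigma=cfg.intensity_sigma, size=cfg.n_sites)
        strand = rng.random(cfg.n_sites) < cfg.forward_prob
        for k in range(cfg.n_sites):
            rows.append(
                (
                    f"{chrom}_s{k:04d}",
                    chrom,
                    int(pos[k]) - 200,
                    int(pos[k]) + 200,
                    int(pos[k]),
                    FORWARD if strand[k] else REVERSE,
                    signal[k],
                )
            )
    sites = pd.DataFrame(
        rows,
        columns=["site_id", "chrom", "peak_start", "peak_end", "pos", "orientation", "signal_raw"],
    )
    sites["x"] = cfg.peak_enrichment * sites["signal_raw"] / sites["signal_raw"].mean()
    return sites


def _candidate_loops(occupied: pd.DataFrame, params: ModelParams, max_span: int):
    """Ordered candidate loops among occupied sites of one chromosome."""
    pos = occupied["pos"].to_numpy()
    ori = occupied["orientation"].to_numpy()
    cands = []
    n = len(occupied)
    for a in range(n):
        for b in range(a + 1, n):
            d = pos[b] - pos[a]
            if d <= 0 or d > max_span:
                continue
            cls = (
                "convergent"
                if (ori[a] == FORWARD and ori[b] == REVERSE)
                else ("tandem" if ori[a] == ori[b] else "divergent")
            )
            accept = orientation_weight_from_class(cls, params) * distance_decay(d, params)
            cands.append((pos[a], pos[b], occupied.index[a], occupied.index[b], accept))
    cands.sort(key=lambda t: (t[0], t[1]))
    return cands


def sample_extrusion(
    sites: pd.DataFrame, params: ModelParams, rng: np.random.Generator, max_span: int = 1_000_000
) -> set[tuple[str, str]]:
    """One realization of the occupancy-then-extrude mechanism.

    Returns the set of formed loops as (site_id_i, site_id_j) tuples.
    """
    formed: set[tuple[str, str]] = set()
    p = binding_probability(sites["x"].to_numpy(), params)
    occupied_mask = rng.random(len(sites)) < p
    occ = sites[occupied_mask]
    for chrom, grp in occ.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        grp = grp.reset_index(drop=True)
        accepted: list[tuple[int, int]] = []
        for pa, pb, _, _, acc in _candidate_loops(grp, params, max_span):
            # open-interval overlap with an already formed loop blocks extrusion
            if any(pa < b and a < pb for a, b in accepted):
                continue
            if rng.random() < acc:
                accepted.append((pa, pb))
                ia = grp.loc[grp["pos"] == pa, "site_id"].iloc[0]
                ib = grp.loc[grp["pos"] == pb, "site_id"].iloc[0]
                formed.add((ia, ib))
    return formed


def generate_labels(
    sites: pd.DataFrame,
    cfg: SyntheticConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Labelled candidate pairs (+ synthetic PET counts) from the true model.

    Labels follow ``cfg.mechanism``; PET counts of positives are
    ``1 + Poisson(pet_scale * p_ij)`` so stronger loops get deeper support.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    pairs = enumerate_pairs(sites, max_span=cfg.max_span)
    pairs = score_pairs(sites, pairs, cfg.params, lc="approx")
    if cfg.mechanism == "bernoulli_closed_form":
        label = (rng.random(len(pairs)) < pairs["p_ij"].to_numpy()).astype(int)
    else:
        formed = sample_extrusion(sites, cfg.params, rng, max_span=cfg.max_span)
        label = np.fromiter(
            ((i, j) in formed for i, j in zip(pairs["i"], pairs["j"])), dtype=int, count=len(pairs)
        )
    pairs["label"] = label
    pet = np.zeros(len(pairs), dtype=int)
    pos_idx = np.flatnonzero(label)
    pet[pos_idx] = 1 + rng.poisson(cfg.pet_scale * pairs["p_ij"].to_numpy()[pos_idx])
    pairs["pet_count"] = pet
    return pairs


def brute_force_pij(
    sites: pd.DataFrame, params: ModelParams, max_span: int = 1_000_000, max_sites: int = 12
) -> pd.DataFrame:
    """Exact loop marginals of the occupancy-then-extrude mechanism.

    Enumerates every occupancy configuration and every acceptance outcome of
    the ordered extrusion walk, weighting each path by its probability.
    Feasible only for tiny instances (<= ``max_sites`` sites); the exact
    marginals are the oracle for :func:`sample_extrusion` and, on isolated
    pairs, reduce to the closed form w_ij * p_i * p_j * D_ij.
    """
    if len(sites) > max_sites:
        raise ValueError(f"instance too large for enumeration ({len(sites)} > {max_sites})")
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)
    p = binding_probability(sites["x"].to_numpy(), params)
    marginals: dict[tuple[str, str], float] = {}

    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        n = len(idx)
        for occ in itertools.product((0, 1), repeat=n):
            w_occ = float(np.prod([p[idx[k]] if occ[k] else 1 - p[idx[k]] for k in range(n)]))
            if w_occ == 0.0:
                continue
            occupied = grp[np.array(occ, bool)]
            cands = _candidate_loops(occupied.reset_index(drop=True), params, max_span)
            ids = occupied["site_id"].to_numpy()
            pos = occupied["pos"].to_numpy()
            pos_to_id = dict(zip(pos, ids))

            # DFS over accept/reject branches of the ordered walk
            stack = [(0, (), w_occ)]
            while stack:
                ci, accepted, weight = stack.pop()
                if ci == len(cands):
                    for pa, pb in accepted:
                        key = (pos_to_id[pa], pos_to_id[pb])
                        marginals[key] = marginals.get(key, 0.0) + weight
                    continue
                pa, pb, _, _, acc = cands[ci]
                if any(pa < b and a < pb for a, b in accepted):
                    stack.append((ci + 1, accepted, weight))  # blocked
                    continue
                if acc > 0:
                    stack.append((ci + 1, accepted + ((pa, pb),), weight * acc))
                if acc < 1:
                    stack.append((ci + 1, accepted, weight * (1 - acc)))

    pairs = enumerate_pairs(sites, max_span=max_span)
    pairs["p_exact"] = [
        marginals.get((i, j), 0.0) for i, j in zip(pairs["i"], pairs["j"])
    ]
    return pairs


def simulate_dataset(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sites, labelled pairs and the positive loops as a BEDPE-ready table."""
    sites = generate_sites(cfg)
    pairs = generate_labels(sites, cfg)
    pos = pairs[pairs["label"] == 1]
    anchors = sites.set_index("site_id")
    loops = pd.DataFrame(
        {
            "chrom": pos["chrom"].to_numpy(),
            "anchor1_start": anchors.loc[pos["i"], "peak_start"].to_numpy(),
            "anchor1_end": anchors.loc[pos["i"], "peak_end"].to_numpy(),
            "anchor2_start": anchors.loc[pos["j"], "peak_start"].to_numpy(),
            "anchor2_end": anchors.loc[pos["j"], "peak_end"].to_numpy(),
            "pet_count": pos["pet_count"].to_numpy(),
        }
    )
    return sites, pairs, loops


# --- small sequence fixtures (synthetic stand-ins, not database exports) ---

_DEMO_CONSENSUS = "CCACCAGGTGGCGCTA"


def demo_ctcf_motif(strength: int = 97):
    """A synthetic CTCF-like count matrix (NOT the JASPAR matrix).

    Sixteen positions with a dominant consensus base (count ``strength``) and
    the remainder spread uniformly; good enough to exercise orientation
    annotation and examples without shipping database content.
    """
    from Bio import motifs

    counts = {b: [] for b in "ACGT"}
    minor = (100 - strength) / 3.0
    for base in _DEMO_CONSENSUS:
        for b in "ACGT":
            counts[b].append(float(strength) if b == base else minor)
    m = motifs.Motif(alphabet="ACGT", counts=counts)
    m.name = "CTCF_synthetic"
    return m


def write_demo_genome(path, sites: pd.DataFrame, chrom_length: int, seed: int = 0) -> None:
    """Write a FASTA genome with the demo consensus planted at forward/reverse sites.

    Ambiguous sites get random sequence.  Purely a synthetic fixture for
    orientation-annotation round trips.
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    rc = str(Seq(_DEMO_CONSENSUS).reverse_complement())
    with open(path, "w") as out:
        for chrom, grp in sites.groupby("chrom", sort=False):
            seq = rng.choice(list("ACGT"), size=chrom_length)
            for row in grp.itertuples(index=False):
                if row.orientation == FORWARD:
                    planted = _DEMO_CONSENSUS
                elif row.orientation == REVERSE:
                    planted = rc
                else:
                    continue
                start = int(row.pos) - len(planted) // 2
                seq[start : start + len(planted)] = list(planted)
            out.write(f">{chrom}\n")
            s = "".join(seq)
            for k in range(0, len(s), 80):
                out.write(s[k : k + 80] + "\n")
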