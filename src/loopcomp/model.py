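"""Core probability computations of the loop-competition-and-extrusion (LCE) model.

The model scores every candidate pair of CTCF-binding sites (i, j) on the same
chromosome with a loop-formation probability

    p_ij = w_ij * p_i * p_j * D_ij * LC_ij

where

* ``p_i = x_i / (x_i + a)`` is the equilibrium occupancy of site *i*, with *x*
  the ChIP-seq binding intensity normalized to genome mean 1 and *a* the
  dimensionless average Kd/[CTCF] scale (a ``tanh`` parameterization is
  available as an alternative),
* ``w_ij`` encodes motif orientation: 1 for convergent pairs, 1/w for tandem,
  1/w**2 for divergent (optionally independent weights w1, w2),
* ``D_ij`` is the probability that Cohesin survives extruding the distance
  d_ij: ``exp(-d_ij / lambda)`` for a constant dissociation rate, a power law
  ``(d_ij/kb)**-k`` as an alternative, or 1 when disabled,
* ``LC_ij`` is the loop-competition term: the probability that no overlapping
  loop has already formed and blocked Cohesin.

LC couples all pairs, so the exact model is a fixed point
``p_ij = q_ij * prod_{mn overlapping ij} (1 - p_mn)`` solved here by damped
(successive over-relaxation) iteration; the cheaper approximation
``LC_ij = prod_{i < m < j} (1 - p_m)`` requires only that sites strictly
internal to the loop are unoccupied.  A Cohesin pass-through probability
``s`` (WAPL-knockout regime) attenuates every competition factor to
``1 - (1 - s) * p``.

Sites and candidate pairs are kept in pandas DataFrames; see
:mod:`loopcomp.io` for the column schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FORWARD",
    "REVERSE",
    "AMBIGUOUS",
    "CONVERGENT",
    "TANDEM",
    "DIVERGENT",
    "ModelParams",
    "SolverConfig",
    "SolverResult",
    "binding_probability",
    "occupancy_scale_from_affinity",
    "orientation_class",
    "orientation_weight",
    "distance_decay",
    "lc_approx",
    "loop_probability",
    "score_pairs",
    "solve_lc_fixed_point",
]

FORWARD = "forward"
REVERSE = "reverse"
AMBIGUOUS = "ambiguous"

CONVERGENT = "convergent"
TANDEM = "tandem"
DIVERGENT = "divergent"

# floor on (1 - p) factors so log-space products stay finite
_EPS = 1e-12


@dataclass
class ModelParams:
    """All constants of the LCE model.

    Parameters
    ----------
    a:
        Dimensionless occupancy scale, the genome-average Kd/[CTCF]; the
        fitted value on GM12878-like data is 8.5.
    w:
        Orientation penalty scalar (> 1): tandem pairs are w-fold and
        divergent pairs w**2-fold less likely to loop than convergent ones.
    w1, w2:
        Optional independent tandem/divergent penalties; when both are set
        they override ``w`` and ``w**2``.
    lam:
        Cohesin processivity (decay length) in bp for the exponential
        distance term; ``None`` disables the distance term entirely.
    decay_kind:
        "exponential", "powerlaw" or "none".
    k:
        Power-law exponent, used only when ``decay_kind == "powerlaw"``.
        Distances are expressed in kb for this variant so the term stays
        <= 1 over the modeled (>= 1 kb) range.
    s:
        Cohesin pass-through probability in [0, 1]; 0 is complete blocking,
        values around 0.4 emulate the WAPL-knockout regime.
    binding_kind:
        "hill" for p = x/(x+a), "tanh" for p = tanh(a_tanh * x).
    a_tanh:
        Scale of the tanh binding variant (fit independently of ``a``).
    """

    a: float = 8.5
    w: float = 3.0
    w1: float | None = None
    w2: float | None = None
    lam: float | None = 3_000_000.0
    decay_kind: str = "exponential"
    k: float = 1.0
    s: float = 0.0
    binding_kind: str = "hill"
    a_tanh: float = 0.1

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"occupancy scale a must be > 0, got {self.a}")
        if self.w < 1 and (self.w1 is None or self.w2 is None):
            # w = 1 disables the orientation effect (reduction limit)
            raise ValueError(f"orientation penalty w must be >= 1, got {self.w}")
        if self.decay_kind not in ("exponential", "powerlaw", "none"):
            raise ValueError(f"unknown decay_kind {self.decay_kind!r}")
        if self.decay_kind == "exponential" and self.lam is None:
            # a null decay length means the distance term is disabled
            self.decay_kind = "none"
        if self.lam is not None and self.lam <= 0:
            raise ValueError(f"decay length lam must be > 0, got {self.lam}")
        if self.decay_kind == "powerlaw" and self.k <= 0:
            raise ValueError(f"power-law exponent k must be > 0, got {self.k}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"pass-through probability s must be in [0,1], got {self.s}")
        if self.binding_kind not in ("hill", "tanh"):
            raise ValueError(f"unknown binding_kind {self.binding_kind!r}")

    @property
    def tandem_weight(self) -> float:
        return 1.0 / (self.w1 if self.w1 is not None else self.w)

    @property
    def divergent_weight(self) -> float:
        return 1.0 / (self.w2 if self.w2 is not None else self.w**2)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class SolverConfig:
    """Damped (successive over-relaxation) fixed-point iteration settings.

    ``b`` is the relaxation rate: the update mixes the freshly computed value
    with the previous iterate as (p_new + b * p_old) / (1 + b).  b = 0 is
    plain fixed-point iteration; larger b damps harder.
    """

    b: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("relaxation rate b must be >= 0")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class SolverResult:
    p: np.ndarray
    n_iter: int
    converged: bool
    max_delta: float


def occupancy_scale_from_affinity(kd: float, ctcf_concentration: float) -> float:
    """Kd/[CTCF] for an in-vitro affinity and nuclear concentration (same units).

    Gives the physically expected magnitude of the occupancy scale ``a``: the
    measured CTCF affinity at the H19/Igf2 site (Kd = 370 nM) together with a
    nuclear concentration of 144 nM yields 2.6, the same order as the value
    fitted from interaction data (8.5, plausibly higher on chromatin than on
    naked DNA).
    """
    if kd <= 0 or ctcf_concentration <= 0:
        raise ValueError("affinity and concentration must be positive")
    return kd / ctcf_concentration


def binding_probability(x, params: ModelParams):
    """Occupancy probability of a site with normalized intensity ``x``.

    Hill form ``x / (x + a)`` from the chemical equilibrium of CTCF binding,
    or the saturating alternative ``tanh(a_tanh * x)``.  Accepts scalars or
    arrays; strictly increasing in x, with range [0, 1).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("binding intensity x must be >= 0")
    if params.binding_kind == "hill":
        out = arr / (arr + params.a)
    else:
        # clip so saturation stays strictly below 1 (a bound site can unbind)
        out = np.minimum(np.tanh(params.a_tanh * arr), 1.0 - _EPS)
    return float(out) if np.isscalar(x) else out


def orientation_class(ori_i, ori_j):
    """Orientation class of a coordinate-ordered pair (i upstream of j).

    Convergent = (forward, reverse), tandem = same orientation, divergent =
    (reverse, forward).  Ambiguous orientations are rejected; such sites are
    excluded before pairing.  Vectorized over arrays of orientation strings.
    """
    oi = np.asarray(ori_i, dtype=object)
    oj = np.asarray(ori_j, dtype=object)
    for o in (oi, oj):
        bad = ~np.isin(o, (FORWARD, REVERSE))
        if bad.any():
            raise ValueError(
                f"orientation must be {FORWARD!r} or {REVERSE!r}; got {o[bad][0]!r}"
            )
    out = np.where(
        oi == oj, TANDEM, np.where((oi == FORWARD) & (oj == REVERSE), CONVERGENT, DIVERGENT)
    )
    if np.isscalar(ori_i) or (isinstance(ori_i, str) and isinstance(ori_j, str)):
        return str(out.item()) if out.shape == () else str(out[0])
    return out


def orientation_weight(ori_i, ori_j, params: ModelParams):
    """w_ij term: 1, 1/w or 1/w**2 for convergent/tandem/divergent pairs."""
    cls = orientation_class(ori_i, ori_j)
    return orientation_weight_from_class(cls, params)


def orientation_weight_from_class(ori_class, params: ModelParams):
    cls = np.asarray(ori_class, dtype=object)
    known = np.isin(cls, (CONVERGENT, TANDEM, DIVERGENT))
    if not known.all():
        raise ValueError(f"unknown orientation class {cls[~known][0]!r}")
    out = np.where(
        cls == CONVERGENT,
        1.0,
        np.where(cls == TANDEM, params.tandem_weight, params.divergent_weight),
    ).astype(float)
    if out.shape == ():
        return float(out)
    return out


def distance_decay(d, params: ModelParams):
    """D_ij term: Cohesin survival over the extruded distance ``d`` (bp).

    Exponential ``exp(-d/lam)`` for a constant per-bp dissociation rate;
    power-law ``(d/1000)**-k`` (distances in kb so the term is <= 1 for
    d >= 1 kb); 1 when the distance term is disabled.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("pair distance d must be > 0")
    if params.decay_kind == "none":
        out = np.ones_like(arr)
    elif params.decay_kind == "exponential":
        out = np.exp(-arr / params.lam)
    else:
        out = (arr / 1000.0) ** (-params.k)
    return float(out) if np.isscalar(d) else out


def _lc_log_factors(p, s: float):
    """log(1 - (1-s) * p), clipped away from -inf."""
    p = np.asarray(p, dtype=float)
    return np.log(np.clip(1.0 - (1.0 - s) * p, _EPS, 1.0))


def lc_approx(internal_p: Iterable[float], params: ModelParams | None = None) -> float:
    """Approximate loop-competition term from internal-site occupancies.

    The probability that every retained site strictly between the two anchors
    is unoccupied, ``prod_m (1 - p_m)``; with pass-through s each factor
    becomes ``1 - (1-s) * p_m``.  Empty input gives 1.  Computed in log space.
    """
    s = params.s if params is not None else 0.0
    p = np.asarray(list(internal_p), dtype=float)
    if p.size == 0:
        return 1.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("occupancy probabilities must be in [0, 1]")
    return float(np.exp(_lc_log_factors(p, s).sum()))


def _sorted_sites(sites: pd.DataFrame) -> pd.DataFrame:
    out = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def _site_indices(sites: pd.DataFrame, pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row indices into the sorted site table for each pair's two anchors."""
    lookup = pd.Series(np.arange(len(sites)), index=sites["site_id"])
    try:
        si = lookup.loc[pairs["i"]].to_numpy()
        sj = lookup.loc[pairs["j"]].to_numpy()
    except KeyError as exc:  # pragma: no cover - defensive
        raise KeyError(f"pair references unknown site_id: {exc}") from exc
    return si, sj


def score_pairs(
    sites: pd.DataFrame,
    pairs: pd.DataFrame,
    params: ModelParams,
    lc: str = "approx",
    solver: SolverConfig | None = None,
) -> pd.DataFrame:
    """Populate the model terms (w_ij, D_ij, LC_ij, p_i, p_j, p_ij) for all pairs.

    ``lc`` selects the competition term: "approx" (internal-site product),
    "iterative" (full overlapping-loop fixed point, see
    :func:`solve_lc_fixed_point`) or "none".  Returns a copy of ``pairs``
    with the term columns set; site occupancies are recomputed from ``x``.
    """
    if lc not in ("approx", "iterative", "none"):
        raise ValueError(f"unknown lc mode {lc!r}")
    sites = _sorted_sites(sites)
    pairs = pairs.reset_index(drop=True).copy()
    si, sj = _site_indices(sites, pairs)
    if (sites["chrom"].to_numpy()[si] != sites["chrom"].to_numpy()[sj]).any():
        raise ValueError("pair anchors must lie on the same chromosome")

    p_site = binding_probability(sites["x"].to_numpy(), params)
    d = sites["pos"].to_numpy()[sj] - sites["pos"].to_numpy()[si]
    if np.any(d <= 0):
        raise ValueError("pairs must be coordinate ordered with pos_i < pos_j")

    if "ori_class" in pairs.columns:
        cls = pairs["ori_class"].to_numpy()
    else:
        cls = orientation_class(
            sites["orientation"].to_numpy()[si], sites["orientation"].to_numpy()[sj]
        )
        pairs["ori_class"] = cls
    w_ij = orientation_weight_from_class(cls, params)
    d_ij = distance_decay(d, params)

    if lc == "none":
        lc_ij = np.ones(len(pairs))
    elif lc == "approx":
        # prefix sums of log(1 - (1-s) p_m) over the coordinate-sorted sites;
        # internal sites of (i, j) are rows si+1 .. sj-1, never crossing a
        # chromosome boundary because pairs are intra-chromosomal
        cum = np.concatenate([[0.0], np.cumsum(_lc_log_factors(p_site, params.s))])
        lc_ij = np.exp(cum[sj] - cum[si + 1])
    else:
        base = w_ij * p_site[si] * p_site[sj] * d_ij
        res = _solve_fixed_point_arrays(
            pairs["chrom"].to_numpy(),
            sites["pos"].to_numpy()[si],
            sites["pos"].to_numpy()[sj],
            base,
            params.s,
            solver or SolverConfig(),
        )
        if not res.converged:
            raise RuntimeError(
                f"LC fixed point did not converge in {res.n_iter} iterations "
                f"(max delta {res.max_delta:.3g}); relax SolverConfig"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            lc_ij = np.where(base > 0, res.p / base, 1.0)

    pairs["pos_i"] = sites["pos"].to_numpy()[si]
    pairs["pos_j"] = sites["pos"].to_numpy()[sj]
    pairs["d"] = d
    pairs["p_i"] = p_site[si]
    pairs["p_j"] = p_site[sj]
    pairs["w_ij"] = w_ij
    pairs["D_ij"] = d_ij
    pairs["LC_ij"] = lc_ij
    pairs["p_ij"] = w_ij * p_site[si] * p_site[sj] * d_ij * lc_ij
    return pairs


def loop_probability(
    sites: pd.DataFrame, site_i: str, site_j: str, params: ModelParams, lc: str = "approx"
) -> pd.Series:
    """Score a single pair (by site ids) and return its populated term row."""
    sites = _sorted_sites(sites)
    sel = sites.set_index("site_id")
    for sid in (site_i, site_j):
        if sid not in sel.index:
            raise KeyError(f"unknown site_id {sid!r}")
    a, b = sel.loc[site_i], sel.loc[site_j]
    if a["chrom"] != b["chrom"]:
        raise ValueError("sites lie on different chromosomes")
    if a["pos"] > b["pos"]:
        site_i, site_j = site_j, site_i
    pair = pd.DataFrame({"chrom": [a["chrom"]], "i": [site_i], "j": [site_j]})
    return score_pairs(sites, pair, params, lc=lc).iloc[0]


def _solve_fixed_point_arrays(
    chrom: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    base: np.ndarray,
    s: float,
    config: SolverConfig,
) -> SolverResult:
    """Damped iteration of p_ij = q_ij * prod_{mn overlap ij} (1 - (1-s) p_mn).

    Two loops (a, b) and (c, d) compete iff their open midpoint intervals
    intersect (c < b and a < d); loops sharing only an endpoint do not.  The
    per-pair product over competitors is evaluated with prefix sums: for pair
    (a, b) on one chromosome,

        log LC = S_total - S[right <= a] - S[left >= b] - own term

    which makes each sweep O(P log P) instead of O(P^2).
    """
    n = len(base)
    p = base.astype(float).copy()
    if n == 0:
        return SolverResult(p, 0, True, 0.0)

    groups = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        by_right = idx[np.argsort(right[idx], kind="mergesort")]
        by_left = idx[np.argsort(left[idx], kind="mergesort")]
        # insertion points of each pair's endpoints into the sorted endpoint lists
        n_right_le = np.searchsorted(right[by_right], left[idx], side="right")
        n_left_ge = np.searchsorted(left[by_left], right[idx], side="left")
        groups.append((idx, by_right, by_left, n_right_le, n_left_ge))

    max_delta = np.inf
    for it in range(1, config.max_iter + 1):
        t = _lc_log_factors(p, s)
        log_lc = np.zeros(n)
        for idx, by_right, by_left, n_right_le, n_left_ge in groups:
            tg_total = t[idx].sum()
            cum_r = np.concatenate([[0.0], np.cumsum(t[by_right])])
            cum_l = np.concatenate([[0.0], np.cumsum(t[by_left])])
            total_l = cum_l[-1]
            s_left = cum_r[n_right_le]
            s_right = total_l - cum_l[n_left_ge]
            log_lc[idx] = tg_total - s_left - s_right - t[idx]
        p_fresh = base * np.exp(log_lc)
        p_next = (p_fresh + config.b * p) / (1.0 + config.b)
        max_delta = float(np.max(np.abs(p_next - p)))
        p = p_next
        if max_delta < config.tol:
            return SolverResult(p, it, True, max_delta)
    return SolverResult(p, config.max_iter, False, max_delta)


def solve_lc_fixed_point(
    sites: pd.DataFrame,
    pairs: pd.DataFrame,
    params: ModelParams,
    config: SolverConfig | None = None,
) -> tuple[pd.DataFrame, SolverResult]:
    """Solve the full loop-competition fixed point for all candidate pairs.

    Returns the pair table with term columns populated (LC_ij is the
    converged competition term) together with the raw :class:`SolverResult`.
    Non-convergence is flagged on the result, not raised, so callers can
    inspect the final iterate.
    """
    config = config or SolverConfig()
    sites = _sorted_sites(sites)
    pairs = pairs.reset_index(drop=True).copy()
    si, sj = _site_indices(sites, pairs)
    p_site = binding_probability(sites["x"].to_numpy(), params)
    d = sites["pos"].to_numpy()[sj] - sites["pos"].to_numpy()[si]
    if np.any(d <= 0):
        raise ValueError("pairs must be coordinate ordered with pos_i < pos_j")
    if "ori_class" in pairs.columns:
        cls = pairs["ori_class"].to_numpy()
    else:
        cls = orientation_class(
            sites["orientation"].to_numpy()[si], sites["orientation"].to_numpy()[sj]
        )
        pairs["ori_class"] = cls
    w_ij = orientation_weight_from_class(cls, params)
    d_ij = distance_decay(d, params)
    base = w_ij * p_site[si] * p_site[sj] * d_ij
    res = _solve_fixed_point_arrays(
        pairs["chrom"].to_numpy(),
        sites["pos"].to_numpy()[si],
        sites["pos"].to_numpy()[sj],
        base,
        params.s,
        config,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        lc_ij = np.where(base > 0, res.p / base, 1.0)
    pairs["pos_i"] = sites["pos"].to_numpy()[si]
    pairs["pos_j"] = sites["pos"].to_numpy()[sj]
    pairs["d"] = d
    pairs["p_i"] = p_site[si]
    pairs["p_j"] = p_site[sj]
    pairs["w_ij"] = w_ij
    pairs["D_ij"] = d_ij
    pairs["LC_ij"] = lc_ij
    pairs["p_ij"] = res.p
    return pairs, res
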