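"""Fractional site occupancy model of CRM activity with TF cooperativity.

The model treats each motif site of a CRM as bound or unbound; every one of
the 2^n binding configurations receives a statistical weight. A bound pMad
site contributes base weight ``a0`` and a bound Tin site ``b0`` (the fully
unbound configuration has weight 1). Cooperativity between adjacently bound
pMad and Tin enters through the geometric overlap of spherical "interaction
spaces" of radius r around each bound protein: for an edge-to-edge gap d the
overlap fraction is

    omega(d, r) = (4r + d) (2r - d)^2 / (16 r^3)   for d < 2r, else 0,

the lens volume of two equal spheres normalized to full overlap. The radius
depends on the orientation of the Tin motif (``r_sense`` / ``r_antisense``).
An interacting pair multiplies the configuration weight by
``1 + (q1 - 1) * omega`` — exactly 1 when the spheres do not touch, the full
cooperative factor ``q1`` at complete overlap. The higher-order model variant
additionally multiplies ``1 + (q2 - 1) * min(omega_left, omega_right)`` for
each contiguous bound pMad-Tin-pMad or Tin-pMad-Tin triple (a chain is as
strong as its weaker contact).

CRM activity in a tissue is the probability mass of configurations that
contain at least one fully bound, cooperatively interacting minimal unit:
a pMad-Tin pair with omega > 0 under the ``pairs_only`` variant, or a
contiguous tissue-specific triple (pMad-Tin-pMad for visceral mesoderm,
Tin-pMad-Tin for heart) with both contacts under ``higher_order``.

Parameters q1, q2, r_sense, r_antisense are fitted to measured penetrance
and expressivity by least squares on a deterministic coarse-to-fine grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .motifs import CRMDesign, Site

__all__ = [
    "ModelParams",
    "TissueRule",
    "VM_RULE",
    "HEART_RULE",
    "VARIANTS",
    "BindingConfiguration",
    "PredictionRecord",
    "FitConfig",
    "CVResult",
    "PMAD_MOTIF",
    "TIN_MOTIF",
    "alternating_design",
    "overlap_weight",
    "enumerate_configurations",
    "partition_function",
    "site_occupancy",
    "activation_probability",
    "predict_observables",
    "predict_measurements",
    "fit_parameters",
    "predict_short_crms",
    "leave_two_out_cv",
    "motif_number_curve",
]

VARIANTS = ("pairs_only", "higher_order")

#: Consensus stand-in motif instances for the two TFs. The occupancy model
#: depends only on edge-to-edge gaps; the 9 bp Tin instance makes the
#: pMad-pMad spacing of alternating designs equal gap + 9 + gap (13 bp at
#: 2 bp gaps, 25 bp at 8 bp gaps).
PMAD_MOTIF = "GGCGCCGG"
TIN_MOTIF = "CTCAAGTGG"

_WEIGHT_FLOOR = 1e-300  # keeps log-domain arithmetic finite for zero weights


@dataclass(frozen=True)
class ModelParams:
    """Thermodynamic model parameters.

    q1, q2 are the effective cooperative weights of an interacting pMad-Tin
    pair and of an interacting triple; r_sense / r_antisense are the
    interaction length scales (bp) used when the Tin site of a contact is in
    sense / antisense orientation. a0 and b0 are the fixed independent
    binding weights of pMad and Tin (not fitted).
    """

    q1: float = 1.0
    q2: float = 1.0
    r_sense: float = 0.0
    r_antisense: float = 0.0
    a0: float = 1.0
    b0: float = 1.0

    def __post_init__(self) -> None:
        if self.q1 < 1 or self.q2 < 1:
            raise ValueError("cooperative weights q1, q2 must be >= 1")
        if self.r_sense < 0 or self.r_antisense < 0:
            raise ValueError("interaction radii must be >= 0")
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("base binding weights must be > 0")

    def base_weight(self, tf_name: str) -> float:
        if tf_name == "pMad":
            return self.a0
        if tf_name == "Tin":
            return self.b0
        raise KeyError(f"no base binding weight defined for TF {tf_name!r}")


@dataclass(frozen=True)
class TissueRule:
    """Tissue-specific minimal cooperative unit required for activity."""

    tissue: str
    minimal_unit: tuple[str, str, str]
    n_domains: int = 4

    def __post_init__(self) -> None:
        if len(self.minimal_unit) != 3:
            raise ValueError("minimal unit must be a TF triple")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")


VM_RULE = TissueRule("VM", ("pMad", "Tin", "pMad"), n_domains=4)
HEART_RULE = TissueRule("heart", ("Tin", "pMad", "Tin"), n_domains=4)


@dataclass(frozen=True)
class BindingConfiguration:
    occupancy: tuple[bool, ...]
    weight: float


@dataclass(frozen=True)
class PredictionRecord:
    crm_name: str
    tissue: str
    predicted_penetrance: float
    predicted_expressivity: float


# ---------------------------------------------------------------------------
# Sphere-overlap cooperativity geometry
# ---------------------------------------------------------------------------

def overlap_weight(gap: float, radius: float) -> float:
    """Fractional overlap of two equal interaction spheres.

    ``gap`` is the center separation (edge-to-edge motif spacing in bp, with
    sphere centers at the motif-proximal edges); ``radius`` the interaction
    length scale. Returns the lens volume normalized to full overlap:
    1 at gap 0, 0 once gap >= 2*radius, monotone non-increasing between.
    """
    if gap < 0 or radius < 0:
        raise ValueError("gap and radius must be >= 0")
    return float(_overlap_weight_vec(np.asarray(gap, float), np.asarray(radius, float)))


def _overlap_weight_vec(gap: np.ndarray, radius: np.ndarray) -> np.ndarray:
    """Vectorized overlap fraction; radius 0 gives 0 everywhere."""
    gap, radius = np.broadcast_arrays(gap, radius)
    out = np.zeros(gap.shape, dtype=float)
    r = np.where(radius > 0, radius, 1.0)  # avoid 0/0; masked out below
    inside = (gap < 2 * radius) & (radius > 0)
    num = (4 * r + gap) * (2 * r - gap) ** 2
    out = np.where(inside, num / (16 * r**3), 0.0)
    return out


# ---------------------------------------------------------------------------
# Design structure (cached per design)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Structure:
    """Precomputed combinatorial structure of one design."""

    n: int
    gaps: np.ndarray           # (G,) float gap lengths
    gap_hetero: np.ndarray     # (G,) bool: adjacent pMad-Tin pair
    gap_homo: np.ndarray       # (G,) bool: adjacent identical-TF pair
    gap_antisense: np.ndarray  # (G,) bool: the contact's Tin is antisense
    configs: np.ndarray        # (2^n, n) float 0/1 occupancy patterns
    pair_bound: np.ndarray     # (2^n, G) float: both gap neighbours bound
    triple_bound: np.ndarray   # (2^n, T) float: window of 3 all bound
    triple_patterns: tuple[tuple[str, str, str], ...]
    triple_alternating: np.ndarray  # (T,) bool: pMad-Tin-pMad or Tin-pMad-Tin


def _tin_orientation_for_gap(left: Site, right: Site) -> bool:
    """True if the Tin site flanking this gap is antisense.

    For a pMad-Tin gap the Tin neighbour decides; for a Tin-Tin gap (only
    reachable through the homotypic extension) antisense wins if either is.
    """
    tins = [s for s in (left, right) if s.tf_name == "Tin"]
    if not tins:
        return True  # homotypic pMad pairs use r_antisense by convention
    return any(s.orientation == "antisense" for s in tins)


@lru_cache(maxsize=256)
def _structure(design: CRMDesign) -> _Structure:
    n = design.n_sites
    if n > 20:
        raise ValueError(f"design {design.name!r} has {n} sites; 2^n enumeration capped at 20")
    sites = design.sites
    gaps = np.asarray(design.spacings, dtype=float)
    g = len(gaps)
    gap_hetero = np.zeros(g, dtype=bool)
    gap_homo = np.zeros(g, dtype=bool)
    gap_antisense = np.zeros(g, dtype=bool)
    for i in range(g):
        left, right = sites[i], sites[i + 1]
        pair = {left.tf_name, right.tf_name}
        gap_hetero[i] = pair == {"pMad", "Tin"}
        gap_homo[i] = left.tf_name == right.tf_name
        gap_antisense[i] = _tin_orientation_for_gap(left, right)
    # all 2^n occupancy patterns, site 0 in the lowest bit
    idx = np.arange(2**n, dtype=np.int64)
    configs = ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(float)
    pair_bound = configs[:, :-1] * configs[:, 1:] if g else np.zeros((2**n, 0))
    t = max(n - 2, 0)
    if t:
        triple_bound = configs[:, :-2] * configs[:, 1:-1] * configs[:, 2:]
    else:
        triple_bound = np.zeros((2**n, 0))
    patterns = tuple(
        (sites[j].tf_name, sites[j + 1].tf_name, sites[j + 2].tf_name) for j in range(t)
    )
    alternating = np.array(
        [p in (("pMad", "Tin", "pMad"), ("Tin", "pMad", "Tin")) for p in patterns],
        dtype=bool,
    )
    return _Structure(
        n=n,
        gaps=gaps,
        gap_hetero=gap_hetero,
        gap_homo=gap_homo,
        gap_antisense=gap_antisense,
        configs=configs,
        pair_bound=pair_bound,
        triple_bound=triple_bound,
        triple_patterns=patterns,
        triple_alternating=alternating,
    )


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; choose from {VARIANTS}")


def _gap_omegas(
    struct: _Structure, rs: np.ndarray, ra: np.ndarray
) -> np.ndarray:
    """Overlap fraction per gap, shape broadcast(rs, ra).shape + (G,)."""
    rs = np.asarray(rs, float)[..., None]
    ra = np.asarray(ra, float)[..., None]
    r = np.where(struct.gap_antisense, ra, rs)
    return _overlap_weight_vec(struct.gaps, r)


def _log_weights(
    struct: _Structure,
    sites: Sequence[Site],
    params_a0: float,
    params_b0: float,
    q1: np.ndarray,
    q2: np.ndarray,
    omega: np.ndarray,
    variant: str,
    include_homotypic: bool,
) -> np.ndarray:
    """Log statistical weight of every configuration.

    ``q1``, ``q2`` broadcast against ``omega[..., G]``; returns an array of
    shape broadcast + (2^n,).
    """
    base = np.array(
        [
            max(params_a0 if s.tf_name == "pMad" else params_b0, _WEIGHT_FLOOR)
            for s in sites
        ]
    )
    log_base = struct.configs @ np.log(base)
    q1 = np.asarray(q1, float)[..., None]
    q2 = np.asarray(q2, float)[..., None]
    coop_gap = struct.gap_hetero | (struct.gap_homo if include_homotypic else False)
    pair_log = np.where(coop_gap, np.log1p((q1 - 1.0) * omega), 0.0)
    logw = log_base + pair_log @ struct.pair_bound.T
    if variant == "higher_order" and struct.triple_bound.shape[1]:
        both = np.minimum(omega[..., :-1], omega[..., 1:])
        trip_log = np.where(
            struct.triple_alternating, np.log1p((q2 - 1.0) * both), 0.0
        )
        logw = logw + trip_log @ struct.triple_bound.T
    return logw


def _unit_mask(
    struct: _Structure,
    tissue_rule: TissueRule,
    variant: str,
    omega: np.ndarray,
) -> np.ndarray:
    """Boolean array (broadcast + 2^n): configuration contains an
    interacting minimal activity unit."""
    if variant == "pairs_only":
        unit = struct.gap_hetero
        contact = (omega > 0) & unit
        hits = contact.astype(float) @ struct.pair_bound.T
    else:
        unit = np.array(
            [p == tissue_rule.minimal_unit for p in struct.triple_patterns], dtype=bool
        )
        if unit.size == 0:
            return np.zeros(omega.shape[:-1] + (2**struct.n,), dtype=bool)
        both = (omega[..., :-1] > 0) & (omega[..., 1:] > 0) & unit
        hits = both.astype(float) @ struct.triple_bound.T
    return hits > 0


# ---------------------------------------------------------------------------
# Public model evaluation
# ---------------------------------------------------------------------------

def enumerate_configurations(
    design: CRMDesign,
    params: ModelParams,
    variant: str = "higher_order",
    include_homotypic: bool = False,
) -> list[BindingConfiguration]:
    """All 2^n binding configurations of the design with their weights."""
    _check_variant(variant)
    struct = _structure(design)
    omega = _gap_omegas(struct, np.array(params.r_sense), np.array(params.r_antisense))
    logw = _log_weights(
        struct, design.sites, params.a0, params.b0,
        np.array(params.q1), np.array(params.q2), omega, variant, include_homotypic,
    )
    weights = np.exp(logw)
    return [
        BindingConfiguration(tuple(bool(b) for b in struct.configs[i]), float(weights[i]))
        for i in range(weights.shape[-1])
    ]


def partition_function(
    design: CRMDesign,
    params: ModelParams,
    variant: str = "higher_order",
    include_homotypic: bool = False,
) -> float:
    """Sum of configuration weights Z (log-domain accumulation)."""
    _check_variant(variant)
    struct = _structure(design)
    omega = _gap_omegas(struct, np.array(params.r_sense), np.array(params.r_antisense))
    logw = _log_weights(
        struct, design.sites, params.a0, params.b0,
        np.array(params.q1), np.array(params.q2), omega, variant, include_homotypic,
    )
    return float(np.exp(logsumexp(logw, axis=-1)))


def site_occupancy(
    design: CRMDesign,
    params: ModelParams,
    variant: str = "higher_order",
    include_homotypic: bool = False,
) -> np.ndarray:
    """Marginal probability that each site is bound."""
    _check_variant(variant)
    struct = _structure(design)
    omega = _gap_omegas(struct, np.array(params.r_sense), np.array(params.r_antisense))
    logw = _log_weights(
        struct, design.sites, params.a0, params.b0,
        np.array(params.q1), np.array(params.q2), omega, variant, include_homotypic,
    )
    w = np.exp(logw - logsumexp(logw, axis=-1))
    return struct.configs.T @ w


def activation_probability(
    design: CRMDesign,
    params: ModelParams,
    tissue_rule: TissueRule,
    variant: str = "higher_order",
    include_homotypic: bool = False,
) -> float:
    """Probability mass of configurations with >= 1 interacting activity unit."""
    p = _activation_batch(
        design,
        np.array(params.q1), np.array(params.q2),
        np.array(params.r_sense), np.array(params.r_antisense),
        tissue_rule, variant, params.a0, params.b0, include_homotypic,
    )
    return float(p)


def _activation_batch(
    design: CRMDesign,
    q1: np.ndarray,
    q2: np.ndarray,
    rs: np.ndarray,
    ra: np.ndarray,
    tissue_rule: TissueRule,
    variant: str,
    a0: float = 1.0,
    b0: float = 1.0,
    include_homotypic: bool = False,
) -> np.ndarray:
    """Activation probability for broadcastable parameter arrays."""
    _check_variant(variant)
    struct = _structure(design)
    q1, q2, rs, ra = np.broadcast_arrays(
        np.asarray(q1, float), np.asarray(q2, float),
        np.asarray(rs, float), np.asarray(ra, float),
    )
    shape = q1.shape
    q1f, q2f, rsf, raf = (x.reshape(-1) for x in (q1, q2, rs, ra))
    out = np.empty(q1f.shape[0])
    chunk = max(1, 2**22 // 2**struct.n)  # cap transient arrays at ~32 MB
    for lo in range(0, q1f.shape[0], chunk):
        sl = slice(lo, lo + chunk)
        omega = _gap_omegas(struct, rsf[sl], raf[sl])
        logw = _log_weights(
            struct, design.sites, a0, b0, q1f[sl], q2f[sl], omega,
            variant, include_homotypic,
        )
        active = _unit_mask(struct, tissue_rule, variant, omega)
        w = np.exp(logw - logsumexp(logw, axis=-1, keepdims=True))
        out[sl] = np.sum(w * active, axis=-1)
    return out.reshape(shape) if shape else out[0]


def predict_observables(p_domain: float, n_domains: int) -> tuple[float, float]:
    """Map a per-domain activation probability to (penetrance, expressivity).

    Domains are taken as independent: expressivity equals the per-domain
    probability and penetrance is the chance that at least one of the
    ``n_domains`` scored domains is active, 1 - (1 - p)^n.
    """
    p = float(p_domain)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p_domain must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** n_domains, p


def predict_measurements(
    designs: Sequence[CRMDesign],
    params: ModelParams,
    tissue_rule: TissueRule,
    variant: str = "higher_order",
    link: str = "power",
) -> pd.DataFrame:
    """Model penetrance/expressivity for each design as a DataFrame."""
    rows = []
    for d in designs:
        p = activation_probability(d, params, tissue_rule, variant)
        if link == "power":
            pen, exp_ = predict_observables(p, tissue_rule.n_domains)
        elif link == "identity":
            pen, exp_ = p, p
        else:
            raise ValueError(f"unknown link {link!r}")
        rows.append(
            {"line": d.name, "tissue": tissue_rule.tissue,
             "penetrance": pen, "expressivity": exp_, "p_domain": p}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parameter fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Deterministic coarse-to-fine grid search settings.

    The coarse grid spans q in [q_min, q_max] log-spaced and the radii in
    [0, r_max] with step ``r_step``; ``n_refine`` local refinement rounds
    shrink the grid around the running optimum (q spacing / 4 and r spacing
    / 5 per round).
    """

    q_min: float = 1.0
    q_max: float = 1000.0
    n_q: int = 13
    r_max: float = 15.0
    r_step: float = 0.5
    n_refine: int = 2
    polish: bool = True
    link: str = "power"
    seed: int = 0

    def q_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.q_min), np.log10(self.q_max), self.n_q)

    def r_grid(self) -> np.ndarray:
        return np.arange(0.0, self.r_max + 1e-9, self.r_step)


def _observed_arrays(
    measurements: pd.DataFrame, designs: Sequence[CRMDesign]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-design observed (penetrance, expressivity), NaN where missing."""
    table = measurements.set_index("line")
    pen = np.full(len(designs), np.nan)
    exp_ = np.full(len(designs), np.nan)
    for i, d in enumerate(designs):
        if d.name not in table.index:
            raise KeyError(f"no measurement row for design {d.name!r}")
        row = table.loc[d.name]
        pen[i] = row.get("penetrance", np.nan)
        exp_[i] = row.get("expressivity", np.nan)
    return pen, exp_


def _grid_residual(
    designs: Sequence[CRMDesign],
    pen_obs: np.ndarray,
    exp_obs: np.ndarray,
    q1: np.ndarray,
    q2: np.ndarray,
    rs: np.ndarray,
    ra: np.ndarray,
    tissue_rule: TissueRule,
    variant: str,
    link: str,
    design_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Summed squared penetrance+expressivity error over designs, per grid point.

    NaN observations contribute nothing; ``design_mask`` selects the designs
    entering the residual (used by cross-validation folds).
    """
    resid = np.zeros(np.broadcast(q1, q2, rs, ra).shape)
    for i, d in enumerate(designs):
        if design_mask is not None and not design_mask[i]:
            continue
        p = _activation_batch(d, q1, q2, rs, ra, tissue_rule, variant)
        if link == "power":
            pen_m = 1.0 - (1.0 - p) ** tissue_rule.n_domains
            exp_m = p
        else:
            pen_m = exp_m = p
        if np.isfinite(pen_obs[i]):
            resid = resid + (pen_m - pen_obs[i]) ** 2
        if np.isfinite(exp_obs[i]):
            resid = resid + (exp_m - exp_obs[i]) ** 2
    return resid


def _coarse_tables(
    designs: Sequence[CRMDesign],
    pen_obs: np.ndarray,
    exp_obs: np.ndarray,
    tissue_rule: TissueRule,
    variant: str,
    config: FitConfig,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Coarse parameter grid and each design's residual contribution on it.

    Shared across cross-validation folds: a fold's coarse residual is the
    sum of contributions over its training designs.
    """
    qg, rg = config.q_grid(), config.r_grid()
    grids = np.meshgrid(qg, qg, rg, rg, indexing="ij")
    flat = [g.reshape(-1) for g in grids]
    contrib = np.zeros((len(designs), flat[0].shape[0]))
    for i, d in enumerate(designs):
        p = _activation_batch(d, *flat, tissue_rule, variant)
        if config.link == "power":
            pen_m = 1.0 - (1.0 - p) ** tissue_rule.n_domains
            exp_m = p
        else:
            pen_m = exp_m = p
        if np.isfinite(pen_obs[i]):
            contrib[i] += (pen_m - pen_obs[i]) ** 2
        if np.isfinite(exp_obs[i]):
            contrib[i] += (exp_m - exp_obs[i]) ** 2
    return flat, contrib


def _search(
    designs: Sequence[CRMDesign],
    pen_obs: np.ndarray,
    exp_obs: np.ndarray,
    tissue_rule: TissueRule,
    variant: str,
    config: FitConfig,
    design_mask: np.ndarray | None = None,
    coarse: tuple[list[np.ndarray], np.ndarray] | None = None,
) -> tuple[ModelParams, float]:
    """Coarse grid search followed by local grid refinement."""
    if coarse is None:
        coarse = _coarse_tables(designs, pen_obs, exp_obs, tissue_rule, variant, config)
    flat, contrib = coarse
    if design_mask is None:
        resid = contrib.sum(axis=0)
    else:
        resid = contrib[design_mask].sum(axis=0)
    best = int(np.argmin(resid))
    q1b, q2b, rsb, rab = (g[best] for g in flat)
    best_resid = float(resid[best])

    dq = (np.log10(config.q_max) - np.log10(config.q_min)) / max(config.n_q - 1, 1)
    dr = config.r_step
    for _ in range(config.n_refine):
        dq /= 4.0
        dr /= 5.0
        q1g = np.clip(q1b * np.logspace(-4 * dq, 4 * dq, 9), config.q_min, None)
        q2g = np.clip(q2b * np.logspace(-4 * dq, 4 * dq, 9), config.q_min, None)
        rsg = np.clip(rsb + np.arange(-5, 6) * dr, 0.0, config.r_max)
        rag = np.clip(rab + np.arange(-5, 6) * dr, 0.0, config.r_max)
        grids = np.meshgrid(q1g, q2g, rsg, rag, indexing="ij")
        flat = [g.reshape(-1) for g in grids]
        resid = _grid_residual(
            designs, pen_obs, exp_obs, *flat, tissue_rule, variant,
            config.link, design_mask,
        )
        best = int(np.argmin(resid))
        if float(resid[best]) <= best_resid:
            q1b, q2b, rsb, rab = (g[best] for g in flat)
            best_resid = float(resid[best])

    if config.polish:
        # Simplex polish along the (often shallow) q1/q2 ridge; radii move
        # only within the continuous region found by the grid. Deterministic.
        from scipy.optimize import minimize

        def objective(x: np.ndarray) -> float:
            lq1, lq2, rs_, ra_ = x
            if lq1 < 0 or lq2 < 0 or not (0 <= rs_ <= config.r_max) or not (
                0 <= ra_ <= config.r_max
            ):
                return float("inf")
            r = _grid_residual(
                designs, pen_obs, exp_obs,
                np.array(10.0**lq1), np.array(10.0**lq2),
                np.array(rs_), np.array(ra_),
                tissue_rule, variant, config.link, design_mask,
            )
            return float(r)

        x0 = np.array([np.log10(q1b), np.log10(q2b), rsb, rab])
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
        )
        if np.isfinite(res.fun) and res.fun <= best_resid:
            q1b, q2b = 10.0 ** res.x[0], 10.0 ** res.x[1]
            rsb, rab = res.x[2], res.x[3]
            best_resid = float(res.fun)

    params = ModelParams(
        q1=float(q1b), q2=float(q2b),
        r_sense=float(rsb), r_antisense=float(rab),
    )
    return params, best_resid


def fit_parameters(
    measurements: pd.DataFrame,
    designs: Sequence[CRMDesign],
    tissue_rule: TissueRule,
    variant: str = "higher_order",
    fit_config: FitConfig | None = None,
) -> tuple[ModelParams, float]:
    """Fit (q1, q2, r_sense, r_antisense) to penetrance/expressivity data.

    Minimizes the summed squared difference between model and observation
    for both observables over all designs (missing observations are
    skipped). The search is a deterministic coarse grid followed by local
    refinement; returns the fitted parameters and the residual.
    """
    _check_variant(variant)
    if measurements is None or len(measurements) == 0:
        raise ValueError("measurements table is empty")
    designs = list(designs)
    if len(designs) < 2:
        raise ValueError("need measurements for at least two CRMs")
    config = fit_config or FitConfig()
    pen_obs, exp_obs = _observed_arrays(measurements, designs)
    return _search(designs, pen_obs, exp_obs, tissue_rule, variant, config)


def predict_short_crms(
    params: ModelParams,
    short_designs: Sequence[CRMDesign],
    tissue_rule: TissueRule,
    variant: str = "higher_order",
    link: str = "power",
) -> list[PredictionRecord]:
    """Predict held-out (e.g. shortened) CRMs with no refitting."""
    records = []
    for d in short_designs:
        p = activation_probability(d, params, tissue_rule, variant)
        if link == "power":
            pen, exp_ = predict_observables(p, tissue_rule.n_domains)
        else:
            pen = exp_ = p
        records.append(PredictionRecord(d.name, tissue_rule.tissue, pen, exp_))
    return records


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVResult:
    tolerances: np.ndarray
    fraction_within: np.ndarray   # fitted-model held-out predictions
    random_baseline: np.ndarray   # analytic expectation for uniform guesses
    errors: np.ndarray            # pooled |prediction - observation|
    n_folds: int


def leave_two_out_cv(
    measurements: pd.DataFrame,
    designs: Sequence[CRMDesign],
    tissue_rule: TissueRule,
    variant: str = "higher_order",
    tolerance_grid: Sequence[float] | None = None,
    fit_config: FitConfig | None = None,
) -> CVResult:
    """Leave-two-out cross-validation over all C(n, 2) design pairs.

    Each fold refits on the remaining designs and predicts the held-out
    pair; the curve reports, per tolerance, the fraction of held-out
    penetrance and expressivity predictions within that absolute error.
    The analytic baseline is the same fraction expected for predictions
    drawn uniformly from [0, 1].
    """
    designs = list(designs)
    if len(designs) < 3:
        raise ValueError("leave-two-out needs at least three designs")
    config = fit_config or FitConfig()
    tol = np.asarray(
        tolerance_grid if tolerance_grid is not None else np.arange(0.05, 0.501, 0.05)
    )
    pen_obs, exp_obs = _observed_arrays(measurements, designs)
    coarse = _coarse_tables(designs, pen_obs, exp_obs, tissue_rule, variant, config)
    errors: list[float] = []
    observed: list[float] = []
    n_folds = 0
    for i, j in itertools.combinations(range(len(designs)), 2):
        mask = np.ones(len(designs), dtype=bool)
        mask[[i, j]] = False
        params, _ = _search(
            designs, pen_obs, exp_obs, tissue_rule, variant, config,
            design_mask=mask, coarse=coarse,
        )
        for k in (i, j):
            p = activation_probability(designs[k], params, tissue_rule, variant)
            if config.link == "power":
                pen_m, exp_m = predict_observables(p, tissue_rule.n_domains)
            else:
                pen_m = exp_m = p
            if np.isfinite(pen_obs[k]):
                errors.append(abs(pen_m - pen_obs[k]))
                observed.append(pen_obs[k])
            if np.isfinite(exp_obs[k]):
                errors.append(abs(exp_m - exp_obs[k]))
                observed.append(exp_obs[k])
        n_folds += 1
    err = np.asarray(errors)
    obs = np.asarray(observed)
    fraction = np.array([np.mean(err <= t) for t in tol])
    baseline = np.array(
        [np.mean(np.minimum(obs + t, 1.0) - np.maximum(obs - t, 0.0)) for t in tol]
    )
    return CVResult(tol, fraction, baseline, err, n_folds)


# ---------------------------------------------------------------------------
# Design builders and motif-number curves
# ---------------------------------------------------------------------------

def alternating_design(
    name: str,
    n_sites: int,
    gap: int,
    tin_orientation: str = "antisense",
    first_tf: str = "pMad",
) -> CRMDesign:
    """Alternating pMad/Tin design with uniform edge-to-edge gaps."""
    order = ("pMad", "Tin") if first_tf == "pMad" else ("Tin", "pMad")
    sites = []
    for i in range(n_sites):
        tf = order[i % 2]
        seq = PMAD_MOTIF if tf == "pMad" else TIN_MOTIF
        orient = "sense" if tf == "pMad" else tin_orientation
        sites.append(Site(tf, seq, orient))
    return CRMDesign(name, tuple(sites), tuple([gap] * (n_sites - 1)))


def motif_number_curve(
    params: ModelParams,
    orientation: str,
    gap: int,
    n_range: Iterable[int],
    tissue_rule: TissueRule,
) -> pd.DataFrame:
    """Predicted activity versus total motif count for both model variants.

    Designs alternate pMad/Tin starting with pMad, with the given Tin
    orientation and uniform gap.
    """
    rows = []
    for n in n_range:
        if not 1 <= n <= 10:
            raise ValueError("motif counts must lie in [1, 10]")
        d = alternating_design(f"pMad-Tin x{n}", n, gap, orientation)
        row = {"n_motifs": n}
        for variant in VARIANTS:
            row[variant] = activation_probability(d, params, tissue_rule, variant)
        rows.append(row)
    return pd.DataFrame(rows)
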