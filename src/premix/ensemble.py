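"""Ensemble reweighting against observed PREs.

A sparse ensemble explaining the observed Γ₂ rates is selected from a large
candidate pool by minimizing the ensemble Q-factor

    Q_ens = sqrt( Σ_i (Γ₂ᵒᵇˢ(i) − Σ_k p_k Γ₂ᶜᵃˡᶜ'ᵏ(i))² / Σ_i Γ₂ᵒᵇˢ(i)² )

over nonnegative population weights p_k, where i runs over the observed
(label site, methyl) pairs and k over pool members.  The weights are not
constrained to sum to one: the observed rates are transferred PREs scaled by
the (unknown) bound fraction, so the overall scale is absorbed into the
weights and they are renormalized only for visualization.

Optimization follows a stepwise funnel: populations of small random groups
are optimized independently (simulated annealing followed by quasi-Newton
polish), groups are merged with damped previous weights as starting values,
the top fraction of members by weight survives each merge, and a final joint
optimization is run on the surviving members.

The library surface is a statsmodels-style pair: :class:`PREEnsembleModel`
built from observed Γ₂ sets and a back-calculated Γ₂ matrix, whose ``fit()``
returns a :class:`PREEnsembleResults` with the weights, fit quality and
provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .peaks import Gamma2Set, PeakFlag

__all__ = [
    "FitConfig",
    "WeightedEnsemble",
    "q_ens",
    "align_observed",
    "best_single_structure",
    "optimize_group",
    "hierarchical_fit",
    "PREEnsembleModel",
    "PREEnsembleResults",
]


@dataclass(frozen=True)
class FitConfig:
    """Settings of the stepwise weight optimization.

    ``group_size`` members are optimized per initial group; ``merge_factor``
    groups are merged per super-group; the ``top_fraction`` of members by
    weight survives each super-group; survivors are pooled to ``final_size``
    for the last joint optimization.  Previous-stage weights are damped by
    ``init_damping`` when used as starting values.  ``sa_steps`` Metropolis
    moves precede the quasi-Newton polish in every group optimization.
    """

    group_size: int = 100
    merge_factor: int = 10
    top_fraction: float = 0.10
    final_size: int = 1000
    init_damping: float = 0.1
    sa_steps: int = 200
    sa_t_start: float = 0.1
    sa_t_end: float = 1e-4
    sa_move_sigma: float = 0.1
    gtol: float = 1e-12
    maxiter: int = 2000
    refine: bool = True
    lasso_scale: float = 2.0
    #: independent funnel replicates whose unanimously selected members form
    #: the final support on noisy data (stability selection); 1 disables it
    consensus_runs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.group_size < 1 or self.merge_factor < 1 or self.final_size < 1:
            raise ValueError("group sizes must be positive")


@dataclass
class WeightedEnsemble:
    """A weighted structure ensemble and its fit quality.

    ``member_ids`` index rows of the back-calculated Γ₂ matrix; ``weights``
    are the (nonnegative, unnormalized) populations; ``provenance`` logs the
    optimization stages.
    """

    member_ids: np.ndarray
    weights: np.ndarray
    q_ens: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.member_ids = np.asarray(self.member_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.member_ids) != len(self.weights):
            raise ValueError("member_ids and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.q_ens < 0:
            raise ValueError("q_ens must be nonnegative")

    @property
    def normalized_weights(self) -> np.ndarray:
        s = self.weights.sum()
        return self.weights / s if s > 0 else self.weights

    @property
    def q_ls(self) -> float:
        """Q-factor of the unregularized stepwise minimization (stage 4).

        Equals ``q_ens`` when no noise-driven support selection ran.
        """
        return float(self.provenance.get("q_ls", self.q_ens))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "member_id": self.member_ids,
                "weight": self.weights,
                "normalized_weight": self.normalized_weights,
            }
        )


def align_observed(
    observed: Sequence[Gamma2Set], calc: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, pd.MultiIndex, np.ndarray]:
    """Align observed Γ₂ entries with the back-calculated matrix columns.

    Only entries with flag ``ok`` enter the fit (nonpositive and unresolved
    entries carry no usable rate).  Returns the observed vector, the aligned
    calc matrix (members × observables), the (site, methyl) index and the
    propagated Γ₂ uncertainties.
    """
    pairs: list[tuple[str, str]] = []
    values: list[float] = []
    errors: list[float] = []
    for gset in observed:
        for e in gset.entries:
            if e.flag is PeakFlag.OK:
                pairs.append((gset.label_site, e.methyl_id))
                values.append(e.gamma2)
                errors.append(e.gamma2_err)
    if not pairs:
        raise ValueError("no usable (flag=ok) observed Γ₂ entries")
    missing = [p for p in pairs if p not in calc.columns]
    if missing:
        raise KeyError(f"calc matrix lacks columns for {missing[:5]}")
    idx = pd.MultiIndex.from_tuples(pairs, names=["site", "methyl_id"])
    C = calc.loc[:, idx].to_numpy(dtype=float)
    if not np.all(np.isfinite(C)):
        bad = calc.index[~np.isfinite(C).all(axis=1)][0]
        raise ValueError(f"non-finite back-calculated Γ₂ for member {bad!r}")
    return (
        np.asarray(values, dtype=float),
        C,
        idx,
        np.asarray(errors, dtype=float),
    )


def q_ens(obs: np.ndarray, calc: np.ndarray, weights: np.ndarray) -> float:
    """Ensemble Q-factor for an aligned observed vector and calc matrix.

    ``calc`` has shape (n_members, n_obs); ``weights`` length n_members.
    """
    obs = np.asarray(obs, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    den = float(np.sum(obs**2))
    if den == 0:
        raise ValueError("all observed Γ₂ are zero: Q-factor undefined")
    pred = w @ np.asarray(calc, dtype=float)
    return math.sqrt(float(np.sum((obs - pred) ** 2)) / den)


def best_single_structure(
    obs: np.ndarray, calc: np.ndarray
) -> tuple[int, float, float]:
    """Best single-structure fit with one free nonnegative scale.

    For each member k the Q-factor is minimized over a scalar population
    p ≥ 0 (closed form p = Σ obs·calc / Σ calc², clipped at zero); returns
    ``(k_best, q_best, p_best)``.
    """
    obs = np.asarray(obs, dtype=float)
    C = np.asarray(calc, dtype=float)
    if C.ndim != 2 or len(C) == 0:
        raise ValueError("calc must be a nonempty (members, observables) matrix")
    den = float(np.sum(obs**2))
    if den == 0:
        raise ValueError("all observed Γ₂ are zero: Q-factor undefined")
    num = C @ obs                       # Σ_i obs·calc per member
    c2 = np.einsum("ki,ki->k", C, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(c2 > 0, np.clip(num / np.where(c2 > 0, c2, 1.0), 0, None), 0.0)
    resid = den - 2.0 * p * num + p**2 * c2
    q2 = np.maximum(resid, 0.0) / den
    k = int(np.argmin(q2))
    return k, math.sqrt(float(q2[k])), float(p[k])


def _q2_and_grad(w: np.ndarray, C: np.ndarray, obs: np.ndarray, den: float):
    resid = obs - w @ C
    q2 = float(resid @ resid) / den
    grad = (-2.0 / den) * (C @ resid)
    return q2, grad


def _active_set_refine(
    C: np.ndarray,
    obs: np.ndarray,
    w0: np.ndarray,
    tol_rel: float = 1e-12,
    max_outer: int | None = None,
) -> np.ndarray:
    """Active-set (Lawson–Hanson-type) polish of a nonnegative LS solution.

    Starting from the support of a feasible ``w0``, alternately solves the
    least-squares problem restricted to the passive set (removing members
    driven negative) and admits the excluded member with the largest positive
    residual correlation, until the first-order optimality conditions hold.
    Converges to a vertex solution, driving redundant members to exact zero —
    which quasi-Newton iterations approach only asymptotically.
    """
    n, n_obs = C.shape
    w = np.clip(np.asarray(w0, dtype=float), 0.0, None).copy()
    passive = w > 0
    g0 = np.abs(C @ obs).max()
    tol = tol_rel * max(g0, 1.0)
    max_outer = max_outer or 3 * min(n, n_obs) + 10
    for _ in range(max_outer):
        # restricted least squares with removal of negative members
        for _ in range(2 * n + 2):
            idx = np.flatnonzero(passive)
            if len(idx) == 0:
                w[:] = 0.0
                break
            z, *_ = np.linalg.lstsq(C[idx].T, obs, rcond=None)
            if np.all(z > 0):
                w[:] = 0.0
                w[idx] = z
                break
            # step from w toward z, stopping at the first zero crossing
            wi = w[idx]
            neg = z <= 0
            denom = wi[neg] - z[neg]
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas = np.where(denom > 0, wi[neg] / denom, 0.0)
            alpha = float(np.min(alphas)) if len(alphas) else 0.0
            wi = wi + alpha * (z - wi)
            wi[wi < 1e-14] = 0.0
            w[:] = 0.0
            w[idx] = wi
            passive = w > 0
        r = obs - w @ C
        grad = C @ r
        grad[passive] = -np.inf
        k = int(np.argmax(grad))
        if grad[k] <= tol:
            break
        passive[k] = True
    return w


def optimize_group(
    obs: np.ndarray,
    calc: np.ndarray,
    init_weights: np.ndarray | None,
    cfg: FitConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Optimize the populations of one member group.

    A short simulated-annealing stage over latent variables q (p = q², which
    enforces nonnegativity) precedes a bounded quasi-Newton (L-BFGS-B) polish
    from the annealing optimum; an active-set refinement then resolves the
    solution's support exactly.  The returned Q never exceeds the Q at the
    starting weights.
    """
    C = np.asarray(calc, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if C.ndim != 2 or len(C) == 0:
        raise ValueError("empty member group")
    den = float(np.sum(obs**2))
    if den == 0:
        raise ValueError("all observed Γ₂ are zero: Q-factor undefined")
    n = len(C)
    if init_weights is None:
        # uniform start at the least-squares scale of the mean fingerprint
        s = C.sum(axis=0)
        alpha = max(float(obs @ s) / float(s @ s), 0.0) if s @ s > 0 else 0.0
        w0 = np.full(n, alpha)
    else:
        w0 = np.clip(np.asarray(init_weights, dtype=float), 0.0, None)
        if len(w0) != n:
            raise ValueError("init_weights length mismatch")

    q2_init, _ = _q2_and_grad(w0, C, obs, den)
    if not np.isfinite(q2_init):
        raise ValueError("non-finite Q at the starting weights")

    # --- simulated annealing over latents (incremental residual updates)
    rng = rng or np.random.default_rng(cfg.seed)
    lat = np.sqrt(w0)
    pred = (lat**2) @ C
    resid = obs - pred
    e = float(resid @ resid)
    best_lat, best_e = lat.copy(), e
    if cfg.sa_steps > 0 and n > 0:
        T = cfg.sa_t_start * den
        cool = (cfg.sa_t_end / cfg.sa_t_start) ** (1.0 / max(cfg.sa_steps - 1, 1))
        js = rng.integers(0, n, size=cfg.sa_steps)
        moves = rng.normal(0.0, cfg.sa_move_sigma, size=cfg.sa_steps)
        us = rng.random(cfg.sa_steps)
        for step in range(cfg.sa_steps):
            j = js[step]
            new_lj = lat[j] + moves[step]
            dw = new_lj**2 - lat[j] ** 2
            new_resid = resid - dw * C[j]
            e_new = float(new_resid @ new_resid)
            if e_new <= e or us[step] < math.exp(-(e_new - e) / T):
                lat[j] = new_lj
                resid = new_resid
                e = e_new
                if e < best_e:
                    best_e = e
                    best_lat = lat.copy()
            T *= cool

    # --- quasi-Newton polish with analytic gradient, bounds p >= 0
    # (rows scaled to unit norm: fingerprint norms vary over orders of
    # magnitude, which otherwise cripples the quasi-Newton conditioning)
    w_sa = best_lat**2
    norms = np.linalg.norm(C, axis=1)
    norms[norms == 0] = 1.0
    Cn = C / norms[:, None]
    res = minimize(
        _q2_and_grad,
        w_sa * norms,
        args=(Cn, obs, den),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * n,
        options={"maxiter": cfg.maxiter, "gtol": cfg.gtol, "ftol": 1e-15},
    )
    if not np.isfinite(res.fun):
        raise ValueError("optimization produced a non-finite Q")
    w_qn = np.clip(res.x, 0.0, None) / norms
    candidates = [(q2_init, w0), (best_e / den, w_sa), (float(res.fun), w_qn)]
    if cfg.refine:
        w_ref = _active_set_refine(C, obs, w_qn)
        candidates.append((_q2_and_grad(w_ref, C, obs, den)[0], w_ref))
    q2_best, w_best = min(candidates, key=lambda t: t[0])
    return w_best, math.sqrt(max(q2_best, 0.0))


def _nn_lasso(
    C: np.ndarray, obs: np.ndarray, lam: float, sweeps: int = 400
) -> np.ndarray:
    """Nonnegative L1-penalized least squares by cyclic coordinate descent.

    Minimizes ||obs − wᵀC||² + λ Σ w_k over w ≥ 0; the penalty on the total
    population drives redundant members to exact zero.
    """
    n = len(C)
    w = np.zeros(n)
    r = obs.astype(float).copy()
    c2 = np.einsum("ki,ki->k", C, C)
    for _ in range(sweeps):
        delta = 0.0
        for k in range(n):
            if c2[k] == 0:
                continue
            new = max(0.0, w[k] + (C[k] @ r - lam) / c2[k])
            d = new - w[k]
            if d != 0.0:
                r -= d * C[k]
                w[k] = new
                delta = max(delta, abs(d))
        if delta < 1e-10:
            break
    return w


def hierarchical_fit(
    obs: np.ndarray,
    calc: np.ndarray,
    cfg: FitConfig | None = None,
    obs_err: np.ndarray | None = None,
) -> WeightedEnsemble:
    """Stepwise grouped population optimization over a full candidate pool.

    (1) the pool is partitioned into disjoint random groups of ``group_size``
    and each group's populations are optimized; (2) ``merge_factor`` groups at
    a time are merged into super-groups and re-optimized starting from the
    damped previous weights; (3) the ``top_fraction`` of members with the
    highest populations survives each super-group; (4) survivors are pooled
    (truncated to ``final_size`` by damped weight if needed) and a final
    joint optimization is run.  Deterministic given ``cfg.seed``.

    When propagated Γ₂ uncertainties are supplied (``obs_err``) a support
    selection stage follows: an unconstrained least-squares optimum spreads
    population over members that merely absorb measurement noise, so the
    final member set is re-estimated with an L1 (total population) penalty
    scaled to the noise level, and the selected support is refit without the
    penalty.  With ``cfg.consensus_runs > 1`` the whole funnel is repeated
    with independent random partitions and only members selected in every
    replicate keep weight (stability selection) — noise-fitting decoys vary
    between partitions while genuinely required members persist.  The
    reported ``q_ens`` is always the unpenalized Q-factor of the returned
    weights; the provenance records the per-replicate stages and the
    unregularized optimum ``q_ls``.
    """
    cfg = cfg or FitConfig()
    C = np.asarray(calc, dtype=float)
    obs = np.asarray(obs, dtype=float)

    sigma = 0.0
    if obs_err is not None:
        err = np.asarray(obs_err, dtype=float)
        finite = err[np.isfinite(err)]
        if finite.size:
            sigma = float(np.median(finite))

    if not (sigma > 0 and cfg.lasso_scale > 0 and cfg.consensus_runs > 1):
        return _hierarchical_once(obs, C, cfg, sigma)

    replicates = []
    for rep in range(cfg.consensus_runs):
        rep_cfg = _dc_replace(cfg, seed=cfg.seed + 7919 * rep)
        replicates.append(_hierarchical_once(obs, C, rep_cfg, sigma))
    # unanimity consensus: keep members carrying weight in every replicate
    supports = [
        set(np.asarray(e.member_ids)[e.weights > 1e-6].tolist())
        for e in replicates
    ]
    consensus = sorted(set.intersection(*supports))
    base = replicates[0]
    if not consensus:
        return base
    members = np.asarray(base.member_ids)
    w_final = np.zeros(len(members))
    pos = {int(m): i for i, m in enumerate(members)}
    cons_pos = np.array([pos[m] for m in consensus])
    w_final[cons_pos] = _active_set_refine(
        C[np.asarray(consensus)], obs, np.full(len(consensus), 1e-6)
    )
    q_final = q_ens(obs, C[members], w_final)
    provenance = {
        "seed": cfg.seed,
        "pool_size": len(C),
        "consensus_runs": cfg.consensus_runs,
        "n_consensus": len(consensus),
        "q_ls": base.provenance.get("q_ls", base.q_ens),
        "replicates": [e.provenance for e in replicates],
    }
    return WeightedEnsemble(members, w_final, q_final, provenance)


def _hierarchical_once(
    obs: np.ndarray,
    C: np.ndarray,
    cfg: FitConfig,
    sigma: float,
) -> WeightedEnsemble:
    """One pass of the stepwise funnel (stages 1–5)."""
    n = len(C)
    if n < cfg.group_size:
        raise ValueError(f"pool size {n} smaller than group_size {cfg.group_size}")
    rng = np.random.default_rng(cfg.seed)
    provenance: dict = {"seed": cfg.seed, "pool_size": n, "stages": []}

    # stage 1: disjoint random groups
    perm = rng.permutation(n)
    groups = [perm[i : i + cfg.group_size] for i in range(0, n, cfg.group_size)]
    group_weights: list[np.ndarray] = []
    stage1_q: list[float] = []
    for g in groups:
        w, q = optimize_group(obs, C[g], None, cfg, rng)
        group_weights.append(w)
        stage1_q.append(q)
    provenance["stages"].append(
        {"stage": "groups", "n_groups": len(groups), "q": stage1_q}
    )

    # stage 2: merge groups into super-groups, damped re-optimization
    super_members: list[np.ndarray] = []
    super_weights: list[np.ndarray] = []
    stage2_q: list[float] = []
    for i in range(0, len(groups), cfg.merge_factor):
        chunk = groups[i : i + cfg.merge_factor]
        members = np.concatenate(chunk)
        init = cfg.init_damping * np.concatenate(group_weights[i : i + cfg.merge_factor])
        w, q = optimize_group(obs, C[members], init, cfg, rng)
        super_members.append(members)
        super_weights.append(w)
        stage2_q.append(q)
    provenance["stages"].append(
        {"stage": "merge", "n_supergroups": len(super_members), "q": stage2_q}
    )

    # stage 3: keep the top fraction by weight from each super-group
    surv_members: list[np.ndarray] = []
    surv_weights: list[np.ndarray] = []
    for members, w in zip(super_members, super_weights):
        n_keep = max(1, int(round(cfg.top_fraction * len(members))))
        order = np.lexsort((members, -w))  # weight desc, ties by member index
        keep = order[:n_keep]
        surv_members.append(members[keep])
        surv_weights.append(w[keep])
    members = np.concatenate(surv_members)
    weights = np.concatenate(surv_weights)
    if len(members) > cfg.final_size:
        order = np.lexsort((members, -weights))[: cfg.final_size]
        members, weights = members[order], weights[order]
    order = np.argsort(members)
    members, weights = members[order], weights[order]
    provenance["stages"].append({"stage": "select", "n_survivors": int(len(members))})

    # stage 4: final joint optimization from damped survivor weights
    w_final, q_final = optimize_group(
        obs, C[members], cfg.init_damping * weights, cfg, rng
    )
    provenance["stages"].append({"stage": "final", "q": q_final})
    provenance["q_ls"] = q_final

    # stage 5 (noisy data only): noise-scaled L1 support selection + refit
    if sigma > 0 and cfg.lasso_scale > 0:
        Cf = C[members]
        lam = cfg.lasso_scale * sigma * float(
            np.median(np.linalg.norm(Cf, axis=1))
        )
        w_l1 = _nn_lasso(Cf, obs, lam)
        support = np.flatnonzero(w_l1 > 1e-6)
        if support.size:
            w_sel = np.zeros(len(members))
            w_sel[support] = _active_set_refine(
                Cf[support], obs, np.full(support.size, 1e-6)
            )
            q_sel = q_ens(obs, Cf, w_sel)
            provenance["stages"].append(
                {
                    "stage": "support_selection",
                    "lambda": lam,
                    "sigma": sigma,
                    "n_support": int(support.size),
                    "q_ls": q_final,
                    "q": q_sel,
                }
            )
            w_final, q_final = w_sel, q_sel
    return WeightedEnsemble(members, w_final, q_final, provenance)


# ---------------------------------------------------------------------------
# model / results surface


class PREEnsembleModel:
    """Ensemble reweighting model: observed PREs vs a candidate pool.

    Parameters
    ----------
    observed : sequence of Gamma2Set
        Per-label-site observed Γ₂ rates (only flag=ok entries are fitted).
    calc : pandas.DataFrame
        Back-calculated Γ₂ matrix, rows = pool members, columns = a
        (site, methyl_id) MultiIndex covering every observed pair.
    """

    def __init__(self, observed: Sequence[Gamma2Set], calc: pd.DataFrame):
        self.observed = list(observed)
        self.calc = calc
        self.endog, self.exog, self.obs_index, self.endog_err = align_observed(
            self.observed, calc
        )

    @classmethod
    def from_tables(cls, gamma2_paths: dict[str, str], matrix_path: str):
        """Build from per-site Γ₂ TSVs (site → path) and a matrix TSV."""
        from .forward import read_gamma2_matrix
        from .peaks import read_gamma2_table

        observed = [read_gamma2_table(p, site) for site, p in gamma2_paths.items()]
        return cls(observed, read_gamma2_matrix(matrix_path))

    @property
    def n_obs(self) -> int:
        return len(self.endog)

    @property
    def n_members(self) -> int:
        return len(self.exog)

    def q_ens(self, weights: np.ndarray, member_ids: np.ndarray | None = None) -> float:
        C = self.exog if member_ids is None else self.exog[np.asarray(member_ids)]
        return q_ens(self.endog, C, weights)

    def fit(
        self, method: str = "hierarchical", config: FitConfig | None = None
    ) -> "PREEnsembleResults":
        """Fit population weights.

        ``method='hierarchical'`` runs the stepwise grouped minimization;
        ``method='single'`` selects the best single structure with one free
        scale; ``method='group'`` jointly optimizes the whole pool in one go.
        """
        config = config or FitConfig()
        if method == "hierarchical":
            ens = hierarchical_fit(self.endog, self.exog, config, self.endog_err)
        elif method == "single":
            k, q, p = best_single_structure(self.endog, self.exog)
            ens = WeightedEnsemble(
                np.array([k]), np.array([p]), q, {"stages": [{"stage": "single"}]}
            )
        elif method == "group":
            rng = np.random.default_rng(config.seed)
            w, q = optimize_group(self.endog, self.exog, None, config, rng)
            ens = WeightedEnsemble(
                np.arange(self.n_members), w, q, {"stages": [{"stage": "joint"}]}
            )
        else:
            raise ValueError(f"unknown fit method {method!r}")
        return PREEnsembleResults(self, ens, method, config)


class PREEnsembleResults:
    """Fitted ensemble weights and diagnostics."""

    def __init__(
        self,
        model: PREEnsembleModel,
        ensemble: WeightedEnsemble,
        method: str,
        config: FitConfig,
    ):
        self.model = model
        self.ensemble = ensemble
        self.method = method
        self.config = config

    @property
    def member_ids(self) -> np.ndarray:
        return self.ensemble.member_ids

    @property
    def weights(self) -> pd.Series:
        return pd.Series(self.ensemble.weights, index=self.ensemble.member_ids,
                         name="weight")

    @property
    def normalized_weights(self) -> pd.Series:
        return pd.Series(self.ensemble.normalized_weights,
                         index=self.ensemble.member_ids, name="normalized_weight")

    @property
    def q_ens(self) -> float:
        return self.ensemble.q_ens

    @property
    def n_active(self) -> int:
        """Members carrying more than 0.1% of the total weight."""
        w = self.ensemble.normalized_weights
        return int(np.sum(w > 1e-3))

    def predict(self) -> pd.Series:
        """Ensemble-averaged Γ₂ per observed (site, methyl)."""
        members = np.asarray(self.ensemble.member_ids, dtype=int)
        pred = self.ensemble.weights @ self.model.exog[members]
        return pd.Series(pred, index=self.model.obs_index, name="gamma2_calc")

    def per_site_q(self) -> pd.Series:
        obs = pd.Series(self.model.endog, index=self.model.obs_index)
        pred = self.predict()
        out = {}
        for site in obs.index.get_level_values("site").unique():
            o = obs.xs(site, level="site").to_numpy()
            p = pred.xs(site, level="site").to_numpy()
            out[site] = math.sqrt(float(np.sum((o - p) ** 2) / np.sum(o**2)))
        return pd.Series(out, name="q_site")

    def observed_vs_calc(self) -> pd.DataFrame:
        """Table of observed and ensemble-calculated Γ₂ (for bar plots)."""
        return pd.DataFrame(
            {
                "gamma2_obs": pd.Series(self.model.endog, index=self.model.obs_index),
                "gamma2_calc": self.predict(),
            }
        )

    def summary(self) -> str:
        lines = [
            "PRE ensemble reweighting results",
            "=" * 48,
            f"method:            {self.method}",
            f"observables:       {self.model.n_obs}",
            f"pool members:      {self.model.n_members}",
            f"ensemble members:  {len(self.ensemble.member_ids)}",
            f"active members:    {self.n_active} (>0.1% weight)",
            f"total population:  {self.ensemble.weights.sum():.4f}",
            f"Q_ens:             {self.ensemble.q_ens:.4f}",
            "per-site Q:",
        ]
        for site, q in self.per_site_q().items():
            lines.append(f"  {site:<20s} {q:.4f}")
        top = self.weights.sort_values(ascending=False).head(10)
        lines.append("top members by weight:")
        for mid, w in top.items():
            lines.append(f"  member {mid:<8} weight {w:.4f}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Bar plot of observed Γ₂ with ensemble-calculated values overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        table = self.observed_vs_calc()
        x = np.arange(len(table))
        ax.bar(x, table["gamma2_obs"], color="0.6", label=r"$\Gamma_2^{obs}$")
        ax.plot(x, table["gamma2_calc"], "_", color="tab:orange", markersize=8,
                label=r"$\Gamma_2^{calc}$")
        ax.set_ylabel(r"$\Gamma_2$ (s$^{-1}$)")
        ax.set_xlabel("observable index (site, methyl)")
        ax.legend()
        return ax

    def save(self, weights_path, report_path) -> None:
        """Write the weights TSV and a JSON fit report."""
        self.ensemble.to_frame().to_csv(weights_path, sep="\t", index=False)
        report = {
            "method": self.method,
            "q_ens": self.ensemble.q_ens,
            "per_site_q": self.per_site_q().to_dict(),
            "n_obs": self.model.n_obs,
            "n_members_pool": self.model.n_members,
            "n_members_ensemble": int(len(self.ensemble.member_ids)),
            "total_population": float(self.ensemble.weights.sum()),
            "provenance": _jsonable(self.ensemble.provenance),
        }
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
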