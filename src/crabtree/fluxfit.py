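"""Intracellular flux estimation from SFL measurements and extracellular rates.

The fitter minimizes a weighted least-squares objective

    SSR = sum_i ((SFL_sim,i - SFL_obs,i) / sd_i)^2
        + sum_r ((v_r - r_obs,r) / sd_r)^2

over steady-state flux distributions with the glucose uptake fixed to 100
(the normalized scale of the reported flux maps).  Steady state is enforced
structurally: the optimizer works in free-flux coordinates spanning the
null space of the stoichiometric matrix, so every candidate flux vector
satisfies S v = 0 to machine precision.  Bounds on irreversible dependent
fluxes are handled by clipping inside the label simulator plus a smooth
penalty residual; the returned solution is checked against the bounds.

The global search is a seeded multistart of a trust-region-reflective
least-squares solver; the best objective wins, ties (within 1e-9) broken by
lowest start index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .labeling import AminoAcidFragmentMap, EMUSimulator, default_fragment_map
from .network import AtomMapNetwork, stoichiometric_matrix

__all__ = [
    "FluxState",
    "MeasurementSet",
    "FluxFitResult",
    "FitConfig",
    "FreeFluxBasis",
    "steady_state_flux_map",
    "fit_fluxes",
    "normalize_fluxes",
    "monte_carlo_intervals",
    "linearized_flux_sd",
]

STEADY_TOL = 1e-9
BOUND_PENALTY = 1e3


@dataclass
class FluxState:
    """Net fluxes per reaction (glucose uptake = 100 scale) and exchange
    extents in [0, 1] for reversible reactions (0 = no bidirectional
    exchange)."""

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def vector(self, reaction_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.net.get(r, 0.0) for r in reaction_ids])

    def scaled(self, factor: float) -> "FluxState":
        return FluxState({r: v * factor for r, v in self.net.items()},
                         dict(self.exchange))


@dataclass
class MeasurementSet:
    """SFL observations plus measured (normalized) uptake/secretion rates.

    ``sfl``: DataFrame with columns fragment_id, sfl_percent, sd_percent.
    ``rates``: DataFrame with columns reaction, rate, sd.  Measured rates of
    absent products are included as 0 +/- sd rather than omitted.
    """

    sfl: pd.DataFrame
    rates: pd.DataFrame

    def __post_init__(self):
        if len(self.sfl) + len(self.rates) == 0:
            raise ValueError("measurement set is empty")
        for df, sd_col in ((self.sfl, "sd_percent"), (self.rates, "sd")):
            if len(df) and (df[sd_col] <= 0).any():
                raise ValueError("measurement sds must be > 0")


@dataclass
class FluxFitResult:
    fluxes: FluxState
    ssr: float
    residuals: pd.DataFrame
    converged: bool
    n_starts: int
    start_objectives: np.ndarray
    multistart_dispersion: float
    message: str = ""


@dataclass
class FitConfig:
    multistart: int = 20
    seed: int = 17
    basis_reaction: str = "HXK"
    basis_value: float = 100.0
    flux_upper: float = 300.0
    start_upper: float = 150.0
    fragment_map: AminoAcidFragmentMap | None = None
    max_nfev: int = 300
    n_polish: int = 4
    polish_nfev: int = 150
    initial: "FluxState | None" = None


class FreeFluxBasis:
    """Null-space parameterization with deterministic pivoting.

    Gaussian elimination runs over columns in a fixed order (preferred-free
    reactions last), so the pivot (dependent) set is reproducible and
    scenario-relevant fluxes stay free.  v = T u, with u the free fluxes.
    """

    def __init__(self, net: AtomMapNetwork, preferred_free: Sequence[str] | None = None):
        S = stoichiometric_matrix(net)
        self.reaction_ids = list(S.columns)
        if preferred_free is None:
            preferred_free = self._default_preferred(net)
        order = [r for r in self.reaction_ids if r not in preferred_free]
        order += [r for r in preferred_free if r in self.reaction_ids]
        A = S[order].to_numpy().astype(float)
        m, n = A.shape
        piv_cols: list[int] = []
        row = 0
        A = A.copy()
        for col in range(n):
            if row >= m:
                break
            sub = np.abs(A[row:, col])
            imax = int(np.argmax(sub))
            if sub[imax] < 1e-10:
                continue
            A[[row, row + imax]] = A[[row + imax, row]]
            A[row] = A[row] / A[row, col]
            mask = np.arange(m) != row
            A[mask] -= np.outer(A[mask, col], A[row])
            piv_cols.append(col)
            row += 1
        dep = [order[c] for c in piv_cols]
        free = [r for r in order if r not in dep]
        self.dependent = dep
        self.free = free
        # v_dep = -S_dep^{-1} S_free v_free
        Sd = S[dep].to_numpy()
        Sf = S[free].to_numpy()
        D = -np.linalg.lstsq(Sd, Sf, rcond=None)[0]
        self.T = np.zeros((len(self.reaction_ids), len(free)))
        ridx = {r: i for i, r in enumerate(self.reaction_ids)}
        for j, r in enumerate(free):
            self.T[ridx[r], j] = 1.0
        for i, r in enumerate(dep):
            self.T[ridx[r], :] = D[i]
        self._S = S.to_numpy()

    @staticmethod
    def _default_preferred(net: AtomMapNetwork) -> list[str]:
        # later in the list = more strongly preferred free
        pref = [r for r in ("PYC", "PDC", "ACT", "ADH") if r in net.reactions]
        pref += [r for r in net.reactions if r.startswith("EX_")]
        pref += [r for r in net.reactions if r.startswith("BM_")]
        pref += [r for r in ("ZWF", "MAE", "ICL", "PDH", "HXK") if r in net.reactions]
        return pref

    def fluxes(self, u: np.ndarray) -> np.ndarray:
        return self.T @ u

    def free_values(self, flux: Mapping[str, float]) -> np.ndarray:
        return np.array([float(flux.get(r, 0.0)) for r in self.free])

    def bounds(self, net: AtomMapNetwork, upper: float) -> tuple[np.ndarray, np.ndarray]:
        lb, ub = [], []
        for r in self.free:
            rev = net.reactions[r].reversible
            lb.append(-upper if rev else 0.0)
            ub.append(upper)
        return np.array(lb), np.array(ub)


def steady_state_flux_map(net: AtomMapNetwork, targets: Mapping[str, float],
                          require_feasible: bool = True) -> FluxState:
    """Construct a steady-state flux map hitting the given target fluxes.

    The targets must pin down all degrees of freedom (an exact linear solve
    in null-space coordinates); a dependency among targets or an infeasible
    (negative irreversible) solution raises.
    """
    from scipy.linalg import null_space

    S = stoichiometric_matrix(net)
    rids = list(S.columns)
    N = null_space(S.to_numpy())
    P = np.zeros((len(targets), len(rids)))
    t = np.zeros(len(targets))
    for i, (r, val) in enumerate(targets.items()):
        if r not in rids:
            raise ValueError(f"unknown reaction {r}")
        P[i, rids.index(r)] = 1.0
        t[i] = val
    A = P @ N
    u, *_ = np.linalg.lstsq(A, t, rcond=None)
    v = N @ u
    miss = np.abs(P @ v - t)
    if miss.max() > 1e-6:
        bad = [r for (r, _), m in zip(targets.items(), miss) if m > 1e-6]
        raise ValueError(f"targets not simultaneously satisfiable (check dependencies): {bad}")
    flux = dict(zip(rids, (float(x) for x in v)))
    if require_feasible:
        neg = [r for r, x in flux.items()
               if x < -1e-9 and not net.reactions[r].reversible]
        if neg:
            raise ValueError(f"no feasible steady-state flux map: negative irreversible {neg}")
        for r in flux:
            if not net.reactions[r].reversible and flux[r] < 0:
                flux[r] = 0.0
    return FluxState(flux)


def _residual_builder(net: AtomMapNetwork, meas: MeasurementSet, config: FitConfig,
                      basis: FreeFluxBasis):
    frag_map = config.fragment_map or default_fragment_map()
    frag_map.validate(net)
    sim = EMUSimulator(net, frag_map.all_precursors(), check_steady_state=False)
    sfl_obs = meas.sfl["sfl_percent"].to_numpy(dtype=float)
    sfl_sd = meas.sfl["sd_percent"].to_numpy(dtype=float)
    sfl_labels = list(meas.sfl["fragment_id"])
    entry_map = dict(frag_map.entries)
    missing = [l for l in sfl_labels if l not in entry_map]
    if missing:
        raise ValueError(f"measured fragments not in fragment map: {missing}")
    parts_per_label = [entry_map[l] for l in sfl_labels]
    rate_rxns = list(meas.rates["reaction"]) if len(meas.rates) else []
    rate_obs = meas.rates["rate"].to_numpy(dtype=float) if rate_rxns else np.zeros(0)
    rate_sd = meas.rates["sd"].to_numpy(dtype=float) if rate_rxns else np.ones(0)
    ridx = {r: i for i, r in enumerate(basis.reaction_ids)}
    rate_idx = np.array([ridx[r] for r in rate_rxns], dtype=int)
    irrev_idx = np.array([i for i, r in enumerate(basis.reaction_ids)
                          if not net.reactions[r].reversible], dtype=int)
    fixed_j = basis.free.index(config.basis_reaction)

    def expand(u_opt: np.ndarray) -> np.ndarray:
        u = np.insert(u_opt, fixed_j, config.basis_value)
        return basis.fluxes(u)

    def residuals(u_opt: np.ndarray) -> np.ndarray:
        v = expand(u_opt)
        viol = np.minimum(v[irrev_idx], 0.0)
        v_sim = v.copy()
        v_sim[irrev_idx] = np.maximum(v_sim[irrev_idx], 0.0)
        fluxmap = dict(zip(basis.reaction_ids, v_sim))
        try:
            sims = sim.mids(fluxmap, strict=False)
        except Exception:
            return np.full(len(sfl_obs) + len(rate_idx) + len(irrev_idx), 1e6)
        sfl_sim = np.empty(len(sfl_obs))
        for i, parts in enumerate(parts_per_label):
            mid = None
            for frag in parts:
                m = sims[frag]
                mid = m if mid is None else np.convolve(mid, m)
            sfl_sim[i] = 100.0 * np.dot(np.arange(len(mid)), mid)
        res = [(sfl_sim - sfl_obs) / sfl_sd]
        if len(rate_idx):
            res.append((v[rate_idx] - rate_obs) / rate_sd)
        res.append(BOUND_PENALTY * viol)
        return np.concatenate(res)

    return residuals, expand, fixed_j, sfl_labels, rate_rxns


def _feasible_starts(net: AtomMapNetwork, basis: FreeFluxBasis, fixed_j: int,
                     config: FitConfig, meas: MeasurementSet,
                     lb: np.ndarray, ub: np.ndarray,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Multistart points inside the steady-state flux polytope.

    Start 0 anchors the measured rates: a small ridge-regularized quadratic
    program fits the (linear) rate measurements subject to the
    irreversible-flux inequalities.  The remaining starts are drawn by a
    seeded hit-and-run walk from it along rate-consistent directions (the
    null space of the rate map), so every start satisfies the bounds and
    already matches the measured secretion/drain fluxes.  With no measured
    rates the walk explores the full free-flux space from the maximum-slack
    (Chebyshev-style) center.
    """
    from scipy.linalg import null_space
    from scipy.optimize import LinearConstraint, linprog, minimize

    irrev = [i for i, r in enumerate(basis.reaction_ids)
             if not net.reactions[r].reversible]
    T_opt = np.delete(basis.T, fixed_j, axis=1)
    c0 = basis.T[:, fixed_j] * config.basis_value
    A_ir = T_opt[irrev]            # feasibility: c0_ir + A_ir u >= 0
    b_ir = c0[irrev]
    n = T_opt.shape[1]
    # feasibility check and fallback center: max eps of the slack
    A_ub = np.hstack([-A_ir, np.ones((len(irrev), 1))])
    c = np.zeros(n + 1)
    c[-1] = -1.0
    lp = linprog(c, A_ub=A_ub, b_ub=b_ir,
                 bounds=[(l, u) for l, u in zip(lb, ub)] + [(0, config.start_upper)],
                 method="highs")
    if not lp.success or lp.x[-1] <= 0:
        raise ValueError("no feasible steady-state flux exists within bounds")
    center = lp.x[:-1]
    directions = np.eye(n)
    base = center
    if len(meas.rates):
        ridx = {r: i for i, r in enumerate(basis.reaction_ids)}
        rows = [ridx[r] for r in meas.rates["reaction"]]
        A = T_opt[rows]
        b = meas.rates["rate"].to_numpy(dtype=float) - c0[rows]
        w = 1.0 / meas.rates["sd"].to_numpy(dtype=float)

        def obj(u):
            r = w * (A @ u - b)
            return float(r @ r) + 1e-6 * float(u @ u)

        def grad(u):
            return 2.0 * A.T @ (w * w * (A @ u - b)) + 2e-6 * u

        qp = minimize(obj, center, jac=grad, method="trust-constr",
                      constraints=[LinearConstraint(A_ir, -b_ir + 0.3, np.inf)],
                      bounds=list(zip(lb, ub)),
                      options={"maxiter": 300, "gtol": 1e-10})
        base = np.clip(qp.x, lb, ub)
        N = null_space(A)
        if N.shape[1] > 0:
            directions = N
    starts = []
    if config.initial is not None:
        u0 = basis.free_values(config.initial.net)
        starts.append(np.clip(np.delete(u0, fixed_j), lb, ub))
    starts.append(base)
    x = base.copy()
    while len(starts) < max(config.multistart, 1):
        for _step in range(3):
            d = directions @ rng.standard_normal(directions.shape[1])
            nrm = np.linalg.norm(d)
            if nrm == 0:
                continue
            d /= nrm
            lo, hi = -1e9, 1e9
            Ad = A_ir @ d
            slack = A_ir @ x + b_ir
            for a, s in zip(Ad, slack):
                if a > 1e-12:
                    lo = max(lo, -s / a)
                elif a < -1e-12:
                    hi = min(hi, -s / a)
            for dj, xj, l, u in zip(d, x, lb, ub):
                if dj > 1e-12:
                    hi = min(hi, (u - xj) / dj)
                    lo = max(lo, (l - xj) / dj)
                elif dj < -1e-12:
                    hi = min(hi, (l - xj) / dj)
                    lo = max(lo, (u - xj) / dj)
            if hi > lo:
                x = x + (lo + rng.uniform(0.0, 1.0) * (hi - lo)) * d
        starts.append(x.copy())
    return starts[: max(config.multistart, 1)]


def _basis_for(net: AtomMapNetwork, config: FitConfig) -> FreeFluxBasis:
    """Basis with the configured basis reaction forced into the free set."""
    pref = FreeFluxBasis._default_preferred(net)
    pref = [r for r in pref if r != config.basis_reaction] + [config.basis_reaction]
    return FreeFluxBasis(net, preferred_free=pref)


def fit_fluxes(net: AtomMapNetwork, meas: MeasurementSet,
               config: FitConfig | None = None) -> FluxFitResult:
    """Estimate net fluxes by constrained weighted least squares.

    Best of ``config.multistart`` seeded starts; deterministic given the
    seed.  Start 0 anchors the measured rates (a feasible quadratic-program
    solution); the remaining starts explore rate-consistent directions of
    the flux polytope by a seeded hit-and-run walk.  The best candidates
    are polished with a central-difference Levenberg-Marquardt pass.
    """
    config = config or FitConfig()
    basis = _basis_for(net, config)
    if config.basis_reaction not in basis.free:
        raise ValueError(f"basis reaction {config.basis_reaction} is not a free flux")
    residuals, expand, fixed_j, _, _ = _residual_builder(net, meas, config, basis)
    lb, ub = basis.bounds(net, config.flux_upper)
    lb = np.delete(lb, fixed_j)
    ub = np.delete(ub, fixed_j)
    rng = np.random.default_rng(config.seed)
    starts = _feasible_starts(net, basis, fixed_j, config, meas, lb, ub, rng)
    stage1 = []
    for k, x0 in enumerate(starts):
        sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                            diff_step=1e-4, x_scale="jac",
                            xtol=1e-10, ftol=1e-12, gtol=1e-12,
                            max_nfev=config.max_nfev)
        stage1.append((float(2.0 * sol.cost), k, sol))
    objectives = np.array([s[0] for s in stage1])
    # polish the best few candidates: the identifiable directions are often
    # shallow valleys, which need an accurate (central-difference) Jacobian
    order = sorted(stage1, key=lambda s: (s[0], s[1]))
    best = None
    for obj1, k, sol1 in order[: max(config.n_polish, 1)]:
        sol = least_squares(residuals, sol1.x, method="lm", jac="3-point",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14,
                            max_nfev=config.polish_nfev)
        out_of_bounds = bool(np.any(sol.x < lb - 1e-6) or np.any(sol.x > ub + 1e-6))
        if out_of_bounds:
            sol = least_squares(residuals, np.clip(sol1.x, lb, ub),
                                bounds=(lb, ub), method="trf", jac="3-point",
                                x_scale="jac", xtol=1e-14, ftol=1e-14,
                                gtol=1e-14, max_nfev=config.polish_nfev)
        obj = float(2.0 * sol.cost)
        if best is None or obj < best[0] - 1e-9:
            best = (obj, k, sol)
    obj, k_best, sol = best
    v = expand(sol.x)
    # snap tiny negative irreversible values produced by the penalty scheme
    flux = {}
    for r, x in zip(basis.reaction_ids, v):
        if not net.reactions[r].reversible and -1e-6 < x < 0:
            x = 0.0
        flux[r] = float(x)
    state = FluxState(flux)
    infeasible = [r for r, x in state.net.items()
                  if x < -1e-6 and not net.reactions[r].reversible]
    n_meas = len(meas.sfl) + len(meas.rates)
    converged = (not infeasible) and (bool(sol.status > 0) or obj <= n_meas)
    res_vec = residuals(sol.x)
    _, _, _, sfl_labels, rate_rxns = _residual_builder(net, meas, config, basis)
    names = [f"sfl:{l}" for l in sfl_labels] + [f"rate:{r}" for r in rate_rxns]
    res_df = pd.DataFrame({"measurement": names,
                           "weighted_residual": res_vec[:len(names)]})
    return FluxFitResult(
        fluxes=state, ssr=obj, residuals=res_df, converged=converged,
        n_starts=len(starts), start_objectives=objectives,
        multistart_dispersion=float(np.std(objectives)),
        message="" if converged else f"non-convergence or infeasible fluxes {infeasible}",
    )


def normalize_fluxes(raw: FluxState, basis_reaction: str,
                     basis_value: float = 100.0) -> FluxState:
    """Rescale all net fluxes so the basis reaction equals ``basis_value``.

    Exchange extents are a dimensionless parameterization and are kept.
    """
    b = raw.net.get(basis_reaction, 0.0)
    if b == 0:
        raise ValueError(f"basis reaction {basis_reaction} has zero flux")
    return raw.scaled(basis_value / b)


def monte_carlo_intervals(net: AtomMapNetwork, meas: MeasurementSet,
                          fit: FluxFitResult, n_resamples: int = 100,
                          seed: int = 0, config: FitConfig | None = None,
                          wide_interval: float = 50.0) -> pd.DataFrame:
    """Percentile (2.5-97.5%) flux intervals by measurement resampling.

    Each resample perturbs the measurements with their stated sds and
    refits (a short local fit started at the point estimate).  Fluxes whose
    interval spans more than ``wide_interval`` units are flagged poorly
    determined.  Failed refits are counted, not silently dropped.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    if n_resamples < 10:
        raise ValueError("n_resamples must be >= 10")
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    basis = _basis_for(net, config)
    samples = []
    failures = 0
    x_center = None
    for b in range(n_resamples):
        sfl = meas.sfl.copy()
        sfl["sfl_percent"] = sfl["sfl_percent"] + rng.normal(
            0.0, sfl["sd_percent"].to_numpy())
        rates = meas.rates.copy()
        if len(rates):
            rates["rate"] = rates["rate"] + rng.normal(0.0, rates["sd"].to_numpy())
        pmeas = MeasurementSet(sfl, rates)
        residuals, expand, fixed_j, _, _ = _residual_builder(net, pmeas, config, basis)
        if x_center is None:
            u = basis.free_values(fit.fluxes.net)
            x_center = np.delete(u, fixed_j)
        lb, ub = basis.bounds(net, config.flux_upper)
        lb = np.delete(lb, fixed_j)
        ub = np.delete(ub, fixed_j)
        try:
            sol = least_squares(residuals, np.clip(x_center, lb, ub),
                                bounds=(lb, ub), method="trf",
                                diff_step=1e-4, x_scale="jac",
                                xtol=1e-9, max_nfev=config.max_nfev)
            samples.append(expand(sol.x))
        except Exception:
            failures += 1
    if not samples:
        raise RuntimeError("all Monte-Carlo refits failed")
    arr = np.array(samples)
    lo = np.percentile(arr, 2.5, axis=0)
    hi = np.percentile(arr, 97.5, axis=0)
    df = pd.DataFrame({
        "reaction": basis.reaction_ids,
        "fitted": [fit.fluxes.net[r] for r in basis.reaction_ids],
        "lo2.5": lo, "hi97.5": hi,
    })
    df["poorly_determined"] = (df["hi97.5"] - df["lo2.5"]) > wide_interval
    df.attrs["n_failures"] = failures
    return df


def linearized_flux_sd(net: AtomMapNetwork, meas: MeasurementSet,
                       at: FluxState, config: FitConfig | None = None) -> pd.Series:
    """First-order flux standard deviations at a given flux state.

    Propagates the measurement sds through the local Jacobian of the
    weighted residuals: cov(u) = (J'J)^+ and cov(v) = T cov(u) T'.  A
    first-order screen for which fluxes the data determine at a given
    noise level (curved shallow valleys can still exceed it).
    """
    config = config or FitConfig()
    basis = _basis_for(net, config)
    residuals, expand, fixed_j, _, _ = _residual_builder(net, meas, config, basis)
    u = np.delete(basis.free_values(at.net), fixed_j)
    n = len(u)
    r0 = residuals(u)
    J = np.empty((len(r0), n))
    h = 1e-4 * np.maximum(np.abs(u), 1.0)
    for j in range(n):
        up = u.copy(); up[j] += h[j]
        dn = u.copy(); dn[j] -= h[j]
        J[:, j] = (residuals(up) - residuals(dn)) / (2 * h[j])
    cov_u = np.linalg.pinv(J.T @ J, rcond=1e-12)
    # full-u covariance with the fixed basis coordinate at zero variance
    cov_full = np.zeros((n + 1, n + 1))
    keep = [i for i in range(n + 1) if i != fixed_j]
    cov_full[np.ix_(keep, keep)] = cov_u
    cov_v = basis.T @ cov_full @ basis.T.T
    sd = np.sqrt(np.clip(np.diag(cov_v), 0.0, None))
    return pd.Series(sd, index=basis.reaction_ids, name="flux_sd")
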