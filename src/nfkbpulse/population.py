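"""Heterogeneous cell populations.

Two noise models reproduce cell-to-cell variability:

* **extrinsic** — biochemical parameters differ between cells but are fixed
  within a cell (imprinted states); per-cell values are drawn once from a
  truncated-normal (or lognormal) distribution and reused for the cell's
  lifetime, so repeated identical stimulation of the same cell gives
  identical responses;
* **intrinsic** — all cells share one parameter set but the two
  NF-κB-controlled feedback genes (IκBα and A20) switch stochastically
  between transcriptionally active and silent states (a telegraph process),
  so repeated stimulation of the same cell can give different responses.

The module also implements the quantile calibration that maps a measured
fraction-of-responding-cells curve onto the per-cell total-IKKK
distribution: for each pulse interval Δ a response threshold θ(Δ) is found
by bisection, and the distribution s.d. σ is fitted so that
P(IKKK > θ(Δ)) matches the measured fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.integrate import odeint
from scipy.optimize import minimize_scalar

from .model import N_STATE, Trajectory, _rhs, _segment_signals, simulate_cell, steady_state
from .params import ModelParameters, PARAM_NAMES
from .protocols import Pulse, StimulationProtocol, two_pulse

__all__ = [
    "NoiseMode", "PopulationSpec", "CellSpec", "sample_population",
    "run_population", "simulate_cell_intrinsic", "response_threshold",
    "calibrate_ikkk_distribution", "CalibrationResult",
    "equilibrated_pulse_experiment", "calibrated_population",
]

#: mean total IKKK per branch (molecules); anchors the molecule scale
IKKK_MEAN = 1.0e6


class NoiseMode(str, Enum):
    extrinsic = "extrinsic"
    intrinsic = "intrinsic"


@dataclass(frozen=True)
class DistributedParam:
    mean: float
    sd: float
    family: str = "normal_truncated"   # or "lognormal"

    def sample(self, rng: np.random.Generator, n: int,
               stratified: bool = False) -> np.ndarray:
        """Draw ``n`` values; ``stratified`` draws one value per probability
        quantile slice (jittered within the slice, order shuffled), so a
        population of n cells covers the distribution's quantiles evenly —
        the same construction that maps responder fractions onto quantiles
        during calibration."""
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.sd == 0:
            return np.full(n, self.mean)
        if stratified:
            u = (np.arange(n) + rng.uniform(size=n)) / n
            u = rng.permutation(u)
        else:
            u = rng.uniform(size=n)
        if self.family == "normal_truncated":
            a = -self.mean / self.sd          # truncate at zero
            return stats.truncnorm.ppf(u, a, np.inf, loc=self.mean, scale=self.sd)
        if self.family == "lognormal":
            # mean/sd interpreted on the natural scale
            s2 = math.log(1.0 + (self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - 0.5 * s2
            return np.exp(stats.norm.ppf(u, loc=mu, scale=math.sqrt(s2)))
        raise ValueError(f"unknown distribution family {self.family!r}")


@dataclass
class PopulationSpec:
    n_cells: int = 300
    noise_mode: NoiseMode = NoiseMode.extrinsic
    distributed_params: Mapping[str, DistributedParam] = field(default_factory=dict)
    gene_switch_on: float = 0.2     # intrinsic mode: max on-switch rate (1/min)
    gene_switch_off: float = 0.1    # intrinsic mode: off-switch rate (1/min)
    stratified: bool = False        # quantile-stratified per-parameter draws
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in self.distributed_params:
            if name not in PARAM_NAMES and name not in ModelParameters().to_dict():
                raise ValueError(f"unknown parameter name {name!r}")


@dataclass
class CellSpec:
    """One cell: parameter overrides drawn once and fixed (imprinting)."""
    cell_id: str
    overrides: dict[str, float]
    seed: int
    noise_mode: NoiseMode = NoiseMode.extrinsic

    def params(self, base: ModelParameters) -> ModelParameters:
        return base.replace(**self.overrides)


def all_parameter_noise(base: ModelParameters, cv: float = 0.3,
                        exclude: Sequence[str] = ("h_tx", "h_ikk")) -> dict[str, DistributedParam]:
    """σ = cv·μ truncated-normal spread on every kinetic parameter.

    Hill exponents are excluded by default (they are shape constants, not
    rates); the dose/washout constants are left fixed as protocol properties.
    """
    skip = set(exclude) | {"K_d_T", "K_d_I", "h_d", "tau_w"}
    out = {}
    for name in PARAM_NAMES:
        if name in skip:
            continue
        mu = float(getattr(base, name))
        if mu > 0:
            out[name] = DistributedParam(mean=mu, sd=cv * mu)
    return out


def sample_population(spec: PopulationSpec, base: ModelParameters) -> list[CellSpec]:
    """Draw ``spec.n_cells`` cells with per-cell fixed parameter overrides."""
    rng = np.random.default_rng(spec.rng_seed)
    draws = {name: dp.sample(rng, spec.n_cells, stratified=spec.stratified)
             for name, dp in spec.distributed_params.items()}
    cell_seeds = rng.integers(0, 2**31 - 1, size=spec.n_cells)
    cells = []
    for i in range(spec.n_cells):
        overrides = {name: float(vals[i]) for name, vals in draws.items()}
        cells.append(CellSpec(cell_id=f"cell{i:04d}", overrides=overrides,
                              seed=int(cell_seeds[i]), noise_mode=spec.noise_mode))
    return cells


def run_population(cells: Sequence[CellSpec], protocol: StimulationProtocol,
                   base: ModelParameters | None = None, dt_out: float = 1.0,
                   ) -> list[Trajectory]:
    """Simulate every cell under ``protocol``; deterministic per cell in
    extrinsic mode, seeded stochastic in intrinsic mode.

    The resting steady state does not depend on the branch IKKK totals (the
    kinase cycles are off at rest), so it is reused across cells whose
    overrides touch only those totals.
    """
    if not cells:
        raise ValueError("cells must be non-empty")
    base = base or ModelParameters()
    core_names = {"IKKKtott_T", "IKKKtott_I"}
    shared_y0 = None
    if all(set(c.overrides) <= core_names for c in cells):
        shared_y0 = steady_state(base)
    out = []
    for cell in cells:
        try:
            p = cell.params(base)
            if cell.noise_mode == NoiseMode.intrinsic:
                traj = simulate_cell_intrinsic(cell, protocol, base=base, dt_out=dt_out)
            else:
                traj = simulate_cell(p, protocol, dt_out=dt_out, y0=shared_y0,
                                     cell_id=cell.cell_id)
        except Exception as exc:
            raise RuntimeError(f"simulation failed for {cell.cell_id}: {exc}") from exc
        out.append(traj)
    return out


# ---------------------------------------------------------------------------
# intrinsic noise: telegraph feedback genes


def simulate_cell_intrinsic(cell: CellSpec, protocol: StimulationProtocol,
                            base: ModelParameters | None = None,
                            dt_out: float = 1.0,
                            switch_on: float = 0.2,
                            switch_off: float = 0.1,
                            rng: np.random.Generator | None = None) -> Trajectory:
    """Hybrid simulation: ODE species with stochastic two-state feedback genes.

    Each feedback gene (IκBα, A20) is ON or OFF.  The ON-switch hazard is
    ``switch_on`` times the NF-κB transcription Hill term, the OFF-switch
    hazard is ``switch_off``; while ON, transcription runs at the Hill rate
    divided by the stationary ON-occupancy, so the fast-switching (and the
    population-mean) limit reproduces the deterministic model at every
    activity level.  Between switches the ODE is integrated deterministically;
    switch times come from inverting the integrated hazard (next-reaction
    scheme), reproducible per cell seed.
    """
    if switch_on <= 0 or switch_off <= 0:
        raise ValueError("gene switch rates must be > 0")
    base = base or ModelParameters()
    p = cell.params(base)
    rng = rng if rng is not None else np.random.default_rng(cell.seed)

    y0 = steady_state(p)
    vec = p.vector()

    def hill_of(nfn: float) -> float:
        nh = nfn ** p.h_tx
        return nh / (p.k_nfkb_half ** p.h_tx + nh)

    # stationary gene states at rest
    h0 = hill_of(y0[7])
    p_on0 = switch_on * h0 / (switch_on * h0 + switch_off)
    gene = np.array([rng.random() < p_on0, rng.random() < p_on0])  # IκBα, A20
    budget = rng.exponential(size=2)

    grid = np.arange(0.0, protocol.t_end + 0.5 * dt_out, dt_out)
    ys = np.full((grid.size, N_STATE), np.nan)
    ys[0] = y0
    y = y0.copy()
    # sub-grid fine enough to localize switches of the faster process
    dt_sub = min(dt_out, max(0.005, 0.25 / (switch_on + switch_off)))

    for (a, b, trT0, decT, trI0, decI) in _segment_signals(protocol, p):
        t = a
        while t < b - 1e-9:
            rate_scale = switch_on * hill_of(y[7]) + switch_off
            chunk = min(b - t, max(2.0 * dt_out, 4.0 / max(rate_scale, 1e-3)))
            t_hi = min(b, t + chunk)
            ts = np.unique(np.concatenate([
                np.arange(t, t_hi, dt_sub), [t_hi],
                grid[(grid > t) & (grid <= t_hi)]]))
            ts = ts[np.concatenate([[True], np.diff(ts) > 1e-9])]
            if ts[-1] < t_hi - 1e-9:
                ts = np.append(ts, t_hi)
            if len(ts) < 2:
                ts = np.array([t, t_hi])
            tr0T = trT0 * (math.exp(-decT * (t - a)) if decT > 0 else 1.0)
            tr0I = trI0 * (math.exp(-decI * (t - a)) if decI > 0 else 1.0)
            sol = odeint(_rhs, y, ts,
                         args=(vec, tr0T, tr0I, decT, decI, t,
                               float(gene[0]), float(gene[1]),
                               switch_on, switch_off),
                         rtol=1e-6, atol=1e-2, mxstep=50000)
            hills = np.array([hill_of(s[7]) for s in sol])
            hz = np.empty((len(ts), 2))
            for j in range(2):
                hz[:, j] = switch_off if gene[j] else switch_on * hills
            dt_seg = np.diff(ts)
            cum = np.vstack([np.zeros(2),
                             np.cumsum(0.5 * (hz[1:] + hz[:-1]) * dt_seg[:, None],
                                       axis=0)])
            fired_j, fired_k = -1, len(ts)
            for j in range(2):
                k = int(np.searchsorted(cum[:, j], budget[j]))
                if k < fired_k:
                    fired_j, fired_k = j, k
            stop = fired_k if fired_j >= 0 else len(ts) - 1
            # commit output samples up to the stopping point
            for k in range(stop + 1):
                gi = int(round(ts[k] / dt_out))
                if gi < grid.size and abs(grid[gi] - ts[k]) < 1e-9:
                    ys[gi] = sol[k]
            budget -= cum[stop]
            y = sol[stop]
            t = float(ts[stop])
            if fired_j >= 0:
                gene[fired_j] = not gene[fired_j]
                budget[fired_j] = rng.exponential()
    # forward-fill any grid points skipped by event alignment
    for i in range(1, grid.size):
        if np.isnan(ys[i, 0]):
            ys[i] = ys[i - 1]
    ys = np.clip(ys, 0.0, None)
    return Trajectory(t=grid, y=ys, params=p, protocol=protocol, cell_id=cell.cell_id)


# ---------------------------------------------------------------------------
# responder rule on trajectories (model rule; re-exported by trace analysis)


def _net_amplitude(traj: Trajectory, pulse_time: float, window: float = 45.0) -> float:
    nf = traj.nfkb_nuclear_fraction
    i0 = int(np.argmin(np.abs(traj.t - pulse_time)))
    i1 = int(np.argmin(np.abs(traj.t - (pulse_time + window))))
    if traj.t[-1] + 1e-9 < pulse_time + window or i1 <= i0:
        raise ValueError("trajectory does not cover the response window")
    return float(nf[i0:i1 + 1].max() - nf[i0])


def _responds(traj: Trajectory, pulse_time: float, threshold: float = 0.15) -> bool:
    return _net_amplitude(traj, pulse_time) > threshold


# ---------------------------------------------------------------------------
# quantile calibration of the IKKK distribution


def response_threshold(delta: float, base: ModelParameters,
                       protocol_kind: str = "TT",
                       which: str | None = None,
                       lo_frac: float = 0.01, hi_frac: float = 30.0,
                       rtol: float = 1e-3,
                       y0: np.ndarray | None = None) -> float:
    """Minimal branch-IKKK total θ(Δ) for which the cell responds to pulse 2.

    Bisection (geometric midpoint) on the relevant branch total; the second
    pulse of a Δ-spaced pair is classified with the >15 %-of-total nuclear
    NF-κB rule.
    """
    mu = IKKK_MEAN
    which = which or ("IKKKtott_I" if protocol_kind[1] == "I" else "IKKKtott_T")
    proto = two_pulse(delta, protocol_kind, tail=50.0)
    if y0 is None:
        y0 = steady_state(base)

    def ok(tot: float) -> bool:
        traj = simulate_cell(base.replace(**{which: tot}), proto, y0=y0)
        return _responds(traj, delta)

    lo, hi = lo_frac * mu, hi_frac * mu
    if ok(lo):
        return lo
    if not ok(hi):
        raise RuntimeError(f"response threshold not bracketed in [{lo:g}, {hi:g}]")
    while hi / lo > 1.0 + rtol:
        mid = math.sqrt(lo * hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return math.sqrt(lo * hi)


@dataclass
class CalibrationResult:
    sigma: float
    mu: float
    thresholds: dict[float, float]          # Δ -> θ(Δ)
    achieved_fractions: dict[float, float]  # Δ -> fitted P(IKKK > θ)
    target_fractions: dict[float, float]
    degenerate: bool = False

    def fraction_above(self, threshold: float, sigma: float | None = None) -> float:
        """P(IKKK > threshold) under the fitted zero-truncated normal."""
        s = self.sigma if sigma is None else sigma
        z0 = stats.norm.cdf(-self.mu / s)
        return float((1.0 - stats.norm.cdf((threshold - self.mu) / s)) / (1.0 - z0))


def calibrate_ikkk_distribution(fractions: Mapping[float, float],
                                base: ModelParameters,
                                mu: float = IKKK_MEAN,
                                protocol_kind: str = "TT") -> CalibrationResult:
    """Fit the per-cell total-IKKK distribution to a responder-fraction curve.

    For each pulse interval Δ the minimal responding total θ(Δ) is found by
    bisection; σ of the zero-truncated Normal(μ, σ) is then chosen to
    minimise the squared error between P(IKKK > θ(Δ)) and the measured
    fractions.
    """
    deltas = sorted(fractions)
    vals = [fractions[d] for d in deltas]
    if any(not (0.0 <= v <= 1.0) for v in vals):
        raise ValueError("fractions must be in [0, 1]")
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ValueError("fractions must be non-decreasing in pulse interval")

    y0 = steady_state(base)
    thresholds = {d: response_threshold(d, base, protocol_kind, y0=y0) for d in deltas}

    if all(v >= 1.0 for v in vals):
        # every interval fully responsive: sigma unconstrained from above
        return CalibrationResult(sigma=math.inf, mu=mu, thresholds=thresholds,
                                 achieved_fractions={d: 1.0 for d in deltas},
                                 target_fractions=dict(fractions), degenerate=True)

    def sse(sigma: float) -> float:
        z0 = stats.norm.cdf(-mu / sigma)
        err = 0.0
        for d in deltas:
            pred = (1.0 - stats.norm.cdf((thresholds[d] - mu) / sigma)) / (1.0 - z0)
            err += (pred - fractions[d]) ** 2
        return err

    res = minimize_scalar(sse, bounds=(1e-3 * mu, 5.0 * mu), method="bounded")
    sigma = float(res.x)
    out = CalibrationResult(sigma=sigma, mu=mu, thresholds=thresholds,
                            achieved_fractions={}, target_fractions=dict(fractions))
    out.achieved_fractions = {d: out.fraction_above(thresholds[d]) for d in deltas}
    return out


#: the measured fraction-of-responding-cells curve for paired TNFα pulses
MEASURED_TT_FRACTIONS: dict[float, float] = {50.0: 0.05, 60.0: 0.30,
                                             70.0: 0.70, 100.0: 0.93}


def calibrated_population(n_cells: int = 300, seed: int = 0,
                          base: ModelParameters | None = None,
                          sigma: float | None = None,
                          mu: float = IKKK_MEAN,
                          both_branches: bool = True,
                          stratified: bool = True) -> list[CellSpec]:
    """Population with branch-IKKK totals from the calibrated distribution.

    If ``sigma`` is not given it is obtained by quantile calibration against
    the measured paired-pulse fraction curve.  Both branch totals are drawn
    independently from the same distribution (the IL-1β branch shows the
    same kind of cell-to-cell variability).  Draws are quantile-stratified
    by default, mirroring the calibration's quantile construction.
    """
    base = base or ModelParameters()
    if sigma is None:
        sigma = calibrate_ikkk_distribution(MEASURED_TT_FRACTIONS, base, mu=mu).sigma
    dp = DistributedParam(mean=mu, sd=sigma)
    dist = {"IKKKtott_T": dp}
    if both_branches:
        dist["IKKKtott_I"] = dp
    spec = PopulationSpec(n_cells=n_cells, distributed_params=dist,
                          stratified=stratified, rng_seed=seed)
    return sample_population(spec, base)


# ---------------------------------------------------------------------------
# equilibrated pulse pairs


def equilibrated_pulse_experiment(cells: Sequence[CellSpec], delta: float = 70.0,
                                  gap: float = 480.0,
                                  base: ModelParameters | None = None,
                                  ) -> list[tuple[bool, bool]]:
    """Two pulse pairs separated by an equilibration gap; per-cell responder
    calls for the second pulse of each pair (pulses 2 and 4).

    The gap is checked numerically: before the second pair starts, the
    nominal cell must be back at rest — nuclear NF-κB fraction within 0.005
    and total IκBα within 0.5 % of the pre-stimulation level.  The slow tail
    of the IκBα overshoot sets the required gap (~8 h in this model); with a
    shorter gap the residual state can flip borderline responder calls,
    which would confound the determinism contrast between the noise models.
    """
    base = base or ModelParameters()
    t3 = delta + 5.0 + gap       # start of second pair
    pulses = tuple(Pulse(t) for t in (0.0, delta, t3, t3 + delta))
    proto = StimulationProtocol(pulses, t_end=t3 + delta + 60.0)

    probe = simulate_cell(base, StimulationProtocol((Pulse(0.0), Pulse(delta)),
                                                    t_end=t3), dt_out=1.0)
    nf_off = abs(probe.nfkb_nuclear_fraction[-1] - probe.nfkb_nuclear_fraction[0])
    tot_off = abs(probe.total_ikba[-1] / probe.total_ikba[0] - 1.0)
    if nf_off > 0.005 or tot_off > 0.005:
        raise ValueError("equilibration gap too short: cell not back at rest")

    out = []
    for traj in run_population(cells, proto, base=base):
        out.append((_responds(traj, delta), _responds(traj, t3 + delta)))
    return out


def discordant_fraction(calls: Sequence[tuple[bool, bool]]) -> float:
    """Fraction of cells whose pulse-2 and pulse-4 responder calls differ."""
    if not calls:
        raise ValueError("no calls")
    return float(np.mean([a != b for a, b in calls]))
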