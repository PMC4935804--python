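"""Deterministic single-cell ODE model.

Structure: stimulus → cytokine-specific IKKK cycle (neutral → active →
inactive → neutral, with A20 inhibiting activation divisively) → IKK cycle
(neutral → active → inactive → neutral, activation a Hill function of the
summed active IKKK of both branches) → NF-κB/IκBα core with NF-κB-driven
transcription of the IκBα and A20 feedback genes.

Conservation holds by construction: per-branch IKKK states sum to that
branch's total, IKK states to ``IKKtot`` and NF-κB-containing species to
``nfkbtot``; the neutral kinase forms are reconstructed from the totals.

State vector layout (molecules):

====  ==========  =======================================
 0    IKKKa_T     active TNF-branch IKKK
 1    IKKKi_T     inactive TNF-branch IKKK
 2    IKKKa_I     active IL-1-branch IKKK
 3    IKKKi_I     inactive IL-1-branch IKKK
 4    IKKa        active IKK
 5    IKKi        inactive IKK
 6    NFkB_c      free cytoplasmic NF-κB
 7    NFkB_n      free nuclear NF-κB
 8    IkB_c       free cytoplasmic IκBα
 9    IkB_n       free nuclear IκBα
10    cplx_c      cytoplasmic NF-κB:IκBα complex
11    cplx_n      nuclear NF-κB:IκBα complex
12    mRNA_IkB    IκBα mRNA
13    mRNA_A20    A20 mRNA
14    A20         A20 protein
====  ==========  =======================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import odeint
from scipy.optimize import fsolve

from .params import ModelParameters
from .protocols import Cytokine, StimulationProtocol, dose_activation

__all__ = [
    "STATE_NAMES", "Trajectory", "derivatives", "steady_state", "simulate_cell",
]

STATE_NAMES: tuple[str, ...] = (
    "IKKKa_T", "IKKKi_T", "IKKKa_I", "IKKKi_I", "IKKa", "IKKi",
    "NFkB_c", "NFkB_n", "IkB_c", "IkB_n", "cplx_c", "cplx_n",
    "mRNA_IkB", "mRNA_A20", "A20",
)

N_STATE = len(STATE_NAMES)

# indices into the packed parameter vector (see params.PARAM_NAMES)
(_C1, _C2, _C3, _C4, _C1A, _C2A, _C3A, _C4A, _KA20T, _KA20I, _SIKKK, _KACT,
 _K1, _K4, _KAT, _KAI, _KI, _M3, _TOTT, _TOTI, _IKKTOT, _NFKBTOT, _KNIN,
 _KIIN, _KIOUT, _KCOUT, _KASS, _KDEG, _KDEGC, _KCDEG, _KHALF, _HTX,
 _HIKK) = range(33)


@njit(cache=True)
def _rhs(y, t, p, trT0, trI0, decT, decI, t0, gate_ikb, gate_a20, q_on, q_off):
    """Packed right-hand side; ``trX0 * exp(-decX (t - t0))`` is the receptor signal.

    ``gate_ikb``/``gate_a20`` gate feedback-gene transcription: 1.0 in the
    deterministic model (with ``q_on = 0``), or the binary telegraph-gene
    state in the hybrid simulator (``q_on``/``q_off`` > 0), where the ON
    rate is compensated by the stationary occupancy q_on·hill/(q_on·hill +
    q_off) so the fast-switching mean equals the deterministic rate.
    """
    d = np.zeros(15)
    trT = trT0 * math.exp(-decT * (t - t0)) if decT > 0.0 else trT0
    trI = trI0 * math.exp(-decI * (t - t0)) if decI > 0.0 else trI0

    a20 = y[14]
    inh_T = p[_KA20T] / (p[_KA20T] + a20)
    inh_I = p[_KA20I] / (p[_KA20I] + a20)

    ikkkn_T = p[_TOTT] - y[0] - y[1]
    ikkkn_I = p[_TOTI] - y[2] - y[3]

    actT = p[_KAT] * trT * ikkkn_T * inh_T
    actI = p[_KAI] * trI * ikkkn_I * inh_I
    d[0] = actT - p[_KI] * y[0]
    d[1] = p[_KI] * y[0] - p[_M3] * y[1]
    d[2] = actI - p[_KI] * y[2]
    d[3] = p[_KI] * y[2] - p[_M3] * y[3]

    s = y[0] + y[2]
    sh = s ** p[_HIKK]
    ikkn = p[_IKKTOT] - y[4] - y[5]
    act_ikk = p[_KACT] * ikkn * sh / (p[_SIKKK] ** p[_HIKK] + sh)
    d[4] = act_ikk - p[_K1] * y[4]
    d[5] = p[_K1] * y[4] - p[_K4] * y[5]

    nh = y[7] ** p[_HTX]
    hill = nh / (p[_KHALF] ** p[_HTX] + nh)
    if q_on > 0.0:
        # telegraph mode: ON-state rate compensated by stationary occupancy
        tx_ikb = (hill + q_off / q_on) * gate_ikb
        tx_a20 = (hill + q_off / q_on) * gate_a20
    else:
        tx_ikb = hill * gate_ikb
        tx_a20 = hill * gate_a20
    d[12] = p[_C1A] * tx_ikb - p[_C3A] * y[12]
    d[13] = p[_C1] * tx_a20 - p[_C3] * y[13]
    d[14] = p[_C2] * y[13] - p[_C4] * y[14]

    assoc_c = p[_KASS] * y[6] * y[8]
    assoc_n = p[_KASS] * y[7] * y[9]
    rel_c = (p[_KCDEG] + p[_KDEGC] * y[4]) * y[10]   # complex IκBα loss, frees NF-κB
    rel_n = p[_KCDEG] * y[11]

    d[6] = -p[_KNIN] * y[6] - assoc_c + rel_c
    d[7] = p[_KNIN] * y[6] - assoc_n + rel_n
    d[8] = (p[_C2A] * y[12] - assoc_c - (p[_C4A] + p[_KDEG] * y[4]) * y[8]
            - p[_KIIN] * y[8] + p[_KIOUT] * y[9])
    d[9] = p[_KIIN] * y[8] - p[_KIOUT] * y[9] - assoc_n - p[_C4A] * y[9]
    d[10] = assoc_c + p[_KCOUT] * y[11] - rel_c
    d[11] = assoc_n - p[_KCOUT] * y[11] - rel_n
    return d


def derivatives(state: np.ndarray, t: float, params: ModelParameters,
                protocol: StimulationProtocol) -> np.ndarray:
    """Time derivative of the model state under ``protocol`` at time ``t``."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATE,):
        raise ValueError(f"state must have {N_STATE} components")
    if np.any(state < 0):
        raise ValueError("state components must be non-negative")
    from .protocols import receptor_signal
    trT = receptor_signal(protocol, t, Cytokine.TNF,
                          k_d=params.K_d_T, h_d=params.h_d, tau_w=params.tau_w)
    trI = receptor_signal(protocol, t, Cytokine.IL1,
                          k_d=params.K_d_I, h_d=params.h_d, tau_w=params.tau_w)
    return _rhs(state, t, params.vector(), trT, trI, 0.0, 0.0, t, 1.0, 1.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# steady state


def _core_residual(z: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Residual of the unstimulated core (kinases off); one NF-κB balance is
    replaced by the conservation constraint to remove the rank deficiency."""
    y = np.zeros(N_STATE)
    y[6:15] = z
    d = _rhs(y, 0.0, p, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0)
    res = d[6:15].copy()
    res[0] = (y[6] + y[7] + y[10] + y[11]) - p[_NFKBTOT]
    return res


def steady_state(params: ModelParameters, *, tol: float = 1e-6,
                 t_equil: float = 4000.0) -> np.ndarray:
    """Unstimulated fixed point of the model.

    Pre-equilibrates the core from an all-complexed initial condition, then
    polishes with a Newton solve.  At rest the kinase cycles are exactly off,
    so only the nine core species need solving; the neutral kinase pools sit
    at their totals.
    """
    p = params.vector()
    y0 = np.zeros(N_STATE)
    y0[10] = params.nfkbtot          # all NF-κB complexed in the cytoplasm
    ts = np.array([0.0, t_equil])
    y = odeint(_rhs, y0, ts, args=(p, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0),
               rtol=1e-8, atol=1e-4, mxstep=50000)[-1]
    z, info, ier, msg = fsolve(_core_residual, y[6:15], args=(p,),
                               full_output=True, xtol=1e-12)
    if ier != 1 or np.any(z < -1e-6):
        raise RuntimeError(f"steady-state solve failed: {msg}")
    y_ss = np.zeros(N_STATE)
    y_ss[6:15] = np.clip(z, 0.0, None)
    resid = _rhs(y_ss, 0.0, p, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0)
    scale = max(params.nfkbtot, 1.0)
    if np.max(np.abs(resid)) > tol * scale:
        raise RuntimeError("steady state did not converge below tolerance")
    return y_ss


# ---------------------------------------------------------------------------
# trajectory container


@dataclass
class Trajectory:
    """Uniformly sampled model output for one cell."""

    t: np.ndarray                 # minutes
    y: np.ndarray                 # (n_t, N_STATE) molecules
    params: ModelParameters
    protocol: StimulationProtocol
    cell_id: str = "cell0"

    @property
    def nuclear_nfkb(self) -> np.ndarray:
        """All nuclear NF-κB (free + complexed), molecules."""
        return self.y[:, 7] + self.y[:, 11]

    @property
    def nfkb_nuclear_fraction(self) -> np.ndarray:
        return self.nuclear_nfkb / self.params.nfkbtot

    @property
    def total_ikba(self) -> np.ndarray:
        """Total IκBα: free + complexed, both compartments (the eGFP observable)."""
        return self.y[:, 8] + self.y[:, 9] + self.y[:, 10] + self.y[:, 11]

    @property
    def a20_protein(self) -> np.ndarray:
        return self.y[:, 14]

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.t - t)))
        return self.y[i]

    def conservation_error(self) -> float:
        """Worst relative violation of the three conservation laws."""
        p = self.params
        ikkk_T = self.y[:, 0] + self.y[:, 1]
        ikkk_I = self.y[:, 2] + self.y[:, 3]
        ikk = self.y[:, 4] + self.y[:, 5]
        nf = self.y[:, 6] + self.y[:, 7] + self.y[:, 10] + self.y[:, 11]
        e = [
            np.max(np.abs(np.clip(ikkk_T - p.IKKKtott_T, 0, None))) / p.IKKKtott_T,
            np.max(np.abs(np.clip(ikkk_I - p.IKKKtott_I, 0, None))) / p.IKKKtott_I,
            np.max(np.abs(np.clip(ikk - p.IKKtot, 0, None))) / p.IKKtot,
            np.max(np.abs(nf - p.nfkbtot)) / p.nfkbtot,
        ]
        return float(max(e))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        df.insert(0, "time_min", self.t)
        df["nfkb_nuclear_fraction"] = self.nfkb_nuclear_fraction
        df["total_ikba"] = self.total_ikba
        df["a20_protein"] = self.a20_protein
        df.insert(0, "cell_id", self.cell_id)
        return df


# ---------------------------------------------------------------------------
# simulation


def _segment_signals(protocol: StimulationProtocol, params: ModelParameters):
    """Per-segment receptor-signal description: list of
    (t_a, t_b, trT0, decT, trI0, decI) with TR(t) = tr0·exp(-dec·(t - t_a))."""
    bounds = protocol.boundaries()
    segs = []
    for a, b in zip(bounds, bounds[1:]):
        out = []
        for cyt, kd in ((Cytokine.TNF, params.K_d_T), (Cytokine.IL1, params.K_d_I)):
            tr0, dec = 0.0, 0.0
            for pu in protocol.pulses_of(cyt):
                if pu.start <= a and a < pu.end:
                    tr0, dec = dose_activation(pu.dose, kd, params.h_d), 0.0
                elif pu.end <= a:
                    phi = dose_activation(pu.dose, kd, params.h_d)
                    resid = phi * math.exp(-(a - pu.end) / params.tau_w)
                    if resid > tr0:
                        tr0, dec = resid, 1.0 / params.tau_w
            if tr0 < 1e-12:
                tr0, dec = 0.0, 0.0
            out.append((tr0, dec))
        segs.append((a, b, out[0][0], out[0][1], out[1][0], out[1][1]))
    return segs


def simulate_cell(params: ModelParameters, protocol: StimulationProtocol,
                  dt_out: float = 1.0, *, y0: np.ndarray | None = None,
                  rtol: float = 1e-7, atol: float = 1e-4,
                  cell_id: str = "cell0",
                  conservation_tol: float = 1e-6) -> Trajectory:
    """Integrate one cell from its unstimulated steady state under ``protocol``.

    Output is sampled on a uniform grid of step ``dt_out``; integration is
    piecewise between pulse boundaries so the pulse on/off discontinuities are
    never stepped over.  Raises if the integrator fails or conservation drifts
    beyond ``conservation_tol`` (relative).
    """
    if not np.isfinite(protocol.t_end):
        raise ValueError("protocol.t_end must be finite")
    p = params.vector()
    if y0 is None:
        y0 = steady_state(params)
    grid = np.arange(0.0, protocol.t_end + 0.5 * dt_out, dt_out)
    grid[-1] = min(grid[-1], protocol.t_end)
    ys = np.empty((grid.size, N_STATE))
    wrote = np.zeros(grid.size, dtype=bool)
    y = y0.copy()
    for (a, b, trT0, decT, trI0, decI) in _segment_signals(protocol, params):
        mask = (grid >= a - 1e-9) & (grid <= b + 1e-9)
        pts = grid[mask]
        ts = np.unique(np.concatenate(([a], pts, [b])))
        sol, info = odeint(_rhs, y, ts,
                           args=(p, trT0, trI0, decT, decI, a, 1.0, 1.0, 0.0, 0.0),
                           rtol=rtol, atol=atol, mxstep=100000,
                           full_output=True)
        if info["message"] != "Integration successful.":
            raise RuntimeError(
                f"integration failed in [{a:.1f}, {b:.1f}] min: {info['message']}")
        for tp, row in zip(ts, sol):
            hits = np.where(mask & ~wrote & (np.abs(grid - tp) < 1e-9))[0]
            for h in hits:
                ys[h] = row
                wrote[h] = True
        y = sol[-1]
    if not wrote.all():
        # grid points coinciding with segment ends are written by the next
        # segment's start; fill any leftovers from nearest written sample
        idx = np.where(~wrote)[0]
        for i in idx:
            j = np.argmin(np.abs(np.where(wrote)[0] - i))
            ys[i] = ys[np.where(wrote)[0][j]]
    ys = np.where(np.abs(ys) < 1e-9, 0.0, ys)
    if np.any(ys < -atol * 10):
        raise RuntimeError("integration produced significantly negative species")
    ys = np.clip(ys, 0.0, None)
    traj = Trajectory(t=grid, y=ys, params=params, protocol=protocol, cell_id=cell_id)
    err = traj.conservation_error()
    if err > conservation_tol:
        raise RuntimeError(f"conservation violated: relative error {err:.2e}")
    return traj
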