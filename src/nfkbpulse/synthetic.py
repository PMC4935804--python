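"""Synthetic-data generators emulating the study's measured data.

Every analysis stage in this package is testable without any measured data:
these generators produce single-cell reporter traces (model-driven with
measurement corruption, or template-spliced responder/non-responder
mixtures at stated fractions), daughter-cell pairs with a controlled
divergence probability, and panel count matrices whose condition means
track integrated nuclear NF-κB activity.  Ground-truth labels are always
returned alongside, never mixed into the data.

Measurement corruption follows microscopy practice: multiplicative
lognormal intensity noise (scale-dependent) and a slow linear
photobleaching-like drift applied to the IκBα intensity only (the N/T
ratio is self-normalizing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Trajectory, simulate_cell, steady_state
from .params import ModelParameters
from .population import (CellSpec, DistributedParam, IKKK_MEAN, run_population)
from .protocols import StimulationProtocol, two_pulse
from .traces import TraceTable
from .expression import CountMatrix

__all__ = ["TraceGenSpec", "CountGenSpec", "generate_traces",
           "generate_daughter_pairs", "generate_counts"]


@dataclass
class TraceGenSpec:
    n_cells: int = 100
    protocol: StimulationProtocol = field(default_factory=lambda: two_pulse(60.0))
    responder_fraction: float | None = None   # label mode when set
    noise_sd: float = 0.05          # multiplicative lognormal sd
    drift_per_min: float = -2e-4    # linear drift on IκBα intensity
    dt_out: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.responder_fraction is not None and not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must be in [0, 1]")


def _corrupt(tbl: TraceTable, spec: TraceGenSpec,
             rng: np.random.Generator) -> TraceTable:
    n_t, n_c = tbl.ikba.shape
    drift = 1.0 + spec.drift_per_min * tbl.time
    ikba = tbl.ikba.to_numpy() * drift[:, None]
    nt = None if tbl.nt_ratio is None else tbl.nt_ratio.to_numpy().copy()
    if spec.noise_sd > 0:
        s = spec.noise_sd
        m = -0.5 * math.log(1.0 + s * s)
        ikba = ikba * rng.lognormal(m, math.sqrt(math.log(1 + s * s)), size=ikba.shape)
        if nt is not None:
            nt = np.clip(nt * rng.lognormal(m, math.sqrt(math.log(1 + s * s)),
                                            size=nt.shape), 0.0, 1.0)
    out = TraceTable(tbl.time, pd.DataFrame(ikba, columns=tbl.ikba.columns),
                     None if nt is None else pd.DataFrame(nt, columns=tbl.ikba.columns),
                     tbl.lineage)
    return out.normalized()


def _templates(spec: TraceGenSpec, base: ModelParameters,
               ) -> tuple[Trajectory, Trajectory]:
    """Responder / non-responder template responses from nominal-parameter
    model runs: a high-IKKK cell responds to every pulse, a low-IKKK cell
    only to the first."""
    y0 = steady_state(base)
    # both templates respond fully to the first pulse (as every measured
    # cell does); only the high-IKKK template re-responds to later pulses
    hi = simulate_cell(base.replace(IKKKtott_T=2.5 * IKKK_MEAN,
                                    IKKKtott_I=2.5 * IKKK_MEAN),
                       spec.protocol, dt_out=spec.dt_out, y0=y0, cell_id="hi")
    lo = simulate_cell(base.replace(IKKKtott_T=0.6 * IKKK_MEAN,
                                    IKKKtott_I=0.6 * IKKK_MEAN),
                       spec.protocol, dt_out=spec.dt_out, y0=y0, cell_id="lo")
    return hi, lo


def generate_traces(spec: TraceGenSpec, base: ModelParameters | None = None,
                    cells: Sequence[CellSpec] | None = None,
                    ) -> tuple[TraceTable, pd.Series]:
    """Synthetic reporter traces plus ground-truth responder labels.

    Label mode (``responder_fraction`` set): each cell is a responder or
    non-responder template from a nominal model run, at the stated mixture
    fraction, with measurement corruption.  Model mode: the supplied (or
    calibrated) cells are simulated and corrupted; labels are the model
    responder rule applied to the uncorrupted second-pulse response.
    """
    base = base or ModelParameters()
    rng = np.random.default_rng(spec.rng_seed)
    pulse2 = spec.protocol.pulse_starts[-1] if spec.protocol.pulses else 0.0

    if spec.responder_fraction is not None:
        hi, lo = _templates(spec, base)
        n_resp = int(round(spec.responder_fraction * spec.n_cells))
        labels = np.zeros(spec.n_cells, dtype=bool)
        labels[rng.choice(spec.n_cells, n_resp, replace=False)] = True
        ik = {}
        nt = {}
        for i, is_resp in enumerate(labels):
            tpl = hi if is_resp else lo
            cid = f"cell{i:04d}"
            ik[cid] = tpl.total_ikba
            nt[cid] = tpl.nfkb_nuclear_fraction
        tbl = TraceTable(hi.t, pd.DataFrame(ik), pd.DataFrame(nt)).normalized()
        truth = pd.Series(labels, index=tbl.cell_ids, name="responder")
    else:
        if cells is None:
            from .population import calibrated_population
            cells = calibrated_population(spec.n_cells, seed=spec.rng_seed, base=base)
        trajs = run_population(cells, spec.protocol, base=base, dt_out=spec.dt_out)
        from .traces import classify_responder_model
        truth = pd.Series({tr.cell_id: classify_responder_model(tr, pulse2)[0]
                           for tr in trajs}, name="responder")
        tbl = TraceTable.from_trajectories(trajs)
    return _corrupt(tbl, spec, rng), truth


def generate_daughter_pairs(n_pairs: int = 56, divergence_prob: float = 0.15,
                            spec: TraceGenSpec | None = None,
                            base: ModelParameters | None = None,
                            sigma: float | None = None,
                            divergence_mode: str = "opposite",
                            ) -> tuple[TraceTable, pd.DataFrame]:
    """Daughter-cell pairs sharing parameter draws; with probability
    ``divergence_prob`` one sibling's IKKK total diverges.

    ``divergence_mode="opposite"`` (default) redraws the diverged sibling
    from the other side of the second-pulse response threshold, so the pair
    is guaranteed discordant and the measured concordance is
    1 − divergence_prob.  ``"independent"`` redraws unconditionally, so a
    diverged pair may still agree by chance (the independence reference).

    Returns the trace table (lineage annotated) and a per-pair ground-truth
    frame with each sibling's IKKK total and a ``diverged`` flag.
    """
    if not 0.0 <= divergence_prob <= 1.0:
        raise ValueError("divergence_prob must be in [0, 1]")
    if divergence_mode not in ("opposite", "independent"):
        raise ValueError(f"unknown divergence mode {divergence_mode!r}")
    spec = spec or TraceGenSpec(protocol=two_pulse(70.0))
    base = base or ModelParameters()
    rng = np.random.default_rng(spec.rng_seed)
    if sigma is None:
        from .population import MEASURED_TT_FRACTIONS, calibrate_ikkk_distribution
        sigma = calibrate_ikkk_distribution(MEASURED_TT_FRACTIONS, base).sigma
    dp = DistributedParam(mean=IKKK_MEAN, sd=sigma)
    theta = None
    if divergence_mode == "opposite":
        from .population import response_threshold
        delta = spec.protocol.pulse_starts[-1]
        theta = response_threshold(delta, base)

    margin = 0.10   # keep draws clear of the threshold so both responder
                    # rules (model and trace gradient) agree on the class

    def clear_of_threshold(v: float) -> bool:
        return theta is None or abs(v - theta) > margin * theta

    def draw_clear(side_of: float | None = None) -> float:
        """Draw from the fitted distribution, away from the threshold and,
        if ``side_of`` is given, on the opposite side from it."""
        for _ in range(10_000):
            v = float(dp.sample(rng, 1)[0])
            if not clear_of_threshold(v):
                continue
            if side_of is None or theta is None or (v > theta) != (side_of > theta):
                return v
        raise RuntimeError("could not draw a clear-of-threshold IKKK value")

    mother_draws = np.array([draw_clear() for _ in range(n_pairs)])
    n_div = int(round(divergence_prob * n_pairs))
    diverged = np.zeros(n_pairs, dtype=bool)
    diverged[rng.choice(n_pairs, n_div, replace=False)] = True
    cells, records = [], []
    for i in range(n_pairs):
        a = float(mother_draws[i])
        if diverged[i]:
            b = draw_clear(side_of=a) if divergence_mode == "opposite" else draw_clear()
        else:
            b = a
        div_time = float(rng.uniform(-300.0, -30.0))   # minutes before stimulation
        for suffix, tot in (("a", a), ("b", b)):
            cells.append(CellSpec(cell_id=f"pair{i:03d}{suffix}",
                                  overrides={"IKKKtott_T": tot, "IKKKtott_I": tot},
                                  seed=int(rng.integers(2**31 - 1))))
        records.append(dict(pair=f"pair{i:03d}", ikkk_a=a, ikkk_b=b,
                            diverged=bool(diverged[i]), division_time=div_time))
    trajs = run_population(cells, spec.protocol, base=base, dt_out=spec.dt_out)
    tbl = TraceTable.from_trajectories(trajs)
    tbl.lineage = pd.DataFrame(records)
    return _corrupt(tbl, spec, rng), pd.DataFrame(records)


@dataclass
class CountGenSpec:
    """Panel-count generator: per-gene activity coefficients times
    per-condition integrated NF-κB activity set the condition means."""
    genes: Mapping[str, float]              # endogenous gene -> activity coefficient
    activity: Mapping[str, float]           # condition -> integrated activity
    baseline: float = 200.0                 # counts at zero activity
    replicates: int = 3
    dispersion: float = 100.0               # negative-binomial size (≈10% biological CV)
    n_housekeeping: int = 5
    n_positive: int = 6
    n_negative: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float,
             ) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size (dispersion) parameter;
    size → ∞ approaches Poisson."""
    mean = np.asarray(mean, dtype=float)
    if np.isinf(size_param):
        return rng.poisson(mean)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_counts(spec: CountGenSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Synthetic count matrix plus the true per-condition linear fold
    changes of every endogenous gene (relative to condition 'U' when
    present, else the first condition)."""
    rng = np.random.default_rng(spec.rng_seed)
    conditions = list(spec.activity)
    samples, cond_labels = [], []
    for cond in conditions:
        for r in range(spec.replicates):
            samples.append(f"{cond}_r{r+1}")
            cond_labels.append(cond)

    gene_rows, classes = {}, {}
    for g, coef in spec.genes.items():
        means = np.array([spec.baseline * (1.0 + coef * spec.activity[c])
                          for c in cond_labels])
        gene_rows[g] = _nb_draw(rng, means, spec.dispersion)
        classes[g] = "endogenous"
    for i in range(spec.n_housekeeping):
        g = f"HK{i+1}"
        gene_rows[g] = _nb_draw(rng, np.full(len(samples), 5.0 * spec.baseline),
                                spec.dispersion)
        classes[g] = "housekeeping"
    for i in range(spec.n_positive):
        g = f"POS{i+1}"
        gene_rows[g] = _nb_draw(rng, np.full(len(samples), 8.0 * spec.baseline),
                                spec.dispersion)
        classes[g] = "positive_control"
    for i in range(spec.n_negative):
        g = f"NEG{i+1}"
        gene_rows[g] = rng.poisson(2.0, size=len(samples))
        classes[g] = "negative_control"

    counts = pd.DataFrame(gene_rows, index=samples).T
    cm = CountMatrix(counts, pd.Series(classes),
                     pd.Series(cond_labels, index=samples))
    ref = "U" if "U" in conditions else conditions[0]
    truth = pd.DataFrame({
        c: {g: (1.0 + coef * spec.activity[c]) / (1.0 + coef * spec.activity[ref])
            for g, coef in spec.genes.items()}
        for c in conditions if c != ref})
    return cm, truth
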