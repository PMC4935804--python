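"""Model parameters: named rate constants and totals for one cell.

Units are molecules per cell and minutes throughout.  The mean total IKKK
level anchors the molecule scale at 1e6 per branch; NF-κB and IKK totals are
set relative to it.  ``c1..c4`` are the A20 feedback gene rates (max
transcription, translation, mRNA degradation, protein degradation) and
``c1a..c4a`` the same four roles for IκBα.

The nominal values were calibrated in-repo against population-imaging summary
statistics: single-pulse total-IκBα trough at 20 min and peak at 125 min with
baseline recovery by 300 min, ~100 min oscillation period under continuous
TNFα, resting nuclear NF-κB below the 15% responder threshold, and the
fraction-of-responding-cells curve under paired pulses (including the
TNFα/IL-1β cross-talk asymmetry, which requires ``kA20_T < kA20_I``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

__all__ = ["ModelParameters", "PARAM_NAMES"]


@dataclass
class ModelParameters:
    # --- A20 feedback gene ---
    c1: float = 33.9714        # A20 mRNA max transcription rate (molec/min)
    c2: float = 1.2         # A20 translation rate (protein per mRNA per min)
    c3: float = 0.025       # A20 mRNA degradation (1/min)
    c4: float = 0.0462955       # A20 protein degradation (1/min)
    # --- IκBα feedback gene ---
    c1a: float = 39.0431      # IκBα mRNA max transcription rate (molec/min)
    c2a: float = 1.74243        # IκBα translation rate (1/min)
    c3a: float = 0.0253587      # IκBα mRNA degradation (1/min)
    c4a: float = 0.018052       # free IκBα protein degradation (1/min)
    # --- A20 inhibition of IKKK activation, per cytokine branch ---
    kA20_T: float = 2560.16   # TNF branch half-inhibition constant (molecules)
    kA20_I: float = 202338   # IL-1 branch half-inhibition constant (molecules)
    # --- IKK cycle ---
    sIKKK: float = 133668    # half-maximal IKK activation (IKKKa molecules)
    kact: float = 0.034759       # max IKK activation rate (1/min)
    k1: float = 0.145389        # IKK inactivation (1/min)
    k4: float = 0.0746354      # IKK recycling (1/min)
    # --- IKKK cycles (per branch) ---
    ka_T: float = 2.74828       # TNF-branch IKKK activation (1/min per unit signal)
    ka_I: float = 0.757175       # IL-1-branch IKKK activation
    ki: float = 1.46271        # IKKK inactivation (1/min)
    m3: float = 0.0345044        # IKKK recovery from inactive state (1/min)
    # --- totals ---
    IKKKtott_T: float = 1.0e6   # total TNF-branch IKKK (molecules)
    IKKKtott_I: float = 1.0e6   # total IL-1-branch IKKK (molecules)
    IKKtot: float = 2.0e5       # total IKK (molecules)
    nfkbtot: float = 1.0e5      # total NF-κB (molecules)
    # --- transport / complex ---
    k_nfkb_in: float = 0.563735      # nuclear import of free NF-κB (1/min)
    k_ikb_in: float = 0.0845469      # nuclear import of free IκBα (1/min)
    k_ikb_out: float = 0.0100714    # nuclear export of free IκBα (1/min)
    k_cplx_out: float = 1.26564    # nuclear export of NF-κB:IκBα complex (1/min)
    k_assoc: float = 0.000201956     # NF-κB + IκBα association (1/molec/min)
    k_ikk_deg: float = 1.16818e-05   # IKKa-catalysed degradation of free IκBα (1/molec/min)
    k_ikk_deg_c: float = 1.16818e-05 # IKKa-catalysed degradation of complexed IκBα
    k_cplx_deg: float = 2.0e-5  # constitutive complexed-IκBα turnover (1/min)
    # --- transcription Hill ---
    k_nfkb_half: float = 4705.17  # half-saturation of NF-κB-driven transcription (molecules)
    h_tx: float = 2.0           # transcriptional Hill coefficient
    h_ikk: float = 2.0          # Hill coefficient of IKK activation by IKKKa
    # --- receptor / dose (outside the ODE right-hand side) ---
    K_d_T: float = 0.05     # TNF dose for half receptor activation (ng/ml)
    K_d_I: float = 0.05     # IL-1 dose constant (ng/ml)
    h_d: float = 1.0        # dose Hill coefficient
    tau_w: float = 2.0      # washout decay time constant (min)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")
        for name in ("IKKKtott_T", "IKKKtott_I", "IKKtot", "nfkbtot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"total {name} must be > 0")
        if not self.kA20_T < self.kA20_I:
            raise ValueError(
                "kA20_T must be < kA20_I (the TNF branch is the more strongly "
                "A20-inhibited one; required by the TI/IT response asymmetry)"
            )

    # -- plumbing ---------------------------------------------------------
    def replace(self, **overrides: float) -> "ModelParameters":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        """Load from YAML or JSON keyed by parameter name (missing keys -> defaults)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} must contain a mapping")
        return cls.from_dict({k: float(v) for k, v in data.items()})

    def save(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def vector(self) -> np.ndarray:
        """Rate vector in the fixed order the compiled right-hand side uses."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=np.float64)


#: ordering of the ODE-level parameters inside the packed vector
PARAM_NAMES: tuple[str, ...] = (
    "c1", "c2", "c3", "c4",
    "c1a", "c2a", "c3a", "c4a",
    "kA20_T", "kA20_I",
    "sIKKK", "kact", "k1", "k4",
    "ka_T", "ka_I", "ki", "m3",
    "IKKKtott_T", "IKKKtott_I", "IKKtot", "nfkbtot",
    "k_nfkb_in", "k_ikb_in", "k_ikb_out", "k_cplx_out",
    "k_assoc", "k_ikk_deg", "k_ikk_deg_c", "k_cplx_deg",
    "k_nfkb_half", "h_tx", "h_ikk",
)
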