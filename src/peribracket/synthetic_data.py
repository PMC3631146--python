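"""Synthetic inputs with the statistical structure the analysis assumes.

Three generator families stand in for the study's clinical and imaging
inputs, so the whole pipeline is testable without any external data:

* patient cohorts — per-site log10 CFU plus gingival index (GI) and
  pocket depth (PD), drawn around the published per-group means and SDs
  with a shared within-patient effect;
* dilution plating — Poisson colony counts on a serial 10-fold dilution
  ladder of 50 ul aliquots;
* analytic flow fields — closed-form velocity fields (uniform, shear,
  plane Poiseuille, Lamb-Oseen vortex) evaluated on the staggered grid,
  used as oracles for the solver and the flow metrics.

Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clinical_stats import ALIQUOT_ML, BASELINE_SITE, SITES
from .errors import ConfigurationError
from .flow_solver import MM, FlowField, zero_field
from .geometry import GeometryModel

# Published per-group log10 CFU means and SDs: baseline bracket area at
# T0, the four peri-bracket sites one week after bonding (T1) and one
# week after archwire placement (T2).
LOG10_CFU_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("T0", BASELINE_SITE): (8.6332, 0.0207),
    ("T1", "BO"): (9.0279, 0.0118),
    ("T1", "BG"): (9.3366, 0.0057),
    ("T1", "BL"): (9.0324, 0.0096),
    ("T1", "BR"): (9.0360, 0.0131),
    ("T2", "BO"): (9.0248, 0.0158),
    ("T2", "BG"): (9.3908, 0.0177),
    ("T2", "BL"): (9.3916, 0.0170),
    ("T2", "BR"): (9.3837, 0.0170),
}

# Published longitudinal periodontal means and SDs per timepoint.
GI_PARAMS: dict[str, tuple[float, float]] = {
    "T0": (0.2222, 0.2229),
    "T1": (0.2870, 0.2471),
    "T2": (0.3611, 0.2532),
}
PD_PARAMS: dict[str, tuple[float, float]] = {
    "T0": (0.6488, 0.1755),
    "T1": (0.6759, 0.1677),
    "T2": (0.7203, 0.2206),
}


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: 27 patients, the published
    per-(timepoint, site) log10 CFU means/SDs and GI/PD means/SDs, and a
    within-patient correlation ``rho_w`` = 0.5 across a patient's
    measurements (a shared Gaussian patient effect on the log10 / index
    scale).  GI is generated as a continuous score clipped to [0, 3];
    ``ordinal_gi`` rounds it to the 0-3 grid instead.  PD is floored at 0.
    """

    n_patients: int = 27
    cfu_params: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(LOG10_CFU_PARAMS)
    )
    gi_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GI_PARAMS)
    )
    pd_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PD_PARAMS)
    )
    rho_w: float = 0.5
    ordinal_gi: bool = False

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not 0.0 <= self.rho_w < 1.0:
            raise ConfigurationError("rho_w must lie in [0, 1)")
        for params in (self.cfu_params, self.gi_params, self.pd_params):
            for key, (_, sd) in params.items():
                if sd < 0:
                    raise ConfigurationError(f"negative SD for group {key}")


def _draw(rng, mean, sd, shared, rho):
    """mean + sd * (sqrt(rho) * shared + sqrt(1-rho) * noise)."""
    noise = rng.standard_normal(np.shape(shared))
    return mean + sd * (math.sqrt(rho) * shared + math.sqrt(1 - rho) * noise)


def generate_cohort(params: CohortParams, seed: int) -> pd.DataFrame:
    """Draw a synthetic cohort as a clinical-record DataFrame.

    Each patient carries one shared standard-normal effect per variable
    family (CFU, GI, PD) entering every group draw with weight
    sqrt(rho_w), so measurements of one patient are positively correlated
    across timepoints and sites while group-level means and SDs match the
    requested parameters.
    """
    rng = np.random.default_rng(seed)
    n = params.n_patients
    rho = params.rho_w
    z_cfu = rng.standard_normal(n)
    z_gi = rng.standard_normal(n)
    z_pd = rng.standard_normal(n)
    patients = np.arange(1, n + 1)

    gi_by_tp, pd_by_tp = {}, {}
    for tp in ("T0", "T1", "T2"):
        g = _draw(rng, *params.gi_params[tp], z_gi, rho)
        g = np.clip(g, 0.0, 3.0)
        if params.ordinal_gi:
            g = np.round(g)
        gi_by_tp[tp] = g
        pd_by_tp[tp] = np.maximum(_draw(rng, *params.pd_params[tp], z_pd, rho), 0.0)

    rows = []
    for (tp, site), (mean, sd) in sorted(params.cfu_params.items()):
        cfu = _draw(rng, mean, sd, z_cfu, rho)
        for i, pid in enumerate(patients):
            rows.append(
                {
                    "patient_id": int(pid),
                    "timepoint": tp,
                    "site": site,
                    "log10_cfu": float(cfu[i]),
                    "gi": float(gi_by_tp[tp][i]),
                    "pd": float(pd_by_tp[tp][i]),
                }
            )
    df = pd.DataFrame(rows, columns=list(
        ("patient_id", "timepoint", "site", "log10_cfu", "gi", "pd")
    ))
    return df.sort_values(
        ["timepoint", "site", "patient_id"], ignore_index=True
    )


@dataclass(frozen=True)
class PlatingParams:
    """Serial-dilution plating of one sample.

    ``true_density`` is the CFU density of the transport medium (CFU/ml);
    aliquots of ``aliquot_volume`` ml of each 10^-k dilution are plated
    for k in ``dilution_exponents``.
    """

    true_density: float
    dilution_exponents: Sequence[int] = tuple(range(0, 10))
    aliquot_volume: float = ALIQUOT_ML

    def __post_init__(self):
        if self.true_density <= 0:
            raise ConfigurationError("true_density must be > 0")
        if self.aliquot_volume <= 0:
            raise ConfigurationError("aliquot_volume must be > 0")
        if any(k < 0 for k in self.dilution_exponents):
            raise ConfigurationError("dilution exponents must be >= 0")


def simulate_plating(
    params: PlatingParams, seed: int
) -> list[tuple[int, int]]:
    """Poisson colony counts per dilution: [(dilution_exponent, count), ...].

    The expected count at dilution 10^-k is
    true_density * aliquot_volume * 10^-k.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k in params.dilution_exponents:
        lam = params.true_density * params.aliquot_volume * 10.0 ** (-k)
        # Poisson sampling overflows for enormous means; those plates are
        # uncountable lawns anyway, so clamp to a sentinel above 300.
        if lam > 1e9:
            count = int(lam)
        else:
            count = int(rng.poisson(lam))
        out.append((int(k), count))
    return out


def analytic_field(kind: str, model: GeometryModel, **params) -> FlowField:
    """Closed-form velocity field evaluated at the staggered locations.

    Kinds
    -----
    uniform : constant velocity ``velocity=(vx, vy, vz)`` m/s.
    shear : u = alpha * z (``alpha`` in 1/s), a linear wall shear profile.
    poiseuille : plane channel flow along y between z = 0 and z = depth,
        v(z) = u_max * (1 - (2 z / h - 1)^2) with ``u_max`` m/s.
    lamb_oseen : in-plane vortex centred at ``center`` (x0, y0) mm with
        circulation ``gamma`` m^2/s and core radius ``r_core`` mm:
        v_theta(r) = gamma / (2 pi r) * (1 - exp(-r^2 / r_core^2)).
    """
    fld = zero_field(model)
    nx, ny, nz = model.shape
    h = model.cell_size * MM

    if kind == "uniform":
        vx, vy, vz = params["velocity"]
        fld.u[:] = vx
        fld.v[:] = vy
        fld.w[:] = vz
    elif kind == "shear":
        alpha = params["alpha"]
        z = (np.arange(nz) + 0.5) * h  # u faces sit at cell-centre heights
        fld.u[:] = alpha * z[None, None, :]
    elif kind == "poiseuille":
        u_max = params["u_max"]
        height = nz * h
        z = (np.arange(nz) + 0.5) * h
        profile = u_max * (1.0 - (2.0 * z / height - 1.0) ** 2)
        fld.v[:] = profile[None, None, :]
    elif kind == "lamb_oseen":
        x0, y0 = params["center"]
        gamma = params["gamma"]
        r_core = params["r_core"] * MM
        x0, y0 = x0 * MM, y0 * MM

        def v_theta(r):
            r = np.maximum(r, 1e-12)
            return gamma / (2 * np.pi * r) * (1.0 - np.exp(-(r**2) / r_core**2))

        # u faces: x = i*h, y = (j+0.5)*h
        xu = np.arange(nx + 1)[:, None] * h - x0
        yu = (np.arange(ny)[None, :] + 0.5) * h - y0
        ru = np.hypot(xu, yu)
        fld.u[:] = (-v_theta(ru) * yu / np.maximum(ru, 1e-12))[:, :, None]
        # v faces: x = (i+0.5)*h, y = j*h
        xv = (np.arange(nx)[:, None] + 0.5) * h - x0
        yv = np.arange(ny + 1)[None, :] * h - y0
        rv = np.hypot(xv, yv)
        fld.v[:] = (v_theta(rv) * xv / np.maximum(rv, 1e-12))[:, :, None]
    else:
        raise ConfigurationError(f"unknown analytic field kind {kind!r}")
    return fld


def lamb_oseen_speed(r: np.ndarray | float, gamma: float,
                     r_core_mm: float) -> np.ndarray | float:
    """Tangential Lamb-Oseen speed at radius ``r`` (m), SI."""
    r_core = r_core_mm * MM
    r = np.maximum(np.asarray(r, dtype=float), 1e-12)
    return gamma / (2 * np.pi * r) * (1.0 - np.exp(-(r**2) / r_core**2))
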