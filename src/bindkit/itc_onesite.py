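"""One-site ITC binding model with displaced-volume correction.

Implements the single-set-of-identical-sites model used by isothermal
titration calorimeters with an overflow cell: the total heat content Q of
the cell is the closed-form (quadratic) Wiseman isotherm, injections
dilute both species because the displaced volume leaves the active
volume, and the per-injection heat carries the standard displaced-volume
correction. Fitting the injection heats yields the stoichiometry ``n``,
the dissociation constant ``Kd`` and the molar enthalpy ``dH``; the free
energy and entropic term follow from ``dG = RT ln Kd`` (standard state
1 M) and ``TdS = dH - dG``.

Units: cell volume in uL, concentrations in M, enthalpy in kcal/mol,
per-injection heats in ucal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL",
    "TitrationProtocol",
    "OneSiteModel",
    "ThermoDecomposition",
    "ITCFitResult",
    "concentrations_after",
    "one_site_q",
    "injection_heats",
    "fit_one_site",
    "derive_thermodynamics",
    "read_heats_csv",
    "write_heats_csv",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Default injection schedule: one 0.4 uL pre-injection then 14 x 3 uL.
DEFAULT_INJECTIONS_UL = (0.4,) + (3.0,) * 14


@dataclass(frozen=True)
class TitrationProtocol:
    """Cell geometry and injection schedule of an ITC run.

    Parameters
    ----------
    v0_ul : active cell volume in uL.
    cell_conc0_m : initial macromolecule concentration in the cell (M).
    syringe_conc_m : titrant concentration in the syringe (M).
    injections_ul : ordered injection volumes dV_i in uL.
    temperature_k : run temperature in K.
    """

    v0_ul: float = 200.0
    cell_conc0_m: float = 30e-6
    syringe_conc_m: float = 300e-6
    injections_ul: tuple[float, ...] = DEFAULT_INJECTIONS_UL
    temperature_k: float = 298.35

    def __post_init__(self) -> None:
        if not (self.v0_ul > 0 and np.isfinite(self.v0_ul)):
            raise ValueError("cell volume must be positive and finite")
        if self.cell_conc0_m <= 0 or self.syringe_conc_m <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")
        dv = np.asarray(self.injections_ul, dtype=float)
        if dv.size == 0 or np.any(dv <= 0) or not np.all(np.isfinite(dv)):
            raise ValueError("all injection volumes must be positive and finite")
        object.__setattr__(self, "injections_ul", tuple(float(v) for v in dv))

    @property
    def n_injections(self) -> int:
        return len(self.injections_ul)

    def cumulative_volume_ul(self, i: int) -> float:
        """Total injected volume after injection ``i`` (1-based)."""
        if not 1 <= i <= self.n_injections:
            raise ValueError(f"injection index {i} out of range 1..{self.n_injections}")
        return float(sum(self.injections_ul[:i]))


@dataclass(frozen=True)
class OneSiteModel:
    """Binding parameters of the identical-sites model.

    ``n`` sites per macromolecule, dissociation constant ``kd_m`` (M) and
    per-site molar enthalpy ``dh_kcal_mol`` (kcal/mol).
    """

    n: float
    kd_m: float
    dh_kcal_mol: float

    def __post_init__(self) -> None:
        for v in (self.n, self.kd_m, self.dh_kcal_mol):
            if not np.isfinite(v):
                raise ValueError("model parameters must be finite")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.kd_m < 0:
            raise ValueError("Kd must be non-negative")


@dataclass(frozen=True)
class ThermoDecomposition:
    """Gibbs decomposition dG = dH - TdS at a stated temperature."""

    dg_kcal_mol: float
    dh_kcal_mol: float
    tds_kcal_mol: float
    minus_tds_kcal_mol: float
    temperature_k: float


def concentrations_after(protocol: TitrationProtocol, i: int) -> tuple[float, float]:
    """Total cell concentrations of macromolecule and titrant after injection ``i``.

    The overflow-cell dilution bookkeeping: with cumulative injected
    volume ``v``, the macromolecule is diluted by
    ``(1 - v/2V0)/(1 + v/2V0)`` and the titrant accumulates as
    ``syringe_conc * (v/V0)/(1 + v/2V0)``.

    Returns ``(macromolecule_t, titrant_t)`` in M. ``i = 0`` returns the
    pre-titration state.
    """
    if i == 0:
        return protocol.cell_conc0_m, 0.0
    v = protocol.cumulative_volume_ul(i)
    half = v / (2.0 * protocol.v0_ul)
    if half >= 1.0:
        raise ValueError("cumulative injected volume exceeds 2*V0: model breakdown")
    mac_t = protocol.cell_conc0_m * (1.0 - half) / (1.0 + half)
    tit_t = protocol.syringe_conc_m * (v / protocol.v0_ul) / (1.0 + half)
    return mac_t, tit_t


def one_site_q(
    model: OneSiteModel, mac_t: float, tit_t: float, v0_ul: float
) -> float:
    """Total heat content Q (cal) of the cell at the given total concentrations.

    Wiseman isotherm for n identical independent sites::

        Q = (n * M_t * dH * V0 / 2) * [X - sqrt(X^2 - 4*L_t/(n*M_t))]
        X = 1 + L_t/(n*M_t) + Kd/(n*M_t)

    The discriminant is clamped at zero to absorb rounding; a tiny
    negative value can only arise numerically at Kd -> 0 saturation.
    """
    if mac_t <= 0:
        raise ValueError("macromolecule concentration must be positive")
    if tit_t == 0 or model.dh_kcal_mol == 0:
        return 0.0
    nm = model.n * mac_t
    x = 1.0 + tit_t / nm + model.kd_m / nm
    disc = x * x - 4.0 * tit_t / nm
    bracket = x - math.sqrt(max(disc, 0.0))
    v0_l = v0_ul * 1e-6
    q = 0.5 * nm * (model.dh_kcal_mol * 1e3) * v0_l * bracket
    if not np.isfinite(q):
        raise ValueError("non-finite Q: pathological model parameters")
    return q


def injection_heats(model: OneSiteModel, protocol: TitrationProtocol) -> np.ndarray:
    """Per-injection heats dQ(i) in ucal with the displaced-volume correction.

    ``dQ(i) = Q(i) + (dV_i/V0) * (Q(i) + Q(i-1))/2 - Q(i-1)`` with
    ``Q(0) = 0`` and Q(i) evaluated at the post-injection total
    concentrations. The correction term accounts for the heat carried
    out of the active volume by the displaced liquid.
    """
    heats = np.empty(protocol.n_injections)
    q_prev = 0.0
    for i in range(1, protocol.n_injections + 1):
        mac_t, tit_t = concentrations_after(protocol, i)
        q_i = one_site_q(model, mac_t, tit_t, protocol.v0_ul)
        dv = protocol.injections_ul[i - 1]
        dq = q_i + (dv / protocol.v0_ul) * 0.5 * (q_i + q_prev) - q_prev
        heats[i - 1] = dq * 1e6  # cal -> ucal
        q_prev = q_i
    return heats


@dataclass
class ITCFitResult:
    """Result of a one-site fit to injection heats."""

    model: OneSiteModel
    stderr: dict = field(default_factory=dict)
    residuals_ucal: np.ndarray | None = None
    success: bool = True
    unidentifiable: bool = False
    message: str = ""
    thermo: ThermoDecomposition | None = None

    def to_dict(self) -> dict:
        out = {
            "n": self.model.n,
            "Kd_M": self.model.kd_m,
            "dH_kcal_mol": self.model.dh_kcal_mol,
            "success": self.success,
            "unidentifiable": self.unidentifiable,
        }
        for k, v in self.stderr.items():
            out[f"se_{k}"] = v
        if self.thermo is not None:
            out["dG_kcal_mol"] = self.thermo.dg_kcal_mol
            out["TdS_kcal_mol"] = self.thermo.tds_kcal_mol
            out["minus_TdS_kcal_mol"] = self.thermo.minus_tds_kcal_mol
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def fit_one_site(
    heats_ucal: np.ndarray,
    protocol: TitrationProtocol,
    init: OneSiteModel,
    *,
    skip_first: bool = True,
    sigma_ucal: np.ndarray | None = None,
) -> ITCFitResult:
    """Fit (n, Kd, dH) to observed injection heats by weighted least squares.

    The first (small pre-) injection is excluded by default, matching
    standard ITC practice. Kd is fitted on a log scale so it stays
    positive. Unit weights unless per-point ``sigma_ucal`` is supplied.
    """
    heats = np.asarray(heats_ucal, dtype=float)
    if heats.size != protocol.n_injections:
        raise ValueError("number of heats must match the injection schedule")
    use = np.ones(heats.size, dtype=bool)
    if skip_first:
        use[0] = False
    if use.sum() < 5:
        raise ValueError("need at least 5 usable injections")
    weights = np.ones(heats.size)
    if sigma_ucal is not None:
        sig = np.asarray(sigma_ucal, dtype=float)
        if np.any(sig <= 0):
            raise ValueError("sigmas must be positive")
        weights = 1.0 / sig

    scale = np.max(np.abs(heats[use]))
    if scale < 1e-9:
        # No signal: dH -> 0 and nothing else is determined.
        return ITCFitResult(
            model=OneSiteModel(init.n, init.kd_m, 1e-30),
            residuals_ucal=heats.copy(),
            success=True,
            unidentifiable=True,
            message="all heats are zero; only dH -> 0 is identified",
        )

    params = lmfit.Parameters()
    params.add("n", value=init.n, min=1e-3, max=1e3)
    params.add("log10_kd", value=math.log10(init.kd_m), min=-15.0, max=3.0)
    params.add("dh", value=init.dh_kcal_mol if init.dh_kcal_mol != 0 else scale)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = OneSiteModel(p["n"].value, 10.0 ** p["log10_kd"].value, p["dh"].value)
        pred = injection_heats(model, protocol)
        return ((pred - heats) * weights)[use]

    out = lmfit.minimize(residual, params, method="leastsq")
    p = out.params
    fitted = OneSiteModel(p["n"].value, 10.0 ** p["log10_kd"].value, p["dh"].value)
    stderr: dict[str, float] = {}
    if p["n"].stderr is not None:
        stderr["n"] = p["n"].stderr
        stderr["dH_kcal_mol"] = p["dh"].stderr
        # delta method: se(Kd) = Kd * ln(10) * se(log10 Kd)
        stderr["Kd_M"] = fitted.kd_m * math.log(10.0) * p["log10_kd"].stderr

    model_heats = injection_heats(fitted, protocol)
    message = out.message if not out.success else ""
    if not out.success:
        grad_norm = float(np.linalg.norm(out.residual))
        message = f"{out.message} (final residual norm {grad_norm:.3g})"
    thermo = derive_thermodynamics(
        fitted.kd_m, fitted.dh_kcal_mol, protocol.temperature_k
    )
    return ITCFitResult(
        model=fitted,
        stderr=stderr,
        residuals_ucal=heats - model_heats,
        success=bool(out.success),
        unidentifiable=False,
        message=message,
        thermo=thermo,
    )


def derive_thermodynamics(
    kd_m: float, dh_kcal_mol: float, temperature_k: float
) -> ThermoDecomposition:
    """Free energy and entropic term from Kd and dH.

    ``dG = R*T*ln(Kd)`` with Kd in molar (standard state 1 M),
    ``TdS = dH - dG``. ``minus_tds`` is the ``-TdS`` quantity reported
    alongside calorimetric enthalpies.
    """
    if kd_m <= 0:
        raise ValueError("Kd must be positive")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    dg = R_KCAL * temperature_k * math.log(kd_m)
    tds = dh_kcal_mol - dg
    return ThermoDecomposition(
        dg_kcal_mol=dg,
        dh_kcal_mol=dh_kcal_mol,
        tds_kcal_mol=tds,
        minus_tds_kcal_mol=-tds,
        temperature_k=temperature_k,
    )


def read_heats_csv(path) -> pd.DataFrame:
    """Read an injection-heat table: injection_index, dV_uL, heat_ucal[, sigma_ucal]."""
    df = pd.read_csv(path)
    required = {"injection_index", "dV_uL", "heat_ucal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in heat table: {sorted(missing)}")
    return df.sort_values("injection_index").reset_index(drop=True)


def write_heats_csv(path, protocol: TitrationProtocol, heats_ucal: np.ndarray) -> None:
    pd.DataFrame(
        {
            "injection_index": np.arange(1, protocol.n_injections + 1),
            "dV_uL": protocol.injections_ul,
            "heat_ucal": np.asarray(heats_ucal, dtype=float),
        }
    ).to_csv(path, index=False)
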