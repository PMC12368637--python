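"""Seeded synthetic-data generators for every analysis stage.

Each generator evaluates the same forward model the corresponding fitter
inverts — the ITC heats come from :func:`bindkit.itc_onesite.injection_heats`,
the MST responses from :func:`bindkit.mst_binding.fraction_bound`, the
relaxation decays from :func:`bindkit.nmr_relaxation.forward_rates`, and
the ESI envelopes from :func:`bindkit.native_ms.mz_from_mass` — then
perturbs the result according to a :class:`NoiseSpec`. Generators are
pure functions of their parameters and the noise seed: the same call
produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import itc_onesite, mst_binding, native_ms, nmr_relaxation
from .itc_onesite import OneSiteModel, TitrationProtocol
from .mst_binding import DoseResponseSeries
from .native_ms import PROTON_MASS_DA, PeakList
from .nmr_relaxation import (
    R1_DELAYS_S,
    R2_DELAYS_S,
    FieldContext,
    ModelFreeParams,
)

__all__ = [
    "NoiseSpec",
    "gen_itc_heats",
    "gen_mst_series",
    "gen_relaxation_decays",
    "gen_esi_envelope",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model applied to generated observables.

    ``gaussian_relative`` scales each value by ``1 + N(0, scale)``;
    ``gaussian_absolute`` adds ``N(0, scale)`` in the observable's own
    units; ``none`` leaves the forward model untouched.
    """

    kind: str = "none"
    scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian_relative", "gaussian_absolute"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator | None = None):
        """Perturb ``values``; a fresh seeded RNG is used unless one is passed."""
        x = np.asarray(values, dtype=float)
        if self.kind == "none" or self.scale == 0.0:
            return x.copy()
        if rng is None:
            rng = np.random.default_rng(self.seed)
        eps = rng.normal(0.0, self.scale, size=x.shape)
        if self.kind == "gaussian_relative":
            return x * (1.0 + eps)
        return x + eps

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NO_NOISE = NoiseSpec()

#: default ITC noise: absolute Gaussian, sigma 0.05 ucal, reflecting the
#: low signal-to-noise regime of weak (uM, small-dH) binding heats.
DEFAULT_ITC_NOISE = NoiseSpec(kind="gaussian_absolute", scale=0.05, seed=0)


def gen_itc_heats(
    model: OneSiteModel,
    protocol: TitrationProtocol,
    noise: NoiseSpec = NO_NOISE,
) -> pd.DataFrame:
    """Synthetic per-injection heat table (injection_index, dV_uL, heat_ucal)."""
    heats = itc_onesite.injection_heats(model, protocol)
    heats = noise.apply(heats)
    return pd.DataFrame(
        {
            "injection_index": np.arange(1, protocol.n_injections + 1),
            "dV_uL": protocol.injections_ul,
            "heat_ucal": heats,
        }
    )


def gen_mst_series(
    kd_m: float,
    target_conc_m: float,
    top_ligand_m: float,
    n_points: int = 16,
    dilution_factor: float = 2.0,
    plateaus: tuple[float, float] = (800.0, 900.0),
    noise: NoiseSpec = NO_NOISE,
) -> DoseResponseSeries:
    """Serial-dilution dose-response series.

    Ligand concentrations run from ``top_ligand_m`` down by
    ``dilution_factor`` for ``n_points`` steps; responses interpolate
    between the ``(unbound, bound)`` plateaus by the exact fraction
    bound. ``kd_m = inf`` produces a flat series at the unbound plateau.
    """
    if top_ligand_m <= 0:
        raise ValueError("top ligand concentration must be positive")
    if n_points < 4:
        raise ValueError("need at least 4 dilution points")
    if dilution_factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    unbound, bound = plateaus
    if unbound == bound:
        raise ValueError("equal plateaus make the series unidentifiable")
    ligand = top_ligand_m / dilution_factor ** np.arange(n_points)
    if np.isinf(kd_m):
        fb = np.zeros(n_points)
    else:
        fb = mst_binding.fraction_bound(target_conc_m, ligand, kd_m)
    responses = noise.apply(unbound + (bound - unbound) * fb)
    return DoseResponseSeries(
        target_conc_m=target_conc_m, ligand_concs_m=ligand, responses=responses
    )


def rigid_residue_params(
    tau_r_s: float,
    s2: float = 0.85,
    tau_e_s: float = 20e-12,
    rex_s1: float = 0.0,
) -> ModelFreeParams:
    """Model-free parameters of a rigid secondary-structure residue.

    Defaults emulate a well-ordered backbone amide: order parameter 0.85
    and a fast internal correlation time of 20 ps, values typical of
    helix/strand residues in Lipari-Szabo fits and small enough that the
    residue passes the NOE > 0.75 rigidity filter at high field.
    """
    return ModelFreeParams(tau_r_s=tau_r_s, s2=s2, tau_e_s=tau_e_s, rex_s1=rex_s1)


def gen_relaxation_decays(
    params: ModelFreeParams | dict,
    field: FieldContext,
    residues,
    r1_delays_s=R1_DELAYS_S,
    r2_delays_s=R2_DELAYS_S,
    noise: NoiseSpec = NO_NOISE,
    a0: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic R1/R2 decay amplitudes and NOE amplitude pairs.

    ``params`` is either one :class:`ModelFreeParams` shared by all
    residues or a mapping residue -> params. Returns a long-format
    amplitude table (residue, series, delay_s, amplitude) and a NOE
    table (residue, I_sat, I_ref) with ``I_sat/I_ref`` equal to the
    forward-model NOE. A single RNG drawn from the noise seed perturbs
    all amplitudes, so the whole dataset is reproducible from one seed.
    """
    r1_delays = np.asarray(r1_delays_s, dtype=float)
    r2_delays = np.asarray(r2_delays_s, dtype=float)
    for d in (r1_delays, r2_delays):
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("delays must be positive and strictly increasing")
    rng = noise.rng()
    rows = []
    noe_rows = []
    for residue in residues:
        p = params[residue] if isinstance(params, dict) else params
        r1, r2, noe_val = nmr_relaxation.forward_rates(p, field)
        for series_id, rate, delays in (("R1", r1, r1_delays), ("R2", r2, r2_delays)):
            if np.any(rate * delays > 50.0):
                raise ValueError(
                    f"{series_id} decay underflows (R*t > 50) for residue {residue}"
                )
            amps = noise.apply(a0 * np.exp(-rate * delays), rng=rng)
            rows.extend(
                {
                    "residue": residue,
                    "series": series_id,
                    "delay_s": t,
                    "amplitude": amp,
                }
                for t, amp in zip(delays, amps)
            )
        i_ref, i_sat = noise.apply(np.array([a0, a0 * noe_val]), rng=rng)
        noe_rows.append({"residue": residue, "I_sat": i_sat, "I_ref": i_ref})
    return pd.DataFrame(rows), pd.DataFrame(noe_rows)


def gen_esi_envelope(
    mass_da: float,
    charges,
    intensity_width: float | None = None,
    peak_intensity: float = 100.0,
    mz_jitter: NoiseSpec = NO_NOISE,
) -> PeakList:
    """Synthetic ESI charge-state envelope for a species of the given mass.

    One peak per charge at ``(M + z*mp)/z`` with a Gaussian intensity
    profile over charge, centered mid-range (the profile shape does not
    affect zero-charge reconstruction; it is fixed for reproducibility).
    ``mz_jitter`` perturbs the m/z axis, emulating calibration and
    centroiding error.
    """
    z = np.asarray(sorted(charges), dtype=int)
    if z.size == 0:
        raise ValueError("empty charge range")
    if np.any(z < 1):
        raise ValueError("charges must be >= 1")
    if mass_da <= 0:
        raise ValueError("mass must be positive")
    mz = (mass_da + z * PROTON_MASS_DA) / z
    center = z.mean()
    width = intensity_width if intensity_width is not None else max(np.ptp(z) / 4.0, 1.0)
    intensity = peak_intensity * np.exp(-0.5 * ((z - center) / width) ** 2)
    mz = mz_jitter.apply(mz)
    return PeakList(mz=mz, intensity=intensity)
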