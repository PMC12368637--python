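"""Backbone amide 15N relaxation analysis.

The pipeline covered here:

* monoexponential fitting of peak-amplitude decays to R1/R2 rates, with
  Monte-Carlo uncertainty estimates (200 resampled refits by default);
* heteronuclear NOE from saturated/reference amplitude ratios;
* forward model-free rates (Lipari-Szabo spectral density, 1H-15N
  dipolar + 15N CSA mechanisms) used as generator and oracle;
* local correlation time tauC from the R2/R1 ratio, and the overall
  rotational correlation time tauR as the mean tauC over rigid residues
  (secondary-structure mask, NOE threshold);
* reduced spectral density mapping (single high-frequency approximation)
  giving J(0), J(wN), J(0.87 wH) per residue;
* two-state exchange population from free/bound/observed correlation
  times, in both the linear-tau and inverse-rate mixing conventions;
* composite 1H/15N chemical-shift perturbations.

The static field is an explicit argument everywhere: rates at different
fields are never comparable, so no default field is baked in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import trim_mean

__all__ = [
    "FieldContext",
    "ModelFreeParams",
    "RelaxationRateSet",
    "SpectralDensityTriple",
    "ExchangeTwoState",
    "RateFit",
    "R1_DELAYS_S",
    "R2_DELAYS_S",
    "spectral_density",
    "forward_rates",
    "fit_exponential_rate",
    "compute_noe",
    "tauc_from_ratio",
    "overall_tau_r",
    "reduced_sdm",
    "exchange_population",
    "csp",
]

#: gyromagnetic ratios, rad s^-1 T^-1
GAMMA_H = 2.6752219e8
GAMMA_N = -2.7126e7
HBAR = 1.054571817e-34  # J s
MU0_OVER_4PI = 1e-7  # T m A^-1

#: R1 evolution times (s): 10 ms to 1010 ms in nine steps.
R1_DELAYS_S = (0.010, 0.090, 0.170, 0.290, 0.410, 0.550, 0.690, 0.850, 1.010)
#: R2 CPMG relaxation delays (s): 10 ms to 150 ms in eight steps.
R2_DELAYS_S = (0.010, 0.030, 0.050, 0.070, 0.090, 0.110, 0.130, 0.150)


@dataclass(frozen=True)
class FieldContext:
    """Static field and the interaction constants of the 15N relaxation model.

    ``r_nh_m`` is the effective N-H bond length (1.02 A default) and
    ``delta_sigma_n`` the 15N chemical-shift anisotropy (-172 ppm
    default); both are conventions of the model, exposed for adjustment.
    """

    b0_t: float
    r_nh_m: float = 1.02e-10
    delta_sigma_n_ppm: float = -172.0
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N

    def __post_init__(self) -> None:
        if self.b0_t <= 0:
            raise ValueError("B0 must be positive")
        if self.r_nh_m <= 0:
            raise ValueError("bond length must be positive")

    @property
    def omega_h(self) -> float:
        """1H Larmor angular frequency (rad/s, positive)."""
        return self.gamma_h * self.b0_t

    @property
    def omega_n(self) -> float:
        """15N Larmor angular frequency (rad/s, signed: negative for 15N)."""
        return self.gamma_n * self.b0_t

    @property
    def d_dipolar(self) -> float:
        """Dipolar coupling constant d = (mu0/4pi) hbar gH gN / r^3 (rad/s)."""
        return (
            MU0_OVER_4PI * HBAR * self.gamma_h * self.gamma_n / self.r_nh_m**3
        )

    @property
    def c_csa(self) -> float:
        """CSA constant c = wN * dSigma / sqrt(3) (rad/s)."""
        return self.omega_n * self.delta_sigma_n_ppm * 1e-6 / math.sqrt(3.0)


@dataclass(frozen=True)
class ModelFreeParams:
    """Lipari-Szabo parameters: overall tumbling, order parameter, internal motion.

    ``rex_s1`` adds a chemical-exchange contribution to R2 only.
    """

    tau_r_s: float
    s2: float = 1.0
    tau_e_s: float = 0.0
    rex_s1: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_r_s <= 0:
            raise ValueError("tau_R must be positive")
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError("S2 must lie in [0, 1]")
        if self.tau_e_s < 0 or self.tau_e_s >= self.tau_r_s:
            raise ValueError("tau_e must satisfy 0 <= tau_e < tau_R")


def spectral_density(omega, params: ModelFreeParams):
    """Lipari-Szabo spectral density J(w) in s/rad.

    ``J(w) = (2/5) [S2 tauR/(1+(w tauR)^2) + (1-S2) tau'/(1+(w tau')^2)]``
    with ``1/tau' = 1/tauR + 1/taue``. Accepts scalar or array ``omega``.
    """
    w = np.abs(np.asarray(omega, dtype=float))
    tr = params.tau_r_s
    j = params.s2 * tr / (1.0 + (w * tr) ** 2)
    if params.s2 < 1.0 and params.tau_e_s > 0.0:
        tp = 1.0 / (1.0 / tr + 1.0 / params.tau_e_s)
        j = j + (1.0 - params.s2) * tp / (1.0 + (w * tp) ** 2)
    j = 0.4 * j
    return j if j.ndim else float(j)


def forward_rates(
    params: ModelFreeParams, field: FieldContext
) -> tuple[float, float, float]:
    """Model-free (R1, R2, NOE) for an amide 15N at the given field.

    Standard dipolar + CSA expressions; Rex (if any) is added to R2.
    """
    d2 = field.d_dipolar**2
    c2 = field.c_csa**2
    # omega_N keeps the sign of gamma_N: the double-quantum frequency
    # wH + wN is then |wH| - |wN| (~0.9 wH), which is what the 0.87 wH
    # effective frequency of reduced SDM presupposes.
    wh, wn = field.omega_h, field.omega_n
    j = lambda w: spectral_density(w, params)
    jhmn, jn, jhpn = j(wh - wn), j(wn), j(wh + wn)
    j0, jh = j(0.0), j(wh)
    r1 = (d2 / 4.0) * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = (
        (d2 / 8.0) * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn)
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn)
        + params.rex_s1
    )
    noe = 1.0 + (d2 / (4.0 * r1)) * (field.gamma_h / field.gamma_n) * (
        6.0 * jhpn - jhmn
    )
    return r1, r2, noe


@dataclass
class RateFit:
    """Monoexponential decay fit: amplitude A0 and rate R with MC uncertainty."""

    rate_s1: float
    rate_sigma_s1: float
    a0: float
    noise_sigma: float
    negative_rate: bool = False


def fit_exponential_rate(
    delays_s,
    amplitudes,
    n_mc: int = 200,
    seed: int | None = None,
    noise_sigma: float | None = None,
) -> RateFit:
    """Fit A(t) = A0 exp(-R t) and estimate sigma(R) by Monte-Carlo resampling.

    The uncertainty is the SD of the rate over ``n_mc`` refits of the
    best-fit curve perturbed with Gaussian noise at the supplied
    per-point amplitude noise; when no noise estimate is supplied the
    RMS of the fit residuals is used. Noiseless data therefore yield a
    zero uncertainty.
    """
    t = np.asarray(delays_s, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 delays")
    if np.any(a <= 0):
        raise ValueError("amplitudes must be positive for a log-seeded fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("delays must be strictly increasing")

    # log-linear regression seeds the nonlinear fit
    slope, intercept = np.polyfit(t, np.log(a), 1)
    p0 = (math.exp(intercept), max(-slope, 0.0))

    def decay(tt, a0, r):
        return a0 * np.exp(-r * tt)

    popt, _ = curve_fit(decay, t, a, p0=p0, maxfev=10000)
    a0_hat, r_hat = float(popt[0]), float(popt[1])
    resid = a - decay(t, *popt)
    sigma = float(noise_sigma) if noise_sigma is not None else float(
        np.sqrt(np.mean(resid**2))
    )

    rate_sigma = 0.0
    if sigma > 0 and n_mc > 0:
        rng = np.random.default_rng(seed)
        best = decay(t, a0_hat, r_hat)
        rates = np.empty(n_mc)
        for k in range(n_mc):
            synth = best + rng.normal(0.0, sigma, size=t.size)
            try:
                pk, _ = curve_fit(decay, t, synth, p0=(a0_hat, r_hat), maxfev=10000)
                rates[k] = pk[1]
            except RuntimeError:
                rates[k] = np.nan
        rate_sigma = float(np.nanstd(rates, ddof=1))

    return RateFit(
        rate_s1=r_hat,
        rate_sigma_s1=rate_sigma,
        a0=a0_hat,
        noise_sigma=sigma,
        negative_rate=r_hat < 0,
    )


def compute_noe(
    i_sat: float, i_ref: float, sigma_sat: float = 0.0, sigma_ref: float = 0.0
) -> tuple[float, float]:
    """Heteronuclear NOE = I_sat / I_ref with first-order error propagation."""
    if abs(i_ref) < 1e-300:
        raise ValueError("reference amplitude is zero; NOE undefined")
    noe = i_sat / i_ref
    sigma = abs(noe) * math.sqrt(
        (sigma_sat / i_sat) ** 2 + (sigma_ref / i_ref) ** 2
    ) if i_sat != 0 else abs(sigma_sat / i_ref)
    return noe, sigma


def tauc_from_ratio(r2: float, r1: float, field: FieldContext) -> float:
    """Local correlation time from the R2/R1 ratio.

    ``tauC = sqrt(6 R2/R1 - 7) / (2 |wN|)``, valid when ``6 R2/R1 > 7``
    (slow-tumbling, high-field approximation keeping only J(0) and
    J(wN)). Returns NaN when the ratio falls below the validity bound;
    callers exclude such residues from averages.
    """
    if r1 <= 0:
        raise ValueError("R1 must be positive")
    arg = 6.0 * r2 / r1 - 7.0
    if arg < 0:
        return math.nan
    return math.sqrt(arg) / (2.0 * abs(field.omega_n))


@dataclass(frozen=True)
class RelaxationRateSet:
    """Per-residue relaxation observables at one stated field."""

    residues: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    noe: np.ndarray
    r1_err: np.ndarray | None = None
    r2_err: np.ndarray | None = None
    noe_err: np.ndarray | None = None
    field: FieldContext | None = None

    def __post_init__(self) -> None:
        res = np.asarray(self.residues)
        for name in ("r1", "r2", "noe"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != res.shape:
                raise ValueError(f"{name} must align with residues")
            object.__setattr__(self, name, arr)
        if np.any(self.r1 <= 0) or np.any(self.r2 <= 0):
            raise ValueError("R1 and R2 must be positive")
        object.__setattr__(self, "residues", res)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"residue": self.residues, "R1_s1": self.r1, "R2_s1": self.r2, "NOE": self.noe}
        )
        for col, arr in (
            ("R1_err", self.r1_err),
            ("R2_err", self.r2_err),
            ("NOE_err", self.noe_err),
        ):
            if arr is not None:
                df[col] = arr
        return df


def overall_tau_r(
    rates: RelaxationRateSet,
    field: FieldContext,
    mask: np.ndarray | set | None = None,
    noe_min: float = 0.75,
    trim_fraction: float = 0.0,
) -> tuple[float, float, int]:
    """Overall rotational correlation time from rigid-residue R2/R1 ratios.

    Residues are kept when they are in the secondary-structure ``mask``
    (a set of residue ids; None keeps all) and have NOE above
    ``noe_min`` — both filters reject flexible residues whose local
    motion biases tauC low. Residues whose ratio falls below the tauC
    validity bound are excluded. Returns (mean, standard error, n_used);
    ``trim_fraction`` > 0 switches to a symmetric trimmed mean, which is
    robust to a minority of exchange-broadened residues.
    """
    keep = rates.noe > noe_min
    if mask is not None:
        in_mask = np.array([r in set(mask) for r in rates.residues])
        keep &= in_mask
    tauc = np.array(
        [
            tauc_from_ratio(r2, r1, field)
            for r1, r2 in zip(rates.r1[keep], rates.r2[keep])
        ]
    )
    tauc = tauc[np.isfinite(tauc)]
    if tauc.size < 5:
        raise ValueError("fewer than 5 residues pass the rigidity filters")
    if trim_fraction > 0:
        mean = float(trim_mean(tauc, trim_fraction))
    else:
        mean = float(tauc.mean())
    sem = float(tauc.std(ddof=1) / math.sqrt(tauc.size)) if tauc.size > 1 else 0.0
    return mean, sem, int(tauc.size)


@dataclass(frozen=True)
class SpectralDensityTriple:
    """Per-residue reduced spectral densities, s/rad."""

    j0: np.ndarray
    j_wn: np.ndarray
    j_wh087: np.ndarray
    j0_err: np.ndarray | None = None
    j_wn_err: np.ndarray | None = None
    j_wh087_err: np.ndarray | None = None


def reduced_sdm(
    r1,
    r2,
    noe,
    field: FieldContext,
    r1_err=None,
    r2_err=None,
    noe_err=None,
) -> SpectralDensityTriple:
    """Reduced spectral density mapping of (R1, R2, NOE) triples.

    Single high-frequency approximation J(wH +/- wN) ~ J(wH) ~
    J(0.87 wH) applied to the forward dipolar+CSA expressions::

        sigma_NOE   = (NOE - 1) R1 gN/gH
        J(0.87 wH)  = 4 sigma_NOE / (5 d^2)
        J(wN)       = [R1 - (7/5) sigma_NOE] / (3 d^2/4 + c^2)
        J(0)        = [R2 - (13 d^2/8) J(0.87wH) - (3 d^2/8 + c^2/2) J(wN)]
                      / (d^2/2 + 2 c^2/3)

    Exchange contributions to R2 surface as inflated J(0). Negative J
    values (noise or Rex pathology) are reported as-is, never clipped.
    Uncertainties, when the rate errors are given, follow first-order
    propagation through the linear map.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    noe = np.asarray(noe, dtype=float)
    d2 = field.d_dipolar**2
    c2 = field.c_csa**2
    g_ratio = field.gamma_n / field.gamma_h

    sigma_noe = (noe - 1.0) * r1 * g_ratio
    j_wh = 4.0 * sigma_noe / (5.0 * d2)
    denom_n = 0.75 * d2 + c2
    j_wn = (r1 - 1.4 * sigma_noe) / denom_n
    denom_0 = 0.5 * d2 + (2.0 / 3.0) * c2
    j0 = (r2 - (13.0 * d2 / 8.0) * j_wh - (3.0 * d2 / 8.0 + c2 / 2.0) * j_wn) / denom_0

    errs = (None, None, None)
    if r1_err is not None and r2_err is not None and noe_err is not None:
        r1e = np.asarray(r1_err, dtype=float)
        r2e = np.asarray(r2_err, dtype=float)
        noee = np.asarray(noe_err, dtype=float)
        # sigma_NOE error from independent R1, NOE
        s_err = np.abs(g_ratio) * np.sqrt(
            ((noe - 1.0) * r1e) ** 2 + (r1 * noee) ** 2
        )
        j_wh_err = 4.0 * s_err / (5.0 * d2)
        j_wn_err = np.sqrt(r1e**2 + (1.4 * s_err) ** 2) / denom_n
        j0_err = (
            np.sqrt(
                r2e**2
                + ((13.0 * d2 / 8.0) * j_wh_err) ** 2
                + ((3.0 * d2 / 8.0 + c2 / 2.0) * j_wn_err) ** 2
            )
            / denom_0
        )
        errs = (j0_err, j_wn_err, j_wh_err)

    return SpectralDensityTriple(
        j0=j0, j_wn=j_wn, j_wh087=j_wh,
        j0_err=errs[0], j_wn_err=errs[1], j_wh087_err=errs[2],
    )


@dataclass(frozen=True)
class ExchangeTwoState:
    """Two-state fast-exchange mixing of free and bound correlation times."""

    tau_r_free_s: float
    tau_r_bound_s: float
    tau_r_obs_s: float
    convention: str = "linear_tau"

    def __post_init__(self) -> None:
        if not self.tau_r_free_s < self.tau_r_bound_s:
            raise ValueError("free-state tau_R must be below bound-state tau_R")
        if self.convention not in ("linear_tau", "inverse_rate"):
            raise ValueError("convention must be linear_tau or inverse_rate")


def exchange_population(model: ExchangeTwoState) -> float:
    """Bound fraction from the observed overall correlation time.

    ``linear_tau`` (default) treats the observed tauR as the
    population-weighted average of the free and bound correlation
    times::

        p = (tau_obs - tau_f) / (tau_b - tau_f)

    ``inverse_rate`` mixes the tumbling *rates* instead::

        1/tau_obs = (1 - p)/tau_f + p/tau_b

    The two agree to first order for small p but diverge strongly when
    the bound-state tau is much larger than the free-state tau; both are
    exposed because the appropriate convention depends on which
    observable averages linearly under fast exchange.
    """
    tf, tb, to = model.tau_r_free_s, model.tau_r_bound_s, model.tau_r_obs_s
    if not tf <= to <= tb:
        warnings.warn(
            "observed tau_R outside [free, bound]: extrapolating population",
            stacklevel=2,
        )
    if model.convention == "linear_tau":
        return (to - tf) / (tb - tf)
    return (1.0 / tf - 1.0 / to) / (1.0 / tf - 1.0 / tb)


def csp(
    dh_a, dn_a, dh_b, dn_b, nitrogen_weight: float = 0.14
) -> np.ndarray:
    """Composite 1H/15N chemical-shift perturbation in ppm.

    ``ddelta = sqrt(ddH^2 + (w * ddN)^2)`` with the conventional 15N
    scaling weight 0.14. Inputs are the per-residue (1H, 15N) shifts of
    the two states, matched by position.
    """
    dh = np.asarray(dh_b, dtype=float) - np.asarray(dh_a, dtype=float)
    dn = np.asarray(dn_b, dtype=float) - np.asarray(dn_a, dtype=float)
    return np.sqrt(dh**2 + (nitrogen_weight * dn) ** 2)


def csp_outliers(deltas: np.ndarray, n_sd: float = 1.0) -> np.ndarray:
    """Indices of residues whose perturbation exceeds mean + n_sd * SD."""
    d = np.asarray(deltas, dtype=float)
    return np.flatnonzero(d > d.mean() + n_sd * d.std(ddof=1))


def load_structured_mask() -> set[int]:
    """Residue ids in helix/strand secondary structure for monomeric cystatin C.

    This packaged mask is a SYNTHETIC stand-in sketching the cystatin
    fold (one alpha-helix, five beta-strands); it exercises the mask
    plumbing of :func:`overall_tau_r` and is not derived from a
    deposited structure. Supply a structure-derived mask for real data.
    """
    import json
    from importlib import resources

    raw = json.loads(
        resources.files("bindkit.data")
        .joinpath("hcc_structured_mask_synthetic.json")
        .read_text()
    )
    residues: set[int] = set()
    for lo, hi in raw["elements"].values():
        residues.update(range(lo, hi + 1))
    return residues


def fit_rates_from_table(
    table: pd.DataFrame,
    n_mc: int = 200,
    seed: int | None = None,
    noise_sigma: float | None = None,
) -> pd.DataFrame:
    """Fit per-residue rates from a long-format amplitude table.

    Expects columns (residue, series, delay_s, amplitude) where
    ``series`` distinguishes the R1 and R2 decays ("R1"/"R2"). Returns a
    wide per-residue rate table. Seeds for the Monte-Carlo resampling
    are drawn deterministically per residue/series from ``seed``.
    """
    required = {"residue", "series", "delay_s", "amplitude"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns in amplitude table: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for residue, grp in table.groupby("residue", sort=True):
        row: dict = {"residue": residue}
        for series_id, decay in grp.groupby("series"):
            decay = decay.sort_values("delay_s")
            fit = fit_exponential_rate(
                decay["delay_s"].to_numpy(),
                decay["amplitude"].to_numpy(),
                n_mc=n_mc,
                seed=int(rng.integers(0, 2**31 - 1)),
                noise_sigma=noise_sigma,
            )
            row[f"{series_id}_s1"] = fit.rate_s1
            row[f"{series_id}_err"] = fit.rate_sigma_s1
        rows.append(row)
    return pd.DataFrame(rows)
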