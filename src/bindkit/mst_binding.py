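"""MST dose-response Kd fitting with the exact two-component binding model.

A microscale-thermophoresis experiment titrates an unlabeled ligand
against a fixed, low concentration of fluorescently labeled target and
records a response that interpolates between an unbound and a bound
plateau. The fraction bound comes from the exact mass-action quadratic
(no weak-titrant approximation), so fits stay correct when the target
concentration is comparable to Kd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseSeries",
    "MSTFitResult",
    "fraction_bound",
    "fit_kd",
    "read_series_csv",
    "write_series_csv",
]


@dataclass(frozen=True)
class DoseResponseSeries:
    """A ligand dilution series at fixed labeled-target concentration.

    ``target_conc_m`` is the constant labeled-partner concentration (M),
    ``ligand_concs_m`` the titrated-partner concentrations (M), and
    ``responses`` the instrument read-out in arbitrary units.
    """

    target_conc_m: float
    ligand_concs_m: np.ndarray
    responses: np.ndarray
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        lig = np.asarray(self.ligand_concs_m, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if lig.shape != resp.shape:
            raise ValueError("ligand_concs_m and responses must have the same shape")
        if np.any(lig < 0):
            raise ValueError("ligand concentrations must be non-negative")
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        if self.target_conc_m <= 0:
            raise ValueError("target concentration must be positive")
        object.__setattr__(self, "ligand_concs_m", lig)
        object.__setattr__(self, "responses", resp)
        if self.replicate_id is not None:
            object.__setattr__(self, "replicate_id", np.asarray(self.replicate_id))


def fraction_bound(a_m, l_m, kd_m):
    """Fraction of target A bound to ligand L at dissociation constant Kd.

    Exact two-component equilibrium::

        FB = [(A + L + Kd) - sqrt((A + L + Kd)^2 - 4*A*L)] / (2A)

    Vectorized over ``l_m``. The discriminant is non-negative
    analytically; tiny negatives from rounding are clamped.
    """
    a = float(a_m)
    l = np.asarray(l_m, dtype=float)
    if a <= 0:
        raise ValueError("target concentration must be positive")
    if np.any(l < 0) or kd_m < 0:
        raise ValueError("ligand concentration and Kd must be non-negative")
    s = a + l + kd_m
    disc = s * s - 4.0 * a * l
    fb = (s - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * a)
    fb = np.clip(fb, 0.0, 1.0)
    return fb if fb.ndim else float(fb)


@dataclass
class MSTFitResult:
    kd_m: float
    kd_stderr: float | None
    unbound: float
    bound: float
    residuals: np.ndarray = field(repr=False, default=None)
    success: bool = True
    unidentifiable: bool = False
    kd_unbounded: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "Kd_M": self.kd_m,
            "se_Kd_M": self.kd_stderr,
            "U": self.unbound,
            "B": self.bound,
            "success": self.success,
            "unidentifiable": self.unidentifiable,
            "kd_unbounded": self.kd_unbounded,
        }


def _pool(series) -> DoseResponseSeries:
    if isinstance(series, DoseResponseSeries):
        return series
    seqs = list(series)
    if not seqs:
        raise ValueError("no series supplied")
    target = seqs[0].target_conc_m
    if any(s.target_conc_m != target for s in seqs):
        raise ValueError("replicates must share the target concentration")
    return DoseResponseSeries(
        target_conc_m=target,
        ligand_concs_m=np.concatenate([s.ligand_concs_m for s in seqs]),
        responses=np.concatenate([s.responses for s in seqs]),
        replicate_id=np.concatenate(
            [np.full(s.ligand_concs_m.size, i) for i, s in enumerate(seqs)]
        ),
    )


def fit_kd(
    series: DoseResponseSeries | list[DoseResponseSeries],
    init_kd_m: float | None = None,
) -> MSTFitResult:
    """Least-squares fit of Kd and the two plateaus to a dose-response series.

    Replicates (a list of series) are pooled point-by-point. The model is
    ``response = U + (B - U) * FB(A, L, Kd)`` with Kd log-parameterized.
    A flat series is flagged unidentifiable; a fitted Kd far outside the
    sampled concentration range is flagged ``kd_unbounded`` (transition
    not covered by the titration).
    """
    pooled = _pool(series)
    lig, resp = pooled.ligand_concs_m, pooled.responses
    if np.unique(lig[lig > 0]).size < 6:
        raise ValueError("need at least 6 distinct concentration points")
    span = resp.max() - resp.min()
    if span < 1e-12 * max(1.0, np.abs(resp).max()):
        return MSTFitResult(
            kd_m=np.nan,
            kd_stderr=None,
            unbound=float(resp.mean()),
            bound=float(resp.mean()),
            success=True,
            unidentifiable=True,
            message="responses are constant; Kd not identifiable",
        )

    pos = lig[lig > 0]
    if init_kd_m is None:
        init_kd_m = float(np.exp(np.mean(np.log(pos))))  # geometric mid-point
    params = lmfit.Parameters()
    params.add("log10_kd", value=math.log10(init_kd_m), min=-15.0, max=3.0)
    params.add("unbound", value=float(resp[np.argmin(lig)]))
    params.add("bound", value=float(resp[np.argmax(lig)]))

    def residual(p: lmfit.Parameters) -> np.ndarray:
        fb = fraction_bound(pooled.target_conc_m, lig, 10.0 ** p["log10_kd"].value)
        model = p["unbound"].value + (p["bound"].value - p["unbound"].value) * fb
        return model - resp

    out = lmfit.minimize(residual, params, method="leastsq")
    p = out.params
    kd = 10.0 ** p["log10_kd"].value
    se = None
    if p["log10_kd"].stderr is not None:
        se = kd * math.log(10.0) * p["log10_kd"].stderr
    unbounded = not (pos.min() / 50.0 <= kd <= pos.max() * 50.0)
    return MSTFitResult(
        kd_m=kd,
        kd_stderr=se,
        unbound=p["unbound"].value,
        bound=p["bound"].value,
        residuals=out.residual,
        success=bool(out.success),
        kd_unbounded=unbounded,
        message="Kd outside sampled transition" if unbounded else "",
    )


def read_series_csv(path, target_conc_m: float) -> list[DoseResponseSeries]:
    """Read CSV (ligand_conc_M, response[, replicate]) into one series per replicate."""
    df = pd.read_csv(path)
    required = {"ligand_conc_M", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in MST table: {sorted(missing)}")
    if "replicate" not in df.columns:
        df = df.assign(replicate=0)
    return [
        DoseResponseSeries(
            target_conc_m=target_conc_m,
            ligand_concs_m=g["ligand_conc_M"].to_numpy(),
            responses=g["response"].to_numpy(),
        )
        for _, g in df.groupby("replicate")
    ]


def write_series_csv(path, series: DoseResponseSeries) -> None:
    df = pd.DataFrame(
        {"ligand_conc_M": series.ligand_concs_m, "response": series.responses}
    )
    if series.replicate_id is not None:
        df["replicate"] = series.replicate_id
    df.to_csv(path, index=False)
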