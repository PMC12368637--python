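"""Native ESI charge-state deconvolution and stoichiometry assignment.

An intact protein or complex electrosprayed in native conditions appears
as an envelope of multiply protonated ions, one peak per charge z at
m/z = (M + z*mp)/z. This module assigns charges to an envelope, collapses
it to a zero-charge (neutral average) mass, and assigns an integer
component stoichiometry to a reconstructed complex mass by exhaustive
search against measured reference masses of the components.

Average masses are used throughout: at 13-80 kDa in linear-MALDI or
native-ESI conditions, isotopic fine structure is not resolved. The
electron-mass correction is below the stated precision and is omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PROTON_MASS_DA",
    "PeakList",
    "SpeciesAssignment",
    "mz_from_mass",
    "infer_charge_states",
    "reconstruct_zero_charge",
    "assign_stoichiometry",
    "read_peaklist_csv",
    "write_peaklist_csv",
]

PROTON_MASS_DA = 1.007276


@dataclass(frozen=True)
class PeakList:
    """A centroided peak list: m/z values (Th) sorted ascending with intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "positive"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity must have the same shape")
        if np.any(mz <= 0):
            raise ValueError("m/z values must be positive")
        order = np.argsort(mz)
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    def __len__(self) -> int:
        return self.mz.size


def mz_from_mass(mass_da: float, z: int) -> float:
    """m/z of the z-fold protonated ion [M + zH]^z+."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    if mass_da <= 0:
        raise ValueError("mass must be positive")
    return (mass_da + z * PROTON_MASS_DA) / z


def infer_charge_states(
    peaklist: PeakList, max_charge: int = 100, rel_tolerance: float = 5e-4
) -> np.ndarray:
    """Assign consecutive charge states to a single ESI envelope.

    Within one envelope, peaks sorted by ascending m/z carry descending
    consecutive charges. Every admissible charge for the lowest-m/z peak
    is tried; the assignment whose implied neutral masses agree best
    (minimum relative spread) wins. An envelope whose best spread
    exceeds ``rel_tolerance`` is rejected: its peaks are not a single
    charge-state series.
    """
    n = len(peaklist)
    if n < 2:
        raise ValueError("need at least 2 peaks to infer charge states")
    mz = peaklist.mz
    best: tuple[float, np.ndarray] | None = None
    # lowest-m/z peak carries the highest charge; it must be >= n for all
    # descending charges to stay >= 1
    for z_top in range(n, max_charge + 1):
        charges = z_top - np.arange(n)
        masses = charges * (mz - PROTON_MASS_DA)
        spread = masses.std() / masses.mean()
        if best is None or spread < best[0]:
            best = (spread, charges)
    assert best is not None
    if best[0] > rel_tolerance:
        raise ValueError(
            f"inconsistent peak spacing (relative mass spread {best[0]:.2e} "
            f"> {rel_tolerance:.2e}): not a single charge-state envelope"
        )
    return best[1]


def reconstruct_zero_charge(
    peaklist: PeakList, charges: np.ndarray | None = None
) -> tuple[float, float]:
    """Zero-charge mass from a charge-assigned envelope.

    Each peak implies a neutral mass ``z * (m/z - mp)``; the reported
    mass is their intensity-weighted mean and the spread the weighted
    SD. A single peak yields a mass with NaN spread (no internal
    consistency check possible).
    """
    if charges is None:
        charges = infer_charge_states(peaklist)
    charges = np.asarray(charges)
    if charges.shape != peaklist.mz.shape:
        raise ValueError("one charge per peak required")
    masses = charges * (peaklist.mz - PROTON_MASS_DA)
    w = peaklist.intensity
    if np.all(w == 0):
        w = np.ones_like(w)
    mean = float(np.average(masses, weights=w))
    if len(peaklist) == 1:
        return mean, float("nan")
    var = float(np.average((masses - mean) ** 2, weights=w))
    return mean, var**0.5


@dataclass(frozen=True)
class SpeciesAssignment:
    """An integer stoichiometry assigned to a reconstructed mass."""

    mass_da: float
    spread_da: float
    stoichiometry: dict[str, int] | None
    mass_error_da: float | None
    ambiguous: bool = False
    co_optimal: tuple = ()
    charges_used: tuple = ()

    @property
    def assigned(self) -> bool:
        return self.stoichiometry is not None


def assign_stoichiometry(
    mass_complex_da: float,
    component_masses_da: dict[str, float],
    tolerance_da: float,
    max_copies: int = 4,
    spread_da: float = 0.0,
) -> SpeciesAssignment:
    """Best integer composition of a complex mass from component masses.

    Exhaustively searches all copy-number combinations (0..max_copies
    per component, not all zero) minimizing
    ``|sum_k a_k * M_k - M_complex|``; returns the best combination if
    within ``tolerance_da``, else an unassigned result. Component masses
    should come from reference spectra measured in the same run, since
    native masses carry adducts that sequence masses miss. Exact ties
    are reported as ambiguous with all co-optimal compositions.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    names = sorted(component_masses_da)
    if not names:
        raise ValueError("need at least one component mass")
    grids = np.meshgrid(*[np.arange(max_copies + 1)] * len(names), indexing="ij")
    counts = np.stack([g.ravel() for g in grids], axis=1)
    counts = counts[counts.sum(axis=1) > 0]
    masses = counts @ np.array([component_masses_da[k] for k in names], dtype=float)
    errors = np.abs(masses - mass_complex_da)
    best_err = errors.min()
    winners = counts[errors == best_err]
    if best_err > tolerance_da:
        return SpeciesAssignment(
            mass_da=mass_complex_da,
            spread_da=spread_da,
            stoichiometry=None,
            mass_error_da=None,
        )
    compositions = tuple(dict(zip(names, map(int, row))) for row in winners)
    return SpeciesAssignment(
        mass_da=mass_complex_da,
        spread_da=spread_da,
        stoichiometry=compositions[0],
        mass_error_da=float(best_err),
        ambiguous=len(compositions) > 1,
        co_optimal=compositions if len(compositions) > 1 else (),
    )


def read_peaklist_csv(path) -> PeakList:
    """Read a two-column CSV peak list (mz, intensity)."""
    df = pd.read_csv(path)
    missing = {"mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in peak list: {sorted(missing)}")
    return PeakList(mz=df["mz"].to_numpy(), intensity=df["intensity"].to_numpy())


def write_peaklist_csv(path, peaklist: PeakList) -> None:
    pd.DataFrame({"mz": peaklist.mz, "intensity": peaklist.intensity}).to_csv(
        path, index=False
    )
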