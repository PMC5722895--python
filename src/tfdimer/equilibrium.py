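"""Monomer-dimer equilibrium analysis of SEC-MALS mass-vs-concentration data.

For a fast two-state equilibrium 2 M <-> M2 with dissociation constant K_D,
the weight-averaged molar mass observed at total monomer-equivalent
concentration [M] is

    M_w = 2 M - M * (-K_D + sqrt(K_D^2 + 8 [M] K_D)) / (4 [M]),

which runs from M (all monomer, [M] -> 0) to 2 M (all dimer).  K_D is fitted
by nonlinear least squares in log10(K_D) with the monomer mass fixed from
sequence; datasets that stay flat at the monomer mass over the sampled range
only support a lower limit on K_D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

LOG10_KD_BOUNDS = (-3.0, 5.0)  # K_D search window, 1 nM .. 100 mM (in µM)


@dataclass
class BindingCurve:
    """(concentration µM, M_w kDa) pairs with the monomer mass in kDa."""

    conc_uM: np.ndarray
    mw_kDa: np.ndarray
    monomer_mass_kDa: float
    label: str = ""

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.mw_kDa = np.asarray(self.mw_kDa, dtype=float)
        if np.any(self.conc_uM <= 0):
            raise ValueError("concentrations must be positive")
        if len(self.conc_uM) != len(self.mw_kDa):
            raise ValueError("concentration and mass arrays differ in length")


@dataclass
class KdEstimate:
    kd_uM: float
    ci95_uM: tuple[float, float]
    bound_flag: str = "none"  # "none" | "lower_limit"

    def __post_init__(self) -> None:
        if self.bound_flag == "none":
            lo, hi = self.ci95_uM
            if not (lo <= self.kd_uM <= hi):
                raise ValueError("CI does not bracket the estimate")


def mw_monomer_dimer(conc_uM, kd_uM: float, monomer_mass_kDa: float):
    """Weight-averaged molar mass (kDa) of the mass-action monomer-dimer mix."""
    conc = np.asarray(conc_uM, dtype=float)
    if np.any(conc <= 0) or kd_uM <= 0 or monomer_mass_kDa <= 0:
        raise ValueError("conc, kd and monomer mass must be positive")
    m = monomer_mass_kDa
    root = np.sqrt(kd_uM**2 + 8.0 * conc * kd_uM)
    out = 2.0 * m - m * (-kd_uM + root) / (4.0 * conc)
    return float(out) if np.isscalar(conc_uM) else out


def fit_kd(curve: BindingCurve, noise_sd: float = 0.01) -> KdEstimate:
    """Fit K_D (µM) to a binding curve; 95% CI from the fit covariance.

    The fit parameter is log10(K_D), bounded to [1e-3, 1e5] µM, reflecting
    the orders-of-magnitude spread of dimer affinities across domain
    constructs.  ``noise_sd`` is the fractional M_w uncertainty used both for
    weighting and for the flatness test: if the observed M_w rise across the
    curve is below 3 sigma of the noise, no dimerization was detected and the
    largest probed concentration is returned as a lower limit on K_D.
    """
    conc, mw, m = curve.conc_uM, curve.mw_kDa, curve.monomer_mass_kDa
    if len(conc) < 3:
        raise ValueError("need at least 3 points to fit K_D")
    if np.min(mw) > 1.9 * m:
        raise ValueError("no monomer regime sampled (all points near 2M)")
    rise = (np.max(mw) - np.min(mw)) / m
    if rise < 3.0 * noise_sd:
        cmax = float(np.max(conc))
        return KdEstimate(cmax, (cmax, np.inf), bound_flag="lower_limit")

    def model(c, log10_kd):
        return mw_monomer_dimer(c, 10.0**log10_kd, m)

    sigma = np.maximum(noise_sd * mw, 1e-12)
    p0 = np.clip(np.log10(np.median(conc)), *LOG10_KD_BOUNDS)
    popt, pcov = curve_fit(model, conc, mw, p0=[p0], sigma=sigma,
                           absolute_sigma=True, bounds=LOG10_KD_BOUNDS,
                           maxfev=10000)
    log_kd = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    kd = 10.0**log_kd
    ci = (10.0 ** (log_kd - 1.959964 * se), 10.0 ** (log_kd + 1.959964 * se))
    return KdEstimate(kd, ci)


def read_binding_curve(text: str, monomer_mass_kDa: float,
                       label: str = "") -> BindingCurve:
    """TSV with columns concentration_uM, mw_kDa."""
    import pandas as pd
    from io import StringIO
    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    return BindingCurve(df["concentration_uM"].to_numpy(),
                        df["mw_kDa"].to_numpy(), monomer_mass_kDa, label)


#: Average residue masses (Da) for computing a monomer mass from sequence.
_AVG_RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}


def monomer_mass_from_sequence(seq: str) -> float:
    """Average molar mass (kDa) of a one-letter-code protein sequence."""
    seq = seq.strip().upper()
    mass = sum(_AVG_RESIDUE_MASS[a] for a in seq) + 18.02  # + water
    return mass / 1000.0
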