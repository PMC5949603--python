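"""Binding analysis: amide-proton temperature-coefficient classification,
one-set-of-sites ITC, and 1:1 quadratic MST fits.

Temperature coefficients
------------------------
The temperature dependence -d(delta)/dT of an amide proton chemical
shift (ppb/K) reports on intramolecular hydrogen bonding: values below
4.0 indicate a fully H-bonded proton, 4.0-7.0 (inclusive) a partially
H-bonded one, and larger values a solvent-exposed proton.

ITC
---
The one-set-of-sites model describes n identical independent sites with
association constant Ka (1/M) and molar enthalpy dH (kcal/mol). The
bound complex after injection i follows the single-site quadratic
binding equation at the running cell concentrations; injection volumes
displace cell contents, handled by the Origin-style effective
concentration correction (1 - dV/2V0)/(1 + dV/2V0) (a naive-dilution
convention is available). Thermodynamics complete via
dG = dH - T dS = -R T ln Ka with R = 1.98 cal/(mol K).

MST
---
Fraction bound of a 1:1 complex at fixed labeled-protein concentration P
and total ligand L is the exact quadratic solution
FB = ((P + L + KD) - sqrt((P + L + KD)^2 - 4 P L)) / (2 P),
with the excess-ligand limit L / (L + KD) as P -> 0. The measured signal
interpolates linearly between free and bound plateaus.

Both fitters are exposed statsmodels-style: a model object built from
data whose ``fit()`` returns a results object carrying estimates,
standard errors, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R_GAS_KCAL",
    "classify_temp_coeff",
    "thermodynamics",
    "ITCExperiment",
    "Isotherm",
    "itc_model",
    "OneSiteITCModel",
    "ITCResults",
    "MSTSeries",
    "mst_model",
    "MSTBindingModel",
    "MSTResults",
    "dilution_series",
    "BindingFitResult",
]

# gas constant as used for the printed thermodynamics: 1.98 cal/(mol K)
R_GAS_KCAL = 1.98e-3  # kcal / (mol K)


def classify_temp_coeff(c: float) -> Literal["full", "partial", "none"]:
    """H-bond class from -d(delta)/dT in ppb/K.

    < 4.0 -> full; 4.0 .. 7.0 inclusive -> partial; > 7.0 -> none.
    Negative coefficients are legal and classify as full.
    """
    if not math.isfinite(c):
        raise ValueError("coefficient must be finite")
    if c < 4.0:
        return "full"
    if c <= 7.0:
        return "partial"
    return "none"


def thermodynamics(Ka: float, dH: float, T: float) -> Tuple[float, float]:
    """(dG, dS) from Ka (1/M) and dH (kcal/mol) at T (K).

    dG = -R T ln Ka in kcal/mol; dS = (dH - dG)/T in kcal/(mol K), so
    dG = dH - T dS holds identically.
    """
    if Ka <= 0 or T <= 0:
        raise ValueError("Ka and T must be positive")
    dG = -R_GAS_KCAL * T * math.log(Ka)
    dS = (dH - dG) / T
    return dG, dS


@dataclass(frozen=True)
class ITCExperiment:
    """Titration protocol: volumes in uL, syringe in mM, cell in uM."""

    cell_volume_uL: float = 200.0
    injection_volumes_uL: Tuple[float, ...] = (2.5,) * 15
    syringe_conc_mM: float = 0.7
    cell_conc_uM: float = 50.0
    temperature_K: float = 298.15

    def __post_init__(self):
        if self.cell_volume_uL <= 0 or self.syringe_conc_mM <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if self.cell_conc_uM <= 0 or not self.injection_volumes_uL:
            raise ValueError("need a positive cell concentration and >= 1 injection")
        if any(v <= 0 for v in self.injection_volumes_uL):
            raise ValueError("injection volumes must be positive")


@dataclass
class Isotherm:
    """Heat per injection (ucal) with the running syringe/cell molar ratio."""

    heats_ucal: np.ndarray
    molar_ratio: np.ndarray

    def __post_init__(self):
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        if self.heats_ucal.shape != self.molar_ratio.shape:
            raise ValueError("heats and molar ratios must have equal length")


def _effective_concentrations(
    e: ITCExperiment, convention: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Running total cell (M) and titrant (X) concentrations in mol/L
    after each injection."""
    V0 = e.cell_volume_uL * 1e-6  # L
    M0 = e.cell_conc_uM * 1e-6  # mol/L
    X0 = e.syringe_conc_mM * 1e-3  # mol/L
    inj = np.asarray(e.injection_volumes_uL, dtype=float) * 1e-6  # L
    dV = np.cumsum(inj)
    if convention == "displacement":
        # Origin-style: injected volume displaces fully mixed cell contents
        Mt = M0 * (1 - dV / (2 * V0)) / (1 + dV / (2 * V0))
        Xt = X0 * (dV / V0) / (1 + dV / (2 * V0))
    elif convention == "naive":
        Mt = M0 * V0 / (V0 + dV)
        Xt = X0 * dV / (V0 + dV)
    else:
        raise ValueError(f"unknown dilution convention {convention!r}")
    return Mt, Xt


def _bound_complex(n: float, Ka: float, Mt: np.ndarray, Xt: np.ndarray) -> np.ndarray:
    """[complex] from the single-site quadratic binding equation, with n
    identical sites per macromolecule."""
    sites = n * Mt
    s = sites + Xt + 1.0 / Ka
    disc = s * s - 4.0 * sites * Xt
    return 0.5 * (s - np.sqrt(np.maximum(disc, 0.0)))


def itc_model(
    n: float,
    Ka: float,
    dH: float,
    e: ITCExperiment,
    convention: str = "displacement",
) -> Isotherm:
    """Forward one-set-of-sites isotherm.

    Heat of injection i is the difference of cumulative binding heats
    Q(i) = [complex]_i * V0 * dH plus the displaced-volume correction
    (v_i/V0) * (Q(i) + Q(i-1))/2. Heats are returned in ucal.
    """
    if Ka <= 0:
        raise ValueError("Ka must be positive")
    if n <= 0:
        raise ValueError("site number must be positive")
    V0 = e.cell_volume_uL * 1e-6
    inj = np.asarray(e.injection_volumes_uL, dtype=float) * 1e-6
    Mt, Xt = _effective_concentrations(e, convention)
    mx = _bound_complex(n, Ka, Mt, Xt)
    Q = mx * V0 * dH  # kcal
    Qprev = np.concatenate([[0.0], Q[:-1]])
    if convention == "displacement":
        q = Q - Qprev + (inj / V0) * (Q + Qprev) / 2.0
    else:
        q = Q - Qprev
    ratio = Xt / Mt
    return Isotherm(heats_ucal=q * 1e9, molar_ratio=ratio)


@dataclass
class BindingFitResult:
    """Shared thermodynamic summary of a binding fit."""

    n: float
    Ka: float  # 1/M
    KD: float  # M
    dH: Optional[float]  # kcal/mol (None for MST)
    dG: Optional[float]
    dS: Optional[float]
    temperature_K: Optional[float]
    bse: Dict[str, float]
    residual_norm: float
    converged: bool
    warnings: List[str] = field(default_factory=list)


class OneSiteITCModel:
    """One-set-of-sites model for an observed isotherm.

    Parameters
    ----------
    isotherm : Isotherm
        Observed heats per injection (ucal).
    experiment : ITCExperiment
        The titration protocol that produced them.
    convention : str
        Cell-displacement handling, 'displacement' (Origin-style,
        default) or 'naive'.
    drop_first : bool
        Discard the first injection before fitting (common instrument
        practice for the first-injection anomaly; off by default).
    """

    param_names = ("n", "Ka", "dH")

    def __init__(
        self,
        isotherm: Isotherm,
        experiment: ITCExperiment,
        convention: str = "displacement",
        drop_first: bool = False,
    ):
        if len(isotherm.heats_ucal) != len(experiment.injection_volumes_uL):
            raise ValueError("isotherm length != number of injections")
        n_eff = len(isotherm.heats_ucal) - int(drop_first)
        if n_eff < 4:
            raise ValueError("need at least 4 informative injections")
        self.isotherm = isotherm
        self.experiment = experiment
        self.convention = convention
        self.drop_first = drop_first

    def predict(self, params: Sequence[float]) -> np.ndarray:
        n, Ka, dH = params
        return itc_model(n, Ka, dH, self.experiment, self.convention).heats_ucal

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        n, logKa, dH = x
        pred = self.predict((n, 10.0**logKa, dH))
        res = pred - self.isotherm.heats_ucal
        return res[1:] if self.drop_first else res

    def fit(self, start: Optional[Tuple[float, float, float]] = None) -> "ITCResults":
        heats = self.isotherm.heats_ucal
        if start is None:
            dH0 = float(heats[0]) / (
                self.experiment.injection_volumes_uL[0]
                * 1e-6
                * self.experiment.syringe_conc_mM
                * 1e-3
                * 1e9
            )
            start = (1.0, 1e6, dH0 if abs(dH0) > 1e-3 else -1.0)
        best = None
        # multistart over Ka decades guards against the flat tail of the
        # likelihood at very high / very low c values
        for logKa0 in dict.fromkeys(
            [math.log10(start[1])] + [3.0, 4.5, 6.0, 7.5, 9.0]
        ):
            sol = least_squares(
                self._residuals,
                x0=np.array([start[0], logKa0, start[2]]),
                bounds=([1e-3, 0.0, -1e4], [1e3, 12.0, 1e4]),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        return ITCResults(self, best)


class ITCResults:
    """Estimates, uncertainties and diagnostics of a one-site ITC fit."""

    def __init__(self, model: OneSiteITCModel, solution):
        self.model = model
        self._sol = solution
        n, logKa, dH = solution.x
        self.n = float(n)
        self.Ka = float(10.0**logKa)
        self.KD = 1.0 / self.Ka
        self.dH = float(dH)
        T = model.experiment.temperature_K
        self.temperature_K = T
        self.dG, self.dS = thermodynamics(self.Ka, self.dH, T)
        self.residual_norm = float(np.linalg.norm(solution.fun))
        self.converged = bool(solution.success)
        self.bse = self._standard_errors()
        self.warnings: List[str] = []
        c_value = self.n * self.Ka * model.experiment.cell_conc_uM * 1e-6
        self.c_value = c_value
        if not (1.0 <= c_value <= 1000.0):
            self.warnings.append(
                f"c = n*Ka*Mt = {c_value:.3g} outside ~1-1000; "
                "Ka is weakly determined by the isotherm shape"
            )
        if not self.converged:
            self.warnings.append("optimizer did not report convergence")

    def _standard_errors(self) -> Dict[str, float]:
        J = self._sol.jac
        m, p = J.shape
        dof = max(m - p, 1)
        s2 = 2.0 * self._sol.cost / dof
        try:
            cov = np.linalg.inv(J.T @ J) * s2
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
        # delta method: se(Ka) from se(log10 Ka)
        return {
            "n": float(se[0]),
            "Ka": float(se[1] * self.Ka * math.log(10.0)),
            "dH": float(se[2]),
        }

    def as_result(self) -> BindingFitResult:
        return BindingFitResult(
            n=self.n, Ka=self.Ka, KD=self.KD, dH=self.dH, dG=self.dG,
            dS=self.dS, temperature_K=self.temperature_K, bse=self.bse,
            residual_norm=self.residual_norm, converged=self.converged,
            warnings=list(self.warnings),
        )

    def summary(self) -> str:
        lines = [
            "One-set-of-sites ITC fit",
            "=" * 40,
            f"injections        {len(self.model.isotherm.heats_ucal):>12d}",
            f"T (K)             {self.temperature_K:>12.2f}",
            f"c value           {self.c_value:>12.3g}",
            "-" * 40,
            f"n                 {self.n:>12.4f} +/- {self.bse['n']:.2g}",
            f"Ka (1/M)          {self.Ka:>12.4g} +/- {self.bse['Ka']:.2g}",
            f"KD (uM)           {self.KD * 1e6:>12.4f}",
            f"dH (kcal/mol)     {self.dH:>12.4f} +/- {self.bse['dH']:.2g}",
            f"dG (kcal/mol)     {self.dG:>12.4f}",
            f"dS (cal/mol/K)    {self.dS * 1e3:>12.4f}",
            f"residual norm     {self.residual_norm:>12.4g}",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


@dataclass
class MSTSeries:
    """Dose-response series: total ligand (M), fixed labeled protein (M),
    normalized signal per point."""

    ligand_conc_M: np.ndarray
    protein_conc_M: float
    signal: np.ndarray

    def __post_init__(self):
        self.ligand_conc_M = np.asarray(self.ligand_conc_M, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ligand_conc_M.shape != self.signal.shape:
            raise ValueError("concentration and signal lengths disagree")


def mst_model(L: float, P: float, KD: float) -> float:
    """Fraction of protein bound for a 1:1 interaction (exact quadratic
    solution); P = 0 falls back to the excess-ligand limit L/(L+KD)."""
    if KD <= 0:
        raise ValueError("KD must be positive")
    if L < 0 or P < 0:
        raise ValueError("concentrations must be non-negative")
    if P == 0:
        return L / (L + KD)
    s = P + L + KD
    disc = s * s - 4.0 * P * L
    return (s - math.sqrt(max(disc, 0.0))) / (2.0 * P)


def dilution_series(
    top: float, factor: float = 2.0, levels: int = 15, mix: bool = False
) -> np.ndarray:
    """Serial dilution top/factor^k for k = 0..levels-1; ``mix`` applies a
    final 1:1 mixing step that halves every concentration."""
    if factor <= 1:
        raise ValueError("dilution factor must be > 1")
    if levels < 1:
        raise ValueError("need at least one level")
    series = top / factor ** np.arange(levels, dtype=float)
    return series / 2.0 if mix else series


class MSTBindingModel:
    """1:1 quadratic binding model for a dose-response series.

    ``fit()`` estimates (KD, S_free, S_bound) by least squares on the
    signal; KD is parameterized on a log scale.
    """

    param_names = ("KD", "s_free", "s_bound")

    def __init__(self, series: MSTSeries):
        if len(series.ligand_conc_M) < 6:
            raise ValueError("need >= 6 concentrations spanning the transition")
        self.series = series

    def predict(self, params: Sequence[float]) -> np.ndarray:
        KD, s_free, s_bound = params
        fb = np.array(
            [
                mst_model(L, self.series.protein_conc_M, KD)
                for L in self.series.ligand_conc_M
            ]
        )
        return s_free + (s_bound - s_free) * fb

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        logKD, s_free, s_bound = x
        return self.predict((10.0**logKD, s_free, s_bound)) - self.series.signal

    def fit(self, start_KD: Optional[float] = None) -> "MSTResults":
        sig = self.series.signal
        conc = self.series.ligand_conc_M
        if start_KD is None:
            # concentration at half signal change as a crude start
            mid = 0.5 * (np.nanmax(sig) + np.nanmin(sig))
            idx = int(np.argmin(np.abs(sig - mid)))
            start_KD = float(conc[idx]) if conc[idx] > 0 else float(np.median(conc))
        best = None
        for logKD0 in dict.fromkeys(
            [math.log10(start_KD), -7.0, -6.0, -5.0, -4.0]
        ):
            sol = least_squares(
                self._residuals,
                x0=np.array([logKD0, float(sig[np.argmin(conc)]), float(sig[np.argmax(conc)])]),
                bounds=([-12.0, -np.inf, -np.inf], [0.0, np.inf, np.inf]),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        return MSTResults(self, best)


class MSTResults:
    """Estimates and diagnostics of a 1:1 MST fit."""

    def __init__(self, model: MSTBindingModel, solution):
        self.model = model
        self._sol = solution
        logKD, s_free, s_bound = solution.x
        self.KD = float(10.0**logKD)
        self.Ka = 1.0 / self.KD
        self.s_free = float(s_free)
        self.s_bound = float(s_bound)
        self.residual_norm = float(np.linalg.norm(solution.fun))
        self.converged = bool(solution.success)
        self.bse = self._standard_errors()
        self.warnings: List[str] = []
        conc = model.series.ligand_conc_M
        amplitude = abs(self.s_bound - self.s_free)
        rms_sig = float(np.std(model.series.signal))
        if amplitude < 1e-12 or (rms_sig > 0 and amplitude < 0.1 * rms_sig):
            self.warnings.append("no transition detected (flat signal)")
        if not (conc.min() <= self.KD <= conc.max()):
            self.warnings.append(
                "fitted KD lies outside the measured concentration range; "
                "estimate unreliable"
            )
        self.reliable = not self.warnings

    def _standard_errors(self) -> Dict[str, float]:
        J = self._sol.jac
        m, p = J.shape
        dof = max(m - p, 1)
        s2 = 2.0 * self._sol.cost / dof
        try:
            cov = np.linalg.inv(J.T @ J) * s2
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
        return {
            "KD": float(se[0] * self.KD * math.log(10.0)),
            "s_free": float(se[1]),
            "s_bound": float(se[2]),
        }

    def as_result(self) -> BindingFitResult:
        return BindingFitResult(
            n=1.0, Ka=self.Ka, KD=self.KD, dH=None, dG=None, dS=None,
            temperature_K=None, bse=self.bse,
            residual_norm=self.residual_norm, converged=self.converged,
            warnings=list(self.warnings),
        )

    def summary(self) -> str:
        lines = [
            "1:1 quadratic MST fit",
            "=" * 40,
            f"points            {len(self.model.series.signal):>12d}",
            f"protein (nM)      {self.model.series.protein_conc_M * 1e9:>12.2f}",
            "-" * 40,
            f"KD (uM)           {self.KD * 1e6:>12.4f} +/- {self.bse['KD'] * 1e6:.2g}",
            f"S_free            {self.s_free:>12.4f} +/- {self.bse['s_free']:.2g}",
            f"S_bound           {self.s_bound:>12.4f} +/- {self.bse['s_bound']:.2g}",
            f"residual norm     {self.residual_norm:>12.4g}",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)
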