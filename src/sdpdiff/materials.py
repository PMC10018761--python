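"""Material descriptors: heat of adsorption, Young's modulus, polymer-water
distance, and the parametric moisture-content trend fits.

The integral heat of adsorption compares the enthalpy of the hydrated mixture
with dry polymer plus water vapor, per mole of water, referenced to liquid
water:

    Q_ad = (H_p + H_wv - H_c) / n_water - H_latent,   H_wv = 4 n_water R T

with the latent heat of water H_latent = 40.68 kJ/mol.  Enthalpies may be
supplied directly (kJ) or as per-frame thermodynamic series, in which case
H = <U> + <P V> (the time mean of the instantaneous PV product, keeping the
P-V covariance).

Young's modulus is the least-squares slope of the stress-strain curve in the
linear regime (strain <= 1% by default, matching a stepwise tensile protocol
of ~0.01% increments up to ~1% total strain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .trajectory import Box, StressStrainTable, ThermoSeries

__all__ = [
    "GAS_CONSTANT_KJ",
    "H_LATENT_WATER",
    "BAR_NM3_TO_KJ_MOL",
    "EnthalpyInputs",
    "MaterialRecord",
    "YoungModulusFit",
    "PolymerWaterDistance",
    "TrendFit",
    "TrendFitError",
    "TREND_FORMS",
    "heat_of_adsorption",
    "enthalpy_from_thermo",
    "young_modulus",
    "polymer_water_distance",
    "fit_property_trends",
    "records_to_frame",
]

#: molar gas constant in kJ mol^-1 K^-1
GAS_CONSTANT_KJ = constants.R / 1000.0
#: latent heat of vaporization of water at ambient conditions, kJ mol^-1
H_LATENT_WATER = 40.68
#: 1 bar * 1 nm^3, expressed in kJ/mol (per Avogadro number of boxes)
BAR_NM3_TO_KJ_MOL = 1e5 * 1e-27 * constants.N_A / 1000.0


@dataclass
class EnthalpyInputs:
    """Inputs of the heat-of-adsorption formula.

    H_p, H_c : enthalpy of the dry polymer and of the polymer-water mixture
        (kJ, on the same molar bookkeeping as the MD energies).
    n_water : amount of adsorbed water, mol.
    T : temperature, K.
    H_latent : latent heat of water, kJ/mol (liquid-water reference state).
    """

    H_p: float
    H_c: float
    n_water: float
    T: float
    H_latent: float = H_LATENT_WATER

    def __post_init__(self) -> None:
        if self.n_water <= 0:
            raise ValueError("n_water must be positive")
        if self.T <= 0:
            raise ValueError("temperature must be positive")


def heat_of_adsorption(inputs: EnthalpyInputs) -> float:
    """Integral heat of adsorption Q_ad in kJ per mole of water.

    With zero net binding (H_c = H_p + H_wv) this returns -H_latent: relative
    to liquid water, unbound vapor-like water costs the latent heat.
    """
    H_wv = 4.0 * inputs.n_water * GAS_CONSTANT_KJ * inputs.T
    return (inputs.H_p + H_wv - inputs.H_c) / inputs.n_water - inputs.H_latent


def enthalpy_from_thermo(series: ThermoSeries) -> float:
    """H = <U> + <P V> in kJ/mol; the PV time average keeps the P-V covariance."""
    return float(np.mean(series.U) + np.mean(series.P * series.V) * BAR_NM3_TO_KJ_MOL)


@dataclass
class YoungModulusFit:
    E: float              # GPa
    intercept: float      # GPa
    stderr: float         # GPa, standard error of the slope
    n_points: int

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * self.stderr
        return (self.E - half, self.E + half)


def young_modulus(
    table: StressStrainTable, linear_max_strain: float = 0.01
) -> YoungModulusFit:
    """Least-squares slope (GPa) of stress vs strain in the linear regime."""
    mask = table.strain <= linear_max_strain
    if mask.sum() < 3:
        raise ValueError(
            f"need at least 3 points with strain <= {linear_max_strain}, got {int(mask.sum())}"
        )
    x, y = table.strain[mask], table.stress[mask]
    fit = linregress(x, y)
    return YoungModulusFit(
        E=float(fit.slope),
        intercept=float(fit.intercept),
        stderr=float(fit.stderr) if np.isfinite(fit.stderr) else 0.0,
        n_points=int(mask.sum()),
    )


@dataclass
class PolymerWaterDistance:
    d_pw: float       # mean nearest-polymer distance over all waters, nm
    d_pw_w: float     # over waiting-labelled waters (NaN if none)
    d_pw_m: float     # over moving-labelled waters (NaN if none)
    per_water: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def polymer_water_distance(
    water_positions: np.ndarray,
    polymer_positions: np.ndarray,
    box: Box | np.ndarray,
    labels: np.ndarray | None = None,
) -> PolymerWaterDistance:
    """Per-water distance to the nearest polymer atom (minimum image), averaged
    over all waters and, when waiting/moving ``labels`` are given, per state.

    Labels follow the segmentation convention: 0 = waiting, 1 = moving.
    """
    water_positions = np.asarray(water_positions, dtype=float)
    polymer_positions = np.asarray(polymer_positions, dtype=float)
    if len(water_positions) == 0 or len(polymer_positions) == 0:
        raise ValueError("need at least one water and one polymer site")
    L = box.lengths if isinstance(box, Box) else np.asarray(box, dtype=float)
    wp = water_positions - np.floor(water_positions / L) * L
    pp = polymer_positions - np.floor(polymer_positions / L) * L
    wp = np.where(wp >= L, 0.0, wp)
    pp = np.where(pp >= L, 0.0, pp)
    tree = cKDTree(pp, boxsize=L)
    dists, _ = tree.query(wp, k=1)
    d_pw = float(dists.mean())
    d_w = d_m = float("nan")
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != (len(wp),):
            raise ValueError("labels must have one entry per water site")
        if (labels == 0).any():
            d_w = float(dists[labels == 0].mean())
        if (labels == 1).any():
            d_m = float(dists[labels == 1].mean())
    return PolymerWaterDistance(d_pw=d_pw, d_pw_w=d_w, d_pw_m=d_m, per_water=dists)


@dataclass
class MaterialRecord:
    """One material/moisture state: everything the SDP model consumes."""

    label: str
    m: float                  # moisture content, g water / g dry polymer
    Q_ad: float               # kJ/mol
    E: float                  # GPa
    p_p: float                # percolation probability
    D_mu: float               # nm^2/ns
    d_pw: float = float("nan")
    d_pw_w: float = float("nan")
    d_pw_m: float = float("nan")

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("moisture content must be non-negative")
        if self.E < 0:
            raise ValueError("Young's modulus must be non-negative")
        if not 0 <= self.p_p <= 1:
            raise ValueError("percolation probability must lie in [0, 1]")


def records_to_frame(records) -> pd.DataFrame:
    """Normalize a list of MaterialRecord (or a DataFrame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# moisture-content trend fits
# ---------------------------------------------------------------------------

class TrendFitError(RuntimeError):
    pass


def _form_d_pw(m, a, b, c):
    return np.power(m - a, b) + c


def _form_p_p(m, a, b):
    return 1.0 / (np.exp(-a * m + b) + 1.0)


def _form_q_ad(m, a, b, c):
    return a * np.exp(-b * m) + c


def _form_e(m, a, b):
    return a * np.power(1.0 + m, b)


#: parametric forms of each material property as a function of moisture content
TREND_FORMS = {
    "d_pw": (_form_d_pw, ("a", "b", "c"), "d_pw = (m - a)^b + c"),
    "p_p": (_form_p_p, ("a", "b"), "p_p = 1 / (exp(-a m + b) + 1)"),
    "Q_ad": (_form_q_ad, ("a", "b", "c"), "Q_ad = a exp(-b m) + c"),
    "E": (_form_e, ("a", "b"), "E = a (1 + m)^b"),
}


@dataclass
class TrendFit:
    property: str
    formula: str
    params: dict
    residual_norm: float
    n_points: int

    def predict(self, m) -> np.ndarray:
        func = TREND_FORMS[self.property][0]
        return func(np.asarray(m, dtype=float), *self.params.values())


def _initial_guesses(prop: str, m: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Data-driven starting points, plus deterministic perturbations."""
    guesses: list[np.ndarray] = []
    if prop == "d_pw":
        c0 = y.min() - 0.1 * max(np.ptp(y), 1e-3)
        base = np.array([m.min() - 0.05, 0.5, c0])
        for da in (0.0, -0.05, -0.2, -0.5, -1.0):
            g = base.copy()
            g[0] = m.min() - 0.05 + da
            guesses.append(g)
    elif prop == "p_p":
        yc = np.clip(y, 1e-9, 1 - 1e-9)
        logit = np.log(yc / (1 - yc))
        if np.ptp(m) > 0 and np.ptp(logit) > 0:
            slope, intercept = np.polyfit(m, logit, 1)
        else:
            slope, intercept = 10.0, 3.0
        base = np.array([slope, -intercept])
        for s in (1.0, 0.5, 2.0, 0.25, 4.0):
            guesses.append(base * s)
    elif prop == "Q_ad":
        c0 = y.min()
        a0 = max(y.max() - c0, 1e-6)
        span = np.ptp(m) if np.ptp(m) > 0 else 1.0
        for b0 in (1.0 / span, 3.0 / span, 8.0 / span, 0.3 / span, 20.0 / span):
            guesses.append(np.array([a0, b0, c0]))
    elif prop == "E":
        yc = np.clip(y, 1e-12, None)
        slope, intercept = np.polyfit(np.log1p(m), np.log(yc), 1)
        base = np.array([np.exp(intercept), slope])
        for s in (1.0, 0.8, 1.2, 0.5, 2.0):
            g = base.copy()
            g[0] *= s
            guesses.append(g)
    return guesses


def fit_property_trends(records, prop: str, max_iter: int = 20000) -> TrendFit:
    """Nonlinear least-squares fit of a property's moisture-content trend.

    ``records`` is a MaterialRecord list/DataFrame with columns ``m`` and the
    property; ``prop`` is one of d_pw, p_p, Q_ad, E.  Fits run from several
    deterministic starting points and the lowest-residual solution wins.
    """
    if prop not in TREND_FORMS:
        raise ValueError(f"property must be one of {sorted(TREND_FORMS)}, got {prop!r}")
    df = records_to_frame(records)
    if prop not in df.columns or "m" not in df.columns:
        raise ValueError(f"records lack columns 'm' and {prop!r}")
    sub = df[["m", prop]].dropna().sort_values("m")
    m = sub["m"].to_numpy(dtype=float)
    y = sub[prop].to_numpy(dtype=float)
    if len(m) < 4:
        raise TrendFitError(f"need at least 4 records, got {len(m)}")
    func, names, formula = TREND_FORMS[prop]
    if np.ptp(y) == 0:
        raise TrendFitError(
            f"constant {prop} series: the {formula} form is unidentifiable"
        )
    bounds = (-np.inf, np.inf)
    if prop == "d_pw":
        # keep the power-law base positive over the data range
        lo = np.full(3, -np.inf)
        hi = np.full(3, np.inf)
        hi[0] = m.min() - 1e-9
        bounds = (lo, hi)
    best = None
    errors = []
    for guess in _initial_guesses(prop, m, y):
        if prop == "d_pw":
            guess = np.minimum(guess, [m.min() - 1e-6, np.inf, np.inf])
        try:
            with np.errstate(all="ignore"):
                popt, _ = curve_fit(
                    func, m, y, p0=guess, maxfev=max_iter, bounds=bounds,
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            resid = float(np.linalg.norm(func(m, *popt) - y))
            if np.all(np.isfinite(popt)) and (best is None or resid < best[1]):
                best = (popt, resid)
        except (RuntimeError, ValueError) as exc:  # non-convergence for this start
            errors.append(str(exc))
    if best is None:
        raise TrendFitError(
            f"trend fit for {prop} did not converge from any starting point: {errors[-1] if errors else 'no valid start'}"
        )
    popt, resid = best
    scale = float(np.linalg.norm(y - y.mean()))
    if scale > 0 and resid > max(0.5 * scale, 1e-8):
        # residual comparable to total variation: the form does not describe the data
        raise TrendFitError(
            f"trend fit for {prop} failed to describe the data "
            f"(residual {resid:.3g} vs signal {scale:.3g})"
        )
    return TrendFit(
        property=prop,
        formula=formula,
        params=dict(zip(names, map(float, popt))),
        residual_norm=resid,
        n_points=len(m),
    )
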