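"""Biophysical models for CCPO folding and stability measurements.

Forward models and nonlinear fits for

* stopped-flow FRET refolding traces: single-exponential folding phase
  with a linear drift, ``y(t) = a exp(-k t) + b t + c``;
* chemical (Gdn-HCl) denaturation of FRET-labelled cages: a two-state
  sigmoid with a sloped folded baseline,
  ``FRET([G]) = B + C (1 + D [G]) / (1 + exp(-(dG_fold - m [G]) / RT))``;
* helical content from mean residue ellipticity at 222 nm;
* thermal denaturation followed by CD at 222 nm: two-state (folded
  fraction ``alpha_f(T) = K / (1 + K)``, ``K = exp(-dH (1 - T/Tm) / RT)``)
  and three-state (U <-> I <-> F with equilibrium constants ``K_i``,
  ``K_f`` of the same van 't Hoff form and the intermediate contributing
  half the folded CD signal), with linear folded/unfolded baselines
  fitted jointly;
* native-contact formation order from per-CC contact-fraction time
  series (a CC counts as formed when >= 50 % of its native contacts are
  present).

Conventions: temperatures are kelvin internally and degrees Celsius at
all user-facing interfaces; energies are kJ/mol; folding enthalpies are
negative; ``dG_fold`` is positive for a protein folded in the absence of
denaturant and crosses zero at the midpoint ``dG_fold / m``.  All
synthetic generators use additive Gaussian noise scaled to the clean
signal range and are deterministic for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

from ccpo.errors import FitError, SchemaError

R_GAS = 8.314462618e-3  # kJ / (mol K)
T_ZERO_C = 273.15
MRE_HELIX_222 = -39_500.0  # deg cm^2 dmol^-1, infinitely long helix

#: Reference study conditions for synthetic data and recovery ensembles.
#: Rates/midpoints mirror the measured cage values (refolding rates in the
#: 14-60 1/s range, chemical midpoint 2.5 M Gdn-HCl, melting midpoints at
#: 44-56 deg C); enthalpies are realistic van 't Hoff magnitudes for
#: multi-CC transitions; sampling follows the measurement protocols
#: (1 ms stopped-flow sampling, 1 deg C melt increments, three averaged
#: technical replicates).  Noise is Gaussian with sd equal to
#: ``noise_fraction`` of the clean signal range per replicate.
REFERENCE_CONDITIONS = {
    "kinetics": {"k": 24.0, "a": 1.0, "b": 0.05, "c": 0.2,
                 "t_max_s": 0.5, "dt_s": 0.001},
    "chem_denaturation": {"dG_fold": 25.0, "m": 10.0, "B": 0.2, "C": 1.0,
                          "D": 0.05, "conc_max_M": 5.0, "dconc_M": 0.1},
    "melt_two_state": {"dH": -250.0, "Tm_C": 56.0,
                       "f0": -33000.0, "f1": 30.0, "u0": -15000.0, "u1": 25.0},
    "melt_three_state": {"dH_i": -300.0, "Tm1_C": 57.5, "dH_f": -300.0,
                         "Tm2_C": 44.0,
                         "f0": -33000.0, "f1": 30.0, "u0": -15000.0, "u1": 25.0},
    "noise_fraction": 0.05,
    "n_replicates": 3,
}


def celsius_to_kelvin(t_C):
    return np.asarray(t_C, dtype=float) + T_ZERO_C


def kelvin_to_celsius(t_K):
    return np.asarray(t_K, dtype=float) - T_ZERO_C


# ---------------------------------------------------------------------------
# stopped-flow kinetics


@dataclass
class KineticTrace:
    """Stopped-flow FRET refolding trace."""

    time_s: np.ndarray
    signal: np.ndarray
    denaturant_M: Optional[float] = None
    dead_time_s: Optional[float] = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.signal.shape:
            raise SchemaError("time and signal must be 1-D arrays of equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise SchemaError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.time_s)) and np.all(np.isfinite(self.signal))):
            raise SchemaError("non-finite values in kinetic trace")

    @classmethod
    def from_csv(cls, path, **meta) -> "KineticTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["signal"].to_numpy(), **meta)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "signal": self.signal}).to_csv(
            path, index=False
        )


@dataclass
class KineticFit:
    """Two-state refolding fit: rate k, amplitude a, drift b, background c."""

    k: float
    a: float
    b: float
    c: float
    stderr: dict
    rss: float
    rmsd: float
    n_points: int
    result: lmfit.model.ModelResult = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "k_per_s": self.k,
            "a": self.a,
            "b_per_s": self.b,
            "c": self.c,
            "stderr": self.stderr,
            "rss": self.rss,
            "rmsd": self.rmsd,
            "n_points": self.n_points,
        }


def kinetic_model(t, k, a, b, c):
    """Single-exponential folding phase plus linear drift."""
    t = np.asarray(t, dtype=float)
    return a * np.exp(-k * t) + b * t + c


def simulate_kinetic_trace(
    k: float,
    a: float,
    b: float,
    c: float,
    time_s: Sequence[float],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    n_replicates: int = 1,
    **meta,
) -> KineticTrace:
    """Synthetic stopped-flow trace; ``noise_sd`` is the absolute Gaussian
    standard deviation of a single shot, and ``n_replicates`` independent
    noisy shots are averaged (measured traces are replicate averages)."""
    if k <= 0:
        raise SchemaError("folding rate k must be positive")
    t = np.asarray(time_s, dtype=float)
    y = kinetic_model(t, k, a, b, c)
    y = _add_noise(y, noise_sd, seed, n_replicates)
    return KineticTrace(t, y, **meta)


def _add_noise(y, noise_sd, seed, n_replicates=1):
    if not noise_sd:
        return y
    rng = np.random.default_rng(seed)
    shots = y[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, y.size))
    return shots.mean(axis=0)


def fit_kinetics(trace: KineticTrace) -> KineticFit:
    """Nonlinear least squares of the two-state kinetic model.

    Initialization: background from the tail mean, drift from the tail
    slope, amplitude from the early-minus-tail signal, and the rate from
    a log-linear regression of the drift-corrected early phase.
    """
    t, y = trace.time_s, trace.signal
    if len(t) < 5:
        raise SchemaError("kinetic fit needs at least 5 points")
    n_tail = max(len(t) // 4, 2)
    tail_t, tail_y = t[-n_tail:], y[-n_tail:]
    b0 = np.polyfit(tail_t, tail_y, 1)[0]
    c0 = float(np.mean(tail_y) - b0 * np.mean(tail_t))
    a0 = float(y[0] - (b0 * t[0] + c0))
    if a0 == 0.0:
        a0 = float(np.ptp(y)) or 1.0
    k0 = _rate_guess(t, y, a0, b0, c0)
    span = t[-1] - t[0]
    model = lmfit.Model(kinetic_model)
    params = model.make_params(k=k0, a=a0, b=b0, c=c0)
    params["k"].set(min=1e-12)
    result = model.fit(y, params, t=t)
    if not result.success or result.params["k"].value <= 0:
        raise FitError(
            f"kinetic fit failed (init k={k0:.3g}, a={a0:.3g}, b={b0:.3g}, c={c0:.3g})"
        )
    if span * result.params["k"].value < 1.0:
        warnings.warn(
            "time span is shorter than ~1/k; rate may be poorly identifiable",
            stacklevel=2,
        )
    resid = result.residual
    return KineticFit(
        k=result.params["k"].value,
        a=result.params["a"].value,
        b=result.params["b"].value,
        c=result.params["c"].value,
        stderr={p: (result.params[p].stderr or float("nan")) for p in result.params},
        rss=float(np.sum(resid**2)),
        rmsd=float(np.sqrt(np.mean(resid**2))),
        n_points=len(t),
        result=result,
    )


def _rate_guess(t, y, a0, b0, c0) -> float:
    resid = y - (b0 * t + c0)
    if a0 < 0:
        resid = -resid
    mask = resid > max(abs(a0) * 0.05, 1e-12)
    if mask.sum() >= 3:
        coef = np.polyfit(t[mask], np.log(resid[mask]), 1)
        if coef[0] < 0:
            return -coef[0]
    # no resolvable decay phase: assume the span covers less than half a
    # lifetime (also triggers the identifiability warning)
    return 0.5 / max(t[-1] - t[0], 1e-9)


# ---------------------------------------------------------------------------
# chemical denaturation


@dataclass
class ChemDenatCurve:
    """FRET intensity versus denaturant concentration."""

    conc_M: np.ndarray
    fret: np.ndarray
    temperature_K: float = 298.15

    def __post_init__(self):
        self.conc_M = np.asarray(self.conc_M, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        if self.conc_M.shape != self.fret.shape:
            raise SchemaError("concentration and FRET must have equal length")

    @classmethod
    def from_csv(cls, path, **meta) -> "ChemDenatCurve":
        df = pd.read_csv(path)
        return cls(df["gdnhcl_M"].to_numpy(), df["fret"].to_numpy(), **meta)

    def to_csv(self, path) -> None:
        pd.DataFrame({"gdnhcl_M": self.conc_M, "fret": self.fret}).to_csv(
            path, index=False
        )


@dataclass
class ChemDenatFit:
    dG_fold: float  # kJ/mol
    m: float  # kJ/mol/M
    B: float
    C: float
    D: float
    midpoint_M: float
    stderr: dict
    rmsd: float
    midpoint_in_range: bool
    result: lmfit.model.ModelResult = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "dG_fold_kJ_mol": self.dG_fold,
            "m_kJ_mol_M": self.m,
            "B": self.B,
            "C": self.C,
            "D": self.D,
            "midpoint_M": self.midpoint_M,
            "midpoint_in_range": self.midpoint_in_range,
            "stderr": self.stderr,
            "rmsd": self.rmsd,
        }


def chem_denat_model(conc_M, dG_fold, m, B, C, D, temperature_K=298.15):
    """Two-state FRET denaturation with a sloped folded baseline.

    The sigmoid factor equals 1/2 at the midpoint ``[G] = dG_fold / m``;
    with ``dG_fold > 0`` and ``m > 0`` the protein is folded (high FRET)
    at low denaturant.
    """
    g = np.asarray(conc_M, dtype=float)
    rt = R_GAS * temperature_K
    frac = 1.0 / (1.0 + np.exp(-(dG_fold - m * g) / rt))
    return B + C * (1.0 + D * g) * frac


def simulate_chem_denaturation(
    dG_fold: float,
    m: float,
    B: float,
    C: float,
    D: float,
    conc_M: Sequence[float],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    n_replicates: int = 1,
    temperature_K: float = 298.15,
) -> ChemDenatCurve:
    g = np.asarray(conc_M, dtype=float)
    y = chem_denat_model(g, dG_fold, m, B, C, D, temperature_K)
    y = _add_noise(y, noise_sd, seed, n_replicates)
    return ChemDenatCurve(g, y, temperature_K=temperature_K)


def fit_chem_denaturation(curve: ChemDenatCurve) -> ChemDenatFit:
    """Least-squares fit of the two-state chemical-denaturation model."""
    g, y = curve.conc_M, curve.fret
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi - lo < 1e-12 or len(g) < 6:
        raise FitError("curve has no transition to fit")
    norm = (y - lo) / (hi - lo)
    # midpoint guess: concentration where the normalized signal crosses 1/2
    order = np.argsort(g)
    crossings = np.where(np.diff(norm[order] > 0.5))[0]
    mid0 = float(g[order][crossings[0]]) if len(crossings) else float(np.median(g))
    if len(crossings) == 0:
        warnings.warn("no transition midpoint inside measured range", stacklevel=2)
    m0 = 10.0
    model = lmfit.Model(
        chem_denat_model, independent_vars=["conc_M", "temperature_K"]
    )
    params = model.make_params(
        dG_fold=m0 * mid0, m=m0, B=lo, C=hi - lo, D=0.0
    )
    params["m"].set(min=1e-6)
    result = model.fit(y, params, conc_M=g, temperature_K=curve.temperature_K)
    if not result.success:
        raise FitError("chemical denaturation fit did not converge")
    dg = result.params["dG_fold"].value
    m = result.params["m"].value
    midpoint = dg / m
    in_range = bool(np.min(g) <= midpoint <= np.max(g))
    if not in_range:
        warnings.warn(
            f"fitted midpoint {midpoint:.2f} M outside measured range", stacklevel=2
        )
    resid = result.residual
    return ChemDenatFit(
        dG_fold=dg,
        m=m,
        B=result.params["B"].value,
        C=result.params["C"].value,
        D=result.params["D"].value,
        midpoint_M=midpoint,
        stderr={p: (result.params[p].stderr or float("nan")) for p in result.params},
        rmsd=float(np.sqrt(np.mean(resid**2))),
        midpoint_in_range=in_range,
        result=result,
    )


# ---------------------------------------------------------------------------
# helicity


def helical_content(mre222: float, n_residues: int) -> float:
    """Percent helicity from mean residue ellipticity at 222 nm.

    ``100 * MRE222 / (MRE_H * (1 - 2.57 / n))`` with the infinite-helix
    limit ``MRE_H = -39,500 deg cm^2 dmol^-1``.  Values above 100 % are
    returned as computed (and flagged with a warning).
    """
    if n_residues <= 2.57:
        raise SchemaError("chain length must exceed 2.57 residues")
    pct = 100.0 * mre222 / (MRE_HELIX_222 * (1.0 - 2.57 / n_residues))
    if pct > 100.0:
        warnings.warn(f"helical content {pct:.1f}% exceeds 100%", stacklevel=2)
    return pct


# ---------------------------------------------------------------------------
# thermal denaturation


@dataclass
class ThermalCurve:
    """CD melt: mean residue ellipticity at 222 nm versus temperature."""

    temperature_K: np.ndarray
    mre222: np.ndarray

    def __post_init__(self):
        self.temperature_K = np.asarray(self.temperature_K, dtype=float)
        self.mre222 = np.asarray(self.mre222, dtype=float)
        if self.temperature_K.shape != self.mre222.shape:
            raise SchemaError("temperature and MRE must have equal length")
        if np.any(self.temperature_K <= 0):
            raise SchemaError("temperatures must be positive kelvin")

    @classmethod
    def from_celsius(cls, temp_C, mre222) -> "ThermalCurve":
        return cls(celsius_to_kelvin(temp_C), mre222)

    @classmethod
    def from_csv(cls, path) -> "ThermalCurve":
        df = pd.read_csv(path)
        return cls.from_celsius(df["temp_C"].to_numpy(), df["mre222"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"temp_C": kelvin_to_celsius(self.temperature_K), "mre222": self.mre222}
        ).to_csv(path, index=False)


def alpha_f_two_state(T_K, dH, Tm_K):
    """Folded fraction of a two-state van 't Hoff transition.

    ``alpha_f = K / (1 + K)`` with ``K = exp(-dH (1 - T/Tm) / (R T))``;
    folding enthalpy ``dH`` is negative, so ``alpha_f -> 1`` below ``Tm``
    and equals exactly 1/2 at ``T = Tm``.
    """
    from scipy.special import expit

    T = np.asarray(T_K, dtype=float)
    # K / (1 + K) with K = exp(-x); expit avoids overflow for extreme dH
    x = dH * (1.0 - T / Tm_K) / (R_GAS * T)
    return expit(-x)


def mre_two_state(T_K, dH, Tm_K, f0, f1, u0, u1):
    """Two-state melt signal with linear folded/unfolded baselines."""
    T = np.asarray(T_K, dtype=float)
    af = alpha_f_two_state(T, dH, Tm_K)
    mre_f = f0 + f1 * T
    mre_u = u0 + u1 * T
    return mre_u + af * (mre_f - mre_u)


def three_state_populations(T_K, dH_i, Tm1_K, dH_f, Tm2_K):
    """(alpha_u, alpha_i, alpha_f) of the U <-> I <-> F scheme.

    ``K_i = [I]/[U]`` and ``K_f = [F]/[I]`` are van 't Hoff constants
    with midpoints ``Tm1`` and ``Tm2``; populations always sum to one.
    """
    from scipy.special import softmax

    T = np.asarray(T_K, dtype=float)
    log_ki = -dH_i * (1.0 - T / Tm1_K) / (R_GAS * T)
    log_kf = -dH_f * (1.0 - T / Tm2_K) / (R_GAS * T)
    # populations are a softmax over log-Boltzmann weights {0, ln K_i,
    # ln K_i + ln K_f}; evaluated jointly to stay finite for any dH
    logits = np.stack([np.zeros_like(T), log_ki, log_ki + log_kf])
    pops = softmax(logits, axis=0)
    return pops[0], pops[1], pops[2]


def mre_three_state(T_K, dH_i, Tm1_K, dH_f, Tm2_K, f0, f1, u0, u1):
    """Three-state melt signal: the intermediate carries half the folded
    CD signal (``alpha_f + 0.5 alpha_i`` between the linear baselines)."""
    T = np.asarray(T_K, dtype=float)
    _, ai, af = three_state_populations(T, dH_i, Tm1_K, dH_f, Tm2_K)
    mre_f = f0 + f1 * T
    mre_u = u0 + u1 * T
    return mre_u + (af + 0.5 * ai) * (mre_f - mre_u)


def simulate_thermal_curve(
    params: dict,
    temp_C: Sequence[float],
    model: str = "two-state",
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    n_replicates: int = 1,
) -> ThermalCurve:
    """Synthetic CD melt.  ``params`` uses deg C midpoints (``Tm_C`` or
    ``Tm1_C``/``Tm2_C``), kJ/mol enthalpies and baseline coefficients
    ``f0, f1, u0, u1`` (intercepts at 0 K, slopes per K)."""
    T = celsius_to_kelvin(temp_C)
    base = (params["f0"], params["f1"], params["u0"], params["u1"])
    if model == "two-state":
        y = mre_two_state(T, params["dH"], celsius_to_kelvin(params["Tm_C"]), *base)
    elif model == "three-state":
        y = mre_three_state(
            T,
            params["dH_i"],
            celsius_to_kelvin(params["Tm1_C"]),
            params["dH_f"],
            celsius_to_kelvin(params["Tm2_C"]),
            *base,
        )
    else:
        raise SchemaError(f"unknown melt model {model!r}")
    y = _add_noise(y, noise_sd, seed, n_replicates)
    return ThermalCurve(T, y)


@dataclass
class TwoStateThermalFit:
    dH: float  # kJ/mol, negative (folding)
    Tm_K: float
    baselines: dict  # f0, f1, u0, u1
    stderr: dict
    rmsd: float
    result: lmfit.model.ModelResult = field(repr=False, default=None)

    @property
    def Tm_C(self) -> float:
        return float(kelvin_to_celsius(self.Tm_K))

    def alpha_f(self, T_K):
        return alpha_f_two_state(T_K, self.dH, self.Tm_K)

    def to_dict(self) -> dict:
        return {
            "dH_kJ_mol": self.dH,
            "Tm_C": self.Tm_C,
            "baselines": self.baselines,
            "stderr": self.stderr,
            "rmsd": self.rmsd,
        }


@dataclass
class ThreeStateThermalFit:
    dH_i: float
    Tm1_K: float
    dH_f: float
    Tm2_K: float
    baselines: dict
    stderr: dict
    rmsd: float
    result: lmfit.model.ModelResult = field(repr=False, default=None)

    @property
    def Tm1_C(self) -> float:
        return float(kelvin_to_celsius(self.Tm1_K))

    @property
    def Tm2_C(self) -> float:
        return float(kelvin_to_celsius(self.Tm2_K))

    def populations(self, T_K):
        return three_state_populations(T_K, self.dH_i, self.Tm1_K, self.dH_f, self.Tm2_K)

    def to_dict(self) -> dict:
        return {
            "dH_i_kJ_mol": self.dH_i,
            "Tm1_C": self.Tm1_C,
            "dH_f_kJ_mol": self.dH_f,
            "Tm2_C": self.Tm2_C,
            "baselines": self.baselines,
            "stderr": self.stderr,
            "rmsd": self.rmsd,
        }


def _baseline_guesses(T, y):
    n = max(len(T) // 10, 3)
    f1, f0 = np.polyfit(T[:n], y[:n], 1)
    u1, u0 = np.polyfit(T[-n:], y[-n:], 1)
    return f0, f1, u0, u1


def _normalized_signal(T, y, f0, f1, u0, u1):
    mre_f = f0 + f1 * T
    mre_u = u0 + u1 * T
    denom = mre_f - mre_u
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    return (y - mre_u) / denom


def fit_thermal_two_state(curve: ThermalCurve) -> TwoStateThermalFit:
    """Joint fit of dH, Tm and linear baselines to a two-state CD melt.

    The midpoint is initialized where the baseline-normalized signal
    crosses 1/2 and the enthalpy from the 25-75 % transition width.
    """
    T, y = curve.temperature_K, curve.mre222
    f0, f1, u0, u1 = _baseline_guesses(T, y)
    norm = _normalized_signal(T, y, f0, f1, u0, u1)
    tm0 = _crossing(T, norm, 0.5) or float(np.median(T))
    dh0 = _width_enthalpy(T, norm, tm0)
    model = lmfit.Model(mre_two_state, independent_vars=["T_K"])
    params = model.make_params(dH=dh0, Tm_K=tm0, f0=f0, f1=f1, u0=u0, u1=u1)
    params["dH"].set(max=-1e-3)
    params["Tm_K"].set(min=150.0, max=500.0)
    result = model.fit(y, params, T_K=T)
    if not result.success:
        raise FitError("two-state thermal fit did not converge")
    resid = result.residual
    return TwoStateThermalFit(
        dH=result.params["dH"].value,
        Tm_K=result.params["Tm_K"].value,
        baselines={k: result.params[k].value for k in ("f0", "f1", "u0", "u1")},
        stderr={p: (result.params[p].stderr or float("nan")) for p in result.params},
        rmsd=float(np.sqrt(np.mean(resid**2))),
        result=result,
    )


def fit_thermal_three_state(curve: ThermalCurve) -> ThreeStateThermalFit:
    """Joint fit of the U <-> I <-> F melt with linear baselines.

    Midpoints are initialized where the normalized signal crosses 3/4
    (lower, F -> I) and 1/4 (upper, I -> U); indistinguishable
    transitions trigger an identifiability warning.
    """
    T, y = curve.temperature_K, curve.mre222
    f0, f1, u0, u1 = _baseline_guesses(T, y)
    norm = _normalized_signal(T, y, f0, f1, u0, u1)
    t_hi = _crossing(T, norm, 0.75) or float(np.percentile(T, 40))
    t_lo = _crossing(T, norm, 0.25) or float(np.percentile(T, 60))
    if t_lo - t_hi < 1.0:
        warnings.warn(
            "three-state transitions overlap; parameters may be degenerate",
            stacklevel=2,
        )
    model = lmfit.Model(mre_three_state, independent_vars=["T_K"])
    params = model.make_params(
        dH_i=-300.0, Tm1_K=t_lo, dH_f=-300.0, Tm2_K=t_hi, f0=f0, f1=f1, u0=u0, u1=u1
    )
    for name in ("dH_i", "dH_f"):
        params[name].set(min=-3000.0, max=-1e-3)
    for name in ("Tm1_K", "Tm2_K"):
        params[name].set(min=150.0, max=500.0)
    result = model.fit(y, params, T_K=T)
    if not result.success:
        raise FitError("three-state thermal fit did not converge")
    resid = result.residual
    return ThreeStateThermalFit(
        dH_i=result.params["dH_i"].value,
        Tm1_K=result.params["Tm1_K"].value,
        dH_f=result.params["dH_f"].value,
        Tm2_K=result.params["Tm2_K"].value,
        baselines={k: result.params[k].value for k in ("f0", "f1", "u0", "u1")},
        stderr={p: (result.params[p].stderr or float("nan")) for p in result.params},
        rmsd=float(np.sqrt(np.mean(resid**2))),
        result=result,
    )


def _crossing(T, norm, level) -> Optional[float]:
    above = norm > level
    idx = np.where(np.diff(above.astype(int)) != 0)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    x0, x1 = T[i], T[i + 1]
    y0, y1 = norm[i], norm[i + 1]
    if y1 == y0:
        return float(x0)
    return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))


def _width_enthalpy(T, norm, tm) -> float:
    t25 = _crossing(T, norm, 0.25)
    t75 = _crossing(T, norm, 0.75)
    if t25 and t75 and t25 > t75:
        width = t25 - t75
        # two-state van 't Hoff: alpha spans 0.75 -> 0.25 over ~ RTm^2 * 2 ln 3 / |dH|
        return -2.0 * np.log(3.0) * R_GAS * tm**2 / width
    return -300.0


# ---------------------------------------------------------------------------
# native-contact formation order


@dataclass
class ContactTraceSet:
    """Per-CC native-contact-fraction time series from folding
    trajectories."""

    time: np.ndarray
    fractions: dict  # CC name -> array in [0, 1]
    threshold: float = 0.5

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.fractions = {k: np.asarray(v, dtype=float) for k, v in self.fractions.items()}
        for name, frac in self.fractions.items():
            if frac.shape != self.time.shape:
                raise SchemaError(f"trace {name!r} length mismatch")
            if np.any((frac < -1e-9) | (frac > 1 + 1e-9)):
                raise SchemaError(f"trace {name!r} outside [0, 1]")
        if not self.fractions:
            raise SchemaError("contact trace set is empty")

    @classmethod
    def from_csv(cls, path, threshold: float = 0.5) -> "ContactTraceSet":
        df = pd.read_csv(path)
        time_col = df.columns[0]
        return cls(
            df[time_col].to_numpy(),
            {c: df[c].to_numpy() for c in df.columns[1:]},
            threshold=threshold,
        )


def formation_order(
    traces: ContactTraceSet,
    mode: str = "first-passage",
    sustain_window: int = 5,
) -> list[tuple]:
    """Order of CC formation from contact-fraction traces.

    A CC is formed at the first time its native-contact fraction reaches
    the threshold (default 50 %).  ``mode='sustained'`` instead requires
    the fraction to stay at or above threshold for ``sustain_window``
    consecutive samples (MD traces recross).  Returns ``(name, time)``
    sorted by formation time (ties keep both, NaN time marks unformed
    CCs, sorted last).
    """
    out = []
    thr = traces.threshold
    for name, frac in traces.fractions.items():
        hit = frac >= thr
        if mode == "first-passage":
            idx = np.where(hit)[0]
            t = float(traces.time[idx[0]]) if len(idx) else float("nan")
        elif mode == "sustained":
            t = float("nan")
            run = np.convolve(hit.astype(int), np.ones(sustain_window, dtype=int), "valid")
            idx = np.where(run == sustain_window)[0]
            if len(idx):
                t = float(traces.time[idx[0]])
        else:
            raise SchemaError(f"unknown formation-order mode {mode!r}")
        out.append((name, t))
    return sorted(out, key=lambda item: (np.isnan(item[1]), item[1], item[0]))


def simulate_contact_traces(
    formation_times: dict,
    time: Sequence[float],
    sharpness: float = 2.0,
    plateau: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    threshold: float = 0.5,
) -> ContactTraceSet:
    """Sigmoidal native-contact traces crossing ``threshold * plateau``
    at the requested formation times."""
    t = np.asarray(time, dtype=float)
    rng = np.random.default_rng(seed)
    fractions = {}
    for name, t_form in formation_times.items():
        if plateau > threshold:
            # shift the logistic so it crosses `threshold` exactly at t_form
            shift = t_form + np.log(plateau / threshold - 1.0) / sharpness
        else:
            shift = t_form  # never reaches threshold: an unformed CC
        clean = np.clip(plateau / (1.0 + np.exp(-sharpness * (t - shift))), 0.0, 1.0)
        if noise_sd:
            clean = np.clip(clean + rng.normal(0.0, noise_sd, size=t.shape), 0.0, 1.0)
        fractions[name] = clean
    return ContactTraceSet(t, fractions, threshold=threshold)
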