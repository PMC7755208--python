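"""SPR 1:1 Langmuir kinetics: simulation and linearization fitting.

Multi-cycle kinetics analysis for a 1:1 interaction.  Each
association-phase sensogram Γ(t) at analyte concentration C follows

    Γ(t) = Γ_eq · (1 − e^(−k_obs·t)),      k_obs = ka·C + kd,

rewritten for fitting as Γ(t) = c + a·e^(−b·t) with a < 0, c > 0 and
b = k_obs.  Per concentration the parameters (a, b, c) minimise

    χ² = Σ (Γ_fit − Γ_obs)² / (n − p),     p = 3,

by bounded Nelder–Mead (tolerance 1e-12, ≤1e6 iterations; bounds
a ∈ (−700, 0), b ∈ (1e-4, 1e-1) s⁻¹, c ∈ (0, 700) RU).  The fitted
k_obs values are regressed linearly on concentration: the slope is ka,
the intercept kd, and K_d = kd/ka.  Dispersion comes from N
leave-one-concentration-out refits: s = √(Σ(xᵢ − x̄)²/(N − 1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["Sensogram", "ExpFit", "KineticsEstimate", "simulate_sensogram",
           "double_reference", "fit_association", "kobs_regression",
           "jackknife_sd", "analyze_series",
           "A_BOUNDS", "B_BOUNDS", "C_BOUNDS"]

A_BOUNDS = (-7e2, 0.0)
B_BOUNDS = (1e-4, 1e-1)
C_BOUNDS = (0.0, 7e2)

#: default phases: 180 s association sampled at 5 Hz (900 points),
#: then 360 s dissociation
ASSOC_END = 180.0
DISSOC_END = 540.0


@dataclass
class Sensogram:
    """Time/response trace for one analyte concentration."""

    time: np.ndarray          # s, strictly increasing uniform grid
    response: np.ndarray      # RU
    concentration: float      # M
    assoc_start: float = 0.0
    assoc_end: float = ASSOC_END
    dissoc_end: float = DISSOC_END

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.response = np.asarray(self.response, float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.concentration < 0:
            raise ValueError("negative concentration")

    def association_phase(self) -> tuple[np.ndarray, np.ndarray]:
        m = (self.time >= self.assoc_start) & (self.time < self.assoc_end)
        return self.time[m] - self.assoc_start, self.response[m]


@dataclass
class ExpFit:
    """Γ(t) = c + a·e^(−b·t) fit of one association phase."""

    a: float   # RU, negative
    b: float   # s⁻¹ (= k_obs)
    c: float   # RU, positive
    chi2: float
    converged: bool = True
    at_boundary: bool = False

    @property
    def kobs(self) -> float:
        return self.b


@dataclass
class KineticsEstimate:
    ka: float        # M⁻¹ s⁻¹
    kd: float        # s⁻¹
    Kd: float        # M (= kd/ka exactly)
    sd_ka: float
    sd_kd: float
    sd_Kd: float
    fits: list[ExpFit] = field(default_factory=list)
    concentrations: list[float] = field(default_factory=list)

    @property
    def chi2(self) -> float:
        """Series-level χ²: mean of the per-concentration fit χ² values."""
        return float(np.mean([f.chi2 for f in self.fits])) if self.fits else np.nan


# ---------------------------------------------------------------------------
# Simulation


def default_grid(assoc_s: float = ASSOC_END, dissoc_s: float = 360.0,
                 hz: float = 5.0) -> np.ndarray:
    """Uniform time grid: 5 Hz sampling gives the canonical 900
    association points over 180 s."""
    dt = 1.0 / hz
    return np.arange(0.0, assoc_s + dissoc_s, dt)


def simulate_sensogram(ka: float, kd: float, rmax: float, conc: float,
                       time: np.ndarray | None = None,
                       noise_sd: float = 0.0,
                       seed: int | None = None) -> Sensogram:
    """Noisy (or noiseless) 1:1 sensogram at one analyte concentration.

    Association: R(t) = R_eq·(1 − e^(−k_obs·t)) with k_obs = ka·C + kd
    and R_eq = Rmax·C/(C + kd/ka); dissociation decays from the
    association end point with rate kd.  C = 0 produces a blank.
    """
    if ka <= 0 or kd <= 0 or rmax <= 0:
        raise ValueError("ka, kd and Rmax must be positive")
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = default_grid() if time is None else np.asarray(time, float)
    assoc_end = ASSOC_END
    resp = np.zeros_like(t)
    if conc > 0:
        kobs = ka * conc + kd
        req = rmax * conc / (conc + kd / ka)
        assoc = t < assoc_end
        resp[assoc] = req * (1.0 - np.exp(-kobs * t[assoc]))
        r_end = req * (1.0 - np.exp(-kobs * assoc_end))
        resp[~assoc] = r_end * np.exp(-kd * (t[~assoc] - assoc_end))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    return Sensogram(time=t, response=resp, concentration=conc,
                     assoc_end=assoc_end, dissoc_end=t[-1])


def double_reference(sample: Sensogram, reference: Sensogram,
                     blank: Sensogram) -> Sensogram:
    """Subtract reference-surface and zero-concentration traces."""
    for other in (reference, blank):
        if (other.time.shape != sample.time.shape
                or not np.allclose(other.time, sample.time)):
            raise ValueError("sensogram time grids are not aligned")
    return Sensogram(time=sample.time.copy(),
                     response=sample.response - reference.response - blank.response,
                     concentration=sample.concentration,
                     assoc_start=sample.assoc_start,
                     assoc_end=sample.assoc_end,
                     dissoc_end=sample.dissoc_end)


# ---------------------------------------------------------------------------
# Fitting


def _chi2(params: np.ndarray, t: np.ndarray, obs: np.ndarray, p: int = 3) -> float:
    a, b, c = params
    fit = c + a * np.exp(-b * t)
    return float(np.sum((fit - obs) ** 2) / (len(obs) - p))


def fit_association(s: Sensogram, tol: float = 1e-12,
                    max_iter: int = 1_000_000) -> ExpFit:
    """Fit Γ(t) = c + a·e^(−b·t) to the association phase.

    Bounded Nelder–Mead started from a₀ = −max(Γ), b₀ = √(b_lo·b_hi)
    (the geometric mean of the rate bounds), c₀ = max(Γ).
    """
    t, obs = s.association_phase()
    if len(t) < 10:
        raise ValueError("association phase needs at least 10 points")
    top = float(np.max(obs))
    top = max(top, 1e-6)  # flat-zero blanks still need a feasible start
    b0 = float(np.sqrt(B_BOUNDS[0] * B_BOUNDS[1]))
    x0 = np.array([-top, b0, top])
    bounds = [A_BOUNDS, B_BOUNDS, C_BOUNDS]
    res = minimize(_chi2, x0, args=(t, obs), method="Nelder-Mead",
                   bounds=bounds,
                   options={"xatol": tol, "fatol": tol,
                            "maxiter": max_iter, "maxfev": max_iter})
    a, b, c = res.x
    eps = 1e-10
    at_boundary = (a >= A_BOUNDS[1] - 1e-6 or a <= A_BOUNDS[0] + eps
                   or b <= B_BOUNDS[0] * (1 + 1e-9) or b >= B_BOUNDS[1] * (1 - 1e-9)
                   or c <= C_BOUNDS[0] + 1e-6 or c >= C_BOUNDS[1] - eps)
    if not res.success:
        warnings.warn("association fit did not converge within the "
                      "iteration cap", RuntimeWarning)
    return ExpFit(a=float(a), b=float(b), c=float(c), chi2=float(res.fun),
                  converged=bool(res.success), at_boundary=at_boundary)


def kobs_regression(concs, kobs) -> tuple[float, float]:
    """OLS of k_obs on concentration: returns (ka = slope, kd = intercept)."""
    c = np.asarray(concs, float)
    k = np.asarray(kobs, float)
    if len(c) < 2 or len(np.unique(c)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    slope, intercept = np.polyfit(c, k, 1)
    return float(slope), float(intercept)


def jackknife_sd(concs, kobs) -> tuple[float, float, float]:
    """Leave-one-concentration-out SDs of ka, kd and Kd.

    N refits each dropping one concentration; s = √(Σ(xᵢ−x̄)²/(N−1))
    over the N leave-one-out parameter values.
    """
    c = np.asarray(concs, float)
    k = np.asarray(kobs, float)
    n = len(c)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 concentrations")
    kas, kds, Kds = [], [], []
    for i in range(n):
        keep = np.arange(n) != i
        ka_i, kd_i = kobs_regression(c[keep], k[keep])
        kas.append(ka_i)
        kds.append(kd_i)
        Kds.append(kd_i / ka_i)
    sd = lambda x: float(np.std(x, ddof=1))
    return sd(kas), sd(kds), sd(Kds)


def write_sensogram_csv(s: Sensogram, path) -> None:
    """Persist as CSV: time_s, response_RU, concentration_M, phase."""
    import pandas as pd
    phase = np.where(s.time < s.assoc_end, "association", "dissociation")
    pd.DataFrame({"time_s": s.time, "response_RU": s.response,
                  "concentration_M": s.concentration,
                  "phase": phase}).to_csv(path, index=False)


def read_sensogram_csv(path) -> Sensogram:
    import pandas as pd
    df = pd.read_csv(path)
    required = {"time_s", "response_RU", "concentration_M", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    assoc = df[df["phase"] == "association"]
    assoc_end = float(assoc["time_s"].max()) + (
        float(np.diff(df["time_s"])[0]) if len(df) > 1 else 0.0)
    return Sensogram(time=df["time_s"].to_numpy(),
                     response=df["response_RU"].to_numpy(),
                     concentration=float(df["concentration_M"].iloc[0]),
                     assoc_end=assoc_end,
                     dissoc_end=float(df["time_s"].max()))


def analyze_series(sensograms: list[Sensogram]) -> KineticsEstimate:
    """Full linearization pipeline over a multi-cycle concentration series.

    Per-concentration exponential fits → k_obs list → linear regression
    on C → (ka, kd, Kd = kd/ka) → leave-one-out SDs.
    """
    non_blank = [s for s in sensograms if s.concentration > 0]
    if len(non_blank) < 3:
        raise ValueError("need at least 3 non-blank concentrations")
    non_blank.sort(key=lambda s: s.concentration)
    fits = [fit_association(s) for s in non_blank]
    concs = [s.concentration for s in non_blank]
    kobs = [f.kobs for f in fits]
    for f, c in zip(fits, concs):
        if f.at_boundary:
            warnings.warn(f"fit at C={c:g} M ended on a parameter bound",
                          RuntimeWarning)
    ka, kd = kobs_regression(concs, kobs)
    if kd < 0:
        warnings.warn("negative fitted dissociation rate (kd intercept); "
                      "reported as-is", RuntimeWarning)
    sd_ka, sd_kd, sd_Kd = jackknife_sd(concs, kobs)
    return KineticsEstimate(ka=ka, kd=kd, Kd=kd / ka,
                            sd_ka=sd_ka, sd_kd=sd_kd, sd_Kd=sd_Kd,
                            fits=fits, concentrations=concs)
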