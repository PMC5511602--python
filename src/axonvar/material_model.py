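"""Fiber-reinforced hyper-viscoelastic brain material at a material point.

The Gasser-Ogden-Holzapfel (GOH) strain-energy density per reference
volume is

    W = G/2 (I1~ - 3) + K ((J^2 - 1)/4 - ln(J)/2)
        + k1/k2 (exp(k2 <Ea~>^2) - 1),

with J = det F, C~ = J^(-2/3) F^T F the isochoric right Cauchy-Green
tensor, I1~ = tr C~, I4~ = n0 . C~ n0 the squared isochoric fiber stretch,
and the generalized fiber (axonal) strain

    Ea~ = k (I1~ - 3) + (1 - 3k) (I4~ - 1).

k in [0, 1/3] is the fiber dispersion parameter (1/3 = isotropic, 0 =
perfectly aligned); the Macaulay bracket <.> makes the fiber family
contribute in tension only; k2 -> 0 is evaluated through its analytic
limit k1 <Ea~>^2. The Cauchy stress is the exact derivative of W, split
into a volumetric part and a deviatorically projected isochoric part.
Viscoelasticity is quasi-linear: the isochoric second Piola-Kirchhoff
stress is convolved with a six-term Prony relaxation function
g(t) = M_inf + sum_i M_i exp(-t/tau_i) via the standard recursive
exponential update (piecewise-linear stress within a step); the
volumetric response stays elastic.

The axonal strain Ea~ is the injury metric: its peak over a deformation
history is the maximum axonal strain (MAS), compared against the maximum
principal Green-St. Venant strain (MPS), the largest eigenvalue of
E = (F^T F - I)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import DeformationHistory


@dataclass
class PronySeries:
    """Relative relaxation moduli M_i with times tau_i, plus M_inf.

    The partition of unity M_inf + sum M_i = 1 is enforced so that
    g(0) = 1 recovers the instantaneous hyperelastic stress.
    """

    moduli: np.ndarray
    taus: np.ndarray
    m_inf: float

    def __post_init__(self) -> None:
        self.moduli = np.asarray(self.moduli, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)
        if len(self.moduli) != len(self.taus):
            raise ValueError("moduli and taus must have equal length")
        if np.any(self.moduli < 0) or np.any(self.taus <= 0) or self.m_inf < 0:
            raise ValueError("Prony coefficients must be non-negative, taus positive")
        if abs(self.m_inf + self.moduli.sum() - 1.0) > 1e-8:
            raise ValueError("Prony series must satisfy M_inf + sum M_i = 1")

    def g(self, t: np.ndarray) -> np.ndarray:
        """Reduced relaxation function."""
        t = np.asarray(t, dtype=float)
        return self.m_inf + np.sum(
            self.moduli * np.exp(-t[..., None] / self.taus), axis=-1
        )


#: Six-term brain relaxation spectrum (relative moduli over 1e-6..1e-1 s).
BRAIN_PRONY = PronySeries(
    moduli=[0.7685, 0.1856, 0.0148, 0.0190, 0.0026, 0.0070],
    taus=[1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1],
    m_inf=0.0025,
)

ELASTIC = PronySeries(moduli=np.zeros(6), taus=np.full(6, 1.0), m_inf=1.0)


@dataclass
class MaterialParams:
    """GOH brain parameters: G, K in Pa, dispersion k, fiber k1 (Pa), k2."""

    G: float = 2990.0
    K: float = 50e6
    k: float = 0.0
    k1: float = 100.0
    k2: float = 0.0
    prony: PronySeries = field(default_factory=lambda: BRAIN_PRONY)

    def __post_init__(self) -> None:
        if self.G <= 0 or self.K <= 0:
            raise ValueError("G and K must be positive")
        if not 0.0 <= self.k <= 1.0 / 3.0 + 1e-12:
            raise ValueError("dispersion k must lie in [0, 1/3]")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")


@dataclass
class KinematicState:
    F: np.ndarray
    J: float
    C_iso: np.ndarray
    I1_iso: float
    I4_iso: float
    n0: np.ndarray


def kinematics(F: np.ndarray, n0: np.ndarray) -> KinematicState:
    """Isochoric invariants of a deformation gradient and fiber direction."""
    F = np.asarray(F, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise ValueError("det F must be positive")
    if abs(np.linalg.norm(n0) - 1.0) > 1e-6:
        raise ValueError("fiber direction must be a unit vector")
    C_iso = J ** (-2.0 / 3.0) * (F.T @ F)
    return KinematicState(
        F=F,
        J=J,
        C_iso=C_iso,
        I1_iso=float(np.trace(C_iso)),
        I4_iso=float(n0 @ C_iso @ n0),
        n0=n0,
    )


def axonal_strain(state: KinematicState, k: float) -> float:
    """Generalized fiber strain Ea~ = k (I1~ - 3) + (1 - 3k)(I4~ - 1)."""
    return k * (state.I1_iso - 3.0) + (1.0 - 3.0 * k) * (state.I4_iso - 1.0)


def _fiber_energy(Ea: float, k1: float, k2: float) -> float:
    e = max(Ea, 0.0)  # Macaulay bracket: tension only
    if k2 < 1e-8:
        return k1 * e**2  # analytic k2 -> 0 limit
    return k1 / k2 * (np.exp(k2 * e**2) - 1.0)


def _fiber_energy_derivative(Ea: float, k1: float, k2: float) -> float:
    """d(fiber energy)/d Ea~ with the tension-only bracket."""
    e = max(Ea, 0.0)
    if k2 < 1e-8:
        return 2.0 * k1 * e
    return 2.0 * k1 * e * np.exp(k2 * e**2)


def strain_energy(state: KinematicState, params: MaterialParams) -> float:
    """GOH strain energy per unit reference volume (Pa); W(I) = 0."""
    Ea = axonal_strain(state, params.k)
    W_iso = params.G / 2.0 * (state.I1_iso - 3.0)
    W_vol = params.K * ((state.J**2 - 1.0) / 4.0 - 0.5 * np.log(state.J))
    return float(W_iso + W_vol + _fiber_energy(Ea, params.k1, params.k2))


def _second_pk_split(
    state: KinematicState, params: MaterialParams
) -> tuple[np.ndarray, np.ndarray]:
    """Volumetric and isochoric second Piola-Kirchhoff stresses.

    With W = W_vol(J) + W_iso(I1~, I4~):
      S_vol = K (J^2 - 1)/2 C^{-1}
      S_iso = 2 J^{-2/3} [ w1 (I - I1~/3 C~^{-1} ... ) ] expressed via the
      deviatoric projection in the C~ metric.
    """
    C = state.F.T @ state.F
    C_inv = np.linalg.inv(C)
    J = state.J
    S_vol = params.K * (J**2 - 1.0) / 2.0 * C_inv

    Ea = axonal_strain(state, params.k)
    dpsi = _fiber_energy_derivative(Ea, params.k1, params.k2)
    w1 = params.G / 2.0 + dpsi * params.k  # dW/dI1~
    w4 = dpsi * (1.0 - 3.0 * params.k)  # dW/dI4~
    A = np.outer(state.n0, state.n0)
    S_iso = 2.0 * J ** (-2.0 / 3.0) * (
        w1 * (np.eye(3) - state.I1_iso / 3.0 * J ** (2.0 / 3.0) * C_inv)
        + w4 * (A - state.I4_iso / 3.0 * J ** (2.0 / 3.0) * C_inv)
    )
    return S_vol, S_iso


def cauchy_stress(state: KinematicState, params: MaterialParams) -> np.ndarray:
    """Instantaneous hyperelastic Cauchy stress sigma = J^{-1} F S F^T."""
    S_vol, S_iso = _second_pk_split(state, params)
    S = S_vol + S_iso
    sigma = state.F @ S @ state.F.T / state.J
    return 0.5 * (sigma + sigma.T)


def viscoelastic_stress(
    history: DeformationHistory, params: MaterialParams
) -> np.ndarray:
    """Cauchy stress time series with Prony relaxation on the isochoric part.

    Quasi-linear viscoelasticity: S_iso(t) = int g(t - s) dS_iso^e(s) with
    the recursive exponential update per step (exact for piecewise-linear
    S_iso^e); the volumetric stress remains elastic. With M_inf = 1 this
    reduces to the instantaneous hyperelastic stress at every step.
    """
    times, F_series = history.times, history.F
    n0 = history.fiber_dir0
    prony = params.prony
    n_terms = len(prony.moduli)

    states = [kinematics(F, n0) for F in F_series]
    splits = [_second_pk_split(s, params) for s in states]
    S_iso_e = np.array([iso for _vol, iso in splits])
    S_vol = np.array([vol for vol, _iso in splits])

    q = np.zeros((n_terms, 3, 3))
    sigma = np.empty((len(times), 3, 3))
    S_visc = prony.m_inf * S_iso_e[0] + S_iso_e[0] * prony.moduli.sum()
    sigma[0] = states[0].F @ (S_vol[0] + S_visc) @ states[0].F.T / states[0].J
    q[:] = prony.moduli[:, None, None] * S_iso_e[0]
    for n in range(1, len(times)):
        dt = times[n] - times[n - 1]
        dS = S_iso_e[n] - S_iso_e[n - 1]
        x = dt / prony.taus
        decay = np.exp(-x)
        # (1 - e^{-x})/x, stable for small x
        ramp = np.where(x > 1e-8, (1.0 - decay) / np.where(x > 1e-8, x, 1.0), 1.0 - x / 2.0)
        q = decay[:, None, None] * q + (prony.moduli * ramp)[:, None, None] * dS
        S_total = S_vol[n] + prony.m_inf * S_iso_e[n] + q.sum(axis=0)
        sig = states[n].F @ S_total @ states[n].F.T / states[n].J
        sigma[n] = 0.5 * (sig + sig.T)
    return sigma


@dataclass
class StrainTimeSeries:
    """Axonal and principal strain traces with their scalar peaks."""

    times: np.ndarray
    axonal_strain: np.ndarray
    principal_strain: np.ndarray
    cauchy_stress: np.ndarray  # (T, 3, 3) Pa
    mas: float  # peak axonal strain over time (clamped at 0)
    mps: float  # peak principal Green-St. Venant strain over time
    mas_clamped: bool = False


def evaluate_history(
    history: DeformationHistory,
    params: MaterialParams,
    fiber_dir: np.ndarray | None = None,
) -> StrainTimeSeries:
    """Strain and stress traces of a material point under prescribed F(t).

    Per step: the axonal strain Ea~, the largest eigenvalue of the
    Green-St. Venant strain E = (F^T F - I)/2, and the viscoelastic Cauchy
    stress. The scalar peaks MAS = max_t Ea~ and MPS = max_t lambda_max(E)
    are taken independent of their time of occurrence (worst case); a MAS
    that would be negative at all times is clamped to 0 and flagged.
    """
    n0 = history.fiber_dir0 if fiber_dir is None else np.asarray(fiber_dir, dtype=float)
    hist = DeformationHistory(times=history.times, F=history.F, fiber_dir0=n0)
    axial = np.array([axonal_strain(kinematics(F, n0), params.k) for F in hist.F])
    E = 0.5 * (np.einsum("tji,tjk->tik", hist.F, hist.F) - np.eye(3))
    principal = np.linalg.eigvalsh(E)[:, -1]
    sigma = viscoelastic_stress(hist, params)
    mas_raw = float(axial.max())
    clamped = mas_raw < 0.0
    return StrainTimeSeries(
        times=hist.times,
        axonal_strain=axial,
        principal_strain=principal,
        cauchy_stress=sigma,
        mas=max(mas_raw, 0.0),
        mps=float(principal.max()),
        mas_clamped=clamped,
    )
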