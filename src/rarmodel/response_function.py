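"""Gamma-shaped respiration amplitude response functions and basis sets.

The event-related respiration amplitude response (RAR) is modelled as the
output of a linear time-invariant system. Its response function is built
from gamma-density components

    y(t) = A / (theta^k Gamma(k)) (t - x0)^(k-1) exp(-(t - x0)/theta)

with shape k, scale theta (s), onset shift x0 (s) and free amplitude A.
Two canonical components are shipped with the package: an early response
(ER) peaking at ~4.9 s after CS onset and a late response (LR) peaking at
~10.25 s. Basis sets combine them:

    G1 = {ER}, G2 = {ER, dER/dt}, G3 = {ER, LR}, G4 = {ER, dER/dt, LR},

with primed variants (G1'-G4') identical in shape but time-locked to the
unconditioned stimulus, i.e. shifted by SOA - 3.5 s.

The ER parameterization is extreme (k ~ 2.6e7), so the gamma is always
evaluated in log space; the ER temporal derivative is computed by central
finite differences of the sampled ER rather than analytically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = [
    "GammaRF",
    "BasisSet",
    "DifferenceWaveform",
    "GammaFitResult",
    "eval_gamma_rf",
    "fit_gamma_rf",
    "build_basis",
    "load_canonical_parameters",
    "MODEL_COMPONENTS",
]

#: components per basis-set model
MODEL_COMPONENTS = {
    "G1": ("ER",),
    "G2": ("ER", "dER"),
    "G3": ("ER", "LR"),
    "G4": ("ER", "dER", "LR"),
}

#: default response-function support (s); both canonical components decay to
#: < 1% of peak well before this
DEFAULT_RF_DURATION = 20.0

#: reference SOA (s) of the development design; primed bases shift by soa - this
REFERENCE_SOA = 3.5


@dataclass
class GammaRF:
    """Gamma response-function component.

    k : shape (dimensionless, > 0)
    theta : scale (s, > 0)
    x0 : onset shift (s); the function is 0 for t <= x0 when k > 1
    A : amplitude (free parameter at inversion time)
    """

    k: float
    theta: float
    x0: float
    A: float = 1.0

    @property
    def mode(self) -> float:
        """Analytic peak time x0 + (k - 1)*theta (valid for k > 1)."""
        return self.x0 + (self.k - 1.0) * self.theta


@dataclass
class BasisSet:
    """Sampled response-function components on a uniform grid.

    ``components`` has shape (n_components, n_samples); each component is
    peak-normalized to unit maximum absolute value so that GLM betas carry
    the response amplitude.
    """

    model_id: str
    components: np.ndarray
    component_labels: tuple[str, ...]
    sampling_rate: float
    time_lock: str = "CS"
    soa_shift: float = 0.0

    def component(self, label: str) -> np.ndarray:
        return self.components[self.component_labels.index(label)]


@dataclass
class DifferenceWaveform:
    """CS+ minus CS- average response on a uniform grid.

    ``window`` gives [start, end] in seconds relative to CS onset.
    """

    values: np.ndarray
    sampling_rate: float
    window: tuple[float, float] = (0.0, 11.0)

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(np.asarray(self.values).size) / self.sampling_rate


@dataclass
class GammaFitResult:
    rf: GammaRF
    rss: float
    converged: bool
    n_iterations: int


def eval_gamma_rf(rf: GammaRF, t) -> np.ndarray:
    """Evaluate the gamma response function at times ``t`` (seconds).

    Returns A/(theta^k Gamma(k)) (t-x0)^(k-1) exp(-(t-x0)/theta) for
    t > x0 and 0 otherwise. Evaluated in log space, which is mandatory for
    the canonical ER parameterization (k ~ 2.6e7 overflows the naive form).
    """
    if rf.k <= 0 or rf.theta <= 0:
        raise ValueError("invalid gamma parameters: k and theta must be positive")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    m = t > rf.x0
    if np.any(m):
        dt = t[m] - rf.x0
        k, theta = rf.k, rf.theta
        if k < 1e4:
            logy = -k * np.log(theta) - gammaln(k) + (k - 1.0) * np.log(dt) - dt / theta
        else:
            # direct log-space evaluation cancels O(k log k) terms and loses
            # ~8 digits at k ~ 1e7; substituting Stirling's expansion for
            # log Gamma(k) regroups the sum into O(1)-sized terms:
            #   log y = (k-1) log1p(delta) - d/theta - log(theta)
            #           - 0.5 log(2 pi k) - eps(k),
            # with d = dt - k*theta and delta = d/(k*theta)
            d = dt - k * theta
            delta = d / (k * theta)
            stirling_corr = 1.0 / (12.0 * k) - 1.0 / (360.0 * k**3)
            logy = (
                (k - 1.0) * np.log1p(delta)
                - d / theta
                - 0.5 * np.log(k)
                - np.log(theta)
                - 0.5 * np.log(2.0 * np.pi)
                - stirling_corr
            )
        out[m] = rf.A * np.exp(logy)
    return out[0] if scalar else out


def load_canonical_parameters() -> dict[str, GammaRF]:
    """Load the packaged canonical ER/LR gamma parameters."""
    text = resources.files("rarmodel").joinpath("data/canonical_rf.yaml").read_text()
    doc = yaml.safe_load(text)
    return {
        name: GammaRF(k=float(p["k"]), theta=float(p["theta"]), x0=float(p["x0"]))
        for name, p in doc["components"].items()
    }


def _canonical_id(model_id: str) -> tuple[str, bool]:
    mid = model_id.strip()
    primed = mid.endswith(("p", "'", "′"))
    base = mid.rstrip("p'′")
    if base not in MODEL_COMPONENTS:
        raise ValueError(f"unknown model id {model_id!r}; expected G1-G4 or G1p-G4p")
    return base, primed


def build_basis(
    model_id: str,
    sampling_rate: float,
    duration: float = DEFAULT_RF_DURATION,
    soa: float = REFERENCE_SOA,
    parameters: dict[str, GammaRF] | None = None,
) -> BasisSet:
    """Sample a basis set on a uniform grid.

    The canonical ER and LR are evaluated on the grid, the ER derivative is
    taken by central finite differences, each component is peak-normalized
    to |max| = 1, and primed (US-locked) variants are shifted right by
    soa - 3.5 s. Alternative gamma parameters may be supplied via
    ``parameters`` (a dict with keys "ER" and "LR").
    """
    base, primed = _canonical_id(model_id)
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    shift = (soa - REFERENCE_SOA) if primed else 0.0
    if duration < 11.0 + max(shift, 0.0):
        raise ValueError(
            f"basis duration {duration:g} s too short for the 11 s response "
            f"window plus a {shift:g} s US shift"
        )
    params = parameters if parameters is not None else load_canonical_parameters()
    n = int(round(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    er = eval_gamma_rf(params["ER"], t)
    waveforms = {
        "ER": er,
        "dER": np.gradient(er, 1.0 / sampling_rate),
        "LR": eval_gamma_rf(params["LR"], t),
    }
    shift_samples = int(round(shift * sampling_rate))
    comps = []
    for label in MODEL_COMPONENTS[base]:
        v = waveforms[label]
        v = v / np.max(np.abs(v))
        if shift_samples > 0:
            v = np.concatenate([np.zeros(shift_samples), v[: n - shift_samples]])
        elif shift_samples < 0:
            v = np.concatenate([v[-shift_samples:], np.zeros(-shift_samples)])
        comps.append(v)
    return BasisSet(
        model_id=base + ("p" if primed else ""),
        components=np.vstack(comps),
        component_labels=MODEL_COMPONENTS[base],
        sampling_rate=sampling_rate,
        time_lock="US" if primed else "CS",
        soa_shift=shift,
    )


def fit_gamma_rf(
    diff: DifferenceWaveform,
    init: GammaRF,
    fit_window: tuple[float, float] | None = None,
    max_iterations: int = 10_000,
    tol: float = 1e-8,
) -> GammaFitResult:
    """Fit gamma parameters to a difference waveform by Nelder-Mead.

    Minimizes the residual sum of squares between the waveform and the
    gamma function over ``fit_window`` (defaults to the full waveform).
    The simplex searches (log k, log theta, x0); the amplitude A is
    profiled out analytically at each step, so an all-zero waveform
    yields A = 0 immediately. Gamma parameters may trade off against each
    other; waveform equivalence, not parameter identity, is the contract.

    Non-convergence after ``max_iterations`` returns the best point with a
    warning and ``converged=False``.
    """
    t = diff.times
    d = np.asarray(diff.values, dtype=float)
    if fit_window is not None:
        m = (t >= fit_window[0]) & (t <= fit_window[1])
        if not np.any(m):
            raise ValueError("fit_window does not overlap the waveform")
        t, d = t[m], d[m]

    def profile(p: np.ndarray) -> tuple[float, float]:
        g = eval_gamma_rf(GammaRF(np.exp(p[0]), np.exp(p[1]), p[2]), t)
        gg = float(g @ g)
        a = float(d @ g) / gg if gg > 0 else 0.0
        r = d - a * g
        return float(r @ r), a

    res = minimize(
        lambda p: profile(p)[0],
        x0=[np.log(init.k), np.log(init.theta), init.x0],
        method="Nelder-Mead",
        options={
            "xatol": tol,
            "fatol": tol,
            "maxiter": max_iterations,
            "maxfev": 2 * max_iterations,
        },
    )
    rss, a = profile(res.x)
    if not res.success:
        warnings.warn(
            f"gamma fit did not converge after {res.nit} iterations "
            f"(final RSS {rss:.3g})",
            stacklevel=2,
        )
    rf = GammaRF(k=float(np.exp(res.x[0])), theta=float(np.exp(res.x[1])), x0=float(res.x[2]), A=a)
    return GammaFitResult(rf=rf, rss=rss, converged=bool(res.success), n_iterations=int(res.nit))
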