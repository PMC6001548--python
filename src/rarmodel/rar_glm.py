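"""Convolution GLM for condition-wise respiration amplitude responses.

The filtered amplitude time series Y is modelled as Y = X beta + eps. Each
design-matrix column is a unit-impulse train at the CS onsets of one
condition, convolved with one basis-set component; a constant column models
the session baseline. Betas are the minimum-norm least-squares solution
beta = pinv(X) Y, so they estimate the amplitude of the cognitive input per
condition and component.

Two scoring rules summarize a fitted model into one number per condition:
for single-pulse bases (G1, G2) the signed maximal deviation from baseline
of the reconstructed response in the 2-11 s window; for bases with a late
component (G3, G4) the difference beta(LR) - beta(ER).

Because the observed series is built by sampling the underlying response
once per breath and interpolating, ``build_design_matrix`` can optionally
pass the regressors through the same sample-and-interpolate operator
(``sample_times``) before filtering, which removes the systematic
attenuation that a continuously sampled regressor would suffer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .resp_preproc import AmplitudeTimeseries, butter_bandpass_filtfilt, AMPLITUDE_BAND_HZ
from .response_function import BasisSet, _canonical_id

__all__ = [
    "EventSchedule",
    "DesignMatrix",
    "GlmFit",
    "build_design_matrix",
    "invert_glm",
    "score_reconstruction",
    "score_lr_minus_er",
    "model_score",
    "RESPONSE_WINDOW_S",
    "SCORE_WINDOW_S",
]

#: single-trial analysis window (s after CS onset); equals the minimum
#: inter-onset interval of the reference designs
RESPONSE_WINDOW_S = 11.0

#: scoring window (s after CS onset) for reconstruction-based scores
SCORE_WINDOW_S = (2.0, 11.0)


@dataclass
class EventSchedule:
    """CS onsets with condition labels, SOA and reinforcement flags.

    ``reinforced`` marks CS+ trials on which the US was delivered; it is
    carried for simulation bookkeeping only and is not modelled (the GLM
    has one input per CS condition).
    """

    cs_onsets: np.ndarray
    conditions: np.ndarray
    soa: float = 3.5
    reinforced: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cs_onsets = np.asarray(self.cs_onsets, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.cs_onsets.size != self.conditions.size:
            raise ValueError("onsets and condition labels must have equal length")
        if self.cs_onsets.size and np.any(np.diff(self.cs_onsets) <= 0):
            raise ValueError("CS onsets must be strictly increasing")
        if self.cs_onsets.size > 1 and np.min(np.diff(self.cs_onsets)) < RESPONSE_WINDOW_S:
            warnings.warn(
                "inter-onset interval shorter than the 11 s analysis window",
                stacklevel=2,
            )
        if self.reinforced is None:
            self.reinforced = np.zeros(self.cs_onsets.size, dtype=bool)
        else:
            self.reinforced = np.asarray(self.reinforced, dtype=bool)
            if self.reinforced.size != self.cs_onsets.size:
                raise ValueError("reinforced flags must align with onsets")

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.conditions)))

    def onsets_for(self, condition: str) -> np.ndarray:
        return self.cs_onsets[self.conditions == condition]


@dataclass
class DesignMatrix:
    X: np.ndarray
    column_map: dict[tuple[str, str], int]
    intercept_index: int
    basis: BasisSet
    sampling_rate: float

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted({c for c, _ in self.column_map}))


@dataclass
class GlmFit:
    betas: np.ndarray
    column_map: dict[tuple[str, str], int]
    intercept_index: int
    residuals: np.ndarray
    fitted: np.ndarray
    reconstructed: dict[str, np.ndarray]
    model_id: str
    sampling_rate: float
    basis: BasisSet = field(repr=False)

    def beta(self, condition: str, component: str) -> float:
        return float(self.betas[self.column_map[(condition, component)]])

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted({c for c, _ in self.column_map}))


def build_design_matrix(
    events: EventSchedule,
    basis: BasisSet,
    n_samples: int,
    sampling_rate: float,
    sample_times: np.ndarray | None = None,
    filter_regressors: bool = True,
) -> DesignMatrix:
    """Build the convolution design matrix on the amplitude-series grid.

    Per condition, a unit-impulse train at the CS onsets (nearest grid
    sample) is convolved with each basis component; convolution is
    truncated at the data end. If ``sample_times`` is given, each column is
    then sampled at those times and linearly re-interpolated onto the grid,
    mimicking the per-breath observation of the amplitude series. Columns
    finally receive the identical 0.01-2 Hz zero-phase band-pass as the
    data (``filter_regressors=True``), and an all-ones intercept column is
    appended.
    """
    if abs(basis.sampling_rate - sampling_rate) > 1e-9 * sampling_rate:
        raise ValueError("basis must be sampled at the amplitude-series rate")
    t_grid = np.arange(n_samples) / sampling_rate
    cols: list[np.ndarray] = []
    column_map: dict[tuple[str, str], int] = {}
    for cond in events.condition_names:
        impulse = np.zeros(n_samples)
        for onset in events.onsets_for(cond):
            i = int(round(onset * sampling_rate))
            if i < 0 or i >= n_samples:
                raise ValueError(f"event outside data span: onset {onset:g} s")
            impulse[i] += 1.0
        for label in basis.component_labels:
            col = np.convolve(impulse, basis.component(label))[:n_samples]
            if sample_times is not None:
                sampled = np.interp(sample_times, t_grid, col)
                col = np.interp(t_grid, sample_times, sampled)
            if filter_regressors:
                col = butter_bandpass_filtfilt(
                    col, sampling_rate, *AMPLITUDE_BAND_HZ, order=1, demean=True
                )
            if not np.any(col):
                raise ValueError(f"all-zero design column for ({cond}, {label})")
            column_map[(cond, label)] = len(cols)
            cols.append(col)
    intercept_index = len(cols)
    X = np.column_stack(cols + [np.ones(n_samples)])
    return DesignMatrix(X, column_map, intercept_index, basis, sampling_rate)


def invert_glm(design: DesignMatrix, amplitude) -> GlmFit:
    """Invert the GLM by Moore-Penrose pseudoinverse.

    ``amplitude`` is an AmplitudeTimeseries or a plain array on the design
    grid. Returns the minimum-norm least-squares betas (rank deficiency is
    reported as a warning, never an error), the exact fitted/residual
    decomposition, and the per-condition response reconstruction over the
    first 11 s after CS onset.
    """
    y = amplitude.values if isinstance(amplitude, AmplitudeTimeseries) else np.asarray(amplitude, float)
    X = design.X
    if y.size != X.shape[0]:
        raise ValueError("data length does not match the design matrix")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient design matrix (rank {rank} < {X.shape[1]}); "
            "betas are the minimum-norm solution",
            stacklevel=2,
        )
    betas = np.linalg.pinv(X) @ y
    fitted = X @ betas
    residuals = y - fitted
    sr = design.sampling_rate
    n11 = int(round(RESPONSE_WINDOW_S * sr)) + 1
    reconstructed = {}
    for cond in design.conditions:
        rec = np.zeros(n11)
        for label in design.basis.component_labels:
            b = betas[design.column_map[(cond, label)]]
            rec += b * design.basis.component(label)[:n11]
        reconstructed[cond] = rec
    return GlmFit(
        betas=betas,
        column_map=design.column_map,
        intercept_index=design.intercept_index,
        residuals=residuals,
        fitted=fitted,
        reconstructed=reconstructed,
        model_id=design.basis.model_id,
        sampling_rate=sr,
        basis=design.basis,
    )


def score_reconstruction(fit: GlmFit, condition: str) -> float:
    """Signed maximal deviation from baseline of the reconstructed response.

    The extremum of largest absolute value of the condition's reconstructed
    response in the 2-11 s window after CS onset, returned with its sign.
    Used for single-pulse bases (G1, G2).
    """
    rec = fit.reconstructed[condition]
    sr = fit.sampling_rate
    i0 = int(round(SCORE_WINDOW_S[0] * sr))
    i1 = int(round(SCORE_WINDOW_S[1] * sr))
    seg = rec[i0 : i1 + 1]
    return float(seg[np.argmax(np.abs(seg))])


def score_lr_minus_er(fit: GlmFit, condition: str) -> float:
    """Signed difference beta(LR) - beta(ER) for bases with a late component."""
    labels = fit.basis.component_labels
    if "LR" not in labels or "ER" not in labels:
        raise ValueError("score undefined for this model: basis lacks an LR component")
    return fit.beta(condition, "LR") - fit.beta(condition, "ER")


def model_score(fit: GlmFit, condition: str) -> float:
    """Dispatch to the scoring rule of the fitted model (G1/G2 vs G3/G4)."""
    base, _ = _canonical_id(fit.model_id)
    if base in ("G1", "G2"):
        return score_reconstruction(fit, condition)
    return score_lr_minus_er(fit, condition)
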