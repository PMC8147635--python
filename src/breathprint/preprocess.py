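"""Compression chain from raw 64 x 36 x 3 tensors to 19-element breathprints.

Stage order: per-participant [0, 1] normalization -> peak shaving ->
Fourier clean-air compensation -> e-power -> NOx-sensor selection ->
Tucker compression -> 19-element feature extraction -> cohort-wise
[-1, 1] rescaling.  All stages are deterministic.

The cohort-level steps (Tucker factors and the rescaling map) are fitted
on a training cohort and can then be applied frozen to held-out
participants; :class:`BreathprintPreprocessor` packages this as a
scikit-learn transformer.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import N_CYCLE, N_FEATURES, N_SENSOR, N_TEMP, FeatureVector, SensorTensor


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. a constant tensor: dead sensor)."""


class ConvergenceError(RuntimeError):
    """Tucker alternating least squares failed to converge."""


# ---------------------------------------------------------------------------
# per-participant stages (pure array -> array)


def normalize_participant(values: np.ndarray) -> np.ndarray:
    """Affine map of all 6912 values onto [0, 1] (min -> 0, max -> 1)."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi - lo <= 0.0:
        raise DegenerateInputError(
            "constant tensor: cannot normalize (dead sensor?)"
        )
    return (values - lo) / (hi - lo)


def peak_shave(values: np.ndarray, window: int = 5, k: float = 4.0) -> np.ndarray:
    """Replace spikes by the running median along the cycle axis.

    For each temperature step and sensor, values deviating from their
    running median (window ``window`` cycles, edges clamped) by more than
    ``k`` robust SDs (1.4826 x MAD of the residuals, per series) are
    replaced by that median.  A series with zero MAD falls back to its
    residual standard deviation; if that is also zero the series is left
    untouched.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("shave window must be odd and >= 3")
    if window > N_CYCLE:
        raise ValueError(f"shave window {window} exceeds {N_CYCLE} cycles")
    values = np.asarray(values, dtype=float)
    med = ndimage.median_filter(values, size=(1, window, 1), mode="nearest")
    resid = values - med
    mad = np.median(np.abs(resid), axis=1, keepdims=True)
    scale = 1.4826 * mad
    fallback = resid.std(axis=1, keepdims=True)
    scale = np.where(scale > 0.0, scale, fallback)
    with np.errstate(invalid="ignore", divide="ignore"):
        outlier = np.abs(resid) > k * scale
    outlier &= scale > 0.0
    return np.where(outlier, med, values)


def clean_air_compensate(values: np.ndarray, fourier_cut: int = 1) -> np.ndarray:
    """Remove the lowest ``fourier_cut`` frequency components (incl. DC)
    of each cycle series, per temperature step and sensor.

    The clean-air signal varies slowly across cycles, so zeroing the
    lowest Fourier bins of the 36-cycle series and back-transforming
    subtracts it while keeping breath-synchronous structure.
    ``fourier_cut=0`` is the identity (to numerical precision).
    """
    n_cycle = values.shape[1]
    if not 0 <= fourier_cut <= n_cycle // 2:
        raise ValueError(
            f"fourier_cut must be in [0, {n_cycle // 2}], got {fourier_cut}"
        )
    spec = np.fft.rfft(values, axis=1)
    spec[:, :fourier_cut, ...] = 0.0
    return np.fft.irfft(spec, n=n_cycle, axis=1)


def epower(values: np.ndarray) -> np.ndarray:
    """Elementwise natural exponential, x -> e^x."""
    return np.exp(np.asarray(values, dtype=float))


def select_sensor(values: np.ndarray, nox_sensor_index: int = 0) -> np.ndarray:
    """Slice out the NOx sensor's 64 x 36 matrix."""
    if not 0 <= nox_sensor_index < values.shape[2]:
        raise ValueError(f"sensor index {nox_sensor_index} out of range")
    return values[:, :, nox_sensor_index]


def participant_stage_chain(
    values: np.ndarray,
    shave_window: int = 5,
    shave_k: float = 4.0,
    fourier_cut: int = 1,
    nox_sensor_index: int = 0,
) -> np.ndarray:
    """normalize -> shave -> compensate -> e-power -> select; returns 64 x 36."""
    v = normalize_participant(values)
    v = peak_shave(v, window=shave_window, k=shave_k)
    v = clean_air_compensate(v, fourier_cut=fourier_cut)
    v = epower(v)
    return select_sensor(v, nox_sensor_index)


# ---------------------------------------------------------------------------
# Tucker compression (higher-order orthogonal iteration)


def _unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def _multi_mode_dot(tensor: np.ndarray, factors: list[np.ndarray | None], transpose: bool) -> np.ndarray:
    out = tensor
    for mode, f in enumerate(factors):
        if f is None:
            continue
        m = f.T if transpose else f
        out = np.moveaxis(np.tensordot(m, out, axes=(1, mode)), 0, mode)
    return out


def tucker3_compress(
    stack: np.ndarray,
    ranks: tuple[int, ...],
    max_iter: int = 200,
    tol: float = 1e-10,
    return_factors: bool = False,
):
    """Tucker decomposition of a participant stack by alternating least
    squares (HOOI), leaving the participant mode uncompressed.

    ``stack`` has shape (n_participants, ...), e.g. (n, 64, 36) after
    sensor selection or (n, 64, 36, 3) before it.  ``ranks`` gives the
    target rank of each non-participant mode (extra entries are ignored,
    so the canonical (temperature, cycle, sensor) triple can be passed for
    either input).  Factor matrices have orthonormal columns; each
    participant's core coefficients are returned flattened in C order,
    i.e. temperature-major.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim < 3:
        raise ValueError("stack must be (n_participants, mode1, mode2, ...)")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    n_modes = stack.ndim - 1
    use_ranks = tuple(int(r) for r in ranks[:n_modes])
    if len(use_ranks) < n_modes:
        raise ValueError(f"need {n_modes} ranks, got {len(ranks)}")
    for r, dim in zip(use_ranks, stack.shape[1:]):
        if not 1 <= r <= dim:
            raise ValueError(f"infeasible rank {r} for mode of size {dim}")

    def leading_basis(matrix: np.ndarray, r: int) -> np.ndarray:
        # full_matrices=True so r columns exist even when rank(matrix) < r
        u, _, _ = np.linalg.svd(matrix, full_matrices=True)
        return u[:, :r]

    # HOSVD initialization, then orthogonal iteration
    factors: list[np.ndarray] = []
    for mode in range(1, stack.ndim):
        factors.append(leading_basis(_unfold(stack, mode), use_ranks[mode - 1]))

    norm_x = np.linalg.norm(stack)
    prev_err = np.inf
    converged = False
    for _ in range(max_iter):
        for mode in range(1, stack.ndim):
            others = [None] + [
                factors[m - 1] if m != mode else None for m in range(1, stack.ndim)
            ]
            proj = _multi_mode_dot(stack, others, transpose=True)
            factors[mode - 1] = leading_basis(_unfold(proj, mode), use_ranks[mode - 1])
        core = _multi_mode_dot(stack, [None] + factors, transpose=True)
        # orthonormal factors: ||X - X_hat||^2 = ||X||^2 - ||core||^2
        err = np.sqrt(max(norm_x**2 - np.linalg.norm(core) ** 2, 0.0)) / norm_x
        if abs(prev_err - err) < tol:
            converged = True
            break
        prev_err = err
    if not converged:
        raise ConvergenceError(
            f"Tucker ALS did not converge in {max_iter} iterations "
            f"(relative residual {err:.3e})"
        )
    cores = core.reshape(core.shape[0], -1)
    if return_factors:
        return cores, factors, err
    return cores


def tucker_reconstruction_error(stack: np.ndarray, ranks: tuple[int, ...]) -> float:
    """Relative Frobenius reconstruction error at the given ranks.

    Computed from an explicit reconstruction (numerically exact near zero,
    unlike the norm-difference shortcut used during the iteration).
    """
    stack = np.asarray(stack, dtype=float)
    cores, factors, _ = tucker3_compress(stack, ranks, return_factors=True)
    core = cores.reshape(stack.shape[0], *[f.shape[1] for f in factors])
    recon = _multi_mode_dot(core, [None] + factors, transpose=False)
    return float(np.linalg.norm(stack - recon) / np.linalg.norm(stack))


# ---------------------------------------------------------------------------
# feature extraction and rescaling


def extract_features(cores: np.ndarray, n_features: int = N_FEATURES) -> np.ndarray:
    """Deterministic 19-element vector per participant from Tucker cores.

    With ranks (19, r_c) the core is 19 x r_c per participant; the feature
    vector is the temperature-mode coefficient column paired with the
    *last* cycle component.  The leading cycle component is the
    cycle-constant profile (dominated by what the clean-air compensation
    already targeted), so with r_c = 2 the last column is the leading
    breath-synchronous contrast, which is where class information that
    survived DC removal lives.  With r_c = 1 this reduces to the single
    available column.
    """
    cores = np.asarray(cores, dtype=float)
    if cores.ndim != 2 or cores.shape[1] % n_features != 0:
        raise ValueError(
            f"cores of shape {cores.shape} cannot yield {n_features} features"
        )
    r_rest = cores.shape[1] // n_features
    per = cores.reshape(cores.shape[0], n_features, r_rest)
    return per[:, :, -1]


def rescale_features(raw: np.ndarray, bounds: tuple[np.ndarray, np.ndarray] | None = None):
    """Per-coordinate affine map onto [-1, 1] across the cohort.

    Returns ``(rescaled, (lo, hi))``.  A constant coordinate maps to 0.
    When ``bounds`` is given (frozen from a training cohort), it is applied
    instead of refitting and out-of-range values are clipped.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 1:
        raise ValueError("need a (n_participants, n_features) array")
    if bounds is None:
        lo = raw.min(axis=0)
        hi = raw.max(axis=0)
    else:
        lo, hi = bounds
    span = hi - lo
    safe = np.where(span > 0.0, span, 1.0)
    scaled = 2.0 * (raw - lo) / safe - 1.0
    scaled = np.where(span > 0.0, scaled, 0.0)
    return np.clip(scaled, -1.0, 1.0), (lo, hi)


# ---------------------------------------------------------------------------
# scikit-learn transformer


class BreathprintPreprocessor(BaseEstimator, TransformerMixin):
    """Full tensor-to-breathprint chain as a scikit-learn transformer.

    ``fit`` runs the per-participant stages on a training cohort, fits the
    Tucker factors on the stacked post-selection matrices, and freezes the
    per-coordinate [-1, 1] rescaling map.  ``transform`` applies the frozen
    factors and map, clipping held-out participants that fall outside the
    training range.

    Parameters
    ----------
    shave_window, shave_k : peak-shaving running-median window (cycles) and
        robust-threshold multiplier.
    fourier_cut : number of low-frequency cycle components (incl. DC)
        attributed to clean air and removed.
    nox_sensor_index : which of the three sensors is the NOx sensor.
    tucker_ranks : (temperature, cycle, sensor) Tucker ranks; the
        temperature rank must equal ``n_features`` and the sensor rank is
        unused after selection.
    """

    def __init__(
        self,
        shave_window: int = 5,
        shave_k: float = 4.0,
        fourier_cut: int = 1,
        nox_sensor_index: int = 0,
        tucker_ranks: tuple[int, int, int] = (19, 2, 1),
        n_features: int = N_FEATURES,
    ):
        self.shave_window = shave_window
        self.shave_k = shave_k
        self.fourier_cut = fourier_cut
        self.nox_sensor_index = nox_sensor_index
        self.tucker_ranks = tucker_ranks
        self.n_features = n_features

    def _validate(self) -> None:
        if self.n_features != N_FEATURES:
            raise ValueError(f"n_features is fixed at {N_FEATURES}")
        if self.tucker_ranks[0] != self.n_features:
            raise ValueError(
                "temperature-mode Tucker rank must equal n_features "
                f"({self.n_features}), got {self.tucker_ranks[0]}"
            )
        if not 1 <= self.fourier_cut < N_CYCLE // 2:
            raise ValueError("fourier_cut must be in [1, 17]")

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if len(X) and isinstance(X[0], SensorTensor):
            arr = np.stack([t.values for t in X])
        else:
            arr = np.asarray(X, dtype=float)
        if arr.ndim != 4 or arr.shape[1:] != (N_TEMP, N_CYCLE, N_SENSOR):
            raise ValueError(
                f"expected (n, {N_TEMP}, {N_CYCLE}, {N_SENSOR}) input, got {arr.shape}"
            )
        return arr

    def _stage_chain(self, arr: np.ndarray) -> np.ndarray:
        mats = [
            participant_stage_chain(
                v,
                shave_window=self.shave_window,
                shave_k=self.shave_k,
                fourier_cut=self.fourier_cut,
                nox_sensor_index=self.nox_sensor_index,
            )
            for v in arr
        ]
        return np.stack(mats)

    def fit(self, X, y=None):
        self._validate()
        arr = self._as_array(X)
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 participants to fit")
        stack = self._stage_chain(arr)
        cores, factors, err = tucker3_compress(
            stack, self.tucker_ranks, return_factors=True
        )
        self.temperature_factors_ = factors[0]
        self.cycle_factors_ = factors[1]
        self.reconstruction_error_ = err
        raw = extract_features(cores, self.n_features)
        _, self.feature_bounds_ = rescale_features(raw)
        self.n_features_in_ = N_TEMP * N_CYCLE * N_SENSOR
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "feature_bounds_")
        arr = self._as_array(X)
        stack = self._stage_chain(arr)
        u_cyc = self.cycle_factors_[:, -1]
        raw = np.einsum("ntc,tf,c->nf", stack, self.temperature_factors_, u_cyc)
        scaled, _ = rescale_features(raw, bounds=self.feature_bounds_)
        return scaled


def preprocess_pipeline(cohort, config: BreathprintPreprocessor | None = None) -> list[FeatureVector]:
    """Fit-and-transform a cohort in one call, returning FeatureVectors."""
    prep = config if config is not None else BreathprintPreprocessor()
    feats = prep.fit(cohort).transform(cohort)
    out = []
    for t, f in zip(cohort, feats):
        out.append(FeatureVector(participant_id=t.participant_id, features=f, label=t.label))
    return out
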