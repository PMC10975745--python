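"""Spectral pre-processing: Savitzky-Golay smoothing and the standard normal
variate (SNV) transform, plus the identity ("raw") transform.

Savitzky-Golay coefficients are derived here from the defining local
least-squares polynomial fit rather than taken from a filter library: a
degree-p polynomial is fitted to the 2m+1 window points and its d-th
derivative evaluated at the window centre.  For d = 0 the coefficients are
symmetric and sum to one, so the smoother reproduces constants (and, with
p = 3, any cubic) exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import SpectraSet


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay filter parameters.

    half_window m gives window size 2m+1; poly_order p is the local
    polynomial degree; deriv_order d selects the derivative returned at the
    window centre (d = 0 is plain smoothing).  Requires 2m+1 > p >= d >= 0.
    """

    half_window: int = 3
    poly_order: int = 3
    deriv_order: int = 0

    def __post_init__(self) -> None:
        m, p, d = self.half_window, self.poly_order, self.deriv_order
        if m < 1:
            raise ValueError("half_window must be >= 1")
        if not (2 * m + 1 > p >= d >= 0):
            raise ValueError(
                f"require 2m+1 > p >= d >= 0, got m={m}, p={p}, d={d}"
            )

    @property
    def window(self) -> int:
        return 2 * self.half_window + 1


def sg_coefficients(params: SGParams) -> np.ndarray:
    """Convolution coefficients c_{-m..m} of the Savitzky-Golay filter.

    Solves the window least-squares problem directly: with the Vandermonde
    matrix V[j, q] = j**q over offsets j = -m..m and q = 0..p, the fitted
    polynomial coefficients are (V'V)^{-1} V' y, and the d-th derivative at
    the centre picks out row d times d!.  The resulting weights applied to
    the window values give the filter output.
    """
    m, p, d = params.half_window, params.poly_order, params.deriv_order
    offsets = np.arange(-m, m + 1, dtype=float)
    V = np.vander(offsets, p + 1, increasing=True)
    # row d of the pseudoinverse = weights for the d-th polynomial coefficient
    pinv = np.linalg.solve(V.T @ V, V.T)
    return math.factorial(d) * pinv[d]


def sg_smooth(
    spectrum: np.ndarray,
    params: SGParams = SGParams(),
    *,
    convention: str = "least-squares",
) -> np.ndarray:
    """Apply Savitzky-Golay filtering to one spectrum, preserving length.

    Interior points are the convolution with :func:`sg_coefficients`.  The m
    points at each end are handled by fitting a degree-p polynomial to the
    first (last) 2m+1 points and evaluating it in place, which keeps
    polynomial reproduction exact at the edges.

    ``convention`` selects the coefficient normalisation: the default
    ``"least-squares"`` uses the polynomial-fit coefficients as derived
    (summing to 1 for d = 0); ``"windowed"`` additionally divides by the
    window size 2m+1, the literal reading of a formulation that writes an
    explicit 1/(2m+1) prefactor in front of the coefficient sum.
    """
    if convention not in ("least-squares", "windowed"):
        raise ValueError(f"unknown convention {convention!r}")
    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1:
        raise ValueError("sg_smooth expects a 1-d spectrum")
    m, p = params.half_window, params.poly_order
    n = y.size
    if n < params.window:
        raise ValueError(
            f"spectrum length {n} shorter than window {params.window}"
        )

    c = sg_coefficients(params)
    # np.convolve flips the kernel; c is symmetric for d=0 but not for d>0
    out = np.convolve(y, c[::-1], mode="valid")  # length n - 2m, centres m..n-m-1
    result = np.empty_like(y)
    result[m : n - m] = out

    # edge fits on the first / last full window
    offs = np.arange(params.window, dtype=float)
    V = np.vander(offs, p + 1, increasing=True)
    d = params.deriv_order
    dfact = math.factorial(d)
    for lo, idx in (((slice(0, params.window)), np.arange(m)),
                    ((slice(n - params.window, n)), np.arange(n - m, n))):
        base = lo.start
        coef, *_ = np.linalg.lstsq(V, y[lo], rcond=None)
        # evaluate d-th derivative of the fitted polynomial at each edge point
        t = (idx - base).astype(float)
        val = np.zeros_like(t)
        for q in range(d, p + 1):
            val += coef[q] * (math.factorial(q) / math.factorial(q - d)) * t ** (q - d)
        result[idx] = val

    if convention == "windowed":
        result = result / params.window
    return result


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to mean 0, SD 1.

    Uses the sample SD (n-1 denominator).  Removes additive baseline offsets
    and multiplicative scatter: snv(a + b*x) == snv(x) for any a and b > 0.
    A constant spectrum has no scale to normalise by and is rejected.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("snv expects a 1-d spectrum with >= 2 channels")
    sd = np.std(y, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance spectrum: SNV undefined")
    return (y - y.mean()) / sd


@dataclass(frozen=True)
class PreprocessorSpec:
    """Named pre-processing choice: one of 'raw', 'snv', 'sg'."""

    name: str
    sg_params: SGParams = field(default_factory=SGParams)

    def __post_init__(self) -> None:
        if self.name not in ("raw", "snv", "sg"):
            raise ValueError(f"unknown preprocessor {self.name!r}")

    @property
    def label(self) -> str:
        return {"raw": "Raw", "snv": "SNV", "sg": "SG smoothing"}[self.name]


#: The three pre-processing variants compared in the evaluation grid.
DEFAULT_SPECS = (
    PreprocessorSpec("raw"),
    PreprocessorSpec("snv"),
    PreprocessorSpec("sg"),
)


def apply(spectra: SpectraSet, spec: PreprocessorSpec) -> SpectraSet:
    """Apply a pre-processing transform independently to each sample spectrum.

    Expects an averaged (replicate-free) SpectraSet; the wavelength grid and
    matrix shape are never changed.
    """
    if spectra.has_replicates:
        raise ValueError("average replicates before pre-processing")
    if spec.name == "raw":
        return spectra.copy()
    rows = []
    for k in range(spectra.n_samples):
        row = spectra.values[k]
        try:
            if spec.name == "snv":
                rows.append(snv(row))
            else:
                rows.append(sg_smooth(row, spec.sg_params))
        except ValueError as exc:
            raise ValueError(f"sample {spectra.samples[k]!r}: {exc}") from exc
    return spectra.with_values(np.array(rows))
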