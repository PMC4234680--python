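"""Autoregressive spectral estimation (Burg) with MDL order selection.

The AR(p) model is written with denominator convention

    x(n) + a_1 x(n-1) + ... + a_p x(n-p) = e(n),

where e(n) is zero-mean white noise of variance sigma^2.  Its one-sided
power spectral density on a grid of frequencies f in (0, 1/(2T)] is

    S(f) = 2 sigma^2 T / | 1 + sum_k a_k exp(-i 2 pi f k T) |^2,

with 1/T the sampling frequency.  The factor 2 folds negative frequencies
so that the integral of S over [0, 1/(2T)] equals the process variance.

Burg's method estimates reflection coefficients from forward/backward
prediction errors; a single recursion sweep yields the coefficients and
innovation variance of *every* order up to ``max_order``, which makes the
minimum-description-length (MDL) search over orders essentially free:

    MDL(p) = N ln(sigma_p^2) + p ln(N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ARSpectrum:
    """A fitted AR model and its evaluated one-sided PSD grid."""

    coeffs: np.ndarray        # a_1..a_p (denominator convention)
    sigma2: float             # innovation variance
    order: int
    T: float                  # sampling interval, seconds
    freqs: np.ndarray         # Hz, uniform over (0, 1/(2T)]
    psd: np.ndarray           # signal-units^2 / Hz, one-sided
    stable: bool = True
    mdl: np.ndarray | None = field(default=None, repr=False)

    @property
    def fs(self) -> float:
        return 1.0 / self.T


def burg_sweep(x: np.ndarray, max_order: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Burg recursion returning coefficients and variances for orders 0..max_order.

    Returns ``(coeffs, variances)`` where ``coeffs[p]`` is the length-p array
    of a_1..a_p and ``variances[p]`` the innovation variance of the order-p
    model.  Order 0 has no coefficients and variance equal to the mean square
    of ``x``.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if max_order >= N:
        raise ValueError(f"max_order {max_order} must be < series length {N}")
    f = x.copy()
    b = x.copy()
    var = float(np.dot(x, x) / N)
    variances = np.empty(max_order + 1)
    variances[0] = var
    coeffs: list[np.ndarray] = [np.zeros(0)]
    a = np.zeros(0)
    for m in range(1, max_order + 1):
        fv = f[m:]
        bv = b[m - 1 : N - 1]
        den = np.dot(fv, fv) + np.dot(bv, bv)
        k = 0.0 if den <= 0 else -2.0 * np.dot(fv, bv) / den
        a = np.concatenate([a + k * a[::-1], [k]])
        var *= 1.0 - k * k
        f_new = fv + k * bv
        b_new = bv + k * fv
        f[m:] = f_new
        b[m:] = b_new
        variances[m] = var
        coeffs.append(a.copy())
    return coeffs, variances


def evaluate_ar_psd(
    coeffs: np.ndarray, sigma2: float, T: float, freqs: np.ndarray
) -> np.ndarray:
    """One-sided AR PSD evaluated on ``freqs`` (Hz) from (a_k, sigma^2, T)."""
    coeffs = np.asarray(coeffs, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    k = np.arange(1, coeffs.size + 1)
    # A(f) = 1 + sum_k a_k exp(-i 2 pi f k T)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) * T)
    A = 1.0 + phase @ coeffs if coeffs.size else np.ones_like(freqs, dtype=complex)
    return 2.0 * sigma2 * T / np.abs(A) ** 2


def is_stable(coeffs: np.ndarray) -> bool:
    """True when no root of A(z) lies outside the unit circle.

    Burg-estimated models are minimum phase by construction (all
    reflection coefficients have magnitude < 1), so roots can only reach
    the circle in the noise-free limit; a small tolerance keeps such
    near-singular but evaluable models (e.g. a pure sinusoid) usable
    while still catching numerically diverged fits.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        return True
    roots = np.roots(np.concatenate([[1.0], coeffs]))
    return bool(np.all(np.abs(roots) < 1.0 + 1e-3))


def mdl_criterion(variances: np.ndarray, N: int) -> np.ndarray:
    """MDL(p) = N ln(sigma_p^2) + p ln N, for p = 0..len(variances)-1."""
    p = np.arange(variances.size)
    with np.errstate(divide="ignore"):
        return N * np.log(variances) + p * np.log(N)


def fit_ar_psd(
    segment: np.ndarray,
    T: float,
    max_order: int = 30,
    n_grid: int = 256,
    order: int | None = None,
) -> ARSpectrum | None:
    """Fit an AR model to a (uniformly sampled) segment and evaluate its PSD.

    The segment is demeaned first.  When ``order`` is None the order is
    selected by MDL over p = 1..max_order; a fixed ``order`` skips the
    search (used for the pulse-rate-variability AR(16) spectrum).  An
    unstable selected model falls back to the next-best MDL order and the
    result is flagged ``stable=False``.

    Returns None for degenerate (near-constant) segments.
    """
    x = np.asarray(segment, dtype=float)
    x = x - x.mean()
    N = x.size
    p_max = min(max_order if order is None else order, N - 1)
    if p_max < 1:
        return None
    if float(np.dot(x, x) / N) < 1e-14:
        return None
    coeffs, variances = burg_sweep(x, p_max)
    mdl = mdl_criterion(variances, N)
    fell_back = False
    if order is not None:
        p = min(order, p_max)
    else:
        # MDL competition over p = 1..p_max; fall back through the ranking
        # until a stable model is found.
        ranking = 1 + np.argsort(mdl[1:], kind="stable")
        p = int(ranking[0])
        for cand in ranking:
            if is_stable(coeffs[cand]):
                fell_back = cand != ranking[0]
                p = int(cand)
                break
    a = coeffs[p]
    sigma2 = float(variances[p])
    stable = is_stable(a)
    f_nyq = 0.5 / T
    freqs = f_nyq * np.arange(1, n_grid + 1) / n_grid
    psd = evaluate_ar_psd(a, sigma2, T, freqs)
    if not np.all(np.isfinite(psd)):
        return None
    return ARSpectrum(
        coeffs=a, sigma2=sigma2, order=p, T=T, freqs=freqs, psd=psd,
        stable=stable and not fell_back, mdl=mdl,
    )


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral of the PSD over [lo, hi] Hz.

    Band edges falling between grid points are inserted by linear
    interpolation, so adjacent bands sum exactly to the enclosing band.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    if hi <= lo:
        return 0.0
    inside = (freqs > lo) & (freqs < hi)
    fgrid = np.concatenate([[lo], freqs[inside], [hi]])
    pgrid = np.concatenate(
        [[np.interp(lo, freqs, psd)], psd[inside], [np.interp(hi, freqs, psd)]]
    )
    return float(np.trapezoid(pgrid, fgrid))


def total_power(spec: ARSpectrum) -> float:
    """Integral of the PSD over the full grid, extended to f = 0.

    The f = 0 ordinate is evaluated from the model so that the integral
    approximates the variance of the modelled signal.
    """
    p0 = float(evaluate_ar_psd(spec.coeffs, spec.sigma2, spec.T, np.array([0.0]))[0])
    fgrid = np.concatenate([[0.0], spec.freqs])
    pgrid = np.concatenate([[p0], spec.psd])
    return float(np.trapezoid(pgrid, fgrid))


def spectral_entropy_bits(psd: np.ndarray) -> float:
    """Shannon entropy (bits) of the PSD ordinates normalized to sum 1."""
    psd = np.asarray(psd, dtype=float)
    s = psd.sum()
    if s <= 0:
        return 0.0
    p = psd / s
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))
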