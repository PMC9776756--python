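"""Gaussian mixture fitting of sedimentation profiles.

Each protein x condition mean curve (25 fractions, sum-to-100 scale) is
modelled as a sum of 1..max_peaks Gaussians. Candidate peak positions
are taken from local maxima of the lightly smoothed curve; for every
candidate count k the k highest candidates seed a bounded nonlinear
least-squares fit, and the best model is selected by BIC. Components
with negligible amplitude are pruned and near-coincident components
merged, refitting after each simplification. The optimizer and the
multi-start order are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares

from .errors import InvalidParameterError
from .simulate import FRACTIONS, GaussianPeak, gaussian_curve

__all__ = ["FitConfig", "MixtureFit", "detect_initial_maxima", "fit_mixture", "evaluate_fit_quality"]


@dataclass(frozen=True)
class FitConfig:
    """Tunable parameters of profile fitting.

    max_peaks        : largest number of Gaussian components considered
    rel_height       : candidate maxima must reach this fraction of the global max
    smooth_sigma     : sigma (fractions) of the pre-detection smoothing kernel
    min_amplitude    : components below this height (sum-100 scale) are pruned
    merge_distance   : components closer than this (fractions) are merged
    qc_threshold     : minimum r-squared for a fit to pass quality control
    max_area_deviation : QC also requires the fitted grid area to stay within
                       this relative deviation of the data curve's total
    mu_bounds        : allowed peak centre range; extends half a fraction past
                       the grid so boundary peaks are representable
    sigma_bounds     : allowed peak width range; excludes one-point spikes and
                       structureless plateaus
    """

    max_peaks: int = 5
    rel_height: float = 0.05
    smooth_sigma: float = 0.75
    min_amplitude: float = 1.0
    merge_distance: float = 0.5
    qc_threshold: float = 0.8
    max_area_deviation: float = 0.05
    mu_bounds: tuple[float, float] = (0.5, 25.5)
    sigma_bounds: tuple[float, float] = (0.3, 6.0)


@dataclass
class MixtureFit:
    """A fitted sum-of-Gaussians profile for one protein x condition."""

    protein_id: str
    condition: str
    peaks: list[GaussianPeak]  # sorted by position ascending
    r_squared: float  # nan when undefined (zero-variance data)
    qc_pass: bool
    fitted_curve: np.ndarray
    reason: str = ""  # why qc failed, if it did

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def curve_at(self, x) -> np.ndarray | float:
        """Evaluate the fitted mixture at arbitrary position(s)."""
        scalar = np.isscalar(x)
        val = gaussian_curve(self.peaks, np.atleast_1d(np.asarray(x, dtype=float)))
        return float(val[0]) if scalar else val


def detect_initial_maxima(
    mean_curve: np.ndarray, config: FitConfig | None = None
) -> list[int]:
    """Candidate peak positions: local maxima of the smoothed curve.

    Boundary maxima (fraction 1 or 25) are allowed. Candidates below
    ``rel_height`` x the global maximum are dropped; at most
    ``max_peaks`` are returned, sorted by height descending.
    """
    cfg = config or FitConfig()
    y = np.asarray(mean_curve, dtype=float)
    if y.shape != FRACTIONS.shape:
        raise InvalidParameterError(f"mean curve must have {len(FRACTIONS)} fractions")
    if np.any(y < 0):
        raise InvalidParameterError("mean curve must be non-negative")
    if not np.any(y > 0):
        return []
    s = gaussian_filter1d(y, cfg.smooth_sigma, mode="nearest") if cfg.smooth_sigma > 0 else y
    # local maxima with plateaus and boundaries included
    left = np.r_[-np.inf, s[:-1]]
    right = np.r_[s[1:], -np.inf]
    is_max = (s >= left) & (s > right) | (s > left) & (s >= right)
    floor = cfg.rel_height * s.max()
    cand = [int(f) for f, m, h in zip(FRACTIONS, is_max, s) if m and h >= floor]
    cand.sort(key=lambda f: -s[f - 1])
    return cand[: cfg.max_peaks]


def _pack(peaks: list[GaussianPeak]) -> np.ndarray:
    return np.array([v for p in peaks for v in (p.amplitude, p.position, p.width)])


def _unpack(theta: np.ndarray) -> list[GaussianPeak]:
    return [
        GaussianPeak(theta[i], theta[i + 1], theta[i + 2]) for i in range(0, len(theta), 3)
    ]


def _nls(y: np.ndarray, init: list[tuple[float, float, float]], cfg: FitConfig):
    """Bounded least squares for a fixed component count. Returns (peaks, ss) or None."""
    k = len(init)
    a_hi = max(3.0 * float(y.max()), 1e-6)
    lo = np.tile([0.0, cfg.mu_bounds[0], cfg.sigma_bounds[0]], k)
    hi = np.tile([a_hi, cfg.mu_bounds[1], cfg.sigma_bounds[1]], k)
    x0 = np.array([v for t in init for v in t])
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

    def resid(theta):
        return gaussian_curve(_unpack(theta), FRACTIONS) - y

    try:
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=400 * k)
    except Exception:
        return None
    if not np.all(np.isfinite(sol.x)):
        return None
    peaks = _unpack(sol.x)
    ss = float(np.sum(sol.fun**2))
    return peaks, ss


def _bic(ss: float, k: int, n: int = len(FRACTIONS)) -> float:
    return n * np.log(max(ss, 1e-12) / n) + 3 * k * np.log(n)


def _simplify(peaks: list[GaussianPeak], cfg: FitConfig) -> list[tuple[float, float, float]] | None:
    """Prune tiny components, merge near-coincident ones; return new inits
    if the model changed, else None."""
    kept = [p for p in peaks if p.amplitude >= cfg.min_amplitude]
    if not kept:
        kept = [max(peaks, key=lambda p: p.amplitude)] if peaks else []
    changed = len(kept) != len(peaks)
    kept = sorted(kept, key=lambda p: p.position)
    merged: list[list[GaussianPeak]] = []
    for p in kept:
        if merged and p.position - merged[-1][-1].position < cfg.merge_distance:
            merged[-1].append(p)
            changed = True
        else:
            merged.append([p])
    if not changed:
        return None
    inits = []
    for group in merged:
        a = sum(p.amplitude for p in group)
        mu = sum(p.amplitude * p.position for p in group) / a if a > 0 else group[0].position
        sigma = max(p.width for p in group)
        inits.append((a, mu, sigma))
    return inits


def fit_mixture(
    mean_curve: np.ndarray,
    candidates: list[int] | None = None,
    config: FitConfig | None = None,
    protein_id: str = "",
    condition: str = "",
) -> MixtureFit:
    """Fit a sum of Gaussians to one mean curve.

    Tries component counts 1..len(candidates), each seeded from the k
    highest candidate maxima, and keeps the BIC-best model; then prunes
    amplitudes below ``min_amplitude`` and merges components closer than
    ``merge_distance``, refitting until stable.
    """
    cfg = config or FitConfig()
    y = np.asarray(mean_curve, dtype=float)
    if candidates is None:
        candidates = detect_initial_maxima(y, cfg)
    if not candidates:
        return MixtureFit(
            protein_id, condition, [], float("nan"), False, np.zeros_like(y),
            reason="no candidate maxima (flat or empty curve)",
        )

    default_sigma = 1.5
    best = None
    for k in range(1, len(candidates) + 1):
        init = [(max(y[c - 1], 1e-3), float(c), default_sigma) for c in candidates[:k]]
        res = _nls(y, init, cfg)
        if res is None:
            continue
        peaks, ss = res
        score = _bic(ss, k)
        if best is None or score < best[0] - 1e-9:
            best = (score, peaks, ss)
    if best is None:
        return MixtureFit(
            protein_id, condition, [], float("nan"), False, np.zeros_like(y),
            reason="optimizer failed to converge for every candidate model",
        )

    _, peaks, ss = best
    for _ in range(cfg.max_peaks):
        inits = _simplify(peaks, cfg)
        if inits is None:
            break
        res = _nls(y, inits, cfg)
        if res is None:
            break
        peaks, ss = res
    peaks = sorted(
        [p for p in peaks if p.amplitude > 0], key=lambda p: p.position
    ) or sorted(peaks, key=lambda p: p.position)

    fitted = gaussian_curve(peaks, FRACTIONS)
    r2, qc = evaluate_fit_quality(fitted, y, cfg.qc_threshold)
    reason = "" if qc else (
        "zero-variance curve" if np.isnan(r2) else f"r_squared {r2:.3f} below threshold"
    )
    # plausibility: the fitted mixture must carry (nearly) the data's total
    total = y.sum()
    if qc and total > 0 and abs(fitted.sum() - total) > cfg.max_area_deviation * total:
        qc = False
        reason = (
            f"fitted area {fitted.sum():.1f} deviates more than "
            f"{100 * cfg.max_area_deviation:.0f}% from the curve total {total:.1f}"
        )
    return MixtureFit(protein_id, condition, peaks, r2, qc, fitted, reason)


def evaluate_fit_quality(
    fitted_curve: np.ndarray, mean_curve: np.ndarray, qc_threshold: float = 0.8
) -> tuple[float, bool]:
    """Coefficient of determination of a fit against its mean curve.

    ``r_squared = 1 - SS_res / SS_tot``; a zero-variance data curve has
    no defined r-squared (nan) and never passes QC.
    """
    y = np.asarray(mean_curve, dtype=float)
    f = np.asarray(fitted_curve, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan"), False
    ss_res = float(np.sum((y - f) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return r2, bool(r2 >= qc_threshold)
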