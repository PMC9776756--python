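"""Synthetic R-DeeP screen generator with known ground truth.

Emulates a triplicate density-gradient screen: each protein sediments
into 25 fractions under two conditions (CTRL / RNASE), its profile a sum
of 1-3 Gaussian peaks. RNase treatment moves none, part or all of the
protein amount to a different gradient position (left shift toward
lighter fractions, right shift, or precipitation into fractions > 23).
Measurement noise is multiplicative lognormal per measurement plus a
per-channel (fraction x condition x replicate) loading bias, mimicking
reporter-ion quantification where each fraction is one multiplexed run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError

#: integer sample grid of the gradient — fraction 1 (top, light) .. 25 (bottom, dense)
FRACTIONS = np.arange(1, 26)

CONDITIONS = ("CTRL", "RNASE")

#: scenario kinds understood by the generator
SCENARIO_KINDS = ("none", "left_partial", "left_complete", "right", "precipitation")

#: default scenario mixture: majority of the proteome is RNA-independent,
#: most real shifts go left (complexes lose mass when RNA is degraded)
DEFAULT_MIXTURE = {
    "none": 0.60,
    "left_complete": 0.25,
    "right": 0.05,
    "precipitation": 0.05,
    "left_partial": 0.05,
}


@dataclass(frozen=True)
class GaussianPeak:
    """One Gaussian component of a sedimentation profile.

    amplitude
        Peak height in the units of the profile (after the sum-to-100
        normalization this is "percent of protein amount per fraction").
    position
        Peak centre in continuous fraction units.
    width
        Gaussian sigma in fraction units.
    """

    amplitude: float
    position: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidParameterError(f"peak width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise InvalidParameterError(f"peak amplitude must be >= 0, got {self.amplitude}")

    @property
    def area(self) -> float:
        """Analytic area A * sigma * sqrt(2*pi)."""
        return self.amplitude * self.width * np.sqrt(2.0 * np.pi)

    def grid_area(self, fractions: np.ndarray = FRACTIONS) -> float:
        """Area restricted to the sampled gradient (sum over the grid)."""
        return float(gaussian_curve([self], fractions).sum())


def _as_peaks(peaks: Iterable) -> list[GaussianPeak]:
    out = []
    for p in peaks:
        if isinstance(p, GaussianPeak):
            out.append(p)
        else:
            a, mu, sigma = p
            out.append(GaussianPeak(a, mu, sigma))
    return out


def gaussian_curve(peaks: Iterable, fractions: np.ndarray | None = None) -> np.ndarray:
    """Evaluate a sum of Gaussian peaks on the fraction grid.

    Returns ``sum_k A_k * exp(-(f - mu_k)^2 / (2 sigma_k^2))`` at each
    fraction; an empty peak list yields all zeros.
    """
    f = FRACTIONS if fractions is None else np.asarray(fractions, dtype=float)
    curve = np.zeros_like(f, dtype=float)
    for p in _as_peaks(peaks):
        curve += p.amplitude * np.exp(-((f - p.position) ** 2) / (2.0 * p.width**2))
    return curve


@dataclass
class ShiftScenario:
    """Ground-truth behaviour of one protein under RNase treatment.

    Peaks are (amplitude_fraction, position, width) triples where the
    amplitude fractions within a condition sum to 1 (they partition the
    protein amount). ``moved_amount`` is the fraction of total protein
    that changes peak between conditions.
    """

    kind: str
    control_peaks: list[tuple[float, float, float]]
    rnase_peaks: list[tuple[float, float, float]]
    moved_amount: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigError(f"unknown scenario kind {self.kind!r}")
        for name, peaks in (("control", self.control_peaks), ("rnase", self.rnase_peaks)):
            tot = sum(p[0] for p in peaks)
            if abs(tot - 1.0) > 1e-9:
                raise ConfigError(f"{name} amplitude fractions sum to {tot}, expected 1")
            for amp, pos, width in peaks:
                if not (0 < amp <= 1):
                    raise ConfigError(f"{name} amplitude fraction {amp} outside (0,1]")
                if not (1 <= pos <= 25.5):
                    raise ConfigError(f"{name} peak position {pos} outside gradient")
                if not (0.3 <= width <= 6):
                    raise ConfigError(f"{name} peak width {width} outside [0.3, 6]")
        if not (0 <= self.moved_amount <= 1):
            raise ConfigError(f"moved_amount {self.moved_amount} outside [0,1]")
        if self.kind == "none" and self.control_peaks != self.rnase_peaks:
            raise ConfigError("kind='none' requires identical control and rnase peaks")
        if self.kind == "precipitation" and not any(p[1] > 23 for p in self.rnase_peaks):
            raise ConfigError("kind='precipitation' requires an rnase peak at fraction > 23")

    def peaks_for(self, condition: str, total: float = 100.0) -> list[GaussianPeak]:
        """Materialize the condition's peaks so the grid area equals ``total``."""
        triples = self.control_peaks if condition == "CTRL" else self.rnase_peaks
        peaks = []
        for amp_frac, pos, width in triples:
            # unit-amplitude component; rescale so its *grid* area carries amp_frac of total
            unit = GaussianPeak(1.0, pos, width)
            ga = unit.grid_area()
            peaks.append(GaussianPeak(amp_frac * total / ga, pos, width))
        return peaks


@dataclass
class NoiseModel:
    """Measurement noise of the synthetic screen.

    replicate_sigma_log
        Std of multiplicative lognormal noise per measurement; the factor
        has expectation 1 (log-mean ``-sigma^2/2``).
    channel_bias_range
        Per-channel loading biases are drawn uniformly from
        ``[1 - range, 1 + range]`` once per (fraction, condition,
        replicate), unless ``channel_bias`` is given explicitly.
    channel_bias
        Optional explicit array of shape (25, n_conditions, n_replicates),
        strictly positive.
    background
        Additive non-negative floor per fraction (scalar or length-25).
    """

    replicate_sigma_log: float = 0.15
    channel_bias_range: float = 0.2
    channel_bias: np.ndarray | None = None
    background: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if self.replicate_sigma_log < 0:
            raise ConfigError("replicate_sigma_log must be >= 0")
        if not (0 <= self.channel_bias_range < 1):
            raise ConfigError("channel_bias_range must be in [0, 1)")
        if self.channel_bias is not None:
            cb = np.asarray(self.channel_bias, dtype=float)
            if np.any(cb <= 0):
                raise ConfigError("channel_bias factors must be strictly positive")
            self.channel_bias = cb
        if np.any(np.asarray(self.background) < 0):
            raise ConfigError("background must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(replicate_sigma_log=0.0, channel_bias_range=0.0, background=0.0)

    def draw_biases(self, rng: np.random.Generator, n_rep: int) -> np.ndarray:
        if self.channel_bias is not None:
            return self.channel_bias
        if self.channel_bias_range == 0:
            return np.ones((len(FRACTIONS), len(CONDITIONS), n_rep))
        return rng.uniform(
            1.0 - self.channel_bias_range,
            1.0 + self.channel_bias_range,
            size=(len(FRACTIONS), len(CONDITIONS), n_rep),
        )


# --------------------------------------------------------------------------
# scenario sampling

def _draw_scenario(kind: str, rng: np.random.Generator) -> ShiftScenario:
    w = lambda: round(rng.uniform(1.0, 2.2), 3)

    if kind == "none":
        if rng.random() < 0.3:
            a = round(rng.uniform(0.3, 0.7), 3)
            p1, p2 = sorted(rng.uniform(3, 21, size=2))
            while p2 - p1 < 6:  # keep peaks resolvable
                p1, p2 = sorted(rng.uniform(3, 21, size=2))
            peaks = [(a, round(p1, 2), w()), (round(1 - a, 3), round(p2, 2), w())]
        else:
            peaks = [(1.0, round(rng.uniform(3, 20), 2), w())]
        return ShiftScenario("none", peaks, list(peaks), 0.0)

    if kind in ("left_complete", "left_partial"):
        pos = round(rng.uniform(9, 21), 2)
        dist = rng.uniform(3, min(8.0, pos - 1.5))
        new = round(pos - dist, 2)
        if kind == "left_complete":
            return ShiftScenario(
                "left_complete", [(1.0, pos, w())], [(1.0, new, w())], 1.0
            )
        m = round(rng.uniform(0.3, 0.6), 3)
        wc = w()
        return ShiftScenario(
            "left_partial",
            [(1.0, pos, wc)],
            [(round(1 - m, 3), pos, wc), (m, new, w())],
            m,
        )

    if kind == "right":
        pos = round(rng.uniform(3, 14), 2)
        new = round(min(22.5, pos + rng.uniform(3, 6)), 2)
        return ShiftScenario("right", [(1.0, pos, w())], [(1.0, new, w())], 1.0)

    if kind == "precipitation":
        pos = round(rng.uniform(5, 18), 2)
        new = round(rng.uniform(23.5, 25.0), 2)
        return ShiftScenario("precipitation", [(1.0, pos, w())], [(1.0, new, w())], 1.0)

    raise ConfigError(f"unknown scenario kind {kind!r}")


def _serialize_peaks(triples: Sequence[tuple[float, float, float]]) -> str:
    return ";".join(f"{a:g}:{p:g}:{s:g}" for a, p, s in triples)


def parse_peaks(text: str) -> list[tuple[float, float, float]]:
    """Inverse of the `a:pos:width;...` peak serialization used in ground-truth TSVs."""
    if not text:
        return []
    out = []
    for chunk in text.split(";"):
        a, p, s = chunk.split(":")
        out.append((float(a), float(p), float(s)))
    return out


def simulate_screen(
    n_proteins: int,
    scenario_mixture: dict[str, float] | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full screen; returns (abundance table, ground truth).

    The abundance table is long-format with columns ``protein_id,
    condition, replicate, fraction, intensity`` covering the complete
    ``n_proteins x 2 x n_replicates x 25`` grid. The ground-truth table
    has one row per protein with the scenario kind, true peak parameters
    per condition, the moved amount and the signed true shift distance.
    """
    if n_proteins < 1:
        raise ConfigError("n_proteins must be >= 1")
    if seed is None:
        raise ConfigError("a seed is required for reproducible simulation")
    mixture = dict(DEFAULT_MIXTURE if scenario_mixture is None else scenario_mixture)
    unknown = set(mixture) - set(SCENARIO_KINDS)
    if unknown:
        raise ConfigError(f"unknown scenario kinds in mixture: {sorted(unknown)}")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"scenario mixture sums to {total}, expected 1")
    noise = NoiseModel() if noise is None else noise

    rng = np.random.default_rng(seed)
    kinds = list(mixture)
    probs = np.array([mixture[k] for k in kinds])
    drawn = rng.choice(len(kinds), size=n_proteins, p=probs)

    biases = noise.draw_biases(rng, n_replicates)
    bg = np.broadcast_to(np.asarray(noise.background, dtype=float), FRACTIONS.shape)
    s = noise.replicate_sigma_log

    width = len(str(n_proteins))
    rows_int = np.empty((n_proteins, 2, n_replicates, len(FRACTIONS)))
    truth_rows = []
    ids = []
    for i, ki in enumerate(drawn):
        kind = kinds[ki]
        scen = _draw_scenario(kind, rng)
        pid = f"P{i + 1:0{width}d}"
        ids.append(pid)
        total_amount = 10 ** rng.uniform(5.0, 6.5)
        for ci, cond in enumerate(CONDITIONS):
            clean = gaussian_curve(scen.peaks_for(cond, total_amount))
            for r in range(n_replicates):
                if s > 0:
                    factor = np.exp(rng.normal(-0.5 * s * s, s, size=len(FRACTIONS)))
                else:
                    factor = 1.0
                rows_int[i, ci, r] = clean * biases[:, ci, r] * factor + bg

        ctrl_mu = max(scen.control_peaks, key=lambda t: t[0])[1]
        if kind == "none":
            rnase_mu, dist = ctrl_mu, 0.0
        else:
            # destination = the rnase peak not present in control (the moved mass)
            ctrl_pos = {p[1] for p in scen.control_peaks}
            moved = [p for p in scen.rnase_peaks if p[1] not in ctrl_pos]
            rnase_mu = moved[0][1] if moved else ctrl_mu
            dist = rnase_mu - ctrl_mu
        truth_rows.append(
            {
                "protein_id": pid,
                "kind": kind,
                "moved_amount": scen.moved_amount,
                "ctrl_mu": ctrl_mu,
                "rnase_mu": rnase_mu,
                "shift_distance": dist,
                "control_peaks": _serialize_peaks(scen.control_peaks),
                "rnase_peaks": _serialize_peaks(scen.rnase_peaks),
            }
        )

    idx = pd.MultiIndex.from_product(
        [ids, list(CONDITIONS), range(1, n_replicates + 1), FRACTIONS.tolist()],
        names=["protein_id", "condition", "replicate", "fraction"],
    )
    table = pd.DataFrame({"intensity": rows_int.ravel()}, index=idx).reset_index()
    truth = pd.DataFrame(truth_rows)
    return table, truth
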