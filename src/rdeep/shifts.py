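"""Shift calling between control and RNase-treated profile fits.

A shift is a statistically supported displacement of a protein's fitted
profile maximum upon RNase treatment. The calling rule: the distance
between matched control and RNase maxima must exceed one fraction, and
the replicate amounts must differ significantly at one of the two
maxima. Shifts into fractions beyond the precipitation boundary
(fraction 23) are classified as precipitation — aggregation upon RNA
loss. Each shift carries a shifting coefficient in [0, 1]: the amount of
protein held by the peak times the relative amplitude change at its
maximum, i.e. the fraction of the protein population that changed
complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import ttest_ind

from .fitting import MixtureFit
from .simulate import FRACTIONS, GaussianPeak

__all__ = [
    "ShiftConfig",
    "PeakPairing",
    "ShiftCall",
    "ProteinResult",
    "match_peaks",
    "test_amplitude_difference",
    "call_shift",
    "shifting_coefficient",
    "classify_dependence",
    "call_shifts_for_protein",
    "summarize_screen",
]


@dataclass(frozen=True)
class ShiftConfig:
    """Shift-calling parameters.

    alpha                  : significance level of the amplitude test
    min_distance           : strict lower bound (fractions) on |shift distance|
    max_match_distance     : peaks farther apart than this are never paired
    complete_threshold     : shifting coefficient at or above which a protein
                             counts as completely RNA-dependent
    precipitation_fraction : RNase peaks beyond this fraction are precipitation
    """

    alpha: float = 0.05
    min_distance: float = 1.0
    max_match_distance: float = 10.0
    complete_threshold: float = 0.75
    precipitation_fraction: float = 23.0


@dataclass
class PeakPairing:
    """A matched (or one-sided) control/RNase peak pair."""

    control_peak: GaussianPeak | None
    rnase_peak: GaussianPeak | None
    distance: float | None = None  # rnase mu - control mu (or vs partner peak)

    def __post_init__(self) -> None:
        if self.control_peak is None and self.rnase_peak is None:
            raise ValueError("a pairing needs at least one peak")
        if (
            self.distance is None
            and self.control_peak is not None
            and self.rnase_peak is not None
        ):
            self.distance = self.rnase_peak.position - self.control_peak.position


@dataclass
class ShiftCall:
    """Outcome of the shift rule for one peak pairing."""

    pairing: PeakPairing
    p_control_max: float  # nan where untestable
    p_rnase_max: float
    significant: bool
    direction: str  # left | right | precipitation | none
    shifting_coefficient: float  # nan when undefined
    amplitude_delta: float
    reason: str = ""


@dataclass
class ProteinResult:
    """Per-protein aggregate over all its peak pairings."""

    protein_id: str
    shift_calls: list[ShiftCall] = field(default_factory=list)
    dependence_class: str = "independent"  # independent | partial | complete
    n_left: int = 0
    n_right: int = 0
    n_precipitated: int = 0
    novelty: str = "unknown"  # known_rbp | novel_candidate | not_shifting | unknown
    qc_pass: bool = True
    qc_reason: str = ""

    @property
    def shifting(self) -> bool:
        return any(c.significant for c in self.shift_calls)


def match_peaks(
    control: MixtureFit, rnase: MixtureFit, config: ShiftConfig | None = None
) -> list[PeakPairing]:
    """Optimal one-to-one peak assignment minimizing total |position change|.

    Pairs farther apart than ``max_match_distance`` are forbidden;
    unmatched peaks on either side become one-sided pairings (peaks lost
    or gained upon RNase treatment). Ties in total distance are broken
    toward the assignment with larger combined peak area.
    """
    cfg = config or ShiftConfig()
    cp, rp = control.peaks, rnase.peaks
    if not cp or not rp:
        return [PeakPairing(p, None) for p in cp] + [PeakPairing(None, p) for p in rp]

    cost = np.empty((len(cp), len(rp)))
    big = 1e6
    for i, c in enumerate(cp):
        for j, r in enumerate(rp):
            d = abs(r.position - c.position)
            if d > cfg.max_match_distance:
                cost[i, j] = big
            else:
                # tiny area bonus: deterministic tie-break toward heavier pairs
                cost[i, j] = d - 1e-9 * (c.area + r.area)
    rows, cols = linear_sum_assignment(cost)
    pairings, used_c, used_r = [], set(), set()
    for i, j in zip(rows, cols):
        if cost[i, j] >= big:
            continue
        pairings.append(PeakPairing(cp[i], rp[j]))
        used_c.add(i)
        used_r.add(j)
    pairings += [PeakPairing(c, None) for i, c in enumerate(cp) if i not in used_c]
    pairings += [PeakPairing(None, r) for j, r in enumerate(rp) if j not in used_r]
    pairings.sort(
        key=lambda p: p.control_peak.position if p.control_peak else p.rnase_peak.position
    )
    return pairings


def nearest_fraction(position: float) -> int:
    """Integer gradient fraction nearest a continuous peak position."""
    return int(np.clip(round(position), FRACTIONS[0], FRACTIONS[-1]))


def test_amplitude_difference(
    replicate_curves_ctrl: np.ndarray,
    replicate_curves_rnase: np.ndarray,
    position: float,
) -> float:
    """Welch two-sample t-test of replicate amounts at a peak position.

    The continuous fitted position is rounded to the nearest integer
    fraction; the test compares the normalized replicate amounts of the
    two conditions at that fraction (two-sided, unequal variances).
    Returns nan when either condition has fewer than two replicates.
    """
    f = nearest_fraction(position) - 1
    a = np.asarray(replicate_curves_ctrl, dtype=float)[:, f]
    b = np.asarray(replicate_curves_rnase, dtype=float)[:, f]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 1e-12
    p = ttest_ind(a, b, equal_var=False).pvalue
    if np.isnan(p):
        return 1.0
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def shifting_coefficient(
    pairing: PeakPairing, control: MixtureFit, rnase: MixtureFit
) -> float:
    """Fraction of the protein population that changed complex.

    Anchored at the control peak when one exists: (area of the control
    peak / 100) x relative amplitude *loss* at its maximum, where both
    fitted mixtures are evaluated at the control peak position. A gained
    RNase peak (no control partner) uses the symmetric *gain* form with
    the RNase peak area. Clipped to [0, 1]; nan when the anchoring
    mixture is zero at the anchor position.
    """
    if pairing.control_peak is not None:
        anchor = pairing.control_peak
        f_own = control.curve_at(anchor.position)
        f_other = rnase.curve_at(anchor.position)
    else:
        anchor = pairing.rnase_peak
        f_own = rnase.curve_at(anchor.position)
        f_other = control.curve_at(anchor.position)
    if f_own <= 0:
        return float("nan")
    rel_change = max(0.0, f_own - f_other) / f_own
    sc = (anchor.grid_area() / 100.0) * rel_change
    return float(np.clip(sc, 0.0, 1.0))


def call_shift(
    pairing: PeakPairing,
    control: MixtureFit,
    rnase: MixtureFit,
    replicate_curves_ctrl: np.ndarray,
    replicate_curves_rnase: np.ndarray,
    config: ShiftConfig | None = None,
) -> ShiftCall:
    """Apply the shift rule to one peak pairing.

    Significant iff the maxima are more than ``min_distance`` fractions
    apart (strict) and the replicate amounts differ at alpha at one of
    the maxima. Direction follows the sign of the distance (left =
    toward lighter fractions); a significant shift whose RNase-side peak
    sits beyond the precipitation boundary is classified precipitation.
    One-sided pairings (lost/gained peaks) take their distance from the
    nearest fitted peak of the other condition when one exists; a gained
    RNase peak beyond the boundary is precipitation on the amplitude
    test alone.
    """
    cfg = config or ShiftConfig()
    cp, rp = pairing.control_peak, pairing.rnase_peak

    p_ctrl = (
        test_amplitude_difference(replicate_curves_ctrl, replicate_curves_rnase, cp.position)
        if cp is not None
        else float("nan")
    )
    p_rnase = (
        test_amplitude_difference(replicate_curves_ctrl, replicate_curves_rnase, rp.position)
        if rp is not None
        else float("nan")
    )
    ps = [p for p in (p_ctrl, p_rnase) if not np.isnan(p)]
    p_min = min(ps) if ps else float("nan")
    p_ok = bool(ps) and p_min < cfg.alpha

    distance = pairing.distance
    reason = ""
    if distance is None:
        # one-sided pairing: measure against the nearest peak of the other side
        if cp is not None and rnase.peaks:
            partner = min(rnase.peaks, key=lambda q: abs(q.position - cp.position))
            distance = partner.position - cp.position
        elif rp is not None and control.peaks:
            partner = min(control.peaks, key=lambda q: abs(q.position - rp.position))
            distance = rp.position - partner.position
        else:
            reason = "no partner peak; distance undefined"

    dist_ok = distance is not None and abs(distance) > cfg.min_distance
    significant = bool(dist_ok and p_ok)
    if significant:
        direction = "left" if distance < 0 else "right"
        if rp is not None and rp.position > cfg.precipitation_fraction and distance > 0:
            direction = "precipitation"
    else:
        direction = "none"
        if not dist_ok and distance is not None:
            reason = f"distance {distance:+.2f} within +/-{cfg.min_distance} fraction"
        elif not p_ok:
            reason = "no significant amplitude difference at either maximum"

    # a newly gained peak past the boundary is precipitation even without
    # a measurable distance
    if (
        not significant
        and cp is None
        and rp is not None
        and rp.position > cfg.precipitation_fraction
        and p_ok
    ):
        significant, direction, reason = True, "precipitation", ""

    if significant:
        sc = shifting_coefficient(pairing, control, rnase)
    else:
        sc = shifting_coefficient(pairing, control, rnase)
        sc = 0.0 if np.isnan(sc) else sc

    anchor = cp if cp is not None else rp
    amp_delta = float(
        control.curve_at(anchor.position) - rnase.curve_at(anchor.position)
    )
    out = ShiftCall(
        pairing=PeakPairing(cp, rp, distance) if distance is not None else pairing,
        p_control_max=p_ctrl,
        p_rnase_max=p_rnase,
        significant=significant,
        direction=direction,
        shifting_coefficient=sc,
        amplitude_delta=amp_delta,
        reason=reason,
    )
    return out


def classify_dependence(
    shift_calls: list[ShiftCall], config: ShiftConfig | None = None
) -> str:
    """RNA-dependence class from the shifting coefficients.

    No significant shift -> ``independent``; the largest shifting
    coefficient among significant shifts at or above the completeness
    threshold -> ``complete``; otherwise ``partial`` (only part of the
    protein population changes complex).
    """
    cfg = config or ShiftConfig()
    sig = [c for c in shift_calls if c.significant]
    if not sig:
        return "independent"
    best = max((c.shifting_coefficient for c in sig if not np.isnan(c.shifting_coefficient)), default=0.0)
    return "complete" if best >= cfg.complete_threshold else "partial"


def _fuse_one_sided(pairings: list[PeakPairing]) -> list[PeakPairing]:
    """Fuse a lost control peak with a gained RNase peak when each is the
    other's nearest orphan — one physical move larger than the matching
    limit, not two events."""
    lost = [p for p in pairings if p.rnase_peak is None]
    gained = [p for p in pairings if p.control_peak is None]
    if not lost or not gained:
        return pairings
    fused, used = [], set()
    for lp in lost:
        cands = [g for g in gained if id(g) not in used]
        if not cands:
            fused.append(lp)
            continue
        g = min(cands, key=lambda q: abs(q.rnase_peak.position - lp.control_peak.position))
        # mutual nearest check against the other orphans
        back = min(
            (x for x in lost),
            key=lambda q: abs(q.control_peak.position - g.rnase_peak.position),
        )
        if back is lp:
            used.add(id(g))
            fused.append(PeakPairing(lp.control_peak, g.rnase_peak))
        else:
            fused.append(lp)
    fused.extend(g for g in gained if id(g) not in used)
    fused.extend(p for p in pairings if p.control_peak is not None and p.rnase_peak is not None)
    fused.sort(
        key=lambda p: p.control_peak.position if p.control_peak else p.rnase_peak.position
    )
    return fused


def call_shifts_for_protein(
    protein_id: str,
    control: MixtureFit,
    rnase: MixtureFit,
    replicate_curves_ctrl: np.ndarray,
    replicate_curves_rnase: np.ndarray,
    config: ShiftConfig | None = None,
) -> ProteinResult:
    """Match peaks and call every shift for one protein (both fits QC-passing)."""
    cfg = config or ShiftConfig()
    pairings = _fuse_one_sided(match_peaks(control, rnase, cfg))
    calls = [
        call_shift(p, control, rnase, replicate_curves_ctrl, replicate_curves_rnase, cfg)
        for p in pairings
    ]
    res = ProteinResult(protein_id=protein_id, shift_calls=calls)
    res.dependence_class = classify_dependence(calls, cfg)
    res.n_left = sum(c.direction == "left" for c in calls)
    res.n_right = sum(c.direction == "right" for c in calls)
    res.n_precipitated = sum(c.direction == "precipitation" for c in calls)
    return res


def summarize_screen(
    results: list[ProteinResult], annotations: pd.DataFrame | None = None
) -> dict:
    """Screen-level counts and novelty bookkeeping.

    A protein with multiple peaks can contribute several shifts, so the
    directional counts are shift-level while ``n_shifting`` is
    protein-level. Novel candidates are shifting proteins absent from
    prior proteome-wide RBP studies (``rbp_listed`` false); without
    annotations novelty stays ``unknown``.
    """
    have_ann = annotations is not None and len(annotations) > 0
    listed = (
        annotations["rbp_listed"].fillna(False).to_dict()
        if have_ann and "rbp_listed" in annotations
        else {}
    )
    scores = (
        annotations["rbp2go_score"].to_dict()
        if have_ann and "rbp2go_score" in annotations
        else {}
    )

    n_novel = 0
    shifting_listed_scores, nonshifting_listed_scores = [], []
    for r in results:
        if not r.shifting:
            r.novelty = "not_shifting"
        elif r.protein_id in listed:
            r.novelty = "known_rbp" if listed[r.protein_id] else "novel_candidate"
        else:
            r.novelty = "unknown"
        if r.novelty == "novel_candidate":
            n_novel += 1
        if listed.get(r.protein_id, False) and r.protein_id in scores:
            (shifting_listed_scores if r.shifting else nonshifting_listed_scores).append(
                scores[r.protein_id]
            )

    return {
        "n_proteins": len(results),
        "n_qc_failed": sum(not r.qc_pass for r in results),
        "n_shifting": sum(r.shifting for r in results),
        "n_not_shifting": sum(r.qc_pass and not r.shifting for r in results),
        "n_left_shifts": sum(r.n_left for r in results),
        "n_right_shifts": sum(r.n_right for r in results),
        "n_precipitations": sum(r.n_precipitated for r in results),
        "n_novel_candidates": n_novel if have_ann else None,
        "mean_rbp2go_shifting": (
            float(np.mean(shifting_listed_scores)) if shifting_listed_scores else None
        ),
        "mean_rbp2go_nonshifting": (
            float(np.mean(nonshifting_listed_scores)) if nonshifting_listed_scores else None
        ),
        "n_independent": sum(r.dependence_class == "independent" for r in results),
        "n_partial": sum(r.dependence_class == "partial" for r in results),
        "n_complete": sum(r.dependence_class == "complete" for r in results),
    }
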