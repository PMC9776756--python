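"""Replicate harmonization and per-protein profile scaling.

Two stages, matching how multiplexed gradient screens are processed:

1. **Between-replicate normalization** — each measurement channel (one
   condition x replicate) is rescaled within every fraction so that all
   channel totals at that fraction agree. The common per-fraction target
   is the across-channel mean of the depth-corrected totals, so the
   gradient's true fraction-to-fraction protein load is preserved while
   per-channel loading/labelling biases are removed. Factors are
   constructed from channel *share* profiles, which makes the final
   normalized profiles exactly invariant to rescaling any channel by a
   positive constant.

2. **Per-protein scaling** — for every protein and condition the
   replicate-mean curve is scaled to sum to 100 (percent of protein per
   fraction); replicate curves carry the same factor so between-replicate
   variability at each fraction is preserved for significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ScreenTable, N_FRACTIONS
from .simulate import FRACTIONS

__all__ = [
    "normalize_between_replicates",
    "normalize_protein_total",
    "NormalizedProfile",
]


def _channel_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Total intensity per (fraction, channel); channels are (condition, replicate)."""
    return df.pivot_table(
        index="fraction",
        columns=["condition", "replicate"],
        values="intensity",
        aggfunc="sum",
        fill_value=0.0,
    ).reindex(FRACTIONS, fill_value=0.0)


def normalize_between_replicates(
    screen: ScreenTable, method: str = "total"
) -> ScreenTable:
    """Equalize channel totals within each fraction.

    method="total"
        Per-fraction total-intensity scaling: channel (condition,
        replicate) is scaled at fraction f by ``target_f * G / T[f, ch]``
        where ``T`` is the observed channel total, ``target_f`` the
        across-channel mean of the channels' fraction-share profiles
        (``T[f, ch] / sum_f T[f, ch]``) and ``G`` the geometric mean of
        the channel depths. After scaling, every channel's total at
        fraction f equals ``target_f * G``.

    method="median_ratio"
        As above, but the effective channel total at each fraction is a
        median-of-ratios estimate (robust to a few dominant proteins)
        instead of the plain sum.

    Channels with zero total are flagged in the returned table's
    ``scale_flags`` attribute and left unscaled. Relative protein
    proportions within a channel are never altered.
    """
    if method not in ("total", "median_ratio"):
        raise ConfigError(f"unknown between-replicate method {method!r}")
    df = screen.data.copy()
    T = _channel_matrix(df)  # fractions x channels

    flags: list[str] = []
    depth = T.sum(axis=0)  # per-channel depth
    live = depth[depth > 0].index
    dead = depth[depth <= 0].index
    for cond, rep in dead:
        flags.append(f"channel ({cond}, replicate {rep}) has zero total; left unscaled")
    if len(live) == 0:
        out = ScreenTable(df, min_replicates=screen.min_replicates, validate=False)
        out.scale_flags = flags
        return out

    if method == "median_ratio":
        T_eff = _median_ratio_totals(df, T, live)
    else:
        T_eff = T[live]
        # re-derive depths from effective totals (identical for "total")
    depth_eff = T_eff.sum(axis=0)
    shares = T_eff / depth_eff  # each column sums to 1
    target = shares.mean(axis=1)  # average gradient load profile, sums to 1
    G = float(np.exp(np.log(depth_eff).mean()))  # geometric-mean depth

    # per (fraction, channel) factor; 1 where the channel total is zero
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = (target.to_numpy()[:, None] * G) / T_eff.to_numpy()
    gamma = pd.DataFrame(gamma, index=T_eff.index, columns=T_eff.columns)
    n_zero = int((~np.isfinite(gamma.to_numpy())).sum())
    if n_zero:
        flags.append(f"{n_zero} (fraction, channel) cells with zero total; left unscaled")
    gamma = gamma.replace([np.inf, -np.inf], np.nan).fillna(1.0)

    factor_long = gamma.stack(list(range(gamma.columns.nlevels)), future_stack=True)
    factor_long.name = "_factor"
    df = df.join(
        factor_long, on=["fraction", "condition", "replicate"]
    )
    df["_factor"] = df["_factor"].fillna(1.0)
    df["intensity"] = df["intensity"] * df["_factor"]
    df = df.drop(columns="_factor")
    out = ScreenTable(df, min_replicates=screen.min_replicates, validate=False)
    out.scale_flags = flags
    return out


def _median_ratio_totals(df: pd.DataFrame, T: pd.DataFrame, live) -> pd.DataFrame:
    """Effective channel totals via median-of-ratios within each fraction."""
    depth = T[live].sum(axis=0)
    wide = df.pivot_table(
        index=["protein_id", "fraction"],
        columns=["condition", "replicate"],
        values="intensity",
        aggfunc="first",
    )[live]
    z = wide / depth  # depth-corrected per-channel values
    ref = z.mean(axis=1)  # across-channel reference per (protein, fraction)
    ratios = z.div(ref, axis=0).where(ref > 0)
    med = ratios.groupby(level="fraction").median()
    ref_total = ref.groupby(level="fraction").sum()
    # effective total: median relative level x reference load x channel depth
    T_eff = (med.mul(ref_total, axis=0)).mul(depth, axis=1)
    T_eff = T_eff.reindex(FRACTIONS).fillna(T[live])
    return T_eff


@dataclass
class NormalizedProfile:
    """One protein x condition profile on the sum-to-100 scale."""

    protein_id: str
    condition: str
    mean_curve: np.ndarray  # (25,), sums to 100
    replicate_curves: np.ndarray  # (n_rep, 25), same scale factor as the mean
    replicate_ids: list[int]
    scale_note: dict = field(default_factory=dict)


def normalize_protein_total(
    screen: ScreenTable, min_replicates: int | None = None
) -> tuple[dict[tuple[str, str], NormalizedProfile], pd.DataFrame]:
    """Scale each protein x condition so the replicate-mean curve sums to 100.

    Returns ``(profiles, exclusions)``: profiles keyed by
    ``(protein_id, condition)`` and a table of excluded combinations with
    reasons (``not quantified`` for all-zero or absent data,
    ``insufficient replicates`` below the minimum).
    """
    min_rep = screen.min_replicates if min_replicates is None else min_replicates
    profiles: dict[tuple[str, str], NormalizedProfile] = {}
    excluded = []

    mat = screen.data.pivot_table(
        index=["protein_id", "condition", "replicate"],
        columns="fraction",
        values="intensity",
        aggfunc="first",
    ).reindex(columns=FRACTIONS)
    complete = mat.dropna(axis=0)

    seen = set()
    for (pid, cond), block in complete.groupby(level=["protein_id", "condition"]):
        seen.add((pid, cond))
        reps = block.index.get_level_values("replicate").tolist()
        curves = block.to_numpy(dtype=float)
        if len(reps) < min_rep:
            excluded.append((pid, cond, f"insufficient replicates ({len(reps)} < {min_rep})"))
            continue
        mean = curves.mean(axis=0)
        total = mean.sum()
        if total <= 0:
            excluded.append((pid, cond, "not quantified"))
            continue
        factor = 100.0 / total
        profiles[(pid, cond)] = NormalizedProfile(
            protein_id=pid,
            condition=cond,
            mean_curve=mean * factor,
            replicate_curves=curves * factor,
            replicate_ids=reps,
            scale_note={"protein_scale": factor, "n_replicates": len(reps)},
        )
    for pid in screen.data["protein_id"].unique():
        for cond in ("CTRL", "RNASE"):
            if (pid, cond) not in seen and (pid, cond) not in {
                (p, c) for p, c, _ in excluded
            }:
                excluded.append((pid, cond, "not quantified"))
    exclusions = pd.DataFrame(excluded, columns=["protein_id", "condition", "reason"])
    return profiles, exclusions
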