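"""Model/Results interface over the full screen analysis.

:class:`RnaDependenceScreen` is built from a validated abundance table
(plus optional annotations and a gradient calibration); its ``fit()``
runs the whole chain — between-replicate normalization, per-protein
sum-to-100 scaling, Gaussian mixture fitting with quality control, peak
matching, significance testing, shift calling, shifting coefficients,
RNA-dependence classes, apparent-MW size classes — and returns a
:class:`ScreenResults` carrying the per-peak, per-shift and per-protein
tables, screen-level counts and a text ``summary()``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from . import io as rio
from .calibration import CalibrationModel, ReferencePoint, classify_size, fit_calibration
from .errors import ConfigError
from .fitting import FitConfig, MixtureFit, fit_mixture
from .normalize import (
    NormalizedProfile,
    normalize_between_replicates,
    normalize_protein_total,
)
from .properties import property_report
from .shifts import (
    ProteinResult,
    ShiftConfig,
    call_shifts_for_protein,
    summarize_screen,
)

__all__ = ["ScreenConfig", "RnaDependenceScreen", "ScreenResults"]


@dataclass
class ScreenConfig:
    """All tunable parameters of a screen analysis, with field-level
    defaults matching the per-stage configs."""

    between_replicate_method: str = "total"  # total | median_ratio
    min_replicates: int = 2
    fit: FitConfig = field(default_factory=FitConfig)
    shift: ShiftConfig = field(default_factory=ShiftConfig)
    size_tol: float = 2.0  # factor defining "roughly monomeric"
    properties_qc_passing_only: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        d = dict(d)
        fit = FitConfig(**{k: _tup(v) for k, v in d.pop("fit", {}).items()})
        shift = ShiftConfig(**d.pop("shift", {}))
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(fit=fit, shift=shift, **d)

    def to_dict(self) -> dict:
        return asdict(self)


def _tup(v):
    return tuple(v) if isinstance(v, list) else v


class RnaDependenceScreen:
    """An RNase-dependence gradient screen ready to be analysed.

    Parameters
    ----------
    screen
        Validated :class:`~rdeep.io.ScreenTable` of raw intensities.
    annotations
        Optional protein annotation table (see
        :func:`~rdeep.io.read_annotations`).
    calibration_points
        Optional reference proteins for the MW calibration.
    config
        :class:`ScreenConfig`; defaults apply where omitted.
    """

    def __init__(
        self,
        screen: rio.ScreenTable,
        annotations: pd.DataFrame | None = None,
        calibration_points: list[ReferencePoint] | None = None,
        config: ScreenConfig | None = None,
    ):
        self.screen = screen
        self.annotations = annotations
        self.calibration_points = calibration_points
        self.config = config or ScreenConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RnaDependenceScreen":
        """Build from a long-format DataFrame (protein_id, condition,
        replicate, fraction, intensity)."""
        cfg = kwargs.get("config") or ScreenConfig()
        return cls(rio.ScreenTable(df, min_replicates=cfg.min_replicates), **kwargs)

    @classmethod
    def from_tsv(cls, path, format: str = "long", **kwargs) -> "RnaDependenceScreen":
        cfg = kwargs.get("config") or ScreenConfig()
        return cls(
            rio.read_screen(path, format=format, min_replicates=cfg.min_replicates),
            **kwargs,
        )

    # ------------------------------------------------------------------
    def fit(self) -> "ScreenResults":
        """Run the full analysis and return the results object."""
        cfg = self.config

        normalized = normalize_between_replicates(self.screen, cfg.between_replicate_method)
        profiles, exclusions = normalize_protein_total(normalized, cfg.min_replicates)

        fits: dict[tuple[str, str], MixtureFit] = {}
        for (pid, cond), prof in profiles.items():
            fits[(pid, cond)] = fit_mixture(
                prof.mean_curve, config=cfg.fit, protein_id=pid, condition=cond
            )

        results: list[ProteinResult] = []
        for pid in self.screen.proteins:
            cf, rf = fits.get((pid, "CTRL")), fits.get((pid, "RNASE"))
            if cf is None or rf is None:
                reason = "missing condition: " + ", ".join(
                    c for c, f in (("CTRL", cf), ("RNASE", rf)) if f is None
                )
                results.append(
                    ProteinResult(protein_id=pid, qc_pass=False, qc_reason=reason)
                )
                continue
            if not (cf.qc_pass and rf.qc_pass):
                reason = "; ".join(
                    f"{c} fit failed QC ({f.reason})"
                    for c, f in (("CTRL", cf), ("RNASE", rf))
                    if not f.qc_pass
                )
                results.append(
                    ProteinResult(protein_id=pid, qc_pass=False, qc_reason=reason)
                )
                continue
            res = call_shifts_for_protein(
                pid,
                cf,
                rf,
                profiles[(pid, "CTRL")].replicate_curves,
                profiles[(pid, "RNASE")].replicate_curves,
                cfg.shift,
            )
            results.append(res)

        calibration = (
            fit_calibration(self.calibration_points) if self.calibration_points else None
        )
        counts = summarize_screen(results, self.annotations)
        return ScreenResults(
            model=self,
            profiles=profiles,
            exclusions=exclusions,
            fits=fits,
            protein_results=results,
            calibration=calibration,
            counts=counts,
        )


class ScreenResults:
    """Results of a fitted :class:`RnaDependenceScreen`."""

    def __init__(
        self,
        model: RnaDependenceScreen,
        profiles: dict[tuple[str, str], NormalizedProfile],
        exclusions: pd.DataFrame,
        fits: dict[tuple[str, str], MixtureFit],
        protein_results: list[ProteinResult],
        calibration: CalibrationModel | None,
        counts: dict,
    ):
        self.model = model
        self.profiles = profiles
        self.exclusions = exclusions
        self.fits = fits
        self.protein_results = protein_results
        self.calibration = calibration
        self.counts = counts
        self._tables: dict[str, pd.DataFrame] | None = None

    # -- tables --------------------------------------------------------
    def _build_tables(self) -> dict[str, pd.DataFrame]:
        peak_rows = []
        for (pid, cond), f in sorted(self.fits.items()):
            for p in f.peaks:
                peak_rows.append(
                    {
                        "protein_id": pid,
                        "condition": cond,
                        "amplitude": p.amplitude,
                        "position": p.position,
                        "width": p.width,
                        "area": p.grid_area(),
                        "r_squared": f.r_squared,
                        "qc_pass": f.qc_pass,
                    }
                )
        peak_table = pd.DataFrame(
            peak_rows,
            columns=[
                "protein_id", "condition", "amplitude", "position", "width",
                "area", "r_squared", "qc_pass",
            ],
        )

        shift_rows = []
        for r in self.protein_results:
            for c in r.shift_calls:
                cp, rp = c.pairing.control_peak, c.pairing.rnase_peak
                ps = [p for p in (c.p_control_max, c.p_rnase_max) if not np.isnan(p)]
                shift_rows.append(
                    {
                        "protein_id": r.protein_id,
                        "ctrl_mu": cp.position if cp else np.nan,
                        "rnase_mu": rp.position if rp else np.nan,
                        "distance": np.nan if c.pairing.distance is None else c.pairing.distance,
                        "direction": c.direction,
                        "p_ctrl": c.p_control_max,
                        "p_rnase": c.p_rnase_max,
                        "p_min": min(ps) if ps else np.nan,
                        "shifting_coefficient": c.shifting_coefficient,
                        "amplitude_delta": c.amplitude_delta,
                        "significant": c.significant,
                        "dependence_class": r.dependence_class,
                        "reason": c.reason,
                    }
                )
        shift_table = pd.DataFrame(
            shift_rows,
            columns=[
                "protein_id", "ctrl_mu", "rnase_mu", "distance", "direction",
                "p_ctrl", "p_rnase", "p_min", "shifting_coefficient",
                "amplitude_delta", "significant", "dependence_class", "reason",
            ],
        )
        # Benjamini-Hochberg q-values over all tested pairings (reported as
        # an extra column; the default calling itself is uncorrected)
        q = np.full(len(shift_table), np.nan)
        if len(shift_table):
            tested = shift_table["p_min"].notna().to_numpy()
            if tested.any():
                q[tested] = false_discovery_control(
                    shift_table.loc[tested, "p_min"].to_numpy(), method="bh"
                )
        shift_table.insert(8, "q_value", q)

        ann = self.model.annotations
        tol = self.model.config.size_tol
        precip = self.model.config.shift.precipitation_fraction
        prot_rows = []
        for r in self.protein_results:
            cf, rf = self.fits.get((r.protein_id, "CTRL")), self.fits.get((r.protein_id, "RNASE"))
            sig_sc = [
                c.shifting_coefficient
                for c in r.shift_calls
                if c.significant and not np.isnan(c.shifting_coefficient)
            ]
            main_rnase = (
                max(rf.peaks, key=lambda p: p.grid_area()) if rf and rf.peaks else None
            )
            mono = np.nan
            if ann is not None and "monomeric_mw_kda" in getattr(ann, "columns", []):
                mono = ann["monomeric_mw_kda"].get(r.protein_id, np.nan)
            apparent = (
                self.calibration.apparent_mw(main_rnase.position)
                if self.calibration and main_rnase
                else np.nan
            )
            size = ""
            if r.shifting and self.calibration and main_rnase is not None:
                size = classify_size(
                    None if np.isnan(mono) else float(mono),
                    main_rnase.position,
                    self.calibration,
                    tol=tol,
                    precipitation_fraction=precip,
                )
            prot_rows.append(
                {
                    "protein_id": r.protein_id,
                    "qc_pass": r.qc_pass,
                    "qc_reason": r.qc_reason,
                    "n_peaks_ctrl": cf.n_peaks if cf else 0,
                    "n_peaks_rnase": rf.n_peaks if rf else 0,
                    "r2_ctrl": cf.r_squared if cf else np.nan,
                    "r2_rnase": rf.r_squared if rf else np.nan,
                    "shifting": r.shifting,
                    "dependence_class": r.dependence_class,
                    "n_left": r.n_left,
                    "n_right": r.n_right,
                    "n_precipitated": r.n_precipitated,
                    "max_shifting_coefficient": max(sig_sc) if sig_sc else 0.0,
                    "novelty": r.novelty,
                    "main_rnase_peak": main_rnase.position if main_rnase else np.nan,
                    "apparent_mw_kda": apparent,
                    "monomeric_mw_kda": mono,
                    "size_class": size,
                }
            )
        protein_table = pd.DataFrame(prot_rows)
        return {"peaks": peak_table, "shifts": shift_table, "proteins": protein_table}

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        if self._tables is None:
            self._tables = self._build_tables()
        return self._tables

    @property
    def peak_table(self) -> pd.DataFrame:
        return self.tables["peaks"]

    @property
    def shift_table(self) -> pd.DataFrame:
        return self.tables["shifts"]

    @property
    def protein_table(self) -> pd.DataFrame:
        return self.tables["proteins"]

    # -- analysis extras ----------------------------------------------
    def compare_properties(self, qc_passing_only: bool | None = None) -> pd.DataFrame:
        """Shifting vs non-shifting Wilcoxon comparisons on the annotations."""
        if self.model.annotations is None:
            raise ConfigError("no annotation table was provided to the model")
        flag = (
            self.model.config.properties_qc_passing_only
            if qc_passing_only is None
            else qc_passing_only
        )
        return property_report(
            self.protein_results, self.model.annotations, qc_passing_only=flag
        )

    def size_class_fractions(self) -> dict[str, float]:
        """Share of shifting proteins per post-RNase size class."""
        sizes = self.protein_table.loc[
            self.protein_table["size_class"] != "", "size_class"
        ]
        n = len(sizes)
        return {} if n == 0 else (sizes.value_counts() / n).to_dict()

    def summary(self) -> str:
        """Human-readable screen summary."""
        c = self.counts
        lines = [
            "RNA-dependence screen summary",
            "=============================",
            f"proteins analysed            {c['n_proteins']:>6}",
            f"  failed fit QC / incomplete {c['n_qc_failed']:>6}",
            f"proteins with >=1 shift      {c['n_shifting']:>6}",
            f"  left shifts (calls)        {c['n_left_shifts']:>6}",
            f"  right shifts (calls)       {c['n_right_shifts']:>6}",
            f"  precipitations (calls)     {c['n_precipitations']:>6}",
            f"RNA-independent proteins     {c['n_independent']:>6}",
            f"partially RNA-dependent      {c['n_partial']:>6}",
            f"completely RNA-dependent     {c['n_complete']:>6}",
        ]
        if c.get("n_novel_candidates") is not None:
            lines.append(f"novel RBP candidates         {c['n_novel_candidates']:>6}")
        if c.get("mean_rbp2go_shifting") is not None and c.get("mean_rbp2go_nonshifting") is not None:
            lines.append(
                "mean RBP2GO score (shifting vs non-shifting listed RBPs)  "
                f"{c['mean_rbp2go_shifting']:.2f} vs {c['mean_rbp2go_nonshifting']:.2f}"
            )
        if self.calibration is not None:
            lines.append(
                f"MW calibration: log10(kDa) = {self.calibration.slope:.4f} x fraction "
                f"+ {self.calibration.intercept:.4f}"
            )
            fracs = self.size_class_fractions()
            if fracs:
                lines.append(
                    "post-RNase size classes: "
                    + ", ".join(f"{k} {100 * v:.0f}%" for k, v in sorted(fracs.items()))
                )
        return "\n".join(lines)

    # -- output --------------------------------------------------------
    def save(self, outdir, manifest_extra: dict | None = None) -> dict:
        """Write result tables and a JSON run manifest; returns the paths."""
        outdir = Path(outdir)
        paths = rio.write_results(self, outdir)
        self.exclusions.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
        manifest = {
            "config": self.model.config.to_dict(),
            "counts": self.counts,
            **(manifest_extra or {}),
        }
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        paths["manifest"] = mpath
        return paths

    def plot_profile(self, protein_id: str, ax=None):
        """Plot normalized mean curves and their Gaussian fits for one protein."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        from .simulate import FRACTIONS

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        colors = {"CTRL": "tab:green", "RNASE": "tab:red"}
        for cond in ("CTRL", "RNASE"):
            prof = self.profiles.get((protein_id, cond))
            if prof is None:
                continue
            ax.plot(FRACTIONS, prof.mean_curve, "o-", ms=3, lw=0.8, color=colors[cond], label=f"{cond} data")
            f = self.fits.get((protein_id, cond))
            if f is not None and f.peaks:
                x = np.linspace(1, 25, 400)
                ax.plot(x, f.curve_at(x), color=colors[cond], lw=2, alpha=0.6, label=f"{cond} fit")
        ax.set_xlabel("fraction")
        ax.set_ylabel("protein amount (sum = 100)")
        ax.set_title(protein_id)
        ax.legend(fontsize=8)
        return ax
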