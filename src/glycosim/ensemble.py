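"""Control-vs-KO ensembles of per-sample flux curves.

One sample-specific model per proteomics sample is swept over the glucose
grid; group statistics use the sample (n-1) standard deviation.  Grid
points that failed to converge for a sample are excluded from that group's
statistics at that point (pairwise exclusion, logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError
from .model import KineticModel
from .proteomics import GROUP_CONTROL, GROUP_KO, ScalingFactors, instantiate_sample_model
from .steady_state import FluxCurve, glucose_sweep, integrate_to_steady_state

log = logging.getLogger(__name__)


@dataclass
class EnsembleResult:
    """Per-sample flux curves plus group mean/SD and KO-control differences."""

    grid: np.ndarray
    curves: dict[str, FluxCurve]  # sample id -> curve
    groups: dict[str, str]  # sample id -> group label

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.curves if self.groups[s] == group]

    def tidy(self) -> pd.DataFrame:
        """Long-format table: sample, group, glucose_mM, glc_flux, lac_flux,
        converged."""
        frames = []
        for sid, curve in self.curves.items():
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sid,
                        "group": self.groups[sid],
                        "glucose_mM": curve.grid,
                        "glc_flux": curve.glc_flux,
                        "lac_flux": curve.lac_flux,
                        "converged": curve.converged,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def group_stats(self) -> pd.DataFrame:
        """Per grid point and group: mean, sample SD (n-1) and n for each
        exchange flux.  Non-converged points are excluded; a group with a
        single usable sample reports SD as NaN (undefined), never 0."""
        rows = []
        for group in sorted(set(self.groups.values())):
            sids = self.samples_in(group)
            for i, glc in enumerate(self.grid):
                vals = {
                    "glc_flux": [
                        self.curves[s].glc_flux[i]
                        for s in sids
                        if self.curves[s].converged[i]
                    ],
                    "lac_flux": [
                        self.curves[s].lac_flux[i]
                        for s in sids
                        if self.curves[s].converged[i]
                    ],
                }
                row = {"group": group, "glucose_mM": glc, "n": len(vals["glc_flux"])}
                for key, v in vals.items():
                    arr = np.asarray(v, dtype=float)
                    row[f"{key}_mean"] = arr.mean() if arr.size else np.nan
                    row[f"{key}_sd"] = (
                        arr.std(ddof=1) if arr.size > 1 else np.nan
                    )
                rows.append(row)
        return pd.DataFrame(rows)

    def difference(
        self, group_a: str = GROUP_KO, group_b: str = GROUP_CONTROL
    ) -> pd.DataFrame:
        """Per-grid-point (group_a mean - group_b mean) for both fluxes."""
        stats = self.group_stats()
        a = stats[stats["group"] == group_a].set_index("glucose_mM")
        b = stats[stats["group"] == group_b].set_index("glucose_mM")
        return pd.DataFrame(
            {
                "glucose_mM": a.index,
                "glc_flux_diff": (a["glc_flux_mean"] - b["glc_flux_mean"]).to_numpy(),
                "lac_flux_diff": (a["lac_flux_mean"] - b["lac_flux_mean"]).to_numpy(),
            }
        ).reset_index(drop=True)


def simulate_ensemble(
    base: KineticModel,
    factors: ScalingFactors,
    grid,
    hard_ko_group: dict[str, list[str]] | None = None,
    clip: tuple[float, float] | None = None,
    **tolerances,
) -> EnsembleResult:
    """One glucose sweep per sample via its scaled model instantiation.

    ``hard_ko_group`` optionally maps a group label to reactions forced to
    zero activity for that group's samples (in silico deletion).
    Deterministic given its inputs.  A sample failing at every grid point
    raises :class:`ConvergenceError` naming the sample.
    """
    groups = factors.groups
    if not groups:
        raise ValidationError("scaling factors carry no group labels")
    if len(set(groups.values())) < 2:
        raise ValidationError("need at least two groups (control and KO)")
    hard_ko_group = hard_ko_group or {}

    grid = np.asarray(grid, dtype=float)

    # Warm start every sample from the base model's steady state at the
    # first grid point: scaled models are perturbations of the base, and a
    # good initial guess avoids long stiff transients per sample.
    x0 = None
    try:
        warm = base.copy()
        clamp = warm.sweep_clamp or "Glc_ext"
        if clamp in warm.clamp_values and grid.size:
            warm.clamp_values[clamp] = float(grid[0])
        warm_res = integrate_to_steady_state(warm, **tolerances)
        if warm_res.converged:
            x0 = warm_res.state
    except ConvergenceError:
        pass

    curves: dict[str, FluxCurve] = {}
    for sid in factors.samples:
        hard = hard_ko_group.get(groups[sid], [])
        inst = instantiate_sample_model(base, factors, sid, hard_ko=hard, clip=clip)
        curve = glucose_sweep(inst, grid, x0=x0, **tolerances)
        n_bad = int((~curve.converged).sum())
        if n_bad:
            log.warning("sample %s: %d/%d grid points not converged", sid, n_bad, grid.size)
        if n_bad == grid.size:
            raise ConvergenceError(f"sample {sid} failed at every grid point")
        curves[sid] = curve
    return EnsembleResult(grid=grid, curves=curves, groups=dict(groups))


@dataclass
class DirectionReport:
    """Descriptive comparison of KO vs control exchange fluxes (no test)."""

    glucose_mM: np.ndarray
    glc_diff: np.ndarray  # KO mean - control mean, glucose uptake
    lac_diff: np.ndarray  # KO mean - control mean, lactate release
    fraction_glc_elevated: float
    fraction_lac_elevated: float
    direction: str  # "elevated glycolysis in KO" | "reduced ..." | "none" | "mixed"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "glucose_mM": self.glucose_mM,
                "glc_flux_diff": self.glc_diff,
                "lac_flux_diff": self.lac_diff,
                "glc_elevated": self.glc_diff > 0,
                "lac_elevated": self.lac_diff > 0,
            }
        )


def compare_glycolysis(
    ensemble: EnsembleResult,
    ko_group: str = GROUP_KO,
    control_group: str = GROUP_CONTROL,
) -> DirectionReport:
    """Sign of (KO - control) glucose consumption and lactate production
    per grid point, and the fraction of points where KO exceeds control."""
    for group in (ko_group, control_group):
        if not ensemble.samples_in(group):
            raise ValidationError(f"group {group!r} has no samples")
    diff = ensemble.difference(ko_group, control_group)
    glc = diff["glc_flux_diff"].to_numpy()
    lac = diff["lac_flux_diff"].to_numpy()
    usable_g = np.isfinite(glc)
    usable_l = np.isfinite(lac)
    frac_g = float(np.mean(glc[usable_g] > 0)) if usable_g.any() else np.nan
    frac_l = float(np.mean(lac[usable_l] > 0)) if usable_l.any() else np.nan

    if np.all(glc[usable_g] == 0) and np.all(lac[usable_l] == 0):
        direction = "none"
    elif frac_g == 1.0 and frac_l == 1.0:
        direction = "elevated glycolysis in KO"
    elif frac_g == 0.0 and frac_l == 0.0 and np.any(glc[usable_g] < 0):
        direction = "reduced glycolysis in KO"
    else:
        direction = "mixed"
    return DirectionReport(
        glucose_mM=diff["glucose_mM"].to_numpy(),
        glc_diff=glc,
        lac_diff=lac,
        fraction_glc_elevated=frac_g,
        fraction_lac_elevated=frac_l,
        direction=direction,
    )
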