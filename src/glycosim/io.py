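"""File formats: proteomics CSV/TSV, group CSV, enzyme-map YAML, factor and
flux-curve CSV, ensemble outputs.

CSV dialect: comma-separated, UTF-8, header row, '.' decimal.  Floats are
written with repr-level precision (17 significant digits) so write-then-read
round-trips are value-exact and byte-deterministic.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .proteomics import EnzymeMap, ProteomicsTable, ScalingFactors, validate_enzyme_map
from .steady_state import FluxCurve

FLOAT_FMT = "%.17g"


def _read_table(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip", **kwargs)
    except (pd.errors.ParserError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


# -- proteomics -------------------------------------------------------------

def read_proteomics(table_path, groups_path) -> ProteomicsTable:
    """Intensity CSV/TSV (first column = gene symbol, header = sample ids)
    plus a two-column group file (sample_id, group)."""
    df = _read_table(table_path, index_col=0)
    df.index = df.index.astype(str)
    for j, col in enumerate(df.columns):
        bad = pd.to_numeric(df[col], errors="coerce")
        mask = bad.isna() & df[col].notna()
        if mask.any():
            row = str(df.index[mask.argmax()])
            raise ParseError(
                f"{table_path}: non-numeric intensity at row {row!r}, "
                f"column {col!r}"
            )
        df[col] = bad
    if df.isna().any().any():
        col = df.columns[df.isna().any().argmax()]
        row = str(df.index[df[col].isna().argmax()])
        raise ParseError(f"{table_path}: missing value at row {row!r}, column {col!r}")

    gdf = _read_table(groups_path)
    if gdf.shape[1] < 2:
        raise ParseError(f"{groups_path}: expected columns sample_id, group")
    groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    return ProteomicsTable(intensities=df, groups=groups)


def write_proteomics(table: ProteomicsTable, table_path, groups_path) -> None:
    df = table.intensities.copy()
    df.index.name = "gene"
    df.to_csv(table_path, float_format=FLOAT_FMT)
    with open(groups_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "group"])
        for sid in table.samples:
            w.writerow([sid, table.groups[sid]])


# -- enzyme map -------------------------------------------------------------

def read_enzyme_map(path) -> EnzymeMap:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ParseError(f"{path}: expected a mapping reaction -> gene list")
    return validate_enzyme_map(
        {str(k): [str(g) for g in (v or [])] for k, v in doc.items()}
    )


def write_enzyme_map(emap: EnzymeMap, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in emap.items()}, fh, sort_keys=True)


# -- scaling factors --------------------------------------------------------

def write_scaling_factors(factors: ScalingFactors, path) -> None:
    """Tidy CSV: reaction, sample, group, factor, control_mean, provenance."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["reaction", "sample", "group", "factor", "control_mean", "provenance"])
        for rid in factors.factors.index:
            prov = factors.provenance.loc[rid]
            cm = factors.control_mean.loc[rid]
            for sid in factors.samples:
                w.writerow(
                    [
                        rid,
                        sid,
                        factors.groups.get(sid, ""),
                        FLOAT_FMT % factors.factors.loc[rid, sid],
                        "" if pd.isna(cm) else FLOAT_FMT % cm,
                        prov,
                    ]
                )


def read_scaling_factors(path) -> ScalingFactors:
    df = _read_table(path)
    need = {"reaction", "sample", "factor", "provenance"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    fac = df.pivot(index="reaction", columns="sample", values="factor")
    cm = df.groupby("reaction")["control_mean"].first()
    prov = df.groupby("reaction")["provenance"].first()
    groups = {}
    if "group" in df.columns:
        groups = {
            str(s): str(g)
            for s, g in df.dropna(subset=["group"])
            .groupby("sample")["group"]
            .first()
            .items()
            if str(g)
        }
    order = list(dict.fromkeys(df["reaction"]))
    sample_order = list(dict.fromkeys(df["sample"].astype(str)))
    return ScalingFactors(
        factors=fac.reindex(index=order, columns=sample_order),
        control_mean=cm.reindex(order),
        provenance=prov.reindex(order),
        groups=groups,
    )


# -- flux curves ------------------------------------------------------------

def write_flux_curve(curve: FluxCurve, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["glucose_mM", "glc_flux", "lac_flux", "converged"])
        for g, a, b, c in zip(curve.grid, curve.glc_flux, curve.lac_flux, curve.converged):
            w.writerow([FLOAT_FMT % g, FLOAT_FMT % a, FLOAT_FMT % b, bool(c)])


def read_flux_curve(path) -> FluxCurve:
    df = _read_table(path)
    need = {"glucose_mM", "glc_flux", "lac_flux", "converged"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    return FluxCurve(
        grid=df["glucose_mM"].to_numpy(dtype=float),
        glc_flux=df["glc_flux"].to_numpy(dtype=float),
        lac_flux=df["lac_flux"].to_numpy(dtype=float),
        converged=df["converged"].astype(bool).to_numpy(),
    )


# -- ensembles --------------------------------------------------------------

def write_ensemble(ensemble, tidy_path, summary_path) -> None:
    """Tidy per-sample CSV plus the per-group mean/SD summary CSV."""
    ensemble.tidy().to_csv(tidy_path, index=False, float_format=FLOAT_FMT)
    ensemble.group_stats().to_csv(summary_path, index=False, float_format=FLOAT_FMT)


def plot_ensemble(ensemble, path, ko_group="KO", control_group="control") -> None:
    """Mean line + SD band per group for both exchange fluxes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats = ensemble.group_stats()
    colors = {ko_group: "tab:red", control_group: "tab:blue"}
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, flux, title in zip(
        axes, ("glc_flux", "lac_flux"), ("Glucose exchange flux", "Lactate exchange flux")
    ):
        for group, sub in stats.groupby("group"):
            x = sub["glucose_mM"].to_numpy()
            mean = sub[f"{flux}_mean"].to_numpy()
            sd = sub[f"{flux}_sd"].to_numpy()
            c = colors.get(group)
            ax.plot(x, mean, label=group, color=c)
            band = np.nan_to_num(sd)
            ax.fill_between(x, mean - band, mean + band, alpha=0.25, color=c)
        ax.set_xlabel("external glucose (mM)")
        ax.set_ylabel("flux (mM/min)")
        ax.set_title(title)
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
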