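"""Per-sample Vmax scaling from proteomics intensity tables.

The scaling law: a sample's maximal enzyme activity is the control-group
mean activity multiplied by the ratio of the sample's protein abundance to
the control-group mean abundance.  Isoform intensities mapped to the same
reaction are summed (isozyme activities add); reactions without a measured
gene keep factor 1 and are flagged ``default_unmeasured``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import KineticModel

log = logging.getLogger(__name__)

GROUP_CONTROL = "control"
GROUP_KO = "KO"

PROVENANCE_MEASURED = "measured"
PROVENANCE_DEFAULT = "default_unmeasured"


@dataclass
class ProteomicsTable:
    """Genes x samples intensity matrix with group labels."""

    intensities: pd.DataFrame  # index: gene symbols, columns: sample ids
    groups: dict[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        df = self.intensities
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate gene symbols: {dupes}")
        vals = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("intensities must be finite")
        if np.any(vals < 0):
            raise ValidationError("intensities must be nonnegative")
        missing = [s for s in df.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        if not any(g == GROUP_CONTROL for g in self.groups.values()):
            raise ValidationError("need at least one control sample")

    @property
    def genes(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def control_samples(self) -> list[str]:
        return [s for s in self.samples if self.groups[s] == GROUP_CONTROL]


# reaction id -> gene symbols whose summed intensity constitutes that activity
EnzymeMap = dict[str, list[str]]


def validate_enzyme_map(emap: Mapping[str, Sequence[str]]) -> EnzymeMap:
    out: EnzymeMap = {}
    for rid, genes in emap.items():
        genes = [str(g) for g in genes]
        if len({g.casefold() for g in genes}) != len(genes):
            raise ValidationError(f"enzyme map for {rid}: duplicate gene symbols")
        out[str(rid)] = genes
    return out


def aggregate_isoforms(
    table: ProteomicsTable, emap: Mapping[str, Sequence[str]]
) -> tuple[pd.DataFrame, list[str]]:
    """Sum mapped gene intensities per reaction.

    Gene symbols are matched case-insensitively (mouse vs human casing);
    case-folded matches are logged.  Returns the reaction x sample abundance
    matrix and the list of unmeasured reaction ids (no mapped gene present).
    """
    emap = validate_enzyme_map(emap)
    by_fold = {g.casefold(): g for g in table.genes}
    rows = {}
    unmeasured: list[str] = []
    for rid, genes in emap.items():
        present = []
        for g in genes:
            if g in table.intensities.index:
                present.append(g)
            elif g.casefold() in by_fold:
                actual = by_fold[g.casefold()]
                log.info(
                    "enzyme map %s: gene %s matched table row %s by case-folding",
                    rid, g, actual,
                )
                present.append(actual)
        if not present:
            unmeasured.append(rid)
            continue
        rows[rid] = table.intensities.loc[present].sum(axis=0)
    abundance = pd.DataFrame(rows).T
    if abundance.empty:
        abundance = pd.DataFrame(columns=table.samples)
    abundance = abundance.reindex(columns=table.samples)
    return abundance, unmeasured


@dataclass
class ScalingFactors:
    """Per-sample, per-reaction multiplicative Vmax factors."""

    factors: pd.DataFrame  # index: reaction ids, columns: sample ids
    control_mean: pd.Series  # reaction -> mean control abundance
    provenance: pd.Series  # reaction -> measured | default_unmeasured
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.factors.columns)

    def for_sample(self, sample_id: str) -> dict[str, float]:
        if sample_id not in self.factors.columns:
            raise ValidationError(f"unknown sample {sample_id!r}")
        return self.factors[sample_id].to_dict()


def compute_scaling_factors(
    table: ProteomicsTable, emap: Mapping[str, Sequence[str]]
) -> ScalingFactors:
    """factor[sample, reaction] = abundance / mean control abundance.

    A reaction whose control-mean abundance is 0 is demoted to unmeasured
    (factor 1) with a warning; no division by zero is ever performed.
    """
    abundance, unmeasured = aggregate_isoforms(table, emap)
    controls = table.control_samples()

    reactions = list(validate_enzyme_map(emap))
    factors = pd.DataFrame(1.0, index=reactions, columns=table.samples)
    control_mean = pd.Series(np.nan, index=pd.Index(reactions), dtype=float)
    provenance = pd.Series(PROVENANCE_DEFAULT, index=pd.Index(reactions))

    for rid in abundance.index:
        mean_ctrl = abundance.loc[rid, controls].mean()
        if mean_ctrl == 0:
            log.warning(
                "reaction %s: control-mean abundance is 0; demoted to unmeasured",
                rid,
            )
            unmeasured.append(rid)
            continue
        factors.loc[rid] = abundance.loc[rid] / mean_ctrl
        control_mean.loc[rid] = mean_ctrl
        provenance.loc[rid] = PROVENANCE_MEASURED

    for rid in unmeasured:
        log.info("reaction %s: unmeasured, factor defaults to 1", rid)

    return ScalingFactors(
        factors=factors,
        control_mean=control_mean,
        provenance=provenance,
        groups=dict(table.groups),
    )


def instantiate_sample_model(
    base: KineticModel,
    factors: ScalingFactors,
    sample_id: str,
    hard_ko: Sequence[str] = (),
    clip: tuple[float, float] | None = None,
) -> KineticModel:
    """Non-destructively build the sample-specific model.

    Every scalable reaction's forward (and explicit reverse) vmax is
    multiplied by the sample's factor; equilibrium constants and all other
    parameters are untouched.  ``hard_ko`` forces the listed reactions'
    factor to 0 (in silico deletion); outside that mode, nonpositive
    factors are rejected.  ``clip`` optionally bounds factors (guard rail,
    off by default; clipping is logged).
    """
    fmap = factors.for_sample(sample_id)
    for rid in hard_ko:
        fmap[rid] = 0.0
    for rid, f in fmap.items():
        if rid not in set(hard_ko) and not f > 0:
            raise ValidationError(
                f"sample {sample_id}: nonpositive factor {f!r} for reaction "
                f"{rid} (use hard_ko for in silico deletion)"
            )
        if clip is not None and rid not in set(hard_ko):
            lo, hi = clip
            clipped = min(max(f, lo), hi)
            if clipped != f:
                log.warning(
                    "sample %s: factor for %s clipped %g -> %g",
                    sample_id, rid, f, clipped,
                )
                fmap[rid] = clipped
    inst = base.copy()
    inst.scale_vmax(fmap)
    inst.name = f"{base.name}[{sample_id}]"
    return inst
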