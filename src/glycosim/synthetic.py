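"""Synthetic proteomics tables and analytic toy models.

The intensity generator emulates group-structured DIA-style data with
multiplicative (lognormal) noise and a configurable Bpgm knockdown factor,
so the whole pipeline is testable without any deposited data.  The toy
linear chain has a closed-form steady state and serves as the analytic
oracle for the integrators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import KineticModel, Metabolite, RateLaw, Reaction, build_reference_model
from .proteomics import GROUP_CONTROL, GROUP_KO, EnzymeMap, ProteomicsTable

#: Baseline intensities for the reference-model enzymes.  Order-of-magnitude
#: placeholders (arbitrary DIA intensity units), deliberately chosen as
#: powers of two so that zero-noise fold-change recovery is bitwise exact.
DEFAULT_BASELINES: dict[str, float] = {
    "Slc2a1": 2.0**18, "Slc2a2": 2.0**17, "Hk1": 2.0**19, "Hk2": 2.0**17,
    "G6pc": 2.0**16, "Gpi1": 2.0**20, "Pfkl": 2.0**18, "Pfkm": 2.0**17,
    "Pfkp": 2.0**16, "Fbp1": 2.0**17, "Pfkfb3": 2.0**15, "Aldoa": 2.0**21,
    "Tpi1": 2.0**21, "Gapdh": 2.0**22, "Pgk1": 2.0**20, "Bpgm": 2.0**18,
    "Pgp": 2.0**15, "Pgam1": 2.0**19, "Eno1": 2.0**20, "Pkm": 2.0**20,
    "Ldha": 2.0**21, "Ldhb": 2.0**18, "Slc16a1": 2.0**17, "Pcx": 2.0**17,
    "Pck1": 2.0**18, "Mdh1": 2.0**19, "Mdh2": 2.0**19, "Akr1b1": 2.0**18,
    "Sord": 2.0**17, "Slc2a5": 2.0**15, "Khk": 2.0**16, "Aldob": 2.0**19,
}

DEFAULT_BPGM_FOLD_CHANGE = 0.05


@dataclass
class SynthSpec:
    """Specification of a synthetic group-structured proteomics table."""

    n_control: int = 6
    n_ko: int = 6
    baseline: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    fold_changes: dict[str, float] = field(
        default_factory=lambda: {"Bpgm": DEFAULT_BPGM_FOLD_CHANGE}
    )
    noise_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_ko < 1:
            raise ValidationError("need at least one sample per group")
        for g, b in self.baseline.items():
            if not b > 0:
                raise ValidationError(f"baseline for {g} must be > 0")
        for g, fc in self.fold_changes.items():
            if fc < 0:
                raise ValidationError(f"fold change for {g} must be >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def generate_proteomics(spec: SynthSpec) -> ProteomicsTable:
    """intensity(g, s) = baseline(g) * FC(g if s in KO) * exp(eps),
    eps ~ Normal(0, sigma^2), independent per cell; deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.baseline)
    ctrl = [f"control_{i + 1}" for i in range(spec.n_control)]
    ko = [f"KO_{i + 1}" for i in range(spec.n_ko)]
    samples = ctrl + ko
    base = np.array([spec.baseline[g] for g in genes])[:, None]
    fc = np.array([spec.fold_changes.get(g, 1.0) for g in genes])[:, None]
    mean = np.hstack(
        [np.repeat(base, len(ctrl), axis=1), np.repeat(base * fc, len(ko), axis=1)]
    )
    if spec.noise_sigma > 0:
        mean = mean * np.exp(
            rng.normal(0.0, spec.noise_sigma, size=mean.shape)
        )
    df = pd.DataFrame(mean, index=pd.Index(genes, name="gene"), columns=samples)
    groups = {s: GROUP_CONTROL for s in ctrl} | {s: GROUP_KO for s in ko}
    return ProteomicsTable(intensities=df, groups=groups)


@dataclass
class ToyModelSpec:
    """Open two-species linear chain: constant uptake k0 into X1,
    conversion X1 -> X2 at k1*x1, export at k2*x2.

    Closed-form steady state: x1* = k0/k1, x2* = k0/k2, throughput k0.
    """

    k0: float = 1.0
    k1: float = 2.0
    k2: float = 4.0

    def __post_init__(self) -> None:
        if self.k0 < 0 or not self.k1 > 0 or not self.k2 > 0:
            raise ValidationError("toy chain needs k0 >= 0, k1 > 0, k2 > 0")

    def steady_state(self) -> tuple[float, float]:
        return self.k0 / self.k1, self.k0 / self.k2


def generate_toy_chain(spec: ToyModelSpec) -> KineticModel:
    """Build the analytic toy chain as a regular :class:`KineticModel`."""
    mets = [
        Metabolite("X1", "intermediate 1", "dynamic", 1, init_conc=1e-6),
        Metabolite("X2", "intermediate 2", "dynamic", 1, init_conc=1e-6),
        Metabolite("X_src", "source pool", "external", 1),
        Metabolite("X_sink", "sink pool", "external", 1),
    ]
    reactions = [
        Reaction(
            id="UPTAKE",
            stoichiometry={"X_src": -1, "X1": 1},
            rate_law=RateLaw(
                "mass_action_reversible", vmax_forward=spec.k0, vmax_reverse=0.0
            ),
        ),
        Reaction(
            id="CONVERT",
            stoichiometry={"X1": -1, "X2": 1},
            rate_law=RateLaw(
                "mass_action_reversible", vmax_forward=spec.k1, vmax_reverse=0.0
            ),
        ),
        Reaction(
            id="EXPORT",
            stoichiometry={"X2": -1, "X_sink": 1},
            rate_law=RateLaw(
                "mass_action_reversible", vmax_forward=spec.k2, vmax_reverse=0.0
            ),
        ),
    ]
    model = KineticModel(
        metabolites=mets,
        reactions=reactions,
        clamp_values={"X_src": 1.0, "X_sink": 0.0},
        exchange_fluxes={"X1": "UPTAKE", "X2": "EXPORT"},
        name="toy_linear_chain",
    )
    model.validate()
    return model


def enzyme_map_from_model(model: KineticModel) -> EnzymeMap:
    """Reaction -> gene list, read off the model's own gene annotations."""
    return {r.id: list(r.gene_symbols) for r in model.reactions if r.gene_symbols}


def make_ko_scenario(
    n_per_group: int = 6,
    seed: int = 0,
    noise_sigma: float = 0.075,
    bpgm_fold_change: float = DEFAULT_BPGM_FOLD_CHANGE,
    fold_changes: Mapping[str, float] | None = None,
) -> tuple[ProteomicsTable, EnzymeMap]:
    """Packaged end-to-end fixture: a synthetic table covering every
    reference-model enzyme (Bpgm knocked down, everything else at fold
    change 1) plus the matching enzyme map."""
    fcs = {"Bpgm": bpgm_fold_change}
    if fold_changes:
        fcs.update(fold_changes)
    spec = SynthSpec(
        n_control=n_per_group,
        n_ko=n_per_group,
        fold_changes=fcs,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    table = generate_proteomics(spec)
    emap = enzyme_map_from_model(build_reference_model())
    return table, emap
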