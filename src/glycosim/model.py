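"""Reaction-network core: metabolites, rate laws, stoichiometry, ODE right-hand side.

The network couples glycolysis, gluconeogenesis, the 2,3-bisphosphoglycerate
shunt and the polyol pathway.  Dynamic metabolites are integrated; cofactors
(NAD/NADH, ATP/ADP, ...) and boundary metabolites (external glucose, lactate,
...) are held at fixed ("clamped") concentrations.

Units: concentrations in mM, fluxes in mM/min (referenced to cell water
volume).  Sign convention for exchange fluxes: positive glucose flux = net
uptake into the tissue; positive lactate flux = net release.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    ConsistencyError,
    NumericalError,
    ValidationError,
)

ROLE_DYNAMIC = "dynamic"
ROLE_CLAMPED = "clamped"
ROLE_EXTERNAL = "external"
ROLES = (ROLE_DYNAMIC, ROLE_CLAMPED, ROLE_EXTERNAL)

FORM_MASS_ACTION = "mass_action_reversible"
FORM_MM_IRREV = "michaelis_menten_irreversible"
FORM_MM_REV = "michaelis_menten_reversible"
FORM_TRANSPORTER = "transporter_facilitated"
RATE_FORMS = (FORM_MASS_ACTION, FORM_MM_IRREV, FORM_MM_REV, FORM_TRANSPORTER)

KIND_COMPETITIVE = "competitive_inhibitor"
KIND_ALLO_INHIB = "allosteric_inhibitor"
KIND_ALLO_ACTIV = "allosteric_activator"
MODIFIER_KINDS = (KIND_COMPETITIVE, KIND_ALLO_INHIB, KIND_ALLO_ACTIV)

#: Dynamic metabolites of the reference renal glucose-metabolism network.
REFERENCE_DYNAMIC_SET = frozenset(
    {
        "DHAP", "Fru", "Fru1P", "Fru6P", "Fru16P2", "Fru26P2", "GAP", "Glc",
        "Glc6P", "Lac", "Mal", "OA", "P", "PEP", "13P2G", "23P2G", "2PG",
        "3PG", "PP", "Pyr", "Sorb",
    }
)

#: Cofactors that must never be integrated.
REFERENCE_CLAMPED_COFACTORS = ("NAD", "NADH", "ADP", "ATP")

HALDANE_RTOL = 1e-6


@dataclass(frozen=True)
class Metabolite:
    """A chemical species of the network."""

    id: str
    name: str
    role: str
    carbon_count: int
    init_conc: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"metabolite {self.id}: unknown role {self.role!r}")
        if self.carbon_count < 0:
            raise ValidationError(f"metabolite {self.id}: negative carbon count")
        if self.role == ROLE_DYNAMIC and not self.init_conc > 0:
            raise ValidationError(
                f"metabolite {self.id}: dynamic species needs init_conc > 0"
            )


@dataclass(frozen=True)
class Modifier:
    """A non-stoichiometric effector of a rate law.

    ``coupling`` is an optional tag used to toggle groups of modifiers
    (e.g. the 2,3-BPG feedback onto hexokinase) on or off at build time.
    """

    metabolite: str
    kind: str
    constant: float
    hill: float = 1.0
    coupling: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODIFIER_KINDS:
            raise ValidationError(f"unknown modifier kind {self.kind!r}")
        if not self.constant > 0:
            raise ValidationError(
                f"modifier on {self.metabolite}: constant must be > 0"
            )
        if not self.hill > 0:
            raise ValidationError(f"modifier on {self.metabolite}: hill must be > 0")


@dataclass
class RateLaw:
    """Kinetic law of one reaction.

    ``km`` maps metabolite id -> Michaelis constant (mM).  Only metabolites
    with a ``km`` entry enter the kinetics of Michaelis-Menten forms; mass
    action uses the stoichiometry directly.  For reversible forms either
    ``vmax_reverse`` or ``keq`` (or both, checked for Haldane consistency)
    must be supplied.
    """

    form: str
    vmax_forward: float
    vmax_reverse: float | None = None
    keq: float | None = None
    km: dict[str, float] = field(default_factory=dict)
    modifiers: list[Modifier] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.form not in RATE_FORMS:
            raise ValidationError(f"unknown rate-law form {self.form!r}")
        if not self.vmax_forward >= 0:
            raise ValidationError("vmax_forward must be >= 0")
        for met, k in self.km.items():
            if not k > 0:
                raise ValidationError(f"Km for {met} must be > 0")
        if self.keq is not None and not self.keq > 0:
            raise ValidationError("Keq must be > 0")
        if self.vmax_reverse is not None and self.vmax_reverse < 0:
            raise ValidationError("vmax_reverse must be >= 0")


@dataclass
class Reaction:
    """A reaction: signed stoichiometry plus a rate law.

    Negative stoichiometry = consumed, positive = produced.  Clamped and
    external species appear explicitly so every reaction is elementally
    balanced.
    """

    id: str
    stoichiometry: dict[str, float]
    rate_law: RateLaw
    gene_symbols: list[str] = field(default_factory=list)

    # substrate/product lists and the Haldane Km ratio are cached: the
    # stoichiometry and Km values are immutable after model construction
    # (only vmax is rescaled by proteomics instantiation).
    @cached_property
    def substrates(self) -> list[str]:
        return [m for m, s in self.stoichiometry.items() if s < 0]

    @cached_property
    def products(self) -> list[str]:
        return [m for m, s in self.stoichiometry.items() if s > 0]

    @cached_property
    def _km_ratio(self) -> float:
        law = self.rate_law
        km_s = math.prod(law.km[m] for m in self.substrates if m in law.km)
        km_p = math.prod(law.km[m] for m in self.products if m in law.km)
        return km_p / km_s

    def reverse_vmax(self) -> float:
        """Reverse maximal rate, derived from Keq via the Haldane relation
        when not given explicitly."""
        law = self.rate_law
        if law.vmax_reverse is not None:
            return law.vmax_reverse
        if law.keq is None:
            raise ConfigurationError(
                f"reaction {self.id}: reversible law needs vmax_reverse or keq"
            )
        if law.form == FORM_MASS_ACTION:
            return law.vmax_forward / law.keq
        return law.vmax_forward * self._km_ratio / law.keq


@dataclass
class KineticModel:
    """The full network: species, reactions and clamped concentrations.

    ``clamp_values`` holds fixed concentrations for every clamped or
    external species.  ``exchange_fluxes`` names, per boundary species, the
    reaction whose flux is reported as that species' exchange flux (sign
    convention documented in the module docstring).
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    clamp_values: dict[str, float]
    exchange_fluxes: dict[str, str] = field(default_factory=dict)
    name: str = "model"
    sweep_clamp: str | None = None

    # -- derived structure ------------------------------------------------

    @cached_property
    def dynamic_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.role == ROLE_DYNAMIC]

    @cached_property
    def metabolite_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @cached_property
    def reaction_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S of shape (n dynamic species, n reactions)."""
        dyn = {m: i for i, m in enumerate(self.dynamic_ids)}
        S = np.zeros((len(dyn), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, s in rxn.stoichiometry.items():
                i = dyn.get(met)
                if i is not None:
                    S[i, j] = s
        return S

    def initial_state(self) -> np.ndarray:
        return np.array(
            [m.init_conc for m in self.metabolites if m.role == ROLE_DYNAMIC],
            dtype=float,
        )

    def state_dict(self, state: np.ndarray) -> dict[str, float]:
        return dict(zip(self.dynamic_ids, np.asarray(state, dtype=float)))

    def copy(self) -> "KineticModel":
        return copy.deepcopy(self)

    def scale_vmax(self, factors: Mapping[str, float]) -> None:
        """Multiply forward (and explicit reverse) maximal rates in place.

        Keq values are untouched, so Haldane-derived reverse rates scale
        with the forward rate automatically.
        """
        for rxn in self.reactions:
            f = factors.get(rxn.id)
            if f is None:
                continue
            rxn.rate_law.vmax_forward *= f
            if rxn.rate_law.vmax_reverse is not None:
                rxn.rate_law.vmax_reverse *= f

    # -- validation -------------------------------------------------------

    def validate(self, haldane_rtol: float = HALDANE_RTOL) -> None:
        ids = [m.id for m in self.metabolites]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dupes}")
        index = self.metabolite_index
        for sp in (m.id for m in self.metabolites if m.role != ROLE_DYNAMIC):
            if sp not in self.clamp_values:
                raise ValidationError(f"clamped/external species {sp} has no clamp value")
        for sp in self.clamp_values:
            if sp not in index:
                raise ValidationError(f"clamp value for unknown species {sp}")
            if index[sp].role == ROLE_DYNAMIC:
                raise ValidationError(f"dynamic species {sp} cannot be clamped")

        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            raise ValidationError("duplicate reaction ids")

        participating: set[str] = set()
        for rxn in self.reactions:
            self._validate_reaction(rxn, index, haldane_rtol)
            participating.update(rxn.stoichiometry)

        orphans = [m for m in self.dynamic_ids if m not in participating]
        if orphans:
            raise ValidationError(f"dynamic species in no reaction: {orphans}")

        for sp, rid in self.exchange_fluxes.items():
            if sp not in index:
                raise ValidationError(f"exchange species {sp} unknown")
            if rid not in self.reaction_index:
                raise ValidationError(f"exchange reaction {rid} unknown")

    def _validate_reaction(
        self, rxn: Reaction, index: dict[str, Metabolite], haldane_rtol: float
    ) -> None:
        for met in rxn.stoichiometry:
            if met not in index:
                raise ValidationError(f"reaction {rxn.id}: unknown metabolite {met}")
        if not rxn.substrates:
            raise ValidationError(f"reaction {rxn.id}: no substrate")
        if not rxn.products:
            raise ValidationError(f"reaction {rxn.id}: no product")

        # carbon balance across ALL participants (clamps/externals included)
        delta = sum(
            s * index[m].carbon_count for m, s in rxn.stoichiometry.items()
        )
        if abs(delta) > 1e-12:
            raise ValidationError(
                f"reaction {rxn.id}: carbon imbalance of {delta:+g} atoms"
            )

        law = rxn.rate_law
        for met in law.km:
            if met not in rxn.stoichiometry:
                raise ValidationError(
                    f"reaction {rxn.id}: Km given for non-participant {met}"
                )
        for mod in law.modifiers:
            if mod.metabolite not in index:
                raise ConsistencyError(
                    f"reaction {rxn.id}: modifier references unknown "
                    f"metabolite {mod.metabolite}"
                )
            if law.form == FORM_MASS_ACTION and mod.kind == KIND_COMPETITIVE:
                raise ValidationError(
                    f"reaction {rxn.id}: competitive inhibition is undefined "
                    "for mass-action laws"
                )

        if law.form in (FORM_MM_IRREV, FORM_MM_REV, FORM_TRANSPORTER):
            sides = [("substrate", rxn.substrates)]
            if law.form in (FORM_MM_REV, FORM_TRANSPORTER):
                sides.append(("product", rxn.products))
            for side, mets in sides:
                missing = [
                    m
                    for m in mets
                    if m not in law.km and index[m].role == ROLE_DYNAMIC
                ]
                if missing:
                    raise ConfigurationError(
                        f"reaction {rxn.id}: missing Km for {side}(s) {missing}"
                    )
                if not any(m in law.km for m in mets):
                    raise ConfigurationError(
                        f"reaction {rxn.id}: needs a Km on the {side} side"
                    )
        if law.form in (FORM_MASS_ACTION, FORM_MM_REV):
            if law.vmax_reverse is None and law.keq is None:
                raise ConfigurationError(
                    f"reaction {rxn.id}: reversible law needs vmax_reverse or keq"
                )
            if (
                law.vmax_reverse is not None
                and law.vmax_reverse > 0
                and law.keq is not None
            ):
                # Haldane consistency: validate, never silently renormalise.
                if law.form == FORM_MASS_ACTION:
                    implied = law.vmax_forward / law.vmax_reverse
                else:
                    km_s = math.prod(law.km[m] for m in rxn.substrates if m in law.km)
                    km_p = math.prod(law.km[m] for m in rxn.products if m in law.km)
                    implied = law.vmax_forward / law.vmax_reverse * km_p / km_s
                if abs(implied - law.keq) > haldane_rtol * abs(law.keq):
                    raise ValidationError(
                        f"reaction {rxn.id}: Haldane violation — Keq implied by "
                        f"vmax ratio is {implied:g}, declared {law.keq:g}"
                    )


# ---------------------------------------------------------------------------
# rate evaluation
# ---------------------------------------------------------------------------

def _pos(x: float) -> float:
    return x if x > 0.0 else 0.0


def _modifier_factors(law: RateLaw, get) -> tuple[float, float]:
    """Return (competitive denominator term, multiplicative factor)."""
    comp = 0.0
    mult = 1.0
    for mod in law.modifiers:
        x = get(mod.metabolite)
        r = (x / mod.constant) ** mod.hill if x > 0 else 0.0
        if mod.kind == KIND_COMPETITIVE:
            comp += r
        elif mod.kind == KIND_ALLO_INHIB:
            mult *= 1.0 / (1.0 + r)
        else:  # allosteric activator, saturating
            mult *= r / (1.0 + r)
    return comp, mult


def reaction_rate(
    reaction: Reaction,
    state: Mapping[str, float],
    clamps: Mapping[str, float] | None = None,
) -> float:
    """Evaluate one reaction's flux (mM/min) at the given concentrations.

    ``state`` maps dynamic metabolite ids to concentrations; ``clamps``
    supplies fixed species.  Raises :class:`ConsistencyError` when a
    referenced metabolite resolves in neither.
    """
    clamps = clamps or {}

    def get(met: str) -> float:
        if met in state:
            return state[met]
        if met in clamps:
            return clamps[met]
        raise ConsistencyError(
            f"reaction {reaction.id}: metabolite {met} not in state or clamps"
        )

    law = reaction.rate_law
    comp, mult = _modifier_factors(law, get)
    vf = law.vmax_forward

    if law.form == FORM_MASS_ACTION:
        vr = reaction.reverse_vmax()
        fwd = math.prod(get(m) ** -s for m, s in reaction.stoichiometry.items() if s < 0)
        rev = math.prod(get(m) ** s for m, s in reaction.stoichiometry.items() if s > 0)
        v = mult * (vf * fwd - vr * rev)
    elif law.form == FORM_MM_IRREV:
        num, den = vf, 1.0
        for m in reaction.substrates:
            if m in law.km:
                r = _pos(get(m)) / law.km[m]
                num *= r
                den *= 1.0 + r
        v = mult * num / (den + comp)
    elif law.form == FORM_MM_REV:
        vr = reaction.reverse_vmax()
        gs = gp = 1.0
        ds = dp = 1.0
        for m in reaction.substrates:
            if m in law.km:
                r = _pos(get(m)) / law.km[m]
                gs *= r
                ds *= 1.0 + r
        for m in reaction.products:
            if m in law.km:
                r = _pos(get(m)) / law.km[m]
                gp *= r
                dp *= 1.0 + r
        v = mult * (vf * gs - vr * gp) / (ds + dp - 1.0 + comp)
    elif law.form == FORM_TRANSPORTER:
        (sub,) = [m for m in reaction.substrates if m in law.km] or reaction.substrates[:1]
        (prod,) = [m for m in reaction.products if m in law.km] or reaction.products[:1]
        rs = _pos(get(sub)) / law.km[sub]
        rp = _pos(get(prod)) / law.km[prod]
        v = mult * vf * (rs - rp) / (1.0 + rs + rp + comp)
    else:  # pragma: no cover - guarded by RateLaw.__post_init__
        raise ValidationError(f"unknown rate-law form {law.form!r}")

    return v


def reaction_rates(model: KineticModel, state: np.ndarray) -> np.ndarray:
    """Flux vector over ``model.reactions`` at a dynamic state vector."""
    conc = model.state_dict(state)
    v = np.empty(len(model.reactions))
    for j, rxn in enumerate(model.reactions):
        vj = reaction_rate(rxn, conc, model.clamp_values)
        if not math.isfinite(vj):
            raise NumericalError(f"reaction {rxn.id}: non-finite rate {vj}")
        v[j] = vj
    return v


def rhs(model: KineticModel, state: np.ndarray) -> np.ndarray:
    """dx/dt = S·v for the dynamic species (mM/min)."""
    return model.stoichiometric_matrix() @ reaction_rates(model, state)


def carbon_balance_residual(model: KineticModel, fluxes: np.ndarray) -> float:
    """Flux-weighted net carbon creation (mM carbon/min).

    Equals carbon accumulating in the dynamic pool minus net carbon entering
    across the boundary; identically 0 for an elementally balanced network
    and equal to the introduced imbalance otherwise.
    """
    index = model.metabolite_index
    total = 0.0
    for v, rxn in zip(fluxes, model.reactions):
        delta = sum(s * index[m].carbon_count for m, s in rxn.stoichiometry.items())
        total += v * delta
    return total


def exchange_carbon_inflow(model: KineticModel, fluxes: np.ndarray) -> float:
    """Net carbon crossing into the dynamic pool from clamped/external
    species (mM carbon/min); ~0 at any converged steady state of a balanced
    open network."""
    index = model.metabolite_index
    total = 0.0
    for v, rxn in zip(fluxes, model.reactions):
        for m, s in rxn.stoichiometry.items():
            if index[m].role != ROLE_DYNAMIC:
                total -= v * s * index[m].carbon_count
    return total


# ---------------------------------------------------------------------------
# parameter-file loading
# ---------------------------------------------------------------------------

def _quantity(node, where: str) -> float:
    """Read a ``{value, unit}`` mapping; units are mandatory by design
    (transcription of kinetic constants without units is rejected)."""
    if not isinstance(node, Mapping) or "value" not in node:
        raise ConfigurationError(f"{where}: expected a {{value, unit}} mapping")
    if "unit" not in node or not str(node["unit"]).strip():
        raise ConfigurationError(f"{where}: missing units")
    try:
        return float(node["value"])
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{where}: non-numeric value {node['value']!r}") from exc


def model_from_dict(doc: Mapping, couplings: Mapping[str, bool] | None = None) -> KineticModel:
    """Build a :class:`KineticModel` from a parsed parameter document.

    ``couplings`` toggles tagged modifier groups; unknown tags are ignored,
    omitted tags default to ON.
    """
    couplings = dict(couplings or {})
    mets = []
    for node in doc.get("metabolites", []):
        mets.append(
            Metabolite(
                id=str(node["id"]),
                name=str(node.get("name", node["id"])),
                role=str(node.get("role", ROLE_DYNAMIC)),
                carbon_count=int(node.get("carbon", 0)),
                init_conc=float(node.get("init", 0.0)),
            )
        )

    clamps = {
        str(k): _quantity(vnode, f"clamp {k}")
        for k, vnode in (doc.get("clamps") or {}).items()
    }

    reactions = []
    for node in doc.get("reactions", []):
        rid = str(node["id"])
        lawnode = node.get("rate_law")
        if not isinstance(lawnode, Mapping):
            raise ConfigurationError(f"reaction {rid}: missing rate_law")
        form = str(lawnode.get("form", ""))
        if form not in RATE_FORMS:
            raise ConfigurationError(f"reaction {rid}: unknown rate-law form {form!r}")
        if "vmax" not in lawnode:
            raise ConfigurationError(f"reaction {rid}: missing parameter vmax")
        vmax = _quantity(lawnode["vmax"], f"reaction {rid}, vmax")
        vrev = (
            _quantity(lawnode["vmax_reverse"], f"reaction {rid}, vmax_reverse")
            if "vmax_reverse" in lawnode
            else None
        )
        keq = (
            _quantity(lawnode["keq"], f"reaction {rid}, keq")
            if "keq" in lawnode
            else None
        )
        km = {
            str(m): _quantity(knode, f"reaction {rid}, Km[{m}]")
            for m, knode in (lawnode.get("km") or {}).items()
        }
        modifiers = []
        for mnode in lawnode.get("modifiers") or []:
            tag = mnode.get("coupling")
            if tag is not None and not couplings.get(str(tag), True):
                continue
            modifiers.append(
                Modifier(
                    metabolite=str(mnode["metabolite"]),
                    kind=str(mnode["kind"]),
                    constant=_quantity(
                        mnode["constant"], f"reaction {rid}, modifier constant"
                    ),
                    hill=float(mnode.get("hill", 1.0)),
                    coupling=str(tag) if tag is not None else None,
                )
            )
        stoich = {str(m): float(s) for m, s in (node.get("stoichiometry") or {}).items()}
        if not stoich:
            raise ConfigurationError(f"reaction {rid}: missing stoichiometry")
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                gene_symbols=[str(g) for g in node.get("genes") or []],
                rate_law=RateLaw(
                    form=form,
                    vmax_forward=vmax,
                    vmax_reverse=vrev,
                    keq=keq,
                    km=km,
                    modifiers=modifiers,
                ),
            )
        )

    model = KineticModel(
        metabolites=mets,
        reactions=reactions,
        clamp_values=clamps,
        exchange_fluxes={
            str(k): str(v) for k, v in (doc.get("exchange_fluxes") or {}).items()
        },
        name=str(doc.get("name", "model")),
        sweep_clamp=doc.get("sweep_clamp"),
    )
    model.validate()
    return model


def load_model(path, couplings: Mapping[str, bool] | None = None) -> KineticModel:
    """Load a model from a YAML/JSON parameter file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"{path}: not a mapping document")
    return model_from_dict(doc, couplings)


def build_reference_model(
    param_source=None,
    couplings: Mapping[str, bool] | None = None,
) -> KineticModel:
    """Build the renal glucose-metabolism reference network.

    ``param_source`` may be a path to a parameter file or a parsed mapping;
    by default the packaged reference parameter set is used.  ``couplings``
    toggles the 2,3-BPG feedback terms (tags ``bpg_hk`` and ``bpg_pgam``,
    both ON by default).
    """
    if param_source is None:
        ref = resources.files("glycosim.data").joinpath("reference_model.yaml")
        doc = yaml.safe_load(ref.read_text())
    elif isinstance(param_source, Mapping):
        doc = param_source
    else:
        with open(param_source) as fh:
            doc = yaml.safe_load(fh)

    model = model_from_dict(doc, couplings)

    dyn = set(model.dynamic_ids)
    if dyn != REFERENCE_DYNAMIC_SET:
        missing = sorted(REFERENCE_DYNAMIC_SET - dyn)
        extra = sorted(dyn - REFERENCE_DYNAMIC_SET)
        raise ValidationError(
            f"reference dynamic set mismatch (missing {missing}, extra {extra})"
        )
    for cof in REFERENCE_CLAMPED_COFACTORS:
        met = model.metabolite_index.get(cof)
        if met is None or met.role != ROLE_CLAMPED or cof not in model.clamp_values:
            raise ValidationError(f"cofactor {cof} must be clamped")
    # pyruvate leaves only via lactate formation or carboxylation
    pyr_consumers = {
        r.id for r in model.reactions if r.stoichiometry.get("Pyr", 0) < 0
    }
    if not pyr_consumers <= {"LDH", "PC"}:
        raise ValidationError(
            f"unexpected pyruvate-consuming reactions: {sorted(pyr_consumers)}"
        )
    for required in ("BPGM", "BPG_PHOSPHATASE"):
        if required not in model.reaction_index:
            raise ValidationError(f"reference model must contain reaction {required}")
    return model


def model_to_dict(model: KineticModel) -> dict:
    """Serialise a model back to the parameter-document structure
    (inverse of :func:`model_from_dict` up to float representation)."""
    doc: dict = {"name": model.name}
    if model.sweep_clamp:
        doc["sweep_clamp"] = model.sweep_clamp
    doc["metabolites"] = [
        {
            "id": m.id,
            "name": m.name,
            "role": m.role,
            "carbon": m.carbon_count,
            **({"init": m.init_conc} if m.role == ROLE_DYNAMIC else {}),
        }
        for m in model.metabolites
    ]
    doc["clamps"] = {
        k: {"value": v, "unit": "mM"} for k, v in model.clamp_values.items()
    }
    rxns = []
    for r in model.reactions:
        law = r.rate_law
        lawnode: dict = {"form": law.form, "vmax": {"value": law.vmax_forward, "unit": "mM/min"}}
        if law.vmax_reverse is not None:
            lawnode["vmax_reverse"] = {"value": law.vmax_reverse, "unit": "mM/min"}
        if law.keq is not None:
            lawnode["keq"] = {"value": law.keq, "unit": "dimensionless"}
        if law.km:
            lawnode["km"] = {m: {"value": k, "unit": "mM"} for m, k in law.km.items()}
        if law.modifiers:
            lawnode["modifiers"] = [
                {
                    "metabolite": mod.metabolite,
                    "kind": mod.kind,
                    "constant": {"value": mod.constant, "unit": "mM"},
                    "hill": mod.hill,
                    **({"coupling": mod.coupling} if mod.coupling else {}),
                }
                for mod in law.modifiers
            ]
        rxns.append(
            {
                "id": r.id,
                "genes": list(r.gene_symbols),
                "stoichiometry": dict(r.stoichiometry),
                "rate_law": lawnode,
            }
        )
    doc["reactions"] = rxns
    doc["exchange_fluxes"] = dict(model.exchange_fluxes)
    return doc


def save_model(model: KineticModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)
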