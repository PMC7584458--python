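"""Kinetic, damage, and regional parameter sets.

This module is the single home of the rate symbols of the coupled
two-protein heterodimer model.  One :class:`KineticParams` instance fixes a
kinetic regime for a pair of interacting protein families (amyloid-beta and
tau in the motivating application): production and clearance of the healthy
species, clearance of the toxic species, autocatalytic conversion rates, the
one-way amyloid-to-tau coupling ``b3``, and per-species effective
diffusivities that scale the graph Laplacian.

ASCII spellings ``a1t`` and ``b1t`` are used throughout for the toxic
clearance rates (a-tilde-1, b-tilde-1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import yaml

__all__ = [
    "KineticParams",
    "DamageParams",
    "RegionalParameterMap",
    "Override",
    "preset",
    "PRESET_NAMES",
    "validate",
    "resolve_regional",
    "save_params",
    "load_params",
]

_RATE_FIELDS = ("a0", "a1", "a2", "a1t", "b0", "b1", "b2", "b1t")
_DIFF_FIELDS = ("rho_u", "rho_ut", "rho_v", "rho_vt")
_ALL_FIELDS = _RATE_FIELDS + ("b3",) + _DIFF_FIELDS


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and diffusivities of one kinetic regime.

    Parameters
    ----------
    a0, a1 : float
        Healthy amyloid-beta production and clearance rates (1/time).
    a2 : float
        Healthy-to-toxic amyloid conversion rate (1/(conc*time)).
    a1t : float
        Toxic amyloid clearance rate (1/time).
    b0, b1, b2, b1t : float
        The analogous rates for the tau protein family.
    b3 : float
        Amyloid-to-tau interaction rate (1/(conc^2*time)); toxic amyloid
        acts enzymatically on tau conversion and is not depleted.  May be
        zero (uncoupled model).
    rho_u, rho_ut, rho_v, rho_vt : float
        Per-species effective diffusivities: scale factors of the graph
        Laplacian (continuum scalar diffusivities in one dimension).
    """

    a0: float
    a1: float
    a2: float
    a1t: float
    b0: float
    b1: float
    b2: float
    b1t: float
    b3: float = 1.0
    rho_u: float = 1.0
    rho_ut: float = 1.0
    rho_v: float = 1.0
    rho_vt: float = 1.0

    def replace(self, **changes: float) -> "KineticParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)


@dataclass(frozen=True)
class DamageParams:
    """Rates of the first-order neuronal damage model.

    ``k1``/``k2`` mediate damage from toxic amyloid / toxic tau alone,
    ``k3`` damage requiring both, and ``k4`` the transneuronal
    (deafferentation) rate weighting the neighbor-damage sum.  Defaults are
    the baseline values used in the damage-progression study.
    """

    k1: float = 1e-4
    k2: float = 1e-2
    k3: float = 1e-1
    k4: float = 1e-3

    def validate(self) -> list[str]:
        return [
            f"{name} must be >= 0 (got {getattr(self, name)})"
            for name in ("k1", "k2", "k3", "k4")
            if getattr(self, name) < 0
        ]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: A node selector: explicit indices, a region-label substring, or a predicate
#: on (label, coordinate).
Selector = Union[Sequence[int], str, Callable]


@dataclass(frozen=True)
class Override:
    """A partial parameter replacement targeting a set of nodes."""

    target: Selector
    changes: dict


@dataclass(frozen=True)
class RegionalParameterMap:
    """Base kinetic parameters plus per-region overrides.

    Overrides are applied in listed order, last write wins.  Every override
    target must resolve to at least one node of the companion graph.
    """

    base: KineticParams
    overrides: tuple = field(default_factory=tuple)


def validate(p: KineticParams) -> list[str]:
    """Return a list of invariant violations (empty iff the set is valid).

    All rates must be strictly positive except ``b3`` (may vanish:
    uncoupled model) and the diffusivities (may vanish: no transport).
    """
    violations = []
    for name in _RATE_FIELDS:
        v = getattr(p, name)
        if not v > 0:
            violations.append(f"{name} must be strictly positive (got {v})")
    if p.b3 < 0:
        violations.append(f"b3 must be >= 0 (got {p.b3})")
    for name in _DIFF_FIELDS:
        v = getattr(p, name)
        if v < 0:
            violations.append(f"{name} must be >= 0 (got {v})")
    return violations


# ---------------------------------------------------------------------------
# Presets


def _table1(**changes) -> KineticParams:
    base = dict(a0=0.75, a1=1.0, a2=1.0, a1t=0.6, b0=0.5, b1=1.0, b2=1.0,
                b1t=0.4, b3=1.0,
                rho_u=1.0, rho_ut=1.0, rho_v=1.0, rho_vt=1.0)
    base.update(changes)
    return KineticParams(**base)


def _unit_rates(**changes) -> KineticParams:
    base = dict(a0=1.0, a1=1.0, a2=1.0, a1t=1.0, b0=1.0, b1=1.0, b2=1.0,
                b1t=1.0, b3=1.0,
                # inferred constant: reproduces every printed 1D front speed
                rho_u=0.01, rho_ut=0.01, rho_v=0.01, rho_vt=0.01)
    base.update(changes)
    return KineticParams(**base)


def _adni_mixed() -> tuple[KineticParams, RegionalParameterMap]:
    base = KineticParams(
        a0=1.035, a1=1.38, a2=1.38, a1t=0.828,
        b0=0.69, b1=1.38, b2=1.035, b1t=0.552, b3=4.14,
        rho_u=1.38, rho_ut=0.138, rho_v=1.38, rho_vt=0.014,
    )
    # Regional b3 modifications for secondary-tauopathy regions.
    secondary_b3 = {
        "Pars Opercularis": 7.452,
        "Rostral middle frontal gyrus": 6.707,
        "Superior frontal gyrus": 7.452,
        "Caudal middle frontal gyrus": 7.452,
        "Precentral gyrus": 5.589,
        "Postcentral gyrus": 3.726,
        "Lateral orbitofrontal cortex": 6.486,
        "Medial orbitofrontal cortex": 6.486,
        "Pars triangularis": 5.520e-6,
        "Rostral anterior cingulate": 6.210e-6,
        "Posterior cingulate cortex": 3.45,
        "Inferior temporal cortex": 13.11,
        "Middle temporal gyrus": 11.04,
        "Superior temporal sulcus": 8.97,
        "Superior temporal gyrus": 8.28,
        "Superior parietal lobule": 12.42,
        "Cuneus": 13.8,
        "Pericalcarine cortex": 13.8,
        "Inferior parietal lobule": 11.73,
        "Lateral occipital sulcus": 15.18,
        "Lingual gyrus": 13.8,
        "Fusiform gyrus": 7.59,
        "Parahippocampal gyrus": 11.04,
        "Temporal pole": 1.104e-5,
    }
    # Regions switched to a locally primary regime via (b2, b3).
    primary_b2_b3 = {
        "Entorhinal cortex": (3.125, 1.104e-5),
        "Putamen": (3.795, 3.795),
        "Pallidum": (2.76, 2.76),
        "Precuneus": (3.105, 3.105),
        "Locus coeruleus": (1.38, 1.38),
    }
    overrides = tuple(
        Override(region, {"b3": b3}) for region, b3 in secondary_b3.items()
    ) + tuple(
        Override(region, {"b2": b2, "b3": b3})
        for region, (b2, b3) in primary_b2_b3.items()
    )
    return base, RegionalParameterMap(base=base, overrides=overrides)


_PRESETS: dict[str, Callable] = {
    # Baseline primary-tauopathy parameter table.
    "primary_table1": lambda: _table1(),
    # Secondary tauopathy: same table with b2=0.75 and b3=3.
    "secondary_table1": lambda: _table1(b2=0.75, b3=3.0),
    # Homogeneous/1D phase-portrait parameter sets.
    "fig22_primary": lambda: _unit_rates(a1t=0.75, b1t=0.75, b3=0.5),
    "fig23_secondary": lambda: _unit_rates(a1t=0.75, b1t=4.0 / 3.0, b3=3.0),
    # Mixed-modality synthetic parameters with regional overrides.
    "adni_mixed_table3": _adni_mixed,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str):
    """Return a named parameter preset.

    ``adni_mixed_table3`` returns ``(KineticParams, RegionalParameterMap)``;
    every other preset returns a plain :class:`KineticParams`.
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: "
            + ", ".join(PRESET_NAMES)
        ) from None
    return factory()


# ---------------------------------------------------------------------------
# Regional resolution


def _resolve_selector(target: Selector, graph) -> list[int]:
    """Resolve a node selector against a graph; see netsim.resolve_nodes."""
    from .netsim import resolve_nodes

    return resolve_nodes(graph, target)


def resolve_regional(pmap: RegionalParameterMap, graph) -> list[KineticParams]:
    """Expand a regional map into one :class:`KineticParams` per node.

    Nodes without overrides receive the base values; overrides apply in
    listed order (last write wins).  Raises ``ValueError`` if any override
    target resolves to no node, or if a resolved parameter set violates the
    kinetic invariants.
    """
    changes_per_node: list[dict] = [{} for _ in range(graph.n_nodes)]
    for ov in pmap.overrides:
        nodes = _resolve_selector(ov.target, graph)
        if not nodes:
            raise ValueError(f"override target {ov.target!r} resolves to no node")
        for i in nodes:
            changes_per_node[i].update(ov.changes)
    out = []
    for i, changes in enumerate(changes_per_node):
        p = pmap.base.replace(**changes) if changes else pmap.base
        bad = validate(p)
        if bad:
            raise ValueError(f"override at node {i} produces invalid params: {bad}")
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Config file I/O (YAML)


def save_params(p: KineticParams, path, damage: DamageParams | None = None,
                overrides: Sequence[Override] = ()) -> None:
    """Write a flat YAML mapping of parameter names to numbers.

    Keys are exactly the field names (ASCII ``a1t``/``b1t``).  Optional
    ``damage`` rates and an ``overrides`` table keyed by region label are
    appended under their own keys.
    """
    doc: dict = {k: getattr(p, k) for k in _ALL_FIELDS}
    if damage is not None:
        doc["damage"] = damage.to_dict()
    if overrides:
        doc["overrides"] = [
            {"target": ov.target, **ov.changes} for ov in overrides
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path):
    """Read a YAML parameter file written by :func:`save_params`.

    Returns ``KineticParams`` or, if the file carries an ``overrides``
    table, ``(KineticParams, RegionalParameterMap)``.  A ``damage`` block,
    when present, is returned as a third element.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kinetic = KineticParams(**{k: float(doc[k]) for k in _ALL_FIELDS if k in doc})
    damage = DamageParams(**doc["damage"]) if "damage" in doc else None
    if "overrides" in doc:
        ovs = []
        for entry in doc["overrides"]:
            entry = dict(entry)
            target = entry.pop("target")
            ovs.append(Override(target, entry))
        pmap = RegionalParameterMap(base=kinetic, overrides=tuple(ovs))
        return (kinetic, pmap, damage) if damage is not None else (kinetic, pmap)
    return (kinetic, damage) if damage is not None else kinetic
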