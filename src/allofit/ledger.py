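"""Global/local parameter-sharing ledgers for panel fits.

A ledger assigns, for every construct in a panel and every parameter role of
a model family, one optimization *slot*.  Slots are ``global`` (shared by all
constructs), ``local`` (owned by one construct or a small group, e.g. a point
mutant and its insertion combinations), or ``fixed`` (pinned to 1 to encode a
poly-glycine decoupling insertion).  Replicates of a construct always share
every slot because assignment is keyed by construct.

:func:`build_ledger` derives the assignment from construct annotations using
the domain map (sensor 1-219, HAMP 220-260, autokinase 261-494):

* a point mutation localizes the equilibrium constant of its domain;
* a mutation within one heptad (7 residues) of a domain junction also
  localizes the coupling constant across that junction;
* a Gly insertion at 219/220 fixes ``alpha1 = 1``; at 260/261 it fixes
  ``alpha2 = 1``; at 270/271 (after the S-helix) it localizes ``alpha2``;
* combination constructs (``share_with``) reuse the base mutant's local
  slots, with insertion effects applied on top;
* explicit per-construct ``localize``/``delocalize`` overrides encode
  documented exceptions to the positional rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import yaml

__all__ = [
    "ROLES",
    "DOMAIN_MAP",
    "DEFAULT_BOUNDS",
    "ParameterSlot",
    "ParameterLedger",
    "ConstructAnnotation",
    "build_ledger",
]

#: parameter roles per model family, in canonical order
ROLES: Dict[str, Tuple[str, ...]] = {
    "three_domain": ("k_sen", "k_hamp", "k_ak", "alpha1", "alpha2", "s", "kd_off", "kd_on"),
    "two_domain": ("k_sen", "k_ak", "alpha", "s", "kd_off", "kd_on"),
    "concerted": ("k", "s", "kd_off", "kd_on"),
}

#: residue ranges (inclusive) of the three domains
DOMAIN_MAP = {"sensor": (1, 219), "hamp": (220, 260), "autokinase": (261, 494)}

_HEPTAD = 7
_JUNCTION_SENSOR_HAMP = 219  # junction between residues 219/220
_JUNCTION_HAMP_AK = 260  # junction between residues 260/261
_SHELIX_SITE = 270  # insertion site 270/271, after the S-helix

#: box bounds per role (log-uniform sampling range for multistart)
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "k_sen": (1e-5, 1e5),
    "k_hamp": (1e-5, 1e5),
    "k_ak": (1e-5, 1e5),
    "alpha1": (1e-5, 1e5),
    "alpha2": (1e-8, 1e2),
    "s": (1e-5, 1e5),
    "kd_off": (1e-8, 1e2),
    "kd_on": (1e-8, 1e2),
    "alpha": (1e-5, 1e5),
    "k": (1e-5, 1e5),
}


@dataclass(frozen=True)
class ParameterSlot:
    """One optimization slot: a role, a scope, bounds, and its datasets."""

    slot_id: str
    role: str
    scope: str  # "global" | "local" | "fixed"
    lower: float
    upper: float
    affected: FrozenSet[str]
    fixed_value: Optional[float] = None

    def __post_init__(self):
        if self.scope not in ("global", "local", "fixed"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.scope == "fixed":
            if self.fixed_value is None:
                object.__setattr__(self, "fixed_value", 1.0)
        else:
            if self.fixed_value is not None:
                raise ValueError("fixed_value only applies to fixed-scope slots")
            if not (0 < self.lower < self.upper):
                raise ValueError(
                    f"slot {self.slot_id}: bounds must satisfy 0 < lower < upper"
                )


@dataclass(frozen=True)
class ConstructAnnotation:
    """Positional annotation of one construct for ledger construction.

    ``mutations`` are residue positions of point substitutions;
    ``insertions`` are ``(site, n_gly)`` pairs where ``site`` is the residue
    preceding the insertion point (219 -> 219/220, etc.).  ``localize`` and
    ``delocalize`` apply documented exceptions after the positional rules;
    ``share_with`` names the base construct whose local slots a combination
    construct reuses.
    """

    construct_id: str
    mutations: Tuple[int, ...] = ()
    insertions: Tuple[Tuple[int, int], ...] = ()
    localize: Tuple[str, ...] = ()
    delocalize: Tuple[str, ...] = ()
    share_with: Optional[str] = None


@dataclass(frozen=True)
class ParameterLedger:
    """Slots plus the (construct, role) -> slot assignment for one family."""

    model: str
    slots: Mapping[str, ParameterSlot]
    assignment: Mapping[str, Mapping[str, str]]

    def __post_init__(self):
        if self.model not in ROLES:
            raise ValueError(f"unknown model family {self.model!r}")
        roles = ROLES[self.model]
        for construct, mapping in self.assignment.items():
            missing = set(roles) - set(mapping)
            if missing:
                raise ValueError(f"{construct}: roles {sorted(missing)} unassigned")
            for role, sid in mapping.items():
                slot = self.slots.get(sid)
                if slot is None:
                    raise ValueError(f"{construct}.{role}: unknown slot {sid}")
                if slot.role != role:
                    raise ValueError(f"{construct}.{role}: slot {sid} has role {slot.role}")

    @property
    def roles(self) -> Tuple[str, ...]:
        return ROLES[self.model]

    @property
    def constructs(self) -> Tuple[str, ...]:
        return tuple(self.assignment)

    def slot_for(self, construct: str, role: str) -> ParameterSlot:
        return self.slots[self.assignment[construct][role]]

    def free_slot_ids(self) -> Tuple[str, ...]:
        """Non-fixed slot ids in deterministic order (globals first)."""
        role_rank = {r: i for i, r in enumerate(self.roles)}
        free = [s for s in self.slots.values() if s.scope != "fixed"]
        free.sort(key=lambda s: (s.scope != "global", role_rank[s.role], s.slot_id))
        return tuple(s.slot_id for s in free)

    def fixed_slot_ids(self) -> Tuple[str, ...]:
        return tuple(sorted(s.slot_id for s in self.slots.values() if s.scope == "fixed"))

    def census(self) -> Dict[str, int]:
        counts = {"global": 0, "local": 0, "fixed": 0}
        for s in self.slots.values():
            counts[s.scope] += 1
        counts["free"] = counts["global"] + counts["local"]
        counts["total"] = len(self.slots)
        return counts

    def params_for(self, construct: str, values: Mapping[str, float]) -> Dict[str, float]:
        """Resolve a construct's role -> value mapping from slot values."""
        out = {}
        for role in self.roles:
            slot = self.slot_for(construct, role)
            out[role] = slot.fixed_value if slot.scope == "fixed" else values[slot.slot_id]
        return out

    def to_yaml(self) -> str:
        all_constructs = set(self.assignment)
        slots = []
        for sid in sorted(self.slots):
            s = self.slots[sid]
            slots.append(
                {
                    "slot_id": s.slot_id,
                    "role": s.role,
                    "scope": s.scope,
                    "lower_bound": s.lower,
                    "upper_bound": s.upper,
                    "fixed_value": s.fixed_value,
                    "affected_datasets": (
                        "ALL" if set(s.affected) == all_constructs else sorted(s.affected)
                    ),
                }
            )
        payload = {
            "model": self.model,
            "constructs": list(self.assignment),
            "slots": slots,
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ParameterLedger":
        payload = yaml.safe_load(text)
        model = payload["model"]
        raw = payload["slots"]
        all_constructs = payload.get("constructs")
        if all_constructs is None:
            all_constructs = sorted(
                {
                    c
                    for entry in raw
                    if entry["affected_datasets"] != "ALL"
                    for c in entry["affected_datasets"]
                }
            )
        slots = {}
        assignment: Dict[str, Dict[str, str]] = {}
        for entry in raw:
            affected = entry["affected_datasets"]
            if affected == "ALL":
                affected = list(all_constructs)
            slot = ParameterSlot(
                slot_id=entry["slot_id"],
                role=entry["role"],
                scope=entry["scope"],
                lower=entry["lower_bound"],
                upper=entry["upper_bound"],
                affected=frozenset(affected),
                fixed_value=entry.get("fixed_value") if entry["scope"] == "fixed" else None,
            )
            if slot.slot_id in slots:
                raise ValueError(f"duplicate slot id {slot.slot_id}")
            slots[slot.slot_id] = slot
            for construct in affected:
                roles = assignment.setdefault(construct, {})
                if slot.role in roles:
                    raise ValueError(
                        f"conflicting assignment for ({construct}, {slot.role}): "
                        f"{roles[slot.role]} vs {slot.slot_id}"
                    )
                roles[slot.role] = slot.slot_id
        return cls(model=model, slots=slots, assignment=assignment)


def _domain_of(position: int) -> str:
    for name, (lo, hi) in DOMAIN_MAP.items():
        if lo <= position <= hi:
            return name
    raise ValueError(f"residue position {position} lies outside the domain map")


_DOMAIN_ROLE = {"sensor": "k_sen", "hamp": "k_hamp", "autokinase": "k_ak"}

# role translation from the three-domain vocabulary used in annotations
_ROLE_MAP = {
    "two_domain": {
        "k_sen": "k_sen",
        "k_hamp": "alpha",
        "k_ak": "k_ak",
        "alpha1": "alpha",
        "alpha2": "alpha",
    },
    "concerted": {
        "k_sen": "k",
        "k_hamp": "k",
        "k_ak": "k",
        "alpha1": "k",
        "alpha2": "k",
    },
}


def _rule_roles(ann: ConstructAnnotation):
    """Apply the positional rules; returns (local_roles, fixed_roles, own_local)."""
    local = set()
    for pos in ann.mutations:
        local.add(_DOMAIN_ROLE[_domain_of(pos)])
        if abs(pos - _JUNCTION_SENSOR_HAMP) <= _HEPTAD or abs(pos - (_JUNCTION_SENSOR_HAMP + 1)) <= _HEPTAD:
            local.add("alpha1")
        if abs(pos - _JUNCTION_HAMP_AK) <= _HEPTAD or abs(pos - (_JUNCTION_HAMP_AK + 1)) <= _HEPTAD:
            local.add("alpha2")
    fixed = set()
    own = set()
    for site, n_gly in ann.insertions:
        if n_gly < 1:
            raise ValueError(f"{ann.construct_id}: insertion length must be >= 1")
        if site == _JUNCTION_SENSOR_HAMP:
            fixed.add("alpha1")
        elif site == _JUNCTION_HAMP_AK:
            fixed.add("alpha2")
        elif site == _SHELIX_SITE:
            own.add("alpha2")
        else:
            raise ValueError(
                f"{ann.construct_id}: insertion site {site} is not a recognized "
                "junction (219/220, 260/261 or 270/271)"
            )
    local |= set(ann.localize)
    local -= set(ann.delocalize)
    local -= fixed
    return local, fixed, own


def build_ledger(
    annotations: Sequence[ConstructAnnotation],
    model: str = "three_domain",
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> ParameterLedger:
    """Construct a :class:`ParameterLedger` from construct annotations.

    ``model`` selects the family; for the reduced families the three-domain
    role vocabulary of the annotations is translated (HAMP equilibrium and
    both couplings collapse onto ``alpha`` for ``two_domain`` and onto the
    single ``k`` for ``concerted``, where decoupling insertions become local
    perturbations of ``k`` since a one-domain model has no coupling to cut).
    """
    if model not in ROLES:
        raise ValueError(f"unknown model family {model!r}")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    by_id = {a.construct_id: a for a in annotations}
    if len(by_id) != len(annotations):
        raise ValueError("duplicate construct ids in annotations")

    # resolve positional rules in the three-domain vocabulary
    resolved: Dict[str, Tuple[set, set, set]] = {}
    for ann in annotations:
        if ann.share_with is not None and ann.share_with not in by_id:
            raise ValueError(f"{ann.construct_id}: unknown share_with base {ann.share_with!r}")
        resolved[ann.construct_id] = _rule_roles(ann)

    def translate(roles: Iterable[str]) -> set:
        if model == "three_domain":
            return set(roles)
        mapping = _ROLE_MAP[model]
        return {mapping[r] for r in roles if r in mapping}

    role_order = ROLES[model]
    all_ids = [a.construct_id for a in annotations]

    # (role, owner) -> slot members; owner is the construct that owns the slot
    local_groups: Dict[Tuple[str, str], set] = {}
    fixed_groups: Dict[Tuple[str, str], set] = {}
    per_construct: Dict[str, Dict[str, Tuple[str, str]]] = {}  # role -> (scope, owner)

    for ann in annotations:
        cid = ann.construct_id
        local, fixed, own = resolved[cid]
        entry: Dict[str, Tuple[str, str]] = {}
        if ann.share_with is not None:
            base = ann.share_with
            base_local, base_fixed, _ = resolved[base]
            # inherit the base construct's local slots
            for role in translate(base_local):
                entry[role] = ("local", base)
            # inherit the base's fixed slots so a repeated insertion shares one
            for role in translate(base_fixed) if model != "concerted" else set():
                entry[role] = ("fixed", base)
            if model == "concerted" and (base_local or base_fixed or resolved[base][2]):
                entry["k"] = ("local", base)
        for role in translate(local):
            entry.setdefault(role, ("local", cid))
        if model == "concerted":
            # any perturbation (mutation or insertion) localizes k
            if local or fixed or own:
                entry["k"] = entry.get("k", ("local", ann.share_with or cid))
        else:
            for role in translate(own):
                entry[role] = ("local", cid)  # own-local always overrides sharing
            for role in translate(fixed):
                cur = entry.get(role)
                if cur is None or cur[0] != "fixed":
                    entry[role] = ("fixed", cid)
        per_construct[cid] = entry
        for role, (scope, owner) in entry.items():
            group = fixed_groups if scope == "fixed" else local_groups
            group.setdefault((role, owner), set()).add(cid)

    slots: Dict[str, ParameterSlot] = {}
    assignment: Dict[str, Dict[str, str]] = {c: {} for c in all_ids}

    for role in role_order:
        covered = {c for c, e in per_construct.items() if role in e}
        remaining = [c for c in all_ids if c not in covered]
        if remaining:
            sid = f"{role}:global"
            slots[sid] = ParameterSlot(
                slot_id=sid,
                role=role,
                scope="global",
                lower=bounds[role][0],
                upper=bounds[role][1],
                affected=frozenset(remaining),
            )
            for c in remaining:
                assignment[c][role] = sid

    for (role, owner), members in sorted(local_groups.items()):
        sid = f"{role}:local:{owner}"
        slots[sid] = ParameterSlot(
            slot_id=sid,
            role=role,
            scope="local",
            lower=bounds[role][0],
            upper=bounds[role][1],
            affected=frozenset(members),
        )
        for c in members:
            assignment[c][role] = sid
    for (role, owner), members in sorted(fixed_groups.items()):
        sid = f"{role}:fixed:{owner}"
        slots[sid] = ParameterSlot(
            slot_id=sid,
            role=role,
            scope="fixed",
            lower=bounds[role][0],
            upper=bounds[role][1],
            affected=frozenset(members),
            fixed_value=1.0,
        )
        for c in members:
            assignment[c][role] = sid

    return ParameterLedger(model=model, slots=slots, assignment=assignment)
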