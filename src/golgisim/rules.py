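"""Enzyme rule table: substrate predicates, actions and site multiplicity.

The nine-enzyme table (ManI, Mgat1, ManII, Mgat2, Fut8, Mgat4, Mgat5, GalT,
SiaT) is loaded from a bundled YAML file so that pathway variants are
configuration changes rather than code changes.  Two behaviours matter for
the kinetics downstream:

* ordinary rules fire with multiplicity 1 and a deterministic product;
* site rules (GalT, SiaT) act on whichever antenna slots currently carry
  the substrate sugar — their propensity scales with the number of eligible
  slots and the acted slot is chosen uniformly, so each eligible slot is an
  equal-rate transition to a distinct product state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import yaml

from .glycans import ARM_FIELDS, Antenna, GlycanState

ENZYMES = ("ManI", "Mgat1", "ManII", "Mgat2", "Fut8", "Mgat4", "Mgat5", "GalT", "SiaT")

_FIELD_NAMES = ("glc", "man", "fuc", *ARM_FIELDS)


class RuleNotApplicableError(ValueError):
    """Raised when a rule's substrate predicate does not hold for a state."""


def _parse_value(name: str, raw):
    if name in ("glc", "man", "fuc"):
        return int(raw)
    return Antenna(raw)


def _compile_condition(name: str, raw) -> Callable[[GlycanState], bool]:
    if name not in _FIELD_NAMES:
        raise ValueError(f"unknown predicate field {name!r} in rule file")
    if isinstance(raw, dict):
        if "not" in raw:
            forbidden = _parse_value(name, raw["not"])
            return lambda s: getattr(s, name) != forbidden
        lo, hi = int(raw["min"]), int(raw["max"])
        return lambda s: lo <= getattr(s, name) <= hi
    wanted = _parse_value(name, raw)
    return lambda s: getattr(s, name) == wanted


@dataclass(frozen=True)
class _Clause:
    predicate: Callable[[GlycanState], bool]
    changes: dict

    def matches(self, state: GlycanState) -> bool:
        return self.predicate(state)

    def apply(self, state: GlycanState) -> GlycanState:
        return state.replace(**{
            name: (getattr(state, name) + delta) if is_inc else delta
            for name, delta, is_inc in self.changes["ops"]
        })


def _compile_clause(raw: dict) -> _Clause:
    conds = [_compile_condition(k, v) for k, v in raw["when"].items()]
    ops = []
    for name, value in raw["do"].get("set", {}).items():
        ops.append((name, _parse_value(name, value), False))
    for name, delta in raw["do"].get("inc", {}).items():
        ops.append((name, int(delta), True))
    if not ops:
        raise ValueError("rule clause with empty action")
    return _Clause(
        predicate=lambda s, _c=conds: all(c(s) for c in _c),
        changes={"ops": ops},
    )


@dataclass(frozen=True)
class EnzymeRule:
    """Specificity and action of one enzyme.

    ``products(state)`` lists every distinct product reachable in one event,
    one entry per eligible site; ``multiplicity`` is its length.  For
    non-site rules the list has a single entry.
    """

    enzyme: str
    clauses: tuple = ()
    site_from: Antenna | None = None
    site_to: Antenna | None = None
    _site_slots: tuple = field(default=ARM_FIELDS, repr=False)

    @property
    def is_site_rule(self) -> bool:
        return self.site_from is not None

    def applicable(self, state: GlycanState) -> bool:
        if self.is_site_rule:
            return any(getattr(state, a) is self.site_from for a in self._site_slots)
        return any(c.matches(state) for c in self.clauses)

    def multiplicity(self, state: GlycanState) -> int:
        if self.is_site_rule:
            return sum(getattr(state, a) is self.site_from for a in self._site_slots)
        return 1 if self.applicable(state) else 0

    def products(self, state: GlycanState) -> list[GlycanState]:
        if self.is_site_rule:
            return [
                state.replace(**{a: self.site_to})
                for a in self._site_slots
                if getattr(state, a) is self.site_from
            ]
        for clause in self.clauses:
            if clause.matches(state):
                return [clause.apply(state)]
        return []


def load_rules(path=None) -> list[EnzymeRule]:
    """Load an enzyme rule table from YAML (bundled table by default)."""
    if path is None:
        raw = yaml.safe_load(
            resources.files("golgisim.data").joinpath("rules.yaml").read_text()
        )
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    rules = []
    for rec in raw["rules"]:
        enzyme = rec["enzyme"]
        if enzyme not in raw["enzymes"]:
            raise ValueError(f"rule for unknown enzyme {enzyme!r}")
        if "site" in rec:
            rules.append(
                EnzymeRule(
                    enzyme=enzyme,
                    site_from=Antenna(rec["site"]["from"]),
                    site_to=Antenna(rec["site"]["to"]),
                )
            )
        else:
            rules.append(
                EnzymeRule(enzyme=enzyme, clauses=tuple(_compile_clause(c) for c in rec["clauses"]))
            )
    names = [r.enzyme for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("duplicate enzyme in rule file")
    return rules


_DEFAULT_RULES: list[EnzymeRule] | None = None


def rule_table() -> list[EnzymeRule]:
    """The canonical nine-rule mammalian pathway table (cached)."""
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def applicable_enzymes(state: GlycanState, rules=None) -> set[str]:
    rules = rule_table() if rules is None else rules
    return {r.enzyme for r in rules if r.applicable(state)}


def apply_rule(state: GlycanState, rule: EnzymeRule, site: int = 0) -> GlycanState:
    """Apply one enzymatic event; ``site`` indexes the eligible-site list."""
    prods = rule.products(state)
    if not prods:
        raise RuleNotApplicableError(
            f"{rule.enzyme} is not applicable to {state.code()}"
        )
    return prods[site]
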