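"""Read/write the BMA-style JSON model dialect.

The dialect (as emitted by map-to-model conversion for qualitative-network
tools) is::

    {
      "variables":     [{"id": 1, "name": "A", "rangeFrom": 0, "rangeTo": 1,
                         "formula": "min(var(2), 1 - var(3))"}, ...],
      "relationships": [{"fromVariable": 2, "toVariable": 1,
                         "type": "Activator"}, ...]
    }

Target-function grammar (granularity 1): ``var(id)``, ``min(...)``,
``max(...)``, the constants ``0``/``1``, and the complement ``1 - expr`` as
NOT.  ``min`` maps to AND and ``max`` to OR.  Other function symbols
(``avg``, ``ceil``, ``floor``) are rejected with a clear error, since they
cannot occur in a Boolean-valued formula built from Boolean operands.

A variable with an empty formula takes the conventional default rule from its
relationships ((OR of activators) AND NOT (OR of inhibitors)); with no
incoming relationships either, it is an input.  A top-level ``{"Model": ...}``
wrapper and capitalised key spellings are tolerated on input.
"""

from __future__ import annotations

import json
import re
from typing import Any

from .errors import DanglingReferenceError, GranularityError, UnsupportedRuleError
from .expr import And, BoolExpr, Const, Not, Or, Var, and_all, or_all
from .model import BooleanModel, Node

_TOKEN_RE = re.compile(r"\s*(min|max|avg|ceil|floor|var|\d+|[(),\-])")


def _tokenize(formula: str, owner: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(formula):
        m = _TOKEN_RE.match(formula, pos)
        if m is None:
            raise UnsupportedRuleError(
                f"{owner}: cannot tokenize formula near {formula[pos:pos + 12]!r}"
            )
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _FormulaParser:
    def __init__(self, tokens: list[str], id_to_name: dict[int, str], owner: str):
        self.tokens = tokens
        self.pos = 0
        self.id_to_name = id_to_name
        self.owner = owner

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self, expected: str | None = None) -> str:
        tok = self.peek()
        if tok is None:
            raise UnsupportedRuleError(f"{self.owner}: formula ended unexpectedly")
        if expected is not None and tok != expected:
            raise UnsupportedRuleError(
                f"{self.owner}: expected {expected!r}, found {tok!r}"
            )
        self.pos += 1
        return tok

    def parse(self) -> BoolExpr:
        expr = self.expr()
        if self.peek() is not None:
            raise UnsupportedRuleError(
                f"{self.owner}: trailing tokens {self.tokens[self.pos:]!r}"
            )
        return expr

    def expr(self) -> BoolExpr:
        tok = self.peek()
        if tok in ("avg", "ceil", "floor"):
            raise UnsupportedRuleError(
                f"{self.owner}: function {tok!r} is not Boolean-valued at granularity 1"
            )
        if tok in ("min", "max"):
            op = self.take()
            self.take("(")
            args = [self.expr()]
            while self.peek() == ",":
                self.take(",")
                args.append(self.expr())
            self.take(")")
            if len(args) == 1:
                return args[0]
            return And(tuple(args)) if op == "min" else Or(tuple(args))
        if tok == "var":
            self.take()
            self.take("(")
            ident = int(self.take())
            self.take(")")
            if ident not in self.id_to_name:
                raise DanglingReferenceError(
                    f"{self.owner}: var({ident}) refers to no declared variable"
                )
            return Var(self.id_to_name[ident])
        if tok == "(":
            self.take("(")
            inner = self.expr()
            self.take(")")
            return self._maybe_minus(inner, allow=False)
        if tok is not None and tok.isdigit():
            value = int(self.take())
            if self.peek() == "-":
                if value != 1:
                    raise UnsupportedRuleError(
                        f"{self.owner}: only the complement form '1 - expr' is supported"
                    )
                self.take("-")
                return Not(self.expr())
            if value not in (0, 1):
                raise GranularityError(
                    f"{self.owner}: constant {value} outside the Boolean range"
                )
            return Const(value)
        raise UnsupportedRuleError(f"{self.owner}: unexpected token {tok!r}")

    @staticmethod
    def _maybe_minus(expr: BoolExpr, allow: bool) -> BoolExpr:
        return expr


def _norm_keys(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k[:1].lower() + k[1:]: _norm_keys(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_norm_keys(v) for v in obj]
    return obj


def parse_bma_json(document: str, name: str | None = None) -> BooleanModel:
    """Parse a BMA-dialect JSON document into a :class:`BooleanModel`."""
    raw = _norm_keys(json.loads(document))
    if "model" in raw:
        model_name = raw.get("model", {}).get("name") or name
        raw = raw["model"]
    else:
        model_name = raw.get("name") or name
    variables = raw.get("variables", [])
    relationships = raw.get("relationships", [])

    id_to_name: dict[int, str] = {}
    for v in variables:
        ident = int(v["id"])
        vname = str(v.get("name", f"var{ident}")).strip()
        lo = int(v.get("rangeFrom", 0))
        hi = int(v.get("rangeTo", 1))
        if (lo, hi) != (0, 1):
            raise GranularityError(
                f"variable {vname!r} has range [{lo}, {hi}]; Boolean models require [0, 1]"
            )
        id_to_name[ident] = vname

    activators: dict[int, list[int]] = {}
    inhibitors: dict[int, list[int]] = {}
    for r in relationships:
        src, dst = int(r["fromVariable"]), int(r["toVariable"])
        for ident in (src, dst):
            if ident not in id_to_name:
                raise DanglingReferenceError(
                    f"relationship endpoint {ident} refers to no declared variable"
                )
        rtype = str(r["type"]).lower()
        if rtype == "activator":
            activators.setdefault(dst, []).append(src)
        elif rtype == "inhibitor":
            inhibitors.setdefault(dst, []).append(src)
        else:
            raise UnsupportedRuleError(f"unknown relationship type {r['type']!r}")

    rules: dict[str, BoolExpr] = {}
    nodes: list[Node] = []
    for v in variables:
        ident = int(v["id"])
        vname = id_to_name[ident]
        formula = str(v.get("formula", "") or "").strip()
        expr: BoolExpr | None = None
        if formula:
            expr = _FormulaParser(_tokenize(formula, vname), id_to_name, vname).parse()
        else:
            acts = [Var(id_to_name[a]) for a in activators.get(ident, [])]
            inhs = [Var(id_to_name[i]) for i in inhibitors.get(ident, [])]
            if acts and inhs:
                expr = and_all([or_all(acts), Not(or_all(inhs))])
            elif acts:
                expr = or_all(acts)
            elif inhs:
                expr = Not(or_all(inhs))
        kind = "internal" if expr is not None else "input"
        nodes.append(Node(name=vname, kind=kind,
                          annotations=(("bma_id", str(ident)),)))
        if expr is not None:
            rules[vname] = expr
    return BooleanModel(nodes=tuple(nodes), rules=rules,
                        name=model_name or "model")


def _sign_map(expr: BoolExpr, negated: bool = False,
              out: dict[str, set[str]] | None = None) -> dict[str, set[str]]:
    """Syntactic regulator signs: refs under an even/odd number of NOTs."""
    if out is None:
        out = {}
    if isinstance(expr, Var):
        out.setdefault(expr.name, set()).add("Inhibitor" if negated else "Activator")
    elif isinstance(expr, Not):
        _sign_map(expr.arg, not negated, out)
    elif isinstance(expr, (And, Or)):
        for a in expr.args:
            _sign_map(a, negated, out)
    return out


def _render(expr: BoolExpr, name_to_id: dict[str, int]) -> str:
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Var):
        return f"var({name_to_id[expr.name]})"
    if isinstance(expr, Not):
        return f"1 - {_render(expr.arg, name_to_id)}"
    if isinstance(expr, And):
        return "min(" + ", ".join(_render(a, name_to_id) for a in expr.args) + ")"
    if isinstance(expr, Or):
        return "max(" + ", ".join(_render(a, name_to_id) for a in expr.args) + ")"
    raise TypeError(type(expr).__name__)


def write_bma_json(model: BooleanModel, indent: int = 2) -> str:
    """Serialise a model to the BMA-dialect JSON (round-trips semantically)."""
    name_to_id: dict[str, int] = {}
    for n in model.nodes:
        tag = n.annotation("bma_id")
        if tag is not None and tag.isdigit() and int(tag) not in name_to_id.values():
            name_to_id[n.name] = int(tag)
    next_id = max(name_to_id.values(), default=0) + 1
    for n in model.nodes:
        if n.name not in name_to_id:
            name_to_id[n.name] = next_id
            next_id += 1

    variables = []
    relationships = []
    for n in model.nodes:
        expr = model.rules.get(n.name)
        variables.append({
            "id": name_to_id[n.name],
            "name": n.name,
            "rangeFrom": 0,
            "rangeTo": 1,
            "formula": _render(expr, name_to_id) if expr is not None else "",
        })
        if expr is not None:
            for src, signs in sorted(_sign_map(expr).items()):
                for sign in sorted(signs):
                    relationships.append({
                        "fromVariable": name_to_id[src],
                        "toVariable": name_to_id[n.name],
                        "type": sign,
                    })
    doc = {"name": model.name, "variables": variables, "relationships": relationships}
    return json.dumps(doc, indent=indent)
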