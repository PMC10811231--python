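"""SBML-qual reader (granularity 1).

Parses the qualitative-models extension of SBML level 3: one node per
qualitative species, one rule per transition, inputs being species with no
incoming transition.  Only Boolean species (``maxLevel`` 1) are accepted.

The MathML subset covered is what Boolean transitions need: ``and``, ``or``,
``not``, level comparisons (``eq``, ``geq``, ``leq``, ``gt``, ``lt``) of a
species against 0/1, bare ``ci`` references, ``cn`` constants and
``true``/``false``.  Anything else raises an unsupported-rule error naming
the affected node.
"""

from __future__ import annotations

from lxml import etree

from .errors import GranularityError, UnsupportedRuleError
from .expr import BoolExpr, Const, Not, Var, or_all
from .model import BooleanModel, Node

_QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATH_NS = "http://www.w3.org/1998/Math/MathML"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _qattr(elem: etree._Element, attr: str) -> str | None:
    v = elem.get(f"{{{_QUAL_NS}}}{attr}")
    return v if v is not None else elem.get(attr)


def _math_to_expr(elem: etree._Element, owner: str) -> BoolExpr:
    tag = _local(elem.tag)
    if tag == "math":
        children = [c for c in elem if isinstance(c.tag, str)]
        if len(children) != 1:
            raise UnsupportedRuleError(f"{owner}: math must hold one expression")
        return _math_to_expr(children[0], owner)
    if tag == "ci":
        return Var(elem.text.strip())
    if tag == "cn":
        value = int(float(elem.text.strip()))
        if value not in (0, 1):
            raise GranularityError(f"{owner}: constant {value} outside Boolean range")
        return Const(value)
    if tag == "true":
        return Const(1)
    if tag == "false":
        return Const(0)
    if tag != "apply":
        raise UnsupportedRuleError(f"{owner}: unsupported MathML element <{tag}>")

    children = [c for c in elem if isinstance(c.tag, str)]
    op, args = _local(children[0].tag), children[1:]
    if op in ("and", "or"):
        sub = [_math_to_expr(a, owner) for a in args]
        if not sub:
            raise UnsupportedRuleError(f"{owner}: empty <{op}>")
        out = sub[0]
        for s in sub[1:]:
            out = (out & s) if op == "and" else (out | s)
        return out
    if op == "not":
        if len(args) != 1:
            raise UnsupportedRuleError(f"{owner}: <not> takes one argument")
        return Not(_math_to_expr(args[0], owner))
    if op in ("eq", "geq", "leq", "gt", "lt"):
        if len(args) != 2:
            raise UnsupportedRuleError(f"{owner}: <{op}> takes two arguments")
        left, right = args
        if _local(left.tag) == "cn" and _local(right.tag) == "ci":
            # normalise to ci-op-cn by flipping the comparison
            left, right = right, left
            op = {"geq": "leq", "leq": "geq", "gt": "lt", "lt": "gt", "eq": "eq"}[op]
        if _local(left.tag) != "ci" or _local(right.tag) != "cn":
            raise UnsupportedRuleError(
                f"{owner}: comparison must be species-vs-constant"
            )
        var = Var(left.text.strip())
        level = int(float(right.text.strip()))
        if level not in (0, 1):
            raise GranularityError(f"{owner}: comparison level {level} exceeds 1")
        table = {
            ("eq", 1): var, ("eq", 0): Not(var),
            ("geq", 1): var, ("geq", 0): Const(1),
            ("leq", 0): Not(var), ("leq", 1): Const(1),
            ("gt", 0): var, ("gt", 1): Const(0),
            ("lt", 1): Not(var), ("lt", 0): Const(0),
        }
        return table[(op, level)]
    raise UnsupportedRuleError(f"{owner}: unsupported MathML operator <{op}>")


def parse_sbml_qual(document: str | bytes, name: str | None = None) -> BooleanModel:
    """Parse an SBML-qual document into a :class:`BooleanModel`."""
    if isinstance(document, str):
        document = document.encode()
    root = etree.fromstring(document)
    model_elem = next((c for c in root if _local(c.tag) == "model"), None)
    if model_elem is None:
        raise UnsupportedRuleError("document has no <model> element")
    model_name = name or model_elem.get("id") or model_elem.get("name") or "model"

    species_order: list[tuple[str, str]] = []  # (id, display name)
    for elem in model_elem.iter():
        if _local(elem.tag) == "qualitativeSpecies":
            sid = _qattr(elem, "id")
            max_level = _qattr(elem, "maxLevel")
            if max_level is not None and int(max_level) != 1:
                raise GranularityError(
                    f"species {sid!r} has maxLevel={max_level}; Boolean models require 1"
                )
            display = (_qattr(elem, "name") or sid).strip()
            species_order.append((sid, display))
    id_to_name = dict(species_order)
    if len(id_to_name) != len(species_order):
        raise ValueError("duplicate qualitative species ids")

    rules: dict[str, BoolExpr] = {}
    for trans in model_elem.iter():
        if _local(trans.tag) != "transition":
            continue
        outputs = [_qattr(e, "qualitativeSpecies") for e in trans.iter()
                   if _local(e.tag) == "output"]
        default_level = 0
        terms_at: dict[int, list[BoolExpr]] = {0: [], 1: []}
        for e in trans.iter():
            tag = _local(e.tag)
            if tag == "defaultTerm":
                default_level = int(_qattr(e, "resultLevel") or 0)
                if default_level not in (0, 1):
                    raise GranularityError("defaultTerm resultLevel exceeds 1")
            elif tag == "functionTerm":
                level = int(_qattr(e, "resultLevel") or 0)
                if level not in (0, 1):
                    raise GranularityError("functionTerm resultLevel exceeds 1")
                math = next((c for c in e if _local(c.tag) == "math"), None)
                if math is None:
                    raise UnsupportedRuleError(
                        f"transition for {outputs}: functionTerm without math"
                    )
                terms_at[level].append(_math_to_expr(math, str(outputs)))
        # value is 1 iff a level-1 term fires, or none of the level-0 terms
        # fires and the default is 1 (function terms are disjoint in SBML-qual)
        on = or_all(terms_at[1])
        if default_level == 1:
            off = or_all(terms_at[0])
            expr: BoolExpr = Not(off) if not terms_at[1] else (on | Not(off))
        else:
            expr = on
        for out_id in outputs:
            if out_id not in id_to_name:
                raise UnsupportedRuleError(f"transition output {out_id!r} undeclared")
            rules[id_to_name[out_id]] = _rename_refs(expr, id_to_name)

    nodes = tuple(
        Node(name=display, kind="internal" if display in rules else "input",
             annotations=(("sbml_id", sid),))
        for sid, display in species_order
    )
    return BooleanModel(nodes=nodes, rules=rules, name=model_name)


def _rename_refs(expr: BoolExpr, id_to_name: dict[str, str]) -> BoolExpr:
    """Map ci references given as species ids onto display names."""
    from .expr import And, Or

    if isinstance(expr, Var):
        return Var(id_to_name.get(expr.name, expr.name))
    if isinstance(expr, Not):
        return Not(_rename_refs(expr.arg, id_to_name))
    if isinstance(expr, And):
        return And(tuple(_rename_refs(a, id_to_name) for a in expr.args))
    if isinstance(expr, Or):
        return Or(tuple(_rename_refs(a, id_to_name) for a in expr.args))
    return expr
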