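"""Content-MathML → infix serialization.

SBML stores kinetic laws, rules and triggers as content MathML; graph
properties want a flat string.  This walks the ``<math>`` subtree and
prints a fixed infix dialect: single spaces around binary operators,
minimal parentheses by precedence, function calls as ``name(a, b)``.
Only the operator/function subset that appears in SBML models is
handled; anything unknown falls back to ``name(args...)`` so the
serializer is total.
"""

from __future__ import annotations

from lxml import etree

_BINOPS = {
    "plus": ("+", 1, "assoc"),
    "minus": ("-", 1, "left"),
    "times": ("*", 2, "assoc"),
    "divide": ("/", 2, "left"),
    "power": ("^", 3, "right"),
    "eq": ("==", 0, "left"),
    "neq": ("!=", 0, "left"),
    "leq": ("<=", 0, "left"),
    "lt": ("<", 0, "left"),
    "geq": (">=", 0, "left"),
    "gt": (">", 0, "left"),
    "and": ("&&", 0, "assoc"),
    "or": ("||", 0, "assoc"),
}

_FUNCTIONS = {
    "abs", "exp", "ln", "log", "floor", "ceiling", "factorial", "root",
    "sin", "cos", "tan", "sec", "csc", "cot", "sinh", "cosh", "tanh",
    "arcsin", "arccos", "arctan", "arcsinh", "arccosh", "arctanh",
    "not", "xor", "min", "max", "rem", "quotient",
}

_ATOM = 100


def _local(elem) -> str:
    return etree.QName(elem).localname


def _children(elem):
    return [c for c in elem if isinstance(c.tag, str)]


def mathml_to_infix(math_elem) -> str:
    """Serialize a ``<math>`` element (or any content-MathML node)."""
    kids = _children(math_elem)
    if _local(math_elem) == "math":
        if not kids:
            return ""
        return " ".join(_expr(k)[0] for k in kids)
    return _expr(math_elem)[0]


def _expr(elem) -> tuple[str, int]:
    """Return (text, precedence) for a MathML node."""
    name = _local(elem)
    if name == "ci" or name == "csymbol":
        return (elem.text or "").strip(), _ATOM
    if name == "cn":
        return _number(elem), _ATOM
    if name in ("true", "false", "pi", "exponentiale", "infinity", "notanumber"):
        return {"exponentiale": "e", "infinity": "INF", "notanumber": "NaN"}.get(
            name, name
        ), _ATOM
    if name == "apply":
        return _apply(elem)
    if name == "piecewise":
        parts = []
        for piece in _children(elem):
            parts.extend(_expr(k)[0] for k in _children(piece))
        return f"piecewise({', '.join(parts)})", _ATOM
    if name == "lambda":
        kids = _children(elem)
        bvars = [_expr(_children(b)[0])[0] for b in kids if _local(b) == "bvar"]
        body = [k for k in kids if _local(k) != "bvar"]
        body_s = _expr(body[0])[0] if body else ""
        return f"lambda({', '.join(bvars + [body_s])})", _ATOM
    # Unknown node: render children as a call.
    args = ", ".join(_expr(k)[0] for k in _children(elem))
    return f"{name}({args})", _ATOM


def _number(cn) -> str:
    typ = cn.get("type", "real")
    if typ == "e-notation":
        mant = (cn.text or "").strip()
        sep_tail = [(s.tail or "").strip() for s in cn if _local(s) == "sep"]
        exp = sep_tail[0] if sep_tail else "0"
        return f"{mant}e{exp}"
    if typ == "rational":
        mant = (cn.text or "").strip()
        sep_tail = [(s.tail or "").strip() for s in cn if _local(s) == "sep"]
        return f"{mant}/{sep_tail[0]}" if sep_tail else mant
    return (cn.text or "").strip()


def _apply(elem) -> tuple[str, int]:
    kids = _children(elem)
    if not kids:
        return "()", _ATOM
    head, args = kids[0], kids[1:]
    op = _local(head)

    if op == "minus" and len(args) == 1:
        text, prec = _expr(args[0])
        if prec < _ATOM and prec <= 2:
            text = f"({text})"
        return f"-{text}", 2
    if op in _BINOPS and len(args) >= 2:
        sym, prec, assoc = _BINOPS[op]
        parts = []
        for i, a in enumerate(args):
            text, aprec = _expr(a)
            need = aprec < prec or (
                aprec == prec
                and (
                    (assoc == "left" and i > 0)
                    or (assoc == "right" and i < len(args) - 1)
                )
            )
            parts.append(f"({text})" if need else text)
        return f" {sym} ".join(parts), prec
    if op == "root":
        degree = [k for k in args if _local(k) == "degree"]
        rest = [k for k in args if _local(k) != "degree"]
        arg_s = _expr(rest[0])[0] if rest else ""
        if degree:
            deg_kids = _children(degree[0])
            deg_s = _expr(deg_kids[0])[0] if deg_kids else "2"
            return f"root({deg_s}, {arg_s})", _ATOM
        return f"sqrt({arg_s})", _ATOM
    if op == "log":
        base = [k for k in args if _local(k) == "logbase"]
        rest = [k for k in args if _local(k) != "logbase"]
        arg_s = _expr(rest[0])[0] if rest else ""
        if base:
            base_kids = _children(base[0])
            base_s = _expr(base_kids[0])[0] if base_kids else "10"
            return f"log({base_s}, {arg_s})", _ATOM
        return f"log10({arg_s})", _ATOM
    if op == "ci":
        # User-defined function call: <apply><ci>f</ci> args...</apply>
        fname = (head.text or "").strip()
        return f"{fname}({', '.join(_expr(a)[0] for a in args)})", _ATOM
    if op == "csymbol":
        fname = (head.text or "").strip() or "csymbol"
        return f"{fname}({', '.join(_expr(a)[0] for a in args)})", _ATOM
    # Named function (possibly unary minus handled above).
    fname = op if op in _FUNCTIONS or op not in _BINOPS else op
    return f"{fname}({', '.join(_expr(a)[0] for a in args)})", _ATOM
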