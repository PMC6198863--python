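"""Validation and compilation of kinetic rate-law expressions.

Rate laws are ordinary arithmetic expressions over species names,
parameter names and a small function whitelist (currently ``exp``).
They are parsed with :mod:`ast`, checked against a whitelist of node
types, and compiled to plain Python code objects so that evaluating a
rate vector inside an ODE right-hand side costs microseconds.
"""

from __future__ import annotations

import ast
import math
from typing import Iterable

#: names that may never be used for species or parameters
RESERVED_NAMES = frozenset({"t", "time", "exp", "pow"})

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.USub, ast.UAdd)
_ALLOWED_CALLS = frozenset({"exp"})

_EVAL_GLOBALS = {"__builtins__": {}, "exp": math.exp}


class ExpressionError(ValueError):
    """Raised when a rate expression is syntactically or semantically invalid."""


def parse_expression(text: str) -> ast.Expression:
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:  # pragma: no cover - message content varies
        raise ExpressionError(f"invalid rate expression {text!r}: {exc.msg}") from exc
    _check(tree.body, text)
    return tree


def _check(node: ast.AST, text: str) -> None:
    if isinstance(node, ast.BinOp):
        if not isinstance(node.op, _ALLOWED_BINOPS):
            raise ExpressionError(
                f"operator {type(node.op).__name__} not allowed in {text!r}"
            )
        _check(node.left, text)
        _check(node.right, text)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, _ALLOWED_UNARY):
            raise ExpressionError(
                f"unary operator {type(node.op).__name__} not allowed in {text!r}"
            )
        _check(node.operand, text)
    elif isinstance(node, ast.Call):
        if not (isinstance(node.func, ast.Name) and node.func.id in _ALLOWED_CALLS):
            raise ExpressionError(f"only {sorted(_ALLOWED_CALLS)} calls allowed in {text!r}")
        if node.keywords or len(node.args) != 1:
            raise ExpressionError(f"{node.func.id} takes exactly one argument in {text!r}")
        _check(node.args[0], text)
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric constant in {text!r}")
    elif isinstance(node, ast.Name):
        pass
    else:
        raise ExpressionError(
            f"construct {type(node).__name__} not allowed in rate expression {text!r}"
        )


def expression_symbols(text: str) -> set[str]:
    """Return the free symbols (species/parameter names) used by ``text``."""
    tree = parse_expression(text)
    return {
        n.id
        for n in ast.walk(tree)
        if isinstance(n, ast.Name) and n.id not in _ALLOWED_CALLS
    }


def compile_expression(text: str):
    """Compile a validated expression to a code object for :func:`eval`."""
    parse_expression(text)
    return compile(text, "<rate>", "eval")


def evaluate(code, namespace: dict) -> float:
    return eval(code, _EVAL_GLOBALS, namespace)


def check_identifier(name: str, kind: str = "name") -> str:
    if not name.isidentifier():
        raise ExpressionError(f"{kind} {name!r} is not a valid identifier")
    if name in RESERVED_NAMES:
        raise ExpressionError(f"{kind} {name!r} is reserved")
    return name


def make_rate_function(
    expressions: Iterable[str],
    state_names: list[str],
    fixed: dict[str, float],
    parameter_names: list[str],
):
    """Build ``rates(t, y, p) -> tuple`` evaluating every rate law.

    ``y`` is the state vector ordered as ``state_names`` and ``p`` the
    parameter vector ordered as ``parameter_names``.  Fixed (boundary)
    species are baked in as constants.  The function is generated as
    Python source and ``exec``-ed once, so per-call overhead is a single
    function call.
    """
    lines = ["def _rates(t, y, p):"]
    for i, name in enumerate(state_names):
        lines.append(f"    {name} = y[{i}]")
    for name, value in fixed.items():
        lines.append(f"    {name} = {value!r}")
    for i, name in enumerate(parameter_names):
        lines.append(f"    {name} = p[{i}]")
    exprs = list(expressions)
    for expr in exprs:
        parse_expression(expr)  # refuse anything outside the whitelist
    body = ", ".join(f"({e})" for e in exprs) or ""
    lines.append(f"    return ({body}{',' if len(exprs) == 1 else ''})")
    source = "\n".join(lines)
    namespace: dict = {}
    exec(compile(source, "<rates>", "exec"), dict(_EVAL_GLOBALS), namespace)
    return namespace["_rates"]
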