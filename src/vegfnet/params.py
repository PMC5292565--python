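"""Named parameter sets with arithmetic expressions, units and fit bounds.

Every kinetic constant, compartment size and initial amount in the model is
a named entry.  Entries may be defined as arithmetic expressions of other
entries (e.g. a surcharge rate ``k_deg*(fold_deg-1)``), which keeps derived
rates consistent when a base rate or a fold-change is overridden during a
scan or a fit.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field


class ParameterError(ValueError):
    pass


_ALLOWED_FUNCS = {"exp": math.exp, "log": math.log, "log10": math.log10,
                  "sqrt": math.sqrt, "abs": abs, "min": min, "max": max}


def _safe_eval(expr: str, env) -> float:
    """Evaluate an arithmetic expression over parameter names."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as e:
        raise ParameterError(f"cannot parse expression {expr!r}: {e}") from None

    def ev(node):
        if isinstance(node, ast.Expression):
            return ev(node.body)
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            return float(node.value)
        if isinstance(node, ast.Name):
            return env(node.id)
        if isinstance(node, ast.BinOp):
            a, b = ev(node.left), ev(node.right)
            if isinstance(node.op, ast.Add):
                return a + b
            if isinstance(node.op, ast.Sub):
                return a - b
            if isinstance(node.op, ast.Mult):
                return a * b
            if isinstance(node.op, ast.Div):
                return a / b
            if isinstance(node.op, ast.Pow):
                return a ** b
            raise ParameterError(f"operator not allowed in {expr!r}")
        if isinstance(node, ast.UnaryOp):
            v = ev(node.operand)
            if isinstance(node.op, ast.USub):
                return -v
            if isinstance(node.op, ast.UAdd):
                return v
            raise ParameterError(f"operator not allowed in {expr!r}")
        if isinstance(node, ast.Call) and isinstance(node.func, ast.Name) \
                and node.func.id in _ALLOWED_FUNCS and not node.keywords:
            return _ALLOWED_FUNCS[node.func.id](*[ev(a) for a in node.args])
        raise ParameterError(f"construct not allowed in expression {expr!r}")

    return ev(tree)


@dataclass
class ParameterSet:
    """Symbol table: name -> defining expression (often just a number)."""

    exprs: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.exprs), dict(self.units), dict(self.bounds))

    def __contains__(self, name):
        return name in self.exprs

    def names(self):
        return list(self.exprs)

    def set(self, name: str, value) -> None:
        self.exprs[name] = value if isinstance(value, str) else repr(float(value))

    def get(self, name: str) -> float:
        return self._resolve(name, ())

    __getitem__ = get

    def __setitem__(self, name, value):
        self.set(name, value)

    def _resolve(self, name: str, stack: tuple) -> float:
        if name in stack:
            raise ParameterError(f"circular parameter definition at {name!r}")
        if name not in self.exprs:
            raise ParameterError(f"unresolvable parameter reference {name!r}")
        return _safe_eval(self.exprs[name],
                          lambda n, s=stack + (name,): self._resolve(n, s))

    def evaluate(self, expr: str) -> float:
        """Evaluate an arbitrary expression against this parameter set."""
        return _safe_eval(expr, lambda n: self._resolve(n, ()))

    def as_dict(self) -> dict[str, float]:
        return {n: self.get(n) for n in self.exprs}

    def with_overrides(self, **overrides) -> "ParameterSet":
        out = self.copy()
        for k, v in overrides.items():
            if k not in out.exprs:
                raise ParameterError(f"override of unknown parameter {k!r}")
            out.set(k, v)
        return out

    def scaled(self, name: str, fold: float) -> "ParameterSet":
        """Multiply a parameter by ``fold`` (keeps expression semantics)."""
        if fold <= 0:
            raise ParameterError("fold scalings must be > 0")
        out = self.copy()
        out.exprs[name] = f"({self.exprs[name]})*{float(fold)!r}"
        return out

    def validate(self, rate_names=None) -> None:
        """Check resolvability, nonnegative rates, bounds containing values."""
        for n in self.exprs:
            v = self.get(n)
            if rate_names is not None and n in rate_names and v < 0:
                raise ParameterError(f"rate {n} is negative: {v}")
            if n in self.bounds:
                lo, hi = self.bounds[n]
                if not (lo <= v <= hi):
                    raise ParameterError(
                        f"parameter {n}={v} outside declared bounds [{lo}, {hi}]")
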