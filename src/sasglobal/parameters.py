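"""Parameter flags, link functions and the optimizer-vector registry.

Every model parameter (and every model weight) carries a flag:

====  ========================================================
flag  meaning
====  ========================================================
0     fixed at the starting value
1     fitted between lower and upper, per curve
2     "common": one shared value for every curve using the model
4     computed by a link function; f-coefficients are per curve
5     as 4, but the f-coefficients are shared by all curves
6     polydisperse; distribution parameters fitted per curve
7     polydisperse; distribution parameters shared
8     polydisperse; distribution parameters from link functions,
      f-coefficients per curve
9     as 8, with shared f-coefficients
====  ========================================================

Link functions are arithmetic expressions over per-curve condition
coefficients (*p*-coefficients: temperature, concentration, ...) and
adjustable *f*-coefficients.  The reserved variable ``fout`` accumulates
a penalty term added to the objective but reported separately.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (LinkRuntimeError, LinkSemanticError, LinkSyntaxError,
                     ParameterError)

VALID_FLAGS = frozenset({0, 1, 2, 4, 5, 6, 7, 8, 9})
LINK_FLAGS = frozenset({4, 5, 8, 9})
POLY_FLAGS = frozenset({6, 7, 8, 9})
GLOBAL_F_FLAGS = frozenset({5, 9})

# ---------------------------------------------------------------------------
# link expression language
# ---------------------------------------------------------------------------

BASE_FUNCTIONS = {
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
    "sin": math.sin,
    "cos": math.cos,
    "tan": math.tan,
    "abs": abs,
    "min": min,
    "max": max,
}

#: extra named functions (domain built-ins may register themselves here)
EXTRA_FUNCTIONS: dict = {}


def register_link_function(name: str, fn) -> None:
    """Make ``fn`` callable from link expressions under ``name``."""
    if name in BASE_FUNCTIONS:
        raise ValueError(f"cannot override base function {name!r}")
    EXTRA_FUNCTIONS[name] = fn


_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.USub, ast.UAdd)


class _Validator(ast.NodeVisitor):
    def __init__(self, declared_p, functions):
        self.declared_p = set(declared_p)
        self.functions = functions
        self.p_names: list[str] = []
        self.f_names: list[str] = []

    def generic_visit(self, node):
        raise LinkSyntaxError(
            f"construct {type(node).__name__} not allowed in link expressions",
            getattr(node, "col_offset", None))

    def visit_Expression(self, node):
        self.visit(node.body)

    def visit_BinOp(self, node):
        if not isinstance(node.op, _ALLOWED_BINOPS):
            raise LinkSyntaxError(
                f"operator {type(node.op).__name__} not allowed",
                node.col_offset)
        self.visit(node.left)
        self.visit(node.right)

    def visit_UnaryOp(self, node):
        if not isinstance(node.op, _ALLOWED_UNARY):
            raise LinkSyntaxError("unary operator not allowed", node.col_offset)
        self.visit(node.operand)

    def visit_Constant(self, node):
        if not isinstance(node.value, (int, float)):
            raise LinkSyntaxError("only numeric literals allowed",
                                  node.col_offset)

    def visit_Call(self, node):
        if not isinstance(node.func, ast.Name):
            raise LinkSyntaxError("only named function calls allowed",
                                  node.col_offset)
        name = node.func.id
        if name not in self.functions:
            raise LinkSyntaxError(f"unknown function {name!r}",
                                  node.col_offset)
        if node.keywords:
            raise LinkSyntaxError("keyword arguments not allowed",
                                  node.col_offset)
        for arg in node.args:
            self.visit(arg)

    def visit_Name(self, node):
        name = node.id
        if name == "fout":
            return
        if name in self.functions:
            raise LinkSemanticError(
                f"identifier {name!r} shadows a link function")
        if name in self.declared_p:
            if name not in self.p_names:
                self.p_names.append(name)
        elif name not in self.f_names:
            self.f_names.append(name)


_ASSIGN_TOKEN = "="


def _split_statements(expr: str):
    return [s for s in (part.strip() for part in expr.split(";")) if s]


@dataclass
class CompiledLink:
    """A compiled link expression: statements + classified identifiers."""

    source: str
    statements: list          # (is_fout_assignment, code object, text)
    p_names: list
    f_names: list
    assigns_fout: bool

    def evaluate(self, p_values: dict, f_values: dict, fout_in: float = 0.0):
        """Return (value, fout_accumulated).

        Pure in (p, f) apart from the fout accumulation; fout starts
        from ``fout_in`` and every ``fout = <expr>`` statement adds the
        expression's value to it.
        """
        env = dict(BASE_FUNCTIONS)
        env.update(EXTRA_FUNCTIONS)
        env.update(p_values)
        env.update(f_values)
        fout = fout_in
        value = None
        for is_fout, code, text in self.statements:
            env["fout"] = fout
            try:
                result = eval(code, {"__builtins__": {}}, env)  # noqa: S307
            except ZeroDivisionError as exc:
                raise LinkRuntimeError(
                    f"division by zero in link {text!r}") from exc
            except (ValueError, OverflowError) as exc:
                raise LinkRuntimeError(
                    f"numerical error in link {text!r}: {exc}") from exc
            if is_fout:
                fout += float(result)
            else:
                value = float(result)
        if value is None:
            raise LinkSemanticError(
                f"link {self.source!r} has no value expression")
        return value, fout


def compile_link(expr: str, declared_p, functions=None) -> CompiledLink:
    """Compile a link expression.

    Grammar: numbers, identifiers, ``+ - * / ^``, parentheses, calls to
    the registered functions, and optional ``fout = <expr>`` statements
    separated by ``;``.  Identifiers found in ``declared_p`` are
    p-coefficients; all others are f-coefficients.
    """
    if not expr or not expr.strip():
        raise LinkSyntaxError("empty link expression")
    funcs = dict(BASE_FUNCTIONS)
    funcs.update(EXTRA_FUNCTIONS)
    if functions:
        funcs.update(functions)

    statements = []
    p_names: list[str] = []
    f_names: list[str] = []
    assigns_fout = False
    for text in _split_statements(expr):
        target = None
        body = text
        # a single leading "name =" (not "==", which the grammar lacks)
        if _ASSIGN_TOKEN in text:
            left, _, right = text.partition(_ASSIGN_TOKEN)
            candidate = left.strip()
            if candidate.isidentifier():
                target, body = candidate, right.strip()
        if target is not None:
            if target in declared_p:
                raise LinkSemanticError(
                    f"cannot assign to p-coefficient {target!r}")
            if target != "fout":
                raise LinkSemanticError(
                    f"only 'fout' may be assigned, not {target!r}")
            assigns_fout = True
        try:
            tree = ast.parse(body.replace("^", "**"), mode="eval")
        except SyntaxError as exc:
            raise LinkSyntaxError(f"syntax error in {text!r}: {exc.msg}",
                                  exc.offset) from exc
        validator = _Validator(declared_p, funcs)
        validator.visit(tree)
        for name in validator.p_names:
            if name not in p_names:
                p_names.append(name)
        for name in validator.f_names:
            if name not in f_names:
                f_names.append(name)
        code = compile(tree, "<link>", "eval")
        statements.append((target == "fout", code, text))

    return CompiledLink(expr, statements, p_names, f_names, assigns_fout)


# ---------------------------------------------------------------------------
# parameter specifications
# ---------------------------------------------------------------------------

@dataclass
class PolyParam:
    """One parameter of a polydispersity distribution (mean, width, ...)."""

    starting: float
    lower: float = 0.0
    upper: float = 1.0
    fixed: bool = False
    link: str | None = None


@dataclass
class PolyConfig:
    """Distribution attached to a polydisperse model parameter."""

    kind: str = "gaussian"
    params: dict = field(default_factory=dict)   # name -> PolyParam
    n_points: int = 21
    n_width: float = 4.0

    def __post_init__(self):
        if self.n_points < 3 or self.n_points % 2 == 0:
            raise ParameterError("n_points must be odd and >= 3")
        if self.n_width <= 0:
            raise ParameterError("n_width must be > 0")


@dataclass
class ParameterSpec:
    """One model parameter or weight with its fitting flag."""

    name: str
    starting: float = 0.0
    lower: float = -np.inf
    upper: float = np.inf
    flag: int = 0
    link: str | None = None
    poly: PolyConfig | None = None

    def __post_init__(self):
        if self.flag not in VALID_FLAGS:
            raise ParameterError(
                f"parameter {self.name!r}: invalid flag {self.flag} "
                f"(flag 3 does not exist)")
        if self.flag in (1, 2) and not (self.lower <= self.starting <= self.upper):
            raise ParameterError(
                f"parameter {self.name!r}: starting value outside bounds")
        if (self.link is not None) != (self.flag in (4, 5)):
            if self.flag in (4, 5) and self.link is None:
                raise ParameterError(
                    f"parameter {self.name!r}: flag {self.flag} requires a link")
            if self.link is not None and self.flag not in LINK_FLAGS:
                raise ParameterError(
                    f"parameter {self.name!r}: link given but flag is "
                    f"{self.flag}")
        if (self.poly is not None) != (self.flag in POLY_FLAGS):
            raise ParameterError(
                f"parameter {self.name!r}: polydispersity config present "
                f"iff flag in {sorted(POLY_FLAGS)}")
        if self.flag in (8, 9) and self.poly is not None:
            for pname, pp in self.poly.params.items():
                if not pp.fixed and pp.link is None:
                    raise ParameterError(
                        f"parameter {self.name!r}: flag {self.flag} requires "
                        f"a link on poly parameter {pname!r}")


@dataclass
class ResolvedPoly:
    kind: str
    params: dict          # name -> float
    n_points: int
    n_width: float


@dataclass
class ResolvedModel:
    weight: float
    params: dict                     # name -> float
    poly: dict                       # name -> ResolvedPoly


@dataclass
class ResolvedProblem:
    models: list        # per curve: list of ResolvedModel
    psi: float


@dataclass
class Slot:
    """One free quantity in the optimizer vector."""

    name: str
    start: float
    lower: float
    upper: float


class ParameterRegistry:
    """Maps the optimizer vector onto concrete per-curve parameter values.

    Slot ordering is deterministic: curve order, then model order, then
    parameter order (weight first), with global f-coefficients last.
    """

    def __init__(self, curves, model_stacks, f_bounds=None, f_start=None):
        if len(curves) != len(model_stacks):
            raise ParameterError("one model stack per curve required")
        self.curves = curves
        self.model_stacks = model_stacks
        self.declared_p = set()
        for curve in curves:
            self.declared_p.update(curve.p_coeffs.keys())
        self.f_bounds = dict(f_bounds or {})
        self.f_start = dict(f_start or {})
        self.slots: list[Slot] = []
        self._slot_index: dict = {}
        self._compiled: dict = {}
        self._global_f: list[str] = []
        self._build()

    # -- construction ------------------------------------------------------

    def _add_slot(self, key, name, start, lower, upper):
        if key not in self._slot_index:
            self._slot_index[key] = len(self.slots)
            self.slots.append(Slot(name, float(start), float(lower),
                                   float(upper)))
        return self._slot_index[key]

    def _f_slot_params(self, fname):
        lo, hi = self.f_bounds.get(fname, (0.0, 1.0))
        start = self.f_start.get(fname, 0.5 * (lo + hi))
        return start, lo, hi

    def _register_f(self, fname, ci, global_scope):
        if global_scope:
            if fname not in self._global_f:
                self._global_f.append(fname)
            return ("fg", fname)
        start, lo, hi = self._f_slot_params(fname)
        label = self.curves[ci].label or f"c{ci + 1}"
        self._add_slot(("f", ci, fname), f"{fname}.{label}", start, lo, hi)
        return ("f", ci, fname)

    def _compile(self, expr):
        if expr not in self._compiled:
            self._compiled[expr] = compile_link(expr, self.declared_p)
        return self._compiled[expr]

    def _build(self):
        for ci, stack in enumerate(self.model_stacks):
            label = self.curves[ci].label or f"c{ci + 1}"
            for mi, inst in enumerate(stack):
                suffix = f"{label}.m{mi + 1}"
                for spec in inst.all_specs():
                    self._build_spec(spec, ci, mi, inst, suffix)
        # global f-coefficients, in first-encounter order
        for fname in self._global_f:
            start, lo, hi = self._f_slot_params(fname)
            self._add_slot(("fg", fname), fname, start, lo, hi)

    def _build_spec(self, spec, ci, mi, inst, suffix):
        flag = spec.flag
        if flag == 1:
            self._add_slot(("p1", ci, mi, spec.name),
                           f"{spec.name}.{suffix}",
                           spec.starting, spec.lower, spec.upper)
        elif flag == 2:
            self._add_slot(("p2", inst.model, spec.name),
                           f"{spec.name}.{inst.model}.common",
                           spec.starting, spec.lower, spec.upper)
        elif flag in (4, 5):
            link = self._compile(spec.link)
            for fname in link.f_names:
                self._register_f(fname, ci, flag in GLOBAL_F_FLAGS)
        if flag in POLY_FLAGS and spec.poly is not None:
            for pname, pp in spec.poly.params.items():
                if pp.fixed:
                    continue
                if flag == 6:
                    self._add_slot(("pp6", ci, mi, spec.name, pname),
                                   f"{spec.name}.{pname}.{suffix}",
                                   pp.starting, pp.lower, pp.upper)
                elif flag == 7:
                    self._add_slot(("pp7", inst.model, spec.name, pname),
                                   f"{spec.name}.{pname}.{inst.model}.common",
                                   pp.starting, pp.lower, pp.upper)
                else:  # 8, 9
                    link = self._compile(pp.link)
                    for fname in link.f_names:
                        self._register_f(fname, ci, flag == 9)

    # -- public API --------------------------------------------------------

    @property
    def n_free(self) -> int:
        return len(self.slots)

    def slot_keys(self):
        """Internal keys in slot order (kind tag first element)."""
        inv = {v: k for k, v in self._slot_index.items()}
        return [inv[i] for i in range(len(self.slots))]

    def x0(self) -> np.ndarray:
        return np.array([s.start for s in self.slots])

    def bounds(self):
        return (np.array([s.lower for s in self.slots]),
                np.array([s.upper for s in self.slots]))

    def set_bounds(self, name, lower, upper, start=None):
        """Adjust the bounds of a slot by name (par-file second pass)."""
        for slot in self.slots:
            if slot.name == name:
                slot.lower, slot.upper = float(lower), float(upper)
                if start is not None:
                    slot.start = float(start)
                return
        raise ParameterError(f"no slot named {name!r}")

    # -- resolution --------------------------------------------------------

    def _slot_value(self, key, x, clip=True):
        idx = self._slot_index[key]
        v = x[idx]
        if clip:
            slot = self.slots[idx]
            v = min(max(v, slot.lower), slot.upper)
        return v

    def _eval_link(self, expr, ci, x, fout):
        link = self._compile(expr)
        curve = self.curves[ci]
        p_values = {}
        for pname in link.p_names:
            if pname not in curve.p_coeffs:
                raise LinkRuntimeError(
                    f"curve {curve.label!r}: p-coefficient {pname!r} "
                    f"not defined")
            p_values[pname] = float(curve.p_coeffs[pname])
        f_values = {}
        for fname in link.f_names:
            key = ("fg", fname) if ("fg", fname) in self._slot_index \
                else ("f", ci, fname)
            if key not in self._slot_index:
                raise LinkRuntimeError(
                    f"curve {curve.label!r}: f-coefficient {fname!r} "
                    f"has no slot")
            f_values[fname] = self._slot_value(key, x)
        return link.evaluate(p_values, f_values, fout)

    def resolve(self, x) -> ResolvedProblem:
        """Concrete per-curve parameter values for optimizer vector x."""
        x = np.asarray(x, dtype=float)
        if x.size != self.n_free:
            raise ParameterError(
                f"x has length {x.size}, expected {self.n_free}")
        fout = 0.0
        per_curve = []
        for ci, stack in enumerate(self.model_stacks):
            resolved_stack = []
            for mi, inst in enumerate(stack):
                params = {}
                poly = {}
                weight = None
                for spec in inst.all_specs():
                    value, fout = self._resolve_spec(spec, ci, mi, inst, x,
                                                     fout)
                    if spec is inst.weight:
                        weight = value
                    else:
                        params[spec.name] = value
                    if spec.flag in POLY_FLAGS:
                        rp, fout = self._resolve_poly(spec, ci, mi, inst, x,
                                                      fout, value)
                        poly[spec.name] = rp
                resolved_stack.append(ResolvedModel(weight, params, poly))
            per_curve.append(resolved_stack)
        return ResolvedProblem(per_curve, fout)

    def _resolve_spec(self, spec, ci, mi, inst, x, fout):
        flag = spec.flag
        if flag in (0, 6, 7, 8, 9):
            return float(spec.starting), fout
        if flag == 1:
            return self._slot_value(("p1", ci, mi, spec.name), x), fout
        if flag == 2:
            return self._slot_value(("p2", inst.model, spec.name), x), fout
        value, fout = self._eval_link(spec.link, ci, x, fout)
        return value, fout

    def _resolve_poly(self, spec, ci, mi, inst, x, fout, base_value):
        cfg = spec.poly
        values = {}
        for pname, pp in cfg.params.items():
            if pp.fixed:
                values[pname] = float(pp.starting)
            elif spec.flag == 6:
                values[pname] = self._slot_value(
                    ("pp6", ci, mi, spec.name, pname), x)
            elif spec.flag == 7:
                values[pname] = self._slot_value(
                    ("pp7", inst.model, spec.name, pname), x)
            else:
                values[pname], fout = self._eval_link(pp.link, ci, x, fout)
        values.setdefault("mean", base_value)
        return ResolvedPoly(cfg.kind, values, cfg.n_points, cfg.n_width), fout
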