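"""SBML export and an independent generic SBML integrator.

Validation path only: the model is exported to SBML Level 3 (rate-rule
form, content MathML), and a small generic reader parses any such file
back into an ODE system without touching :mod:`castates.model`'s
right-hand side.  Integrating the parsed system and comparing against
:func:`castates.model.simulate` exercises two independent code paths
from the equations to a trajectory.

The deposited reference model this layout mirrors is distributed as an
SBML file; when a copy is available it can be read and integrated with
the same machinery.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from castates.model import (
    StimulusProtocol,
    find_rest_state,
    leak_rate,
)

__all__ = ["export_sbml", "read_sbml_odes", "simulate_sbml"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"


def _mathml(expr: str) -> str:
    """Wrap a content-MathML fragment in a <math> element."""
    return f'<math xmlns="{_MATHML_NS}">{expr}</math>'


def _ci(name: str) -> str:
    return f"<ci>{name}</ci>"


def _cn(value: float) -> str:
    return f"<cn>{value!r}</cn>"


def _apply(op: str, *args: str) -> str:
    return f"<apply><{op}/>{''.join(args)}</apply>"


_TIME_CI = f'<csymbol encoding="text" definitionURL="{_TIME_CSYMBOL}">t</csymbol>'


def export_sbml(params: Mapping[str, float], protocol: StimulusProtocol,
                basal_ca: float, path) -> None:
    """Write the model as an SBML Level 3 document with rate rules.

    All 17 kinetic constants, the derived leak coefficient and the
    stimulus description become SBML parameters; the four state
    variables are non-constant parameters governed by rate rules whose
    MathML transcribes the model equations.
    """
    v_leak = leak_rate(params, basal_ca)
    rest = find_rest_state(params, basal_ca)

    consts = dict(params)
    consts["v_leak"] = v_leak
    consts["atp"] = protocol.atp
    consts["t_on"] = protocol.t_on

    # ligand step with first-order desensitization
    ligand = (
        "<piecewise><piece>"
        + _apply("times", _ci("atp"),
                 _apply("exp", _apply("minus",
                        _apply("times", _ci("k_r"),
                               _apply("minus", _TIME_CI, _ci("t_on"))))))
        + _apply("geq", _TIME_CI, _ci("t_on"))
        + "</piece><otherwise>" + _cn(0.0) + "</otherwise></piecewise>"
    )
    d_plc = _apply("minus",
                   _apply("times", _ci("k_plc"), ligand),
                   _apply("times", _ci("k_plc_deg"), _ci("plc")))

    plc_n = _apply("power", _ci("plc"), _ci("n_hill"))
    hill = _apply("divide", plc_n,
                  _apply("plus",
                         _apply("power", _ci("k_hill"), _ci("n_hill")),
                         plc_n))
    d_ip3 = _apply("minus",
                   _apply("times", _ci("v_ip3"), hill),
                   _apply("times", _ci("k_ip3_deg"), _ci("ip3")))

    ca_er = _apply("divide", _apply("minus", _ci("c0"), _ci("ca")), _ci("c1"))
    m_inf = _apply("divide", _ci("ip3"),
                   _apply("plus", _ci("ip3"), _ci("d1")))
    n_inf = _apply("divide", _ci("ca"),
                   _apply("plus", _ci("ca"), _ci("d5")))
    p_open = _apply("power",
                    _apply("times", m_inf, n_inf, _ci("h")), _cn(3.0))
    ca2 = _apply("power", _ci("ca"), _cn(2.0))
    j_serca = _apply("divide",
                     _apply("times", _ci("v_serca"), ca2),
                     _apply("plus",
                            _apply("power", _ci("k_serca"), _cn(2.0)), ca2))
    d_ca = _apply(
        "times", _ci("b_buf"),
        _apply("minus",
               _apply("times",
                      _apply("plus",
                             _apply("times", _ci("v_rel"), p_open),
                             _ci("v_leak")),
                      _apply("minus", ca_er, _ci("ca"))),
               j_serca))

    d_h = _apply("times", _ci("a2"),
                 _apply("minus",
                        _apply("times", _ci("dinh"),
                               _apply("minus", _cn(1.0), _ci("h"))),
                        _apply("times", _ci("ca"), _ci("h"))))

    initial = {"ip3": rest.ip3, "plc": rest.plc, "ca": rest.ca, "h": rest.h}
    rules = {"ip3": d_ip3, "plc": d_plc, "ca": d_ca, "h": d_h}

    param_xml = "".join(
        f'<parameter id="{name}" value="{value!r}" constant="true"/>'
        for name, value in consts.items())
    state_xml = "".join(
        f'<parameter id="{name}" value="{initial[name]!r}" constant="false"/>'
        for name in rules)
    rule_xml = "".join(
        f'<rateRule variable="{name}">{_mathml(expr)}</rateRule>'
        for name, expr in rules.items())
    doc = (
        f'<?xml version="1.0" encoding="UTF-8"?>'
        f'<sbml xmlns="{_SBML_NS}" level="3" version="2">'
        f'<model id="calcium_response">'
        f"<listOfParameters>{param_xml}{state_xml}</listOfParameters>"
        f"<listOfRules>{rule_xml}</listOfRules>"
        f"</model></sbml>")
    Path(path).write_text(doc)


def _compile_mathml(node: ET.Element,
                    names: dict[str, int]) -> Callable:
    """Recursively compile content MathML to ``f(t, y, consts) -> float``."""
    tag = node.tag.split("}")[-1]
    if tag == "math":
        children = list(node)
        if len(children) != 1:
            raise ValueError("expected a single top-level math expression")
        return _compile_mathml(children[0], names)
    if tag == "ci":
        name = node.text.strip()
        if name in names:
            i = names[name]
            return lambda t, y, c: y[i]
        return lambda t, y, c, _n=name: c[_n]
    if tag == "cn":
        value = float(node.text.strip())
        return lambda t, y, c: value
    if tag == "csymbol":
        if node.get("definitionURL") == _TIME_CSYMBOL:
            return lambda t, y, c: t
        raise ValueError(f"unsupported csymbol {node.get('definitionURL')}")
    if tag == "piecewise":
        pieces = []
        otherwise = lambda t, y, c: 0.0
        for child in node:
            ctag = child.tag.split("}")[-1]
            parts = [_compile_mathml(g, names) for g in child]
            if ctag == "piece":
                pieces.append((parts[0], parts[1]))
            elif ctag == "otherwise":
                otherwise = parts[0]
        def f(t, y, c, _p=pieces, _o=otherwise):
            for val, cond in _p:
                if cond(t, y, c):
                    return val(t, y, c)
            return _o(t, y, c)
        return f
    if tag == "apply":
        children = list(node)
        op = children[0].tag.split("}")[-1]
        args = [_compile_mathml(g, names) for g in children[1:]]
        if op == "plus":
            return lambda t, y, c: sum(a(t, y, c) for a in args)
        if op == "times":
            def prod(t, y, c, _a=args):
                out = 1.0
                for a in _a:
                    out *= a(t, y, c)
                return out
            return prod
        if op == "minus":
            if len(args) == 1:
                return lambda t, y, c: -args[0](t, y, c)
            return lambda t, y, c: args[0](t, y, c) - args[1](t, y, c)
        if op == "divide":
            return lambda t, y, c: args[0](t, y, c) / args[1](t, y, c)
        if op == "power":
            return lambda t, y, c: args[0](t, y, c) ** args[1](t, y, c)
        if op == "exp":
            return lambda t, y, c: math.exp(args[0](t, y, c))
        if op == "geq":
            return lambda t, y, c: args[0](t, y, c) >= args[1](t, y, c)
        if op == "leq":
            return lambda t, y, c: args[0](t, y, c) <= args[1](t, y, c)
        if op == "gt":
            return lambda t, y, c: args[0](t, y, c) > args[1](t, y, c)
        if op == "lt":
            return lambda t, y, c: args[0](t, y, c) < args[1](t, y, c)
        raise ValueError(f"unsupported MathML operator {op!r}")
    raise ValueError(f"unsupported MathML element {tag!r}")


def read_sbml_odes(path):
    """Parse an SBML rate-rule model into (state names, y0, consts, rhs).

    Supports the subset of SBML Level 3 used by :func:`export_sbml`:
    constant parameters, non-constant parameters with rate rules, and
    content MathML over the basic arithmetic operators.
    """
    tree = ET.parse(path)
    root = tree.getroot()

    def findall(elem, tag):
        return elem.iter(f"{{{_SBML_NS}}}{tag}")

    consts: dict[str, float] = {}
    state0: dict[str, float] = {}
    for p in findall(root, "parameter"):
        if p.get("constant") == "false":
            state0[p.get("id")] = float(p.get("value"))
        else:
            consts[p.get("id")] = float(p.get("value"))
    rules = {}
    for r in findall(root, "rateRule"):
        math_elem = r.find(f"{{{_MATHML_NS}}}math")
        rules[r.get("variable")] = math_elem
    names = list(rules)
    index = {n: i for i, n in enumerate(names)}
    compiled = [_compile_mathml(rules[n], index) for n in names]
    y0 = np.array([state0[n] for n in names])

    def rhs(t, y):
        return np.array([f(t, y, consts) for f in compiled])

    return names, y0, consts, rhs


def simulate_sbml(path, t_eval: np.ndarray, rtol: float = 1e-8,
                  atol: float = 1e-11) -> dict[str, np.ndarray]:
    """Integrate a parsed SBML model on the given time grid."""
    names, y0, _, rhs = read_sbml_odes(path)
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(rhs, (float(t_eval[0]), float(t_eval[-1])), y0,
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"SBML integration failed: {sol.message}")
    return {name: sol.y[i] for i, name in enumerate(names)}
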