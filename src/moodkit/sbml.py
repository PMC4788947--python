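"""Minimal SBML Level 3 Version 1 export of the reduced circuit model.

Writes the ten model species (the nine ODE states plus the algebraic
monomer M), all kinetic constants as parameters, one rate rule per ODE
state and an assignment rule for M, with content MathML generated
symbolically. The document is re-parsed after writing as a
well-formedness check. This is a compact single-purpose writer for this
one model, not a general SBML library.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .errors import InvalidParameterError
from .model import CircuitParameters, pre_equilibrate

__all__ = ["export_sbml", "SPECIES_IDS"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

#: The ten variables of the reduced model.
SPECIES_IDS = ("x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8", "x9", "M")

_PARAM_NAMES = (
    "kmA_CgA", "dmA", "kpA", "dA", "k2", "k_2", "kd", "dI", "k3", "k_3rev",
    "dAI2", "kmB_CgB", "gamma1", "dmB", "kpB", "dB", "kmC_CgC", "gamma2",
    "gamma3", "gamma4", "gamma5", "beta1", "beta2", "dmC", "kpC", "dC",
    "dIe", "dAI", "basal_c",
)


def _model_math():
    """Symbolic rate rules (x1..x9) and the M assignment, as sympy exprs."""
    import sympy as sp

    s = {name: sp.Symbol(name) for name in SPECIES_IDS}
    p = {name: sp.Symbol(name) for name in _PARAM_NAMES}
    p["K_cells"] = sp.Symbol("K_cells")
    x1, x2, x3, x4, x5, x6, x7, x8, x9, M = (s[i] for i in SPECIES_IDS)

    bind = p["k2"] * x2 * x3
    num = x4 + p["beta1"] * p["gamma4"] * x6 \
        + p["beta2"] * p["gamma5"] * x4 * x6 + p["basal_c"]
    den = p["gamma2"] + p["gamma3"] * x4 + p["gamma4"] * x6 \
        + p["gamma5"] * x4 * x6
    rates = {
        "x1": p["kmA_CgA"] - p["dmA"] * x1,
        "x2": p["kpA"] * x1 - p["dA"] * x2 - bind + p["k_2"] * M,
        "x3": -bind + p["k_2"] * M + p["kd"] * (x9 - x3) - p["dI"] * x3,
        "x4": p["k3"] * M**2 - p["k_3rev"] * x4 - p["dAI2"] * x4,
        "x5": p["kmB_CgB"] * x4 / (p["gamma1"] + x4) - p["dmB"] * x5,
        "x6": p["kpB"] * x5 - p["dB"] * x6,
        "x7": p["kmC_CgC"] * num / den - p["dmC"] * x7,
        "x8": p["kpC"] * x7 - p["dC"] * x8,
        "x9": p["K_cells"] * p["kd"] * (x3 - x9) - p["dIe"] * x9,
    }
    a = p["dAI"] + p["k_2"]
    assignment = (-a + sp.sqrt(a**2 + 8 * p["k3"] * (bind + 2 * p["k_3rev"] * x4))) \
        / (4 * p["k3"])
    return rates, assignment


def _content_mathml(expr) -> str:
    """Content-MathML for the restricted expression grammar the model uses.

    sympy's own MathML printer renders subscripted symbol names as
    presentation markup with an unbound namespace prefix, which SBML
    readers reject; this printer keeps every symbol a plain <ci>.
    """
    import sympy as sp

    if isinstance(expr, sp.Symbol):
        return f"<ci>{expr.name}</ci>"
    if isinstance(expr, sp.Integer):
        return f"<cn>{int(expr)}</cn>"
    if isinstance(expr, sp.Rational):
        return (f"<apply><divide/><cn>{int(expr.p)}</cn>"
                f"<cn>{int(expr.q)}</cn></apply>")
    if isinstance(expr, sp.Float):
        return f"<cn>{float(expr)!r}</cn>"
    if isinstance(expr, sp.Add):
        args = "".join(_content_mathml(a) for a in expr.args)
        return f"<apply><plus/>{args}</apply>"
    if isinstance(expr, sp.Mul):
        args = "".join(_content_mathml(a) for a in expr.args)
        return f"<apply><times/>{args}</apply>"
    if isinstance(expr, sp.Pow):
        base, exponent = expr.args
        if exponent == sp.Rational(1, 2):
            return f"<apply><root/>{_content_mathml(base)}</apply>"
        return (f"<apply><power/>{_content_mathml(base)}"
                f"{_content_mathml(exponent)}</apply>")
    raise InvalidParameterError(f"cannot serialize expression node {expr!r}")


def _mathml(expr) -> str:
    return f'<math xmlns="{MATHML_NS}">{_content_mathml(expr)}</math>'


def export_sbml(params: CircuitParameters, path: str | Path,
                model_id: str = "i1ffl_reduced") -> Path:
    """Serialize the model for ``params`` to SBML L3V1 at ``path``.

    Initial concentrations are the zero-inducer steady state. Returns the
    written path; raises on serialization failure or an unwritable path.
    """
    if not isinstance(params, CircuitParameters):
        raise InvalidParameterError("params must be a CircuitParameters instance")
    rates, assignment = _model_math()
    y0 = pre_equilibrate(params)
    init = {f"x{i + 1}": float(y0[i]) for i in range(9)}
    init["M"] = 0.0

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<sbml xmlns="{SBML_NS}" level="3" version="1">',
        f'  <model id="{model_id}" name="Reduced I1-FFL adaptation circuit">',
        "    <listOfCompartments>",
        '      <compartment id="cell" size="1" constant="true"/>',
        "    </listOfCompartments>",
        "    <listOfSpecies>",
    ]
    for sid in SPECIES_IDS:
        parts.append(
            f'      <species id="{sid}" compartment="cell" '
            f'initialConcentration="{init[sid]!r}" '
            'hasOnlySubstanceUnits="false" boundaryCondition="false" '
            'constant="false"/>'
        )
    parts.append("    </listOfSpecies>")
    parts.append("    <listOfParameters>")
    for name in _PARAM_NAMES:
        parts.append(
            f'      <parameter id="{name}" value="{getattr(params, name)!r}" '
            'constant="true"/>'
        )
    parts.append(
        f'      <parameter id="K_cells" value="{params.Kcells!r}" constant="true"/>'
    )
    parts.append("    </listOfParameters>")
    parts.append("    <listOfRules>")
    parts.append(
        f'      <assignmentRule variable="M">{_mathml(assignment)}</assignmentRule>'
    )
    for sid in ("x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8", "x9"):
        parts.append(
            f'      <rateRule variable="{sid}">{_mathml(rates[sid])}</rateRule>'
        )
    parts.append("    </listOfRules>")
    parts.append("  </model>")
    parts.append("</sbml>")
    doc = "\n".join(parts)

    # well-formedness check before anything touches the disk
    root = ET.fromstring(doc)
    n_species = len(root.findall(f".//{{{SBML_NS}}}species"))
    if n_species != len(SPECIES_IDS):
        raise InvalidParameterError(
            f"serialization produced {n_species} species, expected {len(SPECIES_IDS)}"
        )
    path = Path(path)
    path.write_text(doc)
    return path
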