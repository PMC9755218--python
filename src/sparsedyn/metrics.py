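"""Scoring and reporting of identified governing equations.

The deviation of identified coefficients (DIC) compares a fitted coefficient
map against a reference:

    DIC = (1/K) Σ_i |w_i − w'_i| / max(|w_i|, |w'_i|)

where the sum runs over the union support (terms with at least one nonzero
coefficient, matched by canonical term *name*, not position) and K is its
size.  DIC = 0 means a perfectly identified equation; each pair contributes
at most 2, a missing or spurious term contributes exactly 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .bayes_core import SparseModel

__all__ = ["dic", "format_equation", "parse_equation", "EquationReport"]


def dic(est: dict[str, float], ref: dict[str, float]) -> float:
    """Mean relative coefficient deviation over the union support."""
    keys = {k for k, v in est.items() if v != 0} | {k for k, v in ref.items() if v != 0}
    if not keys:
        raise ValueError("DIC undefined: both coefficient maps are empty")
    total = 0.0
    for k in keys:
        w = float(est.get(k, 0.0))
        wp = float(ref.get(k, 0.0))
        total += abs(w - wp) / max(abs(w), abs(wp))
    return total / len(keys)


def _fmt_coef(c: float, precision: int) -> str:
    s = f"{c:.{precision}g}"
    return s


def format_equation(
    model: SparseModel | dict[str, float],
    names: tuple[str, ...] | None = None,
    target_name: str = "dx/dt",
    precision: int = 6,
) -> str:
    """Render a fitted model as e.g. ``dx/dt = -2.001 x^3 + 11.98 x^2``.

    Terms appear in library order (or insertion order for plain maps);
    the constant term ``1`` is printed as a bare number.
    """
    if isinstance(model, SparseModel):
        coeffs = model.coefficients()
        order = [n for n in model.column_names if n in coeffs]
    else:
        coeffs = {k: v for k, v in model.items() if v != 0}
        order = [n for n in (names or coeffs.keys()) if n in coeffs]
    if not order:
        return f"{target_name} = 0"
    parts: list[str] = []
    for i, name in enumerate(order):
        c = coeffs[name]
        mag = _fmt_coef(abs(c), precision)
        body = mag if name == "1" else f"{mag} {name}"
        if i == 0:
            parts.append(body if c >= 0 else f"-{body}")
        else:
            parts.append(f"{'+' if c >= 0 else '-'} {body}")
    return f"{target_name} = " + " ".join(parts)


def parse_equation(text: str) -> tuple[str, dict[str, float]]:
    """Inverse of :func:`format_equation` (to printed precision)."""
    lhs, _, rhs = text.partition("=")
    rhs = rhs.strip()
    coeffs: dict[str, float] = {}
    if rhs == "0":
        return lhs.strip(), coeffs
    # split into signed chunks: a leading '-' or separators ' + ' / ' - '
    tokens = re.split(r"\s+([+-])\s+", rhs)
    chunks = [
        (s, chunk.strip())
        for chunk, s in zip(tokens[0::2], ["+"] + tokens[1::2])
    ]
    for s, chunk in chunks:
        sign = -1.0 if s == "-" else 1.0
        if chunk.startswith("-"):
            sign *= -1.0
            chunk = chunk[1:]
        bits = chunk.split(None, 1)
        coef = sign * float(bits[0])
        name = bits[1] if len(bits) > 1 else "1"
        coeffs[name] = coef
    return lhs.strip(), coeffs


@dataclass
class EquationReport:
    """Human/machine-readable record of one identified equation."""

    target: str
    terms: list[dict]  # [{"name", "coef", "sd"}]
    dic: float | None = None
    fit: dict = field(default_factory=dict)

    @classmethod
    def from_model(
        cls,
        model: SparseModel,
        target: str,
        reference: dict[str, float] | None = None,
        fit_info: dict | None = None,
    ) -> "EquationReport":
        coeffs = model.coefficients()
        sds = model.uncertainties()
        terms = [
            {"name": n, "coef": coeffs[n], "sd": sds.get(n)}
            for n in model.column_names
            if n in coeffs
        ]
        d = dic(coeffs, reference) if reference is not None else None
        return cls(target=target, terms=terms, dic=d, fit=dict(fit_info or {}))

    def coefficients(self) -> dict[str, float]:
        return {t["name"]: t["coef"] for t in self.terms}

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "terms": self.terms,
            "dic": self.dic,
            "fit": self.fit,
        }
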