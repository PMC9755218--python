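"""Candidate-function terms and library specifications.

Governing equations are modelled as sparse linear combinations of *terms*
drawn from a function library Θ.  A term is a small evaluable object with a
canonical name following the grammar

    ``1``, ``x``, ``x^2*y``, ``sin(x)``, ``cos(w t)``, ``cos(w t)*x^3``,
    ``u_x``, ``u_xx``, ``lap_u``, ``u_xx*v^2``

Monomial factors are written in library variable order; products are joined
with ``*``.  Names are the stable identity of a term: fitted models are
reported as ``{name: coefficient}`` maps, and two libraries with different
orderings compare correctly through them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Term",
    "Monomial",
    "Trig",
    "Derivative",
    "TimeModulated",
    "Product",
    "LibrarySpec",
    "polynomial_spec",
    "parse_term",
]


class Term:
    """Base class for library terms. Subclasses define ``name`` and ``evaluate``."""

    name: str

    def evaluate(self, data: Mapping[str, np.ndarray]):  # pragma: no cover - abstract
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.name!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Term) and self.name == other.name

    def __hash__(self) -> int:
        return hash(self.name)


@dataclass(frozen=True, eq=False)
class Monomial(Term):
    """Product of integer powers of state variables; empty product is the constant 1."""

    exponents: tuple[tuple[str, int], ...]  # ((var, power), ...), powers >= 1

    @property
    def name(self) -> str:
        if not self.exponents:
            return "1"
        parts = [v if p == 1 else f"{v}^{p}" for v, p in self.exponents]
        return "*".join(parts)

    def evaluate(self, data: Mapping[str, np.ndarray]):
        out = None
        for v, p in self.exponents:
            f = data[v] ** p if p != 1 else data[v]
            out = f if out is None else out * f
        if out is None:
            probe = next(iter(data.values()))
            return np.ones_like(np.asarray(probe, dtype=float))
        return out


@dataclass(frozen=True, eq=False)
class Trig(Term):
    kind: str  # "sin" | "cos"
    var: str

    @property
    def name(self) -> str:
        return f"{self.kind}({self.var})"

    def evaluate(self, data: Mapping[str, np.ndarray]):
        f = np.sin if self.kind == "sin" else np.cos
        return f(data[self.var])


@dataclass(frozen=True, eq=False)
class Derivative(Term):
    """A precomputed derivative field, looked up by label (e.g. ``u_xx``, ``lap_u``)."""

    label: str

    @property
    def name(self) -> str:
        return self.label

    def evaluate(self, data: Mapping[str, np.ndarray]):
        return data[self.label]


@dataclass(frozen=True, eq=False)
class TimeModulated(Term):
    """A base term multiplied by cos(ω t); ω is a known model parameter."""

    base: Term
    omega: float

    @property
    def name(self) -> str:
        if isinstance(self.base, Monomial) and not self.base.exponents:
            return "cos(w t)"
        return f"cos(w t)*{self.base.name}"

    def evaluate(self, data: Mapping[str, np.ndarray]):
        return np.cos(self.omega * data["t"]) * self.base.evaluate(data)


@dataclass(frozen=True, eq=False)
class Product(Term):
    factors: tuple[Term, ...]

    @property
    def name(self) -> str:
        return "*".join(f.name for f in self.factors)

    def evaluate(self, data: Mapping[str, np.ndarray]):
        out = self.factors[0].evaluate(data)
        for f in self.factors[1:]:
            out = out * f.evaluate(data)
        return out


@dataclass(frozen=True)
class LibrarySpec:
    """An ordered collection of candidate terms over named state variables."""

    variables: tuple[str, ...]
    terms: tuple[Term, ...]

    def __post_init__(self):
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate term names in library: {dup}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def derivative_labels(self) -> tuple[str, ...]:
        labels: list[str] = []

        def walk(t: Term):
            if isinstance(t, Derivative):
                if t.label not in labels:
                    labels.append(t.label)
            elif isinstance(t, Product):
                for f in t.factors:
                    walk(f)
            elif isinstance(t, TimeModulated):
                walk(t.base)

        for t in self.terms:
            walk(t)
        return tuple(labels)

    def evaluate(self, data: Mapping[str, np.ndarray]) -> np.ndarray:
        """Evaluate all terms on aligned flat arrays, returning an N x K design."""
        cols = []
        with np.errstate(over="ignore", invalid="ignore"):
            for t in self.terms:
                col = np.asarray(t.evaluate(data), dtype=float)
                if not np.all(np.isfinite(col)):
                    raise ValueError(f"non-finite values in library term {t.name!r}")
                cols.append(col)
        return np.column_stack(cols)

    # -- serialization ---------------------------------------------------
    def to_config(self) -> dict:
        omega = None
        for t in self.terms:
            if isinstance(t, TimeModulated):
                omega = t.omega
        cfg = {"variables": list(self.variables), "terms": list(self.names)}
        if omega is not None:
            cfg["omega"] = omega
        return cfg

    @classmethod
    def from_config(cls, cfg: Mapping) -> "LibrarySpec":
        variables = tuple(cfg["variables"])
        omega = cfg.get("omega")
        terms = tuple(parse_term(s, variables, omega=omega) for s in cfg["terms"])
        return cls(variables, terms)


def polynomial_spec(
    variables: Sequence[str], max_degree: int, include_constant: bool = True
) -> LibrarySpec:
    """All monomials in ``variables`` of total degree <= ``max_degree``.

    Terms are ordered by total degree, then lexicographically by the variable
    order given.  Three variables with degree <= 5 give 56 terms.
    """
    variables = tuple(variables)
    terms: list[Term] = []
    lo = 0 if include_constant else 1
    for d in range(lo, max_degree + 1):
        for combo in itertools.combinations_with_replacement(range(len(variables)), d):
            expo: list[tuple[str, int]] = []
            for vi in combo:
                v = variables[vi]
                if expo and expo[-1][0] == v:
                    expo[-1] = (v, expo[-1][1] + 1)
                else:
                    expo.append((v, 1))
            terms.append(Monomial(tuple(expo)))
    return LibrarySpec(variables, tuple(terms))


def _parse_factor(tok: str, variables: tuple[str, ...], omega) -> Term:
    tok = tok.strip()
    if tok == "1":
        return Monomial(())
    if tok in ("cos(w t)", "cos(w*t)"):
        if omega is None:
            raise ValueError("time-modulated term requires omega")
        return TimeModulated(Monomial(()), float(omega))
    for kind in ("sin", "cos"):
        if tok.startswith(kind + "(") and tok.endswith(")"):
            inner = tok[len(kind) + 1 : -1].strip()
            if inner in variables:
                return Trig(kind, inner)
    if "^" in tok:
        v, p = tok.split("^", 1)
        if v in variables:
            return Monomial(((v, int(p)),))
    if tok in variables:
        return Monomial(((tok, 1),))
    # anything of the form u_x / u_xy / lap_u is a derivative label
    if "_" in tok and not tok[0].isdigit():
        return Derivative(tok)
    raise ValueError(f"cannot parse library term factor {tok!r}")


def parse_term(name: str, variables: Iterable[str], omega: float | None = None) -> Term:
    """Parse a canonical term name back into an evaluable :class:`Term`."""
    variables = tuple(variables)
    factors = [_parse_factor(tok, variables, omega) for tok in name.split("*")]
    # merge two-token forms like "cos(w" "t)": names never contain '*' inside
    # parentheses, so a raw split is safe except for "cos(w t)" which has no '*'.
    mono_expo: dict[str, int] = {}
    modulated = False
    others: list[Term] = []
    for f in factors:
        if isinstance(f, Monomial):
            for v, p in f.exponents:
                mono_expo[v] = mono_expo.get(v, 0) + p
        elif isinstance(f, TimeModulated) and isinstance(f.base, Monomial) and not f.base.exponents:
            modulated = True
        else:
            others.append(f)
    mono = Monomial(tuple((v, mono_expo[v]) for v in variables if v in mono_expo))
    # canonical factor order: derivative/trig factors first, monomial last
    parts: list[Term] = list(others)
    if mono.exponents or (not others and not modulated):
        parts.append(mono)
    if len(parts) == 1:
        term = parts[0]
    else:
        term = Product(tuple(parts))
    if modulated:
        if omega is None:
            raise ValueError("time-modulated term requires omega")
        term = TimeModulated(term if parts else Monomial(()), float(omega))
    return term
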