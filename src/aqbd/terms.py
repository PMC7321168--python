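"""Polynomial model terms over coded factors.

A :class:`ModelSpec` is an ordered list of :class:`Term` objects — intercept,
linear, pure quadratic and (two- or three-way) interaction terms — that maps
a coded design to an OLS model matrix.  The two stock specs mirror the two
stages of a screening → optimisation study: a first-order model (intercept +
one linear term per factor) and a full quadratic response-surface model
(intercept, linear, pure quadratic, all two-way interactions and the single
three-way interaction for three factors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Term", "ModelSpec"]


@dataclass(frozen=True)
class Term:
    """One polynomial term, identified by the factor names it multiplies.

    ``factors`` is a sorted tuple; repetition encodes powers, so
    ``("x1", "x1")`` is the pure quadratic of ``x1`` and ``()`` is the
    intercept.
    """

    factors: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(sorted(self.factors)))

    @property
    def order(self) -> int:
        return len(self.factors)

    @property
    def kind(self) -> str:
        if self.order == 0:
            return "intercept"
        if self.order == 1:
            return "linear"
        if len(set(self.factors)) == 1:
            return "quadratic"
        return "interaction"

    @property
    def name(self) -> str:
        if self.order == 0:
            return "intercept"
        if self.kind == "quadratic":
            return f"{self.factors[0]}^2"
        return "*".join(self.factors)

    def parents(self) -> list["Term"]:
        """Lower-order terms hierarchy forces in while this term is retained.

        Quadratics require their linear term; an n-way interaction requires
        every lower-order sub-product of distinct factors.
        """
        if self.order <= 1:
            return []
        if self.kind == "quadratic":
            return [Term((self.factors[0],))]
        import itertools

        uniq = sorted(set(self.factors))
        out = []
        for r in range(1, len(uniq)):
            out.extend(Term(c) for c in itertools.combinations(uniq, r))
        return out

    def column(self, coded: pd.DataFrame) -> np.ndarray:
        col = np.ones(len(coded))
        for f in self.factors:
            col = col * coded[f].to_numpy()
        return col

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Term({self.name})"


class ModelSpec:
    """An ordered, duplicate-free term list with the intercept always first."""

    def __init__(self, terms: Sequence[Term]):
        terms = list(terms)
        if Term(()) not in terms:
            terms = [Term(())] + terms
        else:
            terms = [Term(())] + [t for t in terms if t.order > 0]
        names = [t.name for t in terms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate terms in spec: {names}")
        self.terms = tuple(terms)

    # -- stock specs ---------------------------------------------------
    @classmethod
    def linear(cls, factor_names: Sequence[str]) -> "ModelSpec":
        """First-order screening model: intercept + one linear term each."""
        return cls([Term((f,)) for f in factor_names])

    @classmethod
    def full_quadratic(
        cls, factor_names: Sequence[str], *, three_way: bool = True
    ) -> "ModelSpec":
        """Full response-surface model: linear, pure quadratic and two-way
        interaction terms, plus the three-way interaction when there are
        exactly three factors and ``three_way`` is set."""
        import itertools

        f = list(factor_names)
        terms = [Term((a,)) for a in f]
        terms += [Term((a, a)) for a in f]
        terms += [Term(c) for c in itertools.combinations(f, 2)]
        if three_way and len(f) == 3:
            terms.append(Term(tuple(f)))
        return cls(terms)

    # -- queries -------------------------------------------------------
    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: Term) -> bool:
        return term in self.terms

    def __eq__(self, other) -> bool:
        return isinstance(other, ModelSpec) and self.terms == other.terms

    def drop(self, term: Term) -> "ModelSpec":
        if term.order == 0:
            raise ValueError("the intercept cannot be dropped")
        return ModelSpec([t for t in self.terms if t != term])

    def protected(self) -> set[Term]:
        """Terms that hierarchy-preserving elimination may not remove:
        the intercept and every parent of a retained higher-order term."""
        keep = {Term(())}
        for t in self.terms:
            for p in t.parents():
                if p in self.terms:
                    keep.add(p)
        return keep

    def model_matrix(self, coded: pd.DataFrame) -> pd.DataFrame:
        """OLS model matrix (runs × terms) for a coded design table."""
        return pd.DataFrame(
            {t.name: t.column(coded) for t in self.terms}, index=coded.index
        )

    # -- serialisation -------------------------------------------------
    def to_json_obj(self) -> list[list[str]]:
        return [list(t.factors) for t in self.terms]

    @classmethod
    def from_json_obj(cls, obj: Sequence[Sequence[str]]) -> "ModelSpec":
        return cls([Term(tuple(t)) for t in obj])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ModelSpec({' + '.join(self.term_names)})"
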