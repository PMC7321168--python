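"""Two-level screening and response-surface designs on coded factors.

Factor settings live in two equivalent coordinate systems: *natural* units
(mM, pH units, °C, %, %/min) and *coded* units, the affine map that sends the
low end of a factor's studied range to −1, the high end to +1 and the
midpoint to 0.  All model fitting in :mod:`aqbd.model` happens on coded
factors, which makes coefficient magnitudes directly comparable across
factors; natural units are for reporting and for talking to the instrument.

The two generators provided are the ones a screening → optimisation
chromatographic workflow needs:

* a two-level fractional factorial ``2^(k−g)`` with appended centre points,
  with generator sets chosen so the 6-factor, 2-generator case is
  resolution IV (no main effect aliased with any two-factor interaction);
* a face-centred central composite (CCF): the full ``2^k`` cube, ``2k``
  face-centre axial points and centre replicates, all coordinates in
  {−1, 0, +1}.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "generate_fractional_factorial",
    "generate_ccf",
    "alias_structure",
    "read_design_csv",
]

#: |coded value| below this is treated as exactly 0 when classifying rows
#: as centre / axial / cube points.
CENTER_TOL = 1e-6


@dataclass(frozen=True)
class FactorSpec:
    """A controllable method parameter and its studied range.

    Parameters
    ----------
    name
        Identifier, unique within a study (e.g. ``"temperature_C"``).
    low, high
        Ends of the studied range in natural units; ``low < high``.
    units
        Free-text units used in reports (``"mM"``, ``"°C"``, ``"%/min"`` ...).
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, natural):
        """Map natural units to coded units (low → −1, high → +1)."""
        return (np.asarray(natural, dtype=float) - self.mid) / self.half_range

    def decode(self, coded):
        """Inverse of :meth:`code`."""
        return np.asarray(coded, dtype=float) * self.half_range + self.mid


def _check_unique_names(factors: Sequence[FactorSpec]) -> None:
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names in {names}")


class DesignMatrix:
    """An ordered set of experimental runs over a fixed list of factors.

    The canonical representation is the *coded* table (runs × factors,
    values typically in [−1, +1]); the natural-unit view is derived through
    the factor specs.  Run labels are preserved so printed tables can be
    carried through verbatim.
    """

    def __init__(self, coded: pd.DataFrame, factors: Sequence[FactorSpec]):
        _check_unique_names(factors)
        factors = tuple(factors)
        expected = [f.name for f in factors]
        if list(coded.columns) != expected:
            raise ValueError(
                f"coded columns {list(coded.columns)} do not match factors {expected}"
            )
        self.factors = factors
        self.coded = coded.astype(float)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_natural(
        cls,
        natural: pd.DataFrame,
        factors: Sequence[FactorSpec],
        *,
        tol: float = 1e-6,
    ) -> "DesignMatrix":
        """Build a design from natural-unit settings (``code_factors``).

        Every value must lie inside its factor's [low, high] range up to a
        relative tolerance ``tol``; an out-of-range value is rejected with
        the offending run named.
        """
        _check_unique_names(factors)
        for f in factors:
            if f.name not in natural.columns:
                raise KeyError(f"design table has no column for factor {f.name!r}")
        extra = set(natural.columns) - {f.name for f in factors}
        if extra:
            raise KeyError(f"unknown factor column(s) {sorted(extra)}")
        coded = {}
        for f in factors:
            c = f.code(natural[f.name])
            bad = np.abs(c) > 1.0 + tol
            if bad.any():
                run = natural.index[np.argmax(bad)]
                raise ValueError(
                    f"run {run!r}: factor {f.name!r} value "
                    f"{float(natural[f.name].loc[run])} outside "
                    f"[{f.low}, {f.high}]"
                )
            coded[f.name] = np.clip(c, -1.0, 1.0)
        return cls(pd.DataFrame(coded, index=natural.index), factors)

    # -- views --------------------------------------------------------
    @property
    def natural(self) -> pd.DataFrame:
        """Natural-unit view (inverse of the coding map)."""
        return pd.DataFrame(
            {f.name: f.decode(self.coded[f.name]) for f in self.factors},
            index=self.coded.index,
        )

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    @property
    def is_center(self) -> pd.Series:
        """True for runs whose coded settings are all (numerically) zero."""
        return (self.coded.abs() < CENTER_TOL).all(axis=1)

    def replicate_groups(self, decimals: int = 6) -> list[list]:
        """Run labels grouped by identical coded settings (after rounding).

        Groups of size ≥ 2 carry pure replicate error; the three centre
        points of a screening or CCF design form one such group.
        """
        key = self.coded.round(decimals)
        groups = key.groupby(list(key.columns), sort=False).groups
        return [list(idx) for idx in groups.values()]

    def subset(self, mask) -> "DesignMatrix":
        return DesignMatrix(self.coded.loc[mask], self.factors)

    # -- CSV dialect ---------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the design in natural units: ``run_id``, one column per
        factor, plus ``is_center``.  :func:`read_design_csv` is the inverse."""
        out = self.natural.copy()
        out.insert(0, "run_id", self.coded.index)
        out["is_center"] = self.is_center.to_numpy().astype(int)
        out.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DesignMatrix {self.n_runs} runs × {len(self.factors)} factors "
            f"({int(self.is_center.sum())} centre)>"
        )


def read_design_csv(path, factors: Sequence[FactorSpec]) -> DesignMatrix:
    """Read a design written by :meth:`DesignMatrix.to_csv`."""
    df = pd.read_csv(path)
    if "run_id" not in df.columns:
        raise ValueError("design CSV must have a run_id column")
    df = df.set_index("run_id")
    df = df.drop(columns=[c for c in ("is_center",) if c in df.columns])
    return DesignMatrix.from_natural(df[[f.name for f in factors]], factors)


def code_factors(
    natural: pd.DataFrame, factors: Sequence[FactorSpec], *, tol: float = 1e-6
) -> DesignMatrix:
    """Functional alias for :meth:`DesignMatrix.from_natural`."""
    return DesignMatrix.from_natural(natural, factors, tol=tol)


# ---------------------------------------------------------------------
# design generators
# ---------------------------------------------------------------------

def _coded_factors(k: int) -> list[FactorSpec]:
    return [FactorSpec(f"x{i + 1}", -1.0, 1.0, "coded") for i in range(k)]


def _full_factorial(k: int) -> np.ndarray:
    # standard (Yates) order: first column alternates fastest
    levels = np.array(list(itertools.product([-1.0, 1.0], repeat=k)))
    return levels[:, ::-1]


# Generator sets for 2^(k−g) fractions, as products of base-factor indices.
# The 6-factor, 2-generator entry (x5 = x1·x2·x3, x6 = x2·x3·x4) is a
# standard minimum-aberration resolution-IV choice.
_GENERATORS: dict[tuple[int, int], list[tuple[int, ...]]] = {
    (3, 1): [(0, 1)],
    (4, 1): [(0, 1, 2)],
    (5, 1): [(0, 1, 2, 3)],
    (5, 2): [(0, 1), (0, 2, 3)],
    (6, 1): [(0, 1, 2, 3, 4)],
    (6, 2): [(0, 1, 2), (1, 2, 3)],
    (7, 2): [(0, 1, 2, 3), (1, 2, 3, 4)],
    (7, 3): [(0, 1, 2), (0, 1, 3), (1, 2, 3)],
}


def _append_center(levels: np.ndarray, n_center: int, k: int) -> pd.DataFrame:
    if n_center:
        levels = np.vstack([levels, np.zeros((n_center, k))])
    labels = [f"N{i + 1}" for i in range(len(levels))]
    return pd.DataFrame(levels, index=labels, columns=[f"x{i + 1}" for i in range(k)])


def generate_fractional_factorial(
    n_factors: int,
    n_generators: int,
    n_center: int = 0,
    *,
    generators: Iterable[tuple[int, ...]] | None = None,
    require_resolution: int | None = None,
) -> DesignMatrix:
    """A coded ``2^(k−g)`` two-level design with appended centre points.

    The first ``k − g`` factors form a full factorial; each remaining factor
    is the product of a base-factor subset (the *generator words*).  For
    ``generators=None`` a catalogue of minimum-aberration choices is used
    (``g = 0`` gives the full factorial).  When ``require_resolution`` is
    given the realised alias structure is checked and a violating word is
    reported by name.
    """
    k, g = n_factors, n_generators
    if k < 2:
        raise ValueError("need at least 2 factors")
    if not 0 <= g < k:
        raise ValueError("need 0 <= n_generators < n_factors")
    base = _full_factorial(k - g)
    if g == 0:
        levels = base
    else:
        if generators is None:
            try:
                generators = _GENERATORS[(k, g)]
            except KeyError:
                raise ValueError(
                    f"no catalogued generator set for 2^({k}-{g}); pass generators="
                ) from None
        generators = [tuple(w) for w in generators]
        if len(generators) != g:
            raise ValueError(f"expected {g} generator words, got {len(generators)}")
        extra = np.column_stack([base[:, list(w)].prod(axis=1) for w in generators])
        levels = np.hstack([base, extra])
    design = DesignMatrix(_append_center(levels, n_center, k), _coded_factors(k))
    if require_resolution is not None:
        res, word = _resolution(design)
        if res < require_resolution:
            raise ValueError(
                f"design has resolution {res} < {require_resolution}: "
                f"defining word {word} aliases low-order effects"
            )
    return design


def generate_ccf(n_factors: int, n_center: int = 0) -> DesignMatrix:
    """A coded face-centred central composite design.

    ``2^k`` cube points, ``2k`` face-centre axial points (a single ±1
    coordinate) and ``n_center`` centre replicates; every coordinate is in
    {−1, 0, +1}, so the design stays inside the already-studied cube.
    """
    k = n_factors
    if k < 2:
        raise ValueError("need at least 2 factors")
    cube = _full_factorial(k)
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -1.0
        axial[2 * i + 1, i] = 1.0
    levels = np.vstack([cube, axial])
    return DesignMatrix(_append_center(levels, n_center, k), _coded_factors(k))


# ---------------------------------------------------------------------
# alias structure
# ---------------------------------------------------------------------

def _effect_columns(coded: np.ndarray, k: int, max_order: int):
    for order in range(1, max_order + 1):
        for combo in itertools.combinations(range(k), order):
            yield combo, coded[:, list(combo)].prod(axis=1)


def alias_structure(
    design: DesignMatrix, max_order: int = 3
) -> dict[tuple[int, ...], list[tuple[int, ...]]]:
    """Group effects whose coded product columns coincide up to sign.

    Centre rows are excluded before comparing columns.  Keys are factor
    index tuples (``(0,)`` = main effect of the first factor,
    ``(0, 1)`` = their interaction, ...); each maps to the other effect
    words confounded with it.  In a full factorial every alias set is a
    singleton; in a resolution-IV fraction main effects are aliased only
    with interactions of order ≥ 3.
    """
    coded = design.coded.loc[~design.is_center].to_numpy()
    if not np.all(np.isin(np.round(coded, 9), (-1.0, 1.0))):
        raise ValueError("alias structure requires a two-level design")
    k = coded.shape[1]
    effects = list(_effect_columns(coded, k, max_order))
    aliases: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
    for i, (word_i, col_i) in enumerate(effects):
        partners = [
            word_j
            for j, (word_j, col_j) in enumerate(effects)
            if j != i
            and (np.array_equal(col_i, col_j) or np.array_equal(col_i, -col_j))
        ]
        aliases[word_i] = partners
    return aliases


def _resolution(design: DesignMatrix, max_order: int = 4) -> tuple[int, tuple]:
    """Realised resolution = length of the shortest defining word.

    Returns ``(resolution, word)`` where ``word`` is a shortest product of
    factor columns equal to ±1 everywhere; resolution ``max_order + 1``
    means no such word up to the inspected order.
    """
    coded = design.coded.loc[~design.is_center].to_numpy()
    k = coded.shape[1]
    for order in range(1, max_order + 1):
        for combo in itertools.combinations(range(k), order):
            col = coded[:, list(combo)].prod(axis=1)
            if np.all(col == col[0]):
                return order, combo
    return max_order + 1, ()
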