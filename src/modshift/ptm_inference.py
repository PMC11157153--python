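"""Decomposing observed mass shifts into candidate PTM patterns.

Each observed mass shift ``obs`` is explained by an integer count vector
``p`` over a user-supplied table of PTM types with masses ``m``, subject
to ``|m . p - obs| <= eps_max`` and per-type upper bounds.  Three integer
linear programs rank the (often many) feasible patterns:

* ``min_ptm``   — minimize the total number of PTMs ``P = sum(p)``;
* ``min_error`` — minimize the mass error ``eps = |m . p - obs|``;
* ``min_both``  — minimize the normalized sum ``eps/eps_max + P/P_max``.

The k best patterns ("laps") are enumerated by re-solving with a
strict-improvement constraint on the previous optimum.  The programs run
on scipy's MILP solver (HiGHS); a brute-force enumerator over the bounded
integer box serves as an independent oracle in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp

from pyteomics import mass as _pmass

__all__ = [
    "PtmEntry",
    "PtmTable",
    "PtmPattern",
    "InferenceConfig",
    "default_ptm_table",
    "enumerate_feasible_patterns",
    "solve_min_ptm",
    "solve_min_error",
    "solve_min_both",
    "enumerate_k_solutions",
]

#: compositions of the nine stock PTM types: five biological modifications
#: and four common intact-MS artifacts/adducts.
_STOCK_COMPOSITIONS = {
    "Ph": {"H": 1, "P": 1, "O": 3},        # phosphorylation
    "Ac": {"C": 2, "H": 2, "O": 1},        # acetylation
    "Me1": {"C": 1, "H": 2},               # methylation
    "Me2": {"C": 2, "H": 4},               # di-methylation
    "Me3": {"C": 3, "H": 6},               # tri-methylation
    "Ph-OH": {"H": 3, "P": 1, "O": 4},     # phosphate adduct
    "Ox": {"O": 1},                        # oxidation
    "Cys": {"C": 3, "H": 5, "N": 1, "O": 2, "S": 1},  # cysteinylation
    "Na": {"Na": 1, "H": -1},              # sodium adduct (replaces H)
}

#: default per-type upper bounds: maximum multiplicities seen in reported
#: intact-mass p53 patterns below ~400 Da, adducts kept at low counts.
_STOCK_BOUNDS = {
    "Ph": 2, "Ac": 1, "Me1": 1, "Me2": 2, "Me3": 2,
    "Ph-OH": 3, "Ox": 1, "Cys": 3, "Na": 1,
}


def _composition_mass(composition: dict, average: bool = True) -> float:
    comp = _pmass.Composition(composition)
    return float(_pmass.calculate_mass(composition=comp, average=average))


@dataclass
class PtmEntry:
    name: str
    mass: float
    upper_bound: int
    composition: dict | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"PTM {self.name!r}: mass must be positive")
        if self.upper_bound < 0:
            raise ValueError(f"PTM {self.name!r}: upper bound must be >= 0")


@dataclass
class PtmTable:
    """The user-supplied table of PTM types considered for inference."""

    entries: list[PtmEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("PTM names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def masses(self) -> np.ndarray:
        return np.array([e.mass for e in self.entries])

    @property
    def upper_bounds(self) -> np.ndarray:
        return np.array([e.upper_bound for e in self.entries], dtype=int)

    @classmethod
    def from_csv(cls, path, average: bool = True) -> "PtmTable":
        """Columns: ``name``, ``upper_bound`` and either ``mass`` (Da) or a
        chemical ``composition`` such as ``H1P1O3`` (negatives like
        ``Na1H-1`` allowed)."""
        df = pd.read_csv(path, sep=None, engine="python")
        entries = []
        for _, row in df.iterrows():
            comp = None
            if "composition" in df.columns and isinstance(row.get("composition"), str):
                comp = dict(_pmass.Composition(formula=row["composition"]))
            if comp is not None:
                mass = _composition_mass(comp, average=average)
            elif "mass" in df.columns and not pd.isna(row.get("mass")):
                mass = float(row["mass"])
            else:
                raise ValueError(f"PTM {row['name']!r}: need a mass or a composition")
            entries.append(PtmEntry(str(row["name"]), mass, int(row["upper_bound"]), comp))
        return cls(entries)

    def to_csv(self, path) -> None:
        rows = []
        for e in self.entries:
            comp = "".join(f"{el}{n}" for el, n in e.composition.items()) if e.composition else ""
            rows.append({"name": e.name, "composition": comp,
                         "mass": e.mass, "upper_bound": e.upper_bound})
        pd.DataFrame(rows).to_csv(path, index=False)


def default_ptm_table(average: bool = True, upper_bounds: dict | None = None) -> PtmTable:
    """The nine stock PTM types with masses derived from composition.

    Average masses by default (the fitted envelope means of intact
    proteins track average mass); pass ``average=False`` for monoisotopic.
    ``upper_bounds`` overrides individual per-type bounds.
    """
    bounds = dict(_STOCK_BOUNDS)
    if upper_bounds:
        bounds.update(upper_bounds)
    entries = [
        PtmEntry(name, _composition_mass(comp, average=average), bounds[name], dict(comp))
        for name, comp in _STOCK_COMPOSITIONS.items()
    ]
    return PtmTable(entries)


@dataclass
class PtmPattern:
    """An integer PTM count vector explaining one observed mass shift."""

    counts: tuple[int, ...]
    names: tuple[str, ...]
    inferred_mass: float
    error: float
    total_ptms: int
    combined_score: float | None = None

    def __str__(self) -> str:
        parts = [f"{c}[{n}]" for c, n in zip(self.counts, self.names) if c]
        return "".join(parts) if parts else "0[unmodified]"

    def as_dict(self) -> dict[str, int]:
        return {n: c for n, c in zip(self.names, self.counts) if c}


@dataclass
class InferenceConfig:
    """Settings shared by the three integer programs.

    ``eps_max`` (the feasibility tolerance) is the ppm tolerance taken of
    the protein's reference mass, not of the shift itself — the error
    budget of a fitted envelope mean scales with the protein mass.
    """

    reference_mass: float
    mass_tolerance_ppm: float = 20.0
    objective: str = "min_both"
    laps: int = 1
    #: strictness margins for lap constraints; far below any meaningful
    #: objective difference, far above the MILP feasibility tolerance
    epsilon_step: float = 1e-3
    score_step: float = 1e-4
    p_max: int | None = None

    def __post_init__(self) -> None:
        if self.laps < 1:
            raise ValueError("laps must be >= 1")
        if self.objective not in ("min_ptm", "min_error", "min_both"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.eps_max <= 0:
            raise ValueError("eps_max must be positive")

    @property
    def eps_max(self) -> float:
        return self.mass_tolerance_ppm * 1e-6 * self.reference_mass

    def resolve_p_max(self, table: PtmTable) -> int:
        """Normalizer for the combined objective: the largest possible
        total PTM count unless set explicitly."""
        return self.p_max if self.p_max is not None else max(int(table.upper_bounds.sum()), 1)


def _make_pattern(
    counts: np.ndarray, table: PtmTable, obs: float, config: InferenceConfig | None = None
) -> PtmPattern:
    counts = np.asarray(counts, dtype=int)
    inferred = float(table.masses @ counts)
    error = abs(inferred - obs)
    total = int(counts.sum())
    score = None
    if config is not None:
        score = error / config.eps_max + total / config.resolve_p_max(table)
    return PtmPattern(tuple(int(c) for c in counts), table.names, inferred, error, total, score)


def enumerate_feasible_patterns(
    obs: float, table: PtmTable, eps_max: float, config: InferenceConfig | None = None
) -> list[PtmPattern]:
    """Exhaustive enumeration of the bounded integer box — the feasible
    set and the test oracle for the integer programs.

    Returns every pattern with ``|m . p - obs| <= eps_max``, sorted by
    (total PTMs, error).  Guarded against boxes larger than 1e8 points.
    """
    ubs = table.upper_bounds
    n_points = float(np.prod(ubs + 1.0))
    if n_points > 1e8:
        raise ValueError(
            f"feasible box has {n_points:.2g} points; tighten the upper bounds"
        )
    masses = table.masses
    out: list[PtmPattern] = []
    for counts in itertools.product(*(range(ub + 1) for ub in ubs)):
        c = np.array(counts)
        if abs(float(masses @ c) - obs) <= eps_max:
            out.append(_make_pattern(c, table, obs, config))
    out.sort(key=lambda p: (p.total_ptms, p.error, p.counts))
    return out


# ---------------------------------------------------------------------------
# ILP machinery (scipy.optimize.milp / HiGHS)

def _run_milp(c, integrality, bounds, constraints):
    res = milp(c=c, integrality=integrality, bounds=bounds, constraints=constraints)
    if res.status != 0 or res.x is None:
        return None
    return res.x


def _abs_lower_bound_rows(masses: np.ndarray, obs: float, bound: float, big_m: float):
    """Big-M linearization of ``|m . p - obs| >= bound`` using one binary b:

    m.p - obs >= bound - M*b      and      obs - m.p >= bound - M*(1-b).
    """
    n = masses.size
    # variable layout handled by caller; these rows cover [p..., b]
    row_pos = np.concatenate([masses, [big_m]])
    row_neg = np.concatenate([-masses, [-big_m]])
    return (
        LinearConstraint(row_pos, lb=bound + obs, ub=np.inf),
        LinearConstraint(row_neg, lb=bound - obs - big_m, ub=np.inf),
    )


def solve_min_ptm(
    obs: float,
    table: PtmTable,
    config: InferenceConfig,
    previous_P: int | None = None,
) -> PtmPattern | None:
    """Minimize the total PTM count subject to the mass-tolerance window.

    With ``previous_P`` given, the integer strict-improvement constraint
    ``P >= previous_P + 1`` is added.  Returns ``None`` when no pattern
    lies within tolerance.
    """
    n = len(table)
    eps = config.eps_max
    c = np.ones(n)
    constraints = [LinearConstraint(table.masses, lb=obs - eps, ub=obs + eps)]
    if previous_P is not None:
        constraints.append(LinearConstraint(np.ones(n), lb=previous_P + 1, ub=np.inf))
    x = _run_milp(
        c,
        integrality=np.ones(n),
        bounds=Bounds(np.zeros(n), table.upper_bounds.astype(float)),
        constraints=constraints,
    )
    if x is None:
        return None
    return _make_pattern(np.round(x), table, obs, config)


def solve_min_error(
    obs: float,
    table: PtmTable,
    config: InferenceConfig,
    previous_eps: float | None = None,
) -> PtmPattern | None:
    """Minimize the absolute mass error within the tolerance window.

    The absolute value is linearized with one auxiliary variable ``t``
    (``-t <= m.p - obs <= t``).  With ``previous_eps`` given, strict
    improvement is enforced on the *actual* error via a big-M disjunction,
    so the next lap returns the next-best pattern rather than the same
    pattern with a padded auxiliary.
    """
    n = len(table)
    masses = table.masses
    has_prev = previous_eps is not None
    # variables: p (n ints), t (error), [b binary when lapping]
    nv = n + 1 + (1 if has_prev else 0)
    c = np.zeros(nv)
    c[n] = 1.0
    integrality = np.zeros(nv)
    integrality[:n] = 1
    lo = np.zeros(nv)
    hi = np.concatenate([table.upper_bounds.astype(float), [config.eps_max]])
    if has_prev:
        integrality[n + 1] = 1
        hi = np.concatenate([hi, [1.0]])

    def row(pvec, tcoef=0.0, bcoef=0.0):
        r = np.zeros(nv)
        r[:n] = pvec
        r[n] = tcoef
        if has_prev:
            r[n + 1] = bcoef
        return r

    constraints = [
        LinearConstraint(row(masses, tcoef=-1.0), lb=-np.inf, ub=obs),   # m.p - t <= obs
        LinearConstraint(row(masses, tcoef=+1.0), lb=obs, ub=np.inf),    # m.p + t >= obs
    ]
    if has_prev:
        bound = previous_eps + config.epsilon_step
        big_m = 2.0 * (config.eps_max + abs(obs) + bound + 1.0)
        constraints.append(
            LinearConstraint(row(masses, bcoef=big_m), lb=bound + obs, ub=np.inf)
        )
        constraints.append(
            LinearConstraint(row(-masses, bcoef=-big_m), lb=bound - obs - big_m, ub=np.inf)
        )
    x = _run_milp(c, integrality, Bounds(lo, hi), constraints)
    if x is None:
        return None
    return _make_pattern(np.round(x[:n]), table, obs, config)


def solve_min_both(
    obs: float,
    table: PtmTable,
    config: InferenceConfig,
    previous_score: float | None = None,
) -> PtmPattern | None:
    """Minimize the combined normalized objective
    ``|m.p - obs| / eps_max + sum(p) / P_max``.

    With ``previous_score`` given, strict improvement is enforced on the
    actual combined score (big-M disjunction over the sign of the error).
    """
    n = len(table)
    masses = table.masses
    eps_max = config.eps_max
    p_max = config.resolve_p_max(table)
    has_prev = previous_score is not None
    nv = n + 1 + (1 if has_prev else 0)
    c = np.zeros(nv)
    c[:n] = 1.0 / p_max
    c[n] = 1.0 / eps_max
    integrality = np.zeros(nv)
    integrality[:n] = 1
    lo = np.zeros(nv)
    hi = np.concatenate([table.upper_bounds.astype(float), [eps_max]])
    if has_prev:
        integrality[n + 1] = 1
        hi = np.concatenate([hi, [1.0]])

    def row(pvec, tcoef=0.0, bcoef=0.0):
        r = np.zeros(nv)
        r[:n] = pvec
        r[n] = tcoef
        if has_prev:
            r[n + 1] = bcoef
        return r

    constraints = [
        LinearConstraint(row(masses, tcoef=-1.0), lb=-np.inf, ub=obs),  # |m.p - obs| <= t
        LinearConstraint(row(masses, tcoef=+1.0), lb=obs, ub=np.inf),
    ]
    if has_prev:
        bound = previous_score + config.score_step
        big_m = 2.0 * (1.0 + abs(obs) / eps_max + bound + table.upper_bounds.sum() / p_max)
        # score with signed error: (m.p - obs)/eps_max + sum(p)/P_max >= bound - M*b
        pos = masses / eps_max + 1.0 / p_max
        neg = -masses / eps_max + 1.0 / p_max
        constraints.append(
            LinearConstraint(row(pos, bcoef=big_m), lb=bound + obs / eps_max, ub=np.inf)
        )
        constraints.append(
            LinearConstraint(row(neg, bcoef=-big_m), lb=bound - obs / eps_max - big_m, ub=np.inf)
        )
    x = _run_milp(c, integrality, Bounds(lo, hi), constraints)
    if x is None:
        return None
    return _make_pattern(np.round(x[:n]), table, obs, config)


_SOLVERS = {
    "min_ptm": solve_min_ptm,
    "min_error": solve_min_error,
    "min_both": solve_min_both,
}


def _objective_value(pattern: PtmPattern, objective: str):
    if objective == "min_ptm":
        return pattern.total_ptms
    if objective == "min_error":
        return pattern.error
    return pattern.combined_score


def enumerate_k_solutions(
    obs: float, table: PtmTable, config: InferenceConfig
) -> list[PtmPattern]:
    """The k best patterns for one observed shift ("laps").

    Re-solves the chosen program, each lap constrained to strictly improve
    on nothing less than the previous optimum, so objective values
    strictly increase along the returned list.  Stops early when the
    constrained program becomes infeasible.
    """
    solver = _SOLVERS[config.objective]
    out: list[PtmPattern] = []
    previous = None
    for _ in range(config.laps):
        pattern = solver(obs, table, config, previous)
        if pattern is None:
            break
        out.append(pattern)
        previous = _objective_value(pattern, config.objective)
    return out
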