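"""Expected mean squares and balanced ANOVA projections.

For a balanced mixed design the expected value of each term's mean square
is a known linear combination of the variance components; equating observed
mean squares to these expectations and solving the (triangular) linear
system yields method-of-moments component estimates.  The coefficients are
produced by the classical Cornfield-Tukey auxiliary-table algorithm
(restricted-model convention: interactions containing a fixed factor drop
out of the fixed factor's crossed partners' expectations).

The same machinery serves the univariate mixed models (response vector y)
and PERMANOVA (Gower-centered inner-product matrix G): in both cases the
sum of squares of a term is tr(H_T G) with H_T the orthogonal projection
onto the term's contrast subspace, and G = y~ y~' in the univariate case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError

REP = "_rep"  # pseudo-subscript for the replicate index


@dataclass(frozen=True)
class FactorSpec:
    """One classification factor of a balanced design.

    ``n_levels`` counts levels per combination of the nesting parents
    (e.g. 5 locations per island).
    """

    name: str
    n_levels: int
    fixed: bool = False
    nested_in: tuple[str, ...] = ()


class VarPartModel:
    """Balanced mixed-model variance partitioning for a declared term list.

    Parameters
    ----------
    factors : list of FactorSpec in hierarchy order.
    terms : list of tuples of factor names; each tuple is the *essential*
        subscript set of the term (nesting parents are added automatically).
        The residual term is implicit.
    n_replicates : observations per finest cell.
    """

    def __init__(self, factors: list[FactorSpec], terms: list[tuple[str, ...]],
                 n_replicates: int):
        self.factors = {f.name: f for f in factors}
        if len(self.factors) != len(factors):
            raise ValueError("duplicate factor names")
        self.terms = [tuple(t) for t in terms]
        self.n_replicates = int(n_replicates)
        self._ancestors: dict[str, frozenset[str]] = {}
        for f in factors:
            anc = set()
            stack = list(f.nested_in)
            while stack:
                p = stack.pop()
                if p not in self.factors:
                    raise ValueError(f"unknown nesting parent {p!r}")
                if p not in anc:
                    anc.add(p)
                    stack.extend(self.factors[p].nested_in)
            self._ancestors[f.name] = frozenset(anc)
        self.term_names = [self._term_name(t) for t in self.terms]

    # -- structure ---------------------------------------------------------

    def _term_name(self, term: tuple[str, ...]) -> str:
        return ":".join(term)

    def subscripts(self, term: tuple[str, ...]) -> frozenset[str]:
        """Essential plus bracket (nesting) subscripts of a term."""
        subs = set(term)
        for f in term:
            subs |= self._ancestors[f]
        return frozenset(subs)

    def is_random(self, term: tuple[str, ...]) -> bool:
        return any(not self.factors[f].fixed for f in term)

    def df(self, term: tuple[str, ...]) -> int:
        subs = self.subscripts(term)
        out = 1
        for f in subs:
            n = self.factors[f].n_levels
            out *= (n - 1) if f in term else n
        return out

    @property
    def n_observations(self) -> int:
        out = self.n_replicates
        for f in self.factors.values():
            out *= f.n_levels
        return out

    @property
    def residual_df(self) -> int:
        return self.n_observations - 1 - sum(self.df(t) for t in self.terms)

    # -- Cornfield-Tukey table --------------------------------------------

    def _ct_row(self, term: tuple[str, ...]) -> dict[str, float]:
        """Auxiliary-table row of the component belonging to ``term``."""
        subs = self.subscripts(term)
        row: dict[str, float] = {}
        for name, f in self.factors.items():
            if name in subs and name not in term:
                row[name] = 1.0  # bracket (nesting) subscript
            elif name in term:
                row[name] = 0.0 if f.fixed else 1.0
            else:
                row[name] = float(f.n_levels)
        row[REP] = float(self.n_replicates)
        return row

    def ems_matrix(self) -> pd.DataFrame:
        """Coefficient of each variance component in each term's E[MS].

        Rows: model terms plus ``Residual``; columns: components (one per
        term, fixed-effect terms appear as theta-style components) plus
        ``Residual`` (sigma^2_eps).  The residual row is (0, ..., 0, 1).
        """
        all_terms = self.terms + [None]  # None = residual component
        names = self.term_names + ["Residual"]
        coef = np.zeros((len(all_terms), len(all_terms)))
        n_total = self.n_observations
        for i, t in enumerate(self.terms):
            subs_t = self.subscripts(t)
            for j, u in enumerate(all_terms):
                if u is None:
                    coef[i, j] = 1.0  # residual contributes to every E[MS]
                    continue
                subs_u = self.subscripts(u)
                if not subs_t <= subs_u:
                    continue
                row = self._ct_row(u)
                cols = [f for f in self.factors if f not in subs_t] + [REP]
                coef[i, j] = float(np.prod([row[c] for c in cols]))
        coef[-1, -1] = 1.0  # E[MS_resid] = sigma^2_eps
        _ = n_total
        return pd.DataFrame(coef, index=names, columns=names)

    # -- projections -------------------------------------------------------

    def _cell_codes(self, labels: pd.DataFrame, cols: list[str]) -> np.ndarray:
        key = labels[cols].astype(str).agg("\x1f".join, axis=1)
        return pd.factorize(key)[0]

    def projections(self, labels: pd.DataFrame) -> dict[str, np.ndarray]:
        """Orthogonal projection H_T per term (plus ``Residual``).

        ``labels`` must contain one column per factor.  Raises
        :class:`DesignError` if the design is unbalanced.
        """
        n = len(labels)
        for term in self.terms:
            codes = self._cell_codes(labels, sorted(self.subscripts(term)))
            counts = np.bincount(codes)
            if len(set(counts.tolist())) != 1:
                raise DesignError(f"unbalanced cells for term {self._term_name(term)}")

        ones = np.full((n, n), 1.0 / n)
        hs: dict[frozenset, np.ndarray] = {}
        order = sorted(self.terms, key=lambda t: len(self.subscripts(t)))
        for term in order:
            subs = self.subscripts(term)
            codes = self._cell_codes(labels, sorted(subs))
            k = codes.max() + 1
            a = np.zeros((n, k))
            a[np.arange(n), codes] = 1.0
            p = a @ np.linalg.pinv(a)
            h = p - ones
            for usubs, uh in hs.items():
                if usubs < subs:
                    h = h - uh
            hs[subs] = h

        out = {self._term_name(t): hs[self.subscripts(t)] for t in self.terms}
        resid = np.eye(n) - ones
        for h in out.values():
            resid = resid - h
        out["Residual"] = resid
        return out

    # -- fitting -----------------------------------------------------------

    def mean_squares(self, projections: dict[str, np.ndarray],
                     g: np.ndarray) -> pd.DataFrame:
        """SS, df and MS per term from the centered inner-product matrix."""
        rows = []
        for term in self.terms:
            name = self._term_name(term)
            ss = float(np.sum(projections[name] * g.T))
            d = self.df(term)
            rows.append((name, d, ss, ss / d))
        ss_res = float(np.sum(projections["Residual"] * g.T))
        d_res = self.residual_df
        rows.append(("Residual", d_res, ss_res, ss_res / d_res if d_res > 0 else np.nan))
        return pd.DataFrame(rows, columns=["term", "df", "SS", "MS"]).set_index("term")

    def solve_components(self, ms: pd.Series) -> pd.Series:
        """Solve C sigma^2 = MS for the variance components (signed)."""
        c = self.ems_matrix()
        sol = np.linalg.solve(c.to_numpy(), ms.loc[c.index].to_numpy())
        return pd.Series(sol, index=c.index)

    def denominator(self, term_name: str) -> pd.Series:
        """Linear combination of other mean squares forming the F denominator.

        The combination a satisfies sum_U a_U E[MS_U] = E[MS_T] minus the
        tested component's own contribution; for many terms this is a single
        mean square, otherwise a quasi-F combination.
        """
        c = self.ems_matrix()
        target = c.loc[term_name].copy()
        target[term_name] = 0.0
        others = c.drop(index=term_name)
        a, res, *_ = np.linalg.lstsq(others.to_numpy().T, target.to_numpy(), rcond=None)
        approx = others.to_numpy().T @ a
        if not np.allclose(approx, target.to_numpy(), atol=1e-8):
            raise DesignError(f"no mean-square combination matches E[MS] of {term_name}")
        a[np.abs(a) < 1e-10] = 0.0
        return pd.Series(a, index=others.index)

    def pseudo_f(self, ms_table: pd.DataFrame) -> pd.Series:
        """Pseudo-F per model term with EMS-derived denominators."""
        out = {}
        for name in self.term_names:
            denom_w = self.denominator(name)
            denom = float(denom_w @ ms_table.loc[denom_w.index, "MS"])
            ms_t = ms_table.loc[name, "MS"]
            out[name] = ms_t / denom if denom > 0 else np.nan
        return pd.Series(out)


def standard_design_model(design, include_island_observer: bool = True,
                          include_observer: bool = True) -> VarPartModel:
    """Model for the study's balanced design.

    Island is fixed; Location (nested in Island), Transect (nested in
    Location), Observer (crossed) and the Observer interactions are random.
    ``include_island_observer`` controls whether the Island:Observer term is
    in the model (the univariate mixed models omit it); ``include_observer``
    set to False drops Observer and all its interactions (used by the
    multivariate precision proxy).
    """
    factors = [
        FactorSpec("island", design.n_islands, fixed=True),
        FactorSpec("location", design.locations_per_island, nested_in=("island",)),
        FactorSpec("transect", design.transects_per_location, nested_in=("location",)),
    ]
    terms: list[tuple[str, ...]] = [("island",), ("location",), ("transect",)]
    n_rep = design.repeats_per_observer
    if include_observer:
        factors.append(FactorSpec("observer", design.n_observers))
        terms.append(("observer",))
        if include_island_observer:
            terms.append(("island", "observer"))
        terms.append(("location", "observer"))
        terms.append(("transect", "observer"))
    else:
        n_rep = design.repeats_per_observer * design.n_observers
    return VarPartModel(factors, terms, n_replicates=n_rep)
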