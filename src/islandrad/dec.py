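"""Dispersal-Extinction-Cladogenesis (DEC) likelihood and ancestral ranges.

The DEC model describes geographic-range evolution on a time-calibrated
tree.  A range is a non-empty subset of K discrete areas (here: islands),
encoded as a bitmask under a fixed area order.  Along a branch the range
evolves anagenetically as a continuous-time Markov chain: an occupied range
gains area j at rate ``d x (number of occupied source areas with a nonzero
dispersal multiplier into j)`` and loses each occupied area at rate ``e``;
the empty (null) range is an internal absorbing state.  At a speciation
node the parent range splits cladogenetically: a single-area range is
inherited identically by both daughters, while a multi-area range R either
passes to one daughter intact with the other daughter restricted to a
single area a in R (subset sympatry / peripheral-isolate speciation) or is
divided between the daughters as {a} and R \\ {a} (vicariance).  All allowed
ordered daughter-pair scenarios get equal weight by default.

Time stratification expresses island geology: an island that has not yet
emerged at time t is unavailable, so dispersal into it is impossible and no
lineage may occupy a range containing it.  Strata are delimited by the
configured emergence ages; branch transition matrices are computed piecewise
with hard projections at stratum boundaries.  The unconstrained model is
the single-stratum special case with every area always available.

The tip-to-root pruning recursion, maximum-likelihood estimation of (d, e),
marginal ancestral-range reconstruction, the multi-island ("widespread")
summary, and the >= 2 log-likelihood-unit model-selection rule live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .chronogram import Chronogram, RangeTable

__all__ = [
    "DECParams",
    "Stratification",
    "AncestralRangeReport",
    "ModelSelection",
    "FitResult",
    "strata_from_emergence",
    "state_name",
    "cladogenesis_scenarios",
    "build_q",
    "dec_loglik",
    "fit_dec",
    "ancestral_ranges",
    "summarize_widespread",
    "compare_models",
]

MAX_AREAS = 8  # 2^8 = 256 states; larger systems are out of scope


# ---------------------------------------------------------------------------
# state space


def state_name(mask: int, areas: Sequence[str], *, sep: str = "/") -> str:
    if mask == 0:
        return "(null)"
    return sep.join(a for i, a in enumerate(areas) if mask >> i & 1)


def popcount(mask: int) -> int:
    return bin(mask).count("1")


@lru_cache(maxsize=4096)
def cladogenesis_scenarios(state: int) -> tuple[tuple[int, int, str], ...]:
    """Ordered daughter-range scenarios ``(left, right, kind)`` for a range.

    Single-area ranges are inherited identically.  For a multi-area range R
    the scenarios are, for every area a in R: subset sympatry (a, R) and
    (R, a), and vicariance (a, R \\ a) and (R \\ a, a).  Duplicate ordered
    pairs (which arise for |R| = 2) are merged; the list is sorted for
    deterministic iteration.
    """
    if state == 0:
        return ()
    bits = [1 << i for i in range(state.bit_length()) if state >> i & 1]
    if len(bits) == 1:
        return ((state, state, "sympatry"),)
    seen: dict[tuple[int, int], str] = {}
    for a in bits:
        rest = state & ~a
        for pair, kind in (
            ((a, state), "sympatry"),
            ((state, a), "sympatry"),
            ((a, rest), "vicariance"),
            ((rest, a), "vicariance"),
        ):
            seen.setdefault(pair, kind)
    return tuple(sorted((l, r, k) for (l, r), k in seen.items()))


# ---------------------------------------------------------------------------
# parameters and stratification


@dataclass(frozen=True)
class Stratification:
    """Piecewise-constant area availability through time.

    ``boundaries`` are strictly increasing ages (my); stratum ``j`` covers
    the half-open age interval (boundaries[j-1], boundaries[j]] with an
    implicit 0 on the young side and infinity beyond the last boundary.
    ``available`` gives one area-availability bitmask per stratum
    (len(boundaries) + 1 entries, young to old).
    """

    boundaries: tuple[float, ...]
    available: tuple[int, ...]

    def __post_init__(self):
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("stratum boundaries must be strictly increasing")
        if len(self.available) != len(self.boundaries) + 1:
            raise ValueError("need len(boundaries) + 1 availability masks")

    @property
    def n_strata(self) -> int:
        return len(self.available)

    def stratum_at(self, age: float) -> int:
        """Index of the stratum containing ``age`` (boundaries inclusive on
        the old side: an island is available at its exact emergence age)."""
        for j, b in enumerate(self.boundaries):
            if age <= b:
                return j
        return len(self.boundaries)


def strata_from_emergence(
    areas: Sequence[str], emergence_ages: Mapping[str, float]
) -> Stratification:
    """Build a stratification from per-island emergence (shield-end) ages.

    Every declared area must have an age; there is deliberately no default
    for any island.  An island is available at all times up to and including
    its emergence age.
    """
    missing = [a for a in areas if a not in emergence_ages]
    if missing:
        raise ValueError(f"emergence age required for area(s): {missing}")
    ages = {a: float(emergence_ages[a]) for a in areas}
    boundaries = tuple(sorted(set(ages.values())))
    available = []
    for j in range(len(boundaries) + 1):
        # stratum j spans ages up to boundaries[j]; an island is available
        # throughout iff it had emerged by the old end of the stratum
        old_end = boundaries[j] if j < len(boundaries) else math.inf
        mask = sum(
            1 << i for i, a in enumerate(areas) if ages[a] >= old_end
        )
        available.append(mask)
    return Stratification(boundaries=boundaries, available=tuple(available))


@dataclass(frozen=True)
class DECParams:
    """DEC rates plus optional stratification and dispersal multipliers.

    ``d`` and ``e`` are per-my event rates.  ``multipliers`` is an optional
    K x K source-to-target dispersal multiplier matrix (default: all ones,
    i.e. equal transition rates between areas).  ``strata=None`` is the
    unconstrained model.
    """

    d: float
    e: float
    areas: tuple[str, ...]
    strata: Stratification | None = None
    multipliers: np.ndarray | None = field(default=None, repr=False)
    scenario_weights: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise ValueError("rates d and e must be non-negative")
        k = len(self.areas)
        if k < 1 or k > MAX_AREAS:
            raise ValueError(f"number of areas must be in 1..{MAX_AREAS}")
        if self.multipliers is not None:
            m = np.asarray(self.multipliers, dtype=float)
            if m.shape != (k, k):
                raise ValueError("multiplier matrix must be K x K")
            object.__setattr__(self, "multipliers", m)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_states(self) -> int:
        return 1 << len(self.areas)

    def full_mask(self) -> int:
        return self.n_states - 1

    def available_at(self, age: float) -> int:
        if self.strata is None:
            return self.full_mask()
        return self.strata.available[self.strata.stratum_at(age)]

    def n_strata(self) -> int:
        return 1 if self.strata is None else self.strata.n_strata

    def stratum_available(self, j: int) -> int:
        if self.strata is None:
            return self.full_mask()
        return self.strata.available[j]

    def with_rates(self, d: float, e: float) -> "DECParams":
        return DECParams(
            d=d,
            e=e,
            areas=self.areas,
            strata=self.strata,
            multipliers=self.multipliers,
            scenario_weights=self.scenario_weights,
        )

    def scenario_table(self, state: int) -> tuple[tuple[int, int, float], ...]:
        """Normalized (left, right, weight) cladogenetic scenarios."""
        scen = cladogenesis_scenarios(state)
        if not scen:
            return ()
        w = self.scenario_weights or {}
        raw = [float(w.get(kind, 1.0)) for (_, _, kind) in scen]
        total = sum(raw)
        if total <= 0:
            raise ValueError("scenario weights sum to zero")
        return tuple(
            (l, r, wt / total) for (l, r, _), wt in zip(scen, raw)
        )


# ---------------------------------------------------------------------------
# generator matrix


def build_q(params: DECParams, stratum: int = 0) -> np.ndarray:
    """Anagenetic DEC generator over all 2^K range states for one stratum.

    Rows of states that are not subsets of the stratum's available-area mask
    are zeroed (such states cannot be occupied); the null range is absorbing.
    Rows sum to zero.
    """
    k = params.n_areas
    S = params.n_states
    avail = params.stratum_available(stratum)
    m = params.multipliers
    Q = np.zeros((S, S))
    for s in range(1, S):
        if s & ~avail:
            continue  # unoccupiable state in this stratum
        occupied = [i for i in range(k) if s >> i & 1]
        # area gains
        for j in range(k):
            if s >> j & 1 or not avail >> j & 1:
                continue
            if m is None:
                rate = params.d * len(occupied)
            else:
                rate = params.d * sum(m[i, j] for i in occupied)
            if rate > 0:
                Q[s, s | (1 << j)] += rate
        # area losses (to null when the last area is lost)
        for i in occupied:
            Q[s, s & ~(1 << i)] += params.e
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _projection(params: DECParams, stratum: int) -> np.ndarray:
    """Diagonal 0/1 vector keeping states occupiable in the stratum."""
    avail = params.stratum_available(stratum)
    S = params.n_states
    keep = np.zeros(S)
    for s in range(S):
        if not s & ~avail:
            keep[s] = 1.0
    return keep


# ---------------------------------------------------------------------------
# pruning


class _Engine:
    """Shared machinery for likelihood and marginal reconstruction.

    Conditional likelihood vectors are indexed by range bitmask.  ``L[v]``
    is the probability of the data in v's subtree given the range at node v
    immediately before its cladogenetic split; ``B[v]`` maps a vector at
    node v to the message at the parent side of v's branch, including
    stratum-boundary projections.
    """

    def __init__(self, chron: Chronogram, ranges: RangeTable, params: DECParams):
        if tuple(ranges.areas) != tuple(params.areas):
            raise ValueError("range table and DEC params disagree on areas")
        if not chron.is_binary():
            raise ValueError("DEC requires a fully bifurcating tree")
        ranges.check_tips(chron)
        self.chron = chron
        self.ranges = ranges
        self.params = params
        self.S = params.n_states
        self.Qs = [build_q(params, j) for j in range(params.n_strata())]
        self.projs = [_projection(params, j) for j in range(params.n_strata())]
        self._check_tip_availability()
        self._check_root_feasible()

    def _check_tip_availability(self) -> None:
        avail0 = self.params.available_at(0.0)
        for tip in self.chron.tip_labels:
            mask = self.ranges.bitmask(tip)
            if mask & ~avail0:
                raise ValueError(
                    f"tip {tip!r} occupies an area unavailable at present"
                )

    def _check_root_feasible(self) -> None:
        avail = self.params.available_at(self.chron.root_age)
        if avail == 0:
            raise ValueError(
                "the root age predates the emergence of every configured "
                "island; range evolution cannot start — extend the area set "
                "or revisit the emergence ages"
            )

    # -- branch operator --------------------------------------------------

    def _segments(self, t_child: float, t_parent: float):
        """(dt, stratum) pieces of a branch, young to old."""
        strata = self.params.strata
        if strata is None:
            return [(t_parent - t_child, 0)]
        cuts = [t_child]
        for b in strata.boundaries:
            if t_child < b < t_parent:
                cuts.append(b)
        cuts.append(t_parent)
        return [
            (hi - lo, strata.stratum_at(hi))
            for lo, hi in zip(cuts[:-1], cuts[1:])
        ]

    def branch_operator(self, node: dendropy.Node) -> np.ndarray:
        """Matrix B with ``message_parent = B @ L_child`` for node's branch."""
        t_child = self.chron.age(node)
        t_parent = self.chron.age(node.parent_node)
        B = np.eye(self.S)
        for dt, j in self._segments(t_child, t_parent):
            # states unoccupiable anywhere within the segment carry no mass
            # at its young end (an island cannot be occupied before emerging)
            B = self.projs[j][:, None] * B
            if dt > 0:
                B = expm(self.Qs[j] * dt) @ B
        # states unoccupiable at the parent end carry no mass
        top = self.params.strata.stratum_at(t_parent) if self.params.strata else 0
        B = self.projs[top][:, None] * B
        return B

    # -- cladogenesis ------------------------------------------------------

    def combine(self, m_left: np.ndarray, m_right: np.ndarray) -> np.ndarray:
        """Parent-range conditional likelihood from daughter messages."""
        out = np.zeros(self.S)
        for s in range(1, self.S):
            total = 0.0
            for l, r, w in self.params.scenario_table(s):
                total += w * m_left[l] * m_right[r]
            out[s] = total
        return out

    # -- down pass ---------------------------------------------------------

    def down_pass(self):
        """Post-order conditional likelihoods with per-node scaling.

        Returns (L, B, M, logscale, loglik) where the dicts are keyed by
        node; M[v] is the (scaled) message at the parent side of v's branch.
        """
        L: dict = {}
        B: dict = {}
        M: dict = {}
        log_scale = 0.0
        for node in self.chron.tree.postorder_node_iter():
            if node.is_leaf():
                vec = np.zeros(self.S)
                vec[self.ranges.bitmask(node.taxon.label)] = 1.0
            else:
                c1, c2 = node.child_nodes()
                vec = self.combine(M[c1], M[c2])
                age = self.chron.age(node)
                j = (
                    self.params.strata.stratum_at(age)
                    if self.params.strata
                    else 0
                )
                vec = vec * self.projs[j]
            scale = vec.max()
            if scale <= 0:
                return L, B, M, -math.inf, -math.inf
            vec = vec / scale
            log_scale += math.log(scale)
            L[node] = vec
            if node is not self.chron.root:
                B[node] = self.branch_operator(node)
                M[node] = B[node] @ vec
        root_w = self.root_weights()
        total = float(root_w @ L[self.chron.root])
        loglik = -math.inf if total <= 0 else math.log(total) + log_scale
        return L, B, M, log_scale, loglik

    def root_weights(self) -> np.ndarray:
        """Equal weights over non-null ranges occupiable at the root age."""
        avail = self.params.available_at(self.chron.root_age)
        w = np.zeros(self.S)
        states = [s for s in range(1, self.S) if not s & ~avail]
        for s in states:
            w[s] = 1.0 / len(states)
        return w


def dec_loglik(
    chron: Chronogram, ranges: RangeTable, params: DECParams
) -> float:
    """DEC log-likelihood of the tip ranges by pruning over range states.

    The root is summed over all occupiable non-null ranges with equal
    weights; no conditioning on survival is applied.
    """
    engine = _Engine(chron, ranges, params)
    *_, loglik = engine.down_pass()
    return loglik


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class FitResult:
    params: DECParams
    loglik: float
    converged: bool
    n_starts: int
    start_logliks: tuple[float, ...]


_DEFAULT_BOUNDS = ((1e-5, 10.0), (1e-5, 10.0))


def fit_dec(
    chron: Chronogram,
    ranges: RangeTable,
    template: DECParams,
    *,
    bounds: tuple[tuple[float, float], tuple[float, float]] = _DEFAULT_BOUNDS,
    n_starts: int = 3,
) -> FitResult:
    """Bounded two-parameter ML estimation of (d, e).

    Optimizes in log10 space with L-BFGS-B from a small deterministic grid
    of starting points; reports the best run and the per-start optima so
    multiple-start agreement is auditable.
    """
    engine = _Engine(chron, ranges, template)

    def negloglik(x: np.ndarray) -> float:
        p = template.with_rates(10.0 ** x[0], 10.0 ** x[1])
        engine.params = p
        engine.Qs = [build_q(p, j) for j in range(p.n_strata())]
        *_, ll = engine.down_pass()
        return 1e12 if not np.isfinite(ll) else -ll

    log_bounds = [
        (math.log10(bounds[0][0]), math.log10(bounds[0][1])),
        (math.log10(bounds[1][0]), math.log10(bounds[1][1])),
    ]
    starts = [(-2.0, -2.0), (-1.0, -3.0), (-3.0, -1.5)][: max(1, n_starts)]
    best = None
    start_lls = []
    any_converged = False
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in log_bounds], [b[1] for b in log_bounds])
        res = minimize(
            negloglik,
            x0=np.asarray(x0),
            method="L-BFGS-B",
            bounds=log_bounds,
        )
        start_lls.append(-float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError("DEC optimizer failed from every starting point")
    d_hat, e_hat = 10.0 ** best.x[0], 10.0 ** best.x[1]
    return FitResult(
        params=template.with_rates(float(d_hat), float(e_hat)),
        loglik=-float(best.fun),
        converged=any_converged,
        n_starts=len(starts),
        start_logliks=tuple(start_lls),
    )


# ---------------------------------------------------------------------------
# marginal ancestral ranges


@dataclass(frozen=True)
class NodeReconstruction:
    node_id: str
    tip_pair: tuple[str, str]
    age: float
    probs: np.ndarray = field(repr=False)  # length 2^K, null entry 0


@dataclass(frozen=True)
class AncestralRangeReport:
    areas: tuple[str, ...]
    nodes: tuple[NodeReconstruction, ...]
    loglik: float
    stratified: bool

    def node_table(self) -> pd.DataFrame:
        rows = []
        for rec in self.nodes:
            row = {
                "node_id": rec.node_id,
                "mrca_of": f"{rec.tip_pair[0]}|{rec.tip_pair[1]}",
                "age_my": rec.age,
            }
            for s in range(1, len(rec.probs)):
                row[state_name(s, self.areas)] = rec.probs[s]
            rows.append(row)
        return pd.DataFrame(rows)


def ancestral_ranges(
    chron: Chronogram, ranges: RangeTable, params: DECParams
) -> AncestralRangeReport:
    """Marginal range probabilities at every internal node.

    For node v and range s, the marginal is the likelihood of the full data
    with the range at v (immediately before its split) fixed to s, divided
    by the total likelihood; computed by combining the below-node partials
    from the pruning pass with an outside (above-node) pass through the
    cladogenetic scenarios and branch operators.
    """
    engine = _Engine(chron, ranges, params)
    L, B, M, _, loglik = engine.down_pass()
    if not np.isfinite(loglik):
        raise ValueError("data have zero likelihood under these parameters")
    S = engine.S
    U: dict = {engine.chron.root: engine.root_weights()}
    records = []
    counter = 0
    for node in chron.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        # marginal at this node
        post = U[node] * L[node]
        total = post.sum()
        probs = post / total
        counter += 1
        tips = chron.clade_tip_labels(node)
        records.append(
            NodeReconstruction(
                node_id=f"N{counter}",
                tip_pair=(tips[0], tips[-1]),
                age=chron.age(node),
                probs=probs,
            )
        )
        # push outside likelihoods to the children
        c1, c2 = node.child_nodes()
        for child, sib in ((c1, c2), (c2, c1)):
            A = np.zeros(S)
            u = U[node]
            m_sib = M[sib]
            for s in range(1, S):
                if u[s] == 0:
                    continue
                for l, r, w in engine.params.scenario_table(s):
                    tau_c, tau_s = (l, r) if child is c1 else (r, l)
                    A[tau_c] += u[s] * w * m_sib[tau_s]
            u_child = B[child].T @ A
            norm = u_child.max()
            U[child] = u_child / norm if norm > 0 else u_child
    return AncestralRangeReport(
        areas=params.areas,
        nodes=tuple(records),
        loglik=loglik,
        stratified=params.strata is not None,
    )


# ---------------------------------------------------------------------------
# summaries and model choice


def summarize_widespread(
    report: AncestralRangeReport, *, threshold: float = 0.15
) -> pd.DataFrame:
    """Pool multi-island range probabilities per node as "widespread".

    Single-island probabilities are listed per island.  Any individual
    multi-island range whose probability reaches ``threshold`` is named
    explicitly (e.g. ``Maui/Hawaii``) instead of being pooled.
    """
    rows = []
    for rec in report.nodes:
        row: dict = {"node_id": rec.node_id, "age_my": rec.age}
        widespread = 0.0
        for s in range(1, len(rec.probs)):
            p = float(rec.probs[s])
            if popcount(s) == 1:
                row[state_name(s, report.areas)] = p
            elif p >= threshold:
                row[state_name(s, report.areas)] = p
            else:
                widespread += p
        row["widespread"] = widespread
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)


@dataclass(frozen=True)
class ModelSelection:
    best: str | None
    separated: bool
    margin: float
    logliks: Mapping[str, float]

    def __str__(self) -> str:
        if self.separated:
            return f"{self.best} (margin {self.margin:.2f} log-likelihood units)"
        return f"not separated (margin {self.margin:.2f} < 2 units)"


def compare_models(
    fits: Sequence[tuple[str, float]], *, min_separation: float = 2.0
) -> ModelSelection:
    """Pick the model whose log-likelihood beats all others by >= 2 units."""
    if len(fits) < 2:
        raise ValueError("model comparison needs at least two fits")
    ranked = sorted(fits, key=lambda kv: kv[1], reverse=True)
    margin = ranked[0][1] - ranked[1][1]
    separated = margin >= min_separation
    return ModelSelection(
        best=ranked[0][0] if separated else None,
        separated=separated,
        margin=margin,
        logliks=dict(fits),
    )
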