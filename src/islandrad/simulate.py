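"""Synthetic chronograms, DEC range histories, and divergence-pair data.

The generators provide truth-known inputs for every analysis stage:

* birth-death chronograms, either constant-rate or with a recent rate burst
  (speciation rate multiplied after a shift time before present), emulating
  a radiation in which one clade diversified steadily while its sister
  clade shows long stems leading to a near-simultaneous recent burst;
* two-clade trees grafted at a common root, with tip membership lists for
  the skewness contrast;
* forward DEC simulations of island ranges down a chronogram under known
  dispersal/extinction rates, honouring island emergence strata; and
* pairwise COI-style divergence datasets clustered around a true
  rate x age product with occasional planted outliers.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .calibration import DivergencePair
from .chronogram import Chronogram, RangeTable
from .dec import DECParams

__all__ = [
    "TreeSimSpec",
    "DECSimSpec",
    "DECSimResult",
    "DivergencePairSim",
    "simulate_chronogram",
    "simulate_two_clade_tree",
    "simulate_dec_tips",
    "simulate_divergence_pairs",
]


@dataclass(frozen=True)
class TreeSimSpec:
    """Birth-death simulation settings.

    Exactly one of ``n_tips`` (tip-count conditioning, constant-rate only)
    or ``crown_age`` (my) must be given.  ``mode="burst"`` multiplies the
    speciation rate by ``burst_multiplier`` within ``shift_time`` my of the
    present; the defaults (shift 1.5 my, multiplier 8) produce the
    long-stems-then-burst shape typical of a clade whose diversification is
    concentrated in the era of the youngest islands.
    """

    lam: float
    mu: float = 0.0
    mode: str = "constant"
    shift_time: float = 1.5
    burst_multiplier: float = 8.0
    n_tips: int | None = None
    crown_age: float | None = None
    max_retries: int = 1000

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("speciation rate must be positive")
        if self.mu < 0:
            raise ValueError("extinction rate must be non-negative")
        if self.mode not in ("constant", "burst"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.burst_multiplier <= 0:
            raise ValueError("burst multiplier must be positive")
        if self.n_tips is None and self.crown_age is None:
            raise ValueError("specify n_tips, crown_age, or both")
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("need at least two tips")
        if self.mode == "burst" and self.crown_age is None:
            raise ValueError(
                "burst mode needs a known present: condition on crown_age"
            )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# crown-age conditioned recursive simulation


def _lineage_rates(t: float, T: float, spec: TreeSimSpec) -> float:
    lam = spec.lam
    if spec.mode == "burst" and (T - t) < spec.shift_time:
        lam *= spec.burst_multiplier
    return lam


def _next_event(t0: float, T: float, spec: TreeSimSpec, rng) -> tuple[float, str] | None:
    """Time and type of the next event on a lineage, or None if none by T."""
    t = t0
    while t < T:
        seg_end = T
        if spec.mode == "burst" and t < T - spec.shift_time:
            seg_end = T - spec.shift_time
        lam = _lineage_rates(t, T, spec)
        total = lam + spec.mu
        if total <= 0:
            t = seg_end
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt < seg_end:
            kind = "speciation" if rng.random() < lam / total else "extinction"
            return (t + dt, kind)
        t = seg_end
    return None


def _sim_lineage(t0: float, T: float, spec: TreeSimSpec, rng):
    """Simulate a lineage born at t0; return (node, node_time) or None.

    Extinct subtrees are pruned on the fly, so a surviving child whose
    sibling died simply inherits the full branch.
    """
    event = _next_event(t0, T, spec, rng)
    if event is None:
        leaf = dendropy.Node()
        return leaf, T
    t_ev, kind = event
    if kind == "extinction":
        return None
    left = _sim_lineage(t_ev, T, spec, rng)
    right = _sim_lineage(t_ev, T, spec, rng)
    if left is None and right is None:
        return None
    if left is None or right is None:
        return left or right
    node = dendropy.Node()
    for child, child_time in (left, right):
        node.add_child(child)
        child.edge.length = child_time - t_ev
    return node, t_ev


def _finalize(root: dendropy.Node, labels: list[str] | None = None) -> Chronogram:
    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter()):
        label = labels[i] if labels else f"t{i + 1}"
        taxon = tree.taxon_namespace.require_taxon(label=label)
        leaf.taxon = taxon
    return Chronogram(tree)


def _simulate_crown(spec: TreeSimSpec, rng) -> dendropy.Node:
    """Crown tree of fixed age: both root children must survive to T."""
    T = spec.crown_age
    for _ in range(spec.max_retries):
        left = _sim_lineage(0.0, T, spec, rng)
        right = _sim_lineage(0.0, T, spec, rng)
        if left is None or right is None:
            continue
        root = dendropy.Node()
        for child, child_time in (left, right):
            root.add_child(child)
            child.edge.length = child_time
        if spec.n_tips is not None:
            # joint conditioning on crown age and tip count, by rejection
            if sum(1 for _ in root.leaf_iter()) != spec.n_tips:
                continue
        return root
    raise RuntimeError("crown simulation failed: all lineages died repeatedly")


# ---------------------------------------------------------------------------
# tip-count conditioned iterative simulation


def _simulate_n_tips(spec: TreeSimSpec, rng) -> dendropy.Node:
    """Forward Gillespie from a crown pair, cut at a uniform time after the
    lineage count first reaches the target (generalized-sampling style)."""
    lam, mu, n = spec.lam, spec.mu, spec.n_tips
    for _ in range(spec.max_retries):
        root = dendropy.Node()
        # each active lineage: [birth_time, parent_node]
        active: list[list] = [[0.0, root], [0.0, root]]
        dead: list[dendropy.Node] = []
        t = 0.0
        cut = None
        while True:
            k = len(active)
            if k == 0:
                break
            total = k * (lam + mu)
            dt = rng.exponential(1.0 / total)
            if k == n:
                cut = t + rng.random() * dt
                break
            t += dt
            idx = rng.integers(k)
            birth, parent = active.pop(idx)
            node = dendropy.Node()
            parent.add_child(node)
            node.edge.length = t - birth
            if rng.random() < lam / (lam + mu):
                active.append([t, node])
                active.append([t, node])
            else:
                node.annotations.add_new("extinct", True)
                dead.append(node)
        if cut is None:
            continue
        for birth, parent in active:
            leaf = dendropy.Node()
            parent.add_child(leaf)
            leaf.edge.length = cut - birth
        if not _prune_dead(root, dead):
            continue
        return root
    raise RuntimeError("tip-count simulation failed: clade kept dying out")


def _prune_dead(root: dendropy.Node, dead: list[dendropy.Node]) -> bool:
    """Remove extinct tips and suppress unifurcations; True if the crown
    (two root children) survived."""
    for node in dead:
        current = node
        while current is not root and not current.child_nodes():
            parent = current.parent_node
            parent.remove_child(current)
            current = parent
    # suppress out-degree-1 internals, merging edge lengths
    stack = list(root.child_nodes())
    while stack:
        node = stack.pop()
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length += node.edge.length
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
            stack.append(child)
        else:
            stack.extend(children)
    return len(root.child_nodes()) == 2


def simulate_chronogram(spec: TreeSimSpec, seed) -> Chronogram:
    """Simulate a rooted ultrametric birth-death chronogram.

    Conditioning is on tip count (constant-rate) or on crown age; lineages
    that die out are pruned and the whole replicate is redrawn (up to
    ``spec.max_retries``) if the crown itself is lost.
    """
    rng = _rng(seed)
    if spec.crown_age is not None:
        root = _simulate_crown(spec, rng)
    else:
        root = _simulate_n_tips(spec, rng)
    return _finalize(root)


def simulate_two_clade_tree(
    spec1: TreeSimSpec,
    spec2: TreeSimSpec,
    *,
    root_age: float,
    seed,
) -> tuple[Chronogram, tuple[str, ...], tuple[str, ...]]:
    """Two crown-age-conditioned clades grafted to a common root.

    Returns the chronogram plus the two clades' tip label sets, ready for
    the branch-length skewness contrast.  Both specs must condition on
    crown ages strictly younger than ``root_age``.
    """
    rng = _rng(seed)
    if spec1.crown_age is None or spec2.crown_age is None:
        raise ValueError("both clades must condition on crown_age")
    if not (spec1.crown_age < root_age and spec2.crown_age < root_age):
        raise ValueError("crown ages must be younger than the root age")
    roots = [_simulate_crown(spec1, rng), _simulate_crown(spec2, rng)]
    top = dendropy.Node()
    for crown, spec in zip(roots, (spec1, spec2)):
        top.add_child(crown)
        crown.edge.length = root_age - spec.crown_age
    tree = dendropy.Tree(seed_node=top)
    tree.is_rooted = True
    clade_labels: list[list[str]] = [[], []]
    for ci, crown in enumerate(roots):
        prefix = "a" if ci == 0 else "b"
        for i, leaf in enumerate(crown.leaf_iter()):
            label = f"{prefix}{i + 1}"
            leaf.taxon = tree.taxon_namespace.require_taxon(label=label)
            clade_labels[ci].append(label)
    chron = Chronogram(tree)
    return chron, tuple(clade_labels[0]), tuple(clade_labels[1])


# ---------------------------------------------------------------------------
# DEC forward simulation


@dataclass(frozen=True)
class DECSimSpec:
    """Ground-truth settings for forward range simulation."""

    params: DECParams
    root_range: frozenset[str]
    resimulate_null: bool = True
    max_retries: int = 1000

    def root_mask(self) -> int:
        mask = 0
        for i, a in enumerate(self.params.areas):
            if a in self.root_range:
                mask |= 1 << i
        if mask == 0:
            raise ValueError("root range must be non-empty")
        return mask


@dataclass(frozen=True)
class DECSimResult:
    ranges: RangeTable
    node_truth: dict  # frozenset of tip labels -> range bitmask
    n_null_restarts: int


def _gain_rates(state: int, t: float, params: DECParams) -> dict[int, float]:
    avail = params.available_at(t)
    k = params.n_areas
    occupied = [i for i in range(k) if state >> i & 1]
    m = params.multipliers
    rates: dict[int, float] = {}
    for j in range(k):
        if state >> j & 1 or not avail >> j & 1:
            continue
        if m is None:
            rate = params.d * len(occupied)
        else:
            rate = params.d * sum(m[i, j] for i in occupied)
        if rate > 0:
            rates[j] = rate
    return rates


def _evolve_branch(state: int, t_from: float, t_to: float, params: DECParams, rng):
    """Anagenetic Gillespie from age t_from down to t_to (t_from > t_to).

    Returns the end state, possibly 0 (null) if the last area was lost.
    Availability can only grow toward the present, so stratum boundaries
    simply open new dispersal targets; the memoryless property lets us
    redraw the waiting time at each boundary.
    """
    t = t_from
    strata = params.strata
    while t > t_to and state != 0:
        gains = _gain_rates(state, t, params)
        loss_total = params.e * bin(state).count("1")
        total = sum(gains.values()) + loss_total
        boundary = t_to
        if strata is not None:
            below = [b for b in strata.boundaries if t_to < b < t]
            if below:
                boundary = max(below)
        if total <= 0:
            t = boundary
            if boundary == t_to:
                break
            continue
        dt = rng.exponential(1.0 / total)
        if t - dt <= boundary:
            t = boundary
            if boundary == t_to:
                break
            continue
        t -= dt
        u = rng.random() * total
        for j, rate in gains.items():
            if u < rate:
                state |= 1 << j
                break
            u -= rate
        else:
            if params.e > 0:
                occupied = [i for i in range(params.n_areas) if state >> i & 1]
                lost = occupied[min(int(u // params.e), len(occupied) - 1)]
                state &= ~(1 << lost)
    return state


def simulate_dec_tips(chron: Chronogram, spec: DECSimSpec, seed) -> DECSimResult:
    """Forward-simulate ranges down the chronogram under known DEC truth.

    Cladogenetic splits are drawn from the model's scenario distribution;
    anagenesis follows the stratum-specific generator.  A branch whose
    lineage collapses to the null range is redrawn (counted in
    ``n_null_restarts``) unless ``resimulate_null`` is off, in which case
    the null range propagates and the simulation fails if it reaches a tip.
    """
    rng = _rng(seed)
    params = spec.params
    root_mask = spec.root_mask()
    root_age = chron.root_age
    if root_mask & ~params.available_at(root_age):
        raise ValueError(
            "root range includes an island not yet emerged at the root age"
        )
    node_state: dict = {chron.root: root_mask}
    node_truth: dict = {}
    null_restarts = 0
    for node in chron.tree.preorder_node_iter():
        state = node_state[node]
        if node.is_leaf():
            continue
        tipset = frozenset(chron.clade_tip_labels(node))
        node_truth[tipset] = state
        scen = params.scenario_table(state)
        weights = np.array([w for (_, _, w) in scen])
        idx = rng.choice(len(scen), p=weights / weights.sum())
        left_state, right_state, _ = scen[idx]
        for child, start in zip(node.child_nodes(), (left_state, right_state)):
            t_from, t_to = chron.age(node), chron.age(child)
            end = _evolve_branch(start, t_from, t_to, params, rng)
            if spec.resimulate_null:
                tries = 0
                while end == 0:
                    tries += 1
                    null_restarts += 1
                    if tries > spec.max_retries:
                        raise RuntimeError(
                            "branch kept collapsing to the null range"
                        )
                    end = _evolve_branch(start, t_from, t_to, params, rng)
            node_state[child] = end
    ranges = {}
    for leaf in chron.tree.leaf_node_iter():
        mask = node_state[leaf]
        if mask == 0:
            raise RuntimeError(
                "a tip reached the null range with resimulate_null disabled"
            )
        ranges[leaf.taxon.label] = frozenset(
            a for i, a in enumerate(params.areas) if mask >> i & 1
        )
    return DECSimResult(
        ranges=RangeTable(areas=params.areas, ranges=ranges),
        node_truth=node_truth,
        n_null_restarts=null_restarts,
    )


# ---------------------------------------------------------------------------
# divergence pairs


@dataclass(frozen=True)
class DivergencePairSim:
    pairs: tuple[DivergencePair, ...]
    outlier_indices: tuple[int, ...]
    true_rate_pct_per_my: float
    calibration_age_my: float


def simulate_divergence_pairs(
    true_rate_pct_per_my: float,
    T: float,
    n: int,
    *,
    noise_sd: float = 0.0,
    outlier_frac: float = 0.0,
    seed,
) -> DivergencePairSim:
    """Pairwise divergences clustered near rate x T with planted outliers.

    Each clean pair's p-distance is ``rate/100 * T`` plus Gaussian noise
    (clipped to [0, 1]); a fraction ``outlier_frac`` of pairs is replaced
    by divergences 5-10x the true value, mimicking comparisons that predate
    the calibrating island.  The planted outlier index set is returned.
    """
    rng = _rng(seed)
    base = true_rate_pct_per_my / 100.0 * T
    n_out = int(round(outlier_frac * n))
    out_idx = (
        tuple(sorted(rng.choice(n, size=n_out, replace=False).tolist()))
        if n_out
        else ()
    )
    pairs = []
    for i in range(n):
        if i in out_idx:
            value = base * (5.0 + 5.0 * rng.random())
        else:
            value = base + rng.normal(0.0, noise_sd) if noise_sd > 0 else base
        value = float(np.clip(value, 0.0, 1.0))
        pairs.append(
            DivergencePair(
                pair_id=f"pair{i + 1}", id1=f"x{i + 1}", id2=f"y{i + 1}",
                p_distance=value,
            )
        )
    return DivergencePairSim(
        pairs=tuple(pairs),
        outlier_indices=out_idx,
        true_rate_pct_per_my=float(true_rate_pct_per_my),
        calibration_age_my=float(T),
    )
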