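"""Time-calibrated trees (chronograms) and tip-to-island range tables.

A chronogram is a rooted tree whose branch lengths are in absolute time
(here: millions of years, my).  All tips are contemporaneous, so the tree is
ultrametric and every node carries a well-defined age: its time before
present.  Everything downstream — patristic distances, clade branch-length
samples, DEC range reconstruction — consumes this object.

Tree plumbing (Newick parsing, MRCA queries, traversal) is delegated to
:mod:`dendropy`; this module adds age computation, ultrametricity
validation, and the island-range table used by the biogeographic stages.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "Chronogram",
    "RangeTable",
    "UltrametricityError",
    "HAWAIIAN_ISLANDS",
    "read_newick",
    "read_range_table",
    "mrca",
]

#: Conventional old-to-young ordering of the five high Hawaiian islands used
#: as the default area list.  The order is load-bearing: range bitmasks are
#: defined with bit ``i`` = presence on ``areas[i]``.
HAWAIIAN_ISLANDS: tuple[str, ...] = ("Kauai", "Oahu", "Molokai", "Maui", "Hawaii")


class UltrametricityError(ValueError):
    """Raised when a tree fails the equal root-to-tip path-length check."""


class Chronogram:
    """A rooted, ultrametric, time-calibrated tree.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree` with branch lengths in my.
    eps:
        Relative tolerance for the ultrametricity check: the spread of
        root-to-tip path lengths divided by tree height must not exceed it.
    strict:
        If True (default), non-ultrametric input raises
        :class:`UltrametricityError`; otherwise a warning is emitted and
        ages are still defined as the maximum path length to a descendant
        tip.
    """

    def __init__(self, tree: dendropy.Tree, *, eps: float = 1e-6, strict: bool = True):
        self.tree = tree
        self.eps = float(eps)
        self._validate_shape()
        self._ages: dict[dendropy.Node, float] = {}
        self._compute_ages()
        self._check_ultrametric(strict=strict)

    # -- construction / validation ---------------------------------------

    def _validate_shape(self) -> None:
        seen: set[str] = set()
        labels = []
        for leaf in self.tree.leaf_node_iter():
            label = _leaf_label(leaf)
            if label is None or label == "":
                raise ValueError("every tip must carry a label")
            if label in seen:
                raise ValueError(f"duplicate tip label: {label!r}")
            seen.add(label)
            labels.append(label)
        if len(labels) < 2:
            raise ValueError("a chronogram needs at least two tips")
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            if node.edge.length is None:
                raise ValueError(f"missing branch length above node {node!r}")
            if node.edge.length < 0:
                raise ValueError("negative branch length")
        self._tip_labels = tuple(labels)

    def _compute_ages(self) -> None:
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                self._ages[node] = 0.0
            else:
                self._ages[node] = max(
                    self._ages[c] + c.edge.length for c in node.child_nodes()
                )

    def _check_ultrametric(self, *, strict: bool) -> None:
        depths = []
        self.tree.seed_node._depth = 0.0
        for node in self.tree.preorder_node_iter():
            if node is not self.tree.seed_node:
                node._depth = node.parent_node._depth + node.edge.length
            if node.is_leaf():
                depths.append(node._depth)
        lo, hi = min(depths), max(depths)
        spread = (hi - lo) / hi if hi > 0 else 0.0
        if spread > self.eps:
            msg = (
                f"tree is not ultrametric: root-to-tip path lengths span "
                f"[{lo:.6g}, {hi:.6g}] (relative spread {spread:.3g} > eps {self.eps:g})"
            )
            if strict:
                raise UltrametricityError(msg)
            warnings.warn(msg, stacklevel=3)

    # -- queries ----------------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in the order encountered in the input tree."""
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def age(self, node: dendropy.Node) -> float:
        """Age of ``node`` in my before present (tips are at age 0)."""
        return self._ages[node]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def root_age(self) -> float:
        return self._ages[self.tree.seed_node]

    def leaf(self, label: str) -> dendropy.Node:
        for node in self.tree.leaf_node_iter():
            if _leaf_label(node) == label:
                return node
        raise KeyError(f"unknown tip label: {label!r}")

    def mrca(self, tips: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of a set of tip labels.

        The deepest node whose descendant tip set contains all the given
        labels; for a single label, the tip itself.
        """
        tips = list(tips)
        if not tips:
            raise ValueError("mrca of an empty tip set is undefined")
        unknown = set(tips) - set(self._tip_labels)
        if unknown:
            raise KeyError(f"unknown tip label(s): {sorted(unknown)}")
        if len(tips) == 1:
            return self.leaf(tips[0])
        node = self.tree.mrca(taxon_labels=tips)
        if node is None:  # pragma: no cover - dendropy returns root otherwise
            raise ValueError("MRCA could not be resolved")
        return node

    def clade_tip_labels(self, node: dendropy.Node) -> tuple[str, ...]:
        """Labels of all tips descending from ``node`` (input tip order)."""
        members = {_leaf_label(leaf) for leaf in node.leaf_iter()}
        return tuple(lbl for lbl in self._tip_labels if lbl in members)

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self.tree.preorder_internal_node_iter()
        )

    def clade_sets(self) -> set[frozenset[str]]:
        """Set of tip-label sets of every internal node (topology signature)."""
        return {
            frozenset(_leaf_label(l) for l in n.leaf_iter())
            for n in self.tree.preorder_internal_node_iter()
        }

    # -- output -----------------------------------------------------------

    def newick(self) -> str:
        """Plain Newick string with full-precision branch lengths."""
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        ).strip() + "\n"


def _leaf_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def read_newick(text: str, *, eps: float = 1e-6, strict: bool = True) -> Chronogram:
    """Parse a single-tree Newick string into a validated :class:`Chronogram`.

    Labels after a closing parenthesis are treated as internal node names
    (not support values).  Branch lengths are required on every non-root
    edge and interpreted as millions of years.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return Chronogram(tree, eps=eps, strict=strict)


def mrca(chronogram: Chronogram, tips: Iterable[str]) -> dendropy.Node:
    """Module-level convenience wrapper for :meth:`Chronogram.mrca`."""
    return chronogram.mrca(tips)


@dataclass(frozen=True)
class RangeTable:
    """Tip label → set of occupied islands, over a fixed, ordered area list.

    The area order is part of the object's identity: all bitmask encodings
    downstream (DEC state indices) reference it.
    """

    areas: tuple[str, ...]
    ranges: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        for tip, rng in self.ranges.items():
            if not rng:
                raise ValueError(f"tip {tip!r} has an empty range")
            bad = rng - set(self.areas)
            if bad:
                raise ValueError(
                    f"tip {tip!r} occupies undeclared area(s): {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.ranges)

    def __getitem__(self, tip: str) -> frozenset[str]:
        return self.ranges[tip]

    def bitmask(self, tip: str) -> int:
        """Encode a tip's range as a bitmask under the declared area order."""
        rng = self.ranges[tip]
        return sum(1 << i for i, a in enumerate(self.areas) if a in rng)

    def check_tips(self, chronogram: Chronogram) -> None:
        """Require exactly one row per tree tip (pipeline join check)."""
        tree_tips = set(chronogram.tip_labels)
        missing = tree_tips - set(self.ranges)
        if missing:
            raise ValueError(f"tips without a range row: {sorted(missing)}")
        extra = set(self.ranges) - tree_tips
        if extra:
            raise ValueError(f"range rows for unknown tips: {sorted(extra)}")

    def to_csv(self) -> str:
        rows = []
        for tip, rng in self.ranges.items():
            rows.append(
                {"tip": tip, **{a: int(a in rng) for a in self.areas}}
            )
        return pd.DataFrame(rows).to_csv(index=False)


_NAME_SEPARATORS = "|;/"


def read_range_table(
    text: str,
    *,
    areas: tuple[str, ...] = HAWAIIAN_ISLANDS,
    dialect: str = "binary",
) -> RangeTable:
    """Parse a CSV/TSV range table.

    ``dialect='binary'``: header ``tip,<area1>,...,<areaK>`` with 0/1 cells.
    ``dialect='names'``: header ``tip,islands`` where the islands cell lists
    area names separated by ``|``, ``;`` or ``/``.
    """
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    tip_col = df.columns[0]
    ranges: dict[str, frozenset[str]] = {}
    if dialect == "binary":
        declared = tuple(df.columns[1:])
        unknown = set(declared) - set(areas)
        if unknown:
            raise ValueError(f"undeclared area column(s): {sorted(unknown)}")
        for _, row in df.iterrows():
            tip = str(row[tip_col]).strip()
            present = frozenset(a for a in declared if int(row[a]) != 0)
            if not present:
                raise ValueError(f"tip {tip!r} has an all-zero range")
            ranges[tip] = present
    elif dialect == "names":
        value_col = df.columns[1]
        for _, row in df.iterrows():
            tip = str(row[tip_col]).strip()
            cell = str(row[value_col])
            for ch in _NAME_SEPARATORS[1:]:
                cell = cell.replace(ch, _NAME_SEPARATORS[0])
            present = frozenset(
                part.strip() for part in cell.split(_NAME_SEPARATORS[0]) if part.strip()
            )
            if not present:
                raise ValueError(f"tip {tip!r} has an empty island list")
            ranges[tip] = present
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(ranges) != len(df):
        raise ValueError("duplicate tip rows in range table")
    return RangeTable(areas=tuple(areas), ranges=ranges)
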