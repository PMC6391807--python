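"""Group (pathway) membership, overlap expansion and coefficient collapse.

Predictors may belong to several groups (a gene can sit in more than one
pathway).  Following the overlap-group-lasso convention, each predictor is
replicated once per group it belongs to, so that on the *expanded* design
the groups are disjoint and every expanded coefficient has an unambiguous
group.  A fitted expanded coefficient vector is collapsed back to the
original predictors by summing replicates, which preserves the linear
predictor exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupStructure",
    "ExpandedDesign",
    "expand_overlap",
    "collapse_coefficients",
    "read_gmt",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupStructure:
    """Ordered, possibly overlapping predictor groups.

    Attributes
    ----------
    groups : tuple of ndarray
        For each of the G groups, the original predictor indices it
        contains (file/definition order preserved).
    names : tuple of str
        Group names, unique.
    n_predictors : int
        Number of original predictors covered (columns of the design).
    """

    groups: tuple
    names: tuple
    n_predictors: int

    def __post_init__(self) -> None:
        groups = tuple(np.asarray(g, dtype=np.intp) for g in self.groups)
        if len(groups) < 1:
            raise ValueError("at least one group is required")
        names = tuple(self.names) if self.names else tuple(f"group{i+1}" for i in range(len(groups)))
        if len(names) != len(groups):
            raise ValueError("names and groups must have equal length")
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        for name, g in zip(names, groups):
            if g.size == 0:
                raise ValueError(f"group {name!r} is empty")
            if g.min() < 0 or g.max() >= self.n_predictors:
                raise ValueError(f"group {name!r} has predictor index out of range")
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "names", names)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_sizes(self) -> np.ndarray:
        """J_g, the number of (expanded) predictors per group."""
        return np.array([g.size for g in self.groups], dtype=np.intp)

    def covered(self) -> np.ndarray:
        """Sorted unique original predictor indices in some group."""
        return np.unique(np.concatenate(self.groups))

    def with_catch_all(self, n_predictors: int | None = None) -> "GroupStructure":
        """Pool predictors not listed in any group into one extra group."""
        p = self.n_predictors if n_predictors is None else n_predictors
        rest = np.setdiff1d(np.arange(p), self.covered())
        if rest.size == 0:
            return self if p == self.n_predictors else GroupStructure(self.groups, self.names, p)
        return GroupStructure(
            self.groups + (rest,), self.names + ("_rest_",), p
        )

    @staticmethod
    def from_spec(spec, n_predictors: int) -> "GroupStructure":
        """Build from a list of index arrays or a ``{name: indices}`` dict."""
        if isinstance(spec, GroupStructure):
            return spec
        if isinstance(spec, dict):
            return GroupStructure(tuple(np.asarray(v) for v in spec.values()), tuple(spec.keys()), n_predictors)
        groups = tuple(np.asarray(g) for g in spec)
        return GroupStructure(groups, tuple(f"group{i+1}" for i in range(len(groups))), n_predictors)

    @staticmethod
    def single_group(n_predictors: int) -> "GroupStructure":
        return GroupStructure((np.arange(n_predictors),), ("all",), n_predictors)


@dataclass(frozen=True)
class ExpandedDesign:
    """Overlap-expanded design bookkeeping.

    ``orig_index[j]`` and ``group_index[j]`` give, for expanded column j,
    the original predictor and the group of the replicate.  J = sum_g J_g.
    """

    orig_index: np.ndarray
    group_index: np.ndarray
    n_predictors: int
    n_groups: int

    @property
    def n_expanded(self) -> int:
        return self.orig_index.shape[0]

    def expand_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_predictors:
            raise ValueError("X has wrong number of columns for this expansion")
        return X[:, self.orig_index]


def expand_overlap(X, gs: GroupStructure):
    """Replicate each predictor once per group it belongs to.

    Returns ``(Xe, ed)`` where ``Xe`` is the n x J expanded matrix and
    ``ed`` the :class:`ExpandedDesign` back-map.  For non-overlapping
    structures ``Xe`` is a column permutation (selection) of ``X``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    if gs.n_predictors != X.shape[1]:
        raise ValueError("group structure does not match the number of columns of X")
    orig = np.concatenate(gs.groups)
    grp = np.concatenate([np.full(g.size, k, dtype=np.intp) for k, g in enumerate(gs.groups)])
    ed = ExpandedDesign(orig, grp, X.shape[1], gs.n_groups)
    return X[:, orig], ed


def collapse_coefficients(expanded_beta, ed: ExpandedDesign) -> np.ndarray:
    """Sum replicate coefficients back onto the original predictors.

    Summation preserves the fitted linear predictor:
    ``X @ collapse(beta_e) == Xe @ beta_e`` exactly.
    """
    b = np.asarray(expanded_beta, dtype=float)
    if b.shape[0] != ed.n_expanded:
        raise ValueError("expanded coefficient length does not match the back-map")
    out = np.zeros(ed.n_predictors)
    np.add.at(out, ed.orig_index, b)
    return out


def read_gmt(path, predictor_names=None) -> GroupStructure:
    """Read GMT gene-set lines: ``name<TAB>description<TAB>member...``.

    Members are resolved against ``predictor_names`` (the header of the
    predictor matrix); unmatched members are dropped with a log message, and
    a group with no matched member is dropped with a warning.
    """
    names, groups = [], []
    raw = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, members): {line[:60]!r}")
            raw.append((parts[0], parts[2:]))
    if not raw:
        raise ValueError(f"GMT file {path!s} contains no groups")
    seen = set()
    for name, _ in raw:
        if name in seen:
            raise ValueError(f"duplicate group name in GMT: {name!r}")
        seen.add(name)
    if predictor_names is None:
        # resolve against the union of all members, in first-appearance order
        order = {}
        for _, members in raw:
            for m in members:
                order.setdefault(m, len(order))
        predictor_names = list(order)
    lookup = {str(n): i for i, n in enumerate(predictor_names)}
    for name, members in raw:
        idx, missing = [], []
        for m in members:
            if m in lookup:
                idx.append(lookup[m])
            else:
                missing.append(m)
        if missing:
            logger.info("GMT group %s: %d member(s) not in predictor matrix: %s",
                        name, len(missing), ", ".join(missing[:5]))
        if not idx:
            logger.warning("GMT group %s has no matched members; dropped", name)
            continue
        names.append(name)
        groups.append(np.asarray(idx, dtype=np.intp))
    if not groups:
        raise ValueError("no GMT group had any member matching the predictor matrix")
    return GroupStructure(tuple(groups), tuple(names), len(predictor_names))
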