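"""Phylogenetic trees, Brownian-motion covariance, Pagel's lambda, and
continuous-trait utilities.

The central object is :class:`Phylogeny`, a thin validated wrapper around a
rooted :class:`dendropy.Tree`.  All covariance conventions follow the standard
Brownian-motion (BM) model: the covariance between two tips is the shared
root-to-MRCA path length, and the variance of a tip is its root-to-tip depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "CovarianceMatrix",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "bm_covariance",
    "lambda_transform",
    "simulate_bm",
    "reconstruct_ancestral",
    "normalize_label",
]

#: relative tolerance on root-to-tip depth spread before warning about
#: non-ultrametric input
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


def normalize_label(label: str) -> str:
    """Canonical form used to match species labels across data sources.

    Case is folded and spaces become underscores, so ``"Mus musculus"`` and
    ``"mus_musculus"`` compare equal.
    """
    return label.strip().replace(" ", "_").casefold()


class Phylogeny:
    """A rooted phylogenetic tree with branch lengths in time units.

    Parameters
    ----------
    tree:
        A dendropy tree.  Every non-root edge must carry a finite,
        non-negative length.  Tip labels must be unique.  Multifurcations are
        accepted.  Ultrametricity is checked and a warning (not an error) is
        emitted when root-to-tip depths differ by more than
        ``ULTRAMETRIC_RTOL`` relative to the maximum depth.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._index_nodes()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeValidationError("tree contains an unlabeled tip")
            label = leaf.taxon.label.replace(" ", "_")
            leaf.taxon.label = label
            if label in seen:
                raise TreeValidationError(f"duplicate tip label: {label!r}")
            seen.add(label)
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            length = node.edge.length
            if length is None or not np.isfinite(length):
                raise TreeValidationError(
                    "non-root edge without a finite branch length "
                    f"(above node {_node_name(node)!r})"
                )
            if length < 0:
                raise TreeValidationError(
                    f"negative branch length {length} above node "
                    f"{_node_name(node)!r}"
                )

    def _index_nodes(self) -> None:
        self._depth: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                self._depth[node] = 0.0
            else:
                self._depth[node] = self._depth[parent] + node.edge.length
        self.tips: list[str] = [
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        ]
        self._tip_index = {label: i for i, label in enumerate(self.tips)}
        depths = np.array(
            [self._depth[leaf] for leaf in self._tree.leaf_node_iter()]
        )
        self.max_depth = float(depths.max()) if len(depths) else 0.0
        if self.max_depth > 0:
            spread = (depths.max() - depths.min()) / self.max_depth
            if spread > ULTRAMETRIC_RTOL:
                warnings.warn(
                    "tree is not ultrametric: root-to-tip depths vary by "
                    f"{spread:.3g} (relative); downstream covariances use the "
                    "actual depths",
                    UserWarning,
                    stacklevel=3,
                )

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.tips)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def tip_depths(self) -> dict[str, float]:
        return {
            leaf.taxon.label: self._depth[leaf]
            for leaf in self._tree.leaf_node_iter()
        }

    def to_newick(self) -> str:
        return write_newick(self)

    def match_tips(self, labels: Iterable[str]) -> dict[str, str]:
        """Map external labels onto tip labels after normalization.

        Returns a dict ``external -> tip``; labels with no match are omitted.
        """
        lookup = {normalize_label(t): t for t in self.tips}
        out = {}
        for lab in labels:
            hit = lookup.get(normalize_label(lab))
            if hit is not None:
                out[lab] = hit
        return out


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return "<internal>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into a validated :class:`Phylogeny`.

    Raises :class:`NewickParseError` with position information for malformed
    input and :class:`TreeValidationError` for duplicate tip labels or
    missing branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip label: {exc}") from exc
        col = getattr(exc, "col_num", None)
        line = getattr(exc, "line_num", None)
        where = ""
        if line is not None and col is not None:
            where = f" at line {line}, column {col}"
        raise NewickParseError(f"malformed newick{where}: {exc}") from exc
    return Phylogeny(tree)


def write_newick(tree: Phylogeny) -> str:
    """Serialize with full float precision so write->parse round-trips."""
    text = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )
    return text.strip()


# ---------------------------------------------------------------------------
# covariance machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovarianceMatrix:
    """A labeled symmetric PSD matrix of shared evolutionary path lengths."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.allclose(values, values.T, atol=1e-10 * max(1.0, np.trace(values))):
            raise ValueError("covariance matrix is not symmetric")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, labels: Iterable[str]) -> "CovarianceMatrix":
        """Restrict to a subset of labels (BM covariance is closed under
        taking submatrices)."""
        labels = list(labels)
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            idx = [index[lab] for lab in labels]
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} not in covariance matrix")
        return CovarianceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.values))
        if np.any(d <= 0):
            raise ValueError("zero variance on the diagonal")
        return self.values / np.outer(d, d)


def bm_covariance(tree: Phylogeny) -> CovarianceMatrix:
    """Brownian-motion tip covariance: entry (i, j) is the root-to-MRCA path
    length of tips i and j; the diagonal holds root-to-tip depths.

    Computed in a single postorder sweep: every tip pair receives its value
    exactly once, at its MRCA.
    """
    n = len(tree)
    V = np.zeros((n, n))
    tip_index = tree._tip_index
    below: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            i = tip_index[node.taxon.label]
            V[i, i] = tree._depth[node]
            below[node] = np.array([i])
            continue
        child_sets = [below.pop(c) for c in node.child_nodes()]
        d = tree._depth[node]
        for a, b in combinations(child_sets, 2):
            V[np.ix_(a, b)] = d
            V[np.ix_(b, a)] = d
        below[node] = np.concatenate(child_sets)
    return CovarianceMatrix(tuple(tree.tips), V)


def lambda_transform(V: CovarianceMatrix, lam: float) -> CovarianceMatrix:
    """Pagel's lambda: scale off-diagonal covariances by ``lam`` in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = lam * V.values
    np.fill_diagonal(out, np.diag(V.values))
    return CovarianceMatrix(V.labels, out)


def simulate_bm(
    tree: Phylogeny,
    sigma2: float,
    root_value: float,
    seed: int,
) -> dict[str, float]:
    """Draw one Brownian-motion trait on the tree.

    Tip values are multivariate normal with mean ``root_value`` and
    covariance ``sigma2 * bm_covariance(tree)``.  Deterministic given
    ``seed``.
    """
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    rng = np.random.default_rng(seed)
    V = bm_covariance(tree)
    draw = sample_mvn_bm(V.values, sigma2, root_value, rng, 1)[0]
    return dict(zip(V.labels, draw))


def sample_mvn_bm(
    V: np.ndarray,
    sigma2: float,
    root_value: float,
    rng: np.random.Generator,
    n_reps: int,
) -> np.ndarray:
    """Vectorized BM draws: ``n_reps`` rows of tip values for covariance
    ``sigma2 * V``.  Separated out so simulation nulls can reuse one
    factorization."""
    n = V.shape[0]
    if sigma2 == 0:
        return np.full((n_reps, n), float(root_value))
    L = _chol_with_jitter(sigma2 * V)
    z = rng.standard_normal((n_reps, n))
    return root_value + z @ L.T

def _chol_with_jitter(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(C)
        return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))


# ---------------------------------------------------------------------------
# ancestral reconstruction
# ---------------------------------------------------------------------------


def reconstruct_ancestral(
    tree: Phylogeny, tip_values: Mapping[str, float]
) -> dict[str, float]:
    """Maximum-likelihood (GLS) ancestral estimates of a continuous trait.

    Under Brownian motion the ML estimate at an internal node is the
    conditional expectation given the tips::

        mu_hat = (1' V^-1 1)^-1 1' V^-1 y          (GLS root/mean estimate)
        a_hat  = mu_hat + C_nt V^-1 (y - mu_hat)

    where ``V`` is the tip covariance and ``C_nt`` the node-tip covariance
    (shared root-to-MRCA path lengths).  Internal nodes are keyed by their
    label when present, otherwise ``"root"`` / ``"n<k>"`` in preorder.
    """
    missing = [t for t in tree.tips if t not in tip_values]
    if missing:
        raise ValueError(f"missing tip values for: {missing}")
    V = bm_covariance(tree)
    y = np.array([float(tip_values[t]) for t in V.labels])

    dtree = tree.dendropy_tree
    internal = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    names = []
    for k, nd in enumerate(internal):
        if nd.label:
            names.append(nd.label)
        elif nd.parent_node is None:
            names.append("root")
        else:
            names.append(f"n{k}")

    # tips below each node, for node-tip covariance
    below: dict[dendropy.Node, set[str]] = {}
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = {nd.taxon.label}
        else:
            below[nd] = set().union(*(below[c] for c in nd.child_nodes()))

    tip_index = {lab: i for i, lab in enumerate(V.labels)}
    C_nt = np.zeros((len(internal), len(V)))
    for k, nd in enumerate(internal):
        # walk rootward: the MRCA of nd and a tip outside its subtree is the
        # first ancestor whose subtree contains that tip
        anc = nd
        while anc is not None:
            for lab in below[anc]:
                j = tip_index[lab]
                if C_nt[k, j] == 0.0:
                    C_nt[k, j] = tree._depth[anc]
            if below[anc] >= set(V.labels):
                break
            anc = anc.parent_node

    Vinv_y, Vinv_1 = np.linalg.solve(
        V.values, np.column_stack([y, np.ones(len(y))])
    ).T
    mu_hat = (np.ones(len(y)) @ Vinv_y) / (np.ones(len(y)) @ Vinv_1)
    resid_w = np.linalg.solve(V.values, y - mu_hat)
    estimates = mu_hat + C_nt @ resid_w
    return dict(zip(names, estimates))
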