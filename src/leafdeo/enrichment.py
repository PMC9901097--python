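"""GO term enrichment (classic Fisher and elim) and PCA with loading sets.

The GO graph is a DAG of terms (child -> parent, multiple parents allowed)
with the true-path rule applied on load: a feature annotated to a term is
implicitly annotated to all of its ancestors.  Classic enrichment is the
one-sided hypergeometric upper tail of the study/term overlap within the
universe.  The ``elim`` variant decorrelates the DAG bottom-up: when a
term is significant at ``alpha``, its annotated features are removed from
all of its ancestors before those are tested, so parents are not dragged
to significance by a strong child.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import InputError


class GODag:
    """GO DAG with direct annotations and true-path closure."""

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        annotations: Mapping[str, Iterable[str]] | None = None,
    ):
        """``edges`` are (child, parent) pairs; ``annotations`` maps a
        feature to the terms it is directly annotated with."""
        self.graph = nx.DiGraph()  # edge child -> parent
        for child, parent in edges:
            self.graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise InputError("GO edge table contains a cycle")
        self.direct: dict[str, set[str]] = {t: set() for t in self.graph.nodes}
        if annotations:
            self.annotate(annotations)

    def annotate(self, annotations: Mapping[str, Iterable[str]]) -> None:
        for feature, terms in annotations.items():
            for term in terms:
                if term not in self.graph:
                    self.graph.add_node(term)
                self.direct.setdefault(term, set()).add(feature)
        self._closure = None

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)  # edges point child -> parent

    def term_genes(self) -> dict[str, set[str]]:
        """Closed annotation: features of a term and all its descendants."""
        if getattr(self, "_closure", None) is None:
            closure: dict[str, set[str]] = {}
            for term in nx.topological_sort(self.graph):  # children before parents
                genes = set(self.direct.get(term, ()))
                for child in self.graph.predecessors(term):
                    genes |= closure[child]
                closure[term] = genes
            self._closure = closure
        return self._closure

    def levels(self) -> dict[str, int]:
        """Longest-path depth from the leaves (leaf = 0), the elim order."""
        lev: dict[str, int] = {}
        for term in nx.topological_sort(self.graph):
            children = list(self.graph.predecessors(term))
            lev[term] = 0 if not children else 1 + max(lev[c] for c in children)
        return lev


def _check_sets(study_set: set, universe_set: set) -> None:
    if not study_set or not universe_set:
        raise InputError("study and universe sets must be non-empty")
    if not study_set <= universe_set:
        raise InputError("study set must be a subset of the universe")


def fisher_go(dag: GODag, study_set: Iterable, universe_set: Iterable) -> pd.Series:
    """Classic one-sided hypergeometric upper-tail p per term."""
    study = set(study_set)
    universe = set(universe_set)
    _check_sets(study, universe)
    closure = dag.term_genes()
    m = len(universe)
    n = len(study)
    out = {}
    for term in dag.terms:
        genes = closure.get(term, set()) & universe
        if not genes:
            continue
        k = len(genes & study)
        out[term] = float(hypergeom.sf(k - 1, m, len(genes), n))
    return pd.Series(out).sort_index()


def elim_go(
    dag: GODag,
    study_set: Iterable,
    universe_set: Iterable,
    alpha: float = 0.01,
) -> pd.Series:
    """elim-adjusted enrichment p per term.

    Terms are processed bottom-up by longest-path depth from the leaves;
    when a term's p falls below ``alpha`` its (closed) annotated features
    are eliminated from all of its ancestors before those are tested.
    Totals (universe and study size) stay global, as in the published
    algorithm.
    """
    study = set(study_set)
    universe = set(universe_set)
    _check_sets(study, universe)
    closure = dag.term_genes()
    levels = dag.levels()
    m = len(universe)
    n = len(study)
    eliminated: dict[str, set] = {t: set() for t in dag.terms}
    out = {}
    for term in sorted(dag.terms, key=lambda t: (levels[t], t)):
        genes = (closure.get(term, set()) & universe) - eliminated[term]
        if not genes:
            continue
        k = len(genes & study)
        p = float(hypergeom.sf(k - 1, m, len(genes), n))
        out[term] = p
        if p < alpha:
            for anc in dag.ancestors(term):
                eliminated[anc] |= genes
    return pd.Series(out).sort_index()


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # feature x component
    scores: pd.DataFrame  # sample x component
    variance_explained: np.ndarray  # fraction per component


def pca_loadings(expr: pd.DataFrame, n_components: int) -> PCAResult:
    """SVD-based PCA of samples on a feature x sample matrix.

    Features (rows) are centered internally; variance fractions come from
    the squared singular values.  The sign of each component is fixed so
    its largest-magnitude loading is positive.
    """
    if expr.shape[1] < 2:
        raise InputError("PCA needs at least 2 samples")
    if n_components > min(expr.shape):
        raise InputError(
            f"n_components={n_components} exceeds min(matrix dims)={min(expr.shape)}"
        )
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / max((s**2).sum(), np.finfo(float).tiny)
    loadings = u[:, :n_components]
    scores = (vt[:n_components].T * s[:n_components])
    for j in range(n_components):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        pd.DataFrame(loadings, index=expr.index, columns=comps),
        pd.DataFrame(scores, index=expr.columns, columns=comps),
        var[:n_components],
    )


def top_loading_sets(
    loadings: pd.Series, fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """Features with the top and bottom ``fraction`` of loadings.

    Boundary ties are included on each side; disjointness is enforced by
    rank when the quantile rule would make the sets overlap (degenerate
    near-constant loadings).  Each set has at least one feature.
    """
    if not 0 < fraction < 0.5:
        raise InputError("fraction must be in (0, 0.5)")
    n = len(loadings)
    if n < 1 / fraction:
        warnings.warn(
            f"only {n} features for fraction={fraction}; sets of size >= 1 guaranteed",
            stacklevel=2,
        )
    vals = loadings.to_numpy(dtype=float)
    q_lo = np.quantile(vals, fraction)
    q_hi = np.quantile(vals, 1 - fraction)
    bottom = list(loadings.index[vals <= q_lo])
    top = list(loadings.index[vals >= q_hi])
    if set(top) & set(bottom):
        order = sorted(loadings.index, key=lambda f: (loadings[f], f))
        size = max(1, int(np.ceil(n * fraction)))
        bottom = order[:size]
        top = [f for f in order[::-1][:size] if f not in bottom]
        if not top:  # fewer than 2 features
            top = order[-1:]
            bottom = [f for f in bottom if f not in top]
    return sorted(top), sorted(bottom)
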