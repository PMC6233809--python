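"""Multisubject effective connectivity: score-based search plus non-gaussian
orientation.

The search follows the independent-multisample design: every subject
contributes a trials x ROIs sample matrix, each candidate structure is scored
with a decomposable gaussian BIC summed over subjects, and greedy equivalence
search (GES) moves through Markov equivalence classes with Insert/Delete
operators until no move improves the pooled score. The resulting CPDAG's
undirected edges are then oriented on the fixed skeleton by a pairwise
likelihood-ratio rule that exploits non-gaussianity of the linear-model
innovations (LiNGAM-family orientation). Per-subject edge coefficients are
ordinary least squares of each child on its parents.

For networks of up to a few nodes, :func:`exhaustive_search` enumerates every
DAG and returns the CPDAG of the best-scoring equivalence class; it serves as
an exact oracle for the greedy search.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROISampleSet", "CPDAGGraph", "bic_score", "images_search",
    "exhaustive_search", "orient_fixed_structure", "estimate_edge_coefficients",
]


# ---------------------------------------------------------------------------
# data container

@dataclass
class ROISampleSet:
    """Per-subject trial-sample matrices over a shared ROI set."""

    matrices: list[np.ndarray]          # each trials x ROIs
    roi_labels: list[str]
    groups: list[str] | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        p = len(self.roi_labels)
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        for i, m in enumerate(self.matrices):
            if m.ndim != 2 or m.shape[1] != p:
                raise ValueError(f"subject {i}: expected trials x {p} matrix")
            if m.shape[0] < p + 2:
                raise ValueError(
                    f"subject {i}: needs at least ROIs + 2 = {p + 2} trials")
        if self.groups is not None and len(self.groups) != len(self.matrices):
            raise ValueError("groups length must match number of subjects")
        if self.subject_ids is None:
            self.subject_ids = [f"s{i:03d}" for i in range(len(self.matrices))]

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @classmethod
    def from_records(cls, records, rois: list[str] | None = None) -> "ROISampleSet":
        """Build from simulated SubjectRecord objects' trial samples."""
        first = records[0].trial_samples
        labels = list(rois) if rois is not None else list(first.columns)
        return cls(
            matrices=[r.trial_samples[labels].to_numpy() for r in records],
            roi_labels=labels,
            groups=[r.group for r in records],
            subject_ids=[r.subject_id for r in records],
        )

    def subset(self, mask) -> "ROISampleSet":
        idx = [i for i, m in enumerate(mask) if m]
        return ROISampleSet(
            matrices=[self.matrices[i] for i in idx],
            roi_labels=list(self.roi_labels),
            groups=None if self.groups is None else [self.groups[i] for i in idx],
            subject_ids=[self.subject_ids[i] for i in idx],
        )


@dataclass
class CPDAGGraph:
    """Partially directed graph over ROI labels with a pooled score."""

    nodes: list[str]
    directed_edges: set = field(default_factory=set)    # (parent, child)
    undirected_edges: set = field(default_factory=set)  # frozenset({a, b})
    score: float = float("nan")
    ambiguous_edges: set = field(default_factory=set)   # flagged by orientation

    def __post_init__(self) -> None:
        for (a, b) in self.directed_edges:
            if frozenset((a, b)) in self.undirected_edges:
                raise ValueError(f"edge {a}-{b} both directed and undirected")
        if self._has_directed_cycle():
            raise ValueError("directed edges contain a cycle")

    def _has_directed_cycle(self) -> bool:
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for a, b in self.directed_edges:
            children[a].append(b)
        state = {n: 0 for n in self.nodes}

        def dfs(u: str) -> bool:
            state[u] = 1
            for v in children[u]:
                if state[v] == 1 or (state[v] == 0 and dfs(v)):
                    return True
            state[u] = 2
            return False

        return any(state[n] == 0 and dfs(n) for n in self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)

    def has_edge(self, a: str, b: str) -> bool:
        return ((a, b) in self.directed_edges or (b, a) in self.directed_edges
                or frozenset((a, b)) in self.undirected_edges)

    def edge_orientation(self, a: str, b: str) -> str | None:
        """'a->b', 'b->a', 'undirected', or None if absent."""
        if (a, b) in self.directed_edges:
            return f"{a}->{b}"
        if (b, a) in self.directed_edges:
            return f"{b}->{a}"
        if frozenset((a, b)) in self.undirected_edges:
            return "undirected"
        return None

    def to_edge_table(self) -> pd.DataFrame:
        rows = [{"parent": a, "child": b, "orientation_state": "directed"}
                for a, b in sorted(self.directed_edges)]
        rows += [{"parent": a, "child": b, "orientation_state": "undirected"}
                 for a, b in sorted(tuple(sorted(e)) for e in self.undirected_edges)]
        return pd.DataFrame(rows, columns=["parent", "child", "orientation_state"])

    def to_dot(self) -> str:
        lines = ["digraph connectivity {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for a, b in sorted(self.directed_edges):
            lines.append(f'  "{a}" -> "{b}";')
        for e in sorted(tuple(sorted(e)) for e in self.undirected_edges):
            lines.append(f'  "{e[0]}" -> "{e[1]}" [dir=none];')
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# pooled gaussian BIC score

class _Scorer:
    """Decomposable pooled gaussian-BIC local score with caching.

    Per subject i and node y with parent set P the local score is
    2 * loglik(y | P) - penalty * (|P| + 1) * log(n_i), where the gaussian
    log-likelihood is profiled at the OLS residual variance; the pooled score
    sums over subjects. Higher is better; the score is score-equivalent, so
    Markov-equivalent DAGs tie exactly.
    """

    def __init__(self, samples: ROISampleSet, penalty_discount: float = 1.0):
        self.penalty = float(penalty_discount)
        self.p = samples.n_rois
        self.ns = [m.shape[0] for m in samples.matrices]
        self.covs = []
        for m in samples.matrices:
            c = m - m.mean(axis=0)
            self.covs.append((c.T @ c) / m.shape[0])
        self._cache: dict[tuple[int, frozenset], float] = {}

    def local(self, y: int, parents: frozenset) -> float:
        key = (y, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        P = sorted(parents)
        total = 0.0
        for S, n in zip(self.covs, self.ns):
            if P:
                Spp = S[np.ix_(P, P)]
                Spy = S[P, y]
                try:
                    coef = np.linalg.solve(Spp, Spy)
                except np.linalg.LinAlgError:
                    warnings.warn("singular parent covariance; score -inf",
                                  stacklevel=2)
                    total = -np.inf
                    break
                sigma2 = S[y, y] - Spy @ coef
            else:
                sigma2 = S[y, y]
            if sigma2 <= 1e-12:
                warnings.warn("degenerate residual variance; score -inf",
                              stacklevel=2)
                total = -np.inf
                break
            ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
            total += 2.0 * ll - self.penalty * (len(P) + 1) * np.log(n)
        self._cache[key] = total
        return total

    def dag_score(self, parents_of: list[frozenset]) -> float:
        return sum(self.local(y, parents_of[y]) for y in range(self.p))


def bic_score(samples: ROISampleSet, dag: "CPDAGGraph | dict",
              penalty_discount: float = 1.0) -> float:
    """Pooled gaussian-BIC score of a fully directed acyclic graph.

    ``dag`` may be a fully directed :class:`CPDAGGraph` or a mapping
    node label -> iterable of parent labels. Decomposes as a sum of
    per-node local scores; higher is better.
    """
    scorer = _Scorer(samples, penalty_discount)
    idx = {lbl: j for j, lbl in enumerate(samples.roi_labels)}
    parents_of = [frozenset() for _ in samples.roi_labels]
    if isinstance(dag, CPDAGGraph):
        if dag.undirected_edges:
            raise ValueError("bic_score requires a fully directed graph")
        for a, b in dag.directed_edges:
            parents_of[idx[b]] = parents_of[idx[b]] | {idx[a]}
    else:
        for child, pars in dag.items():
            parents_of[idx[child]] = frozenset(idx[p] for p in pars)
    return scorer.dag_score(parents_of)


# ---------------------------------------------------------------------------
# PDAG machinery (integer-indexed)

class _PDAG:
    """Mutable partially directed graph on nodes 0..p-1."""

    def __init__(self, p: int):
        self.p = p
        self.par: list[set] = [set() for _ in range(p)]   # x in par[y]: x -> y
        self.und: list[set] = [set() for _ in range(p)]   # symmetric

    def copy(self) -> "_PDAG":
        g = _PDAG(self.p)
        g.par = [set(s) for s in self.par]
        g.und = [set(s) for s in self.und]
        return g

    def adjacent(self, x: int, y: int) -> bool:
        return y in self.und[x] or x in self.par[y] or y in self.par[x]

    def neighbors(self, y: int) -> set:
        return set(self.und[y])

    def adj(self, y: int) -> set:
        out = set(self.und[y]) | set(self.par[y])
        out |= {v for v in range(self.p) if y in self.par[v]}
        return out

    def na(self, y: int, x: int) -> set:
        """Undirected neighbors of y that are adjacent to x."""
        return {w for w in self.und[y] if self.adjacent(w, x)}

    def is_clique(self, nodes: set) -> bool:
        return all(self.adjacent(a, b) for a, b in itertools.combinations(nodes, 2))

    def exists_semi_directed_path(self, frm: int, to: int, avoid: set) -> bool:
        """Path from ``frm`` to ``to`` along undirected or forward edges,
        visiting no node in ``avoid``."""
        seen = {frm}
        stack = [frm]
        while stack:
            u = stack.pop()
            nxt = set(self.und[u]) | {v for v in range(self.p) if u in self.par[v]}
            for v in nxt:
                if v == to:
                    return True
                if v not in seen and v not in avoid:
                    seen.add(v)
                    stack.append(v)
        return False


def _pdag_to_dag(g: _PDAG) -> _PDAG:
    """Consistent DAG extension (Dor & Tarsi). Raises if none exists."""
    work = g.copy()
    dag = g.copy()
    remaining = set(range(g.p))
    while remaining:
        found = None
        for x in remaining:
            out_directed = any(x in work.par[v] for v in remaining if v != x)
            if out_directed:
                continue
            nbrs = work.und[x] & remaining
            adj_x = (work.adj(x) & remaining) - {x}
            ok = all(
                all(work.adjacent(w, v) for v in adj_x if v != w)
                for w in nbrs)
            if ok:
                found = x
                break
        if found is None:
            raise ValueError("PDAG admits no consistent DAG extension")
        for w in work.und[found] & remaining:
            dag.par[found].add(w)          # orient w -> found
            dag.und[found].discard(w)
            dag.und[w].discard(found)
        remaining.discard(found)
        for v in range(g.p):
            work.par[v].discard(found)
            work.und[v].discard(found)
    return dag


def _dag_to_cpdag(dag: _PDAG) -> _PDAG:
    """CPDAG of a DAG: keep v-structure arrows, close under Meek rules 1-3."""
    p = dag.p
    g = _PDAG(p)
    # start fully undirected on the skeleton
    for y in range(p):
        for x in dag.par[y]:
            g.und[x].add(y)
            g.und[y].add(x)
    # orient v-structure arrows
    for y in range(p):
        for a, b in itertools.combinations(sorted(dag.par[y]), 2):
            if not dag.adjacent(a, b):
                for parent in (a, b):
                    g.par[y].add(parent)
                    g.und[y].discard(parent)
                    g.und[parent].discard(y)
    # Meek closure (rules 1-3 suffice without background knowledge)
    changed = True
    while changed:
        changed = False
        for b in range(p):
            for c in list(g.und[b]):
                # R1: a -> b, b - c, a and c non-adjacent  =>  b -> c
                if any(not g.adjacent(a, c) for a in g.par[b]):
                    g.par[c].add(b)
                    g.und[b].discard(c)
                    g.und[c].discard(b)
                    changed = True
                    continue
                # R2: b -> k -> c with b - c  =>  b -> c
                if any(b in g.par[k] and k in g.par[c] for k in range(p)):
                    g.par[c].add(b)
                    g.und[b].discard(c)
                    g.und[c].discard(b)
                    changed = True
                    continue
                # R3: b - a1, b - a2, a1 -> c, a2 -> c, a1/a2 non-adjacent
                ins = [a for a in g.par[c] if a in g.und[b]]
                if any(not g.adjacent(a1, a2)
                       for a1, a2 in itertools.combinations(ins, 2)):
                    g.par[c].add(b)
                    g.und[b].discard(c)
                    g.und[c].discard(b)
                    changed = True
    return g


def _cpdag_from_pdag(g: _PDAG) -> _PDAG:
    return _dag_to_cpdag(_pdag_to_dag(g))


def _pdag_to_graph(g: _PDAG, labels: list[str], score: float) -> CPDAGGraph:
    directed = {(labels[x], labels[y]) for y in range(g.p) for x in g.par[y]}
    und = {frozenset((labels[a], labels[b]))
           for a in range(g.p) for b in g.und[a] if a < b}
    return CPDAGGraph(nodes=list(labels), directed_edges=directed,
                      undirected_edges=und, score=score)


def _graph_to_pdag(graph: CPDAGGraph, labels: list[str]) -> _PDAG:
    idx = {lbl: j for j, lbl in enumerate(labels)}
    g = _PDAG(len(labels))
    for a, b in graph.directed_edges:
        g.par[idx[b]].add(idx[a])
    for e in graph.undirected_edges:
        a, b = tuple(e)
        g.und[idx[a]].add(idx[b])
        g.und[idx[b]].add(idx[a])
    return g


# ---------------------------------------------------------------------------
# GES (greedy equivalence search) with pooled score

def _dag_parent_sets(g: _PDAG) -> list[frozenset]:
    return [frozenset(g.par[y]) for y in range(g.p)]


def _forward_step(g: _PDAG, scorer: _Scorer):
    """Best valid Insert(x, y, T); returns (delta, apply) or None."""
    best = None
    p = g.p
    for x in range(p):
        for y in range(p):
            if x == y or g.adjacent(x, y):
                continue
            na_yx = g.na(y, x)
            t0 = [w for w in g.neighbors(y) if not g.adjacent(w, x)]
            pa_y = frozenset(g.par[y])
            for r in range(len(t0) + 1):
                for T in itertools.combinations(t0, r):
                    Tset = set(T)
                    cond = na_yx | Tset
                    if not g.is_clique(cond):
                        continue
                    if g.exists_semi_directed_path(y, x, avoid=cond):
                        continue
                    base = pa_y | cond
                    delta = (scorer.local(y, frozenset(base | {x}))
                             - scorer.local(y, frozenset(base)))
                    if best is None or delta > best[0] + 1e-12:
                        best = (delta, x, y, Tset)
    if best is None or best[0] <= 1e-9:
        return None
    delta, x, y, Tset = best

    def apply(gg: _PDAG) -> _PDAG:
        gg = gg.copy()
        gg.par[y].add(x)
        for t in Tset:
            gg.und[y].discard(t)
            gg.und[t].discard(y)
            gg.par[y].add(t)
        return _cpdag_from_pdag(gg)

    return delta, apply


def _backward_step(g: _PDAG, scorer: _Scorer):
    """Best valid Delete(x, y, H); returns (delta, apply) or None."""
    best = None
    p = g.p
    pairs = [(x, y) for y in range(p) for x in g.par[y]]
    pairs += [(a, b) for a in range(p) for b in g.und[a]]
    for x, y in pairs:
        na_yx = g.na(y, x)
        pa_y = frozenset(g.par[y])
        for r in range(len(na_yx) + 1):
            for H in itertools.combinations(sorted(na_yx), r):
                Hset = set(H)
                if not g.is_clique(na_yx - Hset):
                    continue
                keep = (na_yx - Hset)
                base = (pa_y | keep) - {x}
                delta = (scorer.local(y, frozenset(base))
                         - scorer.local(y, frozenset(base | {x})))
                if best is None or delta > best[0] + 1e-12:
                    best = (delta, x, y, Hset)
    if best is None or best[0] <= 1e-9:
        return None
    delta, x, y, Hset = best

    def apply(gg: _PDAG) -> _PDAG:
        gg = gg.copy()
        gg.par[y].discard(x)
        gg.und[x].discard(y)
        gg.und[y].discard(x)
        for h in Hset:
            # orient y - h as y -> h; and x - h as x -> h when undirected
            if h in gg.und[y]:
                gg.und[y].discard(h)
                gg.und[h].discard(y)
                gg.par[h].add(y)
            if h in gg.und[x]:
                gg.und[x].discard(h)
                gg.und[h].discard(x)
                gg.par[h].add(x)
        return _cpdag_from_pdag(gg)

    return delta, apply


def _turning_step(g: _PDAG, scorer: _Scorer):
    """Best score-improving single-edge reversal (turning move).

    Works on a consistent DAG extension of the current class: any edge whose
    reversal keeps the DAG acyclic proposes the equivalence class of the
    reversed DAG; the score change involves only the two endpoint nodes.
    Escapes local optima where an edge must flip (e.g. to form a collider)
    before an insertion or deletion can pay off.
    """
    D = _pdag_to_dag(g)
    p = g.p
    children: dict[int, set] = {u: set() for u in range(p)}
    for y in range(p):
        for x in D.par[y]:
            children[x].add(y)

    def creates_cycle(x: int, y: int) -> bool:
        # after reversing x -> y to y -> x: cycle iff a path x ~> y survives
        seen, stack = {x}, [x]
        while stack:
            u = stack.pop()
            for v in children[u]:
                if u == x and v == y:
                    continue
                if v == y:
                    return True
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    best = None
    for y in range(p):
        for x in list(D.par[y]):
            if creates_cycle(x, y):
                continue
            pa_x, pa_y = frozenset(D.par[x]), frozenset(D.par[y])
            delta = (scorer.local(x, pa_x | {y})
                     + scorer.local(y, pa_y - {x})
                     - scorer.local(x, pa_x)
                     - scorer.local(y, pa_y))
            if best is None or delta > best[0] + 1e-12:
                best = (delta, x, y)
    if best is None or best[0] <= 1e-9:
        return None
    delta, x, y = best

    def apply(gg: _PDAG) -> _PDAG:
        DD = _pdag_to_dag(gg)
        DD.par[y].discard(x)
        DD.par[x].add(y)
        return _dag_to_cpdag(DD)

    return delta, apply


def _skeleton_edges(g: _PDAG) -> list[tuple[int, int]]:
    p = g.p
    return sorted({tuple(sorted((x, y))) for y in range(p) for x in g.par[y]}
                  | {tuple(sorted((a, b))) for a in range(p) for b in g.und[a]})


def _best_orientation(edges: list[tuple[int, int]], p: int, scorer: _Scorer):
    """Exact best-scoring acyclic orientation of a given skeleton.

    Returns (score, parent sets); enumerates all 2^edges orientations.
    """
    best_score, best_parents = -np.inf, [set() for _ in range(p)]
    for bits in itertools.product((0, 1), repeat=len(edges)):
        parents = [set() for _ in range(p)]
        for (a, b), bit in zip(edges, bits):
            if bit:
                parents[b].add(a)
            else:
                parents[a].add(b)
        # acyclicity via Kahn's algorithm
        indeg = [len(parents[v]) for v in range(p)]
        order = [v for v in range(p) if indeg[v] == 0]
        seen = 0
        while order:
            u = order.pop()
            seen += 1
            for v in range(p):
                if u in parents[v]:
                    indeg[v] -= 1
                    if indeg[v] == 0:
                        order.append(v)
        if seen < p:
            continue
        s = sum(scorer.local(y, frozenset(parents[y])) for y in range(p))
        if s > best_score:
            best_score, best_parents = s, parents
    return best_score, best_parents


def _parents_to_cpdag(parents: list[set], p: int) -> _PDAG:
    D = _PDAG(p)
    for y in range(p):
        D.par[y] = set(parents[y])
    return _dag_to_cpdag(D)


def _reorientation_sweep(g: _PDAG, scorer: _Scorer, max_edges: int = 14):
    """Exact best orientation of the current skeleton.

    Enumerates every acyclic orientation of the skeleton (skipped above
    ``max_edges`` edges), scores each, and jumps to the equivalence class of
    the best one if it beats the current class. Complements the single-edge
    turning move, which cannot cross multi-edge reorientation valleys.
    """
    edges = _skeleton_edges(g)
    if not edges or len(edges) > max_edges:
        return None
    current = scorer.dag_score(_dag_parent_sets(_pdag_to_dag(g)))
    best_score, best_parents = _best_orientation(edges, g.p, scorer)
    if best_score <= current + 1e-9:
        return None
    return best_score - current, lambda gg: _parents_to_cpdag(best_parents, g.p)


def _skeleton_perturbation(g: _PDAG, scorer: _Scorer, max_nodes: int = 6,
                           max_edges: int = 14):
    """Small-network refinement: exact sweep over one-edge skeleton changes.

    For every possible single edge addition or removal, finds the exact best
    orientation of the perturbed skeleton and moves to the best class found
    if it improves the current score. Enabled only for small node sets, where
    the enumeration is cheap and near-exact search is expected.
    """
    p = g.p
    if p > max_nodes:
        return None
    current_edges = _skeleton_edges(g)
    current = scorer.dag_score(_dag_parent_sets(_pdag_to_dag(g)))
    all_pairs = list(itertools.combinations(range(p), 2))
    candidates: list[list[tuple[int, int]]] = []
    for e in all_pairs:
        candidates.append([x for x in current_edges if x != e]
                          if e in current_edges else current_edges + [e])
    if p <= 4:
        # also try single edge replacements (swap one present for one absent)
        absent = [e for e in all_pairs if e not in current_edges]
        for e_out in current_edges:
            for e_in in absent:
                candidates.append([x for x in current_edges if x != e_out]
                                  + [e_in])
    best = None
    for edges in candidates:
        if len(edges) > max_edges:
            continue
        s, parents = _best_orientation(edges, p, scorer)
        if s > current + 1e-9 and (best is None or s > best[0]):
            best = (s, parents)
    if best is None:
        return None
    s, parents = best
    return s - current, lambda gg: _parents_to_cpdag(parents, p)


def images_search(samples: ROISampleSet,
                  penalty_discount: float = 1.0) -> CPDAGGraph:
    """Greedy equivalence search with the pooled (summed) multisubject score.

    The forward phase inserts the best-scoring edge (with Chickering's
    validity conditions) until no insertion improves the pooled BIC; the
    backward phase deletes edges the same way; a turning phase reverses
    single edges; a reorientation sweep exactly re-optimizes the orientation
    of the final skeleton. The phases alternate until none improves, and the
    CPDAG of the final equivalence class is returned with its pooled score.
    """
    if samples.n_subjects < 2:
        raise ValueError("the multisample search requires at least 2 subjects")
    scorer = _Scorer(samples, penalty_discount)
    g = _PDAG(samples.n_rois)
    # alternate the phases until no move improves the pooled score
    improved = True
    while improved:
        improved = False
        for step in (_forward_step, _backward_step, _turning_step,
                     _reorientation_sweep, _skeleton_perturbation):
            while True:
                move = step(g, scorer)
                if move is None:
                    break
                g = move[1](g)
                improved = True
    dag = _pdag_to_dag(g)
    score = scorer.dag_score(_dag_parent_sets(dag))
    return _pdag_to_graph(g, samples.roi_labels, score)


def exhaustive_search(samples: ROISampleSet,
                      penalty_discount: float = 1.0,
                      max_nodes: int = 4) -> CPDAGGraph:
    """Exact search: enumerate every DAG, score, return the best class's CPDAG.

    Feasible only for small networks (the DAG count grows super-exponentially);
    serves as the oracle for :func:`images_search`.
    """
    p = samples.n_rois
    if p > max_nodes:
        raise ValueError(f"exhaustive enumeration limited to {max_nodes} nodes")
    scorer = _Scorer(samples, penalty_discount)
    nodes = list(range(p))
    candidate_sets = []
    for y in nodes:
        others = [x for x in nodes if x != y]
        sets = []
        for r in range(p):
            sets.extend(frozenset(c) for c in itertools.combinations(others, r))
        candidate_sets.append(sets)

    def acyclic(parents_of) -> bool:
        color = [0] * p

        def dfs(u):
            color[u] = 1
            for v in range(p):
                if u in parents_of[v]:
                    if color[v] == 1 or (color[v] == 0 and dfs(v)):
                        return True
            color[u] = 2
            return False

        return not any(color[u] == 0 and dfs(u) for u in nodes)

    best_score, best_parents = -np.inf, None
    for combo in itertools.product(*candidate_sets):
        if not acyclic(combo):
            continue
        s = sum(scorer.local(y, combo[y]) for y in nodes)
        if s > best_score:
            best_score, best_parents = s, combo
    dag = _PDAG(p)
    for y in nodes:
        dag.par[y] = set(best_parents[y])
    cpdag = _dag_to_cpdag(dag)
    return _pdag_to_graph(cpdag, samples.roi_labels, best_score)


# ---------------------------------------------------------------------------
# non-gaussian orientation on a fixed skeleton

_H_GAUSS = 0.5 * (1.0 + np.log(2.0 * np.pi))
_K1, _GAMMA = 79.047, 0.37457
_K2 = 7.4129


def _entropy_approx(u: np.ndarray) -> float:
    """Maximum-entropy differential entropy approximation for standardized u."""
    return float(_H_GAUSS
                 - _K1 * (np.mean(np.log(np.cosh(u))) - _GAMMA) ** 2
                 - _K2 * np.mean(u * np.exp(-0.5 * u ** 2)) ** 2)


def _standardize(u: np.ndarray) -> np.ndarray:
    return (u - u.mean()) / u.std()


def pairwise_evidence(x: np.ndarray, y: np.ndarray,
                      rule: str = "entropy_lr") -> float:
    """Directional evidence for x -> y on standardized data; antisymmetric.

    ``entropy_lr``: likelihood-ratio of the two directions using the
    maximum-entropy approximation of the differential entropies of each
    regressor and its opposite residual. ``skew``: third-moment variant for
    skewed innovations. Positive values favor x -> y.
    """
    x = _standardize(np.asarray(x, dtype=float))
    y = _standardize(np.asarray(y, dtype=float))
    rho = float(np.mean(x * y))
    if abs(rho) >= 1.0 - 1e-12:
        return 0.0
    if rule == "skew":
        return rho * float(np.mean(x ** 2 * y) - np.mean(x * y ** 2))
    if rule != "entropy_lr":
        raise ValueError(f"unknown orientation rule {rule!r}")
    scale = np.sqrt(1.0 - rho ** 2)
    r_y = (y - rho * x) / scale   # residual when x -> y
    r_x = (x - rho * y) / scale   # residual when y -> x
    ll_xy = -_entropy_approx(x) - _entropy_approx(r_y)
    ll_yx = -_entropy_approx(y) - _entropy_approx(r_x)
    return ll_xy - ll_yx


def _pool_standardized(samples: ROISampleSet) -> np.ndarray:
    mats = []
    for m in samples.matrices:
        c = m - m.mean(axis=0)
        sd = c.std(axis=0)
        sd[sd == 0] = 1.0
        mats.append(c / sd)
    return np.vstack(mats)


def orient_fixed_structure(
    samples: ROISampleSet,
    skeleton: CPDAGGraph,
    rule: str = "entropy_lr",
    ambiguity_scale: float = 10.0,
) -> CPDAGGraph:
    """Orient a CPDAG's undirected edges by pairwise non-gaussian evidence.

    Subjects are standardized then concatenated. Each undirected edge is
    assigned the direction whose regression residual stays closer to
    independent non-gaussian innovations (pairwise likelihood-ratio); edges
    whose absolute evidence falls below ``ambiguity_scale / n_pooled`` are
    left undirected and flagged as ambiguous. Directed skeleton edges are
    retained. If orientation creates a directed cycle, the cycle edge with
    the weakest evidence is reversed until the graph is acyclic.
    """
    pooled = _pool_standardized(samples)
    idx = {lbl: j for j, lbl in enumerate(samples.roi_labels)}
    tol = ambiguity_scale / pooled.shape[0]

    directed = set(skeleton.directed_edges)
    ambiguous = set()
    evidence: dict[tuple[str, str], float] = {}
    for e in skeleton.undirected_edges:
        a, b = sorted(e)
        ev = pairwise_evidence(pooled[:, idx[a]], pooled[:, idx[b]], rule=rule)
        if abs(ev) < tol:
            ambiguous.add(frozenset((a, b)))
            continue
        edge = (a, b) if ev > 0 else (b, a)
        directed.add(edge)
        evidence[edge] = abs(ev)

    # break any directed cycles by reversing the weakest oriented edge
    def find_cycle(edges: set) -> list | None:
        children: dict[str, list[str]] = {}
        for a, b in edges:
            children.setdefault(a, []).append(b)
        state: dict[str, int] = {}
        stack_path: list[tuple[str, str]] = []

        def dfs(u):
            state[u] = 1
            for v in children.get(u, ()):
                stack_path.append((u, v))
                if state.get(v, 0) == 1:
                    i = next(i for i, (s, _) in enumerate(stack_path) if s == v)
                    return stack_path[i:]
                if state.get(v, 0) == 0:
                    cyc = dfs(v)
                    if cyc:
                        return cyc
                stack_path.pop()
            state[u] = 2
            return None

        for n in list(children):
            if state.get(n, 0) == 0:
                cyc = dfs(n)
                if cyc:
                    return cyc
        return None

    for _ in range(len(directed) + 1):
        cyc = find_cycle(directed)
        if cyc is None:
            break
        reversible = [e for e in cyc if e in evidence]
        if not reversible:
            weakest = cyc[0]
            directed.discard(weakest)
            ambiguous.add(frozenset(weakest))
            continue
        weakest = min(reversible, key=lambda e: evidence[e])
        directed.discard(weakest)
        evidence.pop(weakest)
        directed.add((weakest[1], weakest[0]))

    return CPDAGGraph(nodes=list(skeleton.nodes), directed_edges=directed,
                      undirected_edges=ambiguous, score=skeleton.score,
                      ambiguous_edges=set(ambiguous))


def estimate_edge_coefficients(samples: ROISampleSet,
                               dag: CPDAGGraph) -> pd.DataFrame:
    """Per-subject OLS edge coefficients for a fully directed graph.

    Each child is regressed (with intercept) on all its parents within each
    subject; the table has one row per subject and one ``parent->child``
    column per directed edge.
    """
    if dag.undirected_edges:
        raise ValueError("edge coefficients require a fully directed graph")
    idx = {lbl: j for j, lbl in enumerate(samples.roi_labels)}
    parents_of: dict[str, list[str]] = {}
    for a, b in sorted(dag.directed_edges):
        parents_of.setdefault(b, []).append(a)
    cols = [f"{a}->{b}" for a, b in sorted(dag.directed_edges)]
    out = pd.DataFrame(index=samples.subject_ids, columns=cols, dtype=float)
    out.index.name = "subject_id"
    for sid, m in zip(samples.subject_ids, samples.matrices):
        for child, pars in parents_of.items():
            X = np.column_stack([np.ones(m.shape[0])]
                                + [m[:, idx[p]] for p in pars])
            beta, *_ = np.linalg.lstsq(X, m[:, idx[child]], rcond=None)
            for k, p_ in enumerate(pars):
                out.loc[sid, f"{p_}->{child}"] = beta[k + 1]
    if samples.groups is not None:
        out["group"] = samples.groups
    return out


def edge_coefficient(coefs: pd.DataFrame, parent: str, child: str) -> pd.Series:
    """Column lookup helper; raises if the directed edge is absent."""
    col = f"{parent}->{child}"
    if col not in coefs.columns:
        raise KeyError(f"directed edge {col} not present in the graph")
    return coefs[col]
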