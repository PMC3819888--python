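"""Evolutionary multiple-kernel SVM (EMK-SVM).

Genetic programming over kernel expression trees. Internal nodes come
from the function set {+, x, exp} (exp unary, + and x binary); leaves
from the terminal set {K_Poly, K_RBF, alpha} with alpha a constant in
[-1, 1] fixed at creation, where

    K_Poly(x, y) = <x, y> + 1
    K_RBF(x, y)  = exp(-||x - y||^2 / 2).

Each tree is a candidate multiple-kernel function; its fitness is the
stratified inner-cross-validated accuracy of a soft-margin SVM trained
on the tree's Gram matrix. Evolution uses tournament selection with
elitism; per offspring one of {reproduction, crossover, mutation} is
sampled with the configured probabilities renormalized to sum to one.
The best kernel appearing in any generation is the result.

Evolved expressions with negative constants need not be positive
semidefinite; Gram matrices are repaired by spectral clipping (negative
eigenvalues set to zero) before SVM training, while prediction-time
cross-kernels are evaluated raw. Arguments of exp are saturated at
+/-50 to avoid overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

EXP_CAP = 50.0

_BINARY = ("+", "*")
_LEAF_KINDS = ("poly", "rbf", "const")
_LEAF_NAMES = {"poly": "K_Poly", "rbf": "K_RBF"}


class KernelTree:
    """Mutable expression tree over base kernels and scalar constants."""

    __slots__ = ("op", "value", "children")

    def __init__(self, op: str, value: Optional[float] = None,
                 children: Optional[List["KernelTree"]] = None):
        self.op = op
        self.value = value
        self.children = children or []

    # -- structure ---------------------------------------------------------
    def copy(self) -> "KernelTree":
        return KernelTree(self.op, self.value,
                          [c.copy() for c in self.children])

    def depth(self) -> int:
        if not self.children:
            return 1
        return 1 + max(c.depth() for c in self.children)

    def nodes(self) -> List["KernelTree"]:
        out = [self]
        for c in self.children:
            out.extend(c.nodes())
        return out

    def has_kernel_leaf(self) -> bool:
        if self.op in ("poly", "rbf"):
            return True
        return any(c.has_kernel_leaf() for c in self.children)

    def validate(self, max_depth: int = 8) -> None:
        for node in self.nodes():
            if node.op in _BINARY and len(node.children) != 2:
                raise ValueError(f"'{node.op}' node needs two children")
            if node.op == "exp" and len(node.children) != 1:
                raise ValueError("'exp' node needs one child")
            if node.op in ("poly", "rbf", "const") and node.children:
                raise ValueError("leaf nodes cannot have children")
            if node.op == "const" and node.value is None:
                raise ValueError("constant leaf without a value")
        if self.depth() > max_depth:
            raise ValueError(f"tree depth {self.depth()} > {max_depth}")
        if not self.has_kernel_leaf():
            raise ValueError("tree must contain at least one kernel leaf")

    # -- evaluation --------------------------------------------------------
    def evaluate(self, kp, kr):
        """Evaluate elementwise given base-kernel values (scalar or array)."""
        if self.op == "poly":
            return kp
        if self.op == "rbf":
            return kr
        if self.op == "const":
            return self.value if np.isscalar(kp) else np.full_like(
                np.asarray(kp, dtype=float), self.value)
        if self.op == "+":
            return self.children[0].evaluate(kp, kr) + \
                self.children[1].evaluate(kp, kr)
        if self.op == "*":
            return self.children[0].evaluate(kp, kr) * \
                self.children[1].evaluate(kp, kr)
        if self.op == "exp":
            arg = self.children[0].evaluate(kp, kr)
            if np.any(np.abs(arg) > EXP_CAP):
                warnings.warn("exp argument saturated at +/-%g" % EXP_CAP,
                              RuntimeWarning, stacklevel=2)
                arg = np.clip(arg, -EXP_CAP, EXP_CAP)
            return np.exp(arg)
        raise ValueError(f"unknown node op {self.op!r}")

    # -- serialization -----------------------------------------------------
    def to_string(self) -> str:
        if self.op in _LEAF_NAMES:
            return _LEAF_NAMES[self.op]
        if self.op == "const":
            return repr(self.value)
        args = " ".join(c.to_string() for c in self.children)
        return f"({self.op} {args})"

    @staticmethod
    def from_string(expr: str) -> "KernelTree":
        tokens = expr.replace("(", " ( ").replace(")", " ) ").split()
        pos = 0

        def parse() -> KernelTree:
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            if tok == "(":
                op = tokens[pos]
                pos += 1
                children = []
                while tokens[pos] != ")":
                    children.append(parse())
                pos += 1
                return KernelTree(op, children=children)
            if tok == "K_Poly":
                return KernelTree("poly")
            if tok == "K_RBF":
                return KernelTree("rbf")
            return KernelTree("const", value=float(tok))

        tree = parse()
        if pos != len(tokens):
            raise ValueError(f"trailing tokens in kernel expression {expr!r}")
        return tree

    def __repr__(self):
        return f"KernelTree({self.to_string()})"


def base_kernels(X: np.ndarray,
                 Y: Optional[np.ndarray] = None
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """(K_Poly, K_RBF) matrices between rows of X and Y (Y defaults to X)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    kp = X @ Y.T + 1.0
    kr = np.exp(-0.5 * cdist(X, Y, "sqeuclidean"))
    return kp, kr


def eval_kernel_tree(tree: KernelTree, x: np.ndarray,
                     y: np.ndarray) -> float:
    """Evaluate the multiple-kernel function at one vector pair."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    kp = float(np.dot(x, y) + 1.0)
    kr = float(np.exp(-0.5 * np.sum((x - y) ** 2)))
    return float(tree.evaluate(kp, kr))


@dataclass
class PSDRepair:
    min_eigenvalue: float     # smallest eigenvalue before clipping
    clipped: bool


def psd_clip(G: np.ndarray, tol: float = 1e-10
             ) -> Tuple[np.ndarray, PSDRepair]:
    """Clip negative eigenvalues of a symmetric matrix to zero."""
    G = 0.5 * (G + G.T)
    evals, evecs = np.linalg.eigh(G)
    min_eig = float(evals[0])
    if min_eig < -tol:
        evals = np.clip(evals, 0.0, None)
        G = (evecs * evals) @ evecs.T
        G = 0.5 * (G + G.T)
        # rounding in the reconstruction reintroduces eigenvalues of
        # order eps*||G||; a scale-proportional ridge keeps the matrix
        # numerically PSD even for extreme kernel magnitudes
        G[np.diag_indices_from(G)] += 1e-12 * float(evals[-1])
        return G, PSDRepair(min_eig, True)
    return G, PSDRepair(min_eig, False)


def gram_matrix(tree: KernelTree, X: np.ndarray, tol: float = 1e-10
                ) -> Tuple[np.ndarray, PSDRepair]:
    """PSD-repaired Gram matrix of a kernel tree on sample rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    kp, kr = base_kernels(X)
    G = np.asarray(tree.evaluate(kp, kr), dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError(
            f"non-finite Gram entries for kernel {tree.to_string()}")
    return psd_clip(G, tol)


@dataclass
class GPConfig:
    pop_size: int = 100
    max_gen: int = 100
    max_depth: int = 8
    p_reproduction: float = 0.1
    p_crossover: float = 0.85
    p_mutation: float = 0.1
    tournament_size: int = 3
    elitism: int = 1
    inner_folds: int = 5
    svm_c: float = 1.0
    seed: int = 0
    sequential_variation: bool = False  # mutate after crossover instead of
    #                                     renormalized operator sampling

    def __post_init__(self):
        for p in (self.p_reproduction, self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("operator probabilities must be in [0, 1]")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")


@dataclass
class EvolutionResult:
    best_tree: KernelTree
    best_fitness: float
    best_generation: int
    history: pd.DataFrame     # gen, best_fitness, mean_fitness, best_expr

    @property
    def best_fitness_history(self) -> np.ndarray:
        return self.history["best_fitness"].to_numpy()


def _random_node(rng: np.random.Generator, depth_left: int,
                 grow: bool) -> KernelTree:
    if depth_left <= 1 or (grow and rng.random() < 0.35):
        kind = _LEAF_KINDS[rng.integers(len(_LEAF_KINDS))]
        if kind == "const":
            return KernelTree("const", value=float(rng.uniform(-1, 1)))
        return KernelTree(kind)
    op = ("+", "*", "exp")[rng.integers(3)]
    n_children = 1 if op == "exp" else 2
    return KernelTree(op, children=[
        _random_node(rng, depth_left - 1, grow) for _ in range(n_children)])


def random_tree(config: GPConfig, rng: np.random.Generator) -> KernelTree:
    """Ramped half-and-half tree generation between depths 2 and max."""
    for _ in range(100):
        depth = int(rng.integers(2, config.max_depth + 1))
        grow = bool(rng.integers(2))
        tree = _random_node(rng, depth, grow)
        if tree.has_kernel_leaf() and tree.depth() <= config.max_depth:
            return tree
    # constant-only draws are rare; force a kernel leaf as last resort
    return KernelTree("rbf")


def _valid(tree: KernelTree, max_depth: int) -> bool:
    return tree.has_kernel_leaf() and tree.depth() <= max_depth


def crossover(a: KernelTree, b: KernelTree, rng: np.random.Generator,
              max_depth: int = 8) -> Tuple[KernelTree, KernelTree]:
    """Swap random subtrees; invalid offspring fall back to parent copies."""
    for _ in range(10):
        c1, c2 = a.copy(), b.copy()
        n1 = c1.nodes()[rng.integers(len(c1.nodes()))]
        n2 = c2.nodes()[rng.integers(len(c2.nodes()))]
        n1.op, n2.op = n2.op, n1.op
        n1.value, n2.value = n2.value, n1.value
        n1.children, n2.children = n2.children, n1.children
        if _valid(c1, max_depth) and _valid(c2, max_depth):
            return c1, c2
    return a.copy(), b.copy()


def mutate(a: KernelTree, rng: np.random.Generator,
           max_depth: int = 8) -> KernelTree:
    """Perturb a constant or replace a random subtree with a fresh one."""
    for _ in range(10):
        c = a.copy()
        node = c.nodes()[rng.integers(len(c.nodes()))]
        if node.op == "const" and rng.random() < 0.5:
            node.value = float(np.clip(node.value + rng.normal(0, 0.25),
                                       -1.0, 1.0))
        else:
            depth_left = max(max_depth - c.depth() + node.depth(), 1)
            fresh = _random_node(rng, min(depth_left, 4), grow=True)
            node.op, node.value = fresh.op, fresh.value
            node.children = fresh.children
        if _valid(c, max_depth):
            return c
    return a.copy()


def fitness(tree: KernelTree, X: np.ndarray, labels: np.ndarray,
            config: GPConfig,
            base: Optional[Tuple[np.ndarray, np.ndarray]] = None,
            groups: Optional[np.ndarray] = None) -> float:
    """Stratified inner-CV accuracy of an SVM using the tree's kernel.

    The inner split is derived deterministically from ``config.seed`` so
    every tree in one evolution run is scored on identical folds. When
    ``groups`` is given (e.g. subject ids for repeated sessions) the
    inner folds keep groups whole, so the fitness estimate is free of
    within-group train/validation leakage.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    kp, kr = base_kernels(X) if base is None else base
    G = np.asarray(tree.evaluate(kp, kr), dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError(
            f"non-finite Gram entries for kernel {tree.to_string()}")
    G = 0.5 * (G + G.T)
    if groups is not None:
        skf = StratifiedGroupKFold(n_splits=config.inner_folds,
                                   shuffle=True,
                                   random_state=config.seed % (2 ** 31))
        splits = skf.split(X, y, groups=groups)
    else:
        skf = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                              random_state=config.seed % (2 ** 31))
        splits = skf.split(X, y)
    accs = []
    for tr, te in splits:
        if len(np.unique(y[tr])) < 2:
            warnings.warn("skipping degenerate fold (single class)",
                          RuntimeWarning, stacklevel=2)
            continue
        G_tr, _ = psd_clip(G[np.ix_(tr, tr)])
        # iteration cap: degenerate evolved kernels (entries ~ e^50) can
        # make libsvm cycle or blow up its duals; such trees are unfit
        clf = SVC(C=config.svm_c, kernel="precomputed", max_iter=20000)
        try:
            clf.fit(G_tr, y[tr])
            pred = clf.predict(G[np.ix_(te, tr)])
        except ValueError:
            accs.append(0.0)
            continue
        accs.append(float(np.mean(pred == y[te])))
    if not accs:
        raise ValueError("all inner folds degenerate")
    return float(np.mean(accs))


def _tournament(pop, fits, rng, size):
    idx = rng.integers(0, len(pop), size=size)
    best = idx[int(np.argmax([fits[i] for i in idx]))]
    return pop[best]


def evolve(X: np.ndarray, labels: np.ndarray,
           config: GPConfig = GPConfig(),
           groups: Optional[np.ndarray] = None) -> EvolutionResult:
    """Run the GP loop and return the best kernel found in any generation."""
    rng = np.random.default_rng(config.seed)
    kp, kr = base_kernels(np.atleast_2d(np.asarray(X, dtype=float)))
    base = (kp, kr)

    def score(t):
        return fitness(t, X, labels, config, base=base, groups=groups)

    pop = [random_tree(config, rng) for _ in range(config.pop_size)]
    fits = [score(t) for t in pop]
    best_i = int(np.argmax(fits))
    best_tree, best_fit, best_gen = pop[best_i].copy(), fits[best_i], 0

    probs = np.array([config.p_reproduction, config.p_crossover,
                      config.p_mutation], dtype=float)
    probs = probs / probs.sum()
    rows = []
    for gen in range(1, config.max_gen + 1):
        if best_fit >= 1.0:
            break
        new_pop: List[KernelTree] = []
        if config.elitism > 0:
            elite = np.argsort(fits)[::-1][:config.elitism]
            new_pop.extend(pop[i].copy() for i in elite)
        while len(new_pop) < config.pop_size:
            if config.sequential_variation:
                p1 = _tournament(pop, fits, rng, config.tournament_size)
                p2 = _tournament(pop, fits, rng, config.tournament_size)
                if rng.random() < config.p_crossover:
                    child, _ = crossover(p1, p2, rng, config.max_depth)
                else:
                    child = p1.copy()
                if rng.random() < config.p_mutation:
                    child = mutate(child, rng, config.max_depth)
                new_pop.append(child)
                continue
            op = rng.choice(3, p=probs)
            if op == 0:
                new_pop.append(_tournament(pop, fits, rng,
                                           config.tournament_size).copy())
            elif op == 1:
                p1 = _tournament(pop, fits, rng, config.tournament_size)
                p2 = _tournament(pop, fits, rng, config.tournament_size)
                c1, c2 = crossover(p1, p2, rng, config.max_depth)
                new_pop.append(c1)
                if len(new_pop) < config.pop_size:
                    new_pop.append(c2)
            else:
                p1 = _tournament(pop, fits, rng, config.tournament_size)
                new_pop.append(mutate(p1, rng, config.max_depth))
        pop = new_pop
        fits = [score(t) for t in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_tree, best_fit = pop[gen_best].copy(), fits[gen_best]
            best_gen = gen
        rows.append({"gen": gen, "best_fitness": best_fit,
                     "mean_fitness": float(np.mean(fits)),
                     "best_expr": best_tree.to_string()})
    history = pd.DataFrame(rows, columns=["gen", "best_fitness",
                                          "mean_fitness", "best_expr"])
    return EvolutionResult(best_tree=best_tree, best_fitness=best_fit,
                           best_generation=best_gen, history=history)
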