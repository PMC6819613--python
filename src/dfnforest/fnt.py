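"""Flexible neural trees: evaluation, structure search (GGGP), parameter search (PSO).

A flexible neural tree (FNT) is a tree-structured regressor whose leaves are
input features and whose internal nodes are "flexible neurons": a node of
arity k (written +_k) holds k connection weights w_i and two activation
parameters (a, b) and computes

    net = sum_i w_i * child_i          out = exp(-((net - a) / b)^2)

the Gaussian flexible activation of the FNT literature. The root's value is
the tree output, so a neuron-rooted tree maps into (0, 1].

Structure is searched by grammar-guided genetic programming (GGGP) over the
productions

    S -> N        N -> +_k(A, ..., A)  for each arity k in the function set
    A -> N | T    (T = terminal; forced at the depth bound)

so every individual ever produced is grammatically valid, has all neuron
arities inside the configured function set, and respects the depth bound.
Continuous parameters (all weights, a, b of every neuron) are tuned by
particle swarm optimisation (PSO) with velocity clipping. During evolution
each candidate receives a short PSO polish before its RMSE fitness is read;
the generation winner gets a full PSO run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class TreeStructureError(ValueError):
    """Raised when a tree violates its structural invariants."""


B_MIN = 0.05  # |b| floor; keeps the Gaussian width bounded away from zero


# ---------------------------------------------------------------------------
# Representation
# ---------------------------------------------------------------------------

@dataclass
class FNTNode:
    """A tree node: either a terminal (input feature) or a flexible neuron."""

    kind: str  # "terminal" | "neuron"
    feature_index: int = -1
    children: list["FNTNode"] = field(default_factory=list)
    weights: np.ndarray = field(default_factory=lambda: np.zeros(0))
    a: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("terminal", "neuron"):
            raise TreeStructureError(f"unknown node kind {self.kind!r}")
        if self.kind == "neuron":
            self.weights = np.asarray(self.weights, dtype=float)

    @property
    def arity(self) -> int:
        return len(self.children)

    def clone(self) -> "FNTNode":
        if self.kind == "terminal":
            return FNTNode(kind="terminal", feature_index=self.feature_index)
        return FNTNode(
            kind="neuron",
            children=[c.clone() for c in self.children],
            weights=self.weights.copy(),
            a=self.a,
            b=self.b,
        )

    def depth(self) -> int:
        """Number of neuron levels on the deepest root-to-leaf path."""
        if self.kind == "terminal":
            return 0
        return 1 + max(c.depth() for c in self.children)

    def n_parameters(self) -> int:
        if self.kind == "terminal":
            return 0
        return self.arity + 2 + sum(c.n_parameters() for c in self.children)


@dataclass
class FNTree:
    """A flexible neural tree bound to a feature space and a grammar."""

    root: FNTNode
    function_set: frozenset[int]
    n_features: int
    max_depth: int

    def __post_init__(self) -> None:
        self.function_set = frozenset(int(k) for k in self.function_set)
        self.validate()

    def validate(self) -> None:
        if not self.function_set or any(k < 1 for k in self.function_set):
            raise TreeStructureError(f"invalid function set {set(self.function_set)}")
        if self.root.kind != "neuron" and self.root.kind != "terminal":
            raise TreeStructureError("root must be a node")
        if self.root.depth() > self.max_depth:
            raise TreeStructureError(
                f"tree depth {self.root.depth()} exceeds max_depth {self.max_depth}"
            )
        self._validate_node(self.root)

    def _validate_node(self, node: FNTNode) -> None:
        if node.kind == "terminal":
            if not 0 <= node.feature_index < self.n_features:
                raise TreeStructureError(
                    f"terminal references feature {node.feature_index} outside "
                    f"[0, {self.n_features})"
                )
            return
        if node.arity not in self.function_set:
            raise TreeStructureError(
                f"neuron arity {node.arity} not in function set {set(self.function_set)}"
            )
        if node.weights.shape != (node.arity,):
            raise TreeStructureError("weights length differs from arity")
        if node.b == 0.0:
            raise TreeStructureError("neuron has b == 0")
        if not (np.all(np.isfinite(node.weights)) and np.isfinite(node.a) and np.isfinite(node.b)):
            raise TreeStructureError("neuron holds non-finite parameters")
        for child in node.children:
            self._validate_node(child)

    def clone(self) -> "FNTree":
        return FNTree(
            root=self.root.clone(),
            function_set=self.function_set,
            n_features=self.n_features,
            max_depth=self.max_depth,
        )

    # -- flat parameter vector (preorder: per neuron [w_1..w_k, a, b]) ------

    def get_parameters(self) -> np.ndarray:
        out: list[float] = []

        def visit(node: FNTNode) -> None:
            if node.kind == "neuron":
                out.extend(node.weights.tolist())
                out.append(node.a)
                out.append(node.b)
                for c in node.children:
                    visit(c)

        visit(self.root)
        return np.asarray(out, dtype=float)

    def set_parameters(self, params: np.ndarray) -> None:
        params = np.asarray(params, dtype=float)
        pos = 0

        def visit(node: FNTNode) -> None:
            nonlocal pos
            if node.kind == "neuron":
                k = node.arity
                node.weights = params[pos : pos + k].copy()
                node.a = float(params[pos + k])
                node.b = float(_clamp_b(params[pos + k + 1]))
                pos += k + 2
                for c in node.children:
                    visit(c)

        visit(self.root)
        if pos != params.size:
            raise TreeStructureError(
                f"parameter vector length {params.size} != tree parameter count {pos}"
            )


def _clamp_b(b: float | np.ndarray) -> float | np.ndarray:
    """Keep |b| >= B_MIN, preserving sign (zero maps to +B_MIN)."""
    return np.copysign(np.maximum(np.abs(b), B_MIN), np.where(np.asarray(b) < 0, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Evaluation and fitness
# ---------------------------------------------------------------------------

def _eval_node(node: FNTNode, x: np.ndarray) -> float:
    if node.kind == "terminal":
        return float(x[node.feature_index])
    net = sum(
        float(w) * _eval_node(c, x) for w, c in zip(node.weights, node.children)
    )
    return float(np.exp(-(((net - node.a) / node.b) ** 2)))


def evaluate_tree(tree: FNTree, x: np.ndarray) -> float:
    """Recursive evaluation of one sample (reference scalar path)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (tree.n_features,):
        raise TreeStructureError(
            f"input has shape {x.shape}, tree expects ({tree.n_features},)"
        )
    return _eval_node(tree.root, x)


def _eval_node_batch(node: FNTNode, X: np.ndarray) -> np.ndarray:
    if node.kind == "terminal":
        return X[:, node.feature_index]
    net = np.zeros(X.shape[0])
    for w, child in zip(node.weights, node.children):
        net += w * _eval_node_batch(child, X)
    return np.exp(-(((net - node.a) / node.b) ** 2))


def evaluate_tree_batch(tree: FNTree, X: np.ndarray) -> np.ndarray:
    """Vectorised evaluation over the rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != tree.n_features:
        raise TreeStructureError(
            f"input has {X.shape[1]} features, tree expects {tree.n_features}"
        )
    return _eval_node_batch(tree.root, X)


def _compile_structure(root: FNTNode) -> list[tuple]:
    """Postorder instruction list for fast repeated evaluation.

    Instructions: ("t", feature_index) pushes a feature column;
    ("n", param_offset, arity) pops `arity` values and pushes the neuron
    output. Parameter offsets follow the preorder flat layout used by
    get_parameters / set_parameters.
    """
    instructions: list[tuple] = []
    pos = 0

    def walk(node: FNTNode) -> None:
        nonlocal pos
        if node.kind == "terminal":
            instructions.append(("t", node.feature_index))
            return
        offset = pos
        pos += node.arity + 2
        for child in node.children:
            walk(child)
        instructions.append(("n", offset, node.arity))

    walk(root)
    return instructions


def _eval_compiled(
    instructions: list[tuple], X: np.ndarray, params: np.ndarray
) -> np.ndarray:
    """Evaluate a compiled structure under many parameter vectors at once.

    params has shape (P, D); positions are assumed b-clamped already.
    Accumulation order matches the recursive evaluator exactly.
    """
    P, N = params.shape[0], X.shape[0]
    stack: list[np.ndarray] = []
    for ins in instructions:
        if ins[0] == "t":
            stack.append(X[:, ins[1]].reshape(1, N))
        else:
            _, offset, k = ins
            children = stack[-k:]
            del stack[-k:]
            net = params[:, offset, None] * children[0]
            for i in range(1, k):
                net += params[:, offset + i, None] * children[i]
            net -= params[:, offset + k, None]
            net /= params[:, offset + k + 1, None]
            net *= net
            np.negative(net, out=net)
            stack.append(np.exp(net, out=net))
    return stack[0]


def _eval_particles(
    node: FNTNode, X: np.ndarray, params: np.ndarray, pos: int
) -> tuple[np.ndarray, int]:
    """Evaluate one structure under many parameter vectors at once.

    params has shape (P, D); returns ((P, N) outputs, next offset).
    Retained as the readable reference path; hot loops use
    :func:`_compile_structure` + :func:`_eval_compiled`.
    """
    if node.kind == "terminal":
        return np.broadcast_to(X[:, node.feature_index], (params.shape[0], X.shape[0])), pos
    k = node.arity
    w = params[:, pos : pos + k]
    a = params[:, pos + k]
    b = np.asarray(_clamp_b(params[:, pos + k + 1]), dtype=float)
    pos += k + 2
    net = np.zeros((params.shape[0], X.shape[0]))
    for i, child in enumerate(node.children):
        val, pos = _eval_particles(child, X, params, pos)
        net += w[:, i : i + 1] * val
    return np.exp(-(((net - a[:, None]) / b[:, None]) ** 2)), pos


def tree_rmse(tree: FNTree, X: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared error of the tree output against targets in [0, 1]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise TreeStructureError("empty data")
    if X.shape[0] != y.shape[0]:
        raise TreeStructureError(
            f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
        )
    resid = evaluate_tree_batch(tree, X) - y
    return float(np.sqrt(np.mean(resid * resid)))


# ---------------------------------------------------------------------------
# Grammar-guided sampling and variation operators
# ---------------------------------------------------------------------------

# Probability of expanding A -> T above the depth bound. Terminal-heavy
# growth keeps sampled trees sparse — the point of the flexible-neuron-tree
# representation — and limits parameter counts relative to the small sample
# sizes the model targets.
P_TERMINAL = 0.7


def _sample_neuron(
    arities: tuple[int, ...],
    n_features: int,
    depth: int,
    max_depth: int,
    rng: np.random.Generator,
) -> FNTNode:
    k = int(rng.choice(arities))
    children = []
    for _ in range(k):
        if depth >= max_depth or rng.random() < P_TERMINAL:
            children.append(
                FNTNode(kind="terminal", feature_index=int(rng.integers(n_features)))
            )
        else:
            children.append(
                _sample_neuron(arities, n_features, depth + 1, max_depth, rng)
            )
    return FNTNode(
        kind="neuron",
        children=children,
        weights=rng.uniform(-1.0, 1.0, size=k),
        a=float(rng.uniform(-1.0, 1.0)),
        b=float(rng.uniform(0.1, 2.0)),
    )


def sample_tree(
    function_set: frozenset[int] | set[int],
    n_features: int,
    max_depth: int,
    rng: np.random.Generator,
) -> FNTree:
    """Grow a random grammar-valid tree (root is always a neuron)."""
    if not function_set:
        raise TreeStructureError("function_set must be nonempty")
    if max_depth < 1:
        raise TreeStructureError(f"max_depth must be >= 1, got {max_depth}")
    arities = tuple(sorted(int(k) for k in function_set))
    root = _sample_neuron(arities, n_features, 1, max_depth, rng)
    return FNTree(
        root=root,
        function_set=frozenset(arities),
        n_features=n_features,
        max_depth=max_depth,
    )


def _collect_nodes(root: FNTNode) -> list[tuple[FNTNode, FNTNode | None, int, int]]:
    """Preorder list of (node, parent, child_slot, depth); root depth is 1."""
    out: list[tuple[FNTNode, FNTNode | None, int, int]] = []

    def visit(node: FNTNode, parent: FNTNode | None, slot: int, depth: int) -> None:
        out.append((node, parent, slot, depth))
        for i, c in enumerate(node.children):
            visit(c, node, i, depth + 1)

    visit(root, None, -1, 1)
    return out


def crossover(
    tree1: FNTree, tree2: FNTree, rng: np.random.Generator, tries: int = 10
) -> tuple[FNTree, FNTree]:
    """Grammar-respecting subtree exchange.

    A swap is accepted only if both offspring stay within their depth
    bounds and keep a neuron at the root; after ``tries`` failed draws the
    parents are returned unchanged (as clones).
    """
    t1, t2 = tree1.clone(), tree2.clone()
    nodes1 = _collect_nodes(t1.root)
    nodes2 = _collect_nodes(t2.root)
    for _ in range(tries):
        n1, p1, s1, d1 = nodes1[int(rng.integers(len(nodes1)))]
        n2, p2, s2, d2 = nodes2[int(rng.integers(len(nodes2)))]
        if p1 is None and n2.kind != "neuron":
            continue
        if p2 is None and n1.kind != "neuron":
            continue
        if (d1 - 1) + n2.depth() > t1.max_depth:
            continue
        if (d2 - 1) + n1.depth() > t2.max_depth:
            continue
        if p1 is None:
            t1.root = n2
        else:
            p1.children[s1] = n2
        if p2 is None:
            t2.root = n1
        else:
            p2.children[s2] = n1
        break
    t1.validate()
    t2.validate()
    return t1, t2


def mutate(tree: FNTree, rng: np.random.Generator) -> FNTree:
    """Grammar-respecting point mutation.

    With equal probability either regrows a uniformly chosen subtree
    (within the remaining depth budget) or perturbs one neuron parameter
    with Gaussian noise.
    """
    out = tree.clone()
    arities = tuple(sorted(out.function_set))
    nodes = _collect_nodes(out.root)
    if rng.random() < 0.5:
        node, parent, slot, depth = nodes[int(rng.integers(len(nodes)))]
        budget = out.max_depth - (depth - 1)
        if parent is None or budget >= 1:
            new = _sample_neuron(arities, out.n_features, depth, out.max_depth, rng)
            if parent is None:
                out.root = new
            else:
                # A -> T regrow is also legal below the root
                if rng.random() < P_TERMINAL:
                    new = FNTNode(
                        kind="terminal", feature_index=int(rng.integers(out.n_features))
                    )
                parent.children[slot] = new
    else:
        params = out.get_parameters()
        if params.size:
            i = int(rng.integers(params.size))
            params[i] += rng.normal(0.0, 0.3)
            out.set_parameters(params)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Particle swarm optimisation of tree parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSOConfig:
    """PSO settings: cognitive/social accelerations and velocity cap."""

    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 2.0
    swarm_size: int = 20
    iterations: int = 50
    inertia: float = 0.729
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError(f"v_max must be > 0, got {self.v_max}")
        if self.swarm_size < 2:
            raise ValueError(f"swarm_size must be >= 2, got {self.swarm_size}")
        if self.iterations < 0:
            raise ValueError(f"iterations must be >= 0, got {self.iterations}")


def _rmse_for_particles(
    instructions: list[tuple], X: np.ndarray, y: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """RMSE of every particle's parameter vector, evaluated in one pass."""
    resid = _eval_compiled(instructions, X, positions) - y[None, :]
    return np.sqrt(np.mean(resid * resid, axis=1))


def pso_optimize(
    tree: FNTree,
    X: np.ndarray,
    y: np.ndarray,
    config: PSOConfig,
    return_trace: bool = False,
) -> FNTree | tuple[FNTree, list[float]]:
    """Tune all neuron parameters of a fixed structure by standard PSO.

    The flat parameter vector (weights, a, b per neuron, preorder) is the
    particle position. Velocity components are clipped to +/- v_max and b
    components are clamped to |b| >= 0.05. The tree with the global-best
    parameters is returned; the gbest RMSE trace is non-increasing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if config.iterations == 0:
        return (tree.clone(), []) if return_trace else tree.clone()
    base = tree.get_parameters()
    D = base.size
    if D == 0:
        return (tree.clone(), []) if return_trace else tree.clone()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    instructions = _compile_structure(tree.root)
    b_cols = _b_column_indices(tree)

    # Half the swarm explores locally around the incoming parameters, half
    # restarts globally in the sampling ranges; particle 0 keeps them exactly.
    # Zero initial velocities make the first moves purely attraction-driven,
    # which matters for the short polish runs used during evolution.
    positions = base[None, :] + rng.uniform(-0.25, 0.25, size=(config.swarm_size, D))
    positions[0] = base
    n_global = config.swarm_size // 2
    if n_global:
        fresh = rng.uniform(-1.0, 1.0, size=(n_global, D))
        if b_cols.size:
            fresh[:, b_cols] = rng.uniform(0.1, 2.0, size=(n_global, b_cols.size))
        positions[config.swarm_size - n_global :] = fresh
    if b_cols.size:
        positions[:, b_cols] = _clamp_b(positions[:, b_cols])
    velocities = np.zeros((config.swarm_size, D))

    fitness = _rmse_for_particles(instructions, X, y, positions)
    pbest_pos = positions.copy()
    pbest_fit = fitness.copy()
    g = int(np.argmin(pbest_fit))
    gbest_pos, gbest_fit = pbest_pos[g].copy(), float(pbest_fit[g])
    trace = [gbest_fit]

    for _ in range(config.iterations):
        r1 = rng.random((config.swarm_size, D))
        r2 = rng.random((config.swarm_size, D))
        velocities = (
            config.inertia * velocities
            + config.c1 * r1 * (pbest_pos - positions)
            + config.c2 * r2 * (gbest_pos[None, :] - positions)
        )
        np.clip(velocities, -config.v_max, config.v_max, out=velocities)
        positions = positions + velocities
        if b_cols.size:
            positions[:, b_cols] = _clamp_b(positions[:, b_cols])
        fitness = _rmse_for_particles(instructions, X, y, positions)
        improved = fitness < pbest_fit
        pbest_pos[improved] = positions[improved]
        pbest_fit[improved] = fitness[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest_pos, gbest_fit = pbest_pos[g].copy(), float(pbest_fit[g])
        trace.append(gbest_fit)

    out = tree.clone()
    out.set_parameters(gbest_pos)
    return (out, trace) if return_trace else out


def _b_column_indices(tree: FNTree) -> np.ndarray:
    """Indices of the b parameters inside the flat parameter vector."""
    idx: list[int] = []
    pos = 0

    def visit(node: FNTNode) -> None:
        nonlocal pos
        if node.kind == "neuron":
            idx.append(pos + node.arity + 1)
            pos += node.arity + 2
            for c in node.children:
                visit(c)

    visit(tree.root)
    return np.asarray(idx, dtype=int)


def _clamp_b_columns(tree: FNTree, positions: np.ndarray) -> np.ndarray:
    cols = _b_column_indices(tree)
    if cols.size:
        positions[:, cols] = _clamp_b(positions[:, cols])
    return positions


# ---------------------------------------------------------------------------
# Grammar-guided genetic programming
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPConfig:
    """GGGP settings (population 50, crossover 0.4, mutation 0.01 defaults)."""

    population_size: int = 50
    crossover_prob: float = 0.4
    mutation_prob: float = 0.01
    generations: int = 30
    tournament_size: int = 2
    seed: int = 0
    polish_iterations: int = 10
    final_candidates: int = 5

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError(
                f"population_size must be >= 2, got {self.population_size}"
            )
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.generations < 0:
            raise ValueError(f"generations must be >= 0, got {self.generations}")
        if self.tournament_size < 1:
            raise ValueError(f"tournament_size must be >= 1, got {self.tournament_size}")


@dataclass
class _Individual:
    tree: FNTree
    fitness: float
    order: int  # insertion order; used only for deterministic tie-breaks


def _tournament(
    population: list[_Individual], size: int, rng: np.random.Generator
) -> _Individual:
    picks = rng.integers(len(population), size=size)
    chosen = [population[int(i)] for i in picks]
    return min(chosen, key=lambda ind: (ind.fitness, ind.order))


def gggp_search(
    X: np.ndarray,
    y: np.ndarray,
    function_set: frozenset[int] | set[int],
    gp: GPConfig,
    pso: PSOConfig,
    max_depth: int = 4,
) -> FNTree:
    """Evolve an FNT structure by GGGP, tuning parameters by PSO.

    Fitness of every candidate is its training RMSE after a short PSO
    polish (``gp.polish_iterations``); the evolved winner receives a full
    PSO run before being returned. Elitism guarantees a non-increasing
    best-so-far fitness across generations.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(gp.seed))

    def polished(tree: FNTree, order: int) -> _Individual:
        cfg = replace(
            pso,
            iterations=gp.polish_iterations,
            swarm_size=pso.swarm_size,
            seed=int(rng.integers(2**31)),
        )
        tuned = pso_optimize(tree, X, y, cfg)
        return _Individual(tuned, tree_rmse(tuned, X, y), order)

    counter = 0
    population: list[_Individual] = []
    for _ in range(gp.population_size):
        population.append(
            polished(sample_tree(function_set, X.shape[1], max_depth, rng), counter)
        )
        counter += 1
    best = min(population, key=lambda ind: (ind.fitness, ind.order))

    for _ in range(gp.generations):
        next_pop: list[_Individual] = [best]  # elitism
        while len(next_pop) < gp.population_size:
            parent1 = _tournament(population, gp.tournament_size, rng)
            parent2 = _tournament(population, gp.tournament_size, rng)
            changed = False
            if rng.random() < gp.crossover_prob:
                child_tree, _ = crossover(parent1.tree, parent2.tree, rng)
                changed = True
            else:
                child_tree = parent1.tree.clone()
            if rng.random() < gp.mutation_prob:
                child_tree = mutate(child_tree, rng)
                changed = True
            if changed:
                child = polished(child_tree, counter)
            else:
                child = _Individual(child_tree, parent1.fitness, counter)
            counter += 1
            next_pop.append(child)
        population = next_pop
        gen_best = min(population, key=lambda ind: (ind.fitness, ind.order))
        if (gen_best.fitness, gen_best.order) < (best.fitness, best.order):
            best = gen_best

    # Final full PSO on the strongest evolved structures: the short polish is
    # a noisy ranking, so giving the top few candidates a full run (cheap,
    # vectorised) acts as random restarts over good structures.
    ranked = sorted(population, key=lambda ind: (ind.fitness, ind.order))
    finalists = [best] + [ind for ind in ranked if ind is not best]
    finalists = finalists[: max(1, gp.final_candidates)]
    champion, champion_rmse = best.tree, best.fitness
    for ind in finalists:
        final_cfg = replace(pso, seed=int(rng.integers(2**31)))
        candidate = pso_optimize(ind.tree, X, y, final_cfg)
        rmse = tree_rmse(candidate, X, y)
        if rmse < champion_rmse:
            champion, champion_rmse = candidate, rmse
    return champion


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def tree_to_text(tree: FNTree) -> str:
    """Human-readable nested expression; floats round-trip exactly via repr."""

    def fmt(node: FNTNode) -> str:
        if node.kind == "terminal":
            return f"x{node.feature_index}"
        w = ",".join(repr(float(v)) for v in node.weights)
        kids = ",".join(fmt(c) for c in node.children)
        return f"+{node.arity}(a={node.a!r},b={node.b!r},w=[{w}];{kids})"

    header = (
        f"fnt n_features={tree.n_features} max_depth={tree.max_depth} "
        f"function_set={','.join(str(k) for k in sorted(tree.function_set))}"
    )
    return header + "\n" + fmt(tree.root) + "\n"


def tree_from_text(text: str) -> FNTree:
    lines = [l for l in text.strip().splitlines() if l.strip()]
    if len(lines) != 2 or not lines[0].startswith("fnt "):
        raise TreeStructureError("malformed tree text")
    meta = dict(part.split("=", 1) for part in lines[0].split()[1:])
    expr = lines[1].strip()

    def parse(s: str, pos: int) -> tuple[FNTNode, int]:
        if s[pos] == "x":
            end = pos + 1
            while end < len(s) and s[end].isdigit():
                end += 1
            return FNTNode(kind="terminal", feature_index=int(s[pos + 1 : end])), end
        if s[pos] != "+":
            raise TreeStructureError(f"parse error at position {pos}")
        open_paren = s.index("(", pos)
        arity = int(s[pos + 1 : open_paren])
        head_end = s.index(";", open_paren)
        head = s[open_paren + 1 : head_end]
        fields = dict(item.split("=", 1) for item in head.split(",", 2))
        a = float(fields["a"])
        b = float(fields["b"])
        w_text = fields["w"].strip("[]")
        weights = np.asarray(
            [float(v) for v in w_text.split(",")] if w_text else [], dtype=float
        )
        children = []
        cursor = head_end + 1
        for i in range(arity):
            child, cursor = parse(s, cursor)
            children.append(child)
            if i < arity - 1:
                if s[cursor] != ",":
                    raise TreeStructureError(f"expected ',' at position {cursor}")
                cursor += 1
        if s[cursor] != ")":
            raise TreeStructureError(f"expected ')' at position {cursor}")
        return (
            FNTNode(kind="neuron", children=children, weights=weights, a=a, b=b),
            cursor + 1,
        )

    root, end = parse(expr, 0)
    if end != len(expr):
        raise TreeStructureError("trailing characters after tree expression")
    return FNTree(
        root=root,
        function_set=frozenset(int(k) for k in meta["function_set"].split(",")),
        n_features=int(meta["n_features"]),
        max_depth=int(meta["max_depth"]),
    )
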