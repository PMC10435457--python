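"""Multi-gene symbolic regression over {+, -, *, /, exp}.

A model is a weighted sum of evolved expression trees ("genes") plus a bias:

    y_hat = b0 + w1 * g1(x) + ... + wk * gk(x)

The gene structures evolve by genetic programming (tournament selection,
subtree and gene-level crossover, subtree mutation, elitism) while the
weights w and bias b0 are refit by least squares for every candidate, so
selection pressure acts only on the functional forms.  Fitness is the
training RMSD of the weighted model.

Trees are nested tuples:

    ("const", value)
    ("var", column_index)
    ("op", name, child [, child])      # add/sub/mul/div binary, exp unary

Arithmetic is protected so that finite inputs always give finite outputs:
division returns 1 when |denominator| < 1e-12, the exp argument is clamped
to at most 50, and every operator output is clipped to +/-1e100 as an
overflow guard.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

DIV_EPS = 1e-12
EXP_CLAMP = 50.0
_CLIP = 1e100

BINARY_OPS = ("add", "sub", "mul", "div")
UNARY_OPS = ("exp",)
_SYMBOL = {"add": "+", "sub": "-", "mul": "*", "div": "/"}


@dataclass(frozen=True)
class GPConfig:
    population: int = 180
    generations: int = 180
    operators: tuple = BINARY_OPS + UNARY_OPS
    max_genes: int = 8
    max_depth: int = 5
    crossover_rate: float = 0.85
    mutation_rate: float = 0.1
    tournament_size: int = 4
    constant_range: tuple = (-10.0, 10.0)
    constant_prob: float = 0.2   # chance a terminal is a constant
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class MultiGeneModel:
    genes: list
    weights: np.ndarray
    bias: float
    variable_names: list[str]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if self.weights.size != len(self.genes):
            raise ValueError("one weight per gene required")
        if not (np.all(np.isfinite(self.weights)) and np.isfinite(self.bias)):
            raise ValueError("non-finite model parameters")

    def to_json(self) -> str:
        return json.dumps({
            "genes": self.genes,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "variable_names": self.variable_names,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MultiGeneModel":
        obj = json.loads(text)

        def tupleize(node):
            if node[0] == "op":
                return ("op", node[1], *[tupleize(c) for c in node[2:]])
            return (node[0], node[1])

        return cls(
            genes=[tupleize(g) for g in obj["genes"]],
            weights=np.asarray(obj["weights"], float),
            bias=float(obj["bias"]),
            variable_names=list(obj["variable_names"]),
        )


# ---------------------------------------------------------------- evaluation

def _eval_node(node, X: np.ndarray) -> np.ndarray:
    kind = node[0]
    if kind == "const":
        return np.full(X.shape[0], float(node[1]))
    if kind == "var":
        return X[:, node[1]]
    op = node[1]
    if op == "exp":
        a = _eval_node(node[2], X)
        return np.exp(np.minimum(a, EXP_CLAMP))
    a = _eval_node(node[2], X)
    b = _eval_node(node[3], X)
    if op == "add":
        out = a + b
    elif op == "sub":
        out = a - b
    elif op == "mul":
        out = a * b
    elif op == "div":
        out = np.where(np.abs(b) < DIV_EPS, 1.0, a / np.where(np.abs(b) < DIV_EPS, 1.0, b))
    else:
        raise ValueError(f"unknown operator {op!r}")
    return np.clip(out, -_CLIP, _CLIP)


def eval_tree(tree, row) -> float:
    """Evaluate one gene tree at a single variable assignment.

    *row* maps variable names (or indices) to values; unbound variables
    raise KeyError.
    """
    def rec(node):
        kind = node[0]
        if kind == "const":
            return float(node[1])
        if kind == "var":
            idx = node[1]
            if isinstance(row, dict):
                if idx not in row:
                    raise KeyError(f"unbound variable {idx!r}")
                return float(row[idx])
            return float(row[idx])
        op = node[1]
        if op == "exp":
            return float(np.exp(min(rec(node[2]), EXP_CLAMP)))
        a, b = rec(node[2]), rec(node[3])
        if op == "add":
            v = a + b
        elif op == "sub":
            v = a - b
        elif op == "mul":
            v = a * b
        elif op == "div":
            v = 1.0 if abs(b) < DIV_EPS else a / b
        else:
            raise ValueError(f"unknown operator {op!r}")
        return float(np.clip(v, -_CLIP, _CLIP))

    return rec(tree)


def eval_genes(genes, X: np.ndarray) -> np.ndarray:
    """Stack gene outputs into an n x k matrix."""
    X = np.asarray(X, float)
    return np.column_stack([_eval_node(g, X) for g in genes]) if genes else \
        np.empty((X.shape[0], 0))


def tree_depth(node) -> int:
    if node[0] in ("const", "var"):
        return 1
    return 1 + max(tree_depth(c) for c in node[2:])


def fit_gene_weights(genes, X, y, variable_names=None) -> MultiGeneModel:
    """Least-squares weights and bias for a fixed list of gene trees.

    Gene columns with non-finite output are dropped (weight pinned to 0);
    collinear gene outputs are resolved by the minimum-norm solution.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if y.size < len(genes) + 2:
        raise ValueError("need n >= number of genes + 2")
    G = eval_genes(genes, X)
    ok = np.all(np.isfinite(G), axis=0)
    A = np.column_stack([np.ones(y.size), G[:, ok]])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    weights = np.zeros(len(genes))
    weights[np.flatnonzero(ok)] = sol[1:]
    names = list(variable_names) if variable_names is not None else \
        [f"x{j+1}" for j in range(X.shape[1])]
    return MultiGeneModel(genes=list(genes), weights=weights, bias=float(sol[0]),
                          variable_names=names)


def predict_multigene(model: MultiGeneModel, X) -> np.ndarray:
    G = eval_genes(model.genes, np.asarray(X, float))
    G = np.where(np.isfinite(G), G, 0.0)
    return model.bias + G @ model.weights


# ---------------------------------------------------------------- generation

def _random_tree(rng, n_vars, config: GPConfig, depth: int, full: bool):
    if depth <= 1 or (not full and rng.random() < 0.3):
        if rng.random() < config.constant_prob:
            lo, hi = config.constant_range
            return ("const", float(rng.uniform(lo, hi)))
        return ("var", int(rng.integers(n_vars)))
    op = config.operators[int(rng.integers(len(config.operators)))]
    if op in UNARY_OPS:
        return ("op", op, _random_tree(rng, n_vars, config, depth - 1, full))
    return ("op", op,
            _random_tree(rng, n_vars, config, depth - 1, full),
            _random_tree(rng, n_vars, config, depth - 1, full))


def _all_nodes(tree, path=()):
    yield path, tree
    if tree[0] == "op":
        for i, child in enumerate(tree[2:]):
            yield from _all_nodes(child, path + (i + 2,))


def _replace_at(tree, path, subtree):
    if not path:
        return subtree
    i = path[0]
    children = list(tree)
    children[i] = _replace_at(tree[i], path[1:], subtree)
    return tuple(children)


def _subtree_crossover(rng, g1, g2, max_depth):
    paths1 = [p for p, _ in _all_nodes(g1)]
    paths2 = [p for p, _ in _all_nodes(g2)]
    p1 = paths1[int(rng.integers(len(paths1)))]
    p2 = paths2[int(rng.integers(len(paths2)))]
    sub2 = g2
    for i in p2:
        sub2 = sub2[i]
    child = _replace_at(g1, p1, sub2)
    return child if tree_depth(child) <= max_depth else g1


def _subtree_mutation(rng, gene, n_vars, config: GPConfig):
    paths = [p for p, _ in _all_nodes(gene)]
    p = paths[int(rng.integers(len(paths)))]
    new = _random_tree(rng, n_vars, config, depth=int(rng.integers(2, 4)), full=False)
    child = _replace_at(gene, p, new)
    return child if tree_depth(child) <= config.max_depth else gene


def _init_individual(rng, n_vars, config: GPConfig):
    n_genes = int(rng.integers(1, min(4, config.max_genes) + 1))
    genes = []
    for _ in range(n_genes):
        depth = int(rng.integers(2, 5))           # ramped depths 2-4
        full = bool(rng.integers(2))              # half-and-half
        genes.append(_random_tree(rng, n_vars, config, depth, full))
    return genes


def _fitness(genes, X, y):
    try:
        model = fit_gene_weights(genes, X, y)
    except (ValueError, np.linalg.LinAlgError):
        return np.inf, None
    pred = predict_multigene(model, X)
    if not np.all(np.isfinite(pred)):
        return np.inf, None
    return float(np.sqrt(np.mean((y - pred) ** 2))), model


def evolve(X, y, config: GPConfig | None = None, variable_names=None):
    """Evolve a multi-gene model; returns (best MultiGeneModel, fitness trace).

    The trace records the best training RMSD present in each generation;
    with one elite copied forward it is non-increasing.
    """
    config = config or GPConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if y.size < 4 or np.all(y == y[0]):
        raise ValueError("degenerate dataset")
    n_vars = X.shape[1]
    names = list(variable_names) if variable_names is not None else \
        [f"x{j+1}" for j in range(n_vars)]
    rng = np.random.default_rng(config.seed)

    pop = [_init_individual(rng, n_vars, config) for _ in range(config.population)]
    fits = [_fitness(g, X, y) for g in pop]
    trace = []
    best_i = int(np.argmin([f[0] for f in fits]))
    best_fit, best_model = fits[best_i]
    best_genes = pop[best_i]

    def tournament():
        idx = rng.integers(len(pop), size=config.tournament_size)
        return pop[min(idx, key=lambda i: fits[i][0])]

    for _ in range(config.generations):
        new_pop = [best_genes]                     # elitism 1
        while len(new_pop) < config.population:
            r = rng.random()
            if r < config.crossover_rate:
                pa, pb = tournament(), tournament()
                if rng.random() < 0.5 and (len(pa) > 1 or len(pb) > 1):
                    # gene-level two-point exchange
                    ca = int(rng.integers(len(pa) + 1))
                    cb = int(rng.integers(len(pb) + 1))
                    child = (pa[:ca] + pb[cb:])[: config.max_genes]
                    if not child:
                        child = list(pa)
                else:
                    child = list(pa)
                    gi = int(rng.integers(len(child)))
                    donor = pb[int(rng.integers(len(pb)))]
                    child[gi] = _subtree_crossover(rng, child[gi], donor, config.max_depth)
            elif r < config.crossover_rate + config.mutation_rate:
                child = list(tournament())
                gi = int(rng.integers(len(child)))
                child[gi] = _subtree_mutation(rng, child[gi], n_vars, config)
            else:
                child = list(tournament())
            new_pop.append(child)
        pop = new_pop
        fits = [_fitness(g, X, y) for g in pop]
        gen_best = int(np.argmin([f[0] for f in fits]))
        if fits[gen_best][0] < best_fit:
            best_fit, best_model = fits[gen_best]
            best_genes = pop[gen_best]
        trace.append(best_fit)

    if best_model is None:
        raise RuntimeError("evolution failed to produce a finite model")
    best_model.variable_names = names
    return best_model, trace


# ------------------------------------------------------------- serialization

def _fmt(v: float) -> str:
    if float(v) == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def _tree_to_text(node, names) -> str:
    kind = node[0]
    if kind == "const":
        v = float(node[1])
        return _fmt(v) if v >= 0 else f"({_fmt(v)})"
    if kind == "var":
        return names[node[1]]
    op = node[1]
    if op == "exp":
        return f"exp({_tree_to_text(node[2], names)})"
    a = _tree_to_text(node[2], names)
    b = _tree_to_text(node[3], names)
    return f"({a} {_SYMBOL[op]} {b})"


def serialize_expression(model: MultiGeneModel) -> str:
    """Render the model as an infix formula: bias + w1*(g1) + w2*(g2) + ..."""
    parts = [_fmt(model.bias)]
    for w, g in zip(model.weights, model.genes):
        parts.append(f"{_fmt(w)}*({_tree_to_text(g, model.variable_names)})")
    return " + ".join(parts)


_TOKEN = re.compile(r"\s*(exp|[A-Za-z_][A-Za-z_0-9]*|\d+\.?\d*(?:[eE][-+]?\d+)?|\*\*|[-+*/()])")


def parse_expression(text: str, variable_names) -> tuple:
    """Parse an infix formula back into a single expression tree.

    The grammar covers exactly what :func:`serialize_expression` emits
    (numbers, named variables, + - * /, exp(...), parentheses, unary minus);
    the whole formula comes back as one tree whose evaluation reproduces
    the model's predictions.
    """
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip() == "":
                break
            raise ValueError(f"cannot tokenize {text[pos:pos+10]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    var_index = {n: i for i, n in enumerate(variable_names)}
    it = {"i": 0}

    def peek():
        return tokens[it["i"]] if it["i"] < len(tokens) else None

    def take():
        tok = peek()
        it["i"] += 1
        return tok

    def expr():
        node = term()
        while peek() in ("+", "-"):
            op = take()
            rhs = term()
            node = ("op", "add" if op == "+" else "sub", node, rhs)
        return node

    def term():
        node = factor()
        while peek() in ("*", "/"):
            op = take()
            rhs = factor()
            node = ("op", "mul" if op == "*" else "div", node, rhs)
        return node

    def factor():
        tok = take()
        if tok == "-":
            return ("op", "sub", ("const", 0.0), factor())
        if tok == "+":
            return factor()
        if tok == "(":
            node = expr()
            if take() != ")":
                raise ValueError("unbalanced parentheses")
            return node
        if tok == "exp":
            if take() != "(":
                raise ValueError("exp requires parentheses")
            node = expr()
            if take() != ")":
                raise ValueError("unbalanced parentheses")
            return ("op", "exp", node)
        if tok is None:
            raise ValueError("unexpected end of formula")
        if tok in var_index:
            return ("var", var_index[tok])
        try:
            return ("const", float(tok))
        except ValueError:
            raise ValueError(f"unknown variable {tok!r}") from None

    tree = expr()
    if it["i"] != len(tokens):
        raise ValueError("trailing tokens in formula")
    return tree
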