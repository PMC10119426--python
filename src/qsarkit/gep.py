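"""Gene expression programming over a fixed seven-function set.

Genotypes are fixed-length Karva strings (head + tail per gene, optional
multigene chromosomes joined by a linking function); phenotypes are
expression trees decoded breadth-first.  The function set is
``+ - * / Inv Cos Tan`` with terminals ``d0 ... d{k-1}``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FUNCTIONS",
    "MAX_ARITY",
    "Chromosome",
    "Node",
    "EvolutionConfig",
    "EvolutionResult",
    "tail_length",
    "decode_karva",
    "encode_karva",
    "tree_to_infix",
    "evaluate_tree",
    "evaluate_chromosome",
    "fitness",
    "select_elite_roulette",
    "mutate",
    "recombine_one_point",
    "recombine_two_point",
    "recombine_gene",
    "transpose_is",
    "transpose_ris",
    "transpose_gene",
    "random_chromosome",
    "evolve",
    "parse_model_expression",
    "REFERENCE_GEP_MODEL",
    "TERMINAL_BINDING",
]

FUNCTIONS: dict[str, int] = {
    "+": 2,
    "-": 2,
    "*": 2,
    "/": 2,
    "Inv": 1,
    "Cos": 1,
    "Tan": 1,
}
MAX_ARITY = 2

SATURATION = 1e6
GUARD_EPS = 1e-12

# Reference terminal assignment for the five-descriptor activity models.
TERMINAL_BINDING = {
    "d0": "MREB",
    "d1": "NN",
    "d2": "YZS/YZR",
    "d3": "MPCO(ZPC)",
    "d4": "MSEC",
}

# Shipped reconstruction of the literature GEP activity model.  The source
# prints this expression without parentheses; it is parsed here under the
# package's documented convention (unary functions bind tighter than binary
# operators, * and / over + and -, left association).  The reconstruction is
# one reading, not asserted to be the only one.
REFERENCE_GEP_MODEL = (
    "Cosd0*d2+Tand0+Tand3*d3*d0-d0+d3/Cos1/d3/d0+d3*d3"
    "+TanTanTanTanCosd4/d1/d2+TanTanTanTanTand0+d0/d2"
)


def tail_length(h: int, n_max: int = MAX_ARITY) -> int:
    """Karva tail length ``t = h * (n_max - 1) + 1``."""
    if h < 1 or n_max < 1:
        raise ValueError("head length and max arity must be >= 1")
    return h * (n_max - 1) + 1


def terminal_symbols(n_terminals: int) -> list[str]:
    return [f"d{i}" for i in range(n_terminals)]


@dataclass
class Chromosome:
    """Karva genotype: one or more equal-length genes (head + tail)."""

    genes: list[list[str]]
    head: int
    n_terminals: int = 5
    linking: str = "+"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def tail(self) -> int:
        return tail_length(self.head)

    @property
    def gene_length(self) -> int:
        return self.head + self.tail

    def flat(self) -> list[str]:
        return [s for g in self.genes for s in g]

    def validate(self) -> None:
        terms = set(terminal_symbols(self.n_terminals))
        glen = self.head + tail_length(self.head)
        if not self.genes:
            raise ValueError("chromosome has no genes")
        if self.linking not in FUNCTIONS or FUNCTIONS[self.linking] != 2:
            raise ValueError(f"linking function must be binary, got {self.linking!r}")
        for gi, gene in enumerate(self.genes):
            if len(gene) != glen:
                raise ValueError(
                    f"gene {gi}: length {len(gene)} != head+tail = {glen}"
                )
            for pos, sym in enumerate(gene):
                if pos < self.head:
                    if sym not in FUNCTIONS and sym not in terms:
                        raise ValueError(f"gene {gi} head position {pos}: unknown symbol {sym!r}")
                else:
                    if sym not in terms:
                        raise ValueError(
                            f"gene {gi} tail position {pos}: {sym!r} is not a terminal"
                        )

    def copy(self) -> "Chromosome":
        return replace(self, genes=[list(g) for g in self.genes])

    def __str__(self) -> str:
        return " | ".join("".join(g) for g in self.genes)


@dataclass
class Node:
    """Expression-tree node: a function symbol or a terminal/constant leaf."""

    symbol: str
    children: list["Node"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.symbol in FUNCTIONS:
            if len(self.children) != FUNCTIONS[self.symbol]:
                raise ValueError(
                    f"{self.symbol!r} expects {FUNCTIONS[self.symbol]} children, "
                    f"got {len(self.children)}"
                )
        elif self.children:
            raise ValueError(f"terminal {self.symbol!r} cannot have children")

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _decode_gene(gene: list[str], head: int) -> Node:
    arity = [FUNCTIONS.get(s, 0) for s in gene]
    if arity[0] and 0 >= head:
        raise ValueError("function symbol in tail")
    # level-order fill: queue of nodes awaiting children, cursor over symbols
    root = Node(gene[0], []) if arity[0] == 0 else None
    if root is not None:
        return root
    nodes = [[gene[0], []]]
    queue = [0]
    cursor = 1
    while queue:
        idx = queue.pop(0)
        need = FUNCTIONS[nodes[idx][0]]
        for _ in range(need):
            if cursor >= len(gene):
                raise ValueError("gene exhausted during decoding")
            sym = gene[cursor]
            if sym in FUNCTIONS and cursor >= head:
                raise ValueError(f"function symbol {sym!r} in tail position {cursor}")
            child_idx = len(nodes)
            nodes.append([sym, []])
            nodes[idx][1].append(child_idx)
            if sym in FUNCTIONS:
                queue.append(child_idx)
            cursor += 1

    def build(i: int) -> Node:
        sym, kids = nodes[i]
        return Node(sym, [build(k) for k in kids])

    return build(0)


def decode_karva(chromosome: Chromosome) -> Node:
    """Decode a chromosome breadth-first into its expression tree.

    Multigene chromosomes are joined left-to-right with the linking function.
    """
    trees = [_decode_gene(g, chromosome.head) for g in chromosome.genes]
    tree = trees[0]
    for t in trees[1:]:
        tree = Node(chromosome.linking, [tree, t])
    return tree


def encode_karva(tree: Node, head: int, n_terminals: int = 5) -> Chromosome:
    """Level-order serialize a tree into a single-gene chromosome.

    Raises if the tree does not fit: any function symbol would land in the
    tail, or the serialization exceeds the gene length.  Padding symbols
    (ignored by decoding) are ``d0``.
    """
    serial: list[str] = []
    queue = [tree]
    while queue:
        node = queue.pop(0)
        serial.append(node.symbol)
        queue.extend(node.children)
    t = tail_length(head)
    if len(serial) > head + t:
        raise ValueError("tree too large for the requested head length")
    for pos, sym in enumerate(serial):
        if sym in FUNCTIONS and pos >= head:
            raise ValueError("tree does not fit: function symbol lands in tail")
    pad = ["d0"] * (head + t - len(serial))
    gene = serial + pad
    # pad head positions must still be legal (terminals are)
    return Chromosome(genes=[gene], head=head, n_terminals=n_terminals)


def tree_to_infix(tree: Node) -> str:
    if tree.is_leaf:
        return tree.symbol
    if FUNCTIONS[tree.symbol] == 1:
        return f"{tree.symbol}({tree_to_infix(tree.children[0])})"
    a, b = (tree_to_infix(c) for c in tree.children)
    return f"({a} {tree.symbol} {b})"


# ---------------------------------------------------------------------------
# evaluation


def _saturate(x: np.ndarray) -> np.ndarray:
    x = np.where(np.isnan(x), SATURATION, x)
    return np.clip(x, -SATURATION, SATURATION)


def _apply(symbol: str, args: list[np.ndarray]) -> np.ndarray:
    with np.errstate(all="ignore"):
        if symbol == "+":
            out = args[0] + args[1]
        elif symbol == "-":
            out = args[0] - args[1]
        elif symbol == "*":
            out = args[0] * args[1]
        elif symbol == "/":
            den = np.where(np.abs(args[1]) < GUARD_EPS, np.nan, args[1])
            out = args[0] / den
        elif symbol == "Inv":
            den = np.where(np.abs(args[0]) < GUARD_EPS, np.nan, args[0])
            out = 1.0 / den
        elif symbol == "Cos":
            out = np.cos(args[0])
        elif symbol == "Tan":
            out = np.tan(args[0])
        else:  # pragma: no cover - guarded by Node validation
            raise ValueError(f"unknown function {symbol!r}")
    return _saturate(out)


def _postfix(tree: Node) -> list[str]:
    out: list[str] = []
    stack = [(tree, False)]
    while stack:
        node, done = stack.pop()
        if done or node.is_leaf:
            out.append(node.symbol)
        else:
            stack.append((node, True))
            for c in reversed(node.children):
                stack.append((c, False))
    return out


def evaluate_tree(tree: Node, binding: dict[str, float | np.ndarray]) -> float | np.ndarray:
    """Evaluate a tree at a terminal binding (scalars or equal-length arrays).

    Singularities of ``/``, ``Inv`` are guarded; all intermediates saturate
    at +/-1e6 so ``Tan`` cannot overflow the evolution loop.
    """
    stack: list[np.ndarray] = []
    for sym in _postfix(tree):
        if sym in FUNCTIONS:
            arity = FUNCTIONS[sym]
            args = stack[-arity:]
            del stack[-arity:]
            stack.append(_apply(sym, args))
        else:
            if sym in binding:
                val = np.asarray(binding[sym], dtype=float)
            else:
                try:
                    val = np.asarray(float(sym))
                except ValueError:
                    raise KeyError(f"unbound terminal {sym!r}") from None
            stack.append(val)
    result = stack[0]
    return float(result) if result.ndim == 0 else result


def evaluate_chromosome(chromosome: Chromosome, X: np.ndarray) -> np.ndarray:
    """Evaluate a chromosome on a data matrix (columns = terminals d0, d1, ...)."""
    X = np.asarray(X, dtype=float)
    binding = {f"d{i}": X[:, i] for i in range(X.shape[1])}
    out = evaluate_tree(decode_karva(chromosome), binding)
    if np.ndim(out) == 0:
        out = np.full(X.shape[0], float(out))
    return out


def fitness(predictions, y, spec: str = "rmse") -> float:
    """Fitness of a prediction vector: ``1000/(1+RMSE)`` or squared Pearson r."""
    predictions = np.asarray(predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    if predictions.shape != y.shape:
        raise ValueError("predictions and y must have equal length")
    if spec == "rmse":
        rmse = float(np.sqrt(np.mean((predictions - y) ** 2)))
        return 1000.0 / (1.0 + rmse)
    if spec == "correlation":
        if np.ptp(y) < 1e-300:
            raise ValueError("zero-variance response under correlation fitness")
        if np.ptp(predictions) < 1e-300:
            return 0.0
        r = float(np.corrcoef(predictions, y)[0, 1])
        return r * r if np.isfinite(r) else 0.0
    raise ValueError(f"unknown fitness spec {spec!r}")


# ---------------------------------------------------------------------------
# selection and genetic operators


def select_elite_roulette(
    population: list[Chromosome],
    fitnesses,
    elitism: int,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Elite-roulette parent selection.

    The ``elitism`` best individuals are copied unchanged; the remaining slots
    are sampled with replacement, probability proportional to fitness.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    if np.any(fitnesses < 0):
        raise ValueError("fitnesses must be >= 0")
    n = len(population)
    elitism = min(elitism, n)
    order = np.argsort(-fitnesses, kind="stable")
    out = [population[i].copy() for i in order[:elitism]]
    total = fitnesses.sum()
    if total <= 0:
        warnings.warn("all-zero fitness: falling back to uniform selection")
        probs = np.full(n, 1.0 / n)
    else:
        probs = fitnesses / total
    idx = rng.choice(n, size=n - elitism, p=probs)
    out.extend(population[i].copy() for i in idx)
    return out


def _random_symbol(head_pos: bool, terms: list[str], rng: np.random.Generator) -> str:
    if head_pos and rng.random() < 0.5:
        funcs = list(FUNCTIONS)
        return funcs[rng.integers(len(funcs))]
    return terms[rng.integers(len(terms))]


def mutate(chromosome: Chromosome, rate: float, rng: np.random.Generator) -> Chromosome:
    """Point mutation: head positions draw any symbol, tail positions terminals."""
    out = chromosome.copy()
    terms = terminal_symbols(out.n_terminals)
    for gene in out.genes:
        for pos in range(len(gene)):
            if rng.random() < rate:
                gene[pos] = _random_symbol(pos < out.head, terms, rng)
    out.validate()
    return out


def _flat_to_genes(flat: list[str], template: Chromosome) -> list[list[str]]:
    glen = template.gene_length
    return [flat[i * glen : (i + 1) * glen] for i in range(len(template.genes))]


def recombine_one_point(
    a: Chromosome, b: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Exchange everything after a random cut point in the flattened strings."""
    fa, fb = a.flat(), b.flat()
    cut = int(rng.integers(1, len(fa)))
    na = fa[:cut] + fb[cut:]
    nb = fb[:cut] + fa[cut:]
    return (
        replace(a, genes=_flat_to_genes(na, a)),
        replace(b, genes=_flat_to_genes(nb, b)),
    )


def recombine_two_point(
    a: Chromosome, b: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    fa, fb = a.flat(), b.flat()
    i, j = sorted(rng.choice(len(fa) + 1, size=2, replace=False))
    na = fa[:i] + fb[i:j] + fa[j:]
    nb = fb[:i] + fa[i:j] + fb[j:]
    return (
        replace(a, genes=_flat_to_genes(na, a)),
        replace(b, genes=_flat_to_genes(nb, b)),
    )


def recombine_gene(
    a: Chromosome, b: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Swap one whole gene between two chromosomes."""
    gi = int(rng.integers(len(a.genes)))
    na = [list(g) for g in a.genes]
    nb = [list(g) for g in b.genes]
    na[gi], nb[gi] = nb[gi], na[gi]
    return replace(a, genes=na), replace(b, genes=nb)


def transpose_is(
    chromosome: Chromosome, rng: np.random.Generator, max_len: int = 3
) -> Chromosome:
    """Insertion-sequence transposition: copy a random fragment into the head
    of a random gene (never at the root), truncating the head to length."""
    out = chromosome.copy()
    if out.head < 2:
        return out
    flat = out.flat()
    length = int(rng.integers(1, max_len + 1))
    start = int(rng.integers(0, len(flat) - length + 1))
    seq = flat[start : start + length]
    gi = int(rng.integers(len(out.genes)))
    target = int(rng.integers(1, out.head))
    gene = out.genes[gi]
    head = gene[: out.head]
    new_head = head[:target] + seq + head[target:]
    out.genes[gi] = new_head[: out.head] + gene[out.head :]
    out.validate()
    return out


def transpose_ris(
    chromosome: Chromosome, rng: np.random.Generator, max_len: int = 3
) -> Chromosome:
    """Root-insertion-sequence transposition: a fragment starting at a
    function symbol in the head is copied to the gene root."""
    out = chromosome.copy()
    gi = int(rng.integers(len(out.genes)))
    gene = out.genes[gi]
    start_scan = int(rng.integers(0, out.head))
    fstart = next(
        (p for p in range(start_scan, out.head) if gene[p] in FUNCTIONS), None
    )
    if fstart is None:
        return out
    length = int(rng.integers(1, max_len + 1))
    seq = gene[fstart : min(fstart + length, out.head + out.tail)]
    head = gene[: out.head]
    new_head = (seq + head)[: out.head]
    out.genes[gi] = new_head + gene[out.head :]
    out.validate()
    return out


def transpose_gene(chromosome: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Move a randomly chosen gene (other than the first) to the front."""
    out = chromosome.copy()
    if len(out.genes) < 2:
        return out
    gi = int(rng.integers(1, len(out.genes)))
    gene = out.genes.pop(gi)
    out.genes.insert(0, gene)
    out.validate()
    return out


def random_chromosome(
    head: int, n_genes: int, n_terminals: int, rng: np.random.Generator
) -> Chromosome:
    terms = terminal_symbols(n_terminals)
    t = tail_length(head)
    genes = []
    for _ in range(n_genes):
        gene = [_random_symbol(True, terms, rng) for _ in range(head)]
        gene += [terms[rng.integers(len(terms))] for _ in range(t)]
        genes.append(gene)
    return Chromosome(genes=genes, head=head, n_terminals=n_terminals)


# ---------------------------------------------------------------------------
# evolution


@dataclass
class EvolutionConfig:
    population: int = 500
    generations: int = 200
    head: int = 10
    n_genes: int = 1
    n_terminals: int = 5
    linking: str = "+"
    mutation_rate: float = 0.044
    one_point_rate: float = 0.3
    two_point_rate: float = 0.3
    gene_recomb_rate: float = 0.1
    is_rate: float = 0.1
    ris_rate: float = 0.1
    gene_transp_rate: float = 0.1
    elitism: int = 1
    fitness_spec: str = "rmse"
    stop_fitness: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name in (
            "mutation_rate",
            "one_point_rate",
            "two_point_rate",
            "gene_recomb_rate",
            "is_rate",
            "ris_rate",
            "gene_transp_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class EvolutionResult:
    best: Chromosome
    best_fitness: float
    history: list[float]
    mean_history: list[float]

    @property
    def tree(self) -> Node:
        return decode_karva(self.best)

    def to_dict(self) -> dict:
        return {
            "genes": ["".join(" " + s if s.startswith("d") else s for s in g).strip()
                      for g in self.best.genes],
            "gene_symbols": [list(g) for g in self.best.genes],
            "head": self.best.head,
            "linking": self.best.linking,
            "infix": tree_to_infix(self.tree),
            "best_fitness": float(self.best_fitness),
            "history": [float(h) for h in self.history],
        }


def evolve(X, y, config: EvolutionConfig) -> EvolutionResult:
    """Run the GEP loop: initialize, express, evaluate, select, operate, iterate.

    Deterministic for a fixed seed and config; with elitism >= 1 the
    best-so-far fitness history is non-decreasing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y) or X.shape[0] < 2:
        raise ValueError("X must be 2D with >= 2 rows matching y")
    if X.shape[1] < config.n_terminals:
        raise ValueError(
            f"X has {X.shape[1]} columns but config binds {config.n_terminals} terminals"
        )
    rng = np.random.default_rng(config.seed)
    pop = [
        random_chromosome(config.head, config.n_genes, config.n_terminals, rng)
        for _ in range(config.population)
    ]
    for c in pop:
        c.linking = config.linking

    def evaluate(c: Chromosome) -> float:
        return fitness(evaluate_chromosome(c, X), y, config.fitness_spec)

    best: Chromosome | None = None
    best_fit = -np.inf
    history: list[float] = []
    mean_history: list[float] = []
    for _gen in range(config.generations):
        fits = np.array([evaluate(c) for c in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best = pop[gen_best].copy()
        history.append(best_fit)
        mean_history.append(float(fits.mean()))
        if config.stop_fitness is not None and best_fit >= config.stop_fitness:
            break
        parents = select_elite_roulette(pop, fits, config.elitism, rng)
        elite = parents[: config.elitism]
        rest = parents[config.elitism :]
        rest = [mutate(c, config.mutation_rate, rng) for c in rest]
        for i in range(len(rest)):
            if rng.random() < config.is_rate:
                rest[i] = transpose_is(rest[i], rng)
            if rng.random() < config.ris_rate:
                rest[i] = transpose_ris(rest[i], rng)
            if config.n_genes > 1 and rng.random() < config.gene_transp_rate:
                rest[i] = transpose_gene(rest[i], rng)
        order = rng.permutation(len(rest))
        for a, b in zip(order[0::2], order[1::2]):
            roll = rng.random()
            if roll < config.one_point_rate:
                rest[a], rest[b] = recombine_one_point(rest[a], rest[b], rng)
            elif roll < config.one_point_rate + config.two_point_rate:
                rest[a], rest[b] = recombine_two_point(rest[a], rest[b], rng)
            elif (
                config.n_genes > 1
                and roll < config.one_point_rate + config.two_point_rate + config.gene_recomb_rate
            ):
                rest[a], rest[b] = recombine_gene(rest[a], rest[b], rng)
        pop = elite + rest
    assert best is not None
    return EvolutionResult(
        best=best, best_fitness=best_fit, history=history, mean_history=mean_history
    )


# ---------------------------------------------------------------------------
# expression parsing


class _Tokenizer:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, str, int]] = []
        self._run()

    def _run(self) -> None:
        text = self.text
        i = 0
        n = len(text)
        funcs = sorted((f for f in FUNCTIONS if f.isalpha()), key=len, reverse=True)
        while i < n:
            ch = text[i]
            if ch.isspace():
                i += 1
                continue
            if ch in "+-*/()":
                kind = "op" if ch in "+-*/" else ch
                self.tokens.append((kind, ch, i))
                i += 1
                continue
            matched = False
            for f in funcs:
                if text.startswith(f, i):
                    self.tokens.append(("func", f, i))
                    i += len(f)
                    matched = True
                    break
            if matched:
                continue
            if ch == "d":
                j = i + 1
                # accept d0, d[0], d(0)
                open_br = None
                if j < n and text[j] in "[(":
                    open_br = text[j]
                    j += 1
                k = j
                while k < n and text[k].isdigit():
                    k += 1
                if k == j:
                    raise ValueError(f"cannot tokenize at position {i}: {text[i:i+8]!r}")
                idx = text[j:k]
                if open_br:
                    close = "]" if open_br == "[" else ")"
                    if k >= n or text[k] != close:
                        raise ValueError(f"unclosed terminal index at position {i}")
                    k += 1
                self.tokens.append(("term", f"d{idx}", i))
                i = k
                continue
            if ch.isdigit() or ch == ".":
                j = i
                while j < n and (text[j].isdigit() or text[j] == "."):
                    j += 1
                self.tokens.append(("num", text[i:j], i))
                i = j
                continue
            raise ValueError(f"cannot tokenize at position {i}: {text[i:i+8]!r}")


def parse_model_expression(text: str) -> Node:
    """Parse an infix expression over the function set into a tree.

    Convention (documented, configur-able only by rewriting the text): unary
    functions bind tighter than binary operators and apply to the immediately
    following unary expression (``Cosd0*d2`` is ``Cos(d0)*d2``,
    ``TanTand0`` is ``Tan(Tan(d0))``); ``*``/``/`` bind tighter than
    ``+``/``-``; binary operators associate left.
    """
    tokens = _Tokenizer(text).tokens
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None, None)

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> Node:
        node = parse_term()
        while peek()[0] == "op" and peek()[1] in "+-":
            op = take()[1]
            node = Node(op, [node, parse_term()])
        return node

    def parse_term() -> Node:
        node = parse_unary()
        while peek()[0] == "op" and peek()[1] in "*/":
            op = take()[1]
            node = Node(op, [node, parse_unary()])
        return node

    def parse_unary() -> Node:
        kind, val, at = peek()
        if kind == "func":
            take()
            return Node(val, [parse_unary()])
        if kind == "op" and val == "-":
            take()
            return Node("-", [Node("0"), parse_unary()])
        return parse_primary()

    def parse_primary() -> Node:
        kind, val, at = take() if pos < len(tokens) else (None, None, None)
        if kind in ("term", "num"):
            return Node(val)
        if kind == "(":
            node = parse_expr()
            k, v, a = take() if pos < len(tokens) else (None, None, None)
            if k != ")":
                raise ValueError(f"expected ')' at position {a}")
            return node
        raise ValueError(f"unexpected token {val!r} at position {at}")

    tree = parse_expr()
    if pos != len(tokens):
        raise ValueError(f"trailing input at position {tokens[pos][2]}")
    return tree


def save_model_json(result: EvolutionResult, path, extra: dict | None = None) -> None:
    payload = result.to_dict()
    payload["terminal_binding"] = dict(TERMINAL_BINDING)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
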