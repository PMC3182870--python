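"""Synthetic benchmark generator: random networks with planted, logic-encoding
modules, so the whole pipeline is testable without any external cohort.

A scenario plants one or more connected gene modules inside a random
background network. Each planted gene has a latent binary up/down state per
sample; the class label is a specified Boolean function of those states, and
observed expression is ``baseline + effect_size * state + N(0, 1)``, with
uninformative noise genes drawn as pure ``N(0, 1)``. The effect size is thus
the mean up-vs-down expression shift in units of the noise standard
deviation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .dataset import LabeledExpression, derive_rng
from .graph_io import ProteinNetwork, write_network
from .dataset import write_expression

__all__ = [
    "BooleanFunction",
    "ModuleSpec",
    "PlantedScenario",
    "generate",
    "write_scenario",
    "load_ground_truth",
    "and_not_scenario",
    "two_module_scenario",
]


# ---------------------------------------------------------------------------
# Tiny Boolean expression language: NAME, AND, OR, NOT, parentheses.


class BooleanFunction:
    """Boolean function over gene up/down states, parsed from a string like
    ``"A AND NOT B"``. A bare gene name means "that gene is up"."""

    def __init__(self, expression: str):
        self.expression = expression
        self._ast = _parse(_tokenize(expression))
        self.genes = sorted(_names(self._ast))

    def __call__(self, states: dict[str, bool]) -> bool:
        return _eval(self._ast, states)

    def truth_table(self) -> list[tuple[dict[str, bool], bool]]:
        rows = []
        for bits in itertools.product([False, True], repeat=len(self.genes)):
            assignment = dict(zip(self.genes, bits))
            rows.append((assignment, self(assignment)))
        return rows

    def __repr__(self) -> str:
        return f"BooleanFunction({self.expression!r})"


def _tokenize(s: str) -> list[str]:
    out, i = [], 0
    while i < len(s):
        ch = s[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            out.append(ch)
            i += 1
        else:
            j = i
            while j < len(s) and not s[j].isspace() and s[j] not in "()":
                j += 1
            out.append(s[i:j])
            i = j
    return out


def _parse(tokens: list[str]):
    pos = [0]

    def peek():
        return tokens[pos[0]] if pos[0] < len(tokens) else None

    def eat(tok=None):
        t = peek()
        if t is None or (tok is not None and t != tok):
            raise ValueError(f"boolean expression syntax error near token {pos[0]} ({t!r})")
        pos[0] += 1
        return t

    def expr():
        node = term()
        while peek() == "OR":
            eat("OR")
            node = ("or", node, term())
        return node

    def term():
        node = factor()
        while peek() == "AND":
            eat("AND")
            node = ("and", node, factor())
        return node

    def factor():
        if peek() == "NOT":
            eat("NOT")
            return ("not", factor())
        if peek() == "(":
            eat("(")
            node = expr()
            eat(")")
            return node
        name = eat()
        if name in ("AND", "OR", "NOT", ")"):
            raise ValueError(f"unexpected token {name!r} in boolean expression")
        return ("var", name)

    node = expr()
    if pos[0] != len(tokens):
        raise ValueError(f"trailing tokens in boolean expression: {tokens[pos[0]:]}")
    return node


def _eval(node, states: dict[str, bool]) -> bool:
    op = node[0]
    if op == "var":
        return bool(states[node[1]])
    if op == "not":
        return not _eval(node[1], states)
    if op == "and":
        return _eval(node[1], states) and _eval(node[2], states)
    return _eval(node[1], states) or _eval(node[2], states)


def _names(node) -> set[str]:
    if node[0] == "var":
        return {node[1]}
    return set().union(*(_names(c) for c in node[1:]))


# ---------------------------------------------------------------------------
# Scenario specification


@dataclass
class ModuleSpec:
    genes: list[str]
    function: str  # boolean expression over the module genes
    effect_size: float = 3.0  # mean shift in units of noise SD

    def __post_init__(self):
        fn = BooleanFunction(self.function)
        extra = set(fn.genes) - set(self.genes)
        if extra:
            raise ValueError(f"function references genes outside the module: {sorted(extra)}")
        if self.effect_size <= 0 and self.effect_size != 0.0:
            raise ValueError("effect size must be >= 0")


@dataclass
class PlantedScenario:
    """Study conditions for one synthetic benchmark.

    ``n_per_class`` fixes exact class sizes by conditioning the latent states
    on the label (the default benchmark); set it to None to draw
    ``n_samples`` samples with unconditioned Bernoulli(0.5) states. When
    several modules are planted, the sample label is the OR of the module
    functions.
    """

    modules: list[ModuleSpec]
    n_noise_genes: int = 30
    n_per_class: dict[str, int] | None = field(default_factory=lambda: {"control": 100, "target": 100})
    n_samples: int = 200
    background_density: float = 0.2
    background_model: str = "erdos-renyi"  # or "scale-free"
    min_module_degree: int = 5
    state_correlation: float = 0.0  # within-module latent-state coupling
    baseline: float = 0.0
    target_label: str = "target"
    control_label: str = "control"
    seed: int = 0


def _build_network(scenario: PlantedScenario, rng: np.random.Generator) -> ProteinNetwork:
    noise = [f"N{i:03d}" for i in range(scenario.n_noise_genes)]
    g = nx.Graph()
    g.add_nodes_from(noise)
    if scenario.background_model == "scale-free":
        m = max(1, int(round(scenario.background_density * scenario.n_noise_genes / 2)))
        bg = nx.barabasi_albert_graph(scenario.n_noise_genes, m, seed=int(rng.integers(2**31)))
        g.add_edges_from((noise[a], noise[b]) for a, b in bg.edges)
    else:
        bg = nx.erdos_renyi_graph(
            scenario.n_noise_genes, scenario.background_density, seed=int(rng.integers(2**31))
        )
        g.add_edges_from((noise[a], noise[b]) for a, b in bg.edges)
    for spec in scenario.modules:
        # plant the module as a clique (connected by construction) ...
        for a, b in itertools.combinations(spec.genes, 2):
            g.add_edge(a, b)
        # ... and pad each planted gene up to the root-eligibility degree
        for gene in spec.genes:
            deficit = scenario.min_module_degree - g.degree[gene]
            if deficit > 0:
                pool = [x for x in noise if not g.has_edge(gene, x)]
                picks = rng.choice(len(pool), size=min(deficit, len(pool)), replace=False)
                for i in picks:
                    g.add_edge(gene, pool[i])
    return ProteinNetwork.from_graph(g)


def _draw_states(
    module_genes: list[list[str]], scenario: PlantedScenario, rng: np.random.Generator
) -> dict[str, bool]:
    states: dict[str, bool] = {}
    for genes in module_genes:
        shared = bool(rng.integers(2))
        for g in genes:
            if scenario.state_correlation > 0 and rng.random() < scenario.state_correlation:
                states[g] = shared
            else:
                states[g] = bool(rng.integers(2))
    return states


def generate(scenario: PlantedScenario) -> tuple[ProteinNetwork, LabeledExpression, dict]:
    """Materialize a scenario: network, labeled expression and ground truth."""
    rng = derive_rng(scenario.seed, "synthetic")
    net = _build_network(scenario, rng)
    functions = [BooleanFunction(m.function) for m in scenario.modules]
    module_genes = [m.genes for m in scenario.modules]
    all_planted = [g for m in scenario.modules for g in m.genes]
    noise = [f"N{i:03d}" for i in range(scenario.n_noise_genes)]
    genes = all_planted + noise

    def label_of(states: dict[str, bool]) -> str:
        out = any(fn(states) for fn in functions)
        return scenario.target_label if out else scenario.control_label

    samples_states: list[dict[str, bool]] = []
    labels: list[str] = []
    if scenario.n_per_class is None:
        for _ in range(scenario.n_samples):
            st = _draw_states(module_genes, scenario, rng)
            samples_states.append(st)
            labels.append(label_of(st))
        if len(set(labels)) < 2:
            raise ValueError("unconditioned draw produced a single class; increase n_samples")
    else:
        for cls, n in scenario.n_per_class.items():
            for _ in range(n):
                for _attempt in range(10000):
                    st = _draw_states(module_genes, scenario, rng)
                    if label_of(st) == cls:
                        break
                else:
                    raise ValueError(f"could not draw a sample of class {cls!r}; is the function constant?")
                samples_states.append(st)
                labels.append(cls)

    n = len(labels)
    values = rng.normal(0.0, 1.0, size=(len(genes), n))
    for gi, g in enumerate(all_planted):
        spec = next(m for m in scenario.modules if g in m.genes)
        shift = np.array([float(st[g]) for st in samples_states]) * spec.effect_size
        values[gi] += scenario.baseline + shift

    data = LabeledExpression(
        genes=genes,
        samples=[f"S{i:04d}" for i in range(n)],
        values=values,
        labels=np.array(labels, dtype=object),
        target_class=scenario.target_label,
    )
    truth = {
        "target_class": scenario.target_label,
        "noise_genes": noise,
        "modules": [
            {
                "genes": m.genes,
                "function": m.function,
                "effect_size": m.effect_size,
                "pairs": [sorted(p) for p in itertools.combinations(m.genes, 2)],
                "truth_table": [
                    {
                        "states": {g: ("up" if v else "down") for g, v in assign.items()},
                        "output": scenario.target_label if out else scenario.control_label,
                    }
                    for assign, out in BooleanFunction(m.function).truth_table()
                ],
            }
            for m in scenario.modules
        ],
    }
    return net, data, truth


def write_scenario(scenario: PlantedScenario, out_dir: str | Path) -> dict:
    """Generate and write edges.tsv, expr.tsv, labels.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, data, truth = generate(scenario)
    write_network(net, out / "edges.tsv")
    write_expression(data, out / "expr.tsv", out / "labels.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def load_ground_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def and_not_scenario(
    seed: int = 0,
    effect_size: float = 3.0,
    n_per_class: int = 100,
    n_noise_genes: int = 30,
) -> PlantedScenario:
    """Canonical benchmark: one planted pair encoding "A AND NOT B"
    (target phenotype = A up and B down), balanced classes."""
    return PlantedScenario(
        modules=[ModuleSpec(genes=["A", "B"], function="A AND NOT B", effect_size=effect_size)],
        n_noise_genes=n_noise_genes,
        n_per_class={"control": n_per_class, "target": n_per_class},
        seed=seed,
    )


def two_module_scenario(seed: int = 0, effect_size: float = 3.0, n_per_class: int = 100) -> PlantedScenario:
    """Two planted modules in disjoint network regions with distinct logic."""
    return PlantedScenario(
        modules=[
            ModuleSpec(genes=["A1", "A2", "A3"], function="A1 AND A2 AND NOT A3", effect_size=effect_size),
            ModuleSpec(genes=["B1", "B2"], function="NOT B1 AND NOT B2", effect_size=effect_size),
        ],
        n_noise_genes=40,
        n_per_class={"control": n_per_class, "target": n_per_class},
        seed=seed,
    )
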