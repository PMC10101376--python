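"""Semantic-network knowledge bases as human-readable text files.

A knowledge base is a directory containing a ``node_list`` file (one node
name per line, defining processing precedence for ties) plus one attribute
file per node.  Each attribute occupies a single line::

    LeftOf spine 50 100            # relational attribute with a range in mm
    IntensityRange 300 2000        # segmentation parameter (HU)
    XSectionAreaFuzzy 100 0.0 500 1.0   # fuzzy vertices: value/confidence pairs
    NeuralNet_LearningRate 1.0 -2 {45, 46, -5, -2}

Tokens are whitespace separated; ``#`` starts a comment; a scalar may carry a
``cm`` suffix (converted to mm at parse time).  A ``{start_bit, end_bit,
lower, upper}`` group immediately following a numeric token marks that
parameter as tunable: the bit range of a binary chromosome decodes to a value
between the bounds (see :mod:`cognimage.genome`).

Attribute names are drawn from a vocabulary (data, not code) that fixes each
attribute's parameter arity and category; the default vocabulary ships with
the package and can be extended by the user.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import networkx as nx
import yaml

from .fuzzy import FuzzyFunction

__all__ = [
    "AttributeDefinition", "ValueEncoding", "Attribute", "SNNode",
    "SemanticNetwork", "Vocabulary", "KBParseError", "load_vocabulary",
    "parse_network", "write_network", "list_tunable_parameters",
    "summarize_graph",
]

NODE_LIST_FILENAME = "node_list"

#: category -> agent family responsible for acting on the attribute
CATEGORY_FAMILY = {
    "segmentation-param": "segmentation",
    "preprocessing": "segmentation",
    "unary-feature": "reasoning",
    "relational-feature": "reasoning",
    "decision": "reasoning",
    "learning": "knowledge",
}

PARAM_KINDS = {"node", "scalar", "vertices", "nodes", "word"}


class KBParseError(ValueError):
    """Raised for any structural error in a knowledge-base file."""


@dataclass(frozen=True)
class AttributeDefinition:
    """Vocabulary entry: an attribute name, its arity and its category."""
    name: str
    params: tuple[str, ...]     # ordered kinds from PARAM_KINDS
    category: str

    def __post_init__(self):
        if self.category not in CATEGORY_FAMILY:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        for kind in self.params:
            if kind not in PARAM_KINDS:
                raise ValueError(f"unknown param kind {kind!r} in {self.name}")
        variadic = [k for k in self.params if k in ("vertices", "nodes")]
        if variadic and self.params[-1] not in ("vertices", "nodes"):
            raise ValueError(f"variadic param must come last in {self.name}")

    @property
    def family(self) -> str:
        return CATEGORY_FAMILY[self.category]


@dataclass(frozen=True)
class Vocabulary:
    definitions: dict[str, AttributeDefinition]

    def __contains__(self, name: str) -> bool:
        return name in self.definitions

    def __getitem__(self, name: str) -> AttributeDefinition:
        return self.definitions[name]


@dataclass(frozen=True)
class ValueEncoding:
    """Chromosome binding ``{bit_start, bit_end, lower, upper}`` for one
    tunable scalar parameter."""
    bit_start: int
    bit_end: int
    lower: float
    upper: float

    def __post_init__(self):
        if self.bit_end < self.bit_start or self.bit_start < 0:
            raise ValueError(f"invalid bit range [{self.bit_start}, {self.bit_end}]")
        if self.upper < self.lower:
            raise ValueError(f"bounds out of order [{self.lower}, {self.upper}]")

    @property
    def n_bits(self) -> int:
        return self.bit_end - self.bit_start + 1

    @property
    def n_values(self) -> int:
        return 2 ** self.n_bits


@dataclass(frozen=True)
class Attribute:
    """One attribute line: a vocabulary definition plus its parameter values.

    ``params`` holds node names (str), scalars (float), a word token (str),
    a tuple of node names, or a FuzzyFunction for a vertex list.
    ``encodings`` maps param index -> ValueEncoding for tunable scalars.
    """
    definition: AttributeDefinition
    params: tuple
    encodings: dict[int, ValueEncoding] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.definition.name

    def node_refs(self) -> tuple[str, ...]:
        """Node names referenced by this attribute, in parameter order."""
        refs = []
        for kind, value in zip(self.definition.params, self.params):
            if kind == "node":
                refs.append(value)
            elif kind == "nodes":
                refs.extend(value)
        return tuple(refs)


@dataclass(frozen=True)
class SNNode:
    name: str
    attributes: tuple[Attribute, ...]
    source_file: str = ""

    def attrs(self, name: str) -> tuple[Attribute, ...]:
        return tuple(a for a in self.attributes if a.name == name)

    def attr(self, name: str) -> Attribute | None:
        found = self.attrs(name)
        return found[0] if found else None


@dataclass(frozen=True)
class SemanticNetwork:
    """A validated knowledge base: ordered nodes plus the vocabulary."""
    nodes: tuple[SNNode, ...]
    vocabulary: Vocabulary

    def __post_init__(self):
        names = [n.name for n in self.nodes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise KBParseError(f"duplicate node names: {sorted(dupes)}")
        known = set(names)
        for node in self.nodes:
            for attr in node.attributes:
                for ref in attr.node_refs():
                    if ref not in known:
                        raise KBParseError(
                            f"node {node.name!r}: attribute {attr.name} references "
                            f"unknown node {ref!r}")

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    def node(self, name: str) -> SNNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def edges(self) -> tuple[tuple[str, str, str], ...]:
        """Directed dependency links (dependent, referenced, attribute name)."""
        out = []
        for node in self.nodes:
            for attr in node.attributes:
                for ref in attr.node_refs():
                    out.append((node.name, ref, attr.name))
        return tuple(out)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for src, dst, attr in self.edges():
            g.add_edge(src, dst, attribute=attr)
        return g


# ---------------------------------------------------------------------------
# vocabulary loading

def load_vocabulary(path: str | Path | None = None) -> Vocabulary:
    """Load an attribute vocabulary; the packaged default when path is None."""
    if path is None:
        text = (resources.files("cognimage") / "data" / "vocabulary.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    defs = {}
    for rec in raw["attributes"]:
        d = AttributeDefinition(name=rec["name"],
                                params=tuple(rec.get("params") or ()),
                                category=rec["category"])
        if d.name in defs:
            raise KBParseError(f"duplicate vocabulary entry {d.name!r}")
        defs[d.name] = d
    return Vocabulary(defs)


# ---------------------------------------------------------------------------
# parsing

_BRACE_RE = re.compile(r"\{[^{}]*\}")
_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?(cm|mm)?$")


def _parse_scalar(token: str, where: str) -> float:
    m = _NUM_RE.match(token)
    if not m:
        raise KBParseError(f"{where}: expected a number, got {token!r}")
    value = float(token[: len(token) - len(m.group(3) or "")])
    if m.group(3) == "cm":
        value *= 10.0
    return value


def _parse_encoding(token: str, where: str) -> ValueEncoding:
    body = token.strip()[1:-1]
    parts = [p.strip() for p in body.split(",")]
    if len(parts) != 4:
        raise KBParseError(f"{where}: malformed value-encoding {token!r} "
                           "(need {{start_bit, end_bit, lower, upper}})")
    try:
        a, b = int(parts[0]), int(parts[1])
        lo, hi = float(parts[2]), float(parts[3])
        return ValueEncoding(a, b, lo, hi)
    except ValueError as exc:
        raise KBParseError(f"{where}: malformed value-encoding {token!r}: {exc}") from exc


def _tokenize(line: str) -> list[str]:
    """Split a line into tokens, keeping brace groups as single tokens."""
    groups: list[str] = []

    def stash(m):
        groups.append(m.group(0))
        return f" \x00{len(groups) - 1}\x00 "

    line = _BRACE_RE.sub(stash, line)
    if "{" in line or "}" in line:
        raise KBParseError(f"unbalanced braces in line: {line.strip()!r}")
    tokens = []
    for tok in line.split():
        if tok.startswith("\x00"):
            tokens.append(groups[int(tok.strip("\x00"))])
        else:
            tokens.append(tok)
    return tokens


def parse_attribute_line(line: str, vocabulary: Vocabulary, where: str) -> Attribute:
    tokens = _tokenize(line)
    name, rest = tokens[0], tokens[1:]
    if name not in vocabulary:
        raise KBParseError(f"{where}: unknown attribute name {name!r}")
    definition = vocabulary[name]

    params: list = []
    encodings: dict[int, ValueEncoding] = {}
    i = 0
    for kind in definition.params:
        if kind in ("node", "word"):
            if i >= len(rest):
                raise KBParseError(f"{where}: {name} missing parameter {len(params) + 1}")
            params.append(rest[i]); i += 1
        elif kind == "scalar":
            if i >= len(rest):
                raise KBParseError(f"{where}: {name} missing parameter {len(params) + 1}")
            params.append(_parse_scalar(rest[i], where)); i += 1
            if i < len(rest) and rest[i].startswith("{"):
                encodings[len(params) - 1] = _parse_encoding(rest[i], where)
                i += 1
        elif kind == "nodes":
            names = tuple(rest[i:])
            if len(names) < 2:
                raise KBParseError(f"{where}: {name} needs at least 2 node operands")
            params.append(names); i = len(rest)
        elif kind == "vertices":
            values = [_parse_scalar(t, where) for t in rest[i:]]
            if len(values) < 2 or len(values) % 2:
                raise KBParseError(f"{where}: {name} needs value/confidence pairs")
            pairs = tuple(zip(values[0::2], values[1::2]))
            try:
                params.append(FuzzyFunction(pairs))
            except ValueError as exc:
                raise KBParseError(f"{where}: {name}: {exc}") from exc
            i = len(rest)
    if i < len(rest):
        raise KBParseError(f"{where}: {name} has trailing tokens {rest[i:]!r}")
    return Attribute(definition, tuple(params), encodings)


def _strip_comment(line: str) -> str:
    pos = line.find("#")
    return line if pos < 0 else line[:pos]


def parse_node_file(path: Path, name: str, vocabulary: Vocabulary) -> SNNode:
    attributes = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        where = f"{path.name}:{lineno}"
        attributes.append(parse_attribute_line(line, vocabulary, where))
    return SNNode(name=name, attributes=tuple(attributes), source_file=str(path))


def parse_network(node_list_path: str | Path,
                  vocabulary: Vocabulary | None = None) -> SemanticNetwork:
    """Parse a knowledge base starting from its Node List file.

    ``node_list_path`` may be the Node List file itself or the knowledge-base
    directory containing a file named ``node_list``.  Each listed node must
    have an attribute file of the same name in the same directory.
    """
    path = Path(node_list_path)
    if path.is_dir():
        path = path / NODE_LIST_FILENAME
    if not path.is_file():
        raise KBParseError(f"node list file not found: {path}")
    vocabulary = vocabulary or load_vocabulary()

    names = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = _strip_comment(raw).strip()
        if line:
            names.append(line.split()[0])
    nodes = []
    for name in names:
        node_path = path.parent / name
        if not node_path.is_file():
            raise KBParseError(f"missing node file for node {name!r} "
                               f"(expected {node_path})")
        nodes.append(parse_node_file(node_path, name, vocabulary))
    return SemanticNetwork(nodes=tuple(nodes), vocabulary=vocabulary)


# ---------------------------------------------------------------------------
# writing

def _format_num(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


def format_attribute(attr: Attribute) -> str:
    parts = [attr.name]
    for idx, (kind, value) in enumerate(zip(attr.definition.params, attr.params)):
        if kind in ("node", "word"):
            parts.append(value)
        elif kind == "scalar":
            parts.append(_format_num(value))
            if idx in attr.encodings:
                e = attr.encodings[idx]
                parts.append("{%d, %d, %s, %s}" % (e.bit_start, e.bit_end,
                                                   _format_num(e.lower),
                                                   _format_num(e.upper)))
        elif kind == "nodes":
            parts.extend(value)
        elif kind == "vertices":
            for x, c in value.vertices:
                parts.extend([_format_num(x), _format_num(c)])
    return " ".join(parts)


def write_network(net: SemanticNetwork, directory: str | Path) -> Path:
    """Write a knowledge base back to text files; parse(write(net)) == net."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / NODE_LIST_FILENAME).write_text(
        "".join(f"{n.name}\n" for n in net.nodes), encoding="utf-8")
    for node in net.nodes:
        lines = [format_attribute(a) for a in node.attributes]
        (directory / node.name).write_text("".join(f"{l}\n" for l in lines),
                                           encoding="utf-8")
    return directory


# ---------------------------------------------------------------------------
# tunable parameters and graph summary

@dataclass(frozen=True)
class TunableParameter:
    node: str
    attribute: str
    param_index: int
    encoding: ValueEncoding


def list_tunable_parameters(net: SemanticNetwork) -> list[TunableParameter]:
    """All value-encoded parameters, sorted by chromosome bit start.

    Raises KBParseError when two encodings claim the same bit.
    """
    tunables = []
    for node in net.nodes:
        for attr in node.attributes:
            for idx, enc in sorted(attr.encodings.items()):
                tunables.append(TunableParameter(node.name, attr.name, idx, enc))
    tunables.sort(key=lambda t: (t.encoding.bit_start, t.encoding.bit_end))
    for a, b in zip(tunables, tunables[1:]):
        if b.encoding.bit_start <= a.encoding.bit_end:
            raise KBParseError(
                "overlapping chromosome bits: "
                f"{a.node}.{a.attribute}[{a.param_index}] bits "
                f"{a.encoding.bit_start}-{a.encoding.bit_end} and "
                f"{b.node}.{b.attribute}[{b.param_index}] bits "
                f"{b.encoding.bit_start}-{b.encoding.bit_end}")
    return tunables


def chromosome_span(net: SemanticNetwork) -> int:
    """Number of chromosome bits required: max(bit_end) + 1 (0 when untuned)."""
    tunables = list_tunable_parameters(net)
    return max((t.encoding.bit_end for t in tunables), default=-1) + 1


def summarize_graph(net: SemanticNetwork) -> tuple[tuple[tuple[str, str, str], ...], str]:
    """Deterministic edge list plus a text report of the network."""
    edges = net.edges()
    tunables = list_tunable_parameters(net)
    lines = [
        f"nodes: {len(net.nodes)}",
        f"edges: {len(edges)}",
        f"tunable parameters: {len(tunables)} (chromosome span {chromosome_span(net)} bits)",
        "",
    ]
    for src, dst, attr in edges:
        lines.append(f"{src} -> {dst} [{attr}]")
    return edges, "\n".join(lines) + "\n"


def replace_param(net: SemanticNetwork, node: str, attribute: str,
                  param_index: int, value: float,
                  clear_encoding: bool = True) -> SemanticNetwork:
    """Return a new network with one scalar parameter replaced."""
    new_nodes = []
    for n in net.nodes:
        if n.name != node:
            new_nodes.append(n)
            continue
        new_attrs = []
        done = False
        for a in n.attributes:
            if a.name == attribute and param_index in a.encodings and not done:
                params = list(a.params)
                params[param_index] = float(value)
                encodings = dict(a.encodings)
                if clear_encoding:
                    encodings.pop(param_index)
                new_attrs.append(Attribute(a.definition, tuple(params), encodings))
                done = True
            else:
                new_attrs.append(a)
        if not done:
            raise KeyError(f"no tunable {attribute}[{param_index}] on node {node}")
        new_nodes.append(replace(n, attributes=tuple(new_attrs)))
    return SemanticNetwork(nodes=tuple(new_nodes), vocabulary=net.vocabulary)
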