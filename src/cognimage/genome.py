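"""Binary chromosomes over tunable knowledge-base parameters.

Every tunable scalar parameter in a semantic network carries a value
encoding ``{bit_start, bit_end, lower, upper}``.  The bits of a fixed-length
binary chromosome, read as an unsigned index over that range, select one of
``2**n_bits`` candidate values spaced equidistantly between the bounds
(inclusive): all-zeros decodes to the lower bound, all-ones to the upper.
Applying a chromosome to a network substitutes every tunable parameter with
its decoded value, yielding a fully specified knowledge base.

Bit positions are 0-based inclusive indices into the chromosome.  Unused bits
between genes are permitted and ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .kb import (SemanticNetwork, ValueEncoding, chromosome_span,
                 list_tunable_parameters, replace_param)

__all__ = ["Chromosome", "ParameterSet", "decode_gene", "decoded_values",
           "apply_chromosome", "random_chromosome"]


@dataclass(frozen=True)
class Chromosome:
    """Fixed-length bit string."""
    bits: str

    def __post_init__(self):
        if not self.bits or set(self.bits) - {"0", "1"}:
            raise ValueError(f"chromosome must be a non-empty 0/1 string, got {self.bits!r}")

    def __len__(self) -> int:
        return len(self.bits)

    def gene(self, enc: ValueEncoding) -> str:
        if enc.bit_end >= len(self.bits):
            raise ValueError(
                f"chromosome length {len(self.bits)} does not cover bits "
                f"{enc.bit_start}-{enc.bit_end}")
        return self.bits[enc.bit_start: enc.bit_end + 1]


#: map (node, attribute, param_index) -> decoded scalar
ParameterSet = dict


def decode_gene(bits: str, enc: ValueEncoding) -> float:
    """Decode a gene substring to its equidistant candidate value.

    The candidate set has ``2**n`` values between ``enc.lower`` and
    ``enc.upper`` inclusive; the bit pattern is an unsigned index into it.
    Grid points are computed as exact rationals, then rendered to float.
    """
    if len(bits) != enc.n_bits:
        raise ValueError(f"gene needs {enc.n_bits} bits, got {len(bits)} ({bits!r})")
    if set(bits) - {"0", "1"}:
        raise ValueError(f"gene must be binary, got {bits!r}")
    index = int(bits, 2)
    n = enc.n_values
    if n == 1 or enc.lower == enc.upper:
        return float(enc.lower) if index == 0 else float(enc.upper)
    step = Fraction(enc.upper - enc.lower) / (n - 1)
    return float(Fraction(enc.lower) + index * step)


def decoded_values(enc: ValueEncoding) -> tuple[float, ...]:
    """The full candidate set of an encoding, in index order."""
    return tuple(decode_gene(format(i, f"0{enc.n_bits}b"), enc)
                 for i in range(enc.n_values))


def apply_chromosome(net: SemanticNetwork,
                     chrom: Chromosome | str | None) -> tuple[ParameterSet, SemanticNetwork]:
    """Specify a network: replace each tunable parameter by its decoded value.

    Returns the parameter set and the specified network (no active encodings
    remain).  A network with no encodings passes through unchanged; a
    chromosome shorter than the required bit span is an error.
    """
    tunables = list_tunable_parameters(net)
    if not tunables:
        return {}, net
    if chrom is None:
        raise ValueError(f"network has {len(tunables)} tunable parameters "
                         "but no chromosome was given")
    if isinstance(chrom, str):
        chrom = Chromosome(chrom)
    span = chromosome_span(net)
    if len(chrom) < span:
        raise ValueError(f"chromosome length {len(chrom)} < required span {span}")
    assignments: ParameterSet = {}
    specified = net
    for t in tunables:
        value = decode_gene(chrom.gene(t.encoding), t.encoding)
        assignments[(t.node, t.attribute, t.param_index)] = value
        specified = replace_param(specified, t.node, t.attribute, t.param_index, value)
    return assignments, specified


def random_chromosome(length: int, seed: int | np.random.Generator) -> Chromosome:
    """Uniform random bit string; deterministic for a fixed seed."""
    if length <= 0:
        raise ValueError(f"chromosome length must be positive, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=length)
    return Chromosome("".join("1" if b else "0" for b in bits))
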