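"""BNF grammars and grammatical-evolution genotype-to-phenotype mapping.

A genotype is a variable-length string of 8-bit codons. Mapping expands the
grammar's start symbol by always rewriting the leftmost non-terminal; at each
choice point the production picked is ``codon mod n_productions``, consuming
codons left to right and wrapping back to the first codon a bounded number of
times. If non-terminals remain when the wrap budget is spent, the genotype is
invalid — invalidity is a value (``MappingResult.expression is None``), not an
exception.

Rule order and production order are exactly those of the grammar file, since
the codon arithmetic depends on them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "Grammar",
    "GrammarError",
    "Genotype",
    "MappingResult",
    "load_grammar",
    "load_default_grammar",
    "map_genotype",
    "random_genotype",
]

_LAMBDA_TOKENS = {"λ", "<lambda>", "lambda"}
#: Cap on derivation length; recursive rules driven by a wrapped genotype can
#: grow without bound, so a derivation exceeding this is declared invalid.
_MAX_SYMBOLS = 4000


class GrammarError(ValueError):
    """Malformed grammar text or reference to an undefined non-terminal."""


@dataclass(frozen=True)
class _NT:
    """A non-terminal occurrence in a production."""

    name: str

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"[{self.name}]"


@dataclass
class Grammar:
    """Ordered production rules: non-terminal -> list of productions.

    Each production is a tuple of symbols; a symbol is either a terminal
    string or a non-terminal reference. The empty tuple is the λ production.
    """

    rules: dict[str, list[tuple]]
    start: str

    def __post_init__(self) -> None:
        if self.start not in self.rules:
            raise GrammarError(f"start symbol [{self.start}] has no rule")
        for lhs, prods in self.rules.items():
            if not prods:
                raise GrammarError(f"rule [{lhs}] has no productions")
            for prod in prods:
                for sym in prod:
                    if isinstance(sym, _NT) and sym.name not in self.rules:
                        raise GrammarError(
                            f"production of [{lhs}] references undefined "
                            f"non-terminal [{sym.name}]")

    def __len__(self) -> int:
        return len(self.rules)


_RULE_RE = re.compile(r"^\s*\[([^\]\[]+)\]\s*(?:::=|→|->)\s*(.*)$")
_NT_RE = re.compile(r"\[([^\]\[]+)\]")


def _parse_production(text: str) -> tuple:
    """Split one production into terminal chunks and non-terminal refs.

    Whitespace is insignificant; λ yields the empty production.
    """
    text = text.strip()
    if text in _LAMBDA_TOKENS or not text:
        return ()
    syms: list = []
    pos = 0
    for m in _NT_RE.finditer(text):
        lit = "".join(text[pos:m.start()].split())
        if lit:
            syms.append(lit)
        syms.append(_NT(m.group(1)))
        pos = m.end()
    lit = "".join(text[pos:].split())
    if lit:
        syms.append(lit)
    return tuple(syms)


def load_grammar(text: str, start: str | None = None) -> Grammar:
    """Parse BNF text into a :class:`Grammar`.

    Rules use ``[symbol] ::= alt | alt`` (``→`` also accepted); a rule's
    right-hand side may continue over following lines until the next rule.
    Lines starting with ``#`` are comments. The first rule is the start
    symbol unless ``start`` is given.
    """
    rules: dict[str, list[tuple]] = {}
    current: str | None = None
    pending: list[str] = []

    def flush() -> None:
        if current is None:
            return
        rhs = " ".join(pending)
        prods = [_parse_production(p) for p in rhs.split("|")]
        if current in rules:
            raise GrammarError(f"duplicate rule for [{current}]")
        rules[current] = prods

    for line in text.splitlines():
        if line.strip().startswith("#"):
            continue
        m = _RULE_RE.match(line)
        if m:
            flush()
            current = m.group(1)
            pending = [m.group(2)]
        elif line.strip():
            if current is None:
                raise GrammarError(f"text before first rule: {line.strip()!r}")
            pending.append(line.strip())
    flush()
    if not rules:
        raise GrammarError("no rules found")
    return Grammar(rules=rules, start=start or next(iter(rules)))


def load_default_grammar() -> Grammar:
    """The shipped glucose grammar (``data/glucose.bnf``)."""
    text = resources.files("glucoge.data").joinpath("glucose.bnf").read_text()
    return load_grammar(text)


@dataclass(frozen=True)
class Genotype:
    """Variable-length sequence of 8-bit codons."""

    codons: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.codons) < 1:
            raise ValueError("genotype needs at least one codon")
        if any(not (0 <= c <= 255) for c in self.codons):
            raise ValueError("codons must be integers in [0, 255]")

    def __len__(self) -> int:
        return len(self.codons)


@dataclass
class MappingResult:
    """Outcome of genotype-to-phenotype mapping.

    ``phenotype`` is the derived terminal string, or ``None`` when the wrap
    budget (or the derivation-size cap) was exhausted with non-terminals
    remaining. ``codons_consumed`` counts codon draws including re-reads
    after wrapping.
    """

    phenotype: str | None
    codons_consumed: int
    wraps_used: int

    @property
    def valid(self) -> bool:
        return self.phenotype is not None


def map_genotype(genotype: Genotype, grammar: Grammar, max_wraps: int = 2) -> MappingResult:
    """Standard GE leftmost derivation under ``grammar``.

    ``max_wraps`` counts additional passes over the codon string beyond the
    first read; rules with a single production consume no codon (they are
    not choice points).
    """
    codons = genotype.codons
    idx = 0
    wraps = 0
    consumed = 0
    symbols: list = [_NT(grammar.start)]
    out: list[str] = []

    while symbols:
        sym = symbols.pop(0)
        if not isinstance(sym, _NT):
            out.append(sym)
            continue
        prods = grammar.rules[sym.name]
        if len(prods) == 1:
            choice = 0
        else:
            if idx >= len(codons):
                if wraps >= max_wraps:
                    return MappingResult(None, consumed, wraps)
                wraps += 1
                idx = 0
            choice = codons[idx] % len(prods)
            idx += 1
            consumed += 1
        symbols[:0] = prods[choice]
        if len(symbols) > _MAX_SYMBOLS:
            return MappingResult(None, consumed, wraps)
    return MappingResult("".join(out), consumed, wraps)


def random_genotype(rng: np.random.Generator, min_len: int = 15,
                    max_len: int = 100) -> Genotype:
    """Uniform length in [min_len, max_len], uniform codons in [0, 255]."""
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    n = int(rng.integers(min_len, max_len + 1))
    return Genotype(tuple(int(c) for c in rng.integers(0, 256, size=n)))
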